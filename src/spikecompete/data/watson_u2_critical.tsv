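# Critical values of Watson's two-sample U^2 statistic.
# Asymptotic null distribution P(U^2 > u) = 2*sum_{k>=1} (-1)^(k-1) exp(-2 k^2 pi^2 u)
# (Watson, Biometrika 49:57-63, 1962); values solve P(U^2 > u) = alpha.
alpha	critical_value
0.05	0.1869
0.01	0.2684
0.001	0.3851
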