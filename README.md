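# spikecompete

Winner-take-all competition among cortical neurons can emerge without any
built-in asymmetry: in a sparse recurrent network of spiking neurons, the
interplay of spontaneously generated population oscillation, axonal
conduction delays, and spike timing-dependent plasticity (STDP) is enough to
split the excitatory population into a *winner* assembly (many strong
afferent synapses, weak efferents) and a *loser* assembly with the opposite
profile. `spikecompete` simulates that system and ships the complete
analysis chain needed to detect, quantify, and dissect the competition. It
is aimed at computational neuroscientists studying self-organization under
STDP and at anyone who needs a fast, reproducible delayed-STDP network
simulator with a serious statistics layer.

## Model

The network has N = 1000 Izhikevich neurons (800 regular-spiking excitatory,
200 fast-spiking inhibitory), randomly connected with probability 0.1 (no
self- or inhibitory-to-inhibitory connections):

```
v' = 0.04 v^2 + 5 v + 140 - u + I(t)
u' = a (b v - u),        with v <- c, u <- u + d  when v >= 30 mV
```

Synapses are delta pulses: a somatic spike of neuron *i* adds the signed
weight w_ij to neuron *j*'s input current exactly one conduction delay later
(1–10 ms, uniform, for excitatory axons; 1 ms for inhibitory). Every neuron
also receives an independent Poisson spike train (rate *f*, 20 mV per
spike). E→E synapses are plastic under the additive, hard-bound STDP window

```
dw = { +lambda exp(-|dt|/tau)           dt > 0   (LTP)
     { -alpha lambda exp(-|dt|/tau)     otherwise (LTD)
```

with lambda = 0.1 mV, alpha = 1.2, tau = 20 ms, w in [0, w_max = 10 mV], and
dt = t_post − t_arrival measured against the *presynaptic-terminal arrival
time* (somatic spike + axonal delay) — the detail that makes the delay
composition of a neuron's afferents decide its fate. Derivatives accumulate
per firing event (nearest-neighbor pairing by default); weights commit once
per second with a small activity-independent drift.

The analysis layer implements in/out strengths (s = Σ w / w_max), joint
strength distribution matrices, the edge-end strength-correlation
coefficients r_in / r_out (negative = disassortative = competition),
winner/loser identification and stability, delay-resolved synapse
statistics, oscillation phase via negative-peak anchoring of the 35-Hz
low-pass-filtered population rate, phase-gap distributions, Kendall's tau
(counting construction) and Watson's two-sample U² for circular data.

## Worked example

Run the 10-spk/s baseline for 1200 simulated seconds (~20 s of wall time;
the strength correlations are converged by ~1000 s) and summarize it:

```python
from spikecompete.pipeline import RECIPES, run_recipe, summarize_run

rec = run_recipe(RECIPES["baseline_10hz"]()[0], seed=1, duration_s=1200)
summary = summarize_run(rec)
for key, value in summary.items():
    print(f"{key:>28}: {value:.4f}" if isinstance(value, float) else f"{key:>28}: {value}")
```

prints

```
                r_in_plateau: -0.0985
                     r_in_sd: 0.0043
               r_out_plateau: -0.1158
                    r_out_sd: 0.0047
         mean_weight_plateau: 1.6426
              max_switch_pct: 0.3750
                   n_winners: 297
                    n_losers: 503
      tau_exc_presyn_vs_s_in: 0.2554
      tau_inh_presyn_vs_s_in: -0.3293
         watson_u2_phase_gap: 3.2072
        watson_u2_p_lt_0.001: True
```

Reading it: both strength correlations settle clearly negative
(r_in ≈ −0.10, r_out ≈ −0.12) — connected neurons have dissimilar
strengths, the signature of two competing assemblies (297 winners, 503
losers here). The mean plastic weight has decayed from its initial 6 mV to
a ≈1.6-mV plateau with a bimodal weight distribution. Assembly membership
is stable (at most 0.375% of excitatory neurons switch sides per second).
The afferent-count correlations are weak (tau ≈ 0.26 / −0.33), so who wins
is *not* decided by how many inputs a neuron happens to have — it is
decided by its afferent delays: winners' presynaptic volleys hug the global
oscillation peak, and their phase-gap distribution differs from the losers'
far beyond the U² critical value at alpha = 0.001 (0.385).

The same machinery is scriptable from the shell:

```sh
spikecompete run baseline_10hz --seed 1 --duration-s 1200 --out runs/b10
spikecompete summarize runs/b10
spikecompete stats u2 winner_phases.tsv loser_phases.tsv
```

Recipes: `baseline_1hz`, `baseline_10hz`, `baseline_40hz`, `sweep_wmax`,
`sweep_alpha_inhibition`, `init_distributions`, `all_to_all`. Pass
`--full` for the original 3600-s protocol.

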