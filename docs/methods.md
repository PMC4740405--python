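# Methods

## Model and integration

Neurons follow the two-variable Izhikevich equations with the
regular-spiking preset (a = 0.02, b = 0.2, c = −65, d = 8) for the 800
excitatory cells and the fast-spiking preset (a = 0.1, b = 0.2, c = −65,
d = 2) for the 200 inhibitory cells. The simulation lives on a 1-ms event
grid; within each millisecond the order is fixed:

1. external Poisson input (Bernoulli thinning at f/1000 per bin, +20 mV of
   current per input spike, identical statistics for E and I cells);
2. delayed synaptic deliveries — each delivery adds its full signed weight
   to the target's input current for exactly this one step (delta-pulse
   synapse), and, on plastic synapses, counts as a presynaptic-terminal
   arrival for STDP;
3. two 0.5-ms forward-Euler substeps of (v, u) under the constant step
   current; if v crosses 30 mV in the first substep the second is skipped,
   so a super-threshold v is never integrated further;
4. spike detection and reset (v ← c, u ← u + d) within the same step; each
   somatic spike schedules one delivery per efferent synapse at t + delay;
5. STDP bookkeeping for this step's postsynaptic spikes.

The step size is not part of the model contract; 0.5-ms substeps on a 1-ms
event grid keep spikes aligned with the integer axonal delays while
resolving the quadratic upstroke acceptably. Neurons start at
v = −65 mV, u = b·v. Non-finite membrane potentials abort the run with the
time and neuron id; they do not occur under the study conditions.

Simulations are deterministic given their seeds. A master seed is split
(via `SeedSequence`) into independent streams for the adjacency draw, the
delay draw, the initial-weight draw, and the Poisson drive, so sweeps can
vary one random factor at a time.

## STDP conventions

The window is additive with hard bounds [0, w_max]: LTP = λ·exp(−Δt/τ) for
Δt > 0, LTD = −αλ·exp(−|Δt|/τ) otherwise, with Δt = t_post − t_arrival and
the arrival time = somatic spike time + axonal delay of that synapse.
Derivatives (`sd`) change at firing events; weights commit once per second
as w ← clip(w + 0.01 + sd, 0, w_max), then sd ← 0.9·sd (add-then-decay).
The +0.01 mV/s drift and the 0.9 decay are the standard bookkeeping of the
delayed-STDP network scheme this model family uses; both are exposed in
`STDPConfig`.

Two timing conventions deserve explicit statement because the 1-ms grid
forces a choice that continuous-time formulas leave open:

- **Causal same-bin pairs.** An arrival that lands in the same millisecond
  in which the postsynaptic neuron crosses threshold happened *before* the
  spike it helped cause, so the simulator scores it on the potentiation
  branch at Δt → 0⁺ (full λ). Scoring it as Δt = 0 → LTD instead (the
  literal reading of the window's "otherwise") destroys the phenomenon:
  the most common causally ordered pairing then carries the largest
  depression in the rule, the weight distribution loses its upper-bound
  mode, and no competition develops. The scalar window function
  `stdp_delta` keeps the literal convention (Δt = 0 on the LTD branch);
  the event accumulators accept either convention via the `coincident`
  argument.
- **Nearest-neighbor pairing** is immediate-predecessor pairing: an event
  pairs with the most recent opposite event only if no event of its own
  kind intervened. (The alternative "reset trace" variant, where every
  post pairs with the latest arrival regardless of intervening posts,
  produces slightly weaker competition; the immediate-predecessor rule
  reproduces the reference values better and is the package contract.)
  All-to-all mode pairs every event with every earlier opposite event via
  exponentially decaying traces and equals the brute-force double loop to
  machine precision.

## Network statistics

Degrees and strengths are computed on the E→E subnetwork; a synapse counts
while w > 0 ("surviving") and disappears from degrees, edge-end
correlations, and delay statistics once it reaches the lower bound.
Strengths are sums of w/w_max. The strength-correlation coefficients are
Pearson correlations over surviving directed edges between the tail's and
the head's strength; the normalization uses standard deviations (the
printed definition of the denominators omits the square root, which would
not keep the coefficient in [−1, 1]). Degenerate cases (fewer than two
surviving edges, or zero variance at either end) raise rather than return
a silent 0.

**Winner/loser identification** follows the descending-instrength
threshold procedure: sort excitatory neurons by s_in descending; the first
neuron whose s_in does not exceed its s_out starts the loser assembly and
every neuron from it onward is a loser (ties sit on the loser side; if no
neuron qualifies, all are winners). This is the rule behind all
group-composition analyses.

**Stability** is counted on per-neuron margin labels (winner ⟺
s_in > s_out) instead. The threshold rule's label map is discontinuous: a
single diagonal-straddling neuron high in the ranking relabels a whole
contiguous block of ranks in one second, so per-second membership-change
counts under it measure threshold jitter (tens of neurons in occasional
seconds) rather than actual movement between assemblies. The margin rule
is continuous in each neuron's own strengths, agrees with the threshold
rule for all but the handful of diagonal-straddling neurons, and puts the
per-second maximum at 2–3 neurons of 800 — the scale of membership change
the stability result is about.

**Delay statistics** report, per group, the mean fraction of a neuron's
surviving afferents at each delay 1–10 ms (each neuron's fractions sum
to 1) and the mean surviving weight per delay. In converged
10-spk/s runs the loser curve rises again slightly at 9–10 ms; those
sparse bins carry the preferentially strengthened winner→loser synapses,
so the package treats "weight falls with delay" as: the 1-ms bin is the
maximum and the rank trend across bins is strongly negative, rather than
bin-by-bin monotonicity.

## Rates, phase, and phase gaps

Firing rates are forward-boxcar estimates: rate(t) = spikes in
[t, t + 10 ms) / 10 ms, in spk/s; population rates average member rates.
Presynaptic-terminal rates shift every afferent somatic spike by its
synapse's delay before the same estimate and average over the afferent
terminal set (the topological E→E afferents by default; a
`surviving_weights` argument restricts to live synapses — immaterial in
the default 5–50-s analysis window, where almost all synapses survive).

Phase is deliberately not a Hilbert phase: the population rate is low-pass
filtered (order-4 Butterworth, 35-Hz cutoff, forward–backward so the
filter adds no delay), strict local minima over a ±3-ms neighborhood
anchor the phase at −π, and the phase ramps linearly to +π at the next
anchor, putting the positive peak near 0. Phase-gap distributions assign
each local maximum of a neuron's filtered presynaptic rate the global
phase at that time; spike-phase distributions do the same with the
neuron's own spikes against its presynaptic oscillation. Group-level
comparisons pool the phase samples of 20 sampled neurons per group before
the U² test — the group claim concerns the mean distributions, and single
neurons rarely carry enough maxima in 45 s to reach the 0.001 level.

## Non-parametric statistics

Kendall's tau uses the P/Q counting construction (concordant minus
discordant over pairs, denominator m(m−1)/2); pairs tied in either
coordinate are excluded from the counts but not the denominator, so heavy
tying shrinks tau toward 0 (tau-a-like). `scipy.stats.kendalltau` serves
only as a cross-check in the tests (the two agree exactly on tie-free
data).

Watson's two-sample U² builds d_k as the running ECDF difference
i/m1 − j/m2 along the ascending merge of both samples (ties advance the
second sample first) and returns U² = (m1·m2/M²)·Σ(d_k − d̄)². The
statistic is invariant under common rotation of both samples. Significance
is read from a packaged table of asymptotic critical values (0.1869,
0.2684, 0.3851 at α = 0.05, 0.01, 0.001), computed from the series
P(U² > u) = 2·Σ_k (−1)^(k−1) exp(−2k²π²u); the null rejection rate is
verified at α = 0.05 in the test suite.

## Synthetic data and what the tests show

All inputs are generated: random topologies per the recipe above, Poisson
drive, and three hand-checkable micro-fixtures (`chain3`, `star5`,
`loop4`) whose exact weights and delays are printed in their docstrings
and serve as oracles for every network statistic. The generator emulates
the study conditions (1000 neurons, 4:1 E:I, p = 0.1, delays 1–10 ms,
w_init = 6/−5 mV, f ∈ {1, 10, 40} spk/s) — not real cortex: there is no
spatial embedding (delays are independent of any distance), no synaptic
time constants, no heterogeneity in neuron parameters, and input trains
are homogeneous Poisson. Passing tests therefore show that the
*mechanism* — oscillation + delays + STDP ⇒ stable two-assembly
competition — is reproduced under the stated model, not that real tissue
behaves this way.

## Problem sizes and defaults

Converged analyses use 1200 simulated seconds (the strength correlations
are converged by ~1000 s; plateau statistics are means over the final
100 s, and the stability maximum is taken over that window). The original
protocol length of 3600 s is available everywhere (`--full`, or
`duration_s=3600`) and gives the same plateaus. The
oscillation/phase analyses use t ∈ [5, 50] s, where the oscillation is
strong and the synapse population still largely intact.

## Known limitations

- The 1-spk/s regime reproduces the *qualitative* results (near-zero
  correlations, no competition, oscillation dying out) but its mean-weight
  plateau settles near 3.2 mV rather than ~2 mV; the value is stable from
  300 s through 3600 s. The 10-spk/s plateau (~1.65 mV) and every other
  reported quantity are reproduced.
- Spike times are quantized to 1 ms; sub-millisecond timing effects are
  outside the model.
- The U² significance table is asymptotic; for samples of a few dozen the
  0.05-level calibration is verified, but very small samples should be
  interpreted with care.
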