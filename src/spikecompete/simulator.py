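"""Event-driven simulation of the delayed recurrent Izhikevich network.

The network integrates on a 1-ms event grid.  Within each millisecond
the order of operations is fixed:

1. draw the external Poisson input (one 20-mV current pulse per input
   spike, identical statistics for excitatory and inhibitory cells);
2. deliver synaptic pulses whose conduction delay expires this step --
   each delivery adds the full signed weight to the target's input
   current for exactly this step, and (for plastic synapses) counts as
   a presynaptic-terminal arrival for STDP;
3. advance every neuron's (v, u) by two 0.5-ms forward-Euler substeps
   under the constant step current;
4. neurons with v >= 30 mV spike: the spike is recorded, v is reset to
   c and u incremented by d before the next step, and the somatic
   spike schedules one delivery per efferent synapse at t + delay;
5. STDP bookkeeping for the postsynaptic spikes of this step (arrivals
   in the same millisecond pair on the depression branch, dt == 0).

Actual weights change only at 1-second commits (see
:mod:`spikecompete.plasticity`).  Identical seeds give bit-identical
rasters and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from numba import njit

from spikecompete.netgen import EXCITATORY, INHIBITORY, NetworkTopology, NeuronParams
from spikecompete.plasticity import STDPConfig

__all__ = [
    "PoissonDriveConfig",
    "SpikeRaster",
    "SimulationResult",
    "IntegrationBlowUpError",
    "run_simulation",
    "step_neuron",
    "poisson_input_mask",
]

#: Spike detection threshold, mV.
V_PEAK = 30.0
#: Length of the exp(-dt/tau) lookup table used by the kernel (ms).
_LUT_LEN = 1024
#: Ring-buffer length for recent firings; must exceed the largest delay.
_RING = 16


class IntegrationBlowUpError(RuntimeError):
    """Raised when a membrane potential becomes non-finite."""

    def __init__(self, t_ms: int, neuron: int):
        super().__init__(f"non-finite membrane potential at t={t_ms} ms, neuron {neuron}")
        self.t_ms = t_ms
        self.neuron = neuron


@dataclass
class PoissonDriveConfig:
    """Independent per-neuron Poisson drive.

    Each neuron receives an independent Bernoulli-thinned spike train:
    in every 1-ms bin an input spike occurs with probability
    ``rate / 1000`` and contributes ``amplitude`` mV of current for
    that step.  The default 20-mV amplitude is suprathreshold for a
    resting cell.
    """

    rate: float = 10.0
    amplitude: float = 20.0
    seed: int | None = None

    def validate(self) -> None:
        if self.rate < 0:
            raise ValueError(f"rate must be nonnegative, got {self.rate}")
        if self.rate >= 1000.0:
            raise ValueError(
                f"rate must be < 1000 spk/s for 1-ms Bernoulli thinning, got {self.rate}"
            )


@dataclass
class SpikeRaster:
    """Somatic spike events as parallel (time, neuron id) arrays."""

    times: np.ndarray
    ids: np.ndarray
    duration_ms: int
    n_neurons: int

    def __post_init__(self) -> None:
        self.times = np.ascontiguousarray(self.times, dtype=np.int32)
        self.ids = np.ascontiguousarray(self.ids, dtype=np.int32)

    @property
    def n_spikes(self) -> int:
        return len(self.times)

    def window(self, t0_ms: int, t1_ms: int) -> "SpikeRaster":
        """Spikes with ``t0_ms <= t < t1_ms`` (times kept absolute)."""
        lo = np.searchsorted(self.times, t0_ms, side="left")
        hi = np.searchsorted(self.times, t1_ms, side="left")
        return SpikeRaster(self.times[lo:hi], self.ids[lo:hi], self.duration_ms, self.n_neurons)

    def subset(self, neuron_ids) -> "SpikeRaster":
        mask = np.isin(self.ids, np.asarray(neuron_ids))
        return SpikeRaster(self.times[mask], self.ids[mask], self.duration_ms, self.n_neurons)

    def spike_times(self, neuron: int) -> np.ndarray:
        return self.times[self.ids == neuron]

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# duration_ms={self.duration_ms}\tn_neurons={self.n_neurons}\n")
            fh.write("time_ms\tneuron_id\n")
            for t, j in zip(self.times, self.ids):
                fh.write(f"{t}\t{j}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpikeRaster":
        path = Path(path)
        with path.open() as fh:
            meta = dict(
                item.split("=") for item in fh.readline().lstrip("# ").strip().split("\t")
            )
            fh.readline()
            rows = [line.split("\t") for line in fh if line.strip()]
        times = np.array([int(r[0]) for r in rows], dtype=np.int32)
        ids = np.array([int(r[1]) for r in rows], dtype=np.int32)
        return cls(times, ids, int(meta["duration_ms"]), int(meta["n_neurons"]))


@dataclass
class SimulationResult:
    """Outputs of :func:`run_simulation`."""

    raster: SpikeRaster
    weights: np.ndarray  # final per-synapse weights, topology order
    mean_weight_per_s: np.ndarray  # mean plastic weight after each commit
    exc_spikes_per_s: np.ndarray
    inh_spikes_per_s: np.ndarray
    v_final: np.ndarray = field(repr=False, default=None)
    sd_final: np.ndarray = field(repr=False, default=None)

    @property
    def duration_s(self) -> int:
        return len(self.mean_weight_per_s)

    def exc_rate_per_s(self, n_excitatory: int) -> np.ndarray:
        """Mean excitatory firing rate per second, spk/s."""
        return self.exc_spikes_per_s / n_excitatory


# ----------------------------------------------------------------------
# single-neuron reference dynamics (also used by the spec-level tests)
# ----------------------------------------------------------------------

def step_neuron(
    v: float, u: float, params: NeuronParams, current: float, dt: float = 0.5
) -> tuple[float, float, bool]:
    """One 1-ms membrane update made of ``1/dt`` forward-Euler substeps.

    Returns ``(v', u', fired)``.  On firing, v is reset to ``params.c``
    and u incremented by ``params.d`` within the same step, so the
    returned v never carries a value above threshold forward.
    """
    n_sub = round(1.0 / dt)
    if abs(n_sub * dt - 1.0) > 1e-9:
        raise ValueError(f"dt must divide 1 ms, got {dt}")
    for _ in range(n_sub):
        if v >= V_PEAK:  # already at threshold: never integrated further
            break
        dv = 0.04 * v * v + 5.0 * v + 140.0 - u + current
        du = params.a * (params.b * v - u)
        v = v + dt * dv
        u = u + dt * du
    if not np.isfinite(v):
        raise IntegrationBlowUpError(-1, -1)
    if v >= V_PEAK:
        return params.c, u + params.d, True
    return v, u, False


def poisson_input_mask(
    rate: float, n_steps: int, n_neurons: int, rng: np.random.Generator
) -> np.ndarray:
    """Bernoulli spike mask of shape (n_steps, n_neurons) at 1-ms bins."""
    if rate < 0 or rate >= 1000.0:
        raise ValueError(f"rate must be in [0, 1000) spk/s, got {rate}")
    if rate == 0:
        return np.zeros((n_steps, n_neurons), dtype=np.bool_)
    return rng.random((n_steps, n_neurons)) < rate / 1000.0


# ----------------------------------------------------------------------
# numba kernel
# ----------------------------------------------------------------------

@njit(cache=True)
def _run_chunk(
    t0,
    n_steps,
    v,
    u,
    pa,
    pb,
    pc,
    pd,
    n_exc,
    eff_ptr,
    syn_post,
    syn_w,
    syn_plastic,
    syn_sd,
    syn_last_arr,
    aff_ptr,
    aff_syn,
    last_post,
    fired_cnt,
    fired_ids,
    input_mask,
    input_amp,
    stdp_on,
    interaction_all,
    lam,
    alpha,
    exp_lut,
    trace_pre,
    trace_pre_t,
    trace_post,
    trace_post_t,
    spike_t_buf,
    spike_id_buf,
):
    n = v.shape[0]
    n_rec = 0
    blow_t = -1
    blow_j = -1
    current = np.zeros(n)
    for step in range(n_steps):
        t = t0 + step
        # 1. external drive
        for j in range(n):
            current[j] = input_amp if input_mask[step, j] else 0.0
        # 2. delayed deliveries (synapses grouped by (pre, delay))
        for d in range(1, 11):
            src = (t - d) & (_RING - 1)
            cnt = fired_cnt[src]
            for idx in range(cnt):
                i = fired_ids[src, idx]
                for s in range(eff_ptr[i, d - 1], eff_ptr[i, d]):
                    j = syn_post[s]
                    current[j] += syn_w[s]
                    if stdp_on and syn_plastic[s]:
                        if interaction_all:
                            tp = trace_post_t[j]
                            if tp >= 0:
                                ddt = t - tp
                                if ddt < _LUT_LEN:
                                    syn_sd[s] -= alpha * lam * trace_post[j] * exp_lut[ddt]
                            ta = trace_pre_t[s]
                            if ta >= 0:
                                ddt = t - ta
                                dec = exp_lut[ddt] if ddt < _LUT_LEN else 0.0
                                trace_pre[s] = trace_pre[s] * dec + 1.0
                            else:
                                trace_pre[s] = 1.0
                            trace_pre_t[s] = t
                        else:
                            # nearest-neighbor: the last post pairs only if
                            # no other arrival on this synapse intervened
                            lp = last_post[j]
                            if lp >= 0 and lp >= syn_last_arr[s]:
                                ddt = t - lp
                                if ddt < _LUT_LEN:
                                    syn_sd[s] -= alpha * lam * exp_lut[ddt]
                        syn_last_arr[s] = t
        # 3-4. membrane update and spike detection
        slot = t & (_RING - 1)
        fired_cnt[slot] = 0
        for j in range(n):
            vj = v[j]
            uj = u[j]
            cj = current[j]
            dv = 0.04 * vj * vj + 5.0 * vj + 140.0 - uj + cj
            du = pa[j] * (pb[j] * vj - uj)
            vj += 0.5 * dv
            uj += 0.5 * du
            if vj < V_PEAK:
                dv = 0.04 * vj * vj + 5.0 * vj + 140.0 - uj + cj
                du = pa[j] * (pb[j] * vj - uj)
                vj += 0.5 * dv
                uj += 0.5 * du
            if not np.isfinite(vj):
                blow_t = t
                blow_j = j
                return n_rec, blow_t, blow_j
            if vj >= V_PEAK:
                spike_t_buf[n_rec] = t
                spike_id_buf[n_rec] = j
                n_rec += 1
                k = fired_cnt[slot]
                fired_ids[slot, k] = j
                fired_cnt[slot] = k + 1
                v[j] = pc[j]
                u[j] = uj + pd[j]
            else:
                v[j] = vj
                u[j] = uj
        # 5. STDP postsynaptic-spike bookkeeping
        if stdp_on:
            cnt = fired_cnt[slot]
            for idx in range(cnt):
                j = fired_ids[slot, idx]
                if j >= n_exc:
                    continue
                for q in range(aff_ptr[j], aff_ptr[j + 1]):
                    s = aff_syn[q]
                    if interaction_all:
                        ta = trace_pre_t[s]
                        if ta >= 0:
                            ddt = t - ta
                            dec = exp_lut[ddt] if ddt < _LUT_LEN else 0.0
                            # arrivals in this same ms preceded the threshold
                            # crossing, so they pair on the potentiation branch
                            syn_sd[s] += lam * trace_pre[s] * dec
                    else:
                        # nearest-neighbor: the last arrival pairs only if
                        # no other post of this neuron intervened (arrivals
                        # in this same ms preceded the threshold crossing,
                        # so they pair on the potentiation branch)
                        la = syn_last_arr[s]
                        if la >= 0 and la > last_post[j]:
                            ddt = t - la
                            if ddt < _LUT_LEN:
                                syn_sd[s] += lam * exp_lut[ddt]
                if interaction_all:
                    tp = trace_post_t[j]
                    if tp >= 0:
                        ddt = t - tp
                        dec = exp_lut[ddt] if ddt < _LUT_LEN else 0.0
                        trace_post[j] = trace_post[j] * dec + 1.0
                    else:
                        trace_post[j] = 1.0
                    trace_post_t[j] = t
                else:
                    last_post[j] = t
    return n_rec, blow_t, blow_j


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

class _KernelData:
    """Topology rearranged for the kernel: efferents grouped by (pre, delay)."""

    def __init__(self, topology: NetworkTopology):
        n = topology.n_neurons
        order = np.lexsort((topology.delay, topology.pre))
        self.order = order
        self.inv_order = np.argsort(order)
        self.pre = topology.pre[order]
        self.post = topology.post[order].astype(np.int64)
        self.weight = topology.weight[order].copy()
        self.delay = topology.delay[order].astype(np.int64)
        self.plastic = topology.plastic[order].copy()

        # eff_ptr[i, d] = end of neuron i's synapses with delay <= d
        eff_ptr = np.zeros((n, 11), dtype=np.int64)
        counts = np.zeros((n, 11), dtype=np.int64)
        np.add.at(counts, (self.pre, self.delay), 1)
        block_start = np.zeros(n, dtype=np.int64)
        block_start[1:] = np.cumsum(counts.sum(axis=1))[:-1]
        eff_ptr[:, 0] = block_start
        for d in range(1, 11):
            eff_ptr[:, d] = eff_ptr[:, d - 1] + counts[:, d]
        # shift so eff_ptr[i, d-1] is the start of the delay-d run
        starts = np.zeros((n, 11), dtype=np.int64)
        starts[:, 0] = block_start
        starts[:, 1:] = eff_ptr[:, 1:]
        self.eff_ptr = starts

        # afferent plastic synapse lists grouped by postsynaptic neuron
        n_exc = topology.n_excitatory
        pl_idx = np.nonzero(self.plastic)[0]
        by_post = pl_idx[np.argsort(self.post[pl_idx], kind="stable")]
        aff_counts = np.bincount(self.post[pl_idx], minlength=n_exc)
        aff_ptr = np.zeros(n_exc + 1, dtype=np.int64)
        aff_ptr[1:] = np.cumsum(aff_counts[:n_exc])
        self.aff_ptr = aff_ptr
        self.aff_syn = by_post.astype(np.int64)


def _neuron_param_arrays(topology: NetworkTopology):
    n, n_exc = topology.n_neurons, topology.n_excitatory
    pa = np.empty(n)
    pb = np.empty(n)
    pc = np.empty(n)
    pd = np.empty(n)
    for arr, name in ((pa, "a"), (pb, "b"), (pc, "c"), (pd, "d")):
        arr[:n_exc] = getattr(EXCITATORY, name)
        arr[n_exc:] = getattr(INHIBITORY, name)
    return pa, pb, pc, pd


def run_simulation(
    topology: NetworkTopology,
    drive: PoissonDriveConfig | float,
    stdp: STDPConfig | None = None,
    duration_s: int = 10,
    seed: int | np.random.SeedSequence | None = None,
    raster_windows: Sequence[tuple[float, float]] | None = None,
    input_spikes: np.ndarray | None = None,
    on_second: Callable[[int, np.ndarray], None] | None = None,
) -> SimulationResult:
    """Simulate the network for ``duration_s`` whole seconds.

    Parameters
    ----------
    topology
        Network to simulate; its ``weight`` array is *not* modified.
    drive
        Poisson drive configuration, or a bare rate in spk/s.
    stdp
        STDP configuration; ``None`` disables plasticity entirely
        (weights are then constant to the bit).
    seed
        Seed for the Poisson input stream (overridden by
        ``drive.seed`` when that is set).
    raster_windows
        Optional list of ``(t0_s, t1_s)`` intervals; somatic spikes are
        kept only inside these windows.  ``None`` keeps everything.
    input_spikes
        Optional boolean array (duration_ms, n_neurons) of external
        input spike times, replacing the Poisson draw (for tests and
        controlled protocols).
    on_second
        Optional callback ``f(second_index, weights)`` invoked after
        each 1-s commit with the committed weights in topology order.
    """
    if not isinstance(drive, PoissonDriveConfig):
        drive = PoissonDriveConfig(rate=float(drive))
    drive.validate()
    if stdp is not None:
        stdp.validate()
    duration_s = int(duration_s)
    if duration_s <= 0:
        raise ValueError("duration_s must be a positive integer number of seconds")

    n = topology.n_neurons
    n_exc = topology.n_excitatory
    kd = _KernelData(topology)
    pa, pb, pc, pd = _neuron_param_arrays(topology)

    # state
    v = np.full(n, -65.0)
    u = pb * v
    syn_sd = np.zeros(kd.weight.shape)
    syn_last_arr = np.full(len(kd.weight), -1, dtype=np.int64)
    last_post = np.full(n_exc, -1, dtype=np.int64)
    fired_cnt = np.zeros(_RING, dtype=np.int64)
    fired_ids = np.zeros((_RING, n), dtype=np.int64)
    trace_pre = np.zeros(len(kd.weight))
    trace_pre_t = np.full(len(kd.weight), -1, dtype=np.int64)
    trace_post = np.zeros(n_exc)
    trace_post_t = np.full(n_exc, -1, dtype=np.int64)

    stdp_on = stdp is not None
    if stdp_on:
        tau = stdp.tau_ms
        lam = stdp.lam
        alpha = stdp.alpha
    else:
        tau, lam, alpha = 20.0, 0.0, 0.0
    exp_lut = np.exp(-np.arange(_LUT_LEN) / tau)
    interaction_all = stdp_on and stdp.interaction == "all_to_all"
    plastic_idx = np.nonzero(kd.plastic)[0]

    drive_seed = drive.seed if drive.seed is not None else seed
    rng = np.random.default_rng(drive_seed)

    spike_t_buf = np.zeros(1000 * n, dtype=np.int32)
    spike_id_buf = np.zeros(1000 * n, dtype=np.int32)

    if raster_windows is not None:
        windows_ms = [(int(a * 1000), int(b * 1000)) for a, b in raster_windows]
    else:
        windows_ms = None

    raster_t: list[np.ndarray] = []
    raster_id: list[np.ndarray] = []
    mean_w = np.zeros(duration_s)
    exc_per_s = np.zeros(duration_s, dtype=np.int64)
    inh_per_s = np.zeros(duration_s, dtype=np.int64)

    for sec in range(duration_s):
        t0 = sec * 1000
        if input_spikes is not None:
            mask = np.ascontiguousarray(input_spikes[t0 : t0 + 1000], dtype=np.bool_)
            if mask.shape != (1000, n):
                raise ValueError("input_spikes must cover duration_ms x n_neurons")
        else:
            mask = poisson_input_mask(drive.rate, 1000, n, rng)
        n_rec, blow_t, blow_j = _run_chunk(
            t0,
            1000,
            v,
            u,
            pa,
            pb,
            pc,
            pd,
            n_exc,
            kd.eff_ptr,
            kd.post,
            kd.weight,
            kd.plastic,
            syn_sd,
            syn_last_arr,
            kd.aff_ptr,
            kd.aff_syn,
            last_post,
            fired_cnt,
            fired_ids,
            mask,
            drive.amplitude,
            stdp_on,
            interaction_all,
            lam,
            alpha,
            exp_lut,
            trace_pre,
            trace_pre_t,
            trace_post,
            trace_post_t,
            spike_t_buf,
            spike_id_buf,
        )
        if blow_t >= 0:
            raise IntegrationBlowUpError(blow_t, blow_j)

        st = spike_t_buf[:n_rec]
        si = spike_id_buf[:n_rec]
        exc_per_s[sec] = int(np.count_nonzero(si < n_exc))
        inh_per_s[sec] = n_rec - exc_per_s[sec]
        if windows_ms is None:
            raster_t.append(st.copy())
            raster_id.append(si.copy())
        else:
            keep = np.zeros(n_rec, dtype=bool)
            for a, b in windows_ms:
                if b > t0 and a < t0 + 1000:
                    keep |= (st >= a) & (st < b)
            if keep.any():
                raster_t.append(st[keep].copy())
                raster_id.append(si[keep].copy())

        # 1-s weight commit (plastic synapses only)
        if stdp_on:
            wp = kd.weight[plastic_idx]
            np.clip(wp + stdp.drift_add + syn_sd[plastic_idx], 0.0, stdp.w_max, out=wp)
            kd.weight[plastic_idx] = wp
            syn_sd[plastic_idx] *= stdp.drift_decay
        mean_w[sec] = kd.weight[plastic_idx].mean() if len(plastic_idx) else np.nan
        if on_second is not None:
            on_second(sec, kd.weight[kd.inv_order].copy())

    times = np.concatenate(raster_t) if raster_t else np.empty(0, dtype=np.int32)
    ids = np.concatenate(raster_id) if raster_id else np.empty(0, dtype=np.int32)
    raster = SpikeRaster(times, ids, duration_ms=duration_s * 1000, n_neurons=n)
    return SimulationResult(
        raster=raster,
        weights=kd.weight[kd.inv_order].copy(),
        mean_weight_per_s=mean_w,
        exc_spikes_per_s=exc_per_s,
        inh_spikes_per_s=inh_per_s,
        v_final=v,
        sd_final=syn_sd[kd.inv_order].copy(),
    )
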