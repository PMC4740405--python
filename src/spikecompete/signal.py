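"""Firing-rate estimation, oscillation phase, and phase-gap analyses.

Rates are boxcar estimates on the 1-ms grid: the rate at time ``t`` is
the spike count in the window ``[t, t + T)`` divided by ``T`` (default
10 ms), in spk/s.  Population rates average the member rates, which
for a common window equals the pooled count divided by ``N * T``.

The oscillation phase is *not* a Hilbert phase: the population rate is
low-pass filtered (zero-phase Butterworth, 35-Hz cutoff) and the phase
ramps linearly from -pi at one negative peak of the filtered rate to
+pi at the next, so the positive peak between two anchors sits near
phase 0.  Phase-gap histograms then ask where events of interest
(local maxima of a presynaptic-terminal rate, or postsynaptic spikes)
fall within that cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sp_signal

from spikecompete.netgen import NetworkTopology
from spikecompete.simulator import SpikeRaster

__all__ = [
    "firing_rate",
    "population_rate",
    "presynaptic_terminal_raster",
    "presynaptic_terminal_rate",
    "lowpass",
    "PhaseSeries",
    "extract_phase",
    "local_extrema",
    "phase_gap_histogram",
    "spike_phase_histogram",
    "spectrogram",
]

DEFAULT_WINDOW_MS = 10
LOWPASS_CUTOFF_HZ = 35.0
LOWPASS_ORDER = 4
#: Strict-extremum neighborhood half-width, ms (plateau suppression).
EXTREMUM_ORDER = 3


def _boxcar_rate(counts: np.ndarray, window_ms: int) -> np.ndarray:
    """Forward boxcar: rate[t] = sum(counts[t : t + T]) / T in spk/s."""
    if window_ms < 1:
        raise ValueError("window must be at least 1 ms")
    padded = np.concatenate([counts, np.zeros(window_ms - 1)])
    kernel = np.ones(window_ms)
    summed = np.convolve(padded, kernel, mode="valid")
    return summed * (1000.0 / window_ms)


def _bin_events(times: np.ndarray, t0_ms: int, t1_ms: int) -> np.ndarray:
    counts = np.zeros(t1_ms - t0_ms)
    inside = (times >= t0_ms) & (times < t1_ms)
    np.add.at(counts, (times[inside] - t0_ms).astype(np.int64), 1.0)
    return counts


def firing_rate(
    raster: SpikeRaster,
    neuron: int,
    window_ms: int = DEFAULT_WINDOW_MS,
    t0_ms: int = 0,
    t1_ms: int | None = None,
) -> np.ndarray:
    """Single-neuron boxcar firing rate (spk/s), one sample per ms."""
    if t1_ms is None:
        t1_ms = raster.duration_ms
    counts = _bin_events(raster.spike_times(neuron), t0_ms, t1_ms)
    return _boxcar_rate(counts, window_ms)


def population_rate(
    raster: SpikeRaster,
    subset: np.ndarray,
    window_ms: int = DEFAULT_WINDOW_MS,
    t0_ms: int = 0,
    t1_ms: int | None = None,
) -> np.ndarray:
    """Mean firing rate (spk/s) over the neurons in ``subset``."""
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("population_rate needs a non-empty subset")
    if t1_ms is None:
        t1_ms = raster.duration_ms
    sub = raster.subset(subset)
    counts = _bin_events(sub.times, t0_ms, t1_ms)
    return _boxcar_rate(counts, window_ms) / subset.size


def presynaptic_terminal_raster(
    raster: SpikeRaster, topology: NetworkTopology, postsynaptic: int,
    surviving_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Terminal firing times at the afferent synapses of one neuron.

    Each somatic spike of an excitatory afferent is shifted by its
    synapse's conduction delay; a presynaptic neuron with several...
    distinct synapses onto the target contributes one terminal event
    per synapse.  Returns ``(sorted event times ms, n_terminals)``.
    Restricted to E->E afferents; optionally only synapses whose
    weight in ``surviving_weights`` is positive.
    """
    mask = topology.plastic & (topology.post == postsynaptic)
    if surviving_weights is not None:
        mask &= np.asarray(surviving_weights) > 0
    pres = topology.pre[mask]
    delays = topology.delay[mask].astype(np.int64)
    n_terminals = int(mask.sum())
    if n_terminals == 0:
        return np.empty(0, dtype=np.int64), 0
    events = []
    for p, d in zip(pres, delays):
        st = raster.spike_times(p)
        if len(st):
            events.append(st.astype(np.int64) + d)
    if not events:
        return np.empty(0, dtype=np.int64), n_terminals
    return np.sort(np.concatenate(events)), n_terminals


def presynaptic_terminal_rate(
    raster: SpikeRaster,
    topology: NetworkTopology,
    postsynaptic: int,
    window_ms: int = DEFAULT_WINDOW_MS,
    t0_ms: int = 0,
    t1_ms: int | None = None,
    surviving_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Mean rate (spk/s) of the presynaptic terminals of one neuron.

    Somatic afferent spikes are delay-shifted to terminal arrival times
    before the boxcar estimate; the result is averaged over the
    afferent terminal set of the neuron.
    """
    if t1_ms is None:
        t1_ms = raster.duration_ms
    events, n_terminals = presynaptic_terminal_raster(
        raster, topology, postsynaptic, surviving_weights
    )
    if n_terminals == 0:
        raise ValueError(f"neuron {postsynaptic} has no afferent terminals")
    counts = _bin_events(events, t0_ms, t1_ms)
    return _boxcar_rate(counts, window_ms) / n_terminals


def lowpass(
    series: np.ndarray,
    cutoff_hz: float = LOWPASS_CUTOFF_HZ,
    fs_hz: float = 1000.0,
    order: int = LOWPASS_ORDER,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward), unit DC gain."""
    sos = sp_signal.butter(order, cutoff_hz, btype="low", fs=fs_hz, output="sos")
    return sp_signal.sosfiltfilt(sos, np.asarray(series, dtype=float))


def local_extrema(series: np.ndarray, kind: str = "min", order: int = EXTREMUM_ORDER) -> np.ndarray:
    """Indices of strict local extrema over a +/- ``order``-sample window."""
    comparator = np.less if kind == "min" else np.greater
    idx = sp_signal.argrelextrema(np.asarray(series, dtype=float), comparator, order=order)[0]
    return idx


@dataclass
class PhaseSeries:
    """Piecewise-linear oscillation phase anchored at negative peaks.

    ``values[t]`` is the phase in [-pi, pi) at sample ``t`` (NaN outside
    the span of the anchors); ``anchors`` are the sample indices of the
    negative peaks, where the phase is exactly -pi.
    """

    values: np.ndarray
    anchors: np.ndarray

    def at(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.int64)
        out = np.full(t.shape, np.nan)
        ok = (t >= 0) & (t < len(self.values))
        out[ok] = self.values[t[ok]]
        return out


def extract_phase(filtered: np.ndarray, order: int = EXTREMUM_ORDER) -> PhaseSeries:
    """Phase of an oscillatory series from its negative-peak anchors.

    Between consecutive negative peaks t_k and t_{k+1} the phase is
    ``2*pi*(t - t_k)/(t_{k+1} - t_k) - pi``, i.e. -pi at each anchor
    and ~0 at the positive peak in between.  Requires at least two
    anchors.
    """
    x = np.asarray(filtered, dtype=float)
    anchors = local_extrema(x, kind="min", order=order)
    if len(anchors) < 2:
        raise ValueError("need at least two negative peaks to define a phase")
    values = np.full(len(x), np.nan)
    for k in range(len(anchors) - 1):
        a, b = anchors[k], anchors[k + 1]
        t = np.arange(a, b)
        values[t] = 2.0 * np.pi * (t - a) / (b - a) - np.pi
    return PhaseSeries(values=values, anchors=anchors)


def phase_gap_histogram(
    global_phase: PhaseSeries,
    event_times: np.ndarray,
    bins: int = 36,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distribution of the global-oscillation phase at given event times.

    Typically the events are local maxima of a neuron's filtered
    presynaptic-terminal rate; the histogram then measures how that
    neuron's afferent volley lags the global excitatory oscillation.
    Returns ``(bin_centers, probabilities, phases)``; probabilities sum
    to 1 over events with a defined phase.
    """
    phases = global_phase.at(np.asarray(event_times, dtype=np.int64))
    phases = phases[np.isfinite(phases)]
    if len(phases) == 0:
        raise ValueError("no events fall inside the phase-defined span")
    edges = np.linspace(-np.pi, np.pi, bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts / counts.sum(), phases


def spike_phase_histogram(
    presyn_phase: PhaseSeries,
    spike_times: np.ndarray,
    bins: int = 36,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Distribution of a neuron's spikes over its presynaptic-oscillation phase.

    Spikes just after the presynaptic volley (small positive phase)
    indicate effective potentiation; spikes before the volley indicate
    depression-dominated timing.
    """
    spike_times = np.asarray(spike_times, dtype=np.int64)
    if len(spike_times) == 0:
        raise ValueError("no spikes to characterize")
    return phase_gap_histogram(presyn_phase, spike_times, bins)


def spectrogram(
    series: np.ndarray,
    fs_hz: float = 1000.0,
    window_ms: int = 1024,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time power spectrum, each time slice normalized to peak 1.

    Returns ``(freqs_hz, times_s, power)`` with ``power`` of shape
    (n_freqs, n_times).  Slices with no power are left at zero.
    """
    x = np.asarray(series, dtype=float)
    nperseg = min(window_ms, len(x))
    f, t, sxx = sp_signal.spectrogram(
        x - x.mean(), fs=fs_hz, nperseg=nperseg, noverlap=int(nperseg * overlap)
    )
    peak = sxx.max(axis=0, keepdims=True)
    peak[peak == 0] = 1.0
    return f, t, sxx / peak
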