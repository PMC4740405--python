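"""Additive spike timing-dependent plasticity with hard bounds.

The STDP window is the classic additive (weight-independent) double
exponential: a presynaptic arrival followed by a postsynaptic spike
``dt`` ms later potentiates by ``lam * exp(-dt / tau)``; the opposite
order (including exact coincidence, ``dt == 0``) depresses by
``alpha * lam * exp(-|dt| / tau)``.  The presynaptic time is always the
*arrival* time at the synaptic terminal, i.e. the somatic spike time
plus the axonal conduction delay of that synapse -- this is what makes
the delay composition of a neuron's afferents matter.

Event-driven changes accumulate in a per-synapse derivative ``sd``;
the actual weights are only updated at 1-second commits, where a small
activity-independent drift (+0.01 mV per commit) is added, the result
is clipped to the hard bounds [0, w_max], and ``sd`` is decayed by a
factor 0.9.

Two spike-interaction schemes are supported:

- ``nearest_neighbor`` (default): each event pairs only with the most
  recent event of the opposite kind on the same synapse.
- ``all_to_all``: each event pairs with *every* earlier opposite event,
  implemented with exponentially decaying traces; the accumulated
  derivative equals the brute-force sum of the window function over
  all (arrival, post-spike) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "STDPConfig",
    "stdp_delta",
    "STDPAccumulator",
    "all_to_all_sd",
    "nearest_neighbor_sd",
    "commit_weights",
]

INTERACTIONS = ("nearest_neighbor", "all_to_all")


@dataclass
class STDPConfig:
    """Parameters of the additive STDP rule.

    lam       learning rate, mV per pairing at zero lag (LTP side)
    alpha     LTD/LTP asymmetry; LTD amplitude is alpha * lam
    tau_ms    common time constant of both window branches, ms
    w_max     hard upper bound of plastic weights, mV (lower bound is 0)
    interaction  'nearest_neighbor' or 'all_to_all' spike pairing
    drift_add    activity-independent weight increment per 1-s commit, mV
    drift_decay  multiplicative decay of the accumulated derivative per commit
    """

    lam: float = 0.1
    alpha: float = 1.2
    tau_ms: float = 20.0
    w_max: float = 10.0
    interaction: str = "nearest_neighbor"
    drift_add: float = 0.01
    drift_decay: float = 0.9

    def validate(self) -> None:
        if self.lam <= 0 or self.tau_ms <= 0 or self.alpha <= 0 or self.w_max <= 0:
            raise ValueError("lam, alpha, tau_ms and w_max must all be positive")
        if self.interaction not in INTERACTIONS:
            raise ValueError(
                f"interaction must be one of {INTERACTIONS}, got {self.interaction!r}"
            )


def stdp_delta(dt, config: STDPConfig | None = None):
    """Weight change (mV) for relative timing ``dt = t_post - t_arrival``.

    ``dt > 0`` falls on the potentiation branch, ``dt <= 0`` (spike
    before or coincident with the arrival) on the depression branch.
    Accepts scalars or arrays.
    """
    if config is None:
        config = STDPConfig()
    dt = np.asarray(dt, dtype=float)
    mag = config.lam * np.exp(-np.abs(dt) / config.tau_ms)
    out = np.where(dt > 0, mag, -config.alpha * mag)
    return out if out.ndim else float(out)


class STDPAccumulator:
    """Event-by-event derivative accumulation for a single synapse.

    Feed presynaptic-terminal arrivals and postsynaptic spikes in time
    order through :meth:`on_event`; the running derivative is available
    as :attr:`sd`.  Events at the same millisecond must be fed
    arrival-first (a coincident pair then lands on the depression
    branch, ``dt == 0``).
    """

    def __init__(self, config: STDPConfig | None = None, coincident: str = "depress"):
        """``coincident`` picks the branch for same-millisecond
        arrival->spike pairs: ``'depress'`` is the literal dt == 0
        reading of the window function; ``'potentiate'`` is the causal
        convention the simulator uses (an arrival in the same 1-ms bin
        preceded the threshold crossing it helped cause)."""
        if coincident not in ("depress", "potentiate"):
            raise ValueError("coincident must be 'depress' or 'potentiate'")
        self.coincident = coincident
        self.config = config or STDPConfig()
        self.config.validate()
        self.sd = 0.0
        self._last_t = -np.inf
        self._last_kind: str | None = None
        # nearest-neighbor state
        self._last_pre: float | None = None
        self._last_post: float | None = None
        # all-to-all traces (value at the time of the last update)
        self._pre_trace = 0.0
        self._pre_trace_t = -np.inf
        self._post_trace = 0.0
        self._post_trace_t = -np.inf

    def on_event(self, kind: str, t: float) -> float:
        """Process one event; returns the updated derivative ``sd``.

        ``kind`` is ``'pre'`` (terminal arrival) or ``'post'``
        (postsynaptic somatic spike).  Events must arrive in
        nondecreasing time order, with arrivals before spikes at ties.
        """
        if kind not in ("pre", "post"):
            raise ValueError(f"event kind must be 'pre' or 'post', got {kind!r}")
        if t < self._last_t or (
            t == self._last_t and self._last_kind == "post" and kind == "pre"
        ):
            raise ValueError(
                f"events must be processed in time order (pre before post at ties); "
                f"got {kind} at t={t} after {self._last_kind} at t={self._last_t}"
            )
        cfg = self.config
        if cfg.interaction == "nearest_neighbor":
            # pair only with the immediately preceding event, and only
            # when it is of the opposite kind: an intervening same-kind
            # event blocks the pairing
            if kind == "pre":
                opposite_is_predecessor = self._last_post is not None and (
                    self._last_pre is None or self._last_post >= self._last_pre
                )
                if opposite_is_predecessor:
                    self.sd += stdp_delta(self._last_post - t, cfg)
                self._last_pre = t
            else:
                # at a tie the arrival precedes the post, so an arrival at
                # the same time as the previous post belongs to that post
                opposite_is_predecessor = self._last_pre is not None and (
                    self._last_post is None or self._last_pre > self._last_post
                )
                if opposite_is_predecessor:
                    dt = t - self._last_pre
                    if dt == 0 and self.coincident == "potentiate":
                        self.sd += cfg.lam
                    else:
                        self.sd += stdp_delta(dt, cfg)
                self._last_post = t
        else:  # all_to_all: pair with every earlier opposite event
            tau = cfg.tau_ms
            if kind == "pre":
                post = self._post_trace * np.exp(-(t - self._post_trace_t) / tau)
                self.sd += -cfg.alpha * cfg.lam * post
                self._pre_trace = (
                    self._pre_trace * np.exp(-(t - self._pre_trace_t) / tau) + 1.0
                )
                self._pre_trace_t = t
            else:
                pre = self._pre_trace * np.exp(-(t - self._pre_trace_t) / tau)
                if self._pre_trace_t == t and self.coincident == "depress":
                    self.sd += cfg.lam * (pre - 1.0) - cfg.alpha * cfg.lam
                else:
                    self.sd += cfg.lam * pre
                self._post_trace = (
                    self._post_trace * np.exp(-(t - self._post_trace_t) / tau) + 1.0
                )
                self._post_trace_t = t
        self._last_t = t
        self._last_kind = kind
        return self.sd


def nearest_neighbor_sd(
    arrivals, posts, config: STDPConfig | None = None, coincident: str = "depress"
) -> float:
    """Accumulated derivative for sorted arrival/post time lists (NN pairing)."""
    cfg = config or STDPConfig()
    cfg = STDPConfig(**{**cfg.__dict__, "interaction": "nearest_neighbor"})
    return _replay(arrivals, posts, cfg, coincident)


def all_to_all_sd(
    arrivals, posts, config: STDPConfig | None = None, coincident: str = "depress"
) -> float:
    """Accumulated derivative for sorted arrival/post time lists (all pairs)."""
    cfg = config or STDPConfig()
    cfg = STDPConfig(**{**cfg.__dict__, "interaction": "all_to_all"})
    return _replay(arrivals, posts, cfg, coincident)


def _replay(arrivals, posts, config: STDPConfig, coincident: str = "depress") -> float:
    events = sorted(
        [(float(t), 0, "pre") for t in arrivals]
        + [(float(t), 1, "post") for t in posts]
    )
    acc = STDPAccumulator(config, coincident=coincident)
    for t, _, kind in events:
        acc.on_event(kind, t)
    return float(acc.sd)


def commit_weights(
    weights: np.ndarray,
    sd: np.ndarray,
    config: STDPConfig,
    plastic: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply a 1-second weight commit; returns ``(weights', sd')``.

    For plastic synapses ``w <- clip(w + drift_add + sd, 0, w_max)`` and
    ``sd <- drift_decay * sd``; non-plastic entries pass through.
    """
    weights = np.asarray(weights, dtype=float)
    sd = np.asarray(sd, dtype=float)
    new_w = np.clip(weights + config.drift_add + sd, 0.0, config.w_max)
    new_sd = config.drift_decay * sd
    if plastic is not None:
        plastic = np.asarray(plastic, dtype=bool)
        new_w = np.where(plastic, new_w, weights)
        new_sd = np.where(plastic, new_sd, sd)
    return new_w, new_sd
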