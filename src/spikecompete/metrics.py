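"""Weighted-network summaries of the excitatory subnetwork.

All statistics here are computed on the excitatory-to-excitatory
(plastic) subnetwork only.  A synapse *survives* while its weight is
strictly positive; a weight driven to the lower hard bound counts as
pruned and disappears from degrees, edge-end correlations and
delay-resolved statistics.

Degrees count surviving afferent/efferent synapses.  Strengths are
sums of weights normalized by the hard upper bound ``w_max``, so a
neuron's instrength ``s_in`` is bounded by its indegree.  The
*instrength-* and *outstrength-correlation coefficients* (``r_in``,
``r_out``) are Pearson correlations over surviving directed edges
between the strength of the edge tail and the strength of the edge
head; negative values mean dissimilar neurons sit at the two ends of
a typical connection (disassortativity), which is the signature of
winner/loser competition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from spikecompete.netgen import NetworkTopology

__all__ = [
    "DegenerateStrengthsError",
    "exc_edges",
    "degrees",
    "strengths",
    "strength_table",
    "strength_correlation",
    "identify_winners",
    "assembly_switches",
    "delay_profile",
    "weight_by_delay",
    "joint_distribution",
    "JointDistributionMatrix",
]


class DegenerateStrengthsError(ValueError):
    """Edge-end correlation is undefined (zero variance at one end)."""


def exc_edges(
    topology: NetworkTopology, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pre, post, weight) arrays of the E->E subnetwork.

    ``weights`` optionally overrides the topology's stored weights
    (full-length, topology synapse order) -- the usual case when
    analyzing an evolved weight vector from a simulation.
    """
    w = topology.weight if weights is None else np.asarray(weights, dtype=float)
    if len(w) != topology.n_synapses:
        raise ValueError("weights must be aligned with the topology synapse list")
    m = topology.plastic
    return topology.pre[m], topology.post[m], w[m]


def degrees(
    topology: NetworkTopology, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Surviving in/outdegree (k_in, k_out) per excitatory neuron."""
    pre, post, w = exc_edges(topology, weights)
    surv = w > 0
    n_exc = topology.n_excitatory
    k_in = np.bincount(post[surv], minlength=n_exc)
    k_out = np.bincount(pre[surv], minlength=n_exc)
    return k_in, k_out


def strengths(
    topology: NetworkTopology,
    weights: np.ndarray | None = None,
    w_max: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (s_in, s_out) per excitatory neuron."""
    pre, post, w = exc_edges(topology, weights)
    n_exc = topology.n_excitatory
    s_in = np.bincount(post, weights=w, minlength=n_exc) / w_max
    s_out = np.bincount(pre, weights=w, minlength=n_exc) / w_max
    return s_in, s_out


def strength_table(
    topology: NetworkTopology,
    weights: np.ndarray | None = None,
    w_max: float = 10.0,
    label: bool = True,
) -> pd.DataFrame:
    """Per-excitatory-neuron table of k_in, k_out, s_in, s_out (+ label)."""
    k_in, k_out = degrees(topology, weights)
    s_in, s_out = strengths(topology, weights, w_max)
    table = pd.DataFrame(
        {"k_in": k_in, "k_out": k_out, "s_in": s_in, "s_out": s_out},
        index=pd.RangeIndex(topology.n_excitatory, name="neuron"),
    )
    if label:
        winners = identify_winners(table)
        table["label"] = np.where(winners, "winner", "loser")
    return table


def strength_correlation(
    topology: NetworkTopology,
    weights: np.ndarray | None = None,
    which: str = "in",
    w_max: float = 10.0,
) -> float:
    """Edge-end Pearson correlation of instrengths or outstrengths.

    Over surviving E->E edges (w > 0), correlates the chosen strength
    of the edge tail with that of the edge head.  Means and standard
    deviations are taken over edges (a neuron contributes once per
    surviving synapse end).  Raises :class:`DegenerateStrengthsError`
    when either end has zero variance.
    """
    if which not in ("in", "out"):
        raise ValueError(f"which must be 'in' or 'out', got {which!r}")
    pre, post, w = exc_edges(topology, weights)
    surv = w > 0
    if surv.sum() < 2:
        raise DegenerateStrengthsError("need at least 2 surviving synapses")
    s_in, s_out = strengths(topology, weights, w_max)
    s = s_in if which == "in" else s_out
    tail = s[pre[surv]]
    head = s[post[surv]]
    sigma_t = tail.std()
    sigma_h = head.std()
    if sigma_t == 0.0 or sigma_h == 0.0:
        raise DegenerateStrengthsError(
            f"edge-end {which}strengths have zero variance; correlation undefined"
        )
    return float(((tail - tail.mean()) * (head - head.mean())).mean() / (sigma_t * sigma_h))


def identify_winners(table: pd.DataFrame, rule: str = "threshold") -> np.ndarray:
    """Boolean winner mask separating the two competing assemblies.

    ``rule='threshold'`` (default): neurons are ranked by descending
    ``s_in``; the first neuron (in that order) whose instrength does
    not exceed its outstrength marks the start of the loser assembly,
    and every neuron from it onward is a loser.  Ties
    (s_in == s_out) therefore fall on the loser side.  If no neuron
    qualifies, all are winners.

    ``rule='margin'``: a neuron is a winner iff its own
    ``s_in > s_out``.  The two rules agree except for neurons
    straddling the diagonal; the margin rule is continuous in each
    neuron's strengths (no rank coupling), which makes it the right
    basis for counting membership *changes* over time -- under the
    threshold rule a single borderline neuron crossing the diagonal
    relabels a whole block of ranks at once.
    """
    s_in = table["s_in"].to_numpy()
    s_out = table["s_out"].to_numpy()
    if rule == "margin":
        return s_in > s_out
    if rule != "threshold":
        raise ValueError(f"rule must be 'threshold' or 'margin', got {rule!r}")
    order = np.argsort(-s_in, kind="stable")
    below = s_in[order] <= s_out[order]
    winners = np.zeros(len(s_in), dtype=bool)
    threshold_rank = int(np.argmax(below)) if below.any() else len(s_in)
    winners[order[:threshold_rank]] = True
    return winners


def assembly_switches(
    winners_t: np.ndarray, winners_t1: np.ndarray
) -> tuple[int, int]:
    """(winner->loser, loser->winner) counts between consecutive labelings."""
    a = np.asarray(winners_t, dtype=bool)
    b = np.asarray(winners_t1, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("labelings must cover the same neurons")
    return int(np.count_nonzero(a & ~b)), int(np.count_nonzero(~a & b))


def delay_profile(
    topology: NetworkTopology,
    winners: np.ndarray,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean afferent delay composition of winner and loser neurons.

    For each excitatory neuron the fraction of its surviving E->E
    afferents carried at each conduction delay 1-10 ms (the ten
    fractions sum to 1), averaged within the winner and within the
    loser group.  Neurons with no surviving afferents are excluded
    from their group's average.
    """
    w = topology.weight if weights is None else np.asarray(weights, dtype=float)
    m = topology.plastic & (w > 0)
    post = topology.post[m]
    delay = topology.delay[m].astype(int)
    n_exc = topology.n_excitatory
    counts = np.zeros((n_exc, 10))
    np.add.at(counts, (post, delay - 1), 1.0)
    total = counts.sum(axis=1)
    has = total > 0
    frac = np.full_like(counts, np.nan)
    frac[has] = counts[has] / total[has, None]
    winners = np.asarray(winners, dtype=bool)
    rows = {}
    for name, group in (("winner", winners), ("loser", ~winners)):
        sel = group & has
        rows[name] = frac[sel].mean(axis=0) if sel.any() else np.full(10, np.nan)
    return pd.DataFrame(rows, index=pd.RangeIndex(1, 11, name="delay_ms")).T


def weight_by_delay(
    topology: NetworkTopology,
    winners: np.ndarray,
    weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Mean surviving E->E weight per conduction delay, per target group."""
    w = topology.weight if weights is None else np.asarray(weights, dtype=float)
    m = topology.plastic & (w > 0)
    post = topology.post[m]
    delay = topology.delay[m].astype(int)
    wv = w[m]
    winners = np.asarray(winners, dtype=bool)
    rows = {}
    for name, group in (("winner", winners), ("loser", ~winners)):
        sel = group[post]
        sums = np.bincount(delay[sel], weights=wv[sel], minlength=11)[1:]
        cnts = np.bincount(delay[sel], minlength=11)[1:]
        with np.errstate(invalid="ignore"):
            rows[name] = np.where(cnts > 0, sums / np.maximum(cnts, 1), np.nan)
    return pd.DataFrame(rows, index=pd.RangeIndex(1, 11, name="delay_ms")).T


@dataclass
class JointDistributionMatrix:
    """2-D histogram over (in, out) strengths or degrees."""

    counts: np.ndarray
    x_edges: np.ndarray  # s_in / k_in axis
    y_edges: np.ndarray  # s_out / k_out axis
    mode: str

    @property
    def n_neurons(self) -> int:
        return int(self.counts.sum())

    def local_maxima(self, min_count: int = 2, size: int = 5) -> list[tuple[int, int]]:
        """Bin indices of strict-neighborhood local maxima of the histogram."""
        from scipy import ndimage

        h = self.counts
        peak = (h == ndimage.maximum_filter(h, size=size)) & (h >= min_count)
        # collapse plateaus: keep one representative per connected component
        lab, n = ndimage.label(peak)
        out = []
        for k in range(1, n + 1):
            idx = np.argwhere(lab == k)
            out.append(tuple(int(v) for v in idx[len(idx) // 2]))
        return out


def joint_distribution(
    table: pd.DataFrame, mode: str = "strength", bins: int = 50
) -> JointDistributionMatrix:
    """Joint (in, out) strength or degree histogram over excitatory neurons.

    With ``mode='strength'`` this is the joint strength distribution
    matrix (JSDM); with ``mode='degree'`` the joint degree distribution
    matrix (JDDM).  Counts sum to the number of neurons in the table.
    """
    if mode == "strength":
        x, y = table["s_in"].to_numpy(), table["s_out"].to_numpy()
    elif mode == "degree":
        x, y = table["k_in"].to_numpy(), table["k_out"].to_numpy()
    else:
        raise ValueError(f"mode must be 'strength' or 'degree', got {mode!r}")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return JointDistributionMatrix(counts=counts, x_edges=xe, y_edges=ye, mode=mode)
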