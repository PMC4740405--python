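"""Non-parametric statistics: Kendall's tau and Watson's two-sample U².

Both are implemented from their counting constructions rather than
delegated to a library, because the counting details (tie handling,
the ECDF merge walk) are part of the analysis contract; library
implementations serve as independent cross-checks in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "kendall_tau",
    "WatsonU2Result",
    "watson_u2",
    "watson_u2_critical_values",
]


def kendall_tau(x, y) -> float:
    """Kendall's rank correlation via the P/Q counting construction.

    Pairs are sorted in ascending order of ``x``; for each position i,
    ``P_i`` counts later positions whose y-value is larger (concordant)
    and ``Q_i`` those whose y-value is smaller (discordant).  Pairs
    tied in either coordinate are excluded from both counts, while the
    denominator remains m(m-1)/2, so ties shrink the coefficient
    toward 0 (tau-a-like behaviour).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    m = len(x)
    if m < 2:
        raise ValueError("need at least two paired observations")
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    p_total = 0
    q_total = 0
    for i in range(m - 1):
        later_x = xs[i + 1 :]
        later_y = ys[i + 1 :]
        untied = later_x != xs[i]
        p_total += int(np.count_nonzero(untied & (later_y > ys[i])))
        q_total += int(np.count_nonzero(untied & (later_y < ys[i])))
    if p_total == 0 and q_total == 0:
        raise ValueError("all pairs are tied; tau is undefined")
    return 2.0 * (p_total - q_total) / (m * (m - 1))


# ----------------------------------------------------------------------
# Watson's two-sample U2
# ----------------------------------------------------------------------

def watson_u2_critical_values() -> dict[float, float]:
    """Critical values of Watson's U² shipped with the package.

    Asymptotic values of the two-sample statistic; see the packaged
    table for provenance.
    """
    text = (
        resources.files("spikecompete") / "data" / "watson_u2_critical.tsv"
    ).read_text()
    out = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("alpha"):
            continue
        alpha, crit = line.split("\t")
        out[float(alpha)] = float(crit)
    return out


@dataclass
class WatsonU2Result:
    """Watson U² statistic with tabulated significance flags."""

    u2: float
    n_x: int
    n_y: int
    #: alpha -> True when u2 exceeds the critical value at that level
    significant: dict[float, bool]

    def __float__(self) -> float:
        return self.u2


def watson_u2(phi_x, phi_y) -> WatsonU2Result:
    """Two-sample Watson U² test for circular (phase) data.

    Both samples are sorted ascending and merged; at each merge step
    ``d_k`` is the difference of the two empirical CDFs,
    ``d_k = i/m1 - j/m2``, where i and j count how many x- and
    y-values have been consumed.  At ties the y-pointer advances
    first.  The statistic is

        U² = (m1 m2 / M²) · sum_k (d_k - mean(d))²,   M = m1 + m2,

    which is invariant under a common rotation of both samples.
    Significance is read from the packaged critical-value table.
    """
    phi_x = np.sort(np.asarray(phi_x, dtype=float))
    phi_y = np.sort(np.asarray(phi_y, dtype=float))
    m1, m2 = len(phi_x), len(phi_y)
    if m1 == 0 or m2 == 0:
        raise ValueError("both phase samples must be non-empty")
    m_tot = m1 + m2
    d = np.empty(m_tot)
    i = j = 0
    for k in range(m_tot):
        if i < m1 and (j >= m2 or phi_x[i] < phi_y[j]):
            i += 1
        else:
            j += 1
        d[k] = i / m1 - j / m2
    u2 = (m1 * m2 / m_tot**2) * float(np.sum((d - d.mean()) ** 2))
    crit = watson_u2_critical_values()
    significant = {alpha: u2 > c for alpha, c in sorted(crit.items())}
    return WatsonU2Result(u2=u2, n_x=m1, n_y=m2, significant=significant)
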