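"""Random network construction and deterministic micro-fixtures.

The network is a simple directed graph over ``n_neurons`` Izhikevich
neurons, the first ``n_excitatory`` of which are regular-spiking
excitatory cells and the remainder fast-spiking inhibitory cells.
Every ordered pair (i, j) with i != j carries a synapse independently
with probability ``connection_probability``, except that inhibitory
neurons never project onto each other.  Excitatory synapses get an
integer conduction delay drawn uniformly from 1-10 ms; inhibitory
synapses always conduct in 1 ms.  Only excitatory-to-excitatory
synapses are plastic.

A master seed is split into independent sub-streams for the adjacency
draw, the delay draw, and the initial-weight draw, so parameter sweeps
can vary one random factor while holding the others fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkConfig",
    "NetworkTopology",
    "build_network",
    "sample_initial_weights",
    "make_fixture",
    "FIXTURE_NAMES",
]

#: Default per-spike amplitudes, mV
W_EXC_INIT = 6.0
W_INH_INIT = -5.0

#: Delay support for excitatory synapses, ms (inclusive)
DELAY_MIN, DELAY_MAX = 1, 10
INHIBITORY_DELAY = 1


@dataclass(frozen=True)
class NeuronParams:
    """Izhikevich model constants for one cell class.

    ``a`` sets the recovery time scale, ``b`` the recovery sensitivity
    to subthreshold voltage, ``c`` the post-spike reset potential (mV)
    and ``d`` the post-spike recovery increment.
    """

    a: float
    b: float
    c: float
    d: float
    is_excitatory: bool


#: Regular-spiking excitatory preset.
EXCITATORY = NeuronParams(a=0.02, b=0.2, c=-65.0, d=8.0, is_excitatory=True)
#: Fast-spiking inhibitory preset.
INHIBITORY = NeuronParams(a=0.1, b=0.2, c=-65.0, d=2.0, is_excitatory=False)


@dataclass
class NetworkConfig:
    """Parameters of the random-network recipe."""

    n_neurons: int = 1000
    excitatory_fraction: float = 0.8
    connection_probability: float = 0.1
    w_exc_init: float = W_EXC_INIT
    w_inh_init: float = W_INH_INIT
    #: Optional (low, high) uniform range for the initial plastic weights.
    initial_weight_range: tuple[float, float] | None = None
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_neurons <= 0:
            raise ValueError(f"n_neurons must be positive, got {self.n_neurons}")
        if not (0.0 < self.excitatory_fraction < 1.0):
            raise ValueError(
                "excitatory_fraction must lie strictly in (0, 1), got "
                f"{self.excitatory_fraction}"
            )
        if not (0.0 <= self.connection_probability <= 1.0):
            raise ValueError(
                "connection_probability must lie in [0, 1], got "
                f"{self.connection_probability}"
            )

    @property
    def n_excitatory(self) -> int:
        return int(round(self.n_neurons * self.excitatory_fraction))


@dataclass
class NetworkTopology:
    """Directed synapse list with weights, integer delays and plasticity flags.

    Synapses are stored as parallel arrays: ``pre[k] -> post[k]`` with
    weight ``weight[k]`` (mV, signed), conduction delay ``delay[k]``
    (integer ms) and ``plastic[k]`` true iff both endpoints are
    excitatory.  Neurons ``0 .. n_excitatory-1`` are excitatory.
    """

    n_neurons: int
    n_excitatory: int
    pre: np.ndarray = field(repr=False)
    post: np.ndarray = field(repr=False)
    weight: np.ndarray = field(repr=False)
    delay: np.ndarray = field(repr=False)
    plastic: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.pre = np.ascontiguousarray(self.pre, dtype=np.int32)
        self.post = np.ascontiguousarray(self.post, dtype=np.int32)
        self.weight = np.ascontiguousarray(self.weight, dtype=np.float64)
        self.delay = np.ascontiguousarray(self.delay, dtype=np.int16)
        self.plastic = np.ascontiguousarray(self.plastic, dtype=bool)
        n = len(self.pre)
        if not (len(self.post) == len(self.weight) == len(self.delay) == len(self.plastic) == n):
            raise ValueError("synapse arrays must have equal length")

    @property
    def n_inhibitory(self) -> int:
        return self.n_neurons - self.n_excitatory

    @property
    def n_synapses(self) -> int:
        return len(self.pre)

    def is_excitatory(self, ids: np.ndarray | int) -> np.ndarray | bool:
        return np.asarray(ids) < self.n_excitatory

    def copy(self) -> "NetworkTopology":
        return NetworkTopology(
            n_neurons=self.n_neurons,
            n_excitatory=self.n_excitatory,
            pre=self.pre.copy(),
            post=self.post.copy(),
            weight=self.weight.copy(),
            delay=self.delay.copy(),
            plastic=self.plastic.copy(),
        )

    # ------------------------------------------------------------------
    # serialization
    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write the edge list as TSV (pre, post, weight, delay, plastic)."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# n_neurons={self.n_neurons}\tn_excitatory={self.n_excitatory}\n")
            fh.write("pre\tpost\tweight\tdelay\tplastic\n")
            for p, q, w, d, pl in zip(
                self.pre, self.post, self.weight, self.delay, self.plastic
            ):
                fh.write(f"{p}\t{q}\t{float(w)!r}\t{d}\t{int(pl)}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NetworkTopology":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline()
            meta = dict(
                item.split("=") for item in header.lstrip("# ").strip().split("\t")
            )
            fh.readline()  # column names
            rows = [line.split("\t") for line in fh if line.strip()]
        pre = np.array([int(r[0]) for r in rows], dtype=np.int32)
        post = np.array([int(r[1]) for r in rows], dtype=np.int32)
        weight = np.array([float(r[2]) for r in rows], dtype=np.float64)
        delay = np.array([int(r[3]) for r in rows], dtype=np.int16)
        plastic = np.array([bool(int(r[4])) for r in rows], dtype=bool)
        return cls(
            n_neurons=int(meta["n_neurons"]),
            n_excitatory=int(meta["n_excitatory"]),
            pre=pre,
            post=post,
            weight=weight,
            delay=delay,
            plastic=plastic,
        )

    def to_hdf5(self, path: str | Path, group: str = "topology") -> None:
        with h5py.File(path, "a") as fh:
            if group in fh:
                del fh[group]
            g = fh.create_group(group)
            g.attrs["n_neurons"] = self.n_neurons
            g.attrs["n_excitatory"] = self.n_excitatory
            g.create_dataset("pre", data=self.pre)
            g.create_dataset("post", data=self.post)
            g.create_dataset("weight", data=self.weight)
            g.create_dataset("delay", data=self.delay)
            g.create_dataset("plastic", data=self.plastic)

    @classmethod
    def from_hdf5(cls, path: str | Path, group: str = "topology") -> "NetworkTopology":
        with h5py.File(path, "r") as fh:
            g = fh[group]
            return cls(
                n_neurons=int(g.attrs["n_neurons"]),
                n_excitatory=int(g.attrs["n_excitatory"]),
                pre=g["pre"][:],
                post=g["post"][:],
                weight=g["weight"][:],
                delay=g["delay"][:],
                plastic=g["plastic"][:],
            )


def build_network(config: NetworkConfig) -> NetworkTopology:
    """Draw a random topology from the configured recipe.

    Each ordered pair (i, j), i != j and not inhibitory->inhibitory,
    carries a synapse independently with ``connection_probability``.
    The adjacency, delay and initial-weight draws consume independent
    RNG streams spawned from ``config.rng_seed``.
    """
    config.validate()
    n = config.n_neurons
    n_exc = config.n_excitatory
    adj_ss, delay_ss, weight_ss = np.random.SeedSequence(config.rng_seed).spawn(3)
    adj_rng = np.random.default_rng(adj_ss)

    mask = adj_rng.random((n, n)) < config.connection_probability
    np.fill_diagonal(mask, False)
    mask[n_exc:, n_exc:] = False  # no inhibitory -> inhibitory synapses
    pre, post = np.nonzero(mask)
    pre = pre.astype(np.int32)
    post = post.astype(np.int32)

    exc_pre = pre < n_exc
    delay_rng = np.random.default_rng(delay_ss)
    delay = np.full(len(pre), INHIBITORY_DELAY, dtype=np.int16)
    delay[exc_pre] = delay_rng.integers(
        DELAY_MIN, DELAY_MAX + 1, size=int(exc_pre.sum()), dtype=np.int16
    )

    weight = np.where(exc_pre, config.w_exc_init, config.w_inh_init).astype(np.float64)
    plastic = exc_pre & (post < n_exc)

    topo = NetworkTopology(
        n_neurons=n,
        n_excitatory=n_exc,
        pre=pre,
        post=post,
        weight=weight,
        delay=delay,
        plastic=plastic,
    )
    if config.initial_weight_range is not None:
        low, high = config.initial_weight_range
        topo = sample_initial_weights(topo, (low, high), rng=np.random.default_rng(weight_ss))
    return topo


def sample_initial_weights(
    topology: NetworkTopology,
    weight_range: tuple[float, float],
    w_max: float = 10.0,
    rng: np.random.Generator | int | None = None,
) -> NetworkTopology:
    """Redraw the plastic weights i.i.d. uniform on ``[low, high]``.

    Inhibitory and non-plastic excitatory weights are left untouched.
    The range must lie within the hard bounds ``[0, w_max]``.
    """
    low, high = weight_range
    if not (0.0 <= low <= high <= w_max):
        raise ValueError(
            f"initial weight range ({low}, {high}) must satisfy 0 <= low <= high <= {w_max}"
        )
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = topology.copy()
    n_plastic = int(out.plastic.sum())
    out.weight[out.plastic] = rng.uniform(low, high, size=n_plastic)
    return out


# ----------------------------------------------------------------------
# deterministic micro-fixtures for oracle tests
# ----------------------------------------------------------------------

def _fixture_chain3() -> NetworkTopology:
    # feed-forward triple: 0 -> 1 (w=10, d=1), 1 -> 2 (w=5, d=2)
    return NetworkTopology(
        n_neurons=3,
        n_excitatory=3,
        pre=[0, 1],
        post=[1, 2],
        weight=[10.0, 5.0],
        delay=[1, 2],
        plastic=[True, True],
    )


def _fixture_star5() -> NetworkTopology:
    # hub 0 with 4 leaves feeding in: leaf k -> 0 with w = 8, 6, 4, 2 and d = 1..4
    return NetworkTopology(
        n_neurons=5,
        n_excitatory=5,
        pre=[1, 2, 3, 4],
        post=[0, 0, 0, 0],
        weight=[8.0, 6.0, 4.0, 2.0],
        delay=[1, 2, 3, 4],
        plastic=[True, True, True, True],
    )


def _fixture_loop4() -> NetworkTopology:
    # directed cycle 0 -> 1 -> 2 -> 3 -> 0, mixed weights 9, 6, 3, 1 and d = 1, 2, 3, 4
    return NetworkTopology(
        n_neurons=4,
        n_excitatory=4,
        pre=[0, 1, 2, 3],
        post=[1, 2, 3, 0],
        weight=[9.0, 6.0, 3.0, 1.0],
        delay=[1, 2, 3, 4],
        plastic=[True, True, True, True],
    )


_FIXTURES = {
    "chain3": _fixture_chain3,
    "star5": _fixture_star5,
    "loop4": _fixture_loop4,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def make_fixture(name: str) -> NetworkTopology:
    """Return a tiny deterministic topology for hand-checking statistics.

    Catalogue:

    - ``chain3``: feed-forward triple 0->1 (w=10, d=1), 1->2 (w=5, d=2).
    - ``star5``: hub 0 receiving from leaves 1-4 with weights 8, 6, 4, 2
      and delays 1-4; the hub has no efferents.
    - ``loop4``: directed cycle 0->1->2->3->0 with weights 9, 6, 3, 1 and
      delays 1, 2, 3, 4.

    All fixture neurons are excitatory and all synapses plastic.
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        ) from None
    return factory()
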