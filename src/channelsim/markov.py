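"""Linear hidden-Markov topologies of ion-channel gating and their rate parameterizations.

A gating model is a linear chain of states, each labeled by its conductance
class: ``"C"`` (closed, non-conducting) or ``"O"`` (open, conducting). State
``i`` exchanges only with its neighbors ``i±1``; the kinetics are set by the
directed transition rates ``k_ij`` (s^-1). The rate vector is laid out edge by
edge from state 1 outward, alternating forward/backward::

    [k_12, k_21, k_23, k_32, ..., k_{n-1,n}, k_{n,n-1}]

so an n-state chain carries exactly ``2*(n-1)`` rates. Reading a chain
backwards yields the same physical model, so topologies are identified up to
chain reversal, and for palindromic label strings the rate vector has a
canonical orientation (``k_12 > k_{n,n-1}``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Topology",
    "KineticModel",
    "RateRange",
    "enumerate_linear_topologies",
    "interconductance_rank",
    "generator_matrix",
    "stationary_distribution",
    "sample_rates",
    "canonicalize_labels",
]

_VALID = frozenset("CO")


@dataclass(frozen=True)
class Topology:
    """Conductance labeling of a linear chain of gating states."""

    labels: str

    def __post_init__(self) -> None:
        if not set(self.labels) <= _VALID:
            raise ValueError(f"labels must be drawn from 'C'/'O', got {self.labels!r}")
        if "C" not in self.labels or "O" not in self.labels:
            raise ValueError("a topology needs at least one closed and one open state")

    @property
    def n_states(self) -> int:
        return len(self.labels)

    @property
    def n_rates(self) -> int:
        return 2 * (self.n_states - 1)

    @property
    def is_palindromic(self) -> bool:
        return self.labels == self.labels[::-1]

    def reversed(self) -> "Topology":
        return Topology(self.labels[::-1])

    def canonical(self) -> "Topology":
        """Lexicographic minimum of the chain and its reversal ('C' < 'O')."""
        return Topology(min(self.labels, self.labels[::-1]))

    @property
    def open_mask(self) -> np.ndarray:
        return np.frombuffer(self.labels.encode(), dtype=np.uint8) == ord("O")

    def __str__(self) -> str:  # serialized form is the bare label string
        return self.labels


@dataclass(frozen=True)
class RateRange:
    """Log-uniform sampling range for transition rates, in s^-1."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"require 0 < lo < hi, got ({self.lo}, {self.hi})")


@dataclass(frozen=True)
class KineticModel:
    """A topology plus its directed nearest-neighbor transition rates."""

    topology: Topology
    rates: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "rates", rates)
        if rates.shape != (self.topology.n_rates,):
            raise ValueError(
                f"{self.topology} needs {self.topology.n_rates} rates, "
                f"got shape {rates.shape}"
            )
        if np.any(rates < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_states(self) -> int:
        return self.topology.n_states

    def forward_backward(self) -> tuple[np.ndarray, np.ndarray]:
        """Split the alternating layout into (k_{i,i+1}, k_{i+1,i}) arrays."""
        return self.rates[0::2], self.rates[1::2]

    def to_dict(self) -> dict:
        return {
            "topology": self.topology.labels,
            "rates": self.rates.tolist(),
            "rate_order": _rate_order(self.topology.n_states),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KineticModel":
        return cls(Topology(d["topology"]), np.asarray(d["rates"], dtype=float))


def _rate_order(n_states: int) -> list[str]:
    order = []
    for i in range(1, n_states):
        order += [f"k{i}{i + 1}", f"k{i + 1}{i}"]
    return order


def enumerate_linear_topologies(n_states: int) -> list[Topology]:
    """All conductance labelings of a linear chain, up to chain reversal.

    Labelings that are all-closed or all-open are excluded (they produce no
    gating events). The returned list is sorted lexicographically on the
    canonical representative, giving a stable class index for classification.

    For ``n_states=5`` this yields the 18 distinct linear five-state
    topologies.
    """
    if n_states < 2:
        raise ValueError("a gating chain needs at least 2 states")
    seen: set[str] = set()
    for bits in range(1, 2**n_states - 1):  # skip uniform labelings
        labels = "".join("O" if bits & (1 << i) else "C" for i in range(n_states))
        seen.add(min(labels, labels[::-1]))
    return [Topology(s) for s in sorted(seen)]


def interconductance_rank(topology: Topology) -> int:
    """Number of independent closed-open links of the chain.

    Computed as the matrix rank of the closed-to-open adjacency block: rows
    index closed states, columns open states, entry 1 iff the two states are
    chain neighbors. This rank constrains how much of the model is
    identifiable from the observable conductance signal.
    """
    labels = topology.labels
    closed = [i for i, c in enumerate(labels) if c == "C"]
    opened = [i for i, c in enumerate(labels) if c == "O"]
    block = np.zeros((len(closed), len(opened)), dtype=int)
    for r, i in enumerate(closed):
        for c, j in enumerate(opened):
            if abs(i - j) == 1:
                block[r, c] = 1
    return int(np.linalg.matrix_rank(block)) if block.size else 0


def generator_matrix(model: KineticModel) -> np.ndarray:
    """CTMC generator Q with Q[i, j] = k_{ij} for |i-j| = 1, diagonal = -row sum."""
    n = model.n_states
    fwd, bwd = model.forward_backward()
    q = np.zeros((n, n))
    for i in range(n - 1):
        q[i, i + 1] = fwd[i]
        q[i + 1, i] = bwd[i]
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def stationary_distribution(model: KineticModel) -> np.ndarray:
    """Equilibrium occupancy pi with pi @ Q = 0 and sum(pi) = 1.

    On a linear chain the stationary law satisfies detailed balance,
    pi_i * k_{i,i+1} = pi_{i+1} * k_{i+1,i}, which is used directly: it is
    exact, positive and cheap.
    """
    fwd, bwd = model.forward_backward()
    if np.any(fwd <= 0) or np.any(bwd <= 0):
        raise np.linalg.LinAlgError(
            "chain is not irreducible: some nearest-neighbor rate is zero"
        )
    log_pi = np.concatenate([[0.0], np.cumsum(np.log(fwd) - np.log(bwd))])
    log_pi -= log_pi.max()
    pi = np.exp(log_pi)
    return pi / pi.sum()


def sample_rates(
    topology: Topology,
    ranges: RateRange | Sequence[RateRange],
    seed: int | np.random.Generator,
) -> KineticModel:
    """Draw a model with rates log-uniform within the given range(s).

    Each directed rate is drawn independently as ``10**u`` with ``u`` uniform
    on ``[log10 lo, log10 hi]``; either one shared :class:`RateRange` or one
    per directed rate may be given. The resulting rate vector is put into its
    canonical orientation (see :func:`canonicalize_labels`).
    """
    rng = np.random.default_rng(seed)
    n = topology.n_rates
    if isinstance(ranges, RateRange):
        ranges = [ranges] * n
    if len(ranges) != n:
        raise ValueError(f"need {n} rate ranges, got {len(ranges)}")
    lo = np.log10([r.lo for r in ranges])
    hi = np.log10([r.hi for r in ranges])
    rates = 10.0 ** rng.uniform(lo, hi)
    return KineticModel(topology, canonicalize_labels(topology, rates))


def canonicalize_labels(topology: Topology, rates: np.ndarray) -> np.ndarray:
    """Resolve the orientation ambiguity of palindromic chains.

    A palindromic topology (e.g. COCOC) read backwards is the same physical
    model, so the same kinetics admit two rate-vector layouts. The canonical
    layout enforces ``k_12 > k_{n,n-1}``: if the topology is palindromic and
    ``k_12 < k_{n,n-1}`` the fully reversed layout
    ``[k_{n,n-1}, k_{n-1,n}, ..., k_21, k_12]`` is returned, otherwise the
    input is returned unchanged. Idempotent by construction.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (topology.n_rates,):
        raise ValueError("rate vector does not match topology layout")
    if topology.is_palindromic and rates[0] < rates[-1]:
        return rates[::-1].copy()
    return rates
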