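"""Four-state Markov model of two correlated binary traits.

The composite state space crosses colouration (cryptic/aposematic) with
aggregation (solitary/group-living):

    index 0  SC  solitary-cryptic
    index 1  SA  solitary-aposematic
    index 2  GC  group-cryptic
    index 3  GA  group-aposematic

Under the correlated-evolution model both traits never change in the
same instant, so the four dual transitions SC<->GA and SA<->GC have rate
zero and eight single-trait rates remain.  The canonical numbering of
those eight rates is::

    q1: GC->SC   q2: SA->SC   q3: SC->GC   q4: GA->GC
    q5: SC->SA   q6: GA->SA   q7: GC->GA   q8: SA->GA

which makes (q1,q3), (q2,q5), (q4,q7), (q6,q8) the forward/backward
pairs along each edge of the state cycle, (q1,q6)/(q3,q8) the
group-loss/group-gain rates in the two colour contexts, and
(q2,q4)/(q5,q7) the colour rates in the two aggregation contexts.

Constrained models are named ``nXY...`` (rates X, Y, ... fixed at zero:
the transitions are impossible) and ``eqXY`` (rates X and Y share one
free parameter).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import IntEnum

import numpy as np
import scipy.linalg

__all__ = [
    "CompositeState",
    "N_STATES",
    "STATE_NAMES",
    "LONG_STATE_NAMES",
    "RATE_TRANSITIONS",
    "N_RATES",
    "ModelSpec",
    "GENERAL",
    "build_rate_matrix",
    "transition_probabilities",
    "stationary_distribution",
    "StationaryResult",
    "is_irreducible",
]


class CompositeState(IntEnum):
    """Joint (aggregation, colouration) state, in canonical index order."""

    SC = 0  # solitary-cryptic
    SA = 1  # solitary-aposematic
    GC = 2  # group-cryptic
    GA = 3  # group-aposematic

    @property
    def colour(self) -> str:
        return "aposematic" if self in (CompositeState.SA, CompositeState.GA) else "cryptic"

    @property
    def grouping(self) -> str:
        return "group" if self in (CompositeState.GC, CompositeState.GA) else "solitary"


N_STATES = 4
STATE_NAMES = ("SC", "SA", "GC", "GA")
LONG_STATE_NAMES = (
    "solitary-cryptic",
    "solitary-aposematic",
    "group-cryptic",
    "group-aposematic",
)

#: rate index (1-based) -> (from_state, to_state)
RATE_TRANSITIONS: dict[int, tuple[CompositeState, CompositeState]] = {
    1: (CompositeState.GC, CompositeState.SC),
    2: (CompositeState.SA, CompositeState.SC),
    3: (CompositeState.SC, CompositeState.GC),
    4: (CompositeState.GA, CompositeState.GC),
    5: (CompositeState.SC, CompositeState.SA),
    6: (CompositeState.GA, CompositeState.SA),
    7: (CompositeState.GC, CompositeState.GA),
    8: (CompositeState.SA, CompositeState.GA),
}

N_RATES = 8

#: state pairs whose direct interchange is forbidden (both traits at once)
DUAL_TRANSITIONS = (
    (CompositeState.SC, CompositeState.GA),
    (CompositeState.GA, CompositeState.SC),
    (CompositeState.SA, CompositeState.GC),
    (CompositeState.GC, CompositeState.SA),
)


class ModelError(ValueError):
    """Invalid model specification or rate vector."""


@dataclass(frozen=True)
class ModelSpec:
    """A named constraint pattern over the eight transition rates.

    ``zero_set`` lists rates fixed at 0; ``equality_partition`` groups
    the remaining rate indices into classes sharing one free parameter.
    The free-parameter count K is the number of equality classes.
    """

    name: str
    zero_set: frozenset[int] = frozenset()
    equality_partition: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self):
        zero = frozenset(int(i) for i in self.zero_set)
        if not zero <= set(range(1, N_RATES + 1)):
            raise ModelError(f"zero_set indices must be in 1..8, got {sorted(zero)}")
        part = self.equality_partition
        if not part:
            part = tuple((i,) for i in sorted(set(range(1, N_RATES + 1)) - zero))
        else:
            part = tuple(tuple(sorted(int(i) for i in cls)) for cls in part)
        covered: list[int] = [i for cls in part for i in cls]
        expected = sorted(set(range(1, N_RATES + 1)) - zero)
        if sorted(covered) != expected or len(covered) != len(set(covered)):
            raise ModelError(
                f"equality_partition must partition the non-zero rates {expected}, "
                f"got {part}"
            )
        object.__setattr__(self, "zero_set", zero)
        object.__setattr__(self, "equality_partition", tuple(sorted(part)))

    @property
    def k(self) -> int:
        """Number of free rate parameters."""
        return len(self.equality_partition)

    def expand(self, free: np.ndarray) -> np.ndarray:
        """Map K free parameters to the full q1..q8 vector (0-based array)."""
        free = np.asarray(free, dtype=float)
        if free.shape != (self.k,):
            raise ModelError(f"expected {self.k} free parameters, got shape {free.shape}")
        q = np.zeros(N_RATES)
        for value, cls in zip(free, self.equality_partition):
            for i in cls:
                q[i - 1] = value
        return q

    def project(self, q: np.ndarray) -> np.ndarray:
        """Project a full rate vector onto this spec's free parameters
        (class means), the reverse of :meth:`expand`."""
        q = np.asarray(q, dtype=float)
        return np.array([np.mean([q[i - 1] for i in cls]) for cls in self.equality_partition])

    def satisfied_by(self, q: np.ndarray) -> bool:
        q = np.asarray(q, dtype=float)
        if any(q[i - 1] != 0.0 for i in self.zero_set):
            return False
        return all(
            len({q[i - 1] for i in cls}) == 1 for cls in self.equality_partition
        )

    def nests_within(self, other: "ModelSpec") -> bool:
        """True when ``other``'s constraints are implied by this spec's,
        i.e. this model is nested inside ``other`` and its maximized
        likelihood can never exceed ``other``'s."""
        if not other.zero_set <= self.zero_set:
            return False
        for cls in other.equality_partition:
            live = [i for i in cls if i not in self.zero_set]
            if len(live) == len(cls):
                if len(live) > 1 and not any(
                    set(live) <= set(mine) for mine in self.equality_partition
                ):
                    return False
            elif live:  # partially zeroed class: equality no longer implied
                return False
        return True

    def to_json(self) -> str:
        return json.dumps(
            {
                "name": self.name,
                "zero": sorted(self.zero_set),
                "equal": [list(cls) for cls in self.equality_partition],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        return cls(
            name=d["name"],
            zero_set=frozenset(d["zero"]),
            equality_partition=tuple(tuple(c) for c in d["equal"]),
        )

    @classmethod
    def zero_model(cls, indices: "frozenset[int] | set[int] | tuple[int, ...]") -> "ModelSpec":
        """The ``n``-style model with the given rates impossible."""
        idx = sorted(int(i) for i in indices)
        return cls(name="n" + "".join(str(i) for i in idx), zero_set=frozenset(idx))

    @classmethod
    def equal_model(cls, i: int, j: int) -> "ModelSpec":
        """The ``eqXY`` model with rates i and j sharing one parameter."""
        i, j = sorted((int(i), int(j)))
        part = tuple(
            (k,) for k in range(1, N_RATES + 1) if k not in (i, j)
        ) + ((i, j),)
        return cls(name=f"eq{i}{j}", equality_partition=part)


GENERAL = ModelSpec(name="general")


def _parse_name(name: str) -> ModelSpec:
    if name == "general":
        return GENERAL
    if name.startswith("eq") and len(name) == 4 and name[2:].isdigit():
        return ModelSpec.equal_model(int(name[2]), int(name[3]))
    if name.startswith("n") and name[1:].isdigit() and len(set(name[1:])) == len(name[1:]):
        idx = [int(c) for c in name[1:]]
        if all(1 <= i <= 8 for i in idx) and 0 < len(idx) < 8:
            return ModelSpec.zero_model(idx)
    raise ModelError(f"unknown model name: {name!r}")


def spec_by_name(name: str) -> ModelSpec:
    """Resolve ``'general'``, ``'nXY...'`` or ``'eqXY'`` to a ModelSpec."""
    return _parse_name(name)


def build_rate_matrix(q: np.ndarray, spec: ModelSpec | None = None) -> np.ndarray:
    """Assemble the 4x4 generator from the 8-rate vector ``q1..q8``.

    ``q`` is the full 8-vector (index 0 is q1).  If ``spec`` is given,
    rates in its zero set are forced to 0 and each equality class is
    replaced by its shared value (the class mean, exact when the inputs
    already satisfy the constraint).  Rows sum to zero; the dual
    transitions stay structurally zero.
    """
    q = np.asarray(q, dtype=float)
    if q.shape != (N_RATES,):
        raise ModelError(f"expected 8 rates, got shape {q.shape}")
    if np.any(q < 0) or not np.all(np.isfinite(q)):
        raise ModelError(f"rates must be finite and nonnegative, got {q}")
    if spec is not None:
        q = spec.expand(spec.project(q))
    Q = np.zeros((N_STATES, N_STATES))
    for idx, (src, dst) in RATE_TRANSITIONS.items():
        Q[src, dst] = q[idx - 1]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def rates_from_matrix(Q: np.ndarray) -> np.ndarray:
    """Extract the q1..q8 vector from a generator."""
    return np.array([Q[src, dst] for src, dst in RATE_TRANSITIONS.values()])


_EIG_COND_MAX = 1e8


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t), a stochastic matrix.

    Uses scipy's scaling-and-squaring Pade implementation, which stays
    robust for the near-defective generators that arise under zero
    constraints.  Entries are clipped of float dust so each row is a
    probability vector.
    """
    if t < 0:
        raise ModelError(f"elapsed time must be nonnegative, got {t}")
    P = scipy.linalg.expm(np.asarray(Q, dtype=float) * float(t))
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


class _EdgeKernel:
    """Vectorized P(t) over many branch lengths for one fixed Q.

    An eigendecomposition fast path covers the typical diagonalizable
    case; when Q is near-defective (condition number of the eigenvector
    matrix above 1e8, or complex dust above tolerance) every length
    falls back to expm.
    """

    def __init__(self, Q: np.ndarray):
        self.Q = np.asarray(Q, dtype=float)
        self._use_eig = False
        try:
            w, V = np.linalg.eig(self.Q)
            cond = np.linalg.cond(V)
            if np.isfinite(cond) and cond < _EIG_COND_MAX:
                self._w = w
                self._V = V
                self._Vinv = np.linalg.inv(V)
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    def __call__(self, ts: np.ndarray) -> np.ndarray:
        """Return stacked P(t) with shape (len(ts), 4, 4)."""
        ts = np.asarray(ts, dtype=float)
        if self._use_eig:
            ew = np.exp(ts[:, None] * self._w[None, :])  # (E, 4)
            P = (self._V[None, :, :] * ew[:, None, :]) @ self._Vinv
            P = np.ascontiguousarray(P.real)
        else:
            P = np.stack([scipy.linalg.expm(self.Q * t) for t in ts])
        np.clip(P, 0.0, 1.0, out=P)
        P /= P.sum(axis=2, keepdims=True)
        return P


@dataclass
class StationaryResult:
    """Stationary distribution with an irreducibility guarantee flag.

    ``unique`` is True only when the chain is irreducible, in which
    case the distribution is the unique solution; otherwise the vector
    is one least-squares solution (possibly concentrated on absorbing
    states) and should be interpreted with care."""

    pi: np.ndarray
    unique: bool

    def __iter__(self):
        yield from (self.pi, self.unique)


def is_irreducible(Q: np.ndarray) -> bool:
    """Whether every state reaches every other through positive rates."""
    n = Q.shape[0]
    adj = (np.asarray(Q) > 0).astype(float)
    np.fill_diagonal(adj, 1.0)
    reach = np.linalg.matrix_power(adj, n - 1)
    return bool(np.all(reach > 0))


def stationary_distribution(Q: np.ndarray) -> StationaryResult:
    """Solve pi Q = 0, sum(pi) = 1.

    For a reducible generator the solution is not unique; the returned
    vector is then one least-squares solution and ``unique`` is False.
    """
    Q = np.asarray(Q, dtype=float)
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones((1, n))])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    s = pi.sum()
    pi = pi / s if s > 0 else np.full(n, 1.0 / n)
    return StationaryResult(pi=pi, unique=is_irreducible(Q))
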