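"""Maximum-likelihood fitting of one constrained rate model.

Free rates are optimized on the log scale with a derivative-free
Nelder-Mead search (matrix-exponential gradients are awkward and the
surfaces under zero constraints are multimodal, so we multi-start
instead).  Rates are bounded to [1e-9, 100] events per unit branch
time; hits on either bound are flagged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import scipy.optimize

from .ctmc import (
    GENERAL,
    ModelSpec,
    RATE_TRANSITIONS,
    STATE_NAMES,
    build_rate_matrix,
    is_irreducible,
)
from .likelihood import PruneEngine, RootPolicy, TipStates
from .tree_io import PhyloTree

__all__ = ["OptimizerSettings", "FitResult", "fit_model"]

RATE_MIN = 1e-9
RATE_MAX = 100.0
#: restarts are drawn log-uniformly from this window rather than the full
#: [RATE_MIN, RATE_MAX] bounds: starts pinned at 1e-9 sit on a flat
#: plateau of the likelihood and waste restarts
START_LOW = 1e-2
START_HIGH = 10.0


@dataclass
class OptimizerSettings:
    """Knobs for the multi-start local search."""

    n_restarts: int = 10
    seed: int = 0
    rate_min: float = RATE_MIN
    rate_max: float = RATE_MAX
    loglik_tol: float = 1e-8
    max_iter: int = 4000
    root: RootPolicy = RootPolicy.FLAT
    #: optional warm start: full q1..q8 vector (e.g. the general-model MLE)
    #: projected onto the spec's constraints and used as an extra start
    init_rates: np.ndarray | None = None


@dataclass
class FitResult:
    """MLE of one model: rates, log-likelihood, K and AIC."""

    name: str
    mle_rates: np.ndarray  # full q1..q8, exact zeros where constrained
    loglik: float
    k: int
    aic: float
    converged: bool
    n_restarts: int
    seed: int
    root_policy: str = RootPolicy.FLAT.value
    at_bound: bool = False
    irreducible: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["mle_rates"] = [float(x) for x in self.mle_rates]
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        d = dict(d)
        d["mle_rates"] = np.asarray(d["mle_rates"], dtype=float)
        return cls(**d)

    @classmethod
    def from_json(cls, text: str) -> "FitResult":
        return cls.from_dict(json.loads(text))

    def rates_table(self) -> "list[tuple[int, str, str, float]]":
        """(index, from_state, to_state, mle) rows for the 8 rates."""
        return [
            (i, STATE_NAMES[src], STATE_NAMES[dst], float(self.mle_rates[i - 1]))
            for i, (src, dst) in RATE_TRANSITIONS.items()
        ]


class _Objective:
    """Negative log-likelihood over log free rates, with the pruning
    engine (traversal waves, tip partials) prepared once."""

    def __init__(self, tree: PhyloTree, states: TipStates, spec: ModelSpec,
                 settings: OptimizerSettings):
        self.spec = spec
        self.settings = settings
        self.engine = PruneEngine(tree, states)
        self.n_evals = 0

    def loglik(self, log_free: np.ndarray) -> float:
        free = np.exp(np.clip(log_free, np.log(self.settings.rate_min),
                              np.log(self.settings.rate_max)))
        Q = build_rate_matrix(self.spec.expand(free))
        self.n_evals += 1
        try:
            return self.engine.loglik(Q, self.settings.root)
        except ArithmeticError:
            return -np.inf

    def __call__(self, log_free: np.ndarray) -> float:
        ll = self.loglik(log_free)
        return -ll if np.isfinite(ll) else 1e12


def fit_model(
    tree: PhyloTree,
    states: TipStates,
    spec: ModelSpec = GENERAL,
    settings: OptimizerSettings | None = None,
) -> FitResult:
    """Maximize the pruning log-likelihood over the spec's free rates.

    Runs ``settings.n_restarts`` Nelder-Mead searches from log-uniform
    draws (plus a warm start projected from ``settings.init_rates`` if
    supplied) and keeps the best.  Deterministic for a fixed seed.  If
    no restart converges the best point found is still returned, with
    ``converged=False``.
    """
    settings = settings or OptimizerSettings()
    obj = _Objective(tree, states, spec, settings)
    rng = np.random.default_rng(settings.seed)
    k = spec.k

    starts: list[np.ndarray] = []
    if settings.init_rates is not None:
        proj = np.clip(spec.project(np.asarray(settings.init_rates, dtype=float)),
                       settings.rate_min, settings.rate_max)
        starts.append(np.log(proj))
    lo, hi = np.log(START_LOW), np.log(START_HIGH)
    for _ in range(max(settings.n_restarts, 1)):
        starts.append(rng.uniform(lo, hi, size=k))

    best_x = starts[0]
    best_f = np.inf
    converged = False
    for x0 in starts:
        res = scipy.optimize.minimize(
            obj,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": settings.max_iter,
                "fatol": settings.loglik_tol,
                "xatol": 1e-6,
                "adaptive": k > 4,
            },
        )
        if res.fun < best_f:
            best_f = res.fun
            best_x = np.asarray(res.x)
        if res.success:
            converged = True

    log_lo = np.log(settings.rate_min)
    log_hi = np.log(settings.rate_max)
    clipped = np.clip(best_x, log_lo, log_hi)
    free = np.exp(clipped)
    at_bound = bool(np.any(clipped <= log_lo + 1e-6) or np.any(clipped >= log_hi - 1e-6))
    q = spec.expand(free)
    Q = build_rate_matrix(q)
    loglik = -best_f
    aic = 2.0 * k - 2.0 * loglik
    return FitResult(
        name=spec.name,
        mle_rates=q,
        loglik=float(loglik),
        k=k,
        aic=float(aic),
        converged=converged,
        n_restarts=settings.n_restarts,
        seed=settings.seed,
        root_policy=settings.root.value,
        at_bound=at_bound,
        irreducible=is_irreducible(Q),
    )
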