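"""The full constrained-model space and AIC model comparison.

The candidate set contains the unconstrained general model, every model
obtained by forbidding a nonempty proper subset of the eight transitions
(2^8 - 2 = 254 "n" models), and the eight "eq" models that tie one pair
of rates together: four symmetric pairs (eq13, eq25, eq47, eq68) and
four trait-independence pairs (eq16, eq24, eq38, eq57).  Models are
ranked by AIC = 2K - 2 logLik; evidence ratios are exp((AIC_min-AIC)/2)
and Akaike weights normalize those ratios over the whole fitted set.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from .ctmc import GENERAL, ModelSpec, N_RATES
from .fitting import FitResult, OptimizerSettings, fit_model
from .likelihood import TipStates
from .tree_io import PhyloTree

__all__ = [
    "enumerate_zero_models",
    "equality_models",
    "full_model_set",
    "build_aic_table",
    "run_model_selection",
    "AIC_COLUMNS",
]

AIC_COLUMNS = ["model", "K", "logLik", "AIC", "dAIC", "LikRatio", "AkaikeWeight"]

#: the four symmetric pairs and four independence pairs, in canonical order
EQUALITY_PAIRS = ((1, 3), (2, 5), (4, 7), (6, 8), (1, 6), (2, 4), (3, 8), (5, 7))


def enumerate_zero_models() -> list[ModelSpec]:
    """All 254 models with a nonempty proper subset of rates forbidden.

    Named ``n`` + ascending digits (n1, n12, ... n2345678); the empty
    constraint (the general model) and the all-zero model are excluded.
    Ordering is deterministic: by constraint size, then lexicographic.
    """
    specs = []
    for size in range(1, N_RATES):
        for combo in itertools.combinations(range(1, N_RATES + 1), size):
            specs.append(ModelSpec.zero_model(combo))
    return specs


def equality_models() -> list[ModelSpec]:
    """The eight two-rate equality models, each with K = 7."""
    return [ModelSpec.equal_model(i, j) for i, j in EQUALITY_PAIRS]


def full_model_set() -> list[ModelSpec]:
    """general + 254 zero-constrained + 8 equality models (263 specs)."""
    return [GENERAL] + enumerate_zero_models() + equality_models()


def build_aic_table(fits: "list[FitResult]") -> pd.DataFrame:
    """Model-comparison table sorted by AIC (ties broken by name).

    Columns: model, K, logLik, AIC, dAIC, LikRatio, AkaikeWeight; the
    weights are normalized over all supplied fits, so they sum to one
    for the full set even when only the head of the table is displayed.
    """
    if not fits:
        raise ValueError("at least one fit is required")
    names = [f.name for f in fits]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate model names: {dupes}")
    df = pd.DataFrame(
        {
            "model": names,
            "K": [f.k for f in fits],
            "logLik": [f.loglik for f in fits],
            "AIC": [f.aic for f in fits],
        }
    )
    df["dAIC"] = df["AIC"] - df["AIC"].min()
    df["LikRatio"] = np.exp(-df["dAIC"] / 2.0)
    df["AkaikeWeight"] = df["LikRatio"] / df["LikRatio"].sum()
    df = df.sort_values(["AIC", "model"], kind="mergesort").reset_index(drop=True)
    return df[AIC_COLUMNS]


def run_model_selection(
    tree: PhyloTree,
    states: TipStates,
    settings: OptimizerSettings | None = None,
    specs: "list[ModelSpec] | None" = None,
    output_dir: "Path | str | None" = None,
    progress: bool = False,
) -> "tuple[pd.DataFrame, dict[str, FitResult]]":
    """Fit every candidate model and build the comparison table.

    The general model is fitted first and its MLE, projected onto each
    constraint, seeds one extra restart of every constrained fit.  With
    ``output_dir`` the sweep is resumable: completed fits are serialized
    as ``fit_<name>.json`` and skipped on re-run.  A failing fit is
    recorded (converged flag false, or an error note) without aborting
    the sweep.
    """
    settings = settings or OptimizerSettings()
    if specs is None:
        specs = full_model_set()
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # general first: warm starts for everything else
    ordered = sorted(specs, key=lambda s: (s.name != "general", s.name))
    fits: dict[str, FitResult] = {}
    general_rates = settings.init_rates
    failures: dict[str, str] = {}
    for spec in ordered:
        path = out / f"fit_{spec.name}.json" if out is not None else None
        if path is not None and path.exists():
            fits[spec.name] = FitResult.from_json(path.read_text())
        else:
            import dataclasses

            local = dataclasses.replace(settings, init_rates=general_rates)
            try:
                fits[spec.name] = fit_model(tree, states, spec, local)
            except Exception as exc:  # pragma: no cover - defensive
                failures[spec.name] = str(exc)
                continue
            if path is not None:
                path.write_text(fits[spec.name].to_json())
        if spec.name == "general":
            general_rates = fits["general"].mle_rates
        if progress:
            f = fits[spec.name]
            print(f"{spec.name}\tlogLik={f.loglik:.3f}\tK={f.k}\tAIC={f.aic:.3f}")

    _repair_nesting(tree, states, settings, ordered, fits, out)

    table = build_aic_table(list(fits.values()))
    table.attrs["failures"] = failures
    irr = {name: f.irreducible for name, f in fits.items()}
    table.insert(len(table.columns), "reducible", [not irr[m] for m in table["model"]])
    if out is not None:
        write_aic_table(table, out / "aic_table.tsv")
        (out / "aic_table.json").write_text(table.to_json(orient="records", indent=1))
    return table, fits


_NESTING_TOL = 1e-6
_REPAIR_ROUNDS = 3


def _repair_nesting(tree, states, settings, specs, fits, out) -> None:
    """Enforce likelihood monotonicity across nested model pairs.

    A model nested inside another can never have a higher maximized
    likelihood; when finite optimization leaves such an inversion, the
    less-constrained model is refit warm-started from the winning nested
    solution.  A few rounds suffice because repairs only propagate
    improvements upward through the constraint lattice.
    """
    import dataclasses

    by_name = {s.name: s for s in specs if s.name in fits}
    pairs = [
        (child, parent)
        for child in by_name.values()
        for parent in by_name.values()
        if child.name != parent.name and child.nests_within(parent)
    ]
    for _ in range(_REPAIR_ROUNDS):
        dirty = False
        for child, parent in pairs:
            fc, fp = fits[child.name], fits[parent.name]
            if fc.loglik > fp.loglik + _NESTING_TOL:
                local = dataclasses.replace(
                    settings, n_restarts=1,
                    init_rates=np.maximum(fc.mle_rates, settings.rate_min),
                )
                refit = fit_model(tree, states, parent, local)
                if refit.loglik > fp.loglik:
                    fits[parent.name] = refit
                    if out is not None:
                        (out / f"fit_{parent.name}.json").write_text(refit.to_json())
                    dirty = True
        if not dirty:
            break


def write_aic_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_aic_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
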