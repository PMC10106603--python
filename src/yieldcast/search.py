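"""Exhaustive trait-subset search with repeated random-subset calibration.

Every non-empty subset of the candidate predictor traits (15 models for
the four traits NDVI, PH, DH, EARS) is fitted on each of ``n_iter``
random training subsets drawn from the training pool. Within one
iteration every combo sees the SAME training plots, so BIC comparisons
across combos are paired. The winning combo has the lowest median BIC
across iterations, and the representative model returned for validation
is the actually-fitted run sitting at the median (lower-middle order
statistic) of the winning combo's sorted BICs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._seeds import child_seed
from .ridge import LambdaSearch, RidgeTraitCV, RidgeTraitRegressor
from .trial import TrialTable

#: canonical predictor ordering (the field's conventional listing)
CANONICAL_TRAITS = ("ndvi", "ph", "dh", "ears")

MAX_CANDIDATE_TRAITS = 10  # exhaustive search guard: at most 2^10-1 combos


def canonical_combo(traits) -> tuple[str, ...]:
    """Normalize a trait collection to the canonical (ndvi, ph, dh, ears) order."""
    traits = list(traits)
    if not traits:
        raise ValueError("trait combo must be non-empty")
    if len(set(traits)) != len(traits):
        raise ValueError(f"duplicate traits in combo: {traits}")
    known = [t for t in traits if t in CANONICAL_TRAITS]
    extra = sorted(t for t in traits if t not in CANONICAL_TRAITS)
    ordered = [t for t in CANONICAL_TRAITS if t in known] + extra
    return tuple(ordered)


def enumerate_models(candidate_traits=CANONICAL_TRAITS) -> list[tuple[str, ...]]:
    """All 2^p - 1 non-empty predictor subsets, largest first.

    Deterministic order: by subset size descending, then lexicographic in
    canonical trait order — the full model first, the last single trait
    last.
    """
    traits = canonical_combo(candidate_traits)
    p = len(traits)
    if p > MAX_CANDIDATE_TRAITS:
        raise ValueError(f"exhaustive search limited to {MAX_CANDIDATE_TRAITS} traits, got {p}")
    combos: list[tuple[str, ...]] = []
    for size in range(p, 0, -1):
        combos.extend(itertools.combinations(traits, size))
    return combos


def _combo_sort_key(combo, traits_order):
    return (len(combo), tuple(traits_order.index(t) for t in combo))


@dataclass
class CalibrationRun:
    """One fitted model: iteration x combo, with its training subset and BIC."""

    iteration: int
    combo: tuple[str, ...]
    train_plot_ids: frozenset
    model: RidgeTraitRegressor
    bic: float
    lam: float
    r2_train: float
    rmse_train: float


@dataclass
class CalibrationEnsemble:
    """The full combo-by-iteration grid of calibrated models."""

    runs: list[CalibrationRun]
    training_size: int
    n_iter: int
    seed: int
    combo_summary: dict = field(default_factory=dict)
    best_combo: tuple[str, ...] | None = None
    representative_model: RidgeTraitRegressor | None = None
    skipped_iterations: list[int] = field(default_factory=list)

    def runs_for(self, combo) -> list[CalibrationRun]:
        combo = canonical_combo(combo)
        return [r for r in self.runs if r.combo == combo]

    def representative_for(self, combo) -> RidgeTraitRegressor:
        """The median-BIC (lower-middle) run of ``combo``."""
        runs = self.runs_for(combo)
        if not runs:
            raise KeyError(f"no runs for combo {combo}")
        runs = sorted(runs, key=lambda r: r.bic)
        return runs[(len(runs) - 1) // 2].model

    def to_flat_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "iteration": [r.iteration for r in self.runs],
                "combo": ["+".join(r.combo) for r in self.runs],
                "bic": [r.bic for r in self.runs],
                "lambda": [r.lam for r in self.runs],
                "r2_train": [r.r2_train for r in self.runs],
                "rmse_train": [r.rmse_train for r in self.runs],
            }
        )

    def to_dict(self) -> dict:
        return {
            "training_size": self.training_size,
            "n_iter": self.n_iter,
            "seed": self.seed,
            "best_combo": list(self.best_combo) if self.best_combo else None,
            "representative_model": (
                self.representative_model.to_dict() if self.representative_model else None
            ),
            "combo_summary": {
                "+".join(c): {k: float(v) for k, v in s.items()}
                for c, s in self.combo_summary.items()
            },
            "skipped_iterations": list(self.skipped_iterations),
        }


def _train_stats(model: RidgeTraitRegressor, X, y):
    pred = model.predict(X)
    rmse = float(np.sqrt(np.mean((y - pred) ** 2)))
    if np.std(pred) == 0 or np.std(y) == 0:
        return np.nan, rmse
    r = np.corrcoef(y, pred)[0, 1]
    return float(r**2), rmse


def _lower_median(values: np.ndarray) -> float:
    """Lower-middle order statistic: an actually-observed value even for even n."""
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def _draw_subset(pool_df: pd.DataFrame, combos, size: int, seed: int,
                 max_retries: int = 10):
    """Seeded draw of ``size`` plot ids, redrawn while any combo's predictor
    has zero variance on the subset (rare on continuous traits)."""
    all_traits = sorted({t for c in combos for t in c})
    for retry in range(max_retries + 1):
        rng = np.random.default_rng(seed if retry == 0 else child_seed(seed, "retry", retry))
        idx = rng.choice(len(pool_df), size=size, replace=False)
        sub = pool_df.iloc[idx]
        if all(sub[t].std() > 0 for t in all_traits):
            return sub
    return None


def calibrate_once(train_pool: TrialTable, combo, size: int, iteration_seed: int,
                   search: LambdaSearch | None = None) -> CalibrationRun:
    """Fit one combo on one seeded random training subset of ``size`` plots."""
    combo = canonical_combo(combo)
    pool = train_pool.complete_cases(list(combo) + ["gy"]).to_dataframe()
    if size > len(pool):
        raise ValueError(
            f"requested {size} training plots but only {len(pool)} complete cases for {combo}"
        )
    sub = _draw_subset(pool, [combo], size, iteration_seed)
    if sub is None:
        raise ValueError(f"degenerate training subset for combo {combo} after retries")
    return _fit_subset(sub, combo, iteration=1, seed=iteration_seed, search=search)


def _fit_subset(sub: pd.DataFrame, combo, iteration: int, seed: int,
                search: LambdaSearch | None) -> CalibrationRun:
    base = search if search is not None else LambdaSearch()
    X = sub[list(combo)]
    y = sub["gy"].to_numpy()
    est = RidgeTraitCV(
        LambdaSearch(grid=base.grid, n_grid=base.n_grid, k_folds=base.k_folds,
                     seed=child_seed(seed, "cvfolds"))
    ).fit(X, y)
    r2, rmse = _train_stats(est, X, y)
    return CalibrationRun(
        iteration=iteration,
        combo=combo,
        train_plot_ids=frozenset(sub["plot_id"]),
        model=est,
        bic=float(est.bic_) if est.bic_ is not None else -np.inf,
        lam=float(est.alpha_),
        r2_train=r2,
        rmse_train=rmse,
    )


def run_calibration(train_pool: TrialTable, combos=None, size: int = 50,
                    n_iter: int = 100, master_seed: int = 0,
                    search: LambdaSearch | None = None,
                    max_skipped_fraction: float = 0.2) -> CalibrationEnsemble:
    """Repeated random-subset calibration over all combos.

    Subsets are drawn from plots complete for every candidate trait plus
    GY, so all combos share the same plots within an iteration (paired
    BIC comparison). Iteration seeds derive deterministically from
    ``master_seed``. Aborts if more than ``max_skipped_fraction`` of
    iterations are degenerate.
    """
    if combos is None:
        combos = enumerate_models()
    combos = [canonical_combo(c) for c in combos]
    traits_order = canonical_combo({t for c in combos for t in c})
    all_traits = sorted({t for c in combos for t in c})
    pool = train_pool.complete_cases(all_traits + ["gy"]).to_dataframe()
    if size > len(pool):
        raise ValueError(
            f"requested {size} training plots but only {len(pool)} complete cases"
        )

    runs: list[CalibrationRun] = []
    skipped: list[int] = []
    for it in range(1, n_iter + 1):
        sub = _draw_subset(pool, combos, size, child_seed(master_seed, "calib", size, it))
        if sub is None:
            skipped.append(it)
            continue
        for combo in combos:
            runs.append(_fit_subset(sub, combo, iteration=it,
                                    seed=child_seed(master_seed, "fit", size, it),
                                    search=search))
    if len(skipped) > max_skipped_fraction * n_iter:
        raise RuntimeError(
            f"{len(skipped)}/{n_iter} iterations skipped as degenerate; pool too small "
            "or a predictor nearly constant"
        )

    ens = CalibrationEnsemble(runs=runs, training_size=size, n_iter=n_iter,
                              seed=master_seed, skipped_iterations=skipped)
    for combo in combos:
        bics = np.array([r.bic for r in runs if r.combo == combo])
        ens.combo_summary[combo] = {
            "median_bic": _lower_median(bics),
            "mean_bic": float(bics.mean()),
            "mean_r2_train": float(np.nanmean([r.r2_train for r in runs if r.combo == combo])),
            "mean_rmse_train": float(np.mean([r.rmse_train for r in runs if r.combo == combo])),
        }
    ens.best_combo = min(
        combos,
        key=lambda c: (ens.combo_summary[c]["median_bic"], _combo_sort_key(c, traits_order)),
    )
    ens.representative_model = ens.representative_for(ens.best_combo)
    return ens


class CalibrationSearch(BaseEstimator):
    """Estimator facade over :func:`run_calibration`.

    ``fit`` takes a :class:`TrialTable` (or a DataFrame with trait columns
    and ``gy``); ``predict`` delegates to the representative model of the
    best combo.
    """

    def __init__(self, candidate_traits=CANONICAL_TRAITS, size: int = 50,
                 n_iter: int = 100, master_seed: int = 0,
                 search: LambdaSearch | None = None):
        self.candidate_traits = candidate_traits
        self.size = size
        self.n_iter = n_iter
        self.master_seed = master_seed
        self.search = search

    def fit(self, table, y=None):
        if isinstance(table, pd.DataFrame):
            df = table.copy()
            if "plot_id" not in df.columns:
                df["plot_id"] = [f"p{i}" for i in range(len(df))]
            table = TrialTable(df)
        ens = run_calibration(
            table, enumerate_models(self.candidate_traits), size=self.size,
            n_iter=self.n_iter, master_seed=self.master_seed, search=self.search,
        )
        self.ensemble_ = ens
        self.best_combo_ = ens.best_combo
        self.representative_model_ = ens.representative_model
        self.combo_summary_ = ens.combo_summary
        return self

    def predict(self, X):
        if isinstance(X, TrialTable):
            X = X.to_dataframe()
        if isinstance(X, pd.DataFrame):
            X = X[list(self.best_combo_)]
        return self.representative_model_.predict(X)
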