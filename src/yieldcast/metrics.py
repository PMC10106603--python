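"""Validation metrics: observed-vs-predicted R^2, RMSE and benchmark deltas.

Prediction accuracy is the squared Pearson correlation between observed
and predicted grain yield on held-out plots, with the two-sided p-value
from the t-test with n - 2 degrees of freedom. Model-vs-benchmark
improvements are reported as relative percentages (a +50% accuracy gain
means R^2 rose from 0.40 to 0.60).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ridge import RidgeTraitRegressor
from .trial import TrialTable

#: smallest p-value reported; below this we clamp rather than print 0
P_FLOOR = 1e-15


def pearson_r2(x, y) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value.

    Requires n >= 3 and non-constant inputs. p-values below 1e-15 are
    floored there (reported as "< 1e-15" territory, never exactly 0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError(f"need at least 3 observations, got {len(x)}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return float(r**2), float(max(p, P_FLOOR))


@dataclass
class ValidationMetrics:
    """Held-out performance of one model on one validation set."""

    r2: float | None          # None when predictions are constant
    rmse: float
    p_value: float | None
    n: int
    slope: float | None       # observed ~ predicted OLS
    intercept_ov: float | None

    def to_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "p_value": self.p_value,
            "n": self.n, "slope": self.slope, "intercept_ov": self.intercept_ov,
        }


def evaluate(model: RidgeTraitRegressor, validation: TrialTable) -> ValidationMetrics:
    """Predict GY on the validation plots complete for the model's traits.

    RMSE is always reported; R^2/p/slope are None (flagged undefined) if
    the predictions are constant.
    """
    combo = [str(c) for c in model.feature_names_in_]
    cases = validation.complete_cases(combo + ["gy"]).to_dataframe()
    if len(cases) < 3:
        raise ValueError(f"need >= 3 complete validation cases, got {len(cases)}")
    obs = cases["gy"].to_numpy()
    pred = model.predict(cases[combo])
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(pred) == 0 or np.std(obs) == 0:
        return ValidationMetrics(r2=None, rmse=rmse, p_value=None,
                                 n=len(obs), slope=None, intercept_ov=None)
    r2, p = pearson_r2(obs, pred)
    slope, intercept = np.polyfit(pred, obs, 1)
    return ValidationMetrics(r2=r2, rmse=rmse, p_value=p, n=len(obs),
                             slope=float(slope), intercept_ov=float(intercept))


@dataclass
class ComparisonReport:
    """Best multivariate model vs the NDVI-only benchmark on shared plots."""

    best_model_metrics: ValidationMetrics
    benchmark_metrics: ValidationMetrics
    delta_r2_relative: float | None    # percent; None if benchmark r2 = 0
    delta_rmse_relative: float | None
    delta_r2_absolute: float | None = None   # filled when relative undefined
    delta_rmse_absolute: float | None = None

    def to_dict(self) -> dict:
        return {
            "best_model": self.best_model_metrics.to_dict(),
            "benchmark": self.benchmark_metrics.to_dict(),
            "delta_r2_relative_pct": self.delta_r2_relative,
            "delta_rmse_relative_pct": self.delta_rmse_relative,
            "delta_r2_absolute": self.delta_r2_absolute,
            "delta_rmse_absolute": self.delta_rmse_absolute,
        }


def compare_to_benchmark(best: RidgeTraitRegressor, benchmark: RidgeTraitRegressor,
                         validation: TrialTable) -> ComparisonReport:
    """Relative R^2 / RMSE deltas of ``best`` against the NDVI benchmark.

    Both models are evaluated on the same validation table. If the
    benchmark R^2 is 0 (or undefined), relative deltas are undefined and
    absolute deltas are reported instead.
    """
    bench_combo = tuple(str(c) for c in benchmark.feature_names_in_)
    if bench_combo != ("ndvi",):
        raise ValueError(f"benchmark must be the NDVI-only model, got {bench_combo}")
    m_best = evaluate(best, validation)
    m_bench = evaluate(benchmark, validation)
    if m_bench.r2 and m_best.r2 is not None:
        return ComparisonReport(
            best_model_metrics=m_best, benchmark_metrics=m_bench,
            delta_r2_relative=100.0 * (m_best.r2 - m_bench.r2) / m_bench.r2,
            delta_rmse_relative=100.0 * (m_best.rmse - m_bench.rmse) / m_bench.rmse,
        )
    return ComparisonReport(
        best_model_metrics=m_best, benchmark_metrics=m_bench,
        delta_r2_relative=None, delta_rmse_relative=None,
        delta_r2_absolute=(None if (m_best.r2 is None or m_bench.r2 is None)
                           else m_best.r2 - m_bench.r2),
        delta_rmse_absolute=m_best.rmse - m_bench.rmse,
    )


def relative_deltas(r2_best: float, r2_bench: float,
                    rmse_best: float, rmse_bench: float) -> tuple[float, float]:
    """The reporting convention for improvement percentages.

    Returns ``(delta_r2_pct, delta_rmse_pct)``; e.g. R^2 0.60 vs 0.40 and
    RMSE 0.9 vs 1.0 give (+50.0, -10.0).
    """
    if r2_bench == 0:
        raise ValueError("relative delta undefined for benchmark r2 = 0")
    return (100.0 * (r2_best - r2_bench) / r2_bench,
            100.0 * (rmse_best - rmse_bench) / rmse_bench)
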