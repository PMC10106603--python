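"""NDVI saturation analysis: stratified NDVI-GY correlation around a yield threshold.

Over dense wheat canopies NDVI loses sensitivity to further biomass, so
the NDVI-yield relation flattens in high-yielding plots. The analysis
splits plots at a grain-yield threshold (default 8 t/ha) and contrasts
the NDVI-GY squared correlation below vs above it; a large gap is the
signature of saturation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import pearson_r2
from .trial import TrialTable

DEFAULT_THRESHOLD = 8.0  # t/ha
MIN_STRATUM_N = 3


def stratify_by_yield(table: TrialTable, threshold: float = DEFAULT_THRESHOLD):
    """Partition plots into (below, above) the yield threshold.

    The boundary ``gy == threshold`` goes to "above" (closed on the
    right); either side may come back ``None`` when empty.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0 t/ha")
    df = table.to_dataframe()
    below_idx = df.index[df["gy"] < threshold]
    above_idx = df.index[df["gy"] >= threshold]
    below = table.select(below_idx) if len(below_idx) else None
    above = table.select(above_idx) if len(above_idx) else None
    return below, above


@dataclass
class SaturationReport:
    """NDVI-GY correlation below vs above one yield threshold."""

    threshold: float
    n_below: int
    n_above: int
    r2_below: float | None
    r2_above: float | None
    p_below: float | None
    p_above: float | None
    sufficient: bool          # both strata had >= 3 NDVI-complete plots

    @property
    def r2_gap(self) -> float | None:
        if self.r2_below is None or self.r2_above is None:
            return None
        return self.r2_below - self.r2_above

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_below": self.n_below, "n_above": self.n_above,
            "r2_below": self.r2_below, "r2_above": self.r2_above,
            "p_below": self.p_below, "p_above": self.p_above,
            "r2_gap": self.r2_gap, "sufficient": self.sufficient,
        }


def _stratum_r2(stratum: TrialTable | None):
    """(n, r2, p) on NDVI-complete plots; r2/p None when under-populated."""
    if stratum is None:
        return 0, None, None
    df = stratum.to_dataframe()
    cases = df[df["ndvi"].notna()]
    n = len(cases)
    if n < MIN_STRATUM_N:
        return n, None, None
    try:
        r2, p = pearson_r2(cases["ndvi"].to_numpy(), cases["gy"].to_numpy())
    except ValueError:  # constant NDVI or GY within the stratum
        return n, None, None
    return n, r2, p


def saturation_report(table: TrialTable,
                      threshold: float = DEFAULT_THRESHOLD) -> SaturationReport:
    """NDVI-GY stratified correlation at one threshold."""
    below, above = stratify_by_yield(table, threshold)
    n_b, r2_b, p_b = _stratum_r2(below)
    n_a, r2_a, p_a = _stratum_r2(above)
    return SaturationReport(
        threshold=threshold, n_below=n_b, n_above=n_a,
        r2_below=r2_b, r2_above=r2_a, p_below=p_b, p_above=p_a,
        sufficient=(r2_b is not None and r2_a is not None),
    )


def saturation_scan(table: TrialTable, thresholds) -> list[SaturationReport]:
    """Stratified NDVI-GY correlation at each threshold.

    Under-populated strata (fewer than 3 NDVI-complete plots) flag the
    report ``sufficient=False`` rather than raising.
    """
    return [saturation_report(table, float(t)) for t in thresholds]
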