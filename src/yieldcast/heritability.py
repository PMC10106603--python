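"""Broad-sense heritability from replicated trials.

For a balanced one-way layout (each genotype with the same number r of
replicate plots), variance components come from the ANOVA method of
moments:

    sigma2_e = within-genotype mean square (MSE)
    sigma2_g = (between-genotype mean square - MSE) / r, truncated at 0

and broad-sense heritability on a genotype-mean basis is

    H^2 = sigma2_g / (sigma2_g + sigma2_e / r)

Unbalanced replication is rejected rather than silently approximated:
the formula presumes a single r, and heritability is only meaningful in
replicated trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trial import TrialTable


@dataclass(frozen=True)
class VarianceComponents:
    sigma2_g: float    # genotypic variance, (t/ha)^2 for GY
    sigma2_e: float    # plot-to-plot error variance
    r: int             # replicates per genotype
    n_genotypes: int


def variance_components(trial: TrialTable, trait: str = "gy") -> VarianceComponents:
    """Method-of-moments variance components for ``trait``.

    Requires >= 2 genotypes, all with the same replicate count r >= 2 and
    no missing trait values among the replicated plots. A negative
    genotypic-variance estimate is truncated to 0 with a warning.
    """
    df = trial.to_dataframe()
    if df["genotype_id"].isna().any():
        raise ValueError("all plots need a genotype_id for heritability")
    df = df[df[trait].notna()]
    counts = df.groupby("genotype_id")[trait].count()
    if len(counts) < 2:
        raise ValueError(f"need >= 2 genotypes, got {len(counts)}")
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced replication: replicate counts per genotype are "
            f"{sorted(counts.unique())}; heritability needs a single r"
        )
    r = int(counts.iloc[0])
    if r < 2:
        raise ValueError("heritability requires replicated trials (r >= 2)")

    groups = df.groupby("genotype_id")[trait]
    g = len(counts)
    grand = df[trait].mean()
    ss_between = float((r * (groups.mean() - grand) ** 2).sum())
    ss_within = float(((df[trait] - groups.transform("mean")) ** 2).sum())
    msg = ss_between / (g - 1)
    mse = ss_within / (g * (r - 1))
    sigma2_g = (msg - mse) / r
    if sigma2_g < 0:
        warnings.warn(
            f"negative genotypic-variance estimate {sigma2_g:.4g} truncated to 0",
            stacklevel=2,
        )
        sigma2_g = 0.0
    return VarianceComponents(sigma2_g=sigma2_g, sigma2_e=mse, r=r, n_genotypes=g)


def broad_sense_h2(vc: VarianceComponents) -> float:
    """H^2 = sigma2_g / (sigma2_g + sigma2_e / r), in [0, 1]."""
    if vc.sigma2_g == 0 and vc.sigma2_e == 0:
        raise ValueError("H^2 undefined: both variance components are zero")
    return vc.sigma2_g / (vc.sigma2_g + vc.sigma2_e / vc.r)


def h2_summary(trial: TrialTable, traits=("gy", "ndvi", "dh", "ph", "ears"),
               by_experiment: bool = True) -> pd.DataFrame:
    """Per-trait (optionally per-experiment) heritability table.

    Traits or experiments where estimation fails (missing values breaking
    balance, single genotype) are reported with NaN rather than aborting
    the whole summary.
    """
    df = trial.to_dataframe()
    groups = df.groupby("experiment_id") if by_experiment else [(None, df)]
    rows = []
    for exp, sub in groups:
        for trait in traits:
            row = {"experiment_id": exp, "trait": trait, "sigma2_g": np.nan,
                   "sigma2_e": np.nan, "r": np.nan, "h2": np.nan}
            try:
                vc = variance_components(TrialTable(sub), trait)
                row.update(sigma2_g=vc.sigma2_g, sigma2_e=vc.sigma2_e, r=vc.r,
                           h2=broad_sense_h2(vc))
            except ValueError:
                pass
            rows.append(row)
    return pd.DataFrame(rows)
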