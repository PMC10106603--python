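"""Vegetation indices from plot-level band reflectances.

The only index used downstream is NDVI, computed from plot-aggregated mean
reflectances in a generic red band (nominal 660/668 nm) and near-infrared
band (nominal 790/840 nm):

    NDVI = (R_nir - R_red) / (R_nir + R_red)

Pixel-to-plot aggregation, orthomosaicking and radiometric calibration are
upstream of this package; the analysis consumes one NDVI value per plot.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def compute_ndvi(r_red, r_nir):
    """Normalized difference vegetation index from band reflectances.

    Parameters
    ----------
    r_red, r_nir : float or array-like
        Dimensionless mean reflectances, >= 0, same shape.

    Returns
    -------
    float or ndarray
        ``(r_nir - r_red) / (r_nir + r_red)``, in [-1, 1].

    Raises
    ------
    ValueError
        On negative or non-finite reflectance, shape mismatch, or a plot
        where both bands are zero (NDVI undefined); the error names the
        offending element index.
    """
    red = np.asarray(r_red, dtype=float)
    nir = np.asarray(r_nir, dtype=float)
    scalar = red.ndim == 0 and nir.ndim == 0
    red, nir = np.atleast_1d(red), np.atleast_1d(nir)
    if red.shape != nir.shape:
        raise ValueError(f"band shape mismatch: red {red.shape} vs nir {nir.shape}")
    for name, band in (("red", red), ("nir", nir)):
        bad = ~np.isfinite(band) | (band < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(f"invalid {name} reflectance at element {i}: {band.flat[i]!r}")
    total = nir + red
    zero = total == 0
    if zero.any():
        i = int(np.flatnonzero(zero)[0])
        raise ValueError(f"NDVI undefined at element {i}: both bands zero")
    ndvi = (nir - red) / total
    return float(ndvi[0]) if scalar else ndvi


def ndvi_from_reflectance_table(df: pd.DataFrame, red_col: str = "r_red",
                                nir_col: str = "r_nir") -> pd.DataFrame:
    """Compute per-plot NDVI from a reflectance table keyed by ``plot_id``.

    Returns a new DataFrame with columns ``plot_id`` and ``ndvi``.
    """
    if "plot_id" not in df.columns:
        raise ValueError("reflectance table must have a plot_id column")
    for c in (red_col, nir_col):
        if c not in df.columns:
            raise ValueError(f"reflectance table missing column {c!r}")
    ndvi = compute_ndvi(df[red_col].to_numpy(), df[nir_col].to_numpy())
    return pd.DataFrame({"plot_id": df["plot_id"].to_numpy(), "ndvi": ndvi})
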