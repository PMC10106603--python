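"""Synthetic wheat trial generator.

Emits plot-level trait tables with the statistical structure the analysis
assumes, so every pipeline stage is testable without field data:

* genotype effects and replicate error within each experiment cell
  (one-way layout: gy = cell mean + N(0, sigma2_g) genotype effect +
  N(0, sigma2_e) plot error), giving a controllable broad-sense
  heritability H^2 = sigma2_g / (sigma2_g + sigma2_e / r);
* landrace vs modern germplasm classes that differ in yield mean and in
  harvest index (grain/biomass ratio; landraces ~0.33, modern ~0.48), so
  landraces carry high biomass and high NDVI despite low yield;
* a saturating NDVI response to above-ground biomass,
  ndvi = soil + (ndvi_max - soil) * (1 - exp(-k * biomass)), biomass
  = gy / harvest_index — a Beer-Lambert-like light-interception curve
  that flattens over dense canopies and reproduces the loss of NDVI-GY
  correlation above ~8 t/ha;
* Gaussian-copula co-variation of (GY, DH, PH, EARS) with a configurable
  correlation matrix.

Presets mirror the two case studies' trial structure: a large
unreplicated landrace/modern panel (two seasons) and a seven-experiment
replicated multi-environment set spanning 4.1-11.9 t/ha cell means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .heritability import broad_sense_h2, variance_components
from .saturation import saturation_report
from .trial import TrialTable

#: latent trait order for the correlation matrix
CORR_ORDER = ("gy", "dh", "ph", "ears")

#: default latent correlations: later-heading genotypes yield less in these
#: environments; taller plants and more ears track yield within a class
DEFAULT_TRAIT_CORR = (
    (1.00, -0.60, 0.70, 0.70),
    (-0.60, 1.00, -0.30, -0.30),
    (0.70, -0.30, 1.00, 0.50),
    (0.70, -0.30, 0.50, 1.00),
)

DEFAULT_TRAIT_MEANS = {
    "landrace": {"dh": (142.0, 5.0), "ph": (120.0, 12.0), "ears": (420.0, 70.0)},
    "modern": {"dh": (133.0, 5.0), "ph": (85.0, 10.0), "ears": (470.0, 75.0)},
}

#: landrace harvest index ~0.30 (tall Mediterranean landraces), modern ~0.48,
#: so landrace biomass (= gy / HI) and hence canopy NDVI rivals modern plots
#: despite ~4 t/ha lower grain yield
DEFAULT_HARVEST_INDEX = {"landrace": 0.30, "modern": 0.48}


@dataclass(frozen=True)
class ExperimentCell:
    """One experiment x germplasm-class cell of the trial design."""

    experiment_id: str
    gy_mean: float            # t/ha
    gy_sd: float              # t/ha, total plot-level SD
    n_genotypes: int
    n_reps: int = 1           # 1 = unreplicated
    germplasm_class: str = "modern"
    water_regime: str = "rainfed"
    sowing_date: str = "2020-11-15"
    h2: float | None = None   # target broad-sense heritability
    sigma2_g: float | None = None   # direct overrides of the variance split
    sigma2_e: float | None = None

    def variance_split(self) -> tuple[float, float]:
        """(sigma2_g, sigma2_e) with sigma2_g + sigma2_e = gy_sd^2.

        Direct components win; else the split that hits the target H^2 at
        this cell's r; else a default 60/40 genotype/error split.
        """
        total = self.gy_sd**2
        if self.sigma2_g is not None and self.sigma2_e is not None:
            return float(self.sigma2_g), float(self.sigma2_e)
        if self.h2 is not None:
            r = max(self.n_reps, 1)
            sg2 = (total / r) / (1.0 / self.h2 - 1.0 + 1.0 / r)
            return sg2, total - sg2
        return 0.6 * total, 0.4 * total


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic trial simulator."""

    experiments: tuple
    harvest_index: dict = field(default_factory=lambda: dict(DEFAULT_HARVEST_INDEX))
    ndvi_max: float = 0.92
    ndvi_soil: float = 0.15
    sat_rate: float = 0.09        # per t/ha biomass; NDVI ~0.75 at ~16.7 t/ha
    ndvi_noise_sd: float = 0.03
    saturation_enabled: bool = True
    nonsat_biomass_ref: float = 30.0  # biomass reaching ndvi_max in the affine map
    trait_corr: tuple = DEFAULT_TRAIT_CORR
    trait_means: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TRAIT_MEANS.items()
    })
    gy_floor: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if not self.experiments:
            raise ValueError("config needs at least one experiment cell")
        C = np.asarray(self.trait_corr, dtype=float)
        if C.shape != (4, 4) or not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("trait_corr must be a symmetric 4x4 matrix with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-10:
            raise ValueError("trait_corr is not positive semi-definite")
        if not (0.0 < self.ndvi_max <= 1.0):
            raise ValueError("ndvi_max must be in (0, 1]")
        for cls, hi in self.harvest_index.items():
            if not (0.0 < hi <= 1.0):
                raise ValueError(f"harvest index for {cls!r} must be in (0, 1]")
        for cell in self.experiments:
            sg2, se2 = cell.variance_split()
            if sg2 < 0 or se2 < 0:
                raise ValueError(f"cell {cell.experiment_id}: negative variance component")
        if self.ndvi_noise_sd < 0:
            raise ValueError("ndvi_noise_sd must be >= 0")


def saturating_ndvi(biomass, config: GeneratorConfig, rng: np.random.Generator | None = None):
    """NDVI response to above-ground biomass (t/ha).

    Noiseless saturating form: ``soil + (max - soil) * (1 - exp(-k * b))``
    (soil baseline at zero biomass, asymptote ``ndvi_max``). With
    ``saturation_enabled=False`` an affine ramp reaching ``ndvi_max`` at
    ``nonsat_biomass_ref`` t/ha is used instead. Passing ``rng`` adds
    Gaussian measurement noise; output is clipped to [0, 1].
    """
    b = np.asarray(biomass, dtype=float)
    if np.any(b < 0):
        raise ValueError("biomass must be >= 0")
    span = config.ndvi_max - config.ndvi_soil
    if config.saturation_enabled:
        ndvi = config.ndvi_soil + span * (1.0 - np.exp(-config.sat_rate * b))
    else:
        ndvi = config.ndvi_soil + span * b / config.nonsat_biomass_ref
    if rng is not None and config.ndvi_noise_sd > 0:
        ndvi = ndvi + rng.normal(0.0, config.ndvi_noise_sd, size=np.shape(b))
    out = np.clip(ndvi, 0.0, 1.0)
    return float(out) if np.ndim(biomass) == 0 else out


def _conditional_chol(C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Regression weights and Cholesky of (dh, ph, ears) | gy."""
    rho = C[0, 1:]
    cond = C[1:, 1:] - np.outer(rho, rho)
    # guard tiny negative eigenvalues from a PSD-boundary matrix
    w, V = np.linalg.eigh(cond)
    L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return rho, L


def generate_trial(config: GeneratorConfig) -> TrialTable:
    """Generate a plot-level trial table; deterministic given ``config.seed``."""
    C = np.asarray(config.trait_corr, dtype=float)
    rho, L = _conditional_chol(C)
    frames = []
    for cell in config.experiments:
        rng = np.random.default_rng(
            child_seed(config.seed, "cell", cell.experiment_id, cell.germplasm_class)
        )
        sg2, se2 = cell.variance_split()
        g, r = cell.n_genotypes, max(cell.n_reps, 1)
        geno_eff = rng.normal(0.0, np.sqrt(sg2), size=g)
        n = g * r
        geno_idx = np.repeat(np.arange(g), r)
        rep_idx = np.tile(np.arange(1, r + 1), g)
        gy_raw = cell.gy_mean + geno_eff[geno_idx] + rng.normal(0.0, np.sqrt(se2), size=n)
        gy = np.maximum(gy_raw, config.gy_floor)

        # correlated agronomic traits via the Gaussian copula conditional on gy
        z_gy = (gy_raw - cell.gy_mean) / cell.gy_sd
        eps = rng.standard_normal((n, 3))
        z_traits = np.outer(z_gy, rho) + eps @ L.T
        tm = config.trait_means[cell.germplasm_class]
        dh = np.maximum(tm["dh"][0] + tm["dh"][1] * z_traits[:, 0], 1.0)
        ph = np.maximum(tm["ph"][0] + tm["ph"][1] * z_traits[:, 1], 1.0)
        ears = np.maximum(tm["ears"][0] + tm["ears"][1] * z_traits[:, 2], 1.0)

        biomass = gy / config.harvest_index[cell.germplasm_class]
        ndvi = saturating_ndvi(biomass, config, rng=rng)

        cls3 = cell.germplasm_class[:3]
        frames.append(pd.DataFrame({
            "plot_id": [f"{cell.experiment_id}-{cls3}-G{gi:03d}-R{ri}"
                        for gi, ri in zip(geno_idx, rep_idx)],
            "genotype_id": [f"{cell.experiment_id}-{cls3}-G{gi:03d}" for gi in geno_idx],
            "germplasm_class": cell.germplasm_class,
            "experiment_id": cell.experiment_id,
            "water_regime": cell.water_regime,
            "sowing_date": cell.sowing_date,
            "replicate": rep_idx if r > 1 else np.full(n, np.nan),
            "gy": gy, "ndvi": ndvi, "dh": dh, "ph": ph, "ears": ears,
        }))
    return TrialTable(pd.concat(frames, ignore_index=True), provenance="synthetic")


# -- presets mirroring the two case studies' trial structure ---------------

def default_configs() -> dict[str, GeneratorConfig]:
    """Named presets for the case-study trial structures.

    ``case1_2017`` / ``case1_2018``: one unreplicated rainfed season of a
    diverse panel, 170 landrace + 184 modern plots with contrasting
    yield means (e.g. 5.10 vs 9.48 t/ha) but similar canopy NDVI.
    ``case2_2021``: seven replicated alpha-lattice experiments of modern
    varieties under rainfed/irrigated regimes and two sowing dates, cell
    means 4.1-11.9 t/ha and heritabilities 0.664-0.903, populating both
    sides of the 8 t/ha saturation threshold.
    """
    case1_2017 = GeneratorConfig(experiments=(
        ExperimentCell("1", 5.10, 0.91, 170, 1, "landrace", "rainfed", "2016-11-21"),
        ExperimentCell("1", 9.48, 1.01, 184, 1, "modern", "rainfed", "2016-11-21"),
    ), seed=0)
    case1_2018 = GeneratorConfig(experiments=(
        ExperimentCell("1", 5.63, 0.82, 170, 1, "landrace", "rainfed", "2017-11-15"),
        ExperimentCell("1", 9.94, 0.98, 184, 1, "modern", "rainfed", "2017-11-15"),
    ), seed=0)
    case2_2021 = GeneratorConfig(experiments=(
        ExperimentCell("1", 5.33, 1.61, 10, 3, "modern", "rainfed", "2020-12-27", h2=0.688),
        ExperimentCell("2", 8.87, 1.77, 10, 3, "modern", "irrigated", "2020-12-27", h2=0.885),
        ExperimentCell("3", 7.86, 2.17, 10, 3, "modern", "rainfed", "2020-12-03", h2=0.776),
        ExperimentCell("4", 10.32, 1.90, 10, 3, "modern", "irrigated", "2020-12-03", h2=0.903),
        ExperimentCell("5", 11.87, 1.54, 22, 3, "modern", "irrigated", "2020-12-03", h2=0.678),
        ExperimentCell("6", 10.55, 1.02, 22, 3, "modern", "irrigated", "2020-12-03", h2=0.664),
        ExperimentCell("7", 4.14, 1.09, 16, 6, "modern", "rainfed", "2020-12-03", h2=0.697),
    ), seed=0)
    return {"case1_2017": case1_2017, "case1_2018": case1_2018, "case2_2021": case2_2021}


def config_with_seed(config: GeneratorConfig, seed: int) -> GeneratorConfig:
    return replace(config, seed=seed)


def generate_linear_response_trial(n_plots: int, coefs: dict[str, float],
                                   noise_sd: float = 0.5, gy_mean: float = 7.0,
                                   seed: int = 0) -> TrialTable:
    """Trial table with a KNOWN linear response for selection tests.

    Predictor traits are drawn independently at realistic scales
    (NDVI ~ N(0.65, 0.08) clipped, DH ~ N(135, 6), PH ~ N(85, 10),
    EARS ~ N(450, 80)); yield is ``gy_mean + sum coefs[t] * z_t + noise``
    on standardized traits, so the traits named in ``coefs`` are the true
    predictors and the rest are pure noise.
    """
    rng = np.random.default_rng(child_seed(seed, "linear-response"))
    traits = {
        "ndvi": np.clip(rng.normal(0.65, 0.08, n_plots), 0.02, 0.98),
        "dh": rng.normal(135.0, 6.0, n_plots),
        "ph": rng.normal(85.0, 10.0, n_plots),
        "ears": rng.normal(450.0, 80.0, n_plots),
    }
    gy = np.full(n_plots, float(gy_mean))
    for t, c in coefs.items():
        z = (traits[t] - traits[t].mean()) / traits[t].std()
        gy = gy + c * z
    gy = np.maximum(gy + rng.normal(0.0, noise_sd, n_plots), 0.1)
    return TrialTable(pd.DataFrame({
        "plot_id": [f"SIM-{i:04d}" for i in range(n_plots)],
        "genotype_id": [f"SIMG-{i:04d}" for i in range(n_plots)],
        "germplasm_class": "modern", "experiment_id": "SIM",
        "water_regime": "rainfed", "sowing_date": "2020-11-15",
        "gy": gy, **traits,
    }), provenance="synthetic linear-response")


# -- self-verification -----------------------------------------------------

@dataclass
class GeneratorReport:
    """Empirical summaries of an emitted table against its config targets."""

    cell_moments: pd.DataFrame       # per cell: n, target/empirical mean & sd, pass
    trait_corr_empirical: np.ndarray
    trait_corr_target: np.ndarray
    corr_checked: bool               # only flagged pass/fail at n >= 1000
    corr_pass: bool | None
    h2_by_cell: pd.DataFrame         # replicated cells only
    saturation: dict                 # stratified NDVI-GY r2 at 8 t/ha
    all_moment_checks_pass: bool

    def to_dict(self) -> dict:
        return {
            "cell_moments": self.cell_moments.to_dict(orient="records"),
            "trait_corr_empirical": self.trait_corr_empirical.tolist(),
            "trait_corr_target": self.trait_corr_target.tolist(),
            "corr_checked": self.corr_checked,
            "corr_pass": self.corr_pass,
            "h2_by_cell": self.h2_by_cell.to_dict(orient="records"),
            "saturation": self.saturation,
            "all_moment_checks_pass": self.all_moment_checks_pass,
        }


def verify_generator(table: TrialTable, config: GeneratorConfig,
                     threshold: float = 8.0) -> GeneratorReport:
    """Check an emitted table against its configuration targets.

    GY cell means must sit within 3 standard errors of target; latent
    trait correlations (computed on within-cell standardized values) are
    compared at +/-0.1 tolerance when the table has >= 1000 plots;
    heritability is re-estimated per replicated cell.
    """
    df = table.to_dataframe()
    rows = []
    zcols = {t: [] for t in CORR_ORDER}
    for cell in config.experiments:
        sub = df[(df["experiment_id"] == cell.experiment_id)
                 & (df["germplasm_class"] == cell.germplasm_class)]
        n = len(sub)
        emp_mean, emp_sd = sub["gy"].mean(), sub["gy"].std(ddof=1)
        se = cell.gy_sd / np.sqrt(n)
        rows.append({
            "experiment_id": cell.experiment_id, "class": cell.germplasm_class,
            "n": n, "target_mean": cell.gy_mean, "empirical_mean": emp_mean,
            "target_sd": cell.gy_sd, "empirical_sd": emp_sd,
            "mean_pass": bool(abs(emp_mean - cell.gy_mean) <= 3 * se),
        })
        for t in CORR_ORDER:
            v = sub[t]
            zcols[t].append((v - v.mean()) / v.std(ddof=1))
    moments = pd.DataFrame(rows)
    Z = np.column_stack([pd.concat(zcols[t]).to_numpy() for t in CORR_ORDER])
    emp_corr = np.corrcoef(Z.T)
    target = np.asarray(config.trait_corr, dtype=float)
    checked = len(df) >= 1000
    corr_pass = bool(np.all(np.abs(emp_corr - target) <= 0.1)) if checked else None

    h2_rows = []
    for cell in config.experiments:
        if cell.n_reps < 2:
            continue
        sub = df[(df["experiment_id"] == cell.experiment_id)
                 & (df["germplasm_class"] == cell.germplasm_class)]
        vc = variance_components(TrialTable(sub), "gy")
        h2_rows.append({
            "experiment_id": cell.experiment_id, "target_h2": cell.h2,
            "estimated_h2": broad_sense_h2(vc),
            "sigma2_g": vc.sigma2_g, "sigma2_e": vc.sigma2_e, "r": vc.r,
        })
    h2_df = pd.DataFrame(h2_rows, columns=["experiment_id", "target_h2", "estimated_h2",
                                           "sigma2_g", "sigma2_e", "r"])
    sat = saturation_report(table, threshold).to_dict()
    return GeneratorReport(
        cell_moments=moments, trait_corr_empirical=emp_corr, trait_corr_target=target,
        corr_checked=checked, corr_pass=corr_pass, h2_by_cell=h2_df, saturation=sat,
        all_moment_checks_pass=bool(moments["mean_pass"].all()),
    )
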