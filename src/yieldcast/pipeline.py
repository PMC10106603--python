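"""End-to-end case-study workflow: data -> split -> calibrate -> select -> validate.

A run loads or generates a trial table, splits it into training pool and
validation set, optionally stratifies both at the NDVI-saturation yield
threshold and fits independent calibration ensembles per stratum and
training size, then validates each representative model against the
NDVI-only benchmark on the matching held-out plots. Every stochastic
stage derives its seed from the single master seed, so a run is fully
reproducible; outputs are plain JSON/CSV/YAML with sorted keys and no
timestamps, hence byte-identical across repeats.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._seeds import child_seed
from .heritability import h2_summary
from .metrics import ComparisonReport, compare_to_benchmark
from .ridge import LambdaSearch
from .saturation import DEFAULT_THRESHOLD, saturation_report, stratify_by_yield
from .search import CANONICAL_TRAITS, CalibrationEnsemble, enumerate_models, run_calibration
from .simulate import config_with_seed, default_configs, generate_trial
from .trial import SplitScheme, TrialTable, read_trial_table, split_train_validation

log = logging.getLogger("yieldcast")


@dataclass
class RunConfig:
    """Configuration of one case-study run."""

    source: str = "case2_2021"            # generator preset name or a CSV path
    split: SplitScheme | None = None      # default: by_experiment train {2,3,4,6,7}
    candidate_traits: tuple = CANONICAL_TRAITS
    training_sizes: tuple = (20, 50, 100)
    n_iter: int = 100
    k_folds: int = 10
    n_grid: int = 100
    saturation_threshold: float = DEFAULT_THRESHOLD
    stratified_mode: bool = True
    master_seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        split = raw.pop("split", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if split is not None:
            for key in ("train_experiments", "validation_experiments"):
                if key in split:
                    split[key] = frozenset(str(e) for e in split[key])
            cfg.split = SplitScheme(**split)
        return cfg

    def to_dict(self) -> dict:
        d = {
            "source": self.source,
            "candidate_traits": list(self.candidate_traits),
            "training_sizes": list(self.training_sizes),
            "n_iter": self.n_iter, "k_folds": self.k_folds, "n_grid": self.n_grid,
            "saturation_threshold": self.saturation_threshold,
            "stratified_mode": self.stratified_mode,
            "master_seed": self.master_seed,
        }
        if self.split is not None:
            d["split"] = {
                "kind": self.split.kind, "train_size": self.split.train_size,
                "strata_sizes": dict(self.split.strata_sizes),
                "train_experiments": sorted(self.split.train_experiments),
                "validation_experiments": sorted(self.split.validation_experiments),
                "seed": self.split.seed,
            }
        return d


#: default Case-2-style split: two experiments held out whole as independent
#: low- and high-yield validation sets
DEFAULT_CASE2_SPLIT = SplitScheme(
    kind="by_experiment",
    train_experiments=frozenset({"2", "3", "4", "6", "7"}),
    validation_experiments=frozenset({"1", "5"}),
)


@dataclass
class StratumResult:
    """Calibration + validation results for one stratum at one training size."""

    stratum: str                      # "all", "below", "above"
    training_size: int
    ensemble: CalibrationEnsemble
    comparison: ComparisonReport | None   # None when validation was infeasible
    note: str = ""


@dataclass
class ResultBundle:
    config: RunConfig
    n_plots: int
    results: list[StratumResult] = field(default_factory=list)
    saturation: dict = field(default_factory=dict)
    heritability: list = field(default_factory=list)
    skipped: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "n_plots": self.n_plots,
            "results": [
                {
                    "stratum": r.stratum,
                    "training_size": r.training_size,
                    "best_combo": list(r.ensemble.best_combo),
                    "ensemble": r.ensemble.to_dict(),
                    "comparison": None if r.comparison is None else r.comparison.to_dict(),
                    "note": r.note,
                }
                for r in self.results
            ],
            "saturation": self.saturation,
            "heritability": self.heritability,
            "skipped": self.skipped,
        }


def load_table(source: str, seed: int) -> TrialTable:
    """A generator preset name (seeded from the master seed) or a CSV path."""
    presets = default_configs()
    if source in presets:
        return generate_trial(config_with_seed(presets[source], child_seed(seed, "generate")))
    return read_trial_table(source)


def _count_complete(table: TrialTable, traits) -> int:
    df = table.to_dataframe()
    return int(df[list(traits) + ["gy"]].notna().all(axis=1).sum())


def run_case_study(config: RunConfig) -> ResultBundle:
    """Execute the full workflow described by ``config``.

    With ``stratified_mode`` the training pool and validation set are both
    split at the saturation threshold and independent ensembles are
    fitted below/above; each representative model is compared against the
    NDVI-only benchmark drawn from the same ensemble. A (stratum, size)
    whose complete-case pool is smaller than the training size is skipped
    with a logged note, not an error.
    """
    table = load_table(config.source, config.master_seed)
    split = config.split if config.split is not None else DEFAULT_CASE2_SPLIT
    train_pool, validation = split_train_validation(table, split)
    if train_pool is None or validation is None:
        raise ValueError("split produced an empty training pool or validation set")
    log.info("split: %d training-pool plots, %d validation plots",
             len(train_pool), len(validation))

    if config.stratified_mode:
        tb, ta = stratify_by_yield(train_pool, config.saturation_threshold)
        vb, va = stratify_by_yield(validation, config.saturation_threshold)
        strata = [("below", tb, vb), ("above", ta, va)]
    else:
        strata = [("all", train_pool, validation)]

    combos = enumerate_models(config.candidate_traits)
    search = LambdaSearch(k_folds=config.k_folds, n_grid=config.n_grid)
    bundle = ResultBundle(config=config, n_plots=len(table))

    for name, pool, val in strata:
        if pool is None:
            bundle.skipped.append(f"stratum {name}: empty training pool")
            continue
        avail = _count_complete(pool, config.candidate_traits)
        for size in config.training_sizes:
            if size > avail:
                msg = (f"stratum {name} size {size}: only {avail} complete-case "
                       "training plots; skipped")
                log.warning(msg)
                bundle.skipped.append(msg)
                continue
            ens = run_calibration(
                pool, combos, size=size, n_iter=config.n_iter,
                master_seed=child_seed(config.master_seed, "ensemble", name, size),
                search=search,
            )
            note = ""
            comparison = None
            if val is not None and _count_complete(val, config.candidate_traits) >= 3:
                best = ens.representative_model
                bench = ens.representative_for(("ndvi",))
                comparison = compare_to_benchmark(best, bench, val)
            else:
                note = "validation stratum too small; metrics omitted"
            bundle.results.append(StratumResult(
                stratum=name, training_size=size, ensemble=ens,
                comparison=comparison, note=note,
            ))

    bundle.saturation = saturation_report(table, config.saturation_threshold).to_dict()
    h2 = h2_summary(table, traits=("gy",))
    bundle.heritability = [
        {k: (None if v != v else v) for k, v in row.items()}
        for row in h2.to_dict(orient="records")
    ]
    if config.out_dir:
        write_bundle(bundle, config.out_dir)
    return bundle


def write_bundle(bundle: ResultBundle, out_dir) -> None:
    """Write results.json, a per-run flat CSV per ensemble, and a config echo."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "results.json").write_text(
        json.dumps(bundle.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    (out / "config.yaml").write_text(yaml.safe_dump(bundle.config.to_dict(), sort_keys=True))
    for r in bundle.results:
        r.ensemble.to_flat_frame().to_csv(
            out / f"ensemble_{r.stratum}_{r.training_size}.csv", index=False
        )
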