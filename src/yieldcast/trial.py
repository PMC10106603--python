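"""Plot-level trial tables: data model, CSV I/O and train/validation splits.

A trial table holds one row per experimental plot with design factors
(genotype, germplasm class, experiment, water regime, sowing date,
replicate) and measured traits: grain yield GY (t/ha at 12% moisture),
NDVI at anthesis, days to heading DH, plant height PH (cm) and ear
density EARS (ears/m^2). Optional trait values may be absent (empty CSV
cell <-> NaN); a plot missing a trait a model needs is dropped from that
model's fit or validation only (listwise per-model deletion).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, datetime

import numpy as np
import pandas as pd

GERMPLASM_CLASSES = ("landrace", "modern")
WATER_REGIMES = ("rainfed", "irrigated")

#: canonical trait columns usable as model predictors or response
TRAIT_COLUMNS = ("gy", "ndvi", "dh", "ph", "ears")

#: all canonical columns, in on-disk order
CANONICAL_COLUMNS = (
    "plot_id", "genotype_id", "germplasm_class", "experiment_id",
    "water_regime", "sowing_date", "replicate",
    "gy", "ndvi", "dh", "ph", "ears",
)

_STRING_COLS = ("plot_id", "genotype_id", "germplasm_class", "experiment_id", "water_regime")


@dataclass(frozen=True)
class PlotRecord:
    """One experimental plot. Absent values are ``None``."""

    plot_id: str
    gy: float
    genotype_id: str | None = None
    germplasm_class: str | None = None
    experiment_id: str | None = None
    water_regime: str | None = None
    sowing_date: date | None = None
    replicate: int | None = None
    ndvi: float | None = None
    dh: float | None = None
    ph: float | None = None
    ears: float | None = None


def _parse_date(value) -> date | None:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    if isinstance(value, datetime):
        return value.date()
    if isinstance(value, date):
        return value
    s = str(value).strip()
    for fmt in ("%Y-%m-%d", "%d/%m/%Y"):
        try:
            return datetime.strptime(s, fmt).date()
        except ValueError:
            continue
    raise ValueError(f"unparseable date {s!r} (expected ISO-8601 or dd/mm/yyyy)")


def _numeric_column(series: pd.Series, col: str) -> pd.Series:
    out = []
    for i, v in enumerate(series):
        if v is None or v is pd.NA or (isinstance(v, float) and np.isnan(v)):
            out.append(np.nan)
            continue
        try:
            out.append(float(v))
        except (TypeError, ValueError):
            raise ValueError(f"row {i}, column {col!r}: unparseable numeric cell {v!r}") from None
    return pd.Series(out, index=series.index, dtype=float)


def _check_row(i: int, row: pd.Series) -> None:
    """Raise with a row-indexed message on any trait invariant violation."""
    gy = row["gy"]
    if pd.isna(gy):
        raise ValueError(f"row {i}: gy is mandatory")
    if gy < 0:
        raise ValueError(f"row {i}: gy must be >= 0, got {gy}")
    ndvi = row["ndvi"]
    if not pd.isna(ndvi) and not (0.0 <= ndvi <= 1.0):
        raise ValueError(f"row {i}: ndvi must be in [0, 1], got {ndvi}")
    for col in ("dh", "ph", "ears"):
        v = row[col]
        if not pd.isna(v) and v <= 0:
            raise ValueError(f"row {i}: {col} must be > 0, got {v}")
    rep = row["replicate"]
    if not pd.isna(rep) and rep < 1:
        raise ValueError(f"row {i}: replicate must be a positive integer, got {rep}")
    gc = row["germplasm_class"]
    if gc is not None and not pd.isna(gc) and gc not in GERMPLASM_CLASSES:
        raise ValueError(f"row {i}: unknown germplasm_class {gc!r}")
    wr = row["water_regime"]
    if wr is not None and not pd.isna(wr) and wr not in WATER_REGIMES:
        raise ValueError(f"row {i}: unknown water_regime {wr!r}")


class TrialTable:
    """Validated, immutable-by-convention collection of plot records.

    Backed by a pandas DataFrame in canonical column order; accessors
    return copies so no operation mutates a table in place.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = ""):
        df = df.copy()
        for col in CANONICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[list(CANONICAL_COLUMNS)].reset_index(drop=True)
        if len(df) == 0:
            raise ValueError("trial table must be non-empty")
        for col in _STRING_COLS:
            df[col] = df[col].map(
                lambda v: None if (v is None or (isinstance(v, float) and np.isnan(v))) else str(v)
            )
        df["sowing_date"] = df["sowing_date"].map(_parse_date)
        # exact float() per cell: value-preserving round trips, row-indexed errors
        for col in TRAIT_COLUMNS:
            df[col] = _numeric_column(df[col], col)
        rep = _numeric_column(df["replicate"], "replicate")
        if any(not np.isnan(v) and v != int(v) for v in rep):
            i = next(i for i, v in enumerate(rep) if not np.isnan(v) and v != int(v))
            raise ValueError(f"row {i}: replicate must be an integer, got {rep[i]}")
        df["replicate"] = pd.array([None if np.isnan(v) else int(v) for v in rep],
                                   dtype="Int64")
        for i, row in df.iterrows():
            _check_row(int(i), row)
        ids = df["plot_id"]
        if ids.isna().any():
            raise ValueError(f"row {int(ids.isna().idxmax())}: plot_id is mandatory")
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate plot_id {dup!r}")
        self._df = df
        self.provenance = provenance

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self):
        for _, row in self._df.iterrows():
            kw = {}
            for f in dataclasses.fields(PlotRecord):
                v = row[f.name]
                kw[f.name] = None if (v is pd.NA or (isinstance(v, float) and np.isnan(v))) else v
            if kw["replicate"] is not None:
                kw["replicate"] = int(kw["replicate"])
            yield PlotRecord(**kw)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self._df.equals(other._df)

    def to_dataframe(self) -> pd.DataFrame:
        """A defensive copy of the underlying canonical DataFrame."""
        return self._df.copy()

    @property
    def plot_ids(self) -> list[str]:
        return list(self._df["plot_id"])

    def completeness(self, trait: str) -> int:
        """Number of rows with a present (non-absent) value for ``trait``."""
        if trait not in CANONICAL_COLUMNS:
            raise KeyError(f"unknown column {trait!r}")
        return int(self._df[trait].notna().sum())

    def complete_cases(self, traits) -> "TrialTable":
        """Sub-table of plots with present values for every listed trait."""
        mask = self._df[list(traits)].notna().all(axis=1)
        if not mask.any():
            raise ValueError(f"no complete cases for traits {list(traits)}")
        return self.select(self._df.index[mask])

    def select(self, index) -> "TrialTable":
        sub = self._df.loc[index]
        return TrialTable(sub, provenance=self.provenance)

    def subset_by_ids(self, plot_ids) -> "TrialTable":
        wanted = set(plot_ids)
        unknown = wanted - set(self._df["plot_id"])
        if unknown:
            raise KeyError(f"unknown plot ids: {sorted(unknown)[:5]}")
        mask = self._df["plot_id"].isin(wanted)
        return self.select(self._df.index[mask])


@dataclass(frozen=True)
class SplitScheme:
    """How to split a table into training pool and validation set.

    kinds:
      ``random_n``          -- draw ``train_size`` plots for training, rest validate
      ``stratified_random`` -- draw ``strata_sizes`` plots per germplasm class
                               for the VALIDATION set; remainder is the training
                               pool (the Case-1 convention: e.g. 20 landraces +
                               20 modern held out, models trained on draws from
                               the remaining plots)
      ``by_experiment``     -- whole experiments to each side
    """

    kind: str
    train_size: int | None = None
    strata_sizes: dict = field(default_factory=dict)
    train_experiments: frozenset = frozenset()
    validation_experiments: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("random_n", "stratified_random", "by_experiment"):
            raise ValueError(f"unknown split kind {self.kind!r}")
        if self.kind == "random_n" and (self.train_size is None or self.train_size < 1):
            raise ValueError("random_n requires a positive train_size")
        if self.kind == "stratified_random" and not self.strata_sizes:
            raise ValueError("stratified_random requires strata_sizes")
        if self.kind == "by_experiment":
            overlap = set(self.train_experiments) & set(self.validation_experiments)
            if overlap:
                raise ValueError(f"experiment sets overlap: {sorted(overlap)}")


def split_train_validation(table: TrialTable, scheme: SplitScheme):
    """Partition ``table`` into (train, validation) per ``scheme``.

    Deterministic given ``scheme.seed``. The two sides are disjoint and
    their union is the input (``random_n`` with ``train_size == len(table)``
    yields an empty validation side, returned as ``None``).
    """
    df = table.to_dataframe()
    rng = np.random.default_rng(scheme.seed)

    if scheme.kind == "random_n":
        n = scheme.train_size
        if n > len(df):
            raise ValueError(f"train_size {n} exceeds table size {len(df)}")
        train_idx = np.sort(rng.choice(df.index.to_numpy(), size=n, replace=False))
        val_idx = df.index.difference(train_idx)
    elif scheme.kind == "stratified_random":
        val_parts = []
        for cls, count in sorted(scheme.strata_sizes.items()):
            stratum = df.index[df["germplasm_class"] == cls].to_numpy()
            if count > len(stratum):
                raise ValueError(
                    f"stratum {cls!r}: requested {count} of {len(stratum)} available plots"
                )
            val_parts.append(rng.choice(stratum, size=count, replace=False))
        val_idx = np.sort(np.concatenate(val_parts))
        train_idx = df.index.difference(val_idx)
    else:  # by_experiment
        known = set(df["experiment_id"].dropna())
        for exp in set(scheme.train_experiments) | set(scheme.validation_experiments):
            if exp not in known:
                raise KeyError(f"unknown experiment id {exp!r}")
        val_idx = df.index[df["experiment_id"].isin(scheme.validation_experiments)]
        if scheme.train_experiments:
            train_idx = df.index[df["experiment_id"].isin(scheme.train_experiments)]
        else:
            train_idx = df.index.difference(val_idx)

    train = table.select(train_idx) if len(train_idx) else None
    validation = table.select(val_idx) if len(val_idx) else None
    return train, validation


# -- CSV I/O ---------------------------------------------------------------

def read_trial_table(path, dialect: dict | None = None,
                     provenance: str | None = None) -> TrialTable:
    """Read a trial table from CSV.

    ``dialect`` maps canonical column names to the file's header names for
    non-canonical inputs, e.g. ``{"gy": "Yield_t_ha"}``. ``plot_id`` and
    ``gy`` must be resolvable; other columns are optional and absent values
    are empty cells. Invalid rows raise with the row index and column named.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    rename = {}
    for canonical, header in (dialect or {}).items():
        if canonical not in CANONICAL_COLUMNS:
            raise KeyError(f"dialect maps unknown canonical column {canonical!r}")
        rename[header] = canonical
    raw = raw.rename(columns=rename)
    for col in ("plot_id", "gy"):
        if col not in raw.columns:
            raise ValueError(f"mandatory column {col!r} not found in {path}")
    raw = raw[[c for c in CANONICAL_COLUMNS if c in raw.columns]]
    raw = raw.replace({"": None})
    return TrialTable(raw, provenance=provenance if provenance is not None else str(path))


def write_trial_table(table: TrialTable, path) -> None:
    """Write a trial table as canonical CSV (absent values as empty cells).

    Round-trip safe: ``read_trial_table(write_trial_table(t)) == t``.
    """
    df = table.to_dataframe()
    df["sowing_date"] = df["sowing_date"].map(lambda d: "" if d is None else d.isoformat())
    for col in TRAIT_COLUMNS:
        df[col] = df[col].map(lambda v: "" if np.isnan(v) else repr(v))
    df["replicate"] = [("" if pd.isna(v) else str(int(v))) for v in df["replicate"]]
    df = df.fillna("")
    df.to_csv(path, index=False)


def write_split(train: TrialTable | None, validation: TrialTable | None, path) -> None:
    """Export a split as one CSV with an added ``set`` column."""
    parts = []
    for tbl, tag in ((train, "train_pool"), (validation, "validation")):
        if tbl is not None:
            d = tbl.to_dataframe()
            d["set"] = tag
            parts.append(d)
    pd.concat(parts, ignore_index=True).to_csv(path, index=False)
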