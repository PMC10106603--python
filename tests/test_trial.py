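import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yieldcast.simulate import generate_linear_response_trial
from yieldcast.trial import (SplitScheme, TrialTable, read_trial_table,
                             split_train_validation, write_split,
                             write_trial_table)

CSV_3ROW = """plot_id,gy,ndvi,dh
p1,5.2,0.71,133
p2,8.9,0.84,129
p3,3.1,0.55,140
"""


def test_read_valid_csv(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text(CSV_3ROW)
    t = read_trial_table(f)
    assert len(t) == 3
    assert t.completeness("ndvi") == 3
    assert t.completeness("ears") == 0


def test_read_rejects_out_of_range_ndvi(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("plot_id,gy,ndvi\np1,5.0,0.7\np2,6.0,1.3\n")
    with pytest.raises(ValueError, match=r"row 1.*ndvi"):
        read_trial_table(f)


def test_read_missing_mandatory_column(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("plot_id,ndvi\np1,0.7\n")
    with pytest.raises(ValueError, match="gy"):
        read_trial_table(f)


def test_read_empty_cell_is_absent(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("plot_id,gy,ears\np1,5.0,410\np2,6.0,\np3,7.0,380\n")
    t = read_trial_table(f)
    assert t.completeness("ears") == len(t) - 1
    recs = list(t)
    assert recs[1].ears is None


def test_dialect_maps_foreign_headers(tmp_path):
    f = tmp_path / "t.csv"
    f.write_text("Plot,Yield\nA,5.5\n")
    t = read_trial_table(f, dialect={"plot_id": "Plot", "gy": "Yield"})
    assert list(t)[0].gy == 5.5


def test_duplicate_plot_id_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        TrialTable(pd.DataFrame({"plot_id": ["a", "a"], "gy": [1.0, 2.0]}))


def test_date_formats_parse():
    t = TrialTable(pd.DataFrame({"plot_id": ["a", "b"], "gy": [1, 2],
                                 "sowing_date": ["21/11/2016", "2017-11-15"]}))
    recs = list(t)
    assert recs[0].sowing_date.isoformat() == "2016-11-21"
    assert recs[1].sowing_date.isoformat() == "2017-11-15"


def test_roundtrip_small_table(tmp_path, small_table):
    f = tmp_path / "rt.csv"
    write_trial_table(small_table, f)
    back = read_trial_table(f)
    assert back == small_table
    # absent stays absent, not a sentinel
    raw = f.read_text()
    assert "nan" not in raw.lower()


def test_roundtrip_large_synthetic_table(tmp_path):
    t = generate_linear_response_trial(3000, {"ndvi": 1.0}, seed=3)
    f = tmp_path / "big.csv"
    write_trial_table(t, f)
    assert read_trial_table(f) == t


@st.composite
def trial_frames(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    floats = st.floats(min_value=0.01, max_value=1e3, allow_nan=False)
    maybe = st.one_of(st.none(), floats)
    return pd.DataFrame({
        "plot_id": [f"p{i}" for i in range(n)],
        "gy": [draw(floats) for _ in range(n)],
        "ndvi": [min(v, 1.0) if (v := draw(maybe)) is not None else None for _ in range(n)],
        "dh": [draw(maybe) for _ in range(n)],
        "ph": [draw(maybe) for _ in range(n)],
        "ears": [draw(maybe) for _ in range(n)],
    })


@settings(derandomize=True, max_examples=30)
@given(df=trial_frames())
def test_roundtrip_property(tmp_path_factory, df):
    t = TrialTable(df)
    f = tmp_path_factory.mktemp("rt") / "t.csv"
    write_trial_table(t, f)
    assert read_trial_table(f) == t


# -- splits ----------------------------------------------------------------

def test_stratified_split_case1_convention(case1_table):
    scheme = SplitScheme(kind="stratified_random",
                         strata_sizes={"landrace": 20, "modern": 20}, seed=11)
    train, val = split_train_validation(case1_table, scheme)
    assert len(val) == 40
    assert len(train) == len(case1_table) - 40
    classes = val.to_dataframe()["germplasm_class"].value_counts()
    assert classes["landrace"] == 20 and classes["modern"] == 20


def test_random_n_full_train_empty_validation(small_table):
    train, val = split_train_validation(
        small_table, SplitScheme(kind="random_n", train_size=len(small_table), seed=0))
    assert len(train) == len(small_table)
    assert val is None


def test_by_experiment_split(case2_table):
    scheme = SplitScheme(kind="by_experiment",
                         train_experiments=frozenset({"2", "3", "4"}),
                         validation_experiments=frozenset({"1"}))
    train, val = split_train_validation(case2_table, scheme)
    assert set(val.to_dataframe()["experiment_id"]) == {"1"}
    assert set(train.to_dataframe()["experiment_id"]) == {"2", "3", "4"}


def test_split_is_partition_and_deterministic(case2_table):
    scheme = SplitScheme(kind="random_n", train_size=200, seed=5)
    t1, v1 = split_train_validation(case2_table, scheme)
    t2, v2 = split_train_validation(case2_table, scheme)
    assert t1.plot_ids == t2.plot_ids and v1.plot_ids == v2.plot_ids
    assert set(t1.plot_ids).isdisjoint(v1.plot_ids)
    assert set(t1.plot_ids) | set(v1.plot_ids) == set(case2_table.plot_ids)


def test_split_does_not_mutate_input(small_table):
    before = small_table.to_dataframe()
    split_train_validation(small_table, SplitScheme(kind="random_n", train_size=4, seed=1))
    pd.testing.assert_frame_equal(before, small_table.to_dataframe())


def test_oversized_stratum_errors(small_table):
    scheme = SplitScheme(kind="stratified_random", strata_sizes={"landrace": 6}, seed=0)
    with pytest.raises(ValueError, match="landrace"):
        split_train_validation(small_table, scheme)


def test_unknown_experiment_errors(small_table):
    scheme = SplitScheme(kind="by_experiment", validation_experiments=frozenset({"E9"}))
    with pytest.raises(KeyError, match="E9"):
        split_train_validation(small_table, scheme)


def test_overlapping_experiment_sets_rejected():
    with pytest.raises(ValueError, match="overlap"):
        SplitScheme(kind="by_experiment", train_experiments=frozenset({"1"}),
                    validation_experiments=frozenset({"1"}))


def test_write_split_adds_set_column(tmp_path, small_table):
    train, val = split_train_validation(
        small_table, SplitScheme(kind="random_n", train_size=6, seed=2))
    f = tmp_path / "split.csv"
    write_split(train, val, f)
    out = pd.read_csv(f)
    assert sorted(out["set"].unique()) == ["train_pool", "validation"]
    assert len(out) == len(small_table)
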