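"""The chained random-forest imputation engine."""

import numpy as np
import pandas as pd
import pytest

from cogimpute.missforest import (
    ImputationConfig,
    ImputationError,
    MissForest,
    UnimputableColumnError,
    impute,
    impute_with_simulated_missing,
    initialize,
    stop_index,
)
from cogimpute.schema import Schema, VariableSchema

from conftest import make_visits


def _xy_schema(y_type="continuous", y_range=None, integer=False):
    return Schema([
        VariableSchema("participant_id", "categorical", "identifier",
                       levels=("*",)),
        VariableSchema("dataset_id", "categorical", "identifier",
                       levels=("*",)),
        VariableSchema("x", "continuous", "demographic"),
        VariableSchema("y", y_type, "demographic",
                       valid_range=y_range, integer_valued=integer),
    ])


def _xy_table(x, y):
    return pd.DataFrame({
        "participant_id": [f"p{i}" for i in range(len(x))],
        "dataset_id": "A",
        "x": np.asarray(x, float),
        "y": np.asarray(y, float),
    })


# -- initialization ----------------------------------------------------------

def test_initialize_median_and_mode():
    schema = Schema([
        VariableSchema("participant_id", "categorical", "identifier",
                       levels=("*",)),
        VariableSchema("dataset_id", "categorical", "identifier",
                       levels=("*",)),
        VariableSchema("num", "continuous", "demographic"),
        VariableSchema("cat", "categorical", "demographic",
                       levels=("A", "B", "C")),
    ])
    df = pd.DataFrame({
        "participant_id": list("pqrs"), "dataset_id": "A",
        "num": [1.0, 2.0, np.nan, 100.0],
        "cat": ["A", "A", "B", np.nan],
    })
    out = initialize(df, schema)
    assert out.loc[2, "num"] == 2.0           # median of {1, 2, 100}
    assert out.loc[3, "cat"] == "A"           # mode


def test_initialize_tie_breaks_lexicographically():
    schema = Schema([
        VariableSchema("participant_id", "categorical", "identifier",
                       levels=("*",)),
        VariableSchema("dataset_id", "categorical", "identifier",
                       levels=("*",)),
        VariableSchema("cat", "categorical", "demographic",
                       levels=("A", "B")),
    ])
    df = pd.DataFrame({"participant_id": list("pqr"), "dataset_id": "A",
                       "cat": ["B", "A", np.nan]})
    out = initialize(df, schema)
    assert out.loc[2, "cat"] == "A"


def test_initialize_rejects_all_missing_column():
    schema = _xy_schema()
    df = _xy_table([1, 2, 3], [np.nan] * 3)
    with pytest.raises(UnimputableColumnError):
        initialize(df, schema)


# -- stopping rule ------------------------------------------------------------

@pytest.mark.parametrize("trace, expected", [
    ([(0.50, 0), (0.20, 0), (0.30, 0)], 1),   # numeric increase at sweep 3
    ([(0.50, 0), (0.20, 0), (0.10, 0)], None),
    ([(0.10, 0.0), (0.05, 0.2)], 0),          # categorical increase
    ([(0.10, 0)], None),
])
def test_first_increase_stopping_rule(trace, expected):
    assert stop_index(trace) == expected


def test_engine_reports_criterion_stop_consistently(imputed_small):
    res = imputed_small
    t = res.delta_trace
    assert res.iterations_run == len(t)
    if res.stopped_by == "criterion":
        last, prev = t.iloc[-1], t.iloc[-2]
        assert (last["delta_numeric"] > prev["delta_numeric"]
                or last["delta_categorical"] > prev["delta_categorical"])
    else:
        assert res.iterations_run == res.config.max_iterations


# -- core behaviour -----------------------------------------------------------

def test_fully_observed_table_is_a_noop(schema):
    df = make_visits(schema, subjects=(("p1", [0.0, 18.0]),
                                       ("p2", [0.0]),))
    res = impute(df, schema, ImputationConfig(n_trees=5))
    assert res.iterations_run == 0
    pd.testing.assert_frame_equal(res.completed, df)


def test_observed_cells_preserved_bit_exact(schema, joined_small,
                                            imputed_small):
    joined, _ = joined_small
    res = imputed_small
    obs = joined.notna()
    for col in joined.columns:
        a = joined.loc[obs[col], col]
        b = res.completed.loc[obs[col], col]
        if a.dtype.kind == "O":
            assert (a == b).all()
        else:
            np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
    # nothing left missing among imputable columns
    imputable = [c for c in joined.columns
                 if schema[c].role not in ("identifier", "auxiliary")]
    assert res.completed[imputable].notna().all().all()


def test_same_seed_same_imputation(schema, joined_small, imputed_small):
    joined, _ = joined_small
    cfg = ImputationConfig(n_trees=5, rng_seed=3,
                           excluded_predictors=frozenset({"dataset_id"}))
    r2 = impute(joined, schema, cfg)
    pd.testing.assert_frame_equal(imputed_small.completed, r2.completed)
    pd.testing.assert_frame_equal(imputed_small.delta_trace, r2.delta_trace)


def test_integer_scores_rounded_and_in_range(schema, imputed_small):
    res = imputed_small
    for v in schema:
        c = v.canonical_name
        if c not in res.completed.columns or not v.integer_valued:
            continue
        vals = res.completed[c].dropna().to_numpy(float)
        assert (vals == np.round(vals)).all(), c
        lo, hi = v.valid_range
        assert vals.min() >= lo and vals.max() <= hi, c


def test_imputed_values_within_observed_range():
    """Forest predictions average observed responses, so imputed values stay
    inside the observed min/max (before integer rounding, which cannot
    escape it either)."""
    rng = np.random.default_rng(5)
    x = rng.uniform(0, 10, 120)
    y = 3 * x + rng.normal(0, 1, 120)
    y[::7] = np.nan
    df = _xy_table(x, y)
    res = impute(df, _xy_schema(), ImputationConfig(n_trees=10, rng_seed=0))
    imputed = res.completed.loc[df["y"].isna(), "y"]
    obs = df["y"].dropna()
    assert imputed.min() >= obs.min() and imputed.max() <= obs.max()


def test_noiseless_relation_imputed_close_to_truth():
    """y == x exactly on observed rows: the forest must land within 1.0 of
    the true value, no further than a single-tree oracle's neighborhood."""
    from sklearn.tree import DecisionTreeRegressor

    x = np.linspace(0, 20, 201)
    y = x.copy()
    miss_at = 100
    y_true = y[miss_at]
    y[miss_at] = np.nan
    df = _xy_table(x, y)
    res = impute(df, _xy_schema(), ImputationConfig(n_trees=25, rng_seed=2))
    got = res.completed.loc[miss_at, "y"]
    obs = df["y"].dropna()
    assert obs.min() <= got <= obs.max()
    assert abs(got - y_true) <= 1.0
    tree = DecisionTreeRegressor(random_state=0).fit(
        x[~np.isnan(y), None], y[~np.isnan(y)])
    oracle = tree.predict([[x[miss_at]]])[0]
    assert abs(oracle - y_true) <= 1.0


def test_degenerate_single_tree_is_exact_lookup():
    """One unlimited-depth tree, no bootstrap, all predictors: with distinct
    predictor values and a deterministic relation, imputation is a lookup of
    the matching training row's response."""
    x = np.arange(40, dtype=float)
    y = (x ** 2) % 17.0
    miss_at = 23
    x_full = np.append(x, x[miss_at])       # missing row repeats a train x
    y_full = np.append(y, np.nan)
    df = _xy_table(x_full, y_full)
    cfg = ImputationConfig(n_trees=1, bootstrap=False, max_features=1.0,
                           min_samples_leaf=1, rng_seed=0)
    res = impute(df, _xy_schema(), cfg)
    assert res.completed.loc[40, "y"] == y[miss_at]


def test_categorical_imputation_produces_valid_labels(schema):
    df = make_visits(schema, subjects=tuple(
        (f"p{i}", [0.0, 18.0]) for i in range(15)))
    rng = np.random.default_rng(1)
    df["sex"] = rng.choice(["F", "M"], len(df))
    df.loc[[2, 9], "sex"] = np.nan
    df.loc[[4, 11], "mmse"] = np.nan
    res = impute(df, schema, ImputationConfig(n_trees=5, rng_seed=0))
    assert set(res.completed["sex"]) <= {"F", "M"}
    assert "delta_categorical" in res.delta_trace.columns
    assert res.completed["sex"].notna().all()


# -- simulated-missing wrapper ------------------------------------------------

def test_simulated_missing_empty_mask_equals_plain_impute(schema, joined_small):
    joined, _ = joined_small
    cfg = ImputationConfig(n_trees=5, rng_seed=4,
                           excluded_predictors=frozenset({"dataset_id"}))
    res0 = impute(joined, schema, cfg)
    res1, actual = impute_with_simulated_missing(
        joined, "mmse", np.zeros(len(joined), bool), cfg, schema)
    assert actual.empty
    pd.testing.assert_frame_equal(res0.completed, res1.completed)


def test_simulated_missing_constant_column_recovered():
    x = np.arange(30, dtype=float)
    df = _xy_table(x, np.full(30, 7.0))
    mask = np.zeros(30, bool)
    mask[10] = True
    res, actual = impute_with_simulated_missing(
        df, "y", mask, ImputationConfig(n_trees=3, rng_seed=0), _xy_schema())
    assert actual.tolist() == [7.0]
    assert res.completed.loc[10, "y"] == 7.0


def test_simulated_missing_rejects_missing_cells():
    x = np.arange(10, dtype=float)
    y = x.copy()
    y[3] = np.nan
    df = _xy_table(x, y)
    mask = np.zeros(10, bool)
    mask[3] = True
    with pytest.raises(ImputationError, match="already missing"):
        impute_with_simulated_missing(df, "y", mask,
                                      ImputationConfig(n_trees=2),
                                      _xy_schema())


def test_config_validation():
    with pytest.raises(ImputationError):
        ImputationConfig(n_trees=0)
    with pytest.raises(ImputationError):
        ImputationConfig(max_iterations=0)
    with pytest.raises(ImputationError):
        ImputationConfig(visit_order_policy="sideways")


def test_schema_order_policy_runs(schema, joined_small):
    joined, _ = joined_small
    sub = pd.concat([joined[joined["dataset_id"] == "A"].head(120),
                     joined[joined["dataset_id"] == "B"].head(120)],
                    ignore_index=True)
    res = impute(sub, schema, ImputationConfig(
        n_trees=3, rng_seed=0, max_iterations=2,
        visit_order_policy="schema_order",
        excluded_predictors=frozenset({"dataset_id"})))
    assert res.iterations_run >= 1
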