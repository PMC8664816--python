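import numpy as np
import pandas as pd
import pytest

from cogimpute.harmonize import harmonize_studies
from cogimpute.schema import default_schema
from cogimpute.synthetic import demo_config, generate_cohorts


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def small_cohorts(schema):
    """A small masked two-cohort pair plus its ground truth."""
    cfg = demo_config(seed=11, n_a=80, n_b=80, max_followup=54.0)
    tables, truth = generate_cohorts(cfg, schema)
    return tables, truth


@pytest.fixture(scope="session")
def joined_small(small_cohorts, schema):
    tables, _ = small_cohorts
    joined, log = harmonize_studies(tables, schema)
    return joined, log


@pytest.fixture(scope="session")
def imputed_small(joined_small, schema):
    """One shared full imputation run on the small joined table."""
    from cogimpute.missforest import ImputationConfig, impute

    joined, _ = joined_small
    cfg = ImputationConfig(n_trees=5, rng_seed=3,
                           excluded_predictors=frozenset({"dataset_id"}))
    return impute(joined, schema, cfg)


def make_visits(schema, study="A", subjects=(("p1", [0.0, 18.0, 36.0]),),
                **overrides):
    """Hand-built minimal canonical visit table for filter tests."""
    rows = []
    for pid, months in subjects:
        for t in months:
            row = {
                "participant_id": pid,
                "dataset_id": study,
                "months_since_baseline": t,
                "age": 72.0 + t / 12.0,
                "sex": "F",
                "education": "13-15",
                "apoe_e4": 1.0,
                "clinical_class": "CN",
                "cdr": 0.0,
                "mmse": 29.0,
            }
            for name in schema.cognitive_names:
                row[name] = 10.0
            row.update({k: v for k, v in overrides.items()
                        if not callable(v)})
            for k, v in overrides.items():
                if callable(v):
                    row[k] = v(pid, t)
            rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture()
def tiny_table(schema):
    return make_visits(schema)


def assert_frames_equal_nan(a: pd.DataFrame, b: pd.DataFrame):
    pd.testing.assert_frame_equal(a.reset_index(drop=True),
                                  b.reset_index(drop=True),
                                  check_dtype=False)
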