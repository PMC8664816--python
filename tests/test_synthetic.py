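"""Statistical and structural properties of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest

from cogimpute.synthetic import (
    AmyloidParams,
    default_config,
    demo_config,
    generate_cohorts,
)


def test_subject_counts_match_config(schema):
    cfg = demo_config(seed=1, n_a=100, n_b=170)
    tables, _ = generate_cohorts(cfg, schema)
    assert tables["A"]["participant_id"].nunique() == 100
    assert tables["B"]["participant_id"].nunique() == 170


def test_same_seed_identical_tables(schema):
    a1, t1 = generate_cohorts(demo_config(seed=42, n_a=40, n_b=40), schema)
    a2, t2 = generate_cohorts(demo_config(seed=42, n_a=40, n_b=40), schema)
    for s in a1:
        pd.testing.assert_frame_equal(a1[s], a2[s])
        pd.testing.assert_frame_equal(t1.complete_tables[s],
                                      t2.complete_tables[s])
    pd.testing.assert_frame_equal(t1.mask, t2.mask)


def test_different_seed_differs(schema):
    a1, _ = generate_cohorts(demo_config(seed=1, n_a=30, n_b=30), schema)
    a2, _ = generate_cohorts(demo_config(seed=2, n_a=30, n_b=30), schema)
    assert not a1["A"].equals(a2["A"])


def test_systematic_masking_is_total(small_cohorts):
    tables, _ = small_cohorts
    assert tables["B"]["cvlt_immediate"].isna().all()
    assert tables["A"]["ravlt_immediate"].isna().all()
    assert tables["A"]["cvlt_immediate"].notna().sum() > 0
    assert tables["B"]["ravlt_immediate"].notna().sum() > 0


def test_released_equals_complete_outside_mask(small_cohorts):
    tables, truth = small_cohorts
    for study, rel in tables.items():
        comp = truth.complete_tables[study]
        masked = truth.mask[truth.mask["dataset_id"] == study]
        key = rel["participant_id"].astype(str) + "@" + rel[
            "months_since_baseline"].astype(str)
        for col in rel.columns:
            if col not in comp.columns:
                continue
            cell_masked = key.isin(
                masked.loc[masked["variable"] == col, "participant_id"]
                .astype(str) + "@" +
                masked.loc[masked["variable"] == col,
                           "months_since_baseline"].astype(str))
            free = ~cell_masked
            a, b = rel.loc[free, col], comp.loc[free, col]
            if a.dtype.kind == "O":
                assert (a.fillna("·") == b.fillna("·")).all()
            else:
                np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())
            assert rel.loc[cell_masked, col].isna().all()


def test_mcar_rate_recovered(schema):
    cfg = demo_config(seed=5, n_a=600, n_b=600).with_overrides(
        mcar_rate=0.15, class_missing_rate=0.0)
    tables, _ = generate_cohorts(cfg, schema)
    score_cols = [v.canonical_name for v in schema
                  if v.role in ("clinical", "cognitive")
                  and v.canonical_name not in ("cvlt_immediate",
                                               "ravlt_immediate")]
    frac = pd.concat([tables["A"][score_cols],
                      tables["B"][score_cols]]).isna().to_numpy().mean()
    n_cells = sum(len(tables[s]) for s in tables) * len(score_cols)
    assert n_cells >= 10_000
    tol = 4 * np.sqrt(0.15 * 0.85 / n_cells)
    assert abs(frac - 0.15) < tol


def test_class_means_recovered_at_baseline(schema):
    cfg = default_config(seed=3).with_overrides(
        n_subjects_by_study={"A": 1000, "B": 1000},
        mcar_rate=0.0, class_missing_rate=0.0)
    _, truth = generate_cohorts(cfg, schema)
    allc = pd.concat(truth.complete_tables.values())
    base = allc[allc["months_since_baseline"] == 0]
    for var in ("mmse", "cvlt_immediate", "lm_ii", "bnt"):
        for cls, grp in base.groupby("clinical_class"):
            target = cfg.score_means_by_class[var][cls]
            se = grp[var].std(ddof=1) / np.sqrt(len(grp))
            # rounding/clipping biases bounded scores slightly; 3 SE + 0.5 unit
            assert abs(grp[var].mean() - target) < 3 * se + 0.5, (var, cls)


def test_list_learning_tests_strongly_correlated(schema):
    """The two single-study tests share the latent factor: complete-data r > 0.8."""
    cfg = default_config(seed=7).with_overrides(
        n_subjects_by_study={"A": 1000, "B": 1000},
        mcar_rate=0.0, class_missing_rate=0.0)
    _, truth = generate_cohorts(cfg, schema)
    allc = pd.concat(truth.complete_tables.values())
    assert len(allc) >= 2000
    r = np.corrcoef(allc["cvlt_immediate"], allc["ravlt_immediate"])[0, 1]
    assert r > 0.8


def test_amyloid_negatively_coupled_in_enriched_subgroup(schema):
    cfg = demo_config(seed=9, n_a=400, n_b=400).with_overrides(
        class_proportions={s: {"CN": 0.2, "MCI": 0.6, "AD": 0.2}
                           for s in ("A", "B")},
        apoe_probs_by_study={s: (0.3, 0.3, 0.4) for s in ("A", "B")},
        mcar_rate=0.0, class_missing_rate=0.0)
    _, truth = generate_cohorts(cfg, schema)
    allc = pd.concat(truth.complete_tables.values())
    sub = allc[(allc["clinical_class"] == "MCI") & (allc["apoe_e4"] == 2)]
    assert len(sub) >= 500
    r = np.corrcoef(sub["amyloid_centiloid"], sub["cvlt_immediate"])[0, 1]
    assert r < 0


def test_default_config_mirrors_cohort_facts():
    cfg = default_config()
    assert cfg.n_subjects_by_study == {"A": 1805, "B": 2122}
    a = cfg.class_proportions["A"]
    assert a["CN"] == pytest.approx(0.65, abs=0.02)
    assert a["MCI"] == pytest.approx(0.17, abs=0.02)
    assert a["AD"] == pytest.approx(0.18, abs=0.02)
    assert cfg.visit_interval_months_by_study == {"A": 18.0, "B": 6.0}


def test_observation_ratio_near_1_7(schema):
    """Expected per-subject visit counts give a B:A observation ratio ≈ 1.7."""
    cfg = default_config()
    ret = cfg.retention_per_visit
    n_a_visits = int(cfg.max_followup_months //
                     cfg.visit_interval_months_by_study["A"]) + 1
    exp_a = sum(ret ** k for k in range(n_a_visits))
    n_b_visits = int(cfg.max_followup_months //
                     cfg.visit_interval_months_by_study["B"]) + 1 + 1  # +3mo
    exp_b = sum(ret ** k for k in range(n_b_visits))
    ratio = (2122 * exp_b) / (1805 * exp_a)
    assert 1.4 < ratio < 2.0


def test_config_validation_errors():
    with pytest.raises(ValueError, match="sum to 1"):
        demo_config().with_overrides(
            class_proportions={"A": {"CN": 0.5, "MCI": 0.2, "AD": 0.2},
                               "B": {"CN": 0.4, "MCI": 0.4, "AD": 0.2}}
        ).validate()
    with pytest.raises(ValueError, match="mcar"):
        demo_config().with_overrides(mcar_rate=1.0).validate()


def test_amyloid_params_defaults():
    p = AmyloidParams()
    assert all(v > 0 for v in p.coupling_by_class.values())
    assert p.mean_by_class["AD"] > p.mean_by_class["CN"]
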