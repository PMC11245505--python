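"""Feature fusion, screening, boosted models, and the metric panel."""

import numpy as np
import pandas as pd
import pytest

from ulcerquant import (
    bootstrap_auc_ci,
    cross_validate,
    evaluate,
    fit_prognostic_model,
    fuse_features,
    lasso_screen,
    panel_from_scores,
    rank_auc,
    split_cohort,
)
from ulcerquant.prognosis import CohortError, cohort_feature_columns
from ulcerquant.quantify import LesionFeatures, QuantifiedFeatures
from ulcerquant.synthetic import CohortSpec, generate_cohort, planted_cohort_spec


def qf(eye_id, scar_grade=0, **kw):
    lesions = {
        "scar": LesionFeatures(scar_grade, kw.get("scar_occ", 0), kw.get("scar_quad", 0)),
        "descemetocele": LesionFeatures(0),
        "abscess": LesionFeatures(0),
        "blue_ulcer": LesionFeatures(0, 0, 0),
        "neovascularization": LesionFeatures(0, 0, 0),
    }
    return QuantifiedFeatures(eye_id=eye_id, lesions=lesions)


@pytest.fixture
def clinical():
    return pd.DataFrame(
        {
            "patient_id": ["p1", "p2", "p3", "p4", "p5"],
            "age": [40, 55, 63, 70, 35],
            "sex": ["male", "female", "male", "female", "male"],
            "bcva": [0.3, 1.0, 0.1, 1.8, 0.5],
            "ulcer_type": ["bacterial", "fungal", "viral", "bacterial", "fungal"],
        }
    )


def test_fusion_single_image_passthrough_and_max_rule(clinical):
    quant = {
        "p1": [qf("e1", scar_grade=2)],
        "p2": [qf("e2", scar_grade=2), qf("e3", scar_grade=3)],
    }
    cohort = fuse_features(quant, clinical)
    row1 = cohort.set_index("patient_id").loc["p1"]
    row2 = cohort.set_index("patient_id").loc["p2"]
    assert row1["scar_grade"] == 2  # one image passes through unchanged
    assert row2["scar_grade"] == 3  # worst-lesion fusion
    mean_cohort = fuse_features(quant, clinical, rule="mean")
    assert mean_cohort.set_index("patient_id").loc["p2", "scar_grade"] == 2.5


def test_fusion_one_hot_encoding_sums_to_one(clinical):
    cohort = fuse_features({"p1": [qf("e1")]}, clinical)
    onehot = cohort[[c for c in cohort.columns if c.startswith("ulcer_type_")]]
    assert onehot.shape[1] == 4
    assert (onehot.sum(axis=1) == 1).all()


def test_fusion_rejects_patient_without_clinical_row(clinical):
    with pytest.raises(CohortError):
        fuse_features({"p9": [qf("e9")]}, clinical)


def test_split_cohort_sizes_and_determinism():
    cohort = generate_cohort(CohortSpec(n=240, seed=5))
    tr, va = split_cohort(cohort, "perforation_1m", ratio=0.8, seed=11)
    assert (len(tr), len(va)) == (192, 48)
    tr2, va2 = split_cohort(cohort, "perforation_1m", ratio=0.8, seed=11)
    assert list(tr.patient_id) == list(tr2.patient_id)
    with pytest.raises(ValueError):
        split_cohort(cohort, "perforation_1m", ratio=1.0)


def test_split_cohort_errors_on_degenerate_outcome():
    cohort = generate_cohort(CohortSpec(n=30, seed=5))
    cohort["perforation_1m"] = 1.0
    with pytest.raises(CohortError):
        split_cohort(cohort, "perforation_1m")


def test_lasso_screen_always_keeps_overwhelming_feature():
    rng = np.random.default_rng(0)
    n = 300
    x = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "patient_id": range(n),
            "big": x,
            "junk1": rng.normal(size=n),
            "junk2": rng.normal(size=n),
            "flat": np.ones(n),
            "y": (5 * x + rng.normal(scale=0.5, size=n) > 0).astype(int),
        }
    )
    for seed in range(3):
        sel = lasso_screen(df, "y", feature_cols=["big", "junk1", "junk2", "flat"], seed=seed)
        assert "big" in sel


def test_rank_auc_equals_pairwise_concordance(rng):
    for _ in range(20):
        n = int(rng.integers(6, 30))
        y = rng.integers(0, 2, size=n)
        if y.min() == y.max():
            continue
        s = rng.choice(np.linspace(0, 1, 7), size=n)  # ties likely
        pos, neg = s[y == 1], s[y == 0]
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert rank_auc(y, s) == pytest.approx(brute)


def test_rank_auc_requires_both_classes():
    with pytest.raises(ValueError):
        rank_auc([1, 1, 1], [0.2, 0.5, 0.9])


def test_bootstrap_ci_contains_point_auc(rng):
    for seed in range(5):
        r = np.random.default_rng(seed)
        y = np.r_[np.ones(30), np.zeros(40)].astype(int)
        s = np.r_[r.normal(1.0, 1, 30), r.normal(0, 1, 40)]
        lo, hi = bootstrap_auc_ci(y, s, n_boot=300, seed=seed)
        assert lo <= rank_auc(y, s) <= hi


def test_panel_metric_identities_and_closed_forms():
    # constructed confusion: TP=5, FN=2, TN=13, FP=5 at threshold 0.5
    y = np.r_[np.ones(7), np.zeros(18)].astype(int)
    s = np.r_[np.full(5, 0.9), np.full(2, 0.1), np.full(13, 0.2), np.full(5, 0.8)]
    rep = panel_from_scores(y, s, n_boot=100, seed=0)
    assert rep.sensitivity == pytest.approx(5 / 7)
    assert rep.specificity == pytest.approx(13 / 18)
    assert rep.ppv == pytest.approx(0.5)
    assert rep.npv == pytest.approx(13 / 15)
    assert rep.precision == rep.ppv and rep.recall == rep.sensitivity
    assert rep.f1 == pytest.approx(2 * rep.ppv * rep.sensitivity / (rep.ppv + rep.sensitivity))
    assert rep.ci_low <= rep.auc <= rep.ci_high


def test_panel_perfect_scores():
    y = np.r_[np.ones(10), np.zeros(10)].astype(int)
    s = np.r_[np.full(10, 0.99), np.full(10, 0.01)]
    rep = panel_from_scores(y, s, n_boot=100, seed=0)
    assert (rep.accuracy, rep.auc, rep.f1) == (1.0, 1.0, 1.0)


def test_panel_undefined_ratio_is_missing_not_zero():
    y = np.r_[np.ones(5), np.zeros(5)].astype(int)
    s = np.full(10, 0.1)  # nothing predicted positive
    rep = panel_from_scores(y, s, n_boot=50, seed=0)
    assert rep.ppv is None and rep.f1 is None
    assert rep.sensitivity == 0.0


def test_boosted_model_separable_data_and_importance():
    cohort = generate_cohort(planted_cohort_spec(400, seed=2))
    feats = cohort_feature_columns(cohort)
    cohort["perfect"] = cohort["perforation_1m"] * 2 - 1.0
    model = fit_prognostic_model(cohort, "perforation_1m", ["perfect"], "xgb", seed=0)
    rep = evaluate(model, cohort, "perforation_1m", n_boot=50, seed=0)
    assert rep.auc == 1.0
    model2 = fit_prognostic_model(cohort, "perforation_1m", feats, "xgb", seed=0)
    top3 = set(model2.feature_importances().index[:4])
    assert {"scar_grade", "blue_ulcer_grade"} & top3


@pytest.mark.parametrize("algorithm", ["xgb", "lgbm"])
def test_boosted_model_recovers_planted_signal(algorithm):
    cohort = generate_cohort(planted_cohort_spec(500, seed=4))
    tr, va = split_cohort(cohort, "perforation_1m", seed=4)
    sel = lasso_screen(tr, "perforation_1m", seed=4)
    model = fit_prognostic_model(tr, "perforation_1m", sel, algorithm, seed=4)
    rep = evaluate(model, va, "perforation_1m", n_boot=200, seed=4)
    assert rep.auc > 0.80


def test_fit_reproducible_given_seed():
    cohort = generate_cohort(planted_cohort_spec(300, seed=6))
    feats = cohort_feature_columns(cohort)
    m1 = fit_prognostic_model(cohort, "vision_1m", feats, "xgb", seed=9)
    m2 = fit_prognostic_model(cohort, "vision_1m", feats, "xgb", seed=9)
    assert np.array_equal(m1.predict_proba(cohort), m2.predict_proba(cohort))


def test_cross_validate_fold_structure_and_determinism():
    cohort = generate_cohort(planted_cohort_spec(200, seed=8))
    reports, mean = cross_validate(
        cohort, "perforation_1m", k=5, seed=8, screen=False, n_boot=50
    )
    assert len(reports) == 5
    assert all(r.n == 40 for r in reports)
    reports2, mean2 = cross_validate(
        cohort, "perforation_1m", k=5, seed=8, screen=False, n_boot=50
    )
    assert mean == mean2
    assert mean["auc"] > 0.7


def test_cross_validate_rejects_k_above_minority_count():
    cohort = generate_cohort(CohortSpec(n=40, intercept=-2.0, seed=3))
    counts = cohort["perforation_1m"].value_counts()
    with pytest.raises(CohortError):
        cross_validate(cohort, "perforation_1m", k=int(counts.min()) + 1)


def test_nested_screening_does_not_beat_leaky_screening_on_null_data():
    """On pure-noise outcomes, screening on the full table before CV leaks
    information; the honest nested procedure must not look better."""
    nested_aucs, leaky_aucs = [], []
    for rep in range(6):
        cohort = generate_cohort(
            CohortSpec(n=150, n_noise=8, features=("age", "sex", "bcva"), seed=900 + rep)
        )
        feats = cohort_feature_columns(cohort)
        _, nested = cross_validate(
            cohort, "vision_3m", k=3, seed=rep, screen=True, n_boot=20
        )
        leaked = lasso_screen(cohort, "vision_3m", seed=rep) or feats
        _, leaky = cross_validate(
            cohort, "vision_3m", k=3, seed=rep, screen=False,
            feature_cols=leaked, n_boot=20,
        )
        nested_aucs.append(nested["auc"])
        leaky_aucs.append(leaky["auc"])
    assert np.mean(nested_aucs) <= np.mean(leaky_aucs) + 0.05
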