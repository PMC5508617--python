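import numpy as np
import pandas as pd
import pytest

from livertex.analysis import (
    MODELS,
    StabilityResult,
    bootstrap_stability,
    cross_validate,
    kruskal_wallis,
    roc_analysis,
    roc_auc,
    screen_features,
    train_classifier,
)
from livertex.io import FeatureTable, FeatureVector, ValidationError


def _table(X: np.ndarray, labels, cohorts=None) -> FeatureTable:
    vecs = [
        FeatureVector(
            values={f"f{j}": float(X[i, j]) for j in range(X.shape[1])},
            subject_id=f"s{i}",
            label=labels[i],
        )
        for i in range(len(X))
    ]
    return FeatureTable.from_vectors(vecs, cohorts)


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kw_separated_groups_significant():
    h, p = kruskal_wallis([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
    assert p < 0.05


def test_kw_constant_groups_all_ties():
    h, p = kruskal_wallis([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
    assert h == 0.0
    assert p == 1.0


def test_kw_single_group_rejected():
    with pytest.raises(ValidationError):
        kruskal_wallis([1.0, 2.0, 3.0])


def test_kw_null_pvalues_uniform(rng):
    """Under permuted labels the p-value distribution is U(0,1):
    KS distance < 0.05 and rejection rate 0.05 +/- 0.01 at 1e4 draws."""
    from scipy.stats import kstest

    n = 25
    pvals = np.empty(10_000)
    pooled = rng.standard_normal(2 * n)
    for i in range(10_000):
        perm = rng.permutation(pooled)
        _, pvals[i] = kruskal_wallis(perm[:n], perm[n:])
    assert abs((pvals < 0.05).mean() - 0.05) < 0.01
    assert kstest(pvals, "uniform").statistic < 0.05


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def test_roc_perfect_separation():
    r = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert r.auc == 1.0
    assert r.sensitivity == 1.0 and r.specificity == 1.0


def test_roc_four_point_hand_example():
    r = roc_analysis([1.0, 2.0, 3.0, 4.0], [0, 0, 1, 1])
    assert r.auc == 1.0
    assert 2.0 < r.cutoff < 3.0
    assert r.sensitivity == 1.0 and r.specificity == 1.0


def test_roc_null_auc_near_half(rng):
    scores = rng.standard_normal(2000)
    labels = rng.integers(0, 2, size=2000)
    assert abs(roc_auc(scores, labels) - 0.5) < 0.03


def test_roc_matches_sklearn(rng):
    """Rank-formulation AUC equals scikit-learn's trapezoid AUC."""
    from sklearn.metrics import roc_auc_score

    for _ in range(10):
        scores = rng.standard_normal(50)
        labels = rng.integers(0, 2, size=50)
        if labels.min() == labels.max():
            continue
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12
        )


def test_roc_one_class_rejected():
    with pytest.raises(ValidationError):
        roc_analysis([1.0, 2.0], [1, 1])


def test_roc_hanley_mcneil_se_positive(rng):
    scores = np.concatenate([rng.normal(0, 1, 30), rng.normal(1, 1, 30)])
    labels = np.array([0] * 30 + [1] * 30)
    r = roc_analysis(scores, labels)
    assert 0 < r.se < 0.2
    assert r.ci95[0] <= r.auc <= r.ci95[1]


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def _separable_xy(rng, n=40):
    X = np.vstack(
        [rng.normal(0, 0.3, size=(n // 2, 2)), rng.normal(3, 0.3, size=(n // 2, 2))]
    )
    y = np.array([0] * (n // 2) + [1] * (n // 2))
    return X, y


@pytest.mark.parametrize("model", MODELS)
def test_all_models_fit_separable_toy(model, rng):
    X, y = _separable_xy(rng)
    fitted = train_classifier(model, X, y, seed=0)
    assert (fitted.predict(X) == y).mean() == 1.0


@pytest.mark.parametrize("model", MODELS)
def test_label_permuted_cv_auc_near_half(model, rng):
    """With labels shuffled independently of X, CV AUC ~ 0.5."""
    from livertex.analysis import _cv_auc

    X = rng.standard_normal((60, 4))
    aucs = [
        _cv_auc(model, X, np.random.default_rng(s).permutation([0] * 30 + [1] * 30),
                {}, 5, s)
        for s in range(6)
    ]
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_ann_refit_deterministic(rng):
    X, y = _separable_xy(rng)
    a = train_classifier("BP-ANN", X, y, {"hidden": 5}, seed=7)
    b = train_classifier("BP-ANN", X, y, {"hidden": 5}, seed=7)
    np.testing.assert_array_equal(
        a.named_steps["clf"].coefs_[0], b.named_steps["clf"].coefs_[0]
    )
    np.testing.assert_array_equal(a.predict(X), b.predict(X))


def test_unknown_model_rejected(rng):
    X, y = _separable_xy(rng)
    with pytest.raises(ValidationError):
        train_classifier("RandomForest", X, y)


# ---------------------------------------------------------------------------
# cross_validate / metrics
# ---------------------------------------------------------------------------

def _two_class_tables(rng, sep, n_train=60, n_val=30):
    def make(n):
        X = np.vstack(
            [
                rng.normal(0, 1, size=(n // 2, 3)),
                rng.normal(sep, 1, size=(n // 2, 3)),
            ]
        )
        labels = ["classA"] * (n // 2) + ["classB"] * (n // 2)
        return X, labels

    Xt, lt = make(n_train)
    Xv, lv = make(n_val)
    train = _table(Xt, lt, ["training"] * n_train)
    val = _table(Xv, lv, ["validation"] * n_val)
    return train, val


@pytest.mark.parametrize("model", MODELS)
def test_cross_validate_strong_separation(model, rng):
    train, val = _two_class_tables(rng, sep=4.0)
    ev = cross_validate(model, train, val, ("classA", "classB"),
                        ["f0", "f1", "f2"], k=5, seed=1)
    assert ev.auc >= 0.95
    assert ev.accuracy >= 0.9
    # metrics recomputed from the stored confusion matrix agree exactly
    tn, fp, fn, tp = ev.confusion
    assert ev.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
    assert ev.sensitivity == pytest.approx(tp / (tp + fn))
    assert ev.specificity == pytest.approx(tn / (tn + fp))
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    assert ev.mcc == pytest.approx((tp * tn - fp * fn) / denom)


def test_mcc_perfect_confusion_is_one(rng):
    train, val = _two_class_tables(rng, sep=8.0)
    ev = cross_validate("Logistic", train, val, ("classA", "classB"),
                        ["f0", "f1", "f2"], k=5, seed=0)
    assert ev.mcc == pytest.approx(1.0)
    assert ev.confusion[1] == ev.confusion[2] == 0


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

def test_rsd_worked_example():
    s = StabilityResult(auc_samples=np.array([0.8, 0.9]), model="KNN")
    assert s.rsd == pytest.approx(np.sqrt(0.005) / 0.85 * 100, rel=1e-12)
    assert s.rsd == pytest.approx(8.3189, abs=1e-3)


def test_rsd_constant_samples_zero():
    s = StabilityResult(auc_samples=np.full(30, 0.77), model="SVM")
    assert s.rsd == pytest.approx(0.0, abs=1e-10)


def test_rsd_scale_invariance(rng):
    samples = rng.uniform(0.6, 0.9, size=50)
    a = StabilityResult(auc_samples=samples, model="KNN").rsd
    b = StabilityResult(auc_samples=3.0 * samples, model="KNN").rsd
    assert a == pytest.approx(b, rel=1e-12)


def test_rsd_monotone_in_sigma():
    mu = 0.8
    tight = mu + 0.01 * np.array([-1, 1, -1, 1.0])
    wide = mu + 0.1 * np.array([-1, 1, -1, 1.0])
    assert (
        StabilityResult(tight, "KNN").rsd < StabilityResult(wide, "KNN").rsd
    )


def test_bootstrap_stability_runs(rng):
    train, _ = _two_class_tables(rng, sep=3.0, n_train=60)
    res = bootstrap_stability(
        "Logistic", train, ("classA", "classB"), ["f0", "f1", "f2"],
        n_resamples=25, seed=0,
    )
    assert res.auc_samples.size == 25
    assert 0.0 <= res.rsd < 30.0
    with pytest.raises(ValidationError):
        bootstrap_stability(
            "Logistic", train, ("classA", "classB"), ["f0"], n_resamples=10, seed=0
        )


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def test_screen_features_pairwise_structure(rng):
    X = rng.standard_normal((60, 3))
    X[:20, 0] += 4.0  # feature f0 separates classA from the rest
    labels = ["classA"] * 20 + ["classB"] * 20 + ["classC"] * 20
    table = _table(X, labels)
    res = screen_features(table)
    assert set(res) == {("classA", "classB"), ("classA", "classC"), ("classB", "classC")}
    assert "f0" in res[("classA", "classB")].significant
    assert "f0" in res[("classA", "classC")].significant
    assert "f0" not in res[("classB", "classC")].significant
    for r in res.values():
        assert ((r.table["p"] >= 0) & (r.table["p"] <= 1)).all()
        assert (r.table["p_adj"] >= r.table["p"] - 1e-12).all()
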