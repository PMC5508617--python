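"""Group screening, ROC analysis, classifiers and bootstrap stability.

The discrimination question is posed pairwise (three two-class tasks:
A vs B, B vs C, A vs C).  Per task:

* each feature is screened with a Kruskal-Wallis rank test (raw p < 0.05
  flags significance; Benjamini-Hochberg adjusted p-values are also
  reported);
* significant features get a ROC analysis: AUC by the rank (Mann-Whitney)
  formulation, Youden-optimal cut-off with its sensitivity/specificity,
  and a Hanley-McNeil standard error with a 95% CI;
* four classifiers (KNN k=5 Euclidean, a one-hidden-layer back-propagation
  neural network, a C-SVM with RBF kernel, and unpenalized logistic
  regression) are tuned by stratified 10-fold CV on the training cohort,
  refit on the full training cohort and scored on the held-out validation
  cohort (Acc, Sens, Spec, MCC, AUC);
* stability is the relative standard deviation (RSD = sigma/mu * 100) of
  AUCs over B bootstrap half-split train/validate rounds of the training
  cohort.

Features are z-scored with statistics fitted on the training data of each
fit, so no information leaks from validation folds.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .io import FeatureTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "MODELS",
    "ScreeningResult",
    "RocResult",
    "ModelEval",
    "StabilityResult",
    "kruskal_wallis",
    "screen_features",
    "roc_auc",
    "roc_analysis",
    "make_model",
    "train_classifier",
    "tune_hyperparameters",
    "cross_validate",
    "bootstrap_stability",
]

MODELS = ("KNN", "BP-ANN", "SVM", "Logistic")

DEFAULT_ALPHA = 0.05
DEFAULT_FOLDS = 10
DEFAULT_BOOTSTRAP = 100

ANN_HIDDEN_GRID = (3, 5, 10)
SVM_C_GRID = (0.1, 1.0, 10.0)
SVM_GAMMA_GRID = (0.01, 0.1, 1.0)


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

def kruskal_wallis(*groups) -> tuple[float, float]:
    """Rank-based Kruskal-Wallis H with tie correction; chi-square p (k-1 df).

    All-tied samples carry no rank information and return (0, 1).
    """
    if len(groups) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if g.size < 2:
            raise ValidationError("each group needs >= 2 observations")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


@dataclasses.dataclass
class ScreeningResult:
    """Per-feature Kruskal-Wallis screening for one class pair."""

    pair: tuple[str, str]
    table: "pd.DataFrame"  # index: feature; columns H, p, p_adj, significant
    alpha: float = DEFAULT_ALPHA

    @property
    def significant(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0.0, 1.0)
    return out


def screen_features(
    table: FeatureTable,
    features: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> dict[tuple[str, str], ScreeningResult]:
    """Pairwise Kruskal-Wallis screening of every feature, per class pair.

    Significance is flagged on the raw p-value (the study convention);
    BH-adjusted p-values are reported alongside.
    """
    features = features or table.feature_names
    labels = sorted(table.labels().unique())
    results: dict[tuple[str, str], ScreeningResult] = {}
    for a, b in itertools.combinations(labels, 2):
        rows = []
        ga = table.frame["label"] == a
        gb = table.frame["label"] == b
        for f in features:
            h, p = kruskal_wallis(
                table.frame.loc[ga, f].to_numpy(), table.frame.loc[gb, f].to_numpy()
            )
            rows.append({"feature": f, "H": h, "p": p})
        frame = pd.DataFrame(rows).set_index("feature")
        frame["p_adj"] = _bh_adjust(frame["p"].to_numpy())
        frame["significant"] = frame["p"] < alpha
        results[(a, b)] = ScreeningResult(pair=(a, b), table=frame, alpha=alpha)
    return results


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RocResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float


def roc_auc(scores, labels) -> float:
    """AUC by the rank (Mann-Whitney) formulation, ties counted half."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("ROC needs both classes present")
    ranks = stats.rankdata(s)
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_analysis(scores, labels) -> RocResult:
    """AUC, Hanley-McNeil SE/CI and the Youden-optimal operating point.

    The cut-off is placed midway between the adjacent observed scores that
    maximize Youden's J = sensitivity + specificity - 1; positives are
    scores > cut-off.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    auc = roc_auc(s, y)
    n1 = int(y.sum())
    n0 = y.size - n1
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    se = float(
        np.sqrt(
            (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2))
            / (n1 * n0)
        )
    )
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))

    uniq = np.unique(s)
    # candidate thresholds: below all, between adjacent uniques, above all
    mids = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best = None
    for t in mids:
        pred = s > t
        sens = float((pred & y).sum() / n1)
        spec = float((~pred & ~y).sum() / n0)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, t, sens, spec)
    _, cutoff, sens, spec = best
    return RocResult(auc=auc, se=se, ci95=ci, cutoff=float(cutoff),
                     sensitivity=sens, specificity=spec)


# ---------------------------------------------------------------------------
# classifiers
# ---------------------------------------------------------------------------

def make_model(model: str, hyper: dict | None = None, seed: int = 0) -> Pipeline:
    """A z-scored classifier pipeline for one of the four model families."""
    hyper = hyper or {}
    if model == "KNN":
        clf = KNeighborsClassifier(n_neighbors=hyper.get("k", 5), metric="euclidean")
    elif model == "BP-ANN":
        clf = MLPClassifier(
            hidden_layer_sizes=(hyper.get("hidden", 5),),
            activation="logistic",
            solver="lbfgs",
            max_iter=500,
            random_state=seed,
        )
    elif model == "SVM":
        clf = SVC(
            kernel="rbf",
            C=hyper.get("C", 1.0),
            gamma=hyper.get("gamma", 0.1),
            random_state=seed,
        )
    elif model == "Logistic":
        clf = LogisticRegression(penalty=None, solver="lbfgs", max_iter=2000)
    else:
        raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _scores(fitted: Pipeline, X: np.ndarray) -> np.ndarray:
    """Continuous decision score for ROC (probability of the positive class
    where available, decision function otherwise)."""
    clf = fitted.named_steps["clf"]
    if hasattr(clf, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    return fitted.decision_function(X)


def train_classifier(
    model: str, X: np.ndarray, y: np.ndarray, hyper: dict | None = None, seed: int = 0
) -> Pipeline:
    """Fit one classifier (with its z-scoring step) on a binary task."""
    if len(np.unique(y)) != 2:
        raise ValidationError("classifier training needs exactly two classes")
    import warnings

    if model == "KNN":
        # k can never exceed the fitted sample size (tiny bootstrap halves)
        hyper = {**(hyper or {}), "k": min((hyper or {}).get("k", 5), len(y))}
    pipe = make_model(model, hyper, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP/logistic convergence chatter
        pipe.fit(X, y)
    return pipe


def _grid(model: str) -> list[dict]:
    if model == "BP-ANN":
        return [{"hidden": h} for h in ANN_HIDDEN_GRID]
    if model == "SVM":
        return [{"C": c, "gamma": g} for c in SVM_C_GRID for g in SVM_GAMMA_GRID]
    return [{}]


def _cv_auc(model: str, X, y, hyper, k, seed) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        if len(np.unique(y[te])) < 2:
            continue
        fitted = train_classifier(model, X[tr], y[tr], hyper, seed)
        aucs.append(roc_auc(_scores(fitted, X[te]), y[te]))
    if not aucs:
        raise ValidationError("no fold contained both classes")
    return float(np.mean(aucs))


def tune_hyperparameters(
    model: str, X: np.ndarray, y: np.ndarray, k: int = DEFAULT_FOLDS, seed: int = 0
) -> tuple[dict, float]:
    """Pick the grid point with the best stratified k-fold CV AUC."""
    k = min(k, int(np.bincount(y).min()))
    if k < 2:
        raise ValidationError("need >= 2 subjects per class for CV")
    best: tuple[float, dict] | None = None
    for hyper in _grid(model):
        auc = _cv_auc(model, X, y, hyper, k, seed)
        if best is None or auc > best[0]:
            best = (auc, hyper)
    return best[1], best[0]


@dataclasses.dataclass
class ModelEval:
    """Validation-cohort performance of one tuned classifier."""

    model: str
    accuracy: float
    sensitivity: float
    specificity: float
    mcc: float
    auc: float
    cv_auc: float  # inner-CV AUC on the training cohort
    hyper: dict
    confusion: tuple[int, int, int, int]  # tn, fp, fn, tp

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mcc": self.mcc,
            "auc": self.auc,
            "cv_auc": self.cv_auc,
            "hyper": self.hyper,
            "confusion": list(self.confusion),
        }


def _confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple:
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    acc = (tp + tn) / max(1, tp + tn + fp + fn)
    sens = tp / max(1, tp + fn)
    spec = tn / max(1, tn + fp)
    denom = np.sqrt(float((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return acc, sens, spec, float(mcc), (tn, fp, fn, tp)


def _binary_xy(table: FeatureTable, pair: tuple[str, str], features: list[str]):
    sub = table.frame[table.frame["label"].isin(pair)]
    X = sub[features].to_numpy(dtype=float)
    y = (sub["label"] == pair[1]).to_numpy().astype(int)
    return X, y


def cross_validate(
    model: str,
    train_table: FeatureTable,
    val_table: FeatureTable,
    pair: tuple[str, str],
    features: list[str],
    k: int = DEFAULT_FOLDS,
    seed: int = 0,
) -> ModelEval:
    """Tune by stratified k-fold CV on the training cohort, refit on all of
    it, and report Acc/Sens/Spec/MCC/AUC on the held-out validation cohort."""
    Xtr, ytr = _binary_xy(train_table, pair, features)
    Xva, yva = _binary_xy(val_table, pair, features)
    if len(np.unique(yva)) < 2:
        raise ValidationError(f"validation cohort lacks a class for pair {pair}")
    hyper, cv_auc = tune_hyperparameters(model, Xtr, ytr, k=k, seed=seed)
    fitted = train_classifier(model, Xtr, ytr, hyper, seed)
    y_pred = fitted.predict(Xva)
    acc, sens, spec, mcc, conf = _confusion_metrics(yva, y_pred)
    auc = roc_auc(_scores(fitted, Xva), yva)
    return ModelEval(
        model=model,
        accuracy=acc,
        sensitivity=sens,
        specificity=spec,
        mcc=mcc,
        auc=auc,
        cv_auc=cv_auc,
        hyper=hyper,
        confusion=conf,
    )


# ---------------------------------------------------------------------------
# bootstrap stability
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class StabilityResult:
    """Bootstrap half-split AUC sample with its RSD stability score."""

    auc_samples: np.ndarray
    model: str

    @property
    def mu(self) -> float:
        return float(self.auc_samples.mean())

    @property
    def sigma(self) -> float:
        # sample (ddof=1) standard deviation of the bootstrap AUC sample
        return float(self.auc_samples.std(ddof=1))

    @property
    def median(self) -> float:
        return float(np.median(self.auc_samples))

    @property
    def rsd(self) -> float:
        """Relative standard deviation of the AUC sample, in percent."""
        return self.sigma / self.mu * 100.0

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "auc_median": self.median,
            "auc_mean": self.mu,
            "auc_std": self.sigma,
            "rsd_percent": self.rsd,
            "n_resamples": int(self.auc_samples.size),
        }


def bootstrap_stability(
    model: str,
    train_table: FeatureTable,
    pair: tuple[str, str],
    features: list[str],
    n_resamples: int = DEFAULT_BOOTSTRAP,
    seed: int = 0,
    hyper: dict | None = None,
) -> StabilityResult:
    """B rounds of stratified random half-split train/validate on the
    training cohort; the spread of the resulting AUCs measures stability.

    Degenerate splits (a class missing on either side) are skipped and
    logged; at least 90% of the requested resamples must succeed.
    """
    if n_resamples < 20:
        raise ValidationError(f"need >= 20 bootstrap resamples, got {n_resamples}")
    X, y = _binary_xy(train_table, pair, features)
    rng = np.random.default_rng(seed)
    aucs: list[float] = []
    skipped = 0
    for b in range(n_resamples):
        half_a: list[int] = []
        half_b: list[int] = []
        for cls in (0, 1):
            idx = np.flatnonzero(y == cls)
            idx = rng.permutation(idx)
            half_a.extend(idx[: len(idx) // 2])
            half_b.extend(idx[len(idx) // 2 :])
        ia = np.array(half_a)
        ib = np.array(half_b)
        if len(np.unique(y[ia])) < 2 or len(np.unique(y[ib])) < 2:
            skipped += 1
            logger.warning("bootstrap resample %d skipped: degenerate split", b)
            continue
        fitted = train_classifier(model, X[ia], y[ia], hyper, seed=int(rng.integers(2**31)))
        aucs.append(roc_auc(_scores(fitted, X[ib]), y[ib]))
    if len(aucs) < 0.9 * n_resamples:
        raise ValidationError(
            f"only {len(aucs)}/{n_resamples} bootstrap resamples succeeded"
        )
    return StabilityResult(auc_samples=np.array(aucs), model=model)
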