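"""Outcome modeling: feature fusion, LASSO screening, boosted classifiers,
the binary-classification metric panel with bootstrap AUC confidence
intervals, and stratified cross-validation.

The modeled outcomes are corneal perforation and vision improvement at one
and three months, as binary columns of a per-patient cohort table that fuses
quantified lesion features with clinical covariates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler

from .quantify import QuantifiedFeatures, feature_columns
from .segmetrics import round_half_up

log = logging.getLogger(__name__)

OUTCOME_COLUMNS = ("perforation_1m", "perforation_3m", "vision_1m", "vision_3m")

#: Declared etiology categories for the ulcer_type covariate.
ULCER_TYPES = ("bacterial", "fungal", "viral", "acanthamoeba")

CLINICAL_COLUMNS = ("age", "sex", "bcva", "ulcer_type")


class CohortError(ValueError):
    """Cohort table violates a structural requirement."""


# ---------------------------------------------------------------------------
# feature fusion
# ---------------------------------------------------------------------------

def encode_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Numeric encoding of the clinical covariates.

    sex -> 0/1 indicator (male = 1); ulcer_type -> one-hot indicator columns
    over the declared category set; age and bcva pass through.
    """
    missing = [c for c in ("patient_id",) + CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise CohortError(f"clinical table missing columns: {missing}")
    if clinical["patient_id"].duplicated().any():
        dup = clinical.loc[clinical["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise CohortError(f"duplicate patient_id in clinical table: {dup!r}")
    if (clinical["age"] < 0).any():
        raise CohortError("negative age in clinical table")
    bad_type = set(clinical["ulcer_type"]) - set(ULCER_TYPES)
    if bad_type:
        raise CohortError(f"unknown ulcer_type values: {sorted(bad_type)}")
    bad_sex = set(clinical["sex"]) - {"male", "female"}
    if bad_sex:
        raise CohortError(f"unknown sex values: {sorted(bad_sex)}")
    out = pd.DataFrame({"patient_id": clinical["patient_id"]})
    out["age"] = clinical["age"].astype(float)
    out["sex"] = (clinical["sex"] == "male").astype(int)
    out["bcva"] = clinical["bcva"].astype(float)
    for level in ULCER_TYPES:
        out[f"ulcer_type_{level}"] = (clinical["ulcer_type"] == level).astype(int)
    return out


def clinical_feature_columns() -> list[str]:
    return ["age", "sex", "bcva"] + [f"ulcer_type_{t}" for t in ULCER_TYPES]


def fuse_features(
    quantified: Mapping[str, Sequence[QuantifiedFeatures]] | pd.DataFrame,
    clinical: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    rule: str = "max",
) -> pd.DataFrame:
    """Fuse per-image quantified features with clinical covariates.

    Patients imaged more than once (e.g. under both light sources) have
    their per-image features aggregated element-wise; ``rule="max"``
    (default) keeps the worst observed value of each feature, ``rule="mean"``
    averages.  Clinical covariates are encoded numerically, and outcome
    columns are merged when an outcomes table is given.

    ``quantified`` is either a mapping patient_id -> QuantifiedFeatures list,
    or a DataFrame of per-image rows with a ``patient_id`` column and the
    quantified feature columns.
    """
    if rule not in ("max", "mean"):
        raise ValueError(f"unknown fusion rule {rule!r}")
    if isinstance(quantified, pd.DataFrame):
        img = quantified.copy()
        if "patient_id" not in img.columns:
            raise CohortError("per-image feature table must have a patient_id column")
    else:
        rows = []
        for pid, qfs in quantified.items():
            for qf in qfs:
                row = qf.to_row()
                row["patient_id"] = pid
                rows.append(row)
        img = pd.DataFrame(rows)
    feat_cols = feature_columns()
    missing = [c for c in feat_cols if c not in img.columns]
    if missing:
        raise CohortError(f"quantified features missing columns: {missing}")
    for c in feat_cols:
        if not pd.api.types.is_numeric_dtype(img[c]):
            raise CohortError(f"non-numeric quantified feature column: {c}")
    agg = img.groupby("patient_id", sort=True)[feat_cols].agg(rule).reset_index()
    enc = encode_clinical(clinical)
    unmatched = set(agg["patient_id"]) - set(enc["patient_id"])
    if unmatched:
        raise CohortError(f"patients with images but no clinical row: {sorted(unmatched)[:5]}")
    cohort = enc.merge(agg, on="patient_id", how="left")
    # patients without images carry zero lesion features (no lesion observed)
    cohort[feat_cols] = cohort[feat_cols].fillna(0)
    cohort = cohort[["patient_id"] + feat_cols + clinical_feature_columns()]
    if outcomes is not None:
        if "patient_id" not in outcomes.columns:
            raise CohortError("outcomes table must have a patient_id column")
        keep = ["patient_id"] + [c for c in OUTCOME_COLUMNS if c in outcomes.columns]
        cohort = cohort.merge(outcomes[keep], on="patient_id", how="left")
        for c in keep[1:]:
            vals = cohort[c].dropna().unique()
            if not set(vals) <= {0, 1}:
                raise CohortError(f"outcome column {c} is not binary: {sorted(vals)[:5]}")
    return cohort


def cohort_feature_columns(cohort: pd.DataFrame) -> list[str]:
    """All model feature columns present in a cohort table, in canonical order."""
    known = feature_columns() + clinical_feature_columns()
    cols = [c for c in known if c in cohort.columns]
    extra = [
        c
        for c in cohort.columns
        if c not in cols and c not in OUTCOME_COLUMNS and c != "patient_id"
    ]
    return cols + sorted(extra)


# ---------------------------------------------------------------------------
# splitting and screening
# ---------------------------------------------------------------------------

def split_cohort(
    cohort: pd.DataFrame, outcome: str, ratio: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/validation split; ``ratio`` is the training fraction."""
    if not 0 < ratio < 1:
        raise ValueError("split ratio must lie strictly between 0 and 1 (both sides non-empty)")
    data = cohort.dropna(subset=[outcome])
    y = data[outcome].astype(int)
    if y.nunique() < 2:
        raise CohortError(f"outcome {outcome!r} has a single class; cannot stratify")
    if y.value_counts().min() < 2:
        raise CohortError(
            f"outcome {outcome!r} minority class has <2 members; "
            "collect more data or merge tasks"
        )
    train, val = train_test_split(
        data, train_size=ratio, stratify=y, random_state=int(seed), shuffle=True
    )
    return train.reset_index(drop=True), val.reset_index(drop=True)


def lasso_screen(
    train: pd.DataFrame,
    outcome: str,
    feature_cols: Sequence[str] | None = None,
    seed: int = 0,
    n_folds: int = 5,
    n_penalties: int = 25,
) -> list[str]:
    """L1-penalized logistic screening of the feature columns.

    Features are standardized to zero mean / unit variance, an L1 logistic
    path is fit, the penalty is chosen by ``n_folds``-fold cross-validated
    deviance (log-loss), and the features with non-zero coefficients at that
    penalty are returned.  Zero-variance features are dropped with a warning.
    """
    if feature_cols is None:
        feature_cols = cohort_feature_columns(train)
    data = train.dropna(subset=[outcome])
    y = data[outcome].astype(int).to_numpy()
    if np.unique(y).size < 2:
        raise CohortError(f"outcome {outcome!r} is constant in the training data")
    X = data[list(feature_cols)].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    if not keep.all():
        dropped = [c for c, k in zip(feature_cols, keep) if not k]
        log.warning("dropping zero-variance features: %s", dropped)
        feature_cols = [c for c, k in zip(feature_cols, keep) if k]
        X = X[:, keep]
    Xs = StandardScaler().fit_transform(X)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=int(seed))
    model = LogisticRegressionCV(
        penalty="l1",
        solver="liblinear",
        Cs=np.logspace(-2.5, 1.5, n_penalties),
        scoring="neg_log_loss",
        cv=cv,
        max_iter=2000,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xs, y)
    coefs = model.coef_.ravel()
    return [c for c, b in zip(feature_cols, coefs) if b != 0.0]


# ---------------------------------------------------------------------------
# boosted models
# ---------------------------------------------------------------------------

#: Default boosting hyperparameters: shallow trees, modest learning rate,
#: early stopping on an internal stratified holdout.
DEFAULT_BOOST_PARAMS = {
    "max_depth": 3,
    "n_estimators": 200,
    "learning_rate": 0.1,
    "early_stopping_rounds": 20,
    "validation_fraction": 0.2,
}

ALGORITHMS = ("xgb", "lgbm")


@dataclass
class PrognosticModel:
    """A fitted boosted-tree classifier restricted to screened features."""

    algorithm: str
    features: list[str]
    booster: object
    params: dict = field(default_factory=dict)

    def predict_proba(self, data: pd.DataFrame) -> np.ndarray:
        X = data[self.features].astype(float)
        return np.asarray(self.booster.predict_proba(X)[:, 1], dtype=float)

    def feature_importances(self) -> pd.Series:
        imp = np.asarray(self.booster.feature_importances_, dtype=float)
        return pd.Series(imp, index=self.features).sort_values(ascending=False)


def fit_prognostic_model(
    train: pd.DataFrame,
    outcome: str,
    features: Sequence[str],
    algorithm: str = "xgb",
    params: Mapping | None = None,
    seed: int = 0,
) -> PrognosticModel:
    """Train a gradient-boosted binary classifier on the screened features.

    ``algorithm`` selects the XGBoost or LightGBM implementation; both are
    run single-threaded with a fixed seed so fits are reproducible.  A
    stratified internal holdout drives early stopping; if the holdout would
    be degenerate (too few minority cases) the full round budget is used.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if not features:
        raise ValueError("no features to train on (screening selected none?)")
    p = dict(DEFAULT_BOOST_PARAMS)
    p.update(params or {})
    data = train.dropna(subset=[outcome])
    y = data[outcome].astype(int).to_numpy()
    if np.unique(y).size < 2:
        raise CohortError(f"outcome {outcome!r} is constant; nothing to learn")
    X = data[list(features)].astype(float)

    vfrac = p.pop("validation_fraction")
    esr = p.pop("early_stopping_rounds")
    can_stop = np.bincount(y).min() >= max(2, int(round(1 / vfrac)))
    if can_stop:
        Xf, Xv, yf, yv = train_test_split(
            X, y, test_size=vfrac, stratify=y, random_state=int(seed)
        )
    else:
        Xf, yf = X, y
        Xv = yv = None

    if algorithm == "xgb":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            **p,
            objective="binary:logistic",
            eval_metric="logloss",
            early_stopping_rounds=esr if can_stop else None,
            n_jobs=1,
            random_state=int(seed),
            verbosity=0,
        )
        if can_stop:
            clf.fit(Xf, yf, eval_set=[(Xv, yv)], verbose=False)
        else:
            clf.fit(Xf, yf)
    else:
        from lightgbm import LGBMClassifier, early_stopping

        clf = LGBMClassifier(
            **p,
            objective="binary",
            n_jobs=1,
            random_state=int(seed),
            verbosity=-1,
        )
        if can_stop:
            clf.fit(
                Xf,
                yf,
                eval_set=[(Xv, yv)],
                eval_metric="binary_logloss",
                callbacks=[early_stopping(esr, verbose=False)],
            )
        else:
            clf.fit(Xf, yf)
    return PrognosticModel(algorithm=algorithm, features=list(features), booster=clf, params=p)


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rank_auc(labels, scores) -> float:
    """Area under the ROC curve by the Mann-Whitney rank statistic.

    Equals the fraction of (positive, negative) pairs where the positive
    scores higher, counting ties as one half.
    """
    from scipy.stats import rankdata

    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes present")
    r = rankdata(s)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def bootstrap_auc_ci(
    labels,
    scores,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified percentile bootstrap CI for the AUC.

    Positives and negatives are resampled separately so every replicate has
    both classes.  The interval is widened, if necessary, to contain the
    point estimate (degenerate score distributions can otherwise place the
    point estimate on a percentile edge).
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    pos = s[y == 1]
    neg = s[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC CI undefined: need both classes present")
    rng = np.random.default_rng(int(seed))
    aucs = np.empty(n_boot)
    chunk = max(1, int(2e6 // max(1, pos.size * neg.size)))
    for start in range(0, n_boot, chunk):
        b = min(chunk, n_boot - start)
        pi = rng.integers(0, pos.size, size=(b, pos.size))
        ni = rng.integers(0, neg.size, size=(b, neg.size))
        P = pos[pi][:, :, None]
        N = neg[ni][:, None, :]
        gt = (P > N).mean(axis=(1, 2))
        eq = (P == N).mean(axis=(1, 2))
        aucs[start : start + b] = gt + 0.5 * eq
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    point = rank_auc(y, s)
    return float(min(lo, point)), float(max(hi, point))


def _safe_ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


@dataclass(frozen=True)
class PrognosisReport:
    """The binary-classification metric panel, all values as fractions.

    ``precision``/``recall`` duplicate ``ppv``/``sensitivity`` by construction
    (the panel lists both).  Ratios with a zero denominator are ``None``.
    """

    accuracy: float
    auc: float
    ci_low: float
    ci_high: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    f1: float | None
    n: int
    threshold: float

    @property
    def precision(self) -> float | None:
        return self.ppv

    @property
    def recall(self) -> float | None:
        return self.sensitivity

    def to_dict(self, ndigits: int = 2) -> dict:
        rnd = lambda v: None if v is None else round_half_up(v, ndigits)  # noqa: E731
        return {
            "accuracy": rnd(self.accuracy),
            "auc": rnd(self.auc),
            "ci_low": rnd(self.ci_low),
            "ci_high": rnd(self.ci_high),
            "sensitivity": rnd(self.sensitivity),
            "specificity": rnd(self.specificity),
            "ppv": rnd(self.ppv),
            "npv": rnd(self.npv),
            "precision": rnd(self.precision),
            "recall": rnd(self.recall),
            "f1": rnd(self.f1),
            "n": self.n,
            "threshold": self.threshold,
        }


def panel_from_scores(
    labels,
    scores,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> PrognosisReport:
    """Metric panel from true labels and predicted scores."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise ValueError("labels and scores must align")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = y.size
    auc = rank_auc(y, s)  # raises on single-class data
    lo, hi = bootstrap_auc_ci(y, s, n_boot=n_boot, seed=seed)
    sens = _safe_ratio(tp, tp + fn)
    ppv = _safe_ratio(tp, tp + fp)
    f1 = None
    if sens is not None and ppv is not None and (sens + ppv) > 0:
        f1 = 2 * ppv * sens / (ppv + sens)
    return PrognosisReport(
        accuracy=(tp + tn) / n,
        auc=auc,
        ci_low=lo,
        ci_high=hi,
        sensitivity=sens,
        specificity=_safe_ratio(tn, tn + fp),
        ppv=ppv,
        npv=_safe_ratio(tn, tn + fn),
        f1=f1,
        n=n,
        threshold=threshold,
    )


def evaluate(
    model: PrognosticModel,
    data: pd.DataFrame,
    outcome: str,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> PrognosisReport:
    """Score a fitted model on labeled data (rows with a missing outcome drop)."""
    d = data.dropna(subset=[outcome])
    y = d[outcome].astype(int).to_numpy()
    scores = model.predict_proba(d)
    return panel_from_scores(y, scores, threshold=threshold, n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def cross_validate(
    cohort: pd.DataFrame,
    outcome: str,
    algorithm: str = "xgb",
    k: int = 5,
    seed: int = 0,
    feature_cols: Sequence[str] | None = None,
    screen: bool = True,
    params: Mapping | None = None,
    threshold: float = 0.5,
    n_boot: int = 500,
) -> tuple[list[PrognosisReport], dict]:
    """Stratified k-fold cross-validation with in-fold feature screening.

    LASSO screening is re-run inside each training fold so no information
    from a fold's held-out patients leaks into its feature selection.  If
    screening selects nothing in a fold, all candidate features are used for
    that fold.  Returns the per-fold reports and the mean of each metric.
    """
    data = cohort.dropna(subset=[outcome]).reset_index(drop=True)
    y = data[outcome].astype(int)
    if y.nunique() < 2:
        raise CohortError(f"outcome {outcome!r} has a single class")
    if k > y.value_counts().min():
        raise CohortError(
            f"k={k} exceeds the minority class count ({y.value_counts().min()})"
        )
    if feature_cols is None:
        feature_cols = cohort_feature_columns(data)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    reports: list[PrognosisReport] = []
    for fold, (tr, te) in enumerate(skf.split(data, y)):
        train, test = data.iloc[tr], data.iloc[te]
        feats = list(feature_cols)
        if screen:
            selected = lasso_screen(train, outcome, feature_cols=feats, seed=seed)
            if selected:
                feats = selected
            else:
                log.warning("fold %d: screening selected no features; using all", fold)
        model = fit_prognostic_model(
            train, outcome, feats, algorithm=algorithm, params=params, seed=seed
        )
        reports.append(
            evaluate(model, test, outcome, threshold=threshold, n_boot=n_boot, seed=seed)
        )
    keys = ("accuracy", "auc", "sensitivity", "specificity", "ppv", "npv", "f1")
    mean = {}
    for key in keys:
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        mean[key] = float(np.mean(vals)) if vals else None
    return reports, mean
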