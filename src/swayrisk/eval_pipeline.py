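"""Model validation engine: LOSO-CV, SFFS, bootstrap inference, calibration.

The unit of inference is the subject.  Every model is evaluated with
leave-one-subject-out cross-validation (LOSO-CV): all trials of one subject
form the test fold, features are z-scored with training-fold statistics
only, and the held-out subject's trial probabilities are arithmetically
averaged into a single subject-level risk probability.  Discrimination is
summarised by the subject-level AUC with 1000-replicate bootstrap mean, SD
and 95% percentile CI; the operating point is the Youden-index-optimal
threshold; calibration is reported as three quantile bins plus the Brier
score; and each model is compared to the random-forest baseline with a
paired bootstrap AUC-difference test.

Feature selection uses sequential forward floating selection (SFFS) with a
subject-level inner-LOSO AUC objective.  Two modes are provided: ``nested``
(SFFS re-run inside every outer fold on training subjects only — the
leakage-safe mode; the reported subset is the modal subset across folds) and
``descriptive`` (a single SFFS pass over all subjects, matching the style of
a single reported subset; labelled descriptive because it sees every
subject).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

__all__ = [
    "ModelSpec",
    "MODEL_SPECS",
    "FoldResult",
    "BootstrapSummary",
    "EvalResult",
    "make_model",
    "loso_splits",
    "standardize_fit",
    "standardize_apply",
    "train_predict",
    "aggregate_subject",
    "subject_auc",
    "youden_threshold",
    "sffs",
    "select_features",
    "bootstrap_auc",
    "bootstrap_auc_diff_test",
    "calibration_bins",
    "brier",
    "loso_predict",
    "screen_conditions",
    "evaluate_models",
    "heatmap_matrix",
]

logger = logging.getLogger(__name__)

META_COLS = ("subject_id", "condition", "trial_index", "label")
POSITIVE_LABEL = "fall_risk"


@dataclass(frozen=True)
class ModelSpec:
    """A classifier identity plus its fixed hyperparameters."""

    model_id: str
    params: tuple[tuple[str, object], ...]

    def as_dict(self) -> dict[str, object]:
        return dict(self.params)


def _spec(model_id: str, **params: object) -> ModelSpec:
    return ModelSpec(model_id=model_id, params=tuple(sorted(params.items())))


#: The five study classifiers with their fixed configurations.  Class
#: weighting is always on (8 vs 24 subjects is a 1:3 imbalance) and every
#: stochastic component is seeded.
MODEL_SPECS: dict[str, ModelSpec] = {
    "DT": _spec("DT", max_depth=3, min_samples_leaf=1, class_weight="balanced", random_state=42),
    "RF": _spec("RF", n_estimators=100, max_depth=3, class_weight="balanced", random_state=42),
    "XGB": _spec("XGB", scale_pos_weight=3, n_estimators=50, max_depth=2,
                 learning_rate=0.1, random_state=42),
    "LR": _spec("LR", C=5.0, class_weight="balanced", random_state=42),
    "SVM": _spec("SVM", C=1.5, kernel="linear", class_weight="balanced",
                 probability=True, random_state=42),
}

BASELINE_MODEL = "RF"


def make_model(spec: ModelSpec):
    """Instantiate the scikit-learn / xgboost estimator for a spec."""
    p = spec.as_dict()
    if spec.model_id == "DT":
        return DecisionTreeClassifier(**p)
    if spec.model_id == "RF":
        return RandomForestClassifier(**p, n_jobs=1)
    if spec.model_id == "XGB":
        return XGBClassifier(**p, n_jobs=1, eval_metric="logloss")
    if spec.model_id == "LR":
        return LogisticRegression(**p, max_iter=5000)
    if spec.model_id == "SVM":
        return SVC(**p)
    raise ValueError(f"unknown model_id {spec.model_id!r}")


# ---------------------------------------------------------------------------
# folds, standardization, per-fold prediction
# ---------------------------------------------------------------------------

def _subject_labels(features: pd.DataFrame) -> pd.Series:
    return features.groupby("subject_id", sort=True)["label"].first()


def loso_splits(features: pd.DataFrame) -> list[tuple[list[str], str]]:
    """One (train_subjects, test_subject) split per subject.

    Raises if fewer than 3 subjects, a class is missing, or removing a
    subject would leave a single-class training fold (degenerate cohort).
    """
    labels = _subject_labels(features)
    subjects = list(labels.index)
    if len(subjects) < 3:
        raise ValueError("LOSO needs at least 3 subjects")
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < 2:
        raise ValueError(
            "a class with a single subject leaves single-class training folds"
        )
    return [([s for s in subjects if s != t], t) for t in subjects]


def standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature mean and SD (N-1) from training rows only.

    Zero-SD features get SD 1 so they pass through centered (flagged in the
    debug log rather than raising).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("standardization needs at least 2 training rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.debug("zero-SD features pass through centered: %d", degenerate.sum())
        sd = np.where(degenerate, 1.0, sd)
    return mean, sd


def standardize_apply(params: tuple[np.ndarray, np.ndarray], X: np.ndarray) -> np.ndarray:
    mean, sd = params
    return (np.asarray(X, dtype=float) - mean) / sd


def train_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
) -> np.ndarray:
    """Fall-risk probability per test trial (inputs already standardized)."""
    y_train = np.asarray(y_train, dtype=int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("single-class training data")
    model = make_model(spec)
    model.fit(X_train, y_train)
    proba = model.predict_proba(X_test)
    pos_col = int(np.flatnonzero(model.classes_ == 1)[0])
    return proba[:, pos_col]


def aggregate_subject(trial_probs: np.ndarray) -> float:
    """Arithmetic mean of one subject's trial probabilities."""
    trial_probs = np.asarray(trial_probs, dtype=float)
    if trial_probs.size == 0:
        raise ValueError("no trial probabilities to aggregate")
    return float(np.mean(trial_probs))


@dataclass
class FoldResult:
    """Per-fold prediction with provenance for leakage auditing."""

    test_subject: str
    train_subjects: tuple[str, ...]
    trial_probs: np.ndarray
    subject_prob: float
    selected_features: tuple[str, ...]
    standardization_source: tuple[str, ...]  # subjects the z-params came from

    def assert_no_leakage(self) -> None:
        if self.test_subject in self.train_subjects:
            raise AssertionError(f"test subject {self.test_subject} in training fold")
        if self.test_subject in self.standardization_source:
            raise AssertionError(
                f"standardization used test subject {self.test_subject}"
            )


def loso_predict(
    features: pd.DataFrame,
    feature_cols: list[str],
    spec: ModelSpec,
    sffs_candidates: list[str] | None = None,
    sffs_base_spec: ModelSpec | None = None,
) -> tuple[pd.DataFrame, list[FoldResult]]:
    """Run LOSO-CV and return per-subject aggregated probabilities.

    When ``sffs_candidates`` is given, SFFS is re-run inside every fold on
    training subjects only (the nested, leakage-safe mode) and the selected
    subset is recorded per fold.  Returns a subject-level frame
    (subject_id, label, y, prob) and the per-fold provenance records.
    """
    folds = loso_splits(features)
    records = []
    fold_results: list[FoldResult] = []
    for train_subjects, test_subject in folds:
        train = features[features["subject_id"].isin(train_subjects)]
        test = features[features["subject_id"] == test_subject]
        cols = feature_cols
        if sffs_candidates is not None:
            cols = sffs(train, sffs_candidates, sffs_base_spec or MODEL_SPECS[BASELINE_MODEL])
        params = standardize_fit(train[cols].to_numpy())
        Xtr = standardize_apply(params, train[cols].to_numpy())
        Xte = standardize_apply(params, test[cols].to_numpy())
        ytr = (train["label"] == POSITIVE_LABEL).to_numpy(dtype=int)
        probs = train_predict(spec, Xtr, ytr, Xte)
        fr = FoldResult(
            test_subject=test_subject,
            train_subjects=tuple(train_subjects),
            trial_probs=probs,
            subject_prob=aggregate_subject(probs),
            selected_features=tuple(cols),
            standardization_source=tuple(train_subjects),
        )
        fr.assert_no_leakage()
        fold_results.append(fr)
        records.append(
            {
                "subject_id": test_subject,
                "label": test["label"].iloc[0],
                "y": int(test["label"].iloc[0] == POSITIVE_LABEL),
                "prob": fr.subject_prob,
            }
        )
    return pd.DataFrame(records), fold_results


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def subject_auc(y: np.ndarray, probs: np.ndarray) -> float:
    """Mann-Whitney AUC: fraction of (positive, negative) pairs correctly
    ordered, ties counted one half."""
    y = np.asarray(y, dtype=int)
    probs = np.asarray(probs, dtype=float)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = sps.rankdata(probs)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def youden_threshold(y: np.ndarray, probs: np.ndarray) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) maximizing J = sens + spec - 1.

    Candidates are midpoints of consecutive sorted unique probabilities
    (``p >= threshold`` classifies positive); ties take the lowest
    threshold, favouring sensitivity.
    """
    y = np.asarray(y, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("Youden threshold needs both classes")
    uniq = np.unique(probs)
    cands = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else uniq
    best = None
    for thr in cands:  # ascending, so first argmax is the lowest threshold
        pred = probs >= thr
        sens = float((pred & (y == 1)).sum() / (y == 1).sum())
        spec = float((~pred & (y == 0)).sum() / (y == 0).sum())
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-15:
            best = (j, float(thr), sens, spec)
    _, thr, sens, spec = best
    return thr, sens, spec


def brier(y: np.ndarray, probs: np.ndarray) -> float:
    """Mean squared error of the probabilities against the 0/1 outcomes."""
    y = np.asarray(y, dtype=float)
    probs = np.asarray(probs, dtype=float)
    return float(np.mean((probs - y) ** 2))


def calibration_bins(y: np.ndarray, probs: np.ndarray, n_bins: int = 3) -> pd.DataFrame:
    """Quantile-binned calibration table (rank-based equal-count bins).

    Subjects are sorted by predicted probability and split into ``n_bins``
    near-equal groups (32 subjects -> 11/11/10), giving per bin the count,
    mean predicted probability and observed risk fraction.  Equal-count
    binning keeps each bin populated despite the small cohort.
    """
    y = np.asarray(y, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if len(y) < n_bins:
        raise ValueError("fewer subjects than calibration bins")
    order = np.argsort(probs, kind="stable")
    rows = []
    for i, idx in enumerate(np.array_split(order, n_bins)):
        rows.append(
            {
                "bin": i + 1,
                "count": len(idx),
                "mean_predicted": float(probs[idx].mean()),
                "observed_fraction": float(y[idx].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# bootstrap inference
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSummary:
    """Subject-resampled AUC summary with per-replicate Youden operating points."""

    auc_mean: float
    auc_sd: float
    ci_low: float
    ci_high: float
    sens_mean: float
    spec_mean: float
    n_valid: int
    point_auc: float


def _resample_both_classes(
    y: np.ndarray, rng: np.random.Generator, max_attempts: int = 100
) -> np.ndarray | None:
    n = len(y)
    for _ in range(max_attempts):
        idx = rng.integers(0, n, size=n)
        if 0 < y[idx].sum() < n:
            return idx
    return None


def bootstrap_auc(
    y: np.ndarray, probs: np.ndarray, B: int = 1000, seed: int = 0
) -> BootstrapSummary:
    """Bootstrap over subjects: AUC mean/SD/95% percentile CI plus the mean
    sensitivity and specificity at each replicate's own Youden threshold.

    Single-class replicates are redrawn (up to 100 attempts) rather than
    silently scored; if fewer than half of the replicates are valid the
    cohort is too degenerate and an error is raised.
    """
    y = np.asarray(y, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    aucs, senss, specs = [], [], []
    for _ in range(B):
        idx = _resample_both_classes(y, rng)
        if idx is None:
            logger.debug("bootstrap replicate skipped: single class after redraws")
            continue
        yb, pb = y[idx], probs[idx]
        aucs.append(subject_auc(yb, pb))
        _, sens, spec = youden_threshold(yb, pb)
        senss.append(sens)
        specs.append(spec)
    if len(aucs) < 0.5 * B:
        raise ValueError(f"too few valid bootstrap replicates: {len(aucs)}/{B}")
    aucs = np.asarray(aucs)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return BootstrapSummary(
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        ci_low=float(lo),
        ci_high=float(hi),
        sens_mean=float(np.mean(senss)),
        spec_mean=float(np.mean(specs)),
        n_valid=len(aucs),
        point_auc=subject_auc(y, probs),
    )


def bootstrap_auc_diff_test(
    y: np.ndarray,
    probs_model: np.ndarray,
    probs_baseline: np.ndarray,
    B: int = 1000,
    seed: int = 0,
) -> float:
    """Two-sided paired bootstrap test of AUC_model - AUC_baseline.

    Subjects are resampled jointly for both models; the p-value is the
    sign-fraction form ``2*min(P(d<=0), P(d>=0))`` clipped to [1/B, 1].
    A model tested against itself gives all-zero differences and p = 1.
    """
    y = np.asarray(y, dtype=int)
    pm = np.asarray(probs_model, dtype=float)
    pb = np.asarray(probs_baseline, dtype=float)
    if not (len(y) == len(pm) == len(pb)):
        raise ValueError("probability vectors must cover the same subjects")
    rng = np.random.default_rng(seed)
    deltas = []
    for _ in range(B):
        idx = _resample_both_classes(y, rng)
        if idx is None:
            continue
        deltas.append(subject_auc(y[idx], pm[idx]) - subject_auc(y[idx], pb[idx]))
    if len(deltas) < 0.5 * B:
        raise ValueError(f"too few valid bootstrap replicates: {len(deltas)}/{B}")
    deltas = np.asarray(deltas)
    p = 2.0 * min(np.mean(deltas <= 0), np.mean(deltas >= 0))
    return float(np.clip(p, 1.0 / B, 1.0))


# ---------------------------------------------------------------------------
# SFFS
# ---------------------------------------------------------------------------

def inner_loso_objective(
    features: pd.DataFrame, cols: list[str], spec: ModelSpec
) -> float:
    """Subject-level AUC of ``spec`` under LOSO over the given subjects."""
    subj, _ = loso_predict(features, cols, spec)
    return subject_auc(subj["y"].to_numpy(), subj["prob"].to_numpy())


def sffs(
    features: pd.DataFrame,
    candidates: list[str],
    base_spec: ModelSpec,
    eps: float = 1e-4,
    max_features: int = 10,
) -> list[str]:
    """Sequential forward floating selection with an inner-LOSO AUC objective.

    Forward steps add the feature with the largest objective gain; after
    each addition, floating steps remove any feature (except the one just
    added) whose removal strictly improves on the best objective previously
    seen at the smaller size.  Selection stops when the best forward gain is
    below ``eps`` or the subset reaches ``max_features``.  Ties break
    deterministically in feature-name order.
    """
    candidates = sorted(dict.fromkeys(candidates))
    if len(candidates) < 2:
        raise ValueError("SFFS needs at least 2 candidate features")
    selected: list[str] = []
    best_by_size: dict[int, float] = {0: -np.inf}
    current = -np.inf
    while len(selected) < max_features:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        best_feat, best_obj = None, -np.inf
        for f in remaining:  # name order => deterministic tie-break
            obj = inner_loso_objective(features, selected + [f], base_spec)
            if obj > best_obj + 1e-15:
                best_feat, best_obj = f, obj
        gain = best_obj - (current if np.isfinite(current) else 0.0)
        if selected and gain < eps:
            break
        selected.append(best_feat)
        current = best_obj
        best_by_size[len(selected)] = max(
            best_by_size.get(len(selected), -np.inf), current
        )
        # floating: conditional exclusion of earlier picks
        while len(selected) > 2:
            best_drop, best_drop_obj = None, -np.inf
            for f in selected[:-1]:
                obj = inner_loso_objective(
                    features, [c for c in selected if c != f], base_spec
                )
                if obj > best_drop_obj + 1e-15:
                    best_drop, best_drop_obj = f, obj
            k = len(selected) - 1
            if best_drop_obj > best_by_size.get(k, -np.inf) + eps:
                selected.remove(best_drop)
                current = best_drop_obj
                best_by_size[k] = best_drop_obj
            else:
                break
    return selected


def select_features(
    features: pd.DataFrame,
    candidates: list[str],
    base_spec: ModelSpec | None = None,
    mode: str = "nested",
    eps: float = 1e-4,
    max_features: int = 10,
) -> dict[str, object]:
    """Run SFFS in ``nested`` or ``descriptive`` mode.

    ``nested``: SFFS inside every outer LOSO fold (training subjects only);
    the reported subset is the modal subset across folds (ties resolved
    toward the lexicographically smallest sorted tuple).  ``descriptive``:
    one SFFS pass over all subjects, reported as-is and labelled descriptive
    because it is not leakage-guarded.
    """
    base_spec = base_spec or MODEL_SPECS[BASELINE_MODEL]
    if mode == "descriptive":
        subset = sffs(features, candidates, base_spec, eps=eps, max_features=max_features)
        return {"mode": mode, "subset": subset, "per_fold": None}
    if mode != "nested":
        raise ValueError(f"unknown SFFS mode {mode!r}")
    per_fold: dict[str, list[str]] = {}
    for train_subjects, test_subject in loso_splits(features):
        train = features[features["subject_id"].isin(train_subjects)]
        per_fold[test_subject] = sffs(
            train, candidates, base_spec, eps=eps, max_features=max_features
        )
    counts = Counter(tuple(sorted(s)) for s in per_fold.values())
    max_count = counts.most_common(1)[0][1]
    modal = min(k for k, v in counts.items() if v == max_count)
    return {"mode": mode, "subset": list(modal), "per_fold": per_fold}


# ---------------------------------------------------------------------------
# condition screening and model comparison
# ---------------------------------------------------------------------------

def screen_conditions(
    features: pd.DataFrame,
    base_spec: ModelSpec | None = None,
    B: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-condition (plus pooled "all") full-feature baseline screen.

    For each standing condition, and for all conditions pooled as extra
    trials per subject, runs full-feature LOSO with the baseline model,
    aggregates to subject level and bootstraps the AUC.  Rows are sorted by
    mean AUC, best first.
    """
    base_spec = base_spec or MODEL_SPECS[BASELINE_MODEL]
    feature_cols = [c for c in features.columns if c not in META_COLS]
    rows = []
    conditions = list(dict.fromkeys(features["condition"])) + ["all"]
    for cond in conditions:
        sub = features if cond == "all" else features[features["condition"] == cond]
        subj, _ = loso_predict(sub, feature_cols, base_spec)
        bs = bootstrap_auc(subj["y"].to_numpy(), subj["prob"].to_numpy(), B=B, seed=seed)
        rows.append(
            {
                "condition": cond,
                "auc_mean": bs.auc_mean,
                "auc_sd": bs.auc_sd,
                "ci_low": bs.ci_low,
                "ci_high": bs.ci_high,
                "point_auc": bs.point_auc,
            }
        )
    return (
        pd.DataFrame(rows).sort_values("auc_mean", ascending=False).reset_index(drop=True)
    )


@dataclass
class EvalResult:
    """One model's full subject-level evaluation."""

    model_id: str
    subjects: pd.DataFrame  # subject_id, label, y, prob
    trial_probs: pd.DataFrame  # subject_id, label, trial columns
    bootstrap: BootstrapSummary
    youden: float
    sensitivity: float
    specificity: float
    brier_score: float
    calibration: pd.DataFrame
    auc_diff_p: float | None  # vs baseline; None for the baseline itself
    folds: list[FoldResult] = field(repr=False, default_factory=list)


def _trial_prob_frame(features: pd.DataFrame, folds: list[FoldResult]) -> pd.DataFrame:
    rows = []
    for fr in folds:
        test = features[features["subject_id"] == fr.test_subject]
        row = {"subject_id": fr.test_subject, "label": test["label"].iloc[0]}
        for i, p in enumerate(fr.trial_probs, start=1):
            row[f"trial_{i}"] = float(p)
        rows.append(row)
    return pd.DataFrame(rows)


def evaluate_models(
    features: pd.DataFrame,
    condition: str | None,
    feature_subset: list[str],
    specs: dict[str, ModelSpec] | None = None,
    B: int = 1000,
    seed: int = 0,
) -> dict[str, EvalResult]:
    """Evaluate the five configured models on one condition's trials.

    ``condition=None`` uses the frame as-is (e.g. the pooled "all" set).
    Each model gets LOSO trial probabilities, subject aggregation, the
    Youden operating point, bootstrap summaries, calibration, Brier score
    and — for non-baseline models — the paired AUC-difference p-value
    against the baseline.
    """
    if not feature_subset:
        raise ValueError("feature_subset must be non-empty")
    specs = specs or MODEL_SPECS
    if BASELINE_MODEL not in specs:
        raise ValueError(f"specs must include the baseline {BASELINE_MODEL}")
    df = features if condition is None else features[features["condition"] == condition]
    if df.empty:
        raise ValueError(f"no trials for condition {condition!r}")

    results: dict[str, EvalResult] = {}
    per_model_probs: dict[str, tuple[pd.DataFrame, list[FoldResult]]] = {}
    for model_id, spec in specs.items():
        per_model_probs[model_id] = loso_predict(df, feature_subset, spec)

    base_subj = per_model_probs[BASELINE_MODEL][0]
    y = base_subj["y"].to_numpy()
    base_probs = base_subj["prob"].to_numpy()

    for model_id, (subj, folds) in per_model_probs.items():
        probs = subj["prob"].to_numpy()
        bs = bootstrap_auc(y, probs, B=B, seed=seed)
        thr, sens, spec_ = youden_threshold(y, probs)
        diff_p = (
            None
            if model_id == BASELINE_MODEL
            else bootstrap_auc_diff_test(y, probs, base_probs, B=B, seed=seed)
        )
        results[model_id] = EvalResult(
            model_id=model_id,
            subjects=subj,
            trial_probs=_trial_prob_frame(df, folds),
            bootstrap=bs,
            youden=thr,
            sensitivity=sens,
            specificity=spec_,
            brier_score=brier(y, probs),
            calibration=calibration_bins(y, probs),
            auc_diff_p=diff_p,
            folds=folds,
        )
    return results


def heatmap_matrix(result: EvalResult) -> pd.DataFrame:
    """Subject x trial probability matrix with a FINAL (mean) column.

    Rows are grouped with the fall-risk subjects first (each group in
    subject order), mirroring the usual presentation of subject-level risk
    heatmaps; FINAL is the arithmetic mean of the trial columns.
    """
    df = result.trial_probs.copy()
    trial_cols = [c for c in df.columns if c.startswith("trial_")]
    df["FINAL"] = df[trial_cols].mean(axis=1)
    df["_order"] = (df["label"] != POSITIVE_LABEL).astype(int)
    df = df.sort_values(["_order", "subject_id"]).drop(columns="_order")
    return df.reset_index(drop=True)
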