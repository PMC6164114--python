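"""Repeated double cross-validation with LDA and SVM learners.

The design has two nested loops.  The inner loop randomly splits the
calibration cohort into a training set (80%) for model derivation and an
internal-validation set (20%).  The outer loop scores a fixed, untouched
external-validation cohort with the model fitted on the calibration
training set.  Preprocessing (vector normalization, then autoscaling) is
fitted on the training subjects only and applied unchanged to both
validation sets, so no held-out information leaks into the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import pairwise_distances
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .diagnostics import ConfusionMatrix, DiagnosticReport, compute_metrics, roc_auc
from .errors import ConfigurationError, DataError, LeakageError
from .scaling import AutoscalerState, apply_autoscaler, fit_autoscaler, normalize_samples

__all__ = [
    "SplitPlan",
    "TrainedModel",
    "ValidationResult",
    "make_split",
    "train_classifier",
    "double_cross_validate",
    "pca_projection",
    "PCAProjection",
]

logger = logging.getLogger(__name__)

SVM_COST_GRID = (0.1, 1.0, 10.0, 100.0)
SVM_WIDTH_FACTORS = (0.5, 1.0, 2.0)


@dataclass
class SplitPlan:
    """Seeded assignment of calibration subjects to training / internal sets."""

    calibration_ids: list[str]
    training_ids: list[str]
    internal_validation_ids: list[str]
    external_ids: list[str]
    seed: int
    repeat_index: int = 0


@dataclass
class TrainedModel:
    """A fitted learner plus the preprocessing state it was trained under.

    Scores are oriented so that higher = more case-like.
    """

    learner: str  # "lda" | "svm"
    estimator: object
    scaler: AutoscalerState | None = None
    normalize: bool = True
    best_params: dict = field(default_factory=dict)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.decision_function(X), dtype=float)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_scores(X) > 0).astype(int)


@dataclass
class ValidationResult:
    """One repeat of the double cross-validation."""

    split: SplitPlan
    learner: str
    internal_scores: np.ndarray
    internal_labels: np.ndarray
    internal_predictions: np.ndarray
    external_scores: np.ndarray
    external_labels: np.ndarray
    external_predictions: np.ndarray
    internal_report: DiagnosticReport
    external_report: DiagnosticReport
    scaler_digest: str = ""


def make_split(
    subject_ids,
    labels,
    frac: float = 0.8,
    seed: int = 0,
    stratified: bool = False,
    external_ids=None,
    repeat_index: int = 0,
) -> SplitPlan:
    """Randomly split calibration subjects into training (frac) and internal sets.

    Unstratified by default; stratified mode preserves the class ratio within
    one subject.  If either class is absent from the training set, the split
    is rejected and deterministically reseeded with seed+1.
    """
    ids = [str(s) for s in subject_ids]
    y = np.asarray(labels).astype(int)
    if len(ids) != y.size:
        raise DataError("subject_ids and labels length mismatch")
    if len(ids) < 10:
        raise DataError("need at least 10 calibration subjects")
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present in the calibration set")
    if not 0 < frac < 1:
        raise ConfigurationError("frac must be in (0, 1)")

    current_seed = seed
    while True:
        rng = np.random.default_rng(current_seed)
        if stratified:
            train_idx: list[int] = []
            for cls in np.unique(y):
                cls_idx = np.where(y == cls)[0]
                perm = rng.permutation(cls_idx)
                n_train = int(round(frac * cls_idx.size))
                train_idx.extend(perm[:n_train].tolist())
            train_set = set(train_idx)
        else:
            perm = rng.permutation(len(ids))
            n_train = int(round(frac * len(ids)))
            train_set = set(perm[:n_train].tolist())
        train_mask = np.array([i in train_set for i in range(len(ids))])
        if len(np.unique(y[train_mask])) == 2:
            break
        logger.warning(
            "split seed %d left a class out of training; reseeding with %d",
            current_seed,
            current_seed + 1,
        )
        current_seed += 1

    return SplitPlan(
        calibration_ids=ids,
        training_ids=[s for s, m in zip(ids, train_mask) if m],
        internal_validation_ids=[s for s, m in zip(ids, train_mask) if not m],
        external_ids=[str(s) for s in external_ids] if external_ids is not None else [],
        seed=current_seed,
        repeat_index=repeat_index,
    )


def _median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF width from the median pairwise Euclidean distance: 1/(2 d_med^2)."""
    d = pairwise_distances(X)
    med = float(np.median(d[np.triu_indices_from(d, k=1)]))
    if med <= 0:
        med = 1.0
    return 1.0 / (2.0 * med**2)


def train_classifier(
    X_train: np.ndarray,
    y_train: np.ndarray,
    learner: str = "lda",
    inner_folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Fit LDA or an RBF SVM on (already preprocessed) training data.

    LDA switches to Ledoit-Wolf shrinkage of the pooled covariance when the
    training set is small relative to the 32 features (n < 2p), which keeps
    the discriminant well-posed.  The SVM's cost and kernel width are chosen
    by inner stratified cross-validation maximizing accuracy, over costs
    {0.1, 1, 10, 100} and the median-heuristic width scaled by {0.5, 1, 2}.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train).astype(int)
    if len(np.unique(y)) < 2:
        raise DataError("training labels must contain both classes")
    learner = learner.lower()
    if learner == "lda":
        n, p = X.shape
        if n < 2 * p:
            est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        else:
            est = LinearDiscriminantAnalysis(solver="svd")
        est.fit(X, y)
        return TrainedModel(learner="lda", estimator=est)
    if learner == "svm":
        gamma0 = _median_heuristic_gamma(X)
        grid = {
            "C": list(SVM_COST_GRID),
            "gamma": [f * gamma0 for f in SVM_WIDTH_FACTORS],
        }
        min_class = int(np.bincount(y).min())
        folds = max(2, min(inner_folds, min_class))
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed % 2**31)
        search = GridSearchCV(SVC(kernel="rbf"), grid, scoring="accuracy", cv=cv)
        search.fit(X, y)
        return TrainedModel(
            learner="svm", estimator=search.best_estimator_, best_params=search.best_params_
        )
    raise ConfigurationError(f"unknown learner {learner!r}; use 'lda' or 'svm'")


def _preprocess(X: np.ndarray, normalize: bool) -> np.ndarray:
    return normalize_samples(X) if normalize else np.asarray(X, dtype=float)


def _report(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray) -> DiagnosticReport:
    cm = ConfusionMatrix(
        tp=int(np.sum((y_pred == 1) & (y_true == 1))),
        fp=int(np.sum((y_pred == 1) & (y_true == 0))),
        tn=int(np.sum((y_pred == 0) & (y_true == 0))),
        fn=int(np.sum((y_pred == 0) & (y_true == 1))),
    )
    rep = compute_metrics(cm)
    rep.auc, lo, hi = roc_auc(scores, y_true)
    rep.auc_ci = (lo, hi)
    return rep


def double_cross_validate(
    X_cal: np.ndarray,
    y_cal,
    ids_cal,
    X_ext: np.ndarray,
    y_ext,
    ids_ext,
    learner: str = "lda",
    n_repeats: int = 1,
    seed: int = 0,
    frac: float = 0.8,
    stratified: bool = False,
    normalize: bool = True,
    paper_faithful_scaling: bool = False,
    inner_folds: int = 5,
) -> list[ValidationResult]:
    """Run the nested validation design for ``n_repeats`` seeded splits.

    Per repeat: split the calibration cohort 80/20, fit the scaler and the
    learner on the training portion only, then score the internal set and the
    untouched external set and compute full diagnostic reports for both.
    With ``paper_faithful_scaling`` the autoscaler is instead fitted on all
    subjects jointly (calibration and external), reproducing whole-database
    scaling at the cost of leakage.
    """
    ids_cal = [str(s) for s in ids_cal]
    ids_ext = [str(s) for s in ids_ext]
    overlap = set(ids_cal) & set(ids_ext)
    if overlap:
        raise LeakageError(
            f"calibration and external sets overlap: {sorted(overlap)[:5]}"
        )
    X_cal = np.asarray(X_cal, dtype=float)
    X_ext = np.asarray(X_ext, dtype=float)
    y_cal = np.asarray(y_cal).astype(int)
    y_ext = np.asarray(y_ext).astype(int)

    Xn_cal = _preprocess(X_cal, normalize)
    Xn_ext = _preprocess(X_ext, normalize)

    results: list[ValidationResult] = []
    for r in range(n_repeats):
        split = make_split(
            ids_cal,
            y_cal,
            frac=frac,
            seed=seed + r,
            stratified=stratified,
            external_ids=ids_ext,
            repeat_index=r,
        )
        tr_mask = np.isin(ids_cal, split.training_ids)
        iv_mask = ~tr_mask
        if paper_faithful_scaling:
            scaler = fit_autoscaler(np.vstack([Xn_cal, Xn_ext]))
        else:
            scaler = fit_autoscaler(Xn_cal[tr_mask])
        Z_tr = apply_autoscaler(Xn_cal[tr_mask], scaler).values
        Z_iv = apply_autoscaler(Xn_cal[iv_mask], scaler).values
        Z_ex = apply_autoscaler(Xn_ext, scaler).values

        model = train_classifier(
            Z_tr, y_cal[tr_mask], learner=learner, inner_folds=inner_folds, seed=seed + r
        )
        model.scaler = scaler
        model.normalize = normalize

        s_iv = model.decision_scores(Z_iv)
        s_ex = model.decision_scores(Z_ex)
        p_iv = (s_iv > 0).astype(int)
        p_ex = (s_ex > 0).astype(int)
        results.append(
            ValidationResult(
                split=split,
                learner=model.learner,
                internal_scores=s_iv,
                internal_labels=y_cal[iv_mask],
                internal_predictions=p_iv,
                external_scores=s_ex,
                external_labels=y_ext,
                external_predictions=p_ex,
                internal_report=_report(y_cal[iv_mask], p_iv, s_iv),
                external_report=_report(y_ext, p_ex, s_ex),
                scaler_digest=scaler.digest(),
            )
        )
    return results


@dataclass
class PCAProjection:
    """Centered-SVD principal component scores with fixed component signs."""

    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray


def pca_projection(X: np.ndarray, n_components: int = 2) -> PCAProjection:
    """Project autoscaled data onto its leading principal components.

    Component signs follow the largest-loading-positive convention so the
    projection is reproducible across SVD implementations.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-12)) if S.size else 0
    if n_components > rank:
        raise DataError(f"n_components={n_components} exceeds rank {rank}")
    for i in range(n_components):
        j = int(np.argmax(np.abs(Vt[i])))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
            U[:, i] = -U[:, i]
    scores = U[:, :n_components] * S[:n_components]
    var = S**2
    return PCAProjection(
        scores=scores,
        loadings=Vt[:n_components].T,
        explained_variance_ratio=var[:n_components] / var.sum(),
    )
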