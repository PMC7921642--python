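"""Multinomial stage classifier with standardized-coefficient reduction.

The signature-discovery procedure:

1. z-score each gene across samples, fit a softmax multinomial logistic
   regression of the 8 ordered stages with L2 regularization (p >> n, so
   regularization is essential);
2. standardize the fitted coefficients jointly over all class x gene entries
   (intercepts excluded) to zero mean / unit SD, and keep genes whose
   standardized coefficient magnitude exceeds a threshold (default 0.78 SD,
   strict inequality, max over classes per gene);
3. repeat train-and-select once on the surviving genes (two rounds total).

Evaluation follows the train-equals-test protocol of the source study (no
cross-validation by default): the confusion matrix, accuracy, and the
macro-averaged per-class Jaccard index TP / (TP + FP + FN).  The "Jaccard
index" of the study is reported both ways since its prose definition (the
proportion of correctly categorized cases) is accuracy while its reported
value tracks the macro-Jaccard.

A permutation-style control trains the same protocol on ``n_sets`` random
gene sets of the signature's size and compares the observed score against
that null distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import jaccard_score as _sk_jaccard

from .errors import DegenerateDataError, PipelineError, ValidationError

__all__ = [
    "CoefficientMatrix",
    "ClassificationReport",
    "NullDistribution",
    "ReductionResult",
    "train_classifier",
    "standardize_coefficients",
    "select_features",
    "two_round_reduction",
    "evaluate",
    "random_signature_null",
    "null_calibration",
]

SELECT_ALL = float("-inf")  # sentinel threshold: select every feature


@dataclass
class CoefficientMatrix:
    """Fitted multinomial coefficients and their joint z-scores."""

    beta: np.ndarray  # classes x features
    z: np.ndarray  # classes x features, standardized jointly
    class_labels: list
    feature_ids: list
    model: LogisticRegression
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Xs = (np.asarray(X, float) - self.feature_mean) / self.feature_sd
        return self.model.predict(Xs)

    def max_abs_z(self) -> np.ndarray:
        """Per-feature max over classes of |z|."""
        return np.abs(self.z).max(axis=0)


@dataclass
class ClassificationReport:
    confusion: pd.DataFrame  # rows = true class, columns = predicted class
    accuracy: float
    per_class_jaccard: pd.Series
    macro_jaccard: float


@dataclass
class NullDistribution:
    jaccard_values: np.ndarray
    observed: float
    empirical_p: float
    seed: int


@dataclass
class ReductionResult:
    round1: list
    round2: list
    model1: CoefficientMatrix
    model2: CoefficientMatrix


def _as_matrix(X, feature_ids=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if feature_ids is None:
        feature_ids = list(range(X.shape[1]))
    return X, list(feature_ids)


def train_classifier(
    X,
    y,
    l2_strength: float = 0.7,
    seed: int = 0,
    feature_ids=None,
    standardize: bool = True,
    max_iter: int = 5000,
) -> CoefficientMatrix:
    """Fit the softmax multinomial stage classifier.

    ``X`` is samples x features (DataFrame columns become feature ids);
    features are z-scored per gene before fitting unless ``standardize`` is
    off, which is what makes the coefficient magnitudes comparable for the
    threshold rule.  Deterministic: the lbfgs solve depends only on the
    inputs, so identical inputs reproduce coefficients to solver tolerance.
    """
    Xm, feats = _as_matrix(X, feature_ids)
    y = np.asarray(y)
    if Xm.shape[0] != y.shape[0]:
        raise ValidationError("X and y have different sample counts")
    if not np.isfinite(Xm).all():
        raise ValidationError("X contains non-finite values")
    labels, counts = np.unique(y, return_counts=True)
    if labels.size < 2:
        raise DegenerateDataError("training needs >= 2 classes")
    small = labels[counts < 2]
    if small.size:
        raise DegenerateDataError(f"classes with < 2 samples: {list(small)}")
    if l2_strength <= 0:
        raise ValidationError("l2_strength must be > 0")

    if standardize:
        mean = Xm.mean(axis=0)
        sd = Xm.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant gene carries no signal either way
    else:
        mean = np.zeros(Xm.shape[1])
        sd = np.ones(Xm.shape[1])
    Xs = (Xm - mean) / sd

    model = LogisticRegression(
        C=1.0 / l2_strength,
        solver="lbfgs",
        max_iter=max_iter,
        tol=1e-8,
        random_state=seed,
    )
    model.fit(Xs, y)
    beta = np.asarray(model.coef_, dtype=float)
    try:
        z = standardize_coefficients(beta)
    except DegenerateDataError:
        # a 1x1 or all-equal coefficient matrix carries no ranking information
        z = np.zeros_like(beta)
    return CoefficientMatrix(
        beta=beta,
        z=z,
        class_labels=list(model.classes_),
        feature_ids=feats,
        model=model,
        feature_mean=mean,
        feature_sd=sd,
    )


def standardize_coefficients(beta: np.ndarray) -> np.ndarray:
    """z-score coefficients jointly over all class x feature entries.

    Population SD (ddof = 0); intercepts are not part of ``beta``.  All-equal
    coefficients are degenerate (nothing to rank).
    """
    beta = np.asarray(beta, dtype=float)
    mean = beta.mean()
    sd = beta.std(ddof=0)
    if sd == 0:
        raise DegenerateDataError("all coefficients equal; cannot standardize")
    return (beta - mean) / sd


def select_features(z: np.ndarray, threshold: float = 0.78) -> tuple[np.ndarray, np.ndarray]:
    """Keep features whose max-over-classes |z| strictly exceeds ``threshold``.

    Returns (boolean mask over features, per-feature max |z|).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    score = np.abs(z).max(axis=0)
    return score > threshold, score


def two_round_reduction(
    X,
    y,
    threshold: float = 0.78,
    l2_strength: float = 0.7,
    seed: int = 0,
    feature_ids=None,
) -> ReductionResult:
    """Train -> threshold standardized coefficients -> retrain -> threshold.

    Round 1 selects S1 from all features; round 2 refits on S1 and selects
    S2 ⊆ S1.  ``threshold = SELECT_ALL`` keeps everything in both rounds.
    """
    Xm, feats = _as_matrix(X, feature_ids)
    model1 = train_classifier(Xm, y, l2_strength, seed, feature_ids=feats)
    mask1, _ = select_features(model1.z, threshold)
    s1 = [f for f, keep in zip(feats, mask1) if keep]
    if not s1:
        raise PipelineError(
            "round-1 selection is empty; lower the threshold (default 0.78 SD)"
        )
    model2 = train_classifier(Xm[:, mask1], y, l2_strength, seed, feature_ids=s1)
    mask2, _ = select_features(model2.z, threshold)
    s2 = [f for f, keep in zip(s1, mask2) if keep]
    return ReductionResult(round1=s1, round2=s2, model1=model1, model2=model2)


def evaluate(y_true, y_pred, class_labels=None) -> ClassificationReport:
    """Confusion matrix (rows true, columns predicted), accuracy, Jaccard.

    The per-class Jaccard index is TP / (TP + FP + FN); ``macro_jaccard`` is
    its unweighted mean over classes present in ``y_true`` or ``y_pred``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred have different lengths")
    seen = set(np.unique(y_true)) | set(np.unique(y_pred))
    if class_labels is None:
        class_labels = sorted(seen)
    elif not seen <= set(class_labels):
        raise ValidationError(f"unknown labels: {sorted(seen - set(class_labels))}")
    labels = list(class_labels)
    conf = _sk_confusion(y_true, y_pred, labels=labels)
    confusion = pd.DataFrame(conf, index=pd.Index(labels, name="true"),
                             columns=pd.Index(labels, name="predicted"))
    accuracy = float(np.trace(conf) / conf.sum()) if conf.sum() else 0.0
    per_class = _sk_jaccard(y_true, y_pred, labels=labels, average=None, zero_division=0)
    per_class = pd.Series(per_class, index=labels, name="jaccard")
    return ClassificationReport(
        confusion=confusion,
        accuracy=accuracy,
        per_class_jaccard=per_class,
        macro_jaccard=float(per_class.mean()),
    )


def _fit_and_score(Xm, y, cols, l2_strength, seed) -> float:
    model = train_classifier(Xm[:, cols], y, l2_strength, seed)
    pred = model.predict(Xm[:, cols])
    return evaluate(y, pred).macro_jaccard


def random_signature_null(
    X,
    y,
    observed: float,
    k: int = 15,
    n_sets: int = 500,
    l2_strength: float = 0.7,
    seed: int = 0,
) -> NullDistribution:
    """Macro-Jaccard null from ``n_sets`` random gene sets of size ``k``.

    Each set is a uniform draw without replacement; a classifier is trained
    and scored with the same train-equals-test protocol as the observed
    signature.  ``empirical_p = (1 + #{null >= observed}) / (n_sets + 1)``.
    """
    Xm, _ = _as_matrix(X)
    n_features = Xm.shape[1]
    if k > n_features:
        raise ValidationError(f"k={k} exceeds the {n_features} available features")
    if n_sets < 1:
        raise ValidationError("n_sets must be >= 1")
    rng = np.random.default_rng(seed)
    values = np.empty(n_sets)
    for i in range(n_sets):
        cols = rng.choice(n_features, size=k, replace=False)
        values[i] = _fit_and_score(Xm, y, cols, l2_strength, seed)
    empirical_p = (1.0 + int((values >= observed).sum())) / (n_sets + 1.0)
    return NullDistribution(
        jaccard_values=values, observed=float(observed), empirical_p=empirical_p, seed=seed
    )


def null_calibration(
    X,
    y,
    signature,
    n_sets: int = 100,
    n_trials: int = 20,
    l2_strength: float = 0.7,
    seed: int = 0,
    feature_ids=None,
) -> float:
    """Coverage check of the random-set null under label permutation.

    For each trial the stage labels are permuted (destroying any signal), the
    *fixed* signature gene set is trained and scored, and a fresh null of
    ``n_sets`` random sets of the same size is built on the permuted labels.
    The signature is never re-selected on the permuted labels — re-selection
    would overfit the permuted noise and say nothing about calibration.
    Returns the fraction of trials in which the signature's score falls
    inside the null's central 95% interval (2.5th-97.5th percentile,
    endpoints included).
    """
    Xm, feats = _as_matrix(X, feature_ids)
    index = {f: i for i, f in enumerate(feats)}
    try:
        cols = np.array([index[g] for g in signature])
    except KeyError as err:
        raise ValidationError(f"signature gene not among features: {err.args[0]}")
    rng = np.random.default_rng(seed)
    inside = 0
    for trial in range(n_trials):
        y_perm = np.asarray(y)[rng.permutation(len(y))]
        obs = _fit_and_score(Xm, y_perm, cols, l2_strength, seed)
        null_seed = int(rng.integers(0, 2**31 - 1))
        null = random_signature_null(
            Xm, y_perm, observed=obs, k=len(cols), n_sets=n_sets,
            l2_strength=l2_strength, seed=null_seed,
        )
        lo, hi = np.percentile(null.jaccard_values, [2.5, 97.5])
        inside += int(lo <= obs <= hi)
    return inside / n_trials
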