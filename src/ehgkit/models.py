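"""Base classifiers, majority-vote ensemble, metrics and classifier comparison.

Simple, clinically interpretable classifiers are used deliberately: k-nearest
neighbours, linear discriminant analysis and logistic regression, combined by
label-level majority voting into an ensemble.  Performance is measured per
holdout partition by accuracy, F1, sensitivity, specificity, PPV, NPV and
AUC (preterm is the positive class throughout), compared across classifiers
with a Friedman test plus Nemenyi post-hoc pairwise decisions, and the
between-partition variability is summarized by the coefficient of variation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler

__all__ = [
    "POSITIVE_LABEL",
    "ClassifierSpec",
    "fit_predict",
    "majority_vote",
    "compute_metrics",
    "ComparisonResult",
    "compare_classifiers",
    "variability_report",
    "METRIC_NAMES",
]

logger = logging.getLogger(__name__)

POSITIVE_LABEL = "preterm"
METRIC_NAMES = ("accuracy", "f1", "sensitivity", "specificity", "ppv", "npv", "auc")


@dataclass(frozen=True)
class ClassifierSpec:
    """One base classifier: kind in {'knn', 'lda', 'lr'}.

    ``knn_k`` must be odd so the KNN vote itself cannot tie; features are
    z-scored on the training rows only before fitting.
    """

    kind: str
    knn_k: int = 5
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("knn", "lda", "lr"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.kind == "knn" and self.knn_k % 2 == 0:
            raise ValueError(f"knn_k must be odd, got {self.knn_k}")

    def build(self):
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        if self.kind == "lda":
            return LinearDiscriminantAnalysis(solver="svd")
        # maximum likelihood with negligible ridge for numerical stability
        return LogisticRegression(C=1e4, max_iter=5000)


def fit_predict(
    spec: ClassifierSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_eval: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on the training rows, return (binary labels, continuous scores)
    for the evaluation rows.

    ``y`` is binary with 1 = preterm.  Scores are the preterm posterior
    (LDA/LR) or the preterm fraction among the k neighbours (KNN); labels
    threshold the score at 0.5.  A singular LDA covariance falls back to a
    shrinkage (ridge-regularized) solver with a warning.
    """
    X_train = np.asarray(X_train, dtype=np.float64)
    X_eval = np.asarray(X_eval, dtype=np.float64)
    if spec.standardize:
        scaler = StandardScaler().fit(X_train)
        X_train = scaler.transform(X_train)
        X_eval = scaler.transform(X_eval)
    clf = spec.build()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X_train, y_train)
    except np.linalg.LinAlgError:
        if spec.kind != "lda":
            raise
        logger.warning("singular LDA covariance: falling back to shrinkage solver")
        clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
        clf.fit(X_train, y_train)
    pos_col = int(np.where(clf.classes_ == 1)[0][0])
    scores = clf.predict_proba(X_eval)[:, pos_col]
    labels = (scores >= 0.5).astype(int)
    return labels, scores


def majority_vote(labels_knn, labels_lda, labels_lr) -> np.ndarray:
    """Per-row label held by at least 2 of the 3 base classifiers."""
    arrs = [np.asarray(a, dtype=int) for a in (labels_knn, labels_lda, labels_lr)]
    n = arrs[0].size
    if any(a.size != n for a in arrs):
        raise ValueError(
            f"base label vectors have mismatched lengths: {[a.size for a in arrs]}"
        )
    return (np.sum(arrs, axis=0) >= 2).astype(int)


def compute_metrics(y_true, y_pred, scores) -> dict[str, float]:
    """Confusion-matrix metrics plus trapezoidal ROC AUC, preterm positive.

    Undefined ratios (e.g. PPV with zero predicted positives) are reported
    as 0.0; a single-class truth vector is an error since sensitivity /
    specificity / AUC would be meaningless.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present in the truth labels")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    return {
        "accuracy": (tp + tn) / y_true.size,
        "f1": ratio(2 * tp, 2 * tp + fp + fn),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": ppv,
        "npv": npv,
        "auc": float(roc_auc_score(y_true, np.asarray(scores, dtype=np.float64))),
    }


@dataclass
class ComparisonResult:
    """Friedman omnibus test plus Nemenyi pairwise significance decisions."""

    friedman_statistic: float
    friedman_p: float
    mean_ranks: pd.Series
    critical_difference: float
    significant: pd.DataFrame  # symmetric boolean matrix

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        pairs = [
            f"{a} vs {b}: {'*' if self.significant.loc[a, b] else 'ns'}"
            for i, a in enumerate(self.significant.index)
            for b in self.significant.index[i + 1:]
        ]
        return (
            f"Friedman chi2={self.friedman_statistic:.3f} "
            f"(p={self.friedman_p:.4g}); CD={self.critical_difference:.3f}; "
            + "; ".join(pairs)
        )


def _nemenyi_critical_difference(k: int, n: int, alpha: float = 0.05) -> float:
    """CD = q_alpha * sqrt(k(k+1)/(12n)), q from the studentized range at
    infinite degrees of freedom (large-df approximation)."""
    q = stats.studentized_range.ppf(1.0 - alpha, k, 1e6) / np.sqrt(2.0)
    return float(q * np.sqrt(k * (k + 1) / (12.0 * n)))


def compare_classifiers(f1_by_classifier: pd.DataFrame, alpha: float = 0.05) -> ComparisonResult:
    """Friedman test on partition-wise ranks of per-classifier scores,
    followed by Nemenyi pairwise decisions at ``alpha``.

    ``f1_by_classifier``: rows = partitions, columns = classifiers.  All
    columns identical everywhere gives p = 1 and no significant pair.
    """
    cols = list(f1_by_classifier.columns)
    k, n = len(cols), len(f1_by_classifier)
    if k < 2 or n < 5:
        raise ValueError(f"need >= 2 classifiers and >= 5 partitions, got {k} x {n}")
    data = f1_by_classifier.to_numpy(dtype=np.float64)
    ranks = np.apply_along_axis(stats.rankdata, 1, data)
    mean_ranks = pd.Series(ranks.mean(axis=0), index=cols)
    if np.allclose(data, data[:, [0]]):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.friedmanchisquare(*[data[:, j] for j in range(k)])
    cd = _nemenyi_critical_difference(k, n, alpha)
    diff = np.abs(mean_ranks.to_numpy()[:, None] - mean_ranks.to_numpy()[None, :])
    sig = pd.DataFrame(diff > cd, index=cols, columns=cols)
    np.fill_diagonal(sig.values, False)
    if p > alpha:  # omnibus not significant: no pairwise claims
        sig.loc[:, :] = False
    return ComparisonResult(
        friedman_statistic=float(stat),
        friedman_p=float(p),
        mean_ranks=mean_ranks,
        critical_difference=cd,
        significant=sig,
    )


def variability_report(metrics_long: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation (SD/mean) per metric and classifier, plus
    min/mean/max CV across the base classifiers.

    ``metrics_long`` columns: 'classifier', 'partition', one column per
    metric.  A zero-mean metric reports CV as NaN (sentinel).
    """
    if metrics_long["partition"].nunique() < 2:
        raise ValueError("need >= 2 partitions for a variability report")
    metric_cols = [c for c in metrics_long.columns
                   if c not in ("classifier", "partition", "split")]
    rows = {}
    for clf, grp in metrics_long.groupby("classifier"):
        means = grp[metric_cols].mean()
        sds = grp[metric_cols].std(ddof=1)
        cv = sds / means.replace(0.0, np.nan)
        rows[clf] = cv
    report = pd.DataFrame(rows).T
    base = report.loc[[c for c in report.index if c != "ensemble"]]
    report.loc["base_min"] = base.min()
    report.loc["base_mean"] = base.mean()
    report.loc["base_max"] = base.max()
    return report
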