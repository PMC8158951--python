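"""ROI summaries and diagnostic statistics.

Covers the evaluation used for tumor/normal/BPH discrimination:

* per-ROI means of the fitted metrics over valid voxels,
* Wilcoxon signed-rank (paired, e.g. PZ tumor vs normal tissue of the
  same patients) and Mann-Whitney U (unpaired, e.g. non-PZ tumor vs
  BPH) two-sided tests, exact for small samples,
* Bonferroni-adjusted significance level,
* voxel-wise ROC with tie-corrected AUC, and transfer of the
  training-set optimal threshold (Youden's J) to the test set,
* Spearman rank correlation between tumor metrics and tumor grade.

The metric polarity is explicit everywhere: signal fractions are
higher in tumor, ADC is lower.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.utils.validation import check_is_fitted

from .fitting import FitMaps

__all__ = [
    "METRIC_COLUMNS",
    "RocResult",
    "DiagnosticSummary",
    "ThresholdClassifier",
    "roi_summary",
    "paired_test",
    "unpaired_test",
    "adjusted_alpha",
    "roc_analysis",
    "threshold_transfer",
    "spearman_grade_correlation",
]

#: fitted map and summary column per model, with its tumor polarity
METRIC_COLUMNS = {
    "two_component": ("sf_slow", "sf_two_component", "higher"),
    "bi_exponential": ("sf_slow", "sf_bi_exponential", "higher"),
    "mono": ("adc", "adc", "lower"),
}


def roi_summary(
    fit_maps: dict[str, FitMaps],
    roi_masks: dict[str, np.ndarray],
    metadata: dict,
) -> pd.DataFrame:
    """One row per ROI: per-model means over valid voxels plus metadata.

    Raises if an ROI has no valid voxel — a silent NaN mean would hide a
    fully-excluded region.
    """
    rows = []
    for roi_name, mask in roi_masks.items():
        mask = np.asarray(mask, dtype=bool)
        row: dict = dict(metadata)
        row["roi"] = roi_name
        n_valid = None
        for model, fm in fit_maps.items():
            map_key, col, _ = METRIC_COLUMNS[model]
            sel = mask & fm.valid
            if not sel.any():
                raise ValueError(
                    f"ROI {roi_name!r} of patient {metadata.get('patient_id')!r} "
                    f"has no valid voxel for model {model!r}"
                )
            row[col] = float(fm[map_key][sel].mean())
            n_valid = int(sel.sum()) if n_valid is None else min(n_valid, int(sel.sum()))
        row["n_valid"] = n_valid
        rows.append(row)
    return pd.DataFrame(rows)


def paired_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped (Wilcoxon's rule); the exact null
    distribution is used for small samples without ties, the normal
    approximation otherwise.  Identical lists leave no nonzero
    difference, which makes the test undefined; that degenerate case is
    reported as p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if np.all(x == y):
        warnings.warn("all paired differences are zero; signed-rank test undefined, p = 1")
        return 1.0
    res = sps.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided", method="auto")
    return float(res.pvalue)


def unpaired_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U p-value (exact for small tie-free samples)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)


def adjusted_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted significance level alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def spearman_grade_correlation(values: np.ndarray, grades: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p-value."""
    res = sps.spearmanr(values, grades)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # on the original metric scale
    auc: float
    polarity: str


@dataclass
class DiagnosticSummary:
    """Table-2-style summary: test AUC, training threshold, test sens/spec (%)."""

    metric: str
    polarity: str
    auc: float
    threshold: float
    sensitivity_pct: float
    specificity_pct: float


def _oriented(values: np.ndarray, polarity: str) -> np.ndarray:
    if polarity == "higher":
        return np.asarray(values, dtype=float)
    if polarity == "lower":
        return -np.asarray(values, dtype=float)
    raise ValueError("polarity must be 'higher' or 'lower'")


def roc_analysis(
    tumor_values: np.ndarray, non_tumor_values: np.ndarray, polarity: str = "higher"
) -> RocResult:
    """Voxel-wise ROC of tumor vs non-tumor values.

    AUC is the rank (Mann-Whitney) statistic with tie correction; the
    curve has a point at every distinct threshold.
    """
    t = np.asarray(tumor_values, dtype=float)
    n = np.asarray(non_tumor_values, dtype=float)
    if len(t) == 0 or len(n) == 0:
        raise ValueError("both voxel groups must be non-empty")
    scores = _oriented(np.concatenate([t, n]), polarity)
    labels = np.concatenate([np.ones(len(t), dtype=int), np.zeros(len(n), dtype=int)])
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    thresholds = thr if polarity == "higher" else -thr
    return RocResult(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc, polarity=polarity)


class ThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-metric tumor classifier with a Youden-optimal threshold.

    ``fit`` picks the threshold maximizing Youden's J
    (sensitivity + specificity - 1) on the training values; ties are
    broken toward the threshold classifying fewer voxels as tumor.
    ``predict`` applies the fixed threshold, so fitting on the training
    split and predicting on the test split is exactly the
    train-to-test threshold transfer.

    Parameters
    ----------
    polarity : {"higher", "lower"}
        Whether tumor voxels have higher or lower metric values; the
        decision rule is ``value >= threshold`` or ``value <= threshold``
        respectively.
    """

    def __init__(self, polarity: str = "higher") -> None:
        self.polarity = polarity

    def fit(self, X: np.ndarray, y: np.ndarray) -> "ThresholdClassifier":
        v = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y).astype(int).reshape(-1)
        if v.shape != y.shape:
            raise ValueError("X and y must have the same length")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary (1 = tumor)")
        if not (y == 1).any() or not (y == 0).any():
            raise ValueError("both classes must be present")
        s = _oriented(v, self.polarity)
        tumor = np.sort(s[y == 1])
        non = np.sort(s[y == 0])
        # oriented rule: s >= theta -> tumor; candidates at observed values
        cand = np.unique(s)
        sens = 1.0 - np.searchsorted(tumor, cand, side="left") / len(tumor)
        spec = np.searchsorted(non, cand, side="left") / len(non)
        j = sens + spec - 1.0
        best = np.flatnonzero(j == j.max())
        theta = cand[best[-1]]  # largest oriented threshold = fewest tumor calls
        self.threshold_ = float(theta if self.polarity == "higher" else -theta)
        self.youden_j_ = float(j.max())
        self.auc_ = float(roc_auc_score(y, s))
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        check_is_fitted(self, "threshold_")
        v = np.asarray(X, dtype=float).reshape(-1)
        if self.polarity == "higher":
            return (v >= self.threshold_).astype(int)
        return (v <= self.threshold_).astype(int)


def threshold_transfer(
    train_tumor: np.ndarray,
    train_non_tumor: np.ndarray,
    test_tumor: np.ndarray,
    test_non_tumor: np.ndarray,
    polarity: str = "higher",
    metric: str = "",
) -> DiagnosticSummary:
    """Train-set threshold applied to the test set.

    AUC is computed on the test voxels; the Youden-optimal threshold is
    determined from the training voxels only and fixed before the test
    sensitivity/specificity are evaluated.
    """
    clf = ThresholdClassifier(polarity=polarity)
    clf.fit(
        np.concatenate([train_tumor, train_non_tumor]),
        np.concatenate([np.ones(len(train_tumor), int), np.zeros(len(train_non_tumor), int)]),
    )
    auc = roc_analysis(test_tumor, test_non_tumor, polarity).auc
    sens = float(clf.predict(test_tumor).mean() * 100.0)
    spec = float((1 - clf.predict(test_non_tumor)).mean() * 100.0)
    return DiagnosticSummary(
        metric=metric,
        polarity=polarity,
        auc=auc,
        threshold=clf.threshold_,
        sensitivity_pct=sens,
        specificity_pct=spec,
    )
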