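"""Performance metrics and descriptive statistics.

Confusion-matrix summaries (sensitivity, specificity, accuracy, balanced
accuracy, PPV, NPV), rank-based AUC, Welch's unequal-variance t-test,
normalized-count group sums and classical (Torgerson) multidimensional
scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .containers import NormalizedMatrix, ValidationError

METRIC_NAMES = ("sensitivity", "specificity", "accuracy", "balanced_accuracy", "ppv", "npv")


def round_half_up(x: float, decimals: int = 3) -> float:
    """Half-up rounding for reporting (0.9355 -> 0.936, unlike banker's)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMetrics:
    """Counts of a binary confusion matrix and the six derived statistics.

    Ratios with a zero denominator are ``None`` (reported as NA), never 0.
    Full precision is kept here; rounding happens only in :meth:`rounded`.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    balanced_accuracy: float | None
    ppv: float | None
    npv: float | None

    def rounded(self, decimals: int = 3) -> dict:
        out: dict = {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn}
        for name in METRIC_NAMES:
            v = getattr(self, name)
            out[name] = None if v is None else round_half_up(v, decimals)
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> ConfusionMetrics:
    """Derive the six performance statistics from confusion-matrix counts."""
    for v in (tp, tn, fp, fn):
        if v < 0 or int(v) != v:
            raise ValidationError("confusion counts must be nonnegative integers")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    bal = None if sens is None or spec is None else (sens + spec) / 2
    return ConfusionMetrics(
        tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn),
        sensitivity=sens,
        specificity=spec,
        accuracy=(tp + tn) / total,
        balanced_accuracy=bal,
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
    )


def auc_score(labels, scores) -> float:
    """Area under the ROC curve; ties contribute 0.5 concordance
    (Mann–Whitney convention). ``labels`` are 0/1 with 1 = positive."""
    return float(roc_auc_score(np.asarray(labels), np.asarray(scores)))


def group_sum(normalized: NormalizedMatrix, probe_subset, sample_id: str) -> float:
    """Sum of a sample's normalized counts over a probe subset."""
    probes = list(probe_subset)
    if not probes:
        warnings.warn("empty probe subset: group sum is 0", stacklevel=2)
        return 0.0
    missing = [p for p in probes if p not in normalized.values.columns]
    if missing:
        raise ValidationError(f"probes missing from normalized matrix: {missing[:5]}")
    return float(normalized.values.loc[sample_id, probes].sum())


def welch_t(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns (t statistic, Welch–Satterthwaite degrees of freedom, two-sided p).
    Degenerate zero-variance inputs are resolved by the sign of the mean
    difference rather than erroring.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("welch_t requires >= 2 values per group")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        warnings.warn("both variances zero with unequal means; p -> 0", stacklevel=2)
        t = np.inf if x.mean() > y.mean() else -np.inf
        return float(t), float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class MDSEmbedding:
    """Classical-scaling coordinates with the eigenvalues that produced them."""

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    metric: str = "euclidean"


def classical_mds(normalized: NormalizedMatrix, probe_subset=None, dims: int = 2) -> MDSEmbedding:
    """Torgerson classical scaling of Euclidean distances on a probe subset.

    Double-centers -D^2/2, takes the top ``dims`` eigenpairs and scales
    eigenvectors by sqrt(eigenvalue). Negative eigenvalues are truncated to 0
    with a warning; missing positive dimensions are zero-padded.
    """
    X = normalized.values if probe_subset is None else normalized.values.loc[:, list(probe_subset)]
    if len(X) < 3:
        raise ValidationError("classical MDS needs >= 3 samples")
    return _classical_mds_points(X.to_numpy(dtype=float), X.index, dims)


def _classical_mds_points(pts: np.ndarray, index, dims: int) -> MDSEmbedding:
    n = pts.shape[0]
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if (evals[:dims] < -1e-9 * max(1.0, abs(evals[0]))).any():
        warnings.warn("negative eigenvalues truncated to 0 in classical MDS", stacklevel=2)
    top = np.clip(evals[:dims], 0.0, None)
    if (top == 0).any() and (evals[:dims] > 0).sum() < dims:
        warnings.warn("fewer positive eigenvalues than requested dims; zero-padded", stacklevel=2)
    coords = evecs[:, :dims] * np.sqrt(top)
    coords -= coords.mean(axis=0)  # numerically exact centering
    cols = [f"dim{i + 1}" for i in range(dims)]
    return MDSEmbedding(
        coordinates=pd.DataFrame(coords, index=index, columns=cols),
        eigenvalues=evals,
    )
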