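"""Univariate two-class Gaussian linear discriminant models.

Each probe (or CpG) is modeled on its own: both classes share one variance,
differ in mean, and the posterior probability of the positive class is a
logistic function of the observed value. A per-model decision cutoff on the
posterior is chosen to maximize accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .containers import ValidationError


@dataclass
class UnivariateLDAModel:
    """One-feature LDA with equal within-class variance.

    Posterior P(positive | x) = sigmoid(a*x + b) with
    a = (mu1 - mu0) / sigma2 and
    b = (mu0^2 - mu1^2) / (2 sigma2) + ln(pi1 / pi0).
    With equal priors the 0.5-posterior boundary is (mu0 + mu1) / 2.
    """

    mu0: float
    mu1: float
    sigma2: float
    pi0: float
    pi1: float
    cutoff: float = 0.5
    positive_class: str = "1"

    a: float = field(init=False)
    b: float = field(init=False)

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValidationError("degenerate LDA model: pooled variance is 0")
        if not math.isclose(self.pi0 + self.pi1, 1.0, abs_tol=1e-9):
            raise ValidationError("class priors must sum to 1")
        self.a = (self.mu1 - self.mu0) / self.sigma2
        self.b = (self.mu0**2 - self.mu1**2) / (2 * self.sigma2) + math.log(self.pi1 / self.pi0)

    def posterior(self, x) -> np.ndarray:
        """P(positive class | x), elementwise."""
        z = self.a * np.asarray(x, dtype=float) + self.b
        return expit(z)

    def predict(self, x) -> np.ndarray:
        """Vote: posterior >= cutoff."""
        return self.posterior(x) >= self.cutoff

    def to_dict(self) -> dict:
        return {
            "mu0": self.mu0, "mu1": self.mu1, "sigma2": self.sigma2,
            "pi0": self.pi0, "pi1": self.pi1, "cutoff": self.cutoff,
            "positive_class": self.positive_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "UnivariateLDAModel":
        return cls(**d)


def fit_lda(values, labels, positive_class: str = "1") -> UnivariateLDAModel:
    """Fit a univariate LDA from values and 0/1 labels (1 = positive).

    Class means, pooled within-class variance with denominator n-2, and
    empirical class proportions as priors.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.shape != y.shape:
        raise ValidationError("values and labels have different lengths")
    n0, n1 = int((y == 0).sum()), int((y == 1).sum())
    if n0 < 2 or n1 < 2:
        raise ValidationError("need >= 2 samples in each class")
    x0, x1 = x[y == 0], x[y == 1]
    mu0, mu1 = float(x0.mean()), float(x1.mean())
    ss = float(((x0 - mu0) ** 2).sum() + ((x1 - mu1) ** 2).sum())
    sigma2 = ss / (n0 + n1 - 2)
    if sigma2 <= 0:
        raise ValidationError("degenerate LDA model: pooled variance is 0")
    n = n0 + n1
    return UnivariateLDAModel(
        mu0=mu0, mu1=mu1, sigma2=sigma2, pi0=n0 / n, pi1=n1 / n,
        positive_class=positive_class,
    )


def candidate_thresholds(scores) -> np.ndarray:
    """Midpoints of adjacent sorted unique scores plus the sentinels 0 and 1.

    This set is complete with respect to achievable confusion matrices of the
    rule ``score >= t``.
    """
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.empty(0)
    return np.unique(np.concatenate([[0.0], mids, [1.0]]))


def choose_cutoff(scores, labels) -> float:
    """Accuracy-maximizing threshold for ``score >= t`` -> positive.

    Exhaustive scan over :func:`candidate_thresholds`; ties broken toward the
    smallest threshold (favoring sensitivity).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if not ((y == 0).any() and (y == 1).any()):
        raise ValidationError("both classes required to choose a cutoff")
    best_t, best_acc = None, -1.0
    for t in candidate_thresholds(s):
        acc = float(((s >= t).astype(int) == y).mean())
        if acc > best_acc:  # strict: keeps the smallest optimal t
            best_t, best_acc = float(t), acc
    return best_t
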