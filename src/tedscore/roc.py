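"""ROC curves, tie-corrected AUC and Youden-index cutoff selection.

Orientation convention for the whole package: the positive class is
non-response to intravenous glucocorticoids (steroid resistance) and a higher
score means more resistant. A patient is classified positive when their score
is at or above the cutoff (the ">= c" convention on the observed score grid).

The AUC is the pairwise-concordance form,

    AUC = (#{pos > neg} + 1/2 #{pos = neg}) / (n_pos * n_neg),

computed via mid-ranks, which for step curves with the half-tie convention
coincides with the trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .stats import _midranks

__all__ = ["RocCurve", "CutoffResult", "auc", "roc_curve", "youden_optimal",
           "sens_spec_at", "delong_ci"]


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve on the observed score grid.

    ``thresholds`` are ascending candidate cutoffs (unique scores plus +inf);
    operating point i classifies positive when score >= thresholds[i].
    """

    thresholds: tuple[float, ...]
    sensitivity: tuple[float, ...]
    specificity: tuple[float, ...]
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _validate(scores: Sequence[float], labels: Sequence[bool]):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-d sequences")
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    return s, y


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Tie-corrected AUC with non-responders (labels True) as positives."""
    s, y = _validate(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    ranks = _midranks(s)
    # rank-sum identity: wins + ties/2 = R_pos - n_pos(n_pos+1)/2
    return (float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """All operating points over the observed scores, plus the (0, 1) endpoint.

    The lowest threshold classifies everyone positive (sens 1, spec 0); the
    +inf sentinel classifies everyone negative (sens 0, spec 1).
    """
    s, y = _validate(scores, labels)
    thresholds = np.append(np.unique(s), np.inf)
    pos, neg = s[y], s[~y]
    sens = [float(np.mean(pos >= c)) for c in thresholds]
    spec = [float(np.mean(neg < c)) for c in thresholds]
    return RocCurve(tuple(thresholds.tolist()), tuple(sens), tuple(spec),
                    auc(s, y), int(y.sum()), int((~y).sum()))


def youden_optimal(curve: RocCurve) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties are broken toward higher sensitivity, then toward the lower
    threshold.
    """
    if len(curve.thresholds) < 2:
        raise ValueError("degenerate curve: a single operating point")
    best = None
    for c, se, sp in zip(curve.thresholds, curve.sensitivity, curve.specificity):
        j = se + sp - 1.0
        key = (j, se, -c)
        if best is None or key > best[0]:
            best = (key, CutoffResult(c, se, sp))
    return best[1]


def sens_spec_at(
    scores: Sequence[float], labels: Sequence[bool], cutoff: float
) -> CutoffResult:
    """Sensitivity/specificity of the rule 'positive when score >= cutoff'."""
    s, y = _validate(scores, labels)
    sens = float(np.mean(s[y] >= cutoff))
    spec = float(np.mean(s[~y] < cutoff))
    return CutoffResult(float(cutoff), sens, spec)


def delong_ci(
    scores: Sequence[float], labels: Sequence[bool], alpha: float = 0.05
) -> tuple[float, float, float]:
    """DeLong asymptotic (auc, lower, upper) CI via placement values.

    Provided for comparison; the pipeline's reported interval is the
    percentile bootstrap.
    """
    from scipy.special import ndtri

    s, y = _validate(scores, labels)
    pos, neg = s[y], s[~y]
    m, n = len(pos), len(neg)
    # placement of each positive among negatives and vice versa
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    a = float(v10.mean())
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0:
        return a, a, a
    z = float(ndtri(1.0 - alpha / 2.0))
    half = z * math.sqrt(var)
    return a, max(0.0, a - half), min(1.0, a + half)
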