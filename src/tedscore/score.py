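"""The 3-factor composite resistance score and its validation.

One point each for: serum FGL2 > 39.5 ng/mL (strict), TSAb in the top
quartile (> 2597%), and current smoking. The score (0-3) predicts resistance
to intravenous glucocorticoids; discrimination is summarized by the
tie-corrected AUC with a Youden-optimal ">= c" cutoff, and its uncertainty by
a percentile bootstrap over patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from . import roc
from .synthetic import CohortTable, PatientRecord

__all__ = ["ScoreComponent", "ScoreDefinition", "ScoreResult", "BootstrapCi",
           "default_score_definition", "composite_score",
           "responder_rate_by_score", "evaluate_score", "ablate",
           "bootstrap_auc_ci", "FGL2_CUTOFF_NG_ML", "TSAB_TOP_QUARTILE"]

FGL2_CUTOFF_NG_ML = 39.5
TSAB_TOP_QUARTILE = 4


@dataclass(frozen=True)
class ScoreComponent:
    name: str
    rule: Callable[[PatientRecord], bool]
    points: int = 1

    def __post_init__(self) -> None:
        if self.points <= 0:
            raise ValueError("points must be a positive integer")


@dataclass(frozen=True)
class ScoreDefinition:
    components: tuple[ScoreComponent, ...]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("a score needs at least one component")
        names = [c.name for c in self.components]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")

    @property
    def max_score(self) -> int:
        return sum(c.points for c in self.components)


def default_score_definition(
    fgl2_cutoff: float = FGL2_CUTOFF_NG_ML,
) -> ScoreDefinition:
    """FGL2 > cutoff (strict), TSAb quartile 4, current smoking; 1 point each."""
    return ScoreDefinition((
        ScoreComponent("fgl2", lambda r: r.fgl2 > fgl2_cutoff),
        ScoreComponent("tsab", lambda r: r.tsab_quartile == TSAB_TOP_QUARTILE),
        ScoreComponent("smoking", lambda r: r.smoking),
    ))


def composite_score(record: PatientRecord, definition: ScoreDefinition) -> int:
    """Integer sum of points for satisfied component rules."""
    total = 0
    for comp in definition.components:
        try:
            satisfied = comp.rule(record)
        except AttributeError as exc:
            raise ValueError(
                f"record lacks a field required by component {comp.name!r}"
            ) from exc
        if satisfied:
            total += comp.points
    return total


@dataclass(frozen=True)
class ScoreResult:
    """Per-level responder rates and, when computed, discrimination summary."""

    responder_rate_by_score: dict[int, tuple[int, int, float]]
    auc: float | None = None
    optimal_cutoff: roc.CutoffResult | None = None

    @property
    def n_total(self) -> int:
        return sum(v[1] for v in self.responder_rate_by_score.values())


def responder_rate_by_score(
    cohort: CohortTable, definition: ScoreDefinition
) -> ScoreResult:
    """Responder count / total / rate at every score level 0..max_score.

    Levels with no patients are reported with n = 0 and a NaN rate.
    """
    counts: dict[int, list[int]] = {
        s: [0, 0] for s in range(definition.max_score + 1)
    }
    for record in cohort.records:
        s = composite_score(record, definition)
        counts[s][1] += 1
        if record.responder:
            counts[s][0] += 1
    table = {
        s: (n_r, n_tot, n_r / n_tot if n_tot else math.nan)
        for s, (n_r, n_tot) in counts.items()
    }
    return ScoreResult(table)


def evaluate_score(
    scores: Sequence[float], outcomes: Sequence[bool]
) -> ScoreResult:
    """AUC and Youden-optimal cutoff, non-response positive.

    ``outcomes`` are responder flags (True = responder); they are inverted
    internally so that higher scores align with the positive (resistant)
    class.
    """
    scores = np.asarray(scores, dtype=float)
    responder = np.asarray(outcomes, dtype=bool)
    labels = ~responder  # positive class: non-responder
    curve = roc.roc_curve(scores, labels)
    cutoff = roc.youden_optimal(curve)
    table: dict[int, tuple[int, int, float]] = {}
    for s in np.unique(scores):
        at = scores == s
        n_tot = int(at.sum())
        n_r = int(responder[at].sum())
        table[int(s) if float(s).is_integer() else float(s)] = (
            n_r, n_tot, n_r / n_tot)
    return ScoreResult(table, auc=curve.auc, optimal_cutoff=cutoff)


def ablate(definition: ScoreDefinition, drop: str) -> ScoreDefinition:
    """Score definition with the named component removed."""
    names = [c.name for c in definition.components]
    if drop not in names:
        raise ValueError(f"unknown component: {drop!r}")
    if len(definition.components) == 1:
        raise ValueError("cannot drop the last component")
    return ScoreDefinition(tuple(c for c in definition.components
                                 if c.name != drop))


@dataclass(frozen=True)
class BootstrapCi:
    b: int
    auc_samples: np.ndarray
    point_estimate: float
    ci_lower: float
    ci_upper: float
    alpha: float
    seed: int
    n_redrawn: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_lower <= self.ci_upper <= 1.0):
            raise ValueError("CI bounds must be ordered and in [0, 1]")
        if len(self.auc_samples) != self.b:
            raise ValueError("need exactly b AUC samples")


def bootstrap_auc_ci(
    scores: Sequence[float],
    outcomes: Sequence[bool],
    b: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> BootstrapCi:
    """Percentile bootstrap CI of the AUC over patient resamples.

    Patients are resampled with replacement; resamples in which one outcome
    class is absent are redrawn (and counted), so exactly ``b`` AUC values
    enter the empirical (alpha/2, 1-alpha/2) quantiles (linear, "type 7",
    interpolation).
    """
    if b < 1:
        raise ValueError("b must be at least 1")
    scores = np.asarray(scores, dtype=float)
    responder = np.asarray(outcomes, dtype=bool)
    labels = ~responder
    if labels.all() or not labels.any():
        raise ValueError("both outcome classes required")
    rng = np.random.default_rng(seed)
    n = len(scores)
    samples = np.empty(b)
    redrawn = 0
    for i in range(b):
        while True:
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if lab.any() and not lab.all():
                break
            redrawn += 1
        samples[i] = roc.auc(scores[idx], lab)
    lo, hi = np.percentile(samples, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCi(b, samples, roc.auc(scores, labels), float(lo),
                       float(hi), alpha, seed, redrawn)
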