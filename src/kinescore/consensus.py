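"""Rater-panel summaries and consensus-aware evaluation metrics.

Clinical ordinal ratings by multiple experts disagree systematically: the
more behavioral cues a task demands, the lower the consensus. This module
provides the panel summary statistics (mean, sample SD), the complete /
majority / no-agreement decomposition, the regression of agreement on task
complexity, and two prediction accuracies — the conventional within-±1
rule and a distribution-aware rule whose tolerance band is the panel's own
empirical SD, so it tightens for high-consensus tasks and relaxes for
contentious ones. Composite-score aggregation and ON/OFF medication
contrasts operate on the model's predicted means.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, InsufficientRatersError

#: half-class floor applied to a unanimous panel's SD so the
#: distribution-aware band never degenerates to a point
DEFAULT_SIGMA_FLOOR = 0.5


@dataclass(frozen=True)
class RaterPanel:
    """Ordinal scores (0..K-1) assigned to one clip by >= 2 raters."""

    scores: tuple[int, ...]
    num_classes: int = 5

    def __post_init__(self) -> None:
        if len(self.scores) < 2:
            raise InsufficientRatersError("a panel needs at least 2 raters")
        if any(not float(s).is_integer() for s in self.scores):
            raise ValueError("scores must be integers")
        object.__setattr__(self, "scores", tuple(int(s) for s in self.scores))
        if any(s < 0 or s >= self.num_classes for s in self.scores):
            raise ValueError(f"scores must lie in [0, {self.num_classes - 1}]")


@dataclass(frozen=True)
class RatingSummary:
    """Panel mean t, sample standard deviation sigma, and rater count."""

    mean: float
    sd: float
    n_raters: int


@dataclass(frozen=True)
class AgreementStats:
    """Complete / majority / none percentages (disjoint; sum to 100)."""

    complete_pct: float
    majority_pct: float
    none_pct: float

    @property
    def majority_or_better_pct(self) -> float:
        """Cumulative 'two or more raters agree' view."""
        return self.complete_pct + self.majority_pct


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float


def summarize_panel(panel: RaterPanel) -> RatingSummary:
    """Arithmetic mean and sample (n-1 denominator) SD of a panel.

    The sample SD is what makes a (1, 2, 2) panel summarize to
    mean 1.67, SD 0.58 (the population formula would give 0.47).
    """
    scores = np.asarray(panel.scores, dtype=float)
    return RatingSummary(mean=float(scores.mean()),
                         sd=float(scores.std(ddof=1)),
                         n_raters=len(scores))


def agreement_category(panel: RaterPanel) -> str:
    """'complete' if all raters agree, 'majority' if a strict majority
    shares one score, 'none' otherwise (for 3 raters: all distinct)."""
    counts = Counter(panel.scores)
    top = max(counts.values())
    n = len(panel.scores)
    if top == n:
        return "complete"
    if top > n / 2:
        return "majority"
    return "none"


def agreement_percentages(panels: Iterable[RaterPanel]) -> AgreementStats:
    """Fraction of panels in each agreement category, as percentages.

    'majority' counts majority-only panels; complete agreement is reported
    separately (use ``majority_or_better_pct`` for the cumulative view).
    """
    cats = [agreement_category(p) for p in panels]
    if not cats:
        raise InsufficientDataError("no panels given")
    n = len(cats)
    c = Counter(cats)
    return AgreementStats(
        complete_pct=100.0 * c["complete"] / n,
        majority_pct=100.0 * c["majority"] / n,
        none_pct=100.0 * c["none"] / n,
    )


def complexity_regression(points: Sequence[tuple[float, float]]) -> RegressionFit:
    """OLS of an agreement statistic (y) on task complexity (x).

    Returns slope, intercept, r^2, and the two-sided slope p-value.
    """
    if len(points) < 3:
        raise InsufficientDataError("regression needs >= 3 points")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise InsufficientDataError("need >= 2 distinct complexities")
    res = stats.linregress(x, y)
    return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2),
                         p_value=float(res.pvalue))


def _check_paired(preds: Sequence, targets: Sequence) -> None:
    if len(preds) != len(targets):
        raise ValueError("predictions and targets must have equal length")
    if len(preds) == 0:
        raise InsufficientDataError("no predictions to score")


def _pred_mean(pred) -> float:
    """Accept a Prediction-like object (``.mean`` attribute) or a bare number."""
    import numbers

    if isinstance(pred, numbers.Real) or np.isscalar(pred):
        return float(pred)
    return float(pred.mean)


def within_pm1_accuracy(preds: Sequence, targets: Sequence[RatingSummary]) -> float:
    """Fraction of predictions whose mean lies within +/-1 of the panel mean.

    Applied to the continuous predicted mean against the continuous panel
    mean, i.e. |mu_hat - t| <= 1.
    """
    _check_paired(preds, targets)
    hits = [abs(_pred_mean(p) - t.mean) <= 1.0 for p, t in zip(preds, targets)]
    return float(np.mean(hits))


def distribution_aware_interval(target: RatingSummary, width_k: float = 1.0,
                                sigma_floor: float = DEFAULT_SIGMA_FLOOR,
                                strict: bool = False) -> tuple[float, float]:
    """[t - k*sigma, t + k*sigma] acceptance band for one panel.

    ``strict`` reproduces printed-table arithmetic by rounding the mean and
    SD to 2 decimals before forming the band (so panel (1,2,2) gives
    [1.09, 2.25]); otherwise unrounded values are used. ``sigma_floor``
    keeps unanimous panels from degenerating to a point band.
    """
    t, s = target.mean, target.sd
    if strict:
        t, s = round(t, 2), round(s, 2)
    half = width_k * max(s, sigma_floor)
    return (t - half, t + half)


def distribution_aware_accuracy(preds: Sequence, targets: Sequence[RatingSummary],
                                width_k: float = 1.0,
                                sigma_floor: float = DEFAULT_SIGMA_FLOOR,
                                strict: bool = False) -> float:
    """Fraction of predictions inside the panel's +/- k*sigma band.

    A prediction is correct iff |mu_hat - t| <= k * max(sigma, sigma_floor):
    the band tightens for high-consensus panels and widens where experts
    themselves disagree. Monotone non-decreasing in both ``width_k`` and
    ``sigma_floor``.
    """
    _check_paired(preds, targets)
    if width_k <= 0 or sigma_floor < 0:
        raise ValueError("width_k must be > 0 and sigma_floor >= 0")
    hits = []
    for p, t in zip(preds, targets):
        lo, hi = distribution_aware_interval(t, width_k, sigma_floor, strict)
        hits.append(lo <= _pred_mean(p) <= hi)
    return float(np.mean(hits))


def composite_score(task_preds: Mapping[tuple[str, str], object]) -> float:
    """Sum of predicted means over all present (task, side) slots.

    Approximates the total motor-exam score; absent slots are simply
    excluded (the caller sees which keys it passed).
    """
    if not task_preds:
        raise InsufficientDataError("no task predictions to aggregate")
    return float(sum(_pred_mean(p) for p in task_preds.values()))


def medication_contrast(off: Mapping[str, float], on: Mapping[str, float]
                        ) -> tuple[dict[str, float], float]:
    """Per-patient ON minus OFF composite deltas and the fraction improved.

    Negative delta means the predicted severity decreased on medication.
    """
    if set(off) != set(on):
        raise ValueError(f"patient ids differ: {set(off) ^ set(on)}")
    if not off:
        raise InsufficientDataError("no patients")
    deltas = {pid: float(on[pid] - off[pid]) for pid in off}
    frac = float(np.mean([d < 0 for d in deltas.values()]))
    return deltas, frac
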