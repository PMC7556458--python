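"""Speed-accuracy trade-off analysis and paired model comparison.

Varying the entropy threshold of a recurrent classifier traces a curve of
top-1 accuracy against mean computational cost (floating-point operations at
the decision step, averaged over images).  For each threshold the
distribution of per-image costs is summarised as a histogram whose weighted
mean reproduces the curve point exactly.  Matched-cost comparison selects the
threshold whose mean cost is closest to a feedforward model's fixed cost.
Accuracy differences between paired classifiers are tested with McNemar's
test with Bonferroni correction across the comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .decision import DecisionPolicy, ReadoutSequence, decide

#: discordant-pair count below which the exact binomial McNemar test is used
EXACT_MCNEMAR_CUTOFF = 25


@dataclass(frozen=True)
class SATPoint:
    entropy_threshold: float
    mean_cost: float
    accuracy: float
    #: map cost -> (fraction of images deciding at that cost, accuracy there)
    cost_histogram: dict


@dataclass(frozen=True)
class SATCurve:
    points: tuple[SATPoint, ...]

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([p.entropy_threshold for p in self.points])

    @property
    def mean_costs(self) -> np.ndarray:
        return np.array([p.mean_cost for p in self.points])

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([p.accuracy for p in self.points])


def default_threshold_grid(seq: ReadoutSequence, readout_mode: str = "cumulative") -> np.ndarray:
    """Sorted unique entropies observed in the set, plus 0 and ln(n_classes).

    Guarantees every achievable operating point appears on the curve.
    """
    from .decision import entropy

    readouts = seq.cumulative() if readout_mode == "cumulative" else seq.probs
    ent = entropy(readouts).ravel()
    grid = np.unique(np.concatenate([ent, [0.0, np.log(seq.n_classes)]]))
    return grid


def sat_curve(
    seq: ReadoutSequence,
    labels,
    thresholds=None,
    *,
    readout_mode: str = "cumulative",
) -> SATCurve:
    """Accuracy and mean cost at each entropy threshold."""
    if thresholds is None:
        thresholds = default_threshold_grid(seq, readout_mode)
    thresholds = np.atleast_1d(np.asarray(thresholds, dtype=float))
    if thresholds.size == 0:
        raise ValueError("thresholds must be non-empty")
    labels = np.asarray(labels)
    points = []
    for theta in thresholds:
        policy = DecisionPolicy(
            mode="threshold_based", readout_mode=readout_mode, entropy_threshold=float(theta)
        )
        dec = decide(seq, policy)
        correct = dec.predicted_class == labels
        hist = {}
        for cost in np.unique(dec.cost_at_decision):
            at = dec.cost_at_decision == cost
            hist[float(cost)] = (float(at.mean()), float(correct[at].mean()))
        points.append(
            SATPoint(
                entropy_threshold=float(theta),
                mean_cost=float(dec.cost_at_decision.mean()),
                accuracy=float(correct.mean()),
                cost_histogram=hist,
            )
        )
    return SATCurve(points=tuple(points))


def matched_cost_threshold(curve: SATCurve, target_cost: float) -> float:
    """Threshold minimising |mean_cost - target_cost|; ties -> larger theta."""
    if not curve.points:
        raise ValueError("curve is empty")
    dev = np.abs(curve.mean_costs - target_cost)
    best = dev.min()
    candidates = curve.thresholds[dev <= best]
    return float(candidates.max())


def mcnemar(preds_a, preds_b, labels, *, exact: bool | None = None) -> tuple[float, float]:
    """McNemar's test for paired classifier accuracy.

    Uses the exact two-sided binomial test when the number of discordant
    pairs b + c is below 25, otherwise the continuity-corrected chi-square
    statistic (|b - c| - 1)^2 / (b + c); pass ``exact`` to force a branch.
    Returns (statistic, p_value); with no discordant pairs p = 1 by
    convention.
    """
    preds_a, preds_b, labels = map(np.asarray, (preds_a, preds_b, labels))
    if not preds_a.shape == preds_b.shape == labels.shape:
        raise ValueError("prediction and label vectors must be aligned")
    a_right = preds_a == labels
    b_right = preds_b == labels
    b = int(np.sum(a_right & ~b_right))
    c = int(np.sum(~a_right & b_right))
    if b + c == 0:
        return 0.0, 1.0
    table = [[0, b], [c, 0]]  # only discordant counts matter
    if exact is None:
        exact = (b + c) < EXACT_MCNEMAR_CUTOFF
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bonferroni(p_values, family_size: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) elementwise."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if family_size is None else family_size
    return np.minimum(1.0, p * m)
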