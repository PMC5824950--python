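"""Evaluation statistics for the sorter.

The device is a binary sorter at heart — class 2 (small-budded) cells
go to the collect reservoir, everything else to waste — so evaluation
collapses the three morphology classes to "class 2 vs not".  The
headline numbers are the classifier precision (positive predictive
value) and a Wilson score interval on the probability of a cell being
mechanically sorted to the destination the classifier chose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Tuple

from scipy.stats import norm

POSITIVE_CLASS = 2


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts with class 2 as the positive label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_labels(cls, true_labels: Sequence[int],
                    predicted_labels: Sequence[int],
                    positive: int = POSITIVE_CLASS) -> "ConfusionMatrix":
        if len(true_labels) != len(predicted_labels):
            raise ValueError("label lists must have equal length")
        tp = fp = fn = tn = 0
        for t, p in zip(true_labels, predicted_labels):
            if p == positive:
                if t == positive:
                    tp += 1
                else:
                    fp += 1
            else:
                if t == positive:
                    fn += 1
                else:
                    tn += 1
        return cls(tp, fp, fn, tn)


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int],
              positive: int = POSITIVE_CLASS) -> ConfusionMatrix:
    """Binary confusion matrix (positive = class 2 by default)."""
    return ConfusionMatrix.from_labels(true_labels, predicted_labels, positive)


def precision(cm: ConfusionMatrix) -> float:
    """Positive predictive value tp / (tp + fp).

    Raises ``ValueError`` when nothing was predicted positive, in which
    case precision is undefined.
    """
    if cm.tp + cm.fp == 0:
        raise ValueError("precision undefined: no positive predictions")
    return cm.tp / (cm.tp + cm.fp)


def wilson_interval(successes: int, n: int,
                    alpha: float = 0.05) -> Tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Inverts the normal-approximation score test at level ``alpha``
    (two-sided); unlike the Wald interval it stays inside [0, 1] and
    behaves sensibly at the boundaries (0/n gives a lower bound of
    exactly 0, n/n an upper bound of exactly 1).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = norm.ppf(1.0 - alpha / 2.0)
    phat = successes / n
    denom = 1.0 + z * z / n
    centre = (phat + z * z / (2.0 * n)) / denom
    half = z * math.sqrt(phat * (1.0 - phat) / n
                         + z * z / (4.0 * n * n)) / denom
    # The score-test roots are exactly 0 and 1 at the boundaries; pin
    # them so floating-point round-off cannot exclude the estimate.
    lower = 0.0 if successes == 0 else max(0.0, centre - half)
    upper = 1.0 if successes == n else min(1.0, centre + half)
    return lower, upper


def percent_floor(fraction: float) -> int:
    """Percentage truncated to an integer, the report's house style
    (9/11 -> 81, not 82)."""
    return int(math.floor(fraction * 100.0 + 1e-12))


def sorting_accuracy_report(forward_counts: Mapping[str, int],
                            reverse_counts: Mapping[str, int],
                            alpha: float = 0.05) -> dict:
    """Summarize a forward-sort / reverse-recovery experiment.

    ``forward_counts`` and ``reverse_counts`` each map ``"class2"`` and
    ``"not_class2"`` to cell counts: forward tallies every cell the
    classifier handled, reverse tallies what was recovered from the
    collect reservoir.  Discrepancies are flagged as mis-sorts: a
    non-class-2 cell found among the collected, or a collected class-2
    cell that failed to reappear.  Sorting success is (total handled -
    mis-sorts) / total handled, with a Wilson interval.
    """
    f2 = int(forward_counts["class2"])
    fn2 = int(forward_counts["not_class2"])
    r2 = int(reverse_counts["class2"])
    rn2 = int(reverse_counts["not_class2"])
    total = f2 + fn2
    if total == 0:
        raise ValueError("no cells in forward counts")
    missorts = rn2 + max(0, f2 - r2)
    successes = max(0, total - missorts)
    lo, hi = wilson_interval(successes, total, alpha)
    report = {
        "forward": {"class2": f2, "not_class2": fn2, "total": total},
        "reverse": {"class2": r2, "not_class2": rn2, "total": r2 + rn2},
        "missorted": missorts,
        "successes": successes,
        "success_fraction": successes / total,
        "wilson_alpha": alpha,
        "wilson_lower": lo,
        "wilson_upper": hi,
    }
    return report


def format_report(report: Mapping) -> str:
    """Human-readable rendering of :func:`sorting_accuracy_report`."""
    f = report["forward"]
    r = report["reverse"]
    lines = [
        "Sorting performance",
        f"  forward: class 2 = {f['class2']}, not class 2 = "
        f"{f['not_class2']}, total = {f['total']}",
        f"  reverse (collect reservoir): class 2 = {r['class2']}, "
        f"not class 2 = {r['not_class2']}, total = {r['total']}",
        f"  mis-sorted cells: {report['missorted']}",
        f"  sorting success: {report['successes']}/{f['total']} = "
        f"{percent_floor(report['success_fraction'])}%",
        f"  Wilson {100 * (1 - report['wilson_alpha']):.0f}% CI: "
        f"[{100 * report['wilson_lower']:.1f}%, "
        f"{100 * report['wilson_upper']:.1f}%]",
    ]
    return "\n".join(lines)
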