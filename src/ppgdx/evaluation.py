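"""Diagnostic-test evaluation: confusion matrices, majority voting,
exact binomial confidence intervals, crosshair-plot data export.

SSc is the positive class throughout. Per-fold confusion matrices are
summed into one combined matrix; accuracy, sensitivity and specificity
are reported as percentages with exact (Clopper-Pearson) 95% CIs, the
interval that inverts the binomial tail probabilities via beta-
distribution quantiles and therefore has conservative (>= nominal)
coverage. Participant-level classification takes the majority class of
a participant's image predictions, with exact ties resolved to SSc —
the sensitivity-preserving direction for a screening test where missing
a patient is the costlier error.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .recording import SSC

POSITIVE_LABEL = SSC


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with SSc as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(self.tp + other.tp, self.fn + other.fn,
                               self.fp + other.fp, self.tn + other.tn)

    @classmethod
    def from_predictions(cls, true_labels: Sequence[str], predicted_labels: Sequence[str],
                         positive: str = POSITIVE_LABEL) -> "ConfusionMatrix":
        t = np.asarray(true_labels) == positive
        p = np.asarray(predicted_labels) == positive
        return cls(tp=int((t & p).sum()), fn=int((t & ~p).sum()),
                   fp=int((~t & p).sum()), tn=int((~t & ~p).sum()))


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Accuracy/sensitivity/specificity in percent with exact 95% CIs."""

    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]

    def rounded(self, ndigits: int = 1) -> dict[str, float | tuple[float, float]]:
        """Half-up rounding to ``ndigits`` decimals, as in printed tables."""
        r = lambda v: round_half_up(v, ndigits)
        return {
            "accuracy": r(self.accuracy), "accuracy_ci": (r(self.accuracy_ci[0]), r(self.accuracy_ci[1])),
            "sensitivity": r(self.sensitivity),
            "sensitivity_ci": (r(self.sensitivity_ci[0]), r(self.sensitivity_ci[1])),
            "specificity": r(self.specificity),
            "specificity_ci": (r(self.specificity_ci[0]), r(self.specificity_ci[1])),
        }


def round_half_up(value: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def combine_confusions(matrices: Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum of per-fold confusion matrices."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no confusion matrices to combine")
    out = matrices[0]
    for m in matrices[1:]:
        out = out + m
    return out


def exact_ci(successes: int, trials: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Clopper-Pearson) binomial CI, as percentages."""
    if trials <= 0 or not (0 <= successes <= trials):
        raise ValueError(f"invalid counts: {successes}/{trials}")
    lo, hi = proportion_confint(successes, trials, alpha=alpha, method="beta")
    lo = 0.0 if successes == 0 else float(lo)
    hi = 1.0 if successes == trials else float(hi)
    return (100.0 * lo, 100.0 * hi)


def metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> DiagnosticMetrics:
    """Accuracy, sensitivity and specificity with exact 95% CIs (percent)."""
    if cm.tp + cm.fn == 0:
        raise ValueError("no positive-class items; sensitivity undefined")
    if cm.fp + cm.tn == 0:
        raise ValueError("no negative-class items; specificity undefined")
    return DiagnosticMetrics(
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        accuracy_ci=exact_ci(cm.tp + cm.tn, cm.total, alpha),
        sensitivity=100.0 * cm.tp / (cm.tp + cm.fn),
        sensitivity_ci=exact_ci(cm.tp, cm.tp + cm.fn, alpha),
        specificity=100.0 * cm.tn / (cm.fp + cm.tn),
        specificity_ci=exact_ci(cm.tn, cm.fp + cm.tn, alpha),
    )


def majority_vote(image_labels: Sequence[str], positive: str = POSITIVE_LABEL,
                  negative: str = "Control") -> str:
    """Majority class of one participant's image predictions; ties -> SSc."""
    labels = list(image_labels)
    if not labels:
        raise ValueError("no image predictions for participant")
    n_pos = sum(1 for x in labels if x == positive)
    n_neg = len(labels) - n_pos
    return positive if n_pos >= n_neg else negative


def participant_votes(image_predictions: pd.DataFrame) -> pd.DataFrame:
    """Aggregate image predictions (columns participant_id, true_label,
    predicted_label) into one majority-vote row per participant."""
    rows = []
    for pid, grp in image_predictions.groupby("participant_id", sort=True):
        true = grp["true_label"].iloc[0]
        rows.append({
            "participant_id": pid,
            "true_label": true,
            "predicted_label": majority_vote(grp["predicted_label"].tolist()),
            "n_images": len(grp),
        })
    return pd.DataFrame(rows)


def crosshair_export(metric_sets: Mapping[str, DiagnosticMetrics]) -> pd.DataFrame:
    """Sensitivity vs false-positive rate (100 - specificity) per
    classifier, CIs transformed with endpoints swapped."""
    if not metric_sets:
        raise ValueError("no metric sets to export")
    rows = []
    for name, m in metric_sets.items():
        rows.append({
            "classifier": name,
            "sensitivity": m.sensitivity,
            "sensitivity_ci_low": m.sensitivity_ci[0],
            "sensitivity_ci_high": m.sensitivity_ci[1],
            "fpr": 100.0 - m.specificity,
            "fpr_ci_low": 100.0 - m.specificity_ci[1],
            "fpr_ci_high": 100.0 - m.specificity_ci[0],
        })
    return pd.DataFrame(rows)


def metrics_report(cm: ConfusionMatrix, branch: str, level: str) -> dict:
    """JSON-ready report entry for one combined confusion matrix."""
    m = metrics(cm)
    return {
        "branch": branch,
        "level": level,
        "cm": [cm.tp, cm.fn, cm.fp, cm.tn],
        **{k: v for k, v in m.rounded().items()},
    }
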