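"""Evaluation statistics: quadrant gating, enrichment, sensitivity/accuracy.

Three readouts quantify what compensation did to the single-cell table:

* biaxial quadrant fractions for a pair of mutually exclusive markers —
  the double-positive fraction is the primary spillover readout;
* relative cell-type enrichment for one channel: the change in cell-type
  composition among channel-positive cells, (after - before) / before * 100;
* per-type and pooled sensitivity (correct calls / ground-truth count) and
  accuracy (correct calls / algorithm calls) of a cell-type annotation.

Positivity is strict (value > threshold; ties are negative), with a default
threshold of 0 counts. Divisions by zero are reported as missing values with
a reason, never as 0 or infinity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .imgio import CellFeatureTable

#: Annotation value for cells the classifier could not assign. Counts against
#: sensitivity (the cell stays in the truth denominator) but never enters an
#: accuracy denominator (it is not a call).
NOT_DETERMINED = "not determined"


@dataclass(frozen=True)
class QuadrantResult:
    """Percentages of cells per biaxial quadrant; they sum to 100."""

    double_negative: float
    x_single_positive: float
    y_single_positive: float
    double_positive: float
    threshold_x: float
    threshold_y: float
    n_cells: int

    def as_dict(self) -> dict[str, float]:
        return {
            "double_negative": self.double_negative,
            "x_single_positive": self.x_single_positive,
            "y_single_positive": self.y_single_positive,
            "double_positive": self.double_positive,
        }


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-type composition among channel-positive cells, before vs after.

    ``table`` columns: cell_type, percentage_before, percentage_after,
    relative_change (NaN when undefined), undefined_reason (empty string
    when defined).
    """

    table: pd.DataFrame
    channel: str
    n_before: int
    n_after: int


@dataclass(frozen=True)
class ClassificationScore:
    """Per-type and pooled annotation agreement.

    ``per_type`` columns: cell_type, n_truth, n_called, n_correct,
    sensitivity, accuracy (NaN + reason when the denominator is zero).
    """

    per_type: pd.DataFrame
    overall_sensitivity: float
    overall_accuracy: float | None
    contingency: pd.DataFrame


def quadrant_fractions(
    table: CellFeatureTable,
    channel_x: str,
    channel_y: str,
    threshold_x: float = 0.0,
    threshold_y: float = 0.0,
    use_compensated: bool = False,
) -> QuadrantResult:
    """Gate all cells on two channels and report the four quadrant percentages."""
    if len(table.frame) == 0:
        raise ValueError("cannot gate an empty feature table")
    if threshold_x < 0 or threshold_y < 0:
        raise ValueError("thresholds must be >= 0")
    getter = table.compensated if use_compensated else table.original
    x = getter(channel_x).to_numpy(dtype=np.float64)
    y = getter(channel_y).to_numpy(dtype=np.float64)
    px = x > threshold_x
    py = y > threshold_y
    n = len(x)
    counts = np.array(
        [(~px & ~py).sum(), (px & ~py).sum(), (~px & py).sum(), (px & py).sum()]
    )
    dn, xs, ys, dp = (100.0 * counts / n).tolist()
    return QuadrantResult(dn, xs, ys, dp, threshold_x, threshold_y, n)


def relative_enrichment(
    table: CellFeatureTable, annotations: pd.Series, channel: str
) -> EnrichmentResult:
    """Change in cell-type composition among cells positive for ``channel``.

    ``annotations`` maps every cell label in the table to a cell-type string.
    Before-composition is over cells with original count > 0; after, over
    cells whose compensated count stayed > 0.
    """
    if channel not in table.channel_names:
        raise KeyError(f"channel {channel!r} not in table")
    ann = annotations.reindex(table.frame.index)
    if ann.isna().any():
        missing = table.frame.index[ann.isna()].tolist()
        raise ValueError(f"annotations missing for cells {missing[:5]}")
    before_mask = table.original(channel).to_numpy(dtype=np.float64) > 0
    after_mask = table.compensated(channel).to_numpy(dtype=np.float64) > 0
    types = sorted(ann.unique())
    n_before = int(before_mask.sum())
    n_after = int(after_mask.sum())
    rows = []
    for t in types:
        is_t = (ann == t).to_numpy()
        pct_before = 100.0 * (is_t & before_mask).sum() / n_before if n_before else np.nan
        pct_after = 100.0 * (is_t & after_mask).sum() / n_after if n_after else np.nan
        if n_before and pct_before > 0 and n_after:
            change = (pct_after - pct_before) / pct_before * 100.0
            reason = ""
        else:
            change = np.nan
            reason = (
                "no positive cells before compensation"
                if not n_before
                else "no positive cells after compensation"
                if not n_after
                else "type absent before compensation"
            )
        rows.append(
            {
                "cell_type": t,
                "percentage_before": pct_before,
                "percentage_after": pct_after,
                "relative_change": change,
                "undefined_reason": reason,
            }
        )
    return EnrichmentResult(pd.DataFrame(rows), channel, n_before, n_after)


def classification_scores(
    predicted: pd.Series, truth: pd.Series, not_determined: str = NOT_DETERMINED
) -> ClassificationScore:
    """Sensitivity and accuracy of predicted cell types against ground truth.

    Sensitivity of type A = correctly-called A cells / ground-truth A cells;
    accuracy of type A = correctly-called A cells / cells the algorithm
    called A. Cells predicted ``not_determined`` lower sensitivity but are
    excluded from every accuracy denominator. Pooled values use total
    correct calls over total truth cells (sensitivity) and over total
    determined calls (accuracy).
    """
    if set(predicted.index) != set(truth.index):
        raise ValueError("predicted and truth must cover the same cell ids")
    predicted = predicted.reindex(truth.index)
    types = sorted(set(truth.unique()))
    correct = predicted == truth
    rows = []
    for t in types:
        n_truth = int((truth == t).sum())
        n_called = int((predicted == t).sum())
        n_correct = int((correct & (truth == t)).sum())
        sens = 100.0 * n_correct / n_truth if n_truth else np.nan
        acc = 100.0 * n_correct / n_called if n_called else np.nan
        rows.append(
            {
                "cell_type": t,
                "n_truth": n_truth,
                "n_called": n_called,
                "n_correct": n_correct,
                "sensitivity": sens,
                "accuracy": acc,
                "undefined_reason": "" if n_called else "type never called by algorithm",
            }
        )
    total_correct = int(correct.sum())
    overall_sens = 100.0 * total_correct / len(truth)
    n_determined = int((predicted != not_determined).sum())
    overall_acc = 100.0 * total_correct / n_determined if n_determined else None
    contingency = pd.crosstab(truth, predicted, rownames=["truth"], colnames=["predicted"])
    return ClassificationScore(pd.DataFrame(rows), overall_sens, overall_acc, contingency)
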