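"""Traffic-efficiency readouts, deviation scores, hit calling and t-tests.

Per-cell traffic efficiency is the ratio of integrated surface-label to
integrated total-reporter fluorescence. The per-image value is the median
over QC-passing cells; the per-condition value is the mean (optionally
median) of per-image medians, with its SEM. A condition's deviation score
for a readout is

    (mean_test - mean_neg) / (k * sem_neg)        (default k = 2)

so that |score| > 1 is exactly "effect larger than twice the negative
control's SEM". Conditions score above +1 as enhancers and below -1 as
inhibitors (strict inequalities). Significance versus the negative control
is a two-tailed two-sample Student's t-test on per-image values (pooled
variance; Welch available behind a flag). All three readouts — traffic
efficiency, total expression, and surface amount — are scored identically.
No multiple-testing correction is applied; p-values are raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import ContractViolationError, DegenerateControlError, ParameterError
from .segmentation import CellRecord

READOUTS = ("traffic_efficiency", "total", "surface")

ENHANCER = "enhancer"
INHIBITOR = "inhibitor"
NEUTRAL = "neutral"

ENHANCER_SCORE_THRESHOLD = 1.0
INHIBITOR_SCORE_THRESHOLD = -1.0


@dataclass
class ImageSummary:
    """Median readouts over the QC-passing cells of one field."""

    well: str
    field: int
    condition: str
    median_traffic_efficiency: float
    median_total: float
    median_surface: float
    n_cells: int
    qc_status: str = "pass"

    def readout(self, name: str) -> float:
        return {
            "traffic_efficiency": self.median_traffic_efficiency,
            "total": self.median_total,
            "surface": self.median_surface,
        }[name]


@dataclass
class ConditionSummary:
    """Per-condition mean, SEM and n over per-image medians, per readout."""

    condition: str
    mean: dict[str, float]
    sem: dict[str, float | None]
    n_images: int


@dataclass
class HitCall:
    condition: str
    readout: str
    deviation_score: float
    classification: str
    p_value: float
    negative_control_ref: str
    sem_multiplier: float


def cell_traffic_efficiency(cell: CellRecord) -> float:
    """Surface/total intensity ratio for one QC-passing cell."""
    if cell.integrated_total <= 0:
        raise ContractViolationError(
            "traffic efficiency undefined for integrated_total <= 0; such cells must "
            "carry the low_expression flag and never reach scoring"
        )
    return cell.integrated_surface / cell.integrated_total


def image_summary(
    cells: Sequence[CellRecord], well: str, field: int, condition: str
) -> ImageSummary | None:
    """Median readouts over passing cells; None when no cell passes QC.

    Medians use the standard convention: even counts average the two
    middle values.
    """
    passing = [c for c in cells if c.passes_qc]
    if not passing:
        return None
    ratios = [cell_traffic_efficiency(c) for c in passing]
    return ImageSummary(
        well=well,
        field=field,
        condition=condition,
        median_traffic_efficiency=float(np.median(ratios)),
        median_total=float(np.median([c.integrated_total for c in passing])),
        median_surface=float(np.median([c.integrated_surface for c in passing])),
        n_cells=len(passing),
    )


def condition_summary(
    summaries: Iterable[ImageSummary], condition: str, aggregation: str = "mean"
) -> ConditionSummary:
    """Aggregate per-image medians for one condition.

    ``aggregation`` is ``"mean"`` (default) or ``"median"``. SEM is the
    sample sd of per-image values divided by sqrt(n); undefined (None) for
    a single image, in which case the condition is excluded from deviation
    scoring downstream.
    """
    if aggregation not in ("mean", "median"):
        raise ParameterError(f"aggregation must be mean|median, got {aggregation!r}")
    selected = [s for s in summaries if s.condition == condition and s.qc_status == "pass"]
    if not selected:
        raise ParameterError(f"no passing images for condition {condition!r}")
    agg = np.mean if aggregation == "mean" else np.median
    mean: dict[str, float] = {}
    sem: dict[str, float | None] = {}
    n = len(selected)
    for readout in READOUTS:
        values = np.array([s.readout(readout) for s in selected], dtype=float)
        mean[readout] = float(agg(values))
        sem[readout] = float(values.std(ddof=1) / math.sqrt(n)) if n >= 2 else None
    return ConditionSummary(condition=condition, mean=mean, sem=sem, n_images=n)


def deviation_score(
    test: ConditionSummary,
    neg: ConditionSummary,
    readout: str = "traffic_efficiency",
    k: float = 2.0,
) -> float:
    """(mean_test - mean_neg) / (k * sem_neg); |score| > 1 marks significance."""
    sem_neg = neg.sem.get(readout)
    if sem_neg is None or sem_neg == 0 or not np.isfinite(sem_neg):
        raise DegenerateControlError(
            f"negative control {neg.condition!r} has undefined or zero SEM for {readout!r}"
        )
    return (test.mean[readout] - neg.mean[readout]) / (k * sem_neg)


def classify_condition(score: float) -> str:
    """Enhancer above +1, inhibitor below -1, neutral otherwise (strict)."""
    if not np.isfinite(score):
        raise ParameterError(f"deviation score must be finite, got {score}")
    if score > ENHANCER_SCORE_THRESHOLD:
        return ENHANCER
    if score < INHIBITOR_SCORE_THRESHOLD:
        return INHIBITOR
    return NEUTRAL


def compare_condition(
    test_values: Sequence[float], neg_values: Sequence[float], welch: bool = False
) -> float:
    """Two-tailed two-sample Student's t-test p-value on per-image values."""
    test_values = np.asarray(test_values, dtype=float)
    neg_values = np.asarray(neg_values, dtype=float)
    if test_values.size < 2 or neg_values.size < 2:
        raise ParameterError("t-test requires at least 2 per-image values in each group")
    result = stats.ttest_ind(test_values, neg_values, equal_var=not welch)
    return float(result.pvalue)


def score_screen(
    image_summaries: Sequence[ImageSummary],
    negative_control: str,
    k: float = 2.0,
    aggregation: str = "mean",
    welch: bool = False,
) -> tuple[list[ConditionSummary], list[HitCall], list[str]]:
    """Score every condition versus the negative control, all three readouts.

    Returns condition summaries, hit calls, and the names of conditions
    excluded from scoring (single passing image, SEM undefined).
    """
    conditions = sorted({s.condition for s in image_summaries})
    if negative_control not in conditions:
        raise DegenerateControlError(
            f"negative control {negative_control!r} has no passing images"
        )
    summaries = {
        name: condition_summary(image_summaries, name, aggregation=aggregation)
        for name in conditions
    }
    neg = summaries[negative_control]
    if neg.n_images < 2:
        raise DegenerateControlError(
            f"negative control {negative_control!r} has fewer than 2 passing images"
        )
    neg_values = {
        readout: [
            s.readout(readout)
            for s in image_summaries
            if s.condition == negative_control and s.qc_status == "pass"
        ]
        for readout in READOUTS
    }
    hits: list[HitCall] = []
    excluded: list[str] = []
    for name in conditions:
        if name == negative_control:
            continue
        summary = summaries[name]
        if summary.n_images < 2:
            excluded.append(name)
            continue
        values = {
            readout: [
                s.readout(readout)
                for s in image_summaries
                if s.condition == name and s.qc_status == "pass"
            ]
            for readout in READOUTS
        }
        for readout in READOUTS:
            score = deviation_score(summary, neg, readout=readout, k=k)
            hits.append(
                HitCall(
                    condition=name,
                    readout=readout,
                    deviation_score=score,
                    classification=classify_condition(score),
                    p_value=compare_condition(values[readout], neg_values[readout], welch=welch),
                    negative_control_ref=negative_control,
                    sem_multiplier=k,
                )
            )
    return list(summaries.values()), hits, excluded
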