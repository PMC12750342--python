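"""Four-quadrant applicability analysis and soil-quality classification.

A (soil threshold, grain limit) pair classifies each site by the sign pair
(ln(soil/threshold), ln(grain/limit)) into quadrant I (both exceed: true
positive), II (soil safe, grain exceeds: false negative), III (both safe:
true negative) or IV (soil exceeds, grain safe: false positive). Sites
exactly on a boundary count as safe. The false-positive/false-negative
rates are quadrant shares of all classified sites, so the three reported
rates sum to 100%.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .core import (
    PH_BINS,
    RICE_COLUMNS,
    SOIL_TOTAL_COLUMNS,
    Dataset,
    PhBin,
    RegulatoryLimits,
    assign_ph_bin,
)
from .safety import ThresholdSet

QUADRANTS = ("I", "II", "III", "IV")
SEVERITY = {"I": 1, "II": 2, "III": 3}  # quality classes, I least severe


@dataclass
class QuadrantResult:
    element: str
    counts: dict[str, int]
    labels: dict[str, str]
    soil_threshold_used: float | Mapping[str, float]
    grain_limit_used: float
    skipped: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return sum(self.counts.values())


@dataclass
class CriterionScore:
    element: str
    ph_bin: str
    criterion: str  # RSV, ST, RIV or HT
    value: float  # soil threshold applied, mg·kg⁻¹
    n: int
    accuracy: float
    false_positive_rate: float
    false_negative_rate: float


@dataclass
class QualityClass:
    """Per-site quality class: I priority protection, II controllable risk,
    III strict control. Composite is the worst per-element class."""

    site_id: str
    clazz: str
    per_element: dict[str, str]


def _quadrant(soil: float, threshold: float, grain: float, limit: float) -> str:
    # boundary ties (ratio exactly 1) fall on the safe (<= 0) branch
    soil_exceeds = math.log(soil / threshold) > 0
    grain_exceeds = math.log(grain / limit) > 0
    if soil_exceeds:
        return "I" if grain_exceeds else "IV"
    return "II" if grain_exceeds else "III"


def quadrant_classify(
    dataset: Dataset | pd.DataFrame,
    element: str,
    soil_threshold: float | Mapping[str, float],
    grain_limit: float,
) -> QuadrantResult:
    """Classify every site into a quadrant.

    ``soil_threshold`` is a single value or a map of pH-bin label to value;
    in the latter case sites whose pH resolves to no bin are skipped with a
    warning and listed in ``skipped``.
    """
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    per_bin = not isinstance(soil_threshold, (int, float))
    counts = {q: 0 for q in QUADRANTS}
    labels: dict[str, str] = {}
    skipped: list[str] = []
    soil_col, rice_col = SOIL_TOTAL_COLUMNS[element], RICE_COLUMNS[element]
    for _, row in frame.iterrows():
        sid = str(row["site_id"])
        if per_bin:
            b = assign_ph_bin(float(row["pH"]))
            if b is None or b.label not in soil_threshold:
                skipped.append(sid)
                continue
            thr = float(soil_threshold[b.label])
        else:
            thr = float(soil_threshold)
        q = _quadrant(float(row[soil_col]), thr, float(row[rice_col]), grain_limit)
        counts[q] += 1
        labels[sid] = q
    if skipped:
        warnings.warn(
            f"{len(skipped)} sample(s) outside supported pH bins skipped",
            stacklevel=2,
        )
    return QuadrantResult(
        element=element,
        counts=counts,
        labels=labels,
        soil_threshold_used=soil_threshold,
        grain_limit_used=grain_limit,
        skipped=skipped,
    )


def misclassification_rates(result: QuadrantResult) -> tuple[float, float, float]:
    """(accuracy, false-positive rate, false-negative rate), percent.

    accuracy = (I + III)/n, fp = IV/n, fn = II/n — shares of all classified
    sites, summing to exactly 100 before any rounding.
    """
    n = result.n
    if n == 0:
        raise ValueError("empty quadrant result")
    acc = 100.0 * (result.counts["I"] + result.counts["III"]) / n
    fp = 100.0 * result.counts["IV"] / n
    fn = 100.0 * result.counts["II"] / n
    return acc, fp, fn


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal rounding with halves away from zero (report formatting)."""
    factor = 10.0 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def score_criteria(
    dataset: Dataset | pd.DataFrame,
    element: str,
    limits: Mapping[tuple[str, str], RegulatoryLimits],
    thresholds: Sequence[ThresholdSet],
    grain_limit: float | None = None,
    bins: tuple[PhBin, ...] = PH_BINS,
) -> list[CriterionScore]:
    """Accuracy/FP/FN per pH bin for each criterion RSV, ST, RIV, HT.

    Each criterion's soil value is applied to the samples of its own bin
    only; rates are shares of that bin's sample count.
    """
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    ts = {(t.element, t.ph_bin): t for t in thresholds}
    out = []
    for b in bins:
        lim = limits[(element, b.label)]
        gl = lim.mac if grain_limit is None else grain_limit
        sub = frame[frame["pH"].map(lambda p, b=b: b.contains(float(p)))]
        t = ts.get((element, b.label))
        criterion_values = {
            "RSV": lim.rsv,
            "ST": t.st if t else None,
            "RIV": lim.riv,
            "HT": t.ht if t else None,
        }
        for criterion, value in criterion_values.items():
            if value is None:
                raise ValueError(
                    f"no {criterion} threshold available for {element}/{b.label}"
                )
            if len(sub) == 0:
                out.append(
                    CriterionScore(element, b.label, criterion, float(value), 0,
                                   float("nan"), float("nan"), float("nan"))
                )
                continue
            res = quadrant_classify(sub, element, float(value), gl)
            acc, fp, fn = misclassification_rates(res)
            out.append(
                CriterionScore(element, b.label, criterion, float(value),
                               res.n, acc, fp, fn)
            )
    return out


def classify_quality(
    dataset: Dataset | pd.DataFrame,
    thresholds: Mapping[str, Mapping[str, tuple[float, float]]],
    demote_when_grain_safe: bool = False,
    grain_limits: Mapping[str, float] | None = None,
) -> list[QualityClass]:
    """Three-class quality assignment per site under a (lower, upper) system.

    ``thresholds[element][ph_bin]`` is the (lower, upper) pair — (RSV, RIV)
    for the national system or (ST, HT) for the regional one. Per element:
    class I when the soil total is at or below the lower value, II up to
    the upper value, III above it; exact boundary ties go to the safer
    class. The composite class is the worst across elements. With
    ``demote_when_grain_safe``, class III drops to II when the site's
    measured grain is within its limit (co-monitoring override).
    """
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    out = []
    for _, row in frame.iterrows():
        sid = str(row["site_id"])
        per_element: dict[str, str] = {}
        for el, per_bin in thresholds.items():
            b = assign_ph_bin(float(row["pH"]))
            if b is None or b.label not in per_bin:
                continue
            lower, upper = per_bin[b.label]
            c = float(row[SOIL_TOTAL_COLUMNS[el]])
            if c <= lower:
                clazz = "I"
            elif c <= upper:
                clazz = "II"
            else:
                clazz = "III"
            if clazz == "III" and demote_when_grain_safe and grain_limits:
                if float(row[RICE_COLUMNS[el]]) <= grain_limits[el]:
                    clazz = "II"
            per_element[el] = clazz
        if not per_element:
            continue
        composite = max(per_element.values(), key=lambda c: SEVERITY[c])
        out.append(QualityClass(site_id=sid, clazz=composite, per_element=per_element))
    return out


def tally_classes(classes: Sequence[QualityClass]) -> dict[str, int]:
    tally = {"I": 0, "II": 0, "III": 0}
    for qc in classes:
        tally[qc.clazz] += 1
    return tally
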