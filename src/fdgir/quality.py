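"""Reference selection and good/poor input-quality classification.

Two screens operate on peak-aligned plasma curves:

* Reference selection — a curve qualifies as reference-grade when its
  peak-to-washout ratio RT (peak activity over the activity at UAVt + 2.5
  min) reaches the population threshold RT1 (the boundary between the third
  and fourth quarters of the RT distribution, i.e. its 75th percentile), its
  peak time is at most UAVt + 1 min, and its peak reaches 50 kBq/mL.

* Quality classification — a linear selection rule on the SUV-scaled peak
  height and the peak-to-5-min ratio:

      selection value = -0.36 + 0.038 * maxSUV + 0.052 * peak/5th

  with curves at or above 0.47 labelled good and the rest poor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import PeakAlignment, find_peak_time
from .tac import SubjectMeta, TimeActivityCurve, to_suv

__all__ = [
    "QualityScore",
    "SELECTION_COEFFS",
    "SELECTION_THRESHOLD",
    "compute_rt",
    "select_reference",
    "selection_value",
    "quality_score",
]

#: intercept and slopes (maxSUV, peak/5th) of the linear selection rule
SELECTION_COEFFS = (-0.36, 0.038, 0.052)
#: good/poor decision threshold on the selection value (ties -> good)
SELECTION_THRESHOLD = 0.47

#: reference-selection constants
PEAK_FLOOR_KBQ_ML = 50.0
RT_WASHOUT_OFFSET_MIN = 2.5
PEAK_TIME_SLACK_MIN = 1.0
RT1_PERCENTILE = 75.0


@dataclass(frozen=True)
class QualityScore:
    max_suv: float
    peak_to_5th: float
    selection_value: float
    label: str  # "good" | "poor"


def compute_rt(curve: TimeActivityCurve, uav_t: float) -> float:
    """Peak activity divided by the (interpolated) activity at UAVt + 2.5 min."""
    t_wash = uav_t + RT_WASHOUT_OFFSET_MIN
    if not (curve.times[0] <= t_wash <= curve.times[-1]):
        raise ValueError(
            f"curve does not bracket the washout time {t_wash:.2f} min")
    denom = float(np.interp(t_wash, curve.times, curve.activities))
    if denom == 0:
        raise ZeroDivisionError("activity at UAVt + 2.5 min is zero")
    return curve.max_activity / denom


def select_reference(curves: Sequence[TimeActivityCurve],
                     alignment: PeakAlignment,
                     peak_floor: float = PEAK_FLOOR_KBQ_ML,
                     rt_percentile: float = RT1_PERCENTILE,
                     ) -> tuple[list[str], float]:
    """Select reference-grade peak-aligned curves.

    Returns the selected curve names and the RT1 threshold actually used.
    An empty selection is returned as-is (the caller decides how to react).
    """
    if len(curves) < 8:
        raise ValueError("reference selection needs at least 8 aligned curves")
    rts = np.array([compute_rt(c, alignment.uav_t) for c in curves])
    rt1 = float(np.percentile(rts, rt_percentile))
    selected = []
    for c, rt in zip(curves, rts):
        peak_t = find_peak_time(c)
        if (rt >= rt1 and peak_t <= alignment.uav_t + PEAK_TIME_SLACK_MIN
                and c.max_activity >= peak_floor):
            selected.append(c.name)
    return selected, rt1


def selection_value(max_suv: float, peak_to_5th: float,
                    coeffs: tuple[float, float, float] = SELECTION_COEFFS) -> float:
    """The linear selection rule applied to precomputed features."""
    b0, b1, b2 = coeffs
    return b0 + b1 * max_suv + b2 * peak_to_5th


def quality_score(curve: TimeActivityCurve,
                  meta: SubjectMeta | None = None,
                  coeffs: tuple[float, float, float] = SELECTION_COEFFS,
                  threshold: float = SELECTION_THRESHOLD) -> QualityScore:
    """Linear good/poor classification of an input curve.

    ``peak/5th`` uses the activity linearly interpolated at exactly 5 min;
    the curve must therefore cover [0, 5] min.
    """
    meta = meta or curve.meta
    if meta is None:
        raise ValueError("quality_score requires SubjectMeta (dose, weight)")
    if curve.times[-1] < 5.0:
        raise ValueError("curve must extend to at least 5 min")
    suv = to_suv(curve, meta)
    max_suv = suv.max_activity
    at5 = float(np.interp(5.0, curve.times, curve.activities))
    if at5 <= 0:
        raise ZeroDivisionError("activity at 5 min is non-positive")
    peak_to_5th = curve.max_activity / at5
    value = selection_value(max_suv, peak_to_5th, coeffs)
    label = "good" if value >= threshold else "poor"
    return QualityScore(max_suv=float(max_suv), peak_to_5th=float(peak_to_5th),
                        selection_value=float(value), label=label)
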