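"""Input-curve onset cleaning and population peak alignment.

Plasma curves sampled by hand carry noisy, sometimes negative onsets and
subject-specific tracer arrival delays.  This stage (a) floors spuriously
low leading samples against a population threshold, (b) locates each curve's
peak (with a mid-time rule for near-equal double peaks), (c) extrapolates
the start of the ascending limb, and (d) aligns every peak to a common
population delay time, the upper adjacent value of the peak-time
distribution (largest peak time <= Q3 + 1.5*IQR).  Per-curve delays are
stored so the shift can be undone before kinetic modelling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .tac import TimeActivityCurve

__all__ = [
    "PeakAlignment",
    "floor_low_onsets",
    "find_peak_time",
    "estimate_ascent_start",
    "align_peaks",
    "restore_delay",
]


@dataclass
class PeakAlignment:
    """Population alignment state.

    uav_t
        Population delay time: the largest observed peak time that does not
        exceed the Tukey upper inner fence (Q3 + 1.5*IQR) of peak times.
    delays
        Per-curve rightward shift dt >= 0 applied to align its peak to
        ``uav_t`` (0 for curves already at or beyond it).
    """

    uav_t: float
    delays: dict[str, float] = field(default_factory=dict)
    peak_times: dict[str, float] = field(default_factory=dict)
    floor_threshold: float | None = None

    def delay_of(self, curve: TimeActivityCurve) -> float:
        return self.delays.get(_key(curve), 0.0)


def _key(curve: TimeActivityCurve) -> str:
    return curve.name or f"id{id(curve)}"


# ---------------------------------------------------------------------------


def floor_low_onsets(curves: Sequence[TimeActivityCurve],
                     iterative: bool = True,
                     ) -> tuple[list[TimeActivityCurve], float]:
    """Zero spuriously low leading samples against a population threshold.

    The threshold is the median over curves of each curve's first non-zero
    activity.  For every curve, the leading first non-zero sample is set to
    0 while it lies below the threshold; with ``iterative=True`` (default)
    the rule is re-applied to the next leading non-zero sample until one
    reaches the threshold.  Samples at or after the first above-threshold
    sample are never touched.  Negative leading values count as non-zero and
    are floored the same way.
    """
    if len(curves) < 2:
        raise ValueError("flooring threshold needs at least 2 curves")
    firsts = []
    for c in curves:
        nz = np.nonzero(c.activities)[0]
        if nz.size == 0:
            raise ValueError(f"curve {c.name!r} is all zero")
        firsts.append(abs(c.activities[nz[0]]))
    threshold = float(np.median(firsts))

    out = []
    for c in curves:
        acts = c.activities.copy()
        while True:
            nz = np.nonzero(acts)[0]
            if nz.size == 0:
                raise ValueError(f"curve {c.name!r} floored to all-zero")
            i = nz[0]
            if abs(acts[i]) < threshold:
                acts[i] = 0.0
                if not iterative:
                    break
            else:
                break
        out.append(c.with_values(activities=acts))
    return out, threshold


def find_peak_time(curve: TimeActivityCurve, near_tol: float = 0.10) -> float:
    """Time of the curve maximum, with a double-peak mid-time rule.

    If a second local maximum lies within ``near_tol`` (10%) of the global
    maximum, the mid-time between the two peaks is returned.
    """
    a = curve.activities
    if np.max(a) <= 0:
        raise ValueError("curve has no positive maximum")
    imax = int(np.argmax(a))
    # interior local maxima (plateau-tolerant: >= both neighbours, > one)
    locs = [i for i in range(1, len(a) - 1)
            if a[i] >= a[i - 1] and a[i] >= a[i + 1]
            and (a[i] > a[i - 1] or a[i] > a[i + 1])]
    rivals = [i for i in locs if i != imax and a[i] > 0]
    if rivals:
        j = max(rivals, key=lambda i: a[i])
        if (a[imax] - a[j]) / a[imax] < near_tol:
            return float(0.5 * (curve.times[imax] + curve.times[j]))
    return float(curve.times[imax])


def estimate_ascent_start(curve: TimeActivityCurve) -> float:
    """Extrapolated time at which the ascending limb crosses zero.

    With <= 2 samples strictly between the first non-zero sample and the
    peak, a straight line is fitted through the ascending samples and its
    zero crossing returned; with more, a quadratic is fitted and its latest
    real root before the peak is used.  The result is clamped to
    [0, first-non-zero time].
    """
    nz = np.nonzero(curve.activities)[0]
    if nz.size == 0:
        raise ValueError("all-zero curve")
    i0 = int(nz[0])
    ip = int(np.argmax(curve.activities))
    if ip <= i0:
        raise ValueError("peak at or before the first non-zero sample")
    t = curve.times[i0:ip + 1]
    y = curve.activities[i0:ip + 1]
    n_between = ip - i0 - 1
    t_first = float(curve.times[i0])
    if n_between <= 2:
        slope, intercept = np.polyfit(t, y, 1)
        if slope <= 0:
            return 0.0
        root = -intercept / slope
    else:
        coeffs = np.polyfit(t, y, 2)
        roots = np.roots(coeffs)
        real = [float(r.real) for r in roots
                if abs(r.imag) < 1e-6 and r.real < curve.times[ip]]
        if not real:
            return 0.0
        root = max(real)
    return float(min(max(root, 0.0), t_first))


def _upper_adjacent(values: np.ndarray) -> float:
    """Largest observation <= Q3 + 1.5*IQR (linear-interpolation quartiles)."""
    q1, q3 = np.percentile(values, [25, 75])
    fence = q3 + 1.5 * (q3 - q1)
    inside = values[values <= fence]
    if inside.size == 0:  # cannot happen for finite data, but be safe
        return float(np.max(values))
    return float(np.max(inside))


def align_peaks(curves: Sequence[TimeActivityCurve],
                ) -> tuple[list[TimeActivityCurve], PeakAlignment]:
    """Shift every curve so its peak sits at the population delay time.

    UAVt is the largest peak time not exceeding the Tukey upper inner fence
    of the peak-time distribution.  Curves with earlier peaks are shifted
    right by dt = UAVt - peak time (a (0, 0) anchor sample is inserted so
    integrals still start at t = 0); curves at or beyond UAVt get dt = 0.
    """
    if len(curves) < 4:
        raise ValueError("peak alignment needs at least 4 curves")
    peaks = np.array([find_peak_time(c) for c in curves])
    uav_t = _upper_adjacent(peaks)
    alignment = PeakAlignment(uav_t=uav_t)
    aligned = []
    for c, pk in zip(curves, peaks):
        dt = max(uav_t - pk, 0.0)
        alignment.peak_times[_key(c)] = float(pk)
        alignment.delays[_key(c)] = float(dt)
        if dt > 0:
            times = c.times + dt
            acts = c.activities
            if times[0] > 0:
                times = np.concatenate(([0.0], times))
                acts = np.concatenate(([0.0], acts))
            aligned.append(c.with_values(times, acts))
        else:
            aligned.append(c.with_values())
    return aligned, alignment


def restore_delay(curve: TimeActivityCurve, dt: float) -> TimeActivityCurve:
    """Undo a peak-alignment shift: times -= dt, dropping negative times."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if dt == 0:
        return curve.with_values()
    times = curve.times - dt
    keep = times >= 0
    return curve.with_values(times[keep], curve.activities[keep])
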