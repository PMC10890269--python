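"""Core time-activity-curve (TAC) types, metrics and file I/O.

The whole pipeline trades in one currency: a sampled, decay-corrected
activity-concentration curve, with time in minutes post-injection and
activity in kBq/mL.  Plasma input functions and tissue ROI curves share the
same container.  Curve summary metrics follow standard pharmacokinetic
definitions:

    AUC  = integral of c(t) over the sampled support        [kBq/mL*min]
    AUMC = integral of c(t)*t (first-moment curve)          [kBq/mL*min^2]
    MRT  = AUMC / AUC                                       [min]
    VSS  = Dose * MRT / AUC  (steady-state volume)          [L]
    SUV  = c(t) * body weight / injected dose               [g/mL]

All integrals are trapezoidal on the sampled grid with linear interpolation
at window edges; curves are assumed decay-corrected on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "SubjectMeta",
    "TimeActivityCurve",
    "CurveMetrics",
    "read_tac",
    "write_tac",
    "read_tissue_table",
    "to_suv",
    "trapezoid_auc",
    "curve_metrics",
]


@dataclass(frozen=True)
class SubjectMeta:
    """Per-subject study metadata.

    dose_mbq
        Injected activity in MBq.
    weight_kg
        Body weight in kg.
    hematocrit
        Haematocrit as a fraction in (0, 1).
    cbf
        Optional cerebral blood flow in mL blood / mL tissue / min, used to
        derive the theoretical K1 upper bound.
    """

    subject_id: str = ""
    dose_mbq: float = float("nan")
    weight_kg: float = float("nan")
    hematocrit: float = float("nan")
    cbf: Optional[float] = None

    def validate(self) -> "SubjectMeta":
        if not (self.dose_mbq > 0):
            raise ValueError(f"dose_mbq must be > 0, got {self.dose_mbq}")
        if not (self.weight_kg > 0):
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")
        if not (0.0 < self.hematocrit < 1.0):
            raise ValueError(
                f"hematocrit must be in (0,1), got {self.hematocrit}"
            )
        return self


@dataclass
class TimeActivityCurve:
    """Sampled activity concentration versus time.

    times
        Minutes post-injection, strictly increasing, >= 0, length >= 3.
    activities
        Activity concentration in kBq/mL (decay-corrected).  Raw curves may
        contain small negative onset values; preprocessing floors them.
    frames
        Optional (n, 2) array of frame [start, end] bounds in minutes for
        frame-averaged tissue curves.
    """

    times: np.ndarray
    activities: np.ndarray
    label: str = "plasma"
    name: str = ""
    meta: Optional[SubjectMeta] = None
    frames: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.ndim != 1 or self.activities.ndim != 1:
            raise ValueError("times and activities must be 1-D")
        if self.times.size != self.activities.size:
            raise ValueError("times and activities must have equal length")
        if self.times.size < 3:
            raise ValueError("curve must have at least 3 samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")
        if not np.all(np.isfinite(self.activities)):
            raise ValueError("activities must be finite")
        if self.frames is not None:
            self.frames = np.asarray(self.frames, dtype=float)

    # -- convenience -----------------------------------------------------
    def __len__(self) -> int:
        return int(self.times.size)

    def interp(self, t) -> np.ndarray:
        """Linear interpolation of activity at time(s) ``t`` (0 outside)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.activities,
                         left=0.0, right=0.0)

    @property
    def max_activity(self) -> float:
        return float(np.max(self.activities))

    @property
    def max_time(self) -> float:
        return float(self.times[int(np.argmax(self.activities))])

    def with_values(self, times=None, activities=None, **kw) -> "TimeActivityCurve":
        """Copy with replaced arrays/fields."""
        new = replace(self)
        if times is not None:
            new.times = np.asarray(times, dtype=float)
        if activities is not None:
            new.activities = np.asarray(activities, dtype=float)
        for k, v in kw.items():
            setattr(new, k, v)
        new.__post_init__()
        return new

    def window(self, t0: float, t1: float) -> "TimeActivityCurve":
        """Sub-curve of samples with t0 <= t <= t1."""
        m = (self.times >= t0) & (self.times <= t1)
        if m.sum() < 3:
            raise ValueError(f"window [{t0}, {t1}] holds fewer than 3 samples")
        return self.with_values(self.times[m], self.activities[m])


@dataclass(frozen=True)
class CurveMetrics:
    auc: float                 # kBq/mL*min
    aumc: float                # kBq/mL*min^2
    mrt: float                 # min
    max_activity: float        # kBq/mL
    max_time: float            # min
    vss: Optional[float] = None  # liters (requires dose)


# ---------------------------------------------------------------------------
# File I/O: delimited text, 2 columns (time, activity), '#' header lines may
# declare units, e.g. "# time[s]  activity[Bq/cc]".  Comma, tab or whitespace
# delimited.  Times are converted to minutes and activities to kBq/mL.
# ---------------------------------------------------------------------------

_TIME_UNITS = {"min": 1.0, "minutes": 1.0, "s": 1.0 / 60.0, "sec": 1.0 / 60.0,
               "seconds": 1.0 / 60.0}
_ACT_UNITS = {"kbq/ml": 1.0, "kbq/cc": 1.0, "bq/ml": 1e-3, "bq/cc": 1e-3,
              "mbq/ml": 1e3}


def _parse_units(header_lines: Sequence[str]) -> tuple[float, float]:
    tf, af = 1.0, 1.0
    for line in header_lines:
        text = line.lstrip("#").strip().lower()
        for token in text.replace(",", " ").split():
            if "[" in token and token.endswith("]"):
                name, unit = token.split("[", 1)
                unit = unit[:-1]
                if name.startswith("time"):
                    if unit not in _TIME_UNITS:
                        raise ValueError(f"unknown time unit {unit!r} in header {line!r}")
                    tf = _TIME_UNITS[unit]
                elif name.startswith(("activity", "conc", "value")):
                    if unit not in _ACT_UNITS:
                        raise ValueError(f"unknown activity unit {unit!r} in header {line!r}")
                    af = _ACT_UNITS[unit]
    return tf, af


def _split_row(line: str) -> list[str]:
    if "," in line:
        return [p for p in line.split(",") if p.strip()]
    return line.split()


def read_tac(path, label: str = "plasma", name: str = "") -> TimeActivityCurve:
    """Read a two-column delimited TAC file.

    '#'-prefixed header lines may declare units (``time[min]``/``time[s]``,
    ``activity[kBq/mL]``/``activity[Bq/cc]``); values are converted to
    minutes and kBq/mL.  Non-monotonic times raise.
    """
    headers, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                headers.append(line)
                continue
            parts = _split_row(line)
            if len(parts) < 2:
                raise ValueError(f"{path}: expected 2 columns, got {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise ValueError(f"{path}: no data rows")
    tf, af = _parse_units(headers)
    arr = np.asarray(rows, dtype=float)
    times = arr[:, 0] * tf
    acts = arr[:, 1] * af
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: times are not strictly increasing")
    return TimeActivityCurve(times, acts, label=label,
                             name=name or os.path.splitext(os.path.basename(path))[0])


def write_tac(curve: TimeActivityCurve, path) -> None:
    """Write a curve as comma-delimited text (minutes, kBq/mL).

    The format is fixed-width-free and deterministic: two identical curves
    produce byte-identical files.
    """
    lines = ["# time[min],activity[kbq/ml]"]
    for t, a in zip(curve.times, curve.activities):
        lines.append(f"{float(t)!r},{float(a)!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_tissue_table(path) -> dict[str, TimeActivityCurve]:
    """Read a multi-ROI tissue file: time column plus one named ROI column.

    The single '#' header row names the columns; the first must be time.
    """
    headers, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                headers.append(line)
            else:
                rows.append([float(x) for x in _split_row(line)])
    if not headers:
        raise ValueError(f"{path}: multi-ROI file requires a '#' header row")
    names = _split_row(headers[-1].lstrip("#").strip())
    tf, af = _parse_units(headers[:-1] or headers)
    arr = np.asarray(rows, dtype=float)
    times = arr[:, 0] * tf
    out = {}
    for j, roi in enumerate(names[1:], start=1):
        out[roi] = TimeActivityCurve(times, arr[:, j] * af, label="tissue", name=roi)
    return out


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def to_suv(curve: TimeActivityCurve, meta: Optional[SubjectMeta] = None) -> TimeActivityCurve:
    """Body-weight standardized uptake value curve.

    suv(t) = activity(t)[kBq/mL] * weight[kg] / dose[MBq]; unitless up to the
    conventional 1 g/mL tissue density.
    """
    meta = meta or curve.meta
    if meta is None or not (meta.dose_mbq > 0) or not (meta.weight_kg > 0):
        raise ValueError("to_suv requires SubjectMeta with dose and weight")
    scale = meta.weight_kg / meta.dose_mbq
    return curve.with_values(activities=curve.activities * scale, label=curve.label)


def trapezoid_auc(curve: TimeActivityCurve, t0: float, t1: float) -> float:
    """Trapezoidal integral of the curve over [t0, t1].

    The window is intersected with the sampled support; edge values are
    linearly interpolated.  A window entirely outside the support raises.
    """
    if not t0 < t1:
        raise ValueError(f"need t0 < t1, got [{t0}, {t1}]")
    lo, hi = curve.times[0], curve.times[-1]
    a, b = max(t0, lo), min(t1, hi)
    if a >= b:
        raise ValueError(
            f"window [{t0}, {t1}] does not overlap support [{lo}, {hi}]")
    inner = curve.times[(curve.times > a) & (curve.times < b)]
    grid = np.concatenate(([a], inner, [b]))
    vals = np.interp(grid, curve.times, curve.activities)
    return float(np.trapezoid(vals, grid))


def curve_metrics(curve: TimeActivityCurve,
                  meta: Optional[SubjectMeta] = None) -> CurveMetrics:
    """AUC, AUMC, MRT (and VSS when dose is known) over the sampled support."""
    meta = meta or curve.meta
    auc = float(np.trapezoid(curve.activities, curve.times))
    if auc <= 0:
        raise ValueError("curve has non-positive AUC; metrics undefined")
    aumc = float(np.trapezoid(curve.activities * curve.times, curve.times))
    mrt = aumc / auc
    vss = None
    if meta is not None and meta.dose_mbq > 0:
        # dose[kBq] * MRT / AUC -> mL; report liters.
        vss = meta.dose_mbq * 1e3 * mrt / auc / 1e3
    return CurveMetrics(auc=auc, aumc=aumc, mrt=mrt,
                        max_activity=curve.max_activity,
                        max_time=curve.max_time, vss=vss)
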