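"""Irreversible two-tissue compartment (3k) modelling, K1max screening, FUR.

The FDG brain model has plasma Cp feeding a free compartment Cf (rates K1
in, k2 out) which feeds an irreversibly trapped compartment Cb at rate k3
(k4 = 0; phosphorylated FDG is not dephosphorylated on the experiment's
time scale).  With a = k2 + k3 the analytic solution is

    Cf(t) + Cb(t) = K1*k3/a * int_0^t Cp
                    + K1*k2/a * (exp(-a t) (*) Cp)            [kBq/mL]
    C_PET(t)      = (1 - vB) * (Cf + Cb) + vB * Cp

with the vascular fraction fixed at vB = 0.05.  Fitting is done in the
(K1, K1/k2, k3) parameterization; the net influx constant Ki is derived
(canonically Ki = K1*k3/(k2+k3)).

Physiological plausibility of fitted K1 is screened against the perfusion
limit K1max = CBF*(1 - hematocrit) (cerebral plasma flow at unit
extraction): a delivery rate constant cannot exceed the plasma flow.

The fractional uptake rate FUR(T) = C_tissue(T) / int_0^T Cp is the
late-scan retention index approximating Ki.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .tac import TimeActivityCurve

__all__ = [
    "KineticParameters",
    "PerfusionConstraint",
    "FurResult",
    "simulate_2tcm",
    "fit_2tcm",
    "derive_ki",
    "k1max",
    "plausibility_screen",
    "compute_fur",
]

VB_FIXED = 0.05
CONV_STEP_MIN = 0.02  # dense convolution grid step

#: fit bounds in the (K1, K1/k2, k3) parameterization
K1_BOUNDS = (0.0, 1.0)
V_BOUNDS = (0.01, 10.0)
K3_BOUNDS = (0.0, 0.5)


@dataclass(frozen=True)
class KineticParameters:
    """3k rate constants with fixed vascular fraction and fit diagnostics."""

    k1: float                  # mL plasma / mL tissue / min
    k2: float                  # 1/min
    k3: float                  # 1/min
    vb: float = VB_FIXED
    wrss: float = float("nan")
    at_bound: tuple[str, ...] = ()
    converged: bool = True

    @property
    def ki(self) -> float:
        return derive_ki(self.k1, self.k2, self.k3)


@dataclass(frozen=True)
class PerfusionConstraint:
    """Perfusion-derived delivery bound: K1max = CBF*(1-Htk)*Extraction."""

    cbf: float          # mL blood / mL tissue / min
    hematocrit: float
    cpf: float          # cerebral plasma flow, mL/mL/min
    k1max: float        # mL/mL/min
    extraction: float = 1.0


@dataclass(frozen=True)
class FurResult:
    fur: float              # 1/min
    eval_time: float        # min (mean of frame times used)
    input_auc_0_t: float    # kBq/mL*min at eval_time
    per_frame: tuple[float, ...] = ()


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def _dense_grid(t_end: float, step: float = CONV_STEP_MIN) -> np.ndarray:
    n = int(np.ceil(t_end / step)) + 1
    return np.linspace(0.0, step * (n - 1), n)


def _exp_conv(theta: float, cp: np.ndarray, dt: float) -> np.ndarray:
    """y(t) = int_0^t exp(-theta (t-s)) cp(s) ds, exact for piecewise-linear
    cp on a uniform grid (recursive update via a first-order filter)."""
    if theta == 0.0:
        return cumulative_trapezoid(cp, dx=dt, initial=0.0)
    e = np.exp(-theta * dt)
    c0 = cp[:-1]
    m = (cp[1:] - cp[:-1]) / dt
    drive = c0 * (1.0 - e) / theta + m * (dt * theta - (1.0 - e)) / theta ** 2
    y = lfilter([1.0], [1.0, -e], drive)
    return np.concatenate(([0.0], y))


def _frame_average(grid: np.ndarray, values: np.ndarray,
                   frames: np.ndarray) -> np.ndarray:
    cum = cumulative_trapezoid(values, grid, initial=0.0)
    starts = np.interp(frames[:, 0], grid, cum)
    ends = np.interp(frames[:, 1], grid, cum)
    return (ends - starts) / (frames[:, 1] - frames[:, 0])


def _as_frames(frame_times) -> np.ndarray:
    frames = np.asarray(frame_times, dtype=float)
    if frames.ndim != 2 or frames.shape[1] != 2:
        raise ValueError("frame_times must be an (n, 2) array of [start, end]")
    if np.any(frames[:, 1] <= frames[:, 0]):
        raise ValueError("frame ends must exceed frame starts")
    return frames


def simulate_2tcm(input_curve: TimeActivityCurve,
                  params: KineticParameters,
                  frame_times,
                  step: float = CONV_STEP_MIN) -> TimeActivityCurve:
    """Frame-averaged tissue curve from the irreversible 2TCM.

    The plasma input is linearly interpolated onto a dense uniform grid
    (0 before its first sample); the exponential convolution is exact for
    the piecewise-linear input; frame averages use trapezoids within the
    frame bounds.  The returned curve's times are frame midpoints and the
    frame bounds travel along in ``frames``.
    """
    frames = _as_frames(frame_times)
    if input_curve.times[-1] < frames[-1, 1] - 1e-9:
        raise ValueError("input does not cover the last frame end")
    grid = _dense_grid(frames[-1, 1], step)
    cp = np.interp(grid, input_curve.times, input_curve.activities,
                   left=0.0, right=float(input_curve.activities[-1]))
    a = params.k2 + params.k3
    icp = cumulative_trapezoid(cp, grid, initial=0.0)
    if a == 0.0:
        tissue = params.k1 * icp
    else:
        tissue = (params.k1 * params.k3 / a) * icp \
            + (params.k1 * params.k2 / a) * _exp_conv(a, cp, grid[1] - grid[0])
    c_pet = (1.0 - params.vb) * tissue + params.vb * cp
    vals = _frame_average(grid, c_pet, frames)
    mids = frames.mean(axis=1)
    return TimeActivityCurve(mids, vals, label="tissue",
                             name=input_curve.name, frames=frames)


# ---------------------------------------------------------------------------
# Inverse problem
# ---------------------------------------------------------------------------

_DEFAULT_STARTS = (
    (0.10, 0.60, 0.05),
    (0.05, 0.30, 0.03),
    (0.30, 1.00, 0.10),
)


def fit_2tcm(tissue: TimeActivityCurve,
             input_curve: TimeActivityCurve,
             frames=None,
             vb: float = VB_FIXED,
             starts: Sequence[tuple[float, float, float]] = _DEFAULT_STARTS,
             step: float = CONV_STEP_MIN) -> KineticParameters:
    """Bounded least squares in the (K1, K1/k2, k3) parameterization.

    Uniform frame weights.  Multi-start from a small set of physiologic
    initial points; the best optimum is kept.  Parameters within numerical
    distance of their box bounds are flagged as saturated ("touching the
    boundaries") rather than rejected.
    """
    frames = _as_frames(frames if frames is not None else tissue.frames)
    y = tissue.activities
    lo = np.array([K1_BOUNDS[0], V_BOUNDS[0], K3_BOUNDS[0]])
    hi = np.array([K1_BOUNDS[1], V_BOUNDS[1], K3_BOUNDS[1]])

    # precompute dense input and operators once
    grid = _dense_grid(frames[-1, 1], step)
    cp = np.interp(grid, input_curve.times, input_curve.activities,
                   left=0.0, right=float(input_curve.activities[-1]))
    icp = cumulative_trapezoid(cp, grid, initial=0.0)
    dt = grid[1] - grid[0]
    cum_w = {}

    def model(p):
        k1, v, k3 = p
        k2 = k1 / v
        a = k2 + k3
        if a <= 0:
            tissue_d = k1 * icp
        else:
            tissue_d = (k1 * k3 / a) * icp + (k1 * k2 / a) * _exp_conv(a, cp, dt)
        c_pet = (1.0 - vb) * tissue_d + vb * cp
        return _frame_average(grid, c_pet, frames)

    def resid(p):
        return model(p) - y

    best = None
    for p0 in starts:
        p0 = np.clip(np.asarray(p0, float), lo + 1e-9, hi - 1e-9)
        sol = least_squares(resid, p0, bounds=(lo, hi), method="trf",
                            ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    k1, v, k3 = best.x
    k2 = k1 / v
    tol = 1e-6
    flags = []
    for name, val, (blo, bhi) in (("k1", k1, K1_BOUNDS),
                                  ("k1_k2", v, V_BOUNDS),
                                  ("k3", k3, K3_BOUNDS)):
        if val - blo <= tol * max(1.0, bhi - blo) or bhi - val <= tol * max(1.0, bhi - blo):
            flags.append(name)
    return KineticParameters(k1=float(k1), k2=float(k2), k3=float(k3), vb=vb,
                             wrss=float(2.0 * best.cost),
                             at_bound=tuple(flags),
                             converged=bool(best.success))


def derive_ki(k1: float, k2: float, k3: float,
              convention: str = "canonical") -> float:
    """Net influx rate constant of the irreversible model.

    ``canonical``: Ki = K1*k3/(k2 + k3), the standard net-influx constant.
    ``printed``: the variant K1*k3/(K1 + k2) found in some reports, kept
    behind an explicit flag for comparability; the two are not reconciled.
    """
    if min(k1, k2, k3) < 0:
        raise ValueError("rate constants must be non-negative")
    if convention == "canonical":
        denom = k2 + k3
        if denom == 0:
            raise ZeroDivisionError("k2 + k3 must be > 0")
        return k1 * k3 / denom
    if convention == "printed":
        denom = k1 + k2
        if denom == 0:
            raise ZeroDivisionError("K1 + k2 must be > 0")
        return k1 * k3 / denom
    raise ValueError(f"unknown Ki convention {convention!r}")


# ---------------------------------------------------------------------------
# Plausibility screening and FUR
# ---------------------------------------------------------------------------

def k1max(cbf: float, hematocrit: float) -> PerfusionConstraint:
    """Perfusion-derived K1 upper bound at unit extraction.

    CPF = CBF * (1 - Htk);  K1max = CPF * 1.
    """
    if not cbf > 0:
        raise ValueError("cbf must be > 0")
    if not (0.0 < hematocrit < 1.0):
        raise ValueError("hematocrit must be in (0, 1)")
    cpf = cbf * (1.0 - hematocrit)
    return PerfusionConstraint(cbf=cbf, hematocrit=hematocrit, cpf=cpf,
                               k1max=cpf, extraction=1.0)


def plausibility_screen(fits: dict[str, dict[str, KineticParameters]],
                        constraints: dict[str, PerfusionConstraint],
                        fits_after: Optional[dict[str, dict[str, KineticParameters]]] = None,
                        ) -> pd.DataFrame:
    """Count K1 exceedances of the perfusion bound, per subject and ROI.

    ``fits`` maps subject -> ROI -> KineticParameters (before recovery);
    ``fits_after`` optionally the same after input recovery.  Returns one
    row per subject with per-ROI exceedance counts and an "any ROI" flag,
    plus a "TOTAL" row (subjects counted once in the any-ROI tally).
    """
    rows = []
    for sid, roi_fits in fits.items():
        cons = constraints[sid]
        row = {"subject": sid, "k1max": cons.k1max}
        n_over = sum(1 for f in roi_fits.values() if f.k1 > cons.k1max)
        row["n_roi"] = len(roi_fits)
        row["n_over_before"] = n_over
        row["any_over_before"] = n_over > 0
        if fits_after is not None:
            after = fits_after.get(sid, {})
            n_after = sum(1 for f in after.values() if f.k1 > cons.k1max)
            row["n_over_after"] = n_after
            row["any_over_after"] = n_after > 0
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"subject": "TOTAL", "k1max": np.nan,
             "n_roi": df["n_roi"].sum(),
             "n_over_before": df["n_over_before"].sum(),
             "any_over_before": int(df["any_over_before"].sum())}
    if fits_after is not None:
        total["n_over_after"] = df["n_over_after"].sum()
        total["any_over_after"] = int(df["any_over_after"].sum())
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def compute_fur(tissue: TimeActivityCurve,
                input_curve: TimeActivityCurve,
                window: Optional[tuple[float, float]] = None) -> FurResult:
    """Fractional uptake rate averaged over (late) tissue frames.

    FUR_i = C_tissue(t_i) / int_0^{t_i} Cp;  frames inside ``window``
    (default: all frames) are averaged.  The input must cover every frame
    time used.
    """
    times = tissue.times
    if window is not None:
        m = (times >= window[0]) & (times <= window[1])
        if not np.any(m):
            raise ValueError(f"no tissue frames inside window {window}")
    else:
        m = np.ones_like(times, dtype=bool)
    use_t = times[m]
    use_c = tissue.activities[m]
    if input_curve.times[-1] < use_t[-1] - 1e-9:
        raise ValueError("input does not cover the latest tissue frame")
    aucs = np.array([np.trapezoid(
        np.interp(np.linspace(0.0, t, 2001), input_curve.times,
                  input_curve.activities, left=0.0),
        np.linspace(0.0, t, 2001)) for t in use_t])
    if np.any(aucs <= 0):
        raise ValueError("input AUC is non-positive at a frame time")
    furs = use_c / aucs
    return FurResult(fur=float(np.mean(furs)), eval_time=float(np.mean(use_t)),
                     input_auc_0_t=float(aucs[-1]), per_frame=tuple(furs))
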