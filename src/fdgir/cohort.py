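"""Synthetic clamp-study cohorts: inputs, degradations, tissue curves.

The generator emulates the study conditions of frequent-sampling
[18F]FDG brain PET under hyperinsulinemic euglycemic clamp:

* Feng-shaped plasma inputs with a sharp peak (~75 kBq/mL at ~2 min) and a
  slowly declining tail (~9 kBq/mL at 30 min), drawn log-normally around
  reference-like means chosen for mutual consistency with the published
  constraint regressions (see docs/methods.md for the derivation);
* injected dose ~ N(187, 30) MBq truncated positive, with body weight,
  hematocrit and (clamp) cerebral blood flow from physiologic normals;
* a frequent-sampling schedule (every 10 s to 3 min, sparser to 100 min)
  and 2% multiplicative sampling noise on plasma;
* peak-degradation failure modes (attenuated, missed or delayed early
  samples) that leave the 5-100 min tail untouched;
* 2TCM brain tissue curves with frame-duration-scaled additive noise.

Everything is fully determined by ``CohortSpec.seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import yaml

from .feng import FengParameters, feng_eval
from .kinetics import KineticParameters, simulate_2tcm
from .tac import SubjectMeta, TimeActivityCurve, write_tac

__all__ = [
    "CohortSpec",
    "Cohort",
    "default_sample_schedule",
    "default_frame_schedule",
    "generate_input",
    "degrade_input",
    "generate_tissue",
    "generate_cohort",
    "write_cohort",
]


def default_sample_schedule() -> np.ndarray:
    """Frequent-sampling plasma schedule: 10 s to 3 min, 20 s to 5 min,
    then sparser out to 100 min."""
    return np.unique(np.concatenate([
        np.arange(0.0, 3.0 + 1e-9, 1.0 / 6.0),
        np.arange(3.0, 5.0 + 1e-9, 1.0 / 3.0),
        np.arange(6.0, 10.0 + 1e-9, 1.0),
        np.array([12.0, 15.0, 20.0, 25.0, 30.0, 40.0, 50.0,
                  60.0, 75.0, 90.0, 100.0]),
    ]))


def default_frame_schedule() -> np.ndarray:
    """Dynamic brain framing: 4x0.5, 4x1, 4x2.5, 4x6, 6x10 min (to 100 min)."""
    durs = np.concatenate([np.full(4, 0.5), np.full(4, 1.0),
                           np.full(4, 2.5), np.full(4, 6.0), np.full(6, 10.0)])
    ends = np.cumsum(durs)
    starts = ends - durs
    return np.column_stack([starts, ends])


#: reference-like Feng means (see docs/methods.md for the calibration)
DEFAULT_FENG_MEAN = {"tau": 1.7, "a1": 560.0, "a2": 16.0, "a3": 11.0,
                     "l1": -3.5, "l2": -0.12, "l3": -0.006}
#: log-normal sigma per parameter (tau is normal, truncated)
DEFAULT_FENG_SPREAD = {"tau": 0.12, "a1": 0.10, "a2": 0.15, "a3": 0.15,
                       "l1": 0.08, "l2": 0.12, "l3": 0.12}


@dataclass
class CohortSpec:
    """Everything needed to regenerate a cohort deterministically."""

    n_subjects: int = 13
    seed: int = 0
    feng_mean: dict = field(default_factory=lambda: dict(DEFAULT_FENG_MEAN))
    feng_spread: dict = field(default_factory=lambda: dict(DEFAULT_FENG_SPREAD))
    dose_mbq: tuple[float, float] = (187.0, 30.0)       # mean, SD (trunc > 0)
    weight_kg: tuple[float, float] = (78.0, 14.0)
    hematocrit: tuple[float, float] = (0.41, 0.04)
    cbf: tuple[float, float] = (0.55, 0.08)             # mL/mL/min
    k1_range: tuple[float, float] = (0.07, 0.14)
    k2_range: tuple[float, float] = (0.10, 0.25)
    k3_range: tuple[float, float] = (0.03, 0.08)
    noise_sd: float = 0.02          # relative, plasma samples
    onset_noise_sd: float = 0.11    # kBq/mL, half-normal on pre-peak zeros
    tissue_noise_sd: float = 0.03   # relative at 1-min frame duration
    degradation: Optional[tuple] = None   # e.g. ("attenuate", 0.5)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["degradation"] is not None:
            d["degradation"] = list(d["degradation"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("dose_mbq", "weight_kg", "hematocrit", "cbf",
                    "k1_range", "k2_range", "k3_range"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("degradation") is not None:
            d["degradation"] = tuple(d["degradation"])
        return cls(**d)

    def spec_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class Cohort:
    spec: CohortSpec
    inputs: list[TimeActivityCurve]
    truth_params: list[FengParameters]
    metas: list[SubjectMeta]
    degraded: list[TimeActivityCurve]
    tissues: list[TimeActivityCurve]
    kin_truth: list[KineticParameters]
    frames: np.ndarray


def _rng(spec: CohortSpec, index: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index, stream])


def _truncated_normal(rng, mean, sd, low=0.0, high=np.inf) -> float:
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if low < v < high:
            return float(v)
    raise RuntimeError("truncated normal failed to produce a sample")


def draw_feng(spec: CohortSpec, rng: np.random.Generator) -> FengParameters:
    m, s = spec.feng_mean, spec.feng_spread
    tau = max(rng.normal(m["tau"], s["tau"]), 0.3)
    vals = {}
    for name in ("a1", "a2", "a3", "l1", "l2", "l3"):
        vals[name] = m[name] * np.exp(s[name] * rng.standard_normal())
    return FengParameters(tau=tau, a1=vals["a1"], a2=vals["a2"], a3=vals["a3"],
                          l1=vals["l1"], l2=vals["l2"], l3=vals["l3"])


def draw_meta(spec: CohortSpec, rng: np.random.Generator,
              subject_id: str) -> SubjectMeta:
    dose = _truncated_normal(rng, *spec.dose_mbq, low=1.0)
    weight = _truncated_normal(rng, *spec.weight_kg, low=35.0)
    hct = _truncated_normal(rng, *spec.hematocrit, low=0.2, high=0.6)
    cbf = _truncated_normal(rng, *spec.cbf, low=0.2)
    return SubjectMeta(subject_id=subject_id, dose_mbq=dose,
                       weight_kg=weight, hematocrit=hct, cbf=cbf)


def generate_input(spec: CohortSpec, index: int,
                   schedule: Optional[np.ndarray] = None,
                   ) -> tuple[TimeActivityCurve, FengParameters, SubjectMeta]:
    """One subject's measured plasma input plus its ground truth."""
    rng = _rng(spec, index)
    params = draw_feng(spec, rng)
    meta = draw_meta(spec, rng, subject_id=f"s{index:03d}")
    times = default_sample_schedule() if schedule is None else np.asarray(schedule, float)
    clean = feng_eval(params, times)
    if spec.noise_sd > 0:
        noisy = clean * (1.0 + spec.noise_sd * rng.standard_normal(times.size))
        noisy = np.where(clean > 0, np.maximum(noisy, 0.0), 0.0)
    else:
        noisy = clean.copy()
    if spec.onset_noise_sd > 0:
        # hand-sampled curves carry a tiny noisy background before tracer
        # arrival (half-normal; median first value ~ 0.074 kBq/mL at the
        # default sigma), which the onset-flooring stage exists to clean
        pre = clean == 0.0
        noisy[pre] = np.abs(rng.normal(0.0, spec.onset_noise_sd, pre.sum()))
    curve = TimeActivityCurve(times, noisy, label="plasma",
                              name=f"input_{index:03d}", meta=meta)
    return curve, params, meta


def degrade_input(curve: TimeActivityCurve, mode) -> TimeActivityCurve:
    """Apply a peak-degradation failure mode; the tail (>= 5 min) is untouched.

    Modes: ``("none",)``; ``("attenuate", f)`` scales samples at t <= 4 min
    by f in (0, 1]; ``("drop_early", k)`` removes the k earliest post-onset
    samples before 5 min; ``("delay", d)`` makes the early curve lag by d
    minutes (early samples read the true curve d minutes earlier).
    """
    kind = mode[0]
    if kind == "none":
        return curve.with_values()
    if kind == "attenuate":
        f = float(mode[1])
        if not (0.0 < f <= 1.0):
            raise ValueError("attenuation factor must be in (0, 1]")
        acts = curve.activities.copy()
        acts[curve.times <= 4.0] *= f
        return curve.with_values(activities=acts, name=curve.name + "_att")
    if kind == "drop_early":
        k = int(mode[1])
        onset = np.nonzero(curve.activities)[0]
        early = [i for i in onset if curve.times[i] < 5.0][:k]
        keep = np.ones(len(curve), dtype=bool)
        keep[early] = False
        return curve.with_values(curve.times[keep], curve.activities[keep],
                                 name=curve.name + "_drop")
    if kind == "delay":
        d = float(mode[1])
        if d < 0:
            raise ValueError("delay must be >= 0")
        acts = curve.activities.copy()
        early = curve.times < 5.0
        acts[early] = np.interp(curve.times[early] - d, curve.times,
                                curve.activities, left=0.0)
        return curve.with_values(activities=acts, name=curve.name + "_del")
    raise ValueError(f"unknown degradation mode {mode!r}")


def draw_kinetics(spec: CohortSpec, rng: np.random.Generator) -> KineticParameters:
    return KineticParameters(k1=rng.uniform(*spec.k1_range),
                             k2=rng.uniform(*spec.k2_range),
                             k3=rng.uniform(*spec.k3_range))


def generate_tissue(truth: FengParameters,
                    kin: KineticParameters,
                    frames: np.ndarray,
                    noise_sd: float = 0.0,
                    rng: Optional[np.random.Generator] = None,
                    ) -> TimeActivityCurve:
    """Frame-averaged tissue curve driven by the noiseless true input.

    Additive Gaussian frame noise with SD = noise_sd * value / sqrt(duration
    in min), the usual count-statistics scaling (a 1-min frame carries
    exactly ``noise_sd`` relative noise).
    """
    frames = np.asarray(frames, float)
    t_end = frames[-1, 1]
    grid = np.arange(0.0, t_end + 1e-9, 0.02)
    dense_input = TimeActivityCurve(grid, feng_eval(truth, grid), label="plasma")
    tissue = simulate_2tcm(dense_input, kin, frames)
    if noise_sd > 0:
        if rng is None:
            raise ValueError("rng required when noise_sd > 0")
        durs = frames[:, 1] - frames[:, 0]
        sigma = noise_sd * np.abs(tissue.activities) / np.sqrt(durs)
        vals = np.maximum(tissue.activities + sigma * rng.standard_normal(len(tissue)), 0.0)
        tissue = tissue.with_values(activities=vals)
    return tissue


def generate_cohort(spec: CohortSpec,
                    frames: Optional[np.ndarray] = None) -> Cohort:
    """Full deterministic cohort bundle (inputs, degradations, tissues, truths)."""
    frames = default_frame_schedule() if frames is None else np.asarray(frames, float)
    inputs, truths, metas, degraded, tissues, kins = [], [], [], [], [], []
    for i in range(spec.n_subjects):
        curve, params, meta = generate_input(spec, i)
        inputs.append(curve)
        truths.append(params)
        metas.append(meta)
        mode = spec.degradation or ("none",)
        degraded.append(degrade_input(curve, mode))
        rng_t = _rng(spec, i, stream=1)
        kin = draw_kinetics(spec, rng_t)
        kins.append(kin)
        tissues.append(generate_tissue(params, kin, frames,
                                       noise_sd=spec.tissue_noise_sd, rng=rng_t))
    return Cohort(spec=spec, inputs=inputs, truth_params=truths, metas=metas,
                  degraded=degraded, tissues=tissues, kin_truth=kins,
                  frames=frames)


def write_cohort(cohort: Cohort, out_dir) -> str:
    """Write the cohort as TAC files plus a manifest; returns the manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    files = []
    for i, (inp, deg, tis) in enumerate(zip(cohort.inputs, cohort.degraded,
                                            cohort.tissues)):
        for tag, curve in (("input", inp), ("degraded", deg), ("tissue", tis)):
            fname = f"{tag}_{i:03d}.tac"
            write_tac(curve, os.path.join(out_dir, fname))
            files.append(fname)
    np.savetxt(os.path.join(out_dir, "frames.tsv"), cohort.frames,
               delimiter="\t", header="start\tend", fmt="%.6g")
    files.append("frames.tsv")
    meta_rows = ["subject_id\tdose_mbq\tweight_kg\thematocrit\tcbf"]
    for m in cohort.metas:
        meta_rows.append(f"{m.subject_id}\t{m.dose_mbq!r}\t{m.weight_kg!r}"
                         f"\t{m.hematocrit!r}\t{m.cbf!r}")
    with open(os.path.join(out_dir, "meta.tsv"), "w") as fh:
        fh.write("\n".join(meta_rows) + "\n")
    files.append("meta.tsv")
    manifest = {"seed": cohort.spec.seed, "spec_hash": cohort.spec.spec_hash(),
                "spec": cohort.spec.to_dict(), "files": files}
    path = os.path.join(out_dir, "manifest.json")
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return path
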