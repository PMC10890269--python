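# fdgir — input recovery for [18F]FDG plasma curves

Quantitative FDG PET needs the arterial input function Cp(t). In clinical
practice the early peak (0–5 min) of a sampled plasma curve is often
ruined — a few missed, attenuated or late samples — while the 5–100 min
tail survives. A corrupted peak biases the two-tissue-compartment delivery
constant K1 upward, frequently past the physiological ceiling
K1max = CBF·(1 − Hct), and invalidates the whole kinetic analysis.

`fdgir` recovers the peak from the tail. It fits the three-exponential
Feng input model

    Cp(t) = (A1(t−τ) − A2 − A3) e^{λ1(t−τ)} + A2 e^{λ2(t−τ)} + A3 e^{λ3(t−τ)}

to the tail alone under a six-term penalized objective: a
population-SD-normalized tail-noise term, ridge shrinkage to a
reference-trained prior, three linear population constraints (peak height
vs λ1/A1; A1 vs steady-state volume VSS = Dose·MRT/AUC; early AUC vs
injected dose) of which the two weakest carry *fitted* weights (p8, p9),
and a tail-MRT match — nine fitted parameters in all. Around the core it
provides onset flooring and population peak alignment, reference selection
and a linear good/poor quality classifier, irreversible 2TCM (3k)
modelling with the K1max plausibility screen, FUR, paired-comparison
statistics, and a fully seeded synthetic-cohort generator that emulates
frequent-sampling clamp studies (dose 187 ± 30 MBq, sharp ~2-min peaks,
peak-degradation failure modes).

Intended users: PET kinetic-modelling researchers salvaging studies with
poor-quality blood data, and methodologists stress-testing input-function
pipelines on synthetic cohorts.

## Worked example

Train on a 13-curve reference cohort, degrade one curve's peak, classify,
recover, and validate kinetically:

```python
from fdgir import *
from fdgir.feng import fit_feng_full, build_population_prior

cohort = generate_cohort(CohortSpec(n_subjects=13, seed=1))
floored, thr = floor_low_onsets(cohort.inputs)
aligned, alignment = align_peaks(floored)

fits = [fit_feng_full(c) for c in aligned]
prior = build_population_prior([f.params for f in fits], aligned)

curve, meta = aligned[0], cohort.metas[0]
degraded = degrade_input(curve, ("attenuate", 0.4))   # 60% of the peak lost
score = quality_score(degraded, meta)
res = recover_input(degraded, meta, RecoveryConfig(), prior)

tissue = cohort.tissues[0]
bad  = fit_2tcm(tissue, degraded, frames=cohort.frames)
good = fit_2tcm(tissue, res.recovered_curve, frames=cohort.frames)
bound = k1max(meta.cbf, meta.hematocrit)
```

Output (printing the quantities above):

```
floor threshold: 0.094 kBq/mL, UAVt: 2.00 min
prior built from 11 fits (excluded: ['input_003', 'input_007'])
degraded curve: maxSUV=12.4, peak/5th=1.51, selection value=0.191 -> poor
recovered peak 72.2 kBq/mL (degraded 30.6, true 76.5)
K1 true 0.118 | degraded-input fit 0.465 | recovered-input fit 0.114 | K1max 0.319
```

Reading it: the attenuated curve falls below the 0.47 selection threshold
and is labelled poor; tail-only recovery rebuilds the peak to within ~6%
of truth; fitting the 3k model with the degraded input inflates K1 four-fold
past the perfusion ceiling (0.465 > 0.319 mL/mL/min), while the recovered
input restores a physiological estimate (0.114 vs true 0.118).

The same flow is available from the shell:

```sh
fdgir pipeline out/ --seed 1 --n-subjects 20 --n-reference 13
fdgir simulate cohort/ --seed 1          # synthetic TAC files + manifest
fdgir train-prior refs/ --out prior.yaml
fdgir recover tails/ meta.csv prior.yaml out/
```

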