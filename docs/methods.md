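# Methods

## Problem

Quantitative [18F]FDG PET modelling needs the arterial plasma input
function Cp(t). With manual or arterialized-venous sampling the early peak
(roughly 0–5 min post-injection) is the fragile part: a few missed,
attenuated or late samples destroy it, while the slow tail (5–100 min)
usually survives. A corrupted peak biases the two-tissue-compartment
delivery constant K1 upward — often past the physiological ceiling set by
plasma flow — and with it every downstream parameter. `fdgir` rebuilds the
peak from the tail plus population knowledge, then checks the result by
compartmental modelling and the fractional uptake rate (FUR).

## Input model

Plasma curves are described by the three-exponential Feng form (model 2):

    Cp(t) = (A1 (t-τ) - A2 - A3) e^{λ1 (t-τ)} + A2 e^{λ2 (t-τ)} + A3 e^{λ3 (t-τ)},  t > τ

with Cp = 0 for t ≤ τ. Parameter-vector order is p1=τ, p2=A1, p3=A2,
p4=A3, p5=λ1, p6=λ2, p7=λ3; Ratio52 = p5/p2 = λ1/A1. Units: A1 in
kBq/mL/min, A2/A3 in kBq/mL, λ in 1/min (λ1 ≤ λ2 ≤ λ3 ≤ 0), τ in min.
Default fit bounds (τ ∈ [0,5]; λ1 ∈ [−20,−0.5]; λ2 ∈ [−2,−0.01];
λ3 ∈ [−0.1,0); positive amplitudes) bracket published FDG fits and
suppress oscillating solutions; fits violating eigenvalue ordering or
going negative on a dense grid are flagged rather than silently accepted.

## Preprocessing

1. **Onset flooring.** The flooring threshold is the population median of
   first non-zero activities; leading samples below it are zeroed,
   iteratively until one reaches the threshold (the iterative closure is
   config-selectable back to a single application — with realistic onset
   noise the two rarely differ).
2. **Peak time.** Global maximum; two local maxima within 10% of each
   other yield the mid-time.
3. **Ascent start.** With ≤ 2 samples strictly between the first non-zero
   sample and the peak, a line through the ascending limb is extrapolated
   to zero; with more, a quadratic (the lowest order able to capture a
   convex ascent) whose latest real root before the peak is used, clamped
   to [0, first-non-zero time].
4. **Peak alignment.** The population delay UAVt is the largest peak time
   not exceeding the Tukey upper inner fence (Q3 + 1.5·IQR,
   linear-interpolation quartiles). Earlier-peaking curves are shifted
   right by dt = UAVt − peak time (with a (0,0) anchor inserted so
   integrals start at zero); dt is stored and removed again after
   recovery, before any kinetic modelling.

## Reference selection and quality classification

Reference-grade curves satisfy RT ≥ RT1, peak time ≤ UAVt + 1 min, and
peak ≥ 50 kBq/mL, where RT is peak activity over the activity at
UAVt + 2.5 min and RT1 is the boundary between the third and fourth
quarters of the RT distribution, read as its 75th percentile
(config-overridable). Good/poor classification uses the linear rule

    selection value = −0.36 + 0.038·maxSUV + 0.052·(peak / value at 5 min)

with threshold 0.47; ties classify as good. SUV is body-weight normalized
(activity · kg / MBq). The coefficients are cohort-trained constants with
config override; re-deriving them is out of scope.

## Recovery objective

The tail (nominal window 5–100 min; samples up to 2.5 min past the window
end are kept because alignment can shift the last sample past 100 min;
tails ending before 60 min are rejected) is fitted with nine parameters —
seven Feng plus two fitted regularization weights p8, p9 — under six
residual blocks:

| term | content | weight |
|------|---------|--------|
| T1 | (model − data)/σ_pop at tail samples | w_noise = 1 |
| T2 | (p − prior mean)/prior SD, all 7 params | w_param |
| T3 | maxPA − (149.05 + 10943·Ratio52) | w_maxpa |
| T4 | A1 − (6357.91 − 520·VSS_model) | p8² |
| T5 | AUC(2–4 min) − (33.47 + 0.23·Dose) | p9² |
| T6 | MRT(model tail) − MRT(data tail) | w_mrt |

σ_pop is the per-timepoint population SD of the reference curves on a
canonical grid, floored at 1% of the population mean so near-noiseless
samples cannot dominate. T2 is ridge shrinkage toward the prior mean
normalized by the prior SD — plain magnitude shrinkage would be
unit-inconsistent across amplitudes and eigenvalues. The two weakest
population regressions (T4, R² 0.46; T5, R² 0.35 in the training cohorts)
carry the fitted weights, entered squared so the optimizer cannot exploit
negative weights; their box is [0, 10], so the solver may relax an
uninformative constraint to zero (on synthetic cohorts it generally
does). maxPA is located by dense-grid search (0.01 min) on [τ, 5] min;
VSS_model = Dose·MRT/AUC uses the model curve on [0, 300] min (a
numerically converged horizon for physiologic λ3), dose in kBq and the
result in liters — the unit convention under which the T4 constants give
positive A1 at physiologic VSS ≈ 10–12 L. All constants live in
`RecoveryConfig` and can be re-estimated for other cohorts.

Optimization is bounded trust-region-reflective least squares initialized
at the prior means; the recovered output splices the dense model curve
(t < 5 min, 0.05-min steps) with the measured tail (pure-model output via
`splice_tail=False`). A post-fit dense-grid negativity check flags
"unrealistic" fits, standing in for the visual screening a human operator
would do.

**Weight tuning** recovers each reference curve from its own tail and
minimizes the mean absolute percent error of maxSUV, AUC and MRT against
the known full curves, by one pass of coordinate descent over a coarse
log-spaced grid per fixed weight — at 13 curves a finer search changes
the result by less than the sampling noise.

## Kinetic validation

The irreversible 2TCM (k4 = 0, vB fixed at 0.05) is solved analytically:
Cf+Cb = K1k3/(k2+k3)·∫Cp + K1k2/(k2+k3)·[e^{−(k2+k3)t} ⊛ Cp], with the
exponential convolution computed exactly for a piecewise-linear input on
a uniform 0.02-min grid (first-order recursive filter), and
C_PET = (1−vB)(Cf+Cb) + vB·Cp. The vascular term uses plasma activity —
for FDG the whole-blood/plasma distinction is small and the choice is
flag-switchable. Frames are trapezoid-averaged within their bounds.
Fitting runs in the (K1, K1/k2, k3) parameterization, bounds K1 ∈ [0,1],
K1/k2 ∈ [0.01,10], k3 ∈ [0,0.5], uniform frame weights (frame-duration
weighting optional), multi-start from three physiologic points;
bound-touching parameters are flagged as saturated. Ki defaults to the
canonical K1k3/(k2+k3); an alternative printed variant K1k3/(K1+k2)
encountered in the applied literature is available behind
`convention="printed"` and is never silently substituted.

Plausibility screening compares fitted K1 against
K1max = CBF·(1−hematocrit)·E with extraction E fixed at 1 (an upper
limit): delivery cannot exceed plasma flow. FUR is tissue activity at a
late frame divided by ∫₀ᵗ Cp, averaged over frames in a configurable late
window (default all supplied frames in library use; 60–100 min in the
pipeline).

## Synthetic cohort

Because the clinical curves cannot be redistributed, a generator supplies
study-condition-matched data. Reference-like Feng means are τ=1.7,
A1=560, A2=16, A3=11, λ1=−3.5, λ2=−0.12, λ3=−0.006, chosen (before any
testing, and not revisited) to satisfy simultaneously: peak ≈ 77 kBq/mL
at ≈ 2 min and tail ≈ 9 kBq/mL at 30 min (the reported reference-curve
shape); approximate self-consistency with the three printed constraint
lines at the mean dose (the T3 line predicts maxPA ≈ 81 vs an actual
≈ 77; the T5 line predicts AUC(2–4) ≈ 76.5 vs ≈ 83; T4 is the loosest,
predicted A1 within a factor ≈ 2); and maxSUV ≈ 30, so that half-peak
attenuation crosses the 0.47 selection threshold the way poor clinical
curves do. Log-normal spreads (10% A1, 8% λ1, 15% A2/A3, 12% λ2/λ3,
τ SD 0.12 min) reflect a homogeneous selected reference set under one
protocol. Doses are N(187, 30) MBq truncated positive; weight N(78, 14)
kg; hematocrit N(0.41, 0.04); clamp gray-matter CBF N(0.55, 0.08)
mL/mL/min; rate constants uniform in K1 ∈ [0.07,0.14], k2 ∈ [0.10,0.25],
k3 ∈ [0.03,0.08] 1/min.

Noise: 2% multiplicative Gaussian on plasma samples; a half-normal
background (σ = 0.11 kBq/mL, median first value ≈ 0.074) on pre-arrival
samples, which is what the onset-flooring stage exists to clean; additive
tissue frame noise with SD = rel·value/√(duration in min) (a 1-min frame
carries exactly the nominal relative noise, default 3%). Degradation
modes — attenuate(f) on t ≤ 4 min, drop_early(k), delay(d) — never touch
the tail beyond 5 min, mirroring how real sampling failures spare it.
Late-scan subjects are emulated by restricting tissue frames to late
windows.

What passing on this generator does *not* show: robustness to metabolite
or decay-correction errors, dispersion between sampling sites, non-Feng
input shapes, inter-protocol schedule variation, or constraint
regressions whose true coefficients differ from the printed ones. The
generator draws parameters independently (except as induced by the Feng
form itself), so the constraint lines are weaker individualizers here
than in cohorts where they were estimated; the recovery consequently
leans more on the tail and the prior.

## Problem sizes and numerical choices

Validation experiments use 13-curve reference cohorts (matching the
reference-set size of the clamp cohorts), 100 draws for forward–inverse
consistency, and 50 subjects for the K1-bias experiment. Feng and
recovery fits: TRF least squares, ftol 1e−10, at most 2000 evaluations;
2TCM: 0.02-min convolution grid, 3 starts, 400 evaluations each.
Degenerate guards: population SDs floored (1e−3·|mean|); zero AUC, flat
curves, all-zero curves, zero denominators raise informative errors;
k2+k3 = 0 switches to the pure-trapping branch K1·∫Cp.

## Known limitations

* The recovered peak of a single curve is identifiable only up to the
  population information (prior + constraint lines + tail); individual
  peak-height errors around 5–10% remain and average out, which is why
  fidelity targets are stated as cohort means.
* Constraint constants are used in fixed units (kBq/mL, min, MBq, L);
  cohorts in other unit systems must rescale them in `RecoveryConfig`.
* No dispersion, decay or metabolite correction anywhere; inputs must be
  decay-corrected.
* FUR is a retention index, not Ki; its agreement with Ki degrades when
  k2 is large or scans are early.
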