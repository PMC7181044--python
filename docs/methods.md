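# Methods

## Scope and data model

The pipeline quantifies dynamic brain PET of a tau tracer in mice over a
90-min acquisition with the frame schedule 18×10 s, 4×30 s, 5×60 s,
10×300 s, 3×600 s (40 frames, 5400 s). Activity concentrations are
kBq/mL, decay-corrected to injection; frame values are treated as time
averages over the frame. No SUV (dose/weight) normalization is applied
because every downstream quantity — frame-wise SUVR, windowed SUVR,
Logan DVR — is a target/reference ratio in which that normalization
cancels; injected dose is metadata only.

Regions are integer labels on the image grid (cortex CX, hippocampus HIP,
striatum STR, midbrain MB, cerebellum CB as reference). Images must
already be aligned to the label grid: no registration, motion or
partial-volume correction is provided. Inputs are assumed fully
decay-corrected (whether a vendor chain corrects at reconstruction or
analysis time is not observable downstream).

## Numerical conventions

* **Integration.** Time integrals use the rectangular, duration-weighted
  rule Σ value·Δt over frames with mid-time ≤ T, because frame means are
  already time averages; a trapezoid on mid-times would double-count the
  within-frame averaging. A frame belongs to a window/integral iff its
  mid-time lies in the closed interval — unambiguous for the 40–70-min
  window given 5- and 10-min frames.
* **Forward SRTM.** The convolution solution is evaluated on a 1-s grid
  with an exponential-integrator recursion (exact homogeneous propagation,
  trapezoidal source term) and then frame-averaged. Against an adaptive
  ODE solver the frame-averaged solution agrees to ~2·10⁻⁴ relative. When
  the reference input is itself a frame-sampled TAC it is linearly
  interpolated through (0, 0); that interpolation, not the integrator,
  dominates the error budget (up to ~2% on the earliest fast-rising
  frames, far less late).
* **Logan regression.** Ordinary least squares on the Logan coordinates
  over frames with mid-time ≥ t*; OLS (not perpendicular) matches the
  standard formulation, and its noise-induced slope attenuation is
  accepted and covered by tests rather than corrected.
* **SRTM fitting.** Weighted nonlinear least squares (weights √frame
  duration, the usual count-statistics proxy) with bounds R1 ∈ (0, 5],
  k2 ∈ (0, 2] min⁻¹, BPnd ∈ [0, 10], restarted from a fixed 3-point grid;
  the best converged start wins. Noiseless self-consistency is ~10⁻¹⁵;
  when target ≡ reference, k2 is structurally unidentifiable (any value
  fits with R1 = 1, BPnd = 0) and is not interpreted.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| t* | 40 | min | uptake plateaus at 30–40 min; fixed t* keeps DVR deterministic (automatic selection available) |
| k2ref | fitted per animal | min⁻¹ | SRTM on the cortex (largest specific signal) per animal; k2ref = k2/R1 is a reference-tissue property shared across that animal's regions; a fixed population value is configurable |
| analysis window | 40–70 | min | selected by the window scan; also the calibration window |
| window grid | 30-min windows, 10-min step, + full scan | min | the selected window is a 30-min interval; grid duration/step configurable since the original scan layout is not fully specified |
| r² threshold | 0.90 | — | window qualifies only if every non-excluded region reaches it |
| excluded regions | MB | — | midbrain binding emerges late and weakly; its regression never clears the threshold |
| stats engine | ANOVA + Tukey HSD | — | see below |

t* selection (when enabled) returns the earliest frame mid-time from which
the max relative residual of the Logan line fit is ≤ 10%, falling back to
40 min.

## Synthetic cohort

The generator stands in for the study animals: 6 age groups (2, 4, 6, 8,
9, 11 months) × 3 animals, cross-sectional.

* **Reference kinetics** are phenomenological — C_ref(t) =
  A(e^(−λs·t) − e^(−λf·t)) with A = 100 kBq/mL, λf = 0.7 min⁻¹,
  λs = 0.005 min⁻¹ — because the Logan and SUVR machinery needs only
  C_ref, never plasma input. The curve peaks at ~7 min and declines
  thereafter. λs together with k2 controls how far the late tissue ratio
  sits above DVR; the chosen pair keeps the windowed SUVR at DVR = 1
  within 0.5% of unity and the SUVR plateau (within 5% of its end value)
  at ~32 min, matching the observed 30–40-min plateau.
* **Target kinetics**: forward SRTM with R1 = 0.9, k2 = 0.10 min⁻¹ and
  BPnd = DVR − 1. Per-animal kinetic variability r1_sd = 0.10,
  k2_sd = 0.02 min⁻¹ (one draw per animal, shared across regions) models
  between-animal delivery/efflux differences; without it, early static
  windows are unrealistically tight DVR surrogates and the window scan
  loses its discriminating structure (observed 0–30-min r² ≈ 0.88 with
  jitter vs ≈ 0.98 without).
* **Calibration.** Ground-truth group-mean DVRs are obtained at run time
  by inverting (Brent's method) the noiseless map DVR → windowed
  SUVR(40–70) against a packaged table of published group-mean SUVRs per
  region and age. Between-animal DVR SD is the published SUVR SD divided
  by the local slope of that map. Baseline ratios slightly below 1
  (2-month groups, 4-month midbrain) are unreachable because the
  reference region is devoid of specific binding (DVR ≥ 1); they clamp to
  DVR = 1 and their between-animal DVR SD is set to 0 so one-sided
  truncation cannot inflate the group mean. Consequence: simulated
  baseline SUVR is ~1.005 rather than ~0.98, so recovered percent changes
  vs baseline are compressed ~2.5–3.5 points relative to the published
  figures; this is a structural property of a reference-tissue generator,
  not an estimation bias.
* **Noise**: additive Gaussian with sd = scale·√(value/duration_min),
  scale 0.5, clipped at 0 — a count-statistics surrogate (short early
  frames noisy, long late frames quiet). True Poisson sinogram noise,
  scanner PSF, anatomy and atrophy are not modelled. Each animal uses a
  deterministic substream (spec seed + animal index), so cohorts are
  reproducible and extending a cohort does not perturb existing animals.

What passing tests therefore show: the estimation chain (extraction →
SRTM → Logan → SUVR windows → group stats) recovers known ground truth
under realistic TAC-level noise and between-animal variability. What they
do not show: robustness to registration error, partial-volume effects,
reference-region spill-in, or radiometabolites — none of which the
generator emulates.

## Group statistics

The named comparison procedure ("nonparametric one-way ANOVA with Tukey's
multiple comparisons") is internally inconsistent — Tukey's HSD is a
parametric procedure — so both engines are implemented: one-way ANOVA +
Tukey HSD (default, since Tukey is named explicitly) and Kruskal–Wallis +
Dunn with Bonferroni as the nonparametric alternative; the engine used is
recorded in run metadata. Summary tables report group mean ± SD, percent
change vs the 2-month baseline computed from unrounded means, and the
adjusted baseline-contrast p-value with stars at 0.05/0.01/0.001.
Note that percent changes recomputed from rounded published group means
(e.g. 1.27/0.98 → +29.6%) differ slightly from the published in-text
percentages (+28.9%), which were evidently computed on unrounded data.
Contrasts compare each age to baseline (all pairwise values are computed;
baseline contrasts are flagged). With n = 3 per group the family-wise
type-I rate of the default engine measures ~3–4% at α = 0.05.

## Validation problem sizes

Chosen to characterize each quantity to well below its tolerance: 200
replicate cohorts for percent-change recovery in the test suite (2000 in
the acceptance script, Monte-Carlo SE ~0.07 points), 25 cohorts for the
absolute-scale hippocampal check (a single n = 3 group mean has sampling
SE ~0.09, larger than the ±0.10 band being checked), 1000 replicates for
type-I control, 50 for SRTM noise bias.

## Known limitations

* The optimal-window rule can select 50–80 min on some cohorts: once
  equilibrium is reached, adjacent late windows are near-equivalent and
  the slope criterion decides by small margins. The published window is
  within the qualifying set in all tested seeds.
* Noise-free Logan under the rectangular integration rule shows a small
  positive bias (+0.2% at DVR 1 to +1.3% at DVR 2.5), growing with
  binding.
* The highest-binding simulated group (11-month striatum) reaches its
  SUVR plateau last: 5.2% below its end value at the 42.5-min frame,
  within 5% from 45 min.
* Cross-sectional only; no longitudinal (repeated-measures) modelling.
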