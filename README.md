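# taupet

Quantification pipeline for dynamic small-animal tau-PET: regional
time–activity curve (TAC) extraction, distribution volume ratio (DVR) by
reference Logan graphical analysis with an SRTM-derived reference efflux
constant, standardized uptake value ratio (SUVR) static-window
optimization, and cross-sectional group comparison. It is aimed at
preclinical imaging groups who acquire 90-min dynamic scans in tauopathy
mouse models (e.g. rTg4510) and want to (a) validate a short static SUVR
protocol against full kinetic modelling and (b) quantify age-dependent
regional uptake differences.

Because no raw animal data are distributable, the package ships a
synthetic-cohort generator with known ground truth, calibrated so its
windowed SUVRs reproduce the published regional group means; all
validation is parameter recovery against that ground truth.

## Model

With `C_voi(t)` and `C_ref(t)` the target- and reference-region (cerebellum)
TACs, the reference Logan linearization

```
∫₀ᵀ C_voi dt / C_voi(T) = DVR · [∫₀ᵀ C_ref dt + C_ref(T)/k2ref] / C_voi(T) + b
```

becomes linear for `T ≥ t*` (default 40 min); the slope is the DVR
(= 1 + BPnd). `k2ref` is obtained per animal from a simplified reference
tissue model (SRTM) fit of the cortical TAC,

```
C_t(t) = R1·C_ref(t) + (k2 − R1·k2a) · C_ref(t) ⊛ exp(−k2a·t),   k2a = k2/(1+BPnd),
```

and `k2ref = k2/R1`. The windowed SUVR over `[a, b]` minutes is the ratio of
duration-weighted mean activities and approximates DVR at transient
equilibrium; the window scan regresses SUVR on DVR across the cohort per
region and candidate window and picks the window in which every region
(midbrain excluded) reaches r² ≥ 0.90 with regression slope closest to 1.

The synthetic cohort draws the reference TAC from a biexponential
bolus-washout model, target TACs from forward SRTM kinetics with
ground-truth DVR per region and age group, per-animal delivery/efflux
variability, and frame-duration-scaled Gaussian noise.

## Worked example

Reproduce the full synthetic study (the numbered drivers build on each
other):

```
python analysis/01_simulate_cohort.py
python analysis/02_fit_kinetics.py
python analysis/03_window_scan.py
python analysis/04_group_comparison.py
python analysis/05_validation.py
```

`02_fit_kinetics.py` prints, for the seed-42 cohort:

```
Logan DVR for 72 animal-regions (t* = 40 min, fitted k2ref)
recovery: mean err +0.0067, max |err| 0.0630
```

i.e. the per-animal Logan estimates track the simulated ground-truth DVRs
to within 0.06 under measurement noise. `03_window_scan.py` reports the
per-window criterion (minimum r² across cortex/hippocampus/striatum and
mean |slope − 1|); windows starting at or after 40 min all exceed r² 0.97
while the 0–30-min window fails (r² 0.88), and the selected static window
for this cohort is 50–80 min (40–70 on other seeds — late windows are
nearly equivalent once equilibrium is reached). `04_group_comparison.py`
prints the region × age summary with Tukey-adjusted baseline contrasts;
for the cortex:

```
4-mo:  +8.3% (p_adj = 0.85)
6-mo: +28.1% (p_adj = 0.019)
8-mo: +36.4% (p_adj = 0.0028)
9-mo: +39.2% (p_adj = 0.0015)
11-mo: +37.0% (p_adj = 0.0025)
```

— the first significant cortical elevation appears at 6 months and the
effect plateaus around 8–9 months, while the midbrain separates from
baseline only at 11 months.

`05_validation.py` re-derives the calibration checks: noiseless Logan
recovery error ≤ 0.6% across BPnd 0–0.75, mean cortical percent changes of
+13.0/+26.1/+35.1/+34.1% (4/6/9/11 months, 200 replicate cohorts), an
11-month hippocampal group-mean SUVR of 1.389, and a 3.4% family-wise
type-I rate for the baseline contrasts under zero effect.

A CLI wraps the same stages (`taupet simulate | extract | kinetics |
window-scan | group-stats | run-all`, with `--config`, `--seed`,
`--outdir`); `taupet extract` reads 4D NIfTI dynamic images plus integer
label volumes for real data already aligned to the mask grid.

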