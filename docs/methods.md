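# Methods

## Kinetic model

The package implements the one-tissue compartment model (1TCM) for
dynamic cardiac PET. The tissue compartment obeys
`dCt/dt = K1·Ca(t) − k2·Ct(t)` with `Ct(0) = 0`; the measured regional
signal is `C_PET = (1 − Vb)·Ct + Vb·Ca`. Assumptions carried by this
model:

- the tracer is well mixed in a single tissue pool (no second
  compartment, no irreversible trapping term);
- the left-ventricular cavity TAC is an adequate arterial input, with
  whole blood treated as plasma (no metabolite or hematocrit
  correction) — appropriate for extracellular chelates and for the
  early phase of acetate;
- no transit delay or dispersion between the LV cavity and tissue is
  fitted; at small-animal bolus time scales with 3-s frames this is a
  sub-frame effect;
- no partial-volume or spill-over correction is applied; fitted K1
  values are therefore apparent values, as in typical small-animal
  practice.

`K1` (mL·min⁻¹·mL⁻¹) serves as the perfusion surrogate, `k2` (min⁻¹) is
clearance (for ¹¹C-acetate it tracks oxidative metabolism), `Vb` ∈ [0,1]
the fractional blood volume. Time is seconds in schedules and files,
minutes inside kinetic math; conversion is centralised in
`myoperf.units`.

## Numerical solution

The convolution `Ct(t) = K1 ∫₀ᵗ Ca(s)e^(−k2(t−s)) ds` is advanced by a
recursive exponential update on a uniform fine grid (default step 0.5 s,
far below the shortest 3-s frame): over one step `h` with `Ca` linear,

    Ct(t+h) = e^(−k2·h)·Ct(t) + K1·(a·I0 + b·I1)

with `I0 = (1−e^(−k2h))/k2`, `I1 = h·I0 − (1−e^(−k2h)(1+k2h))/k2²`,
`a = Ca(t)` and `b` the slope. For `k2·h < 1e−8` the series limits
`I0 = h`, `I1 = h²/2` are used, making `k2 = 0` (irreversible uptake)
exact rather than a 0/0 hazard. The scheme is exact for piecewise-linear
input, unconditionally stable, and implemented as a first-order linear
filter (`scipy.signal.lfilter`), so a forward evaluation is a few
vector operations. Tests verify it against high-accuracy ODE
integration (`solve_ivp`, rtol 1e−10) to < 1e−4 maximum relative
deviation over random parameter draws.

The continuous model is mapped onto the acquisition frames by
trapezoidal frame averaging. When frame boundaries coincide with grid
points (always true for the default 0.5-s grid and integer-second
schedules) this is a precomputed weight-matrix product; otherwise
boundary points are interpolated into the integration grid.

The measured LV input TAC is converted back to a continuous curve by
treating frame values as samples at frame midpoints, anchoring (0, 0)
before the first midpoint. This re-sampling is the model's view of the
input; consequently an exact "round trip" is defined through the model's
own `predict`, and a tissue TAC literally equal to the input TAC is
explained by `Vb → 1` with a small but nonzero residual floor.

## Estimation

Weighted nonlinear least squares over `(K1, k2, Vb)` with box bounds
[0, 10] × [0, 20] × [0, 1]:

- weights `wᵢ ∝ frame duration`, normalised to sum 1 (standard dynamic
  PET weighting; `uniform` or explicit per-frame weights selectable).
  Normalisation makes the argmin invariant to weight rescaling.
- multi-start from three fixed points (0.1, 0.1, 0.05), (0.5, 0.5, 0.1),
  (2, 2, 0.2); lowest weighted RSS wins, ties broken toward lower K1 —
  fully deterministic.
- `scipy.optimize.least_squares` (TRF), parameter tolerance 1e−8, at
  most 500 evaluations per start; non-convergence is flagged and the
  best point still returned; solutions pinned at a bound are flagged.
- standard errors are asymptotic: `cov = (JᵀJ)⁻¹ · WRSS/(n−p)` from the
  weighted Jacobian at the optimum (pseudo-inverse when singular).

Fit windows default to the tracer mode: 600 s for ¹¹C-acetate (a 10-min
scan), 1800 s for ⁶⁸Ga-DOTA (the full 30-min protocol). Windows must
end on frame boundaries; partial frames are refused. A fit needs at
least 3 frames; an all-zero tissue TAC converges at K1 ≈ 0 and is not
an error. In region-set fits each segment is fitted independently and
one segment's failure is recorded in its slot without aborting the rest.

## Polar maps and infarct sizing

Per-segment K1 values with positive area weights form a `PolarMap`
(default layout: 17 AHA segments, equal weights; the algorithms are
weight-agnostic, so pixel-level maps reduce to the same formulas).
Normalisation rescales to percent of the maximal K1; since any cutoff
below 100% classifies the maximal segment as viable, the global maximum
is the viable maximum, which resolves the apparent circularity of
"normalise to the viable maximum". The infarct area is the
area-weighted percentage of segments strictly below the 60% cutoff; a
segment exactly at 60% is viable. A caveat tested explicitly: the
monotonicity "lowering a segment never shrinks the infarct" holds at a
fixed normalisation reference; lowering the unique maximum itself moves
the 100% point and can reclassify other segments.

Remote and infarct quantification segments are explicit sets (defaults:
septal segments {2, 3, 8, 9, 14} remote; anterior/anterolateral
{1, 6, 7, 12, 13, 16} infarct); regional K1 is the area-weighted mean
and the contrast is reported as remote/MI with the orientation in the
name.

## SUV and late retention

SUV = concentration / (injected activity / body weight), assuming
1 g/mL tissue. TACs are assumed decay-corrected to injection time
before SUV or fitting; `decay_correct` (frame-midpoint 2^(Δt/T½)
scaling) handles uncorrected input and refuses double correction.
Late retention is the duration-weighted SUV mean over 25–30 min
post-injection; the early-peak window is 0–20 s. Both windows are
config defaults and overridable. Negative noisy TAC values are
preserved everywhere (clipping would bias fits and SUV summaries).

## Autoradiography

Count density = total ROI counts / ROI area (PSL/mm²); background is
subtracted in density space, which under mean aggregation equals
pixel-space subtraction. Negative corrected densities are preserved and
flagged. The infarct/remote fold ratio is calibration-free. Default
pixel size 0.025 mm (25 µm plate scanner), overridable; plain-text
grids and single-channel TIFFs are read, 16-bit TIFF values taken as
raw PSL proxy counts without a calibration curve.

## Statistics

Mean ± sample SD (ddof 1; SD reported missing for n = 1). "Student's
t-test" is the classical equal-variance test (Welch behind a flag);
paired tests are used for within-animal contrasts, unpaired for
MI-vs-sham, and the pairing is labelled in every report. Zero-variance
degenerate inputs are flagged (t = 0, p = 1 for exactly null
differences; infinite t, p = 0 otherwise) rather than returned as NaN.
Regression is OLS with Pearson r and the two-sided p from
`t = r√((n−2)/(1−r²))`; p is undefined below n = 3. Two-sided p-values
throughout; the 0.05 threshold is echoed in reports but never used to
drop data. Computation is delegated to scipy.stats; tests cross-check
hand closed forms and, for small samples, an exact permutation oracle
(rank agreement on strictly-ordered pairs — the permutation p has a
1/C(n, k) resolution floor).

## Synthetic studies

The generator emulates a two-tracer rat MI study end to end:

- **Input function**: a Feng-type bolus
  `Cp(t) = (A1(t−τ) − A2 − A3)e^(−λ1(t−τ)) + A2e^(−λ2(t−τ)) + A3e^(−λ3(t−τ))`,
  defaults τ = 0.1 min, A1 = 36 000 kBq·mL⁻¹·min⁻¹, A2 = 600,
  A3 = 560 kBq·mL⁻¹, λ = (6, 1.2, 0.06) min⁻¹. Amplitudes scale with
  injected dose per body weight (reference 29 MBq / 300 g). Defaults
  were chosen so the LV curve peaks within 20 s of injection at a
  rat-bolus amplitude, the remote early-peak SUV is ≈ 8.8, remote late
  SUV ≈ 0.9–1.0 and the late MI/remote SUV ratio ≈ 1.2.
- **Cohort**: 6 MI + 6 sham animals, 17 segments, remote K1
  0.9 ± 0.15 mL·min⁻¹·mL⁻¹ between animals with 5% within-animal
  segment scatter; remote-to-infarct K1 ratio 4.7 ± 0.6 (acetate) and
  4.3 ± 1.0 (DOTA); k2 0.5 / 1.0 min⁻¹ (± 10%) for acetate / DOTA;
  Vb 0.12 ± 0.02. Doses: acetate 27 ± 5 MBq, DOTA 29 ± 3 (MI) and
  14 ± 1 MBq (sham); body weight 300 ± 25 g (a typical adult
  Sprague-Dawley scale). Sham hearts are kinetically homogeneous.
- **Late retention** in the infarct is modelled as a reduced infarct k2
  (scale 0.25 for DOTA, 0.3 for acetate) — the smallest mechanism that
  reproduces, within a 1TCM world, the early remote-dominance /
  late infarct-dominance crossover of an extracellular tracer pooling
  in the enlarged extracellular space. This is a modelling choice, not
  a physiological claim; no quantitative washout rate for infarcted
  tissue is asserted.
- **Noise**: zero-mean Gaussian per frame with
  `sd = α·√(max(c̄, c_floor)/Δt)` (Δt in minutes, default α = 0.3,
  c_floor = 0.01 kBq/mL), a count-statistics proxy making long frames
  proportionally quieter. This emulates reconstructed-image noise
  magnitude scaling, not its correlation structure.
- **Autoradiograph phantoms**: an annular LV section with an
  anterolateral infarct sector at ρ× the remote density, uniform plate
  background, optional Gaussian noise, and infarct/remote/background
  ROI masks with margins off the sector borders.
- **Seeding**: one integer seed expands into per-animal, per-stage
  `numpy` SeedSequence substreams keyed by (animal key, stage, tracer),
  so reordering or regenerating single animals never changes another
  animal's draws; outputs are byte-reproducible.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: partial-volume and spill-over
effects between cavity and wall (the dominant small-animal confound),
motion, scatter/randoms structure, reconstruction-correlated noise,
metabolite kinetics, or anatomical variation in segment geometry.
Recovery results on synthetic cohorts bound estimation error under the
model's own assumptions only.

## Problem sizes used in the test suite

Self-tests run at desk scale: forward-model oracle comparisons use 100
random parameter draws on a 10-minute window; noisy K1 recovery uses 50
seeded single-region fits; the study-level battery runs the full
6 + 6-animal, 52-frame, 17-segment pipeline for 20 seeds with the
30-minute tracer (the two-tracer pipeline is exercised separately); the
acceptance script performs one complete two-tracer run. These sizes
keep a full run in the minutes range on one CPU while leaving the
study conditions themselves (cohort size, schedule, noise) at their
defaults.

## Known limitations

- No delay/dispersion fitting of the input function; biased K1 if
  applied to data with substantial transit delay.
- Equal-variance t-tests mirror conventional reporting; for strongly
  heteroscedastic groups use the Welch flag.
- The normalisation maximum is a single segment value; a smoothed
  maximum (as some clinical software uses) would shift infarct
  fractions slightly near the threshold.
- 16-bit TIFF autoradiographs are treated as linear PSL proxies; no
  instrument calibration curve is applied.
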