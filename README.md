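# myoperf

Quantitative analysis of dynamic cardiac PET in small animals:
one-tissue-compartment kinetic modelling with an image-derived
left-ventricular input function, SUV and late-retention quantification,
polar-map infarct sizing with a viability threshold, ex-vivo
autoradiography quantification, and the group statistics that tie a
two-tracer myocardial-infarction study together.

The package is aimed at preclinical imaging scientists who quantify
myocardial perfusion from dynamic PET (e.g. rat coronary-ligation models
imaged with a perfusion tracer such as ¹¹C-acetate and an extracellular
chelate such as ⁶⁸Ga-DOTA) and who want every stage — from time–activity
curves to the final t-tests — reproducible and testable without scanner
data. A built-in synthetic-study generator produces complete cohorts
with known ground truth.

## The model

Tracer exchange between blood and a single tissue compartment:

    dCt/dt = K1·Ca(t) − k2·Ct(t),    Ct(0) = 0
    C_PET(t) = (1 − Vb)·Ct(t) + Vb·Ca(t)

where `Ca` is the arterial input taken from a left-ventricular cavity
ROI, `K1` (mL·min⁻¹·mL⁻¹) is the uptake rate — the perfusion surrogate —
`k2` (min⁻¹) the tissue-to-blood clearance, and `Vb` the fractional
blood volume. The tissue solution is the convolution
`Ct(t) = K1 ∫₀ᵗ Ca(s)·e^(−k2(t−s)) ds`, evaluated exactly for
piecewise-linear `Ca` on a fine grid and averaged over the acquisition
frames. `(K1, k2, Vb)` are estimated by frame-duration-weighted
nonlinear least squares under box bounds with fixed multi-start
initialisation.

Downstream, per-segment K1 values form a bullseye polar map, normalised
to the maximal (viable) K1 = 100%; segments strictly below 60% count as
infarcted, and the infarct area is their area-weighted percentage.
Autoradiographs are quantified as background-subtracted count densities
(PSL/mm²) with the infarct/remote fold ratio. Statistics follow the
conventional small-animal reporting style: mean ± SD, Student's t-tests
(paired and unpaired), and OLS regression with Pearson r.

## Worked example

Fit one myocardial segment of a synthetic infarcted animal:

```python
from myoperf import OneTissueModel, make_ground_truth, simulate_study
from myoperf.synthetic import TRACER_DOTA

gt = make_ground_truth(seed=1)            # 6 MI + 6 sham animals
study = simulate_study(gt)                # 52-frame, 30-min protocol
animal = gt.animals[0]
block = study.data[animal.animal_id][TRACER_DOTA]

model = OneTissueModel(block["segments"][3], block["input"], fit_window_s=1800)
res = model.fit()
print(res.summary())
```

```
One-tissue compartment model fit
================================================
region: seg03
frames used: 52    fit window: 1800 s
weighted RSS: 118.864    converged: True
------------------------------------------------
 param     estimate      std err  at bound
    K1       1.0578      0.01444     False
    k2      0.88239       0.0133     False
    Vb     0.090878     0.006805     False
================================================
```

The true parameters behind this noisy segment were
`K1 = 1.030, k2 = 0.856, Vb = 0.097`: the fitted K1 is within ~3% of
truth and each estimate sits within about two standard errors. Running
the whole cohort instead of one segment:

```sh
myoperf run-all --seed 1 --outdir out/
```

prints, among other lines,

```
remote_mi_k1_ratio[c11-acetate]: 5.083 ± 0.6784 (n=6)
remote_mi_k1_ratio[ga68-dota]: 4.395 ± 0.7685 (n=6)
sham_anterior_septum_k1_ratio[ga68-dota]: 0.9956 ± 0.04545 (n=6)
late_suv_mi_remote_ratio[ga68-dota]: 1.134 ± 0.2551 (n=6)
autorad fold ratio (infarct/remote): 4.61
```

i.e. the pipeline recovers the configured remote-to-infarct perfusion
contrast (truth 4.7× and 4.3× for the two tracers), a null contrast in
sham animals, the late-phase retention excess in the infarct, and the
autoradiographic fold — each traceable to the per-animal tables and
intermediate files written to `out/`.

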