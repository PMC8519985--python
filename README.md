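# dilkit

Kinetic analysis of **short-duration (22-min) dynamic PSMA-PET** and **CT
perfusion** for localizing the dominant intraprostatic lesion (DIL) in
prostate cancer — implemented as a fully synthetic, testable pipeline.

Localized prostate cancer usually has one dominant focus whose accurate
delineation matters for targeted biopsy, radiotherapy boosting and focal
ablation. PSMA tracers such as [¹⁸F]DCFPyL image that focus well, but the
standard static SUV readout requires waiting ~2 h post-injection. Kinetic
analysis of a much shorter dynamic acquisition can separate blood-borne
tracer from specifically bound tracer and recover the uptake parameters
early. `dilkit` is aimed at researchers in quantitative PET/CT who want a
self-contained, reproducible implementation of that analysis chain — from
forward models through voxel-wise estimation to cross-validated lesion
classification — runnable entirely on digital phantoms (no patient data).

## Models

**Dynamic PET — flow-modified two-tissue compartment (F2TC).** The impulse
residue function prepends a vascular delivery phase (flow *F*, transit
window *W*) to the reversible two-tissue compartment model:

    H(t) = 0                                   t < t0
    H(t) = F                                   t0 ≤ t < t0 + W
    H(t) = K1·[(k3+k4−α)e^{−αt'} + (β−k3−k4)e^{−βt'}]/(β−α)   t' = t−t0−W ≥ 0

with α,β = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4k2k4)]/2. A tissue time–activity
curve is the frame-averaged convolution of the arterial input with H.
Derived quantities: net uptake rate constant **Ki = K1·k3/(k2+k3)** and
distribution volume **DV = (K1/k2)(1 + k3/k4)**, plus SUV_Early (mean of
the 10–22-min frames) and SUV_Late (2-h window).

**CT perfusion — adiabatic tissue homogeneity (Johnson–Wilson).** The
residue function is a unit plateau of length *Tc* followed by an
interstitial tail `E·exp(−E·BF·t'/(60·Ve))`; tissue enhancement is the
BF-scaled convolution with the contrast input. Derived maps: **BV =
BF·Tc/60**, **MTT = Tc**, **PS = −BF·ln(1−E)** (Crone–Renkin).

**Classification.** Per-patient paired Wilcoxon signed-rank screening of
the 13 parametric maps (exact permutation distribution, Bonferroni m=13),
voxel-wise multivariable logistic regression with backward elimination on
Wald p-values, leave-one-patient-out cross-validation (ER/FPR/FNR/AUC),
and Dice similarity of the detected lesion mask against ground truth.

The synthetic module generates phantom cohorts whose class-median kinetics
reproduce the reported DIL vs non-DIL contrast (e.g. K1 0.236 vs 0.187
mL/min/g, Ki 0.055 vs 0.036 mL/min/g, BF 56.58 vs 46.43 mL/min/100 g) on
the exact acquisition schedules (28 PET frames over 22 min; two-phase
2.8 s/15 s CT sampling over 3 min).

## Worked example

Generate a noiseless lesion-class tissue curve on the 22-min schedule and
recover its kinetics:

```python
from dilkit import (pet_frame_schedule, default_pet_aif_params, f2tc_forward,
                    fit_f2tc, FitOptions)
from dilkit.synthetic import dil_reference_f2tc

schedule = pet_frame_schedule()
aif = default_pet_aif_params()
truth = dil_reference_f2tc()
tac = f2tc_forward(truth, aif, schedule)
fit = fit_f2tc(tac, aif, schedule, FitOptions(n_starts=5, seed=1))
print(f"K1 = {fit.params.K1:.3f} mL/min/g   (generating value 0.236)")
print(f"k4 = {fit.params.k4:.3f} /min       (generating value 0.085)")
print(f"Ki = {fit.ki:.3f} mL/min/g   (generating value 0.055)")
print(f"DV = {fit.dv:.2f} mL/g       (generating value 2.29)")
print(f"converged = {fit.converged}, residual SS = {fit.rss:.2e}")
```

Output:

```
K1 = 0.236 mL/min/g   (generating value 0.236)
k4 = 0.085 /min       (generating value 0.085)
Ki = 0.055 mL/min/g   (generating value 0.055)
DV = 2.29 mL/g       (generating value 2.29)
converged = True, residual SS = 3.07e-32
```

K1 is the tracer influx rate into tissue, k4 the dissociation rate from
the PSMA target; a lesion voxel shows high Ki (avid net uptake) and low k4
(stable binding). On noiseless input the weighted multi-start estimator
returns the generating values to machine precision.

The end-to-end phantom study (simulate → smooth → fit 13 maps per voxel →
screen → select → cross-validate → Dice) runs from the shell:

```bash
dilkit run-all --out runs/demo --seed 0
dilkit simulate --out phantoms --patients 2 --seed 1
dilkit evaluate --table voxels.csv --model ki_k4 --out cv.json
```

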