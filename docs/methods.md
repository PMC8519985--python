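# Methods

This note records the models, numerical choices and design decisions behind
`dilkit`, and what the synthetic validation does and does not demonstrate.

## Kinetic models

### Flow-modified two-tissue compartment (PET)

The F2TC impulse residue function used throughout is

- `H(t) = 0` for `t < t0`;
- `H(t) = F` on the vascular window `[t0, t0+W)`;
- `H(t) = K1·[(k3+k4−α)e^{−αt'} + (β−k3−k4)e^{−βt'}]/(β−α)` afterwards,
  `t' = t − t0 − W`, with eigenvalues
  `α, β = [(k2+k3+k4) ∓ √((k2+k3+k4)² − 4·k2·k4)]/2`.

H is continuous from the right at the window edge (`H(t0+W) = K1`), bounded
by `0 ≤ H ≤ F`, and the repeated-eigenvalue case is evaluated through its
analytic limit `K1·e^{−αt'}(1 + (k3+k4−α)t')` rather than failing. The
measured tissue curve is the frame-average of `AIF ⊛ H`. Whole-blood and
plasma concentrations are not distinguished (a single arterial curve drives
the model), and radioactive decay is assumed corrected to injection time.

Derived quantities follow the standard identities `Ki = K1·k3/(k2+k3)` and
`DV = (K1/k2)(1 + k3/k4)`. The vascular window contributes `F·W` of
residence area but is deliberately excluded from DV, which we define over
the exchangeable compartments only; `DV` is flagged undefined when `k2` or
`k4` is fitted at zero instead of being silently extrapolated.

### Adiabatic tissue homogeneity (CT perfusion)

`R(t)` is 0 before the contrast delay `T0`, 1 during the capillary transit
`[T0, T0+Tc)`, and `E·exp(−E·BF·t'/(60·Ve))` afterwards. Tissue enhancement
is `(BF/100)/60 · (AIF ⊛ R)` — flow expressed per mL of tissue at density
1 g/mL so tissue and arterial curves share one concentration unit. Derived
maps are `BV = BF·Tc/60`, `MTT = Tc` and `PS = −BF·ln(1−E)`.

MTT is defined as the *vascular* transit time `Tc`, and BV excludes
extravasated tracer. This makes BF, MTT and PS independently settable, which
is necessary for all three class-median contrasts to be representable at
once; the trade-off is that the generator cannot simultaneously reproduce
the published BV medians, which violate `BV = BF·MTT/60` by about 6%
(commercial perfusion software may define BV over a larger blood space).
Hounsfield-to-concentration conversion and breathing-motion registration
are out of scope: phantom curves are already concentration-like and
motion-free.

## Arterial input functions

The PET input is a tri-exponential bolus (Feng form): a linear-rise-times-
exponential delivery term plus two washout exponentials, zero before a 15-s
arrival delay, peaking ~60 s post-injection, with washout half-times of
~1.4 min and ~46 min. The CT input is a gamma-variate bolus (peak ~10.5 s
after an 8-s arrival) plus a delayed, 20%-amplitude gamma-variate
recirculation bump. Both forms are closed-form, non-negative and
integrable; image-derived AIF extraction from an artery ROI is not
modelled. The PET amplitude is calibrated once so that the lesion-class
reference kinetics yield an early SUV of 2.53 g/mL at the cohort dosimetry
(325 MBq, 88.8 kg), tying the synthetic activity scale to the reported
medians.

## Reference tissue classes

Class parameter sets are anchored to the reported class voxel medians:

| quantity | lesion (DIL) | non-lesion |
|---|---|---|
| K1 (mL/min/g) | 0.236 | 0.187 |
| k4 (1/min) | 0.085 | 0.130 |
| Ki (mL/min/g) | 0.055 | 0.036 |
| DV (mL/g) | 2.29 | 1.17 |
| BF (mL/min/100 g) | 56.58 | 46.43 |
| MTT (s) | 8.94 | 8.07 |
| PS (mL/min/100 g) | 24.39 | 19.44 |

`k2` and `k3` are not reported; they are the unique closure of the Ki and
DV identities given K1 and k4 (`k2 = K1/(DV − K1·Ki/((K1−Ki)·k4))`,
`k3 = Ki·k2/(K1−Ki)`), giving k2 = 0.1632/0.2261 and k3 = 0.0496/0.0539
per minute for the two classes. The PET vascular phase re-expresses the
perfusion medians per gram (`F = BF/100`, `W = MTT`). The extraction
fraction closes the Crone–Renkin identity (`E = 1 − exp(−PS/BF)`, 0.3502
and 0.3421); the interstitial volume Ve = 15 mL/100 g is a free choice in
the normal soft-tissue range. The late-uptake scale of each class is
calibrated so the 2-h forward-model SUV equals the reported SUV_Late
medians (1.55 / 0.67 g/mL), absorbing late binding accumulation the 22-min
model does not represent.

## Synthetic data

Two generator tiers serve different validation purposes.

**Image-level phantoms** (`simulate_study`, `make_cohort`): an ellipsoidal
prostate (default semi-axes 12×12×5 voxels on a 26×26×12 grid at
2×2×3.27 mm — ~3000 prostate voxels per patient, so the default 15-patient
cohort pools ~45k voxels) containing an ellipsoidal lesion of ~12% of the
prostate volume. Every in-prostate voxel receives class parameters with
voxel-level log-normal jitter (default σ = 0.25), its PET/CTP curves from
the forward models, a late-SUV volume from the 120–135-min window, and
stored truth maps. Patients differ by a multiplicative log-normal factor
per parameter (default σ = 0.1) *shared between the two classes of a
patient* — a patient-level effect that preserves the paired class contrast,
as the signed-rank design assumes.

Frame noise is mean-zero Gaussian with variance proportional to
value/duration — the standard frame-weighted proxy, matching the
duration-weighted fitting — made unit-invariant by a per-curve reference
amplitude: `SD = noise_scale·√(value/Δt)·√(mean value·mean Δt)`, so
`noise_scale` reads as the relative noise of an average-intensity,
average-duration frame (0.1 ≈ 10%). Values are clamped non-negative.
Poisson emission statistics, scatter, partial volume and reconstruction
physics are not modelled.

**Feature-level voxel tables** (`simulate_voxel_table`): per-voxel values
of the 13 parametric maps drawn log-normally around class medians with
nested patient (σ = 0.12), class-by-patient (σ = 0.03) and voxel
(σ = 0.35) variation. `k2`, `k3` and `T0` carry equal class medians (they
did not separate the classes in the source data). The voxel spread was
chosen once to give a realistic cross-validated AUC (~0.88 for the Ki+k4
model). Features are drawn independently, so inter-map correlations and
deterministic identities (e.g. BV = BF·MTT/60) are *not* present at voxel
level; this tier validates the selection/validation machinery at scale
without per-voxel refitting, not the estimators.

Passing tests on these phantoms demonstrates internal consistency
(estimators invert the forward models; the statistics behave as designed
under known contrast), not clinical performance: real voxel data are
spatially correlated, motion-affected and reconstruction-smoothed in ways
the generator does not emulate. The published patient-cohort figures (AUC
90.4%, ER 9.9%, Dice 0.8) are therefore treated as directional context
only — the suite checks the *ordering* (kinetic model above the perfusion
model) rather than those values.

## Estimation

Both estimators are weighted nonlinear least squares with weights
proportional to frame duration (the inverse of the generator's noise
variance profile, up to the value factor). Convolution runs on a fine
uniform grid — 0.5 s for PET and 0.2 s for CT, each ≪ the shortest frame
and chosen to land every frame boundary on the grid — with the exponential
kernels applied by an O(n) recursion that is exact for the piecewise-linear
interpolant of the input, and box (vascular/transit) terms as differences
of the running integral.

The models are linear in their amplitudes, so the fits use variable
projection: only the shape parameters are optimised by bounded
trust-region least squares (`W ∈ [0,30] s`, `t0 ∈ [0,60] s`,
`k2,k3,k4 ∈ [0,3] /min`; `Tc ∈ [0,30] s`, `E ∈ [0,0.95]`, washout rate
`∈ [0,5] /s`, `T0 ∈ [0,20] s`), while F/K1 are profiled out by
non-negative least squares in the basis `{b1+b2, b1}` — whose coefficients
`(K1, F−K1)` make the physiological constraint `K1 ≤ F` plain
non-negativity — and BF by a closed-form projection. Amplitudes are capped
at the declared bounds (3 mL/min/g; 300 mL/min/100 g) afterwards. Each fit
runs one fixed mid-range start plus `n_starts` Latin-hypercube starts
(seeded; 5 for single-curve analyses, 1 by default for whole-volume map
production) and keeps the lowest-RSS solution. An all-zero input curve
short-circuits to a zero, `degenerate`-flagged result; non-convergence is
flagged, never raised, during map production.

On noiseless reference curves all parameters are recovered to machine
precision. Under noise, K1 and the CTP parameters are stable, while Ki, k3,
k4 and DV — weakly identified by a 22-min acquisition — are low-bias only
in the low-noise regime (median Ki bias < 10% up to `noise_scale` ≈ 0.02
unsmoothed, ≈ 0.05 with the 3×3 in-slice mean filter); at higher noise they
are visibly biased, consistent with the known limitation of short dynamic
protocols.

## Statistics

*Wilcoxon signed-rank*: exact two-sided p-values from the full
sign-permutation distribution for up to 25 non-zero pairs, computed by a
polynomial-product dynamic programme over doubled midranks (zeros dropped,
ties mid-ranked); normal approximation with continuity and tie corrections
beyond. The screen takes per-patient ROI medians as its paired unit — the
only construction consistent with a signed-rank pairing — and applies
Bonferroni with m = 13 (all maps).

*Logistic regression*: IRLS/Newton with step-halving (the penalised
log-likelihood never decreases), features z-scored internally, Wald
p-values from the inverse Fisher information. Complete separation is
detected by runaway coefficients and handled by a declared L2-ridge refit
(penalty 10⁻³·n on the slopes). Voxels are pooled across patients,
ignoring within-patient correlation — mirroring a voxel-wise analysis and
a known limitation (p-values are anti-conservative). No class re-balancing
is applied; the intercept absorbs prevalence.

*Backward elimination* removes the largest-Wald-p feature while any exceeds
0.05, refitting each step, and never empties the model. *LOPO CV* fixes the
feature set once (selected on the full cohort — the literal reading of
validating "the selected model"; per-fold re-selection is available behind
a flag), refits coefficients per fold, thresholds probabilities at 0.5 for
ER/FPR/FNR and uses raw probabilities for AUC (Mann–Whitney formulation,
ties at ½); single-class held-out folds are flagged and excluded from the
AUC aggregate. Both SD and SE across folds are reported. Detected-lesion
masks are thresholded probability maps (optional largest-26-connected-
component post-processing, off by default) scored by Dice (two empty masks
define 1).

## Determinism and problem sizes

All randomness flows from one master seed: per-patient seeds are spawned
via `numpy.random.SeedSequence`, fits use seeded Latin-hypercube starts,
and voxels are visited in fixed C-order, so a configuration reproduces
bit-for-bit. The default pipeline configuration runs the full chain on a
0.45-scaled geometry (~275 prostate voxels/patient, 15 patients), keeping
whole-cohort per-voxel fitting at minutes on a single core; the test suite
exercises estimator-level claims on a ~64-voxel geometry and
statistics-level claims on feature tables of 300–400 voxels/patient ×
15 patients, sizes at which every asserted property is comfortably
resolved. The acceptance script's recovery targets use single noiseless
curves on the full acquisition schedules.

## Known limitations

- The exact parameterisation of the original flow-modified model is not
  fully published; the piecewise vascular-window form here is a standard
  reconstruction and may differ from the original in how flow enters.
- Units: source text mixes g/mL and mL/g for DV; we follow the results
  convention (mL/g). All internal times are seconds, rates per-minute.
- Feature-level tables ignore inter-parameter correlation; image-level
  phantoms ignore spatial correlation beyond the class geometry.
- No registration, partial-volume, decay or reconstruction modelling; no
  statistical comparison *between* models' AUCs (only point estimates and
  dispersions are produced).
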