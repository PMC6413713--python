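# Methods

## Scope and design

The package implements two quantification chains over 3-D/4-D brain
volumes with region-label atlases, a synthetic generator that emulates
the four-group mouse study the chains were designed for, and the
statistical layer used to compare the groups.  All computation lives in
`src/neuroperf/`; the `analysis/` scripts are thin drivers.

Coordinates are plain 0-based voxel indices; atlas labels travel with
the data and replace manual ROI placement, so registration, motion
correction and skull stripping are out of scope.  The region vocabulary
is fixed: `cortex`, `hippocampus`, `thalamus` for the perfusion arm;
`motor_cortex`, `sensory_cortex`, `striatum`, `hippocampus`, `thalamus`,
`cerebellum` for the reactivity arm; plus the derived `whole_brain`
(all labeled voxels).  Left/right structures are pre-merged in the
atlas.  Reported SDs are sample (n−1) SDs throughout.

## Perfusion (ASL) chain

Model: continuous labeling by slice-selective vs. global inversion gives
two apparent T1s per voxel, and

    CBF = output_scale · λ · (T1_glob/T1_blood) · (1/T1_sel − 1/T1_glob)

with defaults λ = 0.9 ml/g (blood/tissue water partition coefficient),
T1_blood = 2.007 s (blood at 7 T), output_scale = 6000 (ml·g⁻¹·s⁻¹ →
ml/100 g/min).  The formula is implemented exactly in this prefactor
form (T1_glob/T1_blood), not as any algebraically different variant of
the two-compartment literature.  The output unit is labeled
ml/100 g/min, the conventional unit consistent with resting rodent
magnitudes of 100–250.

T1 fitting: magnitude inversion recovery S(TI) = |M0·(1 − η·e^(−TI/T1))|
with inversion efficiency η = 2 by default (a config knob).  Magnitude
data lose the sign of the recovering magnetization, so the fitter tests
every "first k points negative" polarity assignment; at fixed T1 the
model is linear in M0, so a log-spaced T1 grid (0.1–5 s, 48 points) ×
polarity search has closed-form M0 and RSS.  The best candidate seeds a
Gauss–Newton refinement of (T1, M0) with the signs frozen; bounds
[0.05 s, 8 s], parameter tolerance 1e-9, ties broken by RSS then by the
smaller T1 (ascending grid, first minimum).  Constant or all-zero
signals, or non-positive M0, are flagged non-converged and masked
downstream.

Noise-floor handling: near the zero-crossing the magnitude signal is
dominated by the Rician noise floor, which biases plain least squares;
since CBF is a small difference of two large relaxation rates, even a
0.1% differential T1 bias is magnified roughly fifteen-fold.  When a
noise level σ is available the fit therefore refines against the exact
Rician expectation E[R | s, σ] (which is even in the signed signal, so
polarity drops out of this stage).  σ is estimated from background
(unlabeled) voxels via E[R²] = 2σ²; with a clean background the stage
reduces to plain magnitude least squares, preserving exact noiseless
recovery.  Monte Carlo at SNR 50 puts the residual regional CBF bias
near +2% (it was −2.5% without the Rician stage, with the sign flipping
under the simpler `sqrt(R² − 2σ²)` data correction, which is why the
expectation fit was adopted).

Inversion times: the acquisition protocol leaves the TI schedule open;
the default is 8 log-spaced TIs over 0.1–8 s, which spans 0.1·T1 to
beyond 3·T1 for tissue T1s around 1.7 s.

Regional statistics are voxelwise CBF aggregated by ROI (mean over
finite voxels); a region with over half its voxels non-converged is
flagged unreliable.  Negative CBF voxels (noise pushing T1_sel above
T1_glob) are preserved in the map and counted, not clipped.

## Reactivity (CVR) chain

Timing model: 8 pre-contrast scans at baseline Spre; a 100-repetition
main series at 40 s per repetition; vasodilator after repetition 30
(= 20 min); repetitions 31–100 span 0.67–46.7 min post-stimulus.

Kinetics: with an intravascular susceptibility agent at steady state the
T2-weighted log signal drop is proportional to blood volume, giving
CBV0 = −ln(S0/Spre) and ΔCBV%(t) = 100·ln(S(t)/S0)/ln(S0/Spre).  The
ratio-of-log-ratios form is unit-invariant (any global intensity scaling
cancels), which the suite asserts as a property.  Signals are ROI-mean
first, log second ("ROI-mean-then-log"): the mean is taken over the
region's voxels per repetition before any transform, which matches
per-ROI reporting and is far more robust at low signal than
voxelwise logs.

The post-contrast steady-state window defaults to repetitions 15–30
(5 min after contrast through the stimulus), configurable.  The response
fit is OLS of √(ΔCBV%) on t over strictly post-stimulus repetitions
(the repetition at t = 0 still carries the pre-stimulus steady state);
negative ΔCBV% points are clipped to 0 before the square root and their
count reported; the goodness R is the Pearson correlation between the
fitted line and the data (undefined for a zero-variance response).  The
late response is the arithmetic mean of ΔCBV% over repetitions 90–100
inclusive (40–46.7 min).

Exclusion rule: an animal whose whole-brain mean post-stimulus ΔCBV% is
negative is excluded entirely (per-animal, not per-region — the
judgement call is documented here because either reading is plausible);
exclusions are logged with subject id and value.

## Synthetic cohort generator

The generator is the inverse of the two chains, so with zero noise the
full analysis recovers (CBF, CBV0, a, b, late ΔCBV%) to machine
precision — asserted at 1e-6 relative in the suite.

* **Phantom**: 48×48×8 grid (0.15×0.2×1 mm voxels), seven disjoint box
  ROIs covering both region sets, baseline 100 a.u. inside the brain
  box, 0 outside.  Each region is at least 8 voxels; overlaps are
  rejected.  A reduced 16×16×4 variant exists for Monte-Carlo work.
* **ASL**: per-region true CBF is converted to a selective T1 by
  inverting the perfusion formula; both series follow magnitude IR with
  full inversion (η = 2); Rician noise adds independent N(0, σ) to both
  quadrature channels before the magnitude.
* **CVR**: pre-contrast block at Spre; repetitions through the stimulus
  at S0 = Spre·e^(−CBV0); afterwards S(t) = S0·(S0/Spre)^(ΔCBV%(t)/100)
  with ΔCBV%(t) = (a·t + b)².  Truth ΔCBV% is exactly 0 before the
  stimulus; the estimators still compute it from data, so pre-stimulus
  curves show noise around 0.  The response is instantaneous (√-linear
  from t = 0⁺) rather than smoothly ramping, because the analysis fits
  the whole 0–46.7 min window.  A `response_sign = −1` switch simulates
  contrast failure (rising signal) to exercise the exclusion rule.
* **Cohort**: four genotype × treatment groups with n = 8/9/9/11 and the
  study's sex split.  Between-subject variation is Gaussian on the
  regional truths (truncated at 0 by rejection), not on scan noise,
  because the study's group SDs (tens of ml/100 g/min) far exceed
  within-scan noise.  Group CBF means/SDs: cortex 165.4±31.1 /
  165.4±31.1 / 123.0±40.8 / 167.6±33.9 and thalamus 200.5±38.4 /
  200.5±38.4 / 154.1±61.1 / 196.3±43.8 for control / treated control /
  transgenic / treated transgenic; hippocampal perfusion was not
  reported, so it is set between the two (180±35 control, 170±40
  transgenic, treated arms tracking their genotype's pattern — a mild,
  non-significant reduction).  Response (a, b) means and SDs per group
  and region come from the study's regression table (caudate nucleus
  mapped to `striatum`).  Those printed ± values are per-group
  regression uncertainties, which understates the between-subject spread
  implied by the late-response SDs; adopting them as subject-level SDs
  makes group orderings sharper than in vivo, which the ordering
  property test should be read in light of.  Baseline CBV truth is
  0.5±0.05 everywhere (a ~40% signal drop, typical for iron-oxide doses
  of this size; the study reported no group differences).  Default scan
  noise is σ = 2 on a 100 a.u. baseline (SNR 50) for both arms.
* **Seeding**: one master seed; child seeds spawn deterministically per
  subject and per modality (`numpy.random.SeedSequence`), so any subset
  of modalities reproduces bit-identically.

What the generator does not emulate: realistic anatomy, partial-volume
effects, motion, B0/B1 inhomogeneity, bolus first-pass dynamics,
hemodynamic onset ramps, or slice-wise ROI statistics (volumetric ROIs
are used; the per-slice alternative is indistinguishable from the box
phantom anyway).  Passing tests therefore validate the estimators and
their statistical calibration, not robustness to those real-data
effects.

## Statistical layer

* Power: exact noncentral-F, power = P(F′(k−1, k(n−1), f²kn) > F_crit);
  minimal n by integer search.  At the study design (k = 4, f = 0.72,
  α = 0.05, target 80%) the exact computation gives n = 7 with power
  0.8504 (β = 0.1496).
* Summary t-test: pooled Student t by default (df = n1+n2−2), Welch
  optional.  Pooled is the default because it reproduces the study's
  printed p = 0.0338 from the printed summaries at n = 6/6 exactly;
  group sizes 6/6 are adopted where the source is internally
  inconsistent (6 vs 7 in one place, 6 vs 6 in another).
* Two-way ANOVA: fixed effects with interaction, Type III sums of
  squares with sum-to-zero contrasts (statsmodels OLS + anova_lm),
  mirroring the behavior of the GUI statistics package the study used on
  its unbalanced groups.  Region enters as a stratifier — one ANOVA per
  region — rather than as a model factor, since the original modeling of
  region is not recoverable; p-values are Tukey-adjusted within one
  ANOVA family only, with no correction across families.
* Tukey–Kramer: authored on scipy's studentized-range distribution,
  q = |Δ|/√(MSE/2·(1/ni+1/nj)), cross-checked in the suite against
  statsmodels' implementation and against the pooled-error pairwise
  t-test it must dominate.
* Shapiro–Wilk and Pearson test–retest delegate to scipy.

## Problem sizes and runtimes

Monte-Carlo suites run on the reduced 16×16×4 phantom: 20 subjects per
arm for the SNR-50 recovery checks, 100 cohort replicates for the
slope-ordering property, 10 000 null simulations for the two-way ANOVA
type-I calibration (interaction-term rate 0.05 ± 0.01), and 100 000
replicates for the power-function simulation check.  The full-size
phantom is the default everywhere else, including the `analysis/`
drivers.  These sizes were chosen so the whole suite completes in a few
minutes on one CPU while keeping Monte-Carlo error well below each
test's tolerance.

## Known limitations

* The Rician-expectation T1 fit leaves a ~2% regional CBF bias at
  SNR 50 — inherent to differencing two relaxation rates — and the
  quoted bias bound (3%) holds at the default TI schedule; sparser or
  narrower TI ranges degrade it.
* The exclusion rule and the steady-state window are interpretations of
  an under-specified protocol (documented above); both are configurable.
* Between-subject response SDs adopted from the regression table are
  optimistic (see above).
* Statistical calibration is verified under Gaussian nulls; the
  pipeline's real sampling distributions after clipping/exclusion are
  only approximately normal.
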