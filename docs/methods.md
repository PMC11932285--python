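# Methods

## Scope and data model

The package analyses processed (phased, baseline-corrected) 1D ¹H-NMR
urine spectra for a two-group comparison. Raw-FID processing (window
functions, Fourier transform, phasing, baseline reconstruction) and
2D-NMR assignment are out of scope: spectra enter as two-column
(ppm, intensity) text and every metabolite is represented by one
overlap-free resonance in a signal library (name, half-open integration
window in ppm, proton count, multiplicity).

The reference study design is 12 exposed vs 13 control subjects and 50
quantified variables: 46 named urinary metabolites and 4 unknown
compounds (U01–U04), with TSP (9 equivalent protons, 0 ppm) as the
internal concentration standard and the creatinine singlet at 4.05 ppm
as the dilution reference. The creatinine reference entry carries 3
protons as a fixture constant.

## Internal-standard quantification

Window integrals use the trapezoidal rule on the native grid, with the
intensity linearly interpolated at the window bounds so the integral
covers exactly [lo, hi). No baseline is subtracted inside windows
(spectra are assumed baseline-corrected); negative integrals, possible
with noisy baselines, are clamped to zero with a logged warning.

For signal *m*: c_m = [(I_m / n_m) / (I_TSP / 9)] × c_TSP, with
c_TSP = 1.82 mM by default. The creatinine concentration used for
normalisation is quantified from its own singlet through the same
formula, and analyte output is 1000 × c_m / c_creatinine in µmol/mmol
creatinine. Because the quantity is a ratio of integrals, it is
invariant to any overall intensity rescaling of the spectrum.

## Synthetic-data generator

`simulate_concentrations` draws each subject × metabolite entry
log-normally around a per-metabolite baseline (the baseline is the
population median); exposed-group medians are multiplied by
2^(log2 fold change) per effect. Defaults are the study conditions:
n = 12 + 13, sigma = 0.3 on the natural-log scale, and the
direction-of-change pattern of 22 variables shifted toward the control
group and 6 toward the exposed group (log2 fold changes of ∓0.5, about
1.15 pooled standard deviations on the log scale) with furoylglycine at
+2 (a 4× median ratio). Baseline levels are plausible urinary values
(µmol/mmol creatinine) chosen once; trimethyl (9-proton) resonances sit
at modest concentrations so that no quantification window is dominated
by a neighbour's Lorentzian tail.

`synthesize_spectrum` renders a subject's spectrum as a sum of
Lorentzian multiplets (binomial line intensities, default singlets) on a
uniform grid from −0.3 to 9.5 ppm. Each metabolite's total multiplet
area equals its molar concentration times its proton count, so the
quantification chain inverts the construction. Numerical choices:

* window half-width 0.02 ppm for every signal — a uniform width makes
  the truncated fraction of each Lorentzian identical across signals, so
  it cancels exactly in the internal-standard ratio;
* linewidth (HWHM) 0.0002 ppm with grid step 5 × 10⁻⁵ ppm (~4 points per
  HWHM), keeping trapezoidal integration error well under 0.1% and
  neighbour-tail leakage small against every window's own signal;
* optional additive Gaussian noise (default off) drawn from a stream
  derived from the cohort seed.

With noise off, quantifying a synthesized cohort recovers the true
concentrations to better than 1% relative error for every metabolite
(verified over multiple seeds in the test suite). What the generator
does **not** emulate: peak overlap, phase and baseline artifacts,
chemical-shift drift with pH/ionic strength, water/urea residuals, and
inter-metabolite correlation structure (variables are drawn
independently). Passing tests therefore demonstrate correctness of the
analysis chain, not robustness to real-spectrum artifacts.

## PLS-DA and repeated double cross-validation

The classifier is PLS1 (NIPALS) on autoscaled data against ±1 class
codes (+1 = Exposed, −1 = CTRL); y is centered internally, prediction
thresholds at 0 with exact ties assigned to the positive class.
Autoscaling uses ddof = 1 standard deviations; a zero-variance column is
an error naming the column. The regression coefficient vector is
recovered as b = W(PᵀW)⁻¹q; coefficient paths for all truncations of the
latent-variable sequence are stored so nested cross-validation evaluates
every model complexity from a single fit. Components are terminated
early if a weight or score norm underflows (1e-12).

DCV geometry (all knobs in `DcvConfig`): 20 repetitions × 5 stratified
outer folds × 5 stratified inner folds, maximum 5 latent variables
(capped by training-set size). The inner criterion is minimum mean
misclassification rate; ties go to fewer latent variables. Autoscaling
is refitted inside each outer-training set, honouring the validation
contract; a single global pre-scaling is available behind
`global_scaling=True` as a diagnostic. Stratified folds are built by
round-robin assignment of per-class permuted indices; all randomness
derives from one master seed via per-repetition and per-fold seed
sequences, making results bit-reproducible. These repetition/fold counts
are the package's own defaults — standard chemometrics practice — and
the problem sizes used in the test suite (25 × 50) match the reference
design.

For the two-class case the discriminant subspace is one-dimensional;
its canonical representative ("CV1") is taken as the unit-norm
coefficient vector b, signed so the exposed centroid projects positive.
The first weight vector w₁ is available instead via `cv1_mode="w1"`.

Figures of merit (sensitivity, specificity, accuracy, percent correct
classification, all in percent with Exposed as the positive class) are
computed from each repetition's pooled outer predictions; accuracy and
percent correct coincide by construction for a pooled two-class table
and both are reported because both are conventional.

## Sign-stability variable selection

Each outer-fold model of each repetition contributes one CV1 weight
sample (100 samples at the default geometry). A variable is selected iff
(a) every sample has the same sign and (b) the percentile interval at
the configured level (default 95%) excludes zero. Positive median weight
assigns the variable to the Exposed group, negative to CTRL.

**Known limitation — anti-conservative at small n.** The weight samples
are not independent draws: every fold model is fitted on 80% of the same
25 subjects, so a noise variable whose chance sample correlation with
the class labels is moderately large (|r| ≳ 0.25, expected for a
handful of variables out of dozens at n = 25) keeps its sign in every
fold model. Measured on null simulations at the reference design, the
per-variable selection rate is ~18%, far above the nominal 5%
complement of the confidence level, and in effect simulations the rule
admits ~4–5 false selections alongside ~91% recovery of 28 injected
variables. Increasing repetitions tightens the all-same-sign condition
but trades recovery for specificity (50 repetitions: ~2 false
selections, ~79% recovery). Users should read the selection as a
stability ranking, not a calibrated test; a permutation-based
calibration would be the natural extension.

## Univariate branch

Per metabolite: Shapiro–Wilk on each group and median-centered Levene
across groups, both at α = 0.05 (config-exposed). Both-normal and
homoscedastic routes to the equal-variance two-sample t-test; anything
else to the Wilcoxon rank-sum test — exact enumeration when both groups
have n ≤ 10 and no ties, otherwise the normal approximation with tie and
continuity correction. Two-sided p-values; significance at p < 0.05 with
no multiple-testing correction by default, Benjamini–Hochberg adjusted
p-values always emitted alongside. Direction comes from group medians
(means break exact median ties); constant data in both groups yields a
flagged degenerate result with p = 1. Under the global null at the
reference design the non-rejection rate measures ≈ 95% (the acceptance
script recomputes this on 2000 simulated variables). For Gaussian
equal-variance groups the t-route is taken in ~86–87% of draws — the
product of three assumption checks each passing at the 95% level — not
more.

## Pipeline

The `urinmr` command chains simulate → quantify → analyze → univariate
with a YAML config (unknown sections rejected before any stage runs),
one master seed, logging to stderr and file, and a JSON manifest
echoing the effective configuration; reruns with the same config and
seed are byte-identical. Each stage also runs standalone on the
documented text formats, and quantifying pre-generated spectra
reproduces the end-to-end intermediate matrix exactly.
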