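# urinmr

Urinary ¹H-NMR metabolomics for small two-group occupational-exposure
studies: internal-standard quantification of processed 1D spectra,
PLS-DA classification validated by repeated double cross-validation
(DCV), sign-stability variable selection, and an assumption-routed
univariate branch — plus a synthetic-data generator with known ground
truth so the whole chain is testable end to end without any external
data.

## Who this is for

Metabolomics practitioners comparing a small exposed-worker group against
matched controls from urine NMR profiles. The reference design is 12
exposed vs 13 control subjects with 50 quantified variables (46 named
urinary metabolites plus 4 unknown compounds), each metabolite quantified
from one overlap-free resonance.

## The methods

**Quantification.** For each metabolite resonance *m* with window
integral *I_m* generated by *n_m* protons, and a TSP internal-standard
singlet at 0 ppm (9 protons, spiked to a known concentration, default
1.82 mM):

    c_m [mM] = (I_m / n_m) / (I_TSP / 9) × c_TSP

Concentrations are then divided by the creatinine concentration —
quantified from its 4.05 ppm singlet by the same formula — and reported
as µmol/mmol creatinine to correct for urine dilution.

**Classification.** Two-class PLS-DA: NIPALS PLS1 regression of
autoscaled concentrations against ±1 class codes (+1 = Exposed). The
validation is repeated double cross-validation: per repetition, a
stratified 5-fold outer split; per outer fold, an inner 5-fold CV on the
outer-training set picks the number of latent variables (minimum
misclassification, ties to the smaller model), autoscaling is fitted on
the outer-training set only, and the refit model predicts the untouched
fold. Figures of merit (sensitivity, specificity, accuracy, percent
correct classification) are computed per repetition and summarised as
mean ± sd over 20 repetitions.

**Variable selection.** Every outer-fold model contributes one sample of
the unit-norm discriminant direction ("CV1 weights", the PLS regression
coefficient vector, oriented so the exposed centroid projects positive).
A variable is significant when all weight samples share one sign *and*
the 95% percentile interval of the samples excludes zero; its sign
assigns it to the CTRL or Exposed group.

**Univariate branch.** Per metabolite, Shapiro–Wilk normality checks on
each group and a median-centered Levene homoscedasticity check route the
comparison to an equal-variance two-sample *t*-test or a Wilcoxon
rank-sum test, two-sided at the 95% confidence level, with
Benjamini–Hochberg adjusted p-values reported alongside.

## Worked example

```python
from urinmr import (SimulationConfig, DcvConfig, paper_effects,
                    simulate_concentrations, double_cross_validate,
                    select_significant_variables, run_univariate)

m = simulate_concentrations(SimulationConfig(seed=11, effects=paper_effects()))
res = double_cross_validate(m.values, m.class_codes(), DcvConfig(seed=11))
report = select_significant_variables(res)
uni = run_univariate(m)

s = res.summary()
print(f"accuracy {s['accuracy']['mean']:.1f} +/- {s['accuracy']['sd']:.1f} %")
print("selected variables:", len(report.selected))
print(report.table.loc["furoylglycine"])
```

prints

```
accuracy 100.0 +/- 0.0 %
selected variables: 36
median_weight        0.264036
ci_lo                 0.25291
ci_hi                0.279681
sign_consistency          1.0
selected                 True
group                 Exposed
```

The simulated cohort carries the reference direction-of-change pattern
(22 metabolites lower and 6 higher in the exposed group, furoylglycine
4× higher), so the exposed and control groups are fully separable and
the exposure marker furoylglycine is recovered with a stably positive
(Exposed-pointing) weight; the univariate branch flags it at
p = 2.5 × 10⁻⁵ (rank-sum, up in exposed).

The same chain runs from a shell, from synthetic spectra on disk through
every report:

```sh
urinmr all --seed 11 --out-dir out/
```

which writes `spectra/` (two-column ppm/intensity text files plus a
subject manifest), `concentrations.csv`, `dcv_summary.json`,
`selection.csv`, `univariate.csv` and a reproducibility manifest.

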