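# Methods

This package implements the statistical workflow behind an
ultrasound-assisted extraction optimization and HPLC-DAD quantification
method for leaf polyphenols of *Cecropia* species: design-of-experiments
screening, response-surface optimization, ICH-style method validation,
external-standard quantification with censoring, and chemometric analysis
of the resulting composition matrix. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Experimental designs

**Fractional factorial screening.** Seven extraction factors (methanol
fraction A, extraction time B, number of methanol extractions C,
temperature D, mass/solvent ratio E, number of acetone extractions F,
particle size G) are screened on a regular 2^(7−3) fraction — 16 factorial
runs plus duplicate centre points. The generator words are not part of the
published record; the package defaults to **E = ABC, F = BCD, G = ACD**, a
resolution-IV choice under which no main effect is aliased with another
main effect and the seven two-factor alias classes have representatives
{AB, AC, AD, AE, AF, AG, BD} — exactly the interaction set reported
alongside the seven main effects (14 contrasts; the 15th contrast of a
16-run design is confounded with three-factor interactions only).
Generators are configurable. Designs are emitted in standard (Yates)
order; an optional seeded shuffle is provided.

**Central composite design.** Two factors (methanol fraction X1,
temperature X2) at five coded levels {−α, −1, 0, +1, +α} with α = 1.414
(rotatable), 4 factorial + 4 axial + 3 centre runs by default. The
coded↔natural mapping is mandatory configuration; the documented defaults
centre the design at 70 % (v/v) methanol (half-range 20) and 60 °C
(half-range 10). All model arithmetic is done in coded units, so nothing
downstream depends on this mapping.

## Effect screening (Dong-style critical effect)

An effect is E_x = mean(y at +1) − mean(y at −1) along a contrast column;
centre points are excluded. A saturated fraction leaves no residual
degrees of freedom, so the effect standard error is estimated from the
small effects themselves, and the critical effect is

    E_critical = t(1 − α, one-sided; dof = m) × (SE)_e ,

with m the number of estimated effects (14 here) and α = 0.05. Two
retention rules for (SE)_e are implemented because the three published
thresholds are not mutually consistent with a single rule:

* `lowest75` (default): (SE)_e is the RMS of the floor(0.75·m) smallest
  |E_x|. Reproduces the published thresholds for chlorogenic acid (10.97)
  and flavonolignans (0.47) to 2 decimals.
* `dong_classic`: initial scale s0 = 1.5 × median|E_x|; retain |E_x| ≤
  2.5·s0; (SE)_e is the RMS of the retained set. Reproduces the published
  total-flavonoid threshold (84.54; computed 84.56).

Both results are always reported. The one-sided t quantile with dof = m is
what the published numbers require; note that applied to |E_x| it is a
two-sided test at level 2α, so the pure-noise false-flag rate corresponds
to α when the function is called with α/2. The flavonolignan response of
the published table has factor F (0.85) above its threshold (0.47) but
unstarred in print; classification here follows the threshold rule.

## Response surface and optimization

The full quadratic y = b0 + Σ bᵢXᵢ + Σ bᵢᵢXᵢ² + Σ bᵢⱼXᵢXⱼ is fit by OLS
(statsmodels) in coded units with per-coefficient t tests, matching the
published coefficient/SE/p layout; lack-of-fit ANOVA is deliberately
omitted (not part of the published record). Optima are located by grid
search (coded step 0.01) over a square [−1.414, 1.414]² or the
circumscribed disk, polished by constrained local ascent; ties break
toward lower temperature, then lower methanol. Multi-response optimization
uses Derringer-type desirability: each response is linearly scaled to
[0, 1] by its min/max over the search region and the geometric mean is
maximized — invariant to positive affine rescaling of any one response.
Verification compares predicted and experimental means by a Welch t test
from summary statistics (nominal n = 3 on the predicted side,
configurable); the percent difference is |pred − exp|/pred × 100.

## Method validation

* **Linearity** — OLS calibration (≥ 5 levels) with r², slope/intercept t
  tests (N−2 dof, α = 0.05), 95 % CIs, and per-level replicate %RSD
  against a 5 % homoscedasticity screen. **Mandel's fitting test** at
  α = 0.01 compares first- and second-order fits: DS² = RSS₁ − RSS₂,
  F = DS²/s²_quad vs F(1−α; 1, N−3). Exact fits are recognised with a
  relative tolerance of 1e−20 on the residual sum of squares (perfect
  linear data → F = 0 by convention; perfect quadratic with nonzero DS² →
  F = ∞).
* **Precision** — repeatability s_r² pools within-cell variances of the
  day × level table (cells weighted by dof if unbalanced); intermediate
  precision adds a between-cell component from a one-way random-effects
  decomposition, s_R² = s_r² + max(0, (MS_between − MS_within)/n), with
  the day/level cells treated as a single random grouping (the published
  summary reports one intermediate value across days *and* levels; a
  two-way decomposition is not attempted). Both are %RSD on the grand
  mean — which presumes determinations are on a common scale, i.e.
  expressed relative to nominal content when levels differ.
  **Cochran's C** = s²_max/Σs²ⱼ with the F-based closed-form critical
  value C = [1 + (k−1)/F(α/k; n−1, (k−1)(n−1))]⁻¹; empirical size at
  α = 0.05 is ≈ 5 % (measured 4.3–5.7 % over 1000-draw batches).
* **Horwitz limits** — RSD_R = 2^(1−0.5·log₁₀C) for a dimensionless mass
  fraction C, with the repeatability limit exactly 2/3 of it. The C
  values behind the published limits are unprinted, so consistency is
  checked through the 2/3 relation.
* **Accuracy** — the headline recovery is the unweighted mean of the
  per-level mean recoveries (this is what reproduces the published
  means); %RSD and the t-based 95 % CI use raw replicates when present.
  Pass criteria: CI contains 100 %, mean within 98–102 %, %RSD at or
  below a repeatability reference.
* **Detection limits** — LoD = 3.3σ/slope and LoQ = 10σ/slope with σ the
  intercept standard error, or empirically the lowest concentrations
  meeting S/N ≥ 3 and %RSD ≤ 5 on a dilution series. The published
  LoQ/LoD ratios (~2.5) are not consistent with the 3.3/10 multipliers;
  the printed limits are therefore carried as reference data only.

## Quantification

Single-point external standards: conc = area/area_std × conc_std, with
chlorogenic acid quantified against its own standard (20.12 µg/mL),
flavone C-glycosides and flavonolignans as vitexin equivalents
(20.32 µg/mL; flavonolignans at 390 nm) and flavonol O-glycosides as
rutin equivalents (18.69 µg/mL). Mass fraction = conc × flask volume ×
dilution / sample mass (default 50 mL, 1:2 dilution, 1:30 mass/solvent
ratio → 1.667 g). Compounds below their LoQ contribute **zero** to totals
and category sums (the convention required to reproduce the published
totals from quantified rows; LOQ/2 imputation is available but
non-default), and a total whose members are all censored is itself
reported censored. Totals: TF sums all flavonoid rows, total FL the
flavonolignans. The packaged composition table carries 36 compounds × 19
samples; two of its printed cells are internally inconsistent (one SD
lost in extraction, one flavonolignan total that contradicts its member
rows) and are documented in the fixture rather than repaired.

## Chemometrics

The 8-category roll-up (CA, LG, AG, LMG, AMG, DG, QG, FL) feeds pairwise
Pearson correlations and a PCA computed by SVD of the centred,
unit-variance-scaled matrix (the standard choice for concentration data
of disparate magnitude; the original preprocessing is unstated, so the
published 79.0 % three-component figure is treated as a ±5-point
qualitative check — this implementation gives 76.5 %). Sign convention:
the largest-magnitude entry of each loading vector is positive, making
scores reproducible across linear-algebra backends. Zero-variance
categories are dropped before scaling with a warning; their correlations
are reported missing.

## Synthetic data

Generators (all seeded through `numpy.random.default_rng`; same seed →
bit-identical tables) emulate each stage's inputs: screening responses as
grand mean + half-effect contrasts + additive Gaussian noise; CCD
responses as quadratic surface + Gaussian noise; calibration as a
homoscedastic straight line; precision as level mean + day effect +
residual (two Gaussian variance components); recoveries as Gaussian
around a true percentage; dilution series with S/N proportional to
concentration; and peak tables back-computed from the packaged
composition table with multiplicative lognormal area noise (mean-one, so
zero noise reproduces the table exactly). Default sample sizes mirror the
study protocol: duplicate centre points, 11-run CCD, six calibration
levels in triplicate, 4 days × 3 levels × 6 replicates, three spike
levels in triplicate, n = 3 preparations. Gaussian noise is the minimal
assumption consistent with the t/F statistics applied downstream; the
generators do not emulate retention-time drift, peak overlap,
heteroscedastic detector response or non-normal contamination, so passing
tests demonstrate correctness of the statistics, not robustness of the
bench method to those effects.

## Problem sizes and determinism

Simulation-based checks use 100–1000 seeded repetitions (binomial or χ²
acceptance bands at 99 % confidence); the whole suite runs in well under
a minute on one core. All stochastic tests are fixed-seed; hypothesis
property tests run derandomized.

## Known limitations

* The raw design-response tables behind the screening/optimization stages
  are supplementary-only, so those fits are validated by
  parameter-recovery on synthetic data rather than end-to-end
  reproduction; the published verification row (predicted 1786.0/356.6/
  13.9) is carried as reference data.
* The published "% Difference (CV)" column of the verification table
  matches no recoverable formula and is not computed.
* Intermediate precision treats day/level cells as one random grouping;
  day-crossed-level designs with strong interactions would need the
  non-default two-way option.
* The desirability criterion of the original optimization software is
  undocumented; the linear Derringer scaling used here is a documented
  package choice.
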