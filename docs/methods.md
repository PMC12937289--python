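# Methods

This note documents the models, conventions and design choices behind
feedval, in the order the pipeline applies them.

## Compositions and variability

An `IngredientComposition` is an analyte panel (percent of mass; MJ/kg for
gross energy; mg/kg for trace minerals) with an explicit reporting basis.
Basis conversion is a single common rescaling by the dry-matter fraction,
so analyte ratios are invariant and a round trip reproduces the input to
machine precision. The dry-matter content itself is basis-free and is never
rescaled. Analyte names live in a controlled vocabulary with
case-insensitive matching; unknown names pass through untouched so the
panel can carry lab-specific assays.

The variability summary reports the arithmetic mean, range, and the
coefficient of variation with the **population** standard deviation
(denominator *n*). This is deliberate: the survey tables the package ships
were computed with that convention (the sample-SD CV of the crude-protein
row would be 11.11%, not the tabulated 10.54%), and the choice is exposed
as `cv_denominator` for users who prefer *n − 1*. CVs are undefined at mean
zero and require at least two samples; both cases raise typed errors
rather than returning NaN.

## Diet and ingredient energy

Diet digestible energy (DE) and metabolizable energy (ME) come from
total-collection balance records: gross-energy intake minus fecal (and,
for ME, urinary) gross energy, per kg of dry-matter intake. Negative
digestibility (fecal energy exceeding intake) is reported with a warning,
never clipped — an aberrant collection should stay visible downstream.

Ingredient energy uses the difference (substitution) method. The corn
basal diet's energy is corrected to its energy-supplying fraction
(`energy_fraction`, default 0.97: the remaining 3% is minerals and premix,
assumed to contribute no energy), and the test ingredient's energy follows
from subtracting the basal contribution at the substitution fraction
`substitution_x` (default 0.30). The substitution fraction is interpreted
*within* the energy-supplying portion — the test ingredient replaces 29.10
of 97.00 parts, 29.10/97.00 = 0.30 — because only this reading makes the
shipped diet and ingredient energy tables mutually consistent: back-solving
the corrected basal DE from each of the ten as-fed rows gives 13.81–13.82
MJ/kg, a spread of 0.011 MJ/kg (`backsolved_basal_energy` exposes this
check; the suite requires agreement within 0.15 MJ/kg).

The per-observation pipeline mirrors the replicated crossover design:
diet energy is computed per pig-period record, the corrected basal energy
is the mean over all basal-diet observations (optionally per period), and
ingredient estimates are averaged by diet. Treatment summaries report the
mean and a pooled SEM (pooled residual SD across diets over √replicates);
mixed-model multiple comparisons are out of scope.

## Ileal digestibility

Apparent ileal digestibility (AID) uses the indigestible-marker ratio
between diet and ileal digesta (TiO₂ at 0.20% of the diet). AID is
invariant to any common rescaling of one sample's concentrations — the
property that makes marker ratios robust to digesta-flow differences — and
is not floored at zero. Standardized ileal digestibility (SID) adds the
basal endogenous-loss credit `100·IAA/AA₂`, with diet amino-acid content
converted to g/kg DM first (the endogenous table is per kg of dry-matter
intake). SID above 100% is legal; proline routinely exceeds it because the
nitrogen-free diet used to measure endogenous losses itself stimulates
proline secretion.

The endogenous-loss table is an *input* with a configurable
`scale_factor` (default 1.0, i.e. values applied verbatim). The shipped
table's magnitudes are large relative to typical basal losses; because the
per-observation digesta concentrations behind it were never published, the
package applies the table as given rather than guessing at a rescaling,
and exposes the factor for sensitivity analysis.

Total amino acids (TAA) are computed from total-AA concentrations, not by
averaging the per-AA digestibilities. Diet-level results average over
pig-period observations; grand means are unweighted means of the ten
per-diet means.

## Correlation screen and prediction equations

Regressions and correlations run on the ten ingredient-level means, DM
basis (n = 10) — the unit on which the shipped ash equation for DE
(21.71 − 0.68·Ash; R² 0.57, RMSE 1.06) is exactly reproducible —
per-observation fitting is available by passing any other table. Pearson
p-values are two-sided from the t distribution with n − 2 df; at n = 10
they agree with a 10⁵-resample permutation test within 0.02 (tested). Two
significance-star conventions are provided, one marking p < 0.05/p < 0.01
and one marking tendency bands (0.05 ≤ p < 0.10 / 0.01 ≤ p < 0.05). No
multiple-testing correction is applied anywhere in the screen — a
deliberate fidelity choice the user should keep in mind when reading the
starred matrices.

Equation selection defaults to exhaustive best-subset search over model
sizes 1..`max_terms` (default 2): with at most a dozen candidates this is
cheap, implements "maximize R², minimize RMSE" literally, and is
reproducible. Ties break toward fewer terms, then lexicographic predictor
names. A classical forward-stepwise selector (entry/stay p of 0.15) exists
for fidelity to traditional stepwise software; the two can disagree, and
best-subset may prefer a two-term fibre model (CF + ADF) where a
significance-driven search keeps only tryptophan. RMSE uses residual
degrees of freedom n − k − 1; the overall F test supplies the model p.

OLS fitting and its diagnostics are delegated to statsmodels; the
selection logic, ranking and equation registry are this package's own.

## Synthetic trials

The simulator exists to validate the estimators, not to model gut
physiology. Its defaults are the study conditions: a replicated 11 × 3
incomplete Latin square (22 pigs, six replicates per diet) for the energy
experiment, a 10 × 6 square (10 cannulated pigs) for the SID experiment,
daily intake at 4% of a 36.47 kg initial body weight over a 5-day
collection, substitution at X = 0.30 with a 0.97 energy fraction, and a
TiO₂ marker at 0.20% of the diet. Default ground-truth parameters are
seeded from the packaged tables (ingredient energies around 13.8–19.1
MJ/kg DM, SIDs spanning the observed spread) so simulated data resemble
the survey; all are overridable.

The design generator is a cyclic Youden square (pig *i*, period *j* →
diet *(i + j) mod n*), randomized by seeded label shuffles. Only the
combinatorial constraints are contractual — every diet exactly at its
replicate count, no pig repeating a diet; the construction requires the
pig count to be a multiple of the diet count and no more periods than
diets. Carryover effects between periods are not simulated.

Noise is multiplicative lognormal with unit mean (concentrations and
energy outputs are positive), defaults 2% CV on fecal/urinary energy and
5% on digesta concentrations; one seeded generator drives all draws, so a
seed fixes the dataset byte-for-byte, and a zero CV degenerates to exactly
1.0 so the zero-noise round trip is exact (tested to 1e-9; observed at
~1e-13). The forward model is the algebraic inverse of the estimators:
diet energy composed as `X·ingredient + (1 − X)·basal/0.97`, digesta
concentrations from the marker mass balance with the digesta marker
concentrated 2.5-fold by default. Because the noise is unit-mean on the
*outputs*, the DE estimator is unbiased by construction; over 1000
replicate trials at 2% noise the measured bias of mean ingredient DE is
below 0.01 MJ/kg (the suite requires < 0.05), and the Monte-Carlo spread
matches first-order error propagation within 15%.

What passing these tests shows — and does not. They establish that the
estimation chain inverts its own generative model and is stable at
realistic assay noise. They cannot establish robustness to features the
generator omits: pig and period effects (optional additive terms are off
by default), incomplete marker recovery, correlated assay errors, or
diet-dependent (specific) endogenous losses.

## Numerical and I/O conventions

All persisted tables are UTF-8 CSV with header rows, carrying percents (as
printed sources do); internal math converts to fractions explicitly at
module boundaries. Unicode minus and dash variants are normalized to ASCII
on ingest. Reported tables round to 2 decimals; all internal computation is
full precision. Anchor checks in `reproduce_tables` compare unrounded
values at half a printed unit, relaxed to one printed unit for the two
quantities (ash-equation intercept, TAA-equation RMSE) whose third decimal
is not recoverable from 2-decimal rounded inputs.

## Known limitations

* No mixed-effects ANOVA or Tukey groupings; treatment tables report
  means ± pooled SEM only.
* No net-energy system, growth modelling, or assay chemistry; compositions
  are taken as measured.
* SID is basal-endogenous-corrected only; true ileal digestibility and
  specific endogenous losses are out of scope.
* Prediction equations are descriptive fits on ten ingredient sources;
  they should not be extrapolated beyond the surveyed composition ranges.
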