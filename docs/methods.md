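# Methods

## Nutritional accounting

Yield observations are long-format records of site x calendar year x
rotation x group x crop, where a *group* is one crossing of experimental
treatments and replicates (two treatments A, B with three replicates give
groups A1..B3). All yields are converted to dry weight from their reported
water content before anything else.

Per-crop conversion to human-available nutrients follows the
food-balance-sheet chain `M = Y (1 − f_H2O)^{-1} α f_ref γ_n`: dry yield is
re-expressed on the fresh retail-product basis via the product's water
fraction, scaled by the crop-to-retail factor (e.g. milling extraction for
flour, oil extraction for seed oil), the edible fraction of the product,
and the nutrient content per kg of product. Calories are carried in
Gcal ha⁻¹ yr⁻¹ and macronutrients in kg ha⁻¹ yr⁻¹; each output row carries
a unit tag.

Forage crops (ley, ryegrass, forage rape, silage maize) have no direct
food value; their dry matter is converted through an end-use scenario:
1.05 l of whole milk or 0.047 kg of boneless beef per kg of dry-matter
intake, or zero for biofuel. Dry-matter intake is taken equal to dry
yield; feed-out losses are not modelled (a deliberate simplification — the
conversion coefficients already embody farm-level efficiencies). The
product mass is already on the fresh retail basis, so only the product's
refuse factor and γ apply. Residue streams of food crops are not credited
to feed. Crops grown for forage in some rotations and food in others are
disambiguated by a per-rotation-year `use` field.

The whole-rotation annual output weights each rotation year by
1/(rotation length): on a fixed land area, a longer rotation devotes
proportionally less area to each phase in any given year. Fallow years
count in the length and contribute zero output. Aggregation requires every
crop of a rotation to be present in every season; a violated cell is an
error, not a silent drop.

Energy factors for diet shares are the standard Atwater densities
(carbohydrate and protein 4 kcal g⁻¹, fat 9 kcal g⁻¹). Note that γ for
calories is per kg of product while Atwater factors are per gram of
macronutrient; the two uses are kept separate and dimensionally
consistent. Recommended ranges are closed intervals (45–65%, 10–35%,
20–35% of calories); a share exactly on a bound counts as within. Percent
changes round half away from zero, matching how integer percents are
conventionally reported.

## Quality control

The outlier screen computes, per site x crop pooling all years, the closed
interval `[Q1 − 2·IQR, Q3 + 2·IQR]`; values strictly outside are flagged
implausible. Quartiles use linear interpolation (numpy default, R type 7);
the convention is configurable because flags can differ at small n, and
groups with fewer than 4 usable values are skipped with a warning. Zeros
never enter the bounds: a zero with an agronomic annotation (fallow, frost)
is an explained zero and kept; an unannotated zero is flagged. Low but
non-zero values inside the bounds are retained — they plausibly reflect
poor growing conditions.

Flagged records (missing, unexplained zero, implausible) are replaced by
the mean of donor records sharing crop, site, calendar year, rotation and
treatment, i.e. differing only in replicate; when a table carries no
treatment column all groups of a site x rotation are treated as replicates
of one treatment. A target without donors causes exclusion of its whole
site x rotation x year x treatment combination, always reported, never
silent. Gap filling is idempotent, and both the filling and the zero
handling are switchable so that sensitivity runs (keep unexplained zeros;
skip filling) are one flag away. Flagged outliers default to
treated-as-missing because the plausibility judgement of extreme values is
an expert decision this package does not automate.

## The mixed model

For each nutrient, `√O` is modelled with fixed effects FR (categorical,
monoculture 1M as reference), scaled time, time², and full FR x time
interactions, plus random intercepts for site, group-in-site and calendar
year. Calendar year (categorical, crossed with site where experiment eras
overlap) absorbs year-specific growing conditions shared by all rotations,
while continuous time captures systematic trends — both are identifiable
because many sites and staggered eras are observed. The square root
stabilises the right-skewed outputs; predictions are back-transformed by
squaring.

**Time scaling.** Time since rotation implementation is divided by a
scaling constant before fitting (default: the maximum observed time), and
the divisor is recorded on the fitted model. Raw-year coefficients from
different datasets are not comparable without knowing this divisor; this
is the single most consequential representation choice in the model and is
surfaced in every serialisation.

**Estimation.** REML, implemented over the Woodbury identity for the
variance-component structure: each criterion evaluation costs O(q³) in the
total number of random-effect levels q, independent of n after one pass of
cross products. The optimiser works on log variance ratios (L-BFGS-B with
a Nelder-Mead polish); ratios below 1e-7 are pinned at zero and reported
as boundary estimates, mirroring the singular-fit behaviour of standard
mixed-model software. Negative responses and non-convergence are hard
errors. The fitter agrees with statsmodels MixedLM and with R lme4 to at
least four significant digits on test fixtures (both serve as independent
oracles in the test suite, not as the implementation — the package needs
Satterthwaite df and seeded multivariate-t adjustments that neither
statsmodels exposes nor the pipeline could take from R).

**Inference.** Contrast standard errors come from the GLS coefficient
covariance; degrees of freedom use Satterthwaite's approximation,
`df = 2f²/(gᵀAg)` with `f = cᵀCov(β)c`, `g` its finite-difference gradient
in the variance parameters and `A` the inverse observed REML information.
Families of contrasts (FR levels within a time, or times within an FR) are
multiplicity-adjusted with the equicoordinate multivariate *t*: adjusted
p = P(max|T_j| ≥ |t_i|) under the family's correlation matrix and the
family's smallest df, evaluated by seeded Monte Carlo (default 10⁵ draws,
standard error ≈ √(p(1−p)/draws)); adjusted p is floored at the raw p to
absorb Monte-Carlo noise. A zero contrast (a time compared with itself)
returns estimate 0 and p 1 rather than an error.

**Predictions.** The sqrt-scale linear predictor's variance includes the
fixed-coefficient uncertainty and, by default, the summed random-intercept
variances ("including the random component", i.e. intervals for a new
site-year); a fixed-only mode gives the narrower conditional alternative.
5–95% intervals use the t quantile at the cell's Satterthwaite df; interval
endpoints are clipped at zero before squaring so lower ≤ prediction ≤
upper always holds. Marginal R² is var(Xβ̂) over the total of fixed,
random and residual variances; conditional R² adds the random components
to the numerator (Nakagawa-style variance partition).

**Sensitivity.** The leave-one-site-out loop refits once per held-out site
and flags contrasts whose sign or significance (at α = 0.05, adjusted p)
changes relative to the full fit; a refit that loses an entire FR level is
reported as degenerate for the affected contrasts instead of crashing.

## Synthetic experiment generator

The generator emulates a network of European LTEs: by default 16 sites of
differing productivity running 11–53 consecutive seasons with start years
staggered over 1970–2005, five rotations spanning FR 1M/1C/2/3 plus one
with fallow, and three replicate groups. Yields arise on the square-root
scale as `s = √(baseline·fr_effect) + trend(t′) + u_site + u_year +
u_group + ε`, truncated at zero and squared, so yields are never negative
and — for single-crop rotations with identity conversion factors — the
analysis model is exactly the generating model. That exactness is what the
parameter-recovery suite exploits (30 sites x 30 years, 100 replicates:
95% CI coverage of all fixed effects within ±5% of nominal; mean
variance-component estimates within 10% of truth). For multi-crop
rotations the mapping from configured effects to sqrt-output coefficients
is only approximate (√ of a sum ≠ sum of √); `true_params` fits the
implied quadratic by least squares and labels the result approximate.

Defaults: dry-yield baselines 6.0/4.5/4.0 t ha⁻¹ for winter wheat, spring
barley and oats, 2.8 for oilseed rape, 3.0 for peas, 7.0 t DM for ley
(typical European magnitudes); grain water content 0.14; FR yield
multipliers {1M: 1.00, 1C: 0.93, 2: 0.96, 3: 1.08} and trends declining
for 1M, rising for 1C and 3 — qualitative shapes chosen to mirror the
direction of diversity effects reported in the LTE literature, not fitted
to any dataset. Random-effect SDs (sqrt-yield scale) are site 8, year 3,
group 2, residual 5: sites dominate, as between-site productivity
differences dominate real networks. Missing records (2.28%) and
unexplained zeros (0.92%) are injected completely at random among actual
yield observations — the data give no missingness mechanism, so MCAR is
the neutral choice — with a provenance flag so QC recall is testable.
Gaussian-on-sqrt-scale is likewise a modelling choice, not an empirical
claim; no distributional form for yields is established.

What passing tests on this generator do show: the pipeline's conversions
are exact, QC recovers exactly what was injected, and the estimator is
calibrated when its assumptions hold. What they do not show: robustness to
real-data features the generator omits — non-Gaussian yield tails,
spatially correlated plots, informative missingness, management changes
mid-experiment, or conversion factors varying with site and season.

## Problem sizes and numerical choices

The test suite runs the recovery study at 30 sites x 30 years x 4
rotations x 2 groups (7,200 records per replicate, 100 replicates) and the
null-calibration study at 6 sites x 8 years x 200 replicates; both sizes
give stable Monte-Carlo estimates of coverage and p-value uniformity while
keeping a full suite run in single-digit minutes. Acceptance reruns the
default 16-site network (~22,000 yield observations, ~31,000 whole-rotation
outputs). Finite-difference steps for the Satterthwaite machinery are
1e-4 of each variance parameter (floored relative to the residual
variance); a numerically perfect fit (zero residual variance) is detected
and derivative-based inference skipped with fallback df = n − p.

## Known limitations

- Conversion factors are constant across sites, years and rotation
  positions; protein responses to rotational nitrogen carryover are not
  modelled.
- The bundled catalogs are representative, not authoritative; factor-value
  sensitive conclusions require user-supplied catalogs.
- Only random intercepts are supported (the stated sensitivity structures
  are subsets of the default); no residual correlation in time.
- Micronutrients, metabolizable-energy feed accounting and herd dynamics
  are out of scope.
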