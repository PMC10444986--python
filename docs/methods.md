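# Methods

This note documents the models, conventions and design choices behind
`florivis`, and what the synthetic-data tests do and do not demonstrate.

## Survey data model

The unit of field observation is the **plot × occasion**: open floral
units of each species counted in a 1 m² plot on a survey date, followed by
timed insect-visit observation (visits stored pre-summed over the two
10-minute observation rounds; round identity is never analysed). Floral
units are flower heads for composites and clovers and single flowers
otherwise, and all per-flower quantities refer to that unit. Missing
occasions (e.g. mowing gaps) are absent rows — never zeros — so trend fits
are not biased by artificial zeros. Two study years are defined as
half-open date intervals (defaults: 21 Apr 2018 – 13 Apr 2019 and
14 Apr 2019 – 4 Apr 2020); month labels are the occasion's calendar month.
Honeybee (managed), Coleoptera and Hemiptera (scarce) records are excluded
by the visit filter before any analysis; removals are logged per group.

## Per-flower quantification

**Nectar sugar.** s = 10·d(C)·v·C µg, with d(C) the empirical
sucrose-solution density polynomial. For the rinse method, the same
relation is applied to the diluted reading with the rinse-water volume
(2 µL default) as v; the nectar's own volume is ignored, as no correction
is defined for the dilution protocol. Concentrations are bounded by the
refractometric limit (85 g/100 g, configurable). No flower-age or
depletion correction is applied — values are relative measures for
comparing species, not absolute productivities.

**Pollen.** Grains per flower N = mean(two 10-µL aliquot counts) · U/10
for suspension volume U; grain volume V = 4/3·π·A·B² from semi-axes of the
grain's major/minor dimensions. Species means are computed **before**
multiplication: mean axis lengths → one grain volume per species, then
species-mean grain count × that volume, converted at 10⁹ µm³/µL. Species
means for both resources are unweighted arithmetic means across samples.
Unmeasured species carry NaN with a zero sample count; absence of
measurement is never coded as a zero resource value, and such species are
excluded resource-wise (a species can contribute to pollen totals but not
sugar totals).

## Availability, contributions, diversity

Plot availability = floral units × species mean, summed over measured
species per plot/occasion, separately per resource. Contribution shares
pool raw totals over all plots and occasions of a (site, month) or
(site, study-year) cell and divide by the grand total; annual shares are
**pooled totals, not averages of monthly proportions**, and months with
two survey occasions contribute both without reweighting. Cells with a
zero denominator are dropped (logged), never emitted as NaN. Visit shares
include species without resource profiles; resource shares never do.
Shares below 10⁻³ are retained (truncation is a display concern only).

Shannon H′ = −Σ p_i ln p_i (nats) over nonzero shares; evenness
J′ = H′/ln S. By default S is the category-specific nonzero richness; a
`site_total` mode divides by the site/year observed richness instead,
since with annual pooled proportions the two definitions differ and both
are defensible. J′ is undefined (NaN) at S = 1. Tukey HSD compares
categories in a one-way layout with sites as replicates within a year —
with four sites this is the only replicate unit available; the error
structure of more elaborate designs (site × year interactions) is out of
scope. Adjusted p-values use the studentized-range distribution directly
(scipy), with a compact letter display derived by insert-and-absorb.

## Seasonal GAMs

One smooth of census day (days since the site's first survey) spans both
study years, with basis dimension k = 10 (reference df ≈ 9). Resource
series are fitted as (value + 0.0001) with a gamma family and log link —
the offset admits exact zeros in a positive continuous model; visit counts
with a negative-binomial family and log link, θ estimated during fitting.
Fitting is delegated to mgcv (thin-plate penalized splines) through a
batched `Rscript` call; smoothing parameters are selected by GCV for the
gamma models and by REML for the negative-binomial models, because θ
estimation requires an ML-type criterion. All of k, criterion and
prediction-grid size are configurable.

Degenerate inputs: a constant (zero-variance) response is reported as an
intercept-only fit with a flat curve and p = 1 (no evidence of
seasonality) rather than passed to the spline fitter, whose test statistic
is meaningless at zero residual variance; all-zero count series are
returned flagged (`fit.error`) rather than raised. Fewer than three
distinct census days is a design error and raises. Fitted-curve peaks are
local maxima with prominence ≥ 10 % of the curve's range (configurable),
which suppresses ripple on near-flat fits.

Calibration, checked by simulation in the test suite: the smooth-term test
on iid negative-binomial counts (26 biweekly occasions × 5 plots) rejects
at 0.01–0.12 at nominal α = 0.05 over 200 series, and two planted activity
peaks (days 60 and 200, sd 25, weekly surveys) are recovered as two local
maxima within ±20 days in ≥ 95 of 100 series.

## Synthetic-data generator

The generator's defaults are the study conditions the pipeline targets:
4 sites × 5 plots of 1 m², two-week survey cadence in year 1 and monthly
in year 2, and a 30-species community — four alien archetypes flowering
~200 days with high per-flower resources (sugar 700–2500 µg, pollen
0.5–1.2 µL per head) and 26 natives with ~50-day staggered windows and
low resources (8–170 µg, 0.02–0.1 µL). Counts are negative-binomial
(θ = 2) around a Gaussian-in-time phenology (sd = duration/6, truncated at
± duration/2), which makes community availability bimodal: a late-spring/
early-summer peak and an autumn peak with a mid-summer trough, dominated
by the aliens throughout.

Resource samples are emitted as raw field measurements whose pipeline
recovery equals the true means: per-sample sugar masses are lognormal
(σ_log = 0.5) around the species mean and re-expressed as
(volume, concentration) pairs — or as rinse-dilution readings for species
under 15 µg/flower, solving 10·d(C)·2·C = s for C; pollen samples choose
an aliquot count near 50 grains/10 µL and set the suspension volume so the
count arithmetic inverts exactly. Zero-variance archetypes therefore
round-trip to machine precision; with σ_log = 0.5 and 50 samples the
species mean is recovered within 15 % in ≈ 95 % of seeds. A few natives
are flagged unmeasured per resource so that coverage bookkeeping and
exclusion paths are always exercised.

Visits: per plot/occasion and group, a negative-binomial total around the
group's seasonal activity curve (bees/wasps bimodal at days 55/180,
hoverflies broad, butterflies late-season — chosen to track the bimodal
floral season, as observed overall visit abundance does), normalized so a
site receives ~10⁴ expected wild visits per study year; totals are
allocated to the plot's flowering species by the regime. Under
`resource_proportional` the weights are floral units × a unit-free
combined index (sugar and pollen each normalized by their community mean
before summing — raw µg + µL would let sugar dominate numerically). Under
`even_preference` weights are configured preference weights (default
equal) over flowering species; `native_biased` additionally inflates
native weights (default ×3). Small honeybee/Coleoptera/Hemiptera counts
are emitted to exercise the wild filter.

What the generator does *not* emulate: per-round visit structure, spatial
autocorrelation between plots, flower-age/depletion dynamics within the
nectar standing crop, observation-hour effects, and site-specific survey
gaps. Passing tests therefore demonstrate correct and calibrated analysis
machinery under the stated generative assumptions, not field realism of
any particular parameter value.

## Regime recovery

The package's headline simulation property: with default conditions, the
diversity gap ΔH = H′(all-insect visits) − mean(H′(sugar), H′(pollen))
averages ≈ 1.6 under `even_preference` (visits spread over ~30 species
vs. alien-dominated resources) and ≈ 0.11 — within the ±0.15 band — under
`resource_proportional`, where visited-flower diversity inherits the
resource concentration. The test suite checks the positive gap in ≥ 90 %
of 50 seeds and the near-zero mean over 50 seeds; `scripts/acceptance.py`
reports both statistics over 10 replicate datasets (sizes chosen to keep
the script's full run under a minute while leaving the per-seed statistic
unchanged).

## Known limitations

- Tukey letters come from pairwise significance only; with unbalanced or
  strongly heteroscedastic panels the one-way HSD assumptions may be
  optimistic.
- The GCV/REML split between families follows the fitting backend's
  requirements; resource and visit models therefore use different
  smoothing criteria.
- The rinse-method inversion assumes the full sugar mass is captured in
  the rinse volume; systematically incomplete rinses would bias small
  flowers' means low in real data (the pipeline has no correction).
- Evenness under the default category-specific richness is not comparable
  across categories with very different richness; use `site_total` mode
  for a common denominator.
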