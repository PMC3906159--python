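# Methods

This note documents the statistical procedures, the synthetic-data
generator that stands in for field data, the numerical choices made where
the design was genuinely open, and the known limitations. No empirical
claim here goes beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## The inference problem

A set of fixed transects, each walked repeatedly through one flight
season, is resurveyed years later with an identical protocol. Under
regional warming the expected signature is *community thermalisation*:
warm-associated species gain relative abundance, cool-associated species
lose it, while habitat structure (which transect hosts which community)
stays put. The package measures that signature three ways — through a
thermal index (CTI), through an elevational classification (T_sp, T_ab),
and through unstructured composition change (ANOSIM / PERMANOVA / per-
species screens) — and separately establishes the temperature trend
itself.

## Thermal classification (atlas.py)

Species are classed from national atlas presence records:
**W** (widespread) iff occupancy > 50% of all atlas localities; otherwise
**HA** iff > 50% of the species' records lie above 1000 m (zones 3–4 of
the atlas' four-grade elevation scale: 0–500, 500–1000, 1000–1500,
>1500 m); otherwise **LA**. Both thresholds are *strict* — at exactly
50% of records above 1000 m a species is LA. The sources the rule comes
from say "more than 50%" and are silent at equality, so the strict
reading was adopted and both thresholds are exposed as parameters.
Atlas records are presences: duplicate (species, locality) pairs collapse.

`sampling_adequacy` reports localities-per-km² per zone and the Spearman
coefficient (mid-rank ties) of the four (localities, area) pairs. No
p-value is attached: with n = 4 the exact permutation floor is 1/12, so
only the coefficient is informative. A fully tied margin returns 0.0
with a `tie_degenerate` flag (the rank covariance is identically zero).

## Community Temperature Index (thermal.py)

CTI of a transect-year is the abundance-weighted mean STI over the
species present, with counts pooled over all visits of that year.
Species lacking an STI are excluded with a logged warning rather than
imputed — the conservative reading when the index is defined over
"species with known STI"; the count of exclusions is carried in the
result. CTI is bounded by the min/max STI present and invariant to
scaling all counts.

The year comparison is a Wilcoxon rank-sum test on the transect-level
CTIs of the two years. The reported W is the Mann-Whitney U of the
*first* sample (sum of its mid-ranks minus n₁(n₁+1)/2) — the convention
of classic statistical software, so published W values are directly
comparable. Exact enumeration is used when n₁+n₂ ≤ 20 and the pooled
data are tie-free; otherwise a normal approximation with mid-rank tie
correction and continuity correction (the two branches agree to within
p ± 0.02 at n₁ = n₂ = 10, asserted in the suite).

The phenology check drops the first visit of the baseline year and the
last visit of the resurvey year and recomputes the comparison: a CTI
change produced merely by species flying earlier would be carried by
those season-edge visits, so a change that survives trimming is a
composition signal.

## Elevational-shift statistics (shift.py)

With widespread species excluded,

    T_sp = L2/(L2+H2) − L1/(L1+H1),    T_ab = l2/(l2+h2) − l1/(l1+h1),

where L/H count low/high-altitude species observed in a year and l/h sum
their individuals. Both statistics lie in [−1, 1], are antisymmetric
under exchanging the years, and are positive when the low-altitude share
grows. The published worked example (25/40 LA/HA species with 913/1557
individuals in the baseline year; 31/40 with 1657/1161 in the resurvey)
gives T_sp = 0.0520 and T_ab = 0.2184, printed as 0.05 and 0.2.

**Null.** Both years equivalent and both classes equally likely in any
sample. It is materialised by shuffling year labels *without
replacement* across elementary units, preserving each year's unit total
and the pooled class margin (asserted on every permutation). The unit is
the individual for T_ab and the species-detection record (a species×year
presence) for T_sp; the choice of unit is exposed behind a flag because
the level at which "no replacement" operates is a genuine modelling
decision. p = (k+1)/(n_perm+1), two-sided on |T|; the decision rule
declares a shift at p < 0.025, kept as the published convention even
though it is a nonstandard threshold. For ≤ 6 units the Monte-Carlo p
matches exhaustive enumeration of all label assignments (asserted).

Under Poisson-like counts the individual-level permutation null is exact
(conditioning on year totals makes the low-class count in one year
hypergeometric); strong within-cell overdispersion would make it
anticonservative, which is why the generator's dispersion is a knob.

## Diversity (diversity.py)

Shannon H′ uses the natural log: with ~15–25 species per transect this
puts values in the 2–3 nat range consistent with published transect-level
magnitudes. Whittaker β = S/ā − 1 over the transects of one habitat
errors on an empty transect (ā semantics undefined) rather than dropping
it silently. Chao1 uses the classic form S_obs + F1²/(2F2), switching to
the bias-corrected S_obs + F1(F1−1)/(2(F2+1)) when F2 = 0; sampling
efficiency is S_obs/Chao1. Year contrasts are two-group OLS — the
minimal "general linear model" yielding one F and one p per contrast —
and equal the squared pooled-variance t (asserted against an oracle).
The contrast is unpaired; repeated-measures pairing across years is left
to the caller. Zero residual variance with a real group difference is
reported as F = ∞, p = 0, flagged degenerate.

## Composition change (composition.py)

Bray-Curtis d = Σ|x−y|/Σ(x+y) on counts; it is a semimetric, so the
triangle inequality is not asserted (symmetry, range and zero diagonal
are). ANOSIM is Clarke's R = (r̄_B − r̄_W)/(M/2) on the mid-ranks of the
M = n(n−1)/2 dissimilarities, with a one-sided permutation p (separation
inflates R); being rank-based it is invariant to monotone transforms of
the distances (property-tested with d → d²).

PERMANOVA uses the distance-based identity SS_total = Σ_{i<j} d²_ij / n
and within-group analogues per group; for the balanced year × transect
crossed design, SS_year and SS_transect are the one-way between-group
sums, the interaction is SS_cells − SS_year − SS_transect, and the
partition sums to SS_total (asserted to 1e-9 relative on every run).
Both factors are *fixed* and p-values come from unrestricted permutation
of sample labels. Treating the repeated transects as a random effect, as
a mixed-model formulation would, is not implemented: the partition (and
hence the degrees of freedom) would differ, which is why published
mixed-design F statistics are not directly comparable. The interaction
is only estimable with ≥ 2 replicate samples (visits) per cell; the
pipeline uses visit-level samples when every cell is balanced with
replicates, and otherwise falls back to one pooled sample per
transect-year without the interaction. A posteriori year tests within
each transect are one-factor permutation tests on that transect's visit
samples — exhaustively enumerated when ≤ 500 distinct assignments exist
— reported raw and Holm-adjusted.

The per-species screen is the two-group Poisson likelihood ratio with a
log-exposure offset, computed in closed form
LR = 2[n₁ ln(r₁/r̄) + n₂ ln(r₂/r̄)] (0·ln 0 ≡ 0) — identical to an
iteratively fitted GLM (asserted to 1e-6 against one) with no
convergence concerns. Percent change is N₂/N₁ − 1 on raw totals,
matching the published signed-percent convention; N₁ = 0 is reported as
a colonization sentinel rather than a number. Raw p-values are the
primary output (the published convention retains species at P < 0.05);
Holm adjustments are reported alongside.

## Climate trend (climate.py)

The in-area (target) station is regressed on the reference station over
their overlap (≥ 3 years required); the fitted line converts the full
reference record into an in-area series. The *model-predicted* series is
used for every year, including years with target observations — a splice
of observed and predicted values would mix two noise variances — with a
`splice_observed` flag for the alternative. The trend is the OLS slope
on year; its null distribution reassigns the observed annual values to
years at random, p two-sided on |slope| with the add-one correction.
Total change is slope × (last − first year): a 0.0432 °C/yr series over
1990–2012 yields 0.95 °C, the magnitude exercised in the noiseless
synthetic check.

## Synthetic data (simulate.py)

The generator emulates the study design rather than any particular
dataset: 7 habitats × 3 transects × 15 visits in each of two years
(subset years with fewer transects/visits are expressible), ~60 species.
Counts per (transect, year, visit, species) are negative binomial with

    log μ = log(baseline) + habitat offset + transect offset
            + 1[year = last] · δ · (STI − mean STI).

Defaults, chosen once as field-realistic and frozen: baseline mean count
0.15 per species-visit (yearly totals ≈ 2800 individuals, the scale of
the motivating surveys); dispersion (NB size) 5 — visit-level transect
counts with sub-1 cell means are near-Poisson, and the biologically
important overdispersion is carried by the explicit offsets; habitat and
transect log-offsets N(0, 0.6²) and N(0, 0.4²), drawn once per dataset
and shared by both years, so between-transect structure is real but
cancels from between-year contrasts; STI uniform on [8, 15] °C (the
European-range span of a Mediterranean butterfly fauna); class mix
(HA, LA, W) = (0.5, 0.4, 0.1), close to the observed 40/31/≤7 split.
Widespread species are drawn at random; the rest are ranked by a
noise-perturbed STI and the coolest ranks become HA, reproducing the
observed STI-vs-elevational-class consistency. δ = 0 makes the years
exchangeable in distribution — the null all resampling tests are
calibrated against; δ·Var(STI) approximates the expected CTI shift
(δ = 0.1 ≈ 0.4 °C), the calibration used in the signal-recovery test.

The atlas generator apportions localities to the four elevation zones
proportionally to zone area, places each species' presences so its true
class is recoverable by construction (recovery is asserted to be 100%),
and gives otherwise-uncovered localities one class-safe record, since an
atlas locality is by definition a place with records.

Station series are a linear trend plus i.i.d. Gaussian noise for the
reference, and a linear recalibration plus independent noise of the same
scale for the target, restricted to its coverage window (defaults:
1990–2012 reference, 1994–2004 target, trend 0.0432 °C/yr, noise sd
0.4 °C).

All randomness descends from one integer seed through CRC-labelled
`SeedSequence` children (`thermoshift._rng`), so any stage re-run in
isolation reproduces its in-pipeline result bit-identically.

**What the generator does not emulate** — and hence what passing tests
do not establish about field data: within-season phenology (visit means
are uniform, so the phenology check's power is only exercised through
constructed cases); species-level abundance heterogeneity (all species
share the baseline, so every species is detected in every year at the
default scale and T_sp is degenerate at 0 — its permutation machinery is
exercised on low-abundance constructions instead); spatial
autocorrelation among transects; detection error; and compositional
(species-specific) habitat preferences — habitat offsets scale all
species alike, which keeps between-year CTI contrasts clean but makes
between-habitat *composition* differences purely abundance-scale.

## Calibration results the suite computes

Over 500 replicate synthetic surveys at the design above with δ = 0, the
empirical type-I error is checked against the central 99% binomial band
of each nominal level: the T_ab Monte-Carlo test (rule p < 0.025), the
CTI rank-sum and the trend randomization (α = 0.05) all sit inside their
bands. The year-grouping ANOSIM does not: it rejects essentially never.
This is a real property, not an implementation defect (R matches an
independent oracle exactly): with one pooled sample per transect-year,
the two samples of the same transect share their abundance offset, so
the 21 same-transect cross-year pairs are systematically the most
similar pairs in the matrix. They are always between-year pairs in the
observed labelling but are scattered by unrestricted permutation, which
biases observed R about two null standard deviations low. Classical
ANOSIM with unrestricted permutation is simply conservative for paired
resurvey designs with real site structure — worth knowing when
interpreting a non-significant ANOSIM from such a design; the same
structure is handled correctly by PERMANOVA's explicit transect term.

## Problem sizes

The suite's simulation studies use 500 replicates for null calibration
and 200 for signal recovery, with 999 permutations/randomizations per
test (1000 is the conventional choice mirrored by the pipeline
defaults); oracle-equivalence checks run on ≤ 8-sample instances where
exhaustive enumeration is feasible. These sizes give binomial-band and
enumeration checks their stated resolution while keeping the full suite
in the minutes range.

## Known limitations

- Fixed-effects PERMANOVA only (see above); published mixed-design F
  values are not reproducible by construction.
- The T_sp/T_ab permutation unit is a modelling choice; published
  p-values depending on the authors' (unrecoverable) unit are out of
  scope.
- STI values are inputs; computing them from European range grids is out
  of scope.
- No autocorrelation-robust trend test; annual values are treated as
  exchangeable under the null.
- No rarefaction, Hill numbers, ordination plots, or GIS.
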