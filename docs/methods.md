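# Methods

## Diversity framework

All diversity values are effective numbers of species: the count of
equally abundant, completely distinct species giving the same index value.
For relative abundances `p` (zeros dropped, renormalized) and order `q ≥ 0`
the naive Hill number is `(Σ p_i^q)^(1/(1−q))`, and the
similarity-sensitive value replaces species rarity `1/p_i` by reciprocal
ordinariness `1/(Zp)_i`, where `Z` is an S × S similarity matrix with unit
diagonal and entries in [0, 1] (1 = completely identical, 0 = completely
distinct). `q = 1` is always computed by its analytic limit (the
exponential of the similarity-weighted entropy), never by numeric limiting;
unit tests check continuity across `q = 1 ± 1e−6` at 1e−4.

Per-site ("alpha") diversity uses the subcommunity convention: species with
zero count at a site are dropped and `Z` is subset to the species present.
This makes the `q = 0` naive value equal the site's observed richness.
Effective numbers are kept unrounded internally; rounding happens only in
the report layer.

Redundancy is the ratio of naive to similarity-constrained richness at
`q = 0`. Because `(Zp)_i ≥ p_i` for any unit-diagonal `Z`, constrained
diversity never exceeds naive diversity and redundancy is ≥ 1.

## Similarity matrices

* **Naive**: identity.
* **Functional**: one matrix per trait, never pooled. A single categorical
  trait gives Gower similarity 1 (match) / 0 (mismatch); a single
  continuous trait gives `1 − |x_i − x_j| / range`. Pairs involving a
  missing categorical value receive the mean similarity of all fully
  observed pairs for that trait (logged as imputed); this keeps `Z`
  complete without dropping species. A wingspan published as a min–max
  range is collapsed to its midpoint first.
* **Taxonomic**: equal step lengths over (species, genus, family),
  normalized so the maximum distance is 1: similarity 1 within a species,
  2/3 within a genus, 1/3 within a family, 0 across families. Variable
  step lengths weighted by clade sizes exist in the literature but depend
  on the sampled pool; equal steps are reproducible and are the common
  default, so they are used here.

Phylogenetic (branch-length) similarity is deliberately out of scope: moth
phylogenies are not resolved finely enough at the community level.

## Permutation null model and SES

The null model shuffles abundance values across species independently
within each site. This preserves each site's total abundance, richness and
count multiset while breaking the trait–abundance association — randomly
assembled communities of equal species richness. The wording "permute
abundance across each site" could also mean reassigning whole trait rows
across the species pool; that alternative is available as
`shuffle_trait_rows` / the `traits` permutation scheme, but the per-site
shuffle is the default because it conditions on the observed abundance
structure. Each permutation re-derives relative abundances and re-subsets
`Z`, consistent with the subcommunity convention.

SES = (observed − null mean) / null sd with the sample sd (ddof = 1). A
site whose null distribution is degenerate (for a crisp categorical trait
at `q = 0` the statistic is the integer count of categories present, which
small permutation counts may never change) is an error at the operation
level; the pipeline skips such sites with a warning. The habitat-level
test is a no-intercept linear model of SES on habitat, equivalent to a
one-sample t test of mean SES = 0 per habitat ((n − 1) df). Negative mean
SES indicates environmental filtering, positive niche complementarity.

Calibration: when the observed community is itself a draw from the null,
|SES| > 1.96 in ≈5% of independent communities (checked over 500
communities with 199 permutations each). Within one study, site-level SES
share a single trait-table realization and are therefore positively
correlated; a single study's habitat test can deviate from zero by more
than its within-study SE suggests (per-study mean SES has sd ≈ 0.9 under
neutral simulation). This is a property of the design, not of the
implementation; the filtering positive control is detected reliably
because the filter effect is much larger than this between-study spread.

## Mixed models

Each response (one diversity value per site) gets a habitat fixed effect
(broadleaf reference, plantation indicator) and two random intercept
terms: pair-within-year and pair-within-month — pairs, not individual
sites, are the repeated unit in a paired design. With each pair sampled in
a single year and month the two groupings induce the same partition of
sites and only the **sum** of their variances is identifiable; the
Gaussian fit then uses one variance component, reports it under
`pair_year` with `pair_month` pinned at zero, and flags the fit singular.
An observation-level alternative (`random_structure="site"`) and a
no-random-terms reduction (`"none"`, which reproduces OLS to 1e−8) are
available.

* **Gaussian** responses (constrained effective numbers, redundancy
  ratios, naive q = 1, 2): REML via statsmodels `MixedLM` variance
  components. No transformation is applied to effective numbers.
* **Poisson** responses (naive richness, q = 0, log link): maximum
  likelihood with a Laplace approximation, implemented in
  `lepdiv.mixedmodels`. The inner Newton solve finds the conditional mode
  of the random effects (tolerance 1e−10); the outer L-BFGS-B optimizes
  fixed effects and log-SDs of the random terms (ftol 1e−12, log-SD
  bounded in [−7, 3]; an SD at or below 1e−4 flags a boundary/singular
  fit). Fixed-effect covariance comes from the fixed-effect block of the
  inverse joint observed information at the mode. The fit is validated in
  the test suite against `lme4::glmer` (coefficients to 1e−3; SEs to 5%;
  variance-component sum to 15%).

Variance explained uses the variance-partitioning R²: marginal
= var(fixed predictor) / total, conditional adds the random-intercept
variances to the numerator; the denominator is fixed + random + residual
variance. For the Poisson model the latent-scale residual variance uses
the log-normal approximation `ln(1 + 1/λ̄)` with `λ̄ = exp(intercept)`. A
constant response (e.g. a categorical constraint at q = 0 when every site
covers every category) has zero total variance; such fits short-circuit to
a degenerate result (effect 0, R² undefined/NaN, flagged singular) rather
than erroring the pipeline.

Effects are flagged "significant" when |estimate| > SE (the ±1 SE interval
excludes zero). This field convention is liberal — under a zero effect it
fires at roughly the 32% implied by one-SE coverage, which the test suite
verifies — so the flag is reported alongside t values rather than p-values.
No multiple-testing correction is applied across model rows.

## Synthetic study generator

The generator emulates a paired light-trapping study; its defaults are the
study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_pairs` | 13 | broadleaf/plantation site pairs (26 sites) |
| `pool_size` | 120 | regional species pool |
| `mean_richness_broadleaf` / `sd` | 63 / 3 | per-site species richness draw |
| `mean_richness_plantation` / `sd` | 27 / 5 | idem, plantation |
| `abundance_model` | log-series | regional abundance distribution (lognormal alternative) |
| `trait_sharing` | 1.0 | probability rare species duplicate common species' trait profiles |
| `habitat_effect_on_traits` | 0.0 | plantation penalty exp(−4·f) on disfavoured host plants (herb, lichen) |
| `pair_effect_sd` | 0.1 | log-scale pair-level richness multiplier (feeds the random intercepts) |
| `mean_count_per_species` | 6 | site total ≈ 6 × richness individuals |
| `wingspan_median_mm` / `log_sd` | 32 / 0.35 | log-normal wingspan |

Structure: species are indexed by decreasing regional commonness;
log-series regional abundances (shape 0.995) are assigned by rank.
Broadleaf sites sample their richness (clipped normal, times the pair
multiplier) weighted by regional abundance; plantation sites sample a
subset of their pair's broadleaf community with extra commonness bias
(exponent 1.5). Under `trait_sharing`, rare pool species copy full trait
profiles from the common half, and a repair step swaps species so that
every categorical-trait category present in the broadleaf community stays
covered in the plantation subset — this is the operational meaning of
"rare species share functional traits with common species", and it is what
makes constrained diversity equal between habitats while naive richness
halves. Counts are `1 + Poisson` proportional to regional abundance. Pairs
split across two years and three summer months to exercise the nested
random effects. All randomness flows from one seed through a spawned
`SeedSequence` tree (pool, communities, permutation streams).

What the generator does **not** emulate: detection/trap-night effects,
spatial autocorrelation between pairs, micro-moth communities, intra-site
trap heterogeneity, and any trait–abundance correlation beyond the
sharing/filter mechanisms. Passing tests therefore demonstrate that the
pipeline recovers known structure of this generative model, not that the
field study's numbers are reproduced; with the original abundance/trait
CSVs supplied, the same pipeline computes the corresponding empirical
quantities directly.

## Problem sizes used in checks

Framework exactness: 1,000 random communities (identity-Z agreement to
1e−10). Null calibration: 500 independent communities × 199 permutations.
Signature recovery: 100 studies in the test suite, 50 in the acceptance
script; a study's signature = significant naive Poisson deficit +
non-significant host-plant q = 0 difference + higher broadleaf redundancy.
Smaller Monte-Carlo sizes (e.g. 60 replicates for Poisson effect coverage,
150 for the SE-rule firing rate, 12 seeds for generator calibration) keep
the default test run fast while leaving the binomial error well inside the
asserted bands. The pipeline default of 999 permutations matches standard
practice for SES null models.

## Known limitations

* With a single categorical trait, constrained diversity at q = 0 is an
  integer (categories present), so Gaussian LMMs on such responses are
  frequently degenerate or near-degenerate; q = 1, 2 responses are smooth.
* The Laplace approximation can understate random-effect variance for very
  small counts; at the richness scales here (λ ≈ 15–65) it is accurate,
  as the lme4 cross-check shows.
* The variance split between the two coincident random terms is reported
  as identifiable-sum-plus-zero rather than an arbitrary 50/50 split.
* SES tests within one study inherit trait-table-level correlation (see
  above); between-study replication is the honest calibration target.
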