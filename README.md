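# lepdiv

Similarity-sensitive diversity analysis for paired insect communities
sampled under contrasting disturbance regimes.

## The scientific problem

Species richness treats every species as equally different, so it can
overstate the ecological cost of losing species that are functional
duplicates of species still present. `lepdiv` implements the
similarity-sensitive Hill-number framework for a paired study design —
macro-moth communities light-trapped in native broadleaf woodlands versus
intensively managed conifer plantations — and asks three questions:

1. Does the apparent habitat difference depend on the diversity metric
   (naive vs taxonomically or functionally constrained)?
2. Do the habitats differ in functional **redundancy** (species per
   functional role)?
3. Is there a signal of **environmental filtering** (co-occurring species
   more similar than chance) in either habitat?

## The model

The Hill number of order *q* is the effective number of species

> ᵠD(**p**) = (Σᵢ pᵢᵠ)^(1/(1−q)),  with ¹D = exp(−Σᵢ pᵢ ln pᵢ),

where **p** are relative abundances; *q* = 0, 1, 2 give richness,
exponential Shannon entropy, and inverse Simpson concentration. The
similarity-sensitive generalization replaces the rarity 1/pᵢ with the
reciprocal *ordinariness* 1/(Z**p**)ᵢ:

> ᵠD^Z(**p**) = (Σᵢ pᵢ (Z**p**)ᵢ^(q−1))^(1/(1−q)),

where Z is an S × S species-similarity matrix (entries in [0, 1], unit
diagonal). Z = I recovers the naive Hill number; Z built from a single
functional trait (Gower similarity) or from shared taxonomic ranks gives
functionally or taxonomically constrained diversity. Functional redundancy
is naive richness / constrained richness at *q* = 0 (≥ 1).

Habitat contrasts are fitted with mixed models (Poisson GLMM for naive
richness, Gaussian LMM for constrained effective numbers; random
intercepts for pair-in-year and pair-in-month) summarized with marginal and
conditional R² by variance partitioning. Environmental filtering is tested
with a permutation null model: abundances are shuffled across species
within each site, and the standardized effect size
SES = (observed − null mean)/null sd is tested against zero per habitat.

Because the original field data are not redistributable, the package ships
a first-class synthetic generator (`lepdiv.synthetic`) that emulates the
study's structure: 13 site pairs, per-site mean richness 63 (broadleaf) vs
27 (plantation), log-series regional abundances, plantation communities as
common-biased subsets, and rare species sharing trait profiles with common
ones — so naive richness differs sharply between habitats while
functionally constrained diversity does not.

## Worked example

```bash
python examples/06_full_pipeline.py
```

prints (abridged):

```
Per-habitat effective numbers (mean +/- sd):
  naive (q=0): broadleaf: 60.7 +/- 7.6; plantation: 28.6 +/- 6.2 | plantation = 47.1% of broadleaf (deficit 52.9%)
  host_plant (q=0): broadleaf: 6.0 +/- 0.0; plantation: 6.0 +/- 0.0 | plantation = 100.0% of broadleaf (deficit 0.0%)
  ...
Habitat-comparison mixed models (broadleaf = reference):
  naive q=0      [poisson]  intercept 4.10 +/- 0.04, plantation -0.75 +/- 0.06 *, R2m 0.86, R2c 0.90
  host_plant q=0 [gaussian] intercept 6.00 +/- 0.00, plantation 0.00 +/- 0.00,    R2m nan, R2c nan
  redundancy host_plant [gaussian] intercept 10.12 +/- 0.32, plantation -5.35 +/- 0.30 *, ...
```

Reading: plantations hold roughly half the species of their paired
broadleaf sites (log-scale deficit −0.75, i.e. exp(−0.75) ≈ 47%, flagged
significant because the ±1 SE interval excludes zero), yet the
host-plant-constrained effective number is identical — every host-plant
guild is still represented — so the deficit is concentrated in functional
duplicates, and redundancy is correspondingly lower in plantations
(−5.35 species per guild).

Other entry points: `examples/01–05` cover each capability separately, and
a thin CLI mirrors the stages:

```bash
lepdiv simulate --seed 1 --out data/
lepdiv run-all --abundance data/abundance.csv --traits data/traits.csv \
    --taxonomy data/taxonomy.csv --n-perm 999 --seed 1 --out results/
```

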