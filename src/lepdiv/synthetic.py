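"""Synthetic paired-community generator.

Emulates a paired light-trapping study of macro-moth communities in two
woodland types under different disturbance regimes: 13 site pairs, each with
one broadleaf (less disturbed) and one plantation (highly disturbed) site,
sampled across two years and three summer months.  The generator produces
the three pipeline inputs -- abundance, trait and taxonomy tables -- with
the statistical structure the analysis assumes:

* regional species abundances follow a log-series (the classic fit to
  light-trap moth samples; a lognormal alternative is available);
* broadleaf sites draw ~63 species and plantation sites ~27, with
  plantation communities being subsets of their pair's broadleaf community
  biased toward regionally common species;
* rare species share functional trait profiles with common species
  (``trait_sharing``), so that functionally constrained diversity is
  preserved in plantations even though naive richness is halved;
* an optional trait filter (``habitat_effect_on_traits``) suppresses
  species carrying disfavoured trait values from plantation sites, creating
  a positive control for environmental-filtering detection.

Pair-level multiplicative noise on richness creates the between-pair
variance picked up by the random intercepts of the mixed models.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import AbundanceTable, META_COLUMNS

DEFAULT_TRAIT_VOCAB: dict[str, list[str]] = {
    "host_plant": ["herb", "grass", "shrub", "deciduous_tree", "conifer", "lichen"],
    "larval_specialism": ["single_family", "multi_family"],
    "overwintering_stage": ["egg", "larva", "pupa", "adult"],
}

#: host-plant values suppressed in plantations when the trait filter is on
FILTERED_HOST_PLANTS = ("herb", "lichen")


class SyntheticError(ValueError):
    """Invalid study configuration."""


@dataclass
class StudyConfig:
    """Study-level knobs for the generator.

    Defaults encode the emulated study: 13 pairs, per-site mean richness 63
    (broadleaf) vs 27 (plantation) with across-site spreads 3 and 5, a
    log-series regional abundance distribution, and full trait sharing
    between rare and common species (no trait filter).
    """

    n_pairs: int = 13
    pool_size: int = 120
    n_families: int = 12
    n_genera: int = 40
    mean_richness_broadleaf: float = 63.0
    mean_richness_plantation: float = 27.0
    sd_richness_broadleaf: float = 3.0
    sd_richness_plantation: float = 5.0
    abundance_model: str = "log-series"
    trait_sharing: float = 1.0
    habitat_effect_on_traits: float = 0.0
    pair_effect_sd: float = 0.1
    mean_count_per_species: float = 6.0
    plantation_commonness_bias: float = 1.5
    wingspan_median_mm: float = 32.0
    wingspan_log_sd: float = 0.35
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise SyntheticError("n_pairs must be >= 0")
        if not (self.n_families <= self.n_genera <= self.pool_size):
            raise SyntheticError(
                "need n_families <= n_genera <= pool_size"
            )
        if max(self.mean_richness_broadleaf, self.mean_richness_plantation) > self.pool_size:
            raise SyntheticError("mean richness exceeds pool size")
        if not (0 <= self.trait_sharing <= 1):
            raise SyntheticError("trait_sharing must be in [0, 1]")
        if self.habitat_effect_on_traits < 0:
            raise SyntheticError("habitat_effect_on_traits must be >= 0")
        if self.abundance_model not in ("log-series", "lognormal"):
            raise SyntheticError(f"unknown abundance model {self.abundance_model!r}")


def generate_species_pool(
    pool_size: int,
    n_families: int,
    n_genera: int,
    trait_vocab: dict[str, list[str]] | None = None,
    seed=0,
    trait_sharing: float = 0.0,
    wingspan_median_mm: float = 32.0,
    wingspan_log_sd: float = 0.35,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample a species pool: taxonomy plus functional traits.

    Species are indexed in decreasing regional commonness (sp001 most
    common); with probability ``trait_sharing`` each species in the rarer
    half duplicates the full trait profile of a random species from the
    common half.  Returns ``(traits, taxonomy)`` DataFrames.
    """
    if not (1 <= n_families <= n_genera <= pool_size):
        raise SyntheticError("need 1 <= n_families <= n_genera <= pool_size")
    vocab = trait_vocab or DEFAULT_TRAIT_VOCAB
    rng = np.random.default_rng(seed)
    species = [f"sp{i + 1:03d}" for i in range(pool_size)]
    families = [f"fam{i + 1:02d}" for i in range(n_families)]
    genus_family = rng.integers(0, n_families, size=n_genera)
    # every family owns at least one genus
    genus_family[:n_families] = np.arange(n_families)
    species_genus = rng.integers(0, n_genera, size=pool_size)
    species_genus[:n_genera] = np.arange(n_genera)
    rng.shuffle(species_genus)
    taxonomy = pd.DataFrame(
        {
            "species_id": species,
            "genus": [f"gen{g + 1:02d}" for g in species_genus],
            "family": [families[genus_family[g]] for g in species_genus],
        }
    )
    traits = pd.DataFrame({"species_id": species})
    for trait, levels in vocab.items():
        traits[trait] = rng.choice(levels, size=pool_size)
    traits["wingspan"] = np.round(
        wingspan_median_mm * np.exp(rng.normal(0.0, wingspan_log_sd, size=pool_size)), 1
    )
    # rare species inherit whole trait profiles from common species
    half = pool_size // 2
    trait_cols = [*vocab, "wingspan"]
    for i in range(half, pool_size):
        if rng.random() < trait_sharing:
            donor = int(rng.integers(0, max(half, 1)))
            traits.loc[i, trait_cols] = traits.loc[donor, trait_cols]
    return traits, taxonomy


def _regional_abundances(config: StudyConfig, rng: np.random.Generator) -> np.ndarray:
    """Regional relative abundances, sorted descending (rank = species index)."""
    if config.abundance_model == "log-series":
        a = stats.logser.rvs(0.995, size=config.pool_size, random_state=rng).astype(float)
    else:
        a = np.exp(rng.normal(2.0, 1.2, size=config.pool_size))
    a = np.sort(a)[::-1]
    return a / a.sum()


def _draw_richness(rng, mean, sd, pair_mult, lo, hi) -> int:
    r = int(round(rng.normal(mean, sd) * pair_mult))
    return int(np.clip(r, lo, hi))


def _draw_counts(rng, n_species, weights, total) -> np.ndarray:
    """Counts >= 1 per selected species, expected site total ~ ``total``."""
    lam = np.maximum(total - n_species, 0) * weights / weights.sum()
    return 1 + rng.poisson(lam)


def _repair_trait_coverage(idx_p, idx_b, traits, trait_sharing, rng):
    """Keep plantation categorical-trait coverage equal to the pair's broadleaf.

    Rare species dropped from the plantation subset share trait values with
    retained common species; operationally, each categorical-trait category
    present in the broadleaf community but missing from the plantation draw
    is (with probability ``trait_sharing``) restored by swapping in its most
    common broadleaf carrier for a redundant selected species.  Richness is
    unchanged.
    """
    if trait_sharing <= 0:
        return idx_p
    idx_p = list(idx_p)
    cat_traits = [t for t in DEFAULT_TRAIT_VOCAB if t in traits.columns]
    values = {t: traits[t].to_numpy() for t in cat_traits}
    for trait in cat_traits:
        v = values[trait]
        present_b = set(v[list(idx_b)])
        for cat in sorted(present_b - set(v[idx_p])):
            if rng.random() >= trait_sharing:
                continue
            carriers = [i for i in idx_b if v[i] == cat and i not in idx_p]
            if not carriers:
                continue
            donor = min(carriers)  # lowest index = regionally most common
            removable = [
                j for j in idx_p
                if all(
                    np.sum(values[t][idx_p] == values[t][j]) > 1
                    for t in cat_traits
                )
            ]
            if not removable:
                continue
            idx_p.remove(max(removable))  # drop the rarest redundant species
            idx_p.append(donor)
    return np.asarray(idx_p, dtype=int)


def generate_paired_communities(
    config: StudyConfig, pool: tuple[pd.DataFrame, pd.DataFrame]
) -> AbundanceTable:
    """Draw the site x species abundance table for all pairs.

    Broadleaf sites sample ~``mean_richness_broadleaf`` species from the
    regional pool (weighted by regional abundance); plantation sites sample
    ~``mean_richness_plantation`` species from their pair's broadleaf
    community with extra weight on common species and, when the trait
    filter is on, a penalty ``exp(-4 * habitat_effect_on_traits)`` on
    species with disfavoured host plants.
    """
    config.validate()
    traits, taxonomy = pool
    species = traits["species_id"].tolist()
    if len(species) != config.pool_size:
        raise SyntheticError("pool size does not match config")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    regional_p = _regional_abundances(config, rng)
    filtered = traits["host_plant"].isin(FILTERED_HOST_PLANTS).to_numpy()
    penalty = np.exp(-4.0 * config.habitat_effect_on_traits)

    rows, meta_rows, index = [], [], []
    for pair in range(config.n_pairs):
        pair_id = f"pair{pair + 1:02d}"
        year = 2014 if pair < (config.n_pairs + 1) // 2 else 2015
        month = ("june", "july", "august")[pair % 3]
        pair_mult = float(np.exp(rng.normal(0.0, config.pair_effect_sd)))

        r_b = _draw_richness(
            rng, config.mean_richness_broadleaf, config.sd_richness_broadleaf,
            pair_mult, 5, config.pool_size,
        )
        idx_b = rng.choice(
            config.pool_size, size=r_b, replace=False,
            p=regional_p,
        )
        w_b = regional_p[idx_b]
        counts_b = np.zeros(config.pool_size, dtype=int)
        counts_b[idx_b] = _draw_counts(
            rng, r_b, w_b, config.mean_count_per_species * r_b
        )

        r_p = _draw_richness(
            rng, config.mean_richness_plantation, config.sd_richness_plantation,
            pair_mult, 2, r_b,
        )
        w_p = regional_p[idx_b] ** config.plantation_commonness_bias
        w_p = w_p * np.where(filtered[idx_b], penalty, 1.0)
        w_p = w_p / w_p.sum()
        idx_p = rng.choice(idx_b, size=r_p, replace=False, p=w_p)
        idx_p = _repair_trait_coverage(
            idx_p, idx_b, traits, config.trait_sharing, rng
        )
        counts_p = np.zeros(config.pool_size, dtype=int)
        counts_p[idx_p] = _draw_counts(
            rng, r_p, regional_p[idx_p], config.mean_count_per_species * r_p
        )

        for habitat, counts in (("broadleaf", counts_b), ("plantation", counts_p)):
            index.append(f"{pair_id}_{habitat}")
            meta_rows.append(
                {"pair_id": pair_id, "habitat": habitat, "year": year, "month": month}
            )
            rows.append(counts)

    meta = pd.DataFrame(meta_rows, columns=META_COLUMNS, index=index)
    counts = pd.DataFrame(
        np.asarray(rows, dtype=int).reshape(len(index), config.pool_size),
        index=index, columns=species,
    )
    return AbundanceTable(meta=meta, counts=counts)


def generate_study(
    config: StudyConfig | None = None, out_dir: str | Path | None = None
) -> tuple[AbundanceTable, pd.DataFrame, pd.DataFrame]:
    """One call yields a complete dataset ready for the full pipeline.

    Returns ``(abundance, traits, taxonomy)``; when ``out_dir`` is given,
    writes ``abundance.csv``, ``traits.csv``, ``taxonomy.csv`` and a
    provenance JSON recording the configuration and seed.
    """
    config = config or StudyConfig()
    config.validate()
    pool_seed = np.random.SeedSequence(config.seed).spawn(2)[1]
    traits, taxonomy = generate_species_pool(
        config.pool_size, config.n_families, config.n_genera,
        seed=pool_seed, trait_sharing=config.trait_sharing,
        wingspan_median_mm=config.wingspan_median_mm,
        wingspan_log_sd=config.wingspan_log_sd,
    )
    abundance = generate_paired_communities(config, (traits, taxonomy))
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        abundance.to_csv(out / "abundance.csv")
        traits.to_csv(out / "traits.csv", index=False)
        taxonomy.to_csv(out / "taxonomy.csv", index=False)
        provenance = {
            "generator": "lepdiv.synthetic.generate_study",
            "config": dataclasses.asdict(config),
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return abundance, traits, taxonomy
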