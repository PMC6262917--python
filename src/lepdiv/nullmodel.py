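"""Permutation null model and standardized effect sizes (SES).

To test for environmental filtering vs niche complementarity, observed
similarity-constrained diversity at each site is compared with a null
distribution obtained by shuffling the abundance values across species
within that site.  The shuffle preserves each site's total abundance,
its richness and its abundance structure (the multiset of counts) while
breaking the association between abundance and traits, i.e. it builds
randomly assembled communities of equal species richness.

SES = (observed - null mean) / null sd.  Negative mean SES within a habitat
indicates environmental filtering (co-occurring species more functionally
similar than chance); positive values indicate niche complementarity.  The
habitat-level test is a no-intercept linear model of SES on habitat, which
per habitat equals a one-sample t-test of mean SES against zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .diversity import relative_abundance, similarity_diversity
from .io import AbundanceTable
from .similarity import SimilarityMatrix

DEFAULT_N_PERM = 999


class NullModelError(ValueError):
    """Degenerate null distribution or invalid null-model input."""


@dataclass
class SESResult:
    site_id: str
    constraint: str
    q: float
    observed: float
    null_mean: float
    null_sd: float
    ses: float
    n_perm: int


@dataclass
class HabitatSESTest:
    habitat: str
    constraint: str
    q: float
    mean_ses: float
    se_ses: float
    p_value: float
    n_sites: int


def permute_site_abundances(table: AbundanceTable, seed) -> AbundanceTable:
    """Shuffle abundance values across species independently within each site.

    Site totals and each site's multiset of counts are preserved; the trait
    and taxonomy tables are untouched, so the permutation breaks only the
    trait-abundance association.  ``seed`` may be an int or a numpy Generator.
    """
    rng = np.random.default_rng(seed)
    arr = table.counts.to_numpy().copy()
    for i in range(arr.shape[0]):
        rng.shuffle(arr[i])
    counts = pd.DataFrame(arr, index=table.counts.index, columns=table.counts.columns)
    return AbundanceTable(meta=table.meta.copy(), counts=counts)


def shuffle_trait_rows(traits: pd.DataFrame, seed) -> pd.DataFrame:
    """Alternative null: permute whole trait profiles across the species pool.

    Species ids stay in place; the rows of trait values are reassigned at
    random, breaking the trait-abundance association pool-wide instead of
    per site.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(traits))
    shuffled = traits.iloc[perm].reset_index(drop=True).copy()
    shuffled["species_id"] = traits["species_id"].to_numpy()
    return shuffled


def ses(
    observed: float,
    null_values: Sequence[float],
    site_id: str = "",
    constraint: str = "",
    q: float = 0.0,
) -> SESResult:
    """Standardized effect size of an observed value against its null draws."""
    null = np.asarray(list(null_values), dtype=float)
    if null.size < 2:
        raise NullModelError("need at least two null values")
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd <= 0:
        raise NullModelError(
            f"degenerate null distribution (sd = 0) for site {site_id!r}"
        )
    return SESResult(
        site_id=site_id,
        constraint=constraint,
        q=q,
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        ses=(float(observed) - mean) / sd,
        n_perm=null.size,
    )


def _site_null_diversities(
    counts: np.ndarray, Z: SimilarityMatrix, q: float, n_perm: int,
    rng: np.random.Generator, species_ids: list[str],
) -> np.ndarray:
    """Null diversities for one site from within-row shuffles of its counts."""
    out = np.empty(n_perm)
    c = counts.copy()
    for k in range(n_perm):
        rng.shuffle(c)
        p = relative_abundance(c, species_ids)
        out[k] = similarity_diversity(p, Z.subset(p.species_ids), q)
    return out


def null_model_test(
    table: AbundanceTable,
    Z: SimilarityMatrix,
    q: float = 0.0,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    constraint: str = "",
    on_degenerate: str = "raise",
) -> list[SESResult]:
    """Per-site SES of similarity-constrained diversity against the shuffle null.

    Each permutation re-derives relative abundances and subsets Z to the
    species that received a nonzero count, consistently with the per-site
    subcommunity convention of the diversity module.  The permutation stream
    is reproducible from ``seed`` (one spawned substream per site).

    A site whose null distribution is degenerate (all permuted diversities
    identical, e.g. a categorical constraint at q = 0 whose category count
    never changes under the shuffle) raises by default; with
    ``on_degenerate="skip"`` it is dropped with a warning instead.
    """
    if on_degenerate not in ("raise", "skip"):
        raise NullModelError(f"unknown on_degenerate policy {on_degenerate!r}")
    if n_perm < 1:
        raise NullModelError("n_perm must be >= 1")
    if set(table.species_ids) - set(Z.species_ids):
        raise NullModelError("similarity matrix does not cover all species")
    master = np.random.default_rng(seed)
    streams = master.spawn(table.n_sites)
    species = table.species_ids
    results = []
    for site, rng in zip(table.site_ids, streams):
        counts = table.site_counts(site).to_numpy()
        p = relative_abundance(counts, species)
        obs = similarity_diversity(p, Z.subset(p.species_ids), q)
        null = _site_null_diversities(counts, Z, q, n_perm, rng, species)
        try:
            results.append(
                ses(obs, null, site_id=site, constraint=constraint, q=q)
            )
        except NullModelError:
            if on_degenerate == "raise":
                raise
            warnings.warn(
                f"degenerate null for site {site!r} ({constraint}, q={q}); "
                "site skipped", stacklevel=2,
            )
    return results


def habitat_ses_test(
    results: Sequence[SESResult], habitat_labels: dict[str, str]
) -> list[HabitatSESTest]:
    """Per-habitat mean SES, its SE, and a two-sided test of mean = 0.

    Equivalent to a no-intercept linear model of SES on habitat: for each
    habitat level, t = mean / se with (n - 1) degrees of freedom.
    """
    df = pd.DataFrame(
        {
            "habitat": [habitat_labels[r.site_id] for r in results],
            "ses": [r.ses for r in results],
            "constraint": [r.constraint for r in results],
            "q": [r.q for r in results],
        }
    )
    out = []
    for habitat, grp in df.groupby("habitat", sort=True):
        n = len(grp)
        if n < 2:
            raise NullModelError(f"habitat {habitat!r} has fewer than 2 sites")
        mean = float(grp["ses"].mean())
        se = float(grp["ses"].std(ddof=1) / np.sqrt(n))
        if se == 0:
            # all SES identical: degenerate, flag with p = 0 unless mean is 0
            p = 1.0 if mean == 0 else 0.0
        else:
            t = mean / se
            p = float(2 * stats.t.sf(abs(t), df=n - 1))
        out.append(
            HabitatSESTest(
                habitat=str(habitat),
                constraint=str(grp["constraint"].iloc[0]),
                q=float(grp["q"].iloc[0]),
                mean_ses=mean,
                se_ses=se,
                p_value=p,
                n_sites=n,
            )
        )
    return out


def ses_results_frame(results: Sequence[SESResult], habitat_labels=None) -> pd.DataFrame:
    """Long-format frame of SES results (one row per site)."""
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "constraint": [r.constraint for r in results],
            "q": [r.q for r in results],
            "observed": [r.observed for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "ses": [r.ses for r in results],
            "n_perm": [r.n_perm for r in results],
        }
    )
    if habitat_labels is not None:
        df.insert(1, "habitat", [habitat_labels[r.site_id] for r in results])
    return df
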