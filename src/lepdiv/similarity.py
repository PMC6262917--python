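"""Species-pair similarity matrices.

Similarity-sensitive diversity needs an S x S matrix ``Z`` whose entries lie
in [0, 1]: 1 on the diagonal (a species is identical to itself), 0 for a pair
treated as completely distinct.  Three families of matrices are built here:

* **naive** -- the identity matrix; every species equally different.
* **functional** -- one matrix per trait, from Gower similarity
  (``1 - normalized Gower distance``).  A single categorical trait gives a 0/1
  match matrix; a single continuous trait gives ``1 - |x_i - x_j| / range``.
* **taxonomic** -- shared-lineage similarity over (species, genus, family)
  with equal step lengths per rank, normalized so the maximum distance is 1:
  same genus -> 2/3, same family -> 1/3, different families -> 0.

Each trait gets its own matrix; multi-trait pooled Gower matrices are
deliberately not provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Traits recognised by :func:`trait_similarity`, with their type.
TRAIT_KINDS: dict[str, str] = {
    "host_plant": "categorical",
    "larval_specialism": "categorical",
    "overwintering_stage": "categorical",
    "wingspan": "continuous",
}

#: Constraint labels used across the pipeline (naive + taxonomy + four traits).
CONSTRAINTS: tuple[str, ...] = (
    "naive",
    "taxonomic",
    "host_plant",
    "larval_specialism",
    "overwintering_stage",
    "wingspan",
)


class SimilarityError(ValueError):
    """Invalid input for a similarity-matrix builder."""


@dataclass
class SimilarityMatrix:
    """S x S symmetric species similarity matrix with unit diagonal.

    Parameters
    ----------
    species_ids
        Ordered species identifiers labelling rows and columns.
    values
        Square array of similarities in [0, 1].
    """

    species_ids: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.species_ids = [str(s) for s in self.species_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        ids, Z = self.species_ids, self.values
        if len(ids) == 0:
            raise SimilarityError("empty species list")
        if len(set(ids)) != len(ids):
            raise SimilarityError("duplicate species ids")
        if Z.shape != (len(ids), len(ids)):
            raise SimilarityError(
                f"matrix shape {Z.shape} does not match {len(ids)} species"
            )
        if not np.allclose(Z, Z.T, atol=1e-12):
            raise SimilarityError("similarity matrix must be symmetric")
        if np.any(Z < -1e-12) or np.any(Z > 1 + 1e-12):
            raise SimilarityError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(Z), 1.0, atol=1e-12):
            raise SimilarityError("diagonal must be exactly 1")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    def subset(self, ids: Sequence[str]) -> "SimilarityMatrix":
        """Restrict to ``ids`` (in the given order)."""
        index = {s: i for i, s in enumerate(self.species_ids)}
        try:
            pos = [index[str(s)] for s in ids]
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise SimilarityError(f"unknown species id {exc.args[0]!r}") from exc
        return SimilarityMatrix(list(ids), self.values[np.ix_(pos, pos)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.species_ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="species_id")

    @classmethod
    def from_csv(cls, path) -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index.astype(str)) != [str(c) for c in df.columns]:
            raise SimilarityError("row and column species ids differ")
        return cls(list(df.columns.astype(str)), df.to_numpy(dtype=float))


def identity_similarity(species_ids: Sequence[str]) -> SimilarityMatrix:
    """Naive similarity: every species completely distinct from every other."""
    ids = list(species_ids)
    if not ids:
        raise SimilarityError("empty species list")
    if len(set(ids)) != len(ids):
        raise SimilarityError("duplicate species ids")
    return SimilarityMatrix(ids, np.eye(len(ids)))


def categorical_trait_similarity(
    species_ids: Sequence[str], trait_values: Sequence
) -> SimilarityMatrix:
    """Gower similarity for one categorical trait: 1 on match, 0 on mismatch.

    Pairs where either value is missing (None/NaN) get the mean similarity of
    all fully observed pairs for the trait; imputed pairs are logged.
    """
    ids = list(species_ids)
    vals = pd.Series(list(trait_values), dtype=object)
    if len(vals) != len(ids):
        raise SimilarityError("one trait value per species required")
    observed = vals.notna().to_numpy()
    if not observed.any():
        raise SimilarityError("all trait values missing")
    S = len(ids)
    arr = vals.to_numpy(dtype=object)
    Z = np.zeros((S, S))
    obs_idx = np.flatnonzero(observed)
    eq = np.equal.outer(arr[obs_idx], arr[obs_idx]).astype(float)
    Z[np.ix_(obs_idx, obs_idx)] = eq
    n_missing = S - len(obs_idx)
    if n_missing:
        # off-diagonal mean over fully observed pairs
        if len(obs_idx) < 2:
            raise SimilarityError(
                "cannot impute: fewer than two observed trait values"
            )
        off = eq[np.triu_indices(len(obs_idx), k=1)]
        fill = float(off.mean())
        miss_idx = np.flatnonzero(~observed)
        Z[miss_idx, :] = fill
        Z[:, miss_idx] = fill
        logger.info(
            "categorical trait: imputed similarity %.3f for %d species with "
            "missing values", fill, n_missing,
        )
    np.fill_diagonal(Z, 1.0)
    return SimilarityMatrix(ids, Z)


def continuous_trait_similarity(
    species_ids: Sequence[str], trait_values: Sequence[float]
) -> SimilarityMatrix:
    """Gower similarity for one continuous trait: ``1 - |x_i - x_j| / range``."""
    ids = list(species_ids)
    x = np.asarray(list(trait_values), dtype=float)
    if len(x) != len(ids):
        raise SimilarityError("one trait value per species required")
    if not np.all(np.isfinite(x)):
        raise SimilarityError("non-finite trait values")
    rng = x.max() - x.min()
    if rng <= 0:
        raise SimilarityError("zero trait range: similarity undefined")
    Z = 1.0 - np.abs(np.subtract.outer(x, x)) / rng
    np.fill_diagonal(Z, 1.0)
    return SimilarityMatrix(ids, Z)


def taxonomic_similarity(taxonomy: pd.DataFrame) -> SimilarityMatrix:
    """Shared-lineage similarity from a species/genus/family table.

    Equal step lengths over the three ranks, normalized so the maximum
    distance (different families) is 1.  Hence similarity is 1 for the same
    species, 2/3 within a genus, 1/3 within a family, 0 across families.

    Parameters
    ----------
    taxonomy
        DataFrame with columns ``species_id``, ``genus``, ``family``.
    """
    required = {"species_id", "genus", "family"}
    if not required.issubset(taxonomy.columns):
        raise SimilarityError(f"taxonomy table needs columns {sorted(required)}")
    tab = taxonomy[["species_id", "genus", "family"]].astype(str)
    if tab.isin(["nan", "None", ""]).any().any() or taxonomy[list(required)].isna().any().any():
        raise SimilarityError("species with missing taxonomic rank")
    if tab["species_id"].duplicated().any():
        raise SimilarityError("duplicate species in taxonomy table")
    # a genus must not straddle families
    fam_per_genus = tab.groupby("genus")["family"].nunique()
    if (fam_per_genus > 1).any():
        bad = fam_per_genus[fam_per_genus > 1].index.tolist()
        raise SimilarityError(f"genus in multiple families: {bad}")
    ids = tab["species_id"].tolist()
    genus = tab["genus"].to_numpy()
    family = tab["family"].to_numpy()
    same_genus = np.equal.outer(genus, genus)
    same_family = np.equal.outer(family, family)
    Z = np.where(same_genus, 2.0 / 3.0, np.where(same_family, 1.0 / 3.0, 0.0))
    np.fill_diagonal(Z, 1.0)
    return SimilarityMatrix(ids, Z)


def trait_similarity(traits: pd.DataFrame, trait_name: str) -> SimilarityMatrix:
    """Build the similarity matrix for one declared trait.

    Dispatches to the categorical or continuous builder according to
    :data:`TRAIT_KINDS`.  ``traits`` must have a ``species_id`` column and a
    column named ``trait_name``.
    """
    if trait_name not in TRAIT_KINDS:
        raise SimilarityError(
            f"unknown trait {trait_name!r}; expected one of {sorted(TRAIT_KINDS)}"
        )
    if "species_id" not in traits.columns or trait_name not in traits.columns:
        raise SimilarityError(f"trait table lacks column {trait_name!r}")
    ids = traits["species_id"].astype(str).tolist()
    vals = traits[trait_name]
    if TRAIT_KINDS[trait_name] == "categorical":
        return categorical_trait_similarity(ids, vals)
    return continuous_trait_similarity(ids, vals.astype(float))


def constraint_similarity(
    constraint: str,
    species_ids: Sequence[str],
    traits: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> SimilarityMatrix:
    """Similarity matrix for a named constraint, aligned to ``species_ids``.

    ``naive`` needs no tables; ``taxonomic`` needs the taxonomy table; the
    four trait constraints need the trait table.
    """
    if constraint == "naive":
        return identity_similarity(species_ids)
    if constraint == "taxonomic":
        if taxonomy is None:
            raise SimilarityError("taxonomic constraint requires a taxonomy table")
        return taxonomic_similarity(taxonomy).subset([str(s) for s in species_ids])
    if taxonomy is None and traits is None:
        raise SimilarityError(f"constraint {constraint!r} requires a trait table")
    if traits is None:
        raise SimilarityError(f"constraint {constraint!r} requires a trait table")
    z = trait_similarity(traits, constraint)
    return z.subset([str(s) for s in species_ids])


def wingspan_midpoint(low: float, high: float) -> float:
    """Collapse a published wingspan min-max range to its midpoint (mm)."""
    if not (0 < low <= high):
        raise SimilarityError("wingspan range must satisfy 0 < low <= high")
    return 0.5 * (low + high)
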