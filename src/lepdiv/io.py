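"""Readers, validators and writers for the three CSV inputs.

The pipeline consumes three rectangular tables:

* abundance: one row per site; metadata columns ``pair_id, habitat, year,
  month`` followed by one integer count column per species (explicit zeros
  for absences);
* traits: one row per species with ``species_id, host_plant,
  larval_specialism, overwintering_stage, wingspan`` (empty fields mark
  missing values);
* taxonomy: ``species_id, genus, family``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .similarity import TRAIT_KINDS

META_COLUMNS = ["pair_id", "habitat", "year", "month"]
HABITATS = ("broadleaf", "plantation")


class ValidationError(ValueError):
    """An input table violates the schema; message names the offending cell."""


@dataclass
class AbundanceTable:
    """Sites x species count matrix plus per-site metadata.

    ``meta`` and ``counts`` share the site_id index; ``counts`` holds
    non-negative integers with one column per pool species.
    """

    meta: pd.DataFrame = field(repr=False)
    counts: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing:
            raise ValidationError(f"metadata columns missing: {missing}")
        if not self.meta.index.equals(self.counts.index):
            raise ValidationError("metadata and counts site ids differ")
        if self.meta.index.has_duplicates:
            raise ValidationError("duplicate site ids")
        bad_habitat = ~self.meta["habitat"].isin(HABITATS)
        if bad_habitat.any():
            site = self.meta.index[bad_habitat][0]
            raise ValidationError(
                f"unknown habitat label {self.meta.loc[site, 'habitat']!r} "
                f"at site {site!r}"
            )
        arr = self.counts.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValidationError("non-numeric abundance entries")
            neg = np.argwhere(arr < 0)
            if neg.size:
                r, c = neg[0]
                raise ValidationError(
                    f"negative count at site {self.counts.index[r]!r}, "
                    f"species {self.counts.columns[c]!r}"
                )
            frac = np.argwhere(arr != np.floor(arr))
            if frac.size:
                r, c = frac[0]
                raise ValidationError(
                    f"non-integer count at site {self.counts.index[r]!r}, "
                    f"species {self.counts.columns[c]!r}"
                )
        self.counts = self.counts.astype(int)

    @property
    def site_ids(self) -> list[str]:
        return [str(s) for s in self.meta.index]

    @property
    def species_ids(self) -> list[str]:
        return [str(s) for s in self.counts.columns]

    @property
    def n_sites(self) -> int:
        return len(self.meta)

    def site_counts(self, site_id: str) -> pd.Series:
        return self.counts.loc[site_id]

    def habitat_of(self, site_id: str) -> str:
        return str(self.meta.loc[site_id, "habitat"])

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.meta[META_COLUMNS], self.counts], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="site_id")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AbundanceTable":
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"metadata columns missing: {missing}")
        species = [c for c in df.columns if c not in META_COLUMNS]
        return cls(meta=df[META_COLUMNS].copy(), counts=df[species].copy())


def read_abundance(path) -> AbundanceTable:
    """Read and validate a site x species abundance CSV."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return AbundanceTable.from_frame(df)


def read_traits(path) -> pd.DataFrame:
    """Read and validate a species trait CSV (missing values allowed)."""
    df = pd.read_csv(path)
    return validate_traits(df)


def validate_traits(df: pd.DataFrame) -> pd.DataFrame:
    required = ["species_id", *TRAIT_KINDS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"trait table columns missing: {missing}")
    df = df.copy()
    df["species_id"] = df["species_id"].astype(str)
    if df["species_id"].duplicated().any():
        dup = df.loc[df["species_id"].duplicated(), "species_id"].iloc[0]
        raise ValidationError(f"duplicate species {dup!r} in trait table")
    ws = df["wingspan"]
    bad = ws.notna() & (ws <= 0)
    if bad.any():
        sp = df.loc[bad, "species_id"].iloc[0]
        raise ValidationError(f"non-positive wingspan for species {sp!r}")
    return df


def read_taxonomy(path) -> pd.DataFrame:
    """Read and validate a species/genus/family CSV."""
    df = pd.read_csv(path)
    required = ["species_id", "genus", "family"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"taxonomy table columns missing: {missing}")
    df = df.copy()
    df["species_id"] = df["species_id"].astype(str)
    if df[required].isna().any().any():
        row = df[df[required].isna().any(axis=1)].index[0]
        raise ValidationError(f"taxonomy row {row} has a missing rank")
    if df["species_id"].duplicated().any():
        raise ValidationError("duplicate species in taxonomy table")
    return df


def check_species_consistency(
    abundance: AbundanceTable,
    traits: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> None:
    """Every species column must be described by the trait/taxonomy tables."""
    species = set(abundance.species_ids)
    if traits is not None:
        missing = species - set(traits["species_id"])
        if missing:
            raise ValidationError(
                f"species missing from trait table: {sorted(missing)[:5]}"
            )
    if taxonomy is not None:
        missing = species - set(taxonomy["species_id"])
        if missing:
            raise ValidationError(
                f"species missing from taxonomy table: {sorted(missing)[:5]}"
            )
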