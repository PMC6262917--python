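"""Similarity-sensitive Hill-number diversity.

The Hill number of order ``q`` for relative abundances ``p`` is the
(1 - q)-th order power mean of ``p`` weighted by ``1/p``:

    qD(p) = ( sum_i p_i^q )^(1/(1-q)),      q != 1
    1D(p) = exp( -sum_i p_i ln p_i )

Leinster & Cobbold's similarity-sensitive generalization replaces ``1/p``
with the reciprocal *ordinariness* ``1/(Zp)``, where ``Z`` is a species-pair
similarity matrix:

    qD^Z(p) = ( sum_i p_i (Zp)_i^(q-1) )^(1/(1-q)),   q != 1
    1D^Z(p) = exp( -sum_i p_i ln (Zp)_i )

With ``Z = I`` this reduces exactly to the naive Hill number; with
``Z = all-ones`` every community has diversity 1.  All values are effective
numbers of species: the count of equally abundant, completely distinct
species that would give the same index.

Functional (or taxonomic) redundancy is the ratio of naive richness (q = 0,
identity Z) to similarity-constrained richness (q = 0, trait or taxonomy Z);
it is >= 1, and large when many species fill the same functional role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .similarity import SimilarityMatrix

__all__ = [
    "DiversityError",
    "RelativeAbundance",
    "DiversityProfile",
    "RedundancyResult",
    "power_mean",
    "relative_abundance",
    "naive_diversity",
    "similarity_diversity",
    "diversity_profile",
    "redundancy",
]

DEFAULT_Q_GRID: tuple[float, ...] = (0.0, 1.0, 2.0)


class DiversityError(ValueError):
    """Invalid input for a diversity computation."""


@dataclass
class RelativeAbundance:
    """Relative abundances of the species present in one community.

    Zeros are dropped on construction; the remaining proportions sum to 1.
    """

    species_ids: list[str]
    p: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if len(self.species_ids) != self.p.size:
            raise DiversityError("species ids and proportions differ in length")
        if np.any(self.p <= 0):
            raise DiversityError("retained proportions must be positive")
        if abs(self.p.sum() - 1.0) > 1e-12:
            raise DiversityError("proportions must sum to 1")

    @property
    def n_species(self) -> int:
        return self.p.size


@dataclass
class DiversityProfile:
    """Effective number of species across orders q for one site/constraint."""

    site_id: str
    constraint: str
    points: dict[float, float]

    def qs(self) -> list[float]:
        return sorted(self.points)

    def values(self) -> list[float]:
        return [self.points[q] for q in self.qs()]


@dataclass
class RedundancyResult:
    """Naive vs similarity-constrained richness and their ratio (>= 1)."""

    site_id: str
    constraint: str
    naive_richness: float
    constrained_richness: float
    redundancy: float


def power_mean(weights: np.ndarray, values: np.ndarray, order_t: float) -> float:
    """Weighted power mean ``M_t(w, x) = (sum_i w_i x_i^t)^(1/t)``.

    ``t = 0`` gives the weighted geometric mean, ``t = -inf`` the minimum and
    ``t = +inf`` the maximum over values with positive weight.  Zero-weight
    pairs are excluded before any power is taken.
    """
    w = np.asarray(weights, dtype=float)
    x = np.asarray(values, dtype=float)
    if w.shape != x.shape:
        raise DiversityError("weights and values differ in shape")
    if np.any(w < 0):
        raise DiversityError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-9:
        raise DiversityError("weights must sum to 1")
    keep = w > 0
    w, x = w[keep], x[keep]
    if np.any(x <= 0):
        raise DiversityError("values must be positive where weight is nonzero")
    if np.isneginf(order_t):
        return float(x.min())
    if np.isposinf(order_t):
        return float(x.max())
    if order_t == 0:
        return float(np.exp(np.sum(w * np.log(x))))
    return float(np.sum(w * x**order_t) ** (1.0 / order_t))


def relative_abundance(
    counts: Sequence[float], species_ids: Sequence[str] | None = None
) -> RelativeAbundance:
    """Normalize non-negative counts to proportions, dropping zeros."""
    c = np.asarray(list(counts), dtype=float)
    if c.size == 0:
        raise DiversityError("empty count vector")
    if np.any(c < 0):
        raise DiversityError("negative counts")
    total = c.sum()
    if total <= 0:
        raise DiversityError("all-zero community")
    if species_ids is None:
        species_ids = [f"sp{i}" for i in range(c.size)]
    ids = [str(s) for s in species_ids]
    if len(ids) != c.size:
        raise DiversityError("species ids and counts differ in length")
    keep = c > 0
    return RelativeAbundance(
        [s for s, k in zip(ids, keep) if k], c[keep] / total
    )


def _check_q(q: float) -> float:
    q = float(q)
    if q < 0 or not np.isfinite(q):
        raise DiversityError("order q must be finite and >= 0")
    return q


def naive_diversity(p: RelativeAbundance | np.ndarray, q: float) -> float:
    """Hill number of order q (effective number of species).

    q = 0, 1, 2 give species richness, exponential Shannon entropy, and
    inverse Simpson concentration.  q = 1 uses the closed-form limit.
    """
    q = _check_q(q)
    pv = p.p if isinstance(p, RelativeAbundance) else np.asarray(p, dtype=float)
    if q == 1.0:
        return float(np.exp(-np.sum(pv * np.log(pv))))
    return float(np.sum(pv**q) ** (1.0 / (1.0 - q)))


def similarity_diversity(
    p: RelativeAbundance, Z: SimilarityMatrix | np.ndarray, q: float
) -> float:
    """Similarity-sensitive diversity qD^Z(p).

    ``Z`` must cover exactly the species retained in ``p`` (same order).  The
    ordinariness ``(Zp)_i`` of every species must be positive, which holds
    whenever Z has unit diagonal.
    """
    q = _check_q(q)
    if isinstance(Z, SimilarityMatrix):
        if Z.species_ids != p.species_ids:
            raise DiversityError("Z species do not match abundance species")
        Zv = Z.values
    else:
        Zv = np.asarray(Z, dtype=float)
        if Zv.shape != (p.n_species, p.n_species):
            raise DiversityError("Z shape does not match abundance vector")
    zp = Zv @ p.p
    if np.any(zp <= 0):
        raise DiversityError("non-positive ordinariness (Zp)_i")
    if q == 1.0:
        return float(np.exp(-np.sum(p.p * np.log(zp))))
    return float(np.sum(p.p * zp ** (q - 1.0)) ** (1.0 / (1.0 - q)))


def diversity_profile(
    p: RelativeAbundance,
    Z: SimilarityMatrix | np.ndarray,
    q_grid: Sequence[float] = DEFAULT_Q_GRID,
    site_id: str = "",
    constraint: str = "",
) -> DiversityProfile:
    """Evaluate qD^Z(p) on a grid of orders (non-increasing in q)."""
    qs = [float(q) for q in q_grid]
    if qs != sorted(qs):
        raise DiversityError("q grid must be sorted ascending")
    points = {q: similarity_diversity(p, Z, q) for q in qs}
    return DiversityProfile(site_id=site_id, constraint=constraint, points=points)


def redundancy(
    counts: Sequence[float],
    Z: SimilarityMatrix,
    species_ids: Sequence[str] | None = None,
    site_id: str = "",
    constraint: str = "",
) -> RedundancyResult:
    """Naive richness / similarity-constrained richness at q = 0.

    ``Z`` is given over the full species list (it is subset to the species
    with nonzero count).  The ratio is >= 1 for any Z with unit diagonal.
    """
    p = relative_abundance(counts, species_ids)
    z_sub = Z.subset(p.species_ids)
    naive = float(p.n_species)  # q = 0 Hill number of the subcommunity
    constrained = similarity_diversity(p, z_sub, 0.0)
    return RedundancyResult(
        site_id=site_id,
        constraint=constraint,
        naive_richness=naive,
        constrained_richness=constrained,
        redundancy=naive / constrained,
    )
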