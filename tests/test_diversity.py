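"""Hill numbers, similarity-sensitive diversity, profiles and redundancy."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lepdiv.diversity import (
    DiversityError,
    diversity_profile,
    naive_diversity,
    power_mean,
    redundancy,
    relative_abundance,
    similarity_diversity,
)
from lepdiv.similarity import identity_similarity

from conftest import random_community

Q_GRID = [0.0, 0.5, 1.0, 1.5, 2.0, 5.0]


class TestPowerMean:
    def test_order_one_is_arithmetic_mean(self):
        assert power_mean([0.25] * 4, [1, 2, 3, 4], 1.0) == pytest.approx(2.5)

    def test_order_zero_is_geometric_mean(self):
        assert power_mean([0.5, 0.5], [1.0, 4.0], 0.0) == pytest.approx(2.0)

    def test_idempotent_on_constant_values(self):
        w = np.array([0.2, 0.3, 0.5])
        for t in [-np.inf, -2, 0, 0.5, 1, 3, np.inf]:
            assert power_mean(w, [7.0, 7.0, 7.0], t) == pytest.approx(7.0)

    def test_infinite_orders_give_extremes(self):
        w, x = [0.5, 0.3, 0.2], [2.0, 9.0, 4.0]
        assert power_mean(w, x, -np.inf) == 2.0
        assert power_mean(w, x, np.inf) == 9.0

    def test_zero_weight_pairs_excluded(self):
        # the zero-weighted value may be invalid; it must not matter
        assert power_mean([0.5, 0.5, 0.0], [1.0, 4.0, 123.0], 0.0) == pytest.approx(2.0)

    def test_nonpositive_value_with_weight_rejected(self):
        with pytest.raises(DiversityError):
            power_mean([0.5, 0.5], [1.0, 0.0], 1.0)


class TestRelativeAbundance:
    def test_zeros_dropped_and_normalized(self):
        p = relative_abundance([10, 30, 0, 60])
        assert p.species_ids == ["sp0", "sp1", "sp3"]
        assert np.allclose(p.p, [0.1, 0.3, 0.6])

    def test_single_species(self):
        assert relative_abundance([5]).p.tolist() == [1.0]

    @pytest.mark.parametrize("counts", [[0, 0], [], [-1, 2]])
    def test_degenerate_inputs_rejected(self, counts):
        with pytest.raises(DiversityError):
            relative_abundance(counts)


class TestNaiveDiversity:
    P = relative_abundance([5, 3, 2])

    def test_q0_is_richness(self):
        assert naive_diversity(self.P, 0) == pytest.approx(3.0)

    def test_q2_is_inverse_simpson(self):
        assert naive_diversity(self.P, 2) == pytest.approx(1 / 0.38)

    def test_uniform_community_gives_s_for_every_q(self):
        p = relative_abundance([1] * 7)
        for q in Q_GRID:
            assert naive_diversity(p, q) == pytest.approx(7.0)

    def test_negative_q_rejected(self):
        with pytest.raises(DiversityError):
            naive_diversity(self.P, -0.5)

    @given(st.integers(0, 10_000))
    def test_continuity_at_q1(self, seed):
        p, _ = random_community(np.random.default_rng(seed))
        p = relative_abundance(p * 1000 + 1e-9)  # keep all species
        d1 = naive_diversity(p, 1.0)
        assert abs(d1 - naive_diversity(p, 1 + 1e-6)) < 1e-4
        assert abs(d1 - naive_diversity(p, 1 - 1e-6)) < 1e-4

    @given(st.integers(0, 10_000))
    def test_power_mean_route_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        p, _ = random_community(rng)
        ra = relative_abundance(p)
        for q in Q_GRID:
            via_mean = 1.0 / power_mean(ra.p, ra.p, q - 1.0) if q != 1.0 else (
                1.0 / power_mean(ra.p, ra.p, 0.0)
            )
            # 1/M_{q-1}(p, p) equals (sum p^q)^{1/(1-q)} and its q=1 limit
            assert naive_diversity(ra, q) == pytest.approx(via_mean, abs=1e-10)


class TestSimilarityDiversity:
    def test_identity_z_reduces_to_hill_number(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p, _ = random_community(rng)
            ra = relative_abundance(p)
            z = identity_similarity(ra.species_ids)
            for q in Q_GRID:
                assert similarity_diversity(ra, z, q) == pytest.approx(
                    naive_diversity(ra, q), abs=1e-12
                )

    def test_all_ones_z_gives_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p, _ = random_community(rng)
            ra = relative_abundance(p)
            Z = np.ones((ra.n_species, ra.n_species))
            for q in Q_GRID:
                assert similarity_diversity(ra, Z, q) == pytest.approx(1.0)

    def test_two_species_half_similarity(self):
        ra = relative_abundance([1, 1])
        Z = np.array([[1.0, 0.5], [0.5, 1.0]])
        for q in Q_GRID:
            assert similarity_diversity(ra, Z, q) == pytest.approx(4 / 3)

    def test_species_mismatch_rejected(self):
        ra = relative_abundance([1, 1])
        z = identity_similarity(["x", "y"])
        with pytest.raises(DiversityError):
            similarity_diversity(ra, z, 0)

    @given(st.integers(0, 10_000))
    def test_profile_non_increasing_in_q(self, seed):
        p, Z = random_community(np.random.default_rng(seed))
        ra = relative_abundance(p)
        vals = [similarity_diversity(ra, Z[: ra.n_species, : ra.n_species], q)
                for q in Q_GRID]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    @given(st.integers(0, 10_000))
    def test_bounded_by_naive_diversity_and_range(self, seed):
        p, Z = random_community(np.random.default_rng(seed))
        ra = relative_abundance(p)
        for q in Q_GRID:
            d = similarity_diversity(ra, Z, q)
            assert d <= naive_diversity(ra, q) + 1e-9
            assert 1.0 - 1e-9 <= d <= ra.n_species + 1e-9

    @given(st.integers(0, 10_000))
    def test_invariant_under_species_reordering(self, seed):
        rng = np.random.default_rng(seed)
        p, Z = random_community(rng)
        ra = relative_abundance(p)
        perm = rng.permutation(ra.n_species)
        ra2 = relative_abundance(p[perm])
        Z2 = Z[np.ix_(perm, perm)]
        for q in (0.0, 1.0, 2.0):
            assert similarity_diversity(ra2, Z2, q) == pytest.approx(
                similarity_diversity(ra, Z, q), abs=1e-10
            )

    def test_continuity_at_q1_with_similarity(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            p, Z = random_community(rng)
            ra = relative_abundance(p)
            d1 = similarity_diversity(ra, Z, 1.0)
            assert abs(d1 - similarity_diversity(ra, Z, 1 + 1e-6)) < 1e-4
            assert abs(d1 - similarity_diversity(ra, Z, 1 - 1e-6)) < 1e-4


class TestProfileAndRedundancy:
    def test_uniform_identity_profile_is_constant(self):
        ra = relative_abundance([1] * 6)
        z = identity_similarity(ra.species_ids)
        prof = diversity_profile(ra, z, (0, 1, 2))
        assert prof.values() == pytest.approx([6, 6, 6])

    def test_empty_grid_gives_empty_profile(self):
        ra = relative_abundance([1, 2])
        z = identity_similarity(ra.species_ids)
        assert diversity_profile(ra, z, ()).points == {}

    def test_unsorted_grid_rejected(self):
        ra = relative_abundance([1, 2])
        z = identity_similarity(ra.species_ids)
        with pytest.raises(DiversityError):
            diversity_profile(ra, z, (2, 0))

    def test_block_z_profile_constant_at_block_count(self, block_z):
        ra = relative_abundance([1] * 10, block_z.species_ids)
        prof = diversity_profile(ra, block_z, (0.0, 1.0, 2.0, 5.0))
        assert prof.values() == pytest.approx([2, 2, 2, 2])

    def test_identity_redundancy_is_one(self):
        z = identity_similarity([f"sp{j + 1:03d}" for j in range(4)])
        r = redundancy([3, 1, 2, 9], z, z.species_ids)
        assert r.redundancy == pytest.approx(1.0)

    def test_all_ones_redundancy_equals_richness(self):
        from lepdiv.similarity import SimilarityMatrix

        ids = [f"sp{j}" for j in range(10)]
        z = SimilarityMatrix(ids, np.ones((10, 10)))
        r = redundancy([1] * 10, z, ids)
        assert r.constrained_richness == pytest.approx(1.0)
        assert r.redundancy == pytest.approx(10.0)

    def test_two_block_community_redundancy_five(self, block_z):
        r = redundancy([1] * 10, block_z, block_z.species_ids)
        assert r.naive_richness == 10
        assert r.constrained_richness == pytest.approx(2.0)
        assert r.redundancy == pytest.approx(5.0)

    @given(st.integers(0, 10_000))
    def test_redundancy_at_least_one(self, seed):
        rng = np.random.default_rng(seed)
        p, Z = random_community(rng)
        from lepdiv.similarity import SimilarityMatrix

        ids = [f"sp{j}" for j in range(len(p))]
        counts = np.ceil(p * 1000).astype(int)
        r = redundancy(counts, SimilarityMatrix(ids, Z), ids)
        assert r.redundancy >= 1.0 - 1e-9
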