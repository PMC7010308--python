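import numpy as np
import pytest

from woodwebs.network_metrics import (
    barber_modularity,
    h2_prime,
    horn_overlap,
    modularity_lp,
    niche_overlap,
    species_indices,
    wnodf,
)

from conftest import im, random_trimmed_matrix
import oracles


class TestWnodf:
    def test_perfectly_nested(self):
        assert wnodf(np.array([[3, 2, 1], [2, 1, 0], [1, 0, 0]])) == pytest.approx(100.0)

    def test_equal_totals_score_zero(self):
        assert wnodf(np.array([[1, 1], [1, 1]])) == 0.0

    def test_degenerate_single_row_errors(self):
        with pytest.raises(ValueError):
            wnodf(np.array([[1, 2, 3]]))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(100):
            A = random_trimmed_matrix(rng, 5, 5)
            assert wnodf(A) == pytest.approx(oracles.wnodf_bruteforce(A), abs=1e-9)

    def test_invariant_under_permutation(self, rng):
        for _ in range(20):
            A = random_trimmed_matrix(rng, 6, 6)
            P = A[rng.permutation(A.shape[0])][:, rng.permutation(A.shape[1])]
            assert wnodf(P) == pytest.approx(wnodf(A), abs=1e-9)


class TestModularity:
    def test_two_block_diagonal(self):
        part, q = modularity_lp(np.array([[5, 0], [0, 5]]), seed=0)
        assert q == pytest.approx(0.5)
        assert part["rows"][0] == part["cols"][0] != part["rows"][1]

    def test_single_module_q_zero(self):
        A = np.array([[3, 1], [2, 4]])
        rows = np.zeros(2, dtype=int)
        cols = np.zeros(2, dtype=int)
        assert barber_modularity(A, rows, cols) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_k_equal_blocks_closed_form(self, k):
        A = np.kron(np.eye(k, dtype=int), np.array([[4]]))
        _, q = modularity_lp(A, seed=1)
        assert q == pytest.approx((k - 1) / k, abs=1e-9)

    def test_beats_every_random_partition(self, rng):
        for _ in range(20):
            A = random_trimmed_matrix(rng, 4, 4)
            _, q = modularity_lp(A, seed=3)
            for _ in range(30):
                rows = rng.integers(0, 3, size=A.shape[0])
                cols = rng.integers(0, 3, size=A.shape[1])
                assert q >= barber_modularity(A, rows, cols) - 1e-9

    def test_matches_exhaustive_on_small_matrices(self, rng):
        for _ in range(25):
            A = random_trimmed_matrix(rng, 3, 3, max_count=3)
            _, q = modularity_lp(A, seed=5)
            assert q == pytest.approx(oracles.best_partition_q(A), abs=1e-9)

    def test_seed_determinism(self):
        A = np.array([[3, 1, 0], [0, 2, 2], [1, 0, 4]])
        r1 = modularity_lp(A, seed=9)
        r2 = modularity_lp(A, seed=9)
        assert r1[1] == r2[1]
        assert np.array_equal(r1[0]["rows"], r2[0]["rows"])


class TestH2Prime:
    def test_perfect_specialization(self):
        assert h2_prime(np.array([[2, 0], [0, 2]])) == pytest.approx(1.0)

    def test_independence_table_is_zero(self):
        # a_ij proportional to r_i * c_j: observed equals max entropy
        assert h2_prime(np.array([[1, 1], [1, 1]])) == pytest.approx(0.0)
        assert h2_prime(np.array([[1, 2], [2, 4]])) == pytest.approx(0.0, abs=1e-9)

    def test_single_cell_warns_and_returns_zero(self):
        with pytest.warns(UserWarning):
            assert h2_prime(np.array([[5]])) == 0.0

    def test_close_to_enumeration_oracle(self, rng):
        for _ in range(60):
            A = random_trimmed_matrix(rng, 3, 3, max_count=3)
            if A.sum() > 12:
                continue
            expected = oracles.h2_prime_enumeration(A)
            assert h2_prime(A) == pytest.approx(expected, abs=0.05)

    def test_bounded(self, rng):
        for _ in range(50):
            A = random_trimmed_matrix(rng, 6, 6)
            assert 0.0 <= h2_prime(A) <= 1.0


class TestNicheOverlap:
    def test_identical_usage_is_one(self):
        assert horn_overlap(np.array([2, 1, 1]), np.array([4, 2, 2])) == pytest.approx(1.0)

    def test_disjoint_partners_is_zero(self):
        assert horn_overlap(np.array([1, 0]), np.array([0, 3])) == pytest.approx(0.0)

    def test_mean_of_pairs_matches_bruteforce(self, rng):
        for _ in range(30):
            A = random_trimmed_matrix(rng, 5, 5)
            mat = im(A)
            assert niche_overlap(mat, "host") == pytest.approx(
                oracles.mean_horn_bruteforce(A), abs=1e-9
            )
            assert niche_overlap(mat, "beetle") == pytest.approx(
                oracles.mean_horn_bruteforce(A.T), abs=1e-9
            )

    def test_needs_two_species(self):
        with pytest.raises(ValueError):
            niche_overlap(im(np.array([[1, 2]])), "host")


class TestSpeciesIndices:
    def test_uniform_usage(self):
        mat = im(np.array([[3, 3, 3], [1, 1, 1]]))
        row = species_indices(mat, "host").set_index("species").loc["h00"]
        assert row["degree"] == 3
        assert row["effective_partners"] == pytest.approx(3.0)

    def test_effective_partners_shannon(self):
        mat = im(np.array([[1, 3], [2, 2]]))
        row = species_indices(mat, "host").set_index("species").loc["h00"]
        assert row["effective_partners"] == pytest.approx(1.7548, abs=1e-4)

    def test_species_strength_even_matrix(self):
        mat = im(np.array([[2, 2], [2, 2]]))
        tab = species_indices(mat, "host")
        assert tab["species_strength"].tolist() == pytest.approx([1.0, 1.0])

    def test_strengths_sum_to_partner_count(self, rng):
        for _ in range(30):
            mat = im(random_trimmed_matrix(rng, 6, 6))
            hosts = species_indices(mat, "host")
            beetles = species_indices(mat, "beetle")
            assert hosts["species_strength"].sum() == pytest.approx(len(mat.beetles))
            assert beetles["species_strength"].sum() == pytest.approx(len(mat.hosts))

    def test_effective_partners_bounded_by_degree(self, rng):
        for _ in range(30):
            tab = species_indices(im(random_trimmed_matrix(rng, 6, 6)), "beetle")
            assert (tab["effective_partners"] <= tab["degree"] + 1e-9).all()
            assert (tab["effective_partners"] >= 1.0 - 1e-9).all()

    def test_d_prime_bounds_and_extremes(self, rng):
        for _ in range(30):
            tab = species_indices(im(random_trimmed_matrix(rng, 6, 6)), "beetle")
            assert ((tab["d_prime"] >= 0) & (tab["d_prime"] <= 1)).all()
        # a species using partners exactly at availability has d' = 0
        mat = im(np.array([[1, 2], [1, 2]]))
        tab = species_indices(mat, "host")
        assert tab["d_prime"].tolist() == pytest.approx([0.0, 0.0], abs=1e-12)
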