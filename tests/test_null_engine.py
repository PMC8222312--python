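import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichenull import (
    MatrixValidationError,
    PresenceMatrix,
    UtilizationMatrix,
    count_checkerboard_units,
    randomize_ra1,
    randomize_ra2,
    randomize_ra3,
    randomize_ra4,
    run_null,
    sample_ff,
    swap_step_ff,
    to_utilization,
)
from nichenull import _ff_kernel
from nichenull.null_engine import _ra3, _ra4
from nichenull.overlap import mean_pairwise_overlap

from conftest import random_abundance


def util(rng, n_species=5, n_sites=8, zero_frac=0.4):
    return to_utilization(random_abundance(rng, n_species, n_sites, zero_frac))


def presence(rng, n_species=6, n_sites=10):
    b = rng.integers(0, 2, size=(n_species, n_sites))
    b[b.sum(axis=1) == 0, 0] = 1
    return PresenceMatrix(
        [f"s{j}" for j in range(n_species)], [f"t{i}" for i in range(n_sites)], b
    )


class TestRAFamily:
    def test_ra1_normalizes_and_fills_support(self, rng):
        u = util(rng)
        out = randomize_ra1(u, rng)
        np.testing.assert_allclose(out.p.sum(axis=1), 1.0, atol=1e-9)
        assert (out.p > 0).all()  # continuous draws: zeros almost surely absent

    def test_ra2_preserves_zero_pattern(self, rng):
        u = util(rng)
        for _ in range(20):
            out = randomize_ra2(u, rng)
            np.testing.assert_array_equal(out.p == 0, u.p == 0)
            np.testing.assert_allclose(out.p.sum(axis=1), 1.0, atol=1e-9)

    def test_ra2_single_support_row_becomes_one(self, rng):
        u = UtilizationMatrix(["a", "b"], list("123"), [[0, 1, 0], [0.2, 0.3, 0.5]])
        out = randomize_ra2(u, rng)
        assert out.p[0].tolist() == [0.0, 1.0, 0.0]

    def test_ra2_all_zero_row_rejected(self, rng):
        u = UtilizationMatrix(["a"], list("12"), [[0.5, 0.5]])
        u.p = np.array([[0.0, 0.0]])  # bypass constructor to hit the RA2 guard
        with pytest.raises(MatrixValidationError, match="all-zero row"):
            randomize_ra2(u, rng)

    def test_ra3_preserves_each_rows_value_multiset(self, rng):
        u = util(rng)
        for _ in range(20):
            out = randomize_ra3(u, rng)
            for orig, new in zip(u.p, out.p):
                np.testing.assert_array_equal(np.sort(orig), np.sort(new))

    def test_ra3_moves_zeros_uniformly_across_positions(self, rng):
        u = UtilizationMatrix(["a"], list("1234"), [[1 / 6, 2 / 6, 3 / 6, 0.0]])
        hits = np.zeros(4)
        n = 1000
        for _ in range(n):
            out = randomize_ra3(u, rng)
            hits[np.flatnonzero(out.p[0] == 0.0)[0]] += 1
        np.testing.assert_allclose(hits / n, 0.25, atol=0.05)  # ±3.6 sd at n=1000

    def test_ra4_keeps_zeros_fixed_and_multiset(self, rng):
        u = util(rng)
        for _ in range(20):
            out = randomize_ra4(u, rng)
            np.testing.assert_array_equal(out.p == 0, u.p == 0)
            for orig, new in zip(u.p, out.p):
                np.testing.assert_array_equal(np.sort(orig), np.sort(new))

    def test_ra4_fixed_point_with_single_positive_entry(self, rng):
        u = UtilizationMatrix(["a"], list("123"), [[0.0, 1.0, 0.0]])
        np.testing.assert_array_equal(randomize_ra4(u, rng).p, u.p)

    def test_ra4_exceeds_ra3_for_shared_support(self, rng):
        # guild structure: every species confined to the same 3 of 12 sites.
        # RA4 keeps utilization concentrated there; RA3 spreads it out.
        p = np.zeros((5, 12))
        p[:, :3] = rng.dirichlet(np.ones(3), size=5)
        m3 = np.mean([mean_pairwise_overlap(_ra3(p, rng)) for _ in range(300)])
        m4 = np.mean([mean_pairwise_overlap(_ra4(p, rng)) for _ in range(300)])
        assert m4 >= m3

    def test_same_seed_reproduces_randomization(self, rng):
        u = util(rng)
        for fn in (randomize_ra1, randomize_ra2, randomize_ra3, randomize_ra4):
            a = fn(u, np.random.default_rng(123))
            b = fn(u, np.random.default_rng(123))
            np.testing.assert_array_equal(a.p, b.p)


class TestSwapStep:
    def test_marginals_conserved_over_many_steps(self, rng):
        p = presence(rng)
        R, C = p.R.copy(), p.C.copy()
        for _ in range(500):
            swap_step_ff(p, rng)
        np.testing.assert_array_equal(p.R, R)
        np.testing.assert_array_equal(p.C, C)

    def test_all_ones_matrix_never_changes(self, rng):
        p = PresenceMatrix(["a", "b"], list("12"), np.ones((2, 2), dtype=int))
        for _ in range(100):
            swap_step_ff(p, rng)
        assert p.values.tolist() == [[1, 1], [1, 1]]

    def test_identity_swaps_to_antidiagonal(self, rng):
        p = PresenceMatrix(["a", "b"], list("12"), np.eye(2, dtype=int))
        swap_step_ff(p, rng)  # the only proposal is the checkerboard flip
        assert p.values.tolist() == [[0, 1], [1, 0]]

    def test_too_small_matrix_rejected(self, rng):
        p = PresenceMatrix(["a"], list("12"), [[1, 0]])
        with pytest.raises(MatrixValidationError, match="2×2"):
            swap_step_ff(p, rng)

    def test_two_state_chain_visits_both_states_evenly(self, rng):
        p = PresenceMatrix(["a", "b"], list("12"), np.eye(2, dtype=int))
        freq = 0
        n = 10_000
        for _ in range(n):
            swap_step_ff(p, rng)
            freq += int(p.values[0, 0])
        assert abs(freq / n - 0.5) <= 0.02


class TestSampleFF:
    def test_input_matrix_not_modified_and_kernel_conserves_marginals(self, rng):
        p = presence(rng)
        before = p.values.copy()
        sample_ff(p, 50, rng=rng)
        np.testing.assert_array_equal(p.values, before)
        work = np.ascontiguousarray(before, dtype=np.uint8)
        if _ff_kernel.HAVE_NUMBA:
            _ff_kernel.ff_chain(work, 100, 100, 10, 42)
        else:
            _ff_kernel.ff_chain_python(work, 100, 100, 10, 42)
        np.testing.assert_array_equal(work.sum(axis=1), before.sum(axis=1))
        np.testing.assert_array_equal(work.sum(axis=0), before.sum(axis=0))

    def test_python_and_kernel_agree_on_point_mass(self, rng):
        b = np.ones((3, 3), dtype=np.uint8)
        with pytest.warns(UserWarning, match="point mass"):
            s = sample_ff(PresenceMatrix(list("abc"), list("123"), b), 20, rng=rng)
        assert (s == s[0]).all()

    def test_permutation_matrices_match_enumeration_mean(self, rng):
        # all 6 permutation matrices have mean C-score exactly 1
        p = PresenceMatrix(list("abc"), list("123"), np.eye(3, dtype=int))
        s = sample_ff(p, 2000, rng=rng)
        assert s.mean() == pytest.approx(1.0)

    def test_checkerboard_count(self):
        assert count_checkerboard_units(np.eye(2, dtype=int)) == 1
        assert count_checkerboard_units(np.ones((3, 3), dtype=int)) == 0


class TestRunNull:
    def test_same_seed_is_bit_identical(self, rng):
        m = random_abundance(rng, 5, 8)
        for stat, alg in (("pianka-mean", "RA3"), ("cscore-mean", "FF")):
            a = run_null(m, stat, alg, iterations=200, seed=99)
            b = run_null(m, stat, alg, iterations=200, seed=99)
            assert a.observed == b.observed
            np.testing.assert_array_equal(a.simulated, b.simulated)
            assert (a.p_lower, a.p_upper, a.limits) == (b.p_lower, b.p_upper, b.limits)

    def test_identical_rows_under_ra3_are_an_upper_extreme(self, rng):
        from nichenull import AbundanceMatrix

        m = AbundanceMatrix(["a", "b"], list("1234"), [[1, 2, 3, 0], [2, 4, 6, 0]])
        r = run_null(m, "pianka-mean", "RA3", iterations=500, seed=5)
        assert r.observed == pytest.approx(1.0)
        assert (r.simulated <= 1.0 + 1e-12).all()
        assert r.p_upper <= r.p_lower

    @given(st.integers(0, 10**6))
    @settings(max_examples=10, deadline=None)
    def test_tails_overlap_on_ties(self, seed):
        m = random_abundance(np.random.default_rng(seed), 4, 7)
        r = run_null(m, "pianka-mean", "RA2", iterations=120, seed=seed)
        assert r.p_lower + r.p_upper >= 1.0
        assert 0 < r.p_lower <= 1 and 0 < r.p_upper <= 1
        lo1, hi1 = r.limits["one_tailed"]
        lo2, hi2 = r.limits["two_tailed"]
        assert lo2 <= lo1 <= hi1 <= hi2
        assert r.expected == pytest.approx(r.simulated.mean())

    def test_incompatible_pairings_rejected(self, rng):
        m = random_abundance(rng, 4, 6)
        with pytest.raises(ValueError, match="requires one of"):
            run_null(m, "pianka-mean", "FF", iterations=100)
        with pytest.raises(ValueError, match="requires algorithm 'FF'"):
            run_null(m, "cscore-mean", "RA3", iterations=100)
        with pytest.raises(ValueError, match="unknown statistic"):
            run_null(m, "schoener-mean", "RA3", iterations=100)

    def test_raw_p_value_convention(self, rng):
        m = random_abundance(rng, 5, 8)
        a = run_null(m, "cscore-mean", "FF", iterations=200, seed=3)
        b = run_null(m, "cscore-mean", "FF", iterations=200, seed=3, p_value_method="raw")
        np.testing.assert_array_equal(a.simulated, b.simulated)
        k_ge = int((b.simulated >= b.observed).sum())
        assert b.p_upper == k_ge / 200
        assert a.p_upper == (1 + k_ge) / 201
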