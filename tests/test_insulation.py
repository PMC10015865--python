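import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hics import (
    call_boundaries,
    compute_profile,
    higher_strength_min_distance,
    insulation_strength,
    normalize_and_rank,
    reflection_point,
)
from hics.simulate import simulate_cell

from conftest import brute_force_delta, brute_force_rho, make_map, make_profile


class TestInsulationStrength:
    def test_hand_summation_four_bins(self):
        cmap = make_map({(0, 1): 1, (2, 3): 1}, 4)
        rho = insulation_strength(cmap, W=1)
        # bin 1: I_intra = entry(0,1) + entry(1,2) = 1, I_inter = entry(0,2) = 0
        assert rho[1] == 1.0

    @pytest.mark.parametrize("W", [1, 2, 5, 20])
    def test_uniform_matrix_closed_form(self, W):
        """Interior-bin rho on a constant off-diagonal matrix is 1/(2W+1):
        each flank holds C(W+1,2) pairs, the cross region W^2 pairs."""
        n = 3 * 20 + 5
        mat = np.full((n, n), 3.0)
        np.fill_diagonal(mat, 0.0)
        rho = insulation_strength(mat, W)
        interior = rho[W : n - W]
        np.testing.assert_allclose(interior, 1.0 / (2 * W + 1), rtol=1e-12)

    def test_zero_denominator_gives_zero(self):
        cmap = make_map({(0, 1): 1}, 6)
        rho = insulation_strength(cmap, W=1)
        assert rho[4] == 0.0

    def test_matches_brute_force_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            n = rng.integers(8, 25)
            mat = rng.poisson(0.7, size=(n, n)).astype(float)
            mat = np.triu(mat, 1)
            mat = mat + mat.T
            W = int(rng.integers(1, n - 1))
            np.testing.assert_allclose(
                insulation_strength(mat, W), brute_force_rho(mat, W), atol=1e-12
            )

    def test_rho_bounded(self):
        rng = np.random.default_rng(1)
        mat = rng.poisson(1.0, size=(30, 30)).astype(float)
        mat = np.triu(mat, 1) + np.triu(mat, 1).T
        rho = insulation_strength(mat, 4)
        assert np.all(rho >= -1) and np.all(rho <= 1)

    def test_window_not_smaller_than_chromosome(self):
        with pytest.raises(ValueError, match="W"):
            insulation_strength(np.zeros((5, 5)), W=5)


class TestHigherStrengthMinDistance:
    def test_exhaustive_scan_example(self):
        delta = higher_strength_min_distance(np.array([1.0, 3.0, 2.0]), 10)
        np.testing.assert_array_equal(delta, [1, 10, 1])

    def test_constant_rho_all_max(self):
        delta = higher_strength_min_distance(np.full(7, 2.5), 5)
        np.testing.assert_array_equal(delta, np.full(7, 5))

    @pytest.mark.parametrize("max_search", [2, 7, 50])
    def test_equals_brute_force_random(self, max_search):
        rng = np.random.default_rng(max_search)
        for _ in range(20):
            rho = rng.choice(rng.normal(size=8), size=rng.integers(3, 60))
            np.testing.assert_array_equal(
                higher_strength_min_distance(rho, max_search),
                brute_force_delta(rho, max_search),
            )

    def test_gap_bins_excluded_from_both_roles(self):
        rho = np.array([0.1, 9.0, 0.5, 0.4])
        gaps = np.array([False, True, False, False])
        delta = higher_strength_min_distance(rho, 10, gaps)
        assert np.isnan(delta[1])
        # bin 3's nearest higher is bin 2 (the gap bin is ignored despite rho=9);
        # bin 2 has no higher non-gap bin at all, so it gets MAX
        assert delta[3] == 1 and delta[2] == 10 and delta[0] == 2

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=40),
        st.integers(1, 30),
    )
    def test_property_equals_brute_force(self, values, max_search):
        rho = np.array(values)
        np.testing.assert_array_equal(
            higher_strength_min_distance(rho, max_search),
            brute_force_delta(rho, max_search),
        )


class TestNormalizeAndRank:
    def test_rank_with_index_tie_break(self):
        # engineered so eta comes out [0.9, 0.4, 0.4, 0.1] up to scale
        rho = np.array([0.9, 0.4, 0.4, 0.1])
        delta = np.full(4, 10.0)
        # delta equal => eta ordering follows rho; ties 1 vs 2 break by index
        _, _, eta, gamma, gamma_norm = normalize_and_rank(rho, delta, 10)
        np.testing.assert_array_equal(gamma, [1, 2, 3, 4])
        assert gamma_norm[np.argmax(gamma)] == 1.0

    def test_max_bin_eta_is_one(self):
        rho = np.array([0.0, 0.5, 1.0])
        delta = np.array([1.0, 2.0, 8.0])
        _, _, eta, _, _ = normalize_and_rank(rho, delta, 8)
        assert eta[2] == 1.0

    def test_ranges(self):
        rng = np.random.default_rng(3)
        rho = rng.normal(size=50)  # negative values allowed
        delta = rng.integers(1, 21, size=50).astype(float)
        rho_n, delta_n, eta, gamma, gamma_n = normalize_and_rank(rho, delta, 20)
        for v in (rho_n, delta_n, eta, gamma_n):
            assert np.nanmin(v) >= 0 and np.nanmax(v) <= 1

    def test_flat_profile_is_error(self):
        with pytest.raises(ValueError, match="flat insulation profile"):
            normalize_and_rank(np.ones(5), np.ones(5), 10)


class TestReflectionPoint:
    def test_arithmetic_example(self):
        eta = np.array([1.0, 0.8, 0.1, 0.05])
        gamma_norm = np.array([0.25, 0.5, 0.75, 1.0])
        rank, bin_idx, eta_r = reflection_point(eta, gamma_norm)
        assert rank == 3 and bin_idx == 2 and eta_r == 0.1

    def test_single_bin_profile(self):
        rank, bin_idx, eta_r = reflection_point(np.array([0.7]), np.array([1.0]))
        assert rank == 1 and bin_idx == 0

    def test_elbow_on_synthetic_curve(self):
        """On a fast-decaying eta curve the reflection point sits where both
        eta and gamma' are small, after the strong head of the curve."""
        n = 100
        eta = np.exp(-np.arange(n) / 3.0)
        gamma_norm = np.arange(1, n + 1) / n
        rank, _, eta_r = reflection_point(eta, gamma_norm)
        assert 3 < rank < 30
        assert eta_r < 0.2

    def test_tie_takes_smallest_rank(self):
        # ranks 1 and 2 have exactly equal objectives (0.8,0.6) vs (0.6,0.8)
        eta = np.array([0.8, 0.6, 0.0])
        gamma_norm = np.array([0.6, 0.8, 1.2])
        rank, _, _ = reflection_point(eta, gamma_norm)
        assert rank == 1


class TestCallBoundaries:
    def test_threshold_comparison(self):
        prof = make_profile([0.9, 0.05, 0.4, 0.02], eta_r=0.1)
        bset = call_boundaries(prof, alpha=1.0)
        np.testing.assert_array_equal(bset.bins, [0, 2])

    def test_large_alpha_empty_set(self):
        prof = make_profile([0.9, 0.05, 0.4, 0.02], eta_r=0.1)
        assert len(call_boundaries(prof, alpha=9.5)) == 0

    def test_gap_bins_never_boundaries(self):
        prof = make_profile([0.9, 0.8, 0.4], eta_r=0.1, gap_mask=[False, True, False])
        np.testing.assert_array_equal(call_boundaries(prof, 1.0).bins, [0, 2])

    def test_degenerate_threshold_is_error(self):
        prof = make_profile([0.9, 0.1], eta_r=0.0)
        with pytest.raises(ValueError, match="degenerate threshold"):
            call_boundaries(prof, 1.0)

    def test_alpha_outside_soft_range_warns(self, caplog):
        prof = make_profile([0.9, 0.05], eta_r=0.1)
        with caplog.at_level("WARNING", logger="hics.insulation"):
            call_boundaries(prof, alpha=0.05)
        assert "alpha" in caplog.text

    def test_monotone_nesting_in_alpha(self):
        rng = np.random.default_rng(5)
        prof = make_profile(rng.uniform(0, 1, 200), eta_r=0.2)
        sets = [set(call_boundaries(prof, a).bins.tolist()) for a in (0.3, 1, 2, 5)]
        for small, big in zip(sets[:-1], sets[1:]):
            assert big <= small


class TestComputeProfile:
    def test_profile_fields_consistent(self, sim_cell):
        cmap, _ = sim_cell
        prof = compute_profile(cmap, window=20, max_search=500)
        ok = ~prof.gap_mask
        assert np.isfinite(prof.eta[ok]).all()
        assert np.isnan(prof.eta[prof.gap_mask]).all()
        assert prof.delta[ok].min() >= 1 and prof.delta[ok].max() <= 500
        assert prof.eta_r >= 0
        # gamma is a permutation of 1..n_ranked
        assert sorted(prof.gamma[ok].tolist()) == list(range(1, ok.sum() + 1))

    def test_inter_zero_bins_flagged_as_gaps(self):
        # a contact chain with the cross-pairs around bin 5 removed: bin 5
        # has I_inter = 0 and must be masked even though it carries contacts
        n = 13
        entries = {(i, i + 1): 1 for i in range(n - 1)}
        entries.update({(i, i + 2): 1 for i in range(n - 2) if i != 4})
        entries[(2, 3)] = 5  # non-flat rho among the active bins
        cmap = make_map(entries, n)
        prof = compute_profile(cmap, window=1, max_search=10)
        assert prof.gap_mask[5]
        assert not prof.gap_mask[2]

    def test_shuffle_destroys_boundary_recovery(self):
        """Permuting bins of a structured map leaves no positional signal:
        recall of the planted boundaries drops to chance level."""
        from hics import BoundaryCaller, score_recovery

        cmap, truth = simulate_cell(n_bins=300, depth=15_000, seed=21)
        rng = np.random.default_rng(0)
        perm = rng.permutation(cmap.n_bins)
        shuffled = cmap.matrix[np.ix_(perm, perm)]
        bc = BoundaryCaller(embed=False).fit(cmap.matrix)
        recall, _ = score_recovery(bc.boundaries_.bins, truth.levels[0], 1)
        bs = BoundaryCaller(embed=False).fit(shuffled)
        shuf_recall, _ = score_recovery(bs.boundaries_.bins, truth.levels[0], 1)
        assert recall >= 0.8
        assert shuf_recall <= 0.4
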