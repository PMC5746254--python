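"""Tests for selectivity indices, pair correlations and response filters."""

import numpy as np
import pytest
from scipy import stats

from plaidnet.metrics import (ModulationSummary, ResponseTable,
                              classify_modulation, estimate_rf_centre,
                              fisher_compare, grating_plaid_r2,
                              modulation_index, movie_signal_correlation,
                              osi, pairwise_correlations, psi,
                              responsivity_filter)
from plaidnet.metrics import _exact_fisher_2xk


class TestSelectivityIndices:
    @pytest.mark.parametrize("r, expected", [
        ([1, 0, 0, 0], 1.0),
        ([1, 1, 1, 1], 0.0),
        ([2, 1, 1, 1], 0.2),
    ])
    def test_osi(self, r, expected):
        assert osi(r) == expected

    @pytest.mark.parametrize("r, expected", [
        ([1, 0, 0], 1.0),
        ([2, 2, 2, 2], 0.0),
        ([2, 1, 1], 0.5),
    ])
    def test_psi(self, r, expected):
        assert psi(r) == expected

    @pytest.mark.parametrize("rg, rp, expected", [
        ([1, 2], [2, 1], 0.0),
        ([1, 0.5], [0, 0], -1.0),
        ([1], [3], 0.5),
    ])
    def test_modulation_index(self, rg, rp, expected):
        assert modulation_index(rg, rp) == expected

    def test_undefined_cases_flagged(self):
        assert np.isnan(osi([0, 0, 0]))
        assert np.isnan(psi([0, 0]))
        assert np.isnan(modulation_index([0], [0]))

    def test_range_invariants(self, rng):
        for _ in range(50):
            rg = rng.uniform(0, 5, 6)
            rp = rng.uniform(0, 5, 8)
            assert 0.0 <= osi(rg) <= 1.0
            assert 0.0 <= psi(rp) <= 1.0
            assert -1.0 <= modulation_index(rg, rp) <= 1.0


def _table_from_tuning(G, P):
    G, P = np.asarray(G, float), np.asarray(P, float)
    resp = np.concatenate([G, P], axis=1)[:, :, None]
    kinds = np.array(["grating"] * G.shape[1] + ["plaid"] * P.shape[1])
    return ResponseTable(resp, kinds)


class TestPairwiseCorrelations:
    def test_identical_tuning_correlates_perfectly(self):
        G = np.array([[1.0, 2, 3, 4], [2, 4, 6, 8]])
        P = np.array([[1.0, 3, 2], [2, 6, 4]])
        pairs = pairwise_correlations(_table_from_tuning(G, P))
        assert pairs.rho_g[0] == pytest.approx(1.0)
        assert pairs.rho_p[0] == pytest.approx(1.0)

    def test_one_hot_orthogonal_correlation(self):
        # closed-form Pearson of [1,0,0,0] vs [0,1,0,0] is -1/3
        G = np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]])
        P = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        pairs = pairwise_correlations(_table_from_tuning(G, P))
        assert pairs.rho_g[0] == pytest.approx(-1 / 3)

    def test_symmetry_in_pair_order(self, rng):
        G = rng.uniform(0, 1, (5, 4))
        P = rng.uniform(0, 1, (5, 3))
        t = _table_from_tuning(G, P)
        a = pairwise_correlations(t, scope=[1, 3])
        b = pairwise_correlations(t, scope=[3, 1])
        assert a.rho_g[0] == pytest.approx(b.rho_g[0])

    def test_zero_variance_neuron_excluded(self):
        G = np.array([[1.0, 2, 3, 4], [5, 5, 5, 5], [0, 1, 0, 1]])
        P = np.array([[1.0, 2, 3], [1, 2, 3], [3, 2, 1]])
        pairs = pairwise_correlations(_table_from_tuning(G, P))
        assert 1 in pairs.excluded
        assert len(pairs.rho_g) == 1


class TestGratingPlaidR2:
    def test_perfect_relation(self, rng):
        theta = rng.uniform(-np.pi, np.pi, 40)
        G = np.exp(4 * (np.cos(np.subtract.outer(
            theta, np.linspace(-np.pi, np.pi, 5, endpoint=False))) - 1))
        pairs = pairwise_correlations(_table_from_tuning(G, G[:, :4]))
        # rho_p built from the same tuning vectors: R^2 must be ~1 only
        # when the plaid set equals the grating set
        pairs_same = pairwise_correlations(_table_from_tuning(G, G))
        assert grating_plaid_r2(pairs_same) == pytest.approx(1.0)

    def test_independent_permutation_decorrelates(self, rng):
        # permutation oracle: shuffling one axis destroys the relation
        n = 150
        theta = rng.uniform(-np.pi, np.pi, n)
        G = np.exp(4 * (np.cos(np.subtract.outer(
            theta, np.linspace(-np.pi, np.pi, 6, endpoint=False))) - 1))
        P = G[rng.permutation(n)]
        pairs = pairwise_correlations(_table_from_tuning(G, P))
        assert grating_plaid_r2(pairs) < 0.01

    def test_affine_rescaling_invariance(self, rng):
        G = rng.uniform(0.1, 1, (20, 5))
        P = rng.uniform(0.1, 1, (20, 6))
        t1 = _table_from_tuning(G, P)
        scale = rng.uniform(0.5, 3.0, (20, 1))
        t2 = _table_from_tuning(G * scale, P * scale)
        r1 = grating_plaid_r2(pairwise_correlations(t1), osi_threshold=0)
        r2 = grating_plaid_r2(pairwise_correlations(t2), osi_threshold=0)
        assert r1 == pytest.approx(r2, rel=1e-9)

    def test_too_few_pairs_raises(self):
        G = np.array([[1.0, 0, 0, 0], [0, 1, 0, 0]])
        P = np.array([[1.0, 0, 0], [0, 1, 0]])
        pairs = pairwise_correlations(_table_from_tuning(G, P))
        with pytest.raises(ValueError):
            grating_plaid_r2(pairs)


class TestModulationClassification:
    def test_counts_partition_population(self, rng):
        mis = rng.uniform(-1, 1, 500)
        s = classify_modulation(mis)
        assert s.n_total == 500

    def test_identical_summaries_give_p_one(self):
        a = ModulationSummary(10, 5, 3)
        assert fisher_compare(a, ModulationSummary(10, 5, 3)) == pytest.approx(
            1.0)

    def test_2x2_reduction_matches_exact_hypergeometric(self):
        # oracle: scipy's exact 2x2 Fisher test
        table = np.array([[8, 2], [1, 9]])
        ours = _exact_fisher_2xk(table)
        scipy_p = stats.fisher_exact(table)[1]
        assert ours == pytest.approx(scipy_p, rel=1e-9)
        assert ours == pytest.approx(0.00548, abs=5e-5)

    def test_2x3_matches_scipy_on_collapsed_margins(self):
        # independence: a 2x3 with an empty third column reduces to 2x2
        p3 = _exact_fisher_2xk(np.array([[8, 2, 0], [1, 9, 0]]))
        p2 = stats.fisher_exact([[8, 2], [1, 9]])[1]
        assert p3 == pytest.approx(p2, rel=1e-9)

    def test_different_distributions_detected(self):
        a = ModulationSummary(40, 5, 5)
        b = ModulationSummary(5, 40, 5)
        assert fisher_compare(a, b) < 1e-6


class TestResponsivityFilter:
    def _neuropil(self, rng, scale=1.0, units=300, stims=6, T=10):
        return scale * rng.standard_normal((units, stims, T))

    def test_null_neurons_excluded(self, rng):
        # responses drawn from the neuropil distribution itself are
        # excluded at roughly the nominal specificity
        neuropil = self._neuropil(rng)
        resp = rng.standard_normal((400, 6, 10))
        table = ResponseTable(resp, np.array(["grating"] * 6))
        mask = responsivity_filter(table, neuropil, alpha=0.01)
        assert mask.mean() < 0.02

    def test_strong_responders_included(self, rng):
        neuropil = self._neuropil(rng)
        resp = rng.standard_normal((50, 6, 10)) * 0.1
        resp[:, 2, :] += 10.0      # 10 SD above neuropil at one stimulus
        table = ResponseTable(resp, np.array(["grating"] * 6))
        assert responsivity_filter(table, neuropil, alpha=0.01).all()

    def test_alpha_one_degenerate(self, rng):
        neuropil = self._neuropil(rng)
        resp = np.full((5, 6, 10), 0.5)
        resp += rng.standard_normal(resp.shape) * 1e-3
        table = ResponseTable(resp, np.array(["grating"] * 6))
        # thresholds collapse to the distribution minimum: everything with
        # positive responses passes
        assert responsivity_filter(table, neuropil, alpha=1.0).all()

    def test_single_trial_rejected(self, rng):
        table = ResponseTable(np.ones((3, 4, 1)), np.array(["grating"] * 4))
        with pytest.raises(ValueError):
            responsivity_filter(table, self._neuropil(rng))


class TestRFCentre:
    @pytest.fixture
    def grid(self):
        x, y = np.meshgrid(np.arange(5) * 9.0, np.arange(5) * 9.0,
                           indexing="ij")
        return x, y

    def test_single_peak_at_stimulus_location(self, grid):
        x, y = grid
        w = np.zeros((5, 5))
        w[3, 1] = 2.0
        cx, cy = estimate_rf_centre(w, x, y)
        assert (cx, cy) == (27.0, 9.0)

    def test_square_of_equal_responses_centres_at_midpoint(self, grid):
        # adjacent grid cells: the square is small relative to sigma, so
        # the mixture peaks at the shared midpoint by symmetry
        x, y = grid
        w = np.zeros((5, 5))
        w[1, 1] = w[1, 2] = w[2, 1] = w[2, 2] = 1.0
        cx, cy = estimate_rf_centre(w, x, y)
        assert (cx, cy) == (13.5, 13.5)

    def test_matches_dense_grid_oracle(self, grid, rng):
        x, y = grid
        w = rng.uniform(0, 1, (5, 5))
        cx, cy = estimate_rf_centre(w, x, y, resolution=0.1)
        xs = np.arange(0, 36.01, 0.1)
        X, Y = np.meshgrid(xs, xs, indexing="ij")
        mix = sum(w.ravel()[k] * np.exp(-((X - x.ravel()[k]) ** 2
                                          + (Y - y.ravel()[k]) ** 2)
                                        / (2 * 7.5 ** 2))
                  for k in range(25))
        k = np.argmax(mix)
        assert abs(cx - X.ravel()[k]) <= 0.1 + 1e-9
        assert abs(cy - Y.ravel()[k]) <= 0.1 + 1e-9

    def test_all_zero_rejected(self, grid):
        x, y = grid
        with pytest.raises(ValueError):
            estimate_rf_centre(np.zeros((5, 5)), x, y)


class TestMovieCorrelation:
    def test_identical_traces(self):
        t = np.sin(np.linspace(0, 10, 200))
        assert movie_signal_correlation(t, t, [0.0], dt=0.05) == pytest.approx(
            1.0)

    def test_anticorrelated_traces(self):
        t = np.sin(np.linspace(0, 10, 200))
        assert movie_signal_correlation(t, -t, [0.0],
                                        dt=0.05) == pytest.approx(-1.0)

    def test_exclusion_windows_masked(self, rng):
        a = rng.standard_normal(100)
        b = rng.standard_normal(100)
        onsets = [0.0, 5.0]
        got = movie_signal_correlation(a, b, onsets, exclusion=1.0, dt=0.1)
        keep = np.ones(100, bool)
        keep[0:10] = False
        keep[50:60] = False
        expected = np.corrcoef(a[keep], b[keep])[0, 1]
        assert got == pytest.approx(expected)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            movie_signal_correlation(np.zeros(5), np.zeros(6), [0.0])
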