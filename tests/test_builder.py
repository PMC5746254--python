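"""Tests for population placement and the three connectivity generators."""

import numpy as np
import pytest
from scipy import stats

from plaidnet.builder import (ConnectivitySpec, TorusGeometry,
                              assign_membership, build_synapse_matrix,
                              draw_synapses, feature_binding_probability,
                              generate_subnetwork_fields,
                              like_to_like_probability, peters_probability,
                              place_population, torus_distance,
                              SubnetworkComposition, PopulationLayout)


class TestPlacement:
    def test_inhibitory_count_binomial(self):
        layout = place_population(80_000, seed=0, prop_inhibitory=0.18)
        n_inh = layout.is_inhibitory.sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], 80_000, 0.18)
        assert lo <= n_inh <= hi

    def test_positions_in_range(self, small_layout):
        geo = small_layout.geometry
        assert np.all(small_layout.positions >= 0)
        assert np.all(small_layout.positions[:, 0] < geo.width)
        assert np.all(small_layout.positions[:, 1] < geo.height)

    def test_seed_reproducibility(self):
        a = place_population(50, seed=3)
        b = place_population(50, seed=3)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.theta, b.theta, equal_nan=True)

    def test_anatomical_defaults(self, small_layout):
        inh = small_layout.is_inhibitory
        assert np.all(small_layout.sigma_axon[inh] == 100.0)
        assert np.all(small_layout.sigma_axon[~inh] == 290.0)
        assert np.all(small_layout.synapse_budget[inh] == 8566)
        assert np.all(small_layout.synapse_budget[~inh] == 8142)


class TestTorusDistance:
    def test_coincident(self):
        geo = TorusGeometry(2200, 2200)
        assert torus_distance([5.0, 7.0], [5.0, 7.0], geo) == 0.0

    def test_wraparound(self):
        geo = TorusGeometry(2200, 2200)
        assert torus_distance([0, 0], [2100, 0], geo) == pytest.approx(100)

    def test_maximal_separation(self):
        geo = TorusGeometry(2200, 2200)
        assert torus_distance([0, 0], [1100, 1100], geo) == pytest.approx(
            1100 * np.sqrt(2))


class TestPeters:
    def test_normalised_and_self_free(self, small_layout):
        p = peters_probability(small_layout, 0)
        assert p.sum() == pytest.approx(1.0)
        assert p[0] == 0.0
        assert np.all(p >= 0)

    def test_nearest_most_probable(self):
        geo = TorusGeometry(1000, 1000)
        layout = place_population(2, geo, seed=0)
        layout.positions[:] = [[100, 100], [300, 100]]
        layout = _with_extra_targets(layout, [[150, 100], [600, 100]])
        p = peters_probability(layout, 0)
        assert p.argmax() == 2       # the 50-um neighbour

    def test_matches_torus_quadrature(self):
        # independent oracle: trapezoidal quadrature of the product of
        # the periodised Gaussian fields over the torus (exponentially
        # accurate for smooth periodic integrands)
        geo = TorusGeometry(600.0, 600.0)
        layout = place_population(6, geo, seed=8)
        layout.sigma_dendrite[:] = 40.0
        layout.sigma_axon[:] = 60.0
        grid = 400
        xs = (np.arange(grid) + 0.5) * geo.width / grid
        X, Y = np.meshgrid(xs, xs, indexing="ij")

        def field(u, rho):
            out = np.zeros_like(X)
            for kx in (-1, 0, 1):
                for ky in (-1, 0, 1):
                    out += np.exp(-((X - u[0] + kx * geo.width) ** 2
                                    + (Y - u[1] + ky * geo.height) ** 2)
                                  / (2 * rho ** 2))
            return out

        src = 0
        overlaps = np.zeros(6)
        axon = field(layout.positions[src], 60.0)
        for tgt in range(6):
            if tgt == src:
                continue
            overlaps[tgt] = (axon * field(layout.positions[tgt],
                                          40.0)).sum()
        expected = overlaps / overlaps.sum()
        got = peters_probability(layout, src)
        np.testing.assert_allclose(got, expected, rtol=1e-6, atol=1e-12)

    def test_single_neuron_rejected(self):
        layout = place_population(1, seed=0)
        with pytest.raises(ValueError):
            peters_probability(layout, 0)


def _with_extra_targets(layout, positions):
    """Append excitatory neurons at explicit positions (test helper)."""
    k = len(positions)
    return PopulationLayout(
        geometry=layout.geometry,
        positions=np.vstack([layout.positions, positions]),
        is_inhibitory=np.concatenate([layout.is_inhibitory,
                                      np.zeros(k, bool)]),
        theta=np.concatenate([layout.theta, np.zeros(k)]),
        kappa=np.concatenate([layout.kappa, np.full(k, 4.0)]),
        sigma_dendrite=np.concatenate([layout.sigma_dendrite,
                                       np.full(k, 75.0)]),
        sigma_axon=np.concatenate([layout.sigma_axon, np.full(k, 290.0)]),
        synapse_budget=np.concatenate([layout.synapse_budget,
                                       np.full(k, 8142)]),
    )


class TestLikeToLike:
    def test_s1_zero_reduces_to_peters(self, small_layout):
        src = int(np.flatnonzero(small_layout.excitatory)[0])
        p0 = like_to_like_probability(small_layout, src, s1=0.0)
        np.testing.assert_allclose(p0, peters_probability(small_layout,
                                                          src))

    def test_von_mises_ratio_for_equidistant_targets(self):
        # two targets mirror-symmetric about the source, orientations
        # aligned vs orthogonal; in the pure specific component the
        # probability ratio is e^(2 kappa1)
        geo = TorusGeometry(2200, 2200)
        layout = place_population(3, geo, seed=1)
        layout.is_inhibitory[:] = False
        layout.positions[:] = [[1100, 1100], [1000, 1100], [1200, 1100]]
        layout.theta[:] = [0.0, 0.0, np.pi]   # doubled angles: 0 vs 90 deg
        p = like_to_like_probability(layout, 0, s1=1.0, kappa1=0.5)
        assert p[1] / p[2] == pytest.approx(np.exp(2 * 0.5), rel=1e-9)

    def test_sums_to_one(self, small_layout):
        src = int(np.flatnonzero(small_layout.excitatory)[0])
        p = like_to_like_probability(small_layout, src, s1=0.7)
        assert p.sum() == pytest.approx(1.0)

    def test_invalid_s1(self, small_layout):
        with pytest.raises(ValueError):
            like_to_like_probability(small_layout, 0, s1=1.5)

    def test_inhibitory_source_rejected(self, small_layout):
        src = int(np.flatnonzero(small_layout.is_inhibitory)[0])
        with pytest.raises(ValueError):
            like_to_like_probability(small_layout, src, s1=0.5)

    def test_like_oriented_synapse_fraction_monotone(self, medium_layout):
        # fraction of E->E synapses between neurons < 30 deg apart grows
        # with the specificity parameter
        fracs = []
        for s1 in (0.0, 0.4, 0.8):
            spec = ConnectivitySpec(rule="like_to_like", s1=s1, kappa1=0.5)
            syn = build_synapse_matrix(medium_layout, spec, seed=5)
            C = syn.counts.tocoo()
            exc = medium_layout.excitatory
            ee = exc[C.row] & exc[C.col]
            dtheta = np.abs(np.angle(np.exp(
                1j * (medium_layout.theta[C.row]
                      - medium_layout.theta[C.col]))))
            close = dtheta < np.deg2rad(60)   # 30 deg true orientation
            fracs.append(C.data[ee & close].sum() / C.data[ee].sum())
        assert fracs[0] < fracs[1] < fracs[2]


class TestSubnetworks:
    def test_angles_in_range(self, small_layout):
        comp = generate_subnetwork_fields(small_layout, 3, 2, seed=0)
        a = comp.component_orientations
        assert a.shape == (small_layout.n_neurons, 3, 2)
        assert np.all(a >= -np.pi) and np.all(a <= np.pi)

    def test_spatial_smoothness(self, medium_layout):
        # circular agreement of a component field is higher for nearby
        # neuron pairs than for distant ones
        comp = generate_subnetwork_fields(medium_layout, 1, 1, seed=3)
        ang = comp.component_orientations[:, 0, 0]
        pos = medium_layout.positions
        geo = medium_layout.geometry
        n = medium_layout.n_neurons
        rng = np.random.default_rng(0)
        i = rng.integers(n, size=4000)
        j = rng.integers(n, size=4000)
        d = torus_distance(pos[i], pos[j], geo)
        agree = np.cos(ang[i] - ang[j])
        near = agree[(d > 0) & (d < 40)]
        far = agree[d > 100]
        assert near.size > 20 and far.size > 20
        assert near.mean() > far.mean() + 0.3

    def test_wide_filter_approaches_constant(self, small_layout):
        comp = generate_subnetwork_fields(small_layout, 1, 1,
                                          filter_sigma=1e5, seed=4)
        ang = comp.component_orientations[:, 0, 0]
        spread = np.abs(np.angle(np.exp(1j * (ang - ang[0]))))
        assert spread.max() < 1e-3

    def test_membership_exact_match_dominates(self, small_layout):
        n = small_layout.n_neurons
        comps = np.zeros((n, 2, 2))
        comps[:, 0, :] = [0.0, np.pi / 2]     # subnetwork 0 components
        comps[:, 1, :] = [np.pi, -np.pi / 2]  # orthogonal subnetwork
        comp = SubnetworkComposition(comps, filter_sigma=75.0)
        exc = small_layout.excitatory
        small_layout.theta[exc] = 0.0
        m = assign_membership(small_layout, comp, kappa2=4.0)
        assert np.all(m[exc] == 0)
        assert np.all(m[~exc] == -1)

    def test_every_excitatory_labelled(self, small_layout):
        comp = generate_subnetwork_fields(small_layout, 6, 2, seed=1)
        m = assign_membership(small_layout, comp)
        exc = small_layout.excitatory
        assert np.all((m[exc] >= 0) & (m[exc] < 6))


class TestFeatureBinding:
    @pytest.fixture
    def fb_setup(self, small_layout):
        comp = generate_subnetwork_fields(small_layout, 4, 2, seed=2)
        mem = assign_membership(small_layout, comp)
        src = int(np.flatnonzero(small_layout.excitatory)[0])
        return small_layout, comp, mem, src

    def test_s2_zero_reduces_to_like_to_like(self, fb_setup):
        layout, comp, mem, src = fb_setup
        p = feature_binding_probability(layout, comp, mem, src,
                                        s1=0.3, s2=0.0)
        np.testing.assert_allclose(
            p, like_to_like_probability(layout, src, s1=0.3))

    def test_pure_binding_support(self, fb_setup):
        layout, comp, mem, src = fb_setup
        p = feature_binding_probability(layout, comp, mem, src,
                                        s1=0.0, s2=1.0)
        outside = (mem != mem[src]) & layout.excitatory
        assert np.all(p[outside] == 0.0)
        assert p.sum() == pytest.approx(1.0)

    def test_sums_to_one(self, fb_setup):
        layout, comp, mem, src = fb_setup
        p = feature_binding_probability(layout, comp, mem, src,
                                        s1=0.1, s2=0.25)
        assert p.sum() == pytest.approx(1.0)

    def test_same_subnetwork_fraction_exceeds_baseline(self, medium_layout):
        comp = generate_subnetwork_fields(medium_layout, 6, 2, seed=9)
        mem = assign_membership(medium_layout, comp)

        def same_frac(spec):
            syn = build_synapse_matrix(medium_layout, spec,
                                       composition=comp, membership=mem,
                                       seed=11)
            C = syn.counts.tocoo()
            exc = medium_layout.excitatory
            ee = exc[C.row] & exc[C.col]
            same = mem[C.row] == mem[C.col]
            return C.data[ee & same].sum() / C.data[ee].sum()

        base = same_frac(ConnectivitySpec(rule="random"))
        fb = same_frac(ConnectivitySpec(rule="feature_binding",
                                        s1=0.1, s2=0.25))
        assert fb >= base + 0.25 * (1 - base) - 0.03


class TestDrawSynapses:
    def test_column_sums_match_budgets(self, small_layout):
        spec = ConnectivitySpec(rule="random", density_factor=0.1)
        syn = build_synapse_matrix(small_layout, spec, seed=0)
        col_sums = np.asarray(syn.counts.sum(axis=0)).ravel()
        expected = np.round(small_layout.synapse_budget * 0.1)
        np.testing.assert_array_equal(col_sums, expected)

    def test_total_output_weight_constant_by_class(self, small_layout):
        spec = ConnectivitySpec(rule="random", density_factor=0.1)
        syn = build_synapse_matrix(small_layout, spec, seed=1)
        out_w = np.asarray(np.abs(syn.weights).sum(axis=0)).ravel()
        inh = small_layout.is_inhibitory
        assert np.ptp(out_w[inh]) < 1e-9
        assert np.ptp(out_w[~inh]) < 1e-9
        # density rescaling preserves total conductance: 8142 syn * 0.01
        # pA/Hz * 0.066 Hz/pA with budget rounding applied after scaling
        assert out_w[~inh][0] == pytest.approx(814 * 0.1 * 0.066)

    def test_empirical_frequencies_match_probabilities(self, rng):
        # sampling oracle: 1e5 draws from one source, chi-square test
        layout = place_population(40, TorusGeometry(500, 500), seed=2)
        p = peters_probability(layout, 0)
        layout.synapse_budget[:] = 1_000_000
        spec = ConnectivitySpec(rule="random", density_factor=0.1)
        P = np.tile(p, (40, 1))
        np.fill_diagonal(P, 0.0)
        P[np.arange(40) != 0] = np.roll(P[0], 1)  # rows irrelevant but valid
        syn = draw_synapses(P / P.sum(axis=1, keepdims=True), layout, spec,
                            seed=3)
        counts = np.asarray(syn.counts[:, 0].todense()).ravel()
        keep = p > 1e-6
        chi = stats.chisquare(counts[keep],
                              p[keep] / p[keep].sum() * counts[keep].sum())
        assert chi.pvalue > 0.01

    def test_invalid_density_factor(self, small_layout):
        with pytest.raises(ValueError):
            ConnectivitySpec(rule="random", density_factor=0.0)
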