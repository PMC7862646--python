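"""Closed-form moments of the hidden-variable model against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from densiswitch import model

KAPPA_GRID = np.linspace(0.05, 1.0, 20)
NP_GRID = np.array([2, 3, 5, 10, 27, 60, 126, 250, 500], dtype=float)


def q0_quadrature(kappa, n_potential):
    """Isolated-node fraction by direct integration over the activity density."""
    val, _ = integrate.quad(
        lambda a: (1.0 - kappa * a / 2.0) ** (n_potential - 1.0), 0.0, 1.0,
        epsabs=1e-13, epsrel=1e-13,
    )
    return val


def kbar_quadrature(kappa, n_potential):
    """Mean degree as (N_p - 1) times the average pair-connection probability."""
    val, _ = integrate.dblquad(
        lambda a, b: kappa * a * b, 0.0, 1.0, 0.0, 1.0,
        epsabs=1e-13, epsrel=1e-13,
    )
    return (n_potential - 1.0) * val


class TestEdgeProbability:
    @pytest.mark.parametrize(
        "kappa,a_i,a_j,expected",
        [(1, 1, 1, 1.0), (0.3, 0, 0.8, 0.0), (0.3, 0.5, 0.5, 0.075)],
    )
    def test_values(self, kappa, a_i, a_j, expected):
        assert model.edge_probability(kappa, a_i, a_j) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(-0.1, 0.5, 0.5), (1.5, 0.5, 0.5), (0.5, 1.2, 0.5)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            model.edge_probability(*bad)


class TestClosedForms:
    def test_single_node_is_always_isolated(self):
        for kappa in (0.1, 0.5, 1.0):
            assert model.isolated_fraction(kappa, 1.0) == pytest.approx(1.0)
            assert model.expected_active_nodes(kappa, 1.0) == pytest.approx(0.0)
            assert model.expected_edges(kappa, 1.0) == 0.0
            assert model.mean_degree(kappa, 1.0) == 0.0

    def test_two_node_hand_values(self):
        # q0 = (2/2)(1 - (1/2)^2) = 0.75; N = 2(1 - 0.75); M = 1*2*1/8
        assert model.isolated_fraction(1.0, 2.0) == pytest.approx(0.75)
        assert model.expected_active_nodes(1.0, 2.0) == pytest.approx(0.5)
        assert model.expected_edges(1.0, 2.0) == pytest.approx(0.25)

    def test_two_node_direct_expectation(self):
        # E[N] over two nodes = 2 * Pr(edge) = 2 * kappa * E[a]^2
        assert model.expected_active_nodes(1.0, 2.0) == pytest.approx(2 * 1.0 * 0.25)

    def test_reference_point(self):
        assert model.expected_edges(0.3, 126.0) == pytest.approx(590.625)
        assert model.mean_degree(0.3, 126.0) == pytest.approx(9.375)

    def test_large_population_activity_saturates(self):
        n = model.expected_active_nodes(0.467, 1e6)
        assert n / 1e6 >= 0.999

    @pytest.mark.parametrize("kappa", KAPPA_GRID[::4])
    @pytest.mark.parametrize("n_potential", NP_GRID)
    def test_q0_matches_quadrature(self, kappa, n_potential):
        assert model.isolated_fraction(kappa, n_potential) == pytest.approx(
            q0_quadrature(kappa, n_potential), abs=1e-10
        )

    def test_kbar_matches_quadrature(self):
        for kappa in (0.05, 0.45, 0.6, 1.0):
            for n_potential in (2.0, 41.0, 126.0, 500.0):
                assert model.mean_degree(kappa, n_potential) == pytest.approx(
                    kbar_quadrature(kappa, n_potential), abs=1e-10
                )

    def test_conservation_identities(self):
        # N = (1 - q0) N_p and kbar = 2M / N_p on a dense grid
        kk, nn = np.meshgrid(KAPPA_GRID, NP_GRID)
        q0 = model.isolated_fraction(kk, nn)
        n = model.expected_active_nodes(kk, nn)
        m = model.expected_edges(kk, nn)
        kbar = model.mean_degree(kk, nn)
        np.testing.assert_allclose(n, (1 - q0) * nn, atol=1e-12)
        np.testing.assert_allclose(kbar, 2 * m / nn, atol=1e-12)

    def test_kappa_out_of_real_domain(self):
        with pytest.raises(ValueError):
            model.isolated_fraction(2.5, 10)
        with pytest.raises(ValueError):
            model.isolated_fraction(0.0, 10)


class TestInverses:
    def test_zero_edges_means_single_node(self):
        assert model.invert_population(0.0, 0.7) == pytest.approx(1.0)

    def test_hand_values(self):
        assert model.invert_population(590.625, 0.3) == pytest.approx(126.0)
        assert model.invert_population(0.25, 1.0) == pytest.approx(2.0)
        assert model.invert_activity(590.625, 126.0) == pytest.approx(0.3)
        assert model.invert_activity(0.0, 50.0) == 0.0

    def test_unit_kappa_by_construction(self):
        npot = 37.0
        assert model.invert_activity(npot * (npot - 1) / 8.0, npot) == pytest.approx(1.0)

    @given(
        kappa=st.floats(0.05, 1.0),
        n_potential=st.floats(2.0, 500.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip(self, kappa, n_potential):
        m = model.expected_edges(kappa, n_potential)
        assert model.invert_population(m, kappa) == pytest.approx(n_potential, abs=1e-10)
        assert model.invert_activity(m, n_potential) == pytest.approx(kappa, abs=1e-10)

    def test_inconsistent_inputs_not_clamped(self):
        # more edges than kappa=1 allows: the raw implied value is returned
        assert model.invert_activity(100.0, 10.0) > 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            model.invert_population(-1.0, 0.5)
        with pytest.raises(ValueError):
            model.invert_activity(5.0, 1.0)


class TestRegimeCurves:
    def test_zero_edge_limits(self):
        assert model.regime1_curve(0.0, 0.5) == pytest.approx(0.0)
        assert model.regime2_curve(0.0, 50.0) == pytest.approx(0.0)

    def test_composition_through_two_nodes(self):
        assert model.regime1_curve(0.25, 1.0) == pytest.approx(0.5)
        assert model.regime2_curve(0.25, 2.0) == pytest.approx(0.5)

    def test_regime1_strictly_increasing_in_m(self):
        m = np.linspace(0.0, 2000.0, 400)
        for kappa in (0.1, 0.3, 0.9):
            n = model.regime1_curve(m, kappa)
            assert np.all(np.diff(n) > 0)

    def test_regime2_bounded_by_population(self):
        npot = 126.0
        m_max = npot * (npot - 1) / 8.0  # implied kappa hits 1 here
        m = np.linspace(0.0, m_max, 200)
        n = model.regime2_curve(m, npot)
        assert np.all(n <= npot + 1e-9)

    def test_regime2_rejects_unreal_kappa(self):
        # implied kappa > 2 leaves the real domain of the closed form
        with pytest.raises(ValueError):
            model.regime2_curve(30.0, 5.0)


class TestDensity:
    def test_identity_with_moment_ratio(self):
        for kappa in (0.1, 0.3, 0.8):
            for npot in (20.0, 126.0, 400.0):
                n = model.expected_active_nodes(kappa, npot)
                m = model.expected_edges(kappa, npot)
                direct = 2 * m / (n * (n - 1))
                assert model.expected_density(kappa, npot) == pytest.approx(
                    direct, abs=1e-12
                )

    def test_large_population_limit(self):
        assert abs(model.expected_density(0.4, 1e5) - 0.1) < 1e-3

    def test_monotone_in_population_at_fixed_kappa(self):
        npots = np.linspace(30, 5000, 200)
        dens = np.array([model.expected_density(0.3, v) for v in npots])
        assert np.all(np.diff(dens) < 0)  # approaches kappa/4 from above
        assert dens[-1] == pytest.approx(0.3 / 4, rel=5e-3)
        assert abs(model.expected_density(0.3, 1e5) - 0.3 / 4) < 1e-4

    def test_undefined_below_two_active_nodes(self):
        with pytest.raises(ValueError):
            model.expected_density(0.5, 1.0)
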