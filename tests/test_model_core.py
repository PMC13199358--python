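import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ductsim as d

S = d.STATE_LABELS


def idx(label: str) -> int:
    return S.index(label)


probability = st.floats(0.0, 1.0, allow_nan=False)


def valid_params(p_mut, p_die_frac, p_spr):
    """Map unit-cube draws to a valid parameter triple (p_mut + p_die <= 1)."""
    return d.ModelParams(p_mut, (1.0 - p_mut) * p_die_frac, p_spr * 0.1)


class TestModelParams:
    def test_stay_probability_is_derived(self):
        p = d.ModelParams(0.021, 0.495, 0.009)
        assert p.s == pytest.approx(1.0 - 0.021 - 0.495)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(p_mut=-0.1, p_die=0.0),
            dict(p_mut=0.0, p_die=1.2),
            dict(p_mut=0.6, p_die=0.6),
            dict(p_mut=0.1, p_die=0.1, p_spr=float("nan")),
        ],
    )
    def test_invalid_probabilities_rejected(self, kwargs):
        with pytest.raises(d.ParameterError):
            d.ModelParams(**kwargs)


class TestIntrinsicTable:
    def test_healthy_column_for_calibration_values(self, calib_params):
        tables = d.build_intrinsic(calib_params)
        col = tables.intrinsic[:, idx("H")]
        assert col[idx("H")] == pytest.approx(0.484)
        assert col[idx("M1")] == pytest.approx(0.021)
        assert col[idx("D")] == pytest.approx(0.495)
        assert col.sum() == pytest.approx(1.0)

    def test_mutation_ladder_and_boundary_columns(self, calib_params):
        rho = d.build_intrinsic(calib_params).intrinsic
        for n in range(1, 6):  # M_n -> M_{n+1}
            assert rho[idx(f"M{n+1}"), idx(f"M{n}")] == pytest.approx(0.021)
        assert rho[idx("C"), idx("M6")] == pytest.approx(0.021)
        assert rho[idx("C"), idx("C")] == 1.0  # absorbing
        assert rho[idx("H"), idx("D")] == 1.0  # renewal
        assert rho[idx("D"), idx("C")] == 0.0

    def test_zero_rates_give_identity_except_renewal(self):
        rho = d.build_intrinsic(d.ModelParams(0.0, 0.0, 0.0)).intrinsic
        expected = np.eye(9)
        expected[idx("D"), idx("D")] = 0.0
        expected[idx("H"), idx("D")] = 1.0
        np.testing.assert_allclose(rho, expected)

    @given(probability, probability, probability)
    def test_columns_always_stochastic(self, a, b, c):
        tables = d.build_intrinsic(valid_params(a, b, c))
        np.testing.assert_allclose(tables.intrinsic.sum(axis=0), 1.0, atol=1e-12)
        assert np.all(tables.intrinsic >= 0)

    def test_spreading_weights_scale_with_mutation_count(self, calib_params):
        w = d.build_intrinsic(calib_params).spreading_weight
        np.testing.assert_allclose(w[1:7], 0.009 * np.arange(1, 7))
        assert w[idx("H")] == w[idx("C")] == w[idx("D")] == 0.0


class TestLocalUpdate:
    def test_worked_mixed_neighborhood(self):
        """H cell among {M2, M2, M4, H} with p_die=0: the gamma-normalized table."""
        model = d.nine_state_model(d.ModelParams(0.021, 0.0, 0.009))
        dist = d.local_update_distribution(model, "H", ["M2", "M2", "M4", "H"])
        g = 1.0 / (1.0 + 8 * 0.009)
        assert dist[idx("H")] == pytest.approx(g * (1 - 0.021))
        assert dist[idx("M1")] == pytest.approx(g * 0.021)
        assert dist[idx("M2")] == pytest.approx(4 * g * 0.009)
        assert dist[idx("M4")] == pytest.approx(4 * g * 0.009)
        assert dist[idx("C")] == 0.0
        assert dist.sum() == pytest.approx(1.0)

    def test_cancerous_and_dead_cells_cannot_be_overgrown(self, calib_params):
        model = d.nine_state_model(calib_params)
        for state, target in [("C", "C"), ("D", "H")]:
            dist = d.local_update_distribution(model, state, ["M6"] * 4)
            assert dist[idx(target)] == 1.0

    def test_all_healthy_neighborhood_is_intrinsic_column(self, calib_params):
        model = d.nine_state_model(calib_params)
        dist = d.local_update_distribution(model, "H", ["H"] * 4)
        np.testing.assert_allclose(dist, model.intrinsic[:, idx("H")])

    def test_wrong_neighbor_count_raises(self, calib_params):
        model = d.nine_state_model(calib_params)
        with pytest.raises(d.TopologyError):
            d.local_update_distribution(model, "H", ["H"] * 3)

    @given(probability, probability, probability, st.lists(st.integers(0, 8), min_size=4, max_size=4))
    def test_distribution_normalized_for_any_neighborhood(self, a, b, c, nbs):
        model = d.nine_state_model(valid_params(a, b, c))
        for current in range(9):
            dist = d.local_update_distribution(model, current, nbs)
            assert np.all(dist >= 0)
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_no_spreading_means_intrinsic_column(self, calib_params):
        model = d.nine_state_model(
            d.ModelParams(calib_params.p_mut, calib_params.p_die, 0.0)
        )
        for current in range(9):
            dist = d.local_update_distribution(model, current, ["M3", "M6", "M1", "M5"])
            np.testing.assert_allclose(dist, model.intrinsic[:, current])

    def test_takeover_probability_monotone_in_neighbor_mutations(self):
        # n >= 2 so the landing state is reachable only by takeover
        # (intrinsic transitions from H go to H, M1 or D)
        model = d.nine_state_model(d.ModelParams(0.02, 0.3, 0.01))
        prev = 0.0
        for n in range(2, 7):
            dist = d.local_update_distribution(model, "H", [f"M{n}", "H", "H", "H"])
            takeover = dist[idx(f"M{n}")]
            assert takeover > prev
            prev = takeover


class TestLattice:
    def test_cylinder_neighbors_of_interior_cell(self):
        lat = d.Lattice(circumference=15, n_rings=3, wrap_axial=True)
        nbs = set(lat.neighbors(lat.index(1, 0)))
        expected = {lat.index(1, 14), lat.index(1, 1), lat.index(0, 0), lat.index(2, 0)}
        assert nbs == expected

    def test_torus_corner_neighbors(self):
        lat = d.Lattice(circumference=20, n_rings=20, wrap_axial=True)
        nbs = set(lat.neighbors(lat.index(0, 0)))
        expected = {lat.index(0, 19), lat.index(0, 1), lat.index(19, 0), lat.index(1, 0)}
        assert nbs == expected

    @pytest.mark.parametrize("lat", [d.Lattice(15, 3, True), d.Lattice(5, 5, True)])
    def test_neighbor_relation_is_4_regular_and_symmetric(self, lat):
        appearances = np.zeros(lat.n_cells, dtype=int)
        for i in range(lat.n_cells):
            nbs = lat.neighbors(i)
            assert len(nbs) == 4
            for j in nbs:
                appearances[j] += 1
                assert i in lat.neighbors(j)
        assert np.all(appearances == 4)

    def test_open_ends_reduce_boundary_degree(self):
        lat = d.Lattice(circumference=6, n_rings=3, wrap_axial=False)
        assert len(lat.neighbors(lat.index(0, 0))) == 3
        assert len(lat.neighbors(lat.index(1, 0))) == 4

    def test_out_of_range_index_rejected(self):
        with pytest.raises(d.TopologyError):
            d.Lattice(15, 1).neighbors(15)


class TestScenario:
    def test_exposure_window_switches_parameters(self, calib_params):
        exposed = d.ModelParams(0.022, 0.282, 0.008)
        sc = d.Scenario(
            baseline=calib_params,
            t_max=1080,
            exposure=d.Exposure(params=exposed, start_age=30.0, duration_steps=6, dose_gy=0.1),
        )
        start = 360
        assert sc.params_at(start) == calib_params
        for t in range(start + 1, start + 7):
            assert sc.params_at(t) == exposed
        assert sc.params_at(start + 7) == calib_params

    def test_window_outside_horizon_rejected(self, calib_params):
        with pytest.raises(d.ParameterError):
            d.Scenario(
                baseline=calib_params,
                t_max=100,
                exposure=d.Exposure(calib_params, start_age=30.0, duration_steps=6),
            )
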