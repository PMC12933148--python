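"""Phosphorus/carbon cycle parameterizations and steady-state solves."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from oceancp.constants import SECONDS_PER_YEAR
from oceancp.element_cycles import (
    CycleParameters,
    ParameterDomainError,
    cp_ratio,
    dissolution_operator,
    flux_weighted_mean,
    martin_b,
    normalized_surface_temperature,
    particle_operator,
    q10_rate,
    solve_c_cycle,
    solve_p_cycle,
    uptake_coefficient,
)
from oceancp.grid_transport import Grid, SyntheticGridSpec, build_synthetic_transport
from oceancp.synthetic_ocean import ForcingFields, make_forcing


def column_pair_grid(interfaces, n_euphotic=2) -> Grid:
    """Two adjacent water columns with the given layer interfaces."""
    n_layers = len(interfaces) - 1
    return Grid(
        lat_edges=np.array([-2.0, 0.0, 2.0]),
        lon_edges=np.array([0.0, 2.0]),
        layer_interfaces=np.asarray(interfaces, float),
        wet3d=np.ones((2, 1, n_layers), bool),
        n_euphotic_layers=n_euphotic,
    )


# ---------------------------------------------------------------------------
# scalar parameterizations
# ---------------------------------------------------------------------------


class TestNormalizedTemperature:
    def test_constant_field_degenerate_range(self, ocean90):
        theta = normalized_surface_temperature(
            np.full(ocean90.grid.n_boxes, 12.3), ocean90.grid
        )
        np.testing.assert_array_equal(theta, 0.0)

    def test_two_columns_minmax(self):
        grid = column_pair_grid([0.0, 40.0, 80.0, 120.0, 500.0], n_euphotic=2)
        T = np.where(grid.box_lat < 0, 0.0, 30.0)
        theta = normalized_surface_temperature(T, grid)
        np.testing.assert_allclose(theta[grid.box_lat < 0], 0.0)
        np.testing.assert_allclose(theta[grid.box_lat > 0], 1.0)

    def test_range_and_warm_tropics(self, ocean200):
        theta = ocean200.state.diagnostics["theta_bar"]
        assert theta.min() >= 0 and theta.max() <= 1
        # warmest columns (lowest |lat|) are near 1
        tropics = np.abs(ocean200.grid.box_lat) < 20
        assert theta[tropics].min() > 0.8

    def test_shallow_grid_warns(self, caplog):
        grid = column_pair_grid([0.0, 50.0, 100.0], n_euphotic=1)
        with caplog.at_level("WARNING"):
            normalized_surface_temperature(np.linspace(0, 1, grid.n_boxes), grid)
        assert any("layers" in r.message for r in caplog.records)


class TestScalarLaws:
    def test_martin_b_values(self):
        assert martin_b(np.array([0.5]), 1.0, 0.3)[0] == pytest.approx(1.15)
        np.testing.assert_allclose(martin_b(np.linspace(0, 1, 5), 0.9, 0.0), 0.9)
        with pytest.raises(ParameterDomainError):
            martin_b(np.array([1.0]), 0.1, -0.2)

    def test_q10_reference_and_decade(self):
        kd = 3.0e-8
        assert q10_rate(np.array([30.0]), kd, 2.0)[0] == pytest.approx(kd)
        assert q10_rate(np.array([20.0]), kd, 2.0)[0] == pytest.approx(kd / 2)

    def test_cp_ratio_redfield_limit_and_monotonicity(self):
        dip = np.linspace(0.0, 3e-3, 50)
        np.testing.assert_allclose(cp_ratio(dip, 0.0, 1.0 / 106.0), 106.0)
        r = cp_ratio(dip, 2.0, 7e-3)
        assert np.all(np.diff(r) < 0)
        with pytest.raises(ParameterDomainError):
            cp_ratio(np.array([0.0]), 2.0, 0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        theta=st.floats(0, 1),
        b0=st.floats(0.1, 3),
        btheta=st.floats(0, 2),
        t=st.floats(-2, 35),
        q10=st.floats(1, 5),
    )
    def test_law_properties(self, theta, b0, btheta, t, q10):
        """b is linear-increasing in theta; k is increasing in T, k(T0)=kd."""
        b = martin_b(np.array([theta]), b0, btheta)[0]
        assert b >= b0
        kd = 1e-8
        k = q10_rate(np.array([t]), kd, q10)[0]
        assert k <= kd or t > 30.0


class TestUptakeCoefficient:
    def test_proportional_and_masked(self, ocean90):
        g = ocean90.grid
        f = ocean90.forcing
        r_obs = np.full(g.n_boxes, 106.0)
        gam1 = uptake_coefficient(f.satellite_npp, f.surface_dip_obs, r_obs, g.euphotic_mask)
        gam2 = uptake_coefficient(2 * f.satellite_npp, f.surface_dip_obs, r_obs, g.euphotic_mask)
        np.testing.assert_allclose(gam2, 2 * gam1)
        assert np.all(gam1[~g.euphotic_mask] == 0)

    def test_self_consistency_with_observed_dip(self, ocean90):
        """gamma * DIP_obs * r_C:P(DIP_obs) reproduces NPP exactly."""
        g, f = ocean90.grid, ocean90.forcing
        p = ocean90.params
        r_obs = cp_ratio(np.maximum(f.surface_dip_obs, 1e-12), p.cc, p.dd)
        gam = uptake_coefficient(f.satellite_npp, f.surface_dip_obs, r_obs, g.euphotic_mask)
        np.testing.assert_allclose(gam * f.surface_dip_obs * r_obs, f.satellite_npp)

    def test_zero_dip_under_positive_npp_rejected(self, ocean90):
        g, f = ocean90.grid, ocean90.forcing
        dip = f.surface_dip_obs.copy()
        dip[np.argmax(f.satellite_npp)] = 0.0
        with pytest.raises(ValueError):
            uptake_coefficient(f.satellite_npp, dip, np.full(g.n_boxes, 106.0), g.euphotic_mask)


# ---------------------------------------------------------------------------
# particle redistribution
# ---------------------------------------------------------------------------


class TestParticleOperator:
    def test_closed_form_power_law_fractions(self):
        """Layers z0->2z0->4z0 with b=1: fractions 1/2, 1/4 + seafloor 1/4."""
        z0 = 100.0
        grid = column_pair_grid([0.0, z0 / 2, z0, 2 * z0, 4 * z0], n_euphotic=2)
        S = particle_operator(np.ones(grid.n_boxes), grid)
        col = grid.columns()[0]
        prod = np.zeros(grid.n_boxes)
        prod[col[0]] = 1.0  # unit volumetric production in the top box
        remin = S @ prod
        v = grid.box_volume
        export = v[col[0]]
        frac_layer3 = remin[col[2]] * v[col[2]] / export
        frac_layer4 = remin[col[3]] * v[col[3]] / export
        assert frac_layer3 == pytest.approx(0.5, rel=1e-12)
        # bottom box receives its layer's 1/4 plus the seafloor 1/4
        assert frac_layer4 == pytest.approx(0.5, rel=1e-12)

    @pytest.mark.parametrize("b", [0.4, 0.9, 1.3, 2.5])
    def test_column_mass_balance(self, ocean90, b):
        g = ocean90.grid
        S = particle_operator(np.full(g.n_boxes, b), g)
        prod = np.where(g.euphotic_mask, ocean90.forcing.satellite_npp, 0.0)
        remin = S @ prod
        v = g.box_volume
        assert abs(remin @ v - prod @ v) < 1e-12 * (prod @ v)

    def test_large_b_remineralizes_immediately_below(self, ocean90):
        g = ocean90.grid
        S = particle_operator(np.full(g.n_boxes, 50.0), g)
        prod = np.where(g.euphotic_mask, 1e-9, 0.0)
        remin = S @ prod
        first_sub = g.ilayer == g.n_euphotic_layers
        v = g.box_volume
        assert (remin[first_sub] @ v[first_sub]) / (remin @ v) > 0.999

    def test_dissolution_operator_conserves(self, ocean90):
        g = ocean90.grid
        D = dissolution_operator(3000.0, g)
        prod = np.where(g.euphotic_mask, 1e-9, 0.0)
        v = g.box_volume
        assert abs((D @ prod) @ v - prod @ v) < 1e-12 * (prod @ v)


# ---------------------------------------------------------------------------
# steady-state solves
# ---------------------------------------------------------------------------


def zero_npp_forcing(grid) -> ForcingFields:
    f = make_forcing(grid, seed=0)
    return ForcingFields(
        temperature=f.temperature,
        satellite_npp=np.zeros(grid.n_boxes),
        surface_dip_obs=f.surface_dip_obs,
        npp_total_pg_y=0.0,
    )


class TestPCycle:
    def test_no_biology_limit(self, ocean90):
        """gamma = 0: DIP uniform at the inventory, organic pools empty."""
        g, A, p = ocean90.grid, ocean90.A, ocean90.params
        state = solve_p_cycle(p, A, zero_npp_forcing(g), g)
        np.testing.assert_allclose(state.concentrations["DIP"], p.dip_inventory, rtol=1e-10)
        np.testing.assert_allclose(state.concentrations["DOP"], 0.0, atol=1e-20)
        np.testing.assert_allclose(state.concentrations["DOPl"], 0.0, atol=1e-20)
        for pool in ("POP", "DOP", "DOPl"):
            assert state.production_integral(pool) == 0.0

    def test_mean_dip_pinned_to_inventory(self, ocean90):
        st = ocean90.state
        v = ocean90.grid.box_volume
        mean_dip = st.concentrations["DIP"] @ v / v.sum()
        assert mean_dip == pytest.approx(ocean90.params.dip_inventory, rel=1e-10)

    def test_unpinned_balance_satisfied(self, ocean90):
        """The solution satisfies every original balance equation.

        The inventory constraint replaces one DIP equation; global P
        conservation implies the replaced equation holds too.
        """
        g, A, p, f = ocean90.grid, ocean90.A, ocean90.params, ocean90.forcing
        st = ocean90.state
        c = st.concentrations
        # residual of the DIP equation: transport + remin - uptake
        gamma = st.diagnostics["gamma"]
        k_p = st.diagnostics["k_P"]
        resid = (
            sp.csr_matrix(A) @ c["DIP"]
            - gamma * c["DIP"]
            + st.remineralization["POP"]
            + k_p * c["DOP"]
            + p.kappa_l * c["DOPl"]
        )
        scale = np.abs(gamma * c["DIP"]).max()
        assert np.abs(resid).max() < 1e-8 * scale

    def test_steady_state_production_equals_remineralization(self, ocean200):
        st = ocean200.state
        for pool in ("POP", "DOP", "DOPl", "POC", "DOCs", "DOCl", "DOCr"):
            prod = st.production_integral(pool)
            rem = st.remin_integral(pool)
            if prod == 0.0:
                assert rem == pytest.approx(0.0, abs=1e-20)
            else:
                assert rem == pytest.approx(prod, rel=1e-8)

    @staticmethod
    def fast_two_column_system():
        """Two vigorously exchanging columns (relaxation in years)."""
        grid = column_pair_grid([0.0, 50.0, 120.0, 250.0, 500.0, 1000.0, 2000.0])
        n = grid.n_boxes
        v = grid.box_volume
        A = np.zeros((n, n))

        def exchange(i, j, kvol):
            A[i, i] -= kvol / v[i]; A[i, j] += kvol / v[i]
            A[j, j] -= kvol / v[j]; A[j, i] += kvol / v[j]

        cols = grid.columns()
        for col in cols:
            for a, b in zip(col[:-1], col[1:]):
                exchange(a, b, 2.0e6)
        for a, b in zip(cols[0], cols[1]):
            exchange(a, b, 5.0e6)
        return grid, A, make_forcing(grid, seed=3), CycleParameters()

    def test_dense_oracle_two_columns(self):
        """Sparse pinned solve equals a dense least-squares oracle."""
        grid, A, f, params = self.fast_two_column_system()
        n = grid.n_boxes
        v = grid.box_volume
        state = solve_p_cycle(params, sp.csr_matrix(A), f, grid)

        # oracle: dense overdetermined system (all balances + constraint)
        gamma = state.diagnostics["gamma"]
        k_p = state.diagnostics["k_P"]
        S_p = particle_operator(state.diagnostics["b_P"], grid).toarray()
        G = np.diag(gamma)
        f_pop = 1 - params.sigma_dop - params.sigma_dopl
        Kp = np.diag(k_p)
        Il = params.kappa_l * np.eye(n)
        M = np.block(
            [
                [A - G + f_pop * (S_p @ G), Kp, Il],
                [params.sigma_dop * G, A - Kp, np.zeros((n, n))],
                [params.sigma_dopl * G, np.zeros((n, n)), A - Il],
            ]
        )
        constraint = np.concatenate([v / v.sum(), np.zeros(2 * n)])
        M_aug = np.vstack([M, constraint])
        rhs = np.zeros(3 * n + 1)
        rhs[-1] = params.dip_inventory
        x, *_ = np.linalg.lstsq(M_aug, rhs, rcond=None)
        got = np.concatenate(
            [state.concentrations["DIP"], state.concentrations["DOP"],
             state.concentrations["DOPl"]]
        )
        np.testing.assert_allclose(got, x, rtol=1e-6, atol=1e-12)

    def test_equilibrium_matches_forward_integration(self):
        """2,000 y of forward integration lands on the linear solve."""
        g, Ad, f, p = self.fast_two_column_system()
        st = solve_p_cycle(p, sp.csr_matrix(Ad), f, g)
        n = g.n_boxes
        gamma = st.diagnostics["gamma"]
        k_p = st.diagnostics["k_P"]
        S_p = particle_operator(st.diagnostics["b_P"], g).toarray()
        G = np.diag(gamma)
        f_pop = 1 - p.sigma_dop - p.sigma_dopl
        M = np.block(
            [
                [Ad - G + f_pop * (S_p @ G), np.diag(k_p), p.kappa_l * np.eye(n)],
                [p.sigma_dop * G, Ad - np.diag(k_p), np.zeros((n, n))],
                [p.sigma_dopl * G, np.zeros((n, n)), Ad - p.kappa_l * np.eye(n)],
            ]
        )
        target = np.concatenate(
            [st.concentrations["DIP"], st.concentrations["DOP"],
             st.concentrations["DOPl"]]
        )
        # start from the same total P, all inorganic and uniform
        v = g.box_volume
        total_p = v @ (target[:n] + target[n:2 * n] + target[2 * n:])
        x0 = np.concatenate([np.full(n, total_p / v.sum()), np.zeros(2 * n)])
        x = expm(M * 2000.0 * SECONDS_PER_YEAR) @ x0
        np.testing.assert_allclose(x, target, rtol=2e-6, atol=1e-9 * target[:n].max())


class TestCCycle:
    def test_npp_equal_to_nonlabile_production_kills_labile(self, ocean90):
        g, A, p = ocean90.grid, ocean90.A, ocean90.params
        p_state = solve_p_cycle(p, A, ocean90.forcing, g)
        dip = p_state.concentrations["DIP"]
        # same evaluation order as the solver, so the residual is exactly 0
        u_c = cp_ratio(dip, p.cc, p.dd) * (p_state.diagnostics["gamma"] * dip)
        doctored = ForcingFields(
            temperature=ocean90.forcing.temperature,
            satellite_npp=u_c,
            surface_dip_obs=ocean90.forcing.surface_dip_obs,
            npp_total_pg_y=ocean90.forcing.npp_total_pg_y,
        )
        state = solve_c_cycle(p, A, p_state, doctored, g)
        assert state.production_integral("DOCl") == 0.0
        np.testing.assert_allclose(state.concentrations["DOCl"], 0.0, atol=1e-25)

    def test_toc_production_tops_up_to_npp(self, ocean200):
        """TOC production = integral of max(NPP, non-labile production)."""
        st = ocean200.state
        g = ocean200.grid
        v = g.box_volume
        r_cp = st.diagnostics["r_cp"]
        u_c = r_cp * st.diagnostics["gamma"] * st.concentrations["DIP"]
        expected = np.maximum(ocean200.forcing.satellite_npp, u_c) @ v
        assert st.total_production("C") == pytest.approx(expected, rel=1e-12)
        # and is within a few percent of prescribed NPP (clamping is rare)
        npp = ocean200.forcing.satellite_npp @ v
        assert st.total_production("C") == pytest.approx(npp, rel=0.1)

    def test_symmetry_collapse_c_equals_r_times_p(self, ocean90):
        """Identical C/P parameters, cc=0, no labile top-up, no PIC:
        the organic carbon fields are exactly r x the phosphorus fields."""
        g, A = ocean90.grid, ocean90.A
        r = 106.0
        p = CycleParameters(
            cc=0.0, dd=1.0 / r,
            bC0=0.9, bCtheta=0.5, bP0=0.9, bPtheta=0.5,
            kdC=2e-9, kdP=2e-9, Q10C=2.0, Q10P=2.0,
            sigma_dop=0.3, sigma_dopl=0.0,
            sigma_docs=0.3, sigma_docr=0.0,
            pic_rain_ratio=0.0,
        )
        p_state = solve_p_cycle(p, A, ocean90.forcing, g)
        u_c = r * p_state.diagnostics["gamma"] * p_state.concentrations["DIP"]
        doctored = ForcingFields(
            temperature=ocean90.forcing.temperature,
            satellite_npp=u_c,
            surface_dip_obs=ocean90.forcing.surface_dip_obs,
            npp_total_pg_y=ocean90.forcing.npp_total_pg_y,
        )
        state = solve_c_cycle(p, A, p_state, doctored, g)
        np.testing.assert_allclose(
            state.concentrations["DOCs"], r * state.concentrations["DOP"], rtol=1e-9
        )
        np.testing.assert_allclose(
            state.remineralization["POC"], r * state.remineralization["POP"],
            rtol=1e-9, atol=1e-30,
        )

    def test_dic_alk_o2_solved_and_restored(self, ocean200):
        st = ocean200.state
        g = ocean200.grid
        surf = g.ilayer == 0
        # surface DIC/ALK near their restoring references
        assert np.abs(st.concentrations["DIC"][surf] - st.params.dic_surface_ref).max() < 0.15
        assert np.abs(st.concentrations["ALK"][surf] - st.params.alk_surface_ref).max() < 0.15
        assert np.all(st.concentrations["O2"][surf] > 0)


class TestFluxWeightedMean:
    def test_uniform_field_any_weights(self, ocean90):
        g = ocean90.grid
        w = np.abs(np.sin(np.arange(g.n_boxes, dtype=float)))
        assert flux_weighted_mean(np.full(g.n_boxes, 3.7), w, g.box_volume) == pytest.approx(3.7)

    def test_point_mass_weight(self, ocean90):
        g = ocean90.grid
        f = np.arange(g.n_boxes, dtype=float)
        w = np.zeros(g.n_boxes)
        w[17] = 2.0
        assert flux_weighted_mean(f, w, g.box_volume) == pytest.approx(17.0)

    def test_zero_weight_rejected(self, ocean90):
        with pytest.raises(ValueError):
            flux_weighted_mean(
                np.ones(ocean90.grid.n_boxes),
                np.zeros(ocean90.grid.n_boxes),
                ocean90.grid.box_volume,
            )


class TestParameterConfig:
    def test_round_trip(self, tmp_path):
        p = CycleParameters(kdP=3.3e-9, sigma_dopl=0.2)
        path = str(tmp_path / "params.txt")
        p.to_config(path)
        q = CycleParameters.from_config(path)
        assert q.to_dict() == p.to_dict()

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("not_a_parameter: 1.0\n")
        with pytest.raises(ParameterDomainError, match="not_a_parameter"):
            CycleParameters.from_config(str(path))

    def test_validation(self):
        with pytest.raises(ParameterDomainError):
            CycleParameters(sigma_dop=0.7, sigma_dopl=0.5).validate()
        with pytest.raises(ParameterDomainError):
            CycleParameters(Q10P=0.5).validate()
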