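"""Solver physics: Darcy flow, energy, moisture, humidity, coupling."""

import numpy as np
import pytest

from grainfield.boundary_forcing import ForcingScenario
from grainfield.material_models import MaterialParams
from grainfield.pde_core import (ADIABATIC_BOUNDARIES, BoundarySpec,
                                 CoupledSimulator, FieldState, Mesh,
                                 SolverConfig, advance_coupled)

UNIFORM_PROPS = MaterialParams().with_(kb_coeffs=(0.13, 0.0, 0.0),
                                       cb_coeffs=(1.9634, 0.0))


def adiabatic_sim(mesh, params=None, **kw):
    return CoupledSimulator(mesh, params or MaterialParams(),
                            boundaries=ADIABATIC_BOUNDARIES, **kw)


class TestDarcyFlow:
    def test_isothermal_field_is_quiescent(self):
        p = MaterialParams()
        mesh = Mesh(width=4.0, height=2.0, spacing=0.1)
        st = FieldState.uniform(mesh, T=p.T0 - 273.15)
        adiabatic_sim(mesh, p).solve_darcy_flow(st)
        assert np.abs(st.u).max() == 0.0

    def test_single_circulation_cell_sign_pattern(self):
        # warm left half rises, cool right half sinks
        mesh = Mesh(width=4.0, height=2.0, spacing=0.1)
        st = FieldState.uniform(mesh, T=18.0)
        st.T[:, :20] = 25.0
        st.T[:, 20:] = 15.0
        adiabatic_sim(mesh).solve_darcy_flow(st)
        uz = st.u[1]
        assert uz[:, :20].mean() > 0
        assert uz[:, 20:].mean() < 0
        # interior horizontal transport closes the circulation loop
        assert np.abs(st.u[0]).max() > 0

    def test_velocity_linear_in_permeability(self):
        mesh = Mesh(width=4.0, height=2.0, spacing=0.1)
        p = MaterialParams()

        def solve(perm):
            st = FieldState.uniform(mesh, T=18.0)
            st.T[:, :20] = 25.0
            adiabatic_sim(mesh, p.with_(permeability=perm)).solve_darcy_flow(st)
            return st.u

        u1 = solve(p.permeability)
        u2 = solve(2 * p.permeability)
        assert np.allclose(u2, 2 * u1, rtol=1e-10, atol=1e-18)

    def test_divergence_free_to_tolerance(self):
        mesh = Mesh(width=4.0, height=2.0, spacing=0.1)
        rng = np.random.default_rng(0)
        st = FieldState.uniform(mesh, T=18.0)
        st.T += rng.normal(0, 3, st.T.shape)
        sim = adiabatic_sim(mesh)
        sim.solve_darcy_flow(st)  # raises SolverError if div(u) too large
        ux, uz = sim._ux, sim._uz
        div = (ux[:, 1:] - ux[:, :-1] + uz[1:, :] - uz[:-1, :]) / mesh.spacing
        div[0, 0] = 0.0
        assert np.abs(div).max() < 1e-8 * np.abs(st.u).max() / mesh.spacing


class TestEnergy:
    def test_uniform_adiabatic_state_is_stationary(self):
        mesh = Mesh(width=2.0, height=1.0, spacing=0.1)
        st = FieldState.uniform(mesh, T=20.0)
        adiabatic_sim(mesh).step_energy(st, 600.0)
        assert np.abs(st.T - 20.0).max() < 1e-12

    def test_steady_conduction_linear_profile(self):
        # fixed 10 / 20 degC ends, uniform conductivity: T is linear in x
        mesh = Mesh(width=1.0, height=0.1, spacing=0.02)
        b = {"left": BoundarySpec("dirichlet", 10.0),
             "right": BoundarySpec("dirichlet", 20.0),
             "top": BoundarySpec("adiabatic"),
             "bottom": BoundarySpec("adiabatic")}
        sim = CoupledSimulator(mesh, UNIFORM_PROPS, boundaries=b)
        st = FieldState.uniform(mesh, T=15.0)
        for _ in range(80):   # implicit scheme allows huge steps to steady state
            sim.step_energy(st, 1e6)
        exact = 10.0 + 10.0 * mesh.x
        assert np.abs(st.T - exact[None, :]).max() < 0.01

    def test_gaussian_pulse_variance_growth(self):
        # pure conduction spreads a pulse at d(var)/dt = 2 alpha per axis
        p = UNIFORM_PROPS
        mesh = Mesh(width=2.0, height=2.0, spacing=0.02)
        sim = adiabatic_sim(mesh, p)
        X, Z = mesh.meshgrid()
        T0 = 18.0 + 5.0 * np.exp(-((X - 1) ** 2 + (Z - 1) ** 2) / (2 * 0.15**2))
        st = FieldState.from_temperature(mesh, T0, params=p)
        alpha = 0.13 / (p.rho_b * 1.9634e3)

        def variance(T):
            w = T - 18.0
            return float((w * (X - 1) ** 2).sum() / w.sum())

        v0 = variance(st.T)
        dt, n = 2000.0, 50
        for _ in range(n):
            sim.step_energy(st, dt)
        rate = (variance(st.T) - v0) / (n * dt)
        assert rate == pytest.approx(2 * alpha, rel=0.02)

    def test_adiabatic_energy_conservation(self):
        p = MaterialParams()
        mesh = Mesh(width=2.0, height=2.0, spacing=0.1)
        sim = adiabatic_sim(mesh, p)
        rng = np.random.default_rng(1)
        st = FieldState.uniform(mesh, T=20.0)
        st.T += rng.normal(0, 2, st.T.shape)
        C = p.rho_b * (1.465 + 0.0356 * st.M) * 1e3
        E0 = float((C * st.T).sum())
        for _ in range(1000):
            sim.step_energy(st, 600.0)
        E1 = float((C * st.T).sum())
        assert abs(E1 - E0) / abs(E0) < 1e-8

    def test_envelope_warming_raises_boundary_first(self):
        mesh = Mesh(width=4.0, height=2.0, spacing=0.1)
        sim = CoupledSimulator(mesh, MaterialParams(), ForcingScenario())
        st = FieldState.uniform(mesh, T=16.0)
        for _ in range(36):
            sim.step_energy(st, 600.0)  # 6 hours of August morning
        assert st.T[:, 0].mean() > st.T[:, mesh.nx // 2].mean()


class TestMoisture:
    def test_uniform_state_is_stationary(self):
        mesh = Mesh(width=2.0, height=1.0, spacing=0.1)
        st = FieldState.uniform(mesh, T=20.0, Wg=0.16)
        adiabatic_sim(mesh).step_moisture(st, 600.0)
        assert np.abs(st.Wg - 0.16).max() == 0.0

    def test_closed_domain_conservation(self):
        mesh = Mesh(width=2.0, height=1.0, spacing=0.1)
        sim = adiabatic_sim(mesh)
        st = FieldState.uniform(mesh, T=20.0, Wg=0.16)
        X, Z = mesh.meshgrid()
        st.T = 18.0 + 4.0 * np.exp(-((X - 0.6) ** 2 + (Z - 0.5) ** 2) / 0.1)
        st.Wg = st.Wg + 0.01 * np.sin(3 * X)
        sim.solve_darcy_flow(st)
        total0 = st.Wg.sum()
        for _ in range(100):
            sim.step_moisture(st, 600.0)
        assert abs(st.Wg.sum() - total0) / total0 < 1e-10

    def test_thermal_gradient_drives_moisture_to_cold_side(self):
        mesh = Mesh(width=2.0, height=1.0, spacing=0.1)
        sim = adiabatic_sim(mesh)
        st = FieldState.uniform(mesh, T=20.0, Wg=0.16)
        X, _ = mesh.meshgrid()
        st.T = 15.0 + 5.0 * X  # warm right
        for _ in range(200):
            sim.step_moisture(st, 3600.0)
        assert st.Wg[:, 0].mean() > st.Wg[:, -1].mean()
        assert st.M[:, 0].mean() > st.M[:, -1].mean()  # Eq-consistent wet basis

    def test_wet_basis_resynchronized(self):
        mesh = Mesh(width=1.0, height=1.0, spacing=0.1)
        sim = adiabatic_sim(mesh)
        st = FieldState.uniform(mesh, T=18.0, Wg=0.16)
        X, _ = mesh.meshgrid()
        st.T = 14.0 + 8.0 * X
        sim.step_moisture(st, 3600.0)
        assert np.allclose(st.M, 100 * st.Wg / (1 + st.Wg), atol=1e-12)


class TestHumidity:
    def test_uniform_fields_give_uniform_rh(self):
        mesh = Mesh(width=1.0, height=1.0, spacing=0.1)
        st = FieldState.uniform(mesh, T=20.0, Wg=0.16)
        adiabatic_sim(mesh).update_relative_humidity(st)
        assert np.ptp(st.RH) == 0.0
        assert 0 < st.RH[0, 0] < 1

    def test_warmer_node_has_higher_rh_at_fixed_moisture(self):
        from grainfield.material_models import equilibrium_rh
        mesh = Mesh(width=1.0, height=1.0, spacing=0.5)
        st = FieldState.uniform(mesh, T=20.0, Wg=0.16)
        st.T[0, 0] = 25.0
        adiabatic_sim(mesh).update_relative_humidity(st)
        assert st.RH[0, 0] > st.RH[1, 1]
        assert st.RH[0, 0] == pytest.approx(
            float(equilibrium_rh(25.0 + 273.15, 0.16)))


class TestCoupledAdvance:
    def test_zero_forcing_uniform_state_is_constant(self, params):
        mesh = Mesh(width=2.0, height=1.0, spacing=0.1)
        st = FieldState.uniform(mesh, T=params.T0 - 273.15, Wg=0.16)
        snaps = advance_coupled(st, SolverConfig(dt=1800.0), params,
                                ForcingScenario(), mesh,
                                horizon_s=86400.0,
                                boundaries=ADIABATIC_BOUNDARIES)
        assert len(snaps) == 2
        assert np.abs(snaps[-1].T - snaps[0].T).max() < 1e-9
        assert np.abs(snaps[-1].Wg - snaps[0].Wg).max() < 1e-12

    def test_same_config_bitwise_identical(self, params, forcing):
        mesh = Mesh(width=4.0, height=2.0, spacing=0.2)

        def run():
            X, Z = mesh.meshgrid()
            T0 = 17.0 - 2.0 * np.exp(-((X - 2) ** 2 + (Z - 1) ** 2) / 0.5)
            st = FieldState.from_temperature(mesh, T0, 0.1628, params)
            return advance_coupled(st, SolverConfig(dt=600.0), params, forcing,
                                   mesh, horizon_s=86400.0)[-1]

        a, b = run(), run()
        assert np.array_equal(a.T, b.T)
        assert np.array_equal(a.Wg, b.Wg)
        assert np.array_equal(a.u, b.u)

    def test_august_forcing_warms_mean_monotonically(self, params, forcing):
        mesh = Mesh(width=8.0, height=6.0, spacing=0.2)
        X, Z = mesh.meshgrid()
        T0 = 16.8 - 3.0 * np.exp(-((X - 4) ** 2 + (Z - 3) ** 2) / 2.0)
        st = FieldState.from_temperature(mesh, T0, 0.1628, params)
        snaps = advance_coupled(st, SolverConfig(dt=600.0), params, forcing,
                                mesh, horizon_s=5 * 86400.0)
        means = [s.T.mean() for s in snaps]
        assert all(b >= a for a, b in zip(means, means[1:]))

    def test_grid_refinement_convergence(self, params, forcing):
        # halving the production spacing moves the day-7 mean by < 0.1 degC
        from grainfield.sensor_data import ColdCore, TruthField
        truth = TruthField(cores=(ColdCore((2.0, 2.0), 1.1, 3.0),
                                  ColdCore((6.0, 3.0), 1.8, 3.5)))

        def day7_mean(spacing):
            mesh = Mesh(width=8.0, height=6.0, spacing=spacing)
            X, Z = mesh.meshgrid()
            st = FieldState.from_temperature(mesh, truth(X, Z, 0.0), 0.1628,
                                             params)
            snaps = advance_coupled(st, SolverConfig(dt=600.0), params,
                                    forcing, mesh, horizon_s=7 * 86400.0)
            return snaps[-1].T.mean()

        assert abs(day7_mean(0.1) - day7_mean(0.05)) < 0.1

    def test_stage_errors_are_labelled(self, params, forcing):
        mesh = Mesh(width=2.0, height=1.0, spacing=0.1)
        st = FieldState.uniform(mesh, T=18.0)
        st.T[0, 0] = np.nan
        from grainfield.pde_core import SolverError
        sim = CoupledSimulator(mesh, params, forcing)
        with pytest.raises(SolverError, match="stage 'flow'"):
            list(sim.advance(st, horizon_s=600.0))


class TestValidation:
    def test_mesh_guards(self):
        with pytest.raises(ValueError):
            Mesh(spacing=-0.1)
        with pytest.raises(ValueError):
            Mesh(plane="XY")
        with pytest.raises(ValueError):
            Mesh(face_tags={"left": "south"})

    def test_solver_config_guards(self):
        with pytest.raises(ValueError):
            SolverConfig(dt=0.0)
        with pytest.raises(ValueError):
            SolverConfig(flow_tol=-1.0)

    def test_boundary_spec_guards(self):
        with pytest.raises(ValueError):
            BoundarySpec("magic")
        with pytest.raises(ValueError):
            BoundarySpec("dirichlet")
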