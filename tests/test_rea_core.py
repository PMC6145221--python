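import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from readry.exceptions import ConfigurationError, DomainError
from readry.physics import (
    AmbientState,
    R_GAS,
    rho_v_bulk,
    rho_v_sat,
    transfer_coefficients,
)
from readry.rea_core import (
    ActivationEnergyModel,
    GrainGeometry,
    MaterialProps,
    SOYBEAN_COEFFS,
    SampleState,
    SolverConfig,
    energy_balance_rhs,
    equilibrium_activation_energy,
    mass_balance_rhs,
    relative_activation_energy,
    simulate,
    surface_relative_humidity,
)
from readry.schedule import Schedule
from readry.synthetic_data import DRYING_AMBIENT, default_schedule


class TestEquilibriumActivationEnergy:
    def test_saturated_air_is_zero(self):
        amb = AmbientState(T_b=300.0, RH_b=1.0, u=1.0)
        assert equilibrium_activation_energy(amb) == 0.0

    def test_hand_evaluation(self):
        # 8.314 * 308.15 * ln 5
        amb = AmbientState(T_b=308.15, RH_b=0.20, u=3.0)
        expected = 8.314 * 308.15 * math.log(5.0)
        assert equilibrium_activation_energy(amb) == pytest.approx(expected, rel=1e-12)
        assert equilibrium_activation_energy(amb) == pytest.approx(4123.3, abs=0.5)

    @given(st.floats(min_value=0.01, max_value=0.99))
    def test_monotone_in_humidity(self, rh):
        lo = AmbientState(T_b=308.15, RH_b=rh, u=1.0)
        hi = AmbientState(T_b=308.15, RH_b=min(rh + 0.01, 1.0), u=1.0)
        assert equilibrium_activation_energy(lo) > equilibrium_activation_energy(hi)


class TestSurfaceRelativeHumidity:
    def test_zero_barrier_saturates(self):
        assert surface_relative_humidity(0.0, 300.0) == 1.0

    def test_inverts_equilibrium_definition(self):
        amb = AmbientState(T_b=308.15, RH_b=0.20, u=3.0)
        dEvb = equilibrium_activation_energy(amb)
        assert surface_relative_humidity(dEvb, 308.15) == pytest.approx(0.20, rel=1e-12)

    def test_hand_evaluation(self):
        assert surface_relative_humidity(4123.0, 298.15) == pytest.approx(
            math.exp(-4123.0 / (8.314 * 298.15)), rel=1e-12
        )

    def test_negative_barrier_rejected(self):
        with pytest.raises(DomainError):
            surface_relative_humidity(-1.0, 300.0)

    @given(st.floats(min_value=0.0, max_value=5e4), st.floats(min_value=280.0, max_value=400.0))
    def test_bounded(self, dEv, T):
        assert 0.0 < surface_relative_humidity(dEv, T) <= 1.0


class TestRelativeActivationEnergy:
    MODEL = ActivationEnergyModel(coeffs=SOYBEAN_COEFFS, X_b=0.06, x_max=0.19)

    def test_constant_term_at_equilibrium(self):
        assert relative_activation_energy(self.MODEL, 0.06) == pytest.approx(
            0.9958, rel=1e-12
        )

    def test_term_by_term_oracle(self):
        # cubic at x = 0.1, evaluated term by term
        c3, c2, c1, c0 = SOYBEAN_COEFFS
        x = 0.1
        expected = c3 * x**3 + c2 * x**2 + c1 * x + c0
        assert relative_activation_energy(self.MODEL, 0.16) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.74949, abs=1e-5)

    def test_constant_model(self):
        const = ActivationEnergyModel(coeffs=(0.0, 0.0, 0.0, 1.0), X_b=0.0)
        for X in (0.0, 0.1, 2.0):
            assert relative_activation_energy(const, X) == 1.0

    def test_below_equilibrium_rejected(self):
        with pytest.raises(DomainError):
            relative_activation_energy(self.MODEL, 0.05)

    def test_clamped_above_fitted_range(self):
        at_edge = relative_activation_energy(self.MODEL, 0.06 + 0.19)
        assert relative_activation_energy(self.MODEL, 0.5) == at_edge

    def test_non_increasing_over_fitted_range(self):
        xs = np.linspace(0.06, 0.25, 200)
        vals = [relative_activation_energy(self.MODEL, x) for x in xs]
        assert np.all(np.diff(vals) <= 0)


class TestMassBalance:
    def test_zero_driving_force(self, truth_model, material, geometry, drying_ambient):
        # at T = T_b with dE_R = 1 the surface RH equals RH_b exactly, so the
        # vapor-concentration difference vanishes
        const = ActivationEnergyModel(coeffs=(0.0, 0.0, 0.0, 1.0), X_b=material.X_b)
        state = SampleState(X=0.2, T=drying_ambient.T_b)
        dXdt = mass_balance_rhs(state, drying_ambient, const, material, geometry)
        assert dXdt == pytest.approx(0.0, abs=1e-18)

    def test_linearity_in_area(self, truth_model, material, geometry, drying_ambient):
        state = SampleState(X=0.2, T=300.0)
        doubled = GrainGeometry(
            axes0=geometry.axes0,
            n_grains=geometry.n_grains,
            shrink_L=geometry.shrink_L,
            shrink_A=(2 * geometry.shrink_A[0], 2 * geometry.shrink_A[1]),
        )
        d1 = mass_balance_rhs(state, drying_ambient, truth_model, material, geometry)
        d2 = mass_balance_rhs(state, drying_ambient, truth_model, material, doubled)
        assert d2 == pytest.approx(2.0 * d1, rel=1e-12)

    def test_hand_chained_evaluation(self, truth_model, material, geometry, drying_ambient):
        # independent scalar chain: fingerprint -> equilibrium energy ->
        # surface RH -> vapor concentrations -> transfer -> balance
        state = SampleState(X=material.X0, T=material.T0)
        c3, c2, c1, c0 = truth_model.coeffs
        x = state.X - truth_model.X_b
        dER = c3 * x**3 + c2 * x**2 + c1 * x + c0
        dEvb = -R_GAS * drying_ambient.T_b * math.log(drying_ambient.RH_b)
        dEv = dER * dEvb
        RH_s = math.exp(-dEv / (R_GAS * state.T))
        rho_s = RH_s * rho_v_sat(state.T)
        rho_b = drying_ambient.RH_b * rho_v_sat(drying_ambient.T_b)
        L = geometry.shrink_L[0] + geometry.shrink_L[1] * state.X
        A = geometry.shrink_A[0] + geometry.shrink_A[1] * state.X
        tc = transfer_coefficients(
            drying_ambient, L, 0.5 * (state.T + drying_ambient.T_b)
        )
        expected = -(tc.h_m * A / material.m_s) * (rho_s - rho_b)
        got = mass_balance_rhs(state, drying_ambient, truth_model, material, geometry)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_drying_is_negative_initially(
        self, truth_model, material, geometry, drying_ambient
    ):
        state = SampleState(X=material.X0, T=material.T0)
        assert mass_balance_rhs(state, drying_ambient, truth_model, material, geometry) < 0


class TestEnergyBalance:
    def test_thermal_equilibrium(self, material, geometry, drying_ambient):
        state = SampleState(X=0.2, T=drying_ambient.T_b)
        assert (
            energy_balance_rhs(state, drying_ambient, 0.0, material, geometry) == 0.0
        )

    def test_pure_newtonian_heating_positive(self, material, geometry, drying_ambient):
        state = SampleState(X=0.2, T=drying_ambient.T_b - 10.0)
        assert energy_balance_rhs(state, drying_ambient, 0.0, material, geometry) > 0

    def test_evaporation_cools(self, material, geometry, drying_ambient):
        state = SampleState(X=0.2, T=drying_ambient.T_b)
        assert (
            energy_balance_rhs(state, drying_ambient, -1e-5, material, geometry) < 0
        )

    def test_newtonian_closed_form(self):
        # evaporation disabled, constant cp, no shrinkage: Newtonian heating
        amb = DRYING_AMBIENT
        mat = MaterialProps(
            m_s=0.024, X_b=0.06, X0=0.25, T0=298.15,
            cp_fn=lambda X: 2000.0, dHv_fn=lambda T: 0.0,
        )
        geo = GrainGeometry(
            axes0=(7.2e-3, 6.3e-3, 5.4e-3), n_grains=200,
            shrink_L=(6.15e-3, 0.0), shrink_A=(7.1e-4, 0.0),
        )
        const = ActivationEnergyModel(coeffs=(0.0, 0.0, 0.0, 1.0), X_b=0.06)
        curve = simulate(
            default_schedule(7200.0, 0.0, 7200.0), const, mat, geo,
            SolverConfig(output_dt=10.0),
        )
        tc = transfer_coefficients(
            amb, 6.15e-3, 0.5 * (0.5 * (mat.T0 + amb.T_b) + amb.T_b)
        )
        m_cp = mat.m_s * (1.0 + mat.X0) * 2000.0
        closed = amb.T_b - (amb.T_b - mat.T0) * np.exp(
            -tc.h * 7.1e-4 * curve.t / m_cp
        )
        assert np.max(np.abs(curve.T - closed)) < 0.05


class TestSimulate:
    def test_empty_schedule_returns_initial_state(self, truth_model, material, geometry):
        curve = simulate(Schedule(phases=()), truth_model, material, geometry)
        assert len(curve) == 1
        assert curve.X[0] == material.X0
        assert curve.T[0] == material.T0

    def test_x0_below_equilibrium_rejected(self, truth_model, geometry):
        mat = MaterialProps(m_s=0.024, X_b=0.06, X0=0.25, T0=298.15)
        bad = ActivationEnergyModel(coeffs=SOYBEAN_COEFFS, X_b=0.3)
        with pytest.raises(ConfigurationError):
            simulate(default_schedule(600.0, 0.0, 600.0), bad, mat, geometry)

    def test_target_below_equilibrium_rejected(self, truth_model, material, geometry):
        with pytest.raises(ConfigurationError):
            simulate(
                default_schedule(600.0, 0.0, 600.0),
                truth_model, material, geometry,
                SolverConfig(x_target=0.01),
            )

    def test_eq4_identity(self, continuous_curve):
        assert np.allclose(
            continuous_curve.rho_v_s,
            continuous_curve.RH_s * continuous_curve.rho_v_sat,
            rtol=1e-14,
        )

    def test_monotone_drying(self, continuous_curve):
        assert np.all(np.diff(continuous_curve.X) < 0)

    def test_temperature_bounds(self, continuous_curve, material, drying_ambient):
        assert continuous_curve.T.max() <= max(material.T0, drying_ambient.T_b) + 1e-9

    def test_temperature_bounds_intermittent(
        self, intermittent_curve, material, drying_ambient, tempering_ambient
    ):
        cap = max(material.T0, drying_ambient.T_b, tempering_ambient.T_b)
        assert intermittent_curve.T.max() <= cap + 1e-9

    def test_terminal_moisture_near_equilibrium(self, truth_model, material, geometry):
        # the fingerprint reaches dE_R = 1 (clipped) at x = 0, so the long-run
        # moisture settles within 0.005 kg/kg of X_b; bisection on the cubic
        # confirms no root of dE_R(x) = 1 exists for x > 0
        c3, c2, c1, c0 = truth_model.coeffs
        f = lambda x: c3 * x**3 + c2 * x**2 + c1 * x + c0 - 1.0
        assert f(0.0) < 0 and f(0.19) < 0  # no crossing above X_b
        curve = simulate(
            default_schedule(1800.0, 0.0, 150_000.0),
            truth_model, material, geometry,
            SolverConfig(output_dt=600.0),
        )
        assert abs(curve.X[-1] - truth_model.X_b) < 0.005

    def test_rk4_oracle_short_run(self, truth_model, material, geometry, drying_ambient):
        # independent fixed-step RK4 at dt = 0.1 s over 600 s
        curve = simulate(
            default_schedule(600.0, 0.0, 600.0), truth_model, material, geometry,
            SolverConfig(output_dt=60.0),
        )

        def rhs(t, X, T):
            st_ = SampleState(X=X, T=T, t=t)
            dX = mass_balance_rhs(st_, drying_ambient, truth_model, material, geometry)
            dT = energy_balance_rhs(st_, drying_ambient, dX, material, geometry)
            return dX, dT

        dt, X, T = 0.1, material.X0, material.T0
        rec = {0.0: (X, T)}
        for i in range(6000):
            t = i * dt
            k1 = rhs(t, X, T)
            k2 = rhs(t + dt / 2, X + dt / 2 * k1[0], T + dt / 2 * k1[1])
            k3 = rhs(t + dt / 2, X + dt / 2 * k2[0], T + dt / 2 * k2[1])
            k4 = rhs(t + dt, X + dt * k3[0], T + dt * k3[1])
            X += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            T += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            rec[round(t + dt, 6)] = (X, T)
        for t, Xc, Tc in zip(curve.t, curve.X, curve.T):
            Xr, Tr = rec[round(float(t), 6)]
            assert abs(Xc - Xr) < 1e-4
            assert abs(Tc - Tr) < 0.01

    def test_mass_consistency(self, continuous_curve, truth_model, material, geometry,
                              drying_ambient):
        rho_b = rho_v_bulk(drying_ambient)
        h_m = np.array(
            [
                transfer_coefficients(
                    drying_ambient, geometry.length(x), 0.5 * (T + drying_ambient.T_b)
                ).h_m
                for x, T in zip(continuous_curve.X, continuous_curve.T)
            ]
        )
        A = np.array([geometry.area(x) for x in continuous_curve.X])
        evaporated = np.trapezoid(
            h_m * A * (continuous_curve.rho_v_s - rho_b), continuous_curve.t
        )
        lost = material.m_s * (continuous_curve.X[0] - continuous_curve.X[-1])
        assert evaporated == pytest.approx(lost, rel=0.005)

    def test_tempering_rh_rise(self, intermittent_curve):
        # surface RH at the end of each tempering phase exceeds the value at
        # the end of the preceding drying phase
        curve = intermittent_curve
        for i, (kind, _, _) in enumerate(curve.phase_spans):
            if kind != "tempering" or i == 0:
                continue
            prev = curve.RH_s[curve.phase_index == i - 1]
            this = curve.RH_s[curve.phase_index == i]
            if prev.size and this.size:
                assert this[-1] > prev[-1]

    def test_boundary_samples_belong_to_ending_phase(self, intermittent_curve):
        spans = intermittent_curve.phase_spans
        for i, (kind, t0, t1) in enumerate(spans[:-1]):
            idx = intermittent_curve.phase_index == i
            assert intermittent_curve.t[idx][-1] == pytest.approx(t1)

    def test_expanded_energy_close_to_simplified(self, truth_model, material, geometry):
        simple = simulate(
            default_schedule(3600.0, 0.0, 3600.0), truth_model, material, geometry,
            SolverConfig(output_dt=300.0),
        )
        expanded = simulate(
            default_schedule(3600.0, 0.0, 3600.0), truth_model, material, geometry,
            SolverConfig(output_dt=300.0, expanded_energy=True),
        )
        # the retained T d(mCp)/dt term shifts the evaporative plateau by a
        # few kelvin with these parameters; both stay physically bounded
        diff = np.abs(simple.T - expanded.T)
        assert 0.0 < np.max(diff) < 5.0
        cap = max(298.15, DRYING_AMBIENT.T_b)
        assert expanded.T.max() <= cap + 1e-9
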