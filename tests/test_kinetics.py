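"""Photokinetic ODE system: right-hand side, adaptive integration, dose maps.

The independent reference for the adaptive RK5(4) integrator is a fixed-step
classical RK4 at dt = 1e-3 s, written here against the equations directly
(not sharing any solver code with the package).
"""

import numba as nb
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photodose import (
    BPD_PARAMS,
    EnergyBalance,
    FluenceRateMap,
    PKParams,
    PKState,
    SourceSpec,
    VoxelGrid,
    dose_at_depth,
    dose_map,
    dose_profile,
    integrate_pk,
    pk_rhs,
)
from photodose.exceptions import (
    InvalidParameterError,
    InvalidStateError,
)
from photodose.kinetics import DoseMap


@nb.njit(cache=True)
def _rk4_reference(phi, s0, o2, T, dt, g, delta, beta, sigma, xi, o2i):
    """Fixed-step classical RK4 oracle for the three kinetic equations."""
    y = np.array([s0, o2, 0.0])

    def f(y):
        frac = y[1] / (y[1] + beta)
        ex = xi * phi * y[0] * frac
        return np.array(
            [
                -sigma * xi * phi * (y[0] + delta) * frac * y[0],
                -ex + g * (1.0 - y[1] / o2i),
                ex,
            ]
        )

    n = int(np.ceil(T / dt))
    for i in range(n):
        h = min(dt, T - i * dt)
        k1 = f(y)
        k2 = f(y + 0.5 * h * k1)
        k3 = f(y + 0.5 * h * k2)
        k4 = f(y + h * k3)
        y = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    return y


def rk4_reference(phi, s0, T, params=BPD_PARAMS, dt=1e-3):
    return _rk4_reference(
        phi,
        s0,
        params.O2_initial,
        T,
        dt,
        params.g_supply,
        params.delta,
        params.beta,
        params.sigma,
        params.xi,
        params.O2_initial,
    )


class TestRHS:
    def test_dark_steady_state(self):
        d = pk_rhs(PKState(S0=0.53, O2=40.0), phi=0.0)
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_no_sensitizer_pure_resupply(self):
        """S0 = 0: no photochemistry, oxygen resupplies at g (1 - O2/O2_0)."""
        d = pk_rhs(PKState(S0=0.0, O2=20.0), phi=100.0)
        assert d[0] == 0.0 and d[2] == 0.0
        assert d[1] == pytest.approx(1.7 * (1.0 - 20.0 / 40.0))

    def test_singlet_oxygen_production_rate_arithmetic(self):
        """xi*phi*S0*O2/(O2+beta) at the peak-fluence surface state."""
        d = pk_rhs(PKState(S0=0.53, O2=40.0), phi=168.0)
        assert d[2] == pytest.approx(0.055 * 168.0 * 0.53 * (40.0 / 51.9), rel=1e-12)

    def test_negative_state_rejected(self):
        bad = PKState(S0=0.5, O2=40.0)
        bad.S0 = -0.1  # mutate past the constructor check
        with pytest.raises(InvalidStateError):
            pk_rhs(bad, phi=10.0)
        with pytest.raises(InvalidStateError):
            pk_rhs(PKState(S0=0.5, O2=40.0), phi=-1.0)


class TestIntegratePK:
    def test_dark_fixed_point(self):
        st_ = integrate_pk(0.0, 0.53, T=600.0)
        assert st_.O2rx == 0.0
        assert st_.S0 == pytest.approx(0.53, rel=1e-12)
        assert st_.O2 == pytest.approx(40.0, rel=1e-9)

    @pytest.mark.parametrize(
        "phi,s0,T",
        [
            (168.0, 0.53, 600.0),
            (50.0, 0.84, 2000.0),
            (420.0, 0.81, 2333.0),
            (5.0, 0.41, 1333.0),
        ],
    )
    def test_matches_fixed_step_rk4_oracle(self, phi, s0, T):
        """Adaptive RK5(4) final O2rx within 0.1% of the dt=1e-3 RK4 oracle
        across the treatment-group parameter ranges."""
        ref = rk4_reference(phi, s0, T)
        got = integrate_pk(phi, s0, T=T)
        assert got.O2rx == pytest.approx(ref[2], rel=1e-3)
        assert got.S0 == pytest.approx(ref[0], rel=1e-3, abs=1e-9)
        assert got.O2 == pytest.approx(ref[1], rel=1e-3)

    def test_matches_scipy_stiff_solver(self):
        """Cross-check against an independent library integrator (LSODA)."""
        from scipy.integrate import solve_ivp

        p = BPD_PARAMS

        def f(t, y):
            frac = y[1] / (y[1] + p.beta)
            ex = p.xi * 168.0 * y[0] * frac
            return [
                -p.sigma * p.xi * 168.0 * (y[0] + p.delta) * frac * y[0],
                -ex + p.g_supply * (1.0 - y[1] / p.O2_initial),
                ex,
            ]

        sol = solve_ivp(
            f, [0, 600], [0.53, 40.0, 0.0], method="LSODA", rtol=1e-10, atol=1e-12
        )
        got = integrate_pk(168.0, 0.53, T=600.0)
        assert got.O2rx == pytest.approx(sol.y[2, -1], rel=1e-3)

    def test_trajectory_output_consistent_with_final_state(self):
        """t_eval checkpoints chain to the same final state, and show the
        oxygen transient: rapid depletion then resupply as S0 bleaches."""
        st_, traj = integrate_pk(168.0, 0.53, T=600.0, t_eval=[0.0, 60.0, 600.0])
        single = integrate_pk(168.0, 0.53, T=600.0)
        assert st_.O2rx == pytest.approx(single.O2rx, rel=1e-6)
        assert traj.shape == (3, 4)
        assert traj[1, 2] < 15.0 < traj[2, 2] < 40.0  # O2 dip then recovery
        assert np.all(np.diff(traj[:, 3]) >= 0)

    def test_monotone_trajectories(self):
        """S0 non-increasing, O2rx non-decreasing, O2 <= O2(0) along time."""
        times = np.linspace(0.0, 600.0, 25)
        states = [integrate_pk(168.0, 0.53, T=t) for t in times]
        s0 = np.array([s.S0 for s in states])
        o2rx = np.array([s.O2rx for s in states])
        o2 = np.array([s.O2 for s in states])
        assert np.all(np.diff(s0) <= 1e-9)
        assert np.all(np.diff(o2rx) >= -1e-9)
        assert np.all(o2 <= 40.0 + 1e-6)

    def test_conservation_identity_along_trajectory(self):
        """dO2rx/dt equals -(dO2/dt - g(1 - O2/O2_0)) at sampled states:
        every consumed oxygen molecule beyond resupply becomes reacted dose."""
        for t in (10.0, 120.0, 599.0):
            s = integrate_pk(168.0, 0.53, T=t)
            d = pk_rhs(s, phi=168.0)
            resupply = BPD_PARAMS.g_supply * (1.0 - s.O2 / BPD_PARAMS.O2_initial)
            assert d[2] == pytest.approx(-(d[1] - resupply), rel=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        phi=st.floats(0.0, 500.0),
        s0=st.floats(0.0, 2.0),
        logT=st.floats(0.0, 3.5),
        g=st.floats(0.5, 5.0),
        beta=st.floats(1.0, 50.0),
    )
    def test_nonnegativity_under_random_stress(self, phi, s0, logT, g, beta):
        """Every final component >= 0 for randomized (phi, S0, params, T)."""
        params = PKParams(g_supply=g, beta=beta)
        st_ = integrate_pk(phi, s0, params=params, T=10.0**logT)
        assert st_.S0 >= 0 and st_.O2 >= 0 and st_.O2rx >= 0

    def test_invalid_inputs(self):
        with pytest.raises(InvalidParameterError):
            integrate_pk(100.0, 0.5, T=-1.0)
        with pytest.raises(InvalidStateError):
            integrate_pk(-1.0, 0.5, T=10.0)


def _uniform_map(value, n=8, h=0.05, rate=50.0):
    grid = VoxelGrid.homogeneous(n, h)
    return FluenceRateMap(
        values=np.full(grid.shape, float(value)),
        grid=grid,
        source=SourceSpec(1.0, rate),
        n_photons=1,
        energy_balance=EnergyBalance(0, 0, 0, 1),
    )


class TestDoseMap:
    def test_zero_fluence_gives_zero_dose(self):
        dm = dose_map(_uniform_map(0.0), S0_init=0.53, T=600.0)
        assert np.all(dm.values == 0.0)

    def test_dose_monotone_in_treatment_time(self):
        m = _uniform_map(100.0)
        d1 = dose_map(m, 0.53, T=300.0)
        d2 = dose_map(m, 0.53, T=600.0)
        assert np.all(d2.values >= d1.values)

    def test_voxel_independence_chunked_equals_whole(self):
        """Splitting the voxel set and integrating separately reproduces the
        whole-map result bit for bit (embarrassingly parallel contract)."""
        rng = np.random.default_rng(3)
        m = _uniform_map(0.0, n=6)
        m.values[:] = rng.uniform(0.0, 200.0, m.values.shape)
        whole = dose_map(m, 0.53, T=200.0)
        half = m.values.copy()
        half[3:] = 0.0
        other = m.values - half
        m.values[:] = half
        d_a = dose_map(m, 0.53, T=200.0)
        m.values[:] = other
        d_b = dose_map(m, 0.53, T=200.0)
        merged = np.where(d_a.values > 0, d_a.values, d_b.values)
        np.testing.assert_array_equal(merged, whole.values)

    def test_per_voxel_sensitizer_field(self):
        m = _uniform_map(100.0, n=4)
        s0 = np.full(m.grid.shape, 0.53)
        s0[0, 0, 0] = 0.0
        dm = dose_map(m, s0, T=100.0)
        assert dm.values[0, 0, 0] == 0.0
        assert dm.values[1, 1, 1] > 0

    def test_profile_agrees_with_full_map(self, mc_map_05):
        dm = dose_map(mc_map_05, 0.53, T=600.0)
        prof = dose_profile(mc_map_05, 0.53, T=600.0)
        assert dose_at_depth(prof, 0.3, mc_map_05.grid) == pytest.approx(
            dose_at_depth(dm, 0.3), rel=1e-12
        )


class TestDoseAtDepth:
    def test_uniform_map_returns_constant(self):
        grid = VoxelGrid.homogeneous(10, 0.05)
        dm = DoseMap(
            values=np.full(grid.shape, 0.7),
            grid=grid,
            treatment_time=600.0,
            params=BPD_PARAMS,
        )
        for depth in (0.05, 0.3, 0.45):
            assert dose_at_depth(dm, depth) == pytest.approx(0.7)

    def test_layer_averaging_rule(self):
        """The 3-mm value is the mean of layers 6 and 7 on a 0.5-mm grid."""
        grid = VoxelGrid.homogeneous(10, 0.05)
        values = np.zeros(grid.shape)
        values[:, :, 5] = 1.0  # 6th layer
        values[:, :, 6] = 3.0  # 7th layer
        dm = DoseMap(values, grid, 600.0, BPD_PARAMS)
        assert dose_at_depth(dm, 0.3) == pytest.approx(2.0)

    def test_depth_outside_grid_rejected(self):
        grid = VoxelGrid.homogeneous(4, 0.05)
        dm = DoseMap(np.zeros(grid.shape), grid, 600.0, BPD_PARAMS)
        with pytest.raises(InvalidParameterError):
            dose_at_depth(dm, 0.5)
        with pytest.raises(InvalidParameterError):
            dose_at_depth(dm, 0.07)  # not a layer boundary
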