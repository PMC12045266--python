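"""Pore-density kinetics, conductance factor, and membrane conductivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp

from porefem.pore_model import (
    PoreModelParams,
    MembraneProperties,
    pore_rate,
    equilibrium_density,
    advance_pore_density,
    pore_conductance_factor,
    membrane_conductivity,
    sigma_p_from_bulk,
)

P = PoreModelParams()
PLASMA = MembraneProperties(sigma_m0=1.1e-7, eps_r=5.0, d=0.01e-6)


class TestPoreRate:
    def test_rest_equilibrium_rate_is_zero(self):
        assert pore_rate(0.0, P.N0, P) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "Vm, N, expected, rtol",
        [
            (0.258, 0.0, 1e9 * np.e, 1e-9),  # alpha*e at the characteristic voltage
            (1.05, 1.5e9, 1.56e16, 5e-3),  # suprathreshold creation burst
        ],
    )
    def test_known_rates(self, Vm, N, expected, rtol):
        assert pore_rate(Vm, N, P) == pytest.approx(expected, rel=rtol)

    def test_rate_vanishes_at_equilibrium_density_any_voltage(self):
        for Vm in (0.0, 0.3, 0.7, 1.2):
            n_eq = equilibrium_density(Vm, P)
            assert abs(pore_rate(Vm, n_eq, P)) < 1e-6 * P.alpha


class TestEquilibriumDensity:
    def test_rest_value_is_N0(self):
        assert equilibrium_density(0.0, P) == P.N0

    def test_characteristic_voltage_value(self):
        assert equilibrium_density(0.258, P) == pytest.approx(1.5e9 * np.exp(2.46), rel=1e-12)


class TestAdvancePoreDensity:
    def test_equilibrium_is_preserved(self):
        for dt in (1e-9, 1e-6, 1e-3):
            assert advance_pore_density(P.N0, 0.0, dt, P) == pytest.approx(P.N0, rel=1e-12)

    def test_linear_growth_regime_value(self):
        # at 1.05 V the decay constant b ~ 2e-11/s is negligible over 100 us,
        # so N grows linearly at the creation rate
        N = advance_pore_density(P.N0, 1.05, 100e-6, P)
        assert N == pytest.approx(1.56e12, rel=5e-3)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        Vm=st.floats(0.0, 1.4),
        dt=st.floats(1e-9, 1e-4),
        k=st.integers(2, 7),
    )
    def test_substep_splitting_invariance(self, Vm, dt, k):
        """Exact integrator: one step of dt equals k steps of dt/k."""
        one = advance_pore_density(P.N0, Vm, dt, P)
        many = P.N0
        for _ in range(k):
            many = advance_pore_density(many, Vm, dt / k, P)
        assert many == pytest.approx(one, rel=1e-12)

    def test_monotone_convergence_to_equilibrium(self):
        # at 0.1 V the decay constant b ~ 0.54/s, so ~30 s suffices to relax
        Vm = 0.1
        n_eq = equilibrium_density(Vm, P)
        N, prev = P.N0, P.N0
        for _ in range(300):
            N = advance_pore_density(N, Vm, 0.1, P)
            assert N >= prev - 1e-6
            prev = N
        assert N == pytest.approx(n_eq, rel=1e-6)

    def test_matches_adaptive_stiff_ode_reference(self):
        """Piecewise-frozen-Vm trace: chained exact updates vs solve_ivp."""
        rng = np.random.default_rng(7)
        times = np.linspace(0.0, 50e-6, 26)
        Vm_trace = 1.0 + 0.08 * rng.standard_normal(len(times) - 1)

        N_exact = P.N0
        for Vm, t0, t1 in zip(Vm_trace, times[:-1], times[1:]):
            N_exact = advance_pore_density(N_exact, Vm, t1 - t0, P)

        def rhs(t, y):
            i = min(np.searchsorted(times, t, side="right") - 1, len(Vm_trace) - 1)
            return [pore_rate(Vm_trace[i], y[0], P)]

        ref = solve_ivp(
            rhs, (0.0, times[-1]), [P.N0], method="LSODA",
            rtol=1e-10, atol=1.0, max_step=times[1] - times[0],
        )
        assert N_exact == pytest.approx(ref.y[0, -1], rel=1e-6)


class TestPoreConductanceFactor:
    def test_zero_voltage_limit(self):
        assert pore_conductance_factor(0.0, P) == pytest.approx(np.exp(-P.w0), rel=1e-9)

    def test_one_volt_value(self):
        assert pore_conductance_factor(1.0, P) == pytest.approx(0.56, rel=2e-2)

    def test_even_in_Vm(self):
        for Vm in (0.1, 0.449, 1.0, 2.5):
            assert pore_conductance_factor(-Vm, P) == pytest.approx(
                pore_conductance_factor(Vm, P), rel=1e-12
            )

    def test_continuous_at_removable_singularity(self):
        # n*vm = w0 at Vm = (w0/n_rel)*R*T/F ~ 0.449 V
        v_star = (P.w0 / P.n_rel) * P.R_gas * P.T / P.F
        k_lo = pore_conductance_factor(v_star * (1 - 1e-4), P)
        k_at = pore_conductance_factor(v_star, P)
        k_hi = pore_conductance_factor(v_star * (1 + 1e-4), P)
        assert k_lo < k_at < k_hi
        assert k_hi - k_lo < 1e-3

    def test_monotone_and_bounded(self):
        vs = np.linspace(0.0, 3.0, 1201)
        K = pore_conductance_factor(vs, P)
        assert np.all(np.diff(K) >= -1e-12)
        assert np.all((K > 0) & (K <= 1.0))
        assert pore_conductance_factor(50.0, P) > 0.99  # K -> 1 at large Vm


class TestMembraneConductivity:
    def test_no_pores_gives_resting_conductivity(self):
        assert membrane_conductivity(0.0, 0.0, P, PLASMA) == pytest.approx(1.1e-7)

    def test_electroporated_value_at_threshold_density(self):
        sigma = membrane_conductivity(1e14, 1.0, P, PLASMA)
        assert sigma == pytest.approx(1.32e-4, rel=2e-2)

    def test_strictly_increasing_in_N(self):
        Ns = np.logspace(9, 15, 20)
        sig = membrane_conductivity(Ns, 0.8, P, PLASMA)
        assert np.all(np.diff(sig) > 0)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            membrane_conductivity(-1.0, 0.5, P, PLASMA)


class TestSigmaP:
    def test_equal_bulk_conductivities(self):
        assert sigma_p_from_bulk(0.55, 0.55) == pytest.approx(0.55)

    def test_harmonic_mean_value(self):
        assert sigma_p_from_bulk(0.55, 1.1) == pytest.approx(0.7333, rel=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.floats(1e-3, 10), b=st.floats(1e-3, 10))
    def test_bounded_by_max(self, a, b):
        assert sigma_p_from_bulk(a, b) <= max(a, b) + 1e-12

    def test_params_switch_uses_harmonic_mean(self):
        p2 = P.with_sigma_p_from_bulk(0.55, 0.55)
        assert p2.sigma_p == pytest.approx(0.55)
        assert P.sigma_p == 1.3  # tabulated default untouched


def test_membrane_derived_quantities():
    """Sheet capacitance and resting surface conductance from thickness."""
    assert PLASMA.Cm == pytest.approx(4.43e-3, rel=1e-2)
    assert PLASMA.g0 == pytest.approx(11.0, rel=1e-6)
    nucleus = MembraneProperties(sigma_m0=1.1e-5, eps_r=5.0, d=0.04e-6)
    assert nucleus.g0 == pytest.approx(275.0, rel=1e-6)
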