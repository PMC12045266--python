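"""FEM field solver: pulse shapes, analytic oracles, interface physics."""

import numpy as np
import pytest

from porefem.field_solver import (
    PulseSpec,
    TransientFieldSolver,
    electrode_voltage,
    extract_tmp,
    pulse_value,
)
from porefem.geometry import make_disc_cell_geometry
from porefem.meshing import build_interface_chains, triangulate_with_interfaces

from conftest import cosine_fit_r2

PULSE = PulseSpec(E_app_kV_cm=1.2)


class TestPulse:
    @pytest.mark.parametrize(
        "t_us, expected",
        [(-1, 0.0), (5, 0.5), (10, 1.0), (50, 1.0), (100, 1.0), (105, 0.5), (110, 0.0), (115, 0.0)],
    )
    def test_trapezoid_waypoints(self, t_us, expected):
        assert pulse_value(t_us * 1e-6, PULSE) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "E, expected_V", [(1.2, 12.0), (0.0, 0.0), (3.5, 35.0)]
    )
    def test_electrode_voltage_conversion(self, E, expected_V):
        assert electrode_voltage(PulseSpec(E_app_kV_cm=E)) == pytest.approx(expected_V)

    def test_invalid_pulse_rejected(self):
        with pytest.raises(ValueError):
            PulseSpec(E_app_kV_cm=1.0, width_s=5e-6, rise_s=10e-6)


@pytest.fixture(scope="module")
def schwan_setup():
    """Disc cell R = 5 um with resting membranes, 1e5 V/m applied."""
    g = make_disc_cell_geometry(5.0, 2.0, 0)
    mesh = triangulate_with_interfaces(g, h_bulk=2.0, h_membrane=0.2)
    solver = TransientFieldSolver(mesh)
    chains = build_interface_chains(mesh)
    plasma = [c for c in chains if c.label == "plasma"][0]
    return solver, plasma


class TestHomogeneousBox:
    def test_uniform_field_from_laplace_solution(self):
        mesh = triangulate_with_interfaces(None, h_bulk=2.0, h_membrane=2.0, box=(100.0, 70.0))
        solver = TransientFieldSolver(mesh)
        sol = solver.solve_stationary(12.0, g=np.empty(0))
        # phi must be linear in x: E = U/Lx = 1.2e5 V/m everywhere
        expected = 12.0 * (1.0 - mesh.points[:, 0] / 100.0)
        np.testing.assert_allclose(sol.phi[: mesh.n_nodes], expected, atol=12.0 * 1e-3)

    def test_zero_voltage_gives_zero_potential(self, schwan_setup):
        solver, plasma = schwan_setup
        sol = solver.solve_stationary(0.0)
        assert np.max(np.abs(sol.phi)) < 1e-12
        assert np.max(np.abs(extract_tmp(sol, plasma))) < 1e-12


class TestSchwanValidation:
    def test_pole_tmp_within_two_percent_of_2ER(self, schwan_setup):
        solver, plasma = schwan_setup
        sol = solver.solve_stationary(10.0)  # 1e5 V/m across 100 um
        Vm = extract_tmp(sol, plasma)
        assert np.max(np.abs(Vm)) == pytest.approx(2.0 * 1e5 * 5e-6, rel=2e-2)

    def test_profile_is_cosine(self, schwan_setup):
        solver, plasma = schwan_setup
        sol = solver.solve_stationary(10.0)
        Vm = extract_tmp(sol, plasma)
        amp, r2 = cosine_fit_r2(plasma.s, plasma.total_length, Vm)
        assert r2 >= 0.99
        assert amp == pytest.approx(1.0, rel=3e-2)

    def test_antisymmetry_about_field_axis(self, schwan_setup):
        solver, plasma = schwan_setup
        sol = solver.solve_stationary(10.0)
        Vm = extract_tmp(sol, plasma)
        # mirror the chain (s -> L - s) and compare: Vm is even under the
        # mirror, i.e. symmetric about the two field-aligned poles
        Vm_mirror = np.interp(
            plasma.total_length - plasma.s, plasma.s, Vm, period=plasma.total_length
        )
        assert np.max(np.abs(Vm - Vm_mirror)) < 0.05 * np.max(np.abs(Vm))

    def test_short_circuit_limit(self, schwan_setup):
        solver, plasma = schwan_setup
        g = np.full(solver.n_interface, 1e9)  # membrane shorted
        sol = solver.solve_stationary(10.0, g=g)
        assert np.max(np.abs(extract_tmp(sol, plasma))) < 1e-3

    def test_current_conservation(self, schwan_setup):
        solver, plasma = schwan_setup
        Vm0, N0 = solver.resting_state()
        g = solver.surface_conductance(N0, Vm0)
        sol = solver.solve_stationary(10.0, g=g)
        I_left, I_right = solver.electrode_currents(sol.phi, g)
        assert abs(I_left + I_right) <= 5e-3 * abs(I_left)


class TestMembraneCharging:
    def test_charging_time_constant(self, schwan_setup):
        """Pole Vm charges exponentially with tau = R*Cm*(1/sigma_i + 1/sigma_e)
        (the cylinder analogue of the spherical charging time)."""
        solver, plasma = schwan_setup
        Cm = solver.membranes["plasma"].Cm
        tau_analytic = 5e-6 * Cm * (1 / 0.55 + 1 / 0.55)
        Vm, N = solver.resting_state()
        phi = None
        dt = 4e-9
        trace = []  # pole node is the chain start (rightmost point)
        for _ in range(100):
            sol, Vm, N, _ = solver.step_potential(Vm, N, phi, 10.0, dt)
            phi = sol.phi
            trace.append(abs(extract_tmp(sol, plasma)[0]))
        trace = np.asarray(trace)
        v_inf = trace[-1]
        t = dt * np.arange(1, len(trace) + 1)
        # fit tau from the log-linear charging curve (skip the tail noise)
        m = trace < 0.95 * v_inf
        slope, _ = np.polyfit(t[m], np.log(1.0 - trace[m] / v_inf), 1)
        tau_fit = -1.0 / slope
        assert tau_fit == pytest.approx(tau_analytic, rel=0.2)

    def test_null_forcing_stays_at_rest(self, schwan_setup):
        solver, plasma = schwan_setup
        Vm, N = solver.resting_state()
        sol, Vm, N, n_it = solver.step_potential(Vm, N, None, 0.0, 1e-6)
        assert np.max(np.abs(Vm)) < 1e-12
        assert np.allclose(N, solver.pore.N0)


def test_mesh_convergence_of_pole_tmp():
    """Halving h changes the steady pole TMP by < 1%."""
    g = make_disc_cell_geometry(5.0, 2.0, 0)
    poles = []
    for hm, hb in [(0.3, 3.0), (0.15, 1.5)]:
        mesh = triangulate_with_interfaces(g, h_bulk=hb, h_membrane=hm)
        solver = TransientFieldSolver(mesh)
        sol = solver.solve_stationary(10.0)
        plasma = [c for c in build_interface_chains(mesh) if c.label == "plasma"][0]
        poles.append(np.max(np.abs(extract_tmp(sol, plasma))))
    assert abs(poles[1] - poles[0]) / poles[1] < 1e-2
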