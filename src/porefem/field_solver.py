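"""Transient quasi-static electric-field FEM with membrane interface conditions.

Solves the charge-conservation form of the quasi-static field problem

    div( sigma grad(phi) + eps0 eps_r d/dt grad(phi) ) = 0

on the triangulated bath/cell domain with P1 elements, Dirichlet electrodes
(phi = U(t) on the left box edge, phi = 0 on the right), insulating top and
bottom edges, and every membrane as a distributed-impedance internal
interface: interface nodes carry two potential DOFs (outer/inner side) and
the normal current density through the membrane satisfies

    J.n = Cm dVm/dt + g(N, Vm) Vm,      Vm = phi_outer - phi_inner,

with Cm = eps0 eps_r/d the specific capacitance and g = sigma_m(N, Vm)/d
the electroporation-dependent surface conductance. Time discretization is
backward Euler; the bulk displacement-current term is optional (negligible
for 100 us pulses where the bulk Maxwell-Wagner time ~1 ns, required for
the 100 ns pulse variant).

All solver-internal quantities are SI (meters, volts, seconds); the mesh
arrives in micrometres and is converted on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .meshing import TriMesh, InterfaceNodeChain, REGION_NAMES
from .pore_model import (
    EPS0,
    PoreModelParams,
    MembraneProperties,
    DEFAULT_MEMBRANES,
    membrane_conductivity,
    advance_pore_density,
)

__all__ = [
    "BulkProperties",
    "PulseSpec",
    "FieldSolution",
    "pulse_value",
    "electrode_voltage",
    "TransientFieldSolver",
    "extract_tmp",
]


@dataclass(frozen=True)
class BulkProperties:
    """Per-region bulk conductivity (S/m) and relative permittivity.

    Defaults: all aqueous compartments (bath, cytoplasm, nucleoplasm, ER
    matrix) at 0.55 S/m and eps_r = 67.
    """

    sigma: dict[str, float] = field(
        default_factory=lambda: {name: 0.55 for name in REGION_NAMES}
    )
    eps_r: dict[str, float] = field(
        default_factory=lambda: {name: 67.0 for name in REGION_NAMES}
    )

    def __post_init__(self) -> None:
        for name in REGION_NAMES:
            if self.sigma.get(name, 0.0) <= 0:
                raise ValueError(f"bulk conductivity of {name} must be positive")


@dataclass(frozen=True)
class PulseSpec:
    """Trapezoidal pulse: applied-field amplitude and timing.

    ``width_s`` is measured from pulse start to the start of the falling
    edge, i.e. the plateau ends at ``width_s`` and the field is zero from
    ``width_s + fall_s`` on. The electrode voltage is
    U(t) = waveform(t) * E_app * gap.
    """

    E_app_kV_cm: float
    width_s: float = 100e-6
    rise_s: float = 10e-6
    fall_s: float = 10e-6
    gap_m: float = 100e-6  # electrode spacing = box width

    def __post_init__(self) -> None:
        if min(self.width_s, self.rise_s, self.fall_s) < 0 or self.gap_m <= 0:
            raise ValueError("pulse times must be nonnegative and gap positive")
        if self.width_s < self.rise_s:
            raise ValueError("pulse width must cover the rising edge")

    @property
    def E_app_V_m(self) -> float:
        return self.E_app_kV_cm * 1e5

    @property
    def t_end(self) -> float:
        return self.width_s + self.fall_s


def pulse_value(t: float, spec: PulseSpec) -> float:
    """Normalized trapezoid amplitude in [0, 1] at time t (s)."""
    if t < 0 or t >= spec.width_s + spec.fall_s:
        return 0.0
    if t < spec.rise_s:
        return t / spec.rise_s if spec.rise_s > 0 else 1.0
    if t <= spec.width_s:
        return 1.0
    return 1.0 - (t - spec.width_s) / spec.fall_s if spec.fall_s > 0 else 0.0


def electrode_voltage(spec: PulseSpec) -> float:
    """Peak electrode voltage U_max = E_app * gap (V)."""
    return spec.E_app_V_m * spec.gap_m


@dataclass
class FieldSolution:
    """Nodal potential at one time, with duplicated interface DOFs.

    ``phi`` has one entry per DOF: the first ``n_nodes`` entries are the
    base (outer-side) nodal values, the rest are inner-side copies of the
    interface nodes, indexed through ``inner_dof``.
    """

    phi: np.ndarray
    time: float
    n_nodes: int
    inner_dof: np.ndarray  # (n_nodes,), -1 for non-interface nodes

    def vm_at(self, nodes: np.ndarray) -> np.ndarray:
        """Transmembrane potential phi_outer - phi_inner at interface nodes."""
        inner = self.inner_dof[nodes]
        if np.any(inner < 0):
            raise ValueError("vm_at called on non-interface nodes")
        return self.phi[nodes] - self.phi[inner]


def extract_tmp(solution: FieldSolution, chain: InterfaceNodeChain) -> np.ndarray:
    """Vm(s) ordered along one membrane chain (outer minus inner side)."""
    return solution.vm_at(chain.node_indices)


class TransientFieldSolver:
    """Assembles and advances the coupled field / membrane-state problem.

    Parameters
    ----------
    mesh : TriMesh
        Conforming interface mesh (coordinates in um).
    bulk : BulkProperties
        Per-region conductivity and permittivity.
    membranes : dict[str, MembraneProperties]
        Sheet properties per membrane label.
    pore_params : PoreModelParams
        Pore-kinetics parameters (shared by all membranes).
    use_displacement : bool
        Include the bulk displacement-current term (needed for ns pulses).
    """

    def __init__(
        self,
        mesh: TriMesh,
        bulk: BulkProperties | None = None,
        membranes: dict[str, MembraneProperties] | None = None,
        pore_params: PoreModelParams | None = None,
        use_displacement: bool = False,
    ):
        self.mesh = mesh
        self.bulk = bulk or BulkProperties()
        self.membranes = membranes or dict(DEFAULT_MEMBRANES)
        self.pore = pore_params or PoreModelParams()
        self.use_displacement = use_displacement

        pts = mesh.points * 1e-6  # um -> m
        self.points_m = pts
        n_nodes = mesh.n_nodes

        # --- duplicated DOFs on interface nodes --------------------------
        if_nodes = mesh.interface_nodes()
        self.if_nodes = if_nodes
        self.inner_dof = -np.ones(n_nodes, dtype=int)
        self.inner_dof[if_nodes] = n_nodes + np.arange(len(if_nodes))
        self.n_dofs = n_nodes + len(if_nodes)
        self.n_nodes = n_nodes

        tri_dofs = mesh.triangles.copy()
        for loop in range(len(mesh.loop_labels)):
            loop_nodes = np.unique(mesh.interface_edges[mesh.edge_loop == loop])
            node_on_loop = np.zeros(n_nodes, dtype=bool)
            node_on_loop[loop_nodes] = True
            inside_tris = mesh.tri_inside_loop[loop]
            corner_mask = node_on_loop[mesh.triangles] & inside_tris[:, None]
            tri_dofs[corner_mask] = self.inner_dof[mesh.triangles[corner_mask]]
        self.tri_dofs = tri_dofs

        # --- P1 stiffness entries (unit coefficient), per triangle -------
        p = pts[mesh.triangles]
        x, y = p[..., 0], p[..., 1]
        # gradients of barycentric shape functions
        b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
        c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
        area2 = x[:, 0] * b[:, 0] + x[:, 1] * b[:, 1] + x[:, 2] * b[:, 2]
        area = 0.5 * np.abs(area2)
        Kloc = (
            b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]
        ) / (4.0 * area[:, None, None])
        rows = np.repeat(tri_dofs, 3, axis=1).reshape(-1)
        cols = np.tile(tri_dofs, (1, 3)).reshape(-1)
        vals_unit = Kloc.reshape(-1)

        sigma_tri = np.array([self.bulk.sigma[REGION_NAMES[r]] for r in mesh.tri_region])
        eps_tri = EPS0 * np.array([self.bulk.eps_r[REGION_NAMES[r]] for r in mesh.tri_region])
        sig_entry = np.repeat(sigma_tri, 9)
        eps_entry = np.repeat(eps_tri, 9)

        shape = (self.n_dofs, self.n_dofs)
        self._A_sigma_full = sp.coo_matrix((vals_unit * sig_entry, (rows, cols)), shape=shape).tocsr()
        self._A_eps_full = sp.coo_matrix((vals_unit * eps_entry, (rows, cols)), shape=shape).tocsr()

        # --- Dirichlet electrodes -----------------------------------------
        Lx = mesh.domain_box[0] * 1e-6
        tol = 1e-9
        xcoord = pts[:, 0]
        left = np.flatnonzero(xcoord < tol)
        right = np.flatnonzero(xcoord > Lx - tol)
        if len(left) == 0 or len(right) == 0:
            raise RuntimeError("no electrode (Dirichlet) nodes found on the box edges")
        self.left_nodes, self.right_nodes = left, right
        fixed = np.zeros(self.n_dofs, dtype=bool)
        fixed[left] = True
        fixed[right] = True
        self.fixed_mask = fixed
        self.free_idx = np.flatnonzero(~fixed)
        self.reduced_index = -np.ones(self.n_dofs, dtype=int)
        self.reduced_index[self.free_idx] = np.arange(len(self.free_idx))

        ff = self._A_sigma_full[self.free_idx][:, self.free_idx].tocsr()
        fc = self._A_sigma_full[self.free_idx][:, self.fixed_mask].tocsr()
        self._A_sigma_ff, self._A_sigma_fc = ff, fc
        self._A_eps_ff = self._A_eps_full[self.free_idx][:, self.free_idx].tocsr()
        self._A_eps_fc = self._A_eps_full[self.free_idx][:, self.fixed_mask].tocsr()

        # --- interface lumped weights and per-node membrane properties ---
        e = mesh.interface_edges
        if len(e):
            elen = np.linalg.norm(pts[e[:, 0]] - pts[e[:, 1]], axis=1)
            w = np.zeros(n_nodes)
            np.add.at(w, e[:, 0], 0.5 * elen)
            np.add.at(w, e[:, 1], 0.5 * elen)
            self.if_weight = w[if_nodes]  # lumped membrane length per node, m
        else:
            self.if_weight = np.empty(0)

        node_loop = -np.ones(n_nodes, dtype=int)
        for loop in range(len(mesh.loop_labels)):
            node_loop[np.unique(e[mesh.edge_loop == loop])] = loop
        self.if_loop = node_loop[if_nodes]
        self.if_label = np.array([mesh.loop_labels[l] for l in self.if_loop]) if len(if_nodes) else np.empty(0, dtype=object)
        self.if_Cm = np.array([self.membranes[lab].Cm for lab in self.if_label]) if len(if_nodes) else np.empty(0)
        self.if_d = np.array([self.membranes[lab].d for lab in self.if_label]) if len(if_nodes) else np.empty(0)
        self.if_g0 = np.array([self.membranes[lab].g0 for lab in self.if_label]) if len(if_nodes) else np.empty(0)
        self._if_props = [self.membranes[lab] for lab in self.if_label]

        # interface coupling pattern: (o,o)+, (i,i)+, (o,i)-, (i,o)-
        o = if_nodes
        i = self.inner_dof[if_nodes]
        self._if_rows = np.concatenate([o, i, o, i])
        self._if_cols = np.concatenate([o, i, i, o])
        ro = self.reduced_index[self._if_rows]
        co = self.reduced_index[self._if_cols]
        assert np.all(ro >= 0) and np.all(co >= 0), "interface nodes must not be electrodes"
        self._if_rows_red, self._if_cols_red = ro, co
        self._o_red = self.reduced_index[o]
        self._i_red = self.reduced_index[i]

    # ------------------------------------------------------------------
    @property
    def n_interface(self) -> int:
        return len(self.if_nodes)

    def resting_state(self) -> tuple[np.ndarray, np.ndarray]:
        """Initial (Vm, N): Vm = 0, N = N0 on every interface node."""
        return np.zeros(self.n_interface), np.full(self.n_interface, self.pore.N0)

    def surface_conductance(self, N: np.ndarray, Vm: np.ndarray) -> np.ndarray:
        """Electroporation-dependent surface conductance g = sigma_m/d (S/m^2)."""
        g = np.empty(self.n_interface)
        for lab in np.unique(self.if_label):
            m = self.if_label == lab
            g[m] = membrane_conductivity(N[m], Vm[m], self.pore, self.membranes[lab]) / self.membranes[lab].d
        # cap far beyond the short-circuit limit (g*R >> sigma) so that a
        # transient nonlinear iterate cannot make the system singular
        return np.minimum(g, 1e10)

    # ------------------------------------------------------------------
    def _assemble_and_solve(
        self,
        U: float,
        g: np.ndarray,
        dt: float | None,
        Vm_old: np.ndarray | None,
        phi_old: np.ndarray | None,
    ) -> np.ndarray:
        """One linear solve; dt=None means stationary (no capacitive terms)."""
        nfree = len(self.free_idx)
        A = self._A_sigma_ff
        x_c = np.zeros(int(self.fixed_mask.sum()))
        # fixed-dof vector ordered as flatnonzero(fixed_mask)
        fixed_ids = np.flatnonzero(self.fixed_mask)
        x_c[np.isin(fixed_ids, self.left_nodes)] = U
        b = -self._A_sigma_fc @ x_c

        if dt is not None and self.use_displacement:
            A = A + self._A_eps_ff / dt
            if phi_old is not None:
                b = b + (self._A_eps_ff @ phi_old[self.free_idx] + self._A_eps_fc @ phi_old[fixed_ids]) / dt

        if self.n_interface:
            coeff = self.if_weight * (g + (self.if_Cm / dt if dt is not None else 0.0))
            vals = np.concatenate([coeff, coeff, -coeff, -coeff])
            A_if = sp.coo_matrix(
                (vals, (self._if_rows_red, self._if_cols_red)), shape=(nfree, nfree)
            ).tocsr()
            A = A + A_if
            if dt is not None and Vm_old is not None:
                r = self.if_weight * self.if_Cm / dt * Vm_old
                b[self._o_red] += r
                b[self._i_red] -= r

        phi_free = splu(A.tocsc()).solve(b)
        phi = np.zeros(self.n_dofs)
        phi[self.free_idx] = phi_free
        phi[fixed_ids] = x_c
        return phi

    def solve_stationary(self, U: float, g: np.ndarray | None = None, Vm_for_g: np.ndarray | None = None) -> FieldSolution:
        """Steady-state solve at electrode voltage U with given (or resting)
        surface conductance."""
        if g is None:
            Vm0, N0 = self.resting_state()
            g = self.surface_conductance(N0, Vm_for_g if Vm_for_g is not None else Vm0)
        phi = self._assemble_and_solve(U, g, None, None, None)
        return FieldSolution(phi, np.inf, self.n_nodes, self.inner_dof)

    def step_potential(
        self,
        Vm: np.ndarray,
        N: np.ndarray,
        phi_old: np.ndarray | None,
        U: float,
        dt: float,
        tol: float = 1e-6,
        max_iter: int = 25,
        _depth: int = 0,
    ) -> tuple[FieldSolution, np.ndarray, np.ndarray, int]:
        """Advance one backward-Euler step with fixed-point coupling.

        Iterates (field solve with g(N_it, Vm_it)) <-> (exact exponential
        pore update with frozen Vm) until the relative change of Vm falls
        below ``tol``; the Vm iterate entering g is under-relaxed (factor
        0.7) to damp the stiff N <-> Vm feedback. A non-convergent step is
        retried as two half steps (up to 4 levels) before erroring.
        Returns (solution, Vm_new, N_new, n_iterations).
        """
        Vm_it = Vm.copy()
        N_it = N.copy()
        # Aitken adaptive under-relaxation: the N <-> Vm loop gain grows
        # like alpha*exp((Vm/Vep)^2)*dt during the electroporation burst,
        # so a fixed relaxation factor cannot converge every step
        omega = 1.0 if _depth == 0 else 0.25
        r_prev: np.ndarray | None = None
        for n_it in range(1, max_iter + 1):
            g = self.surface_conductance(N_it, Vm_it)
            phi = self._assemble_and_solve(U, g, dt, Vm, phi_old)
            Vm_new = phi[self.if_nodes] - phi[self.inner_dof[self.if_nodes]]
            N_it = advance_pore_density(N, Vm_new, dt, self.pore)
            r = Vm_new - Vm_it
            scale = max(float(np.max(np.abs(Vm_new))), 1e-9)
            err = float(np.max(np.abs(r))) / scale
            if err < tol:
                return FieldSolution(phi, np.nan, self.n_nodes, self.inner_dof), Vm_new, N_it, n_it
            if r_prev is not None:
                dr = r - r_prev
                denom = float(dr @ dr)
                if denom > 0:
                    omega = float(np.clip(-omega * (r_prev @ dr) / denom, 1e-4, 1.0))
            r_prev = r
            Vm_it = Vm_it + omega * r
        if _depth >= 4:
            raise RuntimeError(
                f"fixed-point coupling did not converge in {max_iter} iterations "
                f"even after halving the step to dt={dt:.3g} s"
            )
        # retry as two half steps (U held at the end-of-step value)
        sol_h, Vm_h, N_h, it1 = self.step_potential(
            Vm, N, phi_old, U, 0.5 * dt, tol, max_iter, _depth + 1
        )
        sol, Vm2, N2, it2 = self.step_potential(
            Vm_h, N_h, sol_h.phi, U, 0.5 * dt, tol, max_iter, _depth + 1
        )
        return sol, Vm2, N2, it1 + it2

    # ------------------------------------------------------------------
    def electrode_currents(self, phi: np.ndarray, g: np.ndarray) -> tuple[float, float]:
        """Conduction current (A per metre of depth) through each electrode,
        from the assembled-residual fluxes at the Dirichlet nodes."""
        A = self._A_sigma_full.copy()
        if self.n_interface:
            vals = np.concatenate([self.if_weight * g] * 2 + [-self.if_weight * g] * 2)
            A = A + sp.coo_matrix(
                (vals, (self._if_rows, self._if_cols)), shape=A.shape
            ).tocsr()
        r = A @ phi
        return float(r[self.left_nodes].sum()), float(r[self.right_nodes].sum())
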