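"""Coupled transient runs and their observables.

Orchestrates geometry -> mesh -> field/pore coupling over a trapezoidal
pulse, recording the observables the analysis works with: point time
series of Vm and N per membrane (at the node of maximal response),
arc-length profiles at snapshot times, running per-membrane peaks, and the
analytic Schwan cosine reference used for validation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .geometry import CellGeometry, make_disc_cell_geometry, make_perturbed_geometry
from .meshing import TriMesh, InterfaceNodeChain, triangulate_with_interfaces, build_interface_chains, longest_chain
from .pore_model import PoreModelParams, MembraneProperties, DEFAULT_MEMBRANES
from .field_solver import (
    BulkProperties,
    PulseSpec,
    TransientFieldSolver,
    electrode_voltage,
    pulse_value,
)

__all__ = [
    "SimulationConfig",
    "ObservableSet",
    "SimContext",
    "prepare_context",
    "run_transient",
    "schwan_reference",
    "sample_arc_profile",
]


@dataclass
class GeometrySpec:
    """Geometry source: parametric ('disc' | 'perturbed') or a JSON file."""

    kind: str = "disc"
    radius_um: float = 4.4
    nucleus_radius_um: float = 2.0
    n_er_loops: int = 0
    fourier_amplitudes: tuple = (0.0, 0.06, 0.04, 0.03)
    seed: int = 0
    box: tuple[float, float] = (100.0, 70.0)
    geometry_file: str | None = None

    def build(self) -> CellGeometry:
        if self.kind == "file":
            with open(self.geometry_file) as f:
                return CellGeometry.from_json(f.read())
        if self.kind == "disc":
            return make_disc_cell_geometry(
                self.radius_um, self.nucleus_radius_um, self.n_er_loops, tuple(self.box)
            )
        if self.kind == "perturbed":
            return make_perturbed_geometry(
                self.radius_um,
                self.fourier_amplitudes,
                self.n_er_loops,
                self.seed,
                tuple(self.box),
                nucleus_radius_um=self.nucleus_radius_um,
            )
        raise ValueError(f"unknown geometry kind {self.kind!r}")


@dataclass
class TimeStepping:
    """Backward-Euler step sizes: fine on the pulse edges, coarser on the
    plateau; the exact exponential pore update needs no sub-stepping."""

    dt_edge_s: float = 0.25e-6
    dt_plateau_s: float = 1.0e-6
    tail_s: float = 10.0e-6
    fixed_point_tol: float = 1e-6
    max_fixed_point_iter: int = 25


@dataclass
class SimulationConfig:
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    h_bulk_um: float = 1.5
    h_membrane_um: float = 0.15
    pulse: PulseSpec = field(default_factory=lambda: PulseSpec(E_app_kV_cm=1.2))
    stepping: TimeStepping = field(default_factory=TimeStepping)
    use_displacement: bool = False
    snapshot_times_s: tuple = (20e-6, 60e-6, 100e-6)
    sigma_p_mode: str = "use_table_value"  # or "use_eq2" (harmonic mean of bulk)
    seed: int = 0

    # ---- parameter objects ------------------------------------------------
    def pore_params(self) -> PoreModelParams:
        p = PoreModelParams()
        if self.sigma_p_mode == "use_eq2":
            bulk = BulkProperties()
            p = p.with_sigma_p_from_bulk(bulk.sigma["extracellular"], bulk.sigma["cytoplasm"])
        elif self.sigma_p_mode != "use_table_value":
            raise ValueError(f"unknown sigma_p_mode {self.sigma_p_mode!r}")
        return p

    def membranes(self) -> dict[str, MembraneProperties]:
        return dict(DEFAULT_MEMBRANES)

    # ---- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "geometry" in d:
            d["geometry"] = GeometrySpec(**d["geometry"])
        if "pulse" in d:
            d["pulse"] = PulseSpec(**d["pulse"])
        if "stepping" in d:
            d["stepping"] = TimeStepping(**d["stepping"])
        return cls(**d)

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(_listify(self.to_dict()), sort_keys=False)
        if path:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text: str) -> "SimulationConfig":
        if os.path.exists(path_or_text):
            with open(path_or_text) as f:
                d = yaml.safe_load(f)
        else:
            d = yaml.safe_load(path_or_text)
        return cls.from_dict(d)


def _listify(obj):
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, list):
        return [_listify(v) for v in obj]
    return obj


# --------------------------------------------------------------------------
@dataclass
class SimContext:
    """Reusable geometry/mesh/solver bundle (one per geometry + materials)."""

    geometry: CellGeometry
    mesh: TriMesh
    chains: list[InterfaceNodeChain]
    solver: TransientFieldSolver

    def chain_for(self, label: str) -> InterfaceNodeChain:
        """Observation chain of a membrane; for the many-loop ER membrane
        the longest closed chain (the longest-loop reporting convention)."""
        return longest_chain(self.chains, label)

    def labels(self) -> list[str]:
        return sorted({c.label for c in self.chains})


def prepare_context(config: SimulationConfig) -> SimContext:
    geometry = config.geometry.build()
    mesh = triangulate_with_interfaces(geometry, config.h_bulk_um, config.h_membrane_um)
    chains = build_interface_chains(mesh)
    solver = TransientFieldSolver(
        mesh,
        membranes=config.membranes(),
        pore_params=config.pore_params(),
        use_displacement=config.use_displacement,
    )
    return SimContext(geometry, mesh, chains, solver)


@dataclass
class MembraneObservables:
    """Time-resolved observables of one membrane (its observation chain)."""

    label: str
    s_um: np.ndarray  # arc-length coordinate of the chain nodes
    Vm: np.ndarray  # (n_times, n_nodes) transmembrane potential, V
    N: np.ndarray  # (n_times, n_nodes) pore density, m^-2
    peak_abs_Vm_series: np.ndarray  # (n_times,) max |Vm| over ALL nodes of this label
    peak_N_series: np.ndarray  # (n_times,) max N over ALL nodes of this label
    obs_node: int = 0  # column index of the observation point in Vm/N

    @property
    def point_Vm(self) -> np.ndarray:
        return self.Vm[:, self.obs_node]

    @property
    def point_N(self) -> np.ndarray:
        return self.N[:, self.obs_node]

    @property
    def peak_abs_Vm(self) -> float:
        return float(self.peak_abs_Vm_series.max()) if len(self.peak_abs_Vm_series) else 0.0

    @property
    def peak_N(self) -> float:
        return float(self.peak_N_series.max()) if len(self.peak_N_series) else 0.0


@dataclass
class ObservableSet:
    times: np.ndarray
    membranes: dict[str, MembraneObservables]
    config: SimulationConfig
    stopped_early: bool = False
    fixed_point_iters: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("observable time stamps must be strictly increasing")


def _time_grid(pulse: PulseSpec, stepping: TimeStepping) -> np.ndarray:
    """Piecewise-uniform grid: fine steps on the edges, coarse on the
    plateau and post-pulse tail."""

    def seg(t0, t1, dt):
        if t1 <= t0 + 1e-18:
            return np.empty(0)
        n = max(1, int(round((t1 - t0) / dt)))
        return t0 + (t1 - t0) * np.arange(1, n + 1) / n

    parts = [
        seg(0.0, pulse.rise_s, stepping.dt_edge_s),
        seg(pulse.rise_s, pulse.width_s, stepping.dt_plateau_s),
        seg(pulse.width_s, pulse.t_end, stepping.dt_edge_s),
        seg(pulse.t_end, pulse.t_end + stepping.tail_s, stepping.dt_plateau_s),
    ]
    return np.concatenate([[0.0], *parts])


def run_transient(
    config: SimulationConfig,
    context: SimContext | None = None,
    stop_when: dict | None = None,
) -> ObservableSet:
    """Run the coupled field/pore transient over the configured pulse.

    Per step: backward-Euler field solve with the current surface
    conductance g(N, Vm), exact exponential pore-density update with frozen
    Vm, fixed-point iterated to tolerance. ``stop_when`` (e.g.
    ``{"membrane": "plasma", "kind": "tmp", "level": 1.0}``) aborts the run
    as soon as the running peak of |Vm| (kind 'tmp') or N (kind
    'pore_density') of that membrane reaches the level — used by the
    threshold sweep, where only criterion attainment matters.
    """
    ctx = context or prepare_context(config)
    solver = ctx.solver
    pulse = config.pulse
    grid = _time_grid(pulse, config.stepping)

    Vm, N = solver.resting_state()
    phi = None

    labels = ctx.labels()
    chains_by_label = {lab: ctx.chain_for(lab) for lab in labels}
    # interface-array indices of each label / each observation chain
    lab_masks = {lab: solver.if_label == lab for lab in labels}
    node_to_ifidx = -np.ones(solver.n_nodes, dtype=int)
    node_to_ifidx[solver.if_nodes] = np.arange(solver.n_interface)
    chain_ifidx = {lab: node_to_ifidx[c.node_indices] for lab, c in chains_by_label.items()}

    rec_Vm = {lab: [Vm[chain_ifidx[lab]].copy()] for lab in labels}
    rec_N = {lab: [N[chain_ifidx[lab]].copy()] for lab in labels}
    rec_peakV = {lab: [0.0] for lab in labels}
    rec_peakN = {lab: [float(config.pore_params().N0)] for lab in labels}
    iters = [0]
    times = [0.0]
    stopped = False

    Umax = electrode_voltage(pulse)
    for t_prev, t in zip(grid[:-1], grid[1:]):
        dt = t - t_prev
        U = Umax * pulse_value(t, pulse)
        sol, Vm, N, n_it = solver.step_potential(
            Vm, N, phi, U, dt,
            tol=config.stepping.fixed_point_tol,
            max_iter=config.stepping.max_fixed_point_iter,
        )
        phi = sol.phi
        times.append(t)
        iters.append(n_it)
        for lab in labels:
            rec_Vm[lab].append(Vm[chain_ifidx[lab]].copy())
            rec_N[lab].append(N[chain_ifidx[lab]].copy())
            rec_peakV[lab].append(float(np.max(np.abs(Vm[lab_masks[lab]]))))
            rec_peakN[lab].append(float(np.max(N[lab_masks[lab]])))
        if stop_when is not None:
            lab = stop_when["membrane"]
            level = float(stop_when["level"])
            hit = (
                rec_peakV[lab][-1] >= level
                if stop_when["kind"] == "tmp"
                else rec_peakN[lab][-1] >= level
            )
            if hit:
                stopped = True
                break

    membranes = {}
    times = np.asarray(times)
    for lab in labels:
        Vm_ts = np.asarray(rec_Vm[lab])
        N_ts = np.asarray(rec_N[lab])
        # observation point: node of max |Vm| at the first plateau sample
        i_plat = int(np.searchsorted(times, pulse.rise_s))
        i_plat = min(i_plat, len(times) - 1)
        obs = int(np.argmax(np.abs(Vm_ts[i_plat])))
        membranes[lab] = MembraneObservables(
            label=lab,
            s_um=chains_by_label[lab].s,
            Vm=Vm_ts,
            N=N_ts,
            peak_abs_Vm_series=np.asarray(rec_peakV[lab]),
            peak_N_series=np.asarray(rec_peakN[lab]),
            obs_node=obs,
        )
    return ObservableSet(
        times=times,
        membranes=membranes,
        config=config,
        stopped_early=stopped,
        fixed_point_iters=np.asarray(iters),
    )


def schwan_reference(E: float, R: float, theta) -> dict[str, np.ndarray | float]:
    """Analytic steady-state induced TMP of a circular cell in a uniform field.

    Returns both conventions, labelled: the spherical-cell (3D) coefficient
    3/2 E R cos(theta) and the value for the plane (cylinder) geometry this
    model actually lives in, 2 E R cos(theta) — the latter is what the 2D
    solver is validated against. E in V/m, R in m, theta in radians from
    the field axis.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    c = np.cos(theta)
    return {"3d": 1.5 * E * R * c, "2d": 2.0 * E * R * c}


def sample_arc_profile(
    observables: ObservableSet, membrane: str, time: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(s, Vm(s), N(s)) of a membrane, linearly interpolated at ``time``."""
    t = observables.times
    if not (t[0] <= time <= t[-1]):
        raise ValueError(f"time {time} outside the run range [{t[0]}, {t[-1]}]")
    mo = observables.membranes[membrane]
    i = int(np.searchsorted(t, time))
    if i == 0 or t[i] == time:
        return mo.s_um, mo.Vm[i], mo.N[i]
    w = (time - t[i - 1]) / (t[i] - t[i - 1])
    Vm = (1 - w) * mo.Vm[i - 1] + w * mo.Vm[i]
    N = (1 - w) * mo.N[i - 1] + w * mo.N[i]
    return mo.s_um, Vm, N


# --------------------------------------------------------------------------
def export_run(observables: ObservableSet, out_dir: str) -> dict:
    """Write CSV traces/profiles and a JSON manifest; returns the manifest."""
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    t = observables.times
    for lab, mo in observables.membranes.items():
        pd.DataFrame(
            {
                "time_s": t,
                "Vm_point_V": mo.point_Vm,
                "N_point_m2": mo.point_N,
                "peak_abs_Vm_V": mo.peak_abs_Vm_series,
                "peak_N_m2": mo.peak_N_series,
            }
        ).to_csv(os.path.join(out_dir, f"trace_{lab}.csv"), index=False)
        for t_snap in observables.config.snapshot_times_s:
            if t_snap <= t[-1]:
                s, Vm, N = sample_arc_profile(observables, lab, t_snap)
                pd.DataFrame({"s_um": s, "Vm_V": Vm, "N_m2": N}).to_csv(
                    os.path.join(out_dir, f"profile_{lab}_{t_snap*1e6:.0f}us.csv"),
                    index=False,
                )
    manifest = {
        "config": _listify(observables.config.to_dict()),
        "n_times": int(len(t)),
        "stopped_early": bool(observables.stopped_early),
        "peaks": {
            lab: {"abs_Vm_V": mo.peak_abs_Vm, "N_m2": mo.peak_N}
            for lab, mo in observables.membranes.items()
        },
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as f:
        json.dump(manifest, f, indent=2)
    return manifest
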