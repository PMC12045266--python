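"""Shared fixtures: coarse meshes/configs sized for fast test runs.

The coarse settings (h_membrane 0.3 um, h_bulk 3 um, 0.5/2 us steps) keep
single transients at a few seconds while preserving the physics well enough
for the structural and property checks; the quantitative acceptance checks
build their own finer setups.
"""

from __future__ import annotations

import numpy as np
import pytest

from porefem.pipeline import SimulationConfig, GeometrySpec, TimeStepping, prepare_context, run_transient


def coarse_config(E_kV_cm: float = 1.2, radius_um: float = 4.4, **geometry_kwargs) -> SimulationConfig:
    from porefem.field_solver import PulseSpec

    return SimulationConfig(
        geometry=GeometrySpec(kind="disc", radius_um=radius_um, **geometry_kwargs),
        h_bulk_um=3.0,
        h_membrane_um=0.3,
        pulse=PulseSpec(E_app_kV_cm=E_kV_cm),
        stepping=TimeStepping(dt_edge_s=0.5e-6, dt_plateau_s=2.0e-6, tail_s=8.0e-6),
    )


@pytest.fixture(scope="session")
def coarse_ctx():
    """Coarse mesh/solver for the reference disc cell (R=4.4 um)."""
    return prepare_context(coarse_config())


@pytest.fixture(scope="session")
def coarse_run(coarse_ctx):
    """One coarse 1.2 kV/cm transient, shared across read-only tests."""
    return run_transient(coarse_config(), context=coarse_ctx)


@pytest.fixture(scope="session")
def default_ctx():
    """Default-resolution context (the acceptance problem size)."""
    return prepare_context(SimulationConfig())


@pytest.fixture(scope="session")
def default_run(default_ctx):
    """Default-resolution 1.2 kV/cm transient (the paper's reference run)."""
    return run_transient(SimulationConfig(), context=default_ctx)


def cosine_fit_r2(s: np.ndarray, total_length: float, values: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of A*cos(theta)+B*sin(theta) along a closed chain;
    returns (|A|, R^2)."""
    theta = 2.0 * np.pi * s / total_length
    design = np.column_stack([np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(design, values, rcond=None)
    pred = design @ coef
    ss_res = float(np.sum((values - pred) ** 2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    return abs(float(coef[0])), 1.0 - ss_res / ss_tot
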