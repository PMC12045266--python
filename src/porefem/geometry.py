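"""Parametric 2D cell geometries: plasma membrane, nucleus, ER loops.

Geometries live in a rectangular bath (default 100 x 70 um) between the two
plate electrodes (left/right box edges). The reference configuration is a
disc cell of radius 4.4 um with a 2 um nucleus; irregular nuclei/ER are
produced by random radial Fourier perturbations of circles. Coordinates are
in micrometres, origin at the lower-left corner of the box, y up,
counterclockwise contours.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "ClosedContour",
    "CellGeometry",
    "make_disc_cell_geometry",
    "make_perturbed_geometry",
    "GeometryError",
]

#: Default membrane sheet thicknesses in um (plasma, nuclear envelope, ER).
DEFAULT_THICKNESS_UM = {"plasma": 0.01, "nucleus": 0.04, "er": 0.01}

DEFAULT_BOX = (100.0, 70.0)


class GeometryError(ValueError):
    """Raised when a requested geometry cannot be constructed validly."""


@dataclass
class ClosedContour:
    """A simple closed counterclockwise polygon boundary of one membrane.

    ``vertices`` is an (n, 2) array in um; the contour is implicitly closed
    (last vertex connects back to the first). ``label`` is one of
    'plasma' | 'nucleus' | 'er'.
    """

    vertices: np.ndarray
    label: str

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if len(self.vertices) < 8:
            raise GeometryError("a closed contour needs at least 8 vertices")
        if self.label not in ("plasma", "nucleus", "er"):
            raise GeometryError(f"unknown membrane label {self.label!r}")
        if self.signed_area() < 0:  # normalize to counterclockwise
            self.vertices = self.vertices[::-1].copy()
        if not self.polygon.is_valid or not self.polygon.is_simple:
            raise GeometryError(f"{self.label} contour is self-intersecting")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def signed_area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.vertices, self.vertices[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class CellGeometry:
    """Full cell geometry: bath box, plasma membrane, nucleus, ER loops."""

    domain_box: tuple[float, float]
    plasma: ClosedContour
    nucleus: ClosedContour
    er_loops: list[ClosedContour] = field(default_factory=list)
    membrane_thickness_um: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THICKNESS_UM))

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        w, h = self.domain_box
        box = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
        plasma = self.plasma.polygon
        if not box.contains(plasma):
            raise GeometryError("plasma membrane must lie strictly inside the domain box")
        if not plasma.contains(self.nucleus.polygon):
            raise GeometryError("nucleus must lie strictly inside the plasma membrane")
        loops = [c.polygon for c in self.er_loops]
        nuc = self.nucleus.polygon
        for i, p in enumerate(loops):
            if not plasma.contains(p):
                raise GeometryError(f"ER loop {i} is not inside the plasma membrane")
            if p.intersects(nuc):
                raise GeometryError(f"ER loop {i} intersects the nucleus")
            for j in range(i):
                if p.intersects(loops[j]):
                    raise GeometryError(f"ER loops {j} and {i} intersect")

    def contours(self) -> list[ClosedContour]:
        return [self.plasma, self.nucleus, *self.er_loops]

    # ---- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "domain_box": list(self.domain_box),
            "membrane_thickness_um": self.membrane_thickness_um,
            "contours": [
                {"label": c.label, "vertices": c.vertices.tolist()} for c in self.contours()
            ],
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "CellGeometry":
        payload = json.loads(text)
        plasma = nucleus = None
        er = []
        for entry in payload["contours"]:
            c = ClosedContour(np.asarray(entry["vertices"]), entry["label"])
            if c.label == "plasma":
                plasma = c
            elif c.label == "nucleus":
                nucleus = c
            else:
                er.append(c)
        if plasma is None or nucleus is None:
            raise GeometryError("geometry JSON must contain a plasma and a nucleus contour")
        return cls(
            domain_box=tuple(payload["domain_box"]),
            plasma=plasma,
            nucleus=nucleus,
            er_loops=er,
            membrane_thickness_um=dict(payload.get("membrane_thickness_um", DEFAULT_THICKNESS_UM)),
        )


def _circle(center: np.ndarray, radius: float, n: int, label: str) -> ClosedContour:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = center + radius * np.column_stack([np.cos(theta), np.sin(theta)])
    return ClosedContour(pts, label)


def _ring_er_positions(r_in: float, r_out: float, n_loops: int, loop_radius: float, margin: float):
    """Deterministic ER loop centres packed on concentric rings of the
    annulus between nucleus and plasma membrane; None if they cannot fit."""
    if n_loops == 0:
        return []
    spacing = 2.0 * loop_radius + margin
    lo = r_in + loop_radius + margin
    hi = r_out - loop_radius - margin
    if hi < lo:
        return None
    centres: list[tuple[float, float]] = []
    r = lo
    remaining = n_loops
    while remaining > 0 and r <= hi + 1e-12:
        n_fit = max(1, int(np.floor(2.0 * np.pi * r / spacing)))
        n_here = min(n_fit, remaining)
        # stagger successive rings so nearest loops on adjacent rings clear
        phase = 0.5 * (len(centres) % 2)
        ang = 2.0 * np.pi * (np.arange(n_here) + phase) / n_fit
        centres.extend(zip(r * np.cos(ang), r * np.sin(ang)))
        remaining -= n_here
        r += spacing
    if remaining > 0:
        return None
    return centres


def make_disc_cell_geometry(
    radius_um: float = 4.4,
    nucleus_radius_um: float = 2.0,
    n_er_loops: int = 0,
    box: tuple[float, float] = DEFAULT_BOX,
    n_vertices: int = 256,
    er_loop_radius_um: float = 0.25,
    er_margin_um: float = 0.1,
    membrane_thickness_um: dict[str, float] | None = None,
) -> CellGeometry:
    """Reference disc-cell geometry centred in the bath.

    The 4.4 um default radius is the calibrated surrogate for the (not
    distributable) imaged cell: at 1.2 kV/cm the 2D steady-state pole TMP
    2*E*R is then 1.056 V, the plateau the transient run reproduces.
    """
    if radius_um <= 0 or nucleus_radius_um <= 0:
        raise ValueError("radii must be positive")
    if not nucleus_radius_um < radius_um:
        raise GeometryError("nucleus radius must be smaller than the cell radius")
    if radius_um >= min(box) / 2.0:
        raise GeometryError("cell must fit strictly inside the domain box")
    if n_er_loops < 0:
        raise ValueError("n_er_loops must be nonnegative")
    if n_vertices < 128:
        n_vertices = 128
    centre = np.array([box[0] / 2.0, box[1] / 2.0])
    plasma = _circle(centre, radius_um, n_vertices, "plasma")
    nucleus = _circle(centre, nucleus_radius_um, max(128, n_vertices // 2), "nucleus")
    er = []
    if n_er_loops:
        margin = er_margin_um
        pos = _ring_er_positions(nucleus_radius_um, radius_um, n_er_loops, er_loop_radius_um, margin)
        if pos is None:
            raise GeometryError(
                f"cannot place {n_er_loops} disjoint ER loops of radius {er_loop_radius_um} um "
                f"between nucleus ({nucleus_radius_um} um) and plasma membrane ({radius_um} um)"
            )
        for cx, cy in pos:
            er.append(_circle(centre + (cx, cy), er_loop_radius_um, 64, "er"))
    return CellGeometry(
        domain_box=box,
        plasma=plasma,
        nucleus=nucleus,
        er_loops=er,
        membrane_thickness_um=dict(membrane_thickness_um or DEFAULT_THICKNESS_UM),
    )


def _perturbed_circle(
    rng: np.random.Generator,
    center: np.ndarray,
    radius: float,
    amplitudes: np.ndarray,
    n: int,
    label: str,
    max_tries: int = 20,
) -> ClosedContour:
    """Radial Fourier perturbation r(theta) = R(1 + sum_k a_k cos(k theta + phi_k)).

    Amplitudes are relative; random phases per mode. Retries with fresh
    phases if the curve self-intersects (possible for aggressive spectra).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    amplitudes = np.asarray(amplitudes, dtype=float)
    for _ in range(max_tries):
        r = np.full(n, radius)
        for k, a_k in enumerate(amplitudes, start=1):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            r += radius * a_k * np.cos(k * theta + phase)
        if np.any(r <= 0):
            continue
        pts = center + np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        try:
            return ClosedContour(pts, label)
        except GeometryError:
            continue
    raise GeometryError(f"could not generate a simple perturbed {label} contour")


def make_perturbed_geometry(
    radius_um: float = 4.4,
    fourier_amplitudes=(0.0, 0.06, 0.04, 0.03),
    n_er_loops: int = 0,
    seed: int = 0,
    box: tuple[float, float] = DEFAULT_BOX,
    nucleus_radius_um: float = 2.0,
    nucleus_amplitudes=(0.0, 0.08, 0.06),
    er_loop_radius_um: float = 0.25,
    n_vertices: int = 256,
) -> CellGeometry:
    """Irregular cell geometry with Fourier-perturbed membranes and randomly
    placed disjoint ER loops (up to 36), reproducible under a fixed seed.

    With all amplitudes zero this reduces exactly to
    :func:`make_disc_cell_geometry` with deterministic ring-placed ER loops.
    """
    amplitudes = np.asarray(fourier_amplitudes, dtype=float)
    nuc_amp = np.asarray(nucleus_amplitudes, dtype=float)
    if not np.any(amplitudes) and not np.any(nuc_amp):
        return make_disc_cell_geometry(
            radius_um, nucleus_radius_um, n_er_loops, box,
            n_vertices=n_vertices, er_loop_radius_um=er_loop_radius_um,
        )
    rng = np.random.default_rng(seed)
    centre = np.array([box[0] / 2.0, box[1] / 2.0])
    plasma = _perturbed_circle(rng, centre, radius_um, amplitudes, n_vertices, "plasma")
    nucleus = _perturbed_circle(rng, centre, nucleus_radius_um, nuc_amp, max(128, n_vertices // 2), "nucleus")

    plasma_poly = plasma.polygon
    nucleus_poly = nucleus.polygon
    er: list[ClosedContour] = []
    margin = 0.1
    attempts = 0
    max_attempts = 400 * max(1, n_er_loops)
    while len(er) < n_er_loops:
        attempts += 1
        if attempts > max_attempts:
            raise GeometryError(
                f"could not place {n_er_loops} disjoint ER loops after {max_attempts} attempts"
            )
        ang = rng.uniform(0.0, 2.0 * np.pi)
        rad = rng.uniform(nucleus_radius_um * 0.6, radius_um)
        c = centre + rad * np.array([np.cos(ang), np.sin(ang)])
        loop = _circle(c, er_loop_radius_um, 64, "er")
        p = loop.polygon
        if not plasma_poly.buffer(-margin).contains(p):
            continue
        if p.buffer(margin).intersects(nucleus_poly):
            continue
        if any(p.buffer(margin).intersects(other.polygon) for other in er):
            continue
        er.append(loop)
    return CellGeometry(domain_box=box, plasma=plasma, nucleus=nucleus, er_loops=er)
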