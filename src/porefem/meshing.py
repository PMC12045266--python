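"""Conforming triangulation with membranes as internal interface polylines.

Membranes (10-40 nm thick) are five orders of magnitude thinner than the
bath (100 um); meshing them as layers is intractable, so each membrane is a
zero-thickness polyline of mesh edges carrying its physical thickness as a
parameter. The field solver recovers the membrane physics through a
distributed-impedance interface condition on these edges.

The mesh is built from a graded point cloud (interface samples at
``h_membrane``, offset rings grading out to ``h_bulk``, a hexagonal bulk
lattice, box boundary points), triangulated with Delaunay, followed by
interface-edge recovery (deleting free points that block a required
segment) and a Laplacian smoothing pass. Region ids (extracellular,
cytoplasm, nucleoplasm, er_matrix) are assigned by point-in-polygon tests
of triangle centroids against the resampled interface polygons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon

from .geometry import CellGeometry

__all__ = [
    "TriMesh",
    "InterfaceNodeChain",
    "triangulate_with_interfaces",
    "build_interface_chains",
    "MeshingError",
    "write_vtk",
]

REGION_NAMES = ("extracellular", "cytoplasm", "nucleoplasm", "er_matrix")


class MeshingError(RuntimeError):
    pass


@dataclass
class TriMesh:
    """Conforming triangulation with tagged regions and interface edges.

    Coordinates in um. ``interface_edges`` are (n1, n2) node pairs;
    ``edge_loop`` maps each edge to a closed-membrane loop id and
    ``loop_labels[loop]`` gives that loop's membrane label. For every loop,
    ``tri_inside_loop[loop]`` flags the triangles enclosed by it (used by
    the solver to split duplicated interface DOFs into inner/outer sides).
    """

    points: np.ndarray  # (n_nodes, 2)
    triangles: np.ndarray  # (n_tris, 3)
    tri_region: np.ndarray  # (n_tris,) index into REGION_NAMES
    interface_edges: np.ndarray  # (n_edges, 2)
    edge_loop: np.ndarray  # (n_edges,)
    loop_labels: list[str]  # membrane label per loop id
    tri_inside_loop: np.ndarray  # (n_loops, n_tris) bool
    h_bulk: float
    h_membrane: float
    geometry: CellGeometry | None = None
    domain_box: tuple[float, float] = (100.0, 70.0)

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    def interface_nodes(self) -> np.ndarray:
        if len(self.interface_edges) == 0:
            return np.empty(0, dtype=int)
        return np.unique(self.interface_edges)

    def triangle_areas(self) -> np.ndarray:
        p = self.points[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def min_angle_deg(self) -> float:
        p = self.points[self.triangles]
        angles = []
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosang = np.einsum("ij,ij->i", a, b) / (
                np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
            )
            angles.append(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        return float(np.min(angles))

    def region_areas(self) -> dict[str, float]:
        areas = self.triangle_areas()
        return {
            name: float(areas[self.tri_region == i].sum()) for i, name in enumerate(REGION_NAMES)
        }


@dataclass
class InterfaceNodeChain:
    """Ordered closed chain of mesh nodes along one membrane loop.

    Counterclockwise order; arc length ``s`` starts at the rightmost node
    (maximum x, ties broken by maximum y). ``normals`` are unit outward
    normals (pointing from the enclosed region to the outside).
    """

    node_indices: np.ndarray
    s: np.ndarray  # cumulative arc length from the start node, um
    label: str
    loop: int
    normals: np.ndarray  # (n, 2)

    @property
    def total_length(self) -> float:
        return float(self._closing_length + self.s[-1])

    _closing_length: float = 0.0


def _resample_closed(vertices: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a closed polygon at (approximately) uniform arc spacing."""
    pts = np.vstack([vertices, vertices[:1]])
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    total = arc[-1]
    n = max(12, int(np.round(total / spacing)))
    s_new = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(s_new, arc, pts[:, 0])
    y = np.interp(s_new, arc, pts[:, 1])
    return np.column_stack([x, y])


def _offset_curves(poly: Polygon, delta: float) -> list[np.ndarray]:
    """Coordinate rings of the polygon offset by +/- delta (may vanish)."""
    out = []
    for signed in (delta, -delta):
        buffered = poly.buffer(signed, quad_segs=8)
        if buffered.is_empty:
            continue
        geoms = getattr(buffered, "geoms", [buffered])
        for g in geoms:
            coords = np.asarray(g.exterior.coords)[:-1]
            if len(coords) >= 4:
                out.append(coords)
    return out


class _PointFilter:
    """Greedy spacing filter: accepts a point only if no previously accepted
    point lies within its exclusion radius. Grid-hash based."""

    def __init__(self, cell: float):
        self.cell = cell
        self.grid: dict[tuple[int, int], list[int]] = {}
        self.pts: list[np.ndarray] = []

    def try_add(self, p: np.ndarray, radius: float) -> bool:
        ci, cj = int(p[0] // self.cell), int(p[1] // self.cell)
        reach = int(np.ceil(radius / self.cell))
        for di in range(-reach, reach + 1):
            for dj in range(-reach, reach + 1):
                for idx in self.grid.get((ci + di, cj + dj), ()):
                    if np.hypot(*(self.pts[idx] - p)) < radius:
                        return False
        self.pts.append(np.asarray(p, dtype=float))
        self.grid.setdefault((ci, cj), []).append(len(self.pts) - 1)
        return True

    def add_fixed(self, p: np.ndarray) -> None:
        ci, cj = int(p[0] // self.cell), int(p[1] // self.cell)
        self.pts.append(np.asarray(p, dtype=float))
        self.grid.setdefault((ci, cj), []).append(len(self.pts) - 1)


def _box_boundary_points(box: tuple[float, float], h: float) -> np.ndarray:
    w, hgt = box
    nx = max(2, int(round(w / h)))
    ny = max(2, int(round(hgt / h)))
    xs = np.linspace(0, w, nx + 1)
    ys = np.linspace(0, hgt, ny + 1)
    pts = [np.column_stack([xs, np.zeros_like(xs)]), np.column_stack([xs, np.full_like(xs, hgt)])]
    inner_y = ys[1:-1]
    pts.append(np.column_stack([np.zeros_like(inner_y), inner_y]))
    pts.append(np.column_stack([np.full_like(inner_y, w), inner_y]))
    return np.vstack(pts)


def _hex_lattice(box: tuple[float, float], h: float) -> np.ndarray:
    w, hgt = box
    dy = h * np.sqrt(3.0) / 2.0
    rows = []
    y = dy * 0.9
    r = 0
    while y < hgt - 0.4 * dy:
        x0 = h * (0.5 if r % 2 else 1.0)
        xs = np.arange(x0, w - 0.25 * h, h)
        rows.append(np.column_stack([xs, np.full_like(xs, y)]))
        y += dy
        r += 1
    return np.vstack(rows) if rows else np.empty((0, 2))


def _tri_edges(tris: np.ndarray) -> set[tuple[int, int]]:
    e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e.sort(axis=1)
    return set(map(tuple, e))


def triangulate_with_interfaces(
    geometry: CellGeometry | None,
    h_bulk: float = 1.5,
    h_membrane: float = 0.15,
    box: tuple[float, float] | None = None,
    smooth_iters: int = 2,
) -> TriMesh:
    """Build the conforming interface mesh of a cell geometry.

    With ``geometry=None`` a plain box mesh (all extracellular) is built;
    ``box`` is then required. Local resolution is ``h_membrane`` at every
    membrane, grading geometrically out to ``h_bulk``.
    """
    if h_membrane > h_bulk:
        raise ValueError("h_membrane must not exceed h_bulk")
    if geometry is None:
        if box is None:
            raise ValueError("box is required when no geometry is given")
        contours = []
        domain_box = box
    else:
        contours = geometry.contours()
        domain_box = geometry.domain_box

    # minimum clearance between distinct membranes must resolve h_membrane
    polys = [Polygon(c.vertices) for c in contours]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            dij = polys[i].exterior.distance(polys[j].exterior)
            if dij < h_membrane:
                raise MeshingError(
                    f"contours {i} and {j} are {dij:.3g} um apart, closer than "
                    f"h_membrane={h_membrane}; refine h_membrane or separate them"
                )

    # --- interface samples (fixed points) --------------------------------
    loop_points: list[np.ndarray] = []
    loop_labels: list[str] = []
    for c in contours:
        loop_points.append(_resample_closed(c.vertices, h_membrane))
        loop_labels.append(c.label)

    filt = _PointFilter(cell=max(h_bulk, h_membrane))
    n_fixed_interface = 0
    loop_node_ranges = []
    for pts in loop_points:
        start = len(filt.pts)
        for p in pts:
            filt.add_fixed(p)
        loop_node_ranges.append((start, len(filt.pts)))
        n_fixed_interface = len(filt.pts)

    boundary_pts = _box_boundary_points(domain_box, h_bulk)
    n_fixed_total_start = len(filt.pts)
    kept_boundary = []
    for p in boundary_pts:
        filt.add_fixed(p)  # box boundary is always kept (convex hull nodes)
        kept_boundary.append(len(filt.pts) - 1)
    n_fixed = len(filt.pts)

    # --- graded offset rings around each membrane ------------------------
    delta = h_membrane
    grow = 1.7
    while delta < 1.6 * h_bulk:
        spacing = float(np.clip(0.9 * delta, h_membrane, h_bulk))
        for poly in polys:
            for ring in _offset_curves(poly, delta):
                for p in _resample_closed(ring, spacing):
                    if 0 < p[0] < domain_box[0] and 0 < p[1] < domain_box[1]:
                        filt.try_add(p, 0.55 * spacing)
        delta *= grow

    # --- bulk lattice -----------------------------------------------------
    for p in _hex_lattice(domain_box, h_bulk):
        filt.try_add(p, 0.55 * h_bulk)

    points = np.asarray(filt.pts)
    free_mask = np.ones(len(points), dtype=bool)
    free_mask[:n_fixed] = False

    # required interface segments as (global a, global b) index pairs
    segments = []
    seg_loop = []
    for loop_id, (a0, a1) in enumerate(loop_node_ranges):
        idx = np.arange(a0, a1)
        seg = np.column_stack([idx, np.roll(idx, -1)])
        segments.append(seg)
        seg_loop.append(np.full(len(seg), loop_id))
    segments = np.vstack(segments) if segments else np.empty((0, 2), dtype=int)
    seg_loop = np.concatenate(seg_loop) if len(seg_loop) else np.empty(0, dtype=int)

    def triangulate(pts: np.ndarray) -> np.ndarray:
        return Delaunay(pts).simplices

    keep = np.ones(len(points), dtype=bool)

    def renumber():
        idx_map = -np.ones(len(points), dtype=int)
        idx_map[keep] = np.arange(keep.sum())
        return points[keep], idx_map

    # --- edge recovery loop ----------------------------------------------
    for attempt in range(10):
        pts_now, idx_map = renumber()
        tris = triangulate(pts_now)
        edges = _tri_edges(tris)
        missing = []
        for (a, b) in segments:
            ea, eb = idx_map[a], idx_map[b]
            if (min(ea, eb), max(ea, eb)) not in edges:
                missing.append((a, b))
        if not missing:
            break
        removed_any = False
        tree = cKDTree(pts_now)
        kept_idx = np.flatnonzero(keep)  # mapping valid for this attempt's tree
        for a, b in missing:
            mid = 0.5 * (points[a] + points[b])
            rad = 0.75 * np.hypot(*(points[a] - points[b]))
            for j in tree.query_ball_point(mid, rad):
                g = kept_idx[j]
                if free_mask[g] and keep[g]:
                    keep[g] = False
                    removed_any = True
        if not removed_any:
            raise MeshingError(f"could not recover {len(missing)} interface edges")
    else:
        raise MeshingError("interface edge recovery did not converge")

    # --- Laplacian smoothing of free nodes (then re-recover) -------------
    for _ in range(max(0, smooth_iters)):
        pts_now, idx_map = renumber()
        tris = triangulate(pts_now)
        n = len(pts_now)
        neigh_sum = np.zeros((n, 2))
        neigh_cnt = np.zeros(n)
        for i in range(3):
            a = tris[:, i]
            for j in (1, 2):
                b = tris[:, (i + j) % 3]
                np.add.at(neigh_sum, a, pts_now[b])
                np.add.at(neigh_cnt, a, 1.0)
        target = neigh_sum / np.maximum(neigh_cnt, 1.0)[:, None]
        movable = free_mask[keep]
        pts_now[movable] = pts_now[movable] + 0.6 * (target[movable] - pts_now[movable])
        points[keep] = pts_now
        # smoothing may break a required edge; verify and re-recover once
        tris = triangulate(pts_now)
        edges = _tri_edges(tris)
        kept_idx = np.flatnonzero(keep)
        tree = cKDTree(pts_now)
        for (a, b) in segments:
            ea, eb = idx_map[a], idx_map[b]
            if (min(ea, eb), max(ea, eb)) not in edges:
                # drop blocking free points around this segment
                mid = 0.5 * (points[a] + points[b])
                rad = 0.75 * np.hypot(*(points[a] - points[b]))
                for j in tree.query_ball_point(mid, rad):
                    g = kept_idx[j]
                    if free_mask[g]:
                        keep[g] = False

    pts_final, idx_map = renumber()
    tris = triangulate(pts_final)
    edges = _tri_edges(tris)
    for (a, b) in segments:
        ea, eb = idx_map[a], idx_map[b]
        if (min(ea, eb), max(ea, eb)) not in edges:
            raise MeshingError("interface edge lost after smoothing")

    interface_edges = (
        np.column_stack([idx_map[segments[:, 0]], idx_map[segments[:, 1]]])
        if len(segments)
        else np.empty((0, 2), dtype=int)
    )

    # --- region classification -------------------------------------------
    import shapely

    centroids = pts_final[tris].mean(axis=1)
    resampled_polys = [Polygon(p) for p in loop_points]
    inside = np.zeros((len(resampled_polys), len(tris)), dtype=bool)
    for k, poly in enumerate(resampled_polys):
        inside[k] = shapely.contains_xy(poly, centroids[:, 0], centroids[:, 1])
    region = np.zeros(len(tris), dtype=int)
    for k, lab in enumerate(loop_labels):
        if lab == "plasma":
            region[inside[k]] = 1
    for k, lab in enumerate(loop_labels):
        if lab == "nucleus":
            region[inside[k]] = 2
        elif lab == "er":
            region[inside[k]] = 3

    return TriMesh(
        points=pts_final,
        triangles=tris,
        tri_region=region,
        interface_edges=interface_edges,
        edge_loop=np.asarray(seg_loop, dtype=int),
        loop_labels=loop_labels,
        tri_inside_loop=inside,
        h_bulk=h_bulk,
        h_membrane=h_membrane,
        geometry=geometry,
        domain_box=tuple(domain_box),
    )


def build_interface_chains(mesh: TriMesh) -> list[InterfaceNodeChain]:
    """Extract one ordered closed node chain per membrane loop.

    Chains are oriented counterclockwise regardless of input orientation;
    arc length starts at the rightmost node. Outward unit normals point
    from the enclosed (inner) region to the outer region.
    """
    chains = []
    for loop_id in range(len(mesh.loop_labels)):
        sel = mesh.edge_loop == loop_id
        edges = mesh.interface_edges[sel]
        if len(edges) == 0:
            continue
        # walk the cycle
        nxt = {}
        for a, b in edges:
            nxt[int(a)] = int(b)
        start = int(edges[0, 0])
        order = [start]
        node = nxt[start]
        while node != start:
            order.append(node)
            if node not in nxt:
                raise MeshingError(f"membrane loop {loop_id} is not closed")
            node = nxt[node]
        order = np.asarray(order, dtype=int)
        pts = mesh.points[order]
        # normalize to counterclockwise
        x, y = pts[:, 0], pts[:, 1]
        area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        if area2 < 0:
            order = order[::-1]
            pts = mesh.points[order]
        # rotate start to rightmost node (ties -> max y)
        i0 = int(np.lexsort((pts[:, 1], pts[:, 0]))[-1])
        order = np.roll(order, -i0)
        pts = mesh.points[order]
        closed = np.vstack([pts, pts[:1]])
        seg = np.diff(closed, axis=0)
        seglen = np.hypot(seg[:, 0], seg[:, 1])
        s = np.concatenate([[0.0], np.cumsum(seglen[:-1])])
        # outward normal: for a CCW curve rotate the tangent by -90 degrees
        tangent = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
        tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
        normals = np.column_stack([tangent[:, 1], -tangent[:, 0]])
        chain = InterfaceNodeChain(
            node_indices=order,
            s=s,
            label=mesh.loop_labels[loop_id],
            loop=loop_id,
            normals=normals,
        )
        chain._closing_length = float(seglen[-1])
        chains.append(chain)
    return chains


def longest_chain(chains: list[InterfaceNodeChain], label: str) -> InterfaceNodeChain:
    """Select the longest closed chain with the given membrane label (the
    observation convention for the many-loop ER membrane)."""
    cands = [c for c in chains if c.label == label]
    if not cands:
        raise ValueError(f"no chain with label {label!r}")
    return max(cands, key=lambda c: c.total_length)


def write_vtk(mesh: TriMesh, path: str, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the mesh (and optional nodal scalars) as legacy ASCII VTK."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nporefem mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        for x, y in mesh.points:
            f.write(f"{x} {y} 0.0\n")
        nt = len(mesh.triangles)
        f.write(f"CELLS {nt} {4 * nt}\n")
        for tri in mesh.triangles:
            f.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        f.write(f"CELL_TYPES {nt}\n")
        f.write("5\n" * nt)
        f.write(f"CELL_DATA {nt}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(r)) for r in mesh.tri_region) + "\n")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v}" for v in np.asarray(arr, dtype=float)) + "\n")
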