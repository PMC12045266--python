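"""Interface triangulation: conformity, region tags, chains, convergence."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Polygon

from porefem.geometry import make_disc_cell_geometry
from porefem.meshing import (
    MeshingError,
    REGION_NAMES,
    build_interface_chains,
    longest_chain,
    triangulate_with_interfaces,
    write_vtk,
)


@pytest.fixture(scope="module")
def disc_mesh():
    g = make_disc_cell_geometry(4.4, 2.0, 0)
    return g, triangulate_with_interfaces(g, h_bulk=2.0, h_membrane=0.2)


class TestBoxMesh:
    def test_all_extracellular_and_well_shaped(self):
        m = triangulate_with_interfaces(None, h_bulk=1.0, h_membrane=1.0, box=(10.0, 10.0))
        assert np.all(m.tri_region == REGION_NAMES.index("extracellular"))
        assert m.min_angle_deg() >= 15.0
        assert m.triangle_areas().sum() == pytest.approx(100.0, rel=1e-9)


class TestDiscMesh:
    def test_min_angle_bound(self, disc_mesh):
        _, m = disc_mesh
        assert m.min_angle_deg() >= 15.0

    def test_plasma_chain_closed_with_circumference(self, disc_mesh):
        _, m = disc_mesh
        chains = build_interface_chains(m)
        plasma = [c for c in chains if c.label == "plasma"][0]
        assert plasma.total_length == pytest.approx(2 * np.pi * 4.4, rel=2e-2)
        assert plasma.s[0] == 0.0
        assert np.all(np.diff(plasma.s) > 0)

    def test_chain_starts_at_rightmost_node_and_is_ccw(self, disc_mesh):
        _, m = disc_mesh
        for c in build_interface_chains(m):
            pts = m.points[c.node_indices]
            assert pts[0, 0] == pytest.approx(pts[:, 0].max())
            x, y = pts[:, 0], pts[:, 1]
            assert np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y) > 0

    def test_outward_normals(self, disc_mesh):
        _, m = disc_mesh
        plasma = [c for c in build_interface_chains(m) if c.label == "plasma"][0]
        pts = m.points[plasma.node_indices]
        centre = np.array([50.0, 35.0])
        radial = pts - centre
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert np.all(np.einsum("ij,ij->i", radial, plasma.normals) > 0.9)

    def test_region_labels_against_point_in_polygon_oracle(self, disc_mesh):
        g, m = disc_mesh
        centroids = m.points[m.triangles].mean(axis=1)
        in_plasma = shapely.contains_xy(Polygon(g.plasma.vertices), centroids[:, 0], centroids[:, 1])
        in_nuc = shapely.contains_xy(Polygon(g.nucleus.vertices), centroids[:, 0], centroids[:, 1])
        expected = np.zeros(len(centroids), int)
        expected[in_plasma] = REGION_NAMES.index("cytoplasm")
        expected[in_nuc] = REGION_NAMES.index("nucleoplasm")
        # the resampled interface polygon differs from the input polygon by
        # << h near the boundary; all but a sliver fraction must agree
        assert (m.tri_region == expected).mean() > 0.999

    def test_region_areas_match_polygon_areas(self, disc_mesh):
        g, m = disc_mesh
        areas = m.region_areas()
        assert areas["nucleoplasm"] == pytest.approx(Polygon(g.nucleus.vertices).area, rel=1e-2)
        cyto_expected = Polygon(g.plasma.vertices).area - Polygon(g.nucleus.vertices).area
        assert areas["cytoplasm"] == pytest.approx(cyto_expected, rel=1e-2)

    def test_interface_edges_separate_correct_regions(self, disc_mesh):
        """Every interface edge is shared by exactly one inside and one
        outside triangle of its membrane loop (conformity)."""
        _, m = disc_mesh
        edge_key = {}
        for t, tri in enumerate(m.triangles):
            for i in range(3):
                a, b = sorted((tri[i], tri[(i + 1) % 3]))
                edge_key.setdefault((a, b), []).append(t)
        for (a, b), loop in zip(m.interface_edges, m.edge_loop):
            tris = edge_key[tuple(sorted((a, b)))]
            assert len(tris) == 2
            sides = sorted(m.tri_inside_loop[loop][t] for t in tris)
            assert sides == [False, True]


def test_chain_length_converges_under_refinement():
    g = make_disc_cell_geometry(4.4, 2.0, 0)
    lengths = []
    for hm, hb in [(0.3, 2.0), (0.15, 2.0)]:
        m = triangulate_with_interfaces(g, h_bulk=hb, h_membrane=hm)
        plasma = [c for c in build_interface_chains(m) if c.label == "plasma"][0]
        lengths.append(plasma.total_length)
    assert abs(lengths[1] - lengths[0]) / lengths[1] < 5e-3


def test_many_er_loops_chains_and_longest_selector():
    g = make_disc_cell_geometry(20.0, 8.0, 36, er_loop_radius_um=0.8, er_margin_um=0.5)
    m = triangulate_with_interfaces(g, h_bulk=3.0, h_membrane=0.25)
    chains = build_interface_chains(m)
    er = [c for c in chains if c.label == "er"]
    assert len(er) == 36
    best = longest_chain(chains, "er")
    assert best.total_length == max(c.total_length for c in er)
    # plasma remains the longest chain overall
    assert longest_chain(chains, "plasma").total_length > best.total_length


def test_contours_closer_than_h_membrane_rejected():
    g = make_disc_cell_geometry(4.4, 4.3, 0)  # 0.1 um gap
    with pytest.raises(MeshingError):
        triangulate_with_interfaces(g, h_bulk=2.0, h_membrane=0.2)


def test_vtk_export_writes_valid_header(tmp_path, disc_mesh):
    _, m = disc_mesh
    path = tmp_path / "mesh.vtk"
    write_vtk(m, str(path), point_data={"phi": np.zeros(m.n_nodes)})
    text = path.read_text().splitlines()
    assert text[0].startswith("# vtk DataFile")
    assert any(line.startswith("CELL_DATA") for line in text)
    assert any(line.startswith("POINT_DATA") for line in text)
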