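"""Planform construction, triangulation quality, boundary tags, regions."""

import numpy as np
import pytest

from hemoflow.geometry import BifurcationGeometry, GeometryError, build_planform
from hemoflow.meshing import (Mesh, label_regions, rectangle_mesh, triangulate,
                              write_vtk)


def ring_is_simple(ring: np.ndarray) -> bool:
    """O(n^2) all-pairs segment-intersection sweep (independent oracle)."""
    n = len(ring)
    segs = [(ring[i], ring[(i + 1) % n]) for i in range(n)]

    def cross2(a, b):
        return a[0] * b[1] - a[1] * b[0]

    def intersects(p1, p2, p3, p4):
        d1 = cross2(p4 - p3, p1 - p3)
        d2 = cross2(p4 - p3, p2 - p3)
        d3 = cross2(p2 - p1, p3 - p1)
        d4 = cross2(p2 - p1, p4 - p1)
        return (d1 * d2 < 0) and (d3 * d4 < 0)

    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent around the ring
            if intersects(*segs[i], *segs[j]):
                return False
    return True


class TestPlanform:
    def test_geometry_invariants_enforced(self):
        with pytest.raises(GeometryError):
            BifurcationGeometry(bulb_factor=1.7)
        with pytest.raises(GeometryError):
            BifurcationGeometry(bifurcation_angle=95.0)
        with pytest.raises(GeometryError):
            BifurcationGeometry(l_ica=10.0)  # < 3 diameters

    def test_default_outline_is_simple(self, default_planform):
        assert ring_is_simple(default_planform.ring)
        assert default_planform.polygon.is_valid

    def test_wide_angle_still_simple(self):
        pf = build_planform(BifurcationGeometry(bifurcation_angle=89.0))
        assert ring_is_simple(pf.ring)

    def test_no_bulb_means_straight_ica_wall(self):
        pf = build_planform(BifurcationGeometry(bulb_factor=1.0))
        g = pf.geom
        # max transverse extent of ring points along the mid-ICA section
        rel = pf.ring - pf.junction
        s = rel @ pf.e_ica
        r = rel @ pf.n_ica
        mid = (s > 0.3 * g.l_ica * 1e-3) & (s < 0.8 * g.l_ica * 1e-3) & (r > 0)
        assert r[mid].max() <= 0.5 * g.d_ica * 1e-3 + 1e-9

    def test_bulb_widens_outer_wall_to_bulb_factor(self, default_planform):
        pf = default_planform
        g = pf.geom
        rel = pf.ring - pf.junction
        s = rel @ pf.e_ica
        r = rel @ pf.n_ica
        sel = (s > 0) & (s < g.l_ica * 1e-3) & (r > 0)
        max_width = r[sel].max() + 0.5 * g.d_ica * 1e-3
        assert max_width == pytest.approx(g.bulb_factor * g.d_ica * 1e-3,
                                          rel=0.03)


class TestTriangulate:
    def test_quality_and_topology(self, coarse_bifurcation_mesh):
        m = coarse_bifurcation_mesh
        assert m.min_angles_deg().min() >= 20.0
        assert (m.triangle_areas() > 0).all()
        edges = np.unique(np.sort(np.vstack(
            [m.triangles[:, [0, 1]], m.triangles[:, [1, 2]],
             m.triangles[:, [2, 0]]]), axis=1), axis=0)
        euler = m.n_vertices - len(edges) + len(m.triangles)
        assert euler == 1  # triangulated disk

    def test_tag_partition_conserves_perimeter(self, coarse_bifurcation_mesh):
        m = coarse_bifurcation_mesh
        lengths = m.boundary_edge_lengths()
        total = lengths.sum()
        by_tag = sum(lengths[m.boundary_tags == t].sum()
                     for t in ("inlet", "wall", "outlet_ica", "outlet_eca"))
        assert by_tag == pytest.approx(total, rel=1e-12)
        assert set(np.unique(m.boundary_tags)) == {
            "inlet", "wall", "outlet_ica", "outlet_eca"}

    def test_refinement_scaling(self, default_planform):
        m1 = triangulate(default_planform, 1.4e-3)
        m2 = triangulate(default_planform, 0.7e-3)
        ratio = len(m2.triangles) / len(m1.triangles)
        assert 2.8 <= ratio <= 5.2  # ~4x with +/-30%

    def test_invalid_target_h_rejected(self, default_planform):
        from hemoflow.meshing import MeshingError
        with pytest.raises(MeshingError):
            triangulate(default_planform, 0.0)

    def test_area_converges_to_polygon_area(self, default_planform):
        area_poly = default_planform.polygon.area
        e1 = abs(triangulate(default_planform, 1.4e-3).triangle_areas().sum()
                 - area_poly) / area_poly
        e2 = abs(triangulate(default_planform, 0.7e-3).triangle_areas().sum()
                 - area_poly) / area_poly
        assert e2 < e1
        assert e2 < 0.01


class TestRegions:
    def test_labels_partition_wall_vertices(self, coarse_bifurcation_mesh):
        m = coarse_bifurcation_mesh
        nonwall = np.unique(m.boundary_edges[m.boundary_tags != "wall"])
        wall = np.setdiff1d(np.unique(m.edges_with_tag("wall")), nonwall)
        labelled = np.concatenate(list(m.region_labels.values()))
        assert len(labelled) == len(set(labelled))  # disjoint
        assert set(labelled) == set(wall)           # cover

    def test_whole_excludes_inlet_and_outlets(self, coarse_bifurcation_mesh):
        m = coarse_bifurcation_mesh
        labelled = set(np.concatenate(list(m.region_labels.values())))
        for tag in ("inlet", "outlet_ica", "outlet_eca"):
            assert labelled.isdisjoint(np.unique(m.edges_with_tag(tag)))

    def test_zero_bulb_extent_empty_bulb_region(self):
        pf = build_planform(BifurcationGeometry(bulb_extent=0.0,
                                                bulb_factor=1.0))
        m = label_regions(triangulate(pf, 1.2e-3))
        assert len(m.region_labels["ica_bulb"]) == 0
        assert len(m.region_labels["ica"]) > 0


class TestStructuredMesh:
    def test_rectangle_mesh_quality_and_tags(self):
        m = rectangle_mesh(1.0, 1.0, 0.25)
        p = m.vertices[m.triangles]
        emax = max(np.linalg.norm(p[:, i] - p[:, (i + 1) % 3], axis=1).max()
                   for i in range(3))
        assert emax <= 0.25 * np.sqrt(2) + 1e-12
        assert m.min_angles_deg().min() >= 20.0
        assert set(np.unique(m.boundary_tags)) == {"inlet", "wall", "outlet_ica"}


def test_vtk_export_is_readable_ascii(tmp_path, coarse_bifurcation_mesh):
    m = coarse_bifurcation_mesh
    path = tmp_path / "mesh.vtk"
    write_vtk(path, m, point_data={"ones": np.ones(m.n_vertices)})
    text = path.read_text()
    assert text.startswith("# vtk DataFile")
    assert f"POINTS {m.n_vertices} double" in text
    assert "SCALARS ones double 1" in text
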