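"""Triangulation of the bifurcation planform and mesh bookkeeping.

The unstructured mesher is a force-equilibrium (truss-relaxation)
scheme over a scipy Delaunay triangulation with a shapely signed
distance: boundary nodes are fixed at a resampled outline, interior
nodes start on a hexagonal lattice and relax until edge lengths match
the target size field.  This produces the near-uniform, well-shaped
triangles a Taylor-Hood discretization wants without an external mesh
generator.

A mesh knows its boundary edges (directed, interior on the left, so the
outward normal is the right-hand rotation of the edge vector), one tag
per boundary edge (inlet / wall / outlet_ica / outlet_eca), and — after
:func:`label_regions` — a partition of the wall vertices into the
anatomical analysis regions (cca, bifurcation_apex_zone, ica, ica_bulb,
eca).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import shapely
from scipy.spatial import Delaunay

from hemoflow.geometry import BifurcationGeometry, Planform, build_planform


class MeshingError(RuntimeError):
    """Triangulation failure."""


@dataclass
class Mesh:
    """Conforming triangle mesh with tagged boundary and wall regions."""

    vertices: np.ndarray                  # (nv, 2) [m]
    triangles: np.ndarray                 # (nt, 3) int, CCW
    boundary_edges: np.ndarray            # (nb, 2) int, directed CCW
    boundary_tags: np.ndarray             # (nb,) str
    region_labels: Dict[str, np.ndarray] = field(default_factory=dict)
    planform: Optional[Planform] = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges_with_tag(self, tag: str) -> np.ndarray:
        return self.boundary_edges[self.boundary_tags == tag]

    @property
    def wall_vertex_ids(self) -> np.ndarray:
        return np.unique(self.edges_with_tag("wall"))

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        return 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])

    def min_angles_deg(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        ang = np.empty((len(self.triangles), 3))
        for i in range(3):
            a = p[:, (i + 1) % 3] - p[:, i]
            b = p[:, (i + 2) % 3] - p[:, i]
            cosv = np.sum(a * b, axis=1) / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
            ang[:, i] = np.degrees(np.arccos(np.clip(cosv, -1, 1)))
        return ang.min(axis=1)

    def boundary_edge_lengths(self) -> np.ndarray:
        d = self.vertices[self.boundary_edges[:, 1]] - self.vertices[self.boundary_edges[:, 0]]
        return np.hypot(d[:, 0], d[:, 1])


# ------------------------------------------------------------------ helpers

def _resample_ring(ring: np.ndarray, h: float) -> np.ndarray:
    """Uniform arc-length resampling of a closed polyline, preserving
    sharp corners (cap/wall junctions) by snapping the nearest sample."""
    closed = np.vstack([ring, ring[:1]])
    seg = np.diff(closed, axis=0)
    L = np.hypot(seg[:, 0], seg[:, 1])
    keep = L > 1e-14
    closed = np.vstack([closed[:-1][keep], closed[:1]])
    seg = np.diff(closed, axis=0)
    L = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(L)])
    per = cum[-1]
    n = max(12, int(round(per / h)))
    s = np.arange(n) * per / n
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(L) - 1)
    frac = ((s - cum[idx]) / L[idx])[:, None]
    pts = closed[idx] + seg[idx] * frac

    dirs = seg / L[:, None]
    turn = np.sum(dirs * np.roll(dirs, 1, axis=0), axis=1)
    corners = closed[:-1][turn < np.cos(np.deg2rad(25.0))]
    for c in corners:
        j = int(np.argmin(np.sum((pts - c) ** 2, axis=1)))
        pts[j] = c
    # drop samples that collapsed onto a snapped corner
    d = np.hypot(*(pts - np.roll(pts, 1, axis=0)).T)
    return pts[d > 0.25 * h]


def _hex_seed(poly, h: float, clearance: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    ys = np.arange(miny + 0.5 * h, maxy, h * np.sqrt(3) / 2)
    pts = []
    for i, y in enumerate(ys):
        off = 0.0 if i % 2 == 0 else 0.5 * h
        xs = np.arange(minx + 0.5 * h + off, maxx, h)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    if not pts:
        return np.empty((0, 2))
    p = np.vstack(pts)
    inside = shapely.contains_xy(poly, p[:, 0], p[:, 1])
    p = p[inside]
    dist = shapely.distance(shapely.points(p), poly.exterior)
    return p[dist > clearance]


def _delaunay_inside(pts: np.ndarray, poly) -> np.ndarray:
    tri = Delaunay(pts).simplices
    cen = pts[tri].mean(axis=1)
    tri = tri[shapely.contains_xy(poly, cen[:, 0], cen[:, 1])]
    p = pts[tri]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    area = 0.5 * (a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0])
    flip = area < 0
    tri[flip] = tri[flip][:, ::-1]
    return tri


def _boundary_edges_directed(triangles: np.ndarray) -> np.ndarray:
    e = np.vstack([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    key = {(a, b) for a, b in map(tuple, e)}
    return np.array([(a, b) for a, b in key if (b, a) not in key], dtype=int)


def triangulate(planform: Planform, target_h: float, boundary_refine: float = 1.0,
                n_iter: int = 60) -> Mesh:
    """Triangulate a bifurcation planform at edge-length ``target_h`` [m].

    ``boundary_refine`` > 1 shrinks near-wall edges to
    ``target_h / boundary_refine``, grading linearly back to ``target_h``
    in the interior.
    """
    if target_h <= 0:
        raise MeshingError("target_h must be positive")
    poly = planform.polygon
    h_b = target_h / boundary_refine
    fixed = _resample_ring(planform.ring, h_b)
    nfix = len(fixed)

    def hsize(p: np.ndarray) -> np.ndarray:
        if boundary_refine <= 1.0:
            return np.full(len(p), target_h)
        d = shapely.distance(shapely.points(p), poly.exterior)
        return np.minimum(h_b + 0.4 * d, target_h)

    interior = _hex_seed(poly, 0.85 * target_h if boundary_refine <= 1 else h_b, 0.55 * h_b)
    if boundary_refine > 1.0:
        # thin graded seeds: keep with probability (h_b / h(x))^2
        rng = np.random.default_rng(0)
        prob = (h_b / hsize(interior)) ** 2
        interior = interior[rng.random(len(interior)) < prob]
    pts = np.vstack([fixed, interior])
    if len(pts) < 6:
        raise MeshingError("too few points; decrease target_h")

    tri = _delaunay_inside(pts, poly)
    for it in range(n_iter):
        if it % 5 == 0:
            tri = _delaunay_inside(pts, poly)
        edges = np.unique(np.sort(np.vstack(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1), axis=0)
        vec = pts[edges[:, 1]] - pts[edges[:, 0]]
        L = np.hypot(vec[:, 0], vec[:, 1])
        mid = 0.5 * (pts[edges[:, 0]] + pts[edges[:, 1]])
        L0 = hsize(mid)
        L0 = L0 * 1.2 * np.sqrt(np.sum(L ** 2) / np.sum(L0 ** 2))
        fmag = np.maximum(L0 - L, 0.0) / np.maximum(L, 1e-30)
        F = fmag[:, None] * vec
        disp = np.zeros_like(pts)
        np.subtract.at(disp, edges[:, 0], F)
        np.add.at(disp, edges[:, 1], F)
        pts[nfix:] += 0.2 * disp[nfix:]
        # project escaped interior points back inside
        out = ~shapely.contains_xy(poly, pts[nfix:, 0], pts[nfix:, 1])
        if np.any(out):
            idx = np.nonzero(out)[0] + nfix
            for i in idx:
                pt = shapely.points(pts[i])
                b = poly.exterior.interpolate(poly.exterior.project(pt))
                b = np.array([b.x, b.y])
                inward = b - pts[i]
                nrm = np.linalg.norm(inward)
                if nrm > 1e-30:
                    pts[i] = b + 0.4 * h_b * inward / nrm
                cand = shapely.contains_xy(poly, pts[i, 0], pts[i, 1])
                if not cand:
                    pts[i] = b + 1e-3 * h_b * inward / max(nrm, 1e-30)

    tri = _delaunay_inside(pts, poly)
    # drop boundary slivers
    mesh = Mesh(pts, tri, np.empty((0, 2), int), np.empty(0, dtype=object))
    bad = mesh.min_angles_deg() < 5.0
    if np.any(bad):
        tri = tri[~bad]
    # remove unused vertices
    used = np.unique(tri)
    remap = -np.ones(len(pts), int)
    remap[used] = np.arange(len(used))
    pts = pts[used]
    tri = remap[tri]

    bedges = _boundary_edges_directed(tri)
    if len(bedges) == 0:
        raise MeshingError("degenerate triangulation; decrease target_h")
    tags = _tag_boundary(planform, pts, bedges, tol=0.25 * h_b)
    return Mesh(pts, tri, bedges, tags, planform=planform)


def _tag_boundary(planform: Planform, pts: np.ndarray, bedges: np.ndarray,
                  tol: float) -> np.ndarray:
    tags = np.empty(len(bedges), dtype=object)
    for i, (a, b) in enumerate(bedges):
        ka = planform.boundary_kind(pts[a], tol)
        kb = planform.boundary_kind(pts[b], tol)
        km = planform.boundary_kind(0.5 * (pts[a] + pts[b]), tol)
        tags[i] = km if (ka == kb == km and km != "wall") else "wall"
    return tags


def label_regions(mesh: Mesh, geom: BifurcationGeometry | None = None) -> Mesh:
    """Partition wall vertices into anatomical regions (in place).

    Regions: ``cca``, ``bifurcation_apex_zone`` (within 0.5*d_cca of the
    flow-divider apex), ``ica``, ``ica_bulb`` (outer ICA wall within the
    bulb arc), ``eca``.  Inlet/outlet vertices are never labelled, so
    the union of the regions is the study-style "whole artery except
    inlet and outlets" wall set.
    """
    pf = mesh.planform
    if pf is None:
        if geom is None:
            raise MeshingError("mesh has no planform; pass the geometry")
        pf = build_planform(geom)
    wall = mesh.wall_vertex_ids
    if wall.size == 0:
        raise MeshingError("mesh has no wall-tagged boundary (untagged mesh?)")
    nonwall = np.unique(mesh.boundary_edges[mesh.boundary_tags != "wall"])
    # vertices shared between a wall edge and a cap edge belong to the cap
    wall = np.setdiff1d(wall, nonwall)
    labels: Dict[str, list] = {k: [] for k in
                               ("cca", "bifurcation_apex_zone", "ica", "ica_bulb", "eca")}
    for v in wall:
        labels[pf.classify_wall_point(mesh.vertices[v])].append(v)
    mesh.region_labels = {k: np.array(sorted(v), int) for k, v in labels.items()}
    return mesh


# ------------------------------------------------------- structured meshes

def rectangle_mesh(length: float, height: float, h: float,
                   tag_left: str = "inlet", tag_right: str = "outlet_ica",
                   y0: float = 0.0) -> Mesh:
    """Structured crossed-diagonal triangulation of [0, length] x [y0, y0+height].

    Left/right boundaries get the given tags, top/bottom are walls.
    Used for channel verification problems.
    """
    nx = max(2, int(round(length / h)))
    ny = max(2, int(round(height / h)))
    x = np.linspace(0.0, length, nx + 1)
    y = np.linspace(y0, y0 + height, ny + 1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])

    def vid(i, j):
        return i * (ny + 1) + j

    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            if (i + j) % 2 == 0:
                tris += [(a, b, c), (a, c, d)]
            else:
                tris += [(a, b, d), (b, c, d)]
    tri = np.array(tris, int)
    bedges = _boundary_edges_directed(tri)
    mids = 0.5 * (pts[bedges[:, 0]] + pts[bedges[:, 1]])
    tol = 1e-9 * max(length, height)
    tags = np.empty(len(bedges), dtype=object)
    tags[:] = "wall"
    tags[np.abs(mids[:, 0]) < tol] = tag_left
    tags[np.abs(mids[:, 0] - length) < tol] = tag_right
    return Mesh(pts, tri, bedges, tags)


# --------------------------------------------------------------- VTK export

def write_vtk(path: str | Path, mesh: Mesh,
              point_data: Dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK unstructured grid with optional per-vertex data.

    Scalar arrays have shape (nv,), vector arrays (nv, 2) and are padded
    to 3-D as VTK requires.
    """
    nv, nt = len(mesh.vertices), len(mesh.triangles)
    lines = ["# vtk DataFile Version 3.0", "hemoflow mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {nv} double"]
    for x, y in mesh.vertices:
        lines.append(f"{x:.10e} {y:.10e} 0.0")
    lines.append(f"CELLS {nt} {4 * nt}")
    for a, b, c in mesh.triangles:
        lines.append(f"3 {a} {b} {c}")
    lines.append(f"CELL_TYPES {nt}")
    lines.extend(["5"] * nt)
    if point_data:
        lines.append(f"POINT_DATA {nv}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10e}" for v in arr)
            else:
                lines.append(f"VECTORS {name} double")
                lines.extend(f"{v[0]:.10e} {v[1]:.10e} 0.0" for v in arr)
    Path(path).write_text("\n".join(lines) + "\n")
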