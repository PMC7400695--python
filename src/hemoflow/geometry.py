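"""Parametric 2D carotid-bifurcation planform.

The common carotid artery (CCA) runs along +x from the inlet at the
origin; at the junction it splits into the internal carotid (ICA, upper
branch, carrying a bulb on its outer wall) and the external carotid
(ECA, lower branch).  The planform is the closed polygonal outline of
this Y-shaped channel, with morphological fillets at the branch
junctions, standing in for an MRA-derived patient lumen at the level of
flow topology (flow split, apex impingement, bulb recirculation).

Lengths in the configuration are millimetres (clinical convention);
everything returned by :func:`build_planform` is SI metres.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Tuple

import numpy as np
import shapely
from shapely.geometry import Polygon

MM = 1.0e-3


class GeometryError(ValueError):
    """Invalid or degenerate vessel geometry."""


@dataclass(frozen=True)
class BifurcationGeometry:
    """Parametric description of a carotid bifurcation (mm / degrees).

    ``bulb_factor`` is the ratio of the maximum bulb width to the ICA
    diameter (1.0 = no bulb); ``bulb_extent`` the fraction of the ICA
    length occupied by the bulb; ``bifurcation_angle`` the angle between
    the ICA and ECA centerlines.
    """

    d_cca: float = 6.2
    d_ica: float = 4.5
    d_eca: float = 3.6
    bulb_factor: float = 1.2
    bifurcation_angle: float = 50.0
    l_cca: float = 20.0
    l_ica: float = 15.0
    l_eca: float = 12.0
    bulb_extent: float = 0.45

    def __post_init__(self) -> None:
        for name in ("d_cca", "d_ica", "d_eca"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if not (self.d_ica < 1.2 * self.d_cca and self.d_eca < 1.2 * self.d_cca):
            raise GeometryError("branch diameters must be < 1.2 * d_cca")
        if not (1.0 <= self.bulb_factor <= 1.6):
            raise GeometryError("bulb_factor must lie in [1.0, 1.6]")
        if not (10.0 < self.bifurcation_angle < 90.0):
            raise GeometryError("bifurcation_angle must lie in (10, 90) degrees")
        if not (0.0 <= self.bulb_extent < 1.0):
            raise GeometryError("bulb_extent must lie in [0, 1)")
        for lname, dname in (("l_cca", "d_cca"), ("l_ica", "d_ica"), ("l_eca", "d_eca")):
            if getattr(self, lname) < 3.0 * getattr(self, dname):
                raise GeometryError(f"{lname} must be >= 3 * {dname} (entrance length)")

    def scaled(self, diam_factors: Tuple[float, float, float], bulb_factor: float | None = None
               ) -> "BifurcationGeometry":
        fc, fi, fe = diam_factors
        return replace(self, d_cca=self.d_cca * fc, d_ica=self.d_ica * fi,
                       d_eca=self.d_eca * fe,
                       bulb_factor=self.bulb_factor if bulb_factor is None else bulb_factor)


@dataclass(frozen=True)
class Planform:
    """Closed outline of the bifurcation plus the analytic frame needed
    for boundary tagging and wall-region labelling (all SI metres)."""

    geom: BifurcationGeometry
    ring: np.ndarray            # (N, 2) CCW closed outline, last != first
    polygon: Polygon
    junction: np.ndarray        # branch origin on the CCA axis
    apex: np.ndarray            # flow-divider apex (inner-wall intersection)
    e_cca: np.ndarray
    e_ica: np.ndarray
    n_ica: np.ndarray           # ICA left normal: outer (bulb) side
    e_eca: np.ndarray
    n_eca: np.ndarray
    bulb_s: Tuple[float, float]  # arc range of the bulb along the ICA axis

    @property
    def inlet_halfwidth(self) -> float:
        return 0.5 * self.geom.d_cca * MM

    def outlet_plane(self, branch: str) -> Tuple[np.ndarray, np.ndarray]:
        """(point, axis direction) of an outlet cap plane."""
        if branch == "ica":
            return self.junction + self.geom.l_ica * MM * self.e_ica, self.e_ica
        if branch == "eca":
            return self.junction + self.geom.l_eca * MM * self.e_eca, self.e_eca
        raise GeometryError(f"unknown branch {branch!r}")

    # -- boundary classification -------------------------------------
    def boundary_kind(self, p: np.ndarray, tol: float) -> str:
        """Classify a boundary point as inlet / outlet_ica / outlet_eca / wall."""
        if abs(p[0]) < tol:
            return "inlet"
        for branch in ("ica", "eca"):
            pt, e = self.outlet_plane(branch)
            if abs(float((p - pt) @ e)) < tol:
                return f"outlet_{branch}"
        return "wall"

    def classify_wall_point(self, p: np.ndarray) -> str:
        """Wall-region label: cca / bifurcation_apex_zone / ica / ica_bulb / eca.

        The apex zone takes precedence (within 0.5*d_cca of the apex);
        then ICA wall points on the outer side within the bulb arc are
        the bulb; remaining points go to the branch whose centerline
        tube they fall in, else to the CCA.
        """
        g = self.geom
        if np.linalg.norm(p - self.apex) < 0.5 * g.d_cca * MM:
            return "bifurcation_apex_zone"
        rel = p - self.junction
        s_i = float(rel @ self.e_ica)
        r_i = float(rel @ self.n_ica)
        s_e = float(rel @ self.e_eca)
        r_e = float(rel @ self.n_eca)
        # normalized transverse distance per branch (with bulb widening)
        if s_i > 0:
            w_out = 0.5 * g.d_ica * MM + self._bulb_bump(s_i)
            w_in = 0.5 * g.d_ica * MM
            score_i = r_i / w_out if r_i >= 0 else -r_i / w_in
        else:
            score_i = np.inf
        score_e = abs(r_e) / (0.5 * g.d_eca * MM) if s_e > 0 else np.inf
        if np.isfinite(score_i) and score_i <= score_e:
            if self.bulb_s[0] <= s_i <= self.bulb_s[1] and r_i > 0:
                return "ica_bulb"
            return "ica"
        if np.isfinite(score_e):
            return "eca"
        return "cca"

    def _bulb_bump(self, s: float) -> float:
        s0, s1 = self.bulb_s
        if s1 <= s0 or not (s0 <= s <= s1):
            return 0.0
        t = (s - s0) / (s1 - s0)
        extra = (self.geom.bulb_factor - 1.0) * self.geom.d_ica * MM
        return extra * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))

    def downstream_direction(self, p: np.ndarray) -> np.ndarray:
        """Unit direction of forward (inlet-to-outlet) flow near a wall point,
        used to fix the sign convention of wall shear stress."""
        rel = p - self.junction
        s_i = float(rel @ self.e_ica)
        s_e = float(rel @ self.e_eca)
        if s_i <= 0 and s_e <= 0:
            return self.e_cca
        label = self.classify_wall_point(p)
        if label in ("ica", "ica_bulb"):
            return self.e_ica
        if label == "eca":
            return self.e_eca
        if label == "bifurcation_apex_zone":
            return self.e_ica if s_i >= s_e else self.e_eca
        return self.e_cca


def _line_intersection(p1, e1, p2, e2) -> np.ndarray:
    A = np.column_stack([e1, -e2])
    t = np.linalg.solve(A, p2 - p1)
    return p1 + t[0] * e1


def build_planform(geom: BifurcationGeometry, wall_resolution: float = 0.25,
                   fillet_radius: float | None = None) -> Planform:
    """Construct the closed bifurcation outline.

    The outline is the union of three straight channel strips (CCA, ICA
    with the bulb widening on its outer wall, ECA), morphologically
    smoothed (dilate-erode-dilate with round joins) to give C1-continuous
    fillets at the branch junctions, then clipped by the inlet plane and
    the two outlet planes so the caps are straight.

    Parameters
    ----------
    wall_resolution : float
        Sampling step along branch walls, mm.
    fillet_radius : float, optional
        Fillet scale, mm; default ``0.35 * d_eca``.
    """
    g = geom
    r_fillet = (0.35 * g.d_eca if fillet_radius is None else fillet_radius) * MM
    half = np.deg2rad(g.bifurcation_angle) / 2.0
    J = np.array([g.l_cca * MM, 0.0])
    e_cca = np.array([1.0, 0.0])
    e_ica = np.array([np.cos(half), np.sin(half)])
    n_ica = np.array([-np.sin(half), np.cos(half)])
    e_eca = np.array([np.cos(half), -np.sin(half)])
    n_eca = np.array([np.sin(half), np.cos(half)])

    ds = wall_resolution * MM
    over = 1.5 * g.d_cca * MM   # branch overlap back into the CCA
    pad = 2.0 * r_fillet        # extra length trimmed off by the clip

    bulb_len = g.bulb_extent * g.l_ica * MM
    bulb_s0 = 0.06 * g.l_ica * MM
    bulb = (bulb_s0, bulb_s0 + bulb_len)

    def branch_strip(e, n, length, w_in, w_out, bump=None) -> Polygon:
        s = np.arange(-over, length + pad + ds, ds)
        c = J[None, :] + s[:, None] * e[None, :]
        wo = np.full_like(s, w_out)
        if bump is not None:
            wo = wo + np.array([bump(si) for si in s])
        left = c + wo[:, None] * n[None, :]
        right = c - w_in * n[None, :]
        return Polygon(np.vstack([left, right[::-1]]))

    pieces = [
        Polygon([(-pad, -0.5 * g.d_cca * MM), (J[0] + 0.5 * g.d_cca * MM, -0.5 * g.d_cca * MM),
                 (J[0] + 0.5 * g.d_cca * MM, 0.5 * g.d_cca * MM), (-pad, 0.5 * g.d_cca * MM)]),
        branch_strip(e_ica, n_ica, g.l_ica * MM, 0.5 * g.d_ica * MM, 0.5 * g.d_ica * MM,
                     bump=lambda s: _bump(s, bulb, (g.bulb_factor - 1.0) * g.d_ica * MM)),
        branch_strip(e_eca, n_eca, g.l_eca * MM, 0.5 * g.d_eca * MM, 0.5 * g.d_eca * MM),
    ]
    union = shapely.unary_union(pieces)
    if union.geom_type != "Polygon":
        raise GeometryError("branch strips do not form a single connected lumen")
    # closing (fill the apex notch to a fillet) then opening (round convex corners)
    smooth = union.buffer(r_fillet, join_style="round", quad_segs=12)
    smooth = smooth.buffer(-2.0 * r_fillet, join_style="round", quad_segs=12)
    smooth = smooth.buffer(r_fillet, join_style="round", quad_segs=12)
    if smooth.geom_type != "Polygon" or not smooth.is_valid:
        raise GeometryError("smoothing produced an invalid outline "
                            "(check bifurcation_angle / bulb_factor)")

    big = 10.0 * (g.l_cca + g.l_ica) * MM

    def halfplane(point, inward) -> Polygon:
        # rectangle on the 'inward' side of the line through `point` with normal `inward`
        t = np.array([-inward[1], inward[0]])
        p0 = point - big * t
        p1 = point + big * t
        return Polygon([p0, p1, p1 + big * inward, p0 + big * inward])

    clip = halfplane(np.array([0.0, 0.0]), np.array([1.0, 0.0]))
    clip = clip.intersection(halfplane(J + g.l_ica * MM * e_ica, -e_ica))
    clip = clip.intersection(halfplane(J + g.l_eca * MM * e_eca, -e_eca))
    poly = smooth.intersection(clip)
    if poly.geom_type != "Polygon" or not poly.is_valid or poly.is_empty:
        raise GeometryError("clipping the smoothed outline failed "
                            "(geometry too short for its diameters?)")
    poly = shapely.geometry.polygon.orient(poly, sign=1.0)  # CCW
    ring = np.asarray(poly.exterior.coords)[:-1]

    apex = _line_intersection(J - 0.5 * g.d_ica * MM * n_ica, e_ica,
                              J + 0.5 * g.d_eca * MM * n_eca, e_eca)
    pf = Planform(geom=g, ring=ring, polygon=poly, junction=J, apex=apex,
                  e_cca=e_cca, e_ica=e_ica, n_ica=n_ica, e_eca=e_eca, n_eca=n_eca,
                  bulb_s=bulb)
    if not poly.is_simple:
        raise GeometryError("outline self-intersects (extreme parameters)")
    return pf


def _bump(s: float, interval: Tuple[float, float], extra: float) -> float:
    s0, s1 = interval
    if s1 <= s0 or not (s0 <= s <= s1):
        return 0.0
    t = (s - s0) / (s1 - s0)
    return extra * 0.5 * (1.0 - np.cos(2.0 * np.pi * t))


def geometry_to_dict(geom: BifurcationGeometry) -> Dict[str, float]:
    return {k: float(getattr(geom, k)) for k in (
        "d_cca", "d_ica", "d_eca", "bulb_factor", "bifurcation_angle",
        "l_cca", "l_ica", "l_eca", "bulb_extent")}


def geometry_from_dict(d: Dict[str, float]) -> BifurcationGeometry:
    return BifurcationGeometry(**{k: float(v) for k, v in d.items()})
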