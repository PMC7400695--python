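"""Shear-rate and wall-shear-stress extraction and cardiac-cycle summaries.

Wall shear stress is the tangential component of the boundary traction
t = sigma . n with sigma = -p I + 2 mu(gamma_dot) D(u), evaluated at the
midside node of every wall edge from the discrete velocity gradient of
the adjacent element.  The sign convention follows the downstream
(inlet-to-outlet) direction of the local branch, so attached forward
flow gives positive values and recirculating flow negative ones.

Cycle summaries use a fixed reduction protocol: length-weighted spatial
mean of the quantity magnitude over a wall region at each saved time,
then minimum / trapezoid time-average / maximum over the retained
cardiac cycle — one scalar triple per region, the shape of a per-artery
study table row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable

import numpy as np

from hemoflow.fem import _p1_basis, _p2_basis, shear_rate_from_grad
from hemoflow.meshing import Mesh
from hemoflow.rheology import CassonParams, RegularizationConfig, apparent_viscosity
from hemoflow.solver import FlowField


class RegionError(ValueError):
    """Empty or unknown wall region."""


# reference coordinates of the midside node of each local edge
_EDGE_MID_REF = {0: (0.5, 0.0), 1: (0.5, 0.5), 2: (0.0, 0.5)}


@dataclass
class WallSamples:
    """Time series of wall quantities at wall-edge midside points."""

    midpoints: np.ndarray       # (ns, 2)
    lengths: np.ndarray         # (ns,) edge lengths (spatial weights)
    normals: np.ndarray         # (ns, 2) outward
    regions: np.ndarray         # (ns,) str region label
    times: np.ndarray           # (nt,)
    wss_signed: np.ndarray      # (nt, ns) [Pa]
    shear_rate: np.ndarray      # (nt, ns) [1/s]

    def region_mask(self, region: str) -> np.ndarray:
        if region == "whole":
            mask = np.ones(len(self.midpoints), bool)
        elif region == "ica":
            mask = np.isin(self.regions, ("ica", "ica_bulb"))
        else:
            mask = self.regions == region
        if not np.any(mask):
            raise RegionError(f"region {region!r} has no wall samples")
        return mask


@dataclass
class HemodynamicSummary:
    """Min / time-averaged / max of one wall quantity over one region."""

    region: str
    quantity: str               # "wss" or "shear_rate"
    minimal: float
    time_averaged: float
    maximal: float
    side: str = ""
    condition: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        if not (self.minimal <= self.time_averaged + 1e-12
                and self.time_averaged <= self.maximal + 1e-12):
            raise ValueError("summary ordering violated: "
                             f"{self.minimal}, {self.time_averaged}, {self.maximal}")


def shear_rate_field(flow: FlowField, mesh: Mesh) -> np.ndarray:
    """(nt, nv) vertex shear-rate magnitude, element values (at centroids)
    projected to vertices by area weighting."""
    th = flow.space
    if th.mesh is not mesh and len(mesh.vertices) != th.n_p1:
        raise ValueError("flow field and mesh do not match")
    cen = np.array([[1 / 3, 1 / 3]])
    _, gref = _p2_basis(cen)
    gphys = np.einsum("qik,tkd->tid", gref, th.invJ)   # (nt_elem, 6, 2)
    areas = 0.5 * th.detJ
    out = np.empty((len(flow.times), th.n_p1))
    wsum = np.zeros(th.n_p1)
    np.add.at(wsum, mesh.triangles.ravel(), np.repeat(areas, 3))
    for it, u in enumerate(flow.velocity):
        g = np.einsum("tid,tic->tcd", gphys, u[th.t6])
        gd = shear_rate_from_grad(g)
        acc = np.zeros(th.n_p1)
        np.add.at(acc, mesh.triangles.ravel(), np.repeat(gd * areas, 3))
        out[it] = acc / wsum
    return out


def wall_shear_stress(flow: FlowField, mesh: Mesh, casson: CassonParams,
                      reg: RegularizationConfig = RegularizationConfig(),
                      newtonian_mu: float | None = None) -> WallSamples:
    """Evaluate signed wall shear stress and wall shear rate over time.

    Samples live at the midside node of every wall-tagged boundary edge;
    the viscosity entering the traction is the same regularized Casson
    law the solver used (or the constant ``newtonian_mu``).
    """
    th = flow.space
    tri = mesh.triangles

    # map each wall boundary edge to (triangle, local edge)
    pair_to_tri: Dict[tuple, tuple] = {}
    for t, (a, b, c) in enumerate(tri):
        for le, (i, j) in enumerate(((a, b), (b, c), (c, a))):
            pair_to_tri[tuple(sorted((i, j)))] = (t, le)

    wall_sel = mesh.boundary_tags == "wall"
    edges = mesh.boundary_edges[wall_sel]
    ns = len(edges)
    if ns == 0:
        raise RegionError("mesh has no wall-tagged boundary edges")

    tids = np.empty(ns, int)
    refpts = np.empty((ns, 2))
    for s, (a, b) in enumerate(edges):
        t, le = pair_to_tri[tuple(sorted((a, b)))]
        tids[s] = t
        refpts[s] = _EDGE_MID_REF[le]

    # P2/P1 basis gradients and values at each sample's reference point
    _, gref = _p2_basis(refpts)                        # (ns, 6, 2)
    psi, _ = _p1_basis(refpts)                         # (ns, 3)
    gphys = np.einsum("sik,skd->sid", gref, th.invJ[tids])

    vec = mesh.vertices[edges[:, 1]] - mesh.vertices[edges[:, 0]]
    lengths = np.hypot(vec[:, 0], vec[:, 1])
    tangents = vec / lengths[:, None]
    normals = np.column_stack([vec[:, 1], -vec[:, 0]]) / lengths[:, None]
    mids = 0.5 * (mesh.vertices[edges[:, 0]] + mesh.vertices[edges[:, 1]])

    pf = mesh.planform
    regions = np.empty(ns, dtype=object)
    downstream = np.empty((ns, 2))
    for s in range(ns):
        if pf is not None:
            regions[s] = pf.classify_wall_point(mids[s])
            downstream[s] = pf.downstream_direction(mids[s])
        else:
            regions[s] = "wall"
            downstream[s] = (1.0, 0.0)
    # orient tangent along the downstream direction
    flip = np.sum(tangents * downstream, axis=1) < 0
    tangents[flip] *= -1.0

    t6s = th.t6[tids]
    tri_s = tri[tids]
    nt = len(flow.times)
    wss = np.empty((nt, ns))
    gdot = np.empty((nt, ns))
    for it, (u, p) in enumerate(zip(flow.velocity, flow.pressure)):
        g = np.einsum("sid,sic->scd", gphys, u[t6s])   # du_c/dx_d
        gd = shear_rate_from_grad(g)
        if newtonian_mu is not None:
            mu = np.full(ns, newtonian_mu)
        else:
            mu = apparent_viscosity(casson, gd, reg)
        ps = np.einsum("si,si->s", psi, p[tri_s])
        D = 0.5 * (g + np.swapaxes(g, 1, 2))
        trac = -ps[:, None] * normals + 2.0 * mu[:, None] * \
            np.einsum("scd,sd->sc", D, normals)
        # sigma.n_out is the wall-on-fluid traction; the hemodynamic WSS is
        # the equal-and-opposite fluid-on-wall drag, positive downstream
        wss[it] = -np.einsum("sc,sc->s", trac, tangents)
        gdot[it] = gd
    return WallSamples(mids, lengths, normals, regions, flow.times, wss, gdot)


def summarize(samples: WallSamples, region: str, quantity: str = "wss"
              ) -> HemodynamicSummary:
    """Reduce a wall time series to (minimal, time-averaged, maximal).

    Protocol: length-weighted spatial mean of the quantity magnitude over
    the region at each saved time; then minimum, trapezoid time average
    and maximum over the retained cycle.
    """
    mask = samples.region_mask(region)
    if quantity == "wss":
        vals = np.abs(samples.wss_signed[:, mask])
    elif quantity == "shear_rate":
        vals = samples.shear_rate[:, mask]
    else:
        raise ValueError("quantity must be 'wss' or 'shear_rate'")
    w = samples.lengths[mask]
    series = vals @ w / w.sum()
    t = samples.times
    if len(t) > 1:
        avg = float(np.trapezoid(series, t) / (t[-1] - t[0]))
    else:
        avg = float(series[0])
    return HemodynamicSummary(region=region, quantity=quantity,
                              minimal=float(series.min()),
                              time_averaged=avg,
                              maximal=float(series.max()))


def detect_recirculation(samples: WallSamples, region: str) -> float:
    """Length-and-time fraction of the region with negative signed wall
    shear stress (near-wall flow reversal)."""
    mask = samples.region_mask(region)
    w = samples.lengths[mask]
    t = samples.times
    if len(t) > 1:
        tw = np.zeros(len(t))
        tw[:-1] += 0.5 * np.diff(t)
        tw[1:] += 0.5 * np.diff(t)
    else:
        tw = np.ones(1)
    neg = (samples.wss_signed[:, mask] < 0.0).astype(float)
    return float((tw @ neg @ w) / (tw.sum() * w.sum()))


def summarize_all(samples: WallSamples, regions: Iterable[str],
                  quantities: Iterable[str] = ("shear_rate", "wss"),
                  **ids) -> list[HemodynamicSummary]:
    """Summaries for every (region, quantity) pair, carrying identifying
    metadata (side / condition / participant_id keyword fields)."""
    out = []
    for region in regions:
        for q in quantities:
            s = summarize(samples, region, q)
            for k, v in ids.items():
                setattr(s, k, v)
            out.append(s)
    return out
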