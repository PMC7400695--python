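"""Taylor-Hood (P2 velocity / P1 pressure) finite elements on triangles.

The inf-sup stable P2/P1 pair is the workhorse discretization for
incompressible flow on simplicial meshes.  This module owns everything
that depends only on the mesh: quadrature, basis gradients, the constant
matrices (mass, pressure stiffness, gradient/divergence couplings) and
boundary bookkeeping (P2 boundary nodes, inlet parabola, boundary flux).
The time-stepping logic lives in :mod:`hemoflow.solver`.

Quadrature is a 7-point degree-5 rule, exact for every product appearing
in the variable-viscosity momentum operator except the convective term,
for which it is a standard, stable under-integration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import scipy.sparse as sp

from hemoflow.meshing import Mesh

# 7-point degree-5 rule (barycentric points, weights summing to 1/2)
_A1, _B1 = 0.059715871789770, 0.470142064105115
_A2, _B2 = 0.797426985353087, 0.101286507323456
_QPTS = np.array([
    [1 / 3, 1 / 3],
    [_B1, _B1], [_A1, _B1], [_B1, _A1],
    [_B2, _B2], [_A2, _B2], [_B2, _A2],
])
_QW = 0.5 * np.array([
    0.225,
    0.132394152788506, 0.132394152788506, 0.132394152788506,
    0.125939180544827, 0.125939180544827, 0.125939180544827,
])
NQ = len(_QW)


def _p2_basis(xi: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """P2 values (nq, 6) and reference gradients (nq, 6, 2).

    Local nodes: 0,1,2 vertices; 3 = mid(0,1); 4 = mid(1,2); 5 = mid(2,0).
    """
    x, y = xi[:, 0], xi[:, 1]
    l0, l1, l2 = 1 - x - y, x, y
    N = np.stack([l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
                  4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0], axis=1)
    d0 = np.array([-1.0, -1.0])
    d1 = np.array([1.0, 0.0])
    d2 = np.array([0.0, 1.0])
    G = np.empty((len(x), 6, 2))
    G[:, 0] = (4 * l0 - 1)[:, None] * d0
    G[:, 1] = (4 * l1 - 1)[:, None] * d1
    G[:, 2] = (4 * l2 - 1)[:, None] * d2
    G[:, 3] = 4 * (l0[:, None] * d1 + l1[:, None] * d0)
    G[:, 4] = 4 * (l1[:, None] * d2 + l2[:, None] * d1)
    G[:, 5] = 4 * (l2[:, None] * d0 + l0[:, None] * d2)
    return N, G


def _p1_basis(xi: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x, y = xi[:, 0], xi[:, 1]
    N = np.stack([1 - x - y, x, y], axis=1)
    G = np.broadcast_to(np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]),
                        (len(x), 3, 2)).copy()
    return N, G


@dataclass
class BoundaryEdgeData:
    """P2 view of the tagged boundary: per edge its three P2 nodes
    (end, midside, end), length, outward unit normal and tag."""

    nodes: np.ndarray      # (nb, 3) int
    lengths: np.ndarray    # (nb,)
    normals: np.ndarray    # (nb, 2) outward
    tags: np.ndarray       # (nb,) str


class TaylorHood:
    """Mesh-bound P2/P1 function-space pair with cached operators."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        tri = mesh.triangles
        nv = mesh.n_vertices

        # global edge numbering for P2 midside nodes
        pairs = np.sort(np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1)
        edges, inverse = np.unique(pairs, axis=0, return_inverse=True)
        ne = len(edges)
        nt = len(tri)
        self.edges = edges
        self.n_p2 = nv + ne
        self.n_p1 = nv
        loc = inverse.reshape(3, nt).T            # local edges (0,1),(1,2),(2,0)
        self.t6 = np.hstack([tri, nv + loc])      # (nt, 6)

        self.p2_coords = np.vstack([mesh.vertices,
                                    0.5 * (mesh.vertices[edges[:, 0]] + mesh.vertices[edges[:, 1]])])

        v = mesh.vertices[tri]
        J = np.stack([v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]], axis=2)  # (nt,2,2) columns
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        if np.any(detJ <= 0):
            raise ValueError("mesh contains non-positively-oriented triangles")
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1] / detJ
        invJ[:, 0, 1] = -J[:, 0, 1] / detJ
        invJ[:, 1, 0] = -J[:, 1, 0] / detJ
        invJ[:, 1, 1] = J[:, 0, 0] / detJ
        self.detJ = detJ
        self.invJ = invJ

        self.phi2, gref2 = _p2_basis(_QPTS)
        self.phi1, gref1 = _p1_basis(_QPTS)
        # physical gradients: G[t,q,i,d] = gref[q,i,k] invJ[t,k,d]
        self.grad2 = np.einsum("qik,tkd->tqid", gref2, invJ)
        self.grad1 = np.einsum("ik,tkd->tid", gref1[0], invJ)  # constant per element
        self.wdet = _QW[None, :] * detJ[:, None]               # (nt, nq)

        # constant element and global matrices
        self.Melem = np.einsum("tq,qi,qj->tij", self.wdet, self.phi2, self.phi2)
        rows = np.repeat(self.t6, 6, axis=1).ravel()
        cols = np.tile(self.t6, (1, 6)).ravel()
        self._p2_rows, self._p2_cols = rows, cols
        self.M2 = sp.csr_matrix((self.Melem.ravel(), (rows, cols)),
                                shape=(self.n_p2, self.n_p2))
        self.Mlump = np.asarray(self.M2.sum(axis=1)).ravel()

        # divergence coupling  D_d[q,j] = int psi_q dN_j/dx_d ; its transpose
        # is the pressure-gradient block of the saddle-point system
        Dx_e = np.einsum("tq,qj,tqi->tji", self.wdet, self.phi1,
                         self.grad2[:, :, :, 0])
        Dy_e = np.einsum("tq,qj,tqi->tji", self.wdet, self.phi1, self.grad2[:, :, :, 1])
        rd = np.repeat(tri, 6, axis=1).ravel()
        cd = np.tile(self.t6, (1, 3)).ravel()
        self.Dx = sp.csr_matrix((Dx_e.ravel(), (rd, cd)), shape=(nv, self.n_p2))
        self.Dy = sp.csr_matrix((Dy_e.ravel(), (rd, cd)), shape=(nv, self.n_p2))

        self.boundary = self._build_boundary()
        self._edge_index = {tuple(e): nv + i for i, e in enumerate(map(tuple, edges))}

    # ------------------------------------------------------------ boundary
    def _build_boundary(self) -> BoundaryEdgeData:
        mesh = self.mesh
        nv = mesh.n_vertices
        idx = {tuple(e): i for i, e in enumerate(map(tuple, self.edges))}
        be = mesh.boundary_edges
        nodes = np.empty((len(be), 3), int)
        for i, (a, b) in enumerate(be):
            nodes[i] = (a, nv + idx[tuple(sorted((a, b)))], b)
        vec = mesh.vertices[be[:, 1]] - mesh.vertices[be[:, 0]]
        lengths = np.hypot(vec[:, 0], vec[:, 1])
        normals = np.column_stack([vec[:, 1], -vec[:, 0]]) / lengths[:, None]
        return BoundaryEdgeData(nodes, lengths, normals, mesh.boundary_tags)

    def p2_nodes_with_tag(self, tag_prefix: str) -> np.ndarray:
        b = self.boundary
        sel = np.array([t.startswith(tag_prefix) for t in b.tags])
        return np.unique(b.nodes[sel])

    def boundary_flux(self, u: np.ndarray, tag_prefix: str) -> float:
        """Integral of u.n over all boundary edges whose tag starts with
        ``tag_prefix`` (Simpson on the quadratic trace: exact)."""
        b = self.boundary
        sel = np.array([t.startswith(tag_prefix) for t in b.tags])
        total = 0.0
        for nodes, L, n in zip(b.nodes[sel], b.lengths[sel], b.normals[sel]):
            un = u[nodes] @ n
            total += L / 6.0 * (un[0] + 4.0 * un[1] + un[2])
        return float(total)

    # --------------------------------------------------------- evaluation
    def velocity_at_qp(self, u: np.ndarray) -> np.ndarray:
        """(nt, nq, 2) velocity values from nodal (n_p2, 2)."""
        return np.einsum("qi,tic->tqc", self.phi2, u[self.t6])

    def velocity_grad_at_qp(self, u: np.ndarray) -> np.ndarray:
        """(nt, nq, 2, 2) gradient du_c/dx_d."""
        return np.einsum("tqid,tic->tqcd", self.grad2, u[self.t6])

    def shear_rate_at_qp(self, u: np.ndarray) -> np.ndarray:
        g = self.velocity_grad_at_qp(u)
        return shear_rate_from_grad(g)

    # ----------------------------------------------------------- assembly
    def assemble_momentum(self, mu_q: np.ndarray, w: np.ndarray,
                          rho: float, dt: float,
                          backflow: bool = True) -> sp.csr_matrix:
        """Scalar momentum operator  (rho/dt) M + C(w) + K(mu),  shared by
        both velocity components.

        K is the gradient (Laplacian) viscous form int mu grad u . grad v,
        matching the mu del^2 u momentum equation; its natural boundary
        condition is the classical do-nothing outflow, which leaves fully
        developed profiles undisturbed at the outlets.  (For unidirectional
        flows this form coincides with the full stress-divergence form,
        so channel benchmarks are unaffected by the choice.)
        C is the skew-symmetric convection rho (w.grad u).v
        + rho/2 (div w)(u.v) with ``w`` the previous-step velocity.
        Lumped backflow stabilization rho/2 (w.n)_- u.v is added on outlet
        edges; it vanishes unless flow re-enters there.
        """
        G = self.grad2
        mw = mu_q * self.wdet
        K = np.einsum("tq,tqid,tqjd->tij", mw, G, G)

        wq = self.velocity_at_qp(w)
        wg = self.velocity_grad_at_qp(w)
        divw = wg[:, :, 0, 0] + wg[:, :, 1, 1]
        wdotg = np.einsum("tqd,tqjd->tqj", wq, G)
        C = rho * np.einsum("tq,qi,tqj->tij", self.wdet, self.phi2, wdotg) \
            + 0.5 * rho * np.einsum("tq,tq,qi,qj->tij", self.wdet, divw,
                                    self.phi2, self.phi2)
        elem = (rho / dt) * self.Melem + C + K
        A = sp.csr_matrix((elem.ravel(), (self._p2_rows, self._p2_cols)),
                          shape=(self.n_p2, self.n_p2))
        if backflow:
            A_bf = self._backflow_matrix(w, rho)
            if A_bf is not None:
                A = A + A_bf
        return A

    def _backflow_matrix(self, w: np.ndarray, rho: float) -> sp.csr_matrix | None:
        b = self.boundary
        sel = np.array([t.startswith("outlet") for t in b.tags])
        if not np.any(sel):
            return None
        idx, val = [], []
        simpson = np.array([1.0, 4.0, 1.0]) / 6.0
        for nodes, L, nrm in zip(b.nodes[sel], b.lengths[sel], b.normals[sel]):
            beta = 0.5 * rho * np.maximum(-(w[nodes] @ nrm), 0.0)
            if np.any(beta > 0):
                idx.extend(nodes)
                val.extend(L * simpson * beta)
        if not idx:
            return None
        return sp.csr_matrix((np.asarray(val), (np.asarray(idx), np.asarray(idx))),
                             shape=(self.n_p2, self.n_p2))


def shear_rate_from_grad(g: np.ndarray) -> np.ndarray:
    """Shear-rate magnitude sqrt(2 D:D) from velocity gradients (..., 2, 2)."""
    dxx = g[..., 0, 0]
    dyy = g[..., 1, 1]
    dxy = g[..., 0, 1] + g[..., 1, 0]
    return np.sqrt(2.0 * dxx ** 2 + 2.0 * dyy ** 2 + dxy ** 2)


def apply_dirichlet(A: sp.csr_matrix, rhs: np.ndarray,
                    dofs: np.ndarray, values: np.ndarray) -> Tuple[sp.csr_matrix, np.ndarray]:
    """Row-replacement Dirichlet enforcement: constrained rows become
    identity rows and the rhs takes the boundary values."""
    n = A.shape[0]
    mask = np.ones(n)
    mask[dofs] = 0.0
    D = sp.diags(mask)
    Ibc = sp.csr_matrix((np.ones(len(dofs)), (dofs, dofs)), shape=(n, n))
    A2 = (D @ A + Ibc).tocsc()
    rhs2 = rhs.copy()
    rhs2[dofs] = values
    return A2, rhs2


def inlet_profile(th: TaylorHood, v_mean: float) -> Tuple[np.ndarray, np.ndarray]:
    """Parabolic inlet velocity for the tagged inlet cap.

    Returns (P2 node ids, (n, 2) velocity values) with centerline speed
    1.5 * v_mean along the inward normal, zero at the cap corners, so the
    depth-1 flux equals v_mean * cap width.
    """
    b = th.boundary
    sel = b.tags == "inlet"
    if not np.any(sel):
        raise ValueError("mesh has no inlet-tagged boundary")
    nodes = np.unique(b.nodes[sel])
    coords = th.p2_coords[nodes]
    inward = -np.mean(b.normals[sel], axis=0)
    inward /= np.linalg.norm(inward)
    tang = np.array([-inward[1], inward[0]])
    s = coords @ tang
    center = 0.5 * (s.min() + s.max())
    halfwidth = 0.5 * (s.max() - s.min())
    xi = (s - center) / halfwidth
    speed = 1.5 * v_mean * (1.0 - xi ** 2)
    return nodes, speed[:, None] * inward[None, :]
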