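"""Quadratic Lagrange finite-element core on triangle meshes.

Internal machinery shared by the electromagnetic and bioheat solvers:
P2 degree-of-freedom numbering (vertices + edge midpoints), Dunavant
triangle quadrature, Gauss edge quadrature, and vectorized assembly of the
axisymmetric bilinear forms.  All volume integrals carry the revolved
measure r dr dz with the 2*pi factor left to the caller.

Two bilinear forms are assembled:

* ``grad``: [c1 * grad(u).grad(v) + c0 * u v] r dr dz   (scalar diffusion)
* ``curl_w``: [c1 * grad(w).grad(g) + c0 * w g] (1/r) dr dz — the
  curl-curl form of an azimuthal field H_phi written in the scaled
  variable w = r H_phi, since curl((w/r) phi_hat) = ((-dw/dz)/r,
  (dw/dr)/r).  The coaxial TEM mode is w = const, exactly representable,
  which keeps thin high-curvature coax layers accurate on coarse radial
  meshes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

# Dunavant degree-4 rule, 6 points (barycentric, weights sum to 1)
_QW = np.array([0.223381589678011] * 3 + [0.109951743655322] * 3)
_a1, _b1 = 0.445948490915965, 0.108103018168070
_a2, _b2 = 0.091576213509771, 0.816847572980459
_QP = np.array([
    [_b1, _a1, _a1], [_a1, _b1, _a1], [_a1, _a1, _b1],
    [_b2, _a2, _a2], [_a2, _b2, _a2], [_a2, _a2, _b2],
])

# Gauss-Legendre 3-point rule on [0, 1]
_EQ = 0.5 + 0.5 * np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
_EW = np.array([5.0, 8.0, 5.0]) / 18.0


def _p2_shapes(lam: np.ndarray):
    """P2 shape values and barycentric-gradients at barycentric points lam (q,3).

    Node order: 3 vertices, then midpoints of edges (0,1), (1,2), (2,0).
    Returns N (q,6) and dN/d(xi,eta) (q,6,2) with lam = (1-xi-eta, xi, eta).
    """
    l1, l2, l3 = lam[:, 0], lam[:, 1], lam[:, 2]
    N = np.stack([l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
                  4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1], axis=1)
    # d lam / d(xi, eta) = [[-1,-1],[1,0],[0,1]]
    dl = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])
    dN = np.zeros((lam.shape[0], 6, 2))
    for k, (li, dli) in enumerate(zip((l1, l2, l3), dl)):
        dN[:, k, :] = (4 * li - 1)[:, None] * dli[None, :]
    pairs = [(0, 1), (1, 2), (2, 0)]
    ls = (l1, l2, l3)
    for k, (i, j) in enumerate(pairs):
        dN[:, 3 + k, :] = 4 * (ls[i][:, None] * dl[j][None, :]
                               + ls[j][:, None] * dl[i][None, :])
    return N, dN


_N_Q, _DN_Q = _p2_shapes(_QP)


def _edge_shapes(t: np.ndarray):
    """P2 shape values on a segment at parameters t: nodes (end a, end b, midpoint)."""
    return np.stack([(1 - t) * (1 - 2 * t), t * (2 * t - 1), 4 * t * (1 - t)], axis=1)


_EN = _edge_shapes(_EQ)


@dataclass
class P2Space:
    """P2 dof numbering for a triangle mesh: vertex dofs then edge dofs."""

    mesh: object
    n_dofs: int
    tri_dofs: np.ndarray      # (m, 6)
    dof_coords: np.ndarray    # (n_dofs, 2)
    edge_of_pair: dict        # frozen (a, b) sorted vertex pair -> edge dof

    def boundary_edge_dofs(self, edge_idx: np.ndarray) -> np.ndarray:
        """(k, 3) dof triples (end, end, midpoint) for boundary edges."""
        mesh = self.mesh
        out = np.empty((len(edge_idx), 3), dtype=int)
        for i, e in enumerate(edge_idx):
            a, b = mesh.boundary_edges[e]
            out[i] = (a, b, self.edge_of_pair[(min(a, b), max(a, b))])
        return out


def build_space(mesh) -> P2Space:
    tris = mesh.triangles
    pairs = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    key = np.sort(pairs, axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    nv = mesh.n_vertices
    m = len(tris)
    e01 = nv + inv[0:m]
    e12 = nv + inv[m:2 * m]
    e20 = nv + inv[2 * m:3 * m]
    tri_dofs = np.column_stack([tris, e01, e12, e20])
    mid = 0.5 * (mesh.vertices[uniq[:, 0]] + mesh.vertices[uniq[:, 1]])
    dof_coords = np.vstack([mesh.vertices, mid])
    edge_of_pair = {(int(a), int(b)): int(nv + i) for i, (a, b) in enumerate(uniq)}
    return P2Space(mesh, nv + len(uniq), tri_dofs, dof_coords, edge_of_pair)


def _geometry_arrays(mesh, elems=None):
    tris = mesh.triangles if elems is None else mesh.triangles[elems]
    p = mesh.vertices[tris]
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # (m,2,2) cols
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJT = np.empty_like(J)
    invJT[:, 0, 0] = J[:, 1, 1]
    invJT[:, 0, 1] = -J[:, 1, 0]
    invJT[:, 1, 0] = -J[:, 0, 1]
    invJT[:, 1, 1] = J[:, 0, 0]
    invJT /= detJ[:, None, None]
    # physical radius at quadrature points: r = sum lam_i * r_i
    r_q = np.einsum("qi,mi->mq", _QP, p[:, :, 0])
    z_q = np.einsum("qi,mi->mq", _QP, p[:, :, 1])
    return p, detJ, invJT, r_q, z_q


def _phys_gradients(invJT):
    """Physical gradients of P2 shapes: (m, q, 6, 2)."""
    return np.einsum("mab,qib->mqia", invJT, _DN_Q)


def assemble_form(mesh, space: P2Space, kind: str, c1, c0, elems=None,
                  dtype=complex):
    """Assemble c1 * B(u,v) + c0 * u v with the r-weighted measure.

    ``kind`` selects B: 'grad' or 'curl' (see module docstring).  c1, c0 are
    per-element coefficient arrays (or scalars); ``elems`` restricts
    assembly to an element subset.
    """
    tris_idx = np.arange(mesh.n_triangles) if elems is None else np.asarray(elems)
    _, detJ, invJT, r_q, _ = _geometry_arrays(mesh, tris_idx)
    grads = _phys_gradients(invJT)              # (m,q,6,2)
    c1 = np.broadcast_to(np.asarray(c1, dtype), tris_idx.shape).astype(dtype)
    c0 = np.broadcast_to(np.asarray(c0, dtype), tris_idx.shape).astype(dtype)

    if kind == "grad":
        w = (_QW[None, :] * 0.5) * np.abs(detJ)[:, None] * r_q   # (m,q)
    elif kind == "curl_w":
        w = (_QW[None, :] * 0.5) * np.abs(detJ)[:, None] / r_q
    else:
        raise ValueError(kind)
    dNr = grads[..., 0]
    dNz = grads[..., 1]
    Bq = np.einsum("mq,mqi,mqj->mij", w, dNr, dNr) \
        + np.einsum("mq,mqi,mqj->mij", w, dNz, dNz)
    Mq = np.einsum("mq,qi,qj->mij", w, _N_Q, _N_Q)
    Ke = c1[:, None, None] * Bq + c0[:, None, None] * Mq

    dofs = space.tri_dofs[tris_idx]
    rows = np.repeat(dofs, 6, axis=1).ravel()
    cols = np.tile(dofs, (1, 6)).ravel()
    A = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(space.n_dofs, space.n_dofs)).tocsr()
    return A


def _edge_measure(r_q, measure):
    if measure == "r":
        return r_q
    if measure == "inv_r":
        return 1.0 / r_q
    if measure == "one":
        return np.ones_like(r_q)
    raise ValueError(measure)


def assemble_edge_mass(mesh, space: P2Space, edge_idx: np.ndarray, coeff,
                       dtype=complex, measure="r"):
    """Assemble coeff * u v over boundary edges with the chosen line measure."""
    if len(edge_idx) == 0:
        return sp.csr_matrix((space.n_dofs, space.n_dofs), dtype=dtype)
    dofs = space.boundary_edge_dofs(edge_idx)
    pa = mesh.vertices[mesh.boundary_edges[edge_idx, 0]]
    pb = mesh.vertices[mesh.boundary_edges[edge_idx, 1]]
    L = np.linalg.norm(pb - pa, axis=1)
    r_q = pa[:, 0:1] * (1 - _EQ)[None, :] + pb[:, 0:1] * _EQ[None, :]
    coeff = np.broadcast_to(np.asarray(coeff, dtype), (len(edge_idx),)).astype(dtype)
    w = _EW[None, :] * L[:, None] * _edge_measure(r_q, measure)   # (k,q)
    Me = coeff[:, None, None] * np.einsum("kq,qi,qj->kij", w, _EN, _EN)
    rows = np.repeat(dofs, 3, axis=1).ravel()
    cols = np.tile(dofs, (1, 3)).ravel()
    return sp.coo_matrix((Me.ravel(), (rows, cols)),
                         shape=(space.n_dofs, space.n_dofs)).tocsr()


def assemble_edge_load(mesh, space: P2Space, edge_idx: np.ndarray, func,
                       coeff=1.0, dtype=complex, measure="r"):
    """Assemble coeff * f(r) v over boundary edges into a load vector."""
    b = np.zeros(space.n_dofs, dtype=dtype)
    if len(edge_idx) == 0:
        return b
    dofs = space.boundary_edge_dofs(edge_idx)
    pa = mesh.vertices[mesh.boundary_edges[edge_idx, 0]]
    pb = mesh.vertices[mesh.boundary_edges[edge_idx, 1]]
    L = np.linalg.norm(pb - pa, axis=1)
    r_q = pa[:, 0:1] * (1 - _EQ)[None, :] + pb[:, 0:1] * _EQ[None, :]
    coeff = np.broadcast_to(np.asarray(coeff, dtype), (len(edge_idx),)).astype(dtype)
    fv = np.asarray(func(r_q), dtype)
    w = _EW[None, :] * L[:, None] * _edge_measure(r_q, measure)
    be = np.einsum("kq,qi->ki", coeff[:, None] * w * fv, _EN)
    np.add.at(b, dofs.ravel(), be.ravel())
    return b


def assemble_element_load(mesh, space: P2Space, values, elems=None, dtype=float):
    """Load vector of a per-element source density: int f N_i r dr dz."""
    tris_idx = np.arange(mesh.n_triangles) if elems is None else np.asarray(elems)
    _, detJ, _, r_q, _ = _geometry_arrays(mesh, tris_idx)
    vals = np.broadcast_to(np.asarray(values, dtype), tris_idx.shape)
    w = (_QW[None, :] * 0.5) * np.abs(detJ)[:, None] * r_q
    be = np.einsum("m,mq,qi->mi", vals, w, _N_Q)
    b = np.zeros(space.n_dofs, dtype=dtype)
    np.add.at(b, space.tri_dofs[tris_idx].ravel(), be.ravel())
    return b


def integrate_elementwise(mesh, values, elems=None) -> float:
    """Revolved volume integral 2*pi * int f r dr dz of per-element values."""
    tris_idx = np.arange(mesh.n_triangles) if elems is None else np.asarray(elems)
    _, detJ, _, r_q, _ = _geometry_arrays(mesh, tris_idx)
    cell = ((_QW[None, :] * 0.5) * np.abs(detJ)[:, None] * r_q).sum(axis=1)
    vals = np.broadcast_to(np.asarray(values, float), tris_idx.shape)
    return float(2 * np.pi * np.sum(vals * cell))


def integrate_nodal(mesh, space: P2Space, nodal, elems=None) -> float:
    """Revolved volume integral of a P2 nodal field."""
    tris_idx = np.arange(mesh.n_triangles) if elems is None else np.asarray(elems)
    _, detJ, _, r_q, _ = _geometry_arrays(mesh, tris_idx)
    w = (_QW[None, :] * 0.5) * np.abs(detJ)[:, None] * r_q
    u_q = np.einsum("qi,mi->mq", _N_Q, np.asarray(nodal)[space.tri_dofs[tris_idx]])
    return float(2 * np.pi * np.sum(w * u_q))


def eval_field_and_gradient(mesh, space: P2Space, u, elems):
    """Field values, gradients and radii at quadrature points of elements.

    Returns (u_q, du_dr, du_dz, r_q, w_q) each of shape (m, q); w_q is the
    r-weighted quadrature weight so that sums approximate int . r dr dz.
    """
    tris_idx = np.asarray(elems)
    _, detJ, invJT, r_q, _ = _geometry_arrays(mesh, tris_idx)
    grads = _phys_gradients(invJT)
    ue = np.asarray(u)[space.tri_dofs[tris_idx]]
    u_q = np.einsum("qi,mi->mq", _N_Q, ue)
    du = np.einsum("mqia,mi->mqa", grads, ue)
    w = (_QW[None, :] * 0.5) * np.abs(detJ)[:, None] * r_q
    return u_q, du[..., 0], du[..., 1], r_q, w


def apply_dirichlet(A, b, dofs, value=0.0):
    """Impose u = value on the given dofs (row/column elimination)."""
    dofs = np.atleast_1d(np.asarray(dofs, int))
    b = b.copy()
    if len(dofs) == 0:
        return A, b
    if value != 0.0:
        b -= np.asarray(A[:, dofs].sum(axis=1)).ravel() * value
    Ac = A.tocoo()
    keep = ~(np.isin(Ac.row, dofs) | np.isin(Ac.col, dofs))
    data = np.concatenate([Ac.data[keep], np.ones(len(dofs), dtype=Ac.data.dtype)])
    rows = np.concatenate([Ac.row[keep], dofs])
    cols = np.concatenate([Ac.col[keep], dofs])
    A2 = sp.coo_matrix((data, (rows, cols)), shape=A.shape).tocsr()
    b[dofs] = value
    return A2, b
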