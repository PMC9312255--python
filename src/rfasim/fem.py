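"""P1 finite-element assembly kernels.

Linear triangles in axisymmetric (r, z) coordinates (all measures carry the
2*pi*r revolution weight) and linear tetrahedra in 3D.  Assembly is fully
vectorized; mass/capacity matrices are row-sum lumped, which keeps the
implicit heat steps monotone and makes the enthalpy bookkeeping nodal.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .mesh import Mesh

__all__ = ["FemSpace"]


class FemSpace:
    """Precomputed P1 geometry for one mesh: shape-function gradients,
    element measures and lumped nodal weights (full revolved / half-domain
    measures, i.e. already including 2*pi*r in axisymmetric mode)."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        nodes, elems = mesh.nodes, mesh.elements
        p = nodes[elems]  # (E, nv, d)
        if mesh.dim == 2:
            v1 = p[:, 1] - p[:, 0]
            v2 = p[:, 2] - p[:, 0]
            det = v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0]
            area = 0.5 * np.abs(det)
            if np.any(area <= 0):
                raise ValueError("degenerate triangle in mesh")
            # grad phi_i, constant per element: (E, 3, 2)
            g = np.empty((len(elems), 3, 2))
            for i, (j, k) in enumerate(((1, 2), (2, 0), (0, 1))):
                g[:, i, 0] = p[:, j, 1] - p[:, k, 1]
                g[:, i, 1] = p[:, k, 0] - p[:, j, 0]
            g /= det[:, None, None]
            r = p[:, :, 0]
            rbar = r.mean(axis=1)
            if mesh.mode == "axisymmetric":
                self.volume = 2.0 * np.pi * rbar * area  # revolved element volume
                # int phi_i r dA * 2pi  ->  nodal volume shares
                w = (area / 12.0)[:, None] * (r + 3.0 * rbar[:, None])
                self.node_weight = 2.0 * np.pi * w
            else:  # plain 2D (used by nothing in production, kept for tests)
                self.volume = area
                self.node_weight = np.repeat(area[:, None] / 3.0, 3, axis=1)
            self.grad = g
        else:
            v = p[:, 1:] - p[:, :1]  # (E, 3, 3)
            det = np.linalg.det(v)
            vol = np.abs(det) / 6.0
            if np.any(vol <= 0):
                raise ValueError("degenerate tetrahedron in mesh")
            g = np.empty((len(elems), 4, 3))
            inv = np.linalg.inv(v)  # rows: dual basis
            g[:, 1:, :] = np.swapaxes(inv, 1, 2)
            g[:, 0, :] = -g[:, 1:, :].sum(axis=1)
            self.grad = g
            self.volume = vol
            self.node_weight = np.repeat(vol[:, None] / 4.0, 4, axis=1)

    # ------------------------------------------------------------------ #
    def stiffness(self, coeff, elems=None, tensor=None) -> sp.csr_matrix:
        """Assemble sum_e coeff_e * int grad(phi_i) . D . grad(phi_j).

        ``coeff`` is scalar or per-element; ``tensor`` an optional (d, d) or
        per-element (E, d, d) diffusivity (defaults to identity).  ``elems``
        restricts assembly to an element subset; the returned matrix is
        always over the full node set.
        """
        mesh = self.mesh
        if elems is None:
            elems = np.arange(len(mesh.elements))
        conn = mesh.elements[elems]
        g = self.grad[elems]
        vol = self.volume[elems]
        c = np.broadcast_to(np.asarray(coeff, float), (len(mesh.elements),))[elems]
        if tensor is None:
            gg = np.einsum("eid,ejd->eij", g, g)
        else:
            D = np.asarray(tensor, float)
            if D.ndim == 2:
                gg = np.einsum("eid,dk,ejk->eij", g, D, g)
            else:
                gg = np.einsum("eid,edk,ejk->eij", g, D[elems], g)
        ke = gg * (c * vol)[:, None, None]
        nv = conn.shape[1]
        rows = np.repeat(conn, nv, axis=1).ravel()
        cols = np.tile(conn, (1, nv)).ravel()
        A = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(mesh.num_nodes,) * 2)
        return A.tocsr()

    def lumped_weights(self, elems=None) -> np.ndarray:
        """Nodal volume weights over an element subset (full node vector)."""
        mesh = self.mesh
        if elems is None:
            elems = np.arange(len(mesh.elements))
        w = np.zeros(mesh.num_nodes)
        np.add.at(w, mesh.elements[elems].ravel(), self.node_weight[elems].ravel())
        return w

    def load_from_element_density(self, q_elem, elems=None) -> np.ndarray:
        """RHS vector for an element-wise constant volumetric source (W/m^3)."""
        mesh = self.mesh
        if elems is None:
            elems = np.arange(len(mesh.elements))
        f = np.zeros(mesh.num_nodes)
        contrib = self.node_weight[elems] * np.asarray(q_elem, float)[:, None]
        np.add.at(f, mesh.elements[elems].ravel(), contrib.ravel())
        return f

    # ------------------------------------------------------------------ #
    def facet_measure(self, facets: np.ndarray) -> np.ndarray:
        """Facet measure: revolved area 2*pi*rbar*L (axisym) or area (3D)."""
        p = self.mesh.nodes[facets]
        if facets.shape[1] == 2:
            L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
            if self.mesh.mode == "axisymmetric":
                rbar = p[:, :, 0].mean(axis=1)
                return 2.0 * np.pi * rbar * L
            return L
        cr = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
        return 0.5 * np.linalg.norm(cr, axis=1)

    def robin_matrices(self, facets: np.ndarray, h: float, T_inf: float):
        """Boundary mass matrix h*int(phi_i phi_j dS) and load h*T_inf*int(phi_i dS)."""
        mesh = self.mesh
        n = mesh.num_nodes
        if len(facets) == 0:
            return sp.csr_matrix((n, n)), np.zeros(n)
        p = mesh.nodes[facets]
        if facets.shape[1] == 2:
            L = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
            if mesh.mode == "axisymmetric":
                r1, r2 = p[:, 0, 0], p[:, 1, 0]
                tp = 2.0 * np.pi
                m11 = tp * L * (3 * r1 + r2) / 12.0
                m22 = tp * L * (r1 + 3 * r2) / 12.0
                m12 = tp * L * (r1 + r2) / 12.0
                f1 = tp * L * (2 * r1 + r2) / 6.0
                f2 = tp * L * (r1 + 2 * r2) / 6.0
            else:
                m11 = m22 = L / 3.0
                m12 = L / 6.0
                f1 = f2 = L / 2.0
            me = np.stack([np.stack([m11, m12], -1), np.stack([m12, m22], -1)], 1)
            fe = np.stack([f1, f2], -1)
        else:
            A = self.facet_measure(facets)
            base = (np.ones((3, 3)) + np.eye(3)) / 12.0
            me = A[:, None, None] * base
            fe = np.repeat(A[:, None] / 3.0, 3, axis=1)
        nv = facets.shape[1]
        rows = np.repeat(facets, nv, axis=1).ravel()
        cols = np.tile(facets, (1, nv)).ravel()
        M = sp.coo_matrix((h * me.ravel(), (rows, cols)), shape=(n, n)).tocsr()
        f = np.zeros(n)
        np.add.at(f, facets.ravel(), h * T_inf * fe.ravel())
        return M, f

    def element_gradient(self, u: np.ndarray, elems=None) -> np.ndarray:
        """Per-element constant gradient of a nodal field."""
        if elems is None:
            elems = np.arange(len(self.mesh.elements))
        return np.einsum("eid,ei->ed", self.grad[elems], u[self.mesh.elements[elems]])
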