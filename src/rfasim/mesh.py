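"""Unstructured-mesh container, structured graded mesh generation and VTK export.

Coordinates are stored in meters (SI) throughout; the geometry builders take
their dimensions in millimeters and convert once.

Two discretization modes are supported:

* ``axisymmetric`` — linear triangles in the (r, z) half-plane, revolved
  (all integrals carry the 2*pi*r measure);
* ``3d_half`` — linear tetrahedra on the y >= 0 half-domain with a symmetry
  plane at y = 0 (reported extensive quantities are doubled).

Region tags partition the elements into tissue, blood, electrode and shaft;
facet sets carry the electrical and thermal boundary/interface conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict

import numpy as np

# element region tags
TISSUE, BLOOD, ELECTRODE, SHAFT = 1, 2, 3, 4
REGION_NAMES = {TISSUE: "tissue", BLOOD: "blood", ELECTRODE: "electrode", SHAFT: "shaft"}

# facet-set keys (electrical view: dispersive_0V / air_blood_zero_current /
# symmetry partition the exterior; thermal view: outer_body_37C is the
# tissue-side subset of dispersive_0V, the *_convective and irrigated sets
# live on the internal solid-blood interface)
FACET_KEYS = (
    "dispersive_0V",
    "air_blood_zero_current",
    "symmetry",
    "irrigated_dirichlet",
    "electrode_blood_convective",
    "tissue_blood_convective",
    "outer_body_37C",
)


@dataclass
class Mesh:
    """Simplicial mesh with region and facet tags.

    ``elements`` is (E, 3) for triangles or (E, 4) for tetrahedra; ``facets``
    maps each key of :data:`FACET_KEYS` to an (F, dim) integer array of facet
    node indices (dim = 2 segments in axisymmetric mode, 3 triangles in 3D).
    """

    nodes: np.ndarray  # (N, 2) or (N, 3), meters
    elements: np.ndarray  # (E, 3) or (E, 4)
    region: np.ndarray  # (E,) int
    facets: Dict[str, np.ndarray] = field(default_factory=dict)
    mode: str = "axisymmetric"  # or "3d_half"

    def __post_init__(self) -> None:
        if self.mode not in ("axisymmetric", "3d_half"):
            raise ValueError(f"unknown mesh mode {self.mode!r}")
        if self.mode == "axisymmetric" and np.any(self.nodes[:, 0] < -1e-12):
            raise ValueError("axisymmetric mesh has nodes with negative radius")
        for key in FACET_KEYS:
            self.facets.setdefault(key, np.empty((0, self.elements.shape[1] - 1), int))

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def num_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def domain_factor(self) -> float:
        """Multiplier turning half-domain integrals into full-domain values."""
        return 2.0 if self.mode == "3d_half" else 1.0

    def elements_of(self, *regions: int) -> np.ndarray:
        return np.flatnonzero(np.isin(self.region, regions))

    def nodes_of_facets(self, key: str) -> np.ndarray:
        return np.unique(self.facets[key])

    def write_vtk(self, path, point_data: Dict[str, np.ndarray] | None = None) -> None:
        """Write a legacy-ASCII VTK unstructured grid with region cell data."""
        nodes = self.nodes
        if nodes.shape[1] == 2:  # pad (r, z) -> (r, z, 0)
            nodes = np.column_stack([nodes, np.zeros(len(nodes))])
        cells = self.elements
        npts, ncell, nn = len(nodes), len(cells), cells.shape[1]
        ctype = 5 if nn == 3 else 10  # VTK_TRIANGLE / VTK_TETRA
        with open(path, "w") as f:
            f.write("# vtk DataFile Version 3.0\nrfasim mesh\nASCII\n")
            f.write("DATASET UNSTRUCTURED_GRID\n")
            f.write(f"POINTS {npts} double\n")
            np.savetxt(f, nodes, fmt="%.9e")
            f.write(f"CELLS {ncell} {ncell * (nn + 1)}\n")
            np.savetxt(f, np.column_stack([np.full(ncell, nn), cells]), fmt="%d")
            f.write(f"CELL_TYPES {ncell}\n")
            np.savetxt(f, np.full(ncell, ctype), fmt="%d")
            f.write(f"CELL_DATA {ncell}\nSCALARS region int 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, self.region, fmt="%d")
            if point_data:
                f.write(f"POINT_DATA {npts}\n")
                for name, values in point_data.items():
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, np.asarray(values, float), fmt="%.9e")


def graded_points(segments) -> np.ndarray:
    """Build a 1D graded point set from ``[(x0, x1, h0, h1), ...]`` segments.

    Within each segment the step size follows a geometric progression from
    ``h0`` at ``x0`` to ``h1`` at ``x1`` (uniform when equal), rescaled so the
    last point lands exactly on ``x1``.  Segment endpoints are always included,
    so feature coordinates (material interfaces) fall on grid lines.
    """
    pts = [segments[0][0]]
    for x0, x1, h0, h1 in segments:
        L = x1 - x0
        if L <= 0:
            raise ValueError("segments must have positive length")
        n = max(1, int(round(2.0 * L / (h0 + h1))))
        if n == 1 or abs(h1 - h0) < 1e-15:
            steps = np.full(n, L / n)
        else:
            q = (h1 / h0) ** (1.0 / (n - 1))
            steps = h0 * q ** np.arange(n)
            steps *= L / steps.sum()
        pts.extend(x0 + np.cumsum(steps))
        pts[-1] = x1  # kill accumulation round-off
    return np.array(pts)


def structured_triangles(x: np.ndarray, y: np.ndarray):
    """Tensor-product grid split into triangles with alternating diagonals.

    Returns (nodes (N,2), triangles (E,3)).  Alternating the diagonal per
    quad avoids the directional bias of a one-diagonal split.
    """
    nx, ny = len(x), len(y)
    X, Y = np.meshgrid(x, y, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * ny + j

    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    i, j = i.ravel(), j.ravel()
    n00, n10 = nid(i, j), nid(i + 1, j)
    n01, n11 = nid(i, j + 1), nid(i + 1, j + 1)
    even = (i + j) % 2 == 0
    # even quads: diagonal n00-n11; odd quads: diagonal n10-n01
    t1 = np.where(even[:, None], np.column_stack([n00, n10, n11]),
                  np.column_stack([n00, n10, n01]))
    t2 = np.where(even[:, None], np.column_stack([n00, n11, n01]),
                  np.column_stack([n10, n11, n01]))
    return nodes, np.vstack([t1, t2])


_KUHN_TETS = np.array(  # six-tetrahedra Kuhn split of the unit cube, corner ids 0..7
    [[0, 1, 3, 7], [0, 1, 5, 7], [0, 2, 3, 7], [0, 2, 6, 7], [0, 4, 5, 7], [0, 4, 6, 7]]
)


def structured_tets(x: np.ndarray, y: np.ndarray, z: np.ndarray):
    """Tensor-product hexahedral grid split into 6 Kuhn tetrahedra per cell."""
    nx, ny, nz = len(x), len(y), len(z)
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    i, j, k = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    i, j, k = i.ravel(), j.ravel(), k.ravel()
    corners = np.stack(
        [nid(i + (c >> 2 & 1), j + (c >> 1 & 1), k + (c & 1)) for c in range(8)], axis=1
    )
    tets = corners[:, _KUHN_TETS].reshape(-1, 4)
    return nodes, tets


def _facet_array(elements: np.ndarray):
    """All facets of each element: (E, n_facets, dim) node-index array."""
    if elements.shape[1] == 3:
        idx = [[0, 1], [1, 2], [2, 0]]
    else:
        idx = [[1, 2, 3], [0, 2, 3], [0, 1, 3], [0, 1, 2]]
    return elements[:, idx]


def facet_adjacency(elements: np.ndarray):
    """Classify mesh facets by the elements sharing them.

    Returns ``(facets, elem_a, elem_b)`` where ``facets`` is (F, dim) with
    original node order, and ``elem_b`` is -1 for exterior facets.
    """
    fa = _facet_array(elements)
    E, nf, d = fa.shape
    flat = fa.reshape(-1, d)
    owner = np.repeat(np.arange(E), nf)
    key = np.sort(flat, axis=1)
    order = np.lexsort(key.T[::-1])
    key_sorted = key[order]
    is_new = np.ones(len(key_sorted), bool)
    is_new[1:] = np.any(key_sorted[1:] != key_sorted[:-1], axis=1)
    group = np.cumsum(is_new) - 1
    ngroups = group[-1] + 1
    elem_a = np.full(ngroups, -1, int)
    elem_b = np.full(ngroups, -1, int)
    first_idx = np.full(ngroups, -1, int)
    # pair first and second occurrence per group (a facet is shared by <= 2 elements)
    first_mask = is_new
    second_mask = np.zeros_like(is_new)
    second_mask[1:] = ~is_new[1:]
    elem_a[group[first_mask]] = owner[order][first_mask]
    first_idx[group[first_mask]] = order[first_mask]
    elem_b[group[second_mask]] = owner[order][second_mask]
    facets = flat[first_idx]
    return facets, elem_a, elem_b
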