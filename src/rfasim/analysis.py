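"""Damage integration, lesion geometry and power/energy accounting.

Thermal damage follows first-order Arrhenius kinetics: the damage index
Omega(t) = int_0^t A exp(-Ea / (R T(tau))) dtau (T in Kelvin) is accumulated
per node with the trapezoidal rule on the solver's time grid.  The Omega = 1
isosurface (63% cell-death probability) is taken as the lesion contour.

Lesion metrics are measured from the undisturbed tissue surface plane z = 0:
depth is the deepest point of the contour, maximum width the largest
horizontal diameter of the Omega >= 1 region over all depths, and volume the
exact integral of the supra-threshold region of the P1 interpolant (revolved
in axisymmetric mode, doubled for the 3D half-domain).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .materials import ArrheniusParams
from .fem import FemSpace
from .mesh import Mesh, TISSUE

__all__ = [
    "DamageField",
    "LesionMetrics",
    "PowerAccounting",
    "arrhenius_integrate",
    "extract_lesion",
    "isotherm_contour",
    "power_energy_accounting",
]

MM = 1e3  # meters -> mm for reported metrics


@dataclass
class DamageField:
    """Nodal damage index time series: ``omega[i]`` at ``times[i]``."""

    times: np.ndarray  # (nt,)
    omega: np.ndarray  # (nt, n_nodes)


@dataclass(frozen=True)
class LesionMetrics:
    """Lesion geometry (mm / mm^3); ``empty`` when Omega < threshold everywhere."""

    depth: float
    max_width: float
    ratio: float
    volume: float
    empty: bool
    width_x: Optional[float] = None  # 3D only: along the fiber/catheter axis
    width_y: Optional[float] = None  # 3D only: across the symmetry plane

    @classmethod
    def none(cls) -> "LesionMetrics":
        return cls(0.0, 0.0, np.nan, 0.0, True)


@dataclass(frozen=True)
class PowerAccounting:
    """Percent of applied power (P_T, at onset) / delivered energy (E_T, at
    pulse end) dissipated in the tissue rather than the blood pool."""

    P_T: float
    E_T: float


def arrhenius_integrate(
    times, T_history, params: ArrheniusParams = ArrheniusParams()
) -> DamageField:
    """Accumulate Omega by trapezoidal quadrature of A exp(-Ea/(R T_K)).

    ``T_history`` is (nt, n_nodes) in degC at strictly increasing ``times``.
    """
    times = np.asarray(times, float)
    T = np.atleast_2d(np.asarray(T_history, float))
    if len(times) != len(T):
        raise ValueError("times and T_history must have matching length")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("time samples must be strictly increasing")
    if not np.all(np.isfinite(T)):
        raise ValueError("temperatures must be finite")
    if np.any(T < -273.15):
        raise ValueError("temperature below absolute zero")
    rate = params.A * np.exp(-params.Ea / (params.R * (T + 273.15)))
    omega = np.zeros_like(rate)
    if len(times) > 1:
        dt = np.diff(times)[:, None]
        omega[1:] = np.cumsum(0.5 * dt * (rate[1:] + rate[:-1]), axis=0)
    return DamageField(times=times, omega=omega)


# --------------------------------------------------------------------- #
# contouring machinery

_TRI_EDGES = np.array([[0, 1], [1, 2], [2, 0]])
_TET_EDGES = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])


def _crossing_points(values: np.ndarray, coords: np.ndarray, level: float):
    """Edge-interpolated level-set points over element arrays.

    ``values`` (E, nv) nodal field per element, ``coords`` (E, nv, d).
    """
    edges = _TRI_EDGES if values.shape[1] == 3 else _TET_EDGES
    va = values[:, edges[:, 0]]
    vb = values[:, edges[:, 1]]
    cross = (va - level) * (vb - level) < 0.0
    on_level = coords[values == level]  # nodes hit exactly by the level set
    if not np.any(cross):
        return on_level.reshape(-1, coords.shape[2])
    t = (level - va[cross]) / (vb[cross] - va[cross])
    pa = coords[:, edges[:, 0], :][cross]
    pb = coords[:, edges[:, 1], :][cross]
    return np.vstack([pa + t[:, None] * (pb - pa), on_level])


def _poly_area_rmoment(poly: np.ndarray):
    """Area and integral of r over a planar polygon ((k, 2) = (r, z) verts)."""
    area = 0.0
    rint = 0.0
    p0 = poly[0]
    for p1, p2 in zip(poly[1:-1], poly[2:]):
        a = 0.5 * ((p1[0] - p0[0]) * (p2[1] - p0[1]) - (p2[0] - p0[0]) * (p1[1] - p0[1]))
        area += a
        rint += a * (p0[0] + p1[0] + p2[0]) / 3.0
    return area, rint


def _clip_triangle_above(values: np.ndarray, coords: np.ndarray, level: float):
    """Sutherland-Hodgman clip of one triangle to the half-space value>=level."""
    poly = []
    n = 3
    for i in range(n):
        j = (i + 1) % n
        vi, vj = values[i], values[j]
        if vi >= level:
            poly.append(coords[i])
        if (vi - level) * (vj - level) < 0.0:
            t = (level - vi) / (vj - vi)
            poly.append(coords[i] + t * (coords[j] - coords[i]))
    return np.array(poly) if len(poly) >= 3 else None


def _revolved_volume_above(values: np.ndarray, coords: np.ndarray, level: float) -> float:
    """Exact revolved (2*pi*r) volume of the supra-level region, P1 triangles."""
    vmax = values.max(axis=1)
    vmin = values.min(axis=1)
    vol = 0.0
    full = vmin >= level
    if np.any(full):
        for v, c in zip(values[full], coords[full]):
            _, rint = _poly_area_rmoment(c)
            vol += 2.0 * np.pi * abs(rint)  # r >= 0, so |int r dA| is orientation-free
    partial = np.flatnonzero((vmax >= level) & (vmin < level))
    for e in partial:
        poly = _clip_triangle_above(values[e], coords[e], level)
        if poly is not None:
            _, rint = _poly_area_rmoment(poly)
            vol += 2.0 * np.pi * abs(rint)
    return vol


def _tet_fraction_above(values: np.ndarray, level: float) -> np.ndarray:
    """Volume fraction of each tetrahedron where the P1 field >= level.

    Exact piecewise-cubic CDF of a linear function over a simplex; nodal
    ties are broken by a tiny symmetric perturbation.
    """
    v = np.sort(values, axis=1).astype(float)
    # de-tie: spread exact duplicates by an epsilon scaled to the data
    span = max(np.ptp(v), 1.0)
    eps = 1e-9 * span
    v = v + np.arange(4) * eps
    frac = np.empty(len(v))
    th = level
    v1, v2, v3, v4 = v.T
    below = th <= v1
    above = th >= v4
    frac[below] = 1.0
    frac[above] = 0.0
    mid = ~below & ~above
    # CDF of the linear field (fraction below th), divided-difference form
    def cdf(vv, t):
        s = np.zeros(len(vv))
        for i in range(4):
            vi = vv[:, i]
            num = np.clip(t - vi, 0.0, None) ** 3
            den = np.ones(len(vv))
            for j in range(4):
                if j != i:
                    den *= vv[:, j] - vi
            s += num / den
        return s

    frac[mid] = 1.0 - cdf(v[mid], th)
    return np.clip(frac, 0.0, 1.0)


def extract_lesion(
    damage: np.ndarray,
    mesh: Mesh,
    threshold: float = 1.0,
    fs: Optional[FemSpace] = None,
) -> LesionMetrics:
    """Lesion metrics of the Omega >= threshold region in the tissue.

    ``damage`` is the nodal damage index.  Depth is measured from the
    undisturbed tissue surface plane z = 0, width is the maximum horizontal
    diameter over all depths; the volume integral is exact for the P1
    interpolant.  An empty lesion is a valid result.
    """
    damage = np.asarray(damage, float)
    fs = fs or FemSpace(mesh)
    tissue = mesh.elements_of(TISSUE)
    conn = mesh.elements[tissue]
    vals = damage[conn]
    coords = mesh.nodes[conn] * MM  # mm
    if not np.any(vals >= threshold):
        return LesionMetrics.none()
    pts = _crossing_points(vals, coords, threshold)
    supra = coords[vals >= threshold]
    all_pts = np.vstack([pts, supra]) if len(pts) else supra
    if mesh.dim == 2:
        depth = float(np.clip(-all_pts[:, 1].min(), 0.0, None))
        max_width = float(2.0 * all_pts[:, 0].max())
        volume = _revolved_volume_above(vals, coords, threshold)
        wx = wy = None
    else:
        depth = float(np.clip(-all_pts[:, 2].min(), 0.0, None))
        wx = float(all_pts[:, 0].max() - all_pts[:, 0].min())
        wy = float(2.0 * np.abs(all_pts[:, 1]).max())  # mirrored half-domain
        max_width = max(wx, wy)
        frac = _tet_fraction_above(vals, threshold)
        volume = float((fs.volume[tissue] * MM**3 * frac).sum() * mesh.domain_factor)
    if depth <= 0.0:
        return LesionMetrics.none()
    return LesionMetrics(
        depth=depth,
        max_width=max_width,
        ratio=max_width / depth,
        volume=volume,
        empty=False,
        width_x=wx,
        width_y=wy,
    )


def isotherm_contour(T_field: np.ndarray, level: float, mesh: Mesh) -> np.ndarray:
    """Edge-interpolated points of the ``T = level`` contour in the tissue (mm)."""
    T_field = np.asarray(T_field, float)
    tissue = mesh.elements_of(TISSUE)
    conn = mesh.elements[tissue]
    return _crossing_points(T_field[conn], mesh.nodes[conn] * MM, level)


def contour_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two point clouds (diagnostic)."""
    from scipy.spatial import cKDTree

    if len(a) == 0 or len(b) == 0:
        return np.inf
    d_ab = cKDTree(b).query(a)[0].max()
    d_ba = cKDTree(a).query(b)[0].max()
    return float(max(d_ab, d_ba))


def power_energy_accounting(log: pd.DataFrame) -> PowerAccounting:
    """P_T / E_T from the per-step solver log.

    P_T uses the first in-pulse electrical solve; E_T the per-region energy
    cumulated to pulse end (each step's split held over its duration).
    """
    in_pulse = log[log["P_total_W"] > 0.0]
    if len(in_pulse) == 0:
        raise ValueError("no in-pulse steps recorded")
    first = in_pulse.iloc[0]
    P_T = 100.0 * first["P_tissue_W"] / first["P_total_W"]
    t = in_pulse["time_s"].to_numpy()
    dt = np.diff(np.concatenate([[0.0], t]))
    E_tis = float((in_pulse["P_tissue_W"].to_numpy() * dt).sum())
    E_tot = float((in_pulse["P_total_W"].to_numpy() * dt).sum())
    if E_tot <= 0:
        raise ValueError("zero delivered energy")
    return PowerAccounting(P_T=P_T, E_T=100.0 * E_tis / E_tot)
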