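"""Model geometries and meshing for the ablation scenarios.

Three scenario families are supported, mirroring the two preclinical
preparations and their hybrid:

* ``BH`` (beating heart): myocardium slab with blood filling the chamber up
  to the domain boundary; the dispersive (return) electrode is a 0 V
  condition on every outer limit.
* ``TM`` (thigh muscle): striated-muscle slab with a blood pool of finite
  height (default 20 mm) whose top surface borders air, so it carries a
  zero-current condition instead of 0 V.
* ``INTERMEDIATE``: the TM geometry with myocardium properties, isolating
  the geometric effect from the material effect.

The irrigated catheter is a 7.5 Fr (2.5 mm diameter) electrode of total
length 3.5 mm, idealized as a 2.25 mm cylinder capped by a 1.25 mm-radius
hemispherical tip, plus a polyurethane shaft.  Orientations: perpendicular
(90 deg, inserted 0.5 mm), 45 deg (0.498 mm) and horizontal (0 deg,
0.193 mm) — insertion depths chosen to equalize the electrode-tissue
contact area.

Perpendicular scenarios mesh exactly in axisymmetric (r, z) coordinates;
45/0 deg scenarios use a 3D half-domain (symmetry plane y = 0).  Meshes are
structured and graded (fine near the electrode, coarse in the far field);
curved electrode surfaces are represented by sub-element staircase
approximation at the local mesh size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .mesh import (
    BLOOD,
    ELECTRODE,
    Mesh,
    SHAFT,
    TISSUE,
    facet_adjacency,
    graded_points,
    structured_tets,
    structured_triangles,
)

MM = 1e-3  # geometry inputs are mm; meshes are built in meters

INSERTION_DEPTH = {90: 0.5, 45: 0.498, 0: 0.193}  # mm


@dataclass(frozen=True)
class CatheterSpec:
    """Irrigated-tip ablation catheter (all lengths in mm)."""

    electrode_diameter: float = 2.5  # 7.5 Fr at 1 Fr = 1/3 mm
    electrode_length: float = 3.5
    orientation: int = 90  # degrees from the tissue surface
    insertion_depth: float | None = None  # default depends on orientation
    shaft_length_modeled: float = 10.0  # 4 electrode diameters

    def __post_init__(self) -> None:
        if self.orientation not in (0, 45, 90):
            raise ValueError("orientation must be 0, 45 or 90 degrees")
        if self.insertion_depth is None:
            object.__setattr__(
                self, "insertion_depth", INSERTION_DEPTH[self.orientation]
            )
        if self.insertion_depth >= self.electrode_length:
            raise ValueError("insertion depth must be below electrode length")

    @property
    def radius(self) -> float:
        return 0.5 * self.electrode_diameter

    @property
    def cylinder_length(self) -> float:
        """Length of the cylindrical electrode body (tip hemisphere excluded)."""
        return self.electrode_length - self.radius

    @property
    def axis_direction(self) -> np.ndarray:
        th = np.deg2rad(self.orientation)
        return np.array([np.cos(th), 0.0, np.sin(th)])

    @property
    def tip_center(self) -> np.ndarray:
        """Center of the tip hemisphere (mm, 3D frame; z=0 tissue surface)."""
        return np.array([0.0, 0.0, self.radius - self.insertion_depth])

    def contact_area(self, n: int = 800) -> float:
        """Electrode-tissue contact area (mm^2) by surface quadrature.

        Samples the hemisphere + cylinder lateral surface with area weights
        and sums the part below the tissue surface plane z = 0.
        """
        R, Lc = self.radius, self.cylinder_length
        A0, u = self.tip_center, self.axis_direction
        # orthonormal frame around the axis
        e1 = np.array([-u[2], 0.0, u[0]])
        e2 = np.array([0.0, 1.0, 0.0])
        phi = (np.arange(n) + 0.5) / n * 2 * np.pi
        area = 0.0
        # cylinder lateral surface
        t = (np.arange(n) + 0.5) / n * Lc
        T, P = np.meshgrid(t, phi, indexing="ij")
        pts = (
            A0[None, None, :]
            + T[..., None] * u
            + R * np.cos(P)[..., None] * e1
            + R * np.sin(P)[..., None] * e2
        )
        w_cyl = (Lc / n) * (2 * np.pi * R / n)
        area += w_cyl * np.count_nonzero(pts[..., 2] < 0.0)
        # hemisphere (axial coordinate s in [-R, 0])
        mu = -(np.arange(n) + 0.5) / n  # cos(angle from axis) in (-1, 0)
        MU, P = np.meshgrid(mu, phi, indexing="ij")
        SR = np.sqrt(1.0 - MU**2)
        pts = A0[None, None, :] + R * (
            MU[..., None] * u
            + (SR * np.cos(P))[..., None] * e1
            + (SR * np.sin(P))[..., None] * e2
        )
        w_sph = (2 * np.pi * R**2) / (n * n) * 0.5 * 2  # R^2 dmu dphi
        w_sph = R**2 * (1.0 / n) * (2 * np.pi / n)
        area += w_sph * np.count_nonzero(pts[..., 2] < 0.0)
        return float(area)


@dataclass(frozen=True)
class ScenarioGeometry:
    """One model variant: geometry family + tissue material + blood pool."""

    model: str = "BH"  # BH | INTERMEDIATE | TM
    catheter: CatheterSpec = field(default_factory=CatheterSpec)
    blood_height: float = 20.0  # mm, TM/INTERMEDIATE only
    domain_margin: float = 40.0  # mm around the electrode

    def __post_init__(self) -> None:
        if self.model not in ("BH", "INTERMEDIATE", "TM"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.uses_blood_pool and self.blood_height <= 0:
            raise ValueError("blood_height must be positive in TM/INTERMEDIATE models")

    @property
    def uses_blood_pool(self) -> bool:
        return self.model in ("TM", "INTERMEDIATE")

    @property
    def tissue_material(self) -> str:
        return "striated_muscle" if self.model == "TM" else "myocardium"

    @property
    def blood_top(self) -> float:
        """Top of the modeled blood region above the tissue surface (mm)."""
        return self.blood_height if self.uses_blood_pool else self.domain_margin


@dataclass(frozen=True)
class Resolution:
    """Mesh refinement control: target edge lengths in mm."""

    h_min: float = 0.12  # near the electrode
    h_max: float = 4.0  # far field
    h_min_3d: float = 0.55  # 3D runs are kept coarser by design
    h_max_3d: float = 7.0

    def refined(self, factor: float) -> "Resolution":
        return Resolution(
            self.h_min / factor, self.h_max / factor,
            self.h_min_3d / factor, self.h_max_3d / factor,
        )


# --------------------------------------------------------------------- #
# classification helpers (mm coordinates)

def _point_segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(pts - proj, axis=1)


def classify_points(scenario: ScenarioGeometry, pts_mm: np.ndarray) -> np.ndarray:
    """Region id per point ((x, y, z) in mm; z = 0 is the tissue surface)."""
    cat = scenario.catheter
    A0, u = cat.tip_center, cat.axis_direction
    R, Lc, Ls = cat.radius, cat.cylinder_length, cat.shaft_length_modeled
    d_el = _point_segment_distance(pts_mm, A0, A0 + Lc * u)
    d_sh = _point_segment_distance(pts_mm, A0 + Lc * u, A0 + (Lc + Ls) * u)
    t_ax = (pts_mm - A0) @ u
    region = np.where(pts_mm[:, 2] <= 0.0, TISSUE, BLOOD)
    region[(d_sh <= R) & (t_ax <= Lc + Ls)] = SHAFT  # flat-cut shaft top
    # electrode = capsule truncated at the cylinder top (the joint plane);
    # beyond it the catheter body is shaft material
    region[(d_el <= R) & (t_ax <= Lc)] = ELECTRODE
    return region


# --------------------------------------------------------------------- #
# axisymmetric (perpendicular) meshing

def _axis_z_segments(scenario: ScenarioGeometry, res: Resolution):
    cat = scenario.catheter
    hf, hc = res.h_min, res.h_max
    ins = cat.insertion_depth
    z_c = cat.radius - ins  # tip-sphere center
    z_cyl = z_c + cat.cylinder_length
    z_sh = z_cyl + cat.shaft_length_modeled
    z_top = scenario.blood_top
    z_bot = -scenario.domain_margin
    hmid = min(8 * hf, 1.2)  # cap so the lesion zone never sees multi-mm cells
    segs = [(z_bot, -8.0, hc, hmid), (-8.0, -ins, hmid, hf), (-ins, z_c, hf, hf)]
    marks = sorted({z_cyl, min(z_sh, z_top), z_top})
    z0 = z_c
    h0 = hf
    for z1 in marks:
        if z1 <= z0 + 1e-12:
            continue
        h1 = hf * 2 if z1 <= z_cyl + 1e-9 else (hc if z1 >= z_top - 1e-9 else hmid)
        segs.append((z0, z1, h0, h1))
        z0, h0 = z1, h1
    return segs


def build_axisymmetric(scenario: ScenarioGeometry, res: Resolution) -> Mesh:
    """Structured graded triangle mesh of a perpendicular-catheter scenario."""
    cat = scenario.catheter
    if cat.orientation != 90:
        raise ValueError("axisymmetric mode requires the perpendicular catheter")
    hf, hc = res.h_min, res.h_max
    R = cat.radius
    r_pts = graded_points(
        [(0.0, R, hf, hf), (R, 6.0, hf, 8 * hf), (6.0, scenario.domain_margin, 8 * hf, hc)]
    )
    z_pts = graded_points(_axis_z_segments(scenario, res))
    nodes_mm, tris = structured_triangles(r_pts, z_pts)
    cent = nodes_mm[tris].mean(axis=1)
    pts3 = np.column_stack([cent[:, 0], np.zeros(len(cent)), cent[:, 1]])
    region = classify_points(scenario, pts3)
    mesh = Mesh(nodes=nodes_mm * MM, elements=tris, region=region, mode="axisymmetric")
    _tag_facets(mesh, scenario, nodes_mm, axisym=True)
    return mesh


# --------------------------------------------------------------------- #
# 3D half-domain meshing (0 and 45 degree orientations; also 90 for checks)

def build_3d_half(scenario: ScenarioGeometry, res: Resolution) -> Mesh:
    cat = scenario.catheter
    hf, hc = res.h_min_3d, res.h_max_3d
    R, Lc, Ls = cat.radius, cat.cylinder_length, cat.shaft_length_modeled
    u = cat.axis_direction
    m = scenario.domain_margin
    # fine window: electrode + expected lesion halo
    x_cat = (cat.tip_center + (Lc + Ls) * u)[0]
    x_hi_fine = max(6.0, min(x_cat + 2 * R, m - 4.0))
    x_pts = np.unique(np.concatenate([
        -graded_points([(5.0, m, 3 * hf, hc)]),
        graded_points([(-5.0, x_hi_fine, hf, hf)]),
        graded_points([(x_hi_fine, m, 3 * hf, hc)]),
    ]))
    y_pts = graded_points([(0.0, 5.0, hf, hf), (5.0, m, 3 * hf, hc)])
    z_res = replace(res, h_min=hf, h_max=hc)
    z_pts = graded_points(_axis_z_segments(scenario, z_res))
    nodes_mm, tets = structured_tets(x_pts, y_pts, z_pts)
    cent = nodes_mm[tets].mean(axis=1)
    region = classify_points(scenario, cent)
    mesh = Mesh(nodes=nodes_mm * MM, elements=tets, region=region, mode="3d_half")
    _tag_facets(mesh, scenario, nodes_mm, axisym=False)
    return mesh


def build_geometry(scenario: ScenarioGeometry, res: Resolution | None = None,
                   mode: str | None = None) -> Mesh:
    """Mesh a scenario: axisymmetric for 90 deg (default), 3D half otherwise."""
    res = res or Resolution()
    if mode is None:
        mode = "axisymmetric" if scenario.catheter.orientation == 90 else "3d_half"
    if mode == "axisymmetric":
        return build_axisymmetric(scenario, res)
    return build_3d_half(scenario, res)


# --------------------------------------------------------------------- #

def _tag_facets(mesh: Mesh, scenario: ScenarioGeometry, nodes_mm, axisym: bool):
    cat = scenario.catheter
    tol = 1e-9
    facets, ea, eb = facet_adjacency(mesh.elements)
    mid = nodes_mm[facets].mean(axis=1)  # (F, 2|3) mm
    reg_a = mesh.region[ea]
    reg_b = np.where(eb >= 0, mesh.region[np.maximum(eb, 0)], -1)
    exterior = eb == -1

    lo = nodes_mm.min(axis=0)
    hi = nodes_mm.max(axis=0)
    zc = mid[:, -1]
    sets = {k: [] for k in mesh.facets}

    if axisym:
        on_axis = np.abs(mid[:, 0]) < tol
        on_top = np.abs(zc - hi[1]) < tol
        on_out = ~on_axis & ~on_top  # r = rmax or z = zmin
    else:
        on_sym = np.abs(mid[:, 1]) < tol
        on_top = np.abs(zc - hi[2]) < tol
        on_out = (
            (np.abs(mid[:, 0] - lo[0]) < tol)
            | (np.abs(mid[:, 0] - hi[0]) < tol)
            | (np.abs(zc - lo[2]) < tol)
            | (np.abs(mid[:, 1] - hi[1]) < tol)
        )
        on_axis = on_sym & ~on_out & ~on_top

    disp = exterior & on_out
    if not scenario.uses_blood_pool:
        disp = disp | (exterior & on_top)  # BH: 0 V on every outer limit
        air = np.zeros(len(facets), bool)
    else:
        air = exterior & on_top & ~on_out
    sym = exterior & ~disp & ~air
    sets["dispersive_0V"] = facets[disp]
    sets["air_blood_zero_current"] = facets[air]
    sets["symmetry"] = facets[sym]
    sets["outer_body_37C"] = facets[disp & (reg_a == TISSUE)]

    solid = np.isin(reg_a, (TISSUE, ELECTRODE, SHAFT))
    pair_blood = (~exterior) & ((reg_b == BLOOD) & solid)
    # orient: make reg_a the solid side for interface bookkeeping (already is)
    pair_blood_rev = (~exterior) & (reg_a == BLOOD) & np.isin(reg_b, (TISSUE, ELECTRODE, SHAFT))
    tb = (pair_blood & (reg_a == TISSUE)) | (pair_blood_rev & (reg_b == TISSUE))
    eb_ = (pair_blood & np.isin(reg_a, (ELECTRODE, SHAFT))) | (
        pair_blood_rev & np.isin(reg_b, (ELECTRODE, SHAFT))
    )
    el_side = (pair_blood & (reg_a == ELECTRODE)) | (pair_blood_rev & (reg_b == ELECTRODE))
    # irrigated: electrode-blood facets on the cylindrical zone (axial
    # coordinate beyond the tip hemisphere); the hemispherical tip stays free
    if axisym:
        pts3 = np.column_stack([mid[:, 0], np.zeros(len(mid)), mid[:, 1]])
    else:
        pts3 = mid
    t_ax = (pts3 - cat.tip_center) @ cat.axis_direction
    irrig = el_side & (t_ax > 1e-6)
    sets["irrigated_dirichlet"] = facets[irrig]
    sets["electrode_blood_convective"] = facets[eb_ & ~irrig]
    sets["tissue_blood_convective"] = facets[tb]
    mesh.facets.update(sets)


# --------------------------------------------------------------------- #

def convergence_study(
    scenario: ScenarioGeometry,
    resolutions: Sequence[Resolution],
    setting,
    depth_tol: float = 0.5,
    temp_tol: float = 1.0,
    **run_kwargs,
):
    """Mesh-convergence harness on lesion depth and peak tissue temperature.

    Runs the scenario at each resolution (ordered coarse -> fine) and returns
    ``(resolution, report)`` for the coarsest resolution whose lesion depth
    changes by less than ``depth_tol`` (mm) and peak temperature by less than
    ``temp_tol`` (degC) against the next finer one.  If none converges, the
    returned resolution is ``None`` and the report carries the deltas.
    """
    from .solver import run_simulation  # deferred: geometry <- solver would cycle

    if len(resolutions) < 2:
        raise ValueError("need at least two resolutions")
    rows = []
    for res in resolutions:
        result = run_simulation(scenario, setting, resolution=res, **run_kwargs)
        metrics = result.lesion_at_end()
        rows.append(
            {
                "resolution": res,
                "depth_mm": metrics.depth,
                "peak_T": result.peak_temperature,
            }
        )
    report = {"rows": rows, "converged": None}
    for coarse, fine in zip(rows[:-1], rows[1:]):
        d_depth = abs(coarse["depth_mm"] - fine["depth_mm"])
        d_temp = abs(coarse["peak_T"] - fine["peak_T"])
        coarse["delta_depth"] = d_depth
        coarse["delta_peak_T"] = d_temp
        if d_depth < depth_tol and d_temp < temp_tol and report["converged"] is None:
            report["converged"] = coarse["resolution"]
    return report["converged"], report
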