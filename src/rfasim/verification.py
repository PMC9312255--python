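"""Self-contained analytic benchmark problems.

Every stage of the electro-thermal pipeline is exercised against a closed
form on a small synthetic domain, so the package is fully testable without
external data:

* transient conduction in a slab with a convective surface (series solution,
  plus the lumped-capacitance limit at small Biot number) — validates the
  implicit heat stepper and Robin machinery;
* conduction between concentric spheres (exact conductance and Joule-density
  profile) — validates the electrical solve, the axisymmetric measures and
  the constant-power normalization;
* prescribed temperature programs with high-precision quadrature references —
  validates the Arrhenius damage integral.

All cases are deterministic and run in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from . import materials as mat
from .analysis import arrhenius_integrate
from .fem import FemSpace
from .mesh import Mesh, TISSUE, graded_points, structured_triangles
from .solver import ElectricProblem, ThermalStepper

__all__ = [
    "AnalyticCase",
    "make_conduction_slab",
    "make_spherical_electrode_case",
    "make_damage_case",
    "run_all",
]


@dataclass
class AnalyticCase:
    """A benchmark with an exact reference: ``run()`` returns a report dict
    with at least ``name``, ``error`` (worst relative/absolute measure as
    documented per case) and ``passed``."""

    name: str
    tolerance: float
    run: Callable[[], Dict]


# --------------------------------------------------------------------- #
# transient slab conduction

def _slab_series_coeffs(Bi: float, n_terms: int = 12):
    """Eigenvalues/coefficients of the convectively cooled slab.

    lambda_n solve lambda tan(lambda) = Bi; theta(x*, Fo) =
    sum C_n exp(-lambda_n^2 Fo) cos(lambda_n x*), x* from the insulated face.
    """
    lams = []
    for n in range(n_terms):
        lo = n * np.pi + 1e-9
        hi = n * np.pi + np.pi / 2 - 1e-9
        lams.append(brentq(lambda l: l * np.tan(l) - Bi, lo, hi, xtol=1e-14))
    lams = np.array(lams)
    C = 4 * np.sin(lams) / (2 * lams + np.sin(2 * lams))
    return lams, C


def slab_series_temperature(x_star, t, L, alpha, Bi, T_init, T_inf, n_terms=12):
    """Closed-form slab temperature; ``x_star`` measured from the insulated base."""
    lams, C = _slab_series_coeffs(Bi, n_terms)
    Fo = alpha * t / L**2
    xi = np.atleast_1d(x_star) / L  # dimensionless position from the insulated face
    theta = (C * np.exp(-(lams**2) * Fo) * np.cos(lams * xi[:, None])).sum(axis=1)
    return T_inf + (T_init - T_inf) * theta


def _slab_setup(L_mm: float, h: float, T_inf: float, nz: int = 60):
    """Axisymmetric slab mesh (uniform in z) with a Robin top surface."""
    lib = mat.load_default_library()
    tissue = lib.myocardium
    L = L_mm * 1e-3
    r = np.linspace(0.0, 2e-3, 5)
    z = np.linspace(0.0, L, nz + 1)
    nodes, tris = structured_triangles(r, z)
    mesh = Mesh(nodes=nodes, elements=tris, region=np.full(len(tris), TISSUE),
                mode="axisymmetric")
    from .mesh import facet_adjacency

    facets, ea, eb = facet_adjacency(tris)
    mid = nodes[facets].mean(axis=1)
    top = facets[(eb == -1) & (np.abs(mid[:, 1] - L) < 1e-12)]
    fs = FemSpace(mesh)
    stepper = ThermalStepper(
        fs, {TISSUE: tissue}, robin=[(top, h, T_inf)], dirichlet=[]
    )
    return mesh, fs, stepper, tissue, L


def make_conduction_slab(
    L_mm: float = 5.0, h: float = 694.0, T_init: float = 37.0, T_inf: float = 57.0
) -> AnalyticCase:
    """Slab with insulated base and convective top, step change in ambient."""

    def run() -> Dict:
        mesh, fs, stepper, tissue, L = _slab_setup(L_mm, h, T_inf)
        alpha = tissue.k / tissue.rho_c
        Bi = h * L / tissue.k
        dt, t_end = 0.1, 30.0
        T = np.full(mesh.num_nodes, T_init)
        q = np.zeros(len(mesh.elements))
        t = 0.0
        while t < t_end - 1e-9:
            T, _ = stepper.step(T, q, dt)
            t += dt
        ref = slab_series_temperature(mesh.nodes[:, 1], t_end, L, alpha, Bi,
                                      T_init, T_inf)
        err = float(np.max(np.abs(T - ref)))
        return {"name": "conduction_slab", "error": err, "passed": err < 0.5,
                "units": "degC"}

    return AnalyticCase("conduction_slab", tolerance=0.5, run=run)


def make_lumped_slab(h: float = 5.0) -> AnalyticCase:
    """Small-Biot limit: the slab cools as a single lumped capacitance."""

    def run() -> Dict:
        T_init, T_inf, L_mm = 37.0, 57.0, 2.0
        mesh, fs, stepper, tissue, L = _slab_setup(L_mm, h, T_inf, nz=20)
        tau = tissue.rho_c * L / h
        dt, t_end = 0.05, 60.0
        T = np.full(mesh.num_nodes, T_init)
        q = np.zeros(len(mesh.elements))
        t = 0.0
        while t < t_end - 1e-9:
            T, _ = stepper.step(T, q, dt)
            t += dt
        ref = T_inf + (T_init - T_inf) * np.exp(-t_end / tau)
        err = float(np.max(np.abs(T - ref)) / abs(T_init - T_inf))
        return {"name": "lumped_slab", "error": err, "passed": err < 0.01,
                "units": "relative"}

    return AnalyticCase("lumped_slab", tolerance=0.01, run=run)


# --------------------------------------------------------------------- #
# concentric spheres conduction

def spherical_shell_mesh(r1_mm: float, r2_mm: float, h_in_mm: float = 0.05,
                         h_out_mm: float = 0.5, nth: int = 64):
    """Axisymmetric mesh of a full spherical shell (half annulus revolved),
    graded fine at the inner sphere where the field concentrates."""
    s = graded_points([(r1_mm * 1e-3, r2_mm * 1e-3, h_in_mm * 1e-3, h_out_mm * 1e-3)])
    th = np.linspace(0.0, np.pi, nth + 1)
    S, TH = np.meshgrid(s, th, indexing="ij")
    # map (s, theta) -> (r, z); r = s sin(theta) >= 0
    nodes_grid, tris = structured_triangles(np.arange(len(s), dtype=float),
                                            np.arange(len(th), dtype=float))
    nodes = np.column_stack([
        (S.ravel() * np.sin(TH.ravel())),
        (S.ravel() * np.cos(TH.ravel())),
    ])
    mesh = Mesh(nodes=nodes, elements=tris, region=np.full(len(tris), TISSUE),
                mode="axisymmetric")
    n_th = len(th)
    inner = np.arange(n_th)  # s index 0
    outer = np.arange((len(s) - 1) * n_th, len(s) * n_th)
    return mesh, inner, outer


def make_spherical_electrode_case(sigma: float = 0.5, r1_mm: float = 1.0,
                                  r2_mm: float = 10.0) -> AnalyticCase:
    """Concentric-spheres conduction: conductance, SAR profile, power control."""

    def run() -> Dict:
        mesh, inner, outer = spherical_shell_mesh(r1_mm, r2_mm)
        fs = FemSpace(mesh)
        all_elems = np.arange(len(mesh.elements))
        prob = ElectricProblem(
            fs, all_elems, lambda T: np.full(len(mesh.elements), sigma),
            source_nodes=inner, ground_nodes=outer,
        )
        T = np.zeros(mesh.num_nodes)
        target = 10.0
        sol = prob.solve(T, target)
        r1, r2 = r1_mm * 1e-3, r2_mm * 1e-3
        G = 4 * np.pi * sigma / (1 / r1 - 1 / r2)
        G_fem = sol.total_power / sol.applied_voltage**2
        g_err = abs(G_fem - G) / G
        p_err = abs(sol.total_power - target) / target
        # SAR ~ s^-4 profile at element centroids (away from the poles)
        cent = mesh.nodes[mesh.elements].mean(axis=1)
        s_c = np.linalg.norm(cent, axis=1)
        V = sol.applied_voltage
        E_ref = V * r1 * r2 / (r2 - r1) / s_c**2
        q_ref = sigma * E_ref**2
        sel = (s_c > 1.3 * r1) & (s_c < 0.8 * r2)
        sar_err = float(np.median(np.abs(sol.q_rf[sel] - q_ref[sel]) / q_ref[sel]))
        return {
            "name": "spherical_electrode",
            "error": float(g_err),
            "power_error": float(p_err),
            "sar_profile_error": sar_err,
            "passed": bool(g_err < 0.01 and p_err < 1e-3 and sar_err < 0.05),
            "units": "relative",
        }

    return AnalyticCase("spherical_electrode", tolerance=0.01, run=run)


# --------------------------------------------------------------------- #
# Arrhenius damage

def damage_reference(T_of_t: Callable[[float], float], t_end: float,
                     params: mat.ArrheniusParams = mat.ArrheniusParams()) -> float:
    """High-precision quadrature of the damage integrand for a scalar program."""
    val, _ = quad(
        lambda tau: params.A * np.exp(-params.Ea / (params.R * (T_of_t(tau) + 273.15))),
        0.0, t_end, limit=200,
    )
    return val


def make_damage_case() -> AnalyticCase:
    """Constant and ramped temperature programs vs. quadrature references."""

    def run() -> Dict:
        params = mat.ArrheniusParams()
        errs = []
        # constant exposures
        for T_c, t_end in ((58.0, 5.0), (72.0, 5.0), (37.0, 60.0)):
            times = np.linspace(0.0, t_end, 201)
            hist = np.full((len(times), 1), T_c)
            om = arrhenius_integrate(times, hist, params).omega[-1, 0]
            ref = damage_reference(lambda tau: T_c, t_end, params)
            errs.append(abs(om - ref) / ref)
        # linear ramp 37 -> 90 degC over 10 s (trapezoid on a fine grid)
        times = np.linspace(0.0, 10.0, 4001)
        hist = (37.0 + 5.3 * times)[:, None]
        om = arrhenius_integrate(times, hist, params).omega[-1, 0]
        ref = damage_reference(lambda tau: 37.0 + 5.3 * tau, 10.0, params)
        errs.append(abs(om - ref) / ref)
        err = float(max(errs))
        return {"name": "damage_programs", "error": err, "passed": err < 1e-4,
                "units": "relative"}

    return AnalyticCase("damage_programs", tolerance=1e-4, run=run)


def run_all() -> List[Dict]:
    """Run every analytic benchmark; returns the list of report dicts."""
    cases = [
        make_conduction_slab(),
        make_lumped_slab(),
        make_spherical_electrode_case(),
        make_damage_case(),
    ]
    return [case.run() for case in cases]
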