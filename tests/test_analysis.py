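"""Arrhenius damage, lesion geometry extraction and power accounting."""

import numpy as np
import pandas as pd
import pytest

from rfasim.analysis import (
    LesionMetrics,
    arrhenius_integrate,
    contour_distance,
    extract_lesion,
    isotherm_contour,
    power_energy_accounting,
)
from rfasim.materials import ArrheniusParams
from rfasim.mesh import Mesh, TISSUE, structured_triangles
from rfasim.verification import damage_reference


def _tissue_patch(extent_mm=6.0, h_mm=0.05):
    """Uniform axisymmetric tissue patch r, z in [0, extent] x [-extent, 0]."""
    n = int(extent_mm / h_mm) + 1
    r = np.linspace(0.0, extent_mm * 1e-3, n)
    z = np.linspace(-extent_mm * 1e-3, 0.0, n)
    nodes, tris = structured_triangles(r, z)
    return Mesh(nodes=nodes, elements=tris, region=np.full(len(tris), TISSUE),
                mode="axisymmetric")


class TestArrhenius:
    def test_empty_history_gives_zero(self):
        field = arrhenius_integrate([0.0], [[55.0, 70.0]])
        assert np.all(field.omega == 0.0)

    def test_constant_exposure_matches_scalar_oracle(self):
        """72 degC for 5 s: Omega = 5*A*exp(-Ea/(R*345.15)), six significant digits."""
        times = np.linspace(0.0, 5.0, 101)
        field = arrhenius_integrate(times, np.full((101, 1), 72.0))
        p = ArrheniusParams()
        exact = 5.0 * p.A * np.exp(-p.Ea / (p.R * 345.15))
        assert field.omega[-1, 0] == pytest.approx(exact, rel=1e-6)
        assert field.omega[-1, 0] == pytest.approx(36.9458, rel=1e-5)
        # independent high-precision quadrature agrees too
        assert damage_reference(lambda t: 72.0, 5.0) == pytest.approx(exact, rel=1e-9)

    def test_near_unity_exposure_point(self):
        """Constant 58 degC for 5 s sits just below the Omega = 1 lesion level."""
        times = np.linspace(0.0, 5.0, 51)
        om = arrhenius_integrate(times, np.full((51, 1), 58.0)).omega[-1, 0]
        assert om == pytest.approx(0.829398, rel=1e-5)
        cold = arrhenius_integrate(np.linspace(0, 60, 61), np.full((61, 1), 37.0))
        assert cold.omega[-1, 0] < 0.02

    def test_duration_linearity_and_additivity(self):
        t1 = np.linspace(0.0, 5.0, 51)
        t2 = np.linspace(0.0, 10.0, 101)
        om1 = arrhenius_integrate(t1, np.full((51, 1), 65.0)).omega[-1, 0]
        om2 = arrhenius_integrate(t2, np.full((101, 1), 65.0)).omega[-1, 0]
        assert om2 == pytest.approx(2.0 * om1, rel=1e-12)
        # piecewise program: splitting the same sampled history at any point
        # decomposes the integral exactly
        times = np.linspace(0.0, 10.0, 201)
        T = (60.0 + times)[:, None]
        total = arrhenius_integrate(times, T).omega[-1, 0]
        seg1 = arrhenius_integrate(times[:101], T[:101]).omega[-1, 0]
        seg2 = arrhenius_integrate(times[100:] - times[100], T[100:]).omega[-1, 0]
        assert total == pytest.approx(seg1 + seg2, rel=1e-12)

    def test_monotone_in_time(self):
        times = np.linspace(0.0, 20.0, 201)
        T = 37.0 + 40.0 * np.exp(-times / 5.0)  # cooling transient
        om = arrhenius_integrate(times, T[:, None]).omega[:, 0]
        assert np.all(np.diff(om) >= 0.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            arrhenius_integrate([0.0, 0.0], [[37.0], [37.0]])  # not increasing
        with pytest.raises(ValueError):
            arrhenius_integrate([0.0, 1.0], [[37.0], [-300.0]])  # below abs zero
        with pytest.raises(ValueError):
            arrhenius_integrate([0.0, 1.0], [[37.0], [np.nan]])


class TestLesionExtraction:
    def test_hemispherical_lesion_metrics(self):
        """Omega >= 1 exactly in a half-ball of radius 3 mm on the surface."""
        mesh = _tissue_patch()
        d = np.linalg.norm(mesh.nodes, axis=1) * 1e3  # mm from surface center
        omega = 2.0 - d / 3.0  # linear in distance; crosses 1 at d = 3
        m = extract_lesion(omega, mesh)
        assert m.depth == pytest.approx(3.0, abs=0.02)
        assert m.max_width == pytest.approx(6.0, abs=0.04)
        assert m.volume == pytest.approx(2 * np.pi * 27.0 / 3.0, rel=0.01)
        assert m.ratio == pytest.approx(2.0, abs=0.02)
        assert not m.empty

    def test_subthreshold_field_is_empty(self):
        mesh = _tissue_patch(h_mm=0.5)
        m = extract_lesion(np.full(mesh.num_nodes, 0.5), mesh)
        assert m.empty
        assert m.depth == 0.0 and m.volume == 0.0

    def test_metrics_stable_under_refinement(self):
        """Contour interpolation: refining 2x moves metrics by < element size."""
        vals = {}
        for h in (0.2, 0.1):
            mesh = _tissue_patch(h_mm=h)
            d = np.linalg.norm(mesh.nodes, axis=1) * 1e3
            vals[h] = extract_lesion(2.0 - d / 3.0, mesh)
        assert abs(vals[0.2].depth - vals[0.1].depth) < 0.2
        assert abs(vals[0.2].max_width - vals[0.1].max_width) < 0.4

    def test_threshold_is_configurable(self):
        mesh = _tissue_patch(h_mm=0.2)
        d = np.linalg.norm(mesh.nodes, axis=1) * 1e3
        omega = 2.0 - d / 3.0
        deeper = extract_lesion(omega, mesh, threshold=0.5)
        assert deeper.depth > extract_lesion(omega, mesh).depth


class TestIsotherm:
    def test_uniform_field_has_no_contour(self):
        mesh = _tissue_patch(h_mm=0.5)
        pts = isotherm_contour(np.full(mesh.num_nodes, 37.0), 50.0, mesh)
        assert len(pts) == 0

    def test_linear_radial_field_inverts_exactly(self):
        mesh = _tissue_patch(extent_mm=8.0, h_mm=0.2)
        r_mm = mesh.nodes[:, 0] * 1e3  # cylindrical radius
        T = 100.0 - 10.0 * r_mm  # linear in r: contour inverts exactly
        pts = isotherm_contour(T, 50.0, mesh)
        assert len(pts) > 0
        assert np.allclose(pts[:, 0], 5.0, atol=1e-9)

    def test_contour_distance_symmetric(self):
        a = np.array([[0.0, 0.0], [1.0, 0.0]])
        b = np.array([[0.0, 0.5]])
        assert contour_distance(a, b) == contour_distance(b, a)


class TestPowerAccounting:
    @staticmethod
    def _log(p_tissue, p_total, times):
        return pd.DataFrame(
            {"time_s": times, "P_tissue_W": p_tissue, "P_total_W": p_total}
        )

    def test_all_power_in_tissue(self):
        log = self._log([10.0, 10.0], [10.0, 10.0], [0.05, 0.1])
        acc = power_energy_accounting(log)
        assert acc.P_T == acc.E_T == 100.0

    def test_constant_split_makes_energy_equal_power_share(self):
        log = self._log([4.0, 4.0, 4.0], [16.0, 16.0, 16.0], [0.05, 0.1, 0.15])
        acc = power_energy_accounting(log)
        assert acc.P_T == pytest.approx(25.0)
        assert acc.E_T == pytest.approx(acc.P_T)

    def test_rising_tissue_share_raises_energy_fraction(self):
        log = self._log([4.0, 6.0], [16.0, 16.0], [0.05, 0.1])
        acc = power_energy_accounting(log)
        assert acc.E_T > acc.P_T

    def test_no_pulse_rejected(self):
        with pytest.raises(ValueError):
            power_energy_accounting(self._log([0.0], [0.0], [0.05]))
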