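"""Scenario geometry, meshing and tagging."""

import numpy as np
import pytest

from rfasim.fem import FemSpace
from rfasim.geometry import (
    CatheterSpec,
    Resolution,
    ScenarioGeometry,
    build_3d_half,
    build_axisymmetric,
    build_geometry,
)
from rfasim.mesh import (
    BLOOD,
    ELECTRODE,
    Mesh,
    SHAFT,
    TISSUE,
    facet_adjacency,
    graded_points,
)


class TestCatheter:
    def test_dimensions(self):
        cat = CatheterSpec()
        assert cat.electrode_diameter == 2.5  # 7.5 Fr
        assert cat.electrode_length == 3.5
        assert cat.cylinder_length == pytest.approx(2.25)

    @pytest.mark.parametrize("orientation,depth", [(90, 0.5), (45, 0.498), (0, 0.193)])
    def test_default_insertion_depths(self, orientation, depth):
        assert CatheterSpec(orientation=orientation).insertion_depth == depth

    def test_contact_area_equal_across_orientations(self):
        """Insertion depths are chosen to equalize the contact surface."""
        areas = {o: CatheterSpec(orientation=o).contact_area() for o in (0, 45, 90)}
        ref = areas[90]
        # perpendicular case is a spherical cap: 2*pi*R*insertion
        assert ref == pytest.approx(2 * np.pi * 1.25 * 0.5, rel=1e-3)
        for o, area in areas.items():
            assert area == pytest.approx(ref, rel=0.05), f"orientation {o}"

    def test_too_deep_insertion_rejected(self):
        with pytest.raises(ValueError):
            CatheterSpec(orientation=90, insertion_depth=3.6)


class TestScenario:
    def test_intermediate_uses_tm_geometry_with_myocardium(self):
        inter = ScenarioGeometry(model="INTERMEDIATE")
        tm = ScenarioGeometry(model="TM")
        assert inter.tissue_material == "myocardium"
        assert tm.tissue_material == "striated_muscle"
        assert inter.blood_top == tm.blood_top == 20.0

    def test_bh_blood_fills_domain(self):
        assert ScenarioGeometry(model="BH").blood_top == 40.0

    def test_nonpositive_blood_height_rejected(self):
        with pytest.raises(ValueError):
            ScenarioGeometry(model="TM", blood_height=0.0)


class TestGradedPoints:
    def test_includes_breakpoints_and_monotone(self):
        pts = graded_points([(0.0, 1.25, 0.1, 0.1), (1.25, 10.0, 0.1, 1.0)])
        assert np.all(np.diff(pts) > 0)
        for x in (0.0, 1.25, 10.0):
            assert np.any(np.isclose(pts, x))

    def test_step_sizes_grade_geometrically(self):
        pts = graded_points([(0.0, 10.0, 0.1, 1.0)])
        steps = np.diff(pts)
        assert steps[0] < 0.2 and steps[-1] > 0.5


class TestAxisymmetricMesh:
    def test_regions_partition_and_radius_nonnegative(self, bh_mesh):
        assert set(np.unique(bh_mesh.region)) == {TISSUE, BLOOD, ELECTRODE, SHAFT}
        assert bh_mesh.nodes[:, 0].min() >= -1e-15

    def test_exterior_facets_partition(self, bh_mesh):
        facets, ea, eb = facet_adjacency(bh_mesh.elements)
        n_ext = int((eb == -1).sum())
        tagged = (
            len(bh_mesh.facets["dispersive_0V"])
            + len(bh_mesh.facets["air_blood_zero_current"])
            + len(bh_mesh.facets["symmetry"])
        )
        assert tagged == n_ext

    def test_bh_every_outer_facet_grounded(self, bh_mesh):
        """BH model: dispersive 0 V on all outer limits (symmetry axis apart)."""
        assert len(bh_mesh.facets["air_blood_zero_current"]) == 0
        mids = bh_mesh.nodes[bh_mesh.facets["dispersive_0V"]].mean(axis=1)
        r, z = mids[:, 0], mids[:, 1]
        on_box = (np.isclose(r, 0.04) | np.isclose(z, -0.04) | np.isclose(z, 0.04))
        assert on_box.all()

    def test_tm_top_is_air_interface(self, tm_mesh):
        top = tm_mesh.facets["air_blood_zero_current"]
        assert len(top) > 0
        assert np.allclose(tm_mesh.nodes[top][:, :, 1], 0.020)

    def test_tissue_volume_matches_analytic(self, bh_mesh):
        """Slab minus embedded spherical cap, within 1%."""
        fs = FemSpace(bh_mesh)
        vt = fs.volume[bh_mesh.region == TISSUE].sum()
        R, ins, margin = 1.25e-3, 0.5e-3, 0.04
        slab = np.pi * margin**2 * margin
        cap = np.pi * ins**2 * (R - ins / 3.0)
        assert vt == pytest.approx(slab - cap, rel=0.01)

    def test_irrigated_zone_is_cylindrical_only(self, bh_mesh):
        """Irrigation (25 degC) on the cylinder side; tip hemisphere stays free."""
        mids = bh_mesh.nodes[bh_mesh.facets["irrigated_dirichlet"]].mean(axis=1) * 1e3
        assert np.all(mids[:, 1] > 0.75 - 1e-6)  # above the tip-sphere equator
        assert np.allclose(mids[:, 0], 1.25, atol=1e-6)  # on the lateral surface
        tip = bh_mesh.nodes[bh_mesh.facets["electrode_blood_convective"]].mean(axis=1) * 1e3
        assert len(tip) > 0

    def test_min_edge_near_electrode_tracks_resolution(self):
        res = Resolution(h_min=0.1)
        mesh = build_axisymmetric(ScenarioGeometry(model="BH"), res)
        p = mesh.nodes[mesh.elements] * 1e3
        edge = np.linalg.norm(p[:, 1] - p[:, 0], axis=1)
        cent = p.mean(axis=1)
        near = np.linalg.norm(cent - [0.0, 0.75], axis=1) < 2.0
        assert edge[near].min() <= 0.118  # paper-fidelity refinement at the tip


class TestHalfDomainMesh:
    def test_axisym_and_3d_region_volumes_agree(self):
        """Revolved axisymmetric volumes match the 3D half-domain within 2%.

        Compared over the near-field cylinder (r <= 6 mm, z >= -8 mm) that
        contains the electrode and the lesion; the outer boxes differ by
        construction (cylinder vs. box far field, screened by the 0 V
        condition at 40 mm).
        """
        sc = ScenarioGeometry(model="TM")
        res = Resolution()
        m2 = build_axisymmetric(sc, res)
        m3 = build_3d_half(sc, res)
        fs2, fs3 = FemSpace(m2), FemSpace(m3)
        c2 = m2.nodes[m2.elements].mean(axis=1)
        c3 = m3.nodes[m3.elements].mean(axis=1)
        in2 = (c2[:, 0] <= 0.006) & (c2[:, 1] >= -0.008)
        in3 = (np.hypot(c3[:, 0], c3[:, 1]) <= 0.006) & (c3[:, 2] >= -0.008)
        for region in (TISSUE, BLOOD):
            v2 = fs2.volume[(m2.region == region) & in2].sum()
            v3 = fs3.volume[(m3.region == region) & in3].sum() * m3.domain_factor
            assert v3 == pytest.approx(v2, rel=0.02), f"region {region}"

    def test_oriented_catheter_mesh_tags(self, coarse_res):
        sc = ScenarioGeometry(model="TM", catheter=CatheterSpec(orientation=45))
        mesh = build_geometry(sc, coarse_res)
        assert mesh.mode == "3d_half"
        assert len(mesh.facets["symmetry"]) > 0
        assert len(mesh.facets["irrigated_dirichlet"]) > 0
        assert len(mesh.facets["air_blood_zero_current"]) > 0
        # electrode tilted toward +x: its centroid sits off-axis
        fs = FemSpace(mesh)
        el = mesh.region == ELECTRODE
        cx = (fs.volume[el] * mesh.nodes[mesh.elements[el]].mean(axis=1)[:, 0]).sum()
        assert cx / fs.volume[el].sum() > 1e-4

    def test_axisymmetric_mode_rejects_tilted_catheter(self, coarse_res):
        sc = ScenarioGeometry(model="BH", catheter=CatheterSpec(orientation=45))
        with pytest.raises(ValueError):
            build_axisymmetric(sc, coarse_res)
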