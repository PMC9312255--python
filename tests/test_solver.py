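"""Electrical solve, thermal stepping and the coupled simulation loop."""

import numpy as np
import pytest

from rfasim.fem import FemSpace
from rfasim.geometry import ScenarioGeometry
from rfasim.mesh import BLOOD, SHAFT, TISSUE
from rfasim.solver import (
    ElectricProblem,
    EnergySetting,
    make_electric_problem,
    run_simulation,
    solve_electric,
)
from rfasim.verification import (
    make_conduction_slab,
    make_lumped_slab,
    make_spherical_electrode_case,
    spherical_shell_mesh,
)


class TestEnergySetting:
    def test_twenty_percent_power_reduction(self):
        s = EnergySetting.preset("MPMD")
        assert (s.nominal_power, s.pulse_duration) == (25.0, 20.0)
        assert s.applied_power == pytest.approx(20.0)
        assert EnergySetting.preset("VHPVSD").applied_power == pytest.approx(72.0)
        assert s.observation_time == 90.0


class TestElectric:
    def test_power_linearity(self, bh_mesh, lib):
        """Doubling target power scales voltage by sqrt(2) and Q_rf by 2."""
        fs = FemSpace(bh_mesh)
        prob = make_electric_problem(fs, lib, lib.myocardium)
        T = np.full(bh_mesh.num_nodes, 37.0)
        a = prob.solve(T, 10.0)
        b = prob.solve(T, 20.0)
        assert b.applied_voltage == pytest.approx(a.applied_voltage * np.sqrt(2.0))
        assert np.allclose(b.q_rf, 2.0 * a.q_rf)

    def test_power_normalization_and_split(self, bh_mesh):
        sol = solve_electric(bh_mesh, 37.0, target_power=20.0)
        assert sol.total_power == pytest.approx(20.0, rel=1e-3)
        fractions = np.array([v for v in sol.power_split.values()]) / sol.total_power
        assert fractions.sum() == pytest.approx(1.0)
        # shaft is an insulator: negligible dissipation
        assert sol.power_split.get("shaft", 0.0) < 1e-4 * sol.total_power

    def test_striated_muscle_draws_more_power_than_myocardium(self, tm_mesh, lib):
        """Material swap on the identical mesh raises the tissue power share."""
        myo = solve_electric(tm_mesh, 37.0, 20.0, lib=lib, tissue=lib.myocardium)
        sm = solve_electric(tm_mesh, 37.0, 20.0, lib=lib, tissue=lib.striated_muscle)
        f_myo = myo.power_split["tissue"] / myo.total_power
        f_sm = sm.power_split["tissue"] / sm.total_power
        assert f_sm > f_myo

    def test_concentric_spheres_conductance(self):
        report = make_spherical_electrode_case().run()
        assert report["error"] < 0.01
        assert report["power_error"] < 1e-3
        assert report["sar_profile_error"] < 0.05

    def test_nonpositive_power_rejected(self, bh_mesh):
        with pytest.raises(ValueError):
            solve_electric(bh_mesh, 37.0, 0.0)

    def test_missing_ground_rejected(self):
        mesh, inner, outer = spherical_shell_mesh(1.0, 5.0, h_in_mm=0.2, nth=16)
        fs = FemSpace(mesh)
        with pytest.raises(ValueError):
            ElectricProblem(fs, np.arange(len(mesh.elements)),
                            lambda T: np.full(len(mesh.elements), 0.5),
                            source_nodes=inner, ground_nodes=np.array([], int))


class TestThermal:
    def test_isothermal_steady_state(self, bh_short_run):
        """No source, ambient at body temperature: the field stays at 37 degC."""
        from rfasim.solver import make_thermal_stepper, BoundaryConditions
        from rfasim.materials import load_default_library

        lib = load_default_library()
        bc = BoundaryConditions(T_irrigation=37.0)  # disable the only cold sink
        fs = bh_short_run.fs
        stepper = make_thermal_stepper(fs, lib, lib.myocardium, bc)
        T = np.full(fs.mesh.num_nodes, 37.0)
        T_new, bal = stepper.step(T, np.zeros(len(fs.mesh.elements)), 0.05)
        assert np.allclose(T_new, 37.0, atol=1e-9)

    def test_heating_raises_peak_temperature(self, bh_short_run):
        log = bh_short_run.log
        assert log.max_tissue_T.iloc[0] > 37.0  # first step already heats
        in_pulse = log[log.P_total_W > 0]
        assert in_pulse.max_tissue_T.is_monotonic_increasing

    def test_slab_series_benchmark(self):
        report = make_conduction_slab().run()
        assert report["error"] < 0.5  # degC against a >=10-term series

    def test_lumped_capacitance_limit(self):
        report = make_lumped_slab().run()
        assert report["error"] < 0.01

    def test_time_step_range_enforced(self, coarse_res):
        with pytest.raises(ValueError):
            run_simulation(ScenarioGeometry(model="BH"),
                           EnergySetting(20.0, 1.0, 2.0),
                           resolution=coarse_res, dt=0.5)


class TestSimulation:
    def test_energy_balance_closes(self, bh_short_run):
        b = bh_short_run.energy_balance
        err = b["deposited_J"] - b["stored_J"] - b["robin_loss_J"] - b["dirichlet_loss_J"]
        assert abs(err) < 0.01 * b["deposited_J"]

    def test_power_held_constant_during_pulse(self, bh_short_run):
        log = bh_short_run.log
        in_pulse = log[log.P_total_W > 0]
        assert np.allclose(in_pulse.P_total_W, 16.0, rtol=1e-3)  # 20 W nominal - 20%
        # and is off afterwards with voltage zeroed
        post = log[log.time_s > 2.0 + 1e-6]
        assert (post.P_total_W == 0).all()
        assert (post.applied_voltage_V == 0).all()

    def test_temperature_bounded_below(self, bh_short_run):
        assert bh_short_run.T_final.min() >= 25.0 - 1e-6

    def test_thermal_latency_grows_lesion(self, bh_short_run):
        """Damage keeps accruing after power off (monotone Omega)."""
        assert np.all(bh_short_run.omega_final >= bh_short_run.omega_pulse_end - 1e-15)

    def test_zero_duration_pulse_is_inert(self, coarse_res):
        r = run_simulation(ScenarioGeometry(model="BH"),
                           EnergySetting(25.0, 0.0, observation_time=1.0),
                           resolution=coarse_res)
        assert r.peak_temperature <= 37.0 + 0.05  # small non-M-matrix overshoot
        assert r.lesion_at_end().empty
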