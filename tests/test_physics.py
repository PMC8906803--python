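"""Stokes density, terminal velocity, and the suction-flow simulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import oroflow as of
from oroflow.physics import (
    NonTerminalError,
    SuctionModel,
    cube_to_sphere_volume_ratio,
    default_release_points,
    fidelity_of,
    particle_relaxation_time,
)
from oroflow.trajectories import FluidProperties, TracerSpec


class TestStokesDensity:
    def test_zero_settling_is_neutral(self):
        assert of.stokes_density(0.0) == pytest.approx(1000.0, abs=1e-12)

    def test_printed_maximum_density(self):
        # the heaviest usable tracer sank at ~5.22 cm/s
        assert of.stokes_density(0.05224) == pytest.approx(1049.0, abs=0.05)

    def test_printed_sample_mean_density(self):
        # the test-sample mean rose at 0.64 cm/s
        assert of.stokes_density(-0.0064) == pytest.approx(994.0, abs=0.05)

    def test_round_trip_with_inverse(self):
        for rho in (950.0, 998.0, 1049.0, 1200.0):
            v = of.settling_velocity(rho)
            assert of.stokes_density(v) == pytest.approx(rho, rel=1e-12)

    def test_high_reynolds_warns(self):
        with pytest.warns(UserWarning, match="Reynolds"):
            of.stokes_density(2.0)

    def test_invalid_diameter(self):
        with pytest.raises(ValueError):
            of.stokes_density(0.01, d=0.0)

    @given(st.floats(-0.1, 0.1), st.floats(-0.1, 0.1))
    @settings(max_examples=30, deadline=None)
    def test_affine_in_settling_velocity(self, v1, v2):
        fluid = FluidProperties()
        d = 1.4e-3
        slope = 18 * fluid.dynamic_viscosity / (fluid.gravity * d**2)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1, r2 = of.stokes_density(v1, fluid, d), of.stokes_density(v2, fluid, d)
        assert r1 - r2 == pytest.approx(slope * (v1 - v2), rel=1e-9, abs=1e-9)


class TestTerminalVelocity:
    def test_exact_linear_descent(self):
        t = np.arange(100) / 50.0
        y = -0.05 * t
        out = of.terminal_velocity(y, 50.0)
        assert out["v_terminal"] == pytest.approx(-0.05, abs=1e-12)
        assert out["fit_quality"] == pytest.approx(0.0, abs=1e-12)

    def test_relaxation_profile_recovered_within_one_percent(self):
        v_t, tau = -0.052, 0.01
        t = np.arange(1000) / 1000.0
        y = v_t * (t - tau * (1 - np.exp(-t / tau)))
        out = of.terminal_velocity(y, 1000.0)
        assert out["v_terminal"] == pytest.approx(v_t, rel=0.01)

    def test_noisy_drop_test_within_five_percent_over_seeds(self):
        """0.1 mm noise at the 50 frames/s drop-test rate, 50 seeds."""
        spec = TracerSpec(density=1049.0)
        for seed in range(50):
            y = of.generate_drop_test(spec, noise_sd=0.1, frame_rate=50.0, seed=seed)
            out = of.terminal_velocity(y, 50.0)
            v_true = -of.settling_velocity(1049.0)
            assert out["v_terminal"] == pytest.approx(v_true, rel=0.05)

    def test_non_terminal_record_raises(self):
        t = np.arange(200) / 50.0
        y = -0.01 * t**2  # still accelerating
        with pytest.raises(NonTerminalError):
            of.terminal_velocity(y, 50.0)


class TestVolumeRatio:
    def test_cube_more_than_five_times_sphere(self):
        ratio = cube_to_sphere_volume_ratio(2e-3, 1.4e-3)
        assert ratio == pytest.approx(8.0 / ((np.pi / 6) * 1.4**3 / 1e3) / 1e3, rel=1e-12)
        assert ratio > 5.0
        assert ratio == pytest.approx(5.57, abs=0.01)


class TestSuctionModel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SuctionModel(time_step=0.01)  # > ramp_time / 10
        with pytest.raises(ValueError):
            SuctionModel(cavity_radius=0.05, cavity_length=0.04)

    def test_pressure_profile_reaches_peak_and_holds(self):
        m = SuctionModel()
        assert m.pressure(0.0) == 0.0
        assert m.pressure(0.020) == pytest.approx(-2000.0)
        assert m.pressure(0.05) == pytest.approx(-2000.0)
        assert -2000.0 < m.pressure(0.010) < 0.0

    def test_aperture_speed_order_of_magnitude(self):
        # sqrt(2 * 2000 / 1000) = 2 m/s at peak suction
        assert SuctionModel().aperture_speed(0.05) == pytest.approx(2.0)

    def test_release_point_must_be_outside(self):
        with pytest.raises(ValueError, match="inflow half-space"):
            of.simulate_suction(SuctionModel(), TracerSpec(density=1000),
                                np.array([-0.005, 0.0, 0.0]))


class TestSimulateSuction:
    def test_neutral_particle_coincides_with_pathline(self):
        """With matched density the reduced force balance degenerates to
        pure advection; at a refined step the two integrations agree to
        within 1e-6 m."""
        model = SuctionModel(time_step=6.25e-5)
        res = of.simulate_suction(model, TracerSpec(density=1000.0),
                                  np.array([0.005, 0.0, 0.005]))
        n = min(len(res.particle_position), len(res.fluid_position)) - 1
        sep = np.linalg.norm(res.particle_position[:n] - res.fluid_position[:n], axis=1)
        assert sep.max() <= 1e-6

    def test_quiescent_stokes_settling(self):
        """No suction: the particle relaxes onto the analytic terminal
        velocity within 1% after ten relaxation times."""
        spec = TracerSpec(density=1049.0)
        tau = particle_relaxation_time(spec)
        m = SuctionModel(pressure_amplitude=0.0, ramp_time=0.5,
                         total_time=12 * tau, time_step=2e-3)
        res = of.simulate_suction(m, spec, np.array([0.005, 0.0, 0.0]))
        v_end = res.particle_velocity[-1]
        assert v_end[1] == pytest.approx(-of.settling_velocity(1049.0), rel=0.01)
        assert abs(v_end[0]) < 1e-9 and abs(v_end[2]) < 1e-9

    def test_density_ladder_increases_path_separation(self):
        """Heavier particles deviate more from the fluid pathline."""
        model = SuctionModel()
        rp = np.array([0.005, 0.0, 0.005])
        seps = []
        for rho in (998.0, 1100.0, 1200.0):
            res = of.simulate_suction(model, TracerSpec(density=rho), rp)
            seps.append(fidelity_of(res).path_separation)
        assert seps[0] < seps[1] < seps[2]

    def test_time_step_convergence(self):
        """Halving the step moves the final position by <1% of path length."""
        rp = np.array([0.005, 0.0, 0.005])
        finals = []
        for dt in (1.25e-4, 6.25e-5):
            res = of.simulate_suction(SuctionModel(time_step=dt),
                                      TracerSpec(density=1100.0), rp)
            finals.append(res.particle_position[-1])
            length = np.sum(np.linalg.norm(np.diff(res.particle_position, axis=0), axis=1))
        assert np.linalg.norm(finals[0] - finals[1]) < 0.01 * length

    def test_scene_rotation_invariance(self):
        """Rotating gravity with the scene leaves the metrics unchanged."""
        from scipy.spatial.transform import Rotation

        spec = TracerSpec(density=1100.0)
        base = SuctionModel()
        rp = np.array([0.005, 0.0, 0.005])
        rep0 = fidelity_of(of.simulate_suction(base, spec, rp))
        # gravity along -z instead of -y is the same scene rotated 90 deg
        rot = SuctionModel(gravity_direction=(0.0, 0.0, -1.0))
        rp_rot = np.array([0.005, -0.005, 0.0])  # the off-axis offset co-rotated
        rep1 = fidelity_of(of.simulate_suction(rot, spec, rp_rot))
        assert rep1.gravity_deviation == pytest.approx(rep0.gravity_deviation, rel=1e-6)
        assert rep1.path_separation == pytest.approx(rep0.path_separation, rel=1e-6)

    def test_nonphysical_density_rejected(self):
        with pytest.raises(ValueError):
            TracerSpec(density=-1.0)


class TestFidelityMetrics:
    def test_identical_paths_all_zero(self):
        p = np.cumsum(np.ones((50, 3)) * 1e-4, axis=0)
        u = np.gradient(p, 1.25e-4, axis=0)
        rep = of.fidelity_metrics(p, p.copy(), u)
        assert rep.max_lag == 0.0 and rep.max_overshoot == 0.0
        assert rep.gravity_deviation == 0.0 and rep.path_separation == 0.0

    def test_gravity_shifted_path(self):
        p = np.cumsum(np.ones((50, 3)) * 1e-4, axis=0)
        u = np.gradient(p, 1.25e-4, axis=0)
        shifted = p + np.array([0.0, -0.5e-3, 0.0])  # 0.5 mm along gravity
        rep = of.fidelity_metrics(shifted, p, u, gravity_direction=(0, -1, 0))
        assert rep.gravity_deviation == pytest.approx(0.5e-3)
        assert rep.path_separation == pytest.approx(0.5e-3)

    def test_empty_paths_raise(self):
        with pytest.raises(ValueError, match="empty"):
            of.fidelity_metrics(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3)))

    def test_slightly_heavy_tracer_within_paper_bound(self):
        """1050 kg/m^3 from both release points: gravity deviation <= 1 mm."""
        model = SuctionModel()
        worst = 0.0
        for rp in default_release_points(model):
            res = of.simulate_suction(model, TracerSpec(density=1050.0), rp)
            worst = max(worst, fidelity_of(res).gravity_deviation)
        assert worst <= 1e-3
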