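"""Geometry, waveform and analytic flow model of the aneurysm phantom."""

import numpy as np
import pytest

import aneupiv as ap
from aneupiv.metrics import oop_fluctuation_ratio, roi_mean_speed
from aneupiv.phantom import SCENARIO_PRESETS, ScenarioConfig


class TestGeometry:
    def test_sac_mask_area_matches_circle(self, model, geometry):
        """Rasterised sac area equals pi r^2 up to one cell per boundary pixel."""
        h = model.geometry.pitch_mm
        area = geometry.sac_mask.sum() * h * h
        perimeter_cells = 2 * np.pi * 10.0 / h
        assert abs(area - np.pi * 10.0 ** 2) < perimeter_cells * h * h

    def test_point_outside_vessel_radius_not_in_lumen(self, model, geometry):
        # 2.1 mm from the parent-vessel centreline (radius 2 mm), far from the sac
        pt = np.array([-10.0, -2.0 + 2.1, 0.0])
        assert not model.in_lumen(pt[None])[0]
        ix = np.argmin(np.abs(geometry.x - pt[0]))
        iy = np.argmin(np.abs(geometry.y - pt[1]))
        assert not geometry.lumen_mask[iy, ix]

    def test_ostium_endpoints_on_circle_and_wall(self, model, geometry):
        cx, cy = model.geometry.sac_center_mm
        for (px, py) in geometry.ostium_mm:
            r = np.hypot(px - cx, py - cy)
            assert abs(r - 10.0) < 0.5 * model.geometry.pitch_mm
            assert abs(py - 0.0) < 0.5 * model.geometry.pitch_mm

    def test_probe_locations(self, geometry):
        p1, p2, p3 = (geometry.probes[k] for k in ("P1", "P2", "P3"))
        assert p1[0] > 0 and p1[1] > 0          # distal, inside the sac
        assert p3[0] < 0                         # proximal
        assert p2[1] > 15.0                      # dome
        assert geometry.roi_mask.any()

    @pytest.mark.parametrize("kwargs", [
        {"sac_diameter_mm": 3.0},                       # sac smaller than vessel
        {"vessel_diameter_mm": -1.0},
        {"bend_angle_deg": 200.0},
        {"pitch_mm": 3.0},                              # pitch above vessel radius
    ])
    def test_invalid_configs_raise(self, kwargs):
        with pytest.raises(ValueError):
            ap.GeometryConfig(**kwargs)


class TestFluidAndWaveform:
    def test_kinematic_viscosity_closure(self):
        fl = ap.FluidProperties()
        assert fl.kinematic_viscosity == fl.dynamic_viscosity / fl.density

    def test_dimensionless_numbers_consistent(self, model):
        wf, fl = model.waveform, model.fluid
        D = model.geometry.vessel_diameter_mm
        nu = fl.kinematic_viscosity
        assert wf.reynolds(fl, D) == pytest.approx(wf.peak_velocity * D * 1e-3 / nu)
        assert wf.womersley(fl, D) == pytest.approx(
            (D / 2 * 1e-3) * np.sqrt(2 * np.pi / (wf.cycle_duration_s * nu)))

    def test_from_womersley_hits_both_targets(self):
        fl = ap.FluidProperties()
        wf = ap.WaveformConfig.from_womersley(1025.0, 2.54, fl, 4.0)
        assert wf.reynolds(fl, 4.0) == pytest.approx(1025.0, rel=1e-12)
        assert wf.womersley(fl, 4.0) == pytest.approx(2.54, rel=1e-12)

    def test_single_systolic_peak(self, model):
        wf = model.waveform
        assert wf.shape(wf.systolic_peak_phase * wf.cycle_duration_s) == \
            pytest.approx(1.0, abs=1e-9)
        t = np.linspace(0.0, 1.0, 2000, endpoint=False)
        s = model.waveform.shape(t)
        assert s.max() == pytest.approx(1.0, abs=1e-5)
        assert s.min() > 0
        # one global maximum: the peak neighbourhood is unique
        peaks = np.flatnonzero((s > np.roll(s, 1)) & (s > np.roll(s, -1))
                               & (s > 0.9 * s.max()))
        assert len(peaks) == 1


class TestFlowField:
    def test_no_slip_on_wall_contour(self, model, geometry):
        pts = np.column_stack([geometry.wall_points,
                               np.zeros(len(geometry.wall_points))])
        for t in (0.0, 0.2, 0.61):
            vel, _ = model.sample_velocity(pts, t)
            assert np.max(np.abs(vel)) < 1e-12

    def test_centreline_peak_velocity(self, model):
        t_pk = model.waveform.systolic_peak_phase * model.waveform.cycle_duration_s
        vel, inside = model.sample_velocity(np.array([0.0, -2.0, 0.0]), t_pk)
        assert inside
        assert vel[0] == pytest.approx(model.waveform.peak_velocity, rel=1e-9)

    def test_sac_centre_stagnation(self, model, geometry):
        """Central stagnation zone: centre speed below 5 % of the jet speed."""
        t_pk = model.waveform.systolic_peak_phase
        cx, cy = model.geometry.sac_center_mm
        v0, _ = model.sample_velocity(np.array([cx, cy, 0.0]), t_pk)
        p1 = geometry.probes["P1"]
        v1, _ = model.sample_velocity(np.array([p1[0], p1[1], 0.0]), t_pk)
        assert np.linalg.norm(v0) < 0.05 * np.linalg.norm(v1)

    def test_outside_slab_zero_with_flag(self, model):
        vel, inside = model.sample_velocity(np.array([0.0, 5.0, 3.0]), 0.1)
        assert not inside and np.all(vel == 0.0)

    def test_periodicity(self, model):
        rng = np.random.default_rng(5)
        pts = rng.uniform([-10, -3.5, -0.4], [10, 18, 0.4], (64, 3))
        m = model.apply_scenario("FDC1")           # include the stochastic channel
        for t in (0.07, 0.5):
            va, _ = m.sample_velocity(pts, t, cycle=3)
            vb, _ = m.sample_velocity(pts, t + m.waveform.cycle_duration_s, cycle=3)
            np.testing.assert_allclose(va, vb, rtol=1e-12, atol=1e-15)

    def test_in_sac_divergence_free(self, model, geometry):
        """The stream-function field is divergence-free on the grid."""
        X, Y = np.meshgrid(geometry.x, geometry.y)
        pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        vel, _ = model.sample_velocity(pts, 0.2)
        U = vel[:, 0].reshape(X.shape)
        V = vel[:, 1].reshape(X.shape)
        h = model.geometry.pitch_mm
        div = np.gradient(U, h, axis=1) + np.gradient(V, h, axis=0)
        cx, cy = model.geometry.sac_center_mm
        interior = ((X - cx) ** 2 + (Y - cy) ** 2 < 9.0 ** 2) & (Y > 1.0)
        scale = np.abs(np.gradient(U, h, axis=1)[interior]).max()
        assert np.abs(div[interior]).max() < 0.05 * scale


class TestScenarios:
    def test_neutral_scenario_is_identity(self, model):
        neutral = ScenarioConfig("neutral", alpha=0.0, jet_entry_shift_mm=0.0,
                                 oop_fluctuation=0.0)
        m = model.apply_scenario(neutral)
        rng = np.random.default_rng(2)
        pts = rng.uniform([-10, -3.5, 0], [10, 18, 0], (128, 3))
        va, _ = model.sample_velocity(pts, 0.31)
        vb, _ = m.sample_velocity(pts, 0.31)
        np.testing.assert_array_equal(va, vb)

    def test_apply_scenario_twice_raises(self, model):
        m = model.apply_scenario("FDC1")
        with pytest.raises(ValueError):
            m.apply_scenario("FDC2")

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig("bad", alpha=1.0)

    def test_presets_baseline(self):
        assert SCENARIO_PRESETS["noFD"].alpha == 0.0
        assert SCENARIO_PRESETS["noFD"].oop_fluctuation == ap.phantom.BASELINE_OOP

    def test_fdc1_reduction_matches_preset(self, model_pacs, coarse_roi):
        """FDC1 attenuates the ROI cyclic-mean speed by 78 +- 2 points."""
        u0 = roi_mean_speed(model_pacs["noFD"], coarse_roi)
        u1 = roi_mean_speed(model_pacs["FDC1"], coarse_roi)
        assert 100.0 * (1.0 - u1 / u0) == pytest.approx(78.0, abs=2.0)

    def test_fdc3_oop_level_matches_table(self, model_pacs, coarse_roi):
        """FDC3 normalized out-of-plane fluctuation reaches 0.364 +- 0.03."""
        ratio = oop_fluctuation_ratio(model_pacs["FDC3"], coarse_roi)
        assert ratio == pytest.approx(0.364, abs=0.03)

    def test_reduction_monotone_in_alpha(self, model, coarse_grid, coarse_roi):
        """ROI cyclic-mean speed decreases strictly with the attenuation."""
        x, y, X, Y = coarse_grid
        speeds = []
        for alpha in (0.0, 0.3, 0.6, 0.9):
            m = model.apply_scenario(ScenarioConfig(f"a{alpha}", alpha=alpha,
                                                    oop_fluctuation=0.0))
            s = m.cycle_mean_speed_inplane(X[coarse_roi], Y[coarse_roi])
            speeds.append(float(np.mean(s)))
        assert all(a > b for a, b in zip(speeds, speeds[1:]))

    def test_oop_disturbance_zero_mean_over_cycles(self, coarse_grid):
        x, y, X, Y = coarse_grid
        m = ap.default_model(seed=0).apply_scenario("FDC3")
        pts = np.column_stack([X.ravel(), Y.ravel(), np.zeros(X.size)])
        acc = np.zeros(X.size)
        n_cycles = 12
        for c in range(n_cycles):
            vel, _ = m.sample_velocity(pts, 0.27, cycle=c)
            acc += vel[:, 2]
        # ensemble mean small relative to the per-cycle spread
        one, _ = m.sample_velocity(pts, 0.27, cycle=0)
        assert np.abs(acc / n_cycles).max() < 0.3 * np.abs(one[:, 2]).max()
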