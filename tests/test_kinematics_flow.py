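import numpy as np
import pytest

from cardioflow.kinematics_flow import (FlowCurve, VolumeCurve,
                                        fit_motion_splines, flow_metrics,
                                        laa_flow_curve, mitral_flow_curve,
                                        ostium_plane_from_labels,
                                        volume_curve)
from cardioflow.mesh_core import Region
from cardioflow.tracking import TrackedSequence


def make_sequence(mesh, labels, displacement_fn, n_frames=20, T=1.0):
    """Sequence whose frame positions are mesh.vertices + displacement(t)."""
    times = np.arange(n_frames) / n_frames * 100.0
    pos = np.stack([mesh.vertices + displacement_fn(t / 100.0 * T)
                    for t in times])
    return TrackedSequence(mesh=mesh, labels=labels, positions=pos,
                           frame_times_pct=times, cycle_length=T)


@pytest.fixture(scope="module")
def phantom_seq():
    """Analytically deformed phantom sequence (no registration error); finer
    than the shared coarse phantom so mesh discretization stays below the
    volume tolerances."""
    from cardioflow.synthetic_phantom import PhantomSpec, generate_phantom_cycle
    data = generate_phantom_cycle(PhantomSpec(mesh_resolution=5.0,
                                              laa_resolution=2.2))
    times = np.arange(20) / 20.0
    pos = np.stack([data.source_positions_at(t) for t in times])
    return data, TrackedSequence(mesh=data.source, labels=data.labels,
                                 positions=pos,
                                 frame_times_pct=times * 100.0,
                                 cycle_length=1.0)


class TestFitMotionSplines:
    def test_constant_trajectory(self, coarse_phantom):
        data = coarse_phantom
        seq = make_sequence(data.source, data.labels, lambda t: 0.0)
        motion = fit_motion_splines(seq)
        assert motion.max_fit_deviation == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(motion.sample(0.3), data.source.vertices)

    def test_single_harmonic_within_2pct(self, coarse_phantom):
        data = coarse_phantom
        amp = 2.0
        seq = make_sequence(data.source, data.labels,
                            lambda t: np.array([amp * np.sin(2 * np.pi * t),
                                                0.0, 0.0]))
        motion = fit_motion_splines(seq)
        for t in (0.125, 0.4, 0.77):
            expected = data.source.vertices + [amp * np.sin(2 * np.pi * t),
                                               0.0, 0.0]
            err = np.abs(motion.sample(t) - expected).max()
            assert err < 0.02 * amp

    def test_export_grid_count(self, coarse_phantom):
        data = coarse_phantom
        seq = make_sequence(data.source, data.labels, lambda t: 0.0)
        motion = fit_motion_splines(seq)
        assert len(motion.export_times(0.0005)) == 2001

    def test_too_many_knots_raises(self, coarse_phantom):
        data = coarse_phantom
        seq = make_sequence(data.source, data.labels, lambda t: 0.0)
        with pytest.raises(ValueError, match="knots"):
            fit_motion_splines(seq, n_knots=30)


class TestVolumeCurve:
    def test_rigid_translation_constant_volume(self, phantom_seq):
        data, _ = phantom_seq
        seq = make_sequence(data.source, data.labels,
                            lambda t: np.array([10 * t, -5 * t, 2 * t]))
        motion = fit_motion_splines(seq)
        curve = volume_curve(motion, data.source, data.labels, Region.LV,
                             dt=0.05)
        assert np.ptp(curve.volumes) / curve.volumes.mean() < 1e-6

    def test_phantom_lv_matches_analytic(self, phantom_seq):
        data, seq = phantom_seq
        motion = fit_motion_splines(seq)
        curve = volume_curve(motion, seq.mesh, seq.labels, Region.LV, dt=0.01)
        truth = data.truth.lv_volume(curve.times)
        assert np.abs(curve.volumes - truth).max() < 0.03 * truth.mean()

    def test_grid_inclusive(self, phantom_seq):
        data, seq = phantom_seq
        motion = fit_motion_splines(seq)
        curve = volume_curve(motion, seq.mesh, seq.labels, Region.LV, dt=0.25)
        assert len(curve.times) == 5
        assert curve.times[-1] == pytest.approx(1.0)

    def test_spline_smoothing_volume_unbiased(self, phantom_seq):
        # cycle-mean volume from the spline within 1% of raw-frame mean
        data, seq = phantom_seq
        from cardioflow.kinematics_flow import (_REGION_SETS,
                                                _RegionVolumeSampler)
        sampler = _RegionVolumeSampler(seq.mesh, seq.labels,
                                       _REGION_SETS[Region.LV])
        raw_mean = np.mean([sampler.volume(p) for p in seq.positions])
        motion = fit_motion_splines(seq)
        curve = volume_curve(motion, seq.mesh, seq.labels, Region.LV, dt=0.005)
        assert curve.volumes[:-1].mean() == pytest.approx(raw_mean, rel=0.01)


class TestMitralFlow:
    def test_linear_ramp(self):
        t = np.arange(0, 1.0001, 0.005)
        ramp = np.minimum(t, 1.0 - t) * 200.0  # up then down, peak 100 ml
        curve = VolumeCurve(times=t, volumes=50.0 + ramp)
        mv = mitral_flow_curve(curve)
        interior = (t > 0.05) & (t < 0.45)
        assert np.allclose(mv.raw_dvdt[interior], 200.0)
        assert np.allclose(mv.flow[interior], 200.0)
        falling = (t > 0.55) & (t < 0.95)
        assert np.allclose(mv.raw_dvdt[falling], -200.0)
        assert np.allclose(mv.flow[falling], 0.0)  # ejection reported as 0

    def test_constant_volume_zero_flow(self):
        t = np.arange(0, 1.0001, 0.005)
        mv = mitral_flow_curve(VolumeCurve(times=t, volumes=np.full_like(t, 80)))
        assert np.allclose(mv.flow, 0.0)
        assert np.allclose(mv.raw_dvdt, 0.0)


class TestLaaFlow:
    def test_static_laa_zero_flow(self, coarse_phantom):
        data = coarse_phantom
        seq = make_sequence(data.source, data.labels, lambda t: 0.0)
        motion = fit_motion_splines(seq)
        plane = ostium_plane_from_labels(data.source, data.labels)
        laa = laa_flow_curve(motion, data.source, data.labels, plane, dt=0.05)
        assert np.abs(laa.flow).max() < 1e-6

    def test_cycle_integral_near_zero(self, phantom_seq):
        data, seq = phantom_seq
        motion = fit_motion_splines(seq)
        plane = ostium_plane_from_labels(seq.mesh, seq.labels)
        laa = laa_flow_curve(motion, seq.mesh, seq.labels, plane, dt=0.01)
        net = np.sum(laa.flow[:-1]) * 0.01   # cyclic integral over one period
        vmax = data.spec.laa_vmax
        assert abs(net) < 0.01 * vmax

    def test_peak_outflow_near_prescribed_contraction(self, phantom_seq):
        data, seq = phantom_seq
        motion = fit_motion_splines(seq)
        plane = ostium_plane_from_labels(seq.mesh, seq.labels)
        laa = laa_flow_curve(motion, seq.mesh, seq.labels, plane, dt=0.005)
        peak_t = laa.times[np.argmax(laa.flow)]
        assert abs(peak_t - data.truth.laa_peak_outflow_time) <= 0.05

    def test_bad_plane_rejected(self, coarse_phantom):
        from cardioflow.mesh_core import OrificePlane
        data = coarse_phantom
        seq = make_sequence(data.source, data.labels, lambda t: 0.0)
        motion = fit_motion_splines(seq)
        plane = OrificePlane((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))
        with pytest.raises(ValueError, match="separate"):
            laa_flow_curve(motion, data.source, data.labels, plane)


def gaussian_mv_curve(dt=0.005, T=1.0):
    t = np.arange(0, T + dt / 2, dt)
    raw = (400.0 * np.exp(-0.5 * ((t - 0.5) / 0.03) ** 2)
           + 200.0 * np.exp(-0.5 * ((t - 0.8) / 0.03) ** 2)
           - 350.0 * np.exp(-0.5 * ((t - 0.2) / 0.05) ** 2))
    return FlowCurve(times=t, flow=np.maximum(raw, 0.0), raw_dvdt=raw)


class TestFlowMetrics:
    def test_constructed_gaussians(self):
        mv = gaussian_mv_curve()
        m = flow_metrics(mv)
        assert m.e_peak == pytest.approx(400.0, rel=0.01)
        assert m.a_peak == pytest.approx(200.0, rel=0.01)
        assert m.e_time == pytest.approx(0.5, abs=0.01)
        assert m.a_time == pytest.approx(0.8, abs=0.01)
        assert m.peak_time_span == pytest.approx(0.3, abs=0.01)
        assert m.ef_af_ratio == pytest.approx(2.0, rel=0.02)

    def test_constant_area_factor_one(self):
        mv = gaussian_mv_curve()
        m = flow_metrics(mv, areas=np.full(20, 123.0))
        assert m.laa_area_factor == pytest.approx(1.0)

    def test_single_peak_not_separable(self):
        dt = 0.005
        t = np.arange(0, 1.0 + dt / 2, dt)
        raw = (400.0 * np.exp(-0.5 * ((t - 0.5) / 0.05) ** 2)
               - 350.0 * np.exp(-0.5 * ((t - 0.1) / 0.04) ** 2))
        mv = FlowCurve(times=t, flow=np.maximum(raw, 0.0), raw_dvdt=raw)
        with pytest.raises(ValueError, match="E/A not separable"):
            flow_metrics(mv)

    @pytest.mark.parametrize("shift", [0.15, 0.5, 0.85])
    def test_time_origin_shift_invariance(self, shift):
        mv = gaussian_mv_curve()
        base = flow_metrics(mv)
        n = len(mv.times) - 1
        k = int(round(shift / 0.005))
        raw = np.roll(mv.raw_dvdt[:n], k)
        raw = np.concatenate([raw, raw[:1]])
        rolled = FlowCurve(times=mv.times, flow=np.maximum(raw, 0.0),
                           raw_dvdt=raw)
        m = flow_metrics(rolled)
        assert m.e_peak == pytest.approx(base.e_peak, rel=0.01)
        assert m.a_peak == pytest.approx(base.a_peak, rel=0.01)
        assert m.peak_time_span == pytest.approx(base.peak_time_span, abs=0.01)
        assert m.stroke_volume == pytest.approx(base.stroke_volume, rel=0.02)
        assert m.e_time == pytest.approx((base.e_time + shift) % 1.0, abs=0.011)

    def test_grid_refinement_stability(self):
        coarse = flow_metrics(gaussian_mv_curve(dt=0.005))
        fine = flow_metrics(gaussian_mv_curve(dt=0.0025))
        assert fine.e_peak == pytest.approx(coarse.e_peak, rel=0.02)
        assert fine.a_peak == pytest.approx(coarse.a_peak, rel=0.02)

    def test_phantom_stroke_volume(self, phantom_seq):
        data, seq = phantom_seq
        motion = fit_motion_splines(seq)
        lv = volume_curve(motion, seq.mesh, seq.labels, Region.LV, dt=0.005)
        mv = mitral_flow_curve(lv)
        m = flow_metrics(mv)
        assert m.stroke_volume == pytest.approx(70.0, rel=0.05)
        # conservation: integral over diastole vs volume-curve extremes
        assert m.stroke_volume == pytest.approx(
            lv.volumes.max() - lv.volumes.min(), rel=0.01)
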