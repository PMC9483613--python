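import warnings

import numpy as np
import pytest

import spiralmap as sm
from spiralmap.errors import DegenerateSignalError, NoSignalError
from spiralmap.synth import FrameStack

UM_PER_CM = 1.0e4


def uniform_stack(template=None, frame_rate=1000.0, shape=(20, 20),
                  onset_ms=30.0, duration_ms=400.0):
    """Every pixel plays the same template simultaneously."""
    if template is None:
        template = sm.APTemplate.from_apds(180.0, 240.0)
    t_ms = np.arange(0.0, duration_ms, 1000.0 / frame_rate)
    trace = 100.0 + 5.0 * template.normalized(t_ms - onset_ms)
    data = np.tile(trace[:, None, None], (1, *shape)).astype(np.float32)
    return FrameStack(data, frame_rate=frame_rate, pixel_size=100.0)


class TestSlicePreprocess:
    def test_constant_stack_normalizes_to_zero(self):
        stack = FrameStack(np.full((50, 8, 8), 3.0, np.float32), 1000.0, 100.0)
        with pytest.warns(UserWarning):
            out = sm.slice_preprocess(stack)
        assert np.allclose(out.intensities, 0.0, atol=1e-6)

    def test_linear_drift_removed(self):
        t = np.arange(200, dtype=np.float32)
        data = np.tile((50.0 + 0.1 * t)[:, None, None], (1, 10, 10))
        stack = FrameStack(data, 1000.0, 100.0)
        out = sm.slice_preprocess(stack)
        assert np.abs(out.intensities).max() < 0.02

    def test_activation_order_preserved(self):
        stack = sm.simulate_slice_stack(cv_long=40.0, cv_trans=40.0,
                                        mode="planar", direction_deg=0.0,
                                        shape=(30, 30), source="corner")
        act = sm.activation_map(sm.slice_preprocess(stack))
        row = act.activation_ms[15, 4:-4]
        assert np.all(np.diff(row) > 0)


class TestActivationMap:
    def test_planar_gradient_inverts_to_speed(self):
        v = 45.0
        stack = sm.simulate_slice_stack(cv_long=v, cv_trans=v, mode="planar",
                                        direction_deg=0.0, shape=(40, 40))
        act = sm.activation_map(sm.slice_preprocess(stack))
        t = act.activation_ms
        # global plane fit over the interior
        inner = t[5:-5, 5:-5]
        cols = np.arange(inner.shape[1]) * act.spacing_um / UM_PER_CM
        g = np.polyfit(cols, inner.mean(axis=0) / 1000.0, 1)[0]
        assert 1.0 / g == pytest.approx(v, rel=0.02)

    def test_simultaneous_activation_constant_map(self):
        act = sm.activation_map(sm.slice_preprocess(uniform_stack()))
        assert np.nanstd(act.activation_ms) < 1.0

    def test_point_source_isochrones_radial(self):
        stack = sm.simulate_slice_stack(cv_long=30.0, cv_trans=30.0,
                                        shape=(41, 41))
        act = sm.activation_map(sm.slice_preprocess(stack))
        t = act.activation_ms
        center = 20
        ray = t[center, center + 2 :]
        assert np.all(np.diff(ray[:-3]) > 0)


class TestAPD90Map:
    def test_uniform_template_recovered(self):
        # the conditioning chain (zero-phase low-pass + normalization +
        # detrend) carries a few-ms systematic on the slow APD90 tail
        tpl = sm.APTemplate.from_apds(180.0, 240.0)
        out = sm.apd90_map(sm.slice_preprocess(uniform_stack(tpl)))
        assert np.nanmedian(out) == pytest.approx(tpl.apd90, abs=4.0)
        assert np.nanstd(out) < 1.0  # spatially uniform input -> uniform map

    def test_below_baseline_artifact_flagged(self):
        stack = uniform_stack()
        data = stack.intensities.copy()
        # motion artifact: a deep dip below diastolic baseline at one site
        data[330:360, 4, 4] = 90.0
        pre = sm.slice_preprocess(
            FrameStack(data, stack.frame_rate, stack.pixel_size),
            spatial_window=1,  # keep the artifact from being diluted
        )
        out = sm.apd90_map(pre)
        assert np.isnan(out[4, 4])
        assert np.isfinite(out[10, 10])

    def test_noise_only_site_invalid(self):
        stack = uniform_stack()
        data = stack.intensities.copy()
        rng = np.random.default_rng(0)
        data[:, 2, 2] = 100.0 + 0.05 * rng.standard_normal(data.shape[0])
        pre = sm.slice_preprocess(
            FrameStack(data, stack.frame_rate, stack.pixel_size),
            spatial_window=1,
        )
        out = sm.apd90_map(pre, min_amplitude=0.5)
        assert np.isnan(out[2, 2])

    def test_all_silent_rejected(self):
        stack = FrameStack(
            np.random.default_rng(0)
            .normal(100.0, 0.01, (100, 6, 6))
            .astype(np.float32),
            1000.0,
            100.0,
        )
        with pytest.raises(DegenerateSignalError):
            sm.apd90_map(stack, min_amplitude=0.5)


class TestDirectionalCV:
    def test_isotropic_planar_long_equals_trans(self):
        v = 35.0
        stack = sm.simulate_slice_stack(cv_long=v, cv_trans=v, mode="planar",
                                        direction_deg=20.0, shape=(40, 40))
        L, T, ang = sm.directional_cv(
            sm.activation_map(sm.slice_preprocess(stack))
        )
        assert L == pytest.approx(v, rel=0.03)
        assert T == pytest.approx(v, rel=0.03)

    def test_two_to_one_anisotropy(self):
        stack = sm.simulate_slice_stack(cv_long=40.0, cv_trans=20.0,
                                        shape=(80, 80))
        L, T, ang = sm.directional_cv(
            sm.activation_map(sm.slice_preprocess(stack))
        )
        assert L / T == pytest.approx(2.0, rel=0.1)
        assert L >= T

    def test_slice_scale_speeds_recovered(self):
        """Longitudinal/transverse speeds at human-slice scale (51 and 28
        cm/s) are each recovered within 5%."""
        stack = sm.simulate_slice_stack(cv_long=51.0, cv_trans=28.0,
                                        shape=(80, 80))
        L, T, _ = sm.directional_cv(
            sm.activation_map(sm.slice_preprocess(stack))
        )
        assert L == pytest.approx(51.0, rel=0.05)
        assert T == pytest.approx(28.0, rel=0.05)

    def test_invariant_to_constant_time_offset(self):
        stack = sm.simulate_slice_stack(cv_long=40.0, cv_trans=20.0,
                                        shape=(40, 40))
        act = sm.activation_map(sm.slice_preprocess(stack))
        L1, T1, _ = sm.directional_cv(act)
        shifted = sm.ActivationMap(act.activation_ms + 123.0, act.spacing_um)
        L2, T2, _ = sm.directional_cv(shifted)
        assert L2 == pytest.approx(L1, rel=1e-9)
        assert T2 == pytest.approx(T1, rel=1e-9)


class TestMEACV:
    def test_radial_wave_recovery(self):
        rec = sm.simulate_mea(cv_true=8.8, mode="radial", noise_sd=0.0)
        act = sm.mea_activation_map(rec)
        assert sm.mea_mean_cv(act) == pytest.approx(8.8, abs=0.2)

    def test_diagonal_distance_geometry(self):
        # hand-built corner wave: t = r / v  ->  all three vectors give v
        v = 10.0
        pitch = 450.0
        jj, ii = np.meshgrid(np.arange(8), np.arange(8))
        r_cm = np.hypot(ii, jj) * pitch / UM_PER_CM
        act = sm.ActivationMap(r_cm / v * 1000.0, pitch)
        assert sm.mea_mean_cv(act) == pytest.approx(v, rel=1e-9)
        # the diagonal leg really spans sqrt(2) x 7 x pitch
        assert r_cm[7, 7] == pytest.approx(np.sqrt(2) * 7 * pitch / UM_PER_CM)

    def test_instantaneous_activation_rejected(self):
        act = sm.ActivationMap(np.zeros((8, 8)), 450.0)
        with pytest.raises(DegenerateSignalError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sm.mea_mean_cv(act)

    def test_missing_vector_dropped_with_warning(self):
        v = 10.0
        pitch = 450.0
        jj, ii = np.meshgrid(np.arange(8), np.arange(8))
        t = np.hypot(ii, jj) * pitch / UM_PER_CM / v * 1000.0
        t[7, 0] = np.nan  # vertical endpoint missing
        with pytest.warns(UserWarning):
            cv = sm.mea_mean_cv(sm.ActivationMap(t, pitch))
        assert cv == pytest.approx(v, rel=1e-9)
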