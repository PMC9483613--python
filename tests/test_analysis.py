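import numpy as np
import pytest

import spiralmap as sm
from spiralmap.analysis import PathProfile, SpiralEndpoints
from spiralmap.errors import (
    DegenerateSignalError,
    InvalidParameterError,
    NoSignalError,
    PairingError,
)
from spiralmap.synth import FrameStack

UM_PER_CM = 1.0e4


def _profile(matrix, frame_rate=30.0, arc_step=0.001, stage="raw"):
    n = matrix.shape[0]
    return PathProfile(
        matrix=matrix,
        arcs=np.arange(n) * arc_step,
        arc_step=arc_step,
        frame_rate=frame_rate,
        stage=stage,
    )


class TestExtractProfile:
    def test_uniform_image_gives_constant_profile(self, small_design):
        shape = sm.fit_image_shape(small_design, 10.0)
        stack = FrameStack(np.full((3, *shape), 7.0, np.float32), 30.0, 10.0)
        prof = sm.extract_path_profile(stack, small_design)
        assert np.allclose(prof.matrix, 7.0)

    def test_extraction_width_irrelevant_on_noiseless_data(self, small_design):
        # at 10 um/px the 10-pixel cross-section stays within the 200 um line,
        # where the kinematic signal is constant across the width
        cfg = sm.SimulationConfig(
            cv_true=5.0, apd80_true=120.0, pacing_cycle_length=400.0,
            n_frames=30, pixel_size=10.0, noise_sd=0.0, bleach_rate=0.0, seed=0,
        )
        movie = sm.simulate_spiral_recording(small_design, cfg)
        p1 = sm.extract_path_profile(movie, small_design, extraction_width=1)
        p10 = sm.extract_path_profile(movie, small_design, extraction_width=10)
        assert np.max(np.abs(p1.matrix - p10.matrix) / p1.matrix) < 1e-3

    def test_band_moves_at_cv(self, noiseless_recording, design):
        """The supra-threshold band advances by cv * dt per frame."""
        config, movie = noiseless_recording
        prof = sm.extract_path_profile(movie, design)
        fronts = []
        for f in (6, 7):
            s = prof.matrix[:, f]
            base = np.median(s)
            thr = base + 0.5 * (s.max() - base)
            fronts.append(prof.arcs[np.nonzero(s >= thr)[0][-1]])
        step = fronts[1] - fronts[0]
        expected = config.cv_true / config.frame_rate
        assert step == pytest.approx(expected, abs=3 * prof.arc_step)


class TestFilterNormalize:
    def test_constant_in_time_profile_goes_to_zero(self):
        rng = np.random.default_rng(0)
        pattern = 100.0 + 10.0 * rng.random(500)
        mat = np.tile(pattern[:, None], (1, 40))
        out = sm.filter_and_normalize(_profile(mat))
        assert np.allclose(out.matrix, 0.0, atol=1e-9)
        assert out.stage == "normalized"

    def test_high_spatial_frequency_attenuated(self):
        """Components well above the 0.005 cutoff drop by > 20 dB."""
        from spiralmap.analysis import butter, filtfilt

        n = 4000
        x = np.sin(2 * np.pi * 0.05 * np.arange(n))  # 0.1 x Nyquist
        b, a = butter(3, 0.005)
        y = filtfilt(b, a, x)
        mid = slice(n // 4, 3 * n // 4)
        assert np.abs(y[mid]).max() < np.abs(x[mid]).max() * 0.1

    def test_zero_phase_preserves_wavefront_position(
        self, noiseless_recording, design
    ):
        """Forward-backward filtering is zero-phase: the 50% wavefront edge
        must not move (a causal filter would drag it backwards)."""
        config, movie = noiseless_recording
        prof = sm.extract_path_profile(movie, design)
        norm = sm.filter_and_normalize(prof)
        f = 8

        def front(matrix, arcs):
            s = matrix[:, f]
            base = np.median(s)
            thr = base + 0.5 * (s.max() - base)
            return arcs[np.nonzero(s >= thr)[0][-1]]

        raw_front = front(prof.matrix, prof.arcs)
        filt_front = front(norm.matrix, norm.arcs)
        assert abs(filt_front - raw_front) < 0.05  # cm

    def test_degenerate_zero_mean_rejected(self):
        mat = np.zeros((100, 10))
        with pytest.raises(DegenerateSignalError):
            sm.filter_and_normalize(_profile(mat))


class TestMeasureWavelength:
    def test_noiseless_wavelength_matches_kinematics(
        self, noiseless_recording, design
    ):
        config, movie = noiseless_recording
        norm = sm.filter_and_normalize(sm.extract_path_profile(movie, design))
        res = sm.measure_wavelength(norm)
        wl_true = config.cv_true * config.apd80_true / 1000.0
        quantum = config.cv_true / config.frame_rate
        assert res.wl_measured == pytest.approx(wl_true, abs=quantum)
        assert res.n_waves_averaged >= 10

    def test_wave_longer_than_path_not_measurable(self, design):
        # 41 cm/s x 180.7 ms = 7.4 cm > 5.5 cm path
        cfg = sm.SimulationConfig(cv_true=41.0, apd80_true=180.7, seed=2)
        movie = sm.simulate_spiral_recording(design, cfg)
        norm = sm.filter_and_normalize(sm.extract_path_profile(movie, design))
        res = sm.measure_wavelength(norm)
        assert res.wl_measured is None
        assert res.reason is not None

    def test_all_zero_profile_has_no_waves(self):
        res = sm.measure_wavelength(
            _profile(np.zeros((200, 20)), stage="normalized")
        )
        assert res.wl_measured is None
        assert res.measurements == []

    def test_requires_normalized_profile(self):
        with pytest.raises(InvalidParameterError):
            sm.measure_wavelength(_profile(np.ones((10, 5))))

    def test_invariant_to_scaling_and_bleach(self, default_noise_recording, design):
        config, movie = default_noise_recording
        norm = sm.filter_and_normalize(sm.extract_path_profile(movie, design))
        wl0 = sm.measure_wavelength(norm).wl_measured

        scaled = FrameStack(movie.intensities * 4.0, movie.frame_rate,
                            movie.pixel_size)
        norm_s = sm.filter_and_normalize(sm.extract_path_profile(scaled, design))
        assert sm.measure_wavelength(norm_s).wl_measured == pytest.approx(
            wl0, rel=1e-6
        )

        bleach_cfg = sm.SimulationConfig(
            cv_true=config.cv_true, apd80_true=config.apd80_true,
            bleach_rate=0.02, seed=config.seed,
        )
        movie_b = sm.simulate_spiral_recording(design, bleach_cfg)
        norm_b = sm.filter_and_normalize(sm.extract_path_profile(movie_b, design))
        assert sm.measure_wavelength(norm_b).wl_measured == pytest.approx(
            wl0, rel=0.03
        )


class TestLinescanAPD80:
    def test_scale_invariance(self, design):
        cfg = sm.SimulationConfig(cv_true=20.0, apd80_true=200.0, seed=9)
        rec = sm.simulate_linescan(design, cfg)
        a1 = sm.linescan_apd80(rec.trace_a, rec.frame_rate)
        a2 = sm.linescan_apd80(rec.trace_a * 10.0, rec.frame_rate)
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_flat_trace_raises_no_signal(self):
        with pytest.raises(NoSignalError):
            sm.linescan_apd80(np.full(600, 1000.0), 150.0)

    @pytest.mark.parametrize("apd_true", [160.0, 180.7, 188.9, 220.0])
    def test_estimator_covers_physiological_range(self, design, apd_true):
        cfg = sm.SimulationConfig(cv_true=20.0, apd80_true=apd_true, seed=4)
        rec = sm.simulate_linescan(design, cfg)
        apd = sm.linescan_apd80(rec.trace_a, rec.frame_rate)
        assert apd == pytest.approx(apd_true, abs=1000.0 / rec.frame_rate)


class TestTravelTime:
    def test_kinematic_recovery(self, design):
        cfg = sm.SimulationConfig(cv_true=30.0, apd80_true=180.0, seed=6)
        rec = sm.simulate_linescan(design, cfg, region_a=(0.3, 0.7),
                                   region_b=(4.75, 5.25))
        tt = sm.travel_time_and_cv(rec.trace_a, rec.trace_b, rec.frame_rate,
                                   rec.separation_cm)
        assert tt.travel_time_ms == pytest.approx(150.0, abs=7.0)
        assert tt.cv == pytest.approx(30.0, abs=2.0)

    def test_identical_traces_rejected(self, design):
        cfg = sm.SimulationConfig(seed=1)
        rec = sm.simulate_linescan(design, cfg)
        with pytest.raises(DegenerateSignalError):
            sm.travel_time_and_cv(rec.trace_a, rec.trace_a, rec.frame_rate, 4.5)

    def test_cv_proportional_to_separation(self, design):
        cfg = sm.SimulationConfig(cv_true=25.0, apd80_true=170.0, seed=8)
        rec = sm.simulate_linescan(design, cfg)
        t1 = sm.travel_time_and_cv(rec.trace_a, rec.trace_b, rec.frame_rate, 4.5)
        t2 = sm.travel_time_and_cv(rec.trace_a, rec.trace_b, rec.frame_rate, 2.25)
        assert t2.cv == pytest.approx(t1.cv / 2.0, rel=1e-9)

    def test_break_upstream_of_terminal_is_detected(self, design):
        """A conduction block before the terminal region must surface as a
        no-signal error, never a silently interpolated CV."""
        cfg = sm.SimulationConfig(cv_true=20.0, apd80_true=160.0, seed=3,
                                  defects=(("break", 3.0),))
        rec = sm.simulate_linescan(design, cfg)
        with pytest.raises(NoSignalError):
            sm.travel_time_and_cv(rec.trace_a, rec.trace_b, rec.frame_rate,
                                  rec.separation_cm)


class TestWavelengthCalculated:
    def test_worked_examples(self):
        assert sm.wavelength_calculated(8.0, 300.0) == pytest.approx(2.4)
        assert sm.wavelength_calculated(54.0, 224.0) == pytest.approx(12.1,
                                                                      abs=0.05)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidParameterError):
            sm.wavelength_calculated(10.0, 0.0)
        with pytest.raises(InvalidParameterError):
            sm.wavelength_calculated(-1.0, 100.0)


class TestWLValidation:
    @staticmethod
    def _record(cv, apd, wl_meas):
        return SpiralEndpoints(cv=cv, apd80=apd,
                               wl_calculated=cv * apd / 1000.0,
                               wl_measured=wl_meas)

    def test_identity_line(self):
        recs = [self._record(cv, 180.0, cv * 0.18) for cv in (10, 15, 20, 25)]
        slope, intercept, r = sm.wl_validation(recs)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_too_few_records_rejected(self):
        recs = [self._record(10, 180, 1.8), self._record(20, 180, 3.6)]
        with pytest.raises(InvalidParameterError):
            sm.wl_validation(recs)

    def test_degenerate_identical_calculated(self):
        recs = [self._record(10, 180, 1.8 + 0.01 * k) for k in range(4)]
        with pytest.raises(DegenerateSignalError):
            sm.wl_validation(recs)
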