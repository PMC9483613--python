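"""Spiral-recording analysis chain.

Mirrors the processing applied to voltage-dye movies of the 1D spiral
device: extract the fluorescence profile along the cell path (10-pixel-wide
cross-section), low-pass filter each frame spatially with a zero-phase
Butterworth filter, normalize each arc position by its temporal mean,
subtract the baseline and rescale ("amplify"), then measure the spatial
extent of each complete conduction wave.  The wave edge is taken where the
signal has repolarized 80% (level = 20% of the frame's maximal wave
amplitude), the same 80%-repolarization convention as APD80, so the
measured wavelength is directly comparable to the calculated one,
WL = CV x APD80.

Conduction velocity and APD80 come from the faster line-scan traces: APD80
at 80% of maximal amplitude with sub-sample interpolation, and travel time
as the difference between AP peak times in the two scanned regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, median_filter
from scipy.signal import butter, filtfilt, find_peaks
from scipy.stats import linregress

from .errors import (
    DegenerateSignalError,
    GeometryError,
    InvalidParameterError,
    NoSignalError,
    PairingError,
)
from .geometry import SpiralDesign, arc_to_pixel
from .synth import FrameStack, LineScanRecording

UM_PER_CM = 1.0e4


@dataclass
class PathProfile:
    """Arc-position x frame intensity matrix along the spiral path."""

    matrix: np.ndarray               # (n_arc, n_frames)
    arcs: np.ndarray                 # (n_arc,), cm
    arc_step: float                  # cm
    frame_rate: float                # Hz
    extraction_width: int = 10
    stage: str = "raw"               # "raw" -> "normalized"

    @property
    def total_length(self) -> float:
        return float(self.arcs[-1])

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[1]


@dataclass
class WaveMeasurement:
    """One per-frame wavelength measurement."""

    frame_index: int
    extent_cm: float
    front_cm: float
    tail_cm: float
    complete: bool


@dataclass
class WavelengthResult:
    measurements: list[WaveMeasurement]
    wl_measured: float | None
    n_waves_averaged: int
    reason: str | None = None


@dataclass
class SpiralEndpoints:
    """Endpoints of one spiral preparation."""

    cv: float                        # cm/s
    apd80: float                     # ms
    wl_calculated: float             # cm
    wl_measured: float | None = None
    n_waves_averaged: int = 0


@dataclass
class TravelTimeResult:
    travel_time_ms: float
    cv: float
    n_beats: int
    reversed_direction: bool = False


# ---------------------------------------------------------------------------
# profile extraction and conditioning
# ---------------------------------------------------------------------------

def extract_path_profile(
    frames: FrameStack,
    design: SpiralDesign,
    arc_step_cm: float = 0.001,
    extraction_width: int = 10,
) -> PathProfile:
    """Mean intensity over a ``extraction_width``-pixel-wide cross-section
    normal to the centerline, at every arc position, for every frame."""
    L = design.total_length
    arcs = np.arange(0.0, L + arc_step_cm / 2, arc_step_cm)
    arcs[-1] = min(arcs[-1], L)
    shape = frames.image_shape
    px = frames.pixel_size

    rc = arc_to_pixel(design, arcs, px, shape)          # (n_arc, 2)
    tang = design.tangent_at_arc(arcs)                  # (n_arc, 2), xy
    # unit normal to the tangent in xy is (-ty, tx); in raster coordinates a
    # +x step is +col and a +y step is -row
    normal_row = -tang[:, 0]
    normal_col = -tang[:, 1]
    offsets = (np.arange(extraction_width) - (extraction_width - 1) / 2.0)
    rows = rc[:, 0][:, None] + normal_row[:, None] * offsets[None, :]
    cols = rc[:, 1][:, None] + normal_col[:, None] * offsets[None, :]
    if (
        rows.min() < -1 or cols.min() < -1
        or rows.max() > shape[0] or cols.max() > shape[1]
    ):
        raise GeometryError("extraction cross-sections fall outside the image")
    coords = np.stack([rows.ravel(), cols.ravel()])

    out = np.empty((arcs.size, frames.n_frames), dtype=np.float64)
    for f in range(frames.n_frames):
        vals = map_coordinates(
            frames.intensities[f], coords, order=1, mode="nearest"
        )
        out[:, f] = vals.reshape(arcs.size, extraction_width).mean(axis=1)
    return PathProfile(
        matrix=out,
        arcs=arcs,
        arc_step=arc_step_cm,
        frame_rate=frames.frame_rate,
        extraction_width=extraction_width,
        stage="raw",
    )


def _diastolic_baseline(
    scaled: np.ndarray, keep: float | None = None, n_iter: int = 2
) -> np.ndarray:
    """Per-row first-order (linear-in-time) diastolic baseline.

    Fits a line over time for every row (arc position / pixel / trace),
    then refits using only the lowest-residual samples so the AP waveform
    does not bias the photobleaching estimate.  The kept fraction defaults
    to an adaptive estimate: samples more than 30% of the residual span
    above the row minimum are counted as "elevated" (depolarized) and
    excluded, clipped to keep 15-50% of samples.
    """
    n_rows, n = scaled.shape
    t = np.arange(n, dtype=float)
    A = np.column_stack([np.ones(n), t])
    coef, *_ = np.linalg.lstsq(A, scaled.T, rcond=None)   # (2, n_rows)
    fit = (A @ coef).T

    for _ in range(n_iter):
        resid = scaled - fit
        if keep is not None:
            keep_row = np.full(n_rows, keep)
        else:
            lo = resid.min(axis=1, keepdims=True)
            span = resid.max(axis=1, keepdims=True) - lo
            span = np.where(span <= 0, 1.0, span)
            elevated = (resid > lo + 0.3 * span).mean(axis=1)
            keep_row = np.clip(0.75 * (1.0 - elevated), 0.15, 0.5)
        order = np.sort(resid, axis=1)
        idx = np.clip((keep_row * (n - 1)).astype(int), 1, n - 1)
        thr = order[np.arange(n_rows), idx]
        w = (resid <= thr[:, None]).astype(float)
        s0 = w.sum(axis=1)
        s1 = (w * t).sum(axis=1)
        s2 = (w * t**2).sum(axis=1)
        sy = (w * scaled).sum(axis=1)
        sty = (w * t * scaled).sum(axis=1)
        det = s0 * s2 - s1**2
        det = np.where(det == 0, 1.0, det)
        a0 = (s2 * sy - s1 * sty) / det
        a1 = (s0 * sty - s1 * sy) / det
        fit = a0[:, None] + a1[:, None] * t[None, :]
    return fit


def filter_and_normalize(
    profile: PathProfile, cutoff: float = 0.005, order: int = 3
) -> PathProfile:
    """Spatial zero-phase Butterworth low-pass per frame, temporal-mean
    scaling per arc position, first-order drift removal, baseline
    subtraction, unit-max rescale.

    ``cutoff`` is the normalized corner frequency (fraction of the spatial
    Nyquist along the arc axis).  Scaling divides each (arc, frame) value by
    that arc position's mean over all frames, cancelling the static
    illumination/dye pattern; the residual first-order photobleaching trend
    is then divided out per arc position (fitted on diastolic frames only),
    so the no-signal condition sits at exactly zero before amplification.
    """
    if profile.n_frames < 2:
        raise InvalidParameterError("need at least 2 frames")
    b, a = butter(order, cutoff)
    filt = filtfilt(b, a, profile.matrix, axis=0)
    tmean = filt.mean(axis=1)
    if np.any(tmean <= 0):
        raise DegenerateSignalError("non-positive temporal mean on the path")
    scaled = filt / tmean[:, None]
    baseline = _diastolic_baseline(scaled)
    baseline = np.where(baseline <= 1e-12, 1.0, baseline)
    resid = scaled / baseline - 1.0
    peak = resid.max()
    # amplify to unit maximum; a peak at numerical-noise level means there is
    # no wave to amplify (e.g. constant-in-time input) and is left as is
    if peak > 1e-8:
        resid = resid / peak
    return PathProfile(
        matrix=resid,
        arcs=profile.arcs,
        arc_step=profile.arc_step,
        frame_rate=profile.frame_rate,
        extraction_width=profile.extraction_width,
        stage="normalized",
    )


# ---------------------------------------------------------------------------
# wavelength measurement
# ---------------------------------------------------------------------------

def _widest_run(above: np.ndarray) -> tuple[int, int] | None:
    """(start, stop) indices of the widest True run; ties -> the wider/first."""
    if not above.any():
        return None
    padded = np.concatenate([[False], above, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    stops = np.nonzero(d == -1)[0]
    widths = stops - starts
    k = int(np.argmax(widths))
    return int(starts[k]), int(stops[k])


def measure_wavelength(
    profile: PathProfile,
    repol_fraction: float = 0.8,
    min_waves: int = 10,
    min_frame_amplitude: float = 0.5,
) -> WavelengthResult:
    """Per-frame wave extent at 80% repolarization of the frame's maximal
    wave amplitude, averaged over complete waves.

    A wave is the widest contiguous arc interval where the normalized signal
    stays above (1 - repol_fraction) x the frame's maximum, with sub-sample
    edges by linear interpolation.  Only ``complete`` waves - both edges at
    least one arc step inside (0, L) - contribute; the mean requires at
    least ``min_waves`` qualifying measurements, otherwise the measured
    wavelength is reported absent with a reason.  Frames whose maximum falls
    below ``min_frame_amplitude`` x the global maximum carry no
    fully-depolarized wave and are skipped.
    """
    if profile.stage != "normalized":
        raise InvalidParameterError("profile must be filtered and normalized first")
    mat = profile.matrix
    arcs = profile.arcs
    L = profile.total_length
    global_max = mat.max()
    measurements: list[WaveMeasurement] = []
    if global_max <= 0:
        return WavelengthResult([], None, 0, reason="no waves detected")

    for f in range(profile.n_frames):
        s = mat[:, f]
        m = s.max()
        if m < min_frame_amplitude * global_max:
            continue
        thr = (1.0 - repol_fraction) * m
        run = _widest_run(s >= thr)
        if run is None:
            continue
        i0, i1 = run  # s[i0:i1] >= thr
        # sub-sample edges
        if i0 == 0:
            tail = arcs[0]
        else:
            frac = (thr - s[i0 - 1]) / (s[i0] - s[i0 - 1])
            tail = arcs[i0 - 1] + frac * (arcs[i0] - arcs[i0 - 1])
        if i1 >= arcs.size:
            front = arcs[-1]
        else:
            frac = (s[i1 - 1] - thr) / (s[i1 - 1] - s[i1])
            front = arcs[i1 - 1] + frac * (arcs[i1] - arcs[i1 - 1])
        complete = (
            tail >= profile.arc_step
            and front <= L - profile.arc_step
            and i0 > 0
            and i1 < arcs.size
        )
        measurements.append(
            WaveMeasurement(
                frame_index=f,
                extent_cm=float(front - tail),
                front_cm=float(front),
                tail_cm=float(tail),
                complete=bool(complete),
            )
        )

    complete_ext = [m.extent_cm for m in measurements if m.complete]
    if len(complete_ext) >= min_waves:
        return WavelengthResult(
            measurements,
            float(np.mean(complete_ext)),
            len(complete_ext),
        )
    reason = (
        "no waves detected"
        if not measurements
        else f"only {len(complete_ext)} complete waves (< {min_waves}); "
        "wavelength likely exceeds the path length"
    )
    return WavelengthResult(measurements, None, len(complete_ext), reason=reason)


# ---------------------------------------------------------------------------
# line-scan measurements
# ---------------------------------------------------------------------------

def default_smoother(trace: np.ndarray, frame_rate: float) -> np.ndarray:
    """Moving median (5 samples) + zero-phase low-pass at 40 Hz.

    Stands in for the (unspecified) smoothing of the original line-scan
    pipeline; pluggable via the ``smoother`` argument of the measurement
    functions.
    """
    out = median_filter(trace, size=5, mode="nearest")
    wn = min(40.0 / (frame_rate / 2.0), 0.9)
    b, a = butter(3, wn)
    return filtfilt(b, a, out)


def _noise_floor(trace: np.ndarray, smoothed: np.ndarray) -> float:
    resid = trace - smoothed
    return float(1.4826 * np.median(np.abs(resid - np.median(resid))))


def _ap_amplitude(smoothed: np.ndarray) -> float:
    """Drift-insensitive robust amplitude (5-95 percentile span of the
    detrended trace; extrema would make pure noise look like signal)."""
    n = smoothed.size
    t = np.arange(n, dtype=float)
    slope, intercept = np.polyfit(t, smoothed, 1)
    detr = smoothed - (intercept + slope * t)
    return float(np.percentile(detr, 95) - np.percentile(detr, 5))


def _detect_peaks(smoothed: np.ndarray, frame_rate: float) -> np.ndarray:
    amp = _ap_amplitude(smoothed)
    if amp <= 0:
        return np.array([], dtype=int)
    peaks, _ = find_peaks(
        smoothed,
        prominence=0.5 * amp,
        distance=max(int(0.2 * frame_rate), 1),
    )
    return peaks


def _refined_peak_time(smoothed: np.ndarray, p: int, frame_rate: float) -> float:
    """Parabolic sub-sample refinement of a peak location, in seconds."""
    if 0 < p < smoothed.size - 1:
        y0, y1, y2 = smoothed[p - 1], smoothed[p], smoothed[p + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return (p + delta) / frame_rate


def linescan_apd80(
    trace: np.ndarray,
    frame_rate: float,
    repol_fraction: float = 0.8,
    smoother=default_smoother,
) -> float:
    """Mean APD80 (ms) over the APs in a line-scan fluorescence trace.

    Per AP: amplitude = peak - preceding diastolic baseline; APD80 is the
    time between the upstroke and repolarization crossings of baseline +
    20% of amplitude, sub-sample interpolated.  Raises NoSignalError when
    the amplitude does not exceed 3x the noise floor.
    """
    trace = np.asarray(trace, dtype=float)
    s = smoother(trace, frame_rate) if smoother is not None else trace
    noise = _noise_floor(trace, s)
    amp = _ap_amplitude(s)
    if not amp > 3.0 * noise or amp <= 0:
        raise NoSignalError("no detectable action potential")
    # remove first-order photobleaching drift, fitted on diastolic samples,
    # so the repolarization level is referenced to a flat baseline
    s = s - _diastolic_baseline(s[None, :])[0]
    peaks = _detect_peaks(s, frame_rate)
    if peaks.size == 0:
        raise NoSignalError("no detectable action potential")

    dt_ms = 1000.0 / frame_rate
    apds = []
    prev = 0
    for p in peaks:
        if p <= prev:
            continue
        # low percentile of the preceding inter-peak segment: lands on the
        # diastolic plateau even when the repolarization tail of the
        # previous AP occupies most of the cycle, and is robust to the
        # small zero-phase-filter undershoot flanking the AP
        base = float(np.percentile(s[prev:p], 10))
        amp_i = s[p] - base
        if amp_i <= 0:
            prev = p
            continue
        level = base + (1.0 - repol_fraction) * amp_i
        # upstroke crossing: last sample below level before the peak
        below = np.nonzero(s[prev:p] < level)[0]
        if below.size == 0:
            prev = p
            continue
        i = prev + below[-1]
        t_up = i + (level - s[i]) / (s[i + 1] - s[i])
        # repolarization crossing: first sample below level after the peak
        after = np.nonzero(s[p:] < level)[0]
        if after.size == 0:
            prev = p
            continue  # truncated AP
        j = p + after[0]
        t_down = j - 1 + (s[j - 1] - level) / (s[j - 1] - s[j])
        apds.append((t_down - t_up) * dt_ms)
        prev = p
    if not apds:
        raise NoSignalError("no complete action potential in trace")
    return float(np.mean(apds))


def travel_time_and_cv(
    trace_a: np.ndarray,
    trace_b: np.ndarray,
    frame_rate: float,
    arc_separation: float,
    smoother=default_smoother,
) -> TravelTimeResult:
    """Travel time (mean peak-time difference b - a over paired APs, ms) and
    CV = arc separation / travel time (cm/s)."""
    if arc_separation <= 0:
        raise InvalidParameterError("arc_separation must be > 0")
    sa = smoother(np.asarray(trace_a, float), frame_rate) if smoother else trace_a
    sb = smoother(np.asarray(trace_b, float), frame_rate) if smoother else trace_b
    for raw, s in ((trace_a, sa), (trace_b, sb)):
        if not _ap_amplitude(s) > 3.0 * _noise_floor(np.asarray(raw, float), s):
            raise NoSignalError(
                "no detectable action potential in one trace "
                "(conduction block upstream?)"
            )
    pa = _detect_peaks(sa, frame_rate)
    pb = _detect_peaks(sb, frame_rate)
    if pa.size == 0 or pb.size == 0:
        raise NoSignalError("no detectable action potential in one trace")
    ta = np.array([_refined_peak_time(sa, p, frame_rate) for p in pa])
    tb = np.array([_refined_peak_time(sb, p, frame_rate) for p in pb])
    # beat-by-beat pairing in order; every paced beat reaches both regions,
    # so unequal counts mean the traces cannot be paired
    if ta.size != tb.size:
        raise PairingError(
            f"unequal AP counts after pairing ({ta.size} vs {tb.size})"
        )
    pairs = tb - ta
    travel_ms = float(np.mean(pairs)) * 1000.0
    reversed_dir = False
    if travel_ms == 0.0:
        raise DegenerateSignalError("zero travel time; CV undefined")
    if travel_ms < 0:
        reversed_dir = True
        travel_ms = abs(travel_ms)
    cv = arc_separation / (travel_ms / 1000.0)
    return TravelTimeResult(
        travel_time_ms=travel_ms,
        cv=cv,
        n_beats=len(pairs),
        reversed_direction=reversed_dir,
    )


def wavelength_calculated(cv: float, duration_ms: float) -> float:
    """Conduction wavelength WL = CV x duration, in cm (duration in ms)."""
    if cv <= 0 or duration_ms <= 0:
        raise InvalidParameterError("cv and duration must be > 0")
    return cv * duration_ms / 1000.0


def wl_validation(records: list[SpiralEndpoints]) -> tuple[float, float, float]:
    """OLS regression (with intercept) of measured on calculated wavelength.

    Returns (slope, intercept, Pearson r) over records that carry a
    measured wavelength; requires at least three such records.
    """
    pts = [
        (r.wl_calculated, r.wl_measured)
        for r in records
        if r.wl_measured is not None
    ]
    if len(pts) < 3:
        raise InvalidParameterError("need >= 3 records with measured wavelength")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.allclose(x, x[0]):
        raise DegenerateSignalError("all calculated wavelengths identical")
    fit = linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

def analyze_spiral_recording(
    frames: FrameStack,
    design: SpiralDesign,
    linescan: LineScanRecording,
    arc_step_cm: float = 0.001,
    extraction_width: int = 10,
    min_waves: int = 10,
) -> SpiralEndpoints:
    """Full chain: profile -> filter/normalize -> measured WL; line scan ->
    APD80 + CV -> calculated WL."""
    profile = extract_path_profile(
        frames, design, arc_step_cm=arc_step_cm, extraction_width=extraction_width
    )
    norm = filter_and_normalize(profile)
    wl = measure_wavelength(norm, min_waves=min_waves)
    apd80 = 0.5 * (
        linescan_apd80(linescan.trace_a, linescan.frame_rate)
        + linescan_apd80(linescan.trace_b, linescan.frame_rate)
    )
    tt = travel_time_and_cv(
        linescan.trace_a,
        linescan.trace_b,
        linescan.frame_rate,
        linescan.separation_cm,
    )
    return SpiralEndpoints(
        cv=tt.cv,
        apd80=apd80,
        wl_calculated=wavelength_calculated(tt.cv, apd80),
        wl_measured=wl.wl_measured,
        n_waves_averaged=wl.n_waves_averaged,
    )
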