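"""2D conduction-map analyses: tissue-slice optical maps and MEA grids.

Slice stacks are conditioned the standard optical-mapping way (temporal
low-pass at 100-150 Hz, 7x7 spatial average, per-pixel 0-1 normalization,
first-order drift removal), activation is timed at 50% of the local AP
upstroke amplitude, and APD90 is mapped at 90% repolarization with the
below-baseline motion-artifact rule.  Longitudinal and transverse CV come
from a plane-fit velocity field: local least-squares planes of activation
time over sliding neighbourhoods give velocity vectors, which are binned by
direction; the maximum and minimum bin-median speeds are the longitudinal
and transverse CV (a standard substitute for dedicated conduction-analysis
tools).

MEA activation is the time of the maximal negative slope of each field
potential, and the array-level CV is the mean of the horizontal, vertical
and diagonal vectors from the stimulation corner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter
from scipy.signal import butter, filtfilt

from .analysis import _diastolic_baseline
from .errors import (
    DegenerateSignalError,
    InvalidParameterError,
    NoSignalError,
)
from .synth import FrameStack, MEARecording

UM_PER_CM = 1.0e4


@dataclass
class ActivationMap:
    """Per-site activation times (ms); NaN where no valid signal."""

    activation_ms: np.ndarray        # (rows, cols)
    spacing_um: float

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.activation_ms)


# ---------------------------------------------------------------------------
# slice-style optical maps
# ---------------------------------------------------------------------------

def slice_preprocess(
    stack: FrameStack,
    cutoff_hz: float = 150.0,
    spatial_window: int = 7,
) -> FrameStack:
    """Temporal low-pass, 7x7 boxcar, per-pixel [0,1] normalization,
    per-pixel linear detrend."""
    if stack.n_frames < 2:
        raise InvalidParameterError("stack must have at least 2 frames")
    data = stack.intensities.astype(np.float64)
    nyq = stack.frame_rate / 2.0
    wn = cutoff_hz / nyq
    if wn >= 1.0:
        warnings.warn(
            f"frame rate {stack.frame_rate} Hz too low for a {cutoff_hz} Hz "
            "low-pass; cutoff clipped",
            stacklevel=2,
        )
        wn = 0.9
    b, a = butter(3, wn)
    data = filtfilt(b, a, data, axis=0)
    data = uniform_filter(data, size=(1, spatial_window, spatial_window))
    lo = data.min(axis=0)
    hi = data.max(axis=0)
    rng = hi - lo
    degenerate = rng <= 0
    if degenerate.any():
        warnings.warn("constant-intensity pixels normalized to 0", stacklevel=2)
    rng = np.where(degenerate, 1.0, rng)
    data = (data - lo) / rng
    # first-order drift removal per pixel, fitted on diastolic frames so the
    # AP hump does not tilt the fit and drag the trace below baseline
    nt = stack.n_frames
    flat = data.reshape(nt, -1).T                     # (npix, t)
    baseline = _diastolic_baseline(flat)
    data = (flat - baseline).T.reshape(data.shape)
    return FrameStack(
        intensities=data.astype(np.float32),
        frame_rate=stack.frame_rate,
        pixel_size=stack.pixel_size,
        design_ref=stack.design_ref,
    )


def _upstroke_time_ms(
    trace: np.ndarray, frame_rate: float, level_fraction: float = 0.5
) -> float:
    """Interpolated first upstroke crossing of the given amplitude fraction."""
    lo, hi = trace.min(), trace.max()
    level = lo + level_fraction * (hi - lo)
    peak = int(np.argmax(trace))
    below = np.nonzero(trace[:peak] < level)[0]
    if below.size == 0:
        return 0.0
    i = below[-1]
    frac = (level - trace[i]) / (trace[i + 1] - trace[i])
    return (i + frac) / frame_rate * 1000.0


def activation_map(
    stack: FrameStack,
    mode: str = "upstroke50",
    min_amplitude: float = 0.3,
) -> ActivationMap:
    """Activation time at 50% of the per-site upstroke amplitude.

    ``min_amplitude`` is the minimum max-min range (in the units of the
    preprocessed stack, nominally [0,1]) for a site to count as carrying an
    AP; weaker sites are marked invalid (NaN).
    """
    if mode != "upstroke50":
        raise InvalidParameterError(f"unknown activation mode {mode!r}")
    data = stack.intensities
    nrows, ncols = stack.image_shape
    out = np.full((nrows, ncols), np.nan)
    amp = data.max(axis=0) - data.min(axis=0)
    for r in range(nrows):
        for c in range(ncols):
            if amp[r, c] < min_amplitude:
                continue
            out[r, c] = _upstroke_time_ms(data[:, r, c], stack.frame_rate, 0.5)
    return ActivationMap(activation_ms=out, spacing_um=stack.pixel_size)


def apd90_map(
    stack: FrameStack,
    repol_fraction: float = 0.9,
    min_amplitude: float = 0.3,
    artifact_fraction: float = 0.1,
) -> np.ndarray:
    """Per-site APD90 (ms); NaN where invalid.

    A site is artifact-flagged (invalid) when its trace dips below the
    diastolic baseline by more than ``artifact_fraction`` of the AP
    amplitude - the below-baseline motion-artifact rule.
    """
    data = stack.intensities
    fr = stack.frame_rate
    nrows, ncols = stack.image_shape
    out = np.full((nrows, ncols), np.nan)
    any_valid = False
    for r in range(nrows):
        for c in range(ncols):
            tr = data[:, r, c].astype(float)
            peak = int(np.argmax(tr))
            pre = tr[:peak]
            if pre.size < 2:
                continue
            # median of the pre-upstroke segment: robust to the small
            # zero-phase filter undershoot that the minimum would pick up
            base = float(np.median(pre))
            amp = tr[peak] - base
            if amp < min_amplitude:
                continue
            if base - tr.min() > artifact_fraction * amp:
                continue  # below-baseline artifact
            level = base + (1.0 - repol_fraction) * amp
            below_up = np.nonzero(pre < level)[0]
            after = np.nonzero(tr[peak:] < level)[0]
            if below_up.size == 0 or after.size == 0:
                continue
            i = below_up[-1]
            t_up = i + (level - tr[i]) / (tr[i + 1] - tr[i])
            j = peak + after[0]
            t_dn = j - 1 + (tr[j - 1] - level) / (tr[j - 1] - tr[j])
            out[r, c] = (t_dn - t_up) / fr * 1000.0
            any_valid = True
    if not any_valid:
        raise DegenerateSignalError("all sites artifactual or silent")
    return out


# ---------------------------------------------------------------------------
# velocity fields
# ---------------------------------------------------------------------------

def directional_cv(
    act: ActivationMap,
    window: int = 7,
    bin_deg: float = 10.0,
    min_vectors_per_bin: int = 3,
    max_speed: float = 500.0,
) -> tuple[float, float, float]:
    """(longitudinal_cv, transverse_cv, principal angle deg).

    Velocity vectors from least-squares plane fits of activation time over
    sliding ``window`` x ``window`` neighbourhoods; speed = 1/|gradient|.
    Speeds are binned by gradient direction (mod 180 deg, ``bin_deg`` wide);
    longitudinal = max bin median, transverse = min.  Near-flat fits (speed
    above ``max_speed`` cm/s) are discarded as numerically singular.
    """
    t = act.activation_ms
    nrows, ncols = t.shape
    h = window // 2
    if nrows < window or ncols < window:
        raise InvalidParameterError("activation map smaller than fit window")
    spacing_cm = act.spacing_um / UM_PER_CM
    offs = np.arange(-h, h + 1) * spacing_cm
    xx, yy = np.meshgrid(offs, offs)
    A = np.column_stack([np.ones(xx.size), xx.ravel(), yy.ravel()])

    speeds, angles = [], []
    for r in range(h, nrows - h):
        for c in range(h, ncols - h):
            patch = t[r - h : r + h + 1, c - h : c + h + 1]
            if not np.isfinite(patch).all():
                continue
            coef, *_ = np.linalg.lstsq(A, patch.ravel(), rcond=None)
            gx, gy = coef[1], coef[2]  # ms per cm
            gnorm = float(np.hypot(gx, gy))
            if gnorm <= 0:
                continue
            speed = 1000.0 / gnorm  # cm/s
            if speed > max_speed:
                continue
            speeds.append(speed)
            angles.append(np.rad2deg(np.arctan2(gy, gx)) % 180.0)
    if len(speeds) < min_vectors_per_bin:
        raise NoSignalError("too few valid velocity vectors")
    speeds = np.asarray(speeds)
    angles = np.asarray(angles)
    bins = (angles // bin_deg).astype(int)
    medians = {}
    for bk in np.unique(bins):
        sel = bins == bk
        if sel.sum() >= min_vectors_per_bin:
            medians[bk] = float(np.median(speeds[sel]))
    if not medians:
        raise NoSignalError("no direction bin has enough velocity vectors")
    long_bin = max(medians, key=medians.get)
    longitudinal = medians[long_bin]
    transverse = min(medians.values())
    angle = (long_bin + 0.5) * bin_deg
    return longitudinal, transverse, float(angle)


# ---------------------------------------------------------------------------
# MEA
# ---------------------------------------------------------------------------

def mea_activation_map(rec: MEARecording) -> ActivationMap:
    """Activation = time of maximal negative slope of each field potential."""
    nrows, ncols, n = rec.traces.shape
    dt_ms = 1000.0 / rec.sample_rate
    out = np.full((nrows, ncols), np.nan)
    for r in range(nrows):
        for c in range(ncols):
            d = np.gradient(rec.traces[r, c])
            k = int(np.argmin(d))
            if d[k] >= 0:
                continue
            # parabolic sub-sample refinement of the derivative minimum
            if 0 < k < n - 1:
                y0, y1, y2 = d[k - 1], d[k], d[k + 1]
                denom = y0 - 2 * y1 + y2
                delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
                delta = float(np.clip(delta, -0.5, 0.5))
            else:
                delta = 0.0
            out[r, c] = (k + delta) * dt_ms
    return ActivationMap(activation_ms=out, spacing_um=rec.electrode_pitch)


def mea_mean_cv(
    act: ActivationMap,
    stim_electrode: tuple[int, int] = (0, 0),
) -> float:
    """Mean CV (cm/s) of the horizontal, vertical, and diagonal vectors from
    the stimulation corner across the electrode grid.

    Each vector's CV is the electrode-path distance divided by the
    activation-time difference between its endpoints.  Vectors with missing
    activation or non-positive time difference are dropped with a warning;
    if all are dropped an error is raised (e.g. instantaneous global
    activation).
    """
    t = act.activation_ms
    nrows, ncols = t.shape
    r0, c0 = stim_electrode
    pitch_cm = act.spacing_um / UM_PER_CM
    rd = nrows - 1 - r0 if r0 == 0 else -r0
    cd = ncols - 1 - c0 if c0 == 0 else -c0
    targets = {
        "horizontal": ((r0, c0 + cd), abs(cd) * pitch_cm),
        "vertical": ((r0 + rd, c0), abs(rd) * pitch_cm),
        "diagonal": ((r0 + rd, c0 + cd),
                     float(np.hypot(abs(rd), abs(cd)) * pitch_cm)),
    }
    cvs = []
    for name, ((r1, c1), dist_cm) in targets.items():
        t0, t1 = t[r0, c0], t[r1, c1]
        if not (np.isfinite(t0) and np.isfinite(t1)) or (t1 - t0) <= 0:
            warnings.warn(f"{name} vector dropped (missing or non-positive "
                          "activation delay)", stacklevel=2)
            continue
        cvs.append(dist_cm / ((t1 - t0) / 1000.0))
    if not cvs:
        raise DegenerateSignalError("no usable conduction vector on the array")
    return float(np.mean(cvs))
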