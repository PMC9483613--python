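"""Synthetic optical and electrical recordings with known ground truth.

Wave propagation is kinematic: a site at arc position x activates at
``t_stim + x/cv`` and then plays a fixed AP template, repeating at the
pacing cycle length.  This gives closed-form ground truth for every
downstream estimator (conduction velocity, APD, wavelength, activation
maps), which is the whole point of the generator; reaction-diffusion
dynamics are intentionally out of scope.

Voltage maps to fluorescence as

    F(t) = F0 * (1 + dye_fraction * V_norm(t)) * (1 - bleach_rate * t) + noise

i.e. a ~2% peak dF/F over a bright baseline, first-order photobleaching
drift, and Gaussian noise proportional to the baseline (shot-noise-like).
All randomness flows through one ``numpy`` generator seeded from the config,
so identical configs give bit-identical outputs.

Pattern defects can be injected: a ``("break", arc)`` blocks conduction past
that arc position; a ``("bridge", arc_a, arc_b)`` short-circuits two arc
positions (cells bridging adjacent spiral turns), activating each end at the
earlier of its own and its partner's activation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .ap_template import APTemplate, RestitutionModel, subtype_template
from .errors import InvalidParameterError
from .geometry import SpiralDesign, fit_image_shape, rasterize_mask

UM_PER_CM = 1.0e4


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and acquisition parameters for one spiral recording."""

    cv_true: float = 20.0            # cm/s
    apd80_true: float = 180.0        # ms
    pacing_cycle_length: float = 500.0  # ms (2 Hz)
    n_frames: int = 300
    frame_rate: float = 30.0         # Hz (full-frame)
    linescan_rate: float = 150.0     # Hz (resonant line-scan mode)
    pixel_size: float = 40.0         # um/px
    dye_fraction: float = 0.02       # peak dF/F
    noise_sd: float = 0.005          # fraction of baseline
    bleach_rate: float = 0.005       # fraction of baseline per second
    baseline: float = 1000.0         # fluorescence units
    stim_arc: float = 0.0            # cm, stimulation electrode position
    seed: int = 0
    defects: tuple = ()              # ("break", arc) / ("bridge", a, b)

    def __post_init__(self):
        if self.cv_true <= 0:
            raise InvalidParameterError("cv_true must be > 0")
        if self.apd80_true >= self.pacing_cycle_length:
            raise InvalidParameterError(
                "apd80_true must be < pacing cycle length (wave fusion)"
            )
        if self.noise_sd < 0 or self.dye_fraction <= 0:
            raise InvalidParameterError("noise_sd >= 0 and dye_fraction > 0 required")
        if self.n_frames < 1 or self.frame_rate <= 0:
            raise InvalidParameterError("need n_frames >= 1 and frame_rate > 0")

    def template(self) -> APTemplate:
        return APTemplate.from_apd80(self.apd80_true)


@dataclass
class FrameStack:
    """Time x rows x cols fluorescence stack with acquisition metadata."""

    intensities: np.ndarray          # (t, rows, cols), float32
    frame_rate: float                # Hz
    pixel_size: float                # um/px
    design_ref: str | None = None

    def __post_init__(self):
        if self.intensities.ndim != 3 or self.intensities.shape[0] < 1:
            raise InvalidParameterError("intensities must be (t, rows, cols)")

    @property
    def n_frames(self) -> int:
        return self.intensities.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class LineScanRecording:
    """Two simultaneously acquired region-mean fluorescence traces."""

    time_s: np.ndarray
    trace_a: np.ndarray
    trace_b: np.ndarray
    frame_rate: float
    region_a: tuple[float, float]    # arc interval, cm
    region_b: tuple[float, float]

    @property
    def separation_cm(self) -> float:
        ca = 0.5 * (self.region_a[0] + self.region_a[1])
        cb = 0.5 * (self.region_b[0] + self.region_b[1])
        return abs(cb - ca)


@dataclass
class MEARecording:
    """8x8 (by default) microelectrode-array field-potential recording."""

    traces: np.ndarray               # (rows, cols, t)
    sample_rate: float               # Hz
    electrode_pitch: float           # um
    true_activation_ms: np.ndarray   # (rows, cols)
    stim_electrode: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# activation times along the 1D path (with defects)
# ---------------------------------------------------------------------------

def path_activation_times(
    arc_positions: np.ndarray,
    cv: float,
    stim_arc: float = 0.0,
    defects: tuple = (),
) -> np.ndarray:
    """First-activation time (s) at each arc position (cm); inf if blocked.

    Breaks cut the path; bridges add shortcut edges whose endpoints activate
    at the earlier of their own and their partner's earliest time, then act
    as secondary sources.
    """
    arc = np.asarray(arc_positions, dtype=float)
    breaks = sorted(float(d[1]) for d in defects if d[0] == "break")
    bridges = [(float(d[1]), float(d[2])) for d in defects if d[0] == "bridge"]

    def unbroken(a, b):
        lo, hi = min(a, b), max(a, b)
        return not any(lo < br < hi for br in breaks)

    # source nodes: (arc, activation time)
    nodes = {stim_arc: 0.0}
    endpoints = [e for br in bridges for e in br]
    for _ in range(len(bridges) + 1):
        for a, b in bridges:
            for p in (a, b):
                best = min(
                    (t + abs(p - s) / cv for s, t in nodes.items() if unbroken(s, p)),
                    default=np.inf,
                )
                nodes[p] = min(nodes.get(p, np.inf), best)
            earlier = min(nodes.get(a, np.inf), nodes.get(b, np.inf))
            nodes[a] = nodes[b] = earlier

    times = np.full(arc.shape, np.inf)
    for s, t0 in nodes.items():
        if not np.isfinite(t0):
            continue
        cand = t0 + np.abs(arc - s) / cv
        reach = np.ones(arc.shape, dtype=bool)
        for br in breaks:
            reach &= ~((np.minimum(arc, s) < br) & (br < np.maximum(arc, s)))
        times = np.where(reach, np.minimum(times, cand), times)
    return times


def _fluorescence(v_norm, t_s, config: SimulationConfig):
    """Map normalized voltage + time to noiseless fluorescence."""
    return (
        config.baseline
        * (1.0 + config.dye_fraction * v_norm)
        * (1.0 - config.bleach_rate * t_s)
    )


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_spiral_recording(
    design: SpiralDesign, config: SimulationConfig
) -> FrameStack:
    """Full-frame fluorescence movie of paced waves on the spiral pattern."""
    if not 0.0 <= config.stim_arc <= design.total_length:
        raise InvalidParameterError("stimulation arc position outside the path")
    shape = fit_image_shape(design, config.pixel_size)
    mask = rasterize_mask(design, config.pixel_size, shape)
    rr, cc = np.nonzero(mask)
    # nearest-centerline arc position of every pattern pixel
    rows, cols = shape
    x = (cc + 0.5 - cols / 2.0) * config.pixel_size
    y = (rows / 2.0 - rr - 0.5) * config.pixel_size
    tree = cKDTree(design.centerline)
    _, idx = tree.query(np.column_stack([x, y]))
    arc_px = design.arc[idx]

    t_act = path_activation_times(
        arc_px, config.cv_true, config.stim_arc, config.defects
    )
    template = config.template()
    cl_s = config.pacing_cycle_length / 1000.0
    t_frames = np.arange(config.n_frames) / config.frame_rate

    rng = np.random.default_rng(config.seed)
    stack = np.empty((config.n_frames, rows, cols), dtype=np.float32)
    finite = np.isfinite(t_act)
    for f, t in enumerate(t_frames):
        tau = t - t_act[finite]
        phase_ms = np.where(tau >= 0, (tau % cl_s) * 1000.0, -1.0)
        v = np.zeros(arc_px.shape)
        v[finite] = template.normalized(phase_ms)
        frame = np.full(
            (rows, cols),
            config.baseline * (1.0 - config.bleach_rate * t),
            dtype=np.float64,
        )
        frame[rr, cc] = _fluorescence(v, t, config)
        if config.noise_sd > 0:
            frame += rng.normal(0.0, config.noise_sd * config.baseline, frame.shape)
        stack[f] = frame.astype(np.float32)
    return FrameStack(
        intensities=stack,
        frame_rate=config.frame_rate,
        pixel_size=config.pixel_size,
        design_ref=f"spiral_L{design.total_length:.3f}cm",
    )


def simulate_linescan(
    design: SpiralDesign,
    config: SimulationConfig,
    region_a: tuple[float, float] = (0.40, 0.44),
    region_b: tuple[float, float] = (4.90, 4.94),
    extraction_width_px: int = 10,
) -> LineScanRecording:
    """Region-mean traces at the line-scan frame rate (default 150 Hz).

    The two regions (arc intervals, cm) emulate a scan line crossing the
    stimulation-electrode area and the terminal of the spiral; because the
    scan line crosses the narrow track, each region spans only ~2 line
    widths of arc (400 um by default), keeping the activation spread within
    a region well below one sample.  The trace is the mean fluorescence over
    each region.
    """
    L = design.total_length
    for reg in (region_a, region_b):
        if not (0.0 <= reg[0] < reg[1] <= L):
            raise InvalidParameterError("region outside [0, L] or empty")
    if max(region_a[0], region_b[0]) < min(region_a[1], region_b[1]):
        raise InvalidParameterError("regions must be disjoint")

    duration_s = config.n_frames / config.frame_rate
    n = int(round(duration_s * config.linescan_rate))
    t = np.arange(n) / config.linescan_rate
    template = config.template()
    cl_s = config.pacing_cycle_length / 1000.0
    rng = np.random.default_rng(config.seed + 1)

    traces = []
    for reg in (region_a, region_b):
        arcs = np.arange(reg[0], reg[1], config.pixel_size / UM_PER_CM)
        t_act = path_activation_times(
            arcs, config.cv_true, config.stim_arc, config.defects
        )
        finite = np.isfinite(t_act)
        tau = t[:, None] - t_act[None, finite]
        phase_ms = np.where(tau >= 0, (tau % cl_s) * 1000.0, -1.0)
        v = np.zeros((n, arcs.size))
        if finite.any():
            v[:, finite] = template.normalized(phase_ms)
        trace = _fluorescence(v, t[:, None], config).mean(axis=1)
        n_eff = max(arcs.size * extraction_width_px, 1)
        if config.noise_sd > 0:
            trace = trace + rng.normal(
                0.0, config.noise_sd * config.baseline / np.sqrt(n_eff), n
            )
        traces.append(trace)
    return LineScanRecording(
        time_s=t,
        trace_a=traces[0],
        trace_b=traces[1],
        frame_rate=config.linescan_rate,
        region_a=region_a,
        region_b=region_b,
    )


def simulate_mea(
    cv_true: float,
    mode: str = "radial",
    direction_deg: float = 0.0,
    grid: tuple[int, int] = (8, 8),
    electrode_pitch: float = 450.0,
    sample_rate: float = 5000.0,
    duration_s: float = 0.5,
    template: APTemplate | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    stim_electrode: tuple[int, int] = (0, 0),
) -> MEARecording:
    """Field-potential recording of one wave crossing the electrode grid.

    ``mode="radial"`` spreads the wave from the stimulation electrode
    (corner pacing, as on the physical array); ``mode="planar"`` is a plane
    wave travelling along ``direction_deg`` (0 = +x = along a row).  The
    field potential is modelled as the negative time-derivative of the AP
    template, giving the sharp negative deflection used for activation
    detection.  True activation times are returned alongside the traces.
    """
    if cv_true <= 0:
        raise InvalidParameterError("cv_true must be > 0")
    nrows, ncols = grid
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    x_cm = jj * electrode_pitch / UM_PER_CM
    y_cm = ii * electrode_pitch / UM_PER_CM
    sr, sc = stim_electrode
    if mode == "radial":
        dist = np.hypot(x_cm - sc * electrode_pitch / UM_PER_CM,
                        y_cm - sr * electrode_pitch / UM_PER_CM)
        act_s = dist / cv_true
    elif mode == "planar":
        th = np.deg2rad(direction_deg)
        proj = x_cm * np.cos(th) + y_cm * np.sin(th)
        act_s = (proj - proj.min()) / cv_true
    else:
        raise InvalidParameterError(f"unknown MEA mode {mode!r}")

    if template is None:
        template = subtype_template("atrial")
    n = int(round(duration_s * sample_rate))
    t_ms = np.arange(n) / sample_rate * 1000.0
    dt_ms = 1000.0 / sample_rate
    onset_ms = 10.0  # pacing latency before the first electrode activates
    act_ms = act_s * 1000.0 + onset_ms

    rng = np.random.default_rng(seed)
    traces = np.zeros((nrows, ncols, n))
    for r in range(nrows):
        for c in range(ncols):
            v = template.normalized(t_ms - act_ms[r, c])
            fp = -np.gradient(v, dt_ms)  # field potential ~ -dV/dt
            if noise_sd > 0:
                fp = fp + rng.normal(0.0, noise_sd, n)
            traces[r, c] = fp
    return MEARecording(
        traces=traces,
        sample_rate=sample_rate,
        electrode_pitch=electrode_pitch,
        true_activation_ms=act_ms,
        stim_electrode=stim_electrode,
    )


def simulate_patch_ap(
    template: APTemplate,
    n_beats: int = 3,
    cycle_ms: float = 800.0,
    sample_rate_khz: float = 10.0,
    noise_sd_mv: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Patch-clamp-style voltage trace (t_ms, v_mV) of paced template APs."""
    if template.apa <= 0:
        raise InvalidParameterError("amplitude must be > 0")
    if cycle_ms <= template.apd(0.95):
        raise InvalidParameterError("cycle shorter than the AP")
    dt = 1.0 / sample_rate_khz
    lead_ms = 150.0
    total = lead_ms + n_beats * cycle_ms
    t = np.arange(0.0, total, dt)
    v = np.full(t.shape, template.mdp)
    for k in range(n_beats):
        v = np.maximum(v, template.voltage(t - lead_ms - k * cycle_ms))
    if noise_sd_mv > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd_mv, v.shape)
    return t, v


def simulate_s1s2(
    model: RestitutionModel,
    s1_cycle_length: float = 1000.0,
    s1_count: int = 10,
    s2_schedule=tuple(range(600, 190, -10)),
) -> list[tuple[float, bool]]:
    """Capture flag for each S2 coupling interval after an S1 drive train.

    The drive train brings APD to (near) steady state; the S2 diastolic
    interval is coupling interval - steady-state APD, and capture requires
    DI >= the model's capture threshold.  Fully deterministic.
    """
    s2 = [float(s) for s in s2_schedule]
    if any(b >= a for a, b in zip(s2, s2[1:])):
        raise InvalidParameterError("s2_schedule must be strictly decreasing")
    apd_ss = model.steady_state_apd(s1_cycle_length, n_beats=s1_count * 5)
    out = []
    for ci in s2:
        di = ci - apd_ss
        out.append((ci, model.captures(di)))
    return out


def simulate_slice_stack(
    cv_long: float,
    cv_trans: float,
    fiber_angle_deg: float = 0.0,
    shape: tuple[int, int] = (60, 60),
    pixel_size: float = 100.0,
    frame_rate: float = 1000.0,
    template: APTemplate | None = None,
    mode: str = "elliptical",
    direction_deg: float = 0.0,
    source: str = "center",
    noise_sd: float = 0.0,
    drift_per_s: float = 0.0,
    seed: int = 0,
    duration_ms: float | None = None,
) -> FrameStack:
    """Tissue-slice-style optical map of one paced wave.

    ``elliptical`` mode spreads an anisotropic wave from a point source
    (longitudinal speed ``cv_long`` along ``fiber_angle_deg``, transverse
    ``cv_trans``); ``planar`` mode propagates a plane wave at ``cv_long``
    along ``direction_deg``.  Pixel intensity is baseline + amplitude *
    V_norm + linear drift + noise, in arbitrary camera units.
    """
    if cv_long <= 0 or cv_trans <= 0:
        raise InvalidParameterError("speeds must be > 0")
    nrows, ncols = shape
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    x = (jj - (ncols - 1) / 2.0) * pixel_size / UM_PER_CM
    y = ((nrows - 1) / 2.0 - ii) * pixel_size / UM_PER_CM
    if source == "corner":
        x = jj * pixel_size / UM_PER_CM
        y = ii * pixel_size / UM_PER_CM
    th = np.deg2rad(fiber_angle_deg)
    xl = x * np.cos(th) + y * np.sin(th)
    xt = -x * np.sin(th) + y * np.cos(th)
    if mode == "elliptical":
        act_s = np.hypot(xl / cv_long, xt / cv_trans)
    elif mode == "planar":
        d = np.deg2rad(direction_deg)
        proj = x * np.cos(d) + y * np.sin(d)
        act_s = (proj - proj.min()) / cv_long
    else:
        raise InvalidParameterError(f"unknown slice mode {mode!r}")

    if template is None:
        template = APTemplate.from_apds(180.0, 240.0)
    if duration_ms is None:
        duration_ms = act_s.max() * 1000.0 + template.apd(0.95) + 80.0
    n = int(round(duration_ms / 1000.0 * frame_rate))
    t_ms = np.arange(n) / frame_rate * 1000.0
    onset_ms = 20.0

    rng = np.random.default_rng(seed)
    stack = np.empty((n, nrows, ncols), dtype=np.float32)
    act_flat = act_s.ravel() * 1000.0 + onset_ms
    v = template.normalized(t_ms[:, None] - act_flat[None, :])
    signal = 100.0 + 5.0 * v + drift_per_s * (t_ms[:, None] / 1000.0)
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, signal.shape)
    stack[:] = signal.reshape(n, nrows, ncols).astype(np.float32)
    return FrameStack(
        intensities=stack, frame_rate=frame_rate, pixel_size=pixel_size
    )
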