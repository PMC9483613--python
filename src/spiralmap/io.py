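"""File formats, run configuration, and deterministic test fixtures.

Image stacks travel as multi-page TIFF plus a JSON metadata sidecar
(``<stack>.json``) carrying the frame rate, pixel size, and design
reference; the sidecar is required on read — there are no silent default
acquisition parameters.  Traces and tables are plain CSV; designs are JSON;
run configuration round-trips through YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .ap_template import RestitutionModel, subtype_template
from .errors import FormatError
from .geometry import SpiralDesign, default_design
from .synth import (
    FrameStack,
    LineScanRecording,
    MEARecording,
    SimulationConfig,
    simulate_linescan,
    simulate_mea,
    simulate_patch_ap,
    simulate_s1s2,
    simulate_spiral_recording,
)


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def write_stack(stack: FrameStack, path) -> None:
    """Write a FrameStack as multi-page TIFF + JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.intensities.astype(np.float32))
    meta = {
        "frame_rate_hz": stack.frame_rate,
        "pixel_size_um": stack.pixel_size,
        "design_ref": stack.design_ref,
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_stack(path) -> FrameStack:
    """Read a TIFF stack; the metadata sidecar is mandatory."""
    path = Path(path)
    side = _sidecar_path(path)
    if not side.exists():
        raise FormatError(f"missing metadata sidecar {side}")
    try:
        data = tifffile.imread(path)
    except Exception as exc:  # tifffile raises various types on truncation
        raise FormatError(f"unreadable TIFF stack {path}: {exc}") from exc
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3 or data.size == 0:
        raise FormatError(f"truncated or empty TIFF stack {path}")
    with open(side) as fh:
        meta = json.load(fh)
    for key in ("frame_rate_hz", "pixel_size_um"):
        if key not in meta:
            raise FormatError(f"sidecar missing required key {key!r}")
    return FrameStack(
        intensities=np.asarray(data, dtype=np.float32),
        frame_rate=float(meta["frame_rate_hz"]),
        pixel_size=float(meta["pixel_size_um"]),
        design_ref=meta.get("design_ref"),
    )


def write_linescan(rec: LineScanRecording, path) -> None:
    df = pd.DataFrame(
        {"time_s": rec.time_s, "trace_a": rec.trace_a, "trace_b": rec.trace_b}
    )
    header = (
        f"# frame_rate_hz={rec.frame_rate} "
        f"region_a={rec.region_a[0]},{rec.region_a[1]} "
        f"region_b={rec.region_b[0]},{rec.region_b[1]}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def read_linescan(path) -> LineScanRecording:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError("line-scan CSV missing metadata header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        df = pd.read_csv(fh)
    ra = tuple(float(x) for x in meta["region_a"].split(","))
    rb = tuple(float(x) for x in meta["region_b"].split(","))
    return LineScanRecording(
        time_s=df["time_s"].to_numpy(),
        trace_a=df["trace_a"].to_numpy(),
        trace_b=df["trace_b"].to_numpy(),
        frame_rate=float(meta["frame_rate_hz"]),
        region_a=ra,
        region_b=rb,
    )


def write_mea_csv(rec: MEARecording, path) -> None:
    nrows, ncols, n = rec.traces.shape
    idx = pd.MultiIndex.from_product(
        [range(nrows), range(ncols)], names=["row", "col"]
    )
    df = pd.DataFrame(rec.traces.reshape(nrows * ncols, n), index=idx)
    df.to_csv(path)


def read_mea_csv(path, sample_rate: float, electrode_pitch: float) -> MEARecording:
    df = pd.read_csv(path, index_col=[0, 1])
    nrows = df.index.get_level_values(0).max() + 1
    ncols = df.index.get_level_values(1).max() + 1
    traces = df.to_numpy().reshape(nrows, ncols, -1)
    return MEARecording(
        traces=traces,
        sample_rate=sample_rate,
        electrode_pitch=electrode_pitch,
        true_activation_ms=np.full((nrows, ncols), np.nan),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration for an end-to-end run.

    Defaults equal the published processing parameters where one exists
    (0.005 Butterworth cutoff, 10-pixel extraction width, 80% repolarization
    level, >= 10 averaged waves, text-rule classifier).
    """

    design: dict = field(
        default_factory=lambda: {"d_l_um": 200.0, "d_s_um": 400.0}
    )
    simulation: dict = field(default_factory=dict)   # SimulationConfig overrides
    filter_cutoff: float = 0.005
    extraction_width: int = 10
    arc_step_cm: float = 0.001
    repol_fraction: float = 0.8
    min_waves: int = 10
    rule_set: str = "text"
    seed: int = 0
    outdir: str = "results"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(seed=self.seed, **self.simulation)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixtures(seed: int = 0) -> dict:
    """Deterministic miniature datasets of every input kind, with ground
    truth in the ``manifest`` entry.  Same seed -> identical arrays."""
    design = default_design()
    config = SimulationConfig(
        cv_true=20.0, apd80_true=160.0, n_frames=150, seed=seed
    )
    movie = simulate_spiral_recording(design, config)
    linescan = simulate_linescan(design, config)
    mea = simulate_mea(cv_true=9.0, mode="radial", seed=seed, noise_sd=0.002)
    patch = {
        label: simulate_patch_ap(subtype_template(label), seed=seed)
        for label in ("nodal", "atrial", "ventricular")
    }
    model = RestitutionModel()
    s1s2 = simulate_s1s2(model)
    manifest = {
        "seed": seed,
        "spiral": {
            "cv_true": config.cv_true,
            "apd80_true": config.apd80_true,
            "wl_true": config.cv_true * config.apd80_true / 1000.0,
        },
        "mea": {"cv_true": 9.0},
        "erp_true": model.true_erp(1000.0),
    }
    return {
        "design": design,
        "config": config,
        "movie": movie,
        "linescan": linescan,
        "mea": mea,
        "patch": patch,
        "s1s2": s1s2,
        "restitution": model,
        "manifest": manifest,
    }
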