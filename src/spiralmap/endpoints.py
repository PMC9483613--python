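"""Protocol-level electrophysiological endpoints.

Shared by the catheter (in vivo), tissue-slice (ex vivo), MEA, and spiral
arms: effective refractory period from an S1-S2 extrastimulus capture scan,
catheter conduction velocity over a fixed electrode span, conduction
wavelength, and cohort summary tables (mean +/- SEM per group/side/endpoint,
with each record's wavelength computed before averaging).

ERP convention: the longest coupling interval that fails to capture (the
interval at loss of capture).  The alternative "last captured interval"
convention is available via ``convention="shortest_capture"``; with a 10 ms
decrement the two differ by exactly one step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ProtocolViolationError


@dataclass(frozen=True)
class ERPResult:
    erp: float | None                # ms; None if capture never lost
    convention: str
    scan: tuple[tuple[float, bool], ...]
    drive_cycle_length: float | None = None

    @property
    def reached(self) -> bool:
        return self.erp is not None


@dataclass(frozen=True)
class EndpointRecord:
    """One preparation's endpoints with provenance."""

    source: str                      # in_vivo | slice | mea | spiral
    cv: float                        # cm/s
    duration: float                  # ms
    duration_type: str = "ERP"       # ERP | APD80 | APD90
    side: str = "n/a"                # LA | RA | n/a
    group: str = "n/a"               # control | AF | n/a
    drive_cycle_length: float | None = None

    @property
    def wl(self) -> float:
        """Conduction wavelength, cm = cv (cm/s) x duration (s)."""
        return self.cv * self.duration / 1000.0


def erp_from_scan(
    scan,
    convention: str = "longest_noncapture",
    drive_cycle_length: float | None = None,
) -> ERPResult:
    """ERP from a decremental coupling-interval capture scan.

    ``scan`` is a sequence of (coupling interval ms, captured flag) with
    strictly decreasing intervals, starting captured.  Capture must be
    monotone (once lost, never regained), else ProtocolViolationError.
    """
    scan = [(float(ci), bool(cap)) for ci, cap in scan]
    if len(scan) < 2:
        raise InvalidParameterError("scan needs at least 2 extrastimuli")
    cis = [ci for ci, _ in scan]
    if any(b >= a for a, b in zip(cis, cis[1:])):
        raise InvalidParameterError("coupling intervals must be strictly decreasing")
    if not scan[0][1]:
        raise ProtocolViolationError("scan must begin with a captured beat")
    caps = [cap for _, cap in scan]
    seen_loss = False
    for cap in caps:
        if not cap:
            seen_loss = True
        elif seen_loss:
            raise ProtocolViolationError("capture regained after loss")
    if convention not in ("longest_noncapture", "shortest_capture"):
        raise InvalidParameterError(f"unknown ERP convention {convention!r}")
    erp: float | None = None
    if seen_loss:
        first_loss = next(ci for ci, cap in scan if not cap)
        if convention == "longest_noncapture":
            erp = first_loss
        else:
            erp = min(ci for ci, cap in scan if cap)
    return ERPResult(
        erp=erp,
        convention=convention,
        scan=tuple(scan),
        drive_cycle_length=drive_cycle_length,
    )


def catheter_cv(conduction_time_ms: float, span_mm: float = 20.0) -> float:
    """CV (cm/s) from conduction time over the catheter's electrode span."""
    if conduction_time_ms <= 0:
        raise InvalidParameterError("conduction time must be > 0")
    if span_mm <= 0:
        raise InvalidParameterError("span must be > 0")
    return (span_mm / 10.0) / (conduction_time_ms / 1000.0)


def summarize_cohort(records: list[EndpointRecord]) -> pd.DataFrame:
    """Mean +/- SEM of CV, duration, and WL per (group, side, duration_type).

    Wavelength is computed per record (CV x duration) before group
    averaging, i.e. the mean of products, not the product of means.  Cells
    with a single record report SEM = NaN.
    """
    if not records:
        raise InvalidParameterError("no records")
    df = pd.DataFrame(
        {
            "group": [r.group for r in records],
            "side": [r.side for r in records],
            "duration_type": [r.duration_type for r in records],
            "cv": [r.cv for r in records],
            "duration": [r.duration for r in records],
            "wl": [r.wl for r in records],
        }
    )
    g = df.groupby(["group", "side", "duration_type"], sort=True)
    out = g.agg(
        n=("cv", "size"),
        cv_mean=("cv", "mean"),
        cv_sem=("cv", "sem"),
        duration_mean=("duration", "mean"),
        duration_sem=("duration", "sem"),
        wl_mean=("wl", "mean"),
        wl_sem=("wl", "sem"),
    ).reset_index()
    return out
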