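"""Patch-clamp AP feature extraction and rule-based subtype classification.

Features per action potential: minimal diastolic potential (MDP), amplitude
(APA = peak - MDP), maximal upstroke rate dV/dt_max, and APD50/APD90 at 50%
and 90% repolarization with sub-sample interpolation.  Multi-beat traces are
averaged beat-by-beat.

Two published rule sets for nodal / atrial / ventricular classification are
implemented.  The "text" set (the stated classification procedure, and the
default) uses MDP < -55 mV with OR-joined APD criteria for working
myocytes; the "caption" set uses MDP < -60 mV with jointly required
criteria.  The two differ, and both leave gaps (e.g. MDP between the nodal
and working-myocyte cutoffs): any cell matching no rule, or matching both
the atrial and ventricular disjuncts, is returned ``unclassified`` with a
rule trace explaining why - never silently tie-broken.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import InvalidParameterError, NoSignalError


@dataclass(frozen=True)
class APFeatures:
    mdp: float          # mV
    apa: float          # mV
    dvdt_max: float     # V/s
    apd50: float        # ms
    apd90: float        # ms

    def __post_init__(self):
        if self.apa <= 0:
            raise InvalidParameterError("APA must be > 0")
        if not self.apd90 >= self.apd50 > 0:
            raise InvalidParameterError("need apd90 >= apd50 > 0")

    @property
    def apd_ratio(self) -> float:
        """APD90/APD50, the repolarization-shape index (>= 1)."""
        return self.apd90 / self.apd50


@dataclass(frozen=True)
class APClass:
    label: str                      # nodal | atrial | ventricular | unclassified
    rule_trace: tuple[str, ...] = ()


def extract_features(
    t_ms: np.ndarray, v_mv: np.ndarray, min_amplitude_mv: float = 20.0
) -> APFeatures:
    """Extract averaged AP features from a voltage trace sampled >= 1 kHz."""
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v_mv, dtype=float)
    if t.size != v.size or t.size < 10:
        raise InvalidParameterError("need matching t/v arrays")
    dt = float(np.median(np.diff(t)))
    if dt > 1.0 + 1e-9:
        raise InvalidParameterError("sampling must be >= 1 kHz")
    span = v.max() - v.min()
    if span < min_amplitude_mv:
        raise NoSignalError("no action potential (flat trace)")
    peaks, _ = find_peaks(v, prominence=0.5 * span, distance=max(int(50 / dt), 1))
    if peaks.size == 0:
        raise NoSignalError("no action potential detected")

    feats = []
    prev = 0
    for p in peaks:
        seg = v[prev:p]
        if seg.size < 2:
            prev = p
            continue
        mdp = float(seg.min())
        apa = float(v[p] - mdp)
        if apa < min_amplitude_mv:
            prev = p
            continue
        # upstroke: from the diastolic minimum to the peak.  Boxcar-smooth
        # then take a 4-sample secant: averaging keeps single-sample noise
        # out of the derivative and a secant never overshoots a slope corner
        i_mdp = prev + int(np.argmin(seg))
        upstroke = v[i_mdp : p + 1].astype(float)
        if upstroke.size >= 10:
            sm_up = np.convolve(upstroke, np.ones(5) / 5.0, mode="valid")
            dvdt = float(np.max((sm_up[4:] - sm_up[:-4]) / (4.0 * dt)))
        else:
            dvdt = float(np.max(np.diff(upstroke) / dt))  # mV/ms == V/s
        apds = {}
        for level_p in (0.5, 0.9):
            level = v[p] - level_p * apa
            up = np.nonzero(v[i_mdp : p + 1] < level)[0]
            after = np.nonzero(v[p:] < level)[0]
            if up.size == 0 or after.size == 0:
                apds = None
                break
            i = i_mdp + up[-1]
            t_up = t[i] + (level - v[i]) / (v[i + 1] - v[i]) * (t[i + 1] - t[i])
            j = p + after[0]
            t_dn = t[j - 1] + (v[j - 1] - level) / (v[j - 1] - v[j]) * (
                t[j] - t[j - 1]
            )
            apds[level_p] = t_dn - t_up
        if apds is not None:
            feats.append((mdp, apa, dvdt, apds[0.5], apds[0.9]))
        prev = p
    if not feats:
        raise NoSignalError("no complete action potential in trace")
    arr = np.array(feats)
    mean = arr.mean(axis=0)
    return APFeatures(
        mdp=float(mean[0]),
        apa=float(mean[1]),
        dvdt_max=float(mean[2]),
        apd50=float(mean[3]),
        apd90=float(mean[4]),
    )


def classify(features: APFeatures, rule_set: str = "text") -> APClass:
    """Assign nodal / atrial / ventricular / unclassified per the rule set.

    ``text`` (default): nodal if APA < 100 mV and MDP > -50 mV and
    dV/dt_max < 5 V/s; cells with MDP < -55 mV and dV/dt_max > 5 V/s are
    ventricular if (APD90 > 400 ms or APD90/APD50 < 1.2) and atrial if
    (APD90 < 300 ms or APD90/APD50 > 1.2); satisfying both disjunct groups
    is ambiguous -> unclassified.

    ``caption``: nodal as above; working myocytes need MDP < -60 mV, APA >
    100 mV, dV/dt_max > 5 V/s, then atrial requires APD90 < 300 ms and
    ratio > 1.2 jointly, ventricular APD90 > 400 ms and ratio < 1.2.
    """
    f = features
    trace: list[str] = []
    if rule_set not in ("text", "caption"):
        raise InvalidParameterError(f"unknown rule set {rule_set!r}")

    nodal = f.apa < 100.0 and f.mdp > -50.0 and f.dvdt_max < 5.0
    if nodal:
        return APClass("nodal", ("APA<100", "MDP>-50", "dVdt<5"))

    if rule_set == "text":
        working = f.mdp < -55.0 and f.dvdt_max > 5.0
        if not working:
            trace.append("not nodal; not working (MDP<-55 & dVdt>5 failed)")
            return APClass("unclassified", tuple(trace))
        ventricular = f.apd90 > 400.0 or f.apd_ratio < 1.2
        atrial = f.apd90 < 300.0 or f.apd_ratio > 1.2
        if atrial and ventricular:
            trace.append("both atrial and ventricular disjuncts fired")
            return APClass("unclassified", tuple(trace))
        if ventricular:
            return APClass("ventricular", ("MDP<-55", "dVdt>5",
                                           "APD90>400 or ratio<1.2"))
        if atrial:
            return APClass("atrial", ("MDP<-55", "dVdt>5",
                                      "APD90<300 or ratio>1.2"))
        trace.append("working myocyte but neither APD criterion fired")
        return APClass("unclassified", tuple(trace))

    # caption rules
    working = f.mdp < -60.0 and f.apa > 100.0 and f.dvdt_max > 5.0
    if not working:
        trace.append("not nodal; not working (MDP<-60 & APA>100 & dVdt>5 failed)")
        return APClass("unclassified", tuple(trace))
    if f.apd90 < 300.0 and f.apd_ratio > 1.2:
        return APClass("atrial", ("MDP<-60", "APA>100", "dVdt>5",
                                  "APD90<300", "ratio>1.2"))
    if f.apd90 > 400.0 and f.apd_ratio < 1.2:
        return APClass("ventricular", ("MDP<-60", "APA>100", "dVdt>5",
                                       "APD90>400", "ratio<1.2"))
    trace.append("working myocyte outside both joint criteria")
    return APClass("unclassified", tuple(trace))


def population_summary(classes: list[APClass]) -> dict[str, float]:
    """Fraction of each label over a classified population (sums to 1)."""
    if not classes:
        raise InvalidParameterError("empty population")
    counts = Counter(c.label for c in classes)
    n = len(classes)
    return {
        label: counts.get(label, 0) / n
        for label in ("nodal", "atrial", "ventricular", "unclassified")
    }
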