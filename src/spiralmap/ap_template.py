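"""Analytic action-potential templates and a phenomenological restitution model.

The template is deliberately simple so every downstream duration measure has
a closed form: a linear upstroke of duration ``upstroke_duration`` from the
minimal diastolic potential (MDP) to the peak, followed by a logistic
repolarization.  With repolarized fraction

    f(t) = (sigma((t - m)/w) - sigma(-m/w)) / (1 - sigma(-m/w)),

where sigma is the standard logistic and t is time after the peak, the
crossing time of any repolarization level p in (0, 1) inverts exactly, so
APD50/APD80/APD90 are available analytically.  ``m`` (ms) sets the plateau
length and ``w`` (ms) the steepness of the final repolarization; together
they control both APD and the APD90/APD50 ratio used to separate atrial-like
from ventricular-like cells.

APD_p convention throughout the package: the duration from the rising-phase
crossing of the level "p repolarized" (i.e. voltage = MDP + (1-p)*APA) to the
falling-phase crossing of the same level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import fsolve

from .errors import InvalidParameterError


def _sigma(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class APTemplate:
    """Single action-potential waveform with analytic APD levels.

    mdp : resting / minimal diastolic potential, mV
    apa : action potential amplitude (peak - mdp), mV
    upstroke_duration : linear upstroke duration, ms
    plateau_midpoint : logistic midpoint m of the repolarized fraction, ms
    fall_width : logistic width w, ms
    """

    mdp: float = -70.0
    apa: float = 100.0
    upstroke_duration: float = 4.0
    plateau_midpoint: float = 150.0
    fall_width: float = 25.0

    def __post_init__(self):
        if self.apa <= 0:
            raise InvalidParameterError("amplitude must be > 0")
        if self.upstroke_duration <= 0 or self.fall_width <= 0:
            raise InvalidParameterError("durations must be > 0")
        if self.plateau_midpoint <= 0:
            raise InvalidParameterError("plateau midpoint must be > 0")

    @property
    def dvdt_max(self) -> float:
        """Maximal upstroke rate, V/s (mV/ms)."""
        return self.apa / self.upstroke_duration

    @property
    def _sigma0(self) -> float:
        return float(_sigma(-self.plateau_midpoint / self.fall_width))

    def repolarized_fraction(self, t_after_peak):
        """Fraction repolarized, 0 at the peak -> 1 at rest."""
        t = np.asarray(t_after_peak, dtype=float)
        s0 = self._sigma0
        f = (_sigma((t - self.plateau_midpoint) / self.fall_width) - s0) / (1.0 - s0)
        return np.clip(f, 0.0, 1.0)

    def normalized(self, t_ms):
        """(V - MDP)/APA at time(s) t_ms after upstroke onset (0 at rest)."""
        t = np.asarray(t_ms, dtype=float)
        up = self.upstroke_duration
        rising = np.clip(t / up, 0.0, 1.0)
        falling = 1.0 - self.repolarized_fraction(np.maximum(t - up, 0.0))
        out = np.where(t < up, rising, falling)
        return np.where(t < 0, 0.0, out)

    def voltage(self, t_ms):
        """Membrane voltage in mV at time(s) after upstroke onset."""
        return self.mdp + self.apa * self.normalized(t_ms)

    def apd(self, p: float) -> float:
        """Closed-form APD at repolarization level p (e.g. 0.8 for APD80)."""
        if not 0.0 < p < 1.0:
            raise InvalidParameterError("repolarization level must be in (0, 1)")
        s0 = self._sigma0
        q = p * (1.0 - s0) + s0
        t_fall = (
            self.upstroke_duration
            + self.plateau_midpoint
            + self.fall_width * np.log(q / (1.0 - q))
        )
        t_rise = (1.0 - p) * self.upstroke_duration
        return float(t_fall - t_rise)

    @property
    def apd50(self) -> float:
        return self.apd(0.5)

    @property
    def apd80(self) -> float:
        return self.apd(0.8)

    @property
    def apd90(self) -> float:
        return self.apd(0.9)

    # -- factories -----------------------------------------------------

    @classmethod
    def from_apds(
        cls,
        apd50: float,
        apd90: float,
        mdp: float = -70.0,
        apa: float = 100.0,
        upstroke_duration: float | None = None,
        dvdt_max: float | None = None,
    ) -> "APTemplate":
        """Solve (m, w) so the template hits the requested APD50 and APD90.

        Exactly one of ``upstroke_duration`` / ``dvdt_max`` may be given
        (dV/dt_max = APA / upstroke duration for the linear upstroke).
        """
        if apd90 <= apd50 or apd50 <= 0:
            raise InvalidParameterError("need apd90 > apd50 > 0")
        if dvdt_max is not None:
            if upstroke_duration is not None:
                raise InvalidParameterError(
                    "give either upstroke_duration or dvdt_max, not both"
                )
            upstroke_duration = apa / dvdt_max
        if upstroke_duration is None:
            upstroke_duration = 4.0
        up = upstroke_duration

        def residual(x):
            m, w = x
            if m <= 0 or w <= 0:
                return [1e6, 1e6]
            t = cls(mdp=mdp, apa=apa, upstroke_duration=up,
                    plateau_midpoint=m, fall_width=w)
            return [t.apd(0.5) - apd50, t.apd(0.9) - apd90]

        w0 = max((apd90 - apd50) / np.log(81.0), 1.0)  # logit(0.9)-logit(0.5)=ln 9
        m0 = max(apd50 - 0.5 * up, 1.0)
        sol = fsolve(residual, [m0, w0], full_output=False)
        m, w = float(sol[0]), float(sol[1])
        tpl = cls(mdp=mdp, apa=apa, upstroke_duration=up,
                  plateau_midpoint=m, fall_width=w)
        if abs(tpl.apd(0.5) - apd50) > 0.05 or abs(tpl.apd(0.9) - apd90) > 0.05:
            raise InvalidParameterError(
                "APD pair not attainable by the logistic template"
            )
        return tpl

    @classmethod
    def from_apd80(
        cls,
        apd80: float,
        mdp: float = -70.0,
        apa: float = 100.0,
        upstroke_duration: float = 4.0,
        fall_fraction: float = 0.12,
    ) -> "APTemplate":
        """Template with a requested APD80 and fall width = fall_fraction*APD80."""
        if apd80 <= 0:
            raise InvalidParameterError("apd80 must be > 0")
        w = fall_fraction * apd80
        up = upstroke_duration

        def residual(m):
            if m[0] <= 0:
                return [1e6]
            t = cls(mdp=mdp, apa=apa, upstroke_duration=up,
                    plateau_midpoint=m[0], fall_width=w)
            return [t.apd(0.8) - apd80]

        m = float(fsolve(residual, [max(apd80 - 1.4 * w, 1.0)])[0])
        return cls(mdp=mdp, apa=apa, upstroke_duration=up,
                   plateau_midpoint=m, fall_width=w)


#: Parameter sets spanning the three iPSC-cardiomyocyte AP phenotypes, used
#: by the synthetic population generator.  Values are typical of published
#: patch-clamp means for each subtype.
SUBTYPE_TEMPLATES = {
    "atrial": dict(mdp=-63.9, apa=110.0, dvdt_max=27.1, apd90=294.6, apd_ratio=1.34),
    "ventricular": dict(mdp=-70.0, apa=115.0, dvdt_max=51.1, apd90=557.3, apd_ratio=1.10),
    "nodal": dict(mdp=-45.0, apa=85.0, dvdt_max=3.0, apd90=250.0, apd_ratio=1.30),
}


def subtype_template(label: str, **overrides) -> APTemplate:
    """Build the canonical template for one AP subtype (see SUBTYPE_TEMPLATES)."""
    if label not in SUBTYPE_TEMPLATES:
        raise InvalidParameterError(f"unknown subtype {label!r}")
    p = dict(SUBTYPE_TEMPLATES[label])
    p.update(overrides)
    apd90 = p["apd90"]
    apd50 = apd90 / p["apd_ratio"]
    return APTemplate.from_apds(
        apd50, apd90, mdp=p["mdp"], apa=p["apa"], dvdt_max=p["dvdt_max"]
    )


@dataclass(frozen=True)
class RestitutionModel:
    """Single-exponential APD and CV restitution.

    APD(DI) = apd_max * (1 - apd_amp * exp(-DI / tau_apd)) and likewise for
    CV; both are monotone non-decreasing in the diastolic interval DI.  A
    premature stimulus captures iff its DI >= capture_threshold_di, so the
    true ERP at steady state equals steady-state APD + capture_threshold_di.
    """

    apd_max: float = 250.0
    cv_max: float = 30.0
    apd_amp: float = 0.35
    cv_amp: float = 0.35
    tau_apd: float = 60.0
    tau_cv: float = 40.0
    capture_threshold_di: float = 40.0

    def apd(self, di):
        di = np.maximum(np.asarray(di, dtype=float), 0.0)
        return self.apd_max * (1.0 - self.apd_amp * np.exp(-di / self.tau_apd))

    def cv(self, di):
        di = np.maximum(np.asarray(di, dtype=float), 0.0)
        return self.cv_max * (1.0 - self.cv_amp * np.exp(-di / self.tau_cv))

    def captures(self, di) -> bool:
        return bool(di >= self.capture_threshold_di)

    def steady_state_apd(self, cycle_length: float, n_beats: int = 50) -> float:
        """APD fixed point under constant pacing at the given cycle length."""
        if cycle_length <= 0:
            raise InvalidParameterError("cycle length must be > 0")
        apd = self.apd_max * (1.0 - self.apd_amp)
        for _ in range(n_beats):
            di = max(cycle_length - apd, 0.0)
            apd = float(self.apd(di))
        return apd

    def true_erp(self, cycle_length: float) -> float:
        """Longest coupling interval that fails to capture at steady state."""
        return self.steady_state_apd(cycle_length) + self.capture_threshold_di
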