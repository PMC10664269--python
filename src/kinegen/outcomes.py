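"""Per-trial performance outcomes and per-participant aggregation.

The torque/power chain follows the study-design formulas literally, in
degrees:

    RT(t)  = segmental mass (kg) x angular acceleration (deg/s^2) / total body mass (kg)
    P(t)   = RT(t) x angular velocity (deg/s)
    RFD    = peak force (N) / time from force onset to that peak (s)
    RSI    = DJ height (m) / ground contact time (s)
    IReaF  = (DJ height - SJ height) / SJ height

No degree-to-radian conversion is applied and no newton-metre claim is made:
the quantities are relative, mass-normalised measures whose unit tension is
documented rather than silently "fixed".  Segmental masses come from an
editable fraction-of-body-mass table; the hip outcome uses the whole leg
extensor chain (thigh + shank + foot) and the knee outcome the shank + foot.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from .errors import DomainError, InputError, ParameterError
from .io_formats import ForcePlateSeries
from .kinematics import AngleSeries

#: Default segment-mass fractions of total body mass (adult female averages
#: from standard anthropometric tables); editable via AnthropometryConfig.
DEFAULT_SEGMENT_FRACTIONS = {
    "trunk": 0.4257,
    "thigh": 0.1478,
    "shank": 0.0481,
    "foot": 0.0129,
}


@dataclass
class AnthropometryConfig:
    """Segment-mass fraction table (fraction of total body mass, per side)."""

    fractions: dict = field(default_factory=lambda: dict(DEFAULT_SEGMENT_FRACTIONS))
    source: str = "adult female segment inertia table"

    def __post_init__(self) -> None:
        for seg, f in self.fractions.items():
            if not 0 < f < 1:
                raise ParameterError(f"segment fraction {seg}={f} must be in (0, 1)")

    def segment_mass(self, segment: str, total_mass_kg: float) -> float:
        if total_mass_kg <= 0:
            raise ParameterError("total body mass must be positive")
        if segment not in self.fractions:
            raise ParameterError(f"unknown segment {segment!r}")
        return self.fractions[segment] * total_mass_kg

    def chain_mass(self, joint: str, total_mass_kg: float) -> float:
        """Mass moved distal to a joint: hip -> thigh+shank+foot, knee -> shank+foot."""
        chains = {"hip": ("thigh", "shank", "foot"), "knee": ("shank", "foot")}
        if joint not in chains:
            raise ParameterError(f"unknown joint {joint!r}")
        return sum(self.segment_mass(s, total_mass_kg) for s in chains[joint])


def relative_torque(segment_mass_kg: float, angular: AngleSeries,
                    total_mass_kg: float,
                    phase: tuple[int, int] | None = None):
    """Relative torque series and its peak magnitude within a phase.

    Returns ``(rt_series, peak)`` where ``peak = max |RT|`` over the phase
    interval (whole series when ``phase`` is None).
    """
    if segment_mass_kg <= 0 or total_mass_kg <= 0:
        raise ParameterError("masses must be positive")
    rt = segment_mass_kg * angular.angular_acceleration / total_mass_kg
    return rt, _peak_abs(rt, phase)


def joint_power(rt_series: np.ndarray, angular_velocity: np.ndarray,
                phase: tuple[int, int] | None = None):
    """Pointwise power = RT x angular velocity; returns (series, peak |P|)."""
    rt_series = np.asarray(rt_series, dtype=float)
    angular_velocity = np.asarray(angular_velocity, dtype=float)
    if rt_series.shape != angular_velocity.shape:
        raise InputError("torque and angular velocity series must be aligned")
    p = rt_series * angular_velocity
    return p, _peak_abs(p, phase)


def _peak_abs(series: np.ndarray, phase: tuple[int, int] | None) -> float:
    if phase is not None:
        s, e = phase
        if e <= s:
            raise DomainError("empty phase interval")
        series = series[s:e]
    if series.size == 0:
        raise DomainError("empty phase interval")
    return float(np.max(np.abs(series)))


def rate_of_force_development(fp: ForcePlateSeries,
                              phase: tuple[int, int]) -> float:
    """RFD (N/s): peak vertical force in the interval over time-to-peak.

    Time runs from the interval start (force onset) to the peak sample; a
    peak at the very first sample leaves RFD undefined.
    """
    s, e = phase
    if e <= s:
        raise DomainError("empty phase interval")
    fz = fp.fz[s:e]
    i_peak = int(np.argmax(fz))
    if i_peak == 0:
        raise DomainError("peak force at interval start: RFD undefined (zero elapsed time)")
    return float(fz[i_peak]) / (i_peak / fp.frequency)


def reactive_indices(dj_height_m: float, sj_height_m: float,
                     contact_time_s: float) -> tuple[float, float]:
    """Reactive strength index and index of reactive force.

    RSI = DJ height / ground contact time;
    IReaF = (DJ height - SJ height) / SJ height.
    """
    if sj_height_m <= 0:
        raise DomainError("SJ height must be positive")
    if contact_time_s <= 0:
        raise DomainError("contact time must be positive")
    rsi = dj_height_m / contact_time_s
    ireaf = (dj_height_m - sj_height_m) / sj_height_m
    return rsi, ireaf


@dataclass
class OutcomeSet:
    """The per-trial / per-participant outcome bundle.

    Any field may be None when the trial type does not produce it; the
    reactive indices are only defined once both DJ and SJ heights exist.
    """

    participant_id: str = ""
    sj_height_m: float | None = None
    cmj_height_m: float | None = None
    dj_height_m: float | None = None
    dj_contact_time_s: float | None = None
    sprint_time_s: float | None = None
    cmj_hip_rt_peak: float | None = None
    cmj_knee_rt_peak: float | None = None
    dj_hip_rt_peak: float | None = None
    dj_knee_rt_peak: float | None = None
    cmj_hip_power_peak: float | None = None
    cmj_knee_power_peak: float | None = None
    dj_hip_power_peak: float | None = None
    dj_knee_power_peak: float | None = None
    cmj_rfd: float | None = None
    dj_rfd: float | None = None
    rsi: float | None = None
    ireaf: float | None = None
    aggregation: str = ""

    def finalize_reactive(self) -> None:
        """Fill RSI/IReaF from the stored heights and contact time."""
        if (self.dj_height_m is not None and self.sj_height_m is not None
                and self.dj_contact_time_s is not None):
            self.rsi, self.ireaf = reactive_indices(
                self.dj_height_m, self.sj_height_m, self.dj_contact_time_s)

    def check(self) -> None:
        """Internal consistency of stored reactive indices."""
        if (self.ireaf is not None and self.dj_height_m is not None
                and self.sj_height_m is not None):
            expect = (self.dj_height_m - self.sj_height_m) / self.sj_height_m
            if abs(self.ireaf - expect) > 1e-12:
                raise DomainError("stored IReaF inconsistent with stored heights")

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: fields where the best-of-trials value is the minimum, not the maximum
_BEST_IS_MIN = {"sprint_time_s", "dj_contact_time_s"}
_NON_NUMERIC = {"participant_id", "aggregation"}


def aggregate_trials(per_trial: Sequence[OutcomeSet], method: str = "mean") -> OutcomeSet:
    """Aggregate repeated trials into one OutcomeSet.

    ``mean`` averages each available field; ``best`` takes the maximum
    (minimum for sprint and contact times).  The reactive indices are
    recomputed from the aggregated heights/contact time so they stay
    internally consistent.
    """
    if not per_trial:
        raise InputError("aggregate_trials needs at least one trial")
    if method not in ("mean", "best"):
        raise ParameterError(f"unknown aggregation method {method!r}")
    out = OutcomeSet(participant_id=per_trial[0].participant_id, aggregation=method)
    for f in fields(OutcomeSet):
        if f.name in _NON_NUMERIC:
            continue
        vals = [getattr(t, f.name) for t in per_trial if getattr(t, f.name) is not None]
        if not vals:
            continue
        if method == "mean":
            agg = float(np.mean(vals))
        else:
            agg = float(min(vals) if f.name in _BEST_IS_MIN else max(vals))
        setattr(out, f.name, agg)
    out.finalize_reactive()
    return out
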