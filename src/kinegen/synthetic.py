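"""Physically consistent synthetic jump/sprint trials and genotype cohorts.

The jump simulator builds the sacrum/pelvis vertical trajectory from smooth
closed-form segments (quiet standing, cosine eccentric dip, a cubic
propulsion profile reaching the exact takeoff velocity ``sqrt(2 g h)`` with
the ground-reaction force fading to zero at takeoff, ballistic flight, a
smooth landing brake) and hangs a planar two-link leg chain
(shank + thigh, foot fixed during ground contact, hip directly above the
ankle) off it by inverse kinematics.  Left/right markers are mirrored with a
fixed pelvic half-width, so the eleven-marker set is complete.  The vertical
ground-reaction force is synthesised from the same trajectory,
``fz = m (g + z_com'')`` during contact and exactly zero in the air, which
makes impulse-momentum consistency hold by construction.

Squat jumps start from a held 90-degree squat with no eccentric phase; drop
jumps start standing on a box (default 20 cm), fall ballistically, and split
their ground contact into eccentric/concentric halves whose total duration
equals the configured contact time.

The cohort generator draws two-locus genotypes (ACTN3 R577X, ACE I/D) from
Hardy-Weinberg proportions and adds configurable additive/dominant genotype
shifts plus Gaussian noise to a chosen outcome, recording the realised truth
so association statistics can be checked against a known architecture.

Everything is seed-deterministic: same config + seed, bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io_formats import (
    ACE_GENOTYPES,
    ACTN3_GENOTYPES,
    ForcePlateSeries,
    MarkerTrajectories,
    TrialMeta,
)

G_DEFAULT = 9.81

# fixed marker-placement geometry (metres): heights above the support surface
# and horizontal offsets in the sagittal (x, forward) / frontal (y) planes
ANKLE_HEIGHT = 0.08
PELVIC_HALFWIDTH = 0.12
TOE_FORWARD = 0.15
TOE_HEIGHT = 0.03
ASIS_FORWARD = 0.10
ASIS_UP = 0.06
SACRUM_BACK = -0.10
SACRUM_UP = 0.03
MIN_KNEE_ANGLE_DEG = 45.0


@dataclass
class JumpSimConfig:
    """Parameters of one simulated ballistic jump trial."""

    jump_type: str = "CMJ"
    target_flight_height: float = 0.25
    countermovement_depth: float = 0.20
    contact_time: float = 0.20          # DJ ground contact (s)
    box_height: float = 0.20            # DJ drop box (m)
    trunk_length: float = 0.55
    thigh_length: float = 0.40
    shank_length: float = 0.40
    foot_length: float = 0.24
    body_mass: float = 55.0
    frequency: float = 200.0            # camera rate (Hz)
    force_frequency: float = 1000.0     # force-plate rate (Hz)
    noise_sd: float = 0.0               # isotropic marker jitter (m)
    seed: int = 0
    quiet_duration: float = 0.5
    eccentric_duration: float = 0.40
    landing_duration: float = 0.30
    settle_duration: float = 0.30
    standing_knee_angle_deg: float = 175.0
    g: float = G_DEFAULT

    def validate(self) -> None:
        if self.jump_type not in ("SJ", "CMJ", "DJ"):
            raise ConfigError(f"unknown jump_type {self.jump_type!r}")
        for name in ("target_flight_height", "trunk_length", "thigh_length",
                     "shank_length", "foot_length", "body_mass", "frequency",
                     "force_frequency", "quiet_duration", "eccentric_duration",
                     "landing_duration", "g"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.jump_type == "DJ":
            if not self.contact_time > 0:
                raise ConfigError("DJ contact_time must be positive")
            if not self.box_height > 0:
                raise ConfigError("DJ box_height must be positive")
        if self.box_height < 0:
            raise ConfigError("box_height must be non-negative")


@dataclass
class SprintSimConfig:
    """Constant-acceleration 5-m sprint between two virtual timing planes."""

    v0: float = 0.0                    # initial forward velocity (m/s)
    acceleration: float = 2.0          # constant forward acceleration (m/s^2)
    start_x: float = 0.0
    gates: tuple[float, float] = (0.0, 5.0)
    duration: float | None = None      # None: auto, 0.3 s past gate B
    frequency: float = 200.0
    noise_sd: float = 0.0
    bob_amplitude: float = 0.02        # vertical pelvis oscillation (m)
    bob_frequency: float = 2.5         # stride-linked bobbing (Hz)
    body_mass: float = 55.0
    thigh_length: float = 0.40
    shank_length: float = 0.40
    seed: int = 0
    standing_knee_angle_deg: float = 175.0
    g: float = G_DEFAULT

    def validate(self) -> None:
        if self.frequency <= 0:
            raise ConfigError("frequency must be positive")
        if self.v0 < 0 or (self.v0 == 0 and self.acceleration <= 0):
            raise ConfigError("sprint must move forward: v0 >= 0 and some speed/acceleration")
        if self.noise_sd < 0 or self.bob_amplitude < 0:
            raise ConfigError("noise_sd and bob_amplitude must be non-negative")


@dataclass
class SimGroundTruth:
    """Exact labels for one simulated trial."""

    phase_times: dict[str, tuple[float, float]]
    flight_height: float | None = None
    v_takeoff: float | None = None
    v_peak: float | None = None          # peak upward COM velocity (>= v_takeoff)
    contact_time: float | None = None
    knee_angle: np.ndarray | None = None
    hip_angle: np.ndarray | None = None
    sacrum_z: np.ndarray | None = None
    gate_times: tuple[float, float] | None = None
    gate_positions: tuple[float, float] | None = None
    frequency: float = 200.0
    g: float = G_DEFAULT

    def phase_frames(self, label: str) -> tuple[int, int]:
        """Phase boundaries as nearest frame indices."""
        t0, t1 = self.phase_times[label]
        return int(round(t0 * self.frequency)), int(round(t1 * self.frequency))


# ---------------------------------------------------------------------------
# trajectory segments: (duration, z(t), zddot(t), supported_on)
# supported_on: "plate", "box" or None (airborne)

Segment = tuple[float, Callable, Callable, "str | None"]


def _seg_quiet(z0: float, T: float, support: str | None) -> Segment:
    return (T, lambda t: np.full_like(t, z0), lambda t: np.zeros_like(t), support)


def _seg_cos_descent(z0: float, depth: float, T: float) -> Segment:
    w = math.pi / T
    return (
        T,
        lambda t: z0 - depth * (1 - np.cos(w * t)) / 2,
        lambda t: -depth * w**2 * np.cos(w * t) / 2,
        "plate",
    )


def _rise_coeffs(dz: float, v_end: float, T: float, g: float):
    beta = -g * T / v_end
    delta = dz / (v_end * T)
    a = beta - 6 + 12 * delta
    b = -3 * beta + 15 - 24 * delta
    c = 2 * beta - 8 + 12 * delta
    return a, b, c


def _rise_peak_velocity(dz: float, v_end: float, T: float, g: float) -> float:
    """Peak velocity of the propulsion profile (slightly above v_end)."""
    a, b, c = _rise_coeffs(dz, v_end, T, g)
    r_at = lambda tau: a * tau + b * tau**2 + c * tau**3  # noqa: E731
    peak = 1.0
    disc = b**2 - 3 * a * c
    if abs(c) > 1e-12 and disc >= 0:
        for tau in ((-b + math.sqrt(disc)) / (3 * c), (-b - math.sqrt(disc)) / (3 * c)):
            if 0 < tau < 1:
                peak = max(peak, r_at(tau))
    return v_end * peak


def _seg_cubic_rise(z_end: float, dz: float, v_end: float, T: float, g: float) -> Segment:
    """Propulsion: rise ``dz`` over ``T``, ending at velocity ``v_end`` with
    acceleration exactly -g, so the ground-reaction force fades smoothly to
    zero at takeoff (velocity peaks just above v_end shortly before, as real
    force traces do).  Cubic velocity shape r(tau) with r(0)=0, r(1)=1,
    r'(1) = -gT/v_end and integral dz/(v_end T)."""
    a, b, c = _rise_coeffs(dz, v_end, T, g)
    if a <= 0:
        raise ConfigError(
            "countermovement too deep relative to the target flight height "
            "for a force-consistent propulsion profile"
        )

    def zf(t):
        tau = t / T
        R = a * tau**2 / 2 + b * tau**3 / 3 + c * tau**4 / 4
        return (z_end - dz) + v_end * T * R

    def af(t):
        tau = t / T
        return v_end * (a + 2 * b * tau + 3 * c * tau**2) / T

    return (T, zf, af, "plate")


def _seg_ballistic(z0: float, v0: float, T: float, g: float) -> Segment:
    return (
        T,
        lambda t: z0 + v0 * t - g * t**2 / 2,
        lambda t: np.full_like(t, -g),
        None,
    )


def _seg_cubic_brake(z0: float, v0: float, T: float, g: float) -> tuple[Segment, float]:
    """Landing: decelerate from ``v0`` (negative) to rest over ``T`` with the
    ground-reaction force growing smoothly from zero at touchdown
    (acceleration starts at exactly -g).  Returns (segment, final height)."""
    a = g * T / v0          # negative
    b = 3 - 2 * a
    c = a - 2

    def S(tau):
        return a * tau**2 / 2 + b * tau**3 / 3 + c * tau**4 / 4

    def zf(t):
        tau = t / T
        return z0 + v0 * T * (tau - S(tau))

    def af(t):
        tau = t / T
        return -v0 * (a + 2 * b * tau + 3 * c * tau**2) / T

    z_end = z0 + v0 * T * (1 - (0.5 + a / 12))
    return (T, zf, af, "plate"), z_end


def _eval_segments(segs: list[Segment], total_T: float, freq: float):
    """Evaluate a piecewise trajectory on a uniform grid.

    Returns (z, zddot, support) arrays; ``support`` is an object array of
    "plate" / "box" / None per sample.
    """
    n = int(math.floor(total_T * freq)) + 1
    tt = np.arange(n) / freq
    z = np.empty(n)
    acc = np.empty(n)
    support = np.empty(n, dtype=object)
    t0 = 0.0
    for T, zf, af, sup in segs:
        sel = (tt >= t0 - 1e-12) & (tt < t0 + T - 1e-12)
        tl = tt[sel] - t0
        z[sel] = zf(tl)
        acc[sel] = af(tl)
        support[sel] = sup
        t0 += T
    tail = tt >= t0 - 1e-12
    if tail.any():                            # trailing grid points
        T, zf, af, sup = segs[-1]
        z[tail] = zf(np.full(int(tail.sum()), T))
        acc[tail] = af(np.full(int(tail.sum()), T))
        support[tail] = sup
    return z, acc, support


# ---------------------------------------------------------------------------
# planar two-link leg pose


def _leg_span(knee_angle_deg: float, ls: float, lt: float) -> float:
    th = math.radians(knee_angle_deg)
    return math.sqrt(ls**2 + lt**2 - 2 * ls * lt * math.cos(th))


def _knee_pose(span: np.ndarray, ls: float, lt: float):
    """Knee inner angle (deg) and knee position (x fwd, z up) rel. ankle."""
    span = np.clip(span, abs(lt - ls) + 1e-12, ls + lt - 1e-12)
    cos_th = (ls**2 + lt**2 - span**2) / (2 * ls * lt)
    knee_deg = np.degrees(np.arccos(np.clip(cos_th, -1.0, 1.0)))
    cos_b = (ls**2 + span**2 - lt**2) / (2 * ls * span)
    beta = np.arccos(np.clip(cos_b, -1.0, 1.0))
    return knee_deg, ls * np.sin(beta), ls * np.cos(beta)


def _hip_angle_deg(knee_x: np.ndarray, knee_z: np.ndarray, span: np.ndarray) -> np.ndarray:
    """Inner angle at the trochanter between ASIS and condyle directions."""
    to_e = np.array([ASIS_FORWARD, ASIS_UP])
    cx, cz = knee_x, knee_z - span
    dot = to_e[0] * cx + to_e[1] * cz
    nn = np.hypot(cx, cz) * np.hypot(*to_e)
    return np.degrees(np.arccos(np.clip(dot / nn, -1.0, 1.0)))


def _marker_frame(hip_z, support_z, knee_x, knee_z, foot_x_offset=0.0):
    """Assemble the eleven-marker positions for vectors of frames.

    All inputs are arrays over frames; returns dict marker -> (n, 3).
    ``support_z`` is the surface the foot rests on (follows the body when
    airborne so that the chain translates rigidly).
    """
    n = len(hip_z)
    w = PELVIC_HALFWIDTH

    def bil(stem, x, z):
        return {
            f"{stem}_L": np.column_stack([x + foot_x_offset, np.full(n, -w), z]),
            f"{stem}_R": np.column_stack([x + foot_x_offset, np.full(n, +w), z]),
        }

    zeros = np.zeros(n)
    out: dict[str, np.ndarray] = {}
    out.update(bil("A5thMet", zeros + TOE_FORWARD, support_z + TOE_HEIGHT))
    out.update(bil("Bmalleolus", zeros, support_z + ANKLE_HEIGHT))
    out.update(bil("Ccondyle", knee_x, support_z + ANKLE_HEIGHT + knee_z))
    out.update(bil("Dtrochanter", zeros, hip_z))
    out.update(bil("E_ASIS", zeros + ASIS_FORWARD, hip_z + ASIS_UP))
    out["F_sacrum"] = np.column_stack(
        [np.full(n, SACRUM_BACK) + foot_x_offset, np.zeros(n), hip_z + SACRUM_UP]
    )
    return out


def _assemble(marker_map: dict[str, np.ndarray], cfg, rng) -> MarkerTrajectories:
    ids = list(marker_map)
    pos = np.stack([marker_map[m] for m in ids])
    if cfg.noise_sd > 0:
        pos = pos + rng.normal(0.0, cfg.noise_sd, size=pos.shape)
    meta = TrialMeta(trial_type=getattr(cfg, "jump_type", "SPRINT"))
    return MarkerTrajectories(ids, pos, cfg.frequency, meta)


# ---------------------------------------------------------------------------
# jump trials


def simulate_jump_trial(config: JumpSimConfig):
    """Simulate one SJ/CMJ/DJ trial.

    Returns ``(MarkerTrajectories, ForcePlateSeries, SimGroundTruth)``.
    """
    cfg = config
    cfg.validate()
    g = cfg.g
    ls, lt = cfg.shank_length, cfg.thigh_length
    span_stand = _leg_span(cfg.standing_knee_angle_deg, ls, lt)
    span_min = _leg_span(MIN_KNEE_ANGLE_DEG, ls, lt)
    z0 = ANKLE_HEIGHT + span_stand           # standing hip height
    v_to = math.sqrt(2 * g * cfg.target_flight_height)
    t_flight = 2 * v_to / g

    phases: dict[str, tuple[float, float]] = {}
    segs: list[Segment] = []
    t = 0.0

    def add(label: str | None, seg: Segment):
        nonlocal t
        segs.append(seg)
        if label is not None:
            phases[label] = (t, t + seg[0])
        t += seg[0]

    def add_landing_and_settle():
        # shrink the landing if the dip would fold the legs past the
        # geometric minimum; the exact decay shape is not an outcome
        nonlocal t
        t_l2 = t
        T_land = cfg.landing_duration
        dip_max = max(z0 - (ANKLE_HEIGHT + span_min) - 0.01, 0.02)
        seg, z_end = _seg_cubic_brake(z0, -v_to, T_land, g)
        if z0 - z_end > dip_max:
            T_land *= dip_max / (z0 - z_end)
            seg, z_end = _seg_cubic_brake(z0, -v_to, T_land, g)
        add(None, seg)
        add(None, _seg_quiet(z_end, cfg.settle_duration, "plate"))
        phases["L2"] = (t_l2, t)

    contact_time = None
    if cfg.jump_type == "CMJ":
        d = cfg.countermovement_depth
        if z0 - d < ANKLE_HEIGHT + span_min:
            raise ConfigError(
                f"countermovement_depth {d} m drives the pelvis below the "
                f"two-link geometric minimum for these segment lengths"
            )
        if d * (math.pi / cfg.eccentric_duration) ** 2 / 2 > g:
            raise ConfigError(
                f"eccentric descent of {d} m in {cfg.eccentric_duration} s "
                f"would need a negative ground-reaction force (free fall is "
                f"the fastest possible unweighted descent)"
            )
        T_con = math.pi * d / (2 * v_to)
        v_peak = _rise_peak_velocity(d, v_to, T_con, g)
        add("L1", _seg_quiet(z0, cfg.quiet_duration, "plate"))
        add("E", _seg_cos_descent(z0, d, cfg.eccentric_duration))
        add("C", _seg_cubic_rise(z0, d, v_to, T_con, g))
        add("F2", _seg_ballistic(z0, v_to, t_flight, g))
        add_landing_and_settle()
    elif cfg.jump_type == "SJ":
        z_squat = ANKLE_HEIGHT + _leg_span(90.0, ls, lt)
        dz = z0 - z_squat
        if dz <= 0:
            raise ConfigError("standing pose must sit above the 90-degree squat")
        T_con = math.pi * dz / (2 * v_to)
        v_peak = _rise_peak_velocity(dz, v_to, T_con, g)
        add(None, _seg_quiet(z_squat, cfg.quiet_duration, "plate"))  # held squat
        add("C", _seg_cubic_rise(z0, dz, v_to, T_con, g))
        add("F2", _seg_ballistic(z0, v_to, t_flight, g))
        add_landing_and_settle()
    else:  # DJ
        v_td = math.sqrt(2 * g * cfg.box_height)
        t_fall = v_td / g

        # split the configured contact time into an eccentric brake (force
        # rising smoothly from zero at touchdown) and the propulsion rise;
        # both durations are tied to the dip depth d, which is solved so the
        # total equals the configured contact time
        def t_ecc_of(d: float) -> float:
            return (-v_td / 2 + math.sqrt(v_td**2 / 4 + g * d / 3)) * 6 / g

        def contact_of(d: float) -> float:
            return t_ecc_of(d) + math.pi * d / (2 * v_to)

        d_max = z0 - (ANKLE_HEIGHT + span_min)
        if contact_of(d_max) < cfg.contact_time:
            raise ConfigError(
                f"contact_time {cfg.contact_time} s implies a dip below the "
                f"two-link geometric minimum for these segment lengths"
            )
        from scipy.optimize import brentq
        d = float(brentq(lambda x: contact_of(x) - cfg.contact_time, 1e-6, d_max))
        t_ecc = t_ecc_of(d)
        T_con = math.pi * d / (2 * v_to)
        v_peak = _rise_peak_velocity(d, v_to, T_con, g)
        add("D", _seg_quiet(z0 + cfg.box_height, cfg.quiet_duration, "box"))
        add("F1", _seg_ballistic(z0 + cfg.box_height, 0.0, t_fall, g))
        phases["L1"] = (t, t)                 # touchdown boundary
        ecc_seg, _ = _seg_cubic_brake(z0, -v_td, t_ecc, g)
        add("E", ecc_seg)
        add("C", _seg_cubic_rise(z0, d, v_to, T_con, g))
        add("F2", _seg_ballistic(z0, v_to, t_flight, g))
        add_landing_and_settle()
        contact_time = cfg.contact_time

    # evaluate the piecewise trajectory on the camera grid and the force on
    # the (typically faster) plate grid
    total_T = t
    hip_z, acc, support = _eval_segments(segs, total_T, cfg.frequency)
    _, acc_f, support_f = _eval_segments(segs, total_T, cfg.force_frequency)
    n = len(hip_z)

    on_box = support == "box"
    airborne = np.array([s is None for s in support])

    fz = np.zeros(len(acc_f))
    plate_f = support_f == "plate"
    fz[plate_f] = cfg.body_mass * (g + acc_f[plate_f])

    # leg pose: supported frames by IK, airborne frames frozen at the
    # extended standing pose and translated rigidly with the pelvis
    support_z = np.zeros(n)
    support_z[on_box] = cfg.box_height
    span = np.where(~airborne, hip_z - support_z - ANKLE_HEIGHT, span_stand)
    knee_deg, knee_x, knee_z = _knee_pose(span, ls, lt)
    # airborne: surface "follows" so the chain translates rigidly
    support_z[airborne] = hip_z[airborne] - ANKLE_HEIGHT - span_stand
    span_eff = np.where(airborne, span_stand, span)
    hip_deg = _hip_angle_deg(knee_x, knee_z, span_eff)

    marker_map = _marker_frame(hip_z, support_z, knee_x, knee_z)
    rng = np.random.default_rng(cfg.seed)
    markers = _assemble(marker_map, cfg, rng)
    fp = ForcePlateSeries(fz=fz, frequency=cfg.force_frequency)
    truth = SimGroundTruth(
        phase_times=phases,
        flight_height=v_to**2 / (2 * g),
        v_takeoff=v_to,
        v_peak=v_peak,
        contact_time=contact_time,
        knee_angle=knee_deg,
        hip_angle=hip_deg,
        sacrum_z=hip_z + SACRUM_UP,
        frequency=cfg.frequency,
        g=g,
    )
    return markers, fp, truth


def simulate_quiet_standing(body_mass: float = 55.0, duration: float = 2.0,
                            frequency: float = 200.0, noise_sd: float = 0.0,
                            seed: int = 0, g: float = G_DEFAULT):
    """A standing trial: constant pose, fz = m g throughout."""
    cfg = JumpSimConfig(jump_type="CMJ", body_mass=body_mass, frequency=frequency,
                        noise_sd=noise_sd, seed=seed, g=g)
    span = _leg_span(cfg.standing_knee_angle_deg, cfg.shank_length, cfg.thigh_length)
    z0 = ANKLE_HEIGHT + span
    n = int(math.floor(duration * frequency)) + 1
    hip_z = np.full(n, z0)
    knee_deg, knee_x, knee_z = _knee_pose(np.full(n, span), cfg.shank_length, cfg.thigh_length)
    marker_map = _marker_frame(hip_z, np.zeros(n), knee_x, knee_z)
    rng = np.random.default_rng(seed)
    markers = _assemble(marker_map, cfg, rng)
    fp = ForcePlateSeries(fz=np.full(n, body_mass * g), frequency=frequency)
    return markers, fp


# ---------------------------------------------------------------------------
# sprint trials


def _gate_crossing_time(x0: float, v0: float, a: float, gate: float) -> float:
    dx = gate - x0
    if dx <= 0:
        return 0.0
    if a == 0:
        return dx / v0
    disc = v0**2 + 2 * a * dx
    return (-v0 + math.sqrt(disc)) / a


def simulate_sprint_trial(config: SprintSimConfig):
    """Simulate a straight-line sprint; returns (MarkerTrajectories, SimGroundTruth).

    The sacrum marker — the point the virtual timing gates watch — moves
    forward with constant acceleration from ``start_x``; vertical bobbing
    emulates stride oscillation.  Ground truth records the exact times the
    sacrum crosses each gate plane.
    """
    cfg = config
    cfg.validate()
    xa, xb = cfg.gates
    t_a = _gate_crossing_time(cfg.start_x, cfg.v0, cfg.acceleration, xa)
    t_b = _gate_crossing_time(cfg.start_x, cfg.v0, cfg.acceleration, xb)
    duration = cfg.duration if cfg.duration is not None else max(t_a, t_b) + 0.3
    n = int(math.floor(duration * cfg.frequency)) + 1
    tt = np.arange(n) / cfg.frequency
    x = cfg.start_x + cfg.v0 * tt + cfg.acceleration * tt**2 / 2
    if x[-1] < max(xa, xb):
        raise ConfigError(
            f"sprint trial of {duration:.2f} s too short to reach x = {max(xa, xb)} m"
        )

    span = _leg_span(cfg.standing_knee_angle_deg, cfg.shank_length, cfg.thigh_length)
    bob = cfg.bob_amplitude * np.sin(2 * math.pi * cfg.bob_frequency * tt)
    hip_z = ANKLE_HEIGHT + span + bob
    knee_deg, knee_x, knee_z = _knee_pose(np.full(n, span), cfg.shank_length, cfg.thigh_length)
    marker_map = _marker_frame(hip_z, bob, knee_x, knee_z)
    # translate the chain so the sacrum marker itself follows x(t)
    for m in marker_map:
        marker_map[m][:, 0] += x - SACRUM_BACK
    rng = np.random.default_rng(cfg.seed)
    markers = _assemble(marker_map, cfg, rng)
    truth = SimGroundTruth(
        phase_times={},
        gate_times=(t_a, t_b),
        gate_positions=(xa, xb),
        sacrum_z=hip_z + SACRUM_UP,
        frequency=cfg.frequency,
        g=cfg.g,
    )
    return markers, truth


# ---------------------------------------------------------------------------
# genotype cohorts


_CODES = {
    "additive": (0.0, 0.5, 1.0),
    "I_dominant": (0.0, 0.0, 1.0),
    "D_dominant": (0.0, 1.0, 1.0),
}


@dataclass
class CohortSimConfig:
    """A cohort with Hardy-Weinberg genotypes and a known outcome architecture.

    ``allele_freq`` gives the frequency of the "effect" allele at each locus
    (X for ACTN3, D for ACE).  The genotype shift on the target outcome is
    ``effect_size * code(genotype)`` under the chosen model, or is derived
    from ``cohens_f`` (between-group sd over within-group sd at the
    Hardy-Weinberg genotype weights) when that is given instead.
    """

    n: int = 283
    allele_freq: dict = field(default_factory=lambda: {"actn3": 0.5, "ace": 0.5})
    model: str = "additive"
    target_locus: str = "ace"
    effect_size: float = 0.0            # outcome units, homozygote difference
    cohens_f: float | None = None
    outcome_name: str = "torque_peak"
    baseline_mean: float = 10.0
    outcome_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ConfigError("cohort needs n >= 2")
        for locus, q in self.allele_freq.items():
            if not 0 < q < 1:
                raise ConfigError(f"allele frequency for {locus} must be in (0, 1)")
        if self.outcome_sd <= 0:
            raise ConfigError("outcome_sd must be positive")
        if self.model not in _CODES:
            raise ConfigError(f"unknown genetic model {self.model!r}")
        if self.target_locus not in self.allele_freq:
            raise ConfigError(f"target_locus {self.target_locus!r} has no allele frequency")


def _genotype_labels(locus: str) -> tuple[str, str, str]:
    """(effect-allele-free homozygote, het, effect homozygote)."""
    return ("RR", "RX", "XX") if locus == "actn3" else ("II", "ID", "DD")


def simulate_cohort(config: CohortSimConfig):
    """Draw genotypes from HWE and an outcome with known genotype shifts.

    Returns ``(genotype_table, outcome_table, truth)`` where the genotype
    table matches :func:`kinegen.io_formats.read_genotype_table`'s schema and
    ``truth`` records the realised allele frequencies and applied shifts.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n

    geno: dict[str, np.ndarray] = {}
    realized: dict[str, float] = {}
    for locus in ("actn3", "ace"):
        q = cfg.allele_freq.get(locus, 0.5)
        labels = _genotype_labels(locus)
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        idx = rng.choice(3, size=n, p=probs)
        geno[locus] = np.array(labels)[idx]
        # realised effect-allele frequency = (het + 2*hom) / 2n
        realized[locus] = float(((idx == 1).sum() + 2 * (idx == 2).sum()) / (2 * n))

    code_vals = np.array(_CODES[cfg.model])
    labels = _genotype_labels(cfg.target_locus)
    lab_to_code = dict(zip(labels, code_vals))
    codes = np.array([lab_to_code[gl] for gl in geno[cfg.target_locus]])

    effect = cfg.effect_size
    if cfg.cohens_f is not None:
        q = cfg.allele_freq[cfg.target_locus]
        w = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
        var_code = float(w @ code_vals**2 - (w @ code_vals) ** 2)
        effect = cfg.cohens_f * cfg.outcome_sd / math.sqrt(var_code) if var_code > 0 else 0.0

    outcome = cfg.baseline_mean + effect * codes + rng.normal(0.0, cfg.outcome_sd, size=n)

    ids = [f"P{i + 1:04d}" for i in range(n)]
    height = rng.normal(1.58, 0.05, size=n)
    bmi = rng.normal(23.0, 2.0, size=n)
    genotype_table = pd.DataFrame({
        "id": ids,
        "actn3": geno["actn3"],
        "ace": geno["ace"],
        "sex": "F",
        "age": np.round(rng.uniform(18, 45, size=n), 1),
        "height_m": np.round(height, 3),
        "body_mass_kg": np.round(bmi * height**2, 2),
        "parq_positive": False,
        "power_sport": False,
    })
    outcome_table = pd.DataFrame({"id": ids, cfg.outcome_name: outcome})
    truth = {
        "model": cfg.model,
        "target_locus": cfg.target_locus,
        "effect_size": effect,
        "shifts": {lab: effect * lab_to_code[lab] for lab in labels},
        "realized_allele_freq": realized,
        "baseline_mean": cfg.baseline_mean,
        "outcome_sd": cfg.outcome_sd,
        "seed": cfg.seed,
    }
    return genotype_table, outcome_table, truth
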