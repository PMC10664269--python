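"""Trial segmentation into movement phases and the timing outcomes.

Phase labels follow the jump taxonomy: D (on-box standing, drop jumps only),
F1 (box-to-ground fall), L1 (quiet standing for CMJ; the touchdown boundary
for DJ), E (eccentric descent), C (concentric propulsion), F2 (ballistic
flight), L2 (landing).  Intervals are half-open frame ranges ``[start, end)``
and must be ordered D < F1 < L1 < E < C < F2 < L2.

Flight is read off the force plate: a maximal run of ``fz`` below a small
threshold (default 10 N) lasting at least 50 ms, with takeoff/landing times
linearly interpolated at the threshold crossings — robust to landing ringing.
Movement onset (SJ/CMJ) uses the conventional body-weight-deviation rule on
the force trace; the drop-jump step-off and the eccentric/concentric split
come from the composite pelvis vertical velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError, ParameterError, SegmentationError
from .io_formats import ForcePlateSeries, MarkerTrajectories
from .kinematics import LinearSeries, central_difference, smooth_lowpass

PHASE_ORDER = ("D", "F1", "L1", "E", "C", "F2", "L2")

FLIGHT_THRESHOLD_N = 10.0
MIN_FLIGHT_S = 0.050


@dataclass
class PhaseSegmentation:
    """Frame-index phase map for one trial, plus timing scalars."""

    phases: dict[str, tuple[int, int]]
    frequency: float
    flight_time: float | None = None      # F2 duration (s, sub-frame)
    contact_time: float | None = None     # DJ touchdown-to-takeoff (s)
    takeoff_time: float | None = None     # F2 start (s, sub-frame)
    landing_time: float | None = None     # F2 end (s, sub-frame)
    jump_type: str = ""

    def __post_init__(self) -> None:
        order = [p for p in PHASE_ORDER if p in self.phases]
        for a, b in zip(order, order[1:]):
            if self.phases[a][1] > self.phases[b][0]:
                raise SegmentationError(
                    f"phases {a} and {b} overlap or are out of order: "
                    f"{self.phases[a]} vs {self.phases[b]}"
                )
        for p, (s, e) in self.phases.items():
            if s > e:
                raise SegmentationError(f"phase {p} has negative extent {s}..{e}")

    def duration(self, label: str) -> float:
        s, e = self.phases[label]
        return (e - s) / self.frequency


def detect_contact_flight(fp: ForcePlateSeries,
                          threshold_n: float = FLIGHT_THRESHOLD_N,
                          min_flight_s: float = MIN_FLIGHT_S):
    """Maximal sub-threshold (airborne) runs of fz.

    Returns a list of ``(takeoff_time, landing_time)`` tuples in seconds.
    Crossing times are linearly interpolated at the threshold; a run touching
    the start (or end) of the record begins (ends) at the record boundary —
    e.g. a drop jump starts in the air as far as the plate is concerned.
    Runs shorter than ``min_flight_s`` are treated as ringing and discarded.
    """
    fz = np.asarray(fp.fz, dtype=float)
    if fz.size == 0:
        raise InputError("force series is empty")
    below = fz < threshold_n
    if not below.any():
        return []
    edges = np.flatnonzero(np.diff(np.r_[0, below.view(np.int8), 0]))
    runs = edges.reshape(-1, 2)  # [start, end) sample indices
    out = []
    dt = 1.0 / fp.frequency
    for s, e in runs:
        if s > 0:
            f0, f1 = fz[s - 1], fz[s]
            t_off = (s - 1 + (f0 - threshold_n) / (f0 - f1)) * dt
        else:
            t_off = 0.0
        if e < len(fz):
            f0, f1 = fz[e - 1], fz[e]
            t_on = (e - 1 + (threshold_n - f0) / (f1 - f0)) * dt
        else:
            t_on = (len(fz) - 1) * dt
        if t_on - t_off >= min_flight_s:
            out.append((t_off, t_on))
    return out


#: markers rigidly attached to the pelvis; averaging them (after removing
#: their constant offsets) suppresses marker jitter without changing the
#: pelvis trajectory shape
PELVIS_MARKERS = ("F_sacrum", "Dtrochanter_L", "Dtrochanter_R",
                  "E_ASIS_L", "E_ASIS_R")

ONSET_CUTOFF_HZ = 6.0


def _pelvis_vertical(markers: MarkerTrajectories) -> np.ndarray:
    """Mean-centred composite vertical pelvis trajectory (rigid-body average)."""
    zs = []
    for mid in PELVIS_MARKERS:
        if mid in markers.marker_ids:
            z = markers.get(mid)[:, 2]
            if not np.isnan(z).any():
                zs.append(z - z.mean())
    if not zs:
        raise InputError("no gap-free pelvis marker available for segmentation")
    return np.mean(zs, axis=0)


def _movement_onset(vel: np.ndarray, search_end: int, direction: int,
                    frequency: float, min_peak: float = 0.3,
                    band: tuple[float, float] = (0.2, 0.6)) -> float:
    """Movement onset time (s) before sustained motion in ``direction`` (+/-1).

    The velocity ramp between ``band`` fractions of its peak (a high
    signal-to-noise stretch) is fit with a line whose zero-crossing is taken
    as the onset — more noise-robust than thresholding near zero.
    """
    seg = direction * vel[:search_end]
    if seg.size == 0 or seg.max() <= min_peak:
        raise SegmentationError("no movement onset found")
    peak = int(np.argmax(seg))
    lo, hi = band[0] * seg[peak], band[1] * seg[peak]
    below = np.flatnonzero(seg[: peak + 1] < lo)
    i_lo = int(below[-1]) if below.size else 0
    ks = np.array(sorted({i for i in range(i_lo, peak + 1) if seg[i] <= hi}))
    if len(ks) < 2:
        ks = np.array([max(i_lo - 1, 0), i_lo])
    slope, intercept = np.polyfit(ks / frequency, seg[ks], 1)
    if slope <= 1e-9:
        return i_lo / frequency
    return max(0.0, -intercept / slope)


def _force_onset(fp: ForcePlateSeries, t_end: float,
                 quiet_window_s: float = 0.3, k_sigma: float = 5.0,
                 min_dev_n: float = 10.0, sustain_s: float = 0.010) -> float:
    """Movement onset (s) from the force trace: first sustained deviation of
    fz from quiet-standing body weight exceeding max(k_sigma * quiet SD,
    ``min_dev_n``) — the conventional body-weight-deviation rule for jump
    onsets, far less noise-limited than marker velocity thresholds.
    """
    nq = max(2, int(quiet_window_s * fp.frequency))
    if nq >= len(fp.fz):
        raise SegmentationError("force record too short for onset detection")
    bw = float(np.mean(fp.fz[:nq]))
    thr = max(k_sigma * float(np.std(fp.fz[:nq])), min_dev_n)
    dev = np.abs(fp.fz - bw) > thr
    i_end = min(len(fp.fz), int(t_end * fp.frequency))
    run = max(1, int(sustain_s * fp.frequency))
    idx = None
    count = 0
    for i in range(nq, i_end):
        count = count + 1 if dev[i] else 0
        if count >= run:
            idx = i - run + 1
            break
    if idx is None:
        raise SegmentationError("no movement onset found in force trace")
    return idx / fp.frequency


def _ecc_con_split(vel: np.ndarray, i_start: int, i_end: int,
                   frequency: float, band: tuple[float, float] = (0.2, 0.6)) -> int:
    """Eccentric/concentric boundary frame within a contact interval.

    The boundary is where vertical velocity crosses zero on its way up; a
    line fit to the concentric rise between ``band`` fractions of its peak,
    extrapolated back to zero, locates it far more precisely than the
    minimum of the (locally flat) height curve.
    """
    seg = vel[i_start:i_end]
    if seg.size == 0:
        return i_start
    i_up = int(np.argmax(seg))
    vp = seg[i_up]
    if vp <= 0:
        return i_start + int(np.argmin(np.abs(seg)))
    lo, hi = band[0] * vp, band[1] * vp
    below = np.flatnonzero(seg[:i_up + 1] < lo)
    i_lo = int(below[-1]) if below.size else 0
    ks = np.array(sorted({i for i in range(i_lo, i_up + 1) if seg[i] <= hi}))
    if len(ks) < 2:
        ks = np.array([max(i_lo - 1, 0), i_lo])
    slope, intercept = np.polyfit(ks / frequency, seg[ks], 1)
    if slope <= 1e-9:
        return i_start + i_lo
    return i_start + int(round(-intercept / slope * frequency))


def segment_jump_phases(markers: MarkerTrajectories, fp: ForcePlateSeries,
                        jump_type: str,
                        flight_threshold_n: float = FLIGHT_THRESHOLD_N,
                        cutoff_hz: float | None = 12.0) -> PhaseSegmentation:
    """Segment a jump trial into its phases.

    The force plate provides takeoff/touchdown and the SJ/CMJ movement
    onset; the pelvis marker trajectory provides the box step-off (DJ) and
    the eccentric/concentric split of ground contact.
    """
    if jump_type not in ("SJ", "CMJ", "DJ"):
        raise SegmentationError(f"unknown jump type {jump_type!r}")
    fs = markers.frequency
    z = _pelvis_vertical(markers)
    # heavier smoothing for the onset search (tiny velocities), moderate for
    # the eccentric/concentric zero-crossing
    v_onset = central_difference(smooth_lowpass(z, fs, ONSET_CUTOFF_HZ), fs)
    v_split = central_difference(smooth_lowpass(z, fs, cutoff_hz or 12.0), fs)
    n = markers.n_frames
    flights = detect_contact_flight(fp, flight_threshold_n)

    def fr(t: float) -> int:
        return min(n - 1, max(0, int(round(t * fs))))

    phases: dict[str, tuple[int, int]] = {}
    contact_time = None

    if jump_type == "DJ":
        # leading airborne run = box standing + fall
        lead = [f for f in flights if f[0] == 0.0]
        if not lead:
            raise SegmentationError("DJ: no leading off-plate interval (phase D/F1) found")
        t_td = lead[0][1]
        rest = [f for f in flights if f[0] > 0.0]
        if not rest:
            raise SegmentationError("DJ: no flight after contact (phase F2) found")
        # the jump flight is the longest airborne run after first contact
        # (brief unweighted dips during vigorous contact are not flights)
        t_to, t_land = max(rest, key=lambda f: f[1] - f[0])
        i_td, i_to = fr(t_td), fr(t_to)
        # step-off: onset of sustained downward motion while still on the box
        i_step = fr(_movement_onset(v_onset, i_td, -1, fs))
        phases["D"] = (0, i_step)
        phases["F1"] = (i_step, i_td)
        phases["L1"] = (i_td, i_td)
        i_min = _ecc_con_split(v_split, i_td, i_to, fs)
        phases["E"] = (i_td, i_min)
        phases["C"] = (i_min, i_to)
        phases["F2"] = (i_to, fr(t_land))
        phases["L2"] = (fr(t_land), n)
        contact_time = t_to - t_td
        flight_time = t_land - t_to
        takeoff, landing = t_to, t_land
    else:
        if not flights:
            raise SegmentationError(f"{jump_type}: no flight (phase F2) detected")
        # longest airborne run = the jump flight; a vigorous countermovement
        # can unweight the plate below threshold briefly without takeoff
        t_to, t_land = max(flights, key=lambda f: f[1] - f[0])
        i_to = fr(t_to)
        if jump_type == "CMJ":
            i_onset = fr(_force_onset(fp, t_to))
            i_min = _ecc_con_split(v_split, i_onset, i_to, fs)
            phases["L1"] = (0, i_onset)
            phases["E"] = (i_onset, i_min)
            phases["C"] = (i_min, i_to)
        else:  # SJ: held squat, purely concentric
            i_onset = fr(_force_onset(fp, t_to))
            phases["C"] = (i_onset, i_to)
        phases["F2"] = (i_to, fr(t_land))
        phases["L2"] = (fr(t_land), n)
        flight_time = t_land - t_to
        takeoff, landing = t_to, t_land

    return PhaseSegmentation(phases=phases, frequency=fs,
                             flight_time=flight_time,
                             contact_time=contact_time,
                             takeoff_time=takeoff, landing_time=landing,
                             jump_type=jump_type)


def jump_height(seg: PhaseSegmentation, kin: LinearSeries,
                method: str = "flight_time", g: float = 9.81,
                box_height: float = 0.0) -> float:
    """Jump height (m) from flight time or from the sacrum apex.

    ``flight_time``: h = g t^2 / 8.  ``marker``: flight apex of the sacrum
    minus a standing reference — mean over L1 (CMJ quiet standing), mean over
    D minus ``box_height`` (DJ on-box standing), or the height at the takeoff
    instant when no standing phase exists (SJ starts in a held squat).
    """
    if method == "flight_time":
        if seg.flight_time is None:
            raise SegmentationError("no flight time available")
        return g * seg.flight_time**2 / 8.0
    if method != "marker":
        raise ParameterError(f"unknown jump height method {method!r}")
    if "F2" not in seg.phases:
        raise SegmentationError("no flight phase (F2) in segmentation")
    s, e = seg.phases["F2"]
    if e <= s:
        raise SegmentationError("empty flight phase")
    apex = float(np.max(kin.position[s:e]))
    if "D" in seg.phases and seg.phases["D"][1] > seg.phases["D"][0]:
        d0, d1 = seg.phases["D"]
        ref = float(np.mean(kin.position[d0:d1])) - box_height
    elif "L1" in seg.phases and seg.phases["L1"][1] > seg.phases["L1"][0]:
        l0, l1 = seg.phases["L1"]
        ref = float(np.mean(kin.position[l0:l1]))
    elif seg.takeoff_time is not None:
        t = np.arange(len(kin.position)) / kin.frequency
        ref = float(np.interp(seg.takeoff_time, t, kin.position))
    else:
        ref = float(kin.position[s])
    return apex - ref


def net_vertical_impulse(fp: ForcePlateSeries, t_start: float, t_end: float,
                         body_mass_kg: float, g: float = 9.81) -> float:
    """Trapezoid integral of (fz - m g) between two (possibly sub-frame) times.

    The endpoints are linearly interpolated so that integration up to an
    interpolated takeoff crossing loses no partial-frame impulse.  By the
    impulse-momentum theorem this equals m * (v(t_end) - v(t_start)) — in
    particular m * v_takeoff over the propulsion phase of a jump.
    """
    if not t_end > t_start:
        raise ParameterError("t_end must exceed t_start")
    t = fp.time
    inner = (t > t_start) & (t < t_end)
    ts = np.concatenate([[t_start], t[inner], [t_end]])
    fz = np.concatenate([[np.interp(t_start, t, fp.fz)], fp.fz[inner],
                         [np.interp(t_end, t, fp.fz)]])
    return float(np.trapezoid(fz - body_mass_kg * g, ts))


def classify_ssc_speed(contact_time_s: float) -> str:
    """Fast vs slow stretch-shortening cycle by the 250 ms contact-time rule.

    Ground contacts under 250 ms are "fast" (drop-jump-like), longer ones
    "slow" (countermovement-like); exactly 250 ms is classed slow.
    """
    if not contact_time_s > 0:
        raise ParameterError("contact time must be positive")
    return "fast" if contact_time_s < 0.250 else "slow"


def sprint_time(markers: MarkerTrajectories,
                gate_positions: tuple[float, float] = (0.0, 5.0),
                marker_id: str = "F_sacrum") -> float:
    """Time (s) between sacrum crossings of two virtual timing planes.

    Crossing times are linearly interpolated between the straddling samples;
    the first forward crossing of each plane is used.
    """
    xa, xb = gate_positions
    if xa == xb:
        raise ParameterError("gate planes must be at distinct positions")
    x = markers.get(marker_id)[:, 0]
    t = markers.time

    def crossing(gate: float) -> float:
        if x[0] >= gate:
            if x[0] == gate:
                return float(t[0])
            raise SegmentationError(f"trajectory starts beyond the gate at x={gate}")
        idx = np.flatnonzero((x[:-1] < gate) & (x[1:] >= gate))
        if idx.size == 0:
            raise SegmentationError(f"gate plane x={gate} m is never crossed")
        i = int(idx[0])
        frac = (gate - x[i]) / (x[i + 1] - x[i])
        return float(t[i] + frac * (t[i + 1] - t[i]))

    return abs(crossing(xb) - crossing(xa))
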