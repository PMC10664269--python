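"""Linear and angular kinematics from marker trajectories.

Marker positions are conditioned with a zero-phase Butterworth low-pass
before numerical differentiation (central differences), the conventional
treatment for optical jump kinematics.  Joint angles are inner angles at the
vertex marker, in degrees: a standing knee reads ~180 deg and a parallel
squat ~90 deg, matching goniometer convention.  All angular series stay in
degrees end to end (deg, deg/s, deg/s^2).

Hip angle uses markers (E, D, C) = (ASIS, trochanter, condyle) with the
trochanter as vertex; knee uses (D, C, B) = (trochanter, condyle, malleolus)
with the condyle as vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import DegenerateGeometryError, InputError, ParameterError
from .io_formats import MarkerTrajectories

#: (proximal, vertex, distal) marker stems per joint; side suffix _L/_R added.
JOINT_TRIPLETS = {
    "hip": ("E_ASIS", "Dtrochanter", "Ccondyle"),
    "knee": ("Dtrochanter", "Ccondyle", "Bmalleolus"),
}

DEFAULT_CUTOFF_HZ = 10.0
DEFAULT_ORDER = 4


@dataclass
class AngleSeries:
    """Joint angle (deg) with its first two derivatives, at ``frequency`` Hz."""

    joint: str
    side: str
    angle: np.ndarray
    angular_velocity: np.ndarray
    angular_acceleration: np.ndarray
    frequency: float

    def __post_init__(self) -> None:
        n = len(self.angle)
        if len(self.angular_velocity) != n or len(self.angular_acceleration) != n:
            raise InputError("angle series and derivatives must share length")


@dataclass
class LinearSeries:
    """Position (m) of one axis with smoothed derivatives, at ``frequency`` Hz."""

    axis: str
    position: np.ndarray
    velocity: np.ndarray
    acceleration: np.ndarray
    frequency: float


def smooth_lowpass(series: np.ndarray, frequency: float,
                   cutoff_hz: float = DEFAULT_CUTOFF_HZ,
                   order: int = DEFAULT_ORDER) -> np.ndarray:
    """Zero-phase Butterworth low-pass (DC gain 1).

    ``order`` is the effective order after the forward-backward pass, so the
    underlying filter is designed at ``order // 2`` — the usual biomechanics
    reading of "4th-order zero-phase Butterworth".
    """
    series = np.asarray(series, dtype=float)
    nyquist = frequency / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyquist} Hz)"
        )
    if order < 2 or order % 2:
        raise ParameterError("order must be an even integer >= 2")
    sos = signal.butter(order // 2, cutoff_hz / nyquist, output="sos")
    return signal.sosfiltfilt(sos, series)


def central_difference(series: np.ndarray, frequency: float) -> np.ndarray:
    """First derivative: central differences inside, one-sided at the ends.

    Exact for polynomials up to degree 2 at interior points; apply twice for
    the second derivative.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise InputError("central difference needs at least 3 samples")
    return np.gradient(series, 1.0 / frequency, axis=-1, edge_order=1)


def _vertex_angle_deg(p: np.ndarray, v: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Inner angle at v between rays v->p and v->d, per frame, degrees."""
    a = p - v
    b = d - v
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    tiny = np.flatnonzero((na < 1e-6) | (nb < 1e-6))
    if tiny.size:
        raise DegenerateGeometryError(
            f"coincident markers at frame {int(tiny[0])}", frame=int(tiny[0])
        )
    cosang = np.einsum("ij,ij->i", a, b) / (na * nb)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def joint_angle_series(markers: MarkerTrajectories,
                       joint: str = "knee", side: str = "R",
                       triplet: tuple[str, str, str] | None = None,
                       cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
                       order: int = DEFAULT_ORDER) -> AngleSeries:
    """Inner-angle series at a joint, with smoothed angular derivatives.

    ``triplet`` overrides the (proximal, vertex, distal) marker ids directly;
    otherwise they come from :data:`JOINT_TRIPLETS` with the ``side`` suffix.
    ``cutoff_hz=None`` skips smoothing (useful on noise-free synthetic data).
    """
    if triplet is None:
        if joint not in JOINT_TRIPLETS:
            raise InputError(f"unknown joint {joint!r}; expected hip or knee")
        stems = JOINT_TRIPLETS[joint]
        triplet = tuple(f"{s}_{side}" for s in stems)  # type: ignore[assignment]
    p, v, d = (markers.get(m) for m in triplet)
    if np.isnan(p).any() or np.isnan(v).any() or np.isnan(d).any():
        raise InputError("joint_angle_series requires gap-free markers; fill gaps first")
    angle = _vertex_angle_deg(p, v, d)
    sm = angle if cutoff_hz is None else smooth_lowpass(angle, markers.frequency, cutoff_hz, order)
    vel = central_difference(sm, markers.frequency)
    acc = central_difference(vel, markers.frequency)
    return AngleSeries(joint, side, angle, vel, acc, markers.frequency)


def linear_kinematics(markers: MarkerTrajectories, marker_id: str = "F_sacrum",
                      axis: str = "z",
                      cutoff_hz: float | None = DEFAULT_CUTOFF_HZ,
                      order: int = DEFAULT_ORDER) -> LinearSeries:
    """Position/velocity/acceleration of one marker along one lab axis."""
    traj = markers.get(marker_id)
    ax = {"x": 0, "y": 1, "z": 2}.get(axis)
    if ax is None:
        raise InputError(f"axis must be x, y or z, got {axis!r}")
    pos = traj[:, ax]
    if np.isnan(pos).any():
        raise InputError("linear_kinematics requires a gap-free marker; fill gaps first")
    sm = pos if cutoff_hz is None else smooth_lowpass(pos, markers.frequency, cutoff_hz, order)
    vel = central_difference(sm, markers.frequency)
    acc = central_difference(vel, markers.frequency)
    return LinearSeries(axis, pos, vel, acc, markers.frequency)
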