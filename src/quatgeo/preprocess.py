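"""Preprocessing of raw orientation recordings.

Turns timestamped orientation samples into analysis-ready trajectories,
following the standard kinematic pipeline for rotational movement data:

1. spherical-linear (slerp) resampling onto a uniform clock (1 kHz for raw
   robot recordings),
2. integer-factor downsampling (to 100 Hz for analysis),
3. angular-velocity estimation from per-step transition quaternions,
4. zero-phase low-pass Butterworth filtering of the velocity components
   (6 Hz, 4th order by default),
5. movement segmentation by angular-speed thresholds.

Velocity uses forward differences over the N-1 per-step transitions,
timestamped at interval starts; this matches the discrete transition-
quaternion definition and keeps ``||w_i|| * dt`` exactly equal to the
angular distance between successive samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from . import quatcore as qc

__all__ = [
    "TrajectoryError",
    "NoMovementError",
    "UnterminatedTrialError",
    "OrientationTrajectory",
    "AngularVelocitySeries",
    "resample_slerp",
    "downsample",
    "angular_velocity",
    "lowpass_zerolag",
    "filter_velocity",
    "segment_trial",
]

DEFAULT_CUTOFF_HZ = 6.0
DEFAULT_FILTER_ORDER = 4

# experiment-1 segmentation defaults
EXP1_PEAK_FRACTION = 0.10
EXP1_PROXIMITY_RAD = np.deg2rad(15.0)
EXP1_DWELL_S = 0.400

# experiment-2 segmentation defaults (rad/s)
EXP2_ONSET_SPEED = 0.25
EXP2_MIN_PEAK_SPEED = 1.0
EXP2_OFFSET_SPEED = 0.25


class TrajectoryError(ValueError):
    """Malformed orientation trajectory (timestamps, norms, lengths)."""


class NoMovementError(ValueError):
    """Angular speed never exceeded the onset threshold."""


class UnterminatedTrialError(ValueError):
    """The movement-termination rule was never satisfied."""


@dataclass
class OrientationTrajectory:
    """Strictly increasing timestamps paired with a continuous quaternion sequence.

    Parameters
    ----------
    t : array, shape (N,)
        Timestamps in seconds, strictly increasing.
    q : array, shape (N, 4)
        Unit quaternions, scalar first.  Sign continuity is enforced on
        construction (successive 4-vector dot products >= 0).
    rate : float, optional
        Nominal sampling rate in Hz; set by the resampling/downsampling
        operations and required by rate-aware consumers (filtering, delays).
    """

    t: np.ndarray
    q: np.ndarray
    rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.t.ndim != 1 or self.q.ndim != 2 or self.q.shape[1] != 4:
            raise TrajectoryError("expected t of shape (N,) and q of shape (N, 4)")
        if len(self.t) != len(self.q):
            raise TrajectoryError("t and q must have the same length")
        if len(self.t) < 2:
            raise TrajectoryError("a trajectory needs at least two samples")
        if np.any(np.diff(self.t) <= 0):
            bad = int(np.nonzero(np.diff(self.t) <= 0)[0][0]) + 1
            raise TrajectoryError(f"timestamps must be strictly increasing (violated at sample {bad})")
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise TrajectoryError("quaternions must be unit norm within 1e-6")
        self.q = qc.enforce_continuity(qc.normalize(self.q))

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def window(self, start: int, stop: int) -> "OrientationTrajectory":
        """Sub-trajectory over the inclusive index range [start, stop]."""
        if not (0 <= start < stop < len(self)):
            raise TrajectoryError(f"invalid window ({start}, {stop}) for length {len(self)}")
        return OrientationTrajectory(self.t[start : stop + 1], self.q[start : stop + 1], rate=self.rate)


@dataclass
class AngularVelocitySeries:
    """Forward-difference angular velocity, one 3-vector per inter-sample step.

    ``w[i]`` is ``(theta_i / dt) * n_i`` from the transition quaternion
    between samples i and i+1, expressed in the declared frame; ``t[i]`` is
    the start of that interval.
    """

    t: np.ndarray
    w: np.ndarray
    frame: str = "extrinsic"
    rate: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[1] != 3 or len(self.t) != len(self.w):
            raise TrajectoryError("expected t of shape (M,) and w of shape (M, 3)")
        if self.frame not in qc.FRAMES:
            raise ValueError(f"frame must be one of {qc.FRAMES}")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def speed(self) -> np.ndarray:
        """Scalar angular speed ``||w||`` in rad/s."""
        return np.linalg.norm(self.w, axis=1)


def _uniform_dt(t: np.ndarray) -> float:
    dt = np.diff(t)
    if dt.max() - dt.min() > 1e-6 * dt.mean():
        raise TrajectoryError("trajectory is not uniformly sampled; resample first")
    return float(dt.mean())


def resample_slerp(traj: OrientationTrajectory, target_rate: float) -> OrientationTrajectory:
    """Resample onto a uniform grid by spherical linear interpolation.

    The output grid runs from the first to the last input timestamp at
    ``target_rate``; each output sample is the geodesic interpolant between
    its two bracketing input samples, so input sample times reproduce the
    input quaternions exactly.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    t0, t1 = traj.t[0], traj.t[-1]
    n_out = int(np.floor((t1 - t0) * target_rate + 1e-9)) + 1
    t_out = t0 + np.arange(n_out) / target_rate
    # bracketing segment for each output time
    idx = np.searchsorted(traj.t, t_out, side="right") - 1
    idx = np.clip(idx, 0, len(traj) - 2)
    ta, tb = traj.t[idx], traj.t[idx + 1]
    h = np.clip((t_out - ta) / (tb - ta), 0.0, 1.0)
    qa, qb = traj.q[idx], traj.q[idx + 1]
    q_out = qc.geodesic(qa, qb, h)
    return OrientationTrajectory(t_out, q_out, rate=float(target_rate))


def downsample(traj: OrientationTrajectory, factor: int) -> OrientationTrajectory:
    """Keep every ``factor``-th sample starting at index 0; rate divides by factor."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor >= len(traj):
        raise TrajectoryError(f"downsampling factor {factor} >= trajectory length {len(traj)}")
    rate = None if traj.rate is None else traj.rate / factor
    return OrientationTrajectory(traj.t[::factor], traj.q[::factor], rate=rate)


def angular_velocity(traj: OrientationTrajectory, frame: str = "extrinsic") -> AngularVelocitySeries:
    """Per-step angular velocity ``w_i = (theta_i / dt) n_i`` in the declared frame.

    The trajectory must be uniformly sampled.  The speed series
    ``||w||`` is identical in both frames (the transition angle is
    frame-invariant); only the axes differ.
    """
    dt = _uniform_dt(traj.t)
    tr = qc.transition(traj.q[:-1], traj.q[1:], frame)
    axis, angle = qc.to_axis_angle(tr.value)
    w = axis * (np.asarray(angle) / dt)[..., None]
    rate = traj.rate if traj.rate is not None else 1.0 / dt
    return AngularVelocitySeries(traj.t[:-1], w, frame=frame, rate=rate)


def lowpass_zerolag(
    x: np.ndarray,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
    rate: float | None = None,
) -> np.ndarray:
    """Zero-phase low-pass Butterworth filter (forward-backward application).

    Filters each column of ``x`` (shape (N,) or (N, C)) along axis 0 with a
    Butterworth design of the stated order, applied forward then backward so
    the net phase shift is zero and the effective attenuation is the squared
    magnitude response.  Ends are padded by reflection over
    ``3 * (order + 1)`` samples.
    """
    if rate is None:
        raise ValueError("rate (Hz) is required")
    if cutoff * 2.0 >= rate:
        raise ValueError(f"cutoff {cutoff} Hz is at or above the Nyquist rate {rate / 2} Hz")
    x = np.asarray(x, dtype=float)
    padlen = 3 * (order + 1)
    if x.shape[0] <= padlen:
        raise ValueError(f"signal length {x.shape[0]} too short for order-{order} zero-phase filtering (needs > {padlen})")
    b, a = signal.butter(order, cutoff, btype="low", fs=rate)
    return signal.filtfilt(b, a, x, axis=0, padlen=padlen)


def filter_velocity(
    series: AngularVelocitySeries,
    cutoff: float = DEFAULT_CUTOFF_HZ,
    order: int = DEFAULT_FILTER_ORDER,
) -> AngularVelocitySeries:
    """Low-pass filter the three velocity components channel-wise (zero phase).

    Filtering acts on the Cartesian components, not on quaternions; the
    filtered axis is renormalized only when a unit axis is extracted
    downstream.
    """
    if series.rate is None:
        raise ValueError("series has no sampling rate")
    w = lowpass_zerolag(series.w, cutoff=cutoff, order=order, rate=series.rate)
    return AngularVelocitySeries(series.t, w, frame=series.frame, rate=series.rate)


def _first_strictly_above(x: np.ndarray, threshold: float) -> int | None:
    hits = np.nonzero(x > threshold)[0]
    return int(hits[0]) if len(hits) else None


def segment_trial(
    speed: np.ndarray,
    mode: str,
    rate: float | None = None,
    proximity: np.ndarray | None = None,
    *,
    peak_fraction: float = EXP1_PEAK_FRACTION,
    proximity_rad: float = EXP1_PROXIMITY_RAD,
    dwell_s: float = EXP1_DWELL_S,
    onset_speed: float = EXP2_ONSET_SPEED,
    min_peak_speed: float = EXP2_MIN_PEAK_SPEED,
    offset_speed: float = EXP2_OFFSET_SPEED,
) -> tuple[int, int]:
    """Onset/offset indices of the movement within an angular-speed series.

    Two segmentation rule sets are provided.  Threshold comparisons are
    strictly-greater / strictly-less; equality does not trigger.

    ``mode="exp1"`` (orientation matching, untimed): the analysis window
    starts at the first sample whose speed exceeds ``peak_fraction`` of the
    maximum speed and ends when the cursor-to-target angular distance
    (``proximity``, radians, same sampling as ``speed``) stays below
    ``proximity_rad`` for ``dwell_s`` seconds; the offset index is the end
    of that dwell.  Requires ``proximity`` and ``rate``.

    ``mode="exp2"`` (fast single rotations): onset at the first sample with
    speed above ``onset_speed`` (rad/s); the movement must then exceed
    ``min_peak_speed`` before the offset, which is the first subsequent
    sample with speed below ``offset_speed``.

    Raises
    ------
    NoMovementError
        If the onset rule is never satisfied.
    UnterminatedTrialError
        If the offset rule is never satisfied.
    """
    speed = np.asarray(speed, dtype=float)
    if speed.ndim != 1 or len(speed) == 0:
        raise ValueError("speed must be a nonempty 1-D series")

    if mode == "exp1":
        peak = speed.max()
        if peak <= 0:
            raise NoMovementError("angular speed is identically zero")
        onset = _first_strictly_above(speed, peak_fraction * peak)
        if onset is None:
            raise NoMovementError("speed never exceeded the onset fraction of its maximum")
        if proximity is None or rate is None:
            raise ValueError("exp1 segmentation requires the proximity series and the sampling rate")
        proximity = np.asarray(proximity, dtype=float)
        if len(proximity) != len(speed):
            raise ValueError("proximity series must match the speed series length")
        dwell = max(int(round(dwell_s * rate)), 1)
        below = proximity < proximity_rad
        # first run of `dwell` consecutive below-threshold samples after onset
        run = 0
        for i in range(onset + 1, len(below)):
            run = run + 1 if below[i] else 0
            if run >= dwell:
                return onset, i
        raise UnterminatedTrialError("cursor never dwelled within the proximity window")

    if mode == "exp2":
        onset = _first_strictly_above(speed, onset_speed)
        if onset is None:
            raise NoMovementError(f"angular speed never exceeded {onset_speed} rad/s")
        fast = _first_strictly_above(speed[onset:], min_peak_speed)
        if fast is None:
            raise UnterminatedTrialError(f"angular speed never exceeded {min_peak_speed} rad/s")
        fast += onset
        slow = np.nonzero(speed[fast:] < offset_speed)[0]
        if len(slow) == 0:
            raise UnterminatedTrialError(f"angular speed never dropped below {offset_speed} rad/s")
        return onset, int(fast + slow[0])

    raise ValueError(f"unknown segmentation mode {mode!r}")
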