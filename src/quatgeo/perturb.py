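"""Rotational visuomotor perturbation and cursor rendering.

In the adaptation task the visual feedback of the hand's rotation is
remapped: the instantaneous (extrinsic) rotation axis of the hand is
rotated by a fixed quaternion ``q_r = cos(theta_r/2) + n_r sin(theta_r/2)``
before being applied to the on-screen cursor, while per-step rotation
angles are untouched.  With the training perturbation (60 degrees about
the x axis) a hand rotation about an axis orthogonal to ``n_r`` shows up
on screen rotated by the full 60 degrees.

Because the instantaneous axis is ill-defined at low angular speed, the
original apparatus computed it from a delayed transition (80 samples at
the 4 kHz haptic rate, i.e. a 20 ms visual delay).  :func:`render_cursor`
reproduces this by reading the hand trajectory with a ``delay_samples``
lag, perturbing each per-step transition axis while keeping its angle,
and integrating the perturbed transitions from the hand's initial
orientation.

Compensation: rotating the hand about the conjugated axis
``n_c = q_r^-1 n_t q_r`` makes the perturbed cursor reproduce the ideal
geodesic toward the target axis ``n_t`` — this is the behaviour a fully
adapted participant converges to, and the same conjugation gives the
predicted full-aftereffect axis once the perturbation is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quatcore as qc
from .preprocess import OrientationTrajectory, TrajectoryError

__all__ = ["VisuomotorRotation", "perturb_axis", "conjugate_axis", "render_cursor"]

#: Per-step rotation angles below this (rad) leave the axis ill-defined;
#: the previous valid axis is reused when rendering.
LOW_SPEED_ANGLE = 1e-10


@dataclass(frozen=True)
class VisuomotorRotation:
    """A fixed rotation applied to the hand's instantaneous rotation axis.

    Parameters
    ----------
    angle : float
        Perturbation angle ``theta_r`` in radians (60 degrees in training).
    axis : array (3,)
        Unit perturbation axis ``n_r`` (x in training); normalized on
        construction.
    delay_samples : int
        Visual delay ``D`` in samples of ``source_rate`` (80 at 4 kHz for a
        20 ms lag).
    source_rate : float, optional
        Sampling rate the delay is counted in, Hz.
    """

    angle: float
    axis: np.ndarray
    delay_samples: int = 0
    source_rate: float | None = None

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(axis)
        if axis.shape != (3,) or n < 1e-12:
            raise ValueError("perturbation axis must be a nonzero 3-vector")
        object.__setattr__(self, "axis", axis / n)
        if self.delay_samples < 0 or int(self.delay_samples) != self.delay_samples:
            raise ValueError("delay_samples must be a non-negative integer")
        object.__setattr__(self, "delay_samples", int(self.delay_samples))

    @property
    def quaternion(self) -> np.ndarray:
        """``q_r = cos(theta_r/2) + n_r sin(theta_r/2)``."""
        return qc.from_axis_angle(self.axis, self.angle)

    @classmethod
    def identity(cls) -> "VisuomotorRotation":
        return cls(angle=0.0, axis=np.array([1.0, 0.0, 0.0]))


def perturb_axis(n, vr: VisuomotorRotation) -> np.ndarray:
    """Perturbed instantaneous axis ``q_r n q_r^-1`` (norm preserved).

    For ``n`` orthogonal to the perturbation axis the angle between input
    and output equals the perturbation angle; ``n = n_r`` is unchanged.
    """
    return qc.rotate_vector(vr.quaternion, n)


def conjugate_axis(n, vr: VisuomotorRotation, direction: str = "inverse") -> np.ndarray:
    """Axis conjugated by the perturbation, forward or inverse.

    ``direction="inverse"`` returns ``q_r^-1 n q_r`` — the compensation
    axis a fully adapted mover rotates about (and, equivalently, the
    full-aftereffect axis).  ``direction="forward"`` returns
    ``q_r n q_r^-1`` (same as :func:`perturb_axis`).
    """
    if direction == "inverse":
        return qc.rotate_vector(qc.conjugate(vr.quaternion), n)
    if direction == "forward":
        return qc.rotate_vector(vr.quaternion, n)
    raise ValueError("direction must be 'inverse' or 'forward'")


def render_cursor(hand: OrientationTrajectory, vr: VisuomotorRotation) -> OrientationTrajectory:
    """Cursor trajectory produced by the perturbed, delayed visual mapping.

    The hand trajectory is read with a lag of ``vr.delay_samples``
    (the cursor holds the initial orientation for the first ``D`` samples —
    hand movements start from rest, so the held segment is smooth).  Each
    per-step transition of the delayed sequence is decomposed into axis and
    angle, the axis is replaced by :func:`perturb_axis` of itself, the angle
    is kept, and the rebuilt transitions are integrated extrinsically from
    ``cursor_0 = hand_0``.  With the identity perturbation and zero delay
    the cursor equals the hand to machine precision.

    Per-step angles below :data:`LOW_SPEED_ANGLE` leave the axis
    ill-defined; the previous valid axis is reused for those steps.
    """
    D = vr.delay_samples
    N = len(hand)
    if N <= D:
        raise TrajectoryError(f"trajectory of length {N} is shorter than the delay {D}")
    if hand.rate is not None and vr.source_rate is not None:
        if abs(hand.rate - vr.source_rate) > 1e-6 * vr.source_rate:
            raise TrajectoryError(
                f"trajectory rate {hand.rate} Hz does not match the perturbation's source rate {vr.source_rate} Hz"
            )

    delayed = hand.q[np.maximum(np.arange(N) - D, 0)]
    tr = qc.transition(delayed[:-1], delayed[1:], "extrinsic")
    axis, angle = qc.to_axis_angle(tr.value)
    angle = np.atleast_1d(np.asarray(angle, dtype=float))

    # reuse the previous valid axis where the step angle is ill-defined
    valid = angle > LOW_SPEED_ANGLE
    if np.any(valid):
        last = np.maximum.accumulate(np.where(valid, np.arange(len(angle)), -1))
        first_valid = int(np.argmax(valid))
        last = np.where(last < 0, first_valid, last)
        axis = axis[last]

    p_axis = perturb_axis(axis, vr)
    steps = np.concatenate(
        [np.cos(angle / 2.0)[:, None], p_axis * np.sin(angle / 2.0)[:, None]], axis=1
    )
    cursor = np.empty_like(hand.q)
    cursor[0] = hand.q[0]
    for i in range(len(steps)):
        cursor[i + 1] = qc.multiply(steps[i], cursor[i])
    return OrientationTrajectory(hand.t, qc.enforce_continuity(cursor), rate=hand.rate)
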