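"""Aiming-axis and aiming-angle metrics for rotational adaptation.

The direction summary of a fast hand rotation is its *aiming axis*: the
unit instantaneous rotation axis at the time of peak angular speed,
computed after pre-rotating the trajectory by the inverse of its initial
orientation (so every trial starts at the identity and axes are
comparable across initial orientations).  To reduce between-participant
variability, a per-participant *baseline axis* — the normalized vector
sum of the aiming axes of 20 randomly chosen trials out of the last 40 of
each baseline set — is mapped onto the session's ideal rotation axis by a
single rotation of the sphere, and that rotation is applied to all of the
participant's aiming axes from the matching sessions (an isometry, so
relative geometry is preserved).

The scalar *aiming angle* is the elevation of the aiming axis out of the
plane spanned by the perturbation axis ``n_r`` and the ideal rotation
axis ``n_id``::

    angle = arctan2(n_a . (n_r x n_id), sqrt((n_a . n_r)^2 + (n_a . n_id)^2))

It spans [-pi/2, pi/2] and is zero when ``n_a = n_id``.  Note the sign
convention: positive means displaced toward ``n_r x n_id``; with the
training geometry (``n_r = x``, extrinsic-group ideal axis) compensation
for the perturbation appears at negative aiming angle.

Adaptation experiments are summarized at six key stages (late BL1, late
BL2, early TRN, late TRN, early TFR, late TFR); a :class:`StagePlan`
selects the trials averaged per stage for a sensitivity parameter
``k`` = 1-10 (e.g. for k = 3: trials 118-120, 178-180, 181-183, 358-360,
361-363, 418-420 of the 420-trial protocol).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from . import quatcore as qc
from .preprocess import (
    AngularVelocitySeries,
    NoMovementError,
    OrientationTrajectory,
    angular_velocity,
    filter_velocity,
)

__all__ = [
    "STAGES",
    "SESSIONS",
    "AimingResult",
    "StagePlan",
    "DegenerateBaselineError",
    "aiming_axis",
    "baseline_axis",
    "remove_baseline",
    "aiming_angle",
    "make_stage_plan",
    "stage_average",
    "analyze_cohort",
]

#: The six key stages of the adaptation protocol, in temporal order.
STAGES = ("lateBL1", "lateBL2", "earlyTRN", "lateTRN", "earlyTFR", "lateTFR")

#: 1-based trial-index ranges (inclusive) of the 420-trial protocol sessions.
SESSIONS = {
    "FML1": (1, 30),
    "FML2": (31, 60),
    "BL1": (61, 120),
    "BL2": (121, 180),
    "TRN": (181, 360),
    "TFR": (361, 420),
}

#: Peak angular speed below this (rad/s) means no scorable movement.
MIN_PEAK_SPEED = 0.25


class DegenerateBaselineError(ValueError):
    """Baseline aiming axes cancel; no meaningful average direction."""


class DegeneratePlaneError(ValueError):
    """Perturbation and ideal axes are parallel; the reference plane is undefined."""


@dataclass(frozen=True)
class AimingResult:
    """Aiming axis of one trial, with the peak-speed sample it came from.

    ``angle`` (the aiming angle, radians) is filled in by the pipeline once
    the reference axes are known; it is ``nan`` straight out of
    :func:`aiming_axis`.
    """

    axis: np.ndarray
    peak_speed: float
    peak_index: int
    angle: float = float("nan")


def aiming_axis(
    traj: OrientationTrajectory,
    frame: str = "intrinsic",
    cutoff: float = 6.0,
    order: int = 4,
    min_peak_speed: float = MIN_PEAK_SPEED,
) -> AimingResult:
    """Unit rotation axis at the time of peak angular speed.

    The trajectory (already segmented to the movement of interest) is
    pre-rotated by ``q_1^-1`` so it starts at the identity, its angular
    velocity is computed in the declared frame and low-pass filtered
    (zero phase), and the axis ``w / ||w||`` is taken at the first index of
    maximal ``||w||``.

    Raises
    ------
    NoMovementError
        If the peak filtered speed does not exceed ``min_peak_speed``.
    """
    q0inv = qc.conjugate(traj.q[0])
    centred = OrientationTrajectory(traj.t, qc.multiply(q0inv, traj.q), rate=traj.rate)
    vel = angular_velocity(centred, frame=frame)
    vel = filter_velocity(vel, cutoff=cutoff, order=order)
    speed = vel.speed
    peak = int(np.argmax(speed))  # argmax returns the first index on ties
    if not speed[peak] > min_peak_speed:
        raise NoMovementError(
            f"peak angular speed {speed[peak]:.3f} rad/s does not exceed {min_peak_speed} rad/s"
        )
    axis = vel.w[peak] / speed[peak]
    return AimingResult(axis=axis, peak_speed=float(speed[peak]), peak_index=peak)


def baseline_axis(
    axes,
    n_pool: int = 40,
    n_pick: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Normalized vector sum of ``n_pick`` axes drawn from the last ``n_pool``.

    This is the per-participant baseline direction of a baseline set; the
    random subsample (without replacement) makes the estimate robust to a
    few atypical late-baseline trials while remaining reproducible given a
    seed.
    """
    axes = np.asarray(axes, dtype=float)
    if axes.ndim != 2 or axes.shape[1] != 3:
        raise ValueError("axes must be an (n, 3) array of unit vectors")
    if len(axes) < n_pool:
        raise ValueError(f"need at least {n_pool} axes, got {len(axes)}")
    rng = np.random.default_rng(seed)
    pool = axes[-n_pool:]
    pick = pool[rng.choice(n_pool, size=n_pick, replace=False)]
    total = pick.sum(axis=0)
    norm = np.linalg.norm(total)
    if norm < 1e-9:
        raise DegenerateBaselineError("selected baseline axes cancel out")
    return total / norm


def remove_baseline(axes, baseline, ideal) -> np.ndarray:
    """Rotate all axes by the rotation taking ``baseline`` onto ``ideal``.

    The rotation has angle ``arccos(baseline . ideal)`` about
    ``baseline x ideal`` (normalized); it is a single isometry of the
    sphere, so all pairwise angles among the axes are preserved and the
    baseline maps exactly onto the ideal axis.
    """
    axes = np.asarray(axes, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    ideal = np.asarray(ideal, dtype=float)
    c = float(np.clip(np.dot(baseline, ideal), -1.0, 1.0))
    cross = np.cross(baseline, ideal)
    cn = np.linalg.norm(cross)
    if c < -1.0 + 1e-12 and cn < 1e-12:
        raise DegenerateBaselineError("baseline is antipodal to the ideal axis; rotation undefined")
    if cn < 1e-12:
        return axes.copy()  # already aligned
    rot = qc.from_axis_angle(cross / cn, np.arccos(c))
    return qc.rotate_vector(rot, axes)


def aiming_angle(n_a, n_r, n_id) -> float:
    """Elevation of the aiming axis from the (perturbation, ideal) plane.

    ``arctan2(n_a.(n_r x n_id), sqrt((n_a.n_r)^2 + (n_a.n_id)^2))``, in
    radians within [-pi/2, pi/2]; zero when ``n_a = n_id``, +pi/2 at the
    plane normal.

    Raises
    ------
    DegeneratePlaneError
        If ``n_r`` and ``n_id`` are (anti)parallel.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_r = np.asarray(n_r, dtype=float)
    n_id = np.asarray(n_id, dtype=float)
    cross = np.cross(n_r, n_id)
    if np.linalg.norm(cross) < 1e-9:
        raise DegeneratePlaneError("perturbation axis is parallel to the ideal axis")
    num = float(np.dot(n_a, cross))
    den = float(np.sqrt(np.dot(n_a, n_r) ** 2 + np.dot(n_a, n_id) ** 2))
    return float(np.arctan2(num, den))


@dataclass(frozen=True)
class StagePlan:
    """Trial indices averaged at each key stage for a k-trial analysis."""

    k: int
    blocks: Mapping[str, range]


def make_stage_plan(k: int = 3) -> StagePlan:
    """Stage blocks of the 420-trial protocol for ``k`` trials per stage.

    Late blocks end at the last trial of their session, early blocks start
    at the first; e.g. k = 3 gives late BL1 = 118-120, late BL2 = 178-180,
    early TRN = 181-183, late TRN = 358-360, early TFR = 361-363 and late
    TFR = 418-420.
    """
    if not (1 <= k <= 10):
        raise ValueError("k must be between 1 and 10")
    blocks = {
        "lateBL1": range(SESSIONS["BL1"][1] - k + 1, SESSIONS["BL1"][1] + 1),
        "lateBL2": range(SESSIONS["BL2"][1] - k + 1, SESSIONS["BL2"][1] + 1),
        "earlyTRN": range(SESSIONS["TRN"][0], SESSIONS["TRN"][0] + k),
        "lateTRN": range(SESSIONS["TRN"][1] - k + 1, SESSIONS["TRN"][1] + 1),
        "earlyTFR": range(SESSIONS["TFR"][0], SESSIONS["TFR"][0] + k),
        "lateTFR": range(SESSIONS["TFR"][1] - k + 1, SESSIONS["TFR"][1] + 1),
    }
    return StagePlan(k=k, blocks=blocks)


def stage_average(
    results: Mapping[int, AimingResult],
    plan: StagePlan,
    ideal_axes: Mapping[str, np.ndarray] | None = None,
) -> dict[str, AimingResult]:
    """Per-stage averaged aiming axis (normalized vector sum) and mean angle.

    ``results`` maps 1-based trial indices to per-trial results.  If
    ``ideal_axes`` maps stages to their ideal rotation axes, each trial
    axis is sign-aligned to have a positive dot product with its stage's
    ideal axis before summation (the double cover leaves the raw sign
    ambiguous for noisy near-degenerate movements).

    Raises
    ------
    KeyError
        Listing the missing trial indices if any stage block is incomplete.
    """
    out: dict[str, AimingResult] = {}
    for stage, block in plan.blocks.items():
        missing = [i for i in block if i not in results]
        if missing:
            raise KeyError(f"stage {stage} is missing trials {missing}")
        axes = np.array([results[i].axis for i in block])
        if ideal_axes is not None and stage in ideal_axes:
            sign = np.where(axes @ np.asarray(ideal_axes[stage]) < 0.0, -1.0, 1.0)
            axes = axes * sign[:, None]
        total = axes.sum(axis=0)
        norm = np.linalg.norm(total)
        if norm < 1e-9:
            raise DegenerateBaselineError(f"axes of stage {stage} cancel out")
        angles = np.array([results[i].angle for i in block])
        peak = float(np.mean([results[i].peak_speed for i in block]))
        out[stage] = AimingResult(
            axis=total / norm, peak_speed=peak, peak_index=-1, angle=float(np.mean(angles))
        )
    return out


def session_of(index: int) -> str:
    """Session label of a 1-based trial index in the 420-trial protocol."""
    for name, (lo, hi) in SESSIONS.items():
        if lo <= index <= hi:
            return name
    raise ValueError(f"trial index {index} outside the 420-trial protocol")


def analyze_cohort(
    trials: Sequence,
    ideal_axes: Mapping[str, np.ndarray],
    n_r,
    frame: str = "intrinsic",
    k: int = 3,
    seed: int | None = None,
    onset_fraction: float = 0.10,
) -> tuple[dict[int, AimingResult], dict[str, AimingResult]]:
    """Full aiming analysis of one simulated or recorded participant.

    Parameters
    ----------
    trials
        Objects with attributes ``index`` (1-based trial number) and
        ``trajectory`` (:class:`OrientationTrajectory`); typically the
        output of the cohort simulator or loaded trial files.
    ideal_axes
        Ideal rotation axes per baseline set, keys ``"BL1"`` and ``"BL2"``,
        expressed in the measurement frame (i.e. as measured by
        :func:`aiming_axis` on a noiseless movement).
    n_r
        Perturbation axis in the measurement frame.
    k, seed
        Stage-plan width and the seed of the random baseline subsample.

    Returns
    -------
    per_trial, per_stage
        Baseline-corrected per-trial results keyed by trial index, and the
        k-trial stage averages.

    Notes
    -----
    Each trial's analysis window starts at the first sample whose angular
    speed exceeds ``onset_fraction`` of its maximum.  Baseline axes are
    computed per baseline set (BL1 corrects BL1+TRN, BL2 corrects
    BL2+TFR); familiarization trials are not analyzed.
    """
    raw: dict[int, AimingResult] = {}
    session: dict[int, str] = {}
    for trial in trials:
        idx = trial.index
        ses = session_of(idx)
        session[idx] = ses
        if ses in ("FML1", "FML2"):
            continue
        traj = trial.trajectory
        speed = angular_velocity(traj, frame="extrinsic").speed
        onset = np.nonzero(speed > onset_fraction * speed.max())[0]
        start = int(onset[0]) if len(onset) else 0
        if start > len(traj) - 20:  # keep enough samples for zero-phase filtering
            start = max(len(traj) - 20, 0)
        windowed = traj.window(start, len(traj) - 1) if start > 0 else traj
        raw[idx] = aiming_axis(windowed, frame=frame)

    per_trial: dict[int, AimingResult] = {}
    for bl, corrected_sessions in (("BL1", ("BL1", "TRN")), ("BL2", ("BL2", "TFR"))):
        bl_indices = sorted(i for i in raw if session[i] == bl)
        axes_bl = np.array([raw[i].axis for i in bl_indices])
        base = baseline_axis(axes_bl, seed=seed)
        target_ideal = np.asarray(ideal_axes[bl], dtype=float)
        idxs = sorted(i for i in raw if session[i] in corrected_sessions)
        corrected = remove_baseline(np.array([raw[i].axis for i in idxs]), base, target_ideal)
        for i, axis in zip(idxs, corrected):
            ang = aiming_angle(axis, n_r, target_ideal)
            per_trial[i] = replace(raw[i], axis=axis, angle=ang)

    plan = make_stage_plan(k)
    stage_ideal = {
        stage: ideal_axes["BL1"] if stage in ("lateBL1", "earlyTRN", "lateTRN") else ideal_axes["BL2"]
        for stage in STAGES
    }
    per_stage = stage_average(per_trial, plan, ideal_axes=stage_ideal)
    return per_trial, per_stage
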