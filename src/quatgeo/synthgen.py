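"""Synthetic orientation-matching trials and simulated adaptation cohorts.

Real recordings of the orientation-matching task are not publicly
deposited, so every stage of the analysis pipeline is exercised against
synthetic data whose ground truth is known by construction:

* :func:`gen_geodetic_trial` samples the geodesic from an initial
  orientation to a target with minimum-jerk timing
  ``h(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5`` — a constant rotation axis
  and the bell-shaped angular-speed profile characteristic of natural
  hand rotations (peak normalized speed 1.875 at mid-movement).

* :func:`gen_noisy_trial` adds smooth jitter to the per-step rotation
  axis (emulating imperfect peripheral execution) and applies a smoothly
  ramped terminal correction so the movement still ends on target, as
  accepted trials do.

* :func:`simulate_cohort` generates one simulated participant of the
  420-trial adaptation protocol (FML 60, BL1 60, BL2 60, TRN 180,
  TFR 60).  The learner is a deliberately simple single-state model: its
  internal aim axis rotates exponentially (rate ``learn_rate`` per trial)
  toward the compensation axis, up to ``asymptote``, and decays by
  ``retention`` per washout trial.  The ``group`` decides whether the
  learned rotation is attached to the extrinsically represented
  compensation axis (so it transfers across the 90-degree change of
  initial orientation in TFR) or to the intrinsic one (so it does not);
  the control group keeps the first initial orientation throughout.
  This is fixture machinery for testing the analysis pipeline, not a
  model of human learning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quatcore as qc
from . import reference as ref
from .adaptation import SESSIONS, aiming_axis
from .perturb import VisuomotorRotation, render_cursor
from .preprocess import OrientationTrajectory

__all__ = [
    "TrialSpec",
    "LearnerSpec",
    "Trial",
    "minimum_jerk",
    "gen_geodetic_trial",
    "gen_noisy_trial",
    "default_protocol",
    "simulate_cohort",
    "ideal_axes_for",
    "measurement_perturbation_axis",
]

#: Accepted terminal cursor-to-target error in the task (radians).
ENDPOINT_CAP = np.deg2rad(15.0)

DEFAULT_RATE_HZ = 100.0
DURATION_RANGE_S = (0.400, 0.600)


@dataclass(frozen=True)
class TrialSpec:
    """Specification of a single synthetic orientation-matching movement.

    ``target_axis``/``target_angle`` define the target as a rotation of the
    initial orientation ``q1``; ``frame`` says whether that rotation is
    composed extrinsically (space-fixed axis) or intrinsically (body-fixed
    axis).  ``noise_axis_sd`` (degrees) is the standard deviation of the
    smooth per-step axis jitter; ``noise_timing_sd`` (fraction) perturbs
    the minimum-jerk time course.
    """

    q1: np.ndarray
    target_axis: np.ndarray
    target_angle: float
    duration: float = 0.5
    rate: float = DEFAULT_RATE_HZ
    frame: str = "extrinsic"
    noise_axis_sd: float = 0.0
    noise_timing_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.rate <= 0:
            raise ValueError("duration and rate must be positive")
        if not (0.0 < self.target_angle < np.pi):
            raise ValueError("target_angle must lie in (0, pi)")
        if self.frame not in qc.FRAMES:
            raise ValueError(f"frame must be one of {qc.FRAMES}")

    @property
    def target(self) -> np.ndarray:
        """The target orientation implied by the spec."""
        step = qc.from_axis_angle(self.target_axis, self.target_angle)
        if self.frame == "extrinsic":
            return qc.multiply(step, self.q1)
        return qc.multiply(self.q1, step)


@dataclass(frozen=True)
class LearnerSpec:
    """Single-state exponential learner used by the cohort simulator."""

    group: str = "extrinsic"
    learn_rate: float = 0.2
    asymptote: float = np.deg2rad(40.0)
    retention: float = 0.95
    motor_noise_sd: float = 2.0  # degrees, between-trial aim jitter
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.group not in ("extrinsic", "intrinsic", "control"):
            raise ValueError("group must be 'extrinsic', 'intrinsic' or 'control'")
        if not (0.0 <= self.learn_rate <= 1.0 and 0.0 <= self.retention <= 1.0):
            raise ValueError("learn_rate and retention must lie in [0, 1]")
        if not (0.0 <= self.asymptote <= ref.PERTURBATION_ANGLE + 1e-12):
            raise ValueError("asymptote must lie in [0, perturbation angle]")


@dataclass
class Trial:
    """One simulated trial: trajectory plus its generating metadata."""

    index: int  # 1-based position in the protocol
    session: str
    group: str
    trajectory: OrientationTrajectory
    q1: np.ndarray
    target_axis: np.ndarray  # extrinsic aim axis actually executed
    target_angle: float
    perturbed: bool = False
    cursor: OrientationTrajectory | None = None
    adaptation_state: float = 0.0  # learner's rotation (rad) when the trial ran


def minimum_jerk(tau) -> np.ndarray:
    """Quintic timing law ``10 tau^3 - 15 tau^4 + 6 tau^5`` on [0, 1]."""
    tau = np.asarray(tau, dtype=float)
    return 10.0 * tau**3 - 15.0 * tau**4 + 6.0 * tau**5


def _time_grid(spec: TrialSpec) -> np.ndarray:
    n = int(round(spec.duration * spec.rate)) + 1
    return np.arange(n) / spec.rate


def _timing_profile(spec: TrialSpec, rng: np.random.Generator | None) -> np.ndarray:
    t = _time_grid(spec)
    h = minimum_jerk(t / t[-1])
    if spec.noise_timing_sd > 0.0 and rng is not None:
        bump = _smooth_noise(len(h), spec.rate, rng)
        # endpoint-pinned multiplicative jitter of the time course
        h = np.clip(h + spec.noise_timing_sd * bump * 4.0 * h * (1.0 - h), 0.0, 1.0)
        h[0], h[-1] = 0.0, 1.0
    return h


def _smooth_noise(n: int, rate: float, rng: np.random.Generator, shape=()) -> np.ndarray:
    """Unit-variance noise smoothed with a ~150 ms Hann window."""
    x = rng.standard_normal((n,) + shape)
    win = max(int(round(0.15 * rate)) | 1, 3)
    kernel = np.hanning(win + 2)[1:-1]
    kernel /= kernel.sum()
    out = np.empty_like(x)
    flat = x.reshape(n, -1)
    res = np.empty_like(flat)
    for j in range(flat.shape[1]):
        res[:, j] = np.convolve(flat[:, j], kernel, mode="same")
    out = res.reshape(x.shape)
    sd = out.std()
    return out / sd if sd > 0 else out


def gen_geodetic_trial(spec: TrialSpec) -> OrientationTrajectory:
    """Noise-free geodesic from ``q1`` to the target with minimum-jerk timing.

    The endpoints match the spec exactly and the trajectory has QGS = 1 to
    numerical precision.
    """
    t = _time_grid(spec)
    h = minimum_jerk(t / t[-1])
    q = qc.geodesic(spec.q1, spec.target, h)
    return OrientationTrajectory(t, q, rate=spec.rate)


def gen_noisy_trial(spec: TrialSpec) -> OrientationTrajectory:
    """Geodetic trial with smooth axis jitter, re-integrated and end-corrected.

    The per-step transition axes of the timed geodesic are perturbed by a
    low-pass-filtered random rotation with standard deviation
    ``noise_axis_sd`` (degrees), the per-step angles are kept, and the
    steps are re-integrated from ``q1``.  A smoothly ramped terminal
    correction then maps the drifted endpoint back onto the target, so the
    endpoint error is zero (well within the task's 15-degree acceptance
    cap).  With zero noise settings the output is identical to
    :func:`gen_geodetic_trial`.
    """
    rng = np.random.default_rng(spec.seed)
    t = _time_grid(spec)
    h = _timing_profile(spec, rng)
    q = qc.geodesic(spec.q1, spec.target, h)
    if spec.noise_axis_sd <= 0.0:
        return OrientationTrajectory(t, q, rate=spec.rate)

    tr = qc.transition(q[:-1], q[1:], "extrinsic")
    axis, angle = qc.to_axis_angle(tr.value)
    angle = np.atleast_1d(np.asarray(angle, dtype=float))
    sd = np.deg2rad(spec.noise_axis_sd)
    rotvec = sd * _smooth_noise(len(angle), spec.rate, rng, shape=(3,))
    rnorm = np.linalg.norm(rotvec, axis=1)
    jitter = qc.from_axis_angle(rotvec / np.where(rnorm < 1e-12, 1.0, rnorm)[:, None], rnorm)
    new_axis = qc.rotate_vector(jitter, axis)
    steps = np.concatenate(
        [np.cos(angle / 2.0)[:, None], new_axis * np.sin(angle / 2.0)[:, None]], axis=1
    )
    out = np.empty_like(q)
    out[0] = spec.q1
    for i in range(len(steps)):
        out[i + 1] = qc.multiply(steps[i], out[i])
    # ramped terminal correction: rotate the path so the endpoint hits the target
    corr = qc.multiply(spec.target, qc.conjugate(out[-1]))
    out = qc.multiply(qc.power(corr, minimum_jerk(t / t[-1]))[..., :], out)
    return OrientationTrajectory(t, qc.enforce_continuity(out), rate=spec.rate)


# --- adaptation-protocol simulation -------------------------------------------


def _session_geometry(group: str) -> dict[str, tuple[np.ndarray, np.ndarray, str, bool]]:
    """Per session: (initial orientation, target axis, axis frame, perturbed)."""
    o1, o2 = ref.EXP2_O1, ref.EXP2_O2
    n1, n2 = ref.AXIS_EXTRINSIC_GROUP, ref.AXIS_INTRINSIC_GROUP
    if group == "extrinsic":
        return {
            "FML1": (o1, n1, "extrinsic", False),
            "FML2": (o2, n1, "extrinsic", False),
            "BL1": (o1, n1, "extrinsic", False),
            "BL2": (o2, n1, "extrinsic", False),
            "TRN": (o1, n1, "extrinsic", True),
            "TFR": (o2, n1, "extrinsic", False),
        }
    if group == "intrinsic":
        return {
            "FML1": (o1, n2, "intrinsic", False),
            "FML2": (o2, n2, "intrinsic", False),
            "BL1": (o1, n2, "intrinsic", False),
            "BL2": (o2, n2, "intrinsic", False),
            "TRN": (o1, n2, "intrinsic", True),
            "TFR": (o2, n2, "intrinsic", False),
        }
    # control: same initial orientation throughout; targets swap between the
    # two ideal axes so the TFR target is orthogonal to the trained one
    return {
        "FML1": (o1, n2, "intrinsic", False),
        "FML2": (o1, n1, "extrinsic", False),
        "BL1": (o1, n2, "intrinsic", False),
        "BL2": (o1, n1, "extrinsic", False),
        "TRN": (o1, n2, "intrinsic", True),
        "TFR": (o1, n1, "extrinsic", False),
    }


def default_protocol() -> list[tuple[str, int]]:
    """Session order and lengths: FML1+FML2 (60), BL1, BL2 (60 each), TRN (180), TFR (60)."""
    return [(name, hi - lo + 1) for name, (lo, hi) in SESSIONS.items()]


def _extrinsic_axis(axis, frame: str, q1) -> np.ndarray:
    if frame == "extrinsic":
        return np.asarray(axis, dtype=float)
    return qc.rotate_vector(q1, axis)  # body-fixed axis expressed in space


def _rotate_about(v, axis, angle) -> np.ndarray:
    return qc.rotate_vector(qc.from_axis_angle(axis, angle), v)


def _jitter_direction(v, sd_deg: float, rng: np.random.Generator) -> np.ndarray:
    if sd_deg <= 0:
        return v
    g = rng.standard_normal(3)
    g -= v * (g @ v)  # tangent component only
    out = v + np.deg2rad(sd_deg) * g
    return out / np.linalg.norm(out)


def simulate_cohort(
    learner: LearnerSpec,
    protocol: list[tuple[str, int]] | None = None,
    vr: VisuomotorRotation | None = None,
    rate: float = DEFAULT_RATE_HZ,
    axis_noise_sd: float = 2.0,
    render_cursors: bool = True,
) -> list[Trial]:
    """Simulate one participant of the adaptation protocol.

    Every trial is a 50-degree rotation generated by
    :func:`gen_noisy_trial` with duration drawn uniformly from the task's
    400-600 ms feedback window; during training the visual consequence is
    additionally rendered through :func:`quatgeo.perturb.render_cursor`.
    The learner's internal adaptation state (a rotation about the
    perturbation axis, radians) evolves exponentially toward ``asymptote``
    during training and decays by ``retention`` per washout trial; whether
    the learned rotation is applied in the transfer session depends on the
    learner's group (see the module docstring).

    Returns the 420 trials in protocol order, 1-based ``index`` matching
    the session table.
    """
    if protocol is None:
        protocol = default_protocol()
    if sum(n for _, n in protocol) != SESSIONS["TFR"][1]:
        raise ValueError("protocol lengths do not cover the 420-trial schedule")
    if vr is None:
        vr = ref.training_perturbation(rate)
    rng = np.random.default_rng(learner.seed)
    geometry = _session_geometry(learner.group)
    n_r = vr.axis
    a = 0.0  # learner adaptation state, radians
    trials: list[Trial] = []
    index = 0
    for session, n_trials in protocol:
        q1, axis, frame, perturbed = geometry[session]
        n_t = _extrinsic_axis(axis, frame, q1)
        for _ in range(n_trials):
            index += 1
            if perturbed:
                aim = _rotate_about(n_t, n_r, -a)
            elif session == "TFR" and learner.group == "extrinsic":
                # extrinsically stored rotation transfers to the new start
                aim = _rotate_about(n_t, n_r, -a)
            else:
                # intrinsic learning does not survive the 90-degree change of
                # initial orientation; control never changes orientation but
                # faces an orthogonal target (narrow generalization)
                aim = n_t
            aim = _jitter_direction(aim, learner.motor_noise_sd, rng)
            spec = TrialSpec(
                q1=q1,
                target_axis=aim,
                target_angle=ref.EXP2_TARGET_ANGLE,
                duration=float(rng.uniform(*DURATION_RANGE_S)),
                rate=rate,
                frame="extrinsic",
                noise_axis_sd=axis_noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            traj = gen_noisy_trial(spec)
            cursor = render_cursor(traj, vr) if (perturbed and render_cursors) else None
            trials.append(
                Trial(
                    index=index,
                    session=session,
                    group=learner.group,
                    trajectory=traj,
                    q1=q1,
                    target_axis=aim,
                    target_angle=ref.EXP2_TARGET_ANGLE,
                    perturbed=perturbed,
                    cursor=cursor,
                    adaptation_state=a,
                )
            )
            if perturbed:
                a += learner.learn_rate * (learner.asymptote - a)
            elif session == "TFR":
                a *= learner.retention
    return trials


def ideal_axes_for(group: str, frame: str = "intrinsic", rate: float = DEFAULT_RATE_HZ) -> dict[str, np.ndarray]:
    """Ideal (baseline) aiming axes of both BL sets, in the measurement frame.

    Computed self-consistently by generating a noise-free geodetic trial of
    each baseline session and measuring its aiming axis with the same
    pipeline used for data.
    """
    geometry = _session_geometry(group)
    out = {}
    for bl in ("BL1", "BL2"):
        q1, axis, axframe, _ = geometry[bl]
        spec = TrialSpec(
            q1=q1, target_axis=axis, target_angle=ref.EXP2_TARGET_ANGLE,
            duration=0.5, rate=rate, frame=axframe,
        )
        out[bl] = aiming_axis(gen_geodetic_trial(spec), frame=frame).axis
    return out


def measurement_perturbation_axis(q1) -> np.ndarray:
    """Perturbation axis expressed in the pre-rotated (trial-start) frame.

    Analysis pre-rotates every trial by ``q1^-1``, which conjugates
    extrinsic axes; both protocol initial orientations are rotations about
    x, so the perturbation axis stays x, but this helper keeps the general
    case explicit.
    """
    return qc.rotate_vector(qc.conjugate(np.asarray(q1, dtype=float)), ref.PERTURBATION_AXIS)
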