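"""The Quaternion Geodicity Score (QGS) and its summary statistics.

The QGS of a sampled orientation trajectory ``{q_i}`` is the swept angular
path length divided by the endpoint angular distance::

    QGS = sum_i dist(q_i, q_{i+1}) / dist(q_1, q_N)

A movement that follows the geodesic (great arc) between its endpoints has
QGS = 1 exactly (the distances telescope); any deviation from the great
arc lengthens the path on the 3-sphere and yields QGS > 1.  The score is
invariant to a global pre-rotation of the whole trajectory and to sign
flips of individual samples, which makes it a frame-robust measure of
rotational path straightness.

A movement is classified as "geodetic enough" when its QGS falls below a
threshold of 1.2: with the task's typical 50-degree rotations this allows
roughly a 10-degree detour in swept angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quatcore as qc
from .preprocess import OrientationTrajectory

__all__ = [
    "GEODETIC_THRESHOLD",
    "DegenerateTrialError",
    "GeodicityResult",
    "qgs",
    "median_qgs_ci",
    "classify_geodetic",
]

#: QGS below this value counts as a geodetic movement.
GEODETIC_THRESHOLD = 1.2

#: Endpoints closer than this (radians) make the score ill-conditioned.
MIN_ENDPOINT_DISTANCE = 1e-6


class DegenerateTrialError(ValueError):
    """Endpoints (nearly) coincide; the score denominator vanishes."""


class InvalidScoreError(ValueError):
    """A QGS value below 1 beyond numerical tolerance was supplied."""


@dataclass(frozen=True)
class GeodicityResult:
    """QGS with its numerator/denominator, for inspection and reporting."""

    qgs: float
    path_length: float
    endpoint_distance: float
    n_samples: int


def _quat_array(traj) -> np.ndarray:
    if isinstance(traj, OrientationTrajectory):
        return traj.q
    q = np.asarray(traj, dtype=float)
    if q.ndim != 2 or q.shape[1] != 4:
        raise ValueError("expected an OrientationTrajectory or an (N, 4) quaternion array")
    return q


def qgs(traj, window: tuple[int, int] | None = None) -> GeodicityResult:
    """Quaternion Geodicity Score of a trajectory (optionally windowed).

    Parameters
    ----------
    traj : OrientationTrajectory or (N, 4) array
        Quaternion samples, scalar first.
    window : (start, stop), optional
        Inclusive index pair restricting the score to a sub-trajectory,
        e.g. ``(onset, peak_speed_index)`` for fast-rotation trials or
        ``(onset, offset)`` from segmentation.  Default: the full trajectory.

    Raises
    ------
    DegenerateTrialError
        If the endpoint angular distance is below 1e-6 rad.
    """
    q = _quat_array(traj)
    if window is not None:
        start, stop = window
        if not (0 <= start < stop < len(q)):
            raise ValueError(f"invalid window {window} for trajectory of length {len(q)}")
        q = q[start : stop + 1]
    if len(q) < 2:
        raise ValueError("need at least two samples to score a trajectory")
    steps = qc.quat_distance(q[:-1], q[1:])
    path = float(np.sum(steps))
    endpoint = float(qc.quat_distance(q[0], q[-1]))
    if endpoint < MIN_ENDPOINT_DISTANCE:
        raise DegenerateTrialError(
            f"endpoint distance {endpoint:.2e} rad is below {MIN_ENDPOINT_DISTANCE}; score undefined"
        )
    return GeodicityResult(
        qgs=path / endpoint,
        path_length=path,
        endpoint_distance=endpoint,
        n_samples=len(q),
    )


def median_qgs_ci(
    scores,
    n_boot: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """Sample median with a percentile-bootstrap 95% confidence interval.

    QGS distributions are strongly right-skewed, so the median is the
    appropriate centre and the CI comes from the 2.5/97.5 percentiles of
    ``n_boot`` resampled medians.  An explicit seed makes runs reproducible.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) == 0:
        raise ValueError("scores must be a nonempty 1-D array")
    if len(scores) < 2:
        raise ValueError("need at least two scores for a bootstrap CI")
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(scores), size=(n_boot, len(scores)))
    medians = np.median(scores[idx], axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return float(np.median(scores)), float(lo), float(hi)


def classify_geodetic(score: float, threshold: float = GEODETIC_THRESHOLD) -> bool:
    """True iff ``score < threshold`` (strict; a score equal to it is not geodetic)."""
    if score < 1.0 - 1e-9:
        raise InvalidScoreError(f"QGS {score} is below 1, which no trajectory can attain")
    return bool(score < threshold)
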