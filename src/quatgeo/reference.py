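"""Task-geometry constants for the orientation-matching experiments.

These are the fixed orientations, rotation axes and perturbation
parameters of the two experimental designs the analysis pipeline targets:

* **Orientation matching** (experiment 1): trials start from one of two
  initial orientations (``EXP1_O1``, ``EXP1_O2``) or end at one of two
  target orientations (``EXP1_T1``, ``EXP1_T2``); targets are produced by
  rotating 40-60 degrees about axes aligned or misaligned with the
  extrinsic/intrinsic reference frames.

* **Visuomotor-rotation adaptation** (experiment 2): trials rotate
  50 degrees from either the unrotated hand orientation ``EXP2_O1``
  (the identity) or ``EXP2_O2`` (90 degrees about x); the extrinsic-group
  ideal axis is ``AXIS_EXTRINSIC_GROUP = (-j + k)/sqrt(2)``, the
  intrinsic-group ideal axis ``AXIS_INTRINSIC_GROUP = (j + k)/sqrt(2)``,
  and training applies a 60-degree perturbation about x with an 80-sample
  delay at the 4 kHz haptic rate (20 ms).

The four experiment-1 orientations are published to two decimal places,
which leaves their norms off unity by about 1e-3; they are renormalized
here and the residual is recorded in ``EXP1_NORM_RESIDUALS``.
"""

from __future__ import annotations

import numpy as np

from . import quatcore as qc
from .perturb import VisuomotorRotation

__all__ = [
    "EXP1_O1",
    "EXP1_O2",
    "EXP1_T1",
    "EXP1_T2",
    "EXP1_NORM_RESIDUALS",
    "EXP1_ALIGNED_AXES",
    "EXP1_MISALIGNED_AXES",
    "EXP2_O1",
    "EXP2_O2",
    "AXIS_EXTRINSIC_GROUP",
    "AXIS_INTRINSIC_GROUP",
    "PERTURBATION_ANGLE",
    "PERTURBATION_AXIS",
    "HAPTIC_RATE_HZ",
    "VISUAL_DELAY_SAMPLES",
    "training_perturbation",
]

_SQ2 = np.sqrt(2.0) / 2.0


def _published(vals) -> tuple[np.ndarray, float]:
    q = np.asarray(vals, dtype=float)
    residual = float(abs(np.linalg.norm(q) - 1.0))
    return qc.normalize(q), residual


# experiment-1 fixed orientations (published to 2 decimals; renormalized)
EXP1_O1, _r1 = _published([0.92, 0.33, -0.06, 0.16])
EXP1_O2, _r2 = _published([0.92, 0.16, -0.06, 0.33])
EXP1_T1, _r3 = _published([0.84, -0.13, -0.22, 0.48])
EXP1_T2, _r4 = _published([0.90, -0.04, -0.08, 0.42])

#: |norm - 1| of the published values before renormalization (~1e-3).
EXP1_NORM_RESIDUALS = {"o1": _r1, "o2": _r2, "t1": _r3, "t2": _r4}

#: Rotation axes aligned with a reference frame (unit basis vectors).
EXP1_ALIGNED_AXES = np.array(
    [
        [1.0, 0.0, 0.0],   # x
        [0.0, -1.0, 0.0],  # -y
        [0.0, 0.0, 1.0],   # z
    ]
)

#: Rotation axes misaligned with the reference frames (45-degree diagonals).
EXP1_MISALIGNED_AXES = np.array(
    [
        [_SQ2, 0.0, _SQ2],    # (x + z)/sqrt2
        [0.0, -_SQ2, _SQ2],   # (-y + z)/sqrt2
        [_SQ2, -_SQ2, 0.0],   # (x - y)/sqrt2
    ]
)

#: Experiment-2 initial orientations: unrotated hand, and 90 degrees about x.
EXP2_O1 = qc.IDENTITY.copy()
EXP2_O2 = qc.from_axis_angle([1.0, 0.0, 0.0], np.pi / 2)

#: Ideal rotation axis of the extrinsic group: (-j + k)/sqrt(2).
AXIS_EXTRINSIC_GROUP = np.array([0.0, -_SQ2, _SQ2])

#: Ideal rotation axis of the intrinsic group: (j + k)/sqrt(2).
AXIS_INTRINSIC_GROUP = np.array([0.0, _SQ2, _SQ2])

#: Training perturbation: 60 degrees about x.
PERTURBATION_ANGLE = np.deg2rad(60.0)
PERTURBATION_AXIS = np.array([1.0, 0.0, 0.0])

#: Haptic loop rate and visual delay (80 samples at 4 kHz = 20 ms).
HAPTIC_RATE_HZ = 4000.0
VISUAL_DELAY_SAMPLES = 80

#: Exp-2 target rotation magnitude (50 degrees) and exp-1 range (40-60).
EXP2_TARGET_ANGLE = np.deg2rad(50.0)
EXP1_TARGET_RANGE = (np.deg2rad(40.0), np.deg2rad(60.0))


def training_perturbation(rate: float = HAPTIC_RATE_HZ) -> VisuomotorRotation:
    """The training perturbation with its delay expressed at ``rate`` Hz."""
    delay = int(round(VISUAL_DELAY_SAMPLES * rate / HAPTIC_RATE_HZ))
    return VisuomotorRotation(
        angle=PERTURBATION_ANGLE,
        axis=PERTURBATION_AXIS.copy(),
        delay_samples=delay,
        source_rate=rate,
    )
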