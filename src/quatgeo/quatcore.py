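"""Unit-quaternion algebra on the 3-sphere.

Rotations of a rigid body are represented by unit quaternions
``q = s + x i + y j + z k`` stored scalar-first as length-4 arrays
``[s, x, y, z]``.  The set of unit quaternions forms the 3-sphere, and a
quaternion ``q`` and its negation ``-q`` encode the same rotation (the
double cover of SO(3)).  This module provides the exact algebra the rest
of the package is built on: Hamilton products, vector rotation, the
angular distance between rotations, geodesics (great arcs) on the
3-sphere, per-step transition quaternions in extrinsic (space-fixed) or
intrinsic (body-fixed) coordinates, robust rotation-matrix conversion,
and sign-continuity enforcement for sampled trajectories.

All functions accept batched inputs: a quaternion argument may be shape
``(4,)`` or ``(..., 4)``, vectors ``(3,)`` or ``(..., 3)``, and operations
broadcast in the usual NumPy way.

Conventions
-----------
* Component order is scalar-first ``(s, x, y, z)`` everywhere, including
  file I/O.
* Constructors (:func:`from_axis_angle`, :func:`from_rotation_matrix`)
  return the hemisphere with ``s >= 0``.  Sampled trajectories instead
  use :func:`enforce_continuity`, because temporal continuity matters
  more than a canonical sign for curves.
* The angular distance ``dist(q1, q2) = 2 arccos|Re(q2 q1^-1)|`` lies in
  ``[0, pi]`` and is invariant to the sign of either argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "IDENTITY",
    "UNIT_TOL",
    "ANTIPODAL_TOL",
    "QuaternionError",
    "InvalidAxisError",
    "InvalidRotationError",
    "UndefinedGeodesicError",
    "AxisAngle",
    "TransitionQuaternion",
    "normalize",
    "from_axis_angle",
    "to_axis_angle",
    "multiply",
    "conjugate",
    "rotate_vector",
    "quat_distance",
    "power",
    "geodesic",
    "transition",
    "from_rotation_matrix",
    "to_rotation_matrix",
    "enforce_continuity",
    "random_quaternion",
]

#: Tolerance within which quaternions are required/guaranteed to be unit norm.
UNIT_TOL = 1e-9

#: Endpoints closer than ``pi - ANTIPODAL_TOL`` to antipodal have no unique
#: geodesic and raise :class:`UndefinedGeodesicError`.
ANTIPODAL_TOL = 1e-6

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])

FRAMES = ("extrinsic", "intrinsic")


class QuaternionError(ValueError):
    """Base class for quaternion-domain errors."""


class InvalidAxisError(QuaternionError):
    """A rotation axis with (near-)zero norm was supplied with a nonzero angle."""


class InvalidRotationError(QuaternionError):
    """A matrix that is not a proper rotation (orthonormal, det = +1)."""


class UndefinedGeodesicError(QuaternionError):
    """Geodesic between (near-)antipodal endpoints is not unique."""


class AxisAngle(NamedTuple):
    """Axis-angle decomposition: unit axis and angle in radians, [0, pi]."""

    axis: np.ndarray
    angle: float | np.ndarray


@dataclass(frozen=True)
class TransitionQuaternion:
    """Per-step rotation taking ``q_i`` to ``q_{i+1}``.

    ``value`` holds the transition quaternion(s); ``frame`` declares whether
    the successor is reconstructed by left multiplication (extrinsic,
    ``q_{i+1} = q^d q_i``) or right multiplication (intrinsic,
    ``q_{i+1} = q_i q^d``).  Both frames share the same rotation angle.
    """

    value: np.ndarray
    frame: str

    @property
    def axis(self) -> np.ndarray:
        return to_axis_angle(self.value).axis

    @property
    def angle(self) -> float | np.ndarray:
        return to_axis_angle(self.value).angle


def _check_frame(frame: str) -> None:
    if frame not in FRAMES:
        raise ValueError(f"frame must be one of {FRAMES}, got {frame!r}")


def _as_quat(q) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if q.shape[-1] != 4:
        raise QuaternionError(f"quaternion must have last dimension 4, got shape {q.shape}")
    return q


def normalize(q) -> np.ndarray:
    """Rescale to unit norm (does not canonicalize sign)."""
    q = _as_quat(q)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < 1e-300):
        raise QuaternionError("cannot normalize a zero quaternion")
    return q / n


def from_axis_angle(axis, angle) -> np.ndarray:
    """Quaternion ``cos(theta/2) + n sin(theta/2)`` for rotation ``theta`` about ``n``.

    The axis is normalized internally; a (near-)zero axis is only legal for a
    zero angle, in which case the identity is returned.  The result is
    canonicalized to the ``s >= 0`` hemisphere.
    """
    axis = np.asarray(axis, dtype=float)
    angle = np.asarray(angle, dtype=float)
    if axis.shape[-1] != 3:
        raise InvalidAxisError(f"axis must have last dimension 3, got shape {axis.shape}")
    if not np.all(np.isfinite(angle)):
        raise QuaternionError("angle must be finite")
    n = np.linalg.norm(axis, axis=-1)
    zero_axis = n < 1e-12
    if np.any(zero_axis & (np.abs(angle) > 1e-12)):
        raise InvalidAxisError("zero axis supplied with a nonzero rotation angle")
    safe_n = np.where(zero_axis, 1.0, n)
    unit = axis / safe_n[..., None]
    half = angle / 2.0
    q = np.concatenate(
        [np.cos(half)[..., None], unit * np.sin(half)[..., None]], axis=-1
    )
    # canonical hemisphere: s >= 0
    sign = np.where(q[..., 0] < 0.0, -1.0, 1.0)
    return normalize(q * sign[..., None])


def to_axis_angle(q) -> AxisAngle:
    """Decompose into unit axis and rotation angle in ``[0, pi]``.

    Sign-invariant: ``q`` and ``-q`` yield the same decomposition.  For a
    (near-)identity rotation the axis is ill-defined and defaults to ``x``.
    """
    q = _as_quat(q)
    q = q * np.where(q[..., 0] < 0.0, -1.0, 1.0)[..., None]
    vnorm = np.linalg.norm(q[..., 1:], axis=-1)
    angle = 2.0 * np.arctan2(vnorm, q[..., 0])
    small = vnorm < 1e-12
    safe = np.where(small, 1.0, vnorm)
    axis = q[..., 1:] / safe[..., None]
    default = np.zeros_like(axis)
    default[..., 0] = 1.0
    axis = np.where(small[..., None], default, axis)
    if angle.ndim == 0:
        return AxisAngle(axis, float(angle))
    return AxisAngle(axis, angle)


def multiply(a, b) -> np.ndarray:
    """Hamilton product ``a (x) b`` (renormalized to unit norm)."""
    a = _as_quat(a)
    b = _as_quat(b)
    s1, x1, y1, z1 = (a[..., i] for i in range(4))
    s2, x2, y2, z2 = (b[..., i] for i in range(4))
    out = np.stack(
        [
            s1 * s2 - x1 * x2 - y1 * y2 - z1 * z2,
            s1 * x2 + x1 * s2 + y1 * z2 - z1 * y2,
            s1 * y2 - x1 * z2 + y1 * s2 + z1 * x2,
            s1 * z2 + x1 * y2 - y1 * x2 + z1 * s2,
        ],
        axis=-1,
    )
    return normalize(out)


def conjugate(q) -> np.ndarray:
    """Conjugate ``q* = s - xi - yj - zk``; the inverse of a unit quaternion."""
    q = _as_quat(q)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def rotate_vector(q, p) -> np.ndarray:
    """Rotate 3-vector(s) ``p`` by ``q``: the vector part of ``q (0,p) q^-1``.

    Uses the expanded form ``p + 2 s (v x p) + 2 v x (v x p)`` which avoids
    building intermediate quaternions; preserves the norm of ``p``.
    """
    q = _as_quat(q)
    p = np.asarray(p, dtype=float)
    if p.shape[-1] != 3:
        raise QuaternionError(f"vector must have last dimension 3, got shape {p.shape}")
    s = q[..., :1]
    v = q[..., 1:]
    cvp = np.cross(v, p)
    return p + 2.0 * s * cvp + 2.0 * np.cross(v, cvp)


def _dot4(q1, q2) -> np.ndarray:
    return np.sum(q1 * q2, axis=-1)


def quat_distance(q1, q2):
    """Angular distance ``2 arccos|Re(q2 q1^-1)|`` between two rotations.

    For unit quaternions ``Re(q2 q1^*)`` equals the 4-vector inner product,
    so the distance reduces to ``2 arccos|<q1, q2>|``.  Symmetric in its
    arguments, sign-invariant (``dist(q, -q) = 0``) and bounded to
    ``[0, pi]``.

    Evaluated in the numerically robust arctangent form
    ``4 arctan2(||q1 - q2'||, ||q1 + q2'||)`` (with ``q2'`` sign-aligned to
    ``q1``), which keeps full precision for nearby rotations where the
    arccosine loses half the significant digits.
    """
    q1 = _as_quat(q1)
    q2 = _as_quat(q2)
    q2 = q2 * np.where(_dot4(q1, q2) < 0.0, -1.0, 1.0)[..., None]
    dm = np.linalg.norm(q1 - q2, axis=-1)
    dp = np.linalg.norm(q1 + q2, axis=-1)
    out = 4.0 * np.arctan2(dm, dp)
    return float(out) if out.ndim == 0 else out


def power(q, h) -> np.ndarray:
    """Quaternion power ``q^h`` along the shortest arc from the identity.

    Computed via the axis-angle (exp/log) maps with a series fallback for
    near-identity rotations where the axis is numerically 0/0.  The input is
    first mapped to the ``s >= 0`` hemisphere so the rotation angle lies in
    ``[0, pi]``.
    """
    q = _as_quat(q)
    h = np.asarray(h, dtype=float)
    q = q * np.where(q[..., 0] < 0.0, -1.0, 1.0)[..., None]
    vnorm = np.linalg.norm(q[..., 1:], axis=-1)
    half = np.arctan2(vnorm, q[..., 0])  # theta/2 in [0, pi/2]
    newhalf = h * half
    s = np.cos(newhalf)
    # for unit q, |v| = sin(theta/2); q^h has vector part v * sin(h theta/2)/sin(theta/2)
    sin_half = np.sin(half)
    small = sin_half < 1e-8
    ratio = np.where(small, np.broadcast_to(h, np.asarray(newhalf).shape),
                     np.sin(newhalf) / np.where(small, 1.0, sin_half))
    out = np.concatenate(
        [np.asarray(s)[..., None], q[..., 1:] * np.asarray(ratio)[..., None]], axis=-1
    )
    return normalize(out)


def geodesic(q1, qN, h) -> np.ndarray:
    """Point(s) on the shortest great arc from ``q1`` to ``qN``.

    Implements ``q1 (q1^* qN)^h``; ``h = 0`` returns ``q1`` and ``h = 1``
    returns ``qN`` (up to the quaternion sign, which is irrelevant to the
    rotation).  The sign of ``qN`` is chosen so the arc is the shorter of the
    two double-cover representatives.  ``h`` may be a scalar or an array, in
    which case a batch of interpolants is returned.

    Raises
    ------
    UndefinedGeodesicError
        If the endpoints are antipodal within :data:`ANTIPODAL_TOL`.
    """
    q1 = _as_quat(q1)
    qN = _as_quat(qN)
    d = _dot4(q1, qN)
    qN = qN * np.where(d < 0.0, -1.0, 1.0)[..., None]
    if np.any(quat_distance(q1, qN) >= np.pi - ANTIPODAL_TOL):
        raise UndefinedGeodesicError("geodesic between antipodal endpoints is not unique")
    rel = multiply(conjugate(q1), qN)
    h = np.asarray(h, dtype=float)
    if h.ndim > 0 and q1.ndim == 1:
        rel = np.broadcast_to(rel, h.shape + (4,))
        q1 = np.broadcast_to(q1, h.shape + (4,))
    return multiply(q1, power(rel, h))


def transition(q_i, q_next, frame: str = "extrinsic") -> TransitionQuaternion:
    """Transition quaternion taking ``q_i`` to ``q_next`` in the declared frame.

    extrinsic: ``q^d = q_next q_i^-1`` (so ``q_next = q^d q_i``);
    intrinsic: ``q^d = q_i^-1 q_next`` (so ``q_next = q_i q^d``).
    The two share the same rotation angle but generally different axes.
    """
    _check_frame(frame)
    q_i = _as_quat(q_i)
    q_next = _as_quat(q_next)
    if frame == "extrinsic":
        value = multiply(q_next, conjugate(q_i))
    else:
        value = multiply(conjugate(q_i), q_next)
    return TransitionQuaternion(value=value, frame=frame)


def from_rotation_matrix(R) -> np.ndarray:
    """Convert proper rotation matrix/matrices ``(..., 3, 3)`` to quaternions.

    Uses Shepperd's method, selecting the branch with the largest pivot of
    ``(trace, R00, R11, R22)`` per matrix for numerical stability near
    half-turns.  The result is canonicalized to ``s >= 0``.

    Raises
    ------
    InvalidRotationError
        If ``R^T R`` deviates from the identity by more than 1e-6 or
        ``det(R)`` deviates from +1 by more than 1e-6.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise InvalidRotationError(f"expected (..., 3, 3) matrix, got shape {R.shape}")
    eye_err = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max(axis=(-2, -1))
    det_err = np.abs(np.linalg.det(R) - 1.0)
    if np.any(eye_err > 1e-6):
        raise InvalidRotationError("matrix is not orthonormal within 1e-6")
    if np.any(det_err > 1e-6):
        raise InvalidRotationError("matrix determinant differs from +1 by more than 1e-6")

    single = R.ndim == 2
    Rb = R.reshape(-1, 3, 3)
    n = Rb.shape[0]
    q = np.empty((n, 4))
    tr = np.trace(Rb, axis1=-2, axis2=-1)
    diag = np.diagonal(Rb, axis1=-2, axis2=-1)
    # candidate pivots: trace and the three diagonal entries
    choice = np.argmax(np.column_stack([tr, diag]), axis=1)
    for k in range(n):
        r = Rb[k]
        c = choice[k]
        if c == 0:
            t = 1.0 + tr[k]
            s = 0.5 / np.sqrt(t)
            q[k] = [0.5 * np.sqrt(t), (r[2, 1] - r[1, 2]) * s, (r[0, 2] - r[2, 0]) * s, (r[1, 0] - r[0, 1]) * s]
        else:
            i = c - 1
            j, l = (i + 1) % 3, (i + 2) % 3
            t = 1.0 + r[i, i] - r[j, j] - r[l, l]
            s = 0.5 / np.sqrt(t)
            qv = np.empty(4)
            qv[0] = (r[l, j] - r[j, l]) * s
            qv[1 + i] = 0.5 * np.sqrt(t)
            qv[1 + j] = (r[j, i] + r[i, j]) * s
            qv[1 + l] = (r[l, i] + r[i, l]) * s
            q[k] = qv
    q *= np.where(q[:, 0] < 0.0, -1.0, 1.0)[:, None]
    q = normalize(q)
    if single:
        return q[0]
    return q.reshape(R.shape[:-2] + (4,))


def to_rotation_matrix(q) -> np.ndarray:
    """Convert quaternion(s) to rotation matrix/matrices ``(..., 3, 3)``."""
    q = normalize(_as_quat(q))
    s, x, y, z = (q[..., i] for i in range(4))
    row0 = np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - s * z), 2 * (x * z + s * y)], axis=-1)
    row1 = np.stack([2 * (x * y + s * z), 1 - 2 * (x * x + z * z), 2 * (y * z - s * x)], axis=-1)
    row2 = np.stack([2 * (x * z - s * y), 2 * (y * z + s * x), 1 - 2 * (x * x + y * y)], axis=-1)
    return np.stack([row0, row1, row2], axis=-2)


def enforce_continuity(q) -> np.ndarray:
    """Flip quaternion signs so successive 4-vector dot products are >= 0.

    Because ``q`` and ``-q`` are the same rotation, a recorded sequence may
    hop between hemispheres; this removes the hops without changing any
    rotation or any pairwise angular distance.  The first sample's sign is
    kept as given.
    """
    q = _as_quat(q)
    if q.ndim != 2:
        raise QuaternionError("expected an (N, 4) quaternion sequence")
    if len(q) == 0:
        raise QuaternionError("empty quaternion sequence")
    dots = _dot4(q[:-1], q[1:])
    flips = np.concatenate([[1.0], np.cumprod(np.where(dots < 0.0, -1.0, 1.0))])
    return q * flips[:, None]


def random_quaternion(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniform random rotation(s) (Haar measure on SO(3)) for simulations."""
    size = (4,) if n is None else (n, 4)
    g = rng.standard_normal(size)
    return normalize(g)
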