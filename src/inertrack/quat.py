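"""Rotation and pose algebra: unit quaternions, DH transforms, TRIAD.

Conventions used throughout the package:

* quaternions are stored ``(w, x, y, z)`` (scalar first), Hamilton product,
  active rotations;
* ``q_AB`` rotates vectors from frame B into frame A, i.e.
  ``v_A = R(q_AB) @ v_B``;
* :func:`qexp` maps a *half-angle* rotation vector ``v`` to the unit
  quaternion ``(cos|v|, sin|v| * v/|v|)``, so ``qexp(0.5*T*omega)`` advances
  an orientation by ``T*|omega|`` radians and ``2*qlog(q)`` is the full
  rotation vector of ``q``.

All functions broadcast over leading axes: a "quaternion array" has shape
``(..., 4)`` and a "vector array" has shape ``(..., 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "UnitQuaternion",
    "RigidTransform",
    "qmul",
    "qconj",
    "qnormalize",
    "qexp",
    "qlog",
    "qrotate",
    "quat_to_matrix",
    "matrix_to_quat",
    "skew",
    "dh_matrix",
    "dh_transform",
    "triad",
    "rotation_angle",
    "random_quaternion",
]

_EPS = 1e-12


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊙ b`` (broadcasting, renormalized not applied)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = a[..., 0], a[..., 1], a[..., 2], a[..., 3]
    bw, bx, by, bz = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    """Quaternion conjugate; the inverse rotation for unit quaternions."""
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] = -out[..., 1:]
    return out


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    n = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(n < _EPS):
        raise ValueError("cannot normalize a zero-norm quaternion")
    return q / n


def qexp(v: np.ndarray) -> np.ndarray:
    """Quaternion exponential of a half-angle rotation vector.

    ``qexp(v) = (cos|v|, sin|v| v/|v|)``; the small-angle limit is handled
    with the series ``sin(x)/x = 1 - x^2/6 + ...`` so the map is smooth at 0.
    """
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    small = n[..., 0] < 1e-8
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(small[..., None], 1.0 - n * n / 6.0, np.sin(n) / np.where(n == 0, 1.0, n))
    w = np.cos(n[..., 0])
    return np.concatenate([w[..., None], s * v], axis=-1)


def qlog(q: np.ndarray) -> np.ndarray:
    """Half-angle rotation vector ``v`` with ``qexp(v) = ±q`` and ``2|v| <= pi``.

    The sign is chosen so that the scalar part is non-negative (shortest
    rotation), acknowledging the double cover q ~ -q.
    """
    q = np.asarray(q, dtype=float)
    q = np.where(q[..., :1] < 0.0, -q, q)
    w = np.clip(q[..., 0], -1.0, 1.0)
    vn = np.linalg.norm(q[..., 1:], axis=-1)
    ang = np.arctan2(vn, w)  # in [0, pi/2] given w >= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(vn < 1e-12, 1.0 + ang * ang / 6.0, ang / np.where(vn == 0, 1.0, vn))
    return scale[..., None] * q[..., 1:]


def qrotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vector(s) ``v`` by quaternion(s) ``q``: ``R(q) @ v``."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    u = q[..., 1:]
    w = q[..., :1]
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of ``q``; output shape ``(..., 3, 3)``."""
    q = np.asarray(q, dtype=float)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    out = np.empty(q.shape[:-1] + (3, 3))
    out[..., 0, 0] = 1 - 2 * (y * y + z * z)
    out[..., 0, 1] = 2 * (x * y - w * z)
    out[..., 0, 2] = 2 * (x * z + w * y)
    out[..., 1, 0] = 2 * (x * y + w * z)
    out[..., 1, 1] = 1 - 2 * (x * x + z * z)
    out[..., 1, 2] = 2 * (y * z - w * x)
    out[..., 2, 0] = 2 * (x * z - w * y)
    out[..., 2, 1] = 2 * (y * z + w * x)
    out[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return out


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Unit quaternion of a rotation matrix (Shepperd's method, stable)."""
    R = np.asarray(R, dtype=float)
    if R.ndim == 2:
        return _matrix_to_quat_single(R)
    flat = R.reshape(-1, 3, 3)
    out = np.array([_matrix_to_quat_single(m) for m in flat])
    return out.reshape(R.shape[:-2] + (4,))


def _matrix_to_quat_single(R: np.ndarray) -> np.ndarray:
    tr = np.trace(R)
    if tr > 0:
        s = np.sqrt(tr + 1.0) * 2
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s, (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        if i == 0:
            s = np.sqrt(1.0 + R[0, 0] - R[1, 1] - R[2, 2]) * 2
            q = np.array(
                [(R[2, 1] - R[1, 2]) / s, 0.25 * s, (R[0, 1] + R[1, 0]) / s, (R[0, 2] + R[2, 0]) / s]
            )
        elif i == 1:
            s = np.sqrt(1.0 + R[1, 1] - R[0, 0] - R[2, 2]) * 2
            q = np.array(
                [(R[0, 2] - R[2, 0]) / s, (R[0, 1] + R[1, 0]) / s, 0.25 * s, (R[1, 2] + R[2, 1]) / s]
            )
        else:
            s = np.sqrt(1.0 + R[2, 2] - R[0, 0] - R[1, 1]) * 2
            q = np.array(
                [(R[1, 0] - R[0, 1]) / s, (R[0, 2] + R[2, 0]) / s, (R[1, 2] + R[2, 1]) / s, 0.25 * s]
            )
    q = q / np.linalg.norm(q)
    return q if q[0] >= 0 else -q


def rotvec_from_matrix(R: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle, radians) of rotation matrices.

    Vectorized over leading axes; accurate away from 180 deg (the axis is
    taken from the skew part), which suffices for per-sample increments.
    """
    R = np.asarray(R, dtype=float)
    v = 0.5 * np.stack(
        [R[..., 2, 1] - R[..., 1, 2], R[..., 0, 2] - R[..., 2, 0], R[..., 1, 0] - R[..., 0, 1]],
        axis=-1,
    )
    s = np.linalg.norm(v, axis=-1)  # sin(angle)
    c = 0.5 * (R[..., 0, 0] + R[..., 1, 1] + R[..., 2, 2] - 1.0)  # cos(angle)
    ang = np.arctan2(s, c)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(s < 1e-12, 1.0 + ang * ang / 6.0, ang / np.where(s == 0, 1.0, s))
    return scale[..., None] * v


def skew(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrix: ``skew(v) @ w == cross(v, w)``."""
    v = np.asarray(v, dtype=float)
    out = np.zeros(v.shape[:-1] + (3, 3))
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def rotation_angle(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Relative rotation angle between unit quaternions, in degrees.

    ``2*acos(|(a ⊙ b*)_w|)`` in ``[0, 180]``; the absolute value of the
    scalar part handles the double cover so sign-flipped quaternions compare
    equal, and the result is symmetric in its arguments.
    """
    d = qmul(np.asarray(a, dtype=float), qconj(b))
    w = np.clip(np.abs(d[..., 0]), -1.0, 1.0)
    return np.degrees(2.0 * np.arccos(w))


def dh_matrix(d: float, a: float, alpha: float, theta: float) -> np.ndarray:
    """Classic Denavit-Hartenberg homogeneous transform as a 4x4 matrix.

    ``Rot_z(theta) · Trans_z(d) · Trans_x(a) · Rot_x(alpha)``.
    """
    ct, st = np.cos(theta), np.sin(theta)
    ca, sa = np.cos(alpha), np.sin(alpha)
    return np.array(
        [
            [ct, -st * ca, st * sa, a * ct],
            [st, ct * ca, -ct * sa, a * st],
            [0.0, sa, ca, d],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def triad(y_a: np.ndarray, y_m: np.ndarray) -> np.ndarray:
    """TRIAD attitude from one accelerometer and one magnetometer sample.

    Returns ``q_GI`` such that the measured specific-force direction maps to
    global +z (up, opposite gravity) and the horizontal projection of the
    magnetic measurement maps to global +x.

    Raises ``ValueError`` for (near-)parallel inputs, where the heading is
    unobservable.
    """
    y_a = np.asarray(y_a, dtype=float)
    y_m = np.asarray(y_m, dtype=float)
    na, nm = np.linalg.norm(y_a), np.linalg.norm(y_m)
    if na < _EPS or nm < _EPS:
        raise ValueError("TRIAD requires non-zero reference vectors")
    up = y_a / na  # global z expressed in the IMU frame
    m = y_m / nm
    x_i = m - np.dot(m, up) * up  # horizontal part of the field, IMU frame
    nx = np.linalg.norm(x_i)
    if nx < 1e-8:
        raise ValueError("TRIAD degenerate: accelerometer and magnetometer are parallel")
    x_i /= nx
    y_i = np.cross(up, x_i)
    # columns of R_IG are the global axes in IMU coordinates
    R_ig = np.stack([x_i, y_i, up], axis=-1)
    return matrix_to_quat(R_ig.T)


def random_quaternion(rng: np.random.Generator, n: int | None = None) -> np.ndarray:
    """Uniform random unit quaternion(s) (w >= 0 hemisphere not enforced)."""
    shape = (4,) if n is None else (n, 4)
    q = rng.standard_normal(shape)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


@dataclass(frozen=True)
class UnitQuaternion:
    """Thin value-type wrapper over a ``(4,)`` wxyz array.

    Most internals operate on raw arrays (see the module functions); this
    class is the convenient public surface for single rotations.
    """

    wxyz: np.ndarray

    def __post_init__(self) -> None:
        arr = qnormalize(np.asarray(self.wxyz, dtype=float).reshape(4))
        object.__setattr__(self, "wxyz", arr)

    @classmethod
    def identity(cls) -> "UnitQuaternion":
        return cls(np.array([1.0, 0.0, 0.0, 0.0]))

    @classmethod
    def from_axis_angle(cls, axis: np.ndarray, angle_rad: float) -> "UnitQuaternion":
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        return cls(qexp(0.5 * angle_rad * axis))

    @classmethod
    def exp(cls, v: np.ndarray) -> "UnitQuaternion":
        return cls(qexp(v))

    def log(self) -> np.ndarray:
        return qlog(self.wxyz)

    def __mul__(self, other: "UnitQuaternion") -> "UnitQuaternion":
        return UnitQuaternion(qmul(self.wxyz, other.wxyz))

    def conjugate(self) -> "UnitQuaternion":
        return UnitQuaternion(qconj(self.wxyz))

    def rotate(self, v: np.ndarray) -> np.ndarray:
        return qrotate(self.wxyz, v)

    def to_matrix(self) -> np.ndarray:
        return quat_to_matrix(self.wxyz)

    @classmethod
    def from_matrix(cls, R: np.ndarray) -> "UnitQuaternion":
        return cls(matrix_to_quat(R))

    def angle_to(self, other: "UnitQuaternion") -> float:
        return float(rotation_angle(self.wxyz, other.wxyz))


@dataclass(frozen=True)
class RigidTransform:
    """Pose ``{q, t}``: rotation plus translation, composing like 4x4 matrices."""

    q: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0, 0.0]))
    t: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", qnormalize(np.asarray(self.q, dtype=float).reshape(4)))
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float).reshape(3))

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, H: np.ndarray) -> "RigidTransform":
        H = np.asarray(H, dtype=float)
        return cls(matrix_to_quat(H[:3, :3]), H[:3, 3])

    def to_matrix(self) -> np.ndarray:
        H = np.eye(4)
        H[:3, :3] = quat_to_matrix(self.q)
        H[:3, 3] = self.t
        return H

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        return RigidTransform(qmul(self.q, other.q), self.t + qrotate(self.q, other.t))

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        qi = qconj(self.q)
        return RigidTransform(qi, -qrotate(qi, self.t))

    def transform_point(self, p: np.ndarray) -> np.ndarray:
        return qrotate(self.q, p) + self.t


def dh_transform(d: float, a: float, alpha: float, theta: float) -> RigidTransform:
    """Classic DH transform ``Rot_z(theta)·Trans_z(d)·Trans_x(a)·Rot_x(alpha)``."""
    return RigidTransform.from_matrix(dh_matrix(d, a, alpha, theta))
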