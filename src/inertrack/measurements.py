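"""Stochastic measurement models and biomechanical constraints.

The residual conventions are shared between the EKF trackers and the
sliding-window optimizer: a residual is observed-minus-predicted (for the
sensors) or the constraint gap (for joints/anchor), and vanishes identically
on noise-free simulator output evaluated at the true state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .quat import qconj, qmul, qrotate

__all__ = [
    "MeasurementNoise",
    "accel_residual",
    "gyro_residual",
    "mag_residual",
    "mag_horizontal_norm",
    "joint_residual",
    "anchor_residual",
    "MAG_HORIZONTAL_TOL",
]

#: below this horizontal-projection norm the heading is unobservable and the
#: scalar magnetometer measurement is skipped.
MAG_HORIZONTAL_TOL = 1e-6


@dataclass
class MeasurementNoise:
    """Sensor and constraint noise levels (standard deviations).

    ``sigma_p`` and ``sigma_anchor`` weight the joint-connectivity and
    global-anchor pseudo-measurements; small values enforce the constraints
    tightly.
    """

    sigma_acc: float = 0.5  # m/s^2
    sigma_gyro: float = 0.02  # rad/s
    sigma_mag: float = np.radians(5.0)  # rad (heading angle)
    sigma_p: float = 1e-3  # m, joint constraint
    sigma_anchor: float = 1e-3  # m, global anchor

    def __post_init__(self) -> None:
        for name in ("sigma_acc", "sigma_gyro", "sigma_mag", "sigma_p", "sigma_anchor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def accel_residual(q_GI: np.ndarray, acc_G: np.ndarray, y_a: np.ndarray, g_G: np.ndarray) -> np.ndarray:
    """``e = y_a - R_GI^T (a_G - g_G)``: accelerometer innovation."""
    pred = qrotate(qconj(q_GI), np.asarray(acc_G, dtype=float) - np.asarray(g_G, dtype=float))
    return np.asarray(y_a, dtype=float) - pred


def gyro_residual(omega_IGI: np.ndarray, y_w: np.ndarray) -> np.ndarray:
    """``e = y_w - omega``: gyroscope innovation (both IMU-frame, rad/s)."""
    return np.asarray(y_w, dtype=float) - np.asarray(omega_IGI, dtype=float)


def mag_horizontal_norm(q_GI: np.ndarray, y_m: np.ndarray) -> np.ndarray:
    """Norm of the horizontal projection of the globally-rotated field."""
    u = qrotate(q_GI, _normalized(y_m))
    return np.hypot(u[..., 0], u[..., 1])


def mag_residual(q_GI: np.ndarray, y_m: np.ndarray) -> np.ndarray:
    """Heading residual: angle of the globally-rotated field from global x.

    ``e = atan2((R_GI y_m)_y, (R_GI y_m)_x)`` in ``(-pi, pi]``; the measured
    value of this scalar is 0 by construction of the magnetometer model.
    Raises for zero-norm input; validity of the horizontal projection is the
    caller's concern (see :func:`mag_horizontal_norm`).
    """
    u = qrotate(q_GI, _normalized(y_m))
    return np.arctan2(u[..., 1], u[..., 0])


def _normalized(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n < 1e-12):
        raise ValueError("zero-norm magnetometer measurement")
    return v / n


def joint_residual(
    q_i: np.ndarray, S_i: np.ndarray, p_iS: np.ndarray,
    q_j: np.ndarray, S_j: np.ndarray, p_jS: np.ndarray,
) -> np.ndarray:
    """Gap between matched endpoints of two segments, in the global frame.

    ``e = (S_i + R_i p_i) - (S_j + R_j p_j)``; zero for a connected chain.
    """
    return (np.asarray(S_i, dtype=float) + qrotate(q_i, p_iS)) - (
        np.asarray(S_j, dtype=float) + qrotate(q_j, p_jS)
    )


def anchor_residual(q_i: np.ndarray, S_i: np.ndarray, p_iS: np.ndarray, P_G: np.ndarray) -> np.ndarray:
    """``e = S_i + R_i p_i - P_G``: drift of an anchored point from its pin."""
    return np.asarray(S_i, dtype=float) + qrotate(q_i, p_iS) - np.asarray(P_G, dtype=float)
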