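"""Biomechanical body models and forward kinematics.

Two equivalent representations of an IMU-instrumented articulated body are
supported:

* the **kinematic chain** view: a rooted serial chain parametrized by
  Denavit-Hartenberg rows, some of whose angles are degrees of freedom; and
* the **free segments** view: every segment carries an independent global
  pose, with joint connectivity expressed as constraints between matched
  segment endpoints.

Segment frames have their origin at the proximal end with the z-axis along
the bone toward the distal end, so ``p_prox = (0,0,0)`` and
``p_dist = (0,0,length)``.  Each segment carries exactly one IMU, rigidly
attached through an IMU-to-segment (I2S) calibration ``{q_SI, r_IS}``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from .quat import (
    RigidTransform,
    dh_matrix,
    matrix_to_quat,
    qmul,
    qnormalize,
    qrotate,
)

__all__ = [
    "SegmentGeometry",
    "I2SCalibration",
    "JointSpec",
    "GlobalAnchor",
    "DHRow",
    "BodyModel",
    "build_arm_model",
    "chain_forward_kinematics",
    "chain_fk_matrices",
    "segment_to_imu_pose",
    "validate_model",
]


@dataclass
class SegmentGeometry:
    """A rigid segment: a bone of given length with endpoint markers."""

    name: str
    length: float
    p_prox: np.ndarray = field(default_factory=lambda: np.zeros(3))
    p_dist: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p_prox = np.asarray(self.p_prox, dtype=float).reshape(3)
        if self.p_dist is None:
            self.p_dist = self.p_prox + np.array([0.0, 0.0, self.length])
        self.p_dist = np.asarray(self.p_dist, dtype=float).reshape(3)


@dataclass
class I2SCalibration:
    """IMU pose in the segment frame: orientation ``q_SI``, position ``r_IS``."""

    q_SI: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    r_IS: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.q_SI = qnormalize(np.asarray(self.q_SI, dtype=float).reshape(4))
        self.r_IS = np.asarray(self.r_IS, dtype=float).reshape(3)


@dataclass
class JointSpec:
    """An intermediate joint: matched endpoints of two connected segments.

    ``parent_point``/``child_point`` select ``"prox"`` or ``"dist"``.
    """

    parent: int
    child: int
    parent_point: str = "dist"
    child_point: str = "prox"


@dataclass
class GlobalAnchor:
    """Pins a segment-frame point to a fixed global point ``P_G``."""

    segment: int
    p_S: np.ndarray = field(default_factory=lambda: np.zeros(3))
    P_G: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.p_S = np.asarray(self.p_S, dtype=float).reshape(3)
        self.P_G = np.asarray(self.P_G, dtype=float).reshape(3)


@dataclass
class DHRow:
    """One Denavit-Hartenberg row; ``alpha_dof``/``theta_dof`` mark a DoF index.

    ``bone`` marks the translation row along segment ``bone``'s z-axis: the
    cumulative transform *before* this row is that segment's frame.
    ``imu_z`` is informational (the z-offset of the IMU along the bone; the
    authoritative I2S position lives in :class:`I2SCalibration`).
    """

    d: float = 0.0
    a: float = 0.0
    alpha: float = 0.0
    theta: float = 0.0
    alpha_dof: int | None = None
    theta_dof: int | None = None
    bone: int | None = None
    imu_z: float | None = None

    def matrix(self, dofs: np.ndarray) -> np.ndarray:
        alpha = self.alpha + (dofs[self.alpha_dof] if self.alpha_dof is not None else 0.0)
        theta = self.theta + (dofs[self.theta_dof] if self.theta_dof is not None else 0.0)
        return dh_matrix(self.d, self.a, alpha, theta)


@dataclass
class BodyModel:
    """Segments, joints, I2S calibrations, anchor and (optionally) a DH table."""

    segments: list[SegmentGeometry]
    joints: list[JointSpec]
    calibrations: list[I2SCalibration]
    anchor: GlobalAnchor
    dh_table: list[DHRow] | None = None

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_dofs(self) -> int:
        if self.dh_table is None:
            return 0
        idx = [r.alpha_dof for r in self.dh_table if r.alpha_dof is not None]
        idx += [r.theta_dof for r in self.dh_table if r.theta_dof is not None]
        return max(idx) + 1 if idx else 0

    def endpoint(self, segment: int, which: str) -> np.ndarray:
        seg = self.segments[segment]
        return seg.p_prox if which == "prox" else seg.p_dist

    def copy(self) -> "BodyModel":
        return BodyModel(
            segments=[dataclasses.replace(s) for s in self.segments],
            joints=[dataclasses.replace(j) for j in self.joints],
            calibrations=[dataclasses.replace(c) for c in self.calibrations],
            anchor=dataclasses.replace(self.anchor),
            dh_table=None if self.dh_table is None else [dataclasses.replace(r) for r in self.dh_table],
        )

    # -- serialization ----------------------------------------------------
    def to_config(self) -> dict:
        cfg = {
            "segments": [
                {"name": s.name, "length": float(s.length), "p_prox": s.p_prox.tolist(), "p_dist": s.p_dist.tolist()}
                for s in self.segments
            ],
            "joints": [
                {"parent": j.parent, "child": j.child, "parent_point": j.parent_point, "child_point": j.child_point}
                for j in self.joints
            ],
            "i2s": [
                {"q_SI": c.q_SI.tolist(), "r_IS": c.r_IS.tolist()} for c in self.calibrations
            ],
            "anchor": {
                "segment": self.anchor.segment,
                "p_S": self.anchor.p_S.tolist(),
                "P_G": self.anchor.P_G.tolist(),
            },
        }
        if self.dh_table is not None:
            cfg["dh_table"] = [
                {
                    "d": r.d, "a": r.a, "alpha": r.alpha, "theta": r.theta,
                    "alpha_dof": r.alpha_dof, "theta_dof": r.theta_dof,
                    "bone": r.bone, "imu_z": r.imu_z,
                }
                for r in self.dh_table
            ]
        return cfg

    @classmethod
    def from_config(cls, cfg: dict) -> "BodyModel":
        segments = [
            SegmentGeometry(s["name"], s["length"], s.get("p_prox", (0, 0, 0)), s.get("p_dist"))
            for s in cfg["segments"]
        ]
        joints = [JointSpec(**j) for j in cfg["joints"]]
        cals = [I2SCalibration(c["q_SI"], c["r_IS"]) for c in cfg["i2s"]]
        anchor = GlobalAnchor(cfg["anchor"]["segment"], cfg["anchor"]["p_S"], cfg["anchor"]["P_G"])
        dh = [DHRow(**r) for r in cfg["dh_table"]] if "dh_table" in cfg else None
        return cls(segments, joints, cals, anchor, dh)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_config(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "BodyModel":
        with open(path) as fh:
            return cls.from_config(yaml.safe_load(fh))


def build_arm_model() -> BodyModel:
    """Three-segment arm-like chain used throughout the simulation study.

    Segment lengths 0.4/0.4/0.2 m, IMUs at (0,0,0.3)/(0,0,0.3)/(0,0,0.1) m
    along the bones with identity I2S orientations, root pinned at
    (0,0,0.5) m.  Each segment contributes four DH rows: two alpha-DoF rows
    (with fixed theta offsets -pi/2 and +pi/2 that cancel at zero angles),
    one theta-DoF row, and the bone translation.  At zero angles the chain
    points straight up, opposite gravity.
    """
    lengths = [0.4, 0.4, 0.2]
    imu_z = [0.3, 0.3, 0.1]
    segments = [SegmentGeometry(f"S{i}", lengths[i]) for i in range(3)]
    joints = [JointSpec(parent=0, child=1), JointSpec(parent=1, child=2)]
    cals = [I2SCalibration(r_IS=(0.0, 0.0, z)) for z in imu_z]
    anchor = GlobalAnchor(segment=0, p_S=(0.0, 0.0, 0.0), P_G=(0.0, 0.0, 0.5))
    rows: list[DHRow] = []
    for i in range(3):
        # DoF order per segment: alpha_{2i}, alpha_{2i+1}, theta_i
        rows.append(DHRow(theta=-np.pi / 2, alpha_dof=3 * i))
        rows.append(DHRow(theta=+np.pi / 2, alpha_dof=3 * i + 1))
        rows.append(DHRow(theta_dof=3 * i + 2))
        rows.append(DHRow(d=lengths[i], bone=i, imu_z=imu_z[i]))
    return BodyModel(segments, joints, cals, anchor, rows)


def _root_matrix(model: BodyModel) -> np.ndarray:
    H = np.eye(4)
    H[:3, 3] = model.anchor.P_G
    return H


def chain_fk_matrices(model: BodyModel, angles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward kinematics in 4x4 form for one DoF vector.

    Returns ``(seg, imu)`` arrays of shape ``(n_segments, 4, 4)``: global
    segment poses (frame before each bone row) and global IMU poses
    (segment pose composed with the I2S calibration).
    """
    if model.dh_table is None:
        raise ValueError("model has no DH table; chain kinematics unavailable")
    angles = np.asarray(angles, dtype=float)
    if angles.shape != (model.n_dofs,):
        raise ValueError(f"expected {model.n_dofs} DoF angles, got shape {angles.shape}")
    T = _root_matrix(model)
    seg = np.zeros((model.n_segments, 4, 4))
    for row in model.dh_table:
        if row.bone is not None:
            seg[row.bone] = T
        T = T @ row.matrix(angles)
    imu = np.zeros_like(seg)
    for i, cal in enumerate(model.calibrations):
        Hc = np.eye(4)
        Hc[:3, :3] = _quat_mat(cal.q_SI)
        Hc[:3, 3] = cal.r_IS
        imu[i] = seg[i] @ Hc
    return seg, imu


def _quat_mat(q: np.ndarray) -> np.ndarray:
    from .quat import quat_to_matrix

    return quat_to_matrix(q)


def chain_fk_batch(model: BodyModel, angles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized forward kinematics over many DoF vectors at once.

    ``angles`` has shape ``(M, n_dofs)``; returns ``(seg, imu)`` arrays of
    shape ``(M, n_segments, 4, 4)``.
    """
    if model.dh_table is None:
        raise ValueError("model has no DH table; chain kinematics unavailable")
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    M = angles.shape[0]
    if angles.shape[1] != model.n_dofs:
        raise ValueError(f"expected {model.n_dofs} DoF columns, got {angles.shape[1]}")
    T = np.broadcast_to(_root_matrix(model), (M, 4, 4)).copy()
    seg = np.zeros((M, model.n_segments, 4, 4))
    for row in model.dh_table:
        if row.bone is not None:
            seg[:, row.bone] = T
        alpha = row.alpha + (angles[:, row.alpha_dof] if row.alpha_dof is not None else 0.0)
        theta = row.theta + (angles[:, row.theta_dof] if row.theta_dof is not None else 0.0)
        T = T @ _dh_matrix_batch(row.d, row.a, alpha, theta, M)
    imu = np.zeros_like(seg)
    for i, cal in enumerate(model.calibrations):
        Hc = np.eye(4)
        Hc[:3, :3] = _quat_mat(cal.q_SI)
        Hc[:3, 3] = cal.r_IS
        imu[:, i] = seg[:, i] @ Hc
    return seg, imu


def _dh_matrix_batch(d: float, a: float, alpha, theta, M: int) -> np.ndarray:
    ct, st = np.broadcast_to(np.cos(theta), (M,)), np.broadcast_to(np.sin(theta), (M,))
    ca, sa = np.broadcast_to(np.cos(alpha), (M,)), np.broadcast_to(np.sin(alpha), (M,))
    out = np.zeros((M, 4, 4))
    out[:, 0, 0] = ct
    out[:, 0, 1] = -st * ca
    out[:, 0, 2] = st * sa
    out[:, 0, 3] = a * ct
    out[:, 1, 0] = st
    out[:, 1, 1] = ct * ca
    out[:, 1, 2] = -ct * sa
    out[:, 1, 3] = a * st
    out[:, 2, 1] = sa
    out[:, 2, 2] = ca
    out[:, 2, 3] = d
    out[:, 3, 3] = 1.0
    return out


def chain_forward_kinematics(
    model: BodyModel, angles: np.ndarray
) -> tuple[list[RigidTransform], list[RigidTransform]]:
    """Forward kinematics returning per-segment and per-IMU global poses."""
    seg, imu = chain_fk_matrices(model, angles)
    return (
        [RigidTransform.from_matrix(H) for H in seg],
        [RigidTransform.from_matrix(H) for H in imu],
    )


def segment_to_imu_pose(seg_pose: RigidTransform, cal: I2SCalibration) -> RigidTransform:
    """Global IMU pose from a global segment pose and the I2S calibration.

    ``I_G = S_G + R_GS r_IS`` and ``q_GI = q_GS ⊙ q_SI``.
    """
    return RigidTransform(
        qmul(seg_pose.q, cal.q_SI), seg_pose.t + qrotate(seg_pose.q, cal.r_IS)
    )


def validate_model(model: BodyModel) -> list[str]:
    """Diagnostic check of model invariants; returns a list of violations."""
    issues: list[str] = []
    n = model.n_segments
    if len(model.calibrations) != n:
        issues.append(f"expected one I2S calibration per segment ({n}), got {len(model.calibrations)}")
    for i, s in enumerate(model.segments):
        gap = abs(np.linalg.norm(s.p_dist - s.p_prox) - s.length)
        if gap > 1e-9:
            issues.append(f"segment {i} ({s.name}): |p_dist - p_prox| differs from length by {gap:.2e}")
    for k, j in enumerate(model.joints):
        for ref, role in ((j.parent, "parent"), (j.child, "child")):
            if not (0 <= ref < n):
                issues.append(f"joint {k}: {role} segment {ref} does not exist")
        if j.parent_point not in ("prox", "dist") or j.child_point not in ("prox", "dist"):
            issues.append(f"joint {k}: endpoint selectors must be 'prox' or 'dist'")
    if not (0 <= model.anchor.segment < n):
        issues.append(f"anchor references missing segment {model.anchor.segment}")
    # chain view requires a rooted tree: each child appears once, no cycles
    children = [j.child for j in model.joints if 0 <= j.child < n]
    if len(set(children)) != len(children):
        issues.append("a segment is the child of more than one joint (not a tree)")
    if model.dh_table is not None:
        used: set[int] = set()
        for r in model.dh_table:
            for ix in (r.alpha_dof, r.theta_dof):
                if ix is not None:
                    if ix in used:
                        issues.append(f"DoF index {ix} used by more than one DH row")
                    used.add(ix)
        bones = [r.bone for r in model.dh_table if r.bone is not None]
        if sorted(bones) != list(range(n)):
            issues.append("DH table bone rows do not cover every segment exactly once")
    return issues
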