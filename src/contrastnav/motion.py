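"""Rigid poses, motion scores, block rejection, and k-space correction.

The *motion score* between two poses combines the chord length traveled by
a point on a sphere of radius R (default 64 mm, a head-sized sphere) under
the relative rotation with the Euclidean distance between the translations:

    M(t, tau) = R * sqrt((1 - cos th)^2 + sin^2 th) + ||x_t - x_tau||_2
             = 2 R sin(th/2) + ||x_t - x_tau||_2,

where th is the geodesic angle of the relative rotation.  Averaged over all
unordered pairs of blocks it summarizes the overall data inconsistency of a
scan.  Blocks adjacent to motion-score jumps above a threshold (default
1.5 mm) are discarded, and the remaining blocks' poses are undone in
k-space: the trajectory of each block is counter-rotated and the data
receive the linear phase that undoes the translation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .recon import KSpaceData

__all__ = [
    "RigidPose",
    "MotionTrace",
    "euler_to_matrix",
    "matrix_to_euler",
    "rotation_angle",
    "motion_score",
    "mean_pairwise_score",
    "reject_blocks",
    "pose_difference",
    "correct_kspace",
    "poses_to_frame",
    "frame_to_poses",
]

DEFAULT_SPHERE_RADIUS_MM = 64.0
DEFAULT_REJECT_THRESHOLD_MM = 1.5


def euler_to_matrix(angles: Sequence[float], ndim: int = 3) -> np.ndarray:
    """Rotation matrix from Euler angles (intrinsic ZYX in 3D; one angle in 2D)."""
    angles = np.atleast_1d(np.asarray(angles, dtype=float))
    if ndim == 2:
        (a,) = angles
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])
    az, ay, ax = angles
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return Rz @ Ry @ Rx


def matrix_to_euler(R: np.ndarray) -> np.ndarray:
    """Euler angles of a rotation matrix (inverse of :func:`euler_to_matrix`)."""
    R = np.asarray(R, dtype=float)
    if R.shape == (2, 2):
        return np.array([np.arctan2(R[1, 0], R[0, 0])])
    sy = -R[2, 0]
    cy = np.sqrt(max(0.0, 1.0 - sy * sy))
    if cy > 1e-9:
        return np.array(
            [np.arctan2(R[1, 0], R[0, 0]), np.arcsin(np.clip(sy, -1, 1)), np.arctan2(R[2, 1], R[2, 2])]
        )
    # gimbal lock: put everything into z
    return np.array([np.arctan2(-R[0, 1], R[1, 1]), np.arcsin(np.clip(sy, -1, 1)), 0.0])


def _check_rotation(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    d = R.shape[0]
    if not np.allclose(R.T @ R, np.eye(d), atol=1e-8):
        raise ValueError("R is not orthogonal")
    if np.linalg.det(R) < 0:
        raise ValueError("R is a reflection, not a rotation")
    return R


@dataclass
class RigidPose:
    """Rigid transform y = R x + t (translations in mm).

    2D poses use a 2x2 rotation and 2-vector translation; scoring embeds
    them as rotations about z with zero out-of-plane translation.
    """

    R: np.ndarray
    t: np.ndarray
    block_index: int = -1
    pattern_id: int = -1

    def __post_init__(self) -> None:
        self.R = _check_rotation(self.R)
        self.t = np.asarray(self.t, dtype=float)
        if self.t.shape != (self.R.shape[0],):
            raise ValueError("translation dimension must match rotation")

    @classmethod
    def identity(cls, ndim: int = 3, **kw) -> "RigidPose":
        return cls(np.eye(ndim), np.zeros(ndim), **kw)

    @property
    def ndim(self) -> int:
        return self.R.shape[0]

    def compose(self, other: "RigidPose") -> "RigidPose":
        """Pose of the composed map self o other (apply ``other`` first)."""
        return RigidPose(self.R @ other.R, self.R @ other.t + self.t)

    def inverse(self) -> "RigidPose":
        return RigidPose(self.R.T, -self.R.T @ self.t)

    def as_matrix(self) -> np.ndarray:
        """Homogeneous (d+1)x(d+1) affine matrix."""
        d = self.ndim
        A = np.eye(d + 1)
        A[:d, :d] = self.R
        A[:d, d] = self.t
        return A

    def rotation3(self) -> np.ndarray:
        """Rotation embedded in 3D (2D poses rotate about z)."""
        if self.ndim == 3:
            return self.R
        R3 = np.eye(3)
        R3[:2, :2] = self.R
        return R3

    def translation3(self) -> np.ndarray:
        if self.ndim == 3:
            return self.t
        return np.array([self.t[0], self.t[1], 0.0])

    def euler(self) -> np.ndarray:
        return matrix_to_euler(self.R)


@dataclass
class MotionTrace:
    """Time-ordered rigid poses at block (or TR) resolution."""

    poses: list[RigidPose]
    resolution: str = "block"  # "block" | "TR"
    sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM

    def __post_init__(self) -> None:
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere radius must be positive")

    def __len__(self) -> int:
        return len(self.poses)

    def __getitem__(self, i: int) -> RigidPose:
        return self.poses[i]


def rotation_angle(pose_t: RigidPose, pose_tau: RigidPose) -> float:
    """Geodesic angle (rad, in [0, pi]) of the relative rotation R_t R_tau^T."""
    Rrel = pose_t.rotation3() @ pose_tau.rotation3().T
    cos_th = (np.trace(Rrel) - 1.0) / 2.0
    return float(np.arccos(np.clip(cos_th, -1.0, 1.0)))


def motion_score(
    pose_t: RigidPose,
    pose_tau: RigidPose,
    sphere_radius_mm: float = DEFAULT_SPHERE_RADIUS_MM,
) -> float:
    """Rotational chord on the R-sphere plus translation distance (mm)."""
    th = rotation_angle(pose_t, pose_tau)
    r = sphere_radius_mm * np.sqrt((1.0 - np.cos(th)) ** 2 + np.sin(th) ** 2)
    d = np.linalg.norm(pose_t.translation3() - pose_tau.translation3())
    return float(r + d)


def mean_pairwise_score(trace: MotionTrace | Sequence[RigidPose], sphere_radius_mm: float | None = None) -> float:
    """Mean motion score over all N(N-1)/2 unordered pose pairs (mm)."""
    if isinstance(trace, MotionTrace):
        poses = trace.poses
        R = trace.sphere_radius_mm if sphere_radius_mm is None else sphere_radius_mm
    else:
        poses = list(trace)
        R = DEFAULT_SPHERE_RADIUS_MM if sphere_radius_mm is None else sphere_radius_mm
    n = len(poses)
    if n < 2:
        raise ValueError("need at least two poses for a pairwise score")
    total = 0.0
    for i in range(n - 1):
        for j in range(i + 1, n):
            total += motion_score(poses[i], poses[j], R)
    return total / (n * (n - 1) / 2)


def reject_blocks(
    trace: MotionTrace | Sequence[RigidPose],
    threshold_mm: float = DEFAULT_REJECT_THRESHOLD_MM,
    sphere_radius_mm: float | None = None,
) -> np.ndarray:
    """Keep-mask over blocks: both neighbors of a score jump above threshold go.

    For every consecutive pair (t, t+1) whose motion score exceeds the
    threshold, both blocks are flagged discarded (``False``).
    """
    poses = trace.poses if isinstance(trace, MotionTrace) else list(trace)
    R = (
        trace.sphere_radius_mm
        if isinstance(trace, MotionTrace) and sphere_radius_mm is None
        else (sphere_radius_mm or DEFAULT_SPHERE_RADIUS_MM)
    )
    keep = np.ones(len(poses), dtype=bool)
    for t in range(len(poses) - 1):
        if motion_score(poses[t], poses[t + 1], R) > threshold_mm:
            keep[t] = False
            keep[t + 1] = False
    return keep


def pose_difference(pose_a: RigidPose, pose_b: RigidPose) -> RigidPose:
    """Relative pose A_b^{-1} A_a ('divide the affine matrices')."""
    return pose_b.inverse().compose(pose_a)


def correct_kspace(
    ks: KSpaceData,
    trace: MotionTrace | Sequence[RigidPose],
    keep: np.ndarray | None = None,
) -> KSpaceData:
    """Undo per-block rigid motion in k-space.

    For block t with pose (R_t, t_t): the block's spoke directions are
    rotated by R_t^T (the trajectory rotates with the object) and the data
    are multiplied by exp(+i k . t_t), cancelling the linear phase the
    object shift imprinted.  Blocks flagged ``False`` in ``keep`` are
    removed from both data and plan.
    """
    poses = trace.poses if isinstance(trace, MotionTrace) else list(trace)
    plan = ks.plan
    if len(poses) != plan.n_blocks:
        raise ValueError(f"{len(poses)} poses for {plan.n_blocks} blocks")
    dirs = plan.spoke_dirs.copy()
    data = ks.data.copy()
    for b, pose in enumerate(poses):
        idx = plan.spokes_of_block(b)
        if idx.size == 0:
            continue
        kc = plan.kcoords(idx)  # (S, M, d) rad/voxel — pre-correction coordinates
        t_vox = pose.t / plan.voxel_mm
        phase = np.exp(1j * np.tensordot(kc, t_vox, axes=([2], [0])))
        data[:, idx, :] *= phase[None]
        dirs[idx] = dirs[idx] @ pose.R  # row vectors: k -> R^T k

    new_plan = replace(plan, spoke_dirs=dirs)
    out = KSpaceData(data=data, plan=new_plan, coil_maps=ks.coil_maps)
    if keep is not None:
        keep = np.asarray(keep, dtype=bool)
        kept_blocks = np.flatnonzero(keep)
        if kept_blocks.size == 0:
            raise ValueError("rejection removed every block; no data left")
        spoke_keep = keep[new_plan.block_of_spoke]
        out = KSpaceData(
            data=data[:, spoke_keep, :],
            plan=new_plan.subset_blocks(kept_blocks),
            coil_maps=ks.coil_maps,
        )
    return out


def poses_to_frame(poses: Sequence[RigidPose]) -> pd.DataFrame:
    """Tabulate poses: translations in mm, rotations as Euler angles in degrees."""
    rows = []
    for i, p in enumerate(poses):
        t3 = p.translation3()
        e3 = matrix_to_euler(p.rotation3())
        rows.append(
            {
                "block": p.block_index if p.block_index >= 0 else i,
                "pattern": p.pattern_id,
                "tx_mm": t3[0],
                "ty_mm": t3[1],
                "tz_mm": t3[2],
                "rz_deg": np.rad2deg(e3[0]),
                "ry_deg": np.rad2deg(e3[1]),
                "rx_deg": np.rad2deg(e3[2]),
            }
        )
    return pd.DataFrame(rows)


def frame_to_poses(df: pd.DataFrame, ndim: int = 3) -> list[RigidPose]:
    """Inverse of :func:`poses_to_frame`."""
    poses = []
    for _, row in df.iterrows():
        angles = np.deg2rad([row["rz_deg"], row["ry_deg"], row["rx_deg"]])
        if ndim == 2:
            R = euler_to_matrix([angles[0]], ndim=2)
            t = np.array([row["tx_mm"], row["ty_mm"]])
        else:
            R = euler_to_matrix(angles, ndim=3)
            t = np.array([row["tx_mm"], row["ty_mm"], row["tz_mm"]])
        poses.append(
            RigidPose(R=R, t=t, block_index=int(row["block"]), pattern_id=int(row.get("pattern", -1)))
        )
    return poses
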