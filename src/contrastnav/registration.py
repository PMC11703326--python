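"""Rigid co-registration of per-block coefficient volumes.

Each block's low-resolution coefficient image is registered to a reference
block to produce one rigid pose per block.  The registrar maximizes
normalized cross-correlation (NCC) over the rigid parameters (1 angle + 2
translations in 2D, 3 Euler angles + 3 translations in 3D) with a
two-level smoothing pyramid and a derivative-free Powell refinement; it is
deterministic given its inputs.  The backend is pluggable: anything that
maps (moving, fixed, config) to a pose can be substituted.

Pose convention: the returned pose maps *fixed* coordinates to *moving*
coordinates about the volume center c, i.e. ``moving(R (x - c) + c + t) ≈
fixed(x)``.  With this convention the pose of a block reconstructed from
motion-corrupted data is directly the motion state to undo in k-space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi
import scipy.optimize

from .motion import RigidPose, euler_to_matrix, matrix_to_euler
from .recon import CoefficientSeries

__all__ = ["RegistrationConfig", "register_rigid", "register_series"]


@dataclass
class RegistrationConfig:
    """Tunables of the NCC registrar.

    ``channel`` selects which coefficient magnitude image drives the
    registration (default 0, the first coefficient — where the
    contrast-optimized basis concentrates the parenchyma/CSF contrast).
    Translations are reported in mm via ``voxel_mm`` of the series.
    """

    channel: int = 0
    levels: int = 2
    smooth_sigma: float = 1.0
    final_smooth_sigma: float = 1.0
    interp_order: int = 3
    upsample_to: int = 48
    max_translation_voxels: float = 8.0
    max_rotation_deg: float = 20.0
    xtol: float = 1e-4


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    if denom == 0:
        raise ValueError("flat (zero-variance) image; cannot register")
    return float(np.vdot(a, b).real / denom)


def _n_params(ndim: int) -> int:
    return 3 if ndim == 2 else 6


def _params_to_pose(params: np.ndarray, ndim: int, voxel_mm: float) -> RigidPose:
    if ndim == 2:
        R = euler_to_matrix([params[0]], ndim=2)
        t = params[1:3] * voxel_mm
    else:
        R = euler_to_matrix(params[:3], ndim=3)
        t = params[3:6] * voxel_mm
    return RigidPose(R=R, t=t)


def _resample(moving: np.ndarray, params: np.ndarray, ndim: int, order: int = 3) -> np.ndarray:
    """Evaluate moving(R (x - c) + c + t) on the fixed grid."""
    if ndim == 2:
        R = euler_to_matrix([params[0]], ndim=2)
        t = params[1:3]
    else:
        R = euler_to_matrix(params[:3], ndim=3)
        t = params[3:6]
    # center matches the Fourier-grid origin used by the k-space operators
    center = (np.array(moving.shape) // 2).astype(float)
    offset = center - R @ center + t
    return ndi.affine_transform(moving, R, offset=offset, order=order, mode="constant", cval=0.0)


def _pyramid(img: np.ndarray, levels: int, sigma: float) -> list[np.ndarray]:
    out = [img]
    for _ in range(levels - 1):
        sm = ndi.gaussian_filter(out[-1], sigma)
        slicer = tuple(slice(None, None, 2) for _ in img.shape)
        out.append(sm[slicer])
    return out[::-1]  # coarse to fine


def register_rigid(
    moving: np.ndarray,
    fixed: np.ndarray,
    config: RegistrationConfig | None = None,
    voxel_mm: float = 1.0,
) -> RigidPose:
    """Estimate the rigid pose aligning ``moving`` to ``fixed`` by NCC.

    Both images must share grid and voxel size.  Returns the pose (rotation
    + translation in mm, about the volume center) such that resampling
    ``moving`` with it matches ``fixed``.
    """
    config = config or RegistrationConfig()
    if moving.shape != fixed.shape:
        raise ValueError("moving and fixed must share the same grid")
    moving = np.ascontiguousarray(np.abs(moving), dtype=float)
    fixed = np.ascontiguousarray(np.abs(fixed), dtype=float)
    if moving.std() == 0 or fixed.std() == 0:
        raise ValueError("flat (zero-variance) image; cannot register")
    ndim = moving.ndim
    n_par = _n_params(ndim)
    n_rot = 1 if ndim == 2 else 3

    # small navigator volumes are spline-upsampled before matching: the NCC
    # landscape over sub-voxel shifts/rotations is much smoother on the
    # oversampled grid
    zoom = 1
    if config.upsample_to and min(moving.shape) < config.upsample_to:
        zoom = int(np.ceil(config.upsample_to / min(moving.shape)))
        moving = ndi.zoom(moving, zoom, order=3)
        fixed = ndi.zoom(fixed, zoom, order=3)

    params = np.zeros(n_par)
    mov_pyr = _pyramid(moving, config.levels, config.smooth_sigma)
    fix_pyr = _pyramid(fixed, config.levels, config.smooth_sigma)
    for level, (mov, fix) in enumerate(zip(mov_pyr, fix_pyr)):
        scale = 2 ** (len(mov_pyr) - 1 - level)
        if level + 1 == len(mov_pyr) and config.final_smooth_sigma > 0:
            mov = ndi.gaussian_filter(mov, config.final_smooth_sigma)
            fix = ndi.gaussian_filter(fix, config.final_smooth_sigma)

        def cost(p):
            return -_ncc(_resample(mov, p, ndim, config.interp_order), fix)

        rot_bound = np.deg2rad(config.max_rotation_deg)
        tr_bound = config.max_translation_voxels * zoom / scale
        bounds = [(-rot_bound, rot_bound)] * n_rot + [(-tr_bound, tr_bound)] * (n_par - n_rot)
        res = scipy.optimize.minimize(
            cost,
            params,
            method="Powell",
            bounds=bounds,
            options={"xtol": config.xtol, "ftol": 1e-10, "maxiter": 300},
        )
        params = res.x
        if level + 1 < len(mov_pyr):
            params = params.copy()
            params[n_rot:] *= 2.0  # translations scale with resolution

    params = params.copy()
    params[n_rot:] /= zoom
    return _params_to_pose(params, ndim, voxel_mm)


def register_series(
    series: CoefficientSeries,
    config: RegistrationConfig | None = None,
) -> list[RigidPose]:
    """One pose per block, relative to the global reference (first block).

    Blocks are registered to the first block of their own flip-angle
    pattern (coefficient images of different patterns live in different
    bases); the per-pattern reference images are then registered to the
    overall first block and the poses composed, so every pose is expressed
    against the common reference.
    """
    config = config or RegistrationConfig()
    if series.n_blocks < 1:
        raise ValueError("empty coefficient series")
    imgs = series.channel(config.channel)
    patterns = series.pattern_of_block
    ref_of_pattern: dict[int, int] = {}
    for b in range(series.n_blocks):
        ref_of_pattern.setdefault(int(patterns[b]), b)
    global_ref = 0

    # pose of each pattern's reference block w.r.t. the global reference
    pattern_pose: dict[int, RigidPose] = {}
    for p, bref in ref_of_pattern.items():
        if bref == global_ref:
            pattern_pose[p] = RigidPose.identity(imgs.ndim - 1)
        else:
            pattern_pose[p] = register_rigid(
                imgs[bref], imgs[global_ref], config, voxel_mm=series.voxel_mm
            )

    poses: list[RigidPose] = []
    for b in range(series.n_blocks):
        p = int(patterns[b])
        bref = ref_of_pattern[p]
        if b == bref:
            rel = RigidPose.identity(imgs.ndim - 1)
        else:
            rel = register_rigid(imgs[b], imgs[bref], config, voxel_mm=series.voxel_mm)
        # T_block<-global = T_block<-patternref o T_patternref<-global
        pose = rel.compose(pattern_pose[p])
        poses.append(
            RigidPose(R=pose.R, t=pose.t, block_index=b, pattern_id=p)
        )
    return poses
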