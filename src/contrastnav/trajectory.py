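"""Golden-angle radial k-space trajectories (2D and 3D koosh-ball) with block structure.

Spokes pass through the k-space center; directions follow golden-angle /
golden-means increments so that any contiguous subset of spokes covers
k-space near-uniformly.  The acquisition is organized into *blocks*: one
block is one repetition of a flip-angle pattern (one RF cycle, nominally
4 s), the temporal unit used for navigation, registration, motion scoring
and data rejection.  Blocks cycle through the patterns in acquisition
order (pattern 1, 2, ..., n, 1, 2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "RadialAcquisitionPlan",
    "GOLDEN_ANGLE",
    "golden_angle_2d",
    "koosh_ball_3d",
    "block_layout",
    "build_plan",
]

#: 2D radial golden-angle increment, pi*(sqrt(5)-1)/2 rad (~111.246 deg);
#: spokes are lines through the center, so the relevant circle is 180 deg
GOLDEN_ANGLE = np.pi * (np.sqrt(5.0) - 1.0) / 2.0

# generalized golden means for the 3D (koosh-ball) lattice
_PHI1 = 0.4656010700114986  # real root of x^3 + x - 1
_PHI2 = 0.6823278038280193  # real root of x^3 + x^2 - 1


@dataclass
class RadialAcquisitionPlan:
    """Radial sampling plan.

    ``spoke_dirs`` is (n_spokes, d) with unit rows; ``kr`` the radial sample
    positions (rad/voxel) shared by all spokes, spanning [-kmax, kmax)
    symmetrically through the center.  Each spoke belongs to one block
    (``block_of_spoke``) and samples one pulse of the block's flip-angle
    pattern (``tr_of_spoke``, index into the schedule).
    """

    spoke_dirs: np.ndarray
    kr: np.ndarray
    block_of_spoke: np.ndarray
    tr_of_spoke: np.ndarray
    pattern_of_block: np.ndarray
    TR: float = 3.5e-3
    kmax: float = np.pi
    voxel_mm: float = 1.0
    pulses_per_block: int = 0  # pulses in one RF cycle; 0 = one pulse per spoke

    def __post_init__(self) -> None:
        self.spoke_dirs = np.atleast_2d(np.asarray(self.spoke_dirs, dtype=float))
        self.kr = np.asarray(self.kr, dtype=float)
        self.block_of_spoke = np.asarray(self.block_of_spoke, dtype=int)
        self.tr_of_spoke = np.asarray(self.tr_of_spoke, dtype=int)
        self.pattern_of_block = np.asarray(self.pattern_of_block, dtype=int)
        norms = np.linalg.norm(self.spoke_dirs, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("spoke directions must be unit vectors")
        if self.block_of_spoke.shape[0] != self.n_spokes:
            raise ValueError("one block index per spoke required")

    @property
    def n_spokes(self) -> int:
        return self.spoke_dirs.shape[0]

    @property
    def n_samples(self) -> int:
        return self.kr.size

    @property
    def n_blocks(self) -> int:
        return self.pattern_of_block.size

    @property
    def ndim(self) -> int:
        return self.spoke_dirs.shape[1]

    @property
    def block_duration(self) -> float:
        ppb = self.pulses_per_block or (int(self.tr_of_spoke.max()) + 1 if self.tr_of_spoke.size else 1)
        return ppb * self.TR

    def spoke_times(self) -> np.ndarray:
        """Acquisition time (s) of each spoke: block start + pulse index * TR."""
        return self.block_of_spoke * self.block_duration + self.tr_of_spoke * self.TR

    def spokes_of_block(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.block_of_spoke == b)

    def blocks_of_pattern(self, p: int) -> np.ndarray:
        return np.flatnonzero(self.pattern_of_block == p)

    def kcoords(self, spokes: np.ndarray | None = None) -> np.ndarray:
        """Sample coordinates (n_spokes, n_samples, d) in rad/voxel."""
        dirs = self.spoke_dirs if spokes is None else self.spoke_dirs[spokes]
        return self.kr[None, :, None] * dirs[:, None, :]

    def lowres(self, factor: int) -> "RadialAcquisitionPlan":
        """Crop to |k| <= kmax/factor and rescale to the coarse grid's voxel.

        Samples beyond the reduced kmax are discarded; the retained radial
        positions are multiplied by ``factor`` so they are again expressed in
        rad per (coarse) voxel.  Mirrors reconstructing at ``factor``-times
        coarser resolution from the k-space center.
        """
        if factor < 1:
            raise ValueError("lowres factor must be >= 1")
        keep = np.abs(self.kr) <= self.kmax / factor + 1e-12
        return replace(
            self,
            kr=self.kr[keep] * factor,
            voxel_mm=self.voxel_mm * factor,
        )

    def subset_blocks(self, keep_blocks: np.ndarray) -> "RadialAcquisitionPlan":
        """Restrict the plan to a subset of blocks (spokes re-indexed)."""
        keep_blocks = np.asarray(keep_blocks, dtype=int)
        spoke_keep = np.isin(self.block_of_spoke, keep_blocks)
        remap = -np.ones(self.n_blocks, dtype=int)
        remap[keep_blocks] = np.arange(keep_blocks.size)
        return replace(
            self,
            spoke_dirs=self.spoke_dirs[spoke_keep],
            block_of_spoke=remap[self.block_of_spoke[spoke_keep]],
            tr_of_spoke=self.tr_of_spoke[spoke_keep],
            pattern_of_block=self.pattern_of_block[keep_blocks],
        )


def _radial_samples(samples_per_spoke: int, kmax: float) -> np.ndarray:
    """Uniform radial positions in [-kmax, kmax), center included for even counts."""
    m = np.arange(samples_per_spoke)
    return -kmax + m * (2.0 * kmax / samples_per_spoke)


def _bit_reversal(n: int) -> np.ndarray:
    """Bit-reversal permutation of 0..n-1 (padded to the next power of two)."""
    bits = max(1, int(np.ceil(np.log2(max(n, 1)))))
    idx = np.arange(2**bits)
    rev = np.zeros_like(idx)
    for b in range(bits):
        rev |= ((idx >> b) & 1) << (bits - 1 - b)
    return rev[rev < n]


def golden_angle_2d(
    n_spokes: int,
    samples_per_spoke: int = 64,
    kmax: float = np.pi,
    repeat_per_block: bool = False,
    n_patterns: int = 1,
    reps: int = 1,
    **layout,
) -> RadialAcquisitionPlan:
    """2D golden-angle plan: spoke j at azimuth j times the radial golden angle.

    With ``repeat_per_block`` the golden-angle sequence restarts at every
    block, so all blocks share an identical spoke set: each repetition then
    covers k-space the same way, and per-block undersampling artifacts are
    reproducible across blocks — the property self-navigated registration
    relies on.
    """
    n_blocks = max(n_patterns * reps, 1)
    if repeat_per_block and n_spokes % n_blocks == 0:
        j = np.tile(np.arange(n_spokes // n_blocks), n_blocks)
    else:
        j = np.arange(n_spokes)
    phi = j * GOLDEN_ANGLE
    dirs = np.stack([np.cos(phi), np.sin(phi)], axis=1)
    return _assemble(dirs, samples_per_spoke, kmax, n_patterns=n_patterns, reps=reps, **layout)


def koosh_ball_3d(
    n_spokes: int,
    samples_per_spoke: int = 64,
    kmax: float = np.pi,
    **layout,
) -> RadialAcquisitionPlan:
    """3D koosh-ball plan from the 2D golden-means lattice.

    Spoke j has polar angle cos(theta) = 1 - 2*frac(j*phi1) and azimuth
    2*pi*frac(j*phi2), with phi1, phi2 the generalized golden means; the
    sequence fills the sphere near-uniformly for any contiguous run.
    """
    j = np.arange(n_spokes)
    cos_t = 1.0 - 2.0 * np.mod(j * _PHI1, 1.0)
    sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
    az = 2.0 * np.pi * np.mod(j * _PHI2, 1.0)
    dirs = np.stack([sin_t * np.cos(az), sin_t * np.sin(az), cos_t], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return _assemble(dirs, samples_per_spoke, kmax, **layout)


def _assemble(
    dirs: np.ndarray,
    samples_per_spoke: int,
    kmax: float,
    n_patterns: int = 1,
    reps: int = 1,
    pulses_per_block: int | None = None,
    TR: float = 3.5e-3,
    reorder: bool = True,
    voxel_mm: float = 1.0,
) -> RadialAcquisitionPlan:
    n_spokes = dirs.shape[0]
    n_blocks = n_patterns * reps
    if n_spokes % n_blocks:
        raise ValueError(f"{n_spokes} spokes do not divide into {n_blocks} blocks")
    spb = n_spokes // n_blocks
    block_of_spoke = np.repeat(np.arange(n_blocks), spb)
    pattern_of_block = np.tile(np.arange(1, n_patterns + 1), reps)

    if reorder and spb > 1:
        # interleave k-space coverage within each block by bit reversal
        perm = _bit_reversal(spb)
        dirs = dirs.reshape(n_blocks, spb, -1)[:, perm].reshape(n_spokes, -1)

    ppb = pulses_per_block if pulses_per_block is not None else spb
    if ppb < spb:
        raise ValueError("fewer pulses per block than spokes per block")
    # spread the spokes evenly over the pulse train of the block
    tr_within = np.floor(np.arange(spb) * ppb / spb).astype(int)
    tr_of_spoke = np.tile(tr_within, n_blocks)

    return RadialAcquisitionPlan(
        spoke_dirs=dirs,
        kr=_radial_samples(samples_per_spoke, kmax),
        block_of_spoke=block_of_spoke,
        tr_of_spoke=tr_of_spoke,
        pattern_of_block=pattern_of_block,
        TR=TR,
        kmax=kmax,
        voxel_mm=voxel_mm,
        pulses_per_block=ppb,
    )


def block_layout(
    n_patterns: int,
    reps: int,
    pulses_per_block: int,
    TR: float = 3.5e-3,
) -> pd.DataFrame:
    """Block table: index, pattern, start time and duration of each RF cycle."""
    if min(n_patterns, reps, pulses_per_block) < 1:
        raise ValueError("n_patterns, reps and pulses_per_block must be positive")
    n_blocks = n_patterns * reps
    duration = pulses_per_block * TR
    return pd.DataFrame(
        {
            "block": np.arange(n_blocks),
            "pattern": np.tile(np.arange(1, n_patterns + 1), reps),
            "start_s": np.arange(n_blocks) * duration,
            "duration_s": duration,
        }
    )


def build_plan(
    n_patterns: int = 6,
    reps: int = 30,
    spokes_per_block: int = 1141,
    samples_per_spoke: int = 64,
    pulses_per_block: int | None = None,
    kmax: float = np.pi,
    TR: float = 3.5e-3,
    ndim: int = 2,
    voxel_mm: float = 1.0,
    repeat_per_block: bool = True,
) -> RadialAcquisitionPlan:
    """Full multi-block golden-angle plan cycling through the patterns."""
    n_spokes = n_patterns * reps * spokes_per_block
    kw = dict(
        n_patterns=n_patterns,
        reps=reps,
        pulses_per_block=pulses_per_block,
        TR=TR,
        voxel_mm=voxel_mm,
    )
    if ndim == 2:
        return golden_angle_2d(
            n_spokes, samples_per_spoke, kmax, repeat_per_block=repeat_per_block, **kw
        )
    return koosh_ball_3d(n_spokes, samples_per_spoke, kmax, **kw)
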