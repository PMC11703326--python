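"""Transient-state signal simulation and fingerprint dictionaries.

A *fingerprint* is the signal time-course a tissue produces under a
transient-state pulse train (an inversion pulse followed by a long train of
hard pulses with varying flip angles, one readout per pulse).  Dictionaries
of fingerprints drive both the temporal-basis construction and the voxel
dynamics of the digital phantom.

The simulator is a single-pool Bloch model: instantaneous rotations for the
RF pulses, free T1/T2 relaxation between them.  It is deliberately pluggable
(see :class:`FingerprintProvider`) so a richer spin model (e.g. a two-pool
magnetization-transfer model) can be substituted without touching the rest
of the pipeline — the basis construction only needs *some* pair of tissue
classes with realistic contrast dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

__all__ = [
    "TissueParams",
    "SequenceSchedule",
    "FingerprintDictionary",
    "FingerprintProvider",
    "BlochFingerprintProvider",
    "simulate_fingerprint",
    "build_dictionary",
    "default_schedules",
    "default_tissue_grid",
    "PARENCHYMA",
    "CSF",
]

PARENCHYMA = "parenchyma"
CSF = "csf"


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of a single tissue compartment.

    Parameters
    ----------
    T1, T2 : float
        Longitudinal / transverse relaxation times in seconds.  Physical
        tissues satisfy ``0 < T2 <= T1``.
    PD : float
        Proton density (arbitrary positive units); scales the signal
        linearly.
    label : str
        Tissue-class tag, e.g. ``"parenchyma"`` or ``"csf"``.
    """

    T1: float
    T2: float
    PD: float = 1.0
    label: str = PARENCHYMA

    def __post_init__(self) -> None:
        if not (self.T1 > 0 and self.T2 > 0):
            raise ValueError(f"relaxation times must be positive, got T1={self.T1}, T2={self.T2}")
        if self.T2 > self.T1:
            raise ValueError(f"non-physical parameters: T2={self.T2} > T1={self.T1}")
        if not self.PD > 0:
            raise ValueError(f"proton density must be positive, got {self.PD}")


@dataclass(frozen=True)
class SequenceSchedule:
    """Flip-angle train of one RF-cycle.

    ``flip_angles`` holds one nutation angle (rad) per hard pulse; pulses are
    spaced ``TR`` seconds apart.  With ``inversion`` a pi pulse precedes the
    train.  ``spoiling`` selects the transverse-coherence handling: ``"none"``
    carries the transverse magnetization from pulse to pulse (hybrid-state
    like behaviour), ``"perfect"`` destroys it before every pulse (classic
    gradient-spoiled limit with an Ernst steady state).
    """

    flip_angles: np.ndarray
    TR: float = 3.5e-3
    inversion: bool = True
    pattern_id: int = 1
    spoiling: str = "none"

    def __post_init__(self) -> None:
        fa = np.asarray(self.flip_angles, dtype=float)
        object.__setattr__(self, "flip_angles", fa)
        if fa.ndim != 1 or fa.size < 1:
            raise ValueError("flip_angles must be a non-empty 1-D array")
        if not self.TR > 0:
            raise ValueError(f"TR must be positive, got {self.TR}")
        if np.any(fa < 0) or np.any(fa > np.pi):
            raise ValueError("flip angles must lie in [0, pi]")
        if self.spoiling not in ("none", "perfect"):
            raise ValueError(f"unknown spoiling mode {self.spoiling!r}")

    def __len__(self) -> int:
        return int(self.flip_angles.size)

    @property
    def duration(self) -> float:
        """Length of one cycle in seconds (pulses times spacing)."""
        return len(self) * self.TR


@dataclass
class FingerprintDictionary:
    """Bank of simulated fingerprints: ``signals`` is T x K (time x atom)."""

    signals: np.ndarray
    params: list[TissueParams]
    schedule: SequenceSchedule

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=complex)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a 2-D (T x K) array")
        if self.signals.shape[1] != len(self.params):
            raise ValueError("one parameter set per dictionary column required")
        if self.signals.shape[0] != len(self.schedule):
            raise ValueError("one time sample per pulse required")
        norms = np.linalg.norm(self.signals, axis=0)
        if np.any(norms == 0):
            raise ValueError("dictionary contains an all-zero fingerprint")

    @property
    def n_atoms(self) -> int:
        return self.signals.shape[1]

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.params]

    def subset(self, label: str) -> "FingerprintDictionary":
        """Restrict to atoms of one tissue class."""
        idx = [k for k, p in enumerate(self.params) if p.label == label]
        if not idx:
            raise ValueError(f"no atoms labelled {label!r} in dictionary")
        return FingerprintDictionary(
            self.signals[:, idx], [self.params[k] for k in idx], self.schedule
        )


class FingerprintProvider(Protocol):
    """Anything that can turn tissue parameters + schedule into a signal."""

    def __call__(self, params: TissueParams, schedule: SequenceSchedule) -> np.ndarray: ...


def simulate_fingerprint(
    params: TissueParams,
    schedule: SequenceSchedule,
    return_mz: bool = False,
) -> np.ndarray:
    """Single-pool Bloch simulation of one fingerprint.

    The magnetization starts at thermal equilibrium ``(0, 0, 1)``; an optional
    inversion flips Mz to -1.  Each hard pulse rotates (Mz, My) instantly by
    its flip angle about the x-axis; the signed transverse component My is
    sampled immediately after the pulse, then the magnetization relaxes
    freely for TR.  The result is scaled by the proton density, so its
    magnitude never exceeds ``params.PD``.

    Returns the length-T complex signal (real-valued up to the phase
    reference); with ``return_mz`` also the longitudinal magnetization
    sampled after each pulse.
    """
    fa = schedule.flip_angles
    E1 = np.exp(-schedule.TR / params.T1)
    E2 = np.exp(-schedule.TR / params.T2)

    mz = -1.0 if schedule.inversion else 1.0
    my = 0.0
    sig = np.empty(len(schedule), dtype=float)
    mz_trace = np.empty(len(schedule), dtype=float)
    for p, alpha in enumerate(fa):
        if schedule.spoiling == "perfect":
            my = 0.0
        c, s = np.cos(alpha), np.sin(alpha)
        my, mz = my * c + mz * s, mz * c - my * s
        sig[p] = my
        mz_trace[p] = mz
        # free relaxation towards equilibrium over one TR
        my *= E2
        mz = 1.0 + (mz - 1.0) * E1

    signal = params.PD * sig.astype(complex)
    if return_mz:
        return signal, params.PD * mz_trace
    return signal


class BlochFingerprintProvider:
    """Default provider wrapping :func:`simulate_fingerprint`."""

    def __call__(self, params: TissueParams, schedule: SequenceSchedule) -> np.ndarray:
        return simulate_fingerprint(params, schedule)


def build_dictionary(
    param_grid: Sequence[TissueParams],
    schedule: SequenceSchedule,
    provider: FingerprintProvider | None = None,
) -> FingerprintDictionary:
    """Simulate one fingerprint per parameter set (labels preserved)."""
    if len(param_grid) == 0:
        raise ValueError("parameter grid is empty")
    provider = provider or BlochFingerprintProvider()
    cols = [provider(p, schedule) for p in param_grid]
    return FingerprintDictionary(np.stack(cols, axis=1), list(param_grid), schedule)


def default_schedules(
    n_patterns: int = 6,
    n_pulses: int = 1141,
    TR: float = 3.5e-3,
    seed: int = 2024,
) -> list[SequenceSchedule]:
    """Six smooth pseudo-random flip-angle patterns.

    Each pattern is a sum of two sinusoidal envelopes with per-pattern
    frequencies and phases drawn from a seeded generator, offset into a
    plausible transient-state range (roughly 5-75 degrees) and clipped to
    [0, pi].  They stand in for optimized acquisition patterns, which are
    sequence-design products outside this package's scope; any set of
    distinct smooth patterns exercises the pipeline identically.
    """
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_pulses)
    schedules = []
    for i in range(n_patterns):
        f1, f2 = rng.uniform(1.5, 6.0, size=2)
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        base = np.deg2rad(40.0) + np.deg2rad(25.0) * np.sin(2 * np.pi * f1 * t + ph1)
        ripple = np.deg2rad(10.0) * np.sin(2 * np.pi * f2 * t + ph2)
        fa = np.clip(base + ripple, 0.0, np.pi)
        schedules.append(SequenceSchedule(fa, TR=TR, inversion=True, pattern_id=i + 1))
    return schedules


def default_tissue_grid() -> list[TissueParams]:
    """Literature-typical 3 T relaxation grid for parenchyma and CSF."""
    grid: list[TissueParams] = []
    for T1 in (0.8, 1.0, 1.2, 1.4):
        for T2 in (0.05, 0.08, 0.11):
            grid.append(TissueParams(T1=T1, T2=T2, PD=1.0, label=PARENCHYMA))
    for T1 in (3.5, 4.0, 4.5):
        for T2 in (1.5, 2.0):
            grid.append(TissueParams(T1=T1, T2=T2, PD=1.0, label=CSF))
    return grid
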