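"""Container formats: HDF5 for k-space and dictionaries, NIfTI for volumes,
CSV for poses and traces, YAML for run configuration."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .basis import SubspaceBasis
from .fingerprints import FingerprintDictionary, SequenceSchedule, TissueParams
from .motion import RigidPose, frame_to_poses, poses_to_frame
from .motionsim import GroundTruthTrace
from .recon import KSpaceData
from .trajectory import RadialAcquisitionPlan

__all__ = [
    "save_plan", "load_plan",
    "save_dictionary", "load_dictionary",
    "save_basis", "load_basis",
    "save_kspace", "load_kspace",
    "save_volume", "load_volume",
    "save_poses", "load_poses",
    "save_trace", "load_trace",
    "load_config", "save_report",
    "load_schedule_csv",
]


def _write_plan(g, plan: RadialAcquisitionPlan) -> None:
    g.create_dataset("dirs", data=plan.spoke_dirs)
    g.create_dataset("kr", data=plan.kr)
    g.create_dataset("block_of_spoke", data=plan.block_of_spoke)
    g.create_dataset("tr_of_spoke", data=plan.tr_of_spoke)
    g.create_dataset("pattern_of_block", data=plan.pattern_of_block)
    g.attrs.update(
        TR=plan.TR, kmax=plan.kmax, voxel_mm=plan.voxel_mm, pulses_per_block=plan.pulses_per_block
    )


def _read_plan(g) -> RadialAcquisitionPlan:
    return RadialAcquisitionPlan(
        spoke_dirs=g["dirs"][:],
        kr=g["kr"][:],
        block_of_spoke=g["block_of_spoke"][:],
        tr_of_spoke=g["tr_of_spoke"][:],
        pattern_of_block=g["pattern_of_block"][:],
        TR=float(g.attrs["TR"]),
        kmax=float(g.attrs["kmax"]),
        voxel_mm=float(g.attrs["voxel_mm"]),
        pulses_per_block=int(g.attrs["pulses_per_block"]),
    )


def save_plan(path: str | Path, plan: RadialAcquisitionPlan) -> None:
    with h5py.File(path, "w") as f:
        _write_plan(f.create_group("traj"), plan)


def load_plan(path: str | Path) -> RadialAcquisitionPlan:
    with h5py.File(path, "r") as f:
        return _read_plan(f["traj"])


def save_dictionary(path: str | Path, d: FingerprintDictionary) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=d.signals)
        f.create_dataset("T1", data=[p.T1 for p in d.params])
        f.create_dataset("T2", data=[p.T2 for p in d.params])
        f.create_dataset("PD", data=[p.PD for p in d.params])
        f.create_dataset("label", data=[p.label for p in d.params])
        g = f.create_group("schedule")
        g.create_dataset("flip_angles", data=d.schedule.flip_angles)
        g.attrs.update(
            TR=d.schedule.TR,
            inversion=d.schedule.inversion,
            pattern_id=d.schedule.pattern_id,
            spoiling=d.schedule.spoiling,
        )


def load_dictionary(path: str | Path) -> FingerprintDictionary:
    with h5py.File(path, "r") as f:
        g = f["schedule"]
        sched = SequenceSchedule(
            g["flip_angles"][:],
            TR=float(g.attrs["TR"]),
            inversion=bool(g.attrs["inversion"]),
            pattern_id=int(g.attrs["pattern_id"]),
            spoiling=str(g.attrs["spoiling"]),
        )
        params = [
            TissueParams(T1=t1, T2=t2, PD=pd_, label=lab.decode() if isinstance(lab, bytes) else str(lab))
            for t1, t2, pd_, lab in zip(f["T1"][:], f["T2"][:], f["PD"][:], f["label"][:])
        ]
        return FingerprintDictionary(f["signals"][:], params, sched)


def save_basis(path: str | Path, basis: SubspaceBasis) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("U", data=basis.U)
        f.attrs.update(kind=basis.kind, pattern_id=basis.pattern_id)
        if basis.eigenvalues is not None:
            f.create_dataset("eigenvalues", data=np.asarray(basis.eigenvalues))


def load_basis(path: str | Path) -> SubspaceBasis:
    with h5py.File(path, "r") as f:
        eig = f["eigenvalues"][:] if "eigenvalues" in f else None
        return SubspaceBasis(
            f["U"][:], kind=str(f.attrs["kind"]), pattern_id=int(f.attrs["pattern_id"]), eigenvalues=eig
        )


def save_kspace(path: str | Path, ks: KSpaceData, **attrs) -> None:
    plan = ks.plan
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=ks.data)
        if ks.coil_maps is not None:
            f.create_dataset("coils", data=ks.coil_maps)
        _write_plan(f.create_group("traj"), plan)
        f.attrs.update(**attrs)


def load_kspace(path: str | Path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        plan = _read_plan(f["traj"])
        coils = f["coils"][:] if "coils" in f else None
        return KSpaceData(data=f["data"][:], plan=plan, coil_maps=coils)


def save_volume(path: str | Path, volume: np.ndarray, voxel_mm: float = 1.0) -> None:
    """Write a (possibly complex) volume as NIfTI; complex data as magnitude."""
    vol = np.asarray(volume)
    if np.iscomplexobj(vol):
        vol = np.abs(vol)
    while vol.ndim < 3:
        vol = vol[..., None]
    affine = np.diag([voxel_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])


def save_poses(path: str | Path, poses: list[RigidPose]) -> None:
    poses_to_frame(poses).to_csv(path, index=False)


def load_poses(path: str | Path, ndim: int = 3) -> list[RigidPose]:
    return frame_to_poses(pd.read_csv(path), ndim=ndim)


def save_trace(path: str | Path, trace: GroundTruthTrace) -> None:
    cols = {"t_s": trace.times}
    for i in range(trace.ndim):
        cols[f"t{'xyz'[i]}_mm"] = trace.translations[:, i]
    for i in range(trace.angles.shape[1]):
        cols[f"r{i}_deg"] = np.rad2deg(trace.angles[:, i])
    pd.DataFrame(cols).to_csv(path, index=False)


def load_trace(path: str | Path, rate_hz: float = 30.0) -> GroundTruthTrace:
    df = pd.read_csv(path)
    tcols = [c for c in df.columns if c.startswith("t") and c.endswith("_mm")]
    rcols = [c for c in df.columns if c.startswith("r") and c.endswith("_deg")]
    return GroundTruthTrace(
        df["t_s"].to_numpy(),
        df[tcols].to_numpy(),
        np.deg2rad(df[rcols].to_numpy()),
        native_rate_hz=rate_hz,
    )


def load_schedule_csv(path: str | Path, TR: float = 3.5e-3, pattern_id: int = 1) -> SequenceSchedule:
    """One flip angle per row, in degrees."""
    fa = np.loadtxt(path, ndmin=1)
    return SequenceSchedule(np.deg2rad(fa), TR=TR, pattern_id=pattern_id)


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_report(path: str | Path, report: dict) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as f:
        json.dump(report, f, indent=2, default=default)
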