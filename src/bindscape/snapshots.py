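"""Snapshot streams: records, CSV round-trip, superposition, ligand RMSD.

A snapshot table is the pipeline's central exchange format: one row per ligand
copy per stored frame, with the ligand center of mass already expressed in the
reference-structure coordinate system (the tested core contract).  Columns::

    traj_id, ligand_id, time_ns, x, y, z [, energy] [, bound]

``energy`` (kcal/mol, from any external scorer) may be blank for frames where
no score exists (e.g. unbound excursions).  Ligand heavy-atom coordinates, when
available, live in a companion long-format table::

    traj_id, ligand_id, time_ns, atom_index, x, y, z

Raw, un-superposed snapshots are supported through :func:`superpose`: fit the
per-frame protein C-alphas to the reference (Kabsch least squares) and apply
the recovered rigid transform to the ligand coordinates of that frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import CorrespondenceError, InputError

__all__ = [
    "SnapshotRecord",
    "RigidTransform",
    "read_snapshots",
    "write_snapshots",
    "superpose",
    "superpose_models",
    "ligand_rmsd",
]


@dataclass
class SnapshotRecord:
    """One ligand copy at one stored time."""

    traj_id: str
    ligand_id: str
    time: float  # ns
    com: np.ndarray  # (3,) Å, reference frame
    ligand_atoms: np.ndarray | None = None  # (k, 3) Å, fixed k per ligand
    energy: float | None = None  # kcal/mol
    bound: bool | None = None

    def __post_init__(self):
        self.com = np.asarray(self.com, dtype=float)
        if self.ligand_atoms is not None:
            self.ligand_atoms = np.asarray(self.ligand_atoms, dtype=float)


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t, the least-squares superposition transform."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float  # Å, C-alpha residual after superposition

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation


def _validate(records: list[SnapshotRecord]) -> None:
    last_time: dict[tuple[str, str], float] = {}
    atom_counts: dict[str, int] = {}
    for rec in records:
        key = (rec.traj_id, rec.ligand_id)
        if key in last_time and rec.time <= last_time[key]:
            raise InputError(
                f"times not strictly increasing for {rec.traj_id}/{rec.ligand_id} "
                f"at t={rec.time}"
            )
        last_time[key] = rec.time
        if rec.ligand_atoms is not None:
            k = len(rec.ligand_atoms)
            if atom_counts.setdefault(rec.ligand_id, k) != k:
                raise InputError(
                    f"ligand {rec.ligand_id} changes atom count "
                    f"({atom_counts[rec.ligand_id]} -> {k})"
                )


def write_snapshots(
    records: list[SnapshotRecord],
    path,
    atoms_path=None,
) -> None:
    """Write records (and, if requested, their atom blocks) as CSV.

    Floats are written with fixed precision so that identical inputs give
    byte-identical files and the round-trip error stays below 1e-9.
    """
    _validate(records)
    rows = []
    for rec in records:
        rows.append(
            {
                "traj_id": rec.traj_id,
                "ligand_id": rec.ligand_id,
                "time_ns": f"{rec.time:.6f}",
                "x": f"{rec.com[0]:.9f}",
                "y": f"{rec.com[1]:.9f}",
                "z": f"{rec.com[2]:.9f}",
                "energy": "" if rec.energy is None else f"{rec.energy:.9f}",
                "bound": "" if rec.bound is None else int(rec.bound),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    if atoms_path is not None:
        arows = []
        for rec in records:
            if rec.ligand_atoms is None:
                continue
            for i, a in enumerate(rec.ligand_atoms):
                arows.append(
                    {
                        "traj_id": rec.traj_id,
                        "ligand_id": rec.ligand_id,
                        "time_ns": f"{rec.time:.6f}",
                        "atom_index": i,
                        "x": f"{a[0]:.9f}",
                        "y": f"{a[1]:.9f}",
                        "z": f"{a[2]:.9f}",
                    }
                )
        pd.DataFrame(arows).to_csv(atoms_path, index=False)


def read_snapshots(path, atoms_path=None) -> list[SnapshotRecord]:
    """Read a snapshot CSV (and optional atoms CSV) back into records."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"traj_id": str, "ligand_id": str})
    required = {"traj_id", "ligand_id", "time_ns", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"snapshot table lacks columns: {sorted(missing)}")
    atoms_lookup: dict[tuple[str, str, float], np.ndarray] = {}
    if atoms_path is not None and Path(atoms_path).exists():
        adf = pd.read_csv(atoms_path, dtype={"traj_id": str, "ligand_id": str})
        for (tid, lid, t), grp in adf.groupby(["traj_id", "ligand_id", "time_ns"]):
            grp = grp.sort_values("atom_index")
            atoms_lookup[(tid, lid, float(t))] = grp[["x", "y", "z"]].to_numpy(float)
    records = []
    for row in df.itertuples(index=False):
        energy = getattr(row, "energy", None)
        if energy is not None and (isinstance(energy, float) and math.isnan(energy)):
            energy = None
        bound = getattr(row, "bound", None)
        if bound is not None and (isinstance(bound, float) and math.isnan(bound)):
            bound = None
        key = (row.traj_id, row.ligand_id, float(row.time_ns))
        records.append(
            SnapshotRecord(
                traj_id=row.traj_id,
                ligand_id=row.ligand_id,
                time=float(row.time_ns),
                com=np.array([row.x, row.y, row.z], dtype=float),
                ligand_atoms=atoms_lookup.get(key),
                energy=None if energy is None else float(energy),
                bound=None if bound is None else bool(int(bound)),
            )
        )
    _validate(records)
    return records


def superpose(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition (Kabsch) of paired coordinate sets.

    Returns the transform that maps ``mobile`` onto ``reference`` with minimal
    RMSD; apply it to every coordinate of the mobile frame (protein and
    ligand alike) before any landscape analysis.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise CorrespondenceError(
            f"coordinate sets differ: {mobile.shape} vs {reference.shape}"
        )
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    rot, _ = Rotation.align_vectors(reference - rc, mobile - mc)
    R = rot.as_matrix()
    t = rc - R @ mc
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return RigidTransform(rotation=R, translation=t, rmsd=rmsd)


def superpose_models(mobile, reference) -> RigidTransform:
    """Superpose two same-topology structures on their C-alpha subsets."""
    mca, rca = mobile.ca_coords, reference.ca_coords
    if len(mca) != len(rca):
        raise CorrespondenceError(
            f"C-alpha counts differ: {len(mca)} vs {len(rca)}"
        )
    if len(mca) == 0:
        raise InputError("no C-alpha atoms available for superposition")
    return superpose(mca, rca)


def ligand_rmsd(snapshot: SnapshotRecord, native_pose: np.ndarray) -> float:
    """RMSD of the (already superposed) ligand heavy atoms to the native pose.

    The ligand is *not* re-fitted: the deviation measures both internal
    conformation and placement relative to the pocket, in fixed atom order.
    """
    if snapshot.ligand_atoms is None:
        raise InputError("snapshot carries no ligand atom coordinates")
    native_pose = np.asarray(native_pose, dtype=float)
    if snapshot.ligand_atoms.shape != native_pose.shape:
        raise CorrespondenceError(
            f"ligand atom counts differ: {snapshot.ligand_atoms.shape} "
            f"vs {native_pose.shape}"
        )
    d = snapshot.ligand_atoms - native_pose
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))
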