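"""Binding-pathway extraction on the landscape.

The binding pathway of a successful trajectory is the time-ordered sequence of
the ligand's bound-state surface positions, ending in the destination well.
Raw per-frame sequences are simplified to sparse *key positions* by run-length
encoding over grid cells: consecutive frames in the same 3°×3° cell merge into
one dwell, and dwells of at least ``dwell_min`` frames survive as key points
(position = spherical mean of the member positions, time = first entry).
Consecutive key points are connected by great-circle segments, along which the
smoothed landscape is sampled to report the energy barrier each hop climbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PathwayUnavailableError
from .geometry import GeoPosition, ReferenceFrame, circular_mean, slerp, to_geographic
from .landscape import GridMap, assign_cell

__all__ = [
    "PathPoint",
    "KeyPoint",
    "BindingPathway",
    "extract_pathway",
    "simplify",
    "annotate_barriers",
]


@dataclass(frozen=True)
class PathPoint:
    """One bound frame on the surface; ``gap_before`` marks an unbound break
    between this point and its predecessor."""

    time: float
    geo: GeoPosition
    cell: tuple[int, int]
    gap_before: bool = False


@dataclass
class KeyPoint:
    """A dwell-merged key position."""

    time: float  # ns, first entry into the dwell
    geo: GeoPosition  # spherical mean of member positions
    cell: tuple[int, int]
    dwell: int  # member frame count
    gap_before: bool = False
    dG: float | None = None


@dataclass
class BindingPathway:
    traj_id: str
    ligand_id: str
    key_points: list[KeyPoint]
    destination_well_id: int | None = None
    barriers: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, kp in enumerate(self.key_points):
            barrier = (
                self.barriers[i] if i < len(self.barriers) else None
            )
            rows.append(
                {
                    "ordinal": i,
                    "time_ns": kp.time,
                    "lat": kp.geo.lat,
                    "lon": kp.geo.lon,
                    "i_lon": kp.cell[0],
                    "i_lat": kp.cell[1],
                    "dwell": kp.dwell,
                    "dG": kp.dG,
                    "barrier_to_next": barrier,
                }
            )
        return pd.DataFrame(rows)


def extract_pathway(
    records,
    frame: ReferenceFrame,
    bound_flags=None,
    successful: bool = True,
) -> list[PathPoint]:
    """Chronological bound-state surface positions of one ligand copy.

    ``records`` are the time-ordered snapshots of a single trajectory/ligand;
    ``bound_flags`` overrides the records' own bound flags.  Unbound stretches
    appear as ``gap_before`` marks on the first bound frame that follows.

    Raises :class:`PathwayUnavailableError` for trajectories that were not
    classified successful or never reach the bound state.
    """
    if not successful:
        raise PathwayUnavailableError("trajectory was not classified successful")
    if bound_flags is None:
        bound_flags = [bool(r.bound) for r in records]
    points: list[PathPoint] = []
    pending_gap = False
    for rec, flag in zip(records, bound_flags):
        if not flag:
            if points:
                pending_gap = True
            continue
        g = to_geographic(frame, rec.com)
        points.append(
            PathPoint(
                time=float(rec.time),
                geo=g,
                cell=assign_cell(g),
                gap_before=pending_gap,
            )
        )
        pending_gap = False
    if not points:
        raise PathwayUnavailableError("ligand is never in the bound state")
    return points


def simplify(points, dwell_min: int = 10) -> list[KeyPoint]:
    """Run-length encode a pathway over grid cells and keep long dwells.

    Accepts raw :class:`PathPoint` sequences or already-simplified
    :class:`KeyPoint` sequences (each key point counts with its stored dwell),
    which makes the operation idempotent.  Runs never merge across unbound
    gaps.
    """
    runs: list[dict] = []
    for p in points:
        dwell = getattr(p, "dwell", 1)
        if runs and runs[-1]["cell"] == p.cell and not p.gap_before:
            runs[-1]["dwell"] += dwell
            runs[-1]["members"].append((p.geo, dwell))
        else:
            runs.append(
                {
                    "cell": p.cell,
                    "time": p.time,
                    "dwell": dwell,
                    "members": [(p.geo, dwell)],
                    "gap_before": p.gap_before,
                }
            )
    keys: list[KeyPoint] = []
    for run in runs:
        if run["dwell"] < dwell_min:
            continue
        # dwell-weighted spherical mean keeps re-simplification a no-op
        expanded = [g for g, w in run["members"] for _ in range(int(w))]
        geo = circular_mean(expanded)
        keys.append(
            KeyPoint(
                time=run["time"],
                geo=geo,
                cell=run["cell"],
                dwell=run["dwell"],
                gap_before=run["gap_before"],
            )
        )
    return keys


def build_pathway(
    records,
    frame: ReferenceFrame,
    grid: GridMap | None = None,
    wells=None,
    traj_id: str = "",
    ligand_id: str = "",
    bound_flags=None,
    successful: bool = True,
    dwell_min: int = 10,
) -> BindingPathway:
    """Extract + simplify + annotate against the grid and well segmentation."""
    raw = extract_pathway(records, frame, bound_flags=bound_flags,
                          successful=successful)
    keys = simplify(raw, dwell_min=dwell_min)
    if not keys:
        # guarantee at least the final dwell as a key point
        keys = simplify(raw, dwell_min=1)[-1:]
    if grid is not None:
        for kp in keys:
            i_lon, i_lat = kp.cell
            v = grid.dG[i_lat, i_lon]
            kp.dG = None if np.isnan(v) else float(v)
    dest = None
    if wells:
        final = keys[-1].cell
        for w in wells:
            if final in w.cells:
                dest = w.id
                break
    return BindingPathway(
        traj_id=traj_id,
        ligand_id=ligand_id,
        key_points=keys,
        destination_well_id=dest,
    )


def annotate_barriers(
    pathway: BindingPathway, surface, n_samples: int = 50
) -> list[float]:
    """Energy barrier climbed on each great-circle hop between key points.

    barrier = max(surface along segment) − max(endpoint values), floored at 0;
    a zero-length segment has no barrier.  ``surface`` is any callable over
    (lon, lat) points, normally the thin-plate-smoothed landscape.
    """
    barriers: list[float] = []
    kps = pathway.key_points
    for a, b in zip(kps[:-1], kps[1:]):
        if (
            abs(a.geo.lat - b.geo.lat) < 1e-12
            and abs(a.geo.lon - b.geo.lon) < 1e-12
        ):
            barriers.append(0.0)
            continue
        pts = slerp(a.geo, b.geo, n_samples)
        z = surface(np.array([[g.lon, g.lat] for g in pts]))
        barrier = float(max(0.0, np.max(z) - max(z[0], z[-1])))
        barriers.append(barrier)
    pathway.barriers = barriers
    return barriers
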