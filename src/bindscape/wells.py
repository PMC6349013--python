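"""Energy-well taxonomy and pocket statistics on the gridded landscape.

Cells with ΔG below the well threshold (−4.1 kcal/mol, i.e. Kd < 1000 μM at
298.15 K) form *energy wells*; the band between −4.1 and 0 is the *barrier*
region.  Wells are connected components of sub-threshold cells under
8-neighbour connectivity, wrapping across the ±180° longitude seam (the map is
periodic in longitude only).  A well whose minimum falls below the deep-well
threshold (−8.2 kcal/mol, Kd < 1000 nM) is a deep well (DW); otherwise it is a
shallow well (SW).

Pocket accounting uses a :class:`PocketMask` — an explicit cell set or a
spherical cap — to split deep-well cells and high-binding-probability cells
(count > 360 num./grid) into inside/outside-pocket populations, the key
numbers of a per-system summary row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from skimage.measure import label as cc_label

from .errors import DependencyError, InputError
from .geometry import GeoPosition, angular_distance
from .landscape import (
    GridMap,
    ThinPlateSpline,
    cell_center,
    exp_average,
    grid_sd,
    tps_smooth,
)

__all__ = [
    "WELL_CUT",
    "DW_CUT",
    "HIGH_BP_CUT",
    "Well",
    "PocketMask",
    "segment_wells",
    "fraction_percent",
    "pocket_fraction",
    "high_bp_cells",
    "high_bp_fraction",
    "probability_surface",
    "minimal_pose_energy",
    "summarize_system",
    "summary_table",
]

WELL_CUT = -4.1  # kcal/mol, Kd < 1000 uM
DW_CUT = -8.2  # kcal/mol, Kd < 1000 nM
HIGH_BP_CUT = 360  # num./grid, 60% of the ~600 num./grid pocket level


@dataclass
class Well:
    """One connected low-energy basin."""

    id: int
    category: str  # "DW" | "SW"
    cells: list[tuple[int, int]]  # (i_lon, i_lat) members
    min_dG: float
    min_cell: tuple[int, int]

    @property
    def area(self) -> int:
        return len(self.cells)


@dataclass
class PocketMask:
    """Cells regarded as 'inside the target pocket'.

    Either an explicit cell set or a spherical cap (center + angular radius in
    degrees); a cap is resolved against cell centers.
    """

    cells: set = field(default_factory=set)
    center: GeoPosition | None = None
    radius_deg: float | None = None

    def __post_init__(self):
        if self.center is not None:
            if self.radius_deg is None or not (0 < self.radius_deg <= 90):
                raise InputError("cap radius must be in (0, 90] degrees")
        elif not self.cells:
            raise InputError("pocket mask is empty")

    def contains(self, i_lon: int, i_lat: int) -> bool:
        if self.center is not None:
            return (
                angular_distance(cell_center(i_lon, i_lat), self.center)
                <= self.radius_deg
            )
        return (i_lon, i_lat) in self.cells

    @classmethod
    def cap_at_minimum(cls, grid: GridMap, radius_deg: float = 15.0) -> "PocketMask":
        """Default mask: cap centred on the landscape's global minimum."""
        mc = grid.min_cell()
        if mc is None:
            raise InputError("grid has no energies; cannot place the pocket cap")
        return cls(center=cell_center(*mc), radius_deg=radius_deg)


def _merge_seam(labels: np.ndarray) -> np.ndarray:
    """Union labels that touch across the ±180° longitude seam (8-neighbour)."""
    n_lat = labels.shape[0]
    parent = {}

    def find(a):
        while parent.get(a, a) != a:
            parent[a] = parent.get(parent[a], parent[a])
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for r in range(n_lat):
        left = labels[r, 0]
        if left == 0:
            continue
        for dr in (-1, 0, 1):
            r2 = r + dr
            if 0 <= r2 < n_lat and labels[r2, -1] != 0:
                union(left, labels[r2, -1])
    out = labels.copy()
    for v in np.unique(labels):
        if v != 0:
            out[labels == v] = find(v)
    return out


def segment_wells(
    grid: GridMap, well_cut: float = WELL_CUT, dw_cut: float = DW_CUT
) -> list[Well]:
    """Segment sub-threshold cells into wells and classify each DW/SW.

    Wells are returned sorted by minimum energy (deepest first) and numbered
    from 1 in that order.
    """
    mask = np.where(np.isnan(grid.dG), False, grid.dG < well_cut)
    labels = cc_label(mask, connectivity=2)
    labels = _merge_seam(labels)
    wells = []
    for v in np.unique(labels):
        if v == 0:
            continue
        member_idx = np.argwhere(labels == v)
        cells = [(int(i_lon), int(i_lat)) for i_lat, i_lon in member_idx]
        dgs = np.array([grid.dG[i_lat, i_lon] for i_lon, i_lat in cells])
        k = int(np.argmin(dgs))
        min_dG = float(dgs[k])
        category = "DW" if min_dG < dw_cut else "SW"
        wells.append(
            Well(id=0, category=category, cells=cells, min_dG=min_dG,
                 min_cell=cells[k])
        )
    wells.sort(key=lambda w: w.min_dG)
    for i, w in enumerate(wells, start=1):
        w.id = i
    return wells


def _round2(pct: float) -> float:
    """Two decimals, half away from zero (table formatting convention)."""
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def fraction_percent(inside: int, total: int) -> float:
    """100 × inside / total at two decimals; 0.00 for an empty total."""
    if total == 0:
        return 0.00
    return _round2(100.0 * inside / total)


def pocket_fraction(
    wells: list[Well], mask: PocketMask, category: str = "DW"
) -> tuple[int, int, float]:
    """(total, inside, percent) over member cells of wells of ``category``."""
    member = [c for w in wells if w.category == category for c in w.cells]
    total = len(member)
    inside = sum(mask.contains(*c) for c in member)
    return total, inside, fraction_percent(inside, total)


def high_bp_cells(
    grid: GridMap, threshold: int = HIGH_BP_CUT
) -> set[tuple[int, int]]:
    """Cells whose binding number strictly exceeds ``threshold`` num./grid."""
    idx = np.argwhere(grid.counts > threshold)
    return {(int(i_lon), int(i_lat)) for i_lat, i_lon in idx}


def high_bp_fraction(
    cells: set[tuple[int, int]], mask: PocketMask
) -> tuple[int, int, float]:
    """(total, inside, percent) of high-binding-probability cells."""
    total = len(cells)
    inside = sum(mask.contains(*c) for c in cells)
    return total, inside, fraction_percent(inside, total)


def probability_surface(grid: GridMap, lam: float = 0.0) -> ThinPlateSpline:
    """Thin-plate smoothing of the raw per-cell binding numbers.

    All-zero grids short-circuit to a zero surface (there is nothing to fit).
    """
    if grid.total_count == 0:
        class _Zero:
            def __call__(self, pts):
                return np.zeros(len(np.atleast_2d(pts)))

            def evaluate_geo(self, positions):
                return np.zeros(len(positions))

        return _Zero()
    occ = int(grid.occupied().sum())
    if occ < 3:
        # too few nodes for a spline; fall back to the raw (nearest-cell) map
        class _Raw:
            def __init__(self, g):
                self.g = g

            def __call__(self, pts):
                from .landscape import assign_cell

                pts = np.atleast_2d(pts)
                out = []
                for lon, lat in pts:
                    i_lon, i_lat = assign_cell(GeoPosition(lat=lat, lon=lon))
                    out.append(float(self.g.counts[i_lat, i_lon]))
                return np.array(out)

            def evaluate_geo(self, positions):
                return self(np.array([[g.lon, g.lat] for g in positions]))

        return _Raw(grid)
    return tps_smooth(grid, lam=lam, quantity="count")


def minimal_pose_energy(
    rmsd_energy: list[tuple[float, float]],
    window: float = 2.0,
    B: int = 200,
    seed: int = 0,
    thermo=None,
) -> tuple[float | None, float | None, float | None]:
    """(min RMSD, exp-average energy of near-minimal poses, bootstrap SD).

    Near-minimal poses are snapshots whose RMSD lies within ``window`` Å of
    the minimal RMSD observed for the system.
    """
    from .landscape import ThermoConstants

    thermo = thermo or ThermoConstants()
    pairs = [(r, e) for r, e in rmsd_energy if e is not None and np.isfinite(r)]
    if not pairs:
        return None, None, None
    rmin = min(r for r, _ in pairs)
    sel = [e for r, e in pairs if r <= rmin + window]
    dg = exp_average(sel, thermo)
    sd = grid_sd(sel, thermo, B=B, seed=seed)
    return float(rmin), float(dg), sd


def summarize_system(
    name: str,
    grid: GridMap,
    wells: list[Well],
    mask: PocketMask,
    calls=None,
    rmsd_energy=None,
    n_successful: int | None = None,
    B: int = 200,
    seed: int = 0,
) -> dict:
    """One per-system summary row (the printed-table column set).

    Raises :class:`DependencyError` naming the missing stage when an upstream
    artifact is absent.
    """
    if grid is None:
        raise DependencyError("landscape")
    if wells is None:
        raise DependencyError("wells")
    from .bound import effective_binding_percent

    dw_total, dw_inside, dw_pct = pocket_fraction(wells, mask, "DW")
    bp = high_bp_cells(grid)
    bp_total, bp_inside, bp_pct = high_bp_fraction(bp, mask)
    min_rmsd, pose_dG, pose_sd = (None, None, None)
    if rmsd_energy:
        min_rmsd, pose_dG, pose_sd = minimal_pose_energy(
            rmsd_energy, B=B, seed=seed, thermo=grid.thermo
        )
    eff_pct = effective_binding_percent(calls) if calls else 0.00
    sd_max = float(np.nanmax(grid.sd)) if not np.all(np.isnan(grid.sd)) else None
    return {
        "system": name,
        "successful_simulations": n_successful,
        "minimal_rmsd_A": min_rmsd,
        "min_pose_dG_kcal_mol": pose_dG,
        "min_pose_dG_sd": pose_sd,
        "landscape_sd_max": sd_max,
        "dw_cells_total": dw_total,
        "dw_cells_inside_pocket": dw_inside,
        "dw_inside_pct": dw_pct,
        "high_bp_cells_total": bp_total,
        "high_bp_cells_inside_pocket": bp_inside,
        "high_bp_inside_pct": bp_pct,
        "effective_binding_pct": eff_pct,
    }


def summary_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-system rows into the report table."""
    return pd.DataFrame(rows)
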