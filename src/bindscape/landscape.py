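"""Gridded binding-energy landscape on the unrolled geographic map.

The globe is unrolled into an equirectangular (plate carrée) map and divided
into 7200 unit cells of 3°×3° (120 longitude columns × 60 latitude rows).
Each bound snapshot contributes its geographic position to one cell's count
(the "num./grid" binding-probability measure) and, when an external scorer
supplied a binding energy, to that cell's exponential (Boltzmann) average

    ΔG_cell = −RT · ln ⟨ exp(−E_i / RT) ⟩_cell ,

which weights low-energy visits more strongly than the arithmetic mean — the
cell energy approaches the best energies seen there as RT → 0 and the plain
mean as RT → ∞.  Cell-level uncertainty is a nonparametric bootstrap SD of the
same estimator.  The Kd calibration ΔG = RT ln(Kd / c°) ties energy thresholds
to dissociation constants: at 298.15 K, Kd = 1000 μM ↔ −4.1 kcal/mol (well
threshold) and Kd = 1000 nM ↔ −8.2 kcal/mol (deep-well threshold).

Continuous surfaces for display and barrier profiling are thin-plate splines
(r² log r kernel plus an affine part) fitted to occupied cell centers on the
map plane; the smoothing parameter λ trades fidelity for stiffness, with λ=0
interpolating the nodes exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from scipy.special import logsumexp

from .errors import FitError, InputError
from .geometry import GeoPosition

__all__ = [
    "ThermoConstants",
    "GridMap",
    "N_LON",
    "N_LAT",
    "CELL_DEG",
    "assign_cell",
    "cell_center",
    "exp_average",
    "kd_to_dG",
    "dG_to_kd",
    "grid_sd",
    "build_grid",
    "ThinPlateSpline",
    "tps_smooth",
]

N_LON = 120
N_LAT = 60
CELL_DEG = 3.0

R_KCAL = 1.9872e-3  # kcal/(mol K)


@dataclass(frozen=True)
class ThermoConstants:
    """Gas constant, temperature and standard concentration for Kd↔ΔG."""

    T: float = 298.15  # K
    R: float = R_KCAL  # kcal/(mol K)
    c0: float = 1.0  # M, reference concentration

    def __post_init__(self):
        if self.T <= 0:
            raise InputError("temperature must be positive")

    @property
    def RT(self) -> float:
        return self.R * self.T


def assign_cell(g: GeoPosition) -> tuple[int, int]:
    """Map a geographic position to its (i_lon, i_lat) cell.

    Bins are half-open [edge, edge + 3°); the north pole (lat = +90) is folded
    into the top row so every valid position lands in exactly one of the 7200
    cells.
    """
    i_lon = int(np.floor((g.lon + 180.0) / CELL_DEG))
    i_lat = int(np.floor((g.lat + 90.0) / CELL_DEG))
    i_lon = min(max(i_lon, 0), N_LON - 1)
    i_lat = min(max(i_lat, 0), N_LAT - 1)
    return i_lon, i_lat


def cell_center(i_lon: int, i_lat: int) -> GeoPosition:
    """Geographic center of cell (i_lon, i_lat)."""
    return GeoPosition(
        lat=-90.0 + CELL_DEG * (i_lat + 0.5),
        lon=-180.0 + CELL_DEG * (i_lon + 0.5),
    )


def exp_average(energies, thermo: ThermoConstants = ThermoConstants()) -> float:
    """Exponential (Boltzmann) average −RT ln⟨e^(−E/RT)⟩, overflow-safe.

    Always lies between min(E) and the arithmetic mean of E, strictly inside
    when the energies differ.
    """
    e = np.asarray(energies, dtype=float)
    if e.size == 0:
        raise InputError("empty energy list")
    rt = thermo.RT
    return float(-rt * (logsumexp(-e / rt) - np.log(e.size)))


def kd_to_dG(kd: float, thermo: ThermoConstants = ThermoConstants()) -> float:
    """Binding free energy (kcal/mol) of a dissociation constant (molar)."""
    if kd <= 0:
        raise InputError("Kd must be positive")
    return float(thermo.RT * np.log(kd / thermo.c0))


def dG_to_kd(dG: float, thermo: ThermoConstants = ThermoConstants()) -> float:
    """Inverse of :func:`kd_to_dG` (molar)."""
    return float(thermo.c0 * np.exp(dG / thermo.RT))


def grid_sd(
    energies,
    thermo: ThermoConstants = ThermoConstants(),
    B: int = 200,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> float | None:
    """Bootstrap SD of the cell exponential average (B resamples, seeded).

    Returns None for cells with fewer than two energies (no resampling
    information)."""
    e = np.asarray(energies, dtype=float)
    if e.size < 2:
        return None
    if rng is None:
        rng = np.random.default_rng(seed)
    idx = rng.integers(0, e.size, size=(B, e.size))
    rt = thermo.RT
    vals = -rt * (logsumexp(-e[idx] / rt, axis=1) - np.log(e.size))
    return float(np.std(vals, ddof=1))


@dataclass
class GridMap:
    """The 120×60 landscape lattice.

    Arrays are indexed ``[i_lat, i_lon]`` (south to north rows, west to east
    columns).  ``counts`` is the binding number per cell (num./grid); ``dG``
    and ``sd`` are NaN where undefined (unvisited cells, or single-visit cells
    for ``sd``).  ``cell_energies`` retains the raw per-cell energy samples so
    downstream stages (minimal-RMSD pose energies, bootstrap refits) can
    reweight without re-binning.
    """

    counts: np.ndarray = field(
        default_factory=lambda: np.zeros((N_LAT, N_LON), dtype=int)
    )
    dG: np.ndarray = field(
        default_factory=lambda: np.full((N_LAT, N_LON), np.nan)
    )
    sd: np.ndarray = field(
        default_factory=lambda: np.full((N_LAT, N_LON), np.nan)
    )
    thermo: ThermoConstants = field(default_factory=ThermoConstants)
    cell_energies: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.counts.size

    @property
    def total_count(self) -> int:
        return int(self.counts.sum())

    def occupied(self) -> np.ndarray:
        """Boolean mask of visited cells."""
        return self.counts > 0

    def min_cell(self) -> tuple[int, int] | None:
        """(i_lon, i_lat) of the global dG minimum, or None if no energies."""
        if np.all(np.isnan(self.dG)):
            return None
        i_lat, i_lon = np.unravel_index(np.nanargmin(self.dG), self.dG.shape)
        return int(i_lon), int(i_lat)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-cell table (all 7200 cells)."""
        rows = []
        for i_lat in range(N_LAT):
            for i_lon in range(N_LON):
                c = cell_center(i_lon, i_lat)
                rows.append(
                    {
                        "i_lon": i_lon,
                        "i_lat": i_lat,
                        "lon_center": c.lon,
                        "lat_center": c.lat,
                        "count": int(self.counts[i_lat, i_lon]),
                        "dG": self.dG[i_lat, i_lon],
                        "sd": self.sd[i_lat, i_lon],
                    }
                )
        return pd.DataFrame(rows)

    def write(self, csv_path, meta_path=None) -> None:
        df = self.to_frame()
        df["dG"] = df["dG"].map(lambda v: "" if np.isnan(v) else f"{v:.4f}")
        df["sd"] = df["sd"].map(lambda v: "" if np.isnan(v) else f"{v:.4f}")
        df.to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = dict(self.meta)
            meta.update(
                {
                    "n_lon": N_LON,
                    "n_lat": N_LAT,
                    "cell_deg": CELL_DEG,
                    "T_K": self.thermo.T,
                    "RT_kcal_mol": self.thermo.RT,
                    "total_count": self.total_count,
                }
            )
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    @classmethod
    def read(cls, csv_path, thermo: ThermoConstants | None = None) -> "GridMap":
        df = pd.read_csv(csv_path)
        grid = cls(thermo=thermo or ThermoConstants())
        for row in df.itertuples(index=False):
            grid.counts[int(row.i_lat), int(row.i_lon)] = int(row.count)
            if not (isinstance(row.dG, float) and np.isnan(row.dG)):
                grid.dG[int(row.i_lat), int(row.i_lon)] = float(row.dG)
            if not (isinstance(row.sd, float) and np.isnan(row.sd)):
                grid.sd[int(row.i_lat), int(row.i_lon)] = float(row.sd)
        return grid


def build_grid(
    positions: list[GeoPosition],
    energies: list[float | None] | None = None,
    thermo: ThermoConstants = ThermoConstants(),
    B: int = 200,
    seed: int = 0,
) -> GridMap:
    """Bin bound-snapshot positions (and energies) into a :class:`GridMap`.

    ``positions`` must contain bound snapshots only; the cell counts then sum
    exactly to the number of snapshots ingested.  ``energies[i]`` may be None
    for snapshots that carry no score — they count toward occupancy but not
    toward the cell energy.
    """
    grid = GridMap(thermo=thermo)
    if energies is None:
        energies = [None] * len(positions)
    if len(energies) != len(positions):
        raise InputError("positions and energies differ in length")
    cell_e: dict[tuple[int, int], list[float]] = {}
    for g, e in zip(positions, energies):
        i_lon, i_lat = assign_cell(g)
        grid.counts[i_lat, i_lon] += 1
        if e is not None:
            cell_e.setdefault((i_lon, i_lat), []).append(float(e))
    rng = np.random.default_rng(seed)
    for (i_lon, i_lat) in sorted(cell_e):
        e = cell_e[(i_lon, i_lat)]
        grid.dG[i_lat, i_lon] = exp_average(e, thermo)
        sd = grid_sd(e, thermo, B=B, rng=rng)
        if sd is not None:
            grid.sd[i_lat, i_lon] = sd
    grid.cell_energies = {k: np.asarray(v) for k, v in cell_e.items()}
    grid.meta["n_snapshots"] = len(positions)
    return grid


class ThinPlateSpline:
    """2-D thin-plate spline fit z(lon, lat) on the unrolled map plane.

    Kernel r² log r plus an affine part; ``lam`` adds a penalty on the kernel
    coefficients (λ=0 interpolates the nodes exactly, affine trends are always
    reproduced exactly).  Thin wrapper over scipy's RBF interpolator, kept as
    a named type so landscape and probability surfaces share one engine.
    """

    def __init__(self, nodes: np.ndarray, values: np.ndarray, lam: float = 0.0):
        nodes = np.asarray(nodes, dtype=float)
        values = np.asarray(values, dtype=float)
        if nodes.ndim != 2 or nodes.shape[1] != 2 or len(nodes) < 3:
            raise FitError("need at least 3 (lon, lat) nodes")
        if lam < 0:
            raise FitError("smoothing parameter must be >= 0")
        span = nodes - nodes.mean(axis=0)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(nodes)), span])) < 3:
            raise FitError("nodes are collinear; thin-plate fit is degenerate")
        self.nodes = nodes
        self.values = values
        self.lam = float(lam)
        self._rbf = RBFInterpolator(
            nodes, values, kernel="thin_plate_spline", degree=1, smoothing=lam
        )

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return self._rbf(points)

    def evaluate_geo(self, positions: list[GeoPosition]) -> np.ndarray:
        pts = np.array([[g.lon, g.lat] for g in positions])
        return self(pts)

    def raster(
        self, n_lon: int = 240, n_lat: int = 120
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Dense (lon, lat, z) raster over the full map."""
        lons = np.linspace(-180.0, 180.0, n_lon)
        lats = np.linspace(-90.0, 90.0, n_lat)
        LO, LA = np.meshgrid(lons, lats)
        Z = self(np.column_stack([LO.ravel(), LA.ravel()])).reshape(LA.shape)
        return LO, LA, Z


def tps_smooth(
    grid: GridMap, lam: float = 0.0, quantity: str = "dG"
) -> ThinPlateSpline:
    """Fit the shared thin-plate engine to occupied cell centers.

    ``quantity`` is ``"dG"`` (landscape surface; cells with defined energy)
    or ``"count"`` (binding-probability surface; all occupied cells).
    Unvisited cells contribute no node — the surface extrapolates across them.
    """
    if quantity == "dG":
        mask = ~np.isnan(grid.dG)
        values_grid = grid.dG
    elif quantity == "count":
        mask = grid.occupied()
        values_grid = grid.counts.astype(float)
    else:
        raise InputError(f"unknown quantity {quantity!r}")
    idx = np.argwhere(mask)
    if len(idx) < 3:
        raise FitError("need at least 3 occupied cells to fit a surface")
    nodes = []
    values = []
    for i_lat, i_lon in idx:
        c = cell_center(int(i_lon), int(i_lat))
        nodes.append([c.lon, c.lat])
        values.append(values_grid[i_lat, i_lon])
    return ThinPlateSpline(np.array(nodes), np.array(values), lam=lam)
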