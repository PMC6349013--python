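"""Synthetic study system: fixture protein, surface potential, sphere walker.

Real inputs to this pipeline are undeposited MD trajectories, so validation
runs end-to-end against a synthetic system whose ground truth is known by
construction:

* a pseudo-atom "protein": quasi-uniform points on a sphere (Fibonacci
  lattice), with a ZN origin atom at the pocket site and two anchor CA atoms
  realizing a known reference frame;
* a prescribed surface potential, a sum of Gaussian wells in great-circle
  angular distance, U(g) = Σ_k depth_k · exp(−Δ_k² / (2 width_k²)) ≤ 0;
* multi-copy ligand trajectories alternating surface-bound Metropolis walks
  (stationary surface density ∝ exp(−U/RT)) with unbound 3D excursions placed
  beyond the bound-state cutoff, and additive Gaussian noise on the reported
  binding energies.

The Metropolis walk uses symmetric tangent-plane Gaussian proposals mapped
back to the sphere.  For multi-well potentials an additional symmetric
*well-swap* proposal (the rotation carrying one well center onto the next,
proposed forward/backward with equal probability and Metropolis-accepted) is
mixed in: it leaves the Boltzmann density invariant but raises the well-to-well
exchange rate from ~exp(−ΔG‡/RT) per *diffusive crossing* to
~Z_shallow/Z_deep per proposal, so occupancy ratios equilibrate within
practical run lengths.  Unbinding attempts are accepted with exp(U/RT) and
uniform rebinding proposals with 1 (U ≤ 0), the detailed-balance pairing for a
flat unbound reservoir, so excursions do not distort the surface density.

Every source of randomness flows from the single mandatory seed through
``numpy.random.SeedSequence`` children, spawned in a fixed order:
(0) fixture lattice, (1) walker, (2) energy noise, (3) atom template and
per-frame rotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .geometry import GeoPosition, ReferenceFrame, build_frame, geo_to_unit
from .landscape import N_LAT, N_LON, assign_cell
from .snapshots import SnapshotRecord

__all__ = [
    "SyntheticPotential",
    "SimulationSpec",
    "SimulationResult",
    "make_fixture_protein",
    "evaluate_potential",
    "simulate",
    "scripted_walk",
    "two_well_potential",
]


@dataclass(frozen=True)
class SyntheticPotential:
    """Sum-of-Gaussian-wells surface potential (kcal/mol, ≤ 0 everywhere)."""

    wells: tuple  # of (GeoPosition, depth<0, width_deg>0)

    def __post_init__(self):
        wells = tuple(self.wells)
        for center, depth, width in wells:
            if depth >= 0:
                raise InputError("well depth must be negative")
            if width <= 0:
                raise InputError("well width must be positive")
        object.__setattr__(self, "wells", wells)

    @property
    def centers_unit(self) -> np.ndarray:
        return np.array([geo_to_unit(c) for c, _, _ in self.wells]).reshape(-1, 3)

    def evaluate_unit(self, u: np.ndarray) -> np.ndarray:
        """Potential at unit vectors ``u`` of shape (..., 3); an empty well
        list is the flat (zero) landscape."""
        u = np.asarray(u, dtype=float)
        if not self.wells:
            return np.zeros(u.shape[:-1])
        dots = np.clip(u @ self.centers_unit.T, -1.0, 1.0)
        delta = np.degrees(np.arccos(dots))  # (..., m) angular distances
        depths = np.array([d for _, d, _ in self.wells])
        widths = np.array([w for _, _, w in self.wells])
        return (depths * np.exp(-(delta**2) / (2.0 * widths**2))).sum(axis=-1)


def evaluate_potential(p: SyntheticPotential, g: GeoPosition) -> float:
    """Closed-form potential value at one geographic position."""
    return float(p.evaluate_unit(geo_to_unit(g)))


def two_well_potential(
    depths=(-8.5, -5.0),
    widths=(8.0, 8.0),
    lat: float = 0.0,
    lons=(-40.0, 40.0),
) -> SyntheticPotential:
    """The standard two-well test landscape: a deep and a shallow Gaussian
    well at equal latitude, far enough apart that their tails stay above the
    well threshold between them."""
    wells = tuple(
        (GeoPosition(lat=lat, lon=lon), d, w)
        for lon, d, w in zip(lons, depths, widths)
    )
    return SyntheticPotential(wells=wells)


@dataclass
class SimulationSpec:
    """Conditions of one synthetic run.

    ``steps`` is per ligand copy; the default 4 copies mirror the four
    inhibitor molecules of the emulated study systems.  RT defaults to
    0.5925 kcal/mol (298.15 K).  ``swap_prob`` None means: 0.1 for multi-well
    potentials, 0 otherwise.
    """

    seed: int  # mandatory
    steps: int = 250_000
    n_copies: int = 4
    rt: float = 0.5925  # kcal/mol
    step_deg: float = 1.5  # tangent proposal scale, ~half a grid cell
    p_unbind: float = 0.0  # unbind attempt probability per bound step
    p_rebind: float = 0.05  # rebind attempt probability per unbound step
    sigma_e: float = 0.3  # kcal/mol, reported-energy noise
    swap_prob: float | None = None
    dt_ns: float = 0.1  # stored-frame spacing
    sphere_radius: float = 30.0  # Å, fixture sphere
    n_atoms: int = 800
    bound_offset: float = 1.5  # Å above the surface when bound
    unbound_offsets: tuple = (6.5, 20.0)  # Å above the surface when unbound
    ligand_atom_count: int = 33
    ligand_gyration: float = 1.2  # Å scale of the rigid atom template

    def __post_init__(self):
        if self.seed is None:
            raise InputError("seed is mandatory")
        for name in ("steps", "n_copies", "rt", "step_deg", "dt_ns",
                     "sphere_radius", "n_atoms"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


def _fibonacci_sphere(n: int, rng: np.random.Generator) -> np.ndarray:
    """Quasi-uniform unit points; a random longitude offset decorrelates the
    lattice from the grid without losing uniformity."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * i + rng.uniform(0, 2 * np.pi)
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


FIXTURE_CENTER = np.array([12.0, -7.5, 4.0])
_ANCHOR_ANGLE_DEG = 70.0  # X/Y anchors deliberately non-orthogonal


def make_fixture_protein(
    spec: SimulationSpec, pdb_path=None, sidecar_path=None
) -> tuple[str, ReferenceFrame, dict]:
    """Build the pseudo-atom fixture protein.

    Surface atoms are CA pseudo-atoms on a sphere of ``spec.sphere_radius``
    around an off-origin center; residues 1 and 2 are placed to realize a
    known frame (res 1 on the +X axis, res 2 at 70° in the XY plane, so
    Gram-Schmidt is genuinely exercised); a single ZN atom sits at the pocket
    origin.  Returns (pdb text, ground-truth frame, sidecar dict).
    """
    if spec.n_atoms < 4:
        raise InputError("fixture needs at least 4 atoms")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[0])
    R = spec.sphere_radius
    pts = _fibonacci_sphere(spec.n_atoms - 2, rng) * R
    a = np.radians(_ANCHOR_ANGLE_DEG)
    anchors = np.array([[R, 0.0, 0.0], [R * np.cos(a), R * np.sin(a), 0.0]])
    coords = np.vstack([anchors, pts]) + FIXTURE_CENTER
    lines = []
    serial = 1
    for i, c in enumerate(coords):
        lines.append(
            f"ATOM  {serial:>5d}  CA  GLY A{i + 1:>4d}    "
            f"{c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}  1.00  0.00           C  "
        )
        serial += 1
    zn = FIXTURE_CENTER
    lines.append(
        f"HETATM{serial:>5d} ZN    ZN A{len(coords) + 1:>4d}    "
        f"{zn[0]:8.3f}{zn[1]:8.3f}{zn[2]:8.3f}  1.00  0.00          ZN  "
    )
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    frame = build_frame(zn, coords[0], coords[1])
    sidecar = {
        "origin": frame.origin.tolist(),
        "ex": frame.ex.tolist(),
        "ey": frame.ey.tolist(),
        "ez": frame.ez.tolist(),
        "sphere_radius": R,
        "n_atoms": int(spec.n_atoms),
        "seed": int(spec.seed),
        "selectors": {
            "origin": "element=ZN",
            "x_anchor": "res=1,name=CA",
            "y_anchor": "res=2,name=CA",
        },
    }
    if pdb_path is not None:
        with open(pdb_path, "w") as fh:
            fh.write(pdb_text)
    if sidecar_path is not None:
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=2)
    return pdb_text, frame, sidecar


def _tangent_basis(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent pairs for unit vectors u of shape (n, 3)."""
    helper = np.zeros_like(u)
    use_z = np.abs(u[:, 2]) < 0.9
    helper[use_z, 2] = 1.0
    helper[~use_z, 0] = 1.0
    t1 = np.cross(u, helper)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(u, t1)
    return t1, t2


def _swap_rotations(potential: SyntheticPotential) -> list[np.ndarray]:
    """Rotations carrying well center k onto well center k+1."""
    cs = potential.centers_unit
    rots = []
    for k in range(len(cs) - 1):
        a, b = cs[k], cs[k + 1]
        v = np.cross(a, b)
        s = np.linalg.norm(v)
        c = float(np.dot(a, b))
        if s < 1e-12:
            rots.append(np.eye(3))
            continue
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rots.append(np.eye(3) + vx + vx @ vx * ((1 - c) / s**2))
    return rots


@dataclass
class SimulationResult:
    """Arrays of one synthetic run plus ground-truth bookkeeping.

    ``positions_unit[t, i]`` is the *true* surface direction of copy ``i`` at
    stored step ``t`` (frame coordinates, meaningful only when bound);
    ``truth`` holds the tallies recorded during generation.
    """

    spec: SimulationSpec
    potential: SyntheticPotential
    frame: ReferenceFrame
    positions_unit: np.ndarray  # (steps, n_copies, 3)
    bound: np.ndarray  # (steps, n_copies) bool
    com_world: np.ndarray  # (steps, n_copies, 3) Å
    energy: np.ndarray  # (steps, n_copies), NaN when unbound
    truth: dict = field(default_factory=dict)
    ligand_template: np.ndarray | None = None  # (k, 3)
    atom_rotations: np.ndarray | None = None  # (steps, n_copies, 3, 3)

    @property
    def n_bound(self) -> int:
        return int(self.bound.sum())

    def iter_records(self, with_atoms: bool = False):
        """Yield :class:`SnapshotRecord` per copy per stored step."""
        steps, n = self.bound.shape
        for i in range(n):
            lid = chr(ord("A") + i) if n <= 26 else f"L{i}"
            for t in range(steps):
                atoms = None
                if with_atoms and self.ligand_template is not None:
                    rot = self.atom_rotations[t, i]
                    atoms = self.com_world[t, i] + self.ligand_template @ rot.T
                e = self.energy[t, i]
                yield SnapshotRecord(
                    traj_id="synthetic:Traj. 1",
                    ligand_id=lid,
                    time=round((t + 1) * self.spec.dt_ns, 6),
                    com=self.com_world[t, i],
                    ligand_atoms=atoms,
                    energy=None if np.isnan(e) else float(e),
                    bound=bool(self.bound[t, i]),
                )

    def to_records(self, with_atoms: bool = False) -> list[SnapshotRecord]:
        return list(self.iter_records(with_atoms=with_atoms))

    def write_csv(self, path, atoms_path=None, truth_path=None) -> None:
        from .snapshots import write_snapshots

        write_snapshots(
            self.to_records(with_atoms=atoms_path is not None), path,
            atoms_path=atoms_path,
        )
        if truth_path is not None:
            with open(truth_path, "w") as fh:
                json.dump(self.truth, fh, indent=2)

    def bound_geo_energy(self):
        """(GeoPosition list, energy list) of bound frames, for build_grid."""
        from .geometry import _unit_to_geo

        positions, energies = [], []
        steps, n = self.bound.shape
        for i in range(n):
            for t in range(steps):
                if self.bound[t, i]:
                    positions.append(_unit_to_geo(self.positions_unit[t, i]))
                    e = self.energy[t, i]
                    energies.append(None if np.isnan(e) else float(e))
        return positions, energies


def simulate(
    potential: SyntheticPotential,
    spec: SimulationSpec,
    frame: ReferenceFrame | None = None,
    emit_atoms: bool = False,
    truth_cap_deg: float = 25.0,
) -> SimulationResult:
    """Run the multi-copy sphere walk and record ground truth.

    ``truth_cap_deg`` sets the angular radius of the per-well caps used for
    the occupancy tallies (both empirical counts and the quadrature of
    exp(−U/RT) over the same caps are stored in ``truth``).
    """
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng = np.random.default_rng(ss[1])
    noise_rng = np.random.default_rng(ss[2])
    atom_rng = np.random.default_rng(ss[3])

    if frame is None:
        frame = ReferenceFrame(
            origin=FIXTURE_CENTER,
            ex=np.array([1.0, 0.0, 0.0]),
            ey=np.array([0.0, 1.0, 0.0]),
            ez=np.array([0.0, 0.0, 1.0]),
        )

    n = spec.n_copies
    steps = spec.steps
    swap_prob = spec.swap_prob
    if swap_prob is None:
        swap_prob = 0.1 if len(potential.wells) > 1 else 0.0
    rots = _swap_rotations(potential) if swap_prob > 0 else []

    # initial state: bound, uniform on the sphere
    u = rng.normal(size=(n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    bound = np.ones(n, dtype=bool)
    U = potential.evaluate_unit(u)

    sigma = np.radians(spec.step_deg)
    rt = spec.rt
    pos_out = np.empty((steps, n, 3))
    bound_out = np.empty((steps, n), dtype=bool)
    com_out = np.empty((steps, n, 3))
    e_out = np.full((steps, n), np.nan)

    counts_true = np.zeros((N_LAT, N_LON), dtype=np.int64)
    centers = potential.centers_unit
    cap_cos = np.cos(np.radians(truth_cap_deg))
    well_counts = np.zeros(len(potential.wells), dtype=np.int64)

    r_bound = spec.sphere_radius + spec.bound_offset
    lo_off, hi_off = spec.unbound_offsets
    accepted = 0
    proposed = 0

    chunk = 8192
    t = 0
    while t < steps:
        m = min(chunk, steps - t)
        xi = rng.normal(scale=sigma, size=(m, n, 2))
        u_move = rng.random((m, n))
        u_acc = rng.random((m, n))
        u_unb = rng.random((m, n))
        u_dir = rng.random((m, n))
        u_excursion = rng.normal(size=(m, n, 3))
        r_excursion = rng.uniform(lo_off, hi_off, size=(m, n))
        for j in range(m):
            move = u_move[j]
            # --- bound copies ---
            if bound.any():
                b = bound
                tb1, tb2 = _tangent_basis(u[b])
                prop = u[b] + xi[j, b, 0, None] * tb1 + xi[j, b, 1, None] * tb2
                prop /= np.linalg.norm(prop, axis=1, keepdims=True)
                if rots and swap_prob > 0:
                    swap = move[b] < swap_prob
                    if swap.any():
                        k = (u_dir[j, b] * len(rots)).astype(int)
                        k = np.clip(k, 0, len(rots) - 1)
                        fwd = u_dir[j, b] * len(rots) - k < 0.5
                        sw_idx = np.where(swap)[0]
                        cur = u[b]
                        for s_i in sw_idx:
                            Rk = rots[k[s_i]]
                            prop[s_i] = (
                                Rk @ cur[s_i] if fwd[s_i] else Rk.T @ cur[s_i]
                            )
                U_prop = potential.evaluate_unit(prop)
                dU = U_prop - U[b]
                acc = u_acc[j, b] < np.exp(np.minimum(0.0, -dU / rt))
                proposed += int(b.sum())
                accepted += int(acc.sum())
                ub = u[b]
                ub[acc] = prop[acc]
                u[b] = ub
                Ub = U[b]
                Ub[acc] = U_prop[acc]
                U[b] = Ub
                # unbind attempts: acceptance exp(U/RT) pairs with uniform rebind
                if spec.p_unbind > 0:
                    attempt = u_move[j, b] > 1.0 - spec.p_unbind
                    a_out = u_unb[j, b] < np.exp(U[b] / rt)
                    leave = attempt & a_out
                    if leave.any():
                        idx = np.where(b)[0][leave]
                        bound[idx] = False
            # --- unbound copies ---
            ub_mask = ~bound
            if ub_mask.any() and spec.p_rebind > 0:
                attempt = move[ub_mask] < spec.p_rebind
                if attempt.any():
                    idx = np.where(ub_mask)[0][attempt]
                    newu = u_excursion[j, idx]
                    newu /= np.linalg.norm(newu, axis=1, keepdims=True)
                    u[idx] = newu
                    U[idx] = potential.evaluate_unit(newu)
                    bound[idx] = True
            # --- record ---
            pos_out[t] = u
            bound_out[t] = bound
            com_surface = frame.to_world(u * r_bound)
            exc = u_excursion[j] / np.linalg.norm(
                u_excursion[j], axis=1, keepdims=True
            )
            com_free = frame.to_world(
                exc * (spec.sphere_radius + r_excursion[j])[:, None]
            )
            com_out[t] = np.where(bound[:, None], com_surface, com_free)
            e_out[t, bound] = U[bound] + noise_rng.normal(
                scale=spec.sigma_e, size=int(bound.sum())
            )
            # ground truth tallies (true positions, noiseless)
            if bound.any():
                ub_u = u[bound]
                lats = np.degrees(np.arcsin(np.clip(ub_u[:, 2], -1, 1)))
                lons = np.degrees(np.arctan2(ub_u[:, 1], ub_u[:, 0]))
                i_lat = np.clip(
                    ((lats + 90.0) / 3.0).astype(int), 0, N_LAT - 1
                )
                i_lon = np.clip(
                    (((lons + 180.0) % 360.0) / 3.0).astype(int), 0, N_LON - 1
                )
                np.add.at(counts_true, (i_lat, i_lon), 1)
                in_cap = ub_u @ centers.T > cap_cos
                well_counts += in_cap.sum(axis=0)
            t += 1

    # quadrature of the stationary density over the same caps
    quad = _cap_quadrature(potential, rt, truth_cap_deg)
    template = None
    atom_rots = None
    if emit_atoms:
        template = atom_rng.normal(
            scale=spec.ligand_gyration, size=(spec.ligand_atom_count, 3)
        )
        template -= template.mean(axis=0)
        from scipy.spatial.transform import Rotation

        atom_rots = Rotation.random(
            steps * n, rng=atom_rng
        ).as_matrix().reshape(steps, n, 3, 3)

    result = SimulationResult(
        spec=spec,
        potential=potential,
        frame=frame,
        positions_unit=pos_out,
        bound=bound_out,
        com_world=com_out,
        energy=e_out,
        ligand_template=template,
        atom_rotations=atom_rots,
    )
    result.truth = {
        "counts_true": counts_true.tolist(),
        "well_cap_counts": well_counts.tolist(),
        "well_cap_boltzmann_weights": quad.tolist(),
        "truth_cap_deg": truth_cap_deg,
        "n_bound": int(bound_out.sum()),
        "n_total": int(bound_out.size),
        "acceptance_rate": accepted / max(proposed, 1),
        "wells": [
            {"lat": c.lat, "lon": c.lon, "depth": d, "width_deg": w}
            for c, d, w in potential.wells
        ],
        "rt": rt,
        "seed": int(spec.seed),
    }
    return result


def _cap_quadrature(
    potential: SyntheticPotential, rt: float, cap_deg: float, n_grid: int = 400
) -> np.ndarray:
    """∫ exp(−U/RT) dA over each well cap, by dense lat-lon quadrature."""
    lats = np.linspace(-90, 90, n_grid)
    lons = np.linspace(-180, 180, 2 * n_grid, endpoint=False)
    LA, LO = np.meshgrid(lats, lons, indexing="ij")
    la, lo = np.radians(LA), np.radians(LO)
    u = np.stack(
        [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1
    )
    Uv = potential.evaluate_unit(u.reshape(-1, 3)).reshape(LA.shape)
    w = np.exp(-Uv / rt) * np.cos(la)  # area element
    cap_cos = np.cos(np.radians(cap_deg))
    out = []
    for c in potential.centers_unit:
        mask = (u @ c) > cap_cos
        out.append(float(w[mask].sum()))
    return np.array(out)


def scripted_walk(
    potential: SyntheticPotential,
    waypoints: list[GeoPosition],
    dwell_frames: int = 30,
    transit_frames: int = 15,
    jitter_deg: float = 0.4,
    seed: int = 0,
    frame: ReferenceFrame | None = None,
    spec: SimulationSpec | None = None,
) -> list[SnapshotRecord]:
    """A deterministic-by-seed trajectory that dwells at each waypoint in turn.

    Used to test pathway extraction: the ligand jitters inside each waypoint's
    cell for ``dwell_frames``, then moves along the great circle to the next
    waypoint.  All frames are bound; emitted energies are the noiseless
    potential.
    """
    from .geometry import slerp as _slerp

    spec = spec or SimulationSpec(seed=seed, steps=1)
    if frame is None:
        frame = ReferenceFrame(
            origin=FIXTURE_CENTER,
            ex=np.array([1.0, 0.0, 0.0]),
            ey=np.array([0.0, 1.0, 0.0]),
            ez=np.array([0.0, 0.0, 1.0]),
        )
    rng = np.random.default_rng(seed)
    geos: list[GeoPosition] = []
    for i, wp in enumerate(waypoints):
        for _ in range(dwell_frames):
            dlat = rng.uniform(-jitter_deg, jitter_deg)
            dlon = rng.uniform(-jitter_deg, jitter_deg)
            geos.append(GeoPosition(lat=wp.lat + dlat, lon=wp.lon + dlon))
        if i + 1 < len(waypoints):
            geos.extend(_slerp(wp, waypoints[i + 1], transit_frames + 2)[1:-1])
    r_bound = spec.sphere_radius + spec.bound_offset
    records = []
    for t, g in enumerate(geos):
        com = frame.to_world(geo_to_unit(g) * r_bound)
        records.append(
            SnapshotRecord(
                traj_id="scripted:Traj. 1",
                ligand_id="A",
                time=round((t + 1) * spec.dt_ns, 6),
                com=com,
                energy=evaluate_potential(potential, g),
                bound=True,
            )
        )
    return records
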