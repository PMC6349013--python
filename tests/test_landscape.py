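"""Grid binning, Boltzmann averaging, Kd calibration, thin-plate smoothing."""

from decimal import Decimal, getcontext

import numpy as np
import pytest

from bindscape.errors import FitError, InputError
from bindscape.geometry import GeoPosition, geo_to_unit
from bindscape.landscape import (
    CELL_DEG,
    N_LAT,
    N_LON,
    GridMap,
    ThermoConstants,
    ThinPlateSpline,
    assign_cell,
    build_grid,
    cell_center,
    dG_to_kd,
    exp_average,
    grid_sd,
    kd_to_dG,
    tps_smooth,
)


class TestAssignCell:
    def test_domain_covers_exactly_7200_cells(self):
        assert N_LON * N_LAT == 7200
        cells = set()
        for lon in np.arange(-180, 180, CELL_DEG) + 1.5:
            for lat in np.arange(-90, 90, CELL_DEG) + 1.5:
                cells.add(assign_cell(GeoPosition(lat=lat, lon=lon)))
        assert len(cells) == 7200

    @pytest.mark.parametrize(
        "lat,lon,expected",
        [
            (-90, -180, (0, 0)),
            (0, 0, (60, 30)),
            (90, 0, (60, 59)),  # north pole folds into the top row
            (89.999, 179.999, (119, 59)),
            (-0.001, -0.001, (59, 29)),
        ],
    )
    def test_corner_conventions(self, lat, lon, expected):
        assert assign_cell(GeoPosition(lat=lat, lon=lon)) == expected

    def test_cell_center_round_trip(self, rng):
        for _ in range(100):
            i_lon = int(rng.integers(0, N_LON))
            i_lat = int(rng.integers(0, N_LAT))
            assert assign_cell(cell_center(i_lon, i_lat)) == (i_lon, i_lat)


def decimal_exp_average(energies, rt, prec=50):
    """Arbitrary-precision direct evaluation of −RT ln⟨e^(−E/RT)⟩."""
    getcontext().prec = prec
    rt_d = Decimal(repr(rt))
    total = sum((-Decimal(repr(float(e))) / rt_d).exp() for e in energies)
    mean = total / Decimal(len(energies))
    return float(-rt_d * mean.ln())


class TestExpAverage:
    RT = 0.5925

    def test_constant_energies(self):
        assert exp_average([-6.0] * 7) == pytest.approx(-6.0, abs=1e-12)

    def test_matches_decimal_oracle_and_brackets(self, rng):
        thermo = ThermoConstants()
        for _ in range(50):
            e = rng.uniform(-12, 2, size=int(rng.integers(2, 30)))
            got = exp_average(e, thermo)
            oracle = decimal_exp_average(e, thermo.RT)
            assert got == pytest.approx(oracle, abs=1e-10)
            if np.ptp(e) > 0:
                assert e.min() < got < e.mean()

    def test_two_point_case_between_min_and_mean(self):
        thermo = ThermoConstants(T=self.RT / ThermoConstants().R)
        got = exp_average([-8.0, -4.0], thermo)
        oracle = decimal_exp_average([-8.0, -4.0], thermo.RT)
        assert got == pytest.approx(oracle, abs=1e-10)
        assert -8.0 < got < -6.0

    def test_dominance_limit(self):
        thermo = ThermoConstants(T=self.RT / ThermoConstants().R)
        got = exp_average([0.0, -50.0], thermo)
        assert got == pytest.approx(-50.0 + thermo.RT * np.log(2), abs=1e-6)

    def test_monotone_in_each_energy(self, rng):
        e = rng.uniform(-10, 0, size=10)
        base = exp_average(e)
        e2 = e.copy()
        e2[3] -= 1.0
        assert exp_average(e2) < base

    def test_permutation_invariance(self, rng):
        e = rng.uniform(-10, 0, size=20)
        assert exp_average(e) == pytest.approx(
            exp_average(e[rng.permutation(20)]), abs=1e-12
        )

    def test_empty_raises(self):
        with pytest.raises(InputError):
            exp_average([])


class TestKdCalibration:
    def test_paper_thresholds_at_room_temperature(self):
        thermo = ThermoConstants(T=298.15)
        assert round(kd_to_dG(1000e-6, thermo), 1) == -4.1
        assert round(kd_to_dG(1000e-9, thermo), 1) == -8.2

    def test_reference_state_is_zero(self):
        assert kd_to_dG(1.0) == 0.0

    def test_round_trip_identity(self, rng):
        thermo = ThermoConstants()
        for kd in 10.0 ** rng.uniform(-12, 2, 50):
            assert dG_to_kd(kd_to_dG(kd, thermo), thermo) == pytest.approx(
                kd, rel=1e-12
            )

    def test_nonpositive_kd_raises(self):
        with pytest.raises(InputError):
            kd_to_dG(0.0)


class TestGridSd:
    def test_identical_energies_give_zero(self):
        assert grid_sd([-5.0] * 10, B=100, seed=1) == 0.0

    def test_deterministic_given_seed(self, rng):
        e = rng.uniform(-8, -2, 30)
        assert grid_sd(e, B=200, seed=5) == grid_sd(e, B=200, seed=5)

    def test_single_energy_has_no_sd(self):
        assert grid_sd([-5.0]) is None

    def test_tracks_standard_error_scale(self, rng):
        # exp-average of near-Gaussian energies: SD should be within a factor
        # 2 of sigma/sqrt(n) (Monte-Carlo reference scale)
        sigma, n = 0.5, 100
        e = -6.0 + rng.normal(0, sigma, n)
        sd = grid_sd(e, B=400, seed=2)
        se = sigma / np.sqrt(n)
        assert se / 2 < sd < se * 2


class TestBuildGrid:
    def test_count_conservation_and_empty_cells(self, random_geo, rng):
        positions = random_geo(500)
        energies = list(rng.uniform(-9, 0, 500))
        grid = build_grid(positions, energies, B=10, seed=0)
        assert grid.total_count == 500
        empty = grid.counts == 0
        assert np.all(np.isnan(grid.dG[empty]))
        assert np.all(np.isnan(grid.sd[empty]))

    def test_energyless_snapshots_count_but_carry_no_dG(self):
        g = GeoPosition(10, 10)
        grid = build_grid([g, g], [None, None])
        i_lon, i_lat = assign_cell(g)
        assert grid.counts[i_lat, i_lon] == 2
        assert np.isnan(grid.dG[i_lat, i_lon])

    def test_csv_round_trip(self, tmp_path, random_geo, rng):
        grid = build_grid(random_geo(300), list(rng.uniform(-9, 0, 300)),
                          B=10, seed=0)
        p = tmp_path / "grid.csv"
        grid.write(p, meta_path=tmp_path / "meta.json")
        back = GridMap.read(p)
        np.testing.assert_array_equal(back.counts, grid.counts)
        mask = ~np.isnan(grid.dG)
        np.testing.assert_allclose(back.dG[mask], grid.dG[mask], atol=5e-5)

    def test_noiseless_simulator_energies_recover_the_potential(
        self, two_well
    ):
        """Occupied-cell dG matches the prescribed potential at cell centers
        to 0.3 kcal/mol RMS when reported energies carry no noise."""
        from bindscape.synth import SimulationSpec, simulate

        spec = SimulationSpec(seed=11, steps=15_000, n_copies=4, sigma_e=1e-12)
        res = simulate(two_well, spec)
        pos, en = res.bound_geo_energy()
        grid = build_grid(pos, en, B=2, seed=1)
        errs = []
        for (i_lon, i_lat) in grid.cell_energies:
            truth = float(
                two_well.evaluate_unit(geo_to_unit(cell_center(i_lon, i_lat)))
            )
            errs.append(grid.dG[i_lat, i_lon] - truth)
        rms = float(np.sqrt(np.mean(np.square(errs))))
        assert rms < 0.3


def tps_augmented_oracle(nodes, values, lam, query):
    """Dense augmented-system thin-plate solve, independent of the fit route."""
    n = len(nodes)
    d = np.linalg.norm(nodes[:, None] - nodes[None], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(d > 0, d**2 * np.log(d), 0.0)
    P = np.column_stack([np.ones(n), nodes])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    sol = np.linalg.solve(A, np.concatenate([values, np.zeros(3)]))
    c, beta = sol[:n], sol[n:]
    dq = np.linalg.norm(query[:, None] - nodes[None], axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Kq = np.where(dq > 0, dq**2 * np.log(dq), 0.0)
    return Kq @ c + np.column_stack([np.ones(len(query)), query]) @ beta


class TestThinPlateSpline:
    def _nodes(self, rng, n=10):
        return rng.uniform([-180, -90], [180, 90], size=(n, 2))

    def test_lambda_zero_interpolates(self, rng):
        nodes = self._nodes(rng)
        values = rng.normal(size=10)
        tps = ThinPlateSpline(nodes, values, lam=0.0)
        np.testing.assert_allclose(tps(nodes), values, atol=1e-6)

    @pytest.mark.parametrize("lam", [0.0, 0.1, 10.0])
    def test_affine_functions_reproduced_exactly(self, rng, lam):
        nodes = self._nodes(rng, 15)
        a, b, c = 2.0, 0.03, -0.05
        values = a + b * nodes[:, 0] + c * nodes[:, 1]
        tps = ThinPlateSpline(nodes, values, lam=lam)
        q = self._nodes(rng, 30)
        np.testing.assert_allclose(tps(q), a + b * q[:, 0] + c * q[:, 1],
                                   atol=1e-6)

    def test_smoothing_matches_augmented_system_oracle(self, rng):
        nodes = self._nodes(rng, 25)
        values = rng.normal(size=25) * 3
        q = self._nodes(rng, 40)
        tps = ThinPlateSpline(nodes, values, lam=0.1)
        np.testing.assert_allclose(
            tps(q), tps_augmented_oracle(nodes, values, 0.1, q), atol=1e-8
        )

    def test_degenerate_nodes_raise(self):
        nodes = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(FitError, match="collinear"):
            ThinPlateSpline(nodes, np.zeros(3), lam=0.0)

    def test_tps_smooth_fits_occupied_cells_only(self, random_geo, rng):
        positions = random_geo(200)
        grid = build_grid(positions, list(rng.uniform(-9, -1, 200)),
                          B=2, seed=0)
        tps = tps_smooth(grid, lam=0.0)
        occ = int((~np.isnan(grid.dG)).sum())
        assert len(tps.nodes) == occ
        np.testing.assert_allclose(tps(tps.nodes), tps.values, atol=1e-5)
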