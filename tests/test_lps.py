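import numpy as np
import pandas as pd
import pytest

from nichedrift.gridio import GridSpec, VelocityFieldSeries
from nichedrift.lps import (
    ConnectivityMatrix,
    LPSConfig,
    Trajectory,
    advect_particle,
    average_annual,
    build_release_schedule,
    compare_pld,
    connectivity_from_trajectories,
    connectivity_matrix,
    detect_barriers,
    interp_velocity,
    run_lps,
    stepping_stone_reach,
)
from nichedrift.synthdata import (
    METERS_PER_DEGREE,
    gen_analytic_flow,
    gen_coastline,
    gen_velocity_jet,
)

JAN_CFG = LPSConfig(pld_days=30, years=(2008,), spawning_months=(1,))


def _uniform_series(grid, u=0.0, v=0.0, days=40, start="2008-01-01"):
    dates = pd.date_range(start, periods=days, freq="D")
    return gen_analytic_flow("uniform", {"u": u, "v": v}, grid, dates)


class TestConfig:
    def test_step_divisibility(self):
        with pytest.raises(ValueError):
            LPSConfig(pld_days=30, step_hours=7)

    def test_month_validation(self):
        with pytest.raises(ValueError):
            LPSConfig(spawning_months=(0, 5))


class TestReleaseSchedule:
    def test_paper_season_release_count(self, lps_grid):
        coastal, _ = gen_coastline(2, "meridional", lps_grid)
        cfg = LPSConfig(years=(2009,))  # non-leap year, default spawning months
        sched = build_release_schedule(cfg, coastal)
        # May-Jul (92) + Oct-Dec (92) + Jan (31) = 215 days per cell
        assert len(sched) == 215 * 2
        assert sorted(sched["date"].dt.month.unique()) == [1, 5, 6, 7, 10, 11, 12]

    def test_empty_months(self, lps_grid):
        coastal, _ = gen_coastline(2, "meridional", lps_grid)
        sched = build_release_schedule(LPSConfig(spawning_months=(), years=(2008,)), coastal)
        assert len(sched) == 0

    def test_two_cells_one_day(self, lps_grid):
        coastal, _ = gen_coastline(2, "meridional", lps_grid)
        cfg = LPSConfig(years=(2008,), spawning_months=(5,))
        sched = build_release_schedule(cfg, coastal)
        one_day = sched[sched["date"] == "2008-05-01"]
        assert len(one_day) == 2


class TestInterpolation:
    def test_cell_center_exact(self, small_grid):
        rng = np.random.default_rng(0)
        u = rng.normal(size=(3,) + small_grid.shape)
        s = VelocityFieldSeries(small_grid, pd.date_range("2008-01-01", periods=3),
                                u, u.copy())
        lon, lat = small_grid.cell_center(5, 7)
        uu, vv = interp_velocity(s, [lon], [lat], "2008-01-02")
        assert uu[0] == pytest.approx(u[1, 7, 5])

    def test_midpoint_of_four_centers(self, small_grid):
        u = np.zeros((1,) + small_grid.shape)
        u[0, 3:5, 3:5] = [[1.0, 2.0], [3.0, 4.0]]
        s = VelocityFieldSeries(small_grid, pd.date_range("2008-01-01", periods=1),
                                u, u.copy())
        lon = small_grid.lon_min + 4 * small_grid.cell_size
        lat = small_grid.lat_min + 4 * small_grid.cell_size
        uu, _ = interp_velocity(s, [lon], [lat], "2008-01-01")
        assert uu[0] == pytest.approx(2.5)

    def test_exact_on_linear_field(self, small_grid):
        lonc, latc = np.meshgrid(small_grid.lon_centers(), small_grid.lat_centers())
        field = 2.0 * lonc + 3.0 * latc
        s = VelocityFieldSeries(small_grid, pd.date_range("2008-01-01", periods=1),
                                field[None], field[None].copy())
        rng = np.random.default_rng(1)
        # interior points (at least half a cell from the boundary centers)
        lon = rng.uniform(small_grid.lon_min + 0.1, small_grid.lon_max - 0.1, 20)
        lat = rng.uniform(small_grid.lat_min + 0.1, small_grid.lat_max - 0.1, 20)
        uu, _ = interp_velocity(s, lon, lat, "2008-01-01")
        np.testing.assert_allclose(uu, 2.0 * lon + 3.0 * lat, rtol=1e-12)

    def test_land_neighbours_renormalised(self, small_grid):
        u = np.ones((1,) + small_grid.shape)
        u[0, 7, 5] = np.nan  # land neighbour
        s = VelocityFieldSeries(small_grid, pd.date_range("2008-01-01", periods=1),
                                u, u.copy())
        lon = small_grid.lon_min + 5 * small_grid.cell_size
        lat = small_grid.lat_min + 7 * small_grid.cell_size
        uu, _ = interp_velocity(s, [lon], [lat], "2008-01-01")
        assert uu[0] == pytest.approx(1.0)  # remaining neighbours all 1


class TestAdvection:
    def test_stationary_in_still_water(self, small_grid):
        s = _uniform_series(small_grid)
        tr = advect_particle(s, 1.0, 0.0, "2008-01-01", JAN_CFG)
        assert len(tr.positions) == 30 * 12 + 1
        assert np.allclose(tr.positions, tr.positions[0])
        assert not tr.exited

    def test_uniform_flow_analytic_displacement(self):
        grid = GridSpec(0.0, -1.0, 0.1, 80, 20)
        s = _uniform_series(grid, u=0.1)
        cfg = LPSConfig(pld_days=1, years=(2008,), spawning_months=(1,))
        tr = advect_particle(s, 0.3, 0.0, "2008-01-01", cfg)
        expected_deg = 0.1 * 86400 / (METERS_PER_DEGREE * np.cos(0.0))
        got = tr.positions[-1, 0] - 0.3
        assert got == pytest.approx(expected_deg, rel=1e-6)

    def test_release_on_land_errors(self, lps_grid, coast):
        coastal, land = coast
        dates = pd.date_range("2008-01-01", periods=5)
        s = gen_velocity_jet(lps_grid, dates, 0.1, "north", land=land)
        land_iy, land_ix = 5, lps_grid.n_lon - 1
        lon, lat = lps_grid.cell_center(land_ix, land_iy)
        with pytest.raises(ValueError, match="land"):
            advect_particle(s, lon, lat, "2008-01-01", JAN_CFG)

    def test_domain_exit_truncates(self):
        grid = GridSpec(0.0, 0.0, 0.1, 4, 4)  # tiny domain
        s = _uniform_series(grid, u=1.0)
        cfg = LPSConfig(pld_days=1, years=(2008,), spawning_months=(1,))
        tr = advect_particle(s, 0.05, 0.2, "2008-01-01", cfg)
        assert tr.exited
        assert len(tr.positions) < cfg.n_steps + 1

    def test_land_step_holds_position(self):
        grid = GridSpec(0.0, 0.0, 0.1, 6, 6)
        dates = pd.date_range("2008-01-01", periods=3)
        u = np.full((3, 6, 6), 0.5)
        u[:, :, 4:] = np.nan  # eastern land strip
        s = VelocityFieldSeries(grid, dates, u, np.where(np.isnan(u), np.nan, 0.0))
        cfg = LPSConfig(pld_days=1, years=(2008,), spawning_months=(1,))
        tr = advect_particle(s, 0.35, 0.25, "2008-01-01", cfg)
        # particle pushes east, parks at the last water cell, never enters land
        assert not tr.exited
        ix, _ = grid.cell_index(tr.positions[:, 0], tr.positions[:, 1])
        assert ix.max() <= 3

    def test_solid_rotation_euler_convergence(self):
        """Return-to-start error after one rotation shrinks ~linearly with
        the step (forward Euler is first order)."""
        grid = GridSpec(0.0, -2.0, 0.1, 40, 40)
        period_days = 10.0
        omega = 2 * np.pi / (period_days * 86400)
        center = (2.0, 0.0)
        dates = pd.date_range("2008-01-01", periods=15)
        s = gen_analytic_flow("solid_rotation", {"omega": omega, "center": center},
                              grid, dates)
        start = (2.5, 0.0)
        radius_m = 0.5 * METERS_PER_DEGREE
        errors = {}
        for step_hours in (4, 2, 1):
            cfg = LPSConfig(pld_days=int(period_days), step_hours=step_hours,
                            years=(2008,), spawning_months=(1,))
            tr = advect_particle(s, *start, "2008-01-01", cfg)
            end = tr.positions[-1]
            err = np.hypot((end[0] - start[0]) * METERS_PER_DEGREE,
                           (end[1] - start[1]) * METERS_PER_DEGREE)
            errors[step_hours] = err
        assert errors[2] < errors[4]
        assert errors[1] < errors[2]
        # first-order: halving the step roughly halves the error
        assert errors[4] / errors[2] == pytest.approx(2.0, rel=0.5)
        # forward Euler on a circle drifts outward by the analytic factor
        # (1 + (w*dt)^2)^(N/2) - 1, i.e. ~17.9% of the radius at 2-hour
        # steps over a 10-day rotation; check we sit at that bound
        w_dt = omega * 2 * 3600
        predicted = ((1 + w_dt**2) ** (120 / 2) - 1) * radius_m
        assert errors[2] == pytest.approx(predicted, rel=0.15)

    def test_rk4_beats_euler(self):
        grid = GridSpec(0.0, -2.0, 0.1, 40, 40)
        omega = 2 * np.pi / (10 * 86400)
        dates = pd.date_range("2008-01-01", periods=12)
        s = gen_analytic_flow("solid_rotation", {"omega": omega, "center": (2.0, 0.0)},
                              grid, dates)
        res = {}
        for integ in ("euler", "rk4"):
            cfg = LPSConfig(pld_days=10, years=(2008,), spawning_months=(1,),
                            integrator=integ)
            tr = advect_particle(s, 2.5, 0.0, "2008-01-01", cfg)
            res[integ] = np.hypot(tr.positions[-1, 0] - 2.5, tr.positions[-1, 1])
        assert res["rk4"] < res["euler"] / 10


class TestRunLps:
    def test_trajectory_counts(self, lps_grid, coast, jet_series):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=30, years=(2008,), spawning_months=(1,))
        runs, trajectories = run_lps(cfg, jet_series, coastal, keep_trajectories=True)
        assert len(runs) == 1
        assert len(trajectories) == 31 * len(coastal)
        assert runs[0].n_released.sum() == 31 * len(coastal)

    def test_deterministic(self, coast, jet_series):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=5, years=(2008,), spawning_months=(1,))
        a = run_lps(cfg, jet_series, coastal)
        b = run_lps(cfg, jet_series, coastal)
        np.testing.assert_array_equal(a[0].step_counts, b[0].step_counts)


class TestConnectivity:
    def _single_traj_matrix(self, coastal, positions, cfg, cell_id=0):
        tr = Trajectory(cell_id=cell_id, release_date=pd.Timestamp("2008-01-01"),
                        positions=np.asarray(positions))
        return connectivity_from_trajectories([tr], coastal, cfg)

    def test_stationary_particle_full_retention(self, lps_grid, coast):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=1, years=(2008,), spawning_months=(1,))
        lon, lat = coastal.centers()[0]
        positions = np.tile([lon, lat], (cfg.n_steps + 1, 1))
        c = self._single_traj_matrix(coastal, positions, cfg)
        assert c.values[0, 0] == pytest.approx(1.0)
        assert c.values[0, 1:].sum() == 0.0

    def test_half_and_half_occupancy(self, lps_grid, coast):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=1, years=(2008,), spawning_months=(1,))
        a = coastal.centers()[0]
        b = coastal.centers()[5]
        half = cfg.n_steps // 2
        positions = np.vstack([np.tile(a, (1 + half, 1)), np.tile(b, (half, 1))])
        c = self._single_traj_matrix(coastal, positions, cfg)
        assert c.values[0, 0] == pytest.approx(0.5)
        assert c.values[0, 5] == pytest.approx(0.5)

    def test_offshore_particle_row_sum_small(self, lps_grid, coast):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=1, years=(2008,), spawning_months=(1,))
        lon, lat = coastal.centers()[0]
        off = np.array([lps_grid.lon_min + 0.01, lat])  # off the coastal strip
        positions = np.vstack([[lon, lat], np.tile(off, (cfg.n_steps, 1))])
        c = self._single_traj_matrix(coastal, positions, cfg)
        assert c.values.sum() == 0.0  # all steps off-strip still count in denominator

    def test_unknown_cell_errors(self, lps_grid, coast):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=1, years=(2008,), spawning_months=(1,))
        tr = Trajectory(cell_id=999, release_date=pd.Timestamp("2008-01-01"),
                        positions=np.zeros((2, 2)))
        with pytest.raises(ValueError, match="unknown"):
            connectivity_from_trajectories([tr], coastal, cfg)

    def test_row_sums_bounded(self, coast, jet_series):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=10, years=(2008,), spawning_months=(1,))
        runs = run_lps(cfg, jet_series, coastal)
        c = connectivity_matrix(runs[0], coastal, cfg)
        assert (c.values.sum(axis=1) <= 1 + 1e-9).all()

    def test_downstream_triangular_under_unidirectional_flow(self, coast, jet_series):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=10, years=(2008,), spawning_months=(1,))
        runs = run_lps(cfg, jet_series, coastal)
        c = connectivity_matrix(runs[0], coastal, cfg)
        upstream = np.tril(c.values, k=-1)
        assert upstream.sum() == 0.0


class TestAveraging:
    def _mat(self, values, pld=30, years=(2008,)):
        n = values.shape[0]
        return ConnectivityMatrix(cell_ids=np.arange(n), values=values,
                                  pld_days=pld, years=years)

    def test_identical_matrices_unchanged(self):
        v = np.diag([0.5, 0.4, 0.3])
        out = average_annual([self._mat(v, years=(2008,)), self._mat(v, years=(2009,))])
        np.testing.assert_array_equal(out.values, v)
        assert out.years == (2008, 2009)

    def test_elementwise_mean(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        b[1, 2] = 0.4
        out = average_annual([self._mat(a), self._mat(b)])
        assert out.values[1, 2] == pytest.approx(0.2)

    def test_preserves_row_sum_bound(self):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(3):
            v = rng.random((4, 4))
            v = v / v.sum(axis=1, keepdims=True)  # row sums exactly 1
            mats.append(self._mat(v))
        out = average_annual(mats)
        assert (out.values.sum(axis=1) <= 1 + 1e-9).all()

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            average_annual([self._mat(np.zeros((3, 3))), self._mat(np.zeros((4, 4)))])


class TestComparePld:
    def test_identical_matrices_r_one(self):
        rng = np.random.default_rng(0)
        v = rng.random((6, 6)) / 6
        a = ConnectivityMatrix(np.arange(6), v, 30)
        b = ConnectivityMatrix(np.arange(6), v.copy(), 90)
        res = compare_pld(a, b, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)

    def test_independent_matrices_usually_ns(self):
        rng = np.random.default_rng(1)
        ps = []
        for k in range(10):
            a = ConnectivityMatrix(np.arange(10), rng.random((10, 10)) / 10, 30)
            b = ConnectivityMatrix(np.arange(10), rng.random((10, 10)) / 10, 90)
            ps.append(compare_pld(a, b, n_perm=199, seed=k).p_value)
        assert np.median(ps) > 0.05

    def test_mismatched_cells_error(self):
        a = ConnectivityMatrix(np.arange(3), np.zeros((3, 3)) + 0.1, 30)
        b = ConnectivityMatrix(np.arange(1, 4), np.zeros((3, 3)) + 0.1, 90)
        with pytest.raises(ValueError):
            compare_pld(a, b)


class TestGraphAnalyses:
    def _mat(self, values):
        return ConnectivityMatrix(cell_ids=np.arange(values.shape[0]),
                                  values=values, pld_days=30)

    def test_no_edges_above_threshold(self):
        c = self._mat(np.eye(5) * 0.9)
        assert stepping_stone_reach(c, [2], 0.05, "both") == {2}

    def test_chain_reachability(self):
        v = np.zeros((6, 6))
        for i in range(5):
            v[i, i + 1] = 0.1
        c = self._mat(v)
        assert stepping_stone_reach(c, [0], 0.05, "up") == set(range(6))
        assert stepping_stone_reach(c, [3], 0.05, "up") == {3, 4, 5}

    def test_threshold_above_one_unreachable(self):
        v = np.full((4, 4), 0.2)
        np.fill_diagonal(v, 0.0)
        c = self._mat(v / 4)
        assert stepping_stone_reach(c, [0], 1.1, "both") == {0}

    def test_strict_inequality_at_threshold(self):
        v = np.zeros((3, 3))
        v[0, 1] = 0.05  # exactly at the threshold: not an edge
        c = self._mat(v)
        assert stepping_stone_reach(c, [0], 0.05, "up") == {0}

    def test_unknown_source(self):
        with pytest.raises(ValueError):
            stepping_stone_reach(self._mat(np.zeros((3, 3))), [7])

    def test_identity_matrix_all_cuts(self):
        c = self._mat(np.eye(5))
        assert detect_barriers(c, None, 0.05, "up") == [0, 1, 2, 3]
        assert detect_barriers(c, None, 0.05, "down") == [0, 1, 2, 3]

    def test_uniform_downstream_flow_one_way_open(self, coast, jet_series):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=10, years=(2008,), spawning_months=(1,))
        runs = run_lps(cfg, jet_series, coastal)
        c = connectivity_matrix(runs[0], coastal, cfg)
        up = detect_barriers(c, coastal, 0.05, "up")
        down = detect_barriers(c, coastal, 0.05, "down")
        assert len(down) == len(coastal) - 1  # against the jet: fully cut
        assert len(up) < len(coastal) - 1     # with the jet: mostly open

    def test_barrier_near_imposed_front(self, coast, jet_series):
        coastal, _ = coast
        cfg = LPSConfig(pld_days=30, years=(2008,), spawning_months=(1,))
        runs = run_lps(cfg, jet_series, coastal)
        c = connectivity_matrix(runs[0], coastal, cfg)
        cuts = detect_barriers(c, coastal, 0.05, "up")
        assert cuts, "expected at least one barrier"
        assert abs(min(cuts) - 45) <= 2  # the imposed front sits above cell 45
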