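"""Reweighting, projection, PMF extraction and block analysis."""
import numpy as np
import pytest

import mgbind as mg
from mgbind import presets
from mgbind.fes import FESGrid, fes_from_csv
from mgbind.sampling import SamplerParams, Trajectory

RT = mg.RT_310


def _traj(cvs_2d, bias=None):
    cvs_2d = np.asarray(cvs_2d, float)
    n = len(cvs_2d)
    return Trajectory(0, np.arange(1, n + 1), None, cvs_2d,
                      np.zeros(n) if bias is None else bias,
                      SamplerParams(seed=0), [f"cv{i}" for i in
                                              range(cvs_2d.shape[1])])


class TestReweighting:
    def test_zero_bias_equals_plain_histogram_exactly(self):
        rng = np.random.default_rng(0)
        x = rng.normal(1.0, 0.3, size=4000)[:, None]
        grid = mg.GridSpec.uniform_1d("x", 0.0, 2.0, 40)
        fes = mg.reweight_to_fes(_traj(x), mg.BiasState(n_cv=1), grid,
                                 discard=0)
        hist, _ = np.histogram(x[:, 0], bins=grid.edges()[0])
        with np.errstate(divide="ignore"):
            expected = np.where(hist > 0, -RT * np.log(hist.astype(float)),
                                np.nan)
        expected -= np.nanmin(expected)
        assert np.array_equal(np.isnan(fes.free_energy), np.isnan(expected))
        assert np.allclose(fes.free_energy[np.isfinite(expected)],
                           expected[np.isfinite(expected)])

    def test_direct_sampling_oracle_with_analytic_bias(self):
        # draw exactly from exp(-(U+V_b)/RT) and check the reweighted FES
        # recovers -RT ln of the *unbiased* target density
        rng = np.random.default_rng(7)
        k = 20.0
        bias = mg.BiasState(n_cv=1)
        bias.add_hill(0.0, [0.5], 4.0, widths=[0.3])
        xs = np.linspace(-1.5, 2.5, 4001)
        u = 0.5 * k * xs**2
        vb = bias.bias(xs[:, None])
        dens = np.exp(-(u + vb) / RT)
        dens /= dens.sum()
        x = rng.choice(xs, size=300_000, p=dens)[:, None]
        grid = mg.GridSpec.uniform_1d("x", -0.8, 1.2, 50)
        fes = mg.reweight_to_fes(_traj(x, bias.bias(x)), bias, grid, discard=0)
        centers = grid.centers()[0]
        target = 0.5 * k * centers**2
        sel = target < 8.0
        resid = fes.free_energy[sel] - target[sel]
        assert np.nanstd(resid) < 0.25
        assert abs(np.nanmean(resid) - np.nanmean(resid[:1])) < 1.0

    def test_gauge_invariance_constant_bias_offset(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0.5, 0.2, size=5000)[:, None]
        grid = mg.GridSpec.uniform_1d("x", 0.0, 1.0, 25)
        base = mg.BiasState(n_cv=1)
        base.add_hill(0.0, [0.5], 2.0, widths=[0.2])

        class Offset:
            def __init__(self, b, c):
                self.b, self.c = b, c

            def __len__(self):
                return len(self.b)

            def bias(self, s):
                return self.b.bias(s) + self.c

        f0 = mg.reweight_to_fes(_traj(x), base, grid, discard=0)
        f1 = mg.reweight_to_fes(_traj(x), Offset(base, 123.4), grid, discard=0)
        ok = np.isfinite(f0.free_energy)
        assert np.allclose(f0.free_energy[ok], f1.free_energy[ok], atol=1e-9)

    def test_wtmetad_double_well_matches_quadrature(self, double_well_run):
        run = double_well_run
        grid = presets.double_well_grid()
        fes = mg.reweight_to_fes(run["trajs"], run["bias"], grid, discard=1 / 3)
        centers = grid.centers()[0]
        est = mg.basin_free_energy_difference(centers, fes.free_energy, 1.25)
        ref = mg.reference_fes_by_quadrature(run["landscape"], grid,
                                             run["cvs"], spacing=0.002)
        quad_gap = mg.basin_free_energy_difference(centers, ref.free_energy,
                                                   1.25)
        assert abs(est - quad_gap) < 0.5

    def test_discard_and_coverage_errors(self):
        x = np.linspace(0, 1, 50)[:, None]
        grid = mg.GridSpec.uniform_1d("x", 0.0, 1.0, 10)
        with pytest.raises(ValueError):
            mg.reweight_to_fes(_traj(x), mg.BiasState(n_cv=1), grid,
                               discard=50)
        off_grid = mg.GridSpec.uniform_1d("x", 5.0, 6.0, 10)
        with pytest.raises(ValueError):
            mg.reweight_to_fes(_traj(x), mg.BiasState(n_cv=1), off_grid,
                               discard=0)


class TestProjection:
    def _separable(self):
        grid = mg.GridSpec(["x", "y"], [-1, -1], [1, 1], [60, 60])
        X, Y = np.meshgrid(*grid.centers(), indexing="ij")
        return FESGrid(grid, 3 * X**2 + 5 * Y**2, RT=RT)

    def test_separable_quadratic_projects_to_quadratic(self):
        fes = self._separable()
        proj = mg.project_fes(fes, ["x"])
        x = proj.grid.centers()[0]
        expected = 3 * x**2
        expected -= expected.min()
        assert np.allclose(proj.free_energy, expected, atol=1e-9)

    def test_projection_idempotent_composition(self):
        grid = mg.GridSpec(["x", "y", "z"], [0, 0, 0], [1, 1, 1], [12, 14, 16])
        rng = np.random.default_rng(2)
        fes = FESGrid(grid, rng.uniform(0, 10, grid.shape), RT=RT)
        one = mg.project_fes(mg.project_fes(fes, ["x", "y"]), ["x"])
        direct = mg.project_fes(fes, ["x"])
        assert np.allclose(one.free_energy, direct.free_energy, atol=1e-9)

    def test_2d_gaussian_basin_projection_vs_1d_quadrature(self):
        grid = mg.GridSpec(["x", "y"], [-2, -2], [2, 2], [200, 200])
        X, Y = np.meshgrid(*grid.centers(), indexing="ij")
        f2 = -8.0 * np.exp(-(X**2 + 0.5 * Y**2) / 0.3)
        fes = FESGrid(grid, f2 - f2.min(), RT=RT)
        proj = mg.project_fes(fes, ["x"])
        # 1D quadrature of the same density over y
        y = grid.centers()[1]
        direct = np.array([
            -RT * np.log(np.sum(np.exp(-(-8.0 * np.exp(-(x**2 + 0.5 * y**2)
                                                       / 0.3)) / RT)))
            for x in grid.centers()[0]])
        direct -= direct.min()
        # common offset from the f2.min() shift cancels after re-zeroing
        assert np.max(np.abs(proj.free_energy - direct)) < 1e-8

    def test_empty_keep_dims_rejected(self):
        with pytest.raises(ValueError):
            mg.project_fes(self._separable(), [])

    def test_missing_cells_excluded_not_imputed(self):
        grid = mg.GridSpec(["x", "y"], [0, 0], [1, 1], [4, 4])
        f = np.zeros((4, 4))
        f[:, 2:] = np.nan
        fes = FESGrid(grid, f, RT=RT)
        proj = mg.project_fes(fes, ["x"])
        assert np.all(np.isfinite(proj.free_energy))
        assert np.allclose(proj.free_energy, 0.0)


class TestPMF:
    def test_flat_fes_gives_zero_pmf(self):
        grid = mg.GridSpec.uniform_1d("L", 0.0, 2.5, 50)
        fes = FESGrid(grid, np.zeros(50), RT=RT)
        pmf = mg.pmf_along_cv(fes, "L", (2.0, 2.5))
        assert np.allclose(pmf.values, 0.0)

    def test_square_well_pmf_levels(self):
        grid = mg.GridSpec.uniform_1d("L", 0.0, 2.5, 250)
        centers = grid.centers()[0]
        f = np.where(centers < 0.4, -10.0, 0.0)
        fes = FESGrid(grid, f - f.min(), RT=RT)
        pmf = mg.pmf_along_cv(fes, "L", (2.0, 2.5))
        assert np.allclose(pmf.values[centers < 0.4], -10.0)
        assert np.allclose(pmf.values[(centers > 2.0) & (centers < 2.5)], 0.0)

    def test_unvisited_window_rejected(self):
        grid = mg.GridSpec.uniform_1d("L", 0.0, 2.5, 50)
        f = np.full(50, np.nan)
        f[:10] = 0.0
        fes = FESGrid(grid, f, RT=RT)
        with pytest.raises(ValueError):
            mg.pmf_along_cv(fes, "L", (2.0, 2.5))

    def test_projection_commutes_with_rezeroing(self):
        grid = mg.GridSpec(["L", "y"], [0, -1], [2.5, 1], [50, 20])
        rng = np.random.default_rng(3)
        f = rng.uniform(0, 5, grid.shape)
        fes_a = FESGrid(grid, f, RT=RT)
        fes_b = FESGrid(grid, f + 7.0 - np.min(f + 7.0), RT=RT)
        pa = mg.pmf_along_cv(fes_a, "L", (2.0, 2.5))
        pb = mg.pmf_along_cv(fes_b, "L", (2.0, 2.5))
        assert np.allclose(pa.values, pb.values, atol=1e-9)


class TestBlockAnalysis:
    def test_constant_series_zero_sem(self):
        res = mg.block_analysis(np.full(1000, 3.3), range(3, 20))
        assert np.allclose(res.sems, 0.0)
        assert res.plateau_value == pytest.approx(3.3)

    def test_iid_normal_sem_matches_closed_form(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(10_000)
        res = mg.block_analysis(x, [10])
        # sigma/sqrt(n) with sigma=1, n=1e4
        assert res.sems[0] == pytest.approx(0.01, rel=0.3)

    def test_ar1_sem_grows_toward_plateau(self):
        rng = np.random.default_rng(4)
        n = 40_000
        phi = 0.9
        eps = rng.standard_normal(n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        # include blocks far below the correlation time (~19 samples) so
        # the small-block SEM underestimation is unambiguous
        res = mg.block_analysis(x, [5, 20, 100, 400, 2000, 20_000])
        order = np.argsort(res.block_sizes)
        sems = res.sems[order]
        assert sems[-1] > 2 * sems[0]
        corr = np.corrcoef(np.log(res.block_sizes[order]), sems)[0, 1]
        assert corr > 0.7

    def test_counts_exceeding_length_skipped(self):
        res = mg.block_analysis(np.arange(10.0), [3, 5, 50])
        assert list(res.block_counts) == [3, 5]

    def test_series_too_short_raises(self):
        with pytest.raises(ValueError):
            mg.block_analysis(np.arange(3.0), [50])


def test_fes_csv_round_trip(tmp_path):
    from mgbind.pipeline import _write_fes_csv

    grid = mg.GridSpec(["L1", "L2"], [0, 0], [1, 1], [8, 9])
    rng = np.random.default_rng(5)
    f = rng.uniform(0, 4, grid.shape)
    f[0, 0] = np.nan
    f -= np.nanmin(f)
    fes = FESGrid(grid, f, RT=RT)
    path = tmp_path / "fes.csv"
    _write_fes_csv(fes, path)
    back = fes_from_csv(path)
    assert back.grid.cv_names == ["L1", "L2"]
    assert back.grid.shape == (8, 9)
    assert np.allclose(back.free_energy[np.isfinite(f)], f[np.isfinite(f)])
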