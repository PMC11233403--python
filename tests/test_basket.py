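import numpy as np
import pytest

from glycovol.basket import (
    SMALL,
    BasketConfig,
    DiameterDistribution,
    VirtualGranuleSet,
    boolean_model_vf,
    fit_quadratic,
    place_granules,
    project_slab,
    run_calibration,
    sample_diameters,
    simulate_basket,
    slice_slabs,
    voxelize,
)


def naive_voxelize(granules, config):
    """Exhaustive voxel-center-in-sphere oracle (triple loop)."""
    nx, ny, nz = config.grid
    occ = np.zeros(config.grid, dtype=bool)
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                p = np.array([ix + 0.5, iy + 0.5, iz + 0.5])
                for c, d in zip(granules.centers, granules.diameters_vox):
                    if ((p - c) ** 2).sum() <= (d / 2) ** 2:
                        occ[ix, iy, iz] = True
                        break
    return occ


class TestDiameters:
    def test_zero_draws(self):
        assert len(sample_diameters(0, SMALL, seed=0)) == 0

    def test_truncation_and_mean(self):
        d = sample_diameters(3000, SMALL, seed=1)
        assert (d >= SMALL.min_nm).all()
        assert abs(d.mean() - 25.0) < 3 * 5.0 / np.sqrt(3000)

    def test_degenerate_sd(self):
        d = sample_diameters(10, DiameterDistribution(20.0, 0.0), seed=0)
        assert (d == 20.0).all()


class TestPlacement:
    def test_concentration_mapping(self):
        cfg = BasketConfig()
        assert cfg.volume_um3 == pytest.approx(0.5)
        assert place_granules(3000, SMALL, cfg, seed=0).n / cfg.volume_um3 == pytest.approx(6000)
        assert place_granules(400, SMALL, cfg, seed=0).n / cfg.volume_um3 == pytest.approx(800)

    def test_centers_uniform(self):
        cfg = BasketConfig()
        g = place_granules(3000, SMALL, cfg, seed=2)
        for axis, extent in enumerate(cfg.grid):
            se = extent / np.sqrt(12) / np.sqrt(3000)
            assert abs(g.centers[:, axis].mean() - extent / 2) < 3 * se
        assert (g.centers >= 0).all() and (g.centers <= cfg.grid).all()


class TestVoxelize:
    small_cfg = BasketConfig(grid=(30, 30, 30), slab_depth_vox=10, slab_start_vox=0)

    def test_empty_set(self):
        grid = voxelize(VirtualGranuleSet(np.empty((0, 3)), np.empty(0)), self.small_cfg)
        assert grid.vf == 0.0

    def test_single_sphere_volume(self):
        cfg = BasketConfig(grid=(40, 40, 40), slab_depth_vox=10, slab_start_vox=0)
        g = VirtualGranuleSet(np.array([[20.0, 20.0, 20.0]]), np.array([20.0]))
        count = voxelize(g, cfg).occupancy.sum()
        assert count == pytest.approx(np.pi / 6 * 20**3, rel=0.02)

    def test_union_idempotence(self):
        g1 = VirtualGranuleSet(np.array([[15.0, 15.0, 15.0]]), np.array([10.0]))
        g2 = VirtualGranuleSet(
            np.array([[15.0, 15.0, 15.0]] * 2), np.array([10.0, 10.0])
        )
        np.testing.assert_array_equal(
            voxelize(g1, self.small_cfg).occupancy, voxelize(g2, self.small_cfg).occupancy
        )

    def test_matches_exhaustive_oracle(self):
        cfg = BasketConfig(grid=(12, 12, 12), slab_depth_vox=4, slab_start_vox=0)
        rng = np.random.default_rng(3)
        g = VirtualGranuleSet(rng.random((5, 3)) * 12, rng.uniform(2, 8, 5))
        np.testing.assert_array_equal(voxelize(g, cfg).occupancy, naive_voxelize(g, cfg))


class TestSlabsAndProjection:
    def test_standard_plan_gives_seven(self):
        grid = voxelize(VirtualGranuleSet(np.empty((0, 3)), np.empty(0)), BasketConfig())
        assert len(slice_slabs(grid, BasketConfig())) == 7

    def test_exact_fit_gives_one(self):
        cfg = BasketConfig(grid=(8, 8, 24), slab_depth_vox=24, slab_start_vox=0)
        grid = voxelize(VirtualGranuleSet(np.empty((0, 3)), np.empty(0)), cfg)
        assert len(slice_slabs(grid, cfg)) == 1

    def test_too_shallow_gives_zero(self):
        cfg = BasketConfig(grid=(8, 8, 23), slab_depth_vox=24, slab_start_vox=0)
        grid = voxelize(VirtualGranuleSet(np.empty((0, 3)), np.empty(0)), cfg)
        assert slice_slabs(grid, cfg) == []

    def test_projection_of_empty_slab(self):
        proj, pf = project_slab(np.zeros((10, 10, 5), dtype=bool))
        assert pf == 0.0 and not proj.any()

    def test_projection_of_contained_sphere(self):
        cfg = BasketConfig(grid=(400, 400, 24), slab_depth_vox=24, slab_start_vox=0)
        g = VirtualGranuleSet(np.array([[200.0, 200.0, 12.0]]), np.array([20.0]))
        grid = voxelize(g, cfg)
        _, pf = project_slab(slice_slabs(grid, cfg)[0])
        assert pf == pytest.approx(np.pi * 10**2 / 400**2, rel=0.05)

    def test_projection_pf_bounds_slab_fraction(self):
        cfg = BasketConfig(grid=(60, 60, 24), slab_depth_vox=24, slab_start_vox=0)
        g = place_granules(40, SMALL, cfg, seed=4)
        slab = slice_slabs(voxelize(g, cfg), cfg)[0]
        _, pf = project_slab(slab)
        assert pf >= slab.mean()

    def test_single_voxel_slab_pf_equals_vf(self):
        cfg = BasketConfig(grid=(60, 60, 1), slab_depth_vox=1, slab_start_vox=0)
        g = place_granules(10, SMALL, cfg, seed=5)
        grid = voxelize(g, cfg)
        _, pf = project_slab(slice_slabs(grid, cfg)[0])
        assert pf == pytest.approx(grid.vf)


class TestCalibration:
    def test_sixteen_points_cover_stated_concentrations(self):
        cfg = BasketConfig(grid=(80, 80, 200))  # narrower basket, same z plan
        pts = run_calibration(cfg, seed=0)
        assert len(pts) == 16
        Gs = sorted({p.G for p in pts})
        assert Gs[0] == pytest.approx(400 / cfg.volume_um3)
        assert Gs[-1] == pytest.approx(3000 / cfg.volume_um3)

    def test_monotone_in_concentration(self):
        pts = run_calibration(seed=0)
        for tag in ("Small", "Large"):
            sub = [p for p in pts if p.distribution_tag == tag]
            pf = [p.pf for p in sub]
            vf = [p.vf for p in sub]
            assert pf == sorted(pf)
            assert vf == sorted(vf)

    def test_low_density_matches_boolean_model(self):
        pt = simulate_basket(400, SMALL, seed=6)
        expected = boolean_model_vf(pt.G, SMALL)
        assert pt.vf == pytest.approx(expected, rel=0.10)

    def test_counts_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            BasketConfig(granule_counts=(400, 400, 500))


class TestFitQuadratic:
    def test_exact_interpolation(self):
        x = np.linspace(0, 1, 8)
        y = 0.05 * x**2 + 0.24 * x
        f = fit_quadratic(np.c_[x, y])
        assert f.a == pytest.approx(0.05, abs=1e-10)
        assert f.b == pytest.approx(0.24, abs=1e-10)
        assert f.c == pytest.approx(0.0, abs=1e-10)

    def test_constant_series(self):
        x = np.linspace(0, 1, 5)
        f = fit_quadratic(np.c_[x, np.full(5, 3.0)])
        assert f.a == pytest.approx(0.0, abs=1e-9)
        assert f.b == pytest.approx(0.0, abs=1e-9)
        assert f.c == pytest.approx(3.0)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_quadratic([(0, 0), (1, 1)])
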