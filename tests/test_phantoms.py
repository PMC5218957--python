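"""Phantom rasterization: geometry, activity bookkeeping, materials, I/O."""

import math

import numpy as np
import pytest

from luquant import phantoms as ph


@pytest.fixture(scope="module")
def grid2mm():
    return ph.VoxelGrid((128, 128, 128), 2.0)


class TestRasterize:
    def test_sphere_113ml_volume_within_1pct(self, grid2mm):
        ins = ph.InsertSpec("sphere", (0, 0, 0), 113.0, 3.19, "S6")
        rast = ph.rasterize_insert(grid2mm, ins)
        assert rast.volume_ml == pytest.approx(113.0, rel=0.01)

    def test_zero_volume_insert_gives_empty_mask(self, grid2mm):
        ins = ph.InsertSpec("sphere", (0, 0, 0), 0.0, 1.0, "empty")
        rast = ph.rasterize_insert(grid2mm, ins)
        assert not rast.mask.any() and rast.volume_ml == 0.0

    def test_cylinder_34ml_matches_analytic_volume(self, grid2mm):
        ins = ph.InsertSpec("cylinder", (10.0, -8.0, 4.0), 34.0, 8.8, "T1")
        rast = ph.rasterize_insert(grid2mm, ins)
        analytic_ml = math.pi * ins.radius_mm**2 * ins.height_mm / 1000.0
        assert analytic_ml == pytest.approx(34.0, rel=1e-12)
        assert rast.volume_ml == pytest.approx(analytic_ml, rel=0.01)

    def test_small_sphere_volume_still_accurate(self, grid2mm):
        ins = ph.InsertSpec("sphere", (0, 0, 0), 1.0, 3.19, "S1")
        rast = ph.rasterize_insert(grid2mm, ins)
        assert rast.volume_ml == pytest.approx(1.0, rel=0.01)

    def test_insert_beyond_grid_raises_with_label(self, grid2mm):
        ins = ph.InsertSpec("sphere", (125.0, 0, 0), 113.0, 1.0, "runaway")
        with pytest.raises(ValueError, match="runaway"):
            ph.rasterize_insert(grid2mm, ins)


class TestMaterials:
    def test_air_is_effectively_vacuum(self):
        assert ph.mu_for_material("air") < 1e-4

    def test_water_near_nist_value(self):
        # mu/rho ~ 0.136 cm^2/g at 208 keV, rho = 1 g/ml
        assert ph.mu_for_material("water") == pytest.approx(0.136, abs=0.005)

    def test_density_ordering(self):
        mus = [ph.mu_for_material(m) for m in ("bone", "water", "lung", "air")]
        assert mus == sorted(mus, reverse=True)

    def test_unknown_material_raises(self):
        with pytest.raises(ValueError, match="unknown material"):
            ph.mu_for_material("cheese")


@pytest.fixture(scope="module")
def coarse_grid():
    return ph.VoxelGrid((96, 96, 96), 3.2)


class TestBuildPhantom:
    def test_warm_background_concentration(self, coarse_grid):
        cfg = ph.preset("jaszczak_spheres_warm_water")
        phantom = ph.build_phantom(cfg, coarse_grid)
        vox = coarse_grid.voxel_volume_ml
        bg_vals = phantom.activity[phantom.background_mask]
        # interior background voxels carry 0.49 MBq/ml x voxel volume
        assert np.median(bg_vals) == pytest.approx(0.49 * vox, rel=1e-6)

    def test_air_background_is_zero(self, coarse_grid):
        cfg = ph.preset("jaszczak_spheres_air")
        phantom = ph.build_phantom(cfg, coarse_grid)
        assert phantom.activity[phantom.background_mask].sum() == 0.0

    def test_total_activity_conservation(self, coarse_grid):
        cfg = ph.preset("jaszczak_bottles_warm_water")
        phantom = ph.build_phantom(cfg, coarse_grid)
        # independent summation oracle: analytic container and insert volumes
        insert_total = sum(s.volume_ml * s.concentration for s in cfg.inserts)
        cyl_ml = math.pi * (ph.JASZCZAK_DIAMETER / 20.0) ** 2 \
            * ph.JASZCZAK_HEIGHT / 10.0
        bg_volume = cyl_ml - sum(s.volume_ml for s in cfg.inserts)
        expected = insert_total + bg_volume * 0.104
        assert phantom.total_activity_MBq == pytest.approx(expected, rel=0.01)

    def test_sbr_matches_configured_ratio_exactly(self):
        cfg = ph.preset("jaszczak_bottles_warm_water")
        assert cfg.sbr == 5.11 / 0.104

    def test_rebuild_is_bit_identical(self, coarse_grid):
        cfg = ph.preset("jaszczak_spheres_cold_water")
        p1 = ph.build_phantom(cfg, coarse_grid)
        p2 = ph.build_phantom(cfg, coarse_grid)
        assert np.array_equal(p1.activity, p2.activity)
        assert np.array_equal(p1.mu, p2.mu)

    def test_overlapping_inserts_raise(self, coarse_grid):
        cfg = ph.StudyConfig("clash",
                             [ph.InsertSpec("sphere", (0, 0, 0), 30.0, 1.0, "a"),
                              ph.InsertSpec("sphere", (5.0, 0, 0), 30.0, 1.0, "b")],
                             0.0, 10.0, "air")
        with pytest.raises(ValueError, match="overlap"):
            ph.build_phantom(cfg, coarse_grid)

    def test_insert_masks_disjoint(self, coarse_grid):
        phantom = ph.build_phantom(ph.preset("jaszczak_spheres_air"), coarse_grid)
        total = sum(m.astype(int) for m in phantom.insert_masks.values())
        assert total.max() <= 1

    def test_all_presets_build(self, coarse_grid):
        for name in ph.PRESET_NAMES:
            phantom = ph.build_phantom(ph.preset(name), coarse_grid)
            assert np.all(phantom.activity >= 0) and np.all(phantom.mu >= 0)

    def test_air_medium_must_have_zero_background(self):
        with pytest.raises(ValueError, match="zero background"):
            ph.StudyConfig("bad", [], 0.1, 10.0, "air")


class TestIO:
    def test_yaml_round_trip(self, tmp_path):
        cfg = ph.preset("thorax_cold_water")
        path = tmp_path / "cfg.yaml"
        ph.save_config_yaml(cfg, str(path))
        back = ph.load_config_yaml(str(path))
        assert back == cfg

    def test_nifti_output(self, tmp_path):
        import nibabel as nib

        grid = ph.VoxelGrid((32, 32, 32), 4.8)
        cfg = ph.StudyConfig("tiny", [ph.InsertSpec("sphere", (0, 0, 0), 20.0,
                                                    1.0, "a")], 0.0, 10.0, "air")
        phantom = ph.build_phantom(cfg, grid)
        ph.save_phantom_nifti(phantom, str(tmp_path / "p"))
        img = nib.load(str(tmp_path / "p_activity.nii.gz"))
        assert np.allclose(img.get_fdata(), phantom.activity)
        assert img.header.get_zooms()[0] == pytest.approx(4.8)
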