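"""IHC quantification against generator ground truth and closed forms."""

import numpy as np
import pytest

from alsquant.histology import SceneConfig, build_scene, render_section
from alsquant.ihc import (
    QuantConfig,
    TissueMask,
    calibrate_automated_counts,
    compute_tissue_mask,
    detect_brown_positive,
    detect_motor_neurons,
    erode_tissue_mask,
    filter_by_min_area,
    percent_area_stained,
)


def _tissue(mask, um=0.65):
    return TissueMask(mask=mask, area_um2=float(mask.sum()) * um**2, um_per_pixel=um)


class TestTissueMask:
    def test_all_white_image(self, quant_config):
        rgb = np.full((64, 64, 3), 255, dtype=np.uint8)
        tm = compute_tissue_mask(rgb, quant_config)
        assert tm.area_um2 == 0.0

    def test_overlap_with_ground_truth(self, small_scene, quant_config):
        truth, sec, _ = small_scene
        tm = compute_tissue_mask(sec.rgb, quant_config)
        inter = (tm.mask & truth.tissue_mask_true).sum()
        union = (tm.mask | truth.tissue_mask_true).sum()
        assert inter / union >= 0.95

    def test_area_definition(self, small_scene, quant_config):
        _, sec, cfg = small_scene
        tm = compute_tissue_mask(sec.rgb, quant_config)
        assert tm.area_um2 == pytest.approx(tm.mask.sum() * cfg.um_per_pixel**2)

    def test_non_rgb_rejected(self, quant_config):
        with pytest.raises(ValueError, match="RGB"):
            compute_tissue_mask(np.zeros((10, 10)), quant_config)


class TestErosion:
    def test_zero_margin_identity(self, small_scene, quant_config):
        _, sec, _ = small_scene
        tm = compute_tissue_mask(sec.rgb, quant_config)
        assert np.array_equal(erode_tissue_mask(tm, 0.0).mask, tm.mask)

    def test_disk_closed_form(self):
        # solid disk radius 100 um, margin 10 um -> area ~ pi * 90^2 um^2
        um = 0.65
        r_px = 100 / um
        yy, xx = np.mgrid[0:400, 0:400]
        disk = (yy - 200) ** 2 + (xx - 200) ** 2 <= r_px**2
        eroded = erode_tissue_mask(_tissue(disk, um), 10.0)
        assert eroded.area_um2 == pytest.approx(np.pi * 90**2, rel=0.05)

    def test_anti_extensive(self, small_scene, quant_config):
        _, sec, _ = small_scene
        tm = compute_tissue_mask(sec.rgb, quant_config)
        for margin in (1.0, 5.0, 20.0):
            er = erode_tissue_mask(tm, margin)
            assert not (er.mask & ~tm.mask).any()
            assert er.area_um2 <= tm.area_um2


class TestMotorNeurons:
    def test_blank_tissue(self, quant_config):
        cfg = SceneConfig(canvas_px=(256, 256), n_cells=0, diffuse_fraction=0.0, seed=1)
        sec = render_section(build_scene(cfg), cfg)
        tm = compute_tissue_mask(sec.rgb, quant_config)
        assert detect_motor_neurons(sec.rgb, tm, quant_config).count == 0

    def test_count_and_centroids_clean(self, quant_config):
        cfg = SceneConfig(n_cells=30, n_touching_pairs=0, diffuse_fraction=0.0, seed=1)
        truth = build_scene(cfg)
        sec = render_section(truth, cfg)
        tm = compute_tissue_mask(sec.rgb, quant_config)
        det = detect_motor_neurons(sec.rgb, tm, quant_config)
        assert det.count == 30
        from scipy.optimize import linear_sum_assignment
        from scipy.spatial.distance import cdist

        d = cdist(np.array(truth.cell_centroids), np.array(det.centroids))
        ri, ci = linear_sum_assignment(d)
        assert (d[ri, ci] * cfg.um_per_pixel).max() <= 5.0

    def test_watershed_splits_touching_pairs(self, quant_config):
        cfg = SceneConfig(
            canvas_px=(512, 512), n_cells=6, n_touching_pairs=3, diffuse_fraction=0.0, seed=3
        )
        sec = render_section(build_scene(cfg), cfg)
        tm = compute_tissue_mask(sec.rgb, quant_config)
        assert detect_motor_neurons(sec.rgb, tm, quant_config).count == 6

    def test_result_invariants(self, small_scene, quant_config):
        _, sec, _ = small_scene
        tm = compute_tissue_mask(sec.rgb, quant_config)
        det = detect_motor_neurons(sec.rgb, tm, quant_config)
        assert det.count == len(det.centroids) == len(det.areas_um2)
        assert det.count == len(np.unique(det.label_mask)) - 1
        for a in det.areas_um2:
            assert quant_config.min_cell_area_um2 <= a <= quant_config.max_cell_area_um2

    def test_degenerate_config_rejected(self, small_scene):
        _, sec, _ = small_scene
        bad = QuantConfig(min_cell_area_um2=500, max_cell_area_um2=100)
        with pytest.raises(ValueError, match="min_cell_area"):
            compute_tissue_mask(sec.rgb, bad)


class TestBrownDetection:
    def test_rule_on_palette(self, quant_config):
        # brown (130,80,40): B ratio 0.16; tissue (190,190,210): 0.356
        rgb = np.zeros((20, 40, 3), dtype=np.uint8)
        rgb[:, :20] = (130, 80, 40)
        rgb[:, 20:] = (190, 190, 210)
        tm = _tissue(np.ones((20, 40), dtype=bool))
        cfg = QuantConfig(open_radius_um=0.0)  # no cleanup: pure rule
        pos = detect_brown_positive(rgb, tm, cfg)
        assert pos[:, :20].all()
        assert not pos[:, 20:].any()

    def test_all_black_is_negative(self, quant_config):
        rgb = np.zeros((16, 16, 3), dtype=np.uint8)
        tm = _tissue(np.ones((16, 16), dtype=bool))
        assert not detect_brown_positive(rgb, tm, quant_config).any()

    def test_threshold_monotonicity(self, small_scene):
        from alsquant.ihc import BrownRule

        _, sec, _ = small_scene
        counts = []
        for thr in (0.20, 0.25, 0.30, 0.35, 0.40):
            cfg = QuantConfig(brown_rule=BrownRule(blue_ratio_max=thr))
            tm = compute_tissue_mask(sec.rgb, cfg)
            counts.append(detect_brown_positive(sec.rgb, tm, cfg).sum())
        assert all(a <= b for a, b in zip(counts, counts[1:]))


class TestClusterFilter:
    def test_cutoff_180(self):
        # 100 um^2 and 200 um^2 components at 1 um/px
        img = np.zeros((40, 80), dtype=bool)
        img[5:15, 5:15] = True  # 100 px = 100 um^2
        img[5:15, 40:60] = True  # 200 px = 200 um^2
        out = filter_by_min_area(img, 180.0, 1.0)
        assert not out[5:15, 5:15].any()
        assert out[5:15, 40:60].all()

    def test_zero_cutoff_identity(self, small_scene):
        truth, _, _ = small_scene
        img = truth.diffuse_mask_true
        assert np.array_equal(filter_by_min_area(img, 0.0, 0.65), img)

    def test_anti_extensive(self, small_scene):
        truth, _, _ = small_scene
        out = filter_by_min_area(truth.diffuse_mask_true, 500.0, 0.65)
        assert not (out & ~truth.diffuse_mask_true).any()


class TestPercentArea:
    def test_arithmetic(self):
        tissue = np.zeros((40, 40), dtype=bool)
        tissue[:20] = True  # 800 px
        pos = np.zeros_like(tissue)
        pos[:5] = True  # 200 px inside tissue
        q = percent_area_stained(pos, _tissue(tissue, um=1.0))
        assert q.percent_area == pytest.approx(25.0)
        full = percent_area_stained(tissue, _tissue(tissue, um=1.0))
        assert full.percent_area == pytest.approx(100.0)

    def test_zero_tissue_errors(self):
        empty = _tissue(np.zeros((8, 8), dtype=bool))
        with pytest.raises(ZeroDivisionError):
            percent_area_stained(np.zeros((8, 8), dtype=bool), empty)

    def test_recovers_diffuse_fraction(self, small_scene, quant_config):
        truth, sec, cfg = small_scene
        tm = compute_tissue_mask(sec.rgb, quant_config)
        pos = detect_brown_positive(sec.rgb, tm, quant_config)
        q = percent_area_stained(pos, tm)
        assert q.percent_area == pytest.approx(
            100 * truth.diffuse_area_fraction_true, abs=1.0
        )


class TestCountCalibration:
    def test_exact_undercount(self):
        pairs = [(m, 0.75 * m) for m in (10, 20, 30, 40)]
        cal = calibrate_automated_counts(pairs)
        assert cal.slope == pytest.approx(0.75)
        assert cal.r_squared == pytest.approx(1.0)
        assert cal.mean_bias_fraction == pytest.approx(0.25)

    def test_identity(self):
        cal = calibrate_automated_counts([(m, m) for m in (5, 10, 15)])
        assert cal.slope == pytest.approx(1.0)
        assert cal.mean_bias_fraction == pytest.approx(0.0)

    def test_ols_recovery_noisy(self):
        rng = np.random.default_rng(12)
        manual = rng.integers(20, 80, size=20)
        auto = 0.75 * manual + rng.normal(0, 2, size=20)
        cal = calibrate_automated_counts(list(zip(manual, auto)))
        assert abs(cal.slope - 0.75) <= 0.1

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            calibrate_automated_counts([(10, 8), (10, 9), (10, 7)])
        with pytest.raises(ValueError):
            calibrate_automated_counts([(10, 8)])
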