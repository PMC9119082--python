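"""Metric semantics against brute-force enumeration and printed examples."""

import numpy as np
import pytest

from llrhnet import metrics
from llrhnet.metrics import (
    BinaryMask,
    UndefinedMetricError,
    assd,
    dice,
    evaluate_multiclass,
    evaluate_volume,
    hausdorff,
    rvd,
    voe,
)

import oracles


def block_pair():
    """3x3 blocks offset by one column on a 3x4 lattice (6-pixel overlap)."""
    p = np.zeros((3, 4), dtype=bool)
    g = np.zeros((3, 4), dtype=bool)
    p[:, 0:3] = True
    g[:, 1:4] = True
    return p, g


class TestOverlapMetrics:
    def test_identity_and_disjoint_limits(self):
        m = np.zeros((4, 4), dtype=bool)
        m[1:3, 1:3] = True
        other = ~m
        assert dice(m, m) == 1.0
        assert voe(m, m) == 0.0
        assert rvd(m, m) == 0.0
        assert dice(m, other) == 0.0
        assert voe(m, other) == 1.0

    def test_block_overlap_worked_example(self):
        p, g = block_pair()
        assert dice(p, g) == pytest.approx(2 * 6 / 18)
        assert voe(p, g) == pytest.approx(1 - 6 / 12)

    def test_rvd_signs(self):
        small = np.zeros((4, 4), dtype=bool)
        small[0, :2] = True  # 2 px
        p8 = np.zeros((4, 4), dtype=bool)
        p8[:2, :] = True  # 8 px
        g12 = np.zeros((4, 4), dtype=bool)
        g12[:3, :] = True  # 12 px
        assert rvd(p8, g12) == pytest.approx(0.5)
        assert rvd(g12, p8) == pytest.approx(-1 / 3)

    def test_point_pair_distance_345(self):
        p = np.zeros((5, 6), dtype=bool)
        g = np.zeros((5, 6), dtype=bool)
        p[0, 0] = True
        g[3, 4] = True
        assert hausdorff(p, g) == pytest.approx(5.0)
        assert assd(p, g) == pytest.approx(5.0)

    def test_oracle_equivalence_on_random_pairs(self, random_mask_pairs):
        for p, g in random_mask_pairs:
            assert dice(p, g) == oracles.brute_dice(p, g)
            assert voe(p, g) == oracles.brute_voe(p, g)
            if p.sum():
                assert rvd(p, g) == pytest.approx(oracles.brute_rvd(p, g), abs=1e-12)
            if p.sum() and g.sum():
                assert hausdorff(p, g) == pytest.approx(
                    oracles.brute_hausdorff(p, g), abs=1e-9)
                assert assd(p, g) == pytest.approx(
                    oracles.brute_assd(p, g), abs=1e-9)

    def test_dc_voe_algebraic_identity(self, random_mask_pairs):
        for p, g in random_mask_pairs:
            v = voe(p, g)
            assert dice(p, g) == pytest.approx(2 * (1 - v) / (2 - v), abs=1e-12)

    def test_symmetry(self, random_mask_pairs):
        for p, g in random_mask_pairs[:10]:
            assert dice(p, g) == dice(g, p)
            assert voe(p, g) == voe(g, p)
            if p.sum() and g.sum():
                assert hausdorff(p, g) == hausdorff(g, p)
                # rvd antisymmetry up to the volume ratio
                assert rvd(p, g) == pytest.approx(-rvd(g, p) * g.sum() / p.sum())

    def test_spacing_scales_distances_only(self):
        p, g = block_pair()
        m1 = BinaryMask(p, (1.0, 1.0)), BinaryMask(g, (1.0, 1.0))
        m2 = BinaryMask(p, (2.0, 2.0)), BinaryMask(g, (2.0, 2.0))
        assert hausdorff(*m2) == pytest.approx(2 * hausdorff(*m1))
        assert assd(*m2) == pytest.approx(2 * assd(*m1))
        assert dice(*m2) == dice(*m1)
        assert voe(*m2) == voe(*m1)
        assert rvd(*m2) == rvd(*m1)

    def test_anisotropic_spacing(self):
        p = np.zeros((3, 3), dtype=bool)
        g = np.zeros((3, 3), dtype=bool)
        p[0, 0] = True
        g[1, 2] = True  # offset (1 row, 2 cols)
        m = BinaryMask(p, (3.0, 0.5)), BinaryMask(g, (3.0, 0.5))
        assert hausdorff(*m) == pytest.approx(np.hypot(3.0, 1.0))


class TestConventionsAndErrors:
    def test_both_empty_conventions(self):
        e = np.zeros((4, 4), dtype=bool)
        assert dice(e, e) == 1.0
        assert voe(e, e) == 0.0

    def test_undefined_metrics_raise(self):
        e = np.zeros((3, 3), dtype=bool)
        f = np.ones((3, 3), dtype=bool)
        with pytest.raises(UndefinedMetricError):
            rvd(e, f)
        for fn in (hausdorff, assd):
            with pytest.raises(UndefinedMetricError):
                fn(e, f)
            with pytest.raises(UndefinedMetricError):
                fn(f, e)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            dice(np.ones((3, 3), dtype=bool), np.ones((3, 4), dtype=bool))

    def test_boundary_only_uses_surface_pixels(self):
        # concentric squares: full-region ASSD differs from boundary ASSD
        p = np.zeros((9, 9), dtype=bool)
        g = np.zeros((9, 9), dtype=bool)
        p[2:7, 2:7] = True
        g[1:8, 1:8] = True
        assert assd(p, g, boundary_only=True) != pytest.approx(assd(p, g))
        assert hausdorff(p, g) >= 0


class TestMulticlass:
    def test_perfect_prediction(self):
        gt = np.zeros((8, 8), dtype=np.uint8)
        gt[1:4, 1:4] = 1
        gt[5:7, 5:7] = 2
        reports = evaluate_multiclass(gt, gt, classes=(1, 2))
        for r in reports:
            assert (r.dc, r.voe, r.rvd, r.assd, r.hd) == (1.0, 0.0, 0.0, 0.0, 0.0)
            assert not r.missing

    def test_absent_class_reported_missing_not_zero(self):
        gt = np.zeros((6, 6), dtype=np.uint8)
        gt[2:4, 2:4] = 1  # class 2 absent everywhere
        reports = {r.class_label: r for r in evaluate_multiclass(gt, gt)}
        r2 = reports[2]
        assert r2.dc == 1.0 and r2.voe == 0.0
        assert np.isnan(r2.hd) and r2.missing["hd"] == "empty"
        assert np.isnan(r2.assd) and r2.missing["assd"] == "empty"
        assert np.isnan(r2.rvd)

    def test_composes_single_class_metrics(self):
        gen = np.random.default_rng(3)
        gt = gen.integers(0, 3, size=(12, 12)).astype(np.uint8)
        pred = gt.copy()
        pred[4, 4] = (pred[4, 4] + 1) % 3  # one mislabeled pixel
        for r in evaluate_multiclass(pred, gt):
            c = r.class_label
            assert r.dc == dice(pred == c, gt == c)
            assert r.voe == voe(pred == c, gt == c)
            assert r.hd == hausdorff(pred == c, gt == c)

    def test_unknown_label_rejected(self):
        gt = np.zeros((4, 4), dtype=np.uint8)
        bad = gt.copy()
        bad[0, 0] = 7
        with pytest.raises(ValueError, match="unknown"):
            evaluate_multiclass(bad, gt)

    def test_volume_mode_matches_slicewise_for_in_plane_lesions(self):
        # identical lesions on independent slices, isotropic spacing: the 3D
        # nearest neighbour of every pixel stays within its own slice
        gen = np.random.default_rng(5)
        gt_slices, pred_slices = [], []
        for _ in range(4):
            gt = np.zeros((10, 10), dtype=np.uint8)
            gt[2:7, 2:7] = 1
            pred = np.zeros_like(gt)
            pred[3:8, 2:7] = 1
            gt_slices.append(gt)
            pred_slices.append(pred)
        vol = {r.class_label: r for r in evaluate_volume(
            pred_slices, gt_slices, classes=(1,), pixel_spacing=(1.0, 1.0, 1.0))}
        sl = {r.class_label: r for r in evaluate_multiclass(
            pred_slices[0], gt_slices[0], classes=(1,))}
        assert vol[1].dc == pytest.approx(sl[1].dc)
        assert vol[1].hd == pytest.approx(sl[1].hd)
        assert vol[1].assd == pytest.approx(sl[1].assd)
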