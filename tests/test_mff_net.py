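"""Detector assembly: shapes, fusion wiring, assignment, losses, decoding."""

import itertools

import numpy as np
import pytest

from svbdete.autograd import Tensor
from svbdete.boxgeom import BoundingBox, PIoUConfig, ciou_loss, piou_loss
from svbdete.dsconv import FeatureMap
from svbdete.mff_net import (DetectorConfig, DownsampleFuse, RawPrediction,
                             UpsampleFuse, assign_targets, build_detector,
                             ciou_loss_tensor, compute_loss,
                             decode_predictions, downsample_fuse,
                             piou_loss_tensor, upsample_fuse)
from svbdete.nn import Adam


def _tiny_cfg(**kw):
    kw.setdefault("input_size", (64, 64))
    kw.setdefault("num_classes", 1)
    kw.setdefault("width", "tiny")
    return DetectorConfig(**kw)


class TestArchitectureContracts:
    def test_head_grids_at_full_resolution(self):
        det = build_detector(_tiny_cfg(input_size=(640, 640))).eval()
        raws = det(Tensor(np.zeros((1, 3, 640, 640), dtype=np.float32)))
        assert [r.grid_size for r in raws] \
            == [(160, 160), (80, 80), (40, 40), (20, 20)]
        assert [r.stride for r in raws] == [4, 8, 16, 32]

    def test_head_grids_at_tiny_resolution(self):
        det = build_detector(_tiny_cfg()).eval()
        raws = det(Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32)))
        assert [r.grid_size for r in raws] \
            == [(16, 16), (8, 8), (4, 4), (2, 2)]

    def test_all_eight_ablation_combinations_build_and_run(self):
        x = Tensor(np.random.default_rng(0)
                   .random((1, 3, 64, 64)).astype(np.float32))
        for dsconv, mff, piou in itertools.product([False, True], repeat=3):
            cfg = _tiny_cfg(use_dsconv=dsconv, use_mff=mff,
                            loss="piou" if piou else "ciou")
            det = build_detector(cfg).eval()
            raws = det(x)
            assert len(raws) == (4 if mff else 3)
            for r in raws:
                assert np.all(np.isfinite(r.output.data))

    def test_mff_adds_parameters_and_a_head(self):
        on = build_detector(_tiny_cfg(use_mff=True))
        off = build_detector(_tiny_cfg(use_mff=False))
        assert len(on.heads) == 4 and len(off.heads) == 3
        assert on.num_parameters() > off.num_parameters()
        assert on.head_strides == (4, 8, 16, 32)
        assert off.head_strides == (8, 16, 32)

    def test_baseline_topology_graph(self):
        off = build_detector(_tiny_cfg(use_mff=False))
        assert set(off.graph_nodes()) \
            == {"P2", "P3", "P4", "P5", "F3", "F4", "N4", "N5"}
        on = build_detector(_tiny_cfg(use_mff=True))
        assert {"F2", "T2", "T4", "T5"} <= set(on.graph_nodes())

    def test_indivisible_input_rejected(self):
        with pytest.raises(ValueError):
            DetectorConfig(input_size=(60, 64))
        det = build_detector(_tiny_cfg())
        with pytest.raises(ValueError):
            det(Tensor(np.zeros((1, 3, 48, 48), dtype=np.float32)))


class TestFusionOps:
    def test_upsample_fuse_shape_contract(self, rng):
        mod = UpsampleFuse(4, 6, 5, rng=rng).eval()
        deep = FeatureMap(rng.random((4, 4, 4)).astype(np.float32), stride=16)
        shallow = FeatureMap(rng.random((6, 8, 8)).astype(np.float32), stride=8)
        out = upsample_fuse(deep, shallow, mod)
        assert out.values.shape == (5, 8, 8)
        assert out.stride == 8

    def test_upsample_fuse_stride_mismatch(self, rng):
        mod = UpsampleFuse(4, 6, 5, rng=rng)
        deep = FeatureMap(rng.random((4, 4, 4)).astype(np.float32), stride=32)
        shallow = FeatureMap(rng.random((6, 8, 8)).astype(np.float32), stride=8)
        with pytest.raises(ValueError, match="stride"):
            upsample_fuse(deep, shallow, mod)

    def test_concat_order_is_deep_then_shallow(self):
        deep = Tensor(np.ones((1, 2, 3, 3), dtype=np.float32))
        shallow = Tensor(np.full((1, 3, 6, 6), 2.0, dtype=np.float32))
        fused = UpsampleFuse.fuse(deep, shallow)
        assert fused.shape == (1, 5, 6, 6)
        assert np.all(fused.data[:, :2] == 1.0)
        assert np.all(fused.data[:, 2:] == 2.0)

    def test_downsample_fuse_shape_contract(self, rng):
        mod = DownsampleFuse(4, 6, 7, rng=rng).eval()
        cur = FeatureMap(rng.random((4, 8, 8)).astype(np.float32), stride=8)
        lat = FeatureMap(rng.random((6, 4, 4)).astype(np.float32), stride=16)
        out = downsample_fuse(cur, lat, mod)
        assert out.values.shape == (7, 4, 4)
        assert out.stride == 16
        with pytest.raises(ValueError, match="stride"):
            downsample_fuse(lat, cur, mod)

    def test_additive_fusion_mode(self, rng):
        mod = DownsampleFuse(4, 6, 7, mode="add", rng=rng).eval()
        cur = Tensor(rng.random((1, 4, 8, 8)).astype(np.float32))
        lat = Tensor(rng.random((1, 6, 4, 4)).astype(np.float32))
        assert mod(cur, lat).shape == (1, 7, 4, 4)

    def test_mff_forward_uses_all_pairings(self, rng):
        # removing the bottom-up path changes the head inputs: graph
        # inspection distinguishes the FPN-only baseline from MFF
        on = build_detector(_tiny_cfg(use_mff=True))
        assert hasattr(on, "f2") and hasattr(on, "t2") \
            and hasattr(on, "t4") and hasattr(on, "t5")
        off = build_detector(_tiny_cfg(use_mff=False))
        assert not hasattr(off, "f2")


class TestAssignment:
    def test_large_box_routes_to_coarsest_head(self):
        gts = [BoundingBox(100, 100, 540, 500, 0)]
        out = assign_targets(gts, (4, 8, 16, 32), (640, 640))
        assert len(out[3]["cls"]) > 0
        assert all(len(out[i]["cls"]) == 0 for i in range(3))

    def test_tiny_box_routes_to_stride4(self):
        gts = [BoundingBox(317, 317, 323, 323, 0)]
        out = assign_targets(gts, (4, 8, 16, 32), (640, 640))
        assert len(out[0]["cls"]) > 0

    def test_every_box_assigned_at_least_once(self, rng):
        for _ in range(20):
            gts = []
            for _ in range(int(rng.integers(1, 6))):
                x, y = rng.uniform(0, 50, 2)
                w, h = rng.uniform(2, 12, 2)
                gts.append(BoundingBox(x, y, min(x + w, 63.9),
                                       min(y + h, 63.9), 0))
            out = assign_targets(gts, (4, 8, 16, 32), (64, 64))
            assert sum(len(d["cls"]) for d in out) >= len(gts)

    def test_outside_image_skipped_with_warning(self):
        gts = [BoundingBox(100, 100, 120, 120, 0)]
        with pytest.warns(UserWarning):
            out = assign_targets(gts, (4, 8, 16, 32), (64, 64))
        assert all(len(d["cls"]) == 0 for d in out)


class TestLosses:
    def _pair(self):
        pred = np.array([[2.0, 3.0, 9.0, 8.0]], dtype=np.float32)
        gt = np.array([[1.0, 2.0, 8.0, 9.0]], dtype=np.float32)
        return pred, gt

    def test_tensor_piou_matches_scalar_reference(self):
        pred, gt = self._pair()
        for mode in ("printed", "corner"):
            for form in ("printed", "corrected"):
                cfg = PIoUConfig(penalty_mode=mode, loss_form=form)
                got = float(piou_loss_tensor(Tensor(pred), gt, cfg).data[0])
                want = piou_loss(BoundingBox(*pred[0]), BoundingBox(*gt[0]),
                                 cfg)
                assert got == pytest.approx(want, rel=1e-4)

    def test_tensor_ciou_matches_scalar_reference(self):
        pred, gt = self._pair()
        got = float(ciou_loss_tensor(Tensor(pred), gt).data[0])
        want = ciou_loss(BoundingBox(*pred[0]), BoundingBox(*gt[0]))
        assert got == pytest.approx(want, rel=1e-4)

    def test_zero_gt_gives_finite_background_loss(self):
        cfg = _tiny_cfg()
        det = build_detector(cfg)
        raws = det(Tensor(np.random.default_rng(0)
                          .random((1, 3, 64, 64)).astype(np.float32)))
        loss, parts = compute_loss(raws, [[]], cfg)
        assert np.isfinite(parts["total"])
        assert parts["num_pos"] == 0

    @pytest.mark.parametrize("loss_name", ["piou", "ciou"])
    def test_one_step_decreases_loss(self, loss_name):
        cfg = _tiny_cfg(loss=loss_name, seed=3)
        det = build_detector(cfg)
        x = Tensor(np.random.default_rng(5)
                   .random((2, 3, 64, 64)).astype(np.float32))
        gts = [[BoundingBox(10, 10, 20, 18, 0)],
               [BoundingBox(30, 30, 44, 40, 0)]]
        opt = Adam(det.parameters(), lr=1e-3)
        loss0, parts0 = compute_loss(det(x), gts, cfg)
        opt.zero_grad()
        loss0.backward()
        opt.step()
        det.apply_constraints()
        _, parts1 = compute_loss(det(x), gts, cfg)
        assert parts1["total"] < parts0["total"]


class TestDecode:
    def _raws(self, fill=-10.0):
        arrs = []
        for s in (4, 8, 16, 32):
            g = 64 // s
            arrs.append(RawPrediction(
                stride=s,
                output=Tensor(np.full((1, 5, g, g), fill, dtype=np.float32))))
        return arrs

    def test_all_below_threshold_gives_empty(self):
        assert decode_predictions(self._raws(), score_threshold=0.25) == []

    def test_nms_keeps_one_of_identical_boxes(self):
        def inv_softplus(y):
            return float(np.log(np.expm1(y)))

        raws = self._raws()
        d = raws[0].output.data
        # two adjacent stride-4 cells (centres (18,18) and (22,18))
        # regressing the exact same box (12.75, 12.75, 23.25, 23.25)
        d[0, :4, 4, 4] = 1.0                       # softplus(1)*4 each side
        d[0, 4, 4, 4] = 4.0
        e = float(np.log1p(np.exp(1.0))) * 4.0     # edge distance 5.253
        x1, x2 = 18.0 - e, 18.0 + e
        d[0, :4, 4, 5] = [inv_softplus((22.0 - x1) / 4), 1.0,
                          inv_softplus((x2 - 22.0) / 4), 1.0]
        d[0, 4, 4, 5] = 3.0
        out = decode_predictions(raws, score_threshold=0.25, nms_iou=0.45)
        assert len(out) == 1
        assert out[0].confidence == pytest.approx(1 / (1 + np.exp(-4.0)))

    def test_decoded_boxes_satisfy_invariants(self, rng):
        raws = []
        for s in (4, 8, 16, 32):
            g = 64 // s
            raws.append(RawPrediction(
                stride=s,
                output=Tensor(rng.normal(0, 3, (1, 6, g, g))
                              .astype(np.float32))))
        out = decode_predictions(raws, score_threshold=0.3, nms_iou=0.5,
                                 input_size=(64, 64))
        confs = [b.confidence for b in out]
        assert confs == sorted(confs, reverse=True)
        for b in out:
            assert 0 <= b.x1 < b.x2 <= 64
            assert 0 <= b.y1 < b.y2 <= 64
            assert 0.3 <= b.confidence <= 1.0
            assert b.class_id in (0, 1)

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            decode_predictions(self._raws(), score_threshold=1.5)
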