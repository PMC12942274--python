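"""Miniature encoder, pyramids, detection head/loss, and mask decoder."""

import numpy as np
import pytest

from ldprompt.distill import DistillConfig, select_regions
from ldprompt.geometry import AnchorPoint, Box, EdgeDistribution, decode_edges
from ldprompt.models import (Detector, DetectionHead, ImageEncoder, MaskDecoder,
                             ModelSpec, PyramidNet, build_anchors,
                             decode_boxes_numpy, decode_boxes_tensor,
                             detection_loss, diou_tensor, predict_boxes,
                             soft_bin_targets)
from ldprompt.nn import AdamW, Tensor
from ldprompt.prompt_encoder import PromptBundle


SPEC = ModelSpec()


class TestModelSpec:
    def test_rejects_undersized_teacher(self):
        with pytest.raises(ValueError):
            ModelSpec(student_width=8, teacher_width=16)

    def test_rejects_encoder_embed_mismatch(self):
        with pytest.raises(ValueError):
            ModelSpec(encoder_widths=(16, 32, 48, 32), embed_dim=64)


class TestImageEncoder:
    def test_stride_16_contract(self):
        enc = ImageEncoder(SPEC, np.random.default_rng(0))
        out = enc(Tensor(np.zeros((2, 64, 64))))
        assert out.shape == (2, 64, 4, 4)

    def test_rejects_resolution_not_divisible_by_16(self):
        enc = ImageEncoder(SPEC, np.random.default_rng(1))
        with pytest.raises(ValueError):
            enc(Tensor(np.zeros((1, 60, 60))))

    def test_frozen_backbone_survives_training_step(self):
        enc = ImageEncoder(SPEC, np.random.default_rng(2), frozen=True)
        before = {i: blk.weight.data.copy() for i, blk in enumerate(enc.blocks)}
        opt = AdamW(enc.trainable_parameters(), lr=0.1)
        out = enc(Tensor(np.random.default_rng(3).normal(size=(2, 64, 64))))
        loss = (out * out).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        for i, blk in enumerate(enc.blocks):
            assert np.array_equal(blk.weight.data, before[i])

    def test_fresh_adapters_are_identity(self):
        rng = np.random.default_rng(4)
        enc = ImageEncoder(SPEC, rng, use_adapters=True)
        plain = ImageEncoder(SPEC, np.random.default_rng(99), use_adapters=False)
        plain.load_backbone(enc.backbone_state())
        x = Tensor(np.random.default_rng(5).normal(size=(1, 64, 64)))
        assert np.allclose(enc(x).data, plain(x).data, atol=1e-12)

    def test_backbone_state_round_trip(self):
        enc = ImageEncoder(SPEC, np.random.default_rng(6))
        other = ImageEncoder(SPEC, np.random.default_rng(7))
        other.load_backbone(enc.backbone_state())
        x = Tensor(np.random.default_rng(8).normal(size=(1, 64, 64)))
        assert np.array_equal(
            ImageEncoderForward(enc, x), ImageEncoderForward(other, x))


def ImageEncoderForward(enc, x):
    # compare backbone-only outputs (fresh adapters are identity anyway)
    return enc(x).data


class TestPyramids:
    def test_stride_contract(self):
        net = PyramidNet(8, np.random.default_rng(9))
        p3, p4, p5 = net(Tensor(np.zeros((1, 64, 64))))
        assert p3.shape == (1, 8, 8, 8)
        assert p4.shape == (1, 16, 4, 4)
        assert p5.shape == (1, 32, 2, 2)

    def test_rejects_resolution_not_divisible_by_32(self):
        net = PyramidNet(8, np.random.default_rng(10))
        with pytest.raises(ValueError):
            net(Tensor(np.zeros((1, 48, 48))))

    def test_teacher_capacity_exceeds_four_times_student(self):
        student = Detector(SPEC.student_width, SPEC, np.random.default_rng(11))
        teacher = Detector(SPEC.teacher_width, SPEC, np.random.default_rng(12))
        assert teacher.pyramid.num_parameters() > 4 * student.pyramid.num_parameters()

    def test_deterministic_forward_under_fixed_seed(self):
        a = PyramidNet(8, np.random.default_rng(13))
        b = PyramidNet(8, np.random.default_rng(13))
        x = Tensor(np.random.default_rng(14).normal(size=(1, 64, 64)))
        for pa, pb in zip(a(x), b(x)):
            assert np.array_equal(pa.data, pb.data)


class TestDetectionHead:
    def test_anchor_count_64x64(self):
        anchors, strides = build_anchors(64)
        assert len(anchors) == 64 + 16 + 4 == 84
        assert (strides[:64] == 8).all() and (strides[-4:] == 32).all()

    def test_output_shapes(self):
        det = Detector(8, SPEC, np.random.default_rng(15))
        out = det(Tensor(np.zeros((2, 64, 64))))
        assert out.class_logits.shape == (2, 84, 2)
        assert out.edge_logits.shape == (2, 84, 4, SPEC.bins)
        assert out.objectness.shape == (2, 84)

    def test_anchor_positions_are_cell_centers(self):
        anchors, _ = build_anchors(64)
        assert (anchors[0].cx, anchors[0].cy, anchors[0].stride) == (4.0, 4.0, 8)
        assert (anchors[64].cx, anchors[64].cy, anchors[64].stride) == (8.0, 8.0, 16)

    def test_decoded_boxes_agree_with_geometry_oracle(self):
        det = Detector(8, SPEC, np.random.default_rng(16))
        out = det(Tensor(np.random.default_rng(17).normal(size=(1, 64, 64))))
        decoded = decode_boxes_numpy(out.edge_logits.data[0], out.anchors,
                                     out.strides)
        for k in (0, 20, 70, 83):
            a = out.anchors[k]
            dists = [EdgeDistribution(out.edge_logits.data[0, k, e],
                                      bin_width=float(out.strides[k]))
                     for e in range(4)]
            want = decode_edges(dists, a)
            assert decoded[k] == pytest.approx(
                [want.xmin, want.ymin, want.xmax, want.ymax], abs=1e-9)

    def test_tensor_decode_matches_numpy_decode(self):
        det = Detector(8, SPEC, np.random.default_rng(18))
        out = det(Tensor(np.random.default_rng(19).normal(size=(2, 64, 64))))
        t = decode_boxes_tensor(out.edge_logits, out.anchors, out.strides).data
        for i in range(2):
            n = decode_boxes_numpy(out.edge_logits.data[i], out.anchors,
                                   out.strides)
            assert np.abs(t[i] - n).max() < 1e-9


class TestSoftBinTargets:
    def test_integer_distance_is_one_hot(self):
        w = soft_bin_targets(np.array([3.0]), 8)
        assert w[0, 3] == pytest.approx(1.0)
        assert w.sum() == pytest.approx(1.0)

    def test_fractional_distance_splits_flanking_bins(self):
        w = soft_bin_targets(np.array([2.25]), 8)
        assert w[0, 2] == pytest.approx(0.75)
        assert w[0, 3] == pytest.approx(0.25)

    def test_clipping_at_range_ends(self):
        w = soft_bin_targets(np.array([-1.0, 99.0]), 8)
        assert w[0, 0] == pytest.approx(1.0)
        assert w[1, 7] == pytest.approx(1.0, abs=1e-6)


class TestDetectionLoss:
    def make_saturated_output(self, gt: Box, spec=SPEC):
        """Predictions in the saturated limit: correct objectness and one-hot
        edge bins matching the ground-truth box at anchor 0 (stride 8)."""
        anchors, strides = build_anchors(64)
        k = 0
        a = anchors[k]
        cls = np.full((1, 84, 2), 0.0)
        cls[:, :, 0] = 50.0                   # confident background
        cls[0, k] = [-50.0, 50.0]             # confident foreground at anchor 0
        edges = np.full((1, 84, 4, spec.bins), 0.0)
        dt = (a.cy - gt.ymin) / 8.0
        db = (gt.ymax - a.cy) / 8.0
        dl = (a.cx - gt.xmin) / 8.0
        dr = (gt.xmax - a.cx) / 8.0
        for e, d in enumerate((dt, db, dl, dr)):
            edges[0, k, e, :] = -1e3
            edges[0, k, e, int(round(d))] = 1e3
        from ldprompt.models import DetectionOutput
        return DetectionOutput(anchors=anchors, class_logits=Tensor(cls),
                               edge_logits=Tensor(edges), strides=strides)

    def test_saturated_predictions_give_near_zero_loss(self):
        gt = Box(4 - 16, 4 - 8, 4 + 8, 4 + 16)  # integer bin distances at anchor 0
        gt = Box(max(gt.xmin, -100), gt.ymin, gt.xmax, gt.ymax)
        out = self.make_saturated_output(gt)
        decoded = decode_boxes_numpy(out.edge_logits.data[0], out.anchors,
                                     out.strides)
        assign = select_regions(decoded, [gt], DistillConfig(alpha_pos=0.7))
        assert 0 in assign.omega_main
        loss = detection_loss(out, [gt], assign)
        assert float(loss) < 1e-6

    def test_empty_main_region_leaves_objectness_only(self):
        det = Detector(8, SPEC, np.random.default_rng(20))
        out = det(Tensor(np.random.default_rng(21).normal(size=(1, 64, 64))))
        from ldprompt.distill import RegionAssignment
        assign = RegionAssignment(scores=np.full(84, -1.0),
                                  omega_main=np.empty(0, int),
                                  omega_vlr=np.empty(0, int),
                                  matched_gt=np.full(84, -1, int))
        loss = detection_loss(out, [], assign)
        # objectness-only: cross-entropy of the background class over anchors
        from ldprompt.nn import log_softmax
        lp = log_softmax(out.class_logits[0], axis=-1).data
        assert float(loss) == pytest.approx(-lp[:, 0].mean(), abs=1e-9)

    def test_two_anchor_case_matches_hand_computation(self):
        from ldprompt.distill import RegionAssignment
        from ldprompt.models import DetectionOutput
        anchors, strides = build_anchors(64)
        rng = np.random.default_rng(22)
        cls = rng.normal(size=(1, 84, 2))
        edges = rng.normal(size=(1, 84, 4, SPEC.bins))
        out = DetectionOutput(anchors=anchors, class_logits=Tensor(cls),
                              edge_logits=Tensor(edges), strides=strides)
        gt = [Box(0, 0, 12, 12)]
        assign = RegionAssignment(scores=np.zeros(84),
                                  omega_main=np.array([0, 9]),
                                  omega_vlr=np.array([1]),
                                  matched_gt=np.zeros(84, int))
        got = float(detection_loss(out, gt, assign))

        # hand computation, term by term
        def lsm(z):
            z = z - z.max(axis=-1, keepdims=True)
            return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))

        lp = lsm(cls[0])
        targets = np.zeros(84)
        targets[[0, 9]] = 1
        consider = np.ones(84)
        consider[1] = 0  # VLR anchor excluded
        ce = -(np.stack([1 - targets, targets], 1) * lp).sum(-1)
        cls_term = (ce * consider).sum() / consider.sum()

        box_terms, bin_terms = [], []
        for k in (0, 9):
            a = anchors[k]
            p = np.exp(lsm(edges[0, k]))
            dist = (p * np.arange(SPEC.bins)).sum(-1) * strides[k]
            pred = Box(a.cx - dist[2], a.cy - dist[0], a.cx + dist[3],
                       a.cy + dist[1])
            from ldprompt.geometry import diou
            box_terms.append(1 - diou(pred, gt[0]))
            d = np.array([(a.cy - 0) / 8, (12 - a.cy) / 8,
                          (a.cx - 0) / 8, (12 - a.cx) / 8])
            w = soft_bin_targets(d, SPEC.bins)
            bin_terms.append(-(w * lsm(edges[0, k])).sum(-1).mean())
        want = cls_term + np.mean(box_terms) + np.mean(bin_terms)
        assert got == pytest.approx(want, abs=1e-9)


class TestDiouTensor:
    def test_agrees_with_scalar_diou(self):
        from ldprompt.geometry import diou
        rng = np.random.default_rng(23)
        pred = rng.uniform(0, 30, size=(10, 4))
        pred[:, 2:] += pred[:, :2]
        gt = rng.uniform(0, 30, size=(10, 4))
        gt[:, 2:] += gt[:, :2]
        got = diou_tensor(Tensor(pred), gt).data
        for i in range(10):
            want = diou(Box(*pred[i]), Box(*gt[i]))
            assert got[i] == pytest.approx(want, abs=1e-6)


class TestMaskDecoder:
    def test_output_resolution_equals_input(self):
        dec = MaskDecoder(SPEC, np.random.default_rng(24))
        z = Tensor(np.random.default_rng(25).normal(size=(2, 64, 4, 4)))
        assert dec(z, None).shape == (2, 64, 64)

    def test_deterministic_under_fixed_seed(self):
        a = MaskDecoder(SPEC, np.random.default_rng(26))
        b = MaskDecoder(SPEC, np.random.default_rng(26))
        z = Tensor(np.random.default_rng(27).normal(size=(1, 64, 4, 4)))
        assert np.array_equal(a(z, None).data, b(z, None).data)

    def test_rejects_embedding_dim_mismatch(self):
        dec = MaskDecoder(SPEC, np.random.default_rng(28))
        with pytest.raises(ValueError):
            dec(Tensor(np.zeros((1, 32, 4, 4))), None)

    def test_l0_reduces_to_token_embedding_dot_product(self):
        spec = ModelSpec(decoder_rounds=0)
        dec = MaskDecoder(spec, np.random.default_rng(29))
        z = np.random.default_rng(30).normal(size=(1, 64, 4, 4))
        got = dec(Tensor(z), None).data
        # forward-pass algebra oracle: upsample the embedding through the
        # transposed-conv stack, then dot with the projected initial token
        feat = z.copy()
        for i, up in enumerate(dec.ups):
            w = up.weight.data[:, :, 0, 0]  # 1x1 kernels
            feat = np.einsum("oc,nchw->nohw", w, feat) \
                + up.bias.data[None, :, None, None]
            n, c4, h, w_ = feat.shape
            c = c4 // 4
            feat = feat.reshape(n, c, 2, 2, h, w_).transpose(0, 1, 4, 2, 5, 3) \
                .reshape(n, c, 2 * h, 2 * w_)
            if i < len(dec.ups) - 1:
                feat = np.maximum(feat, 0)
        tok = dec.output_token.data[0] @ dec.token_proj.weight.data \
            + dec.token_proj.bias.data
        want = (feat * tok[None, :, None, None]).sum(axis=1)
        assert np.allclose(got, want, atol=1e-9)

    def test_conditioning_neutral_at_initialization(self):
        # fresh gates are zero-initialized, so decoder output with sparse
        # tokens is bit-identical to the unconditioned configuration
        dec = MaskDecoder(SPEC, np.random.default_rng(31))
        z = Tensor(np.random.default_rng(32).normal(size=(1, 64, 4, 4)))
        base = dec(z, None).data
        sparse = Tensor(np.random.default_rng(33).normal(size=(1, 4, 64)))
        bundle = PromptBundle(dense=None, alpha=None, sparse=sparse,
                              box_tokens=None)
        assert np.array_equal(dec(z, bundle).data, base)

    def test_sparse_tokens_engage_once_gates_open(self):
        dec = MaskDecoder(SPEC, np.random.default_rng(31))
        rng = np.random.default_rng(34)
        for r in dec.rounds:
            r["i2t"].wo.weight.data = rng.normal(size=(64, 64)) * 0.1
        dec.token_gate.weight.data = rng.normal(size=(64, 64)) * 0.1
        z = Tensor(np.random.default_rng(32).normal(size=(1, 64, 4, 4)))
        base = dec(z, None).data
        sparse = Tensor(np.random.default_rng(33).normal(size=(1, 4, 64)))
        bundle = PromptBundle(dense=None, alpha=None, sparse=sparse,
                              box_tokens=None)
        assert not np.array_equal(dec(z, bundle).data, base)


class TestPredictBoxes:
    def test_returns_at_least_one_box_per_image(self):
        det = Detector(8, SPEC, np.random.default_rng(34))
        images = np.random.default_rng(35).normal(size=(3, 64, 64)) * 0.1 + 0.5
        boxes = predict_boxes(det, images)
        assert len(boxes) == 3
        for per_image in boxes:
            assert 1 <= len(per_image) <= 3
            for b in per_image:
                assert 0 <= b.xmin <= b.xmax <= 64
                assert 0 <= b.ymin <= b.ymax <= 64
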