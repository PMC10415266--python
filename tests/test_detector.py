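"""Detector topology, attention gates, decoding and suppression."""

import numpy as np
import pytest

from jellydet import nn
from jellydet.boxes import DetectionBox
from jellydet.detector import (
    CBAM,
    DEFAULT_ANCHORS,
    ModelConfig,
    build_improved_model,
    decode_predictions,
    desk_config,
    nms,
)


@pytest.fixture(scope="module")
def cbam():
    return CBAM(channels=32, reduction=16, kernel=7, rng=np.random.default_rng(0))


class TestChannelAttention:
    def test_weights_in_open_unit_interval(self, cbam, rng):
        x = nn.Tensor(rng.normal(size=(2, 32, 5, 5)))
        w = cbam.channel_attention(x)
        assert w.shape == (2, 32, 1, 1)
        assert (w.data > 0).all() and (w.data < 1).all()

    def test_zero_input_gives_half(self, cbam):
        w = cbam.channel_attention(nn.Tensor(np.zeros((1, 32, 4, 4))))
        assert np.allclose(w.data, 0.5)  # zero-bias MLP, sigmoid(0)

    def test_indivisible_channels_rejected(self):
        from jellydet.detector import ChannelAttention

        with pytest.raises(ValueError):
            ChannelAttention(channels=30, reduction=16)


class TestSpatialAttention:
    def test_map_shape_and_range(self, cbam, rng):
        x = nn.Tensor(rng.normal(size=(1, 32, 6, 7)))
        w = cbam.spatial_attention(x)
        assert w.shape == (1, 1, 6, 7)
        assert (w.data > 0).all() and (w.data < 1).all()

    def test_constant_zero_input_gives_uniform_half(self, cbam):
        # zero mean/max maps through a zero-bias conv -> sigmoid(0) = 0.5
        w = cbam.spatial_attention(nn.Tensor(np.zeros((1, 32, 4, 4))))
        assert np.allclose(w.data, 0.5, atol=1e-6)

    def test_even_kernel_rejected(self):
        from jellydet.detector import SpatialAttention

        with pytest.raises(ValueError):
            SpatialAttention(kernel=6)


class TestCbam:
    def test_shape_preserved(self, cbam, rng):
        x = nn.Tensor(rng.normal(size=(2, 32, 8, 8)))
        assert cbam(x).shape == x.shape

    def test_zero_input_zero_output(self, cbam):
        out = cbam(nn.Tensor(np.zeros((1, 32, 4, 4))))
        assert np.allclose(out.data, 0.0)

    def test_multiplicative_contraction(self, cbam, rng):
        x = nn.Tensor(rng.normal(size=(1, 32, 6, 6)))
        out = cbam(x)
        assert (np.abs(out.data) <= np.abs(x.data) + 1e-12).all()


class TestTopology:
    def test_head_shapes_at_416(self):
        model = build_improved_model(ModelConfig(input_size=416, num_classes=8))
        model.set_training(False)
        heads = model(nn.Tensor(np.zeros((1, 3, 416, 416), np.float32)))
        assert heads[32].shape == (1, 39, 13, 13)
        assert heads[16].shape == (1, 39, 26, 26)

    def test_head_grids_at_608(self):
        model = build_improved_model(ModelConfig(input_size=608))
        model.set_training(False)
        heads = model(nn.Tensor(np.zeros((1, 3, 608, 608), np.float32)))
        assert heads[32].shape[2:] == (19, 19)
        assert heads[16].shape[2:] == (38, 38)

    def test_zero_image_forward_is_finite(self):
        model = build_improved_model(desk_config())
        model.set_training(False)
        heads = model(nn.Tensor(np.zeros((1, 3, 96, 96), np.float32)))
        for head in heads.values():
            assert np.isfinite(head.data).all()

    def test_input_size_not_multiple_of_32_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=100)

    def test_parameter_count_logged_magnitude(self):
        # full-width improved model lands in the single-digit millions
        model = build_improved_model(ModelConfig())
        assert 5_000_000 < model.num_parameters() < 7_000_000


class TestDecode:
    def test_all_zero_raw_cell_decodes_to_anchor_box(self):
        raw = np.zeros((39, 13, 13))
        boxes = decode_predictions(raw, DEFAULT_ANCHORS[32], stride=32, conf_threshold=0.2)
        # sigmoid(0)=0.5 -> center (16,16); exp(0)=1 -> anchor size; conf 0.25
        b = boxes[0]  # first anchor (81,82), cell (0,0)
        assert b.center == (pytest.approx(16.0), pytest.approx(16.0))
        assert (b.width, b.height) == (pytest.approx(81.0), pytest.approx(82.0))
        assert b.confidence == pytest.approx(0.25, abs=1e-9)

    def test_threshold_one_empty(self):
        raw = np.zeros((39, 13, 13))
        assert decode_predictions(raw, DEFAULT_ANCHORS[32], 32, 1.0) == []

    def test_lower_threshold_never_removes_boxes(self, rng):
        raw = rng.normal(size=(39, 6, 6))
        strict = decode_predictions(raw, DEFAULT_ANCHORS[32], 32, 0.4)
        loose = decode_predictions(raw, DEFAULT_ANCHORS[32], 32, 0.1)
        assert len(loose) >= len(strict)

    def test_bad_shape_rejected(self):
        with pytest.raises(ValueError):
            decode_predictions(np.zeros((40, 13, 13)), DEFAULT_ANCHORS[32], 32)

    def test_decode_recovers_encoded_box(self):
        # encode a ground-truth box into raw target form, decode it back
        stride, (aw, ah) = 32, DEFAULT_ANCHORS[32][0]
        gt = DetectionBox(100.0, 60.0, 190.0, 150.0, class_id=3)
        cx, cy = gt.center
        gx, gy = int(cx // stride), int(cy // stride)
        raw = np.zeros((39, 13, 13))
        logit = lambda p: np.log(p / (1 - p))  # noqa: E731
        raw[0, gy, gx] = logit(cx / stride - gx)
        raw[1, gy, gx] = logit(cy / stride - gy)
        raw[2, gy, gx] = np.log(gt.width / aw)
        raw[3, gy, gx] = np.log(gt.height / ah)
        raw[4, gy, gx] = 20.0  # objectness ~ 1
        raw[5 + gt.class_id, gy, gx] = 20.0
        boxes = decode_predictions(raw, DEFAULT_ANCHORS[32], stride, 0.9, 416)
        assert len(boxes) == 1
        b = boxes[0]
        assert b.class_id == gt.class_id
        for attr in ("x_min", "y_min", "x_max", "y_max"):
            assert getattr(b, attr) == pytest.approx(getattr(gt, attr), abs=1e-4)


class TestNms:
    def test_identical_boxes_keep_highest_confidence(self):
        a = DetectionBox(0, 0, 10, 10, 0, confidence=0.9)
        b = DetectionBox(0, 0, 10, 10, 0, confidence=0.7)
        kept = nms([b, a], 0.45)
        assert kept == [a]

    def test_identical_boxes_different_classes_both_survive(self):
        a = DetectionBox(0, 0, 10, 10, 0, confidence=0.9)
        b = DetectionBox(0, 0, 10, 10, 1, confidence=0.7)
        assert len(nms([a, b], 0.45)) == 2

    def test_hand_computed_overlap_suppression(self):
        # IoU((0,0,2,2),(1,0,3,2)) = 2/6 = 1/3 > 0.3 -> second suppressed
        a = DetectionBox(0, 0, 2, 2, 0, confidence=0.9)
        b = DetectionBox(1, 0, 3, 2, 0, confidence=0.8)
        assert nms([a, b], 0.3) == [a]
        # at threshold 0.35 the overlap is tolerated
        assert len(nms([a, b], 0.35)) == 2
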