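"""Training recipe: label smoothing, schedule, mosaic, loss, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jellydet import nn
from jellydet.boxes import DetectionBox
from jellydet.detector import ModelConfig, build_improved_model, desk_config
from jellydet.synthetic import AnnotatedImage, SceneSpec, make_scene
from jellydet.training import (
    TrainConfig,
    ciou,
    cosine_lr,
    mosaic_augment,
    smooth_labels,
    train,
    yolo_loss,
)


class TestSmoothLabels:
    def test_eight_class_values(self):
        target = smooth_labels(2, 8, 0.01)
        # (1-0.01) + 0.01/8 on the true class, 0.01/8 elsewhere
        assert target[2] == pytest.approx(0.99125, abs=1e-12)
        off = np.delete(target, 2)
        assert np.allclose(off, 0.00125, atol=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        k=st.integers(1, 20),
        eps=st.floats(0.0, 0.99),
        data=st.data(),
    )
    def test_output_is_distribution(self, k, eps, data):
        idx = data.draw(st.integers(0, k - 1))
        target = smooth_labels(idx, k, eps)
        assert target.sum() == pytest.approx(1.0, abs=1e-12)
        assert (target >= 0).all()

    def test_zero_eps_is_onehot(self):
        assert np.array_equal(smooth_labels(3, 8, 0.0), np.eye(8)[3])

    def test_invalid_index_rejected(self):
        with pytest.raises(ValueError):
            smooth_labels(8, 8, 0.01)


class TestCosineLr:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 100, 1e-4, 1e-6) == pytest.approx(1e-4)
        assert cosine_lr(100, 100, 1e-4, 1e-6) == pytest.approx(1e-6)
        assert cosine_lr(50, 100, 1e-4, 1e-6) == pytest.approx((1e-4 + 1e-6) / 2)

    def test_monotone_nonincreasing(self):
        values = [cosine_lr(s, 200, 1e-3, 1e-5) for s in range(201)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_zero_total_steps_rejected(self):
        with pytest.raises(ValueError):
            cosine_lr(0, 0, 1e-4, 1e-6)


@pytest.fixture(scope="module")
def four_scenes():
    return [make_scene(SceneSpec.random(s, width=64, height=64)) for s in range(4)]


class TestMosaic:
    def test_wrong_sample_count_rejected(self, four_scenes):
        with pytest.raises(ValueError):
            mosaic_augment(four_scenes[:3], 96)

    def test_output_size_and_boxes_on_canvas(self, four_scenes):
        out = mosaic_augment(four_scenes, 96, seed=5)
        assert out.image.shape == (96, 96, 3)
        for b in out.boxes:
            assert 0 <= b.x_min < b.x_max <= 96
            assert 0 <= b.y_min < b.y_max <= 96

    def test_seed_determinism_and_variation(self, four_scenes):
        a = mosaic_augment(four_scenes, 96, seed=1)
        b = mosaic_augment(four_scenes, 96, seed=1)
        c = mosaic_augment(four_scenes, 96, seed=2)
        assert np.array_equal(a.image, b.image) and a.boxes == b.boxes
        assert not np.array_equal(a.image, c.image)

    def test_never_invents_boxes(self, four_scenes):
        total_in = sum(len(s.boxes) for s in four_scenes)
        for seed in range(5):
            out = mosaic_augment(four_scenes, 96, seed=seed)
            assert len(out.boxes) <= total_in


class TestCiou:
    def test_identical_boxes_score_one(self):
        pred = {
            "cx": nn.Tensor([50.0]),
            "cy": nn.Tensor([40.0]),
            "w": nn.Tensor([20.0]),
            "h": nn.Tensor([10.0]),
        }
        gt = np.array([[50.0, 40.0, 20.0, 10.0]])
        assert float(ciou(pred, gt).data[0]) == pytest.approx(1.0, abs=1e-6)

    def test_matches_hand_computation(self):
        # pred center (10,10) size (4,4); gt center (12,10) size (4,8)
        pred = {
            "cx": nn.Tensor([10.0]),
            "cy": nn.Tensor([10.0]),
            "w": nn.Tensor([4.0]),
            "h": nn.Tensor([4.0]),
        }
        gt = np.array([[12.0, 10.0, 4.0, 8.0]])
        inter = 2.0 * 4.0  # x overlap [10,12], y overlap [8,12]
        union = 16.0 + 32.0 - inter
        iou_v = inter / union
        rho2 = 2.0**2
        c2 = (14.0 - 8.0) ** 2 + (14.0 - 6.0) ** 2  # enclosing box diagonal
        v = (4 / math.pi**2) * (math.atan(4 / 8) - math.atan(4 / 4)) ** 2
        alpha = v / (1 - iou_v + v)
        expected = iou_v - rho2 / c2 - alpha * v
        assert float(ciou(pred, gt).data[0]) == pytest.approx(expected, abs=1e-5)


@pytest.fixture(scope="module")
def cfg():
    return desk_config()


class TestYoloLoss:
    def _perfect_heads(self, cfg, box, strong=12.0):
        """Raw head tensors encoding one box exactly with confident logits."""
        from jellydet.training import _assign_anchors

        k = cfg.num_classes
        heads = {}
        ((stride, a_idx, _),) = _assign_anchors([box], cfg.anchors)
        for s in cfg.anchors:
            g = cfg.input_size // s
            heads[s] = np.full((1, 3 * (5 + k), g, g), -strong, np.float32)
        raw = heads[stride].reshape(1, 3, 5 + k, cfg.input_size // stride, -1)
        cx, cy = box.center
        gx, gy = int(cx // stride), int(cy // stride)
        logit = lambda p: math.log(p / (1 - p))  # noqa: E731
        aw, ah = cfg.anchors[stride][a_idx]
        raw[0, a_idx, 0, gy, gx] = logit(np.clip(cx / stride - gx, 1e-6, 1 - 1e-6))
        raw[0, a_idx, 1, gy, gx] = logit(np.clip(cy / stride - gy, 1e-6, 1 - 1e-6))
        raw[0, a_idx, 2, gy, gx] = math.log(box.width / aw)
        raw[0, a_idx, 3, gy, gx] = math.log(box.height / ah)
        raw[0, a_idx, 4, gy, gx] = strong
        raw[0, a_idx, 5 + box.class_id, gy, gx] = strong
        return {s: nn.Tensor(h) for s, h in heads.items()}

    def test_perfect_prediction_has_tiny_box_loss(self, cfg):
        box = DetectionBox(20.0, 24.0, 52.0, 60.0, class_id=4)
        loss = yolo_loss(self._perfect_heads(cfg, box), [[box]], cfg, smoothing=0.01)
        assert loss.box_loss < 1e-3
        assert loss.total == pytest.approx(
            loss.box_loss + loss.objectness_loss + loss.class_loss, abs=1e-6
        )

    def test_no_targets_strongly_negative_logits_vanishes(self, cfg):
        heads = {
            s: nn.Tensor(
                np.full(
                    (1, 39, cfg.input_size // s, cfg.input_size // s), -20.0, np.float32
                )
            )
            for s in cfg.anchors
        }
        loss = yolo_loss(heads, [[]], cfg)
        assert loss.total < 1e-6

    def test_loss_nonnegative_and_finite(self, cfg, rng):
        heads = {
            s: nn.Tensor(
                rng.normal(size=(2, 39, cfg.input_size // s, cfg.input_size // s))
            )
            for s in cfg.anchors
        }
        boxes = [[DetectionBox(10, 10, 40, 50, 1)], [DetectionBox(30, 5, 80, 60, 6)]]
        loss = yolo_loss(heads, boxes, cfg)
        for part in (loss.box_loss, loss.objectness_loss, loss.class_loss):
            assert part >= 0 and np.isfinite(part)


class TestTrainLoop:
    def test_identical_seeds_identical_histories(self):
        scenes = [
            AnnotatedImage(image=s.image, boxes=s.boxes)
            for s in (make_scene(SceneSpec.random(i, width=96, height=96)) for i in range(6))
        ]
        cfg = TrainConfig(base_lr=1e-3, batch_size=2, total_steps=3, seed=11)
        hist_a = train(build_improved_model(desk_config(0)), scenes, cfg).history
        hist_b = train(build_improved_model(desk_config(0)), scenes, cfg).history
        assert [h["total"] for h in hist_a] == [h["total"] for h in hist_b]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train(build_improved_model(desk_config()), [], TrainConfig(total_steps=1))
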