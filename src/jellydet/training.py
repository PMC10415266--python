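"""Training recipe for the improved detector.

The recipe combines mosaic augmentation (four source images cropped,
zoomed, flipped, color-jittered and stitched into one), label smoothing
with coefficient 0.01, a cosine-annealed learning rate, the composite YOLO
loss (CIoU box term + objectness and class binary cross-entropies), and the
Adam optimizer.  The loop is deliberately desk-scale: it trains the numpy
network on in-memory synthetic datasets deterministically from a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from . import nn
from .boxes import DetectionBox
from .detector import ImprovedTinyYolo, ModelConfig
from .synthetic import AnnotatedImage, DatasetManifest


@dataclass(frozen=True)
class TrainConfig:
    base_lr: float = 1e-4
    min_lr_fraction: float = 0.01  # cosine floor as a fraction of base_lr
    batch_size: int = 16
    total_steps: int = 200
    smoothing: float = 0.01
    mosaic_enabled: bool = True
    mosaic_prob: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.smoothing < 1):
            raise ValueError("smoothing must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def min_lr(self) -> float:
        return self.base_lr * self.min_lr_fraction


@dataclass
class LossComponents:
    box_loss: float
    objectness_loss: float
    class_loss: float
    total: float
    tensor: nn.Tensor | None = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self) if f.name != "tensor"}


# ---------------------------------------------------------------------------
# Unit pieces of the recipe
# ---------------------------------------------------------------------------


def smooth_labels(class_index: int, num_classes: int, eps: float) -> np.ndarray:
    """(1-eps) * onehot + eps/K everywhere."""
    if not (0 <= class_index < num_classes):
        raise ValueError(f"class index {class_index} outside [0,{num_classes})")
    if not (0 <= eps < 1):
        raise ValueError("eps must lie in [0, 1)")
    target = np.full(num_classes, eps / num_classes)
    target[class_index] += 1.0 - eps
    return target


def cosine_lr(step: int, total_steps: int, base_lr: float, min_lr: float) -> float:
    """Cosine annealing from base_lr (step 0) down to min_lr (final step)."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not (0 <= step <= total_steps):
        raise ValueError("step must lie in [0, total_steps]")
    return min_lr + 0.5 * (base_lr - min_lr) * (1.0 + math.cos(math.pi * step / total_steps))


def _hsv_jitter(image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Hue +-10 degrees, saturation and value +-30%."""
    from skimage import color

    hsv = color.rgb2hsv(image)
    hsv[:, :, 0] = (hsv[:, :, 0] + rng.uniform(-10, 10) / 360.0) % 1.0
    hsv[:, :, 1] = np.clip(hsv[:, :, 1] * rng.uniform(0.7, 1.3), 0, 1)
    hsv[:, :, 2] = np.clip(hsv[:, :, 2] * rng.uniform(0.7, 1.3), 0, 1)
    return color.hsv2rgb(hsv)


def _resize(image: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    from skimage.transform import resize

    return resize(image, shape, order=1, anti_aliasing=False)


def mosaic_augment(
    samples: Sequence[AnnotatedImage], out_size: int, seed: int = 0
) -> AnnotatedImage:
    """Stitch four images into one mosaic canvas.

    A split point partitions the canvas into four quadrants (sampled in the
    central 40-60% of each axis); each source is flipped/HSV-jittered,
    zoomed, randomly cropped to its quadrant, and its boxes are transformed,
    clipped and dropped when less than 25% of their area survives.
    """
    if len(samples) != 4:
        raise ValueError("mosaic requires exactly 4 samples")
    rng = np.random.default_rng(seed)
    split_x = int(rng.uniform(0.4, 0.6) * out_size)
    split_y = int(rng.uniform(0.4, 0.6) * out_size)
    quads = [
        (0, 0, split_x, split_y),
        (split_x, 0, out_size - split_x, split_y),
        (0, split_y, split_x, out_size - split_y),
        (split_x, split_y, out_size - split_x, out_size - split_y),
    ]
    canvas = np.zeros((out_size, out_size, 3))
    out_boxes: list[DetectionBox] = []
    for sample, (qx, qy, qw, qh) in zip(samples, quads):
        img = np.asarray(sample.image, dtype=np.float64)
        boxes = list(sample.boxes)
        if rng.random() < 0.5:  # horizontal flip
            img = img[:, ::-1]
            w = img.shape[1]
            boxes = [
                DetectionBox(w - b.x_max, b.y_min, w - b.x_min, b.y_max, b.class_id)
                for b in boxes
            ]
        img = _hsv_jitter(img, rng)
        zoom = rng.uniform(1.0, 1.5)
        sh, sw = int(round(qh * zoom)), int(round(qw * zoom))
        fy, fx = sh / img.shape[0], sw / img.shape[1]
        img = _resize(img, (sh, sw))
        ox = int(rng.integers(0, sw - qw + 1))
        oy = int(rng.integers(0, sh - qh + 1))
        canvas[qy : qy + qh, qx : qx + qw] = img[oy : oy + qh, ox : ox + qw]
        for b in boxes:
            scaled = DetectionBox(
                b.x_min * fx - ox + qx,
                b.y_min * fy - oy + qy,
                b.x_max * fx - ox + qx,
                b.y_max * fy - oy + qy,
                b.class_id,
            )
            area = scaled.area
            clipped = scaled.clip(qx + qw, qy + qh)
            if clipped is None:
                continue
            # also clip the leading edge to the quadrant
            clipped = DetectionBox(
                max(clipped.x_min, qx),
                max(clipped.y_min, qy),
                clipped.x_max,
                clipped.y_max,
                b.class_id,
            ) if clipped.x_max > max(clipped.x_min, qx) and clipped.y_max > max(clipped.y_min, qy) else None
            if clipped is None or clipped.area < 0.25 * area:
                continue
            out_boxes.append(clipped)
    return AnnotatedImage(image=np.clip(canvas, 0, 1), boxes=out_boxes, source_id="mosaic")


# ---------------------------------------------------------------------------
# YOLO loss
# ---------------------------------------------------------------------------


def ciou(pred: dict[str, nn.Tensor], gt: np.ndarray) -> nn.Tensor:
    """Complete IoU between predicted boxes and constant ground-truth boxes.

    ``pred`` holds center-size Tensors ``cx, cy, w, h`` of shape (P,);
    ``gt`` is a (P, 4) array in the same parametrization.  Returns (P,)
    CIoU values: IoU minus the normalized center distance minus the
    aspect-ratio penalty (its weight treated as a constant, as usual).
    """
    gx, gy, gw, gh = (gt[:, i].astype(np.float32) for i in range(4))
    px0, px1 = pred["cx"] - pred["w"] * 0.5, pred["cx"] + pred["w"] * 0.5
    py0, py1 = pred["cy"] - pred["h"] * 0.5, pred["cy"] + pred["h"] * 0.5
    tx0, tx1 = gx - gw / 2, gx + gw / 2
    ty0, ty1 = gy - gh / 2, gy + gh / 2

    def elem_min(a: nn.Tensor, b: np.ndarray) -> nn.Tensor:
        mask = (a.data <= b).astype(np.float32)
        return a * mask + b * (1.0 - mask)

    def elem_max(a: nn.Tensor, b: np.ndarray) -> nn.Tensor:
        mask = (a.data >= b).astype(np.float32)
        return a * mask + b * (1.0 - mask)

    iw = nn.relu(elem_min(px1, tx1) - elem_max(px0, tx0))
    ih = nn.relu(elem_min(py1, ty1) - elem_max(py0, ty0))
    inter = iw * ih
    union = pred["w"] * pred["h"] + gw * gh - inter
    iou_val = inter / (union + 1e-9)

    # normalized distance between centers
    cw = elem_max(px1, tx1) - elem_min(px0, tx0)
    ch = elem_max(py1, ty1) - elem_min(py0, ty0)
    c2 = cw * cw + ch * ch + 1e-9
    rho2 = (pred["cx"] - gx) ** 2 + (pred["cy"] - gy) ** 2

    v = (4.0 / math.pi**2) * (
        nn.atan(nn.Tensor(gw) / nn.Tensor(gh)) - nn.atan(pred["w"] / (pred["h"] + 1e-9))
    ) ** 2
    alpha = v.data / (1.0 - iou_val.data + v.data + 1e-9)  # constant weight
    return iou_val - rho2 / c2 - v * alpha


def _assign_anchors(
    boxes: list[DetectionBox], anchors: dict[int, tuple]
) -> list[tuple[int, int, DetectionBox]]:
    """Ground truth -> (stride, anchor index) by best width-height IoU."""
    flat = [
        (stride, ai, aw, ah)
        for stride, group in sorted(anchors.items())
        for ai, (aw, ah) in enumerate(group)
    ]
    out = []
    for b in boxes:
        best, best_iou = None, -1.0
        for stride, ai, aw, ah in flat:
            iw = min(b.width, aw)
            ih = min(b.height, ah)
            inter = iw * ih
            wh_iou = inter / (b.width * b.height + aw * ah - inter)
            if wh_iou > best_iou:
                best, best_iou = (stride, ai), wh_iou
        out.append((best[0], best[1], b))
    return out


def yolo_loss(
    predictions: dict[int, nn.Tensor],
    targets: Sequence[Sequence[DetectionBox]],
    config: ModelConfig,
    smoothing: float = 0.01,
    ignore_iou: float = 0.5,
) -> LossComponents:
    """Composite detection loss over both heads.

    Box term: 1 - CIoU for anchor-assigned positives.  Objectness: binary
    cross-entropy over every cell (positives 1, negatives 0, cells whose
    decoded box overlaps some ground truth above ``ignore_iou`` without
    being assigned are ignored).  Class term: binary cross-entropy against
    label-smoothed targets at positive cells.
    """
    k = config.num_classes
    n_img = predictions[next(iter(predictions))].shape[0]
    size = config.input_size

    per_stride: dict[int, dict] = {
        s: {"b": [], "a": [], "gy": [], "gx": [], "gt": [], "cls": []}
        for s in predictions
    }
    for b_idx, boxes in enumerate(targets):
        for stride, a_idx, box in _assign_anchors(list(boxes), config.anchors):
            cx, cy = box.center
            gx = min(int(cx / stride), size // stride - 1)
            gy = min(int(cy / stride), size // stride - 1)
            rec = per_stride[stride]
            rec["b"].append(b_idx)
            rec["a"].append(a_idx)
            rec["gy"].append(gy)
            rec["gx"].append(gx)
            rec["gt"].append([cx, cy, box.width, box.height])
            rec["cls"].append(box.class_id)

    box_terms: list[nn.Tensor] = []
    obj_terms: list[nn.Tensor] = []
    cls_terms: list[nn.Tensor] = []
    n_pos_total = 0
    for stride, head in predictions.items():
        gh, gw = head.shape[2], head.shape[3]
        pred = head.reshape(n_img, 3, 5 + k, gh, gw)
        rec = per_stride[stride]
        anchor_wh = np.asarray(config.anchors[stride], dtype=np.float32)

        obj_target = np.zeros((n_img, 3, gh, gw), dtype=np.float32)
        obj_weight = np.ones((n_img, 3, gh, gw), dtype=np.float32)

        # decoded predictions (constants) for the ignore mask
        raw = head.data.reshape(n_img, 3, 5 + k, gh, gw)
        gyy, gxx = np.mgrid[0:gh, 0:gw]
        pcx = (gxx[None, None] + 1.0 / (1.0 + np.exp(-raw[:, :, 0]))) * stride
        pcy = (gyy[None, None] + 1.0 / (1.0 + np.exp(-raw[:, :, 1]))) * stride
        pw = anchor_wh[None, :, 0, None, None] * np.exp(np.clip(raw[:, :, 2], -10, 10))
        ph = anchor_wh[None, :, 1, None, None] * np.exp(np.clip(raw[:, :, 3], -10, 10))
        for b_idx, boxes in enumerate(targets):
            if not boxes:
                continue
            best = np.zeros((3, gh, gw))
            for gtb in boxes:
                ix = np.maximum(
                    0.0,
                    np.minimum(pcx[b_idx] + pw[b_idx] / 2, gtb.x_max)
                    - np.maximum(pcx[b_idx] - pw[b_idx] / 2, gtb.x_min),
                )
                iy = np.maximum(
                    0.0,
                    np.minimum(pcy[b_idx] + ph[b_idx] / 2, gtb.y_max)
                    - np.maximum(pcy[b_idx] - ph[b_idx] / 2, gtb.y_min),
                )
                inter = ix * iy
                union = pw[b_idx] * ph[b_idx] + gtb.area - inter
                best = np.maximum(best, inter / np.maximum(union, 1e-9))
            obj_weight[b_idx][best > ignore_iou] = 0.0

        if rec["b"]:
            bi = np.asarray(rec["b"])
            ai = np.asarray(rec["a"])
            gyi = np.asarray(rec["gy"])
            gxi = np.asarray(rec["gx"])
            gt = np.asarray(rec["gt"], dtype=np.float32)
            obj_target[bi, ai, gyi, gxi] = 1.0
            obj_weight[bi, ai, gyi, gxi] = 1.0
            n_pos = len(rec["b"])
            n_pos_total += n_pos

            tx = pred[bi, ai, 0, gyi, gxi]
            ty = pred[bi, ai, 1, gyi, gxi]
            tw = nn.clip(pred[bi, ai, 2, gyi, gxi], -8.0, 8.0)
            th = nn.clip(pred[bi, ai, 3, gyi, gxi], -8.0, 8.0)
            decoded = {
                "cx": (nn.sigmoid(tx) + gxi.astype(np.float32)) * float(stride),
                "cy": (nn.sigmoid(ty) + gyi.astype(np.float32)) * float(stride),
                "w": nn.exp(tw) * anchor_wh[ai, 0],
                "h": nn.exp(th) * anchor_wh[ai, 1],
            }
            box_terms.append((1.0 - ciou(decoded, gt)).sum())

            cls_logits = pred[bi, ai, 5:, gyi, gxi]  # (P, K)
            cls_target = np.stack(
                [smooth_labels(c, k, smoothing) for c in rec["cls"]]
            ).astype(np.float32)
            cls_terms.append(nn.bce_with_logits(cls_logits, cls_target).sum())

        obj_logits = pred[:, :, 4, :, :]
        bce = nn.bce_with_logits(obj_logits, obj_target) * obj_weight
        obj_terms.append(bce.sum() * (1.0 / obj_weight.size))

    norm = 1.0 / max(n_pos_total, 1)
    box_t = sum(box_terms) * norm if box_terms else nn.Tensor(0.0)
    cls_t = sum(cls_terms) * norm if cls_terms else nn.Tensor(0.0)
    obj_t = sum(obj_terms)
    total = box_t + obj_t + cls_t
    return LossComponents(
        box_loss=float(box_t.data),
        objectness_loss=float(obj_t.data),
        class_loss=float(cls_t.data),
        total=float(total.data),
        tensor=total,
    )


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    model: ImprovedTinyYolo
    history: list[dict]

    def loss_curve(self) -> np.ndarray:
        return np.array([h["total"] for h in self.history])

    def save_history(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.history).to_csv(path, index=False)


def _load_samples(dataset) -> list[AnnotatedImage]:
    if isinstance(dataset, DatasetManifest):
        samples = []
        for entry in dataset.entries("train"):
            samples.append(
                AnnotatedImage(
                    image=dataset.load_image(entry),
                    boxes=dataset.load_boxes(entry),
                    source_id=entry["id"],
                )
            )
        return samples
    return list(dataset)


def _to_input(sample: AnnotatedImage, size: int) -> tuple[np.ndarray, list[DetectionBox]]:
    """Resize an annotated sample to the square network input."""
    h, w = sample.image.shape[:2]
    img = _resize(sample.image, (size, size)) if (h, w) != (size, size) else sample.image
    sx, sy = size / w, size / h
    boxes = [
        DetectionBox(b.x_min * sx, b.y_min * sy, b.x_max * sx, b.y_max * sy, b.class_id)
        for b in sample.boxes
    ]
    return img, boxes


def train(
    model: ImprovedTinyYolo,
    dataset,
    config: TrainConfig = TrainConfig(),
) -> TrainResult:
    """Adam + cosine schedule + (optional) mosaic over an in-memory dataset."""
    samples = _load_samples(dataset)
    if not samples:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(config.seed)
    size = model.config.input_size
    opt = nn.Adam(model.parameters(), lr=config.base_lr)
    model.set_training(True)
    history: list[dict] = []
    for step in range(config.total_steps):
        lr = cosine_lr(step, config.total_steps, config.base_lr, config.min_lr)
        batch_imgs, batch_boxes = [], []
        for _ in range(config.batch_size):
            if config.mosaic_enabled and len(samples) >= 4 and rng.random() < config.mosaic_prob:
                picks = rng.choice(len(samples), size=4, replace=len(samples) < 4)
                mosaic = mosaic_augment(
                    [samples[i] for i in picks], size, seed=int(rng.integers(2**31))
                )
                img, boxes = mosaic.image, mosaic.boxes
            else:
                img, boxes = _to_input(samples[int(rng.integers(len(samples)))], size)
            batch_imgs.append(img.transpose(2, 0, 1))
            batch_boxes.append(boxes)
        x = nn.Tensor(np.stack(batch_imgs).astype(np.float32))
        heads = model(x)
        loss = yolo_loss(heads, batch_boxes, model.config, smoothing=config.smoothing)
        opt.zero_grad()
        loss.tensor.backward()
        opt.step(lr)
        history.append({"step": step, "lr": lr, **loss.as_dict()})
    return TrainResult(model=model, history=history)


def save_checkpoint(model: ImprovedTinyYolo, path) -> None:
    """Write weights (and batch-norm running stats) as a flat npz archive."""
    np.savez(path, **model.state_dict())


def load_checkpoint(model: ImprovedTinyYolo, path) -> ImprovedTinyYolo:
    with np.load(path) as data:
        model.load_state_dict(dict(data))
    return model
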