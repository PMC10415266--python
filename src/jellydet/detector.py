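"""The improved YOLOv4-tiny detector.

Topology: a CSPDarknet-tiny backbone (three cross-stage-partial stages with
half-channel splits and 2x2 max-pools), a 512-channel tail, a 13x13 stride-32
head, and a 128-channel branch that is upsampled 2x, passed through a CBAM
(convolutional block attention module: channel gate then spatial gate), and
concatenated with the 256-channel stage-3 passthrough to feed the 26x26
stride-16 head.  Each head predicts 3 anchors x (5 + K) channels.

The attention block is placed immediately after the upsampling step, which is
where a two-scale tiny network benefits most: the upsampled coarse features
are re-weighted before being mixed with the fine passthrough, sharpening the
response to small and partially occluded targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .boxes import DetectionBox, iou

#: Canonical YOLOv4-tiny anchor set (pixels at 416 input), small to large.
DEFAULT_ANCHORS = {
    16: ((10.0, 14.0), (23.0, 27.0), (37.0, 58.0)),
    32: ((81.0, 82.0), (135.0, 169.0), (344.0, 319.0)),
}


@dataclass(frozen=True)
class ModelConfig:
    input_size: int = 416
    num_classes: int = 8
    anchors: dict = field(default_factory=lambda: dict(DEFAULT_ANCHORS))
    cbam_reduction: int = 16
    cbam_spatial_kernel: int = 7
    width_multiplier: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 32")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.cbam_spatial_kernel % 2 == 0:
            raise ValueError("cbam_spatial_kernel must be odd")

    def width(self, channels: int) -> int:
        """Scaled channel count, kept even for the CSP half-splits."""
        return max(2, int(round(channels * self.width_multiplier / 2)) * 2)


class ConvBNLeaky(nn.Module):
    def __init__(self, cin, cout, k, stride=1, rng=None):
        self.conv = nn.Conv2d(cin, cout, k, stride=stride, bias=False, rng=rng)
        self.bn = nn.BatchNorm2d(cout)

    def __call__(self, x):
        return nn.leaky_relu(self.bn(self.conv(x)), 0.1)


class ChannelAttention(nn.Module):
    """sigmoid(MLP(avgpool) + MLP(maxpool)) with a shared C/r bottleneck."""

    def __init__(self, channels: int, reduction: int, rng=None):
        if channels % reduction != 0:
            raise ValueError(
                f"channel count {channels} not divisible by reduction {reduction}"
            )
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, bias=True, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, bias=True, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        n, c = x.shape[0], x.shape[1]
        avg = x.mean(axis=(2, 3))  # (N, C)
        mx = x.max(axis=(2, 3))
        shared = lambda v: self.fc2(nn.relu(self.fc1(v)))  # noqa: E731
        gate = nn.sigmoid(shared(avg) + shared(mx))
        return gate.reshape(n, c, 1, 1)


class SpatialAttention(nn.Module):
    """sigmoid(conv_kxk([channel-mean, channel-max]))."""

    def __init__(self, kernel: int, rng=None):
        if kernel % 2 == 0:
            raise ValueError("spatial attention kernel must be odd")
        self.conv = nn.Conv2d(2, 1, kernel, bias=True, rng=rng)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        avg = x.mean(axis=1, keepdims=True)
        mx = x.max(axis=1, keepdims=True)
        return nn.sigmoid(self.conv(nn.concat([avg, mx], axis=1)))


class CBAM(nn.Module):
    """Sequential channel-then-spatial multiplicative attention."""

    def __init__(self, channels: int, reduction: int = 16, kernel: int = 7, rng=None):
        self.channel = ChannelAttention(channels, reduction, rng=rng)
        self.spatial = SpatialAttention(kernel, rng=rng)

    def channel_attention(self, x: nn.Tensor) -> nn.Tensor:
        return self.channel(x)

    def spatial_attention(self, x: nn.Tensor) -> nn.Tensor:
        return self.spatial(x)

    def __call__(self, x: nn.Tensor) -> nn.Tensor:
        gated = x * self.channel(x)
        return gated * self.spatial(gated)


class CSPStage(nn.Module):
    """One cross-stage-partial stage of the tiny backbone.

    conv3x3(c) -> split second half -> two 3x3 convs on c/2 -> concat ->
    1x1 conv (the passthrough feature) -> concat with the stage input ->
    2x2 max-pool.  Doubles the channel count.
    """

    def __init__(self, c: int, rng=None):
        self.conv1 = ConvBNLeaky(c, c, 3, rng=rng)
        self.conv2 = ConvBNLeaky(c // 2, c // 2, 3, rng=rng)
        self.conv3 = ConvBNLeaky(c // 2, c // 2, 3, rng=rng)
        self.conv4 = ConvBNLeaky(c, c, 1, rng=rng)
        self.c = c

    def __call__(self, x):
        full = self.conv1(x)
        half = full[:, self.c // 2 :, :, :]
        y1 = self.conv2(half)
        y2 = self.conv3(y1)
        passthrough = self.conv4(nn.concat([y2, y1], axis=1))
        out = nn.maxpool2(nn.concat([full, passthrough], axis=1))
        return out, passthrough


class ImprovedTinyYolo(nn.Module):
    """CSPDarknet-tiny with a CBAM after the upsample, two detection heads."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w = config.width
        k = config.num_classes
        out_ch = 3 * (5 + k)
        self.stem1 = ConvBNLeaky(3, w(32), 3, stride=2, rng=rng)
        self.stem2 = ConvBNLeaky(w(32), w(64), 3, stride=2, rng=rng)
        self.stage1 = CSPStage(w(64), rng=rng)
        self.stage2 = CSPStage(w(128), rng=rng)
        self.stage3 = CSPStage(w(256), rng=rng)
        self.tail = ConvBNLeaky(w(512), w(512), 3, rng=rng)
        self.lateral = ConvBNLeaky(w(512), w(256), 1, rng=rng)
        self.head32_conv = ConvBNLeaky(w(256), w(512), 3, rng=rng)
        self.head32_out = nn.Conv2d(w(512), out_ch, 1, bias=True, rng=rng)
        self.branch = ConvBNLeaky(w(256), w(128), 1, rng=rng)
        self.cbam = CBAM(
            w(128), config.cbam_reduction, config.cbam_spatial_kernel, rng=rng
        )
        self.head16_conv = ConvBNLeaky(w(128) + w(256), w(256), 3, rng=rng)
        self.head16_out = nn.Conv2d(w(256), out_ch, 1, bias=True, rng=rng)

    def __call__(self, x: nn.Tensor) -> dict[int, nn.Tensor]:
        """Input (N,3,S,S) -> {stride: raw head (N, 3*(5+K), S/stride, S/stride)}."""
        x = self.stem2(self.stem1(x))
        x, _ = self.stage1(x)
        x, _ = self.stage2(x)
        x, passthrough = self.stage3(x)
        x = self.lateral(self.tail(x))
        head32 = self.head32_out(self.head32_conv(x))
        up = nn.upsample2(self.branch(x))
        up = self.cbam(up)
        merged = nn.concat([up, passthrough], axis=1)
        head16 = self.head16_out(self.head16_conv(merged))
        return {32: head32, 16: head16}


def build_improved_model(config: ModelConfig = ModelConfig()) -> ImprovedTinyYolo:
    return ImprovedTinyYolo(config)


def desk_config(seed: int = 0) -> ModelConfig:
    """Desk-scale preset for CPU smoke training.

    A quarter-width network at 96 px input with anchors sized for the
    synthetic generator's target statistics (bodies roughly 10-70 px).  The
    full-scale defaults stay at 416 px / width 1.0.
    """
    return ModelConfig(
        input_size=96,
        width_multiplier=0.25,
        anchors={
            16: ((10.0, 14.0), (16.0, 24.0), (24.0, 18.0)),
            32: ((28.0, 36.0), (44.0, 48.0), (64.0, 72.0)),
        },
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Decoding and suppression
# ---------------------------------------------------------------------------


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def decode_predictions(
    raw: np.ndarray,
    anchors,
    stride: int,
    conf_threshold: float = 0.5,
    image_size: int | tuple[int, int] | None = None,
) -> list[DetectionBox]:
    """Raw head output (3*(5+K), H, W) -> confident detection boxes.

    center = (cell + sigmoid(txy)) * stride, size = anchor * exp(twh),
    confidence = sigmoid(objectness) * best sigmoid(class score).  Boxes are
    clipped to ``image_size`` when it is given.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 3 or raw.shape[0] % 3 != 0:
        raise ValueError(f"expected (3*(5+K), H, W) raw head, got {raw.shape}")
    n_anchor = 3
    per = raw.shape[0] // n_anchor
    k = per - 5
    gh, gw = raw.shape[1:]
    if isinstance(image_size, int):
        image_size = (image_size, image_size)
    pred = raw.reshape(n_anchor, per, gh, gw)
    gy, gx = np.mgrid[0:gh, 0:gw]
    boxes: list[DetectionBox] = []
    for a, (aw, ah) in enumerate(anchors):
        cx = (gx + _sigmoid(pred[a, 0])) * stride
        cy = (gy + _sigmoid(pred[a, 1])) * stride
        bw = aw * np.exp(np.clip(pred[a, 2], -10, 10))
        bh = ah * np.exp(np.clip(pred[a, 3], -10, 10))
        obj = _sigmoid(pred[a, 4])
        cls_scores = _sigmoid(pred[a, 5:])
        best_cls = cls_scores.argmax(axis=0)
        conf = obj * cls_scores.max(axis=0)
        keep = conf >= conf_threshold
        for yy, xx in zip(*np.nonzero(keep)):
            box = DetectionBox(
                x_min=cx[yy, xx] - bw[yy, xx] / 2,
                y_min=cy[yy, xx] - bh[yy, xx] / 2,
                x_max=cx[yy, xx] + bw[yy, xx] / 2,
                y_max=cy[yy, xx] + bh[yy, xx] / 2,
                class_id=int(best_cls[yy, xx]),
                confidence=float(conf[yy, xx]),
            )
            if image_size is not None:
                box = box.clip(*image_size)
            if box is not None:
                boxes.append(box)
    return boxes


def nms(boxes: list[DetectionBox], iou_threshold: float = 0.45) -> list[DetectionBox]:
    """Greedy per-class suppression by descending confidence."""
    survivors: list[DetectionBox] = []
    for cls in sorted({b.class_id for b in boxes}):
        cand = sorted(
            (b for b in boxes if b.class_id == cls),
            key=lambda b: -(b.confidence or 0.0),
        )
        kept: list[DetectionBox] = []
        for b in cand:
            if all(iou(b, other) <= iou_threshold for other in kept):
                kept.append(b)
        survivors.extend(kept)
    return survivors


def detect_image(
    model: ImprovedTinyYolo,
    image: np.ndarray,
    conf_threshold: float = 0.5,
    iou_threshold: float = 0.45,
) -> list[DetectionBox]:
    """Run the detector on one H×W×3 float image; boxes in image coordinates."""
    from skimage.transform import resize

    cfg = model.config
    h, w = image.shape[:2]
    size = cfg.input_size
    resized = resize(image, (size, size), order=1, anti_aliasing=False)
    model.set_training(False)
    x = nn.Tensor(resized.transpose(2, 0, 1)[None].astype(np.float32))
    heads = model(x)
    boxes: list[DetectionBox] = []
    for stride, head in heads.items():
        boxes.extend(
            decode_predictions(
                head.data[0], cfg.anchors[stride], stride, conf_threshold, size
            )
        )
    boxes = nms(boxes, iou_threshold)
    sx, sy = w / size, h / size
    out = []
    for b in boxes:
        scaled = DetectionBox(
            b.x_min * sx, b.y_min * sy, b.x_max * sx, b.y_max * sy, b.class_id, b.confidence
        ).clip(w, h)
        if scaled is not None:
            out.append(scaled)
    return out
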