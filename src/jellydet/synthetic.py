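"""Synthetic annotated underwater scenes.

Real underwater jellyfish photographs are not redistributable at the scale a
detector needs, so this module generates the package's study material: clean
scenes containing elliptical, tentacled "jellyfish-like" targets over a water
color gradient, plus a parametric degradation model

    I_c = attenuation_c * J_c * t + A_c * (1 - t)

(the standard haze/veiling-light formation model, followed by optional blur
and sensor noise) whose parameters are known exactly, enabling
inversion/recovery tests of the dehazing code.

The palette is deliberately "underwater": the red channel is strongly
suppressed, which is both what water absorption does to real scenes and the
regime in which the dark-channel prior holds.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .annotations import write_voc_xml, write_yolo_txt, read_yolo_txt
from .boxes import CLASS_NAMES, NUM_CLASSES, DetectionBox

# One body color per class; most have a near-zero minimum channel, as real
# underwater scenes do after red absorption.
CLASS_PALETTE = np.array(
    [
        (0.50, 0.12, 0.45),  # c_purpurea  - purple bell
        (0.75, 0.72, 0.65),  # r_pulmo     - pale barrel
        (0.70, 0.55, 0.10),  # p_camtschatica - egg-yolk yellow
        (0.15, 0.20, 0.60),  # a_okeni     - deep blue siphonophore
        (0.55, 0.70, 0.75),  # a_aurita    - translucent moon jelly
        (0.20, 0.60, 0.55),  # p_punctata  - spotted teal
        (0.60, 0.25, 0.15),  # r_esculentum - reddish-brown
        (0.65, 0.65, 0.20),  # fish        - olive disruptor
    ]
)


@dataclass(frozen=True)
class EllipseTarget:
    """One rendered target: a rotated ellipse plus optional tentacle strokes."""

    center: tuple[float, float]  # (cx, cy) pixels
    axes: tuple[float, float]  # semi-axes (a along x, b along y) pre-rotation
    rotation: float = 0.0  # radians, counter-clockwise
    n_tentacles: int = 0
    tentacle_length: float = 0.0
    class_id: int = 0


@dataclass(frozen=True)
class SceneSpec:
    width: int
    height: int
    targets: tuple[EllipseTarget, ...]
    background_gradient: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.05, 0.35, 0.55),
        (0.02, 0.12, 0.25),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene dimensions must be positive")
        for t in self.targets:
            if not (0 <= t.class_id < NUM_CLASSES):
                raise ValueError(f"class id {t.class_id} outside [0,{NUM_CLASSES})")

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    @staticmethod
    def random(
        seed: int,
        width: int = 160,
        height: int = 120,
        n_targets: int | None = None,
        with_tentacles: bool = True,
    ) -> "SceneSpec":
        """Draw a plausible scene layout from a seeded generator.

        Targets may overlap and may extend partially out of frame so that the
        detector sees occlusion and clipped boxes.
        """
        rng = np.random.default_rng(seed)
        if n_targets is None:
            n_targets = int(rng.integers(1, 5))
        targets = []
        for _ in range(n_targets):
            a = float(rng.uniform(0.05, 0.16) * min(width, height))
            b = a * float(rng.uniform(0.8, 1.6))
            cx = float(rng.uniform(-0.05, 1.05) * width)
            cy = float(rng.uniform(-0.05, 1.05) * height)
            targets.append(
                EllipseTarget(
                    center=(cx, cy),
                    axes=(a, b),
                    rotation=float(rng.uniform(0, np.pi)),
                    n_tentacles=int(rng.integers(2, 6)) if with_tentacles else 0,
                    tentacle_length=float(rng.uniform(0.5, 1.2) * b),
                    class_id=int(rng.integers(0, NUM_CLASSES)),
                )
            )
        return SceneSpec(width=width, height=height, targets=tuple(targets), seed=seed)


@dataclass(frozen=True)
class DegradationSpec:
    """Parameters of the forward degradation model (all in float [0,1] terms)."""

    ambient_light: tuple[float, float, float] = (0.7, 0.8, 0.9)
    transmission: float | np.ndarray = 0.6
    blur_sigma: float = 0.0
    noise_sigma: float = 0.0
    channel_attenuation: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.transmission, dtype=np.float64)
        if t.min() < 0 or t.max() > 1:
            raise ValueError("transmission must lie in [0, 1]")
        a = np.asarray(self.ambient_light, dtype=np.float64)
        if a.min() < 0 or a.max() > 1:
            raise ValueError("ambient light must lie in [0, 1]^3")

    @staticmethod
    def random(seed: int) -> "DegradationSpec":
        """A realistic water column: blue-green veil, red loss, mild blur+noise."""
        rng = np.random.default_rng(seed)
        return DegradationSpec(
            ambient_light=(
                float(rng.uniform(0.45, 0.65)),
                float(rng.uniform(0.65, 0.8)),
                float(rng.uniform(0.75, 0.95)),
            ),
            transmission=float(rng.uniform(0.4, 0.8)),
            blur_sigma=float(rng.uniform(0.3, 1.0)),
            noise_sigma=float(rng.uniform(0.005, 0.02)),
            channel_attenuation=(
                float(rng.uniform(0.55, 0.75)),
                float(rng.uniform(0.8, 0.95)),
                float(rng.uniform(0.9, 1.0)),
            ),
            seed=seed,
        )


@dataclass
class AnnotatedImage:
    image: np.ndarray  # H x W x 3 float [0,1]
    boxes: list[DetectionBox]
    source_id: str = ""


def _target_mask(
    t: EllipseTarget, width: int, height: int, rng: np.random.Generator
) -> np.ndarray:
    """Rasterize ellipse body + tentacles with pixel-center sampling."""
    yy, xx = np.mgrid[0:height, 0:width]
    x = xx + 0.5 - t.center[0]
    y = yy + 0.5 - t.center[1]
    c, s = np.cos(t.rotation), np.sin(t.rotation)
    u = c * x + s * y
    v = -s * x + c * y
    a, b = t.axes
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    if t.n_tentacles > 0 and t.tentacle_length > 0:
        for k in range(t.n_tentacles):
            # tentacles hang from the lower half of the bell
            ang = rng.uniform(np.pi * 0.25, np.pi * 0.75)
            # attachment point on the (unrotated) ellipse boundary
            pu, pv = a * np.cos(ang + np.pi / 2), b * np.sin(ang)
            px = t.center[0] + c * pu - s * pv
            py = t.center[1] + s * pu + c * pv
            length = t.tentacle_length * rng.uniform(0.7, 1.0)
            drift = rng.uniform(-0.4, 0.4)
            n_steps = max(2, int(length * 2))
            ts = np.linspace(0.0, 1.0, n_steps)
            sx = px + drift * length * ts + 1.5 * np.sin(6 * ts + k)
            sy = py + length * ts
            ix = np.floor(sx).astype(int)
            iy = np.floor(sy).astype(int)
            ok = (ix >= 0) & (ix < width) & (iy >= 0) & (iy < height)
            mask[iy[ok], ix[ok]] = True
    return mask


def make_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render a clean scene; one tight, canvas-clipped box per visible target."""
    rng = np.random.default_rng(spec.seed)
    top, bottom = (np.asarray(c, dtype=np.float64) for c in spec.background_gradient)
    ramp = (
        np.linspace(0.0, 1.0, spec.height)[:, None, None]
        if spec.height > 1
        else np.zeros((1, 1, 1))
    )
    image = top[None, None, :] * (1 - ramp) + bottom[None, None, :] * ramp
    image = np.broadcast_to(image, (spec.height, spec.width, 3)).copy()

    boxes: list[DetectionBox] = []
    for t in spec.targets:
        mask = _target_mask(t, spec.width, spec.height, rng)
        if not mask.any():
            continue
        color = CLASS_PALETTE[t.class_id] * rng.uniform(0.85, 1.1)
        alpha = rng.uniform(0.55, 0.8)
        image[mask] = (1 - alpha) * image[mask] + alpha * np.clip(color, 0, 1)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        boxes.append(
            DetectionBox(
                x_min=float(cols[0]),
                y_min=float(rows[0]),
                x_max=float(cols[-1] + 1),
                y_max=float(rows[-1] + 1),
                class_id=t.class_id,
            )
        )
    return AnnotatedImage(
        image=np.clip(image, 0.0, 1.0), boxes=boxes, source_id=f"scene_{spec.seed}"
    )


def degrade_underwater(image: np.ndarray, deg: DegradationSpec) -> np.ndarray:
    """Apply the forward formation model, then blur, then clipped sensor noise.

    Annotations are untouched by design: degradation changes pixels, never
    geometry.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("expected a float image in [0, 1]")
    t = np.asarray(deg.transmission, dtype=np.float64)
    if t.ndim == 2:
        t = t[:, :, None]
    att = np.asarray(deg.channel_attenuation, dtype=np.float64)
    ambient = np.asarray(deg.ambient_light, dtype=np.float64)
    out = att[None, None, :] * img * t + ambient[None, None, :] * (1.0 - t)
    if deg.blur_sigma > 0:
        out = ndimage.gaussian_filter(
            out, sigma=(deg.blur_sigma, deg.blur_sigma, 0), mode="nearest"
        )
    if deg.noise_sigma > 0:
        rng = np.random.default_rng(deg.seed)
        out = out + rng.normal(0.0, deg.noise_sigma, out.shape)
    return np.clip(out, 0.0, 1.0)


def add_dark_speckles(
    image: np.ndarray, density: float = 0.02, seed: int = 0, skip_top: int = 0
) -> np.ndarray:
    """Sprinkle near-black single-pixel detritus over the scene.

    Real underwater frames contain dark suspended particles and shadowed
    texture; their presence is also exactly what the dark-channel prior
    assumes (some near-zero channel minimum in every patch).  ``skip_top``
    rows are left clean, mimicking the bright featureless surface band that
    carries the veiling-light color.
    """
    rng = np.random.default_rng(seed)
    out = np.asarray(image, dtype=np.float64).copy()
    mask = rng.random(out.shape[:2]) < density
    mask[:skip_top] = False
    out[mask] *= rng.uniform(0.0, 0.1, (int(mask.sum()), 1))
    return out


#: Ambient light used by the dehazing test scenes (bright surface water).
HAZE_AMBIENT = (0.7, 0.8, 0.9)


def haze_test_scene(seed: int, width: int = 160, height: int = 120) -> AnnotatedImage:
    """A clean scene designed for haze-inversion experiments.

    The background runs from the veiling-light color at the top (the far
    field of a water column carries the ambient light itself) down to dark
    deep water, with dark detritus speckles throughout -- the two conditions
    under which dark-channel dehazing can recover both the airlight and the
    transmission.
    """
    spec = SceneSpec.random(seed, width=width, height=height, n_targets=2)
    spec = SceneSpec(
        width=width,
        height=height,
        targets=spec.targets,
        background_gradient=(HAZE_AMBIENT, (0.02, 0.05, 0.10)),
        seed=seed,
    )
    # The clean surface band is exactly one dark-channel patch radius thick:
    # enough for an unbiased airlight estimate, thin enough that every other
    # patch still sees detritus.
    scene = make_scene(spec)
    scene.image = add_dark_speckles(
        scene.image, density=0.02, seed=seed, skip_top=15 // 2 + 1
    )
    return scene


#: Train/valid/test proportions of the emulated dataset distribution.
DEFAULT_FRACTIONS = (9594 / 11926, 1067 / 11926, 1265 / 11926)

SPLIT_NAMES = ("train", "valid", "test")


def split_counts(n: int, fractions: Sequence[float] = DEFAULT_FRACTIONS) -> tuple[int, int, int]:
    """floor(n*f) per split; the remainder goes to the training split."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    counts = [int(np.floor(n * f)) for f in fractions]
    counts[0] += n - sum(counts)
    return tuple(counts)


@dataclass
class DatasetManifest:
    root: str
    split_fractions: tuple[float, float, float]
    splits: dict = field(default_factory=dict)  # split name -> list of entry dicts

    def entries(self, split: str) -> list[dict]:
        return self.splits[split]

    def load_image(self, entry: dict) -> np.ndarray:
        arr = np.asarray(Image.open(os.path.join(self.root, entry["image"])))
        return arr.astype(np.float64) / 255.0

    def load_boxes(self, entry: dict) -> list[DetectionBox]:
        return read_yolo_txt(
            os.path.join(self.root, entry["yolo"]), entry["width"], entry["height"]
        )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "root": self.root,
                    "split_fractions": list(self.split_fractions),
                    "class_names": list(CLASS_NAMES),
                    "splits": self.splits,
                },
                fh,
                indent=2,
            )

    @staticmethod
    def load(path: str | os.PathLike) -> "DatasetManifest":
        with open(path) as fh:
            data = json.load(fh)
        return DatasetManifest(
            root=data["root"],
            split_fractions=tuple(data["split_fractions"]),
            splits=data["splits"],
        )


def make_dataset(
    n: int,
    out_dir: str | os.PathLike,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    width: int = 160,
    height: int = 120,
    degrade: bool = True,
) -> DatasetManifest:
    """Generate ``n`` degraded annotated scenes and write a split dataset.

    Each image is written as PNG with both Pascal-VOC XML and YOLO-txt
    annotations; a JSON manifest records the splits.
    """
    if n < 3:
        raise ValueError("need at least 3 images to populate 3 splits")
    counts = split_counts(n, fractions)
    out = Path(out_dir)
    manifest = DatasetManifest(root=str(out), split_fractions=tuple(fractions))
    idx = 0
    for split, count in zip(SPLIT_NAMES, counts):
        (out / split).mkdir(parents=True, exist_ok=True)
        entries = []
        for _ in range(count):
            scene_seed = seed * 1000003 + idx
            scene = make_scene(SceneSpec.random(scene_seed, width=width, height=height))
            img = scene.image
            if degrade:
                img = degrade_underwater(img, DegradationSpec.random(scene_seed))
            stem = f"{split}/img_{idx:05d}"
            Image.fromarray(
                np.clip(np.rint(img * 255), 0, 255).astype(np.uint8)
            ).save(out / f"{stem}.png")
            write_voc_xml(
                out / f"{stem}.xml", scene.boxes, width, height, filename=f"{stem}.png"
            )
            write_yolo_txt(out / f"{stem}.txt", scene.boxes, width, height)
            entries.append(
                {
                    "id": stem,
                    "image": f"{stem}.png",
                    "voc": f"{stem}.xml",
                    "yolo": f"{stem}.txt",
                    "width": width,
                    "height": height,
                    "n_boxes": len(scene.boxes),
                }
            )
            idx += 1
        manifest.splits[split] = entries
    manifest.save(out / "manifest.json")
    return manifest
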