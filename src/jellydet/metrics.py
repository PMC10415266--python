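"""No-reference underwater image quality metrics: Entropy, UCIQE, UIQM, EOG.

Conventions (declared once, used everywhere):

* gray conversion uses the package luminance weights (0.299/0.587/0.114) and
  the 0-255 scale; 2-D inputs are treated as already-gray;
* EOG is the *mean* squared forward difference (horizontal plus vertical),
  normalized by the count of pixels that have both neighbors, so it does not
  grow with resolution;
* UCIQE terms are computed from CIELab with L, a, b divided by 100, per-pixel
  saturation = chroma / lightness (zero-lightness pixels contribute 0);
* UIQM uses 8x8 blocks with partial edge blocks dropped and 0.1/0.1 trim
  fractions, on the 0-255 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .images import gray_u8, to_float

UCIQE_COEFFS = (0.4680, 0.2745, 0.2576)
UIQM_COEFFS = (0.0282, 0.2953, 3.5753)


def _as_gray_float(image: np.ndarray) -> np.ndarray:
    """0-255 float gray image (2-D inputs pass through unscaled)."""
    img = np.asarray(image)
    if img.ndim == 2:
        return img.astype(np.float64)
    return gray_u8(img).astype(np.float64)


def entropy(image: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin gray histogram."""
    gray = np.clip(np.rint(_as_gray_float(image)), 0, 255).astype(np.uint8)
    counts = np.bincount(gray.ravel(), minlength=256)
    p = counts[counts > 0] / gray.size
    return float(-(p * np.log2(p)).sum())


def eog(image: np.ndarray) -> float:
    """Energy of gradient: mean squared forward differences on the gray image."""
    gray = _as_gray_float(image)
    h, w = gray.shape
    if h < 2 or w < 2:
        raise ValueError("EOG needs at least a 2x2 image")
    dx = np.diff(gray, axis=1)
    dy = np.diff(gray, axis=0)
    return float((np.sum(dx**2) + np.sum(dy**2)) / ((h - 1) * (w - 1)))


def uciqe(image: np.ndarray) -> float:
    """Chroma spread + luminance contrast + mean saturation in CIELab."""
    from skimage import color

    img = to_float(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=2)
    lab = color.rgb2lab(img)
    lightness = lab[:, :, 0] / 100.0
    chroma = np.sqrt(lab[:, :, 1] ** 2 + lab[:, :, 2] ** 2) / 100.0
    sigma_c = float(chroma.std())
    con_l = float(np.percentile(lightness, 99) - np.percentile(lightness, 1))
    sat = np.divide(
        chroma, lightness, out=np.zeros_like(chroma), where=lightness > 1e-6
    )
    mu_s = float(sat.mean())
    c1, c2, c3 = UCIQE_COEFFS
    return c1 * sigma_c + c2 * con_l + c3 * mu_s


def _blocks(arr: np.ndarray, size: int) -> np.ndarray:
    """Non-overlapping size x size blocks; partial edge blocks dropped."""
    h, w = arr.shape
    bh, bw = h // size, w // size
    if bh == 0 or bw == 0:
        # fall back to one block covering the whole image
        return arr[None, None, :, :]
    trimmed = arr[: bh * size, : bw * size]
    return trimmed.reshape(bh, size, bw, size).transpose(0, 2, 1, 3).reshape(
        bh, bw, size, size
    ).reshape(bh * bw, 1, size, size)


def _eme(arr: np.ndarray, block: int) -> float:
    """Enhancement measure: mean log contrast ratio over blocks."""
    blocks = _blocks(arr, block)
    maxs = blocks.max(axis=(2, 3)).ravel()
    mins = blocks.min(axis=(2, 3)).ravel()
    ok = (mins > 0) & (maxs > mins)
    if not ok.any():
        return 0.0
    return float(2.0 / blocks.shape[0] * np.sum(np.log(maxs[ok] / mins[ok])))


def _log_amee(arr: np.ndarray, block: int) -> float:
    """Michelson-contrast entropy measure over blocks."""
    blocks = _blocks(arr, block)
    maxs = blocks.max(axis=(2, 3)).ravel()
    mins = blocks.min(axis=(2, 3)).ravel()
    top = maxs - mins
    bottom = maxs + mins
    ok = (bottom > 0) & (top > 0)
    if not ok.any():
        return 0.0
    m = top[ok] / bottom[ok]
    return float(np.sum(m * np.log(m)) / blocks.shape[0])


def _alpha_trimmed_mean(values: np.ndarray, alpha: float) -> float:
    v = np.sort(values.ravel())
    k = int(np.floor(alpha * v.size))
    trimmed = v[k : v.size - k] if v.size - 2 * k > 0 else v
    return float(trimmed.mean())


def uicm(image: np.ndarray, alpha: float = 0.1) -> float:
    """Colorfulness from asymmetric alpha-trimmed statistics of RG / YB planes."""
    img = to_float(image) * 255.0
    rg = img[:, :, 0] - img[:, :, 1]
    yb = (img[:, :, 0] + img[:, :, 1]) / 2.0 - img[:, :, 2]
    mu_rg = _alpha_trimmed_mean(rg, alpha)
    mu_yb = _alpha_trimmed_mean(yb, alpha)
    var_rg = float(((rg - mu_rg) ** 2).mean())
    var_yb = float(((yb - mu_yb) ** 2).mean())
    return -0.0268 * np.sqrt(mu_rg**2 + mu_yb**2) + 0.1586 * np.sqrt(var_rg + var_yb)


def uism(image: np.ndarray, block: int = 8) -> float:
    """Sharpness: luminance-weighted EME of per-channel Sobel magnitudes."""
    img = to_float(image) * 255.0
    weights = (0.299, 0.587, 0.114)
    total = 0.0
    for c, w in enumerate(weights):
        gx = ndimage.sobel(img[:, :, c], axis=1, mode="nearest")
        gy = ndimage.sobel(img[:, :, c], axis=0, mode="nearest")
        total += w * _eme(np.hypot(gx, gy), block)
    return total


def uiconm(image: np.ndarray, block: int = 8) -> float:
    """Contrast: Michelson-entropy block measure of the gray image."""
    gray = _as_gray_float(to_float(image) if np.asarray(image).ndim == 3 else image)
    return _log_amee(gray, block)


def uiqm(image: np.ndarray, block: int = 8) -> float:
    """Weighted colorfulness + sharpness + contrast."""
    img = to_float(image)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=2)
    c1, c2, c3 = UIQM_COEFFS
    return c1 * uicm(img) + c2 * uism(img, block) + c3 * uiconm(img, block)


ALL_METRICS: dict[str, Callable[[np.ndarray], float]] = {
    "entropy": entropy,
    "uciqe": uciqe,
    "uiqm": uiqm,
    "eog": eog,
}


@dataclass
class MetricReport:
    """Per-image metric values per method, plus per-method means."""

    per_image: pd.DataFrame  # columns: method, image, entropy, uciqe, uiqm, eog
    means: pd.DataFrame = field(init=False)  # one row per method

    def __post_init__(self) -> None:
        self.means = (
            self.per_image.groupby("method", sort=False)[list(ALL_METRICS)]
            .mean()
            .reset_index()
        )

    def to_csv(self, path) -> None:
        self.means.to_csv(path, index=False)


def evaluate_methods(
    images: Sequence[np.ndarray],
    methods: Sequence[str],
    registry: dict[str, Callable] | None = None,
) -> MetricReport:
    """Run each enhancement method over the batch and score all four metrics."""
    if registry is None:
        from .enhancement import METHODS as registry  # noqa: N813
    if not images:
        raise ValueError("need at least one image")
    unknown = [m for m in methods if m not in registry]
    if unknown:
        raise KeyError(
            f"unknown methods {unknown}; registered: {sorted(registry)}"
        )
    rows = []
    for name in methods:
        fn = registry[name]
        for i, img in enumerate(images):
            out = fn(to_float(img))
            rows.append(
                {
                    "method": name,
                    "image": i,
                    **{metric: ALL_METRICS[metric](out) for metric in ALL_METRICS},
                }
            )
    return MetricReport(per_image=pd.DataFrame(rows))
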