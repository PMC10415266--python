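"""Image helpers shared across the package.

Images are H×W×3 RGB numpy arrays, either ``uint8`` in [0,255] or float in
[0,1].  All processing happens in float; quantization to 8-bit occurs only
when a file is written.
"""

from __future__ import annotations

import numpy as np

#: Fixed luminance weights used everywhere (gray conversion, fusion weights,
#: metric gray images).
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_float(image: np.ndarray) -> np.ndarray:
    """Convert to float64 in [0,1]; float input is validated and passed through."""
    if image.dtype == np.uint8:
        return image.astype(np.float64) / 255.0
    img = np.asarray(image, dtype=np.float64)
    if img.size and (img.min() < -1e-9 or img.max() > 1 + 1e-9):
        raise ValueError("float image values must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def to_u8(image: np.ndarray) -> np.ndarray:
    if image.dtype == np.uint8:
        return image
    return np.clip(np.rint(np.asarray(image, dtype=np.float64) * 255.0), 0, 255).astype(
        np.uint8
    )


def luminance(image: np.ndarray) -> np.ndarray:
    """0.299 R + 0.587 G + 0.114 B on whatever scale the input uses."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        return img
    return img @ LUMA_WEIGHTS


def gray_u8(image: np.ndarray) -> np.ndarray:
    """8-bit gray image (rounded luminance of the 0-255 scale)."""
    if image.dtype == np.uint8:
        y = luminance(image)
    else:
        y = luminance(to_float(image)) * 255.0
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB for float [0,1] images."""
    from skimage.metrics import peak_signal_noise_ratio

    return float(peak_signal_noise_ratio(to_float(reference), to_float(test), data_range=1.0))
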