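"""Naive loop-based reference implementations used as independent oracles.

Everything here is deliberately written the slow, obvious way (explicit
windows, explicit padding, explicit PR-curve enumeration) and stays
independent of the library's vectorized code paths.
"""

import numpy as np


def gaussian_kernel_1d(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def dense_gaussian_blur(channel: np.ndarray, sigma: float) -> np.ndarray:
    """Direct 2-D convolution with replicate padding, explicit loops."""
    k1 = gaussian_kernel_1d(sigma)
    kernel = np.outer(k1, k1)
    r = len(k1) // 2
    padded = np.pad(channel, r, mode="edge")
    out = np.empty_like(channel, dtype=float)
    for i in range(channel.shape[0]):
        for j in range(channel.shape[1]):
            out[i, j] = (padded[i : i + 2 * r + 1, j : j + 2 * r + 1] * kernel).sum()
    return out


def naive_dark_channel(img: np.ndarray, patch: int) -> np.ndarray:
    h, w = img.shape[:2]
    r = patch // 2
    cmin = img.min(axis=2)
    padded = np.pad(cmin, r, mode="edge")
    out = np.empty((h, w))
    for i in range(h):
        for j in range(w):
            out[i, j] = padded[i : i + patch, j : j + patch].min()
    return out


def naive_guided_filter(guide, src, radius, eps):
    """Per-window least squares with replicate padding, explicit loops."""
    size = 2 * radius + 1

    def naive_box(a):
        padded = np.pad(a, radius, mode="edge")
        out = np.empty_like(a, dtype=float)
        for i in range(a.shape[0]):
            for j in range(a.shape[1]):
                out[i, j] = padded[i : i + size, j : j + size].mean()
        return out

    mg, ms = naive_box(guide), naive_box(src)
    var = naive_box(guide * guide) - mg * mg
    cov = naive_box(guide * src) - mg * ms
    denom = var + eps
    a = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), 0.0)
    b = ms - a * mg
    return naive_box(a) * guide + naive_box(b)


def naive_msrcr(img: np.ndarray, params) -> np.ndarray:
    eps = params.eps
    out = np.empty_like(img)
    for c in range(3):
        retinex = np.zeros(img.shape[:2])
        for sigma, w in zip(params.scales, params.scale_weights):
            blur = dense_gaussian_blur(img[:, :, c], sigma)
            retinex += w * (np.log(img[:, :, c] + eps) - np.log(blur + eps))
        restore = params.beta * (
            np.log(params.alpha * (img[:, :, c] + eps))
            - np.log(img.sum(axis=2) + 3 * eps)
        )
        out[:, :, c] = params.gain * (restore * retinex) + params.offset
    for c in range(3):
        lo, hi = np.percentile(out[:, :, c], params.clip_percentiles)
        if hi - lo < 1e-12:
            out[:, :, c] = 0.5
        else:
            out[:, :, c] = np.clip((out[:, :, c] - lo) / (hi - lo), 0, 1)
    return out


def naive_blocks(arr, size):
    blocks = []
    for i in range(arr.shape[0] // size):
        for j in range(arr.shape[1] // size):
            blocks.append(arr[i * size : (i + 1) * size, j * size : (j + 1) * size])
    return blocks


def naive_eme(arr, size):
    total, n = 0.0, 0
    for blk in naive_blocks(arr, size):
        n += 1
        lo, hi = blk.min(), blk.max()
        if lo > 0 and hi > lo:
            total += np.log(hi / lo)
    return 2.0 / n * total if n else 0.0


def naive_log_amee(arr, size):
    total, n = 0.0, 0
    for blk in naive_blocks(arr, size):
        n += 1
        lo, hi = blk.min(), blk.max()
        top, bottom = hi - lo, hi + lo
        if bottom > 0 and top > 0:
            m = top / bottom
            total += m * np.log(m)
    return total / n if n else 0.0


def brute_force_envelope_area(flags, n_gt):
    """Enumerate the PR curve and sum rectangles under the monotone envelope."""
    points = [(0.0, None)]
    tp = fp = 0
    for f in flags:
        tp, fp = tp + int(f), fp + int(not f)
        points.append((tp / n_gt, tp / (tp + fp)))
    area = 0.0
    recalls = [p[0] for p in points]
    for i in range(1, len(points)):
        r_prev, r_cur = recalls[i - 1], recalls[i]
        if r_cur == r_prev:
            continue
        best = max(p for r, p in points[1:] if r >= r_cur)
        area += (r_cur - r_prev) * best
    return area
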