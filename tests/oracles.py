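"""Independent brute-force reference implementations used only by tests.

These deliberately avoid scipy.ndimage: the Sobel oracle is an explicit
per-pixel 3x3 window loop, the Gaussian oracle builds its own kernel and
convolves rows/columns with numpy.convolve.  Border handling matches the
implementations' reflective mode (numpy pad mode 'symmetric', i.e. edge
pixels duplicated).
"""

from __future__ import annotations

import numpy as np


def sobel_mgm_oracle(patch: np.ndarray, squared: bool = False) -> float:
    """Mean gradient magnitude via explicit per-pixel Sobel windows."""
    patch = np.asarray(patch, dtype=np.float64)
    p = np.pad(patch, 1, mode="symmetric")
    rows, cols = patch.shape
    total = 0.0
    for i in range(rows):
        for j in range(cols):
            w = p[i : i + 3, j : j + 3]
            gx = (w[0, 2] + 2 * w[1, 2] + w[2, 2]) - (w[0, 0] + 2 * w[1, 0] + w[2, 0])
            gy = (w[2, 0] + 2 * w[2, 1] + w[2, 2]) - (w[0, 0] + 2 * w[0, 1] + w[0, 2])
            m2 = gx * gx + gy * gy
            total += m2 if squared else np.sqrt(m2)
    return total / (rows * cols)


def gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """Normalised sampled-Gaussian kernel, radius = int(truncate*sigma+0.5)."""
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-0.5 * (x / sigma) ** 2)
    return k / k.sum()


def gaussian_blur_oracle(img: np.ndarray, sigma: float) -> np.ndarray:
    """Separable Gaussian blur with symmetric (edge-duplicating) borders."""
    img = np.asarray(img, dtype=np.float64)
    k = gaussian_kernel(sigma)
    r = (len(k) - 1) // 2
    out = np.empty_like(img)
    padded = np.pad(img, ((0, 0), (r, r)), mode="symmetric")
    for i in range(img.shape[0]):
        out[i] = np.convolve(padded[i], k[::-1], mode="valid")
    padded = np.pad(out, ((r, r), (0, 0)), mode="symmetric")
    for j in range(img.shape[1]):
        out[:, j] = np.convolve(padded[:, j], k[::-1], mode="valid")
    return out


def mlr_oracle(patch: np.ndarray, sigma: float = 4.0, scale: float = 1.0) -> float:
    """Mean local ratio from the independent Gaussian blur, per pixel."""
    patch = np.asarray(patch, dtype=np.float64) * scale
    blurred = gaussian_blur_oracle(patch, sigma)
    rows, cols = patch.shape
    total = 0.0
    for i in range(rows):
        for j in range(cols):
            a = (blurred[i, j] + 1.0) / (patch[i, j] + 1.0)
            total += max(a, 1.0 / a)
    return total / (rows * cols)


def td_targets_oracle(rewards, next_q_max, done, gamma) -> np.ndarray:
    """Per-transition python loop for Bellman targets."""
    out = []
    for r, q, d in zip(rewards, next_q_max, done):
        out.append(float(r) if d else float(r) + gamma * float(q))
    return np.array(out)
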