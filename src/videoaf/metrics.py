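"""Scalar contrast-based focus metrics on small grayscale patches.

Two classical sharpness scores are provided, both computed on a 32x32
observation window by default:

* mean gradient magnitude (MGM): the average Sobel gradient magnitude,
  ``(1/n) * sum_p sqrt(Ix(p)^2 + Iy(p)^2)``.  Zero on constant patches,
  scale-equivariant (``mgm(a*I) = a*mgm(I)``), shift-invariant.
* mean local ratio (MLR): the average of
  ``max((G(I)+1)/(I+1), (I+1)/(G(I)+1))`` where ``G`` is a Gaussian blur
  with scale ``sigma_mlr`` (default 4).  Always >= 1, with equality exactly
  when blurring leaves the patch unchanged (constant patches).

The "+1" offsets fix the ratio's dynamic range, so the intensity scale at
which they are applied matters; ``MetricConfig.intensity_scale`` controls it
(default 1.0, i.e. offsets applied to [0, 1] floats; set 255.0 to reproduce
8-bit-count behaviour).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

__all__ = ["MetricConfig", "mgm", "mlr", "locate_patch", "extract_patch", "PATCH_SIZE"]

PATCH_SIZE = 32


@dataclasses.dataclass(frozen=True)
class MetricConfig:
    sigma_mlr: float = 4.0
    intensity_scale: float = 1.0

    def __post_init__(self):
        if self.sigma_mlr <= 0:
            raise ValueError("sigma_mlr must be > 0")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be > 0")


DEFAULT_CONFIG = MetricConfig()


def _as_patch(patch: np.ndarray) -> np.ndarray:
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ValueError("patch must be a 2-d grayscale array")
    if not np.isfinite(patch).all():
        raise ValueError("patch contains non-finite values")
    return patch


def mgm(patch: np.ndarray, squared: bool = False) -> float:
    """Mean gradient magnitude of ``patch``.

    Gradients are the x and y responses of the standard 3x3 Sobel filter
    with reflective borders.  With ``squared=True`` the square root is
    omitted and the mean squared gradient magnitude is returned instead.
    """
    patch = _as_patch(patch)
    gx = ndimage.sobel(patch, axis=1, mode="reflect")
    gy = ndimage.sobel(patch, axis=0, mode="reflect")
    mag2 = gx * gx + gy * gy
    if squared:
        return float(mag2.mean())
    return float(np.sqrt(mag2).mean())


def mlr(patch: np.ndarray, config: MetricConfig = DEFAULT_CONFIG) -> float:
    """Mean local ratio of ``patch`` against its Gaussian-blurred copy."""
    patch = _as_patch(patch)
    if (patch < 0).any():
        raise ValueError("mlr requires non-negative pixel values")
    scaled = patch * config.intensity_scale
    blurred = ndimage.gaussian_filter(scaled, config.sigma_mlr, mode="reflect")
    a = (blurred + 1.0) / (scaled + 1.0)
    ratio = np.maximum(a, 1.0 / a)
    return float(ratio.mean())


def locate_patch(
    frame: np.ndarray,
    patch_size: int = PATCH_SIZE,
    threshold: float = 0.05,
    origin: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Top-left corner of the observation window on ``frame``.

    The window is centred on the content area: pixels above ``threshold``
    form a mask, and if that mask is a genuine sub-region (covers < 90% of
    the frame) the centroid of its largest connected component is used.
    Otherwise — full-content frames with no circular vignette — the window
    falls back to the geometric frame centre.  ``origin`` is a manual
    override that bypasses detection (clamped into bounds).
    """
    frame = np.asarray(frame, dtype=np.float64)
    rows, cols = frame.shape
    if rows < patch_size or cols < patch_size:
        raise ValueError(f"frame {frame.shape} smaller than patch {patch_size}")

    def _clamp(r: float, c: float) -> tuple[int, int]:
        r0 = int(round(r - patch_size / 2))
        c0 = int(round(c - patch_size / 2))
        r0 = min(max(r0, 0), rows - patch_size)
        c0 = min(max(c0, 0), cols - patch_size)
        return r0, c0

    if origin is not None:
        r0 = min(max(int(origin[0]), 0), rows - patch_size)
        c0 = min(max(int(origin[1]), 0), cols - patch_size)
        return r0, c0

    mask = frame > threshold
    coverage = mask.mean()
    if 0 < coverage < 0.9:
        labels, n = ndimage.label(mask)
        if n > 0:
            sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
            largest = int(np.argmax(sizes)) + 1
            cy, cx = ndimage.center_of_mass(mask, labels, largest)
            return _clamp(cy, cx)
    return _clamp(rows / 2, cols / 2)


def extract_patch(
    frame: np.ndarray,
    origin: tuple[int, int] | None = None,
    patch_size: int = PATCH_SIZE,
) -> np.ndarray:
    """Cut the ``patch_size`` square window out of ``frame``.

    When ``origin`` is None the window is placed by :func:`locate_patch`.
    """
    if origin is None:
        origin = locate_patch(frame, patch_size)
    r0, c0 = origin
    return np.asarray(frame, dtype=np.float64)[
        r0 : r0 + patch_size, c0 : c0 + patch_size
    ]


METRICS = {"mgm": lambda p, cfg: mgm(p), "mlr": mlr}


def metric_fn(name: str, config: MetricConfig = DEFAULT_CONFIG):
    """Return ``patch -> score`` for a named metric ('mgm' or 'mlr')."""
    if name == "mgm":
        return lambda patch: mgm(patch)
    if name == "mlr":
        return lambda patch: mlr(patch, config)
    raise ValueError(f"unknown focus metric {name!r}")
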