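"""In-focus scene sources for building simulated focal-time scans.

A scene source emits a deterministic sequence of sharp grayscale frames in
[0, 1].  Three kinds are provided:

* :class:`SyntheticScene` — procedurally textured frames with camera motion
  emulated by sweeping a crop window over a larger static texture.
* :class:`StillImageWalk` — a single user image swept by a smooth random-walk
  crop, turning one photograph into plausible video.
* :class:`VideoWalk` — a directory (or list) of video frames, each cropped by
  the same smooth random walk.

All randomness flows from explicit integer seeds; no global RNG state is
touched.  Emitting the same frame index twice yields bitwise-identical
arrays.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

__all__ = [
    "CropWalk",
    "SceneSource",
    "SyntheticScene",
    "SyntheticSceneSpec",
    "StillImageWalk",
    "VideoWalk",
    "load_grayscale",
    "make_synthetic_source",
    "TEXTURES",
]

TEXTURES = ("filtered-noise", "blobs", "grid-plus-noise")


def load_grayscale(path: str | Path) -> np.ndarray:
    """Read an image file as a float grayscale frame in [0, 1].

    Colour inputs are reduced by an unweighted channel mean; integer bit
    depths are normalised by their dtype maximum, floats are assumed to be
    already scaled.
    """
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=-1)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.float64) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(np.float64)
    return np.clip(arr, 0.0, 1.0)


class CropWalk:
    """Smooth random walk of a crop rectangle inside a larger frame.

    Motion is integrated Gaussian velocity noise: each step the velocity
    receives a N(0, (smoothness/2)^2) kick per axis, is clipped so its
    magnitude never exceeds ``smoothness`` (the per-step displacement bound,
    in pixels), and the position reflects off the valid-rectangle bounds.
    ``smoothness=0`` degenerates to a static crop.

    Positions are continuous; :meth:`origin` rounds to integer pixel offsets
    for extraction.
    """

    def __init__(
        self,
        frame_shape: tuple[int, int],
        crop_size: tuple[int, int],
        smoothness: float = 1.0,
        seed: int = 0,
    ):
        frame_shape = (int(frame_shape[0]), int(frame_shape[1]))
        crop_size = (int(crop_size[0]), int(crop_size[1]))
        if crop_size[0] > frame_shape[0] or crop_size[1] > frame_shape[1]:
            raise ValueError(
                f"crop {crop_size} does not fit inside frame {frame_shape}"
            )
        if smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        self.frame_shape = frame_shape
        self.crop_size = crop_size
        self.smoothness = float(smoothness)
        self.seed = int(seed)
        self._hi = (
            float(frame_shape[0] - crop_size[0]),
            float(frame_shape[1] - crop_size[1]),
        )
        self._rng = np.random.default_rng(self.seed)
        hi = np.asarray(self._hi)
        self._positions = [hi * self._rng.random(2)]
        self._velocity = np.zeros(2)

    def _extend_to(self, t: int) -> None:
        while len(self._positions) <= t:
            kick = self._rng.normal(0.0, self.smoothness / 2.0, size=2)
            v = self._velocity + kick
            speed = float(np.hypot(*v))
            if speed > self.smoothness and speed > 0:
                v *= self.smoothness / speed
            pos = self._positions[-1] + v
            # reflect at each axis bound, flipping that velocity component
            for ax in range(2):
                hi = self._hi[ax]
                if hi == 0.0:
                    pos[ax] = 0.0
                    v[ax] = 0.0
                    continue
                while pos[ax] < 0.0 or pos[ax] > hi:
                    if pos[ax] < 0.0:
                        pos[ax] = -pos[ax]
                        v[ax] = -v[ax]
                    else:
                        pos[ax] = 2.0 * hi - pos[ax]
                        v[ax] = -v[ax]
            self._velocity = v
            self._positions.append(pos)

    def position(self, t: int) -> np.ndarray:
        """Continuous top-left corner (row, col) at step ``t``."""
        if t < 0:
            raise IndexError("t must be >= 0")
        self._extend_to(t)
        return self._positions[t].copy()

    def origin(self, t: int) -> tuple[int, int]:
        """Integer top-left corner used for pixel extraction."""
        r, c = np.rint(self.position(t))
        return int(r), int(c)


class SceneSource:
    """Base class: a deterministic sequence of sharp frames in [0, 1]."""

    kind: str = "abstract"

    def __init__(self, frame_shape: tuple[int, int], length: int):
        if length < 1:
            raise ValueError("length must be >= 1")
        if frame_shape[0] < 1 or frame_shape[1] < 1:
            raise ValueError("frame_shape must be positive")
        self.frame_shape = (int(frame_shape[0]), int(frame_shape[1]))
        self.length = int(length)

    def _render(self, t: int) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def frame_at(self, t: int) -> np.ndarray:
        if not 0 <= t < self.length:
            raise IndexError(f"frame index {t} outside [0, {self.length})")
        frame = self._render(int(t))
        assert frame.shape == self.frame_shape
        return frame

    def __len__(self) -> int:
        return self.length


@dataclasses.dataclass(frozen=True)
class SyntheticSceneSpec:
    """Parameters of a procedurally generated textured scene.

    ``texture`` selects the family; ``contrast`` in (0, 1] scales the frame
    standard deviation (target std = 0.15 * contrast around a 0.5 mean, so
    even full contrast rarely clips).
    """

    texture: str = "filtered-noise"
    contrast: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.texture not in TEXTURES:
            raise ValueError(f"texture must be one of {TEXTURES}")
        if not 0.0 < self.contrast <= 1.0:
            raise ValueError("contrast must lie in (0, 1]")


def _texture_field(spec: SyntheticSceneSpec, shape: tuple[int, int]) -> np.ndarray:
    """Zero-mean, unit-std textured field of the requested family."""
    rng = np.random.default_rng(spec.seed)
    rows, cols = shape
    if spec.texture == "filtered-noise":
        field = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5, mode="wrap")
    elif spec.texture == "blobs":
        field = np.zeros(shape)
        yy, xx = np.mgrid[0:rows, 0:cols]
        n_blobs = max(6, rows * cols // 256)
        cy = rng.uniform(0, rows, n_blobs)
        cx = rng.uniform(0, cols, n_blobs)
        radius = rng.uniform(2.0, 6.0, n_blobs)
        amp = rng.uniform(-1.0, 1.0, n_blobs)
        for y0, x0, r0, a0 in zip(cy, cx, radius, amp):
            field += a0 * np.exp(-((yy - y0) ** 2 + (xx - x0) ** 2) / (2 * r0**2))
    else:  # grid-plus-noise
        yy, xx = np.mgrid[0:rows, 0:cols]
        period = rng.uniform(6.0, 12.0)
        phase = rng.uniform(0, 2 * np.pi, 2)
        grid = np.sin(2 * np.pi * yy / period + phase[0]) * np.sin(
            2 * np.pi * xx / period + phase[1]
        )
        field = grid + 0.35 * ndimage.gaussian_filter(
            rng.standard_normal(shape), 1.0, mode="wrap"
        )
    field -= field.mean()
    std = field.std()
    if std > 0:
        field /= std
    return field


class SyntheticScene(SceneSource):
    """Procedural textured scene with crop-walk camera motion.

    A static texture twice the frame size is generated once; frames are crop
    windows stepped across it by a :class:`CropWalk`, emulating the camera
    drift a handheld operator produces.  Frames have mean ~0.5 and standard
    deviation ~0.15*contrast.
    """

    kind = "synthetic"

    def __init__(
        self,
        spec: SyntheticSceneSpec,
        frame_shape: tuple[int, int] = (64, 64),
        length: int = 200,
        smoothness: float = 1.0,
    ):
        super().__init__(frame_shape, length)
        self.spec = spec
        big = (frame_shape[0] * 2, frame_shape[1] * 2)
        field = _texture_field(spec, big)
        self._texture = np.clip(0.5 + 0.15 * spec.contrast * field, 0.0, 1.0)
        self.walk = CropWalk(big, frame_shape, smoothness, seed=spec.seed + 1)

    def _render(self, t: int) -> np.ndarray:
        r, c = self.walk.origin(t)
        h, w = self.frame_shape
        return self._texture[r : r + h, c : c + w].copy()


class StillImageWalk(SceneSource):
    """A single still image swept by a smooth random-walk crop window."""

    kind = "still_image_walk"

    def __init__(
        self,
        image: np.ndarray | str | Path,
        crop_size: tuple[int, int] = (64, 64),
        length: int = 200,
        smoothness: float = 1.0,
        seed: int = 0,
    ):
        if not isinstance(image, np.ndarray):
            image = load_grayscale(image)
        image = np.asarray(image, dtype=np.float64)
        if image.ndim == 3:
            image = image.mean(axis=-1)
        if not np.isfinite(image).all():
            raise ValueError("image contains non-finite values")
        image = np.clip(image, 0.0, 1.0)
        super().__init__(crop_size, length)
        self.image = image
        self.walk = CropWalk(image.shape, crop_size, smoothness, seed=seed)

    def _render(self, t: int) -> np.ndarray:
        r, c = self.walk.origin(t)
        h, w = self.frame_shape
        return self.image[r : r + h, c : c + w].copy()


class VideoWalk(SceneSource):
    """Video frames (a directory of numbered images, or explicit paths or
    arrays), each cropped by the smooth random walk."""

    kind = "video_walk"

    def __init__(
        self,
        frames: str | Path | Sequence,
        crop_size: tuple[int, int] = (64, 64),
        length: int | None = None,
        smoothness: float = 1.0,
        seed: int = 0,
    ):
        if isinstance(frames, (str, Path)):
            paths = sorted(
                p
                for p in Path(frames).iterdir()
                if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg"}
            )
            if not paths:
                raise ValueError(f"no image frames found under {frames}")
            frames = paths
        self._frames = list(frames)
        if length is None:
            length = len(self._frames)
        if length > len(self._frames):
            raise ValueError("length exceeds available frames")
        first = self._load(0)
        super().__init__(crop_size, length)
        self.walk = CropWalk(first.shape, crop_size, smoothness, seed=seed)
        self._cache: dict[int, np.ndarray] = {0: first}

    def _load(self, t: int) -> np.ndarray:
        item = self._frames[t]
        if isinstance(item, np.ndarray):
            arr = np.asarray(item, dtype=np.float64)
            if arr.ndim == 3:
                arr = arr.mean(axis=-1)
            return np.clip(arr, 0.0, 1.0)
        return load_grayscale(item)

    def _render(self, t: int) -> np.ndarray:
        if t not in self._cache:
            self._cache[t] = self._load(t)
        full = self._cache[t]
        r, c = self.walk.origin(t)
        h, w = self.frame_shape
        return full[r : r + h, c : c + w].copy()


def make_synthetic_source(
    spec: SyntheticSceneSpec,
    frame_shape: tuple[int, int] = (64, 64),
    length: int = 200,
    smoothness: float = 1.0,
) -> SyntheticScene:
    """Build a deterministic synthetic scene source from ``spec``."""
    return SyntheticScene(spec, frame_shape, length, smoothness)
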