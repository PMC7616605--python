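"""Dynamic focal-time-scan simulation.

A *focal stack* is one scene imaged at several focal powers; a *focal-time
scan* is a time series of focal stacks — a dynamic scene renderable at any
focal power f in [0, 1] at every time step.  Defocus is approximated by a
Gaussian blur with

    sigma = sigma0 * |f* - f|,

where f* is the (dynamic) optimal focal power and the blur gain sigma0 is
drawn uniformly in [2, 8] pixels per scan.  f* follows a reflected Gaussian
random walk, giving slow focal drift for a stepping policy to track.

:class:`FocusEnv` wraps a scan as a step environment with the discrete
action set {-h, 0, +h} on the focal power and reward ``r = -|f* - f|``.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .metrics import extract_patch, locate_patch, mgm
from .scenes import SceneSource

__all__ = [
    "SIGMA_EPS",
    "DEFAULT_H",
    "FocalTimeScan",
    "FocalStack",
    "EnvStep",
    "FocusEnv",
    "mosaic_to_grayscale",
    "stack_ground_truth",
    "read_focal_stack",
    "write_scan",
    "read_scan",
]

#: blur below this sigma (pixels) is rendered as the sharp frame — the
#: Gaussian kernel is numerically degenerate under it
SIGMA_EPS = 0.3

#: default focal-power step size h
DEFAULT_H = 0.05

SIGMA0_RANGE = (2.0, 8.0)


def _reflect01(x: float) -> float:
    """Fold a scalar into [0, 1] by reflection at both bounds."""
    x = x % 2.0
    return 2.0 - x if x > 1.0 else x


class FocalTimeScan:
    """A scene source plus defocus model and optimal-focal-power walk.

    Parameters
    ----------
    source
        Sharp-frame provider.
    seed
        Single seed for the scan; draws sigma0, the f* start and the f*
        walk increments.
    fstar_walk_std
        Per-step standard deviation of the reflected Gaussian f* walk
        (default 0.01 — slow relative to the h = 0.05 action step, so
        tracking is feasible).  0 freezes f*.
    sigma0
        Blur gain override in pixels per unit focal error; by default drawn
        uniformly from [2, 8] per scan.
    fstar0
        Optional fixed initial optimal focal power (default: uniform draw).
    """

    def __init__(
        self,
        source: SceneSource,
        seed: int = 0,
        fstar_walk_std: float = 0.01,
        sigma0: float | None = None,
        fstar0: float | None = None,
    ):
        if fstar_walk_std < 0:
            raise ValueError("fstar_walk_std must be >= 0")
        self.source = source
        self.seed = int(seed)
        self.fstar_walk_std = float(fstar_walk_std)
        self.length = source.length
        rng = np.random.default_rng(self.seed)
        drawn = rng.uniform(*SIGMA0_RANGE)
        self.sigma0 = float(sigma0) if sigma0 is not None else float(drawn)
        start = rng.uniform() if fstar0 is None else float(fstar0)
        if not 0.0 <= start <= 1.0:
            raise ValueError("fstar0 must lie in [0, 1]")
        self._fstar = [start]
        self._rng = rng

    def fstar(self, t: int) -> float:
        """Optimal focal power at frame ``t`` (reflected random walk)."""
        if t < 0:
            raise IndexError("t must be >= 0")
        while len(self._fstar) <= t:
            step = self._rng.normal(0.0, self.fstar_walk_std) if self.fstar_walk_std else 0.0
            self._fstar.append(_reflect01(self._fstar[-1] + step))
        return self._fstar[t]

    def frame_at(self, t: int) -> np.ndarray:
        return self.source.frame_at(t)

    def sigma_at(self, t: int, f: float) -> float:
        return self.sigma0 * abs(self.fstar(t) - f)

    def render(self, t: int, f: float) -> np.ndarray:
        """Observed frame at time ``t`` and focal power ``f``.

        At ``f == f*`` (sigma below :data:`SIGMA_EPS`) the sharp frame is
        returned unchanged; otherwise a reflective-border Gaussian blur of
        sigma = sigma0*|f*-f| pixels is applied.
        """
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"focal power {f} outside [0, 1]")
        frame = self.frame_at(t)
        sigma = self.sigma_at(t, f)
        if sigma < SIGMA_EPS:
            return frame
        return ndimage.gaussian_filter(frame, sigma, mode="reflect")

    def render_patch(
        self, t: int, f: float, origin: tuple[int, int] | None = None
    ) -> np.ndarray:
        """The 32x32 observation window of :meth:`render`."""
        return extract_patch(self.render(t, f), origin)


@dataclasses.dataclass
class EnvStep:
    """One environment transition: observation, reward and diagnostics."""

    observation: np.ndarray
    reward: float
    done: bool
    info: dict


class FocusEnv:
    """Step interface over a focal-time scan.

    The action chosen from observation t adjusts f (clamped to [0, 1]) and
    the next observation is rendered at the new f at frame t+1 — one step of
    actuation latency, no lens settling.  Reward is ``-|f* - f|`` computed
    from the post-action f and the new f*, hence always in [-1, 0] and zero
    only at perfect focus.
    """

    def __init__(
        self,
        scan: FocalTimeScan,
        h: float = DEFAULT_H,
        patch: bool = True,
        patch_origin: tuple[int, int] | None = None,
        seed: int | None = None,
    ):
        self.scan = scan
        self.h = float(h)
        self.patch = patch
        self.patch_origin = patch_origin
        self._rng = np.random.default_rng(self.scan.seed + 1 if seed is None else seed)
        self.t: int = 0
        self.f: float = 0.0
        self._started = False

    @property
    def actions(self) -> tuple[float, float, float]:
        return (-self.h, 0.0, +self.h)

    def _observe(self) -> np.ndarray:
        frame = self.scan.render(self.t, self.f)
        if self.patch:
            origin = self.patch_origin
            if origin is None:
                origin = locate_patch(frame)
            return extract_patch(frame, origin)
        return frame

    def reset(self, f0: float | None = None) -> EnvStep:
        """Start an episode; initial f is uniform in [0, 1] unless given."""
        self.t = 0
        self.f = float(self._rng.uniform()) if f0 is None else float(f0)
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")
        self._started = True
        reward = -abs(self.scan.fstar(0) - self.f)
        return EnvStep(
            self._observe(),
            reward,
            self.scan.length <= 1,
            {"t": 0, "f": self.f, "fstar": self.scan.fstar(0),
             "sigma": self.scan.sigma_at(0, self.f)},
        )

    def step(self, action: float) -> EnvStep:
        """Apply a focal increment from {-h, 0, +h} and advance one frame."""
        if not self._started:
            raise RuntimeError("call reset() before step()")
        if not any(np.isclose(action, a) for a in self.actions):
            raise ValueError(f"action {action} not in {self.actions}")
        self.f = float(np.clip(self.f + action, 0.0, 1.0))
        self.t += 1
        fstar = self.scan.fstar(self.t)
        reward = -abs(fstar - self.f)
        done = self.t >= self.scan.length - 1
        return EnvStep(
            self._observe(),
            reward,
            done,
            {"t": self.t, "f": self.f, "fstar": fstar,
             "sigma": self.scan.sigma_at(self.t, self.f)},
        )


def mosaic_to_grayscale(raw: np.ndarray, block: int = 4) -> np.ndarray:
    """Grayscale reconstruction of a snapshot-mosaic frame.

    Each ``block x block`` tile of the sensor samples one full spectral set,
    so its mean is the panchromatic value of that super-pixel: a (1088,
    2048) mosaic becomes a (272, 512) grayscale frame.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 2:
        raise ValueError("mosaic frame must be 2-d")
    rows, cols = raw.shape
    if rows % block or cols % block:
        raise ValueError(f"mosaic dimensions {raw.shape} not multiples of {block}")
    return raw.reshape(rows // block, block, cols // block, block).mean(axis=(1, 3))


class FocalStack:
    """One scene pose imaged at multiple focal powers."""

    def __init__(self, images: dict[float, np.ndarray], pose_id: int = 0):
        if not images:
            raise ValueError("focal stack is empty")
        shapes = {np.asarray(im).shape for im in images.values()}
        if len(shapes) != 1:
            raise ValueError("all images in a stack must share dimensions")
        for p in images:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"focal power {p} outside [0, 1]")
        self.images = {float(p): np.asarray(im, dtype=np.float64) for p, im in images.items()}
        self.pose_id = int(pose_id)

    @property
    def powers(self) -> list[float]:
        return sorted(self.images)


def stack_ground_truth(
    stack: FocalStack, patch_origin: tuple[int, int] | None = None
) -> float:
    """Optimal focal power of a stack by global search of MGM.

    Evaluates mean gradient magnitude on the observation patch of every
    image and returns the focal power maximising it; exact ties go to the
    lowest power.
    """
    best_power, best_score = None, -np.inf
    for power in stack.powers:
        patch = extract_patch(stack.images[power], patch_origin)
        score = mgm(patch)
        if score > best_score:
            best_power, best_score = power, score
    return best_power


def read_focal_stack(directory: str | Path, pose_id: int = 0) -> FocalStack:
    """Load a stack from ``directory/stack.csv`` (columns filename,
    focal_power) plus the image files it names."""
    directory = Path(directory)
    table = pd.read_csv(directory / "stack.csv")
    from .scenes import load_grayscale

    images = {
        float(row.focal_power): load_grayscale(directory / row.filename)
        for row in table.itertuples()
    }
    return FocalStack(images, pose_id)


def write_scan(
    scan: FocalTimeScan,
    directory: str | Path,
    powers: np.ndarray | None = None,
    h: float = DEFAULT_H,
) -> Path:
    """Materialise a scan as ``scan.yaml`` + per-frame focal stacks.

    Frames are written as 8-bit PNGs named ``frames/t{t:04d}_f{power:.3f}.png``
    on the given focal-power grid (default 0, h, ..., 1).
    """
    directory = Path(directory)
    (directory / "frames").mkdir(parents=True, exist_ok=True)
    if powers is None:
        powers = np.round(np.arange(0.0, 1.0 + h / 2, h), 6)
    meta = {
        "seed": scan.seed,
        "sigma0": scan.sigma0,
        "h": float(h),
        "fstar_walk_std": scan.fstar_walk_std,
        "length": scan.length,
        "powers": [float(p) for p in powers],
        "fstar": [float(scan.fstar(t)) for t in range(scan.length)],
    }
    with open(directory / "scan.yaml", "w") as fh:
        yaml.safe_dump(meta, fh)
    for t in range(scan.length):
        for p in powers:
            img = np.clip(scan.render(t, float(p)), 0.0, 1.0)
            iio.imwrite(
                directory / "frames" / f"t{t:04d}_f{p:.3f}.png",
                np.round(img * 255).astype(np.uint8),
            )
    return directory


class MaterialisedScan:
    """Scan reloaded from disk; renders by nearest focal power on the grid."""

    def __init__(self, directory: str | Path):
        directory = Path(directory)
        with open(directory / "scan.yaml") as fh:
            meta = yaml.safe_load(fh)
        self.seed = meta["seed"]
        self.sigma0 = meta["sigma0"]
        self.fstar_walk_std = meta["fstar_walk_std"]
        self.length = meta["length"]
        self.powers = np.asarray(meta["powers"], dtype=float)
        self._fstar = [float(v) for v in meta["fstar"]]
        self._dir = directory
        self._cache: dict[tuple[int, float], np.ndarray] = {}

    def fstar(self, t: int) -> float:
        return self._fstar[t]

    def sigma_at(self, t: int, f: float) -> float:
        return self.sigma0 * abs(self.fstar(t) - f)

    def render(self, t: int, f: float) -> np.ndarray:
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"focal power {f} outside [0, 1]")
        if not 0 <= t < self.length:
            raise IndexError(f"frame index {t} outside [0, {self.length})")
        p = float(self.powers[np.argmin(np.abs(self.powers - f))])
        key = (t, p)
        if key not in self._cache:
            path = self._dir / "frames" / f"t{t:04d}_f{p:.3f}.png"
            self._cache[key] = np.asarray(iio.imread(path), dtype=np.float64) / 255.0
        return self._cache[key].copy()

    def render_patch(self, t, f, origin=None):
        return extract_patch(self.render(t, f), origin)

    def frame_at(self, t: int) -> np.ndarray:
        return self.render(t, self.fstar(t))


def read_scan(directory: str | Path) -> MaterialisedScan:
    return MaterialisedScan(directory)
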