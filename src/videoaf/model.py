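"""Statsmodels-style modelling surface for the learned autofocus policies.

:class:`AutofocusDQN` is the model object: it is constructed from the scan
conditions (scene sources, defocus parameters, episode length) plus the
training configuration, and ``fit(seed)`` runs deep Q-learning, returning
an :class:`AutofocusDQNResults` that carries the fitted weights, the
training log, ``summary()``, held-out evaluation, plotting and
checkpointing.

A light train/validation domain split is built in: training scans come from
procedural texture families, held-out scans from a disjoint family swept as
still-image walks, so evaluation never sees a training texture.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import dqn
from .dqn import DQNConfig, TrainResult, desk_scale
from .evaluation import EvalResult, compare_policies, evaluate
from .policies import FixedPolicy, HillClimberPolicy, save_checkpoint
from .scenes import StillImageWalk, SyntheticScene, SyntheticSceneSpec, _texture_field
from .simulate import FocalTimeScan, FocusEnv

__all__ = [
    "AutofocusDQN",
    "AutofocusDQNResults",
    "ScanConditions",
    "make_scan",
    "make_scan_set",
]


class ScanConditions:
    """The simulated study conditions a scan set is drawn from.

    Defaults: 64x64 synthetic textured frames with 1 px/frame crop-walk
    drift, 200-frame episodes (one 10 s clip at 20 fps), blur gain sigma0
    uniform in [2, 8], optimal-focal-power walk std 0.01 per frame.
    """

    def __init__(
        self,
        textures: tuple[str, ...] = ("filtered-noise", "blobs"),
        frame_shape: tuple[int, int] = (64, 64),
        episode_len: int = 200,
        smoothness: float = 1.0,
        fstar_walk_std: float = 0.01,
        sigma0: float | None = None,
        fstar0: float | None = None,
        contrast_range: tuple[float, float] = (0.6, 1.0),
    ):
        self.textures = tuple(textures)
        self.frame_shape = frame_shape
        self.episode_len = int(episode_len)
        self.smoothness = float(smoothness)
        self.fstar_walk_std = float(fstar_walk_std)
        self.sigma0 = sigma0
        self.fstar0 = fstar0
        self.contrast_range = contrast_range

    def scan(self, seed: int) -> FocalTimeScan:
        rng = np.random.default_rng(seed)
        texture = self.textures[int(rng.integers(len(self.textures)))]
        contrast = float(rng.uniform(*self.contrast_range))
        spec = SyntheticSceneSpec(texture=texture, contrast=contrast, seed=int(seed))
        source = SyntheticScene(
            spec, self.frame_shape, self.episode_len, self.smoothness
        )
        return FocalTimeScan(
            source,
            seed=int(seed),
            fstar_walk_std=self.fstar_walk_std,
            sigma0=self.sigma0,
            fstar0=self.fstar0,
        )

    def env_factory(self, h: float = 0.05):
        def factory(episode: int, seed: int) -> FocusEnv:  # noqa: ARG001
            return FocusEnv(self.scan(seed), h=h)

        return factory


def make_scan(seed: int, **kwargs) -> FocalTimeScan:
    """One synthetic focal-time scan under the default study conditions."""
    return ScanConditions(**kwargs).scan(seed)


def make_scan_set(
    n: int, seed_offset: int = 0, conditions: ScanConditions | None = None
) -> list[FocalTimeScan]:
    conditions = conditions or ScanConditions()
    return [conditions.scan(seed_offset + i) for i in range(n)]


class StillWalkConditions:
    """Held-out validation conditions: smooth-random-walk crops over still
    images of a texture family disjoint from training, mirroring the
    train/validate domain split (train on video-like synthetic scans,
    validate on still-image walks)."""

    def __init__(
        self,
        texture: str = "grid-plus-noise",
        image_shape: tuple[int, int] = (128, 128),
        crop_size: tuple[int, int] = (64, 64),
        episode_len: int = 200,
        smoothness: float = 1.0,
        fstar_walk_std: float = 0.01,
        sigma0: float | None = None,
        contrast_range: tuple[float, float] = (0.6, 1.0),
    ):
        self.texture = texture
        self.image_shape = image_shape
        self.crop_size = crop_size
        self.episode_len = int(episode_len)
        self.smoothness = float(smoothness)
        self.fstar_walk_std = float(fstar_walk_std)
        self.sigma0 = sigma0
        self.contrast_range = contrast_range

    def scan(self, seed: int) -> FocalTimeScan:
        rng = np.random.default_rng(seed)
        contrast = float(rng.uniform(*self.contrast_range))
        spec = SyntheticSceneSpec(self.texture, contrast, int(seed))
        field = _texture_field(spec, self.image_shape)
        image = np.clip(0.5 + 0.15 * contrast * field, 0.0, 1.0)
        source = StillImageWalk(
            image, self.crop_size, self.episode_len, self.smoothness, seed=int(seed)
        )
        return FocalTimeScan(
            source,
            seed=int(seed),
            fstar_walk_std=self.fstar_walk_std,
            sigma0=self.sigma0,
        )


HELD_OUT_CONDITIONS = StillWalkConditions()


class AutofocusDQN:
    """Deep-Q autofocus model over simulated focal-time scans.

    Parameters
    ----------
    conditions
        :class:`ScanConditions` generating the training environments.
    kind
        ``"learned_mlp"`` (scalar focus-metric state) or ``"learned_cnn"``
        (end-to-end patch encoder).
    metric
        Focus metric for the scalar-state variant ('mgm' or 'mlr').
    config
        :class:`~videoaf.dqn.DQNConfig`; desk-scale preset by default.
    """

    def __init__(
        self,
        conditions: ScanConditions | None = None,
        kind: str = "learned_mlp",
        metric: str = "mgm",
        config: DQNConfig | None = None,
    ):
        self.conditions = conditions or ScanConditions()
        self.kind = kind
        self.metric = metric
        self.config = config or desk_scale()

    def fit(self, seed: int = 0) -> "AutofocusDQNResults":
        """Run DQN training and return the fitted results object."""
        result = dqn.train(
            self.conditions.env_factory(self.config.h),
            kind=self.kind,
            metric=self.metric,
            config=self.config,
            seed=seed,
        )
        return AutofocusDQNResults(self, result, seed)


class AutofocusDQNResults:
    """Fitted autofocus policy: weights, training log and diagnostics."""

    def __init__(self, model: AutofocusDQN, result: TrainResult, seed: int):
        self.model = model
        self._result = result
        self.seed = seed
        self.log: pd.DataFrame = result.log

    @property
    def params(self) -> dict[str, np.ndarray]:
        """Fitted Q-network weights (and encoder weights for the CNN)."""
        out = {f"q.{k}": v for k, v in self._result.network.state_dict().items()}
        if self._result.encoder is not None:
            out.update(
                {f"enc.{k}": v for k, v in self._result.encoder.state_dict().items()}
            )
        return out

    def policy(self, epsilon: float = 0.0, seed: int | None = None):
        """Greedy (or epsilon-greedy) policy using the fitted weights."""
        return self._result.make_policy(epsilon=epsilon, seed=seed)

    def evaluate(
        self,
        scans: list[FocalTimeScan] | None = None,
        n_scans: int = 20,
        seed: int = 10_000,
        baselines: bool = True,
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Score the fitted policy (and baselines) on held-out scans.

        Held-out scans use the disjoint texture family unless provided
        explicitly.  Returns the (table, pvalues) pair of
        :func:`videoaf.evaluation.compare_policies`.
        """
        if scans is None:
            scans = [HELD_OUT_CONDITIONS.scan(seed + i) for i in range(n_scans)]
        name = f"{self.model.metric}+learned" if self._result.metric else "cnn+learned"
        policies = {name: self.policy()}
        if baselines:
            policies["fixed"] = FixedPolicy(0.5)
            policies[f"{self.model.metric}+hill-climber"] = HillClimberPolicy(
                self.model.metric, h=self.model.config.h
            )
        seeds = [seed + i for i in range(len(scans))]
        return compare_policies(policies, scans, seeds)

    def evaluate_one(self, scan: FocalTimeScan, seed: int = 0, **kwargs) -> EvalResult:
        return evaluate(self.policy(), scan, seed=seed, **kwargs)

    def save(self, path: str | Path) -> Path:
        return save_checkpoint(
            path,
            kind=self._result.kind,
            network=self._result.network,
            encoder=self._result.encoder,
            metric=self._result.metric,
            h=self.model.config.h,
            n_history=self.model.config.n_history,
            normalise=self.model.config.normalise_metric,
            extra={"seed": self.seed},
        )

    def summary(self) -> str:
        """Plain-text fit summary: recipe, schedule and learning curve."""
        log = self.log
        cfg = self.model.config
        lines = [
            "Autofocus DQN results",
            "=" * 44,
            f"policy kind:        {self._result.kind}",
            f"focus metric:       {self._result.metric or 'learned (CNN encoder)'}",
            f"experiences:        {int(log['steps'].iloc[-1]) if len(log) else 0}",
            f"episodes:           {len(log)}",
            f"gamma / lr / beta:  {cfg.gamma} / {cfg.lr} / {cfg.ema_beta}",
            f"epsilon:            {cfg.eps_start} -> {cfg.eps_end} over {cfg.eps_horizon}",
        ]
        if len(log) >= 10:
            k = max(1, len(log) // 10)
            first = log["mean_reward"].iloc[:k].mean()
            last = log["mean_reward"].iloc[-k:].mean()
            lines += [
                f"mean reward (first tenth): {first:.4f}",
                f"mean reward (last tenth):  {last:.4f}",
            ]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Mean episode reward over training (matplotlib axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.log["steps"], self.log["mean_reward"])
        ax.set_xlabel("experiences")
        ax.set_ylabel("mean episode reward")
        return ax
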