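"""Autofocus policies behind one stepwise interface.

Every policy implements ``reset(seed)`` then, once per frame,
``observe(observation, f) -> next focal power``; the emitted focal power is
always in [0, 1] and differs from the current one by an element of
{-h, 0, +h}.

Policies
--------
* :class:`FixedPolicy` — never moves; the clinical status quo baseline.
* :class:`HillClimberPolicy` — modified hill climbing on a scalar focus
  metric: keep stepping in the previous direction while the metric improves
  and the focal power is interior, otherwise reverse.  Unlike a textbook
  hill climber it never stops, which is what a continuously drifting focal
  target requires.
* :class:`LearnedScalarPolicy` — greedy (or epsilon-greedy) action selection
  from a Q-network over the history of the N most recent (metric, focal
  power) pairs.
* :class:`CNNPolicy` — end-to-end variant: a small convolutional encoder
  turns each 32x32 patch into 8 logits, and the Q-network consumes the N
  most recent (encoding, focal power) pairs.  Only the newest patch is
  encoded per step; previous encodings are cached.
* :class:`OraclePolicy` — sets f to the true optimum; upper performance
  bound for evaluation.
"""

from __future__ import annotations

import json
from collections import deque
from pathlib import Path

import numpy as np

from . import nn
from .metrics import PATCH_SIZE, MetricConfig, metric_fn
from .simulate import DEFAULT_H, FocalTimeScan

__all__ = [
    "Policy",
    "FixedPolicy",
    "HillClimberPolicy",
    "LearnedScalarPolicy",
    "CNNPolicy",
    "OraclePolicy",
    "AgentState",
    "select_action",
    "encode_patch",
    "save_checkpoint",
    "load_policy",
    "HISTORY_LEN",
]

#: number of recent (metric, focal power) pairs in the agent state
HISTORY_LEN = 8

CHECKPOINT_VERSION = 1


def _clamp01(f: float) -> float:
    return float(min(max(f, 0.0), 1.0))


def select_action(
    q_values: np.ndarray,
    epsilon: float = 0.0,
    rng: np.random.Generator | None = None,
) -> int:
    """Epsilon-greedy action index over (−h, 0, +h) Q-values.

    Greedy ties break to the lowest action index so behaviour is
    deterministic.  ``rng`` is required whenever ``epsilon > 0``.
    """
    q_values = np.asarray(q_values, dtype=float)
    if q_values.shape != (3,):
        raise ValueError(f"expected 3 action values, got shape {q_values.shape}")
    if not np.isfinite(q_values).all():
        raise ValueError("non-finite Q-values")
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if epsilon > 0.0:
        if rng is None:
            raise ValueError("epsilon > 0 requires an rng")
        if rng.random() < epsilon:
            return int(rng.integers(3))
    return int(np.argmax(q_values))


class AgentState:
    """Ring buffer of the N most recent (feature, focal power) pairs.

    ``feature`` is a scalar metric value or a latent encoding vector.  The
    state vector is ordered newest-first; histories shorter than N are
    padded by repeating the earliest observed pair, so the input dimension
    is fixed from the first step.
    """

    def __init__(self, n: int = HISTORY_LEN, feature_dim: int = 1):
        self.n = int(n)
        self.feature_dim = int(feature_dim)
        self._items: deque = deque(maxlen=self.n)

    def reset(self) -> None:
        self._items.clear()

    def push(self, feature, f: float) -> None:
        feature = np.atleast_1d(np.asarray(feature, dtype=float))
        if feature.shape != (self.feature_dim,):
            raise ValueError(
                f"feature shape {feature.shape} != ({self.feature_dim},)"
            )
        self._items.append((feature, float(f)))

    def __len__(self) -> int:
        return len(self._items)

    @property
    def dim(self) -> int:
        return self.n * (self.feature_dim + 1)

    def vector(self, transform=None) -> np.ndarray:
        """Newest-first [feat_t, f_t, feat_{t-1}, f_{t-1}, ...] with
        earliest-pair padding.  ``transform`` (optional) maps each feature
        before assembly, e.g. a running metric normaliser."""
        if not self._items:
            raise RuntimeError("empty agent state")
        items = list(self._items)
        padded = [items[0]] * (self.n - len(items)) + items
        parts: list[np.ndarray] = []
        for feature, f in reversed(padded):
            parts.append(transform(feature) if transform is not None else feature)
            parts.append(np.array([f]))
        return np.concatenate(parts)


class RunningMinMax:
    """Running min–max normaliser for scalar focus metrics.

    Maps a metric value to (phi - min)/(max - min) using the extrema seen
    so far in the episode; before any spread exists it returns 0.5.  Makes
    the learned policy's state invariant to the absolute metric scale of
    the scene texture, which varies by an order of magnitude across
    families while carrying no focus information.
    """

    def __init__(self):
        self.reset()

    def reset(self) -> None:
        self.lo = np.inf
        self.hi = -np.inf

    def update(self, phi: float) -> None:
        self.lo = min(self.lo, phi)
        self.hi = max(self.hi, phi)

    def __call__(self, phi):
        span = self.hi - self.lo
        if not np.isfinite(span) or span < 1e-12:
            return np.atleast_1d(0.5)
        return np.atleast_1d((np.asarray(phi, dtype=float) - self.lo) / span)


class Policy:
    """Stepwise policy interface: reset, then observe each frame."""

    def reset(self, seed: int | None = None) -> None:  # noqa: ARG002
        return None

    def observe(self, observation: np.ndarray, f: float) -> float:
        raise NotImplementedError  # pragma: no cover


class FixedPolicy(Policy):
    def __init__(self, f0: float = 0.5):
        if not 0.0 <= f0 <= 1.0:
            raise ValueError("f0 must lie in [0, 1]")
        self.f0 = float(f0)

    def observe(self, observation, f):  # noqa: ARG002
        return self.f0


class OraclePolicy(Policy):
    """Knows the scan's optimal focal power; f := f* at every frame."""

    def __init__(self, scan: FocalTimeScan):
        self.scan = scan
        self._t = 0

    def reset(self, seed=None):  # noqa: ARG002
        self._t = 0

    def observe(self, observation, f):  # noqa: ARG002
        self._t += 1
        return float(self.scan.fstar(self._t))


class HillClimberPolicy(Policy):
    """Modified hill climber on a scalar focus metric.

    Continue in the previous direction d_prev = sign(f_t - f_{t-1}) while
    the metric improved and 0 < f_t < 1; otherwise reverse.  The step size
    is h (default 0.05) and the result is clamped to [0, 1].  At episode
    start d_prev is +1 and the previous metric is -inf, so the first move
    is +h.
    """

    def __init__(
        self,
        metric: str = "mgm",
        h: float = DEFAULT_H,
        metric_config: MetricConfig | None = None,
    ):
        self.metric_name = metric
        self._metric = metric_fn(metric, metric_config or MetricConfig())
        self.h = float(h)
        self.reset()

    def reset(self, seed=None):  # noqa: ARG002
        self._phi_prev = -np.inf
        self._f_prev: float | None = None
        self._d_prev = 1.0

    @staticmethod
    def step_rule(f: float, phi: float, phi_prev: float, d_prev: float, h: float) -> float:
        """One hill-climber update, clamped to [0, 1]."""
        if 0.0 < f < 1.0 and phi > phi_prev:
            return _clamp01(f + d_prev * h)
        return _clamp01(f - d_prev * h)

    def observe(self, observation, f):
        phi = self._metric(observation)
        f = float(f)
        if self._f_prev is not None:
            d = np.sign(f - self._f_prev)
            if d != 0.0:
                self._d_prev = float(d)
        f_next = self.step_rule(f, phi, self._phi_prev, self._d_prev, self.h)
        self._phi_prev = phi
        self._f_prev = f
        return f_next


class LearnedScalarPolicy(Policy):
    """Q-network policy over the (metric, focal power) history."""

    def __init__(
        self,
        network: nn.Sequential,
        metric: str = "mgm",
        h: float = DEFAULT_H,
        n_history: int = HISTORY_LEN,
        epsilon: float = 0.0,
        metric_config: MetricConfig | None = None,
        normalise: bool = False,
        probe_start: bool = False,
        seed: int | None = None,
    ):
        self.network = network
        self.metric_name = metric
        self._metric = metric_fn(metric, metric_config or MetricConfig())
        self.h = float(h)
        self.epsilon = float(epsilon)
        self.state = AgentState(n_history, feature_dim=1)
        self.normaliser = RunningMinMax() if normalise else None
        self.probe_start = bool(probe_start)
        self._rng = np.random.default_rng(seed)
        self.last_action: int | None = None

    @property
    def actions(self) -> tuple[float, float, float]:
        return (-self.h, 0.0, +self.h)

    def reset(self, seed: int | None = None) -> None:
        self.state.reset()
        if self.normaliser is not None:
            self.normaliser.reset()
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self.last_action = None

    def q_values(self) -> np.ndarray:
        out = self.network(self.state.vector(self.normaliser)[None, :])
        out = np.asarray(out)
        if out.shape != (1, 3):
            raise ValueError(f"Q-network must emit 3 action values, got {out.shape}")
        return out[0]

    def observe(self, observation, f):
        phi = self._metric(observation)
        first = len(self.state) == 0
        self.state.push(phi, f)
        if self.normaliser is not None:
            self.normaliser.update(phi)
        if first and self.probe_start:
            # episode-start probe: without metric spread the state is
            # degenerate, and a "stay" greedy action would freeze it
            # forever (the hill climber's d_prev = +1 convention, here)
            a = 2 if f <= 1.0 - self.h else 0
        else:
            a = select_action(self.q_values(), self.epsilon, self._rng)
        self.last_action = a
        return _clamp01(float(f) + self.actions[a])


def encode_patch(patch: np.ndarray, encoder: nn.Sequential) -> np.ndarray:
    """Run the convolutional encoder on one 32x32 patch -> 8 logits."""
    patch = np.asarray(patch, dtype=float)
    if patch.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValueError(f"expected {PATCH_SIZE}x{PATCH_SIZE} patch, got {patch.shape}")
    out = encoder(patch[None, None, :, :])
    return np.asarray(out)[0]


class CNNPolicy(Policy):
    """End-to-end policy: patch encoder + Q-network over encoding history.

    Per step only the most recent patch passes through the encoder; the
    previous N-1 encodings are cached in the agent state
    (``encoder_calls`` counts forward passes, for auditing the cache).
    """

    def __init__(
        self,
        encoder: nn.Sequential,
        network: nn.Sequential,
        h: float = DEFAULT_H,
        n_history: int = HISTORY_LEN,
        epsilon: float = 0.0,
        probe_start: bool = False,
        seed: int | None = None,
    ):
        self.encoder = encoder
        self.network = network
        self.h = float(h)
        self.epsilon = float(epsilon)
        self.state = AgentState(n_history, feature_dim=8)
        self.probe_start = bool(probe_start)
        self._rng = np.random.default_rng(seed)
        self.encoder_calls = 0
        self.last_action: int | None = None

    @property
    def actions(self) -> tuple[float, float, float]:
        return (-self.h, 0.0, +self.h)

    def reset(self, seed: int | None = None) -> None:
        self.state.reset()
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        self.last_action = None

    def observe(self, observation, f):
        encoding = encode_patch(observation, self.encoder)
        self.encoder_calls += 1
        first = len(self.state) == 0
        self.state.push(encoding, f)
        if first and self.probe_start:
            a = 2 if f <= 1.0 - self.h else 0
        else:
            out = np.asarray(self.network(self.state.vector()[None, :]))
            if out.shape != (1, 3):
                raise ValueError(
                    f"Q-network must emit 3 action values, got {out.shape}"
                )
            a = select_action(out[0], self.epsilon, self._rng)
        self.last_action = a
        return _clamp01(float(f) + self.actions[a])


def save_checkpoint(
    path: str | Path,
    kind: str,
    network: nn.Sequential,
    encoder: nn.Sequential | None = None,
    metric: str | None = None,
    h: float = DEFAULT_H,
    n_history: int = HISTORY_LEN,
    normalise: bool = False,
    probe_start: bool = True,
    extra: dict | None = None,
) -> Path:
    """Write a single-file policy checkpoint (versioned npz)."""
    path = Path(path)
    header = {
        "version": CHECKPOINT_VERSION,
        "kind": kind,
        "metric": metric,
        "h": h,
        "n_history": n_history,
        "normalise": normalise,
        "probe_start": probe_start,
        "extra": extra or {},
    }
    arrays = {f"q.{k}": v for k, v in network.state_dict().items()}
    if encoder is not None:
        arrays.update({f"enc.{k}": v for k, v in encoder.state_dict().items()})
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, header=json.dumps(header), **arrays)
    return path


def load_policy(path: str | Path, epsilon: float = 0.0, seed: int | None = None) -> Policy:
    """Rebuild a learned policy from a checkpoint file."""
    data = np.load(path, allow_pickle=False)
    header = json.loads(str(data["header"]))
    if header["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {header['version']}")
    n = header["n_history"]
    h = header["h"]
    rng = np.random.default_rng(0)
    q_state = {k[2:]: data[k] for k in data.files if k.startswith("q.")}
    if header["kind"] == "learned_mlp":
        net = nn.make_q_network(2 * n, rng)
        net.load_state_dict(q_state)
        return LearnedScalarPolicy(
            net,
            metric=header["metric"],
            h=h,
            n_history=n,
            epsilon=epsilon,
            normalise=header.get("normalise", False),
            probe_start=header.get("probe_start", True),
            seed=seed,
        )
    if header["kind"] == "learned_cnn":
        enc_state = {k[4:]: data[k] for k in data.files if k.startswith("enc.")}
        enc = nn.make_encoder(rng)
        enc.load_state_dict(enc_state)
        net = nn.make_q_network(9 * n, rng)
        net.load_state_dict(q_state)
        return CNNPolicy(
            enc,
            net,
            h=h,
            n_history=n,
            epsilon=epsilon,
            probe_start=header.get("probe_start", True),
            seed=seed,
        )
    raise ValueError(f"unknown checkpoint kind {header['kind']!r}")
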