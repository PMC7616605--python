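"""Deep Q-learning for the autofocus policies.

Standard DQN ingredients: uniform experience replay with FIFO eviction,
epsilon-greedy exploration with exponential decay, a target network tracked
by EMA weight updates (beta = 0.005), smoothed-L1 temporal-difference loss,
discount gamma = 0.99 and RMSProp.

Two scales are provided: :func:`paper_scale` keeps the published recipe
(replay 2.5e6, epsilon horizon 2e6 experiences, learning rate 1e-5) and
:func:`desk_scale` shrinks everything proportionally so a full training run
finishes in minutes on one CPU (1e5 experiences; the learning rate is
raised to 1e-3 to compensate for the ~25x shorter schedule — see
docs/methods.md).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from . import nn
from .metrics import MetricConfig, metric_fn
from .policies import AgentState, RunningMinMax, select_action
from .simulate import DEFAULT_H, FocusEnv

__all__ = [
    "DQNConfig",
    "paper_scale",
    "desk_scale",
    "EpsilonSchedule",
    "ReplayMemory",
    "PatchReplay",
    "td_targets",
    "TrainResult",
    "TrainingDiverged",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when mean |Q| exceeds the configured divergence bound."""


@dataclasses.dataclass
class EpsilonSchedule:
    """Exponential decay ``eps(t) = start * (end/start)^(t/horizon)``,
    clamped at ``end`` after the horizon."""

    start: float = 1.0
    end: float = 0.1
    horizon: int = 2_000_000

    def __call__(self, step: int) -> float:
        if step < 0:
            raise ValueError("step must be >= 0")
        if step >= self.horizon:
            return self.end
        return float(self.start * (self.end / self.start) ** (step / self.horizon))


@dataclasses.dataclass
class DQNConfig:
    gamma: float = 0.99
    lr: float = 1e-5
    #: optional final learning rate; when set, the rate decays
    #: exponentially from ``lr`` to ``lr_end`` over the run
    lr_end: float | None = None
    rmsprop_rho: float = 0.95
    batch_size: int = 64
    replay_capacity: int = 2_500_000
    eps_start: float = 1.0
    eps_end: float = 0.1
    eps_horizon: int = 2_000_000
    total_steps: int = 2_500_000
    warmup: int = 1000
    updates_per_step: int = 1
    grad_clip: float = 10.0
    ema_beta: float = 0.005
    h: float = DEFAULT_H
    n_history: int = 8
    divergence_bound: float = 1e3
    #: running min-max normalisation of the scalar focus metric in the
    #: agent state (makes the state invariant to texture-dependent metric
    #: scale; off reproduces the raw-metric state)
    normalise_metric: bool = False
    #: every this many steps, probe the greedy policy on a few held-aside
    #: episodes and snapshot the best weights seen (0 disables; the final
    #: weights then stand).  Counters late-training policy churn.
    eval_every: int = 0
    eval_episodes: int = 5
    #: probe and snapshot the EMA target network instead of the online
    #: network — the averaged weights give a steadier greedy policy
    probe_target: bool = False

    def __post_init__(self):
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if not 0.0 < self.ema_beta <= 1.0:
            raise ValueError("ema_beta must lie in (0, 1]")

    def schedule(self) -> EpsilonSchedule:
        return EpsilonSchedule(self.eps_start, self.eps_end, self.eps_horizon)


def paper_scale() -> DQNConfig:
    """The published training recipe, unscaled."""
    return DQNConfig()


def desk_scale(total_steps: int = 100_000) -> DQNConfig:
    """CPU-minutes preset: everything scaled to ``total_steps`` experiences.

    Replay holds the full run, the epsilon horizon is 80% of the run
    (preserving the published 2e6 / 2.5e6 ratio) and the learning rate is
    1e-3 so the shorter schedule still moves the weights.
    """
    return DQNConfig(
        gamma=0.8,
        lr=1e-3,
        replay_capacity=total_steps,
        eps_horizon=int(0.8 * total_steps),
        total_steps=total_steps,
        normalise_metric=True,
        eval_every=2500,
        eval_episodes=8,
        probe_target=True,
    )


class ReplayMemory:
    """FIFO ring buffer of vector-state transitions, uniform sampling."""

    def __init__(self, capacity: int, state_dim: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = int(capacity)
        self.state_dim = int(state_dim)
        self._s = np.zeros((self.capacity, state_dim), dtype=np.float32)
        self._s2 = np.zeros((self.capacity, state_dim), dtype=np.float32)
        self._a = np.zeros(self.capacity, dtype=np.int64)
        self._r = np.zeros(self.capacity, dtype=np.float64)
        self._done = np.zeros(self.capacity, dtype=bool)
        self._next = 0
        self.size = 0

    def __len__(self) -> int:
        return self.size

    def push(self, s, a: int, r: float, s2, done: bool) -> None:
        i = self._next
        self._s[i] = s
        self._s2[i] = s2
        self._a[i] = a
        self._r[i] = r
        self._done[i] = done
        self._next = (i + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(self.size, size=batch_size)
        return (
            self._s[idx].astype(np.float64),
            self._a[idx],
            self._r[idx],
            self._s2[idx].astype(np.float64),
            self._done[idx],
        )

    def rewards(self) -> np.ndarray:
        return self._r[: self.size]


class PatchReplay:
    """Replay for the end-to-end policy: stores one patch per step and
    reconstructs N-frame windows on sampling.

    Entries are (patch, f, action, reward, done, episode id); the state at
    entry i is the window of the N most recent (patch, f) pairs of the same
    episode ending at i, padded at the episode start by repeating the
    earliest pair — identical to the inference-time agent state.  The next
    state is the window ending at i+1.
    """

    def __init__(self, capacity: int, n_history: int, patch_size: int = 32):
        self.capacity = int(capacity)
        self.n = int(n_history)
        self._patch = np.zeros((self.capacity, patch_size, patch_size), dtype=np.float32)
        self._f = np.zeros(self.capacity, dtype=np.float64)
        self._a = np.zeros(self.capacity, dtype=np.int64)
        self._r = np.zeros(self.capacity, dtype=np.float64)
        self._done = np.zeros(self.capacity, dtype=bool)
        self._ep = np.zeros(self.capacity, dtype=np.int64)
        self._count = 0  # absolute number of pushes

    def __len__(self) -> int:
        return min(self._count, self.capacity)

    def push(self, patch, f, a, r, done, episode):
        i = self._count % self.capacity
        self._patch[i] = patch
        self._f[i] = f
        self._a[i] = a
        self._r[i] = r
        self._done[i] = done
        self._ep[i] = episode
        self._count += 1

    def _window(self, abs_idx: int):
        """(patches, fs) newest-first for the window ending at abs_idx."""
        oldest = max(0, self._count - self.capacity)
        idxs = []
        j = abs_idx
        ep = self._ep[abs_idx % self.capacity]
        for _ in range(self.n):
            idxs.append(j)
            if j - 1 >= oldest and self._ep[(j - 1) % self.capacity] == ep:
                j -= 1
        while len(idxs) < self.n:
            idxs.append(idxs[-1])  # pad with earliest available
        rel = [i % self.capacity for i in idxs]
        return self._patch[rel].astype(np.float64), self._f[rel]

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Uniform sample of transitions.

        An entry whose successor belongs to a different episode (episode
        truncated by the step budget, or overwritten by the ring) is
        treated as terminal so no bootstrap crosses episode boundaries.
        """
        oldest = max(0, self._count - self.capacity)
        hi = self._count - 2
        if hi < oldest:
            raise RuntimeError("no sampleable transitions")
        abs_idx = rng.integers(oldest, hi + 1, size=batch_size)
        n, ps = self.n, self._patch.shape[1]
        patches = np.empty((batch_size, n, ps, ps))
        fs = np.empty((batch_size, n))
        patches2 = np.empty_like(patches)
        fs2 = np.empty_like(fs)
        a = np.empty(batch_size, dtype=np.int64)
        r = np.empty(batch_size)
        done = np.empty(batch_size, dtype=bool)
        for b, vi in enumerate(abs_idx):
            patches[b], fs[b] = self._window(vi)
            rel = vi % self.capacity
            a[b], r[b] = self._a[rel], self._r[rel]
            done[b] = self._done[rel] or self._ep[(vi + 1) % self.capacity] != self._ep[rel]
            nxt = vi if done[b] else vi + 1
            patches2[b], fs2[b] = self._window(nxt)
        return patches, fs, a, r, patches2, fs2, done


def td_targets(
    rewards: np.ndarray,
    next_q_max: np.ndarray,
    done: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Bellman targets ``r + gamma * max_a Q_target(s', a)``; terminal
    transitions bootstrap nothing."""
    rewards = np.asarray(rewards, dtype=float)
    next_q_max = np.asarray(next_q_max, dtype=float)
    done = np.asarray(done, dtype=bool)
    return rewards + gamma * next_q_max * (~done)


@dataclasses.dataclass
class TrainResult:
    """Weights plus per-episode training log."""

    kind: str
    metric: str | None
    network: nn.Sequential
    encoder: nn.Sequential | None
    log: pd.DataFrame
    config: DQNConfig

    def make_policy(
        self, epsilon: float = 0.0, probe_start: bool = True, seed: int | None = None
    ):
        from .policies import CNNPolicy, LearnedScalarPolicy

        if self.kind == "learned_cnn":
            return CNNPolicy(
                self.encoder,
                self.network,
                h=self.config.h,
                n_history=self.config.n_history,
                epsilon=epsilon,
                probe_start=probe_start,
                seed=seed,
            )
        return LearnedScalarPolicy(
            self.network,
            metric=self.metric,
            h=self.config.h,
            n_history=self.config.n_history,
            epsilon=epsilon,
            normalise=self.config.normalise_metric,
            probe_start=probe_start,
            seed=seed,
        )


def _encode_batch(encoder, patches, fs):
    """(B, N, ps, ps), (B, N) -> newest-first state matrix (B, N*9)."""
    b, n, ps, _ = patches.shape
    enc = encoder(patches.reshape(b * n, 1, ps, ps)).reshape(b, n, 8)
    state = np.concatenate([enc, fs[:, :, None]], axis=2)  # (B, N, 9)
    return state.reshape(b, n * 9)


def train(
    env_factory,
    kind: str = "learned_mlp",
    metric: str = "mgm",
    config: DQNConfig | None = None,
    seed: int = 0,
    metric_config: MetricConfig | None = None,
    log_every: int = 1,
) -> TrainResult:
    """Train an autofocus Q-policy on simulated focal-time scans.

    Parameters
    ----------
    env_factory
        ``(episode_index, seed) -> FocusEnv``; a fresh environment per
        episode.
    kind
        ``"learned_mlp"`` (scalar-metric state) or ``"learned_cnn"``
        (end-to-end patch encoder).
    metric
        Focus metric feeding the scalar-state variant.
    seed
        Single seed; network init, exploration and per-episode environment
        seeds all derive from it.

    Returns a :class:`TrainResult`; raises :class:`TrainingDiverged` if the
    mean absolute Q-value on a batch exceeds ``config.divergence_bound``.
    """
    if kind not in ("learned_mlp", "learned_cnn"):
        raise ValueError(f"unknown policy kind {kind!r}")
    config = config or desk_scale()
    ss = np.random.SeedSequence(seed)
    init_seed, act_seed, sample_seed, env_ss, probe_ss = ss.spawn(5)
    rng_init = np.random.default_rng(init_seed)
    rng_act = np.random.default_rng(act_seed)
    rng_sample = np.random.default_rng(sample_seed)

    n = config.n_history
    cnn = kind == "learned_cnn"
    if cnn:
        encoder = nn.make_encoder(rng_init)
        target_encoder = encoder.copy()
        net = nn.make_q_network(9 * n, rng_init)
        replay = PatchReplay(config.replay_capacity, n)
    else:
        encoder = target_encoder = None
        net = nn.make_q_network(2 * n, rng_init)
        replay = ReplayMemory(config.replay_capacity, 2 * n)
    target = net.copy()
    params = net.parameters() + (encoder.parameters() if cnn else [])
    opt = nn.RMSProp(params, lr=config.lr, rho=config.rmsprop_rho)
    schedule = config.schedule()
    phi = metric_fn(metric, metric_config or MetricConfig())
    actions = (-config.h, 0.0, +config.h)

    episode_seeds = env_ss.generate_state(1 << 16, dtype=np.uint32)
    probe_seeds = [int(s) for s in probe_ss.generate_state(max(config.eval_episodes, 1), dtype=np.uint32)]
    global_step = 0
    episode = 0
    records = []
    best: tuple[float, dict, dict | None] | None = None

    def _probe() -> float:
        """Mean greedy-episode reward on the held-aside probe seeds."""
        from .policies import CNNPolicy, LearnedScalarPolicy

        pnet = target if config.probe_target else net
        penc = target_encoder if config.probe_target else encoder
        if cnn:
            pol = CNNPolicy(penc, pnet, h=config.h, n_history=n, probe_start=True)
        else:
            pol = LearnedScalarPolicy(
                pnet, metric=metric, h=config.h, n_history=n,
                normalise=config.normalise_metric, probe_start=True,
            )
        totals = []
        n_probe = len(probe_seeds)
        for k, pseed in enumerate(probe_seeds):
            penv = env_factory(-1 - k, pseed)
            # spread initial focal powers across [0, 1] so the probe
            # exercises both long transits and fine tracking
            f0 = k / (n_probe - 1) if n_probe > 1 else 0.5
            pres = penv.reset(f0=f0)
            pol.reset()
            total, pdone, f = 0.0, pres.done, penv.f
            while not pdone:
                f_next = pol.observe(pres.observation, f)
                delta = f_next - f
                action = 0.0 if abs(delta) < 1e-9 else np.sign(delta) * config.h
                pres = penv.step(action)
                total += pres.reward
                f, pdone = pres.info["f"], pres.done
            totals.append(total)
        return float(np.mean(totals))

    def _snapshot(score: float) -> None:
        nonlocal best
        if best is None or score > best[0]:
            snet = target if config.probe_target else net
            senc = target_encoder if config.probe_target else encoder
            best = (
                score,
                {k: v.copy() for k, v in snet.state_dict().items()},
                {k: v.copy() for k, v in senc.state_dict().items()} if cnn else None,
            )

    while global_step < config.total_steps:
        env = env_factory(episode, int(episode_seeds[episode % len(episode_seeds)]))
        res = env.reset()
        state = AgentState(n, feature_dim=8 if cnn else 1)
        normaliser = RunningMinMax() if (config.normalise_metric and not cnn) else None
        if cnn:
            enc = encoder(res.observation[None, None, :, :])[0]
            state.push(enc, env.f)
        else:
            phi0 = phi(res.observation)
            state.push(phi0, env.f)
            if normaliser is not None:
                normaliser.update(phi0)
        ep_rewards, ep_losses = [], []
        done = False
        while not done and global_step < config.total_steps:
            s_vec = state.vector(normaliser)
            eps = schedule(global_step)
            q = net(s_vec[None, :])[0]
            a = select_action(q, eps, rng_act)
            step_res = env.step(actions[a])
            done = step_res.done
            if cnn:
                # stored patch/f are the pre-action observation, so replay
                # windows reproduce the acting state exactly
                replay.push(
                    res.observation, env_f_prev(state), a, step_res.reward,
                    done, episode,
                )
                enc = encoder(step_res.observation[None, None, :, :])[0]
                state.push(enc, step_res.info["f"])
            else:
                phi_next = phi(step_res.observation)
                state.push(phi_next, step_res.info["f"])
                if normaliser is not None:
                    normaliser.update(phi_next)
                s2_vec = state.vector(normaliser)
                replay.push(s_vec, a, step_res.reward, s2_vec, done)
            res = step_res
            ep_rewards.append(step_res.reward)
            global_step += 1

            if len(replay) >= max(config.warmup, config.batch_size):
                if config.lr_end is not None:
                    frac = min(global_step / config.total_steps, 1.0)
                    opt.lr = config.lr * (config.lr_end / config.lr) ** frac
                for _ in range(config.updates_per_step):
                    loss = _update(
                        net, target, encoder, target_encoder, replay,
                        config, rng_sample, opt, cnn,
                    )
                    ep_losses.append(loss)
                nn.ema_update(net, target, config.ema_beta)
                if cnn:
                    nn.ema_update(encoder, target_encoder, config.ema_beta)
            if (
                config.eval_every
                and global_step % config.eval_every == 0
                and len(replay) >= max(config.warmup, config.batch_size)
            ):
                _snapshot(_probe())
        episode += 1
        if episode % log_every == 0:
            records.append(
                {
                    "episode": episode,
                    "steps": global_step,
                    "mean_reward": float(np.mean(ep_rewards)) if ep_rewards else np.nan,
                    "epsilon": schedule(min(global_step, config.total_steps)),
                    "loss": float(np.mean(ep_losses)) if ep_losses else np.nan,
                }
            )

    if config.eval_every and best is not None:
        _snapshot(_probe())  # final weights compete with the snapshots
        net.load_state_dict(best[1])
        if cnn:
            encoder.load_state_dict(best[2])
    log = pd.DataFrame.from_records(records)
    return TrainResult(kind, None if cnn else metric, net, encoder, log, config)


def env_f_prev(state: AgentState) -> float:
    """Focal power of the newest state entry (pre-action f)."""
    return state._items[-1][1]


def _update(net, target, encoder, target_encoder, replay, config, rng, opt, cnn):
    if cnn:
        p, fs, a, r, p2, fs2, done = replay.sample(config.batch_size, rng)
        s2 = _encode_batch(target_encoder, p2, fs2)
        next_q = target(s2).max(axis=1)
        y = td_targets(r, next_q, done, config.gamma)
        s = _encode_batch(encoder, p, fs)
        q = net(s)
    else:
        s, a, r, s2, done = replay.sample(config.batch_size, rng)
        next_q = target(s2).max(axis=1)
        y = td_targets(r, next_q, done, config.gamma)
        q = net(s)
    if np.abs(q).mean() > config.divergence_bound:
        raise TrainingDiverged(
            f"mean |Q| = {np.abs(q).mean():.3g} exceeded bound "
            f"{config.divergence_bound}"
        )
    pred = q[np.arange(len(a)), a]
    loss, dpred = smooth_l1_selected(pred, y)
    dq = np.zeros_like(q)
    dq[np.arange(len(a)), a] = dpred
    dstate = net.backward(dq)
    if cnn:
        b = dstate.shape[0]
        denc = dstate.reshape(b, config.n_history, 9)[:, :, :8]
        encoder.backward(denc.reshape(b * config.n_history, 8))
    grads = net.gradients() + (encoder.gradients() if cnn else [])
    nn.clip_grad_norm(grads, config.grad_clip)
    opt.step(grads)
    return loss


def smooth_l1_selected(pred: np.ndarray, target: np.ndarray):
    return nn.smooth_l1(pred, target)
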