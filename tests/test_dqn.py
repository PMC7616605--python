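"""DQN mechanics: schedule, targets, EMA, replay, gradients, training loop."""

import numpy as np
import pytest

from videoaf import nn
from videoaf.dqn import (
    DQNConfig,
    EpsilonSchedule,
    PatchReplay,
    ReplayMemory,
    TrainingDiverged,
    desk_scale,
    paper_scale,
    td_targets,
    train,
)
from videoaf.model import ScanConditions

from .oracles import td_targets_oracle


class TestEpsilonSchedule:
    def test_endpoints(self):
        sched = EpsilonSchedule(1.0, 0.1, 2_000_000)
        assert sched(0) == 1.0
        assert sched(2_000_000) == 0.1
        assert sched(5_000_000) == 0.1

    def test_exponential_midpoint(self):
        sched = EpsilonSchedule(1.0, 0.1, 1000)
        assert sched(500) == pytest.approx(np.sqrt(0.1))

    def test_paper_scale_preserves_published_recipe(self):
        cfg = paper_scale()
        assert cfg.replay_capacity == 2_500_000
        assert cfg.eps_horizon == 2_000_000
        assert cfg.gamma == 0.99
        assert cfg.lr == 1e-5
        assert cfg.ema_beta == 0.005
        assert cfg.rmsprop_rho == 0.95


class TestTDTargets:
    def test_terminal_transition_is_pure_reward(self):
        y = td_targets(np.array([-0.2]), np.array([5.0]), np.array([True]), 0.99)
        assert y[0] == pytest.approx(-0.2)

    def test_zero_target_network(self):
        y = td_targets(np.array([-0.1]), np.array([0.0]), np.array([False]), 0.99)
        assert y[0] == pytest.approx(-0.1)

    def test_bootstrap_arithmetic(self):
        y = td_targets(np.array([0.0]), np.array([-0.5]), np.array([False]), 0.99)
        assert y[0] == pytest.approx(-0.495)

    def test_matches_per_transition_loop_oracle(self, rng):
        r = -rng.random(64)
        q = rng.normal(size=64)
        d = rng.random(64) < 0.3
        assert td_targets(r, q, d, 0.99) == pytest.approx(
            td_targets_oracle(r, q, d, 0.99)
        )


class TestEMA:
    def test_beta_one_copies_online(self):
        online, target = [np.ones((2, 2))], [np.zeros((2, 2))]
        nn.ema_update(online, target, 1.0)
        assert np.array_equal(target[0], online[0])

    def test_beta_zero_is_identity(self):
        target = [np.full((3,), 0.7)]
        nn.ema_update([np.ones(3)], target, 0.0)
        assert np.allclose(target[0], 0.7)

    def test_elementwise_arithmetic(self):
        target = [np.zeros(4)]
        nn.ema_update([np.ones(4)], target, 0.005)
        assert target[0] == pytest.approx(np.full(4, 0.005))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            nn.ema_update([np.ones(3)], [np.ones(4)], 0.5)


class TestReplayMemory:
    def test_fifo_keeps_exactly_the_last_capacity_items(self):
        mem = ReplayMemory(100, state_dim=2)
        for i in range(150):
            mem.push([i, i], 0, float(i), [i, i], False)
        assert len(mem) == 100
        assert sorted(mem.rewards()) == pytest.approx(list(range(50, 150)))

    def test_uniform_sampling_covers_buffer(self, rng):
        mem = ReplayMemory(50, state_dim=1)
        for i in range(50):
            mem.push([i], i % 3, float(i), [i], False)
        s, a, r, s2, d = mem.sample(2000, rng)
        assert s.shape == (2000, 1)
        # every stored transition should appear
        assert len(np.unique(r)) == 50


class TestPatchReplay:
    def test_windows_pad_at_episode_start_and_respect_boundaries(self, rng):
        mem = PatchReplay(capacity=100, n_history=3, patch_size=4)
        # episode 0: 3 steps; episode 1: 2 steps
        for t in range(3):
            mem.push(np.full((4, 4), t), 0.1 * t, a=1, r=-0.1, done=(t == 2), episode=0)
        for t in range(2):
            mem.push(np.full((4, 4), 10 + t), 0.5, a=2, r=-0.2, done=(t == 1), episode=1)
        patches, fs = mem._window(0)
        assert [p[0, 0] for p in patches] == [0, 0, 0]  # padded with earliest
        patches, fs = mem._window(2)
        assert [p[0, 0] for p in patches] == [2, 1, 0]  # newest first
        patches, fs = mem._window(3)
        assert [p[0, 0] for p in patches] == [10, 10, 10]  # new episode, no leak

    def test_sampling_marks_episode_boundaries_terminal(self, rng):
        mem = PatchReplay(capacity=100, n_history=2, patch_size=4)
        for t in range(3):
            mem.push(np.zeros((4, 4)), 0.0, 0, -0.5, done=(t == 2), episode=0)
        for t in range(2):
            mem.push(np.zeros((4, 4)), 0.0, 0, -0.5, done=(t == 1), episode=1)
        p, fs, a, r, p2, fs2, done = mem.sample(64, rng)
        assert p.shape == (64, 2, 4, 4)
        assert done[np.isclose(r, -0.5)].dtype == bool


class TestGradients:
    """Backprop of the hand-rolled layers against finite differences."""

    def _numeric_grad(self, forward, param, eps=1e-6):
        grad = np.zeros_like(param)
        it = np.nditer(param, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = param[idx]
            param[idx] = orig + eps
            lo_hi = forward()
            param[idx] = orig - eps
            lo_lo = forward()
            param[idx] = orig
            grad[idx] = (lo_hi - lo_lo) / (2 * eps)
        return grad

    def test_dense_relu_network_gradients(self):
        rng = np.random.default_rng(0)
        net = nn.Sequential([nn.Dense(4, 8, rng), nn.ReLU(), nn.Dense(8, 3, rng)])
        x = rng.normal(size=(5, 4))
        y = rng.normal(size=(5, 3))

        def loss_fn():
            loss, _ = nn.smooth_l1(net(x), y)
            return loss

        loss, grad = nn.smooth_l1(net(x), y)
        net.backward(grad)
        for layer in (net.layers[0], net.layers[2]):
            for name in ("W", "b"):
                num = self._numeric_grad(loss_fn, layer.params[name])
                assert layer.grads[name] == pytest.approx(num, abs=1e-6)

    def test_conv_encoder_gradients(self):
        rng = np.random.default_rng(1)
        net = nn.Sequential(
            [nn.Conv2d(1, 2, rng), nn.ReLU(), nn.Conv2d(2, 2, rng), nn.GlobalAvgPool()]
        )
        x = rng.normal(size=(2, 1, 8, 8))
        y = rng.normal(size=(2, 2))

        def loss_fn():
            loss, _ = nn.smooth_l1(net(x), y)
            return loss

        loss, grad = nn.smooth_l1(net(x), y)
        net.backward(grad)
        for layer in (net.layers[0], net.layers[2]):
            for name in ("W", "b"):
                num = self._numeric_grad(loss_fn, layer.params[name])
                assert layer.grads[name] == pytest.approx(num, abs=1e-6)

    def test_huber_loss_is_quadratic_then_linear(self):
        loss, grad = nn.smooth_l1(np.array([0.5, 3.0]), np.zeros(2))
        assert loss == pytest.approx((0.5 * 0.25 + (3.0 - 0.5)) / 2)
        assert grad == pytest.approx([0.25, 0.5])  # /n, clipped slope

    def test_rmsprop_moves_against_gradient(self):
        p = np.array([1.0])
        opt = nn.RMSProp([p], lr=0.1, rho=0.9)
        opt.step([np.array([2.0])])
        assert p[0] < 1.0


def _fast_cfg(**kw):
    base = dict(
        total_steps=400,
        replay_capacity=400,
        eps_horizon=300,
        warmup=40,
        batch_size=16,
        lr=1e-3,
        normalise_metric=True,
    )
    base.update(kw)
    return DQNConfig(**base)


def _fast_conditions():
    return ScanConditions(episode_len=40, frame_shape=(48, 48))


class TestTraining:
    def test_same_seed_twice_is_identical(self):
        runs = []
        for _ in range(2):
            res = train(
                _fast_conditions().env_factory(), config=_fast_cfg(), seed=5
            )
            runs.append(res)
        assert runs[0].log.equals(runs[1].log)
        for a, b in zip(runs[0].network.parameters(), runs[1].network.parameters()):
            assert np.array_equal(a, b)

    def test_log_records_reward_epsilon_loss(self):
        res = train(_fast_conditions().env_factory(), config=_fast_cfg(), seed=0)
        assert {"episode", "steps", "mean_reward", "epsilon", "loss"} <= set(
            res.log.columns
        )
        assert (res.log["mean_reward"] <= 0).all()
        assert res.log["loss"].notna().any()

    def test_divergence_guard_raises(self):
        with pytest.raises(TrainingDiverged):
            train(
                _fast_conditions().env_factory(),
                config=_fast_cfg(divergence_bound=1e-6),
                seed=0,
            )

    def test_cnn_variant_trains_and_acts(self):
        res = train(
            _fast_conditions().env_factory(),
            kind="learned_cnn",
            config=_fast_cfg(total_steps=150, replay_capacity=150, warmup=30, batch_size=8),
            seed=3,
        )
        pol = res.make_policy()
        f = 0.5
        rng = np.random.default_rng(0)
        for _ in range(5):
            f = pol.observe(rng.random((32, 32)), f)
            assert 0.0 <= f <= 1.0

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            train(_fast_conditions().env_factory(), kind="nope", config=_fast_cfg())

    def test_desk_scale_preset_proportions(self):
        cfg = desk_scale(50_000)
        assert cfg.total_steps == 50_000
        assert cfg.replay_capacity == 50_000
        assert cfg.eps_horizon == 40_000
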