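"""Policies: hill-climber branch rule, action selection, learned policies."""

import numpy as np
import pytest

from videoaf import nn
from videoaf.policies import (
    AgentState,
    CNNPolicy,
    FixedPolicy,
    HillClimberPolicy,
    LearnedScalarPolicy,
    OraclePolicy,
    RunningMinMax,
    encode_patch,
    load_policy,
    save_checkpoint,
    select_action,
)

H = 0.05


class TestFixedPolicy:
    def test_emits_f0_at_every_step(self, random_patch):
        pol = FixedPolicy(0.5)
        assert all(pol.observe(random_patch, 0.3) == 0.5 for _ in range(100))
        assert FixedPolicy(0.0).observe(random_patch, 0.9) == 0.0

    def test_zero_error_on_matching_static_target(self, frozen_scan):
        from videoaf.evaluation import evaluate

        res = evaluate(FixedPolicy(0.45), frozen_scan, f0=0.45)
        assert res.mae == 0.0


class TestHillClimberRule:
    """All branch combinations of the modified hill-climbing update."""

    CASES = [
        # (f, phi, phi_prev, d_prev, expected)
        (0.5, 5.0, 3.0, +1.0, 0.55),  # interior, improving, +1 -> continue up
        (0.5, 5.0, 3.0, -1.0, 0.45),  # interior, improving, -1 -> continue down
        (0.5, 2.0, 3.0, +1.0, 0.45),  # interior, worsening, +1 -> reverse down
        (0.5, 2.0, 3.0, -1.0, 0.55),  # interior, worsening, -1 -> reverse up
        (1.0, 5.0, 3.0, +1.0, 0.95),  # upper boundary, improving -> step back
        (1.0, 2.0, 3.0, +1.0, 0.95),  # upper boundary, worsening -> step back
        (0.0, 5.0, 3.0, -1.0, 0.05),  # lower boundary, improving -> step back
        (0.0, 2.0, 3.0, -1.0, 0.05),  # lower boundary, worsening -> step back
    ]

    @pytest.mark.parametrize("f,phi,phi_prev,d_prev,expected", CASES)
    def test_branch_table(self, f, phi, phi_prev, d_prev, expected):
        out = HillClimberPolicy.step_rule(f, phi, phi_prev, d_prev, H)
        assert out == pytest.approx(expected)

    def test_boundary_reversal_clamps_into_range(self):
        # boundary with inward d_prev: the "otherwise" branch would leave
        # [0, 1] and must be clamped
        assert HillClimberPolicy.step_rule(1.0, 2.0, 3.0, -1.0, H) == 1.0
        assert HillClimberPolicy.step_rule(0.0, 2.0, 3.0, +1.0, 0.0 + H) == 0.0

    def test_oscillates_near_optimum_of_static_landscape(self, frozen_scan):
        """On a static unimodal landscape the climber never stops, ending in
        a bounded oscillation about the optimum."""
        pol = HillClimberPolicy("mgm", h=H)
        pol.reset()
        f = 0.05
        path = [f]
        for t in range(28):
            patch = frozen_scan.render_patch(t, f)
            f = pol.observe(patch, f)
            path.append(f)
        tail = np.array(path[-8:])
        assert np.abs(tail - 0.45).max() <= 2 * H + 1e-9
        assert np.ptp(tail) > 0.0  # keeps moving


class TestSelectAction:
    def test_greedy_argmax_and_tie_breaking(self):
        assert select_action(np.array([0.1, 0.5, 0.2])) == 1
        assert select_action(np.array([-1.0, -2.0, -0.5])) == 2
        assert select_action(np.zeros(3)) == 0  # ties -> lowest index (-h)

    def test_uniform_exploration_frequencies(self):
        rng = np.random.default_rng(7)
        counts = np.zeros(3)
        for _ in range(30_000):
            counts[select_action(np.array([0.0, 1.0, 2.0]), epsilon=1.0, rng=rng)] += 1
        assert np.abs(counts / 30_000 - 1 / 3).max() < 0.01

    def test_validates_inputs(self):
        with pytest.raises(ValueError):
            select_action(np.zeros(4))
        with pytest.raises(ValueError):
            select_action(np.array([np.nan, 0, 0]))
        with pytest.raises(ValueError):
            select_action(np.zeros(3), epsilon=0.5)  # rng required


class _ScriptedNet:
    """Favours +h below the target focal power, -h above (f at index 1)."""

    def __init__(self, target=0.5):
        self.target = target

    def __call__(self, x):
        f = x[0, 1]
        if f < self.target - 1e-9:
            return np.array([[0.0, 0.0, 1.0]])
        return np.array([[1.0, 0.0, 0.0]])


class TestLearnedScalarPolicy:
    def test_constant_zero_network_tie_breaks_to_minus_h(self, random_patch):
        pol = LearnedScalarPolicy(lambda x: np.zeros((1, 3)), h=H)
        f = 0.30
        for _ in range(3):
            f2 = pol.observe(random_patch, f)
            assert f2 == pytest.approx(f - H)
            f = f2

    def test_scripted_network_approaches_target_monotonically(self, random_patch):
        pol = LearnedScalarPolicy(_ScriptedNet(0.5), h=H)
        f = 0.20
        path = [f]
        for _ in range(6):
            f = pol.observe(random_patch, f)
            path.append(f)
        assert path == pytest.approx([0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50])

    def test_clamps_at_upper_bound(self, random_patch):
        pol = LearnedScalarPolicy(lambda x: np.array([[0.0, 0.0, 1.0]]), h=H)
        assert pol.observe(random_patch, 1.0) == 1.0

    def test_wrong_network_output_shape_rejected(self, random_patch):
        pol = LearnedScalarPolicy(lambda x: np.zeros((1, 4)), h=H)
        with pytest.raises(ValueError):
            pol.observe(random_patch, 0.5)

    def test_greedy_invariant_to_positive_affine_q_transforms(self, random_patch):
        rng = np.random.default_rng(0)
        net = nn.make_q_network(16, rng)
        a = LearnedScalarPolicy(net, h=H)
        b = LearnedScalarPolicy(lambda x: 3.0 * net(x) + 7.0, h=H)
        f = 0.5
        for _ in range(5):
            fa = a.observe(random_patch, f)
            fb = b.observe(random_patch, f)
            assert fa == fb
            f = fa


class TestAgentState:
    def test_padding_repeats_earliest_pair(self):
        st = AgentState(n=4, feature_dim=1)
        st.push(2.0, 0.3)
        vec = st.vector()
        assert vec == pytest.approx([2.0, 0.3] * 4)
        st.push(5.0, 0.35)
        assert st.vector() == pytest.approx([5.0, 0.35, 2.0, 0.3, 2.0, 0.3, 2.0, 0.3])

    def test_fifo_eviction_keeps_newest_first(self):
        st = AgentState(n=2, feature_dim=1)
        for i in range(5):
            st.push(float(i), i / 10)
        assert st.vector() == pytest.approx([4.0, 0.4, 3.0, 0.3])

    def test_running_minmax_transform(self):
        norm = RunningMinMax()
        assert norm(3.0) == pytest.approx([0.5])  # no spread yet
        norm.update(1.0)
        norm.update(3.0)
        assert norm(2.0) == pytest.approx([0.5])
        assert norm(1.0) == pytest.approx([0.0])
        assert norm(3.0) == pytest.approx([1.0])


class TestEncoderAndCNNPolicy:
    def test_encoding_is_deterministic_length_8(self, random_patch):
        enc = nn.make_encoder(np.random.default_rng(0))
        e1 = encode_patch(random_patch, enc)
        e2 = encode_patch(random_patch, enc)
        assert e1.shape == (8,)
        assert np.array_equal(e1, e2)

    def test_wrong_patch_size_rejected(self):
        enc = nn.make_encoder(np.random.default_rng(0))
        with pytest.raises(ValueError):
            encode_patch(np.zeros((16, 16)), enc)

    def test_one_encoder_forward_pass_per_step(self, rng):
        enc = nn.make_encoder(np.random.default_rng(0))
        net = nn.make_q_network(9 * 8, np.random.default_rng(1))
        pol = CNNPolicy(enc, net, h=H)
        f = 0.5
        for step in range(1, 11):
            f = pol.observe(rng.random((32, 32)), f)
            assert pol.encoder_calls == step

    def test_policy_emits_valid_steps(self, rng):
        enc = nn.make_encoder(np.random.default_rng(0))
        net = nn.make_q_network(9 * 8, np.random.default_rng(1))
        pol = CNNPolicy(enc, net, h=H)
        f = 0.5
        for _ in range(20):
            f2 = pol.observe(rng.random((32, 32)), f)
            assert 0.0 <= f2 <= 1.0
            assert min(abs(f2 - f - a) for a in (-H, 0.0, H)) < 1e-12
            f = f2


class TestCheckpoints:
    def test_mlp_checkpoint_roundtrip(self, tmp_path, rng):
        net = nn.make_q_network(16, np.random.default_rng(3))
        path = save_checkpoint(
            tmp_path / "p.npz", kind="learned_mlp", network=net, metric="mgm",
            normalise=True,
        )
        pol = load_policy(path)
        ref = LearnedScalarPolicy(net, metric="mgm", normalise=True, probe_start=True)
        f1 = f2 = 0.5
        for _ in range(6):
            patch = rng.random((32, 32))
            f1 = pol.observe(patch, f1)
            f2 = ref.observe(patch, f2)
            assert f1 == f2

    def test_cnn_checkpoint_roundtrip(self, tmp_path, rng):
        enc = nn.make_encoder(np.random.default_rng(0))
        net = nn.make_q_network(72, np.random.default_rng(1))
        path = save_checkpoint(
            tmp_path / "c.npz", kind="learned_cnn", network=net, encoder=enc
        )
        pol = load_policy(path)
        ref = CNNPolicy(enc, net, probe_start=True)
        f1 = f2 = 0.2
        for _ in range(4):
            patch = rng.random((32, 32))
            f1 = pol.observe(patch, f1)
            f2 = ref.observe(patch, f2)
            assert f1 == f2

    def test_oracle_policy_tracks_fstar_exactly(self, tiny_scan):
        from videoaf.evaluation import evaluate

        res = evaluate(OraclePolicy(tiny_scan), tiny_scan, seed=0)
        assert res.mae == 0.0
        assert res.in_focus_pct() == 100.0
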