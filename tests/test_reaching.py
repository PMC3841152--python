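import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bgsr.reaching import (
    ArmParams,
    BGState,
    MCWeights,
    Regime,
    RLConfig,
    bg_update,
    classify_regime,
    default_targets,
    forward_kinematics,
    run_episode,
    td_error,
    train_mc,
    training_run,
    tsv,
    value,
)


def _logit(y):
    return np.log(y / (1 - y))


class TestArm:
    def test_balanced_activations_give_midrange_angles(self):
        arm = ArmParams()
        th1, th2, _ = forward_kinematics([0.4, 0.4, 0.9, 0.9], arm)
        assert th1 == pytest.approx(0.0)
        assert th2 == pytest.approx(np.pi / 2)

    def test_straight_arm_endpoint(self):
        arm = ArmParams(theta1_range=(-1.0, 1.0), theta2_range=(-1.0, 1.0))
        _, _, X = forward_kinematics([0.5, 0.5, 0.5, 0.5], arm)
        assert X == pytest.approx([2.0, 0.0])

    def test_shoulder_angle_monotone_in_agonist(self):
        arm = ArmParams()
        angles = [forward_kinematics([g1, 0.5, 0.5, 0.5], arm)[0]
                  for g1 in np.linspace(0, 1, 7)]
        assert all(a < b for a, b in zip(angles, angles[1:]))

    def test_angles_stay_inside_ranges(self):
        arm = ArmParams()
        rng = np.random.default_rng(0)
        for _ in range(50):
            th1, th2, _ = forward_kinematics(rng.uniform(-3, 3, 4), arm)
            assert arm.theta1_range[0] < th1 < arm.theta1_range[1]
            assert arm.theta2_range[0] < th2 < arm.theta2_range[1]

    def test_default_targets_are_reachable_points(self):
        arm = ArmParams()
        for X in default_targets(arm):
            assert np.hypot(*X) <= arm.L1 + arm.L2 + 1e-9


class TestCriticAndDopamine:
    def test_value_extremes_and_length_scale(self):
        assert value([0, 0], [0, 0], 1.0) == 1.0
        assert value([0, 0], [50, 0], 1.0) < 1e-12
        assert value([0, 0], [0.5, 0], 0.5) == pytest.approx(np.exp(-1))

    def test_value_decreases_with_distance(self):
        vals = [value([d, 0], [0, 0], 1.0) for d in (0.0, 0.3, 0.9, 2.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_td_error_arithmetic(self):
        assert td_error(0.0, 0.4, 0.4) == 0.0
        assert td_error(0.0, 0.6, 0.4) == pytest.approx(0.2)
        assert td_error(1.0, 0.6, 0.4) == pytest.approx(1.2)  # reward included

    def test_sigma_must_be_positive(self):
        with pytest.raises(ValueError):
            value([0, 0], [1, 0], 0.0)


class TestBGUpdate:
    def setup_method(self):
        self.cfg = RLConfig(kappa=0.0)
        self.state = BGState(
            g_bg=np.full(4, 0.5), dg=np.array([0.1, -0.2, 0.0, 0.05]),
            dg_prev=np.zeros(4),
        )

    def test_go_repeats_previous_increment(self):
        new, regime = bg_update(self.cfg.D_hi + 1.0, self.state, self.cfg,
                                np.random.default_rng(0))
        assert regime is Regime.GO
        assert np.allclose(new.dg, self.state.dg)

    def test_nogo_reverses_previous_increment(self):
        new, regime = bg_update(self.cfg.D_lo - 1.0, self.state, self.cfg,
                                np.random.default_rng(0))
        assert regime is Regime.NOGO
        assert np.allclose(new.dg, -self.state.dg)

    def test_explore_step_has_norm_eta(self):
        new, regime = bg_update(0.0, self.state, self.cfg, np.random.default_rng(0))
        assert regime is Regime.EXPLORE
        assert np.linalg.norm(new.dg) == pytest.approx(self.cfg.eta, abs=1e-12)

    def test_momentum_is_added_on_top(self):
        cfg = RLConfig(kappa=0.4)
        new, _ = bg_update(cfg.D_hi + 1.0, self.state, cfg, np.random.default_rng(0))
        assert np.allclose(new.dg, 1.4 * self.state.dg)

    def test_output_accumulates_within_bounds(self):
        new, _ = bg_update(self.cfg.D_hi + 1.0, self.state, self.cfg,
                           np.random.default_rng(0))
        assert np.allclose(new.g_bg, np.clip(self.state.g_bg + new.dg, 0, 1))

    @given(st.floats(-5, 5, allow_nan=False))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_regime_partition_is_exact(self, delta):
        cfg = RLConfig()
        regime = classify_regime(delta, cfg)
        if delta > cfg.D_hi:
            assert regime is Regime.GO
        elif delta < cfg.D_lo:
            assert regime is Regime.NOGO
        else:
            assert regime is Regime.EXPLORE


class TestEpisodes:
    def test_perfect_cortex_reaches_immediately(self):
        arm = ArmParams()
        targets = default_targets(arm)
        # weights whose perceptron output reproduces the canonical activation
        from bgsr.reaching import _CANONICAL_G

        W = MCWeights(_logit(np.array(_CANONICAL_G).T))
        cfg = RLConfig(alpha=1.0, beta=0.0, targets=targets)
        res = run_episode(2, W, cfg, arm, np.random.default_rng(0))
        assert res.success and res.steps == 0

    def test_no_exploration_means_no_movement(self):
        cfg = RLConfig(alpha=0.0, beta=1.0, eta=0.0, max_steps=200)
        res = run_episode(1, MCWeights.random(np.random.default_rng(1)), cfg,
                          ArmParams(), np.random.default_rng(2))
        assert not res.success
        assert np.ptp(res.d) == pytest.approx(0.0, abs=1e-12)

    def test_go_step_keeps_climbing_value_on_average(self):
        # an explore step that raised the value, repeated once (Go, kappa=0),
        # continues to raise the value in expectation: the hill-climbing
        # property the bistable reduction relies on
        cfg = RLConfig(kappa=0.0)
        arm = ArmParams()
        target = np.asarray(default_targets(arm)[0])
        rng = np.random.default_rng(40)
        deltas_after_go = []
        while len(deltas_after_go) < 300:
            state = BGState.initial(rng.uniform(0.2, 0.8, 4))
            _, _, X = forward_kinematics(state.g_bg, arm)
            v0 = value(X, target, cfg.sigma_V)
            state, _ = bg_update(0.0, state, cfg, rng)  # explore
            _, _, X = forward_kinematics(state.g_bg, arm)
            v1 = value(X, target, cfg.sigma_V)
            d1 = td_error(0.0, v1, v0)
            if d1 > cfg.D_hi:
                state, regime = bg_update(d1, state, cfg, rng)
                assert regime is Regime.GO
                _, _, X = forward_kinematics(state.g_bg, arm)
                deltas_after_go.append(td_error(0.0, value(X, target, cfg.sigma_V), v1))
        assert np.mean(deltas_after_go) > 0

    def test_untrained_bg_beats_random_walk_baseline(self):
        arm = ArmParams()
        W = MCWeights.random(np.random.default_rng(0))
        cfg = RLConfig(max_steps=200)
        walk = dataclasses.replace(cfg, D_hi=1e9, D_lo=-1e9)  # always Explore

        def rate(c):
            wins = 0
            for k in range(100):
                rng = np.random.default_rng([10, k])
                wins += run_episode(1 + k % 4, W, c, arm, rng).success
            return wins / 100

        bg, rw = rate(cfg), rate(walk)
        assert bg > rw + 0.15

    def test_budget_exhaustion_is_a_normal_outcome(self):
        cfg = RLConfig(max_steps=3)
        res = run_episode(1, MCWeights.random(np.random.default_rng(4)), cfg,
                          ArmParams(), np.random.default_rng(5))
        assert res.steps == 3 and not res.success

    def test_episode_log_layout(self):
        cfg = RLConfig(max_steps=20)
        res = run_episode(3, MCWeights.random(np.random.default_rng(6)), cfg,
                          ArmParams(), np.random.default_rng(7))
        frame = res.to_frame()
        assert list(frame.columns) == [
            "step", "theta1", "theta2", "x", "y", "d", "V", "delta", "regime",
        ]
        assert set(frame["regime"]) <= {"Go", "NoGo", "Explore"}


class TestLearning:
    def test_delta_rule_fixed_point(self):
        xi = tsv(1)
        W = MCWeights.random(np.random.default_rng(0))
        g_now = W.output(xi)
        W2 = train_mc(W, xi, g_now, eta_m=1.0)
        assert np.allclose(W2.W, W.W)

    def test_delta_rule_contracts_output_error(self):
        xi = tsv(2)
        W = MCWeights.random(np.random.default_rng(1))
        target = np.array([0.8, 0.2, 0.6, 0.4])
        err = np.linalg.norm(target - W.output(xi))
        for _ in range(5):
            W = train_mc(W, xi, target, eta_m=0.5)
            new_err = np.linalg.norm(target - W.output(xi))
            assert new_err < err
            err = new_err

    def test_training_transfers_control_to_cortex(self):
        report = training_run(seed=3)
        assert report.post_success_rate > report.pre_success_rate
        assert report.post_success_rate >= 0.8

    def test_tsv_is_one_hot(self):
        assert tsv(3).tolist() == [0, 0, 1, 0]
        with pytest.raises(ValueError):
            tsv(5)
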