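"""Weighted up-down staircase: update rules, reversals, termination, estimate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ratesync import staircase as sc
from ratesync import synthetic_data as synth


def walk(responses, config=None):
    config = config or sc.StaircaseConfig()
    state = sc.new_state(config)
    for r in responses:
        if sc.is_complete(state, config):
            break
        state = sc.update(state, config, r)
    return state, config


class TestStartValues:
    def test_linear_20_to_27_percent(self):
        vals = sc.start_values(np.linspace(4, 15, 8))
        assert np.allclose(vals, [0.20, 0.21, 0.22, 0.23, 0.24, 0.25, 0.26, 0.27])

    def test_training_values_are_start_plus_ten_percent(self):
        vals = sc.start_values(np.linspace(4, 15, 8)) + 0.10
        assert np.allclose(vals, np.arange(0.30, 0.3701, 0.01))

    def test_wrong_grid_size_rejected(self):
        with pytest.raises(ValueError):
            sc.start_values(np.linspace(4, 15, 7))


class TestUpdateRule:
    @pytest.mark.parametrize("d, correct, expected", [
        (0.20, True, 0.19),     # down by one step
        (0.20, False, 0.23),    # up by three steps
        (0.01, True, 0.005),    # at or below one step: halve instead
        (0.008, True, 0.004),   # below one step: halve
    ])
    def test_single_move(self, d, correct, expected):
        config = sc.StaircaseConfig(start_value=d)
        state = sc.update(sc.new_state(config), config, correct)
        assert state.current_d == pytest.approx(expected)

    def test_reversal_recorded_on_direction_flip(self):
        state, _ = walk([True, True, False])
        assert len(state.reversal_values) == 1
        # the reversal value is the level presented on the flipping trial
        assert state.reversal_values[0] == pytest.approx(0.18)

    def test_first_movement_is_not_a_reversal(self):
        state, _ = walk([True])
        assert state.reversal_values == ()

    def test_step_halves_after_6_and_12_reversals(self):
        # alternate responses to force a reversal on every trial after the first
        responses = [True, False] * 20
        config = sc.StaircaseConfig()
        state = sc.new_state(config)
        steps = []
        for r in responses:
            if sc.is_complete(state, config):
                break
            state = sc.update(state, config, r)
            steps.append(state.current_step)
        steps = np.array(steps)
        assert set(np.round(steps, 6)) <= {0.01, 0.005, 0.0025}
        assert steps[-1] == pytest.approx(0.0025)
        assert np.all(np.diff(steps) <= 1e-12)   # non-increasing schedule

    def test_update_after_completion_rejected(self):
        state, config = walk([True, False] * 30)
        assert sc.is_complete(state, config)
        with pytest.raises(RuntimeError):
            sc.update(state, config, True)


class TestCompletion:
    def test_complete_iff_18_reversals(self):
        config = sc.StaircaseConfig()
        fresh = sc.new_state(config)
        assert not sc.is_complete(fresh, config)
        state, _ = walk([True, False] * 30)
        assert len(state.reversal_values) == 18
        assert sc.is_complete(state, config)

    def test_17_reversals_not_complete(self):
        config = sc.StaircaseConfig(stop_reversals=18)
        state = sc.new_state(config)
        n = 0
        for r in [True, False] * 30:
            if len(state.reversal_values) >= 17:
                break
            state = sc.update(state, config, r)
            n += 1
        assert not sc.is_complete(state, config)


class TestThresholdEstimate:
    def test_mean_of_last_six_reversals(self):
        state, config = walk([True, False] * 30)
        est = sc.estimate_threshold(state, config)
        assert est.threshold == pytest.approx(
            np.mean(state.reversal_values[-6:]))

    def test_incomplete_rejected(self):
        config = sc.StaircaseConfig()
        with pytest.raises(RuntimeError):
            sc.estimate_threshold(sc.new_state(config), config)

    def test_arithmetic_on_known_tail(self):
        vals = (0.04, 0.05, 0.04, 0.05, 0.04, 0.05)
        state = sc.StaircaseState(current_d=0.04, current_step=0.0025,
                                  reversal_values=(0.1,) * 12 + vals)
        est = sc.estimate_threshold(state, sc.StaircaseConfig())
        assert est.threshold == pytest.approx(0.045)


class _Always:
    def __init__(self, p):
        self.p = p

    def p_correct(self, d):
        return self.p


class TestRunStaircase:
    def test_deterministic_under_seed(self, observer):
        config = sc.StaircaseConfig()
        e1, log1 = sc.run_staircase(observer, config, seed=42)
        e2, log2 = sc.run_staircase(observer, config, seed=42)
        assert e1.threshold == e2.threshold
        assert log1.equals(log2)

    def test_perfect_observer_decays_toward_zero(self):
        config = sc.StaircaseConfig(max_trials=200)
        est, log = sc.run_staircase(_Always(1.0), config, seed=0)
        assert not est.complete
        assert est.threshold < 0.001
        assert (log["d"] > 0).all()

    def test_always_wrong_observer_clips_at_ceiling(self):
        config = sc.StaircaseConfig(max_trials=100)
        est, log = sc.run_staircase(_Always(0.0), config, seed=0)
        assert log["d"].max() <= config.ceiling + 1e-12
        assert est.threshold == pytest.approx(config.ceiling)

    def test_chance_observer_terminates(self):
        config = sc.StaircaseConfig()
        est, _ = sc.run_staircase(_Always(0.5), config, seed=1)
        assert est.complete

    def test_converges_near_75_percent_level(self, observer):
        # small-sample convergence check; the full 500-run equilibrium
        # simulation lives in the acceptance suite
        config = sc.StaircaseConfig()
        ests = [sc.run_staircase(observer, config, seed=s)[0].threshold
                for s in range(60)]
        pc = float(observer.p_correct(np.mean(ests)))
        assert abs(pc - 0.75) < 0.04


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=400))
def test_staircase_invariants_under_any_response_sequence(responses):
    """d stays positive, reversal count is monotone, steps only halve."""
    config = sc.StaircaseConfig()
    state = sc.new_state(config)
    prev_revs = 0
    for r in responses:
        if sc.is_complete(state, config):
            break
        state = sc.update(state, config, r)
        assert state.current_d > 0
        assert len(state.reversal_values) >= prev_revs
        assert len(state.reversal_values) <= config.stop_reversals
        prev_revs = len(state.reversal_values)
        assert round(state.current_step, 6) in {0.01, 0.005, 0.0025}
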