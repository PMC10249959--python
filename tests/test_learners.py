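import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trustlearn import (
    MAIN_MODELS,
    CategoryId,
    Choice,
    Params,
    TrialRecord,
    get_model,
    init_state,
    invest_probability,
    prediction_error,
    run_learner,
    update_ep,
)
from trustlearn.learners import compile_trials, initial_ep_vector, nll_compiled
from trustlearn.trial_model import trial_payoff

from conftest import make_ratings


def _trial(cat, choice, gamma, pid="p1", block=1, idx=1):
    return TrialRecord(pid, block, idx, cat, choice, gamma, trial_payoff(choice, gamma))


class TestInitState:
    def test_neutral_ratings_give_midpoint_beliefs(self, neutral_pre):
        state = init_state(neutral_pre, get_model("SimpleLearn"))
        assert state.ep[CategoryId.fair_white] == pytest.approx(0.5)
        assert state.ev[CategoryId.fair_white] == pytest.approx(2.0)

    def test_extreme_rating_maps_to_certainty(self):
        pre = make_ratings(means={CategoryId.fair_arab: 7.0})
        state = init_state(pre, get_model("SimpleLearn"))
        assert state.ep[CategoryId.fair_arab] == pytest.approx(1.0)
        assert state.ev[CategoryId.fair_arab] == pytest.approx(4.0)

    def test_lottery_starts_at_advertised_rate(self, neutral_pre):
        state = init_state(neutral_pre, get_model("SimpleLearn"))
        assert state.ep[CategoryId.lottery] == pytest.approx(0.5)

    def test_optimal_nonlearner_ignores_ratings(self):
        pre = make_ratings(means={CategoryId.fair_arab: 1.0, CategoryId.unfair_white: 7.0})
        state = init_state(pre, get_model("NoLearnOptimal"))
        assert state.ep[CategoryId.fair_arab] == pytest.approx(0.75)
        assert state.ep[CategoryId.unfair_white] == pytest.approx(0.25)
        assert state.ep[CategoryId.lottery] == pytest.approx(0.5)

    def test_missing_category_mean_is_an_error(self):
        pre = make_ratings()
        pre.ratings = {f: r for f, r in pre.ratings.items() if not f.startswith("fair_white")}
        with pytest.raises(ValueError, match="fair_white"):
            init_state(pre, get_model("SimpleLearn"))

    def test_ev_is_always_four_times_ep(self, neutral_pre):
        for name in MAIN_MODELS:
            state = init_state(neutral_pre, get_model(name))
            for cat in state.ep:
                assert state.ev[cat] == pytest.approx(4.0 * state.ep[cat])


class TestPredictionError:
    @pytest.mark.parametrize(
        "ep, gamma, expected", [(0.5, 1, 0.5), (1.0, 1, 0.0), (0.25, 0, -0.25)]
    )
    def test_signed_error(self, ep, gamma, expected):
        assert prediction_error(ep, gamma) == pytest.approx(expected)


class TestUpdate:
    def test_simple_learn_update(self, neutral_pre):
        spec = get_model("SimpleLearn")
        state = init_state(neutral_pre, spec)
        t = _trial(CategoryId.fair_white, Choice.invest, 1)
        new = update_ep(state, t, Params((0.16,), 1.0), spec)
        assert new.ep[CategoryId.fair_white] == pytest.approx(0.58)

    def test_only_the_trials_category_changes(self, neutral_pre):
        spec = get_model("SimpleLearn")
        state = init_state(neutral_pre, spec)
        new = update_ep(state, _trial(CategoryId.lottery, Choice.keep, 1),
                        Params((0.3,), 1.0), spec)
        for cat in state.ep:
            if cat is not CategoryId.lottery:
                assert new.ep[cat] == state.ep[cat]

    def test_zero_learning_rate_is_a_fixed_point(self, neutral_pre):
        spec = get_model("LG")
        state = init_state(neutral_pre, spec)
        new = update_ep(state, _trial(CategoryId.fair_arab, Choice.invest, 0),
                        Params((0.0, 0.0), 1.0), spec)
        assert new.ep == state.ep

    def test_no_learning_models_never_update(self, neutral_pre):
        for name in ("NoLearnBias", "NoLearnOptimal"):
            spec = get_model(name)
            state = init_state(neutral_pre, spec)
            new = update_ep(state, _trial(CategoryId.fair_white, Choice.invest, 0),
                            Params((), 1.0), spec)
            assert new.ep == state.ep

    def test_slot_routing_by_outcome(self, neutral_pre):
        # L2G2 routes (keep, gamma=1) to the relative-loss slot only
        spec = get_model("L2G2")
        state = init_state(neutral_pre, spec)
        params = Params((0.0, 0.0, 0.0, 0.5), 1.0)
        new = update_ep(state, _trial(CategoryId.fair_white, Choice.keep, 1), params, spec)
        assert new.ep[CategoryId.fair_white] == pytest.approx(0.75)

    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.integers(0, 1), st.integers(0, 1)),
            min_size=1, max_size=80,
        ),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(max_examples=60, derandomize=True)
    def test_beliefs_stay_probabilities(self, seq, alpha):
        # convex-combination update keeps ep in [0, 1] for any trial sequence
        cats = list(CategoryId)
        ep = {c: 0.5 for c in cats}
        for cat_i, inv, gamma in seq:
            c = cats[cat_i]
            ep[c] += alpha * (gamma - ep[c])
            assert 0.0 <= ep[c] <= 1.0


class TestSoftmax:
    @pytest.mark.parametrize("beta", [0.0, 0.5, 5.0, 1e5])
    def test_indifference_at_keep_value(self, beta):
        assert invest_probability(2.0, beta) == 0.5

    def test_zero_beta_is_indifferent_everywhere(self):
        for ev in (0.0, 1.3, 4.0):
            assert invest_probability(ev, 0.0) == 0.5

    def test_closed_form_value(self):
        assert invest_probability(4.0, 1.0) == pytest.approx(1.0 / (1.0 + math.exp(-2.0)))

    def test_greedy_limit(self):
        assert invest_probability(4.0, 1e6) == pytest.approx(1.0)
        assert invest_probability(0.0, 1e6) == pytest.approx(0.0)

    @given(st.floats(0, 4), st.floats(0, 4), st.floats(0.01, 100))
    @settings(max_examples=60, derandomize=True)
    def test_monotone_in_expected_value(self, ev1, ev2, beta):
        p1, p2 = invest_probability(ev1, beta), invest_probability(ev2, beta)
        assert 0.0 <= p1 <= 1.0
        if ev1 < ev2:
            assert p1 <= p2

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            invest_probability(2.0, -1.0)


def _fair_sequence(n, pid="p1", rate=0.75, seed=0):
    rng = np.random.default_rng(seed)
    gammas = ([1] * round(rate * n) + [0] * (n - round(rate * n)))
    rng.shuffle(gammas)
    return [
        _trial(CategoryId.fair_white, Choice.invest, g, pid=pid, block=1, idx=i + 1)
        for i, g in enumerate(gammas)
    ]


class TestRunLearner:
    def test_empty_trials_give_empty_trajectory(self, neutral_pre):
        assert run_learner([], neutral_pre, Params((0.16,), 1.0), get_model("SimpleLearn")) == []

    def test_choice_probability_precedes_update(self, neutral_pre):
        # first step must use the initial belief, untouched by trial 1's outcome
        traj = run_learner(
            [_trial(CategoryId.fair_white, Choice.invest, 1)],
            neutral_pre, Params((0.5,), 1.0), get_model("SimpleLearn"),
        )
        assert traj[0].ep == pytest.approx(0.5)
        assert traj[0].p_invest == pytest.approx(0.5)

    def test_optimal_nonlearner_has_constant_policy(self, neutral_pre):
        beta = 1.7
        traj = run_learner(
            _fair_sequence(36), neutral_pre, Params((), beta), get_model("NoLearnOptimal")
        )
        expected = invest_probability(3.0, beta)
        assert all(step.p_invest == pytest.approx(expected) for step in traj)

    def test_simple_learn_converges_toward_base_rate(self, neutral_pre):
        traj_trials = _fair_sequence(36)
        run = run_learner(traj_trials, neutral_pre, Params((0.16,), 1.0),
                          get_model("SimpleLearn"))
        # belief after the last update: one more manual step from final snapshot
        last = run[-1]
        final_ep = last.ep + 0.16 * (traj_trials[-1].partner_response - last.ep)
        assert abs(final_ep - 0.75) < 0.25

    def test_unsorted_trials_rejected(self, neutral_pre):
        trials = list(reversed(_fair_sequence(5)))
        with pytest.raises(ValueError, match="sorted"):
            run_learner(trials, neutral_pre, Params((0.16,), 1.0), get_model("SimpleLearn"))

    def test_multiple_participants_rejected(self, neutral_pre):
        trials = _fair_sequence(2, pid="a") + _fair_sequence(2, pid="b")
        with pytest.raises(ValueError, match="participants"):
            run_learner(trials, neutral_pre, Params((0.16,), 1.0), get_model("SimpleLearn"))

    def test_all_learning_models_coincide_with_equal_rates(self, neutral_pre,
                                                           simple_learn_agent):
        # nesting: with every slot set to the same alpha, all learning models
        # produce the same trajectory
        _, trials = simple_learn_agent
        alpha, beta = 0.23, 1.1
        ref = None
        for name in ("L2G2", "LGK", "LG", "Reputation", "SimpleLearn"):
            spec = get_model(name)
            traj = run_learner(trials, neutral_pre,
                               Params((alpha,) * spec.n_alpha_slots, beta), spec)
            probs = [s.p_invest for s in traj]
            if ref is None:
                ref = probs
            else:
                assert probs == pytest.approx(ref)

    def test_reputation_model_is_choice_blind(self, neutral_pre, simple_learn_agent):
        _, trials = simple_learn_agent
        spec = get_model("Reputation")
        params = Params((0.3, 0.1), 0.9)
        flipped = [
            TrialRecord(t.participant_id, t.block, t.trial_index, t.category,
                        Choice.keep if t.choice is Choice.invest else Choice.invest,
                        t.partner_response,
                        trial_payoff(Choice.keep if t.choice is Choice.invest else Choice.invest,
                                     t.partner_response))
            for t in trials
        ]
        t1 = run_learner(trials, neutral_pre, params, spec)
        t2 = run_learner(flipped, neutral_pre, params, spec)
        assert [s.ep for s in t1] == pytest.approx([s.ep for s in t2])


class TestCompiledPath:
    def test_compiled_nll_matches_trajectory_arithmetic(self, neutral_pre,
                                                        simple_learn_agent):
        _, trials = simple_learn_agent
        for name in MAIN_MODELS:
            spec = get_model(name)
            params = Params(tuple([0.21] * spec.n_alpha_slots), 0.8)
            traj = run_learner(trials, neutral_pre, params, spec)
            expected = -sum(
                math.log(s.p_invest if t.choice is Choice.invest else 1 - s.p_invest)
                for s, t in zip(traj, trials)
            )
            ct = compile_trials(trials, spec)
            ep0 = initial_ep_vector(neutral_pre, spec)
            assert nll_compiled(params.alphas, params.beta, ep0, ct) == pytest.approx(expected)
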