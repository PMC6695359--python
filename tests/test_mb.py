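import pytest

from stgtsim import (
    AgentParams,
    FeatureValues,
    WorldModel,
    advantage,
    apply_iti_revision,
    solve_q,
    update_reward,
    update_transition,
)
from conftest import make_ideal_model

IDEAL_Q = {
    ("s7", "eat"): 1.0,
    ("s5", "goM"): 0.8,
    ("s6", "goM"): 0.8,
    ("s4", "eng"): 0.8,
    ("s2", "eng"): 0.64,
    ("s3", "wait"): 0.64,
    ("s1", "goM"): 0.64,
    ("s1", "goL"): 0.512,
    ("s1", "goE"): 0.512,
    ("s0", "goE"): 0.512,
}


def brute_force_q(model, graph, gamma, sweeps=500):
    """Independent fixed-point oracle: asynchronous sweeps in reversed
    state-action order over an explicit successor list."""
    pairs = list(graph.state_action_pairs())[::-1]
    q = dict.fromkeys(pairs, 0.0)
    for _ in range(sweeps):
        for s, a in pairs:
            total = model.reward(s, a)
            nxt = graph.next_state(s, a)
            if nxt is not None:
                cont = max(q[(nxt, a2)] for a2 in graph.actions(nxt))
                total += gamma * model.transition(s, a, nxt) * cont
            q[(s, a)] = total
    return q


class TestModelUpdates:
    def test_transition_update_moves_toward_one(self):
        m = WorldModel()
        update_transition(m, "s0", "goE", "s1", 0.03)
        assert m.transition("s0", "goE", "s1") == pytest.approx(0.03)

    def test_transition_closed_form_after_n_observations(self):
        m = WorldModel()
        for _ in range(50):
            update_transition(m, "s0", "goE", "s1", 0.03)
        assert m.transition("s0", "goE", "s1") == pytest.approx(1 - 0.97**50)

    def test_full_learning_rate_learns_in_one_step(self):
        m = WorldModel()
        update_transition(m, "s0", "goE", "s1", 1.0)
        assert m.transition("s0", "goE", "s1") == 1.0

    def test_reward_update(self):
        m = WorldModel()
        update_reward(m, "s7", "eat", 1.0, 0.03)
        assert m.reward("s7", "eat") == pytest.approx(0.03)

    def test_reward_fixed_point(self):
        m = WorldModel()
        update_reward(m, "s7", "eat", 1.0, 1.0)
        update_reward(m, "s7", "eat", 1.0, 0.5)
        assert m.reward("s7", "eat") == 1.0

    def test_reward_closed_form_after_n_rewarded_visits(self):
        m = WorldModel()
        for _ in range(50):
            update_reward(m, "s7", "eat", 1.0, 0.03)
        assert m.reward("s7", "eat") == pytest.approx(1 - 0.97**50)


class TestSolveQ:
    def test_zero_model_has_zero_fixed_point(self, standard_food):
        q = solve_q(WorldModel(), standard_food, gamma=0.8)
        assert all(v == 0.0 for v in q.q.values())

    def test_ideal_model_values(self, standard_food, ideal_model):
        q = solve_q(ideal_model, standard_food, gamma=0.8)
        for sa, expected in IDEAL_Q.items():
            assert q.value(*sa) == pytest.approx(expected, abs=1e-9)

    def test_matches_independent_fixed_point_oracle(self, standard_food, rng):
        for _ in range(20):
            m = WorldModel()
            for s, a in standard_food.state_action_pairs():
                nxt = standard_food.next_state(s, a)
                if nxt is not None and rng.random() < 0.9:
                    update_transition(m, s, a, nxt, float(rng.random()))
                update_reward(
                    m, s, a, standard_food.reward(s, a), float(rng.random())
                )
            mine = solve_q(m, standard_food, gamma=0.8)
            oracle = brute_force_q(m, standard_food, gamma=0.8)
            for sa, v in oracle.items():
                assert mine.q[sa] == pytest.approx(v, abs=1e-9)

    def test_halving_gamma_halves_one_step_from_terminal_value(
        self, standard_food, ideal_model
    ):
        q8 = solve_q(ideal_model, standard_food, gamma=0.8)
        q4 = solve_q(ideal_model, standard_food, gamma=0.4)
        assert q4.value("s4", "eng") == pytest.approx(q8.value("s4", "eng") / 2)


class TestAdvantage:
    def test_goal_action_is_the_unique_best_at_cs_onset(
        self, standard_food, ideal_model
    ):
        q = solve_q(ideal_model, standard_food, gamma=0.8)
        adv = advantage(q, standard_food, "s1")
        assert adv["goM"] == 0.0
        assert adv["goL"] == pytest.approx(-0.128)
        assert adv["goE"] == pytest.approx(-0.128)

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.8, 0.99])
    def test_mb_goal_preference_holds_for_any_gamma(self, standard_food, gamma):
        q = solve_q(make_ideal_model(standard_food), standard_food, gamma=gamma)
        adv = advantage(q, standard_food, "s1")
        assert adv["goM"] == 0.0
        assert adv["goL"] < 0.0

    def test_advantages_nonpositive_with_zero_max_on_random_models(
        self, standard_food, rng
    ):
        for _ in range(20):
            m = WorldModel()
            for s, a in standard_food.state_action_pairs():
                nxt = standard_food.next_state(s, a)
                if nxt is not None:
                    update_transition(m, s, a, nxt, float(rng.random()))
                update_reward(m, s, a, float(rng.random()), 1.0)
            q = solve_q(m, standard_food, gamma=0.8)
            for s in standard_food.states:
                adv = advantage(q, standard_food, s)
                assert max(adv.values()) == 0.0
                assert all(v <= 0.0 for v in adv.values())

    def test_advantages_insensitive_to_iti_revision(
        self, standard_food, ideal_model
    ):
        values = FeatureValues({"L": 0.5, "M": 0.5, "E": 0.5})
        q_before = solve_q(ideal_model, standard_food, gamma=0.8)
        adv_before = advantage(q_before, standard_food, "s1")
        apply_iti_revision(values, 0.1)
        q_after = solve_q(ideal_model, standard_food, gamma=0.8)
        assert advantage(q_after, standard_food, "s1") == adv_before


def test_transition_function_converges_on_traversed_edges():
    """After 500 trials T is near 1 on the always-traversed transitions and
    absent (0) on impossible triples."""
    from stgtsim import Agent, build_standard_task

    graph = build_standard_task("magazine")
    agent = Agent(graph, AgentParams(omega=0.5, u_iti=0.1), rng=7)
    for session in range(1, 11):
        for trial in range(1, 51):
            agent.run_trial(session=session, trial=trial)
    # s0-goE and the eat reward are visited exactly once per trial
    assert agent.model.transition("s0", "goE", "s1") == pytest.approx(
        1 - 0.97**500
    )
    assert agent.model.reward("s7", "eat") == pytest.approx(1 - 0.97**500)
    # only structurally possible triples ever appear
    for (s, a), row in agent.model.T.items():
        assert set(row) == {graph.next_state(s, a)}
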