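"""MDP construction, value iteration and wait-time analysis."""

import numpy as np
import pytest

from smilegames import (
    DyadState,
    Episode,
    GoalSpec,
    HazardModel,
    build_mdp,
    empirical_wait_distribution,
    value_iteration,
    wait_time_performance,
)
from smilegames.planner import KEEP, TOGGLE


def _flat_model(p, K=1):
    return HazardModel.from_table(np.full((2, 2, K), float(p)))


class TestGoalSpec:
    def test_mutual_reward_definition(self):
        goal = GoalSpec("mutual", "infant")
        assert goal.reward(1, 1) == 1
        assert goal.reward(1, 0) == 0
        assert goal.reward(0, 1) == 0

    def test_role_swaps_target_pair(self):
        assert GoalSpec("mother_only", "infant").agent_partner_target == (0, 1)
        assert GoalSpec("mother_only", "mother").agent_partner_target == (1, 0)
        assert GoalSpec("infant_only", "mother").agent_partner_target == (0, 1)
        assert GoalSpec("mother_only", "robot").agent_partner_target == (0, 1)

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError):
            GoalSpec("laughing")


class TestBuildMdp:
    def test_four_state_transitions_match_hand_enumeration(self):
        """K = K_a = 1: the 4-state problem equals a hand-written table."""
        h = 0.3
        mdp = build_mdp(_flat_model(h), GoalSpec("mutual"), gamma=0.9, K_a=1)
        assert mdp.n_states == 4
        # state index = a * 2 + p; keep leaves a, toggle flips it; the
        # partner flips with probability h regardless of cell here
        for s in range(4):
            a, p = divmod(s, 2)
            for u, a_next in ((KEEP, a), (TOGGLE, 1 - a)):
                assert mdp.next_stay[s, u] == a_next * 2 + p
                assert mdp.next_toggle[s, u] == a_next * 2 + (1 - p)
            assert mdp.hazard[s] == pytest.approx(h)
        assert mdp.reward.tolist() == [0, 0, 0, 1]

    def test_hazard_uses_pre_action_agent_state(self):
        """The partner's toggle probability is read at the agent state
        before the action takes effect (one-bin reaction latency)."""
        h = np.zeros((2, 2, 1))
        h[0, 0] = 0.1  # partner not smiling, agent not smiling
        h[0, 1] = 0.4  # partner not smiling, agent smiling
        mdp = build_mdp(
            HazardModel.from_table(h), GoalSpec("mutual"), gamma=0.9, K_a=1
        )
        s = 0  # a = 0, p = 0
        # even when the agent toggles to a = 1, the hazard is h[0, 0]
        assert mdp.hazard[s] == pytest.approx(0.1)

    def test_zero_hazard_partner_absorbing(self):
        mdp = build_mdp(_flat_model(0.0, K=3), GoalSpec("mutual"), K_a=2)
        plan = value_iteration(mdp)
        # from p = 0 the reward (1,1) is unreachable
        idx = mdp.state_index(DyadState(a=0, p=0))
        assert plan.V[idx] == pytest.approx(0.0, abs=1e-7)

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            build_mdp(_flat_model(0.1), GoalSpec("mutual"), gamma=1.0)


class TestValueIteration:
    def test_reward_everywhere_gives_closed_form(self):
        gamma = 0.9
        mdp = build_mdp(_flat_model(0.2, K=2), GoalSpec("mutual"), gamma=gamma, K_a=2)
        mdp.reward[:] = 1.0
        plan = value_iteration(mdp)
        assert np.allclose(plan.V, 1.0 / (1.0 - gamma), atol=1e-6)

    def test_small_gamma_policy_is_myopic(self, rng):
        """gamma -> 0: the optimal action maximizes one-step expected reward."""
        h = rng.uniform(0.05, 0.45, (2, 2, 2))
        model = HazardModel.from_table(h)
        mdp = build_mdp(model, GoalSpec("mother_only"), gamma=0.01, K_a=2)
        plan = value_iteration(mdp)
        R = mdp.reward
        one_step = np.stack(
            [
                (1 - mdp.hazard) * R[mdp.next_stay[:, u]]
                + mdp.hazard * R[mdp.next_toggle[:, u]]
                for u in (KEEP, TOGGLE)
            ],
            axis=1,
        )
        # wherever the myopic choice is strict, the plan must agree
        strict = np.abs(one_step[:, 0] - one_step[:, 1]) > 1e-6
        assert np.array_equal(
            plan.policy[strict], one_step.argmax(axis=1)[strict]
        )

    def test_matches_finite_horizon_backward_induction(self, rng):
        """Seeded random problems vs a 5,000-step DP oracle."""
        for seed in (0, 1, 2):
            r = np.random.default_rng(seed)
            h = r.uniform(0.0, 1.0, (2, 2, 3))
            model = HazardModel.from_table(h)
            gamma = 0.95
            for target in ("mutual", "mother_only"):
                mdp = build_mdp(model, GoalSpec(target), gamma=gamma, K_a=3)
                plan = value_iteration(mdp)
                V = np.zeros(mdp.n_states)
                R = mdp.reward
                hz = mdp.hazard[:, None]
                for _ in range(5000):
                    Q = (1 - hz) * (R[mdp.next_stay] + gamma * V[mdp.next_stay]) + hz * (
                        R[mdp.next_toggle] + gamma * V[mdp.next_toggle]
                    )
                    V = Q.max(axis=1)
                assert np.abs(plan.V - V).max() < 1e-6 / (1 - gamma)

    def test_value_bounded_by_discounted_total(self, mother_only_plan):
        gamma = mother_only_plan.gamma
        assert mother_only_plan.V.max() <= 1.0 / (1.0 - gamma) + 1e-9

    def test_relabeling_symmetry(self):
        """Flipping smile labels and swapping mutual <-> neither (and the
        two single-smile goals) yields the same optimal values."""
        rng = np.random.default_rng(5)
        h = rng.uniform(0.05, 0.45, (2, 2, 1))
        # relabeled plant: h'[s, o, t] = h[1-s, 1-o, t]
        h_flip = h[::-1, ::-1, :].copy()
        pairs = [("mutual", "neither"), ("mother_only", "infant_only")]
        for ga, gb in pairs:
            plan_a = value_iteration(
                build_mdp(HazardModel.from_table(h), GoalSpec(ga), gamma=0.9, K_a=1)
            )
            plan_b = value_iteration(
                build_mdp(HazardModel.from_table(h_flip), GoalSpec(gb), gamma=0.9, K_a=1)
            )
            # state (a, p) of problem A corresponds to (1-a, 1-p) of B
            for s in range(4):
                a, p = divmod(s, 2)
                s_flip = (1 - a) * 2 + (1 - p)
                assert plan_a.V[s] == pytest.approx(plan_b.V[s_flip], abs=1e-7)


class TestWaitTimePerformance:
    def test_frozen_smiling_partner_rewards_waiting(self):
        """Partner frozen smiling, goal mother-only: any own smile loses
        occupancy, so performance rises with wait time."""
        plan = value_iteration(
            build_mdp(_flat_model(0.0, K=2), GoalSpec("mother_only"), K_a=2)
        )
        curve = wait_time_performance(plan, DyadState(a=0, p=1), t_max=8)
        assert np.all(np.diff(curve) > 0)
        assert curve.argmax() == 8

    def test_frozen_smiling_partner_mutual_goal_smile_now(self):
        plan = value_iteration(
            build_mdp(_flat_model(0.0, K=2), GoalSpec("mutual"), K_a=2)
        )
        curve = wait_time_performance(plan, DyadState(a=0, p=1), t_max=8)
        assert curve.argmax() == 0
        assert np.all(np.diff(curve) < 0)

    def test_optimal_value_dominates_every_fixed_wait(self, mother_only_plan):
        mdp = mother_only_plan.mdp
        ctx = DyadState(a=0, p=1)
        curve = wait_time_performance(mother_only_plan, ctx, t_max=15)
        v_opt = mother_only_plan.V[mdp.state_index(ctx)] * (1 - mother_only_plan.gamma)
        assert np.all(curve <= v_opt + 1e-9)

    def test_negative_t_max_rejected(self, mother_only_plan):
        with pytest.raises(ValueError):
            wait_time_performance(mother_only_plan, DyadState(0, 1), t_max=-1)


class TestEmpiricalWaitDistribution:
    def _ep(self, agent, partner):
        agent = np.asarray(agent)
        return Episode(0, len(agent), agent, np.asarray(partner))

    def test_unit_wait_gives_point_mass(self):
        # agent toggles into context then out exactly 1 bin later
        agent = [1, 0, 1, 1, 0, 1]
        partner = [1] * 6
        dist = empirical_wait_distribution([self._ep(agent, partner)], DyadState(0, 1))
        assert dist.probs.to_dict() == {1: 1.0}
        assert dist.n_observed == 2

    def test_counting_oracle(self):
        # waits 1, 1, 2, 4 -> probabilities 0.5, 0.25, 0, 0.25 at t=1..4
        chunks = []
        for w in (1, 1, 2, 4):
            chunks += [1, 0] + [0] * (w - 1)
        agent = np.array(chunks + [1])
        partner = np.ones(len(agent), dtype=int)
        dist = empirical_wait_distribution([self._ep(agent, partner)], DyadState(0, 1))
        assert dist.probs.tolist() == [0.5, 0.25, 0.0, 0.25]
        assert dist.n_censored == 0

    def test_censored_waits_counted_not_included(self):
        agent = [1, 0, 0, 0]  # enters context, never toggles again
        dist = empirical_wait_distribution(
            [self._ep(agent, [1] * 4)], DyadState(0, 1)
        )
        assert dist.n_observed == 0 and dist.n_censored == 1
        assert dist.probs.empty

    def test_no_entries_empty_distribution(self):
        dist = empirical_wait_distribution(
            [self._ep([0, 0, 0], [0, 0, 0])], DyadState(0, 1)
        )
        assert dist.probs.empty and dist.n_observed == 0

    def test_synthetic_infant_resmiles_within_seconds(
        self, truth_hazard, mother_only_plan
    ):
        """A goal-directed synthetic infant re-smiles within a few
        seconds of stopping while mother smiles: short waits dominate,
        reflecting the tradeoff between immediate mother-only time and
        keeping mother's rising cessation hazard at bay."""
        from smilegames import GeneratorParams, extract_episodes, simulate_dyad

        params = GeneratorParams(n_sessions=30)
        sessions = simulate_dyad(
            truth_hazard,
            GoalSpec("mother_only"),
            agent_beta=20.0,
            params=params,
            seed=7,
            plan=mother_only_plan,
        )
        episodes = [
            ep for s in sessions for ep in extract_episodes(s, min_len_bins=2)
        ]
        dist = empirical_wait_distribution(episodes, DyadState(0, 1))
        assert dist.n_observed > 50
        assert 1 <= dist.probs.idxmax() <= 10
        assert dist.probs.loc[:10].sum() > 0.5

        # the incentive driving those re-smiles: the action-value
        # advantage of smiling again rises with mother's elapsed smile
        # time, as her cessation hazard ramps up
        mdp = mother_only_plan.mdp
        gap = np.array(
            [
                mother_only_plan.Q[mdp.state_index(DyadState(0, 1, 0, tp))][1]
                - mother_only_plan.Q[mdp.state_index(DyadState(0, 1, 0, tp))][0]
                for tp in range(24)
            ]
        )
        assert np.all(np.diff(gap) > 0)
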