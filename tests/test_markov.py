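"""Engine unit tests: validation, discounting, microsimulation, oracle."""
import numpy as np
import pytest

from ceasim.markov import (ConfigurationError, MarkovModelSpec, RewardSpec,
                           discount, simulate_cohort, simulate_individual,
                           solve_cohort_analytic, validate_model,
                           AnalyticIncompatibleError)
from ceasim.screening import DiagnosticTest, Strategy

from conftest import geometric_effect, make_survival_chain


@pytest.mark.parametrize("amount,rate,years,expected", [
    (100.0, 0.03, 0, 100.0),          # entry year undiscounted
    (100.0, 0.00, 37, 100.0),         # zero rate is the identity
    (100.0, 0.03, 1, 100.0 / 1.03),
    (50.0, 0.10, 2, 50.0 / 1.21),
])
def test_discount_closed_form(amount, rate, years, expected):
    assert discount(amount, rate, years) == pytest.approx(expected, abs=1e-9)


def test_discount_rejects_bad_inputs():
    with pytest.raises(ValueError):
        discount(100.0, 0.03, -1)
    with pytest.raises(ValueError):
        discount(100.0, 1.5, 1)


class TestValidateModel:
    def test_well_formed_chain_has_no_violations(self, survival_chain):
        spec, _, params = survival_chain
        assert validate_model(spec, params) == []

    def test_deficient_row_named(self):
        def transition(state, age, params, action=None):
            if state == "A" and age >= 50:
                return {"A": 0.6, "B": 0.3}     # sums to 0.9
            return {state: 1.0} if state == "B" else {"A": 0.9, "B": 0.1}

        spec = MarkovModelSpec(("A", "B"), frozenset({"B"}), entry_age=49.0,
                               entry_state_distribution=(1.0, 0.0),
                               transition_fn=transition, max_age=51.0)
        violations = validate_model(spec, {})
        assert len(violations) == 1
        v = violations[0]
        assert (v.state, v.age, v.rule) == ("A", 50.0, "row-sum")

    def test_leaky_absorbing_state_flagged(self):
        def transition(state, age, params, action=None):
            if state == "Death":
                return {"Death": 0.99, "Alive": 0.01}
            return {"Alive": 0.8, "Death": 0.2}

        spec = MarkovModelSpec(("Alive", "Death"), frozenset({"Death"}),
                               entry_age=0.0,
                               entry_state_distribution=(1.0, 0.0),
                               transition_fn=transition, max_age=1.0)
        rules = {v.rule for v in validate_model(spec, {})}
        assert rules == {"absorbing-self-loop"}

    def test_bad_entry_distribution_flagged(self, survival_chain):
        spec, _, params = survival_chain
        bad = MarkovModelSpec(spec.state_ids, spec.absorbing, spec.entry_age,
                              (0.7, 0.2), spec.transition_fn, max_age=5.0)
        assert any(v.rule == "entry-distribution"
                   for v in validate_model(bad, params))


class TestSimulateIndividual:
    def test_entry_in_absorbing_state_is_trivial(self, survival_chain):
        spec, rewards, params = survival_chain
        dead_entry = MarkovModelSpec(spec.state_ids, spec.absorbing, 0.0,
                                     (0.0, 1.0), spec.transition_fn)
        traj = simulate_individual(dead_entry, rewards, None, params,
                                   np.random.default_rng(0))
        assert len(traj.records) == 1
        assert traj.discounted_cost == 0.0
        assert traj.discounted_effect == 0.0

    def test_certain_death_accrues_exactly_one_effect_unit(self):
        spec, rewards, params = make_survival_chain(1.0)
        traj = simulate_individual(spec, rewards, None, params,
                                   np.random.default_rng(0),
                                   discount_rate=0.0)
        assert traj.discounted_effect == 1.0
        assert [r.state for r in traj.records] == ["Alive"]

    def test_never_leaves_absorbing_state(self):
        spec, rewards, params = make_survival_chain(0.3)
        for seed in range(20):
            traj = simulate_individual(spec, rewards, None, params,
                                       np.random.default_rng(seed))
            states = [r.state for r in traj.records]
            assert "Dead" not in states    # sink entry terminates the path

    def test_discounted_total_bounded_by_undiscounted(self):
        spec, rewards, params = make_survival_chain(0.1, cost_rate=10.0)
        traj = simulate_individual(spec, rewards, None, params,
                                   np.random.default_rng(5),
                                   discount_rate=0.05)
        assert traj.discounted_cost <= traj.undiscounted_cost
        assert traj.discounted_effect <= traj.undiscounted_effect

    def test_absorbing_state_with_configured_reward_accrues_to_horizon(self):
        # an absorbing-but-lived-in state (e.g. blindness) keeps accruing
        # its utility: effect = u * annuity over the remaining horizon
        def transition(state, age, params, action=None):
            return {state: 1.0}

        u_b = 0.4
        spec = MarkovModelSpec(("Blind",), frozenset({"Blind"}),
                               entry_age=0.0, entry_state_distribution=(1.0,),
                               transition_fn=transition, max_age=10.0)
        rewards = RewardSpec(state_cost={}, state_effect={"Blind": u_b})
        traj = simulate_individual(spec, rewards, None, {},
                                   np.random.default_rng(0),
                                   discount_rate=0.03)
        annuity = sum(1.03 ** -t for t in range(10))
        assert traj.discounted_effect == pytest.approx(u_b * annuity)


class TestSimulateCohort:
    def test_same_seed_is_bit_identical(self, survival_chain):
        spec, rewards, params = survival_chain
        a = simulate_cohort(spec, rewards, None, params, 500, seed=11)
        b = simulate_cohort(spec, rewards, None, params, 500, seed=11)
        assert np.array_equal(a.costs, b.costs)
        assert np.array_equal(a.effects, b.effects)
        c = simulate_cohort(spec, rewards, None, params, 500, seed=12)
        assert not np.array_equal(a.effects, c.effects)

    def test_all_absorbing_cohort_is_zero(self, survival_chain):
        spec, rewards, params = survival_chain
        dead = MarkovModelSpec(spec.state_ids, spec.absorbing, 0.0,
                               (0.0, 1.0), spec.transition_fn)
        res = simulate_cohort(dead, rewards, None, params, 100, seed=0)
        assert res.mean_cost == 0.0 and res.mean_effect == 0.0

    def test_means_are_arithmetic_averages(self, survival_chain):
        spec, rewards, params = survival_chain
        res = simulate_cohort(spec, rewards, None, params, 1000, seed=3)
        assert res.mean_effect == pytest.approx(res.effects.mean(), rel=1e-12)
        assert res.mean_cost == pytest.approx(res.costs.mean(), rel=1e-12)

    def test_geometric_life_expectancy(self):
        spec, rewards, params = make_survival_chain(0.2)
        res = simulate_cohort(spec, rewards, None, params, 100_000, seed=7,
                              discount_rate=0.0)
        se = res.effects.std(ddof=1) / np.sqrt(res.n_individuals)
        assert abs(res.mean_effect - 5.0) < 3 * se

    def test_rejects_degenerate_inputs(self, survival_chain):
        spec, rewards, params = survival_chain
        with pytest.raises(ValueError):
            simulate_cohort(spec, rewards, None, params, 0, seed=0)
        never = MarkovModelSpec(("A",), frozenset(), 0.0, (1.0,),
                                lambda s, a, p, act=None: {"A": 1.0},
                                max_age=None)
        with pytest.raises(ConfigurationError):
            simulate_cohort(never, RewardSpec({}, {"A": 1.0}), None, {},
                            10, seed=0, max_cycles=50)


class TestAnalyticSolver:
    def test_absorbing_start_is_zero(self, survival_chain):
        spec, rewards, params = survival_chain
        dead = MarkovModelSpec(spec.state_ids, spec.absorbing, 0.0,
                               (0.0, 1.0), spec.transition_fn)
        assert solve_cohort_analytic(dead, rewards, params) == (0.0, 0.0)

    @pytest.mark.parametrize("rate", [0.0, 0.03])
    def test_geometric_closed_form(self, rate):
        spec, rewards, params = make_survival_chain(0.2)
        _, effect = solve_cohort_analytic(spec, rewards, params,
                                          discount_rate=rate)
        assert effect == pytest.approx(geometric_effect(0.2, rate),
                                       abs=1e-9)

    def test_monotone_in_discount_rate(self):
        spec, rewards, params = make_survival_chain(0.1, cost_rate=100.0)
        totals = [solve_cohort_analytic(spec, rewards, params,
                                        discount_rate=r)
                  for r in (0.0, 0.02, 0.05, 0.10)]
        costs = [c for c, _ in totals]
        effects = [e for _, e in totals]
        assert costs == sorted(costs, reverse=True)
        assert effects == sorted(effects, reverse=True)

    def test_microsim_agrees_with_oracle_three_state(self):
        def transition(state, age, params, action=None):
            if state == "Well":
                return {"Well": 0.80, "Ill": 0.15, "Dead": 0.05}
            if state == "Ill":
                return {"Ill": 0.70, "Dead": 0.30}
            return {"Dead": 1.0}

        spec = MarkovModelSpec(("Well", "Ill", "Dead"), frozenset({"Dead"}),
                               0.0, (1.0, 0.0, 0.0), transition)
        rewards = RewardSpec(state_cost={"Well": 100.0, "Ill": 900.0},
                             state_effect={"Well": 1.0, "Ill": 0.6},
                             event_cost={("Ill", "Dead"): 500.0})
        cost, effect = solve_cohort_analytic(spec, rewards, {},
                                             discount_rate=0.03)
        res = simulate_cohort(spec, rewards, None, {}, 50_000, seed=123,
                              discount_rate=0.03)
        for mc, exact, vec in ((res.mean_cost, cost, res.costs),
                               (res.mean_effect, effect, res.effects)):
            se = vec.std(ddof=1) / np.sqrt(len(vec))
            assert abs(mc - exact) < 3 * se

    def test_rejects_transition_modifying_screening(self):
        spec, rewards, params = make_survival_chain(0.2)
        test = DiagnosticTest(sensitivity={"Alive": 0.9}, specificity={},
                              fee=1.0)
        strategy = Strategy(test, 1.0,
                            {("positive", "Alive"): "treat-invasive",
                             ("negative", "Alive"): "none"})
        with pytest.raises(AnalyticIncompatibleError):
            solve_cohort_analytic(spec, rewards, params, strategy=strategy)

    def test_non_modifying_screening_fees_fold_exactly(self):
        spec, rewards, params = make_survival_chain(0.25)
        test = DiagnosticTest(sensitivity={}, specificity={"Alive": 0.9},
                              fee=8.0)
        strategy = Strategy(test, 2.0,
                            {("positive", "Alive"): "monitor",
                             ("negative", "Alive"): "none"})
        cost, _ = solve_cohort_analytic(spec, rewards, params,
                                        discount_rate=0.0,
                                        strategy=strategy)
        # 2 applications x fee 8 per surviving cycle: 16 * E[life-years]
        assert cost == pytest.approx(16.0 * geometric_effect(0.25, 0.0),
                                     abs=1e-9)
        res = simulate_cohort(spec, rewards, strategy, params, 50_000,
                              seed=5, discount_rate=0.0)
        se = res.costs.std(ddof=1) / np.sqrt(len(res.costs))
        assert abs(res.mean_cost - cost) < 3 * se
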