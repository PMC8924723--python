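"""PSA sampling, percentile intervals, sweeps and threshold detection."""
import numpy as np
import pandas as pd
import pytest

from ceasim.psa import (DISCOUNT_GRID, ParameterDistribution,
                        ParameterFitError, UnknownParameterError,
                        evaluate_point, find_threshold, one_way_sweep,
                        percentile_ci, run_psa, sample_parameters)
from ceasim.synthetic import generate_known_truth_scenario
from ceasim.use_cases import run_arms

from conftest import make_break_even_scenario


class TestParameterDistribution:
    def test_fixed_passes_through(self):
        dists = [ParameterDistribution("a", "fixed", mean=0.25),
                 ParameterDistribution("b", "fixed", mean=120.0)]
        sampled = sample_parameters(dists, np.random.default_rng(0))
        assert sampled == {"a": 0.25, "b": 120.0}

    def test_uniform_moments(self):
        d = ParameterDistribution("u", "uniform", low=0.1, high=0.3)
        x = d.rvs(np.random.default_rng(1), 100_000)
        se = (0.3 - 0.1) / np.sqrt(12) / np.sqrt(len(x))
        assert abs(x.mean() - 0.2) < 3 * se
        assert x.min() >= 0.1 and x.max() <= 0.3

    @pytest.mark.parametrize("family,mean,ci", [
        ("beta", 0.2, (0.1, 0.3)),
        ("beta", 0.05, (0.02, 0.10)),
        ("gamma", 100.0, (60.0, 150.0)),
        ("gamma", 8.0, (5.0, 12.0)),
    ])
    def test_quantile_round_trip(self, family, mean, ci):
        d = ParameterDistribution("p", family, mean=mean, ci=ci)
        x = d.rvs(np.random.default_rng(3), 100_000)
        lo, hi = np.percentile(x, [2.5, 97.5])
        scale = 1.0 if family == "beta" else mean
        assert abs(lo - ci[0]) < 0.01 * scale
        assert abs(hi - ci[1]) < 0.01 * scale

    def test_mean_outside_ci_rejected(self):
        with pytest.raises(ParameterFitError, match="p_bad"):
            ParameterDistribution("p_bad", "beta", mean=0.5, ci=(0.1, 0.3))

    def test_bounds_are_respected(self):
        d = ParameterDistribution("p", "beta", mean=0.2, ci=(0.1, 0.3),
                                  bounds=(0.15, 0.22))
        x = d.rvs(np.random.default_rng(0), 10_000)
        assert x.min() >= 0.15 and x.max() <= 0.22

    def test_unordered_uniform_rejected(self):
        with pytest.raises(ParameterFitError):
            ParameterDistribution("u", "uniform", low=0.3, high=0.1)


class TestPercentileCI:
    def test_constant_vector(self):
        assert percentile_ci([4.0, 4.0, 4.0]) == (4.0, 4.0)

    def test_linear_interpolation_on_0_to_100(self):
        assert percentile_ci(np.arange(101.0)) == (2.5, 97.5)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        assert percentile_ci(x) == percentile_ci(rng.permutation(x))

    def test_rejects_singletons(self):
        with pytest.raises(ValueError):
            percentile_ci([1.0])


class TestRunPSA:
    def test_all_fixed_collapses_to_single_pair(self, break_even_scenario):
        dists = [ParameterDistribution("fee_ai", "fixed", mean=8.0)]
        result = run_psa(break_even_scenario, dists, n_psa=1,
                         n_individuals=50, master_seed=5)
        sim_seed = int(np.random.default_rng([5, 13, 0]).integers(2 ** 31))
        pair = run_arms(break_even_scenario, 50, sim_seed)
        assert result.draws.cost_ai[0] == pair.ai.mean_cost
        assert result.draws.effect_std[0] == pair.standard.mean_effect

    def test_same_master_seed_is_bit_identical(self, dentistry_paramset):
        scenario = dentistry_paramset.scenario()
        dists = dentistry_paramset.distributions
        a = run_psa(scenario, dists, n_psa=5, n_individuals=60,
                    master_seed=99)
        b = run_psa(scenario, dists, n_psa=5, n_individuals=60,
                    master_seed=99)
        for attr in ("cost_ai", "effect_ai", "cost_std", "effect_std"):
            assert np.array_equal(getattr(a.draws, attr),
                                  getattr(b.draws, attr))

    def test_interval_width_shrinks_with_cohort_size(self):
        kt = generate_known_truth_scenario(seed=4)
        widths = []
        for n in (100, 1000, 10_000):
            res = run_psa(kt.scenario, [], n_psa=25, n_individuals=n,
                          master_seed=0)
            lo, hi = percentile_ci(res.draws.effect_ai)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_summary_interval_brackets_mean(self, dentistry_paramset):
        scenario = dentistry_paramset.scenario()
        res = run_psa(scenario, dentistry_paramset.distributions, n_psa=12,
                      n_individuals=80, master_seed=1)
        for _, row in res.summary.iterrows():
            assert row["ci_low"] <= row["ci_high"]


class TestOneWaySweep:
    def test_inert_parameter_gives_constant_rows(self, break_even_scenario):
        scenario = break_even_scenario.with_params(inert=1.0)
        table = one_way_sweep(scenario, "inert", [0.5, 1.0, 2.0], seed=0,
                              n_individuals=30)
        assert table["delta_cost"].nunique() == 1
        assert table["delta_effect"].nunique() == 1

    def test_fee_sweep_monotone_costs_constant_effects(
            self, dentistry_paramset):
        scenario = dentistry_paramset.scenario()
        table = one_way_sweep(scenario, "fee", [0.0, 8.0, 16.0, 32.0],
                              seed=3, n_individuals=300)
        assert table["cost_ai"].is_monotonic_increasing
        assert np.ptp(table["cost_ai"]) > 0
        assert table["effect_ai"].nunique() == 1
        assert table["cost_std"].nunique() == 1

    def test_discount_zero_matches_disabled_discounting(
            self, break_even_scenario):
        pair_sweep = evaluate_point(break_even_scenario, "discount_rate",
                                    0.0, seed=2, n_individuals=40)
        pair_direct = run_arms(break_even_scenario, 40, 2, discount_rate=0.0)
        assert pair_sweep.ai.mean_cost == pair_direct.ai.mean_cost
        assert pair_sweep.delta_effect == pair_direct.delta_effect

    def test_unknown_parameter_is_named(self, break_even_scenario):
        with pytest.raises(UnknownParameterError, match="no_such"):
            one_way_sweep(break_even_scenario, "no_such", [1.0], seed=0,
                          n_individuals=10)

    def test_builtin_discount_grid(self, break_even_scenario):
        table = one_way_sweep(break_even_scenario, "discount_rate", seed=0,
                              n_individuals=20)
        assert len(table) == len(DISCOUNT_GRID)


class TestFindThreshold:
    def _evaluator(self, scenario, n=1):
        def evaluator(fee):
            return evaluate_point(scenario, "fee", fee, 0, n).delta_cost
        return evaluator

    def test_break_even_fee_is_sixteen(self, break_even_scenario):
        table = one_way_sweep(break_even_scenario, "fee",
                              [0.0, 8.0, 24.0, 32.0], seed=0,
                              n_individuals=1)
        crossing = find_threshold(table,
                                  evaluator=self._evaluator(
                                      break_even_scenario))
        assert crossing == pytest.approx(16.0, abs=0.01)

    def test_invariant_to_grid_refinement(self, break_even_scenario):
        ev = self._evaluator(break_even_scenario)
        coarse = one_way_sweep(break_even_scenario, "fee", [0.0, 32.0],
                               seed=0, n_individuals=1)
        fine = one_way_sweep(break_even_scenario, "fee",
                             np.linspace(0, 32, 17), seed=0,
                             n_individuals=1)
        a = find_threshold(coarse, evaluator=ev)
        b = find_threshold(fine, evaluator=ev)
        assert a == pytest.approx(b, abs=0.02)

    def test_constant_dominance_returns_none(self, break_even_scenario):
        table = one_way_sweep(break_even_scenario, "fee", [0.0, 4.0, 8.0],
                              seed=0, n_individuals=1)
        assert find_threshold(table) is None

    def test_non_monotone_criterion_warns_with_all_crossings(self):
        table = pd.DataFrame({"value": [0.0, 1.0, 2.0, 3.0],
                              "delta_cost": [-1.0, 1.0, -1.0, -2.0]})
        with pytest.warns(UserWarning, match="flips 2 times"):
            crossings = find_threshold(table)
        assert len(crossings) == 2

    def test_unsorted_sweep_rejected(self):
        table = pd.DataFrame({"value": [1.0, 0.0], "delta_cost": [1.0, -1.0]})
        with pytest.raises(ValueError):
            find_threshold(table)
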