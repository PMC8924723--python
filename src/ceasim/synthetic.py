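"""Synthetic, clearly-labelled parameter sets and known-truth scenarios.

The source cost-effectiveness models publish their transition tables only
in supplementary appendices that are not part of this artifact, so this
module generates complete, internally consistent stand-ins with the same
statistical structure: bounded probabilities with 95% intervals, gamma-like
cost uncertainty, a uniform band for caries progression, age-dependent
background mortality, and the printed anchors that *are* available — an
8-unit fee per AI application, 3% annual discounting, entry ages 50/12/40
and the stated screening schedules.  Every emitted set carries a
``synthetic: true`` provenance flag; nothing here approximates the source
models' actual tariffs or probabilities.

Known-truth scenarios are deliberately simple constant-hazard chains whose
expected discounted cost and effect have closed forms (fundamental-matrix
geometric sums), emitted together with those reference values so both the
analytic solver and the microsimulation engine can be checked against an
independent formula.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .markov import MarkovModelSpec, RewardSpec
from .psa import ParameterDistribution
from .screening import DiagnosticTest, Strategy
from .use_cases import BuiltModel, Scenario, USE_CASES

__all__ = [
    "ParamSet",
    "KnownTruthScenario",
    "generate_default_params",
    "generate_life_table",
    "generate_known_truth_scenario",
]

#: anchors printed in the underlying evaluation: fee per AI application (in
#: local currency units), annual discount rate, entry ages, screening
#: schedules (applications per year)
FEE_PER_APPLICATION = 8.0
DISCOUNT_RATE = 0.03
ENTRY_AGES = {"dermatology": 50.0, "dentistry": 12.0, "ophthalmology": 40.0}
SCHEDULES = {"dermatology": 1.0, "dentistry": 2.0, "ophthalmology": 0.5}
CURRENCIES = {"dermatology": "USD", "dentistry": "EUR",
              "ophthalmology": "BRL"}


@dataclass(frozen=True)
class ParamSet:
    """A complete synthetic parameter set for one use case."""

    use_case: str
    params: Mapping
    distributions: Sequence[ParameterDistribution]
    seed: int
    synthetic: bool = True

    def scenario(self, **kw) -> Scenario:
        return USE_CASES[self.use_case](self.params, **kw)


@dataclass(frozen=True)
class KnownTruthScenario:
    """A simple scenario plus closed-form reference values.

    ``reference`` holds the exact expected discounted cost and effect of a
    screening-free run of either arm (the arms are identical by
    construction, so every incremental quantity is exactly zero).
    """

    scenario: Scenario
    reference: Mapping[str, float]
    seed: int
    synthetic: bool = True


def generate_life_table(setting: str = "generic", seed: int = 0,
                        max_age: int = 110) -> np.ndarray:
    """Age-indexed annual death probability with a Gompertz-form hazard.

    Monotone non-decreasing, reaching probability 1 at ``max_age``.  The
    per-setting level constants are synthetic; the seed adds a small
    deterministic jitter so distinct synthetic populations differ.
    """
    levels = {"US": 3.2e-5, "Germany": 3.0e-5, "Brazil": 4.2e-5,
              "generic": 3.5e-5}
    if setting not in levels:
        raise ValueError(f"unknown setting {setting!r}; "
                         f"choose from {sorted(levels)}")
    rng = np.random.default_rng([int(seed), 41])
    a0 = levels[setting] * float(rng.uniform(0.95, 1.05))
    slope = 0.095 * float(rng.uniform(0.98, 1.02))
    ages = np.arange(max_age + 1, dtype=float)
    q = np.minimum(1.0, a0 * np.exp(slope * ages))
    q[-1] = 1.0
    return np.maximum.accumulate(q)


def _beta_ci(mean: float, kappa: float) -> tuple:
    lo, hi = stats.beta.ppf([0.025, 0.975], mean * kappa,
                            (1.0 - mean) * kappa)
    return float(lo), float(hi)


def _gamma_ci(mean: float, shape: float) -> tuple:
    lo, hi = stats.gamma.ppf([0.025, 0.975], shape, scale=mean / shape)
    return float(lo), float(hi)


def _prob_dist(name: str, mean: float, kappa: float = 150.0,
               bounds=(1e-6, 1.0 - 1e-6)) -> ParameterDistribution:
    lo, hi = _beta_ci(mean, kappa)
    return ParameterDistribution(name, "beta", mean=mean, ci=(lo, hi),
                                 bounds=bounds)


def _cost_dist(name: str, mean: float,
               shape: float = 50.0) -> ParameterDistribution:
    lo, hi = _gamma_ci(mean, shape)
    return ParameterDistribution(name, "gamma", mean=mean, ci=(lo, hi),
                                 bounds=(0.0, np.inf))


def _jitter(rng: np.random.Generator, value: float,
            rel: float = 0.10) -> float:
    return float(value * rng.uniform(1.0 - rel, 1.0 + rel))


def generate_default_params(use_case: str, seed: int = 0) -> ParamSet:
    """A plausible synthetic parameter set plus PSA distributions.

    Deterministic given the seed.  Disease probabilities and costs are
    jittered around synthetic anchors; diagnostic accuracies give the AI
    arm a modest edge over the standard of care, mirroring the comparison
    structure (not the values) of the source models.
    """
    if use_case not in USE_CASES:
        raise ValueError(f"unknown use case {use_case!r}; "
                         f"choose from {sorted(USE_CASES)}")
    rng = np.random.default_rng([int(seed), 17])
    setting = {"dermatology": "US", "dentistry": "Germany",
               "ophthalmology": "Brazil"}[use_case]
    life = generate_life_table(setting, seed=seed)
    common = {
        "entry_age": ENTRY_AGES[use_case],
        "max_age": 110.0,
        "schedule": SCHEDULES[use_case],
        "fee_ai": FEE_PER_APPLICATION,
        "background_mortality": life,
        "synthetic": True,
    }
    if use_case == "dermatology":
        params = {
            **common,
            "p_incidence": _jitter(rng, 0.004),
            "p_death_undetected": _jitter(rng, 0.10),
            "p_death_detected": _jitter(rng, 0.02),
            "p_remission": _jitter(rng, 0.30),
            "p_recurrence": _jitter(rng, 0.02),
            "u_undetected": 0.92, "u_detected": 0.80, "u_remission": 0.95,
            "cost_workup": _jitter(rng, 250.0),
            "cost_treatment_initial": _jitter(rng, 6000.0),
            "cost_treatment_cycle": _jitter(rng, 1200.0),
            "sens_ai": 0.90, "spec_ai": 0.85,
            "sens_standard": 0.82, "spec_standard": 0.82,
            "fee_exam": _jitter(rng, 35.0),
        }
        sampled = [
            _prob_dist("p_incidence", params["p_incidence"], kappa=4000.0),
            _prob_dist("p_death_undetected", params["p_death_undetected"]),
            _prob_dist("p_death_detected", params["p_death_detected"],
                       kappa=800.0),
            _prob_dist("p_remission", params["p_remission"]),
            _prob_dist("p_recurrence", params["p_recurrence"], kappa=800.0),
            _cost_dist("cost_workup", params["cost_workup"]),
            _cost_dist("cost_treatment_initial",
                       params["cost_treatment_initial"]),
            _cost_dist("cost_treatment_cycle",
                       params["cost_treatment_cycle"]),
        ]
    elif use_case == "dentistry":
        p_prog = _jitter(rng, 0.12)
        params = {
            **common,
            "treatment_path": "noninvasive",
            "prevalence_initial": 0.15, "prevalence_advanced": 0.05,
            "p_initiation": _jitter(rng, 0.03),
            "p_progression": p_prog,
            "rr_noninvasive": 0.40,
            "p_extraction_advanced": _jitter(rng, 0.08),
            "p_restoration_failure": _jitter(rng, 0.06),
            "p_rerestoration_failure": _jitter(rng, 0.09),
            "cost_restoration": _jitter(rng, 110.0),
            "cost_rerestoration": _jitter(rng, 190.0),
            "cost_extraction": _jitter(rng, 90.0),
            "cost_noninvasive": _jitter(rng, 12.0),
            "sens_ai_initial": 0.80, "sens_ai_advanced": 0.95,
            "spec_ai": 0.91,
            "sens_standard_initial": 0.60, "sens_standard_advanced": 0.90,
            "spec_standard": 0.88,
            "fee_exam": _jitter(rng, 10.0),
        }
        sampled = [
            _prob_dist("p_initiation", params["p_initiation"], kappa=2000.0),
            # progression uncertainty is a uniform band, per the evidence
            # structure for caries progression
            ParameterDistribution("p_progression", "uniform",
                                  low=0.8 * p_prog, high=1.2 * p_prog,
                                  bounds=(1e-6, 1.0 - 1e-6)),
            _prob_dist("p_extraction_advanced",
                       params["p_extraction_advanced"]),
            _prob_dist("p_restoration_failure",
                       params["p_restoration_failure"], kappa=500.0),
            _prob_dist("p_rerestoration_failure",
                       params["p_rerestoration_failure"], kappa=500.0),
            _cost_dist("cost_restoration", params["cost_restoration"]),
            _cost_dist("cost_rerestoration", params["cost_rerestoration"]),
            _cost_dist("cost_extraction", params["cost_extraction"]),
        ]
    else:   # ophthalmology
        params = {
            **common,
            "p_onset": _jitter(rng, 0.06),
            "p_progression": _jitter(rng, 0.07),
            "p_blindness_untreated": _jitter(rng, 0.12),
            "p_blindness_treated": _jitter(rng, 0.02),
            "u_no_dr": 0.90, "u_npdr": 0.85, "u_pdr": 0.70,
            "u_treated": 0.80, "u_blindness": 0.40,
            "cost_workup": _jitter(rng, 60.0),
            "cost_treatment": _jitter(rng, 1500.0),
            "cost_treated_cycle": _jitter(rng, 120.0),
            "sens_ai_npdr": 0.88, "sens_ai_pdr": 0.96, "spec_ai": 0.90,
            "sens_standard_npdr": 0.80, "sens_standard_pdr": 0.92,
            "spec_standard": 0.95,
            "fee_exam": _jitter(rng, 25.0),
        }
        sampled = [
            _prob_dist("p_onset", params["p_onset"], kappa=1500.0),
            _prob_dist("p_progression", params["p_progression"],
                       kappa=1500.0),
            _prob_dist("p_blindness_untreated",
                       params["p_blindness_untreated"], kappa=400.0),
            _prob_dist("p_blindness_treated",
                       params["p_blindness_treated"], kappa=1500.0),
            _prob_dist("u_npdr", params["u_npdr"], kappa=400.0),
            _prob_dist("u_treated", params["u_treated"], kappa=400.0),
            _cost_dist("cost_workup", params["cost_workup"]),
            _cost_dist("cost_treatment", params["cost_treatment"]),
            _cost_dist("cost_treated_cycle", params["cost_treated_cycle"]),
        ]
    return ParamSet(use_case, params, tuple(sampled), int(seed))


# ---------------------------------------------------------------------------
# known-truth scenarios
# ---------------------------------------------------------------------------

def _closed_form_totals(spec: MarkovModelSpec, rewards: RewardSpec,
                        params: Mapping, discount_rate: float,
                        discount_effects: bool = True) -> tuple:
    """Exact totals for an age-constant chain via the fundamental matrix.

    total = e₀ᵀ (I − d·Q)⁻¹ (r + P∘E·1) restricted to transient states,
    with d the per-cycle discount factor and Q the transient block.  This
    is an independent closed form: no occupancy iteration is involved.
    """
    sc, se, ec, ee, _ = rewards.arrays(spec.state_ids)
    absorbing = spec.absorbing_mask()
    k = len(spec.state_ids)
    P = np.zeros((k, k))
    for i, s in enumerate(spec.state_ids):
        if absorbing[i]:
            P[i, i] = 1.0
        else:
            P[i] = spec.row(s, spec.entry_age, params, None)
    T = ~absorbing
    Q = P[np.ix_(T, T)]
    d = 1.0 / (1.0 + discount_rate)
    de = d if discount_effects else 1.0
    e0 = spec.entry_state_distribution[T]
    cost_rate = sc[T] + (P * ec).sum(axis=1)[T]
    effect_rate = se[T] + (P * ee).sum(axis=1)[T]
    occ_c = np.linalg.solve((np.eye(T.sum()) - d * Q).T, e0)
    occ_e = np.linalg.solve((np.eye(T.sum()) - de * Q).T, e0)
    return float(occ_c @ cost_rate), float(occ_e @ effect_rate)


def generate_known_truth_scenario(use_case: str = "generic",
                                  seed: int = 0) -> KnownTruthScenario:
    """A constant-hazard chain with closed-form expected cost and effect.

    Even seeds yield the two-state survival chain (Alive → Dead with a
    constant death probability: discounted life expectancy is a geometric
    sum); odd seeds a three-state progressive chain.  Both arms carry
    identical perfect, equal-fee tests, so the reference incremental
    quantities are exactly zero.
    """
    rng = np.random.default_rng([int(seed), 23])
    p = float(rng.uniform(0.05, 0.40))
    cost_rate = float(rng.uniform(50.0, 500.0))
    discount_rate = float(rng.choice([0.0, 0.03, 0.05]))
    if seed % 2 == 0:
        states = ("Alive", "Dead")
        absorbing = {"Dead"}
        entry = (1.0, 0.0)

        def transition(state, age, params_, action=None):
            if state == "Alive":
                return {"Alive": 1.0 - params_["p_death"],
                        "Dead": params_["p_death"]}
            return {"Dead": 1.0}

        rewards = RewardSpec(state_cost={"Alive": cost_rate},
                             state_effect={"Alive": 1.0})
        params = {"p_death": p, "fee_ai": 0.0}
        healthy = "Alive"
    else:
        states = ("Well", "Ill", "Dead")
        absorbing = {"Dead"}
        entry = (1.0, 0.0, 0.0)
        p_ill = float(rng.uniform(0.05, 0.30))
        ill_cost = cost_rate * 3.0
        u_ill = float(rng.uniform(0.5, 0.9))

        def transition(state, age, params_, action=None):
            if state == "Well":
                return {"Well": 1.0 - params_["p_ill"] - params_["p_death"],
                        "Ill": params_["p_ill"],
                        "Dead": params_["p_death"]}
            if state == "Ill":
                return {"Ill": 1.0 - 2.0 * params_["p_death"],
                        "Dead": 2.0 * params_["p_death"]}
            return {"Dead": 1.0}

        rewards = RewardSpec(
            state_cost={"Well": cost_rate, "Ill": ill_cost},
            state_effect={"Well": 1.0, "Ill": u_ill},
            event_cost={("Ill", "Dead"): cost_rate})
        params = {"p_death": min(p, 0.45), "p_ill": p_ill, "fee_ai": 0.0}
        healthy = "Well"

    spec = MarkovModelSpec(states, frozenset(absorbing), entry_age=0.0,
                           entry_state_distribution=entry,
                           transition_fn=transition, max_age=None)

    def build(params_: Mapping) -> BuiltModel:
        test = DiagnosticTest(sensitivity={},
                              specificity={healthy: 1.0},
                              fee=float(params_.get("fee_ai", 0.0)),
                              label="perfect")
        decision = {("positive", healthy): "none",
                    ("negative", healthy): "none"}
        strat = Strategy(test, 1.0, decision, label="perfect")
        return BuiltModel(spec, rewards, {"ai": strat, "standard": strat})

    scenario = Scenario(f"known-truth #{seed}", use_case, build,
                        dict(params), discount_rate=discount_rate)
    cost, effect = _closed_form_totals(spec, rewards, params, discount_rate)
    reference = {"expected_cost": cost, "expected_effect": effect,
                 "delta_cost": 0.0, "delta_effect": 0.0,
                 "discount_rate": discount_rate}
    return KnownTruthScenario(scenario, reference, int(seed))
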