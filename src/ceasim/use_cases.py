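"""The three concrete screening models built from flat parameter sets.

Each builder maps a flat parameter dictionary to a ``(model, rewards,
strategies)`` triple:

* **dermatology** — melanoma detection in a general population entering at
  age 50 (48 in part of the source literature; configurable).  Distinguishes
  melanoma-specific death from background mortality; effect unit is the QALY.
* **dentistry** — proximal caries detection at the level of a single
  permanent tooth entering at age 12; effect is one tooth-retention-year
  per cycle with the tooth in the mouth.  A ``treatment_path`` flag switches
  what happens to a detected initial lesion (non-invasive management versus
  immediate restoration), which also controls the harm done by false
  positives on sound surfaces.
* **ophthalmology** — diabetic retinopathy screening in a diabetic cohort
  entering at age 40, tested every other year; per-state utilities weight
  each life-year, blindness is absorbing.

Background mortality enters every model as an age-indexed annual death
probability composed with disease dynamics as competing events
(disease-specific transitions first, background death among the survivors).
State lists are defaults, not a closed world: the engine accepts any valid
model specification, so richer stagings are configuration-only extensions.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional

import numpy as np

from .markov import (MarkovModelSpec, RewardSpec, SimulationResult,
                     simulate_cohort)
from .screening import ConfigurationError, DiagnosticTest, Strategy

__all__ = [
    "BuiltModel",
    "Scenario",
    "ArmPair",
    "MissingParameterError",
    "build_melanoma_model",
    "build_caries_model",
    "build_retinopathy_model",
    "melanoma_scenario",
    "caries_scenario",
    "retinopathy_scenario",
    "run_arms",
    "USE_CASES",
]


class MissingParameterError(ConfigurationError):
    """A builder was called without a parameter it requires."""


def _require(params: Mapping, keys, use_case: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise MissingParameterError(
            f"{use_case}: missing required parameter(s) {missing}")


def _mortality(params: Mapping, age: float) -> float:
    table = np.asarray(params["background_mortality"], dtype=float)
    return float(table[min(int(age), len(table) - 1)])


def _with_background(dist: Mapping[str, float], bg: float,
                     death_state: str) -> Mapping[str, float]:
    """Compose disease outcomes with background death as competing risk.

    Mass routed to ``death_state`` is added on top; every non-death outcome
    keeps its share of the surviving probability.  Disease-specific death
    states already present in ``dist`` are untouched (they occurred first).
    """
    out: dict = {}
    for s, p in dist.items():
        out[s] = out.get(s, 0.0) + p * (1.0 - bg)
    survivors = sum(dist.values())
    out[death_state] = out.get(death_state, 0.0) + bg * survivors
    return out


@dataclass(frozen=True)
class BuiltModel:
    """A fully assembled use case: chain, rewards and both arms."""

    model: MarkovModelSpec
    rewards: RewardSpec
    strategies: Mapping[str, Strategy]   # keys "ai" and "standard"


@dataclass(frozen=True)
class Scenario:
    """A rebuildable analysis: builder + parameters + run-level settings.

    ``build(params)`` reassembles the triple from any (e.g. PSA-sampled)
    parameter set, which keeps diagnostic accuracies and fees — themselves
    parameters — in sync with the sampled values.
    """

    label: str
    use_case: str
    build: Callable[[Mapping], BuiltModel]
    params: Mapping
    currency: str = "USD"
    effect_unit: str = "QALY"
    discount_rate: float = 0.03
    discount_effects: bool = True

    def built(self, params: Optional[Mapping] = None) -> BuiltModel:
        return self.build(self.params if params is None else params)

    def with_params(self, **updates) -> "Scenario":
        return replace(self, params={**dict(self.params), **updates})


@dataclass(frozen=True)
class ArmPair:
    """Both arms of one run under common random numbers."""

    ai: SimulationResult
    standard: SimulationResult

    @property
    def delta_cost(self) -> float:
        return self.ai.mean_cost - self.standard.mean_cost

    @property
    def delta_effect(self) -> float:
        return self.ai.mean_effect - self.standard.mean_effect


def run_arms(scenario: Scenario, n: int, seed: int,
             params: Optional[Mapping] = None, *,
             discount_rate: Optional[float] = None) -> ArmPair:
    """Simulate the AI and standard arm with a shared seed (CRN)."""
    built = scenario.built(params)
    rate = scenario.discount_rate if discount_rate is None else discount_rate
    results = {}
    for arm in ("ai", "standard"):
        results[arm] = simulate_cohort(
            built.model, built.rewards, built.strategies[arm],
            params if params is not None else scenario.params,
            n, seed, discount_rate=rate,
            discount_effects=scenario.discount_effects)
    return ArmPair(results["ai"], results["standard"])


# ---------------------------------------------------------------------------
# dermatology: melanoma
# ---------------------------------------------------------------------------

_MELANOMA_REQUIRED = (
    "p_incidence", "p_death_undetected", "p_death_detected", "p_remission",
    "p_recurrence", "u_undetected", "u_detected", "u_remission",
    "cost_workup", "cost_treatment_initial", "cost_treatment_cycle",
    "sens_ai", "spec_ai", "sens_standard", "spec_standard",
    "fee_ai", "fee_exam", "background_mortality",
)

_MEL_STATES = ("Healthy", "Undetected melanoma", "Detected melanoma",
               "Remission", "Melanoma death", "Other death")


def _melanoma_transitions(state: str, age: float, params: Mapping,
                          action: Optional[str]) -> Mapping[str, float]:
    bg = _mortality(params, age)
    if state == "Healthy":
        p = params["p_incidence"]
        nat = {"Healthy": 1.0 - p, "Undetected melanoma": p}
    elif state == "Undetected melanoma":
        pd_ = params["p_death_undetected"]
        if action == "refer":     # detection → work-up → treatment
            nat = {"Melanoma death": pd_, "Detected melanoma": 1.0 - pd_}
        else:
            nat = {"Melanoma death": pd_, "Undetected melanoma": 1.0 - pd_}
    elif state == "Detected melanoma":
        pd_ = params["p_death_detected"]
        pr = params["p_remission"]
        nat = {"Melanoma death": pd_,
               "Remission": (1.0 - pd_) * pr,
               "Detected melanoma": (1.0 - pd_) * (1.0 - pr)}
    elif state == "Remission":
        pr = params["p_recurrence"]
        nat = {"Undetected melanoma": pr, "Remission": 1.0 - pr}
    elif state in ("Melanoma death", "Other death"):
        return {state: 1.0}
    else:
        raise ConfigurationError(f"unknown melanoma state {state!r}")
    # background death competes among those not dying of melanoma this cycle
    alive = {s: p for s, p in nat.items() if s != "Melanoma death"}
    out = _with_background(alive, bg, "Other death")
    if "Melanoma death" in nat:
        out["Melanoma death"] = nat["Melanoma death"]
    return out


def build_melanoma_model(params: Mapping) -> BuiltModel:
    """Melanoma screening: AI-assisted versus dermatologist-only detection.

    The arms differ only in test accuracy and the per-application fee; a
    positive call triggers referral (work-up cost, and treatment when the
    lesion is real).
    """
    _require(params, _MELANOMA_REQUIRED, "dermatology")
    entry_age = float(params.get("entry_age", 50))
    max_age = float(params.get("max_age", 110))
    model = MarkovModelSpec(
        state_ids=_MEL_STATES,
        absorbing=frozenset({"Melanoma death", "Other death"}),
        entry_age=entry_age,
        entry_state_distribution=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        transition_fn=_melanoma_transitions,
        max_age=max_age,
    )
    rewards = RewardSpec(
        state_cost={"Detected melanoma": params["cost_treatment_cycle"]},
        state_effect={"Healthy": 1.0,
                      "Undetected melanoma": params["u_undetected"],
                      "Detected melanoma": params["u_detected"],
                      "Remission": params["u_remission"]},
        event_cost={("Undetected melanoma", "Detected melanoma"):
                    params["cost_treatment_initial"]},
        action_cost={"refer": params["cost_workup"]},
        currency="USD",
    )
    decision = {("positive", "Healthy"): "refer",
                ("negative", "Healthy"): "none",
                ("positive", "Undetected melanoma"): "refer",
                ("negative", "Undetected melanoma"): "none"}
    schedule = float(params.get("schedule", 1.0))
    modifying = frozenset({"refer"})    # referral reroutes a real lesion

    def arm(label, sens, spec_, fee):
        test = DiagnosticTest(
            sensitivity={"Undetected melanoma": sens},
            specificity={"Healthy": spec_}, fee=fee, label=label)
        return Strategy(test, schedule, decision, label=label,
                        modifying_actions=modifying)

    strategies = {
        "ai": arm("ai", params["sens_ai"], params["spec_ai"],
                  params["fee_exam"] + params["fee_ai"]),
        "standard": arm("standard", params["sens_standard"],
                        params["spec_standard"], params["fee_exam"]),
    }
    return BuiltModel(model, rewards, strategies)


# ---------------------------------------------------------------------------
# dentistry: proximal caries, tooth-level
# ---------------------------------------------------------------------------

_CARIES_REQUIRED = (
    "treatment_path", "prevalence_initial", "prevalence_advanced",
    "p_initiation", "p_progression", "rr_noninvasive",
    "p_extraction_advanced", "p_restoration_failure",
    "p_rerestoration_failure", "cost_restoration", "cost_rerestoration",
    "cost_extraction", "cost_noninvasive",
    "sens_ai_initial", "sens_ai_advanced", "spec_ai",
    "sens_standard_initial", "sens_standard_advanced", "spec_standard",
    "fee_ai", "fee_exam", "background_mortality",
)

_CARIES_STATES = ("Sound", "Initial lesion", "Advanced lesion",
                  "Restored", "Re-restored", "Tooth lost")


def _caries_transitions(state: str, age: float, params: Mapping,
                        action: Optional[str]) -> Mapping[str, float]:
    bg = _mortality(params, age)    # person death ends tooth retention
    if state in ("Sound", "Initial lesion", "Advanced lesion",
                 "Restored", "Re-restored"):
        if action == "treat-invasive":
            nat = {"Restored": 1.0}
        elif state == "Sound":
            p = params["p_initiation"]
            nat = {"Sound": 1.0 - p, "Initial lesion": p}
        elif state == "Initial lesion":
            p = params["p_progression"]
            if action == "treat-noninvasive":
                p = p * params["rr_noninvasive"]
            nat = {"Initial lesion": 1.0 - p, "Advanced lesion": p}
        elif state == "Advanced lesion":
            p = params["p_extraction_advanced"]
            nat = {"Advanced lesion": 1.0 - p, "Tooth lost": p}
        elif state == "Restored":
            p = params["p_restoration_failure"]
            nat = {"Restored": 1.0 - p, "Re-restored": p}
        else:                        # Re-restored
            p = params["p_rerestoration_failure"]
            nat = {"Re-restored": 1.0 - p, "Tooth lost": p}
        return _with_background(nat, bg, "Tooth lost")
    if state == "Tooth lost":
        return {"Tooth lost": 1.0}
    raise ConfigurationError(f"unknown caries state {state!r}")


def build_caries_model(params: Mapping) -> BuiltModel:
    """Tooth-level caries screening; effect is one retention-year per cycle.

    ``treatment_path`` ∈ {"invasive", "noninvasive"} decides what a positive
    call on an initial lesion (and on a sound surface — the overtreatment
    channel) triggers: immediate restoration, or non-invasive management
    that slows progression at a small per-cycle cost.
    """
    _require(params, _CARIES_REQUIRED, "dentistry")
    path = params["treatment_path"]
    if path not in ("invasive", "noninvasive"):
        raise ConfigurationError(
            f"treatment_path must be 'invasive' or 'noninvasive', got {path!r}")
    entry_age = float(params.get("entry_age", 12))
    max_age = float(params.get("max_age", 110))
    prev_i = params["prevalence_initial"]
    prev_a = params["prevalence_advanced"]
    model = MarkovModelSpec(
        state_ids=_CARIES_STATES,
        absorbing=frozenset({"Tooth lost"}),
        entry_age=entry_age,
        entry_state_distribution=(1.0 - prev_i - prev_a, prev_i, prev_a,
                                  0.0, 0.0, 0.0),
        transition_fn=_caries_transitions,
        max_age=max_age,
    )
    retained = {s: 1.0 for s in _CARIES_STATES if s != "Tooth lost"}
    rewards = RewardSpec(
        state_cost={},
        state_effect=retained,
        event_cost={(s, "Restored"): params["cost_restoration"]
                    for s in ("Sound", "Initial lesion", "Advanced lesion")}
        | {("Restored", "Re-restored"): params["cost_rerestoration"],
           ("Advanced lesion", "Tooth lost"): params["cost_extraction"],
           ("Re-restored", "Tooth lost"): params["cost_extraction"]},
        action_cost={"treat-noninvasive": params["cost_noninvasive"]},
        currency="EUR",
    )
    initial_action = ("treat-invasive" if path == "invasive"
                      else "treat-noninvasive")
    decision = {("positive", "Sound"): initial_action,
                ("negative", "Sound"): "none",
                ("positive", "Initial lesion"): initial_action,
                ("negative", "Initial lesion"): "none",
                ("positive", "Advanced lesion"): "treat-invasive",
                ("negative", "Advanced lesion"): "none",
                ("positive", "Restored"): "none",
                ("negative", "Restored"): "none",
                ("positive", "Re-restored"): "none",
                ("negative", "Re-restored"): "none"}
    schedule = float(params.get("schedule", 2.0))

    def arm(label, sens_i, sens_a, spec_, fee):
        test = DiagnosticTest(
            sensitivity={"Initial lesion": sens_i, "Advanced lesion": sens_a},
            specificity={"Sound": spec_, "Restored": 1.0, "Re-restored": 1.0},
            fee=fee, label=label)
        return Strategy(test, schedule, decision, label=label)

    strategies = {
        "ai": arm("ai", params["sens_ai_initial"], params["sens_ai_advanced"],
                  params["spec_ai"], params["fee_exam"] + params["fee_ai"]),
        "standard": arm("standard", params["sens_standard_initial"],
                        params["sens_standard_advanced"],
                        params["spec_standard"], params["fee_exam"]),
    }
    return BuiltModel(model, rewards, strategies)


# ---------------------------------------------------------------------------
# ophthalmology: diabetic retinopathy
# ---------------------------------------------------------------------------

_DR_REQUIRED = (
    "p_onset", "p_progression", "p_blindness_untreated",
    "p_blindness_treated", "u_no_dr", "u_npdr", "u_pdr", "u_treated",
    "u_blindness", "cost_workup", "cost_treatment", "cost_treated_cycle",
    "sens_ai_npdr", "sens_ai_pdr", "spec_ai",
    "sens_standard_npdr", "sens_standard_pdr", "spec_standard",
    "fee_ai", "fee_exam", "background_mortality",
)

_DR_STATES = ("No DR", "Nonproliferative DR", "Proliferative DR",
              "Treated DR", "Blindness", "Death")


def _dr_transitions(state: str, age: float, params: Mapping,
                    action: Optional[str]) -> Mapping[str, float]:
    bg = _mortality(params, age)
    if state == "No DR":
        p = params["p_onset"]
        nat = {"No DR": 1.0 - p, "Nonproliferative DR": p}
    elif state == "Nonproliferative DR":
        p = params["p_progression"]
        nat = {"Nonproliferative DR": 1.0 - p, "Proliferative DR": p}
    elif state == "Proliferative DR":
        if action == "treat-invasive":   # photocoagulation after detection
            nat = {"Treated DR": 1.0}
        else:
            p = params["p_blindness_untreated"]
            nat = {"Proliferative DR": 1.0 - p, "Blindness": p}
    elif state == "Treated DR":
        p = params["p_blindness_treated"]
        nat = {"Treated DR": 1.0 - p, "Blindness": p}
    elif state in ("Blindness", "Death"):
        return {state: 1.0}
    else:
        raise ConfigurationError(f"unknown retinopathy state {state!r}")
    return _with_background(nat, bg, "Death")


def build_retinopathy_model(params: Mapping) -> BuiltModel:
    """Diabetic-retinopathy screening with per-state utilities.

    Blindness and death are absorbing; blindness keeps accruing its reduced
    utility until the horizon, so averting it preserves both quality and
    the treated pathway's lower blindness hazard.
    """
    _require(params, _DR_REQUIRED, "ophthalmology")
    utilities = {k: params[k] for k in
                 ("u_no_dr", "u_npdr", "u_pdr", "u_treated", "u_blindness")}
    for name, u in utilities.items():
        if not 0.0 <= u <= 1.0:
            raise ConfigurationError(
                f"utility {name} = {u} outside [0, 1]")
    entry_age = float(params.get("entry_age", 40))
    max_age = float(params.get("max_age", 110))
    model = MarkovModelSpec(
        state_ids=_DR_STATES,
        absorbing=frozenset({"Blindness", "Death"}),
        entry_age=entry_age,
        entry_state_distribution=(1.0, 0.0, 0.0, 0.0, 0.0, 0.0),
        transition_fn=_dr_transitions,
        max_age=max_age,
    )
    rewards = RewardSpec(
        state_cost={"Treated DR": params["cost_treated_cycle"]},
        state_effect={"No DR": utilities["u_no_dr"],
                      "Nonproliferative DR": utilities["u_npdr"],
                      "Proliferative DR": utilities["u_pdr"],
                      "Treated DR": utilities["u_treated"],
                      "Blindness": utilities["u_blindness"]},
        event_cost={("Proliferative DR", "Treated DR"):
                    params["cost_treatment"]},
        action_cost={"refer": params["cost_workup"]},
        currency="BRL",
    )
    decision = {("positive", "No DR"): "refer",
                ("negative", "No DR"): "none",
                ("positive", "Nonproliferative DR"): "refer",
                ("negative", "Nonproliferative DR"): "none",
                ("positive", "Proliferative DR"): "treat-invasive",
                ("negative", "Proliferative DR"): "none"}
    schedule = float(params.get("schedule", 0.5))   # every other year

    def arm(label, sens_n, sens_p, spec_, fee):
        test = DiagnosticTest(
            sensitivity={"Nonproliferative DR": sens_n,
                         "Proliferative DR": sens_p},
            specificity={"No DR": spec_}, fee=fee, label=label)
        return Strategy(test, schedule, decision, label=label)

    strategies = {
        "ai": arm("ai", params["sens_ai_npdr"], params["sens_ai_pdr"],
                  params["spec_ai"], params["fee_exam"] + params["fee_ai"]),
        "standard": arm("standard", params["sens_standard_npdr"],
                        params["sens_standard_pdr"], params["spec_standard"],
                        params["fee_exam"]),
    }
    return BuiltModel(model, rewards, strategies)


def melanoma_scenario(params: Mapping, **kw) -> Scenario:
    return Scenario("melanoma screening", "dermatology",
                    build_melanoma_model, dict(params), currency="USD",
                    effect_unit="QALY", **kw)


def caries_scenario(params: Mapping, **kw) -> Scenario:
    return Scenario("caries screening", "dentistry", build_caries_model,
                    dict(params), currency="EUR",
                    effect_unit="tooth-retention-year", **kw)


def retinopathy_scenario(params: Mapping, **kw) -> Scenario:
    return Scenario("retinopathy screening", "ophthalmology",
                    build_retinopathy_model, dict(params), currency="BRL",
                    effect_unit="QALY", **kw)


USE_CASES = {
    "dermatology": melanoma_scenario,
    "dentistry": caries_scenario,
    "ophthalmology": retinopathy_scenario,
}
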