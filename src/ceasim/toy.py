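"""Miniature reference models with pencil-and-paper solutions.

Used in documentation, tests and the acceptance script: a constant-hazard
survival chain whose discounted life expectancy is a geometric sum, and a
deterministic break-even model in which an AI test replaces a conventional
work-up so that strategy dominance flips exactly where the AI fee meets
the per-visit savings.
"""
from __future__ import annotations

from .markov import MarkovModelSpec, RewardSpec
from .screening import DiagnosticTest, Strategy
from .use_cases import BuiltModel, Scenario

__all__ = ["make_survival_chain", "geometric_effect",
           "make_break_even_scenario"]


def make_survival_chain(p_death: float, cost_rate: float = 0.0,
                        effect_rate: float = 1.0, max_age=None):
    """Alive → Dead with a constant per-cycle death probability.

    Returns (spec, rewards, params).  Discounted life expectancy has the
    closed form of :func:`geometric_effect`.
    """
    def transition(state, age, params, action=None):
        if state == "Alive":
            p = params["p_death"]
            return {"Alive": 1.0 - p, "Dead": p}
        return {"Dead": 1.0}

    spec = MarkovModelSpec(("Alive", "Dead"), frozenset({"Dead"}),
                           entry_age=0.0, entry_state_distribution=(1.0, 0.0),
                           transition_fn=transition, max_age=max_age)
    rewards = RewardSpec(state_cost={"Alive": cost_rate},
                         state_effect={"Alive": effect_rate})
    return spec, rewards, {"p_death": p_death}


def geometric_effect(p_death: float, rate: float) -> float:
    """Closed form Σ_t ((1 − p)/(1 + r))^t = 1 / (1 − (1 − p)/(1 + r))."""
    return 1.0 / (1.0 - (1.0 - p_death) / (1.0 + rate))


def make_break_even_scenario(fee_standard: float = 16.0,
                             fee_ai: float = 8.0,
                             n_cycles: int = 4) -> Scenario:
    """Deterministic toy: the AI test replaces a conventional work-up.

    One never-absorbing state watched annually for ``n_cycles`` years with
    no discounting.  The standard arm pays ``fee_standard`` per
    application, the AI arm ``fee_ai``, so the incremental cost is
    n_cycles × (fee_ai − fee_standard) exactly and dominance flips at
    fee_ai = fee_standard.
    """
    def transition(state, age, params, action=None):
        return {"Watch": 1.0}

    spec = MarkovModelSpec(("Watch",), frozenset(), entry_age=0.0,
                           entry_state_distribution=(1.0,),
                           transition_fn=transition, max_age=float(n_cycles))
    rewards = RewardSpec(state_cost={}, state_effect={"Watch": 1.0})

    def build(params):
        def arm(label, fee):
            test = DiagnosticTest(sensitivity={}, specificity={"Watch": 1.0},
                                  fee=float(fee), label=label)
            decision = {("positive", "Watch"): "none",
                        ("negative", "Watch"): "none"}
            return Strategy(test, 1.0, decision, label=label)

        return BuiltModel(spec, rewards, {
            "ai": arm("ai", params["fee_ai"]),
            "standard": arm("standard", params["fee_standard"])})

    return Scenario("break-even toy", "dentistry", build,
                    {"fee_ai": fee_ai, "fee_standard": fee_standard},
                    discount_rate=0.0)
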