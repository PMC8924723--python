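"""Imperfect diagnostic testing and the resulting treatment decision.

A :class:`DiagnosticTest` is characterised by per-state sensitivity (the
probability of a positive call given a diseased state) and per-state
specificity (probability of a negative call given a non-diseased state),
plus a fee-for-service charged once per application.  A :class:`Strategy`
couples a test with a testing schedule and a decision map sending every
(result, occupied state) pair to a clinical action.  Decision congruence is
assumed: the clinician always acts on the test result.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ACTIONS",
    "DEFAULT_MODIFYING_ACTIONS",
    "ConfigurationError",
    "DiagnosticTest",
    "Strategy",
    "CompiledStrategy",
    "classify",
    "apply_decision",
    "schedule_tests",
]

# Clinical actions in escalation order; when several test applications fall
# in one cycle the escalation-maximal action is the one carried out.
ACTIONS: Tuple[str, ...] = (
    "none",
    "monitor",
    "refer",
    "treat-noninvasive",
    "treat-invasive",
)
ACTION_RANK: Mapping[str, int] = {a: i for i, a in enumerate(ACTIONS)}

#: Actions that by default reroute the occupied state onto a treated branch
#: of the transition function.  Models may override per strategy (e.g. a
#: "refer" that triggers treatment).
DEFAULT_MODIFYING_ACTIONS = frozenset({"treat-noninvasive", "treat-invasive"})


class ConfigurationError(ValueError):
    """A model/strategy configuration violates its contract."""


@dataclass(frozen=True)
class DiagnosticTest:
    """A diagnostic test with per-state accuracy and a per-application fee.

    ``sensitivity`` maps diseased states to P(positive | state);
    ``specificity`` maps non-diseased states to P(negative | state).  States
    present in neither mapping are outside the test's coverage and are not
    screened.
    """

    sensitivity: Mapping[str, float]
    specificity: Mapping[str, float]
    fee: float = 0.0
    label: str = "test"

    def __post_init__(self) -> None:
        for name, table in (("sensitivity", self.sensitivity),
                            ("specificity", self.specificity)):
            for state, p in table.items():
                if not 0.0 <= float(p) <= 1.0:
                    raise ConfigurationError(
                        f"{self.label}: {name}[{state!r}] = {p} outside [0, 1]")
        overlap = set(self.sensitivity) & set(self.specificity)
        if overlap:
            raise ConfigurationError(
                f"{self.label}: states {sorted(overlap)} listed as both "
                "diseased and non-diseased")
        if self.fee < 0:
            raise ConfigurationError(f"{self.label}: fee {self.fee} < 0")

    @property
    def covered_states(self) -> frozenset:
        return frozenset(self.sensitivity) | frozenset(self.specificity)

    def p_positive(self, state: str) -> float:
        """P(positive result | occupied state)."""
        if state in self.sensitivity:
            return float(self.sensitivity[state])
        if state in self.specificity:
            return 1.0 - float(self.specificity[state])
        raise ConfigurationError(
            f"{self.label}: no accuracy entry for state {state!r}")


@dataclass(frozen=True)
class Strategy:
    """A screening arm: test, schedule, decision map and label.

    ``schedule`` is in test applications per year and may be fractional
    (0.5 = one test every other year).  ``decision_map`` must cover every
    (result, state) pair for the test's covered states.
    """

    test: DiagnosticTest
    schedule: float
    decision_map: Mapping[Tuple[str, str], str]
    label: str = "arm"
    modifying_actions: frozenset = DEFAULT_MODIFYING_ACTIONS

    def __post_init__(self) -> None:
        if not self.schedule > 0:
            raise ConfigurationError(
                f"{self.label}: schedule must be > 0, got {self.schedule}")
        for (result, state), action in self.decision_map.items():
            if result not in ("positive", "negative"):
                raise ConfigurationError(
                    f"{self.label}: unknown result {result!r}")
            if action not in ACTIONS:
                raise ConfigurationError(
                    f"{self.label}: unknown action {action!r} for "
                    f"({result}, {state})")
        for state in self.test.covered_states:
            for result in ("positive", "negative"):
                if (result, state) not in self.decision_map:
                    raise ConfigurationError(
                        f"{self.label}: decision map does not cover "
                        f"({result}, {state})")


def classify(true_state: str, test: DiagnosticTest,
             rng: np.random.Generator) -> str:
    """Draw one test result for an individual occupying ``true_state``.

    Positive with probability ``sensitivity[state]`` for diseased states and
    ``1 - specificity[state]`` for non-diseased states.  Exactly one uniform
    variate is consumed per call regardless of the accuracy values, so
    common-random-number alignment across arms is preserved.
    """
    p_pos = test.p_positive(true_state)
    return "positive" if rng.random() < p_pos else "negative"


def apply_decision(result: str, true_state: str, strategy: Strategy):
    """Resolve one test application into (action, fee, transition-modifier).

    The transition modifier is the action itself when the strategy marks it
    as modifying (it is then forwarded to the model's transition function);
    otherwise ``None`` (natural progression continues).
    """
    try:
        action = strategy.decision_map[(result, true_state)]
    except KeyError:
        raise ConfigurationError(
            f"{strategy.label}: decision map does not cover "
            f"({result}, {true_state})") from None
    modifier = action if action in strategy.modifying_actions else None
    return action, strategy.test.fee, modifier


def schedule_tests(schedule: float, cycle_index: int) -> int:
    """Number of test applications falling in cycle ``cycle_index``.

    Applications are spread deterministically, aligned to model entry, so a
    fractional schedule of 0.5/year yields the pattern 1, 0, 1, 0, ... and an
    integer schedule s yields s applications every cycle.
    """
    if not schedule > 0:
        raise ConfigurationError(f"schedule must be > 0, got {schedule}")
    if cycle_index < 0:
        raise ValueError(f"cycle_index must be >= 0, got {cycle_index}")
    # ceil-difference of the cumulative application count; eps guards the
    # representation of rationals like 0.1 * 3.
    eps = 1e-9
    hi = int(np.ceil(schedule * (cycle_index + 1) - eps))
    lo = int(np.ceil(schedule * cycle_index - eps))
    return hi - lo


@dataclass(frozen=True)
class CompiledStrategy:
    """A strategy resolved against an ordered state list for the engine.

    Per-state arrays: ``p_pos`` is NaN for states outside test coverage;
    ``pos_code``/``neg_code`` index into :data:`ACTIONS` (0 where uncovered);
    ``modifies`` flags, per action code, whether the action is forwarded to
    the transition function.
    """

    strategy: Strategy
    p_pos: np.ndarray
    covered: np.ndarray
    pos_code: np.ndarray
    neg_code: np.ndarray
    modifies: np.ndarray

    @classmethod
    def compile(cls, strategy: Strategy,
                state_ids: Sequence[str]) -> "CompiledStrategy":
        k = len(state_ids)
        p_pos = np.full(k, np.nan)
        covered = np.zeros(k, dtype=bool)
        pos_code = np.zeros(k, dtype=np.int64)
        neg_code = np.zeros(k, dtype=np.int64)
        for i, s in enumerate(state_ids):
            if s in strategy.test.covered_states:
                covered[i] = True
                p_pos[i] = strategy.test.p_positive(s)
                pos_code[i] = ACTION_RANK[strategy.decision_map[("positive", s)]]
                neg_code[i] = ACTION_RANK[strategy.decision_map[("negative", s)]]
        modifies = np.array(
            [a in strategy.modifying_actions for a in ACTIONS], dtype=bool)
        return cls(strategy, p_pos, covered, pos_code, neg_code, modifies)
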