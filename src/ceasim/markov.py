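"""Discrete-time Markov microsimulation with reward accrual and discounting.

The engine simulates individuals (or teeth) through a labelled state space
at yearly cycles.  Each cycle applies, in fixed order: screening events due
that cycle, per-state reward accrual, then one state transition.  Costs and
effects are discounted by ``1 / (1 + rate)**t`` with cycle 0 (the entry
year) undiscounted.  An analytic cohort solver propagating an occupancy
vector through the same transition rows serves as the exact counterpart of
the stochastic engine for screening-free (or non-modifying-screening)
configurations.

Randomness is organised as counter-based streams: every (cycle, purpose)
pair derives its own `numpy` generator from the master seed, so two arms
run with the same seed see identical uniform draws per individual and per
cycle — common random numbers — even when the arms consume different
numbers of draws.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence, Tuple

import numpy as np

from .screening import (ACTIONS, CompiledStrategy, ConfigurationError,
                        Strategy, schedule_tests)

__all__ = [
    "MarkovModelSpec",
    "RewardSpec",
    "Trajectory",
    "CycleRecord",
    "SimulationResult",
    "Violation",
    "AnalyticIncompatibleError",
    "validate_model",
    "discount",
    "simulate_individual",
    "simulate_cohort",
    "solve_cohort_analytic",
]

logger = logging.getLogger(__name__)

#: probability bookkeeping tolerance for row sums / entry distributions
_PROB_TOL = 1e-9

# stream tags: disjoint purposes within one master seed
_TAG_ENTRY = 3
_TAG_SCREEN = 101
_TAG_TRANSITION = 202


class AnalyticIncompatibleError(ConfigurationError):
    """The configuration cannot be folded into deterministic cohort rows."""


TransitionFn = Callable[[str, float, Mapping, Optional[str]],
                        Mapping[str, float]]


@dataclass(frozen=True)
class MarkovModelSpec:
    """State space, entry conditions, horizon and transition kernel.

    ``transition_fn(state, age, params, action)`` returns a mapping from
    destination state to probability; ``action`` is ``None`` for natural
    progression or a modifying clinical action (see the screening layer).
    Absorbing states must map to themselves with probability 1.
    """

    state_ids: Tuple[str, ...]
    absorbing: frozenset
    entry_age: float
    entry_state_distribution: Sequence[float]
    transition_fn: TransitionFn
    max_age: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "state_ids", tuple(self.state_ids))
        object.__setattr__(self, "absorbing", frozenset(self.absorbing))
        dist = np.asarray(self.entry_state_distribution, dtype=float)
        object.__setattr__(self, "entry_state_distribution", dist)
        unknown = self.absorbing - set(self.state_ids)
        if unknown:
            raise ConfigurationError(
                f"absorbing states {sorted(unknown)} not in state_ids")
        if dist.shape != (len(self.state_ids),):
            raise ConfigurationError(
                "entry_state_distribution length "
                f"{dist.shape} != number of states {len(self.state_ids)}")
        if self.max_age is not None and self.max_age < self.entry_age:
            raise ConfigurationError(
                f"max_age {self.max_age} < entry_age {self.entry_age}")

    @property
    def index(self) -> Mapping[str, int]:
        return {s: i for i, s in enumerate(self.state_ids)}

    def absorbing_mask(self) -> np.ndarray:
        return np.array([s in self.absorbing for s in self.state_ids],
                        dtype=bool)

    def row(self, state: str, age: float, params: Mapping,
            action: Optional[str] = None) -> np.ndarray:
        """Transition probability vector out of ``state`` at ``age``."""
        raw = self.transition_fn(state, age, params, action)
        vec = np.zeros(len(self.state_ids))
        idx = self.index
        for dest, p in raw.items():
            if dest not in idx:
                raise ConfigurationError(
                    f"transition from {state!r} targets unknown state "
                    f"{dest!r}")
            vec[idx[dest]] += float(p)
        return vec


@dataclass(frozen=True)
class RewardSpec:
    """Per-cycle state rewards, one-time transition rewards and action costs.

    ``state_cost``/``state_effect`` accrue each cycle for the occupied
    state; ``event_cost``/``event_effect`` accrue once on the named
    (from, to) transition; ``action_cost`` accrues once per cycle for the
    escalation-maximal screening action of that cycle (the per-test fee is
    part of the strategy, not of the rewards).  Absorbing states accrue
    nothing unless explicitly given a nonzero per-cycle reward.
    """

    state_cost: Mapping[str, float]
    state_effect: Mapping[str, float]
    event_cost: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    event_effect: Mapping[Tuple[str, str], float] = field(default_factory=dict)
    action_cost: Mapping[str, float] = field(default_factory=dict)
    currency: str = "USD"

    def __post_init__(self) -> None:
        for name, table in (("state_cost", self.state_cost),
                            ("state_effect", self.state_effect),
                            ("event_cost", self.event_cost),
                            ("event_effect", self.event_effect),
                            ("action_cost", self.action_cost)):
            for key, v in table.items():
                if not np.isfinite(v):
                    raise ConfigurationError(
                        f"{name}[{key!r}] is not finite: {v}")
        for action in self.action_cost:
            if action not in ACTIONS:
                raise ConfigurationError(
                    f"action_cost names unknown action {action!r}")

    def arrays(self, state_ids: Sequence[str]):
        """Dense reward arrays aligned with ``state_ids``."""
        k = len(state_ids)
        idx = {s: i for i, s in enumerate(state_ids)}
        sc = np.zeros(k)
        se = np.zeros(k)
        for s, v in self.state_cost.items():
            sc[idx[s]] = v
        for s, v in self.state_effect.items():
            se[idx[s]] = v
        ec = np.zeros((k, k))
        ee = np.zeros((k, k))
        for (a, b), v in self.event_cost.items():
            ec[idx[a], idx[b]] = v
        for (a, b), v in self.event_effect.items():
            ee[idx[a], idx[b]] = v
        ac = np.zeros(len(ACTIONS))
        for a, v in self.action_cost.items():
            ac[ACTIONS.index(a)] = v
        return sc, se, ec, ee, ac


@dataclass(frozen=True)
class CycleRecord:
    age: float
    state: str
    cost: float        # undiscounted, accrued this cycle
    effect: float      # undiscounted, accrued this cycle


@dataclass
class Trajectory:
    """One individual's path with per-cycle records and discounted totals."""

    individual_id: int
    records: list
    discounted_cost: float
    discounted_effect: float

    @property
    def final_state(self) -> str:
        return self.records[-1].state

    @property
    def undiscounted_cost(self) -> float:
        return float(sum(r.cost for r in self.records))

    @property
    def undiscounted_effect(self) -> float:
        return float(sum(r.effect for r in self.records))


@dataclass
class SimulationResult:
    """Aggregate of n independent trajectories under one seed."""

    n_individuals: int
    mean_cost: float
    mean_effect: float
    costs: np.ndarray
    effects: np.ndarray
    seed: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "individual": np.arange(self.n_individuals),
            "cost": self.costs,
            "effect": self.effects,
        })


@dataclass(frozen=True)
class Violation:
    """One model-invariant violation, naming state, age and rule."""

    state: Optional[str]
    age: Optional[float]
    rule: str
    detail: str

    def __str__(self) -> str:
        where = f"state={self.state!r}, age={self.age}"
        return f"[{self.rule}] {where}: {self.detail}"


def discount(amount, rate: float, years_elapsed) -> float:
    """Present value of ``amount`` accrued ``years_elapsed`` years from entry.

    Cycle 0 (the entry year) is undiscounted.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"discount rate must be in [0, 1], got {rate}")
    if np.any(np.asarray(years_elapsed) < 0):
        raise ValueError(f"years_elapsed must be >= 0, got {years_elapsed}")
    return amount / (1.0 + rate) ** years_elapsed


def validate_model(spec: MarkovModelSpec, params: Mapping,
                   age_step: float = 1.0) -> list:
    """Check every model invariant on the age grid; violations are data.

    Returns an empty list iff all transition rows are proper probability
    vectors, absorbing states are genuine self-loops, and the entry
    distribution is a probability vector.
    """
    violations = []
    dist = spec.entry_state_distribution
    if np.any(dist < 0):
        violations.append(Violation(None, None, "entry-distribution",
                                    f"negative entries: {dist}"))
    if abs(dist.sum() - 1.0) > _PROB_TOL:
        violations.append(Violation(None, None, "entry-distribution",
                                    f"sums to {dist.sum():.12f}, not 1"))
    horizon = spec.max_age if spec.max_age is not None else spec.entry_age + 100
    ages = np.arange(spec.entry_age, horizon, age_step)
    if len(ages) == 0:
        ages = np.array([spec.entry_age])
    idx = spec.index
    for age in ages:
        for s in spec.state_ids:
            try:
                vec = spec.row(s, float(age), params, None)
            except Exception as exc:  # noqa: BLE001 - collected as data
                violations.append(Violation(s, float(age), "transition-row",
                                            f"transition_fn raised: {exc}"))
                continue
            if np.any(vec < -_PROB_TOL):
                violations.append(Violation(
                    s, float(age), "nonnegative",
                    f"negative transition probability in {vec}"))
            if abs(vec.sum() - 1.0) > _PROB_TOL:
                violations.append(Violation(
                    s, float(age), "row-sum",
                    f"row sums to {vec.sum():.12f}, not 1"))
            if s in spec.absorbing and abs(vec[idx[s]] - 1.0) > _PROB_TOL:
                violations.append(Violation(
                    s, float(age), "absorbing-self-loop",
                    f"self-probability {vec[idx[s]]:.12f} != 1"))
    return violations


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, tags)])


def _sink_mask(spec: MarkovModelSpec, sc: np.ndarray,
               se: np.ndarray) -> np.ndarray:
    """Absorbing states with zero per-cycle reward: trajectories end there."""
    return spec.absorbing_mask() & (sc == 0) & (se == 0)


def _check_horizon(spec: MarkovModelSpec, sink: np.ndarray) -> None:
    if spec.max_age is None and np.any(spec.absorbing_mask() & ~sink):
        raise ConfigurationError(
            "absorbing states with nonzero per-cycle rewards require a "
            "finite max_age (they accrue until the horizon)")


def simulate_individual(spec: MarkovModelSpec, rewards: RewardSpec,
                        strategy: Optional[Strategy], params: Mapping,
                        rng: np.random.Generator, *,
                        discount_rate: float = 0.03,
                        discount_effects: bool = True,
                        individual_id: int = 0,
                        max_cycles: int = 100_000) -> Trajectory:
    """Simulate one trajectory with an explicit random generator.

    The per-cycle order is screening → reward accrual → transition; the
    trajectory terminates on entering a zero-reward absorbing state or on
    reaching ``max_age``.
    """
    sc, se, ec, ee, ac = rewards.arrays(spec.state_ids)
    sink = _sink_mask(spec, sc, se)
    _check_horizon(spec, sink)
    compiled = (CompiledStrategy.compile(strategy, spec.state_ids)
                if strategy is not None else None)
    idx = spec.index
    absorbing = spec.absorbing_mask()

    i = int(rng.choice(len(spec.state_ids),
                       p=spec.entry_state_distribution))
    records = []
    d_cost = 0.0
    d_effect = 0.0
    t = 0
    while True:
        age = spec.entry_age + t
        if spec.max_age is not None and age >= spec.max_age:
            break
        if sink[i]:
            if not records:
                records.append(CycleRecord(age, spec.state_ids[i], 0.0, 0.0))
            break
        if t > max_cycles:
            raise ConfigurationError(
                "horizon does not converge: no absorbing state reached and "
                "max_age unset")
        dc = 1.0 / (1.0 + discount_rate) ** t
        de = dc if discount_effects else 1.0
        cyc_cost = 0.0
        cyc_effect = 0.0
        action_code = 0
        if compiled is not None and not absorbing[i] and compiled.covered[i]:
            for _ in range(schedule_tests(compiled.strategy.schedule, t)):
                positive = rng.random() < compiled.p_pos[i]
                cyc_cost += compiled.strategy.test.fee
                code = compiled.pos_code[i] if positive else compiled.neg_code[i]
                action_code = max(action_code, int(code))
        cyc_cost += ac[action_code]
        cyc_cost += sc[i]
        cyc_effect += se[i]
        action = (ACTIONS[action_code]
                  if compiled is not None and compiled.modifies[action_code]
                  else None)
        if absorbing[i]:
            j = i
        else:
            vec = spec.row(spec.state_ids[i], age, params, action)
            j = int(rng.choice(len(vec), p=vec))
            cyc_cost += ec[i, j]
            cyc_effect += ee[i, j]
        d_cost += dc * cyc_cost
        d_effect += de * cyc_effect
        records.append(CycleRecord(age, spec.state_ids[i],
                                   cyc_cost, cyc_effect))
        i = j
        t += 1
    if not records:
        records.append(CycleRecord(spec.entry_age, spec.state_ids[i],
                                   0.0, 0.0))
    return Trajectory(individual_id, records, d_cost, d_effect)


def simulate_cohort(spec: MarkovModelSpec, rewards: RewardSpec,
                    strategy: Optional[Strategy], params: Mapping,
                    n: int, seed: int, *,
                    discount_rate: float = 0.03,
                    discount_effects: bool = True,
                    max_cycles: int = 100_000) -> SimulationResult:
    """Monte Carlo microsimulation of ``n`` independent individuals.

    Fully reproducible given ``seed``.  Two strategies run with the same
    seed share random draws per individual, cycle and purpose (common
    random numbers), so arm differences are not inflated by sampling noise.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if seed < 0:
        raise ValueError(f"seed must be >= 0, got {seed}")
    sc, se, ec, ee, ac = rewards.arrays(spec.state_ids)
    sink = _sink_mask(spec, sc, se)
    _check_horizon(spec, sink)
    absorbing = spec.absorbing_mask()
    compiled = (CompiledStrategy.compile(strategy, spec.state_ids)
                if strategy is not None else None)
    k = len(spec.state_ids)
    logger.info("simulate_cohort: n=%d seed=%d entry_age=%s max_age=%s "
                "discount=%.4f arm=%s", n, seed, spec.entry_age, spec.max_age,
                discount_rate, strategy.label if strategy else "none")

    states = _rng(seed, _TAG_ENTRY).choice(
        k, size=n, p=spec.entry_state_distribution)
    costs = np.zeros(n)
    effects = np.zeros(n)
    t = 0
    while True:
        age = spec.entry_age + t
        if spec.max_age is not None and age >= spec.max_age:
            break
        alive = ~sink[states]
        if not np.any(alive):
            break
        if t > max_cycles:
            raise ConfigurationError(
                "horizon does not converge: no absorbing state reached and "
                "max_age unset")
        dc = 1.0 / (1.0 + discount_rate) ** t
        de = dc if discount_effects else 1.0
        action_codes = np.zeros(n, dtype=np.int64)
        if compiled is not None:
            screened = alive & ~absorbing[states] & compiled.covered[states]
            if np.any(screened):
                for app in range(schedule_tests(compiled.strategy.schedule, t)):
                    u = _rng(seed, _TAG_SCREEN, t, app).random(n)
                    positive = screened & (u < np.nan_to_num(
                        compiled.p_pos[states], nan=-1.0))
                    codes = np.where(positive, compiled.pos_code[states],
                                     compiled.neg_code[states])
                    codes = np.where(screened, codes, 0)
                    costs += dc * compiled.strategy.test.fee * screened
                    action_codes = np.maximum(action_codes, codes)
            costs += dc * ac[action_codes]
        costs += dc * np.where(alive, sc[states], 0.0)
        effects += de * np.where(alive, se[states], 0.0)

        movers = alive & ~absorbing[states]
        if np.any(movers):
            u = _rng(seed, _TAG_TRANSITION, t).random(n)
            nxt = states.copy()
            mod = (compiled.modifies[action_codes]
                   if compiled is not None else np.zeros(n, dtype=bool))
            pair_ids = states * len(ACTIONS) + np.where(mod, action_codes, 0)
            for pid in np.unique(pair_ids[movers]):
                si, code = divmod(int(pid), len(ACTIONS))
                sel = movers & (pair_ids == pid)
                action = ACTIONS[code] if code else None
                cum = np.cumsum(spec.row(spec.state_ids[si], age, params,
                                         action))
                nxt[sel] = np.searchsorted(cum, u[sel], side="right")
            nxt = np.minimum(nxt, k - 1)
            costs += dc * np.where(movers, ec[states, nxt], 0.0)
            effects += de * np.where(movers, ee[states, nxt], 0.0)
            states = nxt
        t += 1
    return SimulationResult(n, float(costs.mean()), float(effects.mean()),
                            costs, effects, int(seed))


def _expected_screen_extra(compiled: CompiledStrategy, ac: np.ndarray,
                           n_tests: int, k: int) -> np.ndarray:
    """Per-state expected screening cost per cycle (fee + action costs).

    Valid only for non-modifying strategies; the escalation-maximal action
    over ``n_tests`` independent applications determines the action cost.
    """
    extra = np.zeros(k)
    if n_tests == 0:
        return extra
    fee = compiled.strategy.test.fee
    for i in range(k):
        if not compiled.covered[i]:
            continue
        p = compiled.p_pos[i]
        pos_c = ac[compiled.pos_code[i]]
        neg_c = ac[compiled.neg_code[i]]
        if compiled.pos_code[i] >= compiled.neg_code[i]:
            p_hi = 1.0 - (1.0 - p) ** n_tests   # any positive
            hi, lo = pos_c, neg_c
        else:
            p_hi = 1.0 - p ** n_tests           # any negative
            hi, lo = neg_c, pos_c
        extra[i] = n_tests * fee + p_hi * hi + (1.0 - p_hi) * lo
    return extra


def solve_cohort_analytic(spec: MarkovModelSpec, rewards: RewardSpec,
                          params: Mapping, *,
                          discount_rate: float = 0.03,
                          discount_effects: bool = True,
                          strategy: Optional[Strategy] = None,
                          occupancy_tol: float = 1e-12,
                          max_cycles: int = 100_000) -> Tuple[float, float]:
    """Exact expected discounted (cost, effect) by occupancy propagation.

    Propagates ``o_{t+1} = o_t · P_t`` over the age grid; exact up to
    floating point for deterministic transition rows.  Screening is allowed
    only when no decision action modifies transitions (fees and expected
    action costs then fold into per-state per-cycle costs); otherwise an
    :class:`AnalyticIncompatibleError` explains the rejection.
    """
    sc, se, ec, ee, ac = rewards.arrays(spec.state_ids)
    sink = _sink_mask(spec, sc, se)
    absorbing = spec.absorbing_mask()
    k = len(spec.state_ids)
    compiled = None
    if strategy is not None:
        used = set(strategy.decision_map.values())
        modifying = used & set(strategy.modifying_actions)
        if modifying:
            raise AnalyticIncompatibleError(
                f"strategy {strategy.label!r} routes actions "
                f"{sorted(modifying)} into the transition function; such "
                "stochastic branching is not expressible as composite "
                "cohort rows — use the microsimulation engine")
        compiled = CompiledStrategy.compile(strategy, spec.state_ids)
    if spec.max_age is None and not np.any(absorbing):
        raise ConfigurationError(
            "no absorbing state and max_age unset: horizon cannot converge")
    _check_horizon(spec, sink)

    o = spec.entry_state_distribution.astype(float).copy()
    total_cost = 0.0
    total_effect = 0.0
    t = 0
    while True:
        age = spec.entry_age + t
        if spec.max_age is not None and age >= spec.max_age:
            break
        accruing = float(o[~sink].sum())
        if spec.max_age is None and accruing < occupancy_tol:
            break
        if t > max_cycles:
            raise ConfigurationError(
                "horizon does not converge within max_cycles")
        dc = 1.0 / (1.0 + discount_rate) ** t
        de = dc if discount_effects else 1.0
        active = np.where(sink, 0.0, o)
        cost_rate = sc.copy()
        if compiled is not None:
            n_tests = schedule_tests(compiled.strategy.schedule, t)
            extra = _expected_screen_extra(compiled, ac, n_tests, k)
            cost_rate = cost_rate + np.where(absorbing, 0.0, extra)
        total_cost += dc * float(active @ cost_rate)
        total_effect += de * float(active @ se)
        P = np.zeros((k, k))
        for i, s in enumerate(spec.state_ids):
            if absorbing[i]:
                P[i, i] = 1.0
            else:
                P[i] = spec.row(s, age, params, None)
        flow = active[:, None] * P
        flow[absorbing] = 0.0
        total_cost += dc * float((flow * ec).sum())
        total_effect += de * float((flow * ee).sum())
        o = o @ P
        t += 1
    return total_cost, total_effect
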