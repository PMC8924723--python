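"""Probabilistic sensitivity analysis and one-way deterministic sweeps.

PSA follows the standard two-level design: ``n_psa`` parameter sets are
drawn from their uncertainty distributions, and each set is pushed through
a paired microsimulation of ``n_individuals`` per arm under common random
numbers.  The replicate means form the cost-effectiveness draws on which
percentile intervals and acceptability curves are computed.

Probabilities and utilities default to beta distributions, costs to gamma,
both parameterised by a mean and a 95% interval via quantile fitting;
uniform distributions are available where the source evidence only bounds
a parameter (caries progression).  One-way sweeps rerun the deterministic
base case over a grid for one parameter (built-in grids for the discount
rate, 0–10%, and the AI fee) and a bisection refiner locates dominance
flips such as the break-even fee.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .economics import CEDraws, ICERResult, icer
from .markov import ConfigurationError
from .use_cases import ArmPair, Scenario, run_arms

__all__ = [
    "ParameterDistribution",
    "ParameterFitError",
    "UnknownParameterError",
    "PSAResult",
    "sample_parameters",
    "run_psa",
    "percentile_ci",
    "one_way_sweep",
    "find_threshold",
    "DISCOUNT_GRID",
    "FEE_GRID",
]

logger = logging.getLogger(__name__)

DISCOUNT_GRID = np.round(np.linspace(0.0, 0.10, 11), 4)
FEE_GRID = np.linspace(0.0, 32.0, 9)

_FAMILIES = ("beta", "gamma", "uniform", "fixed")


class ParameterFitError(ValueError):
    """A distribution cannot be fitted to the stated mean/interval."""


class UnknownParameterError(KeyError):
    """A sweep or override names a parameter the scenario does not have."""


def _fit_concentration(mean: float, lo: float, hi: float,
                       quantiles: Callable[[float], np.ndarray],
                       name: str) -> float:
    """Least-squares fit of a one-dimensional spread parameter.

    ``quantiles(kappa)`` returns the (2.5%, 97.5%) quantiles at
    concentration ``kappa`` with the mean held fixed; larger kappa means
    tighter.  Used as the starting point of the exact two-parameter
    quantile fit.
    """
    target = np.array([lo, hi])

    def loss(log_k: float) -> float:
        q = quantiles(float(np.exp(log_k)))
        return float(((q - target) ** 2).sum())

    res = optimize.minimize_scalar(loss, bounds=(np.log(1e-3), np.log(1e8)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    if not res.success:
        raise ParameterFitError(f"{name}: quantile fit failed to converge")
    return float(np.exp(res.x))


def _fit_quantiles(theta0: np.ndarray, lo: float, hi: float,
                   quantiles: Callable[[np.ndarray], np.ndarray],
                   name: str) -> np.ndarray:
    """Solve the 2x2 system ppf(2.5%, 97.5%) = (lo, hi) for two shape
    parameters (on an unconstrained log/logit scale), starting from the
    mean-matched one-parameter fit.  The stated mean is thereby honoured
    approximately while the stated interval is honoured exactly.
    """
    target = np.array([lo, hi])

    def residual(theta: np.ndarray) -> np.ndarray:
        with np.errstate(all="ignore"):
            q = quantiles(theta)
        return np.where(np.isfinite(q), q - target, 1e6)

    res = optimize.least_squares(residual, theta0, xtol=1e-14, ftol=1e-14,
                                 gtol=1e-14)
    if not res.success or float(np.abs(res.fun).max()) > 1e-6 * (hi - lo):
        raise ParameterFitError(
            f"{name}: no distribution in the family matches the 95% CI "
            f"({lo}, {hi})")
    return res.x


@dataclass(frozen=True)
class ParameterDistribution:
    """Uncertainty distribution of one scalar model parameter.

    Families: ``beta`` (probabilities/utilities, support [0, 1]), ``gamma``
    (costs, support (0, ∞)) — both parameterised by ``mean`` plus a 95%
    interval ``ci`` and fitted by matching the mean exactly and the
    quantiles by least squares; ``uniform`` with explicit ``low``/``high``;
    ``fixed`` passes the mean through.  ``bounds``, when given, clip every
    sampled value.
    """

    name: str
    family: str
    mean: Optional[float] = None
    ci: Optional[Sequence[float]] = None
    low: Optional[float] = None
    high: Optional[float] = None
    bounds: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ParameterFitError(
                f"{self.name}: unknown family {self.family!r}")
        if self.family == "uniform":
            if self.low is None or self.high is None or self.low > self.high:
                raise ParameterFitError(
                    f"{self.name}: uniform needs ordered low <= high")
        elif self.family == "fixed":
            if self.mean is None:
                raise ParameterFitError(f"{self.name}: fixed needs a mean")
        else:
            if self.mean is None or self.ci is None:
                raise ParameterFitError(
                    f"{self.name}: {self.family} needs mean and ci")
            lo, hi = self.ci
            if not lo < self.mean < hi:
                raise ParameterFitError(
                    f"{self.name}: mean {self.mean} outside 95% CI "
                    f"({lo}, {hi})")
            if self.family == "beta" and not (0.0 <= lo and hi <= 1.0):
                raise ParameterFitError(
                    f"{self.name}: beta CI ({lo}, {hi}) outside [0, 1]")
            if self.family == "gamma" and lo <= 0.0:
                raise ParameterFitError(
                    f"{self.name}: gamma CI lower bound must be > 0")

    def frozen(self):
        """The fitted scipy distribution (None for the fixed family)."""
        cached = getattr(self, "_frozen", None)
        if cached is not None:
            return cached
        dist = self._fit()
        object.__setattr__(self, "_frozen", dist)
        return dist

    def _fit(self):
        if self.family == "fixed":
            return None
        if self.family == "uniform":
            return stats.uniform(self.low, self.high - self.low)
        m = float(self.mean)
        lo, hi = map(float, self.ci)
        if self.family == "beta":
            kappa0 = _fit_concentration(
                m, lo, hi,
                lambda k: stats.beta.ppf([0.025, 0.975], m * k, (1 - m) * k),
                self.name)

            def q_beta(theta):
                mu = 1.0 / (1.0 + np.exp(-theta[0]))   # logit-mean
                k = np.exp(theta[1])
                return stats.beta.ppf([0.025, 0.975], mu * k, (1 - mu) * k)

            theta = _fit_quantiles(
                np.array([np.log(m / (1 - m)), np.log(kappa0)]),
                lo, hi, q_beta, self.name)
            mu = 1.0 / (1.0 + np.exp(-theta[0]))
            kappa = float(np.exp(theta[1]))
            return stats.beta(mu * kappa, (1 - mu) * kappa)

        kappa0 = _fit_concentration(
            m, lo, hi,
            lambda k: stats.gamma.ppf([0.025, 0.975], k, scale=m / k),
            self.name)

        def q_gamma(theta):
            shape, scale = np.exp(theta)
            return stats.gamma.ppf([0.025, 0.975], shape, scale=scale)

        theta = _fit_quantiles(
            np.array([np.log(kappa0), np.log(m / kappa0)]),
            lo, hi, q_gamma, self.name)
        shape, scale = np.exp(theta)
        return stats.gamma(float(shape), scale=float(scale))

    def sample(self, rng: np.random.Generator) -> float:
        if self.family == "fixed":
            value = float(self.mean)
        else:
            value = float(self.frozen().rvs(random_state=rng))
        if self.bounds is not None:
            value = float(np.clip(value, *self.bounds))
        return value

    def rvs(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Vectorised sampling (same distribution as :meth:`sample`)."""
        if self.family == "fixed":
            values = np.full(size, float(self.mean))
        else:
            values = self.frozen().rvs(size=size, random_state=rng)
        if self.bounds is not None:
            values = np.clip(values, *self.bounds)
        return values


def sample_parameters(distributions: Sequence[ParameterDistribution],
                      rng: np.random.Generator) -> dict:
    """One concrete parameter set: independent draws, fixed pass-through."""
    return {d.name: d.sample(rng) for d in distributions}


def percentile_ci(values: Sequence[float], lo: float = 2.5,
                  hi: float = 97.5):
    """Empirical percentile interval with linear interpolation."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(
            f"need at least 2 values for a percentile interval, "
            f"got {values.size}")
    lower, upper = np.percentile(values, [lo, hi], method="linear")
    return float(lower), float(upper)


@dataclass
class PSAResult:
    """Cost-effectiveness draws plus per-arm summaries of one PSA run."""

    draws: CEDraws
    summary: pd.DataFrame        # per (arm, quantity): mean, ci_low, ci_high
    icer_of_means: ICERResult
    n_psa: int
    n_individuals: int
    master_seed: int

    def mean(self, arm: str, quantity: str) -> float:
        row = self.summary.set_index(["arm", "quantity"]).loc[(arm, quantity)]
        return float(row["mean"])


def _summarise(draws: CEDraws) -> pd.DataFrame:
    rows = []
    for arm, cost, effect in (("ai", draws.cost_ai, draws.effect_ai),
                              ("standard", draws.cost_std,
                               draws.effect_std)):
        for quantity, vec in (("cost", cost), ("effect", effect)):
            if len(vec) >= 2:
                lo, hi = percentile_ci(vec)
            else:
                lo = hi = float(vec[0])
            mean = float(vec.mean())
            if not lo <= mean <= hi:
                logger.warning("PSA %s %s mean %.6g outside percentile "
                               "interval (%.6g, %.6g)", arm, quantity,
                               mean, lo, hi)
            rows.append({"arm": arm, "quantity": quantity, "mean": mean,
                         "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def run_psa(scenario: Scenario,
            distributions: Sequence[ParameterDistribution],
            n_psa: int = 1000, n_individuals: int = 1000,
            master_seed: int = 0) -> PSAResult:
    """Two-level PSA: parameter draws × paired microsimulations.

    Every replicate runs both arms with a replicate-specific seed shared
    across arms (common random numbers); the whole run is reproducible
    from ``master_seed``.
    """
    if n_psa < 1 or n_individuals < 1:
        raise ValueError("n_psa and n_individuals must be >= 1")
    logger.info("run_psa: %s n_psa=%d n_individuals=%d seed=%d",
                scenario.label, n_psa, n_individuals, master_seed)
    cost_ai = np.empty(n_psa)
    effect_ai = np.empty(n_psa)
    cost_std = np.empty(n_psa)
    effect_std = np.empty(n_psa)
    for r in range(n_psa):
        rng = np.random.default_rng([int(master_seed), 7, r])
        sampled = {**dict(scenario.params),
                   **sample_parameters(distributions, rng)}
        sim_seed = int(np.random.default_rng(
            [int(master_seed), 13, r]).integers(2 ** 31))
        pair = run_arms(scenario, n_individuals, sim_seed, params=sampled)
        cost_ai[r] = pair.ai.mean_cost
        effect_ai[r] = pair.ai.mean_effect
        cost_std[r] = pair.standard.mean_cost
        effect_std[r] = pair.standard.mean_effect
    draws = CEDraws(cost_ai, effect_ai, cost_std, effect_std,
                    currency=scenario.currency,
                    effect_unit=scenario.effect_unit)
    result = PSAResult(draws, _summarise(draws),
                       icer(float(draws.delta_cost.mean()),
                            float(draws.delta_effect.mean())),
                       n_psa, n_individuals, int(master_seed))
    return result


def _apply_override(scenario: Scenario, name: str, value: float):
    """Resolve a sweep parameter into (params, discount_rate) overrides."""
    if name == "discount_rate":
        return dict(scenario.params), float(value)
    key = "fee_ai" if name == "fee" else name
    params = dict(scenario.params)
    if key not in params:
        raise UnknownParameterError(
            f"scenario {scenario.label!r} has no parameter {key!r}")
    params[key] = float(value)
    return params, scenario.discount_rate


def evaluate_point(scenario: Scenario, name: str, value: float,
                   seed: int, n_individuals: int) -> ArmPair:
    """One deterministic run of both arms with one parameter overridden."""
    params, rate = _apply_override(scenario, name, value)
    return run_arms(scenario, n_individuals, seed, params=params,
                    discount_rate=rate)


def one_way_sweep(scenario: Scenario, name: str,
                  grid: Optional[Sequence[float]] = None,
                  seed: int = 0, n_individuals: int = 1000) -> pd.DataFrame:
    """Deterministic sensitivity sweep of one parameter over a grid.

    Each point reruns both arms at base-case parameter means with common
    random numbers, so rows differ only through the swept parameter.
    """
    if grid is None:
        builtin = {"discount_rate": DISCOUNT_GRID, "fee": FEE_GRID}
        if name not in builtin:
            raise UnknownParameterError(
                f"no built-in grid for {name!r}; pass one explicitly")
        grid = builtin[name]
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    rows = []
    for value in grid:
        pair = evaluate_point(scenario, name, value, seed, n_individuals)
        res = icer(pair.delta_cost, pair.delta_effect)
        rows.append({
            "value": float(value),
            "cost_ai": pair.ai.mean_cost, "effect_ai": pair.ai.mean_effect,
            "cost_std": pair.standard.mean_cost,
            "effect_std": pair.standard.mean_effect,
            "delta_cost": pair.delta_cost, "delta_effect": pair.delta_effect,
            "icer": np.nan if res.value is None else res.value,
            "flag": res.flag,
        })
    return pd.DataFrame(rows)


def find_threshold(sweep: pd.DataFrame, criterion: str = "delta_cost",
                   evaluator: Optional[Callable[[float], float]] = None,
                   tol: float = 0.01):
    """Locate where the dominance criterion flips along a sweep.

    Scans the sorted sweep for sign changes of ``criterion`` (by default
    the incremental cost: its sign decides dominance whenever the
    incremental effect does not change sign), then refines each crossing —
    by bisection on ``evaluator`` when one is supplied, otherwise by linear
    interpolation.  Returns ``None`` when the criterion never flips, the
    crossing value when it flips once, and all crossings with a warning
    when the sweep is non-monotone.
    """
    x = sweep["value"].to_numpy(dtype=float)
    y = sweep[criterion].to_numpy(dtype=float)
    if np.any(np.diff(x) <= 0):
        raise ValueError("sweep must be sorted by strictly increasing value")
    crossings = []
    for i in range(len(x) - 1):
        y0, y1 = y[i], y[i + 1]
        if y0 == 0.0 and (i == 0 or y[i - 1] != 0.0):
            crossings.append(float(x[i]))
        elif y0 * y1 < 0:
            if evaluator is not None:
                root = optimize.brentq(evaluator, x[i], x[i + 1], xtol=tol)
            else:
                root = x[i] - y0 * (x[i + 1] - x[i]) / (y1 - y0)
            crossings.append(float(root))
    if y[-1] == 0.0 and (len(y) < 2 or y[-2] != 0.0):
        crossings.append(float(x[-1]))
    if not crossings:
        return None
    if len(crossings) > 1:
        warnings.warn(
            f"criterion {criterion!r} flips {len(crossings)} times; "
            "returning all crossings", stacklevel=2)
        return crossings
    return crossings[0]
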