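"""Incremental cost-effectiveness mathematics.

Implements the decision-analytic layer on top of paired simulation output:
incremental cost-effectiveness ratios with dominance flags, the net
monetary benefit ``NB(λ) = λ·ΔE − ΔC``, cost-effectiveness acceptability
curves over probabilistic-sensitivity draws, purchasing-power-parity
currency conversion and the WHO 3×GDP-per-capita willingness-to-pay rule.

A bare negative ICER is ambiguous (cheaper-and-better versus
costlier-and-worse), so ratios always travel together with a dominance
flag.  Internal arithmetic is full precision; rounding happens only at
presentation (2 decimals, half away from zero).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ICERResult",
    "CEDraws",
    "CEACCurve",
    "PPPRates",
    "PPP_2020",
    "icer",
    "net_benefit",
    "ceac",
    "ppp_convert",
    "present",
    "who_threshold",
]


@dataclass(frozen=True)
class PPPRates:
    """OECD purchasing power parities, local currency units per US dollar."""

    eur_per_usd: float = 0.746
    brl_per_usd: float = 2.362
    reference_year: int = 2020

    def __post_init__(self) -> None:
        if self.eur_per_usd <= 0 or self.brl_per_usd <= 0:
            raise ValueError("PPP rates must be > 0")

    def rate_for(self, currency: str) -> float:
        rates = {"EUR": self.eur_per_usd, "BRL": self.brl_per_usd,
                 "USD": 1.0}
        try:
            return rates[currency.upper()]
        except KeyError:
            raise ValueError(f"no PPP rate for currency {currency!r}") from None


#: 2020 OECD rates used throughout
PPP_2020 = PPPRates()


@dataclass(frozen=True)
class ICERResult:
    """An incremental cost-effectiveness ratio with its dominance flag.

    ``flag`` is one of ``ratio`` (well-defined trade-off), ``dominant``
    (cheaper and more effective), ``dominated`` (costlier and less
    effective) or ``undefined`` (zero incremental effect).  ``value`` is
    ΔC/ΔE whenever ΔE ≠ 0, and ``None`` otherwise.
    """

    value: Optional[float]
    flag: str
    delta_cost: float
    delta_effect: float

    def __str__(self) -> str:
        if self.value is None:
            return f"ICER undefined (Δeffect = 0, Δcost = {self.delta_cost:g})"
        return f"ICER = {self.value:g} [{self.flag}]"


def icer(delta_cost: float, delta_effect: float) -> ICERResult:
    """Incremental cost per incremental effect unit, with dominance flag."""
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("delta_cost and delta_effect must be finite")
    if delta_effect == 0:
        return ICERResult(None, "undefined", delta_cost, delta_effect)
    value = delta_cost / delta_effect
    if delta_cost < 0 and delta_effect > 0:
        flag = "dominant"
    elif delta_cost > 0 and delta_effect < 0:
        flag = "dominated"
    else:
        flag = "ratio"
    return ICERResult(value, flag, delta_cost, delta_effect)


def net_benefit(wtp, delta_effect, delta_cost):
    """Net monetary benefit ``WTP × Δeffect − Δcost``; vectorised."""
    wtp = np.asarray(wtp, dtype=float)
    if np.any(wtp < 0):
        raise ValueError("WTP must be >= 0")
    out = wtp * np.asarray(delta_effect, float) - np.asarray(delta_cost, float)
    return float(out) if out.ndim == 0 else out


@dataclass
class CEDraws:
    """Paired (cost, effect) per arm per PSA replicate.

    The substrate of all probabilistic economics: row r holds the replicate
    means of the AI arm and the standard-of-care arm run under common
    random numbers with the r-th sampled parameter set.
    """

    cost_ai: np.ndarray
    effect_ai: np.ndarray
    cost_std: np.ndarray
    effect_std: np.ndarray
    currency: str = "USD"
    effect_unit: str = "QALY"

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.cost_ai, self.effect_ai, self.cost_std,
                   self.effect_std)]
        lengths = {a.shape for a in arrays}
        if len(lengths) != 1 or arrays[0].ndim != 1 or len(arrays[0]) < 1:
            raise ValueError(
                "cost/effect vectors must share one length >= 1, got "
                f"shapes {[a.shape for a in arrays]}")
        self.cost_ai, self.effect_ai, self.cost_std, self.effect_std = arrays

    def __len__(self) -> int:
        return len(self.cost_ai)

    @property
    def delta_cost(self) -> np.ndarray:
        return self.cost_ai - self.cost_std

    @property
    def delta_effect(self) -> np.ndarray:
        return self.effect_ai - self.effect_std

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "replicate": np.arange(len(self)),
            "cost_ai": self.cost_ai,
            "effect_ai": self.effect_ai,
            "cost_std": self.cost_std,
            "effect_std": self.effect_std,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, currency: str = "USD",
                 effect_unit: str = "QALY") -> "CEDraws":
        df = pd.read_csv(path)
        return cls(df["cost_ai"].to_numpy(), df["effect_ai"].to_numpy(),
                   df["cost_std"].to_numpy(), df["effect_std"].to_numpy(),
                   currency=currency, effect_unit=effect_unit)


@dataclass
class CEACCurve:
    """P(AI arm maximises net benefit) on a willingness-to-pay grid."""

    wtp: np.ndarray
    probability: np.ndarray

    def __post_init__(self) -> None:
        self.wtp = np.asarray(self.wtp, dtype=float)
        self.probability = np.asarray(self.probability, dtype=float)
        if self.wtp.shape != self.probability.shape:
            raise ValueError("wtp and probability must align")
        if np.any((self.probability < 0) | (self.probability > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp,
                             "p_cost_effective": self.probability})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def ceac(draws: CEDraws, wtp_grid: Sequence[float]) -> CEACCurve:
    """Acceptability curve: per WTP, the fraction of replicates whose net
    benefit favours the AI arm, counting exact ties as 1/2.
    """
    if len(draws) == 0:
        raise ValueError("draws must contain at least one replicate")
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if np.any(wtp < 0):
        raise ValueError("wtp_grid must be non-negative")
    nb = wtp[:, None] * draws.delta_effect[None, :] \
        - draws.delta_cost[None, :]
    prob = (nb > 0).mean(axis=1) + 0.5 * (nb == 0).mean(axis=1)
    return CEACCurve(wtp, prob)


def ppp_convert(amount, rate: float):
    """Convert a local-currency amount to USD at ``rate`` LCU per USD."""
    if rate <= 0:
        raise ValueError(f"PPP rate must be > 0, got {rate}")
    return np.asarray(amount, dtype=float) / rate \
        if np.ndim(amount) else float(amount) / rate


def present(amount: float, decimals: int = 2) -> float:
    """Presentation rounding: half away from zero at ``decimals`` places."""
    q = Decimal(1).scaleb(-decimals)
    d = Decimal(repr(float(amount))).quantize(q, rounding=ROUND_HALF_UP)
    return float(d)


def who_threshold(gdp_per_capita: float) -> float:
    """WHO willingness-to-pay ceiling: 3 × GDP per capita."""
    if gdp_per_capita <= 0:
        raise ValueError(
            f"gdp_per_capita must be > 0, got {gdp_per_capita}")
    return 3.0 * gdp_per_capita
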