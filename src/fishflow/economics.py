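"""Supply-chain cost model: economies of scale from higher utilisation.

The supply chain cost ``C = C_f + C_v`` splits into a fixed component
(boats, infrastructure, processing facilities) and a variable component.
Two ratios parameterise the chain:

* ``k1`` — share of final market value consumed by the supply chain
  (industry range 40–60%),
* ``k2`` — share of supply-chain cost that is fixed (range 20–30%).

Baseline cost is ``C0 = k1·V_F`` with ``C_f = k2·C0``. When utilisation
rises from ``f0`` to ``f1``, variable cost scales with throughput
(``C = C_f + (f1/f0)·C_v0``) while the fixed cost is spread over the
larger marketed mass ``M_F = f1·M_H``, so the cost per marketed tonne
falls by::

    Δ(C/M_F) = C0/M_F0 − C/M_F = (f1 − f0) · C_f / (f1 · f0 · M_H)

which is independent of the variable cost. Because supply-chain cost is a
``k1``-share of market price, a cost saving propagates to the consumer
price as ``saving / k1``.

The model deliberately excludes capital, operating and transition costs of
the technologies themselves, and any demand response; the savings are
upper-bound efficiency gains conditional on adoption.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import pandas as pd

from .flow import GLOBAL_HARVEST_T, GLOBAL_PARAMS, effective_rates, net_utilisation

__all__ = [
    "EconParams",
    "EconResult",
    "GLOBAL_PRICE_USD_PER_T",
    "PUBLISHED_MARKET_VALUE_USD",
    "SCENARIOS",
    "decompose_costs",
    "baseline_cost_per_tonne",
    "delta_food_mass",
    "cost_saving_per_tonne",
    "price_reduction",
    "scenario_grid",
]

#: IMF benchmark global fish price, 2023 (USD per tonne).
GLOBAL_PRICE_USD_PER_T = 8957.45

#: Published annual market value estimate (USD). Note the internal
#: tension: P_F·M_H = 1.66e12 and P_F·f0·M_H = 0.90e12, neither of which
#: equals this figure; it is kept available as a compatibility override.
PUBLISHED_MARKET_VALUE_USD = 1.25e12

#: Named (k1, k2) scenarios: range endpoints and midpoints.
SCENARIOS = {
    "negative": (0.40, 0.20),
    "neutral": (0.50, 0.25),
    "positive": (0.60, 0.30),
}

_GLOBAL_F0 = net_utilisation(effective_rates(GLOBAL_PARAMS, 0.0))


@dataclass(frozen=True)
class EconParams:
    """Economic parameterisation of the global fish supply chain.

    ``V_F`` (annual market value, USD) defaults to the internally
    consistent ``P_F · f0 · M_H``; pass ``published_compat=True`` to use the
    published 1.25 TUSD estimate instead.
    """

    M_H: float = GLOBAL_HARVEST_T
    P_F: float = GLOBAL_PRICE_USD_PER_T
    k1: float = 0.50
    k2: float = 0.25
    f0: float = _GLOBAL_F0
    V_F: float | None = None
    published_compat: bool = False

    def __post_init__(self) -> None:
        for name in ("M_H", "P_F"):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name}={v!r} must be positive")
        for name, lo, hi in (("k1", 0.0, 1.0), ("k2", 0.0, 1.0), ("f0", 0.0, 1.0)):
            v = getattr(self, name)
            if not (lo < v <= hi):
                raise ValueError(f"{name}={v!r} must lie in ({lo}, {hi}]")
        if self.V_F is not None and not (self.V_F > 0):
            raise ValueError(f"V_F={self.V_F!r} must be positive")

    @property
    def market_value(self) -> float:
        """Annual market value V_F in USD (override > compat > derived)."""
        if self.V_F is not None:
            return self.V_F
        if self.published_compat:
            return PUBLISHED_MARKET_VALUE_USD
        return self.P_F * self.f0 * self.M_H


@dataclass(frozen=True)
class EconResult:
    """Joined cost outputs for one (scenario, adoption) combination."""

    scenario: str
    k1: float
    k2: float
    f0: float
    f1: float
    C0: float
    Cf: float
    Cv0: float
    cost_per_tonne_baseline: float
    cost_per_tonne_scenario: float
    cost_saving_per_tonne: float
    price_reduction_per_tonne: float
    price_reduction_percent: float


def decompose_costs(params: EconParams) -> tuple[float, float, float]:
    """Split baseline supply-chain cost into total, fixed and variable.

    Returns ``(C0, Cf, Cv0)`` with ``C0 = k1·V_F``, ``Cf = k2·C0`` and
    ``Cv0 = (1−k2)·C0``.
    """
    C0 = params.k1 * params.market_value
    Cf = params.k2 * C0
    return C0, Cf, C0 - Cf


def baseline_cost_per_tonne(params: EconParams) -> float:
    """Baseline supply-chain cost per marketed tonne, ``k1·P_F`` (USD/t).

    Algebraically ``C0 / M_F0`` whenever ``V_F = P_F·M_F0``, so the result
    does not depend on which marketed-mass convention defines ``V_F``.
    The neutral scenario gives 0.5 × 8957.45 ≈ 4479 USD/t.
    """
    return params.k1 * params.P_F


def delta_food_mass(M_H: float, f0: float, f: float) -> float:
    """Additional food mass ``M_H·(f − f0)`` unlocked by adoption (t).

    Negative when utilisation falls below baseline, which is flagged with
    a warning rather than an error.
    """
    for name, v in (("f0", f0), ("f", f)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v!r} must lie in [0, 1]")
    delta = M_H * (f - f0)
    if delta < 0:
        warnings.warn(
            f"utilisation f={f} below baseline f0={f0}: negative food-mass gain",
            stacklevel=2,
        )
    return delta


def cost_saving_per_tonne(params: EconParams, f1: float) -> float:
    """Cost saving per marketed tonne when utilisation rises to ``f1``.

    Closed form ``(f1 − f0)·Cf / (f1·f0·M_H)`` (USD/t); depends on the
    fixed cost only — the variable component cancels because it scales
    exactly with throughput.
    """
    if not (0.0 < f1 <= 1.0):
        raise ValueError(f"f1={f1!r} must lie in (0, 1]")
    _, Cf, _ = decompose_costs(params)
    return (f1 - params.f0) * Cf / (f1 * params.f0 * params.M_H)


def price_reduction(cost_saving: float, params: EconParams) -> tuple[float, float]:
    """Propagate a per-tonne cost saving to the consumer price.

    Supply-chain cost is a ``k1``-share of the final market value, so a
    saving of ``s`` on the cost side lowers the price by ``s / k1``.
    Returns ``(USD/t, percent of P_F)``; a 374 USD/t saving at k1 = 0.5
    becomes a 748 USD/t (8.4%) price reduction.
    """
    if cost_saving < 0:
        raise ValueError("cost_saving must be non-negative")
    reduction = cost_saving / params.k1
    return reduction, 100.0 * reduction / params.P_F


def scenario_grid(
    f1: float,
    base: EconParams | None = None,
    scenarios: dict[str, tuple[float, float]] = SCENARIOS,
) -> pd.DataFrame:
    """Evaluate the named (k1, k2) scenarios at a target utilisation.

    Negative / neutral / positive use the endpoints and midpoint of the
    industry ``k1`` and ``k2`` ranges; savings order negative < neutral <
    positive because the fixed cost scales with ``k1·k2``.
    """
    if base is None:
        base = EconParams()
    if not (base.f0 <= f1 <= 1.0):
        raise ValueError(f"f1={f1!r} must lie in [f0={base.f0}, 1]")
    rows = []
    for label, (k1, k2) in scenarios.items():
        p = EconParams(
            M_H=base.M_H, P_F=base.P_F, k1=k1, k2=k2, f0=base.f0,
            V_F=base.V_F, published_compat=base.published_compat,
        )
        C0, Cf, Cv0 = decompose_costs(p)
        saving = cost_saving_per_tonne(p, f1)
        red, red_pct = price_reduction(saving, p)
        base_cpt = baseline_cost_per_tonne(p)
        rows.append(
            EconResult(
                scenario=label, k1=k1, k2=k2, f0=p.f0, f1=f1,
                C0=C0, Cf=Cf, Cv0=Cv0,
                cost_per_tonne_baseline=base_cpt,
                cost_per_tonne_scenario=base_cpt - saving,
                cost_saving_per_tonne=saving,
                price_reduction_per_tonne=red,
                price_reduction_percent=red_pct,
            ).__dict__
        )
    return pd.DataFrame(rows)
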