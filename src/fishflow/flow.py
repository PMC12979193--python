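"""Four-stage mass-flow model of the fish post-harvest value chain.

The model tracks one unit of harvested biomass ``M_H`` through three
sequential decisions:

1. **Allocation** — a fraction ``a`` enters food-use pathways
   (``M1 = a·M_H``); the rest is diverted to productive non-food uses such
   as fishmeal, fish oil and pet food (``M2``).
2. **Post-harvest loss** — of the food-use stream, a fraction ``b``
   survives capture, landing, transport and processing losses
   (``M3 = b·M1``); the complement ``M4`` is lost or wasted and is treated
   as unrecoverable within the system boundary.
3. **By-product management** — processing splits the surviving stream into
   an edible portion ``M_D = c·M3`` consumed directly and structurally
   inedible by-products ``M_B = (1−c)·M3`` (heads, frames, skin, viscera),
   of which a fraction ``d`` is re-valorised into food (``M_R = d·M_B``).

The net utilisation rate is the fraction of the harvest that people
ultimately eat, including re-utilised by-products::

    f = (M_D + M_R) / M_H = a · b · (c + (1 − c) · d)

Technology adoption is a single scalar ``x ∈ [0, 1]`` that moves the three
improvable sub-rates linearly toward their stated ceilings::

    a(x) = a0 + (1 − a0) · lim_a · x
    b(x) = 1 − (1 − b0) · (1 − lim_b · x)
    d(x) = d0 + (d_max − d0) · x

``c`` (edible-portion yield) is a biological constant and does not respond
to adoption. All rates are stored as fractions in [0, 1]; percentages
appear only at I/O boundaries.

At-sea discards, crustaceans and molluscs are outside the system boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "UtilisationParams",
    "AdoptionScenario",
    "EffectiveRates",
    "MassFlowLedger",
    "GLOBAL_PARAMS",
    "GLOBAL_HARVEST_T",
    "effective_rates",
    "net_utilisation",
    "mass_ledger",
    "share_breakdown",
    "adoption_sweep",
    "flow_edges",
    "as_percent",
]

#: Global harvested mass of aquatic animals (tonnes/year): 91 Mt capture
#: plus 94 Mt aquaculture.
GLOBAL_HARVEST_T = 185e6


def _check_fraction(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise TypeError(f"{name} must be a number, got {type(value).__name__}")
    if not math.isfinite(value) or not (lo <= value <= hi):
        raise ValueError(f"{name}={value!r} must lie in [{lo}, {hi}]")


@dataclass(frozen=True)
class UtilisationParams:
    """Per-region sub-rates and improvement ceilings of the value chain.

    Parameters
    ----------
    region
        Free-form region label (e.g. ``"Global"``, ``"Africa"``).
    a0
        Baseline fraction of harvest allocated to food use.
    b0
        Baseline fraction of the food-use stream surviving post-harvest
        loss.
    c
        Edible-portion yield at processing (constant across scenarios).
    d0
        Baseline fraction of by-products re-utilised as food.
    lim_a
        Maximum achievable improvement fraction of the non-food share
        (part of non-food use is structurally non-recoverable).
    lim_b
        Maximum stabilisable fraction of post-harvest losses.
    d_max
        Maximum food-usable fraction of by-products (bones excluded).
    """

    region: str
    a0: float
    b0: float
    c: float
    d0: float
    lim_a: float
    lim_b: float
    d_max: float

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "region":
                continue
            _check_fraction(f"{f.name} (region {self.region!r})", getattr(self, f.name))
        if self.d_max < self.d0:
            raise ValueError(
                f"d_max={self.d_max} must be >= d0={self.d0} (region {self.region!r})"
            )


#: Global baseline parameterisation (FAO-scale aggregates).
GLOBAL_PARAMS = UtilisationParams(
    region="Global",
    a0=0.89,
    b0=0.81,
    c=0.65,
    d0=0.30,
    lim_a=0.68,
    lim_b=0.56,
    d_max=0.70,
)


@dataclass(frozen=True)
class AdoptionScenario:
    """A technology adoption level ``x`` in [0, 1].

    ``x`` scales all three improvement pathways — allocation, loss
    prevention and by-product reuse — simultaneously toward their limits
    (harmonised adoption); it is not a per-node adoption vector.
    """

    x: float

    def __post_init__(self) -> None:
        _check_fraction("x", self.x)


@dataclass(frozen=True)
class EffectiveRates:
    """Sub-rates (a, b, c, d) effective at a given adoption level."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            _check_fraction(name, getattr(self, name))


@dataclass(frozen=True)
class MassFlowLedger:
    """All masses (tonnes) of one scenario, plus the realised rate ``f``.

    Invariants (enforced on construction to 1e-9 relative):
    ``M1 + M2 == M_H``; ``M3 + M4 == M1``; ``M_D + M_B == M3``;
    ``M_F == M_D + M_R``; ``M2 + M4 + M_D + M_B == M_H`` (full partition);
    ``f·M_H == M_F``.
    """

    M_H: float
    M1: float
    M2: float
    M3: float
    M4: float
    M_D: float
    M_B: float
    M_R: float
    M_F: float
    f: float

    def __post_init__(self) -> None:
        if not (self.M_H > 0) or not math.isfinite(self.M_H):
            raise ValueError(f"M_H={self.M_H!r} must be a positive, finite mass")
        tol = 1e-9 * self.M_H
        checks = [
            ("M1 + M2 == M_H", self.M1 + self.M2, self.M_H),
            ("M3 + M4 == M1", self.M3 + self.M4, self.M1),
            ("M_D + M_B == M3", self.M_D + self.M_B, self.M3),
            ("M_F == M_D + M_R", self.M_F, self.M_D + self.M_R),
            ("partition M2+M4+M_D+M_B == M_H", self.M2 + self.M4 + self.M_D + self.M_B, self.M_H),
            ("f * M_H == M_F", self.f * self.M_H, self.M_F),
        ]
        for label, lhs, rhs in checks:
            if abs(lhs - rhs) > tol:
                raise ValueError(f"ledger violates {label}: {lhs!r} vs {rhs!r}")
        if self.M_R > self.M_B + tol:
            raise ValueError("re-utilised by-products M_R exceed by-products M_B")


def effective_rates(
    params: UtilisationParams, scenario: AdoptionScenario | float
) -> EffectiveRates:
    """Transform baseline sub-rates under technology adoption level ``x``.

    Each improvable rate moves affinely from its baseline toward its
    ceiling: at ``x = 0`` the baselines are returned unchanged, at
    ``x = 1`` allocation reaches ``a0 + (1−a0)·lim_a``, the loss complement
    shrinks by the factor ``1 − lim_b``, and by-product reuse reaches
    ``d_max``. The edible yield ``c`` passes through unchanged.
    """
    if not isinstance(scenario, AdoptionScenario):
        scenario = AdoptionScenario(float(scenario))
    x = scenario.x
    a = params.a0 + (1.0 - params.a0) * params.lim_a * x
    b = 1.0 - (1.0 - params.b0) * (1.0 - params.lim_b * x)
    d = params.d0 + (params.d_max - params.d0) * x
    return EffectiveRates(a=a, b=b, c=params.c, d=d)


def net_utilisation(rates: EffectiveRates) -> float:
    """Closed-form net utilisation rate ``f = a·b·(c + (1−c)·d)``.

    Called with baseline rates this is the current (no-adoption) rate;
    globally that is 0.544, reported as 54%.
    """
    return rates.a * rates.b * (rates.c + (1.0 - rates.c) * rates.d)


def mass_ledger(
    params: UtilisationParams,
    scenario: AdoptionScenario | float,
    M_H: float = GLOBAL_HARVEST_T,
) -> MassFlowLedger:
    """Populate the full mass ledger for one (params, adoption) scenario.

    Constructs every node mass of the flow chain explicitly; the resulting
    ``f`` field always agrees with :func:`net_utilisation` on the same
    effective rates because the ledger realises the same sequential,
    mutually exclusive partition.
    """
    if not (isinstance(M_H, (int, float)) and math.isfinite(M_H) and M_H > 0):
        raise ValueError(f"M_H={M_H!r} must be a positive, finite mass in tonnes")
    r = effective_rates(params, scenario)
    M1 = r.a * M_H
    M2 = M_H - M1
    M3 = r.b * M1
    M4 = M1 - M3
    M_D = r.c * M3
    M_B = M3 - M_D
    M_R = r.d * M_B
    M_F = M_D + M_R
    return MassFlowLedger(
        M_H=M_H, M1=M1, M2=M2, M3=M3, M4=M4,
        M_D=M_D, M_B=M_B, M_R=M_R, M_F=M_F, f=M_F / M_H,
    )


@dataclass(frozen=True)
class ShareBreakdown:
    """Fate of the harvest as four exhaustive shares summing to one."""

    consumed: float
    nonfood: float
    byproduct_unused: float
    loss: float


def share_breakdown(ledger: MassFlowLedger) -> ShareBreakdown:
    """Split ``M_H`` into consumed / non-food / unused by-product / loss.

    Globally at baseline this is 54% consumed, 11% non-food, 18%
    non-reutilised by-products and 17% direct post-harvest loss.
    """
    return ShareBreakdown(
        consumed=ledger.M_F / ledger.M_H,
        nonfood=ledger.M2 / ledger.M_H,
        byproduct_unused=(ledger.M_B - ledger.M_R) / ledger.M_H,
        loss=ledger.M4 / ledger.M_H,
    )


_LEDGER_COLS = ["M_H", "M1", "M2", "M3", "M4", "M_D", "M_B", "M_R", "M_F", "f"]
_SHARE_COLS = ["share_consumed", "share_nonfood", "share_byproduct_unused", "share_loss"]


def adoption_sweep(
    params: UtilisationParams,
    xs: list[float],
    M_H: float = GLOBAL_HARVEST_T,
) -> pd.DataFrame:
    """Evaluate the ledger across adoption levels.

    Returns one row per ``x`` with all ledger masses, ``f`` and the four
    shares; ``f`` is non-decreasing along increasing ``x``. An empty
    ``xs`` yields an empty frame with the full schema.
    """
    rows = []
    for x in xs:
        led = mass_ledger(params, x, M_H)
        sh = share_breakdown(led)
        rows.append(
            {"region": params.region, "x": float(x)}
            | {c: getattr(led, c) for c in _LEDGER_COLS}
            | {
                "share_consumed": sh.consumed,
                "share_nonfood": sh.nonfood,
                "share_byproduct_unused": sh.byproduct_unused,
                "share_loss": sh.loss,
            }
        )
    return pd.DataFrame(rows, columns=["region", "x"] + _LEDGER_COLS + _SHARE_COLS)


#: Fixed Sankey edge order: harvest splits, then loss stage, then
#: by-product stage. Order is part of the file contract (bit-stable
#: exports).
_EDGES = [
    ("harvest", "food_use", "M1"),
    ("harvest", "non_food_use", "M2"),
    ("food_use", "consumption_stage", "M3"),
    ("food_use", "post_harvest_loss", "M4"),
    ("consumption_stage", "direct_consumption", "M_D"),
    ("consumption_stage", "by_products", "M_B"),
    ("by_products", "reutilised_food", "M_R"),
    ("by_products", "unutilised_byproduct", None),  # M_B - M_R
]


def flow_edges(
    ledger: MassFlowLedger, region: str = "Global", x: float = 0.0
) -> pd.DataFrame:
    """Export one scenario's ledger as a Sankey-style edge list.

    Columns: region, x, source_node, target_node, mass_t, share (of
    ``M_H``), with a fixed node ordering.
    """
    rows = []
    for src, dst, attr in _EDGES:
        mass = (ledger.M_B - ledger.M_R) if attr is None else getattr(ledger, attr)
        rows.append(
            {
                "region": region,
                "x": float(x),
                "source_node": src,
                "target_node": dst,
                "mass_t": mass,
                "share": mass / ledger.M_H,
            }
        )
    return pd.DataFrame(rows)


def as_percent(fraction: float, ndigits: int = 0) -> float:
    """Render a fraction on the percent scale with round-half-even.

    Integer-percent reporting (``ndigits=0``) matches the printed global
    figures 54, 66 and 74, and returns an ``int``.
    """
    value = round(100.0 * fraction, ndigits)
    return int(value) if ndigits == 0 else value
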