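"""Nutrition layer: portions, protein supply and RDA coverage.

Recovered biomass is expressed as 100-g edible portions, as protein mass
(20% average muscle protein), as adult-equivalents (annual requirement
17.5 kg/person, i.e. 0.83 g·kg⁻¹·day⁻¹ for a 58-kg reference woman), and
as the fraction of a global population whose protein needs a given portion
stream could partially meet.

RDA coverage of a 100-g dry-weight serving is::

    coverage % = 100 × nutrient content / daily requirement

Daily requirements reference a non-pregnant adult woman (19–30 y, 58 kg);
amino-acid requirements given per kg body weight are converted to absolute
amounts. Total lipids are expressed as a percentage of dietary energy and
are excluded from coverage.

The packaged composition table describes a protein isolate produced from
Atlantic herring (*Clupea harengus*) backbones by pH-shift processing.
Oily pelagics are nutrient-rich, so these values are an upper envelope,
not a global species-weighted average.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "NutrientRecord",
    "PortionSpec",
    "GRAMS_PER_TONNE",
    "load_nutrient_table",
    "default_nutrient_table",
    "rda_coverage",
    "coverage_table",
    "mass_to_portions_per_day",
    "protein_mass",
    "adult_equivalents",
    "population_coverage",
]

GRAMS_PER_TONNE = 1e6
DAYS_PER_YEAR = 365.0

#: Mass-unit conversion factors to grams.
_UNIT_TO_G = {"g": 1.0, "mg": 1e-3, "ug": 1e-6, "µg": 1e-6, "mcg": 1e-6}


def _to_grams(value: float, unit: str) -> float:
    try:
        return value * _UNIT_TO_G[unit.strip()]
    except KeyError:
        raise ValueError(f"unknown mass unit {unit!r} (expected g, mg or ug)") from None


@dataclass(frozen=True)
class NutrientRecord:
    """One nutrient: content per 100 g dry weight and its daily requirement.

    ``requirement`` may be ``None`` for nutrients whose reference is not a
    daily mass (total lipids, expressed as % of dietary energy); such
    records are excluded from coverage. ``requirement_per_kg_mg`` carries
    the raw per-kg-bodyweight requirement (mg·kg⁻¹·day⁻¹) where the
    published absolute value is a rounded conversion.
    """

    name: str
    category: str
    content: float
    content_unit: str
    requirement: float | None
    requirement_unit: str | None
    requirement_basis: str = "absolute"
    requirement_per_kg_mg: float | None = None

    def __post_init__(self) -> None:
        if self.content < 0 or not math.isfinite(self.content):
            raise ValueError(f"{self.name}: content must be non-negative")
        _to_grams(1.0, self.content_unit)
        if self.requirement is not None:
            if self.requirement < 0 or not math.isfinite(self.requirement):
                raise ValueError(f"{self.name}: requirement must be non-negative")
            _to_grams(1.0, self.requirement_unit)

    @property
    def content_g(self) -> float:
        return _to_grams(self.content, self.content_unit)

    def requirement_g(
        self, exact_bodyweight: bool = False, bodyweight_kg: float = 58.0
    ) -> float | None:
        """Daily requirement in grams.

        With ``exact_bodyweight`` the per-kg requirement is converted at
        the reference body weight instead of using the published rounded
        absolute value (48 g/day for protein becomes 0.83 × 58 = 48.14).
        """
        if self.requirement is None:
            return None
        if exact_bodyweight and self.requirement_per_kg_mg is not None:
            return self.requirement_per_kg_mg * bodyweight_kg * 1e-3
        return _to_grams(self.requirement, self.requirement_unit)


def rda_coverage(
    record: NutrientRecord,
    exact_bodyweight: bool = False,
    bodyweight_kg: float = 58.0,
) -> float:
    """Percent of the daily requirement covered by 100 g DW of isolate.

    Raises for records without a mass-based daily requirement (total
    lipids) or with a zero requirement.
    """
    req = record.requirement_g(exact_bodyweight, bodyweight_kg)
    if req is None:
        raise ValueError(
            f"{record.name}: no mass-based daily requirement; excluded from coverage"
        )
    if req == 0:
        raise ValueError(f"{record.name}: zero daily requirement")
    return 100.0 * record.content_g / req


def load_nutrient_table(path: str | Path) -> list[NutrientRecord]:
    """Read nutrient records from the CSV schema.

    Columns: ``name, category, content, content_unit, requirement,
    requirement_unit, requirement_basis`` and optionally
    ``requirement_per_kg_mg``. Empty requirement cells mean the nutrient
    is excluded from coverage.
    """
    df = pd.read_csv(path)
    required = ["name", "category", "content", "content_unit", "requirement",
                "requirement_unit", "requirement_basis"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for _, row in df.iterrows():
        has_req = pd.notna(row["requirement"])
        per_kg = row.get("requirement_per_kg_mg")
        records.append(
            NutrientRecord(
                name=str(row["name"]),
                category=str(row["category"]),
                content=float(row["content"]),
                content_unit=str(row["content_unit"]),
                requirement=float(row["requirement"]) if has_req else None,
                requirement_unit=str(row["requirement_unit"]) if has_req else None,
                requirement_basis=str(row["requirement_basis"]),
                requirement_per_kg_mg=float(per_kg) if pd.notna(per_kg) else None,
            )
        )
    return records


def default_nutrient_table() -> list[NutrientRecord]:
    """The packaged herring-backbone protein-isolate composition table."""
    source = resources.files("fishflow").joinpath("data/nutrients.csv")
    with resources.as_file(source) as path:
        return load_nutrient_table(path)


def coverage_table(
    records: list[NutrientRecord], exact_bodyweight: bool = False
) -> pd.DataFrame:
    """Coverage of every coverable record, as integer percent (half-even).

    Columns: name, category, content_g, requirement_g, coverage_percent.
    """
    rows = []
    for rec in records:
        req = rec.requirement_g(exact_bodyweight)
        if req is None:
            continue
        cov = rda_coverage(rec, exact_bodyweight)
        rows.append(
            {
                "name": rec.name,
                "category": rec.category,
                "content_g": rec.content_g,
                "requirement_g": req,
                "coverage_percent": int(round(cov)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PortionSpec:
    """Serving-size and requirement conventions for population arithmetic."""

    portion_mass_g: float = 100.0
    protein_fraction: float = 0.20
    annual_protein_requirement_kg: float = 17.5
    daily_protein_requirement_g: float = 48.0
    population: float = 8.0e9

    def __post_init__(self) -> None:
        for name in (
            "portion_mass_g",
            "protein_fraction",
            "annual_protein_requirement_kg",
            "daily_protein_requirement_g",
            "population",
        ):
            v = getattr(self, name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"{name}={v!r} must be positive")

    def with_overrides(self, **kwargs) -> "PortionSpec":
        return replace(self, **kwargs)


def mass_to_portions_per_day(
    annual_mass_t: float, spec: PortionSpec = PortionSpec()
) -> float:
    """Daily number of portions an annual mass stream provides.

    31 Mt/year of recoverable loss corresponds to about 850 million 100-g
    portions every day.
    """
    if annual_mass_t < 0:
        raise ValueError("annual mass must be non-negative")
    return annual_mass_t * GRAMS_PER_TONNE / spec.portion_mass_g / DAYS_PER_YEAR


def protein_mass(annual_mass_t: float, spec: PortionSpec = PortionSpec()) -> float:
    """Protein contained in an annual fish-mass stream (t/year)."""
    if annual_mass_t < 0:
        raise ValueError("annual mass must be non-negative")
    return annual_mass_t * spec.protein_fraction


def adult_equivalents(
    protein_t_per_year: float, spec: PortionSpec = PortionSpec()
) -> float:
    """Number of adults whose annual protein requirement a stream meets.

    2 Mt/year of protein at 17.5 kg per person-year feeds about
    114 million adults.
    """
    if protein_t_per_year < 0:
        raise ValueError("protein mass must be non-negative")
    return protein_t_per_year * 1e3 / spec.annual_protein_requirement_kg


def population_coverage(
    portions_per_day: float,
    requirement_fraction: float = 0.5,
    spec: PortionSpec = PortionSpec(),
) -> float:
    """Fraction of the population given a share of its daily protein need.

    Each portion supplies ``portion_mass_g × protein_fraction`` grams of
    protein; the stream covers people at ``requirement_fraction`` of their
    daily protein requirement each.
    """
    if not (0 < requirement_fraction <= 1):
        raise ValueError("requirement_fraction must lie in (0, 1]")
    if portions_per_day < 0:
        raise ValueError("portions_per_day must be non-negative")
    protein_per_portion_g = spec.portion_mass_g * spec.protein_fraction
    persons = (
        portions_per_day
        * protein_per_portion_g
        / (spec.daily_protein_requirement_g * requirement_fraction)
    )
    return persons / spec.population
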