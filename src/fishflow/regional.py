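"""Per-region parameter tables and regional adoption sweeps.

Loss accounting is already reported at continental scale by its primary
sources, so the model evaluates each region independently — there is no
country-level aggregation or re-averaging, and no cross-region averaging
of results. Only the global record is shipped with the package; regional
records are user-supplied (CSV) or synthesised (see
:mod:`fishflow.synth`), never invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .flow import GLOBAL_PARAMS, UtilisationParams, adoption_sweep, _SHARE_COLS

__all__ = [
    "RegionalParameterTable",
    "PARAM_COLUMNS",
    "load_regional_table",
    "write_regional_table",
    "regional_sweep",
]

PARAM_COLUMNS = ["region", "a0", "b0", "c", "d0", "lim_a", "lim_b", "d_max"]
_RATE_COLUMNS = PARAM_COLUMNS[1:]


@dataclass(frozen=True)
class RegionalParameterTable:
    """A validated set of :class:`UtilisationParams`, one per region.

    ``provenance`` records where the numbers came from: ``"global"`` for
    the shipped worldwide aggregate, ``"supplementary"`` for user-supplied
    continental data, ``"synthetic"`` for generated fixtures.
    """

    records: tuple[UtilisationParams, ...]
    provenance: str = "supplementary"
    harvest_t: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = [r.region for r in self.records]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ValueError(f"duplicate region labels: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, region: str) -> UtilisationParams:
        for r in self.records:
            if r.region == region:
                return r
        raise KeyError(region)

    @classmethod
    def global_only(cls) -> "RegionalParameterTable":
        from .flow import GLOBAL_HARVEST_T

        return cls(
            records=(GLOBAL_PARAMS,),
            provenance="global",
            harvest_t={GLOBAL_PARAMS.region: GLOBAL_HARVEST_T},
        )


def _parse_rate(value, region: str, column: str) -> float:
    """Accept a fraction or a '%'-suffixed percentage; normalise to fraction."""
    if isinstance(value, str):
        text = value.strip()
        if text.endswith("%"):
            try:
                return float(text[:-1].strip()) / 100.0
            except ValueError:
                raise ValueError(
                    f"region {region!r}: cannot parse {column}={value!r}"
                ) from None
        value = float(text)
    return float(value)


def load_regional_table(
    path: str | Path, provenance: str = "supplementary"
) -> RegionalParameterTable:
    """Read a parameter CSV into a validated table.

    The schema is ``region, a0, b0, c, d0, lim_a, lim_b, d_max`` with an
    optional ``M_H`` column (tonnes). Rate columns accept either fractions
    (``0.89``) or percentages with a ``%`` suffix (``89%``); both parse to
    the same value. Missing columns, out-of-range values and duplicate
    regions fail with messages naming the region and field.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    harvest: dict[str, float] = {}
    for _, row in df.iterrows():
        region = str(row["region"]).strip()
        kwargs = {
            col: _parse_rate(row[col], region, col) for col in _RATE_COLUMNS
        }
        records.append(UtilisationParams(region=region, **kwargs))
        if "M_H" in df.columns and pd.notna(row["M_H"]) and str(row["M_H"]).strip():
            harvest[region] = float(row["M_H"])
    return RegionalParameterTable(
        records=tuple(records), provenance=provenance, harvest_t=harvest
    )


def write_regional_table(table: RegionalParameterTable, path: str | Path) -> None:
    """Write a table back to the CSV schema (fractions, full precision)."""
    rows = []
    for r in table.records:
        row = {f.name: getattr(r, f.name) for f in fields(r)}
        if r.region in table.harvest_t:
            row["M_H"] = table.harvest_t[r.region]
        rows.append(row)
    cols = PARAM_COLUMNS + (["M_H"] if table.harvest_t else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.17g")


def regional_sweep(
    table: RegionalParameterTable,
    xs: list[float],
    default_harvest_t: float = 1.0,
) -> pd.DataFrame:
    """Evaluate every region across the given adoption levels.

    Returns one row per (region, x) with columns ``region, x, f,
    share_consumed, share_nonfood, share_byproduct_unused, share_loss``,
    ordered by region then x. Regions without a harvest mass are evaluated
    on a unit mass — rates and shares are mass-invariant.
    """
    frames = []
    for rec in table.records:
        m_h = table.harvest_t.get(rec.region, default_harvest_t)
        frames.append(adoption_sweep(rec, list(xs), m_h))
    cols = ["region", "x", "f"] + _SHARE_COLS
    if not frames:
        return pd.DataFrame(columns=cols)
    out = pd.concat(frames, ignore_index=True)
    return out[cols]
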