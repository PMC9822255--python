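"""Delimited-table and JSON I/O for the migration pipeline.

All tables are UTF-8 CSV with a header row and '.' decimal separator;
reproducibility metadata (model parameters, seeds) travels in '#'-prefixed
comment lines above the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .scenarios import CONDITIONS, ContactScenario, build_default_scenarios
from .solver import ContactGeometry

__all__ = [
    "read_table",
    "write_table",
    "read_cp0_table",
    "write_cp0_table",
    "read_scenarios_json",
    "write_scenarios_json",
    "write_default_scenarios_json",
    "SchemaError",
]


class SchemaError(ValueError):
    """A table does not carry the columns its schema requires."""


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a '#'-commented CSV and validate required columns."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    return df


def write_table(
    path: str | Path, df: pd.DataFrame, metadata: Optional[Mapping[str, object]] = None
) -> Path:
    """Write a CSV with '#'-prefixed metadata comment lines."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)
    return path


_CP0_COLUMNS = ("acronym", "cp0_min_mg_kg", "cp0_max_mg_kg")


def read_cp0_table(path: str | Path) -> dict[str, tuple[float, float]]:
    """Read a C_P,0 table (acronym, cp0_min_mg_kg, cp0_max_mg_kg)."""
    df = read_table(path, required=_CP0_COLUMNS)
    out: dict[str, tuple[float, float]] = {}
    for row in df.itertuples(index=False):
        out[str(row.acronym)] = (float(row.cp0_min_mg_kg), float(row.cp0_max_mg_kg))
    return out


def write_cp0_table(
    path: str | Path,
    table: Mapping[str, tuple[float, float]],
    seed: Optional[int] = None,
) -> Path:
    df = pd.DataFrame(
        [(a, lo, hi) for a, (lo, hi) in table.items()], columns=list(_CP0_COLUMNS)
    )
    meta: dict[str, object] = {"schema": "cp0_mg_kg_polymer"}
    if seed is not None:
        meta["seed"] = seed
    return write_table(path, df, metadata=meta)


def _scenario_to_dict(s: ContactScenario) -> dict:
    return dict(
        name=s.name,
        area_cm2=s.geometry.area,
        food_volume_cm3=s.geometry.food_volume,
        thickness_cm=s.geometry.thickness,
        rho_polymer_g_cm3=s.geometry.rho_polymer,
        rho_food_g_cm3=s.geometry.rho_food,
        temperature_K=s.temperature,
        time_s=s.t,
        condition_id=s.condition_id,
    )


def write_scenarios_json(path: str | Path, scenarios: Sequence[ContactScenario]) -> Path:
    path = Path(path)
    payload = {"scenarios": [_scenario_to_dict(s) for s in scenarios]}
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path


def write_default_scenarios_json(path: str | Path) -> Path:
    return write_scenarios_json(path, build_default_scenarios())


def read_scenarios_json(path: str | Path) -> list[ContactScenario]:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    try:
        raw = payload["scenarios"]
    except (TypeError, KeyError) as exc:
        raise SchemaError(f"{path}: expected a top-level 'scenarios' list") from exc
    scenarios = []
    for item in raw:
        try:
            geom = ContactGeometry(
                area=float(item["area_cm2"]),
                food_volume=float(item["food_volume_cm3"]),
                thickness=float(item["thickness_cm"]),
                rho_polymer=float(item.get("rho_polymer_g_cm3", 1.4)),
                rho_food=float(item.get("rho_food_g_cm3", 1.0)),
            )
            scenarios.append(
                ContactScenario(
                    name=str(item["name"]),
                    geometry=geom,
                    temperature=float(item["temperature_K"]),
                    t=float(item["time_s"]),
                    condition_id=int(item["condition_id"]),
                )
            )
        except KeyError as exc:
            raise SchemaError(f"{path}: scenario entry missing {exc}") from exc
    return scenarios
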