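"""Synthetic study inputs: in-polymer concentration tables and solver fixtures.

Literature in-polymer concentrations (C_P,0) for PET oligomers exist only in
scattered appendix compilations; this module generates tables with the same
*structure* — per-oligomer min/max ranges, available for 29 of the 52
oligomers, spanning orders of magnitude, with the first-series cyclic trimer
boosted to emulate its repeatedly reported high abundance — without any
claim of matching the real values.  Everything is deterministic under a
seed.

It also provides a clearly synthetic molecular-volume correlation for the
activation-energy diffusion model (anchored to the single genuinely
calibrated substance) so that the full dual-model pipeline can run end to
end, plus a grid of solver fixtures for series-vs-finite-difference
cross-checks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import (
    ArrheniusParams,
    CYCLIC_TRIMER_ARRHENIUS,
    CYCLIC_TRIMER_MV,
    R_GAS,
    WELLE_PET,
    WelleParams,
)
from .oligomers import OligomerRecord, load_oligomers
from .solver import ContactGeometry, MigrationSpec

__all__ = [
    "Cp0GeneratorConfig",
    "synth_cp0_table",
    "synthetic_welle_correlation",
    "synth_sensitivity_grid",
    "write_fixture_bundle",
]


@dataclass(frozen=True)
class Cp0GeneratorConfig:
    """Configuration of the synthetic C_P,0 generator.

    Defaults mirror the structure of the real compilation: 29 of 52
    oligomers carry data; concentrations are log-uniform between 0.1 and
    about 5000 mg/kg; ranges spread by at most a factor 100; everything is
    capped at 1 % w/w (1e4 mg/kg); the first-series cyclic trimer draws
    from the top decade.
    """

    seed: int = 0
    n_with_data: int = 29
    log10_range: tuple[float, float] = (-1.0, 3.7)  # mg/kg
    max_spread: float = 100.0  # cp0_max / cp0_min
    cap_at_1pct: bool = True
    boost_acronyms: tuple[str, ...] = ("C[TPA+EG]3",)

    def __post_init__(self) -> None:
        if not (0 < self.n_with_data <= 52):
            raise ValueError("n_with_data must be in 1..52")
        if self.log10_range[0] >= self.log10_range[1]:
            raise ValueError("log10_range must be ordered")
        if self.max_spread < 1:
            raise ValueError("max_spread must be >= 1")


_CAP = 1e4  # mg/kg, 1 % w/w


def synth_cp0_table(
    config: Cp0GeneratorConfig = Cp0GeneratorConfig(),
    records: Optional[Sequence[OligomerRecord]] = None,
) -> dict[str, tuple[float, float]]:
    """Draw a synthetic C_P,0 table ``{acronym: (cp0_min, cp0_max)}`` mg/kg.

    Exactly ``n_with_data`` oligomers are selected without replacement
    (boosted acronyms always included); ``cp0_min`` is log-uniform over
    ``log10_range``, ``cp0_max = cp0_min * U(1, max_spread)``, both capped
    at 1e4 mg/kg when ``cap_at_1pct``.
    """
    if records is None:
        records = load_oligomers()
    rng = np.random.default_rng(config.seed)
    acronyms = [r.acronym for r in records]
    boosted = [a for a in config.boost_acronyms if a in acronyms]
    pool = [a for a in acronyms if a not in boosted]
    n_rest = config.n_with_data - len(boosted)
    chosen = boosted + list(rng.choice(pool, size=n_rest, replace=False))
    lo10, hi10 = config.log10_range
    table: dict[str, tuple[float, float]] = {}
    for acr in chosen:
        if acr in boosted:
            # top decade of the configured range
            lo = 10.0 ** rng.uniform(hi10 - 1.0, hi10)
        else:
            lo = 10.0 ** rng.uniform(lo10, hi10)
        hi = lo * rng.uniform(1.0, config.max_spread)
        if config.cap_at_1pct:
            lo, hi = min(lo, _CAP), min(hi, _CAP)
        table[acr] = (lo, hi)
    # deterministic ordering for reproducible files
    return {a: table[a] for a in acronyms if a in table}


def synthetic_welle_correlation(
    mv: float, params: WelleParams = WELLE_PET
) -> ArrheniusParams:
    """SYNTHETIC molecular-volume correlation for the activation-energy model.

    This is a stand-in for the published correlation, which is not shipped:
    activation energy grows linearly with molecular volume through the one
    genuinely calibrated anchor (the first-series cyclic trimer,
    M_V = 484.64 A^3, E_A 210.4 kJ/mol), and the pre-exponential factor
    follows a compensation line through the same anchor with slope anchored
    at ln(b).  Use it for pipeline exercises and synthetic studies only —
    never to make claims about real substances other than the anchor.
    """
    if mv <= 0:
        raise ValueError("require M_V > 0")
    ea_ref = CYCLIC_TRIMER_ARRHENIUS.ea
    # linear growth chosen to land near 110 kJ/mol at the smallest packaged
    # oligomer (162.74 A^3), the order of magnitude reported for small
    # migrants in PET
    slope = (ea_ref - 110_000.0) / (CYCLIC_TRIMER_MV - 162.74)
    ea = max(ea_ref + slope * (mv - CYCLIC_TRIMER_MV), 40_000.0)
    # compensation line ln D0 = ln b + a_comp * EA / R through the anchor
    a_comp = (CYCLIC_TRIMER_ARRHENIUS.ln_d0 - np.log(params.b)) * R_GAS / ea_ref
    ln_d0 = float(np.log(params.b) + a_comp * ea / R_GAS)
    return ArrheniusParams(ea=ea, ln_d0=ln_d0)


def synth_sensitivity_grid(
    seed: int, n: int
) -> list[tuple[ContactGeometry, MigrationSpec]]:
    """Deterministic (geometry, spec) fixtures spanning tau in [1e-5, 10]
    and alpha in [1e-2, 1e4] for solver cross-checks."""
    if n < 1:
        raise ValueError("require n >= 1")
    rng = np.random.default_rng(seed)
    fixtures = []
    for _ in range(n):
        tau = 10.0 ** rng.uniform(-5.0, 1.0)
        alpha = 10.0 ** rng.uniform(-2.0, 4.0)
        thickness = 10.0 ** rng.uniform(-3.0, -1.0)  # 10 um .. 1 mm
        area = 10.0 ** rng.uniform(1.5, 3.0)
        k = 10.0 ** rng.uniform(0.0, 3.0)
        food_volume = alpha * k * area * thickness
        t = 10.0 ** rng.uniform(2.0, 8.0)
        d = tau * thickness**2 / t
        fixtures.append(
            (
                ContactGeometry(area=area, food_volume=food_volume, thickness=thickness),
                MigrationSpec(cp0=1000.0, d=d, k=k, t=t),
            )
        )
    return fixtures


def write_fixture_bundle(
    path: str | Path,
    cp0_table: dict[str, tuple[float, float]],
    seed: Optional[int] = None,
) -> dict[str, Path]:
    """Write the C_P,0 table and a scenario config consumed by the CLI.

    Returns the paths of the two files; both round-trip losslessly.
    """
    from .io import write_cp0_table, write_default_scenarios_json

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cp0_path = path / "cp0_synthetic.csv"
    write_cp0_table(cp0_path, cp0_table, seed=seed)
    scen_path = path / "scenarios.json"
    write_default_scenarios_json(scen_path)
    return {"cp0": cp0_path, "scenarios": scen_path}
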