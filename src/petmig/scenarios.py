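"""Application scenarios, safety thresholds, and exposure screening.

Twelve packaging scenarios are screened: three bottle sizes under ambient
(25 C, 365 d) and elevated (40 C, 60 d) storage, and two tray geometries
under heating conditions (70 C / 30 min, 100 C / 10 min, 100 C / 2 h).
Predicted food concentrations are compared against threshold-of-
toxicological-concern (TTC) food limits: Cramer class I for linear
oligomers (1.8 mg/kg food), Cramer class III for cyclic oligomers
(90 ug/kg food), and the stricter limit for potential DNA-reactive
mutagens/carcinogens (0.15 ug/kg food), all derived from exposure limits
via a 60 kg consumer eating 1 kg of packaged food per day.

The module also quantifies the sensitivity of predicted migration to the
(unknown) partition coefficient, and inverts the linear model to obtain
the maximum in-polymer concentration compatible with a threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .diffusion import DiffusionModel, resolve_model
from .oligomers import OligomerRecord
from .solver import ContactGeometry, MigrationSpec, migrate_series

__all__ = [
    "ContactScenario",
    "ThresholdSet",
    "ExposureAssessment",
    "CONDITIONS",
    "build_default_scenarios",
    "ttc_to_food_limit",
    "evaluate",
    "partition_sensitivity",
    "reverse_cp0",
    "classify_cp0",
    "exceedance_matrix",
    "DEFAULT_THRESHOLDS",
]

_DAY = 86_400.0
_C0 = 273.15

#: condition id -> (temperature K, contact time s)
CONDITIONS: dict[int, tuple[float, float]] = {
    1: (_C0 + 25.0, 365.0 * _DAY),  # end of shelf life, controlled storage
    2: (_C0 + 40.0, 60.0 * _DAY),  # extreme summer storage
    3: (_C0 + 70.0, 30.0 * 60.0),  # short microwave/oven heating
    4: (_C0 + 100.0, 10.0 * 60.0),  # short heating at the boiling point
    5: (_C0 + 100.0, 2.0 * 3600.0),  # long-term oven heating
}

_BOTTLE_CONDITIONS = (1, 2)
_TRAY_CONDITIONS = (3, 4, 5)


@dataclass(frozen=True)
class ContactScenario:
    """One named application scenario: geometry plus (T, t) condition."""

    name: str
    geometry: ContactGeometry
    temperature: float  # K
    t: float  # s
    condition_id: int

    def __post_init__(self) -> None:
        if self.condition_id not in CONDITIONS:
            raise ValueError(f"unknown condition id {self.condition_id}")
        if not (self.temperature > 0 and self.t > 0):
            raise ValueError("require T, t > 0")


def build_default_scenarios(thickness_um: float = 300.0) -> list[ContactScenario]:
    """The 12 default scenarios: 3 bottles x conditions 1-2 plus 2 trays x
    conditions 3-5, all with a 300 um PET wall."""
    thickness = thickness_um * 1e-4  # cm
    articles = [
        ("bottle_500mL", 420.0, 500.0, _BOTTLE_CONDITIONS),
        ("bottle_1000mL", 660.0, 1000.0, _BOTTLE_CONDITIONS),
        ("bottle_1500mL", 880.0, 1500.0, _BOTTLE_CONDITIONS),
        ("tray_rectangular", 566.0, 500.0, _TRAY_CONDITIONS),
        ("tray_round", 329.0, 637.0, _TRAY_CONDITIONS),
    ]
    scenarios = []
    for name, area, vol, condition_ids in articles:
        geom = ContactGeometry(area=area, food_volume=vol, thickness=thickness)
        for cid in condition_ids:
            temp, t = CONDITIONS[cid]
            scenarios.append(
                ContactScenario(
                    name=f"{name}_cond{cid}",
                    geometry=geom,
                    temperature=temp,
                    t=t,
                    condition_id=cid,
                )
            )
    return scenarios


def ttc_to_food_limit(ttc_ug_kg_bw_day: float, body_weight_kg: float, intake_kg_day: float) -> float:
    """Convert a TTC exposure limit (ug/kg bw/day) into a food limit
    (ug/kg food) for a consumer of given body weight and daily intake."""
    if ttc_ug_kg_bw_day <= 0 or body_weight_kg <= 0:
        raise ValueError("require positive TTC and body weight")
    if intake_kg_day <= 0:
        raise ValueError("daily intake must be positive")
    return ttc_ug_kg_bw_day * body_weight_kg / intake_kg_day


@dataclass(frozen=True)
class ThresholdSet:
    """Food-concentration limits derived from TTC exposure limits."""

    body_weight: float = 60.0  # kg
    daily_intake: float = 1.0  # kg food/day
    ttc_cramer1: float = 30.0  # ug/kg bw/day, linear oligomers
    ttc_cramer3: float = 1.5  # ug/kg bw/day, cyclic oligomers
    ttc_mutagen: float = 0.0025  # ug/kg bw/day, DNA-reactive mutagens

    @property
    def cramer1_food_mg_kg(self) -> float:
        return ttc_to_food_limit(self.ttc_cramer1, self.body_weight, self.daily_intake) / 1000.0

    @property
    def cramer3_food_ug_kg(self) -> float:
        return ttc_to_food_limit(self.ttc_cramer3, self.body_weight, self.daily_intake)

    @property
    def mutagen_food_ug_kg(self) -> float:
        return ttc_to_food_limit(self.ttc_mutagen, self.body_weight, self.daily_intake)

    def cramer_limit_mg_kg(self, topology: str) -> float:
        """Class limit by structure: linear -> Cramer I, cyclic -> Cramer III."""
        if topology == "linear":
            return self.cramer1_food_mg_kg
        if topology == "cyclic":
            return self.cramer3_food_ug_kg / 1000.0
        raise ValueError(f"unknown topology {topology!r}")


DEFAULT_THRESHOLDS = ThresholdSet()


@dataclass(frozen=True)
class ExposureAssessment:
    """Result of comparing one predicted migration against the thresholds."""

    acronym: str
    scenario: str
    model: str
    k: float
    cp0: float  # mg/kg polymer
    conc_food: float  # mg/kg food
    areal: float  # mg/dm^2
    cramer_class: str  # "I" (linear) or "III" (cyclic)
    exceeds_cramer: bool
    exceeds_mutagen: bool


def _model(model: Union[str, DiffusionModel]) -> DiffusionModel:
    return resolve_model(model) if isinstance(model, str) else model


def evaluate(
    record: OligomerRecord,
    scenario: ContactScenario,
    model: Union[str, DiffusionModel],
    k: float,
    cp0: float,
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
) -> ExposureAssessment:
    """Predict migration for one oligomer in one scenario and flag it
    against the mutagen limit and its structural Cramer-class limit."""
    mdl = _model(model)
    d = mdl.diffusion_coefficient(record, scenario.temperature)
    res = migrate_series(scenario.geometry, MigrationSpec(cp0=cp0, d=d, k=k, t=scenario.t))
    cramer_limit = thresholds.cramer_limit_mg_kg(record.topology)
    return ExposureAssessment(
        acronym=record.acronym,
        scenario=scenario.name,
        model=mdl.key,
        k=k,
        cp0=cp0,
        conc_food=res.conc_food,
        areal=res.areal,
        cramer_class="I" if record.topology == "linear" else "III",
        exceeds_cramer=res.conc_food > cramer_limit,
        exceeds_mutagen=res.conc_food > thresholds.mutagen_food_ug_kg / 1000.0,
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


# reference setup of the partition-sensitivity study: 6 dm^2 of a 10 um film
# against 1 kg of food, 1000 mg/kg in the polymer
_SENSITIVITY_GEOMETRY = dict(area=600.0, food_volume=1000.0, thickness=10e-4)
_SENSITIVITY_CP0 = 1000.0


def partition_sensitivity(
    record: OligomerRecord,
    condition_id: int,
    model: Union[str, DiffusionModel],
    thickness_cm: Optional[float] = None,
) -> int:
    """Integer percent deviation of migrated mass between K = 1 and K = 1000.

    Runs the reference setup (1000 mg/kg, 10 um film, 6 dm^2 per kg food)
    at the condition's (T, t) for both partition coefficients and returns
    ``round_half_up(100 (M_1 - M_1000) / M_1)``; 0 when nothing migrates.
    """
    if condition_id not in CONDITIONS:
        raise ValueError(f"unknown condition id {condition_id}")
    temp, t = CONDITIONS[condition_id]
    geom_kwargs = dict(_SENSITIVITY_GEOMETRY)
    if thickness_cm is not None:
        geom_kwargs["thickness"] = thickness_cm
    geom = ContactGeometry(**geom_kwargs)
    mdl = _model(model)
    d = mdl.diffusion_coefficient(record, temp)
    m1 = migrate_series(geom, MigrationSpec(_SENSITIVITY_CP0, d, 1.0, t)).areal
    m1000 = migrate_series(geom, MigrationSpec(_SENSITIVITY_CP0, d, 1000.0, t)).areal
    if m1 == 0.0:
        return 0
    return _round_half_up(100.0 * (m1 - m1000) / m1)


def reverse_cp0(
    record: OligomerRecord,
    scenario: ContactScenario,
    model: Union[str, DiffusionModel],
    threshold_conc_mg_kg: float,
    k: float = 1.0,
) -> float:
    """Maximum in-polymer concentration (mg/kg) whose predicted migration
    just reaches the food threshold; exploits linearity in cp0.

    Returns ``inf`` when no migration occurs at all (the threshold is
    unreachable).  The worst-case policy is K = 1.
    """
    if threshold_conc_mg_kg <= 0:
        raise ValueError("require a positive threshold concentration")
    probe = evaluate(record, scenario, model, k=k, cp0=1.0)
    if probe.conc_food <= 0.0:
        return math.inf
    return threshold_conc_mg_kg / probe.conc_food


def classify_cp0(cp0_mg_kg: float) -> str:
    """Plausibility of a computed in-polymer concentration.

    ``<= 1e4`` mg/kg (1 % w/w) -> ``"plausible"``; up to ``1e6`` (100 % w/w)
    -> ``"unlikely"``; beyond that (or unreachable) -> ``"impossible"``.
    """
    if cp0_mg_kg < 0:
        raise ValueError("require cp0 >= 0")
    if cp0_mg_kg <= 1e4:
        return "plausible"
    if cp0_mg_kg <= 1e6:
        return "unlikely"
    return "impossible"


#: deviation above which a second run at K = 1000 is added
DUAL_K_CUTOFF_PCT = 10


def exceedance_matrix(
    records: Sequence[OligomerRecord],
    scenarios: Sequence[ContactScenario],
    models: Sequence[Union[str, DiffusionModel]],
    k_policy: str = "dual_1_and_1000",
    cp0_choice: str = "max",
    thresholds: ThresholdSet = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Long-format exposure screen over oligomers x scenarios x models.

    Oligomers without a C_P,0 range are skipped.  Under the
    ``dual_1_and_1000`` policy a second prediction at K = 1000 is added for
    every (oligomer, condition, model) whose partition sensitivity exceeds
    10 %; ``worst_case_1`` always uses K = 1 only.
    """
    if k_policy not in ("worst_case_1", "dual_1_and_1000"):
        raise ValueError(f"unknown K policy {k_policy!r}")
    if cp0_choice not in ("min", "max"):
        raise ValueError("cp0_choice must be 'min' or 'max'")
    rows = []
    sens_cache: dict[tuple[str, int, str], int] = {}
    for model in models:
        mdl = _model(model)
        for rec in records:
            if not rec.has_cp0:
                continue
            cp0 = rec.cp0_min if cp0_choice == "min" else rec.cp0_max
            for scen in scenarios:
                ks = [1.0]
                if k_policy == "dual_1_and_1000":
                    key = (rec.acronym, scen.condition_id, mdl.key)
                    if key not in sens_cache:
                        sens_cache[key] = partition_sensitivity(rec, scen.condition_id, mdl)
                    if sens_cache[key] > DUAL_K_CUTOFF_PCT:
                        ks.append(1000.0)
                for k in ks:
                    a = evaluate(rec, scen, mdl, k=k, cp0=cp0, thresholds=thresholds)
                    rows.append(
                        dict(
                            oligomer=a.acronym,
                            scenario=a.scenario,
                            model=a.model,
                            K=a.k,
                            cp0_mg_kg=a.cp0,
                            conc_food_mg_kg=a.conc_food,
                            areal_mg_dm2=a.areal,
                            cramer_class=a.cramer_class,
                            exceeds_cramer=a.exceeds_cramer,
                            exceeds_mutagen=a.exceeds_mutagen,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "oligomer", "scenario", "model", "K", "cp0_mg_kg",
            "conc_food_mg_kg", "areal_mg_dm2", "cramer_class",
            "exceeds_cramer", "exceeds_mutagen",
        ],
    )
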