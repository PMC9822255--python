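"""Diffusion-coefficient prediction models for migrants in PET.

Two model families are provided:

* the empirical polymer-constant ("A_P") model, exponential in molecular
  weight and reciprocal temperature with PET-specific constants A'_P and a
  temperature correction tau — shipped in its *realistic* and intentionally
  over-estimative *upper-limit* parameterisations;
* an activation-energy-based model in which each migrant carries its own
  Arrhenius parameters (E_A, ln D_0).  The published molecular-volume
  correlation behind the validated PET parameter set (a, b, c, d) is not
  transcribed here; the model therefore runs from an explicit correlation
  callable or from per-substance Arrhenius calibrations and refuses to
  predict otherwise (no silent fallback).

All temperatures are kelvin and all diffusion coefficients cm^2/s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "R_GAS",
    "PiringerParams",
    "WelleParams",
    "ArrheniusParams",
    "PIRINGER_REALISTIC",
    "PIRINGER_UPPER",
    "WELLE_PET",
    "CYCLIC_TRIMER_ARRHENIUS",
    "dp_piringer",
    "dp_arrhenius",
    "dp_welle",
    "fit_arrhenius",
    "effective_activation_energy",
    "CalibrationRequiredError",
    "DiffusionModel",
    "resolve_model",
    "MODEL_KEYS",
]

#: gas constant, J/(mol K)
R_GAS = 8.314

# warn (never zero out) when a predicted D_P drops below this floor, cm^2/s
_D_FLOOR = 1e-30
# clamp on the exponent to avoid floating overflow/underflow
_EXP_CLAMP = 700.0


class CalibrationRequiredError(RuntimeError):
    """The activation-energy model has no correlation and no per-substance
    calibration for the requested migrant."""


@dataclass(frozen=True)
class PiringerParams:
    """Polymer constants of the A_P model for PET.

    ``A_P(T) = ap_prime - tau/T``; the exponent further contains the generic
    molecular-weight terms and a fixed generic activation term, so the
    effective activation energy is R*(generic_activation + tau), about
    100 kJ/mol, for every migrant.
    """

    ap_prime: float  # dimensionless polymer constant A'_P
    tau: float = 1577.0  # K, temperature correction
    d0_ref: float = 1.0e4  # cm^2/s pre-factor
    mw_coeff_23: float = 0.1351  # per (g/mol)^(2/3)
    mw_coeff_lin: float = 0.003  # per (g/mol)
    generic_activation: float = 10454.0  # K

    def __post_init__(self) -> None:
        if self.tau < 0 or not math.isfinite(self.ap_prime):
            raise ValueError("require tau >= 0 and finite A'_P")


PIRINGER_REALISTIC = PiringerParams(ap_prime=3.1)
PIRINGER_UPPER = PiringerParams(ap_prime=6.4)


@dataclass(frozen=True)
class WelleParams:
    """Validated PET parameter set of the activation-energy model.

    The four constants parameterise the (unshipped) molecular-volume
    correlations E_A(M_V) and the compensation relation for ln D_0 anchored
    at ln(b); they are carried so that a user-supplied correlation can
    consume them.
    """

    a: float = 1.93e-3  # 1/K
    b: float = 2.37  # cm^2/s
    c: float = 11.1  # A^3
    d: float = 1.50e-5  # 1/K

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("require b > 0")


WELLE_PET = WelleParams()


@dataclass(frozen=True)
class ArrheniusParams:
    """Per-substance Arrhenius description D = exp(lnD0 - EA/(R T))."""

    ea: float  # activation energy, J/mol
    ln_d0: float  # ln of pre-exponential factor, ln(cm^2/s)

    def __post_init__(self) -> None:
        if self.ea < 0:
            raise ValueError("require EA >= 0")

    @property
    def ea_kj_mol(self) -> float:
        return self.ea / 1000.0


def _check_positive(**kwargs: float) -> None:
    for name, v in kwargs.items():
        if not (v > 0) or not math.isfinite(v):
            raise ValueError(f"require {name} > 0, got {v!r}")


def _safe_exp(arg: float) -> float:
    return math.exp(min(max(arg, -_EXP_CLAMP), _EXP_CLAMP))


def _warn_floor(d: float) -> float:
    if 0 < d < _D_FLOOR:
        warnings.warn(
            f"predicted D_P = {d:.3g} cm^2/s is below {_D_FLOOR:g}; "
            "migration is numerically negligible",
            stacklevel=3,
        )
    return d


def dp_piringer(
    mw: float, temperature: float, params: PiringerParams = PIRINGER_REALISTIC
) -> float:
    """A_P-model diffusion coefficient, cm^2/s.

    ``D_P = 1e4 * exp(A'_P - tau/T - 0.1351 Mw^(2/3) + 0.003 Mw - 10454/T)``

    Parameters
    ----------
    mw : float
        Migrant molecular weight, g/mol.
    temperature : float
        Kelvin.
    """
    _check_positive(mw=mw, temperature=temperature)
    arg = (
        params.ap_prime
        - params.tau / temperature
        - params.mw_coeff_23 * mw ** (2.0 / 3.0)
        + params.mw_coeff_lin * mw
        - params.generic_activation / temperature
    )
    return _warn_floor(params.d0_ref * _safe_exp(arg))


def dp_arrhenius(params: ArrheniusParams, temperature: float) -> float:
    """Evaluate an Arrhenius parameter set, cm^2/s."""
    _check_positive(temperature=temperature)
    return _warn_floor(_safe_exp(params.ln_d0 - params.ea / (R_GAS * temperature)))


def fit_arrhenius(points: Sequence[tuple[float, float]]) -> ArrheniusParams:
    """Least-squares Arrhenius fit of ln D against 1/T.

    Exact interpolation for two points; zero residual for collinear data.

    Parameters
    ----------
    points : sequence of (temperature K, D cm^2/s)
    """
    if len(points) < 2:
        raise ValueError("need at least two (T, D) points")
    temps = np.asarray([p[0] for p in points], dtype=float)
    ds = np.asarray([p[1] for p in points], dtype=float)
    if np.any(temps <= 0) or np.any(ds <= 0):
        raise ValueError("temperatures and diffusion coefficients must be > 0")
    if len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures make the fit ill-posed")
    slope, intercept = np.polyfit(1.0 / temps, np.log(ds), 1)
    return ArrheniusParams(ea=float(-slope * R_GAS), ln_d0=float(intercept))


# Calibration of the activation-energy model for the first-series cyclic
# trimer (M_V = 484.64 A^3), fitted through the model's published predicted
# diffusion coefficients at 176 C and 115 C.  The prediction at 149 C then
# falls on the same Arrhenius line.
CYCLIC_TRIMER_MV = 484.64
CYCLIC_TRIMER_ARRHENIUS = fit_arrhenius([(273.15 + 176.0, 1.4e-9), (273.15 + 115.0, 2.0e-13)])

#: packaged per-substance calibrations for the activation-energy model,
#: keyed by molecular volume (A^3)
WELLE_CALIBRATIONS: dict[float, ArrheniusParams] = {
    CYCLIC_TRIMER_MV: CYCLIC_TRIMER_ARRHENIUS,
}

WelleCorrelation = Callable[[float, WelleParams], ArrheniusParams]


def dp_welle(
    mv: float,
    temperature: float,
    params: WelleParams = WELLE_PET,
    correlation: Optional[WelleCorrelation] = None,
    override: Optional[ArrheniusParams] = None,
) -> float:
    """Activation-energy-model diffusion coefficient, cm^2/s.

    Resolution order: an explicit per-substance ``override`` wins; otherwise
    a ``correlation`` callable mapping molecular volume to Arrhenius
    parameters is used; otherwise a packaged calibration for this exact
    molecular volume; otherwise :class:`CalibrationRequiredError` is raised.

    Parameters
    ----------
    mv : float
        Migrant molecular volume, A^3.
    temperature : float
        Kelvin.
    """
    _check_positive(mv=mv, temperature=temperature)
    if override is not None:
        arr = override
    elif correlation is not None:
        arr = correlation(mv, params)
    elif mv in WELLE_CALIBRATIONS:
        arr = WELLE_CALIBRATIONS[mv]
    else:
        raise CalibrationRequiredError(
            f"no Arrhenius calibration for M_V = {mv} A^3: the molecular-"
            "volume correlation of the activation-energy model is not "
            "shipped; pass `correlation=` or `override=`"
        )
    return dp_arrhenius(arr, temperature)


def effective_activation_energy(
    model_fn: Callable[[float], float], window: tuple[float, float]
) -> float:
    """Effective activation energy over a temperature window, kJ/mol.

    ``-R * d(ln D)/d(1/T)`` evaluated as a finite difference between the two
    window edges; ``model_fn`` maps temperature (K) to D (cm^2/s).
    """
    t1, t2 = window
    if not (t2 > t1 > 0):
        raise ValueError("require 0 < T1 < T2")
    d1, d2 = model_fn(t1), model_fn(t2)
    if d1 <= 0 or d2 <= 0:
        raise ValueError("model returned non-positive D over the window")
    return -R_GAS * (math.log(d2) - math.log(d1)) / (1.0 / t2 - 1.0 / t1) / 1000.0


# ---------------------------------------------------------------------------
# model registry


@dataclass(frozen=True)
class DiffusionModel:
    """A named, resolvable D_P(T) predictor for oligomer records.

    ``uses`` records whether predictions key on molecular weight
    (``"mw"``, A_P family) or molecular volume (``"mv"``, activation-energy
    family).
    """

    key: str
    uses: str  # "mw" | "mv"
    _fn: Callable[[float, float], float]

    def diffusion_coefficient(self, record, temperature: float) -> float:
        """D_P for an :class:`~petmig.oligomers.OligomerRecord` at T (K)."""
        x = record.mw if self.uses == "mw" else record.mv
        return self._fn(x, temperature)

    def dp(self, x: float, temperature: float) -> float:
        """D_P from the raw size descriptor (g/mol or A^3)."""
        return self._fn(x, temperature)


def resolve_model(
    key: str,
    welle_calibrations: Optional[Mapping[float, ArrheniusParams]] = None,
    welle_correlation: Optional[WelleCorrelation] = None,
) -> DiffusionModel:
    """Resolve a registry key to a diffusion model.

    Keys: ``ap_realistic``, ``ap_upper``, ``ea_welle`` and
    ``arrhenius:<EA J/mol>,<lnD0>``.  For ``ea_welle``, per-substance
    calibrations (keyed by molecular volume) and/or a correlation callable
    may be supplied; the packaged trimer calibration is always available.
    """
    if key == "ap_realistic":
        return DiffusionModel(key, "mw", lambda mw, t: dp_piringer(mw, t, PIRINGER_REALISTIC))
    if key == "ap_upper":
        return DiffusionModel(key, "mw", lambda mw, t: dp_piringer(mw, t, PIRINGER_UPPER))
    if key == "ea_welle":
        table = dict(WELLE_CALIBRATIONS)
        if welle_calibrations:
            table.update(welle_calibrations)

        def _ea(mv: float, t: float) -> float:
            return dp_welle(
                mv, t,
                correlation=welle_correlation,
                override=table.get(mv),
            )

        return DiffusionModel(key, "mv", _ea)
    if key.startswith("arrhenius:"):
        try:
            ea_s, lnd0_s = key.split(":", 1)[1].split(",")
            arr = ArrheniusParams(ea=float(ea_s), ln_d0=float(lnd0_s))
        except (ValueError, IndexError) as exc:
            raise KeyError(
                f"bad arrhenius key {key!r}; expected 'arrhenius:<EA>,<lnD0>'"
            ) from exc
        return DiffusionModel(key, "mw", lambda _x, t: dp_arrhenius(arr, t))
    raise KeyError(f"unknown diffusion model key {key!r}")


MODEL_KEYS = ("ap_realistic", "ap_upper", "ea_welle")
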