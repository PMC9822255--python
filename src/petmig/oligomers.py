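"""PET oligomer compositions, acronym grammar, and the packaged oligomer table.

PET condensation oligomers are built from terephthalic acid (TPA) and
ethylene glycol (EG) residues, optionally with diethylene glycol (DEG)
replacing EG, in cyclic or linear arrangements.  The community acronym
grammar encodes topology and block structure, e.g. ``C[TPA+EG]3`` (cyclic
trimer), ``L[TPA+EG]2+TPA`` (linear dimer with a dangling TPA end group).

Molecular weights are recomputed from free-monomer masses minus one water
per ester bond; predicted molecular volumes cannot be derived from the
composition and ship as packaged data.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "OligomerComposition",
    "OligomerRecord",
    "parse_acronym",
    "format_acronym",
    "molecular_weight",
    "load_oligomers",
    "attach_cp0",
    "AcronymError",
]

# free-monomer masses, g/mol (3-decimal average atomic weights)
MASS_TPA = 166.131
MASS_EG = 62.068
MASS_DEG = 106.121
MASS_H2O = 18.015

#: tolerance for agreement between recomputed and tabulated M_W, g/mol
MW_TOLERANCE = 0.02


class AcronymError(ValueError):
    """Raised when an oligomer acronym does not follow the grammar."""


@dataclass(frozen=True)
class OligomerComposition:
    """Monomer-residue composition of one PET oligomer.

    Parameters
    ----------
    topology : {'cyclic', 'linear'}
    n_tpa, n_eg, n_deg : int
        Total counts of terephthalic-acid, ethylene-glycol and
        diethylene-glycol residues (end groups included).
    extra_endgroup : {'none', 'EG', 'TPA'}
        The dangling ``+EG`` / ``+TPA`` end group of linear variants.
    """

    topology: str
    n_tpa: int
    n_eg: int
    n_deg: int = 0
    extra_endgroup: str = "none"

    def __post_init__(self) -> None:
        if self.topology not in ("cyclic", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.extra_endgroup not in ("none", "EG", "TPA"):
            raise ValueError(f"unknown end group {self.extra_endgroup!r}")
        if min(self.n_tpa, self.n_eg, self.n_deg) < 0:
            raise ValueError("residue counts must be non-negative")
        if self.total_residues < 1:
            raise ValueError("empty composition")
        if self.topology == "cyclic":
            if self.extra_endgroup != "none":
                raise ValueError("cyclic oligomers carry no extra end group")
            if self.n_tpa != self.n_eg + self.n_deg:
                raise ValueError(
                    "cyclic ring must alternate diacid/diol: "
                    f"n_TPA={self.n_tpa} != n_EG+n_DEG={self.n_eg + self.n_deg}"
                )

    @property
    def total_residues(self) -> int:
        return self.n_tpa + self.n_eg + self.n_deg

    @property
    def n_ester_bonds(self) -> int:
        """Ester bonds: one per residue on a ring, one fewer on a chain."""
        n = self.total_residues
        return n if self.topology == "cyclic" else n - 1

    @property
    def acronym(self) -> str:
        return format_acronym(self)


_ACRONYM_RE = re.compile(
    r"^(?P<topo>[A-Z])"
    r"(?P<blocks>(?:\[TPA\+(?:EG|DEG)\]\d*)(?:\+\[TPA\+(?:EG|DEG)\]\d*)*)"
    r"(?P<end>\+EG|\+TPA)?$"
)
_BLOCK_RE = re.compile(r"\[TPA\+(?P<diol>EG|DEG)\](?P<count>\d*)")


def parse_acronym(acronym: str) -> OligomerComposition:
    """Parse a community acronym such as ``C[TPA+EG]2+[TPA+DEG]`` into counts.

    Grammar: ``("C"|"L") "[" block "]" [count] { "+" "[" block "]" [count] }
    [ "+EG" | "+TPA" ]`` with blocks ``TPA+EG`` or ``TPA+DEG``.  Repeat counts
    multiply the block; block contributions are aggregated.

    Raises
    ------
    AcronymError
        If the string violates the grammar; the message names the
        offending token.
    """
    if not isinstance(acronym, str) or not acronym:
        raise AcronymError("empty acronym")
    m = _ACRONYM_RE.match(acronym)
    if m is None:
        # localise the failure for a useful message
        if not acronym[0] in "CL":
            raise AcronymError(
                f"unknown topology code {acronym[0]!r} in {acronym!r} "
                "(expected 'C' or 'L')"
            )
        raise AcronymError(f"malformed acronym {acronym!r}")
    if m.group("topo") not in ("C", "L"):
        raise AcronymError(
            f"unknown topology code {m.group('topo')!r} in {acronym!r} "
            "(expected 'C' or 'L')"
        )
    topo = "cyclic" if m.group("topo") == "C" else "linear"
    n_tpa = n_eg = n_deg = 0
    consumed = 0
    for bm in _BLOCK_RE.finditer(m.group("blocks")):
        k = int(bm.group("count") or 1)
        if k < 1:
            raise AcronymError(f"zero repeat count in {acronym!r}")
        n_tpa += k
        if bm.group("diol") == "EG":
            n_eg += k
        else:
            n_deg += k
        consumed += 1
    if consumed == 0:  # pragma: no cover - excluded by the outer regex
        raise AcronymError(f"no [TPA+diol] block in {acronym!r}")
    end = m.group("end") or "none"
    end = end.lstrip("+")
    if end == "EG":
        n_eg += 1
    elif end == "TPA":
        n_tpa += 1
    try:
        return OligomerComposition(topo, n_tpa, n_eg, n_deg, end or "none")
    except ValueError as exc:
        raise AcronymError(f"{acronym!r}: {exc}") from exc


def format_acronym(c: OligomerComposition) -> str:
    """Canonical acronym: ``[TPA+EG]`` block first, ``[TPA+DEG]`` second,
    end-group suffix last."""
    eg_pairs = c.n_eg - (1 if c.extra_endgroup == "EG" else 0)
    deg_pairs = c.n_deg
    expected_tpa = eg_pairs + deg_pairs + (1 if c.extra_endgroup == "TPA" else 0)
    if eg_pairs < 0 or c.n_tpa != expected_tpa:
        raise ValueError(
            f"composition {c} has no canonical block representation"
        )
    parts = [("C" if c.topology == "cyclic" else "L")]
    blocks = []
    if eg_pairs:
        blocks.append("[TPA+EG]" + (str(eg_pairs) if eg_pairs > 1 else ""))
    if deg_pairs:
        blocks.append("[TPA+DEG]" + (str(deg_pairs) if deg_pairs > 1 else ""))
    if not blocks:
        raise ValueError(f"composition {c} has no [TPA+diol] block")
    parts.append("+".join(blocks))
    if c.extra_endgroup != "none":
        parts.append("+" + c.extra_endgroup)
    return "".join(parts)


def molecular_weight(c: OligomerComposition) -> float:
    """Condensation molecular weight, g/mol.

    Sum of free-monomer masses minus one water per ester bond.
    """
    return (
        c.n_tpa * MASS_TPA
        + c.n_eg * MASS_EG
        + c.n_deg * MASS_DEG
        - c.n_ester_bonds * MASS_H2O
    )


@dataclass(frozen=True)
class OligomerRecord:
    """One packaged oligomer: composition, tabulated properties, and the
    optional in-polymer concentration range C_P,0 (mg/kg polymer)."""

    composition: OligomerComposition
    common_name: str
    mw: float  # g/mol
    mv: float  # A^3, predicted molecular volume (external predictor; data)
    hypothetical: bool = False
    cp0_min: Optional[float] = None  # mg/kg polymer
    cp0_max: Optional[float] = None  # mg/kg polymer

    def __post_init__(self) -> None:
        if self.mw <= 0 or self.mv <= 0:
            raise ValueError("M_W and M_V must be positive")
        if (self.cp0_min is None) != (self.cp0_max is None):
            raise ValueError("cp0_min and cp0_max must be set together")
        if self.cp0_min is not None:
            if self.cp0_min < 0 or self.cp0_min > self.cp0_max:
                raise ValueError("require 0 <= cp0_min <= cp0_max")
        recomputed = molecular_weight(self.composition)
        if abs(recomputed - self.mw) > MW_TOLERANCE:
            raise ValueError(
                f"{self.acronym}: tabulated M_W {self.mw} differs from "
                f"recomputed {recomputed:.3f} by more than {MW_TOLERANCE} g/mol"
            )

    @property
    def acronym(self) -> str:
        return self.composition.acronym

    @property
    def topology(self) -> str:
        return self.composition.topology

    @property
    def has_cp0(self) -> bool:
        return self.cp0_min is not None


def _data_text(name: str) -> str:
    return (resources.files("petmig.data") / name).read_text(encoding="utf-8")


def load_oligomers() -> list[OligomerRecord]:
    """Load the 52 packaged PET oligomers (20 cyclic, 32 linear), in table
    order, without C_P,0 values (supply those via :func:`attach_cp0`)."""
    rows = [
        r
        for r in csv.DictReader(
            ln for ln in _data_text("pet_oligomers.csv").splitlines()
            if not ln.startswith("#")
        )
    ]
    records = []
    for r in rows:
        comp = OligomerComposition(
            topology=r["topology"],
            n_tpa=int(r["n_TPA"]),
            n_eg=int(r["n_EG"]),
            n_deg=int(r["n_DEG"]),
            extra_endgroup=r["extra_endgroup"],
        )
        if comp.acronym != r["acronym"]:
            raise ValueError(
                f"packaged acronym {r['acronym']!r} does not round-trip "
                f"({comp.acronym!r})"
            )
        records.append(
            OligomerRecord(
                composition=comp,
                common_name=r["common_name"],
                mw=float(r["Mw_g_mol"]),
                mv=float(r["Mv_A3"]),
                hypothetical=r["hypothetical"].strip().lower() == "true",
            )
        )
    return records


def attach_cp0(
    records: Sequence[OligomerRecord],
    cp0_table: Mapping[str, tuple[float, float] | float],
) -> list[OligomerRecord]:
    """Merge a C_P,0 table (keyed by acronym, mg/kg polymer) into records.

    A scalar value is duplicated into ``cp0_min == cp0_max``.  Records absent
    from the table keep empty C_P,0.  Unknown acronyms in the table raise.
    """
    known = {r.acronym for r in records}
    unknown = sorted(set(cp0_table) - known)
    if unknown:
        raise KeyError(f"C_P,0 table lists unknown acronyms: {unknown}")
    merged = []
    for r in records:
        if r.acronym in cp0_table:
            v = cp0_table[r.acronym]
            lo, hi = (v, v) if isinstance(v, (int, float)) else (v[0], v[1])
            merged.append(replace(r, cp0_min=float(lo), cp0_max=float(hi)))
        else:
            merged.append(r)
    return merged


def records_by_acronym(records: Iterable[OligomerRecord]) -> dict[str, OligomerRecord]:
    return {r.acronym: r for r in records}
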