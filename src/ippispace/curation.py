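"""Inclusion/exclusion rules, activity binning and drug-likeness flags.

The inhibitor collections are filtered to unambiguous, potent, small-
molecule PPI inhibitors: an activity of type Kd/Ki/IC50/EC50 below 30 uM,
molecular weight below 1,200 g/mol, at least 10 heavy atoms, organic
elements only (C, N, O, S, P, halogens), no peptides (more than 3
contiguous peptide bonds), and no macrocycles, salts, metal complexes or
carbocations.  Every excluded record carries the full list of rules it
violated; evaluation is exhaustive, never short-circuited.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

ACTIVITY_TYPES = frozenset({"Kd", "Ki", "IC50", "EC50"})
ALLOWED_ELEMENTS = frozenset({"C", "N", "O", "S", "P", "F", "Cl", "Br", "I"})

ACTIVITY_CUTOFF_UM = 30.0
MW_CUTOFF = 1200.0
MIN_HEAVY_ATOMS = 10
MAX_CONTIGUOUS_PEPTIDE_BONDS = 3


@dataclass
class CompoundAnnotation:
    """Minimal per-compound annotation consumed by :func:`curate`."""

    id: str
    activity_type: str | None = None
    activity_uM: float | None = None
    pXC50: float | None = None
    MW: float | None = None
    heavy_atoms: int | None = None
    elements: frozenset[str] | None = None
    contiguous_peptide_bonds: int | None = None
    is_macrocycle: bool = False
    is_salt: bool = False
    is_metal: bool = False
    is_carbocation: bool = False

    def __post_init__(self) -> None:
        if self.elements is not None:
            self.elements = frozenset(self.elements)
        if self.activity_uM is not None and self.activity_uM <= 0:
            raise ValueError(f"{self.id}: activity_uM must be positive")
        if self.activity_uM is not None and self.pXC50 is not None:
            expected = 6.0 - math.log10(self.activity_uM)
            if abs(self.pXC50 - expected) > 1e-6:
                raise ValueError(
                    f"{self.id}: pXC50 {self.pXC50} inconsistent with "
                    f"activity {self.activity_uM} uM (expected {expected:.6f})"
                )


@dataclass
class CurationReport:
    kept: list[str] = field(default_factory=list)
    excluded: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.excluded)

    def to_lines(self) -> list[str]:
        """One record per line: id, kept flag, semicolon-joined reasons."""
        lines = [f"{i}\tkept\t" for i in self.kept]
        lines += [f"{i}\texcluded\t{';'.join(r)}" for i, r in self.excluded.items()]
        return lines

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tstatus\treasons\n")
            fh.write("\n".join(self.to_lines()) + "\n")


_MANDATORY = (
    "activity_type",
    "activity_uM",
    "MW",
    "heavy_atoms",
    "elements",
    "contiguous_peptide_bonds",
)


def _exclusion_reasons(rec: CompoundAnnotation) -> list[str]:
    reasons = []
    if any(getattr(rec, f) is None for f in _MANDATORY):
        reasons.append("incomplete")
    if rec.activity_type is not None and rec.activity_type not in ACTIVITY_TYPES:
        reasons.append("activity_type")
    # strict inequality: an activity of exactly 30 uM is excluded
    if rec.activity_uM is not None and not rec.activity_uM < ACTIVITY_CUTOFF_UM:
        reasons.append("activity")
    if rec.MW is not None and not rec.MW < MW_CUTOFF:
        reasons.append("MW")
    if rec.heavy_atoms is not None and rec.heavy_atoms < MIN_HEAVY_ATOMS:
        reasons.append("size")
    if rec.elements is not None and not rec.elements <= ALLOWED_ELEMENTS:
        reasons.append("elements")
    if (
        rec.contiguous_peptide_bonds is not None
        and rec.contiguous_peptide_bonds > MAX_CONTIGUOUS_PEPTIDE_BONDS
    ):
        reasons.append("peptide")
    if rec.is_macrocycle:
        reasons.append("macrocycle")
    if rec.is_salt:
        reasons.append("salt")
    if rec.is_metal:
        reasons.append("metal")
    if rec.is_carbocation:
        reasons.append("carbocation")
    return reasons


def curate(records: Iterable[CompoundAnnotation]) -> CurationReport:
    """Apply all inclusion rules; duplicates by id collapse to one record."""
    report = CurationReport()
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            continue
        seen.add(rec.id)
        reasons = _exclusion_reasons(rec)
        if reasons:
            report.excluded[rec.id] = reasons
        else:
            report.kept.append(rec.id)
    return report


def bin_activity(pXC50: float) -> str:
    """Two potency bins: "low" below pXC50 7, "high" at or above.

    The boundary value 7.0 itself is assigned to "high" by convention.
    """
    if not math.isfinite(pXC50):
        raise ValueError("pXC50 must be finite")
    return "low" if pXC50 < 7.0 else "high"


# ---------------------------------------------------------------------------
# drug-likeness / bioavailability threshold rules
#
# The thresholds are those of the cited original rules:
#   Lipinski RO5: MW<=500, logP<=5, HBD<=5, HBA<=10 (fail on >1 violation)
#   Veber:        rotatable bonds<=10, TPSA<=140
#   Egan:         logP<=5.88, TPSA<=131.6
#   GSK 4/400:    MW<=400, logP<=4

def rule_flags(descriptors: Mapping[str, float]) -> dict[str, str]:
    """Evaluate the four threshold rules; missing input -> "undetermined"."""

    def get(*names: str) -> float | None:
        for n in names:
            v = descriptors.get(n)
            if v is not None:
                return float(v)
        return None

    mw = get("MW")
    logp = get("logP", "AlogP")
    hbd = get("HBD")
    hba = get("HBA")
    rot = get("rotatable_bonds")
    tpsa = get("TPSA")

    flags: dict[str, str] = {}

    if None in (mw, logp, hbd, hba):
        flags["lipinski_ro5"] = "undetermined"
    else:
        violations = sum([mw > 500, logp > 5, hbd > 5, hba > 10])
        flags["lipinski_ro5"] = "pass" if violations <= 1 else "fail"

    if None in (rot, tpsa):
        flags["veber"] = "undetermined"
    else:
        flags["veber"] = "pass" if rot <= 10 and tpsa <= 140 else "fail"

    if None in (logp, tpsa):
        flags["egan"] = "undetermined"
    else:
        flags["egan"] = "pass" if logp <= 5.88 and tpsa <= 131.6 else "fail"

    if None in (mw, logp):
        flags["gsk_4_400"] = "undetermined"
    else:
        flags["gsk_4_400"] = "pass" if mw <= 400 and logp <= 4 else "fail"

    return flags
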