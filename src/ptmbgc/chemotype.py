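"""Genotype-to-chemotype prediction for PTMs.

Polycyclic tetramic acid macrolactams (PTMs) carry a carbocycle whose ring
system (5, 5-5, 5-6-5 or 5-5-6) is determined by the dehydrogenase/
oxidoreductase content of the biosynthetic gene cluster, with the sterol
desaturase and cytochrome P450 acting as tailoring enzymes (C-4
hydroxylation and epoxidation respectively). This module turns an enzyme
family set into a ring-system prediction, and supports the mass-spectrometry
side: Hill-notation molecular formulas, nominal/monoisotopic masses,
deprotonated [M-H]- ions, formula-level modifications, and matching of
candidate ions against an observed negative-mode ion list.

The bundled compound records are the four PTM co-metabolites of the
cone-snail isolates: dihydromaltophilin (1, C29H40N2O6, [M-H]- 511), its
desaturated analog (2, -H2, 509), xanthobaccin C (3, -H2O, 493) and FI-3
(4, -H2O -H2, 491).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .families import EnzymeFamily


class RingSystem(Enum):
    """PTM carbocycle categories, labeled as the field writes them."""

    R5 = "5"
    R5_5 = "5-5"
    R5_6_5 = "5-6-5"
    R5_5_6 = "5-5-6"
    UNDETERMINED = "undetermined"


#: Informal compound-class names attached to the determinate ring systems.
RING_CLASS_NAMES = {
    RingSystem.R5: "pactamide E type",
    RingSystem.R5_5: "alteramides",
    RingSystem.R5_6_5: "ikarugamycins",
    RingSystem.R5_5_6: "maltophilins",
}


@dataclass(frozen=True)
class RingPrediction:
    primary: RingSystem
    secondary: Optional[RingSystem] = None
    c4_hydroxylation: bool = False
    epoxidation: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.secondary is not None and (
            self.secondary is not RingSystem.R5_5 or self.primary is not RingSystem.R5_5_6
        ):
            raise ValueError(
                "secondary ring may only be 5-5, and only for a 5-5-6 primary"
            )


def _as_family_set(families: Iterable) -> Set[EnzymeFamily]:
    out: Set[EnzymeFamily] = set()
    for f in families:
        if isinstance(f, EnzymeFamily):
            out.add(f)
        else:
            try:
                out.add(EnzymeFamily[str(f)])
            except KeyError as exc:
                raise ValueError(f"unknown enzyme family label: {f!r}") from exc
    return out


def predict_ring_system(families: Iterable) -> RingPrediction:
    """Ring-system call from the enzyme content of one BGC.

    Rules, applied in order: DH1 is essential for any carbocycle, so without
    it the call is undetermined; DH1+DH2+OxR assembles the maltophilins
    5-5-6 system (such producers can additionally make a 5-5 compound, hence
    the secondary ring); DH1+DH2 without OxR gives the alteramides 5-5;
    DH1+OxR without DH2 gives the ikarugamycins 5-6-5; DH1 alone gives the
    single 5-ring. DH3 never alters the outcome; its presence is noted.
    """
    fams = _as_family_set(families)
    tailoring = predict_tailoring(fams)
    notes = []
    if EnzymeFamily.DH3 in fams:
        notes.append("DH3 present (no known effect on ring system)")
    has = lambda f: f in fams  # noqa: E731
    if not has(EnzymeFamily.DH1):
        primary, secondary = RingSystem.UNDETERMINED, None
        notes.append("DH1 absent: no carbocycle rule applies")
    elif has(EnzymeFamily.DH2) and has(EnzymeFamily.OXR):
        primary, secondary = RingSystem.R5_5_6, RingSystem.R5_5
    elif has(EnzymeFamily.DH2):
        primary, secondary = RingSystem.R5_5, None
    elif has(EnzymeFamily.OXR):
        primary, secondary = RingSystem.R5_6_5, None
    else:
        primary, secondary = RingSystem.R5, None
    return RingPrediction(
        primary=primary,
        secondary=secondary,
        c4_hydroxylation=tailoring["c4_hydroxylation"],
        epoxidation=tailoring["epoxidation"],
        notes="; ".join(notes),
    )


def predict_tailoring(families: Iterable) -> Dict[str, bool]:
    """Tailoring flags: sterol desaturase -> C-4 hydroxylation; CYP450 ->
    epoxide ring formation."""
    fams = _as_family_set(families)
    return {
        "c4_hydroxylation": EnzymeFamily.SD in fams,
        "epoxidation": EnzymeFamily.CYP450 in fams,
    }


# --- molecular formulas ----------------------------------------------------

NOMINAL_MASS = {"C": 12, "H": 1, "N": 14, "O": 16, "S": 32, "P": 31}
MONOISOTOPIC_MASS = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}
#: mass removed on deprotonation in monoisotopic mode (proton mass)
PROTON_MASS = 1.00728

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula:
    """An elemental composition. Immutable; arithmetic returns new objects."""

    counts: Tuple[Tuple[str, int], ...]

    def __post_init__(self) -> None:
        for elem, n in self.counts:
            if elem not in NOMINAL_MASS:
                raise ValueError(f"unsupported element: {elem}")
            if n < 0:
                raise ValueError(f"negative count for {elem}")

    @classmethod
    def from_dict(cls, d: Dict[str, int]) -> "Formula":
        return cls(tuple(sorted((e, n) for e, n in d.items() if n > 0)))

    def as_dict(self) -> Dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, elem: str) -> int:
        return dict(self.counts).get(elem, 0)

    def __add__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for e, n in other.counts:
            d[e] = d.get(e, 0) + n
        return Formula.from_dict(d)

    def __sub__(self, other: "Formula") -> "Formula":
        d = self.as_dict()
        for e, n in other.counts:
            d[e] = d.get(e, 0) - n
            if d[e] < 0:
                raise ValueError(
                    f"subtraction would make {e} count negative ({d[e]})"
                )
        return Formula.from_dict(d)

    def hill(self) -> str:
        """Hill notation: C first, H second, then alphabetical."""
        d = self.as_dict()
        parts = []
        for e in ["C", "H"] + sorted(k for k in d if k not in ("C", "H")):
            n = d.get(e, 0)
            if n == 0:
                continue
            parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str) -> Formula:
    """Parse a Hill-notation formula string like ``C29H40N2O6``."""
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    pos = 0
    counts: Dict[str, int] = {}
    while pos < len(text):
        match = _FORMULA_TOKEN.match(text, pos)
        if not match or not match.group(1):
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        elem, num = match.group(1), match.group(2)
        if elem not in NOMINAL_MASS:
            raise ValueError(f"unknown element symbol {elem!r} in {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = match.end()
    return Formula.from_dict(counts)


def mass(formula: Formula, mode: str = "nominal") -> float:
    """Neutral mass: ``nominal`` uses integer masses, ``monoisotopic`` exact
    isotope masses."""
    if mode == "nominal":
        table = NOMINAL_MASS
    elif mode == "monoisotopic":
        table = MONOISOTOPIC_MASS
    else:
        raise ValueError(f"unknown mass mode: {mode!r}")
    return float(sum(table[e] * n for e, n in formula.counts))


def deprotonated_mz(formula: Formula, mode: str = "nominal") -> float:
    """m/z of the [M-H]- ion.

    Nominal mode subtracts 1; monoisotopic mode subtracts the proton mass
    (1.00728).
    """
    if formula["H"] < 1:
        raise ValueError("cannot deprotonate a formula without hydrogen")
    if mode == "nominal":
        return mass(formula, "nominal") - 1.0
    return mass(formula, "monoisotopic") - PROTON_MASS


_MODIFICATIONS = {
    "desaturation": ("-", parse_formula("H2")),
    "hydroxylation": ("+", parse_formula("O")),
    "dehydration": ("-", parse_formula("H2O")),
}


def apply_modification(formula: Formula, mod: str) -> Formula:
    """Apply a formula-level biosynthetic modification.

    desaturation: -H2; hydroxylation: +O; dehydration: -H2O.
    """
    if mod not in _MODIFICATIONS:
        raise ValueError(f"unknown modification: {mod!r}")
    sign, delta = _MODIFICATIONS[mod]
    return formula + delta if sign == "+" else formula - delta


# --- compound records and ion matching -------------------------------------


@dataclass(frozen=True)
class CompoundRecord:
    label: str
    name: str
    formula: Formula
    expected_mz: float  # nominal [M-H]-


def bundled_compounds() -> List[CompoundRecord]:
    """The four PTM co-metabolites with their nominal [M-H]- ions.

    Compounds 2-4 are derived from dihydromaltophilin at the formula level:
    2 by desaturation, 3 by dehydration, 4 by dehydration plus desaturation.
    """
    c1 = parse_formula("C29H40N2O6")
    c2 = apply_modification(c1, "desaturation")
    c3 = apply_modification(c1, "dehydration")
    c4 = apply_modification(c3, "desaturation")
    return [
        CompoundRecord("1", "dihydromaltophilin", c1, deprotonated_mz(c1)),
        CompoundRecord("2", "dehydro-dihydromaltophilin", c2, deprotonated_mz(c2)),
        CompoundRecord("3", "xanthobaccin C", c3, deprotonated_mz(c3)),
        CompoundRecord("4", "FI-3", c4, deprotonated_mz(c4)),
    ]


@dataclass(frozen=True)
class IonMatch:
    observed_mz: float
    compound_label: str
    delta_mz: float


@dataclass
class IonMatchReport:
    matches: List[IonMatch] = field(default_factory=list)
    unmatched: List[float] = field(default_factory=list)


def match_ion_list(
    candidates: Sequence[CompoundRecord],
    observed: Sequence[float],
    tolerance: float = 0.5,
) -> IonMatchReport:
    """Match observed [M-H]- ions against candidate compounds.

    Each observed ion is matched to every candidate within +/- tolerance;
    ions matching no candidate are reported as unmatched.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    report = IonMatchReport()
    for mz in observed:
        found = False
        for cand in candidates:
            delta = mz - cand.expected_mz
            if abs(delta) <= tolerance:
                report.matches.append(IonMatch(mz, cand.label, delta))
                found = True
        if not found:
            report.unmatched.append(mz)
    return report


def read_ion_table(path) -> List[float]:
    """Read an observed-ion list: two-column TSV (m/z, optional intensity)."""
    ions: List[float] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                ions.append(float(fields[0]))
            except ValueError:
                if line_no == 1:
                    continue  # header row
                raise ValueError(f"bad m/z value on line {line_no}: {fields[0]!r}")
    return ions


def write_match_report(report: IonMatchReport, path) -> int:
    """Write matches as TSV (observed m/z, candidate label, delta m/z)."""
    n = 0
    with open(path, "w") as fh:
        fh.write("observed_mz\tcandidate\tdelta_mz\n")
        for m in report.matches:
            fh.write(f"{m.observed_mz:.4f}\t{m.compound_label}\t{m.delta_mz:+.4f}\n")
            n += 1
        for mz in report.unmatched:
            fh.write(f"{mz:.4f}\tunmatched\t\n")
    return n
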