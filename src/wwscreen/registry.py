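"""Suspect-list data model and exact-mass arithmetic.

A suspect list pairs highly consumed parent pharmaceuticals with their known
human metabolites.  Each entry carries a molecular formula (from which the
monoisotopic mass is derived), the metabolism phase, a link to the parent
compound, logD values at the chromatographic pH of each ionization mode, and
the molar fraction of an administered dose excreted as that compound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

from .constants import ADDUCT_DELTAS, MONOISOTOPIC_MASS, TRANSFORMATIONS

PHASES = ("parent", "I", "II", "I_then_II")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparsable formulas or unsupported elements."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula like ``C15H15NO2`` into element counts.

    Only elements with a tabulated monoisotopic mass are supported.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    s = formula.strip()
    while pos < len(s):
        m = _FORMULA_TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        element, digits = m.group(1), m.group(2)
        if element not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {element!r} in formula {formula!r}")
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return {el: n for el, n in counts.items() if n != 0}


def formula_to_string(counts: dict[str, int]) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    parts = []
    rest = sorted(el for el in counts if el not in ("C", "H"))
    order = [el for el in ("C", "H") if el in counts] + rest
    for el in order:
        n = counts[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def monoisotopic_mass(formula: str | dict[str, int]) -> float:
    """Monoisotopic (most abundant isotope) mass of a molecular formula, Da."""
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    if not counts:
        raise FormulaError("empty molecular formula")
    for el in counts:
        if el not in MONOISOTOPIC_MASS:
            raise FormulaError(f"unsupported element {el!r}")
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in counts.items())


@dataclass(frozen=True)
class AdductSpec:
    """An ESI adduct: label, mass delta relative to the neutral (Da), charge."""

    label: str
    mass_delta: float
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")


def default_adducts(polarity: str = "positive") -> list[AdductSpec]:
    """Adduct specifications shipped for the given ionization mode."""
    specs = [AdductSpec(lbl, d, z) for lbl, (d, z) in ADDUCT_DELTAS.items()]
    if polarity == "positive":
        return [a for a in specs if a.charge > 0]
    if polarity == "negative":
        return [a for a in specs if a.charge < 0]
    raise ValueError(f"unknown polarity {polarity!r}")


def adduct_mz(neutral_mass: float, adduct: AdductSpec) -> float:
    """m/z of the ion formed from a neutral of the given mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return (neutral_mass + adduct.mass_delta) / abs(adduct.charge)


@dataclass
class SuspectEntry:
    """One compound on the suspect list.

    ``excretion_fraction`` is the molar fraction of an administered dose
    excreted as this compound; ``None`` means unknown (propagated as missing,
    downstream modules decide handling).
    """

    name: str
    formula: str
    parent_name: str | None = None
    phase: str = "parent"
    biotransformation: str | None = None
    logD_pos: float | None = None  # logD at pH 2.7 (positive-mode LC)
    logD_neg: float | None = None  # logD at pH 4.8 (negative-mode LC)
    excretion_fraction: float | None = None
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if (self.phase == "parent") != (self.parent_name is None):
            raise ValueError(
                f"{self.name}: phase 'parent' if and only if parent_name is empty"
            )
        if self.excretion_fraction is not None and not (
            0.0 <= self.excretion_fraction <= 1.0
        ):
            raise ValueError(
                f"{self.name}: excretion_fraction must be in [0, 1]"
            )
        # validates the formula eagerly
        self.monoisotopic_mass

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.formula)

    def logD(self, polarity: str) -> float | None:
        return self.logD_pos if polarity == "positive" else self.logD_neg


def apply_biotransformation(parent: SuspectEntry, transformation: str) -> SuspectEntry:
    """Derive a metabolite entry from a parent by a named reaction class.

    The child's formula is the parent formula plus the reaction's element
    delta; its phase follows the reaction class (conjugation of a phase-I
    metabolite yields ``I_then_II``).
    """
    if transformation not in TRANSFORMATIONS:
        raise ValueError(
            f"unsupported biotransformation {transformation!r}; "
            f"known: {sorted(TRANSFORMATIONS)}"
        )
    delta, reaction_phase = TRANSFORMATIONS[transformation]
    counts = parse_formula(parent.formula)
    for el, dn in delta.items():
        counts[el] = counts.get(el, 0) + dn
        if counts[el] < 0:
            raise ValueError(
                f"{transformation} not applicable to {parent.formula}: "
                f"element {el} count would become negative"
            )
    counts = {el: n for el, n in counts.items() if n > 0}
    if reaction_phase == "II" and parent.phase in ("I", "I_then_II"):
        child_phase = "I_then_II"
    elif parent.phase == "II" and reaction_phase == "I":
        child_phase = "I_then_II"
    else:
        child_phase = reaction_phase
    root = parent.parent_name if parent.parent_name is not None else parent.name
    return replace(
        parent,
        name=f"{parent.name}+{transformation}",
        formula=formula_to_string(counts),
        parent_name=root,
        phase=child_phase,
        biotransformation=transformation,
        excretion_fraction=None,
        annotations={},
    )


def transformation_mass_delta(transformation: str) -> float:
    """Exact mass change (Da) of a named biotransformation."""
    delta, _ = TRANSFORMATIONS[transformation]
    return sum(MONOISOTOPIC_MASS[el] * n for el, n in delta.items())


def summarize_list(entries: list[SuspectEntry]) -> dict:
    """Composition of a suspect list by metabolism phase.

    Returns counts and percentages per phase; percentages sum to 100 up to
    rounding (empty input gives all-zero counts and no percentages).
    """
    counts = {phase: 0 for phase in PHASES}
    for entry in entries:
        counts[entry.phase] += 1
    total = len(entries)
    percentages = (
        {phase: 100.0 * n / total for phase, n in counts.items()} if total else {}
    )
    return {"total": total, "counts": counts, "percentages": percentages}
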