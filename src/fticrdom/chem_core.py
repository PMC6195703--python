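"""Pure chemistry kernel: element masses, molecular formulas, validity rules,
aromaticity index, and the chemical building-block table.

Everything downstream (formula enumeration, isotope verification,
building-block propagation, compound classification) consumes this module.
Masses are monoisotopic and carried at >= 9 decimal places; the element table
is shipped as a plain-text data file so it can be audited with a diff.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterator

__all__ = [
    "ElementTable",
    "MolecularFormula",
    "BuildingBlock",
    "ELEMENTS",
    "BUILDING_BLOCKS",
    "EmptyFormulaError",
    "monoisotopic_mass",
    "validate_formula",
    "aromaticity_index",
    "apply_block",
]

_ELEMENT_ORDER = ("c", "h", "o", "n", "p", "s")


class EmptyFormulaError(ValueError):
    """Raised when a mass is requested for a formula with no atoms."""


@dataclass(frozen=True)
class ElementTable:
    """Monoisotopic element masses, isotope mass shifts, and the natural
    13C/12C abundance ratio.

    ``elements`` maps the element symbol (C, H, O, N, P, S) to its
    monoisotopic mass in Da; ``isotope_shifts`` maps an isotope label
    (e.g. ``"13C"``) to the mass shift relative to the principal isotope;
    ``electron`` is the electron mass used for ion/neutral conversion.
    """

    elements: dict[str, float]
    isotope_shifts: dict[str, float]
    electron: float
    c13_abundance: float = 0.0107

    def __post_init__(self) -> None:
        for sym, m in self.elements.items():
            if m <= 0:
                raise ValueError(f"non-positive mass for element {sym}")
        d13c = self.isotope_shifts.get("13C")
        if d13c is not None and not (1.0033 < d13c < 1.0034):
            raise ValueError("13C-12C shift outside (1.0033, 1.0034) Da")
        if not 0.0 < self.c13_abundance < 1.0:
            raise ValueError("13C abundance ratio must lie in (0, 1)")

    @classmethod
    def load(cls) -> "ElementTable":
        """Read the shipped plain-text element/isotope table."""
        elements: dict[str, float] = {}
        shifts: dict[str, float] = {}
        constants: dict[str, float] = {}
        text = (
            resources.files("fticrdom").joinpath("data/elements.tsv").read_text()
        )
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            kind, symbol, value = line.split("\t")
            if kind == "element":
                elements[symbol] = float(value)
            elif kind == "isotope_shift":
                shifts[symbol] = float(value)
            elif kind == "constant":
                constants[symbol] = float(value)
        return cls(
            elements=elements,
            isotope_shifts=shifts,
            electron=constants["electron"],
            c13_abundance=constants["c13_abundance"],
        )


ELEMENTS = ElementTable.load()


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Integer element counts for C, H, O, N, P, S.

    Ordering is lexicographic on ``(c, h, o, n, p, s)``, which gives every
    downstream tie-break a deterministic last resort.
    """

    c: int = 0
    h: int = 0
    o: int = 0
    n: int = 0
    p: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for name in _ELEMENT_ORDER:
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"count {name}={v!r} must be a non-negative int")

    def counts(self) -> tuple[int, int, int, int, int, int]:
        return (self.c, self.h, self.o, self.n, self.p, self.s)

    def __iter__(self) -> Iterator[int]:
        return iter(self.counts())

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(*(a + b for a, b in zip(self, other)))

    def __str__(self) -> str:
        out = []
        for name in _ELEMENT_ORDER:
            v = getattr(self, name)
            if v == 1:
                out.append(name.upper())
            elif v > 1:
                out.append(f"{name.upper()}{v}")
        return "".join(out) if out else "(empty)"

    @classmethod
    def from_string(cls, text: str) -> "MolecularFormula":
        """Parse the canonical text form, e.g. ``"C6H12O6"``."""
        import re

        counts = dict.fromkeys(_ELEMENT_ORDER, 0)
        pos = 0
        for m in re.finditer(r"([CHONPS])(\d*)", text):
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {text!r}")
            pos = m.end()
            counts[m.group(1).lower()] += int(m.group(2) or 1)
        if pos != len(text):
            raise ValueError(f"cannot parse formula {text!r}")
        return cls(**counts)


def monoisotopic_mass(formula: MolecularFormula, table: ElementTable = ELEMENTS) -> float:
    """Sum of monoisotopic element masses, in Da. Additive over formulas."""
    if sum(formula.counts()) == 0:
        raise EmptyFormulaError("formula has no atoms")
    e = table.elements
    return (
        formula.c * e["C"]
        + formula.h * e["H"]
        + formula.o * e["O"]
        + formula.n * e["N"]
        + formula.p * e["P"]
        + formula.s * e["S"]
    )


def validate_formula(formula: MolecularFormula) -> tuple[bool, list[str]]:
    """Apply the twelve elemental exclusion rules.

    Returns ``(ok, violations)`` where ``violations`` names every rule the
    formula breaks.  The rules encode valence and heteroatom plausibility for
    CHONPS organic matter: positive C and H, P and S at most one, the H/C
    window ``C/3 <= H <= 2C+N+P+2``, the even-electron parity rule on
    ``N+H+P``, ``N <= C``, and the oxygen/sulfur bounds
    ``P <= O+S <= C+2N+3P``.
    """
    c, h, o, n, p, s = formula.counts()
    violations = []
    if not c > 0:
        violations.append("C > 0")
    if not n >= 0:
        violations.append("N >= 0")
    if not h > 0:
        violations.append("H > 0")
    if not o >= 0:
        violations.append("O >= 0")
    if not 0 <= p <= 1:
        violations.append("0 <= P <= 1")
    if not 0 <= s <= 1:
        violations.append("0 <= S <= 1")
    if not h >= c / 3:
        violations.append("H >= C/3")
    if not h <= 2 * c + n + p + 2:
        violations.append("H <= 2C + N + P + 2")
    if (n + h + p) % 2 != 0:
        violations.append("N + H + P even")
    if not n <= c:
        violations.append("N <= C")
    if not o + s <= c + 2 * n + 3 * p:
        violations.append("O + S <= C + 2N + 3P")
    if not o + s >= p:
        violations.append("O + S >= P")
    return (not violations, violations)


def aromaticity_index(formula: MolecularFormula, modified: bool = False) -> float:
    """Aromaticity index AI = (1 + C - O - S - H/2) / (C - O - S - N - P).

    ``modified=True`` uses the modified variant in which only half the oxygen
    is counted (O -> O/2 in numerator and denominator), appropriate when
    carboxyl-bound oxygen dominates.  A non-positive numerator or denominator
    clamps the result to 0 (the conventional reading: no aromatic character
    is inferable).
    """
    c, h, o, n, p, s = formula.counts()
    o_eff = 0.5 * o if modified else float(o)
    num = 1.0 + c - o_eff - s - 0.5 * h
    den = c - o_eff - s - n - p
    if num <= 0 or den <= 0:
        return 0.0
    return num / den


@dataclass(frozen=True)
class BuildingBlock:
    """A small functional-group mass difference used to extend formula
    assignments to neighbouring peaks (e.g. a CH2 homologue step).

    ``delta`` is the signed element-count change ``(c, h, o, n, p, s)``;
    ``mass`` is its signed monoisotopic mass in Da.
    """

    name: str
    delta: tuple[int, int, int, int, int, int]
    mass: float


def _block(name: str, c=0, h=0, o=0, n=0, p=0, s=0) -> BuildingBlock:
    e = ELEMENTS.elements
    mass = c * e["C"] + h * e["H"] + o * e["O"] + n * e["N"] + p * e["P"] + s * e["S"]
    return BuildingBlock(name, (c, h, o, n, p, s), mass)


#: The ten shipped building blocks, masses recomputed from the element table.
BUILDING_BLOCKS: tuple[BuildingBlock, ...] = (
    _block("CH4-O", c=1, h=4, o=-1),
    _block("C2H2", c=2, h=2),
    _block("C2H4", c=2, h=4),
    _block("CH2", c=1, h=2),
    _block("H2", h=2),
    _block("H2O", h=2, o=1),
    _block("O", o=1),
    _block("CO2", c=1, o=2),
    _block("NH", n=1, h=1),
    _block("S", s=1),
)

#: Enumeration bounds (inclusive) on each element count.
DEFAULT_BOUNDS: dict[str, tuple[int, int]] = {
    "c": (1, 100),
    "h": (1, 150),
    "o": (0, 50),
    "n": (0, 4),
    "p": (0, 1),
    "s": (0, 1),
}


def within_bounds(formula: MolecularFormula, bounds: dict[str, tuple[int, int]] = DEFAULT_BOUNDS) -> bool:
    return all(bounds[e][0] <= getattr(formula, e) <= bounds[e][1] for e in _ELEMENT_ORDER)


def apply_block(
    formula: MolecularFormula,
    block: BuildingBlock,
    sign: int = 1,
    bounds: dict[str, tuple[int, int]] | None = DEFAULT_BOUNDS,
) -> MolecularFormula | None:
    """Add (+1) or subtract (-1) a building block from a formula.

    Returns the new formula, or ``None`` (rejection) when any element count
    would go negative, the result violates the exclusion rules, or the result
    leaves the enumeration bounds.
    """
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    new_counts = [a + sign * d for a, d in zip(formula, block.delta)]
    if any(v < 0 for v in new_counts):
        return None
    result = MolecularFormula(*new_counts)
    ok, _ = validate_formula(result)
    if not ok:
        return None
    if bounds is not None and not within_bounds(result, bounds):
        return None
    return result
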