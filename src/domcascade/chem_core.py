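"""Molecular formulas, exact masses, structural descriptors, and compound classes.

The elemental composition of a dissolved-organic-matter (DOM) compound, as
resolved by ultrahigh-resolution mass spectrometry, is summarised here by a
:class:`MolecularFormula` (CHNOSP counts), from which exact monoisotopic mass
and the standard structural descriptors of environmental metabolomics are
derived: H/C, O/C and N/C ratios, double-bond equivalents (DBE), and the
modified aromaticity index (AI_mod) of Koch & Dittmar.  Compound classes
("lignin-like", "carbohydrate-like", ...) are assigned from those descriptors
by a first-match rule table in van-Krevelen style; the default table ships
with the package and is fully user-overridable because published boundary
schemes differ in their exact cut points.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Iterable

import yaml

__all__ = [
    "MONOISOTOPIC_MASS",
    "MolecularFormula",
    "FormulaDescriptors",
    "ClassRule",
    "ClassBoundaryTable",
    "DEFAULT_CLASS_TABLE",
    "COMPOUND_CLASSES",
    "parse_formula",
    "format_formula",
    "exact_neutral_mass",
    "descriptors",
    "classify",
]

# Monoisotopic atomic masses, Da.  12C defines the scale exactly; the rest are
# IUPAC/AME values to >= 9 decimal places.  This is the single constant table
# used by every mass computation in the package.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.007825032,
    "N": 14.003074005,
    "O": 15.994914620,
    "S": 31.972071001,
    "P": 30.973761632,
}

#: Canonical element order for formatted formulas.
ELEMENT_ORDER: tuple[str, ...] = ("C", "H", "N", "O", "S", "P")

_FIELD_OF_ELEMENT = {"C": "c", "H": "h", "N": "n", "O": "o", "S": "s", "P": "p"}


class FormulaError(ValueError):
    """Malformed or chemically invalid formula input."""


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Elemental composition (CHNOSP) of a singly-charged-ion-derived neutral.

    Counts are non-negative integers.  Instances are immutable and hashable,
    so they serve as join keys across samples and matrices.
    """

    c: int = 0
    h: int = 0
    o: int = 0
    n: int = 0
    s: int = 0
    p: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "o", "n", "s", "p"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool) or v < 0:
                raise FormulaError(
                    f"element count {name}={v!r} must be a non-negative integer"
                )

    @property
    def n_atoms(self) -> int:
        return self.c + self.h + self.o + self.n + self.s + self.p

    def __str__(self) -> str:
        return format_formula(self)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            c=self.c + other.c,
            h=self.h + other.h,
            o=self.o + other.o,
            n=self.n + other.n,
            s=self.s + other.s,
            p=self.p + other.p,
        )


_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def format_formula(f: MolecularFormula) -> str:
    """Canonical text form: elements in C,H,N,O,S,P order, count 1 elided."""
    parts: list[str] = []
    for el in ELEMENT_ORDER:
        count = getattr(f, _FIELD_OF_ELEMENT[el])
        if count == 0:
            continue
        parts.append(el if count == 1 else f"{el}{count}")
    return "".join(parts)


def parse_formula(text: str) -> MolecularFormula:
    """Parse a canonical formula string.

    Grammar: elements in C,H,N,O,S,P order; zero-count elements omitted; a
    bare element symbol means count 1.  Unknown symbols, out-of-order
    elements, repeats, and explicit zero counts are rejected with an error
    naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty or non-string formula text")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    order: list[str] = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula near {text[pos:]!r}")
        el, digits = m.group(1), m.group(2)
        if el not in ELEMENT_ORDER:
            raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
        if el in counts:
            raise FormulaError(f"repeated element {el!r} in {text!r}")
        count = int(digits) if digits else 1
        if count == 0:
            raise FormulaError(f"explicit zero count for {el!r} in {text!r}")
        counts[el] = count
        order.append(el)
        pos = m.end()
    canonical = [el for el in ELEMENT_ORDER if el in counts]
    if order != canonical:
        raise FormulaError(
            f"elements out of canonical C,H,N,O,S,P order in {text!r} "
            f"(got {''.join(order)})"
        )
    return MolecularFormula(**{_FIELD_OF_ELEMENT[el]: n for el, n in counts.items()})


def exact_neutral_mass(f: MolecularFormula) -> float:
    """Exact neutral monoisotopic mass in Da (sum of count x atomic mass)."""
    if f.n_atoms == 0:
        raise FormulaError("cannot compute the mass of an empty formula")
    return (
        f.c * MONOISOTOPIC_MASS["C"]
        + f.h * MONOISOTOPIC_MASS["H"]
        + f.n * MONOISOTOPIC_MASS["N"]
        + f.o * MONOISOTOPIC_MASS["O"]
        + f.s * MONOISOTOPIC_MASS["S"]
        + f.p * MONOISOTOPIC_MASS["P"]
    )


def double_bond_equivalents(f: MolecularFormula) -> float:
    """DBE = 1 + C - H/2 + N/2 + P/2 (may be half-integer or negative)."""
    return 1.0 + f.c - f.h / 2.0 + f.n / 2.0 + f.p / 2.0


def modified_aromaticity_index(f: MolecularFormula) -> float:
    """AI_mod per Koch & Dittmar, with half the oxygen treated as carbonyl.

    AI_mod = (1 + C - 0.5 O - S - 0.5 (N + P + H)) / (C - 0.5 O - S - N - P).
    Defined as 0 when the denominator is <= 0 or the quotient is negative,
    and clamped to at most 1, so saturated formulas never read as aromatic.
    """
    denom = f.c - 0.5 * f.o - f.s - f.n - f.p
    if denom <= 0:
        return 0.0
    num = 1.0 + f.c - 0.5 * f.o - f.s - 0.5 * (f.n + f.p + f.h)
    ai = num / denom
    return min(max(ai, 0.0), 1.0)


def hetero_group(f: MolecularFormula) -> str:
    """Heteroatom group label (CHO, CHNO, CHOS, ... CHNOSP) from N/S/P presence."""
    label = "CH"
    if f.n > 0:
        label += "N"
    label += "O"
    if f.s > 0:
        label += "S"
    if f.p > 0:
        label += "P"
    return label


# ---------------------------------------------------------------------------
# Compound-class boundary table
# ---------------------------------------------------------------------------

COMPOUND_CLASSES: tuple[str, ...] = (
    "condensed-aromatic-like",
    "tannin-like",
    "carbohydrate-like",
    "amino-sugar-like",
    "protein-like",
    "lipid-like",
    "unsaturated-hydrocarbon-like",
    "lignin-like",
    "other",
)


@dataclass(frozen=True)
class ClassRule:
    """One first-match rule over (H/C, O/C, AI_mod, N count).

    Bound conventions match the written inequalities of van-Krevelen schemes:
    lower bounds on O/C are exclusive and upper bounds inclusive
    (``lo < oc <= hi``), lower bounds on H/C are inclusive and upper bounds
    exclusive (``lo <= hc < hi``), AI_mod lower bound inclusive and upper
    bound exclusive.  ``None`` means unbounded.  ``requires_n`` demands at
    least one nitrogen.
    """

    label: str
    oc_gt: float | None = None
    oc_le: float | None = None
    hc_ge: float | None = None
    hc_lt: float | None = None
    ai_ge: float | None = None
    ai_lt: float | None = None
    requires_n: bool = False

    def matches(self, hc: float, oc: float, ai_mod: float, n: int) -> bool:
        if self.oc_gt is not None and not oc > self.oc_gt:
            return False
        if self.oc_le is not None and not oc <= self.oc_le:
            return False
        if self.hc_ge is not None and not hc >= self.hc_ge:
            return False
        if self.hc_lt is not None and not hc < self.hc_lt:
            return False
        if self.ai_ge is not None and not ai_mod >= self.ai_ge:
            return False
        if self.ai_lt is not None and not ai_mod < self.ai_lt:
            return False
        if self.requires_n and n < 1:
            return False
        return True


@dataclass(frozen=True)
class ClassBoundaryTable:
    """Ordered first-match rule list; the final catch-all guarantees a label."""

    rules: tuple[ClassRule, ...]

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("class table needs at least one rule")
        last = self.rules[-1]
        if any(
            getattr(last, b) is not None
            for b in ("oc_gt", "oc_le", "hc_ge", "hc_lt", "ai_ge", "ai_lt")
        ) or last.requires_n:
            raise ValueError("last rule must be an unconditional catch-all")

    def labels(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(r.label for r in self.rules))

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "ClassBoundaryTable":
        return cls(tuple(ClassRule(**r) for r in records))

    @classmethod
    def from_file(cls, path) -> "ClassBoundaryTable":
        """Load a rule list from YAML or JSON (list of ClassRule field dicts)."""
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        records = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        return cls.from_records(records)

    def to_records(self) -> list[dict]:
        out = []
        for r in self.rules:
            d = {"label": r.label}
            for b in ("oc_gt", "oc_le", "hc_ge", "hc_lt", "ai_ge", "ai_lt"):
                if getattr(r, b) is not None:
                    d[b] = getattr(r, b)
            if r.requires_n:
                d["requires_n"] = True
            out.append(d)
        return out


#: Default van-Krevelen-style boundary table.  First match wins; the AI_mod
#: rule for condensed aromatics fires before any ratio-based rule.
DEFAULT_CLASS_TABLE = ClassBoundaryTable(
    (
        ClassRule("condensed-aromatic-like", ai_ge=0.67),
        ClassRule("tannin-like", ai_lt=0.67, oc_gt=0.67, hc_lt=1.5),
        ClassRule("carbohydrate-like", oc_gt=0.67, hc_ge=1.5),
        ClassRule("amino-sugar-like", oc_gt=0.55, oc_le=0.67, hc_ge=1.5, requires_n=True),
        ClassRule("protein-like", oc_gt=0.3, oc_le=0.55, hc_ge=1.5, requires_n=True),
        ClassRule("lipid-like", oc_le=0.3, hc_ge=1.5),
        ClassRule("unsaturated-hydrocarbon-like", oc_le=0.1, hc_ge=0.7, hc_lt=1.5),
        ClassRule("lignin-like", oc_gt=0.1, oc_le=0.67, hc_ge=0.7, hc_lt=1.5, ai_lt=0.67),
        ClassRule("other"),
    )
)


@dataclass(frozen=True)
class FormulaDescriptors:
    """Derived structural descriptors of one molecular formula."""

    formula: MolecularFormula
    neutral_mass: float
    hc: float
    oc: float
    nc: float
    dbe: float
    ai_mod: float
    hetero_group: str
    compound_class: str


def classify(
    hc: float,
    oc: float,
    ai_mod: float = 0.0,
    n: int = 0,
    table: ClassBoundaryTable = DEFAULT_CLASS_TABLE,
) -> str:
    """Label of the first matching rule in ``table`` (deterministic)."""
    for rule in table.rules:
        if rule.matches(hc, oc, ai_mod, n):
            return rule.label
    raise AssertionError("unreachable: catch-all rule guarantees a match")


def descriptors(
    f: MolecularFormula, table: ClassBoundaryTable = DEFAULT_CLASS_TABLE
) -> FormulaDescriptors:
    """Compute all structural descriptors and the compound class for ``f``.

    Requires at least one carbon (the elemental ratios are undefined
    otherwise).
    """
    if f.c < 1:
        raise FormulaError(f"ratio descriptors need c >= 1 (got {format_formula(f) or f!r})")
    hc = f.h / f.c
    oc = f.o / f.c
    nc = f.n / f.c
    ai = modified_aromaticity_index(f)
    return FormulaDescriptors(
        formula=f,
        neutral_mass=exact_neutral_mass(f),
        hc=hc,
        oc=oc,
        nc=nc,
        dbe=double_bond_equivalents(f),
        ai_mod=ai,
        hetero_group=hetero_group(f),
        compound_class=classify(hc, oc, ai, f.n, table),
    )
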