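"""Compound catalogue: elemental formulas, monoisotopic masses, CSV loading.

A compound database is an ordered catalogue of small molecules (here,
phytohormones, their precursors, conjugates and metabolites), each carrying
the monoisotopic mass used for accurate-mass matching in positive-mode
electrospray LC-MS. Masses are computed from Hill-style elemental formulas
with IUPAC monoisotopic atomic masses, and catalogued masses are checked
against formula-derived masses so that downstream theoretical m/z values are
trustworthy at the 4-decimal precision screens operate at.
"""

from __future__ import annotations

import math
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from types import MappingProxyType
from typing import Optional

import pandas as pd

__all__ = [
    "ElementMassTable",
    "ElementalComposition",
    "Compound",
    "CompoundDatabase",
    "ValidationReport",
    "DEFAULT_MASS_TABLE",
    "FormulaError",
    "DatabaseFormatError",
    "parse_formula",
    "monoisotopic_mass",
    "load_compound_db",
    "load_fixture_db",
    "validate_db",
]

# Tolerance (Da) for agreement between a catalogued monoisotopic mass and the
# mass recomputed from the entry's elemental formula. Catalogued masses are
# typically printed to 2-4 decimals, so 5 mDa separates rounding from a
# genuinely different structure.
MASS_CONSISTENCY_TOL = 0.005


class FormulaError(ValueError):
    """Raised for malformed or unknown-element formulas."""


class DatabaseFormatError(ValueError):
    """Raised when a compound-database CSV violates the format contract."""


class ElementMassTable(Mapping):
    """Immutable element symbol -> monoisotopic atomic mass (Da) table."""

    def __init__(self, masses: Mapping[str, float]):
        for sym, m in masses.items():
            if m <= 0:
                raise ValueError(f"non-positive atomic mass for {sym!r}")
        self._masses = MappingProxyType(dict(masses))

    def __getitem__(self, symbol: str) -> float:
        try:
            return self._masses[symbol]
        except KeyError:
            raise KeyError(f"element {symbol!r} not in mass table") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._masses)

    def __len__(self) -> int:
        return len(self._masses)

    def __repr__(self) -> str:
        return f"ElementMassTable({len(self)} elements)"


#: IUPAC/CODATA monoisotopic atomic masses (most abundant isotope), Da.
DEFAULT_MASS_TABLE = ElementMassTable({
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
    "K": 38.96370668,
    "Li": 7.01600455,
    "Cl": 34.96885268,
    "Na": 22.9897692809,
    "F": 18.99840322,
    "Br": 78.9183371,
    "I": 126.904473,
})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalComposition(Mapping):
    """Element symbol -> positive integer count; empty composition allowed."""

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {sym!r}")
            if n > 0:
                clean[sym] = n
        self._counts = MappingProxyType(clean)

    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self._counts)
        for sym, n in other.items():
            merged[sym] = merged.get(sym, 0) + n
        return ElementalComposition(merged)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return dict(self._counts) == dict(other._counts)
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def hill_formula(self) -> str:
        """Format in Hill order: C first, then H, then alphabetical."""
        syms = sorted(self._counts)
        ordered = [s for s in ("C", "H") if s in self._counts]
        ordered += [s for s in syms if s not in ("C", "H")]
        return "".join(
            f"{s}{self._counts[s]}" if self._counts[s] > 1 else s for s in ordered
        )

    def __repr__(self) -> str:
        return f"ElementalComposition({self.hill_formula()!r})"


def parse_formula(
    formula: str, table: ElementMassTable = DEFAULT_MASS_TABLE
) -> ElementalComposition:
    """Parse a Hill-style elemental formula such as ``"C15H20O4"``.

    Case-sensitive on element symbols; repeated symbols accumulate. Unknown
    element symbols and explicit zero counts raise :class:`FormulaError`.
    """
    formula = formula.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {formula!r} at position {pos}"
            )
        sym, digits = m.group(1), m.group(2)
        if sym not in table:
            raise FormulaError(f"unknown element symbol {sym!r} in {formula!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaError(f"zero count for element {sym!r} in {formula!r}")
        counts[sym] = counts.get(sym, 0) + n
        pos = m.end()
    return ElementalComposition(counts)


def monoisotopic_mass(
    comp: ElementalComposition, table: ElementMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Sum of count x monoisotopic atomic mass over the composition, in Da."""
    return sum(n * table[sym] for sym, n in comp.items())


@dataclass(frozen=True)
class Compound:
    """One catalogue entry: a named hormone, precursor, metabolite or conjugate.

    ``monoisotopic_mass`` is the neutral monoisotopic mass in Da. When an
    elemental formula is present it must agree with the catalogued mass
    within :data:`MASS_CONSISTENCY_TOL`.
    """

    name: str
    hormone_class: str
    monoisotopic_mass: float
    formula: Optional[ElementalComposition] = None
    smiles: Optional[str] = None
    inchi: Optional[str] = None
    predicted_rt: Optional[float] = None
    #: per-instance consistency tolerance; pass ``float("inf")`` to defer the
    #: check to :func:`validate_db` (e.g. when auditing a third-party file).
    mass_tol: float = field(
        default=MASS_CONSISTENCY_TOL, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("compound name must be non-empty")
        if not (self.monoisotopic_mass > 0):
            raise ValueError(
                f"{self.name!r}: monoisotopic mass must be positive"
            )
        disc = self.mass_discrepancy()
        if disc is not None and disc > self.mass_tol:
            raise ValueError(
                f"{self.name!r}: catalogued mass {self.monoisotopic_mass} "
                f"differs from formula-derived mass by {disc:.4f} Da"
            )

    def mass_discrepancy(self) -> Optional[float]:
        """|catalogued - formula-derived| mass, or None without a formula."""
        if self.formula is None:
            return None
        return abs(self.monoisotopic_mass - monoisotopic_mass(self.formula))


@dataclass
class CompoundDatabase:
    """Ordered compound catalogue with unique, whitespace-trimmed names."""

    entries: list[Compound] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.entries:
            if c.name in seen:
                raise DatabaseFormatError(f"duplicate compound name {c.name!r}")
            seen.add(c.name)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Compound]:
        return iter(self.entries)

    def get(self, name: str) -> Compound:
        for c in self.entries:
            if c.name == name:
                return c
        raise KeyError(f"no compound named {name!r}")

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.entries:
            counts[c.hormone_class] = counts.get(c.hormone_class, 0) + 1
        return counts


# Accepted header aliases for the required/optional CSV columns.
_COLUMN_ALIASES = {
    "name": ("name", "compound name", "compound_name", "compound"),
    "class": ("class", "hormone_class", "compound class"),
    "monoisotopic_mass": ("monoisotopic_mass", "monoisotopic mass", "mass"),
    "formula": ("formula", "molecular_formula", "molecular formula"),
    "smiles": ("smiles",),
    "inchi": ("inchi",),
    "predicted_rt": ("predicted_rt", "predicted rt", "predicted rt (min)"),
}


def _resolve_columns(columns: list[str]) -> dict[str, str]:
    lower = {c.strip().lower(): c for c in columns}
    resolved = {}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for a in aliases:
            if a in lower:
                resolved[canonical] = lower[a]
                break
    return resolved


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    return s or None


def load_compound_db(
    path: str | Path,
    provenance: str | None = None,
    mass_table: ElementMassTable = DEFAULT_MASS_TABLE,
    strict: bool = True,
) -> CompoundDatabase:
    """Load a compound-database CSV.

    Required columns (header aliases accepted): ``name``, ``class``,
    ``monoisotopic_mass``. Optional: ``formula``, ``smiles``, ``inchi``,
    ``predicted_rt``. Rows violating compound invariants are collected and
    reported together in a :class:`DatabaseFormatError`. With
    ``strict=False`` mass/formula inconsistencies are admitted so the file
    can be audited with :func:`validate_db`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    cols = _resolve_columns(list(df.columns))
    missing = [k for k in ("name", "class", "monoisotopic_mass") if k not in cols]
    if missing:
        raise DatabaseFormatError(
            f"{path.name}: missing mandatory column(s) {missing}; "
            f"found {list(df.columns)}"
        )

    entries: list[Compound] = []
    row_errors: list[str] = []
    for i, row in df.iterrows():
        try:
            raw_mass = row[cols["monoisotopic_mass"]]
            try:
                mass = float(raw_mass)
            except (TypeError, ValueError):
                raise ValueError(f"non-numeric monoisotopic mass {raw_mass!r}")
            formula_str = _opt_str(row.get(cols.get("formula", ""), None)) if "formula" in cols else None
            comp = parse_formula(formula_str, mass_table) if formula_str else None
            rt_str = _opt_str(row.get(cols.get("predicted_rt", ""), None)) if "predicted_rt" in cols else None
            entries.append(Compound(
                name=str(row[cols["name"]]).strip(),
                hormone_class=str(row[cols["class"]]).strip(),
                monoisotopic_mass=mass,
                formula=comp,
                smiles=_opt_str(row.get(cols.get("smiles", ""), None)) if "smiles" in cols else None,
                inchi=_opt_str(row.get(cols.get("inchi", ""), None)) if "inchi" in cols else None,
                predicted_rt=float(rt_str) if rt_str else None,
                mass_tol=MASS_CONSISTENCY_TOL if strict else float("inf"),
            ))
        except (ValueError, FormulaError) as exc:
            row_errors.append(f"row {i}: {exc}")
    if row_errors:
        raise DatabaseFormatError(
            f"{path.name}: {len(row_errors)} invalid row(s):\n  "
            + "\n  ".join(row_errors)
        )
    return CompoundDatabase(entries, provenance or str(path))


def load_fixture_db() -> CompoundDatabase:
    """Load the compound catalogue shipped with the package.

    A self-contained subset of the full phytohormone catalogue covering the
    compounds used throughout the test suite and documentation examples.
    """
    with resources.as_file(
        resources.files("hormonomics.data") / "fixture_compounds.csv"
    ) as p:
        return load_compound_db(p, provenance="shipped fixture catalogue")


@dataclass(frozen=True)
class ValidationReport:
    """Outcome of a formula-vs-catalogued-mass consistency check."""

    mismatches: tuple[tuple[str, float, float, float], ...]  # name, catalogued, derived, |diff|
    unverifiable: int  # entries without a formula

    @property
    def clean(self) -> bool:
        return not self.mismatches


def validate_db(
    db: CompoundDatabase,
    tol: float = MASS_CONSISTENCY_TOL,
    mass_table: ElementMassTable = DEFAULT_MASS_TABLE,
) -> ValidationReport:
    """Report entries whose catalogued mass deviates from the formula-derived
    mass by more than ``tol`` Da; formula-less entries count as unverifiable.
    """
    mismatches = []
    unverifiable = 0
    for c in db:
        if c.formula is None:
            unverifiable += 1
            continue
        derived = monoisotopic_mass(c.formula, mass_table)
        diff = abs(c.monoisotopic_mass - derived)
        if diff > tol:
            mismatches.append((c.name, c.monoisotopic_mass, derived, diff))
    return ValidationReport(tuple(mismatches), unverifiable)
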