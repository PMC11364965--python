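"""Adduct and biotransformation mass-shift calculus.

A mass-shift rule is a signed multiset of small moieties applied to a parent
molecule, written in the field's ``M+X-Y`` notation: ``M-OH+CH3`` models a
net demethylation-for-hydroxyl exchange, ``M+C6H12O6`` a glycosylation,
``M+H-H2O`` an in-source water loss of the protonated ion. Four built-in
rule sets are provided for screening positive-mode LC-MS data:

``PGR_Monoisotopic``
    the identity rule (peak tables already reduced to neutral mass),
``PGR_MplusH``
    the single protonation rule ``M+H``,
``PGR_Adducts``
    7 common electrospray adducts,
``PGR_Biotransformations``
    27 plausible enzymatic modifications (methylation, hydroxylation,
    glycosylation, amination, carboxylation, and their removals/exchanges).

Theoretical m/z values default to the neutral-shift convention (parent
monoisotopic mass plus the signed moiety deltas, no proton); a protonated
mode adds 1.007276 Da on top for tables of M+H ions.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Literal

from hormonomics.compounds import (
    DEFAULT_MASS_TABLE,
    Compound,
    CompoundDatabase,
    ElementalComposition,
    monoisotopic_mass,
    parse_formula,
)

__all__ = [
    "Moiety",
    "MassShiftRule",
    "RuleSet",
    "ShiftedEntry",
    "ShiftError",
    "PROTON_MASS",
    "MOIETIES",
    "ADDUCT_LABELS",
    "BIOTRANSFORMATION_LABELS",
    "parse_shift",
    "shift_delta",
    "apply_shift",
    "builtin_ruleset",
    "expand_database",
    "ruleset_to_csv",
    "ruleset_from_csv",
]

#: Mass of a proton (Da). Ionic adducts here use neutral-moiety masses and do
#: not subtract the electron mass (~0.00055 Da, below both the 4-decimal
#: printed precision and the conventional 0.02 Da search tolerance).
PROTON_MASS = 1.007276

Mode = Literal["neutral_shift", "protonated"]


class ShiftError(ValueError):
    """Raised for malformed shift notation or physically invalid shifts."""


@dataclass(frozen=True)
class Moiety:
    """A small chemical group exchanged by a shift rule."""

    token: str
    composition: ElementalComposition
    mass: float


def _moiety(token: str, formula: str) -> Moiety:
    comp = parse_formula(formula)
    return Moiety(token, comp, monoisotopic_mass(comp))


#: The moiety vocabulary of the built-in rule notation.
MOIETIES: dict[str, Moiety] = {
    tok: _moiety(tok, f)
    for tok, f in [
        ("C6H12O6", "C6H12O6"),
        ("CH3OH", "CH4O"),
        ("COOH", "CO2H"),
        ("CH3", "CH3"),
        ("NH4", "NH4"),
        ("NH3", "NH3"),
        ("NH2", "NH2"),
        ("H2O", "H2O"),
        ("OH", "OH"),
        ("H2", "H2"),
        ("Li", "Li"),
        ("K", "K"),
        ("H", "H"),
    ]
}

# Longest-first so CH3OH wins over CH3, NH4 over NH3/NH2, H2O over H2/H, etc.
_TOKEN_ORDER = sorted(MOIETIES, key=len, reverse=True)
_TERM_RE = re.compile(
    r"([+-])(\d*)(" + "|".join(re.escape(t) for t in _TOKEN_ORDER) + r")"
)

RuleKind = Literal["adduct", "biotransformation", "protonation", "identity"]


@dataclass(frozen=True)
class MassShiftRule:
    """A parsed ``M±...`` rule: ordered signed terms and their net mass delta."""

    label: str
    terms: tuple[tuple[int, int, Moiety], ...]  # (sign, coefficient, moiety)
    kind: RuleKind

    @property
    def delta(self) -> float:
        """Net signed mass shift in Da."""
        return sum(s * c * m.mass for s, c, m in self.terms)

    def __str__(self) -> str:
        return self.label


def parse_shift(notation: str, kind: RuleKind | None = None) -> MassShiftRule:
    """Parse shift notation like ``"M-OH+CH3"`` or ``"M+H-2H2O"``.

    The grammar is ``M`` followed by zero or more signed terms, each an
    optional positive integer coefficient and a moiety token from
    :data:`MOIETIES`. ``"M"`` alone is the identity rule.
    """
    s = notation.strip()
    if not s.startswith("M"):
        raise ShiftError(f"shift notation must start with 'M': {notation!r}")
    body = s[1:]
    terms: list[tuple[int, int, Moiety]] = []
    pos = 0
    while pos < len(body):
        m = _TERM_RE.match(body, pos)
        if not m:
            raise ShiftError(
                f"cannot parse shift {notation!r} at {body[pos:]!r} "
                f"(unknown moiety or malformed sign)"
            )
        sign = 1 if m.group(1) == "+" else -1
        coeff = int(m.group(2)) if m.group(2) else 1
        if coeff == 0:
            raise ShiftError(f"zero coefficient in {notation!r}")
        terms.append((sign, coeff, MOIETIES[m.group(3)]))
        pos = m.end()
    if kind is None:
        kind = "identity" if not terms else "biotransformation"
    label = "M" + "".join(
        f"{'+' if s > 0 else '-'}{c if c > 1 else ''}{moi.token}"
        for s, c, moi in terms
    )
    return MassShiftRule(label=label, terms=tuple(terms), kind=kind)


def shift_delta(rule: MassShiftRule) -> float:
    """Signed net mass delta of a rule, in Da."""
    return rule.delta


def apply_shift(
    mass: float, rule: MassShiftRule, mode: Mode = "neutral_shift"
) -> float:
    """Theoretical m/z of ``mass`` under ``rule``.

    ``neutral_shift`` returns mass + delta; ``protonated`` additionally adds
    one proton. A non-positive result (removing a moiety heavier than the
    molecule) raises :class:`ShiftError`.
    """
    if mass <= 0:
        raise ShiftError("parent mass must be positive")
    mz = mass + rule.delta
    if mode == "protonated":
        mz += PROTON_MASS
    elif mode != "neutral_shift":
        raise ShiftError(f"unknown mode {mode!r}")
    if mz <= 0:
        raise ShiftError(
            f"rule {rule.label} applied to mass {mass} gives non-positive m/z"
        )
    return mz


#: 7 common positive-mode electrospray adducts.
ADDUCT_LABELS: tuple[str, ...] = (
    "M+H-2H2O",
    "M+H-H2O",
    "M+NH4-H2O",
    "M+Li",
    "M+NH4",
    "M+CH3OH-H",
    "M+K",
)

#: 27 synthetic biotransformations: (de)methylation, hydroxylation,
#: glycosylation, amination, carboxylation and their exchanges.
BIOTRANSFORMATION_LABELS: tuple[str, ...] = (
    "M+CH3",
    "M+C6H12O6",
    "M+OH",
    "M+COOH",
    "M+NH2",
    "M+NH3",
    "M-H+OH",
    "M-H+2OH",
    "M-H+NH2",
    "M-CH3+H",
    "M-CH3+OH",
    "M-CH3+NH2",
    "M-C6H12O6+H",
    "M-C6H12O6+OH",
    "M-C6H12O6+NH2",
    "M-C6H12O6+CH3",
    "M-OH+H2",
    "M-OH+CH3",
    "M-OH+C6H12O6",
    "M-OH+COOH",
    "M-OH+NH2",
    "M-OH+NH3",
    "M-NH2+H2",
    "M-NH2+CH3",
    "M-NH2+C6H12O6",
    "M-NH2+COOH",
    "M-NH2+OH",
)

# Chemically common alternate for methanol adduction (M+CH3OH+H); kept out of
# the default adduct set, which follows the published M+CH3OH-H rule as-is.
# ALT_METHANOL_ADDUCT = parse_shift("M+CH3OH+H", kind="adduct")


@dataclass(frozen=True)
class RuleSet:
    """A named, ordered collection of mass-shift rules."""

    name: str
    rules: tuple[MassShiftRule, ...]

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)


_BUILTIN_ALIASES = {
    "pgr_monoisotopic": "PGR_Monoisotopic",
    "monoisotopic": "PGR_Monoisotopic",
    "pgr_mplush": "PGR_MplusH",
    "mh": "PGR_MplusH",
    "m+h": "PGR_MplusH",
    "pgr_adducts": "PGR_Adducts",
    "adducts": "PGR_Adducts",
    "pgr_biotransformations": "PGR_Biotransformations",
    "biotransformations": "PGR_Biotransformations",
}


def builtin_ruleset(name: str) -> RuleSet:
    """Return one of the four built-in searchable rule sets by name.

    Accepts canonical names (``PGR_Adducts``) or short aliases
    (``adducts``, ``mh``, ...), case-insensitively.
    """
    canonical = _BUILTIN_ALIASES.get(name.strip().lower())
    if canonical is None:
        raise ShiftError(
            f"unknown rule set {name!r}; expected one of "
            f"{sorted(set(_BUILTIN_ALIASES.values()))}"
        )
    if canonical == "PGR_Monoisotopic":
        rules = (parse_shift("M", kind="identity"),)
    elif canonical == "PGR_MplusH":
        rules = (parse_shift("M+H", kind="protonation"),)
    elif canonical == "PGR_Adducts":
        rules = tuple(parse_shift(lbl, kind="adduct") for lbl in ADDUCT_LABELS)
    else:
        rules = tuple(
            parse_shift(lbl, kind="biotransformation")
            for lbl in BIOTRANSFORMATION_LABELS
        )
    return RuleSet(canonical, rules)


@dataclass(frozen=True)
class ShiftedEntry:
    """An expanded database row: compound x rule x theoretical m/z.

    ``predicted_rt`` is copied from the parent compound — the retention time
    prediction applies to the parent, not the transformed metabolite.
    """

    compound: Compound
    rule: MassShiftRule
    theoretical_mz: float
    predicted_rt: float | None = None


def ruleset_to_csv(ruleset: RuleSet, path) -> None:
    """Serialize a rule set to CSV: label, kind, delta, term list.

    ``terms`` is a machine-readable ``sign*coeff*token`` list joined by
    spaces, e.g. ``"-1*1*OH +1*1*CH3"``.
    """
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "kind", "delta", "terms"])
        for r in ruleset:
            terms = " ".join(f"{s:+d}*{c}*{m.token}" for s, c, m in r.terms)
            w.writerow([r.label, r.kind, f"{r.delta:.6f}", terms])


def ruleset_from_csv(path, name: str | None = None) -> RuleSet:
    """Load a rule set serialized by :func:`ruleset_to_csv`.

    Rules are re-parsed from their labels; the stored delta is checked
    against the recomputed one to 1e-4 Da.
    """
    import csv
    from pathlib import Path

    rows = list(csv.DictReader(open(path)))
    rules = []
    for row in rows:
        rule = parse_shift(row["label"], kind=row["kind"])  # type: ignore[arg-type]
        stored = float(row["delta"])
        if abs(stored - rule.delta) > 1e-4:
            raise ShiftError(
                f"{row['label']}: stored delta {stored} disagrees with "
                f"recomputed {rule.delta:.6f}"
            )
        rules.append(rule)
    return RuleSet(name or Path(path).stem, tuple(rules))


def expand_database(
    db: CompoundDatabase | list[Compound],
    rules: RuleSet,
    mode: Mode = "neutral_shift",
) -> list[ShiftedEntry]:
    """Cross every compound with every rule into a searchable entry list.

    Output order is database order x rule order. Combinations producing a
    non-positive m/z are skipped with a warning.
    """
    entries: list[ShiftedEntry] = []
    rejected = 0
    for compound in db:
        for rule in rules:
            try:
                mz = apply_shift(compound.monoisotopic_mass, rule, mode)
            except ShiftError:
                rejected += 1
                continue
            entries.append(ShiftedEntry(
                compound=compound,
                rule=rule,
                theoretical_mz=mz,
                predicted_rt=compound.predicted_rt,
            ))
    if rejected:
        warnings.warn(
            f"expand_database: {rejected} compound x rule combination(s) "
            f"rejected for non-positive m/z",
            stacklevel=2,
        )
    return entries
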