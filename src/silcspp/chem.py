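"""Elemental formulas, monoisotopic mass arithmetic, adduct conventions, and
the built-in biotransformation ruleset.

Mass conventions
----------------
Negative-mode ion m/z values are computed as plain sums of atomic monoisotopic
masses (no electron-mass correction): this is the convention under which the
reference Δppm values for deprotonated ion formulas are reproduced, and it is
applied uniformly.

Two closely related constants appear.  ``C13_MINUS_C12`` (1.0033548 Da) is the
physical mass difference between the carbon isotopes and is used wherever a
formula with explicitly labeled carbons is turned into a mass.  ``SIL_CARBON``
(1.003355 Da) is the per-carbon label spacing used by the isotopologue tracing
and by the ruleset's ".13Cn" variants; the two agree to well below any matching
tolerance used here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Mapping

__all__ = [
    "ATOMIC_MASS",
    "AVERAGE_MASS",
    "C13_MINUS_C12",
    "SIL_CARBON",
    "SIL_MOIETY",
    "ADDUCTS",
    "ElementCount",
    "Adduct",
    "Conversion",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "average_mass",
    "sil_shift",
    "ion_mz",
    "ppm_deviation",
    "builtin_ruleset",
    "read_ruleset",
    "write_ruleset",
]

# Monoisotopic masses, CODATA/NIST, fixed at 7 decimals for bit-stable tests.
ATOMIC_MASS: dict[str, float] = {
    "H": 1.0078250,
    "C": 12.0,
    "N": 14.0030740,
    "O": 15.9949146,
    "S": 31.9720707,
    "Na": 22.9897693,
}

# Standard atomic weights, used only for mole <-> gram conversions.
AVERAGE_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "Na": 22.990,
}

#: Physical 13C - 12C mass difference (Da).
C13_MINUS_C12: float = 13.0033548 - 12.0

#: Per-carbon label spacing used for isotopologue tracing and ruleset variants.
SIL_CARBON: float = 1.003355

#: Mass shift of one fully labeled three-carbon precursor moiety (Da).
SIL_MOIETY: float = 3 * SIL_CARBON

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementCount:
    """A neutral elemental composition, optionally with labeled carbons.

    ``labeled_c`` counts how many of the carbons are 13C; it never exceeds the
    total carbon count.
    """

    counts: tuple[tuple[str, int], ...]
    labeled_c: int = 0

    def __post_init__(self) -> None:
        for element, n in self.counts:
            if element not in ATOMIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if n <= 0:
                raise ValueError(f"count for {element} must be positive, got {n}")
        if not self.counts:
            raise ValueError("empty composition")
        if self.labeled_c < 0:
            raise ValueError("labeled carbon count must be >= 0")
        if self.labeled_c > self.get("C"):
            raise ValueError("labeled carbon count exceeds total carbon count")

    @classmethod
    def from_dict(cls, counts: Mapping[str, int], labeled_c: int = 0) -> "ElementCount":
        items = tuple(sorted((e, int(n)) for e, n in counts.items() if n))
        return cls(items, labeled_c)

    def get(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def items(self) -> Iterator[tuple[str, int]]:
        return iter(self.counts)

    def __add__(self, other: "ElementCount") -> "ElementCount":
        merged = dict(self.counts)
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) + n
        return ElementCount.from_dict(merged, self.labeled_c + other.labeled_c)

    def with_labeled(self, labeled_c: int) -> "ElementCount":
        return ElementCount(self.counts, labeled_c)

    def multiply(self, factor: int) -> "ElementCount":
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return ElementCount.from_dict(
            {e: n * factor for e, n in self.counts}, self.labeled_c * factor
        )


def parse_formula(text: str) -> ElementCount:
    """Parse a Hill-style formula string such as ``"C22H18O12"``.

    Raises ``ValueError`` on unknown element symbols or explicit zero counts.
    """
    if not text or not text.strip():
        raise ValueError("empty formula")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at position {pos}")
        element, digits = match.groups()
        if element not in ATOMIC_MASS:
            raise ValueError(f"unknown element symbol {element!r} in {text!r}")
        n = int(digits) if digits else 1
        if n == 0:
            raise ValueError(f"zero count for {element} in {text!r}")
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at position {pos}")
    return ElementCount.from_dict(counts)


def format_formula(composition: ElementCount) -> str:
    """Format in Hill order (C, H, then alphabetical)."""
    counts = dict(composition.counts)
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


def monoisotopic_mass(composition: ElementCount) -> float:
    """Monoisotopic mass in Da; labeled carbons add ``C13_MINUS_C12`` each."""
    total = sum(ATOMIC_MASS[e] * n for e, n in composition.counts)
    return total + composition.labeled_c * C13_MINUS_C12


def average_mass(composition: ElementCount) -> float:
    """Average molar mass in g/mol (for content normalization)."""
    return sum(AVERAGE_MASS[e] * n for e, n in composition.counts)


def sil_shift(k_moieties: int) -> float:
    """Mass shift from incorporating ``k`` labeled three-carbon moieties."""
    if k_moieties < 0:
        raise ValueError("number of labeled moieties must be >= 0")
    return k_moieties * SIL_MOIETY


@dataclass(frozen=True)
class Adduct:
    """A singly-charged negative-mode ionization form."""

    name: str
    multimer: int
    offset: float


_PROTON = ATOMIC_MASS["H"]
_ACETATE_OFFSET = 2 * ATOMIC_MASS["C"] + 4 * ATOMIC_MASS["H"] + 2 * ATOMIC_MASS["O"] - _PROTON

ADDUCTS: dict[str, Adduct] = {
    "[M-H]-": Adduct("[M-H]-", 1, -_PROTON),
    "[M+Ac-H]-": Adduct("[M+Ac-H]-", 1, _ACETATE_OFFSET),
    "[2M-H]-": Adduct("[2M-H]-", 2, -_PROTON),
}


def ion_mz(neutral: ElementCount, adduct: Adduct | str) -> float:
    """m/z of a singly-charged ion: ``multimer x M + offset``, plain atomic sums.

    For multimer adducts the labeled carbons of ``neutral`` are taken as
    belonging to the whole ion (a mixed light/heavy dimer is expressed by
    setting ``labeled_c`` to the total over both monomers).
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise ValueError(f"unsupported adduct name: {adduct!r}") from None
    unlabeled = sum(ATOMIC_MASS[e] * n for e, n in neutral.counts)
    mz = adduct.multimer * unlabeled + neutral.labeled_c * C13_MINUS_C12 + adduct.offset
    if mz <= 0:
        raise ValueError("ion mass is not positive; adduct loss exceeds neutral mass")
    return mz


def ppm_deviation(observed: float, theoretical: float) -> float:
    """Relative deviation (observed - theoretical) / theoretical in ppm."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class Conversion:
    """One biotransformation rule of the mass-difference ruleset.

    ``elution_order`` follows the reversed-phase convention: 1 means the
    product elutes earlier than the substrate (more polar product, e.g. a
    glycosylation), 2 means the product elutes later.  ``labeled_carbons`` is
    nonzero for the stable-isotope-labeled variants of a rule, whose moiety
    carries that many 13C atoms.
    """

    nr: int | None
    short: str
    name: str
    composition: ElementCount
    elution_order: int
    labeled_carbons: int = 0
    printed_delta: float | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.elution_order not in (1, 2):
            raise ValueError("elution_order must be 1 or 2")
        if self.labeled_carbons < 0:
            raise ValueError("labeled_carbons must be >= 0")
        if self.delta_mass <= 0:
            raise ValueError("delta_mass must be positive")

    @property
    def delta_mass(self) -> float:
        """Full-precision mass delta: moiety mass plus the label shift."""
        base = sum(ATOMIC_MASS[e] * n for e, n in self.composition.counts)
        return base + self.labeled_carbons * SIL_CARBON


class Ruleset(tuple):
    """An ordered, indexable collection of :class:`Conversion` rules."""

    def lookup(self, short: str) -> Conversion:
        for rule in self:
            if rule.short == short:
                return rule
        raise KeyError(short)

    @property
    def base_rules(self) -> tuple[Conversion, ...]:
        return tuple(r for r in self if r.nr is not None)


def read_ruleset(path: str | Path) -> Ruleset:
    """Read a tab-separated conversion table (see the packaged default)."""
    rules: list[Conversion] = []
    lines = Path(path).read_text().splitlines()
    header = lines[0].split("\t")
    expected = ["nr", "short", "name", "composition", "elution_order", "labeled_carbons", "printed_delta"]
    if header != expected:
        raise ValueError(f"ruleset header must be {expected}, got {header}")
    for line in lines[1:]:
        if not line.strip():
            continue
        nr, short, name, comp, order, labeled, printed = line.split("\t")
        rules.append(
            Conversion(
                nr=int(nr) if nr else None,
                short=short,
                name=name,
                composition=parse_formula(comp),
                elution_order=int(order),
                labeled_carbons=int(labeled),
                printed_delta=float(printed) if printed else None,
            )
        )
    return Ruleset(rules)


def write_ruleset(rules: Ruleset, path: str | Path) -> None:
    out = ["nr\tshort\tname\tcomposition\telution_order\tlabeled_carbons\tprinted_delta"]
    for r in rules:
        out.append(
            "\t".join(
                [
                    "" if r.nr is None else str(r.nr),
                    r.short,
                    r.name,
                    format_formula(r.composition),
                    str(r.elution_order),
                    str(r.labeled_carbons),
                    "" if r.printed_delta is None else f"{r.printed_delta:.4f}",
                ]
            )
        )
    Path(path).write_text("\n".join(out) + "\n")


def builtin_ruleset() -> Ruleset:
    """The packaged ruleset: 25 base biotransformations plus the labeled
    variants and the hexose-plus-acetate-adduct row (38 rows)."""
    ref = resources.files("silcspp.data").joinpath("conversions.tsv")
    with resources.as_file(ref) as path:
        return read_ruleset(path)
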