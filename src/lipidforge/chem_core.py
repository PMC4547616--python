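"""Elemental-composition algebra, Hill formulas, monoisotopic/average mass and adduct m/z.

All mass arithmetic in the package funnels through :class:`ElementalComposition`
and the pinned :class:`AtomicMassTable`, so that formulas, neutral masses and
adduct m/z values are bit-reproducible across runs and machines.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from types import MappingProxyType

__all__ = [
    "ElementalComposition",
    "AtomicMassTable",
    "AdductSpec",
    "ADDUCTS",
    "DEFAULT_MASS_TABLE",
    "formula_of",
    "parse_formula",
    "monoisotopic_mass",
    "average_mass",
    "adduct_mz",
]


class ElementalComposition(Mapping[str, int]):
    """An immutable element -> count map with element-wise algebra.

    Counts are non-negative integers; an absent element is equivalent to a
    count of zero.  Addition and subtraction are element-wise; subtraction
    below zero raises ``ValueError`` rather than producing a nonsensical
    composition.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = dict(counts or {})
        merged.update(kw)
        clean: dict[str, int] = {}
        for el, n in merged.items():
            if not isinstance(n, int) or isinstance(n, bool):
                raise TypeError(f"count for element {el!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for element {el!r}: {n}")
            if n > 0:
                clean[el] = n
        self._counts = MappingProxyType(clean)

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el: object) -> bool:  # absent element == count 0
        return self._counts.get(el, 0) > 0  # type: ignore[arg-type]

    # -- algebra -----------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for el, n in other.items():
            out[el] = out.get(el, 0) + n
        return ElementalComposition(out)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        out = dict(self._counts)
        for el, n in other.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise ValueError(
                    f"subtraction would give {new} atoms of {el} "
                    f"({formula_of(self)!r} - {formula_of(other)!r})"
                )
            out[el] = new
        return ElementalComposition(out)

    def __mul__(self, k: int) -> "ElementalComposition":
        if not isinstance(k, int) or k < 0:
            raise ValueError(f"multiplier must be a non-negative integer, got {k!r}")
        return ElementalComposition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return dict(self._counts) == dict(other._counts)
        if isinstance(other, Mapping):
            return dict(self._counts) == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalComposition({dict(sorted(self._counts.items()))})"


def _hill_order(elements: list[str]) -> list[str]:
    """Hill convention: C first, H second, remaining elements alphabetical."""
    rest = sorted(e for e in elements if e not in ("C", "H"))
    ordered = []
    if "C" in elements:
        ordered.append("C")
        if "H" in elements:
            ordered.append("H")
        return ordered + rest
    # no carbon: strictly alphabetical (H included)
    return sorted(elements)


def formula_of(comp: ElementalComposition) -> str:
    """Render *comp* as a Hill-order formula string ('' for the empty composition)."""
    parts = []
    for el in _hill_order(list(comp)):
        n = comp[el]
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementalComposition:
    """Inverse of :func:`formula_of` for plain (non-isotopic) formulas."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at offset {pos}")
        el, digits = m.groups()
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at offset {pos}")
    return ElementalComposition(counts)


@dataclass(frozen=True)
class AtomicMassTable:
    """Pinned atomic masses (Da).

    Monoisotopic values follow the IUPAC 2005 recommended isotopic masses
    (AME2003 evaluation); average values are the IUPAC 2007 standard atomic
    weights.  Hard-coded so library builds are reproducible without network
    access.
    """

    monoisotopic: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {
                "H": 1.0078250319,
                "C": 12.0,
                "N": 14.0030740052,
                "O": 15.9949146221,
                "P": 30.97376151,
                "S": 31.97207069,
                "Na": 22.98976928,
                "K": 38.9637069,
                "Li": 7.0160040,
                "Cl": 34.96885271,
            }
        )
    )
    average: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {
                "H": 1.00794,
                "C": 12.0107,
                "N": 14.0067,
                "O": 15.9994,
                "P": 30.973762,
                "S": 32.065,
                "Na": 22.98977,
                "K": 39.0983,
                "Li": 6.941,
                "Cl": 35.453,
            }
        )
    )
    electron_mass: float = 5.4857990946e-4


DEFAULT_MASS_TABLE = AtomicMassTable()


def monoisotopic_mass(
    comp: ElementalComposition, table: AtomicMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Monoisotopic mass (Da) of *comp*: sum of count(e) * mass(e)."""
    total = 0.0
    for el, n in comp.items():
        try:
            total += n * table.monoisotopic[el]
        except KeyError:
            raise KeyError(f"no monoisotopic mass for element {el!r}") from None
    return total


def average_mass(
    comp: ElementalComposition, table: AtomicMassTable = DEFAULT_MASS_TABLE
) -> float:
    """Isotope-abundance-weighted (average) mass in Da."""
    total = 0.0
    for el, n in comp.items():
        try:
            total += n * table.average[el]
        except KeyError:
            raise KeyError(f"no average mass for element {el!r}") from None
    return total


@dataclass(frozen=True)
class AdductSpec:
    """One MS adduct: a signed mass shift applied to the neutral molecule.

    ``mass_delta`` includes the electron-mass correction, so for example
    [M+H]+ adds the mass of a proton (1.007276 Da), not of a hydrogen atom,
    and the radical cation [M.]+ is M minus one electron.
    """

    label: str
    mass_delta: float
    charge: int
    polarity: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")
        if self.polarity not in ("positive", "negative"):
            raise ValueError(f"polarity must be positive|negative, got {self.polarity!r}")


def _build_default_adducts(table: AtomicMassTable = DEFAULT_MASS_TABLE) -> dict[str, AdductSpec]:
    m = table.monoisotopic
    e = table.electron_mass

    def comp_mass(**c: int) -> float:
        return sum(m[el] * n for el, n in c.items())

    specs = [
        AdductSpec("[M.]+", -e, +1, "positive"),
        AdductSpec("[M+H]+", comp_mass(H=1) - e, +1, "positive"),
        AdductSpec("[M+K]+", comp_mass(K=1) - e, +1, "positive"),
        AdductSpec("[M+Na]+", comp_mass(Na=1) - e, +1, "positive"),
        AdductSpec("[M+Li]+", comp_mass(Li=1) - e, +1, "positive"),
        AdductSpec("[M+NH4]+", comp_mass(N=1, H=4) - e, +1, "positive"),
        AdductSpec("[M-H]-", -comp_mass(H=1) + e, -1, "negative"),
        AdductSpec("[M+Cl]-", comp_mass(Cl=1) + e, -1, "negative"),
        AdductSpec("[M+OAc]-", comp_mass(C=2, H=3, O=2) + e, -1, "negative"),
    ]
    return {s.label: s for s in specs}


#: The nine default adducts commonly reported for glycerolipid MS surveys.
ADDUCTS: Mapping[str, AdductSpec] = MappingProxyType(_build_default_adducts())

# Unicode minus / en-dash variants normalise to ASCII hyphen.
_LABEL_TRANSLATION = str.maketrans({"−": "-", "–": "-"})


def normalize_adduct_label(label: str) -> str:
    return label.translate(_LABEL_TRANSLATION).replace(" ", "")


def resolve_adduct(
    adduct: str | AdductSpec, registry: Mapping[str, AdductSpec] = ADDUCTS
) -> AdductSpec:
    if isinstance(adduct, AdductSpec):
        return adduct
    key = normalize_adduct_label(adduct)
    try:
        return registry[key]
    except KeyError:
        supported = ", ".join(registry)
        raise KeyError(f"unknown adduct {adduct!r}; supported adducts: {supported}") from None


def adduct_mz(
    neutral_mass: float,
    adduct: str | AdductSpec,
    registry: Mapping[str, AdductSpec] = ADDUCTS,
) -> float:
    """m/z of the single-molecule adduct ion: (M + delta) / |z|."""
    if neutral_mass <= 0:
        raise ValueError(f"neutral mass must be positive, got {neutral_mass}")
    spec = resolve_adduct(adduct, registry)
    return (neutral_mass + spec.mass_delta) / abs(spec.charge)


def load_adduct_registry(path: str) -> dict[str, AdductSpec]:
    """Read a user-extensible adduct registry from TSV (label, delta, charge, polarity)."""
    registry: dict[str, AdductSpec] = {}
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.lower().startswith("label\t"):
                continue
            label, delta, charge, polarity = line.split("\t")[:4]
            spec = AdductSpec(
                normalize_adduct_label(label), float(delta), int(charge), polarity.strip()
            )
            registry[spec.label] = spec
    if not registry:
        raise ValueError(f"adduct registry {path!r} contains no adducts")
    return registry


WATER = ElementalComposition(H=2, O=1)
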