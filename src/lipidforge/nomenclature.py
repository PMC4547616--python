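"""Shorthand abbreviations and systematic names.

The shorthand grammar follows the accepted lipidomics conventions:

* ``PC(O-36:5)`` — *Species*: one summed C:DB term; ``O-`` if any ether chain.
* ``PC(O-16:1_20:4)`` — *Molecular subspecies*: per-chain terms, underscore
  separated, sn positions unknown (canonical sorted order, ethers first).
* ``PC(P-16:0/20:4)`` — *Structural subspecies*: slash separated in sn order,
  double-bond positions unknown; empty (lyso) slots print ``0:0``.
* ``PC(P-16:0/20:4(5Z,8Z,11Z,14Z))`` — *Isomeric subspecies*: full positions
  and geometry.

``O-`` marks an alkyl ether bond, ``P-`` a 1Z-alkenyl (vinyl ether) bond; the
vinyl-ether double bond is not written in the chain's DB digit but counts one
toward molecular- and species-level double-bond sums (hence P-16:0 rolls up
through O-16:1 to an O- species with one extra double bond).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from enum import Enum
from typing import Optional, Sequence

from .assembly import IsomericSubspecies, SlotAssignment
from .building_blocks import ClassTemplate

__all__ = [
    "SubspeciesLevel",
    "ChainTerm",
    "Abbreviation",
    "abbreviate",
    "abbreviation_of",
    "parse_abbreviation",
    "ParseError",
    "systematic_name",
]


class SubspeciesLevel(str, Enum):
    SPECIES = "Species"
    MOLECULAR = "Molecular subspecies"
    STRUCTURAL = "Structural subspecies"
    ISOMERIC = "Isomeric subspecies"


@dataclass(frozen=True)
class ChainTerm:
    """One printed chain term: optional ether prefix, C:DB digits, optional positions.

    The empty (lyso) term is ``ChainTerm("", 0, 0)`` and prints ``0:0``.
    """

    prefix: str  # "" | "O-" | "P-"
    carbons: int
    double_bonds: int
    positions: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if self.prefix not in ("", "O-", "P-"):
            raise ValueError(f"prefix must be '', 'O-' or 'P-', got {self.prefix!r}")
        if self.positions and len(self.positions) != self.double_bonds:
            raise ValueError("positions count does not match double-bond count")

    @property
    def is_empty(self) -> bool:
        return self.carbons == 0

    @property
    def is_ether(self) -> bool:
        return self.prefix in ("O-", "P-")

    @property
    def db_total(self) -> int:
        """Double bonds counting the vinyl-ether bond of a P- chain."""
        return self.double_bonds + (1 if self.prefix == "P-" else 0)

    def render(self, with_positions: bool) -> str:
        s = f"{self.prefix}{self.carbons}:{self.double_bonds}"
        if with_positions and self.positions:
            s += "(" + ",".join(f"{p}{g}" for p, g in self.positions) + ")"
        return s

    @property
    def sort_key(self) -> tuple:
        # ethers first, then (C, DB) ascending, position vector as tie-break;
        # empty (0:0) terms sort last, matching the common lyso rendering.
        return (self.is_empty, not self.is_ether, self.carbons, self.double_bonds, self.positions)


@dataclass(frozen=True)
class Abbreviation:
    """A parsed or generated shorthand abbreviation."""

    class_abbrev: str
    level: SubspeciesLevel
    chain_terms: tuple[ChainTerm, ...]

    @property
    def sum_carbons(self) -> int:
        return sum(t.carbons for t in self.chain_terms)

    @property
    def sum_double_bonds(self) -> int:
        return sum(t.db_total for t in self.chain_terms)

    @property
    def has_ether(self) -> bool:
        return any(t.is_ether for t in self.chain_terms)


def abbreviate(abbr: Abbreviation) -> str:
    """Render *abbr* as its exact shorthand string."""
    level = abbr.level
    if level == SubspeciesLevel.SPECIES:
        if len(abbr.chain_terms) != 1:
            raise ValueError("species abbreviation must carry exactly one sum term")
        return f"{abbr.class_abbrev}({abbr.chain_terms[0].render(False)})"
    if level == SubspeciesLevel.MOLECULAR:
        terms = "_".join(t.render(False) for t in abbr.chain_terms)
        return f"{abbr.class_abbrev}({terms})"
    if level == SubspeciesLevel.STRUCTURAL:
        terms = "/".join(t.render(False) for t in abbr.chain_terms)
        return f"{abbr.class_abbrev}({terms})"
    if level == SubspeciesLevel.ISOMERIC:
        terms = "/".join(t.render(True) for t in abbr.chain_terms)
        return f"{abbr.class_abbrev}({terms})"
    raise ValueError(f"unknown level {level!r}")


def _terms_of_assignment(assignment: SlotAssignment) -> tuple[ChainTerm, ...]:
    terms = []
    for pos in assignment:
        fill = assignment[pos]
        if fill.is_empty:
            terms.append(ChainTerm("", 0, 0))
        else:
            chain, linkage = fill.chain, fill.linkage
            terms.append(
                ChainTerm(
                    linkage.abbreviation_prefix,
                    chain.carbons,
                    chain.double_bonds,
                    chain.db_positions,
                )
            )
    return tuple(terms)


def abbreviation_of(
    template: ClassTemplate,
    assignment: SlotAssignment,
    level: SubspeciesLevel = SubspeciesLevel.ISOMERIC,
) -> Abbreviation:
    """Abbreviation of one assignment at the requested level (rolling up as needed)."""
    from .hierarchy import parent_molecular, parent_species, parent_structural

    iso = Abbreviation(template.abbreviation, SubspeciesLevel.ISOMERIC, _terms_of_assignment(assignment))
    if level == SubspeciesLevel.ISOMERIC:
        return iso
    structural = parent_structural(iso)
    if level == SubspeciesLevel.STRUCTURAL:
        return structural
    molecular = parent_molecular(structural)
    if level == SubspeciesLevel.MOLECULAR:
        return molecular
    if level == SubspeciesLevel.SPECIES:
        return parent_species(molecular)
    raise ValueError(f"unknown level {level!r}")


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

class ParseError(ValueError):
    """Malformed shorthand string; carries the character offset of the fault."""

    def __init__(self, text: str, offset: int, message: str):
        super().__init__(f"{message} in {text!r} at offset {offset}")
        self.text = text
        self.offset = offset


_TERM_RE = re.compile(r"(?P<prefix>[OP]-)?(?P<c>\d+):(?P<db>\d+)(?P<pos>\([^()]*\))?")
_POSITION_RE = re.compile(r"(\d+)([ZE])")


def _parse_term(text: str, start: int, term: str) -> ChainTerm:
    m = _TERM_RE.fullmatch(term)
    if not m:
        # locate the first offending character for the offset report
        probe = _TERM_RE.match(term)
        bad = start + (probe.end() if probe else 0)
        raise ParseError(text, bad, f"malformed chain term {term!r}")
    positions: tuple[tuple[int, str], ...] = ()
    if m.group("pos"):
        inner = m.group("pos")[1:-1]
        toks = inner.split(",") if inner else []
        parsed = []
        for tok in toks:
            pm = _POSITION_RE.fullmatch(tok.strip())
            if not pm:
                raise ParseError(text, start + m.start("pos"), f"malformed position {tok!r}")
            parsed.append((int(pm.group(1)), pm.group(2)))
        positions = tuple(parsed)
    c, db = int(m.group("c")), int(m.group("db"))
    if positions and len(positions) != db:
        raise ParseError(text, start, f"{len(positions)} positions for {db} double bonds")
    return ChainTerm(m.group("prefix") or "", c, db, positions)


def _split_terms(text: str, inner: str, base: int, sep: str) -> list[tuple[int, str]]:
    out = []
    offset = 0
    for part in inner.split(sep):
        if part == "":
            raise ParseError(text, base + offset, f"empty chain term before {sep!r}")
        out.append((base + offset, part))
        offset += len(part) + 1
    return out


def parse_abbreviation(text: str) -> Abbreviation:
    """Parse a shorthand string; the level is inferred from separators and positions.

    A single sum term is a *Species*; ``_`` separators mark a *Molecular
    subspecies*; ``/`` separators a *Structural subspecies*, promoted to
    *Isomeric* when any chain carries double-bond positions.
    """
    stripped = text.strip()
    m = re.fullmatch(r"(?P<cls>[A-Za-z][A-Za-z0-9]*)\((?P<inner>.*)\)", stripped)
    if not m:
        raise ParseError(text, 0, "expected CLASS(...) shorthand")
    cls, inner = m.group("cls"), m.group("inner")
    base = m.start("inner")
    if inner == "":
        raise ParseError(text, base, "empty abbreviation body")
    if "_" in inner and "/" in inner:
        raise ParseError(text, base, "mixed '_' and '/' separators")
    # '/' may appear only outside position parentheses; split at depth 0
    if "_" in inner:
        sep, level = "_", SubspeciesLevel.MOLECULAR
        parts = _split_terms(text, inner, base, sep)
    elif "/" in inner:
        sep, level = "/", SubspeciesLevel.STRUCTURAL
        parts = _split_terms(text, inner, base, sep)
    else:
        sep, level = None, SubspeciesLevel.SPECIES
        parts = [(base, inner)]
    terms = tuple(_parse_term(text, off, part) for off, part in parts)
    if level == SubspeciesLevel.SPECIES and len(terms) != 1:
        raise ParseError(text, base, "species abbreviation must have one term")
    if level == SubspeciesLevel.STRUCTURAL and any(t.positions for t in terms):
        level = SubspeciesLevel.ISOMERIC
    if level == SubspeciesLevel.MOLECULAR and any(t.positions for t in terms):
        raise ParseError(text, base, "molecular-level terms cannot carry positions")
    if level == SubspeciesLevel.SPECIES and terms[0].positions:
        raise ParseError(text, base, "species-level sum term cannot carry positions")
    return Abbreviation(cls, level, terms)


# ---------------------------------------------------------------------------
# Systematic names
# ---------------------------------------------------------------------------

def _wrap(residue: str) -> str:
    """Residues that begin with a locant are parenthesised in assembled names."""
    return f"({residue})" if residue[0].isdigit() else residue


_GROUP_MULT = {2: "di", 3: "tri"}


def systematic_name(iso: IsomericSubspecies) -> str:
    """sn-position-ordered residue names joined to the backbone/headgroup name.

    ``PC(P-16:0/20:4(5Z,8Z,11Z,14Z))`` renders
    ``1-O-(1Z-hexadecenyl)-2-(5Z,8Z,11Z,14Z-eicosatetraenoyl)-sn-glycero-3-phosphocholine``;
    identical residues on adjacent positions condense
    (``1,2-dihexadecanoyl-…``); empty (lyso) positions are omitted.
    """
    pieces: list[tuple[tuple[int, ...], str, str]] = []  # (positions, ether_locant, residue)
    for pos, chain, linkage in iso.assignment.filled():
        if linkage.label == "ester":
            residue = chain.systematic_residue_name
            ether = ""
        elif linkage.label == "alkyl":
            residue = chain.systematic_residue_name
            ether = "O-"
        elif linkage.label == "alkenyl":
            from .building_blocks import alkyl_residue_name

            residue = alkyl_residue_name(chain.carbons, ((1, "Z"), *chain.db_positions))
            ether = "O-"
        else:  # pragma: no cover - linkage registry is closed
            raise ValueError(f"unknown linkage {linkage.label!r}")
        if not residue:
            raise ValueError(f"chain at sn-{pos} has no residue name")
        pieces.append(((pos,), ether, residue))

    # condense runs of identical residue/linkage across positions
    grouped: list[tuple[list[int], str, str]] = []
    for (pos,), ether, residue in pieces:
        if grouped and grouped[-1][1] == ether and grouped[-1][2] == residue:
            grouped[-1][0].append(pos)
        else:
            grouped.append(([pos], ether, residue))

    parts = []
    for positions, ether, residue in grouped:
        locants = ",".join(str(p) for p in positions)
        n = len(positions)
        if n == 1:
            parts.append(f"{locants}-{ether}{_wrap(residue)}")
        else:
            mult = _GROUP_MULT[n]
            if residue[0].isdigit():
                parts.append(f"{locants}-{ether}{mult}-({residue})")
            else:
                parts.append(f"{locants}-{ether}{mult}{residue}")
    if not parts:
        return iso.template.systematic_suffix
    return "-".join(parts) + "-" + iso.template.systematic_suffix
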