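"""Combinatorial assembly of isomeric subspecies.

Structures are produced by substituting chain fragments into a backbone
SMILES at numbered slots — an ester slot receives ``OC(=O)…``, an alkyl
ether slot ``OC…``, an alkenyl (vinyl-ether) slot ``O/C=C\\…`` with the
obligatory 1Z double bond, and an empty slot a free hydroxyl.  Elemental
composition is tracked arithmetically in parallel (each condensation
releases one water; an alkenyl chain loses a further H2 relative to its
parent alcohol), so the assembled string and the bookkept formula can be
checked against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Mapping, Optional, Sequence

from .chem_core import WATER, ElementalComposition, formula_of
from .building_blocks import (
    ALKENYL,
    ChainDescriptor,
    ClassTemplate,
    Linkage,
    SlotSpec,
    chain_composition,
)

__all__ = [
    "SlotFill",
    "SlotAssignment",
    "IsomericSubspecies",
    "lipid_composition",
    "assemble_structure",
    "chain_fragment",
    "enumerate_isomeric",
]

_H2 = ElementalComposition(H=2)


@dataclass(frozen=True)
class SlotFill:
    """Occupant of one slot: a chain bound through a linkage, or empty (None/None)."""

    chain: Optional[ChainDescriptor]
    linkage: Optional[Linkage]

    def __post_init__(self) -> None:
        if (self.chain is None) != (self.linkage is None):
            raise ValueError("chain and linkage must both be set or both be None")

    @property
    def is_empty(self) -> bool:
        return self.chain is None

    @property
    def key(self) -> tuple:
        if self.is_empty:
            return ("",)
        assert self.chain is not None and self.linkage is not None
        return (self.linkage.abbreviation_prefix, *self.chain.key)


EMPTY_FILL = SlotFill(None, None)


class SlotAssignment(Mapping[int, SlotFill]):
    """Validated slot -> SlotFill map for one template."""

    def __init__(self, template: ClassTemplate, fills: Mapping[int, SlotFill]):
        self.template = template
        slot_by_pos = {s.sn_position: s for s in template.slots}
        if set(fills) != set(slot_by_pos):
            raise ValueError(
                f"assignment slots {sorted(fills)} do not match template slots {sorted(slot_by_pos)}"
            )
        for pos, fill in fills.items():
            slot = slot_by_pos[pos]
            if fill.is_empty:
                if not slot.may_be_empty:
                    raise ValueError(f"slot sn-{pos} of {template.abbreviation} may not be empty")
                continue
            assert fill.chain is not None and fill.linkage is not None
            if fill.linkage not in slot.allowed_linkages:
                raise ValueError(
                    f"linkage {fill.linkage.label!r} not allowed on slot sn-{pos} "
                    f"of {template.subclass_name}"
                )
            if fill.chain.kind != fill.linkage.chain_kind_required:
                raise ValueError(
                    f"slot sn-{pos}: linkage {fill.linkage.label!r} requires a "
                    f"{fill.linkage.chain_kind_required}, got {fill.chain.kind}"
                )
        self._fills = dict(sorted(fills.items()))

    def __getitem__(self, pos: int) -> SlotFill:
        return self._fills[pos]

    def __iter__(self):
        return iter(self._fills)

    def __len__(self) -> int:
        return len(self._fills)

    @property
    def key(self) -> tuple:
        return tuple((pos, fill.key) for pos, fill in self._fills.items())

    def filled(self) -> list[tuple[int, ChainDescriptor, Linkage]]:
        return [
            (pos, f.chain, f.linkage)
            for pos, f in self._fills.items()
            if not f.is_empty
        ]


def lipid_composition(template: ClassTemplate, assignment: SlotAssignment) -> ElementalComposition:
    """Backbone + chains − one water per filled slot (− H2 per alkenyl linkage)."""
    comp = template.backbone_composition
    for _pos, chain, linkage in assignment.filled():
        comp = comp + chain_composition(chain) - WATER
        if linkage is ALKENYL or linkage.label == "alkenyl":
            comp = comp - _H2
    return comp


# ---------------------------------------------------------------------------
# SMILES fragment construction
# ---------------------------------------------------------------------------

def _chain_body(
    n: int,
    dbs: Mapping[int, str],
    first_atom: str,
) -> tuple[str, str]:
    """Linear chain SMILES for carbons 1..n.

    Returns (incoming_bond_marker, body).  ``dbs`` maps position p (double
    bond between carbons p and p+1) to geometry; cis/trans is encoded with
    the usual /C=C\\ markers on the flanking single bonds, which exist for
    every allowed position except a terminal double bond (geometry is then
    meaningless and the markers are omitted).
    """
    for p in dbs:
        if p + 1 in dbs or p - 1 in dbs:
            raise ValueError("conjugated double bonds are not supported")
    # bond i sits between carbon i and i+1; bond 0 is the incoming bond.
    bond_sym = {i: "" for i in range(0, n)}
    for p, geom in dbs.items():
        bond_sym[p] = "="
        if p + 1 <= n - 1:  # geometry markers need the following bond
            bond_sym[p - 1] = "/"
            bond_sym[p + 1] = "\\" if geom == "Z" else "/"
    body = first_atom
    for i in range(2, n + 1):
        body += bond_sym[i - 1] + "C"
    return bond_sym[0], body


def chain_fragment(chain: ChainDescriptor, linkage: Linkage) -> str:
    """SMILES fragment (starting at the slot oxygen) for a chain bound via *linkage*."""
    dbs = dict(chain.db_positions)
    if linkage.label == "ester":
        marker, body = _chain_body(chain.carbons, dbs, "C(=O)")
        assert marker == ""
        return "O" + body
    if linkage.label == "alkyl":
        marker, body = _chain_body(chain.carbons, dbs, "C")
        assert marker == ""
        return "O" + body
    if linkage.label == "alkenyl":
        if 2 in dbs:
            raise ValueError("alkenyl linkage conjugates with a position-2 double bond")
        dbs = {1: "Z", **dbs}
        marker, body = _chain_body(chain.carbons, dbs, "C")
        return "O" + marker + body
    raise ValueError(f"unknown linkage {linkage.label!r}")


def assemble_structure(template: ClassTemplate, assignment: SlotAssignment) -> str:
    """Substitute every numbered placeholder of the backbone with its slot fragment."""
    smiles = template.backbone_fragment
    for pos in assignment:
        fill = assignment[pos]
        fragment = "O" if fill.is_empty else chain_fragment(fill.chain, fill.linkage)
        placeholder = "{%d}" % pos
        if placeholder not in smiles:
            raise ValueError(
                f"backbone of {template.subclass_name!r} lacks placeholder {placeholder}"
            )
        smiles = smiles.replace(placeholder, fragment)
    if "{" in smiles:
        raise ValueError(f"unreplaced placeholder remains in {smiles!r}")
    return smiles


@dataclass(frozen=True)
class IsomericSubspecies:
    """A fully specified structure: class template + per-slot chains with positions."""

    template: ClassTemplate
    assignment: SlotAssignment
    structure_string: str
    composition: ElementalComposition
    inchikey: Optional[str] = None

    @property
    def formula(self) -> str:
        return formula_of(self.composition)

    @property
    def key(self) -> tuple:
        return (self.template.key, self.assignment.key)


def make_isomeric(template: ClassTemplate, assignment: SlotAssignment) -> IsomericSubspecies:
    return IsomericSubspecies(
        template=template,
        assignment=assignment,
        structure_string=assemble_structure(template, assignment),
        composition=lipid_composition(template, assignment),
    )


def _eligible_fills(slot: SlotSpec, chains: Sequence[ChainDescriptor]) -> list[SlotFill]:
    fills: list[SlotFill] = []
    # fixed linkage order (ester, alkyl, alkenyl follow template declaration),
    # chains in canonical key order: output order is deterministic.
    for linkage in slot.allowed_linkages:
        for chain in sorted(chains, key=lambda c: c.key):
            if chain.kind == linkage.chain_kind_required:
                fills.append(SlotFill(chain, linkage))
    if slot.may_be_empty:
        fills.append(EMPTY_FILL)
    return fills


def enumerate_isomeric(
    template: ClassTemplate,
    chains: Sequence[ChainDescriptor],
    warn: Optional[list] = None,
) -> list[IsomericSubspecies]:
    """Cartesian product over slots of (eligible chain x allowed linkage).

    Only the listed chains are used — no hypothetical double-bond-position
    enumeration.  Two outputs are duplicates iff they share the template and
    every per-slot (chain, linkage) pair; the product over distinct chains
    cannot repeat, so deduplication is a safety net for duplicated input
    chains.  Returns [] (with a warning) if a mandatory slot has no eligible
    chain.
    """
    if not chains:
        raise ValueError("chain list is empty")
    per_slot: list[list[SlotFill]] = []
    for slot in template.slots:
        fills = _eligible_fills(slot, chains)
        if not fills:
            if warn is not None:
                warn.append(
                    f"{template.subclass_name}: no eligible chain for mandatory slot "
                    f"sn-{slot.sn_position}; class skipped"
                )
            return []
        per_slot.append(fills)
    seen: set[tuple] = set()
    out: list[IsomericSubspecies] = []
    for combo in product(*per_slot):
        assignment = SlotAssignment(
            template, {s.sn_position: f for s, f in zip(template.slots, combo)}
        )
        if assignment.key in seen:
            continue
        seen.add(assignment.key)
        out.append(make_isomeric(template, assignment))
    out.sort(key=lambda iso: iso.key)
    return out
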