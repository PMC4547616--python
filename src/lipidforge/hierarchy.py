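"""The seven-level analytical hierarchy.

Category > Class > Subclass > Species > Molecular subspecies > Structural
subspecies > Isomeric subspecies.  The bottom four levels are pure functions
of the printed shorthand: the structural parent of an isomeric subspecies
drops double-bond positions; the molecular parent discards sn positions and
rewrites every vinyl-ether chain ``P-n:d`` as ``O-n:(d+1)`` (the vinyl-ether
double bond becomes indistinguishable from a chain double bond once the
linkage position is unknown); the species parent sums carbons and double
bonds, keeping a single ``O-`` flag when any chain is ether-linked.

Nodes are deduplicated on (level, canonical abbreviation or name), so e.g.
``PC(P-16:0/20:4)`` and ``PC(O-16:1/20:4)`` share the molecular parent
``PC(O-16:1_20:4)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import networkx as nx

from .chem_core import ElementalComposition
from .assembly import IsomericSubspecies
from .nomenclature import (
    Abbreviation,
    ChainTerm,
    SubspeciesLevel,
    abbreviate,
    abbreviation_of,
    systematic_name,
)

__all__ = [
    "HierarchyLevel",
    "Hierarchy",
    "parent_structural",
    "parent_molecular",
    "parent_species",
    "build_hierarchy",
    "level_counts",
]


class HierarchyLevel(IntEnum):
    """Total order over the seven levels, most general first."""

    CATEGORY = 0
    CLASS = 1
    SUBCLASS = 2
    SPECIES = 3
    MOLECULAR_SUBSPECIES = 4
    STRUCTURAL_SUBSPECIES = 5
    ISOMERIC_SUBSPECIES = 6

    @property
    def display(self) -> str:
        return _DISPLAY[self]


_DISPLAY = {
    HierarchyLevel.CATEGORY: "Category",
    HierarchyLevel.CLASS: "Class",
    HierarchyLevel.SUBCLASS: "Subclass",
    HierarchyLevel.SPECIES: "Species",
    HierarchyLevel.MOLECULAR_SUBSPECIES: "Molecular subspecies",
    HierarchyLevel.STRUCTURAL_SUBSPECIES: "Structural subspecies",
    HierarchyLevel.ISOMERIC_SUBSPECIES: "Isomeric subspecies",
}

_SUBLEVEL = {
    SubspeciesLevel.SPECIES: HierarchyLevel.SPECIES,
    SubspeciesLevel.MOLECULAR: HierarchyLevel.MOLECULAR_SUBSPECIES,
    SubspeciesLevel.STRUCTURAL: HierarchyLevel.STRUCTURAL_SUBSPECIES,
    SubspeciesLevel.ISOMERIC: HierarchyLevel.ISOMERIC_SUBSPECIES,
}


# ---------------------------------------------------------------------------
# Rollups (pure functions on abbreviations)
# ---------------------------------------------------------------------------

def parent_structural(iso: Abbreviation) -> Abbreviation:
    """Drop double-bond positions/geometry; keep prefixes and sn assignment."""
    terms = tuple(replace(t, positions=()) for t in iso.chain_terms)
    return Abbreviation(iso.class_abbrev, SubspeciesLevel.STRUCTURAL, terms)


def parent_molecular(structural: Abbreviation) -> Abbreviation:
    """Discard sn positions (canonical sort); rewrite P-n:d as O-n:(d+1)."""
    terms = []
    for t in structural.chain_terms:
        if t.is_empty:
            continue  # unknown sn positions: a lyso 0:0 slot carries no information
        if t.prefix == "P-":
            t = ChainTerm("O-", t.carbons, t.double_bonds + 1)
        else:
            t = ChainTerm(t.prefix, t.carbons, t.double_bonds)
        terms.append(t)
    terms.sort(key=lambda t: t.sort_key)
    return Abbreviation(structural.class_abbrev, SubspeciesLevel.MOLECULAR, tuple(terms))


def parent_species(molecular: Abbreviation) -> Abbreviation:
    """Sum carbons and double bonds; keep an O- flag iff any ether chain."""
    prefix = "O-" if molecular.has_ether else ""
    term = ChainTerm(prefix, molecular.sum_carbons, molecular.sum_double_bonds)
    return Abbreviation(molecular.class_abbrev, SubspeciesLevel.SPECIES, (term,))


# ---------------------------------------------------------------------------
# Hierarchy container
# ---------------------------------------------------------------------------

NodeKey = tuple[HierarchyLevel, str]


@dataclass
class Hierarchy:
    """Deduplicated multi-level DAG; every edge spans one level step downward."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    def add_node(
        self,
        level: HierarchyLevel,
        name: str,
        **attrs,
    ) -> NodeKey:
        key = (level, name)
        if key in self.graph:
            node = self.graph.nodes[key]
            comp = attrs.get("composition")
            if comp is not None and node.get("composition") not in (None, comp):
                # merged nodes with conflicting formulas lose the annotation
                node["composition"] = None
            for k, v in attrs.items():
                if k != "composition":
                    node.setdefault(k, v)
        else:
            self.graph.add_node(key, level=level, name=name, **attrs)
        return key

    def add_edge(self, parent: NodeKey, child: NodeKey) -> None:
        if child[0] - parent[0] != 1:
            raise ValueError(f"edge {parent} -> {child} does not span one level step")
        self.graph.add_edge(parent, child)

    def nodes_at(self, level: HierarchyLevel) -> list[NodeKey]:
        return sorted(k for k in self.graph.nodes if k[0] == level)

    def parents(self, key: NodeKey) -> list[NodeKey]:
        return sorted(self.graph.predecessors(key))

    def children(self, key: NodeKey) -> list[NodeKey]:
        return sorted(self.graph.successors(key))

    def __contains__(self, key: NodeKey) -> bool:
        return key in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def _abbrev_chain(iso: IsomericSubspecies) -> dict[SubspeciesLevel, Abbreviation]:
    isomeric = abbreviation_of(iso.template, iso.assignment, SubspeciesLevel.ISOMERIC)
    structural = parent_structural(isomeric)
    molecular = parent_molecular(structural)
    species = parent_species(molecular)
    return {
        SubspeciesLevel.ISOMERIC: isomeric,
        SubspeciesLevel.STRUCTURAL: structural,
        SubspeciesLevel.MOLECULAR: molecular,
        SubspeciesLevel.SPECIES: species,
    }


def build_hierarchy(isos: Iterable[IsomericSubspecies]) -> Hierarchy:
    """Construct the deduplicated seven-level DAG from enumerated structures.

    Class, subclass and category nodes come from each structure's template
    metadata; species-and-below nodes are keyed by canonical abbreviation and
    carry the shared elemental composition (dropped if merged nodes disagree).
    """
    h = Hierarchy()
    for iso in isos:
        t = iso.template
        cat = h.add_node(HierarchyLevel.CATEGORY, t.category)
        cls = h.add_node(HierarchyLevel.CLASS, t.class_name)
        sub = h.add_node(HierarchyLevel.SUBCLASS, t.subclass_name, abbreviation=t.abbreviation)
        h.add_edge(cat, cls)
        h.add_edge(cls, sub)
        abbrevs = _abbrev_chain(iso)
        keys: dict[SubspeciesLevel, NodeKey] = {}
        for sublevel, abbr in abbrevs.items():
            attrs = {"abbreviation": abbreviate(abbr), "composition": iso.composition}
            if sublevel == SubspeciesLevel.ISOMERIC:
                attrs["structure_string"] = iso.structure_string
                attrs["systematic_name"] = systematic_name(iso)
                if iso.inchikey:
                    attrs["inchikey"] = iso.inchikey
            keys[sublevel] = h.add_node(_SUBLEVEL[sublevel], abbreviate(abbr), **attrs)
        h.add_edge(sub, keys[SubspeciesLevel.SPECIES])
        h.add_edge(keys[SubspeciesLevel.SPECIES], keys[SubspeciesLevel.MOLECULAR])
        h.add_edge(keys[SubspeciesLevel.MOLECULAR], keys[SubspeciesLevel.STRUCTURAL])
        h.add_edge(keys[SubspeciesLevel.STRUCTURAL], keys[SubspeciesLevel.ISOMERIC])
    return h


def level_counts(h: Hierarchy) -> dict[HierarchyLevel, int]:
    counts = {level: 0 for level in HierarchyLevel}
    for level, _name in h.graph.nodes:
        counts[level] += 1
    return counts
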