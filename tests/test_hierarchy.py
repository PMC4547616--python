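"""Rollups and the seven-level DAG, checked against a set-based brute-force oracle."""

import pytest

from lipidforge.assembly import enumerate_isomeric
from lipidforge.building_blocks import fixture_library
from lipidforge.hierarchy import (
    Hierarchy,
    HierarchyLevel,
    build_hierarchy,
    level_counts,
    parent_molecular,
    parent_species,
    parent_structural,
)
from lipidforge.nomenclature import SubspeciesLevel, abbreviate, parse_abbreviation


def oracle_level_sets(isos):
    """Independent exhaustive rollup with set-based dedup, working on strings.

    Re-derives each parent string from the per-slot chain digits without using
    the Abbreviation rollup functions.
    """
    structural, molecular, species = set(), set(), set()
    for iso in isos:
        cls = iso.template.abbreviation
        terms = []  # (prefix, C, DB) in sn order, empty slots as (None)
        for pos in iso.assignment:
            fill = iso.assignment[pos]
            if fill.is_empty:
                terms.append(None)
            else:
                terms.append(
                    (fill.linkage.abbreviation_prefix, fill.chain.carbons, fill.chain.double_bonds)
                )
        structural.add(
            cls + "(" + "/".join("0:0" if t is None else f"{t[0]}{t[1]}:{t[2]}" for t in terms) + ")"
        )
        mol_terms = []
        for t in terms:
            if t is None:
                continue
            prefix, c, d = t
            if prefix == "P-":
                prefix, d = "O-", d + 1
            mol_terms.append((prefix, c, d))
        mol_terms.sort(key=lambda t: (t[0] == "", t[1], t[2]))
        molecular.add(cls + "(" + "_".join(f"{p}{c}:{d}" for p, c, d in mol_terms) + ")")
        sum_c = sum(c for _p, c, _d in mol_terms)
        sum_d = sum(d for _p, _c, d in mol_terms)
        ether = "O-" if any(p == "O-" for p, _c, _d in mol_terms) else ""
        species.add(f"{cls}({ether}{sum_c}:{sum_d})")
    return structural, molecular, species


class TestRollups:
    @pytest.mark.parametrize(
        "child, parent",
        [
            ("PC(P-16:0/20:4(5Z,8Z,11Z,14Z))", "PC(P-16:0/20:4)"),
            ("PC(16:0/18:0)", "PC(16:0/18:0)"),  # fixed point: nothing to drop
            ("PC(16:0/18:1(9Z))", "PC(16:0/18:1)"),
        ],
    )
    def test_parent_structural(self, child, parent):
        assert abbreviate(parent_structural(parse_abbreviation(child))) == parent

    @pytest.mark.parametrize(
        "child, parent",
        [
            ("PC(P-16:0/20:4)", "PC(O-16:1_20:4)"),
            ("PC(18:1/16:0)", "PC(16:0_18:1)"),
            ("PC(O-16:1/20:4)", "PC(O-16:1_20:4)"),  # collides with the plasmalogen's parent
        ],
    )
    def test_parent_molecular(self, child, parent):
        assert abbreviate(parent_molecular(parse_abbreviation(child))) == parent

    @pytest.mark.parametrize(
        "child, parent",
        [
            ("PC(O-16:1_20:4)", "PC(O-36:5)"),
            ("PC(16:0_18:1)", "PC(34:1)"),
            ("LPC(16:0)", "LPC(16:0)"),  # single-chain sums trivially
        ],
    )
    def test_parent_species(self, child, parent):
        abbr = parse_abbreviation(child)
        if abbr.level == SubspeciesLevel.SPECIES:  # lyso single-term shorthand
            from lipidforge.nomenclature import Abbreviation

            abbr = Abbreviation(abbr.class_abbrev, SubspeciesLevel.MOLECULAR, abbr.chain_terms)
        assert abbreviate(parent_species(abbr)) == parent

    def test_rollups_idempotent(self):
        iso = parse_abbreviation("PC(P-16:0/20:4(5Z,8Z,11Z,14Z))")
        s1 = parent_structural(iso)
        assert parent_structural(s1).chain_terms == s1.chain_terms
        m1 = parent_molecular(s1)
        assert parent_molecular(m1).chain_terms == m1.chain_terms


class TestBuildHierarchy:
    def test_table1_chain_has_one_node_per_level(self, plasmalogen_pc):
        h = build_hierarchy([plasmalogen_pc])
        counts = level_counts(h)
        assert all(counts[level] == 1 for level in HierarchyLevel)
        names = {level: h.nodes_at(level)[0][1] for level in HierarchyLevel}
        assert names[HierarchyLevel.CATEGORY] == "Glycerophospholipid"
        assert names[HierarchyLevel.CLASS] == "Glycerophosphocholine"
        assert names[HierarchyLevel.SUBCLASS] == "Monoalkylmonoacylglycerophosphocholine"
        assert names[HierarchyLevel.SPECIES] == "PC(O-36:5)"
        assert names[HierarchyLevel.MOLECULAR_SUBSPECIES] == "PC(O-16:1_20:4)"
        assert names[HierarchyLevel.STRUCTURAL_SUBSPECIES] == "PC(P-16:0/20:4)"
        assert names[HierarchyLevel.ISOMERIC_SUBSPECIES] == "PC(P-16:0/20:4(5Z,8Z,11Z,14Z))"

    def test_empty_input(self):
        h = build_hierarchy([])
        assert len(h) == 0

    def test_three_acid_diacyl_counts(self, diacyl_pc):
        chains, _ = fixture_library(12, 0, 0)
        acids = [c for c in chains if c.double_bonds in (0, 1)][:3]
        isos = enumerate_isomeric(diacyl_pc, acids)
        h = build_hierarchy(isos)
        counts = level_counts(h)
        assert counts[HierarchyLevel.ISOMERIC_SUBSPECIES] == 9
        assert counts[HierarchyLevel.STRUCTURAL_SUBSPECIES] == 9
        assert counts[HierarchyLevel.MOLECULAR_SUBSPECIES] == 6  # unordered pairs
        distinct_sums = {
            (a.carbons + b.carbons, a.double_bonds + b.double_bonds)
            for a in acids
            for b in acids
        }
        assert counts[HierarchyLevel.SPECIES] == len(distinct_sums)

    @pytest.mark.parametrize("n_acids,n_alcohols,seed", [(4, 2, 7), (6, 3, 0), (9, 1, 5)])
    def test_counts_match_oracle(self, n_acids, n_alcohols, seed):
        chains, templates = fixture_library(n_acids, n_alcohols, seed)
        isos = []
        for t in templates:
            isos.extend(enumerate_isomeric(t, chains))
        h = build_hierarchy(isos)
        counts = level_counts(h)
        structural, molecular, species = oracle_level_sets(isos)
        assert counts[HierarchyLevel.ISOMERIC_SUBSPECIES] == len({i.key for i in isos})
        assert counts[HierarchyLevel.STRUCTURAL_SUBSPECIES] == len(structural)
        assert counts[HierarchyLevel.MOLECULAR_SUBSPECIES] == len(molecular)
        assert counts[HierarchyLevel.SPECIES] == len(species)

    def test_count_monotonicity_and_unique_parents(self):
        chains, templates = fixture_library(8, 3, 1)
        isos = []
        for t in templates:
            isos.extend(enumerate_isomeric(t, chains))
        h = build_hierarchy(isos)
        counts = level_counts(h)
        assert (
            counts[HierarchyLevel.ISOMERIC_SUBSPECIES]
            >= counts[HierarchyLevel.STRUCTURAL_SUBSPECIES]
            >= counts[HierarchyLevel.MOLECULAR_SUBSPECIES]
            >= counts[HierarchyLevel.SPECIES]
        )
        for level in (
            HierarchyLevel.ISOMERIC_SUBSPECIES,
            HierarchyLevel.STRUCTURAL_SUBSPECIES,
            HierarchyLevel.MOLECULAR_SUBSPECIES,
        ):
            for key in h.nodes_at(level):
                assert len(h.parents(key)) == 1, key

    def test_acyclic_single_level_steps(self):
        import networkx as nx

        chains, templates = fixture_library(5, 2, 2)
        isos = []
        for t in templates:
            isos.extend(enumerate_isomeric(t, chains))
        h = build_hierarchy(isos)
        assert nx.is_directed_acyclic_graph(h.graph)
        for parent, child in h.graph.edges:
            assert child[0] - parent[0] == 1

    def test_species_descendants_share_composition(self):
        chains, templates = fixture_library(8, 4, 1)
        isos = []
        for t in templates:
            isos.extend(enumerate_isomeric(t, chains))
        h = build_hierarchy(isos)
        import networkx as nx

        for key in h.nodes_at(HierarchyLevel.SPECIES):
            comps = {
                h.graph.nodes[d]["composition"]
                for d in nx.descendants(h.graph, key)
                if d[0] == HierarchyLevel.ISOMERIC_SUBSPECIES
            }
            assert len(comps) == 1, key
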