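"""End-to-end library generation.

Loads chain and class building blocks, enumerates every isomeric subspecies,
builds the seven-level hierarchy, annotates each node (names, formula,
monoisotopic/average mass, the nine adduct m/z values, stable identifiers)
and exports flat node/edge tables plus an SDF of the structures.  Outputs
are deterministic and byte-identical for identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .chem_core import (
    ADDUCTS,
    AdductSpec,
    ElementalComposition,
    adduct_mz,
    average_mass,
    formula_of,
    load_adduct_registry,
    monoisotopic_mass,
)
from .building_blocks import (
    ChainDescriptor,
    ClassTemplate,
    load_chain_library,
    load_templates,
)
from .assembly import IsomericSubspecies, enumerate_isomeric
from .hierarchy import Hierarchy, HierarchyLevel, build_hierarchy, level_counts

__all__ = [
    "LipidRecord",
    "build_library",
    "records_from_hierarchy",
    "assign_ids",
    "generate_library",
    "export_sdf",
]

logger = logging.getLogger(__name__)

ID_PREFIX = "SLF"
_ID_DIGEST_BYTES = 5  # 10 hex characters


@dataclass
class LipidRecord:
    """One node of the generated library at one hierarchy level.

    Species-and-below records carry composition, masses and the nine adduct
    m/z values; only isomeric records carry a structure string.  ``ch``
    (cheminformatics descriptors) and ``cl`` (classified) flags are always
    present on generated records; ``lo`` and ``me`` are added by curated
    occurrence/metabolism annotations.
    """

    id: str
    level: HierarchyLevel
    name: str
    abbreviation: str = ""
    systematic_name: str = ""
    synonyms: tuple[str, ...] = ()
    composition: Optional[ElementalComposition] = None
    monoisotopic_mass: Optional[float] = None
    average_mass: Optional[float] = None
    adduct_mz: dict[str, float] = field(default_factory=dict)
    structure_string: str = ""
    inchikey: str = ""
    parent_ids: tuple[str, ...] = ()
    info_flags: frozenset[str] = frozenset({"ch", "cl"})

    @property
    def formula(self) -> str:
        return formula_of(self.composition) if self.composition is not None else ""


def _node_id(level: HierarchyLevel, name: str) -> str:
    digest = hashlib.blake2b(
        f"{level.name}|{name}".encode("utf-8"), digest_size=_ID_DIGEST_BYTES
    ).hexdigest()
    return f"{ID_PREFIX}{digest.upper()}"


def assign_ids(keys: Iterable[tuple[HierarchyLevel, str]]) -> dict[tuple[HierarchyLevel, str], str]:
    """Deterministic, order-independent ids; aborts on a (vanishingly rare) collision."""
    ids: dict[tuple[HierarchyLevel, str], str] = {}
    seen: dict[str, tuple[HierarchyLevel, str]] = {}
    for key in keys:
        ident = _node_id(*key)
        if ident in seen and seen[ident] != key:
            raise RuntimeError(f"id collision between {seen[ident]} and {key}")
        seen[ident] = key
        ids[key] = ident
    return ids


def records_from_hierarchy(
    h: Hierarchy,
    adduct_registry: Mapping[str, AdductSpec] = ADDUCTS,
) -> list[LipidRecord]:
    """Annotated records for every hierarchy node, in deterministic (level, name) order."""
    keys = sorted(h.graph.nodes)
    ids = assign_ids(keys)
    records = []
    for key in keys:
        level, name = key
        attrs = h.graph.nodes[key]
        comp = attrs.get("composition")
        rec = LipidRecord(
            id=ids[key],
            level=level,
            name=name,
            abbreviation=attrs.get("abbreviation", ""),
            systematic_name=attrs.get("systematic_name", ""),
            structure_string=attrs.get("structure_string", ""),
            inchikey=attrs.get("inchikey", ""),
            parent_ids=tuple(sorted(ids[p] for p in h.parents(key))),
        )
        if comp is not None and level >= HierarchyLevel.SPECIES:
            rec.composition = comp
            rec.monoisotopic_mass = monoisotopic_mass(comp)
            rec.average_mass = average_mass(comp)
            rec.adduct_mz = {
                label: adduct_mz(rec.monoisotopic_mass, spec)
                for label, spec in adduct_registry.items()
            }
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def build_library(
    chains: Sequence[ChainDescriptor],
    templates: Sequence[ClassTemplate],
    adduct_registry: Mapping[str, AdductSpec] = ADDUCTS,
) -> tuple[list[IsomericSubspecies], Hierarchy, list[LipidRecord], list[str]]:
    """Enumerate all templates, build the hierarchy and annotate records."""
    if not templates:
        raise ValueError("template list is empty")
    warnings: list[str] = []
    isos: list[IsomericSubspecies] = []
    for template in sorted(templates, key=lambda t: t.key):
        isos.extend(enumerate_isomeric(template, chains, warn=warnings))
    h = build_hierarchy(isos)
    records = records_from_hierarchy(h, adduct_registry)
    return isos, h, records, warnings


_MZ_COLUMNS = list(ADDUCTS)


def _write_tables(
    out_dir: Path,
    h: Hierarchy,
    records: list[LipidRecord],
    adduct_labels: Sequence[str],
) -> None:
    def fmt(x: Optional[float]) -> str:
        return "" if x is None else f"{x:.6f}"

    node_header = [
        "id", "level", "name", "abbreviation", "systematic_name", "formula",
        "monoisotopic_mass", "average_mass",
        *[f"mz{label}" for label in adduct_labels],
        "structure_string", "inchikey", "parent_ids", "info_flags",
    ]
    lines = ["\t".join(node_header)]
    for rec in records:
        lines.append(
            "\t".join(
                [
                    rec.id,
                    rec.level.display,
                    rec.name,
                    rec.abbreviation,
                    rec.systematic_name,
                    rec.formula,
                    fmt(rec.monoisotopic_mass),
                    fmt(rec.average_mass),
                    *[fmt(rec.adduct_mz.get(label)) for label in adduct_labels],
                    rec.structure_string,
                    rec.inchikey,
                    ",".join(rec.parent_ids),
                    ",".join(sorted(rec.info_flags)),
                ]
            )
        )
    (out_dir / "nodes.tsv").write_text("\n".join(lines) + "\n", encoding="utf-8")

    ids = {key: rec.id for key, rec in zip(sorted(h.graph.nodes), records)}
    edge_lines = ["\t".join(["child_id", "parent_id", "child_level", "parent_level"])]
    for parent, child in sorted(h.graph.edges):
        edge_lines.append(
            "\t".join([ids[child], ids[parent], child[0].display, parent[0].display])
        )
    (out_dir / "edges.tsv").write_text("\n".join(edge_lines) + "\n", encoding="utf-8")

    counts = level_counts(h)
    count_lines = ["level\tcount"]
    for level in HierarchyLevel:
        count_lines.append(f"{level.display}\t{counts[level]}")
    (out_dir / "counts.tsv").write_text("\n".join(count_lines) + "\n", encoding="utf-8")


def generate_library(
    chains_path: str | Path,
    templates_path: str | Path,
    out_dir: str | Path,
    adduct_config: Optional[str | Path] = None,
    write_sdf: bool = True,
) -> dict:
    """Run the full pipeline from input files and write nodes/edges/counts (+ SDF).

    Returns a summary dict with per-level and per-subclass counts and any
    validation diagnostics (also written to ``diagnostics.txt``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chains, diagnostics = load_chain_library(chains_path)
    templates = load_templates(templates_path)
    registry = load_adduct_registry(adduct_config) if adduct_config else dict(ADDUCTS)

    isos, h, records, warnings = build_library(chains, templates, registry)
    _write_tables(out, h, records, list(registry))
    if write_sdf:
        iso_records = [r for r in records if r.level == HierarchyLevel.ISOMERIC_SUBSPECIES]
        export_sdf(iso_records, out / "structures.sdf")

    counts = level_counts(h)
    per_class: dict[str, int] = {}
    for iso in isos:
        per_class[iso.template.subclass_name] = per_class.get(iso.template.subclass_name, 0) + 1
    diag_lines = [str(d) for d in diagnostics] + warnings
    (out / "diagnostics.txt").write_text(
        "\n".join(diag_lines) + ("\n" if diag_lines else ""), encoding="utf-8"
    )
    summary = {
        "n_chains": len(chains),
        "n_templates": len(templates),
        "level_counts": {level.display: counts[level] for level in HierarchyLevel},
        "per_class_isomeric": dict(sorted(per_class.items())),
        "n_diagnostics": len(diag_lines),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n", encoding="utf-8")
    for level in HierarchyLevel:
        logger.info("%s: %d nodes", level.display, counts[level])
    return summary


def export_sdf(records: Sequence[LipidRecord], path: str | Path) -> int:
    """Write isomeric records to SDF (structure block + named data fields).

    Records without a structure string are skipped with a warning; returns
    the number of molecules written.
    """
    from rdkit import Chem  # imported lazily: RDKit startup is not free

    path = Path(path)
    n = 0
    with open(path, "w", encoding="utf-8") as fh:
        writer = Chem.SDWriter(fh)
        writer.SetKekulize(False)
        for rec in records:
            if not rec.structure_string:
                logger.warning("record %s has no structure string; skipped", rec.id)
                continue
            mol = Chem.MolFromSmiles(rec.structure_string)
            if mol is None:
                logger.warning("record %s: unparsable structure; skipped", rec.id)
                continue
            mol.SetProp("_Name", rec.name)
            mol.SetProp("id", rec.id)
            mol.SetProp("abbreviation", rec.abbreviation)
            mol.SetProp("formula", rec.formula)
            if rec.monoisotopic_mass is not None:
                mol.SetProp("monoisotopic_mass", f"{rec.monoisotopic_mass:.6f}")
            for label, mz in rec.adduct_mz.items():
                mol.SetProp(f"mz{label}", f"{mz:.6f}")
            writer.write(mol)
            n += 1
        writer.close()
    return n
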