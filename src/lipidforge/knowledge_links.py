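"""Evidence-linked annotations: lipid occurrence and enzyme-reaction links.

Every curated assertion carries at least one piece of evidence with a
mandatory Evidence Codes Ontology (ECO) code and an optional PubMed citation
and source quotation.  Occurrence annotations tie a lipid to a GO or Uberon
term in a taxon; enzyme links tie a UniProtKB protein to a Rhea reaction
(optionally naming the lipid that participates).  Identifier validity is
syntactic only — no ontology files are fetched.

The per-lipid information flags mirror the entry-page icon logic: ``ch``
(cheminformatic descriptors) and ``cl`` (classified) are always present on
generated records; ``lo`` appears when an occurrence annotation attaches to
the lipid itself, ``me`` when the lipid participates in a curated reaction.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .building_blocks import Diagnostic
from .hierarchy import Hierarchy, NodeKey

__all__ = [
    "Evidence",
    "OccurrenceAnnotation",
    "EnzymeReactionLink",
    "AnnotationStore",
    "load_annotations",
    "info_flags",
]

_ECO_RE = re.compile(r"ECO:\d{7}$")
_TERM_RE = re.compile(r"(GO|UBERON):\d{7}$")
# UniProtKB accession syntax (release 2015_01 grammar, incl. 10-character ids)
_UNIPROT_RE = re.compile(
    r"([OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9]([A-Z][A-Z0-9]{2}[0-9]){1,2})$"
)
_RHEA_RE = re.compile(r"RHEA:\d+$")


@dataclass(frozen=True)
class Evidence:
    eco_code: str
    pmid: Optional[int] = None
    source_text: str = ""

    def __post_init__(self) -> None:
        if not _ECO_RE.match(self.eco_code):
            raise ValueError(f"malformed ECO code {self.eco_code!r} (expected ECO:nnnnnnn)")
        if self.pmid is not None and self.pmid <= 0:
            raise ValueError(f"pmid must be positive, got {self.pmid}")


@dataclass(frozen=True)
class OccurrenceAnnotation:
    lipid_id: str
    term_id: str
    taxon_id: int
    evidence: tuple[Evidence, ...]

    def __post_init__(self) -> None:
        if not _TERM_RE.match(self.term_id):
            raise ValueError(f"term {self.term_id!r} is not a GO:nnnnnnn or UBERON:nnnnnnn id")
        if self.taxon_id <= 0:
            raise ValueError(f"taxon id must be positive, got {self.taxon_id}")
        if not self.evidence:
            raise ValueError("occurrence annotation requires at least one evidence")


@dataclass(frozen=True)
class EnzymeReactionLink:
    protein_acc: str
    reaction_id: str
    evidence: tuple[Evidence, ...]
    lipid_id: str = ""  # participating lipid, when curated

    def __post_init__(self) -> None:
        if not _UNIPROT_RE.match(self.protein_acc):
            raise ValueError(f"malformed UniProtKB accession {self.protein_acc!r}")
        if not _RHEA_RE.match(self.reaction_id):
            raise ValueError(f"malformed Rhea identifier {self.reaction_id!r}")
        if not self.evidence:
            raise ValueError("enzyme-reaction link requires at least one evidence")


@dataclass
class AnnotationStore:
    occurrences: list[OccurrenceAnnotation] = field(default_factory=list)
    enzyme_links: list[EnzymeReactionLink] = field(default_factory=list)

    def occurrences_for(self, lipid_id: str) -> list[OccurrenceAnnotation]:
        return [a for a in self.occurrences if a.lipid_id == lipid_id]

    def reactions_for(self, lipid_id: str) -> list[EnzymeReactionLink]:
        return [l for l in self.enzyme_links if l.lipid_id == lipid_id]


def _evidence_from_row(row: dict) -> Evidence:
    pmid = row.get("pmid", "").strip()
    return Evidence(
        eco_code=row.get("eco", "").strip(),
        pmid=int(pmid) if pmid else None,
        source_text=row.get("source_text", "").strip(),
    )


def _read_tsv(path: Path) -> tuple[list[str], list[tuple[int, dict]]]:
    lines = path.read_text(encoding="utf-8").splitlines()
    header: list[str] | None = None
    rows = []
    for lineno, raw in enumerate(lines, start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            continue
        rows.append((lineno, dict(zip(header, fields))))
    if header is None:
        raise ValueError(f"{path}: no header row found")
    return header, rows


def load_annotations(
    occurrence_path: Optional[str | Path] = None,
    enzyme_path: Optional[str | Path] = None,
    known_lipid_ids: Optional[set[str]] = None,
) -> tuple[AnnotationStore, list[Diagnostic]]:
    """Load occurrence/enzyme TSVs, rejecting invalid rows with per-row diagnostics.

    Occurrence columns: lipid_id, term_id, taxon_id, eco, pmid, source_text.
    Enzyme columns: protein_acc, reaction_id, eco, pmid [, lipid_id].
    When ``known_lipid_ids`` is given, annotations naming unknown lipids are
    rejected.
    """
    store = AnnotationStore()
    diagnostics: list[Diagnostic] = []

    if occurrence_path is not None:
        _header, rows = _read_tsv(Path(occurrence_path))
        for lineno, row in rows:
            try:
                ann = OccurrenceAnnotation(
                    lipid_id=row.get("lipid_id", "").strip(),
                    term_id=row.get("term_id", "").strip(),
                    taxon_id=int(row.get("taxon_id", "").strip() or 0),
                    evidence=(_evidence_from_row(row),),
                )
                if known_lipid_ids is not None and ann.lipid_id not in known_lipid_ids:
                    raise ValueError(f"unknown lipid id {ann.lipid_id!r}")
            except ValueError as exc:
                diagnostics.append(Diagnostic(lineno, f"occurrence: {exc}"))
                continue
            store.occurrences.append(ann)

    if enzyme_path is not None:
        _header, rows = _read_tsv(Path(enzyme_path))
        for lineno, row in rows:
            try:
                link = EnzymeReactionLink(
                    protein_acc=row.get("protein_acc", "").strip(),
                    reaction_id=row.get("reaction_id", "").strip(),
                    evidence=(_evidence_from_row(row),),
                    lipid_id=row.get("lipid_id", "").strip(),
                )
                if (
                    known_lipid_ids is not None
                    and link.lipid_id
                    and link.lipid_id not in known_lipid_ids
                ):
                    raise ValueError(f"unknown lipid id {link.lipid_id!r}")
            except ValueError as exc:
                diagnostics.append(Diagnostic(lineno, f"enzyme: {exc}"))
                continue
            store.enzyme_links.append(link)

    return store, diagnostics


def info_flags(
    lipid_id: str,
    store: AnnotationStore,
    id_to_key: dict[str, NodeKey],
    hierarchy: Hierarchy,
    with_descendants: bool = False,
) -> frozenset[str]:
    """Information flags for one lipid (the entry-page icon set).

    Flags are level-specific: curated annotations count only when attached to
    the lipid itself, unless ``with_descendants`` aggregates over the subtree
    explicitly.
    """
    if lipid_id not in id_to_key:
        raise KeyError(f"unknown lipid id {lipid_id!r}")
    ids = {lipid_id}
    if with_descendants:
        import networkx as nx

        key = id_to_key[lipid_id]
        key_to_id = {v: k for k, v in id_to_key.items()}
        for desc in nx.descendants(hierarchy.graph, key):
            if desc in key_to_id:
                ids.add(key_to_id[desc])
    flags = {"ch", "cl"}
    if any(a.lipid_id in ids for a in store.occurrences):
        flags.add("lo")
    if any(l.lipid_id in ids for l in store.enzyme_links):
        flags.add("me")
    return frozenset(flags)
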