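"""Chain and lipid-class building blocks.

A *chain* is a fatty acid or fatty alcohol described by carbon count, number
of double bonds, and double-bond positions/geometry (Delta nomenclature,
1-based from the carboxyl/hydroxyl carbon).  A *class template* is a glycerol
(or glycerophospho-) backbone with numbered attachment slots, each restricted
to a set of linkage chemistries (ester, alkyl ether, 1Z-alkenyl vinyl ether).
Combining the two yields every feasible structure of a lipid class.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem_core import ElementalComposition, formula_of, parse_formula

__all__ = [
    "ChainDescriptor",
    "Linkage",
    "ESTER",
    "ALKYL",
    "ALKENYL",
    "LINKAGES",
    "SlotSpec",
    "ClassTemplate",
    "Diagnostic",
    "chain_composition",
    "acyl_residue_name",
    "alkyl_residue_name",
    "load_chain_library",
    "write_chain_library",
    "load_templates",
    "write_templates",
    "default_templates",
    "fixture_library",
    "FATTY_ACID_POOL",
    "FATTY_ALCOHOL_POOL",
]

FATTY_ACID = "fatty-acid"
FATTY_ALCOHOL = "fatty-alcohol"

# -- IUPAC alkane stems (the "an"/"en" suffix is appended by the renderers) --
_STEMS = {
    2: "eth", 3: "prop", 4: "but", 5: "pent", 6: "hex", 7: "hept", 8: "oct",
    9: "non", 10: "dec", 11: "undec", 12: "dodec", 13: "tridec", 14: "tetradec",
    15: "pentadec", 16: "hexadec", 17: "heptadec", 18: "octadec", 19: "nonadec",
    20: "eicos", 21: "heneicos", 22: "docos", 23: "tricos", 24: "tetracos",
    25: "pentacos", 26: "hexacos", 27: "heptacos", 28: "octacos", 29: "nonacos",
    30: "triacont",
}
_MULTIPLIERS = {1: "", 2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}


@dataclass(frozen=True)
class ChainDescriptor:
    """One fatty-acid or fatty-alcohol building block.

    ``db_positions`` are (position, geometry) pairs; a position ``p`` places
    the double bond between carbons ``p`` and ``p+1`` counting from the
    carboxyl (acid) or hydroxyl (alcohol) carbon.
    """

    kind: str  # FATTY_ACID | FATTY_ALCOHOL
    carbons: int
    double_bonds: int
    db_positions: tuple[tuple[int, str], ...] = ()
    trivial_name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (FATTY_ACID, FATTY_ALCOHOL):
            raise ValueError(f"kind must be {FATTY_ACID!r} or {FATTY_ALCOHOL!r}, got {self.kind!r}")
        if self.carbons < 2:
            raise ValueError(f"carbons must be >= 2, got {self.carbons}")
        if self.double_bonds < 0:
            raise ValueError(f"double_bonds must be >= 0, got {self.double_bonds}")
        if len(self.db_positions) != self.double_bonds:
            raise ValueError(
                f"db_positions has {len(self.db_positions)} entries "
                f"but double_bonds is {self.double_bonds}"
            )
        prev = 1
        for pos, geom in self.db_positions:
            if geom not in ("Z", "E"):
                raise ValueError(f"geometry must be Z or E, got {geom!r}")
            if not 2 <= pos <= self.carbons - 1:
                raise ValueError(
                    f"db position {pos} outside [2, {self.carbons - 1}] for {self.carbons}-carbon chain"
                )
            if pos <= prev:
                raise ValueError(f"db positions must be strictly increasing, got {self.db_positions}")
            prev = pos

    @property
    def key(self) -> tuple:
        """Canonical identity / sort key: (kind, C, DB, positions)."""
        return (self.kind, self.carbons, self.double_bonds, self.db_positions)

    @property
    def shorthand(self) -> str:
        return f"{self.carbons}:{self.double_bonds}"

    @property
    def systematic_residue_name(self) -> str:
        """Residue name in the form used within systematic lipid names."""
        if self.kind == FATTY_ACID:
            return acyl_residue_name(self.carbons, self.db_positions)
        return alkyl_residue_name(self.carbons, self.db_positions)


def _positions_prefix(db: Sequence[tuple[int, str]]) -> str:
    return ",".join(f"{p}{g}" for p, g in db)


def acyl_residue_name(carbons: int, db: Sequence[tuple[int, str]] = ()) -> str:
    """'hexadecanoyl', '9Z-octadecenoyl', '5Z,8Z,11Z,14Z-eicosatetraenoyl'..."""
    stem = _STEMS[carbons]
    d = len(db)
    if d == 0:
        return f"{stem}anoyl"
    body = f"{stem}{'a' + _MULTIPLIERS[d] if d >= 2 else ''}enoyl"
    return f"{_positions_prefix(db)}-{body}"


def alkyl_residue_name(carbons: int, db: Sequence[tuple[int, str]] = ()) -> str:
    """'hexadecyl', '1Z-hexadecenyl', '1Z,9Z-octadecadienyl'..."""
    stem = _STEMS[carbons]
    d = len(db)
    if d == 0:
        return f"{stem}yl"
    body = f"{stem}{'a' + _MULTIPLIERS[d] if d >= 2 else ''}enyl"
    return f"{_positions_prefix(db)}-{body}"


def chain_composition(chain: ChainDescriptor) -> ElementalComposition:
    """Composition of the free molecule: acid CnH(2n-2d)O2, alcohol CnH(2n+2-2d)O."""
    n, d = chain.carbons, chain.double_bonds
    if chain.kind == FATTY_ACID:
        return ElementalComposition(C=n, H=2 * n - 2 * d, O=2)
    return ElementalComposition(C=n, H=2 * n + 2 - 2 * d, O=1)


# ---------------------------------------------------------------------------
# Linkages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Linkage:
    """Chemistry attaching a chain to a backbone slot.

    The alkenyl (vinyl-ether, plasmalogen) linkage installs an obligatory 1Z
    double bond at chain position 1; that bond is not counted in the chain's
    printed C:DB digits but does contribute to species/molecular-level
    double-bond sums (``species_db_increment``).
    """

    label: str
    abbreviation_prefix: str
    chain_kind_required: str
    species_db_increment: int


ESTER = Linkage("ester", "", FATTY_ACID, 0)
ALKYL = Linkage("alkyl", "O-", FATTY_ALCOHOL, 0)
ALKENYL = Linkage("alkenyl", "P-", FATTY_ALCOHOL, 1)
LINKAGES = {l.label: l for l in (ESTER, ALKYL, ALKENYL)}


# ---------------------------------------------------------------------------
# Class templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlotSpec:
    """One numbered attachment position on a backbone.

    ``allowed_linkages`` empty together with ``may_be_empty`` marks an
    obligate free hydroxyl (lyso classes).
    """

    sn_position: int
    allowed_linkages: tuple[Linkage, ...]
    may_be_empty: bool = False

    def __post_init__(self) -> None:
        if not self.allowed_linkages and not self.may_be_empty:
            raise ValueError(f"slot sn-{self.sn_position} allows no linkage and may not be empty")


@dataclass(frozen=True)
class ClassTemplate:
    """A lipid class: backbone fragment + typed slots + classification names.

    ``backbone_fragment`` is a SMILES string with ``{N}`` placeholders (one
    per slot, N = sn position); substituting each placeholder with ``O``
    (free hydroxyl) must yield ``backbone_composition``.
    """

    category: str
    class_name: str
    subclass_name: str
    abbreviation: str
    backbone_fragment: str
    backbone_composition: ElementalComposition
    slots: tuple[SlotSpec, ...]
    systematic_suffix: str  # e.g. "sn-glycero-3-phosphocholine"
    class_synonym: str = ""  # long form, e.g. "Phosphatidylcholine"

    def __post_init__(self) -> None:
        if not self.abbreviation:
            raise ValueError("class abbreviation must be non-empty")
        placeholders = sorted(
            int(tok) for tok in _iter_placeholders(self.backbone_fragment)
        )
        slot_positions = sorted(s.sn_position for s in self.slots)
        if placeholders != slot_positions:
            raise ValueError(
                f"template {self.abbreviation!r}: backbone placeholders {placeholders} "
                f"do not match slot positions {slot_positions}"
            )

    @property
    def key(self) -> tuple:
        return (self.category, self.class_name, self.subclass_name, self.abbreviation)


def _iter_placeholders(fragment: str) -> Iterable[str]:
    return re.findall(r"\{(\d+)\}", fragment)


# ---------------------------------------------------------------------------
# Chain-library TSV I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Diagnostic:
    row: int
    message: str

    def __str__(self) -> str:
        return f"row {self.row}: {self.message}"


_CHAIN_COLUMNS = ("kind", "carbons", "double_bonds", "positions", "trivial_name")


def _parse_positions(text: str) -> tuple[tuple[int, str], ...]:
    text = text.strip()
    if not text:
        return ()
    out = []
    for tok in text.replace(",", ";").split(";"):
        tok = tok.strip()
        if not tok:
            continue
        geom = tok[-1].upper()
        out.append((int(tok[:-1]), geom))
    return tuple(out)


def load_chain_library(path: str | Path) -> tuple[list[ChainDescriptor], list[Diagnostic]]:
    """Read a chain-library TSV; invalid rows become diagnostics, duplicates collapse.

    Columns: kind, carbons, double_bonds, positions ("9Z" / "5Z;8Z;11Z;14Z" /
    blank), trivial_name.  Lines starting with '#' are comments.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    chains: list[ChainDescriptor] = []
    diagnostics: list[Diagnostic] = []
    seen: dict[tuple, int] = {}
    header: list[str] | None = None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = [f.strip().lower() for f in fields]
            missing = [c for c in _CHAIN_COLUMNS[:3] if c not in header]
            if missing:
                raise ValueError(f"{path}: header missing required columns {missing}")
            continue
        row = dict(zip(header, fields))
        try:
            chain = ChainDescriptor(
                kind=row.get("kind", "").strip(),
                carbons=int(row.get("carbons", "")),
                double_bonds=int(row.get("double_bonds", "")),
                db_positions=_parse_positions(row.get("positions", "")),
                trivial_name=row.get("trivial_name", "").strip(),
            )
        except (ValueError, KeyError) as exc:
            diagnostics.append(Diagnostic(lineno, str(exc)))
            continue
        if chain.key in seen:
            diagnostics.append(
                Diagnostic(lineno, f"duplicate of row {seen[chain.key]} ({chain.kind} {chain.shorthand}); collapsed")
            )
            continue
        seen[chain.key] = lineno
        chains.append(chain)
    if header is None:
        raise ValueError(f"{path}: no header row found")
    if not chains:
        raise ValueError(f"{path}: chain library is empty")
    return chains, diagnostics


def write_chain_library(chains: Iterable[ChainDescriptor], path: str | Path) -> None:
    path = Path(path)
    rows = ["\t".join(_CHAIN_COLUMNS)]
    for c in chains:
        rows.append(
            "\t".join(
                [
                    c.kind,
                    str(c.carbons),
                    str(c.double_bonds),
                    ";".join(f"{p}{g}" for p, g in c.db_positions),
                    c.trivial_name,
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Template JSON I/O
# ---------------------------------------------------------------------------

def _template_to_dict(t: ClassTemplate) -> dict:
    return {
        "category": t.category,
        "class_name": t.class_name,
        "subclass_name": t.subclass_name,
        "abbreviation": t.abbreviation,
        "backbone_fragment": t.backbone_fragment,
        "backbone_formula": formula_of(t.backbone_composition),
        "systematic_suffix": t.systematic_suffix,
        "class_synonym": t.class_synonym,
        "slots": [
            {
                "sn_position": s.sn_position,
                "allowed_linkages": [l.label for l in s.allowed_linkages],
                "may_be_empty": s.may_be_empty,
            }
            for s in t.slots
        ],
    }


def _template_from_dict(d: dict) -> ClassTemplate:
    slots = tuple(
        SlotSpec(
            sn_position=int(s["sn_position"]),
            allowed_linkages=tuple(LINKAGES[l] for l in s.get("allowed_linkages", [])),
            may_be_empty=bool(s.get("may_be_empty", False)),
        )
        for s in d["slots"]
    )
    return ClassTemplate(
        category=d["category"],
        class_name=d["class_name"],
        subclass_name=d["subclass_name"],
        abbreviation=d["abbreviation"],
        backbone_fragment=d["backbone_fragment"],
        backbone_composition=parse_formula(d["backbone_formula"]),
        slots=slots,
        systematic_suffix=d["systematic_suffix"],
        class_synonym=d.get("class_synonym", ""),
    )


def load_templates(path: str | Path) -> list[ClassTemplate]:
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    templates = [_template_from_dict(d) for d in data]
    if not templates:
        raise ValueError(f"{path}: template list is empty")
    return templates


def write_templates(templates: Iterable[ClassTemplate], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([_template_to_dict(t) for t in templates], indent=2) + "\n",
        encoding="utf-8",
    )


# ---------------------------------------------------------------------------
# Built-in backbones and the fixture pool
# ---------------------------------------------------------------------------

# sn-glycerol with the phosphate at sn-3; choline headgroup written zwitterionic.
_GPC_FRAGMENT = "C({1})[C@@H]({2})COP(=O)([O-])OCC[N+](C)(C)C"
_GPC_COMPOSITION = ElementalComposition(C=8, H=20, N=1, O=6, P=1)
_GPE_FRAGMENT = "C({1})[C@@H]({2})COP(=O)([O-])OCC[NH3+]"
_GPE_COMPOSITION = ElementalComposition(C=5, H=14, N=1, O=6, P=1)
_GLYCEROL_FRAGMENT = "C({1})[C@@H]({2})C({3})"
_GLYCEROL_COMPOSITION = ElementalComposition(C=3, H=8, O=3)


def default_templates() -> list[ClassTemplate]:
    """The built-in class templates (a representative subset of the 51 curated classes)."""
    return [
        ClassTemplate(
            category="Glycerophospholipid",
            class_name="Glycerophosphocholine",
            subclass_name="Diacylglycerophosphocholine",
            abbreviation="PC",
            backbone_fragment=_GPC_FRAGMENT,
            backbone_composition=_GPC_COMPOSITION,
            slots=(SlotSpec(1, (ESTER,)), SlotSpec(2, (ESTER,))),
            systematic_suffix="sn-glycero-3-phosphocholine",
            class_synonym="Phosphatidylcholine",
        ),
        ClassTemplate(
            category="Glycerophospholipid",
            class_name="Glycerophosphocholine",
            subclass_name="Monoalkylmonoacylglycerophosphocholine",
            abbreviation="PC",
            backbone_fragment=_GPC_FRAGMENT,
            backbone_composition=_GPC_COMPOSITION,
            slots=(SlotSpec(1, (ALKYL, ALKENYL)), SlotSpec(2, (ESTER,))),
            systematic_suffix="sn-glycero-3-phosphocholine",
            class_synonym="Phosphatidylcholine",
        ),
        ClassTemplate(
            category="Glycerophospholipid",
            class_name="Glycerophosphocholine",
            subclass_name="Monoacylglycerophosphocholine",
            abbreviation="LPC",
            backbone_fragment=_GPC_FRAGMENT,
            backbone_composition=_GPC_COMPOSITION,
            slots=(SlotSpec(1, (ESTER,)), SlotSpec(2, (), may_be_empty=True)),
            systematic_suffix="sn-glycero-3-phosphocholine",
            class_synonym="Lysophosphatidylcholine",
        ),
        ClassTemplate(
            category="Glycerophospholipid",
            class_name="Glycerophosphoethanolamine",
            subclass_name="Diacylglycerophosphoethanolamine",
            abbreviation="PE",
            backbone_fragment=_GPE_FRAGMENT,
            backbone_composition=_GPE_COMPOSITION,
            slots=(SlotSpec(1, (ESTER,)), SlotSpec(2, (ESTER,))),
            systematic_suffix="sn-glycero-3-phosphoethanolamine",
            class_synonym="Phosphatidylethanolamine",
        ),
        ClassTemplate(
            category="Glycerolipid",
            class_name="Triradylglycerol",
            subclass_name="Triacylglycerol",
            abbreviation="TG",
            backbone_fragment=_GLYCEROL_FRAGMENT,
            backbone_composition=_GLYCEROL_COMPOSITION,
            slots=(SlotSpec(1, (ESTER,)), SlotSpec(2, (ESTER,)), SlotSpec(3, (ESTER,))),
            systematic_suffix="sn-glycerol",
            class_synonym="Triacylglycerol",
        ),
    ]


def _Z(*positions: int) -> tuple[tuple[int, str], ...]:
    return tuple((p, "Z") for p in positions)


#: Hard-coded pool of real fatty acids with curated double-bond positions.
FATTY_ACID_POOL: tuple[ChainDescriptor, ...] = (
    ChainDescriptor(FATTY_ACID, 10, 0, (), "capric acid"),
    ChainDescriptor(FATTY_ACID, 12, 0, (), "lauric acid"),
    ChainDescriptor(FATTY_ACID, 14, 0, (), "myristic acid"),
    ChainDescriptor(FATTY_ACID, 16, 0, (), "palmitic acid"),
    ChainDescriptor(FATTY_ACID, 16, 1, _Z(9), "palmitoleic acid"),
    ChainDescriptor(FATTY_ACID, 18, 0, (), "stearic acid"),
    ChainDescriptor(FATTY_ACID, 18, 1, _Z(9), "oleic acid"),
    ChainDescriptor(FATTY_ACID, 18, 2, _Z(9, 12), "linoleic acid"),
    ChainDescriptor(FATTY_ACID, 18, 3, _Z(9, 12, 15), "alpha-linolenic acid"),
    ChainDescriptor(FATTY_ACID, 20, 4, _Z(5, 8, 11, 14), "arachidonic acid"),
    ChainDescriptor(FATTY_ACID, 20, 5, _Z(5, 8, 11, 14, 17), "eicosapentaenoic acid"),
    ChainDescriptor(FATTY_ACID, 22, 6, _Z(4, 7, 10, 13, 16, 19), "docosahexaenoic acid"),
)

#: Hard-coded pool of real fatty alcohols.
FATTY_ALCOHOL_POOL: tuple[ChainDescriptor, ...] = (
    ChainDescriptor(FATTY_ALCOHOL, 14, 0, (), "tetradecanol"),
    ChainDescriptor(FATTY_ALCOHOL, 16, 0, (), "hexadecanol"),
    ChainDescriptor(FATTY_ALCOHOL, 18, 0, (), "octadecanol"),
    ChainDescriptor(FATTY_ALCOHOL, 18, 1, _Z(9), "oleyl alcohol"),
)


def fixture_library(
    n_acids: int, n_alcohols: int = 0, seed: int = 0
) -> tuple[list[ChainDescriptor], list[ClassTemplate]]:
    """Deterministic desk-scale stand-in for the curated building-block tables.

    Draws ``n_acids`` fatty acids and ``n_alcohols`` fatty alcohols from the
    hard-coded pools (seeded sample, stable for a fixed seed) and returns them
    with the built-in class templates.
    """
    if n_acids < 1:
        raise ValueError("n_acids must be >= 1")
    if n_acids > len(FATTY_ACID_POOL):
        raise ValueError(f"n_acids exceeds pool size {len(FATTY_ACID_POOL)}")
    if not 0 <= n_alcohols <= len(FATTY_ALCOHOL_POOL):
        raise ValueError(f"n_alcohols must be in [0, {len(FATTY_ALCOHOL_POOL)}]")
    rng = random.Random(seed)
    acids = sorted(rng.sample(FATTY_ACID_POOL, n_acids), key=lambda c: c.key)
    alcohols = sorted(rng.sample(FATTY_ALCOHOL_POOL, n_alcohols), key=lambda c: c.key)
    return list(acids) + list(alcohols), default_templates()
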