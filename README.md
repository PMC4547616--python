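# lipidforge

Combinatorial generation of glycerolipid and glycerophospholipid structures,
standardized shorthand nomenclature, and the seven-level analytical hierarchy
that maps mass-spectrometry outputs to candidate structures — with m/z search
and compound-identifier mapping on top.

## The problem

Shotgun and LC-MS lipidomics reports lipids at very different levels of
structural ambiguity. A precursor mass alone fixes only the lipid class and
the *sum composition* of the chains, e.g. PC(O-36:5); tandem fragmentation
may reveal the individual chains, PC(O-16:1_20:4); further evidence may pin
the sn positions, PC(P-16:0/20:4), or even every double-bond position,
PC(P-16:0/20:4(5Z,8Z,11Z,14Z)). Interpreting such data needs a reference
library of all *feasible* structures — built from chains that are actually
known to occur, not from hypothetical enumeration of every double-bond
placement — organized so each analytical output maps to exactly the set of
structures compatible with it.

`lipidforge` builds that library. From a table of curated fatty acids and
fatty alcohols (carbon count `n`, double-bond count `d`, Δ-positions and
geometry) and a set of lipid-class templates (a backbone SMILES fragment with
numbered slots, each allowing ester, alkyl-ether and/or 1Z-alkenyl
vinyl-ether linkages), it enumerates the Cartesian product of chains over
slots; assembles an isomeric SMILES for every structure; computes Hill
formula, monoisotopic and average mass, and exact m/z for nine common adducts
([M.]+, [M+H]+, [M+K]+, [M+Na]+, [M+Li]+, [M+NH4]+, [M−H]−, [M+Cl]−,
[M+OAc]−, with electron-mass correction); names every node at every level;
and arranges everything in the deduplicated hierarchy

Category → Class → Subclass → Species → Molecular subspecies →
Structural subspecies → Isomeric subspecies.

Rollups are deterministic functions of the shorthand: the structural parent
drops double-bond positions; the molecular parent discards sn positions and
rewrites every plasmalogen chain P-*n*:*d* as O-*n*:(*d*+1) (the vinyl-ether
double bond becomes indistinguishable from a chain double bond); the species
parent sums carbons and double bonds and keeps a single `O-` flag.

## Worked example

```python
from lipidforge import *
from lipidforge.assembly import SlotFill, make_isomeric
from lipidforge.building_blocks import FATTY_ACID, FATTY_ALCOHOL
from lipidforge.hierarchy import parent_structural, parent_molecular, parent_species

hexadecanol = ChainDescriptor(FATTY_ALCOHOL, 16, 0, (), "hexadecanol")
arachidonic = ChainDescriptor(FATTY_ACID, 20, 4,
                              ((5, "Z"), (8, "Z"), (11, "Z"), (14, "Z")),
                              "arachidonic acid")
pc = next(t for t in default_templates()
          if t.subclass_name == "Monoalkylmonoacylglycerophosphocholine")
iso = make_isomeric(pc, SlotAssignment(pc, {1: SlotFill(hexadecanol, ALKENYL),
                                            2: SlotFill(arachidonic, ESTER)}))
abbr = abbreviation_of(pc, iso.assignment)
print(abbreviate(abbr))
print(abbreviate(parent_structural(abbr)))
print(abbreviate(parent_molecular(parent_structural(abbr))))
print(abbreviate(parent_species(parent_molecular(parent_structural(abbr)))))
print(systematic_name(iso))
print(iso.formula, round(monoisotopic_mass(iso.composition), 6))
```

prints

```
PC(P-16:0/20:4(5Z,8Z,11Z,14Z))
PC(P-16:0/20:4)
PC(O-16:1_20:4)
PC(O-36:5)
1-O-(1Z-hexadecenyl)-2-(5Z,8Z,11Z,14Z-eicosatetraenoyl)-sn-glycero-3-phosphocholine
C44H80NO7P 765.56724
```

i.e. the full analytical rollup of a plasmalogen phosphatidylcholine — the
vinyl-ether chain written `P-16:0` at structural level becomes `O-16:1` at
molecular level and contributes its hidden double bond to the `O-36:5` sum —
plus its systematic name, formula and neutral monoisotopic mass in Da.

From the shell, the same pipeline end to end:

```
lipidforge fixtures --n-acids 12 --n-alcohols 4 --out in/
lipidforge generate --chains in/chains.tsv --templates in/templates.json --out lib/
lipidforge search --library lib/ --mz 760.585082 --tol 5ppm --polarity pos
```

`generate` writes `nodes.tsv`, `edges.tsv`, `counts.tsv` and
`structures.sdf` (byte-identical across runs); the bundled 12-acid/4-alcohol
pool with the five built-in class templates yields 2124 isomeric subspecies,
2124 structural, 616 molecular and 259 species. The `search` query above
returns PC(34:1)-containing records as [M+H]+ hits at ~0 ppm.

Curated knowledge attaches to any node as evidence-backed annotations
(ECO code + optional PMID): occurrence in a GO/Uberon term and taxon, and
UniProtKB-protein/Rhea-reaction links; per-lipid information flags
(`ch`, `cl`, `lo`, `me`) summarize what is known.

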