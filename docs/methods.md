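# Methods

## Model

A lipid structure is modeled as a backbone fragment plus chains attached at
numbered sn slots. Chains are curated fatty acids (CnH(2n−2d)O2 free form)
or fatty alcohols (CnH(2n+2−2d)O), with double bonds recorded as Δ-positions
(1-based from the carboxyl/hydroxyl carbon) and Z/E geometry. Three linkage
chemistries are supported: ester (acyl), alkyl ether, and 1Z-alkenyl vinyl
ether (plasmalogen). The alkenyl building block is the same fatty-alcohol
record flagged at assembly time by the linkage, not a separate chain entry;
this keeps the alcohol pool unduplicated and makes the P-n:d ↔ O-n:(d+1)
composition identity structural rather than coincidental.

Composition bookkeeping is purely arithmetic: backbone + Σ free-chain
compositions − one H2O per filled slot (every ester/ether/vinyl-ether
condensation releases one water), and an additional −H2 for each alkenyl
linkage (the obligatory 1Z double bond). The assembled SMILES is built
independently by substituting chain fragments into the backbone placeholders
(`O C(=O)…` for esters, `OC…` for alkyl ethers, `O/C=C\…` for alkenyls,
`O` for an empty slot), so the atom counts of the structure string provide a
cross-check on the arithmetic; the test suite performs that check with RDKit
as the independent atom counter.

Enumeration is the exact Cartesian product over slots of (eligible chain ×
allowed linkage), restricted to the listed chains — deliberately *not* an
enumeration of hypothetical double-bond placements. sn-positional isomers
are distinct structures; identical ordered assignments deduplicate to one.
Output order is canonical (template key, then slot-wise (prefix, C, DB,
positions)), which makes library builds byte-identical across runs.

## Hierarchy

Seven levels: Category, Class, Subclass, Species, Molecular subspecies,
Structural subspecies, Isomeric subspecies. Two class tiers are modeled
because the classification distinguishes the headgroup class
(Glycerophosphocholine) from the linkage subclass
(e.g. Monoalkylmonoacylglycerophosphocholine). Rollups are pure functions on
the shorthand, so parents are unique and idempotent. Node identity is
(level, canonical abbreviation or name); stable identifiers are a
deterministic BLAKE2b hash of that key (10 hex digits, prefix `SLF`) with a
collision check over the generated set, so ids survive reordering and
incremental regeneration without a registry.

Species-level `O-` does not distinguish alkyl from alkenyl chains: both roll
up to the `O-` sum with the vinyl-ether double bond added for P- chains.
Merged species nodes therefore always agree on elemental composition for the
shipped templates; should user templates ever merge species with different
formulas (e.g. a dialkyl and a diacyl class sharing an abbreviation), the
conflicting annotation is dropped rather than guessed.

## Nomenclature

Generation and parsing share one grammar. Canonical orders: `/`-separated
terms follow sn positions; `_`-separated molecular terms put ether chains
first, then ascending (C, DB), ties broken by the position vector; empty
(lyso) slots print `0:0` at structural/isomeric levels, are dropped from
molecular terms and species sums, and are omitted from systematic names.
Locants are plain ASCII (`5Z,8Z,11Z,14Z`). Residues beginning with a locant
are parenthesised in systematic names; identical residues on adjacent
positions condense (`1,2-di…`).

Two documented degeneracies of the printed shorthand: an isomeric subspecies
whose chains are all saturated prints identically to its structural parent
(the parser returns Structural, the lower of the two); and a single-chain
molecular record prints as a single sum term, which the level-inference rule
reads as Species. In both cases the string round-trip
`abbreviate(parse(x)) == x` and the chain-term content are exact; only the
level label is unrecoverable from the text.

## Masses and adducts

Atomic masses are pinned in code (IUPAC 2005 recommended isotopic masses /
AME2003; IUPAC 2007 standard atomic weights for average mass) for
bit-reproducibility without network access. All nine default adducts include
the electron-mass correction (5.4858e-4 Da): [M+H]+ adds the proton mass
1.007276 Da, and the radical cation [M.]+ is implemented as M minus one
electron — the convention adopted here since the label itself does not state
it. m/z values are reported to 6 decimal places. Monoisotopic mass is the
primary quantity; average mass is computed and stored alongside. The adduct
registry is user-extensible via a TSV config (label, delta, charge,
polarity).

## Search and mapping

The m/z index is a sorted flat array over (record, adduct) pairs queried by
binary search; deterministic, dependency-free and adequate to ~10^6 rows.
ppm tolerances convert to Da windows at the query mass, so a t-ppm search at
mass M equals a t·M·1e-6-Da search. Hits are ranked by |ppm error|, ties by
neutral mass then id. Identifier mapping is exact key equality on InChIKey
(full 27-character key by default; first-block matching is an explicit,
documented relaxation), canonical abbreviation, or formula; ambiguity counts
report the number of targets sharing one source key. InChIKey computation
itself is delegated (keys are accepted as input or computed externally);
the library stores and compares them.

## Annotations

Occurrence annotations link a lipid id to a GO or Uberon term and an NCBI
taxon; enzyme links pair a UniProtKB accession with a Rhea reaction id and
optionally the participating lipid (the enzyme TSV carries an optional
`lipid_id` column for this purpose — without it the per-lipid metabolism
flag would be uncomputable). Every annotation requires at least one evidence
with a syntactically valid ECO code; identifier validation is syntactic only
(no ontology files are fetched). Annotations are level-specific and are not
propagated along the hierarchy; subtree aggregation is an explicit query
option (`with_descendants`), matching the convention that curated assertions
attach at the level the experiment supports.

## Synthetic building-block pool

The packaged pool — 12 fatty acids (10:0 … 22:6(4Z,7Z,10Z,13Z,16Z,19Z)) and
4 fatty alcohols with literature double-bond positions, plus five class
templates (diacyl-PC, alkyl/alkenyl-acyl-PC, lyso-PC, diacyl-PE,
triacylglycerol) — is a representative desk-scale stand-in for the full
curated tables (80 fatty acids, 18 fatty alcohols, 51 glycerophospholipid and
glycerolipid classes) that back the production-scale library. It exercises
every code path (esters, both ether linkages, lyso slots, a three-slot
neutral-lipid class, polyunsaturation) but it is a subset: absolute library
totals at full scale are not reproducible from it, and the corresponding
check in the test suite records that gap. What the passing tests do show is
that enumeration, dedup, rollup, naming and mass arithmetic are exact on any
input of this shape; they do not validate the curation choices (which chains
and classes occur in nature) that a production library encodes.

Real chain tables also contain hydroxylated, branched and cyclic chains and
sphingoid bases; these are out of scope here, as are sterols and
sphingolipids generally, multiply-charged and dimer adducts, isotopologue
envelopes, and MS/MS fragment prediction.

## Numerical and design choices

- Mass comparisons in tests use 1e-6 Da absolute tolerance (1e-9 for
  additivity); formula strings are bit-exact.
- Conjugated double bonds are rejected at SMILES assembly (geometry markers
  would conflict); none occur in the pool. A terminal double bond's
  geometry marker is omitted (it has no cis/trans sense).
- The sn-glycerol stereocentre is written explicitly (`[C@@H]` at C2 with
  the phosphate branch at sn-3); zwitterionic headgroups are written
  charge-separated.
- Ether/vinyl-ether linkages are permitted only on slots whose template
  allows them (sn-1 in the shipped templates), configurable per template.
- `fixture_library(n_acids, n_alcohols, seed)` draws a seeded sample from
  the pool; identical seeds give identical libraries.
- The acceptance script scales its search cross-check to 1000 random
  queries over the full generated record set, and runs the round-trip over
  all ~8.5k generated abbreviations; both complete in about a second.
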