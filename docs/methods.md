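# Methods

This note records the models, conventions and numerical choices behind
`frasebot`, in the order data flows through the pipeline.

## Structures and I/O

Complexes are read from PDB files (gemmi). Polymer amino-acid residues form
the protein; HETATM groups become ligands unless their het code is on a
deny list of waters, common ions, buffers and cryoprotectants — a policy
choice, since deposited structures do not label "the ligand". Peptide
polymer chains are never ligands. Hydrogens are dropped on read: X-ray
inputs rarely carry them and every distance rule in the pipeline is defined
on heavy atoms. Altloc groups resolve to the highest-occupancy conformer
(ties broken alphabetically) for determinism. Coordinates are Cartesian Å
in the deposited asymmetric unit; no symmetry expansion, and only the first
model of multi-model files.

FRASEs are serialized to SDF with the fragment as the molecule block and
the protein environment in the `FRASE_ENV` data field, one
`resname chain seq atom_name element x y z` line per atom (SDF has no
native protein block). Additional fields carry source, label and
environment radius. Reading is streaming and constant-memory; malformed
records are skipped, warned about and counted. Round-trips preserve
coordinates to better than 1e-3 Å.

Metal ions are stored in `hetero_other` and excluded from environments and
from collision/burial statistics by default; whether ions should count as
environment is genuinely open, so the exclusion is configurable at the
loading step (supply a custom deny list).

## Ligand filtering and fragmentation

Drug-likeness filtering combines Lipinski thresholds (MW ≤ 500 by default,
600 for screening-library use; logP ≤ 5; ≤ 5 donors; ≤ 10 acceptors), an
element allow-list (C, N, O, S, halogens — phosphorus and other elements
reject), a peptide rule (two or more overlapping dipeptide backbone units),
and a REOS-style deny list of reactive groups (aldehydes, Michael
acceptors, alkyl/acyl halides, epoxides, azides, …) shipped as an editable
SMARTS table in `frasebot.extract.REOS_SMARTS`. Every violated rule is
reported, not just the first. The high-affinity criterion (K_D, K_i, IC50
or EC50 below 100 nM) is applied from a user-supplied CSV in
`frasebot build-db`; nothing is fetched from the network.

Fragmentation enumerates subsets of acyclic single bonds to cut (at most 3
simultaneous cuts by default — a combinatorics bound, configurable; heavier
fragments would exceed the 300 Da cap anyway). Ring bonds are never cut, so
ring systems stay intact. The alpha-atom rule: when a cut bond touches a
ring atom, the atom across the cut stays with the ring-containing fragment
as an acyclic cap (its aromatic flag cleared, the bond made single). This
reproduces both canonical cases — ethylbenzene yields a toluene-like
fragment, and biphenyl yields each ring plus the attachment carbon of the
other ring. A consequence worth noting: an alpha cap that was itself a ring
atom of the parent enters the fragment detached from its own ring.
Fragment molecular weight is computed with open valences hydrogen-capped
(implicit-H completion), and the 50–300 Da window applied. Duplicate parent
atom sets are emitted once.

Environment membership uses an inclusive threshold: a residue belongs to a
fragment's environment when its minimum heavy-atom distance is ≤ 4.5 Å.
All distance thresholds in the package are inclusive ("within" read as ≤).

## Triplet encoding and matching

The 11-bit residue table lives in `frasebot.triplets.RESIDUE_BITS` with the
published rows preserved verbatim in the adjacent comment. Two conventions:
(1) the canonical bit layout follows the tabulated column order (charge,
HBA, HBD, aromatic, hydrophobic×3, volume×3) rather than the prose order;
(2) the charge columns are assigned chemically (ARG/LYS/HIS positive,
ASP/GLU negative) where the printed table transposes them. Both choices are
applied identically to database and target, so matching results are
invariant to them. Only the 20 standard residues with a Cα participate;
modified residues are skipped as untypable.

"Approximately equilateral" is operationalised as: all three Cα pairwise
distances in [8, 12] Å, bounds inclusive, with no extra aspect-ratio
constraint — the side bounds are the only stated geometry. Matching is
exact equality of canonical keys (the lexicographically smallest of the six
permuted concatenations): the single parameter-free comparison a hash
index supports. Key equality does not imply geometric congruence within
the [8, 12] Å box, so seeding applies a superposition-residual gate
(`rmsd_max`, default 1 Å, configurable or disableable); badly distorted
alignments that slip through are later removed by the collision and
fitness filters.

Superposition is 3-point Kabsch: SVD of the cross-covariance with the
reflection branch removed, residue correspondence fixed by each triplet's
canonical-order permutation. Near-collinear triplets (cross-product norm
below 1e-8) raise a degeneracy error and are skipped with a warning.

## Interaction fingerprint and nativeness model

The 29 ligand and 13 protein atom-type vocabularies are fixed name lists;
their perception rules are editable tables — SMARTS patterns for ligand
atoms (`LIGAND_TYPE_SMARTS`), and a per-residue per-atom-name template for
protein atoms, since environment residues carry no bond orders. Names
without a universal definition are given explicit ones: "Hetero" is any
non-C heavy atom, "Vinyl" is a non-aromatic sp² carbon in a C=C,
"Aliphatic Carbon" any non-aromatic carbon. Atoms are many-hot: an
aromatic carbon is both "Aromatic" and "Aromatic Carbon", and each
(ligand type, protein type) pair it participates in receives the full
distance weight — the Kronecker-delta sum makes this the only consistent
semantics for overlapping types. Untabulated protein atoms (e.g. CYS SG)
contribute nothing.

The weight w(d) = exp(−(d−3)²) for d ≤ 10 Å and 0 beyond is applied to all
heavy-atom pairs; the step at 10 Å is part of the definition (w(10) ≈
e⁻⁴⁹ is already negligible). Sums run over heavy atoms only, consistent
with hydrogen-free X-ray inputs. The fingerprint is invariant under rigid
motion by construction (tested to 1e-9) and equals a literal double-loop
evaluation (tested to 1e-12).

Decoys replace a FRASE's fragment with one drawn (seeded RNG, never the
FRASE's own) from another FRASE, translated to the original fragment's
centroid and oriented by principal-axes alignment with a deterministic
sign convention — no docking or minimisation, preserving pocket context
while scrambling chemistry. Two decoys per true FRASE is the training
ratio; the validation decoy pool size is a free parameter (the published
validation ratio differs from the training ratio without explanation, so
the generator exposes an explicit count).

The classifier is a 377 → 32 → 16 → 1 net (ReLU, ReLU, sigmoid) written
directly on NumPy: mini-batch Adam (lr 1e-3, β 0.9/0.999) on binary
cross-entropy, 500 epochs, batch 50, He initialisation, a fixed seed
controlling both initialisation and shuffling. The 1:2 class imbalance is
left uncorrected (plain BCE). The sigmoid pre-activation is capped at |36|
so outputs stay strictly inside (0, 1) in float64. Weights serialize to a
single JSON file (hyperparameters plus weight lists) that reloads
bit-identically. Training at the package's test scales (≲10³ examples)
takes seconds; the design target is a desk-scale MLP, not GPU training.

## Filters

A seeded pose survives when min clash distance ≥ 1 Å AND mean burial ≥ 5
protein heavy atoms within 5 Å per fragment atom AND fitness ≥ 0.4 — all
inclusive, all recomputed against the target (never copied from the source
complex). Burial is the arithmetic mean over fragment heavy atoms. A
fragment seeded through several matching triplets keeps every pose as a
separate candidate.

## Pharmacophore

Feature perception uses substructure-pattern feature definitions with the
standard family set mapped onto {HBA, HBD, Pos, Neg, Ar, Hyd}; hydrophobic
features whose atoms are aromatic are dropped, since aromatic rings are
represented by Ar at the ring centroid. Clustering is per-type k-means with
k grown from 1 until every cluster's pairwise member diameter is ≤ 3 Å
(diameter, the stricter reading of "maximum distance between cluster
members", with a radius-based alternative switchable); 10 restarts, fixed
seed. "Dense" is defined as size / (1 + mean member–centroid distance) —
one monotone choice among many, swappable. Ranking is size descending,
density descending, cluster id ascending: a total deterministic order.
Query assembly default expects an explicit centroid choice (the published
workflow chose centroids by visual inspection of burial and mutual
reachability); the automated default picks the top-ranked clusters. The
per-feature tolerance radius defaults to 1 Å — a value the source workflow
does not state, exported per feature so downstream tools can override it.

## Synthetic fixtures

The generator plants a palette fragment (embedded once per SMILES with a
fixed conformer seed) and places reduced rigid residue templates around it:
each template is oriented side-chain-inward along a placement direction and
pulled in until its closest heavy atom sits at an exact gap of 3.2–4.4 Å
from the fragment — inside the 4.5 Å environment radius and outside the
1 Å collision limit by construction. The first three directions subtend
~75°, which at the resulting Cα radii yields chords inside the 8–12 Å
triplet window, guaranteeing at least one qualifying triplet. Environments
hold 6–10 residues: the density needed for a planted fragment to be
"buried" in the filter's sense (mean ≥ 5 protein atoms within 5 Å), i.e.
for fixtures to emulate the enclosed drug pockets the real database
represents. Ground-truth triplets are recomputed by exhaustive C(n,3)
enumeration, independent of the indexed path.

What the fixtures do *not* emulate: real rotamers and backbone geometry,
ligand strain, crystallographic noise, sequence composition of real
pockets, and the chemical diversity of 51k real fragments. Passing tests
therefore demonstrate correctness of the algorithms and their contracts,
not screening enrichment on real targets; the one real-structure benchmark
(triplet count on the deposited CIB1 structure) requires downloading PDB
entry 6OCX to `tests/data/6ocx.pdb`.

The fingerprint-space training fixture draws every cell from N(1, 0.25²)
clipped at zero and adds a constant effect to chosen signal cells of the
true class, giving a closed-form Bayes accuracy Φ(effect·√k/(2σ)) against
which the classifier is judged. A null (effect 0 or shuffled labels, equal
class sizes) must sit at chance; note that with the 1:2 training imbalance
a null classifier legitimately drifts toward the majority prior, so null
checks use balanced sets.

## Problem sizes

The test suite and acceptance script run the decoy-generation contract at
the full training scale (38,791 true FRASEs → 77,582 decoys, about a minute
on one CPU) and everything else at reduced scale: 30–60-FRASE databases
for screening, 600–1,200 fingerprints for classifier checks, 100–200
training epochs where the full 500 add nothing to the property under test.
Defaults in `PipelineConfig` always remain the full published operating
point.

## Known limitations

* Protein atom typing is template-driven and ignores protonation states and
  terminal residues beyond OXT.
* Exact bit-string matching cannot rank near-miss environments; there is no
  fuzzy triplet similarity by design.
* Decoy placement by principal axes is deterministic but chemistry-blind;
  pathological swaps (near-identical fragments) produce near-true decoys
  and soften the training signal slightly.
* The funnel counts of the original CIB1 study (5,362 seeded → 726 → 151)
  depend on the authors' unpublished FRASE database and are reproducible
  here only as logged diagnostics, not assertions.
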