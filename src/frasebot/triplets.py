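"""Residue-triplet fingerprints and the triplet index.

Binding-site environments are compared through triplets of residues whose
Cα atoms form an approximately equilateral triangle with all three edges in
[8, 12] Å (bounds inclusive). Each residue maps to a many-hot 11-bit
property string (charge, H-bonding, aromaticity, hydrophobicity, volume);
the three strings are concatenated in all 3! orders, giving up to six 33-bit
fingerprints per triplet, and the lexicographically smallest serves as an
order-invariant hash key. Two triplets match iff their canonical keys are
equal — a parameter-free exact comparison that a hash index supports.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .structures import STANDARD_RESIDUES, Residue

logger = logging.getLogger(__name__)

# Many-hot 11-bit residue property strings, canonical column order:
#   [positive ionizable, negative ionizable, H-bond acceptor, H-bond donor,
#    aromatic, hydrophobic x3, volume x3]
# The published table prints the ARG/LYS/HIS charge bit under the negative
# column and the ASP/GLU bit under the positive column; the shipped table
# assigns ARG/LYS/HIS -> positive and ASP/GLU -> negative (a consistent
# relabelling that leaves triplet matching invariant). Printed rows verbatim:
#   ALA 000001 0 01 0 0   ARG 010000 0 01 1 1   ASN 001100 0 01 1 0
#   ASP 100000 0 01 1 0   CYS 001101 1 01 1 0   GLU 100000 0 01 1 1
#   GLN 001100 0 01 1 0   GLY 000000 0 00 0 0   HIS 010110 0 01 1 0
#   ILE 000001 1 01 1 0   LEU 000001 1 01 1 0   LYS 010000 0 01 1 1
#   MET 000001 1 11 1 1   PHE 000011 1 11 1 1   PRO 000001 0 01 0 0
#   SER 001100 0 01 1 0   THR 001101 1 01 1 0   TRP 000111 1 01 1 1
#   TYR 001101 1 01 1 1   VAL 000001 1 01 1 0
# (TYR prints aromatic=0; kept verbatim.)
RESIDUE_BITS: dict[str, str] = {
    "ALA": "00000" + "100" + "100",
    "ARG": "10000" + "000" + "111",
    "ASN": "00110" + "000" + "110",
    "ASP": "01000" + "000" + "110",
    "CYS": "00110" + "110" + "110",
    "GLU": "01000" + "000" + "111",
    "GLN": "00110" + "000" + "110",
    "GLY": "00000" + "000" + "000",
    "HIS": "10011" + "000" + "110",
    "ILE": "00000" + "110" + "110",
    "LEU": "00000" + "110" + "110",
    "LYS": "10000" + "000" + "111",
    "MET": "00000" + "111" + "111",
    "PHE": "00001" + "111" + "111",
    "PRO": "00000" + "100" + "100",
    "SER": "00110" + "000" + "110",
    "THR": "00110" + "110" + "110",
    "TRP": "00011" + "110" + "111",
    "TYR": "00110" + "110" + "111",
    "VAL": "00000" + "110" + "110",
}

BITS_PER_RESIDUE = 11
DEFAULT_EDGE_MIN = 8.0
DEFAULT_EDGE_MAX = 12.0


class UntypableResidueError(KeyError):
    """Residue code outside the 20-entry property table."""


def residue_bits(code: str) -> str:
    """The 11-bit many-hot property string for a 3-letter residue code."""
    try:
        return RESIDUE_BITS[code.upper()]
    except KeyError as exc:
        raise UntypableResidueError(code) from exc


@dataclass
class ResidueTriplet:
    """Three residues whose Cα atoms form a qualifying triangle."""

    residues: tuple[Residue, Residue, Residue]
    ca_coords: np.ndarray  # (3, 3) Å

    @property
    def edges(self) -> tuple[float, float, float]:
        c = self.ca_coords
        return (
            float(np.linalg.norm(c[0] - c[1])),
            float(np.linalg.norm(c[1] - c[2])),
            float(np.linalg.norm(c[0] - c[2])),
        )

    def codes(self) -> tuple[str, str, str]:
        return tuple(r.name for r in self.residues)  # type: ignore[return-value]


@dataclass(frozen=True)
class TripletKey:
    """Order-invariant fingerprint of a residue triplet."""

    fps: tuple[str, ...]  # distinct 33-bit permutation strings, sorted
    canonical: str  # lexicographic minimum, the hash key


def triplet_key(triplet: ResidueTriplet | Sequence[str]) -> TripletKey:
    """Six order-permuted concatenations of the residue bit strings.

    Accepts a :class:`ResidueTriplet` or a bare 3-tuple of residue codes.
    Raises :class:`UntypableResidueError` for non-standard residues (such
    triplets are skipped upstream).
    """
    codes = triplet.codes() if isinstance(triplet, ResidueTriplet) else tuple(triplet)
    bits = [residue_bits(c) for c in codes]
    fps = sorted({"".join(p) for p in itertools.permutations(bits)})
    return TripletKey(tuple(fps), fps[0])


def canonical_order(triplet: ResidueTriplet) -> tuple[int, int, int]:
    """The residue permutation attaining the canonical (lexicographically
    smallest) concatenated fingerprint; first such permutation in standard
    enumeration order when bit strings tie. Two triplets with equal canonical
    keys correspond residue-by-residue under their canonical orders."""
    bits = [residue_bits(r.name) for r in triplet.residues]
    best: tuple[str, tuple[int, int, int]] | None = None
    for perm in itertools.permutations(range(3)):
        s = bits[perm[0]] + bits[perm[1]] + bits[perm[2]]
        if best is None or s < best[0]:
            best = (s, perm)  # strict < keeps the first permutation on ties
    assert best is not None
    return best[1]


def enumerate_triplets(
    residues: Sequence[Residue],
    edge_min: float = DEFAULT_EDGE_MIN,
    edge_max: float = DEFAULT_EDGE_MAX,
) -> list[ResidueTriplet]:
    """All residue 3-subsets whose pairwise Cα distances lie in [edge_min,
    edge_max] (inclusive).

    Only the 20 standard residues with a Cα atom participate. Output order is
    deterministic: residues are sorted by (chain, seq) and triplets emitted in
    lexicographic index order.
    """
    eligible = [
        r for r in residues if r.name in STANDARD_RESIDUES and r.c_alpha is not None
    ]
    eligible.sort(key=lambda r: (r.chain, r.seq))
    if len(eligible) < 3:
        return []
    cas = np.array([r.c_alpha for r in eligible])
    tree = cKDTree(cas)
    pairs = tree.query_pairs(edge_max, output_type="ndarray")
    ok_pairs: set[tuple[int, int]] = set()
    neighbors: dict[int, list[int]] = {i: [] for i in range(len(eligible))}
    for i, j in pairs:
        d = float(np.linalg.norm(cas[i] - cas[j]))
        if edge_min <= d <= edge_max:
            a, b = (int(i), int(j)) if i < j else (int(j), int(i))
            ok_pairs.add((a, b))
            neighbors[a].append(b)
    triplets = []
    for i in sorted(neighbors):
        nb = sorted(neighbors[i])
        for x, j in enumerate(nb):
            for k in nb[x + 1:]:
                if (j, k) in ok_pairs:
                    triplets.append(
                        ResidueTriplet(
                            (eligible[i], eligible[j], eligible[k]),
                            cas[[i, j, k]].copy(),
                        )
                    )
    return triplets


@dataclass
class TripletIndex:
    """Hash index from canonical triplet keys to FRASE triplets."""

    entries: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    triplets: dict[tuple[int, int], ResidueTriplet] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    def add(self, frase_id: int, triplet_id: int, triplet: ResidueTriplet) -> None:
        key = triplet_key(triplet).canonical
        self.entries.setdefault(key, []).append((frase_id, triplet_id))
        self.triplets[(frase_id, triplet_id)] = triplet
        self.counts[frase_id] = self.counts.get(frase_id, 0) + 1

    def __len__(self) -> int:
        return sum(len(v) for v in self.entries.values())


def build_index(
    frases: Iterable,
    edge_min: float = DEFAULT_EDGE_MIN,
    edge_max: float = DEFAULT_EDGE_MAX,
) -> TripletIndex:
    """Index every qualifying triplet of every FRASE under its canonical key.

    FRASEs with fewer than three eligible residues contribute zero triplets
    and are counted (``index.counts[frase_id] == 0``).
    """
    index = TripletIndex()
    for frase_id, frase in enumerate(frases):
        index.counts[frase_id] = 0
        tps = enumerate_triplets(frase.environment, edge_min, edge_max)
        for tid, tp in enumerate(tps):
            try:
                index.add(frase_id, tid, tp)
            except UntypableResidueError:
                continue
    hist = {}
    for c in index.counts.values():
        hist[c] = hist.get(c, 0) + 1
    logger.info("triplets per FRASE histogram: %s", dict(sorted(hist.items())))
    return index


@dataclass(frozen=True)
class TripletMatch:
    target_triplet: ResidueTriplet
    frase_id: int
    db_triplet_id: int
    db_triplet: ResidueTriplet


def match_target(
    target_triplets: Sequence[ResidueTriplet], index: TripletIndex
) -> list[TripletMatch]:
    """All (target triplet, database triplet) pairs with equal canonical keys.

    Each pair is reported exactly once; an empty result is valid.
    """
    matches = []
    for tt in target_triplets:
        try:
            key = triplet_key(tt).canonical
        except UntypableResidueError:
            continue
        for frase_id, tid in index.entries.get(key, ()):
            matches.append(TripletMatch(tt, frase_id, tid, index.triplets[(frase_id, tid)]))
    return matches


def save_index(index: TripletIndex, path: str) -> None:
    """Persist an index as JSON (keys, id pairs, Cα coordinates, codes)."""
    payload = {
        "entries": {k: v for k, v in index.entries.items()},
        "triplets": {
            f"{fid}:{tid}": {
                "codes": list(tp.codes()),
                "chains": [r.chain for r in tp.residues],
                "seqs": [r.seq for r in tp.residues],
                "ca": tp.ca_coords.tolist(),
            }
            for (fid, tid), tp in index.triplets.items()
        },
        "counts": index.counts,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_index(path: str) -> TripletIndex:
    with open(path) as fh:
        payload = json.load(fh)
    index = TripletIndex()
    index.entries = {k: [tuple(p) for p in v] for k, v in payload["entries"].items()}
    for key, tp in payload["triplets"].items():
        fid, tid = (int(x) for x in key.split(":"))
        residues = tuple(
            Residue(code, chain, seq)
            for code, chain, seq in zip(tp["codes"], tp["chains"], tp["seqs"])
        )
        index.triplets[(fid, tid)] = ResidueTriplet(residues, np.array(tp["ca"]))
    index.counts = {int(k): v for k, v in payload["counts"].items()}
    return index
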