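"""Turning complexes into FRASEs.

A FRASE is a chemically sound ligand fragment together with every protein
residue that has at least one heavy atom within ``env_radius`` (default
4.5 Å, inclusive) of the fragment. Ligands are first screened for
drug-likeness (Lipinski, a REOS-style reactive-group deny-list, and
structural rules removing peptides, inorganic and phosphorus compounds),
then fragmented by breaking subsets of acyclic single bonds. Alpha atoms
stay attached to cyclic fragments: when a cut bond touches a ring atom, the
atom across the cut is retained by the ring-containing fragment as an
acyclic cap. Only fragments of 50–300 Da (open valences hydrogen-capped)
are kept.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from scipy.spatial import cKDTree

from .structures import ComplexStructure, LigandMolecule, Residue

logger = logging.getLogger(__name__)

#: Elements tolerated in drug-like ligands (phosphorus deliberately absent).
ALLOWED_ELEMENTS = frozenset({"C", "N", "O", "S", "F", "Cl", "Br", "I", "H"})

#: REOS-style deny-list of reactive / undesirable groups. Editable.
REOS_SMARTS: list[tuple[str, str]] = [
    ("aldehyde", "[CX3H1](=O)[#6]"),
    ("michael_acceptor", "[CX3]=[CX3][CX3]=[OX1]"),
    ("alkyl_halide", "[CX4][Cl,Br,I]"),
    ("acyl_halide", "[CX3](=[OX1])[F,Cl,Br,I]"),
    ("epoxide_aziridine", "[OX2r3,NX3r3]1[#6r3][#6r3]1"),
    ("azide", "[NX2]=[NX2+]=[NX1-]"),
    ("isocyanate", "[NX2]=[CX2]=[OX1]"),
    ("nitroso", "[NX2]=[OX1]"),
    ("peroxide", "[OX2][OX2]"),
    ("anhydride", "[CX3](=[OX1])[OX2][CX3](=[OX1])"),
    ("thiol", "[SX2H1]"),
    ("hydrazine", "[NX3][NX3]"),
]

#: Overlapping dipeptide backbone unit; ≥2 matches flags a peptide.
_PEPTIDE_SMARTS = Chem.MolFromSmarts(
    "[NX3][CX4][CX3](=[OX1])[NX3][CX4][CX3](=[OX1])"
)


@dataclass
class LigandFilterConfig:
    """Drug-likeness rules applied before fragmentation."""

    mw_max: float = 500.0  # 600 for screening-library variant
    logp_max: float = 5.0
    hbd_max: int = 5
    hba_max: int = 10
    reos_smarts: list[tuple[str, str]] = field(default_factory=lambda: list(REOS_SMARTS))
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS
    exclude_peptides: bool = True

    def compiled_reos(self) -> list[tuple[str, Chem.Mol]]:
        out = []
        for name, smarts in self.reos_smarts:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"REOS SMARTS does not compile: {name}: {smarts}")
            out.append((name, patt))
        return out


def filter_ligand(
    lig: LigandMolecule | Chem.Mol, cfg: LigandFilterConfig | None = None
) -> tuple[bool, list[str]]:
    """Apply drug-likeness filters; returns (passed, list of violated rules).

    Every violated rule is reported, so the reasons list is deterministic and
    complete. A ligand whose bonds could not be perceived fails with the
    single reason ``"unperceivable"``.
    """
    cfg = cfg or LigandFilterConfig()
    mol = lig.mol if isinstance(lig, LigandMolecule) else lig
    if mol is None:
        return False, ["unperceivable"]
    try:
        Chem.SanitizeMol(Chem.Mol(mol))
    except Exception:  # noqa: BLE001
        return False, ["unperceivable"]

    reasons: list[str] = []
    mw = Descriptors.MolWt(mol)
    if mw > cfg.mw_max:
        reasons.append(f"lipinski_mw>{cfg.mw_max:g}")
    if Descriptors.MolLogP(mol) > cfg.logp_max:
        reasons.append(f"lipinski_logp>{cfg.logp_max:g}")
    if Descriptors.NumHDonors(mol) > cfg.hbd_max:
        reasons.append(f"lipinski_hbd>{cfg.hbd_max}")
    if Descriptors.NumHAcceptors(mol) > cfg.hba_max:
        reasons.append(f"lipinski_hba>{cfg.hba_max}")

    elements = {a.GetSymbol() for a in mol.GetAtoms()}
    if "P" in elements:
        reasons.append("phosphorus")
    bad = elements - cfg.allowed_elements
    if bad - {"P"}:
        reasons.append("inorganic_element:" + ",".join(sorted(bad - {"P"})))
    if "C" not in elements:
        reasons.append("inorganic_no_carbon")
    if cfg.exclude_peptides and len(mol.GetSubstructMatches(_PEPTIDE_SMARTS)) >= 2:
        reasons.append("peptide")
    for name, patt in cfg.compiled_reos():
        if mol.HasSubstructMatch(patt):
            reasons.append(f"reos_{name}")
    return (not reasons), reasons


@dataclass
class Fragment:
    """A ligand fragment with the parent's 3D coordinates.

    ``mol`` carries topology (shared, never mutated); ``coords`` carries the
    per-instance 3D coordinates, so transplanting a fragment into another
    frame copies only the array.
    """

    mol: Chem.Mol
    coords: np.ndarray  # (n_atoms, 3) Å
    attachment_points: tuple[int, ...] = ()
    parent_ligand: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (self.mol.GetNumAtoms(), 3):
            raise ValueError("coords shape must match atom count")

    @property
    def mw(self) -> float:
        """Molecular weight in Da with open valences hydrogen-capped."""
        return Descriptors.MolWt(self.mol)

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Fragment":
        return Fragment(self.mol, self.coords @ rotation.T + translation,
                        self.attachment_points, self.parent_ligand)

    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


@dataclass
class Frase:
    """A fragment in its structural environment."""

    fragment: Fragment
    environment: list[Residue]
    env_radius: float = 4.5
    source: str = ""
    label: str = ""  # "true" | "decoy" | "" (unscored target FRASE)

    def env_coords(self) -> np.ndarray:
        pts = [a.position for r in self.environment for a in r.atoms]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))


def _eligible_cut_bonds(mol: Chem.Mol) -> list[int]:
    """Acyclic single bonds between heavy atoms."""
    out = []
    for b in mol.GetBonds():
        if b.IsInRing() or b.GetBondType() != Chem.BondType.SINGLE:
            continue
        if b.GetBeginAtom().GetAtomicNum() == 1 or b.GetEndAtom().GetAtomicNum() == 1:
            continue
        out.append(b.GetIdx())
    return out


def _build_fragment(
    mol: Chem.Mol,
    coords: np.ndarray,
    atom_ids: frozenset[int],
    alpha: dict[int, int],
    parent_name: str,
) -> Fragment | None:
    """Sub-molecule over ``atom_ids`` plus alpha caps (alpha atom → anchor)."""
    ids = sorted(atom_ids | set(alpha))
    idx_map = {old: new for new, old in enumerate(ids)}
    rw = Chem.RWMol()
    for old in ids:
        src = mol.GetAtomWithIdx(old)
        a = Chem.Atom(src.GetSymbol())
        a.SetFormalCharge(src.GetFormalCharge())
        if old in alpha:
            a.SetIsAromatic(False)  # cap detached from its own ring context
        else:
            a.SetIsAromatic(src.GetIsAromatic())
        rw.AddAtom(a)
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i not in idx_map or j not in idx_map:
            continue
        # an alpha cap bonds only to its anchor
        if i in alpha and alpha[i] != j and j in atom_ids:
            continue
        if j in alpha and alpha[j] != i and i in atom_ids:
            continue
        btype = b.GetBondType()
        if i in alpha or j in alpha:
            btype = Chem.BondType.SINGLE
        rw.AddBond(idx_map[i], idx_map[j], btype)
    frag = rw.GetMol()
    try:
        Chem.SanitizeMol(frag)
    except Exception:  # noqa: BLE001 - unkekulizable cut: reject
        return None
    attach = tuple(sorted(idx_map[a] for a in alpha))
    return Fragment(frag, coords[ids], attach, parent_name)


def fragment_ligand(
    lig: LigandMolecule | Chem.Mol,
    mw_min: float = 50.0,
    mw_max: float = 300.0,
    max_cuts: int = 3,
) -> list[Fragment]:
    """Enumerate chemically sound fragments of a ligand.

    All subsets of at most ``max_cuts`` acyclic single bonds are broken; each
    connected component becomes a candidate fragment. When a cut bond touches
    a ring atom inside a component, the atom across the cut (the alpha atom)
    is retained by that component. Ring bonds are never broken, so every ring
    system stays intact. Duplicates (identical parent atom sets) are removed
    and the 50–300 Da window is applied (H-capped molecular weight). The
    whole molecule counts as the zero-cut fragment.
    """
    if isinstance(lig, LigandMolecule):
        if lig.mol is None:
            return []
        mol, coords, name = lig.mol, lig.coords, lig.name
    else:
        mol = lig
        coords = (
            mol.GetConformer().GetPositions().copy()
            if mol.GetNumConformers()
            else np.zeros((mol.GetNumAtoms(), 3))
        )
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""

    cuttable = _eligible_cut_bonds(mol)
    n_atoms = mol.GetNumAtoms()
    adjacency = [
        (b.GetIdx(), b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
    ]
    ring_atom = [mol.GetAtomWithIdx(i).IsInRing() for i in range(n_atoms)]

    seen: set[frozenset[int]] = set()
    fragments: list[Fragment] = []
    for k in range(0, min(max_cuts, len(cuttable)) + 1):
        for cut in itertools.combinations(cuttable, k):
            cutset = set(cut)
            # connected components of the graph minus the cut bonds
            parent = list(range(n_atoms))

            def find(x: int) -> int:
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            for bid, i, j in adjacency:
                if bid in cutset:
                    continue
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
            comps: dict[int, set[int]] = {}
            for i in range(n_atoms):
                comps.setdefault(find(i), set()).add(i)
            for comp in comps.values():
                alpha: dict[int, int] = {}
                for bid, i, j in adjacency:
                    if bid not in cutset:
                        continue
                    if i in comp and j not in comp and ring_atom[i]:
                        alpha[j] = i
                    elif j in comp and i not in comp and ring_atom[j]:
                        alpha[i] = j
                key = frozenset(comp | set(alpha))
                if key in seen:
                    continue
                seen.add(key)
                frag = _build_fragment(mol, coords, frozenset(comp), alpha, name)
                if frag is not None and mw_min <= frag.mw <= mw_max:
                    fragments.append(frag)
    return fragments


def environment_residues(
    fragment_coords: np.ndarray, residues: Sequence[Residue], env_radius: float
) -> list[Residue]:
    """Residues with any heavy atom within ``env_radius`` (inclusive) of any
    fragment heavy atom."""
    if len(fragment_coords) == 0 or env_radius < 0:
        return []
    tree = cKDTree(fragment_coords)
    out = []
    for r in residues:
        if not r.atoms:
            continue
        d, _ = tree.query(r.coords, k=1)
        if float(np.min(d)) <= env_radius:
            out.append(r)
    return out


def extract_frases(
    cx: ComplexStructure,
    env_radius: float = 4.5,
    filter_cfg: LigandFilterConfig | None = None,
    mw_min: float = 50.0,
    mw_max: float = 300.0,
    max_cuts: int = 3,
) -> list[Frase]:
    """Extract true FRASEs from a complex.

    Each ligand passing :func:`filter_ligand` is fragmented; every retained
    fragment with a non-empty 4.5 Å residue environment yields one FRASE
    labelled ``"true"``. Fragments with empty environments are dropped with a
    warning.
    """
    frases = []
    for lig in cx.ligands:
        ok, reasons = filter_ligand(lig, filter_cfg)
        if not ok:
            logger.info("ligand %s rejected: %s", lig.name, reasons)
            continue
        for frag in fragment_ligand(lig, mw_min, mw_max, max_cuts):
            env = environment_residues(frag.coords, cx.residues, env_radius)
            if not env:
                logger.warning(
                    "fragment of %s has empty environment at %.1f Å; dropped",
                    lig.name, env_radius,
                )
                continue
            frases.append(Frase(frag, env, env_radius, source=cx.pdb_id, label="true"))
    return frases
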