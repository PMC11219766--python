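"""Molecular structure I/O and the internal data model.

Protein–ligand complexes are read from PDB files into a lightweight
:class:`ComplexStructure` (protein residues, ligands, other heteroatoms).
FRASEs — a ligand fragment together with every protein residue having at
least one heavy atom within the environment radius — are serialized to and
from SDF: the fragment occupies the molecule block, the protein environment
is stored in SD data fields (see :data:`FRASE_ENV_FIELD` for the schema).

All geometry is heavy-atom only; hydrogens are dropped on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

logger = logging.getLogger(__name__)

#: Standard 20 amino-acid codes (triplet-eligible residues).
STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: HETATM codes never treated as ligands: waters, common ions, buffers and
#: cryoprotectants. Editable module-level policy.
LIGAND_DENY_LIST = frozenset(
    (
        "HOH DOD WAT "  # waters
        "NA K MG CA ZN MN FE FE2 CU CO NI CD HG CL BR IOD F LI SR CS BA AL "  # ions
        "SO4 PO4 NO3 CO3 ACT FMT CIT TLA MLI OXL "  # buffer anions
        "GOL EDO PEG PGE PG4 P6G MPD DMS BME EOH IPA MOH TRS EPE MES BCT NH4"
    ).split()
)


class StructureFormatError(ValueError):
    """Raised when an input file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no polymer chain."""


@dataclass
class AtomRecord:
    """A single heavy atom."""

    element: str
    position: np.ndarray  # shape (3,), Å
    serial: int = 0
    name: str = ""
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be 3 finite coordinates")


@dataclass
class Residue:
    """An amino-acid residue with its heavy atoms."""

    name: str
    chain: str
    seq: int
    atoms: list[AtomRecord] = field(default_factory=list)

    @property
    def c_alpha(self) -> np.ndarray | None:
        """Cα coordinate, or None if no CA atom is present."""
        for a in self.atoms:
            if a.name == "CA" and a.element == "C":
                return a.position
        return None

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Residue":
        atoms = [
            AtomRecord(a.element, rotation @ a.position + translation, a.serial, a.name,
                       a.occupancy, a.altloc)
            for a in self.atoms
        ]
        return Residue(self.name, self.chain, self.seq, atoms)


@dataclass
class LigandMolecule:
    """A small-molecule ligand: atoms plus a perceived connection table."""

    name: str
    atoms: list[AtomRecord]
    mol: Chem.Mol | None = None  # sanitized RDKit molecule with one 3D conformer

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)


@dataclass
class ComplexStructure:
    """A protein–ligand complex: polymer residues, ligands, other het groups."""

    pdb_id: str
    residues: list[Residue]
    ligands: list[LigandMolecule]
    hetero_other: list[AtomRecord] = field(default_factory=list)

    def protein_coords(self) -> np.ndarray:
        """All protein heavy-atom coordinates, shape (n, 3)."""
        pts = [a.position for r in self.residues for a in r.atoms]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc."""
    by_name: dict[str, list[AtomRecord]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        group.sort(key=lambda a: (-a.occupancy, a.altloc))
        out.append(group[0])
    return out


def _gemmi_atoms(res: gemmi.Residue) -> list[AtomRecord]:
    atoms = []
    for at in res:
        el = at.element.name
        if el in ("H", "D"):
            continue
        atoms.append(
            AtomRecord(
                element=el,
                position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                serial=at.serial,
                name=at.name,
                occupancy=at.occ,
                altloc=at.altloc if at.altloc != "\x00" else "",
            )
        )
    return _resolve_altlocs(atoms)


def _perceive_ligand(name: str, atoms: list[AtomRecord]) -> Chem.Mol | None:
    """Build a sanitized RDKit mol from bare atoms via distance-based bond
    perception. Returns None when perception fails (atoms are kept anyway)."""
    try:
        rw = Chem.RWMol()
        conf = Chem.Conformer(len(atoms))
        for i, a in enumerate(atoms):
            rw.AddAtom(Chem.Atom(a.element))
            conf.SetAtomPosition(i, Point3D(*a.position))
        mol = rw.GetMol()
        mol.AddConformer(conf)
        from rdkit.Chem import rdDetermineBonds

        rdDetermineBonds.DetermineConnectivity(mol)
        Chem.SanitizeMol(mol)
        mol.SetProp("_Name", name)
        return mol
    except Exception:  # noqa: BLE001 - perception is best-effort
        logger.warning("bond perception failed for ligand %s", name)
        return None


def load_complex(path: str, ligand_selector: frozenset[str] | None = None) -> ComplexStructure:
    """Read a PDB file into a :class:`ComplexStructure`.

    Polymer chains become protein residues; HETATM groups become ligands
    unless their het code is on the deny list (waters, ions, buffers), in
    which case their atoms go to ``hetero_other``. Peptide polymer chains are
    never ligands. Altlocs resolve to the highest-occupancy conformer; only
    the first model of multi-model files is used.

    Parameters
    ----------
    path : str
        PDB file path.
    ligand_selector : frozenset of str, optional
        Deny-list of het codes; defaults to :data:`LIGAND_DENY_LIST`.
    """
    deny = LIGAND_DENY_LIST if ligand_selector is None else ligand_selector
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"no model in {path}")
    st.setup_entities()
    model = st[0]

    residues: list[Residue] = []
    ligands: list[LigandMolecule] = []
    other: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            atoms = _gemmi_atoms(res)
            if not atoms:
                continue
            info = gemmi.find_tabulated_residue(res.name)
            is_aa = info is not None and info.is_amino_acid()
            if is_aa:
                residues.append(Residue(res.name, chain.name, res.seqid.num, atoms))
            elif res.name in deny or (info is not None and info.is_water()):
                other.extend(atoms)
            else:
                ligands.append(
                    LigandMolecule(res.name, atoms, _perceive_ligand(res.name, atoms))
                )
    if not residues:
        raise EmptyStructureError(f"no polymer chain in {path}")
    return ComplexStructure(st.name or "unknown", residues, ligands, other)


def _pdb_atom_line(record: str, serial: int, name: str, resname: str, chain: str,
                   seq: int, pos: np.ndarray, element: str, occ: float = 1.0) -> str:
    aname = name if len(name) == 4 else f" {name:<3s}"
    return (
        f"{record:<6s}{serial:>5d} {aname:<4s}{'':1s}{resname:>3s} {chain:1s}"
        f"{seq:>4d}    {pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def write_pdb(cx: ComplexStructure, path: str) -> None:
    """Serialize a complex to a minimal PDB file (ATOM/HETATM/TER/END).

    Round-trips through :func:`load_complex` on coordinates (3 decimals) and
    the residue/ligand partition; occupancies written as 1.00.
    """
    serial = 1
    lines = []
    for r in cx.residues:
        for a in r.atoms:
            lines.append(_pdb_atom_line("ATOM", serial, a.name or a.element,
                                        r.name, r.chain, r.seq, a.position, a.element))
            serial += 1
    lines.append(f"TER   {serial:>5d}")
    serial += 1
    for li, lig in enumerate(cx.ligands):
        code = (lig.name if len(lig.name) <= 3 else "LIG").upper()
        for a in lig.atoms:
            lines.append(_pdb_atom_line("HETATM", serial, a.name or a.element,
                                        code, "X", 900 + li, a.position, a.element))
            serial += 1
    for a in cx.hetero_other:
        lines.append(_pdb_atom_line("HETATM", serial, a.name or a.element,
                                    "HOH", "W", 1000, a.position, a.element))
        serial += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\nEND\n")


# --------------------------------------------------------------------------
# FRASE SDF dialect
# --------------------------------------------------------------------------

#: SD data field holding the protein environment. One line per atom:
#: ``<resname> <chain> <seq> <atom name> <element> <x> <y> <z>``
FRASE_ENV_FIELD = "FRASE_ENV"
FRASE_SOURCE_FIELD = "FRASE_SOURCE"
FRASE_LABEL_FIELD = "FRASE_LABEL"
FRASE_RADIUS_FIELD = "FRASE_ENV_RADIUS"


def _env_to_text(residues: Sequence[Residue]) -> str:
    lines = []
    for r in residues:
        for a in r.atoms:
            lines.append(
                f"{r.name} {r.chain} {r.seq} {a.name or a.element} {a.element} "
                f"{a.position[0]:.4f} {a.position[1]:.4f} {a.position[2]:.4f}"
            )
    return "\n".join(lines)


def _env_from_text(text: str) -> list[Residue]:
    residues: dict[tuple[str, str, int], Residue] = {}
    for line in text.splitlines():
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 8:
            raise ValueError(f"malformed FRASE_ENV line: {line!r}")
        name, chain, seq, aname, el = parts[0], parts[1], int(parts[2]), parts[3], parts[4]
        pos = np.array([float(parts[5]), float(parts[6]), float(parts[7])])
        key = (name, chain, seq)
        if key not in residues:
            residues[key] = Residue(name, chain, seq)
        residues[key].atoms.append(AtomRecord(el, pos, name=aname))
    return list(residues.values())


def fragment_to_mol(fragment) -> Chem.Mol:
    """RDKit mol (with conformer set from the fragment's coordinates)."""
    mol = Chem.Mol(fragment.mol)
    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(fragment.coords):
        conf.SetAtomPosition(i, Point3D(*(float(v) for v in xyz)))
    mol.RemoveAllConformers()
    mol.AddConformer(conf)
    return mol


def write_frase_sdf(frases: Iterable, path: str) -> int:
    """Write FRASEs to an SDF file, one record per FRASE, streaming.

    The ligand fragment is the molecule block; the environment residues,
    provenance and label live in SD data fields. Constant memory: ``frases``
    may be any iterator. Returns the number of records written.
    """
    from .extract import Frase  # local import to avoid cycle

    n = 0
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for fr in frases:
            if fr.fragment.mol.GetNumAtoms() < 1 or not fr.environment:
                raise ValueError("FRASE must have ≥1 fragment atom and ≥1 residue")
            mol = fragment_to_mol(fr.fragment)
            mol.SetProp(FRASE_ENV_FIELD, _env_to_text(fr.environment))
            mol.SetProp(FRASE_SOURCE_FIELD, fr.source or "")
            mol.SetProp(FRASE_LABEL_FIELD, fr.label or "")
            mol.SetProp(FRASE_RADIUS_FIELD, repr(fr.env_radius))
            writer.write(mol)
            n += 1
    finally:
        writer.close()
    return n


def read_frase_sdf(path: str) -> Iterator:
    """Iterate FRASEs from an SDF written by :func:`write_frase_sdf`.

    Malformed records are skipped with a logged warning; the running skip
    count is available as the ``skipped`` attribute of the generator's
    enclosing :class:`FraseReader`. Coordinates round-trip to ≥1e-3 Å.
    """
    reader = FraseReader(path)
    return iter(reader)


class FraseReader:
    """Streaming reader for the FRASE SDF dialect.

    Attributes
    ----------
    skipped : int
        Number of malformed records skipped so far.
    """

    def __init__(self, path: str):
        self.path = str(path)
        self.skipped = 0

    def __iter__(self):
        from .extract import Fragment, Frase

        supplier = Chem.ForwardSDMolSupplier(self.path, sanitize=False, removeHs=False)
        for mol in supplier:
            if mol is None:
                self.skipped += 1
                logger.warning("skipping malformed SDF record in %s", self.path)
                continue
            try:
                try:
                    Chem.SanitizeMol(mol)
                except Exception:  # keep unsanitizable fragments readable
                    mol.UpdatePropertyCache(strict=False)
                env = _env_from_text(mol.GetProp(FRASE_ENV_FIELD))
                if not env:
                    raise ValueError("empty environment")
                coords = mol.GetConformer().GetPositions().copy()
                topo = Chem.Mol(mol)
                topo.RemoveAllConformers()
                frag = Fragment(mol=topo, coords=coords)
                yield Frase(
                    fragment=frag,
                    environment=env,
                    env_radius=float(mol.GetProp(FRASE_RADIUS_FIELD))
                    if mol.HasProp(FRASE_RADIUS_FIELD)
                    else 4.5,
                    source=mol.GetProp(FRASE_SOURCE_FIELD)
                    if mol.HasProp(FRASE_SOURCE_FIELD)
                    else "",
                    label=mol.GetProp(FRASE_LABEL_FIELD)
                    if mol.HasProp(FRASE_LABEL_FIELD)
                    else "",
                )
            except (KeyError, ValueError) as exc:
                self.skipped += 1
                logger.warning("skipping malformed FRASE record: %s", exc)
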