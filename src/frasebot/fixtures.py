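"""Self-contained synthetic inputs with known ground truth.

Every pipeline stage is testable without downloading structures: toy
complexes are built by planting a small-molecule fragment at the origin and
placing reduced rigid residue templates around it at controlled distances,
so environment membership, qualifying Cα triplets, and collision/burial
statistics are all known by construction. Residue templates carry Cα plus a
few representative heavy atoms — enough for distance rules and protein atom
typing; rotamer realism is out of scope.

Fingerprint-level training fixtures are generated directly in feature space
(:func:`make_separable_training_set`) with a closed-form Bayes accuracy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .extract import Fragment, Frase
from .structures import AtomRecord, ComplexStructure, Residue

# Reduced residue templates: atom name, element, local coordinates (Å).
# Backbone in a fixed local frame, side chain extending along -z ("inward"
# after placement). Geometry is idealised, not rotamer-accurate.
_TEMPLATES: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLY": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
    ],
    "ALA": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
    ],
    "SER": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("OG", "O", (0.0, -0.6, -2.4)),
    ],
    "VAL": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("CG1", "C", (-0.3, -0.8, -2.4)),
        ("CG2", "C", (2.0, -0.7, -1.4)),
    ],
    "ASP": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("CG", "C", (0.0, -0.5, -2.5)),
        ("OD1", "O", (-1.1, 0.0, -2.7)),
        ("OD2", "O", (0.7, -0.7, -3.5)),
    ],
    "LYS": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("CG", "C", (0.0, -0.5, -2.5)),
        ("CD", "C", (0.6, -1.3, -3.6)),
        ("CE", "C", (0.1, -0.9, -5.0)),
        ("NZ", "N", (0.7, -1.7, -6.1)),
    ],
    "PHE": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("CG", "C", (0.0, -0.5, -2.4)),
        ("CD1", "C", (-1.2, -1.0, -2.9)),
        ("CD2", "C", (0.7, 0.4, -3.2)),
        ("CE1", "C", (-1.7, -0.6, -4.1)),
        ("CE2", "C", (0.2, 0.8, -4.4)),
        ("CZ", "C", (-1.0, 0.3, -4.9)),
    ],
    "LEU": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("CG", "C", (0.0, -0.5, -2.5)),
        ("CD1", "C", (-1.5, -0.6, -2.6)),
        ("CD2", "C", (0.6, -1.4, -3.6)),
    ],
    "THR": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("OG1", "O", (0.0, -0.6, -2.4)),
        ("CG2", "C", (2.0, -0.8, -1.2)),
    ],
    "GLU": [
        ("N", "N", (-1.46, 0.0, 0.6)),
        ("CA", "C", (0.0, 0.0, 0.0)),
        ("C", "C", (0.9, 1.2, 0.3)),
        ("O", "O", (2.1, 1.1, 0.4)),
        ("CB", "C", (0.5, -0.9, -1.1)),
        ("CG", "C", (0.0, -0.5, -2.5)),
        ("CD", "C", (0.6, -1.2, -3.7)),
        ("OE1", "O", (1.8, -1.5, -3.7)),
        ("OE2", "O", (-0.1, -1.5, -4.7)),
    ],
}

DEFAULT_PALETTE = (
    "c1ccccc1",  # benzene
    "c1ccncc1",  # pyridine
    "Oc1ccccc1",  # phenol
    "Cc1ccccc1",  # toluene
    "c1ccc2ccccc2c1",  # naphthalene
    "CC(C)c1ccccc1",  # cumene
    "O=C(N)c1ccccc1",  # benzamide
    "c1ccoc1",  # furan
)

_EMBED_CACHE: dict[str, tuple[Chem.Mol, np.ndarray]] = {}


def palette_fragment(smiles: str) -> Fragment:
    """Heavy-atom 3D fragment for a palette SMILES (embedding cached)."""
    if smiles not in _EMBED_CACHE:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"bad palette SMILES: {smiles}")
        molh = Chem.AddHs(mol)
        if AllChem.EmbedMolecule(molh, randomSeed=0xF00D) != 0:
            raise ValueError(f"embedding failed for {smiles}")
        molh = Chem.RemoveHs(molh)
        coords = molh.GetConformer().GetPositions().copy()
        topo = Chem.Mol(molh)
        topo.RemoveAllConformers()
        _EMBED_CACHE[smiles] = (topo, coords - coords.mean(axis=0))
    topo, coords = _EMBED_CACHE[smiles]
    return Fragment(topo, coords.copy(), parent_ligand=smiles)


@dataclass
class FixtureSpec:
    """Parameters of the synthetic FRASE generator."""

    n_frases: int = 10
    residues_per_env: tuple[int, int] = (6, 10)
    fragment_palette: tuple[str, ...] = DEFAULT_PALETTE
    #: directions of the first three residues subtend ~75° pairwise, which at
    #: the placement radii yields Cα chords inside the 8–12 Å triplet window.
    planted_triplet: bool = True
    gap_range: tuple[float, float] = (3.2, 4.4)  # residue-to-fragment gap, Å
    background_residues: int = 0  # extra residues far outside env_radius
    env_radius: float = 4.5
    seed: int = 0


def _rotation_between(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation taking unit vector a to unit vector b (Rodrigues)."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        axis = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(a, [0.0, 1.0, 0.0])
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def _fixture_directions(n: int, rng: np.random.Generator, planted: bool) -> np.ndarray:
    dirs = []
    if planted and n >= 3:
        # three unit vectors with pairwise angle 75 deg
        c = math.cos(math.radians(75.0))
        u0 = np.array([0.0, 0.0, 1.0])
        u1 = np.array([math.sin(math.radians(75.0)), 0.0, c])
        # u2: dot(u2,u0)=c, dot(u2,u1)=c
        x = (c - c * c) / u1[0]
        z = c
        y = math.sqrt(max(1.0 - x * x - z * z, 0.0))
        u2 = np.array([x, y, z])
        dirs = [u0, u1, u2]
    while len(dirs) < n:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(np.dot(v, u) < 0.85 for u in dirs):  # avoid near-duplicates
            dirs.append(v)
    return np.array(dirs[:n])


def _place_residue(
    name: str,
    direction: np.ndarray,
    fragment_coords: np.ndarray,
    gap: float,
    chain: str,
    seq: int,
    spin: np.ndarray | None = None,
) -> Residue:
    """Place a residue template along ``direction`` so that its closest heavy
    atom sits exactly ``gap`` Å from the closest fragment atom, side chain
    pointing inward."""
    template = _TEMPLATES[name]
    local = np.array([xyz for _, _, xyz in template])
    # local side chains extend along -z; map -z onto -direction (inward)
    R = _rotation_between(np.array([0.0, 0.0, -1.0]), -direction)
    if spin is not None:
        R = R @ spin
    pts = local @ R.T + direction * 12.0  # start far out, then pull in
    # iterate: the pull-in direction is not exactly the closest-pair axis
    for _ in range(8):
        dmin = np.min(
            np.linalg.norm(pts[:, None, :] - fragment_coords[None, :, :], axis=2)
        )
        if abs(dmin - gap) < 1e-3:
            break
        pts = pts - direction * (dmin - gap)
    atoms = [
        AtomRecord(el, pts[i], serial=seq * 100 + i, name=aname)
        for i, (aname, el, _) in enumerate(template)
    ]
    return Residue(name, chain, seq, atoms)


def _spin_about_z(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def brute_force_triplets(
    residues: Sequence[Residue], edge_min: float = 8.0, edge_max: float = 12.0
) -> list[tuple[int, int, int]]:
    """Exhaustive qualifying-triplet oracle over all C(n,3) residue subsets
    (independent of the indexed enumeration)."""
    cas = [r.c_alpha for r in residues]
    out = []
    for i, j, k in combinations(range(len(residues)), 3):
        if cas[i] is None or cas[j] is None or cas[k] is None:
            continue
        d = [
            np.linalg.norm(cas[i] - cas[j]),
            np.linalg.norm(cas[j] - cas[k]),
            np.linalg.norm(cas[i] - cas[k]),
        ]
        if all(edge_min <= x <= edge_max for x in d):
            out.append((i, j, k))
    return out


def make_toy_complex(
    spec: FixtureSpec | None = None,
) -> tuple[ComplexStructure, dict]:
    """A toy complex: one planted fragment ringed by residue templates.

    Returns (complex, ground_truth) where ground_truth holds the planted
    fragment, the indices of residues placed inside the environment radius,
    and the exhaustively enumerated qualifying triplets.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.residues_per_env
    if lo < 1 or hi < lo:
        raise ValueError("infeasible residues_per_env range")
    if spec.gap_range[0] > spec.env_radius:
        n_env = 0  # every residue outside the environment by request
    else:
        n_env = int(rng.integers(lo, hi + 1))

    smiles = spec.fragment_palette[int(rng.integers(len(spec.fragment_palette)))]
    frag = palette_fragment(smiles)
    frag = Fragment(frag.mol, frag.coords @ _random_rotation(rng).T,
                    parent_ligand=smiles)

    names = list(_TEMPLATES)
    residues = []
    n_total = max(n_env, lo) if n_env else lo
    dirs = _fixture_directions(n_total + spec.background_residues, rng,
                               spec.planted_triplet)
    seq = 1
    for i in range(n_total):
        gap = (rng.uniform(*spec.gap_range) if n_env else
               rng.uniform(spec.gap_range[0], spec.gap_range[1]))
        name = names[int(rng.integers(len(names)))]
        residues.append(
            _place_residue(name, dirs[i], frag.coords, gap, "A", seq,
                           _spin_about_z(rng.uniform(0, 2 * math.pi)))
        )
        seq += 1
    for b in range(spec.background_residues):
        name = names[int(rng.integers(len(names)))]
        residues.append(
            _place_residue(name, dirs[n_total + b], frag.coords,
                           rng.uniform(12.0, 20.0), "A", seq)
        )
        seq += 1

    lig_mol = Chem.Mol(frag.mol)
    lig_atoms = [
        AtomRecord(a.GetSymbol(), frag.coords[i], serial=i, name=a.GetSymbol())
        for i, a in enumerate(frag.mol.GetAtoms())
    ]
    from .structures import LigandMolecule

    cx = ComplexStructure(
        pdb_id=f"TOY{spec.seed:04d}",
        residues=residues,
        ligands=[LigandMolecule(smiles, lig_atoms, _with_conf(lig_mol, frag.coords))],
    )
    truth = {
        "fragment": frag,
        "env_residue_indices": [
            i for i, r in enumerate(residues)
            if np.min(np.linalg.norm(
                r.coords[:, None, :] - frag.coords[None, :, :], axis=2
            )) <= spec.env_radius
        ],
        "triplets": brute_force_triplets(residues),
    }
    return cx, truth


def _with_conf(mol: Chem.Mol, coords: np.ndarray) -> Chem.Mol:
    from rdkit.Geometry import Point3D

    conf = Chem.Conformer(mol.GetNumAtoms())
    for i, xyz in enumerate(coords):
        conf.SetAtomPosition(i, Point3D(*(float(v) for v in xyz)))
    mol.RemoveAllConformers()
    mol.AddConformer(conf)
    return mol


def make_frase_set(n: int, seed: int = 0, spec: FixtureSpec | None = None) -> list[Frase]:
    """``n`` true FRASEs with varied fragments and environments.

    Lightweight by design (templated residues, cached fragment embeddings):
    tens of thousands of FRASEs generate in bounded time and memory.
    Deterministic for a fixed seed.
    """
    base = spec or FixtureSpec()
    rng = np.random.default_rng(seed)
    names = list(_TEMPLATES)
    lo, hi = base.residues_per_env
    out = []
    for i in range(n):
        smiles = base.fragment_palette[int(rng.integers(len(base.fragment_palette)))]
        frag0 = palette_fragment(smiles)
        R = _random_rotation(rng)
        frag = Fragment(frag0.mol, frag0.coords @ R.T, parent_ligand=smiles)
        n_res = int(rng.integers(lo, hi + 1))
        dirs = _fixture_directions(n_res, rng, base.planted_triplet)
        residues = []
        for k in range(n_res):
            gap = rng.uniform(*base.gap_range)
            residues.append(
                _place_residue(names[int(rng.integers(len(names)))], dirs[k],
                               frag.coords, gap, "A", k + 1,
                               _spin_about_z(rng.uniform(0, 2 * math.pi)))
            )
        out.append(Frase(frag, residues, base.env_radius,
                         source=f"SYN{i:06d}", label="true"))
    return out


def complex_from_frase(frase: Frase, pdb_id: str = "TARGET") -> ComplexStructure:
    """A target 'protein' that literally contains a FRASE's environment —
    the self-seeding fixture for screening tests."""
    return ComplexStructure(pdb_id=pdb_id, residues=list(frase.environment), ligands=[])


def make_separable_training_set(
    n_true: int,
    signal_cells: Sequence[int] = (5, 40, 123, 200, 333),
    effect: float = 2.0,
    seed: int = 0,
    n_decoys: int | None = None,
    sigma: float = 0.25,
    n_features: int = 377,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fingerprint-space training fixture with known Bayes accuracy.

    Both classes draw every cell from N(1, sigma^2) clipped at 0 (fingerprints
    are nonnegative); the true class adds ``effect`` to each signal cell. With
    equal class priors the Bayes-optimal rule thresholds the summed signal
    cells, giving accuracy Phi(effect * sqrt(k) / (2 * sigma)) for k signal
    cells — returned as the third element. ``effect=0`` makes the classes
    identical (null). Deterministic for a fixed seed.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    n_decoys = 2 * n_true if n_decoys is None else n_decoys
    true_fps = np.clip(rng.normal(1.0, sigma, size=(n_true, n_features)), 0, None)
    decoy_fps = np.clip(rng.normal(1.0, sigma, size=(n_decoys, n_features)), 0, None)
    cells = np.asarray(signal_cells, dtype=int)
    true_fps[:, cells] += effect
    bayes = float(norm.cdf(effect * math.sqrt(len(cells)) / (2.0 * sigma)))
    return true_fps, decoy_fps, bayes
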