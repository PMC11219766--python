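"""Nativeness scoring of FRASEs.

A FRASE is summarised by a 377-dimensional interaction fingerprint: for
every pair of a ligand heavy atom i and a protein heavy atom j, the Gaussian
distance weight

    w(d) = exp(-(d - 3)^2)   for d <= 10 Å,   0 otherwise

is accumulated into every cell (m, n) for which atom i carries ligand type m
(29 types) and atom j carries protein type n (13 types). Atoms are many-hot:
an aromatic carbon contributes to both "Aromatic" and "Aromatic Carbon"
rows. The vector index of cell (m, n) is m * 13 + n.

Fingerprints of crystallographic ("true") FRASEs and of decoys — built by
swapping ligand fragments between FRASEs — train a small feed-forward
classifier (377 → 32 ReLU → 16 ReLU → 1 sigmoid; Adam, binary cross-entropy,
500 epochs, batch 50) whose output is the nativeness / fitness score.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .extract import Frase, Fragment
from .structures import Residue, fragment_to_mol

logger = logging.getLogger(__name__)

# --------------------------------------------------------------------------
# Atom-type vocabularies
# --------------------------------------------------------------------------

#: 29 ligand atom types, in fingerprint row order, with their perception
#: SMARTS. Many-hot: an atom may match several rows. Editable.
LIGAND_TYPE_SMARTS: list[tuple[str, str]] = [
    ("Aromatic", "a"),
    ("Hetero", "[!#6;!#1]"),
    ("Halogen", "[F,Cl,Br,I]"),
    ("Negative Ionizable",
     "[$([-1,-2]),$([OX2H1,OX1-][CX3]=[OX1]),$([OX1]=[CX3][OX2H1,OX1-]),"
     "$([SX4](=O)(=O)[OX2H1,OX1-]),$([PX4][OX2H1,OX1-])]"),
    ("Positive Ionizable",
     "[$([+1,+2;!$([N+](=O)[O-])]),$([NX3;H2,H1,H0;!$(NC=[O,S,N]);!$(N[a]);"
     "!$(N=*);!$(N[O,N]);$(N[CX4])]),$([NX3][CX3]=[NX3,NX2])]"),
    ("H-bond Donor",
     "[$([N;H1,H2;!$([N]=*)]),$([NX4;H1,H2,H3]),$([OX2H1]),$([SX2H1]),$([nH])]"),
    ("H-bond Acceptor",
     "[$([OX2;!$(O=N)]),$([OX1;!$(O=[N+]);!$([O-][N+]=O)]),$([OX1-]),"
     "$([nX2;!$([nH])]),$([NX2;$(N=[C,S,P])]),$([NX3;H2,H1,H0;!$(NC=O);!$(N=*);"
     "!$(N[a]);$(N[CX4])]),$([NX1]#*)]"),
    ("Amide Nitrogen", "[NX3;$(N[CX3]=[OX1])]"),
    ("Amine Nitrogen", "[NX3;!$(N[CX3]=[OX1,SX1,NX2]);!$(N[a]);!$(N=*);!$(N[O,N])]"),
    ("Vinyl", "[CX3;$(C=[CX3]);!$(C=O);!a]"),
    ("Carboxylate Oxygen", "[$([OX2H1,OX1-][CX3]=[OX1]),$([OX1]=[CX3][OX2H1,OX1-])]"),
    ("Alcohol Oxygen", "[OX2H1;$(O[CX4])]"),
    ("Nitro Oxygen", "[$([OX1]=[NX3+][OX1-]),$([OX1-][NX3+]=[OX1]),$([OX1]~[NX3](~[OX1]))]"),
    ("Nitro Nitrogen", "[$([NX3+](=[OX1])[OX1-]),$([NX3](=[OX1])=[OX1])]"),
    ("Phosphate Oxygen", "[OX1,OX2;$(O~[#15])]"),
    ("Sulfone Sulfur", "[SX4;$(S(=[OX1])(=[OX1]))]"),
    ("Sulfoxide Sulfur", "[SX3;$(S=[OX1])]"),
    ("Enol Oxygen", "[OX2H1;$(O[CX3]=[CX3])]"),
    ("Imine Nitrogen", "[NX2;$(N=[CX3]);!a]"),
    ("Enamine Nitrogen", "[NX3;$(N[CX3]=[CX3]);!$(N[CX3]=[OX1])]"),
    ("Aromatic Nitrogen", "n"),
    ("Aromatic Oxygen", "o"),
    ("Aromatic Sulfur", "s"),
    ("Aromatic Carbon", "c"),
    ("Aliphatic Carbon", "[C]"),
    ("F", "[F]"),
    ("Cl", "[Cl]"),
    ("Br", "[Br]"),
    ("I", "[I]"),
]

#: 13 protein atom types, in fingerprint column order.
PROTEIN_TYPES: list[str] = [
    "Aromatic",
    "Negative Ionizable",
    "Positive Ionizable",
    "H-bond Donor",
    "H-bond Acceptor",
    "Amide Nitrogen",
    "Amine Nitrogen",
    "Carboxylate Oxygen",
    "Alcohol Oxygen",
    "Imine Nitrogen",
    "Aromatic Nitrogen",
    "Aromatic Carbon",
    "Aliphatic Carbon",
]

N_LIGAND_TYPES = len(LIGAND_TYPE_SMARTS)  # m = 29
N_PROTEIN_TYPES = len(PROTEIN_TYPES)  # n = 13
FINGERPRINT_DIM = N_LIGAND_TYPES * N_PROTEIN_TYPES  # 377

_PT = {name: i for i, name in enumerate(PROTEIN_TYPES)}

# Per-residue, per-atom-name protein typing templates (heavy atoms). Backbone
# entries apply to every residue; side-chain entries below. Untabulated atoms
# (e.g. CYS SG, MET SD) carry no type and contribute nothing.
_BACKBONE: dict[str, tuple[str, ...]] = {
    "N": ("Amide Nitrogen", "H-bond Donor"),
    "CA": ("Aliphatic Carbon",),
    "C": ("Aliphatic Carbon",),
    "O": ("H-bond Acceptor",),
    "OXT": ("H-bond Acceptor", "Carboxylate Oxygen", "Negative Ionizable"),
}

_AROM_C = ("Aromatic", "Aromatic Carbon")
_AROM_N_D = ("Aromatic", "Aromatic Nitrogen", "H-bond Donor")
_AROM_N_A = ("Aromatic", "Aromatic Nitrogen", "H-bond Acceptor", "Imine Nitrogen")
_CARBOXYL_O = ("Carboxylate Oxygen", "Negative Ionizable", "H-bond Acceptor")
_HYDROXYL_O = ("Alcohol Oxygen", "H-bond Donor", "H-bond Acceptor")
_ALIPH = ("Aliphatic Carbon",)

_SIDECHAIN: dict[tuple[str, str], tuple[str, ...]] = {
    **{("ALA", "CB"): _ALIPH},
    **{("VAL", n): _ALIPH for n in ("CB", "CG1", "CG2")},
    **{("LEU", n): _ALIPH for n in ("CB", "CG", "CD1", "CD2")},
    **{("ILE", n): _ALIPH for n in ("CB", "CG1", "CG2", "CD1")},
    **{("PRO", n): _ALIPH for n in ("CB", "CG", "CD")},
    **{("MET", n): _ALIPH for n in ("CB", "CG", "CE")},
    **{("CYS", "CB"): _ALIPH, ("CYS", "SG"): ("H-bond Donor",)},
    **{("SER", "CB"): _ALIPH, ("SER", "OG"): _HYDROXYL_O},
    **{("THR", "CB"): _ALIPH, ("THR", "CG2"): _ALIPH, ("THR", "OG1"): _HYDROXYL_O},
    **{("ASN", "CB"): _ALIPH, ("ASN", "CG"): _ALIPH,
       ("ASN", "OD1"): ("H-bond Acceptor",),
       ("ASN", "ND2"): ("Amide Nitrogen", "H-bond Donor")},
    **{("GLN", n): _ALIPH for n in ("CB", "CG", "CD")},
    **{("GLN", "OE1"): ("H-bond Acceptor",),
       ("GLN", "NE2"): ("Amide Nitrogen", "H-bond Donor")},
    **{("ASP", "CB"): _ALIPH, ("ASP", "CG"): _ALIPH,
       ("ASP", "OD1"): _CARBOXYL_O, ("ASP", "OD2"): _CARBOXYL_O},
    **{("GLU", n): _ALIPH for n in ("CB", "CG", "CD")},
    **{("GLU", "OE1"): _CARBOXYL_O, ("GLU", "OE2"): _CARBOXYL_O},
    **{("LYS", n): _ALIPH for n in ("CB", "CG", "CD", "CE")},
    **{("LYS", "NZ"): ("Positive Ionizable", "H-bond Donor", "Amine Nitrogen")},
    **{("ARG", n): _ALIPH for n in ("CB", "CG", "CD", "CZ")},
    **{("ARG", "NE"): ("Positive Ionizable", "H-bond Donor"),
       ("ARG", "NH1"): ("Positive Ionizable", "H-bond Donor", "Amine Nitrogen"),
       ("ARG", "NH2"): ("Positive Ionizable", "H-bond Donor", "Amine Nitrogen")},
    **{("HIS", "CB"): _ALIPH},
    **{("HIS", n): _AROM_C for n in ("CG", "CD2", "CE1")},
    **{("HIS", "ND1"): _AROM_N_A + ("Positive Ionizable",),
       ("HIS", "NE2"): _AROM_N_D + ("Positive Ionizable",)},
    **{("PHE", "CB"): _ALIPH},
    **{("PHE", n): _AROM_C for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    **{("TYR", "CB"): _ALIPH},
    **{("TYR", n): _AROM_C for n in ("CG", "CD1", "CD2", "CE1", "CE2", "CZ")},
    **{("TYR", "OH"): _HYDROXYL_O},
    **{("TRP", "CB"): _ALIPH},
    **{("TRP", n): _AROM_C
       for n in ("CG", "CD1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")},
    **{("TRP", "NE1"): _AROM_N_D},
}


def type_ligand_atoms(mol: Chem.Mol) -> list[set[int]]:
    """Many-hot ligand type indices per heavy atom (SMARTS-driven)."""
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # noqa: BLE001
        mol.UpdatePropertyCache(strict=False)
        logger.warning("ligand sanitization failed; typing on raw connectivity")
    types: list[set[int]] = [set() for _ in range(mol.GetNumAtoms())]
    for idx, patt in enumerate(_compiled_ligand_patterns()):
        for (aidx,) in mol.GetSubstructMatches(patt, maxMatches=10000):
            types[aidx].add(idx)
    return types


_LIGAND_PATTERNS: list[Chem.Mol] | None = None


def _compiled_ligand_patterns() -> list[Chem.Mol]:
    global _LIGAND_PATTERNS
    if _LIGAND_PATTERNS is None:
        compiled = []
        for name, smarts in LIGAND_TYPE_SMARTS:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"ligand type SMARTS does not compile: {name}")
            compiled.append(patt)
        _LIGAND_PATTERNS = compiled
    return _LIGAND_PATTERNS


def type_protein_atoms(residues: Sequence[Residue]) -> tuple[np.ndarray, list[set[int]]]:
    """(coords, many-hot protein type indices) over all environment atoms."""
    coords = []
    types: list[set[int]] = []
    for r in residues:
        for a in r.atoms:
            coords.append(a.position)
            names = _BACKBONE.get(a.name, ()) if a.name in _BACKBONE else \
                _SIDECHAIN.get((r.name, a.name), ())
            if r.name == "PRO" and a.name == "N":
                names = ("Amide Nitrogen",)  # no H on proline backbone N
            types.append({_PT[n] for n in names})
    arr = np.array(coords, dtype=float) if coords else np.empty((0, 3))
    return arr, types


DISTANCE_CAP = 10.0  # Å
GAUSS_CENTER = 3.0  # Å


def distance_weight(d):
    """Gaussian distance weight: exp(-(d-3)^2) for d <= 10 Å, else 0."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    w = np.where(d <= DISTANCE_CAP, np.exp(-((d - GAUSS_CENTER) ** 2)), 0.0)
    return float(w) if w.ndim == 0 else w


def interaction_fingerprint(
    frase: Frase, ligand_types: list[set[int]] | None = None
) -> np.ndarray:
    """The 377-dim distance-weighted interaction fingerprint of a FRASE.

    Cell (m, n) accumulates w(d_ij) over every ligand-atom/protein-atom pair
    where atom i carries ligand type m and atom j protein type n; index
    l = m * 13 + n. Multi-typed atoms contribute once per matching type pair.
    An empty environment yields the zero vector with a warning.
    """
    if ligand_types is None:
        ligand_types = type_ligand_atoms(fragment_to_mol(frase.fragment))
    lig_coords = frase.fragment.coords
    prot_coords, prot_types = type_protein_atoms(frase.environment)
    fp = np.zeros((N_LIGAND_TYPES, N_PROTEIN_TYPES))
    if len(prot_coords) == 0 or len(lig_coords) == 0:
        logger.warning("empty FRASE side; zero fingerprint")
        return fp.ravel()
    W = distance_weight(cdist(lig_coords, prot_coords))
    ii, jj = np.nonzero(W)
    for i, j in zip(ii.tolist(), jj.tolist()):
        w = W[i, j]
        for m in ligand_types[i]:
            for n in prot_types[j]:
                fp[m, n] += w
    return fp.ravel()


# --------------------------------------------------------------------------
# Decoys
# --------------------------------------------------------------------------


@dataclass
class DecoySpec:
    """Decoy-generation policy: fragments swapped between true FRASEs."""

    decoys_per_frase: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.decoys_per_frase < 1:
            raise ValueError("decoys_per_frase must be >= 1")


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Right-handed principal axes with a deterministic sign convention
    (largest-magnitude component of each axis made positive)."""
    c = coords - coords.mean(axis=0)
    cov = c.T @ c
    _, vecs = np.linalg.eigh(cov)
    axes = vecs[:, ::-1].T  # rows: major, middle, minor
    for k in range(3):
        j = int(np.argmax(np.abs(axes[k])))
        if axes[k, j] < 0:
            axes[k] = -axes[k]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def place_like(donor: Fragment, recipient: Fragment) -> Fragment:
    """Re-pose ``donor`` onto ``recipient``'s location: centroids coincide and
    principal axes align (deterministic sign convention); no minimisation."""
    if donor.mol.GetNumAtoms() < 2:
        return Fragment(donor.mol, recipient.centroid()[None, :].copy(),
                        donor.attachment_points, donor.parent_ligand)
    A = _principal_axes(donor.coords)
    B = _principal_axes(recipient.coords)
    R = B.T @ A
    moved = (donor.coords - donor.centroid()) @ R.T + recipient.centroid()
    return Fragment(donor.mol, moved, donor.attachment_points, donor.parent_ligand)


def make_decoys(frases: Sequence[Frase], spec: DecoySpec | None = None) -> list[Frase]:
    """Decoy FRASEs by swapping fragments between true FRASEs.

    For each input FRASE, ``decoys_per_frase`` donors are drawn (seeded RNG,
    never the FRASE itself) and re-posed into its environment by centroid and
    principal-axis alignment; the environment is unchanged and the label set
    to ``"decoy"``. Output count = decoys_per_frase × len(frases).
    """
    spec = spec or DecoySpec()
    if len(frases) < 2:
        raise ValueError("cannot swap fragments: need at least 2 FRASEs")
    rng = np.random.default_rng(spec.seed)
    decoys = []
    n = len(frases)
    for i, fr in enumerate(frases):
        for _ in range(spec.decoys_per_frase):
            j = int(rng.integers(0, n - 1))
            if j >= i:
                j += 1  # exclude self-draw
            frag = place_like(frases[j].fragment, fr.fragment)
            decoys.append(Frase(frag, fr.environment, fr.env_radius,
                                source=fr.source, label="decoy"))
    return decoys


def split_ids(ids: Sequence, n_train: int, seed: int = 0) -> tuple[list, list]:
    """Disjoint train/validation split: n_train ids drawn at random, the rest
    validate. No id appears in both halves."""
    if n_train > len(ids):
        raise ValueError("n_train exceeds population")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    train = [ids[i] for i in perm[:n_train]]
    valid = [ids[i] for i in perm[n_train:]]
    return train, valid


# --------------------------------------------------------------------------
# Nativeness classifier: 377 -> 32 -> 16 -> 1 feed-forward net
# --------------------------------------------------------------------------


@dataclass
class TrainConfig:
    epochs: int = 500
    batch_size: int = 50
    learning_rate: float = 1e-3
    seed: int = 0
    hidden: tuple[int, int] = (32, 16)


class NativenessModel:
    """Feed-forward nativeness classifier over interaction fingerprints.

    Architecture: input 377 → 32 (ReLU) → 16 (ReLU) → 1 (sigmoid), trained
    with Adam on binary cross-entropy; mini-batches of 50 over 500 epochs by
    default. Deterministic for a fixed seed. ``fit`` returns the model itself
    with the training curve in ``history``.
    """

    def __init__(self, n_features: int = FINGERPRINT_DIM,
                 config: TrainConfig | None = None):
        self.config = config or TrainConfig()
        self.n_features = n_features
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        self.history: list[float] = []
        self._init_weights()

    def _init_weights(self) -> None:
        rng = np.random.default_rng(self.config.seed)
        sizes = [self.n_features, *self.config.hidden, 1]
        self.weights = [
            rng.normal(0.0, np.sqrt(2.0 / sizes[i]), size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]

    def _forward(self, X: np.ndarray):
        acts = [X]
        h = X
        for k in range(len(self.weights) - 1):
            h = np.maximum(h @ self.weights[k] + self.biases[k], 0.0)
            acts.append(h)
        z = h @ self.weights[-1] + self.biases[-1]
        # |z| capped at 36 so the sigmoid stays strictly inside (0, 1) in
        # float64 arithmetic
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -36, 36)))
        acts.append(p)
        return acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Nativeness scores in (0, 1)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self._forward(X)[-1].ravel()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NativenessModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate single-class training set")
        cfg = self.config
        rng = np.random.default_rng(cfg.seed + 1)
        m = [np.zeros_like(w) for w in self.weights] + [np.zeros_like(b) for b in self.biases]
        v = [np.zeros_like(w) for w in self.weights] + [np.zeros_like(b) for b in self.biases]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        n = len(X)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = X[idx], y[idx]
                acts = self._forward(xb)
                p = np.clip(acts[-1].ravel(), 1e-12, 1 - 1e-12)
                epoch_loss += float(
                    -np.sum(yb * np.log(p) + (1 - yb) * np.log(1 - p))
                )
                # backprop; dL/dz for sigmoid+BCE is (p - y)
                delta = (acts[-1] - yb[:, None]) / len(xb)
                grads_w, grads_b = [], []
                for k in range(len(self.weights) - 1, -1, -1):
                    grads_w.append(acts[k].T @ delta)
                    grads_b.append(delta.sum(axis=0))
                    if k > 0:
                        delta = (delta @ self.weights[k].T) * (acts[k] > 0)
                grads_w.reverse()
                grads_b.reverse()
                step += 1
                params = self.weights + self.biases
                grads = grads_w + grads_b
                for p_i, (param, g) in enumerate(zip(params, grads)):
                    m[p_i] = beta1 * m[p_i] + (1 - beta1) * g
                    v[p_i] = beta2 * v[p_i] + (1 - beta2) * g * g
                    mh = m[p_i] / (1 - beta1 ** step)
                    vh = v[p_i] / (1 - beta2 ** step)
                    param -= cfg.learning_rate * mh / (np.sqrt(vh) + eps)
            self.history.append(epoch_loss / n)
        return self

    # -- persistence: JSON header + flat weight blob ------------------------

    def save(self, path: str) -> None:
        """Portable format: JSON with hyperparameters and base-10 repr-exact
        weight lists (text only, reload-identical)."""
        payload = {
            "n_features": self.n_features,
            "hidden": list(self.config.hidden),
            "epochs": self.config.epochs,
            "batch_size": self.config.batch_size,
            "learning_rate": self.config.learning_rate,
            "seed": self.config.seed,
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "NativenessModel":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = TrainConfig(
            epochs=payload["epochs"],
            batch_size=payload["batch_size"],
            learning_rate=payload["learning_rate"],
            seed=payload["seed"],
            hidden=tuple(payload["hidden"]),
        )
        model = cls(payload["n_features"], cfg)
        model.weights = [np.array(w) for w in payload["weights"]]
        model.biases = [np.array(b) for b in payload["biases"]]
        return model


def train_model(
    true_fps: np.ndarray,
    decoy_fps: np.ndarray,
    config: TrainConfig | None = None,
) -> NativenessModel:
    """Train the nativeness classifier on true (label 1) vs decoy (label 0)
    fingerprints. Class imbalance is left uncorrected (plain BCE)."""
    true_fps = np.atleast_2d(true_fps)
    decoy_fps = np.atleast_2d(decoy_fps)
    if len(true_fps) < 1 or len(decoy_fps) < 1:
        raise ValueError("need at least one example per class")
    X = np.vstack([true_fps, decoy_fps])
    y = np.concatenate([np.ones(len(true_fps)), np.zeros(len(decoy_fps))])
    model = NativenessModel(X.shape[1], config)
    return model.fit(X, y)


def score_frase(model: NativenessModel, frase: Frase) -> float:
    """Nativeness score in (0, 1) for a FRASE. A zero fingerprint (no contact
    within 10 Å) is still scored, with a warning."""
    fp = interaction_fingerprint(frase)
    if not fp.any():
        logger.warning("zero interaction fingerprint; score is uninformative")
    return float(model.predict(fp[None, :])[0])
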