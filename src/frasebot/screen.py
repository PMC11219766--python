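"""Seeding database fragments into a target protein.

For every matched residue triplet, the database FRASE is rigidly aligned to
the target by least-squares superposition of the three Cα atoms (proper
rotation only), its fragment is transplanted into the target frame, a new
target-based FRASE is cut at the environment radius, and collision /
buriedness / fitness filters are applied:

* collision: every fragment atom at least ``clash_min`` (1 Å) from protein atoms;
* buriedness: on average at least ``burial_min_mean`` (5) protein heavy atoms
  within ``burial_radius`` (5 Å) of each fragment atom;
* fitness: nativeness score at least ``fitness_min`` (0.4).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .extract import Frase, Fragment, environment_residues
from .structures import ComplexStructure
from .triplets import TripletMatch, canonical_order

logger = logging.getLogger(__name__)


class DegenerateTripletError(ValueError):
    """The three Cα points are (near) collinear; no unique superposition."""


@dataclass
class RigidTransform:
    """Proper rigid motion x -> R x + t with its superposition residual."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation


def superpose_triplet(db_ca: np.ndarray, target_ca: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of two ordered 3-point sets.

    Kabsch algorithm restricted to proper rotations (reflections excluded by
    flipping the sign of the smallest singular vector). The correspondence is
    positional: point i of ``db_ca`` maps onto point i of ``target_ca``.
    """
    P = np.asarray(db_ca, dtype=float)
    Q = np.asarray(target_ca, dtype=float)
    if P.shape != (3, 3) or Q.shape != (3, 3):
        raise ValueError("expected two (3, 3) coordinate arrays")
    for pts in (P, Q):
        v1, v2 = pts[1] - pts[0], pts[2] - pts[0]
        if np.linalg.norm(np.cross(v1, v2)) < 1e-8:
            raise DegenerateTripletError("degenerate triplet")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1))))
    return RigidTransform(R, t, rmsd)


@dataclass
class SeededFragment:
    """A database fragment transplanted into the target frame."""

    fragment: Fragment  # coordinates already in target frame
    frase_id: int
    pose_id: int
    transform: RigidTransform
    min_clash_dist: float = np.inf
    mean_burial: float = 0.0
    fitness: float = float("nan")


@dataclass
class FilterConfig:
    """Thresholds of the collision / buriedness / fitness filters."""

    clash_min: float = 1.0  # Å
    burial_radius: float = 5.0  # Å
    burial_min_mean: float = 5.0  # protein atoms per fragment atom
    fitness_min: float = 0.4

    def __post_init__(self) -> None:
        for name in ("clash_min", "burial_radius", "burial_min_mean", "fitness_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def clash_and_burial(
    coords: np.ndarray, protein_tree: cKDTree, burial_radius: float = 5.0
) -> tuple[float, float]:
    """(min distance to protein, mean protein-atom count within radius)."""
    if protein_tree.n == 0:
        return float("inf"), 0.0
    d, _ = protein_tree.query(coords, k=1)
    counts = protein_tree.query_ball_point(coords, burial_radius, return_length=True)
    return float(np.min(d)), float(np.mean(counts))


def seed_fragment(
    frase: Frase,
    transform: RigidTransform,
    target: ComplexStructure,
    frase_id: int = 0,
    pose_id: int = 0,
    protein_tree: cKDTree | None = None,
    burial_radius: float = 5.0,
) -> SeededFragment:
    """Map the FRASE's fragment into the target frame and recompute the
    collision / buriedness statistics against all target protein heavy atoms
    (statistics are never copied from the source complex)."""
    frag = frase.fragment.transformed(transform.rotation, transform.translation)
    if protein_tree is None:
        protein_tree = cKDTree(target.protein_coords())
    min_clash, mean_burial = clash_and_burial(frag.coords, protein_tree, burial_radius)
    return SeededFragment(frag, frase_id, pose_id, transform, min_clash, mean_burial)


def cut_target_frase(
    sf: SeededFragment, target: ComplexStructure, env_radius: float = 4.5
) -> Frase | None:
    """Cut a new FRASE around the seeded fragment out of the target protein.

    Returns None (counted by the caller) when no target residue falls within
    the environment radius. The label is left unset; scoring assigns fitness.
    """
    env = environment_residues(sf.fragment.coords, target.residues, env_radius)
    if not env:
        return None
    return Frase(sf.fragment, env, env_radius, source=target.pdb_id, label="")


def filter_seeded(
    sfs: list[SeededFragment], cfg: FilterConfig | None = None
) -> list[SeededFragment]:
    """Retain fragments passing collision AND buriedness AND fitness.

    All thresholds are inclusive. Each rejection is logged with its reasons.
    """
    cfg = cfg or FilterConfig()
    survivors = []
    for sf in sfs:
        reasons = []
        if sf.min_clash_dist < cfg.clash_min:
            reasons.append("collision")
        if sf.mean_burial < cfg.burial_min_mean:
            reasons.append("burial")
        if not (sf.fitness >= cfg.fitness_min):  # NaN fitness also rejects
            reasons.append("fitness")
        if reasons:
            logger.debug(
                "pose %d/%d rejected: %s", sf.frase_id, sf.pose_id, ",".join(reasons)
            )
        else:
            survivors.append(sf)
    return survivors


def seed_matches(
    matches: list[TripletMatch],
    frases: list[Frase],
    target: ComplexStructure,
    rmsd_max: float | None = 1.0,
) -> list[SeededFragment]:
    """Seed one pose per triplet match (Kabsch on the matched Cα triplets).

    Bit-string equality does not guarantee geometric congruence, so an
    optional superposition-residual gate ``rmsd_max`` (default 1 Å; pass None
    to disable) drops badly distorted alignments before scoring. Degenerate
    triplets are skipped with a warning.
    """
    tree = cKDTree(target.protein_coords())
    out = []
    pose_counter: dict[int, int] = {}
    for m in matches:
        db_perm = canonical_order(m.db_triplet)
        tg_perm = canonical_order(m.target_triplet)
        try:
            t = superpose_triplet(
                m.db_triplet.ca_coords[list(db_perm)],
                m.target_triplet.ca_coords[list(tg_perm)],
            )
        except DegenerateTripletError:
            logger.warning("degenerate triplet for FRASE %d; skipped", m.frase_id)
            continue
        if rmsd_max is not None and t.rmsd > rmsd_max:
            continue
        pid = pose_counter.get(m.frase_id, 0)
        pose_counter[m.frase_id] = pid + 1
        out.append(
            seed_fragment(frases[m.frase_id], t, target, m.frase_id, pid, tree)
        )
    return out
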