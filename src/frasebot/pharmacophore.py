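"""Pharmacophore assembly from surviving seeded fragments.

Each fragment is abstracted into typed 3D features — H-bond acceptor/donor
(HBA/HBD), positive/negative ionizable (Pos/Neg), aromatic (Ar) and
hydrophobic-aliphatic (Hyd). Features are clustered per type with k-means,
growing k until every cluster's member diameter is at most 3 Å; clusters are
ranked by size (then density), and chosen centroids assemble into a 3D
query with per-feature tolerance radii for downstream library screening.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, RDConfig
from rdkit.Chem import ChemicalFeatures
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .extract import Fragment
from .structures import fragment_to_mol

logger = logging.getLogger(__name__)

FEATURE_TYPES = ("HBA", "HBD", "Pos", "Neg", "Ar", "Hyd")

#: RDKit feature-family → pharmacophore type. Hydrophobe families map to Hyd
#: only when no member atom is aromatic (aromatic rings are covered by Ar).
_FAMILY_MAP = {
    "Acceptor": "HBA",
    "Donor": "HBD",
    "PosIonizable": "Pos",
    "NegIonizable": "Neg",
    "Aromatic": "Ar",
    "Hydrophobe": "Hyd",
    "LumpedHydrophobe": "Hyd",
}

_factory = ChemicalFeatures.BuildFeatureFactory(
    os.path.join(RDConfig.RDDataDir, "BaseFeatures.fdef")
)


@dataclass(frozen=True)
class PharmacophoreFeature:
    ftype: str  # one of FEATURE_TYPES
    position: tuple[float, float, float]  # Å; atom position or group centroid
    source: int = -1  # seeded-fragment id

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")


def perceive_features(fragment: Fragment, source: int = -1) -> list[PharmacophoreFeature]:
    """Typed 3D features of a fragment in the target frame.

    Perception uses substructure-pattern feature definitions; aromatic
    features sit at ring centroids, hydrophobic-aliphatic features at the
    centroid of each contiguous aliphatic group, ionizable features at
    charged-group centroids, HBA/HBD on the donor/acceptor atom. Duplicate
    (type, position) pairs from overlapping patterns are merged.
    """
    mol = fragment_to_mol(fragment)
    try:
        Chem.SanitizeMol(mol)
    except Exception:  # noqa: BLE001
        logger.warning("fragment sanitization failed; no features perceived")
        return []
    feats: dict[tuple[str, tuple[float, float, float]], PharmacophoreFeature] = {}
    for f in _factory.GetFeaturesForMol(mol):
        ftype = _FAMILY_MAP.get(f.GetFamily())
        if ftype is None:
            continue
        if ftype == "Hyd" and any(
            mol.GetAtomWithIdx(i).GetIsAromatic() for i in f.GetAtomIds()
        ):
            continue  # aromatic hydrophobes are represented by Ar
        pos = f.GetPos()
        key = (ftype, (round(pos.x, 3), round(pos.y, 3), round(pos.z, 3)))
        feats.setdefault(
            key, PharmacophoreFeature(ftype, (pos.x, pos.y, pos.z), source)
        )
    return list(feats.values())


@dataclass
class FeatureCluster:
    """A type-pure cluster of features with its geometry statistics."""

    cluster_id: int
    ftype: str
    members: list[PharmacophoreFeature]
    centroid: np.ndarray
    diameter: float  # max pairwise member distance, Å

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def density(self) -> float:
        """size / (1 + mean member-centroid distance); one monotone choice of
        'dense', swappable in configuration."""
        pts = np.array([m.position for m in self.members])
        return self.size / (1.0 + float(np.mean(np.linalg.norm(pts - self.centroid, axis=1))))


def _diameter(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    return float(pdist(points).max())


def cluster_features(
    features: Sequence[PharmacophoreFeature],
    max_diameter: float = 3.0,
    seed: int = 0,
    n_restarts: int = 10,
) -> list[FeatureCluster]:
    """Per-type k-means with k grown from 1 until every cluster's pairwise
    member diameter is ≤ ``max_diameter`` (3 Å default). Fixed seed and 10
    restarts make the partition deterministic. Clusters of all types are
    pooled; ids number them in the returned order."""
    clusters: list[FeatureCluster] = []
    for ftype in FEATURE_TYPES:
        members = [f for f in features if f.ftype == ftype]
        if not members:
            continue
        pts = np.array([f.position for f in members])
        for k in range(1, len(members) + 1):
            km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(pts)
            groups = [np.nonzero(km.labels_ == c)[0] for c in range(k)]
            groups = [g for g in groups if len(g)]
            if all(_diameter(pts[g]) <= max_diameter for g in groups):
                for g in groups:
                    clusters.append(
                        FeatureCluster(
                            cluster_id=len(clusters),
                            ftype=ftype,
                            members=[members[i] for i in g],
                            centroid=pts[g].mean(axis=0),
                            diameter=_diameter(pts[g]),
                        )
                    )
                break
    return clusters


def rank_clusters(clusters: Sequence[FeatureCluster]) -> list[FeatureCluster]:
    """Total deterministic order: size desc, density desc, cluster id asc."""
    return sorted(clusters, key=lambda c: (-c.size, -c.density, c.cluster_id))


@dataclass
class QueryFeature:
    ftype: str
    position: tuple[float, float, float]
    tolerance: float  # matching radius, Å
    cluster_id: int = -1
    rank: int = -1


@dataclass
class PharmacophoreQuery:
    """Typed feature centroids with tolerance radii, exportable for
    downstream screening tools."""

    features: list[QueryFeature] = field(default_factory=list)

    def type_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for f in self.features:
            out[f.ftype] = out.get(f.ftype, 0) + 1
        return out


def build_query(
    clusters: Sequence[FeatureCluster], tolerance: float = 1.0
) -> PharmacophoreQuery:
    """Assemble a query from chosen clusters (the choice itself — e.g. the
    published 2 HBA + 2 Ar pick — is the caller's, typically after visual
    inspection; :func:`rank_clusters` orders the candidates)."""
    if not clusters:
        raise ValueError("cannot build a query from an empty cluster choice")
    ranked_ids = {c.cluster_id: i for i, c in enumerate(rank_clusters(clusters))}
    return PharmacophoreQuery(
        [
            QueryFeature(c.ftype, tuple(float(x) for x in c.centroid), tolerance,
                         c.cluster_id, ranked_ids[c.cluster_id])
            for c in clusters
        ]
    )


def save_query(query: PharmacophoreQuery, path: str) -> None:
    """JSON export: list of {type, xyz, tolerance, cluster, rank}."""
    payload = [
        {"type": f.ftype, "xyz": list(f.position), "tolerance": f.tolerance,
         "cluster": f.cluster_id, "rank": f.rank}
        for f in query.features
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_query(path: str) -> PharmacophoreQuery:
    with open(path) as fh:
        payload = json.load(fh)
    return PharmacophoreQuery(
        [
            QueryFeature(d["type"], tuple(d["xyz"]), d["tolerance"],
                         d.get("cluster", -1), d.get("rank", -1))
            for d in payload
        ]
    )


def export_query_text(query: PharmacophoreQuery, path: str) -> None:
    """Generic pharmacophore text format: one ``TYPE x y z tolerance`` line
    per feature, importable by common screening front-ends."""
    with open(path, "w") as fh:
        for f in query.features:
            fh.write(
                f"{f.ftype} {f.position[0]:.3f} {f.position[1]:.3f} "
                f"{f.position[2]:.3f} {f.tolerance:.2f}\n"
            )
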