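"""Pipeline configuration: every stage threshold in one place.

Defaults are the operating point of the published workflow this package
implements: 4.5 Å environments, 8–12 Å triplet edges, 1 Å collision
clearance, 5 protein atoms within 5 Å buriedness, 0.4 fitness, 3 Å feature
cluster diameter, two decoys per true FRASE, and a 32/16-node classifier
trained for 500 epochs with batches of 50.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field


@dataclass
class PipelineConfig:
    env_radius: float = 4.5  # Å
    triplet_edge_min: float = 8.0  # Å
    triplet_edge_max: float = 12.0  # Å
    rmsd_max: float = 1.0  # Å gate on triplet superposition residual
    clash_min: float = 1.0  # Å
    burial_radius: float = 5.0  # Å
    burial_min_mean: float = 5.0  # protein atoms per fragment atom
    fitness_min: float = 0.4
    cluster_max_diameter: float = 3.0  # Å
    feature_tolerance: float = 1.0  # Å query matching radius
    decoys_per_frase: int = 2
    fragment_mw_min: float = 50.0  # Da
    fragment_mw_max: float = 300.0  # Da
    affinity_max_nm: float = 100.0  # K_D/K_i/IC50/EC50 cap for "high affinity"
    hidden_nodes: tuple[int, int] = (32, 16)
    epochs: int = 500
    batch_size: int = 50
    n_query_features: int = 4  # default centroid pick size
    seed: int = 0

    def hash(self) -> str:
        """Stable digest recorded in all pipeline outputs."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        cfg = cls(**{k: v for k, v in data.items()})
        if isinstance(cfg.hidden_nodes, list):
            cfg.hidden_nodes = tuple(cfg.hidden_nodes)
        return cfg
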