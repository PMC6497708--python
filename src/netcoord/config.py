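"""Run configuration for the synthetic-experiment pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import yaml

from .game import PayoffScheme, EXPERIMENT
from .networks import (
    CENTRALIZED,
    CLUSTERED,
    EXPERIMENT_EDGES,
    EXPERIMENT_NODES,
    RANDOM,
    ParameterError,
)

NETWORK_CLASSES = (RANDOM, CLUSTERED, CENTRALIZED)


@dataclass
class RunConfig:
    """Parameters of a full synthetic study.

    Defaults mirror the experimental design: 12 sessions of 20 subjects,
    three 20-node / 38-edge networks per session played for 20 rounds, 10
    players of each type, 10/8/0 stakes; the model side uses 100 replicates
    and learning rate 0.5, and the synthetic subjects deviate from the myopic
    best reply on 4% of decisions.
    """

    n_nodes: int = EXPERIMENT_NODES
    target_edges: int = EXPERIMENT_EDGES
    rounds: int = 20
    sessions: int = 12
    replicates: int = 100
    noise_rate: float = 0.04
    learning_rate: float = 0.5
    last_k: int = 5
    seed: int = 1
    payoffs: tuple[float, float, float] = (10, 8, 0)
    sw_lattice_neighbors: int = 4
    sw_rewire_prob: float = 0.1
    ba_attach_count: int = 2
    round1_noise: bool = True
    out_dir: str = "netcoord_out"

    def __post_init__(self) -> None:
        if not 0 <= self.noise_rate <= 1:
            raise ParameterError("noise_rate must be in [0, 1]")
        if not 0 < self.learning_rate <= 1:
            raise ParameterError("learning_rate must be in (0, 1]")
        if self.rounds < self.last_k:
            raise ParameterError("rounds must be >= last_k")
        if self.n_nodes % 2 != 0:
            raise ParameterError("n_nodes must be even for a balanced type assignment")
        for name in ("rounds", "sessions", "replicates", "last_k"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be >= 1")
        self.payoffs = tuple(self.payoffs)  # type: ignore[assignment]
        self.scheme  # validates ordering

    @property
    def scheme(self) -> PayoffScheme:
        return PayoffScheme(*self.payoffs)

    @property
    def per_type(self) -> int:
        return self.n_nodes // 2

    def to_dict(self) -> dict:
        d = asdict(self)
        d["payoffs"] = list(self.payoffs)
        return d

    def config_hash(self) -> str:
        """Stable short hash identifying the configuration in manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**data)

    def quick(self) -> "RunConfig":
        """A scaled-down variant (3 sessions, 20 replicates) for smoke runs."""
        d = self.to_dict()
        d.update(sessions=3, replicates=20)
        return RunConfig(**d)
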