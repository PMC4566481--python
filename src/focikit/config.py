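"""Run configuration, seed management and provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Any, Optional

import numpy as np
import yaml

__all__ = ["RunConfig", "derive_seed", "config_hash"]


def derive_seed(master_seed: int, *path) -> int:
    """Deterministic sub-seed for a named stage; independent of the order
    stages run in.  Strings are folded to stable integers."""
    keys = [int(master_seed) & 0x7FFFFFFF]
    for p in path:
        if isinstance(p, str):
            keys.append(int.from_bytes(
                hashlib.sha256(p.encode()).digest()[:4], "big"))
        else:
            keys.append(int(p) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(keys).generate_state(1)[0] & 0x7FFFFFFF)


def config_hash(obj: Any) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    canon = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


@dataclass
class RunConfig:
    """Configuration for an end-to-end pipeline run.

    Stage blocks are plain dicts so YAML configs round-trip unchanged;
    every stochastic stage derives its seed from ``seed`` via
    :func:`derive_seed`.
    """

    seed: int = 0
    outdir: str = "focikit_out"
    dataset_path: Optional[str] = None       # load instead of generate
    variants: list[int] = field(default_factory=lambda: list(range(1, 21)))
    design: dict = field(default_factory=dict)       # n_cells, ...
    bounds: dict = field(default_factory=dict)       # per-parameter (lo, hi)
    use_study_bounds: bool = True
    optimizer: dict = field(default_factory=dict)    # population, ...
    selection: dict = field(default_factory=dict)    # cutoff, replicates
    crossval: dict = field(default_factory=dict)     # enabled, variant_id
    profile: dict = field(default_factory=dict)      # parameters, n_points
    robustness: dict = field(default_factory=dict)   # rel_width, n_samples
    err: dict = field(default_factory=dict)          # rule, doses
    budget_scale: float = 1.0

    def __post_init__(self) -> None:
        bad = [v for v in self.variants if not 1 <= int(v) <= 20]
        if bad:
            raise ValueError(f"unknown variant id(s) {bad}; legal ids are 1-20")

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        return config_hash(self.to_dict())

    def stage_seed(self, stage: str, *extra) -> int:
        return derive_seed(self.seed, stage, *extra)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
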