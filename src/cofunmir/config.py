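"""Runtime configuration: every tunable the method exposes, with defaults."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class Config:
    alpha: float = 0.8          # convex weight of the functional similarity part
    lam: int = 5                # sequence-order correlation depth (lambda)
    w: float = 0.05             # weight factor of the order-effect terms
    mode: str = "sqrt"          # pair-kernel mode: average | sqrt | centre
    c: float = 1.0              # SVM regularization constant
    fc_threshold: float = 0.05  # |log2 FC| below which a miRNA is 'flat'
    min_diseases: int = 10      # shared-disease threshold for pair ranking
    top_n: int = 3000           # predicted edges added at reconstruction
    n_models: int = 100         # ensemble size
    top_targets: int = 10       # targets reported per ranked pair
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path) -> "Config":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
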