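"""Run configuration: training hyperparameters and (de)serialisation.

The defaults are the published training recipe for this architecture:
batch 32, 200 epochs, pixelwise binary cross-entropy, Adam with
beta1 = 0.99 (as printed, higher than the conventional 0.9 — override via
``beta1`` if desired), beta2 = 0.999, learning rate 1e-3 and weight decay
5e-4 (decoupled by default; set ``decoupled_weight_decay: false`` for
classic L2).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class TrainConfig:
    batch_size: int = 32
    epochs: int = 200
    learning_rate: float = 1e-3
    beta1: float = 0.99
    beta2: float = 0.999
    weight_decay: float = 5e-4
    decoupled_weight_decay: bool = True
    val_fraction: float = 0.1
    threshold: float = 0.5
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown train-config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> dict:
    """Load a JSON or YAML run config with sections {data, network, train, eval}."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def save_config(cfg: dict, path):
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(cfg, indent=2))
    else:
        path.write_text(yaml.safe_dump(cfg, sort_keys=False))
    return path
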