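"""Run configuration: a serializable schema tying the data manifest, network
spec, split and training hyperparameters together.  Every run writes a
resolved copy of its configuration so the output directory is self-describing.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

from .network import CHANNELS, AutoencoderSpec, Conv1DSpec, FusionSpec, GCNSpec, NetworkSpec
from .train_eval import TrainingConfig


class RunConfig(BaseModel):
    """Validated, round-trippable configuration of a single run."""

    manifest: str | None = None
    out_dir: str = "runs/run"
    seed: int = 0
    split_mode: str = "mixed"
    ratios: tuple[int, int, int] = (8, 1, 1)

    channels: tuple[str, ...] = CHANNELS
    lr: float = 1e-3
    epochs: int = 30
    batch_size: int | None = 256
    cne_pretrain_epochs: int = 20
    cne_lr: float = 1e-3
    finetune_cne: bool = True
    dropout: float = 0.1
    fusion_hidden: tuple[int, ...] = (1024, 512, 128)

    @field_validator("channels")
    @classmethod
    def _known_channels(cls, v):
        unknown = set(v) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels {sorted(unknown)}")
        return tuple(v)

    @field_validator("split_mode")
    @classmethod
    def _known_mode(cls, v):
        if v not in ("mixed", "drug_blind", "cell_blind"):
            raise ValueError(f"unknown split mode {v!r}")
        return v

    def to_training_config(self) -> TrainingConfig:
        spec = NetworkSpec(
            channels=tuple(c for c in CHANNELS if c in self.channels),
            conv=Conv1DSpec(), gcn=GCNSpec(), autoencoder=AutoencoderSpec(),
            fusion=FusionSpec(hidden=tuple(self.fusion_hidden), dropout=self.dropout))
        return TrainingConfig(
            network=spec, lr=self.lr, epochs=self.epochs, batch_size=self.batch_size,
            cne_pretrain_epochs=self.cne_pretrain_epochs, cne_lr=self.cne_lr,
            finetune_cne=self.finetune_cne)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=False)
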