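"""Structured run configuration with strict schema validation."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict

from .network import EncoderConfig
from .training import TrainConfig

__all__ = ["ModelSection", "ObjectivesSection", "TrainingSection",
           "IOSection", "RunConfig", "load_config", "config_hash"]

_STRICT = ConfigDict(extra="forbid")


class ModelSection(BaseModel):
    model_config = _STRICT

    d_model: int = 128
    n_heads: int = 4
    n_layers: int = 2
    k: int = 2
    alpha_init: float = 0.1
    beta_init: float = 1.0
    transformer_layers: int = 2
    dropout: float = 0.0
    message_rule: str = "modulated_div"
    laplacian: str = "normalized"
    use_HF: bool = True
    use_LF: bool = True
    use_MA: bool = True
    use_PT: bool = True


class ObjectivesSection(BaseModel):
    model_config = _STRICT

    gamma: float = 0.1
    epsilon: float = 1.0e-8
    tau: float = 0.1
    lambda_contrastive: float = 0.1
    beta_cb: float = 0.99
    use_DTW: bool = True
    use_CIH: bool = True
    use_CL: bool = True
    mask_fraction: float = 0.15


class TrainingSection(BaseModel):
    model_config = _STRICT

    epochs: int = 100
    batch_size: int = 16
    lr: float = 3.0e-3
    seed: int = 0


class IOSection(BaseModel):
    model_config = _STRICT

    table: str = "fixtures"       # path to a delimited table, or "fixtures"
    smiles_column: str = "smiles"
    id_column: str | None = None
    sep: str = ","
    n_fixture_molecules: int | None = None
    fixture_noise_sd: float = 0.1


class RunConfig(BaseModel):
    model_config = _STRICT

    model: ModelSection = ModelSection()
    objectives: ObjectivesSection = ObjectivesSection()
    training: TrainingSection = TrainingSection()
    io: IOSection = IOSection()

    def encoder_config(self) -> EncoderConfig:
        return EncoderConfig(**self.model.model_dump())

    def train_config(self, seed: int | None = None) -> TrainConfig:
        o = self.objectives
        t = self.training
        return TrainConfig(epochs=t.epochs, batch_size=t.batch_size,
                           lr=t.lr, seed=t.seed if seed is None else seed,
                           use_DTW=o.use_DTW, use_CIH=o.use_CIH,
                           use_CL=o.use_CL, gamma=o.gamma, epsilon=o.epsilon,
                           tau=o.tau, lambda_contrastive=o.lambda_contrastive,
                           beta_cb=o.beta_cb, mask_fraction=o.mask_fraction)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run config; unknown keys are rejected."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
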