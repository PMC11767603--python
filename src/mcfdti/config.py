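"""Model and training configuration.

Hyperparameters the source protocol fixes (learning rate 0.001, batch size 64,
500 epochs, 5-fold CV, conv channels (32, 64, 96) with kernels (4, 6, 8) on the
drug side and (4, 8, 12) on the target side) are the defaults here; everything
the protocol leaves open is an explicit, documented default. ``small()`` presets
scale the architecture down for CPU-sized experiments.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

VARIANTS = (
    "mcf_dti",
    "mscnn_mscnn",
    "mscnn_transformer",
    "mscnn2_mscnn2",
    "mscnn2_mscnn_transformer_s",
    "cnn_transformer",
    "mscnn_mscnn_transformer_c",
)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Channel/kernel triples follow the published protocol; transformer and
    fusion sizes are package defaults (the protocol says only "default
    settings" for those modules).
    """

    # tokenization
    smiles_max_len: int = 100
    protein_max_len: int = 1000
    bpe_max_tokens: int = 545
    bpe_num_merges: int = 1000
    # embeddings
    embed_dim: int = 128
    # drug-side two-branch multi-scale CNN
    drug_conv_channels: tuple[int, int, int] = (32, 64, 96)
    drug_kernel_sizes: tuple[int, int, int] = (4, 6, 8)
    share_drug_branch_weights: bool = False
    # target-side conv path
    target_conv_channels: tuple[int, int, int] = (32, 64, 96)
    target_kernel_sizes: tuple[int, int, int] = (4, 8, 12)
    # target-side transformer path
    d_model: int = 128
    num_heads: int = 8
    num_layers: int = 2
    ffn_dim: int = 256
    # fusion
    fusion_channels: int = 96    # C_f: common width L/G are projected to
    fusion_time_bins: int = 64   # T_f: common length after adaptive pooling
    sfm_reduction: int = 4       # r in d_r = max(2*C_f / r, 4)
    se_reduction: int = 4
    sfm_on_target_LG: bool = False   # apply SFM to (L, G) pre-interaction
    bfim_bilinear: bool = False      # bilinear BFIM variant
    # prediction head
    head_widths: tuple[int, ...] = (512, 128)
    dropout: float = 0.1
    variant: str = "mcf_dti"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; choose from {VARIANTS}")
        if self.d_model % self.num_heads:
            raise ValueError("d_model must be divisible by num_heads")

    @classmethod
    def small(cls) -> "ModelConfig":
        """CPU-sized preset used by the synthetic end-to-end experiments."""
        return cls(
            smiles_max_len=48,
            protein_max_len=120,
            bpe_max_tokens=60,
            bpe_num_merges=100,
            embed_dim=32,
            drug_conv_channels=(16, 32, 48),
            target_conv_channels=(16, 32, 48),
            d_model=32,
            num_heads=4,
            num_layers=1,
            ffn_dim=64,
            fusion_channels=32,
            fusion_time_bins=32,
            head_widths=(128, 32),
        )


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    epochs: int = 500
    folds: int = 5
    seed: int = 0
    decision_threshold: float = 0.5
    pooled_metrics: bool = False  # pool out-of-fold scores instead of fold means
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class RunConfig:
    """Fully resolved configuration for one command invocation."""

    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict[str, Any]:
        d = {**dataclasses.asdict(self.model), **dataclasses.asdict(self.train)}
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_MODEL_KEYS = {f.name: f for f in fields(ModelConfig)}
_TRAIN_KEYS = {f.name: f for f in fields(TrainConfig)}


def _coerce(key: str, value: Any, default: Any) -> Any:
    """Coerce a string override to the type of the default value."""
    if not isinstance(value, str):
        return tuple(value) if isinstance(default, tuple) else value
    if isinstance(default, bool):
        low = value.lower()
        if low in ("true", "1", "yes"):
            return True
        if low in ("false", "0", "no"):
            return False
        raise ValueError(f"cannot parse boolean for {key!r}: {value!r}")
    if isinstance(default, tuple):
        parts = [p for p in value.replace("(", "").replace(")", "").split(",") if p]
        return tuple(int(p) for p in parts)
    if isinstance(default, int) and not isinstance(default, bool):
        return int(value)
    if isinstance(default, float) or default is None and key == "early_stop_patience":
        return float(value) if isinstance(default, float) else int(value)
    return value


def resolve_config(config_file: str | Path | None = None,
                   overrides: dict[str, Any] | None = None) -> RunConfig:
    """Merge defaults, an optional YAML file, and key=value overrides.

    Precedence: overrides > file > defaults. Unknown keys are rejected with a
    closest-match suggestion so typos fail loudly instead of silently using a
    default.
    """
    merged: dict[str, Any] = {}
    if config_file is not None:
        loaded = yaml.safe_load(Path(config_file).read_text())
        if loaded:
            merged.update(loaded)
    if overrides:
        merged.update(overrides)

    model_kwargs: dict[str, Any] = {}
    train_kwargs: dict[str, Any] = {}
    known = list(_MODEL_KEYS) + list(_TRAIN_KEYS)
    for key, value in merged.items():
        if key in _MODEL_KEYS:
            default = getattr(ModelConfig(), key)
            model_kwargs[key] = _coerce(key, value, default)
        elif key in _TRAIN_KEYS:
            default = getattr(TrainConfig(), key)
            train_kwargs[key] = _coerce(key, value, default)
        else:
            hint = difflib.get_close_matches(key, known, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise KeyError(f"unknown config key {key!r}{suggestion}")
    return RunConfig(model=ModelConfig(**model_kwargs),
                     train=TrainConfig(**train_kwargs))
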