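"""Shared fixtures: tiny model configurations and synthetic datasets."""

import numpy as np
import pytest

from mcfdti.config import ModelConfig, TrainConfig
from mcfdti.synthetic import SyntheticSpec, generate_pairs


def tiny_model_config(**overrides) -> ModelConfig:
    """A deliberately minuscule architecture for fast structural tests."""
    base = dict(
        smiles_max_len=24, protein_max_len=40, bpe_max_tokens=24,
        bpe_num_merges=20, embed_dim=8,
        drug_conv_channels=(4, 6, 8), drug_kernel_sizes=(4, 6, 8),
        target_conv_channels=(4, 6, 8), target_kernel_sizes=(4, 8, 12),
        d_model=8, num_heads=2, num_layers=1, ffn_dim=16,
        fusion_channels=8, fusion_time_bins=8, head_widths=(16, 8))
    base.update(overrides)
    return ModelConfig(**base)


def tiny_spec(**overrides) -> SyntheticSpec:
    base = dict(n_drugs=12, n_targets=12,
                smiles_length_range=(10, 24), protein_length_range=(20, 40),
                seed=7)
    base.update(overrides)
    return SyntheticSpec(**base)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_config():
    return tiny_model_config()


@pytest.fixture
def tiny_records():
    records, rule = generate_pairs(tiny_spec(), 60)
    return records


@pytest.fixture
def fast_train_config():
    return TrainConfig(epochs=2, folds=2, seed=5, batch_size=16)
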