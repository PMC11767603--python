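"""Full interaction classifier assembling encoders, fusion and head.

The default architecture: SMILES characters are embedded and run through two
parallel multi-scale conv branches; the protein runs through a conv path
(amino-acid characters) and a transformer path (BPE subwords). Both sides are
projected to a common channel width and pooled to a common number of time
bins; a shared cross-attention block exchanges information between the two
sides; the biased feature interaction module (BFIM) crosses them position-wise;
the selective fusion module (SFM) plus squeeze-and-excitation selects and
re-calibrates channels; and a fully connected head on max-pooled features emits
the interaction probability. Ablation variants gate individual stages.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .autograd import Tensor, concat
from .config import ModelConfig
from .encoders import (
    ConvBranchParams,
    Linear,
    TargetEncoder,
    align_time,
    conv_branch,
    embed,
    encode_drug,
)
from .fusion import (
    BfimParams,
    PredictionHead,
    SfmParams,
    SharedCrossAttention,
    bfim,
    predict,
    se_recalibrate,
    sfm,
)


def variant_flags(variant: str) -> dict[str, object]:
    """Map an architecture-variant name to the stages it enables."""
    return {
        "drug_branches": 2 if variant in (
            "mcf_dti", "mscnn2_mscnn2", "mscnn2_mscnn_transformer_s") else 1,
        # a "plain CNN" drug encoder uses one kernel width at every layer
        "drug_multiscale": variant != "cnn_transformer",
        "target_conv": variant not in ("mscnn_transformer", "cnn_transformer"),
        "target_transformer": variant not in ("mscnn_mscnn", "mscnn2_mscnn2"),
        "fusion": variant == "mcf_dti",
    }


class MCFDTI:
    """Drug–target interaction classifier over tokenized sequence batches."""

    def __init__(self, config: ModelConfig, smiles_vocab_size: int,
                 protein_vocab_size: int, bpe_vocab_size: int, seed: int = 0):
        self.config = config
        self.vocab_sizes = (smiles_vocab_size, protein_vocab_size, bpe_vocab_size)
        self.flags = variant_flags(config.variant)
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(seed + 1)
        c = config

        drug_kernels = c.drug_kernel_sizes if self.flags["drug_multiscale"] else (
            (c.drug_kernel_sizes[1],) * 3)
        self.drug_table = Tensor(
            rng.normal(0.0, 1.0 / np.sqrt(c.embed_dim),
                       (smiles_vocab_size, c.embed_dim)), requires_grad=True)
        self.drug_branch1 = ConvBranchParams(
            rng, c.embed_dim, c.drug_conv_channels, drug_kernels)
        if self.flags["drug_branches"] == 2:
            if c.share_drug_branch_weights:
                self.drug_branch2 = self.drug_branch1
            else:
                self.drug_branch2 = ConvBranchParams(
                    rng, c.embed_dim, c.drug_conv_channels, drug_kernels)
        else:
            self.drug_branch2 = None

        self.target = TargetEncoder(
            rng, protein_vocab_size, bpe_vocab_size, c.embed_dim,
            c.target_conv_channels, c.target_kernel_sizes, c.d_model,
            c.num_heads, c.num_layers, c.ffn_dim, c.bpe_max_tokens,
            c.fusion_channels, c.fusion_time_bins)

        drug_width = self.flags["drug_branches"] * c.drug_conv_channels[-1]
        n_paths = int(self.flags["target_conv"]) + int(self.flags["target_transformer"])
        cf = c.fusion_channels
        if self.flags["fusion"]:
            self.proj_drug = Linear(rng, drug_width, cf)
            self.reduce_target = Linear(rng, n_paths * cf, cf)
            self.cross = SharedCrossAttention(rng, cf)
            self.bfim_params = BfimParams(rng, cf, bilinear=c.bfim_bilinear)
            self.sfm_params = SfmParams(rng, cf, c.sfm_reduction, c.se_reduction)
            head_in = drug_width + 2 * cf
        else:
            self.proj_drug = None
            self.reduce_target = None
            self.cross = None
            self.bfim_params = None
            self.sfm_params = None
            head_in = drug_width + n_paths * cf
        self.head = PredictionHead(rng, head_in, c.head_widths, c.dropout)

    # ------------------------------------------------------------------
    def forward(self, batch: dict[str, np.ndarray], train: bool = False) -> Tensor:
        """Interaction probability for a batch of tokenized pairs, shape (B,)."""
        c = self.config
        if self.drug_branch2 is not None:
            f_drug = encode_drug(batch["drug_idx"], batch["drug_mask"],
                                 self.drug_table, self.drug_branch1,
                                 self.drug_branch2)
        else:
            x = embed(batch["drug_idx"], self.drug_table, batch["drug_mask"])
            f_drug = conv_branch(x, self.drug_branch1)

        l_map, g_map, f_target = self.target(
            batch["prot_idx"], batch["prot_mask"],
            batch["bpe_idx"], batch["bpe_mask"],
            use_local=self.flags["target_conv"],
            use_global=self.flags["target_transformer"])

        if self.flags["fusion"]:
            if c.sfm_on_target_LG:
                # literal reading: select between L and G before interaction
                f_target = se_recalibrate(sfm(l_map, g_map, self.sfm_params),
                                          self.sfm_params)
            d_rep = align_time(self.proj_drug(f_drug), c.fusion_time_bins)
            t_rep = self.reduce_target(f_target)
            a_d, a_t = self.cross(d_rep, t_rep)
            f_cross = bfim(a_d, a_t, self.bfim_params)
            if c.sfm_on_target_LG:
                f_select = f_cross
            else:
                cf = c.fusion_channels
                f_select = se_recalibrate(
                    sfm(f_cross[:, :, :cf], f_cross[:, :, cf:], self.sfm_params),
                    self.sfm_params)
        else:
            f_select = f_target

        return predict(f_drug, f_select, self.head, train=train,
                       rng=self._dropout_rng)

    # ------------------------------------------------------------------
    @property
    def params(self) -> list[Tensor]:
        out = [self.drug_table, *self.drug_branch1.params]
        if self.drug_branch2 is not None and self.drug_branch2 is not self.drug_branch1:
            out += self.drug_branch2.params
        out += self.target.params
        for comp in (self.proj_drug, self.reduce_target, self.cross,
                     self.bfim_params, self.sfm_params):
            if comp is not None:
                out += comp.params
        out += self.head.params
        return out

    # ------------------------------------------------------------------
    def save(self, path: str | Path, meta: dict | None = None) -> None:
        """Write parameters (.npz) plus a JSON sidecar with config and meta."""
        path = Path(path)
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        np.savez(path, **arrays)
        import dataclasses
        sidecar = {
            "config": {k: list(v) if isinstance(v, tuple) else v
                       for k, v in dataclasses.asdict(self.config).items()},
            "vocab_sizes": list(self.vocab_sizes),
            "meta": meta or {},
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> tuple["MCFDTI", dict]:
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg_dict = {k: tuple(v) if isinstance(v, list) else v
                    for k, v in sidecar["config"].items()}
        model = cls(ModelConfig(**cfg_dict), *sidecar["vocab_sizes"])
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz_path) as data:
            params = model.params
            if len(data.files) != len(params):
                raise ValueError("checkpoint does not match this architecture")
            for i, p in enumerate(params):
                arr = data[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError(
                        f"checkpoint parameter {i} has shape {arr.shape}, "
                        f"model expects {p.data.shape} (vocabulary mismatch?)")
                p.data = arr.astype(p.data.dtype)
        return model, sidecar["meta"]


def bce_loss(prob: Tensor, labels: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over a batch of probabilities."""
    clipped = Tensor(np.clip(prob.data, eps, 1.0 - eps))
    # clip only the forward values; route gradients through prob directly
    p = prob + (clipped - Tensor(prob.data))
    y = Tensor(np.asarray(labels, dtype=np.float32))
    losses = -(y * p.log() + (1.0 - y) * (1.0 - p).log())
    return losses.mean()
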