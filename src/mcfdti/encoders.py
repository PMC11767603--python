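"""Drug and target sequence encoders.

The drug encoder embeds SMILES characters and runs two parallel three-layer
multi-scale convolution branches (Conv-ReLU-Conv-ReLU-Conv, 'same' padding)
whose outputs are concatenated along the channel axis. The target encoder runs
two parallel paths over the same protein: a multi-scale convolution path on
amino-acid characters (local features, ``L``) and a transformer path on
byte-pair-encoded subwords (global features, ``G``). Both paths are linearly
projected to a common channel width and adaptively mean-pooled to a common
number of time bins before concatenation, so downstream fusion sees aligned
feature maps.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, conv1d, embedding

BIG_NEG = 1e9  # additive logit penalty that zeroes a softmax entry


# ---------------------------------------------------------------------------
# parameter containers


class Linear:
    """Affine map ``x @ W + b`` applied to the trailing axis."""

    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int,
                 scale: str = "xavier"):
        if scale == "he":
            std = np.sqrt(2.0 / d_in)
        else:
            std = np.sqrt(2.0 / (d_in + d_out))
        self.w = Tensor(rng.normal(0.0, std, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    @property
    def params(self) -> list[Tensor]:
        return [self.w, self.b]


class ConvBranchParams:
    """Three stacked 1-D convolutions with ReLU between (none after the last)."""

    def __init__(self, rng: np.random.Generator, in_channels: int,
                 out_channels: tuple[int, int, int],
                 kernel_sizes: tuple[int, int, int]):
        self.out_channels = tuple(out_channels)
        self.kernel_sizes = tuple(kernel_sizes)
        self.weights: list[Tensor] = []
        self.biases: list[Tensor] = []
        c_in = in_channels
        for k, c_out in zip(kernel_sizes, out_channels):
            std = np.sqrt(2.0 / (k * c_in))
            self.weights.append(
                Tensor(rng.normal(0.0, std, (k, c_in, c_out)), requires_grad=True))
            self.biases.append(Tensor(np.zeros(c_out), requires_grad=True))
            c_in = c_out

    @property
    def params(self) -> list[Tensor]:
        return [*self.weights, *self.biases]


class LayerNorm:
    """Per-position normalization over the channel axis with learned scale/shift."""

    def __init__(self, d: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps).pow(-0.5)
        return centered * inv * self.gamma + self.beta

    @property
    def params(self) -> list[Tensor]:
        return [self.gamma, self.beta]


# ---------------------------------------------------------------------------
# core operations


def embed(indices: np.ndarray, table: Tensor, mask: np.ndarray | None = None,
          ) -> Tensor:
    """Look up embedding rows; optionally zero out padded positions."""
    out = embedding(indices, table)
    if mask is not None:
        out = out * Tensor(mask[..., None])
    return out


def conv_branch(x: Tensor, params: ConvBranchParams) -> Tensor:
    """Conv3(ReLU(Conv2(ReLU(Conv1(x))))) along the time axis."""
    h = conv1d(x, params.weights[0], params.biases[0]).relu()
    h = conv1d(h, params.weights[1], params.biases[1]).relu()
    return conv1d(h, params.weights[2], params.biases[2])


def encode_drug(indices: np.ndarray, mask: np.ndarray, table: Tensor,
                branch1: ConvBranchParams, branch2: ConvBranchParams) -> Tensor:
    """Two parallel multi-scale conv branches over one embedded SMILES batch."""
    x = embed(indices, table, mask)
    f1 = conv_branch(x, branch1)
    f2 = conv_branch(x, branch2)
    if f1.shape[-2] != f2.shape[-2]:
        raise ValueError("drug branches produced different time lengths")
    return concat([f1, f2], axis=-1)


def scaled_dot_attention(q: Tensor, k: Tensor, v: Tensor,
                         key_mask: np.ndarray | None = None,
                         ) -> tuple[Tensor, Tensor]:
    """softmax(QK^T / sqrt(d_k)) V with masked keys excluded.

    ``key_mask`` broadcasts against the key axis of the logits; positions with
    mask 0 receive a large negative logit so their softmax weight vanishes.
    Returns (output, attention weights).
    """
    d_k = q.shape[-1]
    logits = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(d_k))
    if key_mask is not None:
        key_mask = np.asarray(key_mask, dtype=np.float32)
        if not np.all(key_mask.reshape(key_mask.shape[0], -1).any(axis=-1) if
                      key_mask.ndim > 1 else key_mask.any()):
            raise ValueError("attention is undefined when every key is masked")
        penalty = (key_mask - 1.0) * BIG_NEG
        # broadcast over query axis: (..., m) -> (..., 1, m)
        logits = logits + Tensor(penalty[..., None, :])
    attn = logits.softmax(axis=-1)
    return attn @ v, attn


class MultiHeadAttention:
    """Standard multi-head self/cross attention with shared output projection."""

    def __init__(self, rng: np.random.Generator, d_model: int, num_heads: int):
        if d_model % num_heads:
            raise ValueError("d_model must be divisible by num_heads")
        self.num_heads = num_heads
        self.d_k = d_model // num_heads
        self.wq = Linear(rng, d_model, d_model)
        self.wk = Linear(rng, d_model, d_model)
        self.wv = Linear(rng, d_model, d_model)
        self.wo = Linear(rng, d_model, d_model)
        self.last_attn: np.ndarray | None = None

    def _split(self, x: Tensor) -> Tensor:
        b, t, d = x.shape
        return x.reshape(b, t, self.num_heads, self.d_k).swapaxes(1, 2)

    def __call__(self, x: Tensor, key_mask: np.ndarray) -> Tensor:
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        # key mask (B, T) -> (B, 1, T) to broadcast over heads
        out, attn = scaled_dot_attention(q, k, v, key_mask[:, None, :])
        self.last_attn = attn.data
        b, h, t, dk = out.shape
        merged = out.swapaxes(1, 2).reshape(b, t, h * dk)
        return self.wo(merged)

    @property
    def params(self) -> list[Tensor]:
        return [*self.wq.params, *self.wk.params, *self.wv.params, *self.wo.params]


def sinusoidal_positions(max_len: int, d_model: int) -> np.ndarray:
    """Classic fixed sin/cos positional-encoding table of shape (T, d_model)."""
    pos = np.arange(max_len)[:, None].astype(np.float64)
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return pe.astype(np.float32)


class TransformerEncoder:
    """Embedding + positional encoding + stacked self-attention blocks.

    Post-norm residual blocks; padded positions never contribute as attention
    keys. With zero layers the output is just embedding + positional encoding.
    """

    def __init__(self, rng: np.random.Generator, vocab_size: int, d_model: int,
                 num_heads: int, num_layers: int, ffn_dim: int, max_len: int):
        self.table = Tensor(rng.normal(0.0, 1.0 / np.sqrt(d_model),
                                       (vocab_size, d_model)), requires_grad=True)
        self.pe = sinusoidal_positions(max_len, d_model)
        self.layers = []
        for _ in range(num_layers):
            self.layers.append({
                "mha": MultiHeadAttention(rng, d_model, num_heads),
                "ln1": LayerNorm(d_model),
                "ffn1": Linear(rng, d_model, ffn_dim, scale="he"),
                "ffn2": Linear(rng, ffn_dim, d_model),
                "ln2": LayerNorm(d_model),
            })

    def __call__(self, indices: np.ndarray, mask: np.ndarray) -> Tensor:
        if not np.all(mask.any(axis=-1)):
            raise ValueError("cannot encode an entirely padded sequence")
        t = indices.shape[-1]
        x = embed(indices, self.table) + Tensor(self.pe[:t])
        for layer in self.layers:
            x = layer["ln1"](x + layer["mha"](x, mask))
            h = layer["ffn2"](layer["ffn1"](x).relu())
            x = layer["ln2"](x + h)
        return x

    @property
    def params(self) -> list[Tensor]:
        out = [self.table]
        for layer in self.layers:
            out += layer["mha"].params + layer["ln1"].params
            out += layer["ffn1"].params + layer["ffn2"].params + layer["ln2"].params
        return out


# ---------------------------------------------------------------------------
# temporal alignment


def adaptive_pool_matrix(t_in: int, t_out: int) -> np.ndarray:
    """(t_out, t_in) averaging matrix for adaptive mean pooling."""
    p = np.zeros((t_out, t_in), dtype=np.float32)
    for i in range(t_out):
        s = (i * t_in) // t_out
        e = -(-((i + 1) * t_in) // t_out)  # ceil division
        p[i, s:e] = 1.0 / (e - s)
    return p


def align_time(x: Tensor, t_out: int) -> Tensor:
    """Adaptively mean-pool the time axis of (B, T, C) down/up to ``t_out`` bins."""
    p = Tensor(adaptive_pool_matrix(x.shape[-2], t_out))
    return p @ x


class TargetEncoder:
    """Parallel conv (local) + transformer (global) target paths, aligned."""

    def __init__(self, rng: np.random.Generator, char_vocab_size: int,
                 bpe_vocab_size: int, embed_dim: int,
                 conv_channels: tuple[int, int, int],
                 kernel_sizes: tuple[int, int, int], d_model: int,
                 num_heads: int, num_layers: int, ffn_dim: int,
                 bpe_max_tokens: int, fusion_channels: int, fusion_time_bins: int):
        self.char_table = Tensor(rng.normal(0.0, 1.0 / np.sqrt(embed_dim),
                                            (char_vocab_size, embed_dim)),
                                 requires_grad=True)
        self.conv = ConvBranchParams(rng, embed_dim, conv_channels, kernel_sizes)
        self.transformer = TransformerEncoder(
            rng, bpe_vocab_size, d_model, num_heads, num_layers, ffn_dim,
            bpe_max_tokens)
        self.proj_local = Linear(rng, conv_channels[-1], fusion_channels)
        self.proj_global = Linear(rng, d_model, fusion_channels)
        self.t_f = fusion_time_bins

    def __call__(self, char_idx: np.ndarray, char_mask: np.ndarray,
                 bpe_idx: np.ndarray, bpe_mask: np.ndarray,
                 use_local: bool = True, use_global: bool = True,
                 ) -> tuple[Tensor | None, Tensor | None, Tensor]:
        """Return (L, G, F_target) with L, G of shape (B, T_f, C_f).

        Ablation variants may disable either path; F_target concatenates
        whichever paths are active.
        """
        if not (use_local or use_global):
            raise ValueError("at least one target path must be active")
        l_aligned = g_aligned = None
        if use_local:
            x_char = embed(char_idx, self.char_table, char_mask)
            local = conv_branch(x_char, self.conv)
            l_aligned = align_time(self.proj_local(local), self.t_f)
        if use_global:
            glob = self.transformer(bpe_idx, bpe_mask)
            glob = glob * Tensor(bpe_mask[..., None])  # drop padded rows pre-pooling
            g_aligned = align_time(self.proj_global(glob), self.t_f)
        parts = [p for p in (l_aligned, g_aligned) if p is not None]
        f_target = parts[0] if len(parts) == 1 else concat(parts, axis=-1)
        return l_aligned, g_aligned, f_target

    @property
    def params(self) -> list[Tensor]:
        return [self.char_table, *self.conv.params, *self.transformer.params,
                *self.proj_local.params, *self.proj_global.params]
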