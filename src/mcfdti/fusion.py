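"""Feature interaction, selection and prediction.

The drug and target feature maps are crossed with a shared attention mechanism
(one set of query/key/value projections serves both directions), interacted
position-wise in a biased feature interaction module (BFIM), then passed to the
selective fusion module (SFM): channel statistics are squeezed over time,
bottlenecked, re-expanded through two competing branches, and a per-channel
two-way softmax gates the two halves of the feature map so local and global
information compete for each channel. A squeeze-and-excitation (SE) block
re-calibrates the selected features before the fully connected head emits the
interaction probability.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat
from .encoders import Linear, scaled_dot_attention


class SharedCrossAttention:
    """Bidirectional cross attention with projections shared across directions."""

    def __init__(self, rng: np.random.Generator, channels: int):
        self.wq = Linear(rng, channels, channels)
        self.wk = Linear(rng, channels, channels)
        self.wv = Linear(rng, channels, channels)
        self.last_attn_t: np.ndarray | None = None
        self.last_attn_d: np.ndarray | None = None

    def __call__(self, f_drug: Tensor, f_target: Tensor) -> tuple[Tensor, Tensor]:
        """Return (A_d, A_t): each stream attended over the other plus residual."""
        if f_drug.shape[-1] != f_target.shape[-1]:
            raise ValueError("drug/target maps must share a channel width")
        out_t, attn_t = scaled_dot_attention(
            self.wq(f_target), self.wk(f_drug), self.wv(f_drug))
        out_d, attn_d = scaled_dot_attention(
            self.wq(f_drug), self.wk(f_target), self.wv(f_target))
        self.last_attn_t = attn_t.data
        self.last_attn_d = attn_d.data
        return out_d + f_drug, out_t + f_target

    @property
    def params(self) -> list[Tensor]:
        return [*self.wq.params, *self.wk.params, *self.wv.params]


class BfimParams:
    """Biased feature interaction: affine map over [A_d ; A_t ; A_d ⊙ A_t].

    The interaction term is the element-wise product by default; the bilinear
    variant first mixes the drug stream through a learned square map.
    """

    def __init__(self, rng: np.random.Generator, channels: int,
                 bilinear: bool = False):
        self.channels = channels
        self.bilinear = bilinear
        self.mix = Linear(rng, 3 * channels, 2 * channels, scale="he")
        self.w_bil = Linear(rng, channels, channels) if bilinear else None

    @property
    def params(self) -> list[Tensor]:
        out = self.mix.params
        if self.w_bil is not None:
            out = out + self.w_bil.params
        return out


def bfim(a_d: Tensor, a_t: Tensor, params: BfimParams) -> Tensor:
    """F_cross = ReLU(W·[A_d ; A_t ; A_d ⊙ A_t] + b), position-wise."""
    if a_d.shape != a_t.shape:
        raise ValueError(f"stream shape mismatch: {a_d.shape} vs {a_t.shape}")
    inter = (params.w_bil(a_d) * a_t) if params.bilinear else a_d * a_t
    return params.mix(concat([a_d, a_t, inter], axis=-1)).relu()


class SfmParams:
    """Reduction/expansion maps for selective fusion plus the SE bottleneck."""

    def __init__(self, rng: np.random.Generator, channels: int,
                 reduction: int = 4, se_reduction: int = 4):
        self.channels = channels  # C_f: width of each competing stream
        d_r = max((2 * channels) // reduction, 4)
        self.d_r = d_r
        self.w_f = Linear(rng, 2 * channels, d_r, scale="he")
        self.w_u1 = Linear(rng, d_r, channels)
        self.w_u2 = Linear(rng, d_r, channels)
        d_se = max((2 * channels) // se_reduction, 4)
        self.se_reduce = Linear(rng, 2 * channels, d_se, scale="he")
        self.se_expand = Linear(rng, d_se, 2 * channels)

    def tie_expansions(self) -> None:
        """Make the two expansion branches identical (diagnostic mode)."""
        self.w_u2.w.data = self.w_u1.w.data.copy()
        self.w_u2.b.data = self.w_u1.b.data.copy()

    @property
    def params(self) -> list[Tensor]:
        return [*self.w_f.params, *self.w_u1.params, *self.w_u2.params,
                *self.se_reduce.params, *self.se_expand.params]


def sfm_gates(l_stream: Tensor, g_stream: Tensor, params: SfmParams,
              ) -> tuple[Tensor, Tensor]:
    """Per-channel competition weights (s_L, s_G), each (B, C_f), summing to 1."""
    x = concat([l_stream, g_stream], axis=-1)          # (B, T, 2C_f)
    if x.shape[-2] == 0:
        raise ValueError("cannot pool statistics over an empty time axis")
    i_vec = x.mean(axis=-2)                            # (B, 2C_f)
    x_hat = params.w_f(i_vec).relu()                   # (B, d_r)
    x1 = params.w_u1(x_hat)                            # (B, C_f)
    x2 = params.w_u2(x_hat)
    # stable two-way softmax per channel
    m = Tensor(np.maximum(x1.data, x2.data))
    e1 = (x1 - m).exp()
    e2 = (x2 - m).exp()
    denom = e1 + e2
    return e1 / denom, e2 / denom


def sfm(l_stream: Tensor, g_stream: Tensor, params: SfmParams) -> Tensor:
    """Selective fusion: gate each stream by its per-channel softmax weight."""
    s_l, s_g = sfm_gates(l_stream, g_stream, params)
    gated_l = l_stream * s_l.reshape(s_l.shape[0], 1, s_l.shape[1])
    gated_g = g_stream * s_g.reshape(s_g.shape[0], 1, s_g.shape[1])
    return concat([gated_l, gated_g], axis=-1)


def se_recalibrate(x_f: Tensor, params: SfmParams) -> Tensor:
    """Squeeze-and-excitation channel gating: sigmoid(W2 ReLU(W1 mean_T))."""
    if x_f.shape[-2] == 0:
        raise ValueError("cannot squeeze over an empty time axis")
    squeeze = x_f.mean(axis=-2)                        # (B, 2C_f)
    gate = params.se_expand(params.se_reduce(squeeze).relu()).sigmoid()
    return x_f * gate.reshape(gate.shape[0], 1, gate.shape[1])


class PredictionHead:
    """Fully connected stack over pooled features ending in a sigmoid unit."""

    def __init__(self, rng: np.random.Generator, d_in: int,
                 widths: tuple[int, ...] = (512, 128), dropout: float = 0.1):
        self.layers: list[Linear] = []
        prev = d_in
        for w in widths:
            self.layers.append(Linear(rng, prev, w, scale="he"))
            prev = w
        self.out = Linear(rng, prev, 1)
        self.dropout = dropout

    def __call__(self, x: Tensor, train: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        h = x
        for layer in self.layers:
            h = layer(h).relu()
            if train and self.dropout > 0.0:
                keep = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * Tensor(keep.astype(np.float32))
        return self.out(h).sigmoid()

    @property
    def params(self) -> list[Tensor]:
        out = []
        for layer in self.layers:
            out += layer.params
        return out + self.out.params


def predict(f_drug: Tensor, f_select: Tensor, head: PredictionHead,
            train: bool = False, rng: np.random.Generator | None = None,
            ) -> Tensor:
    """Interaction probability from globally max-pooled drug/selected features."""
    if not (np.isfinite(f_drug.data).all() and np.isfinite(f_select.data).all()):
        raise ValueError("non-finite feature values reached the prediction head")
    pooled = concat([f_drug.max(axis=-2), f_select.max(axis=-2)], axis=-1)
    prob = head(pooled, train=train, rng=rng)
    return prob.reshape(prob.shape[0])
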