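"""The fast local microformer ("former module").

A feature map is tiled into non-overlapping b x b area blocks, each block is
flattened into a token sequence (one token per pixel, features = channels),
and every sequence goes through additive multi-head attention: the queries
are summarized into a single global query by a learned softmax, the global
query modulates the keys element-wise, the modulated keys are summarized
into a global key the same way, and the global key modulates the values.
Cost is linear in the number of tokens, unlike all-pairs dot-product
attention.  Head outputs are re-mixed by a learned stride-1 transposed
convolution over the stacked-head channel axis, blocks are merged back and
the result is blended with the input through a residual connection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import Linear, Module, Parameter

__all__ = [
    "BlockPartition",
    "partition_blocks",
    "merge_blocks",
    "AdditiveAttention",
    "additive_attention",
    "FormerModule",
    "additive_attention_flops",
    "dense_attention_flops",
]


@dataclass
class BlockPartition:
    """Token sequences for each area block plus the geometry to invert them."""

    tokens: Tensor          # (n_blocks, block_size**2, C)
    orig_shape: tuple       # (C, H, W)
    grid: tuple             # (n_blocks_h, n_blocks_w)
    block_size: int


def partition_blocks(x, block_size: int) -> BlockPartition:
    """Zero-pad a (C, H, W) map to multiples of ``block_size`` and flatten
    each b x b tile row-major into a sequence of b**2 C-dim tokens."""
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    x = as_tensor(x)
    c, h, w = x.shape
    b = int(block_size)
    ph, pw = (-h) % b, (-w) % b
    xp = x.pad(((0, 0), (0, ph), (0, pw))) if (ph or pw) else x
    nh, nw = (h + ph) // b, (w + pw) // b
    tokens = (
        xp.reshape(c, nh, b, nw, b)
        .transpose((1, 3, 2, 4, 0))          # (nh, nw, b, b, C)
        .reshape(nh * nw, b * b, c)
    )
    return BlockPartition(tokens=tokens, orig_shape=(c, h, w), grid=(nh, nw),
                          block_size=b)


def merge_blocks(part: BlockPartition, tokens: Tensor | None = None) -> Tensor:
    """Exact inverse of :func:`partition_blocks` (padding is cropped)."""
    t = part.tokens if tokens is None else tokens
    c, h, w = part.orig_shape
    nh, nw = part.grid
    b = part.block_size
    full = (
        t.reshape(nh, nw, b, b, c)
        .transpose((4, 0, 2, 1, 3))          # (C, nh, b, nw, b)
        .reshape(c, nh * b, nw * b)
    )
    return full[:, :h, :w]


class AdditiveAttention(Module):
    """Multi-head additive attention over token sequences.

    ``w_query``/``w_key`` hold one learned scoring vector of length
    head_dim per head; query/key/value maps are shared linear projections
    of width d = channels.
    """

    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads != 0:
            raise ValueError(f"feature width {d} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = d // n_heads
        self.query_map = Linear(d, d, rng, bias=False)
        self.key_map = Linear(d, d, rng, bias=False)
        self.value_map = Linear(d, d, rng, bias=False)
        self.w_query = Parameter(rng.normal(0, 1 / np.sqrt(self.head_dim),
                                            (n_heads, self.head_dim)))
        self.w_key = Parameter(rng.normal(0, 1 / np.sqrt(self.head_dim),
                                          (n_heads, self.head_dim)))

    def forward(self, seq: Tensor, return_weights: bool = False):
        """``seq`` is (..., n, d); attention runs over the n tokens."""
        seq = as_tensor(seq)
        *lead, n, d = seq.shape
        H, dh = self.n_heads, self.head_dim
        scale = 1.0 / np.sqrt(dh)

        nl = len(lead)
        swap = tuple(range(nl)) + (nl + 1, nl, nl + 2)

        def split_heads(t):
            # (..., n, d) -> (..., H, n, dh)
            return t.reshape(*lead, n, H, dh).transpose(swap)

        q = split_heads(self.query_map(seq))
        k = split_heads(self.key_map(seq))
        v = split_heads(self.value_map(seq))

        wq = self.w_query.reshape(H, 1, dh)
        wk = self.w_key.reshape(H, 1, dh)

        alpha = ((q * wq).sum(-1) * scale).softmax(axis=-1)      # (..., H, n)
        q_global = (alpha.reshape(*alpha.shape, 1) * q).sum(-2)  # (..., H, dh)
        p = q_global.reshape(*lead, H, 1, dh) * k * scale        # (..., H, n, dh)
        beta = ((p * wk).sum(-1) * scale).softmax(axis=-1)
        k_global = (beta.reshape(*beta.shape, 1) * p).sum(-2)
        u = k_global.reshape(*lead, H, 1, dh) * v                # (..., H, n, dh)

        out = u.transpose(swap).reshape(*lead, n, d)             # concat heads
        if return_weights:
            return out, (alpha, beta)
        return out


def additive_attention(seq, params: AdditiveAttention,
                       return_weights: bool = False):
    """Functional wrapper around :class:`AdditiveAttention`."""
    return params(as_tensor(seq), return_weights=return_weights)


class FormerModule(Module):
    """Block partition -> additive attention -> head re-mixing -> merge ->
    residual.  Output shape always equals input shape."""

    def __init__(self, channels: int, block_size: int = 8, n_heads: int = 4,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.block_size = block_size
        self.attention = AdditiveAttention(channels, n_heads, rng)
        # stride-1 transposed convolution over the stacked-head channel axis:
        # an affine mix of the H*dh concatenated head channels back to width d
        self.head_aggregate = Linear(channels, channels, rng)

    def forward(self, x) -> Tensor:
        x = as_tensor(x)
        part = partition_blocks(x, self.block_size)
        y = self.attention(part.tokens)
        y = self.head_aggregate(y)
        return merge_blocks(part, y) + x


def additive_attention_flops(n: int, d: int, n_heads: int) -> int:
    """Multiply-accumulate count of one additive-attention pass; Theta(n)."""
    proj = 3 * n * d * d           # query/key/value maps
    scoring = 4 * n * d            # w_q.q, w_k.p dot products
    mixing = 3 * n * d             # global-query/key weighted sums + value mix
    return proj + scoring + mixing


def dense_attention_flops(n: int, d: int) -> int:
    """Reference count for all-pairs dot-product attention; Theta(n**2)."""
    return 3 * n * d * d + 2 * n * n * d + n * n
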