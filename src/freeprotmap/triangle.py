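"""Triangular attention over the pair feature map.

For a pair representation z with feature vectors z[i, j], the update of
entry (i, j) attends over entries (i, k) sharing the starting residue i,
and the attention logit carries an additive bias projected from the third
edge (j, k) of the residue triangle:

    weight(i, j, k) = softmax_k( q(i,j) . k(i,k) / sqrt(d_head) + b(j,k) )

Residue triples whose pairwise distances violate the triangle inequality
produce strongly negative logits after training, so the softmax suppresses
the propagation of geometrically impossible distance relationships.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor
from .nn import Linear, Module

__all__ = ["TriangularAttention", "triangular_attention"]


class TriangularAttention(Module):
    """Starting-node triangular attention with pair-derived bias.

    Parameters: per-head query/key/value projections of total width ``d``,
    a bias projection mapping each pair feature vector to one scalar per
    head, an output projection, and an optional sigmoid gate (off by
    default).
    """

    def __init__(self, d: int, n_heads: int = 4, gated: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        if d % n_heads != 0:
            raise ValueError(f"feature width {d} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.head_dim = d // n_heads
        self.query_map = Linear(d, d, rng, bias=False)
        self.key_map = Linear(d, d, rng, bias=False)
        self.value_map = Linear(d, d, rng, bias=False)
        self.bias_map = Linear(d, n_heads, rng, bias=False)
        self.out_map = Linear(d, d, rng)
        self.gate_map = Linear(d, d, rng) if gated else None

    def forward(self, pair, return_weights: bool = False):
        """``pair`` is (C, n, n); returns the same shape (residual update)."""
        pair = as_tensor(pair)
        if pair.ndim != 3 or pair.shape[1] != pair.shape[2]:
            raise ValueError(
                f"pair map must be C x n x n, got shape {pair.shape}"
            )
        c, n, _ = pair.shape
        H, dh = self.n_heads, self.head_dim
        x = pair.transpose((1, 2, 0))                     # (n, n, C)

        def split_heads(t):
            return t.reshape(n, n, H, dh).transpose((2, 0, 1, 3))

        q = split_heads(self.query_map(x))                # (H, n, n, dh)
        k = split_heads(self.key_map(x))
        v = split_heads(self.value_map(x))
        b = self.bias_map(x).transpose((2, 0, 1))         # (H, j, k)

        logits = (q @ k.transpose((0, 1, 3, 2))) / np.sqrt(dh)  # (H, i, j, k)
        logits = logits + b.reshape(H, 1, n, n)
        weights = logits.softmax(axis=-1)
        out = weights @ v                                 # (H, i, j, dh)
        out = out.transpose((1, 2, 0, 3)).reshape(n, n, c)
        out = self.out_map(out)
        if self.gate_map is not None:
            out = self.gate_map(x).sigmoid() * out
        result = (x + out).transpose((2, 0, 1))
        if return_weights:
            return result, weights
        return result


def triangular_attention(pair, params: TriangularAttention,
                         return_weights: bool = False):
    """Functional wrapper around :class:`TriangularAttention`."""
    return params(as_tensor(pair), return_weights=return_weights)
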