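"""Block partitioning and additive attention of the former module."""

import numpy as np
import pytest

from freeprotmap.autodiff import Tensor
from freeprotmap.former import (
    AdditiveAttention,
    FormerModule,
    additive_attention,
    additive_attention_flops,
    dense_attention_flops,
    merge_blocks,
    partition_blocks,
)


def loop_additive_attention(seq, params):
    """Straight-line per-head transcription of the additive-attention update
    with explicit loops: learned query/key/value projections, softmax
    summarization of queries into a global query, element-wise key
    modulation, softmax summarization into a global key, value modulation,
    head concatenation."""
    n, d = seq.shape
    H, dh = params.n_heads, params.head_dim
    WQ = params.query_map.weight.numpy()
    WK = params.key_map.weight.numpy()
    WV = params.value_map.weight.numpy()
    wq, wk = params.w_query.numpy(), params.w_key.numpy()
    out = np.zeros((n, d))
    for m in range(H):
        sl = slice(m * dh, (m + 1) * dh)
        q = np.array([seq[i] @ WQ for i in range(n)])[:, sl]
        k = np.array([seq[i] @ WK for i in range(n)])[:, sl]
        v = np.array([seq[i] @ WV for i in range(n)])[:, sl]
        scores = np.array([wq[m] @ q[i] / np.sqrt(dh) for i in range(n)])
        alpha = np.exp(scores - scores.max())
        alpha /= alpha.sum()
        q_global = sum(alpha[i] * q[i] for i in range(n))
        p = np.array([q_global * k[i] / np.sqrt(dh) for i in range(n)])
        scores_k = np.array([wk[m] @ p[i] / np.sqrt(dh) for i in range(n)])
        beta = np.exp(scores_k - scores_k.max())
        beta /= beta.sum()
        k_global = sum(beta[i] * p[i] for i in range(n))
        for i in range(n):
            out[i, sl] = k_global * v[i]
    return out


class TestPartition:
    def test_exact_tiling(self):
        x = np.arange(16, dtype=float).reshape(1, 4, 4)
        part = partition_blocks(x, 2)
        assert part.tokens.shape == (4, 4, 1)
        assert part.grid == (2, 2)
        # first block is the top-left 2x2 tile, row-major
        assert np.allclose(part.tokens.numpy()[0, :, 0], [0, 1, 4, 5])

    def test_padded_roundtrip_recovers_input(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 5, 5))
        part = partition_blocks(x, 2)
        assert part.tokens.shape == (9, 4, 3)
        assert np.allclose(merge_blocks(part).numpy(), x)

    def test_block_larger_than_map_gives_single_block(self):
        x = np.ones((2, 3, 3))
        part = partition_blocks(x, 4)
        assert part.tokens.shape == (1, 16, 2)
        assert np.allclose(merge_blocks(part).numpy(), x)

    def test_invalid_block_size(self):
        with pytest.raises(ValueError):
            partition_blocks(np.ones((1, 2, 2)), 0)


class TestAdditiveAttention:
    def test_single_token_weights_are_one(self):
        rng = np.random.default_rng(3)
        params = AdditiveAttention(4, 2, rng)
        _, (alpha, beta) = additive_attention(rng.normal(size=(1, 4)), params,
                                              return_weights=True)
        assert np.allclose(alpha.numpy(), 1.0)
        assert np.allclose(beta.numpy(), 1.0)

    def test_weights_sum_to_one_per_head(self):
        rng = np.random.default_rng(4)
        params = AdditiveAttention(8, 4, rng)
        _, (alpha, beta) = additive_attention(rng.normal(size=(9, 8)), params,
                                              return_weights=True)
        assert np.allclose(alpha.numpy().sum(-1), 1.0, atol=1e-6)
        assert np.allclose(beta.numpy().sum(-1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        params = AdditiveAttention(8, 2, rng)
        seq = rng.normal(size=(7, 8))
        fast = additive_attention(seq, params).numpy()
        assert np.allclose(fast, loop_additive_attention(seq, params),
                           atol=1e-5)

    def test_width_must_divide_heads(self):
        with pytest.raises(ValueError):
            AdditiveAttention(6, 4, np.random.default_rng(0))


class TestFormerModule:
    def test_zeroed_branch_reduces_to_identity(self):
        rng = np.random.default_rng(5)
        mod = FormerModule(4, block_size=2, n_heads=2, rng=rng)
        mod.head_aggregate.weight.data[:] = 0.0
        mod.head_aggregate.bias.data[:] = 0.0
        x = rng.normal(size=(4, 5, 5))
        assert np.allclose(mod(x).numpy(), x)

    @pytest.mark.parametrize("shape", [
        (4, 3, 3), (4, 8, 8), (8, 5, 7), (8, 1, 1), (4, 9, 2),
    ])
    def test_output_shape_equals_input_shape(self, shape):
        rng = np.random.default_rng(6)
        mod = FormerModule(shape[0], block_size=4, n_heads=2, rng=rng)
        out = mod(rng.normal(size=shape))
        assert out.shape == shape
        assert np.isfinite(out.numpy()).all()

    def test_attention_is_local_to_blocks(self):
        """With the residual ablated, perturbing a pixel in one block never
        changes outputs in any other block."""
        rng = np.random.default_rng(7)
        mod = FormerModule(4, block_size=2, n_heads=2, rng=rng)

        def branch(x):  # former module minus the residual connection
            part = partition_blocks(x, mod.block_size)
            y = mod.head_aggregate(mod.attention(part.tokens))
            return merge_blocks(part, y).numpy()

        x = rng.normal(size=(4, 4, 4))
        base = branch(x)
        x2 = x.copy()
        x2[:, 0, 0] += 1.0  # perturb inside the top-left block
        delta = branch(x2) - base
        assert np.any(delta[:, :2, :2] != 0)
        assert np.allclose(delta[:, 2:, :], 0) and np.allclose(delta[:, :2, 2:], 0)

    def test_flop_count_is_linear_in_tokens(self):
        d, H, n = 32, 4, 64
        ratio = additive_attention_flops(2 * n, d, H) / \
            additive_attention_flops(n, d, H)
        dense_ratio = dense_attention_flops(2 * n, d) / \
            dense_attention_flops(n, d)
        assert ratio == pytest.approx(2.0, abs=1e-9)
        assert dense_ratio > 3.0  # quadratic term dominates
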