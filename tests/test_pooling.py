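"""Group pooling, grouping schemes and the reduction baselines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from freeprotmap.pooling import (
    AttentionStack,
    GroupingScheme,
    baseline_reduce,
    group_pool,
    load_maps,
    make_grouping,
    provide_representation,
    save_maps,
)


def brute_force_pool(values, groups):
    """Independent triple-loop oracle for per-group per-position maxima."""
    M, L = len(groups), values.shape[1]
    out = np.empty((M, L, L))
    for g, idx in enumerate(groups):
        for i in range(L):
            for j in range(L):
                out[g, i, j] = max(values[c, i, j] for c in idx)
    return out


class TestMakeGrouping:
    def test_by_layer_equal_blocks(self):
        scheme = make_grouping(720, 36, "by_layer")
        assert scheme.n_groups == 36
        assert all(len(g) == 20 for g in scheme.groups)
        assert np.array_equal(scheme.groups[1], np.arange(20, 40))

    def test_singleton_groups_are_identity_partition(self):
        scheme = make_grouping(6, 6, "contiguous")
        assert [list(g) for g in scheme.groups] == [[i] for i in range(6)]

    def test_contiguous_near_equal_sizes(self):
        scheme = make_grouping(7, 3, "contiguous")
        sizes = sorted(len(g) for g in scheme.groups)
        assert sizes == [2, 2, 3]
        assert sorted(np.concatenate(scheme.groups)) == list(range(7))

    def test_by_layer_requires_divisibility(self):
        with pytest.raises(ValueError, match="C=7.*M=3|7.*3"):
            make_grouping(7, 3, "by_layer")

    def test_too_many_groups_rejected(self):
        with pytest.raises(ValueError):
            make_grouping(4, 5, "contiguous")

    def test_scheme_rejects_overlapping_groups(self):
        with pytest.raises(ValueError, match="disjoint"):
            GroupingScheme(groups=[[0, 1], [1, 2]])

    def test_scheme_rejects_empty_groups(self):
        with pytest.raises(ValueError, match="non-empty"):
            GroupingScheme(groups=[[0], []])


class TestGroupPool:
    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(7)
        stack = AttentionStack(values=rng.random((8, 5, 5)))
        scheme = make_grouping(8, 2, "by_layer")
        pooled = group_pool(stack, scheme)
        assert np.array_equal(pooled.values,
                              brute_force_pool(stack.values, scheme.groups))

    def test_zero_stack_pools_to_zero(self):
        stack = AttentionStack(values=np.zeros((4, 3, 3)))
        out = group_pool(stack, make_grouping(4, 2, "by_layer"))
        assert np.all(out.values == 0)

    def test_singleton_groups_are_identity(self):
        rng = np.random.default_rng(0)
        stack = AttentionStack(values=rng.random((5, 4, 4)))
        scheme = make_grouping(5, 5, "contiguous")
        assert np.array_equal(group_pool(stack, scheme).values, stack.values)

    def test_out_of_range_channel_rejected(self):
        stack = AttentionStack(values=np.ones((3, 2, 2)))
        with pytest.raises(IndexError):
            group_pool(stack, GroupingScheme(groups=[[0, 5]]))

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_increasing_an_entry_never_decreases_pooled_values(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((6, 4, 4))
        scheme = make_grouping(6, 3, "by_layer")
        before = group_pool(AttentionStack(values=values), scheme).values
        c, i, j = rng.integers(6), rng.integers(4), rng.integers(4)
        bumped = values.copy()
        bumped[c, i, j] += rng.random() + 0.1
        after = group_pool(AttentionStack(values=bumped), scheme).values
        assert np.all(after >= before - 1e-12)

    @settings(deadline=None, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_within_group_channel_shuffle_is_invariant(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.random((8, 3, 3))
        scheme = make_grouping(8, 2, "by_layer")
        ref = group_pool(AttentionStack(values=values), scheme).values
        shuffled = values.copy()
        shuffled[0:4] = shuffled[rng.permutation(4)]
        out = group_pool(AttentionStack(values=shuffled), scheme).values
        assert np.allclose(out, ref)


class TestBaselineReduce:
    def setup_method(self):
        rng = np.random.default_rng(11)
        self.stack = AttentionStack(values=rng.random((5, 4, 4)))

    def test_truncation_keeps_first_channels(self):
        out = baseline_reduce(self.stack, 3, "truncation")
        assert np.array_equal(out.values, self.stack.values[:3])

    def test_full_truncation_is_identity(self):
        out = baseline_reduce(self.stack, 5, "truncation")
        assert np.array_equal(out.values, self.stack.values)

    def test_sampling_is_seed_reproducible(self):
        a = baseline_reduce(self.stack, 3, "sampling", seed=9)
        b = baseline_reduce(self.stack, 3, "sampling", seed=9)
        assert np.array_equal(a.values, b.values)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            baseline_reduce(self.stack, 6, "truncation")


class TestProvideRepresentation:
    class FakeBackend:
        def stack_for(self, sequence):
            L = len(sequence)
            return AttentionStack(values=np.ones((2, L, L)),
                                  provider="fake", sequence=sequence)

    def test_valid_sequence_passes_through(self):
        stack = provide_representation("ACDEFGHIKL", self.FakeBackend())
        assert stack.seq_length == 10 and stack.n_channels == 2

    def test_unknown_letters_reported_with_positions(self):
        with pytest.raises(ValueError, match="'B' at 1"):
            provide_representation("ABZ", self.FakeBackend())

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            provide_representation("", self.FakeBackend())


def test_stack_validation_rejects_negative_values():
    with pytest.raises(ValueError, match="non-negative"):
        AttentionStack(values=-np.ones((2, 3, 3)))


def test_maps_roundtrip_with_metadata(tmp_path):
    rng = np.random.default_rng(5)
    arr = rng.random((4, 6, 6))
    path = tmp_path / "stack.npz"
    save_maps(path, arr, provider="synthetic", n_groups=2)
    values, meta = load_maps(path)
    assert np.allclose(values, arr)
    assert meta == {"provider": "synthetic", "n_groups": 2}
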