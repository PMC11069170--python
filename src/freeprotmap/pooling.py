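"""Attention-map stacks and their reduction to compact pair representations.

A protein language model emits one L x L attention map per layer and head —
a C x L x L stack for a length-L sequence.  That stack is high-dimensional
and sparse; group pooling partitions the C channels into M disjoint groups
and keeps, at every residue pair (i, j), the maximum response within each
group, yielding an M x L x L input representation.  Truncation (first
channels) and random sampling are retained as the baseline reductions used
in ablations.

Providers are pluggable: anything with a ``stack_for(sequence)`` method that
returns channels in layer-major order (layer 0 heads 0..H-1, then layer 1,
...) can stand behind the representation-generation step.  The built-in
synthetic provider lives in :mod:`freeprotmap.synthetic`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Sequence

import numpy as np

__all__ = [
    "AttentionStack",
    "GroupingScheme",
    "PooledMaps",
    "make_grouping",
    "group_pool",
    "baseline_reduce",
    "provide_representation",
    "STANDARD_AA",
    "save_maps",
    "load_maps",
]

# the 20 canonical residues plus X (unknown), as accepted sequence letters
STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass
class AttentionStack:
    """C x L x L stack of non-negative residue-residue affinity maps."""

    values: np.ndarray
    provider: str = "unknown"
    sequence: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(
                f"expected a C x L x L array, got shape {self.values.shape}"
            )
        if np.any(self.values < 0):
            raise ValueError("attention stacks must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def seq_length(self) -> int:
        return self.values.shape[1]


@dataclass
class GroupingScheme:
    """Ordered partition of channel indices into M disjoint non-empty groups."""

    groups: List[np.ndarray]
    mode: str = "by_layer"

    def __post_init__(self):
        groups = [np.asarray(g, dtype=np.intp) for g in self.groups]
        seen: set = set()
        for g in groups:
            if g.size == 0:
                raise ValueError("groups must be non-empty")
            if seen.intersection(g.tolist()):
                raise ValueError("groups must be pairwise disjoint")
            seen.update(g.tolist())
        self.groups = groups

    @property
    def n_groups(self) -> int:
        return len(self.groups)


@dataclass
class PooledMaps:
    """M x L x L group-pooled representation, the network input x0."""

    values: np.ndarray
    scheme: GroupingScheme | None = None
    sequence: str | None = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[1] != self.values.shape[2]:
            raise ValueError(
                f"expected an M x L x L array, got shape {self.values.shape}"
            )

    @property
    def n_groups(self) -> int:
        return self.values.shape[0]

    @property
    def seq_length(self) -> int:
        return self.values.shape[1]


def make_grouping(n_channels: int, n_groups: int,
                  mode: str = "by_layer") -> GroupingScheme:
    """Partition channel indices 0..C-1 into M ordered groups.

    ``by_layer`` requires C divisible by M and yields M contiguous blocks of
    C/M channels — with layer-major channel ordering each group is one
    transformer layer's heads.  ``contiguous`` yields near-equal contiguous
    blocks whose sizes differ by at most one.
    """
    if n_groups < 1 or n_channels < 1:
        raise ValueError("n_channels and n_groups must be positive")
    if n_groups > n_channels:
        raise ValueError(
            f"cannot form {n_groups} non-empty groups from {n_channels} channels"
        )
    if mode == "by_layer":
        if n_channels % n_groups != 0:
            raise ValueError(
                f"by_layer grouping needs C divisible by M; "
                f"got C={n_channels}, M={n_groups}"
            )
        size = n_channels // n_groups
        groups = [np.arange(g * size, (g + 1) * size) for g in range(n_groups)]
    elif mode == "contiguous":
        bounds = np.linspace(0, n_channels, n_groups + 1).round().astype(int)
        groups = [np.arange(bounds[g], bounds[g + 1]) for g in range(n_groups)]
    else:
        raise ValueError(f"unknown grouping mode {mode!r}")
    return GroupingScheme(groups=groups, mode=mode)


def group_pool(stack: AttentionStack, scheme: GroupingScheme) -> PooledMaps:
    """Per-group, per-position maximum response over the stack's channels."""
    values = stack.values
    C = values.shape[0]
    out = np.empty((scheme.n_groups,) + values.shape[1:], dtype=np.float64)
    for g, idx in enumerate(scheme.groups):
        if idx.min() < 0 or idx.max() >= C:
            raise IndexError(
                f"group {g} references channels outside 0..{C - 1}"
            )
        out[g] = values[idx].max(axis=0)
    return PooledMaps(values=out, scheme=scheme, sequence=stack.sequence)


def baseline_reduce(stack: AttentionStack, n_out: int, mode: str,
                    seed: int = 0) -> PooledMaps:
    """Reduction baselines: keep the first ``n_out`` channels (truncation) or
    a uniform random subset without replacement (sampling, seed-reproducible).
    """
    C = stack.n_channels
    if n_out < 1 or n_out > C:
        raise ValueError(f"n_out must be in 1..{C}, got {n_out}")
    if mode == "truncation":
        idx = np.arange(n_out)
    elif mode == "sampling":
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(C, size=n_out, replace=False))
    else:
        raise ValueError(f"unknown reduction mode {mode!r}")
    return PooledMaps(values=stack.values[idx].copy(), scheme=None,
                      sequence=stack.sequence)


def provide_representation(sequence: str, backend) -> AttentionStack:
    """Run a representation provider on a validated amino-acid sequence."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    bad = [(i, ch) for i, ch in enumerate(sequence.upper())
           if ch not in STANDARD_AA]
    if bad:
        positions = ", ".join(f"{ch!r} at {i}" for i, ch in bad[:5])
        raise ValueError(f"unknown residue letters: {positions}")
    stack = backend.stack_for(sequence.upper())
    if stack.seq_length != len(sequence):
        raise ValueError(
            f"provider returned L={stack.seq_length} for a length-"
            f"{len(sequence)} sequence"
        )
    return stack


def save_maps(path, arr: np.ndarray, **metadata) -> None:
    """Serialize a channel stack / pooled maps with JSON metadata."""
    np.savez_compressed(
        Path(path), values=np.asarray(arr),
        metadata=np.array(json.dumps(metadata)),
    )


def load_maps(path) -> tuple[np.ndarray, dict]:
    with np.load(Path(path), allow_pickle=False) as f:
        values = f["values"]
        meta = json.loads(str(f["metadata"])) if "metadata" in f else {}
    return values, meta
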