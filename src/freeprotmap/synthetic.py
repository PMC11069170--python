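"""Geometry-consistent toy proteins and matched pseudo-attention stacks.

The generator plays the role of a training corpus: it builds self-avoiding
3-D chains from secondary-structure-like fragments (helical segments with
a 1.5 Å per-residue rise, ~100° turn and 2.3 Å radius; straight
strand-like segments at 3.3 Å per residue; short random turns), derives
valid Cβ-proxy distance maps from them, and emits pseudo-attention stacks
whose channels carry a noisy, monotone-decreasing signal of true distance:
channel c in group g holds row-softmaxed logits  -d(i,j)/τ_g + ε, with a
group-specific temperature τ_g, so max-pooling within a group is
informative and a network can demonstrably learn distance from the stack.

What this emulates — and what it does not — is discussed in
``docs/methods.md``; chains are point clouds, not full-atom backbones.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import pairwise_distance_map
from .pooling import (
    AttentionStack,
    GroupingScheme,
    PooledMaps,
    baseline_reduce,
    group_pool,
    make_grouping,
)
from .training import eval_mask

__all__ = [
    "SyntheticSpec",
    "ProteinSample",
    "SyntheticDataset",
    "SyntheticProvider",
    "generate_chain",
    "attention_from_distance",
    "make_dataset",
    "write_chain_pdb",
]


@dataclass
class SyntheticSpec:
    """Generator parameters (all lengths in residues, all scales in Å)."""

    length_range: tuple = (24, 48)
    helix_rise: float = 1.5          # Å per residue along the helix axis
    helix_turn_deg: float = 100.0    # rotation per residue
    helix_radius: float = 2.3
    strand_step: float = 3.3         # Å per residue, straight
    clash_distance: float = 3.5      # resample fragments closer than this
    sigma_coord: float = 0.1         # coordinate noise, Å
    sigma_attn: float = 0.1          # per-channel logit noise
    tau_range: tuple = (2.0, 16.0)   # group temperature span, Å
    n_channels: int = 72
    n_groups: int = 36
    grouping_mode: str = "by_layer"
    seed: int = 0

    def __post_init__(self):
        if self.length_range[0] < 8:
            raise ValueError("minimum length must be >= 8")
        if min(self.sigma_coord, self.sigma_attn) < 0:
            raise ValueError("noise scales must be non-negative")
        if self.grouping_mode == "by_layer" and \
                self.n_channels % self.n_groups != 0:
            raise ValueError("by_layer grouping needs C divisible by M")

    @property
    def temperatures(self) -> np.ndarray:
        """Per-group softmax temperatures, log-spaced over ``tau_range``."""
        lo, hi = self.tau_range
        return np.geomspace(lo, hi, self.n_groups)


@dataclass
class ProteinSample:
    """One training/evaluation item."""

    pooled: np.ndarray            # (M, L, L) network input
    distance: np.ndarray          # (L, L) reference map, Å
    mask: np.ndarray              # (L, L) bool, (0, 36 Å) pairs
    stack: np.ndarray | None = field(default=None, repr=False)
    seed: int = 0

    @property
    def seq_length(self) -> int:
        return self.distance.shape[0]


def _rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3-D rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _helix_fragment(n: int, spec: SyntheticSpec) -> np.ndarray:
    t = np.arange(n) * np.deg2rad(spec.helix_turn_deg)
    return np.stack([
        spec.helix_radius * np.cos(t),
        spec.helix_radius * np.sin(t),
        spec.helix_rise * np.arange(n, dtype=float),
    ], axis=1)


def _strand_fragment(n: int, spec: SyntheticSpec) -> np.ndarray:
    return np.stack([
        np.zeros(n), np.zeros(n), spec.strand_step * np.arange(n, dtype=float)
    ], axis=1)


def _turn_fragment(n: int, spec: SyntheticSpec,
                   rng: np.random.Generator) -> np.ndarray:
    steps = rng.normal(size=(n, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    steps *= 0.5 * (spec.strand_step + spec.helix_rise * 2)
    return np.vstack([np.zeros(3), np.cumsum(steps, axis=0)[:-1]])


def generate_chain(spec: SyntheticSpec, seed: int) -> np.ndarray:
    """Sample a self-avoiding-ish 3-D chain; (L, 3) Cβ-proxy coordinates.

    Fragments are attached with random rigid placements; a fragment whose
    atoms clash with the existing chain (any non-adjacent pair closer than
    the clash distance) is re-sampled, with a bounded number of retries.
    """
    rng = np.random.default_rng(seed)
    L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    chain = np.zeros((0, 3))
    while chain.shape[0] < L:
        remaining = L - chain.shape[0]
        kind = rng.choice(["helix", "strand", "turn"], p=[0.5, 0.3, 0.2])
        if kind == "helix":
            n = min(int(rng.integers(6, 13)), remaining)
            frag = _helix_fragment(n, spec)
        elif kind == "strand":
            n = min(int(rng.integers(4, 9)), remaining)
            frag = _strand_fragment(n, spec)
        else:
            n = min(int(rng.integers(2, 4)), remaining)
            frag = _turn_fragment(n, spec, rng)
        placed = None
        for _ in range(50):
            rot = _rotation(rng)
            cand = frag @ rot.T
            if chain.shape[0]:
                # a plausible bond step from the current terminus
                direction = rot @ np.array([0.0, 0.0, 1.0])
                offset = chain[-1] + direction * spec.strand_step
                cand = cand + offset
                tail = cand[1:] if cand.shape[0] > 1 else cand
                body = chain[:-1]
                if body.shape[0] and tail.shape[0]:
                    dmin = np.sqrt(
                        ((tail[:, None, :] - body[None, :, :]) ** 2).sum(-1)
                    ).min()
                    if dmin < spec.clash_distance:
                        continue
            placed = cand
            break
        if placed is None:     # accept the last candidate: "avoiding-ish"
            placed = cand
        chain = np.vstack([chain, placed])
    chain = chain[:L]
    if spec.sigma_coord > 0:
        chain = chain + rng.normal(0.0, spec.sigma_coord, size=chain.shape)
    return chain


def attention_from_distance(dmap: np.ndarray, spec: SyntheticSpec,
                            seed: int) -> AttentionStack:
    """Pseudo-attention stack: per channel, row-softmaxed -d/τ_g + noise."""
    rng = np.random.default_rng(seed)
    dmap = np.asarray(dmap, dtype=float)
    L = dmap.shape[0]
    taus = spec.temperatures
    per_group = spec.n_channels // spec.n_groups
    channels = np.empty((spec.n_channels, L, L))
    c = 0
    for g in range(spec.n_groups):
        for _ in range(per_group):
            logits = -dmap / taus[g]
            if spec.sigma_attn > 0:
                logits = logits + rng.normal(0.0, spec.sigma_attn,
                                             size=logits.shape)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            channels[c] = e / e.sum(axis=1, keepdims=True)
            c += 1
    return AttentionStack(values=channels, provider="synthetic")


@dataclass
class SyntheticDataset:
    """Reproducible train/validation split with a per-item seed manifest."""

    train: list
    val: list
    spec: SyntheticSpec
    manifest: dict

    def save_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.manifest, indent=2))


def _make_item(spec: SyntheticSpec, item_seed: int,
               scheme: GroupingScheme, keep_stack: bool) -> ProteinSample:
    coords = generate_chain(spec, item_seed)
    dmap = pairwise_distance_map(coords)
    stack = attention_from_distance(dmap, spec, item_seed + 1)
    pooled = group_pool(stack, scheme)
    return ProteinSample(
        pooled=pooled.values, distance=dmap, mask=eval_mask(dmap),
        stack=stack.values if keep_stack else None, seed=item_seed,
    )


def make_dataset(spec: SyntheticSpec, n_train: int, n_val: int,
                 seed: int | None = None,
                 keep_stacks: bool = False) -> SyntheticDataset:
    """Generate a reproducible dataset of (pooled maps, distance map) pairs.

    Item seeds are drawn from a seed sequence rooted at ``seed`` (default:
    the spec's seed); regenerating from the manifest is bit-identical.
    """
    root = spec.seed if seed is None else int(seed)
    scheme = make_grouping(spec.n_channels, spec.n_groups, spec.grouping_mode)
    n = n_train + n_val
    seeds = np.random.SeedSequence(root).generate_state(n) % (2 ** 31)
    items = [_make_item(spec, int(s), scheme, keep_stacks) for s in seeds]
    manifest = {
        "root_seed": root,
        "n_train": n_train,
        "n_val": n_val,
        "item_seeds": [int(s) for s in seeds],
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
    }
    return SyntheticDataset(train=items[:n_train], val=items[n_train:],
                            spec=spec, manifest=manifest)


def sampled_inputs(dataset: SyntheticDataset, seed: int = 0) -> tuple:
    """Replace group-pooled inputs by the random-sampling reduction (the
    ablation baseline); requires the dataset to keep raw stacks."""
    def convert(items):
        out = []
        for k, item in enumerate(items):
            if item.stack is None:
                raise ValueError("dataset was built without keep_stacks=True")
            stack = AttentionStack(values=item.stack, provider="synthetic")
            red = baseline_reduce(stack, dataset.spec.n_groups, "sampling",
                                  seed=seed + item.seed)
            out.append(ProteinSample(pooled=red.values, distance=item.distance,
                                     mask=item.mask, stack=item.stack,
                                     seed=item.seed))
        return out
    return convert(dataset.train), convert(dataset.val)


class SyntheticProvider:
    """Representation provider backed by the synthetic generator.

    For a sequence of length L it fabricates a chain of exactly that
    length and returns the matching pseudo-attention stack (layer-major
    channel order by construction: per-group channels are contiguous).
    """

    name = "synthetic"
    channel_order = "layer_major"

    def __init__(self, spec: SyntheticSpec | None = None, seed: int = 0):
        self.spec = spec if spec is not None else SyntheticSpec()
        self.seed = seed
        self._last_distance = None

    def stack_for(self, sequence: str) -> AttentionStack:
        L = len(sequence)
        spec = SyntheticSpec(**{**vars(self.spec), "length_range": (L, L)}) \
            if L >= 8 else self.spec
        item_seed = (self.seed + zlib.crc32(sequence.encode())) % (2 ** 31)
        if L >= 8:
            coords = generate_chain(spec, item_seed)[:L]
        else:
            rng = np.random.default_rng(item_seed)
            coords = np.cumsum(rng.normal(scale=2.0, size=(L, 3)), axis=0)
        dmap = pairwise_distance_map(coords)
        self._last_distance = dmap
        stack = attention_from_distance(dmap, self.spec, item_seed + 1)
        stack.sequence = sequence
        return stack


def write_chain_pdb(path, coords: np.ndarray, chain_id: str = "A") -> None:
    """Write a Cβ-proxy chain as a minimal PDB file (one ALA Cβ per residue,
    glycine-free by construction) so the structure readers can round-trip
    synthetic fixtures."""
    lines = []
    for i, (x, y, z) in enumerate(np.asarray(coords, dtype=float), start=1):
        lines.append(
            f"ATOM  {i:5d}  CB  ALA {chain_id}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
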