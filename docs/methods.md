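# Methods

This note records the model as implemented, the parameter choices that
matter, the places where the published design left the details open and
what this package decided, and what the synthetic benchmark does and does
not demonstrate.

## Model

### Input representation

The network consumes an M × L × L stack of pair maps. The intended source
is a transformer protein language model: one L × L attention map per layer
and head, C = layers × heads channels in layer-major order (layer 0 heads
0..H−1, then layer 1, …). Providers are pluggable objects with a
`stack_for(sequence)` method; the package ships only the synthetic
provider, and the channel-order contract is part of the provider
interface because the default grouping depends on it.

Group pooling partitions the C channels into M disjoint groups and takes
the per-position maximum within each group. The published description
does not state the partition; this package defaults to `by_layer` — M
contiguous equal blocks, so with layer-major ordering one group is one
layer's heads — with M = 36, matching the width of the first and last
convolution blocks. Both M and the partition mode are configurable, and
`contiguous` handles C not divisible by M. Pooling consumes stacks as
produced; no re-normalization is applied first.

### The former module (local microformer)

Feature maps are zero-padded to multiples of the block size b, tiled into
b × b blocks, and each block is flattened row-major into a sequence of b²
tokens whose features are the channel vectors (no extra embedding; token
width d equals the incoming channel count). Per head of dimension
d_h = d / H:

1. query/key/value projections q_i, k_i, v_i (shared linear maps of width d);
2. α = softmax_i(w_q·q_i / √d_h), global query q* = Σ α_i q_i;
3. p_i = q* ⊙ k_i / √d_h (element-wise — the only reading under which
   p_i stays a d_h-vector);
4. β = softmax_i(w_k·p_i / √d_h), global key k* = Σ β_i p_i (the softmax
   runs over all n tokens; a partial summation bound in the source
   formula is treated as a typo);
5. u_i = k* ⊙ v_i; head outputs are concatenated.

Cost is Θ(n) in tokens. Head re-mixing ("transposed convolution over the
attention results") is implemented as a learned stride-1 transposed
convolution across the stacked-head channel axis — algebraically an
affine d → d map applied per token — which keeps shapes invertible.
Blocks are merged back, padding cropped, and the result added to the
module input (residual). Block size b = 8 and H = 4 heads are defaults;
neither is stated in the published design.

### Triangular attention

The "starting node" formulation: the update of pair entry (i, j) attends
over entries (i, k), with logits

    q(i,j) · k(i,k) / √d_h + b(j,k)

where b projects the pair feature at the third edge (j, k) to one scalar
per head. Softmax over k, weighted sum of v(i, k), head concatenation,
output projection, residual add. A sigmoid gate exists behind a flag but
is off by default (the published description never mentions one); the
ending-node second pass is out of scope. The module sits on the second
layer of the network (on the 64-channel, half-resolution map), d_t = 64,
4 heads.

### R-former assembly

    x₁ = conv_f(x₀)        max-pool(2) + double 3×3 conv, {64, 64}
    x₂ = tri_attn(x₁)
    x₃ = former_f(x₂)      max-pool(2) + double conv {128, 128} + former module
    x₄ = former_m(x₃, x₂)  2×2 stride-2 up-conv + pad/crop + add x₂
                           + double conv {64, 64} + former module
    x₅ = conv_m(x₄, x₀)    2×2 stride-2 up-conv + pad/crop + add x₀
                           + double conv {36, 36}

Decisions embedded here:

- **1-filter up-convolutions.** The stated transposed convolutions have a
  single filter, which cannot channel-match the 64- and 36-channel skip
  tensors; the up-sampled single channel is therefore broadcast-added to
  the skip. This reads naturally as part of the architecture's bottleneck
  design and keeps the decoder extremely light; it is this package's
  interpretation.
- **Odd lengths.** Right/bottom zero-padding before each pooling;
  after each up-convolution the map is cropped (or zero-padded) to the
  skip tensor's extent before the add. Output is exactly L × L for any
  L ≥ 4, including odd lengths.
- **Former placement.** Inside former_f / former_m the former module runs
  after the double convolution, on its output width; the published figure
  is ambiguous on this.
- **Nonlinearities.** ReLU after each convolution of a double-conv block;
  no normalization layers (the source is silent; both are configurable
  points in code).
- **Skip fusion is addition**, not concatenation.

### Heads

Two independent 1×1 convolutions on x₅, squashed by a sigmoid (the
published range statement does not name the mechanism; sigmoid is the
obvious smooth choice) and scaled by N = 100 Å: a distance map and an
absolute-error map, each in [0, 100] Å. Predictions are not symmetrized
by default (the source never says they are); a flag averages the map
with its transpose when wanted. Head weights are initialized small
(σ = 0.01) with biases placing the initial outputs near 15 Å (distance)
and 3 Å (error): with an MAE objective behind a saturating sigmoid,
kaiming-scale head weights let early Adam steps drive the pre-activation
tens of units negative, after which gradients vanish — small-scale head
initialization removes that failure mode without touching the schedule.

## Training

Masked MAE: only pairs with true distance in (0, 36 Å) contribute, per
protein; a protein with an empty mask raises and is reported. The loss is
computed in Å after denormalization (equivalent to normalized units up to
the constant N; stated for reproducibility). Targets above 100 Å are
clipped to the head range; the clip count is tracked (synthetic chains
never reach it at the default lengths).

Stage 1: Adam (β = 0.9/0.999), weight decay 0.01 added to the gradient,
lr 1e-3 fixed, batch size 1, 30 epochs over the R-former + distance head.
Stage 2: those weights frozen bit-exactly (their subgraphs are dropped
from backward), 5 epochs on the error head against realized absolute
errors of the frozen predictor, same mask. No lr schedule, no early
stopping; the final-epoch model is kept and the best-validation epoch is
only logged. Everything is seeded: two runs with the same seed produce
identical loss traces.

## Synthetic data

`SyntheticSpec` defines the study conditions. Chains concatenate
secondary-structure-like fragments — helical (rise 1.5 Å/residue, 100°
turn, radius 2.3 Å), strand-like (3.3 Å/residue, straight), short random
turns — attached with random rigid placements; a fragment clashing with
the existing chain (any non-adjacent pair < 3.5 Å) is re-sampled up to 50
times. Coordinate noise σ = 0.1 Å emulates experimental coordinate
uncertainty while keeping consecutive-residue distances inside
[2.5, 4.5] Å. Pseudo-attention channels are row-softmaxed
−d/τ_g + N(0, 0.1) logits with group temperatures τ_g log-spaced over
[2, 16] Å, C = 72 channels in M = 36 groups of two — so group pooling is
exercised non-trivially and every pooled channel carries monotone
distance signal. Datasets are reproducible from a per-item seed manifest.

What this emulates: valid metric geometry (symmetry, zero diagonal,
triangle inequality), length heterogeneity, informative-but-noisy
channels, group structure. What it does not: real attention sparsity
patterns, sequence-dependent structure, long proteins, Ramachandran
statistics, side chains. Passing the learning benchmarks therefore shows
the architecture and training loop can extract pairwise distance signal
from stacked pair features under the published schedule — not that the
package reproduces published accuracy on real proteins, which would
require the external language-model backend and trained weights.

## Problem sizes

Training demos run at desk scale, chosen once as the sizes a pure-numpy
trainer handles comfortably while leaving the learning signal
unambiguous: the shared test fixture uses 24 training / 8 validation
chains of length 16–32 with the full 30 + 5 schedule; the
pooling-vs-sampling comparison uses 20/8 over three seeds; the
acceptance script uses 48/16 at lengths 16–40. The learning criterion —
held-out masked MAE at least 30% below the constant mean-distance
predictor — is met by a wide margin (typically > 75% improvement), so
corpus size is not the binding factor.

## Numerical choices and edge cases

- float64 throughout; softmax computed with max-subtraction; sigmoid in
  its numerically stable split form.
- Max-pool padding uses −inf so padded cells are never selected; a
  one-pixel pad cannot produce an all-padding window.
- Contact threshold is strict (< 8.0 Å); the evaluation mask is the open
  interval (0, 36 Å), so diagonal and missing-residue (NaN) pairs drop out.
- Separation classes follow the CASP convention (short 6–11, medium
  12–23, long ≥ 24, "all" ≥ 6); whether "all" should include |i−j| < 6 is
  a convention choice, made here as ≥ 6 and configurable.
- Contact scores from a distance predictor default to the negative
  predicted distance; AUROC is invariant to any monotone choice, Top L/k
  and AUPR are not, so the convention is fixed and documented.
- Ranking ties break by lexicographic (i, j); candidate ties in SSIM
  ranking break by candidate id.
- SSIM: maps clipped to a 100 Å cap, scaled to [0, 1], uniform 7×7
  window (shrunk to the largest odd size that fits on small maps),
  standard stabilization constants, data range 1.0. Unequal map sizes are
  reconciled by bilinear resizing of the larger map to the smaller —
  a package convention; the published workflow does not state its
  procedure, so absolute SSIM values are not comparable to printed ones.
- R² of a zero-variance reference set is 1 for an exact fit and −inf
  otherwise.

## Known limitations

- No pretrained language-model backend is bundled; real-protein accuracy
  is untested here by construction.
- The loop-oracle tests pin the attention algebra, but the 1-filter
  up-convolution reading and the by-layer grouping are interpretations
  the original authors could contradict.
- Training is CPU-bound numpy; the implementation is written for
  correctness and testability at desk scale, not for the
  tens-of-milliseconds inference of an optimized GPU build.
- Chains are Cβ-proxy point clouds; structure parsing supports real
  PDB/mmCIF files, but the bundled corpus never exercises multi-chain
  complexes or altloc-heavy crystal structures beyond the
  highest-occupancy rule.
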