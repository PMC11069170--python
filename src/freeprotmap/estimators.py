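"""scikit-learn style estimators wrapping the pooling and prediction stack.

``GroupPooling`` is a stateless-ish transformer (it only learns the channel
count) turning attention stacks into M x L x L network inputs, and
``DistanceMapRegressor`` is the full two-stage-trained predictor.  Both
follow the estimator contract (get_params/set_params, fitted attributes
with trailing underscores) so they compose with sklearn pipelines, cloning
and parameter search.  X is a list of per-protein arrays — proteins have
different lengths, so samples cannot share a rectangular matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .network import RFormerConfig, build_variant
from .pooling import AttentionStack, baseline_reduce, group_pool, make_grouping
from .synthetic import ProteinSample
from .training import (
    TrainConfig,
    eval_mask,
    heldout_masked_mae,
    train_stage1,
    train_stage2,
)

__all__ = ["GroupPooling", "DistanceMapRegressor"]


def _as_stack(x) -> AttentionStack:
    return x if isinstance(x, AttentionStack) else AttentionStack(values=x)


class GroupPooling(TransformerMixin, BaseEstimator):
    """Group-wise max reduction of C x L x L stacks to M x L x L maps.

    Parameters
    ----------
    n_groups : number of channel groups M (default 36).
    mode : 'by_layer' (equal contiguous blocks, C divisible by M) or
        'contiguous' (near-equal blocks), or 'truncation' / 'sampling'
        for the baseline reductions.
    seed : channel-selection seed, used by 'sampling' only.
    """

    def __init__(self, n_groups: int = 36, mode: str = "by_layer",
                 seed: int = 0):
        self.n_groups = n_groups
        self.mode = mode
        self.seed = seed

    def fit(self, X, y=None):
        stacks = [_as_stack(x) for x in X]
        if not stacks:
            raise ValueError("X must contain at least one stack")
        channels = {s.n_channels for s in stacks}
        if len(channels) != 1:
            raise ValueError(f"inconsistent channel counts: {sorted(channels)}")
        self.n_channels_in_ = channels.pop()
        if self.mode in ("by_layer", "contiguous"):
            self.scheme_ = make_grouping(self.n_channels_in_, self.n_groups,
                                         self.mode)
        elif self.mode in ("truncation", "sampling"):
            self.scheme_ = None
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        return self

    def transform(self, X) -> list[np.ndarray]:
        if not hasattr(self, "n_channels_in_"):
            raise RuntimeError("GroupPooling is not fitted")
        out = []
        for x in X:
            stack = _as_stack(x)
            if self.scheme_ is not None:
                out.append(group_pool(stack, self.scheme_).values)
            else:
                out.append(baseline_reduce(stack, self.n_groups, self.mode,
                                           seed=self.seed).values)
        return out


class DistanceMapRegressor(BaseEstimator):
    """Two-stage-trained residue-residue distance (and error) predictor.

    Fit on lists: X[i] is an (M, L_i, L_i) pooled representation, y[i] the
    matching (L_i, L_i) reference distance map in Å.  Training minimizes
    masked MAE (pairs with true distance in (0, 36 Å)) with Adam, weight
    decay 0.01, lr 1e-3, batch size 1, for ``epochs_stage1`` epochs on the
    R-former + distance head and ``epochs_stage2`` epochs on the frozen-
    backbone error head.

    ``variant`` selects an ablation architecture ('freeprotmap', 'p',
    'tri', 'l', 'tril', 'trip', 'lp', 'baseline'); the architecture flags
    it implies can be overridden via ``tri``/``former``.
    """

    def __init__(self, variant: str = "freeprotmap", tri: bool | None = None,
                 former: bool | None = None, block_size: int = 8,
                 n_heads: int = 4, tri_heads: int = 4,
                 epochs_stage1: int = 30, epochs_stage2: int = 5,
                 lr: float = 1e-3, weight_decay: float = 0.01,
                 symmetrize: bool = False, seed: int = 0):
        self.variant = variant
        self.tri = tri
        self.former = former
        self.block_size = block_size
        self.n_heads = n_heads
        self.tri_heads = tri_heads
        self.epochs_stage1 = epochs_stage1
        self.epochs_stage2 = epochs_stage2
        self.lr = lr
        self.weight_decay = weight_decay
        self.symmetrize = symmetrize
        self.seed = seed

    # ------------------------------------------------------------------
    def _items(self, X, y):
        items = []
        for i, (x, d) in enumerate(zip(X, y)):
            x = np.asarray(x, dtype=float)
            d = np.asarray(d, dtype=float)
            if x.ndim != 3 or x.shape[1] != x.shape[2]:
                raise ValueError(f"X[{i}] must be (M, L, L), got {x.shape}")
            if d.shape != x.shape[1:]:
                raise ValueError(
                    f"y[{i}] shape {d.shape} does not match X[{i}] {x.shape}"
                )
            items.append(ProteinSample(pooled=x, distance=d,
                                       mask=eval_mask(d), seed=i))
        if not items:
            raise ValueError("need at least one training protein")
        return items

    def fit(self, X, y, validation=None):
        """Train both stages; ``validation`` is an optional (X_val, y_val)."""
        items = self._items(X, y)
        from .network import VARIANTS  # canonical flag table
        key = self.variant.lower().replace("_", "").replace("-", "")
        if key not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        _, tri_flag, former_flag = VARIANTS[key]
        tri_flag = tri_flag if self.tri is None else self.tri
        former_flag = former_flag if self.former is None else self.former
        cfg = RFormerConfig(
            n_groups=items[0].pooled.shape[0], block_size=self.block_size,
            n_heads=self.n_heads, tri_heads=self.tri_heads,
            tri_enabled=bool(tri_flag), former_enabled=bool(former_flag),
            symmetrize=self.symmetrize,
        )
        self.model_ = build_variant(pooling=True, tri=bool(tri_flag),
                                    former=bool(former_flag), config=cfg,
                                    seed=self.seed)
        tc = TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                         epochs_stage1=self.epochs_stage1,
                         epochs_stage2=max(self.epochs_stage2, 1),
                         seed=self.seed)
        val_items = self._items(*validation) if validation is not None else None
        self.history_ = train_stage1(self.model_, items, tc,
                                     val_items=val_items)
        if self.epochs_stage2 > 0:
            self.history_ += train_stage2(self.model_, items, tc,
                                          val_items=val_items)
        self.n_groups_in_ = cfg.n_groups
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("DistanceMapRegressor is not fitted")

    def predict(self, X) -> list[np.ndarray]:
        """Predicted distance maps (Å), one (L, L) array per input."""
        self._check_fitted()
        return [self.model_.predict(np.asarray(x, dtype=float)).distance
                for x in X]

    def predict_error(self, X) -> list[np.ndarray]:
        """Predicted absolute-error maps (Å)."""
        self._check_fitted()
        return [self.model_.predict(np.asarray(x, dtype=float)).error
                for x in X]

    def score(self, X, y) -> float:
        """Negative mean masked MAE (higher is better, sklearn convention)."""
        self._check_fitted()
        items = self._items(X, y)
        return -heldout_masked_mae(self.model_, items)
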