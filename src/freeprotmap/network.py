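"""The R-former network and its regression heads.

A U-shaped, fully convolutional/attentional pair-map network:

    x1 = conv_f(x0)           2x max-pool + double 3x3 conv, 64 filters
    x2 = tri_attn(x1)         triangular attention on the half-resolution map
    x3 = former_f(x2)         2x max-pool + double conv 128 + former module
    x4 = former_m(x3, x2)     2x2 up-conv + pad + add skip + double conv 64
                              + former module
    x5 = conv_m(x4, x0)       2x2 up-conv + pad + add skip + double conv 36

The transposed convolutions in the decoder have a single filter: the
up-sampled map is a one-channel bottleneck that is broadcast-added to the
skip tensor before the double convolution.  Two independent 1x1-convolution
heads squash x5 to [0, 1] with a sigmoid and denormalize by N = 100 Å,
yielding the predicted distance map and the predicted absolute-error map.

Odd side lengths are handled by implicit right/bottom padding before each
pooling and cropping after each up-convolution, so the output is always
L x L for any L >= 4.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, as_tensor
from .former import FormerModule
from .nn import Conv2d, ConvTranspose2d, Module
from .triangle import TriangularAttention

__all__ = [
    "RFormerConfig",
    "PredictionPair",
    "RFormer",
    "RegressionHeads",
    "FreeProtMapModel",
    "conv_f",
    "rformer_forward",
    "predict_heads",
    "build_variant",
    "VARIANTS",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class RFormerConfig:
    """Architecture hyperparameters (filter counts follow the published
    design; block size and head counts are open choices, see docs)."""

    n_groups: int = 36            # channels of the input representation x0
    pool_window: int = 2
    conv_f_filters: tuple = (64, 64)
    former_f_filters: tuple = (128, 128)
    former_m_filters: tuple = (64, 64)
    conv_m_filters: tuple = (36, 36)
    conv_kernel: int = 3
    upconv_filters: int = 1
    block_size: int = 8
    n_heads: int = 4
    tri_heads: int = 4
    tri_enabled: bool = True
    former_enabled: bool = True
    tri_gated: bool = False
    symmetrize: bool = False
    denorm_scale: float = 100.0   # Å per unit of head output

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("conv_f_filters", "former_f_filters",
                    "former_m_filters", "conv_m_filters"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RFormerConfig":
        d = dict(d)
        for key in ("conv_f_filters", "former_f_filters",
                    "former_m_filters", "conv_m_filters"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PredictionPair:
    """Predicted distance map and predicted absolute-error map, both in Å."""

    distance: np.ndarray
    error: np.ndarray


class DoubleConv(Module):
    def __init__(self, c_in, c_mid, c_out, kernel, rng):
        self.conv1 = Conv2d(c_in, c_mid, kernel, rng)
        self.conv2 = Conv2d(c_mid, c_out, kernel, rng)

    def forward(self, x):
        return self.conv2(self.conv1(x).relu()).relu()


def _match_spatial(up: Tensor, target_hw: tuple) -> Tensor:
    """Crop (or zero-pad) an up-convolved map to the skip tensor's extent."""
    h, w = target_hw
    c, uh, uw = up.shape
    if uh < h or uw < w:
        up = up.pad(((0, 0), (0, max(0, h - uh)), (0, max(0, w - uw))))
    return up[:, :h, :w]


class RFormer(Module):
    """Pair-map encoder-decoder; input (M, L, L) -> output (36, L, L)."""

    def __init__(self, config: RFormerConfig | None = None,
                 rng: np.random.Generator | None = None):
        cfg = config if config is not None else RFormerConfig()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = cfg
        k = cfg.conv_kernel
        f1, f2 = cfg.conv_f_filters
        g1, g2 = cfg.former_f_filters
        m1, m2 = cfg.former_m_filters
        c1, c2 = cfg.conv_m_filters

        self.conv_f_block = DoubleConv(cfg.n_groups, f1, f2, k, rng)
        self.tri = (TriangularAttention(f2, cfg.tri_heads, cfg.tri_gated, rng)
                    if cfg.tri_enabled else None)
        self.former_f_block = DoubleConv(f2, g1, g2, k, rng)
        self.former_f_former = (FormerModule(g2, cfg.block_size, cfg.n_heads, rng)
                                if cfg.former_enabled else None)
        self.up_m = ConvTranspose2d(g2, cfg.upconv_filters, rng)
        self.former_m_block = DoubleConv(f2, m1, m2, k, rng)
        self.former_m_former = (FormerModule(m2, cfg.block_size, cfg.n_heads, rng)
                                if cfg.former_enabled else None)
        self.up_out = ConvTranspose2d(m2, cfg.upconv_filters, rng)
        self.conv_m_block = DoubleConv(cfg.n_groups, c1, c2, k, rng)

    # the five named stages -------------------------------------------------
    def conv_f(self, x0: Tensor) -> Tensor:
        if x0.shape[1] < 2:
            raise ValueError(f"cannot max-pool a length-{x0.shape[1]} map")
        return self.conv_f_block(x0.maxpool2d())

    def former_f(self, x2: Tensor) -> Tensor:
        x = self.former_f_block(x2.maxpool2d())
        if self.former_f_former is not None:
            x = self.former_f_former(x)
        return x

    def former_m(self, x3: Tensor, x2: Tensor) -> Tensor:
        up = _match_spatial(self.up_m(x3), x2.shape[1:])
        x = self.former_m_block(up + x2)
        if self.former_m_former is not None:
            x = self.former_m_former(x)
        return x

    def conv_m(self, x4: Tensor, x0: Tensor) -> Tensor:
        up = _match_spatial(self.up_out(x4), x0.shape[1:])
        return self.conv_m_block(up + x0)

    def forward(self, x0) -> Tensor:
        x0 = as_tensor(x0)
        if x0.ndim != 3 or x0.shape[1] != x0.shape[2]:
            raise ValueError(f"input must be M x L x L, got {x0.shape}")
        if x0.shape[0] != self.config.n_groups:
            raise ValueError(
                f"expected {self.config.n_groups} input channels, "
                f"got {x0.shape[0]}"
            )
        if x0.shape[1] < 4:
            raise ValueError("two pooling stages require L >= 4")
        x1 = self.conv_f(x0)
        x2 = self.tri(x1) if self.tri is not None else x1
        x3 = self.former_f(x2)
        x4 = self.former_m(x3, x2)
        return self.conv_m(x4, x0)


class RegressionHeads(Module):
    """Two independent 1x1-conv heads: distance and absolute error, in Å."""

    def __init__(self, in_channels: int = 36, denorm_scale: float = 100.0,
                 rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.denorm_scale = denorm_scale
        self.distance_head = Conv2d(in_channels, 1, 1, rng)
        self.error_head = Conv2d(in_channels, 1, 1, rng)
        # small-scale head init: the sigmoid x N denormalization makes MAE
        # gradients vanish once a head saturates, so start near the center
        # of the output range (~15 Å distances, ~3 Å errors) with small
        # weights instead of kaiming-scale ones
        for head, bias0 in ((self.distance_head, -1.73),
                            (self.error_head, -3.48)):
            head.weight.data = rng.normal(0.0, 0.01, head.weight.data.shape)
            head.bias.data = np.full_like(head.bias.data, bias0)

    def _squash(self, head, x5, symmetrize):
        y = head(x5).sigmoid() * self.denorm_scale
        y = y.reshape(y.shape[1], y.shape[2])
        if symmetrize:
            y = (y + y.transpose((1, 0))) * 0.5
        return y

    def forward(self, x5, symmetrize: bool = False):
        return (self._squash(self.distance_head, x5, symmetrize),
                self._squash(self.error_head, x5, symmetrize))


class FreeProtMapModel(Module):
    """R-former plus regression heads; the complete predictor."""

    def __init__(self, config: RFormerConfig | None = None, seed: int = 0):
        cfg = config if config is not None else RFormerConfig()
        rng = np.random.default_rng(seed)
        self.config = cfg
        self.rformer = RFormer(cfg, rng)
        self.heads = RegressionHeads(cfg.conv_m_filters[-1], cfg.denorm_scale,
                                     rng)

    def forward(self, x0):
        x5 = self.rformer(x0)
        return self.heads(x5, symmetrize=self.config.symmetrize)

    def predict(self, x0) -> PredictionPair:
        dist, err = self.forward(as_tensor(np.asarray(x0)))
        return PredictionPair(distance=dist.numpy(), error=err.numpy())


# thin functional wrappers ---------------------------------------------------

def conv_f(x0, model: RFormer) -> Tensor:
    return model.conv_f(as_tensor(x0))


def rformer_forward(x0, model: RFormer) -> Tensor:
    return model(as_tensor(x0))


def predict_heads(x5, heads: RegressionHeads) -> PredictionPair:
    dist, err = heads(as_tensor(x5))
    return PredictionPair(distance=dist.numpy(), error=err.numpy())


#: ablation variant name -> (group pooling?, triangular attention?, former?)
VARIANTS = {
    "baseline": (False, False, False),
    "p": (True, False, False),
    "tri": (False, True, False),
    "l": (False, False, True),
    "tril": (False, True, True),
    "trip": (True, True, False),
    "lp": (True, False, True),
    "freeprotmap": (True, True, True),
}


def build_variant(name: str = None, *, pooling: bool = None, tri: bool = None,
                  former: bool = None, config: RFormerConfig | None = None,
                  seed: int = 0) -> FreeProtMapModel:
    """Construct an ablation variant.

    Either pass a variant ``name`` from :data:`VARIANTS` or explicit flags.
    The ``pooling`` flag is recorded on the model (``model.uses_pooling``)
    and tells the data pipeline whether to feed group-pooled maps or the
    random-sampling reduction; it does not change the network itself.
    """
    if name is not None:
        key = name.lower().replace("_", "").replace("-", "")
        if key not in VARIANTS:
            raise ValueError(
                f"unknown variant {name!r}; choose from {sorted(VARIANTS)}"
            )
        pooling, tri, former = VARIANTS[key]
    if None in (pooling, tri, former):
        raise ValueError("specify a variant name or all three flags")
    cfg = config if config is not None else RFormerConfig()
    cfg = RFormerConfig.from_dict({**cfg.to_dict(),
                                   "tri_enabled": bool(tri),
                                   "former_enabled": bool(former)})
    model = FreeProtMapModel(cfg, seed=seed)
    model.uses_pooling = bool(pooling)
    return model


def save_checkpoint(path, model: FreeProtMapModel, **extra) -> None:
    state = model.state_dict()
    meta = {"config": model.config.to_dict(),
            "uses_pooling": getattr(model, "uses_pooling", True), **extra}
    np.savez_compressed(Path(path), __meta__=np.array(json.dumps(meta)),
                        **state)


def load_checkpoint(path) -> tuple[FreeProtMapModel, dict]:
    with np.load(Path(path), allow_pickle=False) as f:
        meta = json.loads(str(f["__meta__"]))
        state = {k: f[k] for k in f.files if k != "__meta__"}
    model = FreeProtMapModel(RFormerConfig.from_dict(meta["config"]))
    model.uses_pooling = meta.get("uses_pooling", True)
    model.load_state_dict(state)
    return model, meta
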