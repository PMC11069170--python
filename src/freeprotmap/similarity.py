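"""Distance-map structure-similarity screening with SSIM.

Distance maps inherit rotation and translation invariance from the
geometry, so comparing two maps with an image-similarity statistic gives a
fast proxy for structural similarity without 3-D alignment.  Maps are
clipped to a shared distance cap (default 100 Å) and rescaled to [0, 1]
before the structural similarity index is computed; maps of unequal length
are reconciled by bilinear down-scaling of the larger map — a deliberate,
prominent convention of this package, since no standard exists.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from skimage.metrics import structural_similarity
from skimage.transform import resize

__all__ = ["ssim_maps", "rank_candidates"]

DISTANCE_CAP = 100.0  # Å shared intensity cap before rescaling


def _prepare(a: np.ndarray, cap: float) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square distance map, got {a.shape}")
    if a.shape[0] < 2:
        raise ValueError("degenerate 1x1 maps cannot be compared")
    return np.clip(a, 0.0, cap) / cap


def ssim_maps(a, b, cap: float = DISTANCE_CAP, win_size: int = 7) -> float:
    """Structural similarity of two distance maps, in [-1, 1].

    Symmetric in its arguments; identical maps score exactly 1.  If the
    maps differ in size, the larger is bilinearly resized to the smaller.
    """
    a = _prepare(a, cap)
    b = _prepare(b, cap)
    if a.shape[0] > b.shape[0]:
        a = resize(a, b.shape, order=1, anti_aliasing=False)
    elif b.shape[0] > a.shape[0]:
        b = resize(b, a.shape, order=1, anti_aliasing=False)
    win = min(win_size, a.shape[0])
    if win % 2 == 0:
        win -= 1
    win = max(win, 3)
    return float(structural_similarity(a, b, data_range=1.0, win_size=win))


def rank_candidates(reference, candidates: Sequence | dict,
                    cap: float = DISTANCE_CAP) -> list[tuple[str, float]]:
    """Score candidates against a reference map, best first.

    ``candidates`` is a mapping id -> map or an iterable of (id, map).
    Ties are broken by candidate id for determinism.
    """
    items: Iterable = candidates.items() if isinstance(candidates, dict) \
        else candidates
    scored = [(str(cid), ssim_maps(reference, cmap, cap=cap))
              for cid, cmap in items]
    return sorted(scored, key=lambda t: (-t[1], t[0]))
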