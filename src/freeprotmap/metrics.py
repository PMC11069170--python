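"""Evaluation statistics for predicted distance and contact maps.

Distance regression is scored by MAE, RMSE and R² over residue pairs whose
reference distance lies in (0, 36 Å), plus the MAE between predicted and
realized absolute errors when an error map is supplied.  Dataset summaries
report per-statistic means and mean absolute deviations across proteins.

Contact prediction (contact ⇔ distance < 8.0 Å between Cβ atoms, CASP
convention) is scored by Top L/k precision within sequence-separation
classes, AUROC, AUPR, F1 and exportable ROC/PR curves.  Separation classes
follow the CASP convention: short 6 ≤ |i−j| < 12, medium 12 ≤ |i−j| < 24,
long |i−j| ≥ 24, and "all" meaning |i−j| ≥ 6.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import (
    auc,
    f1_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)

from .training import eval_mask

__all__ = [
    "CONTACT_THRESHOLD",
    "SEPARATION_CLASSES",
    "DistanceMetrics",
    "DatasetSummary",
    "ContactMap",
    "distance_metrics",
    "dataset_summary",
    "contact_from_distance",
    "topk_precision",
    "classifier_metrics",
    "channel_correlation",
]

CONTACT_THRESHOLD = 8.0  # Å, strict: contact iff distance < 8.0

#: class name -> (min separation, exclusive max separation)
SEPARATION_CLASSES = {
    "all": (6, None),
    "short": (6, 12),
    "medium": (12, 24),
    "long": (24, None),
}


@dataclass
class DistanceMetrics:
    """Per-protein regression statistics over the (0, 36 Å) mask."""

    mae_d: float
    rmse: float
    r2: float
    n_pairs: int
    mae_p: float | None = None


@dataclass
class DatasetSummary:
    """Aggregate mean and mean absolute deviation of each statistic."""

    mean: dict
    deviation: dict
    per_protein: list = field(repr=False, default_factory=list)


@dataclass
class ContactMap:
    """Boolean contact map binarized at a strict distance threshold."""

    contacts: np.ndarray
    threshold: float = CONTACT_THRESHOLD


def distance_metrics(pred, ref, pred_err=None,
                     protein_id: str | None = None) -> DistanceMetrics:
    """MAE, RMSE and R² of ``pred`` against ``ref`` over masked pairs.

    With ``pred_err`` given, also the MAE between the predicted absolute
    error and the realized absolute error |ref - pred| (same mask).
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, ref {ref.shape}")
    mask = eval_mask(ref)
    n = int(mask.sum())
    if n == 0:
        label = f" for protein {protein_id}" if protein_id else ""
        raise ValueError(f"empty (0, 36 Å) evaluation mask{label}")
    d, dp = ref[mask], pred[mask]
    resid = d - dp
    mae_d = float(np.abs(resid).mean())
    rmse = float(np.sqrt((resid ** 2).mean()))
    ss_tot = float(((d - d.mean()) ** 2).sum())
    ss_res = float((resid ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    mae_p = None
    if pred_err is not None:
        ae_real = np.abs(resid)
        ae_pred = np.asarray(pred_err, dtype=float)[mask]
        mae_p = float(np.abs(ae_real - ae_pred).mean())
    return DistanceMetrics(mae_d=mae_d, rmse=rmse, r2=r2, n_pairs=n,
                           mae_p=mae_p)


def dataset_summary(per_protein: Sequence[DistanceMetrics]) -> DatasetSummary:
    """Mean and mean absolute deviation of each statistic across proteins."""
    if not per_protein:
        raise ValueError("need at least one protein")
    stats = {"mae_d": [m.mae_d for m in per_protein],
             "rmse": [m.rmse for m in per_protein],
             "r2": [m.r2 for m in per_protein]}
    if all(m.mae_p is not None for m in per_protein):
        stats["mae_p"] = [m.mae_p for m in per_protein]
    mean = {k: float(np.mean(v)) for k, v in stats.items()}
    deviation = {k: float(np.abs(np.asarray(v) - mean[k]).mean())
                 for k, v in stats.items()}
    return DatasetSummary(mean=mean, deviation=deviation,
                          per_protein=list(per_protein))


def contact_from_distance(dmap,
                          threshold: float = CONTACT_THRESHOLD) -> ContactMap:
    """Binarize a distance map: contact iff distance strictly < threshold."""
    dmap = np.asarray(dmap, dtype=float)
    return ContactMap(contacts=dmap < threshold, threshold=threshold)


def _class_pairs(L: int, range_class: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        lo, hi = SEPARATION_CLASSES[range_class]
    except KeyError:
        raise ValueError(
            f"unknown range class {range_class!r}; "
            f"choose from {sorted(SEPARATION_CLASSES)}"
        ) from None
    i, j = np.triu_indices(L, k=lo)
    if hi is not None:
        keep = (j - i) < hi
        i, j = i[keep], j[keep]
    return i, j


def topk_precision(score, ref_contacts, k_divisor: int = 5,
                   range_class: str = "all") -> float:
    """Precision (%) of the top ceil(L/k) scored pairs in a separation class.

    Higher score = more likely contact.  Ties are broken by lexicographic
    (i, j) order for determinism.  An empty class yields NaN (missing, not
    zero); if fewer candidate pairs exist than ceil(L/k), all are used and
    a warning is issued.
    """
    score = np.asarray(score, dtype=float)
    contacts = ref_contacts.contacts if isinstance(ref_contacts, ContactMap) \
        else np.asarray(ref_contacts, dtype=bool)
    L = score.shape[0]
    if L < k_divisor:
        raise ValueError(f"sequence length {L} < k divisor {k_divisor}")
    i, j = _class_pairs(L, range_class)
    if i.size == 0:
        return float("nan")
    k = math.ceil(L / k_divisor)
    if i.size < k:
        warnings.warn(
            f"only {i.size} candidate pairs for top-{k}; using all",
            stacklevel=2,
        )
        k = i.size
    order = np.lexsort((j, i, -score[i, j]))[:k]
    return float(contacts[i[order], j[order]].mean() * 100.0)


def classifier_metrics(score, ref_contacts, pred_contacts=None,
                       range_class: str = "all") -> dict:
    """AUROC / AUPR / F1 and ROC/PR curves over upper-triangle pairs.

    F1 is computed on the 8 Å binarization: ``pred_contacts`` if given,
    otherwise score > -8 under the default score = -predicted distance.
    """
    score = np.asarray(score, dtype=float)
    contacts = ref_contacts.contacts if isinstance(ref_contacts, ContactMap) \
        else np.asarray(ref_contacts, dtype=bool)
    i, j = _class_pairs(score.shape[0], range_class)
    y = contacts[i, j].astype(int)
    s = score[i, j]
    if y.min() == y.max():
        raise ValueError("need both contact and non-contact pairs")
    if pred_contacts is None:
        y_pred = (s > -CONTACT_THRESHOLD).astype(int)
    else:
        pc = pred_contacts.contacts if isinstance(pred_contacts, ContactMap) \
            else np.asarray(pred_contacts, dtype=bool)
        y_pred = pc[i, j].astype(int)
    fpr, tpr, roc_thr = roc_curve(y, s)
    prec, rec, pr_thr = precision_recall_curve(y, s)
    return {
        "auroc": float(roc_auc_score(y, s)),
        "aupr": float(auc(rec, prec)),
        "f1": float(f1_score(y, y_pred, zero_division=0.0)),
        "roc_curve": (fpr, tpr, roc_thr),
        "pr_curve": (prec, rec, pr_thr),
    }


def channel_correlation(pooled, ref) -> np.ndarray:
    """Pearson r of each input channel with the reference distances over the
    (0, 36 Å) mask — the per-channel relevance diagnostic."""
    values = pooled.values if hasattr(pooled, "values") else np.asarray(pooled)
    ref = np.asarray(ref, dtype=float)
    mask = eval_mask(ref)
    if mask.sum() < 2:
        raise ValueError("need at least two masked pairs for a correlation")
    d = ref[mask]
    out = np.empty(values.shape[0])
    for c in range(values.shape[0]):
        x = values[c][mask]
        sx, sd = x.std(), d.std()
        out[c] = np.nan if sx == 0 or sd == 0 else \
            float(np.corrcoef(x, d)[0, 1])
    return out
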