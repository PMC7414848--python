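"""Evaluation of predicted distance and contact maps.

Two families of metrics, both restricted to long-range pairs (sequence
separation |i - j| >= 24) by default:

* **MAE_t** — mean absolute error of predicted distances over pairs whose
  *true* distance is below a threshold t (8 or 12 A).  Filtering on the true
  distance means a pair predicted short but truly long contributes nothing.
* **P_L / P_NC** — precision of the top L (sequence length) or top NC
  (number of true long-range contacts) ranked long-range pairs, where a
  match is a true distance below 8 A.  Real-valued distance predictions are
  ranked through the score transform ``P_ij = 4 / D_ij`` for ``D_ij >= 4``
  and 1 otherwise (so an 8 A prediction scores 0.5).

Targets whose native structure has no long-range contact (NC = 0) are
excluded from precision aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binning import decode_to_contact, decode_to_distance
from .distmap import DistanceMap

__all__ = ["RANGE_BOUNDS", "CONTACT_THRESHOLD", "LONG_RANGE_MIN_SEP",
           "EvalReport", "separation_mask", "distance_to_score",
           "mae_at_threshold", "count_long_range_contacts", "topk_precision",
           "evaluate_target", "evaluate_dataset", "contacts_to_rr"]

CONTACT_THRESHOLD = 8.0
LONG_RANGE_MIN_SEP = 24

#: Sequence-separation classes: |i-j| within [lo, hi] (hi=None: unbounded).
RANGE_BOUNDS = {
    "local": (0, 5),
    "short": (6, 11),
    "medium": (12, 23),
    "long": (24, None),
}


def separation_mask(L: int, ranges=("long",)) -> np.ndarray:
    """L x L boolean mask of pairs whose |i - j| falls in the given classes."""
    sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
    mask = np.zeros((L, L), dtype=bool)
    for name in ranges:
        lo, hi = RANGE_BOUNDS[name]
        m = sep >= lo
        if hi is not None:
            m &= sep <= hi
        mask |= m
    return mask


def distance_to_score(D) -> np.ndarray:
    """Contact-likeness score of a predicted distance: 4/D if D >= 4, else 1."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("negative distance")
    with np.errstate(divide="ignore"):
        score = np.where(D >= 4.0, 4.0 / np.where(D > 0, D, 1.0), 1.0)
    if score.ndim == 0:
        return float(score)
    return score


def mae_at_threshold(pred: np.ndarray, true: DistanceMap, threshold: float,
                     ranges=("long",)) -> float:
    """Mean |pred - true| over masked pairs with true distance < threshold.

    Returns NaN (not-applicable) when no pair qualifies.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pred = np.asarray(pred, dtype=float)
    if pred.shape != true.values.shape:
        raise ValueError("shape mismatch")
    sel = true.mask & separation_mask(true.length, ranges) \
        & (true.values < threshold)
    if not sel.any():
        return float("nan")
    return float(np.mean(np.abs(pred[sel] - true.values[sel])))


def _long_range_pairs(true: DistanceMap):
    """Upper-triangle long-range observed pairs as index arrays."""
    L = true.length
    sel = true.mask & separation_mask(L) & np.triu(np.ones((L, L), bool), 1)
    return np.nonzero(sel)


def count_long_range_contacts(true: DistanceMap) -> int:
    """NC: number of true long-range contacts (< 8 A) in the structure."""
    ii, jj = _long_range_pairs(true)
    return int(np.sum(true.values[ii, jj] < CONTACT_THRESHOLD))


def topk_precision(scores: np.ndarray, true: DistanceMap,
                   k_rule: str = "L") -> float:
    """Precision (%) of the top-k ranked long-range pairs.

    ``k_rule='L'`` takes k = sequence length, ``'NC'`` takes k = number of
    true long-range contacts.  Pairs are ranked by score descending with
    ties broken by (i, j) lexicographic order.  Returns NaN if the target
    has no true long-range contact (excluded from evaluation).
    """
    scores = np.asarray(scores, dtype=float)
    ii, jj = _long_range_pairs(true)
    nc = int(np.sum(true.values[ii, jj] < CONTACT_THRESHOLD))
    if nc == 0:
        return float("nan")
    k = true.length if k_rule == "L" else nc
    if k_rule not in ("L", "NC"):
        raise ValueError("k_rule must be 'L' or 'NC'")
    if len(ii) == 0:
        return float("nan")
    order = np.lexsort((jj, ii, -scores[ii, jj]))
    top = order[:min(k, len(order))]
    matches = np.sum(true.values[ii[top], jj[top]] < CONTACT_THRESHOLD)
    return float(matches / len(top) * 100.0)


@dataclass
class EvalReport:
    """Per-target metrics plus unweighted aggregates over non-excluded targets."""

    per_target: pd.DataFrame
    aggregate: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.aggregate is None:
            kept = self.per_target[~self.per_target["excluded"]]
            self.aggregate = kept[["mae8", "mae12", "p_l", "p_nc"]].mean()

    def to_tsv(self, path) -> None:
        frame = self.per_target.copy()
        agg_row = {c: self.aggregate.get(c, np.nan) for c in frame.columns}
        agg_row["id"] = "MEAN"
        frame = pd.concat([frame, pd.DataFrame([agg_row])], ignore_index=True)
        frame.to_csv(path, sep="\t", index=False, float_format="%.3f")


def _scores_and_distances(prediction, mode: str):
    """Per-mode (ranking scores, predicted distances or None)."""
    values = getattr(prediction, "values", prediction)
    if mode == "contact":
        return np.asarray(values, float), None
    if mode == "distance":
        dist = np.asarray(values, float)
        return distance_to_score(dist), dist
    if mode == "binned":
        distogram = prediction.as_distogram() if hasattr(prediction, "as_distogram") \
            else prediction
        return decode_to_contact(distogram), decode_to_distance(distogram)
    raise ValueError(f"unknown mode {mode!r}")


def evaluate_target(prediction, true: DistanceMap, mode: str,
                    target_id: str = "target") -> dict:
    scores, dist = _scores_and_distances(prediction, mode)
    nc = count_long_range_contacts(true)
    row = {
        "id": target_id,
        "L": true.length,
        "NC": nc,
        "excluded": nc == 0,
        "mae8": float("nan"),
        "mae12": float("nan"),
        "p_l": float("nan"),
        "p_nc": float("nan"),
    }
    if dist is not None:
        row["mae8"] = mae_at_threshold(dist, true, 8.0)
        row["mae12"] = mae_at_threshold(dist, true, 12.0)
    if nc > 0:
        row["p_l"] = topk_precision(scores, true, "L")
        row["p_nc"] = topk_precision(scores, true, "NC")
    return row


def evaluate_dataset(predictions: dict, truths: dict, mode: str) -> EvalReport:
    """Evaluate matching id -> prediction / id -> truth maps.

    ``mode='distance'`` ranks via the score transform; ``'binned'`` decodes
    the distogram to both contacts and distances; ``'contact'`` ranks the
    probabilities directly (no MAE).
    """
    if set(predictions) != set(truths):
        raise ValueError("prediction and truth ids differ")
    rows = [evaluate_target(predictions[tid], truths[tid], mode, tid)
            for tid in sorted(predictions)]
    return EvalReport(per_target=pd.DataFrame(rows))


def contacts_to_rr(scores: np.ndarray, path, min_sep: int = LONG_RANGE_MIN_SEP,
                   top: int = None) -> None:
    """Write ranked contacts as CASP RR-like lines ``i j 0 8 score`` (1-based)."""
    scores = np.asarray(scores, dtype=float)
    L = scores.shape[0]
    ii, jj = np.nonzero(np.triu(np.ones((L, L), bool), 1)
                        & (np.abs(np.subtract.outer(np.arange(L),
                                                    np.arange(L))) >= min_sep))
    order = np.lexsort((jj, ii, -scores[ii, jj]))
    if top is not None:
        order = order[:top]
    with open(path, "w") as fh:
        for idx in order:
            fh.write(f"{ii[idx] + 1} {jj[idx] + 1} 0 8 "
                     f"{scores[ii[idx], jj[idx]]:.6f}\n")
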