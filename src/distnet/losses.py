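"""Training objectives for the three output formulations.

Contact prediction uses binary cross-entropy on sigmoid outputs, binned
distance prediction uses categorical cross-entropy on softmax outputs, and
real-valued distance prediction uses the reciprocal log-cosh loss

    Loss = log(cosh(K / (P + e) - K / (T + e)))

with K = 100.  Reciprocation makes an absolute error at a short true
distance cost far more than the same error at a long one, so optimisation
concentrates on the structurally informative short distances first.  In
practice the equivalent *label-space* form is used for training: the label
distance matrices are reciprocated once and a plain log-cosh loss is applied
to the difference — same minimiser, better conditioned for gradient descent.

All losses are means over the masked (observed) cells; probabilities are
clipped to [1e-7, 1 - 1e-7] before logarithms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "logcosh", "reciprocal_logcosh",
           "label_space_logcosh", "contact_bce", "binned_ce", "PROB_CLIP"]

PROB_CLIP = 1e-7


@dataclass
class LossConfig:
    """Loss selection and the reciprocation constants it needs.

    kind : one of ``contact-bce``, ``binned-ce``, ``reciprocal-logcosh``.
    K : reciprocation scale (keeps the transformed labels well away from
        underflow); epsilon : guard against division by zero.
    """

    kind: str = "reciprocal-logcosh"
    K: float = 100.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in {"contact-bce", "binned-ce", "reciprocal-logcosh"}:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if self.K <= 0 or self.epsilon <= 0:
            raise ValueError("K and epsilon must be positive")


def logcosh(x: np.ndarray) -> np.ndarray:
    """Numerically stable ``log(cosh(x))`` (= |x| + log1p(e^{-2|x|}) - log 2)."""
    ax = np.abs(x)
    return ax + np.log1p(np.exp(-2.0 * ax)) - np.log(2.0)


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no cells")
    return mask


def reciprocal_logcosh(P: np.ndarray, T: np.ndarray, config: LossConfig = None,
                       mask: np.ndarray = None) -> float:
    """Mean masked ``log(cosh(K/(P+e) - K/(T+e)))`` over predicted/true distances."""
    config = config or LossConfig()
    P = np.asarray(P, dtype=float)
    T = np.asarray(T, dtype=float)
    mask = _check_mask(np.ones(P.shape, bool) if mask is None else mask)
    p, t = P[mask], T[mask]
    if np.any(p < 0) or np.any(t < 0):
        raise ValueError("distances must be non-negative")
    diff = config.K / (p + config.epsilon) - config.K / (t + config.epsilon)
    return float(np.mean(logcosh(diff)))


def label_space_logcosh(P_recip: np.ndarray, T_recip, mask: np.ndarray = None) -> float:
    """Mean masked ``log(cosh(P_recip - T_recip))`` on reciprocated maps.

    This is the production training loss; it shares its minimiser (P = T on
    every masked cell) with :func:`reciprocal_logcosh`.
    """
    t = T_recip.values if hasattr(T_recip, "values") else np.asarray(T_recip)
    P_recip = np.asarray(P_recip, dtype=float)
    if mask is None and hasattr(T_recip, "mask"):
        mask = T_recip.mask
    mask = _check_mask(np.ones(P_recip.shape, bool) if mask is None else mask)
    return float(np.mean(logcosh(P_recip[mask] - np.asarray(t, float)[mask])))


def contact_bce(P: np.ndarray, true_contacts: np.ndarray,
                mask: np.ndarray = None) -> float:
    """Mean masked binary cross-entropy; a contact is a true distance < 8 A."""
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("contact probabilities must lie in [0, 1]")
    y = np.asarray(true_contacts, dtype=float)
    mask = _check_mask(np.ones(P.shape, bool) if mask is None else mask)
    p = np.clip(P[mask], PROB_CLIP, 1 - PROB_CLIP)
    yb = y[mask]
    return float(np.mean(-(yb * np.log(p) + (1 - yb) * np.log(1 - p))))


def binned_ce(distogram, true_bins: np.ndarray, mask: np.ndarray = None) -> float:
    """Mean masked categorical cross-entropy ``-log p(true bin)``."""
    probs = distogram.probs if hasattr(distogram, "probs") else np.asarray(distogram)
    true_bins = np.asarray(true_bins)
    mask = _check_mask(np.ones(true_bins.shape, bool) if mask is None else mask)
    ii, jj = np.nonzero(mask)
    p = np.clip(probs[ii, jj, true_bins[ii, jj]], PROB_CLIP, None)
    return float(np.mean(-np.log(p)))
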