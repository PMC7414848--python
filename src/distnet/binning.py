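"""Variable-width distance bins and distogram encode/decode.

Short inter-residue distances matter most for structure reconstruction, so
the bins are narrower near the contact range and widen with distance: a
fixed 0.2 A width below 8 A, then each successive bin grows by 0.2 A
(widths 0.4, 0.6, 0.8, ...), starting at 4 A and ending with an open
terminal bin beyond 26 A.  The resulting edges are
4, 4.2, ..., 8, 8.4, 9.0, 9.8, 10.8, 12, ..., 21, 23.4, 26, 26+.

A distogram holds a per-pair probability distribution over these bins.  It
decodes to a contact map by summing the probability mass of all bins below
the 8 A contact threshold, and to a real-valued distance map by taking the
midpoint of the highest-probability bin (e.g. a winning bin [6.5, 7] yields
6.75 A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distmap import DistanceMap

__all__ = ["BinScheme", "Distogram", "build_bin_scheme",
           "encode_distances", "decode_to_distance", "decode_to_contact"]

CONTACT_THRESHOLD = 8.0


@dataclass
class BinScheme:
    """Ordered distance-bin edges, optionally with an open terminal bin.

    Finite bin ``b`` covers the half-open interval ``[edges[b], edges[b+1])``;
    distances below ``edges[0]`` fall into the first bin.  With
    ``has_open_terminal`` a final bin covers ``[edges[-1], inf)`` and decodes
    to ``terminal_value`` (default: the last edge plus half of the last
    finite width, i.e. 27.3 A for the canonical scheme).
    """

    edges: np.ndarray
    has_open_terminal: bool = True
    terminal_value: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or len(self.edges) < 2:
            raise ValueError("need at least two edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.terminal_value is None:
            # open bin decodes as if the last finite width continued past it
            last_width = float(self.edges[-1] - self.edges[-2])
            self.terminal_value = round(self.edges[-1] + last_width / 2, 6)

    @property
    def num_bins(self) -> int:
        return len(self.edges) - 1 + int(self.has_open_terminal)

    @property
    def midpoints(self) -> np.ndarray:
        """Decoded distance per bin (interval midpoint; terminal_value for 26+)."""
        mids = (self.edges[:-1] + self.edges[1:]) / 2.0
        if self.has_open_terminal:
            mids = np.append(mids, self.terminal_value)
        return mids

    def contact_bins(self, threshold: float = CONTACT_THRESHOLD) -> np.ndarray:
        """Boolean mask of bins whose upper edge is <= threshold."""
        sub = self.edges[1:] <= threshold + 1e-9
        if self.has_open_terminal:
            sub = np.append(sub, False)
        return sub


@dataclass
class Distogram:
    """L x L x B per-pair bin probabilities over a :class:`BinScheme`."""

    probs: np.ndarray
    scheme: BinScheme

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("probs must be L x L x B")
        if self.probs.shape[2] != self.scheme.num_bins:
            raise ValueError(
                f"{self.probs.shape[2]} probability bins != "
                f"{self.scheme.num_bins} scheme bins")
        if np.any(self.probs < -1e-9):
            raise ValueError("negative probabilities")
        sums = self.probs.sum(axis=2)
        if np.any(np.abs(sums - 1.0) > 1e-5):
            raise ValueError("per-pair probabilities must sum to 1")

    def symmetrized(self) -> "Distogram":
        return Distogram(probs=(self.probs + self.probs.transpose(1, 0, 2)) / 2,
                         scheme=self.scheme)


def build_bin_scheme() -> BinScheme:
    """The canonical variable-width scheme: 0.2 A bins in [4, 8], then widths
    growing by 0.2 A per bin up to the 26 A edge, plus the open 26+ bin."""
    edges = [round(4.0 + 0.2 * k, 1) for k in range(21)]  # 4.0 .. 8.0
    width = 0.4
    while edges[-1] < 26.0 - 1e-9:
        edges.append(round(edges[-1] + width, 1))
        width = round(width + 0.2, 1)
    return BinScheme(edges=np.array(edges), has_open_terminal=True)


def encode_distances(dmap: DistanceMap, scheme: BinScheme) -> np.ndarray:
    """Assign each pair the index of the bin containing its true distance.

    Intervals are half-open ``[lower, upper)``; distances below the first
    edge are merged into the first bin and distances at or beyond the last
    edge go to the terminal bin (or the last finite bin without one).
    """
    idx = np.searchsorted(scheme.edges, dmap.values, side="right") - 1
    return np.clip(idx, 0, scheme.num_bins - 1).astype(np.int64)


def decode_to_distance(distogram: Distogram) -> np.ndarray:
    """Argmax bin, then the midpoint of its interval, per pair (L x L, A)."""
    best = np.argmax(distogram.probs, axis=2)
    return distogram.scheme.midpoints[best]


def decode_to_contact(distogram: Distogram,
                      threshold: float = CONTACT_THRESHOLD) -> np.ndarray:
    """Contact probability: total mass in bins whose upper edge is <= 8 A."""
    mask = distogram.scheme.contact_bins(threshold)
    return distogram.probs[:, :, mask].sum(axis=2)
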