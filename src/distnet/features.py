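"""Input features: alignment statistics, tiled 1D predictions, feature volumes.

The predictor consumes seven features derived from the query sequence and its
multiple sequence alignment (MSA): sequence profile, three-state secondary
structure probabilities, solvent accessibility, two coevolution matrices
(CCMpred-style and FreeContact-style), an MSA contact-potential matrix, and
the per-column Shannon entropy.  2D features enter as L x L channels; 1D
features are tiled along rows and columns into two L x L channels per
component.  The external predictors themselves (PSIPRED, CCMpred,
FreeContact, alnstats) are not run here — their outputs are parsed from
plain-text files or synthesised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAP", "AA_ALPHABET", "PROFILE_ALPHABET", "PROBABILITY_FEATURES",
    "Alignment", "Feature1D", "Feature2D", "FeatureVolume",
    "clean_alignment", "sequence_profile", "shannon_entropy",
    "tile_1d", "assemble_volume", "crop_or_pad", "sample_crop_window",
]

GAP = "-"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Profile columns: the 20 standard amino acids plus X for anything else.
PROFILE_ALPHABET = AA_ALPHABET + "X"
#: 1D feature names whose values are probabilities (checked to stay in [0,1]).
PROBABILITY_FEATURES = {"profile", "ss3", "solvent_acc"}


@dataclass
class Alignment:
    """An MSA: equal-length rows over amino acids + gap, query first."""

    rows: list
    query_length: int = 0

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("alignment rows have unequal lengths")
        if self.query_length == 0:
            self.query_length = n

    @property
    def query(self) -> str:
        return self.rows[0]

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class Feature1D:
    """Per-residue feature: ``values`` is L x k."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("Feature1D values must be L x k")
        if self.name in PROBABILITY_FEATURES:
            if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
                raise ValueError(f"{self.name}: probabilities outside [0,1]")


@dataclass
class Feature2D:
    """Pairwise feature: ``values`` is L x L."""

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("Feature2D values must be square")


@dataclass
class FeatureVolume:
    """L x L x C stack of input channels with a channel-name manifest."""

    values: np.ndarray
    channel_names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("volume must be L x L x C")
        if len(self.channel_names) != self.values.shape[2]:
            raise ValueError("channel_names length != number of channels")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def num_channels(self) -> int:
        return self.values.shape[2]


def clean_alignment(aln: Alignment) -> Alignment:
    """Drop all-gap rows and exact duplicate rows (first occurrence kept).

    The query row is always retained.  Idempotent.
    """
    seen = set()
    out = []
    for idx, row in enumerate(aln.rows):
        if idx > 0 and set(row) <= {GAP}:
            continue
        if row in seen:
            continue
        seen.add(row)
        out.append(row)
    return Alignment(rows=out, query_length=aln.query_length)


def _column_frequencies(aln: Alignment) -> np.ndarray:
    """(L, 21) relative symbol frequencies per column, gaps excluded."""
    rows = np.array([list(r.upper()) for r in aln.rows])
    L = rows.shape[1]
    idx = {a: k for k, a in enumerate(PROFILE_ALPHABET)}
    counts = np.zeros((L, len(PROFILE_ALPHABET)))
    for j in range(L):
        col = rows[:, j]
        for sym in col:
            if sym == GAP or sym == ".":
                continue
            counts[j, idx.get(sym, idx["X"])] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return counts / totals


def sequence_profile(aln: Alignment) -> Feature1D:
    """Per-column amino-acid frequency profile over the 21-letter alphabet.

    Gaps are excluded from the normalisation, so each column with at least
    one residue sums to 1.
    """
    return Feature1D(name="profile", values=_column_frequencies(aln))


def shannon_entropy(aln: Alignment) -> Feature1D:
    """Per-column Shannon entropy in bits: ``H = -sum p log2 p`` (p > 0)."""
    freqs = _column_frequencies(aln)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    return Feature1D(name="entropy", values=-terms.sum(axis=1, keepdims=True))


def tile_1d(feature: Feature1D, L: int) -> list:
    """Tile each 1D component into two L x L channels (row- and column-wise).

    The row-tiled channel has ``channel[i, j] = v[j]`` and the column-tiled
    channel ``channel[i, j] = v[i]``.
    """
    if feature.values.shape[0] != L:
        raise ValueError(
            f"{feature.name}: length {feature.values.shape[0]} != {L}")
    out = []
    for k in range(feature.values.shape[1]):
        v = feature.values[:, k]
        out.append(Feature2D(name=f"{feature.name}[{k}]:row",
                             values=np.tile(v, (L, 1))))
        out.append(Feature2D(name=f"{feature.name}[{k}]:col",
                             values=np.tile(v[:, None], (1, L))))
    return out


def assemble_volume(features1d: list, features2d: list) -> FeatureVolume:
    """Stack 2D features then tiled 1D features into an L x L x C volume.

    The channel order is deterministic: the 2D features in the order given,
    then each 1D feature's tiled channels (row before column per component)
    in the order given.  Non-finite values are rejected.
    """
    if not features1d and not features2d:
        raise ValueError("no features to assemble")
    L = (features2d[0].values.shape[0] if features2d
         else features1d[0].values.shape[0])
    channels, names = [], []
    for f in features2d:
        if f.values.shape != (L, L):
            raise ValueError(f"{f.name}: shape {f.values.shape} != ({L},{L})")
        channels.append(f.values)
        names.append(f.name)
    for f in features1d:
        for ch in tile_1d(f, L):
            channels.append(ch.values)
            names.append(ch.name)
    volume = np.stack(channels, axis=2)
    if not np.all(np.isfinite(volume)):
        raise ValueError("non-finite values in assembled volume")
    return FeatureVolume(values=volume, channel_names=names)


def sample_crop_window(L: int, crop: int, pad: int, rng) -> tuple:
    """Draw the top-left corner (in padded coordinates) of a crop window.

    Offsets along i and j are independent and uniform over all positions
    where the window fits inside the zero-padded (L + 2*pad) frame.
    """
    padded = L + 2 * pad
    span = max(padded, crop)
    hi = span - crop  # inclusive
    oi = int(rng.integers(0, hi + 1))
    oj = int(rng.integers(0, hi + 1))
    return oi, oj


def _crop_plane(plane: np.ndarray, oi: int, oj: int, crop: int, pad: int,
                fill=0.0) -> np.ndarray:
    """Extract a crop x crop window from a zero-padded 2D plane."""
    L = plane.shape[0]
    out = np.full((crop, crop), fill, dtype=plane.dtype)
    # window origin in original (unpadded) coordinates
    i0 = oi - pad
    j0 = oj - pad
    src_i0, src_i1 = max(i0, 0), min(i0 + crop, L)
    src_j0, src_j1 = max(j0, 0), min(j0 + crop, L)
    if src_i0 < src_i1 and src_j0 < src_j1:
        out[src_i0 - i0:src_i1 - i0, src_j0 - j0:src_j1 - j0] = \
            plane[src_i0:src_i1, src_j0:src_j1]
    return out


def crop_or_pad(volume: FeatureVolume, labels, crop: int, pad: int,
                rng_seed) -> tuple:
    """Random crop augmentation with zero padding, applied jointly.

    Every channel is zero-padded by ``pad`` on all four sides, then a
    ``crop x crop`` window is cut at a position drawn uniformly from the
    seeded generator; the identical window is applied to the label distance
    map, whose mask is false over the padding.  If the padded frame is
    smaller than the crop, it is zero-filled up to the crop size (so an
    L=118 map with pad=5 and crop=128 has exactly one window).
    """
    from .distmap import DistanceMap

    if crop <= 0 or pad < 0:
        raise ValueError("crop must be positive, pad non-negative")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) \
        else np.random.default_rng(rng_seed)
    L = volume.length
    oi, oj = sample_crop_window(L, crop, pad, rng)
    vol_out = np.stack(
        [_crop_plane(volume.values[:, :, c], oi, oj, crop, pad)
         for c in range(volume.num_channels)], axis=2)
    lab_values = _crop_plane(labels.values, oi, oj, crop, pad)
    lab_mask = _crop_plane(labels.mask, oi, oj, crop, pad, fill=False)
    return (FeatureVolume(values=vol_out,
                          channel_names=list(volume.channel_names)),
            DistanceMap(values=lab_values, mask=lab_mask))
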