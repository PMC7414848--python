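"""Ground-truth distance maps and reciprocated label maps.

The regression target for inter-residue distance prediction is the L x L
matrix of Euclidean distances between the beta carbons (Cb) of every residue
pair, computed from the experimentally solved structure.  Residues missing
from the structure (or carrying non-standard amino acids) are masked out
rather than imputed, so downstream losses and metrics only ever see observed
pairs.

For real-valued distance regression the labels are *reciprocated*:
``K / (d + eps)`` with ``K = 100`` by default, after replacing the zero
diagonal by the mean of its horizontal/vertical neighbours.  Reciprocation
maps short distances to large targets, which is what makes a plain log-cosh
loss on the transformed labels concentrate on the structurally important
short distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "STANDARD_AA3",
    "ProteinRecord",
    "DistanceMap",
    "ReciprocalMap",
    "ChainError",
    "UnalignableChainError",
    "clean_chain",
    "compute_distance_map",
    "reciprocate",
    "distances_from_reciprocal",
]

#: Three-letter -> one-letter codes for the 20 standard amino acids.
STANDARD_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


class ChainError(ValueError):
    """Raised for empty or otherwise unusable chains."""


class UnalignableChainError(ChainError):
    """Raised when no residue of a chain can be mapped onto the FASTA sequence."""


@dataclass
class ProteinRecord:
    """A single protein chain aligned to its reference (FASTA) sequence.

    Attributes
    ----------
    id : str
        Target identifier.
    sequence : str
        Reference amino-acid sequence of length L.
    cb_coords : (L, 3) float array
        Cb coordinates in Angstrom (Ca used for glycine); NaN where the
        residue is not observed.
    valid : (L,) bool array
        True where the residue was observed in the structure.
    """

    id: str
    sequence: str
    cb_coords: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.cb_coords = np.asarray(self.cb_coords, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        L = len(self.sequence)
        if self.cb_coords.shape != (L, 3):
            raise ValueError(
                f"cb_coords shape {self.cb_coords.shape} != ({L}, 3)")
        if self.valid.shape != (L,):
            raise ValueError(f"valid shape {self.valid.shape} != ({L},)")
        if not np.all(np.isfinite(self.cb_coords[self.valid])):
            raise ValueError("non-finite coordinates at valid positions")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DistanceMap:
    """Symmetric L x L Cb-Cb distance matrix with a pair validity mask."""

    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 2:
            raise ValueError("values and mask must be matching L x L arrays")
        if np.any(self.values[self.mask] < 0):
            raise ValueError("masked distances must be non-negative")

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass
class ReciprocalMap:
    """Reciprocated distance labels ``K / (d + epsilon)``.

    Larger values mean shorter distances; the transform is strictly
    monotone decreasing, so it is invertible off the (replaced) diagonal.
    """

    values: np.ndarray
    scale_K: float = 100.0
    epsilon: float = 1e-6
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.values.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)


def clean_chain(residues, fasta_sequence: str, id: str = "chain") -> ProteinRecord:
    """Clean a parsed chain and renumber it against the FASTA sequence.

    ``residues`` is a sequence of ``(resname3, ca_xyz_or_None,
    cb_xyz_or_None)`` tuples in chain order (see :func:`distnet.io.
    read_pdb_residues`).  Residues with non-standard amino-acid names (e.g.
    selenomethionine, MSE) are dropped; the remaining one-letter sequence is
    matched to the FASTA sequence — by exact substring search first, then by
    global alignment (match 1, mismatch -1, gap -2).  Positions of the FASTA
    sequence without a mapped residue get ``valid=False``.

    Glycine has no Cb, so its Ca is used; for any other residue missing a
    Cb, Ca is used as a fallback with a warning.
    """
    if not fasta_sequence:
        raise ValueError("empty FASTA sequence")
    kept = []
    for resname, ca, cb in residues:
        aa = STANDARD_AA3.get(str(resname).upper().strip())
        if aa is None:
            continue
        if ca is None and cb is None:
            continue
        kept.append((aa, ca, cb))
    if not kept:
        raise ChainError(f"{id}: no standard residues with coordinates")

    struct_seq = "".join(aa for aa, _, _ in kept)
    mapping = _map_to_fasta(struct_seq, fasta_sequence)
    if not mapping:
        raise UnalignableChainError(
            f"{id}: chain sequence does not align to the FASTA sequence")

    L = len(fasta_sequence)
    coords = np.full((L, 3), np.nan)
    valid = np.zeros(L, dtype=bool)
    for si, fi in mapping.items():
        aa, ca, cb = kept[si]
        xyz = cb
        if aa == "G":
            xyz = ca if ca is not None else cb
        elif cb is None:
            warnings.warn(
                f"{id}: residue {fi + 1} ({aa}) has no Cb atom; using Ca",
                stacklevel=2,
            )
            xyz = ca
        if xyz is None:
            continue
        coords[fi] = xyz
        valid[fi] = True
    if not valid.any():
        raise UnalignableChainError(f"{id}: no residue could be placed")
    return ProteinRecord(id=id, sequence=fasta_sequence,
                         cb_coords=coords, valid=valid)


def _map_to_fasta(struct_seq: str, fasta: str) -> dict:
    """Map structure-sequence indices to FASTA indices.

    Exact contiguous match wins; otherwise a simple global alignment is
    used and only identically matched columns are kept.
    """
    start = fasta.find(struct_seq)
    if start >= 0:
        return {i: start + i for i in range(len(struct_seq))}

    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    alignment = aligner.align(struct_seq, fasta)[0]
    mapping: dict = {}
    for (s0, s1), (f0, f1) in zip(*alignment.aligned):
        for k in range(s1 - s0):
            if struct_seq[s0 + k] == fasta[f0 + k]:
                mapping[s0 + k] = f0 + k
    return mapping


def compute_distance_map(record: ProteinRecord) -> DistanceMap:
    """Pairwise Cb-Cb Euclidean distances from a chain's coordinates.

    ``values[i, j]`` is the distance in Angstrom; ``mask[i, j]`` is true iff
    both residues are observed.  Unmasked entries are zero.
    """
    if not record.valid.any():
        raise ChainError(f"{record.id}: no valid residues")
    coords = np.where(record.valid[:, None], record.cb_coords, 0.0)
    values = cdist(coords, coords)
    mask = np.outer(record.valid, record.valid)
    values[~mask] = 0.0
    return DistanceMap(values=values, mask=mask)


def reciprocate(dmap: DistanceMap, K: float = 100.0,
                epsilon: float = 1e-6) -> ReciprocalMap:
    """Reciprocate a distance map into regression labels.

    The zero diagonal would blow up under ``1/d``, so each diagonal entry is
    first replaced by the mean of its in-bounds horizontal and vertical
    neighbours; every entry ``d`` then becomes ``K / (d + epsilon)``.
    """
    if K <= 0 or epsilon <= 0:
        raise ValueError("K and epsilon must be positive")
    d = np.array(dmap.values, dtype=float)
    if np.any(d[dmap.mask] < 0):
        raise ValueError("negative distances")
    n = d.shape[0]
    for i in range(n):
        neigh = []
        if i > 0:
            neigh += [d[i - 1, i], d[i, i - 1]]
        if i < n - 1:
            neigh += [d[i + 1, i], d[i, i + 1]]
        if neigh:
            d[i, i] = float(np.mean(neigh))
    values = K / (d + epsilon)
    return ReciprocalMap(values=values, scale_K=K, epsilon=epsilon,
                         mask=np.array(dmap.mask, dtype=bool))


def distances_from_reciprocal(values: np.ndarray, K: float = 100.0,
                              epsilon: float = 1e-6,
                              min_value: float | None = None) -> np.ndarray:
    """Invert the reciprocal transform: ``d = K / v - epsilon``.

    ``min_value`` clips the reciprocated values from below before inversion
    (useful for network outputs that can be arbitrarily close to zero).
    """
    v = np.asarray(values, dtype=float)
    if min_value is not None:
        v = np.clip(v, min_value, None)
    return K / v - epsilon
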