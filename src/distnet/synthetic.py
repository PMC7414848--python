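"""Self-consistent toy proteins, feature volumes and alignments.

Every other module is testable offline through this generator.  Chains are
compact 3D walks with realistic consecutive-residue spacing (~3.8 A steps,
as between consecutive alpha carbons), confined to a sphere scaled like a
globular protein so that genuine long-range contacts arise.  Feature
volumes follow the full seven-feature channel manifest; the coevolution-like
2D channels are ``signal_strength * (true contact indicator) + noise`` so a
planted, learnable signal of known strength is available for training smoke
tests.  Alignments are mutated copies of the query with optional planted
duplicate rows, all-gap rows and fully conserved columns.

The folds are geometrically plausible, not physically valid: there is no
self-avoidance, side-chain packing or phylogenetic structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distmap import ProteinRecord, compute_distance_map
from .features import (AA_ALPHABET, Alignment, Feature1D, Feature2D,
                       FeatureVolume, GAP, assemble_volume)

__all__ = ["SyntheticSpec", "make_protein", "make_features",
           "make_alignment", "make_dataset", "FEATURE2D_NAMES"]

FEATURE2D_NAMES = ("ccmpred", "freecontact", "potential")
#: 1D manifest: (name, components); each tiles to two channels per component.
FEATURE1D_MANIFEST = (("profile", 21), ("ss3", 3),
                      ("solvent_acc", 1), ("entropy", 1))
#: 3 native 2D channels + 2 channels per 1D component = 55.
NUM_CHANNELS = len(FEATURE2D_NAMES) + 2 * sum(k for _, k in FEATURE1D_MANIFEST)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic target.

    length: residues (>= 20).  fold_style: 'helix-bundle' (high directional
    persistence, like packed secondary structure) or 'random-walk' (more
    tortuous).  noise_sd: SD of the additive noise on the coevolution-like
    channels.  signal_strength: weight of the true-contact indicator in
    those channels (1 = perfectly informative).  seed: reproducibility.
    """

    length: int = 64
    fold_style: str = "helix-bundle"
    noise_sd: float = 0.1
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 20:
            raise ValueError("length must be >= 20")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.fold_style not in ("helix-bundle", "random-walk"):
            raise ValueError(f"unknown fold_style {self.fold_style!r}")


def make_protein(spec: SyntheticSpec) -> ProteinRecord:
    """A compact chain: fixed ~3.8 A steps confined to a protein-sized sphere.

    The step direction is a persistent random direction plus a pull toward
    the origin that switches on outside the confinement radius
    ``2.5 * L^(1/3)`` A (globular-protein scaling), guaranteeing long-range
    contacts for chains of ~50+ residues.  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    sigma = 0.35 if spec.fold_style == "helix-bundle" else 0.9
    radius = 2.5 * L ** (1.0 / 3.0)
    coords = np.zeros((L, 3))
    direction = _unit(rng.normal(size=3))
    for i in range(1, L):
        prev = coords[i - 1]
        pull = np.zeros(3)
        dist0 = np.linalg.norm(prev)
        if dist0 > radius:
            pull = -_unit(prev) * min(1.0, (dist0 / radius - 1.0) * 2.0)
        direction = _unit(direction + sigma * rng.normal(size=3) + pull)
        coords[i] = prev + rng.uniform(3.75, 3.85) * direction
    sequence = "".join(rng.choice(list(AA_ALPHABET), size=L))
    return ProteinRecord(id=f"synth{spec.seed:04d}", sequence=sequence,
                         cb_coords=coords, valid=np.ones(L, dtype=bool))


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def make_features(record: ProteinRecord, spec: SyntheticSpec) -> FeatureVolume:
    """Feature volume over the full seven-feature manifest (55 channels).

    The three 2D channels are ``signal_strength * contact + N(0, noise_sd)``
    (symmetrised); contact is the true <8 A indicator from the record's own
    coordinates.  1D channels are valid random probabilities (Dirichlet rows
    for profile and secondary structure) and a non-negative entropy column.
    """
    rng = np.random.default_rng(spec.seed + 1)
    L = len(record)
    dmap = compute_distance_map(record)
    contact = ((dmap.values < 8.0) & dmap.mask).astype(float)
    features2d = []
    for name in FEATURE2D_NAMES:
        noise = rng.normal(0.0, spec.noise_sd, size=(L, L)) if spec.noise_sd \
            else np.zeros((L, L))
        noise = (noise + noise.T) / 2.0
        features2d.append(Feature2D(name=name,
                                    values=spec.signal_strength * contact + noise))
    features1d = [
        Feature1D(name="profile", values=rng.dirichlet(np.ones(21), size=L)),
        Feature1D(name="ss3", values=rng.dirichlet(np.ones(3), size=L)),
        Feature1D(name="solvent_acc", values=rng.random((L, 1))),
        Feature1D(name="entropy", values=rng.random((L, 1)) * np.log2(21)),
    ]
    return assemble_volume(features1d, features2d)


def make_alignment(record: ProteinRecord, n_rows: int = 50,
                   mutation_rate: float = 0.1, gap_rate: float = 0.05,
                   seed: int = 0, n_duplicate_rows: int = 0,
                   n_allgap_rows: int = 0,
                   conserved_positions=()) -> Alignment:
    """Query plus mutated copies, with plantable pathologies.

    Mutations and gaps are drawn i.i.d. per position except at
    ``conserved_positions``, which stay identical to the query in every row
    (zero column entropy).  ``n_duplicate_rows`` exact copies of the query
    and ``n_allgap_rows`` all-gap rows are appended for alignment-cleaning
    tests.
    """
    rng = np.random.default_rng(seed)
    query = record.sequence
    L = len(query)
    conserved = set(conserved_positions)
    rows = [query]
    for _ in range(max(n_rows - 1, 0)):
        row = list(query)
        for p in range(L):
            if p in conserved:
                continue
            u = rng.random()
            if u < gap_rate:
                row[p] = GAP
            elif u < gap_rate + mutation_rate:
                row[p] = AA_ALPHABET[int(rng.integers(len(AA_ALPHABET)))]
        rows.append("".join(row))
    rows.extend([query] * n_duplicate_rows)
    rows.extend([GAP * L] * n_allgap_rows)
    return Alignment(rows=rows)


def make_dataset(n_targets: int, base_spec: SyntheticSpec = None,
                 seed: int = 0) -> list:
    """(FeatureVolume, DistanceMap) pairs for ``n_targets`` distinct chains.

    Target ``t`` inherits the base conditions with seed ``seed + t`` so the
    folds differ while the noise/signal conditions stay fixed.
    """
    base = base_spec or SyntheticSpec()
    dataset = []
    for t in range(n_targets):
        spec = SyntheticSpec(length=base.length, fold_style=base.fold_style,
                             noise_sd=base.noise_sd,
                             signal_strength=base.signal_strength,
                             seed=seed + t)
        record = make_protein(spec)
        dataset.append((make_features(record, spec),
                        compute_distance_map(record)))
    return dataset
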