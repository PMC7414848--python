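"""File formats: PDB, FASTA, MSA, PSIPRED tables, matrices, npz containers.

Structures are read with Biopython's PDB parser (single chain, first model,
first altloc).  MSAs are plain text with one aligned sequence per line;
a3m-style files are accepted by stripping lowercase insertion states.
Secondary structure arrives as PSIPRED ``.ss2`` tables and solvent
accessibility as one probability per line; 2D features (CCMpred,
FreeContact, contact potential) are whitespace-delimited square matrices.
Distance maps, feature volumes, distograms and predictions are stored as
``.npz`` containers keyed by channel name.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .binning import BinScheme, Distogram
from .distmap import DistanceMap, ProteinRecord, STANDARD_AA3
from .features import Alignment, Feature1D, Feature2D, FeatureVolume

__all__ = [
    "read_fasta", "write_fasta", "read_msa", "write_msa",
    "read_ss2", "write_ss2", "read_solvent_acc", "write_solvent_acc",
    "read_matrix", "write_matrix", "read_pdb_residues", "write_pdb",
    "save_distance_map", "load_distance_map", "save_volume", "load_volume",
    "save_distogram", "load_distogram", "save_prediction", "load_prediction",
]

ONE_TO_THREE = {v: k for k, v in STANDARD_AA3.items()}


# -- sequences and alignments ----------------------------------------------

def read_fasta(path) -> tuple:
    """(id, sequence) of the first record."""
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return record.id, str(record.seq).upper()


def write_fasta(path, seq_id: str, sequence: str) -> None:
    with open(path, "w") as fh:
        fh.write(f">{seq_id}\n{sequence}\n")


def read_msa(path) -> Alignment:
    """One aligned sequence per line; lowercase (a3m insertions) stripped."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith((">", "#")):
                continue
            rows.append("".join(c for c in line if not c.islower()).upper()
                        .replace(".", "-"))
    return Alignment(rows=rows)


def write_msa(path, aln: Alignment) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(aln.rows) + "\n")


# -- 1D feature tables ------------------------------------------------------

def read_ss2(path) -> Feature1D:
    """PSIPRED .ss2: per residue, columns (idx, aa, state, pC, pH, pE).

    Returned with components ordered (helix, strand, coil).
    """
    probs = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 6 or parts[0].startswith("#"):
                continue
            try:
                int(parts[0])
            except ValueError:
                continue
            pc, ph, pe = (float(parts[3]), float(parts[4]), float(parts[5]))
            probs.append((ph, pe, pc))
    arr = np.array(probs)
    arr = arr / np.clip(arr.sum(axis=1, keepdims=True), 1e-9, None)
    return Feature1D(name="ss3", values=arr)


def write_ss2(path, sequence: str, probs: np.ndarray) -> None:
    """Write (helix, strand, coil) probabilities as a PSIPRED-style table."""
    states = "HEC"
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT-like\n\n")
        for i, (aa, row) in enumerate(zip(sequence, probs), start=1):
            ph, pe, pc = row
            state = states[int(np.argmax(row))]
            fh.write(f"{i:4d} {aa} {state}  {pc:6.3f} {ph:6.3f} {pe:6.3f}\n")


def read_solvent_acc(path) -> Feature1D:
    values = np.loadtxt(str(path), ndmin=1).reshape(-1, 1)
    return Feature1D(name="solvent_acc", values=values)


def write_solvent_acc(path, values: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(values).reshape(-1), fmt="%.4f")


# -- 2D feature matrices ----------------------------------------------------

def read_matrix(path, name: str) -> Feature2D:
    """Whitespace-delimited square matrix; symmetrised by averaging."""
    values = np.loadtxt(str(path))
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"{path}: not a square matrix")
    if not np.allclose(values, values.T, atol=1e-3):
        warnings.warn(f"{path}: matrix noticeably asymmetric; averaging",
                      stacklevel=2)
    return Feature2D(name=name, values=(values + values.T) / 2.0)


def write_matrix(path, values: np.ndarray) -> None:
    np.savetxt(str(path), np.asarray(values), fmt="%.6f")


# -- structures -------------------------------------------------------------

def read_pdb_residues(path, chain_id: str = None) -> list:
    """Residues of one chain as (resname, ca_xyz, cb_xyz) tuples.

    First model only; Biopython resolves altlocs (first/highest occupancy).
    HETATM water is skipped; other HETATM residues (e.g. MSE) are kept so
    that chain cleaning can drop them explicitly.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise ValueError(f"chain {chain_id!r} not found in {path}")
    chain = chains[0]
    out = []
    for residue in chain.get_residues():
        if residue.get_resname() == "HOH":
            continue
        ca = residue["CA"].get_coord() if "CA" in residue else None
        cb = residue["CB"].get_coord() if "CB" in residue else None
        if ca is None and cb is None:
            continue
        out.append((residue.get_resname(),
                    None if ca is None else np.asarray(ca, float),
                    None if cb is None else np.asarray(cb, float)))
    return out


def write_pdb(path, record: ProteinRecord, chain_id: str = "A") -> None:
    """Minimal single-chain PDB: CA (and CB for non-glycine) per valid residue.

    Both atoms share the record's coordinates — sufficient for round-trips
    through chain cleaning and distance-map construction.
    """
    serial = 1
    with open(path, "w") as fh:
        for i, aa in enumerate(record.sequence):
            if not record.valid[i]:
                continue
            res3 = ONE_TO_THREE.get(aa, "UNK")
            x, y, z = record.cb_coords[i]
            atoms = ["CA"] if aa == "G" else ["CA", "CB"]
            for atom in atoms:
                fh.write(
                    f"ATOM  {serial:5d}  {atom:<3s} {res3:3s} {chain_id}"
                    f"{i + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {atom[0]:>2s}\n")
                serial += 1
        fh.write("END\n")


# -- npz containers ---------------------------------------------------------

def save_distance_map(path, dmap: DistanceMap) -> None:
    np.savez_compressed(path, values=dmap.values, mask=dmap.mask)


def load_distance_map(path) -> DistanceMap:
    data = np.load(str(path))
    return DistanceMap(values=data["values"], mask=data["mask"])


def save_volume(path, volume: FeatureVolume) -> None:
    np.savez_compressed(path, values=volume.values,
                        channel_names=np.array(volume.channel_names))


def load_volume(path) -> FeatureVolume:
    data = np.load(str(path))
    return FeatureVolume(values=data["values"],
                         channel_names=[str(n) for n in data["channel_names"]])


def save_distogram(path, distogram: Distogram) -> None:
    np.savez_compressed(path, probs=distogram.probs,
                        edges=distogram.scheme.edges,
                        has_open_terminal=distogram.scheme.has_open_terminal,
                        terminal_value=distogram.scheme.terminal_value)


def load_distogram(path) -> Distogram:
    data = np.load(str(path))
    scheme = BinScheme(edges=data["edges"],
                       has_open_terminal=bool(data["has_open_terminal"]),
                       terminal_value=float(data["terminal_value"]))
    return Distogram(probs=data["probs"], scheme=scheme)


def save_prediction(path, prediction) -> None:
    from .model import PredictionMap

    assert isinstance(prediction, PredictionMap)
    extra = {}
    if prediction.kind == "binned":
        extra = {"edges": prediction.scheme.edges,
                 "has_open_terminal": prediction.scheme.has_open_terminal,
                 "terminal_value": prediction.scheme.terminal_value}
    np.savez_compressed(path, kind=prediction.kind, values=prediction.values,
                        **extra)


def load_prediction(path):
    from .model import PredictionMap

    data = np.load(str(path))
    kind = str(data["kind"])
    scheme = None
    if kind == "binned":
        scheme = BinScheme(edges=data["edges"],
                           has_open_terminal=bool(data["has_open_terminal"]),
                           terminal_value=float(data["terminal_value"]))
    return PredictionMap(kind=kind, values=data["values"], scheme=scheme)


def ensure_dir(path) -> str:
    os.makedirs(path, exist_ok=True)
    return str(path)
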