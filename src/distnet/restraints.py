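"""Distance-to-restraint conversion for 3D model building.

A predicted real-valued distance d becomes a bounded restraint with error
range ``delta = 0.03 * d * d``, lower bound ``l = d - delta/2`` and upper
bound ``u = d + delta/2``.  The quadratic growth of delta mirrors the
training loss, which trusts short predicted distances more than long ones.
Restraints are emitted as TSV or Rosetta-style bounded-constraint lines;
running the modelling protocol itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import separation_mask

__all__ = ["Restraint", "distance_to_restraint", "select_restraints",
           "restraints_to_tsv", "restraints_to_rosetta"]

MIN_LOWER_BOUND = 1e-6  # clamp so the lower bound stays positive


@dataclass
class Restraint:
    """One bounded pair restraint; residue indices are 1-based, i < j."""

    i: int
    j: int
    d: float
    delta: float
    lower: float
    upper: float


def distance_to_restraint(d: float, i: int, j: int) -> Restraint:
    """Bounded restraint for a predicted distance: delta = 0.03 d^2."""
    if d <= 0:
        raise ValueError("predicted distance must be positive")
    if i >= j:
        i, j = min(i, j), max(i, j)
    delta = 0.03 * d * d
    return Restraint(i=i, j=j, d=float(d), delta=float(delta),
                     lower=max(float(d - delta / 2), MIN_LOWER_BOUND),
                     upper=float(d + delta / 2))


def select_restraints(pred, max_distance: float = 12.0,
                      ranges=("medium", "long")) -> list:
    """Restraints for upper-triangle pairs with predicted d <= max_distance.

    ``pred`` is a distance :class:`~distnet.model.PredictionMap` or a plain
    L x L array in Angstrom.  One restraint per unordered pair, sorted by
    predicted distance ascending; output indices are 1-based.
    """
    values = np.asarray(getattr(pred, "values", pred), dtype=float)
    L = values.shape[0]
    sel = np.triu(np.ones((L, L), bool), 1) & separation_mask(L, ranges) \
        & (values <= max_distance) & (values > 0)
    ii, jj = np.nonzero(sel)
    order = np.argsort(values[ii, jj], kind="stable")
    return [distance_to_restraint(values[ii[k], jj[k]],
                                  int(ii[k]) + 1, int(jj[k]) + 1)
            for k in order]


def restraints_to_tsv(restraints: list, path) -> None:
    with open(path, "w") as fh:
        fh.write("i\tj\td\tdelta\tlower\tupper\n")
        for r in restraints:
            fh.write(f"{r.i}\t{r.j}\t{r.d:.3f}\t{r.delta:.3f}"
                     f"\t{r.lower:.3f}\t{r.upper:.3f}\n")


def restraints_to_rosetta(restraints: list, path) -> None:
    """Rosetta bounded-constraint lines: AtomPair CB i CB j BOUNDED l u 1 0.5 tag."""
    with open(path, "w") as fh:
        for r in restraints:
            fh.write(f"AtomPair CB {r.i} CB {r.j} BOUNDED "
                     f"{r.lower:.3f} {r.upper:.3f} 1 0.5 dist\n")
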