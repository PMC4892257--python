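"""Pattern metrics for tissue snapshots.

Quantifies what the tissue figures show qualitatively: phenotype
fractions, connected clusters of like-labelled cells under the
hexagonal neighbour relation, the unlike-neighbour fraction (high for
salt-and-pepper/lateral-inhibition patterns, low for clustered
lateral-induction patterns) and the tissue-mean NICD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .model import ModelError, SPECIES
from .tissue import Snapshot

__all__ = [
    "PatternSummary",
    "phenotype_fractions",
    "cluster_components",
    "unlike_neighbour_fraction",
    "mean_nicd",
    "summarize",
]

_I_NICD = SPECIES.index("nicd")
_EMT_LABELS = ("E", "E/M", "M")


def phenotype_fractions(snapshot: Snapshot) -> Tuple[float, float, float]:
    """(f_E, f_EM, f_M); fractions of all lattice cells, summing to 1."""
    lab = snapshot.emt
    n = len(lab)
    return tuple(float(np.sum(lab == k)) / n for k in _EMT_LABELS)


def cluster_components(snapshot: Snapshot, label: str) -> List[int]:
    """Sizes (descending) of connected components of ``label`` cells.

    Connectivity is the lattice's hexagonal neighbour relation restricted
    to cells carrying the given EMT label; ``label`` may also be
    ``"non-E"`` for the union of E/M and M cells.
    """
    if label == "non-E":
        member = snapshot.emt != "E"
    elif label in _EMT_LABELS:
        member = snapshot.emt == label
    else:
        raise ModelError(f"unknown label {label!r}")
    nb = snapshot.lattice.neighbours
    n = len(member)
    seen = np.zeros(n, bool)
    sizes: List[int] = []
    for i in range(n):
        if member[i] and not seen[i]:
            stack = [i]
            seen[i] = True
            size = 0
            while stack:
                k = stack.pop()
                size += 1
                for j in nb[k]:
                    if j >= 0 and member[j] and not seen[j]:
                        seen[j] = True
                        stack.append(j)
            sizes.append(size)
    return sorted(sizes, reverse=True)


def unlike_neighbour_fraction(snapshot: Snapshot) -> float:
    """Fraction of unordered neighbour pairs whose EMT labels differ.

    Each pair is counted once; open-boundary lattices count only pairs
    that exist.  0 for a uniform tissue; 0.5 in expectation for two
    equally likely independent labels on a periodic lattice.
    """
    nb = snapshot.lattice.neighbours
    lab = snapshot.emt
    i_idx = np.repeat(np.arange(nb.shape[0]), nb.shape[1])
    j_idx = nb.ravel()
    keep = (j_idx >= 0) & (j_idx > i_idx)
    if not np.any(keep):
        return 0.0
    return float(np.mean(lab[i_idx[keep]] != lab[j_idx[keep]]))


def mean_nicd(snapshot: Snapshot, reference: Optional[Snapshot] = None) -> float:
    """Arithmetic mean NICD over cells; relative to ``reference`` if given.

    The relative variant divides by the reference snapshot's mean (the
    paper-style normalisation against an unstimulated run).
    """
    m = float(np.mean(snapshot.states[:, _I_NICD]))
    if reference is None:
        return m
    ref = float(np.mean(reference.states[:, _I_NICD]))
    if ref <= 0:
        raise ModelError("reference snapshot has zero mean NICD")
    return m / ref


@dataclass
class PatternSummary:
    """All metrics of one snapshot."""

    time: float
    fractions: Tuple[float, float, float]
    cluster_sizes: Dict[str, List[int]]
    mean_cluster_non_e: float
    max_cluster_non_e: int
    unlike_neighbour: float
    mean_nicd: float

    def to_dict(self) -> dict:
        return {
            "time_h": self.time,
            "fraction_E": self.fractions[0],
            "fraction_EM": self.fractions[1],
            "fraction_M": self.fractions[2],
            "cluster_sizes": self.cluster_sizes,
            "mean_cluster_non_E": self.mean_cluster_non_e,
            "max_cluster_non_E": self.max_cluster_non_e,
            "unlike_neighbour_fraction": self.unlike_neighbour,
            "mean_nicd": self.mean_nicd,
        }


def summarize(snapshot: Snapshot, reference: Optional[Snapshot] = None) -> PatternSummary:
    sizes = {lab: cluster_components(snapshot, lab) for lab in ("E", "E/M", "M", "non-E")}
    non_e = sizes["non-E"]
    return PatternSummary(
        time=snapshot.time,
        fractions=phenotype_fractions(snapshot),
        cluster_sizes=sizes,
        mean_cluster_non_e=float(np.mean(non_e)) if non_e else 0.0,
        max_cluster_non_e=int(non_e[0]) if non_e else 0,
        unlike_neighbour=unlike_neighbour_fraction(snapshot),
        mean_nicd=mean_nicd(snapshot, reference),
    )
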