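"""Phenotype classification.

EMT state is read off the miR-200 level: epithelial (E) above the upper
band edge, mesenchymal (M) below the lower edge, hybrid E/M in between.
The signalling role is read off receptor/ligand levels: a Sender (S)
presents ligand but carries little receptor, a Receiver (R) the reverse,
and a hybrid Sender/Receiver (S/R) carries both receptor and ligand.

Default thresholds are derived from the model itself rather than typed
in: the miR-200 band edges are geometric midpoints between the three
stable branches of the decoupled EMT core inside its tristable window,
and each high/low signalling boundary is the geometric mean of the
Sender-state and Receiver-state level of that species at the reference
bistable operating point (J_ext = 600, N_ext = 5000).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

from .model import (
    Environment,
    ModelParameters,
    ModelError,
    SPECIES,
    find_stable_states,
)

__all__ = [
    "PhenotypeThresholds",
    "classify_emt",
    "classify_sr",
    "classify_emt_many",
    "classify_sr_many",
    "derive_default_thresholds",
    "DEFAULT_THRESHOLDS",
]

_I_N = SPECIES.index("notch")
_I_D = SPECIES.index("delta")
_I_J = SPECIES.index("jagged")
_I_U200 = SPECIES.index("mir200")


@dataclass(frozen=True)
class PhenotypeThresholds:
    """Band edges (molecules) for the two classifiers."""

    mir200_upper: float = 14900.0   # E above
    mir200_lower: float = 4400.0    # M below
    notch_high: float = 120.0
    delta_high: float = 15.7
    jagged_high: float = 73.0

    def __post_init__(self) -> None:
        if not (self.mir200_upper > self.mir200_lower > 0):
            raise ModelError("require mir200_upper > mir200_lower > 0")
        for f in ("notch_high", "delta_high", "jagged_high"):
            if not getattr(self, f) > 0:
                raise ModelError(f"{f} must be > 0")


DEFAULT_THRESHOLDS = PhenotypeThresholds()


def classify_emt(state, th: PhenotypeThresholds = DEFAULT_THRESHOLDS) -> str:
    """Map a cell state to 'E', 'E/M' or 'M' by its miR-200 band."""
    u = float(np.asarray(state, float)[_I_U200])
    if u > th.mir200_upper:
        return "E"
    if u > th.mir200_lower:
        return "E/M"
    return "M"


def classify_sr(state, th: PhenotypeThresholds = DEFAULT_THRESHOLDS) -> str:
    """Map a cell state to 'S', 'R', 'S/R' or 'none'.

    Ligand-high means Delta or Jagged above its boundary.  A cell that is
    receptor-high and ligand-high is a hybrid Sender/Receiver.
    """
    s = np.asarray(state, float)
    notch_high = s[_I_N] > th.notch_high
    ligand_high = (s[_I_D] > th.delta_high) or (s[_I_J] > th.jagged_high)
    if notch_high and ligand_high:
        return "S/R"
    if notch_high:
        return "R"
    if ligand_high:
        return "S"
    return "none"


def classify_emt_many(states: np.ndarray, th: PhenotypeThresholds = DEFAULT_THRESHOLDS):
    """Vectorised :func:`classify_emt` over an (n, 10) array."""
    u = np.asarray(states, float)[:, _I_U200]
    out = np.where(u > th.mir200_upper, "E", np.where(u > th.mir200_lower, "E/M", "M"))
    return out

def classify_sr_many(states: np.ndarray, th: PhenotypeThresholds = DEFAULT_THRESHOLDS):
    """Vectorised :func:`classify_sr` over an (n, 10) array."""
    s = np.asarray(states, float)
    nh = s[:, _I_N] > th.notch_high
    lh = (s[:, _I_D] > th.delta_high) | (s[:, _I_J] > th.jagged_high)
    return np.where(nh & lh, "S/R", np.where(nh, "R", np.where(lh, "S", "none")))


def _decoupled(params: ModelParameters) -> ModelParameters:
    """EMT core in isolation: no Notch production, no trans-interaction."""
    return params.with_overrides(g_notch=0.0, g_delta=0.0, g_jagged=0.0,
                                 kt_delta=0.0, kt_jagged=0.0)


def derive_default_thresholds(
    params: ModelParameters,
    i_ext_grid: Iterable[float] = tuple(np.arange(25.0, 60.0, 2.5)),
    seed: int = 0,
) -> PhenotypeThresholds:
    """Recompute thresholds from the model (see module docstring).

    Scans ``i_ext_grid`` for the tristable window of the decoupled EMT
    core and places the miR-200 edges at geometric midpoints of adjacent
    branches; then computes signalling boundaries from the Sender and
    Receiver states at the reference operating point.
    """
    dec = _decoupled(params)
    # canonical seeds near the three EMT branches; the hybrid basin is
    # narrow and easily missed by uniform random starts alone
    branch_seeds = [
        np.array([0, 0, 0, 0, 3.0e4, 20, 1.5e3, 2.5e4, 150, 4.0e4]),
        np.array([0, 0, 0, 0, 1.0e4, 300, 6.0e4, 9.0e3, 300, 2.0e5]),
        np.array([0, 0, 0, 0, 8.0e2, 900, 9.0e5, 3.0e3, 500, 3.0e5]),
    ]
    edges = None
    for i_ext in i_ext_grid:
        states = find_stable_states(Environment(i_ext=float(i_ext)), dec,
                                    n_starts=12, seed=seed,
                                    extra_starts=branch_seeds)
        if len(states) == 3:
            u = sorted(s[_I_U200] for s in states)
            edges = (float(np.sqrt(u[1] * u[2])), float(np.sqrt(u[0] * u[1])))
            break
    if edges is None:
        raise ModelError("no tristable window found on the supplied I_ext grid")

    ref = find_stable_states(Environment(j_ext=600.0, n_ext=5000.0), params,
                             n_starts=24, seed=seed)
    if len(ref) < 2:
        raise ModelError("reference operating point is not bistable")
    by_notch = sorted(ref, key=lambda s: s[_I_N])
    sender, receiver = by_notch[0], by_notch[-1]
    gm = lambda a, b: float(np.sqrt(max(a, 1e-9) * max(b, 1e-9)))

    # Jagged is transcriptionally activated by NICD, so even the Receiver
    # carries moderate Jagged; its high/low boundary therefore separates
    # the Receiver branch from the Jagged-high hybrid branch rather than
    # Sender from Receiver.
    hybrid = find_stable_states(Environment(j_ext=3000.0, n_ext=5000.0), params,
                                n_starts=20, seed=seed)
    hybrid_j = [s[_I_J] for s in hybrid
                if edges[1] < s[_I_U200] <= edges[0]]
    j_hi = gm(receiver[_I_J], min(hybrid_j)) if hybrid_j \
        else gm(sender[_I_J], receiver[_I_J])
    return PhenotypeThresholds(
        mir200_upper=edges[0],
        mir200_lower=edges[1],
        notch_high=gm(sender[_I_N], receiver[_I_N]),
        delta_high=gm(sender[_I_D], receiver[_I_D]),
        jagged_high=j_hi,
    )
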