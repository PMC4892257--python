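"""Hexagonal-lattice multicellular simulation.

Every cell runs the single-cell circuit of :mod:`notchemt.model`; its
environment is assembled each step from the ligand and receptor levels
of its six neighbours (odd-r offset hexagonal stencil) plus the global
external signals.  The update is synchronous: all environments are
computed from the current tissue state, then every cell advances one
RK4 step with the shared time step, which makes runs deterministic and
invariant under cell relabelling.

Neighbour aggregation defaults to the summed contribution of the six
neighbouring membranes; the arithmetic mean is available as an option
(``aggregation="mean"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    Environment,
    IntegrationError,
    ModelError,
    ModelParameters,
    N_SPECIES,
    SPECIES,
    derivatives_vec,
)
from .phenotyping import (
    DEFAULT_THRESHOLDS,
    PhenotypeThresholds,
    classify_emt_many,
    classify_sr_many,
)

__all__ = [
    "Lattice",
    "TissueConfig",
    "Snapshot",
    "build_lattice",
    "random_initial_states",
    "neighbour_environment",
    "simulate_tissue",
    "DEFAULT_INIT_RANGES",
]


@dataclass(frozen=True)
class Lattice:
    """Hexagonal grid with a precomputed neighbour map.

    ``neighbours`` is an ``(n, 6)`` integer array; missing neighbours on
    an open boundary are encoded as -1.
    """

    rows: int
    cols: int
    boundary: str
    neighbours: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def degree(self) -> np.ndarray:
        return (self.neighbours >= 0).sum(axis=1)

    def positions(self) -> np.ndarray:
        """(n, 2) axial plot coordinates (odd rows shifted half a cell)."""
        r, c = np.divmod(np.arange(self.n_cells), self.cols)
        x = c + 0.5 * (r % 2)
        y = r * np.sqrt(3.0) / 2.0
        return np.stack([x, y], axis=1)


def build_lattice(rows: int, cols: int, boundary: str = "periodic") -> Lattice:
    """Odd-r offset hexagonal lattice with a symmetric neighbour relation."""
    if rows < 2 or cols < 2:
        raise ModelError("lattice dimensions must be >= 2")
    if boundary not in ("periodic", "open"):
        raise ModelError(f"unknown boundary mode {boundary!r}")
    periodic = boundary == "periodic"
    if periodic and rows % 2:
        # the offset stencil alternates by row parity, so vertical wrapping
        # is only consistent for an even number of rows
        raise ModelError("periodic hexagonal lattices need an even number of rows")
    nb = np.full((rows * cols, 6), -1, dtype=int)
    even = ((-1, -1), (-1, 0), (0, -1), (0, 1), (1, -1), (1, 0))
    odd = ((-1, 0), (-1, 1), (0, -1), (0, 1), (1, 0), (1, 1))
    for r in range(rows):
        offs = odd if r % 2 else even
        for c in range(cols):
            i = r * cols + c
            for k, (dr, dc) in enumerate(offs):
                rr, cc = r + dr, c + dc
                if periodic:
                    nb[i, k] = (rr % rows) * cols + (cc % cols)
                elif 0 <= rr < rows and 0 <= cc < cols:
                    nb[i, k] = rr * cols + cc
    return Lattice(rows, cols, boundary, nb)


#: Default per-species upper bounds for the seeded random initial tissue
#: (uniform draws on [0, hi]); spans the dynamical range of the one-cell
#: attractors so that tissues start as an incoherent mix of phenotypes.
DEFAULT_INIT_RANGES: Dict[str, float] = {
    "notch": 400.0,
    "delta": 350.0,
    "jagged": 1500.0,
    "nicd": 80.0,
    "mir200": 40000.0,
    "zeb_mrna": 900.0,
    "zeb": 9.0e5,
    "mir34": 26000.0,
    "snail_mrna": 500.0,
    "snail": 3.2e5,
}


@dataclass(frozen=True)
class TissueConfig:
    """Run configuration for a tissue simulation."""

    params: ModelParameters = field(default_factory=ModelParameters)
    i_ext: float = 0.0
    sd_ext: float = 0.0
    sj_ext: float = 0.0
    t_end: float = 120.0
    dt: float = 0.1
    seed: int = 0
    aggregation: str = "sum"
    init_ranges: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_INIT_RANGES))
    snapshot_times: Tuple[float, ...] = ()
    thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS

    def __post_init__(self) -> None:
        if self.aggregation not in ("sum", "mean"):
            raise ModelError("aggregation must be 'sum' or 'mean'")
        if self.dt <= 0 or self.t_end <= 0:
            raise ModelError("dt and t_end must be positive")
        bad = [t for t in self.snapshot_times if not (0 <= t <= self.t_end)]
        if bad:
            raise ModelError(f"snapshot times outside [0, t_end]: {bad}")
        for k, v in self.init_ranges.items():
            if k not in SPECIES:
                raise ModelError(f"unknown species in init_ranges: {k!r}")
            if v < 0:
                raise ModelError("init ranges must be >= 0")


@dataclass
class Snapshot:
    """Tissue state at one time point, with phenotype labels attached."""

    time: float
    lattice: Lattice
    states: np.ndarray              # (n_cells, 10)
    emt: np.ndarray                 # (n_cells,) of 'E' | 'E/M' | 'M'
    sr: np.ndarray                  # (n_cells,) of 'S' | 'R' | 'S/R' | 'none'

    def to_frame(self):
        import pandas as pd

        r, c = np.divmod(np.arange(self.lattice.n_cells), self.lattice.cols)
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_h", self.time)
        df.insert(0, "col", c)
        df.insert(0, "row", r)
        df.insert(0, "cell_id", np.arange(self.lattice.n_cells))
        df["emt_label"] = self.emt
        df["sr_label"] = self.sr
        return df

    @classmethod
    def from_frame(cls, df, boundary: str = "periodic",
                   thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS) -> "Snapshot":
        rows = int(df["row"].max()) + 1
        cols = int(df["col"].max()) + 1
        lat = build_lattice(rows, cols, boundary)
        df = df.sort_values("cell_id")
        states = df[list(SPECIES)].to_numpy(float)
        return make_snapshot(float(df["time_h"].iloc[0]), lat, states, thresholds)


def make_snapshot(time: float, lattice: Lattice, states: np.ndarray,
                  thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS) -> Snapshot:
    states = np.asarray(states, float)
    return Snapshot(time, lattice, states.copy(),
                    classify_emt_many(states, thresholds),
                    classify_sr_many(states, thresholds))


def random_initial_states(lattice: Lattice, ranges: Optional[Dict[str, float]] = None,
                          seed: int = 0) -> np.ndarray:
    """Independent uniform draws per species per cell, reproducible by seed."""
    ranges = dict(DEFAULT_INIT_RANGES) if ranges is None else ranges
    hi = np.array([ranges.get(s, DEFAULT_INIT_RANGES[s]) for s in SPECIES])
    if np.any(hi < 0):
        raise ModelError("init ranges must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.uniform(0.0, 1.0, (lattice.n_cells, N_SPECIES)) * hi


def neighbour_environment(lattice: Lattice, states: np.ndarray,
                          config: TissueConfig) -> Dict[str, np.ndarray]:
    """Per-cell environment assembled from the six neighbours.

    ``d_ext``/``j_ext``/``n_ext`` aggregate the neighbours' Delta, Jagged
    and Notch (sum or mean per ``config.aggregation``); soluble ligands
    and ``i_ext`` are global and uniform.
    """
    states = np.asarray(states, float)
    if states.shape != (lattice.n_cells, N_SPECIES):
        raise ModelError(
            f"expected states of shape {(lattice.n_cells, N_SPECIES)}, got {states.shape}")
    nb = lattice.neighbours
    mask = nb >= 0
    safe = np.where(mask, nb, 0)

    def agg(col: int) -> np.ndarray:
        v = np.where(mask, states[safe, col], 0.0).sum(axis=1)
        if config.aggregation == "mean":
            v = v / np.maximum(mask.sum(axis=1), 1)
        return v

    n = lattice.n_cells
    return {
        "d_ext": agg(SPECIES.index("delta")),
        "j_ext": agg(SPECIES.index("jagged")),
        "n_ext": agg(SPECIES.index("notch")),
        "sd_ext": np.full(n, config.sd_ext),
        "sj_ext": np.full(n, config.sj_ext),
        "i_ext": np.full(n, config.i_ext),
    }


def simulate_tissue(lattice: Lattice, states0: np.ndarray,
                    config: TissueConfig) -> List[Snapshot]:
    """Synchronous tissue integration; returns requested snapshots.

    Snapshots are emitted at ``config.snapshot_times`` (rounded to the
    step grid) and always at ``t_end``.  Initial states are taken as
    given -- use :func:`random_initial_states` or a loaded snapshot.
    """
    Y = np.asarray(states0, float).copy()
    if Y.shape != (lattice.n_cells, N_SPECIES):
        raise ModelError(
            f"expected states of shape {(lattice.n_cells, N_SPECIES)}, got {Y.shape}")
    p = config.params
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    want = {int(round(t / dt)) for t in config.snapshot_times if t > 0}
    want.add(n_steps)
    if any(abs(t / dt - round(t / dt)) > 1e-9 for t in config.snapshot_times):
        raise ModelError("snapshot times must be multiples of dt")
    out: List[Snapshot] = []
    if 0.0 in config.snapshot_times:
        out.append(make_snapshot(0.0, lattice, Y, config.thresholds))
    for step in range(1, n_steps + 1):
        env = neighbour_environment(lattice, Y, config)
        k1 = derivatives_vec(Y, env, p)
        k2 = derivatives_vec(np.maximum(Y + 0.5 * dt * k1, 0.0), env, p)
        k3 = derivatives_vec(np.maximum(Y + 0.5 * dt * k2, 0.0), env, p)
        k4 = derivatives_vec(np.maximum(Y + dt * k3, 0.0), env, p)
        Y = np.maximum(Y + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4), 0.0)
        if not np.all(np.isfinite(Y)):
            bad_cell, bad_sp = np.argwhere(~np.isfinite(Y))[0]
            raise IntegrationError(
                f"tissue integration failed at cell {bad_cell}, species "
                f"'{SPECIES[bad_sp]}', t = {step * dt:.2f} h")
        if step in want:
            out.append(make_snapshot(step * dt, lattice, Y, config.thresholds))
    return out
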