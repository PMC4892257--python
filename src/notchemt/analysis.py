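"""Brute-force bifurcation analysis of the one-cell system.

Stable branches are enumerated by multi-start relaxation (no numerical
continuation): at each swept parameter value a set of random initial
conditions -- plus the states found at the previous value, which keeps
branches connected across the sweep -- is integrated to stationarity,
residual-checked and deduplicated.  Fold points are therefore located
only to the sweep's grid resolution.

All starts of all parameter values are stacked into one batch and
integrated together through the vectorised right-hand side, which keeps
brute-force scans affordable at the default resolutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    Environment,
    ModelError,
    ModelParameters,
    N_SPECIES,
    SPECIES,
    START_SCALE,
    derivatives_vec,
    steady_state_residual,
    _dedup,
)
from .phenotyping import (
    DEFAULT_THRESHOLDS,
    PhenotypeThresholds,
    classify_emt,
    classify_sr,
)

__all__ = [
    "BranchPoint",
    "BifurcationResult",
    "PhaseDiagram",
    "sweep_parameter",
    "nullclines_ND",
    "phase_diagram",
]

_SWEEPABLE = ("j_ext", "d_ext", "i_ext", "sj_ext", "sd_ext")

_IN, _ID = SPECIES.index("notch"), SPECIES.index("delta")


def _rk4_batch(Y, dt, env, p):
    k1 = derivatives_vec(Y, env, p)
    k2 = derivatives_vec(np.maximum(Y + 0.5 * dt * k1, 0.0), env, p)
    k3 = derivatives_vec(np.maximum(Y + 0.5 * dt * k2, 0.0), env, p)
    k4 = derivatives_vec(np.maximum(Y + dt * k3, 0.0), env, p)
    return np.maximum(Y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)


def relax_batch(Y0: np.ndarray, env: Dict[str, np.ndarray], params: ModelParameters,
                t_settle: float = 1500.0, dt: float = 0.4) -> np.ndarray:
    """Integrate a batch of cells with per-cell fixed environments."""
    Y = np.asarray(Y0, float).copy()
    for _ in range(int(round(t_settle / dt))):
        Y = _rk4_batch(Y, dt, env, params)
    return Y


@dataclass
class BranchPoint:
    """One stable state on a bifurcation branch, with phenotype labels."""

    value: float
    state: np.ndarray
    emt: str
    sr: str
    residual: float


@dataclass
class BifurcationResult:
    """Stable states found along a 1-D parameter sweep."""

    parameter: str
    values: np.ndarray
    branches: List[List[BranchPoint]]     # one list per parameter value

    def labels_at(self, value_index: int) -> List[Tuple[str, str]]:
        return sorted({(bp.emt, bp.sr) for bp in self.branches[value_index]})

    def emt_sets(self) -> List[Tuple[str, ...]]:
        return [tuple(sorted({bp.emt for bp in col})) for col in self.branches]

    def to_frame(self):
        import pandas as pd

        rows = []
        for col in self.branches:
            for bp in col:
                row = {self.parameter: bp.value, "emt_label": bp.emt,
                       "sr_label": bp.sr, "residual": bp.residual}
                row.update({s: bp.state[i] for i, s in enumerate(SPECIES)})
                rows.append(row)
        return pd.DataFrame(rows)


def _base_env_dict(base_env: Environment, n: int) -> Dict[str, np.ndarray]:
    return {k: np.full(n, getattr(base_env, k))
            for k in ("d_ext", "j_ext", "n_ext", "sd_ext", "sj_ext", "i_ext")}


def sweep_parameter(
    name: str,
    values: Sequence[float],
    base_env: Environment,
    params: ModelParameters,
    n_starts: int = 24,
    seed: int = 0,
    tol: float = 1e-3,
    thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS,
    t_settle: float = 1500.0,
) -> BifurcationResult:
    """Stable-state enumeration along one swept environment variable.

    ``values`` must be sorted; each value's candidate starts include the
    stable states found at the previous value (branch carry-over).
    """
    if name not in _SWEEPABLE:
        raise ModelError(f"sweepable parameters are {_SWEEPABLE}, got {name!r}")
    values = np.asarray(values, float)
    if values.ndim != 1 or len(values) == 0 or np.any(np.diff(values) < 0):
        raise ModelError("values must be a non-empty sorted 1-D sequence")
    if n_starts < 1:
        raise ModelError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)

    # shared random + canonical starts; carried-over branch states are
    # appended per value
    from .model import CANONICAL_STARTS

    base_starts = np.vstack(
        [rng.uniform(0.0, 1.0, (n_starts, N_SPECIES)) * START_SCALE]
        + [s[None, :] for s in CANONICAL_STARTS])
    carry: List[np.ndarray] = []
    branches: List[List[BranchPoint]] = []
    for v in values:
        starts = np.vstack([base_starts] + [s[None, :] for s in carry]) \
            if carry else base_starts
        env = _base_env_dict(base_env, len(starts))
        env[name] = np.full(len(starts), v)
        final = relax_batch(starts, env, params, t_settle=t_settle)
        env1 = {k: arr[:1] for k, arr in env.items()}
        scalar_env = Environment(**{k: float(a[0]) for k, a in env1.items()})
        kept: List[Tuple[float, np.ndarray]] = []
        for y in final:
            res = steady_state_residual(y, scalar_env, params)
            if res < tol:
                kept.append((res, y))
        kept.sort(key=lambda t: t[0])
        uniq = _dedup([y for _, y in kept])
        col = [BranchPoint(float(v), y,
                           classify_emt(y, thresholds), classify_sr(y, thresholds),
                           steady_state_residual(y, scalar_env, params))
               for y in uniq]
        branches.append(col)
        carry = list(uniq)
    return BifurcationResult(name, values, branches)


# ---------------------------------------------------------------------------
# nullclines
# ---------------------------------------------------------------------------

_FAST_IDX = [i for i in range(N_SPECIES) if i not in (_IN, _ID)]


def _relax_others(N_grid, D_grid, env_scalar: Environment, params: ModelParameters,
                  t_relax: float = 500.0, dt: float = 0.4):
    """Relax all species except Notch and Delta at fixed (N, D) pairs."""
    NN, DD = np.meshgrid(N_grid, D_grid, indexing="ij")
    n = NN.size
    Y = np.tile(np.array([0, 0, 10.0, 1.0, 3.0e4, 20.0, 2.0e3, 2.0e4, 150.0, 6.0e4]), (n, 1))
    Y[:, _IN] = NN.ravel()
    Y[:, _ID] = DD.ravel()
    env = _base_env_dict(env_scalar, n)
    for _ in range(int(round(t_relax / dt))):
        Y = _rk4_batch(Y, dt, env, params)
        Y[:, _IN] = NN.ravel()
        Y[:, _ID] = DD.ravel()
    F = derivatives_vec(Y, env, params)
    return Y, F[:, _IN].reshape(NN.shape), F[:, _ID].reshape(NN.shape)


def _zero_contours(N_grid, D_grid, F):
    """Zero-level contour polylines of F over the (N, D) grid."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    from contourpy import contour_generator

    gen = contour_generator(*np.meshgrid(N_grid, D_grid, indexing="ij"), F)
    return [np.asarray(seg) for seg in gen.lines(0.0)]


@dataclass
class NullclineResult:
    notch_grid: np.ndarray
    delta_grid: np.ndarray
    dN_field: np.ndarray
    dD_field: np.ndarray
    notch_nullcline: List[np.ndarray]   # polylines in the (N, D) plane
    delta_nullcline: List[np.ndarray]
    intersections: List[Tuple[np.ndarray, bool]]  # (full state, stable?)


def nullclines_ND(
    env: Environment,
    params: ModelParameters,
    n_max: float = 600.0,
    d_max: float = 250.0,
    resolution: int = 40,
    seed: int = 0,
) -> NullclineResult:
    """Notch/Delta nullclines with the other species at quasi-steady state.

    For every grid point (N, D) the remaining eight species are relaxed
    at fixed (N, D); the two curves are the zero contours of dN/dt and
    dD/dt of the relaxed states.  Intersections are located from the
    coarse fields, polished by full relaxation, and classified stable or
    unstable by perturbed re-integration.
    """
    N_grid = np.linspace(1.0, n_max, resolution)
    D_grid = np.linspace(0.0, d_max, resolution)
    Y, FN, FD = _relax_others(N_grid, D_grid, env, params)
    n_curves = _zero_contours(N_grid, D_grid, FN)
    d_curves = _zero_contours(N_grid, D_grid, FD)

    # candidate intersections: grid cells where both fields change sign
    sN, sD = np.sign(FN), np.sign(FD)
    cand = []
    for i in range(len(N_grid) - 1):
        for j in range(len(D_grid) - 1):
            bn = sN[i:i+2, j:j+2]
            bd = sD[i:i+2, j:j+2]
            if bn.max() >= 0 >= bn.min() and bd.max() >= 0 >= bd.min():
                cand.append(Y[i * len(D_grid) + j].copy())
    # polish: free relaxation of the full system from each candidate
    env1 = _base_env_dict(env, max(len(cand), 1))
    inter: List[Tuple[np.ndarray, bool]] = []
    if cand:
        polished = relax_batch(np.stack(cand), env1, params, t_settle=1200.0)
        stable = []
        for y in polished:
            if steady_state_residual(y, env, params) < 1e-3:
                stable.append(y)
        for y in _dedup(stable):
            inter.append((y, True))
        # unstable points: candidates whose polished state left the cell are
        # saddles between attractors; report the unpolished QSS state
        for y0 in cand:
            moved = all(np.max(np.abs(y0 - y) / (np.abs(y) + 1.0)) > 0.25
                        for y, _ in inter) if inter else True
            near_existing = any(
                np.max(np.abs(y0 - u) / (np.abs(u) + 1.0)) < 0.25 for u, _ in inter)
            if moved and not near_existing:
                inter.append((y0, False))
    return NullclineResult(N_grid, D_grid, FN, FD, n_curves, d_curves, inter)


# ---------------------------------------------------------------------------
# two-parameter phase diagram
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    """Coexisting (EMT, S/R) label sets over a (D_ext, J_ext) grid."""

    d_values: np.ndarray
    j_values: np.ndarray
    label_sets: List[List[Tuple[Tuple[str, str], ...]]]   # [i_d][i_j]

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, d in enumerate(self.d_values):
            for j, jv in enumerate(self.j_values):
                rows.append({
                    "d_ext": d, "j_ext": jv,
                    "labels": "|".join(f"{e},{s}" for e, s in self.label_sets[i][j]),
                })
        return pd.DataFrame(rows)


def phase_diagram(
    d_values: Sequence[float],
    j_values: Sequence[float],
    base_env: Environment,
    params: ModelParameters,
    n_starts: int = 12,
    seed: int = 0,
    thresholds: PhenotypeThresholds = DEFAULT_THRESHOLDS,
    tol: float = 1e-3,
    t_settle: float = 1500.0,
) -> PhaseDiagram:
    """Label sets of coexisting stable states over a (D_ext, J_ext) grid.

    All grid points and starts are integrated as one batch.
    """
    d_values = np.asarray(d_values, float)
    j_values = np.asarray(j_values, float)
    for name, v in (("d_values", d_values), ("j_values", j_values)):
        if v.ndim != 1 or len(v) == 0 or np.any(np.diff(v) < 0):
            raise ModelError(f"{name} must be a sorted 1-D sequence")
    from .model import CANONICAL_STARTS

    rng = np.random.default_rng(seed)
    nd, nj = len(d_values), len(j_values)
    ns = n_starts + len(CANONICAL_STARTS)
    block = np.vstack([np.stack(CANONICAL_STARTS)]
                      + [rng.uniform(0.0, 1.0, (n_starts, N_SPECIES)) * START_SCALE])
    starts = np.tile(block, (nd * nj, 1))
    DD = np.repeat(d_values, nj * ns)
    JJ = np.tile(np.repeat(j_values, ns), nd)
    env = _base_env_dict(base_env, nd * nj * ns)
    env["d_ext"] = DD
    env["j_ext"] = JJ
    final = relax_batch(starts, env, params, t_settle=t_settle)

    label_sets: List[List[Tuple[Tuple[str, str], ...]]] = []
    idx = 0
    for i in range(nd):
        row = []
        for j in range(nj):
            block = final[idx:idx + ns]
            idx += ns
            scalar_env = Environment(
                d_ext=float(d_values[i]), j_ext=float(j_values[j]),
                n_ext=base_env.n_ext, sd_ext=base_env.sd_ext,
                sj_ext=base_env.sj_ext, i_ext=base_env.i_ext)
            kept = [(steady_state_residual(y, scalar_env, params), y) for y in block]
            kept = sorted([t for t in kept if t[0] < tol], key=lambda t: t[0])
            uniq = _dedup([y for _, y in kept])
            labels = sorted({(classify_emt(y, thresholds), classify_sr(y, thresholds))
                             for y in uniq})
            row.append(tuple(labels))
        label_sets.append(row)
    return PhaseDiagram(d_values, j_values, label_sets)
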