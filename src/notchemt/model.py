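"""Single-cell ODE core of the coupled Notch-Delta-Jagged / EMT circuit.

The circuit couples juxtacrine Notch signalling to the core regulatory
network of the epithelial-mesenchymal transition (EMT):

* Notch side: the receptor Notch (N) binds Delta or Jagged presented by
  neighbouring membranes (``D_ext``, ``J_ext``) or supplied as soluble
  ligand (``sD_ext``, ``sJ_ext``).  Each trans-interaction consumes one
  receptor and releases one Notch intracellular domain (NICD, ``I``).
  NICD transcriptionally activates Notch, Jagged and SNAIL and represses
  Delta.  Receptor and ligand in the *same* cell mutually inactivate
  (cis-inhibition).
* EMT side: two interlinked mutually-inhibitory loops, miR-34/SNAIL and
  miR-200/ZEB.  SNAIL activates ZEB transcription and represses both
  microRNAs; ZEB represses both microRNAs; the microRNAs act on their
  target mRNAs through a multi-site binding model that both blocks
  translation and triggers active degradation of the mRNA-microRNA
  complex.  An external EMT-inducing signal ``I_ext`` (lumped TGF-beta /
  Wnt) activates SNAIL transcription.
* Cross-talk: miR-34 translationally inhibits Notch and Delta, miR-200
  translationally inhibits Jagged, and NICD activates SNAIL -- so Notch
  activity drives EMT and EMT de-represses the Notch ligands.

All species are molecule counts (dimensionless numbers of molecules per
cell); time is in hours.  Transcriptional regulation uses the shifted
Hill function H(X) = (1 + lambda (X/X0)^n) / (1 + (X/X0)^n), equal to 1
with no regulator and to the fold-change ``lambda`` at saturation.

The right-hand side is vectorised: a state is a ``(n_cells, 10)`` array,
which makes the multicellular simulator in :mod:`notchemt.tissue` a thin
loop over the same code path used for one cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "SPECIES",
    "HillSpec",
    "MicroRNARepression",
    "ModelParameters",
    "Environment",
    "Trajectory",
    "ModelError",
    "IntegrationError",
    "shifted_hill",
    "mirna_repression",
    "cell_derivatives",
    "integrate_cell",
    "find_stable_states",
]

#: Species order used throughout the package.
SPECIES: Tuple[str, ...] = (
    "notch",       # N   -- Notch receptor (molecules)
    "delta",       # D   -- Delta ligand
    "jagged",      # J   -- Jagged ligand
    "nicd",        # I   -- Notch intracellular domain
    "mir200",      # u200
    "zeb_mrna",    # mz
    "zeb",         # Z
    "mir34",       # u34
    "snail_mrna",  # ms
    "snail",       # S
)

N_SPECIES = len(SPECIES)


class ModelError(ValueError):
    """Invalid model input (negative copy number, malformed spec...)."""


_MIR_TABLE_CACHE: Dict[tuple, tuple] = {}


class IntegrationError(RuntimeError):
    """Trajectory diverged or produced non-finite values."""


# ---------------------------------------------------------------------------
# regulation primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HillSpec:
    """One transcriptional regulation edge, as a shifted Hill function.

    Parameters
    ----------
    threshold:
        Half-response threshold X0 in molecules; must be positive.
    coefficient:
        Hill coefficient n (positive integer).
    fold_change:
        Saturating fold-change lambda; < 1 represses, > 1 activates,
        1 makes the edge neutral.
    """

    threshold: float
    coefficient: int
    fold_change: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ModelError(f"Hill threshold must be > 0, got {self.threshold}")
        if int(self.coefficient) != self.coefficient or self.coefficient < 1:
            raise ModelError(f"Hill coefficient must be a positive integer, got {self.coefficient}")
        if not self.fold_change >= 0:
            raise ModelError(f"Hill fold-change must be >= 0, got {self.fold_change}")


def shifted_hill(X, spec: HillSpec):
    """Evaluate the shifted Hill function of ``spec`` at copy number ``X``.

    Returns ``(1 + lambda (X/X0)^n) / (1 + (X/X0)^n)``; equals 1 at
    ``X = 0`` and approaches ``lambda`` as ``X`` grows.  ``X`` may be a
    scalar or an array.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ModelError("shifted_hill: regulator level must be finite and >= 0")
    r = (X / spec.threshold) ** spec.coefficient
    out = (1.0 + spec.fold_change * r) / (1.0 + r)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class MicroRNARepression:
    """Multi-site microRNA-target interaction.

    A target mRNA carries ``n`` microRNA binding sites.  With microRNA
    level ``mu`` and threshold ``mu0``, the probability of exactly ``i``
    occupied sites is binomial,
    ``M_i = C(n, i) x^i / (1 + x)^n`` with ``x = mu / mu0``.
    Occupancy ``i`` leaves a residual translation rate ``l_i`` (``l_0 = 1``,
    non-increasing) and degrades the complex at rate ``gamma_m_i``,
    consuming ``i`` microRNAs at rate ``gamma_mu_i`` each.
    """

    translation_factors: Tuple[float, ...]
    mrna_degradation: Tuple[float, ...]
    mirna_degradation: Tuple[float, ...]
    threshold: float

    def __post_init__(self) -> None:
        l = self.translation_factors
        if len(l) < 2 or abs(l[0] - 1.0) > 1e-12:
            raise ModelError("translation factors must start at 1 (zero occupancy)")
        if any(b > a + 1e-12 for a, b in zip(l, l[1:])):
            raise ModelError("translation factors must be non-increasing in occupancy")
        if any(v < 0 or v > 1 for v in l):
            raise ModelError("translation factors must lie in [0, 1]")
        if len(self.mrna_degradation) != len(l) or len(self.mirna_degradation) != len(l):
            raise ModelError("per-occupancy sequences must share a length (n_sites + 1)")
        if any(v < 0 for v in self.mrna_degradation + self.mirna_degradation):
            raise ModelError("degradation multipliers must be >= 0")
        if not self.threshold > 0:
            raise ModelError("microRNA threshold must be > 0")

    @property
    def n_sites(self) -> int:
        return len(self.translation_factors) - 1

    def _tables(self):
        key = (self.translation_factors, self.mrna_degradation, self.mirna_degradation)
        tab = _MIR_TABLE_CACHE.get(key)
        if tab is None:
            n = self.n_sites
            i = np.arange(n + 1)
            C = np.array([math.comb(n, k) for k in i], dtype=float)
            tab = (
                C,
                np.asarray(self.translation_factors, float),
                np.asarray(self.mrna_degradation, float),
                i * np.asarray(self.mirna_degradation, float),
                i.astype(float),
            )
            _MIR_TABLE_CACHE[key] = tab
        return tab[:4]

    def rates(self, mu):
        """Return (translation factor, mRNA active degradation, microRNA loss)."""
        mu = np.asarray(mu, dtype=float)
        if np.any(mu < 0) or not np.all(np.isfinite(mu)):
            raise ModelError("microRNA level must be finite and >= 0")
        C, l, gm, gu_i = self._tables()
        n = self.n_sites
        x = (mu / self.threshold)[..., None]
        M = C * x ** np.arange(n + 1) / (1.0 + x) ** n
        L, Ym, Yu = M @ l, M @ gm, M @ gu_i
        if L.ndim == 0:
            return float(L), float(Ym), float(Yu)
        return L, Ym, Yu


def mirna_repression(mu, rep: MicroRNARepression):
    """Translation factor in [0, 1] and active-degradation rate (h^-1).

    The translation factor is 1 with no microRNA and decays to the floor
    set by the per-occupancy coefficients; the active degradation is 0
    with no microRNA and saturates at the top coefficient.
    """
    L, Ym, _ = rep.rates(mu)
    return L, Ym


# canonical per-occupancy ramps for up to six binding sites
_L6 = (1.0, 0.6, 0.3, 0.1, 0.05, 0.05, 0.05)
_GM6 = (0.0, 0.04, 0.2, 1.0, 1.0, 1.0, 1.0)
_GU6 = (0.0, 0.005, 0.05, 0.5, 0.5, 0.5, 0.5)


def _mir(n_sites: int, threshold: float = 1.0e4) -> MicroRNARepression:
    k = n_sites + 1
    return MicroRNARepression(_L6[:k], _GM6[:k], _GU6[:k], threshold)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set: production/degradation rates, binding rate
    constants, one :class:`HillSpec` per regulatory edge, and the
    microRNA interaction records.

    Units: production rates ``g_*`` molecules/h, degradation rates
    ``k_*`` 1/h, interaction rates ``kt_*``/``kc_*`` 1/(molecule h).
    """

    # production (molecules/h); g_zeb and g_snail are per-mRNA translation rates (1/h)
    g_notch: float = 16.0
    g_delta: float = 60.0
    g_jagged: float = 25.0
    g_mir200: float = 2100.0
    g_zeb_mrna: float = 12.0
    g_zeb: float = 100.0
    g_mir34: float = 1350.0
    g_snail_mrna: float = 90.0
    g_snail: float = 100.0
    # degradation (1/h)
    k_notch: float = 0.1
    k_delta: float = 0.05
    k_jagged: float = 0.05
    k_nicd: float = 0.5
    k_mir200: float = 0.05
    k_zeb_mrna: float = 0.5
    k_zeb: float = 0.1
    k_mir34: float = 0.05
    k_snail_mrna: float = 0.5
    k_snail: float = 0.125
    # receptor-ligand interactions (1/(molecule h)); trans rates are
    # ligand-specific: without Fringe, Notch binds Jagged somewhat more
    # readily than Delta
    kt_delta: float = 3.0e-5
    kt_jagged: float = 4.0e-5
    kc_delta: float = 3.0e-3
    kc_jagged: float = 3.0e-4
    # NICD target edges
    nicd_on_notch: HillSpec = HillSpec(8.0, 2, 6.0)
    nicd_on_delta: HillSpec = HillSpec(8.0, 2, 0.0)
    nicd_on_jagged: HillSpec = HillSpec(8.0, 2, 3.0)
    nicd_on_snail: HillSpec = HillSpec(45.0, 2, 6.4)
    # EMT core edges
    zeb_on_mir200: HillSpec = HillSpec(3.0e5, 3, 0.1)
    snail_on_mir200: HillSpec = HillSpec(1.95e5, 2, 0.1)
    zeb_on_zeb: HillSpec = HillSpec(2.5e4, 2, 7.5)
    snail_on_zeb: HillSpec = HillSpec(1.8e5, 2, 10.0)
    snail_on_mir34: HillSpec = HillSpec(2.0e5, 2, 0.1)
    zeb_on_mir34: HillSpec = HillSpec(6.0e5, 2, 0.5)
    snail_on_snail: HillSpec = HillSpec(4.0e5, 1, 0.1)
    iext_on_snail: HillSpec = HillSpec(50.0, 2, 10.0)
    # microRNA interactions
    mir34_on_notch: MicroRNARepression = _mir(1)
    mir34_on_delta: MicroRNARepression = _mir(2)
    mir200_on_jagged: MicroRNARepression = _mir(3)
    mir200_on_zeb_mrna: MicroRNARepression = _mir(6)
    mir34_on_snail_mrna: MicroRNARepression = _mir(2)
    # optional Fringe glycosylation: scales Notch-Delta binding up and
    # Notch-Jagged binding down as a function of an NICD-induced Fringe
    # activity (quasi-steady, dimensionless in [0, 1])
    fringe_enabled: bool = False
    fringe_production: HillSpec = HillSpec(30.0, 2, 10.0)
    fringe_delta_boost: float = 2.0
    fringe_jagged_drop: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "g_notch", "g_delta", "g_jagged", "g_mir200", "g_zeb_mrna", "g_zeb",
            "g_mir34", "g_snail_mrna", "g_snail", "k_notch", "k_delta", "k_jagged",
            "k_nicd", "k_mir200", "k_zeb_mrna", "k_zeb", "k_mir34", "k_snail_mrna",
            "k_snail", "kt_delta", "kt_jagged", "kc_delta", "kc_jagged",
        ):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ModelError(f"parameter {name} must be finite and >= 0, got {v}")

    def with_overrides(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class Environment:
    """External inputs seen by one cell (all molecule counts, >= 0).

    ``d_ext``/``j_ext``/``n_ext`` are membrane-bound ligand/receptor
    presented by neighbours, ``sd_ext``/``sj_ext`` soluble ligands and
    ``i_ext`` the lumped EMT-inducing signal.
    """

    d_ext: float = 0.0
    j_ext: float = 0.0
    n_ext: float = 0.0
    sd_ext: float = 0.0
    sj_ext: float = 0.0
    i_ext: float = 0.0

    def __post_init__(self) -> None:
        for name in ("d_ext", "j_ext", "n_ext", "sd_ext", "sj_ext", "i_ext"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ModelError(f"environment field {name} must be finite and >= 0")


@dataclass
class Trajectory:
    """Time grid (hours) and the state at each grid point."""

    times: np.ndarray            # (n_t,)
    states: np.ndarray           # (n_t, 10)

    @property
    def final(self) -> np.ndarray:
        return self.states[-1]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time_h", self.times)
        return df


# ---------------------------------------------------------------------------
# right-hand side
# ---------------------------------------------------------------------------

def _env_arrays(env, n_cells: int):
    """Broadcast an Environment (or dict of arrays) to per-cell arrays."""
    if isinstance(env, Environment):
        vals = {k: np.full(n_cells, getattr(env, k)) for k in
                ("d_ext", "j_ext", "n_ext", "sd_ext", "sj_ext", "i_ext")}
    else:
        vals = {k: np.broadcast_to(np.asarray(env[k], float), (n_cells,))
                for k in ("d_ext", "j_ext", "n_ext", "sd_ext", "sj_ext", "i_ext")}
    return vals


def _hill_fast(X, spec: HillSpec):
    r = (X / spec.threshold) ** spec.coefficient
    return (1.0 + spec.fold_change * r) / (1.0 + r)


def _mir_fast(mu, rep: MicroRNARepression):
    """(L, Ym, Yu) without input validation, for the hot path."""
    C, l, gm, gu_i = rep._tables()
    n = rep.n_sites
    x = mu[:, None] / rep.threshold
    M = C * x ** _MIR_TABLE_CACHE[(rep.translation_factors, rep.mrna_degradation,
                                   rep.mirna_degradation)][4] / (1.0 + x) ** n
    return M @ l, M @ gm, M @ gu_i


def derivatives_vec(Y: np.ndarray, env, p: ModelParameters) -> np.ndarray:
    """Vectorised right-hand side for a ``(n_cells, 10)`` state array."""
    Y = np.asarray(Y, dtype=float)
    single = Y.ndim == 1
    if single:
        Y = Y[None, :]
        if not np.all(np.isfinite(Y)) or np.any(Y < 0):
            raise ModelError("cell state must be finite and >= 0")
    n_cells = Y.shape[0]
    e = _env_arrays(env, n_cells)
    N, D, J, I, u200, mz, Z, u34, ms, S = Y.T

    L34N, _, _ = _mir_fast(u34, p.mir34_on_notch)
    L34D, _, _ = _mir_fast(u34, p.mir34_on_delta)
    L200J, _, _ = _mir_fast(u200, p.mir200_on_jagged)
    Lmz, Ymz, Yu200 = _mir_fast(u200, p.mir200_on_zeb_mrna)
    Lms, Yms, Yu34 = _mir_fast(u34, p.mir34_on_snail_mrna)

    kt_d, kt_j = p.kt_delta, p.kt_jagged
    if p.fringe_enabled:
        F = _hill_fast(I, p.fringe_production) - 1.0
        F = F / max(p.fringe_production.fold_change - 1.0, 1e-12)  # in [0, 1]
        kt_d = p.kt_delta * (1.0 + (p.fringe_delta_boost - 1.0) * F)
        kt_j = p.kt_jagged * (1.0 + (p.fringe_jagged_drop - 1.0) * F)

    # soluble ligands activate through the same trans rates but are not
    # consumed from a finite pool and do not engage cis-inhibition
    trans_in = kt_d * (e["d_ext"] + e["sd_ext"]) + kt_j * (e["j_ext"] + e["sj_ext"])

    cisD = p.kc_delta * N * D
    cisJ = p.kc_jagged * N * J
    dN = (p.g_notch * _hill_fast(I, p.nicd_on_notch) * L34N
          - cisD - cisJ - trans_in * N - p.k_notch * N)
    dD = (p.g_delta * _hill_fast(I, p.nicd_on_delta) * L34D
          - cisD - kt_d * D * e["n_ext"] - p.k_delta * D)
    dJ = (p.g_jagged * _hill_fast(I, p.nicd_on_jagged) * L200J
          - cisJ - kt_j * J * e["n_ext"] - p.k_jagged * J)
    dI = trans_in * N - p.k_nicd * I
    du200 = (p.g_mir200 * _hill_fast(Z, p.zeb_on_mir200)
             * _hill_fast(S, p.snail_on_mir200)
             - mz * Yu200 - p.k_mir200 * u200)
    dmz = (p.g_zeb_mrna * _hill_fast(Z, p.zeb_on_zeb)
           * _hill_fast(S, p.snail_on_zeb)
           - mz * Ymz - p.k_zeb_mrna * mz)
    dZ = p.g_zeb * mz * Lmz - p.k_zeb * Z
    du34 = (p.g_mir34 * _hill_fast(S, p.snail_on_mir34)
            * _hill_fast(Z, p.zeb_on_mir34)
            - ms * Yu34 - p.k_mir34 * u34)
    dms = (p.g_snail_mrna * _hill_fast(I, p.nicd_on_snail)
           * _hill_fast(e["i_ext"], p.iext_on_snail)
           * _hill_fast(S, p.snail_on_snail)
           - ms * Yms - p.k_snail_mrna * ms)
    dS = p.g_snail * ms * Lms - p.k_snail * S

    out = np.stack([dN, dD, dJ, dI, du200, dmz, dZ, du34, dms, dS], axis=1)
    return out[0] if single else out


def cell_derivatives(state, env: Environment, params: ModelParameters) -> np.ndarray:
    """Rate vector (molecules/h per species) for one cell.

    ``state`` is a length-10 sequence in :data:`SPECIES` order.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (N_SPECIES,):
        raise ModelError(f"state must have shape ({N_SPECIES},), got {state.shape}")
    return derivatives_vec(state, env, params)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def rk4_step(Y, dt, env, p):
    """One classical Runge-Kutta step with a non-negativity clamp."""
    k1 = derivatives_vec(Y, env, p)
    k2 = derivatives_vec(np.maximum(Y + 0.5 * dt * k1, 0.0), env, p)
    k3 = derivatives_vec(np.maximum(Y + 0.5 * dt * k2, 0.0), env, p)
    k4 = derivatives_vec(np.maximum(Y + dt * k3, 0.0), env, p)
    return np.maximum(Y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)


_DIVERGENCE_CAP = 1e9


def integrate_cell(
    state0,
    env: Environment,
    params: ModelParameters,
    t_end: float,
    dt: float = 0.1,
    record_every: int = 1,
) -> Trajectory:
    """Integrate one cell with a fixed-step RK4 scheme.

    Deterministic given its inputs.  Raises :class:`IntegrationError`
    naming the first offending species and time if the state diverges.
    """
    if dt <= 0 or t_end < dt:
        raise ModelError("require dt > 0 and t_end >= dt")
    Y = np.asarray(state0, dtype=float).copy()
    if Y.shape != (N_SPECIES,):
        raise ModelError(f"state must have shape ({N_SPECIES},)")
    n_steps = int(round(t_end / dt))
    times = [0.0]
    states = [Y.copy()]
    for step in range(1, n_steps + 1):
        Y = rk4_step(Y, dt, env, params)
        if not np.all(np.isfinite(Y)) or np.any(Y > _DIVERGENCE_CAP):
            bad = int(np.argmax(~np.isfinite(Y) | (Y > _DIVERGENCE_CAP)))
            raise IntegrationError(
                f"integration diverged for species '{SPECIES[bad]}' at t = {step * dt:.2f} h"
            )
        if step % record_every == 0 or step == n_steps:
            times.append(step * dt)
            states.append(Y.copy())
    return Trajectory(np.asarray(times), np.asarray(states))


# ---------------------------------------------------------------------------
# stable-state enumeration
# ---------------------------------------------------------------------------

#: per-species amplitude used to draw random initial conditions for the
#: multi-start search (roughly twice the largest attractor values)
START_SCALE = np.array([8.0e2, 4.0e2, 2.0e3, 2.0e2, 4.0e4, 1.2e3, 1.2e6, 3.0e4, 8.0e2, 4.0e5])

#: deterministic starts near the characteristic state classes
#: (ligand-dominated, receptor-dominated, hybrid E/M-like, mesenchymal-like);
#: some basins -- notably the Sender's -- are narrow enough that uniform
#: random starts alone can miss them
CANONICAL_STARTS = (
    np.array([20.0, 300.0, 50.0, 1.0, 3.5e4, 20.0, 1.5e3, 2.5e4, 150.0, 5.0e4]),
    np.array([500.0, 5.0, 50.0, 30.0, 3.5e4, 20.0, 1.5e3, 2.5e4, 150.0, 5.0e4]),
    np.array([250.0, 5.0, 300.0, 60.0, 9.0e3, 300.0, 6.0e4, 9.0e3, 300.0, 2.0e5]),
    np.array([150.0, 2.0, 800.0, 90.0, 9.0e2, 900.0, 9.0e5, 2.5e3, 500.0, 3.0e5]),
)


def steady_state_residual(state, env, params) -> float:
    """max_X |dX/dt| / (k_X X + 1): dimensionless steady-state defect."""
    k = np.array([getattr(params, "k_" + s) for s in SPECIES])
    d = derivatives_vec(np.asarray(state, float), env, params)
    return float(np.max(np.abs(d) / (k * np.asarray(state, float) + 1.0)))


def _dedup(states: List[np.ndarray], rel_tol: float = 0.05) -> List[np.ndarray]:
    uniq: List[np.ndarray] = []
    for y in states:
        if not any(np.max(np.abs(y - u) / (np.abs(u) + 1.0)) < rel_tol for u in uniq):
            uniq.append(y)
    return uniq


def find_stable_states(
    env: Environment,
    params: ModelParameters,
    n_starts: int = 24,
    seed: int = 0,
    tol: float = 1e-3,
    t_settle: float = 1500.0,
    dt: float = 0.25,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> List[np.ndarray]:
    """Enumerate stable steady states by relaxation from random starts.

    Each start is integrated to ``t_settle`` (extended once if the state
    is still moving), kept if its steady-state residual is below ``tol``
    and deduplicated at 5 % relative L-infinity distance.  Relaxation
    cannot terminate on unstable saddles, so every survivor is a stable
    state up to the residual tolerance.
    """
    if n_starts < 1:
        raise ModelError("n_starts must be >= 1")
    rng = np.random.default_rng(seed)
    starts = [s.copy() for s in CANONICAL_STARTS]
    starts += [rng.uniform(0.0, 1.0, N_SPECIES) * START_SCALE for _ in range(n_starts)]
    if extra_starts is not None:
        starts = [np.asarray(s, float) for s in extra_starts] + starts
    Y = np.stack(starts)
    n_steps = int(round(t_settle / dt))
    for _ in range(n_steps):
        Y = rk4_step(Y, dt, env, params)
    finals = []
    for y in Y:
        res = steady_state_residual(y, env, params)
        if res >= tol:  # give slow transients one more settling window
            y = integrate_cell(y, env, params, t_settle, dt=dt, record_every=10**9).final
            res = steady_state_residual(y, env, params)
        if res < tol:
            finals.append((res, y))
    # keep the lower-residual representative of each cluster
    finals.sort(key=lambda t: t[0])
    return _dedup([y for _, y in finals])
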