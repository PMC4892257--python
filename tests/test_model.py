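"""Unit and property tests of the single-cell ODE core."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import notchemt as ne
from notchemt.model import SPECIES, derivatives_vec, rk4_step

from conftest import linear_fixed_point


# ---------------------------------------------------------------------------
# shifted Hill
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("n,lam", [(1, 0.1), (2, 6.0), (4, 0.0), (3, 1.0)])
def test_shifted_hill_midpoint_identity(n, lam):
    spec = ne.HillSpec(100.0, n, lam)
    assert ne.shifted_hill(100.0, spec) == pytest.approx((1 + lam) / 2)


def test_shifted_hill_asymptotes():
    spec = ne.HillSpec(50.0, 2, 4.0)
    assert ne.shifted_hill(0.0, spec) == pytest.approx(1.0)
    assert ne.shifted_hill(50.0e6, spec) == pytest.approx(4.0, abs=1e-3)
    neutral = ne.HillSpec(50.0, 3, 1.0)
    for x in (0.0, 17.0, 5000.0):
        assert ne.shifted_hill(x, neutral) == pytest.approx(1.0)


@settings(max_examples=25, deadline=None)
@given(x1=st.floats(0, 1e5), x2=st.floats(0, 1e5),
       lam=st.floats(0.01, 10), n=st.integers(1, 6))
def test_shifted_hill_monotone(x1, x2, lam, n):
    spec = ne.HillSpec(200.0, n, lam)
    lo, hi = sorted((x1, x2))
    a, b = ne.shifted_hill(lo, spec), ne.shifted_hill(hi, spec)
    if lam >= 1:
        assert b >= a - 1e-12
    else:
        assert b <= a + 1e-12


def test_shifted_hill_rejects_invalid():
    with pytest.raises(ne.ModelError):
        ne.shifted_hill(-1.0, ne.HillSpec(10.0, 2, 2.0))
    with pytest.raises(ne.ModelError):
        ne.HillSpec(-5.0, 2, 2.0)
    with pytest.raises(ne.ModelError):
        ne.HillSpec(5.0, 0, 2.0)


# ---------------------------------------------------------------------------
# microRNA repression
# ---------------------------------------------------------------------------

def binomial_occupancy_oracle(mu, rep):
    """Direct evaluation of the occupancy sum, independent of the model code."""
    n = rep.n_sites
    x = mu / rep.threshold
    L = Ym = 0.0
    for i in range(n + 1):
        M = math.comb(n, i) * x**i / (1 + x) ** n
        L += rep.translation_factors[i] * M
        Ym += rep.mrna_degradation[i] * M
    return L, Ym


def test_mirna_no_microrna(params):
    for rep in (params.mir200_on_zeb_mrna, params.mir34_on_notch):
        L, Ym = ne.mirna_repression(0.0, rep)
        assert L == pytest.approx(1.0)
        assert Ym == pytest.approx(0.0)


def test_mirna_saturation(params):
    rep = params.mir200_on_zeb_mrna
    L, Ym = ne.mirna_repression(1e9, rep)
    assert L == pytest.approx(rep.translation_factors[-1], rel=1e-3)
    assert Ym == pytest.approx(rep.mrna_degradation[-1], rel=1e-3)


def test_mirna_matches_occupancy_oracle_and_monotone(params):
    grid = np.linspace(0.0, 1.0e5, 201)
    for rep in (params.mir200_on_zeb_mrna, params.mir34_on_snail_mrna,
                params.mir200_on_jagged):
        prev_L = 1.0 + 1e-12
        for mu in grid:
            L, Ym = ne.mirna_repression(mu, rep)
            L_ref, Ym_ref = binomial_occupancy_oracle(mu, rep)
            assert L == pytest.approx(L_ref, rel=1e-10)
            assert Ym == pytest.approx(Ym_ref, rel=1e-10)
            assert L <= prev_L + 1e-12          # non-increasing translation
            prev_L = L


def test_mirna_rejects_negative(params):
    with pytest.raises(ne.ModelError):
        ne.mirna_repression(-1.0, params.mir34_on_notch)


def test_mirna_invalid_specs():
    with pytest.raises(ne.ModelError):  # increasing translation factors
        ne.MicroRNARepression((1.0, 1.2), (0.0, 0.1), (0.0, 0.1), 1e4)
    with pytest.raises(ne.ModelError):  # does not start at 1
        ne.MicroRNARepression((0.9, 0.5), (0.0, 0.1), (0.0, 0.1), 1e4)


# ---------------------------------------------------------------------------
# cell_derivatives
# ---------------------------------------------------------------------------

def test_linear_birth_death_fixed_point(unregulated):
    state = linear_fixed_point(unregulated)
    d = ne.cell_derivatives(state, ne.Environment(), unregulated)
    assert np.allclose(d, 0.0, atol=1e-9 * max(state))


def test_no_receptor_no_cleavage(params):
    state = np.array([0.0, 50, 20, 40, 2e4, 30, 3e3, 1e4, 100, 5e4])
    env = ne.Environment(d_ext=500.0, j_ext=900.0, n_ext=5000.0, sj_ext=1000.0)
    d = ne.cell_derivatives(state, env, params)
    i_nicd = SPECIES.index("nicd")
    assert d[i_nicd] == pytest.approx(-params.k_nicd * state[i_nicd])
    assert d[i_nicd] <= 0.0


def test_nonnegativity_at_boundary(params):
    rng = np.random.default_rng(11)
    env = ne.Environment(d_ext=300.0, j_ext=600.0, n_ext=5000.0, i_ext=30.0)
    for _ in range(20):
        state = rng.uniform(0, 1, 10) * ne.model.START_SCALE
        k = rng.integers(0, 10)
        state[k] = 0.0
        d = ne.cell_derivatives(state, env, params)
        assert d[k] >= 0.0


def test_derivatives_reject_bad_input(params):
    with pytest.raises(ne.ModelError):
        ne.cell_derivatives(np.full(10, -1.0), ne.Environment(), params)
    with pytest.raises(ne.ModelError):
        ne.cell_derivatives(np.full(10, np.nan), ne.Environment(), params)
    with pytest.raises(ne.ModelError):
        ne.Environment(d_ext=-5.0)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def test_integrate_converges_to_linear_limit(unregulated):
    """With no regulation the trajectory reaches g/k within a few
    degradation time-scales of the slowest species."""
    target = linear_fixed_point(unregulated)
    slowest = 1.0 / min(getattr(unregulated, "k_" + s) for s in SPECIES)
    traj = ne.integrate_cell(np.zeros(10), ne.Environment(), unregulated,
                             t_end=8.0 * slowest, dt=0.1, record_every=50)
    assert np.all(traj.states >= 0)
    final = traj.final
    scale = np.where(target > 0, target, 1.0)
    assert np.max(np.abs(final - target) / scale) < 1e-3


def test_integrate_deterministic(params):
    state0 = np.array([100.0, 50, 20, 5, 3e4, 30, 3e3, 2e4, 150, 6e4])
    env = ne.Environment(j_ext=600.0, n_ext=5000.0)
    t1 = ne.integrate_cell(state0, env, params, 50.0, dt=0.1)
    t2 = ne.integrate_cell(state0, env, params, 50.0, dt=0.1)
    assert np.array_equal(t1.states, t2.states)


def test_step_halving_guard(params):
    """Halving dt changes the final state by < 0.5 % (reference setting)."""
    state0 = np.array([100.0, 50, 20, 5, 3e4, 30, 3e3, 2e4, 150, 6e4])
    env = ne.Environment(j_ext=600.0, n_ext=5000.0)
    a = ne.integrate_cell(state0, env, params, 200.0, dt=0.1, record_every=2000).final
    b = ne.integrate_cell(state0, env, params, 200.0, dt=0.05, record_every=4000).final
    assert np.max(np.abs(a - b) / (np.abs(b) + 1.0)) < 5e-3


def test_integration_error_names_species(params):
    bad = params.with_overrides(g_snail=1e12)  # blow up SNAIL translation
    with pytest.raises((ne.IntegrationError, ne.ModelError)):
        ne.integrate_cell(np.ones(10), ne.Environment(i_ext=100.0), bad, 200.0, dt=0.5)


@settings(max_examples=10, deadline=None)
@given(scale=st.floats(0.2, 3.0), seed=st.integers(0, 100))
def test_nonnegativity_under_parameter_perturbation(params, scale, seed):
    """States stay finite and non-negative for production rates scaled
    away from their defaults."""
    p = params.with_overrides(g_notch=params.g_notch * scale,
                              g_delta=params.g_delta * scale,
                              g_jagged=params.g_jagged * scale)
    rng = np.random.default_rng(seed)
    state0 = rng.uniform(0, 1, 10) * ne.model.START_SCALE
    traj = ne.integrate_cell(state0, ne.Environment(j_ext=600.0, n_ext=5000.0),
                             p, 30.0, dt=0.2, record_every=30)
    assert np.all(np.isfinite(traj.states))
    assert np.all(traj.states >= 0)


# ---------------------------------------------------------------------------
# stable-state enumeration
# ---------------------------------------------------------------------------

def test_unregulated_single_state_at_closed_form(unregulated):
    states = ne.find_stable_states(ne.Environment(), unregulated,
                                   n_starts=8, seed=3)
    assert len(states) == 1
    target = linear_fixed_point(unregulated)
    scale = np.where(target > 0, target, 1.0)
    assert np.max(np.abs(states[0] - target) / scale) < 1e-3


def test_reference_point_bistable_sender_receiver(reference_bistable_states):
    """J_ext = 600, N_ext = 5000: exactly a Sender and a Receiver."""
    states = reference_bistable_states
    assert len(states) == 2
    i_n, i_d = SPECIES.index("notch"), SPECIES.index("delta")
    sender = min(states, key=lambda s: s[i_n])
    receiver = max(states, key=lambda s: s[i_n])
    assert sender[i_d] > 2.0 * sender[i_n]       # high Delta, low Notch
    assert receiver[i_n] > 10.0 * receiver[i_d]  # high Notch, low Delta


def test_stable_states_pass_residual_check(params, reference_bistable_states):
    env = ne.Environment(j_ext=600.0, n_ext=5000.0)
    for s in reference_bistable_states:
        assert ne.steady_state_residual(s, env, params) < 1e-3


def test_stable_state_count_converges(params):
    env = ne.Environment(j_ext=600.0, n_ext=5000.0)
    a = ne.find_stable_states(env, params, n_starts=20, seed=5)
    b = ne.find_stable_states(env, params, n_starts=40, seed=5)
    assert len(a) == len(b)


def test_find_stable_states_deterministic(params):
    env = ne.Environment(j_ext=600.0, n_ext=5000.0)
    a = ne.find_stable_states(env, params, n_starts=12, seed=7)
    b = ne.find_stable_states(env, params, n_starts=12, seed=7)
    assert len(a) == len(b)
    for x, y in zip(a, b):
        assert np.array_equal(x, y)


# ---------------------------------------------------------------------------
# two-cell motif
# ---------------------------------------------------------------------------

def _two_cell_lattice():
    nb = np.full((2, 6), -1, dtype=int)
    nb[0, 0], nb[1, 0] = 1, 0
    return ne.Lattice(1, 2, "open", nb)


def test_two_cell_motif_inhibition_vs_induction(params):
    """A Delta-dominated pair keeps opposite fates, a Jagged-dominated
    pair converges to the same fate, from identical starting conditions.

    Production rates are scaled up 6-fold relative to the tissue values
    because a pair shares one membrane contact instead of six.
    """
    lat = _two_cell_lattice()
    core = [3.0e4, 30, 3.0e3, 2.0e4, 150, 6.0e4]
    s0 = np.array([[5.0, 3800.0, 90.0, 0.2] + core,
                   [300.0, 2.0, 60.0, 60.0] + core])
    i_n, i_d, i_j = (SPECIES.index(k) for k in ("notch", "delta", "jagged"))

    p_delta = params.with_overrides(g_delta=420.0, g_jagged=20.0)
    cfg = ne.TissueConfig(params=p_delta, t_end=600.0, dt=0.1, seed=0)
    snap = ne.simulate_tissue(lat, s0, cfg)[-1]
    a, b = snap.states
    # anti-correlated: one ligand-dominated Sender, one receptor-dominated
    assert ne.classify_sr(a) == "S"
    assert a[i_d] > 100.0 * a[i_n]
    assert b[i_n] > 10.0 * b[i_d]
    assert ne.classify_sr(b) in ("R", "S/R")

    p_jag = params.with_overrides(g_delta=20.0, g_jagged=420.0)
    cfg = ne.TissueConfig(params=p_jag, t_end=600.0, dt=0.1, seed=0)
    snap = ne.simulate_tissue(lat, s0, cfg)[-1]
    a, b = snap.states
    # correlated: the initial asymmetry is erased, both cells Jagged-high
    assert np.max(np.abs(a - b) / (np.abs(b) + 1.0)) < 0.01
    assert a[i_j] > ne.DEFAULT_THRESHOLDS.jagged_high
    assert b[i_j] > ne.DEFAULT_THRESHOLDS.jagged_high
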