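"""Lattice construction and tissue-simulation tests."""

import numpy as np
import pytest

import notchemt as ne
from notchemt.model import SPECIES


# ---------------------------------------------------------------------------
# lattice
# ---------------------------------------------------------------------------

def test_periodic_lattice_uniform_degree():
    lat = ne.build_lattice(50, 50, "periodic")
    assert lat.n_cells == 2500
    assert np.all(lat.degree() == 6)


def test_neighbour_symmetry():
    for rows, cols, boundary in ((8, 9, "periodic"), (7, 9, "open")):
        lat = ne.build_lattice(rows, cols, boundary)
        for i in range(lat.n_cells):
            for j in lat.neighbours[i]:
                if j >= 0:
                    assert i in lat.neighbours[j]


def test_periodic_odd_rows_rejected():
    with pytest.raises(ne.ModelError):
        ne.build_lattice(7, 9, "periodic")


def test_open_3x3_corner_degrees():
    """Hand enumeration of the odd-r stencil on an open 3x3 patch.

    Row 0 and 2 are 'even' rows; corners (0,0) and (2,0) touch 2 cells,
    (0,2) and (2,2) touch 3, and the centre touches all 6.
    """
    lat = ne.build_lattice(3, 3, "open")
    deg = lat.degree().reshape(3, 3)
    assert deg[0, 0] == 2 and deg[2, 0] == 2
    assert deg[0, 2] == 3 and deg[2, 2] == 3
    assert deg[1, 1] == 6
    # explicit neighbour set of the top-left corner
    assert set(lat.neighbours[0][lat.neighbours[0] >= 0]) == {1, 3}


def test_lattice_rejects_tiny_dimensions():
    with pytest.raises(ne.ModelError):
        ne.build_lattice(1, 10)
    with pytest.raises(ne.ModelError):
        ne.build_lattice(3, 3, "weird")


# ---------------------------------------------------------------------------
# random initial states
# ---------------------------------------------------------------------------

def test_random_init_reproducible_and_bounded():
    lat = ne.build_lattice(6, 6)
    a = ne.random_initial_states(lat, None, seed=42)
    b = ne.random_initial_states(lat, None, seed=42)
    assert np.array_equal(a, b)
    hi = np.array([ne.tissue.DEFAULT_INIT_RANGES[s] for s in SPECIES])
    assert np.all(a >= 0) and np.all(a <= hi)
    c = ne.random_initial_states(lat, None, seed=43)
    assert not np.array_equal(a, c)


def test_random_init_zero_ranges():
    lat = ne.build_lattice(4, 4)
    zero = {s: 0.0 for s in SPECIES}
    assert np.all(ne.random_initial_states(lat, zero, seed=0) == 0.0)


# ---------------------------------------------------------------------------
# neighbour environment
# ---------------------------------------------------------------------------

def test_uniform_tissue_environment(params):
    lat = ne.build_lattice(8, 8)
    state = np.array([200.0, 80, 40, 5, 3e4, 30, 3e3, 2e4, 150, 6e4])
    states = np.tile(state, (lat.n_cells, 1))
    cfg_mean = ne.TissueConfig(params=params, aggregation="mean")
    env_mean = ne.neighbour_environment(lat, states, cfg_mean)
    assert np.allclose(env_mean["d_ext"], 80.0)
    assert np.allclose(env_mean["n_ext"], 200.0)
    cfg_sum = ne.TissueConfig(params=params, aggregation="sum")
    env_sum = ne.neighbour_environment(lat, states, cfg_sum)
    # sum and mean differ by exactly the neighbour count on a periodic lattice
    assert np.allclose(env_sum["j_ext"], 6.0 * env_mean["j_ext"])


def test_soluble_jagged_added_uniformly(params):
    lat = ne.build_lattice(4, 6)
    states = np.zeros((lat.n_cells, 10))
    cfg = ne.TissueConfig(params=params, sj_ext=4000.0)
    env = ne.neighbour_environment(lat, states, cfg)
    assert np.allclose(env["sj_ext"], 4000.0)
    assert np.allclose(env["j_ext"], 0.0)


def test_environment_shape_error(params):
    lat = ne.build_lattice(4, 4)
    with pytest.raises(ne.ModelError):
        ne.neighbour_environment(lat, np.zeros((7, 10)),
                                 ne.TissueConfig(params=params))


# ---------------------------------------------------------------------------
# tissue simulation
# ---------------------------------------------------------------------------

def test_uniform_stable_tissue_stays_uniform(params, reference_bistable_states):
    """A tissue initialised at a one-cell stable state computed with the
    matching aggregated environment is stationary and uniform."""
    # the self-consistent uniform state: run the self-coupled dynamics on
    # a small periodic patch until stationary, which solves the one-cell
    # fixed point under its own aggregated environment
    small = ne.build_lattice(4, 4)
    y0 = np.tile(np.array([300.0, 50, 100, 10, 3e4, 30, 3e3, 2e4, 150, 6e4]),
                 (small.n_cells, 1))
    cfg0 = ne.TissueConfig(params=params, t_end=800.0, dt=0.2)
    uniform = ne.simulate_tissue(small, y0, cfg0)[-1].states[0]
    # it is a stable state of one cell in the matching aggregated environment
    env = ne.Environment(d_ext=6.0 * uniform[1], j_ext=6.0 * uniform[2],
                         n_ext=6.0 * uniform[0])
    assert ne.steady_state_residual(uniform, env, params) < 1e-3

    lat = ne.build_lattice(6, 6)
    states0 = np.tile(uniform, (lat.n_cells, 1))
    cfg = ne.TissueConfig(params=params, t_end=50.0, dt=0.1)
    snap = ne.simulate_tissue(lat, states0, cfg)[-1]
    drift = np.max(np.abs(snap.states - states0) / (states0 + 1.0))
    assert drift < 1e-3
    assert np.max(np.std(snap.states, axis=0) / (np.mean(snap.states, axis=0) + 1)) < 1e-9


def test_tissue_deterministic_and_permutation_invariant(params):
    lat = ne.build_lattice(6, 6)
    s0 = ne.random_initial_states(lat, None, seed=9)
    cfg = ne.TissueConfig(params=params, t_end=12.0, dt=0.2)
    a = ne.simulate_tissue(lat, s0, cfg)[-1]
    b = ne.simulate_tissue(lat, s0, cfg)[-1]
    assert np.array_equal(a.states, b.states)

    # relabel cells by a permutation that maps the lattice onto itself
    # (translation by one row on the periodic lattice), then permute back
    shift = np.roll(np.arange(lat.n_cells).reshape(6, 6), 2, axis=0).ravel()
    c = ne.simulate_tissue(lat, s0[shift], cfg)[-1]
    inv = np.argsort(shift)
    assert np.allclose(c.states[inv], a.states, rtol=1e-12, atol=1e-9)


def test_snapshot_roundtrip(params):
    lat = ne.build_lattice(4, 5)
    s0 = ne.random_initial_states(lat, None, seed=2)
    cfg = ne.TissueConfig(params=params, t_end=5.0, dt=0.1)
    snap = ne.simulate_tissue(lat, s0, cfg)[-1]
    df = snap.to_frame()
    back = ne.Snapshot.from_frame(df)
    assert np.allclose(back.states, snap.states)
    assert list(back.emt) == list(snap.emt)


def test_snapshot_times_validated(params):
    with pytest.raises(ne.ModelError):
        ne.TissueConfig(params=params, t_end=10.0, snapshot_times=(20.0,))
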