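import numpy as np
import pytest

import notchemt as ne


@pytest.fixture(scope="session")
def params():
    return ne.default_parameters()


@pytest.fixture(scope="session")
def unregulated(params):
    """All regulation off: every edge neutral, no binding, no microRNA.

    Leaves a pure linear birth-death system whose unique fixed point is
    known in closed form (g/k per species, translation chained for the
    ZEB and SNAIL proteins).
    """
    neutral = lambda spec: ne.HillSpec(spec.threshold, spec.coefficient, 1.0)
    off = ne.MicroRNARepression((1.0, 1.0), (0.0, 0.0), (0.0, 0.0), 1.0e4)
    return params.with_overrides(
        kt_delta=0.0, kt_jagged=0.0, kc_delta=0.0, kc_jagged=0.0,
        nicd_on_notch=neutral(params.nicd_on_notch),
        nicd_on_delta=neutral(params.nicd_on_delta),
        nicd_on_jagged=neutral(params.nicd_on_jagged),
        nicd_on_snail=neutral(params.nicd_on_snail),
        zeb_on_mir200=neutral(params.zeb_on_mir200),
        snail_on_mir200=neutral(params.snail_on_mir200),
        zeb_on_zeb=neutral(params.zeb_on_zeb),
        snail_on_zeb=neutral(params.snail_on_zeb),
        snail_on_mir34=neutral(params.snail_on_mir34),
        zeb_on_mir34=neutral(params.zeb_on_mir34),
        snail_on_snail=neutral(params.snail_on_snail),
        iext_on_snail=neutral(params.iext_on_snail),
        mir34_on_notch=off, mir34_on_delta=off, mir200_on_jagged=off,
        mir200_on_zeb_mrna=off, mir34_on_snail_mrna=off,
    )


def linear_fixed_point(p):
    """Closed-form fixed point of the unregulated system."""
    mz = p.g_zeb_mrna / p.k_zeb_mrna
    ms = p.g_snail_mrna / p.k_snail_mrna
    return np.array([
        p.g_notch / p.k_notch,
        p.g_delta / p.k_delta,
        p.g_jagged / p.k_jagged,
        0.0,
        p.g_mir200 / p.k_mir200,
        mz,
        p.g_zeb * mz / p.k_zeb,
        p.g_mir34 / p.k_mir34,
        ms,
        p.g_snail * ms / p.k_snail,
    ])


@pytest.fixture(scope="session")
def reference_bistable_states(params):
    """Stable states at the reference operating point (J_ext = 600)."""
    return ne.find_stable_states(
        ne.Environment(j_ext=600.0, n_ext=5000.0), params, n_starts=24, seed=1)


@pytest.fixture(scope="session")
def tissue_contrast_runs(params):
    """Delta- vs Jagged-dominated 16x16 tissues, 3 seeds, 120 h and 240 h.

    Shared by the patterning and transience tests; the protocol follows
    the tissue figures (production-rate pair, random initial conditions,
    no external signals).
    """
    lat = ne.build_lattice(16, 16)
    runs = {}
    for tag, g_d, g_j in (("delta", 70.0, 20.0), ("jagged", 20.0, 70.0)):
        p = params.with_overrides(g_delta=g_d, g_jagged=g_j)
        for seed in (1, 2, 3):
            cfg = ne.TissueConfig(params=p, t_end=240.0, dt=0.2, seed=seed,
                                  snapshot_times=(120.0,))
            s0 = ne.random_initial_states(lat, cfg.init_ranges, seed)
            snaps = ne.simulate_tissue(lat, s0, cfg)
            runs[(tag, seed)] = {120.0: snaps[0], 240.0: snaps[1]}
    return runs
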