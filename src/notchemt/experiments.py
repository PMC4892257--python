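"""Reproducible experiment presets: the package's standard figure protocols.

Each named preset bundles one protocol with its reference settings as
defaults (lattice size, time horizon, production rates, external
signals), writes CSV/JSON outputs plus simple PNG panels into an output
directory, and records a manifest.  All presets accept a ``size``
override so scaled-down runs finish quickly; the protocol itself is
unchanged by the scale.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence

import numpy as np

from .analysis import nullclines_ND, phase_diagram, sweep_parameter
from .config import RunManifest, parameters_to_dict
from .metrics import summarize
from .model import Environment, ModelParameters, SPECIES, find_stable_states
from .phenotyping import DEFAULT_THRESHOLDS
from .tissue import (
    Lattice,
    Snapshot,
    TissueConfig,
    build_lattice,
    make_snapshot,
    random_initial_states,
    simulate_tissue,
)

__all__ = ["run_experiment", "EXPERIMENTS", "mixed_em_m_states"]

_EMT_COLORS = {"E": "#2ca02c", "E/M": "#ffbf00", "M": "#d62728"}


def _write_snapshot(snap: Snapshot, path: Path, cfg: TissueConfig, seed: int) -> None:
    from .config import config_hash

    df = snap.to_frame()
    phash = config_hash(parameters_to_dict(cfg.params))
    header = (f"# aggregation={cfg.aggregation} seed={seed} dt={cfg.dt} "
              f"i_ext={cfg.i_ext} sd_ext={cfg.sd_ext} sj_ext={cfg.sj_ext} "
              f"params_hash={phash}\n")
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def _plot_snapshot(snap: Snapshot, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = snap.lattice.positions()
    colors = [_EMT_COLORS[l] for l in snap.emt]
    fig, ax = plt.subplots(figsize=(6, 5.5))
    ax.scatter(xy[:, 0], xy[:, 1], c=colors, s=2200 / max(snap.lattice.rows, snap.lattice.cols),
               marker="h", linewidths=0)
    ax.set_aspect("equal")
    ax.set_title(title)
    ax.set_xticks([]), ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def _plot_bifurcation(result, path: Path, ylabel: str = "miR-200 (molecules)") -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    iu = SPECIES.index("mir200")
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in result.branches:
        for bp in col:
            ax.plot(bp.value, bp.state[iu], "o", ms=3,
                    color=_EMT_COLORS[bp.emt])
    ax.set_xlabel(result.parameter)
    ax.set_ylabel(ylabel)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def mixed_em_m_states(lattice: Lattice, params: ModelParameters, seed: int,
                      em_fraction: float = 0.5) -> np.ndarray:
    """Random per-cell mixture of the hybrid-E/M and M one-cell states.

    The two reference states are computed from the model (stable states
    under Jagged signalling at the operating points where each branch
    exists), then assigned per cell with 10 % multiplicative noise.
    """
    def pick(j_ext: float, want: str) -> np.ndarray:
        from .phenotyping import classify_emt

        states = find_stable_states(Environment(j_ext=j_ext, n_ext=5000.0),
                                    params, n_starts=16, seed=seed)
        for s in sorted(states, key=lambda s: s[SPECIES.index("mir200")]):
            if classify_emt(s) == want:
                return s
        raise RuntimeError(f"no {want} state at j_ext={j_ext}")

    em = pick(3000.0, "E/M")
    m = pick(8000.0, "M")
    rng = np.random.default_rng(seed)
    choice = rng.uniform(size=lattice.n_cells) < em_fraction
    base = np.where(choice[:, None], em[None, :], m[None, :])
    return base * (1.0 + 0.1 * rng.uniform(-1.0, 1.0, base.shape))


def _tissue_run(name: str, outdir: Path, params: ModelParameters, seed: int,
                rows: int, cols: int, g_delta: float, g_jagged: float,
                t_end: float, snaps: Sequence[float], i_ext: float = 0.0,
                sj_ext: float = 0.0, sd_ext: float = 0.0,
                states0: Optional[np.ndarray] = None, dt: float = 0.2,
                plot: bool = True) -> List[str]:
    lat = build_lattice(rows, cols)
    p = params.with_overrides(g_delta=g_delta, g_jagged=g_jagged)
    cfg = TissueConfig(params=p, t_end=t_end, dt=dt, seed=seed,
                       snapshot_times=tuple(snaps), i_ext=i_ext,
                       sj_ext=sj_ext, sd_ext=sd_ext)
    if states0 is None:
        states0 = random_initial_states(lat, cfg.init_ranges, seed)
    snapshots = simulate_tissue(lat, states0, cfg)
    outputs = []
    for snap in snapshots:
        csv = outdir / f"{name}_t{int(snap.time)}.csv"
        _write_snapshot(snap, csv, cfg, seed)
        outputs.append(str(csv))
        summ = outdir / f"{name}_t{int(snap.time)}_summary.json"
        summ.write_text(json.dumps(summarize(snap).to_dict(), indent=2, default=str))
        outputs.append(str(summ))
        if plot:
            png = outdir / f"{name}_t{int(snap.time)}.png"
            _plot_snapshot(snap, png, f"{name} at t={snap.time:.0f} h")
            outputs.append(str(png))
    return outputs


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _fig2c(outdir, params, seed, size, plot):
    """Tissue mean NICD (relative) for increasing EMT-inducer levels."""
    rows = cols = size or 20
    lat = build_lattice(rows, cols)
    states0 = random_initial_states(lat, None, seed)
    levels = [0.0, 20.0, 40.0, 70.0]
    out = {}
    ref = None
    for i_ext in levels:
        cfg = TissueConfig(params=params, t_end=120.0, dt=0.2, seed=seed, i_ext=i_ext)
        snap = simulate_tissue(lat, states0, cfg)[-1]
        if ref is None:
            ref = snap
        out[i_ext] = {"mean_nicd": float(np.mean(snap.states[:, SPECIES.index("nicd")])),
                      "relative_mean_nicd": summarize(snap, ref).mean_nicd}
    path = outdir / "fig2c_mean_nicd.json"
    path.write_text(json.dumps(out, indent=2))
    return [str(path)]


def _fig3a(outdir, params, seed, size, plot):
    n_points = size or 24
    values = np.linspace(0.0, 8000.0, n_points)
    res = sweep_parameter("j_ext", values, Environment(n_ext=5000.0), params,
                          n_starts=20, seed=seed)
    csv = outdir / "fig3a_jext_sweep.csv"
    res.to_frame().to_csv(csv, index=False)
    outputs = [str(csv)]
    if plot:
        png = outdir / "fig3a_jext_sweep.png"
        _plot_bifurcation(res, png)
        outputs.append(str(png))
    return outputs


def _fig3b(outdir, params, seed, size, plot):
    res = nullclines_ND(Environment(j_ext=600.0, n_ext=5000.0), params,
                        resolution=size or 40, seed=seed)
    rows = []
    for y, stable in res.intersections:
        rows.append({"notch": y[SPECIES.index("notch")],
                     "delta": y[SPECIES.index("delta")], "stable": stable})
    path = outdir / "fig3b_intersections.json"
    path.write_text(json.dumps(rows, indent=2))
    outputs = [str(path)]
    if plot:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5.5, 4.5))
        for seg in res.notch_nullcline:
            ax.plot(seg[:, 0], seg[:, 1], color="green", lw=1.5)
        for seg in res.delta_nullcline:
            ax.plot(seg[:, 0], seg[:, 1], color="blue", lw=1.5)
        for y, stable in res.intersections:
            ax.plot(y[SPECIES.index("notch")], y[SPECIES.index("delta")],
                    "o" if stable else "o", mfc=("red" if stable else "white"),
                    mec="red", ms=8)
        ax.set_xlabel("Notch (molecules)")
        ax.set_ylabel("Delta (molecules)")
        png = outdir / "fig3b_nullclines.png"
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        outputs.append(str(png))
    return outputs


def _fig3c(outdir, params, seed, size, plot):
    n_points = size or 24
    values = np.linspace(0.0, 14000.0, n_points)
    res = sweep_parameter("d_ext", values, Environment(n_ext=5000.0), params,
                          n_starts=20, seed=seed)
    csv = outdir / "fig3c_dext_sweep.csv"
    res.to_frame().to_csv(csv, index=False)
    outputs = [str(csv)]
    if plot:
        png = outdir / "fig3c_dext_sweep.png"
        _plot_bifurcation(res, png)
        outputs.append(str(png))
    return outputs


def _fig3d(outdir, params, seed, size, plot):
    n = size or 12
    pd_res = phase_diagram(np.linspace(0.0, 10000.0, n), np.linspace(0.0, 8000.0, n),
                           Environment(n_ext=5000.0), params, n_starts=10, seed=seed)
    csv = outdir / "fig3d_phase_diagram.csv"
    pd_res.to_frame().to_csv(csv, index=False)
    return [str(csv)]


def _fig4(outdir, params, seed, size, plot):
    rows = cols = size or 50
    outputs = []
    outputs += _tissue_run("fig4c_delta_dominated", outdir, params, seed, rows, cols,
                           g_delta=70.0, g_jagged=20.0, t_end=240.0,
                           snaps=(120.0, 240.0), plot=plot)
    outputs += _tissue_run("fig4d_jagged_dominated", outdir, params, seed, rows, cols,
                           g_delta=20.0, g_jagged=70.0, t_end=240.0,
                           snaps=(120.0, 240.0), plot=plot)
    return outputs


def _fig5(outdir, params, seed, size, plot):
    """External inducers on the Jagged-dominated tissue of fig4d at 120 h."""
    rows = cols = size or 50
    lat = build_lattice(rows, cols)
    p = params.with_overrides(g_delta=20.0, g_jagged=70.0)
    cfg0 = TissueConfig(params=p, t_end=120.0, dt=0.2, seed=seed)
    start = simulate_tissue(lat, random_initial_states(lat, None, seed), cfg0)[-1]
    outputs = []
    for tag, kw in (("iext70", dict(i_ext=70.0)),
                    ("sjext2000", dict(sj_ext=2000.0)),
                    ("sjext4000", dict(sj_ext=4000.0))):
        outputs += _tissue_run(f"fig5_{tag}", outdir, params, seed, rows, cols,
                               g_delta=20.0, g_jagged=70.0, t_end=120.0,
                               snaps=(120.0,), states0=start.states, plot=plot, **kw)
    return outputs


def _fig6(outdir, params, seed, size, plot):
    rows = cols = size or 50
    lat = build_lattice(rows, cols)
    states0 = mixed_em_m_states(lat, params.with_overrides(g_delta=20.0, g_jagged=70.0),
                                seed)
    return _tissue_run("fig6_jagged_persistence", outdir, params, seed, rows, cols,
                       g_delta=20.0, g_jagged=70.0, t_end=360.0,
                       snaps=(0.0, 120.0, 360.0), states0=states0, plot=plot)


EXPERIMENTS: Dict[str, Callable] = {
    "fig2c": _fig2c, "fig3a": _fig3a, "fig3b": _fig3b, "fig3c": _fig3c,
    "fig3d": _fig3d, "fig4": _fig4, "fig5": _fig5, "fig6": _fig6,
}


def run_experiment(name: str, outdir="runs", params: Optional[ModelParameters] = None,
                   seed: int = 0, size: Optional[int] = None,
                   plot: bool = True) -> RunManifest:
    """Execute a named figure protocol and write outputs plus a manifest."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {sorted(EXPERIMENTS)}")
    if params is None:
        from .config import default_parameters

        params = default_parameters()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_obj = {"experiment": name, "seed": seed, "size": size,
               "parameters": parameters_to_dict(params)}
    try:
        outputs = EXPERIMENTS[name](outdir, params, seed, size, plot)
        manifest = RunManifest.create(name, seed, cfg_obj, outputs)
    except Exception as exc:  # record the failure, then re-raise
        manifest = RunManifest.create(name, seed, cfg_obj, [], status="failed",
                                      notes=str(exc))
        manifest.write(outdir / f"{name}_manifest.json")
        raise
    manifest.write(outdir / f"{name}_manifest.json")
    return manifest
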