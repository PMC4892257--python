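"""Configuration I/O: packaged defaults, YAML schema validation, manifests.

A config file is a YAML mapping with any of the sections ``parameters``
(overrides of the packaged default parameter set, using the same layout
as ``data/default_params.yaml``), ``thresholds``, ``lattice`` and
``run``.  Unknown keys raise a :class:`ConfigError` naming the key.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from importlib import resources
from pathlib import Path
from typing import Any, Dict, List, Optional, Tuple

import yaml

from .model import HillSpec, MicroRNARepression, ModelParameters, _mir
from .phenotyping import DEFAULT_THRESHOLDS, PhenotypeThresholds
from .tissue import TissueConfig

__all__ = [
    "ConfigError",
    "default_parameters",
    "load_config",
    "load_parameters",
    "parameters_to_dict",
    "RunManifest",
]


class ConfigError(ValueError):
    pass


_EDGE_FIELDS = (
    "nicd_on_notch", "nicd_on_delta", "nicd_on_jagged", "nicd_on_snail",
    "zeb_on_mir200", "snail_on_mir200", "zeb_on_zeb", "snail_on_zeb",
    "snail_on_mir34", "zeb_on_mir34", "snail_on_snail", "iext_on_snail",
)
_MIR_FIELDS = (
    "mir34_on_notch", "mir34_on_delta", "mir200_on_jagged",
    "mir200_on_zeb_mrna", "mir34_on_snail_mrna",
)


def _read_yaml(path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"malformed YAML in {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return data


def _packaged_defaults() -> dict:
    with resources.files("notchemt").joinpath("data/default_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def _hill(d: dict, where: str) -> HillSpec:
    extra = set(d) - {"threshold", "coefficient", "fold_change"}
    if extra:
        raise ConfigError(f"unknown keys {sorted(extra)} in edge {where}")
    try:
        return HillSpec(float(d["threshold"]), int(d["coefficient"]), float(d["fold_change"]))
    except (KeyError, TypeError, ValueError) as exc:
        raise ConfigError(f"invalid Hill spec for {where}: {exc}") from exc


def _mirna(d: dict, where: str) -> MicroRNARepression:
    extra = set(d) - {"sites", "threshold", "translation_factors",
                      "mrna_degradation", "mirna_degradation"}
    if extra:
        raise ConfigError(f"unknown keys {sorted(extra)} in microRNA record {where}")
    if "translation_factors" in d:
        return MicroRNARepression(
            tuple(float(v) for v in d["translation_factors"]),
            tuple(float(v) for v in d["mrna_degradation"]),
            tuple(float(v) for v in d["mirna_degradation"]),
            float(d["threshold"]),
        )
    return _mir(int(d["sites"]), float(d.get("threshold", 1.0e4)))


def _params_from_tree(tree: dict) -> ModelParameters:
    known_sections = {"production", "degradation", "interaction", "edges", "mirna", "fringe"}
    extra = set(tree) - known_sections
    if extra:
        raise ConfigError(f"unknown parameter sections {sorted(extra)}")
    kw: Dict[str, Any] = {}
    for sec in ("production", "degradation", "interaction"):
        for key, val in tree.get(sec, {}).items():
            if not hasattr(ModelParameters, key) and key not in ModelParameters.__dataclass_fields__:
                raise ConfigError(f"unknown parameter {key!r} in section {sec!r}")
            try:
                kw[key] = float(val)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"parameter {key!r} must be a number: {exc}") from exc
    for key, val in tree.get("edges", {}).items():
        if key not in _EDGE_FIELDS:
            raise ConfigError(f"unknown regulatory edge {key!r}")
        kw[key] = _hill(val, key)
    for key, val in tree.get("mirna", {}).items():
        if key not in _MIR_FIELDS:
            raise ConfigError(f"unknown microRNA record {key!r}")
        kw[key] = _mirna(val, key)
    fr = tree.get("fringe", {})
    extra = set(fr) - {"enabled", "production", "delta_boost", "jagged_drop"}
    if extra:
        raise ConfigError(f"unknown fringe keys {sorted(extra)}")
    if "enabled" in fr:
        kw["fringe_enabled"] = bool(fr["enabled"])
    if "production" in fr:
        kw["fringe_production"] = _hill(fr["production"], "fringe.production")
    if "delta_boost" in fr:
        kw["fringe_delta_boost"] = float(fr["delta_boost"])
    if "jagged_drop" in fr:
        kw["fringe_jagged_drop"] = float(fr["jagged_drop"])
    return ModelParameters(**kw)


def _deep_update(base: dict, upd: dict) -> dict:
    out = dict(base)
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def default_parameters() -> ModelParameters:
    """The packaged default parameter set."""
    return _params_from_tree(_packaged_defaults())


def load_parameters(path: Optional[str] = None, overrides: Optional[dict] = None) -> ModelParameters:
    """Defaults, optionally deep-updated from a YAML file and/or a dict."""
    tree = _packaged_defaults()
    if path is not None:
        user = _read_yaml(path)
        tree = _deep_update(tree, user.get("parameters", user))
    if overrides:
        tree = _deep_update(tree, overrides)
    return _params_from_tree(tree)


_RUN_KEYS = {"t_end", "dt", "seed", "i_ext", "sd_ext", "sj_ext", "aggregation",
             "snapshot_times", "init_ranges"}
_LATTICE_KEYS = {"rows", "cols", "boundary"}


def load_config(path: Optional[str] = None, **run_overrides):
    """Load (lattice spec, TissueConfig) from a YAML file plus overrides.

    Returns ``(lattice_kwargs, TissueConfig)``.  An empty or missing file
    yields the full default configuration.
    """
    tree = _read_yaml(path) if path is not None else {}
    extra = set(tree) - {"parameters", "thresholds", "lattice", "run"}
    if extra:
        raise ConfigError(f"unknown config sections {sorted(extra)}")
    params_tree = _deep_update(_packaged_defaults(), tree.get("parameters", {}))
    params = _params_from_tree(params_tree)

    th_tree = tree.get("thresholds", {})
    extra = set(th_tree) - set(dataclasses.asdict(DEFAULT_THRESHOLDS))
    if extra:
        raise ConfigError(f"unknown threshold keys {sorted(extra)}")
    thresholds = (PhenotypeThresholds(**{k: float(v) for k, v in th_tree.items()})
                  if th_tree else DEFAULT_THRESHOLDS)

    lat = dict(rows=50, cols=50, boundary="periodic")
    extra = set(tree.get("lattice", {})) - _LATTICE_KEYS
    if extra:
        raise ConfigError(f"unknown lattice keys {sorted(extra)}")
    lat.update(tree.get("lattice", {}))

    run = dict(tree.get("run", {}))
    extra = set(run) - _RUN_KEYS
    if extra:
        raise ConfigError(f"unknown run keys {sorted(extra)}")
    run.update(run_overrides)
    snapshot_times = tuple(run.pop("snapshot_times", ()))
    cfg = TissueConfig(params=params, thresholds=thresholds,
                       snapshot_times=snapshot_times, **run)
    return lat, cfg


def parameters_to_dict(p: ModelParameters) -> dict:
    """Round-trippable plain-dict form of a parameter set."""
    tree: Dict[str, Any] = {"production": {}, "degradation": {}, "interaction": {},
                            "edges": {}, "mirna": {}, "fringe": {}}
    for f in dataclasses.fields(p):
        v = getattr(p, f.name)
        if f.name.startswith("g_"):
            tree["production"][f.name] = v
        elif f.name.startswith("k_"):
            tree["degradation"][f.name] = v
        elif f.name.startswith(("kt_", "kc_")):
            tree["interaction"][f.name] = v
        elif f.name in _EDGE_FIELDS:
            tree["edges"][f.name] = {"threshold": v.threshold,
                                     "coefficient": v.coefficient,
                                     "fold_change": v.fold_change}
        elif f.name in _MIR_FIELDS:
            tree["mirna"][f.name] = {
                "translation_factors": list(v.translation_factors),
                "mrna_degradation": list(v.mrna_degradation),
                "mirna_degradation": list(v.mirna_degradation),
                "threshold": v.threshold,
            }
    tree["fringe"] = {"enabled": p.fringe_enabled,
                      "production": {"threshold": p.fringe_production.threshold,
                                     "coefficient": p.fringe_production.coefficient,
                                     "fold_change": p.fringe_production.fold_change},
                      "delta_boost": p.fringe_delta_boost,
                      "jagged_drop": p.fringe_jagged_drop}
    return tree


def config_hash(obj: Any) -> str:
    """Stable short hash of any JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


@dataclasses.dataclass
class RunManifest:
    """Provenance record for one experiment run."""

    name: str
    seed: int
    config_hash: str
    version: str
    timestamp: str
    outputs: List[str]
    status: str = "ok"
    notes: str = ""

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def create(cls, name: str, seed: int, cfg_obj: Any, outputs: List[str],
               status: str = "ok", notes: str = "") -> "RunManifest":
        from . import __version__

        return cls(name=name, seed=seed, config_hash=config_hash(cfg_obj),
                   version=__version__,
                   timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
                   outputs=outputs, status=status, notes=notes)
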