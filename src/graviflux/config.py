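"""YAML run-configuration parsing with schema validation and defaults.

An empty file yields the all-defaults configuration.  Unknown keys are
rejected with an error naming the key, so typos never silently fall back
to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ConfigError, ParseError
from .carrier_map import Aux1Scenario, CarrierRules, PinPlacement
from .auxin_model import ModelParams, default_alpha
from .gravi_scenarios import ExperimentConfig
from .root_template import TemplateSpec


@dataclass
class IOConfig:
    out_dir: str = "run"
    svg: bool = False
    float_digits: int = 10


@dataclass
class RunConfig:
    template: TemplateSpec = field(default_factory=TemplateSpec)
    carriers: CarrierRules = field(default_factory=CarrierRules)
    params: ModelParams = field(default_factory=ModelParams)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)
    io: IOConfig = field(default_factory=IOConfig)
    seed: int = 0


def _require_mapping(block, name: str) -> dict:
    if block is None:
        return {}
    if not isinstance(block, dict):
        raise ConfigError(f"config block {name!r} must be a mapping")
    return dict(block)


def _reject_unknown(d: dict, allowed: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"{context}: unknown key(s) {sorted(unknown)}")


def _template_from_dict(d: dict) -> TemplateSpec:
    allowed = {"n_files_per_flank", "n_rows", "columella_tiers",
               "columella_width", "lrc_layers", "cell_width",
               "cell_heights_by_zone", "wall_thickness", "zone_boundaries"}
    _reject_unknown(d, allowed, "template")
    kw = dict(d)
    if "cell_heights_by_zone" in kw:
        base = dict(TemplateSpec().cell_heights_by_zone)
        base.update(kw["cell_heights_by_zone"])
        kw["cell_heights_by_zone"] = base
    if "zone_boundaries" in kw:
        kw["zone_boundaries"] = tuple(kw["zone_boundaries"])
    spec = TemplateSpec(**kw)
    spec.validate()
    return spec


def _carriers_from_dict(d: dict) -> CarrierRules:
    allowed = {"aux1_cell_types", "pin_placements", "pd_density", "aux1_density"}
    _reject_unknown(d, allowed, "carriers")
    kw: dict = {}
    if "aux1_cell_types" in d:
        kw["aux1_cell_types"] = frozenset(d["aux1_cell_types"])
    if "pin_placements" in d:
        placements = []
        for i, rec in enumerate(d["pin_placements"]):
            rec = _require_mapping(rec, f"carriers.pin_placements[{i}]")
            _reject_unknown(rec, {"species", "cell_types", "facing", "density"},
                            f"carriers.pin_placements[{i}]")
            try:
                placements.append(PinPlacement(
                    species=rec["species"],
                    cell_types=frozenset(rec["cell_types"]),
                    facing_rule=rec.get("facing", "all_faces"),
                    density=float(rec.get("density", 1.0)),
                ))
            except KeyError as e:
                raise ConfigError(
                    f"carriers.pin_placements[{i}]: missing key {e}") from e
        kw["pin_placements"] = tuple(placements)
    if "pd_density" in d:
        kw["pd_density"] = float(d["pd_density"])
    if "aux1_density" in d:
        kw["aux1_density"] = float(d["aux1_density"])
    rules = CarrierRules(**kw)
    rules.validate()
    return rules


def _params_from_dict(d: dict) -> ModelParams:
    allowed = {"P_in_bg", "P_out_bg", "P_aux1", "P_pin", "D_wall", "P_pd",
               "alpha", "delta", "exterior", "c_ext", "P_ext"}
    _reject_unknown(d, allowed, "params")
    kw = dict(d)
    if "alpha" in kw:
        base = default_alpha()
        base.update({k: float(v) for k, v in kw["alpha"].items()})
        kw["alpha"] = base
    p = ModelParams(**kw)
    p.validate()
    return p


def _experiment_from_dict(d: dict) -> ExperimentConfig:
    allowed = {"scenario", "factor", "horizon_s", "snapshot_time_s",
               "threshold", "gravistimulus", "relocate_pin7",
               "dense_until_s", "dense_step_s", "coarse_step_s"}
    _reject_unknown(d, allowed, "experiment")
    mode = d.get("scenario", "basal")
    alias = {"basal": "basal", "global": "global_scale",
             "lower": "lower_scale", "upper": "upper_scale"}
    mode = alias.get(mode, mode)
    scenario = Aux1Scenario(mode=mode, factor=float(d.get("factor", 10.0)))
    scenario.validate()
    horizon = float(d.get("horizon_s", 21600.0))
    cfg = ExperimentConfig(
        scenario=scenario,
        horizon=horizon,
        sample_times=sample_grid(horizon,
                                 dense_until=float(d.get("dense_until_s", 600.0)),
                                 dense_step=float(d.get("dense_step_s", 30.0)),
                                 coarse_step=float(d.get("coarse_step_s", 300.0))),
        snapshot_time=float(d.get("snapshot_time_s", 300.0)),
        gravistimulus=bool(d.get("gravistimulus", True)),
        relocate_pin7=bool(d.get("relocate_pin7", False)),
        threshold=float(d.get("threshold", 1.2)),
    )
    cfg.validate()
    return cfg


def sample_grid(horizon: float, dense_until: float = 600.0,
                dense_step: float = 30.0, coarse_step: float = 300.0) -> np.ndarray:
    """Dense early sampling (capturing the fast post-stimulus transient)
    followed by coarse sampling out to the horizon."""
    if horizon <= 0:
        raise ConfigError("horizon_s must be > 0")
    dense_until = min(dense_until, horizon)
    dense = np.arange(0.0, dense_until + dense_step / 2, dense_step)
    coarse = np.arange(dense_until + coarse_step, horizon + coarse_step / 2,
                       coarse_step)
    grid = np.concatenate([dense, coarse])
    if grid[-1] < horizon:
        grid = np.append(grid, horizon)
    return grid


def _io_from_dict(d: dict) -> IOConfig:
    _reject_unknown(d, {"out_dir", "svg", "float_digits"}, "io")
    return IOConfig(out_dir=str(d.get("out_dir", "run")),
                    svg=bool(d.get("svg", False)),
                    float_digits=int(d.get("float_digits", 10)))


def config_from_dict(doc: dict | None) -> RunConfig:
    doc = _require_mapping(doc, "<root>")
    _reject_unknown(doc, {"template", "carriers", "params", "experiment",
                          "io", "seed"}, "config")
    try:
        return RunConfig(
            template=_template_from_dict(_require_mapping(doc.get("template"),
                                                          "template")),
            carriers=_carriers_from_dict(_require_mapping(doc.get("carriers"),
                                                          "carriers")),
            params=_params_from_dict(_require_mapping(doc.get("params"),
                                                      "params")),
            experiment=_experiment_from_dict(
                _require_mapping(doc.get("experiment"), "experiment")),
            io=_io_from_dict(_require_mapping(doc.get("io"), "io")),
            seed=int(doc.get("seed", 0)),
        )
    except TypeError as e:
        raise ConfigError(str(e)) from e


def parse_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (empty file → defaults)."""
    try:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ParseError(f"{path}: invalid YAML: {e}") from e
    return config_from_dict(doc)


def config_to_dict(cfg: RunConfig) -> dict:
    """Effective configuration as a plain YAML-serializable mapping."""
    t = cfg.template
    scen_alias = {"basal": "basal", "global_scale": "global",
                  "lower_scale": "lower", "upper_scale": "upper"}
    return {
        "template": {
            "n_files_per_flank": t.n_files_per_flank,
            "n_rows": t.n_rows,
            "columella_tiers": t.columella_tiers,
            "columella_width": t.columella_width,
            "lrc_layers": t.lrc_layers,
            "cell_width": t.cell_width,
            "cell_heights_by_zone": dict(t.cell_heights_by_zone),
            "wall_thickness": t.wall_thickness,
            "zone_boundaries": list(t.zone_boundaries),
        },
        "carriers": {
            "aux1_cell_types": sorted(cfg.carriers.aux1_cell_types),
            "pin_placements": [
                {"species": p.species, "cell_types": sorted(p.cell_types),
                 "facing": p.facing_rule, "density": p.density}
                for p in cfg.carriers.pin_placements
            ],
            "pd_density": cfg.carriers.pd_density,
            "aux1_density": cfg.carriers.aux1_density,
        },
        "params": {
            "P_in_bg": cfg.params.P_in_bg, "P_out_bg": cfg.params.P_out_bg,
            "P_aux1": cfg.params.P_aux1, "P_pin": cfg.params.P_pin,
            "D_wall": cfg.params.D_wall, "P_pd": cfg.params.P_pd,
            "alpha": dict(cfg.params.alpha), "delta": cfg.params.delta,
            "exterior": cfg.params.exterior, "c_ext": cfg.params.c_ext,
            "P_ext": cfg.params.P_ext,
        },
        "experiment": {
            "scenario": scen_alias[cfg.experiment.scenario.mode],
            "factor": cfg.experiment.scenario.factor,
            "horizon_s": cfg.experiment.horizon,
            "snapshot_time_s": cfg.experiment.snapshot_time,
            "threshold": cfg.experiment.threshold,
            "gravistimulus": cfg.experiment.gravistimulus,
            "relocate_pin7": cfg.experiment.relocate_pin7,
        },
        "io": {"out_dir": cfg.io.out_dir, "svg": cfg.io.svg,
               "float_digits": cfg.io.float_digits},
        "seed": cfg.seed,
    }


def echo_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
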