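"""Gravitropic-stimulus computational experiments.

Each experiment equilibrates the symmetric root (pre-stimulus steady state),
then at t = 0 simultaneously (a) relocates columella PIN3/PIN4 to the
lower-flank membranes (the gravistimulus) and (b) applies an AUX1 activity
scenario, and integrates the perturbed system forward.  The summary
statistic is the mean auxin concentration over transition-zone epidermal
cells on the lower vs the upper flank, and their ratio over time; asymmetry
is considered established when that ratio first reaches a threshold
(default 1.2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GravifluxError, StructuralError
from .carrier_map import (Aux1Scenario, CarrierRules, apply_aux1_scenario,
                          apply_gravistimulus, assign_carriers)
from .auxin_model import (ModelParams, SimulationResult, assemble_system,
                          integrate, steady_state)
from .root_template import RootTemplate


def default_sample_times() -> np.ndarray:
    """Every 30 s for the first 10 min, then every 5 min out to 6 h."""
    return np.concatenate([np.arange(0.0, 601.0, 30.0),
                           np.arange(900.0, 21601.0, 300.0)])


@dataclass
class ExperimentConfig:
    scenario: Aux1Scenario = field(default_factory=Aux1Scenario)
    horizon: float = 21600.0          # s (6 h gravistimulation window)
    sample_times: np.ndarray = field(default_factory=default_sample_times)
    snapshot_time: float = 300.0      # s (5 min)
    gravistimulus: bool = True
    relocate_pin7: bool = False
    threshold: float = 1.2

    def validate(self) -> None:
        st = np.asarray(self.sample_times, dtype=float)
        if st.size < 1 or st[0] != 0.0 or (st.size > 1 and not np.all(np.diff(st) > 0)):
            raise GravifluxError("sample_times must be strictly increasing from 0")
        if self.horizon < st[-1]:
            raise GravifluxError("horizon must cover max(sample_times)")
        if not np.any(np.isclose(st, self.snapshot_time)):
            raise GravifluxError("snapshot_time must be one of sample_times")


@dataclass
class AsymmetrySeries:
    """Flank-averaged transition-zone epidermal auxin levels over time."""

    times: np.ndarray
    mean_upper: np.ndarray
    mean_lower: np.ndarray

    @property
    def ratio(self) -> np.ndarray:
        return self.mean_lower / self.mean_upper

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.times,
            "mean_upper": self.mean_upper,
            "mean_lower": self.mean_lower,
            "ratio": self.ratio,
        })


def run_gravitropic_experiment(t: RootTemplate, rules: CarrierRules,
                               params: ModelParams,
                               cfg: ExperimentConfig) -> SimulationResult:
    """Pre-equilibrate, perturb at t = 0, integrate the transient.

    The returned trajectory starts at t = 0 with the symmetric pre-stimulus
    steady state as its initial field.
    """
    cfg.validate()
    base = assign_carriers(t, rules)
    pre = assemble_system(t, base, params)
    c0 = steady_state(pre)
    post_map = base
    if cfg.gravistimulus:
        post_map = apply_gravistimulus(post_map, t,
                                       relocate_pin7=cfg.relocate_pin7)
    post_map = apply_aux1_scenario(post_map, t, cfg.scenario)
    post = assemble_system(t, post_map, params)
    times = np.asarray(cfg.sample_times, dtype=float)
    return integrate(post, c0, times)


def _flank_cells(t: RootTemplate, side: str) -> list[str]:
    ids = [c.id for c in t.cells_of(cell_type="epidermis", zone="transition",
                                    side=side)]
    if not ids:
        raise StructuralError(f"template has no transition-zone epidermal "
                              f"cells on the {side} flank")
    return sorted(ids)


def epidermal_asymmetry(r: SimulationResult, t: RootTemplate,
                        normalize: bool = False) -> AsymmetrySeries:
    """Average transition-zone epidermal concentrations per flank.

    With ``normalize=True`` both means are divided by their joint value at
    t = 0 (the pre-stimulus baseline), so basal curves start near 1; the
    lower/upper ratio is unaffected by normalization.
    """
    upper = _flank_cells(t, "upper")
    lower = _flank_cells(t, "lower")
    try:
        iu = [r.pos[c] for c in upper]
        il = [r.pos[c] for c in lower]
    except KeyError as e:
        raise StructuralError(f"simulation result not indexed against "
                              f"template cell {e}") from e
    mu = r.values[:, iu].mean(axis=1)
    ml = r.values[:, il].mean(axis=1)
    if normalize:
        base = (mu[0] * len(iu) + ml[0] * len(il)) / (len(iu) + len(il))
        if base > 0:
            mu = mu / base
            ml = ml / base
    return AsymmetrySeries(times=np.asarray(r.times, dtype=float),
                           mean_upper=mu, mean_lower=ml)


def time_to_asymmetry(a: AsymmetrySeries, threshold: float) -> float | None:
    """First time the lower/upper ratio reaches the threshold.

    Linearly interpolated between samples; ``None`` if the threshold is
    never reached within the sampled window (interpreted as "asymmetry not
    established", i.e. slower than any finite crossing time).
    """
    if not threshold > 1.0:
        raise GravifluxError("threshold must be > 1")
    ratio = a.ratio
    if ratio[0] >= threshold:
        return float(a.times[0])
    for k in range(1, len(ratio)):
        if ratio[k] >= threshold:
            r0, r1 = ratio[k - 1], ratio[k]
            t0, t1 = a.times[k - 1], a.times[k]
            if r1 == r0:
                return float(t1)
            return float(t0 + (threshold - r0) / (r1 - r0) * (t1 - t0))
    return None


def snapshot(r: SimulationResult, t: RootTemplate,
             t_s: float) -> tuple[dict[str, float], pd.DataFrame]:
    """Per-cell concentration field at time ``t_s`` (walls dropped).

    Returns the field and a tidy table (cell id, type, zone, side, rectangle
    corners, value) suitable for heat-map rendering.  Values are linearly
    interpolated between the two bracketing samples; ``t_s`` outside the
    sampled range is an error.
    """
    times = np.asarray(r.times, dtype=float)
    if not (times[0] <= t_s <= times[-1]):
        raise GravifluxError(f"snapshot time {t_s} s outside sampled range "
                             f"[{times[0]}, {times[-1]}]")
    k = int(np.searchsorted(times, t_s))
    if k < len(times) and times[k] == t_s:
        vals = r.values[k]
    else:
        t0, t1 = times[k - 1], times[k]
        w = (t_s - t0) / (t1 - t0)
        vals = (1 - w) * r.values[k - 1] + w * r.values[k]
    field = {}
    records = []
    for cid in sorted(t.cells):
        c = t.cells[cid]
        v = float(vals[r.pos[cid]])
        field[cid] = v
        x0, y0, x1, y1 = c.rect
        records.append({"cell_id": cid, "cell_type": c.cell_type,
                        "zone": c.zone, "side": c.side,
                        "x0": x0, "y0": y0, "x1": x1, "y1": y1, "value": v})
    return field, pd.DataFrame.from_records(records)


def compare_to_basal(t: RootTemplate, rules: CarrierRules, params: ModelParams,
                     factor: float = 10.0,
                     cfg: ExperimentConfig | None = None) -> dict[str, dict]:
    """Run the four standard scenarios and summarize against basal.

    Returns, per scenario, the asymmetry series, the time to asymmetry at
    the configured threshold, and the maximum deviation of the ratio curve
    from the basal one.
    """
    base_cfg = cfg or ExperimentConfig()
    out: dict[str, dict] = {}
    scen = {
        "basal": Aux1Scenario("basal", factor),
        "global": Aux1Scenario("global_scale", factor),
        "lower": Aux1Scenario("lower_scale", factor),
        "upper": Aux1Scenario("upper_scale", factor),
    }
    basal_ratio = None
    for name, sc in scen.items():
        cfg_i = ExperimentConfig(scenario=sc, horizon=base_cfg.horizon,
                                 sample_times=base_cfg.sample_times,
                                 snapshot_time=base_cfg.snapshot_time,
                                 gravistimulus=base_cfg.gravistimulus,
                                 relocate_pin7=base_cfg.relocate_pin7,
                                 threshold=base_cfg.threshold)
        res = run_gravitropic_experiment(t, rules, params, cfg_i)
        series = epidermal_asymmetry(res, t, normalize=True)
        if name == "basal":
            basal_ratio = series.ratio
        out[name] = {
            "result": res,
            "series": series,
            "time_to_asymmetry": time_to_asymmetry(series, base_cfg.threshold),
            "max_ratio_dev_from_basal": float(
                np.abs(series.ratio - basal_ratio).max()),
        }
    return out
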