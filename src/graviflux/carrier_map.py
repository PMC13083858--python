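"""Carrier and plasmodesmata densities on a root-tip template.

AUX1/LAX influx carriers and the PIN efflux carrier family are placed on
membranes as dimensionless densities that multiply the corresponding carrier
permeabilities of the transport model.  Default placements follow the
standard published root-tip distributions: AUX1 in lateral root cap,
epidermis and columella; PIN1 rootward in the stele; PIN2 shootward in
epidermis and LRC; PIN3/PIN4/PIN7 apolar in the columella before a gravity
stimulus.

Two perturbations act at the stimulus instant t = 0:

* the gravistimulus relocates all columella PIN3 and PIN4 to the membranes
  facing the lower flank, conserving each cell's per-species total density;
* an AUX1 activity scenario rescales AUX1 densities globally or on one
  flank only (e.g. a ten-fold increase on the lower side).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

from .errors import ConfigError, StructuralError
from .root_template import CELL_TYPES, RootTemplate

PIN_SPECIES = ("PIN1", "PIN2", "PIN3", "PIN4", "PIN7")
FACING_RULES = ("rootward", "shootward", "all_faces")
SCENARIO_MODES = ("basal", "global_scale", "lower_scale", "upper_scale")


@dataclass(frozen=True)
class PinPlacement:
    species: str
    cell_types: frozenset[str]
    facing_rule: str  # rootward | shootward | all_faces
    density: float = 1.0


def default_pin_placements() -> tuple[PinPlacement, ...]:
    return (
        PinPlacement("PIN1", frozenset({"stele"}), "rootward"),
        PinPlacement("PIN2", frozenset({"epidermis", "lateral_root_cap"}),
                     "shootward"),
        PinPlacement("PIN3", frozenset({"columella"}), "all_faces"),
        PinPlacement("PIN4", frozenset({"columella"}), "all_faces"),
        PinPlacement("PIN7", frozenset({"columella"}), "all_faces"),
    )


@dataclass(frozen=True)
class CarrierRules:
    """Which cell types carry which carriers, and at what density."""

    aux1_cell_types: frozenset[str] = frozenset(
        {"lateral_root_cap", "epidermis", "columella"})
    pin_placements: tuple[PinPlacement, ...] = field(
        default_factory=default_pin_placements)
    pd_density: float = 1.0
    aux1_density: float = 1.0

    def validate(self) -> None:
        unknown = set(self.aux1_cell_types) - set(CELL_TYPES)
        if unknown:
            raise ConfigError(f"aux1_cell_types: unknown cell types {sorted(unknown)}")
        seen = set()
        for p in self.pin_placements:
            if p.species not in PIN_SPECIES:
                raise ConfigError(f"pin placement: unknown species {p.species!r}")
            if p.species in seen:
                raise ConfigError(f"pin placement: duplicate species {p.species!r}")
            seen.add(p.species)
            bad = set(p.cell_types) - set(CELL_TYPES)
            if bad:
                raise ConfigError(
                    f"pin placement {p.species}: unknown cell types {sorted(bad)}")
            if p.facing_rule not in FACING_RULES:
                raise ConfigError(
                    f"pin placement {p.species}: unknown facing rule "
                    f"{p.facing_rule!r}")
            if not p.density >= 0:
                raise ConfigError(f"pin placement {p.species}: density must be >= 0")
        if not self.pd_density >= 0:
            raise ConfigError("pd_density must be >= 0")
        if not self.aux1_density >= 0:
            raise ConfigError("aux1_density must be >= 0")


@dataclass
class CarrierMap:
    """Per-membrane AUX1/PIN densities and per-interior-wall PD densities."""

    aux1: dict[str, float]              # membrane id -> density
    pin: dict[str, dict[str, float]]    # species -> membrane id -> density
    pd: dict[str, float]                # interior wall id -> density

    def pin_total(self, membrane_id: str) -> float:
        """Summed PIN density over all species on one membrane."""
        return sum(d.get(membrane_id, 0.0) for d in self.pin.values())

    def copy(self) -> "CarrierMap":
        return CarrierMap(aux1=dict(self.aux1),
                          pin={s: dict(d) for s, d in self.pin.items()},
                          pd=dict(self.pd))


@dataclass(frozen=True)
class Aux1Scenario:
    """AUX1 activity perturbation applied at the stimulus instant."""

    mode: str = "basal"  # basal | global_scale | lower_scale | upper_scale
    factor: float = 10.0

    def validate(self) -> None:
        if self.mode not in SCENARIO_MODES:
            raise ConfigError(f"unknown scenario mode {self.mode!r}")
        import math
        if not (math.isfinite(self.factor) and self.factor > 0):
            raise ConfigError(f"scenario factor must be finite and > 0, "
                              f"got {self.factor!r}")


def _facing_matches(facing: str, rule: str) -> bool:
    if rule == "all_faces":
        return True
    return facing == rule


def assign_carriers(t: RootTemplate, rules: CarrierRules) -> CarrierMap:
    """Decorate every membrane / interior wall of a template with densities.

    The resulting map is mirror-symmetric whenever the rules are
    side-agnostic (they always are: rules select by cell type and facing,
    which the template mirror preserves up to flank exchange).
    """
    rules.validate()
    aux1 = {}
    for m in t.membranes.values():
        cell = t.cells[m.cell_id]
        aux1[m.id] = (rules.aux1_density
                      if cell.cell_type in rules.aux1_cell_types else 0.0)
    pin: dict[str, dict[str, float]] = {s: {m: 0.0 for m in t.membranes}
                                        for s in PIN_SPECIES}
    for p in rules.pin_placements:
        target = pin[p.species]
        for m in t.membranes.values():
            cell = t.cells[m.cell_id]
            if cell.cell_type in p.cell_types and _facing_matches(m.facing,
                                                                  p.facing_rule):
                target[m.id] = p.density
    pd = {w.id: rules.pd_density for w in t.walls.values() if w.kind == "interior"}
    return CarrierMap(aux1=aux1, pin=pin, pd=pd)


def apply_gravistimulus(c: CarrierMap, t: RootTemplate,
                        relocate_pin7: bool = False) -> CarrierMap:
    """Relocate columella PIN3/PIN4 (optionally PIN7) to lower-facing membranes.

    For every columella cell the per-species total density over its membranes
    is conserved; the total is redistributed over the cell's membranes facing
    the lower flank, split proportionally to membrane area when there are
    several.  Idempotent.  Raises :class:`StructuralError` if a columella
    cell carrying the species has no lower-facing membrane.
    """
    out = c.copy()
    species = ("PIN3", "PIN4") + (("PIN7",) if relocate_pin7 else ())
    for cell in t.cells_of(cell_type="columella"):
        mems = t.membranes_of_cell(cell.id)
        lower = [m for m in mems if m.facing == "toward_lower_flank"]
        for sp in species:
            dens = out.pin.get(sp)
            if dens is None:
                continue
            total = sum(dens.get(m.id, 0.0) for m in mems)
            if total == 0.0:
                continue
            if not lower:
                raise StructuralError(
                    f"columella cell {cell.id} has no membrane facing the "
                    f"lower flank; cannot relocate {sp}")
            area_sum = sum(m.area for m in lower)
            for m in mems:
                dens[m.id] = 0.0
            for m in lower:
                dens[m.id] = total * m.area / area_sum
    return out


def apply_aux1_scenario(c: CarrierMap, t: RootTemplate,
                        s: Aux1Scenario) -> CarrierMap:
    """Rescale AUX1 densities according to an activity scenario.

    ``basal`` leaves the map unchanged; ``global_scale`` multiplies every
    AUX1 density by the factor; ``lower_scale`` / ``upper_scale`` multiply
    only on membranes of cells on that flank (on-axis cells untouched).
    PIN and plasmodesmatal densities are never modified.
    """
    s.validate()
    out = c.copy()
    if s.mode == "basal":
        return out
    if s.mode == "global_scale":
        for m in out.aux1:
            out.aux1[m] *= s.factor
        return out
    side = "lower" if s.mode == "lower_scale" else "upper"
    for m_id in out.aux1:
        cell = t.cells[t.membranes[m_id].cell_id]
        if cell.side == side:
            out.aux1[m_id] *= s.factor
    return out


# deep copy helper used by tests / config round-trips
def clone_map(c: CarrierMap) -> CarrierMap:
    return copy.deepcopy(c)
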