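"""Carrier placement, gravistimulus relocation and AUX1 scenarios."""

import pytest

from graviflux.errors import ConfigError, StructuralError
from graviflux.carrier_map import (Aux1Scenario, CarrierRules, PinPlacement,
                                   apply_aux1_scenario, apply_gravistimulus,
                                   assign_carriers)


AUX1_TYPES = {"lateral_root_cap", "epidermis", "columella"}


def test_default_aux1_placement(default_template, default_map):
    t = default_template
    for m in t.membranes.values():
        expected = 1.0 if t.cells[m.cell_id].cell_type in AUX1_TYPES else 0.0
        assert default_map.aux1[m.id] == expected


def test_default_pin_placement(default_template, default_map):
    t = default_template
    for m in t.membranes.values():
        ct = t.cells[m.cell_id].cell_type
        assert default_map.pin["PIN1"][m.id] == (
            1.0 if ct == "stele" and m.facing == "rootward" else 0.0)
        assert default_map.pin["PIN2"][m.id] == (
            1.0 if ct in ("epidermis", "lateral_root_cap")
            and m.facing == "shootward" else 0.0)
        for sp in ("PIN3", "PIN4", "PIN7"):
            assert default_map.pin[sp][m.id] == (1.0 if ct == "columella" else 0.0)


def test_map_is_mirror_symmetric(default_template, default_map):
    t = default_template
    for mid in t.membranes:
        assert default_map.aux1[mid] == default_map.aux1[t.mirror[mid]]
        for sp, dens in default_map.pin.items():
            assert dens[mid] == dens[t.mirror[mid]], (sp, mid)
    for w in t.walls.values():
        if w.kind == "interior":
            assert default_map.pd[w.id] == default_map.pd[t.mirror[w.id]]


def test_empty_rules_give_zero_map(default_template):
    rules = CarrierRules(aux1_cell_types=frozenset(), pin_placements=(),
                         pd_density=0.0)
    cm = assign_carriers(default_template, rules)
    assert all(v == 0.0 for v in cm.aux1.values())
    assert all(v == 0.0 for d in cm.pin.values() for v in d.values())
    assert all(v == 0.0 for v in cm.pd.values())


def test_unknown_cell_type_and_species_rejected(default_template):
    with pytest.raises(ConfigError, match="unknown cell type"):
        assign_carriers(default_template,
                        CarrierRules(aux1_cell_types=frozenset({"phloem"})))
    with pytest.raises(ConfigError, match="unknown species"):
        assign_carriers(default_template, CarrierRules(pin_placements=(
            PinPlacement("PIN9", frozenset({"stele"}), "rootward"),)))


def test_gravistimulus_moves_everything_to_lower_membranes(default_template,
                                                           default_map):
    t = default_template
    out = apply_gravistimulus(default_map, t)
    for cell in t.cells_of(cell_type="columella"):
        mems = t.membranes_of_cell(cell.id)
        for sp in ("PIN3", "PIN4"):
            before = sum(default_map.pin[sp][m.id] for m in mems)
            after = sum(out.pin[sp][m.id] for m in mems)
            assert after == pytest.approx(before, rel=1e-14)
            for m in mems:
                if m.facing != "toward_lower_flank":
                    assert out.pin[sp][m.id] == 0.0
    # PIN7 and non-columella PINs untouched by default
    assert out.pin["PIN7"] == default_map.pin["PIN7"]
    assert out.pin["PIN1"] == default_map.pin["PIN1"]
    assert out.aux1 == default_map.aux1
    assert out.pd == default_map.pd


def test_gravistimulus_concentrates_per_cell_total(default_template,
                                                   default_map):
    # a columella cell with density 1 on each of its n membranes ends up
    # with total n on its lower-facing membrane(s)
    t = default_template
    out = apply_gravistimulus(default_map, t)
    for cell in t.cells_of(cell_type="columella"):
        mems = t.membranes_of_cell(cell.id)
        lower = [m for m in mems if m.facing == "toward_lower_flank"]
        total = sum(out.pin["PIN3"][m.id] for m in lower)
        assert total == pytest.approx(float(len(mems)), rel=1e-14)


def test_gravistimulus_idempotent_and_noop_without_pin(default_template,
                                                       default_map):
    t = default_template
    once = apply_gravistimulus(default_map, t)
    twice = apply_gravistimulus(once, t)
    assert twice.pin == once.pin
    empty = assign_carriers(t, CarrierRules(pin_placements=()))
    assert apply_gravistimulus(empty, t).pin == empty.pin


def test_gravistimulus_optionally_relocates_pin7(default_template, default_map):
    t = default_template
    out = apply_gravistimulus(default_map, t, relocate_pin7=True)
    for cell in t.cells_of(cell_type="columella"):
        for m in t.membranes_of_cell(cell.id):
            if m.facing != "toward_lower_flank":
                assert out.pin["PIN7"][m.id] == 0.0


def test_gravistimulus_requires_lower_membrane(two_cell_template, default_map):
    # a lone "columella" cell whose only membrane faces the upper flank
    import dataclasses
    t = two_cell_template
    t.cells["A"] = dataclasses.replace(t.cells["A"], cell_type="columella")
    from graviflux.carrier_map import CarrierMap
    cm = CarrierMap(aux1={m: 0.0 for m in t.membranes},
                    pin={"PIN3": {m: 1.0 for m in t.membranes}},
                    pd={"w_A__B": 1.0})
    with pytest.raises(StructuralError, match="A"):
        apply_gravistimulus(cm, t)


@pytest.mark.parametrize("mode, side_scaled", [
    ("lower_scale", "lower"), ("upper_scale", "upper")])
def test_one_sided_scenarios(default_template, default_map, mode, side_scaled):
    t = default_template
    out = apply_aux1_scenario(default_map, t, Aux1Scenario(mode, 10.0))
    for mid, before in default_map.aux1.items():
        side = t.cells[t.membranes[mid].cell_id].side
        expected = before * 10.0 if side == side_scaled else before
        assert out.aux1[mid] == pytest.approx(expected, rel=1e-14)
    assert out.pin == default_map.pin
    assert out.pd == default_map.pd


def test_global_and_basal_scenarios(default_template, default_map):
    t = default_template
    assert apply_aux1_scenario(default_map, t,
                               Aux1Scenario("basal", 10.0)).aux1 == \
        default_map.aux1
    assert apply_aux1_scenario(default_map, t,
                               Aux1Scenario("global_scale", 1.0)).aux1 == \
        default_map.aux1
    out = apply_aux1_scenario(default_map, t, Aux1Scenario("global_scale", 10.0))
    for mid, before in default_map.aux1.items():
        assert out.aux1[mid] == pytest.approx(before * 10.0, rel=1e-14)


def test_scenario_rejects_bad_factor(default_template, default_map):
    with pytest.raises(ConfigError):
        apply_aux1_scenario(default_map, default_template,
                            Aux1Scenario("global_scale", 0.0))
    with pytest.raises(ConfigError):
        apply_aux1_scenario(default_map, default_template,
                            Aux1Scenario("sideways", 2.0))


def test_scenario_commutes_with_gravistimulus(default_template, default_map):
    t = default_template
    s = Aux1Scenario("lower_scale", 10.0)
    a = apply_aux1_scenario(apply_gravistimulus(default_map, t), t, s)
    b = apply_gravistimulus(apply_aux1_scenario(default_map, t, s), t)
    assert a.aux1 == b.aux1 and a.pin == b.pin and a.pd == b.pd
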