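import numpy as np
import pytest

from graviflux.root_template import (Cell, Membrane, RootTemplate, TemplateSpec,
                                     Wall, build_root_template)
from graviflux.carrier_map import CarrierRules, assign_carriers


@pytest.fixture(scope="session")
def default_template():
    return build_root_template(TemplateSpec())


@pytest.fixture(scope="session")
def default_rules():
    return CarrierRules()


@pytest.fixture(scope="session")
def default_map(default_template, default_rules):
    return assign_carriers(default_template, default_rules)


def make_two_cell_template(volume: float = 1000.0, wall_area: float = 10.0,
                           thickness: float = 0.2) -> RootTemplate:
    """Hand-built pair of cells sharing a single interior (PD-bearing) wall.

    Deliberately minimal (no exterior walls), for closed-form checks of the
    transport model; it is not a valid full template.
    """
    h = volume / wall_area  # rect height so that width × height = volume
    w = wall_area
    cells = {
        "A": Cell(id="A", cell_type="epidermis", zone="meristem", side="lower",
                  centroid=(-h / 2, w / 2), volume=volume,
                  rect=(-h, 0.0, 0.0, w),
                  membrane_ids=("m_A@w_A__B",)),
        "B": Cell(id="B", cell_type="epidermis", zone="meristem", side="upper",
                  centroid=(h / 2, w / 2), volume=volume,
                  rect=(0.0, 0.0, h, w),
                  membrane_ids=("m_B@w_A__B",)),
    }
    wall = Wall(id="w_A__B", cell_ids=("A", "B"), area=wall_area,
                volume=wall_area * thickness, kind="interior",
                orientation="lateral_inner", p1=(0.0, 0.0), p2=(0.0, w))
    membranes = {
        "m_A@w_A__B": Membrane(id="m_A@w_A__B", cell_id="A", wall_id="w_A__B",
                               area=wall_area, facing="toward_upper_flank"),
        "m_B@w_A__B": Membrane(id="m_B@w_A__B", cell_id="B", wall_id="w_A__B",
                               area=wall_area, facing="toward_lower_flank"),
    }
    mirror = {"A": "B", "B": "A", "w_A__B": "w_A__B",
              "m_A@w_A__B": "m_B@w_A__B", "m_B@w_A__B": "m_A@w_A__B"}
    return RootTemplate(cells=cells, walls={wall.id: wall},
                        membranes=membranes,
                        pd_edges=[("A", "B", "w_A__B")], mirror=mirror,
                        meta={"wall_thickness": thickness, "depth": 1.0})


def make_single_cell_template(volume: float = 500.0) -> RootTemplate:
    """One isolated cell, no walls: the smallest assemblable system."""
    c = Cell(id="solo", cell_type="stele", zone="meristem", side="axial",
             centroid=(0.0, 5.0), volume=volume, rect=(-5.0, 0.0, 5.0, 10.0),
             membrane_ids=())
    return RootTemplate(cells={"solo": c}, walls={}, membranes={},
                        pd_edges=[], mirror={"solo": "solo"},
                        meta={"wall_thickness": 0.2, "depth": 1.0})


@pytest.fixture()
def two_cell_template():
    return make_two_cell_template()


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)
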