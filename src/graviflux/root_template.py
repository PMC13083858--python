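"""Synthetic multicellular root-tip geometry.

The simulator operates on an idealized *Arabidopsis*-like root tip laid out on
a rectilinear grid: a columella block at the tip flanked by the quiescent
centre (QC), two mirror-symmetric flanks of tissue files (stele, endodermis,
cortex, epidermis from the axis outward) and lateral root cap (LRC) layers
wrapping the meristematic region.  Cells are axis-aligned rectangles of unit
depth (1 µm) in the third dimension, so areas are segment lengths × 1 µm and
volumes are rectangle areas × 1 µm.

The template records, for every cell, the wall segments it touches and one
membrane per (cell, wall) incidence.  Each wall segment is its own apoplastic
compartment (volume = contact area × wall thickness).  Plasmodesmatal edges
connect every pair of cells sharing an interior wall.

Gravity semantics are carried by labels only: after a 90° reorientation the
flank at x < 0 is called *lower* and the flank at x > 0 *upper*; the geometry
itself is never rotated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import networkx as nx

from .errors import ParseError, TemplateError

CELL_TYPES = (
    "columella",
    "QC",
    "lateral_root_cap",
    "epidermis",
    "cortex",
    "endodermis",
    "stele",
)
ZONES = ("root_cap", "meristem", "transition", "elongation")
SIDES = ("upper", "lower", "axial")
MEMBRANE_FACINGS = (
    "rootward",
    "shootward",
    "toward_lower_flank",
    "toward_upper_flank",
    "toward_axis",
    "away_from_axis",
)

#: unit depth of the quasi-2D template, µm
DEPTH = 1.0
_TOL = 1e-9
_ROUND = 6


@dataclass(frozen=True)
class TemplateSpec:
    """Parameters of the synthetic root-tip template.

    All lengths are in µm.  ``zone_boundaries`` are the row indices (within
    each flank file of ``n_rows`` rows, counted from the tip) at which the
    meristem, transition and elongation zones begin; rows before the first
    boundary belong to the root cap.
    """

    n_files_per_flank: int = 4
    n_rows: int = 10
    columella_tiers: int = 3
    columella_width: int = 3
    lrc_layers: int = 2
    cell_width: float = 20.0
    cell_heights_by_zone: Mapping[str, float] = field(
        default_factory=lambda: {
            "root_cap": 15.0,
            "meristem": 15.0,
            "transition": 30.0,
            "elongation": 60.0,
        }
    )
    wall_thickness: float = 0.2
    zone_boundaries: tuple[int, int, int] = (2, 6, 8)

    def validate(self) -> None:
        for name in ("n_files_per_flank", "n_rows", "columella_tiers",
                     "columella_width", "lrc_layers"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise TemplateError(f"{name} must be an integer >= 1, got {v!r}")
        for name in ("cell_width", "wall_thickness"):
            v = getattr(self, name)
            if not v > 0:
                raise TemplateError(f"{name} must be > 0, got {v!r}")
        missing = set(ZONES) - set(self.cell_heights_by_zone)
        if missing:
            raise TemplateError(f"cell_heights_by_zone missing zones: {sorted(missing)}")
        for z, h in self.cell_heights_by_zone.items():
            if z not in ZONES:
                raise TemplateError(f"cell_heights_by_zone has unknown zone {z!r}")
            if not h > 0:
                raise TemplateError(f"cell height for zone {z!r} must be > 0, got {h!r}")
        b = self.zone_boundaries
        if len(b) != 3:
            raise TemplateError("zone_boundaries must have exactly 3 entries")
        if not (0 <= b[0] < b[1] < b[2] <= self.n_rows):
            raise TemplateError(
                f"zone_boundaries must be strictly increasing within n_rows, "
                f"got {b} with n_rows={self.n_rows}"
            )

    def zone_of_row(self, r: int) -> str:
        b0, b1, b2 = self.zone_boundaries
        if r < b0:
            return "root_cap"
        if r < b1:
            return "meristem"
        if r < b2:
            return "transition"
        return "elongation"


@dataclass(frozen=True)
class Cell:
    id: str
    cell_type: str
    zone: str
    side: str
    centroid: tuple[float, float]
    volume: float
    rect: tuple[float, float, float, float]  # x0, y0, x1, y1
    membrane_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class Wall:
    id: str
    cell_ids: tuple[str, ...]  # 1 (exterior) or 2 (interior)
    area: float  # µm², contact area = segment length × unit depth
    volume: float  # µm³ = area × wall_thickness
    kind: str  # interior | exterior
    orientation: str  # rootward | shootward | lateral_inner | lateral_outer
    p1: tuple[float, float]
    p2: tuple[float, float]

    @property
    def centroid(self) -> tuple[float, float]:
        return ((self.p1[0] + self.p2[0]) / 2.0, (self.p1[1] + self.p2[1]) / 2.0)


@dataclass(frozen=True)
class Membrane:
    id: str
    cell_id: str
    wall_id: str
    area: float
    facing: str


@dataclass
class RootTemplate:
    cells: dict[str, Cell]
    walls: dict[str, Wall]
    membranes: dict[str, Membrane]
    pd_edges: list[tuple[str, str, str]]  # (cell_i, cell_j, wall_id)
    mirror: dict[str, str]
    meta: dict

    @property
    def wall_thickness(self) -> float:
        return float(self.meta["wall_thickness"])

    def cells_of(self, *, cell_type: str | None = None, zone: str | None = None,
                 side: str | None = None) -> list[Cell]:
        out = []
        for c in self.cells.values():
            if cell_type is not None and c.cell_type != cell_type:
                continue
            if zone is not None and c.zone != zone:
                continue
            if side is not None and c.side != side:
                continue
            out.append(c)
        return out

    def membranes_of_cell(self, cell_id: str) -> list[Membrane]:
        return [self.membranes[m] for m in self.cells[cell_id].membrane_ids]


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues

    def add(self, msg: str) -> None:
        self.issues.append(msg)


# ---------------------------------------------------------------------------
# construction helpers

@dataclass
class _Rect:
    id: str
    cell_type: str
    zone: str
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def cx(self) -> float:
        return (self.x0 + self.x1) / 2.0

    @property
    def cy(self) -> float:
        return (self.y0 + self.y1) / 2.0


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _TOL


def _flank_tissue_order(n_files: int) -> list[str]:
    """Tissue types from the axis outward for ``n_files`` files per flank.

    The outermost files are always epidermis → cortex → endodermis → stele
    (dropped from the inside when fewer than 4 files are requested); extra
    files beyond 4 are additional stele columns next to the axis.
    """
    base = ["stele", "endodermis", "cortex", "epidermis"]
    if n_files <= 4:
        return base[4 - n_files:]
    return ["stele"] * (n_files - 4) + base


def _make_rects(spec: TemplateSpec) -> list[_Rect]:
    w = spec.cell_width
    h_rc = spec.cell_heights_by_zone["root_cap"]
    h_mer = spec.cell_heights_by_zone["meristem"]
    rects: list[_Rect] = []

    # columella tiers (tier 0 at the very tip)
    cw = spec.columella_width
    if cw % 2 == 1:
        ks = range(-(cw // 2), cw // 2 + 1)
    else:
        ks = [k for k in range(-(cw // 2), cw // 2 + 1) if k != 0]
    for t in range(spec.columella_tiers):
        y0, y1 = t * h_rc, (t + 1) * h_rc
        for k in ks:
            if cw % 2 == 1:
                x0 = k * w - w / 2.0
            else:
                x0 = (k - 1) * w if k > 0 else k * w
            rects.append(_Rect(f"col_t{t}_k{k:+d}".replace("+0", "0"),
                               "columella", "root_cap", x0, y0, x0 + w, y1))

    y_qc0 = spec.columella_tiers * h_rc
    y_qc1 = y_qc0 + h_mer
    rects.append(_Rect("qc", "QC", "meristem", -w / 2.0, y_qc0, w / 2.0, y_qc1))

    # flank files
    tissues = _flank_tissue_order(spec.n_files_per_flank)
    for sgn, side in ((-1, "low"), (1, "up")):
        for f, tissue in enumerate(tissues):
            xa, xb = f * w, (f + 1) * w
            x0, x1 = (xa, xb) if sgn > 0 else (-xb, -xa)
            y = y_qc1
            for r in range(spec.n_rows):
                zone = spec.zone_of_row(r)
                h = spec.cell_heights_by_zone[zone]
                rects.append(_Rect(f"{side}_f{f}_{tissue}_r{r}", tissue, zone,
                                   x0, y, x1, y + h))
                y += h
        # lateral root cap layers hugging the outermost file over the
        # root-cap and meristem rows
        n_lrc_rows = spec.zone_boundaries[1]
        for layer in range(spec.lrc_layers):
            fa = spec.n_files_per_flank + layer
            xa, xb = fa * w, (fa + 1) * w
            x0, x1 = (xa, xb) if sgn > 0 else (-xb, -xa)
            y = y_qc1
            for r in range(n_lrc_rows):
                zone = spec.zone_of_row(r)
                h = spec.cell_heights_by_zone[zone]
                rects.append(_Rect(f"{side}_lrc{layer}_r{r}", "lateral_root_cap",
                                   zone, x0, y, x1, y + h))
                y += h
    return rects


def _interval_subtract(lo: float, hi: float,
                       covered: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Parts of [lo, hi] not covered by the given (merged-on-the-fly) intervals."""
    pieces = [(lo, hi)]
    for a, b in sorted(covered):
        nxt = []
        for p0, p1 in pieces:
            if b <= p0 + _TOL or a >= p1 - _TOL:
                nxt.append((p0, p1))
                continue
            if a > p0 + _TOL:
                nxt.append((p0, a))
            if b < p1 - _TOL:
                nxt.append((b, p1))
        pieces = nxt
    return [(a, b) for a, b in pieces if b - a > _TOL]


def build_root_template(spec: TemplateSpec) -> RootTemplate:
    """Construct the rectilinear root-tip template from a spec.

    Raises :class:`TemplateError` if the spec violates its invariants.  The
    returned template satisfies mirror symmetry (the ``mirror`` involution
    exchanges the two flanks and fixes on-axis entities) and all bookkeeping
    invariants checked by :func:`validate_template`.
    """
    spec.validate()
    rects = _make_rects(spec)
    by_id = {r.id: r for r in rects}
    if len(by_id) != len(rects):
        raise TemplateError("internal: duplicate cell ids")

    # --- interior walls from shared edges ------------------------------
    walls: dict[str, Wall] = {}
    # per cell, per edge name, list of covered intervals
    covered: dict[str, dict[str, list[tuple[float, float]]]] = {
        r.id: {"bot": [], "top": [], "left": [], "right": []} for r in rects
    }
    cell_membranes: dict[str, list[Membrane]] = {r.id: [] for r in rects}
    thick = spec.wall_thickness

    def add_membranes(wall: Wall, cells: Iterable[_Rect]) -> None:
        vertical = _close(wall.p1[0], wall.p2[0])
        for c in cells:
            if vertical:
                facing = ("toward_lower_flank" if wall.p1[0] < c.cx
                          else "toward_upper_flank")
            else:
                facing = "rootward" if wall.p1[1] < c.cy else "shootward"
            m = Membrane(id=f"m_{c.id}@{wall.id}", cell_id=c.id,
                         wall_id=wall.id, area=wall.area, facing=facing)
            cell_membranes[c.id].append(m)

    n = len(rects)
    for i in range(n):
        a = rects[i]
        for j in range(i + 1, n):
            b = rects[j]
            seg = None
            # a right edge against b left edge (or vice versa)
            for lo_c, hi_c in ((a, b), (b, a)):
                if _close(lo_c.x1, hi_c.x0):
                    y0 = max(lo_c.y0, hi_c.y0)
                    y1 = min(lo_c.y1, hi_c.y1)
                    if y1 - y0 > _TOL:
                        x = lo_c.x1
                        seg = ((x, y0), (x, y1))
                        covered[lo_c.id]["right"].append((y0, y1))
                        covered[hi_c.id]["left"].append((y0, y1))
                if _close(lo_c.y1, hi_c.y0):
                    x0 = max(lo_c.x0, hi_c.x0)
                    x1 = min(lo_c.x1, hi_c.x1)
                    if x1 - x0 > _TOL:
                        y = lo_c.y1
                        seg = ((x0, y), (x1, y))
                        covered[lo_c.id]["top"].append((x0, x1))
                        covered[hi_c.id]["bot"].append((x0, x1))
                if seg:
                    break
            if seg is None:
                continue
            (p1, p2) = seg
            length = abs(p2[0] - p1[0]) + abs(p2[1] - p1[1])
            area = length * DEPTH
            ca, cb = sorted((a.id, b.id))
            vertical = _close(p1[0], p2[0])
            orientation = "lateral_inner" if vertical else "rootward"
            wall = Wall(id=f"w_{ca}__{cb}", cell_ids=(ca, cb), area=area,
                        volume=area * thick, kind="interior",
                        orientation=orientation, p1=p1, p2=p2)
            walls[wall.id] = wall
            add_membranes(wall, (a, b))

    # --- exterior walls from uncovered edge pieces ---------------------
    for r in rects:
        edges = {
            "bot": ((r.x0, r.x1), r.y0, False),
            "top": ((r.x0, r.x1), r.y1, False),
            "left": ((r.y0, r.y1), r.x0, True),
            "right": ((r.y0, r.y1), r.x1, True),
        }
        for edge, ((lo, hi), const, vertical) in edges.items():
            for k, (a0, a1) in enumerate(_interval_subtract(lo, hi, covered[r.id][edge])):
                if vertical:
                    p1, p2 = (const, a0), (const, a1)
                    orientation = ("lateral_inner" if abs(const) < abs(r.cx)
                                   else "lateral_outer")
                else:
                    p1, p2 = (a0, const), (a1, const)
                    orientation = "rootward" if const < r.cy else "shootward"
                area = (a1 - a0) * DEPTH
                wall = Wall(id=f"w_{r.id}_{edge}{k}", cell_ids=(r.id,),
                            area=area, volume=area * thick, kind="exterior",
                            orientation=orientation, p1=p1, p2=p2)
                walls[wall.id] = wall
                add_membranes(wall, (r,))

    # --- cells ---------------------------------------------------------
    cells: dict[str, Cell] = {}
    for r in rects:
        side = "axial" if abs(r.cx) <= _TOL else ("lower" if r.cx < 0 else "upper")
        mems = tuple(sorted(m.id for m in cell_membranes[r.id]))
        cells[r.id] = Cell(
            id=r.id, cell_type=r.cell_type, zone=r.zone, side=side,
            centroid=(r.cx, r.cy),
            volume=(r.x1 - r.x0) * (r.y1 - r.y0) * DEPTH,
            rect=(r.x0, r.y0, r.x1, r.y1), membrane_ids=mems,
        )

    membranes = {m.id: m for ms in cell_membranes.values() for m in ms}

    pd_edges = sorted(
        (w.cell_ids[0], w.cell_ids[1], w.id)
        for w in walls.values() if w.kind == "interior"
    )

    mirror = _build_mirror(cells, walls, membranes)

    meta = {
        "units": {"length": "um", "area": "um^2", "volume": "um^3"},
        "depth": DEPTH,
        "wall_thickness": thick,
        "spec": {
            "n_files_per_flank": spec.n_files_per_flank,
            "n_rows": spec.n_rows,
            "columella_tiers": spec.columella_tiers,
            "columella_width": spec.columella_width,
            "lrc_layers": spec.lrc_layers,
            "cell_width": spec.cell_width,
            "cell_heights_by_zone": dict(spec.cell_heights_by_zone),
            "wall_thickness": spec.wall_thickness,
            "zone_boundaries": list(spec.zone_boundaries),
        },
    }
    t = RootTemplate(cells=cells, walls=walls, membranes=membranes,
                     pd_edges=pd_edges, mirror=mirror, meta=meta)
    report = validate_template(t)
    if not report.ok:
        raise TemplateError("generated template failed validation: "
                            + "; ".join(report.issues[:5]))
    return t


def _seg_key(p1: tuple[float, float], p2: tuple[float, float]) -> tuple:
    a = (round(p1[0], _ROUND), round(p1[1], _ROUND))
    b = (round(p2[0], _ROUND), round(p2[1], _ROUND))
    return tuple(sorted((a, b)))


def _build_mirror(cells: dict[str, Cell], walls: dict[str, Wall],
                  membranes: dict[str, Membrane]) -> dict[str, str]:
    """Geometric x → −x involution over all cell, wall and membrane ids."""
    mirror: dict[str, str] = {}
    cell_by_rect = {
        tuple(round(v, _ROUND) for v in c.rect): c.id for c in cells.values()
    }
    for c in cells.values():
        x0, y0, x1, y1 = c.rect
        key = tuple(round(v, _ROUND) for v in (-x1, y0, -x0, y1))
        try:
            mirror[c.id] = cell_by_rect[key]
        except KeyError:
            raise TemplateError(f"cell {c.id} has no mirror partner")
    wall_by_seg = {_seg_key(w.p1, w.p2): w.id for w in walls.values()}
    for w in walls.values():
        key = _seg_key((-w.p1[0], w.p1[1]), (-w.p2[0], w.p2[1]))
        try:
            mirror[w.id] = wall_by_seg[key]
        except KeyError:
            raise TemplateError(f"wall {w.id} has no mirror partner")
    for m in membranes.values():
        mc, mw = mirror[m.cell_id], mirror[m.wall_id]
        mirror[m.id] = f"m_{mc}@{mw}"
        if mirror[m.id] not in membranes:
            raise TemplateError(f"membrane {m.id} has no mirror partner")
    return mirror


# ---------------------------------------------------------------------------
# validation

def validate_template(t: RootTemplate) -> ValidationReport:
    """Check every template invariant; returns a report of violations.

    An empty report means the template is valid.  This never raises: it is a
    diagnostic operation.
    """
    rep = ValidationReport()
    thick = float(t.meta.get("wall_thickness", 0.0))

    for c in t.cells.values():
        if not c.volume > 0:
            rep.add(f"cell {c.id}: volume {c.volume} not > 0")
        if c.cell_type not in CELL_TYPES:
            rep.add(f"cell {c.id}: unknown cell_type {c.cell_type!r}")
        if c.zone not in ZONES:
            rep.add(f"cell {c.id}: unknown zone {c.zone!r}")
        if c.side not in SIDES:
            rep.add(f"cell {c.id}: unknown side {c.side!r}")
        if (c.side == "axial") != (abs(c.centroid[0]) <= 1e-6):
            rep.add(f"cell {c.id}: side {c.side!r} inconsistent with centroid x "
                    f"{c.centroid[0]}")
        for mid in c.membrane_ids:
            if mid not in t.membranes:
                rep.add(f"cell {c.id}: membrane id {mid} unresolved")
            elif t.membranes[mid].cell_id != c.id:
                rep.add(f"cell {c.id}: membrane {mid} belongs to another cell")

    mem_by_wall: dict[str, list[Membrane]] = {}
    for m in t.membranes.values():
        if m.cell_id not in t.cells:
            rep.add(f"membrane {m.id}: unknown cell {m.cell_id}")
        if m.wall_id not in t.walls:
            rep.add(f"membrane {m.id}: unknown wall {m.wall_id}")
            continue
        if m.facing not in MEMBRANE_FACINGS:
            rep.add(f"membrane {m.id}: unknown facing {m.facing!r}")
        mem_by_wall.setdefault(m.wall_id, []).append(m)
    pairs = [(m.cell_id, m.wall_id) for m in t.membranes.values()]
    if len(set(pairs)) != len(pairs):
        rep.add("duplicate (cell_id, wall_id) membrane pairs present")

    for w in t.walls.values():
        if not w.area > 0:
            rep.add(f"wall {w.id}: area {w.area} not > 0")
        if not w.volume > 0:
            rep.add(f"wall {w.id}: volume {w.volume} not > 0")
        if thick > 0 and abs(w.volume - w.area * thick) > 1e-9 * max(1.0, w.volume):
            rep.add(f"wall {w.id}: volume != area × wall_thickness")
        if w.kind == "interior":
            if len(set(w.cell_ids)) != 2:
                rep.add(f"wall {w.id}: interior wall must reference exactly 2 "
                        f"distinct cells, got {w.cell_ids}")
        elif w.kind == "exterior":
            if len(w.cell_ids) != 1:
                rep.add(f"wall {w.id}: exterior wall must reference exactly 1 "
                        f"cell, got {w.cell_ids}")
        else:
            rep.add(f"wall {w.id}: unknown kind {w.kind!r}")
        for cid in w.cell_ids:
            if cid not in t.cells:
                rep.add(f"wall {w.id}: unknown cell {cid}")
        ms = mem_by_wall.get(w.id, [])
        want = 2 if w.kind == "interior" else 1
        if len(ms) != want:
            rep.add(f"wall {w.id}: expected {want} membranes, found {len(ms)}")
        for m in ms:
            if abs(m.area - w.area) > 1e-9 * max(1.0, w.area):
                rep.add(f"membrane {m.id}: area differs from wall area")

    for ci, cj, wid in t.pd_edges:
        w = t.walls.get(wid)
        if w is None:
            rep.add(f"pd edge ({ci},{cj}): unknown wall {wid}")
            continue
        if w.kind != "interior":
            rep.add(f"pd edge ({ci},{cj}): wall {wid} is not interior")
        elif set((ci, cj)) != set(w.cell_ids):
            rep.add(f"pd edge ({ci},{cj}): cells do not match wall {wid}")

    # mirror involution and preservation
    all_ids = set(t.cells) | set(t.walls) | set(t.membranes)
    if set(t.mirror) != all_ids:
        rep.add("mirror map does not cover exactly the cell/wall/membrane ids")
    else:
        for i, j in t.mirror.items():
            if t.mirror.get(j) != i:
                rep.add(f"mirror not an involution at {i} -> {j}")
        for cid, c in t.cells.items():
            d = t.cells.get(t.mirror.get(cid, ""), None)
            if d is None:
                rep.add(f"mirror of cell {cid} is not a cell")
                continue
            if (c.cell_type, c.zone) != (d.cell_type, d.zone):
                rep.add(f"mirror breaks type/zone for cell pair ({cid},{d.id})")
            if abs(c.volume - d.volume) > 1e-9 * max(1.0, c.volume):
                rep.add(f"mirror breaks volume equality for cell pair ({cid},{d.id})")
            if c.side == "axial" and d.id != cid:
                rep.add(f"axial cell {cid} not fixed by mirror")
            if {c.side, d.side} not in ({"axial"}, {"upper", "lower"}):
                rep.add(f"mirror side mismatch for cell pair ({cid},{d.id})")
        for wid, w in t.walls.items():
            d = t.walls.get(t.mirror.get(wid, ""), None)
            if d is None:
                rep.add(f"mirror of wall {wid} is not a wall")
                continue
            if w.kind != d.kind or abs(w.area - d.area) > 1e-9 * max(1.0, w.area):
                rep.add(f"mirror breaks kind/area for wall pair ({wid},{d.id})")

    # connectivity of the cell adjacency graph (interior walls)
    g = nx.Graph()
    g.add_nodes_from(t.cells)
    for w in t.walls.values():
        if w.kind == "interior" and len(w.cell_ids) == 2:
            g.add_edge(*w.cell_ids)
    if t.cells and not nx.is_connected(g):
        rep.add("template cell adjacency graph is not connected")

    return rep


# ---------------------------------------------------------------------------
# serialization

def write_template(t: RootTemplate, path) -> None:
    """Serialize a template to JSON (lossless round-trip)."""
    doc = {
        "cells": [asdict(c) for c in sorted(t.cells.values(), key=lambda c: c.id)],
        "walls": [asdict(w) for w in sorted(t.walls.values(), key=lambda w: w.id)],
        "membranes": [asdict(m) for m in
                      sorted(t.membranes.values(), key=lambda m: m.id)],
        "pd_edges": [list(e) for e in t.pd_edges],
        "mirror": t.mirror,
        "meta": t.meta,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_template(path) -> RootTemplate:
    """Parse a template JSON file; raises :class:`ParseError` on bad input."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as e:
        raise ParseError(f"{path}: malformed JSON at line {e.lineno}: {e.msg}") from e
    for key in ("cells", "walls", "membranes", "pd_edges", "mirror", "meta"):
        if key not in doc:
            raise ParseError(f"{path}: missing top-level key {key!r}")
    try:
        cells = {
            d["id"]: Cell(
                id=d["id"], cell_type=d["cell_type"], zone=d["zone"],
                side=d["side"], centroid=tuple(d["centroid"]),
                volume=d["volume"], rect=tuple(d["rect"]),
                membrane_ids=tuple(d["membrane_ids"]),
            )
            for d in doc["cells"]
        }
        walls = {
            d["id"]: Wall(
                id=d["id"], cell_ids=tuple(d["cell_ids"]), area=d["area"],
                volume=d["volume"], kind=d["kind"],
                orientation=d["orientation"], p1=tuple(d["p1"]),
                p2=tuple(d["p2"]),
            )
            for d in doc["walls"]
        }
        membranes = {
            d["id"]: Membrane(
                id=d["id"], cell_id=d["cell_id"], wall_id=d["wall_id"],
                area=d["area"], facing=d["facing"],
            )
            for d in doc["membranes"]
        }
        pd_edges = [tuple(e) for e in doc["pd_edges"]]
    except (KeyError, TypeError) as e:
        raise ParseError(f"{path}: malformed record: {e!r}") from e
    return RootTemplate(cells=cells, walls=walls, membranes=membranes,
                        pd_edges=pd_edges, mirror=dict(doc["mirror"]),
                        meta=doc["meta"])
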