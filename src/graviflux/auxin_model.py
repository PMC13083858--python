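"""Linear ODE model of auxin transport in a root-tip template.

One concentration state variable per cell and per wall (apoplast)
compartment.  The rate matrix collects, per unit membrane area, passive
background influx/efflux of auxin across the plasma membrane, AUX1-mediated
influx, PIN-mediated efflux, diffusive exchange between adjacent wall
compartments, direct cell-to-cell diffusion through plasmodesmata, and
first-order synthesis/degradation inside cells:

    dc/dt = M c + s

with M a Metzler matrix (non-negative off-diagonals), so non-negative
initial data stay non-negative.  With a closed exterior and no
synthesis/degradation the volume-weighted column sums of M vanish and the
total auxin amount Σ V·c is conserved exactly.

Concentrations are dimensionless (the model is linear, so any common scale
factor cancels in the ratios reported by the gravitropism experiments).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.integrate import solve_ivp

from .errors import AssemblyError, IntegrationError, NoSteadyStateError
from .carrier_map import CarrierMap
from .root_template import CELL_TYPES, DEPTH, RootTemplate

_JUNCTION_ROUND = 6


def default_alpha() -> dict[str, float]:
    """Default synthesis rates: elevated in the QC and columella."""
    a = {t: 1e-4 for t in CELL_TYPES}
    a["QC"] = 1e-3
    a["columella"] = 1e-3
    return a


@dataclass(frozen=True)
class ModelParams:
    """Transport parameters.  Permeabilities in µm/s, D_wall in µm²/s,
    delta in 1/s, alpha in concentration/s per cell type."""

    P_in_bg: float = 0.3
    P_out_bg: float = 0.3
    P_aux1: float = 0.5
    P_pin: float = 1.0
    D_wall: float = 30.0
    P_pd: float = 0.5
    alpha: Mapping[str, float] = field(default_factory=default_alpha)
    delta: float = 5e-4
    exterior: str = "closed"  # "closed" or "bath"
    c_ext: float = 0.0
    P_ext: float = 0.0

    def validate(self) -> None:
        for name in ("P_in_bg", "P_out_bg", "P_aux1", "P_pin", "D_wall",
                     "P_pd", "delta", "c_ext", "P_ext"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise AssemblyError(f"parameter {name} must be finite and >= 0, "
                                    f"got {v!r}")
        if self.exterior not in ("closed", "bath"):
            raise AssemblyError(f"exterior must be 'closed' or 'bath', "
                                f"got {self.exterior!r}")
        for t, v in self.alpha.items():
            if t not in CELL_TYPES:
                raise AssemblyError(f"alpha references unknown cell type {t!r}")
            if not (math.isfinite(v) and v >= 0):
                raise AssemblyError(f"alpha[{t!r}] must be finite and >= 0")


@dataclass
class ODESystem:
    """Assembled linear system dc/dt = M c + s over cells then walls."""

    index: list[str]
    M: sp.csr_matrix
    s: np.ndarray
    V: np.ndarray
    n_cells: int

    def __post_init__(self) -> None:
        self.pos = {cid: i for i, cid in enumerate(self.index)}

    @property
    def n(self) -> int:
        return len(self.index)

    def to_vector(self, f: Mapping[str, float]) -> np.ndarray:
        try:
            return np.array([f[cid] for cid in self.index], dtype=float)
        except KeyError as e:
            raise AssemblyError(f"concentration field missing compartment {e}") from e

    def to_field(self, v: np.ndarray) -> dict[str, float]:
        return {cid: float(v[i]) for i, cid in enumerate(self.index)}


@dataclass
class SimulationResult:
    """Concentrations on a time grid; ``values[k, i]`` is compartment
    ``index[i]`` at ``times[k]``."""

    times: np.ndarray
    values: np.ndarray
    index: list[str]

    def __post_init__(self) -> None:
        self.pos = {cid: i for i, cid in enumerate(self.index)}

    def field_at(self, k: int) -> dict[str, float]:
        return {cid: float(self.values[k, i]) for i, cid in enumerate(self.index)}

    def series(self, compartment_id: str) -> np.ndarray:
        return self.values[:, self.pos[compartment_id]]


def _wall_junctions(t: RootTemplate) -> list[tuple[str, str, float, float]]:
    """Pairs of wall compartments meeting at a shared segment endpoint.

    Returns (wall_a, wall_b, cross_section_area, centroid_distance) per pair.
    The junction cross-section is wall_thickness × unit depth.
    """
    by_point: dict[tuple[float, float], list[str]] = {}
    for w in t.walls.values():
        for p in (w.p1, w.p2):
            key = (round(p[0], _JUNCTION_ROUND), round(p[1], _JUNCTION_ROUND))
            by_point.setdefault(key, []).append(w.id)
    a_cross = t.wall_thickness * DEPTH
    pairs: set[tuple[str, str]] = set()
    out = []
    for wids in by_point.values():
        wids = sorted(set(wids))
        for i in range(len(wids)):
            for j in range(i + 1, len(wids)):
                key = (wids[i], wids[j])
                if key in pairs:
                    continue
                pairs.add(key)
                wa, wb = t.walls[wids[i]], t.walls[wids[j]]
                ca, cb = wa.centroid, wb.centroid
                ell = math.hypot(ca[0] - cb[0], ca[1] - cb[1])
                if ell <= 0:
                    continue
                out.append((wa.id, wb.id, a_cross, ell))
    return out


def assemble_system(t: RootTemplate, c: CarrierMap, p: ModelParams) -> ODESystem:
    """Build the sparse rate matrix and source vector for a decorated template.

    Every flux term appears exactly once; each exchange adds a matched
    (+amount into the receiver, −amount out of the donor) pair so that mass
    is conserved by construction for closed systems without turnover.
    """
    p.validate()
    cell_ids = sorted(t.cells)
    wall_ids = sorted(t.walls)
    index = cell_ids + wall_ids
    pos = {cid: i for i, cid in enumerate(index)}
    n = len(index)
    n_cells = len(cell_ids)

    V = np.empty(n)
    for cid in cell_ids:
        V[pos[cid]] = t.cells[cid].volume
    for wid in wall_ids:
        V[pos[wid]] = t.walls[wid].volume

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    s = np.zeros(n)

    def exchange(i: int, j: int, q: float) -> None:
        """Add flux q·c_j (amount/s) flowing from compartment j into i."""
        if q == 0.0:
            return
        rows.append(i); cols.append(j); vals.append(q / V[i])
        rows.append(j); cols.append(j); vals.append(-q / V[j])

    # membrane fluxes: cell <-> adjacent wall compartment
    for m in t.membranes.values():
        if m.cell_id not in t.cells or m.wall_id not in t.walls:
            raise AssemblyError(f"membrane {m.id} references unknown id")
        i = pos[m.cell_id]
        w = pos[m.wall_id]
        a_m = c.aux1.get(m.id)
        if a_m is None:
            raise AssemblyError(f"carrier map missing AUX1 entry for membrane {m.id}")
        p_m = c.pin_total(m.id)
        q_in = m.area * (p.P_in_bg + p.P_aux1 * a_m)
        q_out = m.area * (p.P_out_bg + p.P_pin * p_m)
        exchange(i, w, q_in)   # wall -> cell
        exchange(w, i, q_out)  # cell -> wall

    # plasmodesmatal fluxes: cell <-> cell through shared interior walls
    for ci, cj, wid in t.pd_edges:
        if wid not in t.walls:
            raise AssemblyError(f"pd edge references unknown wall {wid}")
        rho = c.pd.get(wid, 0.0)
        g = t.walls[wid].area * p.P_pd * rho
        i, j = pos[ci], pos[cj]
        exchange(i, j, g)
        exchange(j, i, g)

    # wall-to-wall diffusion at shared junctions
    for wa, wb, a_cross, ell in _wall_junctions(t):
        g = p.D_wall * a_cross / ell
        i, j = pos[wa], pos[wb]
        exchange(i, j, g)
        exchange(j, i, g)

    # synthesis and degradation (cells only)
    for cid in cell_ids:
        i = pos[cid]
        s[i] += float(p.alpha.get(t.cells[cid].cell_type, 0.0))
        if p.delta > 0:
            rows.append(i); cols.append(i); vals.append(-p.delta)

    # exterior bath across exterior walls
    if p.exterior == "bath" and p.P_ext > 0:
        for w in t.walls.values():
            if w.kind != "exterior":
                continue
            i = pos[w.id]
            q = w.area * p.P_ext
            rows.append(i); cols.append(i); vals.append(-q / V[i])
            s[i] += q * p.c_ext / V[i]

    M = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return ODESystem(index=index, M=M, s=s, V=V, n_cells=n_cells)


def steady_state(sys: ODESystem) -> dict[str, float]:
    """Solve M c* + s = 0 by sparse LU; raises when no unique steady state.

    The steady state exists and is unique whenever degradation or an
    exterior bath provides a sink; a closed system without turnover is
    singular (its mass is a conserved quantity).
    """
    try:
        lu = spla.splu(sys.M.tocsc())
        cstar = lu.solve(-sys.s)
    except RuntimeError as e:
        raise NoSteadyStateError(f"rate matrix is singular: {e}") from e
    if not np.all(np.isfinite(cstar)):
        raise NoSteadyStateError("rate matrix is singular (non-finite solution)")
    resid = sys.M @ cstar + sys.s
    scale = max(1.0, float(np.abs(cstar).max()))
    if float(np.abs(resid).max()) > 1e-8 * scale:
        raise NoSteadyStateError("steady-state residual exceeds tolerance; "
                                 "system is (near-)singular")
    floor = -1e-9 * scale
    if float(cstar.min()) < floor:
        raise NoSteadyStateError("steady state has a significantly negative "
                                 "concentration; check parameters")
    return sys.to_field(np.maximum(cstar, 0.0))


def integrate(sys: ODESystem, c0: Mapping[str, float] | np.ndarray,
              times: Sequence[float], rtol: float = 1e-8,
              atol: float = 1e-12) -> SimulationResult:
    """Integrate the linear system over the given time grid (BDF).

    ``times`` must be strictly increasing and start at 0; the initial field
    is reported unchanged at t = 0.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 1 or times[0] != 0.0:
        raise IntegrationError("times must start at 0")
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise IntegrationError("times must be strictly increasing")
    y0 = c0 if isinstance(c0, np.ndarray) else sys.to_vector(c0)
    if np.any(y0 < 0):
        raise IntegrationError("initial concentrations must be non-negative")
    if times.size == 1:
        return SimulationResult(times=times, values=y0[None, :].copy(),
                                index=list(sys.index))
    M = sys.M
    s = sys.s

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        return M @ y + s

    sol = solve_ivp(rhs, (0.0, float(times[-1])), y0, method="BDF",
                    t_eval=times, jac=M, rtol=rtol, atol=atol)
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}")
    values = sol.y.T.copy()
    # tiny negative undershoot from the implicit solver is numerical noise
    floor = -1e-6 * max(1.0, float(np.abs(values).max()))
    if float(values.min()) < floor:
        raise IntegrationError("integration produced significantly negative "
                               "concentrations")
    np.maximum(values, 0.0, out=values)
    return SimulationResult(times=times, values=values, index=list(sys.index))


def total_mass(sys: ODESystem, f: Mapping[str, float] | np.ndarray) -> float:
    """Total auxin amount Σ V·c over all compartments (µm³ · conc)."""
    v = f if isinstance(f, np.ndarray) else sys.to_vector(f)
    return float(np.dot(sys.V, v))
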