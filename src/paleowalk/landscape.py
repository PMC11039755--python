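"""Landscape evolution under precipitation and sea-level forcing.

The elevation field evolves by the continuity of mass

    dz/dt = U + kappa * laplacian(z) + eps * P**d * (P*A)**m * S**n

with U a uniform uplift rate (0 by default for a tectonically quiescent
continent), kappa a hillslope diffusion coefficient, and the last term the
stream power law (SPL): detachment-limited river incision scaling with the
water flux P*A (local precipitation P integrated over the upstream area A)
and the steepest downslope gradient S.  The exponent d scales erodibility
with local precipitation (weathering enhancement).

Water and sediment are routed with a multiple-flow-direction (MFD) scheme:
each cell's outflow is split among all strictly lower D8 neighbours with
weights proportional to slope.  Pits are retained as endorheic sinks; eroded
sediment is deposited at the first lake or ocean cell reached along the
steepest-descent path.  Time stepping is explicit forward Euler with a
CFL-style stability check.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError
from .grids import D8_OFFSETS, ElevationGrid, GridGeometry
from .synthetic_world import ClimateSeries

_OFF = D8_OFFSETS
_DIST = np.array([np.sqrt(2.0), 1.0, np.sqrt(2.0), 1.0, 1.0, np.sqrt(2.0), 1.0, np.sqrt(2.0)])


@dataclass
class ErosionParams:
    """Parameters of the mass-continuity equation.

    Units: ``U`` m/yr; ``kappa`` m²/yr; ``epsilon`` consistent with m and the
    choice of ``m_exp`` (erosion in m/yr when multiplied by P^d (PA)^m S^n
    with PA in m³/yr); ``dt`` yr.
    """

    U: float = 0.0
    kappa: float = 0.1
    epsilon: float = 1.0e-7
    m_exp: float = 0.5
    n_exp: float = 1.0
    d_exp: float = 0.42
    dt: float = 1000.0

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.epsilon < 0:
            raise InvalidInputError("kappa and epsilon must be non-negative")
        if self.m_exp <= 0 or self.n_exp <= 0 or self.d_exp <= 0:
            raise InvalidInputError("m_exp, n_exp, d_exp must be positive")
        if self.dt <= 0:
            raise InvalidInputError("dt must be positive")


@dataclass
class FlowField:
    """MFD routing products on one elevation snapshot.

    ``discharge`` is the water flux P*A in m³/yr (local precipitation input
    plus all upstream inflow), ``upstream_area`` in m², ``flow_fractions`` the
    (n_cells, 8) downslope partition weights in D8 order (rows sum to 1 for
    routed cells, 0 for sinks/ocean), ``receiver`` the steepest-descent D8
    neighbour (-1 for sinks), ``basin_id`` the label of the terminal sink or
    coastal outlet each cell drains to (0 for ocean cells themselves).
    """

    geometry: GridGeometry
    discharge: np.ndarray
    upstream_area: np.ndarray
    flow_fractions: np.ndarray = field(repr=False)
    receiver: np.ndarray = field(repr=False)
    basin_id: np.ndarray = field(repr=False)
    slope: np.ndarray = field(repr=False)
    sink_mask: np.ndarray = field(repr=False)
    ocean_mask: np.ndarray = field(repr=False)


@dataclass
class LandscapeState:
    """One landscape snapshot: elevation plus derived hydrology and rates."""

    elevation: ElevationGrid
    flow: FlowField
    erosion_rate: np.ndarray  # m/yr, >= 0 (applied as surface lowering)
    deposition_rate: np.ndarray  # m/yr
    lake_mask: np.ndarray
    ocean_mask: np.ndarray
    sea_level: float
    time: float  # ka before present
    cumulative_erosion: np.ndarray | None = None  # m, since run start
    cumulative_deposition: np.ndarray | None = None


@njit(cache=False)
def _accumulate(z, order, ocean, precip_m_yr, cell_area_m2, dx_m, off, dist):
    ny, nx = z.shape
    ncell = ny * nx
    discharge = np.zeros(ncell)
    area = np.zeros(ncell)
    frac = np.zeros((ncell, 8))
    receiver = np.full(ncell, -1, np.int64)
    slope = np.zeros(ncell)
    for idx in range(ncell):
        c = order[idx]
        r = c // nx
        col = c % nx
        if ocean[r, col]:
            continue
        discharge[c] += precip_m_yr[r, col] * cell_area_m2
        area[c] += cell_area_m2
        ssum = 0.0
        best = 0.0
        brec = -1
        slopes = np.zeros(8)
        for k in range(8):
            rr = r + off[k, 0]
            cc = col + off[k, 1]
            if rr < 0 or rr >= ny or cc < 0 or cc >= nx:
                continue
            dz = z[r, col] - z[rr, cc]
            if dz > 0.0:
                s = dz / (dx_m * dist[k])
                slopes[k] = s
                ssum += s
                if s > best:
                    best = s
                    brec = rr * nx + cc
        receiver[c] = brec
        slope[c] = best
        if ssum > 0.0:
            for k in range(8):
                if slopes[k] > 0.0:
                    f = slopes[k] / ssum
                    frac[c, k] = f
                    rr = r + off[k, 0]
                    cc = col + off[k, 1]
                    n = rr * nx + cc
                    discharge[n] += f * discharge[c]
                    area[n] += f * area[c]
    return discharge, area, frac, receiver, slope


@njit(cache=False)
def _route_sediment(order, receiver, erosion_flux, ocean_flat, lake_flat):
    """Push eroded flux down the steepest-descent path; deposit at the first
    lake/ocean cell reached or at endorheic sinks."""
    ncell = order.shape[0]
    influx = np.zeros(ncell)
    deposit = np.zeros(ncell)
    for idx in range(ncell):
        c = order[idx]
        total = influx[c] + erosion_flux[c]
        if total == 0.0:
            continue
        if ocean_flat[c] or lake_flat[c] or receiver[c] < 0:
            deposit[c] += total
        else:
            influx[receiver[c]] += total
    return deposit


def _elevation_order(z: np.ndarray) -> np.ndarray:
    """Flat indices in decreasing elevation; ties broken by row-major index."""
    return np.argsort(-z.ravel(), kind="stable")


def route_flow(elev: ElevationGrid, precip: np.ndarray, sea_level: float) -> FlowField:
    """Route water over a DEM with slope-proportional MFD partitioning.

    Cells are processed in decreasing elevation order; each land cell's
    discharge (local precipitation input plus inflow) is split among its
    strictly lower D8 neighbours with weights proportional to slope.  Ocean
    cells (z below ``sea_level``) only receive; land cells with no lower
    neighbour are endorheic sinks.
    """
    precip = np.asarray(precip, dtype=np.float64)
    if precip.shape != elev.geometry.shape:
        raise InvalidInputError("precipitation raster does not match DEM geometry")
    if np.any(precip < 0):
        raise InvalidInputError("precipitation must be non-negative")
    geom = elev.geometry
    z = elev.z
    ocean = z < sea_level
    order = _elevation_order(z)
    dx_m = geom.cell_size * 1000.0
    cell_area_m2 = dx_m * dx_m
    discharge, area, frac, receiver, slope = _accumulate(
        z, order, ocean, precip, cell_area_m2, dx_m, _OFF, _DIST
    )
    sink = (receiver < 0).reshape(geom.shape) & ~ocean
    basin = _label_basins(z, order, receiver, ocean)
    return FlowField(
        geometry=geom,
        discharge=discharge.reshape(geom.shape),
        upstream_area=area.reshape(geom.shape),
        flow_fractions=frac,
        receiver=receiver,
        basin_id=basin,
        slope=slope.reshape(geom.shape),
        sink_mask=sink,
        ocean_mask=ocean,
    )


def _label_basins(z: np.ndarray, order: np.ndarray, receiver: np.ndarray, ocean: np.ndarray) -> np.ndarray:
    """Label cells by terminal endorheic sink or coastal outlet (ocean = 0)."""
    ny, nx = z.shape
    basin = np.zeros(ny * nx, dtype=np.int64)
    ocean_flat = ocean.ravel()
    next_id = 1
    # Increasing elevation: a cell's receiver is always processed first.
    for c in order[::-1]:
        if ocean_flat[c]:
            continue
        rec = receiver[c]
        if rec < 0 or ocean_flat[rec]:
            basin[c] = next_id  # endorheic sink or coastal outlet
            next_id += 1
        else:
            basin[c] = basin[rec]
    return basin.reshape(ny, nx)


def fill_elevation(elev: ElevationGrid, sea_level: float) -> np.ndarray:
    """Depression-filled surface via priority flood seeded at the ocean and
    the grid boundary.  Cells where the filled surface exceeds z lie inside a
    closed basin below its spill elevation."""
    z = elev.z
    ny, nx = z.shape
    ocean = z < sea_level
    fill = np.full_like(z, np.inf)
    visited = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    for r in range(ny):
        for c in range(nx):
            if ocean[r, c] or r == 0 or r == ny - 1 or c == 0 or c == nx - 1:
                fill[r, c] = z[r, c]
                visited[r, c] = True
                heapq.heappush(heap, (z[r, c], r, c))
    while heap:
        f, r, c = heapq.heappop(heap)
        for dr, dc in _OFF:
            rr, cc = r + dr, c + dc
            if 0 <= rr < ny and 0 <= cc < nx and not visited[rr, cc]:
                visited[rr, cc] = True
                fill[rr, cc] = max(z[rr, cc], f)
                heapq.heappush(heap, (fill[rr, cc], rr, cc))
    return fill


def detect_lakes(elev: ElevationGrid, flow: FlowField, sea_level: float) -> np.ndarray:
    """Mask of lake cells: inside a closed basin, below its spill elevation,
    and above sea level (submarine depressions belong to the ocean)."""
    fill = fill_elevation(elev, sea_level)
    ocean = elev.z < sea_level
    return (fill > elev.z + 1e-9) & ~ocean


def make_state(
    elev: ElevationGrid, precip: np.ndarray, sea_level: float, time: float
) -> LandscapeState:
    """Assemble a full landscape state (hydrology, lakes) at one instant."""
    flow = route_flow(elev, precip, sea_level)
    lakes = detect_lakes(elev, flow, sea_level)
    zeros = np.zeros(elev.geometry.shape)
    return LandscapeState(
        elevation=elev,
        flow=flow,
        erosion_rate=zeros,
        deposition_rate=zeros.copy(),
        lake_mask=lakes,
        ocean_mask=flow.ocean_mask,
        sea_level=sea_level,
        time=time,
    )


def stable_dt(params: ErosionParams, precip: np.ndarray, flow: FlowField, dx_m: float) -> float:
    """CFL-style upper bound on the explicit time step (yr)."""
    bounds = [np.inf]
    if params.kappa > 0:
        bounds.append(dx_m * dx_m / (4.0 * params.kappa))
    land = ~flow.ocean_mask
    if params.epsilon > 0 and np.any(land):
        s = flow.slope[land]
        v = (
            params.epsilon
            * np.power(np.maximum(precip[land], 0.0), params.d_exp)
            * np.power(flow.discharge[land], params.m_exp)
            * np.power(np.maximum(s, 1e-12), params.n_exp - 1.0)
        )
        vmax = v.max()
        if vmax > 0:
            bounds.append(dx_m / vmax)
    return 0.5 * min(bounds)


def evolve_step(state: LandscapeState, precip: np.ndarray, params: ErosionParams) -> LandscapeState:
    """Advance the landscape by one explicit step of the continuity equation.

    The SPL term erodes land cells with positive steepest slope; eroded
    sediment is routed downstream and deposited at the first lake/ocean cell
    (or the endorheic sink) reached.  Ocean-cell elevations change only by
    deposition.  Raises :class:`ConfigurationError` when ``params.dt``
    violates the stability bound.
    """
    geom = state.elevation.geometry
    dx_m = geom.cell_size * 1000.0
    precip = np.asarray(precip, dtype=np.float64)
    flow = route_flow(state.elevation, precip, state.sea_level)
    lakes = detect_lakes(state.elevation, flow, state.sea_level)

    dt_max = stable_dt(params, precip, flow, dx_m)
    if params.dt > dt_max:
        raise ConfigurationError(
            f"dt={params.dt} yr exceeds the stability bound {dt_max:.1f} yr"
        )

    land = ~flow.ocean_mask
    erodible = land & ~lakes
    erosion = np.zeros(geom.shape)
    erosion[erodible] = (
        params.epsilon
        * np.power(precip[erodible], params.d_exp)
        * np.power(flow.discharge[erodible], params.m_exp)
        * np.power(flow.slope[erodible], params.n_exp)
    )

    cell_area_m2 = dx_m * dx_m
    order = _elevation_order(state.elevation.z)
    deposit_flux = _route_sediment(
        order,
        flow.receiver,
        (erosion * cell_area_m2).ravel(),
        flow.ocean_mask.ravel(),
        lakes.ravel(),
    )
    deposition = (deposit_flux / cell_area_m2).reshape(geom.shape)

    z_new = state.elevation.z.copy()
    if params.kappa > 0:
        lap = ndimage.laplace(state.elevation.z, mode="nearest") / (dx_m * dx_m)
        z_new[land] += params.dt * params.kappa * lap[land]
    z_new[land] += params.dt * params.U
    z_new -= params.dt * erosion
    z_new += params.dt * deposition

    new_elev = ElevationGrid(geom, z_new)
    new_time = state.time - params.dt / 1000.0
    out = make_state(new_elev, precip, state.sea_level, new_time)
    out.erosion_rate = erosion
    out.deposition_rate = deposition
    return out


def run_history(
    dem: ElevationGrid,
    climate: ClimateSeries,
    params: ErosionParams,
    snapshot_interval: float = 1000.0,
) -> list[LandscapeState]:
    """Run a forward simulation across the climate series, holding forcing
    from the nearest earlier slice and snapshotting every
    ``snapshot_interval`` years (cumulative erosion/deposition tracked for
    the prospecting stage)."""
    if climate.n_slices < 1:
        raise InvalidInputError("empty climate series")
    if snapshot_interval < params.dt or snapshot_interval % params.dt != 0:
        raise InvalidInputError("snapshot_interval must be a multiple of dt")
    t_start, t_end = climate.slice_times[0], climate.slice_times[-1]
    n_steps = int(round((t_start - t_end) * 1000.0 / params.dt))
    steps_per_snap = int(round(snapshot_interval / params.dt))

    idx0 = climate.slice_at(t_start)
    state = make_state(dem.copy(), climate.precipitation[idx0], float(climate.sea_level[idx0]), t_start)
    cum_ero = np.zeros(dem.geometry.shape)
    cum_dep = np.zeros(dem.geometry.shape)
    state.cumulative_erosion = cum_ero.copy()
    state.cumulative_deposition = cum_dep.copy()
    snapshots = [state]

    for step in range(1, n_steps + 1):
        t = t_start - (step - 1) * params.dt / 1000.0
        idx = climate.slice_at(t)
        state.sea_level = float(climate.sea_level[idx])
        state = evolve_step(state, climate.precipitation[idx], params)
        cum_ero += state.erosion_rate * params.dt
        cum_dep += state.deposition_rate * params.dt
        if step % steps_per_snap == 0:
            state.cumulative_erosion = cum_ero.copy()
            state.cumulative_deposition = cum_dep.copy()
            snapshots.append(state)
    return snapshots


def water_balance(flow: FlowField, precip: np.ndarray) -> tuple[float, float]:
    """(total land input, flux delivered to ocean + accumulated in sinks), m³/yr."""
    geom = flow.geometry
    cell_area_m2 = (geom.cell_size * 1000.0) ** 2
    land = ~flow.ocean_mask
    total_in = float(np.sum(precip[land]) * cell_area_m2)
    total_out = float(np.sum(flow.discharge[flow.ocean_mask]) + np.sum(flow.discharge[flow.sink_mask]))
    return total_in, total_out


def mean_denudation_rate(snapshots: list[LandscapeState]) -> float:
    """Land-mean erosion rate (m/yr) averaged over post-initial snapshots."""
    rates = []
    for s in snapshots[1:]:
        land = ~s.ocean_mask
        if np.any(land):
            rates.append(float(np.mean(s.erosion_rate[land])))
    return float(np.mean(rates)) if rates else 0.0
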