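"""Physiographic resistance surfaces.

Each landscape snapshot is reduced to four normalised layers that score how
strongly terrain impedes foot travel:

* a **slope index** — steepest-descent gradient magnitude normalised by the
  land-wide maximum;
* a **physiographic diversity** index — Shannon–Weaver diversity of pooled
  categorical morphometrics (slope, water flux, standardised topographic
  position), normalised by ln(C) to Shannon equitability in [0, 1]; diverse
  landscapes are attractive, so the layer enters the cost as 1 − P_DIV;
* an **environmental index** encoding hard barriers (ocean, endorheic lakes),
  river-crossing costs that grow with discharge, low-cost travel corridors
  along rivers, and high cost for arid flat country;
* optionally **1 − NPP**, penalising low ecological carrying capacity.

The topographic position index TPI_i = z_i − mean(z_k over an annulus) is
computed at a fine and a coarse scale and standardised
(TPI_S = 100 · (TPI − mean)/sd) so the two scales are comparable.  The final
cost is the per-pixel maximum of the layers, with coastal and river-corridor
cells overridden downward and barriers pinned at 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InvalidInputError
from .grids import SECONDS_PER_YEAR, ElevationGrid, GridGeometry
from .landscape import FlowField, LandscapeState


@dataclass
class DiversityConfig:
    """Neighbourhood setup for TPI and the diversity index (lengths in km).

    The default annuli are the km equivalents of 0.02°–0.05° (fine) and
    0.1°–0.15° (coarse) at ~1 km per 0.01°.
    """

    C: int = 3
    neighbourhood_radius: float = 5.0
    fine_annulus: tuple[float, float] = (2.0, 5.0)
    coarse_annulus: tuple[float, float] = (10.0, 15.0)

    def __post_init__(self) -> None:
        if self.C < 1:
            raise InvalidInputError("C must be >= 1")
        for inner, outer in (self.fine_annulus, self.coarse_annulus):
            if not inner < outer:
                raise InvalidInputError("annulus inner radius must be below outer")


@dataclass
class EnvironmentalConfig:
    """Thresholds of the environmental index (discharge in m³/s)."""

    major_river_discharge: float = 80.0
    crossing_cost_range: tuple[float, float] = (0.7, 0.95)
    corridor_min_discharge: float = 8.0
    corridor_cost: float = 0.2
    arid_cost: float = 0.92
    arid_precip_quantile: float = 0.25
    arid_npp_quantile: float = 0.25
    arid_slope_threshold: float = 0.05
    coastal_band_width: int = 1


@dataclass
class MorphometricLayers:
    """Continuous and categorical morphometrics of one snapshot."""

    geometry: GridGeometry
    slope_index: np.ndarray
    tpi_fine: np.ndarray = field(repr=False)
    tpi_coarse: np.ndarray = field(repr=False)
    tpi_s_fine: np.ndarray = field(repr=False)
    tpi_s_coarse: np.ndarray = field(repr=False)
    slope_cats: np.ndarray = field(repr=False)
    flux_cats: np.ndarray = field(repr=False)
    tpi_cats: np.ndarray = field(repr=False)
    p_div: np.ndarray = field(repr=False)


@dataclass
class ResistanceMap:
    """Normalised [0, 1] cost-to-move raster valid over a time interval (ka).

    Cells with cost >= ``barrier_threshold`` are impassable (ocean, lakes).
    """

    geometry: GridGeometry
    cost: np.ndarray
    valid_from: float = np.inf
    valid_to: float = -np.inf
    barrier_threshold: float = 1.0

    def __post_init__(self) -> None:
        self.cost = np.asarray(self.cost, dtype=np.float64)
        if self.cost.shape != self.geometry.shape:
            raise InvalidInputError("cost raster does not match geometry")
        if self.cost.min() < 0 or self.cost.max() > 1:
            raise InvalidInputError("costs must lie within [0, 1]")

    @property
    def barrier_mask(self) -> np.ndarray:
        return self.cost >= self.barrier_threshold


def slope_index(elev: ElevationGrid, land_mask: np.ndarray | None = None) -> np.ndarray:
    """Steepest-descent gradient magnitude normalised to [0, 1] by the
    (land-wide) maximum; an all-flat grid yields zeros."""
    dx_m = elev.geometry.cell_size * 1000.0
    z = elev.z
    raw = np.zeros_like(z)
    for (dr, dc), dist in zip(
        [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
        [np.sqrt(2), 1, np.sqrt(2), 1, 1, np.sqrt(2), 1, np.sqrt(2)],
    ):
        shifted = np.full_like(z, np.inf)
        rs = slice(max(dr, 0), z.shape[0] + min(dr, 0))
        cs = slice(max(dc, 0), z.shape[1] + min(dc, 0))
        rd = slice(max(-dr, 0), z.shape[0] + min(-dr, 0))
        cd = slice(max(-dc, 0), z.shape[1] + min(-dc, 0))
        shifted[rd, cd] = z[rs, cs]
        drop = (z - shifted) / (dx_m * dist)
        raw = np.maximum(raw, np.where(np.isfinite(drop), drop, 0.0))
    raw = np.maximum(raw, 0.0)
    norm = raw[land_mask].max() if land_mask is not None and np.any(land_mask) else raw.max()
    return raw / norm if norm > 0 else raw


def _annulus_kernel(annulus: tuple[float, float], cell_size: float) -> np.ndarray:
    inner, outer = annulus
    if outer < cell_size:
        raise ConfigurationError("annulus outer radius must span at least one cell")
    half = int(np.ceil(outer / cell_size))
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    dist = np.hypot(yy, xx) * cell_size
    kernel = (dist >= inner) & (dist <= outer) & (dist > 0)
    if not kernel.any():
        raise ConfigurationError(f"annulus {annulus} contains no cells at {cell_size} km resolution")
    return kernel.astype(np.float64)


def topographic_position(elev: ElevationGrid, annulus: tuple[float, float]) -> np.ndarray:
    """TPI_i = z_i − mean(z_k) over an annular neighbourhood (radii in km);
    edge cells average over the available neighbours only."""
    kernel = _annulus_kernel(annulus, elev.geometry.cell_size)
    zsum = ndimage.convolve(elev.z, kernel, mode="constant", cval=0.0)
    counts = ndimage.convolve(np.ones_like(elev.z), kernel, mode="constant", cval=0.0)
    mean = np.divide(zsum, counts, out=np.zeros_like(zsum), where=counts > 0)
    return elev.z - mean


def standardize_tpi(tpi: np.ndarray) -> np.ndarray:
    """Rescale a TPI raster to grid-wide mean 0 and standard deviation 100."""
    sd = tpi.std()
    if sd == 0:
        warnings.warn("TPI raster has zero variance; standardised output is all zero")
        return np.zeros_like(tpi)
    return 100.0 * (tpi - tpi.mean()) / sd


def _quantile_labels(values: np.ndarray, k: int, train_mask: np.ndarray | None = None) -> np.ndarray:
    """Equal-frequency class labels in 1..k (edges fitted on ``train_mask``)."""
    train = values[train_mask] if train_mask is not None else values.ravel()
    edges = np.quantile(train, np.linspace(0, 1, k + 1))[1:-1]
    return (np.searchsorted(edges, values, side="right") + 1).astype(np.int64)


def categorize(
    slope_idx: np.ndarray,
    discharge: np.ndarray,
    tpi_s: np.ndarray,
    land_mask: np.ndarray | None = None,
    n_slope: int = 7,
    n_flux: int = 5,
    n_tpi: int = 10,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Quantile-binned categorical rasters: 7 slope, 5 water-flux and 10
    TPI_S classes (class edges fitted over land cells when a mask is given)."""
    return (
        _quantile_labels(slope_idx, n_slope, land_mask),
        _quantile_labels(discharge, n_flux, land_mask),
        _quantile_labels(tpi_s, n_tpi, land_mask),
    )


def physiographic_diversity(
    cats: tuple[np.ndarray, np.ndarray, np.ndarray],
    cfg: DiversityConfig | None = None,
    cell_size: float = 1.0,
) -> np.ndarray:
    """Shannon equitability of pooled categorical observations.

    Within a disk neighbourhood, p_k is the proportion of observations of
    pooled type k across the C categorical layers; the Shannon–Weaver index
    d_SW = −Σ p_k ln p_k is normalised by ln(C) and clipped to [0, 1] (with
    more than C pooled types the printed normalisation can exceed 1).
    Cells with an empty neighbourhood get 0.
    """
    cfg = cfg or DiversityConfig()
    half = max(int(np.ceil(cfg.neighbourhood_radius / cell_size)), 1)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1]
    disk = (np.hypot(yy, xx) * cell_size <= cfg.neighbourhood_radius).astype(np.float64)

    shape = cats[0].shape
    layers = [np.asarray(layer) for layer in cats]
    pooled_values = np.unique(np.concatenate([np.unique(layer) for layer in layers]))
    total = np.zeros(shape)
    counts: list[np.ndarray] = []
    for value in pooled_values:
        ind = np.zeros(shape)
        for layer in layers:
            ind += layer == value
        c = ndimage.convolve(ind, disk, mode="constant", cval=0.0)
        counts.append(c)
        total += c
    d_sw = np.zeros(shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        for c in counts:
            p = np.divide(c, total, out=np.zeros(shape), where=total > 0)
            d_sw -= np.where(p > 0, p * np.log(p), 0.0)
    p_div = np.where(total > 0, d_sw / np.log(cfg.C), 0.0)
    return np.clip(p_div, 0.0, 1.0)


def coastal_mask(ocean_mask: np.ndarray, width: int = 1) -> np.ndarray:
    """Land cells within ``width`` cells of the ocean."""
    grown = ndimage.binary_dilation(ocean_mask, iterations=width)
    return grown & ~ocean_mask


def river_masks(
    flow: FlowField, cfg: EnvironmentalConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(river, major-river, corridor) masks from discharge in m³/s.

    The corridor is the band of land cells adjacent to river cells above the
    minimum corridor discharge — the banks, along which travel is cheap —
    excluding the channel cells themselves, which keep their discharge-scaled
    crossing cost.
    """
    q_cms = flow.discharge / SECONDS_PER_YEAR
    land = ~flow.ocean_mask
    river = (q_cms > cfg.corridor_min_discharge) & land
    major = (q_cms > cfg.major_river_discharge) & land
    corridor = ndimage.binary_dilation(river) & land & ~river
    return river, major, corridor


def environmental_index(
    flow: FlowField,
    lake_mask: np.ndarray,
    ocean_mask: np.ndarray,
    precip: np.ndarray,
    npp: np.ndarray,
    slope_idx: np.ndarray,
    cfg: EnvironmentalConfig | None = None,
) -> np.ndarray:
    """Barrier/river/aridity cost layer.

    Ocean and endorheic-lake cells cost 1 (dispersal barriers).  Major rivers
    (> 80 m³/s) are strong but not impermeable barriers: crossing cost grows
    linearly from 0.7 at the threshold to 0.95 at the land-wide maximum
    discharge.  Modest rivers scale linearly 0 → 0.7 with discharge.  Cells
    adjacent to rivers (the banks) carry the low along-river corridor cost.
    Arid flat cells — jointly below the precipitation and NPP
    quantile thresholds and below the slope threshold — cost 0.92.
    """
    cfg = cfg or EnvironmentalConfig()
    q_cms = flow.discharge / SECONDS_PER_YEAR
    land = ~ocean_mask
    env = np.zeros(flow.geometry.shape)

    lo, hi = cfg.crossing_cost_range
    q_major = cfg.major_river_discharge
    # Modest rivers: crossing cost ramps 0 -> lo with discharge.
    env[land] = lo * np.minimum(q_cms[land], q_major) / q_major
    # Major rivers: lo at the threshold up to hi at the land-wide maximum.
    major = (q_cms > q_major) & land
    if np.any(major):
        q_max = q_cms[land].max()
        span = max(q_max - q_major, 1e-12)
        env[major] = lo + (hi - lo) * (q_cms[major] - q_major) / span

    river, _, corridor = river_masks(flow, cfg)
    env[corridor] = cfg.corridor_cost

    if np.any(land):
        p_thr = np.quantile(precip[land], cfg.arid_precip_quantile)
        n_thr = np.quantile(npp[land], cfg.arid_npp_quantile)
        arid = land & (precip < p_thr) & (npp < n_thr) & (slope_idx < cfg.arid_slope_threshold)
        env[arid] = np.maximum(env[arid], cfg.arid_cost)

    env[ocean_mask] = 1.0
    env[lake_mask & land] = 1.0
    return env


def compute_morphometrics(
    state: LandscapeState, cfg: DiversityConfig | None = None
) -> MorphometricLayers:
    """Derive every morphometric layer from one landscape snapshot.

    The categorical TPI uses the mean of the fine and coarse standardised
    rasters so both observation scales inform the landform classes.
    """
    cfg = cfg or DiversityConfig()
    elev = state.elevation
    land = ~state.ocean_mask
    s_idx = slope_index(elev, land_mask=land)
    tpi_f = topographic_position(elev, cfg.fine_annulus)
    tpi_c = topographic_position(elev, cfg.coarse_annulus)
    tpi_sf = standardize_tpi(tpi_f)
    tpi_sc = standardize_tpi(tpi_c)
    tpi_s = 0.5 * (tpi_sf + tpi_sc)
    slope_cats, flux_cats, tpi_cats = categorize(
        s_idx, state.flow.discharge, tpi_s, land_mask=land
    )
    p_div = physiographic_diversity(
        (slope_cats, flux_cats, tpi_cats), cfg, cell_size=elev.geometry.cell_size
    )
    return MorphometricLayers(
        geometry=elev.geometry,
        slope_index=s_idx,
        tpi_fine=tpi_f,
        tpi_coarse=tpi_c,
        tpi_s_fine=tpi_sf,
        tpi_s_coarse=tpi_sc,
        slope_cats=slope_cats,
        flux_cats=flux_cats,
        tpi_cats=tpi_cats,
        p_div=p_div,
    )


def build_resistance(
    layers: MorphometricLayers,
    env: np.ndarray,
    npp: np.ndarray,
    coast_mask: np.ndarray,
    corridor_mask: np.ndarray,
    barrier_mask: np.ndarray | None = None,
    major_river_mask: np.ndarray | None = None,
    corridor_cost: float = 0.2,
    npp_as_layer: bool = True,
    valid_from: float = np.inf,
    valid_to: float = -np.inf,
) -> ResistanceMap:
    """Combine the layers into the final resistance map.

    cost = per-pixel max over {slope index, 1 − P_DIV, environmental index,
    1 − NPP}; coastal and river-corridor cells are then lowered to the
    corridor cost unless they are barriers; barrier cells (ocean/lakes, at
    env = 1) and major-river crossing cells retain their environmental-index
    values.  Output clipped to [0, 1].
    """
    stack = [layers.slope_index, 1.0 - layers.p_div, env]
    if npp_as_layer:
        stack.append(1.0 - npp)
    for layer in stack:
        if layer.shape != layers.geometry.shape:
            raise InvalidInputError("resistance layers share one geometry")
    cost = np.maximum.reduce(stack)

    if barrier_mask is None:
        barrier_mask = env >= 1.0
    if major_river_mask is not None:
        cost[major_river_mask] = env[major_river_mask]
        barrier_like = barrier_mask | major_river_mask
    else:
        barrier_like = barrier_mask
    override = (coast_mask | corridor_mask) & ~barrier_like
    cost[override] = np.minimum(cost[override], corridor_cost)
    cost[barrier_mask] = 1.0
    return ResistanceMap(
        geometry=layers.geometry,
        cost=np.clip(cost, 0.0, 1.0),
        valid_from=valid_from,
        valid_to=valid_to,
    )


def resistance_stack(
    snapshots: list[LandscapeState],
    climate,
    div_cfg: DiversityConfig | None = None,
    env_cfg: EnvironmentalConfig | None = None,
    npp_as_layer: bool = True,
) -> list[ResistanceMap]:
    """One resistance map per landscape snapshot, stamped with its validity
    interval (from its snapshot time to the next snapshot's)."""
    env_cfg = env_cfg or EnvironmentalConfig()
    maps: list[ResistanceMap] = []
    for i, snap in enumerate(snapshots):
        idx = climate.slice_at(snap.time)
        npp = climate.npp[idx]
        precip = climate.precipitation[idx]
        layers = compute_morphometrics(snap, div_cfg)
        env = environmental_index(
            snap.flow, snap.lake_mask, snap.ocean_mask, precip, npp,
            layers.slope_index, env_cfg,
        )
        _, major, corridor = river_masks(snap.flow, env_cfg)
        coast = coastal_mask(snap.ocean_mask, env_cfg.coastal_band_width)
        barrier = snap.ocean_mask | (snap.lake_mask & ~snap.ocean_mask)
        rmap = build_resistance(
            layers, env, npp, coast, corridor,
            barrier_mask=barrier,
            major_river_mask=major,
            corridor_cost=env_cfg.corridor_cost,
            npp_as_layer=npp_as_layer,
            valid_from=snap.time,
            valid_to=snapshots[i + 1].time if i + 1 < len(snapshots) else snap.time,
        )
        maps.append(rmap)
    return maps
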