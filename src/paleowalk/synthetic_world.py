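"""Synthetic paleo-worlds: terrain, climate forcing, sea level, NPP and sites.

The real study system — a late-Pleistocene continental landmass whose shelf is
exposed at lowered sea level, forced by slowly varying precipitation fields —
relies on external reconstructions that are not redistributable.  This module
generates stand-ins with the statistical structure the downstream stages
assume: a continental platform with a shelf lying between the lowest and
highest sea stands, spectrally synthesised interior relief with an endorheic
depression, spatially smooth and temporally autocorrelated precipitation,
net primary productivity (NPP) increasing monotonically with precipitation,
and dated site tables.  Everything is bit-deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError
from .grids import ElevationGrid, GridGeometry

#: Default sea-level anchors, m relative to present: the run starts with the
#: coastline at the −68 m isobath, deepens to a −85 m lowstand a quarter of
#: the way through (65 ka for the default 75–35 ka window), then recovers by
#: ~25 m to −60 m at the end.
SEA_LEVEL_START = -68.0
SEA_LEVEL_LOWSTAND = -85.0
SEA_LEVEL_END = -60.0


@dataclass
class ClimateSeries:
    """Per-slice climate forcing shared by the landscape and resistance stages.

    ``slice_times`` are epochs in ka before present, strictly decreasing
    toward the present.  Precipitation is in m/yr, sea level in m relative to
    present, NPP normalised to [0, 1].
    """

    geometry: GridGeometry
    slice_times: np.ndarray
    precipitation: np.ndarray  # (n_slices, n_rows, n_cols), m/yr
    sea_level: np.ndarray  # (n_slices,), m
    npp: np.ndarray  # (n_slices, n_rows, n_cols), [0, 1]

    def __post_init__(self) -> None:
        self.slice_times = np.asarray(self.slice_times, dtype=np.float64)
        if self.slice_times.ndim != 1 or len(self.slice_times) < 2:
            raise InvalidInputError("climate series needs at least 2 slices")
        if not np.all(np.diff(self.slice_times) < 0):
            raise InvalidInputError("slice_times must strictly decrease toward present")
        for name, arr in (("precipitation", self.precipitation), ("npp", self.npp)):
            if arr.shape != (len(self.slice_times), *self.geometry.shape):
                raise InvalidInputError(f"{name} shape {arr.shape} inconsistent with geometry")
        if np.any(self.precipitation < 0):
            raise InvalidInputError("precipitation must be non-negative")

    @property
    def n_slices(self) -> int:
        return len(self.slice_times)

    def slice_at(self, time_ka: float) -> int:
        """Index of the nearest slice at or before ``time_ka`` (held forcing)."""
        idx = np.nonzero(self.slice_times >= time_ka - 1e-9)[0]
        return int(idx[-1]) if len(idx) else 0


@dataclass
class SiteRecord:
    """A dated site: planar location (km) and min/mean/max ages (ka)."""

    site_id: str
    location: tuple[float, float]
    age_min: float
    age_mean: float
    age_max: float

    def __post_init__(self) -> None:
        if not (self.age_min <= self.age_mean <= self.age_max):
            raise InvalidInputError(
                f"site {self.site_id}: ages must satisfy min <= mean <= max"
            )


def _power_law_noise(shape: tuple[int, int], exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian random field with power spectral density ∝ k^(−exponent), unit std."""
    ny, nx = shape
    white = rng.standard_normal(shape)
    spec = np.fft.rfft2(white)
    ky = np.fft.fftfreq(ny)[:, None]
    kx = np.fft.rfftfreq(nx)[None, :]
    k = np.sqrt(kx * kx + ky * ky)
    k[0, 0] = np.inf  # zero the mean component
    spec *= k ** (-exponent / 2.0)
    out = np.fft.irfft2(spec, s=shape)
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_dem(
    geometry: GridGeometry,
    relief_amplitude: float = 500.0,
    spectral_exponent: float = 2.0,
    shelf_fraction: float = 0.3,
    seed: int = 0,
    platform_area_fraction: float = 0.5,
    coast_elevation: float = 40.0,
    depression_depth_fraction: float = 0.25,
) -> ElevationGrid:
    """Synthesise a continental platform with shelf, interior relief and an
    endorheic depression.

    The platform occupies ``platform_area_fraction`` of the domain.  Its outer
    ``shelf_fraction`` (by area) is a gentle ramp lying strictly between the
    lowstand (−85 m) and highstand (−60 m) of the default sea-level curve, so
    land area shrinks as the sea recovers from the lowstand.  Interior relief
    is a power-law (spectrum ∝ k^−``spectral_exponent``) random field scaled
    by ``relief_amplitude`` and tapered to zero at the coast; a Gaussian
    depression of depth ``depression_depth_fraction × relief_amplitude`` is
    carved in the interior to guarantee at least one closed basin.
    """
    if relief_amplitude < 0:
        raise InvalidInputError("relief_amplitude must be non-negative")
    if not 0 < shelf_fraction < 1:
        raise InvalidInputError("shelf_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    ny, nx = geometry.shape
    # Normalised radial coordinate from the domain centre, in units where the
    # half-width of the domain's short axis is 1.
    iy, ix = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    half = min(cy, cx)
    r = np.hypot((iy - cy) / half, (ix - cx) / half)

    # Platform/shelf radii from target area fractions (area ∝ r² for the
    # inscribed disc; platform_area_fraction is relative to the inscribed disc
    # area so the shelf never touches the domain edge).
    r_shelf_outer = np.sqrt(platform_area_fraction)
    r_core = r_shelf_outer * np.sqrt(1.0 - shelf_fraction)

    z = np.empty(geometry.shape)
    # Interior core: constant coastal base.
    core = r <= r_core
    z[core] = coast_elevation
    # Shelf ramp: highstand-side depth just below −60 m down to just above −85 m.
    shelf = (r > r_core) & (r <= r_shelf_outer)
    t = (r[shelf] - r_core) / max(r_shelf_outer - r_core, 1e-12)
    z[shelf] = -61.0 + t * (-84.0 - (-61.0))
    # Open ocean: plunge to abyssal depth.
    deep = r > r_shelf_outer
    td = np.clip((r[deep] - r_shelf_outer) / 0.25, 0.0, 1.0)
    z[deep] = -84.0 + td * (-1500.0 - (-84.0))

    if relief_amplitude > 0:
        noise = _power_law_noise(geometry.shape, spectral_exponent, rng)
        # Taper relief to zero before the coast so the shelf band stays clean.
        taper = np.clip(1.0 - r / max(r_core, 1e-12), 0.0, 1.0)
        dome = 0.4 * np.cos(np.clip(r / max(r_core, 1e-12), 0, 1) * np.pi / 2.0)
        z = z + relief_amplitude * taper * (0.35 * np.abs(noise) + dome)
        # Endorheic depression offset from the centre.
        dep_r, dep_c = cy - 0.35 * half, cx + 0.3 * half
        dist2 = ((iy - dep_r) ** 2 + (ix - dep_c) ** 2) / (0.18 * half) ** 2
        z = z - depression_depth_fraction * relief_amplitude * np.exp(-dist2)

    return ElevationGrid(geometry, z)


def default_sea_level_curve(slice_times: np.ndarray) -> np.ndarray:
    """Piecewise-linear sea level through the start/lowstand/end anchors.

    The lowstand sits a quarter of the way through the window (65 ka for the
    default 75–35 ka run, matching the recorded −85 m stand at that epoch).
    """
    slice_times = np.asarray(slice_times, dtype=np.float64)
    t0, t1 = slice_times[0], slice_times[-1]
    t_low = t0 - 0.25 * (t0 - t1)
    anchors_t = np.array([t0, t_low, t1])
    anchors_z = np.array([SEA_LEVEL_START, SEA_LEVEL_LOWSTAND, SEA_LEVEL_END])
    # np.interp needs increasing x; times decrease, so flip.
    return np.interp(-slice_times, -anchors_t, anchors_z)


def generate_climate(
    geometry: GridGeometry,
    n_slices: int = 21,
    mean_precip: float = 1.0,
    anomaly_amplitude: float = 0.35,
    seed: int = 0,
    time_range: tuple[float, float] = (75.0, 35.0),
    correlation_length: float = 10.0,
    temporal_autocorrelation: float = 0.8,
    npp_half_saturation: float | None = None,
) -> ClimateSeries:
    """Generate spatially smooth, temporally autocorrelated climate forcing.

    Precipitation is a fixed north–south gradient (wetter north) around
    ``mean_precip`` plus an AR(1)-in-time smooth anomaly field of standard
    deviation ``anomaly_amplitude`` (the default ±0.35 m/yr brackets the
    −0.4…+0.3 m/yr per-site anomaly envelope the study conditions assume),
    clamped at zero.  NPP is a saturating monotone transform of precipitation
    normalised to [0, 1] over the whole series.  Sea level follows
    :func:`default_sea_level_curve`.
    """
    if n_slices < 2:
        raise InvalidInputError("n_slices must be at least 2")
    if mean_precip <= 0:
        raise InvalidInputError("mean_precip must be positive")
    if anomaly_amplitude >= mean_precip:
        raise InvalidInputError("anomaly_amplitude must be below mean_precip")
    rng = np.random.default_rng(seed)

    slice_times = np.linspace(time_range[0], time_range[1], n_slices)
    ny, nx = geometry.shape
    lat_factor = np.linspace(1.6, 0.4, ny)[:, None] * np.ones((1, nx))
    base = mean_precip * lat_factor

    def smooth_field() -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal(geometry.shape), correlation_length)
        sd = f.std()
        return f / sd if sd > 0 else f

    phi = temporal_autocorrelation
    precip = np.empty((n_slices, ny, nx))
    anomaly = smooth_field()
    for s in range(n_slices):
        if s > 0:
            anomaly = phi * anomaly + np.sqrt(1.0 - phi * phi) * smooth_field()
        precip[s] = np.clip(base + anomaly_amplitude * anomaly, 0.0, None)

    p0 = npp_half_saturation if npp_half_saturation is not None else mean_precip
    npp_raw = 1.0 - np.exp(-precip / p0)
    npp = npp_raw / max(npp_raw.max(), 1e-12)

    return ClimateSeries(
        geometry=geometry,
        slice_times=slice_times,
        precipitation=precip,
        sea_level=default_sea_level_curve(slice_times),
        npp=npp,
    )


def generate_sites(
    landmask: np.ndarray,
    n_sites: int,
    age_bounds: tuple[float, float] = (35.0, 75.0),
    seed: int = 0,
    geometry: GridGeometry | None = None,
) -> list[SiteRecord]:
    """Sample dated sites uniformly (without replacement) over land cells.

    The three ages of each site are i.i.d. uniform draws within
    ``age_bounds`` sorted into (min, mean, max).  Locations are cell centres;
    pass ``geometry`` to express them in world km rather than cell indices.
    """
    landmask = np.asarray(landmask, dtype=bool)
    land_idx = np.flatnonzero(landmask)
    if n_sites > len(land_idx):
        raise InvalidInputError(
            f"requested {n_sites} sites but only {len(land_idx)} land cells"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(land_idx, size=n_sites, replace=False)
    lo, hi = min(age_bounds), max(age_bounds)
    sites: list[SiteRecord] = []
    for i, flat in enumerate(chosen):
        row, col = np.unravel_index(flat, landmask.shape)
        if geometry is not None:
            x, y = geometry.rowcol_to_xy(int(row), int(col))
        else:
            x, y = float(col), float(-row)
        ages = np.sort(rng.uniform(lo, hi, size=3))
        sites.append(
            SiteRecord(
                site_id=f"S{i:04d}",
                location=(float(x), float(y)),
                age_min=float(ages[0]),
                age_mean=float(ages[1]),
                age_max=float(ages[2]),
            )
        )
    return sites


def entry_points(elev: ElevationGrid, sea_level: float) -> dict[str, tuple[float, float]]:
    """Northern and southern coastal entry locations on a synthetic world.

    The northern entry is the northernmost land cell adjacent to ocean, the
    southern entry the westernmost such cell — a planar stand-in for the two
    shelf-crossing arrival routes the double-entry scenario assumes.
    """
    land = elev.z >= sea_level
    ocean = ~land
    coast = land & ndimage.binary_dilation(ocean)
    rows, cols = np.nonzero(coast)
    if len(rows) == 0:
        raise InvalidInputError("no coastal land cells at this sea level")
    north = np.argmin(rows)
    west = np.argmin(cols)
    return {
        "northern": elev.geometry.rowcol_to_xy(int(rows[north]), int(cols[north])),
        "southern": elev.geometry.rowcol_to_xy(int(rows[west]), int(cols[west])),
    }


@dataclass
class CorridorWorld:
    """A two-corridor benchmark world for movement-behaviour recovery tests."""

    geometry: GridGeometry
    cost: np.ndarray
    land_mask: np.ndarray
    corridor_mask: np.ndarray
    entry: tuple[float, float]


def two_corridor_world(
    n: int = 128,
    cell_size: float = 1.0,
    background_cost: float = 0.6,
    corridor_cost: float = 0.2,
    corridor_halfwidth: int = 2,
    ocean_border: int = 6,
) -> CorridorWorld:
    """Build a deterministic world with two low-cost corridors crossing land.

    Land is the interior of an ocean frame (cost 1).  A horizontal and a
    vertical corridor of cost ``corridor_cost`` cross the ``background_cost``
    interior; the walker entry point sits on the western end of the
    horizontal corridor.  Used to make the qualitative corridor-following
    claim of resistance-conditioned walkers assertable.
    """
    geometry = GridGeometry(n, n, cell_size=cell_size)
    cost = np.full((n, n), 1.0)
    b = ocean_border
    land = np.zeros((n, n), dtype=bool)
    land[b : n - b, b : n - b] = True
    cost[land] = background_cost

    corridor = np.zeros((n, n), dtype=bool)
    r0 = n // 2
    c0 = n // 2
    corridor[r0 - corridor_halfwidth : r0 + corridor_halfwidth + 1, b : n - b] = True
    corridor[b : n - b, c0 - corridor_halfwidth : c0 + corridor_halfwidth + 1] = True
    corridor &= land
    cost[corridor] = corridor_cost

    entry = geometry.rowcol_to_xy(r0, b + 1)
    return CorridorWorld(geometry, cost, land, corridor, entry)
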