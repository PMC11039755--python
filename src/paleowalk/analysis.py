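"""Analysis products of walker ensembles.

Turns raw trajectories into the quantities the dispersal study reports:
residential-move aggregation (successive displacements within a knowledge
radius collapse into one mobility event), per-site visitation statistics
within a 10 km access radius, distinct-visit counts via 1-D k-means on
cumulative travelled distance, occupation likelihood maps (kernel density),
presence heat maps (per-cell walker counts), migration speeds from travelled
distances and dated site ages, and prospective ranking of hypothetical
sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy import ndimage
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import InvalidInputError
from .grids import GridGeometry
from .movement import Trajectory
from .synthetic_world import SiteRecord


@dataclass
class ResidentialPath:
    """Aggregated mobility events of one trajectory.

    ``anchors`` are the camp locations; segment i covers the steps walked
    between anchors i and i+1 (the trailing partial event is retained, so
    segment distances sum to the trajectory's total travelled distance).
    """

    anchors: np.ndarray = field(repr=False)
    segment_steps: np.ndarray = field(repr=False)
    segment_distances: np.ndarray = field(repr=False)
    aggregation_radius: float = 50.0

    @property
    def n_events(self) -> int:
        return len(self.segment_steps)


@dataclass
class SiteStats:
    """Visitation summary of one site over an ensemble of realisations."""

    site_id: str
    percent_visited: float  # % of realisations with >= 1 access
    walker_counts: np.ndarray = field(repr=False)  # in-radius points per realisation
    occupation_numbers: np.ndarray = field(repr=False)  # distinct visits per realisation
    first_access_distances: np.ndarray = field(repr=False)  # km, visiting realisations only

    @property
    def mean_walker_count(self) -> float:
        return float(self.walker_counts.mean()) if len(self.walker_counts) else 0.0

    @property
    def mean_distance(self) -> float:
        return float(self.first_access_distances.mean()) if len(self.first_access_distances) else float("nan")

    @property
    def min_distance(self) -> float:
        return float(self.first_access_distances.min()) if len(self.first_access_distances) else float("nan")


@dataclass
class SpeedEstimate:
    """Migration speeds (km/yr) to one site for each dated age bound."""

    site_id: str
    speed_from_mean: dict[str, float]
    speed_from_min: dict[str, float]


@njit(cache=False)
def _aggregate_scan(xs, ys, step_lengths, radius):
    n = xs.shape[0]
    anchor_idx = np.empty(n, np.int64)
    anchor_idx[0] = 0
    n_anchor = 1
    ax, ay = xs[0], ys[0]
    seg_steps = np.zeros(n, np.int64)
    seg_dist = np.zeros(n)
    cur = 0
    for i in range(1, n):
        seg_steps[cur] += 1
        seg_dist[cur] += step_lengths[i - 1]
        dx = xs[i] - ax
        dy = ys[i] - ay
        if dx * dx + dy * dy > radius * radius:
            anchor_idx[n_anchor] = i
            n_anchor += 1
            ax, ay = xs[i], ys[i]
            cur += 1
    return anchor_idx[:n_anchor], seg_steps[:cur + 1], seg_dist[:cur + 1]


def aggregate_residential(traj: Trajectory, radius: float) -> ResidentialPath:
    """Collapse successive displacements within ``radius`` of the current
    anchor into single mobility events.

    The first position anchors the first event; the first position farther
    than ``radius`` from the current anchor closes the event (recording its
    step count and travelled distance) and becomes the next anchor.  A
    trailing partial event is kept so distances stay conserved.
    """
    if radius <= 0:
        raise InvalidInputError("aggregation radius must be positive")
    if len(traj.positions) == 0:
        return ResidentialPath(
            anchors=np.empty((0, 2)), segment_steps=np.empty(0, np.int64),
            segment_distances=np.empty(0), aggregation_radius=radius,
        )
    idx, steps, dists = _aggregate_scan(
        np.ascontiguousarray(traj.positions[:, 0]),
        np.ascontiguousarray(traj.positions[:, 1]),
        traj.step_lengths, radius,
    )
    return ResidentialPath(
        anchors=traj.positions[idx],
        segment_steps=steps,
        segment_distances=dists,
        aggregation_radius=radius,
    )


def site_access(
    traj: Trajectory, sites: list[SiteRecord], access_radius: float = 10.0
) -> dict[str, dict]:
    """Per-site in-radius trajectory points: a site is accessed whenever a
    walker position lies within ``access_radius`` of it.  Returns, per site,
    the step indices, positions and cumulative distances of those points."""
    if access_radius <= 0:
        raise InvalidInputError("access_radius must be positive")
    cum = np.concatenate([[0.0], traj.cumulative_distance]) if traj.n_steps else np.zeros(1)
    out: dict[str, dict] = {}
    for site in sites:
        sx, sy = site.location
        d2 = (traj.positions[:, 0] - sx) ** 2 + (traj.positions[:, 1] - sy) ** 2
        idx = np.flatnonzero(d2 <= access_radius * access_radius)
        out[site.site_id] = {
            "indices": idx,
            "positions": traj.positions[idx],
            "cumulative_distances": cum[idx],
        }
    return out


def count_distinct_visits(
    cumulative_distances: np.ndarray,
    k_max: int = 8,
    min_spread: float = 20.0,
    random_state: int = 0,
) -> int:
    """Number of distinct visits: 1-D k-means over cumulative travelled
    distance with k chosen by silhouette score over k in 1..min(k_max, n−1).

    k = 1 is forced when the spread of distances is below ``min_spread``
    (default twice the 10 km access radius): points that close together in
    travelled distance belong to one pass, not several.
    """
    values = np.asarray(cumulative_distances, dtype=np.float64).ravel()
    n = len(values)
    if n == 0:
        return 0
    if n == 1 or values.max() - values.min() < min_spread:
        return 1
    X = values.reshape(-1, 1)
    best_k, best_score = 1, -np.inf
    for k in range(2, min(k_max, n - 1) + 1):
        labels = KMeans(n_clusters=k, n_init=10, random_state=random_state).fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        score = silhouette_score(X, labels)
        if score > best_score:
            best_k, best_score = k, score
    return best_k


def compute_site_stats(
    ensemble: list[Trajectory],
    sites: list[SiteRecord],
    access_radius: float = 10.0,
    k_max: int = 8,
) -> dict[str, SiteStats]:
    """Visitation statistics per site over every realisation: percent of
    realisations with access, in-radius point counts, distinct-visit counts,
    and cumulative distance at first access."""
    per_site: dict[str, dict[str, list]] = {
        s.site_id: {"counts": [], "occ": [], "dist": []} for s in sites
    }
    for traj in ensemble:
        acc = site_access(traj, sites, access_radius)
        for s in sites:
            rec = acc[s.site_id]
            count = len(rec["indices"])
            per_site[s.site_id]["counts"].append(count)
            if count:
                per_site[s.site_id]["occ"].append(
                    count_distinct_visits(rec["cumulative_distances"],
                                          k_max=k_max, min_spread=2 * access_radius)
                )
                per_site[s.site_id]["dist"].append(float(rec["cumulative_distances"][0]))
            else:
                per_site[s.site_id]["occ"].append(0)
    out = {}
    n_real = len(ensemble)
    for s in sites:
        d = per_site[s.site_id]
        counts = np.array(d["counts"])
        out[s.site_id] = SiteStats(
            site_id=s.site_id,
            percent_visited=100.0 * float(np.count_nonzero(counts)) / n_real,
            walker_counts=counts,
            occupation_numbers=np.array(d["occ"]),
            first_access_distances=np.array(d["dist"]),
        )
    return out


def occupation_kde(
    trajectories: list[Trajectory],
    grid: GridGeometry,
    bandwidth: float | None = None,
    thin: int = 1,
    normalise: bool = True,
) -> np.ndarray:
    """Gaussian-kernel occupation density of trajectory points on ``grid``.

    Implemented as a binned KDE: points are histogrammed onto the grid and
    smoothed with a Gaussian of ``bandwidth`` km (default twice the cell
    size).  With ``normalise`` the map is rescaled to a maximum of 1 (the
    occupation-likelihood convention); otherwise it is a density whose
    integral over the domain approximates the point count.
    """
    if not trajectories:
        raise InvalidInputError("need at least one trajectory")
    bandwidth = bandwidth if bandwidth is not None else 2.0 * grid.cell_size
    pts = np.vstack([t.thin(thin) if thin > 1 else t.positions for t in trajectories])
    counts = _bin_points(pts, grid)
    sigma = bandwidth / grid.cell_size
    density = ndimage.gaussian_filter(counts, sigma, mode="constant") / grid.cell_area
    if normalise:
        peak = density.max()
        return density / peak if peak > 0 else density
    return density


def _bin_points(pts: np.ndarray, grid: GridGeometry) -> np.ndarray:
    x0, y0 = grid.origin
    cols = np.round((pts[:, 0] - x0) / grid.cell_size).astype(np.int64)
    rows = np.round((y0 - pts[:, 1]) / grid.cell_size).astype(np.int64)
    rows = np.clip(rows, 0, grid.n_rows - 1)
    cols = np.clip(cols, 0, grid.n_cols - 1)
    counts = np.zeros(grid.shape)
    np.add.at(counts, (rows, cols), 1.0)
    return counts


def presence_heatmap(
    trajectories: list[Trajectory],
    cell_size: float,
    geometry: GridGeometry | None = None,
    thin: int = 1,
) -> tuple[np.ndarray, GridGeometry]:
    """Per-cell count of trajectory points over all realisations (the
    probability-of-presence heat map at ``cell_size`` resolution).  The sum
    over cells equals the number of binned points exactly."""
    if cell_size <= 0:
        raise InvalidInputError("cell_size must be positive")
    pts = np.vstack([t.thin(thin) if thin > 1 else t.positions for t in trajectories])
    if geometry is None:
        xmin, ymin = pts.min(axis=0)
        xmax, ymax = pts.max(axis=0)
        n_cols = max(int(np.ceil((xmax - xmin) / cell_size)) + 1, 8)
        n_rows = max(int(np.ceil((ymax - ymin) / cell_size)) + 1, 8)
        geometry = GridGeometry(n_rows, n_cols, cell_size, origin=(float(xmin), float(ymax)))
    return _bin_points(pts, geometry), geometry


def migration_speed(
    stats: SiteStats, entry_age: float, site: SiteRecord
) -> SpeedEstimate:
    """Speeds (km/yr) from travelled distances and dated ages:
    distance / ((entry_age − age) × 1000 yr) for each of the site's
    min/mean/max ages, using both the mean and the minimum first-access
    distance over realisations."""
    if len(stats.first_access_distances) == 0:
        raise InvalidInputError(f"site {site.site_id}: empty distance distribution")
    ages = {"age_min": site.age_min, "age_mean": site.age_mean, "age_max": site.age_max}
    for name, age in ages.items():
        if age >= entry_age:
            raise InvalidInputError(
                f"site {site.site_id}: {name}={age} ka is not younger than entry at {entry_age} ka"
            )
    mean_d, min_d = stats.mean_distance, stats.min_distance
    return SpeedEstimate(
        site_id=site.site_id,
        speed_from_mean={k: mean_d / ((entry_age - a) * 1000.0) for k, a in ages.items()},
        speed_from_min={k: min_d / ((entry_age - a) * 1000.0) for k, a in ages.items()},
    )


def prospect_sites(
    candidates: list[SiteRecord],
    site_stats: dict[str, SiteStats],
    percent_threshold: float = 70.0,
    walker_threshold: float = 200.0,
    top_n: int = 10,
) -> pd.DataFrame:
    """Rank hypothetical sites by residential likelihood.

    Candidates with percent visited above ``percent_threshold`` and mean
    in-radius walker count above ``walker_threshold`` are ranked
    lexicographically by (percent visited, mean walker count) descending;
    the top ``top_n`` are returned with their mean walked distances.
    """
    rows = []
    for site in candidates:
        st = site_stats[site.site_id]
        if st.percent_visited > percent_threshold and st.mean_walker_count > walker_threshold:
            rows.append(
                {
                    "site_id": site.site_id,
                    "x": site.location[0],
                    "y": site.location[1],
                    "percent_visited": st.percent_visited,
                    "mean_walker_count": st.mean_walker_count,
                    "mean_walked_distance": st.mean_distance,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["site_id", "x", "y", "percent_visited", "mean_walker_count", "mean_walked_distance"],
    )
    if len(df):
        df = df.sort_values(
            ["percent_visited", "mean_walker_count"], ascending=False, kind="stable"
        ).head(top_n).reset_index(drop=True)
    return df
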