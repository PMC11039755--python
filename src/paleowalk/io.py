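"""File formats: ESRI ASCII grids, NetCDF stacks, site tables, trajectories.

Coordinate convention in every file: planar km, cell-centred registration,
row 0 at the northern (top) edge.  The site-table columns are named
``lon``/``lat`` for interoperability but hold planar x/y km in synthetic
mode.  All round trips are exact to printed precision (floats are written
with 17 significant digits).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .errors import FormatError
from .grids import GridGeometry
from .movement import Trajectory
from .synthetic_world import SiteRecord

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# ESRI ASCII grids (plain-text single-band rasters)

def write_ascii_grid(path, array: np.ndarray, geometry: GridGeometry, nodata: float = -9999.0) -> None:
    array = np.asarray(array, dtype=np.float64)
    if array.shape != geometry.shape:
        raise FormatError(f"{path}: array shape {array.shape} does not match geometry")
    x0, y0 = geometry.origin
    c = geometry.cell_size
    header = (
        f"ncols {geometry.n_cols}\n"
        f"nrows {geometry.n_rows}\n"
        f"xllcorner {x0 - c / 2:.17g}\n"
        f"yllcorner {y0 - (geometry.n_rows - 1) * c - c / 2:.17g}\n"
        f"cellsize {c:.17g}\n"
        f"NODATA_value {nodata:.17g}\n"
    )
    body = np.where(np.isfinite(array), array, nodata)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt=_FLOAT_FMT)


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    path = Path(path)
    fields: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            line = fh.readline().split()
            if len(line) != 2:
                raise FormatError(f"{path}: malformed header line {line!r}")
            fields[line[0].lower()] = float(line[1])
        data = np.loadtxt(fh)
    try:
        n_cols = int(fields["ncols"])
        n_rows = int(fields["nrows"])
        cell = fields["cellsize"]
        x0 = fields["xllcorner"] + cell / 2
        y0 = fields["yllcorner"] + (n_rows - 1) * cell + cell / 2
        nodata = fields.get("nodata_value", -9999.0)
    except KeyError as exc:
        raise FormatError(f"{path}: missing header field {exc}") from exc
    data = np.atleast_2d(data)
    if data.shape != (n_rows, n_cols):
        raise FormatError(f"{path}: body shape {data.shape} contradicts header")
    data = np.where(data == nodata, np.nan, data)
    return data, GridGeometry(n_rows, n_cols, cell, origin=(x0, y0))


# ---------------------------------------------------------------------------
# NetCDF stacks (per-slice rasters with validity epochs)

def write_raster_stack(
    path,
    variables: dict[str, np.ndarray],
    times: np.ndarray,
    geometry: GridGeometry,
    scalars: dict[str, np.ndarray] | None = None,
) -> None:
    """Write per-time-slice rasters (and optional per-slice scalars) to
    NetCDF.  ``variables`` maps name → (n_times, n_rows, n_cols)."""
    x0, y0 = geometry.origin
    coords = {
        "time": np.asarray(times, dtype=np.float64),
        "y": y0 - np.arange(geometry.n_rows) * geometry.cell_size,
        "x": x0 + np.arange(geometry.n_cols) * geometry.cell_size,
    }
    data = {}
    for name, arr in variables.items():
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (len(coords["time"]), geometry.n_rows, geometry.n_cols):
            raise FormatError(f"variable {name}: shape {arr.shape} inconsistent with stack")
        data[name] = (("time", "y", "x"), arr)
    for name, arr in (scalars or {}).items():
        data[name] = (("time",), np.asarray(arr, dtype=np.float64))
    ds = xr.Dataset(data, coords=coords, attrs={"cell_size": geometry.cell_size,
                                                "registration": "cell-centred",
                                                "coordinates": "planar-km, row 0 north"})
    ds.to_netcdf(path, engine="scipy")


def read_raster_stack(path) -> tuple[dict[str, np.ndarray], np.ndarray, GridGeometry]:
    with xr.open_dataset(path, engine="scipy") as ds:
        ds.load()
        times = ds["time"].values
        y = ds["y"].values
        x = ds["x"].values
        cell = float(ds.attrs.get("cell_size", abs(y[1] - y[0]) if len(y) > 1 else 1.0))
        geometry = GridGeometry(len(y), len(x), cell, origin=(float(x[0]), float(y[0])))
        out = {}
        for name, da in ds.data_vars.items():
            out[name] = da.values
    return out, times, geometry


# ---------------------------------------------------------------------------
# site tables

SITE_COLUMNS = ["site_id", "lon", "lat", "age_min", "age_mean", "age_max"]


def write_sites(path, sites: list[SiteRecord]) -> None:
    rows = [
        {
            "site_id": s.site_id,
            "lon": s.location[0],
            "lat": s.location[1],
            "age_min": s.age_min,
            "age_mean": s.age_mean,
            "age_max": s.age_max,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=SITE_COLUMNS).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_sites(path) -> list[SiteRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(SITE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sites = []
    for i, row in df.iterrows():
        if not row.age_min <= row.age_mean <= row.age_max:
            raise FormatError(
                f"{path}: row {i} (site {row.site_id}): ages not ordered "
                f"({row.age_min}, {row.age_mean}, {row.age_max})"
            )
        sites.append(
            SiteRecord(
                site_id=str(row.site_id),
                location=(float(row.lon), float(row.lat)),
                age_min=float(row.age_min),
                age_mean=float(row.age_mean),
                age_max=float(row.age_max),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# trajectories (columnar CSV, optional thinning)

TRAJ_COLUMNS = ["traj_id", "step", "x", "y", "state", "step_length", "cumulative_distance"]


def write_trajectories(path, trajectories: list[Trajectory], thin: int = 1) -> None:
    """Write an ensemble to one columnar CSV.  With ``thin`` > 1 only every
    thin-th step is kept; step lengths are aggregated between kept rows so
    cumulative distance stays exact."""
    frames = []
    for tid, traj in enumerate(trajectories):
        n = traj.n_steps
        keep = np.arange(0, n + 1, thin)
        if n % thin:
            keep = np.append(keep, n)
        cum = np.concatenate([[0.0], traj.cumulative_distance])
        frames.append(
            pd.DataFrame(
                {
                    "traj_id": tid,
                    "step": keep,
                    "x": traj.positions[keep, 0],
                    "y": traj.positions[keep, 1],
                    "state": np.concatenate([[traj.states[0] if n else 0], traj.states])[keep],
                    "step_length": np.concatenate([[0.0], np.diff(cum[keep])]),
                    "cumulative_distance": cum[keep],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectories(path) -> list[Trajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(TRAJ_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for tid, grp in df.groupby("traj_id", sort=True):
        grp = grp.sort_values("step")
        out.append(
            Trajectory(
                positions=grp[["x", "y"]].to_numpy(),
                states=grp["state"].to_numpy()[1:].astype(np.int8),
                step_lengths=grp["step_length"].to_numpy()[1:],
                cumulative_distance=grp["cumulative_distance"].to_numpy()[1:],
                seed=int(tid),
            )
        )
    return out
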