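"""End-to-end orchestration: world → landscape → resistance → walkers → analysis.

A run is described by a flat configuration dictionary (see
:func:`default_config`), a base seed, and an output directory.  Every stage
persists its artefacts (text rasters, NetCDF stacks, CSV tables) and records
their SHA-256 hashes in a JSON run manifest; replaying a manifest reproduces
every artefact hash bit-identically.  Stages are individually resumable:
a later stage loads its inputs from the artefacts on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .analysis import compute_site_stats, migration_speed, occupation_kde, presence_heatmap
from .errors import PipelineError
from .grids import GridGeometry
from .landscape import ErosionParams, run_history
from .movement import MovementParams, run_ensemble
from .resistance import ResistanceMap, resistance_stack
from .synthetic_world import entry_points, generate_climate, generate_dem, generate_sites

log = logging.getLogger(__name__)

STAGES = ["world", "landscape", "resistance", "walkers", "analysis"]

_STAGE_ARTEFACTS = {
    "world": ["dem.asc", "climate.nc", "sites.csv"],
    "landscape": ["snapshots.nc"],
    "resistance": ["resistance.nc"],
    "walkers": ["trajectories.csv"],
    "analysis": ["site_stats.csv", "occupation_kde.asc", "presence_heatmap.asc"],
}


def default_config() -> dict:
    """Desk-scale demo configuration: a 128×128 world at 2 km resolution,
    20 climate slices over 75–35 ka, 20 walkers of 50,000 steps."""
    return {
        "grid": {"n_rows": 128, "n_cols": 128, "cell_size": 2.0},
        "world": {
            "relief_amplitude": 500.0,
            "spectral_exponent": 2.0,
            "shelf_fraction": 0.3,
            "n_slices": 20,
            "mean_precip": 1.0,
            "anomaly_amplitude": 0.35,
            "time_range": [75.0, 35.0],
            "n_sites": 12,
            "age_bounds": [36.0, 70.0],
        },
        "erosion": {"U": 0.0, "kappa": 0.1, "epsilon": 1.0e-7, "dt": 1000.0},
        "snapshot_interval": 2000.0,
        "movement": {
            "n_steps": 50_000,
            "resistance_update_steps": 10_000,
        },
        "analysis": {
            "access_radius": 10.0,
            "aggregation_radii": [25.0, 50.0],
            "heatmap_cell": 5.0,
            "entry_ages": {"northern": 73.0, "southern": 75.0},
        },
        "n_realisations": 20,
        "trajectory_thin": 10,
    }


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    base_seed: int
    seeds: dict = field(default_factory=dict)
    artefacts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            d = json.load(fh)
        return cls(**d)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(base_seed: int, stage: str) -> int:
    return int(np.random.SeedSequence([base_seed, STAGES.index(stage)]).generate_state(1)[0] % (2**31))


def run_pipeline(
    config: dict | None = None,
    out_dir="run",
    base_seed: int = 0,
    start_stage: str = "world",
) -> RunManifest:
    """Execute the pipeline from ``start_stage`` onward, loading earlier
    artefacts from ``out_dir`` when starting mid-way.  Returns the saved
    manifest; any stage failure raises :class:`PipelineError` tagged with the
    stage name."""
    config = config if config is not None else default_config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if start_stage not in STAGES:
        raise PipelineError(f"unknown stage {start_stage!r}")
    manifest = RunManifest(config=config, base_seed=base_seed)
    manifest.seeds = {s: _stage_seed(base_seed, s) for s in STAGES}
    first = STAGES.index(start_stage)

    state: dict = {}
    for i, stage in enumerate(STAGES):
        t0 = _time.perf_counter()
        try:
            if i < first:
                _load_stage(stage, config, out, state)
                for name in _STAGE_ARTEFACTS[stage]:
                    _record(manifest, name, out / name)
            else:
                _run_stage(stage, config, manifest, out, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-tag with the stage name
            raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
        manifest.timings[stage] = round(_time.perf_counter() - t0, 3)
        log.info("stage %s done in %.2fs", stage, manifest.timings[stage])

    manifest.save(out / "manifest.json")
    return manifest


def _record(manifest: RunManifest, name: str, path: Path) -> None:
    manifest.artefacts[name] = {"path": path.name, "sha256": sha256_file(path)}


def _require(out: Path, name: str, stage: str) -> Path:
    p = out / name
    if not p.exists():
        raise PipelineError(
            f"stage '{stage}' requires artefact {name} in {out}; "
            "run the earlier stages first"
        )
    return p


def _geometry(config: dict) -> GridGeometry:
    g = config["grid"]
    return GridGeometry(g["n_rows"], g["n_cols"], g["cell_size"])


def _run_stage(stage: str, config: dict, manifest: RunManifest, out: Path, state: dict) -> None:
    seed = manifest.seeds[stage]
    if stage == "world":
        geom = _geometry(config)
        w = config["world"]
        dem = generate_dem(
            geom, w["relief_amplitude"], w["spectral_exponent"], w["shelf_fraction"], seed
        )
        climate = generate_climate(
            geom, w["n_slices"], w["mean_precip"], w["anomaly_amplitude"], seed + 1,
            time_range=tuple(w["time_range"]),
        )
        land0 = dem.z >= climate.sea_level[0]
        sites = generate_sites(land0, w["n_sites"], tuple(w["age_bounds"]), seed + 2, geometry=geom)
        pio.write_ascii_grid(out / "dem.asc", dem.z, geom)
        pio.write_raster_stack(
            out / "climate.nc",
            {"precipitation": climate.precipitation, "npp": climate.npp},
            climate.slice_times, geom, scalars={"sea_level": climate.sea_level},
        )
        pio.write_sites(out / "sites.csv", sites)
        for name in ("dem.asc", "climate.nc", "sites.csv"):
            _record(manifest, name, out / name)
        state.update(dem=dem, climate=climate, sites=sites)

    elif stage == "landscape":
        params = ErosionParams(**config["erosion"])
        snaps = run_history(state["dem"], state["climate"], params, config["snapshot_interval"])
        geom = state["dem"].geometry
        pio.write_raster_stack(
            out / "snapshots.nc",
            {
                "elevation": np.stack([s.elevation.z for s in snaps]),
                "discharge": np.stack([s.flow.discharge for s in snaps]),
                "erosion_rate": np.stack([s.erosion_rate for s in snaps]),
                "deposition_rate": np.stack([s.deposition_rate for s in snaps]),
                "lake_mask": np.stack([s.lake_mask.astype(float) for s in snaps]),
                "basin_id": np.stack([s.flow.basin_id.astype(float) for s in snaps]),
                "cumulative_erosion": np.stack(
                    [s.cumulative_erosion if s.cumulative_erosion is not None
                     else np.zeros(geom.shape) for s in snaps]
                ),
            },
            np.array([s.time for s in snaps]), geom,
            scalars={"sea_level": np.array([s.sea_level for s in snaps])},
        )
        _record(manifest, "snapshots.nc", out / "snapshots.nc")
        state["snapshots"] = snaps

    elif stage == "resistance":
        maps = resistance_stack(state["snapshots"], state["climate"])
        geom = maps[0].geometry
        pio.write_raster_stack(
            out / "resistance.nc",
            {"cost": np.stack([m.cost for m in maps])},
            np.array([m.valid_from for m in maps]), geom,
        )
        _record(manifest, "resistance.nc", out / "resistance.nc")
        state["resistance"] = maps

    elif stage == "walkers":
        snaps = state["snapshots"]
        entries = entry_points(snaps[0].elevation, snaps[0].sea_level)
        params = MovementParams(**config["movement"])
        trajs = run_ensemble(
            entries, state["resistance"], params, config["n_realisations"], seed
        )
        pio.write_trajectories(out / "trajectories.csv", trajs, thin=config["trajectory_thin"])
        _record(manifest, "trajectories.csv", out / "trajectories.csv")
        # downstream analysis consumes the persisted record, so a resumed run
        # reproduces the analysis artefacts bit-identically
        state["trajectories"] = pio.read_trajectories(out / "trajectories.csv")
        state["entries"] = entries

    elif stage == "analysis":
        cfg = config["analysis"]
        trajs = state["trajectories"]
        sites = state["sites"]
        geom = _geometry(config)
        stats = compute_site_stats(trajs, sites, cfg["access_radius"])
        rows = []
        for s in sites:
            st = stats[s.site_id]
            row = {
                "site_id": s.site_id,
                "percent_visited": st.percent_visited,
                "mean_walker_count": st.mean_walker_count,
                "mean_occupation": float(st.occupation_numbers.mean()),
                "mean_distance": st.mean_distance,
                "min_distance": st.min_distance,
            }
            entry_age = min(cfg["entry_ages"].values())
            if len(st.first_access_distances) and s.age_max < entry_age:
                sp = migration_speed(st, entry_age, s)
                row["speed_mean_age"] = sp.speed_from_mean["age_mean"]
                row["speed_min_age"] = sp.speed_from_min["age_mean"]
            rows.append(row)
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "site_stats.csv", index=False, float_format="%.17g")
        kde = occupation_kde(trajs, geom, thin=10)
        pio.write_ascii_grid(out / "occupation_kde.asc", kde, geom)
        heat, heat_geom = presence_heatmap(trajs, cfg["heatmap_cell"], thin=1)
        pio.write_ascii_grid(out / "presence_heatmap.asc", heat, heat_geom)
        for name in ("site_stats.csv", "occupation_kde.asc", "presence_heatmap.asc"):
            _record(manifest, name, out / name)


def _load_stage(stage: str, config: dict, out: Path, state: dict) -> None:
    """Reload a completed stage's artefacts so a later stage can resume."""
    if stage == "world":
        z, geom = pio.read_ascii_grid(_require(out, "dem.asc", stage))
        from .grids import ElevationGrid
        from .synthetic_world import ClimateSeries

        variables, times, _ = pio.read_raster_stack(_require(out, "climate.nc", stage))
        state["dem"] = ElevationGrid(geom, z)
        state["climate"] = ClimateSeries(
            geometry=geom, slice_times=times,
            precipitation=variables["precipitation"],
            sea_level=variables["sea_level"], npp=variables["npp"],
        )
        state["sites"] = pio.read_sites(_require(out, "sites.csv", stage))
    elif stage == "landscape":
        variables, times, geom = pio.read_raster_stack(_require(out, "snapshots.nc", stage))
        from .grids import ElevationGrid
        from .landscape import make_state

        snaps = []
        for i, t in enumerate(times):
            idx = state["climate"].slice_at(float(t))
            s = make_state(
                ElevationGrid(geom, variables["elevation"][i]),
                state["climate"].precipitation[idx],
                float(variables["sea_level"][i]), float(t),
            )
            s.cumulative_erosion = variables["cumulative_erosion"][i]
            snaps.append(s)
        state["snapshots"] = snaps
    elif stage == "resistance":
        variables, times, geom = pio.read_raster_stack(_require(out, "resistance.nc", stage))
        maps = []
        for i, t in enumerate(times):
            maps.append(ResistanceMap(geom, variables["cost"][i], valid_from=float(t)))
        state["resistance"] = maps
    elif stage == "walkers":
        state["trajectories"] = pio.read_trajectories(_require(out, "trajectories.csv", stage))
        state["sites"] = pio.read_sites(_require(out, "sites.csv", stage))
    elif stage == "analysis":
        raise PipelineError("cannot start after the final stage")
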