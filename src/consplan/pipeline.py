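"""End-to-end orchestration: simulate → account → prioritize → trends.

The pipeline runs the full accounting chain on a synthetic world (or, via
the library API, any world assembled from user rasters) and writes every
product as plain text: CSV tables, ESRI ASCII rasters, GeoJSON reserves,
and a manifest recording the configuration, seed, package version and a
SHA-256 checksum per output — two runs with one seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import consplan
from consplan import io as cio
from consplan.coverage import coverage_report
from consplan.cvi import (
    cvi_surface,
    minmax_standardize,
    province_summaries,
    rarity_weights,
    select_priorities,
)
from consplan.errors import ConfigError, InvariantError
from consplan.grid import union_masks
from consplan.synthetic import SyntheticWorld, WorldConfig, generate_world
from consplan.templates import (
    TemplateLayer,
    overlay_multiplicity,
    representativeness,
    representativeness_report,
)
from consplan.trends import DEFAULT_BREAKS, aggregate_series, piecewise_trend, reserve_series

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_full_pipeline"]

FLOAT_FMT = "%.6f"


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run."""

    out_dir: Path
    seed: int = 0
    world: WorldConfig | None = None
    breaks: tuple[tuple[int, int], ...] = DEFAULT_BREAKS
    value_aggregation: str = "mean"
    zero_share_policy: str = "error"
    write_rasters: bool = True

    def resolved_world(self) -> WorldConfig:
        if self.world is not None:
            if self.world.seed != self.seed:
                return dataclasses.replace(self.world, seed=self.seed)
            return self.world
        return WorldConfig(seed=self.seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FMT)


def _consistency_checks(world: SyntheticWorld, counts, w) -> None:
    """Cross-module invariants; violations are bugs, not bad input."""
    stack = np.stack([t.mask.values for t in world.templates], axis=0)
    expect = stack.sum(axis=0).astype(float)
    land = world.grid.land_mask
    if not np.array_equal(counts.values[land], expect[land]):
        raise InvariantError("overlay multiplicity != sum of template indicators")
    br = world.network_masks["BR"]
    pa_oecm = union_masks(
        [world.network_masks[n] for n in world.network_masks if n != "BR"]
    )
    rep = representativeness(TemplateLayer("land", world.grid.land()), br, pa_oecm)
    combined = union_masks([br, pa_oecm])
    global_cov = 100.0 * combined.area(world.grid.land()) / world.grid.land_area()
    if abs(rep["pct_combined"] - global_cov) > 1e-9:
        raise InvariantError("land-mask representativeness != global coverage")


def run_full_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to disk)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "consplan",
        "version": consplan.__version__,
        "seed": cfg.seed,
        "stages": {},
        "outputs": {},
        "valid": False,
    }
    t0 = time.time()
    stage = "simulate"
    try:
        world = generate_world(cfg.resolved_world())
        manifest["stages"][stage] = round(time.time() - t0, 3)

        stage = "reserves"
        t1 = time.time()
        recs = pd.DataFrame(
            [
                {
                    "id": r.id,
                    "network": r.network,
                    "lon": r.centroid[0],
                    "lat": r.centroid[1],
                    "area_km2": r.terrestrial_area,
                    "year": r.designation_year,
                    "region": r.region,
                    "country": r.country,
                    "status": r.status,
                    "desig": r.desig_label,
                    "has_polygon": r.geometry is not None,
                }
                for r in world.reserves
            ]
        )
        _write_csv(recs, out / "reserves.csv")
        cio.write_reserves_geojson(world.reserves, out / "reserves.geojson")
        br = world.network_masks["BR"]
        pa_oecm = union_masks(
            [world.network_masks[n] for n in world.network_masks if n != "BR"]
        )
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "coverage"
        t1 = time.time()
        for kind, zones in (
            ("region", world.regions),
            ("province", world.provinces),
            ("ecosystem", world.biomes),
        ):
            rep = coverage_report(pa_oecm, br, zones, stratum_kind=kind)
            rep.to_csv(out / f"coverage_{kind}.csv")
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "represent"
        t1 = time.time()
        rep_df = representativeness_report(world.templates, br, pa_oecm, world.regions)
        _write_csv(rep_df, out / "representativeness.csv")
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "overlay"
        t1 = time.time()
        counts, hist, comp = overlay_multiplicity(world.templates)
        _write_csv(hist.reset_index(), out / "overlay_histogram.csv")
        _write_csv(comp.reset_index(), out / "overlay_composition.csv")
        if cfg.write_rasters:
            cio.write_ascii_grid(counts, out / "overlay_count.asc")
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "cvi"
        t1 = time.time()
        w = rarity_weights(world.templates, zero_share_policy=cfg.zero_share_policy)
        raw = cvi_surface(world.templates, w)
        std = minmax_standardize(raw)
        _write_csv(
            pd.DataFrame(
                {"template": world.templates.names, "p": world.templates.shares, "w": w}
            ),
            out / "weights.csv",
        )
        if cfg.write_rasters:
            cio.write_ascii_grid(raw, out / "cvi.asc")
            cio.write_ascii_grid(std, out / "cvi_std.asc")
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "prioritize"
        t1 = time.time()
        network = union_masks([br, pa_oecm])
        summaries = province_summaries(
            std, network, world.provinces, world.pressure, cfg.value_aggregation
        )
        prio = select_priorities(summaries)
        _write_csv(prio.reset_index(), out / "province_priorities.csv")
        _write_csv(
            prio[prio["priority"]].reset_index()[["zone_id", "name", "coverage_pct", "value"]],
            out / "priority_provinces.csv",
        )
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "trends"
        t1 = time.time()
        br_records = [r for r in world.reserves if r.network == "BR"]
        series = [reserve_series(r, world.quality) for r in br_records]
        agg = aggregate_series(series)
        _write_csv(agg, out / "quality_series.csv")
        fit_rows = []
        for stratum, g in agg.groupby("stratum"):
            s = g.set_index("year")["mean"]
            for f in piecewise_trend(s, cfg.breaks):
                fit_rows.append({"stratum": stratum, **f.as_dict()})
        _write_csv(pd.DataFrame(fit_rows), out / "trend_fits.csv")
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "world-outputs"
        t1 = time.time()
        world.truth.to_json(out / "world_truth.json")
        if cfg.write_rasters:
            cio.write_ascii_grid(world.grid.land(), out / "land.asc")
            cio.write_ascii_grid(br, out / "network_BR.asc")
            cio.write_ascii_grid(pa_oecm, out / "network_PA_OECM.asc")
            cio.write_ascii_grid(world.pressure, out / "pressure.asc")
            for t in world.templates:
                cio.write_ascii_grid(t.mask, out / f"template_{t.name}.asc")
        manifest["stages"][stage] = round(time.time() - t1, 3)

        stage = "consistency"
        _consistency_checks(world, counts, w)
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    for p in sorted(out.iterdir()):
        if p.name != "manifest.json" and p.is_file():
            manifest["outputs"][p.name] = _sha256(p)
    manifest["valid"] = True
    manifest["total_seconds"] = round(time.time() - t0, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
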