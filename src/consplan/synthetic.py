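"""Seeded synthetic worlds with full ground-truth bookkeeping.

The generator emits everything the pipeline consumes — a land mask,
province/region/biome partitions, six binary templates with controllable
land-area shares and spatial autocorrelation, three reserve networks
(BR/PA/OECM) with controlled mutual overlap, size distributions and
designation years, an annual habitat-quality stack with known per-reserve
piecewise trends, and a smooth 0–50 pressure surface — plus a
:class:`WorldTruth` record of realized shares, overlaps, footprint areas,
coverage percents and true slopes, so every downstream statistic can be
checked against an independent recount.

Default parameters emulate the structure of the global accounting problem
at desk scale: a protected-area network holding roughly 16–17% of land, a
biosphere-reserve network holding roughly 5% of which about a third
overlaps the existing network, template shares matching the published
magnitudes (Biodiversity Hotspots ~2.5% of land, Phylogenetic Diversity
hotspots 12.86%, Traded Functional Diversity hotspots 14.47%, the others
unpublished and set to plausible 0.20–0.30 values), about a quarter of
biosphere-reserve area available only as centroid+area (exercising the
circular-buffer path), and habitat-quality trends of order 1e-4..1e-3
quality units per year around a 0.75 background.

Randomness flows from one root seed through named
``numpy.random.SeedSequence`` substreams, so adding a component never
perturbs the others and a fixed config is byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
import shapely.affinity

from consplan.errors import ConfigError, DataError
from consplan.grid import (
    BinaryLayer,
    ContinuousLayer,
    GridSpec,
    ZonePartition,
    rasterize_polygon,
    union_masks,
)
from consplan.reserves import ReserveRecord, network_mask, resolve_geometry
from consplan.templates import TemplateLayer, TemplateSet
from consplan.trends import DEFAULT_BREAKS, QualityStack

__all__ = [
    "TemplateSpec",
    "NetworkSpec",
    "TrendSpec",
    "WorldConfig",
    "WorldTruth",
    "SyntheticWorld",
    "generate_world",
    "gen_world",
    "gen_templates",
    "gen_reserves",
    "gen_quality_stack",
    "gen_pressure",
]

# fixed substream keys: adding a component must never perturb the others
_STREAMS = {
    "land": 0,
    "provinces": 1,
    "regions": 2,
    "biomes": 3,
    "templates": 4,
    "reserves": 5,
    "quality": 6,
    "pressure": 7,
}

REGION_NAMES = (
    "Africa",
    "Arab States",
    "Asia-Pacific",
    "Europe-N.America",
    "Latin America-Caribbean",
)


@dataclass(frozen=True)
class TemplateSpec:
    """Target land-area share and smoothing length (cells) for one template."""

    share: float
    corr_len: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.share < 1:
            raise ConfigError(f"template share must be in (0, 1), got {self.share}")
        if self.corr_len < 0:
            raise ConfigError("corr_len must be >= 0")


@dataclass(frozen=True)
class NetworkSpec:
    """Reserve-network generation parameters.

    Areas are lognormal: ``exp(N(log(area_median), area_sigma))`` km².
    ``overlap_partner``/``overlap_target`` steer what fraction of this
    network's area overlaps an earlier-generated network (or the union of
    several, '+'-separated).  ``buffer_only_fraction`` of reserves are
    emitted as centroid+area with no polygon.
    """

    count: int
    area_median: float
    area_sigma: float = 0.6
    buffer_only_fraction: float = 0.0
    overlap_partner: str | None = None
    overlap_target: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ConfigError("network count must be >= 0")
        if self.count and self.area_median <= 0:
            raise ConfigError("area_median must be positive")
        if not 0 <= self.buffer_only_fraction <= 1:
            raise ConfigError("buffer_only_fraction must be in [0, 1]")
        if not 0 <= self.overlap_target < 1:
            raise ConfigError("overlap_target must be in [0, 1)")


@dataclass(frozen=True)
class TrendSpec:
    """Per-sub-period habitat-quality slope distribution and noise level.

    ``slope_means``/``slope_sds`` give, per sub-period, the normal
    distribution each reserve's true slope is drawn from (quality units per
    year); ``noise_sd`` is the additive i.i.d. Gaussian observation noise
    per cell and year.
    """

    breaks: tuple[tuple[int, int], ...] = DEFAULT_BREAKS
    slope_means: tuple[float, ...] = (1e-4, -3e-4, -4e-4)
    slope_sds: tuple[float, ...] = (5e-4, 5e-4, 5e-4)
    noise_sd: float = 0.01
    background: float = 0.75
    background_amplitude: float = 0.05

    def __post_init__(self) -> None:
        if len(self.slope_means) != len(self.breaks) or len(self.slope_sds) != len(self.breaks):
            raise ConfigError("slope_means/slope_sds must match the number of sub-periods")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def _default_templates() -> dict[str, TemplateSpec]:
    return {
        "BH": TemplateSpec(0.025),
        "RE": TemplateSpec(0.30),
        "PD": TemplateSpec(0.1286),
        "TF": TemplateSpec(0.1447),
        "BC": TemplateSpec(0.20),
        "IL": TemplateSpec(0.25),
    }


def _default_networks() -> dict[str, NetworkSpec]:
    return {
        "PA": NetworkSpec(count=60, area_median=20.0, area_sigma=0.8),
        "OECM": NetworkSpec(count=12, area_median=12.0, area_sigma=0.6),
        "BR": NetworkSpec(
            count=25,
            area_median=14.0,
            area_sigma=0.6,
            buffer_only_fraction=0.26,
            overlap_partner="PA+OECM",
            overlap_target=0.35,
        ),
    }


@dataclass(frozen=True)
class WorldConfig:
    """Complete parameterization of one synthetic world."""

    n_rows: int = 120
    n_cols: int = 120
    land_fraction: float = 0.6
    land_corr_len: float = 4.0
    n_provinces: int = 40
    n_biomes: int = 6
    templates: Mapping[str, TemplateSpec] = field(default_factory=_default_templates)
    networks: Mapping[str, NetworkSpec] = field(default_factory=_default_networks)
    year_range: tuple[int, int] = (1976, 2015)
    quality_years: tuple[int, int] = (1992, 2020)
    trend: TrendSpec = field(default_factory=TrendSpec)
    pressure_corr_len: float = 6.0
    pressure_range: tuple[float, float] = (0.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.land_fraction <= 1:
            raise ConfigError("land_fraction must be in (0, 1]")
        n_land = int(round(self.land_fraction * self.n_rows * self.n_cols))
        if self.n_provinces > n_land:
            raise ConfigError(
                f"n_provinces={self.n_provinces} exceeds expected land cells ({n_land})"
            )
        if self.n_provinces < 1 or self.n_biomes < 1:
            raise ConfigError("n_provinces and n_biomes must be >= 1")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigError("year_range must be (lo, hi) with lo <= hi")

    def rng(self, component: str) -> np.random.Generator:
        key = _STREAMS[component]
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(key,)))


@dataclass
class WorldTruth:
    """Generator-side bookkeeping, re-derivable by brute-force recount."""

    land_area: float = 0.0
    template_shares: dict[str, float] = field(default_factory=dict)
    network_areas: dict[str, float] = field(default_factory=dict)
    pairwise_overlap: dict[str, float] = field(default_factory=dict)  # "A|B" -> km²
    reserve_areas: dict[str, float] = field(default_factory=dict)  # rasterized land area
    designation_years: dict[str, int] = field(default_factory=dict)
    coverage_pct: dict[str, float] = field(default_factory=dict)  # stratum -> with-BR %
    coverage_pct_without_br: dict[str, float] = field(default_factory=dict)
    reserve_slopes: dict[str, list[float]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


@dataclass
class SyntheticWorld:
    """One generated world: all layers, records and the truth record."""

    cfg: WorldConfig
    grid: GridSpec
    provinces: ZonePartition
    regions: ZonePartition
    biomes: ZonePartition
    templates: TemplateSet
    reserves: list[ReserveRecord]
    network_masks: dict[str, BinaryLayer]
    quality: QualityStack
    pressure: ContinuousLayer
    truth: WorldTruth


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], corr_len: float) -> np.ndarray:
    z = rng.standard_normal(shape)
    if corr_len > 0:
        z = ndimage.gaussian_filter(z, sigma=corr_len, mode="wrap")
    return z


def _threshold_to_count(field_vals: np.ndarray, eligible: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask selecting exactly the k highest-valued eligible cells."""
    sel = np.zeros(field_vals.shape, dtype=bool)
    if k <= 0:
        return sel
    idx = np.flatnonzero(eligible)
    vals = field_vals.ravel()[idx]
    top = idx[np.argsort(vals, kind="stable")[::-1][:k]]
    sel.ravel()[top] = True
    return sel


def _grow_partition(
    land: np.ndarray, n_zones: int, rng: np.random.Generator
) -> np.ndarray:
    """Contiguous zones by seeded region growth; every land cell assigned."""
    n_land = int(land.sum())
    if n_zones > n_land:
        raise ConfigError(f"{n_zones} zones exceed {n_land} land cells")
    zone = np.full(land.shape, -1, dtype=np.int64)
    land_idx = np.flatnonzero(land)
    seeds = rng.choice(land_idx, size=n_zones, replace=False)
    zone.ravel()[seeds] = np.arange(n_zones)

    shifts = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    while True:
        unassigned = land & (zone < 0)
        if not unassigned.any():
            break
        assigned_any = False
        for si in rng.permutation(len(shifts)):
            dr, dc = shifts[si]
            src = np.roll(zone, (dr, dc), axis=(0, 1))
            take = unassigned & (src >= 0)
            if take.any():
                zone[take] = src[take]
                unassigned &= ~take
                assigned_any = True
        if not assigned_any:
            # disconnected land: attach leftovers to the nearest seed
            rows, cols = np.unravel_index(np.flatnonzero(unassigned), land.shape)
            srows, scols = np.unravel_index(seeds, land.shape)
            d2 = (rows[:, None] - srows[None, :]) ** 2 + (cols[:, None] - scols[None, :]) ** 2
            zone[rows, cols] = np.argmin(d2, axis=1)
            break
    return zone


def gen_world(cfg: WorldConfig) -> tuple[GridSpec, ZonePartition, ZonePartition, ZonePartition]:
    """Land mask plus province / region / biome partitions.

    The land mask hits the requested land fraction exactly (to the nearest
    cell) by thresholding smoothed noise at the matching count; partitions
    grow from random seeds so zones are contiguous where land is.
    """
    shape = (cfg.n_rows, cfg.n_cols)
    n_cells = cfg.n_rows * cfg.n_cols
    k = int(round(cfg.land_fraction * n_cells))
    if cfg.land_fraction >= 1.0:
        land = np.ones(shape, dtype=bool)
    else:
        z = _smooth_noise(cfg.rng("land"), shape, cfg.land_corr_len)
        land = _threshold_to_count(z, np.ones(shape, dtype=bool), k)
    grid = GridSpec(cfg.n_rows, cfg.n_cols, cell_size=1.0, cell_area=1.0, land_mask=land)

    prov_ids = _grow_partition(land, cfg.n_provinces, cfg.rng("provinces"))
    provinces = ZonePartition(
        grid, prov_ids, {i: f"province_{i:03d}" for i in range(cfg.n_provinces)}, name="province"
    )
    n_regions = min(len(REGION_NAMES), cfg.n_provinces)
    region_ids = _grow_partition(land, n_regions, cfg.rng("regions"))
    regions = ZonePartition(
        grid, region_ids, {i: REGION_NAMES[i] for i in range(n_regions)}, name="region"
    )
    biome_ids = _grow_partition(land, cfg.n_biomes, cfg.rng("biomes"))
    biomes = ZonePartition(
        grid, biome_ids, {i: f"biome_{i}" for i in range(cfg.n_biomes)}, name="biome"
    )
    return grid, provinces, regions, biomes


def gen_templates(cfg: WorldConfig, grid: GridSpec) -> TemplateSet:
    """Binary templates by thresholding smoothed noise at the share quantile.

    Each mask selects, among land cells, the smallest top set whose area
    reaches the target share, so the realized share is within one cell of
    the target (±0.01 at any reasonable grid size).
    """
    rng = cfg.rng("templates")
    land = grid.land_mask
    areas = grid.areas()
    land_area = grid.land_area()
    layers = []
    for name, spec in cfg.templates.items():
        z = _smooth_noise(rng, grid.shape, spec.corr_len)
        # weighted top-set: take highest-valued land cells until area target
        idx = np.flatnonzero(land)
        order = idx[np.argsort(z.ravel()[idx], kind="stable")[::-1]]
        cum = np.cumsum(areas.ravel()[order])
        k = int(np.searchsorted(cum, spec.share * land_area, side="left")) + 1
        sel = np.zeros(grid.shape, dtype=bool)
        sel.ravel()[order[:k]] = True
        layers.append(TemplateLayer(name, BinaryLayer(grid, sel, name=name)))
    return TemplateSet(layers)


def _blob_polygon(rng: np.random.Generator, center: tuple[float, float], area: float) -> Polygon:
    """Irregular star-convex polygon scaled to the requested area."""
    n_vert = int(rng.integers(7, 13))
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    radii = np.exp(rng.normal(0.0, 0.35, n_vert))
    pts = np.c_[np.cos(angles) * radii, np.sin(angles) * radii]
    poly = Polygon(pts)
    if not poly.is_valid or poly.area <= 0:
        poly = poly.buffer(0)
    s = float(np.sqrt(area / poly.area))
    poly = shapely.affinity.scale(poly, xfact=s, yfact=s, origin=(0, 0))
    return shapely.affinity.translate(poly, xoff=center[0], yoff=center[1])


def _cell_center(grid: GridSpec, flat_idx: int) -> tuple[float, float]:
    r, c = np.unravel_index(flat_idx, grid.shape)
    x0, y0 = grid.origin
    return (x0 + (c + 0.5) * grid.cell_size, y0 - (r + 0.5) * grid.cell_size)


def gen_reserves(cfg: WorldConfig, grid: GridSpec) -> list[ReserveRecord]:
    """Three reserve networks with steered inter-network overlap.

    Networks are generated in config order; a network with an
    ``overlap_partner`` steers each placement by the running overlap tally:
    when the realized fraction of its area inside the partner mask is below
    target the next center is drawn inside the partner, otherwise outside
    (rejection-resampling — simple and auditable).  A target of exactly 0
    enforces pairwise-disjoint footprints, raising if infeasible.
    """
    rng = cfg.rng("reserves")
    land = grid.land_mask
    land_idx = np.flatnonzero(land)
    if len(land_idx) == 0:
        raise DataError("world has no land")
    records: list[ReserveRecord] = []
    masks: dict[str, np.ndarray] = {}

    for net, spec in cfg.networks.items():
        partner = None
        if spec.overlap_partner:
            parts = spec.overlap_partner.split("+")
            missing = [p for p in parts if p not in masks]
            if missing:
                raise ConfigError(
                    f"network {net}: overlap partner(s) {missing} not generated yet"
                )
            partner = np.zeros(grid.shape, dtype=bool)
            for p in parts:
                partner |= masks[p]
        net_mask = np.zeros(grid.shape, dtype=bool)
        total_area = 0.0
        overlap_area = 0.0
        areas_sample = np.exp(rng.normal(np.log(spec.area_median), spec.area_sigma, spec.count))
        buffer_only = rng.random(spec.count) < spec.buffer_only_fraction
        for i in range(spec.count):
            area = float(areas_sample[i])
            want_inside = False
            if partner is not None and partner.any():
                frac = overlap_area / total_area if total_area > 0 else 0.0
                want_inside = frac < spec.overlap_target
            placed = None
            for _attempt in range(200):
                if want_inside:
                    pool = np.flatnonzero(partner & land)
                else:
                    pool = np.flatnonzero(land & ~partner) if partner is not None else land_idx
                    if len(pool) == 0:
                        pool = land_idx
                center = _cell_center(grid, int(rng.choice(pool)))
                # jitter within the cell
                center = (
                    center[0] + rng.uniform(-0.5, 0.5) * grid.cell_size,
                    center[1] + rng.uniform(-0.5, 0.5) * grid.cell_size,
                )
                if buffer_only[i]:
                    geom = Point(center).buffer(np.sqrt(area / np.pi), quad_segs=128)
                elif rng.random() < 0.5:
                    geom = Point(center).buffer(np.sqrt(area / np.pi), quad_segs=64)
                else:
                    geom = _blob_polygon(rng, center, area)
                fp = rasterize_polygon(geom, grid, terrestrial=True).values
                if partner is not None and spec.overlap_target == 0.0 and (fp & partner).any():
                    continue  # strict disjointness: resample
                placed = (center, geom, fp)
                break
            if placed is None:
                raise ConfigError(
                    f"network {net}: could not place reserve {i} without violating "
                    f"overlap target {spec.overlap_target} (densities too high)"
                )
            center, geom, fp = placed
            cell_areas = grid.areas()
            total_area += float(cell_areas[fp].sum())
            if partner is not None:
                overlap_area += float(cell_areas[fp & partner].sum())
            net_mask |= fp
            year = int(rng.integers(cfg.year_range[0], cfg.year_range[1] + 1))
            records.append(
                ReserveRecord(
                    id=f"{net}_{i:04d}",
                    network=net,
                    centroid=center,
                    terrestrial_area=area,
                    designation_year=year,
                    status="designated",
                    desig_label=net,
                    geometry=None if buffer_only[i] else geom,
                )
            )
        masks[net] = net_mask
    return records


def _piecewise_path(years: np.ndarray, start_value: float, breaks, slopes) -> np.ndarray:
    """Continuous piecewise-linear path: increment per year = that year's slope."""
    out = np.empty(len(years), dtype=float)
    out[0] = start_value
    for j in range(1, len(years)):
        y = years[j]
        slope = 0.0
        for (lo, hi), b in zip(breaks, slopes):
            if lo <= y <= hi:
                slope = b
                break
        out[j] = out[j - 1] + slope
    return out


def gen_quality_stack(
    cfg: WorldConfig,
    reserves: list[ReserveRecord],
    grid: GridSpec,
    truth: WorldTruth | None = None,
) -> QualityStack:
    """Annual quality layers with known piecewise trends inside reserves.

    The background is a static smooth field around ``trend.background``.
    Each reserve owns the cells of its footprint not claimed by an earlier
    reserve; owned cells follow the reserve's piecewise-linear path (true
    slopes recorded in ``truth``) plus i.i.d. Gaussian noise.  Values are
    clipped to [0, 1]; defaults keep the signal far from the bounds so
    clipping almost never binds.
    """
    rng = cfg.rng("quality")
    t = cfg.trend
    y0, y1 = cfg.quality_years
    years = np.arange(y0, y1 + 1)
    base = t.background + t.background_amplitude * np.tanh(
        _smooth_noise(rng, grid.shape, 5.0)
    )

    owner = np.full(grid.shape, -1, dtype=np.int64)
    paths = {}
    for k, r in enumerate(reserves):
        fp = rasterize_polygon(resolve_geometry(r), grid, terrestrial=True).values
        claim = fp & (owner < 0)
        owner[claim] = k
        slopes = [
            float(rng.normal(m, s)) for m, s in zip(t.slope_means, t.slope_sds)
        ]
        start = float(np.clip(t.background + rng.normal(0.0, 0.03), 0.2, 0.9))
        paths[k] = _piecewise_path(years, start, t.breaks, slopes)
        if truth is not None:
            truth.reserve_slopes[r.id] = slopes

    layers = []
    for j, year in enumerate(years):
        vals = base.copy()
        for k in paths:
            vals[owner == k] = paths[k][j]
        if t.noise_sd > 0:
            vals = vals + rng.normal(0.0, t.noise_sd, grid.shape)
        vals = np.clip(vals, 0.0, 1.0)
        vals[~grid.land_mask] = np.nan
        layers.append(ContinuousLayer(grid, vals, name=f"quality_{year}"))
    return QualityStack(list(map(int, years)), layers)


def gen_pressure(cfg: WorldConfig, grid: GridSpec) -> ContinuousLayer:
    """Smooth pressure surface scaled to ``pressure_range`` (HFP-like 0–50)."""
    z = _smooth_noise(cfg.rng("pressure"), grid.shape, cfg.pressure_corr_len)
    land = grid.land_mask
    lo, hi = cfg.pressure_range
    v = z[land]
    if v.max() > v.min():
        z = (z - v.min()) / (v.max() - v.min())
    out = lo + (hi - lo) * z
    out[~land] = np.nan
    return ContinuousLayer(grid, np.clip(out, lo, hi), name="pressure")


def generate_world(cfg: WorldConfig) -> SyntheticWorld:
    """Generate one complete world and its truth record."""
    grid, provinces, regions, biomes = gen_world(cfg)
    templates = gen_templates(cfg, grid)
    reserves = gen_reserves(cfg, grid)
    truth = WorldTruth(land_area=grid.land_area())

    network_masks: dict[str, BinaryLayer] = {}
    for net in cfg.networks:
        layer = network_mask(reserves, net, grid).mask
        network_masks[net] = layer
        truth.network_areas[net] = layer.area(grid.land())

    # pairwise overlaps and per-reserve areas by direct recount
    nets = list(network_masks)
    areas = grid.areas()
    for i, a in enumerate(nets):
        for b in nets[i + 1 :]:
            ov = network_masks[a].values & network_masks[b].values & grid.land_mask
            truth.pairwise_overlap[f"{a}|{b}"] = float(areas[ov].sum())
    for r in reserves:
        fp = rasterize_polygon(resolve_geometry(r), grid, terrestrial=True)
        truth.reserve_areas[r.id] = fp.area()
        truth.designation_years[r.id] = r.designation_year

    for t in templates:
        truth.template_shares[t.name] = t.p

    # coverage truth by direct cell count (global and per region)
    pa_oecm = union_masks([network_masks[n] for n in nets if n != "BR"]) if len(nets) > 1 else network_masks[nets[0]]
    br = network_masks.get("BR", BinaryLayer(grid, np.zeros(grid.shape, bool), name="BR"))
    combined = pa_oecm.values | br.values
    land = grid.land_mask
    truth.coverage_pct["global"] = 100.0 * areas[combined & land].sum() / grid.land_area()
    truth.coverage_pct_without_br["global"] = (
        100.0 * areas[pa_oecm.values & land].sum() / grid.land_area()
    )
    for zid in regions.ids:
        zsel = (regions.zone_id == zid) & land
        za = areas[zsel].sum()
        label = regions.zone_table[zid]
        if za > 0:
            truth.coverage_pct[label] = 100.0 * areas[zsel & combined].sum() / za
            truth.coverage_pct_without_br[label] = 100.0 * areas[zsel & pa_oecm.values].sum() / za

    quality = gen_quality_stack(cfg, [r for r in reserves if r.network == "BR"], grid, truth)
    pressure = gen_pressure(cfg, grid)
    return SyntheticWorld(
        cfg=cfg,
        grid=grid,
        provinces=provinces,
        regions=regions,
        biomes=biomes,
        templates=templates,
        reserves=reserves,
        network_masks=network_masks,
        quality=quality,
        pressure=pressure,
        truth=truth,
    )
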