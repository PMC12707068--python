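"""Reserve ingestion: exclusion rules, buffer geometry, biome classing, masks.

Reserve records arrive as a table (id, network BR/PA/OECM, centroid,
terrestrial area, designation year, region, country, status, designation
label, optional WKT polygon).  Records failing the exclusion rules — by
default a 'proposed' status anywhere, and an 'MAB' designation label inside
the PA/OECM sets (such sites belong to the biosphere-reserve network, not
the protected-area inventory) — are dropped with per-rule counts.  Reserves
without a polygon get an area-preserving circular buffer around their
centroid.  Dominant-biome ecosystem classing and per-network union masks
close the module.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from consplan.errors import DataError, GeometryError
from consplan.grid import BinaryLayer, GridSpec, ZonePartition, rasterize_polygon, union_masks

logger = logging.getLogger(__name__)

__all__ = [
    "ReserveRecord",
    "ReserveNetworkLayer",
    "ExclusionRules",
    "ReserveLoadResult",
    "load_reserves",
    "circular_buffer",
    "resolve_geometry",
    "classify_ecosystem",
    "network_mask",
]

NETWORKS = ("BR", "PA", "OECM")

#: Ecosystem groups used for dominant-biome classing.
ECOSYSTEM_GROUPS = ("Forest", "Grassland", "Polar & Tundra", "Desert", "Ocean", "Freshwater")

#: Quadrant segments for circular buffers.  128 keeps the inscribed-polygon
#: area deficit of a disc below 2e-4, well under rasterization error.
BUFFER_QUAD_SEGS = 128


@dataclass
class ReserveRecord:
    """One reserve: network tag, geometry or centroid+area, attributes."""

    id: str
    network: str
    centroid: tuple[float, float]
    terrestrial_area: float
    designation_year: int
    region: str = ""
    country: str = ""
    status: str = ""
    desig_label: str = ""
    geometry: BaseGeometry | None = None
    ecosystem_group: str | None = None

    def __post_init__(self) -> None:
        if self.network not in NETWORKS:
            raise DataError(f"reserve {self.id}: unknown network {self.network!r}")
        if self.terrestrial_area < 0:
            raise DataError(f"reserve {self.id}: negative terrestrial_area")
        if self.designation_year < 1800:
            raise DataError(f"reserve {self.id}: implausible designation_year {self.designation_year}")


@dataclass
class ReserveNetworkLayer:
    """Union footprint of one network's member reserves (overlaps counted once)."""

    network: str
    members: list[str]
    mask: BinaryLayer


@dataclass(frozen=True)
class ExclusionRules:
    """Record-level exclusion rules applied at load time.

    ``excluded_status`` drops records (any network) whose status matches
    case-insensitively; ``excluded_desig`` drops records whose designation
    label matches, per network.
    """

    excluded_status: frozenset[str] = frozenset({"proposed"})
    excluded_desig: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: {"PA": frozenset({"MAB"}), "OECM": frozenset({"MAB"})}
    )

    def reason(self, network: str, status: str, desig: str) -> str | None:
        if status.strip().lower() in {s.lower() for s in self.excluded_status}:
            return f"status:{status.strip().lower()}"
        labels = {d.lower() for d in self.excluded_desig.get(network, frozenset())}
        if desig.strip().lower() in labels:
            return f"desig:{desig.strip()}"
        return None


DEFAULT_RULES = ExclusionRules()

MANDATORY_COLUMNS = ("id", "network", "lon", "lat", "area_km2", "year")


@dataclass
class ReserveLoadResult:
    """Retained records plus per-rule exclusion counts."""

    records: list[ReserveRecord]
    exclusions: dict[str, int]

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def load_reserves(
    table: pd.DataFrame, rules: ExclusionRules = DEFAULT_RULES
) -> ReserveLoadResult:
    """Build ReserveRecords from a table, applying the exclusion rules.

    The table needs columns id, network, lon, lat, area_km2, year; region,
    country, status, desig and geometry (WKT, may be empty) are optional.
    Exclusions are independent per record, so the survivor set does not
    depend on rule ordering.
    """
    missing = [c for c in MANDATORY_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"reserve table missing mandatory column(s): {', '.join(missing)}")
    records: list[ReserveRecord] = []
    tally: dict[str, int] = {}
    for _, row in table.iterrows():
        status = str(row.get("status", "") or "")
        desig = str(row.get("desig", "") or "")
        network = str(row["network"])
        reason = rules.reason(network, status, desig)
        if reason is not None:
            tally[reason] = tally.get(reason, 0) + 1
            logger.info("excluding reserve %s (%s): %s", row["id"], network, reason)
            continue
        geom = None
        wkt = row.get("geometry")
        if isinstance(wkt, str) and wkt.strip():
            geom = shapely.from_wkt(wkt)
        records.append(
            ReserveRecord(
                id=str(row["id"]),
                network=network,
                centroid=(float(row["lon"]), float(row["lat"])),
                terrestrial_area=float(row["area_km2"]),
                designation_year=int(row["year"]),
                region=str(row.get("region", "") or ""),
                country=str(row.get("country", "") or ""),
                status=status,
                desig_label=desig,
                geometry=geom,
            )
        )
    if tally:
        logger.info("exclusion tally: %s", tally)
    return ReserveLoadResult(records, tally)


def circular_buffer(record: ReserveRecord) -> BaseGeometry:
    """Area-preserving disc approximation for a reserve without a polygon.

    The disc is centred on the centroid with radius r = sqrt(area / π) in
    map units, so its area equals the reserve's reported terrestrial area
    (map units are chosen so one unit cell carries the grid's cell_area).
    """
    if record.terrestrial_area <= 0:
        raise GeometryError(
            f"reserve {record.id}: cannot buffer non-positive area {record.terrestrial_area}"
        )
    r = math.sqrt(record.terrestrial_area / math.pi)
    return Point(*record.centroid).buffer(r, quad_segs=BUFFER_QUAD_SEGS)


def resolve_geometry(record: ReserveRecord) -> BaseGeometry:
    """A reserve's footprint polygon: its own geometry, else a circular buffer.

    After resolution, buffered and polygon reserves are treated identically
    by every later stage.
    """
    if record.geometry is not None:
        return record.geometry
    return circular_buffer(record)


def classify_ecosystem(
    record: ReserveRecord,
    biomes: ZonePartition,
    mapping: Mapping[int, str],
) -> str | None:
    """Ecosystem group of the biome with the largest area share in the footprint.

    Ties break deterministically to the lowest biome id.  A footprint that
    rasterizes to zero land cells yields None (flagged via log), never an
    exception.
    """
    unmapped = set(biomes.ids) - set(mapping)
    if unmapped:
        raise DataError(f"biome ids without an ecosystem-group mapping: {sorted(unmapped)}")
    geom = resolve_geometry(record)
    fp = rasterize_polygon(geom, biomes.grid, terrestrial=True)
    sel = fp.values
    if not sel.any():
        logger.warning("reserve %s: footprint has no land cells; ecosystem undefined", record.id)
        return None
    areas = biomes.grid.areas()[sel]
    zids = biomes.zone_id[sel]
    per_biome = pd.Series(areas).groupby(zids).sum()
    best = per_biome[per_biome == per_biome.max()].index.min()  # tie -> lowest id
    return mapping[int(best)]


def network_mask(
    records: Sequence[ReserveRecord], network: str, grid: GridSpec
) -> ReserveNetworkLayer:
    """Union footprint mask of one network, intersected with the land mask."""
    members = [r for r in records if r.network == network]
    if not members:
        return ReserveNetworkLayer(
            network, [], BinaryLayer(grid, np.zeros(grid.shape, dtype=bool), name=network)
        )
    layers = [
        rasterize_polygon(resolve_geometry(r), grid, name=r.id, terrestrial=True)
        for r in members
    ]
    mask = union_masks(layers)
    mask.name = network
    return ReserveNetworkLayer(network, [r.id for r in members], mask)
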