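"""Conservation coverage accounting and the uplift from counting BRs.

Coverage is the percent of a stratum's terrestrial area inside the
conserved-area network.  The report compares the PA+OECM network alone
("without BR") against its union with the biosphere-reserve network
("with BR"); the difference in percentage points is the coverage uplift,
non-negative by union monotonicity.  Each percent is flagged against the
17% Aichi target and the 30% KMGBF ("30x30") target, with ties counted as
met (>=).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from consplan.errors import DataError
from consplan.grid import BinaryLayer, ZonePartition, mask_area, union_masks, zonal_fraction

__all__ = ["CoverageReport", "coverage_report", "coverage_uplift", "threshold_flags"]

AICHI_TARGET = 17.0
KMGBF_TARGET = 30.0

GLOBAL_STRATUM = "global"


def threshold_flags(percent: float) -> tuple[bool, bool]:
    """Flags (meets 17% Aichi, meets 30% KMGBF) for one coverage percent.

    Ties count as met: the targets speak of coverage being achieved, so a
    stratum sitting exactly on a threshold is not penalized.
    """
    if not 0.0 <= percent <= 100.0:
        raise DataError(f"percent out of [0, 100]: {percent}")
    return percent >= AICHI_TARGET, percent >= KMGBF_TARGET


@dataclass
class CoverageReport:
    """Per-stratum coverage with/without BRs, uplift, and threshold flags.

    ``rows`` is indexed by stratum label with columns pct_without, pct_with,
    uplift_pts, meets17_without, meets17_with, meets30_without, meets30_with,
    stratum_area and defined.  Undefined (zero-area) strata carry NaN
    percents and defined=False.
    """

    stratum_kind: str
    rows: pd.DataFrame

    def to_csv(self, path: str | Path) -> None:
        out = self.rows.reset_index().rename(columns={"index": "stratum"})
        out.to_csv(path, index=False, float_format="%.6f")

    def __getitem__(self, stratum: str) -> pd.Series:
        return self.rows.loc[stratum]


def _flag_columns(df: pd.DataFrame) -> pd.DataFrame:
    for col, thr in (("meets17", AICHI_TARGET), ("meets30", KMGBF_TARGET)):
        for side in ("without", "with"):
            df[f"{col}_{side}"] = df[f"pct_{side}"] >= thr
    return df


def coverage_report(
    pa_oecm: BinaryLayer,
    br: BinaryLayer,
    zones: ZonePartition | None = None,
    stratum_kind: str | None = None,
) -> CoverageReport:
    """Coverage percent per stratum before and after counting BRs.

    Without ``zones`` a single global row is produced; with a partition,
    one row per zone plus the global row.  Denominators are always the
    stratum's terrestrial area; ocean cells never enter.
    """
    combined = union_masks([pa_oecm, br])
    grid = combined.grid
    records: dict[str, dict] = {}

    land_area = grid.land_area()
    if land_area <= 0:
        raise DataError("grid has no terrestrial area")
    g_without = 100.0 * mask_area(pa_oecm, grid.land()) / land_area
    g_with = 100.0 * mask_area(combined, grid.land()) / land_area
    records[GLOBAL_STRATUM] = {
        "pct_without": g_without,
        "pct_with": g_with,
        "stratum_area": land_area,
        "defined": True,
    }

    if zones is not None:
        zf_without = zonal_fraction(pa_oecm, zones)
        zf_with = zonal_fraction(combined, zones)
        for zid in zones.ids:
            label = zones.zone_table[zid]
            records[label] = {
                "pct_without": zf_without.loc[zid, "percent"],
                "pct_with": zf_with.loc[zid, "percent"],
                "stratum_area": zf_without.loc[zid, "zone_area"],
                "defined": bool(zf_without.loc[zid, "defined"]),
            }

    rows = pd.DataFrame.from_dict(records, orient="index")
    rows["uplift_pts"] = rows["pct_with"] - rows["pct_without"]
    # guard against negative-zero artefacts of float subtraction
    rows["uplift_pts"] = rows["uplift_pts"].clip(lower=0.0).where(rows["defined"], np.nan)
    rows = _flag_columns(rows)
    kind = stratum_kind or (zones.name if zones is not None and zones.name else "global")
    return CoverageReport(kind, rows)


def coverage_uplift(report: CoverageReport) -> pd.Series:
    """Uplift in percentage points per stratum (NaN for undefined strata)."""
    return report.rows["uplift_pts"].copy()
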