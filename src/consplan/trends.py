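"""Designation-aligned habitat-quality series and sub-period trend fits.

Habitat quality is a 0–1 per-cell index supplied as an annual raster stack.
For each reserve the series starts five years before its designation year
(floored at the first stack year, so reserves designated at or before
first_year + 5 start at the stack's first year) — conservation activity
typically precedes formal designation.  Series aggregate across reserves by
unweighted mean per year (an area-weighted variant is available), and the
study window splits into sub-periods (default 1992–2000, 2001–2010,
2011–2020), each fitted by ordinary least squares of quality on year with a
two-sided t-test on the slope, a 95% CI, and the conventional significance
stars (*p<0.05, **p<0.01, ***p<0.001).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from consplan.errors import DataError
from consplan.grid import ContinuousLayer, GridSpec, rasterize_polygon
from consplan.reserves import ReserveRecord, resolve_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "QualityStack",
    "ReserveSeries",
    "TrendFit",
    "DEFAULT_BREAKS",
    "reserve_series",
    "aggregate_series",
    "piecewise_trend",
    "significance_label",
]

#: Default sub-period boundaries (inclusive) for the 1992–2020 window.
DEFAULT_BREAKS: tuple[tuple[int, int], ...] = ((1992, 2000), (2001, 2010), (2011, 2020))

#: Years of pre-designation alignment.
PRE_DESIGNATION_YEARS = 5

MIN_POINTS_PER_FIT = 3


@dataclass
class QualityStack:
    """Annual habitat-quality layers (values in [0, 1]) on one grid."""

    years: list[int]
    layers: list[ContinuousLayer]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.layers):
            raise DataError("years and layers differ in length")
        if list(self.years) != sorted(set(self.years)):
            raise DataError("years must be strictly increasing")
        grid = self.layers[0].grid
        for lyr in self.layers[1:]:
            if lyr.grid is not grid and not grid.same_frame(lyr.grid):
                raise DataError("quality layers do not share a grid")

    @property
    def grid(self) -> GridSpec:
        return self.layers[0].grid

    def layer(self, year: int) -> ContinuousLayer:
        return self.layers[self.years.index(year)]


@dataclass
class ReserveSeries:
    """One reserve's designation-aligned annual mean quality."""

    reserve_id: str
    start_year: int
    values: "pd.Series"  # year -> mean quality

    @property
    def defined(self) -> bool:
        return len(self.values) > 0


@dataclass
class TrendFit:
    """OLS slope for one sub-period with uncertainty and a star label."""

    period: tuple[int, int]
    slope: float
    intercept: float
    p_value: float
    ci95: tuple[float, float]
    stars: str
    n: int

    def as_dict(self) -> dict:
        return {
            "year_lo": self.period[0],
            "year_hi": self.period[1],
            "slope": self.slope,
            "intercept": self.intercept,
            "p_value": self.p_value,
            "ci_lo": self.ci95[0],
            "ci_hi": self.ci95[1],
            "stars": self.stars,
            "n": self.n,
        }


def series_start_year(designation_year: int, first_stack_year: int) -> int:
    """First year of a reserve's series: max(first stack year, designation − 5)."""
    return max(first_stack_year, designation_year - PRE_DESIGNATION_YEARS)


def reserve_series(record: ReserveRecord, stack: QualityStack) -> ReserveSeries:
    """Area-weighted mean quality over the reserve's footprint, per year.

    Years before the reserve's aligned start are dropped.  A footprint with
    no valid quality cells yields an empty (flagged) series.
    """
    start = series_start_year(record.designation_year, stack.years[0])
    grid = stack.grid
    fp = rasterize_polygon(resolve_geometry(record), grid, terrestrial=True)
    sel = fp.values
    if not sel.any():
        logger.warning("reserve %s: footprint has no land cells; series undefined", record.id)
        return ReserveSeries(record.id, start, pd.Series(dtype=float))
    areas = grid.areas()
    out = {}
    for year, layer in zip(stack.years, stack.layers):
        if year < start:
            continue
        valid = sel & ~np.isnan(layer.values)
        if not valid.any():
            continue
        w = areas[valid]
        out[year] = float(np.average(layer.values[valid], weights=w))
    if not out:
        logger.warning("reserve %s: no valid quality cells in any year", record.id)
    return ReserveSeries(record.id, start, pd.Series(out, dtype=float).sort_index())


def aggregate_series(
    series: list[ReserveSeries],
    strata: "dict[str, str] | None" = None,
    weights: "dict[str, float] | None" = None,
) -> pd.DataFrame:
    """Mean quality per stratum and year across reserves with a value that year.

    ``strata`` maps reserve id to a stratum label (default: one 'all'
    stratum).  The mean is unweighted across reserves unless ``weights``
    (e.g. reserve areas) is given.  Returns a DataFrame with columns
    stratum, year, mean, n.
    """
    rows = []
    for s in series:
        label = strata.get(s.reserve_id, "all") if strata else "all"
        for year, v in s.values.items():
            rows.append(
                {
                    "stratum": label,
                    "year": int(year),
                    "value": v,
                    "weight": weights.get(s.reserve_id, np.nan) if weights else 1.0,
                }
            )
    if not rows:
        return pd.DataFrame(columns=["stratum", "year", "mean", "n"])
    df = pd.DataFrame(rows)

    def agg(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {"mean": np.average(g["value"], weights=g["weight"]), "n": len(g)}
        )

    out = df.groupby(["stratum", "year"]).apply(agg, include_groups=False).reset_index()
    out["n"] = out["n"].astype(int)
    return out


def piecewise_trend(
    series: "pd.Series",
    breaks: tuple[tuple[int, int], ...] = DEFAULT_BREAKS,
) -> list[TrendFit]:
    """Separate OLS fits of value on year for each sub-period.

    Each sub-period (inclusive bounds) needs at least three observations;
    shorter ones are skipped with a warning.  The slope carries a two-sided
    t-test p-value and a 95% CI from the usual normal-error theory.
    """
    s = pd.Series(series, dtype=float).dropna().sort_index()
    fits: list[TrendFit] = []
    for lo, hi in breaks:
        sub = s[(s.index >= lo) & (s.index <= hi)]
        if len(sub) < MIN_POINTS_PER_FIT:
            logger.warning("sub-period %d–%d has %d < %d points: fit skipped", lo, hi, len(sub), MIN_POINTS_PER_FIT)
            continue
        x = sm.add_constant(sub.index.to_numpy(dtype=float))
        model = sm.OLS(sub.to_numpy(), x).fit()
        slope = float(model.params[1])
        p = float(model.pvalues[1])
        ci = model.conf_int(alpha=0.05)
        # a perfect (zero-residual) fit has no defined t-test; label it blank
        stars = significance_label(p) if np.isfinite(p) else ""
        fits.append(
            TrendFit(
                period=(lo, hi),
                slope=slope,
                intercept=float(model.params[0]),
                p_value=p,
                ci95=(float(ci[1][0]), float(ci[1][1])),
                stars=stars,
                n=len(sub),
            )
        )
    return fits


def significance_label(p: float) -> str:
    """Conventional star label: *** p<0.001, ** p<0.01, * p<0.05, else ''."""
    if not 0.0 <= p <= 1.0:
        raise DataError(f"p-value out of [0, 1]: {p}")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
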