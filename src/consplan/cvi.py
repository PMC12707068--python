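"""Rarity-weighted Conservation Value Index and sextile prioritization.

Each template i gets a rarity weight inversely proportional to its global
land-area share p_i, normalized to sum to one:

    w_i = (1/p_i) / sum_j (1/p_j)

The per-cell CVI is the sum of the weights of the templates hitting the
cell (CVI = sum_i w_i R_i, R_i in {0,1}), so CVI lies in [0, 1] and equals
1 only where every template overlaps.  A min–max standardization over land
cells rescales CVI to [0, 1] for binning.  Provinces are then summarized
(coverage percent of the combined network, area-weighted mean standardized
CVI, optional mean pressure), cross-classified into empirical sextiles
Q1..Q6 of each variable, and flagged as expansion priorities when they sit
in the upper-value (Q5–Q6) and lower-coverage (Q1–Q2) corner of the 6×6
quantile matrix.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping

import numpy as np
import pandas as pd

from consplan.errors import DataError
from consplan.grid import BinaryLayer, ContinuousLayer, ZonePartition, zonal_fraction, zonal_mean
from consplan.templates import TemplateSet

logger = logging.getLogger(__name__)

__all__ = [
    "rarity_weights",
    "cvi_surface",
    "minmax_standardize",
    "province_summaries",
    "sextile_bins",
    "select_priorities",
]

N_QUANTILE_BINS = 6  # sextiles

PRIORITY_VALUE_BINS = frozenset({5, 6})  # Q5–Q6: upper value
PRIORITY_COVERAGE_BINS = frozenset({1, 2})  # Q1–Q2: lower coverage


def rarity_weights(
    ts: "TemplateSet | np.ndarray | list[float]",
    zero_share_policy: str = "error",
) -> np.ndarray:
    """Rarity-based normalized weights w_i = (1/p_i) / Σ_j (1/p_j).

    Accepts a TemplateSet or a bare share vector.  Weights are strictly
    positive and sum to 1 (to 1e-12); rarer templates (smaller p) weigh
    more.  A zero share makes the weight undefined: policy 'error' rejects
    naming the template, 'drop' excludes it (weight 0) and renormalizes
    over the rest, logged.
    """
    if isinstance(ts, TemplateSet):
        p = ts.shares
        names = ts.names
    else:
        p = np.asarray(ts, dtype=float)
        names = [f"template_{i}" for i in range(len(p))]
    if p.ndim != 1 or len(p) == 0:
        raise DataError("share vector must be non-empty and 1-D")
    if np.any(p < 0) or np.any(p > 1):
        raise DataError("shares must lie in [0, 1]")
    zero = p == 0
    if zero.any():
        offenders = [names[i] for i in np.flatnonzero(zero)]
        if zero_share_policy == "error":
            raise DataError(
                f"template share p=0 for {offenders}: rarity weight undefined "
                "(use zero_share_policy='drop' to exclude and renormalize)"
            )
        if zero_share_policy != "drop":
            raise DataError(f"unknown zero_share_policy {zero_share_policy!r}")
        logger.warning("dropping zero-share template(s) %s from rarity weighting", offenders)
    inv = np.zeros_like(p)
    inv[~zero] = 1.0 / p[~zero]
    total = inv.sum()
    if total == 0:
        raise DataError("all template shares are zero; weights undefined")
    return inv / total


def cvi_surface(ts: TemplateSet, w: np.ndarray) -> ContinuousLayer:
    """Raw per-cell CVI = Σ_i w_i R_i over land cells (NaN off land).

    Because Σ w_i = 1 and R_i ∈ {0,1}, the raw CVI is already in [0, 1];
    a cell hits 1 exactly when it lies inside every template.
    """
    w = np.asarray(w, dtype=float)
    if len(w) != ts.n:
        raise DataError(f"weight vector length {len(w)} != number of templates {ts.n}")
    grid = ts.grid
    vals = np.zeros(grid.shape, dtype=float)
    for wi, t in zip(w, ts):
        vals += wi * t.mask.values
    vals[~grid.land_mask] = np.nan
    return ContinuousLayer(grid, vals, name="CVI")


def minmax_standardize(raw: ContinuousLayer) -> ContinuousLayer:
    """Min–max standardization (x − min)/(max − min) over valid land cells.

    A degenerate layer (max == min) maps to all-0 with a loud warning, so
    downstream binning still runs on a defined surface.
    """
    valid = raw.valid()
    if not valid.any():
        raise DataError("minmax_standardize: no valid cells")
    v = raw.values[valid]
    lo, hi = float(v.min()), float(v.max())
    out = np.full(raw.grid.shape, np.nan)
    if hi == lo:
        logger.warning("degenerate standardization: max == min == %g; mapping to 0", lo)
        out[valid] = 0.0
    else:
        out[valid] = (raw.values[valid] - lo) / (hi - lo)
    return ContinuousLayer(raw.grid, out, name=f"{raw.name}_std")


def province_summaries(
    cvi_std: ContinuousLayer,
    network: BinaryLayer,
    zones: ZonePartition,
    pressure: ContinuousLayer | None = None,
    value_aggregation: str = "mean",
) -> pd.DataFrame:
    """Per-province coverage percent, conservation value, and mean pressure.

    ``network`` is the combined BR ∪ PA ∪ OECM mask (coverage reflects the
    overall conservation saturation of each province, not BRs alone).
    Value is the area-weighted mean of standardized CVI by default; the
    median is available via ``value_aggregation``.  Empty provinces yield
    NaN rows flagged defined=False.
    """
    if value_aggregation not in {"mean", "median"}:
        raise DataError(f"unknown value_aggregation {value_aggregation!r}")
    cov = zonal_fraction(network, zones)
    if value_aggregation == "mean":
        val = zonal_mean(cvi_std, zones)["mean"]
    else:
        val = _zonal_weighted_median(cvi_std, zones)
    out = pd.DataFrame(
        {
            "coverage_pct": cov["percent"],
            "value": val,
            "zone_area": cov["zone_area"],
            "defined": cov["defined"] & val.notna(),
        }
    )
    if pressure is not None:
        out["mean_pressure"] = zonal_mean(pressure, zones)["mean"]
    out["name"] = [zones.zone_table[z] for z in out.index]
    return out.rename_axis("zone_id")


def _zonal_weighted_median(layer: ContinuousLayer, zones: ZonePartition) -> pd.Series:
    valid = layer.valid()
    z = zones.zone_id[valid]
    v = layer.values[valid]
    w = layer.grid.areas()[valid]
    out = {}
    for zid in zones.ids:
        sel = z == zid
        if not sel.any():
            out[zid] = np.nan
            continue
        vv, ww = v[sel], w[sel]
        order = np.argsort(vv)
        cw = np.cumsum(ww[order])
        out[zid] = float(vv[order][np.searchsorted(cw, 0.5 * cw[-1])])
    return pd.Series(out).sort_index()


def sextile_bins(values: "pd.Series | Mapping") -> pd.Series:
    """Empirical sextile bin Q1..Q6 (as ints 1..6) for each id.

    Ids are ranked ascending by value with ties broken by stable id order
    (lexicographic, logged); rank r of N maps to bin ceil(6r/N), so bins
    partition the ids as evenly as N allows, lowest values in Q1.
    NaN values are excluded from ranking and get bin <NA>.
    """
    s = pd.Series(values, dtype=float)
    defined = s.dropna()
    if len(defined) < N_QUANTILE_BINS:
        raise DataError(
            f"sextile binning needs >= {N_QUANTILE_BINS} defined values, got {len(defined)}"
        )
    # stable sort on (value, id-as-string): ties resolve by id order
    order = sorted(defined.index, key=lambda i: (defined[i], str(i)))
    n = len(order)
    if len(set(defined.values)) < n:
        logger.warning("sextile_bins: ties present; broken by stable id order")
    bins = pd.Series(pd.NA, index=s.index, dtype="Int64")
    for r, idx in enumerate(order, start=1):
        bins[idx] = math.ceil(N_QUANTILE_BINS * r / n)
    return bins


def select_priorities(summaries: pd.DataFrame) -> pd.DataFrame:
    """6×6 quantile matrix and the Q5–Q6 value × Q1–Q2 coverage priority flag.

    ``summaries`` is the output of :func:`province_summaries`.  Coverage and
    value are binned into sextiles independently; a province is a priority
    iff its value bin is Q5 or Q6 and its coverage bin is Q1 or Q2.
    Returns the summaries augmented with coverage_bin, value_bin and
    priority columns.
    """
    defined = summaries[summaries["defined"]] if "defined" in summaries else summaries
    cov_bins = sextile_bins(defined["coverage_pct"])
    val_bins = sextile_bins(defined["value"])
    out = summaries.copy()
    out["coverage_bin"] = cov_bins.reindex(out.index)
    out["value_bin"] = val_bins.reindex(out.index)
    out["priority"] = (
        out["value_bin"].isin(PRIORITY_VALUE_BINS)
        & out["coverage_bin"].isin(PRIORITY_COVERAGE_BINS)
    ).fillna(False).astype(bool)
    return out
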