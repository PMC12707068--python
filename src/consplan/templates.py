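"""Binary opportunity templates: shares, hotspot deciles, representativeness.

The six canonical templates (BH Biodiversity Hotspots, RE Risk Ecoregions,
PD Phylogenetic Diversity hotspots, TF Traded Functional Diversity
hotspots, BC High Biomass Carbon, IL Indigenous Lands) are boolean land
masks, each carrying its global land-area share p.  Derived hotspot
templates come from the top-decile intersection of continuous layers.
Representativeness of a template under a network is the percent of the
template's area inside the network, judged against the network's own land
share — the random-placement baseline.  The overlay meta-analysis counts
per cell how many templates hit it (0..n).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from consplan.errors import DataError
from consplan.grid import (
    BinaryLayer,
    ContinuousLayer,
    GridSpec,
    ZonePartition,
    intersect_masks,
    mask_area,
    union_masks,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateLayer",
    "TemplateSet",
    "CANONICAL_TEMPLATES",
    "template_share",
    "top_decile_intersection",
    "representativeness",
    "representativeness_report",
    "overlay_multiplicity",
]

#: The canonical template codes in reporting order.
CANONICAL_TEMPLATES = ("BH", "RE", "PD", "TF", "BC", "IL")


@dataclass
class TemplateLayer:
    """One named binary template with its global land-area share p."""

    name: str
    mask: BinaryLayer
    p: float = field(init=False)

    def __post_init__(self) -> None:
        self.mask = self.mask.intersect_land()
        self.p = template_share(self)

    @property
    def grid(self) -> GridSpec:
        return self.mask.grid


def template_share(t: "TemplateLayer | BinaryLayer") -> float:
    """Global land-area share p = area(mask ∩ land) / area(land), in (0, 1].

    An empty mask yields p = 0 and a warning: such a template cannot enter
    rarity weighting.
    """
    mask = t.mask if isinstance(t, TemplateLayer) else t
    land_area = mask.grid.land_area()
    if land_area <= 0:
        raise DataError("grid has no terrestrial area")
    p = mask_area(mask, mask.grid.land()) / land_area
    if p == 0:
        name = getattr(t, "name", "") or mask.name
        logger.warning("template %r covers no land: share 0, unweightable", name)
    return float(p)


@dataclass
class TemplateSet:
    """Ordered collection of templates sharing one grid, unique names."""

    templates: list[TemplateLayer]

    def __post_init__(self) -> None:
        names = [t.name for t in self.templates]
        if len(set(names)) != len(names):
            raise DataError(f"duplicate template names: {names}")
        grids = {id(t.grid) for t in self.templates}
        if len(grids) > 1:
            base = self.templates[0].grid
            for t in self.templates[1:]:
                if not base.same_frame(t.grid):
                    raise DataError("templates do not share a grid")

    @property
    def n(self) -> int:
        return len(self.templates)

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.templates]

    @property
    def shares(self) -> np.ndarray:
        return np.array([t.p for t in self.templates])

    @property
    def grid(self) -> GridSpec:
        return self.templates[0].grid

    def __iter__(self):
        return iter(self.templates)

    def __getitem__(self, name: str) -> TemplateLayer:
        for t in self.templates:
            if t.name == name:
                return t
        raise KeyError(name)


def top_decile_intersection(
    layers: list[ContinuousLayer], name: str = "hotspot", decile: float = 0.10
) -> TemplateLayer:
    """Hotspot template: intersection of each layer's top area-decile cells.

    Per layer, land cells are ranked by value and the smallest set of
    highest-value cells whose area reaches ``decile`` of the land area is
    taken; cells tying the threshold value are included (>=), so the
    realized share can exceed the decile under heavy ties — deterministic
    and conservative.  The result is the cell-wise intersection across
    layers.
    """
    if not layers:
        raise DataError("top_decile_intersection requires at least one layer")
    if not 0 < decile < 1:
        raise DataError(f"decile must be in (0, 1), got {decile}")
    masks = []
    for layer in layers:
        valid = layer.valid()
        if not valid.any():
            raise DataError(f"layer {layer.name!r} has no valid land cells")
        vals = layer.values[valid]
        wts = layer.grid.areas()[valid]
        order = np.argsort(vals)[::-1]  # descending
        cum = np.cumsum(wts[order])
        target = decile * layer.grid.land_area()
        k = int(np.searchsorted(cum, target, side="left"))  # first index reaching target
        k = min(k, len(vals) - 1)
        threshold = vals[order[k]]
        sel = np.zeros(layer.grid.shape, dtype=bool)
        sel[valid] = vals >= threshold
        masks.append(BinaryLayer(layer.grid, sel, name=f"top-decile({layer.name})"))
    inter = intersect_masks(masks)
    return TemplateLayer(name, inter)


def representativeness(
    t: TemplateLayer, br: BinaryLayer, pa_oecm: BinaryLayer
) -> dict[str, float]:
    """One template's representativeness under the three network definitions.

    Returns pct_BR, pct_PA_OECM, pct_combined (percent of the template's
    area inside each network) and baseline_pct — the BR network's own share
    of land, i.e. the coverage a randomly placed network of the same size
    would achieve in expectation.  An empty template yields NaN percents.
    """
    grid = t.grid
    land = grid.land()
    t_area = mask_area(t.mask, land)
    baseline = 100.0 * mask_area(br, land) / grid.land_area()
    if t_area == 0:
        logger.warning("template %r is empty: representativeness undefined", t.name)
        return {
            "pct_BR": np.nan,
            "pct_PA_OECM": np.nan,
            "pct_combined": np.nan,
            "baseline_pct": baseline,
        }
    combined = union_masks([br, pa_oecm])
    return {
        "pct_BR": 100.0 * mask_area(t.mask, br) / t_area,
        "pct_PA_OECM": 100.0 * mask_area(t.mask, pa_oecm) / t_area,
        "pct_combined": 100.0 * mask_area(t.mask, combined) / t_area,
        "baseline_pct": baseline,
    }


def representativeness_report(
    ts: TemplateSet,
    br: BinaryLayer,
    pa_oecm: BinaryLayer,
    zones: ZonePartition | None = None,
) -> pd.DataFrame:
    """Representativeness of every template, optionally per zone.

    Rows are (template, stratum); the 'global' stratum is always present.
    Zones with zero template area yield NaN rows (no spatial overlap).
    """
    rows = []
    for t in ts:
        row = {"template": t.name, "stratum": "global", **representativeness(t, br, pa_oecm)}
        rows.append(row)
        if zones is not None:
            for zid in zones.ids:
                zmask = zones.zone_mask(zid)
                t_in_zone = TemplateLayer(t.name, t.mask & zmask)
                br_z = br & zmask
                pa_z = pa_oecm & zmask
                r = representativeness(t_in_zone, br_z, pa_z)
                rows.append({"template": t.name, "stratum": zones.zone_table[zid], **r})
    return pd.DataFrame(rows)


def overlay_multiplicity(
    ts: TemplateSet,
) -> tuple[ContinuousLayer, pd.Series, pd.DataFrame]:
    """Spatial meta-analysis of template convergence.

    Returns
    -------
    counts : ContinuousLayer
        Per land cell, the number of templates hitting it (0..n); NaN off
        land.
    histogram : pd.Series
        Land area by hit count; sums to the total land area.
    composition : pd.DataFrame
        For each template (rows), the fraction of its own area overlapping
        exactly k of the *other* n-1 templates (columns 0..n-1).
    """
    if ts.n == 0:
        raise DataError("empty template set")
    grid = ts.grid
    stack = np.stack([t.mask.values for t in ts], axis=0)
    counts = stack.sum(axis=0).astype(float)
    counts[~grid.land_mask] = np.nan
    counts_layer = ContinuousLayer(grid, counts, name="overlay_count")

    areas = grid.areas()
    land = grid.land_mask
    hist = {}
    for k in range(ts.n + 1):
        hist[k] = float(areas[land & (counts == k)].sum())
    histogram = pd.Series(hist, name="area").rename_axis("n_templates")

    comp_rows = {}
    for i, t in enumerate(ts):
        others = stack.sum(axis=0) - stack[i]
        own = t.mask.values & land
        own_area = areas[own].sum()
        fracs = {}
        for k in range(ts.n):
            a = float(areas[own & (others == k)].sum())
            fracs[k] = a / own_area if own_area > 0 else np.nan
        comp_rows[t.name] = fracs
    composition = pd.DataFrame.from_dict(comp_rows, orient="index").rename_axis("template")
    return counts_layer, histogram, composition
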