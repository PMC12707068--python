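"""Synthetic worlds: determinism, structural invariants, truth recounts."""

import dataclasses

import numpy as np
import pytest

from consplan.errors import ConfigError
from consplan.grid import rasterize_polygon, union_masks
from consplan.reserves import resolve_geometry
from consplan.synthetic import (
    NetworkSpec,
    TemplateSpec,
    TrendSpec,
    WorldConfig,
    gen_quality_stack,
    gen_reserves,
    gen_templates,
    gen_world,
    generate_world,
)
from consplan.trends import piecewise_trend, reserve_series

from conftest import small_config


class TestGenWorld:
    def test_land_fraction_hit_to_the_cell(self):
        for frac in (0.3, 0.55, 1.0):
            cfg = WorldConfig(n_rows=40, n_cols=40, land_fraction=frac, n_provinces=5, seed=1)
            grid, *_ = gen_world(cfg)
            assert grid.land_mask.sum() == round(frac * 1600)

    def test_single_province_covers_all_land(self):
        cfg = WorldConfig(n_rows=30, n_cols=30, n_provinces=1, seed=2)
        grid, provinces, *_ = gen_world(cfg)
        land = grid.land_mask
        assert (provinces.zone_id[land] == 0).all()

    def test_every_land_cell_assigned_exactly_once(self, small_world):
        for part in (small_world.provinces, small_world.regions, small_world.biomes):
            land = small_world.grid.land_mask
            assert (part.zone_id[land] >= 0).all()
            assert (part.zone_id[~land] == -1).all()

    def test_impossible_config_rejected(self):
        with pytest.raises(ConfigError):
            WorldConfig(n_rows=4, n_cols=4, land_fraction=0.5, n_provinces=100)

    def test_same_seed_identical_partitions(self):
        cfg = small_config(seed=5)
        g1, p1, *_ = gen_world(cfg)
        g2, p2, *_ = gen_world(cfg)
        assert np.array_equal(g1.land_mask, g2.land_mask)
        assert np.array_equal(p1.zone_id, p2.zone_id)


class TestGenTemplates:
    def test_realized_shares_within_tolerance(self, small_world):
        for name, spec in small_world.cfg.templates.items():
            assert small_world.templates[name].p == pytest.approx(spec.share, abs=0.01)

    def test_half_share_on_uniform_noise(self):
        cfg = WorldConfig(
            n_rows=50, n_cols=50, land_fraction=1.0, n_provinces=4,
            templates={"T": TemplateSpec(0.5, corr_len=0.0)},
            seed=3,
        )
        grid, *_ = gen_world(cfg)
        ts = gen_templates(cfg, grid)
        assert ts["T"].p == pytest.approx(0.5, abs=0.01)

    def test_templates_deterministic_and_terrestrial(self, small_world):
        ts2 = gen_templates(small_world.cfg, small_world.grid)
        for t1, t2 in zip(small_world.templates, ts2):
            assert np.array_equal(t1.mask.values, t2.mask.values)
            assert not (t1.mask.values & ~small_world.grid.land_mask).any()


class TestGenReserves:
    def test_overlap_target_zero_gives_disjoint_networks(self):
        cfg = small_config(
            seed=8,
            networks={
                "PA": NetworkSpec(count=15, area_median=10.0),
                "BR": NetworkSpec(count=8, area_median=8.0, overlap_partner="PA", overlap_target=0.0),
            },
        )
        world = generate_world(cfg)
        inter = world.network_masks["PA"].values & world.network_masks["BR"].values
        assert not inter.any()

    def test_overlap_target_achieved_within_tolerance(self, small_world):
        br = small_world.network_masks["BR"]
        partner = union_masks([small_world.network_masks["PA"], small_world.network_masks["OECM"]])
        frac = (br.values & partner.values).sum() / br.values.sum()
        assert frac == pytest.approx(0.35, abs=0.05)

    def test_buffer_only_fraction_one_means_no_polygons(self):
        cfg = small_config(
            seed=9,
            networks={"BR": NetworkSpec(count=10, area_median=10.0, buffer_only_fraction=1.0)},
        )
        recs = gen_reserves(cfg, gen_world(cfg)[0])
        assert all(r.geometry is None for r in recs)

    def test_truth_reserve_areas_match_per_cell_scan(self, small_world):
        grid = small_world.grid
        for r in small_world.reserves[:10]:
            fp = rasterize_polygon(resolve_geometry(r), grid, terrestrial=True)
            assert small_world.truth.reserve_areas[r.id] == fp.values.sum()  # unit areas


class TestGenQuality:
    def test_noiseless_zero_slope_constant_stack(self):
        cfg = small_config(
            seed=10,
            networks={"BR": NetworkSpec(count=3, area_median=20.0)},
            trend=TrendSpec(slope_means=(0.0, 0.0, 0.0), slope_sds=(0.0, 0.0, 0.0),
                            noise_sd=0.0, background_amplitude=0.0),
        )
        world = generate_world(cfg)
        first = world.quality.layers[0].values
        for lyr in world.quality.layers[1:]:
            assert np.array_equal(
                np.nan_to_num(lyr.values), np.nan_to_num(first)
            )

    def test_noiseless_slopes_recovered_exactly(self):
        cfg = small_config(
            seed=11,
            networks={"BR": NetworkSpec(count=4, area_median=25.0)},
            trend=TrendSpec(slope_means=(1e-3, -2e-3, 5e-4), slope_sds=(5e-4,) * 3,
                            noise_sd=0.0, background_amplitude=0.0),
        )
        world = generate_world(cfg)
        for r in world.reserves:
            s = reserve_series(r, world.quality)
            if not s.defined:
                continue
            fits = piecewise_trend(s.values)
            by_period = dict(zip(cfg.trend.breaks, world.truth.reserve_slopes[r.id]))
            assert fits  # at least one sub-period has enough years
            for f in fits:
                assert f.slope == pytest.approx(by_period[f.period], abs=1e-10)

    def test_quality_bounded_unit_interval(self, small_world):
        for lyr in small_world.quality.layers:
            v = lyr.values[small_world.grid.land_mask]
            assert np.nanmin(v) >= 0.0 and np.nanmax(v) <= 1.0


class TestWorldTruthAndDeterminism:
    def test_full_world_byte_identical_under_seed(self):
        cfg = small_config(seed=12)
        w1, w2 = generate_world(cfg), generate_world(cfg)
        assert np.array_equal(w1.grid.land_mask, w2.grid.land_mask)
        for t1, t2 in zip(w1.templates, w2.templates):
            assert np.array_equal(t1.mask.values, t2.mask.values)
        for lyr1, lyr2 in zip(w1.quality.layers, w2.quality.layers):
            assert np.array_equal(np.nan_to_num(lyr1.values), np.nan_to_num(lyr2.values))
        assert np.array_equal(np.nan_to_num(w1.pressure.values), np.nan_to_num(w2.pressure.values))
        assert [r.centroid for r in w1.reserves] == [r.centroid for r in w2.reserves]
        assert w1.truth.coverage_pct == w2.truth.coverage_pct

    def test_truth_entries_rederivable_by_recount(self, small_world):
        """Every WorldTruth entry is reproduced by brute-force per-cell recount."""
        w = small_world
        grid = w.grid
        areas = grid.areas()
        land = grid.land_mask
        assert w.truth.land_area == areas[land].sum()
        for t in w.templates:
            share = areas[t.mask.values & land].sum() / w.truth.land_area
            assert w.truth.template_shares[t.name] == pytest.approx(share, abs=1e-12)
        for net, layer in w.network_masks.items():
            assert w.truth.network_areas[net] == areas[layer.values & land].sum()
        for key, val in w.truth.pairwise_overlap.items():
            a, b = key.split("|")
            ov = w.network_masks[a].values & w.network_masks[b].values & land
            assert val == areas[ov].sum()
        combined = union_masks(list(w.network_masks.values())).values & land
        assert w.truth.coverage_pct["global"] == pytest.approx(
            100 * areas[combined].sum() / w.truth.land_area
        )
        for zid in w.regions.ids:
            label = w.regions.zone_table[zid]
            zsel = (w.regions.zone_id == zid) & land
            if not zsel.any():
                continue
            expect = 100 * areas[zsel & combined].sum() / areas[zsel].sum()
            assert w.truth.coverage_pct[label] == pytest.approx(expect)
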