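"""Rarity weights (Eq-style oracle), CVI surface, sextile binning, priorities."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from consplan.cvi import (
    cvi_surface,
    minmax_standardize,
    province_summaries,
    rarity_weights,
    select_priorities,
    sextile_bins,
)
from consplan.errors import DataError
from consplan.grid import BinaryLayer, ContinuousLayer, GridSpec, ZonePartition
from consplan.templates import TemplateLayer, TemplateSet


def oracle_weights(shares):
    """Independent arbitrary-precision evaluation of the rarity weights."""
    inv = [Fraction(1, 1) / Fraction(str(p)) for p in shares]
    total = sum(inv)
    return [float(v / total) for v in inv]


class TestRarityWeights:
    def test_equal_shares_give_equal_weights(self):
        w = rarity_weights([1 / 6] * 6)
        assert w == pytest.approx([1 / 6] * 6, abs=1e-15)

    def test_published_share_magnitudes_against_oracle(self):
        # BH ~2.5% of land, PD 12.86%, TF 14.47%; the rest plausible
        p = [0.025, 0.1286, 0.1447, 0.30, 0.20, 0.10]
        w = rarity_weights(p)
        expect = oracle_weights(["0.025", "0.1286", "0.1447", "0.30", "0.20", "0.10"])
        assert np.max(np.abs(w - np.array(expect))) < 1e-12
        assert abs(w.sum() - 1.0) < 1e-12

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=12))
    def test_weights_sum_to_one_for_any_positive_shares(self, p):
        assert abs(rarity_weights(p).sum() - 1.0) < 1e-12

    def test_rarer_templates_weigh_more(self):
        w = rarity_weights([0.01, 0.5])
        assert w[0] > w[1]

    def test_zero_share_policies(self):
        with pytest.raises(DataError, match="template_1"):
            rarity_weights([0.5, 0.0])
        w = rarity_weights([0.5, 0.0, 0.25], zero_share_policy="drop")
        assert w[1] == 0.0
        assert abs(w.sum() - 1.0) < 1e-12
        assert w[2] == pytest.approx(2 * w[0])


def toy_templates():
    g = GridSpec(2, 2)
    a = np.array([[1, 1], [0, 0]], bool)
    b = np.array([[1, 0], [1, 0]], bool)
    return TemplateSet([TemplateLayer("a", BinaryLayer(g, a)), TemplateLayer("b", BinaryLayer(g, b))])


class TestCviSurface:
    def test_single_all_and_none_membership(self):
        ts = toy_templates()
        w = rarity_weights(ts)
        cvi = cvi_surface(ts, w)
        assert cvi.values[0, 0] == pytest.approx(1.0)  # hits both -> sum of all weights
        assert cvi.values[1, 1] == 0.0  # hits none
        assert cvi.values[0, 1] == pytest.approx(w[0])  # only template a
        assert cvi.values[1, 0] == pytest.approx(w[1])

    def test_invariant_to_template_ordering(self):
        ts = toy_templates()
        rev = TemplateSet(list(ts.templates[::-1]))
        c1 = cvi_surface(ts, rarity_weights(ts))
        c2 = cvi_surface(rev, rarity_weights(rev))
        assert np.allclose(c1.values, c2.values)

    def test_bounds_and_max_attained_iff_all_hit(self, small_world):
        ts = small_world.templates
        cvi = cvi_surface(ts, rarity_weights(ts))
        land = small_world.grid.land_mask
        v = cvi.values[land]
        assert ((v >= 0) & (v <= 1 + 1e-12)).all()
        stack = np.stack([t.mask.values for t in ts]).sum(axis=0)
        all_hit = stack[land] == ts.n
        assert np.allclose(v[all_hit], 1.0)
        assert (v[~all_hit] < 1.0 - 1e-12).all()


class TestMinmaxStandardize:
    def test_attains_zero_and_one(self):
        g = GridSpec(2, 2)
        out = minmax_standardize(ContinuousLayer(g, np.array([[1.0, 3.0], [2.0, 2.5]])))
        assert out.values.min() == 0.0 and out.values.max() == 1.0

    def test_constant_layer_maps_to_zero(self, caplog):
        g = GridSpec(2, 2)
        out = minmax_standardize(ContinuousLayer(g, np.full((2, 2), 7.0)))
        assert (out.values == 0.0).all()
        assert any("degenerate" in r.message for r in caplog.records)

    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 2**31 - 1))
    def test_affine_invariance(self, a, b, seed):
        g = GridSpec(5, 5)
        x = np.random.default_rng(seed).random(g.shape)
        s1 = minmax_standardize(ContinuousLayer(g, x)).values
        s2 = minmax_standardize(ContinuousLayer(g, a * x + b)).values
        assert np.allclose(s1, s2, atol=1e-9)

    def test_no_valid_cells_rejected(self):
        g = GridSpec(2, 2)
        with pytest.raises(DataError):
            minmax_standardize(ContinuousLayer(g, np.full((2, 2), np.nan)))


class TestProvinceSummaries:
    def setup_toy(self):
        g = GridSpec(2, 3)
        ids = np.array([[0, 0, 1], [0, 1, 1]])
        zones = ZonePartition(g, ids, {0: "west", 1: "east"})
        return g, zones

    def test_constant_value_and_full_network(self):
        g, zones = self.setup_toy()
        std = ContinuousLayer(g, np.full(g.shape, 0.4))
        net = g.land()
        s = province_summaries(std, net, zones)
        assert s["value"].to_numpy() == pytest.approx(0.4)
        assert (s["coverage_pct"] == 100.0).all()

    def test_two_province_hand_scan(self):
        g, zones = self.setup_toy()
        std = ContinuousLayer(g, np.array([[0.0, 0.6, 1.0], [0.3, 0.5, 0.1]]))
        net = BinaryLayer(g, np.array([[1, 0, 1], [0, 0, 0]], bool))
        s = province_summaries(std, net, zones)
        assert s.loc[0, "value"] == pytest.approx((0.0 + 0.6 + 0.3) / 3)
        assert s.loc[1, "value"] == pytest.approx((1.0 + 0.5 + 0.1) / 3)
        assert s.loc[0, "coverage_pct"] == pytest.approx(100 / 3)
        assert s.loc[1, "coverage_pct"] == pytest.approx(100 / 3)

    def test_mean_pressure_column(self):
        g, zones = self.setup_toy()
        std = ContinuousLayer(g, np.zeros(g.shape))
        pres = ContinuousLayer(g, np.full(g.shape, 12.0))
        s = province_summaries(std, g.land(), zones, pressure=pres)
        assert s["mean_pressure"].to_numpy() == pytest.approx(12.0)


def brute_force_bins(values: dict) -> dict:
    order = sorted(values, key=lambda i: (values[i], str(i)))
    n = len(order)
    return {idx: int(np.ceil(6 * (r + 1) / n)) for r, idx in enumerate(order)}


class TestSextileBins:
    def test_twelve_values_two_per_bin(self):
        vals = pd.Series({i: float(i) for i in range(1, 13)})
        bins = sextile_bins(vals)
        for i in range(1, 13):
            assert bins[i] == (i + 1) // 2

    def test_six_distinct_one_per_bin(self):
        vals = pd.Series({chr(97 + i): 10.0 - i for i in range(6)})
        bins = sextile_bins(vals)
        # order-preserving: smallest value -> Q1
        assert bins["f"] == 1 and bins["a"] == 6

    def test_all_equal_ties_stable_by_id(self):
        vals = pd.Series({f"z{i:02d}": 1.0 for i in range(12)})
        bins = sextile_bins(vals)
        expect = brute_force_bins(vals.to_dict())
        assert bins.to_dict() == expect
        assert bins["z00"] == 1 and bins["z11"] == 6

    @pytest.mark.parametrize("seed", range(10))
    def test_random_tables_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        vals = {f"p{i:03d}": float(rng.integers(0, 8)) for i in range(n)}  # forces ties
        assert sextile_bins(pd.Series(vals)).to_dict() == brute_force_bins(vals)

    def test_fewer_than_six_rejected(self):
        with pytest.raises(DataError):
            sextile_bins(pd.Series({1: 1.0, 2: 2.0}))


class TestSelectPriorities:
    def summaries(self, cov, val):
        n = len(cov)
        return pd.DataFrame(
            {
                "coverage_pct": cov,
                "value": val,
                "defined": [True] * n,
                "name": [f"p{i}" for i in range(n)],
            },
            index=range(n),
        )

    def test_rule_corners(self):
        # 12 provinces; coverage ascending, value descending -> low-coverage
        # provinces have high value: exactly the Q1-Q2 x Q5-Q6 overlap selected
        cov = list(range(12))
        val = list(range(12, 0, -1))
        out = select_priorities(self.summaries(cov, val))
        assert out["priority"].tolist() == [True] * 4 + [False] * 8
        sel = out[out["priority"]]
        assert set(sel["value_bin"]) <= {5, 6} and set(sel["coverage_bin"]) <= {1, 2}
        not_sel = out[~out["priority"]]
        assert not (
            not_sel["value_bin"].isin([5, 6]) & not_sel["coverage_bin"].isin([1, 2])
        ).any()

    def test_high_value_high_coverage_not_selected(self):
        cov = list(range(12))
        val = list(range(12))  # value rises with coverage: Q5-Q6 value sits in Q5-Q6 coverage
        out = select_priorities(self.summaries(cov, val))
        assert not out["priority"].any()

    def test_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(4)
        cov = rng.random(20) * 100
        val = rng.random(20)
        base = select_priorities(self.summaries(cov, val))
        warped = select_priorities(self.summaries(np.sqrt(cov), np.exp(3 * val)))
        assert base["priority"].tolist() == warped["priority"].tolist()

    def test_selected_at_most_q1q2_set_size(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            n = int(rng.integers(6, 50))
            out = select_priorities(self.summaries(rng.random(n), rng.random(n)))
            q12 = out["coverage_bin"].isin([1, 2]).sum()
            assert out["priority"].sum() <= q12
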