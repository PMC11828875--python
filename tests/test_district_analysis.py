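import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifeyears.district_analysis import (
    aggregate_characteristics,
    delta_vs_pre,
    effect_size_continuous,
    group_compare,
    group_compare_table,
    values_from_summary,
)


def _muni_table(rows):
    base = {
        "population_density": 100.0,
        "income_per_capita": 2.5e6,
        "medical_professionals": 300.0,
        "medical_institutions": 60.0,
        "pct_primary_industry": 10.0,
        "pct_aged_65plus": 28.0,
        "financial_capability_index": 0.5,
        "natural_growth_rate": -4.0,
        "net_migration_rate": -1.0,
    }
    return pd.DataFrame([{**base, **r} for r in rows])


class TestAggregateCharacteristics:
    def test_population_weighted_mean(self, small_dmap):
        t = _muni_table(
            [
                {"municipality": "M01", "population": 1000, "income_per_capita": 2.0},
                {"municipality": "M02", "population": 3000, "income_per_capita": 4.0},
                {"municipality": "M03", "population": 100, "income_per_capita": 9.9},
                {"municipality": "M04", "population": 100, "income_per_capita": 9.9},
            ]
        )
        out = aggregate_characteristics(t, small_dmap)
        d1 = out[out["district"] == 1].iloc[0]
        assert d1["income_per_capita"] == pytest.approx(3.5)
        assert d1["evacuation"] == 0
        assert out[out["district"] == 2].iloc[0]["evacuation"] == 1

    def test_financial_index_is_simple_mean(self, small_dmap):
        t = _muni_table(
            [
                {"municipality": "M01", "population": 1000, "financial_capability_index": 1.0},
                {"municipality": "M02", "population": 999_000, "financial_capability_index": 3.0},
                {"municipality": "M03", "population": 10, "financial_capability_index": 0.4},
                {"municipality": "M04", "population": 10, "financial_capability_index": 0.6},
            ]
        )
        out = aggregate_characteristics(t, small_dmap)
        assert out[out["district"] == 1].iloc[0]["financial_capability_index"] == pytest.approx(2.0)

    def test_single_municipality_identity(self, small_dmap):
        t = _muni_table(
            [
                {"municipality": "M01", "population": 500, "pct_primary_industry": 33.0},
                {"municipality": "M02", "population": 500, "pct_primary_industry": 33.0},
                {"municipality": "M03", "population": 700, "pct_primary_industry": 12.5},
                {"municipality": "M04", "population": 0, "pct_primary_industry": 99.0},
            ]
        )
        out = aggregate_characteristics(t, small_dmap)
        assert out[out["district"] == 2].iloc[0]["pct_primary_industry"] == pytest.approx(12.5)


class TestDeltaVsPre:
    def test_printed_prefecture_change(self):
        d = delta_vs_pre({"pre": 78.57, "early": 79.49})
        assert d["early"] == pytest.approx(0.92)

    def test_identical_periods_give_zero(self):
        assert delta_vs_pre({"pre": 5.0, "late": 5.0})["late"] == 0.0

    def test_decline_is_negative(self):
        d = delta_vs_pre({"pre": 1.09, "late": 0.82})
        assert d["late"] == pytest.approx(-0.27)

    def test_missing_pre_period_rejected(self):
        with pytest.raises(KeyError):
            delta_vs_pre({"early": 1.0})


class TestEffectSizeContinuous:
    def test_perfect_correlation(self):
        x = np.arange(5.0)
        res = effect_size_continuous(x, x)
        assert res.r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        res = effect_size_continuous(x, -2 * x + 3)
        assert res.r == pytest.approx(-1.0)

    def test_binary_x_hand_computed(self):
        res = effect_size_continuous(np.array([0, 0, 1, 1.0]), np.array([1, 2, 3, 4.0]))
        assert res.r == pytest.approx(2 / np.sqrt(5), abs=1e-6)
        assert res.r == pytest.approx(0.894427, abs=1e-6)
        assert res.df == 2

    def test_significance_flag_follows_half_rule(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=14)
        weak = effect_size_continuous(x, rng.normal(size=14))
        assert weak.significant == (abs(weak.r) > 0.5)
        strong = effect_size_continuous(x, x + rng.normal(scale=0.1, size=14))
        assert strong.significant

    def test_constant_characteristic_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            effect_size_continuous(np.ones(5), np.arange(5.0))


class TestGroupCompare:
    def test_published_summary_reconstruction(self):
        """Group samples rebuilt from printed means/SDs (n=3 evacuation vs
        n=11 non-evacuation) reproduce the published effect size and p."""
        evac = values_from_summary(1.64, 0.458, 3)
        nonevac = values_from_summary(0.88, 0.422, 11)
        res = group_compare(evac, nonevac)
        assert res.r == pytest.approx(0.615, abs=0.01)
        assert res.p == pytest.approx(0.02, abs=0.01)
        assert res.df == 12

    def test_equal_means_give_zero_effect(self):
        res = group_compare([1.0, 2.0, 3.0], [2.0, 2.0])
        assert res.t == pytest.approx(0.0)
        assert res.r == pytest.approx(0.0)

    def test_point_biserial_equals_pearson_with_dummy_coding(self):
        rng = np.random.default_rng(3)
        evac = rng.normal(1.0, 0.5, 3)
        nonevac = rng.normal(0.3, 0.5, 11)
        res = group_compare(evac, nonevac)
        x = np.r_[np.ones(3), np.zeros(11)]
        y = np.r_[evac, nonevac]
        res2 = effect_size_continuous(x, y)
        assert res.r == pytest.approx(res2.r, abs=1e-12)
        assert res.p == pytest.approx(res2.p, abs=1e-12)

    def test_undersized_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            group_compare([1.0], [1.0, 2.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=2, max_size=6),
        st.lists(st.floats(-10, 10), min_size=2, max_size=12),
    )
    def test_point_biserial_identity_property(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        if np.ptp(np.r_[a, b]) == 0 or (np.ptp(a) == 0 and np.ptp(b) == 0):
            return
        res = group_compare(a, b)
        x = np.r_[np.ones(len(a)), np.zeros(len(b))]
        res2 = effect_size_continuous(x, np.r_[a, b])
        assert res.r == pytest.approx(res2.r, abs=1e-9)


class TestValuesFromSummary:
    @pytest.mark.parametrize("mean,sd,n", [(1.64, 0.458, 3), (0.88, 0.422, 11), (0.0, 1.0, 4)])
    def test_summary_is_exact(self, mean, sd, n):
        v = values_from_summary(mean, sd, n)
        assert len(v) == n
        assert v.mean() == pytest.approx(mean, abs=1e-12)
        assert v.std(ddof=1) == pytest.approx(sd, abs=1e-12)


def test_group_compare_table_orientation(small_dmap):
    deltas = pd.DataFrame({"district": [1, 2], "d_x": [0.0, 1.0]})
    with pytest.raises(ValueError):
        # groups of one district each are too small for a pooled t
        group_compare_table(deltas, small_dmap.evacuation)
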