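"""Calibration, quantification, filtering, and blend-statistic unit tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scentdiel.gcms import (
    EmissionTable,
    apply_inclusion_filters,
    benjamini_hochberg,
    blend_composition,
    filter_contaminants,
    fit_calibration,
    mann_whitney,
    occurrence_filter,
    quantify_and_standardize,
    retention_index,
)


class TestRetentionIndex:
    @pytest.mark.parametrize(
        "rt,expected",
        [(11.0, 850.0), (10.0, 800.0), (12.0, 900.0), (13.25, 950.0)],
    )
    def test_linear_interpolation(self, simple_ladder, rt, expected):
        assert retention_index(rt, simple_ladder) == pytest.approx(expected)

    def test_ladder_alkanes_self_index(self, simple_ladder):
        for _, row in simple_ladder.iterrows():
            ri = retention_index(row["rt_min"], simple_ladder)
            assert ri == pytest.approx(100 * row["carbon_number"])

    def test_out_of_range_rejected(self, simple_ladder):
        with pytest.raises(ValueError, match="outside ladder range"):
            retention_index(7.0, simple_ladder)
        with pytest.raises(ValueError, match="outside ladder range"):
            retention_index(15.0, simple_ladder)

    @given(st.lists(st.floats(8.0, 14.5), min_size=2, max_size=20))
    def test_monotone_in_retention_time(self, rts):
        ladder = pd.DataFrame(
            {"carbon_number": [7, 8, 9, 10], "rt_min": [8.0, 10.0, 12.0, 14.5]}
        )
        rts = sorted(rts)
        ris = [retention_index(rt, ladder) for rt in rts]
        assert all(b >= a for a, b in zip(ris, ris[1:]))


class TestCalibration:
    def test_exact_proportional_data(self):
        mass = np.array([1.0, 10.0, 100.0])
        table = pd.DataFrame(
            {"standard": "s", "compound_class": "x", "mass_ng": mass, "response": 2 * mass}
        )
        model = fit_calibration(table)
        slope, intercept = model.curves["s"]
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(np.log10(2.0))
        assert model.mass_from_response("s", 10.0) == pytest.approx(5.0)

    def test_four_decades_exact(self):
        mass = np.array([1.0, 10.0, 100.0, 1000.0])
        table = pd.DataFrame(
            {"standard": "s", "compound_class": "x", "mass_ng": mass, "response": 7 * mass}
        )
        model = fit_calibration(table)
        np.testing.assert_allclose(
            model.predict_response("s", mass), 7 * mass, rtol=1e-12
        )
        # inverse o forward is identity on the fitted grid
        np.testing.assert_allclose(
            model.mass_from_response("s", model.predict_response("s", mass)),
            mass,
            rtol=1e-9,
        )

    def test_noisy_slope_within_3se(self):
        rng = np.random.default_rng(5)
        mass = np.logspace(0, 3, 12)
        true_slope = 0.97
        logresp = 2.0 + true_slope * np.log10(mass) + rng.normal(0, 0.05, mass.size)
        table = pd.DataFrame(
            {
                "standard": "s",
                "compound_class": "x",
                "mass_ng": mass,
                "response": 10**logresp,
            }
        )
        model = fit_calibration(table)
        from scipy.stats import linregress

        ref = linregress(np.log10(mass), logresp)
        assert abs(model.curves["s"][0] - true_slope) < 3 * ref.stderr

    @pytest.mark.parametrize(
        "mass,resp,err",
        [([1, 10], [1, 10], "fewer than 3"), ([1, 10, 0], [1, 10, 5], "non-positive")],
    )
    def test_invalid_inputs(self, mass, resp, err):
        table = pd.DataFrame(
            {"standard": "s", "compound_class": "x", "mass_ng": mass, "response": resp}
        )
        with pytest.raises(ValueError, match=err):
            fit_calibration(table)


class TestQuantify:
    @pytest.fixture
    def identity_cal(self):
        mass = np.array([1.0, 10.0, 100.0, 1000.0])
        table = pd.DataFrame(
            {"standard": "s", "compound_class": "x", "mass_ng": mass, "response": mass}
        )
        return fit_calibration(table, {"x": "s"})

    def test_rate_arithmetic(self, identity_cal):
        areas = pd.DataFrame({"cmp": [100.0]})
        meta = pd.DataFrame({"flowers_open": [10], "duration_h": [0.5]})
        out = quantify_and_standardize(areas, identity_cal, {"cmp": "x"}, meta)
        assert out.rates.loc[0, "cmp"] == pytest.approx(20.0)

    def test_zero_response_gives_zero_rate(self, identity_cal):
        areas = pd.DataFrame({"cmp": [0.0]})
        meta = pd.DataFrame({"flowers_open": [5], "duration_h": [1.0]})
        out = quantify_and_standardize(areas, identity_cal, {"cmp": "x"}, meta)
        assert out.rates.loc[0, "cmp"] == 0.0

    def test_linear_in_response_inverse_in_flowers_duration(self, identity_cal):
        meta1 = pd.DataFrame({"flowers_open": [2], "duration_h": [1.0]})
        meta2 = pd.DataFrame({"flowers_open": [4], "duration_h": [2.0]})
        r1 = quantify_and_standardize(
            pd.DataFrame({"cmp": [40.0]}), identity_cal, {"cmp": "x"}, meta1
        ).rates.loc[0, "cmp"]
        r2 = quantify_and_standardize(
            pd.DataFrame({"cmp": [80.0]}), identity_cal, {"cmp": "x"}, meta1
        ).rates.loc[0, "cmp"]
        r3 = quantify_and_standardize(
            pd.DataFrame({"cmp": [40.0]}), identity_cal, {"cmp": "x"}, meta2
        ).rates.loc[0, "cmp"]
        assert r2 == pytest.approx(2 * r1)
        assert r3 == pytest.approx(r1 / 4)

    def test_missing_class_named(self, identity_cal):
        areas = pd.DataFrame({"mystery": [1.0]})
        meta = pd.DataFrame({"flowers_open": [1], "duration_h": [1.0]})
        with pytest.raises(KeyError, match="mystery"):
            quantify_and_standardize(areas, identity_cal, {}, meta)


def _table(rates: dict, **meta_cols) -> EmissionTable:
    rates_df = pd.DataFrame(rates, dtype=float)
    n = len(rates_df)
    meta = pd.DataFrame(meta_cols if meta_cols else {"sample_id": range(n)})
    return EmissionTable(meta.iloc[:n].reset_index(drop=True), rates_df)


class TestInclusionFilters:
    def test_threshold_rules(self):
        table = _table({"good": [1, 1, 1], "weak_match": [1, 1, 1],
                        "low_abund": [1, 1, 1], "singleton": [1, 0, 0]})
        abund = pd.DataFrame(
            {
                "good": [150000, 10, 10],
                "weak_match": [150000, 10, 10],
                "low_abund": [120000, 10, 10],  # not strictly greater
                "singleton": [150000, 0, 0],
            }
        )
        scores = {"good": 0.80, "weak_match": 0.75, "low_abund": 0.9, "singleton": 0.9}
        out, report = apply_inclusion_filters(table, abund, scores)
        assert out.compounds == ["good"]
        removed = {r["compound"]: r["rules"][0] for r in report}
        assert "not > 0.75" in removed["weak_match"]  # strictly greater than
        assert "not > 120000" in removed["low_abund"]
        assert "fewer than 2" in removed["singleton"]


class TestContaminantFilter:
    def test_bh_hand_example(self):
        # step-up on (0.01, 0.02, 0.04): adjusted (0.03, 0.03, 0.04)
        _, p_adj = benjamini_hochberg([0.01, 0.02, 0.04])
        np.testing.assert_allclose(p_adj, [0.03, 0.03, 0.04])

    def test_bh_matches_step_up_definition(self):
        """Adjusted p's agree with the direct step-up definition on random
        p-vectors, and sorted adjusted values are nondecreasing."""
        rng = np.random.default_rng(3)
        for _ in range(1000):
            m = int(rng.integers(1, 12))
            p = rng.random(m)
            reject, p_adj = benjamini_hochberg(p, alpha=0.05)
            order = np.argsort(p)
            ranked = p[order] * m / np.arange(1, m + 1)
            expect = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
            np.testing.assert_allclose(p_adj[order], expect, rtol=1e-12)
            assert np.all(np.diff(p_adj[order]) >= -1e-15)
            # rejection set: all p <= largest p_(k) with p_(k) <= k/m * alpha
            ks = np.nonzero(p[order] <= np.arange(1, m + 1) / m * 0.05)[0]
            thresh = p[order][ks[-1]] if ks.size else -1.0
            np.testing.assert_array_equal(reject, p <= thresh)

    def test_identical_floral_and_control_removed(self):
        floral = _table({"c": [1.0, 1.0, 1.0]})
        controls = _table({"c": [1.0, 1.0, 1.0]})
        out, report = filter_contaminants(floral, controls)
        assert out.compounds == []

    def test_exclusion_overrides_significance(self):
        floral = _table({"wound": [5.0, 6.0, 5.5, 6.5]})
        controls = _table({"wound": [0.01, 0.02]})
        out, _ = filter_contaminants(floral, controls, exclusions=["wound"])
        assert "wound" not in out.compounds

    def test_absent_from_controls_treated_as_zero(self):
        floral = _table({"floral_only": [5.0, 6.0, 5.5, 6.5]})
        controls = _table({"other": [1.0, 1.0]})
        out, report = filter_contaminants(floral, controls)
        assert out.compounds == ["floral_only"]
        assert any("level 0 assumed" in r["rules"][0] for r in report)

    def test_contaminant_at_control_level_removed(self):
        rng = np.random.default_rng(1)
        floral = _table({"cont": 1.0 + 0.1 * rng.standard_normal(10)})
        controls = _table({"cont": 1.2 + 0.1 * rng.standard_normal(10)})
        out, _ = filter_contaminants(floral, controls)
        assert "cont" not in out.compounds


class TestBlendComposition:
    def test_proportions_sum_to_one(self, blend_table):
        rng = np.random.default_rng(2)
        rates = pd.DataFrame(rng.gamma(1, 1, (6, 5)), columns=list("abcde"))
        table = EmissionTable(pd.DataFrame({"species": ["k"] * 6}), rates)
        props, _ = blend_composition(table)
        assert props["k"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_uniform_blend_shannon(self):
        table = _table({c: [1.0] for c in "abcd"})
        _, shannon = blend_composition(table)
        assert shannon[0] == pytest.approx(np.log(4))

    def test_single_compound_shannon_zero(self):
        table = _table({"a": [3.0], "b": [0.0]})
        _, shannon = blend_composition(table)
        assert shannon[0] == pytest.approx(0.0)

    def test_all_zero_sample_missing(self):
        table = _table({"a": [1.0, 0.0], "b": [1.0, 0.0]})
        _, shannon = blend_composition(table)
        assert np.isnan(shannon[1])


class TestOccurrenceFilter:
    def test_either_species_rule(self):
        meta = pd.DataFrame({"species": ["a"] * 5 + ["b"] * 5})
        rates = pd.DataFrame(
            {
                "b_only": [0, 0, 0, 0, 0, 1, 1, 1, 0, 0],  # 60% of b
                "boundary": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],  # 40% of a -> kept
                "rare": [0, 0, 0, 0, 0, 1, 0, 0, 0, 0],  # 20% of b, strict > -> dropped
            },
            dtype=float,
        )
        table = EmissionTable(meta, rates)
        kept = occurrence_filter(table, threshold=0.20)
        assert kept == ["b_only", "boundary"]

    def test_exact_threshold_dropped(self):
        meta = pd.DataFrame({"species": ["a"] * 5 + ["b"] * 5})
        rates = pd.DataFrame({"at20": [1, 0, 0, 0, 0, 1, 0, 0, 0, 0]}, dtype=float)
        table = EmissionTable(meta, rates)
        assert occurrence_filter(table, threshold=0.20) == []  # strict >


class TestMannWhitney:
    def test_exact_matches_enumeration(self):
        """Exact p equals full enumeration of group assignments (n <= 6)."""
        rng = np.random.default_rng(8)
        for _ in range(20):
            na, nb = rng.integers(2, 7, 2)
            pooled = rng.permutation(np.arange(1.0, na + nb + 1))  # no ties
            a, b = pooled[:na], pooled[na:]
            u_obs, p_obs = mann_whitney(a, b)

            def u_stat(x, y):
                return sum((xi > yi) for xi in x for yi in y)

            pooled_sorted = np.sort(pooled)
            stats_null = []
            for combo in itertools.combinations(range(na + nb), na):
                mask = np.zeros(na + nb, bool)
                mask[list(combo)] = True
                stats_null.append(u_stat(pooled_sorted[mask], pooled_sorted[~mask]))
            stats_null = np.array(stats_null)
            mu = na * nb / 2
            extreme = np.abs(stats_null - mu) >= abs(u_stat(a, b) - mu) - 1e-12
            assert p_obs == pytest.approx(extreme.mean(), abs=1e-12)

    def test_small_example(self):
        u, p = mann_whitney([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups(self):
        _, p = mann_whitney([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_type_one_error_rate(self):
        """Rejection rate at alpha=0.05 under the null stays in the exact
        binomial 99% interval (normal-approximation path, n=20 per group)."""
        from scipy.stats import binom

        rng = np.random.default_rng(17)
        n_sim = 1000
        rejections = 0
        for _ in range(n_sim):
            a = rng.standard_normal(20)
            b = rng.standard_normal(20)
            _, p = mann_whitney(a, b)
            rejections += p <= 0.05
        lo = binom.ppf(0.005, n_sim, 0.05)
        hi = binom.ppf(0.995, n_sim, 0.05)
        assert lo <= rejections <= hi
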