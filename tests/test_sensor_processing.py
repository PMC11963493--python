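"""Sensor cleaning chain and daily summarisation rules."""

import numpy as np
import pandas as pd
import pytest

from drydown.sensor_processing import (
    QUALITY_OK,
    QUALITY_REMOVED,
    QUALITY_REPLACED,
    MAD_CONSISTENCY,
    baseline_correct,
    clean_negative_excursions,
    compute_vpd,
    hampel_filter,
    heat_velocity_to_sapflux,
    nearest_rank_percentile,
    saturation_vapour_pressure,
    summarize_daily,
)


def brute_force_hampel(values, halfwidth, n_mad):
    """Independent per-window oracle for the Hampel filter."""
    v = np.asarray(values, dtype=float)
    out = v.copy()
    flagged = np.zeros(v.size, dtype=bool)
    for i in range(v.size):
        w = v[max(0, i - halfwidth): i + halfwidth + 1]
        med = np.median(w)
        mad = np.median(np.abs(w - med))
        if abs(v[i] - med) > n_mad * MAD_CONSISTENCY * mad:
            out[i] = med
            flagged[i] = True
    return out, flagged


class TestVPD:
    def test_saturated_air_gives_zero(self):
        for t in (-5.0, 10.0, 25.0, 40.0):
            assert compute_vpd(t, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_twenty_degrees_half_humidity(self):
        assert compute_vpd(20.0, 50.0) == pytest.approx(1.169, abs=1e-3)

    def test_dry_air_equals_saturation_pressure(self):
        assert compute_vpd(25.0, 0.0) == pytest.approx(
            saturation_vapour_pressure(25.0))

    def test_rh_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            compute_vpd(20.0, 105.0)


class TestExcursionRemoval:
    def test_clean_series_unchanged(self, make_series):
        s = clean_negative_excursions(make_series([0.5, 1.0, 2.0]), -5.0)
        assert s.removed_fraction == 0.0
        assert list(s.quality) == [QUALITY_OK] * 3

    def test_threshold_must_be_negative(self, make_series):
        with pytest.raises(ValueError):
            clean_negative_excursions(make_series([1.0, 2.0]), 0.0)

    def test_generator_excursion_mask_recovered(self, default_sim):
        # ground-truth injection masks are recovered exactly by thresholding
        truth, ds = default_sim
        for tree in ds.trees:
            hv = ds.sensors[tree]["heat_velocity"]
            cleaned = clean_negative_excursions(hv, -5.0)
            injected = ds.artifact_truth[tree]["excursion"]
            got = cleaned.quality == QUALITY_REMOVED
            np.testing.assert_array_equal(got, injected)


class TestHampel:
    def test_constant_with_spike(self, make_series):
        s = hampel_filter(make_series([1, 1, 1, 10, 1, 1, 1]),
                          window_halfwidth=3, n_mad=3.0)
        assert s.values.tolist() == [1.0] * 7
        assert s.quality[3] == QUALITY_REPLACED

    def test_linear_ramp_untouched(self, make_series):
        ramp = np.linspace(0.0, 10.0, 50)
        s = hampel_filter(make_series(ramp), window_halfwidth=6, n_mad=3.0)
        np.testing.assert_array_equal(s.values, ramp)
        assert s.replaced_fraction == 0.0

    @pytest.mark.parametrize("n,halfwidth", [(20, 2), (100, 6), (200, 10)])
    def test_matches_brute_force_oracle(self, make_series, n, halfwidth):
        rng = np.random.default_rng(n)
        values = np.sin(np.arange(n) / 8.0) + rng.normal(0, 0.2, n)
        values[rng.integers(0, n, 5)] += 8.0
        got = hampel_filter(make_series(values), halfwidth, 3.0)
        expected, flagged = brute_force_hampel(values, halfwidth, 3.0)
        np.testing.assert_allclose(got.values, expected)
        np.testing.assert_array_equal(got.quality == QUALITY_REPLACED,
                                      flagged)

    def test_window_larger_than_series_rejected(self, make_series):
        with pytest.raises(ValueError):
            hampel_filter(make_series([1.0, 2.0, 3.0]), 5, 3.0)

    def test_decisions_shift_invariant(self, make_series):
        # baseline correction after/before Hampel flags the same points
        rng = np.random.default_rng(9)
        values = 5.0 + np.sin(np.arange(80) / 5.0) + rng.normal(0, 0.3, 80)
        values[[10, 40]] += 6.0
        a = hampel_filter(baseline_correct(make_series(values)), 6, 3.0)
        b = baseline_correct(hampel_filter(make_series(values), 6, 3.0))
        np.testing.assert_array_equal(a.quality, b.quality)


class TestSapfluxAndBaseline:
    def test_area_multiplication(self, make_series):
        s = heat_velocity_to_sapflux(make_series([10.0, 0.0]), 5.0)
        assert s.values.tolist() == [50.0, 0.0]
        assert s.unit == "cm3 h-1"

    def test_linearity_in_area(self, make_series):
        v = np.array([1.0, 2.5, 7.0])
        a = heat_velocity_to_sapflux(make_series(v), 4.0).values
        b = heat_velocity_to_sapflux(make_series(v), 8.0).values
        np.testing.assert_allclose(b, 2 * a)

    def test_missing_area_names_tree(self, make_series):
        with pytest.raises(ValueError, match="T7"):
            heat_velocity_to_sapflux(make_series([1.0], tree_id="T7"),
                                     float("nan"))

    def test_baseline_examples(self, make_series):
        s = baseline_correct(make_series([-2.0, 3.0, 5.0]))
        assert s.values.tolist() == [0.0, 5.0, 7.0]
        t = baseline_correct(make_series([0.0, 3.0, 5.0]))
        assert t.values.tolist() == [0.0, 3.0, 5.0]

    def test_baseline_shift_invariance(self, make_series):
        v = np.array([0.3, 1.2, 4.0, 2.2])
        a = baseline_correct(make_series(v)).values
        b = baseline_correct(make_series(v + 17.3)).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_all_removed_rejected(self, make_series):
        s = make_series([1.0, 2.0], quality=[QUALITY_REMOVED] * 2)
        with pytest.raises(ValueError):
            baseline_correct(s)


class TestNearestRank:
    def test_alternating_stem_water_content(self):
        values = [40.0, 60.0] * 48
        assert nearest_rank_percentile(values, 95.0) == 60.0
        assert nearest_rank_percentile(values, 5.0) == 40.0

    def test_small_samples(self):
        assert nearest_rank_percentile([3.0, 1.0, 2.0], 50.0) == 2.0
        assert nearest_rank_percentile([5.0], 95.0) == 5.0


class TestSummarizeDaily:
    def test_rules_on_generated_experiment(self, default_sim):
        truth, ds = default_sim
        from drydown.sensor_processing import clean_sap_flow

        for tree in ds.trees:
            ds.sensors[tree]["sap_flux"] = clean_sap_flow(
                ds.sensors[tree]["heat_velocity"], ds.sapwood_area(tree))
        summary = summarize_daily(ds)
        tab = summary.per_tree[ds.trees[0]]
        cfg = truth.config

        # sampling-day-only variables are missing, not zero, elsewhere
        non_sampling = [d for d in range(cfg.n_days)
                        if d not in cfg.sampling_days]
        assert tab.loc[non_sampling, "soil_moisture"].isna().all()
        assert tab.loc[list(cfg.sampling_days), "soil_moisture"].notna().all()

        # percentile ordering and non-decreasing cumulative loss
        ok = tab["stem_water_min"].notna()
        assert (tab.loc[ok, "stem_water_min"]
                <= tab.loc[ok, "stem_water_max"]).all()
        loss = tab["cumulative_leaf_loss"].dropna().to_numpy()
        assert np.all(np.diff(loss) >= 0)

        # leaf-loss rule: running sum of the tree's records
        ll = ds.leaf_loss[ds.leaf_loss["tree_id"] == ds.trees[0]]
        upto = ll[ll["day"] <= 12]["area_cm2"].sum()
        assert tab.loc[12, "cumulative_leaf_loss"] == pytest.approx(upto)

        # daylight mean of a constant series is that constant
        flux = ds.sensors[ds.trees[0]]["sap_flux"]
        const = flux.with_data(values=np.full(len(flux), 50.0))
        ds.sensors[ds.trees[0]]["sap_flux"] = const
        summary2 = summarize_daily(ds)
        sap = summary2.per_tree[ds.trees[0]]["sap_flow"].dropna()
        assert np.allclose(sap, 50.0)
        ds.sensors[ds.trees[0]]["sap_flux"] = flux

    def test_invariant_to_within_day_record_order(self, default_sim):
        truth, ds = default_sim
        base = summarize_daily(ds)
        shuffled = ds.water_potential.sample(frac=1.0, random_state=1)
        ds2 = ds
        orig = ds.water_potential
        try:
            ds2.water_potential = shuffled
            again = summarize_daily(ds2)
        finally:
            ds2.water_potential = orig
        pd.testing.assert_frame_equal(base.pooled, again.pooled)
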