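"""Generator contracts: meteorology ranges, mass balances, limits, artifacts."""

import numpy as np
import pytest

from drydown.sensor_processing import compute_vpd
from drydown.synthetic_data import (
    ExperimentConfig,
    generate_meteorology,
    inject_sensor_artifacts,
    simulate_drydown,
)


class TestConfig:
    def test_invalid_timestep_rejected(self):
        with pytest.raises(ValueError, match="timestep"):
            ExperimentConfig(timestep_min=7)

    def test_rewater_day_bound(self):
        with pytest.raises(ValueError):
            ExperimentConfig(rewater_day=20, n_days=16)

    def test_nonfinite_tracer_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(tracer_deep_dD=float("nan"))

    def test_nonpositive_capacitance_rejected(self):
        with pytest.raises(ValueError):
            ExperimentConfig(stem_capacity_cm3=0.0)

    def test_round_trip_dict(self):
        cfg = ExperimentConfig(seed=5, n_trees=3)
        assert ExperimentConfig.from_dict(cfg.to_dict()) == cfg


class TestMeteorology:
    def test_zero_jitter_identical_days(self):
        cfg = ExperimentConfig(met_jitter=0.0)
        met = generate_meteorology(cfg)
        daily_max = met["vpd"].groupby(met.index.normalize()).max()
        assert np.allclose(daily_max, daily_max.iloc[0])

    def test_default_ranges(self):
        met = generate_meteorology(ExperimentConfig(seed=11))
        assert met["vpd"].min() >= 0.2 - 1e-9
        assert met["vpd"].max() <= 1.75 + 1e-9
        daily_hi = met["temperature"].groupby(met.index.normalize()).max()
        daily_lo = met["temperature"].groupby(met.index.normalize()).min()
        assert daily_hi.between(18.0, 25.0).all()
        assert daily_lo.between(12.0, 15.0).all()
        assert met["irradiance"].max() <= 1050.0

    def test_vpd_consistent_with_t_and_rh(self):
        met = generate_meteorology(ExperimentConfig(seed=4))
        np.testing.assert_allclose(
            met["vpd"], compute_vpd(met["temperature"], met["rh"]),
            rtol=1e-12)

    def test_same_seed_bit_identical(self):
        cfg = ExperimentConfig()
        a = generate_meteorology(cfg, seed=9)
        b = generate_meteorology(cfg, seed=9)
        assert a.equals(b)


class TestSimulation:
    def test_water_mass_balance_closes(self, default_sim):
        truth, _ = default_sim
        assert truth.water_balance_error() < 1e-6

    def test_isotope_mass_balance_closes(self, default_sim):
        truth, _ = default_sim
        assert truth.isotope_balance_error() < 1e-4

    def test_uptake_fractions_on_simplex(self, default_sim):
        truth, _ = default_sim
        f = truth.uptake_fractions()
        sums = np.nansum(f, axis=2)[~np.isnan(f).all(axis=2)[:, :]]
        active = truth.uptake.sum(axis=2) > 0
        np.testing.assert_allclose(f[active].sum(axis=1), 1.0, atol=1e-9)
        assert np.nanmin(f) >= 0.0

    def test_theta_within_bounds_and_stress_in_unit_interval(self,
                                                             default_sim):
        truth, _ = default_sim
        cfg = truth.config
        assert truth.theta.min() >= cfg.theta_r - 1e-9
        assert truth.theta.max() <= cfg.theta_s + 1e-9
        assert truth.stress_factor.min() >= 0.0
        assert truth.stress_factor.max() <= 1.0

    def test_monotone_drying_without_rewatering(self):
        cfg = ExperimentConfig(seed=2, n_days=12, rewater_day=12,
                               rewater_volume_l=0.0,
                               rewater_tracer_volume_l=0.0, n_trees=2)
        truth, _ = simulate_drydown(cfg)
        # after the day-0 tracer events, every layer can only lose water
        start = cfg.steps_per_day  # from day 1 onward
        dtheta = np.diff(truth.theta[start:], axis=0)
        assert dtheta.max() <= 1e-12

    def test_drydown_then_partial_recovery_with_decoupled_potentials(self):
        # strong stress memory: day-15 flux below day-2 flux for most trees
        # while day-12 predawn potential has recovered to near zero
        cfg = ExperimentConfig(seed=6, legacy_tau_days=16.0, met_jitter=0.0)
        truth, _ = simulate_drydown(cfg)
        daily = truth.daily_table()
        t2 = daily[daily.day == 2].set_index("tree_id").transpiration_cm3
        t15 = daily[daily.day == 15].set_index("tree_id").transpiration_cm3
        assert (t15 < t2).mean() >= 0.5
        assert daily[daily.day == 12].psi_pd.max() > -0.25
        assert daily[daily.day == 8].psi_pd.min() < -1.0

    def test_legacy_limit_recovers_no_memory_trajectory(self):
        # as tau -> 0 the post-rewatering fluxes approach the run with the
        # stress mechanism disabled, and recover within a day of rewatering
        spd = ExperimentConfig().steps_per_day
        base = dict(seed=8, met_jitter=0.0, n_trees=2)
        cfg_fast = ExperimentConfig(legacy_tau_days=1e-4, **base)
        cfg_none = ExperimentConfig(stress_rate=0.0, **base)
        fast, _ = simulate_drydown(cfg_fast)
        none, _ = simulate_drydown(cfg_none)
        day = slice(11 * spd, 12 * spd)
        t_fast = fast.transpiration[day].sum(axis=0)
        t_none = none.transpiration[day].sum(axis=0)
        np.testing.assert_allclose(t_fast, t_none, rtol=0.05)
        # recovered to pre-drydown magnitude within a day of rewatering
        t_early = fast.transpiration[1 * spd: 2 * spd].sum(axis=0)
        assert np.all(t_fast > 0.8 * t_early)


class TestArtifacts:
    def test_identity_at_zero_rates(self, make_series):
        s = make_series(np.linspace(0, 5, 40))
        out, masks = inject_sensor_artifacts(s, 0.0, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, s.values)
        assert not masks["spike"].any() and not masks["excursion"].any()

    def test_excursion_rate_near_nominal(self, make_series):
        n = 20000
        s = make_series(np.full(n, 5.0))
        _, masks = inject_sensor_artifacts(s, 0.0, 0.004, 0.1, seed=3)
        frac = masks["excursion"].mean()
        # 0.4% +/- 4 binomial standard errors
        se = np.sqrt(0.004 * 0.996 / n)
        assert abs(frac - 0.004) < 4 * se

    def test_same_seed_identical(self, make_series):
        s = make_series(np.linspace(0, 5, 200))
        a, ma = inject_sensor_artifacts(s, 0.14, 0.004, 0.3, seed=7)
        b, mb = inject_sensor_artifacts(s, 0.14, 0.004, 0.3, seed=7)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(ma["spike"], mb["spike"])
        np.testing.assert_array_equal(ma["excursion"], mb["excursion"])

    def test_invalid_rates_rejected(self, make_series):
        s = make_series([1.0, 2.0])
        with pytest.raises(ValueError):
            inject_sensor_artifacts(s, 1.5, 0.0, 0.1)
        with pytest.raises(ValueError):
            inject_sensor_artifacts(s, 0.1, 0.0, -0.1)

    def test_masks_disjoint(self, make_series):
        s = make_series(np.full(5000, 3.0))
        _, masks = inject_sensor_artifacts(s, 0.2, 0.05, 0.2, seed=5)
        assert not (masks["spike"] & masks["excursion"]).any()
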