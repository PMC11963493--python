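"""Synthetic drydown-rewatering experiments with known ground truth.

The generator emulates the study design the analysis assumes: ~6 replicate
potted trees on a 0-60 cm layered soil column, a 10-day drydown after a
dual-tracer application (an :sup:`18`\\ O-enriched surface watering and a
D-enriched injection at ~29 cm), rewatering with unlabelled tap water plus
a second surface D tracer on day 10, and a ~6-day recovery, with intensive
sampling days {2, 5, 8, 12, 15}.

The dynamics are a deliberately simple layered bucket model driven by
sinusoidal meteorology: transpiration demand responds to VPD, light, a
soil-water-potential stomatal factor and a stress-legacy factor s(t) in
[0, 1]; per-layer uptake is proportional to root fraction times layer
wetness; the stem is a finite capacitor whose storage imbalance produces
diurnal stem-water-content cycles and whose isotope pool mixes with a
finite residence time (so immediately after rewatering the stem still
carries drydown-enriched water).  s(t) declines with accumulated low water
potential and relaxes back to 1 after rewatering with time constant
``legacy_tau_days``, producing the delayed, partial sap-flow recovery while
predawn water potential recovers immediately.  Water and heavy-isotope mass
balances close to float precision by construction; uptake is
non-fractionating and mixing is delta-linear.

None of this is meant as soil-physics realism (no Richards flow, piston
infiltration, no evaporative fractionation); the generator targets the
statistical structure the downstream cleaning, mixing-inversion and
mutual-information stages need for verification against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import Dataset, save_dataset
from .sensor_processing import SensorSeries, compute_vpd, saturation_vapour_pressure

__all__ = [
    "ExperimentConfig",
    "SyntheticTruth",
    "generate_meteorology",
    "simulate_drydown",
    "inject_sensor_artifacts",
    "write_dataset",
]


@dataclass
class ExperimentConfig:
    """Design and generator constants of one synthetic experiment.

    Tracer compositions, timeline, sampling days, replicate count and the
    organ P50s default to the study conditions; the remaining constants are
    generator choices (documented in the methods note) sized so fluxes,
    water contents and potentials fall in the observed ranges.
    """

    # design / timeline
    n_trees: int = 6
    n_days: int = 16
    timestep_min: int = 15
    n_layers: int = 6
    layer_thickness_cm: float = 10.0
    sampling_days: tuple = (2, 5, 8, 12, 15)
    gas_exchange_days: tuple = (2, 5, 12)
    rewater_day: int = 10
    start_date: str = "2021-07-06"
    seed: int = 0
    # tracers and irrigation water (deltas permil vs VSMOW, volumes litres)
    tracer_surface_d18O: float = 100.0
    tracer_surface_dD: float = -88.0
    tracer_surface_volume_l: float = 5.5
    tracer_deep_dD: float = 350.0
    tracer_deep_d18O: float = -12.2
    tracer_deep_depth_cm: float = 29.0  # injection ports 28-30 cm down
    tracer_deep_volume_l: float = 8.3
    tracer_mixing_efficiency: float = 1.0  # fraction of tracer reaching soil water
    rewater_d18O: float = -12.2
    rewater_dD: float = -88.0
    rewater_volume_l: float = 15.0
    rewater_tracer_dD: float = 350.0
    rewater_tracer_d18O: float = -12.2
    rewater_tracer_volume_l: float = 4.0
    # plant traits
    p50_leaf: float = -2.53  # MPa
    p50_stem: float = -1.48  # MPa
    legacy_tau_days: float = 16.0
    # soil column
    soil_volume_cm3: float = 80_000.0
    theta_s: float = 40.0  # % v/v
    theta_r: float = 5.0
    theta_init: float = 12.0
    root_decay_cm: float = 20.0  # e-folding depth of the root profile
    # background (pre-tracer) soil water isotopes: evaporation-enriched
    # surface grading to depleted depth, linear in depth
    background_d18O_top: float = -6.0
    background_d18O_bottom: float = -14.0
    background_dD_top: float = -55.0
    background_dD_bottom: float = -95.0
    # plant water transport
    g_max: float = 600.0  # cm3 h-1 kPa-1 at full light, open stomata
    tree_scale_sd: float = 0.25  # lognormal spread of g_max across trees
    legacy_tau_sd: float = 0.6  # lognormal spread of legacy tau across trees
    recovery_delay_per_tau: float = 0.7  # per-tree relaxation onset lag, x tau
    stem_capacity_cm3: float = 2500.0
    stem_init_fill: float = 0.95
    stem_min_fill: float = 0.05
    plant_resistance: float = 5.0e-4  # MPa per cm3 h-1 (soil-to-stem)
    leaf_resistance: float = 8.0e-4  # MPa per cm3 h-1 (stem-to-leaf)
    stem_psi_scale: float = 2.5  # MPa at empty capacitor
    psi_gs50: float = -0.7  # MPa, stomatal closure midpoint
    gs_exponent: float = 3.0
    # soil potential pedo-function psi = -a * w^-b (MPa on wetness w)
    psi_soil_a: float = 0.05
    psi_soil_b: float = 2.0
    psi_soil_min: float = -10.0
    # stress legacy and leaf shedding
    stress_threshold: float = -0.7  # MPa leaf potential where stress accrues
    stress_rate: float = 2.5  # day-1 MPa-1 decline rate of s
    shed_tau_days: float = 3.0
    shed_rate: float = 0.03  # day-1 per unit damage pool
    leaf_area0_cm2: float = 12_000.0
    max_leaf_loss_frac: float = 0.65
    # surface evaporation
    evap_rate: float = 40.0  # cm3 h-1 kPa-1 at saturated surface
    # observation model
    sapwood_area_mean_cm2: float = 12.0
    sapwood_area_sd_cm2: float = 1.5
    hv_baseline_cm_h: float = 0.5  # additive heat-velocity offset
    swc_base_pct: float = 40.0
    swc_span_pct: float = 20.0
    swc_noise_pct: float = 0.15
    spike_rate: float = 0.18  # injection rate tuned so ~14% end up replaced
    excursion_rate: float = 0.004
    noise_sd: float = 0.3  # cm/h heat-velocity sensor noise
    psi_noise_mpa: float = 0.05
    vwc_noise_pct: float = 0.8
    iris_noise_dD: float = 1.3
    iris_noise_d18O: float = 0.52
    irms_noise_dD: float = 0.81
    irms_noise_d18O: float = 0.071
    met_jitter: float = 1.0  # scales day-to-day meteorological variation

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if (24 * 60) % self.timestep_min != 0:
            raise ValueError("timestep must divide 24 h")
        if self.rewater_day > self.n_days:
            raise ValueError("rewater_day must not exceed n_days")
        # rewater_day == n_days means rewatering falls after the observed
        # window: a pure-drydown run with an empty recovery stratum
        for name in ("tracer_surface_d18O", "tracer_deep_dD",
                     "rewater_d18O", "rewater_dD"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.stem_capacity_cm3 <= 0:
            raise ValueError("stem capacitance must be positive")
        if self.root_decay_cm <= 0:
            raise ValueError("root profile decay length must be positive")
        if not self.theta_s > self.theta_r >= 0:
            raise ValueError("need theta_s > theta_r >= 0")

    @property
    def column_depth_cm(self) -> float:
        return self.n_layers * self.layer_thickness_cm

    @property
    def steps_per_day(self) -> int:
        return 24 * 60 // self.timestep_min

    @property
    def layer_mid_depths_cm(self) -> np.ndarray:
        return (np.arange(self.n_layers) + 0.5) * self.layer_thickness_cm

    @property
    def layer_volume_cm3(self) -> float:
        return self.soil_volume_cm3 / self.n_layers

    @property
    def root_fractions(self) -> np.ndarray:
        r = np.exp(-self.layer_mid_depths_cm / self.root_decay_cm)
        return r / r.sum()

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("sampling_days", "gas_exchange_days"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def generate_meteorology(config: ExperimentConfig,
                         seed: int | None = None) -> pd.DataFrame:
    """Diurnal sinusoidal meteorology with day-to-day jitter.

    Daily temperature highs fall in 18-25 degC and lows in 12-15 degC; daily
    VPD maxima in 0.75-1.75 kPa and overnight minima in 0.2-0.3 kPa;
    irradiance peaks near 1000 W m-2.  RH is derived so that the returned
    VPD is exactly consistent with T and RH under the module's saturation
    vapour pressure formula.  ``met_jitter=0`` makes every day identical.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    j = config.met_jitter
    n_steps = config.n_days * config.steps_per_day
    timestamps = pd.date_range(config.start_date, periods=n_steps,
                               freq=f"{config.timestep_min}min")
    hours = timestamps.hour + timestamps.minute / 60.0
    day_idx = np.repeat(np.arange(config.n_days), config.steps_per_day)

    t_high = 21.5 + j * rng.uniform(-3.5, 3.5, config.n_days)
    t_low = 13.5 + j * rng.uniform(-1.5, 1.5, config.n_days)
    vpd_max = 1.25 + j * rng.uniform(-0.5, 0.5, config.n_days)
    vpd_min = 0.25 + j * rng.uniform(-0.05, 0.05, config.n_days)
    irr_max = 1000.0 + j * rng.uniform(-60.0, 30.0, config.n_days)

    diurnal = 0.5 - 0.5 * np.cos(2.0 * np.pi * (hours - 5.0) / 24.0)
    temperature = (t_low[day_idx]
                   + (t_high[day_idx] - t_low[day_idx]) * diurnal)
    vpd = (vpd_min[day_idx]
           + (vpd_max[day_idx] - vpd_min[day_idx]) * diurnal ** 1.5)
    irradiance = irr_max[day_idx] * np.clip(
        np.sin(np.pi * (hours - 6.0) / 12.0), 0.0, None)

    es = saturation_vapour_pressure(temperature)
    rh = np.clip(100.0 * (1.0 - vpd / es), 0.0, 100.0)
    vpd = compute_vpd(temperature, rh)  # exact consistency with T, RH
    return pd.DataFrame(
        {"temperature": temperature, "rh": rh, "irradiance": irradiance,
         "vpd": vpd},
        index=pd.DatetimeIndex(timestamps, name="timestamp"),
    )


@dataclass
class SyntheticTruth:
    """Ground-truth states, fluxes and tracer fields of one simulation.

    Step arrays have shape (n_steps, n_trees, ...); daily arrays have shape
    (n_days, n_trees).  Water volumes are cm^3, potentials MPa, deltas
    permil, depths cm.
    """

    config: ExperimentConfig
    seed: int
    timestamps: pd.DatetimeIndex
    theta: np.ndarray  # (steps, trees, layers) % v/v
    soil_dD: np.ndarray
    soil_d18O: np.ndarray
    uptake: np.ndarray  # (steps, trees, layers) cm3/h withdrawal rate
    transpiration: np.ndarray  # (steps, trees) cm3/h
    evaporation: np.ndarray  # (steps, trees) cm3/h
    stem_storage: np.ndarray  # (steps, trees) cm3
    stem_dD: np.ndarray
    stem_d18O: np.ndarray
    stress_factor: np.ndarray  # (steps, trees) s(t)
    psi_stem: np.ndarray  # (steps, trees) MPa
    psi_pd: np.ndarray  # (days, trees)
    psi_md: np.ndarray
    leaf_loss_daily: np.ndarray  # (days, trees) cm2 shed that day
    water_in: np.ndarray  # (steps, trees) cm3 added this step
    water_out: np.ndarray  # (steps, trees) cm3 exported this step
    heavy_in_dD: np.ndarray  # delta-weighted mass flux bookkeeping
    heavy_out_dD: np.ndarray
    heavy_in_d18O: np.ndarray
    heavy_out_d18O: np.ndarray

    @property
    def n_days(self) -> int:
        return self.config.n_days

    def uptake_fractions(self) -> np.ndarray:
        """f_l(t): per-layer uptake fractions, NaN when total uptake is 0."""
        total = self.uptake.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.uptake / total, np.nan)

    def mean_uptake_depth_daily(self) -> np.ndarray:
        """Flux-weighted mean uptake depth per (day, tree), cm."""
        spd = self.config.steps_per_day
        z = self.config.layer_mid_depths_cm
        out = np.full((self.n_days, self.config.n_trees), np.nan)
        for d in range(self.n_days):
            u = self.uptake[d * spd:(d + 1) * spd]  # (spd, trees, layers)
            tot = u.sum(axis=(0, 2))
            num = (u * z).sum(axis=(0, 2))
            with np.errstate(invalid="ignore", divide="ignore"):
                out[d] = np.where(tot > 0, num / tot, np.nan)
        return out

    def total_water(self) -> np.ndarray:
        """(steps, trees): soil + stem water volume, cm^3."""
        vl = self.config.layer_volume_cm3
        soil = (self.theta / 100.0 * vl).sum(axis=2)
        return soil + self.stem_storage

    def water_balance_error(self) -> float:
        """Max per-step closure error relative to mean daily flux magnitude."""
        total = self.total_water()
        dtotal = np.diff(total, axis=0)
        flux = self.water_in[1:] - self.water_out[1:]
        err = np.abs(dtotal - flux)
        daily_flux = np.abs(self.water_out).sum(axis=0).mean() / self.n_days
        return float(err.max() / max(daily_flux, 1e-12))

    def isotope_balance_error(self) -> float:
        """Max relative error of the delta-weighted heavy-isotope budget."""
        vl = self.config.layer_volume_cm3
        worst = 0.0
        for soil_d, stem_d, h_in, h_out in (
            (self.soil_dD, self.stem_dD, self.heavy_in_dD, self.heavy_out_dD),
            (self.soil_d18O, self.stem_d18O,
             self.heavy_in_d18O, self.heavy_out_d18O),
        ):
            budget = ((self.theta / 100.0 * vl) * soil_d).sum(axis=2) \
                + self.stem_storage * stem_d
            dbudget = np.diff(budget, axis=0)
            flux = h_in[1:] - h_out[1:]
            scale = np.abs(budget).max()
            worst = max(worst, float(np.abs(dbudget - flux).max() / scale))
        return worst

    def daily_table(self) -> pd.DataFrame:
        """Per (day, tree) truth summary used for verification and export."""
        spd = self.config.steps_per_day
        depth = self.mean_uptake_depth_daily()
        rows = []
        for tree in range(self.config.n_trees):
            cum_loss = 0.0
            for d in range(self.n_days):
                sl = slice(d * spd, (d + 1) * spd)
                cum_loss += self.leaf_loss_daily[d, tree]
                rows.append({
                    "day": d,
                    "tree_id": f"T{tree + 1}",
                    "transpiration_cm3": float(
                        self.transpiration[sl, tree].sum()
                        * self.config.timestep_min / 60.0),
                    "mean_uptake_depth_cm": float(depth[d, tree]),
                    "psi_pd": float(self.psi_pd[d, tree]),
                    "psi_md": float(self.psi_md[d, tree]),
                    "stress_factor": float(
                        self.stress_factor[sl, tree].mean()),
                    "cumulative_leaf_loss_cm2": float(cum_loss),
                })
        return pd.DataFrame(rows)


def _soil_psi(wetness: np.ndarray, config: ExperimentConfig) -> np.ndarray:
    """Pedotransfer stand-in: water potential (MPa) from layer wetness."""
    w = np.clip(wetness, 1e-4, 1.0)
    return np.maximum(-config.psi_soil_a * w ** (-config.psi_soil_b),
                      config.psi_soil_min)


def _infiltrate(m, dD, d18O, tree, volume, delta_dD, delta_d18O, m_sat,
                start_layer=0):
    """Piston-like fill-to-capacity infiltration; returns drained excess."""
    v = volume
    n_layers = m.shape[1]
    for layer in range(start_layer, n_layers):
        if v <= 0:
            break
        cap = m_sat - m[tree, layer]
        add = min(v, cap)
        if add > 0:
            tot = m[tree, layer] + add
            dD[tree, layer] = (m[tree, layer] * dD[tree, layer]
                               + add * delta_dD) / tot
            d18O[tree, layer] = (m[tree, layer] * d18O[tree, layer]
                                 + add * delta_d18O) / tot
            m[tree, layer] = tot
            v -= add
    return v  # any remainder drains out of the column


def simulate_drydown(config: ExperimentConfig,
                     seed: int | None = None):
    """Run the layered bucket model; returns (truth, observations).

    ``observations`` is a :class:`~drydown.dataset.Dataset` holding the
    emulated measurements (meteorology, per-tree sensor series with injected
    artifacts, sampling-day tables, leaf-loss records); ``truth`` is the
    matching :class:`SyntheticTruth`.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    met = generate_meteorology(config, seed=rng.integers(2 ** 31))
    n_steps = len(met)
    n_trees, n_layers = config.n_trees, config.n_layers
    dt_h = config.timestep_min / 60.0
    dt_d = dt_h / 24.0
    vl = config.layer_volume_cm3
    m_sat = config.theta_s / 100.0 * vl
    m_res = config.theta_r / 100.0 * vl
    z = config.layer_mid_depths_cm
    roots = config.root_fractions

    # per-tree trait variation
    g_scale = np.exp(rng.normal(0.0, config.tree_scale_sd, n_trees))
    tau_tree = config.legacy_tau_days * np.exp(
        rng.normal(0.0, config.legacy_tau_sd, n_trees))
    # trees begin relaxing their stress legacy only after a lag that scales
    # with their own memory time constant (vanishes as tau -> 0)
    relax_start = (config.rewater_day
                   + rng.uniform(0.0, 1.0, n_trees)
                   * config.recovery_delay_per_tau * tau_tree)
    theta0 = config.theta_init + rng.uniform(-1.5, 1.5, n_trees)
    sapwood = np.maximum(
        rng.normal(config.sapwood_area_mean_cm2,
                   config.sapwood_area_sd_cm2, n_trees), 4.0)

    # state
    m = (theta0[:, None] / 100.0) * vl * np.ones((n_trees, n_layers))
    frac_depth = z / config.column_depth_cm
    dD = (config.background_dD_top
          + (config.background_dD_bottom - config.background_dD_top)
          * frac_depth)[None, :] * np.ones((n_trees, 1))
    d18O = (config.background_d18O_top
            + (config.background_d18O_bottom - config.background_d18O_top)
            * frac_depth)[None, :] * np.ones((n_trees, 1))
    W = np.full(n_trees, config.stem_init_fill * config.stem_capacity_cm3)
    stem_dD = dD.mean(axis=1).copy()
    stem_d18O = d18O.mean(axis=1).copy()
    s = np.ones(n_trees)
    damage = np.zeros(n_trees)
    leaf_lost = np.zeros(n_trees)

    # watering events: (step, volume_cm3, dD, d18O, layer)
    eff = config.tracer_mixing_efficiency
    deep_layer = min(int(config.tracer_deep_depth_cm
                         // config.layer_thickness_cm), n_layers - 1)

    def step_of(day, hour):
        return day * config.steps_per_day + int(hour * 60 / config.timestep_min)

    # tracer mixing efficiency < 1 dilutes the applied enrichment with
    # unlabelled tap water (free generator parameter; injection losses)
    events = [
        (step_of(0, 9.0), config.tracer_surface_volume_l * 1000.0,
         config.tracer_surface_dD,
         eff * config.tracer_surface_d18O + (1 - eff) * config.rewater_d18O,
         0),
        (step_of(0, 13.0), config.tracer_deep_volume_l * 1000.0,
         eff * config.tracer_deep_dD + (1 - eff) * config.rewater_dD,
         config.tracer_deep_d18O, deep_layer),
    ]
    if config.rewater_volume_l > 0 and config.rewater_day < config.n_days:
        events.append((step_of(config.rewater_day, 9.75),
                       config.rewater_volume_l * 1000.0,
                       config.rewater_dD, config.rewater_d18O, 0))
        events.append((step_of(config.rewater_day, 13.0),
                       config.rewater_tracer_volume_l * 1000.0,
                       config.rewater_tracer_dD, config.rewater_tracer_d18O,
                       0))
    event_map = {}
    for st, vol, e_dD, e_d18O, layer in events:
        event_map.setdefault(st, []).append((vol, e_dD, e_d18O, layer))

    vpd = met["vpd"].to_numpy()
    light = np.clip(met["irradiance"].to_numpy() / 1000.0, 0.0, 1.0)

    # output arrays
    o_theta = np.empty((n_steps, n_trees, n_layers))
    o_dD = np.empty_like(o_theta)
    o_d18O = np.empty_like(o_theta)
    o_uptake = np.zeros_like(o_theta)
    o_T = np.zeros((n_steps, n_trees))
    o_E = np.zeros((n_steps, n_trees))
    o_W = np.empty((n_steps, n_trees))
    o_sdD = np.empty((n_steps, n_trees))
    o_sd18O = np.empty((n_steps, n_trees))
    o_s = np.empty((n_steps, n_trees))
    o_psi_stem = np.empty((n_steps, n_trees))
    w_in = np.zeros((n_steps, n_trees))
    w_out = np.zeros((n_steps, n_trees))
    h_in_dD = np.zeros((n_steps, n_trees))
    h_out_dD = np.zeros((n_steps, n_trees))
    h_in_d18O = np.zeros((n_steps, n_trees))
    h_out_d18O = np.zeros((n_steps, n_trees))
    psi_leaf_track = np.zeros((n_steps, n_trees))
    shed_daily = np.zeros((config.n_days, n_trees))

    day_idx = np.repeat(np.arange(config.n_days), config.steps_per_day)

    for t in range(n_steps):
        # watering / tracer events
        if t in event_map:
            for vol, e_dD, e_d18O, layer in event_map[t]:
                for tree in range(n_trees):
                    drained = _infiltrate(m, dD, d18O, tree, vol, e_dD,
                                          e_d18O, m_sat, start_layer=layer)
                    w_in[t, tree] += vol
                    h_in_dD[t, tree] += vol * e_dD
                    h_in_d18O[t, tree] += vol * e_d18O
                    if drained > 0:  # excess leaves the pot at input comp.
                        w_out[t, tree] += drained
                        h_out_dD[t, tree] += drained * e_dD
                        h_out_d18O[t, tree] += drained * e_d18O

        wet = np.clip((m - m_res) / (m_sat - m_res), 0.0, 1.0)
        psi_l = _soil_psi(wet, config)  # (trees, layers)
        weights = roots[None, :] * wet
        wsum = weights.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi_soil = np.where(
                wsum > 1e-9, (weights * psi_l).sum(axis=1) / np.maximum(wsum, 1e-12),
                config.psi_soil_min)

        psi_stem = -config.stem_psi_scale * (1.0 - W / config.stem_capacity_cm3)

        # soil-to-stem refill flux
        U = np.maximum(0.0, psi_soil - psi_stem) / config.plant_resistance
        U = np.minimum(U, (config.stem_capacity_cm3 - W) / dt_h)
        avail = np.maximum(m - m_res, 0.0)
        U = np.minimum(U, avail.sum(axis=1) / dt_h)

        # transpiration demand
        f_gs = 1.0 / (1.0 + (np.minimum(psi_stem, -1e-9) / config.psi_gs50)
                      ** config.gs_exponent)
        demand = (g_scale * config.g_max * vpd[t] * light[t] * f_gs * s)
        stem_floor = config.stem_min_fill * config.stem_capacity_cm3
        T = np.minimum(demand, np.maximum(0.0, W - stem_floor) / dt_h + U)

        # per-layer uptake
        u = np.zeros((n_trees, n_layers))
        pos = wsum > 1e-9
        if pos.any():
            p = weights[pos] / wsum[pos, None]
            u[pos] = U[pos, None] * p
            u = np.minimum(u, avail / dt_h)
        U_eff = u.sum(axis=1)

        # surface evaporation
        E = config.evap_rate * vpd[t] * wet[:, 0]
        E = np.minimum(E, np.maximum(avail[:, 0] / dt_h - u[:, 0], 0.0))

        # soil update (removal at layer composition: deltas unchanged)
        m -= u * dt_h
        m[:, 0] -= E * dt_h

        # stem update: inflow mixes, outflow at stem composition
        with np.errstate(invalid="ignore", divide="ignore"):
            up_dD = np.where(U_eff > 0, (u * dD).sum(axis=1)
                             / np.maximum(U_eff, 1e-300), stem_dD)
            up_d18O = np.where(U_eff > 0, (u * d18O).sum(axis=1)
                               / np.maximum(U_eff, 1e-300), stem_d18O)
        W_mid = W + U_eff * dt_h
        stem_dD = (W * stem_dD + U_eff * dt_h * up_dD) / W_mid
        stem_d18O = (W * stem_d18O + U_eff * dt_h * up_d18O) / W_mid
        T = np.minimum(T, np.maximum(W_mid - stem_floor, 0.0) / dt_h)
        W = W_mid - T * dt_h

        # stress legacy: multiplicative damage, exponential relaxation
        psi_leaf = psi_stem - T * config.leaf_resistance
        x = np.maximum(0.0, config.stress_threshold - psi_leaf)
        s = s * np.exp(-config.stress_rate * x * dt_d)
        relaxing = (t * dt_d) >= relax_start
        s = np.where(relaxing,
                     1.0 - (1.0 - s) * np.exp(-dt_d / tau_tree), s)

        # leaf shedding damage pool
        damage = damage + (config.stress_rate * x
                           - damage / config.shed_tau_days) * dt_d
        damage = np.maximum(damage, 0.0)
        headroom = 1.0 - leaf_lost / (config.max_leaf_loss_frac
                                      * config.leaf_area0_cm2)
        shed = (config.shed_rate * damage * dt_d * config.leaf_area0_cm2
                * np.maximum(headroom, 0.0))
        leaf_lost += shed
        shed_daily[day_idx[t]] += shed

        # bookkeeping
        o_theta[t] = m / vl * 100.0
        o_dD[t] = dD
        o_d18O[t] = d18O
        o_uptake[t] = u
        o_T[t] = T
        o_E[t] = E
        o_W[t] = W
        o_sdD[t] = stem_dD
        o_sd18O[t] = stem_d18O
        o_s[t] = s
        o_psi_stem[t] = psi_stem
        psi_leaf_track[t] = psi_leaf
        w_out[t] += (T + E) * dt_h
        h_out_dD[t] += T * dt_h * stem_dD + E * dt_h * dD[:, 0]
        h_out_d18O[t] += T * dt_h * stem_d18O + E * dt_h * d18O[:, 0]

    # daily water potentials: predawn 05:00-05:45, midday 13:30-14:30
    hours = met.index.hour + met.index.minute / 60.0
    pd_mask = (hours >= 5.0) & (hours < 5.75)
    md_mask = (hours >= 13.5) & (hours < 14.5)
    psi_pd = np.full((config.n_days, n_trees), np.nan)
    psi_md = np.full((config.n_days, n_trees), np.nan)
    for d in range(config.n_days):
        in_day = day_idx == d
        psi_pd[d] = o_psi_stem[in_day & pd_mask].mean(axis=0)
        psi_md[d] = psi_leaf_track[in_day & md_mask].mean(axis=0)

    truth = SyntheticTruth(
        config=config, seed=seed, timestamps=met.index,
        theta=o_theta, soil_dD=o_dD, soil_d18O=o_d18O, uptake=o_uptake,
        transpiration=o_T, evaporation=o_E, stem_storage=o_W,
        stem_dD=o_sdD, stem_d18O=o_sd18O, stress_factor=o_s,
        psi_stem=o_psi_stem, psi_pd=psi_pd, psi_md=psi_md,
        leaf_loss_daily=shed_daily,
        water_in=w_in, water_out=w_out,
        heavy_in_dD=h_in_dD, heavy_out_dD=h_out_dD,
        heavy_in_d18O=h_in_d18O, heavy_out_d18O=h_out_d18O,
    )
    observations = _emulate_observations(truth, met, sapwood, rng)
    return truth, observations


def _emulate_observations(truth: SyntheticTruth, met: pd.DataFrame,
                          sapwood: np.ndarray,
                          rng: np.random.Generator) -> Dataset:
    config = truth.config
    n_trees = config.n_trees
    trees = [f"T{i + 1}" for i in range(n_trees)]
    ts = truth.timestamps
    hours = ts.hour + ts.minute / 60.0
    day_idx = np.repeat(np.arange(config.n_days), config.steps_per_day)

    sensors = {}
    artifact_truth = {}
    for i, tree in enumerate(trees):
        hv_true = (truth.transpiration[:, i] / sapwood[i]
                   + config.hv_baseline_cm_h)
        hv = SensorSeries(tree_id=tree, variable="heat_velocity",
                          unit="cm h-1", timestamps=ts, values=hv_true)
        hv_obs, masks = inject_sensor_artifacts(
            hv, spike_rate=config.spike_rate,
            excursion_rate=config.excursion_rate,
            noise_sd=config.noise_sd, seed=int(rng.integers(2 ** 31)))
        swc = (config.swc_base_pct + config.swc_span_pct
               * truth.stem_storage[:, i] / config.stem_capacity_cm3
               + rng.normal(0.0, config.swc_noise_pct, len(ts)))
        sensors[tree] = {
            "heat_velocity": hv_obs,
            "stem_water_content": SensorSeries(
                tree_id=tree, variable="stem_water_content", unit="%",
                timestamps=ts, values=swc),
        }
        artifact_truth[tree] = masks

    # sampling-day tables
    wp_rows, sm_rows, iso_rows, ge_rows = [], [], [], []
    z_layers = config.layer_mid_depths_cm
    spd = config.steps_per_day
    for day in config.sampling_days:
        if day >= config.n_days:
            continue
        stem_step = day * spd + int(15.5 * 60 / config.timestep_min)
        for i, tree in enumerate(trees):
            for _ in range(2):  # two replicate leaves
                wp_rows.append({
                    "day": day, "tree_id": tree,
                    "psi_pd": truth.psi_pd[day, i]
                    + rng.normal(0, config.psi_noise_mpa),
                    "psi_md": truth.psi_md[day, i]
                    + rng.normal(0, config.psi_noise_mpa),
                })
            # handheld probe at 10/30/50 cm: interpolate layer centres
            theta_day = truth.theta[day * spd + spd // 2, i]
            for depth in (10.0, 30.0, 50.0):
                vwc = float(np.interp(depth, z_layers, theta_day))
                sm_rows.append({
                    "day": day, "tree_id": tree, "depth_cm": depth,
                    "vwc_pct": vwc + rng.normal(0, config.vwc_noise_pct),
                })
            for layer in range(config.n_layers):
                iso_rows.append({
                    "day": day, "tree_id": tree, "medium": "soil",
                    "depth_cm": z_layers[layer],
                    "dD": truth.soil_dD[day * spd + spd // 2, i, layer]
                    + rng.normal(0, config.iris_noise_dD),
                    "d18O": truth.soil_d18O[day * spd + spd // 2, i, layer]
                    + rng.normal(0, config.iris_noise_d18O),
                })
            iso_rows.append({
                "day": day, "tree_id": tree, "medium": "stem",
                "depth_cm": np.nan,
                "dD": truth.stem_dD[stem_step, i]
                + rng.normal(0, config.iris_noise_dD),
                "d18O": truth.stem_d18O[stem_step, i]
                + rng.normal(0, config.iris_noise_d18O),
            })

    # daily transpired-water samples (flux-weighted stem outflow)
    dt_h = config.timestep_min / 60.0
    for day in range(config.n_days):
        sl = slice(day * spd, (day + 1) * spd)
        for i, tree in enumerate(trees):
            flux = truth.transpiration[sl, i]
            tot = flux.sum()
            if tot * dt_h < 50.0:  # too little condensate collected
                continue
            iso_rows.append({
                "day": day, "tree_id": tree, "medium": "transpired",
                "depth_cm": np.nan,
                "dD": float((flux * truth.stem_dD[sl, i]).sum() / tot)
                + rng.normal(0, config.irms_noise_dD),
                "d18O": float((flux * truth.stem_d18O[sl, i]).sum() / tot)
                + rng.normal(0, config.irms_noise_d18O),
            })

    # gas exchange on its scheduled days: proportional to the same
    # stomatal and legacy factors that drive transpiration
    for day in config.gas_exchange_days:
        if day >= config.n_days:
            continue
        for label, hour in (("morning", 10.5), ("afternoon", 15.0)):
            step = day * spd + int(hour * 60 / config.timestep_min)
            psi_stem = truth.psi_stem[step]
            f_gs = 1.0 / (1.0 + (np.minimum(psi_stem, -1e-9)
                                 / config.psi_gs50) ** config.gs_exponent)
            gs = 0.4 * f_gs * truth.stress_factor[step]
            for i, tree in enumerate(trees):
                gs_obs = max(float(gs[i] + rng.normal(0, 0.015)), 0.0)
                a_obs = max(20.0 * gs_obs / (gs_obs + 0.08)
                            + rng.normal(0, 0.6), -0.5)
                ge_rows.append({
                    "day": day, "tree_id": tree, "period": label,
                    "assimilation": a_obs, "stomatal_conductance": gs_obs,
                })

    ll_rows = []
    for day in range(config.n_days):
        for i, tree in enumerate(trees):
            area = truth.leaf_loss_daily[day, i]
            if area > 0:
                ll_rows.append({"day": day, "tree_id": tree,
                                "area_cm2": float(area)})

    manifest = {
        "config": config.to_dict(),
        "seed": int(truth.seed),
        "start_date": config.start_date,
        "generator": "drydown.synthetic_data",
    }
    ds = Dataset(
        manifest=manifest,
        meteorology=met,
        sensors=sensors,
        water_potential=pd.DataFrame(wp_rows),
        soil_moisture=pd.DataFrame(sm_rows),
        isotopes=pd.DataFrame(iso_rows),
        leaf_loss=pd.DataFrame(
            ll_rows, columns=["day", "tree_id", "area_cm2"]),
        sapwood=pd.DataFrame({"tree_id": trees,
                              "sapwood_area_cm2": sapwood}),
        gas_exchange=pd.DataFrame(
            ge_rows, columns=["day", "tree_id", "period",
                              "assimilation", "stomatal_conductance"]),
        truth_daily=truth.daily_table(),
    )
    ds.artifact_truth = artifact_truth  # in-memory ground truth, not saved
    return ds


def inject_sensor_artifacts(series: SensorSeries, spike_rate: float = 0.14,
                            excursion_rate: float = 0.004,
                            noise_sd: float = 0.3, seed: int = 0):
    """Add Gaussian noise, isolated spikes and large negative excursions.

    Returns ``(noisy_series, masks)`` where ``masks`` holds boolean arrays
    ``spike`` and ``excursion`` marking the injected artifact positions
    (disjoint).  Spike perturbations are drawn from +/- U(6, 20) x
    ``noise_sd`` but kept above the excursion regime (values stay > -4 of
    the series' units) so the two artifact classes remain separable;
    excursions overwrite the value with -U(10, 30).  With all rates and
    ``noise_sd`` zero the output equals the input.
    """
    for name, rate in (("spike_rate", spike_rate),
                       ("excursion_rate", excursion_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(series)
    values = series.values.astype(float).copy()
    if noise_sd > 0:
        values += rng.normal(0.0, noise_sd, n)

    excursion = rng.random(n) < excursion_rate
    spike = (rng.random(n) < spike_rate) & ~excursion

    values[excursion] = -rng.uniform(10.0, 30.0, int(excursion.sum()))

    n_spikes = int(spike.sum())
    if n_spikes:
        # spike size scales with the larger of the noise floor and the
        # series' spread, so spikes stand out against diurnal structure
        q25, q75 = np.percentile(series.values, [25.0, 75.0])
        scale = max(noise_sd, 0.1 * (q75 - q25))
        amp = rng.uniform(6.0, 20.0, n_spikes) * max(scale, 1e-12)
        sign = rng.choice([-1.0, 1.0], n_spikes)
        perturbed = values[spike] + sign * amp
        flip = perturbed < -4.0  # would masquerade as an excursion
        perturbed[flip] = values[spike][flip] + amp[flip]
        values[spike] = perturbed

    out = series.with_data(values=values)
    return out, {"spike": spike, "excursion": excursion}


def write_dataset(truth: SyntheticTruth, observations: Dataset,
                  directory) -> list:
    """Write the observation tables (and daily truth summary) as CSVs.

    The manifest records the generating config and seed, so the file set
    regenerates bit-identically; round-trips losslessly through
    :func:`drydown.dataset.load_dataset`.
    """
    if observations.truth_daily is None:
        observations.truth_daily = truth.daily_table()
    return save_dataset(observations, directory)
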