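"""Sensor-series cleaning and daily summarisation.

Continuous measurements (heat-pulse velocity, stem water content,
meteorology) arrive on a regular 15-min grid and pass through a fixed
cleaning order:

1. remove large negative heat-velocity excursions (sensor malfunction),
2. convert heat velocity to sap flux via the tree's sapwood area,
3. Hampel-filter spikes (replace with the rolling median),
4. baseline-correct so the minimum (no-transpiration) flux is zero.

Daily summaries then reduce each variable to one value per day per tree
(daylight mean sap flow, daily 5th/95th-percentile stem water content,
daily means of meteorology, sampling-day means of water potentials, soil
moisture averaged over the measured depths, cumulative leaf loss, and mean
water-uptake depth from the isotope inversion), which are the inputs to
the mutual-information analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "QUALITY_OK",
    "QUALITY_REMOVED",
    "QUALITY_REPLACED",
    "SensorSeries",
    "DailySummaryTable",
    "SUMMARY_COLUMNS",
    "compute_vpd",
    "saturation_vapour_pressure",
    "clean_negative_excursions",
    "hampel_filter",
    "heat_velocity_to_sapflux",
    "baseline_correct",
    "clean_sap_flow",
    "nearest_rank_percentile",
    "summarize_daily",
    "processing_report",
]

QUALITY_OK = "ok"
QUALITY_REMOVED = "removed"
QUALITY_REPLACED = "replaced"

#: The twelve daily summary variables, in measurement-group order
#: (physical environment, plant water sources, plant water status,
#: plant fluxes).
SUMMARY_COLUMNS = (
    "soil_moisture",
    "vpd",
    "irradiance",
    "uptake_depth",
    "psi_pd",
    "psi_md",
    "cumulative_leaf_loss",
    "sap_flow",
    "stem_water_max",
    "stem_water_min",
    "assimilation",
    "stomatal_conductance",
)

MAD_CONSISTENCY = 1.4826  # Gaussian consistency constant for the MAD


@dataclass
class SensorSeries:
    """One tree's (or the site's) timestamped measurement series."""

    tree_id: str
    variable: str
    unit: str
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    quality: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        if self.quality is None:
            self.quality = np.full(self.values.size, QUALITY_OK, dtype="<U8")
        else:
            self.quality = np.asarray(self.quality, dtype="<U8")
        if not (len(self.timestamps) == self.values.size == len(self.quality)):
            raise ValueError("timestamps, values and quality must align")
        if len(self.timestamps) > 1:
            steps = np.diff(self.timestamps.asi8)
            if np.any(steps <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if np.ptp(steps) != 0:
                raise ValueError("timestamps must lie on a regular grid")

    def __len__(self) -> int:
        return self.values.size

    @property
    def ok_mask(self) -> np.ndarray:
        """Points usable for analysis (not removed)."""
        return self.quality != QUALITY_REMOVED

    @property
    def removed_fraction(self) -> float:
        return float(np.mean(self.quality == QUALITY_REMOVED))

    @property
    def replaced_fraction(self) -> float:
        return float(np.mean(self.quality == QUALITY_REPLACED))

    def with_data(self, values=None, quality=None, variable=None, unit=None):
        return SensorSeries(
            tree_id=self.tree_id,
            variable=self.variable if variable is None else variable,
            unit=self.unit if unit is None else unit,
            timestamps=self.timestamps,
            values=self.values.copy() if values is None else np.asarray(values, float),
            quality=self.quality.copy() if quality is None else np.asarray(quality, "<U8"),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"timestamp": self.timestamps, "value": self.values,
             "quality": self.quality}
        )


def saturation_vapour_pressure(temperature_c):
    """Saturation vapour pressure e_s(T) in kPa (Tetens-type exponential)."""
    t = np.asarray(temperature_c, dtype=float)
    return 0.61078 * np.exp(17.2694 * t / (t + 237.3))


def compute_vpd(temperature_c, relative_humidity_pct):
    """Vapour pressure deficit (kPa) from air temperature and RH.

    vpd = e_s(T) * (1 - RH/100); non-negative by construction.
    """
    rh = np.asarray(relative_humidity_pct, dtype=float)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("relative humidity must lie in [0, 100] %")
    out = saturation_vapour_pressure(temperature_c) * (1.0 - rh / 100.0)
    return out if np.ndim(out) else float(out)


def clean_negative_excursions(series: SensorSeries,
                              threshold: float = -5.0) -> SensorSeries:
    """Mark values below ``threshold`` as removed (not interpolated).

    Large negative heat-velocity excursions indicate sensor malfunction;
    the threshold must be negative.
    """
    if threshold >= 0.0:
        raise ValueError("excursion threshold must be negative")
    quality = series.quality.copy()
    bad = (series.values < threshold) & (quality != QUALITY_REMOVED)
    quality[bad] = QUALITY_REMOVED
    return series.with_data(quality=quality)


def hampel_filter(series: SensorSeries, window_halfwidth: int = 6,
                  n_mad: float = 3.0) -> SensorSeries:
    """Replace outliers with the rolling median (Hampel filter).

    For each point a centred window of ``2 * window_halfwidth + 1`` points
    (truncated at the edges) gives the rolling median and MAD over
    non-removed points; a point deviating by more than
    ``n_mad * 1.4826 * MAD`` from the median is flagged ``replaced`` and
    set to the median.  Decisions use the original values throughout.
    """
    if window_halfwidth < 1:
        raise ValueError("window_halfwidth must be >= 1")
    if n_mad <= 0:
        raise ValueError("n_mad must be > 0")
    n = len(series)
    if 2 * window_halfwidth + 1 > n:
        raise ValueError("window larger than series")
    v = series.values.astype(float).copy()
    v[series.quality == QUALITY_REMOVED] = np.nan
    out_values = series.values.copy()
    out_quality = series.quality.copy()
    h = window_halfwidth
    for i in range(n):
        if np.isnan(v[i]):
            continue
        window = v[max(0, i - h): i + h + 1]
        window = window[~np.isnan(window)]
        med = np.median(window)
        mad = np.median(np.abs(window - med))
        if np.abs(v[i] - med) > n_mad * MAD_CONSISTENCY * mad:
            out_values[i] = med
            out_quality[i] = QUALITY_REPLACED
    return series.with_data(values=out_values, quality=out_quality)


def heat_velocity_to_sapflux(series: SensorSeries,
                             sapwood_area_cm2: float,
                             wound_correction: float = 1.0) -> SensorSeries:
    """Convert heat velocity (cm/h) to sap flux (cm^3/h).

    Pointwise multiplication by the tree's sapwood cross-sectional area;
    ``wound_correction`` is an optional scalar multiplier (default 1.0).
    """
    if sapwood_area_cm2 is None or not np.isfinite(sapwood_area_cm2):
        raise ValueError(
            f"missing sapwood area for tree {series.tree_id!r}"
        )
    if sapwood_area_cm2 <= 0.0:
        raise ValueError(
            f"sapwood area must be positive (tree {series.tree_id!r})"
        )
    return series.with_data(
        values=series.values * sapwood_area_cm2 * wound_correction,
        variable="sap_flux",
        unit="cm3 h-1",
    )


def baseline_correct(series: SensorSeries) -> SensorSeries:
    """Subtract the minimum non-removed value (no-transpiration baseline).

    The minimum of the output over usable points is exactly zero.
    """
    ok = series.ok_mask
    if not ok.any():
        raise ValueError("baseline correction needs at least one usable point")
    baseline = float(series.values[ok].min())
    return series.with_data(values=series.values - baseline)


def clean_sap_flow(series: SensorSeries, sapwood_area_cm2: float,
                   excursion_threshold: float = -5.0,
                   window_halfwidth: int = 6, n_mad: float = 3.0,
                   wound_correction: float = 1.0) -> SensorSeries:
    """Full heat-velocity cleaning chain in the documented order.

    excursion removal -> sapwood-area conversion -> Hampel -> baseline.
    """
    s = clean_negative_excursions(series, threshold=excursion_threshold)
    s = heat_velocity_to_sapflux(s, sapwood_area_cm2,
                                 wound_correction=wound_correction)
    s = hampel_filter(s, window_halfwidth=window_halfwidth, n_mad=n_mad)
    return baseline_correct(s)


def nearest_rank_percentile(values, p: float) -> float:
    """Nearest-rank percentile: the ceil(p/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty input")
    k = max(1, math.ceil(p / 100.0 * v.size))
    return float(v[k - 1])


@dataclass
class DailySummaryTable:
    """Day-by-variable summary matrices, per tree and pooled across trees."""

    per_tree: dict
    pooled: pd.DataFrame
    counts: dict

    def __post_init__(self) -> None:
        for tab in list(self.per_tree.values()) + [self.pooled]:
            p5 = tab.get("stem_water_min")
            p95 = tab.get("stem_water_max")
            if p5 is not None and p95 is not None:
                both = p5.notna() & p95.notna()
                if not (p5[both] <= p95[both] + 1e-12).all():
                    raise AssertionError("p5 > p95 in stem water content")
            loss = tab.get("cumulative_leaf_loss")
            if loss is not None:
                ld = loss.dropna().to_numpy()
                if ld.size and np.any(np.diff(ld) < -1e-9):
                    raise AssertionError("cumulative leaf loss decreased")


def _day_of(timestamps: pd.DatetimeIndex, start: pd.Timestamp) -> np.ndarray:
    return ((timestamps.normalize() - start.normalize()).days).to_numpy()


def _daylight_mask(met: pd.DataFrame, rule: str, irradiance_threshold: float,
                   fixed_hours: tuple) -> pd.Series:
    if rule == "irradiance":
        return met["irradiance"] > irradiance_threshold
    if rule == "fixed":
        hours = met.index.hour + met.index.minute / 60.0
        return pd.Series((hours >= fixed_hours[0]) & (hours < fixed_hours[1]),
                         index=met.index)
    raise ValueError(f"unknown daylight rule {rule!r}")


def _daily_series_stat(series: SensorSeries, days: np.ndarray, stat,
                       min_coverage: float, expected_per_day: int,
                       select: np.ndarray | None = None) -> dict:
    """Apply ``stat`` per day to usable values; insufficient coverage -> NaN."""
    out = {}
    use = series.ok_mask if select is None else (series.ok_mask & select)
    for day in np.unique(days):
        in_day = days == day
        if select is None:
            expected = int(in_day.sum())
        else:
            expected = int((in_day & select).sum())
        vals = series.values[in_day & use]
        if expected == 0:
            continue
        if vals.size < min_coverage * expected:
            warnings.warn(
                f"day {day} {series.variable} tree {series.tree_id}: "
                f"coverage {vals.size}/{expected} below threshold; cell set "
                "missing",
                stacklevel=2,
            )
            out[int(day)] = np.nan
        else:
            out[int(day)] = float(stat(vals))
    return out


def summarize_daily(
    dataset,
    daylight_rule: str = "irradiance",
    irradiance_threshold: float = 10.0,
    fixed_daylight_hours: tuple = (6.0, 18.0),
    min_coverage: float = 0.75,
    uptake_depths: pd.DataFrame | None = None,
) -> DailySummaryTable:
    """Reduce a loaded dataset to the twelve daily summary variables.

    Summarisation rules: soil moisture is the mean across measured depths;
    VPD and irradiance are daily means; leaf water potentials are daily
    means of replicates; leaf loss is cumulative to date; sap flow is the
    mean during daylight hours; stem water content contributes the daily
    95th and 5th nearest-rank percentiles; gas exchange variables are daily
    means; mean water-uptake depth comes from the isotope mixing inversion
    (``uptake_depths`` frame with columns day, tree_id, uptake_depth_cm).

    Sampling-day-only variables are missing (NaN), not zero, on other days.
    A daily cell on a continuous series requires at least ``min_coverage``
    of the expected points, else it is set missing with a warning.
    """
    start = pd.Timestamp(dataset.manifest["start_date"])
    n_days = int(dataset.manifest["config"]["n_days"])
    days_index = pd.RangeIndex(n_days, name="day")
    met = dataset.meteorology
    met_days = _day_of(met.index, start)
    daylight = _daylight_mask(met, daylight_rule, irradiance_threshold,
                              fixed_daylight_hours).to_numpy()

    # site-level daily means (identical for every tree)
    site = pd.DataFrame(index=days_index, columns=["vpd", "irradiance"],
                        dtype=float)
    expected_per_day = int(round(24 * 3600 / (met.index[1] - met.index[0]).total_seconds())) if len(met) > 1 else 1
    for col in ("vpd", "irradiance"):
        grp = pd.Series(met[col].to_numpy(), index=met_days).groupby(level=0)
        counts = grp.count()
        means = grp.mean()
        enough = counts >= min_coverage * expected_per_day
        site.loc[means.index[enough], col] = means[enough]

    trees = sorted(dataset.sensors.keys())
    per_tree = {}
    counts_per_tree = {}
    for tree in trees:
        tab = pd.DataFrame(index=days_index, columns=list(SUMMARY_COLUMNS),
                           dtype=float)
        cnt = pd.DataFrame(0, index=days_index, columns=list(SUMMARY_COLUMNS))
        tab["vpd"] = site["vpd"]
        tab["irradiance"] = site["irradiance"]

        sensors = dataset.sensors[tree]
        if "sap_flux" in sensors:
            s = sensors["sap_flux"]
            d = _day_of(s.timestamps, start)
            sel = daylight if len(met) == len(s) else None
            if sel is None:
                raise ValueError("sap flux and meteorology grids must align")
            vals = _daily_series_stat(s, d, np.mean, min_coverage,
                                      expected_per_day, select=sel)
            for day, val in vals.items():
                if day in tab.index:
                    tab.loc[day, "sap_flow"] = val
        if "stem_water_content" in sensors:
            s = sensors["stem_water_content"]
            d = _day_of(s.timestamps, start)
            hi = _daily_series_stat(
                s, d, lambda v: nearest_rank_percentile(v, 95.0),
                min_coverage, expected_per_day)
            lo = _daily_series_stat(
                s, d, lambda v: nearest_rank_percentile(v, 5.0),
                min_coverage, expected_per_day)
            for day, val in hi.items():
                if day in tab.index:
                    tab.loc[day, "stem_water_max"] = val
            for day, val in lo.items():
                if day in tab.index:
                    tab.loc[day, "stem_water_min"] = val

        wp = dataset.water_potential
        if wp is not None and len(wp):
            sub = wp[wp["tree_id"] == tree]
            for day, grp in sub.groupby("day"):
                if day in tab.index:
                    tab.loc[day, "psi_pd"] = grp["psi_pd"].mean()
                    tab.loc[day, "psi_md"] = grp["psi_md"].mean()
                    cnt.loc[day, "psi_pd"] = grp["psi_pd"].notna().sum()
                    cnt.loc[day, "psi_md"] = grp["psi_md"].notna().sum()

        sm = dataset.soil_moisture
        if sm is not None and len(sm):
            sub = sm[sm["tree_id"] == tree]
            for day, grp in sub.groupby("day"):
                if day in tab.index:
                    tab.loc[day, "soil_moisture"] = grp["vwc_pct"].mean()
                    cnt.loc[day, "soil_moisture"] = grp["vwc_pct"].notna().sum()

        ge = getattr(dataset, "gas_exchange", None)
        if ge is not None and len(ge):
            sub = ge[ge["tree_id"] == tree]
            for day, grp in sub.groupby("day"):
                if day in tab.index:
                    tab.loc[day, "assimilation"] = grp["assimilation"].mean()
                    tab.loc[day, "stomatal_conductance"] = (
                        grp["stomatal_conductance"].mean())

        ll = dataset.leaf_loss
        if ll is not None and len(ll):
            sub = ll[ll["tree_id"] == tree]
            daily = sub.groupby("day")["area_cm2"].sum()
            running = 0.0
            for day in days_index:
                running += float(daily.get(day, 0.0))
                tab.loc[day, "cumulative_leaf_loss"] = running

        if uptake_depths is not None and len(uptake_depths):
            sub = uptake_depths[uptake_depths["tree_id"] == tree]
            for _, row in sub.iterrows():
                day = int(row["day"])
                if day in tab.index:
                    tab.loc[day, "uptake_depth"] = row["uptake_depth_cm"]

        per_tree[tree] = tab
        counts_per_tree[tree] = cnt

    pooled = pd.concat(per_tree.values()).groupby(level=0).mean()
    pooled = pooled.reindex(days_index)
    return DailySummaryTable(per_tree=per_tree, pooled=pooled,
                             counts=counts_per_tree)


def processing_report(series_list) -> dict:
    """Counts and fractions of removed/replaced points per series."""
    report = {}
    for s in series_list:
        report[f"{s.tree_id}/{s.variable}"] = {
            "n_points": len(s),
            "n_removed": int(np.sum(s.quality == QUALITY_REMOVED)),
            "n_replaced": int(np.sum(s.quality == QUALITY_REPLACED)),
            "removed_fraction": s.removed_fraction,
            "replaced_fraction": s.replaced_fraction,
        }
    return report
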