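"""Entropy and mutual information on daily-summarised experiment variables.

Mutual information I(X;Y) = H(X) - H(X|Y) quantifies, in bits, how much
knowing one daily variable reduces uncertainty about another.  Because the
daily tables are tiny (3-16 paired days per period, 12-18 tree-days when
trees are kept separate), the estimator is deliberately simple: a plug-in
(maximum-likelihood) histogram estimator on coarsely discretized values,
with quantile (median) binning into two bins by default so the estimate is
bounded by 1 bit and comparable across variables.  No bias correction is
applied by default; the optional Miller-Madow correction is available for
sensitivity checks.

The estimator settings (bin count, binning scheme, log base, tree pooling)
are the dominant degrees of freedom in this kind of analysis and are all
surfaced in :class:`EstimatorConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiscretizedVariable",
    "MIResult",
    "EstimatorConfig",
    "discretize",
    "entropy",
    "joint_entropy",
    "conditional_entropy",
    "mutual_information",
    "mutual_information_from_labels",
    "mi_table",
    "MEASUREMENT_ORDER",
    "TARGETS",
]

#: Fig.-9-style ordering of the daily summary variables: physical
#: environment, plant water sources, plant water status, plant fluxes.
MEASUREMENT_ORDER: tuple[str, ...] = (
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

#: Target variables: plant water flux (mean daily sap flow) and plant water
#: status (predawn and midday leaf water potential).
TARGETS: tuple[str, ...] = ("sap_flow", "psi_pd", "psi_md")

_MIN_RELIABLE_PAIRS = 3
_AGREE_TOL = 1e-12


@dataclass
class DiscretizedVariable:
    """Integer bin labels for one variable (missing values excluded)."""

    labels: np.ndarray
    n_bins: int
    scheme: str
    source: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= self.n_bins
        ):
            raise ValueError("labels must lie in [0, n_bins)")


@dataclass
class MIResult:
    """Mutual information between one measurement and one target variable."""

    measurement: str
    target: str
    period: str
    mi: float
    h_x: float
    h_y: float
    h_xy: float
    n: int
    n_bins: int
    scheme: str
    reliable: bool = True

    def __float__(self) -> float:  # convenience for quick comparisons
        return self.mi


@dataclass
class EstimatorConfig:
    """Settings of the plug-in MI estimator.

    ``pooling='mean'`` computes MI on across-tree daily means (one sample per
    day); ``pooling='tree'`` keeps each tree-day as a separate sample, which
    is the only non-degenerate choice for sampling-day-only variables in the
    two-day recovery stratum.
    """

    n_bins: int = 2
    scheme: str = "quantile"
    pooling: str = "mean"
    periods: tuple[str, ...] = ("full", "drydown", "recovery")
    rewater_day: int = 10
    miller_madow: bool = False
    measurements: Sequence[str] | None = None
    targets: Sequence[str] = TARGETS


def discretize(
    values: Iterable[float],
    n_bins: int = 2,
    scheme: str = "quantile",
    source: str = "",
) -> DiscretizedVariable:
    """Bin a 1-D series of values into ``n_bins`` integer labels.

    ``equal_width`` partitions [min, max] into equal intervals with the final
    bin right-closed.  ``quantile`` splits by empirical quantiles with ties
    resolved by rank-then-index ordering, so bin counts are as equal as
    arithmetic allows.  NaNs must be removed by the caller (missing days are
    excluded, never imputed).
    """
    v = np.asarray(list(values) if not isinstance(values, np.ndarray) else values,
                   dtype=float)
    if v.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if np.isnan(v).any():
        raise ValueError("values contain NaN; drop missing entries first")
    if v.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")

    if np.ptp(v) == 0.0:
        # Degenerate constant series: a single occupied bin, entropy zero.
        import warnings

        warnings.warn(
            "constant series: all values fall in a single bin (entropy 0)",
            stacklevel=2,
        )
        labels = np.zeros(v.size, dtype=np.int64)
        return DiscretizedVariable(labels, n_bins, scheme, source)

    if scheme == "equal_width":
        lo, hi = v.min(), v.max()
        width = (hi - lo) / n_bins
        labels = np.minimum((np.floor((v - lo) / width)).astype(np.int64),
                            n_bins - 1)
    elif scheme == "quantile":
        order = np.argsort(v, kind="stable")  # rank, ties broken by index
        labels = np.empty(v.size, dtype=np.int64)
        labels[order] = (np.arange(v.size) * n_bins) // v.size
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return DiscretizedVariable(labels, n_bins, scheme, source)


def _counts(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty label array")
    if labels.min() < 0:
        raise ValueError("labels must be non-negative")
    return np.bincount(labels)


def _entropy_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def entropy(labels: Iterable[int]) -> float:
    """Plug-in Shannon entropy of integer labels, in bits (0·log0 = 0)."""
    labels = np.asarray(list(labels) if not isinstance(labels, np.ndarray)
                        else labels)
    return _entropy_from_counts(_counts(labels))


def joint_entropy(labels_x: Iterable[int], labels_y: Iterable[int]) -> float:
    """Plug-in entropy of the joint (X, Y) histogram, in bits."""
    x = np.asarray(labels_x, dtype=np.int64)
    y = np.asarray(labels_y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("label arrays must have equal length")
    joint = x * (y.max() + 1 if y.size else 1) + y
    return _entropy_from_counts(_counts(joint))


def conditional_entropy(labels_x: Iterable[int], labels_y: Iterable[int]) -> float:
    """H(X|Y) = H(X,Y) - H(Y) on the joint plug-in histogram, in bits."""
    x = np.asarray(labels_x, dtype=np.int64)
    y = np.asarray(labels_y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("label arrays must have equal length")
    return joint_entropy(x, y) - entropy(y)


def mutual_information_from_labels(
    labels_x: Iterable[int],
    labels_y: Iterable[int],
    miller_madow: bool = False,
) -> float:
    """MI in bits between two pre-discretized label series.

    Computed both as H(X) - H(X|Y) and as H(X) + H(Y) - H(X,Y); the two
    routes must agree to 1e-12.  Tiny negative values from float round-off
    are clipped to zero.
    """
    x = np.asarray(labels_x, dtype=np.int64)
    y = np.asarray(labels_y, dtype=np.int64)
    if x.shape != y.shape:
        raise ValueError("label arrays must have equal length")
    h_x = entropy(x)
    h_y = entropy(y)
    h_xy = joint_entropy(x, y)
    via_conditional = h_x - conditional_entropy(x, y)
    via_joint = h_x + h_y - h_xy
    if abs(via_conditional - via_joint) > _AGREE_TOL:
        raise AssertionError(
            f"MI identity violated: {via_conditional!r} vs {via_joint!r}"
        )
    mi = via_joint
    if miller_madow:
        n = x.size
        k_x = len(np.unique(x))
        k_y = len(np.unique(y))
        k_xy = len(np.unique(x * (y.max() + 1) + y))
        mi += (k_x + k_y - k_xy - 1) / (2.0 * n * np.log(2.0))
    if mi < 0.0:
        if mi < -_AGREE_TOL and not miller_madow:
            raise AssertionError(f"plug-in MI should be non-negative, got {mi}")
        mi = 0.0
    return float(mi)


def mutual_information(
    x: Iterable[float],
    y: Iterable[float],
    n_bins: int = 2,
    scheme: str = "quantile",
    miller_madow: bool = False,
    measurement: str = "x",
    target: str = "y",
    period: str = "full",
) -> MIResult:
    """Discretize two paired series and return their mutual information.

    Pairs with a missing value in either series are dropped (pairwise
    complete).  With fewer than 3 complete pairs the result is returned with
    ``reliable=False`` rather than raising.
    """
    xv = np.asarray(list(x) if not isinstance(x, np.ndarray) else x, dtype=float)
    yv = np.asarray(list(y) if not isinstance(y, np.ndarray) else y, dtype=float)
    if xv.shape != yv.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xv) | np.isnan(yv))
    xv, yv = xv[keep], yv[keep]
    n = int(xv.size)
    if n < 2:
        return MIResult(measurement, target, period, float("nan"), float("nan"),
                        float("nan"), float("nan"), n, n_bins, scheme,
                        reliable=False)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dx = discretize(xv, n_bins=n_bins, scheme=scheme)
        dy = discretize(yv, n_bins=n_bins, scheme=scheme)
    mi = mutual_information_from_labels(dx.labels, dy.labels,
                                        miller_madow=miller_madow)
    return MIResult(
        measurement=measurement,
        target=target,
        period=period,
        mi=mi,
        h_x=entropy(dx.labels),
        h_y=entropy(dy.labels),
        h_xy=joint_entropy(dx.labels, dy.labels),
        n=n,
        n_bins=n_bins,
        scheme=scheme,
        reliable=n >= _MIN_RELIABLE_PAIRS,
    )


def _period_mask(days: np.ndarray, period: str, rewater_day: int) -> np.ndarray:
    if period == "full":
        return np.ones(days.size, dtype=bool)
    if period == "drydown":
        return days < rewater_day
    if period == "recovery":
        return days >= rewater_day
    raise ValueError(f"unknown period {period!r}")


def mi_table(
    summary,
    config: EstimatorConfig | None = None,
) -> pd.DataFrame:
    """Mutual information of every (measurement, target, period) triple.

    ``summary`` is a :class:`~drydown.sensor_processing.DailySummaryTable`
    (or any object with ``pooled`` and ``per_tree`` day-by-variable frames).
    Rows follow the measurement grouping order (physical environment, plant
    water sources, plant water status, plant fluxes).
    """
    config = config or EstimatorConfig()
    if config.pooling == "mean":
        frame = summary.pooled.copy()
        frame["_day"] = frame.index.to_numpy()
    elif config.pooling == "tree":
        parts = []
        for tree, tab in summary.per_tree.items():
            part = tab.copy()
            part["_day"] = part.index.to_numpy()
            parts.append(part)
        frame = pd.concat(parts, ignore_index=True)
    else:
        raise ValueError(f"unknown pooling {config.pooling!r}")

    for target in config.targets:
        if target not in frame.columns:
            raise ValueError(
                f"unknown target {target!r}; valid targets: {list(TARGETS)}"
            )
    measurements = tuple(config.measurements) if config.measurements else tuple(
        m for m in MEASUREMENT_ORDER if m in frame.columns
    )

    days = frame["_day"].to_numpy()
    rows = []
    for target in config.targets:
        for measurement in measurements:
            for period in config.periods:
                mask = _period_mask(days, period, config.rewater_day)
                if not mask.any():
                    continue  # empty stratum: row absent, not NaN
                res = mutual_information(
                    frame.loc[mask, measurement].to_numpy(dtype=float),
                    frame.loc[mask, target].to_numpy(dtype=float),
                    n_bins=config.n_bins,
                    scheme=config.scheme,
                    miller_madow=config.miller_madow,
                    measurement=measurement,
                    target=target,
                    period=period,
                )
                rows.append(res)
    out = pd.DataFrame(
        {
            "measurement": [r.measurement for r in rows],
            "target": [r.target for r in rows],
            "period": [r.period for r in rows],
            "mi_bits": [r.mi for r in rows],
            "h_x": [r.h_x for r in rows],
            "h_y": [r.h_y for r in rows],
            "h_xy": [r.h_xy for r in rows],
            "n": [r.n for r in rows],
            "n_bins": [r.n_bins for r in rows],
            "scheme": [r.scheme for r in rows],
            "reliable": [r.reliable for r in rows],
        }
    )
    return out
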