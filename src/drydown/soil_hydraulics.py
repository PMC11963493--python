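"""Bimodal (Durner-type) van Genuchten water retention: evaluate, invert, fit.

The retention curve maps soil water potential psi (kPa, <= 0) to volumetric
water content theta (% v/v) as a weighted sum of two van Genuchten terms,

    S_e(psi) = sum_i w_i * [1 + (alpha_i * |psi|)^n_i]^(-m_i),
    theta(psi) = theta_r + (theta_s - theta_r) * S_e(psi),

with the Mualem constraint m_i = 1 - 1/n_i.  The two-term mixture captures
dual-porosity potting substrates whose drainage shows two distinct pore
systems.  Potentials are handled in kPa internally; helpers convert to MPa
for comparison with plant water potentials.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "RetentionParams",
    "RetentionFit",
    "retention_theta",
    "retention_psi",
    "fit_retention",
    "kpa_to_mpa",
    "mpa_to_kpa",
]

KPA_PER_MPA = 1000.0


def kpa_to_mpa(psi_kpa):
    return np.asarray(psi_kpa, dtype=float) / KPA_PER_MPA


def mpa_to_kpa(psi_mpa):
    return np.asarray(psi_mpa, dtype=float) * KPA_PER_MPA


@dataclass(frozen=True)
class RetentionParams:
    """Parameters of the bimodal van Genuchten retention curve.

    theta_r, theta_s in % v/v; alpha_i in 1/kPa; n_i dimensionless (> 1);
    w1 is the weight of the first pore system (w2 = 1 - w1).
    """

    theta_r: float
    theta_s: float
    w1: float
    alpha1: float
    n1: float
    alpha2: float
    n2: float

    def __post_init__(self) -> None:
        if not self.theta_s > self.theta_r:
            raise ValueError("theta_s must exceed theta_r")
        if not 0.0 < self.w1 < 1.0:
            raise ValueError("w1 must be in (0, 1)")
        for name in ("alpha1", "alpha2"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be > 0")
        for name in ("n1", "n2"):
            if not getattr(self, name) > 1.0:
                raise ValueError(f"{name} must be > 1")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    @property
    def m1(self) -> float:
        return 1.0 - 1.0 / self.n1

    @property
    def m2(self) -> float:
        return 1.0 - 1.0 / self.n2

    def as_array(self) -> np.ndarray:
        return np.array([self.theta_r, self.theta_s, self.w1,
                         self.alpha1, self.n1, self.alpha2, self.n2])


def effective_saturation(psi, params: RetentionParams):
    """S_e(psi) in [0, 1] for psi <= 0 kPa."""
    psi = np.asarray(psi, dtype=float)
    if np.any(psi > 0.0):
        raise ValueError("psi must be <= 0 kPa (tension convention)")
    h = np.abs(psi)
    s1 = (1.0 + (params.alpha1 * h) ** params.n1) ** (-params.m1)
    s2 = (1.0 + (params.alpha2 * h) ** params.n2) ** (-params.m2)
    return params.w1 * s1 + params.w2 * s2


def retention_theta(psi, params: RetentionParams):
    """Volumetric water content (% v/v) at water potential psi (kPa, <= 0)."""
    se = effective_saturation(psi, params)
    out = params.theta_r + (params.theta_s - params.theta_r) * se
    return out if np.ndim(psi) else float(out)


def _psi_scalar(theta: float, params: RetentionParams) -> float:
    if theta > params.theta_s or theta <= params.theta_r:
        raise ValueError(
            f"theta={theta} outside invertible range "
            f"({params.theta_r}, {params.theta_s}] % v/v"
        )
    if theta == params.theta_s:
        return 0.0
    # Bracket on log10|psi|; the curve is strictly decreasing in |psi|.
    f = lambda log_h: retention_theta(-(10.0 ** log_h), params) - theta
    lo, hi = -9.0, 12.0
    while f(lo) < 0 and lo > -30:  # theta extremely close to theta_s
        lo -= 3.0
    while f(hi) > 0 and hi < 30:  # theta extremely close to theta_r
        hi += 3.0
    log_h = optimize.brentq(f, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200)
    return -(10.0 ** log_h)


def retention_psi(theta, params: RetentionParams):
    """Invert the retention curve: water potential (kPa) at theta (% v/v).

    Bracketed monotone root finding; round-trips through
    :func:`retention_theta` to better than 1e-8 relative.
    """
    if np.ndim(theta) == 0:
        return _psi_scalar(float(theta), params)
    return np.array([_psi_scalar(float(t), params) for t in np.asarray(theta)])


@dataclass
class RetentionFit:
    """Result of :func:`fit_retention`."""

    params: RetentionParams
    rmse: float
    converged: bool
    n_starts: int
    cost_history: list


_DEFAULT_BOUNDS = {
    "theta_r": (0.0, 15.0),
    "theta_s": (20.0, 70.0),
    "w1": (1e-3, 1.0 - 1e-3),
    "log10_alpha": (-4.0, 1.0),  # alpha in [1e-4, 10] 1/kPa
    "n": (1.0 + 1e-6, 10.0),
}


def _unpack(x: np.ndarray) -> RetentionParams:
    return RetentionParams(
        theta_r=float(x[0]), theta_s=float(x[1]), w1=float(x[2]),
        alpha1=float(10.0 ** x[3]), n1=float(x[4]),
        alpha2=float(10.0 ** x[5]), n2=float(x[6]),
    )


def _canonical(p: RetentionParams) -> RetentionParams:
    """Order pore systems so alpha1 >= alpha2 (coarse system first)."""
    if p.alpha1 >= p.alpha2:
        return p
    return RetentionParams(p.theta_r, p.theta_s, 1.0 - p.w1,
                           p.alpha2, p.n2, p.alpha1, p.n1)


def fit_retention(
    psi: Sequence[float],
    theta: Sequence[float],
    init: RetentionParams | None = None,
    bounds: dict | None = None,
    n_starts: int = 10,
    seed: int = 0,
) -> RetentionFit:
    """Fit the bimodal retention curve to (psi, theta) pairs.

    Bounded nonlinear least squares on theta residuals (scipy trust-region
    reflective), with ``n_starts`` seeded random restarts; the best-RMSE
    solution is returned.  Requires >= 8 pairs spanning >= 2 decades of
    |psi| so both pore systems are identifiable.
    """
    psi = np.asarray(psi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if psi.shape != theta.shape:
        raise ValueError("psi and theta must have equal length")
    if psi.size < 8:
        raise ValueError("need >= 8 (psi, theta) pairs")
    h = np.abs(psi[psi != 0.0])
    if h.size and np.log10(h.max() / h.min()) < 2.0:
        raise ValueError("pairs must span >= 2 decades of |psi|")

    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    lo = np.array([b["theta_r"][0], b["theta_s"][0], b["w1"][0],
                   b["log10_alpha"][0], b["n"][0],
                   b["log10_alpha"][0], b["n"][0]])
    hi = np.array([b["theta_r"][1], b["theta_s"][1], b["w1"][1],
                   b["log10_alpha"][1], b["n"][1],
                   b["log10_alpha"][1], b["n"][1]])

    def residuals(x):
        return retention_theta(psi, _unpack(x)) - theta

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(np.array([init.theta_r, init.theta_s, init.w1,
                                np.log10(init.alpha1), init.n1,
                                np.log10(init.alpha2), init.n2]))
    # Heuristic start: theta extremes from the data, split pore systems.
    starts.append(np.array([max(theta.min() - 1.0, lo[0] + 0.1),
                            min(theta.max() + 1.0, hi[1] - 0.1),
                            0.5, -1.0, 1.6, -2.5, 1.3]))
    while len(starts) < n_starts:
        starts.append(lo + (hi - lo) * rng.random(7))

    best = None
    history = []
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = optimize.least_squares(
                residuals, x0, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        history.append(float(sol.cost))
        if sol.x[1] <= sol.x[0]:  # theta_s <= theta_r: invalid corner
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("retention fit failed to converge from any start")
    params = _canonical(_unpack(best.x))
    rmse = float(np.sqrt(np.mean(residuals(best.x) ** 2)))
    return RetentionFit(params=params, rmse=rmse,
                        converged=bool(best.success), n_starts=len(starts),
                        cost_history=history)
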