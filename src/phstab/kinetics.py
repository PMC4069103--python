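"""Enzyme inactivation and Michaelis–Menten kinetics fitting.

Irreversible pH/temperature inactivation follows first-order kinetics,
A(t) = A₀·exp(−k_in·t) with t in minutes and k_in in min⁻¹; the
stabilization achieved by a mutation is the ratio of the reference to the
variant inactivation constant.  Steady-state activity follows the
Michaelis–Menten law v = k_cat·E₀·[S]/(K_M + [S]) with [S] and K_M in µM,
k_cat in s⁻¹, and catalytic efficiency k_cat/K_M in µM⁻¹·s⁻¹.

Both fits are nonlinear least squares (trust-region, analytic Jacobian)
with data-driven initial guesses — log-linear regression for the decay,
K_M = median([S]) and V_max = max(v) for the saturation curve — plus two
perturbed restarts, keeping the best solution.  Standard errors come from
the fit covariance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayData",
    "InactivationFit",
    "MMData",
    "MMFit",
    "fit_inactivation",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "stabilization_fold",
]


@dataclass
class DecayData:
    """Residual-activity time course: times (min) and activities (a.u.)."""

    times: np.ndarray
    activities: np.ndarray
    ph: float | None = None
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.activities = np.asarray(self.activities, dtype=float)
        if self.times.shape != self.activities.shape:
            raise ValueError("times and activities must have equal length")
        if self.times.size < 4:
            raise ValueError("need >= 4 points to fit a decay")
        if np.any(self.times < 0) or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")


@dataclass
class InactivationFit:
    """First-order inactivation constants with uncertainties."""

    k_in: float  # min^-1
    a0: float
    k_in_se: float
    a0_se: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.k_in < 0:
            raise ValueError("k_in must be >= 0")
        if self.a0 <= 0:
            raise ValueError("A0 must be > 0")


@dataclass
class MMData:
    """Initial-rate data: substrate concentrations (µM) and rates (µM s⁻¹)."""

    substrate_concentrations: np.ndarray
    initial_rates: np.ndarray
    enzyme_concentration: float = 1.0  # µM

    def __post_init__(self) -> None:
        self.substrate_concentrations = np.asarray(self.substrate_concentrations, dtype=float)
        self.initial_rates = np.asarray(self.initial_rates, dtype=float)
        if self.substrate_concentrations.shape != self.initial_rates.shape:
            raise ValueError("substrate and rate arrays must have equal length")
        if self.substrate_concentrations.size < 5:
            raise ValueError("need >= 5 substrate points")
        if np.any(self.substrate_concentrations <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if self.enzyme_concentration <= 0:
            raise ValueError("enzyme concentration must be > 0")


@dataclass
class MMFit:
    """Michaelis–Menten parameters with uncertainties."""

    k_cat: float  # s^-1
    k_m: float  # µM
    k_cat_se: float
    k_m_se: float
    poorly_constrained: bool = False

    def __post_init__(self) -> None:
        if self.k_cat <= 0 or self.k_m <= 0:
            raise ValueError("k_cat and K_M must be > 0")

    @property
    def efficiency(self) -> float:
        return self.k_cat / self.k_m


def _multistart_fit(model, jac, x, y, p0, rng_factors=(1.0, 0.5, 2.0), bounds=(-np.inf, np.inf)):
    """curve_fit from several scaled starts; return the lowest-SSR solution."""
    best = None
    for factor in rng_factors:
        try:
            popt, pcov = curve_fit(
                model,
                x,
                y,
                p0=[p * factor for p in p0],
                jac=jac,
                bounds=bounds,
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        ssr = float(np.sum((model(x, *popt) - y) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise RuntimeError("nonlinear fit failed to converge from all starts")
    return best


def fit_inactivation(data: DecayData) -> InactivationFit:
    """Fit A(t) = A₀·exp(−k_in·t) by nonlinear least squares.

    Initial guesses come from a log-linear regression on the positive
    activities; constant data fit with k_in = 0.  Non-decaying (rising) or
    entirely non-positive data raise with a diagnostic.
    """
    t, a = data.times, data.activities
    pos = a > 0
    if np.count_nonzero(pos) < 2:
        raise ValueError("cannot fit: fewer than 2 positive activity values")
    slope, intercept = np.polyfit(t[pos], np.log(a[pos]), 1)
    if slope > 1e-12 and a[-1] > a[0] * 1.05:
        raise ValueError(
            "activities increase over time: not first-order inactivation data"
        )
    k0 = max(-slope, 0.0)
    a0_guess = float(np.exp(intercept))

    def model(t, a0, k):
        return a0 * np.exp(-k * t)

    def jac(t, a0, k):
        e = np.exp(-k * t)
        return np.stack([e, -a0 * t * e], axis=1)

    _, popt, pcov = _multistart_fit(
        model, jac, t, a, [a0_guess, k0 if k0 > 0 else 1e-6],
        bounds=([1e-12, 0.0], [np.inf, np.inf]),
    )
    a0_hat, k_hat = popt
    se = np.sqrt(np.diag(pcov))
    ss_res = float(np.sum((a - model(t, *popt)) ** 2))
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return InactivationFit(
        k_in=float(k_hat),
        a0=float(a0_hat),
        k_in_se=float(se[1]),
        a0_se=float(se[0]),
        r_squared=r2,
    )


def fit_michaelis_menten(data: MMData) -> MMFit:
    """Fit v = k_cat·E₀·[S]/(K_M + [S]) by nonlinear least squares.

    Initial guesses: K_M = median([S]), V_max = max(v).  When the substrate
    grid shows no curvature (all [S] far above or far below the fitted K_M)
    the fit is flagged poorly constrained.
    """
    s, v = data.substrate_concentrations, data.initial_rates
    e0 = data.enzyme_concentration
    km0 = float(np.median(s))
    kcat0 = float(np.max(v)) / e0

    def model(s, kcat, km):
        return kcat * e0 * s / (km + s)

    def jac(s, kcat, km):
        denom = km + s
        return np.stack([e0 * s / denom, -kcat * e0 * s / denom**2], axis=1)

    _, popt, pcov = _multistart_fit(
        model, jac, s, v, [kcat0, km0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
    )
    kcat_hat, km_hat = popt
    se = np.sqrt(np.diag(pcov))
    poorly = bool(km_hat < 0.2 * s.min() or km_hat > 5.0 * s.max())
    return MMFit(
        k_cat=float(kcat_hat),
        k_m=float(km_hat),
        k_cat_se=float(se[0]),
        k_m_se=float(se[1]),
        poorly_constrained=poorly,
    )


def catalytic_efficiency(fit_or_kcat, k_m: float | None = None) -> float:
    """k_cat/K_M (µM⁻¹ s⁻¹); accepts an MMFit or the two constants.

    Reports use two significant figures, matching the field's convention.
    """
    if isinstance(fit_or_kcat, MMFit):
        return fit_or_kcat.efficiency
    k_cat = float(fit_or_kcat)
    if k_m is None:
        raise TypeError("pass an MMFit or both k_cat and K_M")
    if k_cat == 0:
        return 0.0
    return k_cat / float(k_m)


def stabilization_fold(k_in_reference: float, k_in_variant: float) -> float:
    """Fold stabilization of a variant: k_in(reference) / k_in(variant)."""
    if k_in_reference <= 0 or k_in_variant <= 0:
        raise ValueError("inactivation constants must be > 0")
    return k_in_reference / k_in_variant
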