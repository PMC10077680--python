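"""Closed-form variance, power and sample size for the HTE test.

Three sizing routes are provided for a two-arm CRT with a continuous outcome
and an individual-level effect modifier:

* :func:`n_complete` — complete follow-up,
* :func:`n_mcar` — attrition missing completely at random, treated as a
  randomly varying observed cluster size ``pi*m`` with coefficient of
  variation driven by the missingness ICC ``tau``,
* :func:`n_direct_inflation` — the naive comparator that divides the
  complete-data requirement by the mean follow-up rate.

All requirements are rounded up to the nearest even integer so the two arms
stay balanced.  Power is for the two-sided Wald z-test of the interaction.
"""

from __future__ import annotations

import warnings
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import (
    AttritionSpec,
    HTEDesign,
    InfeasibleDesignError,
    SampleSizeResult,
    round_up_even,
)

__all__ = [
    "var_beta4_complete",
    "var_beta4_mcar",
    "n_complete",
    "n_mcar",
    "n_direct_inflation",
    "cf_unequal",
    "cf_mcar",
    "observed_size_moments",
    "power_at_n",
    "ratio_contour_grid",
]


def _brace(m: float, rho_y: float, rho_x: float) -> float:
    """Denominator term 1 + (m-2)rho_y - (m-1)rho_x*rho_y; must be positive."""
    b = 1.0 + (m - 2.0) * rho_y - (m - 1.0) * rho_x * rho_y
    if b <= 0:
        raise InfeasibleDesignError(
            f"infeasible ICC combination: 1+(m-2)rho_y-(m-1)rho_x*rho_y = {b:.4g} <= 0 "
            f"(m={m}, rho_y={rho_y}, rho_x={rho_x})"
        )
    return b


def var_beta4_complete(design: HTEDesign, n: int) -> float:
    """Variance of the interaction estimator with complete follow-up.

    Var(b4_hat) = sigma2_y (1-rho_y){1+(m-1)rho_y}
                  / [ n m sigma2_w sigma2_x {1+(m-2)rho_y-(m-1)rho_x rho_y} ].
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = design
    num = d.sigma2_y * (1 - d.rho_y) * (1 + (d.m - 1) * d.rho_y)
    den = n * d.m * d.sigma2_w * d.sigma2_x * _brace(d.m, d.rho_y, d.rho_x)
    return num / den


def power_at_n(variance_at_n: float, delta: float, alpha: float) -> float:
    """Power of the two-sided z-test given the variance of the estimator.

    Phi(|delta|/sqrt(var) - z_{1-alpha/2}); the vanishing tail from the far
    rejection region is ignored, so delta = 0 yields alpha/2.
    """
    if variance_at_n <= 0:
        raise ValueError("variance must be positive")
    z_a = norm.ppf(1 - alpha / 2)
    return float(norm.cdf(abs(delta) / np.sqrt(variance_at_n) - z_a))


def _z_sum(design: HTEDesign) -> float:
    return norm.ppf(1 - design.alpha / 2) + norm.ppf(design.power_target)


def _check_delta(design: HTEDesign) -> None:
    if design.delta == 0:
        raise ValueError("effect size delta must be nonzero for a sample-size call")


def _advise_small_n(n: int) -> None:
    if n < 10:
        warnings.warn(
            f"required n = {n} clusters is very small; the z-test approximation "
            "ignores small-sample degrees of freedom and may be optimistic",
            UserWarning,
            stacklevel=3,
        )


def n_complete(design: HTEDesign) -> SampleSizeResult:
    """Clusters needed for the HTE test under complete follow-up."""
    _check_delta(design)
    n_raw = _z_sum(design) ** 2 * var_beta4_complete(design, 1) / design.delta ** 2
    n = round_up_even(n_raw)
    _advise_small_n(n)
    power = power_at_n(var_beta4_complete(design, n), design.delta, design.alpha)
    return SampleSizeResult(n=n, method="complete", n_raw=n_raw,
                            predicted_power=power, cf=1.0)


def observed_size_moments(m: int, spec: AttritionSpec) -> tuple[float, float, float]:
    """Mean, variance and CV of the observed cluster size under MCAR.

    With follow-up rate pi and exchangeable indicator correlation tau:
    mean = pi*m; var = pi(1-pi)m{1+tau(m-1)}; CV = sqrt of var/mean^2.
    """
    spec.check_tau_bounds(m)
    pi, tau = spec.pi, spec.tau
    mean = pi * m
    var = pi * (1 - pi) * m * (1 + tau * (m - 1))
    var = max(var, 0.0)  # the tau lower bound gives exactly zero up to rounding
    return mean, var, float(np.sqrt(var) / mean)


def cf_unequal(design: HTEDesign, mean_m: float, cv: float) -> float:
    """Sample-size correction factor for randomly varying cluster sizes.

    CF(m_bar, CV) = [1 - CV^2 * m_bar rho_y (1-rho_y)(rho_x-rho_y)
                     / (brace(m_bar) * {1+(m_bar-1)rho_y}^2)]^{-1},
    where brace(.) is the complete-data variance denominator term.  Equals 1
    when CV = 0 or rho_x = rho_y, exceeds 1 when rho_x > rho_y (size-variability
    costs power there) and falls below 1 when rho_x < rho_y.
    """
    if mean_m <= 1:
        raise ValueError("mean cluster size must exceed 1")
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    d = design
    num = mean_m * d.rho_y * (1 - d.rho_y) * (d.rho_x - d.rho_y)
    den = _brace(mean_m, d.rho_y, d.rho_x) * (1 + (mean_m - 1) * d.rho_y) ** 2
    bracket = 1 - cv ** 2 * num / den
    if bracket <= 0:
        raise InfeasibleDesignError(
            f"correction-factor bracket {bracket:.4g} <= 0 at mean_m={mean_m}, cv={cv}"
        )
    return 1.0 / bracket


def cf_mcar(design: HTEDesign, spec: AttritionSpec) -> float:
    """Attrition correction factor CF(pi, tau): cf_unequal at the observed-size
    moments pi*m and CV = sqrt[(1-pi){1+tau(m-1)}/(pi*m)]."""
    mean, _, cv = observed_size_moments(design.m, spec)
    return cf_unequal(design, mean, cv)


def var_beta4_mcar(design: HTEDesign, spec: AttritionSpec, n: float) -> float:
    """Attrition-adjusted variance of the interaction estimator.

    The complete-data variance evaluated at the expected observed cluster
    size pi*m, multiplied by CF(pi, tau).
    """
    d = design
    mc = spec.pi * d.m
    if mc <= 1:
        raise ValueError(f"expected observed cluster size pi*m = {mc:.3g} must exceed 1")
    num = d.sigma2_y * (1 - d.rho_y) * (1 + (mc - 1) * d.rho_y)
    den = n * mc * d.sigma2_w * d.sigma2_x * _brace(mc, d.rho_y, d.rho_x)
    return num / den * cf_mcar(design, spec)


def n_mcar(design: HTEDesign, spec: AttritionSpec) -> SampleSizeResult:
    """Clusters needed under MCAR attrition (adjusted formula)."""
    _check_delta(design)
    cf = cf_mcar(design, spec)
    n_raw = _z_sum(design) ** 2 * var_beta4_mcar(design, spec, 1) / design.delta ** 2
    n = round_up_even(n_raw)
    _advise_small_n(n)
    power = power_at_n(var_beta4_mcar(design, spec, n), design.delta, design.alpha)
    return SampleSizeResult(n=n, method="mcar_formula", n_raw=n_raw,
                            predicted_power=power, cf=cf)


def n_direct_inflation(design: HTEDesign, spec: AttritionSpec) -> SampleSizeResult:
    """Naive comparator: complete-data requirement divided by the follow-up rate."""
    _check_delta(design)
    n_raw = (_z_sum(design) ** 2 * var_beta4_complete(design, 1)
             / design.delta ** 2) / spec.pi
    n = round_up_even(n_raw)
    _advise_small_n(n)
    # the method's implied variance at n clusters keeps the same 1/n scaling
    power = power_at_n(var_beta4_complete(design, n * spec.pi),
                       design.delta, design.alpha)
    return SampleSizeResult(n=n, method="direct_inflation", n_raw=n_raw,
                            predicted_power=power, cf=1.0)


def ratio_contour_grid(
    design: HTEDesign,
    spec: AttritionSpec,
    rho_y_grid: Iterable[float],
    rho_x_grid: Iterable[float],
) -> pd.DataFrame:
    """Unrounded ratio n_mcar / n_direct_inflation over an ICC grid.

    Returns a long DataFrame with columns rho_y, rho_x, n1_raw, n0_raw,
    ratio.  Infeasible ICC cells are kept with NaN entries rather than
    aborting the grid.  Unrounded requirements are used so the surface is
    smooth (the even-rounding staircase would dominate otherwise).
    """
    rows = []
    for ry in rho_y_grid:
        for rx in rho_x_grid:
            d = HTEDesign(m=design.m, rho_y=ry, rho_x=rx,
                          sigma2_y=design.sigma2_y, sigma2_x=design.sigma2_x,
                          sigma2_w=design.sigma2_w, delta=design.delta,
                          alpha=design.alpha, power_target=design.power_target)
            try:
                n1 = _z_sum(d) ** 2 * var_beta4_mcar(d, spec, 1) / d.delta ** 2
                n0 = (_z_sum(d) ** 2 * var_beta4_complete(d, 1)
                      / d.delta ** 2) / spec.pi
                rows.append((ry, rx, n1, n0, n1 / n0))
            except InfeasibleDesignError:
                rows.append((ry, rx, np.nan, np.nan, np.nan))
    return pd.DataFrame(rows, columns=["rho_y", "rho_x", "n1_raw", "n0_raw", "ratio"])
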