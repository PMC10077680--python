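"""Synthetic-trial generators matching the planning model's assumptions.

Everything here is vectorized over clusters and, where useful, over Monte
Carlo replicates: arrays are laid out ``(..., n, m)`` with ``n`` clusters of
planned size ``m``.  All generators are deterministic given a
``numpy.random.Generator``.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermitenorm

from .design import (
    AttritionSpec,
    CalibrationError,
    CovariateSpec,
    HTEDesign,
    LOGISTIC_LATENT_VARIANCE,
    Mechanism,
    TrialData,
)

__all__ = [
    "gen_treatment",
    "gen_covariates",
    "gen_missingness_mcar",
    "gen_missingness_mar",
    "calibrate_mar",
    "gen_outcomes",
    "simulate_trial",
]


def gen_treatment(n: int, rng: np.random.Generator) -> np.ndarray:
    """1:1 cluster randomization: a random permutation with exactly n/2 ones."""
    if n % 2 != 0 or n < 2:
        raise ValueError(f"n must be a positive even integer, got {n}")
    w = np.zeros(n, dtype=np.int64)
    w[: n // 2] = 1
    return rng.permutation(w)


def gen_covariates(
    spec: CovariateSpec, n: int, m: int, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Draw effect-modifier matrices with the requested covariate ICC.

    Returns an array of shape ``(size, n, m)`` squeezed to ``(n, m)`` when
    ``size == 1``.  Continuous covariates follow the random-intercept normal
    model; binary covariates the beta-binomial (cluster rate from a Beta,
    individuals Bernoulli given the rate).
    """
    shape = (size, n, 1)
    if spec.kind == "continuous":
        lam = rng.normal(0.0, np.sqrt(spec.rho_x * spec.sigma2_x), shape)
        gam = rng.normal(0.0, np.sqrt((1 - spec.rho_x) * spec.sigma2_x), (size, n, m))
        x = spec.mean + lam + gam
    else:
        if spec.rho_x == 0:
            p = np.full(shape, spec.mean)
        else:
            q1, q2 = spec.beta_shapes
            p = rng.beta(q1, q2, shape)
        x = (rng.random((size, n, m)) < p).astype(np.float64)
    return x[0] if size == 1 else x


def exchangeable_binary_bounds(m: int, pi: float) -> tuple[float, float]:
    """Correlation range the conditional-linear-family recursion can realize
    for an exchangeable Bernoulli(pi) vector of length m.

    The positive-semidefiniteness bound is [-1/(m-1), 1]; negative
    correlations additionally require every conditional mean to stay inside
    [0, 1] along realizable histories, which constrains tau to
    -min(pi, 1-pi) / (1 - min(pi, 1-pi)) / (m-1) at worst.  We report the PSD
    bound and validate realizability during generation.
    """
    return -1.0 / (m - 1), 1.0


def gen_missingness_mcar(
    n: int, m: int, pi: float, tau: float, rng: np.random.Generator, size: int = 1
) -> np.ndarray:
    """Exchangeable correlated binary follow-up indicators.

    Each cluster row is an exchangeable 0/1 vector with marginal mean ``pi``
    and pairwise correlation ``tau``, built by the conditional linear family:
    the conditional mean of O_j given the previous draws is

        pi + tau / (1 + (j-2) tau) * sum_{k<j} (O_k - pi),

    which reproduces the compound-symmetric correlation exactly and covers
    the whole feasible range, including tau = 1 (whole-cluster attrition) and
    the negative lower bound.  Shape ``(size, n, m)``, squeezed when size==1.
    """
    lo, hi = exchangeable_binary_bounds(m, pi)
    if not lo - 1e-12 <= tau <= hi + 1e-12:
        raise ValueError(
            f"tau={tau} outside attainable range [{lo:.6g}, {hi}] for m={m}"
        )
    out = np.empty((size, n, m), dtype=np.int64)
    out[..., 0] = rng.random((size, n)) < pi
    resid = out[..., 0] - pi  # running sum of (O_k - pi)
    for j in range(1, m):
        lam = pi + tau / (1 + (j - 1) * tau) * resid
        if np.any(lam < -1e-9) or np.any(lam > 1 + 1e-9):
            raise ValueError(
                f"tau={tau} not realizable for Bernoulli({pi}) clusters of size {m}: "
                "a conditional mean left [0, 1]"
            )
        np.clip(lam, 0.0, 1.0, out=lam)
        draw = (rng.random((size, n)) < lam).astype(np.int64)
        out[..., j] = draw
        resid += draw - pi
    return out[0] if size == 1 else out


def calibrate_mar(
    pi_target: float,
    tau: float,
    alpha1: float,
    cov_spec: CovariateSpec,
    n_nodes: int = 80,
) -> tuple[float, float]:
    """Solve the MAR missingness model's intercept and random-intercept variance.

    The model is logit Pr(O_ij = 1 | X_ij, b_i) = alpha0 + alpha1 X_ij + b_i
    with b_i ~ N(0, sigma2_b).  The latent-scale missingness ICC fixes
    sigma2_b = tau * (pi^2/3) / (1 - tau) (circle constant, not follow-up
    rate), and alpha0 is root-solved so the marginal follow-up probability
    E[expit(alpha0 + alpha1 X + b)] equals ``pi_target``.

    For a continuous (normal) covariate the linear predictor is itself
    normal, so the expectation is a one-dimensional Gauss-Hermite quadrature;
    for a binary covariate it is the two-point mixture over X with quadrature
    over b.  Achieved rate matches the target to < 1e-6.
    """
    if not 0 <= tau < 1:
        raise ValueError(f"latent-scale tau must be in [0, 1), got {tau}")
    if not 0 < pi_target < 1:
        raise ValueError(f"pi_target must be in (0, 1), got {pi_target}")
    sigma2_b = tau * LOGISTIC_LATENT_VARIANCE / (1 - tau)

    nodes, weights = roots_hermitenorm(n_nodes)  # N(0,1) nodes
    weights = weights / weights.sum()

    if cov_spec.kind == "continuous":
        sd = np.sqrt(alpha1 ** 2 * cov_spec.sigma2_x + sigma2_b)

        def marginal(a0: float) -> float:
            return float(weights @ expit(a0 + alpha1 * cov_spec.mean + sd * nodes))
    else:
        p1 = cov_spec.mean
        sd_b = np.sqrt(sigma2_b)

        def marginal(a0: float) -> float:
            e0 = weights @ expit(a0 + sd_b * nodes)
            e1 = weights @ expit(a0 + alpha1 + sd_b * nodes)
            return float((1 - p1) * e0 + p1 * e1)

    if sigma2_b == 0 and alpha1 == 0:
        return float(logit(pi_target)), 0.0
    f = lambda a0: marginal(a0) - pi_target
    if f(-20.0) * f(20.0) > 0:
        raise CalibrationError(
            f"cannot bracket alpha0 in [-20, 20] for pi={pi_target}, tau={tau}"
        )
    alpha0 = brentq(f, -20.0, 20.0, xtol=1e-10)
    if abs(marginal(alpha0) - pi_target) > 1e-6:
        raise CalibrationError("alpha0 calibration did not reach 1e-6 accuracy")
    return float(alpha0), float(sigma2_b)


def gen_missingness_mar(
    X: np.ndarray,
    alpha0: float,
    alpha1: float,
    sigma2_b: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Covariate-dependent follow-up indicators from the mixed logistic model.

    ``X`` has shape ``(..., n, m)``; one random intercept is drawn per
    cluster, then indicators are Bernoulli(expit(alpha0 + alpha1 X + b))
    independently given the intercept.
    """
    b = rng.normal(0.0, np.sqrt(sigma2_b), X.shape[:-1] + (1,))
    p = expit(alpha0 + alpha1 * X + b)
    return (rng.random(X.shape) < p).astype(np.int64)


def gen_outcomes(
    X: np.ndarray,
    W: np.ndarray,
    beta: tuple[float, float, float, float],
    rho_y: float,
    sigma2_y: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Continuous outcomes from the interaction linear mixed model.

    Y_ij = b1 + b2 W_i + b3 X_ij + b4 W_i X_ij + mu_i + eps_ij with
    mu_i ~ N(0, rho_y*sigma2_y) and eps_ij ~ N(0, (1-rho_y)*sigma2_y).
    ``W`` broadcasts over the last (individual) axis.
    """
    b1, b2, b3, b4 = beta
    w = np.asarray(W)[..., None]
    mu = rng.normal(0.0, np.sqrt(rho_y * sigma2_y), X.shape[:-1] + (1,))
    eps = rng.normal(0.0, np.sqrt((1 - rho_y) * sigma2_y), X.shape)
    return b1 + b2 * w + (b3 + b4 * w) * X + mu + eps


def simulate_trial(
    design: HTEDesign,
    attrition: AttritionSpec,
    cov_spec: CovariateSpec,
    n: int,
    rng: np.random.Generator,
    beta: tuple[float, float, float, float] | None = None,
) -> TrialData:
    """Draw one complete CRT: treatment, covariates, outcomes, follow-up.

    ``beta`` defaults to (0, 0.25, 0.1, design.delta); the nuisance
    coefficients do not affect power.  Under MAR the attrition spec must
    already carry calibrated (alpha0, sigma2_b) — use :func:`calibrate_mar`.
    """
    if beta is None:
        beta = (0.0, 0.25, 0.1, design.delta)
    W = gen_treatment(n, rng)
    X = gen_covariates(cov_spec, n, design.m, rng)
    Y = gen_outcomes(X, W, beta, design.rho_y, design.sigma2_y, rng)
    if attrition.mechanism is Mechanism.MCAR:
        O = gen_missingness_mcar(n, design.m, attrition.pi, attrition.tau, rng)
    else:
        if attrition.alpha0 is None or attrition.sigma2_b is None:
            raise ValueError("MAR attrition spec must be calibrated first")
        O = gen_missingness_mar(X, attrition.alpha0, attrition.alpha1,
                                attrition.sigma2_b, rng)
    return TrialData(W=W, X=X, Y=Y, O=O)
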