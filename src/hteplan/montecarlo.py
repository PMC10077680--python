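"""Monte Carlo variance estimation and sample-size search under MAR.

When follow-up depends on the effect modifier, the observed cluster size is
correlated with the covariate values and no closed-form variance for the
interaction estimator exists.  Instead, the generalized-least-squares
information for the mean-centered interaction model

    Y_ij = b1 + b2 (W_i - Wbar) + b3 X_ij + b4 (W_i - Wbar) X_ij + ...

is accumulated over simulated draws of covariates and follow-up indicators:
for each draw, sum Z_i' R_i^{-1} Z_i over clusters (Z_i the observed design
rows, R_i the compound-symmetric working correlation of the observed
outcomes), average the 4x4 information over B draws, invert once, and read
Var(b4_hat) as sigma2_y times the (4,4) element.  A +/-2 search on the even
number of clusters then finds the smallest n whose predicted z-test power
reaches the target while n-2 falls short.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import (
    AttritionSpec,
    CovariateSpec,
    HTEDesign,
    Mechanism,
    SampleSizeResult,
)
from .generators import (
    calibrate_mar,
    gen_covariates,
    gen_missingness_mar,
    gen_missingness_mcar,
)
from .mcar import n_mcar, power_at_n

__all__ = ["r_inverse", "cluster_information", "mc_variance", "search_n",
           "MCVarianceResult", "SearchError"]


class SearchError(RuntimeError):
    """Sample-size search failed to terminate within the step cap."""


@dataclass(frozen=True)
class MCVarianceResult:
    """Monte Carlo estimate of Var(b4_hat) at a fixed number of clusters."""

    var_beta4: float
    n: int
    B: int
    info_avg: np.ndarray
    predicted_power: float
    seed: int | None = None


def r_inverse(m_i: int, rho_y: float) -> np.ndarray:
    """Closed-form inverse of the compound-symmetric correlation matrix.

    R = (1-rho)I + rho*J on m_i observed individuals inverts to
    (1-rho)^{-1} I - rho [(1-rho){1+(m_i-1)rho}]^{-1} J.
    """
    if m_i < 1:
        raise ValueError("m_i must be >= 1")
    if not 0 <= rho_y < 1:
        raise ValueError(f"rho_y must be in [0, 1) for an invertible R, got {rho_y}")
    eye = np.eye(m_i)
    ones = np.ones((m_i, m_i))
    return eye / (1 - rho_y) - ones * (
        rho_y / ((1 - rho_y) * (1 + (m_i - 1) * rho_y))
    )


def cluster_information(
    W_i: float, W_bar: float, X_i: np.ndarray, rho_y: float
) -> np.ndarray:
    """GLS information contribution Z_i' R_i^{-1} Z_i of one cluster.

    ``X_i`` holds the covariate values of the observed individuals only; an
    empty cluster contributes a 4x4 zero matrix.  Design rows are
    (1, W_i - W_bar, x, (W_i - W_bar) x).
    """
    X_i = np.asarray(X_i, dtype=float).ravel()
    m_i = X_i.size
    if m_i == 0:
        return np.zeros((4, 4))
    c = W_i - W_bar
    Z = np.column_stack([np.ones(m_i), np.full(m_i, c), X_i, c * X_i])
    return Z.T @ r_inverse(m_i, rho_y) @ Z


def _info_sum(
    mi: np.ndarray, Sx: np.ndarray, Sxx: np.ndarray, c: np.ndarray, rho_y: float
) -> np.ndarray:
    """Total information summed over clusters, vectorized over draws.

    Exploits that each cluster's Z_i' R_i^{-1} Z_i depends only on the
    per-cluster sufficient statistics (m_i, sum of observed x, sum of
    observed x^2) and the centered treatment code c_i:
    Z'R^{-1}Z = A/(1-rho) - k u u' with A the raw cross-product matrix,
    u the column sums of Z and k = rho/[(1-rho){1+(m_i-1)rho}].
    Inputs have shape (B, n) ((n,) for c, broadcast); output (B, 4, 4).
    """
    inv1 = 1.0 / (1 - rho_y)
    k = np.where(mi > 0, rho_y / ((1 - rho_y) * (1 + (mi - 1) * rho_y)), 0.0)
    c = np.broadcast_to(c, mi.shape)

    def cell(a, b):  # sum over clusters of inv1*A_ab - k*u_a*u_b
        return (inv1 * a - k * b).sum(axis=-1)

    one, w = mi, mi * c
    info = np.empty(mi.shape[:-1] + (4, 4))
    info[..., 0, 0] = cell(one, mi * mi)
    info[..., 0, 1] = cell(w, mi * w)
    info[..., 0, 2] = cell(Sx, mi * Sx)
    info[..., 0, 3] = cell(c * Sx, mi * c * Sx)
    info[..., 1, 1] = cell(mi * c * c, w * w)
    info[..., 1, 2] = cell(c * Sx, w * Sx)
    info[..., 1, 3] = cell(c * c * Sx, w * c * Sx)
    info[..., 2, 2] = cell(Sxx, Sx * Sx)
    info[..., 2, 3] = cell(c * Sxx, Sx * c * Sx)
    info[..., 3, 3] = cell(c * c * Sxx, c * Sx * c * Sx)
    iu, ju = np.triu_indices(4, 1)
    info[..., ju, iu] = info[..., iu, ju]
    return info


def _draw_suff_stats(
    design: HTEDesign,
    spec: AttritionSpec,
    cov_spec: CovariateSpec,
    n: int,
    B: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """B draws of per-cluster (m_i, sum x, sum x^2) under the missingness model."""
    X = gen_covariates(cov_spec, n, design.m, rng, size=B)
    if spec.mechanism is Mechanism.MAR:
        O = gen_missingness_mar(X, spec.alpha0, spec.alpha1, spec.sigma2_b, rng)
    else:
        O = gen_missingness_mcar(n, design.m, spec.pi, spec.tau, rng, size=B)
    mi = O.sum(axis=-1).astype(float)
    Sx = (X * O).sum(axis=-1)
    Sxx = (X * X * O).sum(axis=-1)
    return mi, Sx, Sxx


def mc_variance(
    design: HTEDesign,
    spec: AttritionSpec,
    cov_spec: CovariateSpec,
    n: int,
    B: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> MCVarianceResult:
    """Monte Carlo estimate of Var(b4_hat) at n clusters.

    Averages the total GLS information over B simulated draws of covariates
    and follow-up indicators, inverts the averaged matrix once, and scales
    the (4,4) element by sigma2_y.  Deterministic given the seed.  Treatment
    is forced to exact n/2 per arm, so the centered codes are +/-1/2.
    """
    if n < 4 or n % 2 != 0:
        raise ValueError(f"n must be an even integer >= 4, got {n}")
    if spec.mechanism is Mechanism.MAR and (
        spec.alpha0 is None or spec.sigma2_b is None
    ):
        raise ValueError("MAR attrition spec must be calibrated (alpha0, sigma2_b)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # centered treatment codes: under forced balance the information does not
    # depend on which clusters get treatment, only on the +/-1/2 codes
    c = np.concatenate([np.full(n // 2, 0.5), np.full(n - n // 2, -0.5)])
    mi, Sx, Sxx = _draw_suff_stats(design, spec, cov_spec, n, B, rng)
    info_avg = _info_sum(mi, Sx, Sxx, c, design.rho_y).mean(axis=0)
    try:
        cov = np.linalg.inv(info_avg)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"averaged information singular at n={n}, B={B}: {exc}"
        ) from exc
    var = design.sigma2_y * cov[3, 3]
    power = power_at_n(var, design.delta, design.alpha)
    return MCVarianceResult(
        var_beta4=float(var), n=n, B=B, info_avg=info_avg,
        predicted_power=power,
        seed=seed if isinstance(seed, int) else None,
    )


def search_n(
    design: HTEDesign,
    spec: AttritionSpec,
    cov_spec: CovariateSpec,
    B: int = 1000,
    seed: int | None = None,
    n_init: int | None = None,
    max_steps: int = 200,
) -> SampleSizeResult:
    """Smallest even n whose Monte Carlo predicted power reaches the target.

    Starts from the MCAR formula's requirement (a cheap, usually close
    initial value), then steps by +/-2 clusters until
    power(n) >= target and power(n - 2) < target.  Every candidate is
    evaluated with a fresh set of B draws from the same seed sequence, and
    the two stopping conditions share draws, so Monte Carlo noise cannot
    make the stopping pair oscillate.
    """
    if spec.mechanism is Mechanism.MAR and (
        spec.alpha0 is None or spec.sigma2_b is None
    ):
        alpha0, sigma2_b = calibrate_mar(spec.pi, spec.tau, spec.alpha1, cov_spec)
        spec = AttritionSpec(mechanism=Mechanism.MAR, pi=spec.pi, tau=spec.tau,
                             alpha1=spec.alpha1, alpha0=alpha0, sigma2_b=sigma2_b)
    if n_init is None:
        mcar_spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=spec.pi,
                                  tau=min(spec.tau, 1.0))
        n = n_mcar(design, mcar_spec).n
    else:
        if n_init % 2 != 0:
            raise ValueError("n_init must be even")
        n = max(n_init, 4)
    n = max(n, 4)

    entropy = np.random.SeedSequence(seed).entropy
    cache: dict[int, float] = {}
    trace: list[tuple[int, float]] = []

    def power_of(n_cand: int) -> float:
        if n_cand not in cache:
            # one substream per candidate n: the same candidate always sees
            # the same draws, independent of the path the search took
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=entropy, spawn_key=(n_cand,))
            )
            res = mc_variance(design, spec, cov_spec, n_cand, B, rng)
            cache[n_cand] = res.predicted_power
            trace.append((n_cand, res.predicted_power))
        return cache[n_cand]

    target = design.power_target
    for _ in range(max_steps):
        p = power_of(n)
        if p >= target:
            if n <= 4 or power_of(n - 2) < target:
                return SampleSizeResult(
                    n=n, method="mar_montecarlo",
                    n_raw=float(n), predicted_power=p, cf=1.0,
                )
            n -= 2
        else:
            n += 2
    raise SearchError(
        f"sample-size search did not settle after {max_steps} steps; "
        f"trace={trace[-10:]}"
    )
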