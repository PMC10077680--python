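"""Design-parameter containers for planning HTE tests in cluster randomized trials.

A two-arm parallel cluster randomized trial (CRT) randomizes ``n`` clusters of
``m`` individuals 1:1 to treatment or control.  The analysis model is a linear
mixed model with a treatment-by-covariate interaction

    Y_ij = b1 + b2*W_i + b3*X_ij + b4*W_i*X_ij + mu_i + eps_ij,

where ``W_i`` is the cluster-level treatment indicator, ``X_ij`` an
individual-level effect modifier, ``mu_i`` a random cluster intercept and
``b4`` the heterogeneous-treatment-effect (HTE) parameter the trial is powered
to detect.  The containers below carry the design parameters a planner has to
supply: variance components, intracluster correlations (ICCs), the target
effect size and error rates, plus a description of expected outcome attrition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class InfeasibleDesignError(ValueError):
    """Raised when an ICC combination makes the HTE variance nonpositive."""


class CalibrationError(RuntimeError):
    """Raised when the missingness-model intercept cannot be calibrated."""


class Mechanism(str, Enum):
    MCAR = "mcar"
    MAR = "mar"


#: latent residual variance of the standard logistic distribution, pi^2 / 3;
#: used to convert the latent-scale missingness ICC into the random-intercept
#: variance of the logistic missingness model.  This is the circle constant,
#: not the follow-up rate (the two unfortunately share a symbol in the field).
LOGISTIC_LATENT_VARIANCE = math.pi ** 2 / 3


@dataclass(frozen=True)
class HTEDesign:
    """Complete-data design parameters for the HTE test.

    Parameters
    ----------
    m : int
        Planned cluster size (individuals per cluster), >= 2.
    rho_y : float
        Adjusted outcome ICC (share of outcome variance between clusters,
        after covariate adjustment), in [0, 1).
    rho_x : float
        Covariate ICC (between-cluster share of effect-modifier variance),
        in [0, 1].
    sigma2_y : float
        Total adjusted outcome variance (between- plus within-cluster).
    sigma2_x : float
        Marginal variance of the effect modifier.
    sigma2_w : float
        Variance of the treatment indicator; 1/4 under 1:1 allocation.
    delta : float
        Target interaction effect size (difference in covariate slope
        between arms) the trial should detect.
    alpha : float
        Two-sided type-I error rate.
    power_target : float
        Desired power 1 - zeta.
    """

    m: int
    rho_y: float
    rho_x: float
    sigma2_y: float = 1.0
    sigma2_x: float = 1.0
    sigma2_w: float = 0.25
    delta: float = 0.1
    alpha: float = 0.05
    power_target: float = 0.8

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError(f"cluster size m must be >= 2, got {self.m}")
        if not 0 <= self.rho_y < 1:
            raise ValueError(f"outcome ICC rho_y must be in [0, 1), got {self.rho_y}")
        if not 0 <= self.rho_x <= 1:
            raise ValueError(f"covariate ICC rho_x must be in [0, 1], got {self.rho_x}")
        if self.sigma2_y <= 0 or self.sigma2_x <= 0:
            raise ValueError("variances sigma2_y and sigma2_x must be positive")
        if not 0 < self.sigma2_w <= 0.25:
            raise ValueError(f"sigma2_w must be in (0, 1/4], got {self.sigma2_w}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.power_target < 1:
            raise ValueError(f"power_target must be in (0, 1), got {self.power_target}")

    @property
    def sigma2_mu(self) -> float:
        """Between-cluster outcome variance component rho_y * sigma2_y."""
        return self.rho_y * self.sigma2_y

    @property
    def sigma2_eps(self) -> float:
        """Within-cluster residual variance (1 - rho_y) * sigma2_y."""
        return (1.0 - self.rho_y) * self.sigma2_y


@dataclass(frozen=True)
class AttritionSpec:
    """Expected-attrition description.

    ``pi`` is the marginal follow-up rate Pr(O_ij = 1) where O_ij indicates an
    observed outcome.  ``tau`` is the missingness ICC.  Under MCAR it is the
    pairwise correlation of the binary indicators within a cluster, bounded in
    [-1/(m-1), 1]; the lower bound corresponds to a fixed number observed per
    cluster, the upper bound to whole-cluster attrition.  Under MAR (follow-up
    depends on the effect modifier through a mixed logistic model with slope
    ``alpha1`` and random intercept b_i ~ N(0, sigma2_b)), ``tau`` is the
    latent-scale ICC sigma2_b / (sigma2_b + pi^2/3), so tau = 1 is not
    attainable.  ``alpha0`` and ``sigma2_b`` are derived by calibration
    (:func:`hteplan.generators.calibrate_mar`).
    """

    mechanism: Mechanism = Mechanism.MCAR
    pi: float = 1.0
    tau: float = 0.0
    alpha1: float = 0.5
    alpha0: float | None = None
    sigma2_b: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.pi <= 1:
            raise ValueError(f"follow-up rate pi must be in (0, 1], got {self.pi}")
        if self.mechanism is Mechanism.MAR and not 0 <= self.tau < 1:
            raise ValueError(f"MAR latent-scale tau must be in [0, 1), got {self.tau}")
        if self.mechanism is Mechanism.MCAR and not -1 <= self.tau <= 1:
            raise ValueError(f"MCAR tau must be in [-1, 1], got {self.tau}")

    def check_tau_bounds(self, m: int) -> None:
        """Enforce the positive-semidefiniteness bound -1/(m-1) <= tau <= 1."""
        lo = -1.0 / (m - 1)
        if not lo - 1e-12 <= self.tau <= 1 + 1e-12:
            raise ValueError(
                f"missingness ICC tau={self.tau} outside attainable "
                f"[{lo:.6g}, 1] for cluster size m={m}"
            )


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of the effect modifier.

    continuous: X_ij = mean + lambda_i + gamma_ij with lambda_i ~ N(0,
    rho_x*sigma2_x) and gamma_ij ~ N(0, (1-rho_x)*sigma2_x).

    binary: beta-binomial — a cluster event rate p_i ~ Beta(q1, q2), then
    X_ij ~ Bernoulli(p_i).  The shapes are solved from the marginal mean
    q1/(q1+q2) and the covariate ICC rho_x = 1/(1+q1+q2); the marginal
    variance is then q1*q2/(q1+q2)^2 = mean*(1-mean).
    """

    kind: str = "continuous"
    rho_x: float = 0.0
    sigma2_x: float = 1.0
    mean: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "binary"):
            raise ValueError(f"covariate kind must be continuous|binary, got {self.kind}")
        if not 0 <= self.rho_x <= 1:
            raise ValueError(f"rho_x must be in [0, 1], got {self.rho_x}")
        if self.kind == "binary":
            if not 0 < self.mean < 1:
                raise ValueError("binary covariate mean must be in (0, 1)")
            object.__setattr__(self, "sigma2_x", self.mean * (1 - self.mean))
        elif self.sigma2_x <= 0:
            raise ValueError("sigma2_x must be positive")

    @property
    def beta_shapes(self) -> tuple[float, float]:
        """Beta-binomial shapes (q1, q2) for a binary effect modifier."""
        if self.kind != "binary":
            raise ValueError("beta shapes are defined for binary covariates only")
        if self.rho_x == 0:
            raise ZeroDivisionError("rho_x = 0 is the degenerate constant-rate case")
        total = 1.0 / self.rho_x - 1.0
        return self.mean * total, (1.0 - self.mean) * total


@dataclass(frozen=True)
class SampleSizeResult:
    """Required number of clusters from one sizing method.

    ``n`` is the unrounded requirement ``n_raw`` rounded up to the nearest
    even integer (1:1 cluster allocation needs equal arms).  ``cf`` is the
    variable-cluster-size correction factor that entered the calculation
    (1 where not applicable) and ``predicted_power`` the analytic power of
    the two-sided z-test at the returned ``n``.
    """

    n: int
    method: str
    n_raw: float
    predicted_power: float
    cf: float = 1.0

    def __post_init__(self) -> None:
        if self.n % 2 != 0:
            raise ValueError(f"n must be even, got {self.n}")


@dataclass
class TrialData:
    """One simulated CRT in wide (cluster x individual) layout.

    W: (n,) 0/1 treatment indicator, exactly n/2 per arm.
    X: (n, m) effect-modifier values.
    Y: (n, m) outcomes (before attrition).
    O: (n, m) 0/1 follow-up indicators (1 = outcome observed).
    """

    W: np.ndarray
    X: np.ndarray
    Y: np.ndarray
    O: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def m_obs(self) -> np.ndarray:
        """Observed cluster sizes, the row sums of O."""
        return self.O.sum(axis=1)


def round_up_even(x: float) -> int:
    """Round a raw cluster requirement up to the nearest even integer."""
    n = math.ceil(x - 1e-12)  # tolerate float fuzz on exact integers
    return n if n % 2 == 0 else n + 1
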