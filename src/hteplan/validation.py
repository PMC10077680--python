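"""Full-cycle empirical validation of the sample-size predictions.

For a given design, attrition mechanism and cluster count, whole trials are
simulated, the interaction linear mixed model is refit to each trial's
observed rows by REML (random cluster intercept), and the two-sided Wald
z-test of the interaction coefficient is applied.  The rejection rate across
replicates estimates the empirical power (data generated with the design's
effect size) or type-I error (effect size forced to zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .design import (
    AttritionSpec,
    CovariateSpec,
    HTEDesign,
    Mechanism,
    TrialData,
)
from .generators import calibrate_mar, simulate_trial

__all__ = ["fit_and_test", "run_study", "SimulationResult", "trial_to_frame"]


@dataclass
class SimulationResult:
    """Empirical operating characteristics from repeated simulated trials."""

    scenario: dict
    n_used: int
    reps: int
    empirical_power: float
    empirical_t1e: float
    mc_se_power: float
    mc_se_t1e: float
    n_fit_failures: int = 0
    beta4_mean: float = float("nan")
    beta4_se_mean: float = float("nan")
    extras: dict = field(default_factory=dict)


def trial_to_frame(trial: TrialData, observed_only: bool = True) -> pd.DataFrame:
    """Long-format view of one simulated trial (one row per individual)."""
    n, m = trial.X.shape
    df = pd.DataFrame({
        "cluster": np.repeat(np.arange(n), m),
        "individual": np.tile(np.arange(m), n),
        "W": np.repeat(trial.W, m),
        "X": trial.X.ravel(),
        "Y": trial.Y.ravel(),
        "O": trial.O.ravel(),
    })
    return df[df["O"] == 1].reset_index(drop=True) if observed_only else df


def _anova_start(y: np.ndarray, exog: np.ndarray, groups: np.ndarray):
    """Moment-based starting values: OLS slopes plus a one-way ANOVA estimate
    of the between-cluster variance ratio from the OLS residuals."""
    from statsmodels.regression.mixed_linear_model import MixedLMParams

    beta, *_ = np.linalg.lstsq(exog, y, rcond=None)
    resid = y - exog @ beta
    df_r = pd.DataFrame({"e": resid, "g": groups})
    per = df_r.groupby("g")["e"]
    m_bar = per.size().mean()
    msw = float(per.var(ddof=1).mean())
    msb = float(per.mean().var(ddof=1) * m_bar)
    sigma2_mu = max((msb - msw) / m_bar, 1e-4 * msw)
    # MixedLM profiles out the residual variance; cov_re is relative to it
    return MixedLMParams.from_components(
        fe_params=beta, cov_re=np.array([[sigma2_mu / max(msw, 1e-12)]])
    )


def fit_and_test(
    trial: TrialData, alpha: float
) -> tuple[float, float, float, bool]:
    """REML fit of the interaction mixed model on the observed rows.

    Returns (beta4_hat, se, p_value, reject) where the p-value references
    the standard normal (Wald z-test), matching the planning formulas.
    Clusters that lost every individual carry no rows and drop out of the
    fit automatically.
    """
    df = trial_to_frame(trial, observed_only=True)
    if df.empty or df["W"].nunique() < 2:
        raise ValueError("need observed outcomes in both arms to fit the model")
    y = df["Y"].to_numpy()
    exog = np.column_stack([
        np.ones(len(df)), df["W"].to_numpy(dtype=float), df["X"].to_numpy(),
        df["W"].to_numpy(dtype=float) * df["X"].to_numpy(),
    ])
    groups = df["cluster"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=groups)
        try:
            fit = model.fit(reml=True, method="nm", maxiter=500,
                            start_params=_anova_start(y, exog, groups))
        except (np.linalg.LinAlgError, ValueError):
            fit = model.fit(reml=True, method="powell", maxiter=500)
    if not np.isfinite(fit.params[3]) or not np.isfinite(fit.bse[3]):
        raise RuntimeError("REML fit did not produce a finite interaction estimate")
    b4, se = float(fit.params[3]), float(fit.bse[3])
    p = 2 * norm.sf(abs(b4 / se))
    return b4, se, p, bool(p < alpha)


def run_study(
    design: HTEDesign,
    attrition: AttritionSpec,
    cov_spec: CovariateSpec,
    n: int,
    reps: int = 3000,
    seed: int | None = None,
) -> SimulationResult:
    """Estimate empirical power and type-I error at n clusters.

    Runs ``reps`` replicates under the alternative (interaction = design's
    delta) and ``reps`` under the null (interaction = 0).  Each replicate
    gets an independent substream of the seed sequence; a failed REML fit is
    retried once on a fresh draw from the same substream and excluded (and
    counted) if it fails again.
    """
    if reps <= 0:
        raise ValueError("reps must be positive")
    if attrition.mechanism is Mechanism.MAR and (
        attrition.alpha0 is None or attrition.sigma2_b is None
    ):
        a0, s2b = calibrate_mar(attrition.pi, attrition.tau,
                                attrition.alpha1, cov_spec)
        attrition = AttritionSpec(mechanism=Mechanism.MAR, pi=attrition.pi,
                                  tau=attrition.tau, alpha1=attrition.alpha1,
                                  alpha0=a0, sigma2_b=s2b)

    seq = np.random.SeedSequence(seed)
    streams = seq.spawn(2 * reps)
    failures = 0
    rejections = {"alt": [], "null": []}
    b4s: list[float] = []
    ses: list[float] = []

    for r in range(2 * reps):
        hyp = "alt" if r < reps else "null"
        delta = design.delta if hyp == "alt" else 0.0
        beta = (0.0, 0.25, 0.1, delta)
        rng = np.random.default_rng(streams[r])
        done = False
        for _attempt in range(2):  # one retry with a fresh draw
            trial = simulate_trial(design, attrition, cov_spec, n, rng, beta=beta)
            try:
                b4, se, _p, reject = fit_and_test(trial, design.alpha)
            except (RuntimeError, ValueError, np.linalg.LinAlgError):
                continue
            rejections[hyp].append(reject)
            if hyp == "alt":
                b4s.append(b4)
                ses.append(se)
            done = True
            break
        if not done:
            failures += 1

    frac_failed = failures / (2 * reps)
    if frac_failed > 0.10:
        raise RuntimeError(f"{failures} of {2*reps} replicates failed to fit")
    if frac_failed > 0.01:
        warnings.warn(f"{failures} REML fit failures out of {2*reps} replicates")

    power = float(np.mean(rejections["alt"]))
    t1e = float(np.mean(rejections["null"]))
    n_alt, n_null = len(rejections["alt"]), len(rejections["null"])
    return SimulationResult(
        scenario={
            "design": design, "attrition": attrition, "cov_spec": cov_spec,
        },
        n_used=n,
        reps=reps,
        empirical_power=power,
        empirical_t1e=t1e,
        mc_se_power=float(np.sqrt(power * (1 - power) / n_alt)),
        mc_se_t1e=float(np.sqrt(t1e * (1 - t1e) / n_null)),
        n_fit_failures=failures,
        beta4_mean=float(np.mean(b4s)) if b4s else float("nan"),
        beta4_se_mean=float(np.mean(ses)) if ses else float("nan"),
    )
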