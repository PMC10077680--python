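"""Closed-form variance, correction-factor and sample-size checks."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hteplan import (
    AttritionSpec,
    HTEDesign,
    InfeasibleDesignError,
    Mechanism,
    cf_mcar,
    cf_unequal,
    n_complete,
    n_direct_inflation,
    n_mcar,
    observed_size_moments,
    power_at_n,
    ratio_contour_grid,
    var_beta4_complete,
)


def design(**kw) -> HTEDesign:
    base = dict(m=20, rho_y=0.01, rho_x=0.1, sigma2_y=1.0, sigma2_x=1.0,
                sigma2_w=0.25, delta=0.1, alpha=0.05, power_target=0.8)
    base.update(kw)
    return HTEDesign(**base)


class TestVarianceFormula:
    def test_hand_evaluated_value(self, base_design):
        # direct transcription of the variance expression at n=160
        m, ry, rx = 20, 0.01, 0.1
        expect = (1 * (1 - ry) * (1 + (m - 1) * ry)) / (
            160 * m * 0.25 * 1 * (1 + (m - 2) * ry - (m - 1) * rx * ry)
        )
        assert var_beta4_complete(base_design, 160) == pytest.approx(expect, rel=1e-14)

    def test_no_clustering_limit(self):
        d = design(rho_y=0.0)
        assert var_beta4_complete(d, 50) == pytest.approx(
            1.0 / (50 * 20 * 0.25 * 1.0), rel=1e-14
        )

    def test_inverse_n_scaling(self, base_design):
        assert var_beta4_complete(base_design, 100) == pytest.approx(
            2 * var_beta4_complete(base_design, 200), rel=1e-14
        )

    def test_infeasible_cf_bracket_raises(self):
        # the variance brace itself stays positive for any rho_x <= 1, but an
        # extreme cluster-size CV can push the correction bracket nonpositive
        d = design(rho_y=0.1, rho_x=0.9)
        with pytest.raises(InfeasibleDesignError):
            cf_unequal(d, 20.0, 3.0)


class TestCompleteDataSize:
    def test_reference_scenario(self, base_design):
        res = n_complete(base_design)
        assert res.n_raw == pytest.approx(159.29, abs=0.01)
        assert res.n == 160
        assert res.predicted_power >= 0.8

    def test_quadratic_effect_size_scaling(self, base_design):
        double = design(delta=0.2)
        assert n_complete(double).n_raw == pytest.approx(
            n_complete(base_design).n_raw / 4, rel=1e-12
        )

    def test_rounds_to_even(self):
        for d in [design(delta=0.11), design(delta=0.13), design(delta=0.2)]:
            res = n_complete(d)
            assert res.n % 2 == 0
            assert res.n >= res.n_raw
            assert res.n - 2 < res.n_raw


class TestCorrectionFactor:
    def test_zero_cv_is_unity(self, base_design):
        assert cf_unequal(base_design, 14.0, 0.0) == 1.0

    def test_equal_iccs_give_unity(self):
        d = design(rho_y=0.05, rho_x=0.05)
        for cv in (0.1, 0.5, 0.9):
            assert cf_unequal(d, 14.0, cv) == pytest.approx(1.0, abs=1e-15)

    def test_sign_of_deviation_tracks_icc_ordering(self):
        # verified against the published per-scenario cluster counts: the
        # correction exceeds one when the covariate ICC dominates the outcome ICC
        assert cf_unequal(design(rho_y=0.05, rho_x=0.5), 14.0, 0.5) > 1
        assert cf_unequal(design(rho_y=0.10, rho_x=0.01), 14.0, 0.5) < 1

    @settings(deadline=None, derandomize=True)
    @given(
        m=st.integers(5, 200),
        rho_y=st.floats(0.001, 0.2),
        rho_x=st.floats(0.0, 0.9),
        pi=st.floats(0.3, 1.0),
    )
    def test_unity_at_tau_lower_bound(self, m, rho_y, rho_x, pi):
        """At tau = -1/(m-1) every cluster loses the same number of people,
        the observed sizes are constant, and the correction vanishes."""
        d = design(m=m, rho_y=rho_y, rho_x=rho_x)
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=pi, tau=-1.0 / (m - 1))
        assert cf_mcar(d, spec) == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(
        rho_y=st.floats(0.001, 0.2),
        excess=st.floats(0.0, 0.7),
        pi=st.floats(0.3, 0.99),
        t=st.floats(0.0, 0.99),
    )
    def test_nondecreasing_in_tau(self, rho_y, excess, pi, t):
        """More correlated missingness costs power, so the correction grows
        with tau (in the rho_x >= rho_y region where it acts as inflation)."""
        d = design(rho_y=rho_y, rho_x=min(rho_y + excess, 1.0))
        lo = AttritionSpec(mechanism=Mechanism.MCAR, pi=pi, tau=t)
        hi = AttritionSpec(mechanism=Mechanism.MCAR, pi=pi, tau=min(t + 0.01, 1.0))
        assert cf_mcar(d, hi) >= cf_mcar(d, lo) - 1e-12


class TestObservedSizeMoments:
    def test_full_follow_up_degenerate(self):
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=1.0, tau=0.05)
        assert observed_size_moments(20, spec) == (20.0, 0.0, 0.0)

    def test_lower_bound_removes_variability(self):
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=0.6, tau=-1 / 19)
        mean, var, cv = observed_size_moments(20, spec)
        assert mean == pytest.approx(12.0)
        assert var == pytest.approx(0.0, abs=1e-12)
        assert cv == pytest.approx(0.0, abs=1e-7)

    def test_cluster_attrition_variance(self):
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=0.6, tau=1.0)
        _, var, _ = observed_size_moments(20, spec)
        assert var == pytest.approx(0.6 * 0.4 * 20 * 20)

    def test_moments_match_correlated_binary_generator(self):
        """Closed-form mean/variance of the observed size must agree with the
        empirical moments of the exchangeable-binary indicator generator."""
        from hteplan import gen_missingness_mcar

        m, pi, tau, n = 20, 0.7, 0.3, 100_000
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=pi, tau=tau)
        mean, var, _ = observed_size_moments(m, spec)
        o = gen_missingness_mcar(n, m, pi, tau, np.random.default_rng(8))
        sizes = o.sum(axis=1)
        se_mean = sizes.std(ddof=1) / np.sqrt(n)
        assert sizes.mean() == pytest.approx(mean, abs=3 * se_mean)
        # SE of a sample variance ~ s^2 sqrt(2/(n-1)) under normality; pad it
        se_var = var * np.sqrt(2 / (n - 1)) * 3
        assert sizes.var(ddof=1) == pytest.approx(var, abs=3 * se_var)

    def test_out_of_bounds_tau_rejected(self):
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=0.6, tau=-0.2)
        with pytest.raises(ValueError, match="attainable"):
            observed_size_moments(20, spec)


class TestAttritionAdjustedSize:
    def test_no_attrition_recovers_complete(self, base_design):
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=1.0, tau=-1 / 19)
        assert n_mcar(base_design, spec).n == n_complete(base_design).n
        assert n_mcar(base_design, spec).n_raw == pytest.approx(
            n_complete(base_design).n_raw, rel=1e-12
        )

    def test_nonincreasing_in_follow_up_rate(self, base_design):
        raws = [
            n_mcar(base_design,
                   AttritionSpec(mechanism=Mechanism.MCAR, pi=pi, tau=0.05)).n_raw
            for pi in np.linspace(0.4, 1.0, 13)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(raws, raws[1:]))

    def test_predicted_power_meets_target(self, base_design, mcar_70):
        res = n_mcar(base_design, mcar_70)
        assert res.predicted_power >= 0.8
        # one fewer pair of clusters must fall short of the target
        from hteplan import var_beta4_mcar
        under = power_at_n(var_beta4_mcar(base_design, mcar_70, res.n - 2), 0.1, 0.05)
        assert under < 0.8

    def test_direct_inflation_scaling(self, base_design):
        half = AttritionSpec(mechanism=Mechanism.MCAR, pi=0.5, tau=0.0)
        full = AttritionSpec(mechanism=Mechanism.MCAR, pi=1.0, tau=0.0)
        assert n_direct_inflation(base_design, half).n_raw == pytest.approx(
            2 * n_direct_inflation(base_design, full).n_raw, rel=1e-12
        )
        assert n_direct_inflation(base_design, full).n == n_complete(base_design).n


class TestPowerInversion:
    def test_definitional_inversion(self):
        from scipy.stats import norm

        var = (0.1 / (norm.ppf(0.975) + norm.ppf(0.8))) ** 2
        assert power_at_n(var, 0.1, 0.05) == pytest.approx(0.8, abs=1e-12)

    def test_null_effect_gives_half_alpha(self):
        assert power_at_n(0.01, 0.0, 0.05) == pytest.approx(0.025, abs=1e-12)

    def test_monotonicity(self):
        assert power_at_n(0.001, 0.1, 0.05) > power_at_n(0.002, 0.1, 0.05)
        assert power_at_n(0.001, 0.2, 0.05) > power_at_n(0.001, 0.1, 0.05)


class TestRatioGrid:
    def test_adjusted_never_exceeds_inflation_at_low_tau(self, base_design):
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=0.6, tau=0.05)
        df = ratio_contour_grid(base_design, spec,
                                np.linspace(0, 0.2, 9), np.linspace(0, 1, 9))
        ok = df.dropna()
        assert len(ok) > 50
        # direct inflation is conservative wherever the covariate ICC is at
        # least the outcome ICC (the region the published scenarios cover);
        # equality holds on the rho_y = 0 edge where clustering vanishes
        region = ok[ok["rho_x"] >= ok["rho_y"]]
        assert (region["ratio"] <= 1 + 1e-12).all()
        interior = region[(region["rho_y"] > 0) & (region["rho_x"] > region["rho_y"])]
        assert (interior["ratio"] < 1).all()

    def test_no_attrition_ratio_is_one(self, base_design):
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=1.0, tau=0.05)
        df = ratio_contour_grid(base_design, spec,
                                np.linspace(0, 0.2, 5), np.linspace(0, 0.9, 5))
        assert np.allclose(df["ratio"].dropna(), 1.0)

    def test_closed_form_ratio_at_tau_lower_bound(self, base_design):
        """With rho_x = rho_y and tau at its lower bound both CFs are 1 and
        the ratio reduces to pure algebra in the two variance braces."""
        m, pi = 20, 0.6
        spec = AttritionSpec(mechanism=Mechanism.MCAR, pi=pi, tau=-1 / (m - 1))
        ry = 0.05
        df = ratio_contour_grid(base_design, spec, [ry], [ry])
        mc = pi * m

        def brace_var(mm):
            return (1 + (mm - 1) * ry) / (mm * (1 + (mm - 2) * ry - (mm - 1) * ry * ry))

        expect = brace_var(mc) / (brace_var(m) / pi)
        assert df["ratio"].iloc[0] == pytest.approx(expect, rel=1e-12)
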