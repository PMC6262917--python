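"""Mixed-model habitat comparisons, variance-partition R^2, SE rule."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lepdiv.mixedmodels import (
    ModelError,
    ModelFit,
    fit_diversity_model,
    nakagawa_r2,
    significance_by_se,
)


def paired_design(n_pairs=13):
    pair = np.repeat([f"p{i:02d}" for i in range(n_pairs)], 2)
    hab = np.array(["broadleaf", "plantation"] * n_pairs)
    year = np.repeat([2014] * ((n_pairs + 1) // 2) + [2015] * (n_pairs // 2), 2)
    month = np.repeat(
        [("june", "july", "august")[i % 3] for i in range(n_pairs)], 2
    )
    return pair, hab, year, month


def simulate_poisson(rng, effect, n_pairs=13, intercept=4.0, pair_sd=0.25):
    pair, hab, year, month = paired_design(n_pairs)
    b = np.repeat(rng.normal(0, pair_sd, n_pairs), 2)
    eta = intercept + effect * (hab == "plantation") + b
    return rng.poisson(np.exp(eta)), pair, hab, year, month


def simulate_gaussian(rng, effect, n_pairs=13, intercept=10.0, pair_sd=1.5, sd=1.0):
    pair, hab, year, month = paired_design(n_pairs)
    b = np.repeat(rng.normal(0, pair_sd, n_pairs), 2)
    y = intercept + effect * (hab == "plantation") + b + rng.normal(0, sd, 2 * n_pairs)
    return y, pair, hab, year, month


class TestFitDiversityModel:
    def test_identical_habitat_responses_give_zero_effect(self):
        rng = np.random.default_rng(0)
        pair, hab, year, month = paired_design(8)
        per_pair = rng.normal(10, 2, 8)
        y = np.repeat(per_pair, 2)  # both sites of a pair identical
        fit = fit_diversity_model(y, hab, pair, year, month, family="gaussian")
        assert abs(fit.plantation) < 1e-6

    def test_constant_response_degenerate_fit(self):
        pair, hab, year, month = paired_design(5)
        fit = fit_diversity_model([4.0] * 10, hab, pair, year, month)
        assert fit.singular
        assert fit.plantation == 0.0
        assert not significance_by_se(fit)["plantation"]

    def test_noninteger_poisson_response_rejected(self):
        pair, hab, year, month = paired_design(3)
        with pytest.raises(ModelError):
            fit_diversity_model(
                [1.5] * 6, hab, pair, year, month, family="poisson"
            )

    def test_unknown_family_rejected(self):
        pair, hab, year, month = paired_design(3)
        with pytest.raises(ModelError):
            fit_diversity_model([1] * 6, hab, pair, year, month, family="gamma")

    def test_no_random_terms_reproduces_ols(self):
        rng = np.random.default_rng(1)
        y, pair, hab, year, month = simulate_gaussian(rng, -2.0)
        fit = fit_diversity_model(
            y, hab, pair, year, month, family="gaussian", random_structure="none"
        )
        X = np.column_stack([np.ones(len(y)), (hab == "plantation").astype(float)])
        ols = sm.OLS(y, X).fit()
        assert fit.intercept == pytest.approx(ols.params[0], abs=1e-8)
        assert fit.plantation == pytest.approx(ols.params[1], abs=1e-8)
        assert fit.plantation_se == pytest.approx(ols.bse[1], abs=1e-8)

    def test_gaussian_effect_recovery(self):
        rng = np.random.default_rng(2)
        y, pair, hab, year, month = simulate_gaussian(rng, -3.0)
        fit = fit_diversity_model(y, hab, pair, year, month, family="gaussian")
        assert fit.plantation == pytest.approx(-3.0, abs=2 * fit.plantation_se + 0.5)
        assert fit.conditional_r2 > fit.marginal_r2

    def test_poisson_effect_recovery_within_two_se(self):
        """Simulation-based calibration of the Poisson GLMM: a log-scale
        plantation deficit of -0.4 is recovered within 2 SE in >=90% of
        replicates."""
        rng = np.random.default_rng(3)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            y, pair, hab, year, month = simulate_poisson(rng, -0.4)
            fit = fit_diversity_model(y, hab, pair, year, month, family="poisson")
            hits += abs(fit.plantation - (-0.4)) <= 2 * fit.plantation_se
        assert hits / n_rep >= 0.90

    def test_site_random_structure_accepted(self):
        rng = np.random.default_rng(4)
        y, pair, hab, year, month = simulate_gaussian(rng, -1.0)
        fit = fit_diversity_model(
            y, hab, pair, year, month, family="gaussian", random_structure="site"
        )
        assert np.isfinite(fit.plantation)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
    def test_poisson_laplace_agrees_with_glmer(self, tmp_path):
        """Cross-check the authored Laplace fit against lme4::glmer."""
        rng = np.random.default_rng(5)
        y, pair, hab, year, month = simulate_poisson(rng, -0.5)
        fit = fit_diversity_model(y, hab, pair, year, month, family="poisson")
        df = pd.DataFrame(
            {"y": y, "hab": hab, "pair": pair, "year": year, "month": month}
        )
        df.to_csv(tmp_path / "d.csv", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f'd <- read.csv("{tmp_path / "d.csv"}")\n'
            "d$py <- interaction(d$year, d$pair)\n"
            "d$pm <- interaction(d$month, d$pair)\n"
            "m <- suppressWarnings(glmer(y ~ hab + (1|py) + (1|pm), data=d,"
            " family=poisson))\n"
            "co <- summary(m)$coefficients\n"
            "vc <- as.data.frame(VarCorr(m))\n"
            "cat(co[1,1], co[2,1], co[1,2], co[2,2], sum(vc$vcov), sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], check=True, capture_output=True, text=True
        )
        ref = [float(v) for v in out.stdout.split()]
        assert fit.intercept == pytest.approx(ref[0], abs=1e-3)
        assert fit.plantation == pytest.approx(ref[1], abs=1e-3)
        assert fit.intercept_se == pytest.approx(ref[2], rel=0.05)
        assert fit.plantation_se == pytest.approx(ref[3], rel=0.05)
        total_vc = sum(fit.variance_components.values())
        assert total_vc == pytest.approx(ref[4], rel=0.15, abs=0.01)


class TestNakagawaR2:
    def _fit(self, var_f, vc, resid):
        return ModelFit(
            response="x", family="gaussian", intercept=1.0, intercept_se=0.1,
            plantation=0.0, plantation_se=0.1, t_value=0.0,
            variance_components=vc, residual_variance=resid,
            fixed_variance=var_f,
        )

    def test_no_random_or_residual_variance_marginal_equals_conditional(self):
        m, c = nakagawa_r2(self._fit(2.0, {}, 0.0))
        assert m == c == 1.0

    def test_zero_fixed_variance_marginal_zero(self):
        m, c = nakagawa_r2(self._fit(0.0, {"pair": 1.0}, 1.0))
        assert m == 0.0
        assert c == pytest.approx(0.5)

    def test_partition(self):
        m, c = nakagawa_r2(self._fit(1.0, {"a": 2.0, "b": 1.0}, 4.0))
        assert m == pytest.approx(1 / 8)
        assert c == pytest.approx(4 / 8)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ModelError):
            nakagawa_r2(self._fit(0.0, {}, 0.0))

    def test_marginal_never_exceeds_conditional_on_fits(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            y, pair, hab, year, month = simulate_gaussian(rng, -1.0)
            fit = fit_diversity_model(y, hab, pair, year, month)
            assert 0 <= fit.marginal_r2 <= fit.conditional_r2 <= 1


class TestSignificanceBySE:
    def _fit(self, est, se):
        return ModelFit(
            response="x", family="gaussian", intercept=0.0, intercept_se=1.0,
            plantation=est, plantation_se=se, t_value=0.0,
            variance_components={}, residual_variance=1.0, fixed_variance=0.0,
        )

    @pytest.mark.parametrize(
        "est,se,expected",
        [(-0.4, 0.1, True), (0.1, 0.5, False), (0.0, 0.2, False), (0.0, 0.0, False)],
    )
    def test_interval_excludes_zero(self, est, se, expected):
        assert significance_by_se(self._fit(est, se))["plantation"] is expected

    def test_false_positive_rate_matches_one_se_coverage(self):
        """Under zero habitat effect the +/-1 SE rule fires at roughly the
        ~32% rate implied by one-SE coverage -- the rule is liberal."""
        rng = np.random.default_rng(7)
        fires = 0
        n_rep = 150
        for _ in range(n_rep):
            y, pair, hab, year, month = simulate_gaussian(rng, 0.0)
            fit = fit_diversity_model(y, hab, pair, year, month)
            fires += significance_by_se(fit)["plantation"]
        assert 0.32 - 0.08 <= fires / n_rep <= 0.32 + 0.08
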