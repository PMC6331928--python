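"""Pooled regression, mixed models, BIC and the random-structure strategy."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from megamet.data_model import CovariateSpec, validate_for_analysis
from megamet.one_stage import (
    RANDOM_INTERCEPT,
    RANDOM_INTERCEPT_SLOPE,
    EstimationError,
    MixedModelFit,
    MixedModelSpec,
    bic,
    fit_lmm,
    fit_mega_lr,
    lmm_to_fitresult,
    lrt_mixture_pvalue,
    lrt_random_slope,
    select_random_structure,
)
from megamet.synthetic import ScenarioConfig, generate_cohorts
from megamet.two_stage import fit_cohort_ols

from _oracles import ols_pinv, reml_loglik_dense
from conftest import make_dataset, simulated_subset


class TestMegaLR:
    def test_single_cohort_reduces_to_cohort_ols(self, thickness_spec):
        sub = simulated_subset(
            thickness_spec,
            cohort_sizes=((15, 15),),
            seed=1,
            beta_dx=0.3,
            sigma_e=0.5,
        )
        with pytest.warns(UserWarning):
            res = fit_mega_lr(sub)
        ols = fit_cohort_ols(sub.df, "roi", thickness_spec)
        assert res.beta_dx == pytest.approx(ols.beta_dx, abs=1e-12)
        assert res.t == pytest.approx(ols.t, abs=1e-10)

    def test_cohort_dummy_absorbs_intercept_shift(self, nocov_spec):
        """Two cohorts with identical data apart from an intercept shift:
        the dummy absorbs the shift and beta_dx equals the within value."""
        y = np.array([1.0, 2.0, 3.0, 4.0])
        dx = [0, 0, 1, 1]
        rows = [("A", d, 30.0, 0, 1.5e6, v) for d, v in zip(dx, y)]
        rows += [("B", d, 30.0, 0, 1.5e6, v + 7.5) for d, v in zip(dx, y)]
        sub = validate_for_analysis(make_dataset(rows), "roi", nocov_spec, min_cohort_n=2)
        res = fit_mega_lr(sub)
        assert res.beta_dx == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_pseudo_inverse_oracle(self, seed, thickness_spec):
        sub = simulated_subset(
            thickness_spec,
            cohort_sizes=((12, 10), (8, 14), (20, 5)),
            seed=seed,
            beta_dx=-0.2,
            sigma_u=0.4,
            sigma_e=0.8,
            covariate_effects={"age": 0.01, "sex": -0.1},
        )
        res = fit_mega_lr(sub)
        df = sub.df
        cohorts = sorted(df["cohort"].unique())
        X = np.column_stack(
            [np.ones(len(df)), df["dx"], df["age"], df["sex"]]
            + [(df["cohort"] == c).to_numpy(float) for c in cohorts[1:]]
        ).astype(float)
        beta = ols_pinv(X, df["roi"].to_numpy())
        assert res.beta_dx == pytest.approx(beta[1], abs=1e-10)

    def test_residuals_orthogonal_to_design(self, thickness_spec):
        sub = simulated_subset(
            thickness_spec,
            cohort_sizes=((10, 10),) * 4,
            seed=8,
            beta_dx=0.1,
            sigma_u=0.2,
        )
        res = fit_mega_lr(sub)
        df = sub.df
        cohorts = sorted(df["cohort"].unique())
        X = np.column_stack(
            [np.ones(len(df)), df["dx"], df["age"], df["sex"]]
            + [(df["cohort"] == c).to_numpy(float) for c in cohorts[1:]]
        ).astype(float)
        beta = ols_pinv(X, df["roi"].to_numpy())
        resid = df["roi"].to_numpy() - X @ beta
        assert np.abs(X.T @ resid).max() < 1e-6
        # and the reported d is reproduced from the oracle fit
        se = math.sqrt(
            float(resid @ resid / (len(df) - X.shape[1]))
            * np.linalg.inv(X.T @ X)[1, 1]
        )
        t = beta[1] / se
        assert res.t == pytest.approx(t, abs=1e-8)

    def test_dummy_reference_invariance(self, nocov_spec):
        rows = []
        rng = np.random.default_rng(12)
        for label in ("mid", "aaa", "zzz"):
            for dx in (0, 1) * 8:
                rows.append((label, dx, 30.0, 0, 1.5e6, rng.normal(0.2 * dx, 1)))
        ds = make_dataset(rows)
        sub = validate_for_analysis(ds, "roi", nocov_spec, min_cohort_n=2)
        res = fit_mega_lr(sub)
        # relabel so a different cohort sorts first
        ds2 = make_dataset(
            [("b" + r[0], *r[1:]) for r in rows]
        )
        sub2 = validate_for_analysis(ds2, "roi", nocov_spec, min_cohort_n=2)
        res2 = fit_mega_lr(sub2)
        assert res.d == pytest.approx(res2.d, abs=1e-12)


class TestFitLMM:
    def test_zero_between_cohort_variance_boundary(self, nocov_spec):
        sub = simulated_subset(
            nocov_spec,
            cohort_sizes=((200, 200),) * 5,
            seed=7,
            beta_dx=0.3,
            sigma_u=0.0,
            sigma_e=1.0,
        )
        fit = fit_lmm(sub, MixedModelSpec())
        assert fit.converged
        assert fit.sigma_u2 == pytest.approx(0.0, abs=1e-4)
        X = np.column_stack([np.ones(len(sub.df)), sub.df["dx"]]).astype(float)
        beta_ols = ols_pinv(X, sub.df["roi"].to_numpy())
        assert fit.beta["dx"] == pytest.approx(beta_ols[1], abs=1e-3)

    @pytest.mark.parametrize("seed", [100, 104, 111])
    def test_reml_optimum_dominates_dense_grid(self, seed, nocov_spec):
        sub = simulated_subset(
            nocov_spec,
            cohort_sizes=((5, 5),) * 3,
            seed=seed,
            beta_dx=0.3,
            sigma_u=0.4,
            sigma_e=0.8,
        )
        fit = fit_lmm(sub, MixedModelSpec())
        assert fit.converged
        X = np.column_stack([np.ones(len(sub.df)), sub.df["dx"]]).astype(float)
        y = sub.df["roi"].to_numpy()
        groups = sub.df["cohort"].to_numpy()
        opt = reml_loglik_dense(y, X, groups, fit.sigma_u2, fit.sigma_e2)
        assert opt == pytest.approx(fit.loglik_reml, abs=1e-8)
        for su2 in np.logspace(-4, 1, 41):
            for se2 in np.logspace(-3, 1, 41):
                assert opt >= reml_loglik_dense(y, X, groups, su2, se2) - 1e-9

    def test_balanced_design_closed_form(self, nocov_spec):
        """In a balanced one-way design the GLS diagnosis effect equals the
        mean of the per-cohort patient-control mean differences."""
        sub = simulated_subset(
            nocov_spec,
            cohort_sizes=((10, 10),) * 6,
            seed=3,
            beta_dx=0.4,
            sigma_u=0.5,
            sigma_e=1.0,
        )
        fit = fit_lmm(sub, MixedModelSpec())
        diffs = [
            g.loc[g.dx == 1, "roi"].mean() - g.loc[g.dx == 0, "roi"].mean()
            for _, g in sub.df.groupby("cohort")
        ]
        assert fit.beta["dx"] == pytest.approx(np.mean(diffs), abs=1e-10)

    def test_agrees_with_statsmodels_on_well_behaved_instance(self, thickness_spec):
        """Cross-check of the profiled REML search against MixedLM."""
        import statsmodels.api as sm

        sub = simulated_subset(
            thickness_spec,
            cohort_sizes=((30, 30),) * 8,
            seed=19,
            beta_dx=-0.15,
            sigma_u=0.4,
            sigma_e=0.9,
            covariate_effects={"age": -0.004, "sex": 0.05},
        )
        fit = fit_lmm(sub, MixedModelSpec())
        X = pd.DataFrame(
            {
                "intercept": 1.0,
                "dx": sub.df["dx"].astype(float),
                "age": sub.df["age"],
                "sex": sub.df["sex"].astype(float),
            }
        )
        res = sm.MixedLM(
            sub.df["roi"].to_numpy(), X, groups=sub.df["cohort"]
        ).fit(reml=True)
        assert fit.beta["dx"] == pytest.approx(res.fe_params["dx"], abs=1e-6)
        assert fit.se_beta["dx"] == pytest.approx(res.bse_fe["dx"], rel=1e-4)
        assert fit.sigma_u2 == pytest.approx(float(np.asarray(res.cov_re)[0, 0]), rel=1e-3)
        assert fit.loglik_reml == pytest.approx(res.llf, abs=1e-6)

    def test_single_cohort_rejected(self, nocov_spec):
        sub = simulated_subset(nocov_spec, cohort_sizes=((10, 10),), seed=2)
        with pytest.raises(EstimationError):
            fit_lmm(sub, MixedModelSpec())


class TestLmmToFitResult:
    def _fit(self, beta_dx, se=0.1):
        return MixedModelFit(
            spec=MixedModelSpec(),
            beta={"intercept": 0.0, "dx": beta_dx},
            se_beta={"intercept": 0.1, "dx": se},
            sigma_u2=0.1,
            sigma_e2=1.0,
            loglik_reml=-100.0,
            n_obs=200,
            n_fixed=2,
            converged=True,
        )

    def test_zero_effect_gives_zero_d(self):
        res = lmm_to_fitresult(self._fit(0.0), 100, 100)
        assert res.d == 0.0

    def test_sign_preserved(self):
        assert lmm_to_fitresult(self._fit(-0.3), 100, 100).d < 0

    def test_nonconverged_propagates(self):
        bad = MixedModelFit(spec=MixedModelSpec(), converged=False, note="cap")
        res = lmm_to_fitresult(bad, 100, 100)
        assert not res.converged and res.d is None

    def test_reduction_to_mega_lr_without_cohort_variance(self, nocov_spec):
        sub = simulated_subset(
            nocov_spec,
            cohort_sizes=((2500, 2500),) * 2,
            seed=23,
            beta_dx=-0.1,
            sigma_u=0.0,
            sigma_e=1.0,
        )
        d_lr = fit_mega_lr(sub).d
        d_lmm = lmm_to_fitresult(fit_lmm(sub, MixedModelSpec()), sub.n1, sub.n2).d
        assert d_lmm == pytest.approx(d_lr, abs=0.005)


class TestBIC:
    def test_hand_value(self):
        assert bic(-100.0, 3, 100) == pytest.approx(213.8155, abs=1e-4)

    def test_loglik_linearity_and_penalty(self):
        base = bic(-50.0, 2, 64)
        assert bic(-50.0 + 1.5, 2, 64) == pytest.approx(base - 3.0)
        assert bic(-50.0, 3, 64) - base == pytest.approx(math.log(64))


class TestLRT:
    def _mmfit(self, ll, slope=False):
        return MixedModelFit(
            spec=MixedModelSpec(
                random=RANDOM_INTERCEPT_SLOPE if slope else RANDOM_INTERCEPT
            ),
            loglik_reml=ll,
            converged=True,
        )

    def test_equal_likelihoods_prefer_intercept(self):
        stat, p, preferred, _ = lrt_random_slope(
            self._mmfit(-100.0), self._mmfit(-100.0, slope=True)
        )
        assert stat == 0.0 and p == 1.0 and preferred == RANDOM_INTERCEPT

    def test_mixture_pvalue_hand_value(self):
        expected = 0.5 * stats.chi2.sf(6.0, 1) + 0.5 * stats.chi2.sf(6.0, 2)
        assert lrt_mixture_pvalue(6.0) == pytest.approx(expected, rel=1e-12)
        assert lrt_mixture_pvalue(6.0, naive_df2=True) == pytest.approx(
            stats.chi2.sf(6.0, 2), rel=1e-12
        )

    def test_nonconverged_slope_falls_back(self):
        bad = MixedModelFit(
            spec=MixedModelSpec(random=RANDOM_INTERCEPT_SLOPE), converged=False
        )
        _, _, preferred, reason = lrt_random_slope(self._mmfit(-100.0), bad)
        assert preferred == RANDOM_INTERCEPT
        assert "converge" in reason


class TestSelectRandomStructure:
    def test_forced_iteration_cap_falls_back_to_intercept(self, nocov_spec):
        sub = simulated_subset(
            nocov_spec,
            cohort_sizes=((20, 20),) * 6,
            seed=31,
            beta_dx=0.2,
            sigma_u=0.3,
            sigma_slope=0.4,
            sigma_e=1.0,
        )
        result, trace = select_random_structure(sub, maxiter=1)
        assert result.method == "mega_lmm_ri"
        assert trace["preferred"] == RANDOM_INTERCEPT
        assert trace["ris"] is None

    def test_large_slope_heterogeneity_detected(self, nocov_spec):
        """With strong cohort-varying diagnosis effects the slope model wins."""
        sub = simulated_subset(
            nocov_spec,
            cohort_sizes=((50, 50),) * 30,
            seed=37,
            beta_dx=0.2,
            sigma_u=0.3,
            sigma_slope=0.5,
            sigma_e=1.0,
        )
        result, trace = select_random_structure(sub)
        assert trace["preferred"] == RANDOM_INTERCEPT_SLOPE
        assert result.method == "mega_lmm_ris"

    def test_spec_requires_intercept_in_slope_model(self):
        with pytest.raises(ValueError):
            MixedModelSpec(random="slope_only")
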