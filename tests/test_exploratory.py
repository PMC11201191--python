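"""Exploratory moderated regression: OLS, nested F, scan, simple slopes."""

import numpy as np
import pandas as pd
import pytest

from gxecross.exploratory import (
    ComparisonResult,
    LinearFitResult,
    fit_cgs_interaction,
    fit_ols,
    fit_snp_models,
    nested_f_test,
    run_snp_scan,
    simple_slopes,
)
from gxecross.simulate import GenParams, SimConfig, gen_cohort


def _dummy_fit(terms, rss, r2, n):
    k = len(terms)
    idx = pd.Index(terms)
    zeros = pd.Series(np.zeros(k), index=idx)
    return LinearFitResult(
        terms=list(terms), params=zeros, bse=zeros,
        cov=pd.DataFrame(np.eye(k), index=idx, columns=idx), pvalues=zeros,
        r2=r2, f_overall=np.nan, f_p=np.nan, df=(k - 1, n - k), rss=rss, n=n,
        aic=np.nan, bic=np.nan, loglik=np.nan,
    )


class TestFitOls:
    def test_noiseless_line(self):
        x = np.linspace(0, 5, 20)
        fit = fit_ols(2 * x + 1, pd.DataFrame({"x": x}))
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_hand_least_squares(self):
        fit = fit_ols([1, 3, 5, 7], pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0]}))
        assert fit.params["x"] == pytest.approx(2.0)
        assert fit.params["const"] == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-20)

    def test_agrees_with_normal_equations_oracle(self, rng):
        for _ in range(5):
            n, k = 40, 4
            X = pd.DataFrame(rng.standard_normal((n, k)), columns=list("abcd"))
            y = rng.standard_normal(n)
            fit = fit_ols(y, X)
            Xc = np.column_stack([np.ones(n), X.to_numpy()])
            beta = np.linalg.solve(Xc.T @ Xc, Xc.T @ y)
            assert np.allclose(fit.params.to_numpy(), beta, rtol=1e-8, atol=1e-8)

    def test_rank_deficient_design_names_columns(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"x": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            fit_ols(x, X)

    def test_r2_never_decreases_with_added_column(self, rng):
        n = 60
        y = rng.standard_normal(n)
        X = pd.DataFrame({"a": rng.standard_normal(n)})
        r2_prev = fit_ols(y, X).r2
        for name in "bcd":
            X[name] = rng.standard_normal(n)
            r2 = fit_ols(y, X).r2
            assert r2 >= r2_prev - 1e-12
            r2_prev = r2


class TestNestedF:
    def test_formula_value(self):
        """dR²=0.10, dk=1, df_resid=50 on R²_full=0.20 gives F = 6.25."""
        red = _dummy_fit(["const", "a"], rss=0.9, r2=0.10, n=53)
        full = _dummy_fit(["const", "a", "b"], rss=0.8, r2=0.20, n=53)
        comp = nested_f_test(red, full)
        assert comp.f == pytest.approx(6.25)
        assert comp.df == (1, 50)
        assert comp.delta_r2 == pytest.approx(0.10)

    def test_uninformative_addition_gives_zero_f(self, rng):
        n = 50
        x = rng.standard_normal(n)
        y = 2 * x + rng.standard_normal(n)
        Xr = pd.DataFrame({"x": x})
        red = fit_ols(y, Xr)
        # column orthogonal to the design and to the residuals: adds nothing
        w = rng.standard_normal(n)
        Q = np.column_stack([np.ones(n), x, y - red.fitted])
        w -= Q @ np.linalg.lstsq(Q, w, rcond=None)[0]
        full = fit_ols(y, Xr.assign(z=w))
        comp = nested_f_test(red, full)
        assert comp.f == pytest.approx(0.0, abs=1e-8)
        assert comp.p == pytest.approx(1.0, abs=1e-8)

    def test_non_nested_rejected(self):
        a = _dummy_fit(["const", "a"], 1.0, 0.1, 50)
        b = _dummy_fit(["const", "b"], 1.0, 0.1, 50)
        with pytest.raises(ValueError, match="nested"):
            nested_f_test(a, b)
        with pytest.raises(ValueError, match="nested"):
            nested_f_test(a, a)

    def test_pvalues_uniform_under_null(self):
        """Interaction F p-values are U(0,1) when the product term is truly absent."""
        from scipy import stats

        ps = []
        for seed in range(400):
            coh = gen_cohort(SimConfig(n=250, seed=50_000 + seed, model_id="null"))
            _, _, comp = fit_snp_models(coh, "rs281238")
            ps.append(comp.p)
        assert stats.kstest(ps, "uniform").pvalue > 0.001


class TestRecovery:
    def test_product_coefficient_recovered(self):
        """Model 2's product estimate matches its large-sample projection within 2 SE."""
        cfg0 = SimConfig(n=200_000, seed=1, sigma=0.0)
        big = gen_cohort(cfg0)
        _, m2_pop, _ = fit_snp_models(big, "rs281238")
        truth = float(m2_pop.params["pe_x_t"])
        coh = gen_cohort(SimConfig(seed=61))
        _, m2, _ = fit_snp_models(coh, "rs281238")
        assert abs(m2.params["pe_x_t"] - truth) < 2 * m2.bse["pe_x_t"]


class TestScan:
    @pytest.mark.parametrize(
        "m, raw_p, significant",
        [(8, 0.005, True), (8, 0.01, False), (1, 0.04, True)],
    )
    def test_bonferroni_threshold(self, m, raw_p, significant):
        assert (raw_p < 0.05 / m) is significant

    def test_scan_threshold_and_order_invariance(self, paper_scale_cohort):
        scan = run_snp_scan(paper_scale_cohort, alpha=0.05)
        assert scan.threshold == pytest.approx(0.05 / scan.m)
        shuffled = list(reversed(paper_scale_cohort.snp_ids))
        scan2 = run_snp_scan(paper_scale_cohort, shuffled, alpha=0.05)
        assert set(scan.significant) == set(scan2.significant)

    def test_m_override(self, small_cohort):
        scan = run_snp_scan(small_cohort, alpha=0.05, m_override=8)
        assert scan.threshold == pytest.approx(0.05 / 8)

    def test_monomorphic_snp_skipped_with_warning(self, small_cohort):
        from gxecross.cohort import Cohort

        dos = small_cohort.dosages.copy()
        dos["mono"] = 0.0
        coh = Cohort(
            ids=small_cohort.ids, phenotype=small_cohort.phenotype,
            pe=small_cohort.pe, age=small_cohort.age, sex=small_cohort.sex,
            dosages=dos,
        )
        with pytest.warns(UserWarning, match="mono"):
            scan = run_snp_scan(coh)
        assert "mono" not in scan.table.index


class TestCgsInteraction:
    def test_noiseless_linear_by_linear_delta_r2(self):
        cfg = SimConfig(
            n=800, seed=70, sigma=0.0, form="linear", model_id="weak_ds",
            params=GenParams(linear_slopes=(1.0, 0.52)),
        )
        coh = gen_cohort(cfg)
        res = fit_cgs_interaction(coh)
        assert res.interaction.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.comparison.delta_r2 == pytest.approx(1.0 - res.main.r2, abs=1e-10)
        assert res.gate_passed

    def test_interaction_coefficient_recovered(self):
        cfg = SimConfig(seed=71, form="linear", model_id="weak_ds",
                        params=GenParams(linear_slopes=(-2.09, 0.52), crossover=3.34))
        coh = gen_cohort(cfg)
        res = fit_cgs_interaction(coh)
        est, se = res.interaction.params["pe_x_cgs"], res.interaction.bse["pe_x_cgs"]
        assert abs(est - 0.52) < 2 * se

    def test_gate_rate_under_null(self):
        """P(F > 1) under H0 is ~0.32, so the gate is false in ~68% of null runs."""
        fails = 0
        reps = 200
        for seed in range(reps):
            coh = gen_cohort(SimConfig(n=300, seed=80_000 + seed, model_id="null"))
            fails += not fit_cgs_interaction(coh).gate_passed
        assert 0.55 < fails / reps < 0.80

    def test_zero_variance_cgs_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="variance"):
            fit_cgs_interaction(small_cohort, cgs=np.zeros(small_cohort.n))


class TestSimpleSlopes:
    def test_arithmetic(self):
        terms = ["const", "pe", "t", "pe_x_t", "age", "sex"]
        idx = pd.Index(terms)
        params = pd.Series([0.0, 0.63, 0.0, 1.56, 0.0, 0.0], index=idx)
        fit = LinearFitResult(
            terms=terms, params=params, bse=params * 0 + 1,
            cov=pd.DataFrame(np.eye(6) * 0.01, index=idx, columns=idx),
            pvalues=params * 0, r2=0.2, f_overall=1.0, f_p=0.5,
            df=(5, 100), rss=1.0, n=106, aic=0.0, bic=0.0, loglik=0.0,
        )
        out = simple_slopes(fit, [0, 1, 2])
        assert out["slope"].tolist() == pytest.approx([0.63, 2.19, 3.75])

    def test_zero_product_gives_constant_slopes(self, small_cohort):
        _, m2, _ = fit_snp_models(small_cohort, "rs281238")
        m2.params["pe_x_t"] = 0.0
        out = simple_slopes(m2, [0, 1, 2])
        assert np.allclose(out["slope"], out["slope"].iloc[0])

    def test_reference_group_slope_under_strong_model(self):
        """Under strong-DS truth the T=0 simple slope tracks its equal-spacing
        projection (small, near zero), far below the susceptible groups'."""
        big = gen_cohort(SimConfig(n=200_000, seed=1, sigma=0.0))
        _, m2_pop, _ = fit_snp_models(big, "rs281238")
        proj = float(simple_slopes(m2_pop, [0])["slope"].iloc[0])
        coh = gen_cohort(SimConfig(seed=90))
        _, m2, _ = fit_snp_models(coh, "rs281238")
        out = simple_slopes(m2, [0, 2])
        assert abs(out["slope"].iloc[0] - proj) < 2 * out["se"].iloc[0]
        assert out["slope"].iloc[2 - 1] > out["slope"].iloc[0]
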