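"""Re-parameterized crossover regression: profiling, SEs, arbitration."""

import numpy as np
import pandas as pd
import pytest

from gxecross.exploratory import fit_snp_models
from gxecross.reparam import (
    ReparamFitResult,
    compare_models,
    fit_cgs_family,
    fit_crossover_groups,
    fit_crossover_linear,
    fit_group_family,
    fixed_c_value,
    linear_to_crossover,
    nested_f_reparam,
    predicted_surface,
    wald_ci,
)
from gxecross.simulate import GenParams, SimConfig, gen_cohort


class TestWaldCi:
    @pytest.mark.parametrize(
        "est, se, lo, hi",
        [
            # printed (estimate, SE) -> CI anchors from the confirmatory fits
            (3.21, 0.36, 2.50, 3.92),
            (3.21, 0.42, 2.39, 4.03),
            (3.34, 0.56, 2.24, 4.44),
        ],
    )
    def test_worked_examples(self, est, se, lo, hi):
        got = wald_ci(est, se, 0.95)
        assert got[0] == pytest.approx(lo, abs=0.01)
        assert got[1] == pytest.approx(hi, abs=0.01)

    def test_zero_se_degenerates_to_point(self):
        assert wald_ci(1.7, 0.0, 0.9) == (1.7, 1.7)

    def test_validation(self):
        with pytest.raises(ValueError):
            wald_ci(0, 1, 1.5)
        with pytest.raises(ValueError):
            wald_ci(0, -1, 0.95)


class TestFixedC:
    def test_rules(self):
        pe = np.array([1.0, 2, 3, 4, 5])
        assert fixed_c_value(pe, "mean_plus_3sd") == pytest.approx(
            3 + 3 * np.std(pe, ddof=1)
        )
        assert fixed_c_value(pe, "observed_max") == 5.0


class TestGroupFit:
    def test_noiseless_exact_recovery(self):
        cfg = SimConfig(n=500, seed=100, sigma=0.0)
        coh = gen_cohort(cfg)
        fit = fit_crossover_groups(coh, "rs281238", c_mode="free", strong=True)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.c_hat == pytest.approx(3.21, abs=1e-6)
        assert fit.params["slope1"] == pytest.approx(2.49, abs=1e-6)
        assert fit.params["slope2"] == pytest.approx(3.27, abs=1e-6)
        assert fit.params["age"] == pytest.approx(0.91, abs=1e-8)

    def test_fixed_c_equals_transformed_column_ols(self, small_cohort):
        """Fixed-C fitting is plain OLS on (X1-C) columns (statsmodels oracle)."""
        import statsmodels.api as sm

        c = fixed_c_value(small_cohort.pe)
        fit = fit_crossover_groups(
            small_cohort, "rs281238", c_mode="fixed", c_value=c, strong=False
        )
        t = small_cohort.dosage("rs281238")
        X = np.column_stack(
            [
                np.ones(small_cohort.n),
                (t == 0) * (small_cohort.pe - c),
                (t == 1) * (small_cohort.pe - c),
                (t == 2) * (small_cohort.pe - c),
                small_cohort.age,
                small_cohort.sex,
            ]
        )
        res = sm.OLS(small_cohort.phenotype, X).fit()
        assert np.allclose(fit.params.to_numpy(), res.params, atol=1e-10)
        assert fit.rss == pytest.approx(res.ssr, abs=1e-8)
        assert np.allclose(fit.bse.to_numpy(), res.bse, atol=1e-10)

    def test_profiled_c_matches_fine_grid_oracle(self):
        """The profiled crossover equals an exhaustive 1e-3-step grid argmin."""
        for seed in (201, 202):
            coh = gen_cohort(SimConfig(n=400, seed=seed))
            fit = fit_crossover_groups(coh, "rs281238", c_mode="free", strong=True)
            t = coh.dosage("rs281238")

            def rss_of(c):
                X = np.column_stack(
                    [np.ones(coh.n), (t == 1) * (coh.pe - c),
                     (t == 2) * (coh.pe - c), coh.age, coh.sex]
                )
                r = coh.phenotype - X @ np.linalg.lstsq(X, coh.phenotype, rcond=None)[0]
                return r @ r

            sd = np.std(coh.pe, ddof=1)
            grid = np.arange(coh.pe.min() - 2 * sd, coh.pe.max() + 2 * sd, 0.001)
            c_grid = grid[np.argmin([rss_of(c) for c in grid])]
            assert abs(fit.c_hat - c_grid) <= 0.001

    def test_empty_group_rejected(self, small_cohort):
        dosage = np.minimum(small_cohort.dosage("rs281238"), 1.0)  # no T=2
        with pytest.raises(ValueError, match="group sizes"):
            fit_crossover_groups(small_cohort, dosage=dosage, c_mode="free")

    def test_profile_ci_brackets_estimate(self, small_cohort):
        fit = fit_crossover_groups(
            small_cohort, "rs281238", c_mode="free", strong=True, profile_ci=True
        )
        lo, hi = fit.c_ci_profile
        assert lo < fit.c_hat < hi


class TestLinearFit:
    def test_recovery_at_paper_scale(self):
        cfg = SimConfig(
            seed=210, form="linear", model_id="weak_ds",
            params=GenParams(linear_slopes=(-2.09, 0.52), crossover=3.34),
        )
        coh = gen_cohort(cfg)
        fit = fit_crossover_linear(coh, c_mode="free")
        assert abs(fit.c_hat - 3.34) < 2 * fit.c_se
        assert abs(fit.params["a2"] - 0.52) < 2 * fit.bse["a2"]

    def test_flat_profile_flagged_when_crossover_unidentified(self):
        """With no gene-environment slope term (A2=0, sigma=0) C drops out."""
        cfg = SimConfig(
            n=300, seed=211, sigma=0.0, form="linear", model_id="weak_ds",
            params=GenParams(linear_slopes=(1.3, 0.0)),
        )
        coh = gen_cohort(cfg)
        fit = fit_crossover_linear(coh, c_mode="free")
        assert not fit.identified
        assert fit.c_se is None

    def test_fixed_c_equals_transformed_column_ols(self, small_cohort):
        import statsmodels.api as sm

        c = 6.5
        fit = fit_crossover_linear(small_cohort, c_mode="fixed", c_value=c)
        x2 = np.asarray(small_cohort.cgs, dtype=float)
        X = np.column_stack(
            [np.ones(small_cohort.n), small_cohort.pe - c,
             (small_cohort.pe - c) * x2, small_cohort.age, small_cohort.sex]
        )
        res = sm.OLS(small_cohort.phenotype, X).fit()
        assert np.allclose(fit.params.to_numpy(), res.params, atol=1e-10)


class TestReparamIdentity:
    def test_linear_interaction_is_equal_spaced_crossover(self, paper_scale_cohort):
        """Model 2 with numeric T is exactly the common-crossover model with
        equally spaced slopes and C = -A2/A3."""
        _, m2, _ = fit_snp_models(paper_scale_cohort, "rs281238")
        cc = linear_to_crossover(m2)
        t = paper_scale_cohort.dosage("rs281238")
        pred = cc.predict(paper_scale_cohort.pe, t,
                          paper_scale_cohort.age, paper_scale_cohort.sex)
        assert np.allclose(pred, m2.fitted, atol=1e-8)
        s0, s1, s2 = cc.slopes
        assert s1 - s0 == pytest.approx(s2 - s1)


class TestNestingInvariants:
    @pytest.mark.parametrize("seed", [301, 302, 303])
    def test_r2_ordering_group_family(self, seed):
        coh = gen_cohort(SimConfig(n=600, seed=seed))
        fits = fit_group_family(coh, "rs281238")
        eps = 1e-12
        assert fits["3b"].r2 >= fits["3a"].r2 - eps
        assert fits["3b"].r2 >= fits["3d"].r2 - eps
        assert fits["3d"].r2 >= fits["3c"].r2 - eps

    def test_r2_ordering_cgs_family(self, small_cohort):
        fits = fit_cgs_family(small_cohort)
        assert fits["3e"].r2 >= fits["3f"].r2 - 1e-12

    def test_aic_bic_rank_same_df_models_like_rss(self, small_cohort):
        fits = fit_group_family(small_cohort, "rs281238")
        a, d = fits["3a"], fits["3d"]
        assert a.n_mean_params == d.n_mean_params
        assert (a.aic < d.aic) == (a.rss < d.rss)
        assert (a.bic < d.bic) == (a.rss < d.rss)


def _toy_fit(model_id, rss, n=100, k=6, strong=False, c_fixed=False,
             c_hat=3.2, c_se=0.4, c_ci=(2.4, 4.0)):
    idx = pd.Index(["a0"])
    return ReparamFitResult(
        model_id=model_id, form="groups", strong=strong, c_hat=c_hat,
        c_fixed=c_fixed, c_se=None if c_fixed else c_se,
        c_ci=None if c_fixed else c_ci,
        params=pd.Series([0.0], index=idx), bse=pd.Series([1.0], index=idx),
        r2=1 - rss / 100.0, rss=rss, aic=n * np.log(rss / n) + 2 * (k + 1),
        bic=n * np.log(rss / n) + (k + 1) * np.log(n),
        df=(k - 1, n - k), n=n, n_mean_params=k,
    )


class TestCompareModels:
    def test_strong_ds_truth_selected(self):
        coh = gen_cohort(SimConfig(seed=3))
        fits = fit_group_family(coh, "rs281238")
        _, _, comp = fit_snp_models(coh, "rs281238")
        cls = compare_models(fits, comp.f > 1.0, coh.pe_range())
        assert cls.selected_model == "3a"
        assert cls.family == "differential_susceptibility"
        assert cls.strength == "strong"
        assert cls.shape == "disordinal"

    def test_strong_dis_truth_selected(self):
        coh = gen_cohort(SimConfig(seed=401, model_id="strong_dis"))
        fits = fit_group_family(coh, "rs281238")
        _, _, comp = fit_snp_models(coh, "rs281238")
        cls = compare_models(fits, comp.f > 1.0, coh.pe_range())
        assert cls.family == "diathesis_stress"
        assert cls.shape == "ordinal"

    def test_gate_failure_blocks_selection(self, small_cohort):
        fits = fit_group_family(small_cohort, "rs281238")
        cls = compare_models(fits, False, small_cohort.pe_range())
        assert cls.selected_model is None and cls.family == "none"
        assert not cls.gate_passed

    def test_aic_bic_disagreement_is_indeterminate(self):
        # free finalist wins AIC but loses BIC against the fixed finalist
        n, k_free, k_fixed = 100, 6, 5
        rss_free, rss_fixed = 80.0, 81.7
        fits = {
            "3a": _toy_fit("3a", rss_free, n=n, k=k_free, strong=True),
            "3b": _toy_fit("3b", rss_free - 1e-9, n=n, k=k_free + 1),
            "3c": _toy_fit("3c", rss_fixed, n=n, k=k_fixed, strong=True, c_fixed=True),
            "3d": _toy_fit("3d", rss_fixed - 1e-9, n=n, k=k_fixed + 1, c_fixed=True),
        }
        aic_free = fits["3a"].aic
        aic_fixed = fits["3c"].aic
        bic_free = fits["3a"].bic
        bic_fixed = fits["3c"].bic
        assert (aic_free < aic_fixed) != (bic_free < bic_fixed)
        cls = compare_models(fits, True, (1.0, 8.0))
        assert cls.selected_model is None
        assert cls.family == "none"
        assert any("indeterminate" in str(e.get("decision", "")) for e in cls.evidence)

    def test_cgs_branch_free_c_accepted_on_significant_f(self):
        cfg = SimConfig(
            seed=402, form="linear", model_id="weak_ds",
            params=GenParams(linear_slopes=(-2.09, 0.52), crossover=3.34),
        )
        coh = gen_cohort(cfg)
        fits = fit_cgs_family(coh)
        _, f, _, p = nested_f_reparam(fits["3f"], fits["3e"])
        cls = compare_models(fits, True, coh.pe_range())
        assert (cls.selected_model == "3e") == (p < 0.05)

    def test_null_truth_mostly_fails_gate(self):
        from gxecross.exploratory import fit_cgs_interaction

        fails = 0
        for seed in range(30):
            coh = gen_cohort(SimConfig(n=400, seed=90_000 + seed, model_id="null"))
            fails += not fit_cgs_interaction(coh).gate_passed
        assert fails > 15


class TestPredictedSurface:
    def _fit(self):
        idx = pd.Index(["a0", "slope1", "slope2", "age", "sex"])
        return ReparamFitResult(
            model_id="3a", form="groups", strong=True, c_hat=3.21,
            c_fixed=False, c_se=0.36, c_ci=(2.50, 3.92),
            params=pd.Series([-0.90, 2.49, 3.27, 0.91, -2.53], index=idx),
            bse=pd.Series(np.ones(5), index=idx), r2=0.26, rss=1.0,
            aic=0.0, bic=0.0, df=(5, 1471), n=1477, n_mean_params=6,
        )

    def test_groups_agree_at_crossover(self):
        surf = predicted_surface(self._fit(), [3.21], age=116.0, sex=0.0)
        assert surf["predicted"].nunique() == 1

    def test_strong_reference_group_constant_in_pe(self):
        surf = predicted_surface(self._fit(), np.linspace(1, 8, 15), age=116.0, sex=0.0)
        ref = surf[surf["level"] == 0.0]["predicted"]
        assert ref.nunique() == 1

    def test_group_contrast_arithmetic(self):
        """At PE=5 the T=2 vs T=0 contrast is 3.27 * (5 - 3.21) = 5.8533."""
        surf = predicted_surface(self._fit(), [5.0], age=116.0, sex=0.0)
        wide = surf.set_index("level")["predicted"]
        assert wide[2.0] - wide[0.0] == pytest.approx(3.27 * (5 - 3.21), abs=1e-10)

    def test_order_reverses_across_crossover(self):
        surf = predicted_surface(self._fit(), [2.0, 5.0], age=116.0, sex=0.0)
        low = surf[surf.pe == 2.0].set_index("level")["predicted"]
        high = surf[surf.pe == 5.0].set_index("level")["predicted"]
        assert low[2.0] < low[1.0] < low[0.0]
        assert high[2.0] > high[1.0] > high[0.0]
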