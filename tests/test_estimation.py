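"""Estimation tests: NCA oracles, exact-data recovery, structural-model
comparison, bootstrap, covariate machinery, and fit diagnostics."""

import dataclasses

import numpy as np
from scipy import stats

import flunipk as fp
from flunipk.estimation import (
    CovariateEffect,
    FitSettings,
    FittedModel,
    _detect_confounding,
    bootstrap_ci,
    compare_models,
    covariate_search,
    diagnostics,
    fit_population,
    initial_pop_from_nca,
    nca_initial_estimates,
)
from flunipk.model import plasma_concentration
from conftest import SHORT_SCHEDULES, make_dataset


def zero_noise_pop(pop):
    out = pop.copy()
    out.omega = np.zeros((7, 7))
    out.sigma_plasma_prop = out.sigma_plasma_add = 0.0
    out.sigma_urine_prop = out.sigma_urine_add = 0.0
    return out


def inject_bw_on_cl(data, pop, seed, exponent):
    """Regenerate observations with each horse's clearance scaled by
    (BW/475)^exponent, keeping everything else from the source cohort."""
    rng = np.random.default_rng(seed)
    recs = data.records.copy()
    truths = {}
    for hid in data.horse_ids:
        p = data.truths[hid]
        bw = float(recs.loc[recs.ID == hid, "BW"].iloc[0])
        p2 = fp.DispositionParams(p.V1, p.V2, p.V3, p.Cl * (bw / 475.0) ** exponent,
                                  p.Cl2, p.Cl3, p.Rss)
        truths[hid] = p2
        reg = data.regimen_for(hid)
        m = (recs.ID == hid) & (recs.EVID == 0)
        t = recs.loc[m, "TIME"].to_numpy(float)
        pred = plasma_concentration(p2, reg, t)
        urine = (recs.loc[m, "MATRIX"] == "urine").to_numpy()
        pred[urine] *= p2.Rss
        out = np.empty(len(pred))
        out[~urine] = fp.apply_residual_error(pred[~urine], "plasma", pop, rng)
        out[urine] = fp.apply_residual_error(pred[urine], "urine", pop, rng)
        recs.loc[m, "DV"] = out
        recs.loc[m, "BELOW_LOQ"] = out < recs.loc[m, "LOQ"]
    return fp.ConcentrationDataset(recs, truths)


class TestNca:
    def test_monoexponential_oracle(self):
        t = np.arange(1.0, 25.0)
        c = 100.0 * np.exp(-0.1 * t)
        data = make_dataset([(1, float(tt), "plasma", float(cc), 1e-9) for tt, cc in zip(t, c)],
                            dose_rows=[(1, 0.0, 1000.0 * 100.0)])
        res = nca_initial_estimates(data)
        row = res.table.iloc[0]
        assert abs(row["lambda_z"] - 0.1) < 1e-6
        # closed-form AUC_inf is 1000; trapezoids overestimate a convex decay
        # by at most h^2/12 * integral of |C''| = 100*0.1/12 per unit interval
        assert abs(row["AUC_inf"] - 1000.0) < 1.0
        assert row["lambda_z_ok"]

    def test_too_few_terminal_points_flagged(self):
        data = make_dataset([(1, 1.0, "plasma", 90.0, 0.1), (1, 2.0, "plasma", 80.0, 0.1)])
        res = nca_initial_estimates(data)
        assert not res.table.iloc[0]["lambda_z_ok"]

    def test_clearance_within_10pct_on_noise_free_typical(self, published_pop, arms):
        pop = zero_noise_pop(published_pop)
        data = fp.generate_cohort([dataclasses.replace(arms[0], n_horses=1)], pop, seed=0)
        res = nca_initial_estimates(data)
        cl = res.table.iloc[0]["Cl_obs"]
        assert abs(cl - 47.36) / 47.36 < 0.10


def test_exact_data_limit_recovers_theta(published_pop, arms):
    """Noise-free, zero-variability data pins the typical values to 0.1%."""
    pop = zero_noise_pop(published_pop)
    small = [dataclasses.replace(arms[0], n_horses=4, **SHORT_SCHEDULES)]
    data = fp.generate_cohort(small, pop, seed=1)
    init = published_pop.copy()
    init.theta = published_pop.theta * 1.25
    fit = fit_population(data, init, FitSettings(max_outer=60))
    np.testing.assert_allclose(fit.pop.theta, published_pop.theta, rtol=1e-3)


class TestCompareModels:
    def _dummy(self, pop, loglik, k, n=500):
        return FittedModel(pop=pop, loglik=loglik, n_params=k, n_obs=n, ebes={},
                           ebe_covs={}, free_names=("V1",))

    def test_identical_fits(self, published_pop):
        a = self._dummy(published_pop, -100.0, 10)
        res = compare_models(a, self._dummy(published_pop, -100.0, 10))
        assert res["lrt"] == 0.0 and res["p_value"] == 1.0

    def test_chi_square_oracle(self, published_pop):
        a = self._dummy(published_pop, -103.0, 10)
        b = self._dummy(published_pop, -100.0, 12)
        res = compare_models(a, b)
        assert res["df"] == 2
        assert abs(res["p_value"] - stats.chi2.sf(6.0, 2)) < 1e-12
        assert abs(res["p_value"] - 0.0498) < 1e-3

    def test_bic_formula(self, published_pop):
        fit = self._dummy(published_pop, -100.0, 12, n=500)
        assert abs(fit.bic - (200.0 + 12 * np.log(500))) < 1e-9

    def test_non_nested_refused(self, published_pop):
        a = self._dummy(published_pop, -100.0, 12)
        res = compare_models(a, self._dummy(published_pop, -99.0, 10))
        assert not res["nested"]
        assert "delta_bic" in res


def test_three_compartment_preferred_on_three_compartment_data(published_pop, arms):
    small = [dataclasses.replace(arms[0], n_horses=8, **SHORT_SCHEDULES)]
    data = fp.generate_cohort(small, published_pop, seed=21)
    data, _ = fp.censor_loq(data)
    init = initial_pop_from_nca(data)
    fit3 = fit_population(data, init, FitSettings(max_outer=25))
    fit2 = fit_population(data, init, FitSettings(max_outer=25, n_compartments=2))
    res = compare_models(fit2, fit3)
    assert res["nested"]
    assert res["p_value"] < 0.05


class TestBootstrap:
    def test_degenerate_on_exact_data(self, published_pop, arms):
        pop = zero_noise_pop(published_pop)
        d0 = fp.generate_cohort([dataclasses.replace(arms[0], n_horses=4, **SHORT_SCHEDULES)],
                                pop, seed=9)
        table = bootstrap_ci(d0, published_pop, FitSettings(max_outer=15), n_boot=5, seed=2)
        theta_rows = table[table["Parameter"].str.startswith("tv")]
        assert (theta_rows["97.5% CI"] - theta_rows["2.5% CI"]).abs().max() < 1e-2
        np.testing.assert_allclose(
            theta_rows["Estimate"].to_numpy(), published_pop.theta, rtol=1e-3)

    def test_table_layout(self, published_pop, arms):
        # layout mirrors the published bootstrap table: estimate, SE, CV%, CI bounds
        pop = zero_noise_pop(published_pop)
        d0 = fp.generate_cohort([dataclasses.replace(arms[0], n_horses=3, **SHORT_SCHEDULES)],
                                pop, seed=10)
        table = bootstrap_ci(d0, published_pop, FitSettings(max_outer=8), n_boot=3, seed=0)
        assert list(table.columns) == ["Parameter", "Estimate", "Std_err", "CV%",
                                       "2.5% CI", "97.5% CI"]


class TestCovariates:
    def _cohort(self, published_pop, arms, n, seed):
        arm = dataclasses.replace(arms[0], n_horses=n, bw_range=(350, 700), **SHORT_SCHEDULES)
        return fp.generate_cohort([arm], published_pop, seed=seed)

    def test_forced_fit_recovers_realized_exponent(self, published_pop, arms):
        """With a (BW/475)^0.75 effect injected on clearance the covariate fit
        estimates the exponent actually realized in the finite cohort (the
        random clearance effects of 16 horses can tilt the realized
        BW-clearance slope well away from the nominal 0.75)."""
        data = self._cohort(published_pop, arms, 16, 101)
        di = inject_bw_on_cl(data, published_pop, 102, 0.75)
        di, _ = fp.censor_loq(di)
        init = initial_pop_from_nca(di)
        eff = CovariateEffect("Cl", "BW", "power")
        fit_cov = fit_population(di, init, FitSettings(max_outer=12, covariate_effects=(eff,)))
        (coef,) = fit_cov.covariate_coefs.values()
        bw = di.covariates()["BW"].astype(float).to_numpy()
        true_cl = np.log([di.truths[h].Cl for h in di.horse_ids])
        realized = np.polyfit(np.log(bw / 475.0), true_cl, 1)[0]
        assert abs(coef - realized) < 0.2

    def test_strong_effect_selected_null_effect_not(self, published_pop, arms):
        """Stepwise BIC search fires on an unambiguous injected effect and
        stays empty on covariate-free data."""
        data = self._cohort(published_pop, arms, 16, 55)
        strong = inject_bw_on_cl(data, published_pop, 56, 3.0)
        strong, _ = fp.censor_loq(strong)
        init = initial_pop_from_nca(strong)
        st = FitSettings(max_outer=15)
        base = fit_population(strong, init, st)
        res = covariate_search(strong, base, {"BW": "continuous"}, parameters=("Cl",), init=init)
        assert [(e.parameter, e.covariate) for e in res["final_effects"]] == [("Cl", "BW")]

        null_data, _ = fp.censor_loq(data)
        init0 = initial_pop_from_nca(null_data)
        base0 = fit_population(null_data, init0, st)
        res0 = covariate_search(null_data, base0, {"BW": "continuous"}, parameters=("Cl",), init=init0)
        assert res0["final_effects"] == []

    def test_aliased_categoricals_flagged(self, published_pop, arms):
        # breed is constant within country in the six published arms
        data = fp.generate_cohort(arms, published_pop, seed=3)
        flags = _detect_confounding(data, ["BREED", "COUNTRY"])
        assert ("BREED", "COUNTRY") in flags


class TestDiagnostics:
    def test_medium_fit_recovers_major_parameters(self, medium_fit, published_pop):
        # tolerance per parameter reflects the sampling SE of a 28-horse draw:
        # ~BSV/sqrt(28), i.e. ~3% for V1 (18% BSV), ~6% for Cl, ~16% for Rss (99%)
        names = list(medium_fit.pop.parameter_names)
        for nm, tol in (("V1", 0.15), ("Cl", 0.15), ("Rss", 0.40)):
            i = names.index(nm)
            assert abs(medium_fit.pop.theta[i] / published_pop.theta[i] - 1.0) < tol

    def test_cwres_standard_normal_on_well_specified_data(self, medium_fit, medium_cohort):
        diag = diagnostics(medium_fit, medium_cohort, vpc_replicates=50, vpc_seed=1)
        cw = diag.observations["CWRES"]
        assert len(cw) >= 400
        assert abs(cw.mean()) < 0.1
        assert 0.85 < cw.std() < 1.15

    def test_ipred_closer_than_pred(self, medium_fit, medium_cohort):
        diag = diagnostics(medium_fit, medium_cohort, vpc_replicates=10, vpc_seed=1)
        obs = diag.observations
        ip = np.abs(np.log(obs["DV"].clip(lower=1e-6)) - np.log(obs["IPRED"].clip(lower=1e-9)))
        pp = np.abs(np.log(obs["DV"].clip(lower=1e-6)) - np.log(obs["PRED"].clip(lower=1e-9)))
        assert ip.mean() < pp.mean()

    def test_shrinkage_low_for_rich_design(self, medium_fit, medium_cohort):
        diag = diagnostics(medium_fit, medium_cohort, vpc_replicates=10, vpc_seed=1)
        for nm, s in diag.shrinkage.items():
            assert -0.2 < s < 1.0
        assert diag.shrinkage["Cl"] < 0.3

    def test_vpc_coverage_near_nominal(self, medium_fit, medium_cohort):
        diag = diagnostics(medium_fit, medium_cohort, vpc_replicates=200, vpc_seed=7)
        assert 0.73 <= diag.vpc_coverage <= 0.87

    def test_cv_percent_from_fitted_omega(self, medium_fit, medium_cohort):
        diag = diagnostics(medium_fit, medium_cohort, vpc_replicates=10, vpc_seed=1)
        j = list(medium_fit.free_names).index("Cl")
        idx = list(medium_fit.pop.parameter_names).index("Cl")
        expected = 100.0 * np.sqrt(np.expm1(medium_fit.pop.omega[idx, idx]))
        assert np.isclose(diag.cv_percent["Cl"], expected, rtol=1e-9)
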