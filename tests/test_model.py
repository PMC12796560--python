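"""Disposition-model tests: macro-constant algebra against an ODE oracle,
secondary parameters, superposition, population sampling and residual error."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.linalg import expm

import flunipk as fp
from flunipk.model import (
    DispositionParams,
    DosingRegimen,
    InvalidParameterError,
    bsv_cv_percent,
    micro_to_macro,
    sample_etas,
)


def ode_plasma(params, dose, t_eval):
    """Independent oracle: integrate the linear three-compartment system via
    the matrix exponential (exact for a linear ODE, robust over the many
    orders of magnitude the late curve spans where adaptive steppers lose
    relative accuracy)."""
    k10 = params.Cl / params.V1
    k12 = params.Cl2 / params.V1
    k21 = params.Cl2 / params.V2
    k13 = params.Cl3 / params.V1
    k31 = params.Cl3 / params.V3
    a_mat = np.array([
        [-(k10 + k12 + k13), k21, k31],
        [k12, -k21, 0.0],
        [k13, 0.0, -k31],
    ])
    amounts = np.array([dose, 0.0, 0.0])
    return np.array([(expm(a_mat * t) @ amounts)[0] for t in t_eval]) / params.V1


def random_params(rng):
    return DispositionParams(
        V1=rng.uniform(50, 300), V2=rng.uniform(5, 100), V3=rng.uniform(10, 150),
        Cl=rng.uniform(10, 100), Cl2=rng.uniform(0.05, 20), Cl3=rng.uniform(0.5, 30),
        Rss=rng.uniform(1, 100),
    )


class TestMacroConstants:
    def test_closed_form_matches_ode_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            p = random_params(rng)
            reg = DosingRegimen.single(1.1)
            t = np.linspace(0.05, 72, 50)
            closed = fp.plasma_concentration(p, reg, t)
            ode = ode_plasma(p, reg.dose_amount, t)
            assert np.max(np.abs(closed - ode) / ode) < 1e-6

    def test_rate_invariants_match_micro_traces(self, typical):
        m = micro_to_macro(typical)
        k10 = typical.Cl / typical.V1
        k12 = typical.Cl2 / typical.V1
        k21 = typical.Cl2 / typical.V2
        k13 = typical.Cl3 / typical.V1
        k31 = typical.Cl3 / typical.V3
        assert m.rates[0] > m.rates[1] > m.rates[2] > 0
        assert np.isclose(m.rates.sum(), k10 + k12 + k21 + k13 + k31, rtol=1e-9)
        assert np.isclose(np.prod(m.rates), k10 * k21 * k31, rtol=1e-9)
        assert np.isclose(m.coefs.sum(), 1.0, rtol=1e-9)

    def test_published_half_lives(self, typical):
        """The published micro-constants reproduce the printed fast/intermediate
        half-lives (1.4 and 3.8 h) and a terminal half-life within 1% of 28.4 h
        (the printed primaries are rounded)."""
        sec = fp.secondary_parameters(typical)
        assert round(sec.t_half_alpha, 1) == 1.4
        assert round(sec.t_half_beta, 1) == 3.8
        assert abs(sec.t_half_gamma - 28.4) / 28.4 < 0.01

    def test_one_compartment_collapse(self, typical):
        p = DispositionParams(typical.V1, typical.V2, typical.V3, typical.Cl, 0.0, 0.0, typical.Rss)
        m = micro_to_macro(p)
        assert len(m.rates) == 1
        assert np.isclose(m.rates[0], typical.Cl / typical.V1)
        assert np.isclose(m.rates[0], 0.3914, atol=5e-5)

    def test_two_compartment_collapse_matches_ode(self, typical):
        p = DispositionParams(typical.V1, typical.V2, typical.V3, typical.Cl, 0.0, typical.Cl3, typical.Rss)
        reg = DosingRegimen.single(1.1)
        t = np.linspace(0.1, 48, 20)
        assert len(micro_to_macro(p).rates) == 2
        np.testing.assert_allclose(fp.plasma_concentration(p, reg, t),
                                   ode_plasma(p, reg.dose_amount, t), rtol=1e-6)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            DispositionParams(-1, 8.9, 31.7, 47.4, 0.2, 7.5, 35.9)
        with pytest.raises(InvalidParameterError):
            DispositionParams(121, 8.9, 31.7, 47.4, -0.2, 7.5, 35.9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rates_positive_descending_coefs_sum_to_one(self, seed):
        p = random_params(np.random.default_rng(seed))
        m = micro_to_macro(p)
        assert np.all(np.diff(m.rates) < 0)
        assert np.all(m.rates > 0)
        assert np.isclose(m.coefs.sum(), 1.0, rtol=1e-9)


class TestConcentrationCurves:
    def test_initial_concentration_is_dose_over_v1(self, typical):
        reg = DosingRegimen.single(1.1)
        assert np.isclose(fp.plasma_concentration(typical, reg, 0.0), 1.1e6 / 121.00, rtol=1e-9)

    def test_typical_concentration_at_48h(self, typical):
        reg = DosingRegimen.single(1.1)
        c48 = fp.plasma_concentration(typical, reg, 48.0)
        ode = ode_plasma(typical, reg.dose_amount, np.array([48.0]))[0]
        assert np.isclose(c48, ode, rtol=1e-6)
        assert 1.1 < c48 < 1.3  # ~1.19 ng/mL

    def test_single_dose_curve_strictly_decreasing(self, typical):
        reg = DosingRegimen.single(1.1)
        t = np.linspace(0.01, 168, 400)
        c = fp.plasma_concentration(typical, reg, t)
        assert np.all(np.diff(c) < 0)

    def test_time_before_first_dose_returns_zero(self, typical):
        reg = DosingRegimen(1.1e6, (0.0, 24.0))
        assert fp.plasma_concentration(typical, reg, 12.0) > 0
        # the second dose contributes nothing before it is given
        single = DosingRegimen.single(1.1)
        assert np.isclose(fp.plasma_concentration(typical, reg, 12.0),
                          fp.plasma_concentration(typical, single, 12.0))

    def test_superposition_of_shifted_single_doses(self, typical):
        reg = DosingRegimen.repeated(1.1, 24.0, 5)
        single = DosingRegimen.single(1.1)
        for t in (97.0, 120.0, 150.0):
            expected = sum(fp.plasma_concentration(typical, single, t - td)
                           for td in reg.dose_times)
            assert np.isclose(fp.plasma_concentration(typical, reg, t), expected, rtol=1e-12)

    def test_steady_state_trough_accumulation(self, typical):
        """After many daily doses the trough approaches the closed-form
        geometric accumulation of each exponential term."""
        m = micro_to_macro(typical)
        n = 60
        reg = DosingRegimen.repeated(1.1, 24.0, n)
        c0 = 1.1e6 / typical.V1
        expected = c0 * np.sum(m.coefs * np.exp(-m.rates * 24.0) / (1.0 - np.exp(-m.rates * 24.0)))
        trough = fp.plasma_concentration(typical, reg, reg.last_dose_time + 24.0 - 1e-9)
        assert np.isclose(trough, expected, rtol=1e-3)

    def test_urine_is_rss_times_plasma_with_validity_flag(self, typical):
        reg = DosingRegimen.single(1.1)
        c48, valid48 = fp.urine_concentration(typical, reg, 48.0)
        assert valid48
        assert np.isclose(c48, typical.Rss * fp.plasma_concentration(typical, reg, 48.0))
        assert 40 < c48 < 46  # ~42.8 ng/mL
        c12, valid12 = fp.urine_concentration(typical, reg, 12.0)
        assert c12 > 0 and not valid12

    def test_rss_of_one_makes_urine_equal_plasma(self, typical):
        p = DispositionParams(typical.V1, typical.V2, typical.V3, typical.Cl,
                              typical.Cl2, typical.Cl3, 1.0)
        reg = DosingRegimen.single(1.1)
        t = np.array([24.0, 48.0, 96.0])
        u, _ = fp.urine_concentration(p, reg, t)
        np.testing.assert_allclose(u, fp.plasma_concentration(p, reg, t), rtol=1e-12)


class TestSecondaryParameters:
    def test_published_vss_and_mrt(self, typical):
        sec = fp.secondary_parameters(typical)
        assert np.isclose(sec.Vss, 161.58, atol=1e-9)
        assert round(sec.Vss, 1) == 161.6
        assert round(sec.MRT, 1) == 3.4

    def test_half_life_ordering(self, typical):
        sec = fp.secondary_parameters(typical)
        assert sec.t_half_alpha < sec.t_half_beta < sec.t_half_gamma


class TestPopulationSampling:
    def test_zero_omega_returns_typicals(self, published_pop):
        pop = published_pop.copy()
        pop.omega = np.zeros((7, 7))
        drawn = fp.sample_individual(pop, np.random.default_rng(0))
        np.testing.assert_allclose(drawn.as_array(), pop.theta, rtol=1e-12)

    def test_same_seed_same_draw(self, published_pop):
        a = fp.sample_individual(published_pop, np.random.default_rng(7))
        b = fp.sample_individual(published_pop, np.random.default_rng(7))
        assert a == b

    def test_lognormal_moments_match_published_bsv(self, published_pop):
        """50k draws: median Cl near tvCl, CV of Cl near the published 29.8%,
        and the Cl-Rss random-effect correlation near the published 0.626."""
        etas = sample_etas(published_pop, 50_000, np.random.default_rng(123))
        cl = published_pop.theta[3] * np.exp(etas[:, 3])
        assert abs(np.median(cl) / published_pop.theta[3] - 1.0) < 0.01
        cv = 100.0 * np.std(cl) / np.mean(cl)
        assert abs(cv - 29.8) < 2.0
        corr = np.corrcoef(etas[:, 3], etas[:, 6])[0, 1]
        assert abs(corr - 0.626) < 0.02

    def test_non_psd_omega_is_projected(self, published_pop):
        pop = published_pop.copy()
        pop.omega = pop.omega.copy()
        pop.omega[0, 1] = pop.omega[1, 0] = 10.0  # breaks PSD
        drawn = fp.sample_individual(pop, np.random.default_rng(3))
        assert np.all(drawn.as_array() > 0)


class TestResidualError:
    def test_noise_free_limit(self, published_pop):
        pop = published_pop.copy()
        pop.sigma_plasma_prop = pop.sigma_plasma_add = 0.0
        assert fp.apply_residual_error(123.4, "plasma", pop, np.random.default_rng(0)) == 123.4

    def test_variance_sum_oracle(self, published_pop):
        """SD of replicated observations at pred=100 matches
        sqrt((100*sigma_prop)^2 + sigma_add^2) ~ 15.0 for plasma."""
        rng = np.random.default_rng(9)
        obs = fp.apply_residual_error(np.full(10_000, 100.0), "plasma", published_pop, rng)
        expected = np.hypot(100 * published_pop.sigma_plasma_prop, published_pop.sigma_plasma_add)
        assert abs(np.std(obs) - expected) / expected < 0.05
        assert np.isclose(expected, 15.0, atol=0.01)

    def test_zero_prediction_clamped_additive_noise(self, published_pop):
        rng = np.random.default_rng(4)
        obs = fp.apply_residual_error(np.zeros(2000), "plasma", published_pop, rng)
        assert np.all(obs >= 0)
        assert 0 < np.mean(obs) < published_pop.sigma_plasma_add

    def test_unknown_matrix_rejected(self, published_pop):
        with pytest.raises(ValueError, match="matrix"):
            fp.apply_residual_error(1.0, "saliva", published_pop, np.random.default_rng(0))


def test_cv_percent_reproduces_published_bsv_row(published_pop):
    """CV% = 100*sqrt(exp(w2)-1) maps the published variance terms to the
    published BSV row (29.8% for clearance, 99.0% for the urine ratio)."""
    assert round(float(bsv_cv_percent(0.085)), 1) == 29.8
    assert round(float(bsv_cv_percent(0.683)), 1) == 99.0
    assert round(float(bsv_cv_percent(0.303)), 1) == 59.5
    assert round(float(bsv_cv_percent(0.335)), 1) == 63.1
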