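"""Curve evaluation, medians, maximum-likelihood fitting and selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from lifelines import LogLogisticFitter, WeibullFitter
from scipy import optimize

from psmcea.survival import (
    FAMILIES,
    FitDiagnostics,
    FitError,
    ParametricSurvival,
    PseudoIPD,
    fit_all_families,
    fit_parametric,
    median_survival,
    select_best,
    selection_report,
    survival_at,
)

SAMPLE_MODELS = [
    ParametricSurvival("exponential", 0.1),
    ParametricSurvival("weibull", 0.0345, 1.51337),
    ParametricSurvival("weibull", 0.072, 1.3696),
    ParametricSurvival("loglogistic", 15.224, 2.826),
    ParametricSurvival("loglogistic", 12.534, 2.933),
    ParametricSurvival("lognormal", 10.0, 0.8),
    ParametricSurvival("gamma", 4.0, 2.5),
    ParametricSurvival("gompertz", 0.05, 0.08),
]


class TestEvaluation:
    def test_loglogistic_scale_is_median(self):
        m = ParametricSurvival("loglogistic", 15.224, 2.826)
        assert survival_at(m, 15.224) == pytest.approx(0.5, abs=1e-12)

    def test_survival_starts_at_one(self):
        for m in SAMPLE_MODELS:
            assert survival_at(m, 0.0) == pytest.approx(1.0, abs=1e-12)

    def test_weibull_median_matches_root_finding_oracle(self):
        m = ParametricSurvival("weibull", 0.072, 1.3696)
        closed_form = (math.log(2) / 0.072) ** (1 / 1.3696)
        oracle = optimize.brentq(lambda t: survival_at(m, t) - 0.5, 1e-9, 100.0)
        assert survival_at(m, closed_form) == pytest.approx(0.5, abs=1e-10)
        assert oracle == pytest.approx(closed_form, abs=1e-7)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            SAMPLE_MODELS[0].sf(-1.0)

    @pytest.mark.parametrize("scale,shape", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -2.0)])
    def test_nonpositive_parameters_rejected(self, scale, shape):
        with pytest.raises(ValueError):
            ParametricSurvival("weibull", scale, shape)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ParametricSurvival("spline", 1.0, 1.0)

    @given(
        family=st.sampled_from(FAMILIES),
        log_scale=st.floats(-3.0, 3.0),
        shape=st.floats(0.3, 4.0),
        t=st.lists(st.floats(0.0, 200.0), min_size=2, max_size=20),
    )
    @settings(max_examples=80, deadline=None)
    def test_survival_is_a_proper_nonincreasing_probability(
        self, family, log_scale, shape, t
    ):
        scale = math.exp(log_scale)
        if family == "weibull":
            scale = min(scale, 2.0)  # keep exp(-scale*t^shape) numerically sane
        m = ParametricSurvival(family, scale, shape)
        tt = np.sort(np.asarray(t))
        s = m.sf(tt)
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-12)

    @pytest.mark.parametrize("model", SAMPLE_MODELS, ids=lambda m: m.family + str(m.scale))
    def test_median_inverts_survival(self, model):
        med = median_survival(model)
        assert abs(survival_at(model, med) - 0.5) < 1e-6

    def test_exponential_median_closed_form(self):
        m = ParametricSurvival("exponential", 0.2)
        assert median_survival(m) == pytest.approx(math.log(2) / 0.2, rel=1e-12)


class TestFitting:
    def test_exponential_mle_is_events_over_total_time(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(1 / 0.15, size=500)
        censor = np.full_like(t, 12.0)
        obs = np.minimum(t, censor)
        event = (t <= censor).astype(int)
        model, diag = fit_parametric(PseudoIPD(obs, event), "exponential")
        assert model.scale == pytest.approx(event.sum() / obs.sum(), rel=1e-4)
        assert diag.k == 1

    def test_aic_bic_identities(self):
        diag = FitDiagnostics(loglik=-123.4, n=200, k=2)
        assert diag.aic == pytest.approx(2 * 2 - 2 * -123.4)
        assert diag.bic == pytest.approx(2 * math.log(200) - 2 * -123.4)

    def test_weibull_parameter_recovery_within_10pct(self):
        true = ParametricSurvival("weibull", 0.0345, 1.51337)
        t = true.rvs(2000, np.random.default_rng(7))
        model, _ = fit_parametric(PseudoIPD(t, np.ones(2000, int)), "weibull")
        assert model.scale == pytest.approx(0.0345, rel=0.10)
        assert model.shape == pytest.approx(1.51337, rel=0.10)

    def test_loglogistic_median_recovery_within_5pct(self):
        true = ParametricSurvival("loglogistic", 12.534, 2.933)
        t = true.rvs(2000, np.random.default_rng(13))
        model, _ = fit_parametric(PseudoIPD(t, np.ones(2000, int)), "loglogistic")
        assert model.median() == pytest.approx(12.534, rel=0.05)

    def test_bias_shrinks_with_sample_size(self):
        true = ParametricSurvival("weibull", 0.0345, 1.51337)
        errs = {}
        for n in (200, 2000):
            rel = []
            for seed in range(5):
                t = true.rvs(n, np.random.default_rng(100 + seed))
                m, _ = fit_parametric(PseudoIPD(t, np.ones(n, int)), "weibull")
                rel.append(abs(m.median() - true.median()) / true.median())
            errs[n] = np.mean(rel)
        assert errs[2000] < errs[200]

    def test_matches_lifelines_weibull_fit(self):
        # independent route: lifelines' Weibull MLE on the same censored data
        true = ParametricSurvival("weibull", 0.05, 1.4)
        rng = np.random.default_rng(3)
        t = true.rvs(800, rng)
        censor = rng.uniform(5, 40, size=800)
        obs, event = np.minimum(t, censor), (t <= censor).astype(int)
        ours, diag = fit_parametric(PseudoIPD(obs, event), "weibull")
        wf = WeibullFitter().fit(obs, event)
        # lifelines: S(t) = exp(-(t/lambda_)^rho_)  ->  rate scale = lambda_^-rho_
        assert ours.shape == pytest.approx(wf.rho_, rel=1e-3)
        assert ours.scale == pytest.approx(wf.lambda_**-wf.rho_, rel=1e-2)
        assert diag.loglik == pytest.approx(wf.log_likelihood_, abs=1e-3)

    def test_matches_lifelines_loglogistic_fit(self):
        true = ParametricSurvival("loglogistic", 12.0, 2.5)
        t = true.rvs(800, np.random.default_rng(5))
        ours, _ = fit_parametric(PseudoIPD(t, np.ones(800, int)), "loglogistic")
        llf = LogLogisticFitter().fit(t, np.ones(800))
        assert ours.scale == pytest.approx(llf.alpha_, rel=1e-3)
        assert ours.shape == pytest.approx(llf.beta_, rel=1e-3)

    def test_all_censored_is_an_error(self):
        with pytest.raises(FitError):
            fit_parametric(PseudoIPD([1.0, 2.0], [0, 0]), "weibull")


class TestSelection:
    def _fit(self, family, aic_target, n=100, k=2):
        model = ParametricSurvival(family, 1.0, 1.0)
        loglik = (2 * k - aic_target) / 2
        return model, FitDiagnostics(loglik=loglik, n=n, k=k, family=family)

    def test_minimum_aic_wins(self):
        a = self._fit("weibull", 100.0)
        b = self._fit("gamma", 110.0)
        assert select_best([b, a]).family == "weibull"

    def test_aic_tie_broken_by_bic(self):
        # equal log-likelihood and k, smaller n -> smaller BIC wins the tie
        a = (ParametricSurvival("loglogistic", 1, 1),
             FitDiagnostics(loglik=-48.0, n=50, k=2, family="loglogistic"))
        b = (ParametricSurvival("gamma", 1, 1),
             FitDiagnostics(loglik=-48.0, n=5000, k=2, family="gamma"))
        assert select_best([b, a]).family == "loglogistic"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([])

    def test_report_lists_every_candidate(self):
        true = ParametricSurvival("weibull", 0.06, 1.5)
        t = true.rvs(300, np.random.default_rng(2))
        fits = fit_all_families(PseudoIPD(t, np.ones(300, int)))
        report = selection_report(fits)
        assert set(report["family"]) == set(f[0].family for f in fits)
        assert (report["aic"].diff().dropna() >= 0).all()

    def test_true_family_selected_in_most_replicates(self):
        # six-family fit on Weibull data should recover Weibull >= 80% of runs
        true = ParametricSurvival("weibull", 0.0345, 1.51337)
        hits = 0
        n_rep = 50
        for seed in range(n_rep):
            t = true.rvs(500, np.random.default_rng(1000 + seed))
            best = select_best(fit_all_families(PseudoIPD(t, np.ones(500, int))))
            hits += best.family == "weibull"
        assert hits / n_rep >= 0.8
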