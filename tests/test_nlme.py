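"""SAEM estimation against degenerate limits and brute-force oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from dalbapk import (
    REFERENCE_MODEL,
    IndividualParams,
    Observation,
    PopModel,
    StudyDesign,
    Subject,
    empirical_bayes,
    fit_saem,
    generate_pk_dataset,
    initial_estimates,
    log_likelihood,
    rse,
    select_structural_model,
    shrinkage,
    concentration_at,
)
from dalbapk.nlme import SaemSettings, _rank_candidates
from dalbapk.structural_pk import ONE_COMPARTMENT, TWO_COMPARTMENT, conc_profile_1cpt

from conftest import STANDARD_DOSE, make_rich_subject, simulate_cohort_rich

DOSE = STANDARD_DOSE


# ---------------------------------------------------------------------------
# Toy problem shared by the grid and quadrature oracles
# ---------------------------------------------------------------------------

TOY_OMEGA = 0.15


def make_toy_two_subjects():
    rng = np.random.default_rng(42)
    schedules = [np.array([24.0, 240.0, 500.0]), np.array([48.0, 300.0, 620.0])]
    subs = []
    for i, t_obs in enumerate(schedules):
        ev, ec = rng.standard_normal(2) * TOY_OMEGA
        p = IndividualParams(V=17.9 * math.exp(ev), CL=0.036 * math.exp(ec))
        f = np.array([concentration_at(p, [DOSE], t) for t in t_obs])
        y = f * (1 + 0.1 * rng.standard_normal(len(t_obs)))
        subs.append(Subject(id=f"S{i}", doses=[DOSE],
                            observations=[Observation(float(t), float(c)) for t, c in zip(t_obs, y)]))
    return subs


def gh_marginal_loglik(subjects, V, CL, b_arr, omega=TOY_OMEGA, nodes=20):
    """Adaptive-free Gauss-Hermite marginal log-likelihood oracle, vectorised
    over an array of residual-error magnitudes."""
    gh_x, gh_w = np.polynomial.hermite.hermgauss(nodes)
    b_arr = np.atleast_1d(np.asarray(b_arr, dtype=float))
    tot = np.zeros(len(b_arr))
    w2 = np.outer(gh_w, gh_w).ravel() / math.pi
    for s in subjects:
        t_obs = np.array([o.time for o in s.observations])
        y = np.array([o.concentration for o in s.observations])
        Vi = (V * np.exp(math.sqrt(2) * omega * gh_x))[:, None]
        Ci = (CL * np.exp(math.sqrt(2) * omega * gh_x))[None, :]
        f = conc_profile_1cpt(Vi[..., None], Ci[..., None], np.array([DOSE.rate]),
                              np.array([0.0]), np.array([0.5]), t_obs[None, None, :])
        f = np.maximum(f.reshape(-1, len(t_obs)), 1e-12)           # (400, T)
        r2 = ((y - f) / f) ** 2                                     # (400, T)
        logf = np.log(f).sum(axis=1)
        T = len(t_obs)
        # conditional loglik for each b: -T log b - logf - 0.5 r2/b^2 + const
        ll = (-r2.sum(axis=1)[None, :] / (2 * b_arr[:, None] ** 2)
              - logf[None, :] - T * np.log(b_arr)[:, None]
              - 0.5 * T * math.log(2 * math.pi))
        m = ll.max(axis=1, keepdims=True)
        tot += (m[:, 0] + np.log((w2[None, :] * np.exp(ll - m)).sum(axis=1)))
    return tot if tot.size > 1 else float(tot[0])


class TestFitSaem:
    def test_degenerates_to_individual_curve_fit(self):
        """With one richly-sampled subject, no IIV and negligible noise, the
        population fit must equal an independent nonlinear least-squares fit."""
        subj = make_rich_subject(IndividualParams(17.9, 0.036), b=1e-6, seed=5)
        fit = fit_saem([subj], PopModel(10, 0.02, 0.3, 0.3, 0.2),
                       fixed_omega={"V": 0.0, "CL": 0.0}, seed=1, compute_ofv=None)
        ts = np.array([o.time for o in subj.observations])
        ys = np.array([o.concentration for o in subj.observations])

        def f_model(t, V, CL):
            return np.array([concentration_at(IndividualParams(V, CL), [DOSE], x) for x in t])

        popt, _ = curve_fit(f_model, ts, ys, p0=[10.0, 0.02])
        assert fit.theta["V"] == pytest.approx(popt[0], rel=5e-3)
        assert fit.theta["CL"] == pytest.approx(popt[1], rel=5e-3)

    def test_matches_grid_search_ml_oracle_on_toy(self):
        """SAEM estimates on a 2-subject toy (omegas fixed) must land within
        one cell of an exhaustive 50^3 likelihood grid over (V, CL, b)."""
        subs = make_toy_two_subjects()
        Vg = np.linspace(12, 26, 50)
        Cg = np.linspace(0.02, 0.06, 50)
        Bg = np.linspace(0.02, 0.4, 50)
        best = (-np.inf, None)
        for V in Vg:
            for CL in Cg:
                ll = gh_marginal_loglik(subs, V, CL, Bg)
                j = int(np.argmax(ll))
                if ll[j] > best[0]:
                    best = (ll[j], (V, CL, Bg[j]))
        v_star, cl_star, b_star = best[1]
        fit = fit_saem(subs, PopModel(15, 0.03, TOY_OMEGA, TOY_OMEGA, 0.2),
                       fixed_omega={"V": TOY_OMEGA, "CL": TOY_OMEGA}, seed=3,
                       settings=SaemSettings(n_exploration=600, n_smoothing=400),
                       compute_ofv=None)
        assert abs(fit.theta["V"] - v_star) <= (Vg[1] - Vg[0])
        assert abs(fit.theta["CL"] - cl_star) <= (Cg[1] - Cg[0])
        assert abs(fit.b - b_star) <= (Bg[1] - Bg[0])

    def test_seeded_fit_is_bit_reproducible(self, study_dataset):
        init = initial_estimates(study_dataset)
        f1 = fit_saem(study_dataset, init, seed=11, compute_ofv=None)
        f2 = fit_saem(study_dataset, init, seed=11, compute_ofv=None)
        assert f1.theta == f2.theta
        assert f1.omega == f2.omega
        assert f1.b == f2.b

    def test_trace_stabilises(self, study_fit):
        assert study_fit.converged
        assert study_fit.convergence_trace.shape[1] == 5

    def test_empty_dataset_refused(self):
        with pytest.raises(ValueError):
            fit_saem([], PopModel(15, 0.03, 0.3, 0.3, 0.2))


class TestLogLikelihood:
    def test_no_random_effects_matches_closed_form(self):
        """With omega = 0 the marginal equals the conditional likelihood of
        the pooled fixed-effects model, known in closed form."""
        subj = make_rich_subject(IndividualParams(17.9, 0.036), b=0.1, seed=6, n_obs=12)
        fit = fit_saem([subj], PopModel(15, 0.03, 0.3, 0.3, 0.2),
                       fixed_omega={"V": 0.0, "CL": 0.0}, seed=1, compute_ofv=None)
        p = IndividualParams(fit.theta["V"], fit.theta["CL"])
        ts = np.array([o.time for o in subj.observations])
        ys = np.array([o.concentration for o in subj.observations])
        f = np.array([concentration_at(p, [DOSE], t) for t in ts])
        sd = fit.b * f
        ll = float(np.sum(-0.5 * ((ys - f) / sd) ** 2 - np.log(sd) - 0.5 * math.log(2 * math.pi)))
        lik = log_likelihood(fit, [subj], n_is_samples=2000, seed=2)
        assert lik.ofv == pytest.approx(-2 * ll, abs=0.05)

    def test_matches_quadrature_oracle_on_toy(self):
        subs = make_toy_two_subjects()
        fit = fit_saem(subs, PopModel(15, 0.03, TOY_OMEGA, TOY_OMEGA, 0.2),
                       fixed_omega={"V": TOY_OMEGA, "CL": TOY_OMEGA}, seed=3,
                       compute_ofv=None)
        oracle = -2.0 * gh_marginal_loglik(subs, fit.theta["V"], fit.theta["CL"],
                                           fit.b)
        lik = log_likelihood(fit, subs, n_is_samples=4000, seed=17)
        assert abs(lik.ofv - oracle) <= max(3.0 * lik.mc_se, 0.05)

    def test_information_criteria_penalise_extra_parameters(self):
        """AIC ordering on nested toy models agrees with the quadrature
        oracle: the richer 2-compartment model cannot beat the generating
        1-compartment model by more than its parameter penalty."""
        subs = make_toy_two_subjects()
        f1 = fit_saem(subs, PopModel(15, 0.03, TOY_OMEGA, TOY_OMEGA, 0.2),
                      fixed_omega={"V": TOY_OMEGA, "CL": TOY_OMEGA}, seed=3,
                      compute_ofv="is")
        assert f1.aic == pytest.approx(f1.ofv + 2 * 3)   # V, CL, b estimated
        assert f1.bicc >= f1.ofv


class TestEmpiricalBayes:
    def test_no_observations_returns_prior_mode(self, study_fit):
        ghost = Subject(id="ghost", doses=[DOSE], observations=[])
        eta = empirical_bayes(study_fit, ghost)
        np.testing.assert_allclose(eta, 0.0, atol=1e-8)

    def test_rich_subject_ebe_matches_curve_fit(self):
        """As residual noise vanishes with dense data, the conditional mode
        recovers the subject's own parameters."""
        truth = IndividualParams(V=22.0, CL=0.03)
        subj = make_rich_subject(truth, b=1e-6, seed=9)
        model = PopModel(17.9, 0.036, 0.25, 0.25, 0.01)
        fit = fit_saem([subj], model, seed=2, compute_ofv=None,
                       settings=SaemSettings(n_exploration=200, n_smoothing=100))
        eta = empirical_bayes(fit, subj)
        v_hat = fit.theta["V"] * math.exp(eta[0])
        cl_hat = fit.theta["CL"] * math.exp(eta[1])
        assert v_hat == pytest.approx(truth.V, rel=1e-3)
        assert cl_hat == pytest.approx(truth.CL, rel=1e-3)

    def test_ebe_tracks_true_clearance_random_effects(self):
        """EBE eta_CL must correlate with the generating eta_CL at the sparse
        study design (attenuated by shrinkage, hence well below 1)."""
        est, tru = [], []
        for s in (1, 2, 3, 4, 5):
            ds, pars = generate_pk_dataset(StudyDesign(), REFERENCE_MODEL, seed=s,
                                           return_params=True)
            f = fit_saem(ds, initial_estimates(ds), seed=7, compute_ofv=None)
            est.append(f.ebe)
            tru.append(pars[["eta_V", "eta_CL"]].values)
        est = np.vstack(est)
        tru = np.vstack(tru)
        r_cl = np.corrcoef(est[:, 1], tru[:, 1])[0, 1]
        assert r_cl > 0.6


class TestShrinkage:
    def test_all_subjects_data_free_gives_full_shrinkage(self, study_fit):
        ghosts = [Subject(id=f"g{i}", doses=[DOSE], observations=[]) for i in range(8)]
        ebe = np.stack([empirical_bayes(study_fit, g) for g in ghosts])
        from dalbapk.nlme import _shrinkage_from_ebe
        shr = _shrinkage_from_ebe(ebe, study_fit.omega, study_fit.param_names)
        assert shr["V"] == pytest.approx(100.0)
        assert shr["CL"] == pytest.approx(100.0)

    def test_rich_sampling_drives_shrinkage_to_zero(self):
        ds = simulate_cohort_rich(40, REFERENCE_MODEL,
                                  times=[12, 96, 240, 400, 560, 700], seed=3)
        fit = fit_saem(ds, PopModel(15, 0.03, 0.3, 0.3, 0.2), seed=5, compute_ofv=None)
        shr = shrinkage(fit)
        assert shr["V"] < 30.0
        assert shr["CL"] < 30.0

    def test_sparse_design_shrinkage_is_substantial_but_partial(self, study_fit):
        """1-3 troughs per subject leave the EBEs heavily but not totally
        shrunk toward zero."""
        shr = shrinkage(study_fit)
        for p in ("V", "CL"):
            assert 0.0 < shr[p] < 90.0


class TestRse:
    def test_rich_no_iiv_limit_matches_least_squares_se(self):
        """omega = 0 with dense data is a nonlinear regression; the Louis
        information collapses to the least-squares covariance."""
        subj = make_rich_subject(IndividualParams(17.9, 0.036), b=0.05, seed=4, n_obs=60)
        fit = fit_saem([subj], PopModel(15, 0.03, 0.3, 0.3, 0.2),
                       fixed_omega={"V": 0.0, "CL": 0.0}, seed=1, compute_ofv=None)
        got = rse(fit, [subj], method="louis", seed=2)

        ts = np.array([o.time for o in subj.observations])
        ys = np.array([o.concentration for o in subj.observations])

        def f_model(t, V, CL):
            return np.array([concentration_at(IndividualParams(V, CL), [DOSE], x) for x in t])

        popt, pcov = curve_fit(f_model, ts, ys, p0=[15, 0.03],
                               sigma=fit.b * f_model(ts, fit.theta["V"], fit.theta["CL"]),
                               absolute_sigma=True)
        ls_rse_v = 100 * math.sqrt(pcov[0, 0]) / popt[0]
        ls_rse_cl = 100 * math.sqrt(pcov[1, 1]) / popt[1]
        assert got["V_pop"] == pytest.approx(ls_rse_v, rel=0.35)
        assert got["CL_pop"] == pytest.approx(ls_rse_cl, rel=0.35)

    def test_study_design_fixed_effects_well_identified(self, study_fit, study_dataset):
        got = rse(study_fit, study_dataset, method="louis", seed=3)
        assert got["V_pop"] < 25.0
        assert got["CL_pop"] < 25.0

    def test_doubling_cohort_shrinks_rse(self):
        ds18 = generate_pk_dataset(StudyDesign(), REFERENCE_MODEL, seed=11)
        ds36 = generate_pk_dataset(StudyDesign(n_subjects=36), REFERENCE_MODEL, seed=11)
        f18 = fit_saem(ds18, initial_estimates(ds18), seed=7, compute_ofv=None)
        f36 = fit_saem(ds36, initial_estimates(ds36), seed=7, compute_ofv=None)
        r18 = rse(f18, ds18, seed=3)
        r36 = rse(f36, ds36, seed=3)
        for key in ("V_pop", "CL_pop"):
            ratio = r36[key] / r18[key]
            assert 0.5 < ratio < 0.95  # ~1/sqrt(2) with sampling noise

    def test_linearized_fallback_agrees_roughly_with_louis(self, study_fit, study_dataset):
        louis = rse(study_fit, study_dataset, method="louis", seed=3)
        lin = rse(study_fit, study_dataset, method="linearized")
        for key in ("V_pop", "CL_pop"):
            assert lin[key] == pytest.approx(louis[key], rel=0.6, abs=3.0)


class TestModelSelection:
    def test_one_compartment_preferred_on_one_compartment_data(self, study_dataset):
        ranked = select_structural_model(
            study_dataset, seed=5,
            settings=SaemSettings(n_exploration=300, n_smoothing=150))
        top = ranked[ranked["rank"] == 1].iloc[0]
        assert top["model"] == "one_compartment"

    def test_two_compartment_preferred_on_pronounced_two_compartment_data(self):
        rng = np.random.default_rng(8)
        theta = np.array([10.0, 0.05, 0.3, 25.0])
        t_obs = np.array([0.5, 1, 2, 4, 8, 24, 48, 96, 168, 240, 336, 504], dtype=float)
        subs = []
        for i in range(12):
            th = theta * np.exp(rng.standard_normal(4) * np.array([0.15, 0.2, 0.1, 0.1]))
            f = TWO_COMPARTMENT.predict(th, np.array([DOSE.rate]), np.array([0.0]),
                                        np.array([0.5]), t_obs)
            y = f * (1 + 0.08 * rng.standard_normal(len(t_obs)))
            subs.append(Subject(id=f"T{i}", doses=[DOSE],
                                observations=[Observation(float(t), float(max(c, 0.01)))
                                              for t, c in zip(t_obs, y)]))
        ranked = select_structural_model(
            subs, seed=5, settings=SaemSettings(n_exploration=300, n_smoothing=150))
        top = ranked[ranked["rank"] == 1].iloc[0]
        assert top["model"] == "two_compartment"

    def test_exact_ties_broken_by_parsimony(self):
        df = pd.DataFrame([
            {"model": "rich", "excluded": False, "reason": "", "ofv": 100.0,
             "aic": 110.0, "bicc": 120.0, "n_parameters": 9},
            {"model": "lean", "excluded": False, "reason": "", "ofv": 100.0,
             "aic": 110.0, "bicc": 120.0, "n_parameters": 5},
            {"model": "broken", "excluded": True, "reason": "diverged"},
        ])
        ranked = _rank_candidates(df)
        assert ranked.iloc[0]["model"] == "lean"
        assert ranked.iloc[0]["rank"] == 1
        assert pd.isna(ranked[ranked["model"] == "broken"]["rank"]).all()

    def test_requires_two_candidates(self, study_dataset):
        with pytest.raises(ValueError):
            select_structural_model(study_dataset, candidates=(ONE_COMPARTMENT,))
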