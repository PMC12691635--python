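"""Bootstrap, NPDE and pc-VPC diagnostics: calibration and degenerate limits."""

import copy
import math

import numpy as np
import pytest
from scipy import stats

from dalbapk import (
    REFERENCE_MODEL,
    IndividualParams,
    Observation,
    PopModel,
    StudyDesign,
    Subject,
    bootstrap,
    fit_saem,
    generate_pk_dataset,
    gof_table,
    npde,
    pc_vpc,
    concentration_at,
)
from dalbapk.diagnostics import _simulate_replicates
from dalbapk.nlme import SaemSettings

from conftest import STANDARD_DOSE as DOSE, make_rich_subject, simulate_cohort_rich


class TestBootstrap:
    def test_smoke_run_orders_ci_bounds(self, study_dataset, study_fit):
        res = bootstrap(study_dataset, study_fit.estimates, n_resamples=4, seed=1)
        assert res.n_resamples == 4
        assert res.n_converged <= 4
        assert (res.summary["ci_lower"] <= res.summary["median"]).all()
        assert (res.summary["median"] <= res.summary["ci_upper"]).all()

    def test_identical_subjects_collapse_the_ci(self):
        """A cohort of copies of one subject has no sampling variability, so
        the bootstrap distribution degenerates onto the point estimate."""
        proto = make_rich_subject(IndividualParams(17.9, 0.036), b=0.05, seed=2, n_obs=6)
        cohort = [
            Subject(id=f"C{i}", doses=list(proto.doses), observations=list(proto.observations))
            for i in range(12)
        ]
        fit = fit_saem(cohort, PopModel(15, 0.03, 0.2, 0.2, 0.2), seed=3, compute_ofv=None)
        res = bootstrap(cohort, fit.estimates, n_resamples=30, seed=4)
        for p in ("V_pop", "CL_pop"):
            width = res.summary.loc[p, "ci_upper"] - res.summary.loc[p, "ci_lower"]
            assert width / res.summary.loc[p, "median"] < 0.05
            assert res.summary.loc[p, "median"] == pytest.approx(
                fit.theta[p.split("_")[0]], rel=0.05)

    def test_seeded_bootstrap_is_reproducible(self, study_dataset, study_fit):
        r1 = bootstrap(study_dataset, study_fit.estimates, n_resamples=10, seed=9)
        r2 = bootstrap(study_dataset, study_fit.estimates, n_resamples=10, seed=9)
        assert r1.summary.equals(r2.summary)

    def test_ci_percentiles_are_type7(self, study_dataset, study_fit):
        res = bootstrap(study_dataset, study_fit.estimates, n_resamples=25, seed=5)
        v = res.estimates["V_pop"].to_numpy()
        assert res.summary.loc["V_pop", "ci_lower"] == pytest.approx(
            np.quantile(v, 0.025), rel=1e-12)  # numpy default = type 7


class TestNpde:
    def test_scalar_case_equals_inverse_normal_rank(self):
        """With one observation per subject no decorrelation is needed and the
        npde must equal the inverse normal of the simple rank statistic."""
        rng = np.random.default_rng(3)
        subs = []
        for i in range(6):
            t = float(rng.uniform(200, 600))
            p = IndividualParams(
                V=REFERENCE_MODEL.V_pop * math.exp(0.2 * rng.standard_normal()),
                CL=REFERENCE_MODEL.CL_pop * math.exp(0.29 * rng.standard_normal()),
            )
            c = concentration_at(p, [DOSE], t) * (1 + 0.12 * rng.standard_normal())
            subs.append(Subject(id=f"N{i}", doses=[DOSE],
                                observations=[Observation(t, float(c))]))
        K = 500
        res = npde(subs, REFERENCE_MODEL, K=K, seed=7)
        sims = _simulate_replicates(subs, REFERENCE_MODEL, K, np.random.default_rng(7))
        for row, sim in zip(res.table.itertuples(), sims):
            y = row.observed
            less = np.sum(sim[:, 0] - sim.mean(axis=0)[0] < y - sim.mean(axis=0)[0])
            expected = stats.norm.ppf((less + 0.5) / (K + 1))
            assert row.npde == pytest.approx(expected, abs=1e-9)

    def test_refuses_insufficient_replicates(self, study_dataset):
        with pytest.raises(ValueError):
            npde(study_dataset, REFERENCE_MODEL, K=50)

    def test_gross_clearance_misfit_is_detected(self):
        """Doubling CL in the simulation model shifts predictions down, so the
        mean-zero test must reject."""
        wrong = PopModel(REFERENCE_MODEL.V_pop, 2 * REFERENCE_MODEL.CL_pop,
                         REFERENCE_MODEL.omega_V, REFERENCE_MODEL.omega_CL,
                         REFERENCE_MODEL.b)
        rejections = 0
        for s in range(5):
            ds = generate_pk_dataset(StudyDesign(), REFERENCE_MODEL, seed=300 + s)
            res = npde(ds, wrong, K=1000, seed=400 + s)
            rejections += res.p_mean < 0.05
        assert rejections >= 4

    def test_self_simulated_data_passes_normality_most_of_the_time(self):
        ok = 0
        for s in range(20):
            ds = generate_pk_dataset(StudyDesign(), REFERENCE_MODEL, seed=500 + s)
            res = npde(ds, REFERENCE_MODEL, K=1000, seed=600 + s)
            ok += res.p_normality > 0.05
        assert ok >= 17  # Shapiro-Wilk passes in >= 85% of replicates


class TestPcVpc:
    def test_identical_predictions_make_correction_identity(self):
        """When every subject shares the design and parameters, all population
        predictions in a bin are equal and prediction correction is a no-op."""
        rng = np.random.default_rng(5)
        subs = []
        for i in range(10):
            ts = [250.0, 550.0]
            obs = [Observation(t, float(concentration_at(REFERENCE_MODEL.typical(), [DOSE], t)
                                        * (1 + 0.1 * rng.standard_normal()))) for t in ts]
            subs.append(Subject(id=f"P{i}", doses=[DOSE], observations=obs))
        res = pc_vpc(subs, REFERENCE_MODEL, n_sim=100, bins=[0, 400, 800], seed=6)
        raw = {t: [] for t in (250.0, 550.0)}
        for s in subs:
            for o in s.observations:
                raw[o.time].append(o.concentration)
        med_row = res.table[(res.table.percentile == 50.0) & (res.table.bin_left == 0)]
        assert float(med_row["observed"].iloc[0]) == pytest.approx(np.median(raw[250.0]))

    def test_weekly_bins_on_study_design(self, study_dataset):
        edges = [7 * 24.0 * k for k in (1, 2, 3, 4)] + [30 * 24.0]
        res = pc_vpc(study_dataset, REFERENCE_MODEL, n_sim=100, bins=edges, seed=7)
        assert len(res.bin_edges) - 1 + len(res.merged_bins) == 4
        assert set(res.table.percentile) == {10.0, 50.0, 90.0}

    def test_bands_are_nested(self, study_dataset):
        res = pc_vpc(study_dataset, REFERENCE_MODEL, n_sim=200, seed=8)
        assert (res.table["sim_lower"] <= res.table["sim_upper"]).all()

    def test_self_simulated_coverage(self):
        """Observed pc-percentiles should mostly fall inside the simulated 90%
        bands when the data come from the model itself."""
        covs = []
        for s in range(5):
            ds = generate_pk_dataset(StudyDesign(), REFERENCE_MODEL, seed=700 + s)
            res = pc_vpc(ds, REFERENCE_MODEL, n_sim=300, seed=800 + s)
            covs.append(res.coverage())
        assert np.mean(covs) >= 0.8

    def test_bands_widen_with_residual_error(self, study_dataset):
        lo = PopModel(17.9, 0.036, 0.2, 0.29, 0.05)
        hi = PopModel(17.9, 0.036, 0.2, 0.29, 0.35)
        v_lo = pc_vpc(study_dataset, lo, n_sim=300, seed=2)
        v_hi = pc_vpc(study_dataset, hi, n_sim=300, seed=2)
        w_lo = (v_lo.table.sim_upper - v_lo.table.sim_lower).mean()
        w_hi = (v_hi.table.sim_upper - v_hi.table.sim_lower).mean()
        assert w_hi > w_lo


class TestGofTable:
    def test_near_noiseless_rich_data_reproduces_observations(self):
        subj = make_rich_subject(IndividualParams(17.9, 0.036), b=1e-4, seed=5, n_obs=20)
        fit = fit_saem([subj], PopModel(15, 0.03, 0.2, 0.2, 0.2), seed=1, compute_ofv=None)
        g = gof_table(fit, [subj])
        np.testing.assert_allclose(g["ipred"], g["dv"], rtol=0.02)

    def test_zero_observation_subject_absent(self, study_fit, study_dataset):
        ghost = Subject(id="ghost", doses=[DOSE], observations=[])
        ds = list(study_dataset) + [ghost]
        ebe = np.vstack([study_fit.ebe, np.zeros(2)])
        fit = copy.copy(study_fit)
        fit.ebe = ebe
        g = gof_table(fit, ds)
        assert "ghost" not in set(g["subject"])

    def test_iwres_calibrated_on_self_simulated_data(self):
        ds = simulate_cohort_rich(30, REFERENCE_MODEL,
                                  times=[12, 96, 240, 400, 560, 700], seed=3)
        fit = fit_saem(ds, PopModel(15, 0.03, 0.3, 0.3, 0.2), seed=5, compute_ofv=None)
        g = gof_table(fit, ds)
        assert 0.8 <= g["iwres"].std(ddof=1) <= 1.2
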