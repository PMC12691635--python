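"""Model-evaluation diagnostics: bootstrap, NPDE, pc-VPC, goodness of fit.

* Non-parametric bootstrap: subjects are resampled with replacement and the
  model refit on every replicate (all replicates run as one vectorised SAEM
  batch, initialised at the base estimates); per-parameter medians and
  percentile 2.5/97.5% confidence intervals are reported with type-7
  quantiles.  Non-converged replicates are dropped and counted.

* NPDE (normalised prediction distribution errors): each subject's observed
  vector is ranked within K full model simulations (inter-individual plus
  residual variability); ranks are decorrelated with the Cholesky factor of
  the simulated covariance, mapped through the inverse normal, and tested
  globally for mean 0 (t-test), variance 1 (chi-square) and normality
  (Shapiro–Wilk), combined at Bonferroni level.

* pc-VPC (prediction-corrected visual predictive check): observations and
  simulations are rescaled by the ratio of the bin-median population
  prediction to each point's own population prediction, then observed
  10/50/90th percentiles per time bin are compared with simulated 90%
  confidence bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nlme import (
    FitResult,
    SaemSettings,
    Subject,
    _build_arrays,
    _gather,
    _run_saem,
)
from .structural_pk import ONE_COMPARTMENT, PopModel, conc_profile_1cpt

__all__ = [
    "BootstrapResult",
    "VpcBands",
    "bootstrap",
    "npde",
    "pc_vpc",
    "gof_table",
]


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Per-parameter bootstrap medians and percentile 95% CIs."""

    summary: pd.DataFrame       # index parameter; columns median, ci_lower, ci_upper
    estimates: pd.DataFrame     # per-converged-replicate estimates
    n_resamples: int
    n_converged: int
    seed: int
    warnings: tuple = ()

    def __post_init__(self):
        assert self.n_converged <= self.n_resamples


def bootstrap(
    dataset: Sequence[Subject],
    init: PopModel,
    n_resamples: int = 1000,
    seed: int = 0,
    settings: SaemSettings | None = None,
) -> BootstrapResult:
    """Subject-level non-parametric bootstrap of the one-compartment model.

    ``init`` should be the base-fit estimates: replicates are refit from
    there with a reduced iteration budget, which is what keeps 1,000
    replicates tractable (a deviation risk if the likelihood were
    multimodal).  Replicates whose traces drift or whose omegas collapse are
    dropped and counted.
    """
    dataset = list(dataset)
    settings = settings or SaemSettings(n_exploration=150, n_smoothing=75)
    rng = np.random.default_rng(seed)
    S = len(dataset)
    idx = rng.integers(0, S, size=(n_resamples, S))

    arr0 = _build_arrays(dataset)
    arr = _gather(arr0, idx)
    B = n_resamples
    X = np.ones((B, S, 2))
    beta0 = np.tile(np.array([math.log(init.V_pop), math.log(init.CL_pop)]), (B, 1))
    omega0 = np.tile(np.array([init.omega_V, init.omega_CL]), (B, 1))
    b0 = np.full(B, init.b)
    out = _run_saem(arr, ONE_COMPARTMENT, X, [1, 1], beta0, omega0, b0,
                    settings, rng, record_trace=True)

    est = pd.DataFrame({
        "V_pop": np.exp(out["beta"][:, 0]),
        "CL_pop": np.exp(out["beta"][:, 1]),
        "omega_V": out["omega"][:, 0],
        "omega_CL": out["omega"][:, 1],
        "b": out["b"],
    })

    # convergence screen per replicate: drift of the last 20% of smoothing
    trace = out["trace"]  # (iters, B, 5)
    n_last = max(int(0.2 * settings.n_smoothing), 10)
    seg = trace[-n_last:]
    x = np.arange(n_last, dtype=float)
    x -= x.mean()
    denom = float(np.sum(x * x))
    slope = np.einsum("i,ibk->bk", x, seg - seg.mean(axis=0)) / denom
    scale = np.maximum(np.abs(seg.mean(axis=0)), 1e-12)
    drift = np.abs(slope) * n_last / scale
    fixed_ok = np.all(drift[:, :2] < 0.25, axis=1)  # screen on the fixed effects
    collapse = (out["omega"] < 1e-4).any(axis=1)
    ok = fixed_ok & ~collapse

    est_ok = est[ok].reset_index(drop=True)
    n_conv = int(ok.sum())
    warnings = []
    if n_conv < 0.9 * n_resamples:
        warnings.append(
            f"{n_resamples - n_conv}/{n_resamples} bootstrap replicates non-convergent"
        )
    summary = pd.DataFrame({
        "median": est_ok.median(),
        "ci_lower": est_ok.quantile(0.025),
        "ci_upper": est_ok.quantile(0.975),
    })
    return BootstrapResult(summary=summary, estimates=est_ok,
                           n_resamples=n_resamples, n_converged=n_conv,
                           seed=seed, warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# Simulation helper shared by NPDE / VPC
# ---------------------------------------------------------------------------


def _simulate_replicates(dataset, model: PopModel, K: int, rng) -> list:
    """K simulated replicates of each subject's quantifiable observation
    vector (IIV + proportional residual error).  Returns a list of (K, n_i)
    arrays aligned with the dataset order."""
    out = []
    for subj in dataset:
        t = np.array([o.time for o in subj.observations if not o.below_loq])
        rate = np.array([d.rate for d in subj.doses])
        start = np.array([d.start_time for d in subj.doses])
        dur = np.array([d.infusion_duration for d in subj.doses])
        eta = rng.standard_normal((K, 2))
        V = model.V_pop * np.exp(model.omega_V * eta[:, 0])
        CL = model.CL_pop * np.exp(model.omega_CL * eta[:, 1])
        f = conc_profile_1cpt(V[:, None], CL[:, None], rate, start, dur, t[None, :])
        sims = f * (1.0 + model.b * rng.standard_normal((K, len(t))))
        out.append(sims)
    return out


# ---------------------------------------------------------------------------
# NPDE
# ---------------------------------------------------------------------------


@dataclass
class NpdeResult:
    table: pd.DataFrame          # subject, time, observed, npde
    mean: float
    variance: float
    p_mean: float
    p_variance: float
    p_normality: float
    global_p: float              # Bonferroni-combined
    K: int
    seed: int

    @property
    def global_significant(self) -> bool:
        return self.global_p < 0.05


def npde(dataset: Sequence[Subject], model: PopModel, K: int = 1000, seed: int = 0) -> NpdeResult:
    """Normalised prediction distribution errors with per-subject
    decorrelation; refuses K < 100 (rank resolution too coarse)."""
    if K < 100:
        raise ValueError(f"K={K} too small for NPDE; need >= 100")
    dataset = list(dataset)
    rng = np.random.default_rng(seed)
    sims_all = _simulate_replicates(dataset, model, K, rng)
    rows = []
    values = []
    for subj, sims in zip(dataset, sims_all):
        quant = [o for o in subj.observations if not o.below_loq]
        if not quant:
            continue
        y = np.array([o.concentration for o in quant])
        mean = sims.mean(axis=0)
        if len(y) == 1:
            y_dec = (y - mean)
            sims_dec = sims - mean
        else:
            cov = np.cov(sims, rowvar=False)
            cov = cov + 1e-10 * np.eye(len(y))
            L = np.linalg.cholesky(cov)
            y_dec = np.linalg.solve(L, y - mean)
            sims_dec = np.linalg.solve(L, (sims - mean).T).T
        # rank statistic with half-rank ties -> inverse normal
        for j, obs in enumerate(quant):
            less = np.sum(sims_dec[:, j] < y_dec[j])
            ties = np.sum(sims_dec[:, j] == y_dec[j])
            u = (less + 0.5 * ties + 0.5) / (K + 1)
            val = float(stats.norm.ppf(u))
            values.append(val)
            rows.append({"subject": subj.id, "time": obs.time,
                         "observed": obs.concentration, "npde": val})
    v = np.asarray(values)
    t_stat, p_mean = stats.ttest_1samp(v, 0.0)
    n = len(v)
    chi = (n - 1) * np.var(v, ddof=1)
    p_var = 2.0 * min(stats.chi2.cdf(chi, n - 1), stats.chi2.sf(chi, n - 1))
    p_norm = float(stats.shapiro(v).pvalue)
    global_p = min(3.0 * min(p_mean, p_var, p_norm), 1.0)
    return NpdeResult(table=pd.DataFrame(rows), mean=float(v.mean()),
                      variance=float(np.var(v, ddof=1)), p_mean=float(p_mean),
                      p_variance=float(p_var), p_normality=p_norm,
                      global_p=float(global_p), K=K, seed=seed)


# ---------------------------------------------------------------------------
# pc-VPC
# ---------------------------------------------------------------------------


@dataclass
class VpcBands:
    """Observed prediction-corrected percentiles per bin with simulated CIs."""

    table: pd.DataFrame   # bin_left, bin_right, n_obs, percentile, observed, sim_lower, sim_upper
    bin_edges: tuple
    n_sim: int
    seed: int
    merged_bins: tuple = ()

    def coverage(self) -> float:
        """Fraction of (bin x percentile) observed points inside the CIs."""
        t = self.table
        inside = (t["observed"] >= t["sim_lower"]) & (t["observed"] <= t["sim_upper"])
        return float(inside.mean())


def pc_vpc(
    dataset: Sequence[Subject],
    model: PopModel,
    n_sim: int = 500,
    bins: Sequence[float] | None = None,
    seed: int = 0,
    percentiles: tuple = (10.0, 50.0, 90.0),
    ci: float = 90.0,
) -> VpcBands:
    """Prediction-corrected VPC.  ``bins`` are time edges in hours (default
    weekly bins covering the sampling span); bins with fewer than 2
    observations are merged with their right neighbour (logged in
    ``merged_bins``)."""
    dataset = list(dataset)
    rng = np.random.default_rng(seed)

    times, ys, preds = [], [], []
    for subj in dataset:
        typ = model.typical()
        rate = np.array([d.rate for d in subj.doses])
        start = np.array([d.start_time for d in subj.doses])
        dur = np.array([d.infusion_duration for d in subj.doses])
        for o in subj.observations:
            if o.below_loq:
                continue
            times.append(o.time)
            ys.append(o.concentration)
            preds.append(float(conc_profile_1cpt(typ.V, typ.CL, rate, start, dur, o.time)))
    times = np.asarray(times)
    ys = np.asarray(ys)
    preds = np.asarray(preds)

    if bins is None:
        lo = math.floor(times.min() / 168.0) * 168.0
        hi = math.ceil(times.max() / 168.0) * 168.0
        bins = list(np.arange(lo, hi + 1, 168.0))
    edges = list(map(float, bins))
    if len(edges) < 3:
        raise ValueError("need >= 2 bins")

    which = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)
    # merge under-filled bins rightwards
    merged = []
    counts = np.bincount(which, minlength=len(edges) - 1)
    keep_edges = [edges[0]]
    for i in range(len(edges) - 1):
        if counts[i] < 2 and i < len(edges) - 2:
            merged.append((edges[i], edges[i + 1]))
            continue
        keep_edges.append(edges[i + 1])
    edges = keep_edges
    if len(edges) < 3:
        raise ValueError("fewer than 2 usable bins after merging")
    which = np.clip(np.searchsorted(edges, times, side="right") - 1, 0, len(edges) - 2)

    sims = _simulate_replicates(dataset, model, n_sim, rng)
    sim_mat = np.concatenate([s.T for s in sims], axis=0)  # (n_obs_total, n_sim)

    rows = []
    for bi in range(len(edges) - 1):
        sel = which == bi
        if not np.any(sel):
            continue
        med_pred = float(np.median(preds[sel]))
        corr = med_pred / preds[sel]
        y_pc = ys[sel] * corr
        sim_pc = sim_mat[sel] * corr[:, None]
        for pq in percentiles:
            obs_q = float(np.percentile(y_pc, pq))
            sim_q = np.percentile(sim_pc, pq, axis=0)  # per replicate
            lo_q = float(np.percentile(sim_q, (100 - ci) / 2))
            hi_q = float(np.percentile(sim_q, 100 - (100 - ci) / 2))
            rows.append({
                "bin_left": edges[bi], "bin_right": edges[bi + 1],
                "n_obs": int(sel.sum()), "percentile": pq,
                "observed": obs_q, "sim_lower": lo_q, "sim_upper": hi_q,
            })
    return VpcBands(table=pd.DataFrame(rows), bin_edges=tuple(edges),
                    n_sim=n_sim, seed=seed, merged_bins=tuple(merged))


# ---------------------------------------------------------------------------
# Goodness-of-fit table
# ---------------------------------------------------------------------------


def gof_table(fit: FitResult, dataset: Sequence[Subject], npde_result: NpdeResult | None = None) -> pd.DataFrame:
    """Per-observation PRED, IPRED and IWRES (optionally joined with NPDE).

    IWRES = (DV - IPRED) / (b * IPRED); subjects without quantifiable
    observations are absent from the table.
    """
    if fit.ebe is None:
        raise ValueError("fit carries no empirical Bayes estimates")
    rows = []
    for i, subj in enumerate(dataset):
        quant = [o for o in subj.observations if not o.below_loq]
        if not quant:
            continue
        rate = np.array([d.rate for d in subj.doses])
        start = np.array([d.start_time for d in subj.doses])
        dur = np.array([d.infusion_duration for d in subj.doses])
        t = np.array([o.time for o in quant])
        theta_pop = np.array([fit.theta[p] for p in fit.param_names])
        theta_ind = theta_pop * np.exp(fit.ebe[i])
        pred = fit.model.predict(theta_pop, rate, start, dur, t)
        ipred = fit.model.predict(theta_ind, rate, start, dur, t)
        for j, o in enumerate(quant):
            iw = (o.concentration - ipred[j]) / (fit.b * max(ipred[j], 1e-12))
            rows.append({
                "subject": subj.id, "time": o.time, "dv": o.concentration,
                "pred": float(pred[j]), "ipred": float(ipred[j]), "iwres": float(iw),
            })
    df = pd.DataFrame(rows)
    if npde_result is not None:
        df = df.merge(npde_result.table.rename(columns={"observed": "dv", "subject": "subject"}),
                      on=["subject", "time", "dv"], how="left")
    return df
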