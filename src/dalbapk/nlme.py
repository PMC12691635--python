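"""Nonlinear mixed-effects estimation by stochastic-approximation EM (SAEM).

The statistical model, for subject i and observation j:

    log phi_i  = X_i beta + eta_i,      eta_i ~ N(0, diag(omega^2))
    y_ij       = f(t_ij; phi_i) * (1 + b * eps_ij),  eps_ij ~ N(0, 1)

where ``f`` is a closed-form structural model (one- or two-compartment IV
infusion) and ``X_i`` is an intercept-only design unless covariate effects are
attached.  Maximum-likelihood estimation uses SAEM: an MCMC E-step samples the
individual random effects, and the M-step updates (beta, omega, b) from
stochastically-averaged sufficient statistics, which are in closed form for
this model family.  The chain uses two kernels per iteration: an independent
proposal from the random-effect prior and an adaptive random-walk targeting
roughly 35% acceptance.  Step size is 1 during an exploration phase and decays
as k^-0.7 during smoothing.

The engine carries an optional leading batch axis so that bootstrap resamples
and replicate simulation studies are fit simultaneously as one vectorised
computation.

Marginal likelihood (OFV = -2 log L) is estimated by importance sampling with
a t-distributed proposal centred at each subject's conditional mode (a Laplace
approximation is available as a fast deterministic alternative).  Standard
errors use a stochastic (Louis-type) observed Fisher information accumulated
over the MCMC chain, with a finite-difference Laplace Hessian as fallback.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .structural_pk import (
    ONE_COMPARTMENT,
    TWO_COMPARTMENT,
    PopModel,
    StructuralModel,
)

__all__ = [
    "Subject",
    "SaemSettings",
    "FitResult",
    "LikelihoodResult",
    "initial_estimates",
    "fit_saem",
    "fit_replicates",
    "log_likelihood",
    "empirical_bayes",
    "shrinkage",
    "rse",
    "select_structural_model",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Subject:
    """One subject: dosing history, concentration observations, covariates.

    Covariates are free-form; the cohort generator provides age (years), sex,
    height (cm), weight (kg), bmi (kg/m2), serum_creatinine (mg/dL), albumin
    (g/L), egfr (mL/min) and crcl (mL/min).
    """

    id: str
    doses: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    covariates: dict = field(default_factory=dict)

    def validate(self, for_estimation: bool = True) -> None:
        if len(self.doses) < 1:
            raise ValueError(f"subject {self.id}: at least one dose required")
        first_dose = min(d.start_time for d in self.doses)
        for obs in self.observations:
            if obs.time < first_dose:
                raise ValueError(
                    f"subject {self.id}: observation at t={obs.time} precedes "
                    f"first dose start t={first_dose}"
                )
        if for_estimation and self.n_quantifiable == 0:
            raise ValueError(
                f"subject {self.id}: no quantifiable (non-BLQ) observation"
            )

    @property
    def n_quantifiable(self) -> int:
        return sum(1 for o in self.observations if not o.below_loq)


@dataclass
class SaemSettings:
    """SAEM run controls.

    ``n_exploration`` iterations use step size 1 with simulated-annealing
    floors on the variance parameters; ``n_smoothing`` iterations decay the
    step as k**-step_decay.  ``n_chains`` MCMC chains per subject, each doing
    one prior-independent proposal plus ``n_rw_steps`` adaptive random-walk
    proposals per iteration.
    """

    n_exploration: int = 500
    n_smoothing: int = 200
    n_chains: int = 2
    n_rw_steps: int = 2
    step_decay: float = 0.7
    annealing: float = 0.95
    adapt_rate: float = 0.05
    target_accept: float = 0.35
    ofv_samples: int = 1000
    rse_iterations: int = 500


@dataclass
class LikelihoodResult:
    ofv: float
    aic: float
    bicc: float
    mc_se: float
    method: str
    n_parameters: int


@dataclass
class FitResult:
    """Estimation output.

    ``estimates`` is the fitted :class:`PopModel` for the final
    (one-compartment, intercept-only) parameterisation and ``None`` for other
    structural candidates; ``theta``/``omega``/``b`` always carry the raw
    estimates.  ``ebe`` holds per-subject conditional modes of eta.
    """

    model: StructuralModel
    param_names: tuple
    theta: dict
    omega: dict
    b: float
    beta: dict
    covariate_effects: tuple
    estimates: PopModel | None
    rse_percent: dict | None
    eta_shrinkage_percent: dict | None
    ofv: float | None
    aic: float | None
    bicc: float | None
    ofv_mc_se: float | None
    ebe: np.ndarray | None
    subject_ids: tuple
    convergence_trace: pd.DataFrame | None
    converged: bool
    flags: tuple
    seed: int
    fixed_omega: dict
    n_obs: int
    settings: SaemSettings

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


# ---------------------------------------------------------------------------
# Array preparation
# ---------------------------------------------------------------------------


@dataclass
class _Arrays:
    """Padded per-subject arrays; leading dims are (..., S)."""

    y: np.ndarray        # (..., S, T)
    times: np.ndarray    # (..., S, T)
    mask: np.ndarray     # (..., S, T) True where a quantifiable observation
    rate: np.ndarray     # (..., S, D)
    start: np.ndarray    # (..., S, D)
    dur: np.ndarray      # (..., S, D)

    @property
    def n_obs(self):
        return self.mask.sum(axis=(-1,))


def _build_arrays(dataset: Sequence[Subject]) -> _Arrays:
    S = len(dataset)
    T = max(len(s.observations) for s in dataset)
    D = max(len(s.doses) for s in dataset)
    y = np.zeros((S, T))
    times = np.zeros((S, T))
    mask = np.zeros((S, T), dtype=bool)
    rate = np.zeros((S, D))
    start = np.zeros((S, D))
    dur = np.ones((S, D))
    for i, subj in enumerate(dataset):
        for j, obs in enumerate(subj.observations):
            times[i, j] = obs.time
            y[i, j] = obs.concentration
            mask[i, j] = not obs.below_loq
        for d, dose in enumerate(subj.doses):
            rate[i, d] = dose.rate
            start[i, d] = dose.start_time
            dur[i, d] = dose.infusion_duration
    return _Arrays(y, times, mask, rate, start, dur)


def _stack_arrays(arrs: Sequence[_Arrays]) -> _Arrays:
    """Stack datasets of possibly different padded shapes into a batch."""
    S = max(a.y.shape[0] for a in arrs)
    T = max(a.y.shape[1] for a in arrs)
    D = max(a.rate.shape[1] for a in arrs)
    B = len(arrs)

    def pad(get, fill, dtype=float, last=None):
        out = np.full((B, S, last), fill, dtype=dtype)
        for b, a in enumerate(arrs):
            arr = get(a)
            out[b, : arr.shape[0], : arr.shape[1]] = arr
        return out

    return _Arrays(
        y=pad(lambda a: a.y, 0.0, last=T),
        times=pad(lambda a: a.times, 0.0, last=T),
        mask=pad(lambda a: a.mask, False, dtype=bool, last=T),
        rate=pad(lambda a: a.rate, 0.0, last=D),
        start=pad(lambda a: a.start, 0.0, last=D),
        dur=pad(lambda a: a.dur, 1.0, last=D),
    )


def _gather(arr: _Arrays, idx: np.ndarray) -> _Arrays:
    """Resample subjects: idx has shape (B, S) of subject indices."""
    return _Arrays(*(getattr(arr, f)[idx] for f in ("y", "times", "mask", "rate", "start", "dur")))


# ---------------------------------------------------------------------------
# Covariate designs
# ---------------------------------------------------------------------------


def _covariate_column(dataset, effect) -> np.ndarray:
    """Design column for one covariate effect (duck-typed CovariateEffect)."""
    vals = []
    for subj in dataset:
        try:
            v = subj.covariates[effect.covariate]
        except KeyError as exc:
            raise KeyError(
                f"subject {subj.id} lacks covariate '{effect.covariate}'"
            ) from exc
        if effect.form == "power":
            vals.append(math.log(float(v) / effect.reference))
        elif effect.form == "proportional":
            vals.append(1.0 if str(v).lower() in ("female", "f", "1") else 0.0)
        else:
            raise ValueError(f"unknown covariate form {effect.form!r}")
    return np.asarray(vals)


def _build_designs(dataset, param_names, covariate_effects):
    """Per-parameter design matrices X_p of shape (S, q_p); column 0 is the
    intercept (log of the typical value)."""
    S = len(dataset)
    cols = {p: [np.ones(S)] for p in param_names}
    labels = {p: [f"log_{p}_pop"] for p in param_names}
    for eff in covariate_effects:
        if eff.parameter not in cols:
            raise ValueError(f"unknown parameter {eff.parameter!r} for covariate effect")
        cols[eff.parameter].append(_covariate_column(dataset, eff))
        labels[eff.parameter].append(f"beta_{eff.parameter}_{eff.covariate}")
    X = {p: np.column_stack(c) for p, c in cols.items()}
    return X, labels


# ---------------------------------------------------------------------------
# Conditional log-likelihood pieces
# ---------------------------------------------------------------------------

_LOG2PI = math.log(2.0 * math.pi)


def _cond_loglik(f, y, mask, b):
    """Sum over the observation axis of log N(y; f, (b f)^2), padded entries
    masked out.  Constant -0.5*log(2*pi) terms included."""
    f = np.maximum(f, 1e-12)
    sd = np.maximum(b * f, 1e-12)
    r = (y - f) / sd
    ll = -0.5 * r * r - np.log(sd) - 0.5 * _LOG2PI
    return np.sum(np.where(mask, ll, 0.0), axis=-1)


def _predict_batch(model, phi, arr: _Arrays):
    """Predictions f for phi of shape (B, S, C, P) -> (B, S, C, T)."""
    theta = np.exp(phi)[..., None, :]          # (B, S, C, 1, P)
    # times: (B, S, T) -> (B, S, 1, T); doses: (B, S, D) -> (B, S, 1, 1, D)
    times = arr.times[..., None, :]
    rate = arr.rate[..., None, None, :]
    start = arr.start[..., None, None, :]
    dur = arr.dur[..., None, None, :]
    return model.predict(theta, rate, start, dur, times)


# ---------------------------------------------------------------------------
# SAEM core (batched)
# ---------------------------------------------------------------------------


def _run_saem(
    arr: _Arrays,
    model: StructuralModel,
    X: np.ndarray,                # (B, S, Qmax) stacked per-parameter designs
    q_per_param: Sequence[int],   # columns of X used by each parameter
    beta0: np.ndarray,            # (B, Qtot) concatenated initial coefficients
    omega0: np.ndarray,           # (B, P)
    b0: np.ndarray,               # (B,)
    settings: SaemSettings,
    rng: np.random.Generator,
    fixed_omega: np.ndarray | None = None,  # (P,) values; NaN = estimated
    fix_b: float | None = None,
    record_trace: bool = True,
):
    """Vectorised SAEM over a batch of datasets sharing padded shapes.

    ``X`` stacks the per-parameter design columns side by side;
    ``q_per_param`` gives each parameter's slice widths, so parameter p uses
    columns ``slice(off[p], off[p] + q_per_param[p])``.
    """
    B, S, T = arr.y.shape
    P = model.n_params
    C = settings.n_chains
    q = list(q_per_param)
    off = np.concatenate([[0], np.cumsum(q)])[:-1]
    Qtot = int(sum(q))

    beta = beta0.copy()
    omega = omega0.copy()
    bvec = b0.copy() if fix_b is None else np.full(B, fix_b)
    n_obs = arr.mask.sum(axis=(1, 2)).astype(float)  # (B,)

    # Precompute per-parameter X^T X (B, q_p, q_p)
    XtX = [np.einsum("bsi,bsj->bij", X[..., off[p]: off[p] + q[p]], X[..., off[p]: off[p] + q[p]]) for p in range(P)]

    def mu_of(beta_):
        out = np.empty((B, S, P))
        for p in range(P):
            Xp = X[..., off[p]: off[p] + q[p]]
            out[..., p] = np.einsum("bsq,bq->bs", Xp, beta_[:, off[p]: off[p] + q[p]])
        return out

    mu = mu_of(beta)
    eta = np.zeros((B, S, C, P))
    step = np.full((B, S), 0.4)

    def loglik_of(eta_):
        phi = mu[:, :, None, :] + eta_
        f = _predict_batch(model, phi, arr)
        return _cond_loglik(f, arr.y[..., None, :], arr.mask[..., None, :], bvec[:, None, None, None])

    def logprior_of(eta_):
        w = np.maximum(omega[:, None, None, :], 1e-12)
        return np.sum(-0.5 * (eta_ / w) ** 2 - np.log(w), axis=-1)

    ll = loglik_of(eta)

    n_iter = settings.n_exploration + settings.n_smoothing
    s1 = np.zeros((B, Qtot))
    s2 = np.zeros((B, P))
    sres = np.zeros(B)
    trace = np.empty((n_iter, B, P + P + 1)) if record_trace else None

    omega_free = np.isnan(fixed_omega) if fixed_omega is not None else np.ones(P, dtype=bool)
    if fixed_omega is not None:
        omega[:, ~omega_free] = fixed_omega[~omega_free]

    for it in range(n_iter):
        exploring = it < settings.n_exploration
        gamma = 1.0 if exploring else (it - settings.n_exploration + 1) ** (-settings.step_decay)

        # --- E-step: one independent + n_rw random-walk Metropolis proposals
        prop = omega[:, None, None, :] * rng.standard_normal((B, S, C, P))
        ll_prop = loglik_of(prop)
        accept = np.log(rng.random((B, S, C))) < (ll_prop - ll)
        eta = np.where(accept[..., None], prop, eta)
        ll = np.where(accept, ll_prop, ll)

        for _ in range(settings.n_rw_steps):
            lp = logprior_of(eta)
            prop = eta + step[:, :, None, None] * omega[:, None, None, :] * rng.standard_normal((B, S, C, P))
            ll_prop = loglik_of(prop)
            lp_prop = logprior_of(prop)
            accept = np.log(rng.random((B, S, C))) < (ll_prop + lp_prop - ll - lp)
            eta = np.where(accept[..., None], prop, eta)
            ll = np.where(accept, ll_prop, ll)
            acc_rate = accept.mean(axis=-1)
            step *= np.exp(settings.adapt_rate * (acc_rate - settings.target_accept))
        step = np.clip(step, 1e-3, 10.0)

        # --- sufficient statistics (averaged over chains)
        phi = mu[:, :, None, :] + eta
        phibar = phi.mean(axis=2)                      # (B, S, P)
        phi2 = (phi ** 2).mean(axis=2)                 # (B, S, P)
        f = _predict_batch(model, phi, arr)
        fm = np.maximum(f, 1e-12)
        res2 = np.where(arr.mask[..., None, :], ((arr.y[..., None, :] - fm) / fm) ** 2, 0.0)
        res2 = res2.mean(axis=2).sum(axis=(1, 2))

        new_s1 = np.concatenate(
            [np.einsum("bsq,bs->bq", X[..., off[p]: off[p] + q[p]], phibar[..., p]) for p in range(P)],
            axis=1,
        )
        new_s2 = phi2.sum(axis=1)
        s1 += gamma * (new_s1 - s1)
        s2 += gamma * (new_s2 - s2)
        sres += gamma * (res2 - sres)

        # --- M-step (closed form)
        for p in range(P):
            sl = slice(off[p], off[p] + q[p])
            beta[:, sl] = np.linalg.solve(XtX[p], s1[:, sl][..., None])[..., 0]
        mu = mu_of(beta)
        for p in range(P):
            sl = slice(off[p], off[p] + q[p])
            quad = np.einsum("bq,bqr,br->b", beta[:, sl], XtX[p], beta[:, sl])
            var = (s2[:, p] - 2.0 * np.einsum("bq,bq->b", beta[:, sl], s1[:, sl]) + quad) / S
            var = np.maximum(var, 1e-10)
            if omega_free[p]:
                if exploring:
                    var = np.maximum(var, settings.annealing * omega[:, p] ** 2)
                omega[:, p] = np.sqrt(var)
        if fix_b is None:
            bsq = np.maximum(sres / np.maximum(n_obs, 1.0), 1e-12)
            if exploring:
                bsq = np.maximum(bsq, settings.annealing * bvec ** 2)
            bvec = np.sqrt(bsq)

        ll = loglik_of(eta)  # refresh: mu and b changed

        if record_trace:
            trace[it, :, :P] = np.exp(beta[:, off])    # typical values
            trace[it, :, P: 2 * P] = omega
            trace[it, :, 2 * P] = bvec

    return {
        "beta": beta,
        "omega": omega,
        "b": bvec,
        "eta": eta,
        "step": step,
        "trace": trace,
        "mu": mu,
        "off": off,
        "q": q,
    }


def _trace_converged(trace: np.ndarray, n_smoothing: int) -> tuple[bool, tuple]:
    """Post-hoc stabilisation check: relative drift of every parameter trace
    over the last 20% of the smoothing phase must be small."""
    flags = []
    n_last = max(int(0.2 * n_smoothing), 10)
    seg = trace[-n_last:, 0, :]
    x = np.arange(n_last, dtype=float)
    x = x - x.mean()
    denom = float(np.sum(x * x))
    ok = True
    for j in range(seg.shape[1]):
        yv = seg[:, j]
        scale = max(abs(float(yv.mean())), 1e-12)
        slope = float(np.sum(x * (yv - yv.mean()))) / denom
        drift = abs(slope) * n_last / scale
        if drift > 0.10:
            ok = False
            flags.append(f"trace_drift[{j}]={drift:.3f}")
    return ok, tuple(flags)


# ---------------------------------------------------------------------------
# Initial estimates
# ---------------------------------------------------------------------------


def initial_estimates(dataset: Sequence[Subject]) -> PopModel:
    """Naive pooled initial values: the elimination rate from a pooled
    log-linear regression of concentration on time, V from back-extrapolated
    dose / C0, CL = k * V.  Used because sparse troughs carry little curvature
    and SAEM needs only the right order of magnitude."""
    ts, lcs = [], []
    for subj in dataset:
        for obs in subj.observations:
            if not obs.below_loq and obs.concentration > 0:
                ts.append(obs.time)
                lcs.append(math.log(obs.concentration))
    ts = np.asarray(ts)
    lcs = np.asarray(lcs)
    if len(ts) >= 2 and np.ptp(ts) > 0:
        slope, intercept = np.polyfit(ts, lcs, 1)
        k = max(-slope, 1e-4)
    else:
        k, intercept = 2e-3, lcs.mean() if len(lcs) else math.log(50.0)
    v_draws = []
    for subj in dataset:
        dose_total = sum(d.amount for d in subj.doses)
        quant = [o for o in subj.observations if not o.below_loq and o.concentration > 0]
        if not quant or dose_total <= 0:
            continue
        first = min(quant, key=lambda o: o.time)
        c0 = first.concentration * math.exp(k * first.time)
        v_draws.append(dose_total / c0)
    V = float(np.median(v_draws)) if v_draws else 15.0
    return PopModel(V_pop=V, CL_pop=k * V, omega_V=0.3, omega_CL=0.3, b=0.2)


# ---------------------------------------------------------------------------
# Fixed-effects-only fallback (all omegas fixed at zero)
# ---------------------------------------------------------------------------


def _fit_fixed_effects(arr, model, X, q, beta0, b0, fix_b):
    off = np.concatenate([[0], np.cumsum(q)])[:-1]
    P = model.n_params

    def unpack(z):
        beta = z[: sum(q)]
        b = math.exp(z[-1]) if fix_b is None else fix_b
        return beta, b

    def negll(z):
        beta, b = unpack(z)
        mu = np.empty((1, arr.y.shape[1], P))
        for p in range(P):
            Xp = X[..., off[p]: off[p] + q[p]]
            mu[..., p] = np.einsum("bsq,q->bs", Xp, beta[off[p]: off[p] + q[p]])
        f = _predict_batch(model, mu[:, :, None, :], arr)
        ll = _cond_loglik(f, arr.y[..., None, :], arr.mask[..., None, :], b)
        return -float(ll.sum())

    z0 = np.concatenate([beta0, [math.log(max(b0, 1e-3))]])
    res = optimize.minimize(negll, z0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    beta, b = unpack(res.x)
    return beta, b, res


# ---------------------------------------------------------------------------
# Public fitting API
# ---------------------------------------------------------------------------


def _flatten_designs(X_by_param, param_names):
    mats = [X_by_param[p] for p in param_names]
    q = [m.shape[1] for m in mats]
    return np.concatenate(mats, axis=1)[None, ...], q


def _init_beta(init: PopModel | dict, param_names, q) -> np.ndarray:
    vals = []
    if isinstance(init, PopModel):
        theta0 = {"V": init.V_pop, "CL": init.CL_pop}
    else:
        theta0 = dict(init)
    for p, qp in zip(param_names, q):
        vals.append(math.log(theta0[p]))
        vals.extend([0.0] * (qp - 1))
    return np.asarray(vals)


def fit_saem(
    dataset: Sequence[Subject],
    init: PopModel | dict,
    settings: SaemSettings | None = None,
    seed: int = 0,
    covariate_effects: Sequence = (),
    fixed_omega: dict | None = None,
    structural: StructuralModel = ONE_COMPARTMENT,
    init_omega: dict | None = None,
    compute_ofv: str | None = "is",
    compute_rse: bool = False,
) -> FitResult:
    """Fit the population model by SAEM; deterministic given ``seed``.

    ``fixed_omega`` maps parameter names to fixed IIV SDs (0 collapses the
    model to pooled fixed effects, fit directly by likelihood maximisation).
    ``compute_ofv`` is "is" (importance sampling), "laplace" or None.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("dataset is empty")
    for subj in dataset:
        subj.validate()
    settings = settings or SaemSettings()
    param_names = structural.param_names
    P = structural.n_params

    X_by_param, labels = _build_designs(dataset, param_names, covariate_effects)
    X, q = _flatten_designs(X_by_param, param_names)
    beta0 = _init_beta(init, param_names, q)

    if isinstance(init, PopModel):
        om0 = {"V": init.omega_V, "CL": init.omega_CL}
        b_init = init.b
    else:
        om0 = {}
        b_init = 0.2
    if init_omega:
        om0.update(init_omega)
    omega0 = np.array([om0.get(p, 0.3) for p in param_names])

    fixed = np.full(P, np.nan)
    if fixed_omega:
        for name, val in fixed_omega.items():
            fixed[param_names.index(name)] = val

    arr0 = _build_arrays(dataset)
    arr = _Arrays(*(a[None, ...] for a in (arr0.y, arr0.times, arr0.mask, arr0.rate, arr0.start, arr0.dur)))
    rng = np.random.default_rng(seed)
    flags: list[str] = []

    all_zero = fixed_omega is not None and all(
        not math.isnan(fixed[p]) and fixed[p] == 0.0 for p in range(P)
    )
    if all_zero:
        beta, b, res = _fit_fixed_effects(arr, structural, X, q, beta0, b_init, None)
        omega_hat = np.zeros(P)
        eta_modes = np.zeros((len(dataset), P))
        trace_df = None
        converged = bool(res.success)
        if not converged:
            flags.append("fixed_effects_optimizer_not_converged")
        beta = np.asarray(beta)[None, :]
        bvec = np.array([b])
    else:
        out = _run_saem(
            arr, structural, X, q, beta0[None, :].copy(),
            omega0[None, :].copy(), np.array([b_init]), settings, rng,
            fixed_omega=fixed, record_trace=True,
        )
        beta, omega_hat, bvec = out["beta"], out["omega"][0], out["b"]
        converged, drift_flags = _trace_converged(out["trace"], settings.n_smoothing)
        flags.extend(drift_flags)
        free = np.isnan(fixed)
        if np.any(omega_hat[free] < 1e-4):
            converged = False
            flags.append("omega_collapse")
        cols = [f"{p}_pop" for p in param_names] + [f"omega_{p}" for p in param_names] + ["b"]
        trace_df = pd.DataFrame(out["trace"][:, 0, :], columns=cols)
        trace_df.index.name = "iteration"
        eta_modes = None  # filled below

    off = np.concatenate([[0], np.cumsum(q)])[:-1]
    theta = {p: float(math.exp(beta[0, off[i]])) for i, p in enumerate(param_names)}
    omega_d = {p: float(omega_hat[i]) for i, p in enumerate(param_names)}
    b_hat = float(bvec[0])

    beta_d = {}
    for i, p in enumerate(param_names):
        for jq in range(q[i]):
            beta_d[labels[p][jq]] = float(beta[0, off[i] + jq])

    fitted_effects = tuple(
        replace(eff, coefficient=beta_d[f"beta_{eff.parameter}_{eff.covariate}"])
        if hasattr(eff, "__dataclass_fields__") else eff
        for eff in covariate_effects
    )

    estimates = None
    if structural is ONE_COMPARTMENT and not covariate_effects:
        estimates = PopModel(
            V_pop=theta["V"], CL_pop=theta["CL"],
            omega_V=omega_d["V"], omega_CL=omega_d["CL"], b=b_hat,
        )

    fit = FitResult(
        model=structural, param_names=param_names, theta=theta, omega=omega_d,
        b=b_hat, beta=beta_d, covariate_effects=fitted_effects,
        estimates=estimates, rse_percent=None, eta_shrinkage_percent=None,
        ofv=None, aic=None, bicc=None, ofv_mc_se=None, ebe=None,
        subject_ids=tuple(s.id for s in dataset),
        convergence_trace=trace_df, converged=converged, flags=tuple(flags),
        seed=seed, fixed_omega=dict(fixed_omega or {}),
        n_obs=int(arr0.mask.sum()), settings=settings,
    )

    # Empirical Bayes modes and shrinkage
    if eta_modes is None:
        eta_modes = np.stack([_map_eta(fit, dataset, i)[0] for i in range(len(dataset))])
    fit.ebe = eta_modes
    fit.eta_shrinkage_percent = _shrinkage_from_ebe(eta_modes, omega_d, param_names)

    if compute_ofv is not None:
        lik = log_likelihood(fit, dataset, n_is_samples=settings.ofv_samples,
                             seed=seed + 1, method=compute_ofv)
        fit.ofv, fit.aic, fit.bicc, fit.ofv_mc_se = lik.ofv, lik.aic, lik.bicc, lik.mc_se
    if compute_rse:
        fit.rse_percent = rse(fit, dataset, method="louis", seed=seed + 2)
    return fit


def fit_replicates(
    datasets: Sequence[Sequence[Subject]],
    init: PopModel,
    settings: SaemSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit many one-compartment intercept-only datasets in one vectorised SAEM
    pass; returns one row of estimates per dataset."""
    settings = settings or SaemSettings()
    arrs = [_build_arrays(list(ds)) for ds in datasets]
    arr = _stack_arrays(arrs)
    B, S, _ = arr.y.shape
    X = np.ones((B, S, 2))  # two intercept-only designs side by side
    q = [1, 1]
    beta0 = np.tile(np.array([math.log(init.V_pop), math.log(init.CL_pop)]), (B, 1))
    omega0 = np.tile(np.array([init.omega_V, init.omega_CL]), (B, 1))
    b0 = np.full(B, init.b)
    rng = np.random.default_rng(seed)
    out = _run_saem(arr, ONE_COMPARTMENT, X, q, beta0, omega0, b0, settings, rng,
                    record_trace=False)
    return pd.DataFrame({
        "V_pop": np.exp(out["beta"][:, 0]),
        "CL_pop": np.exp(out["beta"][:, 1]),
        "omega_V": out["omega"][:, 0],
        "omega_CL": out["omega"][:, 1],
        "b": out["b"],
    })


# ---------------------------------------------------------------------------
# Subject-level conditional posterior helpers
# ---------------------------------------------------------------------------


def _subject_pieces(fit: FitResult, dataset, i):
    subj = dataset[i]
    quant = [(o.time, o.concentration) for o in subj.observations if not o.below_loq]
    t = np.array([x[0] for x in quant])
    y = np.array([x[1] for x in quant])
    rate = np.array([d.rate for d in subj.doses])
    start = np.array([d.start_time for d in subj.doses])
    dur = np.array([d.infusion_duration for d in subj.doses])
    X_by_param, _ = _build_designs([subj], fit.param_names, fit.covariate_effects)
    mu = np.array([
        float(X_by_param[p][0] @ _beta_vector(fit, p)) for p in fit.param_names
    ])
    return t, y, rate, start, dur, mu


def _beta_vector(fit: FitResult, p: str) -> np.ndarray:
    vals = [fit.beta[f"log_{p}_pop"]]
    for eff in fit.covariate_effects:
        if eff.parameter == p:
            vals.append(fit.beta[f"beta_{p}_{eff.covariate}"])
    return np.asarray(vals)


def _cond_logpost_fn(fit: FitResult, dataset, i):
    """Returns (loglik(eta), logprior(eta)) callables accepting (..., P)."""
    t, y, rate, start, dur, mu = _subject_pieces(fit, dataset, i)
    omega = np.array([max(fit.omega[p], 1e-8) for p in fit.param_names])
    model, b = fit.model, fit.b

    def loglik(eta):
        eta = np.asarray(eta, dtype=float)
        theta = np.exp(mu + eta)
        if len(t) == 0:
            return np.zeros(eta.shape[:-1])
        f = model.predict(theta[..., None, :], rate, start, dur, t)
        return _cond_loglik(f, y, np.ones(len(t), dtype=bool), b)

    def logprior(eta):
        eta = np.asarray(eta, dtype=float)
        return np.sum(-0.5 * (eta / omega) ** 2 - np.log(omega) - 0.5 * _LOG2PI, axis=-1)

    return loglik, logprior, omega


def _map_eta(fit: FitResult, dataset, i):
    """Conditional mode of eta_i and the Hessian of the negative log posterior."""
    loglik, logprior, omega = _cond_logpost_fn(fit, dataset, i)
    P = len(fit.param_names)
    if dataset[i].n_quantifiable == 0:
        return np.zeros(P), np.diag(1.0 / omega ** 2)

    def neg(eta):
        return -float(loglik(eta) + logprior(eta))

    res = optimize.minimize(neg, np.zeros(P), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    res2 = optimize.minimize(neg, res.x, method="BFGS")
    eta_hat = res2.x if res2.fun <= res.fun else res.x
    h = 1e-4
    H = np.zeros((P, P))
    f0 = neg(eta_hat)
    for a in range(P):
        for c in range(a, P):
            ea = np.zeros(P); ea[a] = h
            ec = np.zeros(P); ec[c] = h
            H[a, c] = H[c, a] = (
                neg(eta_hat + ea + ec) - neg(eta_hat + ea - ec)
                - neg(eta_hat - ea + ec) + neg(eta_hat - ea - ec)
            ) / (4 * h * h)
    # guard: keep positive definite
    w, V = np.linalg.eigh(0.5 * (H + H.T))
    w = np.maximum(w, 1e-6)
    H = V @ np.diag(w) @ V.T
    return eta_hat, H


def empirical_bayes(fit: FitResult, subject: Subject, dataset: Sequence[Subject] | None = None) -> np.ndarray:
    """MAP (conditional-mode) estimate of the subject's random effects."""
    eta, _ = _map_eta(fit, [subject], 0)
    return eta


def _shrinkage_from_ebe(ebe: np.ndarray, omega: dict, param_names) -> dict:
    out = {}
    for i, p in enumerate(param_names):
        w = omega[p]
        if w < 1e-10:
            out[p] = float("nan")
        else:
            sd = float(np.std(ebe[:, i], ddof=1)) if ebe.shape[0] > 1 else 0.0
            out[p] = 100.0 * (1.0 - sd / w)
    return out


def shrinkage(fit: FitResult) -> dict:
    """Eta-shrinkage per parameter: 100 * (1 - SD(EBE eta) / omega)."""
    if fit.eta_shrinkage_percent is None:
        raise ValueError("fit has no empirical Bayes estimates")
    return fit.eta_shrinkage_percent


# ---------------------------------------------------------------------------
# Marginal likelihood: importance sampling and Laplace
# ---------------------------------------------------------------------------


def _n_parameters(fit: FitResult):
    """(total p, subject-level count, observation-level count) for AIC/BICc.

    Fixed effects and IIV SDs of parameters carrying random effects are
    penalised with log(n_subjects); the residual-error magnitude (and any
    fixed effect without IIV) with log(n_obs) — the mixed penalty used for
    nonlinear mixed-effects BICc.
    """
    n_subj_level = 0
    n_obs_level = 0
    for i, p in enumerate(fit.param_names):
        qp = 1 + sum(1 for eff in fit.covariate_effects if eff.parameter == p)
        has_iiv = fit.fixed_omega.get(p, None) != 0.0 and fit.omega[p] > 0
        n_free_omega = 0 if p in fit.fixed_omega else 1
        if has_iiv:
            n_subj_level += qp + n_free_omega
        else:
            n_obs_level += qp
    n_obs_level += 1  # b
    return n_subj_level + n_obs_level, n_subj_level, n_obs_level


def log_likelihood(
    fit: FitResult,
    dataset: Sequence[Subject],
    n_is_samples: int = 1000,
    seed: int = 0,
    method: str = "is",
    df: float = 4.0,
) -> LikelihoodResult:
    """OFV (= -2 log marginal likelihood) with AIC and BICc.

    ``method="is"``: importance sampling with a multivariate-t proposal at the
    conditional mode (Monte-Carlo SE reported).  ``method="laplace"``:
    deterministic Laplace approximation (mc_se = 0).
    """
    dataset = list(dataset)
    rng = np.random.default_rng(seed)
    P = len(fit.param_names)
    total = 0.0
    var_total = 0.0
    for i in range(len(dataset)):
        loglik, logprior, omega = _cond_logpost_fn(fit, dataset, i)
        eta_hat, H = _map_eta(fit, dataset, i)
        cov = np.linalg.inv(H)
        if method == "laplace":
            _, logdet = np.linalg.slogdet(H)
            li = float(loglik(eta_hat) + logprior(eta_hat)) + 0.5 * P * _LOG2PI - 0.5 * logdet
            total += li
            continue
        if method != "is":
            raise ValueError(f"unknown likelihood method {method!r}")
        L = np.linalg.cholesky(cov)
        z = rng.standard_normal((n_is_samples, P))
        u = rng.chisquare(df, size=n_is_samples) / df
        draws = eta_hat + (z / np.sqrt(u)[:, None]) @ L.T
        # multivariate-t log density at the draws
        d2 = np.sum((np.linalg.solve(L, (draws - eta_hat).T).T) ** 2, axis=1)
        _, logdetC = np.linalg.slogdet(cov)
        logq = (
            math.lgamma((df + P) / 2) - math.lgamma(df / 2)
            - 0.5 * P * math.log(df * math.pi) - 0.5 * logdetC
            - 0.5 * (df + P) * np.log1p(d2 / df)
        )
        logw = loglik(draws) + logprior(draws) - logq
        m = np.max(logw)
        w = np.exp(logw - m)
        li = m + math.log(np.mean(w))
        total += li
        var_total += float(np.var(w) / (n_is_samples * np.mean(w) ** 2))
    ofv = -2.0 * total
    mc_se = 2.0 * math.sqrt(var_total) if method == "is" else 0.0
    p_tot, p_subj, p_obs = _n_parameters(fit)
    n_subj = len(dataset)
    n_obs = sum(s.n_quantifiable for s in dataset)
    aic = ofv + 2 * p_tot
    bicc = ofv + math.log(n_subj) * p_subj + math.log(n_obs) * p_obs
    return LikelihoodResult(ofv=ofv, aic=aic, bicc=bicc, mc_se=mc_se,
                            method=method, n_parameters=p_tot)


# ---------------------------------------------------------------------------
# Standard errors
# ---------------------------------------------------------------------------


def rse(fit: FitResult, dataset: Sequence[Subject], method: str = "louis",
        seed: int = 0, n_iterations: int | None = None) -> dict:
    """Per-parameter relative standard errors (%) of the estimates.

    "louis": stochastic observed Fisher information accumulated over an MCMC
    sample of the random effects (score/Hessian of the complete-data
    log-likelihood are closed-form for this model family).
    "linearized": finite-difference Hessian of the Laplace-approximated
    log-likelihood.
    """
    dataset = list(dataset)
    if all(v < 1e-6 for v in fit.omega.values()):
        # no random effects: the model is a nonlinear regression and the
        # information is the direct Hessian of its log-likelihood
        return _rse_fixed_effects(fit, dataset)
    if method == "linearized":
        return _rse_linearized(fit, dataset)
    if method != "louis":
        raise ValueError(f"unknown RSE method {method!r}")

    settings = fit.settings
    n_iter = n_iterations or settings.rse_iterations
    rng = np.random.default_rng(seed)
    param_names = fit.param_names
    P = len(param_names)
    labels: list[str] = []
    for p in param_names:
        labels.append(f"log_{p}_pop")
        labels.extend(f"beta_{p}_{e.covariate}" for e in fit.covariate_effects if e.parameter == p)
    free_omega = [p for p in param_names if p not in fit.fixed_omega and fit.omega[p] > 1e-10]
    labels += [f"omega_{p}" for p in free_omega] + ["b"]
    K = len(labels)

    omega = np.array([max(fit.omega[p], 1e-10) for p in param_names])
    b = fit.b
    S = len(dataset)

    sum_s = np.zeros((S, K))
    sum_ss = np.zeros((S, K, K))
    sum_H = np.zeros((S, K, K))
    count = 0

    # per-subject samplers
    pieces = [_cond_logpost_fn(fit, dataset, i) for i in range(S)]
    etas = np.stack([_map_eta(fit, dataset, i)[0] for i in range(S)])
    Xrows = []
    for i in range(S):
        Xp, _ = _build_designs([dataset[i]], param_names, fit.covariate_effects)
        Xrows.append({p: Xp[p][0] for p in param_names})

    burn = max(50, n_iter // 5)
    step = np.full(S, 0.4)
    curll = np.array([float(pieces[i][0](etas[i])) for i in range(S)])

    for it in range(n_iter + burn):
        prop = etas + step[:, None] * omega * rng.standard_normal((S, P))
        llp = np.array([float(pieces[i][0](prop[i])) for i in range(S)])
        lpp = np.sum(-0.5 * (prop / omega) ** 2, axis=1)
        lpc = np.sum(-0.5 * (etas / omega) ** 2, axis=1)
        acc = np.log(rng.random(S)) < (llp + lpp - curll - lpc)
        etas = np.where(acc[:, None], prop, etas)
        curll = np.where(acc, llp, curll)
        step *= np.exp(0.05 * (acc.astype(float) - 0.35))
        if it < burn:
            continue
        count += 1
        for i in range(S):
            s, H = _complete_score_hess(fit, dataset, i, etas[i], Xrows[i],
                                        omega, b, free_omega, labels)
            sum_s[i] += s
            sum_ss[i] += np.outer(s, s)
            sum_H[i] += H
    Es = sum_s / count
    Ess = sum_ss / count
    EH = sum_H / count
    info = np.zeros((K, K))
    for i in range(S):
        info += -EH[i] - (Ess[i] - np.outer(Es[i], Es[i]))
    info = 0.5 * (info + info.T)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out = {"method": "louis"}
    if np.any(np.diag(cov) <= 0) or np.linalg.matrix_rank(info) < K:
        out["singular"] = True
    for j, lab in enumerate(labels):
        if lab.startswith("beta_"):
            ref = abs(fit.beta[lab])
            out[lab] = 100.0 * se[j] / ref if ref > 1e-12 else float("inf")
        else:
            out[_pretty_label(lab)] = 100.0 * se[j]  # log-scale SE == relative SE
    return out


def _pretty_label(lab: str) -> str:
    if lab.startswith("log_") and lab.endswith("_pop"):
        return lab[4:]
    return lab


def _complete_score_hess(fit, dataset, i, eta, Xrow, omega, b, free_omega, labels):
    """Closed-form score and Hessian of the complete-data log-likelihood of
    subject i w.r.t. (beta..., log omega..., log b) at the current estimates."""
    param_names = fit.param_names
    P = len(param_names)
    t, y, rate, start, dur, mu = _subject_pieces(fit, dataset, i)
    e = eta  # phi - mu
    theta = np.exp(mu + eta)
    if len(t):
        f = np.maximum(fit.model.predict(theta[None, :], rate, start, dur, t), 1e-12)
        r = (y - f) / (b * f)
        sum_r2 = float(np.sum(r * r))
        n_i = len(t)
    else:
        sum_r2, n_i = 0.0, 0

    K = len(labels)
    s = np.zeros(K)
    H = np.zeros((K, K))
    pos = {lab: j for j, lab in enumerate(labels)}
    for pi, p in enumerate(param_names):
        x = Xrow[p]
        w2 = omega[pi] ** 2
        blabs = [f"log_{p}_pop"] + [
            f"beta_{p}_{eff.covariate}" for eff in fit.covariate_effects if eff.parameter == p
        ]
        for a, la in enumerate(blabs):
            s[pos[la]] = x[a] * e[pi] / w2
            for c, lc in enumerate(blabs):
                H[pos[la], pos[lc]] += -x[a] * x[c] / w2
        if p in free_omega:
            lo = pos[f"omega_{p}"]
            s[lo] = -1.0 + e[pi] ** 2 / w2
            H[lo, lo] += -2.0 * e[pi] ** 2 / w2
            for a, la in enumerate(blabs):
                H[pos[la], lo] += -2.0 * x[a] * e[pi] / w2
                H[lo, pos[la]] += -2.0 * x[a] * e[pi] / w2
    lb = pos["b"]
    s[lb] = -n_i + sum_r2
    H[lb, lb] = -2.0 * sum_r2
    return s, H


def _rse_fixed_effects(fit: FitResult, dataset):
    """SEs for the omega = 0 limit: finite-difference Hessian of the pooled
    fixed-effects log-likelihood in (log theta..., log b)."""
    param_names = fit.param_names
    labels = [f"log_{p}_pop" for p in param_names] + ["b"]
    theta0 = np.array([math.log(fit.theta[p]) for p in param_names] + [math.log(fit.b)])

    pieces = [_subject_pieces(fit, dataset, i) for i in range(len(dataset))]

    def negll(z):
        theta = np.exp(theta0[:-1] + z[:-1])
        b = math.exp(theta0[-1] + z[-1])
        tot = 0.0
        for t, y, rate, start, dur, _mu in pieces:
            if len(t) == 0:
                continue
            f = fit.model.predict(theta, rate, start, dur, t)
            tot += float(_cond_loglik(f, y, np.ones(len(t), dtype=bool), b))
        return -tot

    K = len(labels)
    h = 1e-4
    Hm = np.zeros((K, K))
    for a in range(K):
        for c in range(a, K):
            ea = np.zeros(K); ea[a] = h
            ec = np.zeros(K); ec[c] = h
            Hm[a, c] = Hm[c, a] = (
                negll(ea + ec) - negll(ea - ec) - negll(-ea + ec) + negll(-ea - ec)
            ) / (4 * h * h)
    cov = np.linalg.pinv(Hm)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out = {"method": "fixed_effects"}
    for j, lab in enumerate(labels):
        out[_pretty_label(lab)] = 100.0 * se[j]
    return out


def _rse_linearized(fit: FitResult, dataset):
    """Numerical Hessian of the Laplace log-likelihood in log-parameters."""
    param_names = fit.param_names
    free_omega = [p for p in param_names if p not in fit.fixed_omega and fit.omega[p] > 1e-10]
    labels = [f"log_{p}_pop" for p in param_names] + [f"omega_{p}" for p in free_omega] + ["b"]

    base_beta = dict(fit.beta)
    base_omega = dict(fit.omega)
    base_b = fit.b

    def with_offset(z):
        f2 = replace(fit)
        beta = dict(base_beta)
        omega = dict(base_omega)
        b = base_b
        for j, lab in enumerate(labels):
            if lab.startswith("log_"):
                beta[lab] = base_beta[lab] + z[j]
            elif lab.startswith("omega_"):
                omega[lab[6:]] = base_omega[lab[6:]] * math.exp(z[j])
            else:
                b = base_b * math.exp(z[j])
        f2.beta = beta
        f2.omega = omega
        f2.b = b
        f2.theta = {p: math.exp(beta[f"log_{p}_pop"]) for p in param_names}
        return f2

    def negll(z):
        lik = log_likelihood(with_offset(z), dataset, method="laplace")
        return 0.5 * lik.ofv

    K = len(labels)
    h = 0.05  # large enough that OFV differences dominate Laplace noise
    Hm = np.zeros((K, K))
    for a in range(K):
        for c in range(a, K):
            ea = np.zeros(K); ea[a] = h
            ec = np.zeros(K); ec[c] = h
            Hm[a, c] = Hm[c, a] = (
                negll(ea + ec) - negll(ea - ec) - negll(-ea + ec) + negll(-ea - ec)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(Hm)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(Hm)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    out = {"method": "linearized"}
    for j, lab in enumerate(labels):
        out[_pretty_label(lab)] = 100.0 * se[j]
    return out


# ---------------------------------------------------------------------------
# Structural model selection
# ---------------------------------------------------------------------------


def select_structural_model(
    dataset: Sequence[Subject],
    candidates: Sequence[StructuralModel] = (ONE_COMPARTMENT, TWO_COMPARTMENT),
    settings: SaemSettings | None = None,
    seed: int = 0,
    compute_rse: bool = False,
    init: PopModel | None = None,
) -> pd.DataFrame:
    """Fit each candidate and rank by BICc, then AIC, then parameter count.

    Non-convergent candidates are excluded with a reason; RSE > 50% on any
    parameter is flagged when ``compute_rse`` is set.
    """
    if len(candidates) < 2:
        raise ValueError("need at least two candidate structural models")
    settings = settings or SaemSettings()
    base_init = init or initial_estimates(list(dataset))
    rows = []
    fits = {}
    for ci, cand in enumerate(candidates):
        if cand.param_names == ("V", "CL"):
            init_c: PopModel | dict = base_init
        else:
            init_c = {
                "V1": 0.6 * base_init.V_pop,
                "CL": base_init.CL_pop,
                "Q": 5.0 * base_init.CL_pop,
                "V2": 0.6 * base_init.V_pop,
            }
        try:
            fit = fit_saem(list(dataset), init_c, settings=settings,
                           seed=seed + 1000 * ci, structural=cand,
                           compute_ofv="is", compute_rse=compute_rse)
        except Exception as exc:  # non-convergence surfaces as exclusion
            rows.append({"model": cand.name, "excluded": True,
                         "reason": f"fit failed: {exc}"})
            continue
        if not fit.converged:
            rows.append({"model": cand.name, "excluded": True,
                         "reason": "non-convergent: " + ";".join(fit.flags)})
            continue
        n_par = _n_parameters(fit)[0]
        rse_flag = False
        if compute_rse and fit.rse_percent:
            rse_flag = any(
                v > 50.0 for k, v in fit.rse_percent.items()
                if isinstance(v, (int, float)) and k not in ("method",)
            )
        rows.append({
            "model": cand.name, "excluded": False, "reason": "",
            "ofv": fit.ofv, "aic": fit.aic, "bicc": fit.bicc,
            "n_parameters": n_par, "rse_over_50": rse_flag,
        })
        fits[cand.name] = fit
    ranked = _rank_candidates(pd.DataFrame(rows))
    ranked.attrs["fits"] = fits
    return ranked


def _rank_candidates(df: pd.DataFrame) -> pd.DataFrame:
    """Order candidate rows by BICc, then AIC, then parsimony (fewer
    parameters win exact ties); excluded candidates trail unranked."""
    ok = df[~df["excluded"]].copy()
    ok = ok.sort_values(["bicc", "aic", "n_parameters"], kind="stable")
    ranked = pd.concat([ok, df[df["excluded"]]], ignore_index=True)
    ranked["rank"] = [i + 1 if not ex else None for i, ex in enumerate(ranked["excluded"])]
    return ranked
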