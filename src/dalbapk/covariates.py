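"""Covariate formulas and the stepwise covariate model-building procedure.

Candidate covariates enter clearance or volume as power functions of a
continuous covariate normalised to a reference (cohort median), e.g.
``CL_i = CL_pop * (CrCL_i / 90)**beta * exp(eta)``, or as a proportional
shift for a binary covariate (sex; reference = male), parameterised
exponentially so the mixed-effects M-step stays linear in log space.

The search is forward inclusion followed by backward elimination on the
objective function value (-2 log L): a covariate is added if it produces the
largest drop exceeding the chi-square(1 df) critical value at ``forward_alpha``
and retained only if its removal worsens the OFV by more than the critical
value at ``backward_alpha``.  Every tested (parameter x covariate) pair is
logged with its delta-OFV; statistical criteria are quantitative only, and a
``plausibility`` column is left for manual review.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .nlme import FitResult, SaemSettings, Subject, fit_saem, log_likelihood

__all__ = [
    "CovariateEffect",
    "cockcroft_gault",
    "ckd_epi_2009",
    "StepwiseResult",
    "stepwise_search",
]


@dataclass(frozen=True)
class CovariateEffect:
    """A single covariate-parameter relation.

    ``form`` is "power" for continuous covariates (exponent ``coefficient`` on
    value/reference) or "proportional" for binary ones (fractional shift
    ``exp(coefficient) - 1`` in the non-reference category).
    """

    parameter: str           # "V" or "CL"
    covariate: str           # covariate column name
    form: str = "power"
    coefficient: float | None = None
    reference: float = 1.0

    def __post_init__(self):
        if self.form == "power" and self.reference <= 0:
            raise ValueError("power-form covariate needs a positive reference value")

    @property
    def proportional_shift(self) -> float | None:
        """For the proportional form: fractional change in the typical value
        for the non-reference category."""
        if self.form != "proportional" or self.coefficient is None:
            return None
        return math.exp(self.coefficient) - 1.0


def _norm_sex(sex) -> str:
    s = str(sex).strip().lower()
    if s in ("f", "female", "1"):
        return "female"
    if s in ("m", "male", "0"):
        return "male"
    raise ValueError(f"unrecognised sex value {sex!r}")


def cockcroft_gault(age: float, weight: float, scr: float, sex) -> float:
    """Cockcroft–Gault creatinine clearance (mL/min).

    ``(140 - age) * weight / (72 * scr)``, times 0.85 for women; age in years,
    weight in kg, serum creatinine in mg/dL.
    """
    if age <= 0 or weight <= 0:
        raise ValueError("age and weight must be positive")
    if scr <= 0:
        raise ValueError("serum creatinine must be positive")
    crcl = (140.0 - age) * weight / (72.0 * scr)
    if _norm_sex(sex) == "female":
        crcl *= 0.85
    return crcl


def ckd_epi_2009(scr: float, age: float, sex) -> float:
    """CKD-EPI 2009 creatinine eGFR (mL/min/1.73 m^2), race term omitted.

    Sex-specific constants: kappa 0.7 (women) / 0.9 (men), alpha -0.329 /
    -0.411, with the 1.018 multiplier for women.
    """
    if scr <= 0 or age <= 0:
        raise ValueError("serum creatinine and age must be positive")
    if _norm_sex(sex) == "female":
        kappa, alpha, mult = 0.7, -0.329, 1.018
    else:
        kappa, alpha, mult = 0.9, -0.411, 1.0
    ratio = scr / kappa
    return (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993 ** age
        * mult
    )


@dataclass
class StepwiseResult:
    final_effects: tuple
    final_fit: FitResult
    base_ofv: float
    final_ofv: float
    log: pd.DataFrame


_CONTINUOUS = ("age", "height", "weight", "bmi", "egfr", "crcl", "albumin", "serum_creatinine")


def _make_effect(dataset, parameter: str, covariate: str) -> CovariateEffect:
    if covariate == "sex":
        return CovariateEffect(parameter=parameter, covariate="sex", form="proportional")
    ref = float(np.median([float(s.covariates[covariate]) for s in dataset]))
    return CovariateEffect(parameter=parameter, covariate=covariate, form="power", reference=ref)


def stepwise_search(
    dataset: Sequence[Subject],
    base_fit: FitResult,
    covariates: Sequence[str],
    forward_alpha: float = 0.05,
    backward_alpha: float = 0.01,
    parameters: Sequence[str] = ("V", "CL"),
    settings: SaemSettings | None = None,
    seed: int = 0,
    ofv_method: str = "laplace",
) -> StepwiseResult:
    """Forward-inclusion / backward-elimination covariate search on V and CL.

    Candidate fits are initialised at the base estimates with a reduced SAEM
    budget.  Delta-OFV ties are broken by the larger reduction in the
    corresponding omega, then alphabetically.  Returns the final covariate
    model and a complete decision log.
    """
    dataset = list(dataset)
    if not base_fit.converged:
        raise ValueError("base fit did not converge; refusing covariate search")
    settings = settings or SaemSettings(n_exploration=200, n_smoothing=100)
    fwd_crit = float(stats.chi2.ppf(1.0 - forward_alpha, df=1))
    bwd_crit = float(stats.chi2.ppf(1.0 - backward_alpha, df=1))

    def ofv_of(fit: FitResult) -> float:
        return log_likelihood(fit, dataset, n_is_samples=settings.ofv_samples,
                              seed=seed + 77, method=ofv_method).ofv

    def refit(effects, k):
        init = dict(base_fit.theta)
        return fit_saem(
            dataset, init, settings=settings, seed=seed + 13 * k + 1,
            covariate_effects=tuple(effects),
            init_omega=dict(base_fit.omega), compute_ofv=None,
        )

    base_ofv = ofv_of(base_fit)
    current: list[CovariateEffect] = []
    current_fit = base_fit
    current_ofv = base_ofv
    rows = []
    step = 0
    k = 0

    # ---- forward inclusion
    while True:
        step += 1
        candidates = []
        for par in parameters:
            for cov in covariates:
                if any(e.parameter == par and e.covariate == cov for e in current):
                    continue
                candidates.append((par, cov))
        significant = []
        for par, cov in sorted(candidates, key=lambda pc: (pc[1], pc[0])):
            k += 1
            eff = _make_effect(dataset, par, cov)
            try:
                fit = refit(current + [eff], k)
                if not fit.converged:
                    raise RuntimeError("candidate fit non-convergent: " + ";".join(fit.flags))
                ofv = ofv_of(fit)
            except Exception as exc:
                rows.append({
                    "step": step, "direction": "forward", "parameter": par,
                    "covariate": cov, "ofv": np.nan, "delta_ofv": np.nan,
                    "significant": False, "action": "skipped", "reason": str(exc),
                    "omega_reduction": np.nan, "plausibility": "",
                })
                continue
            delta = current_ofv - ofv
            om_red = current_fit.omega[par] - fit.omega[par]
            rows.append({
                "step": step, "direction": "forward", "parameter": par,
                "covariate": cov, "ofv": ofv, "delta_ofv": delta,
                "significant": delta > fwd_crit, "action": "tested", "reason": "",
                "omega_reduction": om_red, "plausibility": "",
            })
            if delta > fwd_crit:
                significant.append((delta, om_red, cov, par, eff, fit, ofv))
        if not significant:
            break
        # largest drop wins; ties by larger omega reduction, then alphabetical
        significant.sort(key=lambda c: (-c[0], -c[1], c[2], c[3]))
        delta, _, _, _, eff, fit, ofv = significant[0]
        current.append(eff)
        current_fit, current_ofv = fit, ofv
        rows.append({
            "step": step, "direction": "forward", "parameter": eff.parameter,
            "covariate": eff.covariate, "ofv": ofv, "delta_ofv": delta,
            "significant": True, "action": "included", "reason": "",
            "omega_reduction": np.nan, "plausibility": "",
        })

    # ---- backward elimination
    changed = True
    while changed and current:
        step += 1
        changed = False
        worst = None
        for eff in sorted(current, key=lambda e: (e.covariate, e.parameter)):
            k += 1
            reduced = [e for e in current if e is not eff]
            try:
                fit = refit(reduced, k) if reduced else base_fit
                ofv = ofv_of(fit) if reduced else base_ofv
            except Exception as exc:
                rows.append({
                    "step": step, "direction": "backward", "parameter": eff.parameter,
                    "covariate": eff.covariate, "ofv": np.nan, "delta_ofv": np.nan,
                    "significant": True, "action": "skipped", "reason": str(exc),
                    "omega_reduction": np.nan, "plausibility": "",
                })
                continue
            worsens = ofv - current_ofv
            rows.append({
                "step": step, "direction": "backward", "parameter": eff.parameter,
                "covariate": eff.covariate, "ofv": ofv, "delta_ofv": worsens,
                "significant": worsens > bwd_crit, "action": "tested", "reason": "",
                "omega_reduction": np.nan, "plausibility": "",
            })
            if worsens <= bwd_crit and (worst is None or worsens < worst[0]):
                worst = (worsens, eff, fit, ofv)
        if worst is not None:
            _, eff, fit, ofv = worst
            current.remove(eff)
            current_fit, current_ofv = fit, ofv
            changed = True
            rows.append({
                "step": step, "direction": "backward", "parameter": eff.parameter,
                "covariate": eff.covariate, "ofv": ofv, "delta_ofv": np.nan,
                "significant": False, "action": "removed", "reason": "",
                "omega_reduction": np.nan, "plausibility": "",
            })

    log = pd.DataFrame(rows)
    return StepwiseResult(
        final_effects=tuple(current_fit.covariate_effects if current else ()),
        final_fit=current_fit,
        base_ofv=base_ofv,
        final_ofv=current_ofv,
        log=log,
    )
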