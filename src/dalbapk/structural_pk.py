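"""Closed-form intravenous-infusion pharmacokinetic models.

The final dalbavancin model is a one-compartment disposition model with
zero-order (constant-rate) infusion input and first-order elimination.  A
two-compartment variant is provided as a structural-model candidate for
model selection.  All solutions are analytic: a dose infused over a finite
window is the difference of two step responses (an infusion switched on at
the dose start and an equal infusion switched off at the end), and multiple
doses superpose because the kinetics are linear.

Units are fixed throughout the package: time in hours, amounts in mg,
volumes in L, clearances in L/h, concentrations in mg/L, AUC in mg*h/L.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "LLOQ",
    "DoseEvent",
    "IndividualParams",
    "PopModel",
    "Observation",
    "REFERENCE_MODEL",
    "concentration_at",
    "auc_window",
    "unbound_fraction",
    "apply_residual_error",
    "StructuralModel",
    "ONE_COMPARTMENT",
    "TWO_COMPARTMENT",
]

#: Lower limit of quantification of the bioanalytical assay (mg/L).
LLOQ = 1.0


class ParameterDomainError(ValueError):
    """Raised when a PK parameter or time argument is outside its domain."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DoseEvent:
    """A single intravenous infusion.

    Parameters
    ----------
    amount : float
        Dose amount in mg (>= 0).
    start_time : float
        Infusion start in hours from time origin (>= 0).
    infusion_duration : float
        Infusion length in hours (> 0); 0.5 h for a 30-min short infusion,
        2.0 h for an extended infusion.
    """

    amount: float
    start_time: float = 0.0
    infusion_duration: float = 0.5

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ParameterDomainError(f"dose amount must be >= 0, got {self.amount}")
        if self.start_time < 0:
            raise ParameterDomainError(
                f"dose start time must be >= 0, got {self.start_time}"
            )
        if self.infusion_duration <= 0:
            raise ParameterDomainError(
                f"infusion duration must be > 0, got {self.infusion_duration}"
            )

    @property
    def rate(self) -> float:
        """Zero-order infusion rate in mg/h."""
        return self.amount / self.infusion_duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.infusion_duration


@dataclass(frozen=True)
class IndividualParams:
    """Individual one-compartment parameters: volume V (L), clearance CL (L/h)."""

    V: float
    CL: float

    def __post_init__(self) -> None:
        if self.V <= 0 or self.CL <= 0:
            raise ParameterDomainError(
                f"V and CL must be strictly positive, got V={self.V}, CL={self.CL}"
            )

    @property
    def k(self) -> float:
        """First-order elimination rate constant CL/V (1/h)."""
        return self.CL / self.V


@dataclass(frozen=True)
class PopModel:
    """Population one-compartment model with log-normal inter-individual
    variability on V and CL and proportional residual error.

    Individual parameters are ``V_pop * exp(eta_V)`` and ``CL_pop * exp(eta_CL)``
    with ``eta ~ Normal(0, omega^2)``; an observed concentration is
    ``f * (1 + b * eps)`` with ``eps ~ Normal(0, 1)``.
    """

    V_pop: float
    CL_pop: float
    omega_V: float
    omega_CL: float
    b: float

    def __post_init__(self) -> None:
        if self.V_pop <= 0 or self.CL_pop <= 0 or self.b < 0:
            raise ParameterDomainError("V_pop, CL_pop must be > 0 and b >= 0")
        if self.omega_V < 0 or self.omega_CL < 0:
            raise ParameterDomainError("omega values must be >= 0")

    def typical(self) -> IndividualParams:
        return IndividualParams(V=self.V_pop, CL=self.CL_pop)

    def draw_individuals(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` individual (V, CL) pairs; returns an (n, 2) array."""
        eta = rng.standard_normal((n, 2))
        V = self.V_pop * np.exp(self.omega_V * eta[:, 0])
        CL = self.CL_pop * np.exp(self.omega_CL * eta[:, 1])
        return np.column_stack([V, CL])


#: Published final population estimates for a single 1,500 mg dalbavancin dose
#: in elderly patients with chronic prosthetic joint infection (total plasma
#: concentrations): V 17.9 L, CL 0.036 L/h, IIV SDs 0.200/0.290, proportional
#: error 0.120.  Used as the default truth for synthetic cohorts and as the
#: simulation model for target-attainment tables.
REFERENCE_MODEL = PopModel(V_pop=17.9, CL_pop=0.036, omega_V=0.200, omega_CL=0.290, b=0.120)


@dataclass(frozen=True)
class Observation:
    """A timed total plasma concentration (mg/L); BLQ values carry a flag."""

    time: float
    concentration: float
    below_loq: bool = False

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ParameterDomainError(f"observation time must be >= 0, got {self.time}")
        if not self.below_loq and self.concentration < 0:
            raise ParameterDomainError(
                f"concentration must be >= 0, got {self.concentration}"
            )


# ---------------------------------------------------------------------------
# One-compartment closed forms (vectorised over broadcastable arrays)
# ---------------------------------------------------------------------------


def _step_conc_1cpt(V, CL, tau):
    """Concentration response to a unit-rate (1 mg/h) infusion switched on at
    tau = 0, evaluated at elapsed time tau (0 for tau <= 0)."""
    k = CL / V
    tau = np.asarray(tau, dtype=float)
    pos = np.maximum(tau, 0.0)
    return np.where(tau > 0, -np.expm1(-k * pos) / CL, 0.0)


def _step_auc_1cpt(V, CL, tau):
    """Running integral of `_step_conc_1cpt` from 0 to tau."""
    k = CL / V
    tau = np.asarray(tau, dtype=float)
    pos = np.maximum(tau, 0.0)
    return np.where(tau > 0, (pos + np.expm1(-k * pos) / k) / CL, 0.0)


def conc_profile_1cpt(V, CL, dose_rate, dose_start, dose_duration, t):
    """Total concentration for arbitrary broadcastable parameter/dose/time arrays.

    ``dose_*`` arrays carry a trailing dose axis that is summed out; padding
    doses with rate 0 is allowed.
    """
    V = np.asarray(V, dtype=float)[..., None]
    CL = np.asarray(CL, dtype=float)[..., None]
    t = np.asarray(t, dtype=float)[..., None]
    on = _step_conc_1cpt(V, CL, t - dose_start)
    off = _step_conc_1cpt(V, CL, t - dose_start - dose_duration)
    return np.sum(dose_rate * (on - off), axis=-1)


def _cum_auc_1cpt(V, CL, dose_rate, dose_start, dose_duration, t):
    V = np.asarray(V, dtype=float)[..., None]
    CL = np.asarray(CL, dtype=float)[..., None]
    t = np.asarray(t, dtype=float)[..., None]
    on = _step_auc_1cpt(V, CL, t - dose_start)
    off = _step_auc_1cpt(V, CL, t - dose_start - dose_duration)
    return np.sum(dose_rate * (on - off), axis=-1)


def _dose_arrays(doses: Sequence[DoseEvent]):
    if len(doses) == 0:
        return (np.zeros(1), np.zeros(1), np.ones(1))
    rate = np.array([d.rate for d in doses], dtype=float)
    start = np.array([d.start_time for d in doses], dtype=float)
    dur = np.array([d.infusion_duration for d in doses], dtype=float)
    return rate, start, dur


def concentration_at(params: IndividualParams, doses: Sequence[DoseEvent], t):
    """Total plasma concentration at time(s) ``t`` (hours) under superposition
    of all infusions.  ``t`` may be a scalar or array; negative times raise."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ParameterDomainError("time must be >= 0")
    rate, start, dur = _dose_arrays(doses)
    out = conc_profile_1cpt(params.V, params.CL, rate, start, dur, t_arr)
    return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def auc_window(params: IndividualParams, doses: Sequence[DoseEvent], t1: float, t2: float) -> float:
    """Exact analytic AUC of the total-concentration profile over [t1, t2].

    ``t2 = np.inf`` gives the infinite-horizon exposure, which equals
    total dose / CL.
    """
    if t1 < 0:
        raise ParameterDomainError("t1 must be >= 0")
    if t2 < t1:
        raise ParameterDomainError(f"need t1 <= t2, got [{t1}, {t2}]")
    rate, start, dur = _dose_arrays(doses)
    f1 = float(_cum_auc_1cpt(params.V, params.CL, rate, start, dur, t1))
    if np.isinf(t2):
        total = float(np.sum(rate * dur)) / params.CL
        return total - f1
    f2 = float(_cum_auc_1cpt(params.V, params.CL, rate, start, dur, t2))
    return f2 - f1


def unbound_fraction(protein_binding_percent: float) -> float:
    """Unbound (free) fraction fu from a protein-binding percentage."""
    if not 0 <= protein_binding_percent <= 100:
        raise ParameterDomainError(
            f"protein binding must be in [0, 100] %, got {protein_binding_percent}"
        )
    return (100.0 - protein_binding_percent) / 100.0


def apply_residual_error(pred, b: float, noise):
    """Proportional residual-error model: ``pred * (1 + b * noise)``."""
    if b < 0:
        raise ParameterDomainError("error magnitude b must be >= 0")
    out = np.asarray(pred, dtype=float) * (1.0 + b * np.asarray(noise, dtype=float))
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Structural-model abstraction for the estimation engine
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructuralModel:
    """A disposition model usable by the mixed-effects engine.

    ``predict`` is fully vectorised: ``theta`` has shape (..., n_params) on the
    natural scale, ``times`` shape (..., T); dose arrays carry a trailing dose
    axis broadcastable against the leading dimensions.
    """

    name: str
    param_names: tuple

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def predict(self, theta, dose_rate, dose_start, dose_duration, times):
        raise NotImplementedError


class _OneCompartment(StructuralModel):
    def predict(self, theta, dose_rate, dose_start, dose_duration, times):
        V = theta[..., 0]
        CL = theta[..., 1]
        return conc_profile_1cpt(V, CL, dose_rate, dose_start, dose_duration, times)


class _TwoCompartment(StructuralModel):
    """Two-compartment model parameterised as (V1, CL, Q, V2).

    Central concentration for a unit-rate step infusion is a sum of two
    exponentials with hybrid rate constants lambda1/lambda2; finite infusions
    and multiple doses follow by step-response superposition.
    """

    def predict(self, theta, dose_rate, dose_start, dose_duration, times):
        V1 = theta[..., 0][..., None]
        CL = theta[..., 1][..., None]
        Q = theta[..., 2][..., None]
        V2 = theta[..., 3][..., None]
        k10 = CL / V1
        k12 = Q / V1
        k21 = Q / V2
        s = k10 + k12 + k21
        disc = np.sqrt(np.maximum(s * s - 4.0 * k10 * k21, 0.0))
        # lam2 via the product lam1*lam2 = k10*k21 avoids cancellation when
        # the compartments are weakly coupled (disc ~ s)
        lam1 = 0.5 * (s + disc)
        lam2 = k10 * k21 / lam1
        gap = np.maximum(lam1 - lam2, 1e-12 * s)
        c1 = -(k21 - lam1) / (lam1 * gap) / V1
        c2 = (k21 - lam2) / (lam2 * gap) / V1

        t = np.asarray(times, dtype=float)[..., None]

        def step(tau):
            pos = np.maximum(tau, 0.0)
            val = c1 * -np.expm1(-lam1 * pos) + c2 * -np.expm1(-lam2 * pos)
            return np.where(tau > 0, val, 0.0)

        on = step(t - dose_start)
        off = step(t - dose_start - dose_duration)
        return np.sum(dose_rate * (on - off), axis=-1)


ONE_COMPARTMENT = _OneCompartment(name="one_compartment", param_names=("V", "CL"))
TWO_COMPARTMENT = _TwoCompartment(name="two_compartment", param_names=("V1", "CL", "Q", "V2"))
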