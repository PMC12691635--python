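import math

import numpy as np
import pytest

from dalbapk import (
    REFERENCE_MODEL,
    DoseEvent,
    IndividualParams,
    Observation,
    PopModel,
    StudyDesign,
    Subject,
    concentration_at,
    fit_saem,
    generate_pk_dataset,
    initial_estimates,
)

STANDARD_DOSE = DoseEvent(amount=1500.0, start_time=0.0, infusion_duration=0.5)


@pytest.fixture(scope="session")
def standard_dose():
    return STANDARD_DOSE


@pytest.fixture(scope="session")
def study_dataset():
    """One synthetic sparse cohort at the default study design."""
    return generate_pk_dataset(StudyDesign(), REFERENCE_MODEL, seed=1)


@pytest.fixture(scope="session")
def study_fit(study_dataset):
    """SAEM fit of the default synthetic cohort (shared across tests)."""
    init = initial_estimates(study_dataset)
    return fit_saem(study_dataset, init, seed=7, compute_ofv=None)


def make_rich_subject(params: IndividualParams, b: float, seed: int, n_obs: int = 24,
                      dose: DoseEvent = STANDARD_DOSE, sid: str = "rich") -> Subject:
    """A single subject with dense sampling over the full washout."""
    rng = np.random.default_rng(seed)
    ts = np.linspace(1.0, 700.0, n_obs)
    obs = []
    for t in ts:
        c = concentration_at(params, [dose], t) * (1.0 + b * rng.standard_normal())
        obs.append(Observation(time=float(t), concentration=float(max(c, 1e-9))))
    return Subject(id=sid, doses=[dose], observations=obs)


def simulate_cohort_rich(n: int, model: PopModel, times, seed: int,
                         dose: DoseEvent = STANDARD_DOSE) -> list:
    """Self-simulated cohort with a shared fixed sampling schedule."""
    rng = np.random.default_rng(seed)
    times = np.asarray(times, dtype=float)
    subjects = []
    for i in range(n):
        ev, ec = rng.standard_normal(2)
        p = IndividualParams(
            V=model.V_pop * math.exp(model.omega_V * ev),
            CL=model.CL_pop * math.exp(model.omega_CL * ec),
        )
        f = np.array([concentration_at(p, [dose], t) for t in times])
        y = f * (1.0 + model.b * rng.standard_normal(len(times)))
        subjects.append(Subject(
            id=f"R{i:03d}", doses=[dose],
            observations=[Observation(float(t), float(max(c, 1e-9))) for t, c in zip(times, y)],
        ))
    return subjects
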