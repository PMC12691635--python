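"""Synthetic cohort generation and clinical-outcome aggregates.

Two distinct artefacts live here:

* :func:`generate_pk_dataset` draws a synthetic sparse-sampling PK dataset
  emulating the observed study design — ~18 elderly subjects, a single
  1,500 mg dalbavancin infusion (30 min or 2 h), and 1–3 trough-like total
  concentrations per subject spread over days 8–30 — from a known population
  model.  It is the workhorse for parameter-recovery, diagnostic-calibration
  and covariate type-I-error studies, since the original patient-level data
  are not public.

* :func:`build_cohort_fixture` returns a deterministic 20-patient clinical
  record set whose aggregate counts equal the published cohort summaries
  (sex, joint, isolates, second-stage surgery, cure).  Patient-level values
  that were never published (exact ages, follow-up days, ...) are synthetic,
  constructed only to reproduce the printed medians and interquartile
  intervals; they are labelled as such.

Medians use the mean-of-middle-two convention and quartiles the type-7
(linear interpolation) definition throughout.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import ckd_epi_2009, cockcroft_gault
from .nlme import Subject
from .structural_pk import LLOQ, DoseEvent, Observation, PopModel, REFERENCE_MODEL, concentration_at

__all__ = [
    "StudyDesign",
    "generate_pk_dataset",
    "build_cohort_fixture",
    "load_cohort_fixture",
    "cohort_summary",
]


@dataclass(frozen=True)
class StudyDesign:
    """Sampling/dosing design of the synthetic PK cohort.

    Defaults emulate the modelled cohort: 18 subjects, one 1,500 mg dose
    (half short 0.5 h infusions, half 2 h extended infusions, mirroring the
    two participating centres), 1–3 samples per subject drawn from weekly
    follow-up windows at days 8–14, 18–23 and 26–30, and elderly covariates
    with preserved renal function and normal albumin.
    """

    n_subjects: int = 18
    dose_amount: float = 1500.0
    infusion_durations: tuple = (0.5, 2.0)
    #: probability of drawing 1, 2 or 3 samples; mean ~1.3 samples/subject
    #: matches the observed 23 concentrations over 18 modelled patients.
    samples_per_subject_probs: tuple = (0.70, 0.25, 0.05)
    sampling_windows_days: tuple = ((8.0, 14.0), (18.0, 23.0), (26.0, 30.0))
    age_median: float = 75.5
    age_sd: float = 7.0
    female_fraction: float = 0.70
    albumin_median: float = 45.0
    albumin_sd: float = 4.0
    scr_median: float = 0.80
    scr_sd: float = 0.15


def _draw_covariates(design: StudyDesign, rng: np.random.Generator) -> dict:
    female = rng.random() < design.female_fraction
    sex = "female" if female else "male"
    age = float(np.clip(rng.normal(design.age_median, design.age_sd), 55, 92))
    height = float(rng.normal(158 if female else 170, 6))
    weight = float(np.clip(rng.normal(66 if female else 76, 10), 42, 110))
    bmi = weight / (height / 100) ** 2
    scr = float(np.clip(rng.normal(design.scr_median, design.scr_sd), 0.45, 1.4))
    albumin = float(np.clip(rng.normal(design.albumin_median, design.albumin_sd), 32, 52))
    return {
        "age": age,
        "sex": sex,
        "height": height,
        "weight": weight,
        "bmi": bmi,
        "serum_creatinine": scr,
        "albumin": albumin,
        "egfr": ckd_epi_2009(scr, age, sex),
        "crcl": cockcroft_gault(age, weight, scr, sex),
    }


def generate_pk_dataset(
    design: StudyDesign,
    truth: PopModel = REFERENCE_MODEL,
    seed: int = 0,
    return_params: bool = False,
):
    """Simulate a sparse-sampling PK dataset from ``truth`` under ``design``.

    Concentrations are model predictions perturbed by proportional error;
    values below the 1.0 mg/L quantification limit are flagged BLQ.
    Deterministic given ``seed``.  With ``return_params`` the simulated true
    individual parameters are returned alongside as a DataFrame (columns
    V, CL, eta_V, eta_CL), for estimator-validation studies.
    """
    rng = np.random.default_rng(seed)
    subjects = []
    true_rows = []
    for i in range(design.n_subjects):
        dur = design.infusion_durations[i % len(design.infusion_durations)]
        dose = DoseEvent(amount=design.dose_amount, start_time=0.0, infusion_duration=dur)
        eta_v, eta_cl = rng.standard_normal(2)
        from .structural_pk import IndividualParams

        params = IndividualParams(
            V=truth.V_pop * math.exp(truth.omega_V * eta_v),
            CL=truth.CL_pop * math.exp(truth.omega_CL * eta_cl),
        )
        true_rows.append({"V": params.V, "CL": params.CL,
                          "eta_V": truth.omega_V * eta_v,
                          "eta_CL": truth.omega_CL * eta_cl})
        n_samp = 1 + int(rng.choice(3, p=design.samples_per_subject_probs))
        windows = rng.choice(len(design.sampling_windows_days), size=n_samp, replace=False)
        obs = []
        for w in sorted(windows):
            lo, hi = design.sampling_windows_days[w]
            t = float(rng.uniform(lo, hi)) * 24.0
            pred = concentration_at(params, [dose], t)
            conc = pred * (1.0 + truth.b * rng.standard_normal())
            conc = max(conc, 0.0)
            obs.append(Observation(time=t, concentration=conc, below_loq=conc < LLOQ))
        subjects.append(
            Subject(id=f"SYN{i + 1:03d}", doses=[dose], observations=obs,
                    covariates=_draw_covariates(design, rng))
        )
    if return_params:
        return subjects, pd.DataFrame(true_rows, index=[s.id for s in subjects])
    return subjects


# ---------------------------------------------------------------------------
# Clinical-outcomes fixture
# ---------------------------------------------------------------------------

# Patient-level free fields below (ages, intervals, follow-up, renal values)
# are synthetic: they are chosen so that the type-7 medians/IQIs reproduce the
# published cohort summaries, with the published aggregate counts exact.
_JOINTS = ["hip"] * 11 + ["knee"] * 6 + ["shoulder"] * 2 + ["ankle"]
_SEXES = ["female"] * 14 + ["male"] * 6

# 24 isolates over 20 episodes: 17 CoNS (12 S. epidermidis, 1 S. lugdunensis,
# 2 S. capitis, 1 S. hominis, 1 S. pettenkoferi), 6 C. acnes, 1 E. faecalis.
# The 4 polymicrobial episodes each pair C. acnes with a CoNS.
_ISOLATES = (
    [["Staphylococcus epidermidis", "Cutibacterium acnes"]] * 3
    + [["Staphylococcus capitis", "Cutibacterium acnes"]]
    + [["Staphylococcus epidermidis"]] * 9
    + [["Staphylococcus lugdunensis"]]
    + [["Staphylococcus capitis"]]
    + [["Staphylococcus hominis"]]
    + [["Staphylococcus pettenkoferi"]]
    + [["Cutibacterium acnes"]] * 2
    + [["Enterococcus faecalis"]]
)

# Constructed to the published summaries (n = 20): age median 75.5 (IQI 69-79);
# prior IV median 11.5 d (IQI 10-16); GFR median 90 (IQI 75.8-96.3);
# albumin median 45 g/L (IQI 38-47).
_AGES = [62, 65, 67, 68, 69, 69, 71, 72, 74, 75, 76, 77, 78, 78, 79, 79, 81, 83, 85, 88]
_PRIOR_IV = [8, 9, 9, 10, 10, 10, 10, 11, 11, 11, 12, 12, 13, 14, 16, 16, 17, 18, 20, 22]
_GFR = [62.0, 68.0, 71.0, 74.0, 75.8, 75.8, 80.0, 84.0, 88.0, 89.0, 91.0, 93.0,
        94.0, 95.0, 96.3, 96.3, 98.0, 101.0, 104.0, 108.0]
_ALBUMIN = [33, 35, 36, 37, 38, 38, 40, 42, 44, 44, 46, 46, 46, 46, 47, 47, 48, 49, 50, 51]

# Among the 19 patients with second-stage surgery: interval from first surgery
# median 134 d (IQI 85-175); follow-up after second stage median 693 d
# (IQI 630-824).
_INTERVAL = [70, 76, 80, 85, 85, 85, 100, 112, 125, 134, 140, 152, 160, 175, 175,
             190, 220, 260, 300]
_FOLLOWUP = [520, 560, 600, 630, 630, 630, 662, 680, 685, 693, 720, 760, 800, 824,
             824, 860, 910, 980, 1040]


def build_cohort_fixture() -> pd.DataFrame:
    """Deterministic 20-patient clinical fixture matching the published cohort
    aggregates; one row per patient."""
    rows = []
    # patient 20 declines second-stage surgery; patient 1 has the single
    # positive intraoperative culture at second stage (initially C. acnes,
    # regrowth with CoNS).
    second_stage = [True] * 19 + [False]
    positive_culture = [True] + [False] * 19
    iv_agent = ["vancomycin"] * 15 + ["daptomycin"] * 5
    interval_iter = iter(_INTERVAL)
    fup_iter = iter(_FOLLOWUP)
    # order isolates so that patient 1 (positive second-stage culture) had a
    # C. acnes-only initial infection, as reported.
    isolates = [_ISOLATES[17]] + _ISOLATES[:17] + _ISOLATES[18:]
    for i in range(20):
        has_ss = second_stage[i]
        rows.append({
            "patient_id": f"P{i + 1:02d}",
            "sex": _SEXES[i],
            "age_years": _AGES[i],
            "joint": _JOINTS[i],
            "isolates": ";".join(isolates[i]),
            "polymicrobial": len(isolates[i]) > 1,
            "prior_iv_agent": iv_agent[i],
            "prior_iv_days": _PRIOR_IV[i],
            "gfr_ml_min": _GFR[i],
            "albumin_g_l": _ALBUMIN[i],
            "second_stage_surgery": has_ss,
            "second_stage_culture_positive": positive_culture[i] if has_ss else None,
            "surgery_interval_days": next(interval_iter) if has_ss else None,
            "followup_days": next(fup_iter) if has_ss else None,
        })
    return pd.DataFrame(rows)


def load_cohort_fixture() -> pd.DataFrame:
    """Read the packaged fixture CSV (identical to :func:`build_cohort_fixture`)."""
    with importlib.resources.files("dalbapk.data").joinpath("cohort_fixture.csv").open() as fh:
        df = pd.read_csv(fh)
    for col in ("polymicrobial", "second_stage_surgery"):
        df[col] = df[col].astype(bool)
    df["second_stage_culture_positive"] = df["second_stage_culture_positive"].astype("boolean")
    return df


def _median_iqi(values) -> tuple:
    v = np.asarray([x for x in values if x is not None and not pd.isna(x)], dtype=float)
    return (
        float(np.median(v)),
        float(np.quantile(v, 0.25)),
        float(np.quantile(v, 0.75)),
    )


def cohort_summary(fixture: pd.DataFrame) -> dict:
    """Aggregate report: counts, percentages (1 decimal), medians/IQIs, and
    cure rates.  Microbiological cure = patients with negative second-stage
    intraoperative cultures / patients undergoing second-stage surgery."""
    n = len(fixture)
    out: dict = {"n_patients": n}
    out["n_female"] = int((fixture["sex"] == "female").sum())
    out["pct_female"] = round(100.0 * out["n_female"] / n, 1)
    out["joints"] = fixture["joint"].value_counts().to_dict()

    iso_lists = [s.split(";") for s in fixture["isolates"]]
    flat = [x for lst in iso_lists for x in lst]
    n_iso = len(flat)
    cons_species = {
        "Staphylococcus epidermidis", "Staphylococcus lugdunensis",
        "Staphylococcus capitis", "Staphylococcus hominis",
        "Staphylococcus pettenkoferi",
    }
    out["n_isolates"] = n_iso
    out["n_cons"] = sum(1 for x in flat if x in cons_species)
    out["pct_cons"] = round(100.0 * out["n_cons"] / n_iso, 1)
    out["n_s_epidermidis"] = flat.count("Staphylococcus epidermidis")
    out["n_c_acnes"] = flat.count("Cutibacterium acnes")
    out["n_e_faecalis"] = flat.count("Enterococcus faecalis")
    out["n_polymicrobial"] = int(fixture["polymicrobial"].sum())

    ss = fixture[fixture["second_stage_surgery"].astype(bool)]
    out["n_second_stage"] = len(ss)
    if len(ss):
        neg = int((~ss["second_stage_culture_positive"].astype(bool)).sum())
        out["n_second_stage_culture_negative"] = neg
        out["microbiological_cure_pct"] = round(100.0 * neg / len(ss), 1)
    else:
        out["n_second_stage_culture_negative"] = 0
        out["microbiological_cure_pct"] = None
    # clinical cure: no failure/relapse reported in any patient (the patient
    # without second-stage surgery retained the spacer and was clinically cured)
    out["clinical_cure_pct"] = 100.0

    for col, key in [
        ("age_years", "age"),
        ("prior_iv_days", "prior_iv_days"),
        ("gfr_ml_min", "gfr"),
        ("albumin_g_l", "albumin"),
        ("surgery_interval_days", "surgery_interval_days"),
        ("followup_days", "followup_days"),
    ]:
        med, lo, hi = _median_iqi(fixture[col])
        out[f"{key}_median"] = med
        out[f"{key}_iqi"] = (lo, hi)
    return out
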