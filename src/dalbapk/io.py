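"""Dataset and configuration I/O.

The PK dataset format is a long CSV with one row per event: ``ID``, ``TIME``
(h from first dose), ``DV`` (mg/L, empty on dose rows), ``AMT`` (mg, dose
rows only), ``DUR`` (infusion hours), ``EVID`` (1 dose / 0 observation),
``BLQ`` (0/1) plus covariate columns repeated on every row.  Missing DV on
dose rows is encoded as an empty field rather than a placeholder token.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .nlme import SaemSettings, Subject
from .structural_pk import LLOQ, DoseEvent, Observation

__all__ = [
    "read_dataset",
    "write_dataset",
    "PipelineConfig",
    "load_config",
    "save_config",
    "config_hash",
]

_COVARIATE_COLUMNS = (
    "age", "sex", "height", "weight", "bmi", "serum_creatinine",
    "albumin", "egfr", "crcl",
)
_CORE_COLUMNS = ("ID", "TIME", "DV", "AMT", "DUR", "EVID", "BLQ")


class DatasetFormatError(ValueError):
    pass


def write_dataset(dataset, path) -> None:
    """Write subjects to the long CSV format (lossless round trip)."""
    rows = []
    for subj in dataset:
        cov = {c: subj.covariates.get(c, "") for c in _COVARIATE_COLUMNS}
        for dose in subj.doses:
            rows.append({"ID": subj.id, "TIME": dose.start_time, "DV": "",
                         "AMT": dose.amount, "DUR": dose.infusion_duration,
                         "EVID": 1, "BLQ": 0, **cov})
        for obs in subj.observations:
            rows.append({"ID": subj.id, "TIME": obs.time, "DV": obs.concentration,
                         "AMT": "", "DUR": "", "EVID": 0,
                         "BLQ": int(obs.below_loq), **cov})
    pd.DataFrame(rows, columns=list(_CORE_COLUMNS) + list(_COVARIATE_COLUMNS)).to_csv(
        path, index=False
    )


def read_dataset(path) -> list:
    """Parse and validate the long CSV; raises with row numbers on malformed
    rows and rejects dose-free subjects and pre-dose observations."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"ID": str}, float_precision="round_trip")
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise DatasetFormatError(f"{path}: missing required columns {missing}")

    subjects: dict[str, Subject] = {}
    for pos, row in df.iterrows():
        line_no = pos + 2  # header is line 1
        sid = row["ID"]
        if pd.isna(sid) or sid == "":
            raise DatasetFormatError(f"{path}:{line_no}: empty subject ID")
        subj = subjects.setdefault(sid, Subject(id=sid))
        try:
            evid = int(row["EVID"])
            t = float(row["TIME"])
            if evid == 1:
                subj.doses.append(DoseEvent(
                    amount=float(row["AMT"]),
                    start_time=t,
                    infusion_duration=float(row["DUR"]),
                ))
            elif evid == 0:
                blq = bool(int(row["BLQ"])) if not pd.isna(row["BLQ"]) else False
                dv = row["DV"]
                if pd.isna(dv):
                    raise ValueError("observation row with empty DV")
                dv = float(dv)
                blq = blq or dv < LLOQ
                subj.observations.append(Observation(time=t, concentration=dv, below_loq=blq))
            else:
                raise ValueError(f"EVID must be 0 or 1, got {evid}")
        except (TypeError, ValueError) as exc:
            raise DatasetFormatError(f"{path}:{line_no}: {exc}") from exc
        if not subj.covariates:
            for c in _COVARIATE_COLUMNS:
                if c in df.columns and not pd.isna(row[c]) and row[c] != "":
                    v = row[c]
                    subj.covariates[c] = str(v) if c == "sex" else float(v)

    out = []
    for sid, subj in subjects.items():
        if not subj.doses:
            raise DatasetFormatError(f"{path}: subject {sid} has no dose event")
        try:
            subj.validate(for_estimation=False)
        except ValueError as exc:
            raise DatasetFormatError(f"{path}: {exc}") from exc
        out.append(subj)
    return out


# ---------------------------------------------------------------------------
# Pipeline configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """End-to-end run configuration; every stochastic stage has its own seed.

    Shipped defaults follow the published analysis settings: 1,000 bootstrap
    resamples, 500 VPC simulations, 1,000 NPDE replicates, 1,000 PTA
    profiles.
    """

    dataset_path: str = "dataset.csv"
    output_dir: str = "output"
    # model initials (None -> data-derived pooled initials)
    init_V: float | None = None
    init_CL: float | None = None
    init_omega: float = 0.3
    init_b: float = 0.2
    # SAEM
    saem_exploration: int = 500
    saem_smoothing: int = 200
    saem_chains: int = 2
    fit_seed: int = 101
    # diagnostics
    bootstrap_resamples: int = 1000
    bootstrap_seed: int = 202
    npde_K: int = 1000
    npde_seed: int = 303
    vpc_simulations: int = 500
    vpc_seed: int = 404
    # covariate search
    covariates: tuple = ("age", "sex", "weight", "bmi", "egfr", "crcl", "albumin")
    forward_alpha: float = 0.05
    backward_alpha: float = 0.01
    covariate_seed: int = 505
    # PTA
    pta_profiles: int = 1000
    pta_seed: int = 12345
    pta_only: bool = False
    # supplied model for pta_only runs (V, CL, omega_V, omega_CL, b)
    supplied_model: tuple | None = None
    stages: tuple = ("fit", "diagnostics", "covariates", "pta")

    def saem_settings(self) -> SaemSettings:
        return SaemSettings(
            n_exploration=self.saem_exploration,
            n_smoothing=self.saem_smoothing,
            n_chains=self.saem_chains,
        )


def save_config(config: PipelineConfig, path) -> None:
    data = dataclasses.asdict(config)
    data = {k: (list(v) if isinstance(v, tuple) else v) for k, v in data.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_config(path) -> PipelineConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    fields = {f.name: f for f in dataclasses.fields(PipelineConfig)}
    kwargs = {}
    for key, val in data.items():
        if key not in fields:
            raise DatasetFormatError(f"unknown config key {key!r}")
        if isinstance(val, list):
            val = tuple(val)
        kwargs[key] = val
    return PipelineConfig(**kwargs)


def config_hash(config: PipelineConfig) -> str:
    data = dataclasses.asdict(config)
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
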