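"""Run configuration: one YAML file describing a whole analysis.

Minimal example::

    data:
      path: patients.csv
    lifetable:
      path: lifetable.csv
      columns: {stratum: stratum}
    model:
      baseline_df: 5
      age_df: 3
      td_df: 3
      td_vars: [exposure, age, mediator]
      mediator_exposure_interaction: true
      mediator_levels: [I, II, III, IV]
    mediator_model:
      age_df: 3
    standardization:
      t_start: 0.05
      t_stop: 5.0
      t_step: 0.05
      scales: [net, AC2]
    bootstrap:
      k: 500
      seed: 1
      method: normal
    avoidable:
      nstar: most_recent_year    # or a number, or per_1000
    output_dir: results
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .errors import ConfigurationError
from .io import PatientSchema
from .lifetable import LifetableSchema

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    data_path: str
    lifetable_path: str
    output_dir: str = "results"
    patient_schema: PatientSchema = field(default_factory=PatientSchema)
    lifetable_schema: LifetableSchema = field(default_factory=LifetableSchema)
    mediator_levels: tuple = ("I", "II", "III", "IV")
    baseline_df: int = 5
    age_df: int = 3
    td_df: int = 3
    td_vars: tuple = ("exposure", "age", "mediator")
    mediator_exposure_interaction: bool = True
    orthogonalize: bool = False
    mediator_age_df: int = 3
    t_start: float = 0.05
    t_stop: float = 5.0
    t_step: float = 0.05
    scales: tuple = ("net", "AC2")
    allow_unstratified_ac1: bool = False
    bootstrap_k: int = 500
    bootstrap_seed: int = 0
    bootstrap_method: str = "normal"
    nstar: object = "most_recent_year"
    raw: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    data = raw.get("data") or {}
    lt = raw.get("lifetable") or {}
    if "path" not in data:
        raise ConfigurationError("config is missing data.path")
    if "path" not in lt:
        raise ConfigurationError("config is missing lifetable.path")
    model = raw.get("model") or {}
    med = raw.get("mediator_model") or {}
    std = raw.get("standardization") or {}
    boot = raw.get("bootstrap") or {}
    avd = raw.get("avoidable") or {}
    return RunConfig(
        data_path=data["path"],
        lifetable_path=lt["path"],
        output_dir=raw.get("output_dir", "results"),
        patient_schema=PatientSchema.from_mapping(data.get("columns")),
        lifetable_schema=LifetableSchema(
            **{**(lt.get("columns") or {}), "sex_map": lt.get("sex_map")}
        ),
        mediator_levels=tuple(model.get("mediator_levels", ("I", "II", "III", "IV"))),
        baseline_df=int(model.get("baseline_df", 5)),
        age_df=int(model.get("age_df", 3)),
        td_df=int(model.get("td_df", 3)),
        td_vars=tuple(model.get("td_vars", ("exposure", "age", "mediator"))),
        mediator_exposure_interaction=bool(model.get("mediator_exposure_interaction", True)),
        orthogonalize=bool(model.get("orthogonalize", False)),
        mediator_age_df=int(med.get("age_df", 3)),
        t_start=float(std.get("t_start", 0.05)),
        t_stop=float(std.get("t_stop", 5.0)),
        t_step=float(std.get("t_step", 0.05)),
        scales=tuple(std.get("scales", ("net", "AC2"))),
        allow_unstratified_ac1=bool(std.get("allow_unstratified_ac1", False)),
        bootstrap_k=int(boot.get("k", 500)),
        bootstrap_seed=int(boot.get("seed", 0)),
        bootstrap_method=str(boot.get("method", "normal")),
        nstar=avd.get("nstar", "most_recent_year"),
        raw=raw,
    )
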