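"""Staged analysis workflow behind the command-line interface.

The stages mirror the estimation algorithm: fit both models, standardize to
obtain the mediation surfaces with bootstrap intervals, then translate the
among-exposed contrasts into avoidable deaths.  Every stage writes plain-text
artifacts (JSON fit documents, tidy CSV tables, a JSON manifest recording
knots, seeds, k and N*) so a run is reconstructible from its output directory.
"""

from __future__ import annotations

import json
import os

import numpy as np

from . import avoidable as avd_mod
from . import mediation as med_mod
from .config import RunConfig
from .errors import ConfigurationError
from .io import read_patients
from .lifetable import expected_survival_matrix, load_lifetable
from .mediator import MediatorFit, default_mediator_spec, fit_mediator
from .relsurv import RelSurvFit, default_relsurv_spec, fit_relsurv
from .uncertainty import BootstrapConfig, bootstrap_cis

__all__ = ["run_fit", "run_mediate", "run_avoidable"]


def _load_inputs(cfg: RunConfig):
    if not os.path.exists(cfg.lifetable_path):
        raise ConfigurationError(f"lifetable path {cfg.lifetable_path!r} does not exist")
    if not os.path.exists(cfg.data_path):
        raise ConfigurationError(f"data path {cfg.data_path!r} does not exist")
    lt = load_lifetable(cfg.lifetable_path, cfg.lifetable_schema)
    data = read_patients(cfg.data_path, cfg.patient_schema, mediator_levels=cfg.mediator_levels)
    return data, lt


def _time_grid(cfg: RunConfig):
    return med_mod.default_time_grid(cfg.t_start, cfg.t_stop, cfg.t_step)


def run_fit(cfg: RunConfig) -> dict:
    """Fit the excess-hazard and mediator models; serialize both."""
    data, lt = _load_inputs(cfg)
    os.makedirs(cfg.output_dir, exist_ok=True)
    stratum_col = "stratum" if lt.stratified else None
    rs_spec = default_relsurv_spec(
        data,
        cfg.mediator_levels,
        baseline_df=cfg.baseline_df,
        age_df=cfg.age_df,
        td_df=cfg.td_df,
        td_vars=cfg.td_vars,
        mediator_exposure_interaction=cfg.mediator_exposure_interaction,
        orthogonalize=cfg.orthogonalize,
    )
    rs = fit_relsurv(data, lt, rs_spec, stratum_col=stratum_col)
    mf = fit_mediator(data, default_mediator_spec(data, cfg.mediator_levels, cfg.mediator_age_df))
    rs_path = os.path.join(cfg.output_dir, "relsurv_fit.json")
    mf_path = os.path.join(cfg.output_dir, "mediator_fit.json")
    rs.save(rs_path)
    mf.save(mf_path)
    report = {
        "relsurv": {
            "loglik": rs.loglik,
            "grad_norm": rs.grad_norm,
            "iterations": rs.n_iter,
            "n": rs.n,
            "n_events": rs.n_events,
            "baseline_knots": list(rs.spec.baseline.knots),
        },
        "mediator": {"loglik": mf.loglik, "n": mf.n},
        "paths": {"relsurv": rs_path, "mediator": mf_path},
    }
    with open(os.path.join(cfg.output_dir, "fit_report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    return report


def _load_fits(cfg: RunConfig):
    rs = RelSurvFit.load(os.path.join(cfg.output_dir, "relsurv_fit.json"))
    mf = MediatorFit.load(os.path.join(cfg.output_dir, "mediator_fit.json"))
    return rs, mf


def run_mediate(cfg: RunConfig) -> dict:
    """Mediation surfaces (net and requested all-cause scales) with CIs."""
    data, lt = _load_inputs(cfg)
    rs, mf = _load_fits(cfg)
    t_grid = _time_grid(cfg)
    stratum_col = "stratum" if lt.stratified else None
    boot = BootstrapConfig(k=cfg.bootstrap_k, seed=cfg.bootstrap_seed, method=cfg.bootstrap_method)
    sstar_cache: dict = {}
    engine = med_mod.StandardizationEngine(rs, mf, data, t_grid)
    written = {}
    for setting in cfg.scales:
        def point_surface(rs_params, mf_params, setting=setting):
            if setting == "net":
                ms = med_mod.mediation_effects_net(
                    rs, mf, data, t_grid,
                    rs_params=rs_params, mf_params=mf_params, engine=engine,
                )
            else:
                ms = med_mod.mediation_effects_allcause(
                    rs,
                    mf,
                    lt,
                    data,
                    t_grid,
                    mode=setting,
                    stratum_col=stratum_col,
                    allow_unstratified=cfg.allow_unstratified_ac1,
                    rs_params=rs_params,
                    mf_params=mf_params,
                    engine=engine,
                    sstar_cache=sstar_cache,
                )
            return ms

        ms_point = point_surface(None, None)
        res = bootstrap_cis(
            lambda rp, mp: {k: v for k, v in point_surface(rp, mp).estimates.items() if k != "PM"},
            rs,
            mf,
            boot,
        )
        ms_point.ci = res.ci
        path = os.path.join(cfg.output_dir, f"mediation_{setting.lower()}.csv")
        med_mod.surface_to_frame(ms_point).to_csv(path, index=False)
        written[setting] = path
    _write_manifest(cfg, {"stage": "mediate", "outputs": written, "k": boot.k, "seed": boot.seed})
    return written


def _resolve_nstar(cfg: RunConfig, data) -> tuple:
    cand = avd_mod.candidate_nstar(data)
    if isinstance(cfg.nstar, (int, float)):
        return float(cfg.nstar), "explicit"
    if cfg.nstar in cand:
        return float(cand[cfg.nstar]), str(cfg.nstar)
    raise ConfigurationError(
        f"nstar must be a number or one of {sorted(k for k in cand if k != 'most_recent_year_label')}"
    )


def run_avoidable(cfg: RunConfig) -> dict:
    """Avoidable-deaths curves (scenarios 1 and 2) among the exposed."""
    data, lt = _load_inputs(cfg)
    rs, mf = _load_fits(cfg)
    t_grid = _time_grid(cfg)
    stratum_col = "stratum" if lt.stratified else None
    exposed = med_mod.restrict(data, lambda d: d["exposure"] == 1)
    nstar, nstar_source = _resolve_nstar(cfg, data)
    sstar = expected_survival_matrix(
        lt, exposed, t_grid, stratum_col=stratum_col if lt.stratified else None
    )
    boot = BootstrapConfig(k=cfg.bootstrap_k, seed=cfg.bootstrap_seed, method=cfg.bootstrap_method)
    engine = med_mod.StandardizationEngine(rs, mf, exposed, t_grid)

    def pipeline(rs_params, mf_params):
        res = avd_mod.avoidable_deaths(
            rs, mf, lt, exposed, nstar, t_grid,
            stratum_col=stratum_col, rs_params=rs_params, mf_params=mf_params,
            sstar=sstar, engine=engine,
        )
        return {
            "AD_scenario1": res.ad_scenario1,
            "AD_scenario2": res.ad_scenario2,
            "D1": res.d1,
        }

    point = avd_mod.avoidable_deaths(
        rs, mf, lt, exposed, nstar, t_grid, stratum_col=stratum_col, sstar=sstar, engine=engine
    )
    res = bootstrap_cis(pipeline, rs, mf, boot)
    point.ci = res.ci
    path = os.path.join(cfg.output_dir, "avoidable_deaths.csv")
    point.to_frame().to_csv(path, index=False)
    _write_manifest(
        cfg,
        {
            "stage": "avoidable",
            "outputs": {"avoidable": path},
            "nstar": nstar,
            "nstar_source": nstar_source,
            "k": boot.k,
            "seed": boot.seed,
        },
    )
    return {"path": path, "nstar": nstar, "nstar_source": nstar_source}


def _write_manifest(cfg: RunConfig, payload: dict) -> None:
    os.makedirs(cfg.output_dir, exist_ok=True)
    path = os.path.join(cfg.output_dir, "manifest.json")
    manifest = []
    if os.path.exists(path):
        with open(path) as fh:
            manifest = json.load(fh)
    manifest.append(payload)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
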