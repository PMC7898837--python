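"""Shared fixtures: tiny hand-built lifetables and model objects, plus one
moderately sized simulated dataset with both models fitted (session scope,
reused by several test modules)."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from relmediate import (
    GeneratorConfig,
    Lifetable,
    MediatorFit,
    MediatorSpec,
    RcsSpec,
    RelSurvFit,
    RelSurvSpec,
    default_mediator_spec,
    default_relsurv_spec,
    fit_mediator,
    fit_relsurv,
    generate,
)
from relmediate.design import CategoricalTerm, LinearTerm


def flat_lifetable(rate, ages=(18, 99), years=(2005, 2025), strata=None, sexes=("female", "male")):
    """A constant-rate lifetable covering a generous age/year window."""
    rows = []
    strata_iter = [None] if strata is None else strata
    for sex in sexes:
        for st in strata_iter:
            for a in range(ages[0], ages[1] + 1):
                for y in range(years[0], years[1] + 1):
                    row = {"age": a, "sex": sex, "year": y, "rate": rate}
                    if st is not None:
                        row["stratum"] = st
                    rows.append(row)
    return Lifetable.from_frame(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def zero_lifetable():
    return flat_lifetable(0.0, strata=("0", "1"))


def weibull_fit(log_lambda0, kappa, extra_terms=(), extra_beta=(), cov_scale=0.0):
    """A RelSurvFit with a pure-Weibull baseline (df=1 spline in ln t) and
    arbitrary fixed coefficients -- no fitting involved."""
    spec = RelSurvSpec(
        baseline=RcsSpec(knots=(np.log(0.05), np.log(6.0))),
        terms=tuple(extra_terms),
    )
    beta = np.array([log_lambda0, kappa, *extra_beta], dtype=float)
    return RelSurvFit(
        spec=spec,
        beta=beta,
        cov=cov_scale * np.eye(beta.size),
        colnames=[f"b{i}" for i in range(beta.size)],
        loglik=0.0,
        grad_norm=0.0,
        n_iter=0,
        converged=True,
    )


def toy_mediator_fit(levels, coef, cov_scale=0.0):
    """A MediatorFit over exposure only, with fixed coefficients.

    ``coef``: (J-1, 2) array for design (intercept, exposure)."""
    spec = MediatorSpec(levels=tuple(levels), terms=(LinearTerm("exposure"),))
    coef = np.asarray(coef, dtype=float)
    return MediatorFit(
        spec=spec,
        coef=coef,
        cov=cov_scale * np.eye(coef.size),
        colnames=["(intercept)", "exposure"],
        loglik=0.0,
        converged=True,
    )


@pytest.fixture(scope="session")
def toy_frame():
    """20 hand-specified records with a 3-level mediator for loop oracles."""
    rng = np.random.default_rng(42)
    n = 20
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "time": rng.uniform(0.2, 5.0, n),
            "event": rng.integers(0, 2, n),
            "exposure": rng.integers(0, 2, n),
            "mediator": rng.choice(["a", "b", "c"], n),
            "age": rng.uniform(45, 90, n),
            "sex": rng.choice(["female", "male"], n),
            "year": np.repeat(2012.0, n),
            "stratum": rng.choice(["0", "1"], n),
        }
    )


@pytest.fixture(scope="session")
def toy_models(toy_frame):
    """Fixed-coefficient survival + mediator models over the toy frame."""
    rs = weibull_fit(
        np.log(0.1),
        0.9,
        extra_terms=(
            LinearTerm("exposure"),
            CategoricalTerm("mediator", ("a", "b", "c")),
        ),
        extra_beta=(0.3, 0.5, 1.1),
    )
    mf = toy_mediator_fit(("a", "b", "c"), [[0.2, 0.3], [-0.1, 0.6]])
    return SimpleNamespace(rs=rs, mf=mf)


@pytest.fixture(scope="session")
def sim():
    """One simulated registry (n = 4,000) with both models fitted."""
    cfg = GeneratorConfig(n=4000, seed=2)
    frame, lt = generate(cfg)
    spec = default_relsurv_spec(
        frame,
        cfg.mediator_levels,
        baseline_df=4,
        td_df=0,
        td_vars=(),
        mediator_exposure_interaction=False,
    )
    rs = fit_relsurv(frame, lt, spec, stratum_col="stratum")
    mf = fit_mediator(frame, default_mediator_spec(frame, cfg.mediator_levels))
    return SimpleNamespace(cfg=cfg, frame=frame, lt=lt, rs=rs, mf=mf)
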