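"""Avoidable (postponable) deaths among the exposed under hypothetical
interventions on the mediator distribution and/or relative survival.

Expected deaths by time t under a regime (y, x) -- exposure y for the
excess-hazard process, exposure x for the mediator distribution -- scale the
all-cause death probability of the exposed subset by a population size N*:

    D(t) = N* (1 - (1/N_{X=1}) sum_i S*_i(t) sum_m R(t|X=y, z_i, M=m) P(m|X=x, z_i)).

The expected survival S* of the exposed is kept at its observed value in
every regime: the interventions act on cancer mortality only.  Regimes:

    observed        (y=1, x=1)   the exposed as they are
    mediator_shift  (y=1, x=0)   mediator distribution shifted to the
                                 unexposed (scenario 2)
    full_shift      (y=0, x=0)   mediator distribution and relative survival
                                 shifted (scenario 1)

AD(t) = D1(t) - D_regime(t), and the scenario-1 total partitions exactly into
the scenario-2 (mediator) component plus a relative-survival residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .lifetable import expected_survival_matrix
from .mediation import StandardizationEngine

__all__ = ["REGIMES", "AvoidableDeathsResult", "expected_deaths", "avoidable_deaths", "candidate_nstar"]

REGIMES = {"observed": (1, 1), "mediator_shift": (1, 0), "full_shift": (0, 0)}


@dataclass
class AvoidableDeathsResult:
    """Deaths curves per regime and their avoidable-deaths differences."""

    t_grid: np.ndarray
    nstar: float
    d1: np.ndarray  # observed regime
    d_mediator_shift: np.ndarray  # scenario 2
    d_full_shift: np.ndarray  # scenario 1
    ci: dict = field(default_factory=dict)

    @property
    def ad_scenario1(self) -> np.ndarray:
        """Deaths avoidable by removing mediator and relative-survival differences."""
        return self.d1 - self.d_full_shift

    @property
    def ad_scenario2(self) -> np.ndarray:
        """Deaths avoidable by removing mediator-distribution differences alone."""
        return self.d1 - self.d_mediator_shift

    @property
    def ad_relsurv_residual(self) -> np.ndarray:
        """Scenario-1 total minus the mediator component: the part due to
        relative-survival differences."""
        return self.ad_scenario1 - self.ad_scenario2

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for scenario, d_int, ad in (
            ("1", self.d_full_shift, self.ad_scenario1),
            ("2", self.d_mediator_shift, self.ad_scenario2),
        ):
            key = f"AD_scenario{scenario}"
            lo, hi = self.ci.get(key, (None, None))
            for i, t in enumerate(self.t_grid):
                rows.append(
                    {
                        "time": t,
                        "scenario": scenario,
                        "D1": self.d1[i],
                        "D_scenario": d_int[i],
                        "AD": ad[i],
                        "ci_low": np.nan if lo is None else lo[i],
                        "ci_high": np.nan if hi is None else hi[i],
                        "nstar": self.nstar,
                    }
                )
        return pd.DataFrame(rows)


def _check_exposed(frame):
    if len(frame) == 0:
        raise ValidationError("exposed subset is empty")
    if not np.all(frame["exposure"].to_numpy() == 1):
        raise ValidationError("avoidable-deaths subset must contain exposed records only")


def expected_deaths(
    rs,
    mf,
    lt,
    exposed: pd.DataFrame,
    regime: str,
    nstar: float,
    t_grid,
    stratum_col: str | None = "stratum",
    rs_params=None,
    mf_params=None,
    sstar=None,
    engine: StandardizationEngine | None = None,
):
    """Expected cumulative deaths D(t) among the exposed under a regime.

    ``sstar`` and ``engine`` may carry the precomputed expected-survival
    matrix and standardization designs of the exposed subset (both are
    parameter-free, hence identical across regimes and bootstrap replicates).
    """
    _check_exposed(exposed)
    if regime not in REGIMES:
        raise ValidationError(f"unknown regime {regime!r}; one of {sorted(REGIMES)}")
    y, x = REGIMES[regime]
    if sstar is None:
        col = stratum_col if lt.stratified else None
        sstar = expected_survival_matrix(lt, exposed, t_grid, stratum_col=col)
    eng = engine if engine is not None else StandardizationEngine(rs, mf, exposed, t_grid)
    surv = eng.xi(y, x, rs_params=rs_params, mf_params=mf_params, sstar=sstar)
    return nstar * (1.0 - surv)


def avoidable_deaths(
    rs,
    mf,
    lt,
    exposed: pd.DataFrame,
    nstar: float,
    t_grid,
    stratum_col: str | None = "stratum",
    rs_params=None,
    mf_params=None,
    sstar=None,
    engine: StandardizationEngine | None = None,
) -> AvoidableDeathsResult:
    """Deaths curves for the observed regime and both intervention scenarios."""
    _check_exposed(exposed)
    if sstar is None:
        col = stratum_col if lt.stratified else None
        sstar = expected_survival_matrix(lt, exposed, t_grid, stratum_col=col)
    if engine is None:
        engine = StandardizationEngine(rs, mf, exposed, t_grid)
    kw = dict(
        stratum_col=stratum_col, rs_params=rs_params, mf_params=mf_params,
        sstar=sstar, engine=engine,
    )
    return AvoidableDeathsResult(
        t_grid=np.asarray(t_grid, dtype=float),
        nstar=float(nstar),
        d1=expected_deaths(rs, mf, lt, exposed, "observed", nstar, t_grid, **kw),
        d_mediator_shift=expected_deaths(rs, mf, lt, exposed, "mediator_shift", nstar, t_grid, **kw),
        d_full_shift=expected_deaths(rs, mf, lt, exposed, "full_shift", nstar, t_grid, **kw),
    )


def candidate_nstar(frame: pd.DataFrame) -> dict:
    """Candidate N* values computed from the data: the exposed count in the
    most recent diagnosis year, and the mean annual exposed count."""
    exposed = frame.loc[frame["exposure"] == 1]
    if len(exposed) == 0:
        raise ValidationError("no exposed records")
    years = exposed["year"].astype(int)
    latest = int(years.max())
    per_year = years.value_counts()
    return {
        "most_recent_year": int(per_year[latest]),
        "most_recent_year_label": latest,
        "mean_annual": float(per_year.mean()),
        "per_1000": 1000,
    }
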