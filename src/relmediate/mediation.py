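"""Regression standardization and mediation estimands.

All estimands are built from the standardized mediated relative survival

    xi(y, x; t) = (1/N) sum_i sum_m R(t | X=y, Z2=z_i, M=m) P(M=m | X=x, Z2=z_i),

the survival that would be seen if everyone's exposure were set to y for the
excess-hazard process while the mediator is drawn from its counterfactual
distribution under exposure x.  On the net (relative-survival) scale:

    NDE = xi(1,0) - xi(0,0)        direct effect, mediator held at M_0
    NIE = xi(1,1) - xi(1,0)        indirect effect through the mediator
    TCE = xi(1,1) - xi(0,0) = NDE + NIE
    PM  = NIE / TCE

All-cause variants weight each individual's relative survival by an expected
survival factor S*: AC1 sets the lifetable stratum to match the exposure of
the relative-survival factor (requires an exposure-stratified lifetable),
while AC2 uses every individual's observed-exposure expected survival in both
contrast terms, so AC2 differences are attributable to the cancer alone.

The default reporting scale is the probability of death (1 - survival); signs
flip consistently and PM is unchanged.

The :class:`StandardizationEngine` precomputes every parameter-free design
piece (the counterfactual design matrices and the S* factors), so that
re-evaluating the estimands at bootstrap-drawn coefficients costs a few
matrix-vector products per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CategoricalTerm, build_design
from .errors import ConfigurationError, ValidationError
from .lifetable import expected_survival_matrix
from .mediator import MediatorFit
from .relsurv import RelSurvFit, _covariate_parts, _split_beta, relative_survival_surface
from .splines import rcs_deriv, rcs_eval

__all__ = [
    "StandardizationPlan",
    "MediationSurface",
    "StandardizationEngine",
    "restrict",
    "standardized_relsurv",
    "xi",
    "mediation_effects_net",
    "mediation_effects_allcause",
    "proportion_mediated",
    "default_time_grid",
    "surface_to_frame",
]

#: |TCE| below which the proportion mediated is flagged undefined rather than
#: reported as an unstable ratio (probability scale).
PM_TOLERANCE = 1e-4


def default_time_grid(start: float = 0.05, stop: float = 5.0, step: float = 0.05) -> np.ndarray:
    """Default evaluation grid: 0.05 to 5 years in steps of 0.05 (the model
    lives on the ln t scale, so t = 0 is never evaluated)."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


@dataclass(frozen=True)
class StandardizationPlan:
    """What to standardize over and at which counterfactual settings."""

    t_grid: np.ndarray
    y: int = 1  # exposure for the relative-survival factor
    x: int = 0  # exposure for the mediator distribution
    subset: str = "all"  # "all" or "exposed"
    expected_mode: str = "none"  # none (net) | AC1 | AC2

    def __post_init__(self):
        t = np.asarray(self.t_grid, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) < 0):
            raise ValidationError("time grid must be sorted and strictly positive")
        object.__setattr__(self, "t_grid", t)
        if self.expected_mode not in ("none", "AC1", "AC2"):
            raise ValidationError(f"unknown expected-survival mode {self.expected_mode!r}")


@dataclass
class MediationSurface:
    """Time-indexed mediation estimands with optional confidence bounds.

    ``estimates`` holds TCE/NDE/NIE/PM; ``components`` the xi building
    blocks on the survival scale.  Where |TCE| falls below ``pm_tolerance``
    the PM entry is NaN and the corresponding ``pm_defined`` flag is False.
    """

    t_grid: np.ndarray
    setting: str  # net | AC1 | AC2
    scale: str  # death | survival
    estimates: dict
    components: dict
    pm_defined: np.ndarray
    ci: dict = field(default_factory=dict)

    def at(self, t: float) -> dict:
        """Estimates (and CIs if present) at the grid point nearest ``t``."""
        i = int(np.argmin(np.abs(self.t_grid - t)))
        out = {k: float(v[i]) for k, v in self.estimates.items()}
        for k, (lo, hi) in self.ci.items():
            out[f"{k}_lo"], out[f"{k}_hi"] = float(lo[i]), float(hi[i])
        return out


def restrict(frame: pd.DataFrame, predicate) -> pd.DataFrame:
    """Subset of a patient frame (all columns preserved); empty result raises.

    ``predicate`` is a boolean mask or a callable mapping the frame to one.
    """
    mask = predicate(frame) if callable(predicate) else predicate
    sub = frame.loc[np.asarray(mask, dtype=bool)]
    if len(sub) == 0:
        raise ValidationError("standardization subset is empty")
    return sub


def _mediator_levels_of_rs(rs: RelSurvFit):
    for term in rs.spec.terms:
        if isinstance(term, CategoricalTerm) and term.name == "mediator":
            return set(term.levels)
    return None


def _check_alignment(rs: RelSurvFit, mf: MediatorFit):
    rs_levels = _mediator_levels_of_rs(rs)
    if rs_levels is not None and rs_levels != set(mf.spec.levels):
        raise ValidationError(
            f"mediator levels differ between the survival model ({sorted(map(str, rs_levels))}) "
            f"and the mediator model ({sorted(map(str, mf.spec.levels))})"
        )


def standardized_relsurv(rs: RelSurvFit, frame: pd.DataFrame, x, t_grid, params=None):
    """theta_hat(t | X=x): average R over the subset with everyone's exposure
    set to x, mediator kept at its observed value."""
    if len(frame) == 0:
        raise ValidationError("empty standardization population")
    work = frame.copy()
    work["exposure"] = x
    return relative_survival_surface(rs, work, t_grid, params=params).mean(axis=0)


def proportion_mediated(nie, tce, tol: float = PM_TOLERANCE):
    """PM = NIE / TCE with the ratio flagged undefined where |TCE| < tol.

    Returns ``(pm, defined)``; undefined entries are NaN, never silently
    propagated into summaries.
    """
    nie = np.asarray(nie, dtype=float)
    tce = np.asarray(tce, dtype=float)
    defined = np.abs(tce) >= tol
    pm = np.full(np.broadcast(nie, tce).shape, np.nan)
    np.divide(nie, tce, out=pm, where=defined)
    return pm, defined


class StandardizationEngine:
    """Precomputed standardization over one reference population.

    Freezes, for a fixed frame and time grid, the counterfactual design
    pieces for every (exposure setting y, mediator level m) combination and
    the mediator-model designs for x in {0, 1}.  All of these are
    parameter-free, so evaluating any estimand at new coefficient vectors
    (the parametric-bootstrap inner loop) reduces to matrix products.
    """

    def __init__(self, rs: RelSurvFit, mf: MediatorFit, frame: pd.DataFrame, t_grid):
        _check_alignment(rs, mf)
        if len(frame) == 0:
            raise ValidationError("empty standardization population")
        self.rs = rs
        self.mf = mf
        self.n = len(frame)
        self.t_grid = np.asarray(t_grid, dtype=float)
        if np.any(self.t_grid <= 0):
            raise ValidationError("time grid must be strictly positive")
        lnt = np.log(self.t_grid)
        spec = rs.spec
        self._base = rcs_eval(spec.baseline, lnt)  # (T, df0)
        self._parts = {}  # (y, m) -> (Z, td_zblocks)
        for y in (0, 1):
            for lev in mf.spec.ordered_levels:
                work = frame.copy()
                work["exposure"] = y
                work["mediator"] = lev
                Z, znames, td_blocks = _covariate_parts(spec, work)
                self._parts[(y, lev)] = (Z, [(zb, zn, tspec) for zb, zn, tspec in td_blocks])
        self._znames_len = len(znames)
        self._td_time = [rcs_eval(tspec, lnt) for _, tspec in spec.td]
        self._med_design = {}
        for x in (0, 1):
            work = frame.copy()
            work["exposure"] = x
            Zm, _ = build_design(work, mf.spec.terms, intercept=True)
            self._med_design[x] = Zm

    # -- parameter-dependent pieces -------------------------------------

    def mediator_probs(self, x, mf_params=None) -> np.ndarray:
        coef = self.mf.coef if mf_params is None else self.mf.unpack(mf_params)
        lp = self._med_design[x] @ coef.T
        full = np.concatenate([np.zeros((self.n, 1)), lp], axis=1)
        full -= full.max(axis=1, keepdims=True)
        e = np.exp(full)
        return e / e.sum(axis=1, keepdims=True)

    def _relsurv(self, y, lev, rs_params=None) -> np.ndarray:
        beta = self.rs.beta if rs_params is None else np.asarray(rs_params, dtype=float)
        spec = self.rs.spec
        Z, td_blocks = self._parts[(y, lev)]
        b_int, b_base, b_z, gammas = _split_beta(spec, beta, self._znames_len, td_blocks)
        eta = (Z @ b_z)[:, None] + (b_int + self._base @ b_base)[None, :]
        for (zb, zn, tspec), g, Btd in zip(td_blocks, gammas, self._td_time):
            eta += zb @ (g @ Btd.T)
        return np.exp(-np.exp(eta))

    def xi_matrix(self, y, x, rs_params=None, mf_params=None) -> np.ndarray:
        """Per-individual sum_m R(t|y, z_i, m) P(m|x, z_i): (n, T)."""
        P = self.mediator_probs(x, mf_params)
        acc = np.zeros((self.n, self.t_grid.size))
        for j, lev in enumerate(self.mf.spec.ordered_levels):
            acc += P[:, j : j + 1] * self._relsurv(y, lev, rs_params)
        return acc

    def xi(self, y, x, rs_params=None, mf_params=None, sstar=None) -> np.ndarray:
        mat = self.xi_matrix(y, x, rs_params, mf_params)
        if sstar is not None:
            mat = mat * sstar
        return mat.mean(axis=0)

    def effects(
        self,
        setting: str = "net",
        scale: str = "death",
        pm_tol: float = PM_TOLERANCE,
        rs_params=None,
        mf_params=None,
        sstar11=None,
        sstar10=None,
        sstar00=None,
    ) -> MediationSurface:
        """NDE/NIE/TCE/PM from the three xi building blocks.

        The ``sstar*`` matrices weight the respective blocks (all-cause
        constructions); None means the net scale."""
        xi11 = self.xi(1, 1, rs_params, mf_params, sstar=sstar11)
        xi10 = self.xi(1, 0, rs_params, mf_params, sstar=sstar10)
        xi00 = self.xi(0, 0, rs_params, mf_params, sstar=sstar00)
        sign = -1.0 if scale == "death" else 1.0
        nde = sign * (xi10 - xi00)
        nie = sign * (xi11 - xi10)
        tce = nde + nie  # == sign * (xi11 - xi00); xi(1,0) cancels exactly
        pm, defined = proportion_mediated(nie, tce, tol=pm_tol)
        return MediationSurface(
            t_grid=self.t_grid,
            setting=setting,
            scale=scale,
            estimates={"TCE": tce, "NDE": nde, "NIE": nie, "PM": pm},
            components={"xi11": xi11, "xi10": xi10, "xi00": xi00},
            pm_defined=defined,
        )


def xi(rs, mf, frame, y, x, t_grid, rs_params=None, mf_params=None, sstar=None):
    """Standardized mediated relative survival xi(y, x) on ``t_grid``.

    ``sstar`` (n x T), when given, multiplies each individual's term before
    averaging -- the all-cause construction.
    """
    eng = StandardizationEngine(rs, mf, frame, t_grid)
    return eng.xi(y, x, rs_params=rs_params, mf_params=mf_params, sstar=sstar)


def mediation_effects_net(
    rs,
    mf,
    frame,
    t_grid,
    scale: str = "death",
    pm_tol: float = PM_TOLERANCE,
    rs_params=None,
    mf_params=None,
    engine: StandardizationEngine | None = None,
) -> MediationSurface:
    """NDE/NIE/TCE/PM in the net-survival setting (cancer the only cause)."""
    eng = engine if engine is not None else StandardizationEngine(rs, mf, frame, t_grid)
    return eng.effects("net", scale, pm_tol, rs_params, mf_params)


def ac_sstar_matrices(
    lt,
    frame,
    t_grid,
    mode: str,
    stratum_col: str | None = "stratum",
    stratum_for_exposure: dict | None = None,
    allow_unstratified: bool = False,
) -> dict:
    """Parameter-free expected-survival factors for the all-cause contrasts.

    Returns the matrices keyed "11"/"10"/"00" to weight the respective xi
    blocks.  AC1 sets the lifetable stratum of every individual to the
    stratum of the exposure level entering the relative-survival factor
    (``stratum_for_exposure`` maps exposure value -> stratum label, default
    the string form of the value); with an unstratified lifetable AC1
    degenerates to S*(t|X=1) = S*(t|X=0) and is refused unless
    ``allow_unstratified=True``.  AC2 uses the observed-exposure S* for all
    blocks.
    """
    col = stratum_col if lt.stratified else None
    if mode == "AC2":
        s = expected_survival_matrix(lt, frame, t_grid, stratum_col=col)
        return {"11": s, "10": s, "00": s}
    if mode != "AC1":
        raise ConfigurationError(f"unknown all-cause mode {mode!r}")
    if not lt.stratified:
        if not allow_unstratified:
            raise ConfigurationError(
                "AC1 contrasts need an exposure-stratified lifetable; with an "
                "unstratified table S*(t|X=1) = S*(t|X=0) -- pass "
                "allow_unstratified=True to accept this degeneracy"
            )
        s = expected_survival_matrix(lt, frame, t_grid, stratum_col=None)
        return {"11": s, "10": s, "00": s}
    mapping = stratum_for_exposure or {}
    out = {}
    for yval, keys in ((1, ("11", "10")), (0, ("00",))):
        work = frame.copy()
        work[stratum_col] = str(mapping.get(yval, yval))
        s = expected_survival_matrix(lt, work, t_grid, stratum_col=stratum_col)
        for k in keys:
            out[k] = s
    return out


def mediation_effects_allcause(
    rs,
    mf,
    lt,
    frame,
    t_grid,
    mode: str = "AC2",
    scale: str = "death",
    stratum_col: str | None = "stratum",
    stratum_for_exposure: dict | None = None,
    allow_unstratified: bool = False,
    pm_tol: float = PM_TOLERANCE,
    rs_params=None,
    mf_params=None,
    engine: StandardizationEngine | None = None,
    sstar_cache: dict | None = None,
) -> MediationSurface:
    """All-cause mediation effects, AC1 or AC2 construction.

    ``sstar_cache`` (a dict) can be shared across bootstrap replicates: the
    expected-survival matrices are parameter-free and computed once.
    """
    cache = sstar_cache if sstar_cache is not None else {}
    if mode not in cache:
        cache[mode] = ac_sstar_matrices(
            lt, frame, t_grid, mode,
            stratum_col=stratum_col,
            stratum_for_exposure=stratum_for_exposure,
            allow_unstratified=allow_unstratified,
        )
    s = cache[mode]
    eng = engine if engine is not None else StandardizationEngine(rs, mf, frame, t_grid)
    return eng.effects(
        mode, scale, pm_tol, rs_params, mf_params,
        sstar11=s["11"], sstar10=s["10"], sstar00=s["00"],
    )


def surface_to_frame(ms: MediationSurface) -> pd.DataFrame:
    """Tidy long-format table: one row per (time, estimand)."""
    rows = []
    for name, values in ms.estimates.items():
        lo, hi = ms.ci.get(name, (None, None))
        for i, t in enumerate(ms.t_grid):
            rows.append(
                {
                    "time": t,
                    "estimand": name,
                    "setting": ms.setting,
                    "scale": ms.scale,
                    "estimate": values[i],
                    "ci_low": np.nan if lo is None else lo[i],
                    "ci_high": np.nan if hi is None else hi[i],
                }
            )
    return pd.DataFrame(rows)
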