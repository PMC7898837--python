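"""Flexible parametric relative-survival model on the log cumulative excess
hazard scale.

The all-cause mortality rate of a cancer patient is decomposed as
h(t) = h*(t) + lambda(t): a background (expected) rate taken from a population
lifetable plus an excess rate attributable to the cancer.  The model places a
restricted cubic spline in ln t on the log cumulative excess hazard,

    eta(t; z) = s0(ln t) + z' beta + sum_j z_j * s_j(ln t),

so that Lambda_E(t) = exp(eta), relative survival R(t) = exp(-exp(eta)) and
lambda(t) = (1/t) * (d eta / d ln t) * exp(eta).  Time-dependent effects are
products of covariate columns with their own spline in ln t.  The excess
hazard is not constrained to be nonnegative; a finite penalty only guards the
log of a nonpositive *total* hazard during optimization.

The likelihood (up to terms constant in beta; the ln S* offset is dropped) is

    l(beta) = sum_i [ d_i ln( h*_i(t_i) + lambda_i(t_i) ) - Lambda_{E,i}(t_i) ]

with h*_i evaluated once per record at the attained age and calendar year at
exit.  Fitting uses an analytic gradient with quasi-Newton iterations followed
by Newton polishing on a finite-difference Hessian; the coefficient covariance
is the inverse of the negative Hessian at the optimum.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize

from . import lifetable as lt_mod
from .design import (
    CategoricalTerm,
    InteractionTerm,
    LinearTerm,
    SplineTerm,
    build_design,
    term_from_dict,
)
from .errors import (
    ConvergenceError,
    DomainError,
    RankDeficiencyError,
    ValidationError,
)
from .splines import RcsSpec, make_knots, rcs_deriv, rcs_eval

__all__ = [
    "RelSurvSpec",
    "RelSurvFit",
    "default_relsurv_spec",
    "fit_relsurv",
    "eta",
    "cumulative_excess_hazard",
    "relative_survival",
    "excess_hazard",
    "relative_survival_surface",
    "log_likelihood",
    "validate_patient_frame",
]

# Guard for ln(total hazard) when the unconstrained excess hazard drives the
# total below this floor at an event time: the log is continued linearly,
# log(eps) + (x - eps)/eps, which is finite, smooth in beta, and steers the
# optimizer back towards positive total hazards.
_HAZARD_FLOOR = 1e-10


@dataclass(frozen=True)
class RelSurvSpec:
    """Model specification with frozen knots.

    ``baseline`` is the spline in ln t for the baseline log cumulative excess
    hazard; ``terms`` the covariate main effects and interactions; ``td`` a
    tuple of (term, spline-in-ln t) pairs for time-dependent effects.
    """

    baseline: RcsSpec
    terms: tuple = ()
    td: tuple = ()  # ((term, RcsSpec), ...)

    def __post_init__(self):
        main = {t.name for t in self.terms if not isinstance(t, InteractionTerm)}
        for t in self.terms:
            if isinstance(t, InteractionTerm):
                for side in (t.left, t.right):
                    if side.name not in main:
                        raise ValidationError(
                            f"interaction {t.name!r} references {side.name!r} "
                            "which has no main effect"
                        )
        for term, _ in self.td:
            if term.name not in main:
                raise ValidationError(
                    f"time-dependent term for {term.name!r} has no main effect"
                )

    def to_dict(self) -> dict:
        return {
            "baseline": self.baseline.to_dict(),
            "terms": [t.to_dict() for t in self.terms],
            "td": [[t.to_dict(), s.to_dict()] for t, s in self.td],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RelSurvSpec":
        return cls(
            baseline=RcsSpec.from_dict(d["baseline"]),
            terms=tuple(term_from_dict(t) for t in d["terms"]),
            td=tuple((term_from_dict(t), RcsSpec.from_dict(s)) for t, s in d["td"]),
        )


def validate_patient_frame(frame: pd.DataFrame, mediator_levels=None) -> None:
    """Check the patient-record invariants: time > 0, event in {0, 1}, and
    (optionally) mediator values among the declared levels."""
    required = {"time", "event", "exposure", "mediator", "age", "sex", "year"}
    missing = required - set(frame.columns)
    if missing:
        raise ValidationError(f"patient frame is missing column(s) {sorted(missing)}")
    if np.any(frame["time"].to_numpy(dtype=float) <= 0):
        raise ValidationError("all follow-up times must be > 0")
    ev = frame["event"].to_numpy()
    if not np.isin(ev, (0, 1)).all():
        raise ValidationError("event indicator must be 0 or 1")
    if mediator_levels is not None:
        bad = set(frame["mediator"].unique()) - set(mediator_levels)
        if bad:
            raise ValidationError(f"undeclared mediator level(s) {sorted(map(str, bad))}")


def default_relsurv_spec(
    frame: pd.DataFrame,
    mediator_levels,
    baseline_df: int = 5,
    age_df: int = 3,
    td_df: int = 3,
    td_vars: tuple = ("exposure", "age", "mediator"),
    mediator_exposure_interaction: bool = True,
    orthogonalize: bool = False,
) -> RelSurvSpec:
    """Build the package's default model specification from the data.

    Defaults follow flexible-parametric relative-survival practice: a 5-df
    baseline spline in ln t with knots at equal centiles of the uncensored
    log event times, age as a 3-df restricted cubic spline, mediator (stage)
    and sex as categorical main effects, a mediator x exposure interaction,
    and 3-df time-dependent effects for exposure, age and mediator.
    """
    events = frame.loc[frame["event"] == 1, "time"].to_numpy(dtype=float)
    if events.size == 0:
        raise ValidationError("no events: cannot place baseline knots")
    log_t = np.log(events)
    baseline = make_knots(log_t, baseline_df)
    if orthogonalize:
        baseline = baseline.with_orthogonalization(log_t)

    age_spec = make_knots(frame["age"].to_numpy(dtype=float), age_df)
    exposure = LinearTerm("exposure")
    mediator = CategoricalTerm("mediator", tuple(mediator_levels))
    sexes = tuple(sorted(frame["sex"].astype(str).unique()))
    terms = [exposure, mediator]
    if len(sexes) > 1:
        terms.append(CategoricalTerm("sex", sexes))
    terms.append(SplineTerm("age", age_spec))
    if mediator_exposure_interaction:
        terms.append(InteractionTerm(mediator, exposure))

    td = []
    if td_df >= 1 and td_vars:
        td_spec = make_knots(log_t, td_df)
        if orthogonalize:
            td_spec = td_spec.with_orthogonalization(log_t)
        by_name = {t.name: t for t in terms if not isinstance(t, InteractionTerm)}
        for name in td_vars:
            if name in by_name:
                td.append((by_name[name], td_spec))
    return RelSurvSpec(baseline=baseline, terms=tuple(terms), td=tuple(td))


# ---------------------------------------------------------------------------
# Design construction.  Column order (fixed for fit and prediction):
#   intercept | baseline spline in ln t | covariate terms | td blocks,
# each td block ordered covariate-column-major then time-basis column.
# ---------------------------------------------------------------------------


def _covariate_parts(spec: RelSurvSpec, frame: pd.DataFrame):
    Z, znames = build_design(frame, spec.terms, intercept=False)
    td_blocks = []
    for term, tspec in spec.td:
        zb, zn = term.columns(frame)
        td_blocks.append((zb, zn, tspec))
    return Z, znames, td_blocks


def design_matrices(spec: RelSurvSpec, frame: pd.DataFrame, t: np.ndarray):
    """Design matrix X and its derivative d X / d ln t at per-record times."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise DomainError("time must be > 0 on the log-time scale")
    lnt = np.log(t)
    B = rcs_eval(spec.baseline, lnt)
    Bp = rcs_deriv(spec.baseline, lnt)
    Z, znames, td_blocks = _covariate_parts(spec, frame)
    names = ["(intercept)"]
    names += [f"lnt{j}" for j in range(1, spec.baseline.df + 1)]
    names += znames
    cols = [np.ones((len(frame), 1)), B, Z]
    dcols = [np.zeros((len(frame), 1)), Bp, np.zeros_like(Z)]
    for zb, zn, tspec in td_blocks:
        Btd = rcs_eval(tspec, lnt)
        Btdp = rcs_deriv(tspec, lnt)
        for j, zname in enumerate(zn):
            cols.append(zb[:, j : j + 1] * Btd)
            dcols.append(zb[:, j : j + 1] * Btdp)
            names += [f"{zname}:lnt{k}" for k in range(1, tspec.df + 1)]
    return np.hstack(cols), np.hstack(dcols), names


def _split_beta(spec: RelSurvSpec, beta: np.ndarray, znames_len: int, td_blocks):
    p0 = 1 + spec.baseline.df
    b_int = beta[0]
    b_base = beta[1:p0]
    b_z = beta[p0 : p0 + znames_len]
    rest = beta[p0 + znames_len :]
    gammas = []
    off = 0
    for zb, zn, tspec in td_blocks:
        q = len(zn) * tspec.df
        gammas.append(rest[off : off + q].reshape(len(zn), tspec.df))
        off += q
    return b_int, b_base, b_z, gammas


def _eta_surfaces(spec, beta, frame, t_grid, derivative=False):
    """eta (and optionally d eta/d ln t) on an (n records x T times) grid.

    Exploits separability: the baseline and each time-dependent block factor
    into a covariate part and a shared time part, so the surface costs
    O(n*T) rather than O(n*T*p).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(t_grid <= 0):
        raise DomainError("time grid must be strictly positive")
    lnt = np.log(t_grid)
    Z, znames, td_blocks = _covariate_parts(spec, frame)
    b_int, b_base, b_z, gammas = _split_beta(spec, beta, len(znames), td_blocks)
    base_t = b_int + rcs_eval(spec.baseline, lnt) @ b_base  # (T,)
    const_i = Z @ b_z if len(znames) else np.zeros(len(frame))  # (n,)
    eta = const_i[:, None] + base_t[None, :]
    for (zb, zn, tspec), g in zip(td_blocks, gammas):
        eta += zb @ (g @ rcs_eval(tspec, lnt).T)
    if not derivative:
        return eta
    deta = np.broadcast_to((rcs_deriv(spec.baseline, lnt) @ b_base)[None, :], eta.shape).copy()
    for (zb, zn, tspec), g in zip(td_blocks, gammas):
        deta += zb @ (g @ rcs_deriv(tspec, lnt).T)
    return eta, deta


@dataclass
class RelSurvFit:
    """A fitted excess-hazard model: coefficients, covariance, frozen spec."""

    spec: RelSurvSpec
    beta: np.ndarray
    cov: np.ndarray
    colnames: list
    loglik: float
    grad_norm: float
    n_iter: int
    converged: bool
    n: int = 0
    n_events: int = 0

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "beta": self.beta.tolist(),
            "cov": self.cov.tolist(),
            "colnames": list(self.colnames),
            "loglik": self.loglik,
            "grad_norm": self.grad_norm,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "n": self.n,
            "n_events": self.n_events,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RelSurvFit":
        return cls(
            spec=RelSurvSpec.from_dict(d["spec"]),
            beta=np.asarray(d["beta"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            colnames=list(d["colnames"]),
            loglik=float(d["loglik"]),
            grad_norm=float(d["grad_norm"]),
            n_iter=int(d["n_iter"]),
            converged=bool(d["converged"]),
            n=int(d.get("n", 0)),
            n_events=int(d.get("n_events", 0)),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "RelSurvFit":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# Predictions
# ---------------------------------------------------------------------------


def eta(fit: RelSurvFit, frame: pd.DataFrame, t, params=None):
    """Log cumulative excess hazard; ``t`` scalar or per-record vector."""
    beta = fit.beta if params is None else np.asarray(params, dtype=float)
    t = np.broadcast_to(np.asarray(t, dtype=float), (len(frame),))
    X, _, _ = design_matrices(fit.spec, frame, t)
    return X @ beta


def cumulative_excess_hazard(fit, frame, t, params=None):
    return np.exp(eta(fit, frame, t, params=params))


def relative_survival(fit, frame, t, params=None):
    """R(t) = exp(-Lambda_E(t)) per record."""
    return np.exp(-np.exp(eta(fit, frame, t, params=params)))


def excess_hazard(fit, frame, t, params=None):
    """Excess rate lambda(t) = (1/t)(d eta/d ln t) exp(eta); may be negative."""
    beta = fit.beta if params is None else np.asarray(params, dtype=float)
    t = np.broadcast_to(np.asarray(t, dtype=float), (len(frame),)).astype(float)
    X, Xp, _ = design_matrices(fit.spec, frame, t)
    return np.exp(X @ beta) * (Xp @ beta) / t


def relative_survival_surface(fit, frame, t_grid, params=None):
    """R(t) for every record at every grid time: (n, T) array."""
    beta = fit.beta if params is None else np.asarray(params, dtype=float)
    e = _eta_surfaces(fit.spec, beta, frame, t_grid)
    return np.exp(-np.exp(e))


# ---------------------------------------------------------------------------
# Likelihood and fitting
# ---------------------------------------------------------------------------


def _negll_grad(beta, X, Xp, t, d, hstar):
    eta_v = np.minimum(X @ beta, 500.0)  # overflow guard for wild trial steps
    u = Xp @ beta
    expeta = np.exp(eta_v)
    lam = expeta * u / t
    arg = hstar + lam
    eps = _HAZARD_FLOOR
    ok = arg > eps
    safe = np.maximum(arg, eps)
    logterm = np.where(ok, np.log(safe), np.log(eps) + (arg - eps) / eps)
    ll = float(np.sum(d * logterm) - np.sum(expeta))
    w = np.where(ok, 1.0 / safe, 1.0 / eps)
    coef = d * w * expeta / t
    grad = X.T @ (coef * u - expeta) + Xp.T @ coef
    return -ll, -grad


def log_likelihood(beta, data: pd.DataFrame, lt, spec: RelSurvSpec, stratum_col=None):
    """Excess-hazard log likelihood at ``beta`` (ln S* terms dropped)."""
    t = data["time"].to_numpy(dtype=float)
    d = data["event"].to_numpy(dtype=float)
    hstar = lt_mod.expected_hazard_at_exit(lt, data, stratum_col=stratum_col)
    X, Xp, _ = design_matrices(spec, data, t)
    negll, _ = _negll_grad(np.asarray(beta, dtype=float), X, Xp, t, d, hstar)
    return -negll


def _check_rank(X, names):
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    thresh = np.max(diag) * max(X.shape) * np.finfo(float).eps * 100
    bad = [names[j] for j in np.nonzero(diag < thresh)[0]]
    if bad:
        raise RankDeficiencyError(
            f"design matrix is rank deficient; collinear column(s): {bad}", columns=bad
        )


def _numeric_hessian(grad_fn, beta, step=1e-5):
    p = beta.size
    H = np.empty((p, p))
    for j in range(p):
        h = step * max(1.0, abs(beta[j]))
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h
        bm[j] -= h
        H[:, j] = (grad_fn(bp) - grad_fn(bm)) / (2 * h)
    return (H + H.T) / 2.0


def fit_relsurv(
    data: pd.DataFrame,
    lt,
    spec: RelSurvSpec,
    stratum_col=None,
    gtol: float = 1e-6,
    maxiter: int = 200,
) -> RelSurvFit:
    """Maximize the excess-hazard likelihood.

    Convergence requires the gradient max-norm below ``gtol``; quasi-Newton
    iterations are followed by Newton polishing with a finite-difference
    Hessian, which also supplies the coefficient covariance.  Non-convergence
    and rank deficiency raise with diagnostics rather than returning silently.
    """
    validate_patient_frame(data)
    t = data["time"].to_numpy(dtype=float)
    d = data["event"].to_numpy(dtype=float)
    if d.sum() < 1:
        raise ValidationError("no events in the data; the model is not identifiable")
    hstar = lt_mod.expected_hazard_at_exit(lt, data, stratum_col=stratum_col)
    X, Xp, names = design_matrices(spec, data, t)
    _check_rank(X, names)

    # Fit on column-scaled coordinates (unit root-mean-square columns): a
    # pure reparameterization that leaves the model invariant but keeps the
    # Hessian well conditioned.  beta = scale * beta_tilde.
    scale = 1.0 / np.sqrt(np.mean(X**2, axis=0))
    Xs = X * scale
    Xps = Xp * scale

    # crude exponential start: Lambda = (D / person-time) * t, i.e. eta =
    # ln(rate) + ln t.  With an orthogonalized basis the plain-ln t column is
    # not available, so fall back to intercept-only start.
    beta0 = np.zeros(X.shape[1])
    rate = max(d.sum() / np.sum(t), 1e-8)
    beta0[0] = np.log(rate)
    if spec.baseline.shift is None:
        beta0[1] = 1.0 / scale[1]

    obj = lambda b: _negll_grad(b, Xs, Xps, t, d, hstar)
    res = scipy.optimize.minimize(
        obj,
        beta0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "ftol": 1e-14, "gtol": 1e-9, "maxcor": 30},
    )
    beta = res.x
    grad_only = lambda b: obj(b)[1]

    # Newton polish (numeric Hessian, Levenberg damping on failure) to drive
    # the original-scale gradient max-norm below gtol.
    def orig_gnorm(g):
        return float(np.max(np.abs(g * scale)))

    n_newton = 0
    f, g = obj(beta)
    H = None
    for n_newton in range(40):
        if orig_gnorm(g) < gtol:
            break
        H = _numeric_hessian(grad_only, beta)
        moved = False
        diag = np.mean(np.abs(np.diag(H))) + 1e-12
        for mu in (0.0, 1e-8, 1e-4, 1e-2, 1.0, 1e2):
            try:
                step = np.linalg.solve(H + mu * diag * np.eye(H.shape[0]), -g)
            except np.linalg.LinAlgError:
                continue
            alpha = 1.0
            for _ in range(30):
                f_new, g_new = obj(beta + alpha * step)
                if f_new <= f + 1e-12 * max(1.0, abs(f)):
                    beta, f, g = beta + alpha * step, f_new, g_new
                    moved = True
                    break
                alpha /= 2.0
            if moved:
                break
        if not moved:
            break

    grad_norm = orig_gnorm(g)
    if grad_norm >= gtol:
        raise ConvergenceError(
            f"excess-hazard fit did not converge: gradient max-norm {grad_norm:.3g} "
            f">= {gtol}",
            diagnostics={
                "loglik": -f,
                "grad_norm": grad_norm,
                "iterations": int(res.nit) + n_newton,
            },
        )

    H = _numeric_hessian(grad_only, beta)
    try:
        cov_s = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            "Hessian at the optimum is singular; covariance unavailable",
            diagnostics={"loglik": -f},
        ) from exc
    beta = beta * scale
    cov = cov_s * np.outer(scale, scale)
    cov = (cov + cov.T) / 2.0
    return RelSurvFit(
        spec=spec,
        beta=beta,
        cov=cov,
        colnames=names,
        loglik=-f,
        grad_norm=grad_norm,
        n_iter=int(res.nit) + n_newton,
        converged=True,
        n=len(data),
        n_events=int(d.sum()),
    )
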