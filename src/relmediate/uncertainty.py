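"""Parametric-bootstrap uncertainty for every estimand surface.

Coefficients of the survival and mediator models are drawn independently from
multivariate normal distributions centred at the point estimates with the
estimated covariances (the models are fit separately, so no cross-covariance
exists).  Each draw is pushed through the standardization pipeline; intervals
come either from the normal approximation (point +/- 1.96 x bootstrap SD, the
default) or from the 2.5/97.5 percent quantiles of the replicates.  The point
estimate reported is always the original-fit value, never the bootstrap mean.

Covariances are factorized by eigendecomposition with negative eigenvalues
clipped at zero (numerical Hessians can be indefinite at round-off level); a
clip beyond round-off warns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, ValidationError

__all__ = ["BootstrapConfig", "BootstrapResult", "draw_parameters", "bootstrap_cis"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Replicate count, seed, and interval method for the parametric bootstrap."""

    k: int = 500
    seed: int = 0
    method: str = "normal"  # normal | percentile
    max_failure_frac: float = 0.05

    def __post_init__(self):
        if self.k < 2:
            raise ValidationError("bootstrap needs k >= 2 replicates")
        if self.method not in ("normal", "percentile"):
            raise ValidationError(f"unknown CI method {self.method!r}")


def _factor(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValidationError("covariance must be a square matrix")
    try:
        w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    except np.linalg.LinAlgError as exc:
        raise ConvergenceError(
            "covariance eigendecomposition failed",
            diagnostics={"cond": float(np.linalg.cond(cov))},
        ) from exc
    floor = -1e-8 * max(1.0, float(np.max(np.abs(w))))
    if np.any(w < floor):
        warnings.warn(
            f"covariance has negative eigenvalue(s) down to {w.min():.3g}; "
            "clipped at zero for sampling",
            RuntimeWarning,
        )
    return v * np.sqrt(np.clip(w, 0.0, None))


def draw_parameters(fit, rng: np.random.Generator, factor=None) -> np.ndarray:
    """One draw from MVN(point estimate, covariance) for a fitted model.

    ``fit`` is a RelSurvFit (mean ``beta``) or MediatorFit (mean ``packed``).
    ``factor`` can carry a precomputed covariance factor across draws.
    """
    mean = np.asarray(fit.beta if hasattr(fit, "beta") else fit.packed, dtype=float)
    L = _factor(fit.cov) if factor is None else factor
    return mean + L @ rng.standard_normal(mean.size)


@dataclass
class BootstrapResult:
    """Point estimates, interval bounds and the raw replicate matrices."""

    point: dict
    ci: dict  # name -> (lo, hi)
    replicates: dict  # name -> (k_ok, len) array
    n_requested: int
    n_failed: int
    method: str

    @property
    def sd(self) -> dict:
        return {k: np.nanstd(v, axis=0, ddof=1) for k, v in self.replicates.items()}


def bootstrap_cis(pipeline, rs_fit, mf_fit, cfg: BootstrapConfig) -> BootstrapResult:
    """Propagate parameter uncertainty through an estimand pipeline.

    ``pipeline(rs_params, mf_params)`` must deterministically return a dict of
    named 1-d arrays; it is first evaluated at the point estimates and then at
    ``cfg.k`` independent parameter draws.  Replicates that raise are recorded
    and excluded; more than ``max_failure_frac`` failures is a hard error.
    """
    rng = np.random.default_rng(cfg.seed)
    point = pipeline(rs_fit.beta, mf_fit.packed)
    point = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in point.items()}

    L_rs = _factor(rs_fit.cov)
    L_mf = _factor(mf_fit.cov)
    reps = {k: [] for k in point}
    failures = []
    for b in range(cfg.k):
        rs_params = draw_parameters(rs_fit, rng, factor=L_rs)
        mf_params = draw_parameters(mf_fit, rng, factor=L_mf)
        try:
            out = pipeline(rs_params, mf_params)
        except Exception as exc:  # noqa: BLE001 -- replicate failures are data
            failures.append((b, repr(exc)))
            continue
        for k in point:
            reps[k].append(np.atleast_1d(np.asarray(out[k], dtype=float)))

    if len(failures) > cfg.max_failure_frac * cfg.k:
        raise ConvergenceError(
            f"{len(failures)} of {cfg.k} bootstrap replicates failed "
            f"(> {cfg.max_failure_frac:.0%})",
            diagnostics={"failures": failures[:10]},
        )

    replicates = {k: np.vstack(v) for k, v in reps.items()}
    ci = {}
    for k, mat in replicates.items():
        if cfg.method == "normal":
            sd = np.nanstd(mat, axis=0, ddof=1)
            ci[k] = (point[k] - 1.959963984540054 * sd, point[k] + 1.959963984540054 * sd)
        else:
            ci[k] = (
                np.nanpercentile(mat, 2.5, axis=0),
                np.nanpercentile(mat, 97.5, axis=0),
            )
    return BootstrapResult(
        point=point,
        ci=ci,
        replicates=replicates,
        n_requested=cfg.k,
        n_failed=len(failures),
        method=cfg.method,
    )
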