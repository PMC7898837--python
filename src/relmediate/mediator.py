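"""Mediator model: multinomial logistic regression for a categorical mediator
(stage at diagnosis) given exposure and confounders, and per-individual
counterfactual mediator probabilities P(M = m | X = x, Z2).

The maximum-likelihood fit is delegated to statsmodels' multinomial logit;
predictions are computed from the stored coefficients directly (softmax with
the reference level's linear predictor fixed at 0) so that bootstrap draws of
the coefficient vector reuse the same code path.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .design import (
    CategoricalTerm,
    LinearTerm,
    SplineTerm,
    build_design,
    term_from_dict,
)
from .errors import ConvergenceError, RankDeficiencyError, ValidationError
from .splines import make_knots

__all__ = ["MediatorSpec", "MediatorFit", "default_mediator_spec", "fit_mediator", "mediator_probs"]


@dataclass(frozen=True)
class MediatorSpec:
    """Design for the mediator model: declared levels (first = reference by
    default) and covariate terms (exposure plus confounders)."""

    levels: tuple
    terms: tuple
    reference: object = None

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValidationError("mediator must have at least 2 declared levels")
        ref = self.reference if self.reference is not None else self.levels[0]
        if ref not in self.levels:
            raise ValidationError(f"reference level {ref!r} not among declared levels")
        object.__setattr__(self, "reference", ref)

    @property
    def ordered_levels(self) -> tuple:
        """Reference level first, remaining levels in declared order."""
        return (self.reference,) + tuple(l for l in self.levels if l != self.reference)

    def to_dict(self):
        return {
            "levels": list(self.levels),
            "reference": self.reference,
            "terms": [t.to_dict() for t in self.terms],
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            levels=tuple(d["levels"]),
            terms=tuple(term_from_dict(t) for t in d["terms"]),
            reference=d["reference"],
        )


def default_mediator_spec(frame: pd.DataFrame, levels, age_df: int = 3) -> MediatorSpec:
    """Exposure + sex + age (own restricted cubic spline, knots from the
    pooled age distribution, independent of the survival model's age basis)."""
    terms = [LinearTerm("exposure")]
    sexes = tuple(sorted(frame["sex"].astype(str).unique()))
    if len(sexes) > 1:
        terms.append(CategoricalTerm("sex", sexes))
    terms.append(SplineTerm("age", make_knots(frame["age"].to_numpy(dtype=float), age_df)))
    return MediatorSpec(levels=tuple(levels), terms=tuple(terms))


@dataclass
class MediatorFit:
    """Fitted multinomial-logit mediator model.

    ``coef`` has one row per non-reference level (in ``spec.ordered_levels``
    order, reference excluded) and one column per design column; ``cov`` is
    the covariance of the row-wise stacked coefficient vector.
    """

    spec: MediatorSpec
    coef: np.ndarray  # (J-1, p)
    cov: np.ndarray  # (p*(J-1), p*(J-1))
    colnames: list
    loglik: float
    converged: bool
    n: int = 0

    @property
    def packed(self) -> np.ndarray:
        return self.coef.ravel()

    def unpack(self, params) -> np.ndarray:
        return np.asarray(params, dtype=float).reshape(self.coef.shape)

    def to_dict(self):
        return {
            "spec": self.spec.to_dict(),
            "coef": self.coef.tolist(),
            "cov": self.cov.tolist(),
            "colnames": list(self.colnames),
            "loglik": self.loglik,
            "converged": self.converged,
            "n": self.n,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            spec=MediatorSpec.from_dict(d["spec"]),
            coef=np.asarray(d["coef"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            colnames=list(d["colnames"]),
            loglik=float(d["loglik"]),
            converged=bool(d["converged"]),
            n=int(d.get("n", 0)),
        )

    def save(self, path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path):
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def fit_mediator(data: pd.DataFrame, spec: MediatorSpec) -> MediatorFit:
    """Maximum-likelihood multinomial-logit fit of the mediator model.

    Raises on a single observed level, rank-deficient design, or
    non-convergence (which is how separation typically surfaces).
    """
    observed = set(data["mediator"].unique())
    if len(observed) < 2:
        raise ValidationError("mediator has a single observed level; nothing to model")
    undeclared = observed - set(spec.levels)
    if undeclared:
        raise ValidationError(f"undeclared mediator level(s) {sorted(map(str, undeclared))}")

    ordered = spec.ordered_levels
    codes = data["mediator"].map({lev: i for i, lev in enumerate(ordered)}).to_numpy()
    Z, names = build_design(data, spec.terms, intercept=True)

    _, r = np.linalg.qr(Z)
    diag = np.abs(np.diag(r))
    bad = [names[j] for j in np.nonzero(diag < np.max(diag) * 1e-10)[0]]
    if bad:
        raise RankDeficiencyError(
            f"mediator design is rank deficient; collinear column(s): {bad}", columns=bad
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MNLogit(codes, Z)
        result = model.fit(method="newton", maxiter=200, disp=0)
    if not result.mle_retvals.get("converged", False):
        raise ConvergenceError(
            "multinomial mediator model did not converge (possible separation)",
            diagnostics=dict(result.mle_retvals),
        )

    # statsmodels stores params as (p, J-1); its flat parameter vector (the
    # one cov_params() refers to) is column-major, i.e. level-blocked --
    # exactly our (J-1, p) row-wise stacking.
    coef = np.asarray(result.params).T.copy()
    cov = np.asarray(result.cov_params())
    return MediatorFit(
        spec=spec,
        coef=coef,
        cov=(cov + cov.T) / 2.0,
        colnames=names,
        loglik=float(result.llf),
        converged=True,
        n=len(data),
    )


def mediator_probs(fit: MediatorFit, frame: pd.DataFrame, x, params=None) -> np.ndarray:
    """P(M = m | X = x, Z2 = z_i) for every record, exposure overridden to x.

    Returns an (n, J) array with columns in ``spec.ordered_levels`` order
    (reference first); rows sum to one.
    """
    coef = fit.coef if params is None else fit.unpack(params)
    work = frame.copy()
    work["exposure"] = x
    Z, _ = build_design(work, fit.spec.terms, intercept=True)
    lp = Z @ coef.T  # (n, J-1)
    full = np.concatenate([np.zeros((len(work), 1)), lp], axis=1)
    full -= full.max(axis=1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=1, keepdims=True)
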