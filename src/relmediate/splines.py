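"""Restricted cubic spline (natural cubic spline) bases with analytic derivatives.

The basis used throughout the package is the truncated-power restricted cubic
form: for ordered knots :math:`k_1 < \\dots < k_K` the basis has :math:`K-1`
columns.  The first column is the identity, :math:`v_1(x) = x`.  For
:math:`j = 2, \\dots, K-1`,

.. math::

    v_j(x) = \\frac{(x-k_j)_+^3 - \\lambda_j (x-k_1)_+^3
              - (1-\\lambda_j)(x-k_K)_+^3}{(k_K - k_1)^2},
    \\qquad \\lambda_j = \\frac{k_K - k_j}{k_K - k_1},

which is exactly linear outside :math:`[k_1, k_K]` (the cubic and quadratic
terms cancel) and zero at and below :math:`k_1`.  The division by
:math:`(k_K-k_1)^2` keeps the nonlinear columns on a scale comparable with the
linear one.  The same closed form is used for values and first derivatives so
the two are always consistent.

An optional orthogonalization stores an affine map (shift vector plus an
invertible upper-triangular matrix from a QR decomposition of the sampled
basis).  Because the map is affine and full rank, model predictions that
include an intercept are invariant to whether it is applied; only the
coefficient scale changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

__all__ = ["RcsSpec", "make_knots", "rcs_eval", "rcs_deriv"]


@dataclass(frozen=True)
class RcsSpec:
    """Frozen specification of a restricted cubic spline basis.

    Parameters
    ----------
    knots
        Strictly increasing knot locations on the scale of the input
        variable.  ``len(knots) - 1`` is the basis dimension (degrees of
        freedom).
    shift, transform
        Optional affine orthogonalization: the evaluated raw basis ``B`` is
        mapped to ``(B - shift) @ transform``.  ``None`` means the raw basis
        is used as-is.
    """

    knots: tuple[float, ...]
    shift: tuple[float, ...] | None = None
    transform: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 1 or k.size < 2:
            raise ValidationError("an RCS basis needs at least two knots")
        if not np.all(np.diff(k) > 0):
            raise ValidationError(f"knots must be strictly increasing, got {self.knots}")
        if not np.all(np.isfinite(k)):
            raise ValidationError("knots must be finite")

    @property
    def df(self) -> int:
        """Basis dimension: number of knots minus one."""
        return len(self.knots) - 1

    def with_orthogonalization(self, sample: np.ndarray) -> "RcsSpec":
        """Return a copy whose basis is orthogonalized against ``sample``.

        The raw basis evaluated on ``sample`` is column-centred and mapped
        through the inverse R factor of its QR decomposition, scaled by
        ``sqrt(n)`` so the transformed columns have unit empirical second
        moment and zero empirical correlation on the sample.
        """
        sample = np.asarray(sample, dtype=float).ravel()
        raw = _raw_eval(np.asarray(self.knots), sample)
        shift = raw.mean(axis=0)
        centred = raw - shift
        _, r = np.linalg.qr(centred)
        if np.min(np.abs(np.diag(r))) < 1e-12 * max(1.0, np.max(np.abs(r))):
            raise ValidationError("sample too degenerate to orthogonalize the basis")
        transform = np.linalg.solve(r / np.sqrt(len(sample)), np.eye(self.df))
        return RcsSpec(
            knots=self.knots,
            shift=tuple(shift),
            transform=tuple(tuple(row) for row in transform),
        )

    def to_dict(self) -> dict:
        out = {"knots": list(self.knots)}
        if self.shift is not None:
            out["shift"] = list(self.shift)
            out["transform"] = [list(r) for r in self.transform]
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "RcsSpec":
        shift = d.get("shift")
        transform = d.get("transform")
        return cls(
            knots=tuple(d["knots"]),
            shift=tuple(shift) if shift is not None else None,
            transform=tuple(tuple(r) for r in transform) if transform is not None else None,
        )


def make_knots(values, df: int, strategy: str = "quantile") -> RcsSpec:
    """Place ``df + 1`` knots on a sample of a variable.

    Default placement puts boundary knots at the sample minimum and maximum
    and interior knots at equally spaced centiles (``df = 5`` uses centiles
    0, 20, 40, 60, 80, 100).  ``df = 1`` degenerates to a plain linear term.
    """
    if strategy != "quantile":
        raise ValidationError(f"unknown knot strategy {strategy!r}")
    if df < 1:
        raise ValidationError("df must be >= 1")
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    distinct = np.unique(values)
    if distinct.size < df + 1:
        raise ValidationError(
            f"need at least {df + 1} distinct values for df={df}, got {distinct.size}"
        )
    centiles = np.linspace(0.0, 100.0, df + 1)
    knots = np.percentile(values, centiles)
    if not np.all(np.diff(knots) > 0):
        raise ValidationError(
            f"degenerate knot placement {knots.tolist()} (too many ties); "
            "reduce df or supply knots explicitly"
        )
    return RcsSpec(knots=tuple(knots))


def _raw_eval(knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    kmin, kmax = knots[0], knots[-1]
    scale = (kmax - kmin) ** 2
    out = np.empty(x.shape + (len(knots) - 1,), dtype=float)
    out[..., 0] = x
    for j, kj in enumerate(knots[1:-1], start=1):
        lam = (kmax - kj) / (kmax - kmin)
        out[..., j] = (
            np.maximum(x - kj, 0.0) ** 3
            - lam * np.maximum(x - kmin, 0.0) ** 3
            - (1.0 - lam) * np.maximum(x - kmax, 0.0) ** 3
        ) / scale
    return out


def _raw_deriv(knots: np.ndarray, x: np.ndarray) -> np.ndarray:
    kmin, kmax = knots[0], knots[-1]
    scale = (kmax - kmin) ** 2
    out = np.empty(x.shape + (len(knots) - 1,), dtype=float)
    out[..., 0] = 1.0
    for j, kj in enumerate(knots[1:-1], start=1):
        lam = (kmax - kj) / (kmax - kmin)
        out[..., j] = (
            3.0 * np.maximum(x - kj, 0.0) ** 2
            - 3.0 * lam * np.maximum(x - kmin, 0.0) ** 2
            - 3.0 * (1.0 - lam) * np.maximum(x - kmax, 0.0) ** 2
        ) / scale
    return out


def rcs_eval(spec: RcsSpec, x) -> np.ndarray:
    """Evaluate the basis at ``x``.

    Returns an array of shape ``x.shape + (df,)``; scalars give a ``(df,)``
    vector.  Extrapolation beyond the boundary knots follows the linear tails.
    """
    x = np.asarray(x, dtype=float)
    b = _raw_eval(np.asarray(spec.knots), x)
    if spec.shift is not None:
        b = (b - np.asarray(spec.shift)) @ np.asarray(spec.transform)
    return b


def rcs_deriv(spec: RcsSpec, x) -> np.ndarray:
    """First derivative of each basis column with respect to ``x``."""
    x = np.asarray(x, dtype=float)
    d = _raw_deriv(np.asarray(spec.knots), x)
    if spec.shift is not None:
        d = d @ np.asarray(spec.transform)
    return d
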