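"""Covariate terms and design-matrix construction shared by the survival and
mediator models.

A term turns columns of a patient frame into design columns with stable names
and a stable ordering, so the matrix built at fit time and the matrix built at
prediction time (possibly with exposure or mediator overridden) line up
column-for-column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .splines import RcsSpec, rcs_eval

__all__ = ["LinearTerm", "CategoricalTerm", "SplineTerm", "InteractionTerm", "build_design"]


@dataclass(frozen=True)
class LinearTerm:
    """A numeric column entering linearly (binary 0/1 exposure included)."""

    name: str
    center: float = 0.0

    def columns(self, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        x = frame[self.name].to_numpy(dtype=float) - self.center
        return x[:, None], [self.name]

    def to_dict(self):
        return {"kind": "linear", "name": self.name, "center": self.center}


@dataclass(frozen=True)
class CategoricalTerm:
    """Dummy coding against a declared reference level.

    Levels must be declared up front; values outside the declared set raise,
    so an unseen level can never be silently dropped at prediction time.
    """

    name: str
    levels: tuple
    reference: object = None

    def __post_init__(self):
        if len(self.levels) < 2:
            raise ValidationError(f"categorical term {self.name!r} needs >= 2 levels")
        ref = self.reference if self.reference is not None else self.levels[0]
        if ref not in self.levels:
            raise ValidationError(f"reference {ref!r} not among levels of {self.name!r}")
        object.__setattr__(self, "reference", ref)

    def columns(self, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        vals = frame[self.name]
        unseen = set(vals.unique()) - set(self.levels)
        if unseen:
            raise ValidationError(
                f"column {self.name!r} contains undeclared level(s) {sorted(map(str, unseen))}"
            )
        cols, names = [], []
        for lev in self.levels:
            if lev == self.reference:
                continue
            cols.append((vals == lev).to_numpy(dtype=float))
            names.append(f"{self.name}[{lev}]")
        return np.column_stack(cols), names

    def to_dict(self):
        return {
            "kind": "categorical",
            "name": self.name,
            "levels": list(self.levels),
            "reference": self.reference,
        }


@dataclass(frozen=True)
class SplineTerm:
    """A continuous confounder through a restricted cubic spline basis."""

    name: str
    spec: RcsSpec

    def columns(self, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        b = rcs_eval(self.spec, frame[self.name].to_numpy(dtype=float))
        names = [f"rcs({self.name}){j}" for j in range(1, self.spec.df + 1)]
        return b, names

    def to_dict(self):
        return {"kind": "spline", "name": self.name, "spec": self.spec.to_dict()}


@dataclass(frozen=True)
class InteractionTerm:
    """Elementwise products of the columns of two terms."""

    left: object
    right: object

    @property
    def name(self) -> str:
        return f"{self.left.name}:{self.right.name}"

    def columns(self, frame: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        lb, ln = self.left.columns(frame)
        rb, rn = self.right.columns(frame)
        cols, names = [], []
        for i, a in enumerate(ln):
            for j, b in enumerate(rn):
                cols.append(lb[:, i] * rb[:, j])
                names.append(f"{a}:{b}")
        return np.column_stack(cols), names

    def to_dict(self):
        return {"kind": "interaction", "left": self.left.to_dict(), "right": self.right.to_dict()}


def term_from_dict(d: dict):
    kind = d["kind"]
    if kind == "linear":
        return LinearTerm(d["name"], d.get("center", 0.0))
    if kind == "categorical":
        return CategoricalTerm(d["name"], tuple(d["levels"]), d["reference"])
    if kind == "spline":
        return SplineTerm(d["name"], RcsSpec.from_dict(d["spec"]))
    if kind == "interaction":
        return InteractionTerm(term_from_dict(d["left"]), term_from_dict(d["right"]))
    raise ValidationError(f"unknown term kind {kind!r}")


def build_design(frame: pd.DataFrame, terms, intercept: bool = True):
    """Stack term columns (optionally after a leading intercept).

    Returns ``(X, names)``; ordering follows the term list, which is the
    single source of truth for both fitting and prediction.
    """
    cols = []
    names = []
    if intercept:
        cols.append(np.ones((len(frame), 1)))
        names.append("(intercept)")
    for term in terms:
        b, n = term.columns(frame)
        cols.append(b)
        names.extend(n)
    return np.hstack(cols) if cols else np.empty((len(frame), 0)), names
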