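"""Population lifetables: expected (background) mortality rates and expected survival.

A lifetable holds the expected mortality rate h*(age, sex, year[, stratum]) of
a comparable general population, on the conventional ratetable grid: rates are
piecewise constant over 1-year age bands crossed with 1-year calendar periods,
optionally stratified further (e.g. by deprivation group).  Attained age and
attained calendar year advance together with follow-up time, so the expected
cumulative hazard of a subject is the exact integral of a piecewise-constant
rate path, with change points wherever the subject crosses an age-band or
calendar-year boundary.  Expected survival is S*(t) = exp(-cumhaz(t)).

Ages above the table's cap are clamped to the cap row (registry lifetables end
in an open age band); calendar years outside the covered range are clamped to
the nearest covered year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, SchemaError, ValidationError

__all__ = [
    "Lifetable",
    "LifetableSchema",
    "ExpectedTrajectory",
    "load_lifetable",
    "write_lifetable",
    "expected_hazard_at",
    "expected_survival",
]

_NO_STRATUM = "__none__"


@dataclass(frozen=True)
class LifetableSchema:
    """Column-name mapping (and optional sex recoding) for lifetable files."""

    age: str = "age"
    sex: str = "sex"
    year: str = "year"
    rate: str = "rate"
    stratum: str | None = None
    sex_map: dict | None = None  # raw code -> canonical label


@dataclass
class Lifetable:
    """Expected mortality rates indexed by (age, sex, year[, stratum]).

    Internally each (sex, stratum) pair maps to a dense (n_ages x n_years)
    rate matrix for O(1) lookup.
    """

    age_min: int
    age_max: int
    year_min: int
    year_max: int
    sexes: tuple
    strata: tuple | None  # None <=> unstratified
    _rates: dict = field(repr=False)  # (sex, stratum) -> ndarray

    @property
    def stratified(self) -> bool:
        return self.strata is not None

    @property
    def n_entries(self) -> int:
        return sum(r.size for r in self._rates.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Lifetable":
        """Build and validate from a frame with columns age, sex, year, rate
        and optionally stratum."""
        df = df.copy()
        if "stratum" not in df.columns:
            df["stratum"] = _NO_STRATUM
            strata = None
        else:
            strata = tuple(sorted(df["stratum"].astype(str).unique()))
            df["stratum"] = df["stratum"].astype(str)

        rates = df["rate"].to_numpy(dtype=float)
        if not np.all(np.isfinite(rates)):
            raise ValidationError("lifetable rates must be finite")
        if np.any(rates < 0):
            bad = df.loc[df["rate"] < 0].iloc[0]
            raise ValidationError(
                f"negative expected mortality rate {bad['rate']} at "
                f"age={bad['age']}, sex={bad['sex']}, year={bad['year']}"
            )
        keys = ["age", "sex", "year", "stratum"]
        if df.duplicated(subset=keys).any():
            dup = df[df.duplicated(subset=keys, keep=False)].iloc[0]
            raise ValidationError(
                f"duplicated lifetable key (age={dup['age']}, sex={dup['sex']}, "
                f"year={dup['year']}, stratum={dup['stratum']})"
            )

        df["age"] = df["age"].astype(int)
        df["year"] = df["year"].astype(int)
        age_min, age_max = int(df["age"].min()), int(df["age"].max())
        year_min, year_max = int(df["year"].min()), int(df["year"].max())
        sexes = tuple(sorted(df["sex"].astype(str).unique()))
        df["sex"] = df["sex"].astype(str)

        n_age = age_max - age_min + 1
        n_year = year_max - year_min + 1
        table = {}
        for (sex, stratum), g in df.groupby(["sex", "stratum"], sort=True):
            ages = np.sort(g["age"].unique())
            if len(ages) != n_age or ages[0] != age_min or ages[-1] != age_max:
                raise ValidationError(
                    f"age bands for sex={sex}, stratum={stratum} are not the "
                    f"contiguous range {age_min}..{age_max}"
                )
            years = np.sort(g["year"].unique())
            if len(years) != n_year or years[0] != year_min or years[-1] != year_max:
                raise ValidationError(
                    f"calendar years for sex={sex}, stratum={stratum} are not "
                    f"the contiguous range {year_min}..{year_max}"
                )
            if len(g) != n_age * n_year:
                raise ValidationError(
                    f"missing (age, year) cells for sex={sex}, stratum={stratum}"
                )
            mat = np.empty((n_age, n_year), dtype=float)
            mat[g["age"].to_numpy() - age_min, g["year"].to_numpy() - year_min] = (
                g["rate"].to_numpy(dtype=float)
            )
            table[(sex, stratum)] = mat
        return cls(
            age_min=age_min,
            age_max=age_max,
            year_min=year_min,
            year_max=year_max,
            sexes=sexes,
            strata=strata,
            _rates=table,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sex, stratum), mat in sorted(self._rates.items()):
            for i in range(mat.shape[0]):
                for j in range(mat.shape[1]):
                    rows.append(
                        {
                            "age": self.age_min + i,
                            "sex": sex,
                            "year": self.year_min + j,
                            "rate": mat[i, j],
                            "stratum": stratum,
                        }
                    )
        df = pd.DataFrame(rows)
        if not self.stratified:
            df = df.drop(columns=["stratum"])
        return df

    def _matrix(self, sex, stratum):
        sex = str(sex)
        if self.stratified:
            if stratum is None:
                raise ConfigurationError(
                    "lifetable is stratified: a stratum value is required"
                )
            key = (sex, str(stratum))
        else:
            if stratum is not None:
                raise ConfigurationError(
                    f"stratum {stratum!r} requested but the lifetable is unstratified"
                )
            key = (sex, _NO_STRATUM)
        try:
            return self._rates[key]
        except KeyError:
            raise ConfigurationError(
                f"no lifetable entries for sex={sex!r}, stratum={stratum!r}"
            ) from None


def load_lifetable(path, schema: LifetableSchema | None = None) -> Lifetable:
    """Read a delimited-text lifetable and validate it.

    The separator (comma or tab) is taken from the header line.  ``schema`` maps the
    file's column names onto age / sex / year / rate (+ optional stratum) and
    may recode sex labels via ``sex_map``; codes present in the file but
    absent from the map raise a :class:`SchemaError` naming the code.
    """
    schema = schema or LifetableSchema()
    from .io import read_delimited

    df = read_delimited(path)
    rename = {schema.age: "age", schema.sex: "sex", schema.year: "year", schema.rate: "rate"}
    if schema.stratum is not None:
        rename[schema.stratum] = "stratum"
    missing = [c for c in rename if c not in df.columns]
    if missing:
        raise SchemaError(
            f"lifetable file {path} is missing column(s) {missing}; found {list(df.columns)}"
        )
    df = df.rename(columns=rename)[list(rename.values())]
    if schema.sex_map is not None:
        raw = df["sex"].astype(str)
        mapping = {str(k): v for k, v in schema.sex_map.items()}
        unmapped = sorted(set(raw) - set(mapping))
        if unmapped:
            raise SchemaError(
                f"sex code(s) {unmapped} in {path} are not covered by the "
                f"declared sex mapping {mapping}"
            )
        df["sex"] = raw.map(mapping)
    return Lifetable.from_frame(df)


def write_lifetable(lt: Lifetable, path) -> None:
    """Write the table back as CSV; rates at 17 significant digits so a
    load/write round trip is bit-stable."""
    lt.to_frame().to_csv(path, index=False, float_format="%.17g")


def expected_hazard_at(lt: Lifetable, age_attained, sex, year_attained, stratum=None):
    """Rate of the band containing floor(age) and floor(year), clamped to the
    table's coverage (piecewise-constant ratetable convention)."""
    mat = lt._matrix(sex, stratum)
    i = int(np.clip(np.floor(age_attained), lt.age_min, lt.age_max)) - lt.age_min
    j = int(np.clip(np.floor(year_attained), lt.year_min, lt.year_max)) - lt.year_min
    return float(mat[i, j])


@dataclass(frozen=True)
class ExpectedTrajectory:
    """Expected cumulative hazard and survival of one subject on a time grid."""

    age: float
    sex: str
    year: float
    stratum: str | None
    t_grid: np.ndarray
    cumhaz: np.ndarray
    survival: np.ndarray


def _cumhaz_breakpoints(lt, age, sex, year, stratum, t_max):
    """Breakpoints and cumulative expected hazard along one subject's path.

    Returns (knot times, cumulative hazard at those times); the cumulative
    hazard is exactly piecewise linear between successive knots, so values at
    arbitrary t come from linear interpolation.
    """
    mat = lt._matrix(sex, stratum)
    # times at which the attained age or attained year crosses an integer
    cuts = {0.0, float(t_max)}
    frac_age = age - np.floor(age)
    frac_year = year - np.floor(year)
    for frac in (frac_age, frac_year):
        first = (1.0 - frac) % 1.0
        if first == 0.0:
            first = 1.0
        cuts.update(np.arange(first, t_max, 1.0))
    ts = np.array(sorted(c for c in cuts if 0.0 <= c <= t_max))
    cum = np.zeros_like(ts)
    for k in range(len(ts) - 1):
        a, b = ts[k], ts[k + 1]
        i = int(np.clip(np.floor(age + a), lt.age_min, lt.age_max)) - lt.age_min
        j = int(np.clip(np.floor(year + a), lt.year_min, lt.year_max)) - lt.year_min
        cum[k + 1] = cum[k] + mat[i, j] * (b - a)
    return ts, cum


def expected_survival(lt: Lifetable, age, sex, year, t_grid, stratum=None) -> ExpectedTrajectory:
    """Expected survival S*(t) of a subject diagnosed at the given age and
    calendar year, evaluated on a sorted nonnegative grid of years since
    diagnosis.

    The cumulative expected hazard is the exact integral of the
    piecewise-constant rate path, splitting at every age-band and
    calendar-year boundary.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1:
        raise DomainError("t_grid must be one-dimensional")
    if np.any(t_grid < 0):
        raise DomainError("negative follow-up time in t_grid")
    if np.any(np.diff(t_grid) < 0):
        raise DomainError("t_grid must be sorted")
    t_max = float(t_grid[-1]) if t_grid.size else 0.0
    ts, cum = _cumhaz_breakpoints(lt, float(age), sex, float(year), stratum, max(t_max, 1e-12))
    cumhaz = np.interp(t_grid, ts, cum)
    return ExpectedTrajectory(
        age=float(age),
        sex=str(sex),
        year=float(year),
        stratum=None if stratum is None else str(stratum),
        t_grid=t_grid,
        cumhaz=cumhaz,
        survival=np.exp(-cumhaz),
    )


def expected_survival_matrix(lt, frame, t_grid, stratum_col=None) -> np.ndarray:
    """S*(t) for every row of a patient frame: (n, len(t_grid)) array.

    ``frame`` needs columns age, sex, year; ``stratum_col`` names the column
    holding each record's lifetable stratum (required iff the table is
    stratified).  This is the parameter-free factor of all all-cause
    quantities, so it is computed once per analysis.
    """
    if lt.stratified and stratum_col is None:
        raise ConfigurationError(
            "lifetable is stratified: a stratum column must be declared"
        )
    t_grid = np.asarray(t_grid, dtype=float)
    out = np.empty((len(frame), t_grid.size))
    strata = frame[stratum_col] if lt.stratified else None
    for pos, (_, row) in enumerate(frame.iterrows()):
        s = str(strata.iloc[pos]) if lt.stratified else None
        out[pos] = expected_survival(
            lt, row["age"], row["sex"], row["year"], t_grid, stratum=s
        ).survival
    return out


def expected_hazard_at_exit(lt, frame, stratum_col=None) -> np.ndarray:
    """h*_i at each record's exit time (attained age/year), vectorised over a
    patient frame with columns age, sex, year, time."""
    if lt.stratified and stratum_col is None:
        raise ConfigurationError(
            "lifetable is stratified: a stratum column must be declared"
        )
    out = np.empty(len(frame))
    strata = frame[stratum_col] if lt.stratified else None
    for pos, (_, row) in enumerate(frame.iterrows()):
        s = str(strata.iloc[pos]) if lt.stratified else None
        out[pos] = expected_hazard_at(
            lt, row["age"] + row["time"], row["sex"], row["year"] + row["time"], stratum=s
        )
    return out
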