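"""Tabular input/output and shared grid conventions.

Every quantity in the package lives on a common age x sex grid: one-year age
classes 0..95 where 95 denotes the open-ended class "95+", and a two-level sex
factor (male, female).  All models are estimated and projected fully stratified
by sex.  This module defines the grid, the table containers used throughout
(:class:`RateTable`, :class:`PrevalenceTable`, ...), CSV readers/writers for
them, and the run-configuration parser.  No other module reads files.

Conventions: CSV with header row, UTF-8, "." decimal separator; floats are
written with 12 significant digits, which makes a write -> read cycle
idempotent (values that have been through one cycle round-trip bit-exactly).
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SEXES",
    "SMOKING_STATES",
    "OPEN_AGE",
    "AGES",
    "AgeSexGrid",
    "ValidationError",
    "RateTable",
    "PrevalenceTable",
    "StateRatioTable",
    "NewbornSeries",
    "RunConfig",
    "read_rate_table",
    "write_rate_table",
    "read_prevalence_table",
    "write_prevalence_table",
    "read_state_ratios",
    "write_state_ratios",
    "read_newborns",
    "write_newborns",
    "parse_config",
]

SEXES: tuple[str, str] = ("male", "female")
SMOKING_STATES: tuple[str, str, str] = ("never", "current", "former")
OPEN_AGE: int = 95
AGES: np.ndarray = np.arange(OPEN_AGE + 1)

_FLOAT_FMT = "%.12g"


class ValidationError(ValueError):
    """Raised when a table or configuration violates its contract."""


@dataclass(frozen=True)
class AgeSexGrid:
    """One-year age classes 0..95 (95 open-ended) crossed with sex.

    The grid is fixed for the whole package; instances exist mainly so that
    containers can carry and compare their grid explicitly.
    """

    ages: tuple[int, ...] = tuple(int(a) for a in AGES)
    sexes: tuple[str, ...] = SEXES
    open_age: int = OPEN_AGE

    def __post_init__(self) -> None:
        ages = self.ages
        if list(ages) != list(range(ages[0], ages[-1] + 1)):
            raise ValidationError("ages must be consecutive integers")
        if self.open_age not in ages:
            raise ValidationError(f"open age class {self.open_age} missing from grid")

    @property
    def n_ages(self) -> int:
        return len(self.ages)


DEFAULT_GRID = AgeSexGrid()


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValidationError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return sex


class RateTable:
    """Per-cell probability or rate on the age x sex grid.

    Parameters
    ----------
    values : mapping sex -> array of length 96
    kind : {"probability", "rate"}
        Probabilities are validated to lie in [0, 1]; rates to be >= 0.
    """

    def __init__(self, values: Mapping[str, np.ndarray], kind: str = "probability",
                 grid: AgeSexGrid = DEFAULT_GRID) -> None:
        if kind not in ("probability", "rate"):
            raise ValidationError(f"kind must be 'probability' or 'rate', got {kind!r}")
        self.kind = kind
        self.grid = grid
        self.values: dict[str, np.ndarray] = {}
        for sex in SEXES:
            if sex not in values:
                raise ValidationError(f"missing sex {sex!r}")
            v = np.asarray(values[sex], dtype=float)
            if v.shape != (grid.n_ages,):
                raise ValidationError(
                    f"values for {sex!r} must have length {grid.n_ages}, got {v.shape}")
            self._check_domain(v, sex)
            self.values[sex] = v.copy()

    def _check_domain(self, v: np.ndarray, sex: str) -> None:
        if not np.all(np.isfinite(v)):
            a = int(self.grid.ages[int(np.flatnonzero(~np.isfinite(v))[0])])
            raise ValidationError(f"non-finite value at cell (age={a}, sex={sex})")
        if self.kind == "probability":
            bad = (v < 0) | (v > 1)
        else:
            bad = v < 0
        if np.any(bad):
            a = int(self.grid.ages[int(np.flatnonzero(bad)[0])])
            raise ValidationError(
                f"value {v[bad][0]!r} outside domain for kind={self.kind!r} "
                f"at cell (age={a}, sex={sex})")

    def __getitem__(self, key: tuple[int, str]) -> float:
        age, sex = key
        return float(self.values[_check_sex(sex)][int(age)])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"age": int(age), "sex": sex, "value": self.values[sex][i]}
            for sex in SEXES
            for i, age in enumerate(self.grid.ages)
        ]
        return pd.DataFrame(rows)


class PrevalenceTable:
    """Smoking-state probabilities (never, current, former) per grid cell.

    Each row sums to 1; rows whose raw sum deviates by at most ``tol`` are
    renormalized, larger deviations are rejected.
    """

    def __init__(self, probs: Mapping[str, np.ndarray], grid: AgeSexGrid = DEFAULT_GRID,
                 tol: float = 1e-6) -> None:
        self.grid = grid
        self.probs: dict[str, np.ndarray] = {}
        for sex in SEXES:
            if sex not in probs:
                raise ValidationError(f"missing sex {sex!r}")
            p = np.asarray(probs[sex], dtype=float)
            if p.shape != (grid.n_ages, 3):
                raise ValidationError(
                    f"prevalence for {sex!r} must have shape ({grid.n_ages}, 3)")
            if np.any(~np.isfinite(p)) or np.any(p < 0):
                a = int(grid.ages[int(np.argwhere((~np.isfinite(p)) | (p < 0))[0, 0])])
                raise ValidationError(
                    f"negative or non-finite prevalence at cell (age={a}, sex={sex})")
            s = p.sum(axis=1)
            off = np.abs(s - 1.0)
            if np.any(off > tol):
                a = int(grid.ages[int(np.argmax(off))])
                raise ValidationError(
                    f"smoking-state prevalences sum to {s[np.argmax(off)]:.8f} != 1 "
                    f"at cell (age={a}, sex={sex})")
            # renormalize only rows measurably off 1; rows already exact to
            # within the 12-significant-digit write precision (three parsed
            # values can sum to 1 +- ~1e-12) stay untouched so that
            # write -> read cycles are bit-stable
            scale = np.where(off > 1e-11, s, 1.0)
            self.probs[sex] = p / scale[:, None]

    def __getitem__(self, key: tuple[int, str]) -> np.ndarray:
        age, sex = key
        return self.probs[_check_sex(sex)][int(age)].copy()

    def state(self, sex: str, state: str) -> np.ndarray:
        """Probability curve of one smoking state across ages."""
        return self.probs[_check_sex(sex)][:, SMOKING_STATES.index(state)].copy()

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sex in SEXES:
            for i, age in enumerate(self.grid.ages):
                p = self.probs[sex][i]
                rows.append({"age": int(age), "sex": sex,
                             "never": p[0], "current": p[1], "former": p[2]})
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class StateRatioTable:
    """Per-sex ratios (odds ratios or relative risks) for current and former
    smokers, relative to never smokers (ratio 1 by construction)."""

    current: Mapping[str, float]
    former: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, m in (("current", self.current), ("former", self.former)):
            for sex in SEXES:
                if sex not in m:
                    raise ValidationError(f"missing sex {sex!r} in {name} ratios")
                if not (float(m[sex]) > 0 and np.isfinite(m[sex])):
                    raise ValidationError(
                        f"ratio for {name}/{sex} must be positive, got {m[sex]!r}")

    def ratios(self, sex: str) -> np.ndarray:
        """(never, current, former) ratio triple for one sex."""
        _check_sex(sex)
        return np.array([1.0, float(self.current[sex]), float(self.former[sex])])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"sex": sex, "current": self.current[sex], "former": self.former[sex]}
             for sex in SEXES])


@dataclass(frozen=True)
class NewbornSeries:
    """Projected newborn counts per calendar year and sex."""

    years: tuple[int, ...]
    counts: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        ys = self.years
        if list(ys) != list(range(ys[0], ys[-1] + 1)):
            raise ValidationError("newborn years must be consecutive")
        for sex in SEXES:
            c = np.asarray(self.counts[sex], dtype=float)
            if c.shape != (len(ys),):
                raise ValidationError("newborn counts must match the year range")
            if np.any(c <= 0) or np.any(~np.isfinite(c)):
                raise ValidationError("newborn counts must be positive and finite")

    def count(self, year: int, sex: str) -> float:
        if not (self.years[0] <= year <= self.years[-1]):
            raise ValidationError(
                f"year {year} outside newborn series {self.years[0]}..{self.years[-1]}")
        return float(self.counts[_check_sex(sex)][year - self.years[0]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"year": y, "sex": sex, "count": self.counts[sex][i]}
             for sex in SEXES for i, y in enumerate(self.years)])


@dataclass
class RunConfig:
    """Run configuration with the study defaults.

    baseline_year 2018 with a 30-year horizon reports by default at age 15 in
    the years baseline+10 and baseline+30; 2500 simulated individuals per
    one-year age class per sex.
    """

    baseline_year: int = 2018
    horizon_years: int = 30
    n_per_class: int = 2500
    seed: int = 0
    scenario_names: list[str] = field(default_factory=lambda: ["reference"])
    report_ages: list[int] = field(default_factory=lambda: [15])
    report_years: list[int] | None = None

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValidationError("horizon_years must be >= 1")
        if self.n_per_class < 1:
            raise ValidationError("n_per_class must be >= 1")
        if self.report_years is None:
            self.report_years = [self.baseline_year + 10,
                                 self.baseline_year + self.horizon_years]


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _check_grid_complete(df: pd.DataFrame, path) -> None:
    dup = df.duplicated(subset=["age", "sex"])
    if dup.any():
        r = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate cell (age={int(r['age'])}, sex={r['sex']})")
    have = set(zip(df["age"].astype(int), df["sex"]))
    for sex in SEXES:
        for age in AGES:
            if (int(age), sex) not in have:
                raise ValidationError(f"{path}: missing cell (age={int(age)}, sex={sex})")
    extra = have - {(int(a), s) for a in AGES for s in SEXES}
    if extra:
        a, s = sorted(extra)[0]
        raise ValidationError(f"{path}: unexpected cell (age={a}, sex={s})")


def read_rate_table(path, kind: str = "probability") -> RateTable:
    """Read a per-cell table with columns age, sex, value."""
    df = _read_csv(path)
    for col in ("age", "sex", "value"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    _check_grid_complete(df, path)
    values = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex].sort_values("age")
        values[sex] = sub["value"].to_numpy(dtype=float)
    try:
        return RateTable(values, kind=kind)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_rate_table(table: RateTable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_prevalence_table(path) -> PrevalenceTable:
    """Read smoking-state prevalences with columns age, sex, never, current, former."""
    df = _read_csv(path)
    for col in ("age", "sex", "never", "current", "former"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    _check_grid_complete(df, path)
    probs = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex].sort_values("age")
        probs[sex] = sub[["never", "current", "former"]].to_numpy(dtype=float)
    try:
        return PrevalenceTable(probs)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_prevalence_table(table: PrevalenceTable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_state_ratios(path) -> StateRatioTable:
    """Read per-sex current/former ratios (odds ratios or relative risks)."""
    df = _read_csv(path)
    for col in ("sex", "current", "former"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    try:
        return StateRatioTable(
            current={r["sex"]: float(r["current"]) for _, r in df.iterrows()},
            former={r["sex"]: float(r["former"]) for _, r in df.iterrows()},
        )
    except (ValidationError, KeyError) as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_state_ratios(table: StateRatioTable, path) -> None:
    table.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_newborns(path) -> NewbornSeries:
    df = _read_csv(path)
    for col in ("year", "sex", "count"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    years = tuple(sorted(df["year"].astype(int).unique()))
    counts = {}
    for sex in SEXES:
        sub = df[df["sex"] == sex].sort_values("year")
        if tuple(sub["year"].astype(int)) != years:
            raise ValidationError(f"{path}: newborn years differ between sexes")
        counts[sex] = sub["count"].to_numpy(dtype=float)
    try:
        return NewbornSeries(years=years, counts=counts)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_newborns(series: NewbornSeries, path) -> None:
    series.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


def parse_config(path) -> RunConfig:
    """Parse a YAML key/value run configuration.

    Absent keys take their defaults; scenario names are resolved against the
    scenario registry so that typos fail at parse time.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a key/value mapping")
    known = {"baseline_year", "horizon_years", "n_per_class", "seed",
             "scenarios", "report_ages", "report_years"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("baseline_year", "horizon_years", "n_per_class", "seed"):
        if key in raw:
            val = raw[key]
            if not isinstance(val, int) or isinstance(val, bool):
                raise ValidationError(f"{path}: {key} must be an integer, got {val!r}")
            kwargs[key] = val
    for key in ("report_ages", "report_years"):
        if key in raw:
            vals = raw[key]
            if not isinstance(vals, list) or not all(
                    isinstance(v, int) and not isinstance(v, bool) for v in vals):
                raise ValidationError(f"{path}: {key} must be a list of integers")
            kwargs[key] = list(vals)
    if "scenarios" in raw:
        names = raw["scenarios"]
        if not isinstance(names, list) or not all(isinstance(n, str) for n in names):
            raise ValidationError(f"{path}: scenarios must be a list of names")
        from . import scenarios as _scenarios  # deferred: avoids import cycle

        valid = _scenarios.scenario_names()
        for name in names:
            if name not in valid:
                raise ValidationError(
                    f"{path}: unknown scenario {name!r}; valid names: {sorted(valid)}")
        kwargs["scenario_names"] = list(names)
    return RunConfig(**kwargs)


def write_config(cfg: RunConfig, path) -> None:
    data = {
        "baseline_year": cfg.baseline_year,
        "horizon_years": cfg.horizon_years,
        "n_per_class": cfg.n_per_class,
        "seed": cfg.seed,
        "scenarios": list(cfg.scenario_names),
        "report_ages": list(cfg.report_ages),
        "report_years": list(cfg.report_years or []),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
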