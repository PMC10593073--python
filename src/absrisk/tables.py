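"""Age-rate tables and covariate tables: the tabular inputs of an absolute
risk model.

An :class:`AgeRateTable` holds one annual event rate per single year of
age on a contiguous integer grid — it is used for the marginal disease
incidence ``lambda_m(a)``, the competing mortality rate ``m(a)``, and the
calibrated baseline hazard ``lambda_0(a)``. Rates are hazards per
person-year, treated as constant within ``[a, a+1)``.

A :class:`CovariateTable` couples a typed schema (numeric covariates, or
categorical covariates with an ordered level list whose first entry is the
reference level) with a row table in which missing values are explicit.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "InputError",
    "AgeRateTable",
    "Covariate",
    "CovariateTable",
    "load_rate_table",
    "write_rate_table",
]

#: Text tokens treated as missing in CSV input; JSON uses ``null``.
CSV_MISSING_TOKENS = ("", "NA")


class InputError(ValueError):
    """A user-input validation failure (malformed file, broken invariant).

    The CLI maps this to exit code 2; anything else is an internal error.
    """


# ---------------------------------------------------------------------------
# AgeRateTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AgeRateTable:
    """Per-age annual event rates on a contiguous integer age grid.

    Parameters
    ----------
    ages
        Strictly increasing, contiguous integer years.
    rates
        One rate per age, each in ``[0, 1)`` (probability/hazard per
        person-year).
    """

    ages: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages)
        rates = np.asarray(self.rates, dtype=float)
        if ages.ndim != 1 or rates.ndim != 1 or len(ages) != len(rates):
            raise InputError("ages and rates must be 1-D and equal length")
        if len(ages) == 0:
            raise InputError("rate table must contain at least one age")
        if not np.all(ages == ages.astype(int)):
            raise InputError("ages must be integer years")
        ages = ages.astype(np.int64)
        order = np.argsort(ages, kind="stable")
        ages, rates = ages[order], rates[order]
        dup = ages[:-1][np.diff(ages) == 0]
        if dup.size:
            raise InputError(f"duplicate age in rate table: {int(dup[0])}")
        gaps = np.where(np.diff(ages) != 1)[0]
        if gaps.size:
            missing = int(ages[gaps[0]]) + 1
            raise InputError(f"non-contiguous ages: missing {missing}")
        bad = ~((rates >= 0.0) & (rates < 1.0) & np.isfinite(rates))
        if np.any(bad):
            a = int(ages[np.argmax(bad)])
            r = rates[np.argmax(bad)]
            raise InputError(f"rate {r!r} at age {a} outside [0, 1)")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "rates", rates)
        self.ages.setflags(write=False)
        self.rates.setflags(write=False)

    @property
    def age_min(self) -> int:
        return int(self.ages[0])

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def rate_at(self, age: int | np.ndarray) -> float | np.ndarray:
        """Annual rate(s) at integer age(s); out-of-range is an error."""
        age = np.asarray(age)
        if np.any(age < self.age_min) or np.any(age > self.age_max):
            bad = age[(age < self.age_min) | (age > self.age_max)]
            raise InputError(
                f"age {int(np.atleast_1d(bad)[0])} outside rate table range "
                f"[{self.age_min}, {self.age_max}]"
            )
        out = self.rates[age - self.age_min]
        return float(out) if out.ndim == 0 else out

    def restrict(self, age_lo: int, age_hi: int) -> "AgeRateTable":
        """Restrict to the inclusive age window ``[age_lo, age_hi]``."""
        if age_lo < self.age_min or age_hi > self.age_max or age_lo > age_hi:
            raise InputError(
                f"window [{age_lo}, {age_hi}] not contained in "
                f"[{self.age_min}, {self.age_max}]"
            )
        sel = (self.ages >= age_lo) & (self.ages <= age_hi)
        return AgeRateTable(self.ages[sel], self.rates[sel])

    def to_dict(self) -> dict:
        return {"age": self.ages.tolist(), "rate": self.rates.tolist()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AgeRateTable):
            return NotImplemented
        return np.array_equal(self.ages, other.ages) and np.array_equal(
            self.rates, other.rates
        )


def load_rate_table(
    path_or_text: str | Path, format: Literal["csv", "json"] | None = None
) -> AgeRateTable:
    """Read an :class:`AgeRateTable` from a CSV/JSON file or raw text.

    CSV requires header columns ``age,rate``; JSON is an object with
    parallel arrays ``age`` and ``rate``. When ``format`` is omitted it is
    inferred from the file suffix (raw text defaults to CSV unless it
    starts with ``{``).
    """
    text, fmt = _read_source(path_or_text, format)
    if fmt == "json":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise InputError(f"invalid JSON rate table: {exc}") from exc
        if not isinstance(doc, dict) or "age" not in doc or "rate" not in doc:
            raise InputError("JSON rate table must have 'age' and 'rate' arrays")
        return AgeRateTable(np.asarray(doc["age"]), np.asarray(doc["rate"]))
    try:
        df = pd.read_csv(_io.StringIO(text), float_precision="round_trip")
    except Exception as exc:
        raise InputError(f"invalid CSV rate table: {exc}") from exc
    if list(df.columns)[:2] != ["age", "rate"]:
        raise InputError(
            f"CSV rate table must have header 'age,rate'; got {list(df.columns)}"
        )
    return AgeRateTable(df["age"].to_numpy(), df["rate"].to_numpy())


def write_rate_table(
    table: AgeRateTable, path: str | Path, format: Literal["csv", "json"] | None = None
) -> None:
    """Write a rate table to CSV (``age,rate``) or JSON (parallel arrays)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        path.write_text(json.dumps(table.to_dict(), indent=1) + "\n")
    else:
        pd.DataFrame(
            {"age": table.ages, "rate": table.rates}
        ).to_csv(path, index=False)


def _read_source(
    path_or_text: str | Path, format: Literal["csv", "json"] | None
) -> tuple[str, str]:
    if isinstance(path_or_text, Path) or (
        isinstance(path_or_text, str)
        and "\n" not in path_or_text
        and Path(path_or_text).is_file()
    ):
        path = Path(path_or_text)
        fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
        return path.read_text(), fmt
    text = str(path_or_text)
    fmt = format or ("json" if text.lstrip().startswith("{") else "csv")
    return text, fmt


# ---------------------------------------------------------------------------
# CovariateTable
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Covariate:
    """A typed covariate: numeric, or categorical with ordered levels.

    For categoricals the first level is the reference level used for dummy
    coding.
    """

    name: str
    kind: Literal["numeric", "categorical"]
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind == "categorical":
            if not self.levels or len(self.levels) < 1:
                raise InputError(
                    f"categorical covariate '{self.name}' needs a level list"
                )
            if len(set(self.levels)) != len(self.levels):
                raise InputError(f"duplicate levels for covariate '{self.name}'")
            object.__setattr__(self, "levels", tuple(str(v) for v in self.levels))
        elif self.kind == "numeric":
            if self.levels is not None:
                raise InputError(f"numeric covariate '{self.name}' cannot have levels")
        else:
            raise InputError(f"unknown covariate kind {self.kind!r}")


@dataclass
class CovariateTable:
    """Rows of covariate values validated against a schema.

    Missing values are ``NaN`` (numeric) or ``None`` (categorical) in the
    underlying DataFrame. Categorical values outside the declared level
    list are rejected on construction.
    """

    schema: tuple[Covariate, ...]
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.schema = tuple(self.schema)
        names = [c.name for c in self.schema]
        if len(set(names)) != len(names):
            raise InputError("duplicate covariate names in schema")
        missing_cols = [n for n in names if n not in self.data.columns]
        if missing_cols:
            raise InputError(f"data is missing covariate column(s) {missing_cols}")
        df = self.data.loc[:, names].copy()
        df.index = pd.RangeIndex(len(df))
        for cov in self.schema:
            col = df[cov.name]
            if cov.kind == "numeric":
                try:
                    df[cov.name] = pd.to_numeric(col)
                except (ValueError, TypeError) as exc:
                    raise InputError(
                        f"non-numeric value in numeric covariate '{cov.name}': {exc}"
                    ) from exc
            else:
                vals = col.astype("object").where(col.notna(), None)
                vals = vals.map(lambda v: None if v is None else str(v))
                bad = vals[~vals.isin(cov.levels) & vals.notna()]
                if len(bad):
                    raise InputError(
                        f"value {bad.iloc[0]!r} of covariate '{cov.name}' (row "
                        f"{int(bad.index[0])}) not in declared levels {list(cov.levels)}"
                    )
                df[cov.name] = vals
        self.data = df

    # -- basic views --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.schema]

    def covariate(self, name: str) -> Covariate:
        for c in self.schema:
            if c.name == name:
                return c
        raise InputError(f"unknown covariate '{name}'")

    def missing_mask(self) -> pd.DataFrame:
        """Boolean per-cell mask, True where the value is missing."""
        return self.data.isna()

    def is_complete(self) -> bool:
        return not self.missing_mask().to_numpy().any()

    def require_complete(self, what: str = "table") -> None:
        mask = self.missing_mask()
        if mask.to_numpy().any():
            row = int(mask.any(axis=1).idxmax())
            col = mask.loc[row][mask.loc[row]].index[0]
            raise InputError(
                f"{what} must be complete: missing value at row {row}, "
                f"column '{col}'"
            )

    def row(self, i: int) -> "CovariateTable":
        return CovariateTable(self.schema, self.data.iloc[[i]])

    def select(self, idx: Iterable[int]) -> "CovariateTable":
        return CovariateTable(self.schema, self.data.iloc[list(idx)])

    # -- I/O ----------------------------------------------------------------

    @classmethod
    def from_records(
        cls, schema: Sequence[Covariate], records: Sequence[dict]
    ) -> "CovariateTable":
        names = [c.name for c in schema]
        if len(records) == 0:
            return cls(tuple(schema), pd.DataFrame(columns=names))
        return cls(tuple(schema), pd.DataFrame.from_records(records))

    @classmethod
    def from_csv(
        cls, path_or_text: str | Path, schema: Sequence[Covariate]
    ) -> "CovariateTable":
        df = read_csv_with_missing(path_or_text)
        return cls(tuple(schema), df)

    def to_records(self) -> list[dict]:
        out = []
        for _, row in self.data.iterrows():
            rec = {}
            for cov in self.schema:
                v = row[cov.name]
                if pd.isna(v):
                    rec[cov.name] = None
                elif cov.kind == "numeric":
                    rec[cov.name] = float(v)
                else:
                    rec[cov.name] = str(v)
            out.append(rec)
        return out

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False, na_rep="NA")


def read_csv_with_missing(path_or_text: str | Path) -> pd.DataFrame:
    """Read a CSV where missing values are empty fields or the literal NA."""
    text, _ = _read_source(path_or_text, "csv")
    try:
        return pd.read_csv(
            _io.StringIO(text),
            na_values=list(CSV_MISSING_TOKENS),
            keep_default_na=False,
            skip_blank_lines=True,
            float_precision="round_trip",
        )
    except Exception as exc:
        raise InputError(f"invalid CSV: {exc}") from exc
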