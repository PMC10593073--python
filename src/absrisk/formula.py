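"""Text-formula engine: turn a formula and a covariate table into a named
design matrix of basis functions.

The grammar is a small, fully specified subset of R/patsy-style model
formulas:

* terms joined by ``+``
* interactions with ``:`` (elementwise products)
* crossing with ``*`` (``a*b`` expands to ``a + b + a:b``)
* integer powers of numeric covariates, ``x^2``
* elementwise transforms ``log(x)`` and ``sqrt(x)``
* categorical covariates expand to dummy indicator columns against their
  first declared level, named ``c[level]``

No intercept column is ever produced: relative-risk models are anchored by
the baseline hazard, so an intercept is unidentifiable. Column order is
canonical: main effects in formula order, then interactions (stable).
Missingness propagates per cell — a design cell is masked exactly when any
covariate it depends on is missing in that row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations, product
from typing import Sequence

import numpy as np

from .tables import Covariate, CovariateTable, InputError

__all__ = ["DesignMatrix", "FormulaError", "build_design_matrix", "reference_profile"]


class FormulaError(InputError):
    """A formula that cannot be parsed or applied to the given schema."""


@dataclass(frozen=True)
class DesignMatrix:
    """Numeric basis-function matrix with named columns and a missing mask.

    ``values[i, k]`` is NaN wherever ``mask[i, k]`` is True (a covariate
    the column depends on is missing in row ``i``).
    """

    columns: tuple[str, ...]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.mask.shape or self.values.shape[1] != len(
            self.columns
        ):
            raise ValueError("inconsistent design-matrix shapes")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def linear_predictor(self, beta: dict[str, float]) -> np.ndarray:
        """``beta^T phi(X)`` per row, matching coefficients to columns by
        name. All columns must be covered and no extra names allowed."""
        extra = sorted(set(beta) - set(self.columns))
        missing = sorted(set(self.columns) - set(beta))
        if extra or missing:
            raise InputError(
                "beta names do not match design columns: "
                f"design={sorted(self.columns)}, beta={sorted(beta)}"
                + (f"; unmatched beta {extra}" if extra else "")
                + (f"; uncovered columns {missing}" if missing else "")
            )
        if self.mask.any():
            i, k = np.argwhere(self.mask)[0]
            raise InputError(
                f"cannot form linear predictor: missing value in column "
                f"'{self.columns[k]}' at row {int(i)}"
            )
        b = np.array([beta[c] for c in self.columns])
        return self.values @ b

    def row(self, i: int) -> "DesignMatrix":
        return DesignMatrix(self.columns, self.values[[i]], self.mask[[i]])


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_NAME = r"[A-Za-z_][A-Za-z0-9_.]*"
_FACTOR_RE = re.compile(
    rf"^(?:(?P<func>log|sqrt)\((?P<arg>{_NAME})\)|(?P<base>{_NAME})(?:\^(?P<pow>\d+))?)$"
)


@dataclass(frozen=True)
class _Factor:
    """One multiplicand of a term: a covariate with an optional transform."""

    covariate: str
    func: str | None = None  # 'log' | 'sqrt'
    power: int = 1

    def render(self) -> str:
        if self.func:
            return f"{self.func}({self.covariate})"
        if self.power != 1:
            return f"{self.covariate}^{self.power}"
        return self.covariate


def _parse_factor(text: str) -> _Factor:
    text = text.strip()
    m = _FACTOR_RE.match(text)
    if not m:
        raise FormulaError(f"cannot parse formula factor {text!r}")
    if m.group("func"):
        return _Factor(m.group("arg"), func=m.group("func"))
    power = int(m.group("pow")) if m.group("pow") else 1
    if power < 1:
        raise FormulaError(f"power must be a positive integer in {text!r}")
    return _Factor(m.group("base"), power=power)


def _parse_terms(formula: str) -> list[tuple[_Factor, ...]]:
    """Parse into an ordered, de-duplicated list of terms (factor tuples),
    with ``*`` crossing expanded and interactions placed after main effects."""
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    raw_terms: list[tuple[_Factor, ...]] = []
    for chunk in formula.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise FormulaError(f"empty term in formula {formula!r}")
        cross_parts = [p.strip() for p in chunk.split("*")]
        # each * operand may itself be an interaction joined by ':'
        operands = [
            tuple(_parse_factor(f) for f in part.split(":")) for part in cross_parts
        ]
        if len(operands) == 1:
            raw_terms.append(operands[0])
        else:
            # a*b*c -> all non-empty subsets, smaller orders first
            for r in range(1, len(operands) + 1):
                for combo in combinations(range(len(operands)), r):
                    term = tuple(f for i in combo for f in operands[i])
                    raw_terms.append(term)
    # de-duplicate by unordered factor multiset, keep first occurrence
    seen: set[frozenset] = set()
    terms: list[tuple[_Factor, ...]] = []
    for t in raw_terms:
        key = frozenset((f, t.count(f)) for f in t)
        if key not in seen:
            seen.add(key)
            terms.append(t)
    # canonical order: main effects in formula order, then interactions
    # (stable, so within each interaction order the formula order is kept)
    terms.sort(key=len)
    return terms


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


def _factor_columns(
    factor: _Factor, data: CovariateTable
) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Evaluate one factor to a list of (name, values, missing) columns."""
    cov = _lookup(factor.covariate, data.schema)
    n = len(data)
    if cov.kind == "categorical":
        if factor.func:
            raise FormulaError(
                f"{factor.func}() cannot be applied to categorical '{cov.name}'"
            )
        if factor.power != 1:
            raise FormulaError(f"power of a categorical term: '{cov.name}'")
        col = data.data[cov.name]
        missing = col.isna().to_numpy()
        out = []
        for level in cov.levels[1:]:
            vals = (col == level).to_numpy(dtype=float)
            vals[missing] = np.nan
            out.append((f"{cov.name}[{level}]", vals, missing))
        return out
    x = data.data[cov.name].to_numpy(dtype=float)
    missing = np.isnan(x) if n else np.zeros(0, bool)
    if factor.func == "log":
        bad = (~missing) & (x <= 0)
        if bad.any():
            raise FormulaError(
                f"log of non-positive value {x[bad][0]!r} in covariate "
                f"'{cov.name}' at row {int(np.argmax(bad))}"
            )
        with np.errstate(invalid="ignore"):
            vals = np.log(x)
    elif factor.func == "sqrt":
        bad = (~missing) & (x < 0)
        if bad.any():
            raise FormulaError(
                f"sqrt of negative value {x[bad][0]!r} in covariate "
                f"'{cov.name}' at row {int(np.argmax(bad))}"
            )
        with np.errstate(invalid="ignore"):
            vals = np.sqrt(x)
    else:
        vals = x ** factor.power if factor.power != 1 else x.copy()
    return [(factor.render(), vals, missing)]


def _lookup(name: str, schema: Sequence[Covariate]) -> Covariate:
    for c in schema:
        if c.name == name:
            return c
    raise FormulaError(
        f"unknown covariate '{name}'; available: {[c.name for c in schema]}"
    )


def build_design_matrix(formula: str, data: CovariateTable) -> DesignMatrix:
    """Build the basis-function design matrix ``Phi(X)`` for ``formula``.

    Columns follow canonical order (main effects in formula order, then
    interactions); interaction columns are elementwise products named
    ``left:right``. No intercept is produced. See module docstring for the
    grammar.
    """
    terms = _parse_terms(formula)
    names: list[str] = []
    cols: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for term in terms:
        parts = [_factor_columns(f, data) for f in term]
        for combo in product(*parts):
            name = ":".join(p[0] for p in combo)
            vals = combo[0][1].copy()
            miss = combo[0][2].copy()
            for _, v, m in combo[1:]:
                vals = vals * v
                miss = miss | m
            vals[miss] = np.nan
            names.append(name)
            cols.append(vals)
            masks.append(miss)
    if len(set(names)) != len(names):
        dup = [n for n in names if names.count(n) > 1][0]
        raise FormulaError(f"formula produces duplicate column '{dup}'")
    n = len(data)
    values = np.column_stack(cols) if cols else np.zeros((n, 0))
    mask = np.column_stack(masks) if masks else np.zeros((n, 0), bool)
    return DesignMatrix(tuple(names), values, mask)


def reference_profile(formula: str, schema: Sequence[Covariate]) -> DesignMatrix:
    """The single design row of the reference profile.

    Numeric covariates sit at 0 and categoricals at their reference level,
    so every basis column is 0 by construction and the linear predictor is
    0 for any coefficient vector; the conditional hazard of this profile is
    the baseline hazard itself.
    """
    # Column names need the schema only; values are zeros by definition.
    probe = {c.name: (1.0 if c.kind == "numeric" else c.levels[0]) for c in schema}
    columns = build_design_matrix(
        formula, CovariateTable.from_records(schema, [probe])
    ).columns
    k = len(columns)
    return DesignMatrix(columns, np.zeros((1, k)), np.zeros((1, k), bool))
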