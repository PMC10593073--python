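"""The standardized model-specification document.

A model spec bundles the four inputs an absolute-risk model needs:

1. log relative risks ``beta``, named after design-matrix columns;
2. marginal age-specific disease incidence rates;
3. a complete-case reference dataset representing the risk-factor
   distribution of the target population;
4. age-specific competing mortality rates;

plus the basis-function formula text. The linear predictor is always
plugged into an exponential link, giving the proportional-hazards
conditional incidence rate ``lambda(a|Z) = lambda_0(a) * exp(beta^T Phi(Z))``.

The on-disk format is a single JSON document; rate tables and the
reference dataset may be inlined or referenced by relative path (CSV or
JSON). Structure is enforced with pydantic models; the generated
JSON Schema ships alongside this module (``model_spec.schema.json``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .formula import build_design_matrix
from .tables import (
    AgeRateTable,
    Covariate,
    CovariateTable,
    InputError,
    load_rate_table,
    read_csv_with_missing,
)

__all__ = ["ModelSpec", "load_model_spec", "write_model_spec", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1"


# ---------------------------------------------------------------------------
# JSON document structure (pydantic)
# ---------------------------------------------------------------------------


class CovariateDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    name: str
    kind: Literal["numeric", "categorical"]
    levels: list[str] | None = None


class RateTableDoc(BaseModel):
    """Inline rate table (parallel arrays) or a relative file reference."""

    model_config = ConfigDict(extra="forbid")
    age: list[int] | None = None
    rate: list[float] | None = None
    path: str | None = None


class ReferenceDoc(BaseModel):
    """Inline reference rows (records) or a relative CSV reference."""

    model_config = ConfigDict(extra="forbid")
    records: list[dict] | None = None
    path: str | None = None


class ModelSpecDoc(BaseModel):
    model_config = ConfigDict(extra="forbid")
    schema_version: str = SCHEMA_VERSION
    formula: str
    beta: dict[str, float]
    covariates: list[CovariateDoc] = Field(min_length=1)
    reference: ReferenceDoc
    incidence: RateTableDoc
    mortality: RateTableDoc


def model_spec_json_schema() -> dict:
    """The JSON Schema of the model-spec document."""
    return ModelSpecDoc.model_json_schema()


# ---------------------------------------------------------------------------
# In-memory ModelSpec
# ---------------------------------------------------------------------------


@dataclass
class ModelSpec:
    """A fully validated absolute-risk model definition.

    Invariants (enforced on construction):

    * the design matrix built from ``formula`` on ``reference`` has exactly
      the column names of ``beta`` (matched by name, order-free);
    * ``reference`` contains no missing values;
    * the incidence and mortality age grids overlap on a non-empty
      contiguous interval; all model operations are restricted to it.
    """

    formula: str
    beta: dict[str, float]
    reference: CovariateTable
    incidence: AgeRateTable
    mortality: AgeRateTable

    def __post_init__(self) -> None:
        if len(self.reference) < 1:
            raise InputError("reference dataset must have at least one row")
        self.reference.require_complete("reference dataset")
        design = build_design_matrix(self.formula, self.reference)
        if sorted(design.columns) != sorted(self.beta):
            raise InputError(
                "beta names do not match design-matrix columns: "
                f"design={sorted(design.columns)}, beta={sorted(self.beta)}"
            )
        lo = max(self.incidence.age_min, self.mortality.age_min)
        hi = min(self.incidence.age_max, self.mortality.age_max)
        if lo > hi:
            raise InputError(
                "incidence and mortality age ranges do not overlap: "
                f"[{self.incidence.age_min}, {self.incidence.age_max}] vs "
                f"[{self.mortality.age_min}, {self.mortality.age_max}]"
            )

    @property
    def age_min(self) -> int:
        """Lower end of the usable age range (grid intersection)."""
        return max(self.incidence.age_min, self.mortality.age_min)

    @property
    def age_max(self) -> int:
        """Upper end (inclusive) of the usable age range."""
        return min(self.incidence.age_max, self.mortality.age_max)

    @property
    def schema(self) -> tuple[Covariate, ...]:
        return self.reference.schema

    def reference_design(self):
        return build_design_matrix(self.formula, self.reference)

    def reference_eta(self) -> np.ndarray:
        """Linear predictors ``beta^T Phi(Z_i)`` over the reference rows."""
        return self.reference_design().linear_predictor(self.beta)


# ---------------------------------------------------------------------------
# Load / write
# ---------------------------------------------------------------------------


def _load_rate_doc(doc: RateTableDoc, base: Path, what: str) -> AgeRateTable:
    if doc.path is not None:
        if doc.age is not None or doc.rate is not None:
            raise InputError(f"{what}: give either inline age/rate or path, not both")
        return load_rate_table(base / doc.path)
    if doc.age is None or doc.rate is None:
        raise InputError(f"{what}: needs inline 'age'+'rate' arrays or a 'path'")
    return AgeRateTable(np.asarray(doc.age), np.asarray(doc.rate))


def _covariate_from_doc(doc: CovariateDoc) -> Covariate:
    levels = tuple(doc.levels) if doc.levels is not None else None
    return Covariate(doc.name, doc.kind, levels)


def load_model_spec(path: str | Path) -> ModelSpec:
    """Load and fully validate a model-spec JSON document.

    Relative ``path`` references inside the document resolve against the
    document's own directory.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise InputError(f"{path}: invalid JSON: {exc}") from exc
    try:
        doc = ModelSpecDoc.model_validate(raw)
    except ValidationError as exc:
        raise InputError(f"{path}: invalid model spec: {exc}") from exc
    base = path.parent
    schema = tuple(_covariate_from_doc(c) for c in doc.covariates)
    if doc.reference.path is not None:
        reference = CovariateTable.from_csv(base / doc.reference.path, schema)
    elif doc.reference.records is not None:
        reference = CovariateTable.from_records(schema, doc.reference.records)
    else:
        raise InputError("reference: needs inline 'records' or a 'path'")
    incidence = _load_rate_doc(doc.incidence, base, "incidence")
    mortality = _load_rate_doc(doc.mortality, base, "mortality")
    return ModelSpec(doc.formula, dict(doc.beta), reference, incidence, mortality)


def write_model_spec(spec: ModelSpec, path: str | Path) -> None:
    """Write a model spec as a self-contained (fully inlined) JSON document.

    Round-trip guarantee: loading the written document yields a spec
    semantically identical to ``spec``, preserving beta name order and
    categorical level order.
    """
    doc = ModelSpecDoc(
        schema_version=SCHEMA_VERSION,
        formula=spec.formula,
        beta=dict(spec.beta),
        covariates=[
            CovariateDoc(
                name=c.name,
                kind=c.kind,
                levels=list(c.levels) if c.levels else None,
            )
            for c in spec.schema
        ],
        reference=ReferenceDoc(records=spec.reference.to_records()),
        incidence=RateTableDoc(**spec.incidence.to_dict()),
        mortality=RateTableDoc(**spec.mortality.to_dict()),
    )
    Path(path).write_text(
        json.dumps(doc.model_dump(exclude_none=True), indent=1) + "\n"
    )
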