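"""Synthetic reference datasets and outcome cohorts.

Every stage of the pipeline is testable with no external data: covariates
are drawn from declared per-covariate distributions (categorical
probability vectors; normal or uniform numerics), and disease/competing
outcomes are simulated year by year from the same per-interval
probabilities the risk engine integrates
(:func:`absrisk.risk.interval_probabilities`). By the law of large numbers
the empirical disease proportion of a simulated cohort converges to the
mean predicted risk over the drawn profiles — the property the validation
module's calibration tests rely on.

All randomness flows through one ``numpy`` Generator seeded explicitly per
call; the same seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .formula import build_design_matrix
from .model_spec import ModelSpec
from .risk import interval_probabilities
from .tables import AgeRateTable, Covariate, CovariateTable, InputError
from .validate import ValidationCohort

__all__ = ["CategoricalDist", "NormalDist", "UniformDist", "generate_reference",
           "simulate_cohort", "simulate_outcomes"]


@dataclass(frozen=True)
class CategoricalDist:
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise InputError(
                f"categorical probabilities must be >= 0 and sum to 1, got {list(p)}"
            )


@dataclass(frozen=True)
class NormalDist:
    mean: float
    sd: float


@dataclass(frozen=True)
class UniformDist:
    lo: float
    hi: float


Distribution = CategoricalDist | NormalDist | UniformDist


def generate_reference(
    schema: list[Covariate],
    n: int,
    distributions: dict[str, Distribution],
    seed: int,
) -> CovariateTable:
    """Draw ``n`` complete covariate rows from declared distributions.

    Categorical covariates need a probability per declared level; numeric
    covariates a normal or uniform law. Bit-exact reproducible per seed.
    """
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    for cov in schema:
        try:
            dist = distributions[cov.name]
        except KeyError:
            raise InputError(f"no distribution declared for covariate '{cov.name}'")
        if cov.kind == "categorical":
            if not isinstance(dist, CategoricalDist):
                raise InputError(f"covariate '{cov.name}' needs a CategoricalDist")
            if len(dist.probs) != len(cov.levels):
                raise InputError(
                    f"covariate '{cov.name}': {len(dist.probs)} probabilities "
                    f"for {len(cov.levels)} levels"
                )
            idx = rng.choice(len(cov.levels), size=n, p=np.asarray(dist.probs))
            cols[cov.name] = np.asarray(cov.levels, dtype=object)[idx]
        elif isinstance(dist, NormalDist):
            cols[cov.name] = rng.normal(dist.mean, dist.sd, size=n)
        elif isinstance(dist, UniformDist):
            cols[cov.name] = rng.uniform(dist.lo, dist.hi, size=n)
        else:
            raise InputError(f"covariate '{cov.name}' needs a numeric distribution")
    df = pd.DataFrame(cols, columns=[c.name for c in schema])
    return CovariateTable(tuple(schema), df)


def simulate_outcomes(
    etas: np.ndarray,
    ages: np.ndarray,
    tau: int,
    baseline: AgeRateTable,
    mortality: AgeRateTable,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate the yearly competing-outcome process for each subject.

    Returns 1 where disease occurs within ``tau`` years of the subject's
    entry age, else 0 (competing death or disease-free survival). Uses the
    engine's own per-interval probabilities, so the two share one hazard
    convention.
    """
    etas = np.asarray(etas, dtype=float)
    ages = np.asarray(ages).astype(np.int64)
    n = len(etas)
    rr = np.exp(etas)
    outcome = np.zeros(n, dtype=np.int64)
    at_risk = np.ones(n, dtype=bool)
    for j in range(int(tau)):
        lam = baseline.rate_at(ages + j) * rr
        if np.any(lam >= 1.0):
            i = int(np.argmax(lam >= 1.0))
            raise InputError(
                f"annual disease hazard {lam[i]:.6g} >= 1 at age "
                f"{int(ages[i]) + j}; rate-scale violation"
            )
        p_dis, p_comp, _ = interval_probabilities(lam, mortality.rate_at(ages + j))
        u = rng.random(n)
        disease = at_risk & (u < p_dis)
        dead = at_risk & ~disease & (u < p_dis + p_comp)
        outcome[disease] = 1
        at_risk &= ~(disease | dead)
    return outcome


def simulate_cohort(
    spec: ModelSpec,
    baseline: AgeRateTable,
    n: int,
    entry_age,
    tau: int,
    seed: int,
    distributions: dict[str, Distribution] | None = None,
) -> ValidationCohort:
    """Simulate an outcome cohort under an absolute-risk model.

    Covariates are drawn from ``distributions`` when given, otherwise by
    resampling rows of the model's reference dataset with replacement.
    ``entry_age`` is a fixed integer age or an inclusive ``(lo, hi)``
    range sampled uniformly. Outcomes are interval-censored to the yearly
    grid: ``outcome = 1`` iff disease occurs within ``tau`` years.
    """
    rng = np.random.default_rng(seed)
    if distributions is not None:
        cov = generate_reference(
            list(spec.schema), n, distributions,
            seed=int(rng.integers(2**31)),
        )
    else:
        idx = rng.integers(len(spec.reference), size=n)
        cov = spec.reference.select(idx)
    if np.isscalar(entry_age):
        ages = np.full(n, int(entry_age))
    else:
        lo, hi = entry_age
        ages = rng.integers(int(lo), int(hi) + 1, size=n)
    age_hi = min(baseline.age_max, spec.mortality.age_max)
    age_lo = max(baseline.age_min, spec.mortality.age_min)
    if n and (ages.min() < age_lo or ages.max() + tau - 1 > age_hi):
        raise InputError(
            f"entry ages with horizon {tau} exit the model age range "
            f"[{age_lo}, {age_hi}]"
        )
    etas = build_design_matrix(spec.formula, cov).linear_predictor(spec.beta)
    outcome = simulate_outcomes(etas, ages, tau, baseline, spec.mortality, rng)
    return ValidationCohort(covariates=cov, entry_age=ages, outcome=outcome)


def cohort_to_frame(cohort: ValidationCohort) -> pd.DataFrame:
    """Flatten a cohort to the CSV layout `validate` reads back."""
    df = cohort.covariates.data.copy()
    df["age"] = cohort.entry_age
    df["outcome"] = cohort.outcome
    df["weight"] = cohort.weight
    return df
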