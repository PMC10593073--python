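"""Absolute-risk computation under competing mortality.

The absolute risk ``R(a, a+tau)`` is the probability that a disease-free
individual of age ``a`` develops the disease within ``tau`` years, in the
presence of competing mortality ``m(t)``:

    R = int_a^{a+tau} lambda(t|Z) exp(-int_a^t [lambda(u|Z) + m(u)] du) dt

with ``lambda(t|Z) = lambda_0(t) exp(eta)`` and ``eta = beta^T Phi(Z)``.

Hazards are piecewise constant on single-year age intervals ``[j, j+1)``,
which makes the integral available in closed form per interval: with
``lam_j = lambda_0(j) e^eta``, ``d_j = lam_j + m(j)`` and disease-free
survival ``S`` entering the interval,

    interval risk      = S * (lam_j / d_j) * (1 - e^{-d_j})
    interval mortality = S * (m_j   / d_j) * (1 - e^{-d_j})
    S after interval   = S * e^{-d_j}

A zero total hazard contributes nothing and leaves ``S`` unchanged. These
three per-interval probabilities sum to the probability mass of the
interval exactly, so ``R + P(competing event) + S(a+tau) = 1`` identically.
The cohort simulator draws outcomes from the same per-interval
probabilities (see :mod:`absrisk.simulate`), so engine and simulator share
one hazard convention by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .formula import build_design_matrix
from .model_spec import ModelSpec
from .tables import AgeRateTable, CovariateTable, InputError

__all__ = [
    "RiskResult",
    "conditional_hazard",
    "compute_risk",
    "compute_cohort_risks",
    "interval_probabilities",
    "risk_curve",
]


@dataclass(frozen=True)
class RiskResult:
    """Absolute risk of one subject over ``[age_start, age_start+horizon]``."""

    subject_id: str
    age_start: int
    horizon: int
    linear_predictor: float
    risk: float
    competing_risk: float
    disease_free_survival: float
    imputed: bool = False
    n_donors: int = 1


def interval_probabilities(
    lam: np.ndarray, mort: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-interval (disease, competing-event, survive) probabilities for
    one year under constant hazards ``lam`` and ``mort``.

    This is the single shared implementation of the piecewise-constant
    hazard convention used by both the risk engine and the cohort
    simulator. ``d = lam + mort = 0`` contributes nothing and survives with
    probability 1.
    """
    lam = np.asarray(lam, dtype=float)
    mort = np.asarray(mort, dtype=float)
    d = lam + mort
    safe = np.where(d > 0.0, d, 1.0)
    shrink = -np.expm1(-d)  # 1 - e^{-d}, accurate for small d
    p_disease = np.where(d > 0.0, lam / safe * shrink, 0.0)
    p_competing = np.where(d > 0.0, mort / safe * shrink, 0.0)
    p_survive = np.exp(-d)
    return p_disease, p_competing, p_survive


def conditional_hazard(age: int, eta: float, baseline: AgeRateTable) -> float:
    """Conditional incidence rate ``lambda_0(age) * exp(eta)`` at one age."""
    return float(baseline.rate_at(_int_age(age, "age"))) * float(np.exp(eta))


def risk_curve(
    etas: np.ndarray,
    ages: np.ndarray,
    tau: int,
    baseline: AgeRateTable,
    mortality: AgeRateTable,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized closed-form accumulation over ``tau`` yearly intervals.

    Returns per-subject ``(risk, competing_risk, disease_free_survival)``
    for subjects with linear predictors ``etas`` entering at integer
    ``ages``. Raises when any annual disease hazard reaches 1/year.
    """
    etas = np.atleast_1d(np.asarray(etas, dtype=float))
    ages = np.atleast_1d(np.asarray(ages)).astype(np.int64)
    if tau <= 0 or int(tau) != tau:
        raise InputError(f"projection interval tau must be a positive integer, got {tau!r}")
    tau = int(tau)
    lo = max(baseline.age_min, mortality.age_min)
    hi = min(baseline.age_max, mortality.age_max)
    if np.any(ages < lo) or np.any(ages + tau - 1 > hi):
        bad = ages[(ages < lo) | (ages + tau - 1 > hi)][0]
        raise InputError(
            f"interval [{int(bad)}, {int(bad) + tau}) exits the model age "
            f"range [{lo}, {hi}]"
        )
    rr = np.exp(etas)
    risk = np.zeros_like(rr)
    comp = np.zeros_like(rr)
    surv = np.ones_like(rr)
    for j in range(tau):
        lam = baseline.rate_at(ages + j) * rr
        if np.any(lam >= 1.0):
            i = int(np.argmax(lam >= 1.0))
            raise InputError(
                f"annual disease hazard {lam[i]:.6g} >= 1 at age "
                f"{int(ages[i]) + j} (eta={etas[i]:.6g}); rate-scale violation"
            )
        p_dis, p_comp, p_surv = interval_probabilities(lam, mortality.rate_at(ages + j))
        risk += surv * p_dis
        comp += surv * p_comp
        surv = surv * p_surv
    return risk, comp, surv


def compute_risk(
    spec: ModelSpec,
    baseline: AgeRateTable,
    profile_row,
    a: int,
    tau: int,
    subject_id: str = "0",
) -> RiskResult:
    """Absolute risk for a single complete profile over ``[a, a+tau]``.

    ``profile_row`` is a one-row design matrix (see
    :func:`absrisk.formula.build_design_matrix`); its cells must be
    unmasked — imputation handles missing covariates upstream.
    """
    a = _int_age(a, "entry age")
    if profile_row.n_rows != 1:
        raise InputError("compute_risk expects a single design row")
    eta = float(profile_row.linear_predictor(spec.beta)[0])
    risk, comp, surv = risk_curve([eta], [a], tau, baseline, spec.mortality)
    return RiskResult(
        subject_id=str(subject_id),
        age_start=a,
        horizon=int(tau),
        linear_predictor=eta,
        risk=float(risk[0]),
        competing_risk=float(comp[0]),
        disease_free_survival=float(surv[0]),
    )


def compute_cohort_risks(
    spec: ModelSpec,
    baseline: AgeRateTable,
    profiles: CovariateTable,
    a,
    tau: int,
    subject_ids=None,
) -> list[RiskResult]:
    """Vectorized :func:`compute_risk` over the rows of ``profiles``.

    ``a`` may be a scalar entry age or one integer per row. Rows must be
    complete; route incomplete profiles through
    :func:`absrisk.impute.impute_risk` first. Per-row failures are reported
    with their row index.
    """
    n = len(profiles)
    ages = np.broadcast_to(np.asarray(a), (n,)).astype(object)
    ages = np.array([_int_age(x, f"entry age (row {i})") for i, x in enumerate(ages)])
    ids = [str(i) for i in range(n)] if subject_ids is None else [str(s) for s in subject_ids]
    profiles.require_complete("profiles table")
    design = build_design_matrix(spec.formula, profiles)
    etas = design.linear_predictor(spec.beta)
    risk, comp, surv = risk_curve(etas, ages, tau, baseline, spec.mortality)
    return [
        RiskResult(ids[i], int(ages[i]), int(tau), float(etas[i]), float(risk[i]),
                   float(comp[i]), float(surv[i]))
        for i in range(n)
    ]


def _int_age(a, what: str) -> int:
    if isinstance(a, (bool, np.bool_)):
        raise InputError(f"{what} must be an integer, got {a!r}")
    af = float(a)
    if af != int(af):
        raise InputError(f"{what} must be an integer year, got {a!r}")
    return int(af)
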