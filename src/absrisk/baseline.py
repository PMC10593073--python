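"""Baseline-hazard calibration against marginal incidence rates.

Registries publish the *marginal* age-specific incidence rate
``lambda_m(a)`` — the population average over risk-factor profiles. The
proportional-hazards model instead needs the *baseline* hazard
``lambda_0(a)``, the incidence at the reference profile. Averaging the
model over the reference dataset and equating to the marginal rate gives

    lambda_m(a) = lambda_0(a) * (1/n) sum_i exp(beta^T Phi(Z_i))

so ``lambda_0(a) = lambda_m(a) / M`` with ``M`` the mean relative risk over
the reference rows. ``M`` is age-invariant because the reference dataset
carries no age stratification; the calibration identity — the
reference-mean of ``lambda_0(a) exp(beta^T Z)`` recovering ``lambda_m(a)``
at every age — then holds exactly.
"""

from __future__ import annotations

import numpy as np

from .formula import DesignMatrix
from .tables import AgeRateTable, InputError

__all__ = ["estimate_baseline", "mean_relative_risk"]


def mean_relative_risk(reference_design: DesignMatrix, beta: dict[str, float]) -> float:
    """Unweighted mean of ``exp(beta^T Phi(Z_i))`` over the reference rows."""
    if reference_design.mask.any():
        raise InputError("reference design matrix must have no missing cells")
    eta = reference_design.linear_predictor(beta)
    with np.errstate(over="raise"):
        try:
            m = float(np.mean(np.exp(eta)))
        except FloatingPointError as exc:
            raise InputError(
                "overflow in exp(beta^T Z) while averaging relative risks; "
                "rescale covariates or coefficients"
            ) from exc
    if not np.isfinite(m) or m <= 0.0:
        raise InputError(
            f"mean relative risk M={m!r} is not a positive finite number; "
            "rescale covariates or coefficients"
        )
    return m


def estimate_baseline(
    incidence: AgeRateTable, reference_design: DesignMatrix, beta: dict[str, float]
) -> AgeRateTable:
    """Estimate ``lambda_0(a)`` from marginal incidence and the reference
    risk-factor distribution.

    Returns a rate table on the same age grid as ``incidence``. Raises if
    any calibrated baseline rate reaches 1/year (the model is incompatible
    with the rate table) or if the mean relative risk overflows.
    """
    m = mean_relative_risk(reference_design, beta)
    lam0 = incidence.rates / m
    if np.any(lam0 >= 1.0):
        age = int(incidence.ages[np.argmax(lam0 >= 1.0)])
        raise InputError(
            f"calibrated baseline hazard >= 1/year at age {age} "
            f"(marginal rate / M with M={m:.6g}); model incompatible with "
            "this incidence table"
        )
    return AgeRateTable(incidence.ages.copy(), lam0)
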