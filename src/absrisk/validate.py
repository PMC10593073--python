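"""Model validation on an independent cohort or nested case-control study.

Calibration in the large is summarised by the expected/observed ratio
``E/O`` with a log-normal 95% CI; calibration across the risk spectrum by
a decile table (weighted quantiles of predicted risk) with a Poisson-type
chi-square goodness-of-fit, ``sum_d (O_d - E_d)^2 / E_d`` on the number of
groups as degrees of freedom; discrimination by the weighted pairwise
concordance (AUC) with a Hanley–McNeil CI on effective case/control
counts. Nested case-control designs are supported through user-supplied
inverse selection-probability weights — controls sampled at rate ``p``
carry weight ``1/p``.

The outcome is disease within ``tau`` years of entry. Subjects censored
before ``a + tau`` without disease are excluded, with the count logged and
reported — never silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .impute import impute_risk
from .model_spec import ModelSpec
from .risk import compute_cohort_risks
from .tables import AgeRateTable, Covariate, CovariateTable, InputError, read_csv_with_missing

__all__ = [
    "ValidationCohort",
    "ValidationReport",
    "expected_observed",
    "calibration_by_decile",
    "auc",
    "validate",
]

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ValidationCohort:
    """Per-subject validation data.

    ``followup`` (years observed, NaN = complete follow-up) lets the
    validator drop subjects censored before the projection horizon.
    ``weight`` defaults to 1; use inverse selection probabilities for
    nested case-control samples.
    """

    covariates: CovariateTable
    entry_age: np.ndarray
    outcome: np.ndarray
    weight: np.ndarray = None
    followup: np.ndarray = None

    def __post_init__(self) -> None:
        n = len(self.covariates)
        self.entry_age = np.asarray(self.entry_age)
        self.outcome = np.asarray(self.outcome)
        if self.weight is None:
            self.weight = np.ones(n)
        self.weight = np.asarray(self.weight, dtype=float)
        if self.followup is None:
            self.followup = np.full(n, np.nan)
        self.followup = np.asarray(self.followup, dtype=float)
        for name, arr in [("entry_age", self.entry_age), ("outcome", self.outcome),
                          ("weight", self.weight), ("followup", self.followup)]:
            if len(arr) != n:
                raise InputError(f"cohort column '{name}' length {len(arr)} != {n} rows")
        if not np.isin(self.outcome, [0, 1]).all():
            raise InputError("outcome must be binary 0/1")
        self.outcome = self.outcome.astype(np.int64)
        if np.any(~np.isfinite(self.weight)) or np.any(self.weight <= 0):
            raise InputError("sampling weights must be positive and finite")

    def __len__(self) -> int:
        return len(self.covariates)

    @classmethod
    def from_csv(cls, path_or_text, schema: list[Covariate]) -> "ValidationCohort":
        """Read a cohort CSV: covariate columns plus ``age``, ``outcome``
        and optional ``weight`` / ``followup``."""
        df = read_csv_with_missing(path_or_text)
        for col in ("age", "outcome"):
            if col not in df.columns:
                raise InputError(f"cohort CSV needs an '{col}' column")
        cov = CovariateTable([c for c in schema], df)
        return cls(
            covariates=cov,
            entry_age=df["age"].to_numpy(),
            outcome=df["outcome"].to_numpy(),
            weight=df["weight"].to_numpy() if "weight" in df.columns else None,
            followup=df["followup"].to_numpy() if "followup" in df.columns else None,
        )


@dataclass
class ValidationReport:
    """Calibration and discrimination summary of one validation run."""

    n: int
    n_effective: float
    n_excluded_censored: int
    n_imputed: int
    tau: int
    expected: float
    observed: float
    eo_ratio: float
    eo_ci: tuple[float, float]
    deciles: pd.DataFrame = field(repr=False)
    gof_statistic: float
    gof_df: int
    gof_p_value: float
    auc: float
    auc_ci: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "n_effective": self.n_effective,
            "n_excluded_censored": self.n_excluded_censored,
            "n_imputed": self.n_imputed,
            "tau": self.tau,
            "expected": self.expected,
            "observed": self.observed,
            "eo_ratio": self.eo_ratio,
            "eo_ci": list(self.eo_ci),
            "calibration": {
                "statistic": self.gof_statistic,
                "df": self.gof_df,
                "p_value": self.gof_p_value,
            },
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "deciles": self.deciles.to_dict(orient="records"),
        }


# ---------------------------------------------------------------------------
# Calibration in the large
# ---------------------------------------------------------------------------


def expected_observed(risks, outcomes, weights=None) -> tuple[float, tuple[float, float]]:
    """Expected/observed ratio with a log-normal 95% CI.

    ``E = sum w R`` and ``O = sum w y``; the CI uses the effective observed
    count ``(sum w y)^2 / sum w^2 y`` so that up-weighted subsamples do not
    fake precision.
    """
    r, y, w = _ryw(risks, outcomes, weights)
    e = float(w @ r)
    o = float(w @ y)
    if o <= 0:
        raise InputError("no observed events")
    o_eff = o**2 / float((w**2) @ y)
    ratio = e / o
    half = Z95 * np.sqrt(1.0 / o_eff)
    ci = (float(ratio * np.exp(-half)), float(ratio * np.exp(half)))
    return ratio, ci


def _ryw(risks, outcomes, weights):
    r = np.asarray(risks, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    w = np.ones_like(r) if weights is None else np.asarray(weights, dtype=float)
    if not (len(r) == len(y) == len(w)):
        raise InputError("risks, outcomes and weights must have equal length")
    return r, y, w


# ---------------------------------------------------------------------------
# Decile calibration
# ---------------------------------------------------------------------------


def calibration_by_decile(
    risks, outcomes, weights=None, n_groups: int = 10
) -> tuple[pd.DataFrame, float, int, float]:
    """Calibration table over weighted deciles of predicted risk.

    Subjects are assigned to groups by cumulative weight in stable order of
    predicted risk (ties broken by input order); adjacent groups that add
    no new risk values collapse, and a group with zero expected count is
    merged into its neighbour, so degenerate risk distributions yield fewer
    groups. Returns ``(table, chi-square statistic, df, p-value)`` with
    ``df`` the number of final groups.
    """
    r, y, w = _ryw(risks, outcomes, weights)
    n = len(r)
    if n < n_groups:
        raise InputError(f"need at least {n_groups} subjects, got {n}")
    order = np.argsort(r, kind="stable")
    ws = w[order]
    cum = np.cumsum(ws) - 0.5 * ws  # midpoint cumulative weight
    total = ws.sum()
    group = np.minimum((cum / total * n_groups).astype(int), n_groups - 1)

    # collapse adjacent groups whose risk range adds no new values
    members: list[np.ndarray] = []
    for g in range(n_groups):
        idx = order[group == g]
        if idx.size == 0:
            continue
        lo, hi = r[idx].min(), r[idx].max()
        if members and lo == hi == r[members[-1]].max():
            members[-1] = np.concatenate([members[-1], idx])
        else:
            members.append(idx)
    # merge zero-expected groups into a neighbour
    merged = True
    while merged and len(members) > 1:
        merged = False
        for g, idx in enumerate(members):
            if float(w[idx] @ r[idx]) == 0.0:
                nbr = g + 1 if g + 1 < len(members) else g - 1
                logger.warning("merging decile group %d with zero expected count", g)
                members[nbr] = np.concatenate([members[nbr], members[g]])
                del members[g]
                merged = True
                break

    rows = []
    for g, idx in enumerate(members):
        wg, rg, yg = w[idx], r[idx], y[idx]
        rows.append({
            "group": g + 1,
            "n": int(idx.size),
            "weight": float(wg.sum()),
            "risk_lo": float(rg.min()),
            "risk_hi": float(rg.max()),
            "mean_predicted": float(wg @ rg / wg.sum()),
            "expected": float(wg @ rg),
            "observed": float(wg @ yg),
            "observed_rate": float(wg @ yg / wg.sum()),
        })
    table = pd.DataFrame(rows)
    e_d = table["expected"].to_numpy()
    o_d = table["observed"].to_numpy()
    statistic = float(np.sum((o_d - e_d) ** 2 / e_d))
    df = len(members)
    p_value = float(stats.chi2.sf(statistic, df))
    return table, statistic, df, p_value


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------


def auc(risks, outcomes, weights=None) -> tuple[float, tuple[float, float]]:
    """Weighted pairwise concordance with a Hanley–McNeil 95% CI.

    ``AUC = sum_{i case, j control} w_i w_j [1(R_i > R_j) + 1/2 1(R_i = R_j)]
    / (W_case W_control)``, computed in ``O(n log n)`` by sorting; the CI
    uses effective case/control counts ``(sum w)^2 / sum w^2`` and is
    truncated to ``[0, 1]``.
    """
    r, y, w = _ryw(risks, outcomes, weights)
    cases = y == 1
    w1, w0 = w[cases], w[~cases]
    if w1.size == 0 or w0.size == 0:
        raise InputError("AUC needs at least one case and one control")
    # group by unique risk value, scan ascending
    order = np.argsort(r, kind="stable")
    rs, ys, wsv = r[order], y[order], w[order]
    _, start = np.unique(rs, return_index=True)
    numer = 0.0
    ctrl_below = 0.0
    boundaries = list(start) + [len(rs)]
    for b, e in zip(boundaries[:-1], boundaries[1:]):
        blk_w = wsv[b:e]
        blk_y = ys[b:e]
        case_here = float(blk_w[blk_y == 1].sum())
        ctrl_here = float(blk_w[blk_y == 0].sum())
        numer += case_here * (ctrl_below + 0.5 * ctrl_here)
        ctrl_below += ctrl_here
    a = numer / (float(w1.sum()) * float(w0.sum()))
    n1 = float(w1.sum()) ** 2 / float((w1**2).sum())
    n0 = float(w0.sum()) ** 2 / float((w0**2).sum())
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    half = Z95 * np.sqrt(max(var, 0.0))
    return float(a), (float(max(0.0, a - half)), float(min(1.0, a + half)))


# ---------------------------------------------------------------------------
# End-to-end validation
# ---------------------------------------------------------------------------


def validate(
    spec: ModelSpec,
    baseline: AgeRateTable,
    cohort: ValidationCohort,
    tau: int,
) -> ValidationReport:
    """Validate an absolute-risk model on a cohort.

    Computes each subject's predicted risk over ``[a_i, a_i + tau]``
    (imputing missing covariates from the reference dataset), then
    assembles the E/O ratio, the decile calibration table with its
    goodness-of-fit test, and the AUC. Deterministic given its inputs.

    Weights are normalized to sum to the subject count, so the report is
    invariant under uniform rescaling of the weights (only relative
    weights carry information).
    """
    tau = int(tau)
    censored = (cohort.outcome == 0) & (cohort.followup < tau)
    n_excluded = int(censored.sum())
    if n_excluded:
        logger.warning(
            "excluding %d subjects censored before the %d-year horizon",
            n_excluded, tau,
        )
    keep = np.where(~censored)[0]
    cov = cohort.covariates.select(keep)
    ages = cohort.entry_age[keep]
    y = cohort.outcome[keep]
    w = cohort.weight[keep]
    n_effective = float(w.sum() ** 2 / (w**2).sum())  # Kish effective n
    w = w * (len(keep) / w.sum())  # scale-invariant report

    missing_rows = cov.missing_mask().any(axis=1).to_numpy()
    risks = np.empty(len(cov))
    complete_idx = np.where(~missing_rows)[0]
    if complete_idx.size:
        res = compute_cohort_risks(
            spec, baseline, cov.select(complete_idx), ages[complete_idx], tau
        )
        risks[complete_idx] = [x.risk for x in res]
    for i in np.where(missing_rows)[0]:
        risks[i] = impute_risk(spec, baseline, cov.row(int(i)), int(ages[i]), tau).risk
    n_imputed = int(missing_rows.sum())

    ratio, ci = expected_observed(risks, y, w)
    table, statistic, df, p_value = calibration_by_decile(risks, y, w)
    a, aci = auc(risks, y, w)
    return ValidationReport(
        n=int(len(cov)),
        n_effective=n_effective,
        n_excluded_censored=n_excluded,
        n_imputed=n_imputed,
        tau=tau,
        expected=float(w @ risks),
        observed=float(w @ y),
        eo_ratio=ratio,
        eo_ci=ci,
        deciles=table,
        gof_statistic=statistic,
        gof_df=df,
        gof_p_value=p_value,
        auc=a,
        auc_ci=aci,
    )
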