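# Methods

## Model and hazard convention

The conditional incidence rate is a proportional-hazards model,
λ(a|Z) = λ₀(a)·exp(βᵀΦ(Z)), with a fixed exponential link: the linear
predictor η = βᵀΦ(Z) enters only through exp(η). Absolute risk over
[a, a+τ] is the cumulative incidence in the presence of competing
mortality m(·),

R(a, a+τ) = ∫ₐ^{a+τ} λ(t|Z) exp(−∫ₐᵗ [λ(u|Z) + m(u)] du) dt.

All rate tables are indexed by integer single year of age, matching how
"age-specific" rates are universally published, and hazards are **piecewise
constant on [j, j+1)**. Under that convention the integral is exact per
yearly interval: with λⱼ = λ₀(j)e^η, dⱼ = λⱼ + m(j) and disease-free
survival S entering interval j,

- interval disease probability = S·(λⱼ/dⱼ)(1 − e^(−dⱼ)),
- interval competing probability = S·(mⱼ/dⱼ)(1 − e^(−dⱼ)),
- S ← S·e^(−dⱼ); a dⱼ = 0 interval contributes nothing.

This closed form was chosen over a left-Riemann sum or the discrete product
(1 − λ − m) because it is exact under the declared convention and remains
correct for large annual rates. The three per-interval terms sum to the
interval's probability mass identically, so R + P(competing event) +
S(a+τ) = 1 holds to rounding error — asserted in tests at 1e-10. The
engine is verified two independent ways: against the constant-hazard
closed form (λ/(λ+m))(1 − e^(−(λ+m)τ)) to 1e-10, and against midpoint-rule
numerical integration at Δt = 1e-4 years to 1e-6 on randomized age-varying
fixtures (the midpoint rule keeps the integration error O(Δt²) because the
hazard is smooth within each step when Δt divides the year evenly).

Entry ages and τ are integers; fractional values are rejected rather than
rounded, since silent rounding hides unit errors. Hazards are computed in
log space until exponentiation; an annual disease hazard ≥ 1/yr is a hard
error naming the age and η, never clipped — clipping would silently break
calibration. The model operates only on the intersection of the incidence
and mortality age grids; projection outside it is an error, not an
extrapolation.

## Formula grammar

The basis functions Φ are declared by a deliberately small, closed grammar
rather than an open-ended formula language: `+` for terms, `:` for
interactions, `*` for crossing (`a*b ≡ a + b + a:b`), integer powers
`x^2`, and elementwise `log(x)` / `sqrt(x)`. Categorical covariates
dummy-code against their **first declared level** (model authors must
control the reference category; alphabetical ordering would take it away),
producing columns `c[level]`; interactions are named `left:right` in
formula order because β is matched to columns **by name**, never by
position. No intercept is ever produced — the model is anchored by λ₀(a)
and an intercept would be unidentifiable. `log` rejects non-positive
values (not merely negatives): log(0) = −∞ would silently corrupt the
design matrix. Missingness propagates per cell: a design cell is masked
exactly when any covariate it depends on is missing in that row.

## Baseline calibration

λ₀(a) = λ_m(a)/M with M the unweighted mean of exp(η) over the reference
rows, computed once from the age-invariant reference distribution (the
reference dataset carries no age stratification; an age-stratified M is a
known possible refinement, not implemented). No correction is applied for
depletion of susceptibles over follow-up — the marginal rate is treated as
the cross-sectional population rate at each age. The defining identity,
mean over the reference of λ₀(a)·exp(η) = λ_m(a) at every age, is enforced
by test at 1e-12 relative tolerance.

## Imputation of missing risk factors

A profile with missing factors is completed from the donor pool of
reference rows that match its observed factors: exact match on observed
categoricals, and observed numerics within half the reference's
interdecile range (q90 − q10)/2 — a scale-free rule chosen because
distances on raw covariate scales are not comparable. Each donor yields
one completed row with uniform weight 1/|pool|, and the reported risk is
the **weighted mean of absolute risks** over completed profiles, not the
risk of a mean profile: R is nonlinear (convex at low rates) in η, so
averaging covariates first would bias risks downward and break population
calibration; a dedicated test demonstrates the difference on a wide donor
pool. An empty pool falls back to the full reference — a population-average
risk with a logged warning beats a hard failure when a risk must be
delivered to an end user. The procedure uses every donor deterministically;
no random subsampling, so delivered risks are seed-free.

## Validation

Predicted risks (imputing where covariates are missing) are compared with
binary outcomes "disease within τ years of entry". Subjects censored
disease-free before a+τ are excluded with a logged and reported count; no
person-time adjustment is attempted, so the exclusion is always explicit.
Summaries:

- **E/O** = Σwᵢ Rᵢ / Σwᵢ yᵢ with a log-normal 95% CI,
  exp(log E/O ± 1.96·√(1/O_eff)), O_eff = (Σwy)²/Σw²y — the effective
  observed count keeps up-weighted subsamples from faking precision.
- **Decile table**: groups by cumulative weight in stable order of
  predicted risk; an adjacent group adding no new risk values collapses
  into its predecessor (so an all-constant risk vector yields one group),
  and a zero-expected group merges into its neighbour rather than being
  divided by. Goodness-of-fit is the Poisson-type chi-square
  Σ(O_d − E_d)²/E_d with df = number of final groups — the standard
  statistic for absolute-risk calibration, chosen for its closed,
  deterministic form.
- **AUC**: weighted pairwise concordance (ties count ½), computed by a
  sort-and-scan in O(n log n) and tested against an O(n²) enumeration
  oracle exactly; CI by Hanley–McNeil on Kish effective case/control
  counts, truncated to [0,1]. Bootstrap CIs were deliberately excluded in
  favour of closed forms.
- Nested case-control designs are supported through user-supplied inverse
  selection-probability weights; the tool does not estimate selection
  probabilities, since sampling designs vary too much to guess.

Weights are normalized to sum to n inside `validate`, making the whole
report invariant under uniform weight rescaling (only relative weights
carry information); the reported sample size under weighting is the Kish
effective n = (Σw)²/Σw².

## Synthetic data

The generator emulates a literature-based cancer-risk study: a reference
population with a standardized continuous exposure (normal), a bounded
continuous exposure (uniform), and an ordered categorical factor; marginal
incidence rising from ~1 to ~4 per 1000 person-years across ages 40–80 and
exponentially increasing competing mortality — the shapes typical of
female breast-cancer incidence and all-cause mortality at these ages.
Outcome simulation draws each subject's yearly disease/death/survive
trichotomy from the *same* per-interval probabilities the risk engine
integrates (one shared implementation), so the empirical event proportion
converges to the mean predicted risk by construction; a 200,000-draw test
confirms agreement within 3 binomial standard errors. Cohorts are
interval-censored to the yearly grid; no continuous event times are
emitted, matching the validation module's outcome definition. Each call
uses one explicitly seeded generator, giving byte-identical outputs per
seed and no global random state.

What the synthetic study does **not** emulate: real covariate
distributions or published rate tables, correlated risk factors,
measurement error, informative censoring or loss to follow-up, secular
trends in rates, or covariates that change within the projection interval.
Passing tests therefore demonstrate internal statistical correctness of
the machinery — calibration identities, coverage, consistency of weighted
designs — not the external validity of any particular fitted model.

## Problem sizes and numerical choices

Test and acceptance runs use reference datasets of 500–2000 rows, cohorts
of 5,000–20,000 subjects, 200 replicates for CI-coverage checks, and
200,000 draws for simulator agreement — sizes at which Monte-Carlo noise
is well below the tolerances being asserted while the full suite stays
fast. Quantile computation uses numpy's linear-interpolation default;
decile ties are broken by stable input order; 1 − e^(−d) is computed with
`expm1` to keep precision at small hazards; overflow in exp(η) during
baseline calibration raises an error advising covariate rescaling rather
than propagating infinities.

## Known limitations

Single-year hazard granularity (no sub-annual projection); no time-varying
covariates within the interval; β is an input, never estimated; the donor
matching rule and the validation CI/test forms are declared conventions of
this package rather than consensus standards, isolated behind their module
boundaries so alternatives can be substituted.
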