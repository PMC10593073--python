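"""Absolute-risk computation: closed-form values, the numerical-integration
oracle, decomposition, and monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import absrisk as ar

from conftest import make_model


def const_table(lo, hi, rate):
    ages = np.arange(lo, hi + 1)
    return ar.AgeRateTable(ages, np.full(len(ages), rate))


def one_row(eta_col_value=0.0):
    return ar.DesignMatrix(
        ("x",), np.array([[eta_col_value]]), np.zeros((1, 1), bool)
    )


def make_flat_model(lam, mort, lo=40, hi=80):
    """Single-covariate model whose reference sits at the reference profile,
    so the calibrated baseline equals the marginal incidence."""
    ref = ar.CovariateTable.from_records([ar.Covariate("x", "numeric")], [{"x": 0.0}])
    return ar.ModelSpec(
        "x", {"x": 1.0}, ref, const_table(lo, hi, lam), const_table(lo, hi, mort)
    )


def closed_form(lam, m, tau):
    """Constant-hazard closed form (lam/(lam+m)) (1 - e^{-(lam+m) tau})."""
    d = lam + m
    if d == 0:
        return 0.0
    return lam / d * -np.expm1(-d * tau)


def riemann_oracle(lam0, mort, eta, a, tau, dt=1e-4):
    """Midpoint-rule numerical integration of the cumulative-incidence
    integral under the piecewise-constant yearly hazard convention.
    Independent of the engine's closed-form accumulation."""
    steps_per_year = int(round(1.0 / dt))
    lam_years = lam0.rate_at(np.arange(a, a + tau)) * np.exp(eta)
    m_years = mort.rate_at(np.arange(a, a + tau))
    lam_fine = np.repeat(lam_years, steps_per_year)
    d_fine = np.repeat(lam_years + m_years, steps_per_year)
    cum_at_left = np.concatenate([[0.0], np.cumsum(d_fine * dt)[:-1]])
    cum_mid = cum_at_left + 0.5 * d_fine * dt
    return float(np.sum(lam_fine * np.exp(-cum_mid) * dt))


class TestConditionalHazard:
    def test_reference_profile_gives_baseline(self, baseline):
        assert ar.conditional_hazard(55, 0.0, baseline) == baseline.rate_at(55)

    def test_log2_doubles(self):
        b = const_table(50, 60, 0.001)
        assert ar.conditional_hazard(50, np.log(2.0), b) == pytest.approx(0.002)

    def test_age_out_of_range(self, baseline):
        with pytest.raises(ar.InputError, match="outside"):
            ar.conditional_hazard(200, 0.0, baseline)


class TestComputeRisk:
    def test_zero_disease_hazard(self):
        spec = make_flat_model(0.0, 0.02)
        res = ar.compute_risk(spec, const_table(40, 80, 0.0), one_row(), 50, 10)
        assert res.risk == 0.0
        assert res.disease_free_survival == pytest.approx(np.exp(-0.02 * 10), rel=1e-12)

    def test_constant_hazard_closed_form(self):
        lam, m, tau = 0.01, 0.02, 10
        spec = make_flat_model(lam, m)
        res = ar.compute_risk(spec, const_table(40, 80, lam), one_row(), 50, tau)
        expected = closed_form(lam, m, tau)
        assert expected == pytest.approx(0.0863939, abs=1e-6)
        assert res.risk == pytest.approx(expected, abs=1e-12)
        assert res.risk == pytest.approx(
            riemann_oracle(const_table(40, 80, lam), spec.mortality, 0.0, 50, tau),
            abs=1e-6,
        )

    def test_no_competing_risk_single_year(self):
        lam = 0.015
        spec = make_flat_model(lam, 0.0)
        res = ar.compute_risk(spec, const_table(40, 80, lam), one_row(), 60, 1)
        assert res.risk == pytest.approx(-np.expm1(-lam), rel=1e-12)

    def test_eta_scales_hazard(self):
        lam, m, tau = 0.005, 0.01, 5
        spec = make_flat_model(lam, m)
        base = const_table(40, 80, lam)
        res = ar.compute_risk(spec, base, one_row(np.log(2.0)), 50, tau)
        assert res.linear_predictor == pytest.approx(np.log(2.0))
        assert res.risk == pytest.approx(closed_form(2 * lam, m, tau), rel=1e-12)

    def test_decomposition_sums_to_one(self, model, baseline):
        res = ar.compute_cohort_risks(
            model, baseline, model.reference.select(range(20)), 45, 20
        )
        for r in res:
            total = r.risk + r.competing_risk + r.disease_free_survival
            assert total == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("tau", [0, -3])
    def test_nonpositive_tau(self, model, baseline, tau):
        with pytest.raises(ar.InputError, match="tau"):
            ar.compute_risk(model, baseline, one_row_for(model), 50, tau)

    def test_interval_exits_grid(self, model, baseline):
        with pytest.raises(ar.InputError, match="exits the model age range"):
            ar.compute_risk(model, baseline, one_row_for(model), 75, 10)

    def test_fractional_entry_age_rejected(self, model, baseline):
        with pytest.raises(ar.InputError, match="integer"):
            ar.compute_risk(model, baseline, one_row_for(model), 50.5, 5)

    def test_hazard_at_or_above_one_names_age_and_eta(self):
        spec = make_flat_model(0.5, 0.0)
        with pytest.raises(ar.InputError, match="age 50.*eta"):
            ar.compute_risk(spec, const_table(40, 80, 0.5), one_row(1.0), 50, 5)


def one_row_for(model):
    return ar.build_design_matrix(model.formula, model.reference.row(0))


class TestCohort:
    def test_single_row_matches_scalar_path(self, model, baseline):
        row = model.reference.row(3)
        scalar = ar.compute_risk(
            model, baseline, ar.build_design_matrix(model.formula, row), 50, 5
        )
        vec = ar.compute_cohort_risks(model, baseline, row, 50, 5)[0]
        assert vec.risk == scalar.risk
        assert vec.linear_predictor == scalar.linear_predictor

    def test_permutation_equivariance(self, model, baseline):
        profiles = model.reference.select(range(10))
        perm = [7, 2, 9, 0, 1, 3, 8, 4, 6, 5]
        direct = ar.compute_cohort_risks(model, baseline, profiles, 50, 5)
        permuted = ar.compute_cohort_risks(
            model, baseline, profiles.select(perm), 50, 5
        )
        for i, p in enumerate(perm):
            assert permuted[i].risk == direct[p].risk

    def test_duplicated_row_bit_identical(self, model, baseline):
        profiles = model.reference.select([4, 4])
        a, b = ar.compute_cohort_risks(model, baseline, profiles, 55, 8)
        assert a.risk == b.risk and a.linear_predictor == b.linear_predictor

    def test_per_row_entry_ages(self, model, baseline):
        profiles = model.reference.select([0, 1])
        res = ar.compute_cohort_risks(model, baseline, profiles, [45, 60], 5)
        assert [r.age_start for r in res] == [45, 60]

    def test_incomplete_profiles_rejected(self, model, baseline):
        bad = ar.CovariateTable.from_records(
            model.schema, [{"bmi": None, "alcohol": 0.0, "parity": "1-2"}]
        )
        with pytest.raises(ar.InputError, match="missing"):
            ar.compute_cohort_risks(model, baseline, bad, 50, 5)


class TestMonotonicity:
    @given(
        lam=st.floats(1e-5, 0.2),
        m=st.floats(0.0, 0.3),
        eta=st.floats(-1.0, 1.0),
        tau=st.integers(1, 20),
    )
    @settings(deadline=None, max_examples=60)
    def test_risk_bounds_and_growth_in_tau(self, lam, m, eta, tau):
        if lam * np.exp(eta) >= 1.0:
            return
        spec = make_flat_model(lam, m)
        base = const_table(40, 80, lam)
        risks = [
            ar.compute_risk(spec, base, one_row(eta), 45, t).risk
            for t in range(1, tau + 1)
        ]
        assert all(0.0 <= r <= 1.0 for r in risks)
        assert all(b > a for a, b in zip(risks, risks[1:]))  # strict while lam>0

    @given(m=st.floats(0.0, 0.45), dm=st.floats(0.0, 0.45))
    @settings(deadline=None, max_examples=40)
    def test_raising_competing_mortality_never_raises_risk(self, m, dm):
        lam = 0.01
        spec_lo = make_flat_model(lam, m)
        spec_hi = make_flat_model(lam, m + dm)
        base = const_table(40, 80, lam)
        r_lo = ar.compute_risk(spec_lo, base, one_row(), 50, 10).risk
        r_hi = ar.compute_risk(spec_hi, base, one_row(), 50, 10).risk
        assert r_hi <= r_lo + 1e-15

    @given(eta1=st.floats(-2, 2), eta2=st.floats(-2, 2))
    @settings(deadline=None, max_examples=40)
    def test_monotone_in_linear_predictor(self, eta1, eta2):
        lam = 0.005
        spec = make_flat_model(lam, 0.01)
        base = const_table(40, 80, lam)
        lo, hi = sorted([eta1, eta2])
        r_lo = ar.compute_risk(spec, base, one_row(lo), 50, 10).risk
        r_hi = ar.compute_risk(spec, base, one_row(hi), 50, 10).risk
        assert r_hi >= r_lo


class TestOracleAgreement:
    def test_age_varying_fixtures_match_fine_grid(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            ages = np.arange(40, 75)
            lam0 = ar.AgeRateTable(ages, rng.uniform(0.0005, 0.02, len(ages)))
            mort = ar.AgeRateTable(ages, rng.uniform(0.001, 0.05, len(ages)))
            eta = float(rng.normal(scale=0.5))
            a = int(rng.integers(40, 60))
            tau = int(rng.integers(1, 75 - a))
            engine = ar.risk_curve([eta], [a], tau, lam0, mort)[0][0]
            assert engine == pytest.approx(
                riemann_oracle(lam0, mort, eta, a, tau), abs=1e-6
            )
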