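import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from necsim.curves import (
    ECxQuery,
    LogLogisticParams,
    NECParams,
    ParameterDomainError,
    analytic_ecx_loglogistic,
    analytic_ecx_nec,
    loglogistic_survival_prob,
    matched_loglogistic_from_nec,
    nec_survival_prob,
)

nec_params = st.builds(
    NECParams,
    intercept_l=st.floats(0.05, 1.0),
    slope_m=st.floats(0.1, 50.0),
    threshold_c=st.floats(0.0, 0.9),
)
ll_params = st.builds(
    LogLogisticParams,
    intercept_d=st.floats(0.05, 1.0),
    slope_b=st.floats(0.2, 50.0),
    inflection_e=st.floats(1e-3, 2.0),
)
effect_q = st.floats(0.01, 0.99)


class TestNECCurve:
    def test_at_threshold_equals_intercept(self):
        p = nec_survival_prob(NECParams(0.90, 10.0, 0.20), 0.20)
        assert p == pytest.approx(0.90)

    def test_shallow_ec50_halves_survival(self):
        # survival at the analytic EC50 is half the intercept
        p = nec_survival_prob(NECParams(0.90, 3.0, 0.20), 0.4310)
        assert p == pytest.approx(0.45, abs=1e-3)

    def test_exponential_half_life(self):
        p = nec_survival_prob(NECParams(0.95, 5.0, 0.20), 0.20 + math.log(2) / 5)
        assert p == pytest.approx(0.475, abs=1e-12)

    def test_vectorized_and_continuous_at_threshold(self):
        params = NECParams(0.9, 5.0, 0.2)
        x = np.array([0.0, 0.2 - 1e-12, 0.2, 0.2 + 1e-12, 1.0])
        p = nec_survival_prob(params, x)
        assert p[0] == p[1] == p[2]
        assert p[3] == pytest.approx(p[2], abs=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ParameterDomainError):
            nec_survival_prob(NECParams(0.9, 5.0, 0.2), -0.1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(intercept_l=0.0, slope_m=5.0, threshold_c=0.2),
            dict(intercept_l=1.1, slope_m=5.0, threshold_c=0.2),
            dict(intercept_l=0.9, slope_m=0.0, threshold_c=0.2),
            dict(intercept_l=0.9, slope_m=5.0, threshold_c=1.0),
            dict(intercept_l=0.9, slope_m=5.0, threshold_c=-0.1),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterDomainError):
            NECParams(**kwargs)

    @given(params=nec_params, x=st.floats(0.0, 1.0))
    def test_never_exceeds_intercept_and_flat_below_threshold(self, params, x):
        p = nec_survival_prob(params, x)
        assert p <= params.intercept_l + 1e-15
        if x <= params.threshold_c:
            assert p == params.intercept_l


class TestLogLogisticCurve:
    def test_survival_at_inflection_is_half_asymptote(self):
        p = loglogistic_survival_prob(LogLogisticParams(0.9, 5.0, 0.3386), 0.3386)
        assert p == pytest.approx(0.45)

    def test_limit_at_zero(self):
        p = loglogistic_survival_prob(LogLogisticParams(1.0, 3.0, 0.4310), 0.0)
        assert p == pytest.approx(1.0)

    def test_shallow_ec10_gives_90pct_of_asymptote(self):
        p = loglogistic_survival_prob(LogLogisticParams(0.9, 3.0, 0.4310), 0.2072)
        assert p == pytest.approx(0.81, abs=1e-3)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(intercept_d=0.0, slope_b=3.0, inflection_e=0.3),
            dict(intercept_d=0.9, slope_b=-1.0, inflection_e=0.3),
            dict(intercept_d=0.9, slope_b=3.0, inflection_e=0.0),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ParameterDomainError):
            LogLogisticParams(**kwargs)

    @given(params=ll_params)
    def test_strictly_decreasing(self, params):
        x = np.linspace(0.01, 1.0, 30)
        p = loglogistic_survival_prob(params, x)
        # strictly decreasing wherever not saturated to 0 or d in floats
        assert np.all(np.diff(p) <= 0)
        interior = (p > 1e-300) & (p < params.intercept_d * (1 - 1e-9))
        assert np.all(np.diff(p[interior]) < 0)


class TestAnalyticECx:
    def test_nec_ec50_shallow(self):
        assert analytic_ecx_nec(NECParams(0.9, 3.0, 0.2), 0.5) == pytest.approx(
            0.4310, abs=5e-5
        )

    def test_nec_ec10_shallow(self):
        assert analytic_ecx_nec(NECParams(0.9, 3.0, 0.2), 0.1) == pytest.approx(
            0.2351, abs=5e-5
        )

    def test_infinitely_steep_collapses_to_threshold(self):
        assert analytic_ecx_nec(NECParams(0.9, 1e12, 0.2), 0.5) == pytest.approx(
            0.20, abs=1e-9
        )

    def test_ll_ec5_shallow(self):
        assert analytic_ecx_loglogistic(
            LogLogisticParams(0.9, 3.0, 0.4310), 0.05
        ) == pytest.approx(0.1615, abs=5e-5)

    def test_ll_ec10_intermediate(self):
        assert analytic_ecx_loglogistic(
            LogLogisticParams(0.9, 5.0, 0.3386), 0.10
        ) == pytest.approx(0.2182, abs=5e-5)

    @given(params=ll_params)
    def test_ec50_is_inflection(self, params):
        assert analytic_ecx_loglogistic(params, 0.5) == pytest.approx(
            params.inflection_e, rel=1e-12
        )

    def test_query_domain(self):
        with pytest.raises(ParameterDomainError):
            ECxQuery(0.0)
        with pytest.raises(ParameterDomainError):
            ECxQuery(1.0)

    @given(params=nec_params, q=effect_q)
    def test_nec_round_trip(self, params, q):
        x = analytic_ecx_nec(params, q)
        assert nec_survival_prob(params, x) == pytest.approx(
            (1 - q) * params.intercept_l, abs=1e-10
        )

    @given(params=ll_params, q=effect_q)
    def test_ll_round_trip(self, params, q):
        x = analytic_ecx_loglogistic(params, q)
        assert loglogistic_survival_prob(params, x) == pytest.approx(
            (1 - q) * params.intercept_d, abs=1e-10
        )

    @given(params=nec_params)
    def test_nec_ecx_monotone_in_q(self, params):
        qs = np.linspace(0.05, 0.95, 10)
        ecx = [analytic_ecx_nec(params, q) for q in qs]
        assert np.all(np.diff(ecx) > 0)

    @given(params=ll_params)
    def test_ll_ecx_monotone_in_q(self, params):
        qs = np.linspace(0.05, 0.95, 10)
        ecx = [analytic_ecx_loglogistic(params, q) for q in qs]
        assert np.all(np.diff(ecx) > 0)


class TestMatchedCurves:
    @pytest.mark.parametrize(
        "m,b,expected_e",
        [(3.0, 3.0, 0.4310), (5.0, 5.0, 0.3386), (10.0, 10.0, 0.2693)],
    )
    def test_inflection_matches_nec_ec50(self, m, b, expected_e):
        nec = NECParams(0.90, m, 0.20)
        ll = matched_loglogistic_from_nec(nec, b)
        assert ll.inflection_e == pytest.approx(expected_e, abs=5e-5)
        assert ll.intercept_d == nec.intercept_l
        assert ll.slope_b == b
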