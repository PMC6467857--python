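"""Rate expressions, the maturation function, and the ODE right-hand side."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lhigp.model import (CommunityState, ModelParameters, ParameterError,
                         ingestion_rates, juvenile_mortality, maturation_rate,
                         net_production, rates, rhs, tradeoff_adult_attack)

from conftest import CR_C, CR_R


class TestTradeoff:
    @pytest.mark.parametrize("a_jr, a_p, eps, expected", [
        (0.0, 6.0, 0.0, 6.0),            # full adult specialization
        (6.0, 6.0, 0.0, 0.0),            # full juvenile specialization
        (3.0, 6.0, 5.0, 6.0 / 7.0),      # strong trade-off, direct evaluation
        (3.0, 6.0, 0.0, 3.0),            # linear trade-off midpoint
    ])
    def test_values(self, a_jr, a_p, eps, expected):
        assert tradeoff_adult_attack(a_jr, a_p, eps) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("a_jr, eps", [(-0.1, 0.0), (6.1, 0.0), (3.0, -1.0), (3.0, -1.5)])
    def test_domain_errors(self, a_jr, eps):
        with pytest.raises(ParameterError):
            tradeoff_adult_attack(a_jr, 6.0, eps)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(eps=st.floats(-0.95, 5.0), a_p=st.floats(0.5, 10.0),
           frac=st.floats(0.0, 1.0))
    def test_monotone_decreasing_with_fixed_endpoints(self, eps, a_p, frac):
        """The map a_jr -> a_ac falls from a_p to 0 for every admissible shape."""
        assert tradeoff_adult_attack(0.0, a_p, eps) == pytest.approx(a_p)
        assert tradeoff_adult_attack(a_p, a_p, eps) == 0.0
        a_jr = frac * a_p
        val = tradeoff_adult_attack(a_jr, a_p, eps)
        assert 0.0 <= val <= a_p
        h = 1e-6 * a_p
        if a_jr + h <= a_p:
            assert tradeoff_adult_attack(a_jr + h, a_p, eps) < val + 1e-15


class TestRates:
    def test_consumer_half_saturation(self, params):
        p = params(a_jr=4.0)
        I_c, _, _ = ingestion_rates([1.0, 0.0, 0.0, 0.0], p)
        assert I_c == pytest.approx(0.5 / p.h_c)  # half of maximum ingestion

    def test_consumer_ingestion_at_min_resource(self, params):
        # at the consumer's minimum resource density nu_c = mu_c, so I_c = 2.2
        I_c, _, _ = ingestion_rates([CR_R, 0.0, 0.0, 0.0], params(a_jr=4.0))
        assert I_c == pytest.approx(2.2, abs=1e-12)

    def test_adult_ingestion_on_consumers_only(self, params):
        # a_jr=4 gives a_ac=2 under the linear trade-off
        p = params(a_jr=4.0)
        _, _, I_a = ingestion_rates([0.0, CR_C, 0.0, 0.0], p)
        expected = 2.0 * CR_C / (1.0 + 0.25 * 2.0 * CR_C)
        assert I_a == pytest.approx(expected, abs=1e-12)
        assert I_a == pytest.approx(1.527378, abs=1e-6)

    @pytest.mark.parametrize("I, role, expected", [
        (2.2, "consumer", 0.1),   # exactly covers mu_c at the persistence boundary
        (2.0, "juvenile", 0.6),
        (0.0, "adult", -0.4),     # starving: nu = -T
        (0.0, "consumer", -1.0),
    ])
    def test_net_production(self, I, role, expected, params):
        assert net_production(I, params(a_jr=4.0), role) == pytest.approx(expected)

    def test_juvenile_mortality(self, params):
        p0 = params(a_jr=4.0, beta=0.0)
        assert juvenile_mortality([1.0, 1.0, 1.0, 5.0], p0) == pytest.approx(p0.mu_p)
        # beta=1, a_ac=2, R=C=0, Pj=Pa=1: D_j = mu_p + 2/(1 + 0.25*2)
        p1 = params(a_jr=4.0, beta=1.0)
        assert juvenile_mortality([0.0, 0.0, 1.0, 1.0], p1) == pytest.approx(
            0.04 + 2.0 / 1.5, abs=1e-9)
        assert juvenile_mortality([1.0, 1.0, 1.0, 0.0], p1) == pytest.approx(p1.mu_p)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(R=st.floats(0, 50), C=st.floats(0, 20), Pj=st.floats(0, 20),
           Pa=st.floats(0, 20), a_jr=st.floats(0, 6), beta=st.floats(0, 2),
           a_ar=st.floats(0, 6))
    def test_ingestion_saturation_bounds(self, R, C, Pj, Pa, a_jr, beta, a_ar):
        """Holling type II never exceeds the inverse handling time."""
        p = ModelParameters(a_jr=a_jr, a_ar=a_ar, beta=beta)
        I_c, I_j, I_a = ingestion_rates([R, C, Pj, Pa], p)
        assert 0.0 <= I_c < 1.0 / p.h_c
        assert 0.0 <= I_j < 1.0 / p.h_p
        assert 0.0 <= I_a < 1.0 / p.h_p
        b = rates([R, C, Pj, Pa], p)
        assert b.D_j >= p.mu_p
        assert b.gamma >= 0.0


class TestMaturation:
    def test_direct_evaluation(self):
        assert maturation_rate(0.1, 0.04, 0.01) == pytest.approx(
            0.06 / (1.0 - 0.01 ** 0.6), abs=1e-12)
        assert maturation_rate(0.1, 0.04, 0.01) == pytest.approx(0.064041, abs=1e-6)

    def test_removable_singularity_exact(self):
        # at nu_j == D_j the printed expression has limit -nu_j/ln(z)
        assert maturation_rate(0.04, 0.04, 0.01) == pytest.approx(
            0.04 / math.log(100.0), rel=1e-14)

    def test_starving_juveniles_do_not_mature(self):
        assert maturation_rate(-0.1, 0.04, 0.01) == 0.0
        assert maturation_rate(0.0, 0.04, 0.01) == 0.0

    def test_continuity_across_singularity(self):
        """Two-sided limits approach the exact on-singularity value: the
        deviation shrinks linearly with the offset (the function is smooth,
        not merely patched), reaching 1e-10 agreement near the point."""
        g0 = maturation_rate(0.04, 0.04, 0.01)
        for eps in (1e-11, 1e-12, 1e-13):
            assert maturation_rate(0.04 + eps, 0.04, 0.01) == pytest.approx(g0, abs=1e-10)
            assert maturation_rate(0.04 - eps, 0.04, 0.01) == pytest.approx(g0, abs=1e-10)
        devs = [abs(maturation_rate(0.04 + eps, 0.04, 0.01) - g0)
                for eps in (1e-4, 1e-5, 1e-6)]
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 1e-5

    def test_extreme_mortality_ratio_is_finite(self):
        assert maturation_rate(1e-6, 10.0, 0.01) == 0.0


class TestRhs:
    def test_resource_only_equilibrium(self, params):
        p = params(a_jr=4.0)
        np.testing.assert_allclose(rhs([3.0, 0, 0, 0], p), np.zeros(4), atol=1e-14)

    def test_cr_closed_form_is_equilibrium(self, params):
        p = params(a_jr=4.0)
        np.testing.assert_array_less(np.abs(rhs([CR_R, CR_C, 0, 0], p)), 1e-9)

    def test_absent_predator_stays_absent(self, params):
        p = params(a_jr=4.0, beta=1.0)
        d = rhs([1.7, 0.9, 0.0, 0.0], p)
        assert d[2] == 0.0 and d[3] == 0.0

    def test_flux_consistency_juvenile_equation(self, params):
        """With beta=0 and no adults the juvenile ODE is (nu_j - gamma - mu_p)*Pj."""
        p = params(a_jr=4.0, beta=0.0)
        y = [0.8, 0.4, 0.6, 0.0]
        b = rates(y, p)
        d = rhs(y, p)
        assert d[2] == pytest.approx((b.nu_j - b.gamma - p.mu_p) * y[2], rel=1e-12)

    def test_negative_adult_production_is_adult_loss(self, params):
        # no food for adults (diet shift, no consumers): reproduction flux is
        # zero and the starvation loss nu_a < 0 stays in the adult equation
        p = params(a_jr=4.0, a_ar=0.0, beta=0.0)
        y = [2.0, 0.0, 0.5, 0.8]
        b = rates(y, p)
        assert b.nu_a == pytest.approx(-p.T_p)
        d = rhs(y, p)
        assert d[3] == pytest.approx(b.gamma * y[2] - (p.mu_p + p.T_p) * y[3], rel=1e-12)
        assert d[2] == pytest.approx((b.nu_j - b.gamma - b.D_j) * y[2], rel=1e-12)


class TestContainers:
    def test_parameter_invariants(self):
        with pytest.raises(ParameterError):
            ModelParameters(a_jr=7.0, a_ar=0.0, beta=0.0)  # trait beyond a_p
        with pytest.raises(ParameterError):
            ModelParameters(a_jr=1.0, a_ar=0.0, beta=0.0, sigma=1.5)
        with pytest.raises(ParameterError):
            ModelParameters(a_jr=1.0, a_ar=0.0, beta=0.0, z=1.0)

    def test_a_ac_is_derived_not_stored(self):
        p = ModelParameters(a_jr=4.0, a_ar=0.0, beta=0.0)
        assert p.a_ac == 2.0
        assert p.replace(a_jr=5.0).a_ac == 1.0
        assert "a_ac" not in p.to_dict()

    def test_yaml_round_trip_and_unknown_keys(self):
        p = ModelParameters(a_jr=4.0, a_ar=3.0, beta=1.0, R_max=6.0)
        assert ModelParameters.from_yaml(p.to_yaml()) == p
        with pytest.raises(ParameterError, match="unknown"):
            ModelParameters.from_dict({"a_jr": 4.0, "a_ar": 0.0, "beta": 0.0,
                                       "a_ac": 2.0})

    def test_state_rejects_negative(self):
        with pytest.raises(ValueError):
            CommunityState(1.0, -0.1, 0.0, 0.0)
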