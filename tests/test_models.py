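"""Bell-law rates, built-in parameter sets, and the constant-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from catchbond.models import (
    BellTransition,
    BondState,
    TwoStateBondModel,
    bell_rate,
    builtin_model,
    generator_matrix,
    mean_lifetime_constant_force,
    model_from_dict,
    model_to_dict,
    slip_model,
    survival_function_constant_force,
)


class TestBellRate:
    @pytest.mark.parametrize(
        "k0, Fb, F, expected",
        [
            (3.0, 12.0, 0.0, 3.0),                     # zero-force rate
            (3.0, 12.0, 12.0, 3.0 * math.e),           # F = Fb gives k0*e
            (1.3, -6.0, 6.0, 1.3 / math.e),            # negative force scale
        ],
    )
    def test_examples(self, k0, Fb, F, expected):
        assert bell_rate(BellTransition(k0, Fb), F) == pytest.approx(expected)

    def test_rejects_bad_force(self):
        tr = BellTransition(1.0, 10.0)
        with pytest.raises(ValueError):
            bell_rate(tr, -1.0)
        with pytest.raises(ValueError):
            bell_rate(tr, float("nan"))

    def test_overflow_cap_warns(self):
        with pytest.warns(RuntimeWarning):
            bell_rate(BellTransition(1.0, 0.001), 10.0)

    def test_transition_validation(self):
        with pytest.raises(ValueError):
            BellTransition(-1.0, 10.0)
        with pytest.raises(ValueError):
            BellTransition(1.0, 0.0)
        # k0 = 0 marks an absent transition and is legal
        assert bell_rate(BellTransition(0.0, 5.0), 100.0) == 0.0

    @given(
        k0=st.floats(1e-3, 1e2),
        Fb=st.floats(0.5, 20.0),
        F1=st.floats(0.0, 50.0),
        F2=st.floats(0.0, 50.0),
    )
    @settings(max_examples=50, derandomize=True)
    def test_log_linear_in_force(self, k0, Fb, F1, F2):
        """log k(F) is linear in F with slope 1/Fb, to machine precision."""
        tr = BellTransition(k0, Fb)
        lhs = math.log(bell_rate(tr, F2) / bell_rate(tr, F1))
        assert lhs == pytest.approx((F2 - F1) / Fb, abs=1e-9)


class TestBuiltins:
    def test_type1_table(self, type1):
        assert (type1.t10.k0, type1.t10.Fb) == (3.0, 12.0)
        assert (type1.t20.k0, type1.t20.Fb) == (0.01, 12.0)
        assert (type1.t12.k0, type1.t12.Fb) == (0.02, 3.0)
        # back-switch suppressed by force: 1.0 pN scale, negative sign
        assert (type1.t21.k0, abs(type1.t21.Fb)) == (0.001, 1.0)
        assert type1.t21.Fb < 0

    def test_type2_table(self, type2):
        assert (type2.t10.k0, type2.t10.Fb) == (0.012, 14.0)
        assert (type2.t20.k0, type2.t20.Fb) == (1.0, 4.0)
        assert (type2.t12.k0, type2.t12.Fb) == (1.3, -6.0)
        assert (type2.t21.k0, type2.t21.Fb) == (0.001, 1.0)

    def test_both_types_are_catch_bonds(self, type1, type2):
        """Mean lifetime rises then falls with clamped force for both designs."""
        for m in (type1, type2):
            taus = [mean_lifetime_constant_force(m, F) for F in (0, 5, 20, 50)]
            assert taus[0] < taus[1] < taus[2]
            assert taus[3] < taus[2]

    def test_unknown_name(self):
        with pytest.raises(ValueError, match="type1"):
            builtin_model("typeX")

    def test_config_roundtrip(self, type2):
        again = model_from_dict(model_to_dict(type2))
        assert again == type2
        with pytest.raises(ValueError, match="missing"):
            model_from_dict({"k10": 1.0})
        assert model_from_dict({"name": "type1"}).label == "type1"


class TestGeneratorMatrix:
    def test_type1_at_zero_force(self, type1):
        Q = generator_matrix(type1, 0.0)
        np.testing.assert_allclose(
            Q, [[-3.02, 0.02], [0.001, -0.011]], rtol=1e-12)

    @pytest.mark.parametrize("name", ["type1", "type2"])
    @pytest.mark.parametrize("F", [0.0, 7.5, 20.0])
    def test_row_sum_deficit_is_dissociation_rate(self, name, F):
        m = builtin_model(name)
        Q = generator_matrix(m, F)
        k10, k20, _, _ = m.rates(F)
        assert -Q[0].sum() == pytest.approx(k10)
        assert -Q[1].sum() == pytest.approx(k20)

    def test_slip_model_state2_unreachable(self, slip14):
        Q = generator_matrix(slip14, 0.0)
        assert Q[0, 1] == 0.0 and Q[1, 0] == 0.0
        assert Q[0, 0] == pytest.approx(-1.0)


class TestMeanLifetime:
    def test_derived_values_at_zero_force(self, type1, type2):
        assert mean_lifetime_constant_force(type1, 0.0) == pytest.approx(
            0.031 / 0.03320, rel=1e-3)
        assert mean_lifetime_constant_force(type2, 0.0) == pytest.approx(
            2.301 / 1.312012, rel=1e-3)

    def test_single_pathway_reduces_to_exponential(self, slip14):
        assert mean_lifetime_constant_force(slip14, 0.0) == pytest.approx(1.0)
        assert mean_lifetime_constant_force(slip14, 14.0) == pytest.approx(
            1.0 / math.e)

    def test_no_absorption_raises(self):
        m = TwoStateBondModel(
            t10=BellTransition(0.0, 10.0), t20=BellTransition(0.0, 10.0),
            t12=BellTransition(1.0, 10.0), t21=BellTransition(1.0, 10.0))
        with pytest.raises(ValueError, match="absorption"):
            mean_lifetime_constant_force(m, 0.0)

    def test_agrees_with_independent_markov_solver(self, type1, type2):
        """Cross-check against a direct linear solve of the first-passage system."""
        for m in (type1, type2):
            for F in (0.0, 10.0, 30.0):
                a, c, b, d = m.rates(F)
                A = np.array([[a + b, -b], [-d, c + d]])
                tau = np.linalg.solve(A, np.ones(2))
                assert mean_lifetime_constant_force(
                    m, F, BondState.STATE1) == pytest.approx(tau[0], rel=1e-10)
                assert mean_lifetime_constant_force(
                    m, F, BondState.STATE2) == pytest.approx(tau[1], rel=1e-10)


class TestSurvival:
    @pytest.mark.parametrize("name", ["type1", "type2"])
    def test_starts_at_one_and_decreases(self, name):
        m = builtin_model(name)
        t = np.linspace(0.0, 50.0, 400)
        S = survival_function_constant_force(m, 10.0, t=t)
        assert S[0] == pytest.approx(1.0)
        assert np.all(np.diff(S) <= 1e-12)
        assert S[-1] < 0.05

    def test_single_pathway_is_exponential(self, slip14):
        t = np.linspace(0.0, 5.0, 50)
        S = survival_function_constant_force(slip14, 0.0, t=t)
        np.testing.assert_allclose(S, np.exp(-t), rtol=1e-10)

    @pytest.mark.parametrize("name", ["type1", "type2"])
    @pytest.mark.parametrize("F", [0.0, 20.0])
    def test_integral_equals_mean_lifetime(self, name, F):
        m = builtin_model(name)
        tau = mean_lifetime_constant_force(m, F)
        integral, _ = quad(
            lambda x: survival_function_constant_force(m, F, t=x),
            0.0, np.inf, limit=500)
        assert integral == pytest.approx(tau, rel=1e-6)


def test_slip_model_requires_positive_force_scale():
    with pytest.raises(ValueError):
        slip_model(1.0, -14.0)
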