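"""Kinetic Monte Carlo engine: hazard integrals, samplers, reproducibility."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

from catchbond.engine import (
    EngineOptions,
    integrated_bell_hazard_linear,
    rupture_forces,
    sample_single_bond,
    simulate_ensemble,
)
from catchbond.models import (
    BellTransition,
    builtin_model,
    mean_lifetime_constant_force,
    slip_model,
    survival_function_constant_force,
)
from catchbond.protocols import (
    clamp_after_ramp,
    constant_force,
    cyclic_then_clamp,
    oscillating,
    steady_ramp,
)


class TestHazardIntegral:
    def test_constant_rate(self):
        tr = BellTransition(3.0, 12.0)
        assert integrated_bell_hazard_linear(tr, 0.0, 0.0, 1.0) == pytest.approx(3.0)

    def test_linear_ramp_closed_form(self):
        tr = BellTransition(3.0, 12.0)
        got = integrated_bell_hazard_linear(tr, 0.0, 500.0, 0.024)
        assert got == pytest.approx(3 * (12 / 500) * (math.e - 1), rel=1e-12)

    def test_zero_slope_limit_is_continuous(self):
        tr = BellTransition(2.0, 8.0)
        const = integrated_bell_hazard_linear(tr, 5.0, 0.0, 0.3)
        tiny = integrated_bell_hazard_linear(tr, 5.0, 1e-9, 0.3)
        assert tiny == pytest.approx(const, rel=1e-10)

    @pytest.mark.parametrize("Fb,slope", [(12.0, 500.0), (-6.0, 500.0),
                                          (12.0, -100.0), (3.0, 37.0)])
    def test_matches_adaptive_quadrature(self, Fb, slope):
        tr = BellTransition(1.7, Fb)
        F0, dt = 8.0, 0.05
        expected, _ = quad(lambda u: 1.7 * math.exp((F0 + slope * u) / Fb), 0, dt)
        got = integrated_bell_hazard_linear(tr, F0, slope, dt)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_additive_over_subdivision(self):
        tr = BellTransition(0.5, -4.0)
        whole = integrated_bell_hazard_linear(tr, 2.0, 50.0, 0.1)
        first = integrated_bell_hazard_linear(tr, 2.0, 50.0, 0.04)
        second = integrated_bell_hazard_linear(tr, 4.0, 50.0, 0.06)
        assert whole == pytest.approx(first + second, rel=1e-12)

    def test_rejects_negative_duration(self):
        with pytest.raises(ValueError):
            integrated_bell_hazard_linear(BellTransition(1.0, 1.0), 0.0, 0.0, -1.0)


class TestEngineOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            EngineOptions(sampler="magic")
        with pytest.raises(ValueError):
            EngineOptions(step_cap=0.5)


class TestConstantForce:
    def test_unit_exponential_degenerate_model(self):
        m = slip_model(1.0, 14.0)
        s = simulate_ensemble(m, constant_force(0.0), 20_000, seed=4)
        t = np.array([x.t_rupture for x in s])
        assert t.mean() == pytest.approx(1.0, abs=4 * t.std() / math.sqrt(len(t)))
        ks = kstest(t, lambda x: 1.0 - np.exp(-x)).statistic
        assert ks < 0.02

    @pytest.mark.parametrize("name,F", [("type1", 20.0), ("type2", 0.0)])
    def test_gillespie_matches_markov_oracles(self, name, F):
        m = builtin_model(name)
        s = simulate_ensemble(m, constant_force(F), 5000, seed=9)
        t = np.array([x.t_rupture for x in s])
        tau = mean_lifetime_constant_force(m, F)
        se = t.std(ddof=1) / math.sqrt(len(t))
        assert abs(t.mean() - tau) < 3.5 * se
        ks = kstest(t, lambda x: 1 - survival_function_constant_force(
            m, F, t=x)).statistic
        assert ks < 0.025


class TestSampleFields:
    def test_preclamp_flag_consistency(self, type1):
        p = clamp_after_ramp(500.0, 20.0)
        samples = simulate_ensemble(type1, p, 3000, seed=17)
        for s in samples:
            assert s.t_rupture > 0
            assert s.ruptured_before_clamp == (s.t_rupture < p.clamp_start_time)
            assert s.state_at_rupture in (1, 2)
            if s.visited_state2:
                assert s.n_switches >= 1

    def test_ramp_never_flags_preclamp(self, type2):
        samples = simulate_ensemble(type2, steady_ramp(100.0), 500, seed=3)
        assert not any(s.ruptured_before_clamp for s in samples)

    def test_rupture_force_matches_protocol(self, type1):
        p = steady_ramp(100.0)
        samples = simulate_ensemble(type1, p, 500, seed=3)
        for s in samples[:50]:
            assert s.rupture_force == pytest.approx(100.0 * s.t_rupture)


class TestDeterminismAndCensoring:
    def test_same_seed_is_bit_reproducible(self, type1):
        p = clamp_after_ramp(500.0, 20.0)
        a = simulate_ensemble(type1, p, 200, seed=11)
        b = simulate_ensemble(type1, p, 200, seed=11)
        assert a == b

    def test_different_seeds_differ(self, type1):
        p = clamp_after_ramp(500.0, 20.0)
        a = simulate_ensemble(type1, p, 50, seed=11)
        b = simulate_ensemble(type1, p, 50, seed=12)
        assert a != b

    def test_excess_censoring_raises_for_clamp(self):
        slow = slip_model(1e-5, 14.0)
        with pytest.raises(RuntimeError, match="censored"):
            simulate_ensemble(slow, constant_force(0.0), 50, seed=1,
                              options=EngineOptions(max_time=10.0))

    def test_censored_flagged_for_unclamped(self):
        slow = slip_model(1e-5, 14.0)
        s = simulate_ensemble(slow, oscillating(1.0, 0.1, 1.0), 20, seed=1,
                              options=EngineOptions(max_time=5.0))
        assert all(x.censored and x.t_rupture == 5.0 for x in s)


class TestSamplerEquivalence:
    @pytest.mark.parametrize("name,F", [("type1", 20.0), ("type2", 5.0)])
    def test_fixed_step_agrees_with_segment_exact(self, name, F):
        m = builtin_model(name)
        p = clamp_after_ramp(500.0, F)
        a = simulate_ensemble(m, p, 4000, seed=5)
        b = simulate_ensemble(m, p, 4000, seed=6,
                              options=EngineOptions(sampler="fixed_step"))
        ta = np.array([x.t_rupture for x in a])
        tb = np.array([x.t_rupture for x in b])
        se = math.hypot(ta.std(ddof=1) / math.sqrt(len(ta)),
                        tb.std(ddof=1) / math.sqrt(len(tb)))
        assert abs(ta.mean() - tb.mean()) < 3.5 * se


class TestTimeVaryingHazards:
    def test_slip_ramp_matches_closed_form_rupture_distribution(self, slip14):
        """p(f) = (k(f)/r) exp(-(1/r) int_0^f k) for a slip bond under a ramp."""
        r = 1000.0
        s = simulate_ensemble(slip14, steady_ramp(r), 10_000, seed=8)
        f = rupture_forces(s)
        cdf = lambda x: 1.0 - np.exp(-(14.0 / r) * (np.exp(x / 14.0) - 1.0))
        assert kstest(f, cdf).statistic < 0.02

    def test_thinning_matches_integrated_hazard(self, slip14):
        """Sinusoidal-load sampling agrees with the analytic survival."""
        p = oscillating(20.0, 0.5, 2.0, 10.0)
        s = simulate_ensemble(slip14, p, 4000, seed=8)
        t = np.array([x.t_rupture for x in s])
        grid = np.linspace(0.0, max(t.max(), 1.0), 4000)
        rate = np.exp(np.array([p.force(x) for x in grid]) / 14.0)
        Lam = np.concatenate([[0.0], np.cumsum(
            0.5 * (rate[1:] + rate[:-1]) * np.diff(grid))])
        cdf = lambda x: 1.0 - np.exp(-np.interp(x, grid, Lam))
        assert kstest(t, cdf).statistic < 0.025

    def test_instant_clamp_limit(self):
        """At very fast ramps the pre-clamp rupture fraction vanishes."""
        for name in ("type1", "type2"):
            m = builtin_model(name)
            s = simulate_ensemble(m, clamp_after_ramp(1e6, 20.0), 2000, seed=2)
            frac = np.mean([x.ruptured_before_clamp for x in s])
            assert frac < 0.002

    def test_zero_cycles_identical_to_simple_clamp(self, type1):
        """Same segment structure implies the same RNG draws and samples."""
        a = simulate_ensemble(type1, cyclic_then_clamp(0, 10.0, 100.0, -100.0),
                              300, seed=77)
        b = simulate_ensemble(type1, clamp_after_ramp(100.0, 10.0), 300, seed=77)
        assert [s.t_rupture for s in a] == [s.t_rupture for s in b]
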