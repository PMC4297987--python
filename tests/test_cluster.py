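"""Cluster mechanics, rebinding kinetics, and the coupled FE/MC dynamics."""

import math

import numpy as np
import pytest

from catchbond.cluster import (
    ClusterConfig,
    ClusterDead,
    ClusterState,
    assemble_and_solve_equilibrium,
    bond_tensions,
    cluster_ensemble,
    rebinding_rate,
    simulate_cluster_lifetime,
    step,
)
from catchbond.models import builtin_model
from catchbond.protocols import constant_force, cyclic_then_clamp, oscillating


def _config(**kw):
    defaults = dict(model=builtin_model("type2"),
                    protocol=constant_force(100.0))
    defaults.update(kw)
    return ClusterConfig(**defaults)


class TestConfig:
    def test_defaults_are_consistent(self):
        cfg = _config()
        assert cfg.v0 == pytest.approx(cfg.a / cfg.tau0)
        assert cfg.n <= cfg.N

    def test_validation(self):
        with pytest.raises(ValueError):
            _config(n=50, N=40)
        with pytest.raises(ValueError):
            _config(tau0=5.0)
        with pytest.raises(ValueError):
            _config(k_LR=-1.0)


class TestEquilibrium:
    def test_single_bond_series_springs(self):
        cfg = _config(n=4, N=8, protocol=constant_force(10.0))
        st = ClusterState.initial(cfg)
        st.bound[:] = False
        st.bound[1] = True
        u = assemble_and_solve_equilibrium(cfg, st, 10.0)
        # the bond spring stretches by F/k_LR ...
        assert u[1] == pytest.approx(10.0 / cfg.k_LR)
        # ... and the rod stretches by F*l0/EA per element beyond the bond
        assert u[3] - u[1] == pytest.approx(10.0 * 2 * cfg.l0 / cfg.EA)

    def test_rigid_fiber_equal_load_sharing(self):
        cfg = _config(n=5, N=10, EA=1e12, protocol=constant_force(50.0))
        st = ClusterState.initial(cfg)
        u = assemble_and_solve_equilibrium(cfg, st, 50.0)
        np.testing.assert_allclose(u, 50.0 / (5 * cfg.k_LR), rtol=1e-6)

    def test_global_force_balance_full_cluster(self):
        cfg = ClusterConfig(model=builtin_model("type1"),
                            protocol=constant_force(400.0))
        st = ClusterState.initial(cfg)
        assert bond_tensions(cfg, st).sum() == pytest.approx(400.0, rel=1e-9)

    def test_detached_fiber_raises(self):
        cfg = _config(n=4, N=8)
        st = ClusterState.initial(cfg)
        st.bound[:] = False
        with pytest.raises(ClusterDead):
            assemble_and_solve_equilibrium(cfg, st, 10.0)


class TestRebindingRate:
    def test_velocity_suppression_monotone(self):
        cfg = _config()
        rates = [rebinding_rate(0.0, v, cfg) for v in (0.0, 100.0, 1000.0)]
        assert rates[0] > rates[1] > rates[2]
        assert rates[0] == pytest.approx(cfg.k0_rebind)

    def test_distance_decay(self):
        cfg = _config()
        assert rebinding_rate(1e4, 0.0, cfg) < 1e-12
        r_near = rebinding_rate(cfg.l_bind / 2, 0.0, cfg)
        assert r_near == pytest.approx(cfg.k0_rebind)  # inside binding range
        assert rebinding_rate(cfg.l_bind + 20.0, 0.0, cfg) < r_near

    def test_maximal_at_contact_and_rest(self):
        cfg = _config()
        peak = rebinding_rate(0.0, 0.0, cfg)
        for u, v in [(5.0, 0.0), (0.0, 50.0), (30.0, 500.0)]:
            assert rebinding_rate(u, v, cfg) <= peak

    def test_invalid_inputs(self):
        cfg = _config()
        with pytest.raises(ValueError):
            rebinding_rate(-1.0, 0.0, cfg)
        with pytest.raises(ValueError):
            rebinding_rate(0.0, float("inf"), cfg)


class TestStep:
    def test_ligand_exclusivity_preserved(self):
        cfg = _config(n=6, N=12, protocol=constant_force(60.0), dt=0.01)
        st = ClusterState.initial(cfg)
        rng = np.random.default_rng(0)
        for _ in range(300):
            if not st.bound.any():
                break
            st = step(cfg, st, rng)
            used = st.lig_of[st.bound]
            assert len(used) == len(set(used.tolist()))

    def test_receptor_state_memory_across_rebinding(self):
        cfg = _config(n=2, N=4, protocol=constant_force(0.001),
                      k0_rebind=50.0, dt=0.01)
        st = ClusterState.initial(cfg)
        st.state[0] = 2
        st.bound[0] = False
        rng = np.random.default_rng(1)
        for _ in range(2000):
            st = step(cfg, st, rng)
            if st.bound[0]:
                break
        assert st.bound[0], "receptor failed to rebind at high k0"
        assert st.state[0] == 2  # re-formed bond keeps the receptor's state

    def test_dead_cluster_raises(self):
        cfg = _config(n=2, N=4)
        st = ClusterState.initial(cfg)
        st.bound[:] = False
        with pytest.raises(ClusterDead):
            step(cfg, st, np.random.default_rng(0))


class TestLifetime:
    def test_fast_path_deterministic(self):
        cfg = ClusterConfig(model=builtin_model("type1"),
                            protocol=oscillating(400.0, 0.6, 2.0, 10.0),
                            max_time=500.0)
        a = simulate_cluster_lifetime(cfg, seed=5)
        b = simulate_cluster_lifetime(cfg, seed=5)
        assert a == b
        assert a.lifetime > 0 and not a.censored

    def test_censoring_flag(self):
        cfg = _config(protocol=constant_force(1.0), max_time=0.5)
        run = simulate_cluster_lifetime(cfg, seed=1)
        assert run.censored and run.lifetime == 0.5

    def test_unsupported_protocol_raises(self):
        cfg = _config(protocol=cyclic_then_clamp(1, 10.0, 100.0, -100.0))
        with pytest.raises(NotImplementedError):
            simulate_cluster_lifetime(cfg, seed=0)

    def test_no_rebinding_reduces_to_max_of_independent_bonds(self):
        """With rebinding off and zero force, the cluster dies when the last
        of n independent two-state bonds does; cross-check against a direct
        Monte Carlo of that reduced model built from the single-bond engine."""
        from catchbond.engine import simulate_ensemble

        n = 8
        cfg = _config(n=n, N=n, protocol=constant_force(0.0),
                      k0_rebind=1e-12, dt=0.01, max_time=500.0)
        ens = cluster_ensemble(cfg, n_runs=80, seed=21)
        singles = simulate_ensemble(builtin_model("type2"), constant_force(0.0),
                                    80 * n, seed=22)
        t = np.array([s.t_rupture for s in singles]).reshape(80, n)
        oracle = t.max(axis=1)
        se = math.hypot(ens.se, oracle.std(ddof=1) / math.sqrt(len(oracle)))
        assert abs(ens.mean - oracle.mean()) < 3.5 * se

    def test_fast_and_reference_steppers_agree(self):
        cfg = ClusterConfig(model=builtin_model("type1"),
                            protocol=oscillating(120.0, 0.5, 1.0, 10.0),
                            n=6, N=12, max_time=100.0)
        fast = cluster_ensemble(cfg, n_runs=24, seed=3, stepper="fast")
        ref = cluster_ensemble(cfg, n_runs=24, seed=3, stepper="reference")
        se = math.hypot(fast.se, ref.se)
        assert abs(fast.mean - ref.mean) < 3.5 * se

    def test_ensemble_shape_and_se(self):
        cfg = ClusterConfig(model=builtin_model("type2"),
                            protocol=oscillating(400.0, 0.8, 2.0, 10.0),
                            max_time=500.0)
        ens = cluster_ensemble(cfg, n_runs=10, seed=4)
        assert len(ens.lifetimes) == 10
        assert ens.se > 0
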