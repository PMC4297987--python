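"""Adhesion cluster: an elastic fiber bonded to a rigid substrate.

Geometry (all 1-D, axial): ``n`` receptors sit at positions ``i * l0`` along
an elastic fiber of tensional modulus ``EA``; ``N >= n`` ligand sites sit at
``j * l0`` on a rigid substrate, left-aligned with the receptors so that
``N - n`` free sites extend beyond the loaded end.  Each closed bond is a
spring of stiffness ``k_LR`` anchoring its fiber node to its ligand site.
The external force acts on the rightmost fiber node.

Dynamics advance in small steps ``dt``:

1. the fiber is equilibrated quasi-statically (2-node rod elements of
   stiffness ``EA/l0`` plus grounding bond springs; the solve is tridiagonal
   and, for a fixed bond topology, affine in the applied force, so repeated
   solves cost O(n));
2. every closed bond Bernoulli-samples rupture or state switch from its
   current tension via the same Bell-law two-state kinetics as a single
   bond;
3. every open receptor Bernoulli-samples rebinding to a free ligand with a
   rate that decays with the receptor--ligand gap and with their relative
   sliding velocity (see :func:`rebinding_rate`).

A receptor keeps its conformational state across unbind/rebind cycles: the
state lives in the receptor, and a re-formed bond starts in the state the
receptor had when it last broke.  The cluster is dead when every receptor is
simultaneously open; that first time is the cluster lifetime.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Optional

import numpy as np
from scipy.linalg import solve_banded

from .models import EXP_CAP, TwoStateBondModel, builtin_model
from .protocols import ForceProtocol, Segment, oscillating

__all__ = [
    "ClusterConfig",
    "ClusterState",
    "ClusterRun",
    "ClusterEnsemble",
    "assemble_and_solve_equilibrium",
    "rebinding_rate",
    "step",
    "simulate_cluster_lifetime",
    "cluster_ensemble",
]


@dataclass(frozen=True)
class ClusterConfig:
    """Geometry, mechanics, kinetics and numerics of the bond cluster.

    Defaults are the reference focal-adhesion-scale parameter set: 40
    receptors and 160 ligand sites spaced 32 nm apart, a fiber of tensional
    modulus 46 nN, 0.25 pN/nm bond springs, rebinding rate constant 0.1/s,
    intrinsic velocity v0 = a / tau0 = 400 nm/s, and an oscillating load of
    homeostatic value F0 = 400 pN.
    """

    model: TwoStateBondModel = field(default_factory=lambda: builtin_model("type1"))
    protocol: ForceProtocol = field(
        default_factory=lambda: oscillating(400.0, 0.5, 1.0, 10.0)
    )
    n: int = 40                 # receptors
    N: int = 160                # ligand sites
    l0: float = 32.0            # spacing, nm
    EA: float = 46.0e3          # fiber tensional modulus, pN
    k_LR: float = 0.25          # bond spring constant, pN/nm
    k0_rebind: float = 0.1      # rebinding rate constant, 1/s
    a: float = 10.0             # encounter length, nm
    tau0: float = 0.025         # intrinsic association time, s (v0 = a/tau0)
    l_bind: float = 10.0        # binding distance, nm (default: encounter length a)
    kBT: float = 4.14           # thermal energy, pN nm (T ~ 300 K)
    gamma: float = 10.0         # stress-fiber regulation rate, 1/s
    dt: float = 0.005           # base mechanics/kinetics step, s
    dt_floor: float = 1.0e-7    # smallest adaptive step, s
    event_cap: float = 0.05     # target max rate*dt per entity
    max_time: float = 1.0e4     # censoring horizon, s
    n_runs: int = 100           # default ensemble size
    rebind_window: int = 4      # ligand candidates within +- window sites

    def __post_init__(self) -> None:
        if not (1 <= self.n <= self.N):
            raise ValueError("need 1 <= n <= N")
        for name in ("l0", "EA", "k_LR", "k0_rebind", "a", "tau0", "l_bind",
                     "kBT", "gamma", "dt", "dt_floor", "event_cap", "max_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.01 <= self.tau0 <= 1.0:
            raise ValueError("tau0 must lie in [0.01, 1] s")

    @property
    def v0(self) -> float:
        """Intrinsic velocity a / tau0, nm/s."""
        return self.a / self.tau0

    @property
    def receptor_positions(self) -> np.ndarray:
        """Undeformed receptor node positions, nm."""
        return np.arange(self.n) * self.l0

    @property
    def ligand_positions(self) -> np.ndarray:
        return np.arange(self.N) * self.l0


@dataclass
class ClusterState:
    """Evolving bound/open state, receptor state memory, and fiber kinematics."""

    bound: np.ndarray            # bool[n]
    lig_of: np.ndarray           # int[n], ligand index or -1
    state: np.ndarray            # int8[n], 1 or 2 (memory persists when open)
    u: np.ndarray                # float[n], nodal displacement, nm
    u_prev: np.ndarray
    time: float = 0.0
    dt_prev: float = math.nan    # step used to reach `u` from `u_prev`

    @classmethod
    def initial(cls, config: ClusterConfig) -> "ClusterState":
        """All receptors bound to their aligned ligands, all in State 1."""
        n = config.n
        st = cls(
            bound=np.ones(n, dtype=bool),
            lig_of=np.arange(n, dtype=np.int64),
            state=np.ones(n, dtype=np.int8),
            u=np.zeros(n), u_prev=np.zeros(n),
        )
        F0 = config.protocol.force(0.0)
        st.u = assemble_and_solve_equilibrium(config, st, F0)
        st.u_prev = st.u.copy()
        return st

    def copy(self) -> "ClusterState":
        return ClusterState(
            bound=self.bound.copy(), lig_of=self.lig_of.copy(),
            state=self.state.copy(), u=self.u.copy(),
            u_prev=self.u_prev.copy(), time=self.time, dt_prev=self.dt_prev,
        )


class ClusterDead(RuntimeError):
    """Raised when mechanics is requested with every bond open."""


def _stiffness_banded(config: ClusterConfig, bound: np.ndarray) -> np.ndarray:
    """Tridiagonal stiffness in solve_banded (1,1) layout."""
    n = config.n
    ke = config.EA / config.l0
    diag = np.zeros(n)
    diag[:-1] += ke
    diag[1:] += ke
    diag[bound] += config.k_LR
    ab = np.zeros((3, n))
    ab[0, 1:] = -ke
    ab[1] = diag
    ab[2, :-1] = -ke
    return ab


def _anchor_rhs(config: ClusterConfig, state: ClusterState) -> np.ndarray:
    """Bond-spring anchor contribution k_LR * (X_lig - x_rec) per node."""
    rhs = np.zeros(config.n)
    idx = np.nonzero(state.bound)[0]
    offs = (state.lig_of[idx] - idx) * config.l0
    rhs[idx] = config.k_LR * offs
    return rhs


def assemble_and_solve_equilibrium(
    config: ClusterConfig, state: ClusterState, F_now: float
) -> np.ndarray:
    """Quasi-static nodal displacements (nm) under external force ``F_now``.

    Rod elements of stiffness EA/l0 couple adjacent receptor nodes; each
    closed bond grounds its node through a k_LR spring anchored at its ligand
    site; ``F_now`` pulls the rightmost node.  Raises :class:`ClusterDead`
    when no bond is closed (singular system: the fiber is detached).
    """
    if not state.bound.any():
        raise ClusterDead("all bonds open; fiber detached")
    ab = _stiffness_banded(config, state.bound)
    rhs = _anchor_rhs(config, state)
    rhs[-1] += F_now
    u = solve_banded((1, 1), ab, rhs)
    # residual check: K u - rhs must balance to solver precision
    ke = config.EA / config.l0
    Ku = ab[1] * u
    Ku[:-1] += -ke * u[1:]
    Ku[1:] += -ke * u[:-1]
    resid = np.max(np.abs(Ku - rhs))
    if resid > 1e-8 * max(abs(F_now), 1.0):
        raise RuntimeError(f"equilibrium residual {resid:.3g} too large")
    return u


def bond_tensions(config: ClusterConfig, state: ClusterState) -> np.ndarray:
    """Tension magnitude k_LR * |stretch| of every closed bond (pN); 0 if open."""
    tau = np.zeros(config.n)
    idx = np.nonzero(state.bound)[0]
    offs = (state.lig_of[idx] - idx) * config.l0
    tau[idx] = config.k_LR * np.abs(state.u[idx] - offs)
    return tau


def rebinding_rate(u: float, v: float, config: ClusterConfig) -> float:
    """Rate (1/s) at which an open receptor rebinds a ligand.

    ``k = k0 * v0/(v0 + |v|) * exp(-k_LR * max(u - l_bind, 0)^2 / (2 kBT))``
    where ``u`` is the receptor--ligand gap (nm) and ``v`` their relative
    velocity (nm/s).  Within the binding distance ``l_bind`` the pair reacts
    at the rate constant ``k0``; beyond it the Boltzmann factor charges the
    elastic cost of stretching the newly formed bond spring across the
    remaining slack.  The velocity factor compares the encounter duration
    ~a/|v| with the intrinsic association time tau0 = a/v0 -- faster sliding
    means shorter encounters and a lower rebinding probability.
    """
    if u < 0:
        raise ValueError("separation u must be >= 0")
    if not math.isfinite(v):
        raise ValueError("velocity must be finite")
    slack = max(u - config.l_bind, 0.0)
    x = config.k_LR * slack * slack / (2.0 * config.kBT)
    return (config.k0_rebind * config.v0 / (config.v0 + abs(v))
            * math.exp(-min(x, EXP_CAP)))


def _bound_rates(config: ClusterConfig, state_arr: np.ndarray,
                 tensions: np.ndarray, idx: np.ndarray):
    """(rupture, switch) Bell rates of the closed bonds at their tensions."""
    m = config.model
    s = state_arr[idx]
    F = tensions[idx]
    k0_rup = np.where(s == 1, m.t10.k0, m.t20.k0)
    Fb_rup = np.where(s == 1, m.t10.Fb, m.t20.Fb)
    k0_sw = np.where(s == 1, m.t12.k0, m.t21.k0)
    Fb_sw = np.where(s == 1, m.t12.Fb, m.t21.Fb)
    rup = k0_rup * np.exp(np.minimum(F / Fb_rup, EXP_CAP))
    sw = k0_sw * np.exp(np.minimum(F / Fb_sw, EXP_CAP))
    sw[k0_sw == 0.0] = 0.0
    return rup, sw


def _rebind_candidates(config: ClusterConfig, state: ClusterState, i: int,
                       lig_free: np.ndarray, v_i: float):
    """Free-ligand candidates near receptor ``i`` and their rebinding rates.

    The receptor--ligand gap entering :func:`rebinding_rate` is measured on
    the reference lattice (|i - j| * l0): a receptor reacts with the sites
    its anchoring segment sweeps over, and the coarse-grained elastic
    displacement of the k_LR springs is not a physical molecular separation.
    In practice the exponential decay restricts rebinding to the receptor's
    own site.
    """
    W = config.rebind_window
    js, rates = [], []
    for j in range(max(0, i - W), min(config.N, i + W + 1)):
        if lig_free[j]:
            r = rebinding_rate(abs(i - j) * config.l0, v_i, config)
            if r > 1e-12:
                js.append(j)
                rates.append(r)
    return np.array(js, dtype=np.int64), np.array(rates)


def _free_ligands(config: ClusterConfig, state: ClusterState) -> np.ndarray:
    free = np.ones(config.N, dtype=bool)
    free[state.lig_of[state.bound]] = False
    return free


def step(config: ClusterConfig, state: ClusterState,
         rng: np.random.Generator) -> ClusterState:
    """Advance the cluster by one adaptive step; returns the new state.

    Raises :class:`ClusterDead` if the step begins with every bond open.
    The step size shrinks from ``config.dt`` so that no entity's event
    probability exceeds ``config.event_cap`` (never below ``dt_floor``; an
    entity whose rate outruns even the floor step fires with probability
    ~1, which only happens in the final rupture cascade).
    """
    new = state.copy()
    _advance(config, new, rng)
    return new


def _dt_base(config: ClusterConfig) -> float:
    dt = config.dt
    for seg in config.protocol.segments:
        if seg.kind == "sinusoidal":
            dt = min(dt, 2.0 * math.pi / seg.omega / 50.0)
    return dt


def _advance(config: ClusterConfig, st: ClusterState,
             rng: np.random.Generator, mech_cache: Optional[dict] = None) -> None:
    """In-place single step shared by :func:`step` and the ensemble loop."""
    if not st.bound.any():
        raise ClusterDead("all bonds open; fiber detached")
    F_now = config.protocol.force(st.time)

    # mechanics: u = F * w + c for the current topology
    if mech_cache is not None and mech_cache.get("key") == st.bound.tobytes() + st.lig_of.tobytes():
        w, c = mech_cache["w"], mech_cache["c"]
    else:
        ab = _stiffness_banded(config, st.bound)
        e_last = np.zeros(config.n)
        e_last[-1] = 1.0
        w = solve_banded((1, 1), ab, e_last)
        c = solve_banded((1, 1), ab, _anchor_rhs(config, st))
        if mech_cache is not None:
            mech_cache.update(key=st.bound.tobytes() + st.lig_of.tobytes(),
                              w=w, c=c)
    u = F_now * w + c
    if math.isnan(st.dt_prev):
        v = np.zeros(config.n)
    else:
        v = (u - st.u_prev) / st.dt_prev
    st.u = u

    bnd = np.nonzero(st.bound)[0]
    opn = np.nonzero(~st.bound)[0]
    tensions = np.zeros(config.n)
    offs = (st.lig_of[bnd] - bnd) * config.l0
    tensions[bnd] = config.k_LR * np.abs(u[bnd] - offs)
    rup, sw = _bound_rates(config, st.state, tensions, bnd)
    total_bnd = rup + sw

    lig_free = _free_ligands(config, st)
    rebinds = []
    max_rate = float(total_bnd.max()) if len(bnd) else 0.0
    for i in opn:
        js, rates = _rebind_candidates(config, st, int(i), lig_free, float(v[i]))
        if len(js):
            rebinds.append((int(i), js, rates, float(rates.sum())))
            max_rate = max(max_rate, rebinds[-1][3])

    dt = _dt_base(config)
    if max_rate > 0.0:
        dt = min(dt, config.event_cap / max_rate)
    dt = max(dt, config.dt_floor)

    # closed-bond events: competing rupture/switch per bond
    if len(bnd):
        p_any = -np.expm1(-total_bnd * dt)
        fire = rng.random(len(bnd)) < p_any
        which_rup = rng.random(len(bnd)) * total_bnd < rup
        for k in np.nonzero(fire)[0]:
            i = bnd[k]
            if which_rup[k]:
                st.bound[i] = False   # state memory kept in st.state[i]
            else:
                st.state[i] = 3 - st.state[i]

    # rebinding, random receptor order, ligand exclusivity enforced
    if rebinds:
        for idx in rng.permutation(len(rebinds)):
            i, js, rates, total = rebinds[idx]
            if rng.random() >= -math.expm1(-total * dt):
                continue
            avail = lig_free[js]
            if not avail.any():
                continue
            r_av = np.where(avail, rates, 0.0)
            j = int(js[_weighted_choice(rng, r_av)])
            st.bound[i] = True
            st.lig_of[i] = j
            lig_free[j] = False

    st.time += dt
    st.u_prev = u
    st.dt_prev = dt


def _weighted_choice(rng: np.random.Generator, weights: np.ndarray) -> int:
    tot = weights.sum()
    x = rng.random() * tot
    acc = 0.0
    for k, wk in enumerate(weights):
        acc += wk
        if x <= acc:
            return k
    return len(weights) - 1


class ClusterRun(NamedTuple):
    lifetime: float
    censored: bool
    n_steps: int


def _protocol_params(protocol: ForceProtocol) -> tuple[float, float, float, float]:
    """(Fmean, amp, omega, phase) of a constant or single-sinusoid protocol."""
    segs = protocol.segments
    if len(segs) == 1 and segs[0].kind == "constant":
        return segs[0].F_start, 0.0, 0.0, 0.0
    if len(segs) == 1 and segs[0].kind == "sinusoidal":
        s = segs[0]
        return s.F0, s.amp, s.omega, s.phase
    raise NotImplementedError(
        "cluster simulation supports constant and oscillating loads only"
    )


def simulate_cluster_lifetime(config: ClusterConfig, seed: int,
                              stepper: str = "fast") -> ClusterRun:
    """One cluster trajectory: time until all receptors are open.

    Bit-reproducible for a fixed (config, seed, stepper).  Runs exceeding
    ``config.max_time`` are reported censored.  ``stepper="fast"`` uses the
    compiled loop; ``stepper="reference"`` the plain Python one (identical
    dynamics, independent code path, different random stream).
    """
    if stepper == "fast":
        from ._fastcluster import run_cluster

        Fmean, amp, omega, phase = _protocol_params(config.protocol)
        m = config.model
        lifetime, censored, n_steps = run_cluster(
            config.n, config.N, config.l0, config.EA, config.k_LR,
            config.k0_rebind, config.v0, config.l_bind, config.kBT,
            config.rebind_window,
            m.t10.k0, m.t10.Fb, m.t20.k0, m.t20.Fb,
            m.t12.k0, m.t12.Fb, m.t21.k0, m.t21.Fb,
            Fmean, amp, omega, phase,
            _dt_base(config), config.dt_floor, config.event_cap,
            config.max_time, seed % (2**31),
        )
        return ClusterRun(float(lifetime), bool(censored), int(n_steps))
    if stepper != "reference":
        raise ValueError(f"unknown stepper {stepper!r}")
    rng = np.random.default_rng(seed)
    st = ClusterState.initial(config)
    cache: dict = {}
    n_steps = 0
    while st.time < config.max_time:
        if not st.bound.any():
            return ClusterRun(st.time, False, n_steps)
        _advance(config, st, rng, mech_cache=cache)
        n_steps += 1
    return ClusterRun(config.max_time, True, n_steps)


class ClusterEnsemble(NamedTuple):
    mean: float
    se: float
    lifetimes: np.ndarray
    n_censored: int


def cluster_ensemble(config: ClusterConfig, n_runs: Optional[int] = None,
                     seed: int = 0, stepper: str = "fast") -> ClusterEnsemble:
    """Mean cluster lifetime +- SE over independent runs.

    Per-run seeds are spawned from ``SeedSequence(seed)``.  Censored runs
    enter the mean at the horizon value (a lower bound); their count is
    reported so callers can judge the bias.
    """
    n_runs = config.n_runs if n_runs is None else n_runs
    children = np.random.SeedSequence(seed).spawn(n_runs)
    lifetimes = np.empty(n_runs)
    n_cens = 0
    for k, ch in enumerate(children):
        run = simulate_cluster_lifetime(
            config, seed=int(ch.generate_state(1)[0]) % (2**31), stepper=stepper
        )
        lifetimes[k] = run.lifetime
        n_cens += run.censored
    mean = float(np.mean(lifetimes))
    se = float(np.std(lifetimes, ddof=1) / math.sqrt(n_runs)) if n_runs > 1 else math.nan
    return ClusterEnsemble(mean=mean, se=se, lifetimes=lifetimes,
                           n_censored=n_cens)
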