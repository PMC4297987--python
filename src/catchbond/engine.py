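"""Kinetic Monte Carlo sampling of single-bond trajectories.

A trajectory starts in State 1 when the force protocol begins and evolves by
competing risks among the outgoing Bell-law transitions of the current state,
with hazards k(F(t)), until absorption into the dissociated state.

Two samplers are provided:

``segment_exact`` (default)
    Per protocol segment, the next-event time is drawn by inverting the total
    integrated hazard against a unit-exponential variate.  On constant and
    linear segments the per-transition integrals are closed-form; inversion
    is analytic when a single transition is active and by bracketed
    root-finding otherwise.  On sinusoidal segments the event time is drawn
    by thinning against a constant dominating rate (the total rate at the
    extremal force of the oscillation, which bounds every Bell rate whatever
    the sign of its force scale).  Because the exponential clock is
    memoryless, redrawing the variate at segment boundaries and after state
    switches is exact.  At constant force the scheme reduces to the Gillespie
    algorithm.

``fixed_step``
    An independent cross-check: time advances in steps chosen so that
    (total rate) * dt <= step_cap, with at most one event per step occurring
    with probability 1 - exp(-integrated hazard over the step).  It carries
    an O(dt) discretisation bias and is retained only to corroborate the
    exact sampler.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .models import EXP_CAP, BellTransition, BondState, TwoStateBondModel
from .protocols import ForceProtocol, Segment

__all__ = [
    "EngineOptions",
    "LifetimeSample",
    "integrated_bell_hazard_linear",
    "sample_single_bond",
    "simulate_ensemble",
    "rupture_forces",
]


@dataclass(frozen=True)
class EngineOptions:
    """Sampler selection and numerical controls."""

    sampler: str = "segment_exact"
    step_cap: float = 0.005          # max total-rate * dt per fixed step
    root_tolerance: float = 1e-10    # relative tolerance of hazard inversion
    max_time: float = 1.0e4          # censoring horizon, s

    def __post_init__(self) -> None:
        if self.sampler not in ("segment_exact", "fixed_step"):
            raise ValueError(f"unknown sampler {self.sampler!r}")
        if not 0.0 < self.step_cap <= 0.1:
            raise ValueError("step_cap must lie in (0, 0.1]")
        if self.max_time <= 0:
            raise ValueError("max_time must be > 0")


@dataclass(frozen=True)
class LifetimeSample:
    """Outcome of one single-bond trajectory."""

    t_rupture: float                 # absolute time from force onset, s
    state_at_rupture: int            # 1 or 2
    ruptured_before_clamp: bool
    visited_state2: bool
    n_switches: int
    rupture_force: float             # F(t_rupture), pN
    replicate: int = 0
    censored: bool = False


def _exp_clamped(x: float) -> float:
    return math.exp(x if x <= EXP_CAP else EXP_CAP)


def integrated_bell_hazard_linear(
    tr: BellTransition, F_start: float, slope: float, dt: float
) -> float:
    """Integrated hazard of one Bell transition along a linear force segment.

    Returns ``int_0^dt k0 exp((F_start + slope u)/Fb) du``, i.e.

        k0 * (Fb/slope) * exp(F_start/Fb) * (exp(slope*dt/Fb) - 1)   slope != 0
        k0 * exp(F_start/Fb) * dt                                    slope == 0

    Always >= 0 and additive over subdivisions of the segment.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if tr.k0 == 0.0 or dt == 0.0:
        return 0.0
    x0 = F_start / tr.Fb
    if slope == 0.0:
        return tr.k0 * _exp_clamped(x0) * dt
    y = slope * dt / tr.Fb
    # k0*(Fb/slope)*e^{x0}*expm1(y); expm1 keeps accuracy in the slope->0 limit
    if x0 > EXP_CAP or x0 + y > EXP_CAP:
        # evaluate at the cap; only reachable with non-physical parameters
        return tr.k0 * abs(tr.Fb / slope) * abs(
            _exp_clamped(x0 + y) - _exp_clamped(x0)
        )
    return tr.k0 * (tr.Fb / slope) * math.exp(x0) * math.expm1(y)


def _segment_hazard(trs, seg: Segment, t0: float, dt: float) -> float:
    """Total integrated hazard of active transitions over [t0, t0+dt) in seg."""
    if seg.kind == "sinusoidal":
        raise ValueError("closed-form hazard undefined on sinusoidal segments")
    F0 = seg.force(t0)
    slope = seg.slope if seg.kind == "linear" else 0.0
    return sum(integrated_bell_hazard_linear(tr, F0, slope, dt) for tr in trs)


def _invert_hazard(trs, seg: Segment, t0: float, dt_max: float, target: float,
                   rtol: float) -> Optional[float]:
    """Solve Lambda(dt) = target on [0, dt_max]; None if Lambda(dt_max) < target."""
    total_end = _segment_hazard(trs, seg, t0, dt_max)
    if total_end < target:
        return None
    active = [tr for tr in trs if tr.k0 > 0.0]
    F0 = seg.force(t0)
    slope = seg.slope if seg.kind == "linear" else 0.0
    if len(active) == 1 and slope != 0.0:
        tr = active[0]
        # analytic inversion of k0*(Fb/slope)*e^{F0/Fb}*(e^{slope dt/Fb}-1) = target
        arg = target * slope / (tr.k0 * tr.Fb * math.exp(F0 / tr.Fb))
        return (tr.Fb / slope) * math.log1p(arg)
    if slope == 0.0:
        rate = sum(tr.k0 * _exp_clamped(F0 / tr.Fb) for tr in active)
        return target / rate
    f = lambda dt: _segment_hazard(trs, seg, t0, dt) - target
    return brentq(f, 0.0, dt_max, xtol=1e-15, rtol=max(rtol, 4e-16))


def _rates_at(trs, F: float) -> list[float]:
    return [tr.k0 * _exp_clamped(F / tr.Fb) if tr.k0 > 0 else 0.0 for tr in trs]


def _pick(rng, rates) -> int:
    total = sum(rates)
    u = rng.random() * total
    acc = 0.0
    for i, r in enumerate(rates):
        acc += r
        if u <= acc:
            return i
    return len(rates) - 1


def _force_range_on(seg: Segment, t0: float, t1: float) -> tuple[float, float]:
    """(min, max) of the sinusoidal force over [t0, t1]."""
    f0, f1 = seg.force(t0), seg.force(t1)
    lo, hi = min(f0, f1), max(f0, f1)
    # interior extrema where cos(omega t + phase) = 0
    k0 = math.ceil((seg.omega * t0 + seg.phase - math.pi / 2) / math.pi)
    k1 = math.floor((seg.omega * t1 + seg.phase - math.pi / 2) / math.pi)
    for k in range(k0, min(k1, k0 + 2) + 1):
        t_ext = (math.pi / 2 + k * math.pi - seg.phase) / seg.omega
        if t0 <= t_ext <= t1:
            f = seg.force(t_ext)
            lo, hi = min(lo, f), max(hi, f)
    return max(lo, 0.0), hi


def _thinning_bound(trs, seg: Segment, t0: float, t1: float) -> float:
    """Upper bound on the total rate over [t0, t1] of a sinusoidal segment.

    Bell rates are monotone in F, so each transition is bounded by its rate
    at whichever force extreme its force scale favours.  Bounds are taken
    over short sub-intervals of the period (not the whole cycle): with pN-
    scale force scales the rates span many orders of magnitude over one
    cycle and a whole-cycle bound would make thinning astronomically
    inefficient.
    """
    lo, hi = _force_range_on(seg, t0, t1)
    bound = 0.0
    for tr in trs:
        if tr.k0 > 0.0:
            bound += tr.k0 * _exp_clamped((hi if tr.Fb > 0 else lo) / tr.Fb)
    return bound


def sample_single_bond(
    model: TwoStateBondModel,
    protocol: ForceProtocol,
    rng: np.random.Generator,
    options: EngineOptions = EngineOptions(),
    replicate: int = 0,
) -> LifetimeSample:
    """Sample one trajectory; the bond starts in State 1 at t = 0."""
    if options.sampler == "fixed_step":
        return _sample_fixed_step(model, protocol, rng, options, replicate)
    return _sample_segment_exact(model, protocol, rng, options, replicate)


def _finish(protocol, t, state, n_switches, visited2, replicate, censored=False):
    clamp = protocol.clamp_start_time
    before = clamp is not None and t < clamp
    force = protocol.force(min(t, np.nextafter(protocol.total_duration, 0.0)))
    return LifetimeSample(
        t_rupture=t,
        state_at_rupture=int(state),
        ruptured_before_clamp=bool(before),
        visited_state2=visited2,
        n_switches=n_switches,
        rupture_force=force,
        replicate=replicate,
        censored=censored,
    )


def _sample_segment_exact(model, protocol, rng, options, replicate):
    t = 0.0
    state = BondState.STATE1
    n_switches = 0
    visited2 = False
    horizon = options.max_time
    seg_iter = list(protocol.segments)
    i = 0
    while i < len(seg_iter):
        seg = seg_iter[i]
        if t >= horizon:
            return _finish(protocol, horizon, state, n_switches, visited2,
                           replicate, censored=True)
        if t >= seg.t_end:
            i += 1
            continue
        trs = model.outgoing(state)
        if seg.kind == "sinusoidal":
            # piecewise thinning over sub-intervals of the period
            sub = 2.0 * math.pi / seg.omega / 32.0
            seg_end = min(seg.t_end, horizon)
            advanced = False
            while True:
                t_sub_end = min(t + sub, seg_end)
                bound = _thinning_bound(trs, seg, t, t_sub_end)
                if bound <= 0.0:
                    t = t_sub_end
                else:
                    t_prop = t + rng.exponential() / bound
                    if t_prop >= t_sub_end:
                        t = t_sub_end
                    else:
                        t = t_prop
                        F = seg.force(t)
                        rates = _rates_at(trs, F)
                        if rng.random() * bound <= sum(rates):
                            which = _pick(rng, rates)
                            if which == 0:  # dissociation
                                return _finish(protocol, t, state, n_switches,
                                               visited2, replicate)
                            state = (BondState.STATE2
                                     if state == BondState.STATE1
                                     else BondState.STATE1)
                            n_switches += 1
                            visited2 = visited2 or state == BondState.STATE2
                            trs = model.outgoing(state)
                if t >= seg_end:
                    advanced = True
                    break
            if advanced:
                continue
        else:
            # constant / linear segment: invert the integrated hazard
            seg_end = min(seg.t_end, horizon)
            target = rng.exponential()
            if math.isinf(seg_end):
                seg_end = horizon
            dt_max = seg_end - t
            dt = _invert_hazard(trs, seg, t, dt_max, target,
                                options.root_tolerance)
            if dt is None:
                t = seg_end
                continue
            t = t + dt
            F = seg.force(t)
            rates = _rates_at(trs, F)
            which = _pick(rng, rates)
            if which == 0:
                return _finish(protocol, t, state, n_switches, visited2,
                               replicate)
            state = (BondState.STATE2 if state == BondState.STATE1
                     else BondState.STATE1)
            n_switches += 1
            visited2 = visited2 or state == BondState.STATE2
    return _finish(protocol, min(t, horizon), state, n_switches, visited2,
                   replicate, censored=True)


def _sinusoid_hazard_simpson(trs, seg: Segment, t0: float, dt: float) -> float:
    """Simpson estimate of the integrated hazard on a sinusoidal segment."""
    def total(t):
        return sum(_rates_at(trs, seg.force(t)))
    return dt / 6.0 * (total(t0) + 4.0 * total(t0 + dt / 2.0) + total(t0 + dt))


def _sample_fixed_step(model, protocol, rng, options, replicate):
    t = 0.0
    state = BondState.STATE1
    n_switches = 0
    visited2 = False
    horizon = options.max_time
    i = 0
    segs = protocol.segments
    while t < horizon:
        while i < len(segs) and t >= segs[i].t_end:
            i += 1
        if i >= len(segs):
            break
        seg = segs[i]
        trs = model.outgoing(state)
        F_now = seg.force(t)
        rate_now = sum(_rates_at(trs, F_now))
        if seg.kind == "sinusoidal":
            period = 2.0 * math.pi / seg.omega
            rate_now = max(rate_now, _thinning_bound(
                trs, seg, t, min(t + period / 64.0, seg.t_end)))
        if rate_now <= 0.0:
            t = min(seg.t_end, horizon)
            continue
        dt = min(options.step_cap / rate_now, min(seg.t_end, horizon) - t)
        if seg.kind == "sinusoidal":
            dt = min(dt, 2.0 * math.pi / seg.omega / 64.0)
            H = _sinusoid_hazard_simpson(trs, seg, t, dt)
        else:
            H = _segment_hazard(trs, seg, t, dt)
        if rng.random() < -math.expm1(-H):
            t = t + dt
            rates = _rates_at(trs, seg.force(t))
            which = _pick(rng, rates)
            if which == 0:
                return _finish(protocol, t, state, n_switches, visited2,
                               replicate)
            state = (BondState.STATE2 if state == BondState.STATE1
                     else BondState.STATE1)
            n_switches += 1
            visited2 = visited2 or state == BondState.STATE2
        else:
            t = t + dt
    return _finish(protocol, min(t, horizon), state, n_switches, visited2,
                   replicate, censored=True)


def simulate_ensemble(
    model: TwoStateBondModel,
    protocol: ForceProtocol,
    n_reps: int,
    seed: int,
    options: EngineOptions = EngineOptions(),
) -> list[LifetimeSample]:
    """``n_reps`` independent trajectories with per-replicate substreams.

    Replicate ``i`` uses the i-th child of ``SeedSequence(seed)``, so results
    are bit-reproducible for fixed (seed, n_reps, options) and replicates are
    statistically independent.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    children = np.random.SeedSequence(seed).spawn(n_reps)
    samples = []
    censored = 0
    for i, child in enumerate(children):
        s = sample_single_bond(model, protocol, np.random.default_rng(child),
                               options, replicate=i)
        censored += s.censored
        samples.append(s)
    if censored > max(1, 0.001 * n_reps) and protocol.clamp_start_time is not None:
        raise RuntimeError(
            f"{censored}/{n_reps} trajectories censored at max_time = "
            f"{options.max_time}; lifetimes under this protocol should be finite"
        )
    return samples


def rupture_forces(samples: list[LifetimeSample]) -> np.ndarray:
    """Rupture forces F(t_rupture) of the non-censored samples, pN."""
    return np.array([s.rupture_force for s in samples if not s.censored])
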