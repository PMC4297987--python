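"""Deterministic force histories applied to a bond.

A :class:`ForceProtocol` is a piecewise function of time built from
``linear``, ``constant`` and ``sinusoidal`` segments.  Forces are tensile
magnitudes: every protocol satisfies F(t) >= 0 and is continuous across
segment boundaries.  The segment structure is queryable so that the kinetic
Monte Carlo engine can integrate hazards exactly per segment.

Constructors cover the load histories used throughout the package:

* :func:`constant_force` -- instantaneous clamp.
* :func:`clamp_after_ramp` -- linear ramp to a clamped value (force-clamp).
* :func:`steady_ramp` -- unbounded linear ramp (dynamic force spectroscopy).
* :func:`peak_unload_clamp` -- load to a peak, unload, then clamp.
* :func:`cyclic_then_clamp` -- repeated load/unload triangles, then clamp at
  the peak (cyclic mechanical reinforcement history).
* :func:`oscillating` -- sinusoidal oscillation about a homeostatic force,
  shaped by the contractile stress fiber's regulation (see below).

``clamp_start_time`` marks the instant the force first reaches its final
clamped value; lifetimes measured from that instant (excluding earlier
ruptures) are the T1 convention, lifetimes from t = 0 including every rupture
are T0.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass
from typing import Optional

__all__ = [
    "Segment",
    "ForceProtocol",
    "constant_force",
    "clamp_after_ramp",
    "steady_ramp",
    "peak_unload_clamp",
    "cyclic_then_clamp",
    "oscillating",
    "protocol_from_dict",
]

_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """One piece of a force history on [t_start, t_end).

    kind == "linear":     F(t) = F_start + slope * (t - t_start)
    kind == "constant":   F(t) = F_start
    kind == "sinusoidal": F(t) = F0 + amp * sin(omega * t + phase)
                          (phase referenced to absolute time t, not t_start)
    """

    t_start: float
    t_end: float  # may be math.inf
    kind: str
    F_start: float = 0.0
    slope: float = 0.0       # pN/s, linear only
    F0: float = 0.0          # pN, sinusoidal mean
    amp: float = 0.0         # pN, sinusoidal amplitude
    omega: float = 0.0       # rad/s
    phase: float = 0.0       # rad

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("segment requires t_end > t_start")
        if self.kind not in ("linear", "constant", "sinusoidal"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    def force(self, t: float) -> float:
        if self.kind == "constant":
            return self.F_start
        if self.kind == "linear":
            return self.F_start + self.slope * (t - self.t_start)
        return self.F0 + self.amp * math.sin(self.omega * t + self.phase)

    def force_range(self) -> tuple[float, float]:
        """(min, max) of F over the segment (conservative for sinusoids)."""
        if self.kind == "constant":
            return self.F_start, self.F_start
        if self.kind == "linear":
            if math.isinf(self.t_end):
                hi = math.inf if self.slope > 0 else self.F_start
                lo = self.F_start if self.slope >= 0 else -math.inf
                return lo, hi
            f_end = self.force(self.t_end)
            return min(self.F_start, f_end), max(self.F_start, f_end)
        return self.F0 - abs(self.amp), self.F0 + abs(self.amp)


@dataclass(frozen=True)
class ForceProtocol:
    """An ordered, contiguous, non-negative, continuous force history."""

    segments: tuple[Segment, ...]
    clamp_start_time: Optional[float] = None
    label: str = "protocol"

    def __post_init__(self) -> None:
        segs = self.segments
        if not segs:
            raise ValueError("protocol needs at least one segment")
        if segs[0].t_start != 0.0:
            raise ValueError("first segment must start at t = 0")
        prev_end = 0.0
        prev_force = None
        for s in segs:
            if abs(s.t_start - prev_end) > _EPS:
                raise ValueError("segments must be contiguous")
            f0 = s.force(s.t_start)
            if prev_force is not None and abs(f0 - prev_force) > 1e-6:
                raise ValueError(
                    f"force discontinuity at t = {s.t_start}: {prev_force} -> {f0}"
                )
            lo, _ = s.force_range()
            if lo < -1e-9:
                raise ValueError("force must stay >= 0 on every segment")
            prev_end = s.t_end
            prev_force = None if math.isinf(s.t_end) else s.force(s.t_end)
        if self.clamp_start_time is not None:
            last = segs[-1]
            if last.kind != "constant" or abs(self.clamp_start_time - last.t_start) > _EPS:
                raise ValueError(
                    "clamp_start_time must equal the start of the final constant segment"
                )
        object.__setattr__(self, "_starts", tuple(s.t_start for s in segs))

    @property
    def total_duration(self) -> float:
        return self.segments[-1].t_end

    def segment_at(self, t: float) -> Segment:
        if t < 0:
            raise ValueError("t must be >= 0")
        if t >= self.total_duration:
            raise ValueError(f"t = {t} beyond protocol duration {self.total_duration}")
        i = bisect_right(self._starts, t) - 1
        return self.segments[i]

    def force(self, t: float) -> float:
        """Evaluate F(t) in pN."""
        return self.segment_at(t).force(t)

    __call__ = force

    def segments_between(self, t0: float, t1: float) -> list[tuple[Segment, float, float]]:
        """Partition [t0, t1) into (segment, start, end) triples, exactly."""
        if not 0 <= t0 < t1:
            raise ValueError("need 0 <= t0 < t1")
        if t1 > self.total_duration:
            raise ValueError("t1 beyond protocol duration")
        out = []
        i = bisect_right(self._starts, t0) - 1
        t = t0
        while t < t1 - _EPS:
            s = self.segments[i]
            hi = min(s.t_end, t1)
            out.append((s, t, hi))
            t = hi
            i += 1
        return out


def constant_force(F: float, label: str | None = None) -> ForceProtocol:
    """Instantaneous clamp at ``F`` pN from t = 0 (clamp_start_time = 0)."""
    if F < 0:
        raise ValueError("clamp force must be >= 0")
    seg = Segment(0.0, math.inf, "constant", F_start=F)
    return ForceProtocol((seg,), clamp_start_time=0.0, label=label or f"clamp({F})")


def clamp_after_ramp(ramp_rate: float, clamp_force: float) -> ForceProtocol:
    """Linear ramp at ``ramp_rate`` pN/s until clamped at ``clamp_force`` pN."""
    if ramp_rate <= 0:
        raise ValueError("ramp_rate must be > 0")
    if clamp_force < 0:
        raise ValueError("clamp_force must be >= 0")
    if clamp_force == 0:
        return constant_force(0.0, label=f"clamp_after_ramp({ramp_rate}, 0)")
    tc = clamp_force / ramp_rate
    segs = (
        Segment(0.0, tc, "linear", F_start=0.0, slope=ramp_rate),
        Segment(tc, math.inf, "constant", F_start=clamp_force),
    )
    return ForceProtocol(segs, clamp_start_time=tc,
                         label=f"clamp_after_ramp({ramp_rate}, {clamp_force})")


def steady_ramp(loading_rate: float) -> ForceProtocol:
    """Unbounded ramp F = r_f * t (steady force-ramp load)."""
    if loading_rate <= 0:
        raise ValueError("loading_rate must be > 0")
    seg = Segment(0.0, math.inf, "linear", F_start=0.0, slope=loading_rate)
    return ForceProtocol((seg,), clamp_start_time=None,
                         label=f"steady_ramp({loading_rate})")


def peak_unload_clamp(
    load_rate: float, peak_force: float, unload_rate: float, clamp_force: float
) -> ForceProtocol:
    """Load to ``peak_force``, unload to ``clamp_force``, hold forever.

    ``unload_rate`` is given signed (negative, mirroring the usual notation).
    """
    if not (load_rate > 0 > unload_rate):
        raise ValueError("need load_rate > 0 > unload_rate")
    if not (peak_force >= clamp_force >= 0):
        raise ValueError("need peak_force >= clamp_force >= 0")
    if peak_force == clamp_force:
        return clamp_after_ramp(load_rate, clamp_force)
    t1 = peak_force / load_rate
    t2 = t1 + (peak_force - clamp_force) / abs(unload_rate)
    segs = (
        Segment(0.0, t1, "linear", F_start=0.0, slope=load_rate),
        Segment(t1, t2, "linear", F_start=peak_force, slope=-abs(unload_rate)),
        Segment(t2, math.inf, "constant", F_start=clamp_force),
    )
    return ForceProtocol(
        segs, clamp_start_time=t2,
        label=f"peak_unload_clamp({load_rate}, {peak_force}, {unload_rate}, {clamp_force})",
    )


def cyclic_then_clamp(
    n_cycles: int, peak_force: float, load_rate: float, unload_rate: float
) -> ForceProtocol:
    """``n_cycles`` full triangles 0 -> peak -> 0, a final ramp to the peak,
    then clamp at the peak force forever."""
    if not (isinstance(n_cycles, int) and n_cycles >= 0):
        raise ValueError("n_cycles must be a non-negative integer")
    if peak_force <= 0:
        raise ValueError("peak_force must be > 0")
    if not (load_rate > 0 > unload_rate):
        raise ValueError("need load_rate > 0 > unload_rate")
    tu = peak_force / load_rate
    td = peak_force / abs(unload_rate)
    segs: list[Segment] = []
    t = 0.0
    for _ in range(n_cycles):
        segs.append(Segment(t, t + tu, "linear", F_start=0.0, slope=load_rate))
        t += tu
        segs.append(Segment(t, t + td, "linear", F_start=peak_force,
                            slope=-abs(unload_rate)))
        t += td
    segs.append(Segment(t, t + tu, "linear", F_start=0.0, slope=load_rate))
    t += tu
    segs.append(Segment(t, math.inf, "constant", F_start=peak_force))
    return ForceProtocol(
        tuple(segs), clamp_start_time=t,
        label=f"cyclic_then_clamp({n_cycles}, {peak_force}, {load_rate}, {unload_rate})",
    )


def oscillating(
    F0: float, alpha: float, freq: float, gamma: float = 10.0
) -> ForceProtocol:
    """Periodically oscillating force about the homeostatic value ``F0``.

    The stress fiber pulling on the adhesion remodels toward its homeostatic
    tension ``F0`` at rate ``gamma`` (1/s) while a cyclic substrate stretch of
    amplitude ``alpha`` at frequency ``freq`` (Hz) drives it.  The steady
    periodic force is

        F(t) = F0 * [1 + alpha * beta * sin(omega t + phi)],
        omega = 2 pi f,  beta = omega / sqrt(omega^2 + gamma^2),
        phi = arctan(gamma / omega),

    so slow stretches are absorbed by fiber remodelling (beta -> 0) while
    fast ones are transmitted in full (beta -> 1).  The time average of F
    over one exact period equals F0.

    Raises if the parameters would drive F(t) < 0 (the physical regime is
    oscillation about a positive homeostatic force; clamping negative
    excursions to zero would change the kinetics silently).
    """
    if F0 <= 0:
        raise ValueError("F0 must be > 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if freq <= 0:
        raise ValueError("freq must be > 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    omega = 2.0 * math.pi * freq
    beta = omega / math.hypot(omega, gamma)
    amp = F0 * alpha * beta
    if amp >= F0:
        raise ValueError(
            f"oscillation amplitude {amp:.3g} pN >= F0 = {F0} pN would drive F(t) < 0"
        )
    if amp == 0.0:
        return constant_force(F0, label=f"oscillating({F0}, 0, {freq}, {gamma})")
    phase = math.atan2(gamma, omega)
    seg = Segment(0.0, math.inf, "sinusoidal", F_start=F0 + amp * math.sin(phase),
                  F0=F0, amp=amp, omega=omega, phase=phase)
    return ForceProtocol((seg,), clamp_start_time=None,
                         label=f"oscillating({F0}, {alpha}, {freq}, {gamma})")


def protocol_from_dict(d: dict) -> ForceProtocol:
    """Build a protocol from the config schema.

    ``{"type": "clamp"|"ramp"|"peak_unload_clamp"|"cyclic"|"oscillating"|"constant",
    ...parameters...}`` with forces in pN, rates in pN/s, frequency in Hz.
    """
    kind = d.get("type")
    p = {k: v for k, v in d.items() if k != "type"}
    try:
        if kind == "constant":
            return constant_force(p["force"])
        if kind == "clamp":
            return clamp_after_ramp(p["ramp_rate"], p["clamp_force"])
        if kind == "ramp":
            return steady_ramp(p["loading_rate"])
        if kind == "peak_unload_clamp":
            return peak_unload_clamp(p["load_rate"], p["peak_force"],
                                     p["unload_rate"], p["clamp_force"])
        if kind == "cyclic":
            return cyclic_then_clamp(int(p["n_cycles"]), p["peak_force"],
                                     p["load_rate"], p["unload_rate"])
        if kind == "oscillating":
            return oscillating(p["F0"], p["alpha"], p["freq"],
                               p.get("gamma", 10.0))
    except KeyError as e:
        raise ValueError(f"protocol config for {kind!r} missing key {e}") from None
    raise ValueError(f"unknown protocol type {kind!r}")
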