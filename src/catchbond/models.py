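"""Two-state bond models with Bell-law force-dependent kinetics.

A bound receptor--ligand complex is described by two adhesive conformations
(State 1, State 2) plus a dissociated, absorbing State 0.  Every transition
rate follows Bell's law

    k(F) = k0 * exp(F / Fb),

with the sign of the force scale ``Fb`` carried explicitly: a positive ``Fb``
gives a rate that grows with tensile force (slip-like), a negative ``Fb`` a
rate that is suppressed by force.  Two built-in parameter sets implement the
two canonical "catching" strategies:

* ``type1`` -- the bond forms in the *weak* State 1; force promotes switching
  to the strong State 2 (P-selectin/PSGL-1 style).
* ``type2`` -- the bond forms in the *strong* State 1; force prevents
  switching to the weak State 2 (FimH/mannose style).

In both built-ins the back-switch 2->1 is suppressed by force (its stored
force scale is -1.0 pN): force tilts the conformational landscape against
returning, which is what produces the catch behaviour of the first type.

The module also provides closed-form constant-force oracles (mean first
passage time to dissociation and the survival function) used to validate the
stochastic engine.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

__all__ = [
    "EXP_CAP",
    "BellTransition",
    "BondState",
    "TwoStateBondModel",
    "bell_rate",
    "builtin_model",
    "available_models",
    "slip_model",
    "model_from_dict",
    "model_to_dict",
    "generator_matrix",
    "mean_lifetime_constant_force",
    "survival_function_constant_force",
]

#: Cap on the Bell exponent F/Fb.  Reaching it signals non-physical
#: parameters or forces; the rate is clamped and a warning is emitted.
EXP_CAP = 700.0


class BondState(IntEnum):
    """Bond state labels: 0 is absorbing (dissociated)."""

    DISSOCIATED = 0
    STATE1 = 1
    STATE2 = 2


@dataclass(frozen=True)
class BellTransition:
    """One force-dependent transition, ``k(F) = k0 * exp(F / Fb)``.

    Parameters
    ----------
    k0 : float
        Zero-force rate, 1/s.  ``k0 = 0`` marks an absent transition
        (used for degenerate single-pathway slip bonds).
    Fb : float
        Force scale, pN.  Sign-carrying: negative values are legal and mean
        the rate decreases with force.
    """

    k0: float
    Fb: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k0) and self.k0 >= 0.0):
            raise ValueError(f"k0 must be finite and >= 0, got {self.k0!r}")
        if not (math.isfinite(self.Fb) and self.Fb != 0.0):
            raise ValueError(f"Fb must be finite and nonzero, got {self.Fb!r}")

    def rate(self, F: float) -> float:
        """Rate at tensile force ``F`` (pN), per Bell's law."""
        return bell_rate(self, F)


def bell_rate(tr: BellTransition, F: float) -> float:
    """Evaluate Bell's law ``k0 * exp(F / Fb)`` at tensile force ``F`` >= 0 pN."""
    if not (isinstance(F, (int, float)) and math.isfinite(F)):
        raise ValueError(f"force must be finite, got {F!r}")
    if F < 0.0:
        raise ValueError(f"force must be a tensile magnitude >= 0, got {F!r}")
    if tr.k0 == 0.0:
        return 0.0
    x = F / tr.Fb
    if x > EXP_CAP:
        warnings.warn(
            f"Bell exponent F/Fb = {x:.3g} exceeds {EXP_CAP}; rate clamped. "
            "This indicates non-physical parameters or forces.",
            RuntimeWarning,
            stacklevel=2,
        )
        x = EXP_CAP
    return tr.k0 * math.exp(x)


@dataclass(frozen=True)
class TwoStateBondModel:
    """The four transitions of a two-state bond (1->0, 2->0, 1->2, 2->1)."""

    t10: BellTransition
    t20: BellTransition
    t12: BellTransition
    t21: BellTransition
    label: str = field(default="custom")

    def rates(self, F: float) -> tuple[float, float, float, float]:
        """All four rates ``(k10, k20, k12, k21)`` at force ``F`` (pN)."""
        return (
            bell_rate(self.t10, F),
            bell_rate(self.t20, F),
            bell_rate(self.t12, F),
            bell_rate(self.t21, F),
        )

    def outgoing(self, state: BondState) -> tuple[BellTransition, BellTransition]:
        """Outgoing (dissociation, switch) transitions of a bound state."""
        if state == BondState.STATE1:
            return self.t10, self.t12
        if state == BondState.STATE2:
            return self.t20, self.t21
        raise ValueError(f"state {state!r} has no outgoing transitions")


# Tabulated designed parameters for the two catch-bond types.  The signs of
# the switching force scales implement the common "catching" principle that
# force tilts the conformational landscape toward the mechanically strong
# state: for type1 (State 2 strong) force promotes 1->2 and suppresses 2->1;
# for type2 (State 1 strong) force suppresses 1->2 and promotes 2->1.
_BUILTINS: dict[str, TwoStateBondModel] = {
    "type1": TwoStateBondModel(
        t10=BellTransition(3.0, 12.0),
        t20=BellTransition(0.01, 12.0),
        t12=BellTransition(0.02, 3.0),
        t21=BellTransition(0.001, -1.0),
        label="type1",
    ),
    "type2": TwoStateBondModel(
        t10=BellTransition(0.012, 14.0),
        t20=BellTransition(1.0, 4.0),
        t12=BellTransition(1.3, -6.0),
        t21=BellTransition(0.001, 1.0),
        label="type2",
    ),
}


def available_models() -> list[str]:
    return sorted(_BUILTINS)


def builtin_model(name: str) -> TwoStateBondModel:
    """Return a built-in designed parameter set (``type1`` or ``type2``)."""
    try:
        return _BUILTINS[name]
    except KeyError:
        raise ValueError(
            f"unknown model {name!r}; available: {', '.join(available_models())}"
        ) from None


def slip_model(k_s0: float, Fb: float, label: str | None = None) -> TwoStateBondModel:
    """A pure slip bond: single dissociation pathway, State 2 unreachable.

    ``k(F) = k_s0 * exp(F / Fb)`` with ``Fb > 0``.
    """
    if Fb <= 0:
        raise ValueError("a slip bond requires Fb > 0")
    return TwoStateBondModel(
        t10=BellTransition(k_s0, Fb),
        t20=BellTransition(0.0, Fb),
        t12=BellTransition(0.0, 1.0),
        t21=BellTransition(0.0, 1.0),
        label=label or f"slip(k_s0={k_s0}, Fb={Fb})",
    )


_SCHEMA_KEYS = ("k10", "Fb10", "k20", "Fb20", "k12", "Fb12", "k21", "Fb21")


def model_from_dict(d: dict) -> TwoStateBondModel:
    """Build a model from the config schema.

    Either ``{"name": "type1"}`` for a built-in, or the eight keys
    ``k10, Fb10, k20, Fb20, k12, Fb12, k21, Fb21`` (units 1/s and pN) plus an
    optional ``label``.  Negative ``k0`` or zero ``Fb`` are rejected.
    """
    if "name" in d:
        return builtin_model(d["name"])
    missing = [k for k in _SCHEMA_KEYS if k not in d]
    if missing:
        raise ValueError(f"model config missing keys: {missing}")
    for k in _SCHEMA_KEYS:
        if not isinstance(d[k], (int, float)):
            raise ValueError(f"model config key {k!r} must be a number")
    return TwoStateBondModel(
        t10=BellTransition(float(d["k10"]), float(d["Fb10"])),
        t20=BellTransition(float(d["k20"]), float(d["Fb20"])),
        t12=BellTransition(float(d["k12"]), float(d["Fb12"])),
        t21=BellTransition(float(d["k21"]), float(d["Fb21"])),
        label=str(d.get("label", "custom")),
    )


def model_to_dict(model: TwoStateBondModel) -> dict:
    return {
        "k10": model.t10.k0, "Fb10": model.t10.Fb,
        "k20": model.t20.k0, "Fb20": model.t20.Fb,
        "k12": model.t12.k0, "Fb12": model.t12.Fb,
        "k21": model.t21.k0, "Fb21": model.t21.Fb,
        "label": model.label,
    }


def generator_matrix(model: TwoStateBondModel, F: float) -> np.ndarray:
    """Transient generator over (STATE1, STATE2) at constant force ``F``.

    ``Q[0,0] = -(k10+k12)``, ``Q[0,1] = k12``, ``Q[1,0] = k21``,
    ``Q[1,1] = -(k20+k21)``.  Row-sum deficits equal the dissociation rates.
    """
    a, c, b, d = model.rates(F)  # a=k10, c=k20, b=k12, d=k21
    return np.array([[-(a + b), b], [d, -(c + d)]], dtype=float)


def _check_initial(initial_state: BondState) -> BondState:
    s = BondState(initial_state)
    if s not in (BondState.STATE1, BondState.STATE2):
        raise ValueError("initial_state must be STATE1 or STATE2")
    return s


def mean_lifetime_constant_force(
    model: TwoStateBondModel, F: float, initial_state: BondState = BondState.STATE1
) -> float:
    """Mean first-passage time to dissociation at constant force (seconds).

    With a = k10(F), b = k12(F), c = k20(F), d = k21(F):

        tau1 = (b + c + d) / ((a+b)(c+d) - b d),
        tau2 = (d + a + b) / ((a+b)(c+d) - b d).

    Degenerate single-pathway cases (unreachable second state) reduce to the
    single-exponential escape time.
    """
    s = _check_initial(initial_state)
    a, c, b, d = model.rates(F)
    if s == BondState.STATE1 and b == 0.0:
        if a <= 0.0:
            raise ValueError("no absorption: k10 and k12 both vanish at this force")
        return 1.0 / a
    if s == BondState.STATE2 and d == 0.0:
        if c <= 0.0:
            raise ValueError("no absorption: k20 and k21 both vanish at this force")
        return 1.0 / c
    denom = (a + b) * (c + d) - b * d
    if denom <= 0.0:
        raise ValueError("no absorption: both dissociation rates vanish")
    if s == BondState.STATE1:
        return (b + c + d) / denom
    return (d + a + b) / denom


def survival_function_constant_force(
    model: TwoStateBondModel,
    F: float,
    initial_state: BondState = BondState.STATE1,
    t: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Probability the bond is still associated at time ``t`` under constant force.

    ``S(t) = p1(t) + p2(t)`` with ``p(t) = p(0) expm(Q t)``; the 2x2 matrix
    exponential is evaluated in closed form by eigendecomposition (the
    discriminant ``(a+b-c-d)^2 + 4 b d`` is non-negative, so the eigenvalues
    are real), which keeps this function exact enough to serve as an oracle.
    """
    s = _check_initial(initial_state)
    a, c, b, d = model.rates(F)
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("t must be >= 0")
    alpha = a + b  # total escape rate from state 1
    beta = c + d   # total escape rate from state 2
    # S(t) = A e^{lam1 t} + (1 - A) e^{lam2 t} with A fixed by S(0) = 1 and
    # S'(0) = b - alpha (resp. d - beta).  The eigenvalues are computed
    # stably: the large-magnitude root from the quadratic formula, the
    # small one from the product lam1*lam2 = det -- the naive mu +- delta
    # form cancels catastrophically when one escape rate is enormous (e.g.
    # a back-switch rate ~ e^{F/1 pN} at high force).
    trace = -(alpha + beta)
    det = alpha * beta - b * d
    disc = math.sqrt(max(trace * trace - 4.0 * det, 0.0))
    lam2 = 0.5 * (trace - disc)                    # fast eigenvalue, <= 0
    lam1 = det / lam2 if lam2 != 0.0 else 0.0      # slow eigenvalue
    sprime0 = (b - alpha) if s == BondState.STATE1 else (d - beta)
    if lam1 - lam2 > 1e-12 * abs(lam2):
        A = (sprime0 - lam2) / (lam1 - lam2)
        out = A * np.exp(lam1 * tt) + (1.0 - A) * np.exp(lam2 * tt)
    else:
        # degenerate eigenvalues: S = e^{lam t} (1 + (S'(0) - lam) t)
        out = np.exp(lam1 * tt) * (1.0 + (sprime0 - lam1) * tt)
    out = np.clip(out, 0.0, 1.0)
    if np.ndim(t) == 0:
        return float(out)
    return out
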