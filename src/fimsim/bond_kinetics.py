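"""Two-state allosteric catch-bond kinetics for the FimH tip adhesin.

FimH bound to mannose interconverts between a short-lived low-affinity
conformation (state 1) and a long-lived high-affinity, "activated"
conformation (state 2).  Tensile force biases the allosteric switch toward
activation (catch regime) while also accelerating rupture from either state
(slip regime), so the mean bond lifetime is non-monotone in force with a
maximum at intermediate load.  All rates follow the Bell form
``k(F) = k0 * exp(+-F x / kBT)``; only tensile force enters the rate laws --
compressed bonds are treated as carrying zero force.

Default rate constants follow the two-state allosteric catch-bond literature
scale and are calibrated so that bonds are long-lived between 30 and 70 pN
and break within seconds above 90 pN.

Units: forces pN, lengths nm, rates 1/s, energies pN*nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "BondParams",
    "BondState",
    "UNBOUND",
    "LOW_AFFINITY",
    "ACTIVATED",
    "bond_rates",
    "mean_bond_lifetime",
    "step_bond",
    "attempt_binding",
]

UNBOUND, LOW_AFFINITY, ACTIVATED = 0, 1, 2
_STATUS_NAMES = {UNBOUND: "unbound", LOW_AFFINITY: "low_affinity",
                 ACTIVATED: "activated"}
_STATUS_CODES = {v: k for k, v in _STATUS_NAMES.items()}

# packed parameter vector indices (shared with the whole-cell kernel)
PB_K10, PB_X10, PB_K20, PB_X20 = 0, 1, 2, 3
PB_K12, PB_X12, PB_K21, PB_X21 = 4, 5, 6, 7
PB_KON, PB_CAPTURE, PB_KBT = 8, 9, 10
PB_SIZE = 11

_EXP_CAP = 60.0


@dataclass
class BondParams:
    """Rate constants of the two-state allosteric catch bond.

    ``k0_10``/``x_10``: rupture from the low-affinity state; ``k0_20``/
    ``x_20``: rupture from the activated state; ``k0_12``/``x_12``:
    force-activated switch; ``k0_21``/``x_21``: force-suppressed reverse
    switch.  ``k_on`` applies while the fimbrial tip is within
    ``capture_radius`` of the surface.
    """

    k0_10: float = 0.5       # 1/s
    x_10: float = 0.30       # nm
    k0_20: float = 1.0e-7    # 1/s  (activated state far longer-lived: catch premise)
    x_20: float = 0.70       # nm
    k0_12: float = 0.1       # 1/s
    x_12: float = 1.0        # nm
    k0_21: float = 2.0       # 1/s
    x_21: float = 0.80       # nm
    k_on: float = 10.0       # 1/s while in range
    capture_radius: float = 3.0   # nm
    kBT: float = 4.1         # pN*nm

    def __post_init__(self) -> None:
        for name in ("k0_10", "k0_20", "k0_12", "k0_21", "kBT"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("x_10", "x_20", "x_12", "x_21", "capture_radius"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.k_on < 0:
            raise ValueError("k_on must be >= 0")
        if self.k0_20 >= self.k0_10:
            raise ValueError(
                "catch-bond premise violated: the activated state must be "
                "longer-lived at zero force (k0_20 < k0_10)")

    def as_array(self) -> np.ndarray:
        p = np.empty(PB_SIZE, dtype=np.float64)
        p[PB_K10], p[PB_X10] = self.k0_10, self.x_10
        p[PB_K20], p[PB_X20] = self.k0_20, self.x_20
        p[PB_K12], p[PB_X12] = self.k0_12, self.x_12
        p[PB_K21], p[PB_X21] = self.k0_21, self.x_21
        p[PB_KON], p[PB_CAPTURE] = self.k_on, self.capture_radius
        p[PB_KBT] = self.kBT
        return p


@dataclass
class BondState:
    """Current conformational state of one FimH-mannose bond."""

    status: str = "unbound"
    tensile_force: float = 0.0

    def __post_init__(self) -> None:
        if self.status not in _STATUS_CODES:
            raise ValueError(f"unknown bond status {self.status!r}")

    @property
    def code(self) -> int:
        return _STATUS_CODES[self.status]

    @property
    def bound(self) -> bool:
        return self.status != "unbound"


@njit(cache=True)
def _bond_rates_nb(F: float, p: np.ndarray):
    """(k_10, k_20, k_12, k_21) at tensile force F; F < 0 is clamped to 0."""
    if F < 0.0:
        F = 0.0
    kBT = p[PB_KBT]
    e10 = min(F * p[PB_X10] / kBT, _EXP_CAP)
    e20 = min(F * p[PB_X20] / kBT, _EXP_CAP)
    e12 = min(F * p[PB_X12] / kBT, _EXP_CAP)
    e21 = min(F * p[PB_X21] / kBT, _EXP_CAP)
    return (p[PB_K10] * math.exp(e10), p[PB_K20] * math.exp(e20),
            p[PB_K12] * math.exp(e12), p[PB_K21] * math.exp(-e21))


def bond_rates(F: float, params: BondParams):
    """Bell rates ``(k_10, k_20, k_12, k_21)`` at tensile force ``F`` (pN)."""
    if F < 0:
        raise ValueError("bond kinetics take tensile (>= 0) force; "
                         "clamp compressive contact to zero first")
    return _bond_rates_nb(float(F), params.as_array())


def mean_bond_lifetime(F: float, params: BondParams,
                       initial_status: str = "activated") -> float:
    """Closed-form mean first-passage time to rupture at constant force.

    Solves the two linear first-passage equations of the continuous-time
    chain {1, 2} with the unbound state absorbing:

        T1 = 1/(k10+k12) + k12/(k10+k12) * T2
        T2 = 1/(k20+k21) + k21/(k20+k21) * T1
    """
    if initial_status == "unbound":
        raise ValueError("lifetime is defined for a bound initial state")
    k10, k20, k12, k21 = bond_rates(F, params)
    a1 = k10 + k12
    a2 = k20 + k21
    # [[1, -k12/a1], [-k21/a2, 1]] [T1, T2] = [1/a1, 1/a2]
    det = 1.0 - (k12 / a1) * (k21 / a2)
    T1 = (1.0 / a1 + (k12 / a1) * (1.0 / a2)) / det
    T2 = (1.0 / a2 + (k21 / a2) * (1.0 / a1)) / det
    return T1 if initial_status == "low_affinity" else T2


def step_bond(state: BondState, F: float, dt: float,
              rng: np.random.Generator, params: BondParams | None = None):
    """One fixed-step stochastic update of the bond master equation.

    Transitions compete within the step: with total probability
    ``1 - exp(-sum(k) dt)`` exactly one event fires, chosen in proportion to
    its rate (exact in the dt -> 0 limit).  Returns ``(new_state,
    ruptured)`` where ``ruptured`` flags a transition to unbound.
    """
    if params is None:
        params = BondParams()
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if not state.bound:
        return BondState("unbound", 0.0), False
    Ft = max(float(F), 0.0)
    k10, k20, k12, k21 = _bond_rates_nb(Ft, params.as_array())
    if state.status == "low_affinity":
        events = (("unbound", k10), ("activated", k12))
    else:
        events = (("unbound", k20), ("low_affinity", k21))
    ktot = events[0][1] + events[1][1]
    u = rng.random()
    p_any = -math.expm1(-ktot * dt)
    if u >= p_any:
        return BondState(state.status, Ft), False
    # competing-risk draw over normalized event probabilities
    target = events[0][0] if rng.random() < events[0][1] / ktot else events[1][0]
    ruptured = target == "unbound"
    return BondState(target, 0.0 if ruptured else Ft), ruptured


def attempt_binding(tip_surface_distance: float, dt: float,
                    params: BondParams, rng: np.random.Generator,
                    seed_bond: bool = False):
    """Stochastic association of a fimbrial tip with the mannose surface.

    Binds with probability ``1 - exp(-k_on dt)`` iff the tip is within
    ``capture_radius`` of the wall.  New bonds enter in the low-affinity
    state; the simulation's seed bond enters activated.  Returns the new
    :class:`BondState` or ``None`` if no bond formed.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if tip_surface_distance > params.capture_radius:
        return None
    if params.k_on <= 0.0:
        return None
    if rng.random() < -math.expm1(-params.k_on * dt):
        return BondState("activated" if seed_bond else "low_affinity", 0.0)
    return None
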