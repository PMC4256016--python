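"""Force-extension mechanics and coiling dynamics of a single fimbrial tether.

A type 1 fimbria is a helical quaternary polymer of hundreds to thousands of
subunits.  Each subunit is in one of three states:

* ``A`` -- part of the intact helical coil.  The contiguous A segment behaves
  as a Hookean spring (series of subunit springs).
* ``B`` -- uncoiled.  B subunits contribute contour length ``x0_B`` to a
  worm-like chain of persistence length ``l_pB``.
* ``C`` -- uncoiled and stretched.  Longer contour ``x0_C``, persistence
  length ``l_pC``.

Uncoiling (A<->B) is a cooperative transition occurring only at the single
edge of the helical coil, with Bell-model force dependence; this produces the
flat force plateau characteristic of yielding elasticity.  The B<->C stretch
transition occurs independently per uncoiled subunit and is treated as an
instantaneous force-dependent equilibrium, which produces the sloped late
part of the S-shaped curve.

Three elasticity modes are supported: ``yielding`` (full model), ``linear``
(uncoiling disallowed, pure Hookean rod), and ``strain_hardening``
(uncoiling at negligible force: a single WLC of contour ``n_subunits*x0_B``).

Units throughout: lengths nm, forces pN, energies pN*nm, rates 1/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "FimbriaParams",
    "FimbriaState",
    "wlc_force",
    "extension_at_tension",
    "tension_from_extension",
    "coil_transition_rates",
    "equilibrium_uncoiling_force",
    "step_coiling",
    "stretch_partition",
    "apply_stretch_partition",
    "force_extension_curve",
    "meanfield_pull_curve",
]

MODES = ("yielding", "linear", "strain_hardening")
MODE_YIELDING, MODE_LINEAR, MODE_STRAIN_HARDENING = 0, 1, 2

# indices into the packed parameter vector consumed by numba kernels
PM_RISE_A, PM_X0B, PM_X0C, PM_LPB, PM_LPC = 0, 1, 2, 3, 4
PM_XAB, PM_XBA, PM_K0AB, PM_K0BA = 5, 6, 7, 8
PM_KEQ, PM_XEQ, PM_KBT, PM_KCOIL, PM_FBUCK, PM_MODE = 9, 10, 11, 12, 13, 14
PM_SIZE = 15

_EXP_CAP = 60.0  # cap on Bell exponents; rates saturate instead of overflowing
_TENSION_CAP = 1.0e6  # pN; overstretched configurations saturate here


@dataclass
class FimbriaParams:
    """Mechanical and kinetic parameters of one fimbrial shaft.

    Defaults are calibrated so that the closed-form equilibrium uncoiling
    force is 32.2 pN and constant-speed pulls over 0.1-10 um/s produce
    speed-dependent plateaus ending in an S-curve near 150 pN.
    """

    n_subunits: int = 1430          # ~1 um native rod at 0.7 nm rise
    rise_A: float = 0.7             # nm helical rise per coiled subunit
    k_coil: float = 2000.0          # pN/nm per-subunit stiffness; A segment = k_coil/n_A
    x0_B: float = 5.0               # nm contour per uncoiled subunit
    x0_C: float = 6.6               # nm contour per stretched subunit
    l_pB: float = 3.0               # nm persistence length, segment B
    l_pC: float = 8.0               # nm persistence length, segment C
    x_AB: float = 0.30              # nm Bell distance, uncoiling
    x_BA: float = 1.20              # nm Bell distance, recoiling
    k0_AB: float = 0.2              # 1/s zero-force uncoiling rate
    k0_BA: float = 26135.5          # 1/s zero-force recoiling rate
    k_eq: float = 1.0e-3            # zero-force B<->C equilibrium constant
    x_eq: float = 0.40              # nm stretch-transition distance
    kBT: float = 4.1                # pN*nm
    mode: str = "yielding"
    buckling_force: float = 10.0    # pN compressive clamp

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.n_subunits < 1:
            raise ValueError("n_subunits must be >= 1")
        if self.x0_C < self.x0_B:
            raise ValueError("x0_C must be >= x0_B")
        for name in ("rise_A", "k_coil", "x0_B", "x0_C", "l_pB", "l_pC",
                     "k0_AB", "k0_BA", "k_eq", "kBT", "buckling_force"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("x_AB", "x_BA", "x_eq"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def mode_index(self) -> int:
        return MODES.index(self.mode)

    def as_array(self) -> np.ndarray:
        """Pack into the flat vector consumed by the numba kernels."""
        p = np.empty(PM_SIZE, dtype=np.float64)
        p[PM_RISE_A] = self.rise_A
        p[PM_X0B] = self.x0_B
        p[PM_X0C] = self.x0_C
        p[PM_LPB] = self.l_pB
        p[PM_LPC] = self.l_pC
        p[PM_XAB] = self.x_AB
        p[PM_XBA] = self.x_BA
        p[PM_K0AB] = self.k0_AB
        p[PM_K0BA] = self.k0_BA
        p[PM_KEQ] = self.k_eq
        p[PM_XEQ] = self.x_eq
        p[PM_KBT] = self.kBT
        p[PM_KCOIL] = self.k_coil
        p[PM_FBUCK] = self.buckling_force
        p[PM_MODE] = float(self.mode_index)
        return p

    def initial_state(self) -> "FimbriaState":
        """Subunit occupancy at rest for this elasticity mode."""
        n = self.n_subunits
        if self.mode == "linear":
            return FimbriaState(n_A=n, n_B=0, n_C=0)
        if self.mode == "strain_hardening":
            return FimbriaState(n_A=0, n_B=n, n_C=0)
        return FimbriaState(n_A=n, n_B=0, n_C=0)


@dataclass
class FimbriaState:
    """Per-fimbria subunit occupancy.  ``n_A + n_B + n_C`` is conserved."""

    n_A: int
    n_B: int = 0
    n_C: int = 0
    current_tension: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_A, self.n_B, self.n_C) < 0:
            raise ValueError("subunit counts must be >= 0")

    @property
    def n_total(self) -> int:
        return self.n_A + self.n_B + self.n_C

    @property
    def fraction_uncoiled(self) -> float:
        return (self.n_B + self.n_C) / max(self.n_total, 1)


# ---------------------------------------------------------------------------
# numba scalar primitives (shared with the whole-cell and AFM kernels)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _wlc_force_nb(x: float, lp: float, kBT: float) -> float:
    """Marko-Siggia interpolation force at fractional extension x in [0,1)."""
    om = 1.0 - x
    return (kBT / lp) * (0.25 / (om * om) - 0.25 + x)


@njit(cache=True)
def _wlc_dforce_nb(x: float, lp: float, kBT: float) -> float:
    """dF/dx of the Marko-Siggia form (per unit fractional extension)."""
    om = 1.0 - x
    return (kBT / lp) * (0.5 / (om * om * om) + 1.0)


@njit(cache=True)
def _wlc_frac_at_force_nb(F: float, lp: float, kBT: float) -> float:
    """Inverse Marko-Siggia: fractional extension at tension F >= 0.

    Safeguarded Newton iteration on the monotone form; exact 0 at F = 0.
    """
    if F <= 0.0:
        return 0.0
    g = F * lp / kBT
    lo = 0.0
    hi = 1.0 - 1e-12
    x = 1.0 - 0.5 / math.sqrt(g + 0.265)
    if x < 0.0:
        x = 0.5 * g
    for _ in range(60):
        fx = 0.25 / ((1.0 - x) * (1.0 - x)) - 0.25 + x - g
        if fx > 0.0:
            hi = x
        else:
            lo = x
        dfx = 0.5 / ((1.0 - x) ** 3) + 1.0
        step = fx / dfx
        xn = x - step
        if xn <= lo or xn >= hi:
            xn = 0.5 * (lo + hi)
        if abs(xn - x) < 1e-11:
            x = xn
            break
        x = xn
    return x


@njit(cache=True)
def _coil_rates_nb(F: float, p: np.ndarray) -> tuple[float, float]:
    """Bell-model uncoiling/recoiling rates at tension F (may be negative)."""
    kBT = p[PM_KBT]
    eab = F * p[PM_XAB] / kBT
    eba = -F * p[PM_XBA] / kBT
    if eab > _EXP_CAP:
        eab = _EXP_CAP
    if eba > _EXP_CAP:
        eba = _EXP_CAP
    return p[PM_K0AB] * math.exp(eab), p[PM_K0BA] * math.exp(eba)


@njit(cache=True)
def _stretch_fraction_nb(F: float, p: np.ndarray) -> float:
    """Equilibrium fraction of uncoiled subunits in the stretched C state."""
    if F < 0.0:
        F = 0.0
    e = F * p[PM_XEQ] / p[PM_KBT]
    if e > _EXP_CAP:
        e = _EXP_CAP
    K = p[PM_KEQ] * math.exp(e)
    return K / (1.0 + K)


@njit(cache=True)
def _length_at_tension_nb(F: float, nA: float, nB: float, nC: float,
                          p: np.ndarray) -> float:
    """Total end-to-end length at tension F (counts may be fractional)."""
    L = 0.0
    if nA > 0.0:
        # series spring: segment stiffness k_coil/nA
        L += nA * p[PM_RISE_A] + F * nA / p[PM_KCOIL]
    if F > 0.0:
        if nB > 0.0:
            L += nB * p[PM_X0B] * _wlc_frac_at_force_nb(F, p[PM_LPB], p[PM_KBT])
        if nC > 0.0:
            L += nC * p[PM_X0C] * _wlc_frac_at_force_nb(F, p[PM_LPC], p[PM_KBT])
    return L


@njit(cache=True)
def _dlength_dtension_nb(F: float, nA: float, nB: float, nC: float,
                         p: np.ndarray) -> float:
    """Compliance dL/dF at tension F > 0 (used for stiffness estimates)."""
    c = 0.0
    if nA > 0.0:
        c += nA / p[PM_KCOIL]
    if F > 0.0:
        if nB > 0.0:
            x = _wlc_frac_at_force_nb(F, p[PM_LPB], p[PM_KBT])
            c += nB * p[PM_X0B] / _wlc_dforce_nb(x, p[PM_LPB], p[PM_KBT])
        if nC > 0.0:
            x = _wlc_frac_at_force_nb(F, p[PM_LPC], p[PM_KBT])
            c += nC * p[PM_X0C] / _wlc_dforce_nb(x, p[PM_LPC], p[PM_KBT])
    return c


@njit(cache=True)
def _tension_from_length_nb(ext: float, nA: float, nB: float, nC: float,
                            p: np.ndarray, F0: float = 1.0) -> float:
    """Invert the monotone length-tension map; clamps at -buckling_force.

    Safeguarded Newton iteration warm-started at ``F0`` (callers pass the
    previous step's tension).  If no A segment exists and the extension
    exceeds the WLC contour the tension saturates at a large cap (the
    caller treats this as an immediately rupturing overload).
    """
    fbuck = p[PM_FBUCK]
    natural = nA * p[PM_RISE_A]
    if nA > 0.0 and ext <= natural:
        T = (ext - natural) * p[PM_KCOIL] / nA
        if T < -fbuck:
            T = -fbuck
        return T
    if nA <= 0.0:
        contour = nB * p[PM_X0B] + nC * p[PM_X0C]
        if ext <= 0.0:
            return 0.0
        if ext >= contour:
            return _TENSION_CAP
    lo = 0.0
    hi = -1.0          # upper bracket unknown until a sign change is seen
    F = F0
    if F < 1e-6:
        F = 1e-6
    for _ in range(120):
        L = _length_at_tension_nb(F, nA, nB, nC, p)
        err = L - ext
        if abs(err) < 1e-5 * (1.0 + 1e-3 * abs(ext)):
            return F
        if err < 0.0:
            if F > lo:
                lo = F
        else:
            if hi < 0.0 or F < hi:
                hi = F
        dLdF = _dlength_dtension_nb(F, nA, nB, nC, p)
        if dLdF <= 0.0:
            Fn = -1.0
        else:
            Fn = F - err / dLdF
        if hi > 0.0:
            if Fn <= lo or Fn >= hi:
                Fn = 0.5 * (lo + hi)
            if hi - lo < 1e-12 * (1.0 + hi):
                return 0.5 * (lo + hi)
        else:
            if Fn <= lo or Fn > 4.0 * F + 64.0:
                Fn = 2.0 * F + 64.0
        if Fn >= _TENSION_CAP:
            return _TENSION_CAP
        F = Fn
    return F


@njit(cache=True)
def _length_partition_nb(F: float, nA: float, n_unc: float,
                         p: np.ndarray) -> float:
    """Length at tension F with the B/C split at its instantaneous
    equilibrium phi(F)."""
    phi = _stretch_fraction_nb(F, p)
    return _length_at_tension_nb(F, nA, (1.0 - phi) * n_unc,
                                 phi * n_unc, p)


@njit(cache=True)
def _dlength_partition_nb(F: float, nA: float, n_unc: float,
                          p: np.ndarray) -> float:
    """dL/dF including the partition shift d(phi)/dF (always >= 0)."""
    phi = _stretch_fraction_nb(F, p)
    c = _dlength_dtension_nb(F, nA, (1.0 - phi) * n_unc, phi * n_unc, p)
    if F > 0.0 and n_unc > 0.0:
        dphi = phi * (1.0 - phi) * p[PM_XEQ] / p[PM_KBT]
        xiB = _wlc_frac_at_force_nb(F, p[PM_LPB], p[PM_KBT])
        xiC = _wlc_frac_at_force_nb(F, p[PM_LPC], p[PM_KBT])
        c += n_unc * dphi * (p[PM_X0C] * xiC - p[PM_X0B] * xiB)
    return c


@njit(cache=True)
def _length_compliance_partition_nb(F: float, nA: float, n_unc: float,
                                    p: np.ndarray):
    """(L, dL/dF) at tension F with the equilibrium B/C split, computing
    each WLC inversion once."""
    L = 0.0
    c = 0.0
    if nA > 0.0:
        L += nA * p[PM_RISE_A] + F * nA / p[PM_KCOIL]
        c += nA / p[PM_KCOIL]
    if F > 0.0 and n_unc > 0.0:
        kBT = p[PM_KBT]
        phi = _stretch_fraction_nb(F, p)
        xiB = _wlc_frac_at_force_nb(F, p[PM_LPB], kBT)
        xiC = _wlc_frac_at_force_nb(F, p[PM_LPC], kBT)
        nB = (1.0 - phi) * n_unc
        nC = phi * n_unc
        L += nB * p[PM_X0B] * xiB + nC * p[PM_X0C] * xiC
        c += nB * p[PM_X0B] / _wlc_dforce_nb(xiB, p[PM_LPB], kBT)
        c += nC * p[PM_X0C] / _wlc_dforce_nb(xiC, p[PM_LPC], kBT)
        dphi = phi * (1.0 - phi) * p[PM_XEQ] / kBT
        c += n_unc * dphi * (p[PM_X0C] * xiC - p[PM_X0B] * xiB)
    return L, c


@njit(cache=True)
def _tension_partition_nb(ext: float, nA: float, n_unc: float,
                          p: np.ndarray, F0: float = 1.0) -> float:
    """Tension at a prescribed length with the B/C split in instantaneous
    equilibrium: inverts the monotone map L(F, phi(F)).

    The joint solve avoids the fixed-point oscillation a naive
    solve-then-repartition iteration exhibits across the stretch
    transition.  Clamps at -buckling_force; saturates at the tension cap
    when a fully uncoiled fimbria is stretched past its contour.
    """
    fbuck = p[PM_FBUCK]
    natural = nA * p[PM_RISE_A]
    if nA > 0.0 and ext <= natural:
        T = (ext - natural) * p[PM_KCOIL] / nA
        if T < -fbuck:
            T = -fbuck
        return T
    if nA <= 0.0:
        if ext <= 0.0:
            return 0.0
        if ext >= n_unc * p[PM_X0C]:
            return _TENSION_CAP
    lo = 0.0
    hi = -1.0
    F = F0
    if F < 1e-6:
        F = 1e-6
    for _ in range(120):
        L, dLdF = _length_compliance_partition_nb(F, nA, n_unc, p)
        err = L - ext
        if abs(err) < 1e-5 * (1.0 + 1e-3 * abs(ext)):
            return F
        if err < 0.0:
            if F > lo:
                lo = F
        else:
            if hi < 0.0 or F < hi:
                hi = F
        if dLdF <= 0.0:
            Fn = -1.0
        else:
            Fn = F - err / dLdF
        if hi > 0.0:
            if Fn <= lo or Fn >= hi:
                Fn = 0.5 * (lo + hi)
            if hi - lo < 1e-12 * (1.0 + hi):
                return 0.5 * (lo + hi)
        else:
            if Fn <= lo or Fn > 4.0 * F + 64.0:
                Fn = 2.0 * F + 64.0
        if Fn >= _TENSION_CAP:
            return _TENSION_CAP
        F = Fn
    return F


@njit(cache=True)
def _meanfield_pull_nb(p: np.ndarray, n_sub: float, speed: float,
                       x_max: float, retract: bool, n_out: int,
                       ext_out: np.ndarray, force_out: np.ndarray) -> int:
    """Deterministic (rate-equation) constant-speed pull of one fimbria.

    Extension ramps 0 -> x_max, then back to 0 if ``retract``.  The A count
    evolves by the net Bell rate; the B/C split is the instantaneous
    equilibrium, solved jointly with the tension.  Returns the number of
    samples written.
    """
    total_t = x_max / speed * (2.0 if retract else 1.0)
    dt = total_t / (n_out - 1)
    nA = n_sub
    if p[PM_MODE] == 2.0:
        nA = 0.0
    F = 0.0
    k = 0
    for istep in range(n_out):
        t = istep * dt
        ext = speed * t
        if retract and ext > x_max:
            ext = 2.0 * x_max - ext
        if ext < 0.0:
            ext = 0.0
        F = _tension_partition_nb(ext, nA, n_sub - nA, p,
                                  F if F > 1.0 else 1.0)
        ext_out[k] = ext
        force_out[k] = F
        k += 1
        if p[PM_MODE] == 0.0:
            # relax the coil count by the net Bell flux over dt
            kab, kba = _coil_rates_nb(F, p)
            m = int((kab + kba) * dt / 0.05) + 1
            if m > 4000:
                m = 4000
            h = dt / m
            for _ in range(m):
                kab, kba = _coil_rates_nb(F, p)
                nA -= (kab - kba) * h
                if nA < 0.0:
                    nA = 0.0
                elif nA > n_sub:
                    nA = n_sub
                F = _tension_partition_nb(ext, nA, n_sub - nA, p,
                                          F if F > 1.0 else 1.0)
    return k


# ---------------------------------------------------------------------------
# public, validated operations
# ---------------------------------------------------------------------------

def wlc_force(fractional_extension: float, persistence_length: float,
              kBT: float = 4.1) -> float:
    """Marko-Siggia worm-like-chain tension at a fractional extension.

    Raises ``ValueError`` for fractional extension outside ``[0, 1)`` --
    a WLC cannot be stretched to or beyond its contour length.
    """
    x = float(fractional_extension)
    if not 0.0 <= x < 1.0:
        raise ValueError(f"fractional extension must be in [0, 1), got {x}")
    if persistence_length <= 0 or kBT <= 0:
        raise ValueError("persistence_length and kBT must be positive")
    return _wlc_force_nb(x, persistence_length, kBT)


def extension_at_tension(F: float, state: FimbriaState,
                         params: FimbriaParams) -> float:
    """Total fimbrial length (nm) at tension ``F``: A spring + B/C WLCs."""
    if F <= -params.buckling_force:
        raise ValueError("tension at or below the buckling clamp")
    return _length_at_tension_nb(float(F), float(state.n_A), float(state.n_B),
                                 float(state.n_C), params.as_array())


def tension_from_extension(total_extension: float, state: FimbriaState,
                           params: FimbriaParams) -> float:
    """Tension (pN) at a prescribed end-to-end length.

    Compressive configurations return negative tension clamped at
    ``-buckling_force``.  If the fimbria is fully uncoiled (no A segment)
    an extension at or beyond the WLC contour has no finite solution and
    raises ``ValueError``.
    """
    ext = float(total_extension)
    if state.n_A == 0:
        contour = state.n_B * params.x0_B + state.n_C * params.x0_C
        if ext >= contour:
            raise ValueError(
                f"extension {ext:.3g} nm >= contour {contour:.3g} nm of a "
                "fully uncoiled fimbria: unphysical configuration")
    return _tension_from_length_nb(ext, float(state.n_A), float(state.n_B),
                                   float(state.n_C), params.as_array())


def coil_transition_rates(F: float, params: FimbriaParams) -> tuple[float, float]:
    """Bell-model (uncoiling, recoiling) rates at tension ``F``."""
    if not math.isfinite(F):
        raise ValueError("force must be finite")
    return _coil_rates_nb(float(F), params.as_array())


def equilibrium_uncoiling_force(params: FimbriaParams) -> float:
    """Force at which uncoiling and recoiling rates cross.

    ``F_eq = kBT * ln(k0_BA / k0_AB) / (x_AB + x_BA)``.  Requires the coiled
    state to be favoured at zero force (``k0_BA > k0_AB``).
    """
    if params.k0_BA < params.k0_AB:
        raise ValueError("no positive equilibrium force: the coiled state "
                         "must be favoured at zero force (k0_BA >= k0_AB)")
    return params.kBT * math.log(params.k0_BA / params.k0_AB) / (
        params.x_AB + params.x_BA)


def step_coiling(state: FimbriaState, F: float, dt: float,
                 rng: np.random.Generator,
                 params: FimbriaParams | None = None) -> FimbriaState:
    """One stochastic edge-transition step of the cooperative uncoiling.

    At most one uncoiling (A->B) and one recoiling (B->A) event occurs per
    call, both at the single A/B boundary of the helical coil.  ``params``
    must be in yielding mode.  The caller is responsible for keeping
    ``dt * max(rate)`` small (<= 0.1); the engine sub-steps automatically.
    """
    if params is None:
        params = FimbriaParams()
    if params.mode != "yielding":
        raise ValueError("coiling transitions only occur in yielding mode")
    if dt < 0:
        raise ValueError("dt must be >= 0")
    kab, kba = _coil_rates_nb(float(F), params.as_array())
    nA, nB, nC = state.n_A, state.n_B, state.n_C
    if nA > 0 and rng.random() < -math.expm1(-kab * dt):
        nA -= 1
        nB += 1
    if nA < state.n_total and (nB + nC) >= 1 and \
            rng.random() < -math.expm1(-kba * dt):
        nA += 1
        if nB >= 1:
            nB -= 1
        else:
            nC -= 1
    return FimbriaState(n_A=nA, n_B=nB, n_C=nC,
                        current_tension=state.current_tension)


def stretch_partition(F: float, params: FimbriaParams) -> float:
    """Equilibrium fraction of uncoiled subunits in the stretched C state.

    ``K(F) = k_eq * exp(F * x_eq / kBT)``; the fraction is ``K/(1+K)``.
    """
    if F < 0:
        raise ValueError("stretch partition is defined for tensile force only")
    return _stretch_fraction_nb(float(F), params.as_array())


def apply_stretch_partition(state: FimbriaState, F: float,
                            params: FimbriaParams) -> FimbriaState:
    """Re-partition the uncoiled pool between B and C at tension ``F``.

    Rounding is half-to-even (unbiased).
    """
    n_unc = state.n_B + state.n_C
    n_C = int(np.rint(stretch_partition(F, params) * n_unc))
    return FimbriaState(n_A=state.n_A, n_B=n_unc - n_C, n_C=n_C,
                        current_tension=state.current_tension)


def meanfield_pull_curve(params: FimbriaParams, pull_speed: float,
                         x_max: float | None = None, retract: bool = False,
                         n_points: int = 2000):
    """Deterministic constant-speed pull (rate-equation limit).

    Returns ``(extension_nm, force_pN)`` arrays sampled along the schedule.
    ``pull_speed`` is in nm/s.  ``x_max`` defaults to 97% of the fully
    stretched contour, which places the end of the S-curve near 150 pN for
    the default parameters.
    """
    if pull_speed <= 0:
        raise ValueError("pull_speed must be > 0")
    if x_max is None:
        x_max = 0.97 * params.n_subunits * params.x0_C
    ext = np.empty(n_points)
    frc = np.empty(n_points)
    k = _meanfield_pull_nb(params.as_array(), float(params.n_subunits),
                           float(pull_speed), float(x_max), bool(retract),
                           n_points, ext, frc)
    return ext[:k], frc[:k]


def force_extension_curve(params: FimbriaParams, mode: str | None = None,
                          pull_speed: float = 1000.0):
    """Extension-phase force-extension curve at a constant pull speed.

    Computed in the deterministic mean-field limit of the coiling kinetics
    (the stochastic counterpart lives in :mod:`fimsim.afm_fit`).  Yielding
    mode shows linear rise, a flat cooperative plateau, then the S-shaped
    stretch region; linear mode is Hookean; strain-hardening mode is a
    single WLC with contour ``n_subunits * x0_B``.

    Returns a list of ``(extension_nm, tension_pN)`` pairs.
    """
    if mode is not None and mode != params.mode:
        params = replace(params, mode=mode)
    if params.mode == "linear":
        k = params.k_coil / params.n_subunits
        L0 = params.n_subunits * params.rise_A
        # straight line out to 150 pN
        ext = np.linspace(0.0, L0 + 150.0 / k, 400)
        frc = np.maximum((ext - L0) * k, -params.buckling_force)
        return list(zip(ext.tolist(), frc.tolist()))
    if params.mode == "strain_hardening":
        Lc = params.n_subunits * params.x0_B
        xs = np.linspace(0.0, 0.985, 400)
        frc = [(x * Lc, _wlc_force_nb(x, params.l_pB, params.kBT)) for x in xs]
        return frc
    ext, frc = meanfield_pull_curve(params, pull_speed)
    return list(zip(ext.tolist(), frc.tolist()))
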