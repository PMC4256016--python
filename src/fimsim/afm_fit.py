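"""Single-fimbria constant-speed force spectroscopy: simulation, feature
extraction, and parameter fitting.

A surface-anchored fimbria is pulled through a soft cantilever (series
spring) at constant speed through a back-and-forth waypoint schedule.
During extension the force rises linearly, then plateaus as the helix
uncoils cooperatively; the plateau force rises with pull speed (Bell
kinetics) and exceeds the retraction plateau (hysteresis).  Once fully
uncoiled, extension and retraction collapse onto a single S-shaped
worm-like-chain curve ending near 150 pN.

The fitting operations invert this phenomenology: the speed-dependence of
the extension/retraction plateau forces identifies the coiling kinetics
``(x_AB, x_BA, k0_AB, k0_BA)``; the post-plateau S-curve identifies the
WLC/stretch parameters ``(k_eq, x_eq, l_pB, l_pC, x0_B, x0_C)``.  Fitting
uses the deterministic mean-field limit of the coiling kinetics, which
agrees with the stochastic plateaus to within a piconewton.

Units: nm, pN, s; pull speeds are quoted in um/s as in the protocols.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq, least_squares

from . import _kernel
from .fimbria_mechanics import (
    FimbriaParams,
    PM_RISE_A, PM_X0B, PM_X0C, PM_LPB, PM_LPC, PM_KCOIL, PM_MODE, PM_FBUCK,
    PM_KBT,
    _coil_rates_nb, _stretch_fraction_nb, _length_at_tension_nb,
    _dlength_dtension_nb, _length_partition_nb, _dlength_partition_nb,
    _wlc_frac_at_force_nb,
    equilibrium_uncoiling_force,
)

__all__ = [
    "PullProtocol",
    "PullTrace",
    "PlateauNotFoundError",
    "simulate_pull",
    "extract_plateau",
    "predict_plateau_force",
    "fit_uncoiling_params",
    "fit_stretch_params",
    "generate_synthetic_afm_dataset",
]

DEFAULT_SPEEDS_UM_S = (0.1, 1.0, 3.0, 10.0)


class PlateauNotFoundError(RuntimeError):
    """Raised when a trace has no constant-force uncoiling region
    (e.g. linear or strain-hardening tethers)."""


@dataclass
class PullProtocol:
    """Constant-speed back-and-forth pull schedule."""

    speed: float = 1.0                   # um/s
    waypoints: tuple = ()                # extensions (nm); default 0 -> x_max -> 0
    cantilever_stiffness: float = 6.0    # pN/nm (soft-lever regime)
    noise_sd: float = 0.0                # pN, added to synthetic traces

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be > 0")
        if self.cantilever_stiffness <= 0:
            raise ValueError("cantilever_stiffness must be > 0")

    def resolved_waypoints(self, params: FimbriaParams) -> np.ndarray:
        if self.waypoints:
            w = np.asarray(self.waypoints, dtype=float)
        else:
            x_max = 0.97 * params.n_subunits * params.x0_C
            w = np.array([0.0, x_max, 0.0])
        contour = params.n_subunits * params.x0_C
        if np.any(w < 0) or np.any(w > contour):
            raise ValueError("waypoints outside the physical extension range")
        return w


@dataclass
class PullTrace:
    """Recorded (time, extension, force) series of one pull."""

    time: np.ndarray          # s
    extension: np.ndarray     # nm (fimbria end-to-end)
    force: np.ndarray         # pN (cantilever force)
    speed: float = 1.0        # um/s
    meta: dict = field(default_factory=dict)

    def phase_slice(self, phase: str) -> slice:
        """Index slice of the extension or retraction phase."""
        i_max = int(np.argmax(self.extension))
        if phase == "extension":
            return slice(0, i_max + 1)
        if phase == "retraction":
            return slice(i_max, len(self.extension))
        raise ValueError("phase must be 'extension' or 'retraction'")


@njit(cache=True)
def _series_tension_partition(z, nA, n_unc, pm, kc, T0):
    """Series cantilever + fimbria tension with the B/C split at its
    instantaneous equilibrium: solves L(T, phi(T)) + T/kc = z."""
    fbuck = pm[PM_FBUCK]
    T = T0
    lo = -fbuck
    hi = 0.0
    have_hi = False
    for _ in range(80):
        g = _length_partition_nb(T, nA, n_unc, pm) + T / kc - z
        if abs(g) < 1e-6 * (1.0 + abs(z)):
            return T
        if g < 0.0:
            if T > lo:
                lo = T
        else:
            if (not have_hi) or T < hi:
                hi = T
                have_hi = True
        dg = _dlength_partition_nb(T, nA, n_unc, pm) + 1.0 / kc
        Tn = T - g / dg
        if have_hi:
            if Tn <= lo or Tn >= hi:
                Tn = 0.5 * (lo + hi)
            if hi - lo < 1e-12 * (1.0 + abs(hi)):
                return 0.5 * (lo + hi)
        else:
            if Tn < lo:
                Tn = lo
            elif Tn > 4.0 * abs(T) + 64.0:
                Tn = 4.0 * abs(T) + 64.0
        T = Tn
    return T


@njit(cache=True)
def _series_tension(z, nA, nB, nC, pm, kc, T0):
    """Tension of the fimbria + cantilever series at stage position z.

    Solves the monotone equation L(T) + T/kc = z by safeguarded Newton,
    warm-started at T0; clamps at the compressive buckling force.
    """
    fbuck = pm[PM_FBUCK]
    T = T0
    lo = -fbuck
    hi = 0.0
    have_hi = False
    for _ in range(80):
        g = _length_at_tension_nb(T, nA, nB, nC, pm) + T / kc - z
        if abs(g) < 1e-6 * (1.0 + abs(z)):
            return T
        if g < 0.0:
            if T > lo:
                lo = T
        else:
            if (not have_hi) or T < hi:
                hi = T
                have_hi = True
        dg = _dlength_dtension_nb(T, nA, nB, nC, pm) + 1.0 / kc
        Tn = T - g / dg
        if have_hi:
            if Tn <= lo or Tn >= hi:
                Tn = 0.5 * (lo + hi)
            if hi - lo < 1e-12 * (1.0 + abs(hi)):
                return 0.5 * (lo + hi)
        else:
            if Tn < lo:
                Tn = lo
            elif Tn > 4.0 * abs(T) + 64.0:
                Tn = 4.0 * abs(T) + 64.0
        T = Tn
    return T


@njit(cache=True)
def _pull_kernel(pm, n_sub, kc, speed_nm_s, waypoints, dt, stride,
                 out_t, out_x, out_F, out_nA):
    """Stochastic constant-speed pull through a series cantilever.

    The stage position z(t) tracks the waypoint schedule; at each step the
    tension solves the series system L(T) + T/kc = z (monotone; Newton).
    Coiling uses the same edge-event sampling as the whole-cell kernel.
    """
    nA = int(n_sub)
    nB = 0
    nC = 0
    if pm[PM_MODE] == 2.0:
        nA = 0
        nB = int(n_sub)
    # total schedule time
    total = 0.0
    for w in range(waypoints.shape[0] - 1):
        total += abs(waypoints[w + 1] - waypoints[w]) / speed_nm_s
    n_steps = int(total / dt) + 1
    k = 0
    T_prev = 0.0
    for istep in range(n_steps):
        t = istep * dt
        # piecewise-linear stage position
        trem = t
        z = waypoints[0]
        for w in range(waypoints.shape[0] - 1):
            seg = abs(waypoints[w + 1] - waypoints[w]) / speed_nm_s
            if trem <= seg:
                if waypoints[w + 1] >= waypoints[w]:
                    z = waypoints[w] + speed_nm_s * trem
                else:
                    z = waypoints[w] - speed_nm_s * trem
                break
            trem -= seg
            z = waypoints[w + 1]
        if pm[PM_MODE] == 0.0:
            T = _series_tension_partition(z, float(nA), float(nB + nC), pm,
                                          kc, T_prev)
        else:
            T = _series_tension(z, float(nA), float(nB), float(nC), pm, kc,
                                T_prev)
        T_prev = T
        x = z - T / kc
        F = T if T > 0.0 else 0.0
        if istep % stride == 0 and k < out_t.shape[0]:
            out_t[k] = t
            out_x[k] = x
            out_F[k] = F
            out_nA[k] = nA
            k += 1
        # coiling kinetics (yielding only)
        if pm[PM_MODE] == 0.0:
            kab, kba = _coil_rates_nb(F, pm)
            m = int((kab + kba) * dt / 0.1) + 1
            if m > 500:
                m = 500
            h = dt / m
            for _ in range(m):
                if m > 1:
                    T = _series_tension_partition(z, float(nA),
                                                  float(nB + nC), pm, kc, T)
                    kab, kba = _coil_rates_nb(T if T > 0.0 else 0.0, pm)
                if nA > 0 and np.random.random() < -math.expm1(-kab * h):
                    nA -= 1
                    nB += 1
                if nA < int(n_sub) and (nB + nC) > 0 and \
                        np.random.random() < -math.expm1(-kba * h):
                    nA += 1
                    if nB > 0:
                        nB -= 1
                    else:
                        nC -= 1
            n_unc = nB + nC
            if n_unc > 0:
                phi = _stretch_fraction_nb(F, pm)
                nC = int(np.rint(phi * n_unc))
                nB = n_unc - nC
            T_prev = _series_tension_partition(z, float(nA), float(n_unc),
                                               pm, kc, T_prev)
    return k


def simulate_pull(params: FimbriaParams, protocol: PullProtocol,
                  rng: np.random.Generator | None = None,
                  dt: float = 2.0e-5, n_record: int = 6000) -> PullTrace:
    """Stochastic constant-speed pull; returns the recorded trace."""
    if rng is None:
        rng = np.random.default_rng()
    _kernel.seed_kernel_rng(int(rng.integers(2 ** 31)))
    w = protocol.resolved_waypoints(params)
    speed_nm_s = protocol.speed * 1000.0
    total = float(np.sum(np.abs(np.diff(w)))) / speed_nm_s
    n_steps = int(total / dt) + 1
    stride = max(1, n_steps // n_record)
    cap = n_steps // stride + 2
    out_t = np.zeros(cap)
    out_x = np.zeros(cap)
    out_F = np.zeros(cap)
    out_nA = np.zeros(cap, dtype=np.int64)
    k = _pull_kernel(params.as_array(), float(params.n_subunits),
                     protocol.cantilever_stiffness, speed_nm_s, w, dt,
                     stride, out_t, out_x, out_F, out_nA)
    force = out_F[:k]
    if protocol.noise_sd > 0:
        force = force + rng.normal(0.0, protocol.noise_sd, size=k)
    return PullTrace(time=out_t[:k], extension=out_x[:k], force=force,
                     speed=protocol.speed,
                     meta={"n_coiled": out_nA[:k],
                           "cantilever_stiffness": protocol.cantilever_stiffness})


def _phase_xy(trace: PullTrace, phase: str):
    sl = trace.phase_slice(phase)
    x = trace.extension[sl]
    F = trace.force[sl]
    if phase == "retraction":
        x = x[::-1]
        F = F[::-1]
    return x, F


def extract_plateau(trace: PullTrace, phase: str = "extension",
                    window_nm: float = 50.0,
                    band_fraction: float = 0.05,
                    band_min_pN: float = 2.0,
                    min_length_nm: float = 2000.0) -> float:
    """Mean force over the central 60% of the constant-force region.

    The plateau is the force level whose narrow band (+-max(2 pN, 5%))
    contains the longest contiguous stretch of extension; it must span at
    least ``min_length_nm`` and sit above 5 pN.  Long flat regions only
    arise from cooperative uncoiling, so linear traces (constant slope)
    and strain-hardening traces (monotone WLC) correctly raise
    :class:`PlateauNotFoundError`.
    """
    x, F = _phase_xy(trace, phase)
    if len(x) < 10:
        raise PlateauNotFoundError("trace too short")
    order = np.argsort(x, kind="stable")
    xs, Fs = x[order], F[order]
    dx = window_nm / 5.0
    grid = np.arange(xs[0], xs[-1], dx)
    if len(grid) < 20:
        raise PlateauNotFoundError("extension range too short")
    Fg = np.interp(grid, xs, Fs)
    w = 5
    Fsm = np.convolve(Fg, np.ones(w) / w, mode="same")

    def longest_run(mask):
        best_len, best_start, run = 0, -1, None
        for i, m in enumerate(np.append(mask, False)):
            if m and run is None:
                run = i
            elif not m and run is not None:
                if i - run > best_len:
                    best_len, best_start = i - run, run
                run = None
        return best_len, best_start

    best = (0, -1, np.nan)
    for level in np.percentile(Fsm, np.arange(5, 96, 2.5)):
        if level < 5.0:
            continue
        band = max(band_min_pN, band_fraction * level)
        n, i0 = longest_run(np.abs(Fsm - level) < band)
        if n > best[0]:
            best = (n, i0, level)
    n, i0, _level = best
    if i0 < 0 or n * dx < min_length_nm:
        raise PlateauNotFoundError("no constant-force region detected")
    lo = grid[i0]
    hi = grid[i0 + n - 1]
    span = hi - lo
    sel = (grid >= lo + 0.2 * span) & (grid <= hi - 0.2 * span)
    return float(Fg[sel].mean())


# ---------------------------------------------------------------------------
# mean-field plateau prediction and fitting
# ---------------------------------------------------------------------------

def _uncoil_length_gain(F: float, p: np.ndarray) -> float:
    """Length released per uncoiled subunit at tension F (nm)."""
    phi = _stretch_fraction_nb(F, p)
    kBT = p[PM_KBT]
    s_unc = ((1.0 - phi) * p[PM_X0B] * _wlc_frac_at_force_nb(F, p[PM_LPB], kBT)
             + phi * p[PM_X0C] * _wlc_frac_at_force_nb(F, p[PM_LPC], kBT))
    s_coil = p[PM_RISE_A] * (1.0 + F / p[PM_KCOIL])
    return s_unc - s_coil


def predict_plateau_force(speed_um_s: float, phase: str,
                          params: FimbriaParams) -> float:
    """Mean-field dynamic plateau force at a given pull speed.

    At the plateau the net (un)coiling flux carries exactly the imposed
    length rate: ``(k_AB - k_BA)(F) * dL(F) = v`` during extension and the
    reverse during retraction.
    """
    p = params.as_array()
    v = speed_um_s * 1000.0
    feq = equilibrium_uncoiling_force(params)

    def net_ext(F):
        kab, kba = _coil_rates_nb(F, p)
        return (kab - kba) * max(_uncoil_length_gain(F, p), 1e-9) - v

    def ret_flux(F):
        kab, kba = _coil_rates_nb(F, p)
        return (kba - kab) * max(_uncoil_length_gain(F, p), 1e-9)

    if phase == "extension":
        lo, hi = feq + 1e-9, 400.0
        if net_ext(hi) < 0:
            return hi
        return float(brentq(net_ext, lo, hi, xtol=1e-6))
    if phase == "retraction":
        # the recoil flux vanishes both at F -> 0 (no length released per
        # event) and at F_eq (no net recoil); the plateau is the largest
        # force where the flux matches the pull speed
        grid = np.linspace(1e-3, feq - 1e-9, 400)
        flux = np.array([ret_flux(F) for F in grid])
        i_max = int(np.argmax(flux))
        if flux[i_max] < v:
            raise PlateauNotFoundError(
                f"recoil cannot keep up with a {speed_um_s} um/s retraction")
        above = np.nonzero(flux[i_max:] >= v)[0] + i_max
        i_hi = int(above[-1])
        if i_hi >= len(grid) - 1:
            return float(grid[-1])
        return float(brentq(lambda F: ret_flux(F) - v,
                            grid[i_hi], grid[i_hi + 1], xtol=1e-6))
    raise ValueError("phase must be 'extension' or 'retraction'")


def fit_uncoiling_params(plateau_table: pd.DataFrame,
                         params: FimbriaParams | None = None) -> dict:
    """Fit the coiling kinetics to plateau forces across speeds and phases.

    ``plateau_table`` needs columns ``speed_um_s``, ``phase``
    (extension/retraction), ``force_pN``.  The WLC/geometry parameters of
    ``params`` are held fixed; only ``(x_AB, x_BA, k0_AB, k0_BA)`` move
    (rates in log space).  Returns the fitted parameters plus diagnostics.
    """
    if params is None:
        params = FimbriaParams()
    speeds = plateau_table["speed_um_s"].unique()
    phases = set(plateau_table["phase"])
    if len(speeds) < 2 or phases != {"extension", "retraction"}:
        raise ValueError("need plateau forces at >= 2 speeds for both the "
                         "extension and retraction phases to identify the "
                         "coiling kinetics")

    rows = list(plateau_table.itertuples(index=False))

    def residuals(theta):
        xab, xba, lkab, lkba = theta
        trial = FimbriaParams(
            n_subunits=params.n_subunits, rise_A=params.rise_A,
            k_coil=params.k_coil, x0_B=params.x0_B, x0_C=params.x0_C,
            l_pB=params.l_pB, l_pC=params.l_pC,
            x_AB=max(xab, 1e-3), x_BA=max(xba, 1e-3),
            k0_AB=10.0 ** lkab, k0_BA=10.0 ** lkba,
            k_eq=params.k_eq, x_eq=params.x_eq, kBT=params.kBT)
        res = []
        for r in rows:
            try:
                pred = predict_plateau_force(r.speed_um_s, r.phase, trial)
            except Exception:
                pred = 1e3
            res.append(pred - r.force_pN)
        return np.asarray(res)

    # generic starting point: symmetric transition distances, rates from the
    # apparent equilibrium force (midway between the slowest two plateaus)
    f_slow = plateau_table.groupby("phase")["force_pN"].min()
    feq0 = 0.5 * (f_slow.get("extension", 40.0) + plateau_table[
        plateau_table.phase == "retraction"]["force_pN"].max())
    x0 = 0.4
    k0ab0 = 10.0
    lkba0 = math.log10(k0ab0) + feq0 * (2 * x0) / params.kBT / math.log(10)
    theta0 = np.array([x0, x0, math.log10(k0ab0), lkba0])
    fit = least_squares(residuals, theta0,
                        bounds=([0.01, 0.01, -4.0, -4.0],
                                [3.0, 3.0, 6.0, 8.0]),
                        xtol=1e-12, ftol=1e-12)
    xab, xba, lkab, lkba = fit.x
    return {
        "x_AB": float(xab), "x_BA": float(xba),
        "k0_AB": float(10.0 ** lkab), "k0_BA": float(10.0 ** lkba),
        "residuals": fit.fun, "cost": float(fit.cost),
        "success": bool(fit.success),
    }


def _scurve_model(F, keq, xeq, lpB, lpC, x0B, x0C, kBT):
    """Per-subunit extension of a fully uncoiled fimbria at tension F."""
    F = np.asarray(F, dtype=float)
    K = keq * np.exp(np.minimum(F * xeq / kBT, 60.0))
    phi = K / (1.0 + K)
    xiB = np.array([_wlc_frac_at_force_nb(f, lpB, kBT) for f in F])
    xiC = np.array([_wlc_frac_at_force_nb(f, lpC, kBT) for f in F])
    return (1.0 - phi) * x0B * xiB + phi * x0C * xiC


def fit_stretch_params(s_curve_table: pd.DataFrame,
                       n_subunits: int, kBT: float = 4.1) -> dict:
    """Fit the uncoiled-state WLC and stretch-transition parameters.

    ``s_curve_table`` needs columns ``force_pN`` and ``extension_nm``
    (absolute end-to-end extension of the fully uncoiled fimbria);
    ``n_subunits`` converts to per-subunit extension, making all six of
    ``(k_eq, x_eq, l_pB, l_pC, x0_B, x0_C)`` identifiable.
    """
    tbl = s_curve_table.sort_values("force_pN")
    F = tbl["force_pN"].to_numpy(dtype=float)
    s = tbl["extension_nm"].to_numpy(dtype=float) / n_subunits
    if len(F) < 6:
        raise ValueError("need >= 6 points spanning the post-plateau range")

    def residuals(theta):
        lkeq, xeq, lpB, lpC, x0B, x0C = theta
        return _scurve_model(F, 10.0 ** lkeq, xeq, lpB, lpC, x0B, x0C,
                             kBT) - s

    # initialization: single-WLC fits to the low- and high-force thirds
    n3 = max(len(F) // 3, 3)
    sB = s[:n3].max()
    sC = s[-n3:].max()
    x0B0 = sB / max(_wlc_frac_at_force_nb(float(F[:n3].max()), 3.0, kBT), 0.3)
    x0C0 = sC / max(_wlc_frac_at_force_nb(float(F.max()), 6.0, kBT), 0.5)
    x0C0 = max(x0C0, x0B0 * 1.05)
    Fm = float(np.median(F))
    theta0 = np.array([-Fm * 0.3 / kBT / math.log(10), 0.3, 3.0, 6.0,
                       x0B0, x0C0])
    fit = least_squares(
        residuals, theta0,
        bounds=([-8.0, 0.01, 0.3, 0.3, 0.5, 0.5],
                [0.0, 2.0, 50.0, 50.0, 20.0, 25.0]),
        xtol=1e-13, ftol=1e-13)
    lkeq, xeq, lpB, lpC, x0B, x0C = fit.x
    return {
        "k_eq": float(10.0 ** lkeq), "x_eq": float(xeq),
        "l_pB": float(lpB), "l_pC": float(lpC),
        "x0_B": float(x0B), "x0_C": float(x0C),
        "residuals": fit.fun, "cost": float(fit.cost),
        "success": bool(fit.success),
    }


def generate_synthetic_afm_dataset(params: FimbriaParams | None = None,
                                   speeds=DEFAULT_SPEEDS_UM_S,
                                   noise_sd: float = 0.0,
                                   rng: np.random.Generator | None = None,
                                   cantilever_stiffness: float = 6.0) -> dict:
    """Synthetic force-spectroscopy dataset: traces plus the two fit tables.

    One back-and-forth pull per speed.  The plateau table holds one row per
    (speed, phase); the S-curve table samples the post-uncoiling branch of
    the fastest pull (where extension and retraction coincide).
    """
    if params is None:
        params = FimbriaParams()
    if rng is None:
        rng = np.random.default_rng()
    traces = {}
    plateau_rows = []
    for sp in speeds:
        proto = PullProtocol(speed=sp, noise_sd=noise_sd,
                             cantilever_stiffness=cantilever_stiffness)
        trace = simulate_pull(params, proto, rng)
        traces[sp] = trace
        for phase in ("extension", "retraction"):
            try:
                f = extract_plateau(trace, phase)
            except PlateauNotFoundError:
                f = np.nan
            plateau_rows.append({"speed_um_s": sp, "phase": phase,
                                 "force_pN": f})
    plateau_table = pd.DataFrame(plateau_rows)

    # S-curve: fully uncoiled portion of the slowest trace (its plateau is
    # lowest, so the converged branch spans the widest force range)
    tr = traces[min(speeds)]
    nAr = tr.meta["n_coiled"]
    sl = tr.phase_slice("extension")
    x, F, nA = tr.extension[sl], tr.force[sl], nAr[sl]
    full = nA == 0
    rows = []
    if np.any(full):
        xs, Fs = x[full], F[full]
        order = np.argsort(Fs, kind="stable")
        xs, Fs = xs[order], Fs[order]
        targets = np.linspace(max(Fs[0], 20.0), Fs[-1], 25)
        xi = np.interp(targets, Fs, xs)
        x_max = xi.max()
        for f_t, x_t in zip(targets, xi):
            rows.append({"force_pN": float(f_t), "extension_nm": float(x_t),
                         "normalized_extension": float(x_t / x_max)})
    s_curve_table = pd.DataFrame(rows)
    return {"traces": traces, "plateau_table": plateau_table,
            "s_curve_table": s_curve_table, "params": params}
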