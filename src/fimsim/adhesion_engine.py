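"""Whole-cell stochastic adhesive-dynamics simulation.

Couples the fimbrial shaft mechanics, the FimH catch-bond kinetics and the
near-wall hydrodynamics into a single time loop: a rigid spherical cell
decorated with fimbriae (anchored at random directions, exponentially
distributed lengths) interacts with a mannose-coated wall under a programmed
wall-shear-stress protocol.  Simulations start with a single fimbria bound
in the activated (high-affinity) state, representing a bacterium that has
just transitioned to stationary adhesion.

The update order within a step is fixed: (1) tip positions and
anchor-to-attachment distances; (2) tension per bound fimbria; (3) coiling
and stretch-partition updates for yielding fimbriae; (4) bond-state
transitions with tensile-clamped force; (5) binding attempts for unbound
tips in range; (6) semi-implicit quasi-static pose update.

Public units: um for cell-scale lengths, pN for forces, s for time,
Pa for stresses.  (The compiled kernel works in nm internally.)
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernel
from .bond_kinetics import BondParams, BondState
from .fimbria_mechanics import FimbriaParams, FimbriaState
from .hydrodynamics import DEFAULT_GAP_UM, DEFAULT_RADIUS_UM

__all__ = [
    "FimbriaInstance",
    "SimulationConfig",
    "TrajectoryRecord",
    "AdhesionSystem",
    "place_fimbriae",
    "step",
    "run",
    "detachment_time",
    "MEAN_FIMBRIA_LENGTH_UM",
    "N_FIMBRIAE_DEFAULT",
    "SINGLE_FIMBRIA_LENGTH_UM",
]

# study conditions: fimbrial coat of the simulated bacterium
N_FIMBRIAE_DEFAULT = 186
MEAN_FIMBRIA_LENGTH_UM = 0.572
SINGLE_FIMBRIA_LENGTH_UM = 1.0

EVENT_NAMES = {_kernel.EV_BIND: "bind", _kernel.EV_RUPTURE: "rupture",
               _kernel.EV_ACTIVATE: "activate",
               _kernel.EV_DEACTIVATE: "deactivate"}


@dataclass
class FimbriaInstance:
    """One fimbria on the cell: anchor geometry, mechanics and bond."""

    anchor_direction: np.ndarray          # unit vector, body frame
    native_length: float                  # um
    mechanics_params: FimbriaParams = field(default_factory=FimbriaParams)
    mechanics_state: FimbriaState | None = None
    bond: BondState = field(default_factory=BondState)
    attachment_point: np.ndarray | None = None   # wall coords (um), iff bound

    def __post_init__(self) -> None:
        if self.native_length <= 0:
            raise ValueError("native_length must be > 0")
        if self.bond.bound and self.attachment_point is None:
            raise ValueError("bound fimbriae must have an attachment point")
        if not self.bond.bound and self.attachment_point is not None:
            raise ValueError("unbound fimbriae have no attachment point")


def place_fimbriae(n: int, mean_length: float = MEAN_FIMBRIA_LENGTH_UM,
                   rng: np.random.Generator | None = None,
                   single_fimbria_mode: bool = False,
                   params: FimbriaParams | None = None) -> list[FimbriaInstance]:
    """Draw the fimbrial coat: uniform directions, exponential lengths.

    In single-fimbria mode exactly one fimbria of length 1 um is emitted,
    pointing straight at the wall.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = FimbriaParams()
    if single_fimbria_mode:
        return [FimbriaInstance(anchor_direction=np.array([0.0, 0.0, -1.0]),
                                native_length=SINGLE_FIMBRIA_LENGTH_UM,
                                mechanics_params=params)]
    if rng is None:
        rng = np.random.default_rng()
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    lengths = np.maximum(rng.exponential(mean_length, size=n), 0.02)
    return [FimbriaInstance(anchor_direction=dirs[i],
                            native_length=float(lengths[i]),
                            mechanics_params=params)
            for i in range(n)]


@dataclass
class SimulationConfig:
    """Full configuration of a whole-cell simulation."""

    protocol: object                      # FlowProtocol (see protocols_analysis)
    dt: float = 1.0e-4                    # s, base step; kernel sub-divides
    n_fimbriae: int = N_FIMBRIAE_DEFAULT
    mean_fimbria_length: float = MEAN_FIMBRIA_LENGTH_UM   # um
    single_fimbria_mode: bool = False
    elasticity_mode: str = "yielding"
    rng_seed: int = 0
    max_time: Optional[float] = None      # s; defaults to protocol duration
    fimbria: FimbriaParams = field(default_factory=FimbriaParams)
    bond: BondParams = field(default_factory=BondParams)
    radius: float = DEFAULT_RADIUS_UM     # um
    gap_rest: float = DEFAULT_GAP_UM      # um
    viscosity: float = 1.0e-3             # Pa*s
    k_wall: float = 50.0                  # pN/nm short-range wall repulsion
    grace_window: float = 0.1             # s with zero bonds => detached
    output_dt: float = 0.01               # s between recorded snapshots
    event_capacity: int = 200_000

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.elasticity_mode != self.fimbria.mode:
            self.fimbria = replace(self.fimbria, mode=self.elasticity_mode)


@dataclass
class TrajectoryRecord:
    """Per-snapshot observables of one simulation replicate."""

    times: np.ndarray                 # (k,) s
    shear_stress: np.ndarray          # (k,) Pa
    position: np.ndarray              # (k, 3) um
    rotation: np.ndarray              # (k, 3) accumulated rotation (rad)
    n_bound: np.ndarray               # (k,)
    n_activated: np.ndarray           # (k,)
    n_uncoiled: np.ndarray            # (k,)
    bond_forces: np.ndarray           # (k, n) pN, NaN when unbound
    bond_status: np.ndarray           # (k, n) 0/1/2
    n_coiled_subunits: np.ndarray     # (k, n)
    n_subunits: np.ndarray            # (n,)
    events: pd.DataFrame              # time, fimbria, event
    detach_time: Optional[float]
    grace_window: float
    config_echo: dict

    def frames(self) -> pd.DataFrame:
        """Summary table, one row per snapshot (documented column set)."""
        mean_f = np.full(len(self.times), np.nan)
        act = self.bond_status == 2
        with np.errstate(invalid="ignore"):
            f = np.where(act, np.maximum(self.bond_forces, 0.0), np.nan)
            any_act = act.any(axis=1)
            mean_f[any_act] = np.nanmean(f[any_act], axis=1)
        return pd.DataFrame({
            "time_s": self.times,
            "shear_stress_Pa": self.shear_stress,
            "x_um": self.position[:, 0],
            "y_um": self.position[:, 1],
            "z_um": self.position[:, 2],
            "n_bound": self.n_bound,
            "n_activated": self.n_activated,
            "n_uncoiled_fimbriae": self.n_uncoiled,
            "mean_activated_force_pN": mean_f,
        })


class AdhesionSystem:
    """Mutable simulation state; thin wrapper over the compiled kernel."""

    def __init__(self, config: SimulationConfig):
        self.config = config
        fp = config.fimbria
        bp = config.bond
        ss = np.random.SeedSequence(config.rng_seed)
        placement_seed, kernel_seed = (
            int(x) & 0x7FFFFFFF for x in ss.generate_state(2))
        rng = np.random.default_rng(placement_seed)

        a_nm = config.radius * 1000.0
        gap_rest_nm = config.gap_rest * 1000.0

        # The fimbrial coat is always present (unbound fimbriae touching
        # the wall act as supporting legs); in single-fimbria mode the
        # association rate is zero for every fimbria, so only the seed bond
        # can ever hold the cell, and the seed fimbria is set to 1 um.
        n = config.n_fimbriae
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        L_nm = np.maximum(
            rng.exponential(config.mean_fimbria_length * 1000.0, size=n),
            20.0)
        if config.single_fimbria_mode:
            allow = np.zeros(n, dtype=np.int64)
        else:
            allow = np.ones(n, dtype=np.int64)

        n_sub = np.maximum(np.rint(L_nm / fp.rise_A), 1).astype(np.int64)
        L_nm = n_sub * fp.rise_A

        self.n = n
        self.u_body = np.ascontiguousarray(u)
        self.L_nat = L_nm.astype(np.float64)
        self.n_sub = n_sub
        mode = fp.mode
        if mode == "strain_hardening":
            self.nA = np.zeros(n, dtype=np.int64)
            self.nB = n_sub.copy()
        else:
            self.nA = n_sub.copy()
            self.nB = np.zeros(n, dtype=np.int64)
        self.nC = np.zeros(n, dtype=np.int64)
        self.status = np.zeros(n, dtype=np.int64)
        self.attach = np.zeros((n, 3))
        self.allow_bind = allow

        # initial pose and seed bond
        self.c = np.array([0.0, 0.0, a_nm + gap_rest_nm])
        tips = self.c + (a_nm + self.L_nat[:, None]) * self.u_body
        anchors = self.c + a_nm * self.u_body
        # Seed bond: a cell that has just arrested was moving
        # downstream, so its anchoring tether trails upstream.  Pick
        # the fimbria that maximizes its upstream reach fraction
        # (sin of the tether angle, reach/L with reach^2 = L^2 -
        # anchor_z^2) and attach it exactly taut at the wall point
        # directly upstream of the anchor.  A taut, upstream-pulling
        # seed carries ~drag/(reach/L) from the start -- the
        # force-stabilized catch regime -- instead of being shock-
        # loaded through a slack swing.
        reachable = anchors[:, 2] <= self.L_nat
        if not np.any(reachable):
            reachable = np.ones(n, dtype=bool)
        reach = np.sqrt(np.maximum(self.L_nat ** 2 - anchors[:, 2] ** 2,
                                   0.0))
        score = np.where(reachable, reach / self.L_nat, -np.inf)
        seed_idx = int(np.argmax(score))
        if config.single_fimbria_mode:
            # the anchoring fimbria is always 1 um long
            L1 = SINGLE_FIMBRIA_LENGTH_UM * 1000.0
            self.n_sub[seed_idx] = max(int(round(L1 / fp.rise_A)), 1)
            self.L_nat[seed_idx] = self.n_sub[seed_idx] * fp.rise_A
            if mode == "strain_hardening":
                self.nB[seed_idx] = self.n_sub[seed_idx]
            else:
                self.nA[seed_idx] = self.n_sub[seed_idx]
            reach[seed_idx] = np.sqrt(max(
                self.L_nat[seed_idx] ** 2 - anchors[seed_idx, 2] ** 2,
                0.0))
        anc = anchors[seed_idx]
        self.attach[seed_idx] = (anc[0] - reach[seed_idx], anc[1], 0.0)
        self.status[seed_idx] = 2   # seed bond starts activated
        self.seed_idx = seed_idx

        self.Rm = np.eye(3)
        self.rotacc = np.zeros(3)
        self.t = np.zeros(1)
        self.misc = np.array([0.0, -1.0, 0.0, 0.0])

        # protocol arrays
        t0, s0, rate = config.protocol.to_arrays()
        self.prot_t0, self.prot_s0, self.prot_rate = t0, s0, rate
        self.t_final = (config.max_time if config.max_time is not None
                        else config.protocol.duration)

        # recording buffers
        n_out = int(np.ceil(self.t_final / config.output_dt)) + 3
        self.out_t = np.zeros(n_out)
        self.out_sigma = np.zeros(n_out)
        self.out_pos = np.zeros((n_out, 3))
        self.out_rot = np.zeros((n_out, 3))
        self.out_nbound = np.zeros(n_out, dtype=np.int64)
        self.out_nact = np.zeros(n_out, dtype=np.int64)
        self.out_nunc = np.zeros(n_out, dtype=np.int64)
        self.out_force = np.zeros((n_out, n), dtype=np.float32)
        self.out_status = np.zeros((n_out, n), dtype=np.int8)
        self.out_nA = np.zeros((n_out, n), dtype=np.int32)
        self.k_out = np.zeros(1, dtype=np.int64)
        self.next_out = np.zeros(1)
        cap = config.event_capacity
        self.ev_t = np.zeros(cap)
        self.ev_fim = np.zeros(cap, dtype=np.int64)
        self.ev_type = np.zeros(cap, dtype=np.int64)
        self.ev_n = np.zeros(1, dtype=np.int64)

        self._pm = fp.as_array()
        self._pb = bp.as_array()
        self._a_nm = a_nm
        self._gap_rest_nm = gap_rest_nm
        _kernel.seed_kernel_rng(kernel_seed)
        self.detached = False

    # -- convenience views ------------------------------------------------
    @property
    def time(self) -> float:
        return float(self.t[0])

    @property
    def position_um(self) -> np.ndarray:
        return self.c / 1000.0

    @property
    def n_bound(self) -> int:
        return int(np.count_nonzero(self.status))

    @property
    def bond_tensions(self) -> np.ndarray:
        """Current tensile force per bound fimbria (pN), NaN if unbound."""
        k = int(self.k_out[0])
        if k == 0:
            return np.full(self.n, np.nan)
        return self.out_force[k - 1].astype(float)

    def advance_to(self, t_target: float) -> None:
        cfg = self.config
        res = _kernel.advance(
            self.t, min(t_target, self.t_final), cfg.dt, cfg.viscosity,
            self.prot_t0, self.prot_s0, self.prot_rate,
            self._a_nm, self._gap_rest_nm, cfg.k_wall, cfg.grace_window,
            self._pm, self._pb,
            self.u_body, self.L_nat, self.n_sub,
            self.nA, self.nB, self.nC, self.status, self.attach,
            self.allow_bind,
            self.c, self.Rm, self.rotacc, self.misc,
            self.next_out, cfg.output_dt,
            self.out_t, self.out_sigma, self.out_pos, self.out_rot,
            self.out_nbound, self.out_nact, self.out_nunc,
            self.out_force, self.out_status, self.out_nA,
            self.k_out,
            self.ev_t, self.ev_fim, self.ev_type, self.ev_n)
        if res == -1:
            raise FloatingPointError(
                "non-finite pose encountered; diagnostic state: "
                f"t={self.time:.6g} s, pos={self.c}, n_bound={self.n_bound}")
        if res == 1:
            self.detached = True

    def record(self) -> TrajectoryRecord:
        k = int(self.k_out[0])
        ne = min(int(self.ev_n[0]), len(self.ev_t))
        events = pd.DataFrame({
            "time_s": self.ev_t[:ne],
            "fimbria": self.ev_fim[:ne],
            "event": [EVENT_NAMES[int(e)] for e in self.ev_type[:ne]],
        })
        detach = float(self.misc[1]) if self.detached else None
        cfg = self.config
        echo = {
            "rng_seed": cfg.rng_seed, "dt": cfg.dt,
            "elasticity_mode": cfg.elasticity_mode,
            "n_fimbriae": self.n, "single_fimbria_mode": cfg.single_fimbria_mode,
            "radius_um": cfg.radius, "gap_rest_um": cfg.gap_rest,
            "viscosity_Pa_s": cfg.viscosity,
        }
        return TrajectoryRecord(
            times=self.out_t[:k].copy(),
            shear_stress=self.out_sigma[:k].copy(),
            position=self.out_pos[:k] / 1000.0,
            rotation=self.out_rot[:k].copy(),
            n_bound=self.out_nbound[:k].copy(),
            n_activated=self.out_nact[:k].copy(),
            n_uncoiled=self.out_nunc[:k].copy(),
            bond_forces=self.out_force[:k].copy(),
            bond_status=self.out_status[:k].copy(),
            n_coiled_subunits=self.out_nA[:k].copy(),
            n_subunits=self.n_sub.copy(),
            events=events,
            detach_time=detach,
            grace_window=cfg.grace_window,
            config_echo=echo)

    def check_invariants(self) -> None:
        """Subunit conservation and count consistency; raises on violation."""
        total = self.nA + self.nB + self.nC
        if not np.array_equal(total, self.n_sub):
            raise AssertionError("subunit conservation violated")
        if np.any(self.nA < 0) or np.any(self.nB < 0) or np.any(self.nC < 0):
            raise AssertionError("negative subunit count")


def step(system: AdhesionSystem, dt: float | None = None) -> AdhesionSystem:
    """Advance the simulation by one base time step (in place)."""
    if dt is None:
        dt = system.config.dt
    system.advance_to(system.time + dt)
    return system


def run(config: SimulationConfig) -> TrajectoryRecord:
    """Run a full replicate under the configured flow protocol.

    Terminates at ``max_time`` (default: the protocol duration) or at
    detachment (zero bonds persisting past the grace window).
    """
    system = AdhesionSystem(config)
    system.advance_to(system.t_final)
    system.check_invariants()
    return system.record()


def detachment_time(record: TrajectoryRecord) -> Optional[float]:
    """First time at which the cell has zero bound fimbriae for longer than
    the grace window; ``None`` if it stays bound."""
    if record.detach_time is not None:
        return record.detach_time
    nb = record.n_bound
    t = record.times
    start = None
    for i in range(len(t)):
        if nb[i] == 0:
            if start is None:
                start = t[i]
            if t[i] - start >= record.grace_window:
                return start
        else:
            start = None
    return None
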