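"""Flow protocols, replicate ensembles, and the published observables.

The three protocol families:

* ``step`` -- shear stress stepped 1, 2.5, 5, 10, 15, 20, 25 Pa (10 s
  holds), then dropped to 0.01 Pa.  (The published step schedule is read
  from a figure; this reconstruction is the package default.)
* ``ramp`` -- 1 Pa/s from 1 Pa until 100 Pa (or detachment).
* ``history`` -- hold at one of {1, 2.5, 5, 10} Pa, then drop to 0.01 Pa.

Observables follow the published conventions: snapshots 5 s after each
protocol switch; box-whisker summaries with the middle two quartiles, 9-91%
whiskers, and outliers beyond the whiskers; bonds above 90 pN counted as
vulnerable; a fimbria counts as uncoiled when more than 5% of its subunits
have left the coiled state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .adhesion_engine import (SimulationConfig, TrajectoryRecord,
                              detachment_time, run)

__all__ = [
    "FlowProtocol",
    "EnsembleSummary",
    "build_protocol",
    "run_ensemble",
    "bound_fraction",
    "force_distribution",
    "count_observables",
    "detachment_stress",
    "VULNERABLE_FORCE_PN",
    "UNCOILED_FRACTION_THRESHOLD",
    "STEP_LEVELS_PA",
    "SNAPSHOT_DELAY_S",
]

VULNERABLE_FORCE_PN = 90.0
UNCOILED_FRACTION_THRESHOLD = 0.05
STEP_LEVELS_PA = (1.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0)
SNAPSHOT_DELAY_S = 5.0


@dataclass
class FlowProtocol:
    """Piecewise schedule of wall shear stress versus time.

    ``segments`` is an ordered list of ``(start_time_s, stress_Pa,
    ramp_rate_Pa_per_s)`` tuples; each segment runs until the next one
    starts.  ``duration`` is the total protocol length.
    """

    segments: list[tuple[float, float, float]]
    duration: float

    def __post_init__(self) -> None:
        times = [s[0] for s in self.segments]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValueError("segment start times must be strictly increasing")
        if any(s[1] < 0 for s in self.segments):
            raise ValueError("stresses must be >= 0")

    def stress_at(self, t: float) -> float:
        s0, sig, rate = self.segments[0]
        for seg in self.segments:
            if seg[0] <= t + 1e-12:
                s0, sig, rate = seg
            else:
                break
        return sig + rate * (t - s0)

    def to_arrays(self):
        t0 = np.array([s[0] for s in self.segments], dtype=np.float64)
        s0 = np.array([s[1] for s in self.segments], dtype=np.float64)
        rate = np.array([s[2] for s in self.segments], dtype=np.float64)
        return t0, s0, rate

    @property
    def switch_times(self) -> list[float]:
        return [s[0] for s in self.segments[1:]]


def build_protocol(name: str, *, hold: float = 10.0, level: float = 10.0,
                   drop_stress: float = 0.01, drop_hold: float = 30.0,
                   ramp_rate: float = 1.0, ramp_start: float = 1.0,
                   ramp_max: float = 100.0,
                   post_drop: float = 90.0) -> FlowProtocol:
    """Construct one of the named protocols (``step``, ``ramp``,
    ``history``)."""
    if name == "step":
        segs = []
        t = 0.0
        for lev in STEP_LEVELS_PA:
            segs.append((t, lev, 0.0))
            t += hold
        segs.append((t, drop_stress, 0.0))
        return FlowProtocol(segs, duration=t + drop_hold)
    if name == "ramp":
        t_top = (ramp_max - ramp_start) / ramp_rate
        segs = [(0.0, ramp_start, ramp_rate), (t_top, ramp_max, 0.0)]
        return FlowProtocol(segs, duration=t_top + 1.0)
    if name == "history":
        # cells accumulate in stationary adhesion at 1 Pa before the test
        # level is applied (matching the flow-chamber procedure)
        settle = 10.0
        if level <= 1.0:
            segs = [(0.0, level, 0.0), (settle + hold, drop_stress, 0.0)]
        else:
            segs = [(0.0, 1.0, 0.0), (settle, level, 0.0),
                    (settle + hold, drop_stress, 0.0)]
        return FlowProtocol(segs, duration=settle + hold + post_drop)
    raise ValueError(f"unknown protocol {name!r}")


def _replicate_seeds(master_seed: int, n: int) -> list[int]:
    """Documented splitting rule: child seeds are the first ``n`` uint32
    words of ``SeedSequence(master_seed)``, masked to 31 bits."""
    ss = np.random.SeedSequence(master_seed)
    return [int(x) & 0x7FFFFFFF for x in ss.generate_state(n)]


def run_ensemble(config: SimulationConfig, n_replicates: int,
                 master_seed: int = 0,
                 progress: bool = False) -> list[TrajectoryRecord]:
    """Run independently seeded replicates of one configuration."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    records = []
    for i, seed in enumerate(_replicate_seeds(master_seed, n_replicates)):
        rec = run(replace(config, rng_seed=seed))
        records.append(rec)
        if progress:
            dt = detachment_time(rec)
            msg = "bound" if dt is None else f"detached at t={dt:.2f} s"
            print(f"  replicate {i + 1}/{n_replicates}: {msg}")
    return records


def bound_fraction(records: Sequence[TrajectoryRecord],
                   time_grid: np.ndarray) -> np.ndarray:
    """Fraction of replicates still bound at each time (non-increasing)."""
    if len(records) == 0:
        raise ValueError("need at least one record")
    tg = np.asarray(time_grid, dtype=float)
    out = np.zeros_like(tg)
    for rec in records:
        dt = detachment_time(rec)
        if dt is None:
            out += 1.0
        else:
            out += (tg < dt).astype(float)
    return out / len(records)


def detachment_stress(record: TrajectoryRecord,
                      protocol: FlowProtocol) -> Optional[float]:
    """Wall shear stress at the moment of detachment, or None."""
    dt = detachment_time(record)
    if dt is None:
        return None
    return protocol.stress_at(dt)


def _snapshot_index(record: TrajectoryRecord, time: float) -> int:
    idx = int(np.searchsorted(record.times, time, side="right")) - 1
    if idx < 0:
        raise ValueError(f"time {time} precedes the record")
    return idx


def force_distribution(records: Sequence[TrajectoryRecord],
                       snapshot_time: float) -> dict:
    """Box-whisker summary of tensile force on activated bonds, pooled
    across replicates at one snapshot.

    Compressed activated bonds enter as zero force (tensile convention).
    Returns quartiles, the 9-91% whiskers, the outliers beyond them, and
    the count of vulnerable bonds above 90 pN.
    """
    forces = []
    for rec in records:
        if len(rec.times) == 0 or rec.times[-1] < snapshot_time - 1e-9:
            continue   # replicate detached before the snapshot
        i = _snapshot_index(rec, snapshot_time)
        act = rec.bond_status[i] == 2
        f = np.maximum(rec.bond_forces[i][act].astype(float), 0.0)
        forces.append(f)
    if not forces or sum(len(f) for f in forces) == 0:
        raise ValueError("no activated bonds at the requested snapshot")
    pooled = np.concatenate(forces)
    q1, q2, q3 = np.percentile(pooled, [25, 50, 75])
    w_lo, w_hi = np.percentile(pooled, [9, 91])
    outliers = pooled[(pooled < w_lo) | (pooled > w_hi)]
    return {
        "n": int(pooled.size),
        "forces": pooled,
        "median": float(q2),
        "mean": float(pooled.mean()),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_lo": float(w_lo),
        "whisker_hi": float(w_hi),
        "outliers": outliers,
        "n_vulnerable": int(np.count_nonzero(pooled > VULNERABLE_FORCE_PN)),
    }


def count_observables(record: TrajectoryRecord, time: float,
                      uncoiled_threshold: float = UNCOILED_FRACTION_THRESHOLD):
    """(n_uncoiled_fimbriae, n_activated_bonds) at one snapshot.

    A fimbria counts as uncoiled when more than ``uncoiled_threshold`` of
    its subunits are outside the coiled state.
    """
    i = _snapshot_index(record, time)
    frac_unc = 1.0 - record.n_coiled_subunits[i] / record.n_subunits
    n_unc = int(np.count_nonzero(frac_unc > uncoiled_threshold))
    n_act = int(np.count_nonzero(record.bond_status[i] == 2))
    return n_unc, n_act


@dataclass
class EnsembleSummary:
    """Published observables for one condition's replicate ensemble."""

    condition: str
    time_grid: np.ndarray
    bound_fraction: np.ndarray
    snapshots: pd.DataFrame          # per snapshot time: counts, forces
    creep_displacement_um: float     # final mean downstream displacement
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": self.time_grid,
                           "bound_fraction": self.bound_fraction})
        df["condition"] = self.condition
        return df


def summarize_ensemble(records: Sequence[TrajectoryRecord],
                       protocol: FlowProtocol, condition: str = "",
                       snapshot_times: Sequence[float] | None = None,
                       grid_dt: float = 1.0) -> EnsembleSummary:
    """Compute the standard observable set for one ensemble."""
    t_max = max(rec.times[-1] if len(rec.times) else 0.0 for rec in records)
    grid = np.arange(0.0, t_max + grid_dt, grid_dt)
    bf = bound_fraction(records, grid)
    if snapshot_times is None:
        snapshot_times = [t + SNAPSHOT_DELAY_S for t in protocol.switch_times]
    rows = []
    for st in snapshot_times:
        counts = []
        for rec in records:
            if len(rec.times) and rec.times[-1] >= st - 1e-9:
                counts.append(count_observables(rec, st))
        try:
            fd = force_distribution(records, st)
        except ValueError:
            fd = None
        if counts:
            unc = np.array([c[0] for c in counts])
            act = np.array([c[1] for c in counts])
            rows.append({
                "snapshot_s": st,
                "stress_Pa": protocol.stress_at(st),
                "n_surviving": len(counts),
                "uncoiled_mean": unc.mean(), "uncoiled_sd": unc.std(ddof=0),
                "uncoiled_median": float(np.median(unc)),
                "activated_mean": act.mean(), "activated_sd": act.std(ddof=0),
                "activated_median": float(np.median(act)),
                "force_mean": fd["mean"] if fd else np.nan,
                "force_median": fd["median"] if fd else np.nan,
                "force_q1": fd["q1"] if fd else np.nan,
                "force_q3": fd["q3"] if fd else np.nan,
                "n_vulnerable": fd["n_vulnerable"] if fd else 0,
            })
    disp = []
    for rec in records:
        if len(rec.times):
            disp.append(rec.position[-1, 0] - rec.position[0, 0])
    return EnsembleSummary(
        condition=condition, time_grid=grid, bound_fraction=bf,
        snapshots=pd.DataFrame(rows),
        creep_displacement_um=float(np.mean(disp)) if disp else np.nan,
        n_replicates=len(records))
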