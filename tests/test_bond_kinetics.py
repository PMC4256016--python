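"""Two-state allosteric catch bond: rates, lifetimes, stochastic stepping."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.linalg import expm

import fimsim as fs
from fimsim.bond_kinetics import BondState


class TestBondRates:
    def test_zero_force(self, bond_params):
        k10, k20, k12, k21 = fs.bond_rates(0.0, bond_params)
        assert (k10, k20, k12, k21) == (
            bond_params.k0_10, bond_params.k0_20,
            bond_params.k0_12, bond_params.k0_21)

    def test_monotonicity(self, bond_params):
        F = np.linspace(0, 120, 25)
        rates = np.array([fs.bond_rates(f, bond_params) for f in F])
        assert np.all(np.diff(rates[:, 2]) > 0)   # activation accelerates
        assert np.all(np.diff(rates[:, 3]) < 0)   # deactivation suppressed

    def test_slip_regime_dominated_by_activated_rupture(self, bond_params):
        k10, k20, k12, k21 = fs.bond_rates(150.0, bond_params)
        assert k20 > 1.0 and k20 > k21

    def test_negative_force_rejected(self, bond_params):
        with pytest.raises(ValueError):
            fs.bond_rates(-5.0, bond_params)

    def test_catch_premise_enforced(self):
        with pytest.raises(ValueError):
            fs.BondParams(k0_20=2.0, k0_10=1.0)


def _gillespie_lifetime(F, params, start, n, rng):
    """Independent exact-jump oracle for the mean rupture time."""
    k10, k20, k12, k21 = fs.bond_rates(F, params)
    times = np.zeros(n)
    for i in range(n):
        s = start
        t = 0.0
        while s != 0:
            if s == 1:
                ktot = k10 + k12
                t += rng.exponential(1.0 / ktot)
                s = 0 if rng.random() < k10 / ktot else 2
            else:
                ktot = k20 + k21
                t += rng.exponential(1.0 / ktot)
                s = 0 if rng.random() < k20 / ktot else 1
        times[i] = t
    return times


class TestMeanLifetime:
    def test_one_state_limit(self, bond_params):
        p = dataclasses.replace(bond_params, k0_12=1e-15, k0_21=1e-12)
        for F in (0.0, 40.0):
            k10 = fs.bond_rates(F, p)[0]
            assert fs.mean_bond_lifetime(F, p, "low_affinity") == \
                pytest.approx(1.0 / k10, rel=1e-6)

    @pytest.mark.parametrize("F", [10.0, 50.0, 90.0])
    def test_against_gillespie(self, F, bond_params, rng):
        """Closed form matches exact stochastic simulation within 3 SE."""
        n = 10_000
        times = _gillespie_lifetime(F, bond_params, 2, n, rng)
        se = times.std(ddof=1) / math.sqrt(n)
        pred = fs.mean_bond_lifetime(F, bond_params, "activated")
        assert abs(times.mean() - pred) < 3 * se

    def test_catch_slip_nonmonotone(self, bond_params):
        """Lifetime peaks at intermediate force: the catch-bond signature.

        Bonds are long-lived between 30 and 70 pN but break within seconds
        above 90 pN.
        """
        t10 = fs.mean_bond_lifetime(10.0, bond_params)
        t50 = fs.mean_bond_lifetime(50.0, bond_params)
        t100 = fs.mean_bond_lifetime(100.0, bond_params)
        assert t50 > t10 and t50 > t100
        F = np.linspace(1, 150, 300)
        life = [fs.mean_bond_lifetime(f, bond_params) for f in F]
        fmax = F[int(np.argmax(life))]
        assert 30.0 <= fmax <= 70.0
        assert fs.mean_bond_lifetime(95.0, bond_params) < 10.0


class TestStepBond:
    def test_unbound_unchanged(self, bond_params, rng):
        out, ruptured = fs.step_bond(BondState("unbound"), 0.0, 1e-3, rng,
                                     bond_params)
        assert out.status == "unbound" and not ruptured

    def test_zero_dt_no_events(self, bond_params, rng):
        for _ in range(100):
            out, _ = fs.step_bond(BondState("activated"), 50.0, 0.0, rng,
                                  bond_params)
            assert out.status == "activated"

    def test_transition_frequencies(self, bond_params, rng):
        """Empirical per-step transition frequencies match the exponential
        probabilities within 3 SE."""
        F, dt, n = 30.0, 2e-3, 60_000
        k10, k20, k12, k21 = fs.bond_rates(F, bond_params)
        counts = {"unbound": 0, "activated": 0}
        for _ in range(n):
            out, _ = fs.step_bond(BondState("low_affinity"), F, dt, rng,
                                  bond_params)
            if out.status != "low_affinity":
                counts[out.status] += 1
        ktot = k10 + k12
        p_any = -math.expm1(-ktot * dt)
        for status, k in (("unbound", k10), ("activated", k12)):
            p = p_any * k / ktot
            se = math.sqrt(p * (1 - p) * n)
            assert abs(counts[status] - n * p) < 3 * se

    def test_master_equation_occupancy(self, bond_params, rng):
        """Ensemble state occupancy matches the matrix-exponential solution
        of the master equation within 3 SE at five time points."""
        F, dt = 20.0, 1e-3
        k10, k20, k12, k21 = fs.bond_rates(F, bond_params)
        # generator over (unbound, low, activated)
        Q = np.array([[0.0, 0.0, 0.0],
                      [k10, -(k10 + k12), k12],
                      [k20, k21, -(k20 + k21)]]).T
        n_bonds = 2000
        states = [BondState("low_affinity") for _ in range(n_bonds)]
        checkpoints = [20, 40, 80, 160, 320]
        step_i = 0
        for cp in checkpoints:
            while step_i < cp:
                for j in range(n_bonds):
                    if states[j].bound:
                        states[j], _ = fs.step_bond(states[j], F, dt, rng,
                                                    bond_params)
                step_i += 1
            t = cp * dt
            p = expm(Q * t) @ np.array([0.0, 1.0, 0.0])
            occ = np.array([
                sum(s.status == "unbound" for s in states),
                sum(s.status == "low_affinity" for s in states),
                sum(s.status == "activated" for s in states)]) / n_bonds
            for want, got in zip(p, occ):
                se = math.sqrt(max(want * (1 - want), 1e-12) / n_bonds)
                assert abs(got - want) < 3 * se + 1e-9

    def test_compressive_force_clamped(self, bond_params, rng):
        # compressive contact enters the rate laws as zero force
        out, _ = fs.step_bond(BondState("activated"), -50.0, 1e-6, rng,
                              bond_params)
        assert out.tensile_force == 0.0


class TestAttemptBinding:
    def test_out_of_range_never_binds(self, bond_params, rng):
        for _ in range(200):
            assert fs.attempt_binding(bond_params.capture_radius + 1.0,
                                      1.0, bond_params, rng) is None

    def test_zero_on_rate_never_binds(self, rng):
        p = dataclasses.replace(fs.BondParams(), k_on=0.0)
        for _ in range(200):
            assert fs.attempt_binding(0.0, 1.0, p, rng) is None

    def test_binding_frequency(self, bond_params, rng):
        dt, n = 5e-3, 40_000
        hits = sum(fs.attempt_binding(1.0, dt, bond_params, rng) is not None
                   for _ in range(n))
        p = -math.expm1(-bond_params.k_on * dt)
        se = math.sqrt(p * (1 - p) * n)
        assert abs(hits - n * p) < 3 * se

    def test_new_bonds_low_affinity_seed_activated(self, bond_params, rng):
        got = None
        while got is None:
            got = fs.attempt_binding(0.0, 1.0, bond_params, rng)
        assert got.status == "low_affinity"
        seed = None
        while seed is None:
            seed = fs.attempt_binding(0.0, 1.0, bond_params, rng,
                                      seed_bond=True)
        assert seed.status == "activated"
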