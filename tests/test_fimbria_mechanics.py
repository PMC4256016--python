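"""Single-fimbria mechanics: WLC, three-state inversion, coiling kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fimsim as fs
from fimsim.fimbria_mechanics import (FimbriaState, apply_stretch_partition,
                                      meanfield_pull_curve)
from fimsim.afm_fit import predict_plateau_force


class TestWlcForce:
    def test_zero_extension_zero_force(self):
        assert fs.wlc_force(0.0, 4.1) == 0.0

    def test_marko_siggia_half_extension(self):
        # closed form at x/Lc = 1/2: (kBT/lp) * (1/(4*0.25) - 1/4 + 1/2)
        assert fs.wlc_force(0.5, 4.1, kBT=4.1) == pytest.approx(1.25)

    def test_monotone_divergence(self):
        f = [fs.wlc_force(x, 3.0) for x in (0.5, 0.9, 0.99)]
        assert f[2] > f[1] > f[0]
        assert fs.wlc_force(0.999, 3.0) > 100 * fs.wlc_force(0.5, 3.0)

    @pytest.mark.parametrize("x", [1.0, 1.5, -0.1])
    def test_domain_error(self, x):
        with pytest.raises(ValueError):
            fs.wlc_force(x, 3.0)

    @given(lp=st.floats(0.5, 50.0),
           x1=st.floats(0.01, 0.97), x2=st.floats(0.01, 0.97))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, lp, x1, x2):
        if abs(x1 - x2) < 1e-9:
            return
        lo, hi = sorted((x1, x2))
        assert fs.wlc_force(hi, lp) > fs.wlc_force(lo, lp)


class TestExtensionTension:
    def test_zero_force_natural_length(self, params):
        st_ = FimbriaState(n_A=800, n_B=400, n_C=230)
        assert fs.extension_at_tension(0.0, st_, params) == pytest.approx(
            800 * params.rise_A)

    def test_hookean_limit_fully_coiled(self, params):
        st_ = FimbriaState(n_A=params.n_subunits)
        k_seg = params.k_coil / params.n_subunits
        for F in (0.5, 2.0, 5.0):
            ext = fs.extension_at_tension(F, st_, params)
            assert ext == pytest.approx(
                params.n_subunits * params.rise_A + F / k_seg, rel=1e-9)

    def test_round_trip_grid(self, params, rng):
        """tension_from_extension inverts extension_at_tension to 0.01 pN."""
        for _ in range(8):
            n = params.n_subunits
            na = int(rng.integers(0, n + 1))
            nb = int(rng.integers(0, n - na + 1))
            st_ = FimbriaState(n_A=na, n_B=nb, n_C=n - na - nb)
            for F in np.arange(1.0, 151.0, 10.0):
                ext = fs.extension_at_tension(F, st_, params)
                rec = fs.tension_from_extension(ext, st_, params)
                assert rec == pytest.approx(F, abs=0.01)

    def test_compression_clamp(self, params):
        st_ = FimbriaState(n_A=params.n_subunits)
        natural = params.n_subunits * params.rise_A
        # deep compression exceeds the buckling cap
        T = fs.tension_from_extension(natural - 500.0, st_, params)
        assert T == -params.buckling_force
        # natural length carries zero tension
        assert fs.tension_from_extension(natural, st_, params) == 0.0

    def test_overstretched_uncoiled_error(self, params):
        st_ = FimbriaState(n_A=0, n_B=params.n_subunits, n_C=0)
        contour = params.n_subunits * params.x0_B
        with pytest.raises(ValueError):
            fs.tension_from_extension(contour * 1.01, st_, params)


class TestCoilKinetics:
    def test_zero_force_rates(self, params):
        kab, kba = fs.coil_transition_rates(0.0, params)
        assert kab == pytest.approx(params.k0_AB)
        assert kba == pytest.approx(params.k0_BA)

    def test_monotonicity(self, params):
        F = np.linspace(0, 100, 21)
        rates = np.array([fs.coil_transition_rates(f, params) for f in F])
        assert np.all(np.diff(rates[:, 0]) > 0)   # uncoiling accelerates
        assert np.all(np.diff(rates[:, 1]) < 0)   # recoiling slows

    def test_rates_cross_at_equilibrium_force(self, params):
        feq = fs.equilibrium_uncoiling_force(params)
        kab, kba = fs.coil_transition_rates(feq, params)
        assert kab == pytest.approx(kba, rel=1e-9)

    def test_equilibrium_force_closed_form_scaling(self, params):
        feq = fs.equilibrium_uncoiling_force(params)
        import dataclasses
        doubled = dataclasses.replace(params, x_AB=2 * params.x_AB,
                                      x_BA=2 * params.x_BA)
        assert fs.equilibrium_uncoiling_force(doubled) == pytest.approx(
            feq / 2)

    def test_equal_prefactors_give_zero(self, params):
        import dataclasses
        p = dataclasses.replace(params, k0_BA=params.k0_AB)
        assert fs.equilibrium_uncoiling_force(p) == 0.0

    def test_coiled_state_unfavoured_raises(self, params):
        import dataclasses
        p = dataclasses.replace(params, k0_AB=100.0, k0_BA=1.0)
        with pytest.raises(ValueError):
            fs.equilibrium_uncoiling_force(p)


class TestStepCoiling:
    def test_no_uncoil_from_empty_coil(self, params, rng):
        st_ = FimbriaState(n_A=0, n_B=params.n_subunits, n_C=0)
        out = fs.step_coiling(st_, 100.0, 1e-4, rng, params)
        assert out.n_A >= 0 and out.n_total == st_.n_total

    def test_linear_mode_rejected(self, rng):
        p = fs.FimbriaParams(mode="linear")
        with pytest.raises(ValueError):
            fs.step_coiling(FimbriaState(n_A=10), 10.0, 1e-4, rng, p)

    def test_detailed_balance_at_equilibrium_force(self, params, rng):
        """At F_eq the edge random walk has zero net drift (|z| < 3)."""
        feq = fs.equilibrium_uncoiling_force(params)
        st_ = FimbriaState(n_A=700, n_B=700, n_C=30)
        dt = 5e-4
        kab, _ = fs.coil_transition_rates(feq, params)
        n_steps = 100_000
        s = st_
        for _ in range(n_steps):
            s = fs.step_coiling(s, feq, dt, rng, params)
        drift = s.n_A - st_.n_A
        p = -math.expm1(-kab * dt)
        sd = math.sqrt(2 * n_steps * p * (1 - p))
        assert abs(drift) < 3 * sd
        assert s.n_total == st_.n_total

    def test_strong_force_uncoils_fully(self, params, rng):
        feq = fs.equilibrium_uncoiling_force(params)
        s = FimbriaState(n_A=50, n_B=0, n_C=0)
        for _ in range(300_000):
            s = fs.step_coiling(s, feq + 30.0, 1e-4, rng, params)
            if s.n_A == 0:
                break
        assert s.n_A == 0


class TestStretchPartition:
    def test_symmetric_equilibrium(self):
        p = fs.FimbriaParams(k_eq=1.0)
        assert fs.stretch_partition(0.0, p) == pytest.approx(0.5)

    def test_limit_and_monotone(self, params):
        fr = [fs.stretch_partition(f, params) for f in (0, 50, 100, 200)]
        assert all(b > a for a, b in zip(fr, fr[1:]))
        assert fr[-1] > 0.999

    def test_K_of_three_gives_three_quarters(self, params):
        # force where K = k_eq exp(F x_eq / kBT) = 3
        F = math.log(3.0 / params.k_eq) * params.kBT / params.x_eq
        assert fs.stretch_partition(F, params) == pytest.approx(0.75, rel=1e-6)

    def test_apply_rounds_half_to_even(self, params):
        st_ = FimbriaState(n_A=0, n_B=1000, n_C=0)
        out = apply_stretch_partition(st_, 60.0, params)
        assert out.n_B + out.n_C == 1000
        frac = fs.stretch_partition(60.0, params)
        assert out.n_C == int(np.rint(frac * 1000))


class TestForceExtensionCurve:
    def test_yielding_plateau_is_flat(self, params):
        """Cooperative single-edge uncoiling yields a near-constant force:
        CoV < 10% over the middle 80% of the uncoiling region."""
        curve = np.array(fs.force_extension_curve(params, pull_speed=1000.0))
        ext, frc = curve[:, 0], curve[:, 1]
        x_end = ext[-1]
        sel = (ext > 0.15 * x_end) & (ext < 0.60 * x_end)
        plateau = frc[sel]
        assert plateau.std() / plateau.mean() < 0.10

    def test_linear_mode_is_hookean(self, params):
        curve = np.array(fs.force_extension_curve(params, mode="linear"))
        ext, frc = curve[:, 0], curve[:, 1]
        L0 = params.n_subunits * params.rise_A
        k = params.k_coil / params.n_subunits
        sel = frc > 0
        np.testing.assert_allclose(frc[sel], (ext[sel] - L0) * k, rtol=1e-9)

    def test_strain_hardening_convex(self, params):
        curve = np.array(fs.force_extension_curve(params,
                                                  mode="strain_hardening"))
        ext, frc = curve[:, 0], curve[:, 1]
        Lc = params.n_subunits * params.x0_B
        slope_mid = np.interp(0.51 * Lc, ext, frc) - np.interp(
            0.49 * Lc, ext, frc)
        slope_high = np.interp(0.91 * Lc, ext, frc) - np.interp(
            0.89 * Lc, ext, frc)
        assert slope_high > slope_mid

    def test_hysteresis_sign_mean_field(self, params):
        """Extension plateau > F_eq > retraction plateau at finite speed."""
        feq = fs.equilibrium_uncoiling_force(params)
        for speed in (100.0, 1000.0, 10000.0):   # nm/s = 0.1-10 um/s
            f_ext = predict_plateau_force(speed / 1000.0, "extension", params)
            f_ret = predict_plateau_force(speed / 1000.0, "retraction", params)
            assert f_ext > feq > f_ret

    def test_quasi_static_convergence(self, params):
        """Both plateaus approach F_eq within 1 pN as speed -> 0."""
        feq = fs.equilibrium_uncoiling_force(params)
        f_ext = predict_plateau_force(0.002, "extension", params)
        f_ret = predict_plateau_force(0.002, "retraction", params)
        assert abs(f_ext - feq) < 1.0
        assert abs(f_ret - feq) < 1.0

    def test_meanfield_retraction_recoils(self, params):
        ext, frc = meanfield_pull_curve(params, 500.0, retract=True,
                                        n_points=1500)
        i_max = int(np.argmax(ext))
        assert i_max < len(ext) - 10     # retraction recorded
        # force returns to a low value as the fimbria recoils
        assert frc[-1] < frc[i_max]
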