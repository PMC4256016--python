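"""Force spectroscopy: pull simulation, plateau extraction, and fitting."""

import numpy as np
import pandas as pd
import pytest

import fimsim as fs
from fimsim.afm_fit import (DEFAULT_SPEEDS_UM_S, PlateauNotFoundError,
                            PullProtocol, PullTrace, _scurve_model,
                            extract_plateau, generate_synthetic_afm_dataset)
from fimsim.io import read_tsv, write_tsv


def synthetic_plateau_trace(level=60.0, noise=2.0, seed=0):
    """Hand-built trace: linear rise, flat segment at `level`, final rise."""
    rng = np.random.default_rng(seed)
    x1 = np.linspace(0, 40, 100)          # rise at 1.5 pN/nm
    f1 = 1.5 * x1
    x2 = np.linspace(40, 3540, 1800)      # plateau
    f2 = np.full_like(x2, level)
    x3 = np.linspace(3540, 3940, 300)     # final steep rise
    f3 = level + (x3 - 3540) * 0.5
    x = np.concatenate([x1, x2, x3])
    f = np.concatenate([f1, f2, f3]) + rng.normal(0, noise, x.size)
    t = x / 1000.0
    return PullTrace(time=t, extension=x, force=f, speed=1.0)


class TestExtractPlateau:
    def test_known_flat_segment_recovered(self):
        trace = synthetic_plateau_trace(level=60.0, noise=2.0)
        assert extract_plateau(trace, "extension") == pytest.approx(60.0,
                                                                    abs=0.5)

    def test_linear_trace_signals_absence(self, params):
        curve = np.array(fs.force_extension_curve(params, mode="linear"))
        trace = PullTrace(time=curve[:, 0] / 1000.0, extension=curve[:, 0],
                          force=curve[:, 1])
        with pytest.raises(PlateauNotFoundError):
            extract_plateau(trace, "extension")

    def test_strain_hardening_signals_absence(self, params):
        curve = np.array(fs.force_extension_curve(params,
                                                  mode="strain_hardening"))
        trace = PullTrace(time=curve[:, 0] / 1000.0, extension=curve[:, 0],
                          force=curve[:, 1])
        with pytest.raises(PlateauNotFoundError):
            extract_plateau(trace, "extension")


class TestSimulatePull:
    def test_hysteresis_and_speed_dependence(self, params, rng):
        """Extension plateau > retraction plateau at 1 um/s; faster pulls
        plateau higher."""
        tr1 = fs.simulate_pull(params, PullProtocol(speed=1.0), rng)
        f_ext = extract_plateau(tr1, "extension")
        f_ret = extract_plateau(tr1, "retraction")
        assert f_ext > f_ret
        tr_slow = fs.simulate_pull(params, PullProtocol(speed=0.1), rng)
        f_slow = extract_plateau(tr_slow, "extension")
        assert f_ext > f_slow

    def test_post_plateau_curves_coincide(self, params, rng):
        """After full uncoiling the extension and retraction branches
        collapse onto one S-shaped curve (no hysteresis).

        The converged branch exists where both phases are fully uncoiled:
        above the end of the extension plateau."""
        tr = fs.simulate_pull(params, PullProtocol(speed=1.0), rng)
        nA = tr.meta["n_coiled"]
        x_max = tr.extension.max()
        sl_e = tr.phase_slice("extension")
        ext_x, ext_f, ext_nA = tr.extension[sl_e], tr.force[sl_e], nA[sl_e]
        sl_r = tr.phase_slice("retraction")
        ret_x, ret_f, ret_nA = tr.extension[sl_r], tr.force[sl_r], nA[sl_r]
        full_e = ext_nA == 0
        assert np.any(full_e)
        x_conv = ext_x[full_e].min()
        probe = np.linspace(1.01 * x_conv, 0.985 * x_max, 10)
        oe = np.argsort(ext_x)
        fe = np.interp(probe, ext_x[oe], ext_f[oe])
        o = np.argsort(ret_x)
        # retraction is also fully uncoiled over this range
        assert np.all(ret_nA[ret_x >= probe.min()] == 0)
        fr = np.interp(probe, ret_x[o], ret_f[o])
        assert np.allclose(fe, fr, atol=3.0)

    def test_stochastic_matches_meanfield_plateau(self, params, rng):
        """Stochastic and mean-field plateau predictions agree within 1 pN."""
        tr = fs.simulate_pull(params, PullProtocol(speed=1.0), rng)
        f_st = extract_plateau(tr, "extension")
        f_mf = fs.predict_plateau_force(1.0, "extension", params)
        assert abs(f_st - f_mf) < 1.0

    def test_deterministic_given_rng(self, params):
        p = PullProtocol(speed=3.0)
        t1 = fs.simulate_pull(params, p, np.random.default_rng(5))
        t2 = fs.simulate_pull(params, p, np.random.default_rng(5))
        np.testing.assert_array_equal(t1.force, t2.force)

    def test_hysteresis_area_grows_with_speed(self, params, rng):
        """Work dissipated per cycle (extension minus retraction force over
        the plateau region) is positive and increases with speed."""
        areas = []
        for sp in (0.3, 3.0):
            tr = fs.simulate_pull(params, PullProtocol(speed=sp), rng)
            sl_e = tr.phase_slice("extension")
            sl_r = tr.phase_slice("retraction")
            grid = np.linspace(0.2, 0.6, 50) * tr.extension.max()
            xe, fe = tr.extension[sl_e], tr.force[sl_e]
            xr, fr = tr.extension[sl_r][::-1], tr.force[sl_r][::-1]
            areas.append(np.trapezoid(
                np.interp(grid, xe, fe) - np.interp(grid, xr, fr), grid))
        assert 0 < areas[0] < areas[1]


class TestFitUncoiling:
    def test_parameter_recovery(self, params):
        """Plateau table generated at known parameters recovers
        (x_AB, x_BA) within 20% and the rates within a factor of two."""
        ds = generate_synthetic_afm_dataset(
            params, speeds=DEFAULT_SPEEDS_UM_S, noise_sd=1.0,
            rng=np.random.default_rng(42))
        table = ds["plateau_table"].dropna()
        fit = fs.fit_uncoiling_params(table, params)
        assert fit["x_AB"] == pytest.approx(params.x_AB, rel=0.20)
        assert fit["x_BA"] == pytest.approx(params.x_BA, rel=0.20)
        assert 0.5 < fit["k0_AB"] / params.k0_AB < 2.0
        assert 0.5 < fit["k0_BA"] / params.k0_BA < 2.0
        # recovered kinetics reproduce the equilibrium uncoiling force
        import dataclasses
        rec = dataclasses.replace(params, x_AB=fit["x_AB"], x_BA=fit["x_BA"],
                                  k0_AB=fit["k0_AB"], k0_BA=fit["k0_BA"])
        feq = fs.equilibrium_uncoiling_force(params)
        assert fs.equilibrium_uncoiling_force(rec) == pytest.approx(feq,
                                                                    abs=2.0)

    def test_single_speed_rejected(self, params):
        table = pd.DataFrame({
            "speed_um_s": [1.0, 1.0],
            "phase": ["extension", "retraction"],
            "force_pN": [45.0, 25.0]})
        with pytest.raises(ValueError):
            fs.fit_uncoiling_params(table, params)

    def test_fit_is_deterministic(self, params):
        ds = generate_synthetic_afm_dataset(
            params, speeds=(0.1, 1.0), noise_sd=1.0,
            rng=np.random.default_rng(3))
        table = ds["plateau_table"].dropna()
        f1 = fs.fit_uncoiling_params(table, params)
        f2 = fs.fit_uncoiling_params(table, params)
        assert f1["x_AB"] == f2["x_AB"] and f1["k0_BA"] == f2["k0_BA"]


class TestFitStretch:
    def _table(self, params, noise=0.0, seed=0, n=25):
        rng = np.random.default_rng(seed)
        F = np.linspace(35.0, 150.0, n)
        s = _scurve_model(F, params.k_eq, params.x_eq, params.l_pB,
                          params.l_pC, params.x0_B, params.x0_C, params.kBT)
        ext = s * params.n_subunits
        if noise > 0:
            ext = ext * (1.0 + rng.normal(0, noise, ext.size))
        return pd.DataFrame({"force_pN": F, "extension_nm": ext})

    def test_noiseless_recovery_within_10pct(self, params):
        fit = fs.fit_stretch_params(self._table(params), params.n_subunits,
                                    kBT=params.kBT)
        for key, want in (("x_eq", params.x_eq), ("l_pB", params.l_pB),
                          ("l_pC", params.l_pC), ("x0_B", params.x0_B),
                          ("x0_C", params.x0_C), ("k_eq", params.k_eq)):
            assert fit[key] == pytest.approx(want, rel=0.10), key

    def test_noisy_recovery_within_30pct(self, params):
        """With 2% multiplicative noise the identifiable parameters come
        back within 30% and the fitted curve stays faithful.

        Above the plateau the WLC fractional extensions are near
        saturation, so the persistence lengths and k_eq trade off almost
        exactly against each other under noise; the contour lengths and
        the stretch-transition distance remain identifiable, and the
        fitted curve reproduces the true one to a few per mil.
        """
        fit = fs.fit_stretch_params(
            self._table(params, noise=0.02, seed=7, n=40),
            params.n_subunits, kBT=params.kBT)
        for key, want in (("x_eq", params.x_eq), ("x0_B", params.x0_B),
                          ("x0_C", params.x0_C)):
            assert fit[key] == pytest.approx(want, rel=0.30), key
        F = np.linspace(35.0, 150.0, 40)
        s_true = _scurve_model(F, params.k_eq, params.x_eq, params.l_pB,
                               params.l_pC, params.x0_B, params.x0_C,
                               params.kBT)
        s_fit = _scurve_model(F, fit["k_eq"], fit["x_eq"], fit["l_pB"],
                              fit["l_pC"], fit["x0_B"], fit["x0_C"],
                              params.kBT)
        assert np.sqrt(np.mean((s_fit / s_true - 1.0) ** 2)) < 0.02

    def test_curve_ends_near_150_pN(self, params):
        """The fitted S-curve reaches ~150 pN at the maximum pull extension
        used by the default protocol."""
        fit = fs.fit_stretch_params(self._table(params), params.n_subunits,
                                    kBT=params.kBT)
        x_max = 0.97 * params.n_subunits * params.x0_C
        from scipy.optimize import brentq
        f_end = brentq(
            lambda F: _scurve_model(
                np.array([F]), fit["k_eq"], fit["x_eq"], fit["l_pB"],
                fit["l_pC"], fit["x0_B"], fit["x0_C"],
                params.kBT)[0] * params.n_subunits - x_max, 1.0, 500.0)
        assert f_end == pytest.approx(150.0, rel=0.20)

    def test_too_few_points_rejected(self, params):
        tbl = self._table(params).iloc[:4]
        with pytest.raises(ValueError):
            fs.fit_stretch_params(tbl, params.n_subunits)


class TestSyntheticDataset:
    def test_tables_and_roundtrip(self, params, tmp_path):
        ds = generate_synthetic_afm_dataset(
            params, speeds=(0.5, 2.0), noise_sd=0.0,
            rng=np.random.default_rng(1))
        tbl = ds["plateau_table"]
        assert len(tbl) == 4     # one row per (speed, phase)
        assert set(tbl.phase) == {"extension", "retraction"}
        path = tmp_path / "plateaus.tsv"
        write_tsv(path, tbl)
        back = read_tsv(path)
        pd.testing.assert_frame_equal(
            back.reset_index(drop=True), tbl.reset_index(drop=True),
            check_dtype=False)
        sc = ds["s_curve_table"]
        assert {"force_pN", "extension_nm",
                "normalized_extension"} <= set(sc.columns)
        assert sc["normalized_extension"].max() == pytest.approx(1.0)
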