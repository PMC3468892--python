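"""GLM estimation, contrasts, group statistics and the t/F -> Z conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal, stats

from fmriverse import model as mdl


def _events(tr=2.0):
    rows = []
    for run in range(3):
        for i, tt in enumerate(["go", "stop_success", "stop_fail"] * 4):
            rows.append({"onset": 3.0 + 9.0 * i, "duration": 1.0, "trial_type": tt, "run": run})
    return pd.DataFrame(rows)


def _design(basis="hrf", motion_scheme="m6", highpass="cutoff_128s", concat="on",
            n_per_run=60, n_runs=3, tr=2.0, seed=0):
    rng = np.random.default_rng(seed)
    motion = rng.standard_normal((n_per_run * n_runs, 6)) * 0.1
    opts = mdl.ModelOptions(basis=basis, motion=motion_scheme, highpass=highpass,
                            concat=concat)
    return mdl.build_design(_events(tr), opts, motion, tr, [n_per_run] * n_runs)


class TestCanonicalHRF:
    def test_unit_peak(self):
        h = mdl.canonical_hrf(2.0)
        assert np.isclose(np.max(np.abs(h)), 1.0)

    def test_peak_latency_between_4_and_6_seconds(self):
        # oracle: the double-gamma evaluated at 0.1 s resolution
        t = np.arange(0, 32, 0.1)
        h = stats.gamma.pdf(t, 6.0) - stats.gamma.pdf(t, 16.0) / 6.0
        assert 4.0 <= t[np.argmax(h)] <= 6.0
        assert 4.0 <= 0.1 * np.argmax(mdl.canonical_hrf(0.1)) <= 6.0

    def test_negligible_beyond_32_seconds(self):
        h = mdl.canonical_hrf(0.1, duration=48.0)
        assert np.max(np.abs(h[int(32 / 0.1):])) < 0.01


class TestFIRBasis:
    def test_single_trial_occupies_first_bin_only(self):
        ev = pd.DataFrame({"onset": [0.0], "duration": [1.0], "trial_type": ["go"], "run": [0]})
        blocks = mdl.fir_basis(ev, tr=2.0, n_scans=10)
        go = blocks["go"]
        assert go[0, 0] == 1.0
        assert go[1:, 0].sum() == 0
        assert go[0, 1:].sum() == 0

    def test_absent_condition_gives_zero_block(self):
        ev = pd.DataFrame({"onset": [0.0], "duration": [1.0], "trial_type": ["go"], "run": [0]})
        blocks = mdl.fir_basis(ev, tr=2.0, n_scans=10)
        assert not np.any(blocks["stop_success"])

    def test_total_fir_regressors_three_conditions(self):
        dm = _design(basis="fir_34_vs_baseline", motion_scheme="none", highpass="off")
        n_cond_cols = sum(len(v) for v in dm.condition_map.values())
        assert n_cond_cols == 24  # 3 conditions x 8 bins


class TestMotionRegressors:
    @pytest.mark.parametrize("scheme,n_cols", [("m6", 6), ("m12", 12), ("m24", 24)])
    def test_column_counts(self, rng, scheme, n_cols):
        motion = rng.standard_normal((50, 6))
        assert mdl.motion_regressors(motion, scheme).shape == (50, n_cols)

    def test_m24_squares(self, rng):
        motion = rng.standard_normal((50, 6))
        m24 = mdl.motion_regressors(motion, "m24")
        assert np.array_equal(m24[:, 12:18], m24[:, 0:6] ** 2)
        assert np.array_equal(m24[:, 18:24], m24[:, 6:12] ** 2)

    def test_lagged_block_first_row_zero(self, rng):
        motion = rng.standard_normal((20, 6))
        m12 = mdl.motion_regressors(motion, "m12")
        assert np.array_equal(m12[0, 6:], np.zeros(6))
        assert np.array_equal(m12[1:, 6:], motion[:-1])

    def test_all_zero_motion_pruned_from_design(self):
        opts = mdl.ModelOptions(motion="m6", highpass="off")
        dm = mdl.build_design(_events(), opts, np.zeros((180, 6)), 2.0, [60] * 3)
        assert not any(n.endswith("motion01") for n in dm.names)


class TestBuildDesign:
    def test_concat_has_one_intercept_per_run(self):
        dm = _design()
        assert sum(n.startswith("intercept_run") for n in dm.names) == 3

    def test_no_highpass_means_no_dct_columns(self):
        dm = _design(highpass="off")
        assert not any("dct" in n for n in dm.names)

    def test_minimal_hrf_design_column_count(self):
        dm = _design(motion_scheme="none", highpass="off")
        assert dm.matrix.shape[1] == 6  # 3 conditions + 3 run intercepts

    def test_concat_off_returns_one_design_per_run(self):
        dms = _design(concat="off")
        assert isinstance(dms, list) and len(dms) == 3
        assert all(d.matrix.shape[0] == 60 for d in dms)

    def test_df_residual_matches_rank(self):
        dm = _design()
        assert dm.df_residual == 180 - dm.matrix.shape[1]


class TestEstimateAR1:
    def test_white_noise_near_zero(self, rng):
        resid = rng.standard_normal((2000, 5))
        assert abs(mdl.estimate_ar1(resid)) < 0.05

    def test_recovers_rho(self, rng):
        innov = rng.standard_normal((3000, 5))
        ar = signal.lfilter([1.0], [1.0, -0.3], innov, axis=0)
        assert abs(mdl.estimate_ar1(ar) - 0.3) < 0.05

    def test_constant_series_excluded(self, rng):
        innov = rng.standard_normal((1000, 3))
        ar = signal.lfilter([1.0], [1.0, -0.4], innov, axis=0)
        ar[:, 1] = 5.0  # zero-variance voxel
        rho = mdl.estimate_ar1(ar)
        assert abs(rho - 0.4) < 0.06


class TestFitGLM:
    def test_noiseless_recovery_exact(self, rng):
        dm = _design(motion_scheme="none")
        b_true = rng.standard_normal((dm.matrix.shape[1], 7))
        Y = dm.matrix @ b_true
        fit = mdl.fit_glm(Y, dm, autocorr="off")
        assert np.allclose(fit.betas, b_true, atol=1e-8)
        assert np.all(fit.sigma2 < 1e-16)

    def test_matches_normal_equations_oracle(self, rng):
        dm = _design()
        Y = rng.standard_normal((180, 11))
        fit = mdl.fit_glm(Y, dm, autocorr="off")
        X = dm.matrix
        oracle = np.linalg.solve(X.T @ X, X.T @ Y)
        assert np.allclose(fit.betas, oracle, atol=1e-8)

    def test_zero_rho_prewhitening_equals_ols(self, rng):
        dm = _design()
        Y = rng.standard_normal((180, 4))
        a = mdl.fit_glm(Y, dm, autocorr="off")
        b = mdl.fit_glm(Y, dm, autocorr="ar1", rho=0.0)
        assert np.array_equal(a.betas, b.betas)

    def test_prewhitening_removes_autocorrelation(self, rng):
        """Whitening with the true rho leaves residual lag-1 correlation ~ 0."""
        n = 1000
        X = np.column_stack([np.ones(n), np.arange(n) / n])
        dm = mdl.DesignMatrix(X, ["intercept", "ramp"], {}, [slice(0, n)], n - 2)
        rho = 0.5
        innov = rng.standard_normal((n, 20))
        Y = signal.lfilter([1.0], [1.0, -rho], innov, axis=0)
        fit = mdl.fit_glm(Y, dm, autocorr="ar1", rho=rho)
        Yw = np.empty_like(Y)
        Yw[0] = Y[0] * np.sqrt(1 - rho**2)
        Yw[1:] = Y[1:] - rho * Y[:-1]
        resid = Yw - X @ fit.betas
        assert abs(mdl.estimate_ar1(resid)) < 0.05


class TestContrasts:
    def test_fir_34_weights(self):
        dm = _design(basis="fir_34_vs_baseline", motion_scheme="none", highpass="off")
        c = mdl.contrast_vector(dm, "fir_34_vs_baseline")
        ss = dm.condition_map["stop_success"]
        go = dm.condition_map["go"]
        assert c[ss[2]] == 0.5 and c[ss[3]] == 0.5
        assert c[go[2]] == -0.5 and c[go[3]] == -0.5
        others = np.ones(len(c), bool)
        others[[ss[2], ss[3], go[2], go[3]]] = False
        assert np.all(c[others] == 0)

    def test_t_matches_textbook_oracle(self, rng):
        dm = _design()
        Y = rng.standard_normal((180, 9)) + 0.3
        fit = mdl.fit_glm(Y, dm, autocorr="off")
        res = mdl.contrast_stat(fit, dm, "hrf")
        c = mdl.contrast_vector(dm, "hrf")
        X = dm.matrix
        xtx_inv = np.linalg.inv(X.T @ X)
        betas = xtx_inv @ X.T @ Y
        resid = Y - X @ betas
        s2 = (resid**2).sum(axis=0) / dm.df_residual
        oracle = (c @ betas) / np.sqrt(s2 * (c @ xtx_inv @ c))
        assert np.allclose(res.values, oracle, atol=1e-8)
        assert res.kind == "t" and res.df == dm.df_residual

    def test_interaction_f_nonnegative_with_df8(self, rng):
        dm = _design(basis="fir_interaction")
        Y = rng.standard_normal((180, 6))
        fit = mdl.fit_glm(Y, dm, autocorr="off")
        res = mdl.contrast_stat(fit, dm, "fir_interaction")
        assert res.kind == "F" and res.dfn == 8
        assert np.all(res.values >= 0)


class TestGroupStats:
    def test_group_df_for_13_subjects(self, rng):
        maps = rng.standard_normal((13, 50))
        t, df = mdl.group_ttest(maps)
        assert df == 12

    def test_matches_mean_over_sem_oracle(self, rng):
        maps = rng.standard_normal((9, 40)) + 0.5
        t, df = mdl.group_ttest(maps)
        oracle = maps.mean(axis=0) / (maps.std(axis=0, ddof=1) / 3.0)
        assert np.allclose(t, oracle, atol=1e-10)

    def test_identical_subjects_hit_cap_sentinel(self):
        maps = np.full((5, 10), 2.0)
        t, df = mdl.group_ttest(maps)
        assert np.all(np.isposinf(t))
        z = mdl.stat_to_z(t, df)
        assert np.all(z == mdl.Z_CAP)

    def test_hotelling_needs_more_subjects_than_bins(self, rng):
        with pytest.raises(ValueError, match="subjects"):
            mdl.group_hotelling(rng.standard_normal((6, 8, 10)))

    def test_hotelling_matches_scalar_f_for_known_shift(self, rng):
        D = rng.standard_normal((20, 8, 200)) + 1.0
        F, dfn, dfd = mdl.group_hotelling(D)
        assert dfn == 8 and dfd == 12
        # null maps should have F near its expectation, shifted maps larger
        D0 = rng.standard_normal((20, 8, 200))
        F0, _, _ = mdl.group_hotelling(D0)
        assert F.mean() > F0.mean()


class TestStatToZ:
    def test_zero_t_maps_to_zero_z(self):
        assert mdl.stat_to_z(np.array([0.0]), 12)[0] == 0.0

    def test_t_975_quantile_maps_to_196(self):
        z = mdl.stat_to_z(np.array([2.179]), 12)[0]
        assert abs(z - 1.96) < 0.01

    def test_f_zero_hits_negative_cap(self):
        z = mdl.stat_to_z(np.array([0.0]), 12, kind="F", dfn=8)[0]
        assert z == -mdl.Z_CAP

    def test_nan_propagates(self):
        z = mdl.stat_to_z(np.array([np.nan, 1.0]), 12)
        assert np.isnan(z[0]) and np.isfinite(z[1])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-35, 35), st.floats(-35, 35))
    def test_monotone_and_antisymmetric(self, t1, t2):
        z = mdl.stat_to_z(np.array([t1, t2, -t1]), 12)
        if t1 < t2:
            assert z[0] <= z[1]
            if t2 - t1 > 1e-6:  # strict beyond float resolution
                assert z[0] < z[1]
        elif t1 > t2:
            assert z[0] >= z[1]
            if t1 - t2 > 1e-6:
                assert z[0] > z[1]
        assert np.isclose(z[2], -z[0], atol=1e-9)
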