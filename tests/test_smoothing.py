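import numpy as np
import pandas as pd
import pytest

from tonguefan.smoothing import (
    ModelSpec,
    adjusted_r2,
    build_design,
    check_basis,
    estimate_ar1,
    fit,
    fit_smooth_1d,
    predict,
)
from tests.conftest import two_condition_frame


class TestDesign:
    def test_two_level_dimension_accounting(self):
        df = two_condition_frame(n_contours=5)
        spec = ModelSpec(factor="cond", factor_levels=("A", "B"))
        info = build_design(spec, df)
        # intercept + 1 contrast + 9 reference + 9 difference
        assert info.ncol == 1 + 1 + 9 + 9
        assert info.n_lambda == 2
        assert info.n_unpenalized == 2

    def test_single_level_reduces(self):
        df = two_condition_frame(n_contours=5)
        spec = ModelSpec(factor=None)
        info = build_design(spec, df)
        assert info.ncol == 1 + 9
        assert info.n_lambda == 1

    def test_random_block_accounting(self):
        df = two_condition_frame(n_contours=10)
        df["subject"] = "s" + (df["contour_id"] % 5).astype(str)
        spec = ModelSpec(factor="cond", random_terms=(("subject", None),))
        info = build_design(spec, df)
        # 5 subjects x 10 basis columns under 2 shared penalties
        name = "s(theta,subject)"
        sl = info.term_slices[name]
        assert sl.stop - sl.start == 50
        assert info.n_lambda == 2 + 2
        blk = [b for b in info.blocks if b.name == name][0]
        assert len(blk.mats) == 2 and blk.null_dim == 0

    def test_unused_level_dropped_with_warning(self):
        df = two_condition_frame(n_contours=5)
        spec = ModelSpec(factor="cond", factor_levels=("A", "B", "C"))
        with pytest.warns(UserWarning, match="no rows"):
            info = build_design(spec, df)
        assert info.factor_levels == ("A", "B")

    def test_sum_to_zero_constraint(self):
        df = two_condition_frame(n_contours=5)
        info = build_design(ModelSpec(factor=None), df)
        ref = info.X[:, info.term_slices["s(theta)"]]
        assert np.allclose(ref.mean(axis=0), 0.0, atol=1e-10)


class TestFit:
    def test_null_signal_shrinks_flat(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "theta": rng.uniform(-2.8, -0.5, 2000),
                "rho": 5.0 + rng.standard_normal(2000),
                "contour_id": np.repeat(np.arange(40), 50),
            }
        )
        f = fit(ModelSpec(factor=None), df)
        assert f.edf["s(theta)"] <= 1.5

    def test_fixed_lambda_matches_dense_oracle(self):
        df = two_condition_frame(n_contours=8, seed=2)
        df["subject"] = "s" + (df["contour_id"] % 4).astype(str)
        spec = ModelSpec(factor="cond", random_terms=(("subject", None),))
        info = build_design(spec, df)
        lams = np.array([0.7, 3.0, 11.0, 2.0])
        f = fit(spec, df, lambdas=lams)
        A = info.X.T @ info.X
        for b in info.blocks:
            b.add_to(A, lams)
        beta = np.linalg.solve(A, info.X.T @ df["rho"].to_numpy())
        assert np.abs(beta - f.beta).max() < 1e-8

    def test_bump_recovery_with_ar_noise(self):
        df = two_condition_frame(
            n_contours=40, noise_sd=3.0, phi=0.8, seed=4, diff_amplitude=0.0
        )
        df = df[df["cond"] == "A"].reset_index(drop=True)
        f = fit(ModelSpec(factor=None, ar_phi="estimate"), df)
        assert abs(f.ar_phi - 0.8) < 0.05
        th = np.linspace(-2.8, -0.5, 100)
        truth = 350.0 + 30.0 * np.exp(-0.5 * ((th + 1.5) / 0.4) ** 2)
        est, _ = predict(f, pd.DataFrame({"theta": th}))
        rmse = np.sqrt(np.mean((est - truth) ** 2))
        assert rmse < 0.5 * 3.0

    def test_lambda_infinity_gives_least_squares_line(self):
        # as lambda grows the smooth collapses onto its null space: the
        # least-squares line (checked as a convergence trend; far larger
        # lambdas make the solve numerically ill-conditioned)
        df = two_condition_frame(n_contours=10, seed=6)
        df = df[df["cond"] == "A"].reset_index(drop=True)
        th = df["theta"].to_numpy()
        line = np.polyval(np.polyfit(th, df["rho"].to_numpy(), 1), th)
        devs = []
        for lam in (1e4, 1e6, 1e8):
            f = fit(ModelSpec(factor=None), df, lambdas=np.array([lam]))
            est, _ = predict(f, df)
            devs.append(np.abs(est - line).max())
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] < 0.05
        assert f.edf_total == pytest.approx(2.0, abs=0.01)

    def test_reml_history_non_increasing(self):
        df = two_condition_frame(n_contours=10, seed=7)
        f = fit(ModelSpec(factor="cond"), df)
        h = f.reml_history
        assert len(h) >= 2
        assert all(a >= b for a, b in zip(h, h[1:]))

    def test_min_rows_enforced(self):
        df = two_condition_frame(n_contours=1, n_points=10)
        with pytest.raises(ValueError, match="at least"):
            fit(ModelSpec(factor="cond"), df)


class TestAR1:
    def test_white_noise_null(self):
        rng = np.random.default_rng(0)
        r = rng.standard_normal(10_000)
        g = np.repeat(np.arange(200), 50)
        assert estimate_ar1(r, g) < 0.05

    def test_ar_recovery(self):
        rng = np.random.default_rng(1)
        n = 50_000
        e = np.empty(n)
        e[0] = rng.standard_normal()
        innov = rng.standard_normal(n - 1) * np.sqrt(1 - 0.81)
        for t in range(1, n):
            e[t] = 0.9 * e[t - 1] + innov[t - 1]
        g = np.repeat(np.arange(n // 100), 100)
        assert abs(estimate_ar1(e, g) - 0.9) < 0.02

    def test_whitening_removes_autocorrelation(self):
        df = two_condition_frame(n_contours=40, noise_sd=3.0, phi=0.8, seed=4)
        df = df[df["cond"] == "A"].reset_index(drop=True)
        f = fit(ModelSpec(factor=None, ar_phi="estimate"), df)
        # residuals of the whitened refit
        resid_ac = check_basis(f)["residual_ar1"]
        assert resid_ac < 0.1

    def test_no_pairs_error(self):
        with pytest.raises(ValueError):
            estimate_ar1(np.ones(5), np.arange(5))


class TestPredict:
    def test_fitted_values_at_data(self):
        df = two_condition_frame(n_contours=10, seed=8)
        df["subject"] = "s" + (df["contour_id"] % 3).astype(str)
        spec = ModelSpec(factor="cond", random_terms=(("subject", None),))
        f = fit(spec, df)
        est, se = predict(f, df)
        assert np.allclose(est, f.fitted, atol=1e-10)
        assert np.all(se > 0)

    def test_se_larger_outside_range(self):
        df = two_condition_frame(n_contours=20, seed=9)
        f = fit(ModelSpec(factor=None), df[df.cond == "A"].reset_index(drop=True))
        inside = pd.DataFrame({"theta": [-1.6]})
        outside = pd.DataFrame({"theta": [0.5]})
        _, se_in = predict(f, inside)
        _, se_out = predict(f, outside)
        assert se_out[0] > se_in[0]

    def test_excluding_degenerate_randoms(self):
        df = two_condition_frame(n_contours=10, seed=10)
        df["subject"] = "s" + (df["contour_id"] % 5).astype(str)
        spec = ModelSpec(factor="cond", random_terms=(("subject", None),))
        # force the random curves to zero amplitude with a huge penalty
        f = fit(spec, df, lambdas=np.array([1.0, 1.0, 1e12, 1e12]))
        est_with, _ = predict(f, df, include_random=True)
        est_without, _ = predict(f, df, include_random=False)
        assert np.abs(est_with - est_without).max() < 1e-6

    def test_unseen_level_error(self):
        df = two_condition_frame(n_contours=10, seed=11)
        df["subject"] = "s" + (df["contour_id"] % 5).astype(str)
        f = fit(ModelSpec(factor="cond", random_terms=(("subject", None),)), df)
        nd = pd.DataFrame({"theta": [-1.5], "cond": ["A"], "subject": ["zz"]})
        with pytest.raises(ValueError, match="unseen"):
            predict(f, nd, include_random=True)
        est, _ = predict(f, nd, include_random=False)  # fine without randoms
        assert np.isfinite(est).all()


class TestR2:
    def test_perfect_fit(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(-2.8, -0.5, 500)
        df = pd.DataFrame({"theta": th, "rho": 2.0 + 3.0 * th, "contour_id": 0})
        f = fit(ModelSpec(factor=None), df)
        assert adjusted_r2(f) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {
                "theta": rng.uniform(-2.8, -0.5, 10_000),
                "rho": rng.standard_normal(10_000),
                "contour_id": np.repeat(np.arange(200), 50),
            }
        )
        f = fit(ModelSpec(factor=None), df)
        assert abs(adjusted_r2(f)) < 0.05

    def test_matches_direct_formula(self):
        df = two_condition_frame(n_contours=5, seed=12)
        f = fit(ModelSpec(factor="cond"), df)
        y = df["rho"].to_numpy()
        n = len(y)
        rss = np.sum(f.residuals**2)
        tss = np.sum((y - y.mean()) ** 2)
        expect = 1 - (rss / (n - f.edf_total)) / (tss / (n - 1))
        assert adjusted_r2(f) == pytest.approx(expect, abs=1e-10)


class TestCheckBasis:
    def test_moderate_signal_not_flagged(self):
        # a signal needing ~3-4 EDF sits well below the k=10 ceiling
        rng = np.random.default_rng(13)
        th = np.linspace(-2.8, -0.5, 60)
        rows = [
            pd.DataFrame(
                {
                    "contour_id": c,
                    "theta": th,
                    "rho": 10 * np.sin(th) + rng.standard_normal(60),
                }
            )
            for c in range(20)
        ]
        f = fit(ModelSpec(factor=None), pd.concat(rows, ignore_index=True))
        rep = check_basis(f)
        assert not rep["terms"]["s(theta)"]["flagged"]

    def test_high_frequency_signal_flagged_with_small_k(self):
        rng = np.random.default_rng(14)
        th = np.linspace(-2.8, -0.5, 60)
        rows = []
        for c in range(30):
            rows.append(
                pd.DataFrame(
                    {
                        "contour_id": c,
                        "theta": th,
                        "rho": np.sin(8 * th) * 10 + 0.3 * rng.standard_normal(60),
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True)
        f = fit(ModelSpec(factor=None, k=4), df)
        assert check_basis(f)["terms"]["s(theta)"]["flagged"]

    def test_null_signal_not_flagged(self):
        rng = np.random.default_rng(15)
        df = pd.DataFrame(
            {
                "theta": rng.uniform(-2.8, -0.5, 1000),
                "rho": rng.standard_normal(1000),
                "contour_id": np.repeat(np.arange(20), 50),
            }
        )
        f = fit(ModelSpec(factor=None), df)
        assert not check_basis(f)["terms"]["s(theta)"]["flagged"]


def test_smooth_1d_interface():
    rng = np.random.default_rng(2)
    x = np.linspace(0, 1, 300)
    y = np.sin(2 * np.pi * x) + 0.1 * rng.standard_normal(300)
    sm = fit_smooth_1d(x, y)
    est, se = sm.predict(x, se=True)
    assert np.sqrt(np.mean((est - np.sin(2 * np.pi * x)) ** 2)) < 0.1
    assert np.all(se > 0)
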