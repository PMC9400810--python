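import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cardioeeg.coupling import (
    PREDICTOR_ORDER,
    best_subset_regression,
    correlogram_frame,
    group_compare,
    regression_battery,
    spearman,
    spearman_correlogram,
)


def enumerate_spearman_p(x, y):
    """Independent oracle: two-sided exact permutation p by full enumeration."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float((a * b).sum() / np.sqrt((a**2).sum() * (b**2).sum()))

    obs = abs(rho(rx, ry))
    count = 0
    total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho(rx, np.asarray(perm))) >= obs - 1e-12:
            count += 1
    return count / total


class TestSpearman:
    def test_hand_worked_example(self):
        # d^2 = 4+1+1+1+1 = 8 -> rho = 1 - 6*8/(5*24) = 0.6
        rho, _ = spearman([1, 2, 3, 4, 5], [3, 1, 2, 5, 4])
        assert rho == pytest.approx(0.6, abs=1e-12)

    def test_monotone_map_gives_rho_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0, 20.0])
        y = np.exp(x)  # strictly monotone
        rho, p = spearman(x, y)
        assert rho == pytest.approx(1.0)
        # exact minimum two-sided p at n=5: only identity and reversal
        assert p == pytest.approx(2 / 120, abs=1e-12)

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_exact_p_matches_enumeration(self, n, rng):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        _, p = spearman(x, y)
        assert p == pytest.approx(enumerate_spearman_p(x, y), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(np.exp(x), y**3 + 5 * y)
        # y**3+5y is strictly increasing
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_constant_variable_undefined(self):
        rho, p = spearman([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
        assert np.isnan(rho) and np.isnan(p)

    def test_large_n_t_approximation(self, rng):
        x = rng.standard_normal(30)
        y = x + 0.5 * rng.standard_normal(30)
        rho, p = spearman(x, y)
        rho_sp, p_sp = stats.spearmanr(x, y)
        assert rho == pytest.approx(rho_sp, abs=1e-12)
        assert p == pytest.approx(p_sp, rel=1e-6)


def make_tables(rng, n=8, rho_sign=1.0):
    subjects = [f"s{i}" for i in range(n)]
    tone = rng.standard_normal(n)
    rows = []
    for band in ("theta", "alpha1"):
        for (roi, hemi) in (("F", "L"), ("F", "R"), ("C", "L")):
            for i, s in enumerate(subjects):
                rows.append({"subject": s, "band": band, "roi": roi,
                             "hemisphere": hemi,
                             "power_db": rho_sign * tone[i]
                             + 0.1 * rng.standard_normal()})
    powers = pd.DataFrame(rows)
    hrv = pd.DataFrame({
        "subject": subjects,
        "sdnn_ms": 50 + 10 * tone + rng.standard_normal(n),
        "rmssd_ms": 40 + 8 * tone + rng.standard_normal(n),
        "sd1_ms": (40 + 8 * tone + rng.standard_normal(n)) / np.sqrt(2),
        "hf_ms2": 800 + 100 * tone + 10 * rng.standard_normal(n),
    })
    return powers, hrv


class TestCorrelogram:
    def test_shape_and_filter_rule(self, rng):
        powers, hrv = make_tables(rng)
        cells = spearman_correlogram(powers, hrv, "RE-like")
        assert len(cells) == 2 * 3 * 4  # bands x roi-hemi x hrv params
        frame = correlogram_frame(cells)
        manual = (frame["rho"].abs() >= 0.5) & (frame["p"] < 0.05)
        assert frame["passes_report_filter"].equals(manual)

    def test_sign_recovery(self, rng):
        powers, hrv = make_tables(rng, n=11, rho_sign=1.0)
        frame = correlogram_frame(spearman_correlogram(powers, hrv, "g"))
        assert (frame["rho"] > 0).mean() > 0.9
        powers, hrv = make_tables(rng, n=11, rho_sign=-1.0)
        frame = correlogram_frame(spearman_correlogram(powers, hrv, "g"))
        assert (frame["rho"] < 0).mean() > 0.9

    def test_too_few_subjects(self, rng):
        powers, hrv = make_tables(rng, n=4)
        with pytest.raises(ValueError, match=">= 5"):
            spearman_correlogram(powers, hrv, "g")


class TestGroupCompare:
    def test_identical_groups_p_one(self, rng):
        vals = {"SDNN": rng.standard_normal(8)}
        out = group_compare(vals, {"SDNN": vals["SDNN"].copy()}, family_size=4)
        assert out["SDNN"]["p_corrected"] == 1.0

    def test_bonferroni_definition_oracle(self, rng):
        for _ in range(100):
            a = {"v": rng.standard_normal(9)}
            b = {"v": rng.standard_normal(7) + rng.uniform(-1, 1)}
            m = int(rng.integers(1, 50))
            out = group_compare(a, b, family_size=m)
            _, p_raw = stats.f_oneway(a["v"], b["v"])
            assert out["v"]["p_corrected"] == pytest.approx(min(1.0, m * p_raw))

    def test_separated_groups_detected(self):
        hits = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            a = {"v": r.standard_normal(11)}
            b = {"v": r.standard_normal(7) + 3.0}
            out = group_compare(a, b, family_size=1)
            hits += out["v"]["p_corrected"] < 0.05
        assert hits / 40 >= 0.95

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            group_compare({"v": np.ones(5)}, {"v": np.ones(5)})

    def test_mismatched_variables_rejected(self, rng):
        with pytest.raises(ValueError, match="share"):
            group_compare({"a": rng.standard_normal(5)},
                          {"b": rng.standard_normal(5)})


def random_predictors(rng, n):
    return pd.DataFrame(
        {p: rng.standard_normal(n) for p in PREDICTOR_ORDER}
    )


class TestBestSubset:
    def test_exact_planted_model_recovered(self, rng):
        n = 12
        X = random_predictors(rng, n)
        y = 2.0 + 3.0 * X["F"].to_numpy()
        fit = best_subset_regression(X, y)
        assert fit.included_predictors == ("F",)
        assert fit.coefficients["F"] == pytest.approx(3.0, abs=1e-9)
        assert fit.coefficients["intercept"] == pytest.approx(2.0, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.r2_adj == pytest.approx(1.0, abs=1e-12)

    def test_adjusted_r2_definition_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(8, 20))
            X = random_predictors(rng, n)
            y = X.to_numpy() @ rng.standard_normal(5) + rng.standard_normal(n)
            fit = best_subset_regression(X, y)
            k = len(fit.included_predictors)
            expected = 1 - (1 - fit.r2) * (n - 1) / (n - k - 1)
            assert fit.r2_adj == pytest.approx(expected, rel=1e-12)

    def test_selected_beats_full_model(self, rng):
        for seed in range(20):
            r = np.random.default_rng(seed)
            n = 14
            X = random_predictors(r, n)
            y = 1.5 * X["C"].to_numpy() + r.standard_normal(n)
            fit = best_subset_regression(X, y)
            # fit the full model directly
            Xf = np.column_stack([np.ones(n), X.to_numpy()])
            beta, *_ = np.linalg.lstsq(Xf, y, rcond=None)
            resid = y - Xf @ beta
            r2_full = 1 - (resid**2).sum() / ((y - y.mean()) ** 2).sum()
            r2_adj_full = 1 - (1 - r2_full) * (n - 1) / (n - 5 - 1)
            assert fit.r2_adj >= r2_adj_full - 1e-12

    def test_saturated_flag_n7_full_model(self, rng):
        n = 7
        X = random_predictors(rng, n)
        # response built from all five predictors so the full model can win
        y = X.to_numpy() @ np.array([3.0, -2.0, 1.5, 2.5, -1.0])
        fit = best_subset_regression(X, y)
        if len(fit.included_predictors) == 5:
            assert fit.saturated
        assert fit.meta["residual_df"] == n - len(fit.included_predictors) - 1

    def test_pearson_residuals_zero_sum_and_scaling(self, rng):
        n = 15
        X = random_predictors(rng, n)
        y = X["T"].to_numpy() + rng.standard_normal(n)
        fit = best_subset_regression(X, y)
        # residuals of an intercept model sum to zero; Pearson scaling is a
        # positive constant, so the scaled residuals do too
        assert abs(fit.pearson_residuals.sum()) < 1e-9
        # Pearson residuals have mean-square ~= 1 by construction:
        # sum(r^2) = SSE / (SSE/(n-k-1)) = n-k-1
        k = len(fit.included_predictors)
        assert (fit.pearson_residuals**2).sum() == pytest.approx(n - k - 1, rel=1e-9)
        assert np.isfinite(fit.shapiro_w) and np.isfinite(fit.shapiro_p)

    def test_rescaling_equivariance(self, rng):
        n = 12
        X = random_predictors(rng, n)
        y = 4.0 * X["F"].to_numpy() + 0.01 * rng.standard_normal(n)
        fit1 = best_subset_regression(X, y)
        X2 = X.copy()
        c = 10.0
        X2["F"] = c * X2["F"]
        fit2 = best_subset_regression(X2, y)
        assert fit2.coefficients["F"] == pytest.approx(
            fit1.coefficients["F"] / c, rel=1e-9
        )

    def test_zero_variance_response_rejected(self, rng):
        X = random_predictors(rng, 10)
        with pytest.raises(ValueError, match="zero variance"):
            best_subset_regression(X, np.ones(10))

    def test_too_few_subjects_rejected(self, rng):
        X = random_predictors(rng, 3)
        with pytest.raises(ValueError, match=">= 4"):
            best_subset_regression(X, rng.standard_normal(3))


class TestRegressionBattery:
    def test_battery_runs_per_band_hemisphere(self, rng):
        subjects = [f"s{i}" for i in range(10)]
        rows = []
        for band in ("theta",):
            for hemi in ("L", "R"):
                for roi in PREDICTOR_ORDER:
                    for s in subjects:
                        rows.append({"subject": s, "band": band, "roi": roi,
                                     "hemisphere": hemi,
                                     "power_db": rng.standard_normal()})
        powers = pd.DataFrame(rows)
        hrv = pd.DataFrame({
            "subject": subjects,
            "sdnn_ms": rng.uniform(30, 80, 10),
            "rmssd_ms": rng.uniform(20, 60, 10),
            "sd1_ms": rng.uniform(15, 45, 10),
            "hf_ms2": rng.uniform(300, 1500, 10),
        })
        fits = regression_battery(powers, hrv, group="g")
        assert len(fits) == 2 * 3  # hemisphere x (HF, RMSSD, SDNN)
        for f in fits:
            assert set(f.included_predictors) <= set(PREDICTOR_ORDER)
            assert f.r2_adj <= f.r2 <= 1.0
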