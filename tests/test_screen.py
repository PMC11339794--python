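"""OLS fitting and the exhaustive best-subset screen."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from amsteric.screen import (
    ModelFit,
    ScreenConfig,
    apply_filter,
    apply_robustness,
    fit_ols,
    report,
    screen,
)
from amsteric.synth import TableSpec, simulate_table


class TestFitOLS:
    def test_exact_linear_relation(self):
        x = np.linspace(0, 10, 20)
        y = 2.0 * x - 3.0
        fit = fit_ols(x, y, variables=["x"])
        assert fit.r2 == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-10)
        assert fit.coefficients[0] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(-3.0)

    def test_constant_response_degenerate_guard(self):
        x = np.arange(10.0)
        y = np.full(10, 4.2)
        fit = fit_ols(x, y)
        assert fit.r2 == 0.0
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-12)

    def test_planted_two_variable_model_recovered(self):
        rng = np.random.default_rng(42)
        n = 200
        x1, x2 = rng.uniform(0, 10, n), rng.uniform(-5, 5, n)
        y = 2.5 * x1 - 1.0 * x2 + 3.0 + rng.normal(0, 1.0, n)
        df = pd.DataFrame({"x1": x1, "x2": x2})
        fit = fit_ols(df, y)
        # standard errors from the unbiased residual variance
        A = np.column_stack([np.ones(n), x1, x2])
        resid = y - fit.predict(df)
        sigma2 = resid @ resid / (n - 3)
        cov = sigma2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        for est, truth, s in zip(
            (fit.intercept, *fit.coefficients), (3.0, 2.5, -1.0), se
        ):
            assert abs(est - truth) <= 3 * s

    def test_r2_equals_squared_pearson_of_fit(self):
        """1 − SS_res/SS_tot coincides with the squared correlation between
        fitted and observed values for OLS with intercept."""
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.uniform(0, 1, size=(30, 2)), columns=["a", "b"])
        y = 1.2 * df.a - 0.7 * df.b + rng.normal(0, 0.3, 30)
        fit = fit_ols(df, y)
        r = np.corrcoef(fit.predict(df), y)[0, 1]
        assert fit.r2 == pytest.approx(r**2, abs=1e-12)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(19)
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = 0.5 * X.a - 2.0 * X.c + rng.normal(0, 0.5, 40)
        fit = fit_ols(X, y)
        ref = sm.OLS(y, sm.add_constant(X)).fit()
        assert fit.intercept == pytest.approx(ref.params["const"], abs=1e-9)
        np.testing.assert_allclose(fit.coefficients, ref.params[list("abc")], atol=1e-9)
        assert fit.r2 == pytest.approx(ref.rsquared, abs=1e-12)

    def test_rank_deficiency_names_columns(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(np.linalg.LinAlgError, match="a"):
            fit_ols(df, np.arange(10.0))

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="n >= p \\+ 2"):
            fit_ols(np.arange(2.0), np.arange(2.0))

    def test_affine_rescaling_of_candidates(self):
        """R² is invariant under x -> a·x + b; the slope transforms by 1/a."""
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1, 50)
        y = 3.0 * x + rng.normal(0, 0.1, 50)
        f1 = fit_ols(x, y)
        f2 = fit_ols(5.0 * x - 2.0, y)
        assert f2.r2 == pytest.approx(f1.r2, abs=1e-12)
        assert f2.coefficients[0] == pytest.approx(f1.coefficients[0] / 5.0, abs=1e-10)

    def test_rmse_conventions(self):
        x = np.arange(12.0)
        y = x + np.resize([0.5, -0.5], 12)
        fit = fit_ols(x, y)
        assert fit.rmse == pytest.approx(math.sqrt(((y - fit.predict(pd.DataFrame({"x0": x}))) ** 2).mean()))
        assert fit.rmse_unbiased > fit.rmse


class TestRobustness:
    def test_clip_mode(self):
        df = pd.DataFrame({"y": [-3.0, 2.0, -1.0]})
        out = apply_robustness(df, "y", "clip_negative_to_zero")
        assert out["y"].tolist() == [0.0, 2.0, 0.0]
        assert df["y"].tolist() == [-3.0, 2.0, -1.0]  # input untouched

    def test_drop_mode(self):
        df = pd.DataFrame({"y": [-3.0, 2.0, -1.0], "x": [1, 2, 3]})
        out = apply_robustness(df, "y", "drop_negative")
        assert out["y"].tolist() == [2.0]
        assert out["x"].tolist() == [2]

    def test_nan_responses_survive(self):
        df = pd.DataFrame({"y": [np.nan, -1.0, 5.0]})
        clip = apply_robustness(df, "y", "clip_negative_to_zero")
        assert np.isnan(clip["y"].iloc[0])
        drop = apply_robustness(df, "y", "drop_negative")
        assert len(drop) == 2  # NaN is not negative; listwise deletion handles it later


class TestScreen:
    @pytest.fixture
    def planted(self):
        spec = TableSpec(
            n_rows=60,
            columns={
                "x1": (0, 10), "x2": (0, 10), "x3": (0, 10),
                "x4": (0, 10), "x5": (0, 10),
            },
            active={"x3": 2.0},
            intercept=1.0,
            noise_sd=0.5,
            seed=5,
            response="y",
        )
        return simulate_table(spec)

    def test_single_candidate_equals_fit_ols(self, planted):
        df, _ = planted
        cfg = ScreenConfig(response="y", candidates=("x3",), max_vars=1)
        res = screen(df, cfg)
        direct = fit_ols(df[["x3"]], df["y"].to_numpy())
        assert res.best(1).r2 == pytest.approx(direct.r2, abs=1e-12)
        assert res.n_subsets_evaluated == 1

    def test_subset_count_is_binomial_sum(self, planted):
        df, _ = planted
        k = 5
        cfg = ScreenConfig(response="y", candidates=tuple(df.columns[:k]), max_vars=3)
        res = screen(df, cfg)
        expected = math.comb(k, 1) + math.comb(k, 2) + math.comb(k, 3)
        assert res.n_subsets_evaluated == expected

    def test_active_variable_tops_the_one_variable_ranking(self, planted):
        df, truth = planted
        cfg = ScreenConfig(
            response="y", candidates=("x1", "x2", "x3", "x4", "x5"), max_vars=1
        )
        res = screen(df, cfg)
        assert res.best(1).variables == ("x3",)

    def test_matches_independent_brute_force(self, planted):
        """Best fit per size agrees with a direct re-enumeration via numpy."""
        df, _ = planted
        cands = ("x1", "x2", "x3", "x4", "x5")
        cfg = ScreenConfig(response="y", candidates=cands, max_vars=3)
        res = screen(df, cfg)
        y = df["y"].to_numpy()
        for size in (1, 2, 3):
            best_r2, best_vars = -1.0, None
            for subset in itertools.combinations(cands, size):
                A = np.column_stack([np.ones(len(df))] + [df[c] for c in subset])
                beta, *_ = np.linalg.lstsq(A, y, rcond=None)
                resid = y - A @ beta
                r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
                if r2 > best_r2:
                    best_r2, best_vars = r2, tuple(sorted(subset))
            assert res.best(size).variables == best_vars
            assert res.best(size).r2 == pytest.approx(best_r2, abs=1e-10)

    def test_listwise_deletion_per_subset(self):
        spec = TableSpec(
            n_rows=80,
            columns={"x1": (0, 1), "x2": (0, 1)},
            active={"x1": 1.0},
            noise_sd=0.1,
            missing_rate=0.2,
            seed=9,
            response="y",
        )
        df, _ = simulate_table(spec)
        cfg = ScreenConfig(response="y", candidates=("x1", "x2"), max_vars=2)
        res = screen(df, cfg)
        for size, fits in res.fits_by_size.items():
            for fit in fits:
                expected_n = len(df[list(fit.variables) + ["y"]].dropna())
                assert fit.n == expected_n

    def test_strict_filter_reduces_rows(self):
        df = pd.DataFrame({
            "pyramidalization": [0.40, 0.45, 0.450, 0.46, 0.55, np.nan],
            "x": [1.0, 2, 3, 4, 5, 6],
            "y": [1.0, 2, 3, 4, 5, 6],
        })
        kept = apply_filter(df, "pyramidalization", 0.450)
        assert len(kept) == 2  # strictly greater; 0.450 itself and NaN drop

    def test_filter_threads_through_screen(self):
        rng = np.random.default_rng(0)
        n = 40
        df = pd.DataFrame({
            "pyramidalization": rng.uniform(0.3, 0.6, n),
            "x": rng.uniform(0, 1, n),
        })
        df["y"] = 2 * df.x + rng.normal(0, 0.1, n)
        cfg = ScreenConfig(
            response="y", candidates=("x",), max_vars=1,
            filter=("pyramidalization", 0.450),
        )
        res = screen(df, cfg)
        expected = int((df.pyramidalization > 0.450).sum())
        assert res.best(1).n == expected

    def test_robustness_modes_through_screen(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = df.x - 3.0  # negatives for x < 3
        clip = screen(df, ScreenConfig("y", ("x",), 1, robustness="clip_negative_to_zero"))
        drop = screen(df, ScreenConfig("y", ("x",), 1, robustness="drop_negative"))
        plain = screen(df, ScreenConfig("y", ("x",), 1))
        assert plain.best(1).r2 == pytest.approx(1.0)
        assert drop.best(1).n == 7
        assert drop.best(1).r2 == pytest.approx(1.0)
        assert clip.best(1).n == 10
        assert clip.best(1).r2 < 1.0  # clipping bends the true linear relation

    def test_no_feasible_subset_is_an_error(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="no candidate subset"):
            screen(df, ScreenConfig("y", ("x",), 1))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScreenConfig("y", ("y", "x"), 1)
        with pytest.raises(ValueError):
            ScreenConfig("y", (), 1)
        with pytest.raises(ValueError):
            ScreenConfig("y", ("x",), 4)
        with pytest.raises(ValueError):
            ScreenConfig("y", ("x", "x"), 1)


class TestParameterRecovery:
    def test_true_pair_tops_two_variable_ranking_in_95_pct_of_tables(self):
        """Over 100 seeded tables (n=50, 8 candidates, 2 active, noise well
        below the planted signal) the active pair is the best 2-variable
        model in at least 95% of draws."""
        cols = {f"x{i}": (0.0, 1.0) for i in range(1, 9)}
        hits = 0
        for seed in range(100):
            df, _ = simulate_table(TableSpec(
                n_rows=50, columns=cols, active={"x3": 5.0, "x6": -4.0},
                intercept=1.0, noise_sd=1.0, seed=seed, response="y",
            ))
            res = screen(df, ScreenConfig("y", tuple(cols), max_vars=2))
            hits += set(res.best(2).variables) == {"x3", "x6"}
        assert hits >= 95


class TestReport:
    def test_ledger_round_trips_through_csv(self, tmp_path):
        df, _ = simulate_table(TableSpec(seed=2))
        res = screen(df, ScreenConfig("dg", ("vbur_total", "pka", "e_lumo"), 2))
        ledger = report({"dg": res})
        p = tmp_path / "ledger.csv"
        ledger.to_csv(p, index=False)
        back = pd.read_csv(p)
        assert len(back) == len(ledger)
        np.testing.assert_allclose(back["r2"], ledger["r2"])
        assert (back["variables"] == ledger["variables"]).all()

    def test_one_row_per_ranked_fit(self):
        df, _ = simulate_table(TableSpec(seed=3))
        res = screen(df, ScreenConfig("dg", ("vbur_total", "pka"), 2, top_k=5))
        ledger = report({"run": res})
        expected = sum(len(f) for f in res.fits_by_size.values())
        assert len(ledger) == expected
        assert set(ledger["screen"]) == {"run"}
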