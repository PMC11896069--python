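"""Collinearity screening, best-subsets scoring, ln-scale fitting, prediction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from miombo_aba.modelsel import (
    enumerate_subsets,
    fit_log_mlr,
    predict_attribute,
    screen_collinear,
    select_and_fit,
)


def random_design(rng, n=30, p=5, names=None):
    X = rng.normal(0, 1, (n, p))
    names = names or [f"x{i}" for i in range(p)]
    return pd.DataFrame(X, columns=names)


def oracle_screen(df, y, threshold):
    """Independent greedy re-implementation of the documented drop rule."""
    cols = [c for c in df.columns if df[c].std() > 0]
    resp = {c: abs(np.corrcoef(df[c], y)[0, 1]) for c in cols}
    alive = sorted(cols)
    while True:
        worst = None
        for a, b in combinations(sorted(alive), 2):
            r = abs(np.corrcoef(df[a], df[b])[0, 1])
            if r > threshold and (worst is None or r > worst[0]):
                worst = (r, a, b)
        if worst is None:
            return [c for c in df.columns if c in alive]
        _, a, b = worst
        if resp[a] > resp[b]:
            alive.remove(b)
        elif resp[b] > resp[a]:
            alive.remove(a)
        else:
            alive.remove(max(a, b))


class TestScreen:
    def test_duplicate_column_drops_one(self, rng):
        df = random_design(rng, 40, 3)
        df["x3"] = df["x0"]
        y = rng.normal(0, 1, 40)
        kept = screen_collinear(df, y, 0.85)
        assert ("x0" in kept) != ("x3" in kept)

    def test_uncorrelated_set_unchanged(self, rng):
        df = random_design(rng, 200, 4)
        y = rng.normal(0, 1, 200)
        assert screen_collinear(df, y, 0.85) == list(df.columns)

    def test_constant_columns_dropped_first(self, rng):
        df = random_design(rng, 50, 2)
        df["const"] = 1.0
        kept = screen_collinear(df, rng.normal(0, 1, 50), 0.85)
        assert "const" not in kept

    def test_all_constant_rejected(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        with pytest.raises(ValueError):
            screen_collinear(df, np.arange(10.0), 0.85)

    def test_matches_greedy_oracle(self, rng):
        """Six deliberately collinear predictors resolve exactly as the
        documented descending-|r| greedy procedure does."""
        n = 60
        base = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {
                "a": base + rng.normal(0, 0.1, n),
                "b": base + rng.normal(0, 0.1, n),
                "c": base + rng.normal(0, 0.5, n),
                "d": rng.normal(0, 1, n),
                "e": rng.normal(0, 1, n),
            }
        )
        df["f"] = df["d"] + rng.normal(0, 0.2, n)
        y = base + rng.normal(0, 0.5, n)
        assert screen_collinear(df, y, 0.85) == oracle_screen(df, y, 0.85)


class TestEnumerate:
    def test_subset_combinatorics(self, rng):
        df = random_design(rng, 25, 3)
        y = rng.normal(0, 1, 25)
        cands = enumerate_subsets(df, y, max_size=2)
        assert len(cands) == 3 + 3  # C(3,1) + C(3,2)

    def test_scores_match_statsmodels(self, rng):
        """R^2, adjusted R^2 and SSE-based AICc/BIC agree with an independent
        OLS implementation for every candidate."""
        df = random_design(rng, 28, 4)
        y = rng.normal(0, 1, 28) + df["x0"].to_numpy()
        n = 28
        for cand in enumerate_subsets(df, y, max_size=3):
            X = sm.add_constant(df[list(cand.predictors)])
            fit = sm.OLS(y, X).fit()
            assert cand.r2 == pytest.approx(fit.rsquared, abs=1e-10)
            assert cand.adj_r2 == pytest.approx(fit.rsquared_adj, abs=1e-10)
            k = len(cand.predictors) + 2
            aicc = n * np.log(fit.ssr / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
            assert cand.aicc == pytest.approx(aicc, abs=1e-9)
            bic = n * np.log(fit.ssr / n) + k * np.log(n)
            assert cand.bic == pytest.approx(bic, abs=1e-9)

    def test_pred_r2_matches_explicit_loo(self, rng):
        """PRESS via the hat matrix equals literally refitting without each row."""
        df = random_design(rng, 20, 3)
        y = rng.normal(0, 1, 20) + 2 * df["x1"].to_numpy()
        cand = [c for c in enumerate_subsets(df, y, max_size=2)
                if c.predictors == ("x1",)][0]
        press = 0.0
        for i in range(20):
            keep = np.arange(20) != i
            A = np.column_stack([np.ones(19), df["x1"].to_numpy()[keep]])
            beta = np.linalg.lstsq(A, y[keep], rcond=None)[0]
            pred = beta[0] + beta[1] * df["x1"].iloc[i]
            press += (y[i] - pred) ** 2
        sst = ((y - y.mean()) ** 2).sum()
        assert cand.pred_r2 == pytest.approx(1 - press / sst, abs=1e-9)

    def test_planted_predictor_recovered(self, rng):
        df = random_design(rng, 40, 4)
        y = 2.0 * df["x1"].to_numpy() + rng.normal(0, 1e-8, 40)
        best = enumerate_subsets(df, y, max_size=3)[0]
        assert best.predictors == ("x1",)

    def test_r2_nesting_and_aicc_penalty(self, rng):
        """R^2 never decreases in nested subsets; AICc eventually punishes size."""
        df = random_design(rng, 24, 6)
        y = df["x0"].to_numpy() + rng.normal(0, 0.5, 24)
        cands = {c.predictors: c for c in enumerate_subsets(df, y, max_size=5)}
        chain = [("x0",), ("x0", "x1"), ("x0", "x1", "x2"),
                 ("x0", "x1", "x2", "x3"), ("x0", "x1", "x2", "x3", "x4")]
        r2s = [cands[s].r2 for s in chain]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
        aiccs = [cands[s].aicc for s in chain]
        assert aiccs[-1] > min(aiccs)  # the penalty bites before the largest subset

    def test_ranking_ties_prefer_smaller(self, rng):
        df = random_design(rng, 26, 5)
        y = df["x2"].to_numpy() + rng.normal(0, 0.3, 26)
        cands = enumerate_subsets(df, y, max_size=4)
        aiccs = [c.aicc for c in cands]
        assert aiccs == sorted(aiccs)


class TestFitAndPredict:
    def test_exact_interpolation(self, rng):
        x = np.linspace(0, 5, 12)
        y = np.exp(1.0 + 0.5 * x)
        df = pd.DataFrame({"x": x})
        m = fit_log_mlr(df, y, ["x"])
        assert m.intercept == pytest.approx(1.0, abs=1e-10)
        assert m.coefficients[0] == pytest.approx(0.5, abs=1e-10)
        assert m.mse == pytest.approx(0.0, abs=1e-20)
        assert m.correction_factor == pytest.approx(1.0, abs=1e-10)

    def test_coefficients_match_normal_equations(self, rng):
        df = random_design(rng, 50, 3)
        y = np.exp(rng.normal(0, 0.4, 50) + df["x0"].to_numpy())
        m = fit_log_mlr(df, y, ["x0", "x1", "x2"])
        A = np.column_stack([np.ones(50), df.to_numpy()])
        beta = np.linalg.solve(A.T @ A, A.T @ np.log(y))
        assert m.intercept == pytest.approx(beta[0], abs=1e-10)
        np.testing.assert_allclose(m.coefficients, beta[1:], atol=1e-10)

    def test_rejects_nonpositive_response(self, rng):
        df = random_design(rng, 10, 1)
        y = np.ones(10)
        y[3] = 0.0
        with pytest.raises(ValueError, match="non-positive"):
            fit_log_mlr(df, y, ["x0"])

    def test_rejects_rank_deficiency(self, rng):
        df = random_design(rng, 15, 1)
        df["dup"] = df["x0"]
        with pytest.raises(ValueError, match="rank"):
            fit_log_mlr(df, np.exp(np.arange(15.0) / 10 + 0.1), ["x0", "dup"])

    def test_coefficient_ci_coverage(self, rng):
        """Each slope falls inside its 99% CI in >= 95/100 simulated fits."""
        hits = 0
        for rep in range(100):
            df = random_design(rng, 200, 2)
            lny = 0.3 + 1.2 * df["x0"] - 0.7 * df["x1"] + rng.normal(0, 0.4, 200)
            fit = sm.OLS(lny, sm.add_constant(df)).fit()
            lo, hi = fit.conf_int(alpha=0.01).loc["x0"]
            m = fit_log_mlr(df, np.exp(lny), ["x0", "x1"])
            hits += lo <= 1.2 <= hi and abs(m.coefficients[0] - fit.params["x0"]) < 1e-10
        assert hits >= 95

    def test_prediction_without_mse_is_plain_exponential(self, rng):
        x = np.linspace(0.1, 3, 10)
        df = pd.DataFrame({"x": x})
        m = fit_log_mlr(df, np.exp(2.0 - 0.3 * x), ["x"])
        np.testing.assert_allclose(predict_attribute(m, df), np.exp(2.0 - 0.3 * x),
                                   rtol=1e-9)

    def test_correction_factor_arithmetic(self, rng):
        df = pd.DataFrame({"x": np.linspace(0, 1, 8)})
        m = fit_log_mlr(df, np.exp(df["x"]), ["x"])
        m.mse = 0.08
        base = np.exp(m.intercept + m.coefficients[0] * df["x"].to_numpy())
        np.testing.assert_allclose(predict_attribute(m, df), base * np.exp(0.04),
                                   rtol=1e-12)
        assert np.exp(0.04) == pytest.approx(1.04081, abs=1e-5)

    def test_missing_predictor_rejected(self, rng):
        df = pd.DataFrame({"x": np.linspace(0, 1, 8)})
        m = fit_log_mlr(df, np.exp(df["x"]), ["x"])
        with pytest.raises(KeyError):
            predict_attribute(m, pd.DataFrame({"z": [1.0]}))

    def test_select_and_fit_end_to_end(self, rng):
        df = random_design(rng, 32, 6)
        y = np.exp(0.5 + 0.8 * df["x2"].to_numpy() + rng.normal(0, 0.05, 32))
        model, cands, retained = select_and_fit(df, y, max_size=3)
        assert "x2" in model.predictors
        assert model.correction_factor >= 1.0
        assert cands[0].adj_r2 <= cands[0].r2 + 1e-12

    def test_model_json_roundtrip(self, tmp_path, rng):
        from miombo_aba.modelsel import FittedModel

        df = random_design(rng, 20, 2)
        m = fit_log_mlr(df, np.exp(df["x0"] + 0.1), ["x0", "x1"], "AGB", "siteA")
        p = tmp_path / "m.json"
        m.to_json(p)
        back = FittedModel.from_json(p)
        assert back.response == "AGB" and back.predictors == ("x0", "x1")
        np.testing.assert_allclose(back.coefficients, m.coefficients)
        assert back.correction_factor == pytest.approx(m.correction_factor)
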