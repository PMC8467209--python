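"""Exposure-response models: standardization, OLS against the
normal-equations oracle, multinomial logit against closed forms, and the
mixed correlation matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panoscape.stats import (
    ELEMENT_COVARIATES,
    correlate,
    fit_linear,
    fit_multinomial,
    predicted_level_frequencies,
    standardize,
    stars,
)


class TestStandardize:
    def test_symmetric_triple(self):
        assert np.allclose(standardize([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self):
        x = standardize(np.arange(7.0))
        assert np.allclose(standardize(x), x, atol=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(-100, 100).filter(lambda v: abs(v) > 1e-3),
        b=st.floats(-100, 100),
    )
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, -1.2, 4.5, 2.2, -0.7])
        assert np.allclose(
            standardize(a * x + b), np.sign(a) * standardize(x), atol=1e-8
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            standardize([3.0, 3.0, 3.0])


class TestLinear:
    def test_perfect_fit(self):
        df = pd.DataFrame({"x": np.arange(10.0)})
        df["y"] = 2.0 * df["x"]
        fit = fit_linear(df, ["x"], "y", include_controls=False)
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-10)
        assert fit.model_p == pytest.approx(0.0, abs=1e-12)

    def test_normal_equations_oracle(self):
        """Frozen 12-row worked dataset: coefficients must match the
        closed-form (X'X)^-1 X'y solution on the standardized design."""
        df = pd.DataFrame(
            {
                "x1": [1.2, 0.4, -0.3, 2.2, 1.9, -1.1, 0.0, 0.7, 1.5, -0.6, 0.9, 2.8],
                "x2": [5.0, 3.2, 4.1, 6.3, 5.5, 2.9, 3.8, 4.4, 5.9, 3.1, 4.8, 6.8],
                "y": [10.1, 7.2, 6.9, 13.4, 12.0, 4.8, 6.1, 8.5, 11.7, 5.9, 9.3, 14.8],
            }
        )
        fit = fit_linear(df, ["x1", "x2"], "y", include_controls=False)
        Z = np.column_stack(
            [
                np.ones(12),
                (df.x1 - df.x1.mean()) / df.x1.std(ddof=1),
                (df.x2 - df.x2.mean()) / df.x2.std(ddof=1),
            ]
        )
        yz = (df.y - df.y.mean()) / df.y.std(ddof=1)
        beta = np.linalg.solve(Z.T @ Z, Z.T @ yz)
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-10)
        assert fit.params["x1"] == pytest.approx(beta[1], abs=1e-10)
        assert fit.params["x2"] == pytest.approx(beta[2], abs=1e-10)

    def test_standardized_beta_invariant_under_rescaling(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"x": rng.normal(size=40)})
        df["y"] = 0.5 * df.x + rng.normal(size=40)
        b1 = fit_linear(df, ["x"], "y", include_controls=False).params["x"]
        df["x"] = 100.0 * df["x"] + 7.0
        b2 = fit_linear(df, ["x"], "y", include_controls=False).params["x"]
        assert b2 == pytest.approx(b1, abs=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(size=60), "b": rng.normal(size=60)})
        df["y"] = df.a - df.b + rng.normal(size=60)
        fit = fit_linear(df, ["a", "b"], "y", include_controls=False)
        for col in ["a", "b"]:
            assert abs(np.dot(fit.residuals, standardize(df[col]))) < 1e-8

    def test_rank_deficiency_names_collinear_set(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4, 5, 6]})
        df["z"] = 2 * df.x
        df["y"] = df.x + np.arange(6) * 0.01
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(df, ["x", "z"], "y", include_controls=False)
        with pytest.warns(RuntimeWarning, match="collinear"):
            fit = fit_linear(
                df, ["x", "z"], "y", include_controls=False, drop_collinear=True
            )
        assert "z" not in fit.params.index

    def test_per_model_missingness(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=30)})
        df["y"] = df.x + rng.normal(size=30)
        df.loc[:4, "y"] = np.nan
        fit = fit_linear(df, ["x"], "y", include_controls=False)
        assert fit.n == 25


class TestMultinomial:
    def test_closed_form_log_odds_ratio(self):
        """Contingency design (group 0: 10 at level 1, 20 at level 2;
        group 1: 5 at level 1, 30 at level 2): the level-2 slope is the log
        odds ratio log((30/5)/(20/10)) = log 3."""
        df = pd.DataFrame(
            {
                "x": [0] * 30 + [1] * 35,
                "y": [1] * 10 + [2] * 20 + [1] * 5 + [2] * 30,
            }
        )
        fit = fit_multinomial(df, ["x"], "y", include_controls=False)
        assert fit.params.loc["x", 2] == pytest.approx(np.log(3.0), abs=1e-6)
        assert fit.converged
        # fitted cell probabilities reproduce the observed frequencies
        b0, b1 = fit.params.loc["const", 2], fit.params.loc["x", 2]
        assert 1 / (1 + np.exp(-(b0))) == pytest.approx(20 / 30, abs=1e-6)
        assert 1 / (1 + np.exp(-(b0 + b1))) == pytest.approx(30 / 35, abs=1e-6)

    def test_intercept_only_reproduces_level_frequencies(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.choice([1, 2, 3], size=200, p=[0.5, 0.3, 0.2])})
        fit = fit_multinomial(df, [], "y", include_controls=False)
        freqs = df["y"].value_counts(normalize=True).sort_index()
        probs = predicted_level_frequencies(fit, df)
        for lvl in (1, 2, 3):
            assert probs[lvl] == pytest.approx(freqs[lvl], abs=1e-6)

    def test_reference_level_and_shape(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"x": rng.normal(size=150)})
        df["y"] = rng.choice([1, 2, 3], size=150)
        fit = fit_multinomial(df, ["x"], "y", include_controls=False)
        assert list(fit.params.columns) == [2, 3]  # level 1 is the reference
        assert fit.model_p >= 0.0

    def test_single_level_outcome_rejected(self):
        df = pd.DataFrame({"x": [0.0, 1, 2, 3], "y": [1, 1, 1, 1]})
        with pytest.raises(ValueError):
            fit_multinomial(df, ["x"], "y", include_controls=False)


class TestCorrelate:
    def test_trivial_pairs(self):
        df = pd.DataFrame(
            {
                "EEG.En": [1.0, 2, 3, 4],
                "EEG.Ex": [2.0, 4, 6, 8],
                "HR.Avg": [4.0, 3, 2, 1],
                "EVA.In": [1, 1, 2, 3],
            }
        )
        tab = correlate(df, indicators=["EEG.En", "EEG.Ex", "HR.Avg", "EVA.In"])
        assert tab.r.loc["EEG.En", "EEG.En"] == 1.0
        assert tab.r.loc["EEG.En", "EEG.Ex"] == pytest.approx(1.0)
        assert tab.r.loc["EEG.En", "HR.Avg"] == pytest.approx(-1.0)
        assert tab.method.loc["EEG.En", "EEG.Ex"] == "pearson"
        assert tab.method.loc["EEG.En", "EVA.In"] == "spearman"

    def test_spearman_monotone_invariance(self):
        x = np.linspace(0, 3, 10)
        df = pd.DataFrame({"a": x, "EVA.In": np.exp(x)})
        tab = correlate(df, indicators=["a", "EVA.In"], ordinal={"EVA.In"})
        assert tab.r.loc["a", "EVA.In"] == pytest.approx(1.0)

    def test_pairwise_deletion_and_missing_cells(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 2, 3, np.nan, 5],
                "b": [2.0, 4, 6, 8, np.nan],
                "c": [np.nan, np.nan, np.nan, 1.0, 2.0],
            }
        )
        tab = correlate(df, indicators=["a", "b", "c"], ordinal=set())
        assert tab.n.loc["a", "b"] == 3
        assert np.isnan(tab.r.loc["a", "c"])  # only 1 complete pair

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["a", "b", "c"])
        tab = correlate(df, indicators=["a", "b", "c"], ordinal=set())
        assert np.allclose(tab.r.values, tab.r.values.T)
        assert (tab.r.values <= 1).all() and (tab.r.values >= -1).all()


def test_star_convention():
    assert stars(0.2) == ""
    assert stars(0.09) == "*"
    assert stars(0.04) == "**"
    assert stars(0.009) == "***"
    assert stars(np.nan) == ""
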