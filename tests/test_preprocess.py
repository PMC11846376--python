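"""Covariate screening, encoding and the four missing-data strategies."""

import numpy as np
import pandas as pd
import pytest

from hteforest.preprocess import (EmptyDesignError, encode_and_scale,
                                  filter_correlated, filter_high_missingness,
                                  impute)
from tests.conftest import make_dataset


def _with_missing(values, frac, seed=0):
    rng = np.random.default_rng(seed)
    v = np.array(values, float)
    v[rng.random(len(v)) < frac] = np.nan
    return v


class TestMissingnessFilter:
    def test_boundary_is_strict(self):
        n = 100
        d = make_dataset({
            "a": np.where(np.arange(n) < 31, np.nan, 1.0 * np.arange(n)),
            "b": np.where(np.arange(n) < 29, np.nan, 1.0 * np.arange(n)),
        })
        out, report = filter_high_missingness(d)
        assert out.covariate_names == ["b"]
        assert report.removed_for_missingness == [("a", 0.31)]

    def test_identity_without_missingness(self, small_trial):
        out, report = filter_high_missingness(small_trial)
        assert out.covariate_names == small_trial.covariate_names
        assert report.removed_for_missingness == []

    def test_idempotent(self):
        d = make_dataset({"a": _with_missing(np.arange(50.0), 0.5, 1),
                          "b": np.arange(50.0)})
        once, _ = filter_high_missingness(d)
        twice, _ = filter_high_missingness(once)
        assert once.covariate_names == twice.covariate_names

    def test_empty_design_raises(self):
        d = make_dataset({"a": np.full(20, np.nan)})
        with pytest.raises(EmptyDesignError):
            filter_high_missingness(d)


class TestCorrelationFilter:
    def test_duplicates_drop_exactly_one(self):
        x = np.random.default_rng(0).normal(size=200)
        d = make_dataset({"a": x, "b": x.copy()})
        out, report = filter_correlated(d)
        assert len(out.covariate_names) == 1
        assert len(report.removed_for_correlation) == 1

    def test_strict_inequality_keeps_moderate_pairs(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        # construct pair with correlation approx 0.69
        y = 0.69 * x + np.sqrt(1 - 0.69 ** 2) * rng.normal(size=5000)
        d = make_dataset({"a": x, "b": y})
        r = np.corrcoef(x, y)[0, 1]
        assume_ok = abs(r) <= 0.7
        out, _ = filter_correlated(d)
        assert (len(out.covariate_names) == 2) == assume_ok

    def test_three_way_cluster_drops_two_most_missing(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=400)
        cols = {
            "c0": base + 0.01 * rng.normal(size=400),              # complete
            "c1": _with_missing(base + 0.01 * rng.normal(size=400), 0.10, 3),
            "c2": _with_missing(base + 0.01 * rng.normal(size=400), 0.20, 4),
        }
        d = make_dataset(cols)
        out, report = filter_correlated(d)
        assert out.covariate_names == ["c0"]
        dropped = {drop for _, drop, _ in report.removed_for_correlation}
        assert dropped == {"c1", "c2"}

    def test_derived_score_tiebreak(self):
        x = np.random.default_rng(3).normal(size=300)
        d = make_dataset({"raw": x, "score": x.copy()})
        d.meta["score"].derived_score = True
        out, _ = filter_correlated(d)
        assert out.covariate_names == ["raw"]


class TestEncodeAndScale:
    def test_one_hot_keeps_every_level(self):
        d = make_dataset({"site": pd.Series(["lung", "abdomen", "tissue"] * 10)})
        out, _ = encode_and_scale(d)
        assert sorted(out.covariate_names) == [
            "site=abdomen", "site=lung", "site=tissue"]
        assert all(out.meta[c].parent == "site" for c in out.covariate_names)

    def test_standardisation_and_metadata(self):
        d = make_dataset({"x": [1.0, 2.0, 3.0]})
        out, _ = encode_and_scale(d)
        np.testing.assert_allclose(out.X["x"], [-1.0, 0.0, 1.0])  # sample SD = 1
        assert out.meta["x"].mean == 2.0
        assert out.meta["x"].sd == 1.0

    def test_every_continuous_column_is_standardised(self, small_trial):
        out, _ = encode_and_scale(small_trial)
        for name in out.covariate_names:
            col = out.X[name].to_numpy()
            assert abs(col.mean()) < 1e-8
            assert abs(col.std(ddof=1) - 1) < 1e-8

    def test_threshold_backtransform_roundtrip(self):
        rng = np.random.default_rng(5)
        d = make_dataset({"potassium": 4.58 + 0.937 * rng.normal(size=500)})
        out, _ = encode_and_scale(d)
        fm = out.meta["potassium"]
        raw = fm.mean + 0.106 * fm.sd
        # on the population scale 4.58 + 0.106*0.937 = 4.679
        assert raw == pytest.approx(4.58 + 0.106 * 0.937, abs=0.15)

    def test_zero_variance_column_dropped_with_warning(self):
        d = make_dataset({"flat": np.full(30, 3.7), "x": np.arange(30.0)})
        out, report = encode_and_scale(d)
        assert out.covariate_names == ["x"]
        assert report.dropped_zero_variance == ["flat"]


class TestImpute:
    def test_no_missingness_is_identity(self, small_trial):
        for method in ("missforest", "mean", "complete_case", "ipw"):
            out, report = impute(small_trial, method, seed=1)
            assert out.X.equals(small_trial.X)
            assert report.iterations_run == 0

    def test_mean_then_standardise_gives_zero(self):
        d = make_dataset({"x": _with_missing(np.arange(100.0), 0.2, 7)})
        miss = d.X["x"].isna().to_numpy()
        out, _ = impute(d, "mean")
        std, _ = encode_and_scale(out)
        np.testing.assert_allclose(std.X["x"].to_numpy()[miss], 0.0, atol=1e-12)

    def test_complete_case_row_count(self):
        rng = np.random.default_rng(8)
        n = 408
        x = np.arange(n, dtype=float)
        miss = np.zeros(n, bool)
        miss[rng.choice(n, 153, replace=False)] = True
        x[miss] = np.nan
        d = make_dataset({"x": x, "z": rng.normal(size=n)})
        out, _ = impute(d, "complete_case")
        assert out.n == 255

    def test_ipw_weights_are_inverse_probabilities(self):
        rng = np.random.default_rng(9)
        n = 600
        z = rng.normal(size=n)
        x = rng.normal(size=n)
        x[rng.random(n) < 0.3] = np.nan
        d = make_dataset({"x": x, "z": z})
        out, report = impute(d, "ipw")
        assert out.weights is not None
        assert np.all(out.weights >= 1.0)  # 1/P(complete) with P <= 1
        assert out.n == np.sum(~np.isnan(x))
        assert report.imputation_method == "ipw"

    def test_missforest_recovers_deterministic_relation(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=1000)
        b = 2.0 * a
        mask = rng.random(1000) < 0.2
        b_missing = b.copy()
        b_missing[mask] = np.nan
        d = make_dataset({"a": a, "b": b_missing})
        out, report = impute(d, "missforest", seed=2)
        rmse = np.sqrt(np.mean((out.X["b"].to_numpy()[mask] - b[mask]) ** 2))
        assert rmse < 0.2
        assert report.convergence_trace  # trace recorded for missforest

    def test_missforest_preserves_observed_entries(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=300)
        b = a + rng.normal(size=300)
        b_missing = b.copy()
        b_missing[rng.random(300) < 0.25] = np.nan
        d = make_dataset({"a": a, "b": b_missing})
        out, _ = impute(d, "missforest", seed=3)
        observed = ~np.isnan(b_missing)
        np.testing.assert_array_equal(out.X["b"].to_numpy()[observed],
                                      b_missing[observed])
        np.testing.assert_array_equal(out.X["a"].to_numpy(), a)
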