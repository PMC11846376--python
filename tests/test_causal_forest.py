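"""Honest causal forest: oracles, honesty audit, weights, scores, GATEs."""

from dataclasses import replace

import numpy as np
import pytest

from hteforest import causal_forest as cf
from hteforest.datagen import generate_trial
from tests.conftest import make_dataset


def _exhaustive_root_split(X, wr, yr, treated, params):
    """Independent brute-force search over every (variable, midpoint) split.

    Re-implements the split score with plain loops: child effects are
    residual ratios, the score is
    n_L*n_R*((tau_L-tau_R)^2 - penalty*(Var_L+Var_R)) with sandwich child
    variances, subject to the node-size / arm / balance constraints.
    """
    n, K = X.shape
    min_child = max(params.min_node_size,
                    int(np.ceil(params.balance_fraction * n)))
    best = None
    for j in range(K):
        values = np.unique(X[:, j])
        for a, b in zip(values[:-1], values[1:]):
            thr = 0.5 * (a + b)
            left = X[:, j] <= thr
            nl, nr = left.sum(), n - left.sum()
            if nl < min_child or nr < min_child:
                continue
            for side in (left, ~left):
                if treated[side].sum() < params.min_arm_per_child:
                    break
                if (1 - treated[side]).sum() < params.min_arm_per_child:
                    break
            else:
                bl = (wr[left] ** 2).sum()
                br = (wr[~left] ** 2).sum()
                if bl <= 0 or br <= 0:
                    continue
                tl = (wr[left] * yr[left]).sum() / bl
                tr = (wr[~left] * yr[~left]).sum() / br
                contrast = (tl - tr) ** 2
                if params.variance_penalty:
                    vl = sum((wr[i] * yr[i] - tl * wr[i] ** 2) ** 2
                             for i in np.flatnonzero(left)) / bl ** 2
                    vr = sum((wr[i] * yr[i] - tr * wr[i] ** 2) ** 2
                             for i in np.flatnonzero(~left)) / br ** 2
                    contrast -= params.variance_penalty * (vl + vr)
                score = nl * nr * contrast
                if best is None or score > best[0]:
                    best = (score, j, thr)
    return best


@pytest.mark.parametrize("penalty", [0.0, 1.0])
def test_greedy_root_split_equals_exhaustive_search(penalty):
    rng = np.random.default_rng(14)
    for rep in range(12):
        n = 36
        X = rng.normal(size=(n, 2))
        w = rng.integers(0, 2, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        wr = w - 0.5
        yr = y - y.mean()
        params = cf.ForestParams(min_node_size=4, variance_penalty=penalty,
                                 balance_fraction=0.0, mtry=2)
        builder = cf.grow_causal_tree(X, wr, yr, w.astype(int), params,
                                      np.random.default_rng(rep))
        oracle = _exhaustive_root_split(X, wr, yr, w.astype(int), params)
        if oracle is not None and oracle[0] <= 0:
            oracle = None  # grower refuses zero/negative-score splits
        if oracle is None:
            assert builder.feature[builder.root] == -1
        else:
            _, j, thr = oracle
            assert builder.feature[builder.root] == j
            assert builder.threshold[builder.root] == pytest.approx(thr)


def test_perfectly_separating_binary_covariate_wins_root():
    rng = np.random.default_rng(2)
    n = 400
    group = np.repeat([0.0, 1.0], n // 2)
    w = np.tile([0.0, 1.0], n // 2)
    tau = np.where(group > 0, 0.6, -0.6)
    y = 0.5 + (w - 0.5) * tau + 0.05 * rng.normal(size=n)
    X = np.column_stack([group, rng.normal(size=n)])
    builder = cf.grow_causal_tree(X, w - 0.5, y - y.mean(), w.astype(int),
                                  cf.ForestParams(mtry=2),
                                  np.random.default_rng(0))
    assert builder.feature[builder.root] == 0


def test_constant_effect_data_yields_stump():
    # residual products identical everywhere -> every contrast is zero
    n = 60
    w = np.tile([0.0, 1.0], n // 2)
    y = w.copy()  # wr*yr identical within arm, tau constant
    X = np.linspace(0, 1, n).reshape(-1, 1)
    builder = cf.grow_causal_tree(X, w - 0.5, y - y.mean(), w.astype(int),
                                  cf.ForestParams(mtry=1, variance_penalty=0.0),
                                  np.random.default_rng(0))
    # any split has tau_L == tau_R == 1, criterion 0 everywhere: stump
    assert builder.feature[builder.root] == -1


@pytest.fixture(scope="module")
def fitted(calibrated_dgp):
    data = generate_trial(replace(calibrated_dgp, n_participants=500, seed=8))
    nuisance = cf.fit_nuisance(data, n_trees=100, seed=1)
    model = cf.fit_causal_forest(data, nuisance,
                                 cf.ForestParams(n_trees=60, seed=2))
    return data, nuisance, model


class TestHonesty:
    def test_grow_and_estimate_halves_disjoint(self, fitted):
        _, _, model = fitted
        for tree in model.trees:
            assert not set(tree.grow_indices) & set(tree.estimate_indices)
            members = tree.estimate_indices[tree.leaf_of_estimate >= 0]
            assert set(members) <= set(tree.estimate_indices)

    def test_thresholds_lie_between_grow_half_values(self, fitted):
        data, _, model = fitted
        X = data.matrix()
        for tree in model.trees[:10]:
            for node in np.flatnonzero(tree.feature >= 0):
                vals = X[tree.grow_indices, tree.feature[node]]
                thr = tree.threshold[node]
                assert vals.min() < thr < vals.max()
                assert not np.any(vals == thr)


class TestWeightsAndOOB:
    def test_forest_weights_sum_to_one(self, fitted):
        data, _, model = fitted
        X = data.matrix()
        for i in (0, 17, 123):
            w = cf.forest_weights(model, X, X[i])
            assert w.sum() == pytest.approx(1.0)
            w_oob = cf.forest_weights(model, X, X[i], exclude=i)
            assert w_oob.sum() == pytest.approx(1.0)
            assert w_oob[i] == 0.0

    def test_oob_cate_defined_where_trees_exclude(self, fitted):
        _, _, model = fitted
        has_tree = model.oob_tree_counts > 0
        assert np.all(np.isfinite(model.tau_oob[has_tree]))

    def test_refuses_tiny_forest(self, fitted):
        data, nuisance, _ = fitted
        with pytest.raises(ValueError, match="fewer than 10"):
            cf.fit_causal_forest(data, nuisance, cf.ForestParams(n_trees=5))


def test_stump_forest_reduces_to_weighted_difference_in_means(calibrated_dgp):
    """With +-0.5 treatment residuals and a constant outcome model, each
    stump's effect estimate has the closed form
    2*(sum_T (Y - ybar) - sum_C (Y - ybar))/n over its estimate half,
    i.e. the difference in arm means when the arms are balanced."""
    data = generate_trial(replace(calibrated_dgp, n_participants=300, seed=3))
    ybar = data.y.mean()
    nuisance = cf.NuisanceEstimates(
        p_hat=np.full(data.n, 0.5), m_hat=np.full(data.n, ybar),
        source="fixed_known")
    model = cf.fit_causal_forest(
        data, nuisance,
        cf.ForestParams(n_trees=12, min_node_size=10_000, seed=4))
    for tree in model.trees:
        assert tree.is_stump()
        est = tree.estimate_indices
        n_est = len(est)
        treated = data.w[est] > 0.5
        expected = 2 * ((data.y[est][treated] - ybar).sum()
                        - (data.y[est][~treated] - ybar).sum()) / n_est
        got = tree.leaf_num[tree.root] / tree.leaf_den[tree.root]
        assert got == pytest.approx(expected, abs=1e-12)


class TestNuisance:
    def test_fixed_propensity_gives_half_residuals(self, calibrated_dgp):
        data = generate_trial(replace(calibrated_dgp, n_participants=200, seed=5))
        nu = cf.fit_nuisance(data, n_trees=50, seed=0, fix_propensity=0.5)
        wr, _ = nu.residuals(data)
        assert set(np.unique(wr)) == {-0.5, 0.5}
        assert nu.source == "fixed_known"

    def test_pure_noise_covariates_give_flat_outcome_model(self):
        rng = np.random.default_rng(6)
        n = 800
        d = make_dataset({"a": rng.normal(size=n), "b": rng.normal(size=n)},
                         y=rng.integers(0, 2, n), w=rng.integers(0, 2, n))
        nu = cf.fit_nuisance(d, n_trees=100, seed=0)
        assert np.mean(np.abs(nu.m_hat - d.y.mean())) < 0.05

    def test_prognostic_signal_beats_intercept_only(self, calibrated_dgp):
        data = generate_trial(replace(calibrated_dgp, n_participants=1500, seed=7))
        nu = cf.fit_nuisance(data, n_trees=150, seed=0)
        mse_forest = np.mean((data.y - nu.m_hat) ** 2)
        mse_flat = np.mean((data.y - data.y.mean()) ** 2)
        assert mse_forest < mse_flat


class TestDrScoresAndGate:
    def test_hand_computed_scores_four_rows(self):
        model = cf.CausalForestModel(
            trees=[], nuisance=cf.NuisanceEstimates(
                p_hat=np.full(4, 0.5), m_hat=np.array([0.5, 0.5, 0.25, 0.75]),
                source="fixed_known"),
            tau_oob=np.array([0.1, -0.2, 0.0, 0.3]),
            oob_tree_counts=np.ones(4, dtype=int),
            params=cf.ForestParams(), feature_names=["x"],
            w_resid=np.array([0.5, -0.5, 0.5, -0.5]),
            y_resid=np.zeros(4))
        data = make_dataset({"x": np.zeros(4)},
                            y=[1.0, 0.0, 1.0, 1.0], w=[1.0, 0.0, 1.0, 0.0])
        got = cf.dr_scores(model, data)
        # Gamma_i = tau_i + 4*(W_i-0.5)*(Y_i - m_i - (W_i-0.5)*tau_i)
        expected = [0.1 + 2 * (1 - 0.5 - 0.5 * 0.1),
                    -0.2 - 2 * (0 - 0.5 + 0.5 * (-0.2)),
                    0.0 + 2 * (1 - 0.25 - 0.0),
                    0.3 - 2 * (1 - 0.75 + 0.5 * 0.3)]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_ipw_reduction_when_tau_and_m_are_zero(self):
        rng = np.random.default_rng(9)
        n = 50
        y = rng.integers(0, 2, n).astype(float)
        w = rng.integers(0, 2, n).astype(float)
        model = cf.CausalForestModel(
            trees=[], nuisance=cf.NuisanceEstimates(
                p_hat=np.full(n, 0.5), m_hat=np.zeros(n), source="fixed_known"),
            tau_oob=np.zeros(n), oob_tree_counts=np.ones(n, dtype=int),
            params=cf.ForestParams(), feature_names=["x"],
            w_resid=w - 0.5, y_resid=y)
        data = make_dataset({"x": np.zeros(n)}, y=y, w=w)
        scores = cf.dr_scores(model, data)
        assert scores.mean() == pytest.approx(np.mean(4 * (w - 0.5) * y))

    def test_complementary_subsets_average_to_overall(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(size=200)
        mask = rng.random(200) < 0.4
        low = cf.average_treatment_effect(scores, mask)
        high = cf.average_treatment_effect(scores, ~mask)
        overall = cf.average_treatment_effect(scores)
        pooled = (low.gate * low.n_subset + high.gate * high.n_subset) / 200
        assert pooled == pytest.approx(overall.gate, abs=1e-12)

    def test_constant_scores_degenerate_ci(self):
        res = cf.average_treatment_effect(np.full(30, 0.2))
        assert res.se == pytest.approx(0.0, abs=1e-12)
        assert res.ci_low == pytest.approx(0.2, abs=1e-10)
        assert res.ci_high == pytest.approx(0.2, abs=1e-10)

    def test_small_subset_flagged_and_empty_fails(self):
        scores = np.arange(20.0)
        assert cf.average_treatment_effect(scores, np.arange(20) < 5).small_sample
        with pytest.raises(ValueError, match="empty"):
            cf.average_treatment_effect(scores, np.zeros(20, dtype=bool))


class TestCalibrationTest:
    def test_constant_cate_reports_no_heterogeneity(self):
        n = 40
        model = cf.CausalForestModel(
            trees=[], nuisance=cf.NuisanceEstimates(
                p_hat=np.full(n, 0.5), m_hat=np.zeros(n), source="fixed_known"),
            tau_oob=np.full(n, 0.3), oob_tree_counts=np.ones(n, dtype=int),
            params=cf.ForestParams(), feature_names=["x"],
            w_resid=np.tile([0.5, -0.5], n // 2),
            y_resid=np.random.default_rng(0).normal(size=n))
        data = make_dataset({"x": np.zeros(n)})
        res = cf.test_calibration(model, data)
        assert "no heterogeneity" in res.note

    def test_oracle_cates_give_dfp_near_one(self, calibrated_dgp):
        from scipy.special import expit
        cfg = replace(calibrated_dgp, n_participants=4000, seed=12)
        data = generate_trial(cfg)
        x1 = data.X["X1"].to_numpy()
        s = (data.X["X2"].to_numpy() > cfg.true_threshold).astype(float)
        p1 = expit(cfg.beta0 + cfg.beta_x1 * x1 + cfg.beta_w + cfg.beta_ws * s)
        p0 = expit(cfg.beta0 + cfg.beta_x1 * x1)
        tau_true = p1 - p0
        n = data.n
        model = cf.CausalForestModel(
            trees=[], nuisance=cf.NuisanceEstimates(
                p_hat=np.full(n, 0.5), m_hat=0.5 * (p1 + p0),
                source="fixed_known"),
            tau_oob=tau_true, oob_tree_counts=np.ones(n, dtype=int),
            params=cf.ForestParams(), feature_names=["X1", "X2"],
            w_resid=data.w - 0.5, y_resid=data.y - 0.5 * (p1 + p0))
        res = cf.test_calibration(model, data)
        assert res.differential_forest_prediction == pytest.approx(1.0, abs=0.25)
        assert res.dfp_p_value < 0.01


class TestVariableImportance:
    def test_single_variable_forest_concentrates_importance(self, calibrated_dgp):
        data = generate_trial(replace(calibrated_dgp, n_participants=400, seed=9))
        only_x2 = data.drop_covariates(["X1"])
        nu = cf.fit_nuisance(only_x2, n_trees=60, seed=0, fix_propensity=0.5)
        model = cf.fit_causal_forest(only_x2, nu,
                                     cf.ForestParams(n_trees=30, seed=1))
        imp = cf.variable_importance(model)
        assert imp["X2"] == pytest.approx(1.0)

    def test_stump_forest_importance_all_zero(self, calibrated_dgp):
        data = generate_trial(replace(calibrated_dgp, n_participants=200, seed=9))
        nu = cf.fit_nuisance(data, n_trees=50, seed=0, fix_propensity=0.5)
        model = cf.fit_causal_forest(
            data, nu, cf.ForestParams(n_trees=15, min_node_size=10_000, seed=1))
        assert all(v == 0.0 for v in cf.variable_importance(model).values())


def test_true_threshold_gates_recover_dgp_effects(calibrated_dgp):
    """With the true partition at 4.68, AIPW GATEs should straddle the
    DGP's subgroup risk differences (+0.069 / -0.257) within Monte-Carlo
    error across replicates."""
    lows, highs = [], []
    for rep in range(6):
        data = generate_trial(replace(calibrated_dgp,
                                      n_participants=1000, seed=600 + rep))
        nu = cf.fit_nuisance(data, n_trees=100, seed=rep)
        model = cf.fit_causal_forest(data, nu,
                                     cf.ForestParams(n_trees=150, seed=rep))
        scores = cf.dr_scores(model, data)
        below = data.X["X2"].to_numpy() <= 4.68
        lows.append(cf.average_treatment_effect(scores, below).gate)
        highs.append(cf.average_treatment_effect(scores, ~below).gate)
    for observed, truth in ((lows, 0.069), (highs, -0.257)):
        mean = np.mean(observed)
        se = np.std(observed, ddof=1) / np.sqrt(len(observed))
        assert abs(mean - truth) < 3 * max(se, 0.01)
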