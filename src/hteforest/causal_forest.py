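"""Honest causal forest for conditional average treatment effects.

The estimator targets the CATE tau(x) = E[Y(1) - Y(0) | X = x] in a
randomised two-arm trial, via the residual-on-residual (partially linear)
representation: with nuisance functions p(X) = E[W|X] and m(X) = E[Y|X]
estimated out-of-bag by regression random forests,

    tau_hat(x) = sum_i a_i(x) (W_i - p_i)(Y_i - m_i)
               / sum_i a_i(x) (W_i - p_i)^2,

where the weights a_i(x) count how often observation i shares a leaf with
x across the forest, normalised by leaf size.

Each causal tree is honest: its subsample is split into a grow half, which
chooses splits greedily to maximise the between-child criterion
n_L * n_R * (tau_L - tau_R)^2 (child effects estimated by the residual
ratio), and an estimate half, which alone populates the leaves used for
effect estimation. Out-of-bag CATEs for each participant average only
trees whose subsample excluded that participant.

Post-estimation utilities: the omnibus calibration test (differential
forest prediction with a one-sided heteroskedasticity-robust p-value),
depth-weighted split-frequency variable importance, doubly robust AIPW
scores, and subgroup average treatment effects (GATEs).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import statsmodels.api as sm
from numba import njit
from scipy.stats import t as _student_t
from sklearn.ensemble import RandomForestRegressor

from .dataset import TrialDataset

__all__ = [
    "ForestParams", "NuisanceEstimates", "CausalTree", "CausalForestModel",
    "CalibrationTest", "GateResult",
    "fit_nuisance", "grow_causal_tree", "fit_causal_forest",
    "test_calibration", "variable_importance", "dr_scores",
    "average_treatment_effect", "forest_weights",
]

_PROPENSITY_CLIP = (0.01, 0.99)


@dataclass
class ForestParams:
    """Causal-forest hyperparameters.

    Defaults: B = 2000 trees for single-dataset analyses (use 500 inside
    simulation studies), without-replacement subsampling of half the data,
    half of each subsample reserved for honest leaf estimation, minimum
    node size 5 with at least one treated and one control participant per
    child, and mtry = min(K, ceil(sqrt(K)) + 3) candidate variables per
    split. All values are recorded on the fitted model.
    """

    n_trees: int = 2000
    subsample_fraction: float = 0.5
    honesty_fraction: float = 0.5
    mtry: int | None = None
    min_node_size: int = 5
    min_arm_per_child: int = 1
    balance_fraction: float = 0.05
    variance_penalty: float = 1.0
    seed: int = 0

    def resolved_mtry(self, n_features: int) -> int:
        if self.mtry is not None:
            return min(self.mtry, n_features)
        return min(n_features, int(np.ceil(np.sqrt(n_features))) + 3)


@dataclass
class NuisanceEstimates:
    p_hat: np.ndarray
    m_hat: np.ndarray
    source: str = "forest"  # or "fixed_known"
    clipped: np.ndarray | None = None

    def residuals(self, data: TrialDataset) -> tuple[np.ndarray, np.ndarray]:
        """(W - p_hat, Y - m_hat) for the given dataset."""
        return data.w - self.p_hat, data.y - self.m_hat


@dataclass
class CausalTree:
    """Flat-array binary tree. ``feature[i] == -1`` marks a leaf."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    root: int
    grow_indices: np.ndarray
    estimate_indices: np.ndarray
    leaf_of_estimate: np.ndarray  # node id per estimate row (post-pruning)
    leaf_num: np.ndarray   # per node: mean over leaf members of wr*yr
    leaf_den: np.ndarray   # per node: mean over leaf members of wr^2
    leaf_size: np.ndarray  # per node: number of estimate members

    @property
    def subsample_indices(self) -> np.ndarray:
        return np.concatenate([self.grow_indices, self.estimate_indices])

    def is_stump(self) -> bool:
        return self.feature[self.root] < 0

    def root_split(self) -> tuple[int, float] | None:
        if self.is_stump():
            return None
        return int(self.feature[self.root]), float(self.threshold[self.root])

    def route(self, Xq: np.ndarray) -> np.ndarray:
        node = np.full(len(Xq), self.root, dtype=np.int64)
        while True:
            feat = self.feature[node]
            active = feat >= 0
            if not active.any():
                return node
            nm = node[active]
            go_left = Xq[active, feat[active]] <= self.threshold[nm]
            node[active] = np.where(go_left, self.left[nm], self.right[nm])

    def node_depths(self) -> np.ndarray:
        depth = np.zeros(len(self.feature), dtype=np.int64)
        stack = [(self.root, 1)]
        while stack:
            node, d = stack.pop()
            if self.feature[node] >= 0:
                depth[node] = d
                stack.append((int(self.left[node]), d + 1))
                stack.append((int(self.right[node]), d + 1))
        return depth


@dataclass
class CausalForestModel:
    trees: list[CausalTree]
    nuisance: NuisanceEstimates
    tau_oob: np.ndarray
    oob_tree_counts: np.ndarray
    params: ForestParams
    feature_names: list[str]
    w_resid: np.ndarray
    y_resid: np.ndarray

    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def to_json(self, path: str | Path) -> None:
        """Serialise the ensemble in a tree-interchange JSON format."""
        payload = {
            "feature_names": self.feature_names,
            "params": self.params.__dict__,
            "trees": [
                {
                    "feature": t.feature.tolist(),
                    "threshold": t.threshold.tolist(),
                    "left": t.left.tolist(),
                    "right": t.right.tolist(),
                    "root": t.root,
                    "grow_indices": t.grow_indices.tolist(),
                    "estimate_indices": t.estimate_indices.tolist(),
                    "leaf_of_estimate": t.leaf_of_estimate.tolist(),
                }
                for t in self.trees
            ],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "CausalForestModel":
        """Load a serialised ensemble (tree structure and memberships).

        Leaf-level effect sums, nuisances and OOB CATEs are not part of
        the interchange format; the loaded model supports structural
        consumers (root-split extraction, importance, routing).
        """
        payload = json.loads(Path(path).read_text())
        trees = []
        for t in payload["trees"]:
            feature = np.asarray(t["feature"], dtype=np.int64)
            trees.append(CausalTree(
                feature=feature,
                threshold=np.asarray(t["threshold"], dtype=float),
                left=np.asarray(t["left"], dtype=np.int64),
                right=np.asarray(t["right"], dtype=np.int64),
                root=int(t["root"]),
                grow_indices=np.asarray(t["grow_indices"], dtype=np.int64),
                estimate_indices=np.asarray(t["estimate_indices"], dtype=np.int64),
                leaf_of_estimate=np.asarray(t["leaf_of_estimate"], dtype=np.int64),
                leaf_num=np.zeros(len(feature)),
                leaf_den=np.zeros(len(feature)),
                leaf_size=np.zeros(len(feature), dtype=np.int64),
            ))
        n = max((int(t.subsample_indices.max()) + 1 for t in trees), default=0)
        return cls(
            trees=trees,
            nuisance=NuisanceEstimates(p_hat=np.full(n, 0.5),
                                       m_hat=np.zeros(n), source="fixed_known"),
            tau_oob=np.full(n, np.nan),
            oob_tree_counts=np.zeros(n, dtype=np.int64),
            params=ForestParams(**payload["params"]),
            feature_names=list(payload["feature_names"]),
            w_resid=np.zeros(n), y_resid=np.zeros(n),
        )


@dataclass
class CalibrationTest:
    mean_forest_prediction_coef: float
    differential_forest_prediction: float
    dfp_p_value: float
    note: str = ""


@dataclass
class GateResult:
    subset_definition: str
    n_subset: int
    dr_scores: np.ndarray
    gate: float
    se: float
    ci_low: float
    ci_high: float
    small_sample: bool = False
    warnings: list[str] = field(default_factory=list)


# ------------------------------------------------------------------ nuisance


#: candidate smoothing levels for the nuisance forests; the level with the
#: best out-of-bag error wins (a target unrelated to X, such as a randomised
#: treatment indicator, selects the heaviest smoothing automatically)
_NUISANCE_LEAF_GRID = (5, 25, 125)


def _oob_forest(X, target, n_trees, seed, leaf):
    forest = RandomForestRegressor(
        n_estimators=n_trees, oob_score=True, bootstrap=True,
        min_samples_leaf=leaf, random_state=seed, n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        forest.fit(X, target)
        pred = forest.oob_prediction_
    if np.isnan(pred).any():
        raise RuntimeError("some rows were in-bag for every tree; increase n_trees")
    return pred


def _oob_regression(X: np.ndarray, target: np.ndarray, n_trees: int, seed: int,
                    leaf_grid=_NUISANCE_LEAF_GRID) -> np.ndarray:
    """OOB predictions from a random forest with OOB-selected leaf size.

    An under-smoothed nuisance forest leaves structured noise in the
    residuals (for the treatment indicator it partially memorises W
    itself), which propagates into the downstream effect estimates. The
    leaf size is chosen by OOB error using small pilot forests, then the
    winner is refitted at full size; the constant (mean) predictor
    competes as well, scored by leave-one-out error, and wins whenever
    the covariates carry no usable signal for the target.
    """
    n = len(target)
    loo_mean = (target.sum() - target) / (n - 1)
    const_err = float(np.mean((loo_mean - target) ** 2))

    n_pilot = min(40, n_trees)
    best_leaf, best_err = None, const_err
    for leaf in leaf_grid:
        pred = _oob_forest(X, target, n_pilot, seed, leaf)
        err = float(np.mean((pred - target) ** 2))
        if err < best_err:
            best_leaf, best_err = leaf, err
    if best_leaf is None:
        return np.full(n, float(target.mean()))
    if n_trees <= n_pilot:
        return _oob_forest(X, target, n_pilot, seed, best_leaf)
    return _oob_forest(X, target, n_trees, seed, best_leaf)


def fit_nuisance(
    data: TrialDataset,
    n_trees: int = 500,
    seed: int = 0,
    fix_propensity: float | None = None,
) -> NuisanceEstimates:
    """Out-of-bag nuisance estimates p(X) = E[W|X] and m(X) = E[Y|X].

    Two regression random forests are fitted (W on X; Y on X, never
    including W); each participant's prediction averages only trees whose
    bootstrap sample excluded them, and the leaf size of each forest is
    chosen by out-of-bag error from a small grid. In a randomised design
    the propensity may instead be fixed at the known assignment
    probability with ``fix_propensity``. Propensities are clipped to
    [0.01, 0.99] so the residual-ratio denominators stay bounded.
    """
    X = data.matrix()
    if np.isnan(X).any():
        raise ValueError("nuisance fitting requires complete covariates (impute first)")
    m_hat = _oob_regression(X, data.y, n_trees, seed)

    if fix_propensity is not None:
        p_hat = np.full(data.n, float(fix_propensity))
        source = "fixed_known"
        clipped = np.zeros(data.n, dtype=bool)
    else:
        p_raw = _oob_regression(X, data.w, n_trees, seed + 1)
        clipped = (p_raw < _PROPENSITY_CLIP[0]) | (p_raw > _PROPENSITY_CLIP[1])
        p_hat = np.clip(p_raw, *_PROPENSITY_CLIP)
        source = "forest"
    return NuisanceEstimates(p_hat=p_hat, m_hat=m_hat, source=source, clipped=clipped)


# ----------------------------------------------------------------- tree grow


def _best_split(x: np.ndarray, wr2: np.ndarray, wy: np.ndarray, treated: np.ndarray,
                min_node: int, min_arm: int, min_child: int,
                variance_penalty: float):
    """Best threshold on one variable; returns (criterion, threshold) or None.

    Vectorised scan over midpoints between consecutive distinct sorted
    values. Child effects are residual ratios tau = sum(wr*yr)/sum(wr^2);
    the base criterion is n_L * n_R * (tau_L - tau_R)^2. Because
    E[(tau_L - tau_R)^2] exceeds the true squared contrast by the two
    child sampling variances - an excess that grows as a child shrinks and
    systematically drags the argmax toward noisy unbalanced splits - the
    squared contrast is debiased by subtracting sandwich estimates of
    Var(tau_L) + Var(tau_R), scaled by ``variance_penalty`` (0 recovers
    the plain criterion). ``min_child`` additionally enforces a minimum
    child share of the parent.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    best, best_crit = _scan_split(
        xs, wy[order], wr2[order], treated[order].astype(np.int64),
        max(min_node, min_child), min_arm, float(variance_penalty))
    if best < 0:
        return None  # no admissible split improves on the parent
    threshold = 0.5 * (xs[best] + xs[best + 1])
    return float(best_crit), threshold, order, best


@njit(cache=True)
def _scan_split(xs, wys, wr2s, treated, min_size, min_arm, penalty):
    """Single left-to-right pass over sorted candidate thresholds.

    Returns (index of the last left-child row, score) for the admissible
    split maximising the score, or (-1, 0.0) when none is admissible or
    every admissible score is <= 0.
    """
    n = xs.shape[0]
    tot_y = 0.0
    tot_w = 0.0
    tot_t = 0
    tot_y2 = 0.0
    tot_cross = 0.0
    tot_q = 0.0
    for i in range(n):
        tot_y += wys[i]
        tot_w += wr2s[i]
        tot_t += treated[i]
        tot_y2 += wys[i] * wys[i]
        tot_cross += wys[i] * wr2s[i]
        tot_q += wr2s[i] * wr2s[i]
    best = -1
    best_crit = 0.0
    cy = 0.0
    cw = 0.0
    ct = 0
    cy2 = 0.0
    ccross = 0.0
    cq = 0.0
    for t in range(1, n):
        i = t - 1
        cy += wys[i]
        cw += wr2s[i]
        ct += treated[i]
        cy2 += wys[i] * wys[i]
        ccross += wys[i] * wr2s[i]
        cq += wr2s[i] * wr2s[i]
        if xs[i] >= xs[t]:
            continue  # tied values: threshold must separate observed values
        if t < min_size or n - t < min_size:
            continue
        lt = ct
        lc = t - ct
        rt = tot_t - ct
        rc = (n - t) - rt
        if lt < min_arm or lc < min_arm or rt < min_arm or rc < min_arm:
            continue
        bl = cw
        br = tot_w - cw
        if bl <= 0.0 or br <= 0.0:
            continue
        tau_l = cy / bl
        tau_r = (tot_y - cy) / br
        contrast = (tau_l - tau_r) ** 2
        if penalty > 0.0:
            var_l = (cy2 - 2.0 * tau_l * ccross + tau_l * tau_l * cq) / (bl * bl)
            var_r = ((tot_y2 - cy2) - 2.0 * tau_r * (tot_cross - ccross)
                     + tau_r * tau_r * (tot_q - cq)) / (br * br)
            contrast -= penalty * (var_l + var_r)
        crit = t * (n - t) * contrast
        if crit > best_crit:
            best_crit = crit
            best = i
    return best, best_crit


class _TreeBuilder:
    def __init__(self, X, wr, yr, treated, mtry, min_node, min_arm,
                 balance_fraction, variance_penalty, rng):
        self.X, self.wr2, self.wy = X, wr ** 2, wr * yr
        self.treated = treated
        self.mtry, self.min_node, self.min_arm = mtry, min_node, min_arm
        self.balance_fraction = balance_fraction
        self.variance_penalty = variance_penalty
        self.rng = rng
        self.K = X.shape[1]
        self.feature: list[int] = []
        self.threshold: list[float] = []
        self.left: list[int] = []
        self.right: list[int] = []
        self.grow_leaf_members: dict[int, np.ndarray] = {}

    def new_node(self) -> int:
        self.feature.append(-1)
        self.threshold.append(np.nan)
        self.left.append(-1)
        self.right.append(-1)
        return len(self.feature) - 1

    def build(self, idx: np.ndarray) -> int:
        node = self.new_node()
        if len(idx) < 2 * self.min_node:
            self.grow_leaf_members[node] = idx
            return node
        candidates = self.rng.choice(self.K, size=self.mtry, replace=False)
        min_child = int(np.ceil(self.balance_fraction * len(idx)))
        best = None
        for j in candidates:
            res = _best_split(self.X[idx, j], self.wr2[idx], self.wy[idx],
                              self.treated[idx], self.min_node, self.min_arm,
                              min_child, self.variance_penalty)
            if res is None:
                continue
            crit, thr, order, pos = res
            if best is None or crit > best[0]:
                best = (crit, int(j), thr, order, pos)
        if best is None:
            self.grow_leaf_members[node] = idx
            return node
        _, j, thr, order, pos = best
        left_idx = idx[order[:pos + 1]]
        right_idx = idx[order[pos + 1:]]
        self.feature[node] = j
        self.threshold[node] = thr
        self.left[node] = self.build(left_idx)
        self.right[node] = self.build(right_idx)
        return node


def grow_causal_tree(
    X: np.ndarray, w_resid: np.ndarray, y_resid: np.ndarray, treated: np.ndarray,
    params: ForestParams, rng: np.random.Generator,
) -> _TreeBuilder:
    """Grow one causal tree on the grow half (recursive greedy splitting)."""
    builder = _TreeBuilder(
        X, w_resid, y_resid, treated,
        mtry=params.resolved_mtry(X.shape[1]),
        min_node=params.min_node_size, min_arm=params.min_arm_per_child,
        balance_fraction=params.balance_fraction,
        variance_penalty=params.variance_penalty, rng=rng,
    )
    builder.root = builder.build(np.arange(len(X)))
    return builder


def _prune_empty(feature, left, right, counts, node):
    """Collapse leaves with no estimate-half members into their siblings."""
    if feature[node] < 0:
        return node if counts[node] > 0 else -1
    l = _prune_empty(feature, left, right, counts, left[node])
    r = _prune_empty(feature, left, right, counts, right[node])
    if l < 0 and r < 0:
        return -1
    if l < 0:
        return r
    if r < 0:
        return l
    left[node], right[node] = l, r
    return node


# --------------------------------------------------------------- forest fit


def fit_causal_forest(
    data: TrialDataset,
    nuisance: NuisanceEstimates,
    params: ForestParams | None = None,
) -> CausalForestModel:
    """Fit an honest causal forest and compute out-of-bag CATEs.

    Each of the B trees is grown on a without-replacement subsample (half
    the data by default), itself split half/half into a grow half and an
    estimate half. Leaf-level effect contributions come exclusively from
    estimate-half members; a leaf left empty of estimate rows is collapsed
    into its sibling. The out-of-bag CATE for row i aggregates leaf-mean
    contributions over exactly those trees whose subsample excluded i,
    which is the co-leaf-membership weighting of the ratio estimator.
    """
    params = params or ForestParams()
    if params.n_trees < 10:
        raise ValueError("refusing to fit fewer than 10 trees: weights are too sparse")
    X = data.matrix()
    n = data.n
    wr, yr = nuisance.residuals(data)
    treated = (data.w > 0.5).astype(np.int64)
    rng = np.random.Generator(np.random.PCG64(params.seed))

    n_sub = int(round(params.subsample_fraction * n))
    n_grow = int(round(params.honesty_fraction * n_sub))
    trees: list[CausalTree] = []
    num = np.zeros(n)
    den = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)

    for _ in range(params.n_trees):
        subsample = rng.choice(n, size=n_sub, replace=False)
        grow_idx = subsample[:n_grow]
        est_idx = subsample[n_grow:]

        builder = grow_causal_tree(X[grow_idx], wr[grow_idx], yr[grow_idx],
                                   treated[grow_idx], params, rng)
        feature = np.asarray(builder.feature, dtype=np.int64)
        threshold = np.asarray(builder.threshold, dtype=float)
        left = np.asarray(builder.left, dtype=np.int64)
        right = np.asarray(builder.right, dtype=np.int64)

        tmp = CausalTree(feature, threshold, left, right, builder.root,
                         grow_idx, est_idx, np.empty(0, dtype=np.int64),
                         np.empty(0), np.empty(0), np.empty(0, dtype=np.int64))
        est_leaf = tmp.route(X[est_idx])
        leaf_size = np.bincount(est_leaf, minlength=len(feature))
        root = _prune_empty(feature, left, right, leaf_size, builder.root)
        if root < 0:  # no estimate rows at all (cannot happen for n_sub >= 2)
            continue

        leaf_num = np.zeros(len(feature))
        leaf_den = np.zeros(len(feature))
        np.add.at(leaf_num, est_leaf, wr[est_idx] * yr[est_idx])
        np.add.at(leaf_den, est_leaf, wr[est_idx] ** 2)
        nonzero = leaf_size > 0
        leaf_num[nonzero] /= leaf_size[nonzero]
        leaf_den[nonzero] /= leaf_size[nonzero]

        tree = CausalTree(feature, threshold, left, right, int(root),
                          grow_idx, est_idx, est_leaf,
                          leaf_num, leaf_den, leaf_size)
        trees.append(tree)

        oob = np.ones(n, dtype=bool)
        oob[subsample] = False
        oob_idx = np.flatnonzero(oob)
        leaf_q = tree.route(X[oob_idx])
        num[oob_idx] += leaf_num[leaf_q]
        den[oob_idx] += leaf_den[leaf_q]
        counts[oob_idx] += 1

    with np.errstate(divide="ignore", invalid="ignore"):
        tau_oob = np.where((counts > 0) & (den > 0), num / den, np.nan)
    return CausalForestModel(
        trees=trees, nuisance=nuisance, tau_oob=tau_oob, oob_tree_counts=counts,
        params=params, feature_names=data.covariate_names, w_resid=wr, y_resid=yr,
    )


def forest_weights(model: CausalForestModel, X_all: np.ndarray, x_query: np.ndarray,
                   exclude: int | None = None) -> np.ndarray:
    """Forest weights a_i(x) over all rows for one query point.

    Weights are the co-leaf-membership frequencies of the estimate halves,
    normalised by leaf size and averaged over the contributing trees (all
    trees, or only those excluding row ``exclude``); they sum to one
    whenever any tree contributes.
    """
    n = len(X_all)
    weights = np.zeros(n)
    used = 0
    xq = x_query.reshape(1, -1)
    for tree in model.trees:
        if exclude is not None and (tree.subsample_indices == exclude).any():
            continue
        leaf = int(tree.route(xq)[0])
        members = tree.estimate_indices[tree.leaf_of_estimate == leaf]
        if len(members) == 0:
            continue
        weights[members] += 1.0 / len(members)
        used += 1
    if used:
        weights /= used
    return weights


# ------------------------------------------------------------ post-estimation


def test_calibration(model: CausalForestModel, data: TrialDataset) -> CalibrationTest:
    """Omnibus calibration (heterogeneity) test on out-of-bag CATEs.

    Regresses the outcome residual on A_i = mean(tau)*w_resid_i and
    D_i = (tau_i - mean(tau))*w_resid_i without intercept. The coefficient
    on D is the differential forest prediction (DFP): a value near 1 means
    the forest's heterogeneity is well calibrated, and the one-sided
    HC3-robust p-value on DFP > 0 tests for the presence of heterogeneity.
    """
    tau = model.tau_oob
    ok = np.isfinite(tau)
    tau, wr, yr = tau[ok], model.w_resid[ok], model.y_resid[ok]
    tau_bar = float(tau.mean())
    D = (tau - tau_bar) * wr
    if np.allclose(D, 0):
        return CalibrationTest(np.nan, np.nan, np.nan,
                               note="no heterogeneity detected: CATEs are constant")
    A = tau_bar * wr
    design = np.column_stack([A, D])
    fit = sm.OLS(yr, design).fit(cov_type="HC3")
    dfp = float(fit.params[1])
    tstat = float(fit.tvalues[1])
    p = float(_student_t.sf(tstat, df=fit.df_resid))
    return CalibrationTest(
        mean_forest_prediction_coef=float(fit.params[0]),
        differential_forest_prediction=dfp,
        dfp_p_value=p,
    )


def variable_importance(model: CausalForestModel, max_depth: int = 4,
                        decay: float = 2.0) -> dict[str, float]:
    """Depth-weighted split-frequency importance.

    importance(j) proportional to sum over depths d = 1..max_depth of
    (fraction of depth-d splits made on variable j) * d^(-decay),
    normalised to sum to one. A forest of stumps gives all zeros.
    """
    K = len(model.feature_names)
    counts = np.zeros((max_depth, K))
    for tree in model.trees:
        depths = tree.node_depths()
        internal = tree.feature >= 0
        reachable = depths > 0
        for node in np.flatnonzero(internal & reachable):
            d = depths[node]
            if d <= max_depth:
                counts[d - 1, tree.feature[node]] += 1
    scores = np.zeros(K)
    for d in range(max_depth):
        total = counts[d].sum()
        if total > 0:
            scores += counts[d] / total * (d + 1) ** (-decay)
    if scores.sum() > 0:
        scores /= scores.sum()
    return dict(zip(model.feature_names, scores))


def dr_scores(model: CausalForestModel, data: TrialDataset) -> np.ndarray:
    """Per-participant doubly robust (AIPW) scores Gamma_i.

    Gamma_i = tau_i + (W_i - p_i)/(p_i(1-p_i)) *
              (Y_i - m_i - (W_i - p_i)*tau_i).
    Their subgroup means estimate GATEs; clipped propensities keep the
    inverse-propensity factor finite.
    """
    tau = model.tau_oob
    p = model.nuisance.p_hat
    correction = (data.w - p) / (p * (1 - p)) * (
        data.y - model.nuisance.m_hat - (data.w - p) * tau
    )
    return tau + correction


def average_treatment_effect(scores: np.ndarray, subset: np.ndarray | None = None,
                             definition: str = "all") -> GateResult:
    """Subgroup ATE from doubly robust scores: mean, SE and 95% CI.

    The CI uses the i.i.d. sampling SE of the scores within the subgroup;
    because the same data fitted the forest, this can understate the
    uncertainty and carries a standing warning.
    """
    scores = np.asarray(scores, dtype=float)
    if subset is None:
        subset = np.ones(len(scores), dtype=bool)
    subset = np.asarray(subset, dtype=bool)
    sub = scores[subset]
    sub = sub[np.isfinite(sub)]
    if len(sub) == 0:
        raise ValueError(f"subset {definition!r} is empty")
    gate = float(sub.mean())
    se = float(sub.std(ddof=1) / np.sqrt(len(sub))) if len(sub) > 1 else 0.0
    warn = ["GATE confidence intervals may understate uncertainty; "
            "interpret cautiously"]
    if abs(gate) > 1:
        warn.append("GATE outside [-1, 1] for a binary outcome; check scores")
    return GateResult(
        subset_definition=definition, n_subset=int(len(sub)), dr_scores=sub,
        gate=gate, se=se,
        ci_low=gate - 1.959963984540054 * se, ci_high=gate + 1.959963984540054 * se,
        small_sample=len(sub) < 10, warnings=warn,
    )
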