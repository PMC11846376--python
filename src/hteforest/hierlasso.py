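"""Strong-hierarchy penalised logistic regression for treatment interactions.

The model contains the treatment, every baseline covariate, and every
treatment-by-covariate interaction:

    logit E[Y | W, X] = b0 + b1*W + sum_k { b2_k*X_k + b3_k*W*X_k }.

Penalisation follows the overlapped-group (latent) construction behind
hierarchical group-lasso interaction models: each coefficient is a sum of
latent copies, with

* unpenalised intercept,
* an L1-penalised singleton copy for the treatment and for each covariate
  main effect,
* one three-member group per covariate holding latent copies of the
  treatment effect, that covariate's main effect, and their interaction.

An interaction coefficient can only be nonzero through its group, which
simultaneously activates latent main-effect copies, so the fit satisfies
the strong hierarchy b3_k != 0  =>  b2_k != 0 and b1 != 0 by construction.
Three-member groups carry the sqrt(group size) penalty weight, keeping
singleton and group penalties on a comparable per-coefficient scale.

The penalised negative log-likelihood (mean over observations) is minimised
by monotone proximal-gradient descent with backtracking line search, warm
starts along a geometric lambda path, and relative-objective convergence
at 1e-7. The penalty is selected by 5-fold cross-validation, stratified by
outcome, scoring mean held-out binomial deviance per observation.

Analysis weights (IPW pathway) are not supported by this model and are
ignored with a recorded note.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from scipy.stats import norm as _norm

from .dataset import TrialDataset

__all__ = ["HierLassoFit", "PostSelectionTest", "fit_hierlasso_path",
           "cv_select_lambda", "post_selection_test", "assert_strong_hierarchy"]

_ZERO_TOL = 1e-8


@dataclass
class HierLassoFit:
    covariates: list[str]
    lambda_path: np.ndarray
    coef_path: np.ndarray          # (n_lambda, 2 + 2K): b0, b1, b2_k..., b3_k...
    theta_path: np.ndarray         # latent parameters, for warm starts / audits
    converged: np.ndarray          # per-lambda flag
    cv_error_path: np.ndarray | None = None
    selected_lambda: float | None = None
    selected_index: int | None = None
    notes: list[str] = field(default_factory=list)

    # ---- views at the selected lambda ------------------------------------
    def _index(self, index: int | None = None) -> int:
        if index is None:
            if self.selected_index is None:
                raise ValueError("no lambda selected; run cv_select_lambda")
            index = self.selected_index
        return index

    def coefficients(self, index: int | None = None) -> dict[str, float]:
        beta = self.coef_path[self._index(index)]
        K = len(self.covariates)
        out = {"(Intercept)": beta[0], "W": beta[1]}
        for k, name in enumerate(self.covariates):
            out[name] = beta[2 + k]
            out[f"W:{name}"] = beta[2 + K + k]
        return out

    def selected_interactions(self, index: int | None = None) -> list[str]:
        beta = self.coef_path[self._index(index)]
        K = len(self.covariates)
        return [name for k, name in enumerate(self.covariates)
                if abs(beta[2 + K + k]) > _ZERO_TOL]

    def standardized_or(self, index: int | None = None) -> dict[str, float]:
        return {term: float(np.exp(v)) for term, v in self.coefficients(index).items()
                if term != "(Intercept)" and abs(v) > _ZERO_TOL}


@dataclass
class PostSelectionTest:
    term: str
    selected: bool
    p_value: float | None
    estimate: float | None
    mechanism: str = "naive_refit_wald"

    @property
    def detected(self) -> bool:
        """Significance at 0.05; a term never selected counts as non-detection."""
        return self.selected and self.p_value is not None and self.p_value < 0.05


# --------------------------------------------------------------------------
# internal solver


class _Problem:
    """Smooth logistic loss + overlapped-group penalty bookkeeping.

    Latent layout: [b0, uW, u_1..u_K, vW_1..vW_K, vX_1..vX_K, vI_1..vI_K].
    """

    def __init__(self, y: np.ndarray, w: np.ndarray, Xc: np.ndarray):
        self.y = y
        self.n, self.K = Xc.shape
        self.design = np.column_stack([np.ones(self.n), w, Xc, w[:, None] * Xc])
        self.dim = 2 + 4 * self.K

    def beta_of(self, theta: np.ndarray) -> np.ndarray:
        K = self.K
        beta = np.empty(2 + 2 * K)
        beta[0] = theta[0]
        beta[1] = theta[1] + theta[2 + K:2 + 2 * K].sum()
        beta[2:2 + K] = theta[2:2 + K] + theta[2 + 2 * K:2 + 3 * K]
        beta[2 + K:] = theta[2 + 3 * K:]
        return beta

    def loss_grad(self, theta: np.ndarray):
        beta = self.beta_of(theta)
        eta = self.design @ beta
        # mean logistic nll; stable log(1 + e^eta)
        loss = float(np.mean(np.logaddexp(0.0, eta) - self.y * eta))
        gbeta = self.design.T @ (expit(eta) - self.y) / self.n
        K = self.K
        g = np.empty(self.dim)
        g[0] = gbeta[0]
        g[1] = gbeta[1]
        g[2:2 + K] = gbeta[2:2 + K]
        g[2 + K:2 + 2 * K] = gbeta[1]
        g[2 + 2 * K:2 + 3 * K] = gbeta[2:2 + K]
        g[2 + 3 * K:] = gbeta[2 + K:]
        return loss, g

    def loss(self, theta: np.ndarray) -> float:
        eta = self.design @ self.beta_of(theta)
        return float(np.mean(np.logaddexp(0.0, eta) - self.y * eta))

    #: group-lasso weight for the three-member interaction groups
    #: (sqrt of group size, the Yuan-Lin convention), keeping singleton
    #: and group penalties on a comparable per-coefficient scale
    GROUP_WEIGHT = np.sqrt(3.0)

    def penalty(self, theta: np.ndarray, lam: float) -> float:
        K = self.K
        singles = np.abs(theta[1:2 + K]).sum()
        v = theta[2 + K:].reshape(3, K)
        groups = np.sqrt((v ** 2).sum(axis=0)).sum()
        return lam * (singles + self.GROUP_WEIGHT * groups)

    def prox(self, theta: np.ndarray, step_lam: float) -> np.ndarray:
        K = self.K
        out = theta.copy()
        s = out[1:2 + K]
        out[1:2 + K] = np.sign(s) * np.maximum(np.abs(s) - step_lam, 0.0)
        v = out[2 + K:].reshape(3, K)
        norms = np.sqrt((v ** 2).sum(axis=0))
        shrink = np.where(
            norms > 0,
            np.maximum(1 - self.GROUP_WEIGHT * step_lam / norms, 0.0), 0.0)
        out[2 + K:] = (v * shrink).ravel()
        return out

    def lambda_max(self) -> tuple[float, np.ndarray]:
        """Smallest lambda at which all penalised groups are zero.

        Computed from the gradient at the intercept-only fit.
        """
        theta0 = np.zeros(self.dim)
        ybar = float(np.clip(self.y.mean(), 1e-12, 1 - 1e-12))
        theta0[0] = np.log(ybar / (1 - ybar))
        _, g = self.loss_grad(theta0)
        K = self.K
        singles = np.abs(g[1:2 + K])
        v = g[2 + K:].reshape(3, K)
        groups = np.sqrt((v ** 2).sum(axis=0)) / self.GROUP_WEIGHT
        return float(max(singles.max(), groups.max())), theta0

    def solve(self, lam: float, theta: np.ndarray, tol: float = 1e-7,
              max_iter: int = 5000) -> tuple[np.ndarray, bool]:
        """Monotone proximal-gradient descent with backtracking."""
        theta = theta.copy()
        loss, grad = self.loss_grad(theta)
        obj = loss + self.penalty(theta, lam)
        step = 4.0  # loss curvature <= ||design||^2/(4n); start optimistic
        converged = False
        for _ in range(max_iter):
            while True:
                cand = self.prox(theta - step * grad, step * lam)
                delta = cand - theta
                cand_loss = self.loss(cand)
                quad = loss + grad @ delta + (delta @ delta) / (2 * step)
                if cand_loss <= quad + 1e-12:
                    break
                step *= 0.5
                if step < 1e-12:
                    break
            new_obj = cand_loss + self.penalty(cand, lam)
            if new_obj > obj + 1e-12:  # safeguard monotonicity
                break
            theta = cand
            if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
                obj = new_obj
                converged = True
                break
            obj = new_obj
            loss, grad = self.loss_grad(theta)
            step *= 1.5
        return theta, converged


def _standardisation_check(data: TrialDataset) -> None:
    for name in data.X.columns:
        if data.meta[name].kind == "continuous":
            col = data.X[name].to_numpy(dtype=float)
            col = col[~np.isnan(col)]
            if abs(col.mean()) > 1e-3 or abs(col.std(ddof=1) - 1) > 1e-3:
                raise ValueError(
                    f"continuous covariate {name!r} is not centred/scaled; "
                    "run preprocess.encode_and_scale first"
                )


def _problem_for(data: TrialDataset) -> _Problem:
    Xc = data.matrix()
    if np.isnan(Xc).any():
        raise ValueError("hierarchical lasso requires complete covariates")
    return _Problem(data.y, data.w, Xc)


def fit_hierlasso_path(
    data: TrialDataset,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.001,
    lambdas: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> HierLassoFit:
    """Fit the penalised model along a geometric lambda path with warm starts."""
    _standardisation_check(data)
    return _fit_path(data, n_lambda=n_lambda, lambda_min_ratio=lambda_min_ratio,
                     lambdas=lambdas, tol=tol, max_iter=max_iter)


def _fit_path(
    data: TrialDataset,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.001,
    lambdas: np.ndarray | None = None,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> HierLassoFit:
    prob = _problem_for(data)
    lam_max, theta = prob.lambda_max()
    if lambdas is None:
        lambdas = np.geomspace(lam_max, lambda_min_ratio * lam_max, n_lambda)
    lambdas = np.asarray(lambdas, dtype=float)
    coef_path = np.empty((len(lambdas), 2 + 2 * prob.K))
    theta_path = np.empty((len(lambdas), prob.dim))
    flags = np.zeros(len(lambdas), dtype=bool)
    notes = []
    if data.weights is not None:
        notes.append("analysis weights are not supported by this model; ignored")
    for i, lam in enumerate(lambdas):
        theta, ok = prob.solve(lam, theta, tol=tol, max_iter=max_iter)
        coef_path[i] = prob.beta_of(theta)
        theta_path[i] = theta
        flags[i] = ok
    return HierLassoFit(
        covariates=data.covariate_names,
        lambda_path=lambdas, coef_path=coef_path, theta_path=theta_path,
        converged=flags, notes=notes,
    )


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    assignment = np.empty(len(y), dtype=int)
    for cls in (0.0, 1.0):
        idx = np.flatnonzero(y == cls)
        perm = rng.permutation(idx)
        assignment[perm] = np.arange(len(perm)) % folds
    return assignment


def cv_select_lambda(
    data: TrialDataset,
    folds: int = 5,
    seed: int = 0,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.001,
    tol: float = 1e-7,
    max_iter: int = 5000,
) -> HierLassoFit:
    """Select the penalty by stratified K-fold CV and refit on the full data.

    CV error is the mean held-out binomial deviance per observation; the
    argmin along the path is selected (ties resolve to the strongest
    penalty). A degenerate fold with a single outcome class triggers one
    re-randomisation before failing.
    """
    _standardisation_check(data)
    full = fit_hierlasso_path(data, n_lambda=n_lambda,
                              lambda_min_ratio=lambda_min_ratio,
                              tol=tol, max_iter=max_iter)
    lambdas = full.lambda_path
    rng = np.random.Generator(np.random.PCG64(seed))
    assignment = _stratified_folds(data.y, folds, rng)
    for _attempt in range(2):
        ok = all(len(np.unique(data.y[assignment == f])) == 2 for f in range(folds))
        if ok:
            break
        assignment = _stratified_folds(data.y, folds, rng)
    else:
        raise ValueError("cross-validation folds degenerate: a fold has one outcome class")

    deviance = np.zeros((folds, len(lambdas)))
    for f in range(folds):
        test = assignment == f
        train_data = data.subset_rows(~test)
        fold_fit = _fit_path(train_data, lambdas=lambdas,
                             tol=tol, max_iter=max_iter)
        prob_test = _Problem(data.y[test], data.w[test],
                             data.matrix()[test])
        for i in range(len(lambdas)):
            eta = prob_test.design @ fold_fit.coef_path[i]
            nll = np.mean(np.logaddexp(0.0, eta) - data.y[test] * eta)
            deviance[f, i] = 2.0 * nll
    cv_error = deviance.mean(axis=0)
    best = int(np.argmin(cv_error))
    full.cv_error_path = cv_error
    full.selected_index = best
    full.selected_lambda = float(lambdas[best])
    return full


def post_selection_test(fit: HierLassoFit, data: TrialDataset,
                        term: str) -> PostSelectionTest:
    """Wald p-value for ``term`` from an unpenalised refit on the selected support.

    The refit includes the intercept, the treatment, every selected main
    effect and every selected interaction. This is a naive (non-selective)
    test: the same data chose the support, so p-values are optimistic; the
    mechanism name is recorded so alternatives can be swapped in. A term
    the lasso did not retain yields a defined "not selected" outcome.
    """
    coefs = fit.coefficients()
    if term not in coefs:
        raise KeyError(f"unknown term {term!r}")
    if abs(coefs[term]) <= _ZERO_TOL:
        return PostSelectionTest(term=term, selected=False, p_value=None, estimate=None)

    K = len(fit.covariates)
    beta = fit.coef_path[fit._index()]
    cols: list[np.ndarray] = [np.ones(data.n), data.w]
    names = ["(Intercept)", "W"]
    Xc = data.matrix()
    for k, name in enumerate(fit.covariates):
        if abs(beta[2 + k]) > _ZERO_TOL:
            cols.append(Xc[:, k])
            names.append(name)
    for k, name in enumerate(fit.covariates):
        if abs(beta[2 + K + k]) > _ZERO_TOL:
            cols.append(data.w * Xc[:, k])
            names.append(f"W:{name}")
    design = np.column_stack(cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        refit = sm.GLM(data.y, design, family=sm.families.Binomial()).fit(maxiter=100)
    j = names.index(term)
    est = float(refit.params[j])
    se = float(refit.bse[j])
    if not np.isfinite(se) or se == 0:
        return PostSelectionTest(term=term, selected=True, p_value=1.0, estimate=est)
    p = float(2 * _norm.sf(abs(est / se)))
    return PostSelectionTest(term=term, selected=True, p_value=p, estimate=est)


def assert_strong_hierarchy(fit: HierLassoFit, tol: float = _ZERO_TOL) -> None:
    """Raise if any interaction is active without both its main effects."""
    K = len(fit.covariates)
    for i in range(len(fit.lambda_path)):
        beta = fit.coef_path[i]
        for k, name in enumerate(fit.covariates):
            if abs(beta[2 + K + k]) > tol:
                if abs(beta[2 + k]) == 0.0 or abs(beta[1]) == 0.0:
                    raise AssertionError(
                        f"hierarchy violated at lambda index {i} for {name}"
                    )
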