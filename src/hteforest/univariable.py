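"""Classical per-covariate treatment-interaction screen.

For each candidate effect modifier ``X_k`` a separate logistic model

    logit E[Y | W, X_k] = b0 + b1*W + b2*X_k + b3*W*X_k

is fitted by maximum likelihood (an intercept is always included) and the
Wald test of the interaction coefficient ``b3`` is reported as an odds
ratio with a 95% CI. Across the K screens the Bonferroni threshold
``alpha / K`` controls family-wise error; Benjamini-Hochberg FDR flags are
computed alongside for volcano-plot colouring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm as _norm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .dataset import TrialDataset

__all__ = ["InteractionResult", "ScreenResult", "fit_interaction_logistic",
           "run_screen", "volcano_table"]

#: cap for -log10(p) when p underflows to zero
NEGLOG10_CEILING = 300.0
#: Wald SE above which a fit is treated as separated/unstable
_SE_SENTINEL = 1e3


@dataclass
class InteractionResult:
    covariate: str
    beta1: float  # treatment main effect (log-odds)
    beta2: float  # covariate main effect
    beta3: float  # treatment-by-covariate interaction
    se3: float
    or3: float
    ci3_low: float
    ci3_high: float
    p3: float
    converged: bool
    bonferroni_significant: bool = False
    fdr_significant: bool = False


@dataclass
class ScreenResult:
    results: list[InteractionResult]
    alpha: float
    bonferroni_threshold: float

    @property
    def n_tests(self) -> int:
        return len(self.results)


def fit_interaction_logistic(data: TrialDataset, covariate: str) -> InteractionResult:
    """Fit one interaction model and test b3 (Wald).

    Rows with a missing covariate value are dropped for this fit. Analysis
    weights, when present (IPW pathway), enter as frequency-type variance
    weights. Non-convergence or separation yields ``converged=False`` with
    an infinite-CI sentinel rather than an exception.
    """
    if covariate not in data.X.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    x = data.X[covariate].to_numpy(dtype=float)
    keep = ~np.isnan(x)
    y, w, x = data.y[keep], data.w[keep], x[keep]
    vw = data.effective_weights()[keep]
    design = np.column_stack([np.ones(len(y)), w, x, w * x])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = sm.GLM(y, design, family=sm.families.Binomial(), var_weights=vw).fit(
                maxiter=100
            )
        converged = bool(fit.converged) and np.all(np.isfinite(fit.bse)) \
            and fit.bse[3] < _SE_SENTINEL
    except (PerfectSeparationWarning, Exception):
        converged = False
        fit = None

    if fit is None or not converged:
        b = fit.params if fit is not None else np.full(4, np.nan)
        return InteractionResult(
            covariate=covariate, beta1=float(b[1]), beta2=float(b[2]),
            beta3=float(b[3]), se3=np.inf, or3=float(np.exp(b[3])),
            ci3_low=0.0, ci3_high=np.inf, p3=1.0, converged=False,
        )
    b3, se3 = float(fit.params[3]), float(fit.bse[3])
    z = b3 / se3 if se3 > 0 else 0.0
    p3 = float(2 * _norm.sf(abs(z)))
    return InteractionResult(
        covariate=covariate,
        beta1=float(fit.params[1]), beta2=float(fit.params[2]), beta3=b3, se3=se3,
        or3=float(np.exp(b3)),
        ci3_low=float(np.exp(b3 - 1.959963984540054 * se3)),
        ci3_high=float(np.exp(b3 + 1.959963984540054 * se3)),
        p3=p3, converged=True,
    )


def run_screen(data: TrialDataset, alpha: float = 0.05) -> ScreenResult:
    """One interaction fit per covariate with Bonferroni and BH-FDR flags."""
    names = data.covariate_names
    if not names:
        raise ValueError("no covariates to screen")
    results = [fit_interaction_logistic(data, name) for name in names]
    threshold = alpha / len(results)
    pvals = np.array([r.p3 for r in results])
    fdr_flags = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    for r, fdr in zip(results, fdr_flags):
        r.bonferroni_significant = bool(r.p3 < threshold)
        r.fdr_significant = bool(fdr)
    return ScreenResult(results=results, alpha=alpha, bonferroni_threshold=threshold)


def volcano_table(screen: ScreenResult) -> pd.DataFrame:
    """Effect size vs. -log10 p table for volcano plotting (no refitting)."""
    rows = []
    for r in screen.results:
        neglog = NEGLOG10_CEILING if r.p3 <= 0 else min(-np.log10(r.p3), NEGLOG10_CEILING)
        rows.append({
            "covariate": r.covariate,
            "log_or": r.beta3,
            "neglog10_p": neglog,
            "bonferroni_significant": r.bonferroni_significant,
            "fdr_significant": r.fdr_significant,
            "converged": r.converged,
        })
    return pd.DataFrame(rows)
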