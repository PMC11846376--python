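"""Covariate screening, encoding/scaling, and missing-data strategies.

The preprocessing pipeline mirrors standard practice for baseline-covariate
HTE screens in critical-care trials:

1. drop covariates with >= 30% missingness (only columns with < 30%
   missing are considered candidate effect modifiers),
2. drop one member of each highly correlated pair (|Pearson r| > 0.7),
   keeping the column carrying more information,
3. one-hot encode categoricals (all levels kept) and centre/scale
   continuous columns to mean 0, SD 1 (sample SD, ddof=1),
4. handle remaining missingness by iterative random-forest imputation
   (MissForest-style), mean/mode imputation, complete-case deletion, or
   inverse-probability-of-completeness weighting (IPW).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

import statsmodels.api as sm

from .dataset import FeatureMeta, TrialDataset

__all__ = [
    "PreprocessReport",
    "EmptyDesignError",
    "filter_high_missingness",
    "filter_correlated",
    "encode_and_scale",
    "impute",
]


class EmptyDesignError(ValueError):
    """All covariates were removed; no design left to analyse."""


@dataclass
class PreprocessReport:
    removed_for_missingness: list[tuple[str, float]] = field(default_factory=list)
    removed_for_correlation: list[tuple[str, str, float]] = field(default_factory=list)
    dropped_zero_variance: list[str] = field(default_factory=list)
    imputation_method: str = "none"
    iterations_run: int = 0
    convergence_trace: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def filter_high_missingness(
    data: TrialDataset, max_fraction: float = 0.3
) -> tuple[TrialDataset, PreprocessReport]:
    """Drop covariates whose missing fraction is >= ``max_fraction``.

    Strict "< 30% considered": a column exactly at the boundary is dropped.
    Outcome and treatment are never touched.
    """
    if not 0 < max_fraction < 1:
        raise ValueError("max_fraction must lie in (0, 1)")
    report = PreprocessReport()
    fractions = data.X.isna().mean()
    drop = [name for name in data.X.columns if fractions[name] >= max_fraction]
    report.removed_for_missingness = [(name, float(fractions[name])) for name in drop]
    out = data.drop_covariates(drop)
    for name in out.X.columns:
        out.meta[name].missing_fraction = float(fractions[name])
    if out.X.shape[1] == 0:
        raise EmptyDesignError("every covariate exceeded the missingness threshold")
    return out, report


def _pairwise_r(X: pd.DataFrame) -> pd.DataFrame:
    # pairwise-complete Pearson correlations; categoricals coded by level rank
    numeric = X.copy()
    for name in numeric.columns:
        if numeric[name].dtype == object:
            numeric[name] = numeric[name].astype("category").cat.codes.replace(-1, np.nan)
    return numeric.astype(float).corr(method="pearson")


def filter_correlated(
    data: TrialDataset, r_max: float = 0.7
) -> tuple[TrialDataset, PreprocessReport]:
    """Greedily drop one member of each pair with |Pearson r| > ``r_max``.

    Pairs are visited in order of decreasing |r|; within a pair the member
    with the higher missing fraction is dropped, ties broken in favour of
    dropping a declared derived score, then the later column. Columns
    already dropped by an earlier (stronger) pair are skipped.
    """
    if not 0 < r_max < 1:
        raise ValueError("r_max must lie in (0, 1)")
    report = PreprocessReport()
    corr = _pairwise_r(data.X)
    names = list(data.X.columns)
    pairs = []
    for a_pos, a in enumerate(names):
        for b in names[a_pos + 1:]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > r_max:
                pairs.append((abs(r), a, b, float(r)))
    pairs.sort(key=lambda t: -t[0])

    missing = data.X.isna().mean()
    dropped: set[str] = set()
    for _, a, b, r in pairs:
        if a in dropped or b in dropped:
            continue
        keep, drop = _rank_pair(a, b, missing, data.meta, names)
        dropped.add(drop)
        report.removed_for_correlation.append((keep, drop, r))
    out = data.drop_covariates(sorted(dropped, key=names.index))
    if out.X.shape[1] == 0:
        raise EmptyDesignError("every covariate was removed by the correlation filter")
    return out, report


def _rank_pair(a, b, missing, meta, names):
    """Return (keep, drop): drop the least informative member."""
    ma, mb = missing[a], missing[b]
    if ma != mb:
        return (a, b) if mb > ma else (b, a)
    da, db = meta[a].derived_score, meta[b].derived_score
    if da != db:
        return (a, b) if db else (b, a)
    return (a, b) if names.index(b) > names.index(a) else (b, a)


def encode_and_scale(data: TrialDataset) -> tuple[TrialDataset, PreprocessReport]:
    """One-hot encode categoricals; centre and scale continuous columns.

    Every categorical level becomes its own indicator (no reference level
    is dropped: downstream models are penalised or tree-based, so the
    redundancy is harmless and keeps levels interpretable). Continuous
    columns are standardised with the sample SD (ddof=1) computed over
    observed values; the original mean/SD are stored so learned thresholds
    can be mapped back to raw units. Zero-variance continuous columns are
    dropped with a warning in the report.
    """
    report = PreprocessReport()
    columns: dict[str, np.ndarray] = {}
    meta: dict[str, FeatureMeta] = {}
    for name in data.X.columns:
        fm = data.meta[name]
        col = data.X[name]
        if fm.kind == "categorical":
            observed = col.dropna()
            for level in sorted(observed.unique()):
                new = f"{name}={level}"
                indicator = np.where(col.isna(), np.nan, (col == level).astype(float))
                columns[new] = indicator
                meta[new] = FeatureMeta(
                    name=new, kind="onehot_level", parent=name,
                    missing_fraction=fm.missing_fraction,
                )
        elif fm.kind == "continuous":
            values = col.to_numpy(dtype=float)
            observed = values[~np.isnan(values)]
            mu = float(observed.mean())
            sd = float(observed.std(ddof=1))
            # relative threshold: constant columns can carry O(eps) spread
            if not np.isfinite(sd) or sd <= 1e-12 * (1.0 + abs(mu)):
                report.dropped_zero_variance.append(name)
                report.warnings.append(f"dropped zero-variance column {name!r}")
                continue
            columns[name] = (values - mu) / sd
            meta[name] = replace(fm, mean=mu, sd=sd)
        else:
            columns[name] = col.to_numpy(dtype=float)
            meta[name] = replace(fm)
    if not columns:
        raise EmptyDesignError("no covariates survived encoding")
    out = TrialDataset(
        y=data.y.copy(), w=data.w.copy(), X=pd.DataFrame(columns), meta=meta,
        weights=None if data.weights is None else data.weights.copy(),
    )
    return out, report


# --------------------------------------------------------------------- impute


def impute(
    data: TrialDataset,
    method: str = "missforest",
    max_iter: int = 10,
    n_trees: int = 100,
    seed: int = 0,
) -> tuple[TrialDataset, PreprocessReport]:
    """Handle missing covariate entries.

    missforest
        Iterative random-forest imputation: variables are visited in order
        of increasing missingness; each incomplete variable is regressed on
        all others (regression forest for continuous, classification forest
        otherwise) and its missing part replaced by predictions. Iteration
        stops the first time the summed normalised discrepancy between
        successive imputations increases, returning the previous iterate.
    mean
        Column mean (continuous) / mode (binary, categorical).
    complete_case
        Drop every row with any missing covariate entry.
    ipw
        Keep complete cases, weighted by the inverse of the estimated
        probability of being complete; the completeness indicator is
        modelled by logistic regression on the treatment, the outcome and
        all fully observed covariates. Estimated probabilities below 0.01
        trigger a warning and are truncated at the 1st percentile.
    """
    if method not in {"missforest", "mean", "complete_case", "ipw"}:
        raise ValueError(f"unknown imputation method {method!r}")
    report = PreprocessReport(imputation_method=method)
    incomplete = data.X.columns[data.X.isna().any()].tolist()
    if not incomplete:
        return data.copy(), report

    if method == "mean":
        out = data.copy()
        for name in incomplete:
            col = out.X[name]
            if out.meta[name].kind in {"continuous"}:
                fill = float(col.mean())
            else:
                fill = col.mode(dropna=True).iloc[0]
            out.X[name] = col.fillna(fill)
        return out, report

    if method == "complete_case":
        keep = ~data.X.isna().any(axis=1).to_numpy()
        if keep.sum() == 0:
            raise EmptyDesignError("no complete cases remain")
        return data.subset_rows(keep), report

    if method == "ipw":
        return _impute_ipw(data, report)

    return _missforest(data, report, max_iter=max_iter, n_trees=n_trees, seed=seed)


def _impute_ipw(data: TrialDataset, report: PreprocessReport):
    complete = ~data.X.isna().any(axis=1).to_numpy()
    observed_cols = data.X.columns[~data.X.isna().any()].tolist()
    design = [np.ones(data.n), data.w, data.y]
    for name in observed_cols:
        col = data.X[name]
        if col.dtype == object:
            for level in sorted(col.dropna().unique())[1:]:
                design.append((col == level).astype(float).to_numpy())
        else:
            design.append(col.to_numpy(dtype=float))
    Xmat = np.column_stack(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(complete.astype(float), Xmat, family=sm.families.Binomial()).fit()
    p_complete = np.clip(fit.fittedvalues, 1e-12, 1.0)
    if np.any(p_complete < 0.01):
        floor = float(np.percentile(p_complete, 1))
        report.warnings.append(
            f"estimated completeness probabilities below 0.01; truncated at {floor:.4f}"
        )
        p_complete = np.maximum(p_complete, floor)
    out = data.subset_rows(complete)
    out.weights = 1.0 / p_complete[complete]
    return out, report


def _missforest(data: TrialDataset, report: PreprocessReport,
                max_iter: int, n_trees: int, seed: int):
    rng = np.random.Generator(np.random.PCG64(seed))
    out = data.copy()
    work = out.X.copy()
    cat_cols = [c for c in work.columns if work[c].dtype == object
                or out.meta[c].kind in {"binary", "categorical", "onehot_level"}]
    codes: dict[str, pd.Index] = {}
    for c in work.columns:
        if work[c].dtype == object:
            cats = pd.Index(sorted(work[c].dropna().unique()))
            codes[c] = cats
            work[c] = work[c].map({v: i for i, v in enumerate(cats)}).astype(float)
        else:
            work[c] = work[c].astype(float)

    mask = work.isna()
    order = mask.mean().sort_values(kind="stable")
    targets = [c for c in order.index if mask[c].any()]
    # initial fill: mean / mode
    for c in work.columns:
        if mask[c].any():
            if c in cat_cols:
                work.loc[mask[c], c] = work[c].mode(dropna=True).iloc[0]
            else:
                work.loc[mask[c], c] = work[c].mean()

    prev = work.copy()
    best = work.copy()
    prev_disc = np.inf
    iterations = 0
    for _ in range(max_iter):
        iterations += 1
        for c in targets:
            miss = mask[c].to_numpy()
            others = work.drop(columns=[c]).to_numpy(dtype=float)
            target = work[c].to_numpy(dtype=float)
            seed_c = int(rng.integers(0, 2**31 - 1))
            if c in cat_cols:
                model = RandomForestClassifier(
                    n_estimators=n_trees, random_state=seed_c, n_jobs=1
                )
                model.fit(others[~miss], target[~miss].astype(int))
                pred = model.predict(others[miss]).astype(float)
            else:
                model = RandomForestRegressor(
                    n_estimators=n_trees, random_state=seed_c, n_jobs=1
                )
                model.fit(others[~miss], target[~miss])
                pred = model.predict(others[miss])
            work.loc[miss, c] = pred
        disc = 0.0
        for c in targets:
            new_v = work[c].to_numpy(dtype=float)
            old_v = prev[c].to_numpy(dtype=float)
            if c in cat_cols:
                m = mask[c].to_numpy()
                disc += float(np.mean(new_v[m] != old_v[m])) if m.any() else 0.0
            else:
                denom = float(np.sum(new_v**2))
                disc += float(np.sum((new_v - old_v) ** 2)) / denom if denom else 0.0
        report.convergence_trace.append(disc)
        if disc >= prev_disc:
            work = best  # discrepancy rose: return the previous iterate
            break
        prev_disc = disc
        best = work.copy()
        prev = work.copy()
    report.iterations_run = iterations

    for c, cats in codes.items():
        out.X[c] = pd.Series(cats[work[c].round().astype(int).clip(0, len(cats) - 1)],
                             index=out.X.index, dtype=object)
    for c in work.columns:
        if c not in codes:
            out.X[c] = work[c]
    return out, report
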