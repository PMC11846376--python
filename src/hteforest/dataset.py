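"""Participant-level trial data container and delimited-text I/O.

A :class:`TrialDataset` holds a binary outcome ``y`` (1 = alive at day 28),
a binary treatment indicator ``w``, a covariate table ``X`` with per-column
metadata, and optional positive per-row analysis weights (used by the
inverse-probability-weighting missing-data pathway).

Datasets are written as plain CSV with a JSON sidecar carrying the feature
metadata, so a round trip preserves column kinds and any standardisation
parameters needed to map model thresholds back to raw units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FeatureMeta", "TrialDataset", "load_trial_csv", "SchemaError"]


class SchemaError(ValueError):
    """Raised when a file or frame does not satisfy the trial-data schema."""


@dataclass
class FeatureMeta:
    """Per-covariate metadata.

    kind
        ``continuous``, ``binary``, ``categorical`` (raw, pre-encoding) or
        ``onehot_level`` (an indicator produced from a categorical parent).
    mean, sd
        Original mean / SD recorded when a continuous column is centred and
        scaled, so thresholds learned on the standardised scale can be
        back-transformed to raw units.
    derived_score
        True for summary/derived scores; used as a tie-break when deciding
        which member of a highly correlated pair to drop.
    """

    name: str
    kind: str = "continuous"
    mean: float | None = None
    sd: float | None = None
    missing_fraction: float = 0.0
    parent: str | None = None
    derived_score: bool = False
    threshold: float | None = None  # set for dichotomised indicator columns


@dataclass
class TrialDataset:
    """Two-arm RCT dataset: outcome, treatment, covariates, metadata."""

    y: np.ndarray
    w: np.ndarray
    X: pd.DataFrame
    meta: dict[str, FeatureMeta] = field(default_factory=dict)
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if not set(np.unique(self.y[~np.isnan(self.y)])) <= {0.0, 1.0}:
            raise SchemaError("outcome must be binary 0/1")
        if not set(np.unique(self.w[~np.isnan(self.w)])) <= {0.0, 1.0}:
            raise SchemaError("treatment must be binary 0/1")
        n = len(self.y)
        if len(self.w) != n or len(self.X) != n:
            raise SchemaError("outcome, treatment and covariates must have equal length")
        for name in self.X.columns:
            self.meta.setdefault(name, FeatureMeta(name=name))
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if len(self.weights) != n:
                raise SchemaError("weights must have one entry per row")
            if np.any(self.weights <= 0):
                raise SchemaError("weights must be strictly positive")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.X.columns)

    def effective_weights(self) -> np.ndarray:
        if self.weights is None:
            return np.ones(self.n)
        return self.weights

    def copy(self) -> "TrialDataset":
        return TrialDataset(
            y=self.y.copy(),
            w=self.w.copy(),
            X=self.X.copy(),
            meta={k: replace(v) for k, v in self.meta.items()},
            weights=None if self.weights is None else self.weights.copy(),
        )

    def subset_rows(self, mask: np.ndarray) -> "TrialDataset":
        mask = np.asarray(mask)
        return TrialDataset(
            y=self.y[mask],
            w=self.w[mask],
            X=self.X.loc[mask].reset_index(drop=True),
            meta={k: replace(v) for k, v in self.meta.items()},
            weights=None if self.weights is None else self.weights[mask],
        )

    def drop_covariates(self, names: Sequence[str]) -> "TrialDataset":
        names = list(names)
        return TrialDataset(
            y=self.y.copy(),
            w=self.w.copy(),
            X=self.X.drop(columns=names),
            meta={k: replace(v) for k, v in self.meta.items() if k not in names},
            weights=None if self.weights is None else self.weights.copy(),
        )

    def matrix(self) -> np.ndarray:
        """Covariates as a float matrix (NaN for missing)."""
        return self.X.to_numpy(dtype=float)

    # ------------------------------------------------------------------ I/O

    def to_csv(self, path: str | Path) -> None:
        """Write data as CSV plus a ``<stem>.meta.json`` sidecar."""
        path = Path(path)
        frame = pd.DataFrame({"Y": self.y, "W": self.w})
        frame = pd.concat([frame, self.X.reset_index(drop=True)], axis=1)
        if self.weights is not None:
            frame["weight__"] = self.weights
        frame.to_csv(path, index=False)
        sidecar = {
            "features": {k: asdict(v) for k, v in self.meta.items()},
            "has_weights": self.weights is not None,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=1)
        )


_DEFAULT_NA = ("", "NA", "NaN", "nan", "null")


def load_trial_csv(
    path: str | Path,
    outcome: str = "Y",
    treatment: str = "W",
    kinds: dict[str, str] | None = None,
    na_values: Sequence[str] = _DEFAULT_NA,
) -> TrialDataset:
    """Read a trial CSV (with optional JSON sidecar) into a TrialDataset.

    ``kinds`` maps column name -> feature kind for files without a sidecar;
    unlisted columns are inferred (two observed distinct values in {0,1} ->
    binary, non-numeric -> categorical, else continuous).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, na_values=list(na_values), keep_default_na=False)
    for col in (outcome, treatment):
        if col not in frame.columns:
            raise SchemaError(f"missing required column {col!r}")
        bad = sorted(set(frame[col].dropna().unique()) - {0, 1, 0.0, 1.0, "0", "1"})
        if bad:
            raise SchemaError(f"column {col!r} must be binary 0/1; found values {bad}")
    y = frame[outcome].astype(float).to_numpy()
    w = frame[treatment].astype(float).to_numpy()
    weights = None
    cov = frame.drop(columns=[outcome, treatment])
    if "weight__" in cov.columns:
        weights = cov.pop("weight__").astype(float).to_numpy()

    meta: dict[str, FeatureMeta] = {}
    sidecar_path = path.with_suffix(path.suffix + ".meta.json")
    if sidecar_path.exists():
        payload = json.loads(sidecar_path.read_text())
        for name, fields in payload["features"].items():
            meta[name] = FeatureMeta(**fields)
    else:
        kinds = kinds or {}
        for name in cov.columns:
            series = cov[name]
            if name in kinds:
                kind = kinds[name]
            elif series.dtype == object:
                kind = "categorical"
            else:
                observed = set(series.dropna().unique())
                kind = "binary" if observed <= {0, 1, 0.0, 1.0} else "continuous"
            meta[name] = FeatureMeta(
                name=name,
                kind=kind,
                missing_fraction=float(series.isna().mean()),
            )
    for name in cov.columns:
        if meta.get(name, FeatureMeta(name)).kind != "categorical":
            cov[name] = cov[name].astype(float)
    return TrialDataset(y=y, w=w, X=cov, meta=meta, weights=weights)
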