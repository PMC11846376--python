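"""Data-driven subgroup thresholds from causal-forest root splits.

Each honest causal tree's first (root) split maximises the difference in
estimated treatment effect between the two halves of its subsample, so
across the forest the most common root variable — and the average of its
root thresholds — characterises the dominant "first-order" subgroup
structure. This module tallies root splits, identifies the modal variable,
averages its thresholds in raw units, partitions the trial population at
that threshold, and estimates the subgroup average treatment effect (GATE)
on each side via doubly robust AIPW scores.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .causal_forest import (CausalForestModel, GateResult,
                            average_treatment_effect, dr_scores)
from .dataset import TrialDataset

__all__ = ["RootSplitSummary", "extract_root_splits", "partition_and_gate"]


@dataclass
class RootSplitSummary:
    per_variable_counts: dict[str, int]
    per_variable_thresholds: dict[str, list[float]]
    modal_variable: str | None
    mean_threshold: float | None
    threshold_sd: float | None
    n_trees_with_root: int
    n_stumps: int
    modal_tie: bool = False
    notes: list[str] = field(default_factory=list)


def _raw_threshold(name: str, threshold: float, data: TrialDataset) -> float:
    """Back-transform a threshold on a standardised column to raw units."""
    fm = data.meta.get(name)
    if fm is not None and fm.mean is not None and fm.sd is not None:
        return fm.mean + threshold * fm.sd
    return threshold


def extract_root_splits(model: CausalForestModel,
                        data: TrialDataset) -> RootSplitSummary:
    """Tally root splits per variable; modal variable and mean threshold.

    One-hot indicator columns are tallied under their parent categorical
    variable (their thresholds have no continuous meaning, so a categorical
    modal variable yields level-set subgroups rather than a mean
    threshold). Ties for the modal variable resolve to the lower column
    index and set ``modal_tie``. Thresholds are averaged on the raw scale,
    using stored standardisation parameters where present.
    """
    counts: dict[str, int] = defaultdict(int)
    thresholds: dict[str, list[float]] = defaultdict(list)
    n_stumps = 0
    for tree in model.trees:
        split = tree.root_split()
        if split is None:
            n_stumps += 1
            continue
        j, thr = split
        name = model.feature_names[j]
        fm = data.meta.get(name)
        if fm is not None and fm.kind == "onehot_level" and fm.parent is not None:
            counts[fm.parent] += 1
        else:
            counts[name] += 1
            thresholds[name].append(_raw_threshold(name, thr, data))

    n_with_root = sum(counts.values())
    if n_with_root == 0:
        return RootSplitSummary(
            per_variable_counts={}, per_variable_thresholds={},
            modal_variable=None, mean_threshold=None, threshold_sd=None,
            n_trees_with_root=0, n_stumps=n_stumps,
            notes=["no splits: every tree is a stump"],
        )

    order = {name: i for i, name in enumerate(model.feature_names)}
    parent_order = {}
    for name in counts:
        parent_order[name] = order.get(
            name, min((order[f] for f in model.feature_names
                       if data.meta.get(f) is not None
                       and data.meta[f].parent == name), default=len(order)),
        )
    best_count = max(counts.values())
    tied = [name for name, c in counts.items() if c == best_count]
    modal = min(tied, key=lambda name: parent_order[name])

    notes = []
    vals = thresholds.get(modal, [])
    if vals:
        mean_thr = float(np.mean(vals))
        sd_thr = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
    else:
        mean_thr = sd_thr = None
        notes.append(f"modal variable {modal!r} is categorical: "
                     "subgroups are level sets, no mean threshold")
    return RootSplitSummary(
        per_variable_counts=dict(counts),
        per_variable_thresholds={k: list(v) for k, v in thresholds.items()},
        modal_variable=modal, mean_threshold=mean_thr, threshold_sd=sd_thr,
        n_trees_with_root=n_with_root, n_stumps=n_stumps,
        modal_tie=len(tied) > 1, notes=notes,
    )


def partition_and_gate(
    model: CausalForestModel,
    data: TrialDataset,
    variable: str,
    threshold: float,
) -> tuple[GateResult, GateResult]:
    """Split the population at a raw-units threshold and estimate both GATEs.

    Low group: variable <= threshold; high group: variable > threshold
    (matching the convention of the strict subgroup indicator). Returns
    (low, high). Fails explicitly if either side is empty.
    """
    if variable not in data.X.columns:
        raise KeyError(f"unknown variable {variable!r}")
    values = data.X[variable].to_numpy(dtype=float)
    fm = data.meta[variable]
    if fm.mean is not None and fm.sd is not None:  # column is standardised
        values = fm.mean + values * fm.sd
    low_mask = values <= threshold
    high_mask = values > threshold
    if not low_mask.any():
        raise ValueError(f"empty low subgroup: no {variable} <= {threshold:g}")
    if not high_mask.any():
        raise ValueError(f"empty high subgroup: no {variable} > {threshold:g}")
    scores = dr_scores(model, data)
    low = average_treatment_effect(scores, low_mask,
                                   definition=f"{variable} <= {threshold:g}")
    high = average_treatment_effect(scores, high_mask,
                                    definition=f"{variable} > {threshold:g}")
    return low, high
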