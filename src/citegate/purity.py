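"""Purity of gated populations against ground-truth labels, and overlap
between competing gate definitions.

Gate membership is cross-tabulated against per-cell truth labels (typically
multi-omics annotations supplied as input). From a gate ↔ target-label
mapping the usual classification metrics follow: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TP+TN)/total and purity TP/(TP+FP).
Overlap between two gated cell sets is the Jaccard index |A∩B|/|A∪B|;
compositional similarity between populations is the Jensen–Shannon
divergence (base 2) of their truth-label composition vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import jensenshannon

from .core import MISSING, CitegateError, CitegateWarning
from .gating import UNGATED

__all__ = [
    "ConfusionTable",
    "PurityMetrics",
    "OverlapMatrix",
    "confusion_table",
    "purity_metrics",
    "jaccard_overlap",
    "jsd_overlap",
]


@dataclass
class ConfusionTable:
    """Gates × truth-labels cell counts, plus the number of unlabelled cells
    that were excluded from the tally."""

    counts: pd.DataFrame  # index = gates, columns = truth labels, int counts
    n_excluded_unlabelled: int = 0

    def gate_size(self, gate: str) -> int:
        return int(self.counts.loc[gate].sum())

    def label_size(self, label: str) -> int:
        return int(self.counts[label].sum())

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class PurityMetrics:
    """accuracy, sensitivity, specificity and purity of one gate against one
    target label; metrics whose denominator is zero are None and listed in
    ``undefined``."""

    gate: str
    target_label: str
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None
    purity: Optional[float] = None
    undefined: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "gate": self.gate,
            "target_label": self.target_label,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "tn": self.tn,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "purity": self.purity,
        }


@dataclass
class OverlapMatrix:
    values: pd.DataFrame  # populations × populations
    metric: str  # "jaccard" or "jsd"
    flagged_pairs: list[tuple[str, str]] = field(default_factory=list)


def confusion_table(
    assignment: np.ndarray,
    truth: np.ndarray,
    include_ungated: bool = False,
) -> ConfusionTable:
    """Cross-tabulate per-cell gate assignment against truth labels.

    Unlabelled cells are excluded (their count is reported on the result);
    the ``"ungated"`` assignment is dropped unless ``include_ungated``.
    """
    assignment = np.asarray(assignment, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if assignment.shape != truth.shape:
        raise CitegateError("assignment and truth must be aligned per cell")
    labelled = (truth != MISSING) & ~pd.isna(truth)
    n_excluded = int(np.sum(~labelled))
    if not labelled.any():
        raise CitegateError("no labelled cells to tabulate")
    a, t = assignment[labelled], truth[labelled]
    keep = np.ones(a.shape, dtype=bool)
    if not include_ungated:
        keep = a != UNGATED
    counts = pd.crosstab(
        pd.Series(a[keep], name="gate"), pd.Series(t[keep], name="truth_label")
    )
    # keep all truth labels as columns even if a gate never sees them
    all_labels = sorted(set(t.tolist()))
    counts = counts.reindex(columns=all_labels, fill_value=0)
    counts = counts.sort_index()
    return ConfusionTable(counts.astype(int), n_excluded)


def purity_metrics(
    table: ConfusionTable, gate: str, target_label: str
) -> PurityMetrics:
    """Classification metrics of one gate against one target truth label.

    Accuracy uses all labelled cells in the table as its denominator:
    (TP+TN)/(TP+TN+FP+FN).
    """
    counts = table.counts
    if gate not in counts.index:
        raise CitegateError(f"gate {gate!r} not in confusion table")
    if target_label not in counts.columns:
        raise CitegateError(f"truth label {target_label!r} not in confusion table")
    tp = int(counts.loc[gate, target_label])
    fp = int(counts.loc[gate].sum()) - tp
    fn = int(counts[target_label].sum()) - tp
    tn = table.total - tp - fp - fn
    out = PurityMetrics(gate, target_label, tp, fp, fn, tn)
    total = tp + fp + fn + tn
    if total > 0:
        out.accuracy = (tp + tn) / total
    else:
        out.undefined.append("accuracy")
    if tp + fn > 0:
        out.sensitivity = tp / (tp + fn)
    else:
        out.undefined.append("sensitivity")
    if tn + fp > 0:
        out.specificity = tn / (tn + fp)
    else:
        out.undefined.append("specificity")
    if tp + fp > 0:
        out.purity = tp / (tp + fp)
    else:
        out.undefined.append("purity")
    if out.undefined:
        warnings.warn(
            f"metrics undefined for gate {gate!r} vs {target_label!r}: "
            f"{out.undefined}",
            CitegateWarning,
            stacklevel=2,
        )
    return out


def metrics_table(
    table: ConfusionTable, gate_targets: Mapping[str, str]
) -> pd.DataFrame:
    """PurityMetrics for several (gate, target) pairs as one tidy table."""
    rows = []
    for gate, target in gate_targets.items():
        if gate not in table.counts.index:
            continue
        rows.append(purity_metrics(table, gate, target).as_dict())
    if not rows:
        raise CitegateError("no requested gate present in the confusion table")
    return pd.DataFrame(rows)


def jaccard_overlap(memberships: Mapping[str, np.ndarray]) -> OverlapMatrix:
    """Pairwise Jaccard index |A∩B|/|A∪B| between named cell sets.

    All membership vectors must cover the same cell universe. A pair of two
    empty sets scores 0 and is flagged.
    """
    names = list(memberships)
    if len(names) < 2:
        raise CitegateError("need at least two populations for overlap")
    masks = {k: np.asarray(v, dtype=bool) for k, v in memberships.items()}
    n = {len(v) for v in masks.values()}
    if len(n) != 1:
        raise CitegateError("membership vectors differ in length (cell universes)")
    mat = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    flagged = []
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j < i:
                continue
            union = int(np.sum(masks[a] | masks[b]))
            inter = int(np.sum(masks[a] & masks[b]))
            if union == 0:
                val = 0.0
                flagged.append((a, b))
            else:
                val = inter / union
            mat.iloc[i, j] = mat.iloc[j, i] = val
    return OverlapMatrix(mat, "jaccard", flagged)


def jsd_overlap(compositions: Mapping[str, np.ndarray]) -> OverlapMatrix:
    """Pairwise Jensen–Shannon divergence (base 2, in [0, 1]) between named
    probability vectors over truth labels. Uses the 0·log 0 = 0 convention."""
    names = list(compositions)
    if len(names) < 2:
        raise CitegateError("need at least two compositions")
    vecs = {}
    for k, v in compositions.items():
        v = np.asarray(v, dtype=float)
        if np.any(v < 0):
            raise CitegateError(f"composition {k!r} has negative entries")
        s = v.sum()
        if s <= 0:
            raise CitegateError(f"composition {k!r} sums to zero")
        if abs(s - 1.0) > 1e-9:
            raise CitegateError(f"composition {k!r} does not sum to 1 (sum={s})")
        vecs[k] = v
    dims = {len(v) for v in vecs.values()}
    if len(dims) != 1:
        raise CitegateError("compositions differ in length")
    mat = pd.DataFrame(np.zeros((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if j <= i:
                continue
            # scipy returns the JS *distance* (sqrt of the divergence)
            d = jensenshannon(vecs[a], vecs[b], base=2)
            val = float(d) ** 2 if np.isfinite(d) else 0.0
            mat.iloc[i, j] = mat.iloc[j, i] = val
    return OverlapMatrix(mat, "jsd")
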