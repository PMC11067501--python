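"""Data-driven selection of additional gating markers.

Given a gate and ground-truth labels, gated cells are split into true
positives (truth matches the gate's target population) and false positives
(contaminants). Three evidence streams then rank every candidate marker by
how well it separates TP from FP cells:

1. a differential-expression pre-filter — mean log2(x+1) fold change and a
   two-sided Wilcoxon rank-sum test with Benjamini–Hochberg correction;
   markers with |log2FC| < 2 or adjusted p > 0.05 are filtered out;
2. a per-marker sigmoid-kernel support vector machine, scored by precision,
   accuracy, sensitivity/recall, F1 and FP/FN counts from pooled
   out-of-fold predictions of a stratified 5-fold cross-validation;
3. the unbiased squared maximum mean discrepancy (MMD²) between the TP and
   FP distributions of the marker.

The filter runs first because it is cheap; survivors are scored by SVM and
MMD and ranked by MMD² (F1 breaks ties). Up to two markers are selected,
reflecting how many extra channels a practical sorting panel can absorb;
markers already in the base gate remain eligible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .core import CellDataset, CitegateError, CitegateWarning
from .gating import UNGATED

__all__ = [
    "TPFPLabels",
    "MarkerScore",
    "MarkerSelection",
    "label_tp_fp",
    "de_filter",
    "svm_marker_score",
    "mmd2_unbiased",
    "rank_markers",
    "score_markers",
    "select_markers",
]


@dataclass
class TPFPLabels:
    """TP/FP classes of the cells inside one gate.

    ``indices`` are positions (into the dataset's cell axis) of gated,
    labelled cells; ``is_tp[i]`` says whether ``indices[i]`` carries the
    target truth label.
    """

    gate: str
    target_label: str
    indices: np.ndarray
    is_tp: np.ndarray

    @property
    def n_tp(self) -> int:
        return int(self.is_tp.sum())

    @property
    def n_fp(self) -> int:
        return int((~self.is_tp).sum())


def label_tp_fp(
    assignment: np.ndarray,
    truth: np.ndarray,
    gate: str,
    target_label: str,
) -> TPFPLabels:
    """Split the gate's labelled cells into TP (truth == target) and FP."""
    assignment = np.asarray(assignment, dtype=object)
    truth = np.asarray(truth, dtype=object)
    from .core import MISSING

    mask = (assignment == gate) & (truth != MISSING) & ~pd.isna(truth)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise CitegateError(f"gate {gate!r} holds no labelled cells")
    is_tp = truth[idx] == target_label
    out = TPFPLabels(gate, target_label, idx, np.asarray(is_tp, dtype=bool))
    if out.n_tp == 0:
        raise CitegateError(
            f"target label {target_label!r} absent from gate {gate!r}; "
            "TP/FP scoring is undefined"
        )
    if out.n_fp == 0:
        raise CitegateError(
            f"gate {gate!r} is already pure for {target_label!r}; "
            "TP/FP scoring is undefined"
        )
    return out


# ---------------------------------------------------------------------------
# differential-expression pre-filter


def de_filter(
    dataset: CellDataset,
    labels: TPFPLabels,
    log2fc_min: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-marker DE statistics between TP and FP cells.

    On raw counts, log2FC is the difference of mean log2(x+1) between the TP
    and FP classes; on pre-normalized values a plain mean difference is used
    (with a warning, since it is not a fold change). p-values come from a
    two-sided Wilcoxon rank-sum test and are Benjamini–Hochberg adjusted
    across markers. ``passed`` requires |log2FC| ≥ 2 and adjusted p ≤ 0.05.
    """
    if labels.n_tp < 3 or labels.n_fp < 3:
        raise CitegateError("need at least 3 cells in each of TP and FP")
    sub = dataset.values[labels.indices]
    tp_rows = labels.is_tp
    if dataset.is_raw:
        transformed = np.log2(sub + 1.0)
    else:
        warnings.warn(
            "input is pre-normalized; reporting plain mean differences "
            "instead of log2 fold changes",
            CitegateWarning,
            stacklevel=2,
        )
        transformed = sub
    log2fc = transformed[tp_rows].mean(axis=0) - transformed[~tp_rows].mean(axis=0)
    pvals = np.ones(dataset.n_markers)
    for j in range(dataset.n_markers):
        col = sub[:, j]
        if np.ptp(col) == 0:  # constant marker carries no signal
            pvals[j] = 1.0
            continue
        pvals[j] = mannwhitneyu(
            col[tp_rows], col[~tp_rows], alternative="two-sided"
        ).pvalue
    p_adj = multipletests(pvals, method="fdr_bh")[1]
    passed = (np.abs(log2fc) >= log2fc_min) & (p_adj <= alpha)
    return pd.DataFrame(
        {
            "marker": dataset.marker_names,
            "log2fc": log2fc,
            "p_value": pvals,
            "p_adj": p_adj,
            "passed": passed,
        }
    ).set_index("marker")


# ---------------------------------------------------------------------------
# per-marker SVM


@dataclass
class SVMResult:
    precision: float
    accuracy: float
    sensitivity: float
    recall: float
    f1: float
    fp_count: int
    fn_count: int
    constant_input: bool = False


def svm_marker_score(
    values: np.ndarray,
    labels: TPFPLabels,
    seed: int = 0,
    n_folds: int = 5,
) -> SVMResult:
    """Cross-validated sigmoid-SVM separability of TP vs FP on one marker.

    The single feature is standardized; the classifier is an SVC with
    sigmoid kernel tanh(γ·u·v + r), scale-γ, r = 0, C = 1 and class weights
    inversely proportional to class frequencies. Metrics are computed from
    pooled out-of-fold predictions of a seeded stratified k-fold (k = 5,
    reduced with a warning when the smaller class is smaller than k). The
    TP class is the positive class.
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray(labels.is_tp, dtype=int)
    if values.shape[0] != y.shape[0]:
        raise CitegateError("values must align with the gated cells")
    if len(np.unique(y)) < 2:
        raise CitegateError("single-class input; SVM scoring undefined")
    if labels.n_tp < 10 or labels.n_fp < 10:
        raise CitegateError("need at least 10 cells per class for SVM scoring")
    constant = np.ptp(values) == 0
    if constant:
        x = np.zeros_like(values)[:, None]
        warnings.warn(
            "marker is constant across gated cells; SVM prediction is "
            "degenerate (constant-prediction flag set)",
            CitegateWarning,
            stacklevel=2,
        )
    else:
        x = ((values - values.mean()) / values.std())[:, None]
    smaller = min(labels.n_tp, labels.n_fp)
    folds = min(n_folds, smaller)
    if folds < n_folds:
        warnings.warn(
            f"reducing folds to {folds} (smaller class has {smaller} cells)",
            CitegateWarning,
            stacklevel=2,
        )
    clf = SVC(kernel="sigmoid", gamma="scale", coef0=0.0, C=1.0,
              class_weight="balanced")
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, x, y, cv=cv)
    tn, fp, fn, tp = confusion_matrix(y, pred, labels=[0, 1]).ravel()
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return SVMResult(
        precision=float(precision),
        accuracy=float((tp + tn) / len(y)),
        sensitivity=float(recall),
        recall=float(recall),
        f1=float(f1),
        fp_count=int(fp),
        fn_count=int(fn),
        constant_input=constant,
    )


# ---------------------------------------------------------------------------
# maximum mean discrepancy


def _pairwise_sq_diffs(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a[:, None] - b[None, :]) ** 2


def mmd2_unbiased(
    x: np.ndarray,
    y: np.ndarray,
    kernel: str = "rbf",
    bandwidth="median",
) -> float:
    """Unbiased estimator of the squared maximum mean discrepancy.

    MMD²_u = Σ_{i≠j} k(x_i,x_j)/(m(m−1)) + Σ_{i≠j} k(y_i,y_j)/(n(n−1))
             − 2 Σ_{i,j} k(x_i,y_j)/(mn)

    With the rbf kernel k(a,b) = exp(−(a−b)²/(2σ²)); bandwidth="median"
    sets σ to the median pooled pairwise absolute difference (falling back
    to σ = 1 with a warning when all values coincide). The estimator is
    unbiased and may be negative.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    m, n = len(x), len(y)
    if m < 2 or n < 2:
        raise CitegateError("mmd2_unbiased needs at least 2 points per sample")
    if kernel == "linear":
        kxx = x[:, None] * x[None, :]
        kyy = y[:, None] * y[None, :]
        kxy = x[:, None] * y[None, :]
    elif kernel == "rbf":
        dxx = _pairwise_sq_diffs(x, x)
        dyy = _pairwise_sq_diffs(y, y)
        dxy = _pairwise_sq_diffs(x, y)
        if bandwidth == "median":
            pooled = np.concatenate([x, y])
            diffs = np.abs(pooled[:, None] - pooled[None, :])
            sigma = float(np.median(diffs[np.triu_indices(m + n, k=1)]))
            if sigma == 0.0:
                warnings.warn(
                    "median bandwidth is 0 (all values identical); using σ=1",
                    CitegateWarning,
                    stacklevel=2,
                )
                sigma = 1.0
        else:
            sigma = float(bandwidth)
            if sigma <= 0:
                raise CitegateError("bandwidth must be positive")
        kxx = np.exp(-dxx / (2 * sigma**2))
        kyy = np.exp(-dyy / (2 * sigma**2))
        kxy = np.exp(-dxy / (2 * sigma**2))
    else:
        raise CitegateError(f"unknown kernel {kernel!r}")
    term_x = (kxx.sum() - np.trace(kxx)) / (m * (m - 1))
    term_y = (kyy.sum() - np.trace(kyy)) / (n * (n - 1))
    term_xy = 2.0 * kxy.sum() / (m * n)
    return float(term_x + term_y - term_xy)


# ---------------------------------------------------------------------------
# scoring and ranking


@dataclass
class MarkerScore:
    marker: str
    log2fc: float
    p_adj: float
    passed_de_filter: bool
    precision: float = float("nan")
    accuracy: float = float("nan")
    sensitivity: float = float("nan")
    recall: float = float("nan")
    f1: float = float("nan")
    fp_count: int = -1
    fn_count: int = -1
    mmd2: float = float("nan")

    def as_dict(self) -> dict:
        return {
            "marker": self.marker,
            "log2fc": self.log2fc,
            "p_adj": self.p_adj,
            "passed_de_filter": self.passed_de_filter,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "recall": self.recall,
            "f1": self.f1,
            "fp_count": self.fp_count,
            "fn_count": self.fn_count,
            "mmd2": self.mmd2,
        }


@dataclass
class MarkerSelection:
    scores: list[MarkerScore]
    selected: list[str]
    already_in_base: list[str] = field(default_factory=list)
    de_fallback: bool = False

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame([s.as_dict() for s in self.scores])
        df["selected"] = df["marker"].isin(self.selected)
        return df


def _subsample_classes(
    labels: TPFPLabels, max_cells: int, seed: int
) -> np.ndarray:
    """Row mask (into labels.indices order) capping total cells, stratified."""
    n = len(labels.indices)
    if n <= max_cells:
        return np.ones(n, dtype=bool)
    rng = np.random.default_rng(seed)
    keep = np.zeros(n, dtype=bool)
    for cls_mask in (labels.is_tp, ~labels.is_tp):
        rows = np.flatnonzero(cls_mask)
        quota = max(2, int(round(max_cells * rows.size / n)))
        keep[rng.choice(rows, size=min(quota, rows.size), replace=False)] = True
    return keep


def score_markers(
    dataset: CellDataset,
    labels: TPFPLabels,
    seed: int = 0,
    scoring_values: Optional[np.ndarray] = None,
    max_cells: int = 2000,
    mmd_kernel: str = "rbf",
) -> tuple[list[MarkerScore], bool]:
    """Run the DE filter, then SVM and MMD scoring on the survivors.

    ``scoring_values`` optionally supplies a (cells × markers) matrix (e.g.
    CLR-normalized values) for the SVM/MMD stages while the DE filter sees
    ``dataset``; by default the dataset's own values are used throughout.
    SVM/MMD stages subsample to at most ``max_cells`` gated cells (class-
    stratified, seeded) to bound the quadratic kernel cost on large gates.

    Returns the scores and a flag saying whether the no-survivor fallback
    (score every marker) was taken.
    """
    de = de_filter(dataset, labels)
    fallback = not bool(de["passed"].any())
    if fallback:
        warnings.warn(
            "no marker passed the DE filter; scoring all markers instead",
            CitegateWarning,
            stacklevel=2,
        )
    candidates = list(de.index) if fallback else list(de.index[de["passed"]])
    mat = scoring_values if scoring_values is not None else dataset.values
    mat = np.asarray(mat, dtype=float)
    keep = _subsample_classes(labels, max_cells, seed)
    sub_idx = labels.indices[keep]
    sub_labels = TPFPLabels(
        labels.gate, labels.target_label, sub_idx, labels.is_tp[keep]
    )
    scores: list[MarkerScore] = []
    for marker in de.index:
        row = de.loc[marker]
        score = MarkerScore(
            marker=marker,
            log2fc=float(row["log2fc"]),
            p_adj=float(row["p_adj"]),
            passed_de_filter=bool(row["passed"]),
        )
        if marker in candidates:
            j = dataset.marker_index(marker)
            vals = mat[sub_idx, j]
            svm = svm_marker_score(vals, sub_labels, seed=seed)
            score.precision = svm.precision
            score.accuracy = svm.accuracy
            score.sensitivity = svm.sensitivity
            score.recall = svm.recall
            score.f1 = svm.f1
            score.fp_count = svm.fp_count
            score.fn_count = svm.fn_count
            score.mmd2 = mmd2_unbiased(
                vals[sub_labels.is_tp], vals[~sub_labels.is_tp], kernel=mmd_kernel
            )
        scores.append(score)
    return scores, fallback


def rank_markers(
    scores: Sequence[MarkerScore],
    base_gate_markers: set[str],
    k: int = 2,
) -> MarkerSelection:
    """Select the top-k markers among DE-filter survivors.

    Candidates are sorted by MMD² descending, ties broken by F1 descending
    then marker name; when no marker passed the filter, all scored markers
    compete (with a warning). Markers already used by the base gate stay
    eligible and are annotated on the result.
    """
    if k < 1:
        raise CitegateError("k must be at least 1")
    if k > 2:
        warnings.warn(
            "selecting more than 2 additional markers exceeds what a typical "
            "sorting panel can absorb",
            CitegateWarning,
            stacklevel=2,
        )
    passed = [s for s in scores if s.passed_de_filter]
    fallback = not passed
    if fallback:
        warnings.warn(
            "no marker passed the DE filter; ranking all scored markers",
            CitegateWarning,
            stacklevel=2,
        )
        passed = [s for s in scores if np.isfinite(s.mmd2)]
    if not passed:
        raise CitegateError("no scored markers available for ranking")
    ordered = sorted(passed, key=lambda s: (-s.mmd2, -s.f1, s.marker))
    selected = [s.marker for s in ordered[:k]]
    return MarkerSelection(
        scores=list(scores),
        selected=selected,
        already_in_base=[m for m in selected if m in base_gate_markers],
        de_fallback=fallback,
    )


def select_markers(
    dataset: CellDataset,
    assignment: np.ndarray,
    gate: str,
    target_label: str,
    k: int = 2,
    seed: int = 0,
    scoring_values: Optional[np.ndarray] = None,
    base_gate_markers: Optional[set[str]] = None,
    max_cells: int = 2000,
) -> MarkerSelection:
    """End-to-end marker selection for one gate (label → filter → score → rank)."""
    if dataset.truth_label is None:
        raise CitegateError("dataset carries no truth labels")
    labels = label_tp_fp(assignment, dataset.truth_label, gate, target_label)
    scores, _ = score_markers(
        dataset, labels, seed=seed, scoring_values=scoring_values,
        max_cells=max_cells,
    )
    return rank_markers(scores, base_gate_markers or set(), k=k)
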