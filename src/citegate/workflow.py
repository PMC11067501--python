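"""High-level pipeline: normalize → threshold → gate → score → refine.

Thin orchestration over the library modules, shared by the command-line
interface and the validation experiments. Every step is also usable on its
own; this module just fixes a sensible default order (CLR normalization,
density-based thresholds, the classical panel) and threads one seed through
all stochastic stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import CellDataset, CitegateError, clr_normalize
from .gating import GatePanel, PanelResult, apply_panel
from .panels import CLASSICAL_TARGETS, ThresholdSet, classical_panel, estimate_thresholds
from .refinement import RefinedGate, RefinementReport, fit_density_gate, refine_and_evaluate
from .selection import MarkerSelection, label_tp_fp, select_markers

__all__ = ["GatingRun", "run_classical_gating", "run_selection", "run_refinement"]


@dataclass
class GatingRun:
    """Everything produced by one classical-panel gating pass."""

    raw: Optional[CellDataset]
    normalized: CellDataset
    thresholds: ThresholdSet
    panel: GatePanel
    result: PanelResult

    @property
    def assignment(self) -> np.ndarray:
        return self.result.assignment


def run_classical_gating(
    dataset: CellDataset, pseudocount: float = 1.0
) -> GatingRun:
    """CLR-normalize (if raw), estimate thresholds and apply the classical
    B-cell panel."""
    if dataset.is_raw:
        raw: Optional[CellDataset] = dataset
        norm = clr_normalize(dataset, pseudocount=pseudocount)
    else:
        raw = None
        norm = dataset
    thresholds = estimate_thresholds(norm, fallback="lower-half")
    panel = classical_panel(thresholds)
    result = apply_panel(norm, panel)
    return GatingRun(raw, norm, thresholds, panel, result)


def run_selection(
    run: GatingRun,
    gate: str,
    target_label: Optional[str] = None,
    k: int = 2,
    seed: int = 0,
    max_cells: int = 2000,
) -> MarkerSelection:
    """Marker selection for one panel leaf: DE filter on raw counts (when
    available), SVM + MMD scoring on the normalized values."""
    if target_label is None:
        if gate not in CLASSICAL_TARGETS:
            raise CitegateError(
                f"no default target label for gate {gate!r}; pass target_label"
            )
        target_label = CLASSICAL_TARGETS[gate]
    de_dataset = run.raw if run.raw is not None else run.normalized
    base_markers = set()
    # markers referenced anywhere along the root-to-leaf path of this gate
    def collect(node, path):
        path = path | node.gate.markers
        if node.is_leaf() and (node.label or node.gate.name) == gate:
            base_markers.update(path)
        for child in node.children:
            collect(child, path)

    collect(run.panel.root, set())
    return select_markers(
        de_dataset,
        run.assignment,
        gate,
        target_label,
        k=k,
        seed=seed,
        scoring_values=run.normalized.values,
        base_gate_markers=base_markers,
        max_cells=max_cells,
    )


def _refinement_pair(
    selection: MarkerSelection, exclude: set[str]
) -> tuple[str, str]:
    """The marker pair to refine on: the two selected markers, or — when
    only one was selected — the runner-up by |log2FC| among the rest."""
    selected = list(selection.selected)
    if len(selected) >= 2:
        return selected[0], selected[1]
    scores = sorted(
        (s for s in selection.scores if s.marker not in selected),
        key=lambda s: -abs(s.log2fc),
    )
    for s in scores:
        if s.marker not in exclude:
            return selected[0], s.marker
    raise CitegateError("no partner marker available for the refinement pair")


def run_refinement(
    run: GatingRun,
    gate: str,
    selection: MarkerSelection,
    target_label: Optional[str] = None,
    alpha: float = 0.9,
    grid: int = 128,
) -> tuple[RefinedGate, RefinementReport]:
    """Fit an HDR gate on the selected marker pair and evaluate the gain."""
    if target_label is None:
        if gate not in CLASSICAL_TARGETS:
            raise CitegateError(
                f"no default target label for gate {gate!r}; pass target_label"
            )
        target_label = CLASSICAL_TARGETS[gate]
    norm = run.normalized
    if norm.truth_label is None:
        raise CitegateError("dataset carries no truth labels")
    labels = label_tp_fp(run.assignment, norm.truth_label, gate, target_label)
    pair = _refinement_pair(selection, exclude=set())
    refined = fit_density_gate(norm, labels, pair, alpha=alpha, grid=grid)
    refined.provenance["selected_markers"] = list(selection.selected)
    report = refine_and_evaluate(
        norm, run.assignment, refined, norm.truth_label, target_label
    )
    return refined, report
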