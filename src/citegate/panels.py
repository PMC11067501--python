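"""Built-in gating strategies: a classical B-cell panel and literature gates.

The classical panel reproduces the standard hierarchy used to sort human
B-cell subsets: CD19+ cells are split into a plasmablast branch (CD27+
CD38-high, subdivided by IgM) and a CD38-low/mid branch quadranted on
IgD × CD27 into naïve, unswitched memory, switched memory and IgD− CD27−
(double-negative) B cells. The literature library collects published gate
definitions for atypical/anergic/age-associated B-cell subsets so their
mutual overlap can be quantified on the same dataset.

All cut-offs are data-driven: per-marker negativity thresholds come from
density-based estimation (:func:`citegate.gating.estimate_threshold`), and
"mid/low"/"lo" atoms span the range from the negative threshold up to the
median of the positive population — a declared convention, configurable via
:class:`ThresholdSet`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import CellDataset, CitegateError
from .gating import (
    GateDefinition,
    GateNode,
    GatePanel,
    Interval,
    UnimodalDensityError,
    estimate_threshold,
)

__all__ = [
    "ThresholdSet",
    "estimate_thresholds",
    "classical_panel",
    "literature_gates",
    "CLASSICAL_TARGETS",
]

#: leaf population → truth label it is meant to capture
CLASSICAL_TARGETS = {
    "naive": "naive",
    "unswitched_memory": "unswitched_memory",
    "switched_memory": "switched_memory",
    "igd_cd27_dn": "dnb",
    "plasmablast": "plasmablast",
    "plasmablast_igm": "plasmablast",
}


@dataclass
class ThresholdSet:
    """Per-marker negativity thresholds and positive-population medians.

    ``negative[m]`` separates non-expressing from expressing cells on marker
    m; ``positive_median[m]`` is the median of cells above that threshold and
    anchors "mid/low" style atoms.
    """

    negative: dict[str, float] = field(default_factory=dict)
    positive_median: dict[str, float] = field(default_factory=dict)

    def neg(self, marker: str) -> float:
        if marker not in self.negative:
            raise CitegateError(f"no threshold estimated for marker {marker!r}")
        return self.negative[marker]

    def pos_med(self, marker: str) -> float:
        if marker not in self.positive_median:
            raise CitegateError(f"no positive median for marker {marker!r}")
        return self.positive_median[marker]

    # -- atom builders (the mid/low convention lives here) -----------------
    def positive(self, marker: str) -> Interval:
        return Interval(marker, low=self.neg(marker), low_inclusive=False)

    def negative_atom(self, marker: str) -> Interval:
        return Interval(marker, high=self.neg(marker))

    def mid_low(self, marker: str) -> Interval:
        """Between the negative threshold and the positive median."""
        return Interval(marker, low=self.neg(marker), high=self.pos_med(marker),
                        low_inclusive=False)

    def neg_or_low(self, marker: str) -> Interval:
        """Anything up to the positive median (negative or dim)."""
        return Interval(marker, high=self.pos_med(marker))

    def high(self, marker: str) -> Interval:
        return Interval(marker, low=self.pos_med(marker), low_inclusive=False)


def estimate_thresholds(
    dataset: CellDataset,
    markers=None,
    negative_references: dict[str, np.ndarray] | None = None,
    q: float = 0.995,
    fallback: str | None = None,
) -> ThresholdSet:
    """Estimate a :class:`ThresholdSet` for the given markers.

    Valley mode (density minimum between the two largest modes) is tried
    first; markers whose density is unimodal fall back to the q-quantile of
    a supplied negative reference. With ``fallback="lower-half"`` a missing
    reference is replaced by the cells at or below the marker's median — a
    pragmatic stand-in when no known-negative population is available.
    Unimodal markers with neither raise, as no data-driven cut-off exists.
    """
    markers = list(markers) if markers is not None else list(dataset.marker_names)
    negative_references = negative_references or {}
    ts = ThresholdSet()
    for marker in markers:
        try:
            thr = estimate_threshold(dataset, marker, mode="valley")
        except UnimodalDensityError:
            ref = negative_references.get(marker)
            if ref is None and fallback == "lower-half":
                x = dataset.marker_values(marker)
                ref = x <= np.median(x)
            if ref is None:
                raise
            thr = estimate_threshold(
                dataset, marker,
                negative_reference=ref,
                mode="quantile", q=q,
            )
        ts.negative[marker] = thr
        x = dataset.marker_values(marker)
        pos = x[x > thr]
        ts.positive_median[marker] = float(np.median(pos)) if pos.size else thr
    return ts


def classical_panel(thresholds: ThresholdSet) -> GatePanel:
    """The classical hierarchical B-cell panel (see module docstring)."""
    t = thresholds
    cd38_hi = t.pos_med("CD38")

    root = GateNode(
        gate=GateDefinition("cd19_pos", (t.positive("CD19"),)),
        children=[
            GateNode(
                gate=GateDefinition(
                    "plasmablast_branch",
                    (
                        t.positive("CD27"),
                        Interval("CD38", low=cd38_hi, low_inclusive=False),
                    ),
                ),
                children=[
                    GateNode(
                        gate=GateDefinition("pb_igm_pos", (t.positive("IgM"),)),
                        label="plasmablast_igm",
                    ),
                    GateNode(
                        gate=GateDefinition("pb_igm_neg", (t.negative_atom("IgM"),)),
                        label="plasmablast",
                    ),
                ],
            ),
            GateNode(
                # mature (non-plasmablast) branch: CD38 below the high cut,
                # CD10− to exclude transitional B cells
                gate=GateDefinition(
                    "mature_cd38_low_mid",
                    (Interval("CD38", high=cd38_hi), t.negative_atom("CD10")),
                ),
                children=[
                    GateNode(
                        gate=GateDefinition(
                            "naive",
                            (t.positive("IgD"), t.negative_atom("CD27")),
                        ),
                        label="naive",
                    ),
                    GateNode(
                        gate=GateDefinition(
                            "unswitched_memory",
                            (t.positive("IgD"), t.positive("CD27")),
                        ),
                        label="unswitched_memory",
                    ),
                    GateNode(
                        gate=GateDefinition(
                            "switched_memory",
                            (
                                t.negative_atom("IgD"),
                                t.positive("CD27"),
                                t.negative_atom("IgM"),
                            ),
                        ),
                        label="switched_memory",
                    ),
                    GateNode(
                        gate=GateDefinition(
                            "igd_cd27_dn",
                            (t.negative_atom("IgD"), t.negative_atom("CD27")),
                        ),
                        label="igd_cd27_dn",
                    ),
                ],
            ),
        ],
    )
    return GatePanel("classical_bcell", root)


def literature_gates(thresholds: ThresholdSet) -> dict[str, GateDefinition]:
    """Published gate definitions for unconventional B-cell subsets.

    - B_ND (anergic-enriched naïve): CD19+ IgD+ IgM− CD27− CD10− CD24mid/low
      CD38mid/low
    - CD21− atypical: CD19+ CD20+ CD10− CD21− CD27−
    - double-negative (DNB): CD19+ CD27− IgD−
    - age-associated: CD19+ CD21− CD11c+
    - anergic: CD19+ CD21−/low CD38−
    - IgMlo naïve: CD27− IgD+ IgMlo
    """
    t = thresholds
    return {
        "bnd": GateDefinition(
            "bnd",
            (
                t.positive("CD19"), t.positive("IgD"), t.negative_atom("IgM"),
                t.negative_atom("CD27"), t.negative_atom("CD10"),
                t.mid_low("CD24"), t.mid_low("CD38"),
            ),
        ),
        "cd21_atypical": GateDefinition(
            "cd21_atypical",
            (
                t.positive("CD19"), t.positive("CD20"), t.negative_atom("CD10"),
                t.negative_atom("CD21"), t.negative_atom("CD27"),
            ),
        ),
        "dnb": GateDefinition(
            "dnb",
            (t.positive("CD19"), t.negative_atom("CD27"), t.negative_atom("IgD")),
        ),
        "age_associated": GateDefinition(
            "age_associated",
            (t.positive("CD19"), t.negative_atom("CD21"), t.positive("CD11c")),
        ),
        "anergic": GateDefinition(
            "anergic",
            (t.positive("CD19"), t.neg_or_low("CD21"), t.negative_atom("CD38")),
        ),
        "igmlo_naive": GateDefinition(
            "igmlo_naive",
            (t.negative_atom("CD27"), t.positive("IgD"), t.mid_low("IgM")),
        ),
    }
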