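"""Flow-cytometry-style gates over ADT marker space.

A gate is a conjunction of atoms — 1-D intervals on single markers and 2-D
polygon regions over marker pairs — mirroring how cytometrists draw
rectangular and free-hand gates. Gates compose into hierarchical panels
(rooted trees whose leaves name populations), and negative thresholds are
estimated from the ADT densities of cells known not to express a marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.signal import argrelextrema
from scipy.stats import gaussian_kde

from .core import CellDataset, CitegateError, CitegateWarning

__all__ = [
    "Interval",
    "PolygonRegion",
    "GateDefinition",
    "GateNode",
    "GatePanel",
    "PanelResult",
    "UNGATED",
    "UnimodalDensityError",
    "estimate_threshold",
    "apply_gate",
    "apply_panel",
    "points_in_polygon",
]

UNGATED = "ungated"


class UnimodalDensityError(CitegateError):
    """Raised when valley-mode thresholding finds fewer than two modes."""


# ---------------------------------------------------------------------------
# gate atoms


@dataclass(frozen=True)
class Interval:
    """1-D interval atom: low ≤/< marker ≤/< high (bounds per flags)."""

    marker: str
    low: float = -math.inf
    high: float = math.inf
    low_inclusive: bool = True
    high_inclusive: bool = True

    def __post_init__(self):
        if self.low > self.high:
            raise CitegateError(
                f"interval on {self.marker!r}: low {self.low} > high {self.high}"
            )

    def evaluate(self, dataset: CellDataset) -> np.ndarray:
        x = dataset.marker_values(self.marker)
        lo = x >= self.low if self.low_inclusive else x > self.low
        hi = x <= self.high if self.high_inclusive else x < self.high
        return lo & hi


def points_in_polygon(
    x: np.ndarray, y: np.ndarray, vertices: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Even-odd-rule point-in-polygon test, boundary inclusive, vectorised.

    The polygon is the vertex sequence with an implicit closing edge from the
    last vertex back to the first.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    verts = np.asarray(vertices, dtype=float)
    inside = np.zeros(x.shape, dtype=bool)
    on_edge = np.zeros(x.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        seg_len2 = (x2 - x1) ** 2 + (y2 - y1) ** 2
        if seg_len2 == 0.0:  # repeated vertex; no edge to test
            on_edge |= (x == x1) & (y == y1)
            continue
        # boundary test: point on segment (within floating tolerance)
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        dot = (x - x1) * (x2 - x1) + (y - y1) * (y2 - y1)
        tol = 1e-12 * max(1.0, seg_len2)
        on_edge |= (np.abs(cross) <= tol) & (dot >= -tol) & (dot <= seg_len2 + tol)
        # even-odd ray casting (horizontal ray towards +x)
        if y1 != y2:  # horizontal edges cannot be crossed by a horizontal ray
            crosses = ((y1 > y) != (y2 > y)) & (
                x < (x2 - x1) * (y - y1) / (y2 - y1) + x1
            )
            inside ^= crosses
    return inside | on_edge


@dataclass(frozen=True)
class PolygonRegion:
    """2-D polygon atom over a marker pair; membership by the even-odd rule,
    boundary inclusive. Vertices are stored in declaration order with an
    implicit closing edge."""

    marker_x: str
    marker_y: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        verts = tuple((float(a), float(b)) for a, b in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise CitegateError("polygon needs at least 3 vertices")
        if abs(self.area()) <= 0:
            raise CitegateError("polygon has zero area")

    def area(self) -> float:
        v = np.asarray(self.vertices)
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def evaluate(self, dataset: CellDataset) -> np.ndarray:
        return points_in_polygon(
            dataset.marker_values(self.marker_x),
            dataset.marker_values(self.marker_y),
            self.vertices,
        )


Atom = Interval | PolygonRegion


@dataclass(frozen=True)
class GateDefinition:
    """Named conjunction of interval/polygon atoms. No atoms = all cells."""

    name: str
    atoms: tuple[Atom, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))

    @property
    def markers(self) -> set[str]:
        out: set[str] = set()
        for atom in self.atoms:
            if isinstance(atom, Interval):
                out.add(atom.marker)
            else:
                out.update((atom.marker_x, atom.marker_y))
        return out


def apply_gate(dataset: CellDataset, gate: GateDefinition) -> np.ndarray:
    """Boolean membership: true iff the cell satisfies every atom."""
    out = np.ones(dataset.n_cells, dtype=bool)
    for atom in gate.atoms:
        out &= atom.evaluate(dataset)
    return out


# ---------------------------------------------------------------------------
# panels


@dataclass
class GateNode:
    """Node of a gating tree. Leaves (no children) carry a population label;
    internal nodes refine their parent and pass cells to their children."""

    gate: GateDefinition
    children: list["GateNode"] = field(default_factory=list)
    label: Optional[str] = None

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GatePanel:
    name: str
    root: GateNode

    def leaf_labels(self) -> list[str]:
        out: list[str] = []

        def walk(node: GateNode):
            if node.is_leaf():
                out.append(node.label or node.gate.name)
            for child in node.children:
                walk(child)

        walk(self.root)
        return out


@dataclass
class PanelResult:
    """Per-cell leaf assignment plus bookkeeping about sibling overlap."""

    assignment: np.ndarray  # population name or "ungated", per cell
    sibling_overlap_count: int
    overlapping_pairs: list[tuple[str, str]]

    def counts(self) -> dict[str, int]:
        labels, n = np.unique(self.assignment, return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))


def apply_panel(dataset: CellDataset, panel: GatePanel) -> PanelResult:
    """Assign each cell the deepest leaf whose root-to-leaf conjunction holds.

    Sibling gates are meant to be mutually exclusive on the dataset at hand;
    empirical overlaps are counted and reported, and ties are broken in
    sibling declaration order (first declared wins). Cells satisfying no leaf
    are assigned ``"ungated"``.
    """
    n = dataset.n_cells
    assignment = np.full(n, UNGATED, dtype=object)
    overlap_count = 0
    overlapping: list[tuple[str, str]] = []
    seen: set[int] = set()

    def walk(node: GateNode, mask: np.ndarray):
        nonlocal overlap_count
        if id(node) in seen:
            raise CitegateError("cyclic gating tree")
        seen.add(id(node))
        mask = mask & apply_gate(dataset, node.gate)
        if node.is_leaf():
            label = node.label or node.gate.name
            assignment[mask] = label
            return mask
        claimed = np.zeros(n, dtype=bool)
        child_masks: list[tuple[str, np.ndarray]] = []
        for child in node.children:
            child_mask = walk(child, mask & ~claimed)
            # overlap check uses the raw (unclaimed-independent) membership
            raw = mask & apply_gate(dataset, child.gate)
            for prev_name, prev_raw in child_masks:
                both = int(np.sum(raw & prev_raw))
                if both:
                    overlap_count += both
                    overlapping.append((prev_name, child.gate.name))
            child_masks.append((child.gate.name, raw))
            claimed |= child_mask
        return claimed

    walk(panel.root, np.ones(n, dtype=bool))
    if overlap_count:
        warnings.warn(
            f"panel {panel.name!r}: {overlap_count} cell-level sibling overlaps "
            f"across pairs {sorted(set(overlapping))}; first-declared sibling wins",
            CitegateWarning,
            stacklevel=2,
        )
    return PanelResult(assignment, overlap_count, sorted(set(overlapping)))


# ---------------------------------------------------------------------------
# threshold estimation


def estimate_threshold(
    dataset: CellDataset,
    marker: str,
    negative_reference: Optional[np.ndarray] = None,
    mode: str = "quantile",
    q: float = 0.995,
    grid_size: int = 512,
) -> float:
    """Estimate a positivity threshold for one marker.

    quantile mode returns the q-th quantile (default 0.995) of the marker
    within a negative reference — cells known not to express the marker — so
    the threshold sits just above the negative background. valley mode
    ignores the reference and returns the density minimum between the two
    largest modes of the full marker distribution (Gaussian KDE).
    """
    x = dataset.marker_values(marker)
    if mode == "quantile":
        if negative_reference is None:
            raise CitegateError("quantile mode requires a negative_reference")
        ref = np.asarray(negative_reference)
        if ref.dtype == bool:
            vals = x[ref]
        else:
            vals = x[np.asarray(ref, dtype=int)]
        if vals.size == 0:
            raise CitegateError("negative reference is empty")
        if vals.size < 20:
            warnings.warn(
                f"negative reference for {marker!r} has only {vals.size} cells",
                CitegateWarning,
                stacklevel=2,
            )
        if not 0 < q < 1:
            raise CitegateError("q must be in (0, 1)")
        return float(np.quantile(vals, q))
    if mode == "valley":
        return _valley_threshold(x, marker, grid_size)
    raise CitegateError(f"unknown threshold mode {mode!r}")


def _valley_threshold(x: np.ndarray, marker: str, grid_size: int) -> float:
    if np.ptp(x) == 0:
        raise UnimodalDensityError(
            f"marker {marker!r} is constant; use quantile mode with a reference"
        )
    kde = gaussian_kde(x)
    pad = 0.05 * np.ptp(x)
    grid = np.linspace(x.min() - pad, x.max() + pad, grid_size)
    dens = kde(grid)
    peaks = argrelextrema(dens, np.greater)[0]
    # include boundary maxima
    if dens[0] > dens[1]:
        peaks = np.r_[0, peaks]
    if dens[-1] > dens[-2]:
        peaks = np.r_[peaks, grid_size - 1]
    if len(peaks) < 2:
        raise UnimodalDensityError(
            f"marker {marker!r} density is unimodal; use quantile mode with a "
            "negative reference instead"
        )
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = lo + int(np.argmin(dens[lo : hi + 1]))
    return float(grid[valley])
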