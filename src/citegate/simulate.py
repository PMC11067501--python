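"""Synthetic CITE-seq ADT data with known ground truth.

The generator emulates the count structure of a B-cell ADT panel: each
population has a characteristic mean count per marker, per-cell counts are
negative-binomially distributed around those means (overdispersion via a
size parameter) with an additive Poisson ambient background, and per-sample
population compositions are drawn from a Dirichlet centred on the global
proportions, optionally rescaled per group to create disease-like
composition shifts. An optional planted effect multiplies one population's
mean on one marker by 2^Δ, giving a controlled signal for marker-selection
experiments.

The default panel carries the ten markers used throughout classical B-cell
gating (CD19, CD20, CD21, CD24, CD27, CD38, CD10, CD11c, IgD, IgM) and
seven populations: naïve, unswitched memory, switched memory, IgD−CD27−
(double-negative) B cells, plasmablasts, transitional B cells, and a
CD19-negative non-B population that exercises the root gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .core import CellDataset, CitegateError

__all__ = [
    "Population",
    "GroupSpec",
    "PlantedEffect",
    "SimConfig",
    "simulate_dataset",
    "default_scenarios",
    "default_populations",
    "planted_marker_config",
    "DEFAULT_MARKERS",
]

DEFAULT_MARKERS = [
    "CD19", "CD20", "CD21", "CD24", "CD27",
    "CD38", "CD10", "CD11c", "IgD", "IgM",
]


@dataclass(frozen=True)
class Population:
    """One ground-truth cell population: its global proportion, mean ADT
    count per marker, and negative-binomial size (dispersion) parameters."""

    name: str
    proportion: float
    mu: dict[str, float]
    dispersion: float = 8.0  # NB size; larger = closer to Poisson

    def __post_init__(self):
        if self.proportion < 0:
            raise CitegateError(f"population {self.name!r}: proportion < 0")
        if self.dispersion <= 0:
            raise CitegateError(f"population {self.name!r}: dispersion must be > 0")
        for m, v in self.mu.items():
            if v <= 0:
                raise CitegateError(
                    f"population {self.name!r}: mean for marker {m!r} must be > 0"
                )


@dataclass(frozen=True)
class GroupSpec:
    """A sample group (e.g. a disease state) with per-population composition
    multipliers applied before the Dirichlet draw."""

    name: str
    n_samples: int
    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.n_samples < 1:
            raise CitegateError(f"group {self.name!r}: n_samples must be >= 1")
        for p, v in self.multipliers.items():
            if v < 0:
                raise CitegateError(
                    f"group {self.name!r}: multiplier for {p!r} must be >= 0"
                )


@dataclass(frozen=True)
class PlantedEffect:
    """Shift one population's mean on one marker by a factor 2^log2_shift."""

    population: str
    marker: str
    log2_shift: float


@dataclass(frozen=True)
class SimConfig:
    populations: tuple[Population, ...]
    markers: tuple[str, ...]
    groups: tuple[GroupSpec, ...]
    n_cells_per_sample: int = 500
    dirichlet_concentration: float = 60.0
    background_rate: float = 0.5
    planted: Optional[PlantedEffect] = None
    seed: int = 0

    def __post_init__(self):
        if not self.populations:
            raise CitegateError("populations must be non-empty")
        total = sum(p.proportion for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise CitegateError(
                f"population proportions must sum to 1 (got {total})"
            )
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise CitegateError("duplicate population names")
        for p in self.populations:
            missing = set(self.markers) - set(p.mu)
            if missing:
                raise CitegateError(
                    f"population {p.name!r} lacks means for markers {sorted(missing)}"
                )
        if not self.groups:
            raise CitegateError("groups must be non-empty")
        if self.n_cells_per_sample < 1:
            raise CitegateError("n_cells_per_sample must be >= 1")
        if self.dirichlet_concentration <= 0:
            raise CitegateError("dirichlet_concentration must be > 0")
        if self.background_rate < 0:
            raise CitegateError("background_rate must be >= 0")
        if self.planted is not None:
            if self.planted.population not in names:
                raise CitegateError(
                    f"planted effect references unknown population "
                    f"{self.planted.population!r}"
                )
            if self.planted.marker not in self.markers:
                raise CitegateError(
                    f"planted effect references unknown marker "
                    f"{self.planted.marker!r}"
                )


def simulate_dataset(config: SimConfig) -> CellDataset:
    """Draw a raw-count :class:`CellDataset` from a :class:`SimConfig`.

    Identical configs (including seed) give byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    pops = config.populations
    markers = list(config.markers)
    pi = np.array([p.proportion for p in pops])
    pop_names = [p.name for p in pops]

    # per-population mean matrix, with any planted shift applied
    mu = np.array([[p.mu[m] for m in markers] for p in pops], dtype=float)
    size = np.array([p.dispersion for p in pops], dtype=float)
    if config.planted is not None:
        pi_idx = pop_names.index(config.planted.population)
        mj = markers.index(config.planted.marker)
        mu[pi_idx, mj] *= 2.0 ** config.planted.log2_shift

    values_parts, truth_parts, sample_parts, group_parts, cell_ids = [], [], [], [], []
    sample_counter = 0
    for grp in config.groups:
        mult = np.array([grp.multipliers.get(p.name, 1.0) for p in pops])
        base = pi * mult
        if base.sum() <= 0:
            raise CitegateError(f"group {grp.name!r}: all multipliers zero")
        base = base / base.sum()
        for _ in range(grp.n_samples):
            sample_counter += 1
            sname = f"S{sample_counter:03d}"
            comp = rng.dirichlet(config.dirichlet_concentration * base)
            pop_idx = rng.choice(len(pops), size=config.n_cells_per_sample, p=comp)
            n = config.n_cells_per_sample
            cell_mu = mu[pop_idx]  # n × markers
            cell_size = size[pop_idx][:, None]
            p_nb = cell_size / (cell_size + cell_mu)
            counts = rng.negative_binomial(cell_size, p_nb).astype(float)
            if config.background_rate > 0:
                counts += rng.poisson(config.background_rate, size=counts.shape)
            values_parts.append(counts)
            truth_parts.append(np.array([pop_names[i] for i in pop_idx], dtype=object))
            sample_parts.append(np.full(n, sname, dtype=object))
            group_parts.append(np.full(n, grp.name, dtype=object))
            cell_ids.extend(f"{sname}_c{i:05d}" for i in range(n))

    return CellDataset(
        values=np.vstack(values_parts),
        marker_names=markers,
        cell_ids=cell_ids,
        truth_label=np.concatenate(truth_parts),
        sample_id=np.concatenate(sample_parts),
        group=np.concatenate(group_parts),
    )


# ---------------------------------------------------------------------------
# default panel parameterisation


def default_populations(contaminant_proportion: float = 0.0) -> list[Population]:
    """The default seven-population B-cell panel, optionally plus an
    IgD+ CD27− memory-like contaminant that lands in the naïve gate but is
    separable on CD20/CD21/CD24 (an "atypical memory" population).

    Mean counts follow the usual ADT picture: negatives sit at a few ambient
    counts, positives at one to a few hundred, with "mid" levels between.
    """
    base = [
        Population("naive", 0.40, {
            "CD19": 150, "CD20": 200, "CD21": 150, "CD24": 60, "CD27": 3,
            "CD38": 40, "CD10": 3, "CD11c": 3, "IgD": 200, "IgM": 120,
        }),
        Population("unswitched_memory", 0.08, {
            "CD19": 150, "CD20": 200, "CD21": 120, "CD24": 120, "CD27": 120,
            "CD38": 40, "CD10": 3, "CD11c": 8, "IgD": 150, "IgM": 150,
        }),
        Population("switched_memory", 0.16, {
            "CD19": 150, "CD20": 200, "CD21": 120, "CD24": 120, "CD27": 120,
            "CD38": 30, "CD10": 3, "CD11c": 10, "IgD": 4, "IgM": 4,
        }),
        Population("dnb", 0.07, {
            "CD19": 150, "CD20": 180, "CD21": 15, "CD24": 40, "CD27": 3,
            "CD38": 25, "CD10": 3, "CD11c": 80, "IgD": 4, "IgM": 10,
        }),
        Population("plasmablast", 0.06, {
            "CD19": 60, "CD20": 8, "CD21": 8, "CD24": 5, "CD27": 250,
            "CD38": 400, "CD10": 3, "CD11c": 5, "IgD": 3, "IgM": 10,
        }),
        Population("transitional", 0.09, {
            "CD19": 150, "CD20": 200, "CD21": 30, "CD24": 250, "CD27": 3,
            "CD38": 250, "CD10": 100, "CD11c": 3, "IgD": 150, "IgM": 200,
        }),
        Population("nonb", 0.14, {
            "CD19": 3, "CD20": 3, "CD21": 5, "CD24": 5, "CD27": 80,
            "CD38": 20, "CD10": 3, "CD11c": 30, "IgD": 3, "IgM": 3,
        }),
    ]
    if contaminant_proportion > 0:
        contaminant = Population("atypical_memory", contaminant_proportion, {
            # IgD+ CD27− CD38-mid: indistinguishable from naïve on the
            # classical panel axes, but CD21-low / CD20-high / CD24-high.
            "CD19": 150, "CD20": 420, "CD21": 12, "CD24": 140, "CD27": 4,
            "CD38": 35, "CD10": 3, "CD11c": 20, "IgD": 160, "IgM": 100,
        })
        scale = 1.0 - contaminant_proportion
        base = [replace(p, proportion=p.proportion * scale) for p in base]
        base.append(contaminant)
    # renormalise exactly to 1 to survive the strict sum check
    total = sum(p.proportion for p in base)
    return [replace(p, proportion=p.proportion / total) for p in base]


def default_scenarios(seed: int = 0) -> dict[str, SimConfig]:
    """Named study presets.

    - ``clean``: well-separated populations; the classical panel gates with
      high purity (naïve purity ≥ 0.95 by construction).
    - ``contaminated-naive``: a memory-like population (IgD+ CD27−) overlaps
      the naïve gate but is separable on CD20/CD21/CD24, pulling naïve-gate
      purity down to ≲ 0.8 — the substrate for marker selection and HDR
      refinement.
    - ``group-shift``: same contamination, with one group carrying twice the
      contaminant proportion, for cross-group association tests.
    """
    clean = SimConfig(
        populations=tuple(default_populations(0.0)),
        markers=tuple(DEFAULT_MARKERS),
        groups=(GroupSpec("healthy", 12),),
        n_cells_per_sample=500,
        seed=seed,
    )
    contaminated = SimConfig(
        populations=tuple(default_populations(0.12)),
        markers=tuple(DEFAULT_MARKERS),
        groups=(GroupSpec("healthy", 12),),
        n_cells_per_sample=500,
        seed=seed,
    )
    group_shift = SimConfig(
        populations=tuple(default_populations(0.10)),
        markers=tuple(DEFAULT_MARKERS),
        groups=(
            GroupSpec("healthy", 10),
            GroupSpec("disease", 10, {"atypical_memory": 2.0}),
        ),
        n_cells_per_sample=400,
        seed=seed,
    )
    return {
        "clean": clean,
        "contaminated-naive": contaminated,
        "group-shift": group_shift,
    }


def planted_marker_config(
    delta: float,
    marker: str = "CD21",
    n_cells: int = 5000,
    seed: int = 0,
    base_mean: float = 50.0,
    dispersion: float = 10.0,
) -> SimConfig:
    """Two populations identical on every marker except a 2^delta mean shift
    of the contaminant on ``marker`` — a controlled recovery benchmark for
    the marker-selection pipeline."""
    if marker not in DEFAULT_MARKERS:
        raise CitegateError(f"unknown marker {marker!r}")
    mu = {m: base_mean for m in DEFAULT_MARKERS}
    pops = (
        Population("target", 0.5, dict(mu), dispersion=dispersion),
        Population("contaminant", 0.5, dict(mu), dispersion=dispersion),
    )
    return SimConfig(
        populations=pops,
        markers=tuple(DEFAULT_MARKERS),
        groups=(GroupSpec("all", 1),),
        n_cells_per_sample=n_cells,
        dirichlet_concentration=1e6,  # pin composition at 50:50
        background_rate=0.0,
        planted=PlantedEffect("contaminant", marker, delta),
        seed=seed,
    )
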