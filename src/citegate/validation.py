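"""Seeded calibration experiments for the pipeline's statistical machinery.

Each function runs a controlled simulation study and returns the measured
quantity, so the same code backs both the test suite and reproduction
scripts. All randomness derives from the caller's seed via
``numpy.random.SeedSequence`` spawning, keeping every derived seed below
2^31.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import CellDataset, NormalizationTag, clr_normalize
from .groupstats import CompositionTable, association_tests
from .refinement import fit_density_gate
from .selection import TPFPLabels, mmd2_unbiased, select_markers
from .simulate import default_scenarios, planted_marker_config, simulate_dataset
from .workflow import run_classical_gating, run_refinement, run_selection

__all__ = [
    "child_seeds",
    "planted_recovery",
    "refinement_success",
    "hdr_mass_fraction",
    "anova_type1_error",
    "mmd_null_summary",
    "mmd_delta_monotonicity",
]


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible sub-seeds derived from one master seed (< 2^31)."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def planted_recovery(
    seed: int,
    n_runs: int = 20,
    delta: float = 2.0,
    marker: str = "CD21",
    n_cells: int = 5000,
    max_cells: int = 2000,
) -> dict:
    """Marker-recovery benchmark: two populations identical except a 2^delta
    mean shift on one marker; count the runs in which the selection pipeline
    ranks that marker first."""
    hits = 0
    for s in child_seeds(seed, n_runs):
        config = planted_marker_config(delta, marker=marker, n_cells=n_cells, seed=s)
        sim = simulate_dataset(config)
        norm = clr_normalize(sim)
        assignment = np.full(sim.n_cells, "all", dtype=object)
        sel = select_markers(
            sim, assignment, "all", "target",
            k=2, seed=s, scoring_values=norm.values, max_cells=max_cells,
        )
        if sel.selected and sel.selected[0] == marker:
            hits += 1
    return {"hits": hits, "n_runs": n_runs, "rate": hits / n_runs}


def refinement_success(
    seed: int,
    n_runs: int = 20,
    gate: str = "naive",
    alpha: float = 0.9,
    max_cells: int = 1500,
) -> dict:
    """HDR-refinement benchmark on the contaminated-naïve preset: count the
    runs in which refining on the selected marker pair raises gate purity."""
    hits = 0
    gains = []
    for s in child_seeds(seed, n_runs):
        config = default_scenarios(seed=s)["contaminated-naive"]
        sim = simulate_dataset(config)
        run = run_classical_gating(sim)
        sel = run_selection(run, gate, seed=s, max_cells=max_cells)
        _, report = run_refinement(run, gate, sel, alpha=alpha)
        if report.purity_after_defined and report.purity_after > report.purity_before:
            hits += 1
            gains.append(report.purity_increase_points)
    return {
        "hits": hits,
        "n_runs": n_runs,
        "rate": hits / n_runs,
        "mean_gain_points": float(np.mean(gains)) if gains else float("nan"),
    }


def hdr_mass_fraction(
    seed: int, n: int = 2000, alpha: float = 0.9, grid: int = 128
) -> float:
    """Fraction of standard-Gaussian TP cells inside a fitted HDR gate —
    should sit at ``alpha`` up to Monte-Carlo and gridding error."""
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((n, 2))
    ds = CellDataset(
        values=pts,
        marker_names=["m1", "m2"],
        cell_ids=[f"c{i}" for i in range(n)],
        normalization=NormalizationTag("arcsinh", {"cofactor": 5.0}),
    )
    labels = TPFPLabels("g", "t", np.arange(n), np.ones(n, dtype=bool))
    refined = fit_density_gate(ds, labels, ("m1", "m2"), alpha=alpha, grid=grid)
    inside = refined.stages[0].membership(ds)
    return float(inside.mean())


def anova_type1_error(
    seed: int,
    n_sims: int = 1000,
    n_per_group: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Type-I-error calibration of the cross-group ANOVA: both groups draw
    per-sample frequencies from the same Beta distribution, so rejections at
    level alpha should occur at rate alpha."""
    rng = np.random.default_rng(seed)
    rejections = 0
    tested = 0
    for _ in range(n_sims):
        rows = []
        for g in ("a", "b"):
            props = rng.beta(2.0, 8.0, size=n_per_group)
            for i, p in enumerate(props):
                rows.append(
                    {
                        "sample_id": f"{g}{i}",
                        "group": g,
                        "gate": "g",
                        "truth_label": "x",
                        "proportion": float(p),
                        "n_cells": 1,
                        "n_gated": 1,
                    }
                )
        comp = CompositionTable(pd.DataFrame(rows))
        res = association_tests(comp, "g", "x")
        if not res.eligible:
            continue
        tested += 1
        if res.p_anova < alpha:
            rejections += 1
    return {
        "rate": rejections / tested if tested else float("nan"),
        "n_sims": tested,
    }


def mmd_null_summary(seed: int, n_reps: int = 200, n: int = 500) -> dict:
    """Unbiasedness check of the rbf/median MMD² estimator under the null:
    mean over replicates of same-distribution samples, with its SE."""
    vals = []
    for s in child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        vals.append(mmd2_unbiased(x, y, kernel="rbf", bandwidth="median"))
    vals = np.asarray(vals)
    se = float(vals.std(ddof=1) / np.sqrt(len(vals)))
    return {"mean": float(vals.mean()), "se": se, "n_reps": n_reps,
            "z": float(vals.mean() / se) if se else float("nan")}


def mmd_delta_monotonicity(
    seed: int,
    deltas=(0.0, 0.5, 1.0, 2.0, 4.0),
    n_runs: int = 20,
    n_cells: int = 2000,
    marker: str = "CD21",
) -> dict:
    """Mean MMD² of the planted marker as a function of the planted shift Δ;
    returns the Spearman rank correlation of (Δ, mean MMD²)."""
    from scipy.stats import spearmanr

    means = []
    for delta in deltas:
        vals = []
        for s in child_seeds(seed + int(delta * 1000) % 100000, n_runs):
            config = planted_marker_config(
                delta, marker=marker, n_cells=n_cells, seed=s
            )
            sim = simulate_dataset(config)
            norm = clr_normalize(sim)
            x = norm.marker_values(marker)
            truth = sim.truth_label
            vals.append(
                mmd2_unbiased(
                    x[truth == "target"], x[truth == "contaminant"],
                    kernel="rbf", bandwidth="median",
                )
            )
        means.append(float(np.mean(vals)))
    rho = float(spearmanr(list(deltas), means).statistic)
    return {"deltas": list(deltas), "mean_mmd2": means, "spearman_rho": rho}
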