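"""Per-sample composition of truth labels inside gates, and tests for
composition differences across sample groups (e.g. disease states).

For each (sample, gate) the proportion of gated cells carrying each truth
label is computed. Association of a given (gate, truth label) frequency
with group membership is tested by one-way ANOVA across groups, with all
pairwise two-sided Wilcoxon rank-sum comparisons under Holm step-down
adjustment. Tests run only when every group has more than 3 individuals
with non-zero frequency (read strictly: at least 4), mirroring common
practice for sparse compositional data; ineligible combinations are
flagged and skipped rather than tested.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .core import MISSING, CitegateError, CitegateWarning
from .gating import UNGATED

__all__ = [
    "CompositionTable",
    "GroupTestResult",
    "composition_by_sample",
    "association_tests",
    "holm_adjust",
]


@dataclass
class CompositionTable:
    """Long table: one row per (sample, group, gate, truth label) with the
    label's proportion among that sample's gated cells, plus cell counts.
    Samples in which a gate is empty contribute no rows for it; those
    (sample, gate) pairs are recorded in ``empty_combinations``."""

    table: pd.DataFrame
    empty_combinations: list[tuple[str, str]] = field(default_factory=list)


def composition_by_sample(
    assignment: np.ndarray,
    truth: np.ndarray,
    sample_id: np.ndarray,
    group: np.ndarray,
    include_ungated: bool = False,
) -> CompositionTable:
    """Per-sample truth-label composition of every gate."""
    frames = {
        "assignment": np.asarray(assignment, dtype=object),
        "truth": np.asarray(truth, dtype=object),
        "sample_id": np.asarray(sample_id, dtype=object),
        "group": np.asarray(group, dtype=object),
    }
    lengths = {len(v) for v in frames.values()}
    if len(lengths) != 1:
        raise CitegateError("per-cell vectors differ in length")
    df = pd.DataFrame(frames)
    df = df[(df["truth"] != MISSING) & df["truth"].notna()]
    if df.empty:
        raise CitegateError("no labelled cells")
    if not include_ungated:
        df = df[df["assignment"] != UNGATED]
    gates = sorted(df["assignment"].unique().tolist())
    samples = df[["sample_id", "group"]].drop_duplicates()
    rows = []
    empty: list[tuple[str, str]] = []
    for _, srow in samples.iterrows():
        s, g = srow["sample_id"], srow["group"]
        sdf = df[df["sample_id"] == s]
        for gate in gates:
            gdf = sdf[sdf["assignment"] == gate]
            if gdf.empty:
                empty.append((str(s), gate))
                continue
            n = len(gdf)
            for label, cnt in gdf["truth"].value_counts().items():
                rows.append(
                    {
                        "sample_id": s,
                        "group": g,
                        "gate": gate,
                        "truth_label": label,
                        "proportion": cnt / n,
                        "n_cells": int(cnt),
                        "n_gated": n,
                    }
                )
    table = pd.DataFrame(rows).sort_values(
        ["gate", "sample_id", "truth_label"], ignore_index=True
    )
    return CompositionTable(table, empty)


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (family-wise error control)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


@dataclass
class GroupTestResult:
    gate: str
    truth_label: str
    eligible: bool
    p_anova: Optional[float]
    pairwise: pd.DataFrame  # columns group_a, group_b, p_raw, p_holm
    n_nonzero_per_group: dict[str, int]
    excluded_groups: list[str] = field(default_factory=list)

    def as_rows(self) -> pd.DataFrame:
        base = {
            "gate": self.gate,
            "truth_label": self.truth_label,
            "eligible": self.eligible,
            "p_anova": self.p_anova,
        }
        if self.pairwise.empty:
            return pd.DataFrame([base])
        rows = []
        for _, r in self.pairwise.iterrows():
            rows.append({**base, "group_a": r["group_a"], "group_b": r["group_b"],
                         "p_holm": r["p_holm"]})
        return pd.DataFrame(rows)


def _frequencies(
    composition: CompositionTable, gate: str, truth_label: str
) -> pd.DataFrame:
    """Per-sample frequency of one truth label inside one gate.

    Samples where the gate is non-empty but lacks the label get an explicit
    zero; samples where the gate is empty contribute nothing.
    """
    t = composition.table
    gate_rows = t[t["gate"] == gate]
    if gate_rows.empty:
        raise CitegateError(f"gate {gate!r} absent from the composition table")
    per_sample = gate_rows[["sample_id", "group"]].drop_duplicates()
    label_rows = gate_rows[gate_rows["truth_label"] == truth_label]
    merged = per_sample.merge(
        label_rows[["sample_id", "proportion"]], on="sample_id", how="left"
    )
    merged["proportion"] = merged["proportion"].fillna(0.0)
    return merged


def association_tests(
    composition: CompositionTable,
    gate: str,
    truth_label: str,
    min_nonzero: int = 4,
    transform: str = "identity",
) -> GroupTestResult:
    """Test whether a label's within-gate frequency differs across groups.

    Eligibility requires at least ``min_nonzero`` samples with non-zero
    frequency in *every* group (the ">3 individuals" rule); ineligible
    combinations return with tests skipped and ``eligible=False``. Raw
    proportions are tested by default; ``transform="logit"`` applies an
    empirical logit for users who prefer variance stabilisation.
    """
    freq = _frequencies(composition, gate, truth_label)
    groups = sorted(freq["group"].unique().tolist())
    if len(groups) < 2:
        raise CitegateError("need at least 2 groups for association tests")
    if transform == "logit":
        eps = 0.5 / max(freq["proportion"].size, 1)
        vals_all = np.log(
            (freq["proportion"] + eps) / (1 - freq["proportion"] + eps)
        )
        freq = freq.assign(value=vals_all)
    elif transform == "identity":
        freq = freq.assign(value=freq["proportion"])
    else:
        raise CitegateError(f"unknown transform {transform!r}")

    by_group = {g: freq.loc[freq["group"] == g, "value"].to_numpy() for g in groups}
    nonzero = {
        g: int(np.sum(freq.loc[freq["group"] == g, "proportion"] > 0))
        for g in groups
    }
    eligible = all(n >= min_nonzero for n in nonzero.values())
    empty_pairwise = pd.DataFrame(columns=["group_a", "group_b", "p_raw", "p_holm"])
    if not eligible:
        return GroupTestResult(
            gate, truth_label, False, None, empty_pairwise, nonzero
        )

    p_anova = float(f_oneway(*[by_group[g] for g in groups]).pvalue)

    excluded = [g for g in groups if len(by_group[g]) < 2]
    if excluded:
        warnings.warn(
            f"groups {excluded} have fewer than 2 samples; excluded from "
            "pairwise tests",
            CitegateWarning,
            stacklevel=2,
        )
    testable = [g for g in groups if g not in excluded]
    pairs = list(itertools.combinations(testable, 2))
    raw = []
    for a, b in pairs:
        va, vb = by_group[a], by_group[b]
        if np.ptp(np.concatenate([va, vb])) == 0:
            raw.append(1.0)
        else:
            raw.append(float(mannwhitneyu(va, vb, alternative="two-sided").pvalue))
    adj = holm_adjust(raw) if raw else np.array([])
    pairwise = pd.DataFrame(
        {
            "group_a": [a for a, _ in pairs],
            "group_b": [b for _, b in pairs],
            "p_raw": raw,
            "p_holm": adj,
        }
    )
    return GroupTestResult(
        gate, truth_label, True, p_anova, pairwise, nonzero, excluded
    )
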