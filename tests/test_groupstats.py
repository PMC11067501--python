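"""Per-sample composition and cross-group association tests."""

import numpy as np
import pandas as pd
import pytest

from citegate.core import CitegateError
from citegate.groupstats import (
    CompositionTable,
    association_tests,
    composition_by_sample,
    holm_adjust,
)


def _composition_from_values(values_by_group):
    rows = []
    for g, vals in values_by_group.items():
        for i, v in enumerate(vals):
            rows.append(
                {
                    "sample_id": f"{g}{i}",
                    "group": g,
                    "gate": "g",
                    "truth_label": "x",
                    "proportion": float(v),
                    "n_cells": 1,
                    "n_gated": 1,
                }
            )
    return CompositionTable(pd.DataFrame(rows))


class TestComposition:
    def test_single_sample_proportions(self):
        assignment = np.array(["G", "G", "G"], dtype=object)
        truth = np.array(["naive", "naive", "memory"], dtype=object)
        sample = np.array(["s1"] * 3, dtype=object)
        group = np.array(["g1"] * 3, dtype=object)
        comp = composition_by_sample(assignment, truth, sample, group)
        t = comp.table.set_index("truth_label")
        assert t.loc["naive", "proportion"] == pytest.approx(2 / 3)
        assert t.loc["memory", "proportion"] == pytest.approx(1 / 3)

    def test_proportions_sum_to_one_per_sample_gate(self):
        rng = np.random.default_rng(1)
        n = 600
        assignment = rng.choice(np.array(["A", "B", "ungated"], dtype=object), n)
        truth = rng.choice(np.array(["x", "y", "z"], dtype=object), n)
        sample = rng.choice(np.array(["s1", "s2", "s3"], dtype=object), n)
        group = np.where(sample == "s3", "g2", "g1").astype(object)
        comp = composition_by_sample(assignment, truth, sample, group)
        sums = comp.table.groupby(["sample_id", "gate"])["proportion"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_matches_bruteforce_tally(self):
        rng = np.random.default_rng(2)
        n = 300
        assignment = rng.choice(np.array(["A", "B"], dtype=object), n)
        truth = rng.choice(np.array(["x", "y"], dtype=object), n)
        sample = rng.choice(np.array(["s1", "s2", "s3"], dtype=object), n)
        group = np.full(n, "g1", dtype=object)
        comp = composition_by_sample(assignment, truth, sample, group)
        for _, row in comp.table.iterrows():
            in_cell = (
                (assignment == row["gate"])
                & (sample == row["sample_id"])
            )
            expect = np.sum(in_cell & (truth == row["truth_label"])) / np.sum(in_cell)
            assert row["proportion"] == pytest.approx(expect)

    def test_empty_gate_in_sample_recorded(self):
        assignment = np.array(["A", "A", "B"], dtype=object)
        truth = np.array(["x", "x", "x"], dtype=object)
        sample = np.array(["s1", "s1", "s2"], dtype=object)
        group = np.array(["g1", "g1", "g1"], dtype=object)
        comp = composition_by_sample(assignment, truth, sample, group)
        assert ("s1", "B") in comp.empty_combinations
        assert ("s2", "A") in comp.empty_combinations


class TestHolm:
    def test_hand_stepdown_example(self):
        # sorted: 0.01*3=0.03; 0.03*2=0.06; 0.04*1=0.04 -> monotone max
        adj = holm_adjust([0.01, 0.04, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.06, 0.06], atol=1e-12)

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=8)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestAssociation:
    def test_eligibility_requires_more_than_three_nonzero(self):
        # exactly 3 non-zero per group -> ineligible
        comp = _composition_from_values(
            {"a": [0.1, 0.2, 0.3, 0.0], "b": [0.1, 0.2, 0.3, 0.0]}
        )
        res = association_tests(comp, "g", "x")
        assert not res.eligible and res.p_anova is None
        # 4 non-zero per group -> eligible
        comp = _composition_from_values(
            {"a": [0.1, 0.2, 0.3, 0.4], "b": [0.1, 0.2, 0.3, 0.4]}
        )
        assert association_tests(comp, "g", "x").eligible

    def test_zero_frequency_samples_included_as_zeros(self):
        # the gate exists in every sample; the label is absent from some
        assignment = np.array(["G"] * 8, dtype=object)
        truth = np.array(["x", "y", "x", "y", "x", "x", "x", "x"], dtype=object)
        sample = np.array(["s1", "s1", "s2", "s2", "s3", "s4", "s5", "s6"], dtype=object)
        group = np.array(["a", "a", "a", "a", "b", "b", "b", "b"], dtype=object)
        comp = composition_by_sample(assignment, truth, sample, group)
        res = association_tests(comp, "g".replace("g", "G"), "y", min_nonzero=1)
        # group b has four samples, all with zero frequency of "y"
        assert res.n_nonzero_per_group["b"] == 0

    def test_two_group_anova_equals_t_test(self):
        from scipy.stats import ttest_ind

        rng = np.random.default_rng(5)
        a = rng.uniform(0.1, 0.5, 8)
        b = rng.uniform(0.2, 0.6, 8)
        comp = _composition_from_values({"a": a, "b": b})
        res = association_tests(comp, "g", "x")
        t = ttest_ind(a, b)
        assert res.p_anova == pytest.approx(t.pvalue, abs=1e-9)

    def test_pairwise_wilcoxon_holm_columns(self):
        rng = np.random.default_rng(6)
        comp = _composition_from_values(
            {g: rng.uniform(0.1, 0.9, 6) for g in ("a", "b", "c")}
        )
        res = association_tests(comp, "g", "x")
        assert len(res.pairwise) == 3
        assert np.all(res.pairwise["p_holm"] >= res.pairwise["p_raw"] - 1e-12)

    def test_single_group_rejected(self):
        comp = _composition_from_values({"a": [0.1, 0.2, 0.3, 0.4, 0.5]})
        with pytest.raises(CitegateError, match="2 groups"):
            association_tests(comp, "g", "x")

    def test_type1_error_calibrated(self):
        from citegate.validation import anova_type1_error

        res = anova_type1_error(seed=11, n_sims=400)
        assert abs(res["rate"] - 0.05) <= 0.03

    def test_group_shift_scenario_detected(self):
        import warnings

        from citegate.simulate import default_scenarios, simulate_dataset
        from citegate.workflow import run_classical_gating

        cfg = default_scenarios(seed=3)["group-shift"]
        ds = simulate_dataset(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            run = run_classical_gating(ds)
        comp = composition_by_sample(
            run.assignment, ds.truth_label, ds.sample_id, ds.group
        )
        res = association_tests(comp, "naive", "atypical_memory")
        assert res.eligible
        assert res.p_anova < 0.05
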