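"""TP/FP labelling, DE filter, per-marker SVM, MMD and ranking."""

import numpy as np
import pytest

from citegate.core import CitegateError
from citegate.selection import (
    MarkerScore,
    TPFPLabels,
    de_filter,
    label_tp_fp,
    mmd2_unbiased,
    rank_markers,
    svm_marker_score,
)

from conftest import make_dataset


def _labels(n_tp, n_fp):
    idx = np.arange(n_tp + n_fp)
    is_tp = np.zeros(n_tp + n_fp, dtype=bool)
    is_tp[:n_tp] = True
    return TPFPLabels("g", "t", idx, is_tp)


class TestLabelTPFP:
    def test_basic_split(self):
        assignment = np.array(["G", "G", "G", "ungated"], dtype=object)
        truth = np.array(["naive", "naive", "memory", "naive"], dtype=object)
        lab = label_tp_fp(assignment, truth, "G", "naive")
        assert lab.is_tp.tolist() == [True, True, False]
        assert (lab.n_tp, lab.n_fp) == (2, 1)

    def test_target_absent_from_gate_is_error(self):
        assignment = np.array(["G", "G"], dtype=object)
        truth = np.array(["memory", "memory"], dtype=object)
        with pytest.raises(CitegateError, match="absent"):
            label_tp_fp(assignment, truth, "G", "naive")

    def test_pure_gate_is_error(self):
        assignment = np.array(["G", "G"], dtype=object)
        truth = np.array(["naive", "naive"], dtype=object)
        with pytest.raises(CitegateError, match="pure"):
            label_tp_fp(assignment, truth, "G", "naive")

    def test_matches_bruteforce_on_random_instance(self):
        rng = np.random.default_rng(0)
        assignment = rng.choice(np.array(["G", "H", "ungated"], dtype=object), 1000)
        truth = rng.choice(np.array(["t", "o"], dtype=object), 1000)
        lab = label_tp_fp(assignment, truth, "G", "t")
        expect = [
            (i, truth[i] == "t")
            for i in range(1000)
            if assignment[i] == "G"
        ]
        assert lab.indices.tolist() == [i for i, _ in expect]
        assert lab.is_tp.tolist() == [tp for _, tp in expect]


class TestDEFilter:
    def test_rule_application_on_fold_change_and_p(self, rng):
        # marker 0: huge shift (passes); marker 1: modest shift (fails on FC)
        tp = np.column_stack([rng.poisson(200, 100), rng.poisson(30, 100)])
        fp = np.column_stack([rng.poisson(10, 100), rng.poisson(20, 100)])
        ds = make_dataset(np.vstack([tp, fp]).astype(float))
        res = de_filter(ds, _labels(100, 100))
        assert bool(res.loc["M0", "passed"])
        assert not bool(res.loc["M1", "passed"])
        assert res.loc["M1", "p_adj"] < 0.05  # fails on the FC rule alone

    def test_constant_marker_gets_p_one(self):
        vals = np.column_stack([np.full(20, 5.0), np.arange(20, dtype=float)])
        ds = make_dataset(vals)
        res = de_filter(ds, _labels(10, 10))
        assert res.loc["M0", "p_value"] == 1.0
        assert not bool(res.loc["M0", "passed"])

    def test_bh_adjustment_matches_stepup_oracle(self, rng):
        # Build markers with scattered signal, then compare the BH column
        # against an explicit step-up computation from the raw p-values.
        tp = rng.normal(0, 1, size=(30, 10)) + np.linspace(0, 3, 10)
        fp = rng.normal(0, 1, size=(30, 10))
        ds = make_dataset(np.abs(np.vstack([tp, fp])) * 10)
        res = de_filter(ds, _labels(30, 30))
        p = res["p_value"].to_numpy()
        m = len(p)
        order = np.argsort(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        np.testing.assert_allclose(res["p_adj"].to_numpy(), adj, atol=1e-12)

    def test_prenormalized_input_warns_plain_difference(self, rng):
        from citegate.core import NormalizationTag

        vals = rng.normal(size=(40, 2))
        ds = make_dataset(
            vals, normalization=NormalizationTag("clr", {"pseudocount": 1.0})
        )
        with pytest.warns(match="pre-normalized"):
            res = de_filter(ds, _labels(20, 20))
        tp_mean = vals[:20].mean(axis=0)
        fp_mean = vals[20:].mean(axis=0)
        np.testing.assert_allclose(res["log2fc"], tp_mean - fp_mean, atol=1e-12)


class TestSVMScore:
    def test_wide_separation_near_perfect_accuracy(self, rng):
        vals = np.concatenate([rng.normal(5, 1, 200), rng.normal(-5, 1, 200)])
        res = svm_marker_score(vals, _labels(200, 200), seed=0)
        assert res.accuracy >= 0.99
        # sanity against a 0-threshold oracle
        oracle_acc = np.mean((vals > 0) == np.r_[np.ones(200), np.zeros(200)].astype(bool))
        assert oracle_acc >= 0.99

    def test_same_distribution_chance_level(self, rng):
        vals = rng.normal(0, 1, 1000)
        res = svm_marker_score(vals, _labels(500, 500), seed=0)
        assert abs(res.accuracy - 0.5) <= 0.07

    def test_constant_values_flagged(self):
        vals = np.full(40, 3.0)
        with pytest.warns(match="constant"):
            res = svm_marker_score(vals, _labels(20, 20), seed=0)
        assert res.constant_input

    def test_f1_consistency_and_sensitivity_equals_recall(self, rng):
        vals = np.concatenate([rng.normal(1.5, 1, 60), rng.normal(-1.5, 1, 60)])
        res = svm_marker_score(vals, _labels(60, 60), seed=1)
        assert res.sensitivity == res.recall
        if res.precision + res.recall > 0:
            assert res.f1 == pytest.approx(
                2 * res.precision * res.recall / (res.precision + res.recall)
            )

    def test_too_few_cells_rejected(self, rng):
        vals = rng.normal(size=15)
        with pytest.raises(CitegateError, match="at least 10"):
            svm_marker_score(vals, _labels(5, 10), seed=0)


class TestMMD:
    def test_linear_kernel_hand_example(self):
        assert mmd2_unbiased([0, 1], [0, 1], kernel="linear") == pytest.approx(-0.5)

    def test_linear_kernel_point_mass_shift(self):
        assert mmd2_unbiased([0, 0, 0], [2, 2], kernel="linear") == pytest.approx(4.0)

    def test_symmetry_and_permutation_invariance(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(1, 1, size=60)
        a = mmd2_unbiased(x, y, kernel="rbf")
        assert mmd2_unbiased(y, x, kernel="rbf") == pytest.approx(a)
        assert mmd2_unbiased(rng.permutation(x), y, kernel="rbf") == pytest.approx(a)

    def test_identical_values_fall_back_to_unit_bandwidth(self):
        with pytest.warns(match="median bandwidth"):
            v = mmd2_unbiased([1.0, 1.0], [1.0, 1.0], kernel="rbf")
        assert v == pytest.approx(0.0)

    def test_linear_kernel_converges_to_squared_mean_gap(self, rng):
        # averaged over replicates: a single draw's Monte-Carlo error is
        # comparable to the tolerance
        vals = [
            mmd2_unbiased(
                rng.normal(1.0, 1.0, 2000), rng.normal(0.0, 1.0, 2000),
                kernel="linear",
            )
            for _ in range(10)
        ]
        assert np.mean(vals) == pytest.approx(1.0, abs=0.05)

    def test_rbf_median_unbiased_under_null(self):
        from citegate.validation import mmd_null_summary

        res = mmd_null_summary(seed=42, n_reps=60, n=200)
        assert abs(res["mean"]) <= 3 * res["se"]


class TestRankMarkers:
    def _score(self, marker, mmd2, f1=0.5, passed=True):
        return MarkerScore(
            marker=marker, log2fc=3.0 if passed else 0.5, p_adj=0.01,
            passed_de_filter=passed, f1=f1, mmd2=mmd2,
        )

    def test_mmd_primary_f1_tiebreak(self):
        scores = [
            self._score("A", 0.5, f1=0.2),
            self._score("B", 0.9, f1=0.1),
            self._score("C", 0.5, f1=0.8),
        ]
        sel = rank_markers(scores, set(), k=2)
        assert sel.selected == ["B", "C"]

    def test_single_passing_candidate_returned(self):
        scores = [self._score("A", 0.1), self._score("B", 0.9, passed=False)]
        sel = rank_markers(scores, set(), k=2)
        assert sel.selected == ["A"]

    def test_base_gate_markers_kept_and_annotated(self):
        scores = [self._score("CD24", 0.9), self._score("CD20", 0.5)]
        sel = rank_markers(scores, {"CD24"}, k=2)
        assert sel.selected == ["CD24", "CD20"]
        assert sel.already_in_base == ["CD24"]

    def test_no_survivor_fallback_warns_and_ranks_all(self):
        scores = [self._score("A", 0.3, passed=False), self._score("B", 0.6, passed=False)]
        with pytest.warns(match="DE filter"):
            sel = rank_markers(scores, set(), k=1)
        assert sel.selected == ["B"] and sel.de_fallback

    def test_k_below_one_rejected(self):
        with pytest.raises(CitegateError, match="k"):
            rank_markers([self._score("A", 0.1)], set(), k=0)
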