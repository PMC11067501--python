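"""Gate atoms, panels, threshold estimation and config parsing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from citegate.core import CitegateError
from citegate.gating import (
    GateDefinition,
    GateNode,
    GatePanel,
    Interval,
    PolygonRegion,
    UnimodalDensityError,
    apply_gate,
    apply_panel,
    estimate_threshold,
    points_in_polygon,
)

from conftest import make_normalized


UNIT_SQUARE = ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0))


class TestAtoms:
    def test_interval_validation(self):
        with pytest.raises(CitegateError, match="low"):
            Interval("CD19", low=2.0, high=1.0)

    def test_polygon_validation(self):
        with pytest.raises(CitegateError, match="3 vertices"):
            PolygonRegion("a", "b", ((0, 0), (1, 1)))
        with pytest.raises(CitegateError, match="zero area"):
            PolygonRegion("a", "b", ((0, 0), (1, 1), (2, 2)))

    @pytest.mark.parametrize(
        "point,expected",
        [
            ((0.5, 0.5), True),
            ((2.0, 2.0), False),
            ((0.0, 0.0), True),   # vertex: boundary inclusive
            ((0.5, 0.0), True),   # edge: boundary inclusive
            ((-0.1, 0.5), False),
        ],
    )
    def test_point_in_unit_square(self, point, expected):
        assert points_in_polygon(
            np.array([point[0]]), np.array([point[1]]), UNIT_SQUARE
        )[0] == expected

    def test_closed_polygon_duplicate_vertex_harmless(self):
        closed = UNIT_SQUARE + (UNIT_SQUARE[0],)
        res = points_in_polygon(np.array([0.5, 5.0]), np.array([0.5, 5.0]), closed)
        assert res.tolist() == [True, False]

    def test_concave_polygon_even_odd(self):
        # "C" shape: the notch is outside
        verts = ((0, 0), (3, 0), (3, 1), (1, 1), (1, 2), (3, 2), (3, 3), (0, 3))
        xs = np.array([2.0, 0.5])
        ys = np.array([1.5, 1.5])
        assert points_in_polygon(xs, ys, verts).tolist() == [False, True]


class TestApplyGate:
    def _ds(self):
        return make_normalized(
            [[2.0, 0.1, 0.1], [2.0, 0.1, 3.0], [0.1, 2.0, 0.1]],
            markers=["CD19", "CD27", "IgD"],
        )

    def test_dnb_style_conjunction(self):
        ds = self._ds()
        dnb = GateDefinition(
            "dnb",
            (
                Interval("CD19", low=1.0),
                Interval("CD27", high=1.0),
                Interval("IgD", high=1.0),
            ),
        )
        assert apply_gate(ds, dnb).tolist() == [True, False, False]

    def test_missing_marker_named_in_error(self):
        ds = self._ds()
        with pytest.raises(CitegateError, match="CD38"):
            apply_gate(ds, GateDefinition("g", (Interval("CD38", low=0.0),)))

    def test_polygon_gate_membership(self):
        ds = make_normalized([[0.5, 0.5], [2.0, 2.0]], markers=["a", "b"])
        gate = GateDefinition("poly", (PolygonRegion("a", "b", UNIT_SQUARE),))
        assert apply_gate(ds, gate).tolist() == [True, False]

    def test_empty_dataset_gives_empty_membership(self):
        ds = make_normalized(np.empty((0, 1)), markers=["a"])
        assert apply_gate(ds, GateDefinition("g", (Interval("a", low=0),))).size == 0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_per_cell_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(30, 3))
        ds = make_normalized(vals, markers=["x", "y", "z"])
        gate = GateDefinition(
            "g",
            (
                Interval("x", low=-0.5, high=1.0),
                Interval("z", high=0.3, high_inclusive=False),
            ),
        )
        got = apply_gate(ds, gate)
        for i in range(30):
            expect = (-0.5 <= vals[i, 0] <= 1.0) and (vals[i, 2] < 0.3)
            assert got[i] == expect

    def test_order_invariance_under_permutation(self, rng):
        vals = rng.normal(size=(50, 2))
        ds = make_normalized(vals, markers=["x", "y"])
        gate = GateDefinition("g", (Interval("x", low=0.0),))
        perm = rng.permutation(50)
        ds_perm = make_normalized(vals[perm], markers=["x", "y"])
        assert np.array_equal(apply_gate(ds, gate)[perm], apply_gate(ds_perm, gate))

    def test_tightening_interval_is_monotone(self, rng):
        vals = rng.normal(size=(200, 1))
        ds = make_normalized(vals, markers=["x"])
        loose = apply_gate(ds, GateDefinition("g", (Interval("x", low=-1.0, high=1.0),)))
        tight = apply_gate(ds, GateDefinition("g", (Interval("x", low=-0.5, high=0.8),)))
        assert not np.any(tight & ~loose)


class TestPanel:
    def _panel(self):
        root = GateNode(
            gate=GateDefinition("root", (Interval("CD19", low=1.0),)),
            children=[
                GateNode(
                    gate=GateDefinition("naive", (Interval("CD27", high=1.0),)),
                    label="naive",
                ),
                GateNode(
                    gate=GateDefinition("memory", (Interval("CD27", low=1.0, low_inclusive=False),)),
                    label="memory",
                ),
            ],
        )
        return GatePanel("p", root)

    def test_assignment_counts_partition_all_cells(self, rng):
        vals = rng.uniform(0, 3, size=(100, 2))
        ds = make_normalized(vals, markers=["CD19", "CD27"])
        res = apply_panel(ds, self._panel())
        assert sum(res.counts().values()) == 100

    def test_failing_root_is_ungated_regardless_of_children(self):
        ds = make_normalized([[0.0, 0.0]], markers=["CD19", "CD27"])
        res = apply_panel(ds, self._panel())
        assert res.assignment[0] == "ungated"

    def test_overlapping_siblings_first_declared_wins_and_reported(self):
        root = GateNode(
            gate=GateDefinition("root"),
            children=[
                GateNode(GateDefinition("a", (Interval("x", low=0.0),)), label="A"),
                GateNode(GateDefinition("b", (Interval("x", low=-1.0),)), label="B"),
            ],
        )
        ds = make_normalized([[0.5], [-0.5]], markers=["x"])
        with pytest.warns(match="overlap"):
            res = apply_panel(ds, GatePanel("p", root))
        assert res.assignment.tolist() == ["A", "B"]
        assert res.sibling_overlap_count == 1

    def test_cyclic_tree_rejected(self):
        node = GateNode(GateDefinition("g"))
        node.children = [node]
        with pytest.raises(CitegateError, match="cyclic"):
            apply_panel(make_normalized([[1.0]], markers=["x"]), GatePanel("p", node))


class TestEstimateThreshold:
    def test_constant_reference_returns_constant(self):
        ds = make_normalized([[2.0]] * 25, markers=["m"])
        thr = estimate_threshold(ds, "m", np.ones(25, dtype=bool), mode="quantile")
        assert thr == 2.0

    def test_standard_normal_reference_matches_analytic_quantile(self, rng):
        vals = rng.standard_normal((20000, 1))
        ds = make_normalized(vals, markers=["m"])
        thr = estimate_threshold(
            ds, "m", np.ones(20000, dtype=bool), mode="quantile", q=0.975
        )
        assert thr == pytest.approx(1.96, abs=0.08)

    def test_valley_between_two_gaussian_modes(self, rng):
        vals = np.concatenate(
            [rng.normal(0, 1, 3000), rng.normal(6, 1, 3000)]
        )[:, None]
        ds = make_normalized(vals, markers=["m"])
        thr = estimate_threshold(ds, "m", mode="valley")
        # oracle: dense grid search of the KDE minimum between the modes
        from scipy.stats import gaussian_kde

        kde = gaussian_kde(vals.ravel())
        grid = np.linspace(1.0, 5.0, 4000)
        oracle = grid[np.argmin(kde(grid))]
        assert thr == pytest.approx(oracle, abs=0.1)
        assert 2.5 <= thr <= 3.5

    def test_unimodal_density_instructs_quantile_mode(self, rng):
        vals = rng.normal(0, 1, (3000, 1))
        ds = make_normalized(vals, markers=["m"])
        with pytest.raises(UnimodalDensityError, match="quantile"):
            estimate_threshold(ds, "m", mode="valley")

    def test_small_reference_warns(self):
        ds = make_normalized(np.arange(30, dtype=float)[:, None], markers=["m"])
        ref = np.zeros(30, dtype=bool)
        ref[:5] = True
        with pytest.warns(match="only 5 cells"):
            estimate_threshold(ds, "m", ref, mode="quantile")


class TestConfig:
    def test_yaml_round_trip_with_auto_threshold(self, tmp_path, rng):
        from citegate.config import load_gate_config

        cfg = tmp_path / "gates.yaml"
        cfg.write_text(
            """
gates:
  - name: tcells
    atoms:
      - {marker: CD19, op: le, value: 0.0}
  - name: bcells
    atoms:
      - {marker: CD19, op: gt, value: "auto(quantile=0.9, reference=tcells)"}
panel:
  name: mini
  root:
    gate: bcells
    children:
      - {gate: tcells, label: weird}
"""
        )
        neg = rng.normal(-2, 0.1, 50)
        pos = rng.normal(3, 0.1, 50)
        ds = make_normalized(
            np.concatenate([neg, pos])[:, None], markers=["CD19"]
        )
        gates, panel = load_gate_config(cfg, dataset=ds)
        assert set(gates) == {"tcells", "bcells"}
        thr = gates["bcells"].atoms[0].low
        assert -2.0 < thr < 0.0  # 0.9-quantile of the negative cells
        assert panel is not None and panel.leaf_labels() == ["weird"]

    def test_polygon_atoms_serialize_and_reload(self, tmp_path):
        from citegate.config import load_gate_config, save_gate_config

        gate = GateDefinition("poly", (PolygonRegion("a", "b", UNIT_SQUARE),))
        p = tmp_path / "g.yaml"
        save_gate_config([gate], p)
        gates, _ = load_gate_config(p)
        atom = gates["poly"].atoms[0]
        assert isinstance(atom, PolygonRegion)
        assert atom.vertices == UNIT_SQUARE
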