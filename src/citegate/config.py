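"""Gate and panel configuration files (YAML or JSON).

Schema::

    gates:
      - name: cd19_pos
        atoms:
          - {marker: CD19, op: gt, value: 1.2}
          - {marker: CD27, op: between, low: 0.0, high: 2.0}
          - {marker: IgD, op: gt, value: "auto(quantile=0.995, reference=tcells)"}
          - {op: polygon, marker_x: CD20, marker_y: CD21,
             vertices: [[0, 0], [1, 0], [1, 1], [0, 1]]}
    panel:
      name: classical
      root:
        gate: cd19_pos
        children:
          - {gate: naive, label: naive}

``auto(...)`` thresholds are resolved at load time against a dataset: the
referenced gate (defined earlier in the same file) supplies the negative
reference cells and the stated quantile is taken on the atom's marker.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import yaml

from .core import CellDataset, CitegateError
from .gating import (
    GateDefinition,
    GateNode,
    GatePanel,
    Interval,
    PolygonRegion,
    apply_gate,
    estimate_threshold,
)

__all__ = ["load_gate_config", "panel_to_dict", "gate_to_dict", "save_gate_config"]

_AUTO_RE = re.compile(
    r"auto\(\s*quantile\s*=\s*(?P<q>[0-9.eE+-]+)\s*,\s*reference\s*=\s*(?P<ref>[^)\s]+)\s*\)"
)


def _resolve_value(value, marker, dataset, defined_gates):
    if isinstance(value, (int, float)):
        return float(value)
    m = _AUTO_RE.fullmatch(str(value).strip())
    if not m:
        raise CitegateError(f"cannot parse threshold value {value!r}")
    if dataset is None:
        raise CitegateError(
            "auto(...) thresholds require a dataset at config-load time"
        )
    ref_name = m.group("ref")
    if ref_name not in defined_gates:
        raise CitegateError(
            f"auto threshold references unknown gate {ref_name!r} "
            "(gates are resolved in file order)"
        )
    ref_mask = apply_gate(dataset, defined_gates[ref_name])
    return estimate_threshold(
        dataset, marker, negative_reference=ref_mask,
        mode="quantile", q=float(m.group("q")),
    )


def _parse_atom(atom_spec: dict, dataset, defined_gates):
    op = atom_spec.get("op")
    if op == "polygon":
        return PolygonRegion(
            marker_x=atom_spec["marker_x"],
            marker_y=atom_spec["marker_y"],
            vertices=tuple((float(a), float(b)) for a, b in atom_spec["vertices"]),
        )
    marker = atom_spec.get("marker")
    if marker is None:
        raise CitegateError(f"atom {atom_spec!r} lacks a marker")
    if op in {"gt", "ge"}:
        low = _resolve_value(atom_spec["value"], marker, dataset, defined_gates)
        return Interval(marker, low=low, low_inclusive=(op == "ge"))
    if op in {"lt", "le"}:
        high = _resolve_value(atom_spec["value"], marker, dataset, defined_gates)
        return Interval(marker, high=high, high_inclusive=(op == "le"))
    if op == "between":
        return Interval(
            marker,
            low=_resolve_value(atom_spec["low"], marker, dataset, defined_gates),
            high=_resolve_value(atom_spec["high"], marker, dataset, defined_gates),
            low_inclusive=bool(atom_spec.get("low_inclusive", True)),
            high_inclusive=bool(atom_spec.get("high_inclusive", True)),
        )
    raise CitegateError(f"unknown atom op {op!r}")


def _parse_node(spec: dict, gates: dict[str, GateDefinition]) -> GateNode:
    gate_name = spec.get("gate")
    if gate_name not in gates:
        raise CitegateError(f"panel references undefined gate {gate_name!r}")
    children = [_parse_node(c, gates) for c in spec.get("children", [])]
    return GateNode(gate=gates[gate_name], children=children, label=spec.get("label"))


def load_gate_config(
    path, dataset: Optional[CellDataset] = None
) -> tuple[dict[str, GateDefinition], Optional[GatePanel]]:
    """Load gates (and optionally a panel) from a YAML/JSON config file.

    Returns ``(gates, panel)``; panel is None when the file defines only
    standalone gates. A dataset is required whenever the file uses
    ``auto(...)`` thresholds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gate config not found: {path}")
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "gates" not in doc:
        raise CitegateError(f"config {path} must be a mapping with a 'gates' list")
    gates: dict[str, GateDefinition] = {}
    for gspec in doc["gates"]:
        name = gspec.get("name")
        if not name:
            raise CitegateError("every gate needs a name")
        if name in gates:
            raise CitegateError(f"duplicate gate name {name!r}")
        atoms = tuple(
            _parse_atom(a, dataset, gates) for a in gspec.get("atoms", [])
        )
        gates[name] = GateDefinition(name, atoms)
    panel = None
    if "panel" in doc:
        pspec = doc["panel"]
        panel = GatePanel(
            name=pspec.get("name", "panel"), root=_parse_node(pspec["root"], gates)
        )
    return gates, panel


# ---------------------------------------------------------------------------
# serialization (refined gates round-trip through this schema)


def _atom_to_dict(atom) -> dict:
    if isinstance(atom, PolygonRegion):
        return {
            "op": "polygon",
            "marker_x": atom.marker_x,
            "marker_y": atom.marker_y,
            "vertices": [[float(a), float(b)] for a, b in atom.vertices],
        }
    d: dict = {"marker": atom.marker}
    import math

    if math.isinf(atom.low) and not math.isinf(atom.high):
        d.update(op="le" if atom.high_inclusive else "lt", value=atom.high)
    elif math.isinf(atom.high) and not math.isinf(atom.low):
        d.update(op="ge" if atom.low_inclusive else "gt", value=atom.low)
    else:
        d.update(
            op="between", low=atom.low, high=atom.high,
            low_inclusive=atom.low_inclusive, high_inclusive=atom.high_inclusive,
        )
    return d


def gate_to_dict(gate: GateDefinition) -> dict:
    return {"name": gate.name, "atoms": [_atom_to_dict(a) for a in gate.atoms]}


def _node_to_dict(node: GateNode) -> dict:
    d: dict = {"gate": node.gate.name}
    if node.label:
        d["label"] = node.label
    if node.children:
        d["children"] = [_node_to_dict(c) for c in node.children]
    return d


def panel_to_dict(panel: GatePanel) -> dict:
    gates: dict[str, GateDefinition] = {}

    def collect(node: GateNode):
        gates[node.gate.name] = node.gate
        for c in node.children:
            collect(c)

    collect(panel.root)
    return {
        "gates": [gate_to_dict(g) for g in gates.values()],
        "panel": {"name": panel.name, "root": _node_to_dict(panel.root)},
    }


def save_gate_config(doc_or_gates, path) -> None:
    """Write gates/panel back to YAML or JSON, matching the file suffix."""
    if isinstance(doc_or_gates, GatePanel):
        doc = panel_to_dict(doc_or_gates)
    elif isinstance(doc_or_gates, dict) and "gates" in doc_or_gates:
        doc = doc_or_gates
    else:
        doc = {"gates": [gate_to_dict(g) for g in doc_or_gates]}
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=True))
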