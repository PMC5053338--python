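"""Annotated decision tree over the pathway hierarchy.

Each analysed parent contributes edge annotations (the decision
percentage of every child within that parent — local per parent, no
cross-level renormalization) and node annotations (DC value and
direction).  Export renders activated nodes red, inhibited nodes blue
and neutral nodes grey, with one-decimal percentage edge labels, either
as Graphviz DOT text or as a nested JSON structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from .hierarchy import PathwayHierarchy

__all__ = ["NodeAnnotation", "DecisionTree", "build_decision_tree", "export_tree"]

_COLORS = {"activated": "red", "inhibited": "blue", "neutral": "grey"}


@dataclass(frozen=True)
class NodeAnnotation:
    dc: float
    direction: str
    decision_percentage: float


class DecisionTree:
    """Pathway hierarchy plus per-node decision annotations."""

    def __init__(self, hierarchy: PathwayHierarchy,
                 annotations: dict[str, NodeAnnotation]):
        for node_id in annotations:
            if node_id not in hierarchy:
                raise ValueError(f"annotated node {node_id!r} not in hierarchy")
        self.hierarchy = hierarchy
        self.annotations = dict(annotations)


def build_decision_tree(
    hierarchy: PathwayHierarchy, report: pd.DataFrame
) -> DecisionTree:
    """Assemble the annotated tree from a decision report.

    ``report`` needs columns parent_id, child_id, dc, direction and
    decision_percentage (the layout written by the analysis pipeline).
    Every (parent, child) pair must be an actual hierarchy edge.
    """
    annotations: dict[str, NodeAnnotation] = {}
    for row in report.itertuples(index=False):
        parent, child = str(row.parent_id), str(row.child_id)
        if parent not in hierarchy:
            raise ValueError(f"report parent {parent!r} not in hierarchy")
        if child not in hierarchy or hierarchy.node(child).parent_id != parent:
            raise ValueError(
                f"report child {child!r} is not a child of {parent!r} in the hierarchy"
            )
        annotations[child] = NodeAnnotation(
            dc=float(row.dc),
            direction=str(row.direction),
            decision_percentage=float(row.decision_percentage),
        )
    return DecisionTree(hierarchy, annotations)


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


def export_tree(tree: DecisionTree, format: str = "dot") -> str:
    """Serialize the annotated tree to "dot" or "json" text."""
    if format == "dot":
        return _to_dot(tree)
    if format == "json":
        return _to_json(tree)
    raise ValueError(f"unknown export format {format!r}; expected 'dot' or 'json'")


def _to_dot(tree: DecisionTree) -> str:
    lines = ["digraph decision_tree {", "  rankdir=LR;", '  node [shape=box];']
    for node in tree.hierarchy:
        ann = tree.annotations.get(node.id)
        label = _dot_escape(node.name)
        if ann is None:
            lines.append(f'  "{_dot_escape(node.id)}" [label="{label}"];')
        else:
            lines.append(
                f'  "{_dot_escape(node.id)}" [label="{label}\\nDC={ann.dc:.3f}", '
                f'color={_COLORS.get(ann.direction, "grey")}];'
            )
    for node in tree.hierarchy:
        for child in tree.hierarchy.children(node.id):
            ann = tree.annotations.get(child)
            attrs = ""
            if ann is not None:
                attrs = f' [label="{ann.decision_percentage:.1f}%"]'
            lines.append(
                f'  "{_dot_escape(node.id)}" -> "{_dot_escape(child)}"{attrs};'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"


def _node_json(tree: DecisionTree, node_id: str) -> dict:
    node = tree.hierarchy.node(node_id)
    ann = tree.annotations.get(node_id)
    return {
        "id": node.id,
        "name": node.name,
        "dc": ann.dc if ann else None,
        "direction": ann.direction if ann else None,
        "dp": ann.decision_percentage if ann else None,
        "children": [
            _node_json(tree, child) for child in tree.hierarchy.children(node_id)
        ],
    }


def _to_json(tree: DecisionTree) -> str:
    roots = [_node_json(tree, root) for root in tree.hierarchy.roots()]
    return json.dumps({"roots": roots}, indent=2)
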