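"""Three-level pathway hierarchy (category -> subcategory -> secondary).

Mirrors the KEGG organisation used throughout: top-level categories
(e.g. "Metabolism"), subcategories (e.g. "Lipid Metabolism") and
secondary pathways (e.g. "Fatty acid metabolism").  Each non-category
node has exactly one parent exactly one level above it, which also makes
cycles structurally impossible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

__all__ = ["PathwayNode", "PathwayHierarchy", "LEVELS"]

LEVELS = ("category", "subcategory", "secondary")
_LEVEL_RANK = {name: i for i, name in enumerate(LEVELS)}


@dataclass(frozen=True)
class PathwayNode:
    """One pathway in the hierarchy.

    ``parent_id`` is the empty string exactly for category nodes.
    """

    id: str
    name: str
    level: str
    parent_id: str = ""


class PathwayHierarchy:
    """Validated collection of :class:`PathwayNode`.

    Raises ``ValueError`` on duplicate ids, unknown levels, orphan
    parents, level skips (e.g. a secondary pathway attached directly to
    a category) and categories carrying a parent.
    """

    def __init__(self, nodes: Iterable[PathwayNode]):
        self._nodes: dict[str, PathwayNode] = {}
        for node in nodes:
            if node.id in self._nodes:
                raise ValueError(f"duplicate pathway id {node.id!r}")
            if node.level not in _LEVEL_RANK:
                raise ValueError(
                    f"node {node.id!r}: unknown level {node.level!r}; "
                    f"expected one of {LEVELS}"
                )
            if (node.level == "category") != (node.parent_id == ""):
                raise ValueError(
                    f"node {node.id!r}: parent_id must be empty exactly for "
                    "category nodes"
                )
            self._nodes[node.id] = node
        self._children: dict[str, list[str]] = {nid: [] for nid in self._nodes}
        for node in self._nodes.values():
            if node.level == "category":
                continue
            parent = self._nodes.get(node.parent_id)
            if parent is None:
                raise ValueError(
                    f"node {node.id!r}: parent {node.parent_id!r} does not exist"
                )
            if _LEVEL_RANK[node.level] != _LEVEL_RANK[parent.level] + 1:
                raise ValueError(
                    f"node {node.id!r} ({node.level}) cannot attach to "
                    f"{parent.id!r} ({parent.level}): parent must be exactly "
                    "one level above"
                )
            self._children[parent.id].append(node.id)

    def __len__(self) -> int:
        return len(self._nodes)

    def __iter__(self) -> Iterator[PathwayNode]:
        return iter(self._nodes.values())

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._nodes

    def node(self, node_id: str) -> PathwayNode:
        return self._nodes[node_id]

    def children(self, node_id: str) -> list[str]:
        """Ids of the direct children of ``node_id`` (insertion order)."""
        return list(self._children[node_id])

    def roots(self) -> list[str]:
        return [n.id for n in self._nodes.values() if n.level == "category"]

    def parents_with_children(self) -> list[str]:
        """Ids of all nodes that have at least one child."""
        return [nid for nid, kids in self._children.items() if kids]
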