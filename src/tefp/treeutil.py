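"""Minimal rooted-tree structure shared by the simulator and the NJ builder."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional


@dataclass
class Node:
    """A node in a rooted tree with branch lengths.

    ``length`` is the length of the branch above this node (toward the
    parent); it is 0.0 for the root.
    """

    name: str = ""
    length: float = 0.0
    children: list["Node"] = field(default_factory=list)
    parent: Optional["Node"] = None

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["Node"]:
        if self.is_leaf:
            yield self
        else:
            for c in self.children:
                yield from c.leaves()

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def preorder(self) -> Iterator["Node"]:
        yield self
        for c in self.children:
            yield from c.preorder()

    def newick(self, include_lengths: bool = True) -> str:
        return self._newick_part(include_lengths) + ";"

    def _newick_part(self, lengths: bool) -> str:
        if self.is_leaf:
            body = self.name
        else:
            inner = ",".join(c._newick_part(lengths) for c in self.children)
            body = f"({inner}){self.name}"
        if lengths and self.parent is not None:
            body += f":{self.length:.10g}"
        return body


def tip_distances(root: Node) -> dict[tuple[str, str], float]:
    """Sum-of-branch-length distances between every pair of leaves."""
    dist: dict[tuple[str, str], float] = {}

    def walk(node: Node) -> dict[str, float]:
        if node.is_leaf:
            return {node.name: 0.0}
        below: dict[str, float] = {}
        child_maps = []
        for c in node.children:
            m = {k: v + c.length for k, v in walk(c).items()}
            child_maps.append(m)
        for i in range(len(child_maps)):
            for j in range(i + 1, len(child_maps)):
                for a, da in child_maps[i].items():
                    for b, db in child_maps[j].items():
                        key = (a, b) if a < b else (b, a)
                        dist[key] = da + db
            below.update(child_maps[i])
        return below

    walk(root)
    return dist
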