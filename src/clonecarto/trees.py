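"""Rooted clone trees.

A :class:`CloneTree` is a rooted tree whose root represents a cell with no
genetic alterations. Every node carries the set of events acquired on the
branch leading into it; the branch length is the number of those events.
Taxa (detected subclones, or single-cell clones with cell counts) may sit at
leaves or at internal nodes — an ancestral population detected in a sample is
a taxon on an internal node.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Optional

from .errors import ValidationError


class CloneNode:
    __slots__ = (
        "node_id", "events", "parent", "children", "name",
        "fractions", "extant", "timepoint", "cell_count", "_genotype",
    )

    def __init__(self, node_id: str, events: Iterable[str] = (), parent: "CloneNode | None" = None):
        self.node_id = node_id
        self.events: frozenset[str] = frozenset(events)
        self.parent = parent
        self.children: list[CloneNode] = []
        #: taxon label; None for purely inferred internal nodes
        self.name: Optional[str] = None
        #: per-sample cumulative fraction of cells carrying this genotype
        self.fractions: dict[str, float] = {}
        #: per-sample extant (non-superseded) fraction
        self.extant: dict[str, float] = {}
        self.timepoint: Optional[str] = None
        self.cell_count: Optional[int] = None
        self._genotype: Optional[frozenset[str]] = None

    @property
    def branch_length(self) -> int:
        return len(self.events)

    @property
    def genotype(self) -> frozenset[str]:
        """Union of all events on the path from the root to this node."""
        if self._genotype is None:
            if self.parent is None:
                self._genotype = self.events
            else:
                self._genotype = self.parent.genotype | self.events
        return self._genotype

    @property
    def is_taxon(self) -> bool:
        return self.name is not None

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        label = self.name or self.node_id
        return f"CloneNode({label}, +{len(self.events)} events)"


class CloneTree:
    """Rooted phylogeny of subclones with event-count branch lengths."""

    def __init__(self):
        self.root = CloneNode("root")
        self._counter = 0

    # -- construction ---------------------------------------------------
    def add_child(self, parent: CloneNode, events: Iterable[str] = (),
                  name: Optional[str] = None) -> CloneNode:
        self._counter += 1
        node = CloneNode(f"n{self._counter}", events, parent)
        node.name = name
        parent.children.append(node)
        return node

    # -- traversal ------------------------------------------------------
    def nodes(self) -> Iterator[CloneNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def taxa(self) -> list[CloneNode]:
        return [n for n in self.nodes() if n.is_taxon]

    def find_taxon(self, name: str) -> CloneNode:
        for node in self.nodes():
            if node.name == name:
                return node
        raise ValidationError(f"taxon {name!r} not in tree")

    # -- distances ------------------------------------------------------
    def root_path(self, node: CloneNode) -> list[CloneNode]:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent
        return path[::-1]

    def depth(self, node: CloneNode) -> int:
        """Branch-length distance from the root to ``node``."""
        return sum(n.branch_length for n in self.root_path(node)[1:])

    def distance(self, a: CloneNode, b: CloneNode) -> int:
        anc = self.mrca([a, b])
        return self.depth(a) + self.depth(b) - 2 * self.depth(anc)

    def mrca(self, nodes: list[CloneNode]) -> CloneNode:
        if not nodes:
            raise ValidationError("mrca of an empty node set is undefined")
        paths = [self.root_path(n) for n in nodes]
        common = None
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                common = level[0]
            else:
                break
        return common if common is not None else self.root

    def is_ancestor(self, anc: CloneNode, node: CloneNode) -> bool:
        """True if ``anc`` lies on the root path of ``node`` (including node itself)."""
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    def total_branch_length(self) -> int:
        return sum(n.branch_length for n in self.nodes() if n is not self.root)

    # -- comparison & export --------------------------------------------
    def clusters(self) -> set[frozenset[str]]:
        """Taxon clusters (one per branch): all taxa at or below each non-root node."""
        out: set[frozenset[str]] = set()

        def collect(node: CloneNode) -> set[str]:
            taxa = {node.name} if node.is_taxon else set()
            for child in node.children:
                taxa |= collect(child)
            if node is not self.root and taxa:
                out.add(frozenset(taxa))
            return taxa

        collect(self.root)
        return out

    def newick(self, annotate: Optional[Callable[[CloneNode], str]] = None) -> str:
        def label(node: CloneNode) -> str:
            base = node.name or ""
            if annotate is not None and node.is_taxon:
                base += annotate(node)
            return base

        def render(node: CloneNode) -> str:
            if node.children:
                inner = ",".join(sorted(render(c) for c in node.children))
                return f"({inner}){label(node)}:{node.branch_length}"
            return f"{label(node)}:{node.branch_length}"

        if not self.root.children:
            return f"{label(self.root) or 'root'};"
        inner = ",".join(sorted(render(c) for c in self.root.children))
        return f"({inner}){label(self.root) or 'root'};"


def rooted_rf_distance(a: CloneTree, b: CloneTree) -> int:
    """Robinson–Foulds distance between two rooted, taxon-labeled clone trees.

    Computed as the symmetric difference of the trees' taxon clusters, where
    internal taxa contribute to the clusters of every branch above them.
    Identical labeled topologies give 0.
    """
    ca, cb = a.clusters(), b.clusters()
    return len(ca ^ cb)
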