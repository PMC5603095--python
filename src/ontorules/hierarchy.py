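"""IS-A concept hierarchies: ingestion, sanitization, and closure queries.

Medical terminologies assembled from multiple source vocabularies routinely
contain self-loops, duplicate assertions, and outright cycles.  Rule
learning over value hierarchies requires a clean rooted DAG, so
:func:`sanitize` repairs a raw parent-child edge list deterministically and
keeps an audit trail of every deleted edge.

Cycle repair follows the principle of breaking the links that point back to
concepts higher in the hierarchy: a depth-first traversal from the roots
(lexicographic order throughout) deletes every back edge it meets, i.e. any
edge whose head is already on the current DFS path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx


class HierarchyError(ValueError):
    pass


@dataclass
class RemovedEdge:
    parent: str
    child: str
    reason: str  # self_loop | duplicate | cycle_break


@dataclass
class EdgeList:
    """Raw (parent, child) pairs in file order, plus optional display names."""

    pairs: list
    labels: dict = field(default_factory=dict)


def load_edge_list(source) -> EdgeList:
    """Read a hierarchy from a TSV edge list or a minimal OBO file.

    TSV: one ``parent<TAB>child`` pair per line, ``#`` comments allowed.
    OBO: ``[Term]`` stanzas with ``id:``, ``name:`` and ``is_a:`` tags; a
    ``child is_a parent`` assertion is emitted as ``(parent, child)``.
    """
    path = str(source)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    stripped = text.lstrip()
    if path.endswith(".obo") or stripped.startswith("format-version") or stripped.startswith("[Term]"):
        return _load_obo(path)
    return _load_tsv(path, text)


def _load_tsv(path: str, text: str) -> EdgeList:
    pairs = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2 or not fields[0] or not fields[1]:
            raise HierarchyError(f"{path}: malformed edge at line {lineno}: {line!r}")
        pairs.append((fields[0], fields[1]))
    if not pairs:
        raise HierarchyError(f"{path}: no edges found")
    return EdgeList(pairs=pairs)


def _load_obo(path: str) -> EdgeList:
    import obonet

    graph = obonet.read_obo(path, ignore_obsolete=True)
    pairs = []
    labels = {}
    for node, data in graph.nodes(data=True):
        if "name" in data:
            labels[node] = data["name"]
    # obonet stores `child is_a parent` as an edge child -> parent.
    for child, parent, key in graph.edges(keys=True):
        if key == "is_a":
            pairs.append((parent, child))
    if not pairs:
        raise HierarchyError(f"{path}: no is_a relationships found")
    return EdgeList(pairs=pairs, labels=labels)


class Hierarchy:
    """A sanitized rooted DAG of concept nodes.

    ``depth`` is the minimum edge distance from any root, so for every kept
    edge ``(u, v)``: ``depth[v] <= depth[u] + 1``.
    """

    def __init__(self, edges: Iterable, labels: Optional[dict] = None,
                 removed_edges: Optional[list] = None):
        self.children: dict = {}
        self.parents: dict = {}
        for parent, child in edges:
            self.children.setdefault(parent, [])
            self.children.setdefault(child, [])
            self.parents.setdefault(parent, [])
            self.parents.setdefault(child, [])
            self.children[parent].append(child)
            self.parents[child].append(parent)
        self.labels = dict(labels or {})
        self.removed_edges = list(removed_edges or [])
        self.nodes = frozenset(self.children)
        self.roots = tuple(sorted(n for n in self.nodes if not self.parents[n]))
        if self.nodes and not self.roots:
            raise HierarchyError("hierarchy has no root (every node has a parent)")
        self.depth = self._compute_depths()
        self._closure_cache: dict = {}

    # -- construction helpers ------------------------------------------------

    def _compute_depths(self) -> dict:
        depth = {r: 0 for r in self.roots}
        frontier = list(self.roots)
        while frontier:
            nxt = []
            for u in frontier:
                for v in self.children[u]:
                    if v not in depth or depth[v] > depth[u] + 1:
                        depth[v] = depth[u] + 1
                        nxt.append(v)
            frontier = nxt
        unreachable = self.nodes - set(depth)
        if unreachable:
            raise HierarchyError(f"nodes unreachable from any root: {sorted(unreachable)[:5]}")
        return depth

    def edges(self) -> list:
        return [(u, v) for u in sorted(self.children) for v in self.children[u]]

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    # -- queries ---------------------------------------------------------------

    def _require(self, node: str) -> None:
        if node not in self.nodes:
            raise HierarchyError(f"unknown node {node!r}")

    def ancestors(self, node: str) -> frozenset:
        """All transitive parents of ``node`` (multi-parent aware), excluding it."""
        self._require(node)
        seen = set()
        stack = list(self.parents[node])
        while stack:
            u = stack.pop()
            if u not in seen:
                seen.add(u)
                stack.extend(self.parents[u])
        return frozenset(seen)

    def descendants(self, node: str) -> frozenset:
        self._require(node)
        seen = set()
        stack = list(self.children[node])
        while stack:
            u = stack.pop()
            if u not in seen:
                seen.add(u)
                stack.extend(self.children[u])
        return frozenset(seen)

    def closure(self, node_set: Iterable) -> frozenset:
        """Descendant-or-self set: the match extent of a generalized condition."""
        result = set()
        for node in node_set:
            cached = self._closure_cache.get(node)
            if cached is None:
                cached = frozenset({node} | self.descendants(node))
                self._closure_cache[node] = cached
            result |= cached
        return frozenset(result)

    def leaves(self) -> frozenset:
        return frozenset(n for n in self.nodes if not self.children[n])

    def label(self, node: str) -> str:
        return self.labels.get(node, node)


# -- module-level operation aliases (the spec vocabulary) ----------------------

def ancestors(hierarchy: Hierarchy, node: str) -> frozenset:
    return hierarchy.ancestors(node)


def descendants(hierarchy: Hierarchy, node: str) -> frozenset:
    return hierarchy.descendants(node)


def closure(hierarchy: Hierarchy, node_set) -> frozenset:
    return hierarchy.closure(node_set)


def sanitize(edge_list: EdgeList) -> Hierarchy:
    """Repair a raw edge list into a rooted DAG.

    Self-loops are removed, duplicate pairs collapse to their first
    occurrence, and cycles are broken by deleting DFS back edges (links that
    connect back to concepts higher in the hierarchy).  Fully cyclic input
    (no node without a parent) is rejected.  Every deletion is recorded in
    ``removed_edges`` with a reason code.
    """
    removed: list = []
    seen_pairs = set()
    edges: list = []
    for parent, child in edge_list.pairs:
        if parent == child:
            removed.append(RemovedEdge(parent, child, "self_loop"))
            continue
        if (parent, child) in seen_pairs:
            removed.append(RemovedEdge(parent, child, "duplicate"))
            continue
        seen_pairs.add((parent, child))
        edges.append((parent, child))
    if not edges:
        raise HierarchyError("no usable edges after removing self-loops and duplicates")

    children: dict = {}
    nodes = set()
    indeg: dict = {}
    for parent, child in edges:
        nodes.add(parent)
        nodes.add(child)
        children.setdefault(parent, []).append(child)
        indeg[child] = indeg.get(child, 0) + 1
        indeg.setdefault(parent, 0)

    label_only = set(edge_list.labels) - nodes
    if label_only:
        warnings.warn(f"dropping {len(label_only)} labeled node(s) that appear in no edge")

    roots = sorted(n for n in nodes if indeg[n] == 0)
    if not roots:
        raise HierarchyError("hierarchy has no root: the input graph is fully cyclic")

    kept = {pair: True for pair in edges}
    visited: set = set()

    def dfs(entry: str) -> None:
        # Iterative DFS; children explored in lexicographic order.
        stack = [(entry, iter(sorted(children.get(entry, []))))]
        onpath = {entry}
        visited.add(entry)
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                if not kept.get((node, child), False):
                    continue
                if child in onpath:
                    kept[(node, child)] = False
                    removed.append(RemovedEdge(node, child, "cycle_break"))
                    continue
                if child in visited:
                    continue
                visited.add(child)
                onpath.add(child)
                stack.append((child, iter(sorted(children.get(child, [])))))
                advanced = True
                break
            if not advanced:
                stack.pop()
                onpath.discard(node)

    for root in roots:
        dfs(root)
    # Components unreachable from any root are entered at their
    # lexicographically smallest node; the back edge closing the cycle is
    # deleted there, making the entry a root of the result.
    while visited != nodes:
        dfs(min(nodes - visited))

    final_edges = [pair for pair in edges if kept[pair]]
    hier = Hierarchy(final_edges, labels={k: v for k, v in edge_list.labels.items() if k in nodes},
                     removed_edges=removed)
    assert nx.is_directed_acyclic_graph(hier.to_networkx())
    return hier


def extract_subhierarchy(hierarchy: Hierarchy, base_nodes: Iterable) -> Hierarchy:
    """The complete parent, child, and sibling sub-hierarchy of the base concepts.

    Keeps every path from a base concept up to a root, the base concepts'
    immediate children, and their siblings (nodes sharing at least one
    parent); edges are those induced on the kept node set.
    """
    base = list(base_nodes)
    for node in base:
        hierarchy._require(node)
    keep = set(base)
    for node in base:
        keep |= hierarchy.ancestors(node)
        keep |= set(hierarchy.children[node])
        for parent in hierarchy.parents[node]:
            keep |= set(hierarchy.children[parent])
    induced = [(u, v) for u, v in hierarchy.edges() if u in keep and v in keep]
    return Hierarchy(induced, labels={k: v for k, v in hierarchy.labels.items() if k in keep})


def write_edge_tsv(hierarchy: Hierarchy, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# parent\tchild\n")
        for parent, child in hierarchy.edges():
            fh.write(f"{parent}\t{child}\n")


def write_audit_csv(hierarchy: Hierarchy, path) -> None:
    """Removed-edge audit report: parent,child,reason per line."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("parent,child,reason\n")
        for rec in hierarchy.removed_edges:
            fh.write(f"{rec.parent},{rec.child},{rec.reason}\n")
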