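"""Global ordering of seed contigs on the co-barcoding scaffold graph.

The scaffold graph is an undirected graph over seed contigs whose edges carry
Jaccard-similarity weights above a threshold.  Because a higher JS means two
contigs are closer, ordering uses the *maximum*-JS spanning tree of each
connected component (Prim's algorithm on weight 1 - JS): on three adjacent
contigs this deletes the weakest correlation, which is the non-adjacent pair.

Tree nodes are classified by degree (tip node = 1, linear = 2, junction > 2)
and the maximal linear paths hanging off junctions are classified as tip
branches (< 3 nodes, ending at a tip) or long branches.  A junction with more
than two long branches — a long junction — is strongly associated with
misassembled or repetitive seeds, so an iterative screening pass removes
long-junction nodes from the graph and rebuilds the tree until none remain
(subject to an iteration cap and a cap on the fraction of seeds removed).
Tip branches are pruned, and the remaining branches become ordered scaffolds.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from .prep import JaccardEdge

# node classes
TIP_NODE = "tip_node"
LINEAR_NODE = "linear_node"
TIP_JUNCTION = "tip_junction"
LONG_JUNCTION = "long_junction"
ISOLATED = "isolated"


def build_scaffold_graph(seed_ids: Iterable[str],
                         edges: Iterable[JaccardEdge],
                         js_threshold: float) -> nx.Graph:
    """Undirected JS-weighted graph over seeds, keeping edges with js > threshold.

    Isolated seeds remain as singleton nodes; edges touching non-seed contigs
    are ignored.
    """
    g = nx.Graph()
    seeds = set(seed_ids)
    g.add_nodes_from(sorted(seeds))
    for e in edges:
        if e.contig_a not in seeds or e.contig_b not in seeds:
            continue
        if e.contig_a == e.contig_b:
            continue
        if e.js > js_threshold:
            g.add_edge(e.contig_a, e.contig_b, js=e.js, edge=e)
    return g


def prim_spanning_forest(graph: nx.Graph) -> nx.Graph:
    """Maximum-JS spanning forest via Prim's algorithm, deterministic.

    Each component is grown from its lexicographically smallest node; among
    equal-weight frontier edges the lexicographically smallest (inside,
    outside) node pair wins, so runs are bit-reproducible.
    """
    forest = nx.Graph()
    forest.add_nodes_from(graph.nodes(data=True))
    visited: set[str] = set()
    for start in sorted(graph.nodes):
        if start in visited:
            continue
        visited.add(start)
        heap: list[tuple[float, str, str]] = []
        for nbr, data in sorted(graph[start].items()):
            heapq.heappush(heap, (1.0 - data["js"], start, nbr))
        while heap:
            w, u, v = heapq.heappop(heap)
            if v in visited:
                continue
            visited.add(v)
            forest.add_edge(u, v, **graph[u][v])
            for nbr, data in sorted(graph[v].items()):
                if nbr not in visited:
                    heapq.heappush(heap, (1.0 - data["js"], v, nbr))
    return forest


@dataclass
class Branch:
    """A maximal linear path hanging off ``junction`` in a spanning tree.

    ``nodes`` excludes the junction itself; ``terminal`` is 'tip' when the
    walk ends at a degree-1 node (the tip is included in ``nodes``) and
    'junction' when it reaches another junction (excluded from ``nodes``).
    """

    junction: str
    nodes: list[str]
    terminal: str  # 'tip' or 'junction'

    @property
    def is_tip_branch(self) -> bool:
        return self.terminal == "tip" and len(self.nodes) < 3

    @property
    def is_long(self) -> bool:
        return not self.is_tip_branch


@dataclass
class TreeClassification:
    node_class: dict[str, str] = field(default_factory=dict)
    junction_branches: dict[str, list[Branch]] = field(default_factory=dict)

    def nodes_of_class(self, cls: str) -> list[str]:
        return sorted(n for n, c in self.node_class.items() if c == cls)

    def class_counts(self) -> dict[str, int]:
        counts = {TIP_NODE: 0, LINEAR_NODE: 0, TIP_JUNCTION: 0,
                  LONG_JUNCTION: 0, ISOLATED: 0}
        for c in self.node_class.values():
            counts[c] += 1
        return counts


def _walk_branch(tree: nx.Graph, junction: str, first: str) -> Branch:
    nodes = []
    prev, cur = junction, first
    while True:
        deg = tree.degree(cur)
        if deg > 2:
            return Branch(junction, nodes, "junction")
        nodes.append(cur)
        if deg == 1:
            return Branch(junction, nodes, "tip")
        nxt = next(n for n in tree[cur] if n != prev)
        prev, cur = cur, nxt


def classify_tree(tree: nx.Graph) -> TreeClassification:
    """Assign every node its taxonomy class and enumerate junction branches."""
    cls = TreeClassification()
    for node in tree.nodes:
        deg = tree.degree(node)
        if deg == 0:
            cls.node_class[node] = ISOLATED
        elif deg == 1:
            cls.node_class[node] = TIP_NODE
        elif deg == 2:
            cls.node_class[node] = LINEAR_NODE
        else:
            branches = [_walk_branch(tree, node, nbr)
                        for nbr in sorted(tree[node])]
            cls.junction_branches[node] = branches
            n_long = sum(1 for b in branches if b.is_long)
            cls.node_class[node] = (LONG_JUNCTION if n_long > 2
                                    else TIP_JUNCTION)
    return cls


def prune_tips(tree: nx.Graph) -> tuple[nx.Graph, set[str]]:
    """Remove tip branches attached to junctions, to a fixed point.

    Pruning a tip branch can merge the junction into a linear path and expose
    new tip branches, so the pass repeats until no junction has a tip branch.
    Components that contain no junction (pure paths) are never touched.
    Removed nodes are returned for routing to the unscaffolded pool.
    """
    pruned = tree.copy()
    removed: set[str] = set()
    while True:
        cls = classify_tree(pruned)
        to_remove: set[str] = set()
        for junction, branches in cls.junction_branches.items():
            for b in branches:
                if b.is_tip_branch:
                    to_remove.update(b.nodes)
        if not to_remove:
            return pruned, removed
        pruned.remove_nodes_from(to_remove)
        removed |= to_remove


def screen_non_ideal(graph: nx.Graph, iteration_cap: int = 5,
                     removal_ratio_cap: float = 0.02,
                     ) -> tuple[nx.Graph, set[str], "TreeClassification"]:
    """Iteratively remove long-junction nodes from the scaffold graph.

    Each iteration rebuilds the spanning forest from the surviving graph,
    classifies it, and deletes all long-junction nodes (worst first when the
    removal budget runs short).  Stops at the fixed point (no long junctions),
    at ``iteration_cap``, or when removing more would push the cumulative
    removed fraction of seeds over ``removal_ratio_cap``.

    Returns (final spanning forest, screened node ids, final classification).
    """
    g = graph.copy()
    n_seeds = g.number_of_nodes()
    budget = math.floor(removal_ratio_cap * n_seeds)
    screened: set[str] = set()
    tree = prim_spanning_forest(g)
    cls = classify_tree(tree)
    for _ in range(iteration_cap):
        long_junctions = cls.nodes_of_class(LONG_JUNCTION)
        if not long_junctions:
            break
        remaining = budget - len(screened)
        if remaining <= 0:
            break
        if len(long_junctions) > remaining:
            # worst junctions first: most long branches, then highest degree
            long_junctions.sort(
                key=lambda n: (-sum(1 for b in cls.junction_branches[n]
                                    if b.is_long), -tree.degree(n), n))
            long_junctions = long_junctions[:remaining]
        g.remove_nodes_from(long_junctions)
        screened.update(long_junctions)
        tree = prim_spanning_forest(g)
        cls = classify_tree(tree)
    return tree, screened, cls


@dataclass
class OrderedScaffold:
    """An ordered (not yet oriented) run of seed contigs."""

    contig_ids: list[str]
    branch_id: int = -1


def extract_orders(pruned_tree: nx.Graph) -> list[OrderedScaffold]:
    """Turn the branches of a pruned spanning forest into ordered scaffolds.

    Junction nodes (degree > 2) are emitted as singletons; every maximal
    linear path delimited by junctions or tips becomes one scaffold.  Path
    direction is fixed deterministically from the lexicographically smaller
    endpoint.
    """
    junctions = sorted(n for n in pruned_tree.nodes
                       if pruned_tree.degree(n) > 2)
    linear = pruned_tree.copy()
    linear.remove_nodes_from(junctions)
    scaffolds: list[OrderedScaffold] = [OrderedScaffold([j]) for j in junctions]
    for comp in nx.connected_components(linear):
        comp = set(comp)
        if len(comp) == 1:
            scaffolds.append(OrderedScaffold(sorted(comp)))
            continue
        endpoints = sorted(n for n in comp if linear.degree(n) == 1)
        start = endpoints[0]
        path = [start]
        prev = None
        cur = start
        while True:
            nxts = [n for n in linear[cur] if n != prev]
            if not nxts:
                break
            prev, cur = cur, nxts[0]
            path.append(cur)
        scaffolds.append(OrderedScaffold(path))
    scaffolds.sort(key=lambda s: s.contig_ids[0])
    for i, s in enumerate(scaffolds):
        s.branch_id = i
    return scaffolds


def tree_to_dot(tree: nx.Graph, cls: TreeClassification) -> str:
    """GraphViz text dump of a spanning forest with node classes."""
    lines = ["graph spanning_forest {"]
    shapes = {TIP_NODE: "circle", LINEAR_NODE: "point",
              TIP_JUNCTION: "triangle", LONG_JUNCTION: "doublecircle",
              ISOLATED: "plaintext"}
    for node in sorted(tree.nodes):
        klass = cls.node_class.get(node, ISOLATED)
        lines.append(f'  "{node}" [shape={shapes[klass]} class="{klass}"];')
    for u, v, data in sorted(tree.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [label="{data.get("js", 0):.3f}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def order_seeds(seed_ids: Iterable[str], edges: Sequence[JaccardEdge],
                js_threshold: float, iteration_cap: int = 5,
                removal_ratio_cap: float = 0.02,
                ) -> tuple[list[OrderedScaffold], set[str], set[str],
                           "TreeClassification", nx.Graph]:
    """Full ordering stage: graph -> screening -> pruning -> ordered scaffolds.

    Returns (scaffolds, screened ids, pruned-tip ids, final classification,
    final pruned tree).  Screened and pruned contigs go to the unscaffolded
    pool; every seed ends up in exactly one of the three outputs.
    """
    graph = build_scaffold_graph(seed_ids, edges, js_threshold)
    tree, screened, _ = screen_non_ideal(graph, iteration_cap,
                                         removal_ratio_cap)
    pruned_tree, pruned = prune_tips(tree)
    cls = classify_tree(pruned_tree)
    scaffolds = extract_orders(pruned_tree)
    return scaffolds, screened, pruned, cls, pruned_tree
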