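"""Median-joining haplotype networks and reticulation diagnostics.

A haplotype network displays the mutational relationships among observed
haplotypes; reticulations (independent cycles) signal homoplasy. The
construction follows Bandelt, Forster & Roehl (1999): iterate a minimum
spanning network (the union of all minimum spanning trees, relaxed by a
tolerance epsilon) with insertion of median vectors (per-column majority
consensus of linked triples) until closure, then prune obsolete median
vectors. The network is deterministic: ties are broken lexicographically
and the result is invariant to haplotype input order.

The loop census (cycle rank E - V + components) is the quantity used to
screen alignment columns for homoplasy: a hypervariable site whose removal
collapses loops is a candidate for exclusion before phylogeographic
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .alignment import HaplotypeAlignment, HaplotypeTable, collapse_haplotypes, remove_sites

__all__ = [
    "HaplotypeNetwork",
    "build_mj_network",
    "loop_census",
    "homoplasy_screen",
]


@dataclass
class HaplotypeNetwork:
    """A haplotype network: observed haplotypes plus inferred median vectors.

    ``graph`` is an undirected networkx graph whose nodes carry
    ``sequence``, ``sampled`` (False for median vectors), and per-population
    ``counts``; edges carry ``weight`` = mutational steps.
    """

    graph: nx.Graph
    epsilon: int
    iterations: int

    @property
    def n_medians(self) -> int:
        return sum(1 for _, d in self.graph.nodes(data=True) if not d["sampled"])

    def total_length(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True))

    def to_edge_list(self):
        return [
            (u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)
        ]

    def write_graphml(self, path) -> None:
        g = nx.Graph()
        for node, d in self.graph.nodes(data=True):
            counts = d.get("counts") or {}
            g.add_node(
                node,
                sequence=d["sequence"],
                sampled=d["sampled"],
                frequency=sum(counts.values()),
                **{f"n_{p}": c for p, c in counts.items()},
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=float(d["weight"]))
        nx.write_graphml(g, str(path))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(nodes: list[str], epsilon: int) -> list[tuple[str, str, int]]:
    """Minimum spanning network: edges whose weight is within epsilon of the
    minimax (bottleneck) distance between their endpoints.

    The epsilon = 0 case is exactly the union of all minimum spanning trees.
    """
    k = len(nodes)
    if k == 1:
        return []
    d = {(a, b): _hamming(a, b) for a, b in combinations(nodes, 2)}

    # Kruskal over lexicographically sorted edges -> one canonical MST,
    # then minimax distances over that tree.
    edges = sorted(d.items(), key=lambda kv: (kv[1], kv[0]))
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = nx.Graph()
    tree.add_nodes_from(nodes)
    for (a, b), w in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            tree.add_edge(a, b, weight=w)

    # minimax distance = max edge weight on the unique tree path
    minimax: dict[tuple[str, str], int] = {}
    for src in nodes:
        seen = {src: 0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in tree.adj[u]:
                if v not in seen:
                    seen[v] = max(seen[u], tree.adj[u][v]["weight"])
                    stack.append(v)
        for dst, m in seen.items():
            if src < dst:
                minimax[(src, dst)] = m

    return [
        (a, b, w)
        for (a, b), w in sorted(d.items(), key=lambda kv: (kv[1], kv[0]))
        if w <= minimax[(a, b)] + epsilon
    ]


def _median(u: str, v: str, w: str) -> str | None:
    """Per-column majority consensus; None where no strict majority exists
    at some column (three distinct states)."""
    out = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            out.append(a)
        elif b == c:
            out.append(b)
        else:
            return None
    return "".join(out)


def build_mj_network(table: HaplotypeTable, epsilon: int = 0) -> HaplotypeNetwork:
    """Median-joining network of the haplotypes in ``table``.

    Requires haplotype sequences. epsilon relaxes the spanning-network
    criterion (default 0); larger values admit more alternative links and
    more median vectors.
    """
    if not table.sequences:
        raise ValueError("median-joining network needs haplotype sequences")
    seqs = {table.sequences[h]: h for h in table.haplotypes}
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError("haplotype sequences have unequal lengths")

    sampled = set(seqs)
    X = sorted(sampled)
    iterations = 0
    while True:
        iterations += 1
        links = _msn_edges(X, epsilon)
        adj: dict[str, set[str]] = {n: set() for n in X}
        for a, b, _ in links:
            adj[a].add(b)
            adj[b].add(a)
        new: set[str] = set()
        for v in X:
            for u, w in combinations(sorted(adj[v]), 2):
                m = _median(u, v, w)
                if m is not None and m not in X and m not in new:
                    new.add(m)
        if not new:
            break
        X = sorted(set(X) | new)

    # Prune obsolete median vectors: unsampled nodes that never attain
    # degree >= 3 in the spanning network over the remaining node set.
    while True:
        links = _msn_edges(X, epsilon)
        deg: dict[str, int] = {n: 0 for n in X}
        for a, b, _ in links:
            deg[a] += 1
            deg[b] += 1
        drop = [n for n in X if n not in sampled and deg[n] <= 2]
        if not drop:
            break
        X = [n for n in X if n not in set(drop)]

    g = nx.Graph()
    med = 0
    names: dict[str, str] = {}
    for s in X:
        if s in seqs:
            names[s] = seqs[s]
        else:
            med += 1
            names[s] = f"mv{med}"
    for s in X:
        if s in seqs:
            h = seqs[s]
            counts = {p: int(table.counts.loc[h, p]) for p in table.populations}
            g.add_node(names[s], sequence=s, sampled=True, counts=counts)
        else:
            g.add_node(names[s], sequence=s, sampled=False, counts={})
    for a, b, w in _msn_edges(X, epsilon):
        g.add_edge(names[a], names[b], weight=w)
    return HaplotypeNetwork(graph=g, epsilon=epsilon, iterations=iterations)


def loop_census(net: HaplotypeNetwork) -> int:
    """Number of independent cycles: E - V + number of components."""
    g = net.graph
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def homoplasy_screen(
    aln: HaplotypeAlignment, epsilon: int = 0
) -> dict[int, int]:
    """Change in loop count when each polymorphic site is removed.

    Returns {1-based site: loops(without site) - loops(with site)}. A site
    generating reticulations through parallel mutation shows a negative
    delta; sites carrying clean signal show 0.
    """
    base_net = build_mj_network(collapse_haplotypes(aln), epsilon)
    base_loops = loop_census(base_net)
    out: dict[int, int] = {}
    for col in range(1, aln.L + 1):
        states = {r.sequence[col - 1] for r in aln.records} - {"N"}
        if len(states) < 2:
            continue
        reduced = remove_sites(aln, [col])
        net = build_mj_network(collapse_haplotypes(reduced), epsilon)
        out[col] = loop_census(net) - base_loops
    return out
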