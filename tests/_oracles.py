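"""Independent brute-force oracles used to check the graph-metric code.

These deliberately share no code with wormnet.metrics: paths are found by
exhaustive DFS enumeration of all simple paths, lengths by summing reciprocal
weights along each path, and betweenness by filtering the enumerated minima.
Only practical on graphs of ~8 nodes or fewer.
"""

from fractions import Fraction

import networkx as nx
import numpy as np


def all_simple_paths(G: nx.DiGraph, src: str, dst: str):
    """Every simple directed path src -> dst as a tuple of nodes."""
    out = []
    stack = [(src, (src,))]
    while stack:
        node, path = stack.pop()
        if node == dst:
            out.append(path)
            continue
        for nxt in G.successors(node):
            if nxt not in path:
                stack.append((nxt, path + (nxt,)))
    return out


def path_length(G: nx.DiGraph, path) -> Fraction:
    return sum(
        (Fraction(1, int(G.edges[u, v]["weight"])) for u, v in zip(path, path[1:])),
        Fraction(0),
    )


def brute_inventory(G: nx.DiGraph):
    """(dict (src,dst) -> (min length, set of minimal paths), unreachable count)."""
    pairs = {}
    unreachable = 0
    nodes = sorted(G.nodes)
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = all_simple_paths(G, s, t)
            if not paths:
                unreachable += 1
                continue
            lengths = {p: path_length(G, p) for p in paths}
            best = min(lengths.values())
            pairs[(s, t)] = (best, {p for p, l in lengths.items() if l == best})
    return pairs, unreachable


def brute_betweenness(G: nx.DiGraph):
    pairs, _ = brute_inventory(G)
    stored = [p for _, (_, ps) in sorted(pairs.items()) for p in ps]
    total = len(stored)
    return {n: Fraction(sum(n in p for p in stored), total) for n in G.nodes}


def random_graph(rng: np.random.Generator, max_nodes: int = 8) -> nx.DiGraph:
    """Small random directed weighted graph, integer weights 1..5."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.7))
    G = nx.DiGraph()
    names = [f"n{i}" for i in range(n)]
    G.add_nodes_from(names)
    for u in names:
        for v in names:
            if u != v and rng.random() < p:
                G.add_edge(u, v, weight=int(rng.integers(1, 6)))
    return G
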