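"""Directed-weighted graph metrics for functional connectomes.

The metrics follow the conventions used throughout the analysis:

* **node strength** — total synapse count attached to a node, split into
  out-strength (sum of outgoing edge weights) and in-strength (incoming).
* **path length** — the sum over a path's edges of the *reciprocal* edge
  weight, so heavily wired connections are functionally short.  Lengths are
  exact rationals (:class:`fractions.Fraction`), which makes tie detection and
  comparisons with enumeration oracles exact.
* **betweenness centrality** — the fraction of all shortest paths in the
  network whose node sequence contains the node, *endpoints included*.  With
  endpoints counted, a hub that terminates many strong paths scores high even
  when it is never an intermediate stop.

Sub-network extraction (sex-specific neighborhood, sex-shared induced graph),
cross-sex per-node differences, top-k ranking, the exponential strength-
distribution fit and the two-sample comparison used for group panels live
here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

__all__ = [
    "NodeMetrics",
    "ShortestPath",
    "PathInventory",
    "node_strengths",
    "edge_weights",
    "shortest_paths",
    "betweenness",
    "sex_specific_subnetwork",
    "sex_shared_subnetwork",
    "metric_difference",
    "rank_top",
    "fit_exponential",
    "compare_groups",
    "average_path_length",
]

NODE_METRICS = ("strength", "out_strength", "in_strength", "betweenness")
PAIR_METRICS = ("edge_weight", "path_length")


@dataclass(frozen=True)
class NodeMetrics:
    node: str
    strength: int
    out_strength: int
    in_strength: int


def node_strengths(net: nx.DiGraph) -> list[NodeMetrics]:
    """Per-node synapse totals; an isolated node scores (0, 0, 0)."""
    out = []
    for n in sorted(net.nodes):
        o = sum(w for _, _, w in net.out_edges(n, data="weight"))
        i = sum(w for _, _, w in net.in_edges(n, data="weight"))
        out.append(NodeMetrics(node=n, strength=o + i, out_strength=o, in_strength=i))
    return out


def strength_dict(net: nx.DiGraph, which: str = "strength") -> dict[str, int]:
    """Node -> strength/out_strength/in_strength mapping."""
    return {m.node: getattr(m, which) for m in node_strengths(net)}


def edge_weights(net: nx.DiGraph) -> list[tuple[str, str, int]]:
    """The positive-weight directed edges as (u, v, weight), sorted."""
    return sorted((u, v, w) for u, v, w in net.edges(data="weight") if w > 0)


@dataclass(frozen=True)
class ShortestPath:
    src: str
    dst: str
    nodes: tuple[str, ...]
    length: Fraction

    def __post_init__(self) -> None:
        assert self.nodes[0] == self.src and self.nodes[-1] == self.dst


@dataclass
class PathInventory:
    """All minimal-length simple paths, one group per reachable ordered pair
    of distinct nodes, plus the count of unreachable ordered pairs."""

    paths: list[ShortestPath] = field(default_factory=list)
    unreachable_pairs: int = 0

    def __len__(self) -> int:
        return len(self.paths)

    def by_pair(self) -> dict[tuple[str, str], list[ShortestPath]]:
        out: dict[tuple[str, str], list[ShortestPath]] = {}
        for p in self.paths:
            out.setdefault((p.src, p.dst), []).append(p)
        return out

    def pair_lengths(self) -> dict[tuple[str, str], Fraction]:
        return {(p.src, p.dst): p.length for p in self.paths}


def _reciprocal_length_graph(net: nx.DiGraph) -> nx.DiGraph:
    H = nx.DiGraph()
    H.add_nodes_from(net.nodes)
    for u, v, w in net.edges(data="weight"):
        if w > 0:
            H.add_edge(u, v, length=Fraction(1, int(w)))
    return H


def _paths_from_predecessors(pred: Mapping[str, list[str]], src: str, dst: str) -> list[tuple[str, ...]]:
    """Enumerate every minimal path src->dst from a Dijkstra predecessor DAG."""
    if dst == src:
        return [(src,)]
    out: list[tuple[str, ...]] = []
    stack: list[tuple[str, tuple[str, ...]]] = [(dst, (dst,))]
    while stack:
        node, suffix = stack.pop()
        for p in pred[node]:
            if p == src:
                out.append((src,) + suffix)
            else:
                stack.append((p, (p,) + suffix))
    return out


def shortest_paths(net: nx.DiGraph, ties: str = "all") -> PathInventory:
    """All-pairs shortest paths under reciprocal-weight lengths.

    ``ties="all"`` (default) stores every co-minimal simple path for a pair;
    ``ties="single"`` stores one deterministic representative (the
    lexicographically smallest node sequence).  With positive lengths minimal
    paths are automatically simple.
    """
    if ties not in ("all", "single"):
        raise ValueError("ties must be 'all' or 'single'")
    H = _reciprocal_length_graph(net)
    inv = PathInventory()
    nodes = sorted(H.nodes)
    reachable_pairs = 0
    for src in nodes:
        pred, dist = nx.dijkstra_predecessor_and_distance(H, src, weight="length")
        for dst in nodes:
            if dst == src:
                continue
            if dst not in dist:
                continue
            reachable_pairs += 1
            seqs = sorted(_paths_from_predecessors(pred, src, dst))
            if ties == "single":
                seqs = seqs[:1]
            for seq in seqs:
                inv.paths.append(
                    ShortestPath(src=src, dst=dst, nodes=seq, length=dist[dst])
                )
    n = len(nodes)
    inv.unreachable_pairs = n * (n - 1) - reachable_pairs
    return inv


def betweenness(
    net: nx.DiGraph, inventory: PathInventory | None = None
) -> dict[str, Fraction]:
    """Endpoint-inclusive betweenness: the fraction of stored shortest paths
    whose node sequence contains the node.  Exact rational values."""
    if inventory is None:
        inventory = shortest_paths(net)
    total = len(inventory.paths)
    if total == 0:
        raise ValueError("betweenness is undefined: the path inventory is empty")
    counts = {n: 0 for n in net.nodes}
    for p in inventory.paths:
        for n in set(p.nodes):
            counts[n] += 1
    return {n: Fraction(c, total) for n, c in sorted(counts.items())}


def sex_specific_subnetwork(net: nx.DiGraph) -> nx.DiGraph:
    """Sex-specific nodes plus every node sharing an edge (either direction)
    with one, with the induced edges."""
    specific = {n for n, d in net.nodes(data=True) if d.get("sex_specific")}
    if not specific:
        warnings.warn("network has no sex-specific nodes; sub-network is empty")
        return nx.DiGraph()
    keep = set(specific)
    for n in specific:
        keep.update(net.successors(n))
        keep.update(net.predecessors(n))
    return net.subgraph(keep).copy()


def sex_shared_subnetwork(net: nx.DiGraph) -> nx.DiGraph:
    """Induced sub-graph on the nodes with sex_specific = False."""
    shared = {n for n, d in net.nodes(data=True) if not d.get("sex_specific")}
    return net.subgraph(shared).copy()


def _metric_values(net: nx.DiGraph, metric: str):
    if metric in ("strength", "out_strength", "in_strength"):
        return strength_dict(net, metric)
    if metric == "betweenness":
        return betweenness(net)
    if metric == "edge_weight":
        return {(u, v): w for u, v, w in edge_weights(net)}
    if metric == "path_length":
        return shortest_paths(net).pair_lengths()
    raise ValueError(f"unknown metric {metric!r}")


def metric_difference(net_a: nx.DiGraph, net_b: nx.DiGraph, metric: str) -> dict:
    """Per-key signed differences value_A - value_B over the shared domain
    (shared nodes for node metrics, shared edges/pairs for pair metrics);
    positive means larger in the first network."""
    va, vb = _metric_values(net_a, metric), _metric_values(net_b, metric)
    shared = sorted(set(va) & set(vb))
    if not shared:
        warnings.warn(f"no shared {metric} domain between the two networks")
        return {}
    return {k: va[k] - vb[k] for k in shared}


def rank_top(values: Mapping[str, float], k: int) -> list[str]:
    """Top-k keys by descending value; ties broken by name so the ranking is
    deterministic under any input order."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k > len(values):
        warnings.warn(f"k={k} exceeds the {len(values)} available entries; truncating")
        k = len(values)
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    return [name for name, _ in ordered[:k]]


@dataclass(frozen=True)
class ExponentialFit:
    rate: float
    ks_statistic: float
    p_value: float


def fit_exponential(values: Sequence[float]) -> ExponentialFit:
    """Maximum-likelihood exponential fit (rate = 1/mean) with a one-sample
    Kolmogorov-Smirnov test against the fitted distribution."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 5:
        raise ValueError(f"need at least 5 values for a distribution fit, got {arr.size}")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("values must be positive and finite")
    mean = float(arr.mean())
    ks = stats.kstest(arr, "expon", args=(0.0, mean))
    return ExponentialFit(rate=1.0 / mean, ks_statistic=float(ks.statistic),
                          p_value=float(ks.pvalue))


@dataclass(frozen=True)
class GroupComparison:
    t_statistic: float
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float


def compare_groups(a: Sequence[float], b: Sequence[float]) -> GroupComparison:
    """Two-sample two-tailed Student's t-test with mean +/- SEM summaries."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_statistic=float(t), p_value=float(p),
        mean_a=float(a.mean()), sem_a=float(stats.sem(a)),
        mean_b=float(b.mean()), sem_b=float(stats.sem(b)),
    )


def average_path_length(
    inventory: PathInventory, involving: Iterable[str] | None = None
) -> float:
    """Mean shortest-path length over reachable ordered pairs, optionally
    restricted to pairs with at least one endpoint in ``involving``."""
    lengths = inventory.pair_lengths()
    if involving is not None:
        group = set(involving)
        lengths = {k: v for k, v in lengths.items() if k[0] in group or k[1] in group}
    if not lengths:
        raise ValueError("no pairs to average over")
    return float(np.mean([float(v) for v in lengths.values()]))
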