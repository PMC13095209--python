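"""Synthetic connectome tables with the statistical structure of the worm data.

The generator emits raw synapse tables (neuron level) together with the merge
map and a ground-truth attribute table, so the whole pipeline — parse, merge,
metric, simulate — is testable without downloads.  Its defaults emulate the
features the analyses rely on:

* bilateral neuron pairs sharing an L/R suffix that merge to one node;
* a sex-specific node subset (about a quarter of nodes, matching the
  male-specific share of the real network);
* chemical (directed) and electrical (undirected, stored once) records;
* approximately exponential node-strength distributions, achieved by giving
  each node an exponential "activity" and attaching geometric synapse counts
  to activity-weighted random edges — a Poisson mixture over an exponential
  rate is geometric, the discrete analog of the exponential law.

Also here: the four-neuron worked-example network used to pin down every
graph-metric definition exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import networkx as nx
import numpy as np

from .connectome import (
    ConnectomeTable,
    MergeMap,
    SynapseKind,
    SynapseRecord,
    build_network,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "worked_example",
           "strength_calibration"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator.

    ``n_nodes`` counts *neurons* before merging; ``bilateral_fraction`` of
    them are emitted as L/R pairs (so 100 neurons at 0.5 give 25 pairs + 50
    singles = 75 merged nodes).  ``mean_degree`` is the expected number of
    connections per merged node; ``weight_rate`` is the geometric parameter of
    the per-connection synapse count (mean 1/weight_rate).
    """

    n_nodes: int = 100
    bilateral_fraction: float = 0.5
    specific_fraction: float = 0.25
    mean_degree: float = 8.0
    weight_rate: float = 0.35
    electrical_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be at least 4")
        for name in ("bilateral_fraction", "specific_fraction", "electrical_fraction"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.weight_rate <= 1.0:
            raise ValueError("weight_rate must lie in (0, 1]")
        if self.mean_degree <= 0 or self.mean_degree >= self.n_nodes:
            raise ValueError("mean_degree must be positive and below n_nodes")

    @property
    def n_pairs(self) -> int:
        return int(round(self.bilateral_fraction * self.n_nodes / 2))

    @property
    def n_merged(self) -> int:
        return self.n_nodes - self.n_pairs


@dataclass
class GroundTruth:
    """What the generator intended, for round-trip checks."""

    n_merged_nodes: int
    sex_specific: dict[str, bool]
    strength: dict[str, int] = field(default_factory=dict)
    out_strength: dict[str, int] = field(default_factory=dict)
    in_strength: dict[str, int] = field(default_factory=dict)
    n_edges: int = 0


def generate(spec: SyntheticSpec) -> tuple[ConnectomeTable, MergeMap, GroundTruth]:
    """Sample a synapse table, its merge map and the intended ground truth.

    Deterministic for a fixed seed.  Electrical records are stored once per
    unordered pair occurrence (expanded to reciprocal edges at build time);
    ground-truth strengths account for that expansion.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_pairs
    pair_nodes = [f"NB{i:03d}" for i in range(n_pairs)]
    single_neurons = [f"NS{i:03d}" for i in range(spec.n_nodes - 2 * n_pairs)]
    nodes = pair_nodes + single_neurons

    mapping: dict[str, str] = {}
    constituents: dict[str, list[str]] = {}
    for b in pair_nodes:
        mapping[b + "L"] = b
        mapping[b + "R"] = b
        constituents[b] = [b + "L", b + "R"]
    for s in single_neurons:
        mapping[s] = s
        constituents[s] = [s]

    n_specific = int(round(spec.specific_fraction * len(nodes)))
    specific = set(rng.choice(nodes, size=n_specific, replace=False)) if n_specific else set()
    merge = MergeMap(mapping, {n: (n in specific) for n in nodes})

    n = len(nodes)
    activity = rng.exponential(1.0, n)
    p_node = activity / activity.sum()
    m = int(round(spec.mean_degree * n))

    truth = GroundTruth(
        n_merged_nodes=n,
        sex_specific={nd: (nd in specific) for nd in nodes},
        strength={nd: 0 for nd in nodes},
        out_strength={nd: 0 for nd in nodes},
        in_strength={nd: 0 for nd in nodes},
        n_edges=m,
    )

    records: list[SynapseRecord] = []
    for _ in range(m):
        u = v = None
        while u == v:
            u, v = rng.choice(n, size=2, p=p_node)
        nu, nv = nodes[int(u)], nodes[int(v)]
        count = int(rng.geometric(spec.weight_rate))
        electrical = rng.random() < spec.electrical_fraction
        pre = constituents[nu][int(rng.integers(len(constituents[nu])))]
        post = constituents[nv][int(rng.integers(len(constituents[nv])))]
        if electrical:
            records.append(SynapseRecord(pre, post, SynapseKind.ELECTRICAL, count))
            for a, b in ((nu, nv), (nv, nu)):
                truth.out_strength[a] += count
                truth.in_strength[b] += count
        else:
            records.append(SynapseRecord(pre, post, SynapseKind.CHEMICAL, count))
            truth.out_strength[nu] += count
            truth.in_strength[nv] += count
    for nd in nodes:
        truth.strength[nd] = truth.out_strength[nd] + truth.in_strength[nd]

    table = ConnectomeTable(records=records,
                            provenance=f"synthetic(seed={spec.seed})")
    return table, merge, truth


def worked_example() -> nx.DiGraph:
    """The four-neuron demonstration network with its seven directed edges
    (A->B 2, A->D 3, B->C 2, B->D 2, C->A 3, C->D 1, D->B 4), built through
    the regular table -> merge -> network pipeline."""
    edges = [
        ("A", "B", 2), ("A", "D", 3), ("B", "C", 2), ("B", "D", 2),
        ("C", "A", 3), ("C", "D", 1), ("D", "B", 4),
    ]
    table = ConnectomeTable(
        records=[SynapseRecord(u, v, SynapseKind.CHEMICAL, w) for u, v, w in edges],
        provenance="worked example",
    )
    merge = MergeMap.identity(["A", "B", "C", "D"])
    return build_network(table, merge)


def strength_calibration(
    spec: SyntheticSpec, n_seeds: int = 100, alpha: float = 0.01
) -> float:
    """Fraction of seeds whose merged-network node strengths pass the
    exponential KS fit at level ``alpha`` (zero-strength nodes excluded, the
    fit being defined on positive values)."""
    from .metrics import fit_exponential, strength_dict

    passed = 0
    for s in range(n_seeds):
        table, merge, _ = generate(replace(spec, seed=spec.seed + s))
        net = build_network(table, merge)
        values = [v for v in strength_dict(net).values() if v > 0]
        if fit_exponential(values).p_value > alpha:
            passed += 1
    return passed / n_seeds
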