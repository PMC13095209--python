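"""Behavior-category tallies over top-ranked neurons.

Given any node ranking (by strength, betweenness, upstream/downstream
influence, ...) and a node -> behavior-category annotation, the top-k nodes
are tallied per category to give a coarse behavioral-output prediction for a
network.  A neuron annotated with m categories contributes 1/m to each
(fractional attribution) by default, so the tally over k nodes always sums to
k; nodes missing from the annotation are tallied under ``"unannotated"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["BehaviorAnnotation", "BehaviorTally", "predict", "compare_predictions"]

UNANNOTATED = "unannotated"


@dataclass
class BehaviorAnnotation:
    """node -> non-empty set of behavior-category labels."""

    mapping: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, cats in self.mapping.items():
            if not cats:
                raise ValueError(f"node {node!r} has an empty category set")

    def categories(self, node: str) -> frozenset[str]:
        return self.mapping.get(node, frozenset())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BehaviorAnnotation":
        """TSV with columns ``node`` and ``categories`` (semicolon-separated)."""
        df = pd.read_csv(path, sep="\t")
        mapping = {}
        for row in df.itertuples(index=False):
            cats = frozenset(c.strip() for c in str(row.categories).split(";") if c.strip())
            mapping[str(row.node)] = cats
        return cls(mapping)

    @classmethod
    def default(cls) -> "BehaviorAnnotation":
        """Literature-derived default annotation shipped as editable package
        data; coarse, intended for qualitative tallies only."""
        with resources.as_file(
            resources.files("wormnet.data").joinpath("behavior_categories.tsv")
        ) as p:
            return cls.from_tsv(p)


@dataclass
class BehaviorTally:
    counts: dict[str, float]
    k: int

    @property
    def fractions(self) -> dict[str, float]:
        if self.k == 0:
            return {}
        return {c: v / self.k for c, v in self.counts.items()}


def predict(
    ranked: Sequence[str],
    annotation: BehaviorAnnotation,
    k: int,
    attribution: str = "fractional",
) -> BehaviorTally:
    """Tally behavior categories over the top-k nodes of a ranking.

    ``attribution="fractional"`` (default) spreads a multi-category node
    evenly over its categories; ``"full"`` counts 1 per category.
    """
    if k > len(ranked):
        raise ValueError(f"k={k} exceeds ranking length {len(ranked)}")
    if attribution not in ("fractional", "full"):
        raise ValueError("attribution must be 'fractional' or 'full'")
    counts: dict[str, float] = {}
    unknown = []
    for node in ranked[:k]:
        cats = annotation.categories(node)
        if not cats:
            unknown.append(node)
            counts[UNANNOTATED] = counts.get(UNANNOTATED, 0.0) + 1.0
            continue
        share = 1.0 / len(cats) if attribution == "fractional" else 1.0
        for c in sorted(cats):
            counts[c] = counts.get(c, 0.0) + share
    if unknown:
        warnings.warn(f"{len(unknown)} of the top {k} nodes are unannotated: {unknown}")
    return BehaviorTally(counts=counts, k=k)


def compare_predictions(
    tally_a: BehaviorTally, tally_b: BehaviorTally
) -> dict[str, float]:
    """Per-category difference of fractions; positive = enriched in the first
    tally.  Both tallies must use the same k."""
    if tally_a.k != tally_b.k:
        raise ValueError("tallies must be computed at the same k")
    fa, fb = tally_a.fractions, tally_b.fractions
    return {c: fa.get(c, 0.0) - fb.get(c, 0.0) for c in sorted(set(fa) | set(fb))}
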