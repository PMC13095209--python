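"""Build functional connectomes from raw synapse tables.

The raw data are per-synapse records (pre neuron, post neuron, chemical or
electrical, synapse count).  Functional networks are obtained by merging
bilaterally symmetric (and otherwise functionally equivalent) neurons into a
single node, summing synapse counts, and expanding each electrical synapse
into two reciprocal directed edges — one gap junction couples both neurons, so
it carries weight in both directions.  The result is a directed graph with
non-negative integer edge weights (the synapse count of each connection).
"""

from __future__ import annotations

import csv
import math
import re
import warnings
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "SynapseKind",
    "SynapseRecord",
    "ConnectomeTable",
    "MergeMap",
    "ConnectomeFormatError",
    "MergeError",
    "read_connectome",
    "read_merge_map",
    "infer_merge_map",
    "electrical_as_reciprocal",
    "build_network",
    "write_network",
    "read_network",
]


class ConnectomeFormatError(ValueError):
    """Raised when a synapse table is malformed (missing columns, bad counts)."""


class MergeError(KeyError):
    """Raised when a neuron in the table has no image under the merge map."""


class SynapseKind(str, Enum):
    CHEMICAL = "chemical"
    ELECTRICAL = "electrical"

    @classmethod
    def parse(cls, text: str) -> "SynapseKind":
        t = str(text).strip().lower()
        if t in ("chemical", "chem", "c"):
            return cls.CHEMICAL
        if t in ("electrical", "elec", "e", "gap", "gapjunction", "gap_junction"):
            return cls.ELECTRICAL
        raise ConnectomeFormatError(f"unknown synapse type {text!r}")


@dataclass(frozen=True)
class SynapseRecord:
    """One row of a synapse table: ``count`` synapses from ``pre`` to ``post``."""

    pre: str
    post: str
    kind: SynapseKind
    count: int

    def __post_init__(self) -> None:
        if not self.pre or not self.post:
            raise ConnectomeFormatError("pre and post neuron names must be non-empty")
        if not isinstance(self.count, int) or isinstance(self.count, bool):
            raise ConnectomeFormatError(f"synapse count must be an integer, got {self.count!r}")
        if self.count < 1:
            raise ConnectomeFormatError(f"synapse count must be >= 1, got {self.count}")
        if not isinstance(self.kind, SynapseKind):
            object.__setattr__(self, "kind", SynapseKind.parse(self.kind))


@dataclass
class ConnectomeTable:
    """Ordered raw synapse records; duplicate (pre, post, kind) rows are legal
    and are summed when the network is built."""

    records: list[SynapseRecord] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def total_synapse_weight(self) -> int:
        """Chemical counts plus twice the electrical counts (each gap junction
        contributes one synapse in each direction)."""
        total = 0
        for r in self.records:
            total += r.count if r.kind is SynapseKind.CHEMICAL else 2 * r.count
        return total


@dataclass
class MergeMap:
    """Total many-to-one map neuron name -> node name, with optional per-node
    sex-specific flags (supplied, never inferred)."""

    mapping: dict[str, str]
    sex_specific: dict[str, bool] = field(default_factory=dict)

    def __getitem__(self, neuron: str) -> str:
        try:
            return self.mapping[neuron]
        except KeyError:
            raise MergeError(f"neuron {neuron!r} has no entry in the merge map") from None

    def node_is_specific(self, node: str) -> bool:
        return bool(self.sex_specific.get(node, False))

    @classmethod
    def identity(cls, neurons: Iterable[str],
                 sex_specific: Iterable[str] = ()) -> "MergeMap":
        mapping = {n: n for n in neurons}
        spec = set(sex_specific)
        return cls(mapping, {n: (n in spec) for n in mapping.values()})


def read_connectome(
    path: str | Path,
    sep: str | None = None,
    columns: Mapping[str, str] | None = None,
) -> ConnectomeTable:
    """Read a delimited synapse table with a header.

    Default column names are ``pre``, ``post``, ``type``, ``count``; pass
    ``columns={"pre": ..., "post": ..., "kind": ..., "count": ...}`` to rename.
    ``sep=None`` sniffs the delimiter (TSV and CSV both work).  Malformed rows
    raise :class:`ConnectomeFormatError` naming the offending line.
    """
    path = Path(path)
    names = {"pre": "pre", "post": "post", "kind": "type", "count": "count"}
    if columns:
        names.update(columns)
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = [c for c in names.values() if c not in df.columns]
    if missing:
        raise ConnectomeFormatError(
            f"{path.name}: missing column(s) {missing}; found {list(df.columns)}"
        )
    records: list[SynapseRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        raw = getattr(row, "_asdict", None)
        d = row._asdict() if raw else dict(zip(df.columns, row))
        cnt = d[names["count"]]
        if isinstance(cnt, float):
            if not cnt.is_integer():
                raise ConnectomeFormatError(f"{path.name} line {i}: non-integer count {cnt!r}")
            cnt = int(cnt)
        try:
            cnt = int(cnt)
        except (TypeError, ValueError):
            raise ConnectomeFormatError(f"{path.name} line {i}: non-integer count {cnt!r}") from None
        try:
            rec = SynapseRecord(
                pre=str(d[names["pre"]]).strip(),
                post=str(d[names["post"]]).strip(),
                kind=SynapseKind.parse(d[names["kind"]]),
                count=cnt,
            )
        except ConnectomeFormatError as exc:
            raise ConnectomeFormatError(f"{path.name} line {i}: {exc}") from None
        records.append(rec)
    return ConnectomeTable(records=records, provenance=str(path))


def read_merge_map(path: str | Path, sep: str = "\t") -> MergeMap:
    """Read a merge map TSV with columns ``neuron``, ``node`` and an optional
    ``sex_specific`` column (0/1 or true/false, flagging the *node*)."""
    df = pd.read_csv(path, sep=sep)
    for col in ("neuron", "node"):
        if col not in df.columns:
            raise ConnectomeFormatError(f"merge map {path}: missing column {col!r}")
    mapping = dict(zip(df["neuron"].astype(str), df["node"].astype(str)))
    spec: dict[str, bool] = {}
    if "sex_specific" in df.columns:
        for node, flag in zip(df["node"].astype(str), df["sex_specific"]):
            truthy = str(flag).strip().lower() in ("1", "true", "yes")
            spec[node] = spec.get(node, False) or truthy
    return MergeMap(mapping, spec)


_LR_SUFFIX = re.compile(r"^(?P<base>.+?)(?P<side>[LR])$")


def _default_exceptions() -> dict[str, str]:
    """Editable package-data table of neurons exempt from the L/R rule, or
    remapped to a non-default node (dorsal/ventral RMD classes -> RMD_DV)."""
    out: dict[str, str] = {}
    text = resources.files("wormnet.data").joinpath("merge_exceptions.tsv").read_text()
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        out[row["neuron"].strip()] = row["node"].strip()
    return out


def infer_merge_map(
    neurons: Iterable[str],
    sex_specific_neurons: Iterable[str] = (),
    exceptions: Mapping[str, str] | None = None,
) -> MergeMap:
    """Derive a merge map from standard worm nomenclature rules.

    A neuron ending in L or R merges with its partner (same base name, other
    side) into the base-named node when the partner is present.  Functionally
    distinct left/right neurons (ASEL/ASER) stay separate, and the four RMD
    dorsal/ventral neurons merge into RMD_DV, via the exceptions table.  A node
    is flagged sex-specific when any constituent neuron is.
    """
    neurons = list(dict.fromkeys(str(n) for n in neurons))
    exc = _default_exceptions() if exceptions is None else dict(exceptions)
    present = set(neurons)
    mapping: dict[str, str] = {}
    for n in neurons:
        if n in exc:
            mapping[n] = exc[n]
            continue
        m = _LR_SUFFIX.match(n)
        if m:
            base, side = m.group("base"), m.group("side")
            partner = base + ("R" if side == "L" else "L")
            if partner in present and partner not in exc:
                mapping[n] = base
                continue
        mapping[n] = n
    spec_neurons = set(sex_specific_neurons)
    sex_specific: dict[str, bool] = {}
    for neuron, node in mapping.items():
        sex_specific[node] = sex_specific.get(node, False) or (neuron in spec_neurons)
    return MergeMap(mapping, sex_specific)


def electrical_as_reciprocal(record: SynapseRecord) -> tuple[tuple[str, str, int], tuple[str, str, int]]:
    """Expand one electrical (gap-junction) record into its two reciprocal
    directed weight increments: one electrical synapse between A and B is
    equivalent to two reciprocal chemical synapses."""
    if record.kind is not SynapseKind.ELECTRICAL:
        raise ValueError("electrical_as_reciprocal requires an electrical record")
    return (
        (record.pre, record.post, record.count),
        (record.post, record.pre, record.count),
    )


def build_network(table: ConnectomeTable, merge: MergeMap) -> nx.DiGraph:
    """Aggregate a synapse table into the functional directed-weighted network.

    Chemical records add their count to the merged pre->post edge; electrical
    records add their count in both directions.  Records whose endpoints merge
    to the same node would be self-loops: the paper's graphs carry none, so
    they are dropped from the edge set but tallied in ``G.graph`` diagnostics
    (``self_loop_weight``, ``self_loop_records``) to keep totals auditable.
    """
    G = nx.DiGraph()
    for node in dict.fromkeys(merge.mapping.values()):
        G.add_node(node, sex_specific=merge.node_is_specific(node))
    self_loop_weight = 0
    self_loop_records = 0
    for rec in table:
        u, v = merge[rec.pre], merge[rec.post]
        if rec.kind is SynapseKind.ELECTRICAL:
            increments = electrical_as_reciprocal(rec)
            increments = [(merge[a], merge[b], c) for a, b, c in increments]
        else:
            increments = [(u, v, rec.count)]
        for a, b, c in increments:
            if a == b:
                self_loop_weight += c
                self_loop_records += 1
                continue
            G.add_edge(a, b, weight=G.edges[a, b]["weight"] + c if G.has_edge(a, b) else c)
    G.graph["self_loop_weight"] = self_loop_weight
    G.graph["self_loop_records"] = self_loop_records
    return G


def total_weight(G: nx.DiGraph) -> int:
    """Sum of all directed edge weights."""
    return sum(w for _, _, w in G.edges(data="weight"))


def write_network(net: nx.DiGraph, path: str | Path, fmt: str | None = None) -> Path:
    """Write a network as an edge-list TSV (source, target, weight; edges only)
    or as GraphML (full fidelity: isolated nodes and node attributes).
    ``fmt`` is inferred from the suffix (.tsv / .graphml) when omitted."""
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "tsv")
    if fmt == "graphml":
        nx.write_graphml(net, path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in sorted(net.edges(data="weight")):
                fh.write(f"{u}\t{v}\t{w}\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def read_network(path: str | Path, fmt: str | None = None) -> nx.DiGraph:
    """Read a network written by :func:`write_network`."""
    path = Path(path)
    fmt = fmt or ("graphml" if path.suffix == ".graphml" else "tsv")
    if fmt == "graphml":
        G = nx.read_graphml(path)
        out = nx.DiGraph()
        out.graph.update(G.graph)
        for n, d in G.nodes(data=True):
            out.add_node(str(n), **d)
        for u, v, d in G.edges(data=True):
            out.add_edge(str(u), str(v), weight=int(d["weight"]))
        return out
    df = pd.read_csv(path, sep="\t")
    G = nx.DiGraph()
    for row in df.itertuples(index=False):
        G.add_edge(str(row.source), str(row.target), weight=int(row.weight))
    return G
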