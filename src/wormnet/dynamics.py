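"""Passive (RC) membrane dynamics on a functional connectome.

Every neuron obeys the same leaky membrane equation

    c dV/dt = -g_Na (V - E_Na) - g_K (V - E_K) - g_L (V - E_L) + I_ext

with fixed sodium, potassium and leak conductances (no gating, no spikes:
most C. elegans neurons are non-spiking).  A connection carrying N synapses
from neuron A to neuron B injects a linear diffusive current into B only:

    I_{A->B} = k * N * (V_A - V_B)

so the synaptic graph is used exactly as a directed weighted coupling matrix;
reciprocal edge pairs (from gap junctions) couple both ways.

The stimulation protocol clamps one neuron's potential (a Dirichlet condition,
not an injected current) to V_clamp for the clamp window while every other
neuron evolves freely.  Responses are measured against a matched control
trajectory run from the same initial condition with no clamp: the uncoupled
equilibrium of the membrane equation is the conductance-weighted reversal
average E_eff, not the -60 mV initial condition, so every neuron drifts toward
E_eff even without stimulation — subtracting the control isolates the
stimulus-driven change.  The response magnitude is the maximum absolute
deviation from control during the clamp window (a time-integrated variant is
available).

The system is linear but stiff (coupling terms k*N reach 1e3-1e4), so the
explicit integrator (classical RK4) enforces the step bound

    dt < c / (g_Na + g_K + g_L + k * max_j in_strength(j))

derived from a Gershgorin estimate of the spectrum; the default step is half
the bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "RCParams",
    "SimTrace",
    "ResponseMatrix",
    "InfluenceScores",
    "derivative",
    "integrate",
    "stimulate_all",
    "strongest_responder",
    "functional_pairs",
    "pair_conservation",
    "influence_scores",
]


@dataclass(frozen=True)
class RCParams:
    """Membrane and protocol parameters (model units; potentials in mV,
    time in model seconds)."""

    c: float = 1.0
    g_na: float = 120.0
    g_k: float = 36.0
    g_leak: float = 0.03
    e_na: float = 50.0
    e_k: float = -77.0
    e_leak: float = -54.4
    k: float = 100.0
    v_init: float = -60.0
    v_clamp: float = 60.0
    t_clamp: float = 40.0
    t_total: float | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        if min(self.g_na, self.g_k, self.g_leak) < 0:
            raise ValueError("conductances must be non-negative")
        if self.dt is not None and self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.t_total is not None and self.t_total < self.t_clamp:
            raise ValueError("t_total must be >= t_clamp")

    @property
    def g_total(self) -> float:
        return self.g_na + self.g_k + self.g_leak

    @property
    def e_eff(self) -> float:
        """Conductance-weighted reversal average: the uncoupled fixed point."""
        return (self.g_na * self.e_na + self.g_k * self.e_k
                + self.g_leak * self.e_leak) / self.g_total

    @property
    def tau(self) -> float:
        """Uncoupled membrane time constant c / g_total."""
        return self.c / self.g_total

    def stability_bound(self, max_in_strength: float) -> float:
        return self.c / (self.g_total + self.k * max_in_strength)

    def resolve_dt(self, max_in_strength: float) -> float:
        bound = self.stability_bound(max_in_strength)
        if self.dt is None:
            return bound / 2.0
        if self.dt >= bound:
            raise ValueError(
                f"dt={self.dt:g} violates the explicit stability bound "
                f"dt < {bound:g} for this network"
            )
        return self.dt


def weight_matrix(net: nx.DiGraph, nodes: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Dense coupling matrix W with W[i, j] = synapse count of edge i->j."""
    nodes = list(nodes) if nodes is not None else sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    W = np.zeros((len(nodes), len(nodes)))
    for u, v, w in net.edges(data="weight"):
        W[idx[u], idx[v]] = float(w)
    return nodes, W


def derivative(
    v_all: Mapping[str, float], net: nx.DiGraph, params: RCParams
) -> dict[str, float]:
    """dV/dt for every node at the given potentials.

    The synaptic current into B sums k * E_{A->B} * (V_A - V_B) over the
    in-edges of B: a directed chemical edge drives only its target, while the
    reciprocal edge pair left by a gap junction drives both partners.
    """
    if set(v_all) != set(net.nodes):
        raise ValueError("v_all must supply a potential for every network node")
    nodes, W = weight_matrix(net)
    v = np.array([v_all[n] for n in nodes])
    dv = _dv(v, W, W.sum(axis=0), params)
    return dict(zip(nodes, dv))


def _dv(v: np.ndarray, W: np.ndarray, in_strength: np.ndarray, params: RCParams) -> np.ndarray:
    # v: (..., n); I_ext[j] = k (sum_i W[i,j] v_i - in_strength[j] v_j)
    i_ext = params.k * (v @ W - in_strength * v)
    g_e = params.g_na * params.e_na + params.g_k * params.e_k + params.g_leak * params.e_leak
    return (-params.g_total * v + g_e + i_ext) / params.c


@dataclass
class SimTrace:
    """Membrane-potential time series, one column per node."""

    times: np.ndarray
    potentials: np.ndarray  # shape (len(times), n_nodes)
    nodes: list[str]

    def series(self, node: str) -> np.ndarray:
        return self.potentials[:, self.nodes.index(node)]


def _rk4_steps(
    v: np.ndarray,
    W: np.ndarray,
    in_strength: np.ndarray,
    params: RCParams,
    dt: float,
    n_steps: int,
    clamp_rows: np.ndarray | None = None,
    clamp_cols: np.ndarray | None = None,
    t0: float = 0.0,
    clamp_window: tuple[float, float] | None = None,
    observer=None,
) -> np.ndarray:
    """Advance ``v`` (batch of states, shape (..., n)) by n_steps of RK4.

    During the clamp window the state entries (clamp_rows, clamp_cols) are
    held at v_clamp and their derivative is masked to zero in every stage,
    realizing a Dirichlet condition.  ``observer(step_index, v)`` is called
    after each step.
    """
    v = v.copy()

    def deriv(x: np.ndarray, clamped: bool) -> np.ndarray:
        d = _dv(x, W, in_strength, params)
        if clamped and clamp_rows is not None:
            d[clamp_rows, clamp_cols] = 0.0
        return d

    for step in range(n_steps):
        t = t0 + step * dt
        clamped = (
            clamp_window is not None
            and clamp_window[0] <= t < clamp_window[1]
        )
        if clamped and clamp_rows is not None:
            v[clamp_rows, clamp_cols] = params.v_clamp
        k1 = deriv(v, clamped)
        k2 = deriv(v + 0.5 * dt * k1, clamped)
        k3 = deriv(v + 0.5 * dt * k2, clamped)
        k4 = deriv(v + dt * k3, clamped)
        v = v + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        if clamped and clamp_rows is not None:
            v[clamp_rows, clamp_cols] = params.v_clamp
        if observer is not None:
            observer(step, v)
    return v


def integrate(
    net: nx.DiGraph,
    params: RCParams,
    clamp: tuple[str, tuple[float, float]] | None = None,
    record_every: int | None = None,
) -> SimTrace:
    """Integrate the network from V_init, optionally clamping one node.

    ``clamp`` is (node, (t_start, t_end)) with the window inside
    [0, t_total]; the clamped node sits exactly at V_clamp during the window
    and evolves freely outside it.  ``record_every`` keeps every k-th step
    (default: thinned to at most ~4000 samples).
    """
    nodes, W = weight_matrix(net)
    in_strength = W.sum(axis=0)
    t_total = params.t_total if params.t_total is not None else params.t_clamp
    dt = params.resolve_dt(float(in_strength.max()) if len(nodes) else 0.0)
    n_steps = int(np.ceil(t_total / dt))
    stride = record_every or max(1, n_steps // 4000)

    clamp_rows = clamp_cols = None
    window = None
    if clamp is not None:
        node, window = clamp
        if not (0.0 <= window[0] <= window[1] <= t_total):
            raise ValueError("clamp window must lie within [0, t_total]")
        clamp_rows = np.array([0])
        clamp_cols = np.array([nodes.index(node)])

    v = np.full((1, len(nodes)), params.v_init, dtype=float)
    times = [0.0]
    frames = [v[0].copy()]

    def observer(step: int, state: np.ndarray) -> None:
        if (step + 1) % stride == 0 or step == n_steps - 1:
            times.append((step + 1) * dt)
            frames.append(state[0].copy())

    _rk4_steps(v, W, in_strength, params, dt, n_steps,
               clamp_rows, clamp_cols, 0.0, window, observer)
    return SimTrace(times=np.array(times), potentials=np.array(frames), nodes=nodes)


@dataclass
class ResponseMatrix:
    """response[i, j]: magnitude of node j's deviation from control while node
    i was clamped; the diagonal is excluded (zero)."""

    nodes: list[str]
    response: np.ndarray  # (n, n), diagonal 0

    def row(self, node: str) -> dict[str, float]:
        i = self.nodes.index(node)
        return {m: float(self.response[i, j]) for j, m in enumerate(self.nodes) if j != i}


def stimulate_all(
    net: nx.DiGraph, params: RCParams, response: str = "max"
) -> ResponseMatrix:
    """Clamp every node in turn to V_clamp for t_clamp and record the other
    nodes' deviations from a matched no-clamp control trajectory.

    ``response="max"``: maximum absolute deviation over the clamp window
    (default).  ``response="integral"``: time integral of |deviation|.
    All trajectories (one per stimulated node, plus the control) are advanced
    together in one batch, so nodes unreachable from the stimulated node
    reproduce the control arithmetic exactly and score exactly zero.
    """
    if response not in ("max", "integral"):
        raise ValueError("response must be 'max' or 'integral'")
    nodes, W = weight_matrix(net)
    n = len(nodes)
    in_strength = W.sum(axis=0)
    dt = params.resolve_dt(float(in_strength.max()) if n else 0.0)
    n_steps = int(np.ceil(params.t_clamp / dt))

    # rows 0..n-1: run clamping node i; row n: control.
    v = np.full((n + 1, n), params.v_init, dtype=float)
    clamp_rows = np.arange(n)
    clamp_cols = np.arange(n)
    resp = np.zeros((n, n))

    def observer(step: int, state: np.ndarray) -> None:
        dev = np.abs(state[:n] - state[n])
        if response == "max":
            np.maximum(resp, dev, out=resp)
        else:
            np.add(resp, dev * dt, out=resp)

    _rk4_steps(v, W, in_strength, params, dt, n_steps,
               clamp_rows, clamp_cols, 0.0, (0.0, params.t_clamp), observer)
    np.fill_diagonal(resp, 0.0)
    return ResponseMatrix(nodes=nodes, response=resp)


def strongest_responder(rm: ResponseMatrix, node: str) -> str | None:
    """The responder with the largest response to stimulating ``node``; ties
    break to the lexicographically smallest name, and an all-zero row (no
    reachable responder) returns None."""
    row = rm.row(node)
    if not row:
        return None
    best = min(row.items(), key=lambda kv: (-kv[1], kv[0]))
    if best[1] == 0.0:
        return None
    return best[0]


def functional_pairs(rm: ResponseMatrix) -> dict[str, str | None]:
    """(stimulated neuron -> strongest responder) for every node."""
    return {n: strongest_responder(rm, n) for n in rm.nodes}


def pair_conservation(rm_a: ResponseMatrix, rm_b: ResponseMatrix) -> float:
    """Fraction of shared stimulated nodes (with a defined strongest responder
    in both networks) whose responder is identical."""
    pa, pb = functional_pairs(rm_a), functional_pairs(rm_b)
    shared = [n for n in pa if n in pb and pa[n] is not None and pb[n] is not None]
    if not shared:
        raise ValueError("no shared stimulated nodes with defined responders")
    return sum(pa[n] == pb[n] for n in shared) / len(shared)


@dataclass
class InfluenceScores:
    """Row sums (upstream: total change a node causes elsewhere when
    stimulated) and column sums (downstream: total change a node shows when
    everything else is stimulated) of the response matrix."""

    upstream: dict[str, float]
    downstream: dict[str, float]


def influence_scores(rm: ResponseMatrix) -> InfluenceScores:
    up = rm.response.sum(axis=1)
    down = rm.response.sum(axis=0)
    return InfluenceScores(
        upstream={n: float(up[i]) for i, n in enumerate(rm.nodes)},
        downstream={n: float(down[i]) for i, n in enumerate(rm.nodes)},
    )
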