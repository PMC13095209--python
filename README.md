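# wormnet

Directed-weighted connectome analysis and passive network dynamics for the
sexually dimorphic neural networks of *Caenorhabditis elegans*.

The male and hermaphrodite worm connectomes differ both in which neurons
exist (sex-specific vs sex-shared) and in how strongly shared neurons are
wired. `wormnet` is for researchers who want to quantify those differences
from raw synapse tables: it builds functional networks by merging
functionally equivalent neurons, computes structural metrics tailored to
synapse-count-weighted directed graphs, simulates whole-network responses to
single-neuron stimulation, and turns rankings into coarse behavioral-output
predictions.

## The model in brief

A connectome is a directed graph whose edge weight E_{u→v} is the synapse
count of the connection; one electrical synapse counts as two reciprocal
chemical synapses. On this graph:

* node strength s(u) = Σ_v E_{u→v} + Σ_v E_{v→u} (out- plus in-strength);
* a path's length is Σ 1/E over its edges (reciprocal weights: strong
  connections are functionally *short*), and shortest paths minimize it;
* betweenness of u is the fraction of all shortest paths whose node sequence
  contains u, endpoints included.

Dynamics: every neuron obeys the passive membrane equation
c dV/dt = −g_Na(V−E_Na) − g_K(V−E_K) − g_L(V−E_L) + I_ext with a linear
diffusive synaptic current I_{A→B} = k·N·(V_A−V_B). Clamping one neuron to
+60 mV for 40 s and comparing every other neuron against a matched unclamped
control yields a stimulus→response matrix; its row sums rank neurons as
upstream drivers, its column sums as downstream integrators. See
`docs/methods.md` for assumptions, numerics and limitations.

## Worked example

The four-neuron demonstration network (A→B:2, A→D:3, B→C:2, B→D:2, C→A:3,
C→D:1, D→B:4) pins every definition down:

```python
>>> import wormnet as wn
>>> net = wn.worked_example()
>>> for m in wn.node_strengths(net): print(m)
NodeMetrics(node='A', strength=8, out_strength=5, in_strength=3)
NodeMetrics(node='B', strength=10, out_strength=4, in_strength=6)
NodeMetrics(node='C', strength=6, out_strength=4, in_strength=2)
NodeMetrics(node='D', strength=10, out_strength=4, in_strength=6)
>>> inv = wn.shortest_paths(net)
>>> len(inv), inv.unreachable_pairs
(12, 0)
>>> wn.betweenness(net, inv)['D']
Fraction(1, 2)
```

A has 5 outgoing synapses (2 to B, 3 to D) and 3 incoming, hence strength 8.
There are 12 shortest paths over the 12 ordered node pairs; 6 of them contain
D, so D's betweenness is 6/12 = 0.5 exactly (lengths and centralities are
exact rationals). Stimulating neurons through the RC model:

```python
>>> from wormnet.dynamics import RCParams, stimulate_all, influence_scores
>>> rm = stimulate_all(net, RCParams())
>>> wn.strongest_responder(rm, 'A')
'D'
>>> {k: round(v, 1) for k, v in influence_scores(rm).upstream.items()}
{'A': 111.3, 'B': 100.8, 'C': 121.4, 'D': 83.5}
```

Clamping A perturbs D hardest (A→D carries 3 synapses and D is heavily
recurrently wired); the upstream scores are each neuron's summed influence,
in mV, on the rest of the network.

## Command line

Every step is scriptable: `wormnet synth` (synthetic connectome tables),
`build` (table + merge map → network file), `metrics`, `diff`, `simulate`,
`influence`, `predict`, `calcium`, `choice`. For example:

```sh
wormnet synth --n-nodes 100 --seed 1 --out demo/
wormnet build demo/synapses.tsv demo/merge.tsv --out demo/net.graphml
wormnet metrics demo/net.graphml
```

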