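# Methods

## Scope and data model

`wormnet` analyzes functional connectomes of *C. elegans* males and
hermaphrodites as directed weighted graphs. The raw input is a per-synapse
table (pre neuron, post neuron, chemical/electrical, synapse count), such as
the published adult male and hermaphrodite reconstructions. Three rules turn
it into the functional network:

1. **Merging.** Functionally equivalent neurons (bilateral L/R pairs, the
   four dorsal/ventral RMD neurons) are consolidated into one node and their
   synapse counts are summed. Functionally distinct left/right neurons
   (ASEL/ASER, and by the same logic AWCL/AWCR) stay separate. The full
   curated map for the published nomenclature is not distributable here, so
   the package ships the *rules* (`infer_merge_map`) plus an editable
   exceptions table (`data/merge_exceptions.tsv`); any explicit neuron→node
   TSV is accepted as well, which is how a curated map would be supplied.
2. **Gap junctions.** One electrical synapse couples both partners, so each
   electrical record adds its count to both directed edges (equivalent to two
   reciprocal chemical synapses).
3. **Self-loops.** Merging can turn intra-pair synapses (e.g. ADAL→ADAR)
   into self-loops. The functional graphs carry no self-edges, so these are
   excluded from the edge set — but their weight is tallied in the build
   diagnostics (`G.graph["self_loop_weight"]`) so that total synapse weight
   remains auditable: Σ edge weights + dropped self-loop weight = Σ chemical
   counts + 2 × Σ electrical counts, always. Whether intra-pair weight should
   instead count toward node strength is not decidable from the four-neuron
   example; dropping it is the package's documented choice and the
   diagnostics make the alternative easy to audit.

Sex-specific flags are supplied with the merge map (never inferred from
names). The **sex-specific sub-network** is the sub-graph induced on the
sex-specific nodes plus every node sharing an edge with one in either
direction; the **sex-shared sub-network** is induced on the non-specific
nodes.

## Graph metrics

* **Node strength** — total synapse count attached to a node; out-strength
  and in-strength are the directed halves.
* **Path length** — Σ over a path's edges of 1/(edge weight). Strong
  connections are functionally short. Lengths are exact rationals
  (`fractions.Fraction`), so minimality and ties are decided exactly rather
  than at float precision; Dijkstra (networkx) runs unchanged over rationals.
* **Shortest paths** — for every ordered pair of distinct nodes, *all*
  co-minimal simple paths are stored by default (a `ties="single"` switch
  keeps one deterministic representative; the four-neuron example has unique
  minima and is unaffected). Unreachable ordered pairs are counted and
  excluded from every denominator. Storing all co-minimal paths avoids an
  arbitrary selection bias when ties occur.
* **Betweenness centrality** — the fraction of stored shortest paths whose
  node sequence contains the node, *endpoints included*. The endpoint-
  inclusive convention is forced by the worked four-neuron network: node D is
  an intermediate of no shortest path there, yet scores 6/12 = 0.5 — the six
  paths containing D all have it as an endpoint.
* **Cross-sex differences** — per-node (or per-edge / per-pair) differences
  of a metric over the shared domain, positive meaning larger in the first
  network.
* **Distribution fit** — node strengths are tested against an exponential
  law by maximum likelihood (rate = 1/mean) with a one-sample
  Kolmogorov–Smirnov test against the fitted distribution. Group panels use
  a two-sample two-tailed Student's t-test with mean ± SEM summaries; no
  multiple-testing correction is applied, matching per-panel testing
  practice.

## Network dynamics

Each neuron follows the passive membrane equation

    c dV/dt = −g_Na (V − E_Na) − g_K (V − E_K) − g_L (V − E_L) + I_ext

with c = 1.0, g_Na = 120.0, g_K = 36.0, g_L = 0.03, E_Na = 50 mV,
E_K = −77 mV, E_L = −54.4 mV, and a connection of N synapses from A to B
injects I = k·N·(V_A − V_B) into B only, with k = 100.0. There is no gating
and no spiking (most worm neurons are non-spiking), no rectification and no
per-synapse reversal potential: the graph acts purely as a linear diffusive
coupling. Time is in abstract model seconds; parameters are used exactly as
stated, including g_L = 0.03.

**Protocol.** All neurons start at V_init = −60 mV with no pre-equilibration.
Stimulation clamps one neuron to +60 mV for 40 model seconds as a Dirichlet
condition (the state is overwritten each step, not driven by a current), then
releases it. Note −60 mV is *not* a fixed point of the uncoupled equation —
its equilibrium is the conductance-weighted reversal average
E_eff = (g_Na E_Na + g_K E_K + g_L E_L)/(g_Na+g_K+g_L) ≈ +20.68 mV — so the
whole network drifts toward E_eff even unstimulated. The response of neuron j
to stimulating neuron i is therefore measured against a matched control
trajectory (same initial state, no clamp): by default the maximum absolute
deviation |V_j^clamped − V_j^control| over the clamp window, which matches a
"strongest response" reading; a time-integrated |ΔV| variant is available.
The clamp window is also the observation window. Strongest-responder
functional pairs, their conservation fraction between two networks, and
upstream (row-sum) / downstream (column-sum) influence scores derive from
this response matrix.

**Numerics.** The system is linear but stiff: coupling coefficients k·N reach
10³–10⁴ against a leak of ≈156. The integrator is classical explicit RK4
with the enforced Gershgorin-derived step bound
dt < c / (g_Na + g_K + g_L + k · max_j in-strength(j)); the default step is
half the bound, and a user-supplied dt beyond the bound is refused with the
bound printed. RK4 (rather than a first-order scheme) is used so the
uncoupled closed form V(t) = E_eff + (V_init − E_eff)·e^(−t/τ),
τ = c/(g_Na+g_K+g_L), is matched to better than 10⁻⁶ mV at practical step
sizes; the test suite verifies ~4th-order error decay under dt-halving.
All clamp trajectories and the control advance together in one batched state
matrix, which makes the response matrix bit-reproducible and makes the
response of any node unreachable from the stimulus *exactly* zero (identical
floating-point arithmetic cancels in the subtraction). Responses within a
permutation-symmetric network agree to matmul round-off (~1 ulp), which is
what the symmetry tests assert.

## Behavior-category tallies

Top-k nodes of any ranking (strength, betweenness, influence) are tallied
against a node → behavior-category annotation. A node with m categories
contributes 1/m to each (fractional attribution keeps the tally summing to
k; a full-count switch exists), and unannotated nodes are tallied under
`unannotated`. The shipped annotation (`data/behavior_categories.tsv`) is a
coarse literature-derived default intended for qualitative comparisons only —
the tallies depend entirely on the annotation supplied, so no numeric
category percentages are claimed.

## Assay scores

* **Choice index** = (n on pheromone lawns − n off) / (n on + n off) ∈ [−1, 1].
* **Calcium events** — F₀ is the mean of the first ⌈5%⌉ of frames (which
  frames form the baseline is an open choice; a "dimmest 5%" switch exists),
  ΔF/F₀ = (F − F₀)/F₀, and an event is a maximal contiguous run of frames
  with ΔF/F₀ > 1. Events separated by even a single sub-threshold frame are
  distinct (no gap merging is specified, so none is applied). Counts are also
  reported per minute via the frame rate (default 4.84 fps).

## Synthetic data

The generator emits neuron-level synapse tables with the statistical
structure the analyses assume: bilateral L/R pairs that merge (50% of neurons
by default — 100 neurons → 75 nodes), a sex-specific node subset (25% of
nodes, matching the male-specific share of the real merged network, 41/161),
mixed chemical/electrical records (20% electrical, stored once per unordered
pair and expanded at build time), and approximately exponential node-strength
distributions. Exponential strengths arise by construction: each node gets an
exponential activity, edges pick endpoints with activity-proportional
probability, and per-edge synapse counts are geometric (rate 0.35, mean ≈2.9)
— a Poisson count mixed over an exponential rate is geometric, the discrete
exponential analog. Mean degree defaults to 8 connections per node. A
calibration helper regenerates networks over 100 seeds and reports the
fraction passing the exponential KS fit at α = 0.01 (zero-strength nodes are
excluded, the fit being defined on positive values); the defaults pass in
100/100 seeds.

What the generator does **not** emulate: real worm wiring (no attempt at
anatomical realism, community structure, pharyngeal isolation, or the actual
dimorphic edge set). Passing tests on synthetic data therefore demonstrate
correctness of the *computations* — conservation, metric definitions, solver
fidelity, pipeline round-trips — not biological conclusions about the real
networks, which require the published tables plus a curated merge map.

## Problem sizes and determinism

The test suite runs brute-force path-enumeration equivalence on 200 random
graphs of ≤ 8 nodes, conservation on 500 generated networks, and the
stimulation protocol on networks of ~15 merged nodes — sizes chosen so the
whole suite completes in about a minute while exercising every code path;
the same code runs unmodified on connectome-scale networks. All randomness
flows through seeded `numpy.random.Generator` instances; fixed seeds
reproduce tables byte-identically and response matrices bit-identically.

## Known limitations

* The dynamics are linear and sign-free: inhibitory transmitters, synaptic
  rectification and per-synapse reversal potentials are out of scope, so
  response magnitudes order influence but do not predict signed physiology.
* Betweenness counts endpoint occurrences by definition here; values are not
  comparable to the conventional intermediate-only centrality.
* The exponential fit uses the KS test with an estimated rate, which is
  conservative (the true null distribution of the statistic is tighter);
  it is used as a shape check, not a calibrated goodness-of-fit p-value.
* Dense coupling matrices make the simulator O(n²) per step; fine for
  connectome-scale n (~160) but not for much larger graphs.
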