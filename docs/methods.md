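# Methods

## Model

One Monte Carlo step (MCS) advances the population as follows:

1. every isolated (degree-0) node redraws its strategy uniformly from
   {cooperate, defect};
2. every centered group plays one public goods game and each node's
   round payoff π is stored (strategies are frozen within the round);
3. the current neighbor sets are snapshotted as the imitation
   reference;
4. **stage A, breaking** — each edge's breaking value is computed, its
   weight updated (−1 satisfying / +3 not, clamped to [0, m_max]), and
   the edge removed with probability F(w; λ), the Poisson CDF;
5. **stage C, isolated rejoin** — isolated cooperators attach one new
   edge into the largest component with probability p_isolated;
6. **stage B, dominant reconnection** — cooperators with π > 0 inside
   the largest component, in seeded random order, each attach one new
   edge to a random non-isolated cooperator that is not already a
   neighbor, until the edge cap is reached;
7. one synchronous Fermi update: every node with a nonempty reference
   set draws one reference neighbor and adopts its (pre-update)
   strategy with probability W = 1/(1 + exp(−(π_y − π_x)/k)).

The mechanism variants gate stages: `BASELINE` runs none of A/B/C,
`BREAK_ONLY` runs A, `BREAK_ISOLATED` A+C, `FULL` all three. Isolated
rejoins are processed before dominant additions so that players
re-entering the game are not crowded out of capped edge slots; a
`stage_order` parameter exists for sensitivity checks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| N | 1000 | population size (preliminary experiments use 100) |
| k0 | 4 | initial regular (ring-lattice) degree |
| r | 2 | gain factor; payoffs are in units of the cost c = 1 |
| k_noise | 0.1 | Fermi noise; 0 is the fully rational step-function limit |
| λ (`lam`) | 6 | mean of the Poisson CDF mapping weight → removal probability |
| m_max | 10 | breaking-weight ceiling (floor 0; new edges start at 0) |
| p_isolated | 0.5 | isolated-cooperator reconnection probability |
| edge_cap | N·k0/2 | hard edge-count ceiling = the initial edge count |
| init_coop_fraction | 0.5 | i.i.d. initial cooperation probability |
| steps | 100 | MCS per run; replicates 20, averaged |

With λ = 6 and m_max = 10 the removal probability runs from
F(0) = e^{−6} ≈ 0.0025 (a small attrition floor on satisfied edges) to
F(6) ≈ 0.61 after two unsatisfying rounds and F(10) ≈ 0.96 at the
ceiling.

## Interpretation choices

Several micro-rules are underdetermined by the usual verbal statement
of such models; the package fixes them explicitly and exposes each as
a parameter.

**Breaking value** (`value_mode`). `edge_attributed` (default)
symmetrizes the per-edge payoff attribution over both centered games:
x's share from the edge, (r·s_y − s_x)/g_x, plus y's full payoff in
the x-centered game, r·n_c/g_x − s_y, plus the mirror terms from the
y-centered game. `node_total` uses π_x + π_y. Both are implemented and
the headline behavior is qualitatively the same.

**Zero-value ties** (`zero_value_satisfies`, default False). In any
defector-only region every payoff, and hence every breaking value, is
exactly 0. The default counts such payoff-dead edges as *unsatisfying*:
regions that produce nothing keep fragmenting, their members end up
isolated, and the coin-flip strategy refresh plus the rejoin rule feed
them back into the productive component — this is the engine of
cooperation recovery at small r. Setting True (an edge "at least loses
nothing" is satisfying) freezes dead regions; full defection then
becomes absorbing and at r = 2 the model collapses permanently within
about ten steps. The choice is a knife-edge of the model and is worth
a sensitivity run in any application.

**Rejoin target** (`isolated_target`, default `"cooperator"`). The
rejoin rule only says the isolated cooperator attaches to the largest
component. Attaching to a uniform member almost always lands on a
defector during the post-crash phase, and the re-entrant is converted
before cooperative clusters can nucleate (stationary cooperation stays
near 0.2 with average degree near 1). The default attaches to a
uniform *cooperative* member when one exists (uniform member
otherwise), reading the rejoin as an act of the cooperative community;
this lets clusters nucleate and the degree re-stabilize.

**Isolated strategy refresh** (`isolated_strategy`). Fermi imitation
is undefined without neighbors; uniform resampling (default) is the
minimal mechanism by which an isolated player can "choose" to
cooperate and become eligible to rejoin. `hold` freezes isolated
nodes instead.

**Reference neighbors.** Imitation uses the neighbor sets from before
stage A — players imitate the partners they actually played with this
round, even if the edge has just broken.

**Synchronous updates** (`update_mode`). All adoptions are computed
from one pre-update snapshot and applied simultaneously, consistent
with strategies being frozen within a round. An asynchronous
seeded-order variant exists for sensitivity checks only.

**Entropy** (`entropy_mode`). H_nn is a Shannon entropy over the
half-up-rounded excess average degrees [⟨D_nn⟩_x]. The default
`binned` mode uses the empirical frequencies of the rounded values:
a regular graph has H = 0 and H grows with degree heterogeneity,
which is what makes the measure usable as an onset indicator. The
alternative `weight` mode normalizes the per-node rounded values
themselves into a probability vector; it equals ln N on any regular
graph (its maximum) and can therefore only fall from the initial
state, so it cannot signal onset by rising. Natural logarithms
throughout; headline comparisons min–max normalize the traces, making
the base immaterial.

## Numerical conventions

- Payoffs are recomputed from scratch each round by a vectorized
  accumulation that is oracle-tested (to 1e−12) against the per-group
  closed forms and a scalar reference path.
- The Fermi probability is computed with the logistic `expit`, safe
  for arbitrarily large payoff gaps; k = 0 is handled as the exact
  step-function limit (0.5 on ties).
- Rounding in the entropy is half-up (`floor(x + 0.5)`), so ⟨D_nn⟩ =
  2.5 counts as 3.
- Degenerate inputs: an empty graph has an empty largest component; a
  graph with no positive excess degree has H = 0; min–max
  normalization of a constant series returns zeros; a cooperator in an
  otherwise empty pool (n_c = 0) is rejected as inconsistent.
- Largest-component ties break toward the component containing the
  smallest node id, so every rule that references "the largest part of
  the network" is deterministic given the graph.
- All randomness flows through one `numpy` Generator per run;
  replicate seeds are split from the base seed via `SeedSequence`
  (recorded in the run manifest), and a trace is a pure function of
  (parameters, seed).
- Edges removed and later re-added restart at weight 0: an EdgeState
  dies with its edge.

## Problem sizes

Headline runs use N = 1000, 100 MCS and 20 replicates (the averaged
traces are smooth at this size; stationary summaries are means over
the final 10 steps). Preliminary gain-factor sweeps use N = 100 with
10 replicates. Both are presets of the test suite and the acceptance
script.

## Known limitations

- At r = 2 the full model's stationary cooperation level depends
  strongly on the tie- and target-interpretation choices above; under
  the defaults it settles near 0.27 (N = 1000), with oscillatory
  replicate-level dynamics (invasion/fragmentation cycles between
  roughly 0.2 and 0.55). Reported values for this class of model are higher
  (≈ 0.68); the residual gap is attributable to unresolvable micro-rule
  ambiguities, not to sampling noise.
- Dominant-node reconnection *depresses* cooperation relative to
  breaking + isolated-rejoin alone in this implementation, consistent
  with the qualitative claim that it weakens the isolated-rejoin
  effect, but it also falls below the breaking-only coin-flip level —
  under breaking alone at r = 2 the network dissolves entirely and the
  "cooperation level" is just the isolated-resampling coin flip (0.5),
  which is not comparable to an interacting population's level.
- At r ≥ 4 cooperation saturates, every edge is satisfying, and the
  average degree pins at the cap (4.0) rather than below it; only the
  r = 2 regime sustains the breaking/rebuilding churn.
- The entropy lead indicator: the onset lead is reproduced (maximal
  cross-correlation at lag +3 in the first 10 MCS under the default
  binned mode), but after cooperation plateaus the entropy keeps
  drifting upward, so late-stage correlation between the normalized
  traces is negative here, not positive.
- The simulator starts from regular ring lattices only; directed,
  weighted-interaction, scale-free or Erdős–Rényi initial topologies
  and heterogeneous costs are out of scope, as is any interactive
  (human-play) mode, and there is no parameter inference — this is a
  forward simulator.
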