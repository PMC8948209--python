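# Methods

This note documents the models, estimators, numerical choices and known
limitations of `epiloc`, in the spirit of a package methods appendix. No
number stated here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Spreading process

The simulator is a synchronous, agent-based Susceptible–Infected process
on an undirected simple graph. One node (chosen uniformly at random
unless fixed) is infected at time 0. At each discrete step, every edge
between an infected and a susceptible node transmits independently with
probability β ∈ (0, 1]; a susceptible node with j infected neighbours is
therefore infected with probability 1 − (1 − β)^j, which the simulator
evaluates directly. This collapsed form is exactly equivalent to
independent per-edge trials and makes the update order-free, as a
simultaneous update must be. There is no recovery, so on a connected
graph the process always completes and every node obtains a finite
infection time; `max_steps` exists only as a guard, and the benchmark
layer re-draws truncated runs so that only completed spreads are
evaluated.

The first-passage time over a single link is geometric: mean 1/β,
variance (1 − β)/β². These are the default per-link moments (μ, σ²)
handed to the estimators (`DelayModel.from_beta`). The estimators assume
Gaussian link delays, so feeding them an SI process is a deliberate
model mismatch — the point of the benchmark is precisely how the methods
degrade under it. Both moments are overridable.

## Graphs and preprocessing

Synthetic arenas are Barabási–Albert graphs (attachment m = ⟨k⟩/2,
growth from a complete seed graph on m+1 nodes, always connected) and
Erdős–Rényi G(N, p) with p = ⟨k⟩/(N−1). ER samples can be disconnected;
since the spread cannot leave the source's component and the
distance-based scorers need finite distances, the largest connected
component is retained and reindexed. Empirical networks are read from
plain whitespace edge lists (`#`/`%` comment lines ignored), symmetrised,
de-duplicated, self-loops dropped. Low-degree pruning
(`prune_low_degree`) is iterative: removing a node can push a
neighbour's degree below the threshold, so the filter cascades until a
fixed point — the standard core-style reduction. All preprocessing
reindexes nodes to a dense 0-based range and keeps the original labels
in a side map.

## Observer placement

All deterministic strategies break ties by ascending node index, making
placements reproducible for a fixed preprocessed graph.

- **BC**: betweenness is a per-node sum, so the set-level argmax
  separates into the top-K ranking; computed exactly via networkx.
- **HCR**: greedy. Each pick maximises the number of newly m-covered
  nodes (nodes with ≥ m observer neighbours), starting at m = 1 and
  escalating to m+1 once every node is m-covered. Coverage uses open
  neighbourhoods: an observer does not cover itself. On connected graphs
  the single-coverage phase always has a positive-gain candidate while
  coverage < 1, so coverage reaches 1 before escalation begins.
- **HVO**: the objective counts m-path-covered nodes — nodes lying on at
  least m shortest paths of length ≤ L between observer pairs. Per-node
  path counts for a pair (u, v) use σ(u,w)·σ(w,v) on the shortest-path
  condition d(u,w) + d(w,v) = d(u,v). The initial pair is chosen by
  exhaustive search over all pairs (the seeding rule is otherwise
  underdetermined); later picks escalate multiplicity exactly as HCR.
  Default L is unlimited; it is exposed because small L degenerates the
  objective, in which case the greedy still returns K distinct nodes.
- **RND**: uniform without replacement, seeded.

## Source estimators

All methods score every candidate s and report the full argmax set; ties
are meaningful and feed the precision metric. The reference observer o_0
for LPTV/EPL is the observer with the smallest recorded arrival time
(ties by node index) — consistent with GMLA's "observer one"; the rule
is configurable in the sense that an `ObserverSet` can be constructed
with any times, and is applied deterministically.

**LPTV.** For each candidate s a BFS shortest-path tree rooted at s is
built (deterministic lowest-index parent rule). μ_s holds the scaled
tree-distance differences to o_0; Λ_s is σ² times the number of edges
shared by the tree paths o_0→o_k and o_0→o_i inside that same tree
(computed as symmetric differences of root paths, so the shared-ancestor
segment cancels exactly). Score: μ_sᵀ Λ⁻¹ (d − μ_s/2).

**TRBS** uses absolute times and graph distances, no reference observer;
the score is the negative population variance of the residual vector.
It is invariant to shifting all observed times by a constant.

**PC** correlates hop distances with arrival times. Pearson correlation
is scale- and shift-invariant, so raw hop counts serve as μ_s. A
candidate equidistant from all observers has zero distance variance and
an undefined correlation; it carries no information and receives the
sentinel score −2, strictly below any valid correlation, so it can never
win. If the arrival times themselves are constant every candidate is
undefined; all scores are set to the sentinel and the table is flagged
(`degenerate_times`).

**GMLA** keeps the K₀ observers with the smallest recorded times
(default K₀ = ⌈√N⌉, bounded below by 5 — the constant is a convention of
this package, exposed in `GMLAConfig`) and evaluates candidates with the
LPTV formula on that restricted set. The search starts at observer one
and its neighbours — observer one itself is also scored, since the
source may be an observer — and repeatedly moves to any unvisited
neighbour whose score is at least the running maximum. A visited set
prevents revisiting plateau nodes, guaranteeing termination. Nodes never
visited are absent from the score table and receive the pessimistic
rank N.

**EPL.** The connection between two nodes is the ensemble of all
shortest paths between them. With n = 1 path of length L the delay is
N(Lμ, Lσ²). With n = 2 the delay is min(X₁, X₂) of two such Gaussians
with correlation ρ = (shared edges)/L, collapsed through the closed-form
first two moments of the minimum (the θ = 0 case degenerates to the
pointwise minimum). For n > 2 the same two-path formula is applied with
ρ = 0 — the two-path approximation. μ_s collects these ensemble means
relative to o_0. The covariance is source-independent and computed once
per observer set: Λ_ij is the Jaccard index of the edge unions of the
ensembles o_0→o_i and o_0→o_j, times √(minvar_i · minvar_j), with the
diagonal reducing to the min-distribution variance. Edge unions are
accumulated exactly from the BFS predecessor DAG, independent of the
path-enumeration cap (default 64), so capping only ever truncates the
explicit path list.

On trees every ensemble has n = 1 and EPL's mean vector coincides with
LPTV's; the covariances differ in off-diagonal normalisation (Jaccard vs
raw intersection) but share the diagonal, and the two methods' argmax
agree on the tree instances the suite checks.

**Numerics.** Covariance solves are symmetric linear solves with a ridge
ε·I, ε = 10⁻⁹·max(diag, 1) — never an explicit inverse. The ridge also
handles the σ² = 0 case (β = 1), where exact delay matches dominate the
score and the true source provably attains the maximum. The standard
normal cdf/pdf inside the min-Gaussian moments use scalar `math.erf`
forms because they sit in per-candidate loops. Min-distribution
variances are clamped at 0 against round-off. BFS distances, trees,
path counts and per-pair EPL statistics are memoised on the (immutable)
graph, which is what makes repeated-realisation benchmarks cheap.

## Evaluation

Per-test precision is 1/|argmax set| on a hit, 0 otherwise, averaged
over realisations. Ranks are pessimistic competition ranks (queried node
placed last among its ties; unevaluated nodes get rank N), which makes
CSS_α conservative. CSS_α is the empirical α-quantile of the rank
distribution: the smallest k with at least a fraction α of ranks ≤ k.

`run_cell` evaluates one parameter cell. Synthetic graphs are
regenerated in blocks (default 10 graphs per cell, realisations split
evenly) to average over graph realisations; deterministic placements are
computed once per graph, RND placements re-drawn per graph. Every
realisation draws a fresh random source. All randomness derives from one
master seed via `numpy.random.SeedSequence` spawning, so any cell is
bit-reproducible in isolation. `sweep` flattens a grid of cells into one
table; failed cells are marked and skipped without aborting the sweep.

## Scales used by the shipped checks

The test suite and acceptance script run at desk scale, chosen so the
statistical checks have power while the whole suite stays fast:
deterministic-recovery on 20 connected graphs with N ≤ 50; oracle
comparisons on N ≤ 30 graphs and 10⁶-sample Monte-Carlo grids; the
regime comparison on BA(200, ⟨k⟩ = 8) with observer density 0.2 and 400
realisations (PC vs TRBS at β = 0.2 is tested with a one-sided
two-proportion z-test at 95% confidence; EPL vs PC at β = 0.8 is
reported without a gate because the margin between those two methods is
small at this scale); tree-oracle agreement over 1000 runs with Gaussian
delays N(1, 0.1²). Multi-comparison Monte-Carlo grids carry a Bonferroni
adjustment so the family-wise confidence matches a single 3σ check.

## What the synthetic benchmark does and does not show

The generator reproduces the structural features the estimators are
sensitive to — scale-free vs Poissonian degree mixing, loops vs
tree-likeness, geometric link delays — but not features of real contact
data such as weighted or temporal edges, community structure of
empirical communication graphs, or reporting noise in arrival times.
Passing tests therefore demonstrate correctness of the implementations
and the qualitative regime structure (correlation-based scoring robust
at low β; path-ensemble likelihoods strongest at high β), not
quantitative performance on any particular empirical network. Empirical
edge lists can be loaded through `read_edge_list` and pushed through the
identical pipeline.

## Known limitations

- Undirected, unweighted, static graphs only.
- Single-source spreads; no recovery (SIR/SEIR) and no asynchronous
  (Gillespie) dynamics.
- LPTV's full-information variant (using the infecting neighbour's
  identity) is intentionally absent; only arrival times are observed.
- The minimum over n > 2 parallel paths is approximated by two
  independent paths; the exact n-variate minimum has no tractable closed
  form.
- HVO's exhaustive seed-pair search is O(N³) and is intended for the
  desk-scale networks the benchmark uses.
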