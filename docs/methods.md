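# Methods

## Model

`noisenet` simulates a discrete-time gene regulatory network of *n* genes
(default 40) in the Wagner tradition, extended with heritable, gene-specific
expression noise.  An individual's genotype is a regulatory matrix
W = (w_ij) — entry (i, j) the signed strength with which gene j activates
(w > 0) or represses (w < 0) gene i — together with an intrinsic-noise
vector η, where η_i is the **variance** (squared expression units) of gene
i's per-step expression draw.

A genotype is realized into a phenotype by iterating, for T_r = 50 steps
from the basal state s_i = 20:

    a_i(t)   = Σ_j w_ij s_j(t)                      (summed regulatory input)
    s_i(t+1) ~ N(20 + a_i(t), η_i), clamped to [0, 100]

All genes update synchronously from the same previous state.  Regulation is
additive (no cooperativity, no Hill kinetics, no mRNA/protein split, no
extrinsic noise).  Clamping is a hard per-draw clip, not truncated-normal
resampling.  The phenotype is the state at t = T_r.  With η = 0 the
dynamics are deterministic and, inside the bounds, linear: an interior
fixed point satisfies s = 20·1 + W s.  A trajectory is *stable*
(non-oscillating) iff

    Φ = (1/τ) Σ_{θ=t−τ..t} mean_i |s_i(θ) − s_i(t)| < ε

at t = T_r, with τ = 10 and ε = 1e−6.  The sum runs over τ+1 terms
including the zero θ = t term and is divided by τ, exactly as the criterion
is conventionally written.  A synchronous fixed point is also a fixed point
of the asynchronous (one-gene-at-a-time) update in every order — the test
suite checks this invariance against an independent asynchronous oracle —
and asynchronous dynamics from the basal state reach the same steady state
for most networks.  The clamped system can, however, be multistable: for a
minority of established networks some update orders carry the trajectory
into a different attractor, so path-level equivalence holds only up to
basin selection.

Fitness of a phenotype s under stabilizing selection toward a per-gene
optimum s_opt is

    F(s) = exp(−Σ_i |s_opt_i − s_i| / (n ρ_i)),

with fitness contributions ρ_i = 1 by default.  ρ is implemented dividing
the per-gene deviation, as the formula is conventionally printed; a
`rho_mode="multiply"` switch provides the alternative reading (identical at
ρ = 1).

## Two evolutionary stages

**Network establishment.**  Random connected topologies drive most genes to
an expression bound under deterministic realization, where expression
variance is uninformative.  The establishment stage therefore evolves W
toward intermediate expression: N individuals per generation undergo
deterministic realization, fitness toward s_opt = 50 for every gene,
fitness-proportional (Wright–Fisher) reproduction, and additive N(0, 2)
mutation of each nonzero weight with probability μ_w = 0.1 (topology
preserved; a weight landing exactly on 0 is nudged by the smallest positive
double).  No recombination.  Oscillating individuals receive fitness 0;
if an entire generation oscillates the topology is discarded — at the
default density roughly a third of random founders oscillate and are
replaced.  The highest-fitness stable individual of the final generation
(ties broken by lowest index) founds the next stage.  Genes whose steady
state sits at 0 or 100 stay in the dynamics but are flagged for exclusion
from analysis tables.

**Noise evolution.**  W is frozen; η evolves.  The founder population is N
copies with each individual's η drawn entrywise from the mutation
distribution N(100, 40) (clamped at 0), so generation-1 expression variance
is well defined.  s_opt is the founder's deterministic steady state,
computed once and frozen.  Each generation: stochastic realization →
fitness (or a neutral constant) → reproduction → replacement mutation of η
(probability μ_η = 0.01 per gene, new value ~ N(100, 40) clamped at 0) →
single-breakpoint recombination (each offspring with probability r = 0.05
swaps the η tail beyond a uniform breakpoint with a uniformly chosen
partner; W is never recombined).  Mutation distributions are read as
(mean, standard deviation).  Noise mutations *replace* the current value —
the N(100, 40) mutant distribution is far from zero, and replacement is
what allows selection to drive η toward 0 — while regulatory mutations are
zero-centred additive perturbations.

The per-generation event order is realize → fitness → reproduce → mutate →
recombine.  Records are taken at realization time on an arithmetic
generation grid (stride 2 by default, generations 1 and T always included):
per-gene population mean and sample variance (ddof = 1) of expression, mean
and median η, and mean fitness.

## Randomness and determinism

One root integer seed fully determines a run.  Stage- and generation-level
streams are `SeedSequence(root, spawn_key=path)` children; per-individual
realization streams are Philox generators whose keys are derived by counter
arithmetic, so spawning N streams per generation is cheap and results are
independent of batching.  `realize_population` guarantees its row k is
bitwise identical to a standalone `realize` call on stream k (the batched
mean update uses a per-row matrix–vector product rather than a single
matrix–matrix product precisely to keep the floating-point accumulation
order identical).  Replicate seeds are derived as (root, stage, topology,
replicate), so adding replicates never perturbs existing ones.

## Outcome statistics

* **Expression variance**: per-gene sample variance across the population
  (denominator N−1; at N = 1000 the distinction from N is negligible but it
  is fixed for exact tests).
* **Relative variance change**: (σ²_gen1 − σ²_genT)/(σ²_gen1 + σ²_genT),
  in [−1, 1], positive when variance was reduced; undefined (NaN, with a
  warning) when both variances are 0.
* **Selective pressure**: for each gene, the mean over recorded generations
  g > 1 of (η̄(1) − η̄(g))/η̄(1), where η̄ is the population mean of the
  gene's noise genotype.  The zero generation-1 term is excluded; including
  it would rescale pressures by ≈ (G−1)/G.  Replicates are averaged first,
  then the responsiveness threshold (pressure > 0.5, strict) is applied.
* **Node strengths**: instrength(i) = Σ_j |w_ij|, outstrength(j) =
  Σ_i |w_ij|.
* **Graph-level panel** (12 descriptors): diameter and mean path distance
  (directed, unweighted, unreachable ordered pairs excluded), Freeman-style
  in/out-degree, closeness and betweenness centralizations, average
  total/in/out degree, plus three configurable extras (reciprocity, global
  clustering of the skeleton, mean betweenness) completing the panel.
  Closeness uses the harmonic form so weakly connected graphs stay finite.
  Centralization denominators: (n−1)² for directed degree, (n−1) for
  harmonic closeness normalized to [0, 1], (n−1)²(n−2) for directed
  betweenness.
* **Synthetic axes**: PCA on the correlation matrix of the standardized
  panel (the metrics have incommensurate scales); constant columns are
  dropped with a warning.  Signs are oriented so diameter loads positively
  on PC1 and average degree positively on PC2.
* **Mutual information**: plug-in estimate in nats on equal-frequency
  binned data, ⌈len^(1/3)⌉ bins by default, ties broken by stable rank
  order.  MI magnitudes depend on the binning rule, so printed MI values
  are comparable only under the same rule; significance comes from a Monte
  Carlo permutation test, p = (1 + #{MI_perm ≥ MI_obs})/(1 + B), optionally
  permuting within groups (e.g. within each network topology).  At small
  sample sizes the discrete MI support makes the permutation p
  conservative.

## Topology generation

Directed density is d = m/(n(n−1)); generators target round(d·n·(n−1))
edges (78 at the defaults).  ER graphs are uniform random digraphs with
exactly that many edges.  BA and WS are natively undirected constructions:
the skeleton is built by preferential attachment (m ≈ target/(n−2)) or a
rewired ring lattice (k ≈ 2·target/n, rewiring probability 0.1), randomly
adjusted by single-edge insertions/deletions to the exact edge target, and
each edge is then oriented uniformly at random to a single direction,
keeping edge-count parity with ER.  Nonzero weights are i.i.d. U(−3, 3)
with exact zeros redrawn.  Connectivity of the undirected skeleton is
enforced by rejection sampling (cap 1,000 attempts).  The paper-scale
parameters of the constructions are not uniquely determined by size and
density; the choices above are the package's own and are configurable.

## Desk-scale study conditions

Full-scale runs (2,000–3,000 topologies × N = 1,000 × T = 10,000 × 20
replicates) are not desk-reproducible.  The shipped "desk" preset and the
acceptance script use: 20 ER topologies established at N = 100 for 1,000
generations; noise evolution on 10 founders at N = 200 for 500 generations,
3 replicates per mode.  At this scale the establishment yield of
intermediate-expression genes measures ~70%, inside the 68 ± 10
percentage-point band the acceptance suite asserts.

Two desk-scale behaviours fall short of the asserted full-scale bounds, and
the package reports them honestly rather than matching headline values:

* The correlation of per-gene mean expression between the first and last
  generations of selected runs measures ≈ 0.95 at desk scale; the test
  suite asserts the full-scale bound of ≥ 0.99 and is expected to flag
  this.  With starting noise η ≈ 100, clamping at the expression bounds
  biases generation-1 population means away from the deterministic steady
  state wherever trajectories reach a bound; as selection removes noise the
  means migrate back toward the steady state.  Desk-scale establishment
  leaves steady states further from the target (mean |s − 50| ≈ 16) than
  extensive full-scale optimization would, so this bias — and hence the
  departure from a perfect correlation — is larger at desk scale.
* Selective pressures are compressed: 500 generations is mid-transition
  for the multi-locus response (weak recombination couples the 40 loci), so
  the responsive fraction is smaller and pressure differences among
  responsive genes have restricted range.  Direction-of-effect checks on
  the responsive subset consequently have reduced power at desk scale.

## What the generator emulates — and what it does not

The synthetic topologies and two-stage simulation reproduce the study
conditions: network-position-dependent noise propagation, stabilizing
selection on expression, and drift/mutation/recombination at the stated
rates.  They do not emulate features of real transcriptional networks such
as autoregulation (explicitly excluded as a confounder), cooperative
binding, cell-cycle or extrinsic noise, unequal fitness contributions
(supported via ρ but not default), or empirically calibrated mutation
spectra.  Passing tests therefore demonstrate properties of the model, not
of any measured biological network.

## Numerical choices and degenerate inputs

* Weights, expression levels and η are double precision throughout.
* The establishment stage raises `AllOscillatingError` when no individual
  is stable (orchestration logs and skips such topologies); a single
  oscillating individual merely gets fitness 0.
* `relative_variance_change` emits NaN with a warning when both variances
  are 0; `mutual_information` returns 0 with a warning for constant input;
  `synthetic_axes` refuses fewer than 3 networks or fewer than 2
  non-constant columns.
* Establishment tie-breaks (equal best fitness) go to the lowest individual
  index.  Recombination partners may be chosen repeatedly within a
  generation; events are applied in individual order, single pass.
* Clamp counts are tracked per realization (`RealizationResult.n_clamped`)
  since the frequency of boundary events controls the bias discussed above.

## Known limitations

* Graph distances are unweighted; no weighted-distance convention is
  defined.
* The establishment optimizer is the model's own evolutionary process, not
  a numerical solver; it plateaus with steady states a finite distance from
  the target, which is a property of the mutation granularity (N(0, 2)
  steps on 78 weights), matching the observation that a minority of genes
  never reach intermediate expression.
* The linear-mixed-model / logistic layer of the downstream analysis is out
  of scope: `build_gene_table` exports a model-ready tidy table on which
  standard statistical tooling (e.g. statsmodels, lme4) can be run.
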