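# Methods

## The problem

Bayesian species delimitation with the multispecies coalescent (MSC)
evaluates candidate delimitation models generated by collapsing nodes of a
fixed, rooted *guide tree* over putative populations.  Errors in the guide
tree could inflate the rate at which two populations of one biological
species are wrongly split ("false positives").  This package rebuilds, as a
tested pipeline, a simulation study of that question: sequence data are
simulated under the MSC on known four-species trees, guide trees are
*inferred* from the data by two realistic routes, species are delimited by
reversible-jump MCMC (rjMCMC) on the inferred guide tree, and false-positive
rates and power are scored across replicates.

## Simulation model

Two four-species trees are used, a caterpillar `(((A,B),C),D)` and a
balanced `((A,B),(C,D))`, with divergence times τ and population-size
parameters θ (both in expected substitutions per site):

| setting | τ (tree 1) | τ (tree 2) | θ (all branches) |
|---|---|---|---|
| low rate  | 0.001, 0.002, 0.003 | 0.001, 0.001, 0.003 | 0.002 |
| high rate | 0.01, 0.02, 0.03    | 0.01, 0.01, 0.03    | 0.02  |

Each species consists of two panmictic populations (A1, A2, ..., D2); 3 or 5
sequences are sampled per population.  Because the populations of a species
are panmictic, the simulator draws all `2n` lineages of a species from one
deme and assigns the labels to the two populations afterwards — an
exchangeable, distributionally identical shortcut.  A replicate comprises
one mitochondrial locus (1000 sites; mutation rate 20× and effective size
1/4 of a nuclear locus, hence τ×20 and θ×5) and 1 or 5 nuclear loci (500
sites each).  Gene trees follow the MSC (within a branch holding *k*
lineages, coalescence at rate *k(k−1)/θ*; survivors pass to the parent
branch); sequences evolve under JC69 with a strict clock, uniform root
states, independent sites, no gaps or rate variation.

Simulated data intentionally idealise real data: no gene flow, no
assignment errors, no model misspecification (JC69 both generates and
analyses), no missing data.  Passing tests therefore demonstrate internal
consistency of method and implementation under the study conditions, not
robustness to the many ways real data violate them.

## Guide-tree arms

**Constrained ML (mitochondrial locus).**  Neighbour joining on
JC-corrected distances builds a backbone over the 8 populations
(within-population subtrees by average linkage), branch lengths are
optimised by exact coordinate ascent — each branch's profile likelihood
`Σ_p w_p log(a_p + b_p e)` is solved for its stationary point in
`e = exp(−4t/3)` — and nearest-neighbour interchanges restricted to edges
whose clades are unions of whole populations (these provably preserve the
monophyly constraints) hill-climb to a local optimum.  The tree is midpoint
rooted and collapsed to the population level.  The search runs under JC69,
not GTR: the full-scale study's ML analysis used GTR only because its software lacked
JC69, and attributed a slight accuracy deficit to that mismatch.  If the
midpoint falls inside a population subtree (rare), the tree is rerooted on
the longest edge whose clade is a union of whole populations.  Ties
(longest path, equal likelihoods, modal topologies) break towards the
lexicographically smallest canonical Newick, so the arm is deterministic.

**Species-tree MCMC (nuclear loci).**  The sampler targets
`p(S, τ, θ, λ, {G_i} | X) ∝ Yule(S, τ | λ) f(λ) p(θ | ψ) f(ψ)
∏_i f(X_i|G_i) msc(G_i|S, τ, θ)` over the 8-population tree.  Priors:

* Yule prior in its *conditioned* form (the pure-birth process conditioned
  on the number of extant tips): uniform over labeled histories, node
  heights distributed as sorted iid Exponential(λ), log-density
  `(n−1)log λ − λ Σ(internal heights)`; `f(λ) = 1/λ`, with a gamma Gibbs
  update.
* Population sizes θ per branch under the hierarchical default of the
  species-tree tools this arm emulates: `θ_v | ψ ~ Gamma(2, 2/ψ)` with the
  improper `f(ψ) = 1/ψ` on the mean (Gibbs for 1/ψ).  A literal independent
  `1/θ` per branch leaves fifteen unshrunk nuisance dimensions; branches
  hosting no coalescences then have likelihood-flat θ that absorbs topology
  signal and visibly depresses recovery of deep clades.  θ is additionally
  truncated to `[1e-6, 1]` as a numerical guard.

Moves: gene-tree node-age slides (uniform in the local bracket; multiplier
for the root stem), narrow exchange with node-age redraw, wide exchange,
species node-age slides and root-stem multiplier, species-tree NNI with
node-age redraw bounded above by the youngest gene coalescence joining the
two new daughter sides (the bound enters the Hastings ratio), θ updates
(multiplier and an independence draw from the conditional prior — the
independence draw mixes likelihood-flat θs perfectly), a whole-state scale
("mixing") move over all ages and θs with the appropriate Jacobian, and
Gibbs draws for λ and ψ.  Gene-tree/species-tree compatibility is enforced
by the MSC density itself (−∞ for invalid states).  The chain starts from
UPGMA trees with species divergences shrunk below every conflicting
cross-species coalescence.

The guide tree is the **MAP topology**: the modal topology among the last
73% of sampled trees (mirroring the full protocol's "last 2200 of 3000"),
with per-clade mean node ages.  The full protocol runs 6×10⁶ iterations;
the desk-scale default here is 4×10⁵ elementary proposals, the point where
MAP recovery stops improving with chain length in our calibration runs (an
"iteration" is not comparable across samplers — this sampler's proposals
are much finer-grained than the coordinated operators of the emulated
tool).

## Delimitation (rjMCMC)

Delimitation models are ancestor-closed sets of "split" nodes on the guide
tree (a node may be split only if its parent is); their number obeys
`N(tip)=1, N(node)=1+N(left)·N(right)` — 23 models for the correct tree-1
guide tree, 26 for tree 2.  Parameters: τ₀ ~ G(1, β) on the root age
(G(1,333) at the low rate, G(1,33) at the high rate — prior mean equal to
the generating value); non-root split ages uniform on the
order-constrained region given τ₀, implemented with its exact
normalisation `∏ s_v / τ₀^K` (s_v = split-poset subtree sizes, the
linear-extension count); θ ~ G(1,500) / G(1,50) for every active lineage
(a lineage is active if it is the root or its parent is split); a uniform
prior over models (a switch weights models by their number of split
orderings instead).  When a node is collapsed its τ is 0 and its daughters'
θs leave the state; the subtree root's θ governs the merged species — a
zero-length species branch hosts no coalescences, so collapsing via τ=0 is
exact.

The jump move splits a collapsed candidate node by drawing
`τ_v ~ U(0, U)` with `U = min(parent τ, youngest gene coalescence joining
the two daughter sides)` — any larger τ has zero density — and draws the
two newly active θs from their prior, so the dimension-matching proposal
terms cancel against the prior; the merge move is its mirror image.  The
full-scale protocol's rjMCMC algorithm tags (0 with ε=2; 1 with α=2, m=1)
parameterise another implementation's kernels; the stationary distribution
is kernel-independent, so those tags are recorded as provenance only.
Within-model moves mirror the species-tree sampler's, plus independence
draws for τ₀ and θ from their gamma priors.  The mixing move's step size
auto-tunes during burn-in only.  An analysis is two independent runs
(burn-in 5000, 20 000 samples every 2 sweeps at study scale; 2000 /
2×5000 at desk scale) whose samples are pooled; between-run disagreement
beyond 0.1 in any split probability is flagged.

**Verification oracle.**  For ≤3 populations, ≤2 sequences each, one
locus, per-model marginal likelihoods are computed without MCMC as
prior-predictive Monte Carlo expectations of the sequence likelihood
(2×10⁵ independent draws of parameters and gene trees per model), giving
per-model posteriors with quantified standard errors.  rjMCMC and oracle
agree within total-variation distance 0.005–0.03 on the test fixtures.

## Scoring

A false positive is a replicate in which a within-species pair (A1A2 ...
D1D2) is split with posterior ≥ 0.95; on a wrong guide tree the pair's
posterior is that of the pair's most recent common ancestor node, whose
splitting is what separates the pair.  Summaries use type-7
(linear-interpolation) quantiles and 20 histogram bins of width 0.05 with
the last bin closed at 1.0, so the last-bin count equals the
false-positive count.  Clade-recovery frequencies are strict clade
presence (no partial credit for compatible-but-unresolved trees, which
cannot occur here since every inferred tree is binary).  Binomial standard
errors accompany all rates.

## Numerical choices

Pattern compression before all likelihood work; pruning with per-pattern
max-scaling; MSC density −∞ as the rejection sentinel; ages strictly
ordered (parent > child) with 1e−9 floors at initialisation; seeds flow
from one master `SeedSequence` with per-replicate spawning so any replicate
is independently reproducible; all samplers are bit-reproducible given
their integer seed.

## Problem sizes used by the tests and the reproduction script

The full study (1000 replicates × 8 configurations × 6×10⁶-iteration
chains) is deliberately scaled down: 200 replicates per rate for the ML
arm, 100 (script) / 70 (tests) for the species-tree arm at 4×10⁵
iterations, 16 replicates for the five-locus variant, a 40-replicate
delimitation study with the protocol's scaled chains (burn-in 2000, two
runs of 5000 samples every 2), and 3–5 replicates for the root-split
check.  At these sizes every comparison's binomial noise is well inside
the stated tolerances.

## Known limitations

* The species-tree arm's constant-θ-per-branch MSC (the model family of
  this package) differs from the linked piecewise-linear population-size
  model of the tool the full-scale study used for that arm.  With one
  weakly informative locus this matters: MAP recovery of clade ABC runs
  ~5–10 points below the full-scale study's figures (roughly 46% vs 55% at
  the low rate, ~73% vs 76% at the high rate in our reproduction runs),
  while the cherries (~70–75% vs 77%), the ML arm, and the delimitation
  summaries on correct or ML guide trees reproduce closely.  The
  delimitation engine itself is validated independently of that arm by
  the enumeration oracle.
* Midpoint rooting of the saturated high-rate mitochondrial locus
  (τ_root,mt = 0.6) occasionally places the root off the true root edge
  even when the constrained unrooted topology is correct, leaving the
  ML arm's high-rate clade-ABC recovery ~91% against the original 96%
  (the full-scale study's clock-rooted Bayesian variant reached 98%,
  showing rooting — not topology — is the binding error source there).
* The modal-topology (MAP) estimate from a finite, autocorrelated sample
  is noisy when the posterior is diffuse; this adds estimator variance on
  top of posterior differences for the hardest (low-rate, single-locus)
  cell.
* No gene flow, assignment error, rate variation, or non-clock branch
  rates are modelled (out of scope of the study design).
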