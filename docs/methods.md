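# Methods

## Conventions

A food web is an S×S Boolean adjacency matrix with rows as predators:
a(i, j) = 1 means species i preys on species j. Out-degree is generality
(number of prey, k_out), in-degree is vulnerability (number of predators,
k_in); diagonal entries are cannibal links and are allowed everywhere.
L is the number of 1-entries and connectance is L/S². Duplicate edges in
input files collapse silently — webs are unweighted.

## Analytic MaxEnt degree distributions

Maximizing H = −Σ p ln p over distributions on the lattice [0, S]² under
normalization and the two mean constraints ⟨k_in⟩ = ⟨k_out⟩ = L/S yields
p(k_in, k_out) = e^(−λ₂k_in − λ₃k_out)/Z. Because both constraints carry
the same target, λ₂ = λ₃ is analytically forced and the distribution is
exchangeable in its arguments. We therefore solve a single monotone
scalar equation — the truncated-geometric mean as a function of λ equals
L/S — with Brent's method (bracket expanded geometrically from ±1;
xtol 1e-12), then verify both constraints to 1e-8. A generic SLSQP
maximizer over all (S+1)² probabilities is kept in the test suite as an
independent oracle; the two agree to ~1e-13 in entropy on small grids.

Feasibility is 0 < L < S²: the exponential family on [0, S] attains
means only in the open interval (0, S), so the empty and the complete
web sit on the (excluded) boundary. When L/S equals the support midpoint
S/2 the solution is exactly uniform with λ = 0, which the solver returns
without iteration.

### The two routes to the degree distribution

The total degree k = k_in + k_out has mean 2L/S (each link contributes
one prey and one predator endpoint). Its distribution can be obtained
two ways, and they are *not* the same object by default:

* **Marginalization** of the joint solution gives
  p(k) ∝ m(k)·e^(−λk) on [0, 2S], where m(k) = S + 1 − |k − S| counts
  the lattice pairs summing to k.
* **Direct solve** of the one-dimensional MaxEnt problem with a uniform
  prior measure gives the pure geometric form p(k) = e^(−λk)/Z, by
  convention on the support [0, S].

A triangular-weighted geometric cannot equal a pure geometric pointwise,
so the routes coincide only on *matched supports*: passing
`lattice_degeneracy=True` to `solve_degree_distribution` uses the prior
measure m(k) on [0, 2S], and the direct solve then reproduces the
marginal exactly (same unique λ by monotonicity of the weighted mean).
The default (uniform measure, support [0, S]) is retained because it is
the form usually quoted for geometric degree distributions; both are
exposed and the test suite documents the discrepancy explicitly.

### Sampling joint degree sequences at fixed L

Degree sequences are drawn by taking S iid pairs from the joint
distribution and then repairing toward the hard constraints
Σk_in = Σk_out = L: a uniformly chosen species has its pair resampled
from the joint distribution restricted to pairs that strictly reduce the
total discrepancy |Σk_in − L| + |Σk_out − L|. Each accepted repair
reduces the discrepancy by at least 1, so termination is guaranteed
(cap 10⁶ proposals). The scheme preserves the marginal shape only
approximately; exact conditional sampling at fixed totals is not
attempted. Note that fixing the totals pins the sequence mean at L/S
exactly in every realization.

Predicted sequences are species-agnostic; to compare them with an
observed sequence we pair species by rank after sorting both sequences
descending by total degree (or by in- or out-degree), with deterministic
tie-breaking (complementary degree, then index). Rank pairing by total
degree minimizes the mean absolute total-degree error over all
pairings, which the tests verify by brute-force assignment on small
instances.

## Flexible-links model

L is bounded by S − 1 (a connected web with no isolated species) and S².
The realized flexible links L − (S−1) out of S² − (S−1) are modelled as
beta-binomial with α = μe^φ and β = (1−μ)e^φ; μ is the average
probability a flexible link is realized, φ the log-scale concentration
(larger φ → less between-web spread in connectance). Priors are
μ ~ Beta(3, 7) and φ ~ Normal(3, 0.5).

Posterior sampling uses an adaptive random-walk Metropolis kernel on
(logit μ, φ): 4 chains × 3000 iterations by default, first half
discarded as warm-up. During warm-up the proposal scale is nudged every
50 steps toward ~30 % acceptance and, from iteration 400 on, the
proposal covariance is re-estimated from the recent trajectory
(Haario-style) with the 2.38/√d scaling. The contract is distributional,
not algorithmic: split-R̂ is computed for both parameters and a warning
is raised above 1.01. The model is two-dimensional and log-concave in
practice; at these settings R̂ is typically ≤ 1.01 and posterior means
recover generating parameters on synthetic data (μ within 0.05, φ within
0.5 at m = 200 webs). An empty dataset is valid and samples the prior,
which the tests use to check the sampler against closed-form prior
moments.

Posterior-predictive counterfactuals draw L for a given S (each draw
uses one posterior (μ, φ) sample), take the median and the equal-tailed
67/89/97 % interval bounds, and solve the MaxEnt degree distribution at
each quantile. Quantile L values are clamped into the solver-feasible
range with a warning when a bound lands on S² (mean on the boundary of
the support).

## SVD entropy

For an adjacency matrix with singular values σ₁ ≥ σ₂ ≥ …, keep the
numerical rank R (σ > 1e-10·σ₁ — Boolean matrices are decomposed in
floating point, so "non-zero" needs a tolerance), set s_i = σ_i/Σσ over
the top R, and J = −Σ s_i ln s_i. Standardization divides by ln R,
mapping to [0, 1] with 1 iff the retained spectrum is flat; rank-1
matrices get standardized entropy 0 by convention (the degenerate limit;
a rank-1 web is minimally complex). SVD entropy is invariant under row
and column permutation and under transposition, which the suite checks
property-style. An exact-arithmetic rank oracle (sympy over the
integers) guards the tolerance choice.

## Simulated annealing

Both heuristic models maximize standardized SVD entropy with 4 chains,
2000 steps and initial temperature 0.2 by default. Cooling is geometric
per step with the factor chosen so the final temperature is 1e-6·T0 —
the specific cooling law is a design choice (only "decreasing" is
required by the method), and geometric is the standard one; the factor
is exposed. Moves: type I relocates one uniformly chosen link to a
uniformly chosen empty cell (L invariant); type II applies a
checkerboard double-swap — two links (i,j), (k,l) with empty (i,l),
(k,j) are rewired to the latter — which preserves every row and column
sum exactly. Diagonal cells participate like any others. Uphill moves
are always accepted, downhill with probability exp(ΔJ/T). Chain
initialization: type I draws a fresh uniform web at the same L; type II
shuffles the input web with 10·L accepted swaps (a burn-in randomizer of
fixed-margin matrices; exact uniform sampling over the margin class is
out of scope). A proposal that finds no valid swap within 100 attempts
leaves the state unchanged, which protects near-degenerate margins from
deadlock. The best-so-far configuration per chain is tracked and the
best across chains returned; with `debug_checks` the constraint is
asserted at every step.

On an instance small enough to enumerate (S = 3, L = 3; 84
configurations) the type I annealer at default settings reaches the
exhaustive optimum in effectively every seeded run, which the acceptance
checks quantify.

## Reference models

Type I null: every cell L/S². Type II null: p(i→j) = ½(k_in(j)/S +
k_out(i)/S); its cell mean equals connectance because both degree
sequences sum to L. Neutral model: weights (n_i/N)(n_j/N) from relative
abundances; since only a proportionality is defined, weights are scaled
so that Σp equals the target link count, iteratively capping cells at 1
and rescaling the remainder — this makes Bernoulli realization
well-defined and realized webs comparable across models. The raw
proportional weights are available by passing no target. Probabilistic
webs are realized as Boolean webs by drawing 100 Bernoulli matrices,
counting per-cell successes and keeping the L most-sampled cells, with
seeded uniform tie-breaking at the count boundary; realized webs match L
exactly by construction.

## Structure measures

* **Nestedness ρ**: spectral radius of the adjacency matrix, by default
  normalized by √L (the scale of the spectral radius for a fixed number
  of links); the raw value is available. The normalization is a
  documented choice — spectral-radius nestedness is conventionally
  rescaled, but no single convention dominates.
* **Trophic levels**: prey-averaged, TL(i) = 1 + mean TL over i's prey,
  with self-loops removed first (a pure cannibal is basal). Solved as a
  linear system; if singular, a damped fixed-point iteration (factor
  0.5, tol 1e-8, cap 10⁴) is tried; a feeding cycle with no energy
  pathway to a basal species has no finite prey-averaged levels and
  raises an error naming the strongly connected component. *maxtl* is
  the maximum level. Prey-averaging is one of several conventions in
  use; it is the package's fixed choice.
* **Diameter**: longest finite shortest directed path over ordered
  reachable pairs, self-loops ignored; error on webs with no non-loop
  edge.
* **Omnivory**: proportion of species with ≥ 2 non-self prey whose prey
  levels are not all equal within 1e-6.
* **MxSim**: for each species the maximum over partners of trophic
  similarity (shared prey + shared predators) / (union of prey + union
  of predators), averaged over species; self-loops excluded.
* **Motifs**: all 64 labeled 3-node digraphs without self-loops collapse
  into 13 weakly connected isomorphism classes — 5 with only single
  links (S1 tri-trophic chain, S2 omnivory, S3 feeding loop, S4 apparent
  competition, S5 exploitative competition) and 8 with at least one
  mutual pair (D1–D8, ordered by link count then canonical code). A
  web's profile counts, for every 3-species subset, the class of the
  induced subgraph after stripping self-loops; disconnected triads are
  not counted. The classifier uses a canonical 6-bit code (minimum over
  the 6 node permutations); the tests check it against explicit
  permutation matching.
* **KL divergence** between in- and out-degree frequency distributions
  over 0..S, with 1e-10 smoothing and renormalization so disjoint
  supports stay finite; direction (P‖Q) is a parameter since either
  convention is defensible.
* **Standardized mean difference** across a web collection:
  mean(predicted − empirical)/sd(empirical), sample sd; positive values
  mean overestimation.

## Synthetic data

The generator module stands in for empirical web collections. Random
webs place L links uniformly among the S² cells; prescribed-margin webs
use a greedy Gale–Ryser fill (succeeds iff the sequence is realizable)
followed by seeded checkerboard shuffling — uniformity over the margin
class is not claimed. Abundances are log-normal (mean 0, sd 1 on the log
scale by default), a standard shape for species-abundance
distributions. (S, L) datasets draw S uniformly on [10, 60] and L from
the flexible-links generative model at μ = 0.3, φ = 3 by default —
parameters of the order recovered from empirical web collections, giving
mean connectance ≈ 0.3 on the flexible-link scale with realistic
between-web spread.

What the synthetic conditions do not emulate: empirical webs are not
uniform draws at fixed L (they are nested, have few cycles, and their
degree distributions are fatter-tailed), abundance data carry sampling
error, and real (S, L) collections mix sampling protocols. Passing tests
therefore demonstrate correctness of the machinery and parameter
recovery under the stated generating processes, not ecological fidelity
of any particular empirical corpus.

## Problem sizes

The test and acceptance workloads use small instances chosen so every
oracle is exhaustive or exact: S ≤ 4 grids for the generic entropy
maximizer, the 84-configuration instance for the annealer, S ≤ 8 webs
for brute-force motif/diameter/spectral checks, m = 200 webs for
parameter recovery, 100 seeded annealing runs. These sizes make the
whole suite run in about a minute while keeping every comparison against
an independent route.

## Known limitations

* The analytic model predicts exchangeable (k_in, k_out) — empirical
  webs are more asymmetric at low connectance, and no additional
  constraints (variance, maximum trophic level) are implemented.
* The annealer is a heuristic: no optimality guarantee beyond the
  exhaustive small-instance checks.
* Fixed-L sequence sampling and fixed-margin web construction are
  pragmatic, not exact-uniform, samplers.
* KL-matching annealers and soft/hard-constraint maximum-entropy graph
  ensembles are out of scope.
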