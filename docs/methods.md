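# Methods

## Model

`ssps` models short multivariate time courses with a linear-Gaussian dynamic
Bayesian network: each variable at timepoint *t* is a noisy linear function
of its parents at *t−1*.  Conjugate priors (a Zellner-style g-prior with
g = T_eff on the regression coefficients, the improper 1/σ² prior on the
noise variances) let both be integrated out analytically, so the only
unknowns are the structure indicators `z_ij` and the per-vertex inverse
temperatures `λ_j`.  The resulting marginal likelihood factorizes over
vertices; a change to one vertex's parent set or λ touches exactly one
factor, which is what makes single-site Metropolis–Hastings updates cheap.

Per vertex j, up to a constant shared by all parent sets:

    log P(X | pa(j)) = −(|pa(j)|/2)·log T_eff − (n/2)·log( y'y − (n/T_eff)·y'B β̂ )

with `β̂` the minimum-norm least-squares estimate.  Several courses of
possibly different lengths are pooled by stacking their transitions:
`n = Σ_m (T_m − 1)` and `T_eff = n + 1`, which reduces exactly to the
single-course form (`n = T − 1`, `T_eff = T`) when there is one course.

The structure prior treats each edge as an independent Bernoulli draw with
success probability `e^{−λ_j} / (e^{−c_ij λ_j} + e^{−λ_j})`.  With binary
confidences this is exactly the classical reference-graph prior
`∝ exp(−λ|E(G)∖E(G′)|)` (verified by exhaustive enumeration in the tests);
real-valued confidences interpolate it.  λ_j is uniform on
`[λ_min, λ_max]` = [3, 15] by default: values much below 3 put substantial
prior mass on very dense graphs (computationally hostile and biologically
implausible), while the posterior is insensitive to the upper bound once it
is comfortably large.

### Numerical choices

- Rank-deficient or over-complete designs (no in-degree cap is imposed) use
  the pseudo-inverse / minimum-norm solution; since the fitted term is a
  projection, `y'Bβ̂ ≤ y'y` and the log argument stays positive.
- The log argument is floored at `1e−12 · y'y` to guard floating-point
  cancellation when a design interpolates the response exactly.
- The sampler's cached evaluator solves the normal equations on a
  precomputed Gram matrix; if the solve is ill-conditioned (fit outside
  `[0, y'y]`) it falls back to the pseudo-inverse.  The cached and direct
  code paths are cross-checked in the tests.
- An identically zero response column is a hard error (the marginal
  likelihood is undefined), never a silent NaN.
- Prior Bernoulli masses are evaluated with `logaddexp`; the per-edge delta
  used inside MH updates reduces to `(c_ij − 1)·λ_j` because the
  normalizers cancel.
- Data are standardized (pooled per-variable centering and unit scaling)
  before inference by default — common DBN practice that makes λ and the
  g-prior scale-free — and this can be disabled (`standardize: false`).
  Standardization is recorded in the run manifest.
- Self-edges are allowed by default: a DBN edge runs from t−1 to t, so
  i → i is plain autoregression.  `allow_self_edges: false` removes the
  diagonal from the candidate pools and the prior.

## Sampler

Each iteration sweeps vertices in ascending order, updating λ_j (symmetric
Gaussian walk, ξ = 3; the sampler is insensitive to ξ over a wide range)
and then pa(j).  The parent-set proposal draws one of three actions — add,
remove, swap — with probabilities shaped by the current size s relative to
the reference size `ŝ_j = Σ_i c_ij`: with `u = (s/|V|)^{1/log₂(|V|/ŝ)}`,
unnormalized weights are `(1−u, u, 2u(1−u))`.  Swap moves matter because
the marginal likelihood penalizes parent-set size steeply, so
size-preserving moves have systematically higher acceptance.  ŝ is clamped
to `[1, |V|/2]`, since γ is undefined for an empty prior column and must
have `|V|/ŝ > 1`.

Every action is paired with its exact reverse (add ↔ remove, swap with
itself), giving closed-form reverse masses for the Hastings ratio:
`q(add i) = p(add|s)/(|V|−s)` with reverse `p(remove|s+1)/(s+1)`, and the
swap mass `p(swap|s)/(s(|V|−s))` is identical in both directions.

Chains are initialized overdispersed: λ_j uniform over its bounds, z_ij
drawn from the prior at that λ.  Each chain uses a counter-based Philox
generator seeded with `base_seed + chain_index`; identical seeds give
bit-identical traces.  Wall-time limits are checked at iteration boundaries
so traces always contain whole sweeps.  Traces are delta-encoded (only
accepted changes are stored), and replaying the deltas reconstructs the
state at any iteration exactly.

Default termination mirrors an overnight budget — 4 chains, 100,000
iterations or 12 hours, first half of each chain discarded as burnin — but
every analysis in this repository runs far smaller configurations (see
"Problem sizes" below).

## Diagnostics

Edge probabilities are the pooled post-burnin frequency of each indicator.
Every edge indicator and every λ_j is monitored with split-chain PSRF and a
multi-chain effective sample size (autocovariance by FFT, Geyer initial
monotone positive sequence truncation, capped at the retained total); a
quantity is flagged failed when PSRF ≥ 1.01 or Neff < 10.  Binary
indicator sequences are frequently constant, where the classical formulas
are 0/0: all chains constant and equal gives PSRF = 1 and ESS = the total
retained count (a never-proposed edge is converged at zero); constant but
unequal gives PSRF = +∞ and ESS = the chain count.  Chains of unequal
length are truncated to the shortest retained segment (keeping the latest
samples) so between-chain statistics are well defined.  Passing these
checks does not certify convergence; failing them is a reliable red flag.

## Synthetic benchmark

The generator emulates phosphoproteomic time-course studies:

- truth: adjacency entries i.i.d. Bernoulli(5/|V|) — about five parents per
  vertex, the sparsity scale of signaling pathways — with edge weights
  N(0, 1/|V|), a variance small enough that trajectories do not diverge;
- data: M = 4 courses of T = 8 timepoints; `x₁ ~ N(0, I)` and unit
  observation noise (the initial-state and noise scales are generator
  choices; with standardized inference only their ratio to the signal
  matters);
- prior corruption: remove `round(r·|E0|)` true edges, add `round(a·|E0|)`
  spurious ones (round = ties-to-even); r and a emulate false negatives and
  false positives in curated pathway knowledge;
- grid: |V| ∈ {40, 100, 200} × r, a ∈ {0.1, 0.5, 0.75, 1.0}, five
  replicates per cell — 48 cells, 240 instances, with deterministic
  per-cell seeds.

What the simulator does *not* emulate: real phosphoproteomic intensity
distributions (heavy tails, floor effects), missing values, unobserved
regulators, or nonlinear kinetics.  Tests passing on this benchmark show
the inference machinery is correct and that prior refinement works when the
model family matches the data-generating process; they do not certify
performance on real assays.

## Evaluation

Edge recovery is scored as binary classification over all ordered pairs
with AUCPR estimated by average precision (tied scores enter as one
threshold block; the trapezoidal PR estimate is optimistic).  Self-edges
are included by default, consistent with the model, with a flag to exclude
them.  Differential performance against the prior-knowledge baseline (the
confidence matrix reported verbatim as a prediction) is a paired
t-statistic over replicates, with zero-variance differences mapped to ±∞.
Descendant-set AUCROC thresholds the edge-probability matrix over its
unique values plus sentinels, takes graph reachability from a source
vertex, and integrates TPR vs FPR by the trapezoidal rule.  Dominance
compares a stochastic method's repeat-run score range against a
deterministic score: it must clear the minimum to dominate.

## Problem sizes used in the checked-in analyses

The bundled tests and examples are sized for a laptop-class run: the
exact-enumeration comparisons use |V| ∈ {2, 3} with 4 chains × 4,000
iterations (or 2 × 40,000 for the two-vertex stationary check); the
structure-recovery benchmark uses five |V| = 40 instances at r = a = 0.1
with 4 chains × 1,000 iterations; the sampling-efficiency comparison runs
|V| = 20.  These are package defaults for the bundled analyses, chosen so
the entire suite completes in a few minutes while leaving the statistical
assertions well-powered; production runs on real data should use the
full-scale termination defaults.

## Known limitations

- Only observed variables are modeled; unphosphorylated scaffolds or latent
  regulators cannot enter the network.
- Linear parent effects only; no interaction or nonlinear design columns.
- No missing-value handling; inputs must be complete and finite.
- The converged-constant ESS convention cannot distinguish a genuinely
  converged constant indicator from one frozen identically in every chain;
  overdispersed initialization is the mitigation.
- Proposal parameters are fixed, not adapted, during a run.
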