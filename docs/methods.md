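# Methods

## Model

The population holds N individuals on an interaction structure; each
individual i carries a binary strategy s_i ∈ {A, B} (encoded 1/0), a
personal aspiration e_i (payoff units, unconstrained in sign and
magnitude), and a decision function g_i. One elementary time step:

1. a focal individual i is drawn uniformly from the N;
2. i collects a payoff π_i from the d-player game (see payoff schemes);
3. i switches to the opposite strategy with probability
   g_i(β(e_i − π_i)), where β ≥ 0 is the selection intensity.

The decision-function axioms — differentiable, strictly increasing,
0 < g < 1 — guarantee a strictly positive switching probability in every
state, hence no absorbing state, ergodicity, and a unique stationary
distribution κ. "Generation" and "time step" both mean one elementary
update throughout.

Payoff schemes:

- **single_game** — the focal plays one game with d−1 coplayers drawn
  uniformly without replacement from its neighborhood; on a regular
  network of degree d−1 the draw is the whole neighborhood and the group
  is deterministic. In well-mixed mode the coplayers come from the N−1
  others and are redrawn fresh at every payoff evaluation (one-shot
  interaction; the exact solver correspondingly marginalises the flip
  probability over the hypergeometric group composition rather than
  conditioning on a realised draw).
- **averaged_d_games** — the focal participates in d games, one
  organised by itself and one by each neighbor, each game comprising the
  organiser's closed neighborhood; its payoff is the mean over the d
  games. This is only defined on regular structures of degree d−1: on a
  non-regular graph the organisers' games would have different sizes,
  and both the simulator and the solver refuse rather than guess.

## Weak-selection theory

At β = 0 every switch happens with the payoff-independent probability
g_i(0), so the dynamics are symmetric under relabelling A↔B and the
stationary abundance of A is exactly 1/2 — for any aspirations and any
mix of decision functions with g_i(0) > 0. The same symmetry makes the
abundance exactly 1/2 at *any* β when all payoff entries are equal (a
neutral mutant). The first-order response of the abundance to β is
linear in the payoff entries with aspiration-independent coefficients,
giving the criterion Σ_k σ_k (a_k − b_{d−1−k}) > 0 for A to be more
abundant, with σ_k = C(d−1, k) for identical decision functions with
g′(0) > 0 — identical for rings and well-mixed populations. The package
treats the closed form (`theory.sigma_theoretical`) and the numerical
recovery (`exact_solver.derive_sigma_numeric`,
`sigma_regression.fit_sigma`) as independent routes and tests them
against each other.

Empirically (and used as a sanity scale in tests and the README): for
d = 3 the exact derivative of the abundance at β = 0 equals
g′(0) Σ_k σ_k (a_k − b_{2−k}) / 2^d on rings and well-mixed populations
of every size the solver can enumerate.

Ties: |criterion| ≤ 1e−12 is reported as "neutral" rather than as a
winner — the criterion is a strict inequality.

The weak-selection validity scale β ≪ g′(0)/(|g″(0)|(max|e_i| +
max{|a_k|,|b_k|})) is exposed as `weak_selection_bound`; it is a scale,
not a hard threshold (the constant hidden in "≪" is not quantified). For
the Fermi function g″(0) = 0 and the bound is +∞.

## Exact solver

States are enumerated as bit patterns; the 2^N × 2^N transition matrix
has one off-diagonal entry per single-strategy flip, P[s → s^i] =
g_i(β(e_i − π_i(s)))/N, and is stored sparse. The stationary vector is
solved by replacing one row of (Pᵀ − I) with the normalisation
Σκ = 1 (sparse LU); an independent dense left-eigenvector route is kept
for cross-checks at small N (the two agree to ≤1e−10). The population
cap is N ≤ 14 (16384 states) to stay desk-scale; above ~12 the sparse
solve takes tens of seconds.

Derivatives in β use central finite differences with h = 1e−4, chosen
large relative to the solver residual (~1e−12) and small relative to the
curvature scale of g; the aspiration-independence property tests pass at
1e−6 with this h. Numerical σ recovery sets one payoff entry a_k = 1
(all others 0), computes the derivative per basis game, and normalises
by the k = 0 derivative — the coefficients are only identified up to a
positive factor.

## Monte-Carlo engine

When every individual uses the Fermi function the run dispatches to
numba-compiled kernels (network single-game, well-mixed single-game,
network averaged); otherwise a pure-Python reference loop with identical
semantics is used (tested against the kernel). Coplayer subsets are
drawn by partial Fisher–Yates on the neighbor list; well-mixed draws use
rejection, which is cheap because d ≪ N. One seeded generator drives a
run; the kernel seed is derived from the config seed.

The abundance estimate averages Σs_i/N over the post-burn-in steps; the
standard error comes from batch means over 50 contiguous batches, which
absorbs the serial correlation of the single long run (integrated
autocorrelation time is of order N/g(0) elementary steps, far below the
batch length in every shipped protocol). Batch-means SE is the
single-run analogue of averaging independent runs.

## Population structures

The degree floor d−1 (default 2, so everyone can host a three-player
game) is enforced at generation time. Random regular graphs are
resampled until connected. Erdős–Rényi samples (default p = 4/N, mean
degree 4 — an artifact choice, as is Barabási–Albert attachment m = 2)
would essentially never satisfy a floor of 2 by resampling alone, so
deficient nodes are repaired: each node below the floor is wired to
uniformly chosen non-neighbors, then disconnected components are bridged
by random edges (degrees only grow, so the floor survives). The repair
slightly perturbs the degree distribution in the low-degree tail; for
the questions asked here (sign of the abundance deviation) this is
immaterial, but the repaired graphs should not be used as calibrated
G(n,p) samples.

## Aspiration distributions

The samplers mirror the standard simulation protocols: homogeneous(c);
uniform(lo,hi); the bimodal mixture 0.4·N(2.5, 0.5²) + 0.6·N(4.5, 0.5²)
with untruncated components (sampled by component indicator then normal
draw); and the power law f(x) = 2x⁻³ on x ≥ 1, sampled by inverse CDF
x = (1−u)^(−1/2), so the minimum draw is exactly 1. Aspiration CSVs
(`individual_index,aspiration`, 1-based contiguous indices) round-trip
through `save_aspirations`/`load_aspirations`; the shipped fixture
generator reproduces the *distributions* of the published per-individual
aspiration tables, not their literal values (which are not available in
a plain-text form).

## Shipped protocol sizes (and why)

These are the package's desk-scale study conditions; they reproduce the
qualitative and first-order quantitative behavior, not the sample counts
of the original full-scale runs (10⁸–1.5×10¹⁰ samples), which are out of
scope.

- **Crossing sweep** (ring N=100; Erdős–Rényi and Barabási–Albert
  N=200, floor 2): β = 0.005, uniform [0,5] aspirations, initial A
  fraction 45%, burn-in 10⁷, 1.2×10⁹ post-burn-in steps per condition.
  The true abundance deviation at the probed points a₀ ∈ {1, 3} is
  ~1.3–1.6×10⁻⁴ (first-order formula above), and the batch-means SE at
  1.2×10⁹ correlated samples is ~2×10⁻⁵, so the expected separation is
  5–7.5 SE; a ≥3 SE sign test then has a comfortable margin. A
  materially smaller budget (e.g. 10⁷ samples, SE ≈ 2×10⁻⁴) could not
  resolve the deviation at all at this β.
- **σ regression** (ring N=100, uniform [0,1] aspirations, β = 0.05):
  the 26-point factorial design {−1,0,1}³ minus the all-zero table
  (which carries no signal), 2×10⁶ post-burn-in samples per point in the
  test protocol; the acceptance script uses 4×10⁷ per point so that the
  reported coefficient ratio has ~3% precision rather than ~10%. OLS of
  (abundance − 1/2) on (a₀,a₁,a₂) with intercept; coefficients are
  reported raw and ratio-normalised (σ̂₀ ≡ 1), with 95% margins; the
  normalised margins propagate the coefficient covariance by the delta
  method. The ratio normalisation is scale-free, matching the fact that
  the criterion only identifies σ up to a positive factor.
- **Payoff-accumulation robustness** (ring N=100, β = 0.05, two uniform
  [0,5] aspiration sets, initial A fraction 5%): 3×10⁷ post-burn-in
  steps per run, comparing single-game vs averaged schemes; both must
  put the favored strategy on the same side of 1/2 by ≥3 SE. The exact
  solver additionally confirms that the averaged scheme preserves
  σ = (1,2,1) and the aspiration-independence of the derivative on small
  rings — a property the theory only suggests.

## What the synthetic conditions do and do not show

The generators emulate the published study conditions (distributions,
β values, initial fractions, structures with degree floor 2). They do
not emulate: real behavioral aspiration data, strategy-dependent
decision functions (updating rules that differ between holding A and B
break the label-swap symmetry and with it the neutrality lemma — out of
scope), directed/weighted/rewiring networks, or strong-selection
regimes. Under strong selection with extreme aspiration heterogeneity
the weak-selection ranking can invert (permanently dissatisfied
individuals churn while permanently satisfied ones act as zealots);
the package deliberately reports the weak-selection bound so users can
tell when the σ-rule verdict stops being trustworthy.

## Known limitations

- The exact solver handles non-regular networks not at all (payoffs
  there depend on the sampled neighbor subset; Monte Carlo only).
- Batch-means SEs assume the batch length far exceeds the
  autocorrelation time; for custom configs with tiny step counts the
  50-batch default can under-estimate the error.
- The compiled kernels are Fermi-only; heterogeneous decision functions
  run at pure-Python speed (~10³ times slower), fine for N ≤ ~50 smoke
  tests but not for the shipped large-scale protocols.
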