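# Methods

This note records the models, conventions, numerical choices and known
limitations of `tpslearn`, in the order the pipeline uses them.

## Toy dynamics and the committor oracle

The package's dynamics backends are deliberately minimal: they exist to
exercise the learning loop under conditions where the ground truth is
computable, not to model molecules.

- **Potentials.** `QuarticDoubleWell` U(x) = h (1 − (x/x0)²)² with defaults
  h = 4, x0 = 1 (barrier 4 kT at the default temperature) — the smallest
  system with a nontrivial committor. `TwoChannelDoubleWell`
  U = h(x²−1)² + k y² + g exp(−a x² − b y²) with defaults (h, k, g, a, b) =
  (2, 1, 6, 4, 1): the central bump forces transitions through one of two
  symmetric channels near y ≈ ±1.05, giving a bimodal TP ensemble for the
  clustering stage.
- **Integrators.** Overdamped: Euler–Maruyama,
  dx = −∇U/(mγ) dt + √(2 kT dt/(mγ)) ξ. Underdamped: velocity Verlet with a
  per-step Ornstein–Uhlenbeck velocity randomization (decay e^{−γ dt}).
  Default dt = 0.005 in reduced units — comfortably below the stability
  limit 2/U″ ≈ 0.06 of the quartic well's basins — with friction γ = 1 and
  kT = 1.
- **States** are predicates on configurations; the toys use half-lines
  |x| ≥ 0.8 (state boundaries tighter than the minima at ±1 keep the
  committing frame close to the basin). States are checked for disjointness
  on probe grids.
- **Uncommitted trials.** A trajectory that exhausts `max_steps` without
  committing voids the whole shooting move: it is counted as rejected and
  contributes no training record. The alternative (keeping the committed
  partner's record) would bias the Bernoulli statistics toward fast
  outcomes. At the default settings the uncommitted rate is zero in
  practice (`max_steps` is ~100× the mean commitment time).
- **Committor oracle.** For 1D overdamped dynamics,
  p_B(x) = ∫_a^x e^{U/kT} dy / ∫_a^b e^{U/kT} dy. `analytic_committor_1d`
  evaluates it by adaptive quadrature (tolerance 1e−10);
  `AnalyticCommittor1D` interpolates a 4001-point trapezoid grid for use
  inside samplers, accurate to ~1e−7 — far below shooting noise.

## Shooting records and the likelihood

Each one-way trial is one Bernoulli record (x, s) with s = +1 for first
entry into the first-listed state (A) and s = −1 for the second (B). A
two-way shot contributes **two** records at the same x — one per trial —
consistent with the per-trajectory loss; the correlation between the pair
is ignored, which for overdamped dynamics (velocities redrawn, trials
independent) is exact. The loss

    l(w|θ) = Σ_i log(1 + e^{s_i q(x_i|w)})

equals the binomial negative log-likelihood up to the fixed combinatorial
coefficient; `nll_from_counts` implements the aggregated form and the test
suite asserts the identity. With a linear q this is logistic regression,
which provides closed-form cross-checks throughout.

## Committor network

A pyramid of fully connected tanh blocks whose widths decay geometrically
from an input width to a final width (factor f = (final/input)^{1/(B−1)}),
with an inverted-dropout schedule decaying by the same factor, and a single
linear output neuron producing the log-predictor q. The optional `residual`
flag adds identity skips between equal-width blocks. Training is full-batch
Adam (base rate 1e−3); full-batch keeps gradients deterministic under a
seed, which the toy problem sizes (≤ 10⁴ records) easily afford. The toy
runs use a 12→6 pyramid with dropout 0 — at one input dimension, dropout
only adds variance.

Transfer retraining re-randomizes the final neuron, freezes everything
else, and early-stops on a 20 % held-out split with a patience of 200
epochs (configurable; an appropriate patience scales with how long one
epoch is relative to the dataset, so no single value is canonical).

Gradient attribution of coordinates uses central finite differences of the
composed map q(features(x)) (step 1e−5), scaled by inverse mass; the
network also exposes an analytic input gradient via backprop, and the two
agree to ~1e−6 on smooth maps.

## Guided sampling loop

- Shooting points are drawn from p_sel ∝ 1/(q² + γ²) along the current
  path; γ = 1 by default and is held constant within a run (annealing it
  would complicate the acceptance ratio for no demonstrated benefit at toy
  scale).
- The backward trial inverts momenta at the shooting point; for overdamped
  dynamics it is an independent forward realization, valid by time
  reversibility of the equilibrium dynamics.
- Acceptance uses p_acc = min(1, p_sel(SP|χ′)/p_sel(SP|χ)) with the model
  frozen at move time — one selection density per move, even while the
  model evolves between moves. Because q(X_SP) appears in both densities,
  the ratio reduces to the ratio of the paths' Lorentzian normalizations.
- Rejected moves increment the current path's weight (the path is repeated
  in the ensemble), and their records are kept for training: the learner
  sees every virtual experiment.
- Multiple chains advance round-robin (deterministic order, per-chain RNG
  streams) and share one model and one cumulative training set.
- Retraining is considered every third MC step: the ledger's efficiency
  factor over a k = 100-step window sets lr = α_eff · 10⁻³, and training is
  skipped when lr < 10⁻⁴ (equivalently α_eff < 0.1) — the learning-rate
  floor realizes the training threshold, since the two gating rules
  coincide at these defaults. The toy runs train for 30 epochs per gated
  update rather than 1: with thousands-fold fewer records than a molecular
  run, one epoch is a much smaller gradient step, and the gate (not the
  epoch count) is what prevents overfitting.
- State softening replaces the geometric states by committor iso-levels
  p_B ≤ 0.1 / p_B ≥ 0.9. It is refused for a model that assigns no probe
  point to either side (e.g. the untrained q ≡ 0 model, for which every
  point sits at p_B = 0.5).

## Validation ledger

Per shot, the ledger stores the model's committor at the trial shooting
point *before* the outcome is observed. Expected counts are sums of
2p(1−p) over a sliding window (each term ≤ 1/2, so n_exp ≤ k/2);
α_eff = min(1, (1 − n_gen/n_exp)²), with n_exp = 0 defined as maximal
mismatch 1. Offline, `sample_committor` estimates p̂_B as the fraction of
committed fresh one-way trials entering B, and `crossval_bins` bins sampled
against predicted committors on held-out configurations, reporting empty
bins as absent rather than zero.

## Symmetry functions

G² and G⁵ follow the standard radial / radial-angular forms with the Fermi
cutoff f_c(r) = [1 + exp(α_c(r − r_cut − 1/√α_c))]^{−1} for r ≤ r_cut and 0
beyond. Two conventions of these descriptors are implemented exactly as defined and their
consequences quantified rather than "fixed":

- The −1/√α_c midpoint shift places the sigmoid's half-height beyond
  r_cut, so f_c jumps from 1/(1+e^{−√α_c}) to 0 at the cutoff.
- The isotropic normalization uses the closed form V⁽²⁾ ≈ 8π r_s² √(2/η),
  stated for small η. `g2_probe_volume_quadrature` evaluates the defining
  integral numerically; at the example parameters (η = 25, r_s = 0.5) the
  ratio is ≈ 0.68, and the ideal-gas mean of the normalized G² matches that
  ratio — the quadrature oracle quantifies the bias, and no test asserts
  the closed form's accuracy.

The G⁵ pair normalization uses ⟨N_pairs⟩ ≈ ⟨N⟩²/2 (non-negative by
construction) with V⁽⁵⁾ = 2^{1−ζ} V⁽²⁾ (2ζ−1)!!/ζ!; ζ is an even integer
≤ 16 (the double factorial is computed iteratively). Angles use a clamped
arccos-free dot-product formulation for float safety. The rational distance
switch (1−(r/R0)⁶)/(1−(r/R0)¹²) is evaluated as the algebraically identical
1/(1+(r/R0)⁶), removing the 0/0 point at r = R0 (value 1/2).

## Attribution

Δl_i averages the loss over n_perms ≥ 1 (default 100) copies of the
training set with column i shuffled across the batch, minus the unpermuted
reference loss, subtracting before averaging so an input the model ignores
gets exactly zero. Reported values are raw differences — the ranking is
what matters downstream. Duplicated informative columns split importance
between them; the tests assert only nonnegativity up to Monte-Carlo noise
for that case.

## Symbolic regression

Expression trees over {+, −, ×, ÷, exp, log, neg} (pow available but off
by default). Protected semantics make evaluation total: log(x ≤ 0),
|denominator| ≤ 1e−12 and overflow mark rows invalid; each invalid row
contributes a fixed penalty of 1e3 to the loss. Complexity counts every
operator node, unary negation included (the worked polymer form counts 7
under this convention). Constants are fitted per candidate by L-BFGS-B
(warm start from the inherited values, one seeded random restart).
Mutations are operator swap (40 %), depth-2 subtree replacement (35 %) and
additive/multiplicative constant injection (25 %); offspring above 24 nodes
are discarded, which keeps the search in the compact regime the complexity
penalty is meant to favor. The fitted best-constant model is always in the
comparison, so the result never loses to predicting a single number, and
(N+1) elitism makes the fitness trace monotone. Pareto selection prefers a
held-out validation loss when one is supplied and falls back to the
training loss; the knee (maximal perpendicular distance to the endpoints'
chord in normalized coordinates) is a suggestion — the full front is
always reported.

The gas-hydrate model's reference constants are recorded as metadata only
(`CLATHRATE_CONSTANTS`); its functional form is not reconstructed, so
nothing evaluates it.

## TP analysis

DTW uses the classic three-way dynamic program with Euclidean local cost.
It is symmetric and zero on identical sequences but violates the triangle
inequality — it is a dissimilarity, not a metric. Pairwise matrices
arc-length-resample each polyline to 64 points by default (bounding the
quadratic DP cost; the raw frames can be kept with `resample=None`).
Hierarchical clustering is scipy average linkage by default, cut at
n_clusters = 2 — method and count are flags, not claims. Path density
increments a cell once per visiting path regardless of frame count.

## Synthetic data and what passing tests show

The generators emulate the statistical structure of real inputs — Bernoulli
outcomes from a planted committor, ideal-gas clouds, bundled polylines —
with defaults chosen to be informative at desk scale: logistic records use
n = 5000 (parameter recovery within 10 % is then comfortably testable),
clouds use densities giving a handful of points per probe shell, polyline
bundles are separated by ~7 noise standard deviations. They do not emulate
metastability of real feature distributions, correlated noise, or
high-dimensional redundancy, so passing tests demonstrate correctness of
the machinery, not performance on molecular data.

## Problem sizes of the shipped checks

The statistical acceptance checks run at sizes where their tolerances are
meaningful but desk-cheap: 200–500 shots per committor estimate (binomial
3 s.e. ≈ 0.07), 2000 guided MC steps for committor recovery (MAE < 0.05
against the quadrature oracle), 3000 frozen-model steps thinned to 500
paths for the detailed-balance KS test against 500 directly excised
transitions, 200 ES generations on 1200 planted records for SR recovery,
and ~36 paths for channel clustering. These sizes are the package's
standing study conditions; enlarging them tightens every check
monotonically.

## Known limitations

- No periodic boundaries, no force fields, no GPU paths — by design.
- The underdamped integrator randomizes velocities every step; it is a
  thermostat for shooting, not a tool for dynamical correlation functions.
- The committor network is full-batch; datasets far beyond ~10⁵ records
  would need minibatching, which would break bit-reproducibility of the
  current training path.
- DTW resampling (default 64 points) slightly smooths very long paths;
  distances used for clustering are insensitive to this at the separations
  the toys produce.
- The N-state softmax generalization is implemented at the link/loss level
  only; the samplers are two-state.
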