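# Methods

## Model

Three stochastic layers, independent conditional on their inputs:

1. **Tree growth.**  A linear birth–death process starts from one lineage at
   time 0 and runs for time *t*: each lineage splits at rate λ (> 0) and dies
   at rate μ (≥ 0), both per lineage per unit time.  The edge from time 0 to
   the first speciation is the *stem edge*; leaves of lineages alive at time
   *t* are *extant*, all others are extinct-lineage leaves.  Asymptotic
   quantities assume the supercritical regime λ > μ.

2. **Feature evolution.**  Discrete features arise along every branch
   (extinct lineages included) as a Poisson process at rate *r* per lineage
   per unit time; every gain is a globally novel feature.  Each feature
   currently carried by a lineage is lost at rate ν per feature per unit
   time.  At a speciation the feature set is copied to both daughters.  F₀
   features may be present at the top of the stem (default 0).  On a single
   path of length ℓ started empty, the count is Poisson with mean
   (r/ν)(1 − e^{−νℓ}); the FD of a whole fixed tree started empty is also
   Poisson.

3. **Extinction at the present.**  The field-of-bullets (FOB) model kills
   each extant species independently with probability 1 − s; the generalised
   form allows species-specific s_x.  Fixed-fraction pruning (retain exactly
   round(s·n) tips, chosen uniformly) is also provided because replicated
   simulation studies typically control the survivor count; s always denotes
   the *survival* fraction, and rounding is half-away-from-zero.

Feature diversity FD(A) is the richness-weighted count of distinct features
over the union of the feature sets of A; richness weights are supported in
the set-level layer and fixed at 1 in the tree-based layers.

## Exact quantities

* **Set level.**  E[φ] = Σ_f μ̃(f)(1 − Π_{x: f∈F_x}(1 − s_x)) with μ̃
  normalised over the full assignment.  This is evaluated literally (no
  approximation); it is concave and ≥ s whenever features are shared, equal
  to s for pairwise-disjoint feature sets.  The concentration bound is
  McDiarmid's inequality with bounded differences FD({x})/FD(X):
  P(|φ − E[φ]| > ε) ≤ 2 exp(−2ε²/R_n), R_n = Σ_x [FD({x})/FD(X)]².

* **Fixed tree.**  `expected_fd_tree` uses the recursion
  q(extant leaf) = s, q(extinct leaf) = 0,
  q(v) = 1 − Π_c (1 − e^{−νℓ_c} q(c)), and
  E[FD] = Σ_e (r/ν)(1 − e^{−νℓ_e}) q(bottom(e)) + F₀ e^{−νℓ₀} q(root).
  The edge term thins the gain Poisson process by survival to the edge's
  lower end; independence of feature fates makes the product form exact.
  The recursion form for general trees is this package's construction; it is
  gated in the tests on the two-leaf closed forms (which it must reproduce to
  1e-12 relative error) and on Monte-Carlo agreement on larger random trees.

* **Birth–death trees.**  A feature born at time τ spreads like a linear
  birth–death process with birth λ and death μ + ν; sampling survivors with
  probability s at the present gives the classical survival probability
  R_{t−τ}^s(λ, μ+ν).  Integrating over birth times (lineage intensity
  e^{(λ−μ)τ}) yields E[FD(pruned)]; the large-t ratio reduces to
  φ_FD(s) = s·I(s)/I(1) in the derived parameters ρ = (μ+ν)/λ and
  β = 1 − (λ−μ)/ν.  The expectations are over *all* realisations, including
  trees that die before t; the Monte-Carlo oracles therefore simulate
  unconditionally (a dead tree contributes FD = 0).

* **Singletons.**  Total expected FD changes only by new gains
  (rate r per extant lineage, e^{(λ−μ)t} lineages in expectation) and by
  losses of features carried by exactly one species (rate (μ+ν) per such
  feature — loss of the feature or death of its sole carrier), giving
  U_t = (r e^{(λ−μ)t} − dF_t/dt)/(μ+ν).  The derivative is computed
  analytically (product + Leibniz rule on the integral form); a central
  difference with step max(1e-6, 1e-6·t) is exposed as a cross-check.

## Numerical choices

* Quadratures use `scipy.integrate.quad` at relative tolerance 1e-9.
* Branch selection: |λ − θ| ≤ 1e-12·λ takes the critical branch of R_t^s;
  |ρ − (1−s)| ≤ 1e-9 the removable-singularity branch of φ_PD; |β| ≤ 1e-9
  the ρ = 1 branch of I(s).  Below ρ₂ = ν/λ = 1e-6, φ_FD delegates to φ_PD
  (the curves agree to well within quadrature tolerance there).
* For β < 0 the substitution z = −β ln x maps I(s) to an integral over
  [0, ∞) whose integrand is evaluated in log space, stable for arbitrarily
  large |β| (i.e. ν ≪ λ − μ) where x^β would overflow near 0.
* ν = 0 uses the analytic limits (r/ν)(1 − e^{−νx}) → rx, e^{−νx} → 1,
  with `expm1`-based forms for small ν.
* Endpoints by continuity: φ curves return 0 at s = 0 and 1 at s = 1;
  R_t^s returns 0 at s = 0.
* Trees are dendropy objects wrapped with a stem-edge convention: the seed
  node's edge length is the stem.  On newick input, unary chains above the
  first branching node are collapsed into the stem by summing lengths, so
  all root-to-leaf path lengths are preserved exactly; extant flags are
  recovered as depth = age within 1e-9.  Pruning suppresses unary nodes by
  concatenating lengths (the stem may lengthen), preserving survivor path
  lengths exactly.
* Gillespie feature evolution is per-edge with inherited state in a fixed
  pre-order (children ordered by smallest descendant leaf label), so a run
  is reproducible from its integer seed regardless of how the tree object
  was built.  A loss may evict a feature gained earlier on the same edge.
  Feature identifiers are monotone (`g0, g1, ...`; root features
  `root0, ...`).
* Every stochastic entry point requires an explicit integer seed (`None` is
  rejected); the experiment driver derives per-replicate seeds from the
  master seed via `numpy.random.SeedSequence` spawning, consuming one seed
  for the tree, one per feature-loss rate, and one per (rate, s) pruning
  draw, in that order.

## What the simulators emulate — and what they do not

The synthetic pipeline reproduces the study conditions of the underlying
model: pure-birth trees (λ = 0.055, age 100, filtered by rejection to 250
extant tips, optionally ±2) and birth–death trees (λ = 0.11, μ = 0.088,
age 100, 250–300 extant tips), feature gain r = 0.3 with ν/λ ∈
{0, 0.5, 1, 2, 10}, and fixed-fraction extinction over s = 0.05…0.95.
Real clades violate several idealisations: diversification rates vary over
time and among lineages, features are neither exchangeable nor independent,
feature loss can be adaptive rather than memoryless, and extinction at the
present is not independent across species.  Passing tests therefore
establish internal correctness of the mathematics and the simulators under
the stated model, not the realism of that model for any particular dataset.

## Scaled-down defaults in tests

The replicate-spread study is validated with 100 replicate trees per
scenario (the driver's default is 500) and the Yule tip filter widened to
250 ± 2; tolerances are 3 Monte-Carlo standard errors of an SD estimator,
3·SD/√(2(n−1)).  Theory-vs-simulation checks use 2000 full-stack replicates
at t = 5 (pure birth) and t = 4 (birth–death), where trees stay small.
Problem sizes were chosen so the statistical power is adequate while a full
test run stays in the minutes range.

## Design decisions on open points

* Feature sets may be empty everywhere (FD of an empty union is 0): the
  simulator produces empty leaf sets naturally.
* F₀ is a fixed integer (default 0) rather than a random variable; the
  theory only requires it bounded.
* In fixed-fraction pruning s is the retained proportion.  Replicate spread
  is summarised as the SD across replicate trees at each s, averaged over
  the 19-point s grid.
* The per-species FD limit has no closed form at ρ = 1 and raises there.
* The rejection cap for tip filtering is 10⁶ attempts (configurable);
  pure-birth rejection aborts early once the count exceeds the upper bound,
  which is exact because pure-birth counts never decrease.

## Known limitations

* `expected_fd_tree` is exact only under unit richness and homogeneous
  rates; richness weights and rate heterogeneity across lineages are out of
  scope in the tree-based layers.
* Reconstructed-process samplers (conditioning on the tip count exactly,
  coalescent point process) are not implemented; conditioning is by
  rejection, which is slow for narrow tip windows.
* φ_FD(t, s) convergence in t is checked numerically, not proved here;
  near-critical regimes (λ ≈ μ) make t-convergence slow and the finite-t
  integral the better tool.
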