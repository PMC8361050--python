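# Methods

## Model

Expression levels S = (S₁, …, S_L) are treated as continuous real variables.
The maximum-entropy distribution constrained to reproduce the observed first
and second moments is the multivariate Gaussian with mean ⟨S⟩ and covariance
C; its energy function is pairwise, H = −Σ_{i<j} J_ij S_i S_j, with couplings
J_ij = −(C⁻¹)_ij. The model therefore assumes (a) interactions are adequately
captured at second order, and (b) the informative structure lives in the
*partial* correlations: an off-diagonal zero of the precision matrix means
conditional independence given all other genes. Location is irrelevant —
every downstream quantity is invariant to shifting the means — so synthetic
cohorts are generated mean-zero.

## Estimation

* **Moments.** Per-gene means and the maximum-likelihood covariance
  (divisor n, matching the maximum-entropy derivation; the n vs n−1 choice is
  immaterial at the sample sizes involved but is fixed for determinism).
  Zero-variance genes are dropped with a logged warning — they make C
  singular and carry no pairwise information.
* **Variance filter.** Optionally only the top-k most variable genes are
  kept (default k = 483 in the CLI), ranked by per-gene variance with stable
  ties, since genes with flat profiles contribute noise to C⁻¹ at real-data
  scale.
* **Graphical lasso.** Θ̂ = argmin −log det Θ + tr(SΘ) + λ‖Θ‖₁,off, solved by
  block coordinate descent: each sweep solves one lasso subproblem per
  column against the working covariance W (inner solver: cyclic coordinate
  descent, numba-compiled). The diagonal is not penalized, so at optimality
  diag(Θ̂⁻¹) = diag(S) and |（Θ̂⁻¹ − S)_ij| ≤ λ off the diagonal with signed
  equality on the active set; these KKT conditions are what the tests assert
  (gap < 10⁻⁶), alongside objective agreement with an independent ADMM
  proximal-splitting solver and with scikit-learn's implementation (both
  cross-checks only — the estimator itself is this package's code).
  Convergence is declared when the max absolute change of Θ̂ between sweeps,
  relative to its magnitude, falls below `tol` (default 10⁻⁶) within
  `max_iter` (default 500) sweeps; non-convergence raises with the final gap.
  Covariance (not unit-diagonal correlation) feeds the solver by default;
  `use_correlation=True` switches, since either reading is defensible for
  expression data.
* **Penalty λ.** λ is a free parameter of the analysis with no principled
  universal value. When not supplied, it is chosen to maximize held-out
  Gaussian log-likelihood (single 75/25 split, log-spaced grid 10⁻³…1), and
  the chosen value is recorded in every report. All published-style outputs
  carry the λ used.

## Balance energetics

Closed triangles (all three weights nonzero) are enumerated by per-edge
common-neighbour intersection. E_ijk = J_ij J_jk J_ki; balanced iff E > 0 —
zero-weight edges never form triads, so the dichotomy is total. The quartic
Hamiltonian sums Δ_a Δ_b over unordered pairs of distinct triangles sharing a
common edge, with Δ the *sign* of the triangle's weight product: the identity
H₄ = −s(G) with an integer square count forces the sign reading (a weighted
variant is exposed via `weighted=True`). Distinct triangles of a simple graph
can share at most one edge, so the pair set is unambiguous; the per-edge sum
uses (ΣΔ)² − ΣΔ² over 2, checked against exhaustive pair enumeration.

## Topology

* **Filtration.** Sublevel on |J|: vertices at 0, edge (i,j) at |J_ij|,
  every (k+1)-clique at the max of its edge values, k ≤ `max_dim` (default 3,
  the minimum that makes β₂ exact). Weak edges enter first — the convention
  under which β₀ starts at the gene count and decreases as the threshold
  grows, and under which negative couplings participate by magnitude. A
  raw-weight mode exists for non-negative networks. Ties are broken by
  (value, dimension, lexicographic vertices): deterministic and
  face-consistent.
* **Persistence.** Standard boundary-matrix column reduction over ℤ₂ (columns
  as index sets, pivot dictionary), in filtration order; unpaired classes get
  death = +∞ (essential). Zero-lifetime pairs — artifacts of simultaneous
  insertion, e.g. a chord arriving together with both triangles it closes —
  are dropped and counted in the log. Features of dimension ≥ `max_dim` are
  not reported (their deaths would need (max_dim+1)-simplices).
* **Oracle.** `betti_numbers_static` rebuilds the complex at a fixed
  threshold and computes β_k = dim C_k − rank ∂_k − rank ∂_{k+1} by dense
  GF(2) elimination — a different algorithm sharing no reduction code, used
  to cross-validate the persistence engine at every critical threshold on
  random graphs, plus an Euler-characteristic identity on complexes whose
  largest clique has ≤ 4 vertices. A size guard (200 000 simplices) keeps the
  oracle honest about being a small-instance tool.
* **Summaries.** Connectivity threshold: smallest w with β₀(w) = 1, defined
  only when the full graph is connected. Loop onset: smallest dimension-1
  birth. β₂ "saturation": the smallest threshold at which β₂ attains its
  grid maximum — curves are step functions, so this operationalizes a
  plateau without a smoothness assumption. All summaries are recomputable
  from the persisted pairs CSV alone (round-trip tested).

## Synthetic data

Ground-truth precision matrices have Bernoulli(edge_density) support,
uniform magnitudes in [weight_low, weight_high], signs negative with
probability negative_fraction, and diagonals set to row absolute sum +
diagonal_boost — strict diagonal dominance guarantees SPD for *any*
support/sign pattern at the cost of somewhat diffuse spectra. Cohort pairs
share support, signs and the uniform quantile draw, so the interval width is
the only contrast between "cancer-like" (default magnitudes 0.1–0.2) and
"normal-like" (0.1–0.8) members; defaults p = 50 genes, n = 2000 samples per
cohort, density 0.1 — large enough for stable graphical-lasso support,
small enough to run everywhere. What the generator does **not** emulate:
count noise (no negative-binomial layer), library-size artifacts, batch
effects, or non-Gaussian marginals of real RNA-seq. Passing tests therefore
demonstrate correctness of the estimators and the topology engine under the
model's own assumptions, not robustness to real-data misspecification.

Toy fixtures: `cycle_n` (β = (1,1,0) for n ≥ 4), `complete_n` (contractible),
`octahedron` (K₂,₂,₂, a triangulated sphere: (1,0,1)), `fig1c_analog` (the
octahedron with two edge-disjoint pendant 4-cycles at one vertex: (1,2,1)),
and `fig2_analog` (5 nodes, distinct weights, finite bars in dimensions 0
and 1).

## Numerical choices and degenerate inputs

Edgeless networks are valid everywhere (empty census, vertex-only
filtration, empty histogram descriptor). An expression matrix with a single
sample can be generated but not used for covariance estimation (explicit
error). Non-SPD precision inputs are rejected by Cholesky. The λ-grid
heuristic skips penalties whose fit fails. Perturbing all weights by less
than half the minimum weight gap provably cannot change the pairing
structure, which the stability test exercises.

## Known limitations

* Persistence is pure Python over index sets: comfortable to a few thousand
  simplices, not a replacement for optimized C++ persistence libraries at
  real-network scale (483 genes with a dense λ is feasible but minutes-slow).
* The two-cohort comparison is directional by design; no hypothesis test is
  attached to the flags, and "earlier/lower" statements depend on both
  cohorts being analyzed with the same λ and grid.
* The quartic energy's multiplicity convention (each shared-edge pair counted
  once) is one defensible reading of the square-count identity; the weighted
  variant is provided but not used in reports.
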