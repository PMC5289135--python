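# Methods

`confnav` analyzes collections of molecular conformers through four stages:
a structural metric (environment descriptors combined by an
entropy-regularized matching kernel), a nonlinear 2-D map (sketch-map), a
hierarchical classification (RMS-linkage clustering with representative
structures), and automated diagnostics (dendrogram outlier scanning and a
structure/property consistency screen). This note records the models, the
parameters that matter, the numerical choices, and what the bundled
synthetic data does and does not establish.

## Environment descriptors

Each atom-centered environment is a smooth neighbor density: Gaussians of
width `atom_sigma` (Å) at the displacement vectors of all atoms within
`cutoff` (Å), partitioned by chemical species, multiplied by a cosine
cutoff function ½(cos(πr/r_c)+1) that takes the density smoothly to zero at
r_c. The density is expanded in an orthonormal radial basis times real
spherical harmonics, and the invariant retained is the power spectrum
p_{nn'l}^{ab} = Σ_m c^a_{nlm} c^b_{n'lm}, flattened over species pairs
(a ≤ b), radial pairs and l, with √2 weights on off-diagonal blocks so the
flattened dot product equals the full tensor contraction, then normalized
to unit length. The environment kernel is k(x,x′) = (x·x′)^ζ with the dot
product clamped to [0,1].

Concrete numerical realization:

* radial basis φ_n(r) = (r_c − r)^{n+2}, n = 0..n_max−1, Löwdin
  orthonormalized with the analytically evaluated overlap
  ∫φ_nφ_m r² dr; this family is simple, well conditioned at these sizes,
  and vanishes smoothly at the cutoff;
* the neighbor integrals reduce to 1-D radial integrals of
  g_n(r)·exp(−(r−r_j)²/2σ²)·ĩ_l(r r_j/σ²) r², with ĩ_l the exponentially
  scaled modified spherical Bessel function (no overflow at any distance);
  these are evaluated with 80-node Gauss–Legendre quadrature on [0, r_c],
  converged far below the 1e-8 invariance tolerances used in the tests;
* the central atom contributes to its own density, so an isolated atom has
  a well-defined descriptor;
* the species alphabet is fixed up front (by default the union over the
  fitted dataset, or explicitly via `species_alphabet`), so descriptors of
  different structures are always comparable.

Defaults: cutoff 4.0 Å, atom_sigma 0.3 Å, n_max 8, l_max 6, ζ = 2 —
conventional magnitudes for small organic molecules; all overridable.
Species in `species_mask` are removed both as centers and from the density,
which is exactly equivalent to deleting those atoms (tested). This is how a
perturbing cation is excluded when comparing decorated to bare conformers.

## REMatch kernel and kernel distance

Structures A and B are compared through C_ij = k(x_i^A, x_j^B). The
structure kernel is the entropy-regularized optimal matching

    K^γ(A,B) = Σ_ij P_ij C_ij,   P = argmin Σ_ij P_ij (1 − C_ij + γ ln P_ij)

over matrices with row sums 1/N_A and column sums 1/N_B. This marginal
convention extends the doubly stochastic set to unequal atom counts, keeps
K^γ a weighted mean of C (hence in [0,1]), and gives normalized diagonals
near one. γ interpolates between the best-match kernel (γ→0) and the
average-environment kernel (γ→∞); the default γ = 0.1 sits between the two
regimes. Kernels are normalized K′ = K/√(K_AA K_BB) by default so that the
induced distance D = √(K_AA + K_BB − 2K_AB) reflects shape rather than
molecule size. The REMatch kernel is not guaranteed positive semidefinite;
negative radicands in D are clamped to zero and counted
(`DistanceMatrix.n_clamped`), a signal to raise γ.

Sinkhorn solver: alternating row/column updates carried out entirely in the
log domain (small γ never overflows), with marginal tolerance 1e-6 and
max_iter 5000 by default. Two practical findings are baked in:

* matrices in a dataset-level computation are batched by shape, and
  converged members of a batch are frozen so stragglers do not hold the
  batch hostage;
* for *symmetric* C (self-kernels, duplicated structures) the alternating
  scheme can stall for thousands of iterations on an antisymmetric
  near-null mode; a damped symmetric iteration (f = g, ½ damping) removes
  it and converges in tens of iterations to the same optimum (the entropic
  problem is strictly convex, so the solution is unique and symmetric).

Two caveats on the γ limits, measured with the enumeration oracles used in
the tests: at γ = 0.01 the kernel is biased below the exact best-match
value by the entropy of near-tied assignments (order 1e-3 for random C with
N ≤ 6), and at γ = 100 it exceeds mean(C) by approximately the
doubly-centered variance of C over γ. Neither is a solver artifact; both
shrink with the corresponding limit. Marginal convergence at γ ≤ 0.01 is
also intrinsically slow (residuals plateau near 2e-6 after 1e5
iterations on hard matrices), so small-γ evaluations should use a looser
marginal tolerance — the kernel value converges orders of magnitude earlier
than the marginals.

## Sketch-map

The 2-D embedding minimizes S² = Σ_{i<j} [F(D_ij) − f(d_ij)]², with the
sigmoid F(r) = 1 − (1 + (2^{a/b} − 1)(r/σ)^a)^{−b/a} applied with exponents
(A,B) to the input distances and (a,b) to the map distances; F(0) = 0 and
F(σ) = ½ for any exponents. Defaults A = a = 1, B = b = 4: conformer
databases hold minimum-energy structures, so short-range distances are kept
faithful (A = a = 1) while long-range ones are compressed (B = b = 4). Maps
are labeled "σ–A_B–a_b".

σ is the sensitive parameter. The automatic rule histograms the N(N−1)/2
pairwise distances into 100 equal-width bins, takes D_max as the center of
the most populated bin (leftmost on ties) and sets σ = 0.8·D_max.

Optimization: the stress is non-convex, so the fit runs a deterministic
classical-scaling (Torgerson) initialization — with a sign convention on
the eigenvectors for reproducibility — followed by L-BFGS-B with the
analytic gradient, plus n_starts − 1 = 4 seeded perturbed restarts (10% of
the initial spread); the best final stress wins. Pairs at d = 0 contribute
their residual but no gradient direction (guarded at 1e-12). When distances
are exactly realizable in 2-D the initialization is already globally
optimal and the optimizer polishes to stress ~1e-29.

Out-of-sample projection minimizes a single point's stress against the
fixed landmark coordinates: a 64×64 grid over the landmark bounding box
padded by 25% per side, then L-BFGS refinement from the best cell (tight
ftol/gtol, since projection accuracy is asserted at 1e-3 of the map scale);
the refined point is accepted only if it beats the grid. Landmarks are
selected by farthest point sampling (greedy max–min, ties to the lowest
index), default at most 500.

## RMS-linkage clustering

The linkage Δ(X,Y) = √(mean of D² over cross pairs) is implemented with the
update Δ²(X∪Y,Z) = (N_X Δ²(X,Z) + N_Y Δ²(Y,Z))/(N_X+N_Y), which is
algebraically exact (not an approximation) — the central correctness
property, tested against a from-scratch re-evaluation at every merge and
against the identity with average linkage on squared distances. Ties are
broken by the lexicographically smallest node pair, making merge sequences
platform-independent. RMS linkage is not guaranteed monotone; inversions
are kept as computed and counted in the log, and cutting is therefore
defined by the *maximum* height inside a subtree: a flat cluster is a
maximal subtree whose internal merges all sit at or below the cut.

Representatives minimize the mean squared distance to the members (ties to
the lowest index); the spread σ_D is the RMS distance to the
representative, zero for singletons. `suggest_cut_height` proposes the
midpoint of the largest gap between sorted merge heights; with
`min_child_size ≥ 2` the gap search ignores merges that only attach tiny
branches, so a handful of extreme outliers does not mask the separation
between the main groups.

## Diagnostics

The consistency screen cuts the tree (default 0.1, the same height used to
truncate dendrogram plots) and reports (σ_D, σ_E) per cluster, σ_E being
the population standard deviation of the property (an RMS-about-the-
representative variant is available via `spread_mode`). A cluster is
flagged inconsistent when σ_D < sigma_D_max and σ_E > sigma_E_min —
structurally tight but property-wild, the signature of entries computed
under inconsistent conditions. The thresholds are deliberately user-set;
the (σ_D, σ_E) table itself is the primary output, since real screens are
read from that scatter. Flags are monotone in both thresholds (tested).

The outlier scan walks merges from the root while their height is ≥
min_height and reports branches of ≤ max_size leaves hanging off such
merges — the "small branch at the top of the dendrogram" pattern.

## Synthetic data

The generator builds conformers of a fixed 8-atom chain template (species
O-C-N-C-C-O plus two hydrogens; bonds 1.0–1.5 Å, angles 109.5–112°) by NeRF
placement, with two rotatable torsions (atoms 0-1-2-3 and 2-3-4-5) as the
only degrees of freedom — the smallest system exhibiting a bimodal
torsional landscape analogous to peptide-bond cis/trans isomerism. Study
conditions (defaults): 200 structures, 2 basins at torsion centers
(180°,180°) and (0°,180°), Gaussian torsional noise of 5°, basin energy
offsets 0 and 0.3 eV, torsional stiffness k = 1 eV in
E = offset + Σ_t k(1 − cos(θ_t − θ_center)) + N(0, 0.01 eV), 1% planted
outliers (torsions chosen to maximize the minimum circular distance to all
centers over 200 seeded candidates), and optionally a fraction of entries
with a constant +0.5 eV offset emulating an inconsistent level of theory.
Geometries are resampled on atom clashes below 0.5 Å (error after 100
tries). Everything is reproducible from the seed; basin labels and
outlier/inconsistent flags are returned and written as a TSV sidecar. A
`add_cation` helper attaches one cation (default Ca) 2.4 Å from a random
O/N atom for the species-masked projection workflow.

What the generator emulates: well-separated torsional basins with
sub-basin noise, a smooth structure–energy relation, rare outliers and a
property-inconsistent subset. What it does not: real force-field energetics,
flexible bond lengths/angles, thermal ensembles, solvent effects, and the
size and chemical diversity of a real database. Passing the end-to-end
tests therefore demonstrates that the chain of methods recovers planted
structure at realistic noise levels — not that any particular real database
would cluster equally cleanly.

End-to-end problem sizes used by the tests and the acceptance script: 200
conformers for the recovery study (full 200×200 kernel, ≈20k Sinkhorn
problems of size 8×8), 60 farthest-point landmarks for the out-of-sample
check, 50 points for the planar sketch-map recovery, 8-point matrices (30
replicates) for the linkage brute force, N ≤ 6 for the permutation oracle.
These sizes are chosen so every oracle remains exactly enumerable while
each stage still operates in its intended regime.

## Known limitations

* The REMatch kernel's indefiniteness means kernel distances can require
  clamping at small γ; the count is reported rather than hidden.
* Sketch-map stress is non-convex; restarts mitigate but do not guarantee
  the global optimum on hard landscapes (σ far from the automatic choice).
* `suggest_cut_height` is a heuristic; analyses that depend on a specific
  granularity should set the cut explicitly.
* The toolchain targets isolated molecules; periodic systems, descriptor
  gradients and species-alchemy similarity are out of scope.
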