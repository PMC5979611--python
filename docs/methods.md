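# Methods

## The problem

A potential of mean force (PMF) A(ξ) is the effective free energy of a
system as a function of a low-dimensional reaction coordinate ξ (here,
typically a pair of backbone dihedral angles): A(ξ) = −k_BT ln P(ξ).
Transition states and minor conformers carry exponentially little
probability, so unbiased sampling never visits them.  Umbrella sampling
fixes this by running many *windows* — biased simulations with a harmonic
restraint ω_i(ξ) = ½(ξ−ξ_i^ref)ᵀK_i(ξ−ξ_i^ref) — and recombining their
histograms with WHAM.  The expensive open question is *where to put the
windows*.  `uiexplore` automates that choice: starting from a single
window, it grows the sampled region outward along directions of steepest
descending free energy, so minima and the saddles between them are
discovered in ascending PMF order and the budget is never spent on
irrelevant high-free-energy regions.

## The window model and umbrella-integration gradients

Each window's biased distribution is approximated as a multivariate
normal with the run's sample mean ⟨ξ⟩ᵇ and covariance C (a second-order
cumulant truncation; the N−1 sample covariance is used).  Differentiating
the unbiased free energy under this approximation gives the per-window
gradient estimate

    g_i(ξ) = (1/β) C_i⁻¹ (ξ − ⟨ξ⟩_i^b) − K_i (ξ − ξ_i^ref),

and windows are combined with occupation weights p_i(ξ) ∝ N_i P_i^b(ξ)
normalized over windows.  Weight arithmetic is done in log space with a
max-shift; windows whose normalized weight falls below 1e−12 are dropped —
at double precision they contribute nothing, which also makes "all
neighboring windows" equivalent to "all windows".  These gradients steer
exploration only; PMF *values* always come from WHAM, which behaves
better in more than one dimension.

On a quadratic PMF with exact window statistics (the biased window is then
exactly Gaussian, with precision β(H+K)), the estimate is exact at every
point — the package's strongest correctness oracle, exercised in the tests
to 1e−10 relative error.

## The exploration loop

0. Sample one window at a user-chosen start (ideally near a low minimum).
1. Among windows flagged as *border* windows, pick the one with the lowest
   WHAM PMF at its mean (the *parent*).
2. Spawn candidates on the parent's covariance ellipsoid at Mahalanobis
   radius √3 (radii √(3σ_j²) along the eigen-axes e_j).  In 2D these are N
   equiangular points (default 8, θ = 360°/N); in 1D the two axis points;
   in ≥3D the primitive integer lattice vectors satisfying Σ|K_i| ≤ n+M
   (n = number of nonzero components), read in eigen-axis coordinates and
   Mahalanobis-normalized.  Antiparallel lattice directions are kept
   distinct; positive collinear multiples are collapsed to the primitive
   vector.
3. Prune: a candidate's *nearest neighboring* (N.N.) window is the
   registered window (parent excluded) with maximal biased density at the
   candidate; the candidate is rejected iff its Mahalanobis distance to the
   N.N. mean, in the N.N. window's own metric, is < 2.5.  If everything is
   rejected the parent is no longer a border window.  The parent must be
   excluded from the N.N. search: its own candidates sit at √3 < 2.5 by
   construction and would otherwise always self-reject.
4. Among surviving candidates, pick the one with the steepest-descent
   directional gradient (combined gradient at the parent mean projected on
   the parent→candidate direction); exact ties break to the lowest
   candidate index.
5. Sample the new window there with the default force constant.  If the
   realized mean deviates from the requested center by more than 1.0 in
   the window's own Mahalanobis metric, the force constant is doubled and
   the window resampled (up to 3 retries); a still-deviating window is
   flagged but kept.  The *realized mean* is what future steps treat as
   the window's position.

WHAM is re-solved after every accepted window (warm-started from the
previous offsets; `wham_every` can relax this), so step 1 always sees
current PMF values.  Termination: no border windows remain (full
coverage), every border window's PMF exceeds a configured threshold
(threshold mode), or the window budget `max_iterations` is reached.

## WHAM

Standard self-consistent iteration on a shared grid (default 60 bins per
dihedral dimension over (−π, π], resolving 0.1 rad features), with
periodic wrap-around binning and all exponentials in log space:

    P(b) = Σ_i n_i(b) / Σ_i N_i exp(β(F_i − ω_i(b)))
    F_i  = −(1/β) ln Σ_b P(b) exp(−β ω_i(b))

iterated until max_i|ΔF_i| < 1e−7 kJ/mol (cap 1e5 sweeps).  Because the
fixed-point iteration converges only linearly (thousands of sweeps once
many windows overlap), the solve is accelerated by damped Newton on the
equivalent convex objective Φ(g) = Σ_b M_b ln Σ_i N_i e^{g_i−βω_ib} −
Σ_i N_i g_i (g = βF, gauge g_0 = 0), whose gradient and Hessian are one
softmax sweep; the certifying self-consistent sweeps then terminate
immediately.  Histogram counts are stored as floats so exact
Boltzmann-integrated bin probabilities can stand in for sampled counts in
oracle tests.  Empty bins are masked, not assigned +∞: a partially
explored landscape is the normal operating state, and masked bins are
excluded from normalization and parent-selection queries.  The PMF is
shifted to min 0 after every solve.

Two further maskings protect sampled solves.  Bins with pooled counts
below a small floor (`min_counts`, 5 in the explorer) are treated as
unsampled: a lone excursion count in a bin where every bias is large is
amplified by the unbiasing factor e^{βω} into an absurdly deep PMF value
that would hijack the min-0 normalization.  The explorer additionally
restricts the solve to its *covered* region — bins within the pruning
radius (2.5 Mahalanobis) of some window mean — since beyond that only
Gaussian-tail excursions land.  Whenever bins are cropped, each window's
effective sample count becomes the counts it retains inside the solved
bins (the restricted-domain likelihood); keeping raw totals would bias
frontier windows' offsets, and that bias accumulates along window chains
into whole-kJ/mol basin errors.
PMF queries interpolate multilinearly over bin centers with periodic wrap;
masked corners of the interpolation cell are dropped with weight
renormalization, and a query whose own bin is masked raises an
out-of-explored-region error.  Offsets are gauge-fixed (F_0 = 0); only
differences matter and the tests assert gauge invariance.

## Units and conventions

Internal energies are kJ/mol with k_B = 0.0083144621 kJ/mol/K (reports
convertible to kcal/mol, factor 4.184).  Angular coordinates live in
(−π, π]; the boundary tie wraps to +π.  All periodic displacements use the
minimal image, which is valid because biased windows are localized
(σ = 1/√(βK) ≈ 0.16 rad at K = 100 kJ/mol/rad² and 298 K, far below 2π);
no multi-image summation is performed.  Window moments are computed by
unwrapping samples to the image nearest the bias center and taking
ordinary moments — circular moments would distort the σ_j that set the
candidate radii.  A window whose smallest covariance eigenvalue falls
below 1e−12 is rejected as degenerate rather than regularized, because its
inverse covariance would be meaningless downstream.

## Synthetic surfaces and samplers

MD runs are replaced by analytic surfaces plus samplers drawing from
exp[−β(A+ω)]:

- **quadratic**: A = ½(ξ−μ)ᵀH(ξ−μ); biased window statistics available in
  closed form (covariance (β(H+K))⁻¹, mean solving (H+K)m = Hμ + Kξ^ref),
  both as a noise-free "exact statistics" sampler and as ground truth for
  Monte-Carlo moments.
- **1D double well**: quartic a(x²−1)² + tx with (a, t) solved numerically
  so the barrier above the lower well and the inter-minimum PMF difference
  equal the requested values exactly.
- **toy 4-well torus** (`toy_dipeptide`): four von-Mises-product wells on
  (−π, π]², A = −Σ_w D_w Π_j exp[κ(cos(ξ_j−c_wj)−1)], normalized so the
  deepest minimum is 0.  Default depths 12/9/6/3 kJ/mol, κ = 2, centers in
  a chain around the torus chosen so the saddle that opens each successive
  basin is strictly higher than the previous one (7.4, 9.5, 10.3 kJ/mol):
  a lowest-PMF-first frontier therefore reaches the basins in depth order,
  the desk-scale analogue of discovering conformations in ascending PMF
  order.  The stationary-point catalog is built by Newton refinement of
  the analytic gradient from a coarse grid and classified by Hessian
  signature.

The sampler is random-walk Metropolis (isotropic Gaussian proposals;
the default step is the optimal random-walk scaling 2.38/√d times the
biased well's own width 1/√(βK), which roughly minimizes the integrated
autocorrelation time — measured τ ≈ 7 steps versus ≈ 10 for unit-σ
proposals; burn-in 10% of the requested samples, mirroring a short
equilibration before production).
It needs only A(ξ) itself, is exactly reproducible under a seed, and warns
when the acceptance rate leaves (0.05, 0.95).  Autocorrelation is *not*
corrected: N_i is the raw post-burn-in count.  Consequences: effective
sample sizes are ~an order of magnitude below N, and bins covered only by
the outermost windows' Gaussian tails carry ~1 kJ/mol statistical noise
at 10⁴ samples/window.  Quantitative PMF checks therefore evaluate the
window-tiled interior, where multiple windows overlap.  What passing tests
on these fixtures do *not* show: force-field realism, solvent effects,
kinetic trapping of real MD, or multimodal window distributions that
violate the Gaussian window assumption.

## Stationary-point analysis

Minima are grid bins strictly below all unmasked neighbors (Moore
neighborhood, periodic), refined by a least-squares quadratic fit (5×5
patch where fully sampled, else 3×3 — the wider fit averages out the
selection bias of the lowest noisy bin) and merged if within one bin
width of each other (keeping the lower).  On sampled PMFs, histogram
noise additionally produces shallow dimples that are genuine strict
minima of the noisy grid; an optional topological-persistence filter
(`min_prominence`, in energy units) discards minima whose barrier to a
deeper basin is below the threshold.  Noise dimples have persistence
comparable to the per-bin statistical error (≲0.5 kJ/mol at 10⁴
samples/window), well below physically meaningful barriers; the packaged
2D pipeline reports use 1.0 kJ/mol.  Saddles (2D) come from watershed
basin labeling by ascending-PMF flooding, with shallow basins first
absorbed across their lowest ridge under the same prominence threshold:
for each pair of surviving basins sharing a sampled boundary, the
transition state is the lowest ridge crossing (min over adjacent
opposite-label bin pairs of the higher PMF), refined by a local quadratic
fit only when the local Hessian is saddle-shaped.  This is robust to
bin-level noise where Hessian eigenanalysis of raw WHAM bins is not.  Basin pairs that meet only along
the flat background produce ridge crossings near maxima rather than true
saddles — readers of the report should treat TS entries near the
background level accordingly.  Reports list minima then saddles sorted by
PMF, coordinates to 0.1 rad, energies to 0.1 kJ/mol (or kcal/mol)
relative to the global minimum.

## Numerical and design choices

- **RNG**: one root seed; window i samples with seed root+i, so runs are
  bit-reproducible and windows independent.  Identical config + seed gives
  byte-identical output files (floats written at 17 significant digits).
- **Warm starts**: each WHAM call after a new window starts from the
  previous offsets (the new window inherits the last F value).
- **Candidate positions in masked bins are allowed**: pruning is purely
  distribution-based; the PMF mask only matters for parent selection.
- **Step-0 window** uses the same center-deviation retry rule as step 5.
- **Degenerate inputs**: empty time series, windows with no histogram
  overlap with the rest, fully masked grids, and zero-length child
  directions all raise typed errors rather than propagating NaNs.

## Known limitations

- The force-constant doubling rule (step 5) halves the child's σ per
  doubling, and a narrow child's candidates (radius √3·σ_child) may be
  unable to escape the 2.5·σ_NN pruning radius of wider neighbors.  On
  steep 1D surfaces, where downhill mean drift is the trigger and there
  are no lateral candidates, this can stall the frontier below a barrier.
  The packaged 1D study conditions therefore follow the window-spacing
  guideline — choose K so that √(3/(βK)) comfortably exceeds the drift
  g/(K+H) — e.g. K = 200 kJ/mol/unit² for the barrier-5 double well.  In
  2D the lateral candidates route around the issue.
- Exploration cost grows with the area below the PMF threshold divided by
  the window footprint (∝ 1/(βK)); the desk-scale 4-well run places
  ~150–200 windows.
- Saddle detection requires the barrier region to be sampled; threshold
  mode deliberately leaves barriers above the threshold unsampled, and the
  corresponding TS entries are then absent, not extrapolated.
- Problem sizes used in the shipped tests and acceptance script (10⁴
  samples/window, 60-bin grids, 4-well torus, ≤400 windows) are the
  package's desk-scale reference conditions; they exercise every stage of
  the method at interactive cost.
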