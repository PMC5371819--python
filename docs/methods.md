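# Methods

`swiveldyn` analyses the conformational dynamics of multi-domain enzymes of
the pyruvate phosphate dikinase (PPDK) type, whose central domain (CD)
swivels ~45 Å between the nucleotide-binding domain (NBD) and the
PEP/pyruvate-binding domain (PBD). The package covers two complementary
routes to that picture: geometric/statistical analysis of structural
ensembles (clustering, Cartesian PCA, collectivity, cross-correlation,
domain rotations), and free-energy reconstruction along reaction
coordinates from umbrella-sampling time series (WHAM). A synthetic-data
module supplies every input with exact ground truth, so each estimator is
validated end to end without simulation data or structure downloads.

## Structures and the canonical residue frame

All cross-structure analyses run in the mature *Flaveria trinervia* PPDK
numbering (1–874, post transit-peptide cleavage). Domain boundaries used
throughout: NBD 1–340 (subdomains NBD1 1–111 ∪ 197–243, NBD2 112–196, NBD3
244–340), CD 380–515, PBD 535–874, linker = the remainder of 341–534.
Structures from other organisms are renumbered with user-supplied residue
maps (JSON; injective, unmapped residues dropped and logged). Insertion
codes are part of the residue key, so mapped and unmapped entries cannot
collide silently. Waters are excluded on reading; other hetero groups
(PEP, nucleotide analogues) are kept and flagged because ligand–residue
distances are analysis targets. Alternate locations resolve to the
highest-occupancy conformer.

Ensembles are built over the residues holding a Cα in *every* member
(intersection after mapping); no sequence alignment is computed. The
ensemble archive is a text format: one JSON header line (ids, residues,
fitted flag) plus one whitespace-delimited row of 3M floats per member.

## Geometry

Superposition is the Kabsch least-squares rigid fit (SVD with the
reflection guard), refusing fewer than 3 points or collinear sets. Domain
rotations are measured in two stages: superpose state 2 on state 1 over the
anchor domain's Cα, then extract the residual best-fit rotation of the
moving domain; the angle comes from the rotation vector (reported unsigned
in [0, 180]°, direction carried by the axis), the screw translation is the
centroid shift projected on the axis. For the CD swiveling the anchor is
the PBD; the NBD1 hinge angle uses NBD3 as anchor. Unresolved residues
inside a selection are dropped from the paired set (logged), mirroring
crystal-structure gaps.

Two reaction coordinates summarize the motion: distance(CD–PBD) =
H456 Cα – H565 Cα, and distance(NBD1–NBD3) = S215 Cα – E272 Cα. A missing
landmark flags the coordinate as undefined rather than raising.

## Ensemble analysis

* **Clustering.** Agglomerative, complete linkage, on the pairwise best-fit
  Cα RMSD matrix — each pair superposed independently, so arbitrary
  deposition frames cannot inflate distances. Merging stops strictly below
  the cutoff (default 4 Å). The representative of a cluster is its medoid
  (minimal summed RMSD to co-members; ties → lowest member index).
* **Cartesian PCA.** The superposition frame is found iteratively: fit all
  members to the running mean over the current fit set (initially all
  residues), recompute per-residue positional variance, replace the fit set
  with the `fit_fraction` (default 15 %) least-fluctuating residues, repeat
  until stable (≤ 20 rounds; an oscillating set is accepted with a
  warning — convergence is typically 2–4 rounds). The 3M×3M coordinate
  covariance (uniform Cα weights, population normalization) is then
  eigendecomposed via the thin SVD of the centered member matrix.
  Eigenvalues are variances (Å²); fractions are eigenvalue/trace.
* **Collectivity.** For a component restricted to a domain of N atoms,
  κ = N⁻¹ exp(−Σ uᵢ² ln uᵢ²) with uᵢ² the squared per-atom displacement
  magnitudes normalized to unit sum (0·ln 0 := 0). κ = 1 means uniform
  participation, κ = 1/N a single moving atom; κ is invariant under
  rescaling of the eigenvector. An all-zero restriction raises.
* **Cross-correlation (DCCM).** C_ij = ⟨Δrᵢ·Δrⱼ⟩ / (⟨|Δrᵢ|²⟩⟨|Δrⱼ|²⟩)^½
  about the ensemble mean of a fitted ensemble. Residues with (numerically)
  zero fluctuation are flagged and their rows set to NaN.

## Free-energy reconstruction (WHAM)

Umbrella windows tether one or two reaction coordinates with harmonic
biases w_k(ξ) = Σ_d K_d/2 (ξ_d − ξ_d⁰)² (+ an optional additive constant,
kept for gauge checks). The unbiased distribution is found by iterating

    P(ξ) ∝ Σ_k n_k(ξ) / Σ_k N_k exp[(F_k − w_k(ξ))/k_BT]
    F_k = −k_BT ln Σ_ξ P(ξ) exp(−w_k(ξ)/k_BT)

to self-consistency; the PMF is −k_BT ln P with its minimum over visited
bins anchored at 0, and unvisited bins stay undefined (never extrapolated).
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹, default temperature 300 K.

Numerical choices: bin width 0.5 Å per dimension (two bins per 1 Å window
spacing resolve tooth shapes); convergence when max_k |ΔF_k| < 10⁻⁶
kcal/mol (default cap 2·10⁵ iterations; the solver accepts a warm start,
used by the bootstrap); biases are evaluated at bin centers; samples
outside the grid are dropped and the per-window counts adjusted, so grids
should cover the sampled range with margin. Before solving, the window
graph (edges = shared visited bins) must be connected, otherwise the gap is
reported — free energies of disconnected groups have no common scale.

Uncertainties come from a moving-block bootstrap: per window, the block
length is the integrated autocorrelation time (initial-positive-sequence
estimator on the first coordinate, FFT-based), blocks are resampled to the
original length, and the per-bin standard deviation over (default 100)
re-solves is reported. Split-half consistency solves on the first and
second halves of every window; the package reports the binwise maximal
absolute PMF difference, and the validation study turns it into a z-score
|ΔPMF| / √(s₁² + s₂²) against the halves' own bootstrap uncertainties —
the standard two-sample consistency test. Stationary sampling keeps
max z ≲ 3; a drifting coordinate pushes the raw difference far above the
kcal/mol scale. Window-overlap diagnostics report the histogram
intersection Σ min(p̂₁, p̂₂) for adjacent window pairs (consecutive centers
in 1D; centers within 1.5× the minimal spacing in 2D).

Minima/barrier extraction on binned profiles: a bin is a local minimum if
strictly below all visited orthogonal neighbors; the barrier between two
minima is the lowest level at which they join one connected component of
the thresholded bin graph (min–max path), reported relative to the first
minimum.

## Synthetic data: what it emulates, and what it does not

* **Biased sampling.** Metropolis chains with uniform proposals sample
  U(ξ) + bias at 300 K. `sample_biased` defaults to a 0.5 Å proposal;
  `generate_window_set` auto-scales the proposal to 4·√(k_BT/K) (≈ 3.1 Å at
  K = 1), near the optimum for the tethered distribution — at much smaller
  steps the chain diffuses, and the window-to-window random walk of free
  energies dominates the reconstruction error. Burn-in 10³ steps; every
  chain consumes only its own spawned PCG64 stream, so window sets are
  bit-reproducible and any single window is reproducible in isolation.
  These chains have the exact Boltzmann stationary distribution but no
  molecular kinetics: autocorrelation mimics sampling inefficiency, not
  physical relaxation times.
* **Landscapes.** The swiveling sawtooth (range 10–52 Å, period 10 Å,
  tooth height 2 kcal/mol, tilt −1.4 kcal/mol per period, windows every
  1 Å, K = 1 kcal/mol/Å²) reproduces the shape regime of the swiveling
  PMF — kT-scale teeth on a net slope — not any PPDK quantity. The coupled
  2D landscape adds a harmonic channel in the second coordinate whose
  center is constant below a threshold and linear beyond it, emulating a
  transition that first leaves the second coordinate untouched and then
  proceeds diagonally. Double-well and harmonic forms support calibration
  tests with closed-form answers.
* **Planted ensembles.** Members = base + Σ c_j v_j + ε with c_j ~ N(0,
  variance_j) on orthonormal modes and isotropic per-atom noise; optional
  random rigid transforms emulate arbitrary deposition frames.
  `internal_modes` projects modes orthogonal to the base's six rigid-body
  modes, as physical internal motions are; without this the mandatory
  superposition would absorb planted variance. Validation ensembles use a
  10 Å bead spacing so mode displacements (≈ 1–3 Å per atom) stay small
  against the fold dimensions and the finite superposition remains in the
  linear regime the closed-form spectrum assumes. These ensembles have
  Gaussian, low-rank-plus-noise statistics; real conformational ensembles
  are neither Gaussian nor noise-isotropic, so passing tests certify the
  estimators, not any biological claim.

## Validation studies (problem sizes)

The studies in `swiveldyn.validation` (run by `scripts/acceptance.py` and
the acceptance tests) use: harmonic recovery 42 windows × 5·10⁴ samples
(RMS vs the parabola over |x| ≤ 5 Å); sawtooth recovery 42 × 4·10⁴ with 100
bootstrap resamples (barrier/tilt errors measured against the identical
feature extraction applied to the analytic profile on the same bins);
2D separability 10×10 windows × 2·10⁴ (marginals vs independent 1D solves,
compared over the region with 1D PMF ≤ 4 kcal/mol — outside it, steep-wall
bins carry histogram-discretization offsets that the two routes sample
differently); PCA 2·10⁴ members of a 10-bead planted ensemble, full-residue
fit (see above); DCCM 500 members with a planted −0.3 inter-block
correlation; clustering 2 × 5 planted conformers. Sampling lengths were
sized from the observed n^(−1/2) error scaling to keep recovery errors a
few-fold below the documented tolerances.

The PCA planted-mode study fits over **all** residues rather than the 15 %
subset: at small planted systems the subset fit pins the subset's
coordinates exactly (3 atoms = 9 dof = one rigid transform) and absorbs
part of any planted mode, so the closed-form expected spectrum only applies
in the full-fit frame. The 15 % iterative scheme is the default for real,
heterogeneous structure sets and has its own behavioral test (the fit set
must converge into a planted static region).

## Known limitations

* WHAM evaluates biases at bin centers; strongly curved PMF regions need
  finer bins (bin width is configurable).
* The bootstrap block length is a point estimate of the autocorrelation
  time; severely non-stationary windows should be caught by the split-half
  check, not the bootstrap.
* 2D grids with unvisited interior bins leave the PMF undefined there;
  barrier extraction then reflects the visited graph only.
* Domain-rotation angles depend on the anchor choice; the package reports
  the frame used and makes no attempt to infer hinges.
* The common-residue rule is numbering intersection after mapping; it
  cannot repair wrong residue maps.
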