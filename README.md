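# swiveldyn

Conformational-ensemble and free-energy analysis of large single-domain
motions in multi-domain enzymes, built around the swiveling central domain
(CD) of pyruvate phosphate dikinase (PPDK): the CD carries a catalytic
histidine between two distant active sites (the nucleotide-binding domain,
NBD, and the PEP/pyruvate-binding domain, PBD), one of the largest domain
movements known (~110°, ~45 Å). The package is for structural
bioinformaticians and simulators who want to go from deposited structures
and umbrella-sampling time series to clustered conformational states,
essential motions, and potentials of mean force — with every estimator
validated against synthetic data whose answer is known exactly.

## What it computes

* **Ensembles from structures** — PDB/mmCIF reading (gemmi), residue-map
  renumbering into the canonical *F. trinervia* frame, common-residue Cα
  stacks, Kabsch superposition.
* **Conformational states** — complete-linkage hierarchical clustering on
  pairwise best-fit RMSD (cutoff 4 Å), medoid representatives.
* **Essential motions** — Cartesian PCA of the Cα covariance with an
  iterative least-fluctuating-residue superposition frame; per-domain
  collectivity κ = N⁻¹ exp(−Σ uᵢ² ln uᵢ²) ∈ [1/N, 1]; dynamic
  cross-correlation maps C_ij = ⟨Δrᵢ·Δrⱼ⟩/(⟨|Δrᵢ|²⟩⟨|Δrⱼ|²⟩)^½.
* **Domain geometry** — inter-domain rotation angle/axis/screw after
  anchor-domain superposition; reaction coordinates distance(CD–PBD) =
  d(H456 Cα, H565 Cα) and distance(NBD1–NBD3) = d(S215 Cα, E272 Cα).
* **Free energies** — 1D/2D WHAM on harmonically biased umbrella windows:

      P(ξ) ∝ Σ_k n_k(ξ) / Σ_k N_k exp[(F_k − w_k(ξ))/k_BT],
      F_k = −k_BT ln Σ_ξ P(ξ) e^{−w_k(ξ)/k_BT},   PMF = −k_BT ln P

  with moving-block bootstrap errors, window-overlap diagnostics,
  split-half convergence checks, and minima/barrier extraction.
* **Synthetic ground truth** — Metropolis sampling of analytic landscapes
  (harmonic, tilted sawtooth, double-well, coupled 2D) under the same
  1 Å / 1 kcal mol⁻¹ Å⁻² window geometry as the original umbrella setup,
  and planted-mode structural ensembles for the PCA/DCCM/clustering tests.

## Worked example

Reconstruct a swiveling-like PMF from scratch — sample biased windows from
a tilted sawtooth (four 2 kcal/mol teeth over 10–52 Å, tilt −1.4 kcal/mol
per 10 Å period), then run the full WHAM pipeline:

```sh
python analysis/01_simulate_windows.py
python analysis/02_pmf_1d.py
```

prints

```
WHAM converged in 2854 iterations; min window overlap 0.42
bootstrap max std 0.085 kcal/mol; split-half max |dPMF| 0.272 kcal/mol

 minimum (A)  PMF (kcal/mol)    truth
       10.25           5.685    5.600
       20.25           4.240    4.200
       30.25           2.715    2.800
       40.25           1.380    1.400
       50.25           0.000    0.000

successive-minimum drops (truth 1.4 kcal/mol per period): [-1.445 -1.525 -1.335 -1.38 ]
```

The five minima sit one landscape period apart; each reconstructed depth is
within the bootstrap noise of the analytic value, and the successive drops
recover the planted 1.4 kcal/mol tilt — the signature by which a sawtooth
profile biases thermal fluctuations into directional motion.
`analysis/03_pmf_2d.py` does the same for a coupled 2D landscape (constant
second coordinate below a threshold, then diagonal — the stepped-motion
pattern), and `analysis/04_conformational_analysis.py` runs clustering,
PCA, collectivity and DCCM on a planted-mode ensemble.

The same machinery is scriptable (`swiveldyn simulate|wham|ensemble|
cluster|pca|dccm|geom|make-ensemble|report`, see `--help`) and importable
(`swiveldyn.wham.solve`, `swiveldyn.ensemble_analysis.run_pca`, ...).

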