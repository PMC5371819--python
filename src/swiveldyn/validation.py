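"""Ground-truth recovery studies on synthetic data.

Each function runs one pipeline stage against inputs whose answer is known
in closed form or by construction, and returns the recovery metrics. These
studies are the package's standing evidence that the estimators work at
desk scale: the free-energy studies use the same window geometry as the
original umbrella setup (1 A ladder, 1 kcal/mol/A^2 tethers, 300 K) with
sampling lengths reduced to what a single CPU covers in seconds to minutes.

Problem sizes used here (window counts, samples per window, ensemble sizes)
are the package defaults for validation and are documented in the methods
note; all randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from . import synthetic, wham
from .ensemble_analysis import (cluster_ensemble, collectivity_from_displacements,
                                cross_correlation, run_pca)
from .structures import EnsembleAlignment
from .wham import KB


def _anchored(x: np.ndarray) -> np.ndarray:
    return x - x.min()


# ---------------------------------------------------------------------------
# WHAM studies
# ---------------------------------------------------------------------------

def harmonic_recovery(seed: int = 0, n_windows: int = 42,
                      n_samples: int = 50_000) -> dict:
    """Reconstruct U = 1/2 * 0.5 * x^2 from a ladder of biased windows.

    Windows are spaced 0.5 A apart (``n_windows`` of them, centered on 0)
    with 1 kcal/mol/A^2 tethers; the PMF is compared with the analytic
    parabola over |x| <= 5 A, both anchored at their minimum.
    """
    land = synthetic.Harmonic(stiffness=0.5)
    half = 0.25 * (n_windows - 1)
    centers = np.linspace(-half, half, n_windows)
    windows = synthetic.generate_window_set(
        land, centers, force_constant=1.0, n_samples=n_samples, seed=seed)
    edges = wham.make_grid([(-half - 0.75, half + 0.75)], 0.5)
    _, prof = wham.solve(windows, edges)
    c = prof.bin_centers[0]
    mask = (np.abs(c) <= 5.0) & prof.visited
    est = _anchored(prof.free_energy[mask])
    true = _anchored(land.energy(c[mask]))
    rms = float(np.sqrt(np.mean((est - true) ** 2)))
    return {"rms_deviation": rms, "n_windows": n_windows,
            "n_samples_per_window": n_samples}


def sawtooth_recovery(seed: int = 0, n_samples: int = 40_000,
                      n_bootstrap: int = 100) -> dict:
    """Recover the tilted sawtooth profile emulating the swiveling PMF.

    42 windows every 1 A over 10-52 A, K = 1 kcal/mol/A^2, four ~2 kcal/mol
    teeth with a -1.4 kcal/mol tilt per 10 A period. Reports the errors of
    the extracted barrier heights and end-to-end tilt against the same
    extraction applied to the analytic profile, the split-half maximal PMF
    difference, and bootstrap standard deviations.
    """
    land = synthetic.swiveling_sawtooth()
    lo, hi = land.range
    centers = np.arange(lo, hi, 1.0)  # 42 windows, 1 A ladder
    windows = synthetic.generate_window_set(
        land, centers, force_constant=1.0, n_samples=n_samples, seed=seed)
    edges = wham.make_grid([(lo - 2.0, hi + 2.0)], 0.5)
    _, prof = wham.solve(windows, edges)

    def interior_features(fe: np.ndarray, visited: np.ndarray):
        c = prof.bin_centers[0]
        mask = (c >= lo) & (c <= hi) & visited
        sub = wham.PMFProfile(
            edges=[np.linspace(lo, hi, mask.sum() + 1)],
            free_energy=_anchored(fe[mask]), std=None,
            visited=np.ones(mask.sum(), dtype=bool), temperature=300.0)
        return wham.profile_features(sub)

    est_f = interior_features(prof.free_energy, prof.visited)
    true_fe = land.pmf(prof.bin_centers[0])
    true_f = interior_features(true_fe, np.ones_like(prof.visited))

    def adjacent_barriers(feats):
        mins = sorted(feats.minima)
        return ([feats.barriers.get((a[0], b[0]), np.nan)
                 for a, b in zip(mins, mins[1:])],
                [v for _, _, v in mins])

    bar_e, min_e = adjacent_barriers(est_f)
    bar_t, min_t = adjacent_barriers(true_f)
    n_pair = min(len(bar_e), len(bar_t))
    barrier_err = float(np.max(np.abs(np.asarray(bar_e[:n_pair])
                                      - np.asarray(bar_t[:n_pair]))))
    tilt_est = min_e[0] - min_e[-1]
    tilt_true = min_t[0] - min_t[-1]

    std = wham.bootstrap_errors(windows, edges, n_resamples=n_bootstrap,
                                seed=seed)
    p1, p2, split_diff = wham.split_half_check(windows, edges)
    # consistency z-score: each bin's half-vs-half PMF difference against
    # the bootstrap uncertainty of that difference, sqrt(s1^2 + s2^2)
    half_stds = []
    for half, sub_seed in (("first", seed + 1), ("second", seed + 2)):
        sub = []
        for w in windows:
            r = w.retained
            mid = len(r) // 2
            part = r[:mid] if half == "first" else r[mid:]
            sub.append(wham.UmbrellaWindow(w.centers, w.force_constants, part))
        half_stds.append(wham.bootstrap_errors(sub, edges,
                                               n_resamples=n_bootstrap,
                                               seed=sub_seed))
    joint = p1.visited & p2.visited
    delta = np.abs(p1.free_energy - p2.free_energy)
    sigma = np.sqrt(half_stds[0] ** 2 + half_stds[1] ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(joint, delta / sigma, np.nan)
    return {"barrier_max_error": barrier_err,
            "tilt_error": float(abs(tilt_est - tilt_true)),
            "tilt_estimate": float(tilt_est),
            "tilt_truth": float(tilt_true),
            "split_half_max_difference": float(split_diff),
            "split_half_max_z": float(np.nanmax(z)),
            "bootstrap_max_std": float(np.nanmax(std)),
            "n_windows": len(windows),
            "n_samples_per_window": n_samples}


def separability_2d(seed: int = 0, n_windows_per_dim: int = 10,
                    n_samples_2d: int = 20_000, n_samples_1d: int = 50_000,
                    relevant_pmf: float = 4.0) -> dict:
    """Marginals of a 2D solve on U(x,y) = U1(x) + U2(y) vs the 1D solves.

    The marginal PMF of the 2D solution (Boltzmann sum over the other
    coordinate) must agree with an independent 1D reconstruction of each
    factor. The comparison covers the thermally relevant region (1D PMF <=
    ``relevant_pmf`` kcal/mol); outside it, steep-wall bins carry large
    histogram-discretization offsets in both routes and few samples.
    """
    lx = synthetic.DoubleWell(minima=(-2.0, 2.0), barrier=2.0)
    ly = synthetic.Harmonic(stiffness=0.5)
    land = synthetic.Separable2D(lx, ly)
    gx = np.linspace(-4.0, 4.0, n_windows_per_dim)
    gy = np.linspace(-4.0, 4.0, n_windows_per_dim)
    cc = np.array([(x, y) for x in gx for y in gy])
    w2 = synthetic.generate_window_set(land, cc, force_constant=1.0,
                                       n_samples=n_samples_2d, seed=seed)
    edges = wham.make_grid([(-6.5, 6.5), (-6.5, 6.5)], 0.5)
    sol2, prof2 = wham.solve(w2, edges)
    kt = KB * prof2.temperature
    dens = sol2.probability.reshape(prof2.free_energy.shape)

    devs = {}
    sub_seeds = np.random.default_rng(seed).integers(2 ** 31, size=2)
    for axis, (land1, grid1, child_seed) in enumerate(
            [(lx, gx, sub_seeds[0]), (ly, gy, sub_seeds[1])]):
        marg = dens.sum(axis=1 - axis)
        w1 = synthetic.generate_window_set(
            land1, grid1, force_constant=1.0, n_samples=n_samples_1d,
            seed=int(child_seed))
        _, prof1 = wham.solve(w1, [edges[axis]])
        with np.errstate(divide="ignore"):
            pmf_marg = -kt * np.log(marg)
        ok = (prof1.visited & (marg > 0)
              & (_anchored_nan(prof1.free_energy) <= relevant_pmf))
        d = pmf_marg[ok] - prof1.free_energy[ok]
        d -= d.mean()
        devs["xy"[axis]] = float(np.max(np.abs(d)))
    return {"marginal_max_deviation_x": devs["x"],
            "marginal_max_deviation_y": devs["y"],
            "n_windows": len(w2), "n_samples_per_window": n_samples_2d}


def _anchored_nan(x: np.ndarray) -> np.ndarray:
    return x - np.nanmin(x)


# ---------------------------------------------------------------------------
# ensemble-analysis studies
# ---------------------------------------------------------------------------

def pca_planted_recovery(seed: int = 0, n_residues: int = 10,
                         n_members: int = 20_000) -> dict:
    """Recover two planted modes (variances 9 and 1 A^2) under 0.01 A^2
    per-atom isotropic noise.

    Reports the top-2 variance fractions (expected 0.9/0.1 up to the small
    noise-floor contribution) and the absolute overlap of each estimated
    eigenvector with its planted mode. The ensemble is generated in a common
    frame with modes orthogonal to rigid-body space, so the appropriate
    superposition fits over all residues; the least-fluctuating-subset frame
    is for heterogeneous structure sets and would pin part of a planted mode.
    """
    # wide bead spacing keeps planted displacements (up to ~3 A per atom)
    # small against the fold dimensions, so the finite superposition stays
    # in the linear regime of the rigid-body projection
    base = synthetic.chain_walk_coords(n_residues, seed=seed,
                                       bond_length=10.0)
    modes = synthetic.internal_modes(base, 2, seed=seed)
    spec = synthetic.PlantedEnsembleSpec(
        base=base, modes=modes, variances=np.array([9.0, 1.0]),
        noise_variance=0.01, n_members=n_members, seed=seed)
    ens, truth = synthetic.generate_ensemble(spec)
    pca = run_pca(ens, fit_fraction=1.0)
    overlaps = [float(abs(pca.eigenvectors[j] @ truth.modes[j]))
                for j in range(2)]
    return {"variance_fraction_1": float(pca.variance_fractions[0]),
            "variance_fraction_2": float(pca.variance_fractions[1]),
            "mode_overlap_1": overlaps[0], "mode_overlap_2": overlaps[1],
            "n_members": n_members, "n_residues": n_residues}


def collectivity_limits(n_atoms: int = 10, seed: int = 0) -> dict:
    """kappa at its two exact limits plus agreement with a brute-force
    term-by-term evaluation on a random displacement vector."""
    uniform = np.ones((n_atoms, 3))
    single = np.zeros((n_atoms, 3))
    single[0] = (1.0, 2.0, 3.0)
    rng = np.random.default_rng(seed)
    random_disp = rng.normal(size=(n_atoms, 3))
    # brute force: literal evaluation of the entropy formula
    u2 = np.array([float(v @ v) for v in random_disp])
    u2 = u2 / u2.sum()
    s = 0.0
    for val in u2:
        if val > 0:
            s += val * np.log(val)
    brute = float(np.exp(-s) / n_atoms)
    return {"kappa_uniform": collectivity_from_displacements(uniform),
            "kappa_single_atom": collectivity_from_displacements(single),
            "kappa_random": collectivity_from_displacements(random_disp),
            "kappa_random_brute_force": brute,
            "n_atoms": n_atoms}


def dccm_planted_recovery(seed: int = 0, n_members: int = 500,
                          block_size: int = 20,
                          rho: float = -0.3) -> dict:
    """Estimate a planted inter-block correlation of two 20-residue blocks.

    Each block moves coherently along a fixed direction with unit-variance
    amplitude; the two amplitudes are drawn with correlation ``rho``; small
    isotropic noise keeps per-residue fluctuations non-degenerate.
    """
    rng = np.random.default_rng(seed)
    m = 2 * block_size
    base = synthetic.chain_walk_coords(m, seed=seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    amps = rng.multivariate_normal([0.0, 0.0], cov, size=n_members)
    direction = np.array([1.0, 0.0, 0.0])
    coords = np.repeat(base[None], n_members, axis=0)
    coords[:, :block_size] += amps[:, 0, None, None] * direction
    coords[:, block_size:] += amps[:, 1, None, None] * direction
    coords += rng.normal(0.0, np.sqrt(0.003), size=coords.shape)
    ens = EnsembleAlignment([f"m{i}" for i in range(n_members)],
                            [(i + 1, "") for i in range(m)], coords,
                            fitted=True)
    cc = cross_correlation(ens)
    inter = cc.matrix[:block_size, block_size:]
    return {"inter_block_mean_correlation": float(np.nanmean(inter)),
            "planted_correlation": rho, "n_members": n_members}


def cluster_planted_recovery(seed: int = 0, n_per_blob: int = 5,
                             n_residues: int = 40) -> dict:
    """Two blobs of conformers (intra-blob RMSD < 1 A, inter-blob > 8 A)
    must be recovered exactly by complete-linkage clustering at 4 A."""
    rng = np.random.default_rng(seed)
    base1 = synthetic.chain_walk_coords(n_residues, seed=seed)
    shift = np.zeros((n_residues, 3))
    shift[n_residues // 2:, 0] += 20.0  # half the chain displaced: RMSD >> 8
    base2 = base1 + shift
    members = []
    for b in (base1, base2):
        for _ in range(n_per_blob):
            members.append(b + rng.normal(0.0, 0.3, size=b.shape))
    coords = np.stack(members)
    ens = EnsembleAlignment([f"m{i}" for i in range(len(members))],
                            [(i + 1, "") for i in range(n_residues)],
                            coords, fitted=False)
    cl = cluster_ensemble(ens, cutoff=4.0)
    labels = np.array([cl.labels[f"m{i}"] for i in range(len(members))])
    planted = np.array([0] * n_per_blob + [1] * n_per_blob)
    exact = len(set(labels)) == 2 and all(
        len(set(labels[planted == g])) == 1 for g in (0, 1))
    return {"n_clusters": cl.n_clusters,
            "partition_recovered": bool(exact),
            "n_members": len(members)}
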