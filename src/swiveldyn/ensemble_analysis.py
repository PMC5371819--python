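"""Clustering, Cartesian PCA, collectivity indices and cross-correlation
maps over conformational ensembles.

All analyses operate on the C-alpha stack of an
:class:`~swiveldyn.structures.EnsembleAlignment`. Clustering uses the
pairwise best-fit RMSD (each pair superposed independently) under complete
linkage; PCA diagonalizes the 3M x 3M Cartesian coordinate covariance after
an iterative superposition onto the ensemble mean over the least-fluctuating
residues; the collectivity index kappa quantifies how many atoms of a domain
participate in a principal component.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .geometry import superpose
from .structures import EnsembleAlignment

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: dict[str, int]             # member id -> cluster id (1-based)
    merge_heights: np.ndarray          # linkage heights, Angstrom
    representatives: dict[int, str]    # cluster id -> medoid member id
    linkage: str
    cutoff: float
    distance_matrix: np.ndarray        # (N, N) pairwise best-fit RMSD

    @property
    def n_clusters(self) -> int:
        return len(self.representatives)


def pairwise_rmsd_matrix(e: EnsembleAlignment) -> np.ndarray:
    """(N, N) matrix of pairwise best-fit C-alpha RMSD, each pair superposed
    independently (no shared frame)."""
    n = e.n_members
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = superpose(e.coords[i], e.coords[j]).rmsd
    return d


def cluster_ensemble(e: EnsembleAlignment, cutoff: float = 4.0) -> ClusterResult:
    """Agglomerative complete-linkage clustering of the ensemble.

    Merging stops before any merge whose maximal intra-cluster pairwise RMSD
    would reach ``cutoff`` (strictly-below criterion). The representative of
    each cluster is its medoid: the member minimizing summed RMSD to its
    co-members, ties broken by lowest member index.
    """
    if e.n_members < 2:
        raise ValueError("clustering needs at least 2 members")
    dmat = pairwise_rmsd_matrix(e)
    z = hierarchy.linkage(squareform(dmat, checks=False), method="complete")
    # 'distance' criterion merges up to height <= t; the cutoff is exclusive
    t = np.nextafter(cutoff, -np.inf)
    flat = hierarchy.fcluster(z, t=t, criterion="distance")
    labels = {mid: int(c) for mid, c in zip(e.member_ids, flat)}
    reps: dict[int, str] = {}
    for cid in sorted(set(flat)):
        idx = np.flatnonzero(flat == cid)
        cost = dmat[np.ix_(idx, idx)].sum(axis=1)
        reps[int(cid)] = e.member_ids[idx[int(np.argmin(cost))]]
    return ClusterResult(labels=labels, merge_heights=z[:, 2],
                         representatives=reps, linkage="complete",
                         cutoff=cutoff, distance_matrix=dmat)


# ---------------------------------------------------------------------------
# Cartesian PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    eigenvalues: np.ndarray        # descending, Angstrom^2
    eigenvectors: np.ndarray       # (n_components, 3M), orthonormal rows
    variance_fractions: np.ndarray
    mean_structure: np.ndarray     # (M, 3)
    fit_residue_indices: np.ndarray
    n_members: int
    fitted_coords: np.ndarray | None = None  # (N, M, 3) in the PCA frame

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def _fit_all_to(coords: np.ndarray, ref: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = np.empty_like(coords)
    for i, xyz in enumerate(coords):
        sup = superpose(xyz[idx], ref[idx])
        out[i] = sup.apply(xyz)
    return out


def run_pca(e: EnsembleAlignment, fit_fraction: float = 0.15,
            max_fit_iterations: int = 20) -> PCAResult:
    """Cartesian-coordinate PCA of the C-alpha stack.

    The superposition frame is found iteratively: members are fitted to the
    running mean over the current fit set (initially all residues), the fit
    set is replaced by the ``fit_fraction`` least-fluctuating residues
    (positional variance about the mean, summed over x, y, z), and the cycle
    repeats until the fit set is stable. This removes global translation and
    rotation using the most rigid part of the molecule before the covariance
    matrix is formed.
    """
    if e.n_members < 3:
        raise ValueError("PCA needs at least 3 ensemble members")
    m = e.n_residues
    n_fit = max(3, int(round(fit_fraction * m)))
    coords = e.coords.copy()
    idx = np.arange(m)
    seen: list[frozenset[int]] = []
    for it in range(max_fit_iterations):
        ref = coords.mean(axis=0)
        coords = _fit_all_to(coords, ref, idx)
        mean = coords.mean(axis=0)
        fluct = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # per-residue
        new_idx = np.sort(np.argsort(fluct, kind="stable")[:n_fit])
        key = frozenset(new_idx.tolist())
        if key == frozenset(idx.tolist()) and it > 0:
            idx = new_idx
            break
        if key in seen:
            warnings.warn("fit-set oscillation; accepting last set",
                          stacklevel=2)
            idx = new_idx
            break
        seen.append(key)
        idx = new_idx
    mean = coords.mean(axis=0)
    x = (coords - mean).reshape(e.n_members, 3 * m)
    # economy route: eigenvalues of X X^T / N equal those of the covariance
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s ** 2 / e.n_members
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    vecs = vt[order]
    total = eigvals.sum()
    fractions = eigvals / total if total > 0 else np.zeros_like(eigvals)
    return PCAResult(eigenvalues=eigvals, eigenvectors=vecs,
                     variance_fractions=fractions, mean_structure=mean,
                     fit_residue_indices=idx, n_members=e.n_members,
                     fitted_coords=coords)


# ---------------------------------------------------------------------------
# collectivity index
# ---------------------------------------------------------------------------

def collectivity_from_displacements(disp: np.ndarray) -> float:
    """Collectivity index kappa of a set of per-atom displacement vectors.

    kappa = N^-1 exp(-sum_i u_i^2 ln u_i^2) with u_i^2 the squared per-atom
    displacement magnitudes normalized to unit sum (0 ln 0 := 0). kappa = 1
    for uniform participation of all N atoms, kappa = 1/N when a single atom
    carries the whole mode.
    """
    disp = np.asarray(disp, dtype=float).reshape(-1, 3)
    n = len(disp)
    u2 = (disp ** 2).sum(axis=1)
    total = u2.sum()
    if total <= 0.0:
        raise ValueError("all-zero displacement: collectivity undefined")
    u2 = u2 / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u2 > 0, u2 * np.log(u2), 0.0)
    return float(np.exp(-terms.sum()) / n)


def collectivity(p: PCAResult, component: int, e: EnsembleAlignment,
                 domain_residues: list[int]) -> float:
    """kappa of one principal component restricted to a domain's atoms."""
    if component >= p.n_components:
        raise IndexError(f"component {component} out of range "
                         f"({p.n_components} available)")
    idx = e.residue_indices(domain_residues)
    if len(idx) == 0:
        raise ValueError("domain has no residues within the common set")
    vec = p.eigenvectors[component].reshape(-1, 3)[idx]
    return collectivity_from_displacements(vec)


# ---------------------------------------------------------------------------
# cross-correlation map
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    matrix: np.ndarray           # (M, M), entries in [-1, 1]; NaN = undefined
    residues: list = field(default_factory=list)
    undefined: np.ndarray = None  # boolean mask of zero-fluctuation residues


def cross_correlation(e: EnsembleAlignment) -> CorrelationMatrix:
    """Dynamic cross-correlation map of C-alpha fluctuations.

    C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2> <|dr_j|^2>) with dr the deviation
    from the ensemble mean. Residues with zero fluctuation get NaN rows and
    are flagged in ``undefined``.
    """
    if e.n_members < 3:
        raise ValueError("cross-correlation needs at least 3 members")
    if not e.fitted:
        raise ValueError("ensemble must be superposed (fitted) first")
    dev = e.coords - e.coords.mean(axis=0)          # (N, M, 3)
    inner = np.einsum("nid,njd->ij", dev, dev) / e.n_members
    var = np.diag(inner)
    # tolerance absorbs mean-subtraction roundoff on truly static residues
    undefined = var <= 1e-20 * max(1.0, float(var.max(initial=0.0)))
    with np.errstate(divide="ignore", invalid="ignore"):
        c = inner / np.sqrt(np.outer(var, var))
    c[undefined, :] = np.nan
    c[:, undefined] = np.nan
    ok = ~undefined
    np.fill_diagonal(c, np.where(ok, 1.0, np.nan))
    c_ok = c[np.ix_(ok, ok)]
    np.clip(c_ok, -1.0, 1.0, out=c_ok)
    c[np.ix_(ok, ok)] = c_ok
    return CorrelationMatrix(matrix=c, residues=list(e.residues),
                             undefined=undefined)
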