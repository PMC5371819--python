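"""Weighted-histogram reconstruction of 1D/2D potentials of mean force from
harmonically biased umbrella-sampling time series.

Each umbrella window tethers the reaction coordinate(s) with a harmonic bias
w_k(xi) = sum_d K_d/2 (xi_d - xi0_d)^2. The unbiased probability P(xi) and
per-window free-energy shifts F_k are obtained by iterating the coupled
equations

    P(xi) = sum_k n_k(xi) / sum_k N_k exp[(F_k - w_k(xi)) / k_B T]
    F_k   = -k_B T ln sum_xi P(xi) exp(-w_k(xi) / k_B T)

to self-consistency; the PMF is -k_B T ln P anchored so its minimum over
visited bins is zero. Uncertainties come from a moving-block bootstrap with
block length set by the integrated autocorrelation time of each window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

logger = logging.getLogger(__name__)

#: Boltzmann constant, kcal mol^-1 K^-1
KB = 0.0019872041

DEFAULT_TEMPERATURE = 300.0
DEFAULT_BIN_WIDTH = 0.5
DEFAULT_TOLERANCE = 1e-6
DEFAULT_MAX_ITERATIONS = 200_000

#: fraction of each window discarded as equilibration, mirroring the
#: discard applied to the original umbrella simulations (2.5 of 42.5 ns for
#: the 1D runs, 1 of 9 ns for the 2D runs)
EQUILIBRATION_PRESETS = {"standard-1d": 2.5 / 42.5, "standard-2d": 1.0 / 9.0}


class WhamError(RuntimeError):
    pass


class DisconnectedWindowsError(WhamError):
    pass


class ConvergenceError(WhamError):
    def __init__(self, msg: str, residual_trace: np.ndarray):
        super().__init__(msg)
        self.residual_trace = residual_trace


# ---------------------------------------------------------------------------
# windows and grids
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    """One biased sampling window.

    ``samples`` has shape (n,) for one reaction coordinate or (n, d) for d
    coordinates; the first ``n_equil`` frames are discarded from analysis.
    """

    centers: tuple[float, ...]
    force_constants: tuple[float, ...]
    samples: np.ndarray
    n_equil: int = 0
    offset: float = 0.0  # additive constant in the bias (gauge freedom)

    def __post_init__(self) -> None:
        self.centers = tuple(float(c) for c in np.atleast_1d(self.centers))
        self.force_constants = tuple(
            float(k) for k in np.atleast_1d(self.force_constants))
        if len(self.force_constants) == 1 and len(self.centers) > 1:
            self.force_constants = self.force_constants * len(self.centers)
        if len(self.force_constants) != len(self.centers):
            raise ValueError("force constant / bias center dimension mismatch")
        if any(k <= 0 for k in self.force_constants):
            raise ValueError("force constants must be positive")
        s = np.asarray(self.samples, dtype=float)
        if s.ndim == 1:
            s = s[:, None]
        if s.shape[1] != len(self.centers):
            raise ValueError(f"samples have {s.shape[1]} coordinates, bias "
                             f"has {len(self.centers)}")
        self.samples = s
        if self.n_retained < 1:
            raise ValueError("window retains no samples after equilibration "
                             "discard")

    @property
    def ndim(self) -> int:
        return len(self.centers)

    @property
    def retained(self) -> np.ndarray:
        return self.samples[self.n_equil:]

    @property
    def n_retained(self) -> int:
        return len(self.samples) - self.n_equil


def bias_energy(w: UmbrellaWindow, xi: np.ndarray) -> np.ndarray:
    """Harmonic bias energy (kcal/mol) at point(s) ``xi``."""
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    if xi.shape[-1] != w.ndim:
        raise ValueError(f"point has {xi.shape[-1]} coordinates, window "
                         f"has {w.ndim}")
    k = np.asarray(w.force_constants)
    c = np.asarray(w.centers)
    e = 0.5 * (k * (xi - c) ** 2).sum(axis=-1) + w.offset
    return e if e.size > 1 else float(e[0])


def make_grid(ranges: list[tuple[float, float]],
              bin_width: float | list[float] = DEFAULT_BIN_WIDTH,
              ) -> list[np.ndarray]:
    """Bin edges per dimension for the given (lo, hi) ranges."""
    widths = np.broadcast_to(np.atleast_1d(bin_width), (len(ranges),))
    edges = []
    for (lo, hi), wdt in zip(ranges, widths):
        n = max(1, int(round((hi - lo) / wdt)))
        edges.append(np.linspace(lo, hi, n + 1))
    return edges


def grid_centers(edges: list[np.ndarray]) -> np.ndarray:
    """(B, d) array of flattened bin centers (C-order over dimensions)."""
    cs = [0.5 * (e[1:] + e[:-1]) for e in edges]
    mesh = np.meshgrid(*cs, indexing="ij")
    return np.stack([m.ravel() for m in mesh], axis=-1)


def _histogram(samples: np.ndarray, edges: list[np.ndarray]) -> np.ndarray:
    h, _ = np.histogramdd(samples, bins=edges)
    return h.ravel()


# ---------------------------------------------------------------------------
# solution containers
# ---------------------------------------------------------------------------

@dataclass
class WhamSolution:
    window_free_energies: np.ndarray   # F_k, kcal/mol (F_0 anchored to 0)
    probability: np.ndarray            # flattened per-bin density, sums*binvol=1
    iterations: int
    final_residual: float


@dataclass
class PMFProfile:
    edges: list[np.ndarray]
    free_energy: np.ndarray            # grid-shaped, kcal/mol, NaN unvisited
    std: np.ndarray | None             # same shape, bootstrap std dev
    visited: np.ndarray                # boolean mask
    temperature: float
    counts: np.ndarray | None = None   # total samples per bin

    @property
    def ndim(self) -> int:
        return len(self.edges)

    @property
    def bin_centers(self) -> list[np.ndarray]:
        return [0.5 * (e[1:] + e[:-1]) for e in self.edges]


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------

def _check_connectivity(visited_kb: np.ndarray,
                        windows: list[UmbrellaWindow]) -> None:
    k = len(windows)
    adj = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            adj[i, j] = adj[j, i] = bool(
                np.any(visited_kb[i] & visited_kb[j]))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        groups = []
        for c in range(n_comp):
            centers = [windows[i].centers for i in np.flatnonzero(labels == c)]
            groups.append((min(centers), max(centers)))
        raise DisconnectedWindowsError(
            "umbrella windows have zero sampling overlap between groups "
            f"spanning {groups}; no common free-energy scale exists")


def solve(windows: list[UmbrellaWindow], edges: list[np.ndarray],
          temperature: float = DEFAULT_TEMPERATURE,
          tolerance: float = DEFAULT_TOLERANCE,
          max_iterations: int = DEFAULT_MAX_ITERATIONS,
          f_init: np.ndarray | None = None,
          check_overlap: bool = True,
          ) -> tuple[WhamSolution, PMFProfile]:
    """Self-consistent WHAM solution on the given grid.

    Samples falling outside the grid are dropped (with a log message); the
    per-window sample counts used in the equations are the in-grid counts, so
    the estimator stays consistent. Convergence is declared when the largest
    change of any window free energy falls below ``tolerance`` (kcal/mol).
    """
    if not windows:
        raise ValueError("need at least one umbrella window")
    ndim = windows[0].ndim
    if any(w.ndim != ndim for w in windows):
        raise ValueError("windows have mixed dimensionality")
    if len(edges) != ndim:
        raise ValueError(f"grid has {len(edges)} dimensions, windows {ndim}")
    kt = KB * temperature
    centers = grid_centers(edges)                      # (B, d)
    shape = tuple(len(e) - 1 for e in edges)
    counts = np.stack([_histogram(w.retained, edges) for w in windows])
    n_k = counts.sum(axis=1)
    n_dropped = sum(w.n_retained for w in windows) - n_k.sum()
    if n_dropped:
        logger.info("WHAM: %d samples fell outside the grid and were dropped",
                    int(n_dropped))
    if np.any(n_k == 0):
        bad = [windows[i].centers for i in np.flatnonzero(n_k == 0)]
        raise WhamError(f"windows with no in-grid samples: {bad}")
    if check_overlap and len(windows) > 1:
        _check_connectivity(counts > 0, windows)

    h_b = counts.sum(axis=0)                           # (B,)
    u_kb = np.stack([np.atleast_1d(bias_energy(w, centers)) / kt
                     for w in windows])                # (K, B)
    with np.errstate(under="ignore"):
        expu = np.exp(-u_kb)                           # (K, B)
    f = (np.zeros(len(windows)) if f_init is None
         else np.asarray(f_init, dtype=float) / kt)

    residuals = []
    it = 0
    for it in range(1, max_iterations + 1):
        with np.errstate(under="ignore", divide="ignore", invalid="ignore"):
            denom = (n_k * np.exp(f)) @ expu           # (B,)
            p = np.where(denom > 0, h_b / denom, 0.0)
            p /= p.sum()
            z = expu @ p                               # (K,)
            f_new = -np.log(z)
        f_new -= f_new[0]
        resid = float(np.max(np.abs(f_new - f)) * kt)
        residuals.append(resid)
        f = f_new
        if resid < tolerance:
            break
    else:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iterations} iterations "
            f"(last residual {residuals[-1]:.3g} kcal/mol)",
            np.asarray(residuals))

    visited = h_b > 0
    binvol = np.prod([np.diff(e).mean() for e in edges])
    density = p / binvol
    with np.errstate(divide="ignore"):
        pmf = np.where(visited, -kt * np.log(p, where=p > 0,
                                             out=np.full_like(p, np.nan)),
                       np.nan)
    pmf -= np.nanmin(pmf[visited])
    sol = WhamSolution(window_free_energies=f * kt, probability=density,
                       iterations=it, final_residual=residuals[-1])
    prof = PMFProfile(edges=edges, free_energy=pmf.reshape(shape), std=None,
                      visited=visited.reshape(shape),
                      temperature=temperature,
                      counts=h_b.reshape(shape))
    return sol, prof


# ---------------------------------------------------------------------------
# uncertainties and diagnostics
# ---------------------------------------------------------------------------

def integrated_autocorrelation_time(x: np.ndarray) -> float:
    """Integrated autocorrelation time by the initial-positive-sequence
    estimator (sum of autocorrelations truncated at the first non-positive
    pair sum of a stationary series)."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return 1.0
    xc = x - x.mean()
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n] / np.arange(n, 0, -1)
    acf /= acf[0]
    tau = 1.0
    t = 1
    while t + 1 < n:
        pair = acf[t] + acf[t + 1]
        if pair <= 0:
            break
        tau += 2.0 * pair
        t += 2
    return max(1.0, float(tau))


def _block_resample(x: np.ndarray, block: int, rng: np.random.Generator,
                    ) -> np.ndarray:
    n = len(x)
    block = min(max(1, block), n)
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    out = np.concatenate([x[s:s + block] for s in starts], axis=0)
    return out[:n]


def bootstrap_errors(windows: list[UmbrellaWindow], edges: list[np.ndarray],
                     temperature: float = DEFAULT_TEMPERATURE,
                     n_resamples: int = 100, seed: int = 0,
                     block_length: int | None = None,
                     tolerance: float = DEFAULT_TOLERANCE,
                     ) -> np.ndarray:
    """Per-bin PMF standard deviation from a moving-block bootstrap.

    Blocks of length equal to each window's integrated autocorrelation time
    (or ``block_length`` when given) are resampled with replacement, WHAM is
    re-solved (warm-started from the full-data solution), and the standard
    deviation over resamples is returned on the grid (NaN where any resample
    leaves a bin unvisited).
    """
    if n_resamples < 2:
        raise ValueError("need at least 2 bootstrap resamples")
    sol, prof = solve(windows, edges, temperature, tolerance=tolerance)
    blocks = [block_length if block_length is not None
              else int(np.ceil(integrated_autocorrelation_time(
                  w.retained[:, 0])))
              for w in windows]
    rng = np.random.default_rng(seed)
    pmfs = []
    for _ in range(n_resamples):
        rewindows = [
            UmbrellaWindow(w.centers, w.force_constants,
                           _block_resample(w.retained, b, rng),
                           offset=w.offset)
            for w, b in zip(windows, blocks)]
        _, p = solve(rewindows, edges, temperature, tolerance=tolerance,
                     f_init=sol.window_free_energies, check_overlap=False)
        pmfs.append(p.free_energy)
    arr = np.stack(pmfs)
    return arr.std(axis=0, ddof=1)


def overlap_diagnostics(windows: list[UmbrellaWindow],
                        edges: list[np.ndarray],
                        ) -> dict[tuple[int, int], float]:
    """Histogram-intersection overlap for each adjacent window pair.

    Adjacency is by bias center: consecutive centers in 1D, centers within
    1.5x the minimal center spacing in 2D. The overlap of a pair is
    sum_bins min(p1, p2) of their normalized histograms, in [0, 1].
    """
    if len(windows) < 2:
        raise ValueError("need at least 2 windows")
    centers = np.array([w.centers for w in windows])
    hists = []
    for w in windows:
        h = _histogram(w.retained, edges)
        tot = h.sum()
        hists.append(h / tot if tot > 0 else h)
    out: dict[tuple[int, int], float] = {}
    if windows[0].ndim == 1:
        order = np.argsort(centers[:, 0])
        pairs = [(int(order[i]), int(order[i + 1]))
                 for i in range(len(order) - 1)]
    else:
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        thresh = 1.5 * d.min()
        pairs = [(i, j) for i in range(len(windows))
                 for j in range(i + 1, len(windows)) if d[i, j] <= thresh]
    for i, j in pairs:
        out[(i, j)] = float(np.minimum(hists[i], hists[j]).sum())
    return out


def split_half_check(windows: list[UmbrellaWindow], edges: list[np.ndarray],
                     temperature: float = DEFAULT_TEMPERATURE,
                     tolerance: float = DEFAULT_TOLERANCE,
                     ) -> tuple[PMFProfile, PMFProfile, float]:
    """Solve on the first and second halves of every window's retained
    series; return both profiles and the maximal absolute PMF difference
    over jointly visited bins. Large values flag non-stationary sampling."""
    for w in windows:
        if w.n_retained < 2:
            raise ValueError(f"window at {w.centers} retains fewer than 2 "
                             "frames; cannot split")
    halves = ([], [])
    for w in windows:
        r = w.retained
        mid = len(r) // 2
        halves[0].append(UmbrellaWindow(w.centers, w.force_constants, r[:mid],
                                        offset=w.offset))
        halves[1].append(UmbrellaWindow(w.centers, w.force_constants, r[mid:],
                                        offset=w.offset))
    _, p1 = solve(halves[0], edges, temperature, tolerance=tolerance)
    _, p2 = solve(halves[1], edges, temperature, tolerance=tolerance)
    joint = p1.visited & p2.visited
    diff = float(np.nanmax(np.abs(p1.free_energy[joint] -
                                  p2.free_energy[joint])))
    return p1, p2, diff


# ---------------------------------------------------------------------------
# feature extraction on binned profiles
# ---------------------------------------------------------------------------

@dataclass
class ProfileFeatures:
    minima: list[tuple]        # (bin index tuple, position, free energy)
    barriers: dict = field(default_factory=dict)
    # (min_a, min_b) -> barrier height above min_a along min-max path


def profile_features(prof: PMFProfile) -> ProfileFeatures:
    """Local minima and pairwise barrier heights of a binned PMF.

    A bin is a local minimum if strictly below every visited orthogonal
    neighbor. The barrier between two minima is the lowest maximal free
    energy over all bin-graph paths joining them (computed by threshold
    percolation on visited bins), reported relative to the first minimum.
    """
    fe = prof.free_energy
    visited = prof.visited
    shape = fe.shape
    idx_list = np.argwhere(visited)
    minima = []
    for idx in idx_list:
        val = fe[tuple(idx)]
        is_min = True
        for d in range(len(shape)):
            for step in (-1, 1):
                nb = idx.copy()
                nb[d] += step
                if 0 <= nb[d] < shape[d] and visited[tuple(nb)]:
                    if fe[tuple(nb)] <= val:
                        is_min = False
        if is_min:
            pos = tuple(prof.bin_centers[d][idx[d]] for d in range(len(shape)))
            minima.append((tuple(int(i) for i in idx), pos, float(val)))
    feats = ProfileFeatures(minima=minima)

    # min-max path barrier via union at increasing thresholds
    if len(minima) > 1:
        levels = np.unique(fe[visited])
        for a in range(len(minima)):
            for b in range(a + 1, len(minima)):
                ia, ib = minima[a][0], minima[b][0]
                barrier = None
                for lev in levels:
                    mask = visited & (fe <= lev)
                    if mask[ia] and mask[ib] and _connected(mask, ia, ib):
                        barrier = float(lev)
                        break
                if barrier is not None:
                    feats.barriers[(ia, ib)] = barrier - minima[a][2]
    return feats


def _connected(mask: np.ndarray, a: tuple, b: tuple) -> bool:
    from scipy.ndimage import label
    lab, _ = label(mask)
    return lab[a] == lab[b] and lab[a] > 0


# ---------------------------------------------------------------------------
# window-set I/O (manifest + per-window delimited text)
# ---------------------------------------------------------------------------

def write_window_set(windows: list[UmbrellaWindow], directory,
                     manifest_name: str = "manifest.json") -> None:
    """Write windows as one TSV per window (frame index + coordinates) plus
    a JSON manifest listing file, centers, force constants, discard count."""
    import json
    from pathlib import Path
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, w in enumerate(windows):
        fname = f"window_{i:04d}.tsv"
        data = np.column_stack([np.arange(len(w.samples)), w.samples])
        cols = ["frame"] + [f"xi{d + 1}" for d in range(w.ndim)]
        np.savetxt(directory / fname, data, delimiter="\t",
                   header="\t".join(cols), comments="")
        entries.append({"file": fname, "centers": list(w.centers),
                        "force_constants": list(w.force_constants),
                        "n_equil": w.n_equil})
    (directory / manifest_name).write_text(json.dumps(
        {"windows": entries}, indent=1))


def read_window_set(manifest_path) -> list[UmbrellaWindow]:
    import json
    from pathlib import Path
    manifest_path = Path(manifest_path)
    spec = json.loads(manifest_path.read_text())
    windows = []
    for entry in spec["windows"]:
        fpath = manifest_path.parent / entry["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"window file missing: {fpath}")
        data = np.loadtxt(fpath, delimiter="\t", skiprows=1, ndmin=2)
        windows.append(UmbrellaWindow(
            centers=tuple(entry["centers"]),
            force_constants=tuple(entry["force_constants"]),
            samples=data[:, 1:], n_equil=int(entry.get("n_equil", 0))))
    return windows
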