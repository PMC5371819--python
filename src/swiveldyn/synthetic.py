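"""Synthetic inputs with exact ground truth for every pipeline stage.

Two generators stand in for data the pipeline normally gets from experiment
or simulation:

* Metropolis sampling of analytic 1D/2D free-energy landscapes under
  harmonic biases produces umbrella-sampling window sets whose true PMF is
  known in closed form. The swiveling sawtooth preset mimics the shape of
  the swiveling free-energy profile: a periodic barrier train (~2 kcal/mol
  teeth every ~10 A) superimposed on a linear tilt (~-1.4 kcal/mol per
  period) over a 10-52 A reaction-coordinate range, with windows every 1 A
  and a 1 kcal/mol/A^2 harmonic tether.

* Planted-mode structural ensembles: members are a base C-alpha fold plus
  Gaussian-weighted orthonormal collective modes plus isotropic noise, so
  PCA spectra, collectivity, cross-correlation blocks and cluster partitions
  all have constructed ground truth.

All generators draw from numpy's PCG64 generator and are bit-reproducible
for a fixed seed; per-window/per-member streams come from spawned
SeedSequence children so they are independent and individually addressable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .structures import Atom, EnsembleAlignment, StructureModel
from .wham import KB, UmbrellaWindow

DEFAULT_STEP_SIZE = 0.5   # A, uniform Metropolis proposal half-width
DEFAULT_BURN_IN = 1000


# ---------------------------------------------------------------------------
# analytic landscapes
# ---------------------------------------------------------------------------

class AnalyticLandscape:
    """A potential with a closed-form PMF (up to an additive constant)."""

    ndim: int = 1
    range: tuple = None

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def pmf(self, points: np.ndarray) -> np.ndarray:
        """Ground-truth PMF at the given points, anchored so min = 0."""
        u = np.asarray(self.energy(np.asarray(points, dtype=float)))
        return u - u.min()


@dataclass
class Harmonic(AnalyticLandscape):
    """U(x) = k/2 (x - x0)^2, kcal/mol with x in Angstrom."""

    stiffness: float = 0.5
    center: float = 0.0
    ndim: int = 1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim > 1:
            x = x[..., 0]
        return 0.5 * self.stiffness * (x - self.center) ** 2


@dataclass
class SawtoothTilt(AnalyticLandscape):
    """Periodic barrier train plus linear tilt.

    Within each period a linear rise to ``barrier`` over a fraction
    ``rise_fraction`` of the period is followed by a linear fall; a tilt of
    ``tilt`` kcal/mol per period is added, so successive minima differ by
    ``tilt`` and uphill barriers are barrier + tilt*rise_fraction.
    """

    period: float = 10.0
    barrier: float = 2.0
    tilt: float = -1.4
    x0: float = 10.0
    rise_fraction: float = 0.75
    range: tuple = (10.0, 52.0)
    ndim: int = 1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim > 1:
            x = x[..., 0]
        s = (x - self.x0) / self.period
        p = s - np.floor(s)
        r = self.rise_fraction
        shape = np.where(p < r, p / r, (1.0 - p) / (1.0 - r)) * self.barrier
        return shape + self.tilt * s

    def true_minima(self, lo: float | None = None, hi: float | None = None,
                    ) -> np.ndarray:
        lo = self.range[0] if lo is None else lo
        hi = self.range[1] if hi is None else hi
        ks = np.arange(np.ceil((lo - self.x0) / self.period),
                       np.floor((hi - self.x0) / self.period) + 1)
        return self.x0 + ks * self.period


@dataclass
class DoubleWell(AnalyticLandscape):
    """Quartic double well with minima at the given positions and the stated
    barrier height at the midpoint."""

    minima: tuple[float, float] = (-2.0, 2.0)
    barrier: float = 2.0
    ndim: int = 1

    def energy(self, x):
        x = np.asarray(x, dtype=float)
        if x.ndim > 1:
            x = x[..., 0]
        c = 0.5 * (self.minima[0] + self.minima[1])
        a = 0.5 * (self.minima[1] - self.minima[0])
        return self.barrier * ((x - c) ** 2 - a ** 2) ** 2 / a ** 4


@dataclass
class Separable2D(AnalyticLandscape):
    """U(x, y) = U1(x) + U2(y) from two 1D landscapes."""

    ux: AnalyticLandscape = field(default_factory=DoubleWell)
    uy: AnalyticLandscape = field(default_factory=Harmonic)
    ndim: int = 2

    def energy(self, xy):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return self.ux.energy(xy[..., 0]) + self.uy.energy(xy[..., 1])


@dataclass
class Coupled2D(AnalyticLandscape):
    """Sawtooth-tilt along x plus a harmonic channel in y whose center
    follows g(x): constant below ``threshold``, then linear in x. This
    emulates a 2D landscape where the second coordinate stays constant over
    the first part of the transition and then moves diagonally with the
    first."""

    ux: SawtoothTilt = field(default_factory=SawtoothTilt)
    kappa_y: float = 0.5
    y_base: float = 38.0
    slope: float = -0.5
    threshold: float = 30.0
    ndim: int = 2

    def g(self, x):
        x = np.asarray(x, dtype=float)
        return self.y_base + self.slope * np.maximum(0.0, x - self.threshold)

    def energy(self, xy):
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[..., 0], xy[..., 1]
        return self.ux.energy(x) + 0.5 * self.kappa_y * (y - self.g(x)) ** 2


def swiveling_sawtooth() -> SawtoothTilt:
    """The default 1D test landscape: four ~2 kcal/mol teeth over 10-52 A
    with a -1.4 kcal/mol-per-period tilt."""
    return SawtoothTilt(period=10.0, barrier=2.0, tilt=-1.4, x0=10.0,
                        range=(10.0, 52.0))


# ---------------------------------------------------------------------------
# Metropolis sampling under harmonic bias
# ---------------------------------------------------------------------------

class AcceptanceError(RuntimeError):
    pass


def _run_chains(energy_total, starts: np.ndarray, n_record: int,
                step_size: float, burn_in: int, temperature: float,
                rngs: list[np.random.Generator], thin: int = 1,
                ) -> np.ndarray:
    """Vectorized Metropolis chains: one independent random stream per chain,
    all chains advanced in lockstep. Returns (n_record, C, d) samples."""
    kt = KB * temperature
    x = np.array(starts, dtype=float)           # (C, d)
    n_chain, ndim = x.shape
    n_total = burn_in + n_record * thin
    # pre-draw each chain's stream so a chain's trajectory depends only on
    # its own seed, independent of how many chains run alongside it
    props = np.empty((n_total, n_chain, ndim))
    logu = np.empty((n_total, n_chain))
    for c, rng in enumerate(rngs):
        props[:, c, :] = rng.uniform(-step_size, step_size,
                                     size=(n_total, ndim))
        logu[:, c] = np.log(rng.random(n_total))
    e = np.asarray(energy_total(x), dtype=float)
    out = np.empty((n_record, n_chain, ndim))
    consecutive_rejects = np.zeros(n_chain, dtype=int)
    rec = 0
    for t in range(n_total):
        xp = x + props[t]
        ep = np.asarray(energy_total(xp), dtype=float)
        acc = logu[t] < -(ep - e) / kt
        x[acc] = xp[acc]
        e[acc] = ep[acc]
        consecutive_rejects[acc] = 0
        consecutive_rejects[~acc] += 1
        if np.any(consecutive_rejects >= 10_000):
            raise AcceptanceError(
                "zero acceptance over 10000 consecutive proposals; "
                f"reduce the step size (currently {step_size} A)")
        if t >= burn_in and (t - burn_in) % thin == 0:
            out[rec] = x
            rec += 1
    return out


def sample_biased(landscape: AnalyticLandscape,
                  centers: float | tuple[float, ...],
                  force_constants: float | tuple[float, ...],
                  temperature: float = 300.0, n_samples: int = 10_000,
                  step_size: float = DEFAULT_STEP_SIZE, seed: int = 0,
                  burn_in: int = DEFAULT_BURN_IN, thin: int = 1,
                  start: np.ndarray | None = None) -> UmbrellaWindow:
    """Metropolis chain on U(xi) + harmonic bias; returns the window with
    all recorded frames retained (burn-in already discarded)."""
    c = np.atleast_1d(np.asarray(centers, dtype=float))
    k = np.broadcast_to(np.atleast_1d(np.asarray(force_constants,
                                                 dtype=float)), c.shape)
    if np.any(k < 0):
        raise ValueError("force constants must be non-negative")

    def energy_total(x):
        return (np.asarray(landscape.energy(x))
                + 0.5 * (k * (x - c) ** 2).sum(axis=-1))

    x0 = np.atleast_2d(c if start is None else np.asarray(start, dtype=float))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    samples = _run_chains(energy_total, x0, n_samples, step_size, burn_in,
                          temperature, [rng], thin=thin)
    # UmbrellaWindow requires strictly positive K; an effectively unbiased
    # chain (K = 0 here) is recorded with a vanishing tether
    kk = tuple(float(v) if v > 0 else 1e-12 for v in k)
    return UmbrellaWindow(centers=tuple(float(v) for v in c),
                          force_constants=kk,
                          samples=samples[:, 0, :])


def generate_window_set(landscape: AnalyticLandscape, centers: np.ndarray,
                        force_constant: float = 1.0,
                        n_samples: int = 10_000, temperature: float = 300.0,
                        seed: int = 0, step_size: float | None = None,
                        burn_in: int = DEFAULT_BURN_IN, thin: int = 1,
                        ) -> list[UmbrellaWindow]:
    """One independently seeded Metropolis chain per bias center.

    ``centers`` is a 1D array of centers or an (n, d) array for d reaction
    coordinates; the force constant (kcal/mol/A^2) applies to every
    coordinate, mirroring a 1 A ladder of 1 kcal/mol/A^2 tethers. Chains run
    in lockstep but each consumes only its own spawned random stream, so any
    window is reproducible in isolation.

    The default proposal width scales with the biased-distribution width,
    4 sqrt(kT/K): for near-harmonic biased sampling this keeps the chain's
    integrated autocorrelation time within a few steps of its optimum rather
    than diffusing through the well with tiny moves.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim == 1:
        centers = centers[:, None]
    if centers.shape[1] != landscape.ndim:
        raise ValueError(f"centers have {centers.shape[1]} coordinates, "
                         f"landscape has {landscape.ndim}")
    if landscape.range is not None and landscape.ndim == 1:
        lo, hi = landscape.range
        if centers.min() < lo or centers.max() > hi:
            raise ValueError(f"bias centers outside landscape range "
                             f"[{lo}, {hi}]")
    n_win = len(centers)
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_win)]
    kvec = float(force_constant)
    if step_size is None:
        step_size = 4.0 * np.sqrt(KB * temperature / kvec)

    def energy_total(x):
        return (np.asarray(landscape.energy(x))
                + 0.5 * kvec * ((x - centers) ** 2).sum(axis=-1))

    samples = _run_chains(energy_total, centers, n_samples, step_size,
                          burn_in, temperature, rngs, thin=thin)
    return [UmbrellaWindow(centers=tuple(centers[i]),
                           force_constants=(kvec,) * centers.shape[1],
                           samples=samples[:, i, :])
            for i in range(n_win)]


# ---------------------------------------------------------------------------
# planted-mode structural ensembles
# ---------------------------------------------------------------------------

@dataclass
class PlantedEnsembleSpec:
    """Ensemble = base + sum_j c_j v_j + noise, with c_j ~ N(0, variance_j).

    ``modes`` are orthonormal 3M-vectors; ``noise_variance`` is the isotropic
    per-atom displacement variance E|eps_i|^2 (A^2), i.e. noise_variance/3
    per Cartesian coordinate. Setting ``rigid_transforms`` applies a random
    rotation + translation to each member, emulating arbitrary deposition
    frames.
    """

    base: np.ndarray                  # (M, 3)
    modes: np.ndarray                 # (J, 3M), orthonormal rows
    variances: np.ndarray             # (J,) A^2
    noise_variance: float = 0.0
    n_members: int = 100
    seed: int = 0
    rigid_transforms: bool = False

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        self.variances = np.atleast_1d(np.asarray(self.variances, dtype=float))
        if self.modes.shape[1] != 3 * len(self.base):
            raise ValueError("mode length != 3 x atom count")
        if len(self.variances) != len(self.modes):
            raise ValueError("one variance per mode required")
        if np.any(self.variances < 0):
            raise ValueError("variances must be >= 0")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(len(self.modes)), atol=1e-8):
            raise ValueError("modes are not orthonormal")
        if self.n_members < 2:
            raise ValueError("need at least 2 members")


@dataclass
class PlantedGroundTruth:
    modes: np.ndarray
    variances: np.ndarray
    coefficients: np.ndarray          # (n_members, J)


def generate_ensemble(spec: PlantedEnsembleSpec,
                      ) -> tuple[EnsembleAlignment, PlantedGroundTruth]:
    """Draw a planted-mode ensemble; returns the (unfitted) alignment and
    the planted modes/variances/per-member coefficients."""
    rng = np.random.default_rng(spec.seed)
    m = len(spec.base)
    coeffs = rng.normal(0.0, np.sqrt(spec.variances),
                        size=(spec.n_members, len(spec.variances)))
    flat = spec.base.ravel() + coeffs @ spec.modes
    coords = flat.reshape(spec.n_members, m, 3)
    if spec.noise_variance > 0:
        coords = coords + rng.normal(
            0.0, np.sqrt(spec.noise_variance / 3.0), size=coords.shape)
    if spec.rigid_transforms:
        for i in range(spec.n_members):
            rot = Rotation.random(rng=rng).as_matrix()
            trans = rng.uniform(-10.0, 10.0, size=3)
            coords[i] = coords[i] @ rot.T + trans
    ids = [f"synth_{i:04d}" for i in range(spec.n_members)]
    residues = [(i + 1, "") for i in range(m)]
    ens = EnsembleAlignment(ids, residues, coords, fitted=False)
    return ens, PlantedGroundTruth(modes=spec.modes.copy(),
                                   variances=spec.variances.copy(),
                                   coefficients=coeffs)


def chain_walk_coords(n_res: int, seed: int = 0,
                      bond_length: float = 3.8) -> np.ndarray:
    """A random C-alpha chain with realistic 3.8 A virtual bonds, used as a
    base fold for planted ensembles and geometry fixtures."""
    rng = np.random.default_rng(seed)
    steps = rng.normal(size=(n_res - 1, 3))
    steps /= np.linalg.norm(steps, axis=1, keepdims=True)
    coords = np.vstack([np.zeros(3), np.cumsum(bond_length * steps, axis=0)])
    return coords


def rigid_body_modes(base: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3M) of infinitesimal rigid-body motions (three
    translations, three rotations about the centroid) of a structure."""
    base = np.asarray(base, dtype=float)
    m = len(base)
    centered = base - base.mean(axis=0)
    modes = []
    for d in range(3):
        t = np.zeros((m, 3))
        t[:, d] = 1.0
        modes.append(t.ravel())
    for d in range(3):
        axis = np.zeros(3)
        axis[d] = 1.0
        modes.append(np.cross(axis, centered).ravel())
    q, _ = np.linalg.qr(np.stack(modes).T)
    return q.T[:6]


def internal_modes(base: np.ndarray, n_modes: int, seed: int = 0,
                   ) -> np.ndarray:
    """Random orthonormal modes orthogonal to the rigid-body space of
    ``base``, so a superposition fit cannot absorb planted variance."""
    rng = np.random.default_rng(seed)
    m3 = 3 * len(base)
    rigid = rigid_body_modes(base)
    raw = rng.normal(size=(n_modes, m3))
    raw -= (raw @ rigid.T) @ rigid
    q, _ = np.linalg.qr(raw.T)
    return q.T[:n_modes]


def coords_to_model(model_id: str, coords: np.ndarray, chain: str = "A",
                    start_resnum: int = 1) -> StructureModel:
    """Wrap a C-alpha coordinate array as a poly-alanine StructureModel."""
    atoms = [Atom(chain=chain, resnum=start_resnum + i, icode="",
                  resname="ALA", name="CA", element="C",
                  pos=tuple(float(v) for v in xyz), occupancy=1.0,
                  is_hetero=False)
             for i, xyz in enumerate(np.asarray(coords, dtype=float))]
    return StructureModel(id=model_id, atoms=atoms)
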