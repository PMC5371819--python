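import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.stats import norm

from swiveldyn import synthetic, wham
from swiveldyn.wham import KB, UmbrellaWindow


def reference_wham_1d(windows, edges, temperature=300.0):
    """Independent WHAM oracle: the window free energies are found by
    minimizing the (convex) WHAM negative log-likelihood with BFGS rather
    than by self-consistent iteration; the PMF follows from the stationary
    probabilities. Shares no code with swiveldyn.wham.solve."""
    kt = KB * temperature
    centers = 0.5 * (edges[0][1:] + edges[0][:-1])
    counts = np.stack([np.histogram(w.retained[:, 0], bins=edges[0])[0]
                       for w in windows]).astype(float)
    h = counts.sum(axis=0)
    n_k = counts.sum(axis=1)
    u = np.stack([(0.5 * w.force_constants[0]
                   * (centers - w.centers[0]) ** 2 + w.offset) / kt
                  for w in windows])

    def objective(f):
        with np.errstate(under="ignore"):
            log_denom = np.log((n_k[:, None] * np.exp(f[:, None] - u)
                                ).sum(axis=0))
        return (h * log_denom).sum() - (n_k * f).sum()

    res = minimize(objective, np.zeros(len(windows)), method="BFGS",
                   options={"gtol": 1e-10, "maxiter": 5000})
    f = res.x - res.x[0]
    with np.errstate(under="ignore", divide="ignore"):
        p = h / (n_k[:, None] * np.exp(f[:, None] - u)).sum(axis=0)
        p /= p.sum()
        pmf = -kt * np.log(p)
    pmf -= pmf[h > 0].min()
    return pmf, h > 0


@pytest.fixture(scope="module")
def harmonic_windows():
    land = synthetic.Harmonic(stiffness=0.5)
    centers = np.arange(-6.0, 6.1, 1.0)
    return synthetic.generate_window_set(land, centers, force_constant=1.0,
                                         n_samples=5000, seed=0), land


class TestBiasEnergy:
    def test_zero_at_center(self):
        w = UmbrellaWindow((3.0,), (1.0,), np.array([3.0]))
        assert wham.bias_energy(w, np.array([3.0])) == 0.0

    def test_quadratic_one_d(self):
        w = UmbrellaWindow((0.0,), (1.0,), np.array([0.0]))
        assert wham.bias_energy(w, np.array([2.0])) == pytest.approx(2.0)

    def test_two_d_offsets(self):
        w = UmbrellaWindow((0.0, 0.0), (1.0, 1.0), np.zeros((1, 2)))
        assert wham.bias_energy(w, np.array([1.0, 3.0])) == pytest.approx(5.0)


class TestSolve:
    def test_single_unbiased_window_equals_histogram(self):
        """With one near-zero-stiffness window WHAM reduces to plain
        histogramming: PMF = -kT ln(relative frequency), anchored."""
        rng = np.random.default_rng(0)
        samples = rng.choice([0.25, 0.75, 1.25], size=2000,
                             p=[0.5, 0.3, 0.2])
        w = UmbrellaWindow((0.5,), (1e-12,), samples)
        edges = [np.array([0.0, 0.5, 1.0, 1.5])]
        _, prof = wham.solve([w], edges, check_overlap=False)
        counts = np.histogram(samples, bins=edges[0])[0]
        kt = KB * 300.0
        expected = -kt * np.log(counts / counts.sum())
        expected -= expected.min()
        np.testing.assert_allclose(prof.free_energy, expected, atol=1e-9)

    def test_harmonic_ladder_recovery(self, harmonic_windows):
        windows, land = harmonic_windows
        edges = wham.make_grid([(-7.0, 7.0)], 0.5)
        _, prof = wham.solve(windows, edges)
        c = prof.bin_centers[0]
        mask = (np.abs(c) <= 5.0) & prof.visited
        est = prof.free_energy[mask] - prof.free_energy[mask].min()
        true = land.energy(c[mask]) - land.energy(c[mask]).min()
        assert np.sqrt(np.mean((est - true) ** 2)) <= 0.1

    def test_agrees_with_independent_oracle(self, harmonic_windows):
        windows, _ = harmonic_windows
        edges = wham.make_grid([(-7.0, 7.0)], 0.5)
        _, prof = wham.solve(windows, edges)
        ref_pmf, visited = reference_wham_1d(windows, edges)
        assert np.allclose(prof.free_energy[visited], ref_pmf[visited],
                           atol=0.02)

    def test_gauge_invariance(self, harmonic_windows):
        """Adding a constant to every bias leaves the anchored PMF alone."""
        windows, _ = harmonic_windows
        edges = wham.make_grid([(-7.0, 7.0)], 0.5)
        _, base = wham.solve(windows, edges)
        shifted = [UmbrellaWindow(w.centers, w.force_constants, w.samples,
                                  offset=7.3) for w in windows]
        _, moved = wham.solve(shifted, edges)
        np.testing.assert_allclose(moved.free_energy[moved.visited],
                                   base.free_energy[base.visited], atol=1e-6)

    def test_window_order_invariance(self, harmonic_windows):
        windows, _ = harmonic_windows
        edges = wham.make_grid([(-7.0, 7.0)], 0.5)
        _, a = wham.solve(windows, edges)
        _, b = wham.solve(windows[::-1], edges)
        np.testing.assert_allclose(a.free_energy[a.visited],
                                   b.free_energy[b.visited], atol=1e-9)

    def test_disconnected_windows_rejected(self):
        rng = np.random.default_rng(1)
        w1 = UmbrellaWindow((0.0,), (1.0,), rng.normal(0.0, 0.5, 500))
        w2 = UmbrellaWindow((30.0,), (1.0,), rng.normal(30.0, 0.5, 500))
        edges = wham.make_grid([(-2.0, 32.0)], 0.5)
        with pytest.raises(wham.DisconnectedWindowsError, match="overlap"):
            wham.solve([w1, w2], edges)

    def test_probability_normalized(self, harmonic_windows):
        windows, _ = harmonic_windows
        edges = wham.make_grid([(-7.0, 7.0)], 0.5)
        sol, _ = wham.solve(windows, edges)
        binw = np.diff(edges[0]).mean()
        assert sol.probability.sum() * binw == pytest.approx(1.0, abs=1e-6)

    def test_separable_2d_marginals_match_1d(self):
        from swiveldyn.validation import separability_2d
        res = separability_2d(seed=0, n_windows_per_dim=6,
                              n_samples_2d=8000, n_samples_1d=20_000)
        assert res["marginal_max_deviation_x"] <= 0.15
        assert res["marginal_max_deviation_y"] <= 0.15


class TestBootstrap:
    def test_zero_variance_windows_zero_std(self):
        # both windows pinned at the same value: one visited bin, no noise
        windows = [UmbrellaWindow((c,), (1.0,), np.full(50, 0.2))
                   for c in (0.0, 0.4)]
        edges = [np.array([-0.25, 0.25, 0.75])]
        std = wham.bootstrap_errors(windows, edges, n_resamples=20, seed=0)
        assert np.nanmax(std) == pytest.approx(0.0, abs=1e-12)

    def test_error_scales_as_inverse_sqrt_n(self):
        land = synthetic.Harmonic(stiffness=0.5)
        centers = np.arange(-3.0, 3.1, 1.0)

        def max_std(n):
            ws = synthetic.generate_window_set(land, centers,
                                               force_constant=1.0,
                                               n_samples=n, seed=3)
            edges = wham.make_grid([(-4.0, 4.0)], 0.5)
            std = wham.bootstrap_errors(ws, edges, n_resamples=50, seed=4)
            return np.nanmean(std)

        ratio = max_std(8000) / max_std(2000)
        assert ratio == pytest.approx(0.5, abs=0.15)

    def test_seed_determinism(self, harmonic_windows):
        windows, _ = harmonic_windows
        edges = wham.make_grid([(-7.0, 7.0)], 0.5)
        s1 = wham.bootstrap_errors(windows, edges, n_resamples=10, seed=7)
        s2 = wham.bootstrap_errors(windows, edges, n_resamples=10, seed=7)
        s3 = wham.bootstrap_errors(windows, edges, n_resamples=10, seed=8)
        np.testing.assert_array_equal(s1, s2)
        assert not np.array_equal(s1, s3)

    def test_too_few_resamples_rejected(self, harmonic_windows):
        windows, _ = harmonic_windows
        edges = wham.make_grid([(-7.0, 7.0)], 0.5)
        with pytest.raises(ValueError, match="resamples"):
            wham.bootstrap_errors(windows, edges, n_resamples=1)


class TestOverlap:
    def test_identical_sample_sets(self):
        rng = np.random.default_rng(0)
        s = rng.normal(0, 1, 2000)
        w1 = UmbrellaWindow((0.0,), (1.0,), s)
        w2 = UmbrellaWindow((0.1,), (1.0,), s.copy())
        edges = wham.make_grid([(-5.0, 5.0)], 0.5)
        ov = wham.overlap_diagnostics([w1, w2], edges)
        assert list(ov.values()) == [pytest.approx(1.0)]

    def test_disjoint_supports(self):
        w1 = UmbrellaWindow((0.0,), (1.0,), np.full(100, 0.1))
        w2 = UmbrellaWindow((4.0,), (1.0,), np.full(100, 4.1))
        edges = wham.make_grid([(-1.0, 5.0)], 0.5)
        ov = wham.overlap_diagnostics([w1, w2], edges)
        assert list(ov.values()) == [pytest.approx(0.0)]

    def test_gaussian_closed_form(self):
        """Two unit Gaussians 1 apart: intersection = 2 Phi(-1/2)."""
        rng = np.random.default_rng(5)
        w1 = UmbrellaWindow((0.0,), (1.0,), rng.normal(0.0, 1.0, 100_000))
        w2 = UmbrellaWindow((1.0,), (1.0,), rng.normal(1.0, 1.0, 100_000))
        edges = wham.make_grid([(-6.0, 7.0)], 0.1)
        ov = wham.overlap_diagnostics([w1, w2], edges)
        expected = 2 * norm.cdf(-0.5)
        assert list(ov.values())[0] == pytest.approx(expected, abs=0.02)


class TestSplitHalf:
    def test_drifting_windows_flagged(self):
        """A constant shift of every second half shows up as a PMF
        difference far above the noise."""
        rng = np.random.default_rng(0)
        windows = []
        for c in np.arange(0.0, 6.1, 1.0):
            first = rng.normal(c, 0.7, 2000)
            second = rng.normal(c + 1.5, 0.7, 2000)
            windows.append(UmbrellaWindow((c,), (1.0,),
                                          np.concatenate([first, second])))
        edges = wham.make_grid([(-4.0, 10.0)], 0.5)
        _, _, diff = wham.split_half_check(windows, edges)
        assert diff > 1.0

    def test_single_frame_halves_rejected(self):
        w = UmbrellaWindow((0.0,), (1.0,), np.array([0.1]))
        with pytest.raises(ValueError, match="fewer than 2"):
            wham.split_half_check([w], [np.array([-1.0, 1.0])])


class TestProfileFeatures:
    def test_constructed_minima_and_barriers(self):
        fe = np.array([1.0, 0.4, 1.8, 2.6, 1.2, 0.0, 3.0])
        prof = wham.PMFProfile(edges=[np.arange(0.0, 3.6, 0.5)],
                               free_energy=fe, std=None,
                               visited=np.ones(7, bool), temperature=300.0)
        feats = wham.profile_features(prof)
        positions = sorted(pos[0] for _, pos, _ in feats.minima)
        assert positions == [0.75, 2.75]
        (pair, height), = feats.barriers.items()
        assert height == pytest.approx(2.6 - 0.4)

    def test_unvisited_bins_ignored(self):
        fe = np.array([0.0, np.nan, 0.5])
        prof = wham.PMFProfile(edges=[np.arange(0.0, 2.0, 0.5)],
                               free_energy=fe, std=None,
                               visited=np.array([True, False, True]),
                               temperature=300.0)
        feats = wham.profile_features(prof)
        assert len(feats.minima) == 2  # separated by the gap


class TestWindowIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        windows = [UmbrellaWindow((c, 2 * c), (1.0, 0.5),
                                  rng.normal(c, 0.5, (100, 2)), n_equil=10)
                   for c in (0.0, 1.0)]
        wham.write_window_set(windows, tmp_path)
        back = wham.read_window_set(tmp_path / "manifest.json")
        assert len(back) == 2
        for w0, w1 in zip(windows, back):
            assert w0.centers == w1.centers
            assert w0.force_constants == w1.force_constants
            assert w0.n_equil == w1.n_equil
            np.testing.assert_allclose(w0.samples, w1.samples, atol=1e-12)

    def test_missing_window_file_named(self, tmp_path):
        rng = np.random.default_rng(2)
        windows = [UmbrellaWindow((0.0,), (1.0,), rng.normal(0, 1, 50))]
        wham.write_window_set(windows, tmp_path)
        (tmp_path / "window_0000.tsv").unlink()
        with pytest.raises(FileNotFoundError, match="window_0000"):
            wham.read_window_set(tmp_path / "manifest.json")


class TestWindowValidation:
    def test_nonpositive_force_constant_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            UmbrellaWindow((0.0,), (0.0,), np.array([0.1]))

    def test_no_retained_samples_rejected(self):
        with pytest.raises(ValueError, match="retains no samples"):
            UmbrellaWindow((0.0,), (1.0,), np.array([0.1, 0.2]), n_equil=2)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="coordinates"):
            UmbrellaWindow((0.0, 1.0), (1.0, 1.0), np.array([0.1, 0.2]))
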