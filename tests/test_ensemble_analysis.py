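import numpy as np
import pytest

from swiveldyn import synthetic
from swiveldyn.ensemble_analysis import (cluster_ensemble, collectivity,
                                         collectivity_from_displacements,
                                         cross_correlation,
                                         pairwise_rmsd_matrix, run_pca)
from conftest import make_ensemble_from_coords


def planted_two_blobs(n_per_blob=5, n_res=40, seed=0, separation=20.0):
    rng = np.random.default_rng(seed)
    base1 = synthetic.chain_walk_coords(n_res, seed=seed)
    base2 = base1.copy()
    base2[n_res // 2:, 0] += separation
    members = [b + rng.normal(0, 0.3, b.shape)
               for b in [base1] * n_per_blob + [base2] * n_per_blob]
    return make_ensemble_from_coords(members)


class TestClustering:
    def test_identical_structures_single_cluster(self, chain_coords):
        ens = make_ensemble_from_coords([chain_coords] * 3)
        cl = cluster_ensemble(ens, cutoff=4.0)
        assert cl.n_clusters == 1

    def test_planted_two_blob_partition(self):
        ens = planted_two_blobs()
        cl = cluster_ensemble(ens, cutoff=4.0)
        labels = [cl.labels[mid] for mid in ens.member_ids]
        assert len(set(labels)) == 2
        assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
        assert labels[0] != labels[5]

    def test_cutoff_limits(self):
        ens = planted_two_blobs()
        tiny = cluster_ensemble(ens, cutoff=1e-9)
        assert tiny.n_clusters == ens.n_members
        huge = cluster_ensemble(ens, cutoff=np.inf)
        assert huge.n_clusters == 1

    def test_cluster_count_non_increasing_in_cutoff(self):
        ens = planted_two_blobs()
        counts = [cluster_ensemble(ens, cutoff=c).n_clusters
                  for c in (0.1, 1.0, 4.0, 10.0, 50.0)]
        assert counts == sorted(counts, reverse=True)

    def test_complete_linkage_guarantee(self):
        """Every intra-cluster pair's best-fit RMSD is below the cutoff."""
        ens = planted_two_blobs(seed=3)
        cutoff = 4.0
        cl = cluster_ensemble(ens, cutoff=cutoff)
        d = cl.distance_matrix
        ids = ens.member_ids
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if cl.labels[ids[i]] == cl.labels[ids[j]]:
                    assert d[i, j] < cutoff

    def test_representative_is_medoid(self):
        ens = planted_two_blobs(seed=1)
        cl = cluster_ensemble(ens, cutoff=4.0)
        d = cl.distance_matrix
        ids = ens.member_ids
        for cid, rep in cl.representatives.items():
            idx = [i for i, m in enumerate(ids) if cl.labels[m] == cid]
            costs = d[np.ix_(idx, idx)].sum(axis=1)
            best = min(costs)
            rep_cost = costs[idx.index(ids.index(rep))]
            assert rep_cost == pytest.approx(best)

    def test_pairwise_rmsd_uses_per_pair_fit(self, chain_coords):
        """A globally rotated copy must be at RMSD 0 from the original."""
        from scipy.spatial.transform import Rotation
        rot = Rotation.from_euler("x", 60, degrees=True).as_matrix()
        ens = make_ensemble_from_coords(
            [chain_coords, chain_coords @ rot.T + 5.0])
        assert pairwise_rmsd_matrix(ens)[0, 1] < 1e-9


class TestPCA:
    def test_identical_structures_zero_spectrum(self, chain_coords):
        ens = make_ensemble_from_coords([chain_coords] * 4)
        pca = run_pca(ens)
        assert np.all(pca.eigenvalues < 1e-18)

    def test_planted_mode_spectrum(self):
        base = synthetic.chain_walk_coords(10, seed=0)
        modes = synthetic.internal_modes(base, 2, seed=0)
        spec = synthetic.PlantedEnsembleSpec(
            base=base, modes=modes, variances=np.array([9.0, 1.0]),
            noise_variance=0.01, n_members=4000, seed=0)
        ens, truth = synthetic.generate_ensemble(spec)
        pca = run_pca(ens, fit_fraction=1.0)
        assert pca.variance_fractions[0] == pytest.approx(0.9, abs=0.02)
        assert pca.variance_fractions[1] == pytest.approx(0.1, abs=0.02)
        assert abs(pca.eigenvectors[0] @ truth.modes[0]) > 0.99

    def test_spectrum_invariant_to_member_order(self):
        ens = planted_two_blobs(seed=5)
        pca1 = run_pca(ens)
        rev = make_ensemble_from_coords(list(ens.coords[::-1]))
        pca2 = run_pca(rev)
        np.testing.assert_allclose(pca1.eigenvalues, pca2.eigenvalues,
                                   rtol=1e-8, atol=1e-12)

    def test_trace_conservation(self):
        """Sum of eigenvalues equals the total mean-square fluctuation."""
        ens = planted_two_blobs(seed=2)
        pca = run_pca(ens, fit_fraction=1.0)
        dev = pca.fitted_coords - pca.fitted_coords.mean(axis=0)
        msf = (dev ** 2).sum(axis=(1, 2)).mean()
        assert pca.eigenvalues.sum() == pytest.approx(msf, rel=1e-8)

    def test_eigenvectors_orthonormal(self):
        ens = planted_two_blobs(seed=7)
        pca = run_pca(ens)
        k = min(5, pca.n_components)
        gram = pca.eigenvectors[:k] @ pca.eigenvectors[:k].T
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-8)

    def test_variance_fractions_sum_to_one(self):
        ens = planted_two_blobs(seed=8)
        pca = run_pca(ens)
        assert pca.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)

    def test_fit_set_converges_to_static_residues(self):
        """With a mobile tail, the 15% least-fluctuating fit set must land
        inside the static part of the chain."""
        rng = np.random.default_rng(9)
        base = synthetic.chain_walk_coords(40, seed=9)
        members = []
        for _ in range(30):
            c = base + rng.normal(0, 0.02, base.shape)
            c[30:] += rng.normal(0, 3.0, (10, 3))  # mobile tail
            members.append(c)
        ens = make_ensemble_from_coords(members)
        pca = run_pca(ens, fit_fraction=0.15)
        assert np.all(pca.fit_residue_indices < 30)


class TestCollectivity:
    def test_uniform_displacements_give_one(self):
        disp = np.ones((17, 3))
        assert collectivity_from_displacements(disp) == pytest.approx(1.0)

    def test_single_atom_gives_one_over_n(self):
        disp = np.zeros((25, 3))
        disp[11] = (0.3, -0.2, 0.9)
        assert collectivity_from_displacements(disp) == pytest.approx(1 / 25)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(123)
        disp = rng.normal(size=(10, 3))
        u2 = np.array([v @ v for v in disp])
        u2 /= u2.sum()
        brute = np.exp(-sum(u * np.log(u) for u in u2 if u > 0)) / 10
        assert collectivity_from_displacements(disp) == pytest.approx(
            brute, abs=1e-10)

    def test_invariant_under_rescaling(self):
        rng = np.random.default_rng(4)
        disp = rng.normal(size=(8, 3))
        k1 = collectivity_from_displacements(disp)
        k2 = collectivity_from_displacements(1000.0 * disp)
        assert k1 == pytest.approx(k2, abs=1e-12)

    def test_zero_displacement_flagged(self):
        with pytest.raises(ValueError, match="undefined"):
            collectivity_from_displacements(np.zeros((5, 3)))

    def test_domain_restricted_collectivity(self):
        base = synthetic.chain_walk_coords(20, seed=0)
        modes = synthetic.internal_modes(base, 1, seed=0)
        spec = synthetic.PlantedEnsembleSpec(
            base=base, modes=modes, variances=np.array([4.0]),
            noise_variance=0.0, n_members=200, seed=0)
        ens, truth = synthetic.generate_ensemble(spec)
        pca = run_pca(ens, fit_fraction=1.0)
        kappa = collectivity(pca, 0, ens, list(range(1, 11)))
        direct = collectivity_from_displacements(
            truth.modes[0].reshape(-1, 3)[:10])
        assert kappa == pytest.approx(direct, abs=1e-2)


class TestCrossCorrelation:
    def test_identical_motion_perfectly_correlated(self):
        rng = np.random.default_rng(0)
        base = synthetic.chain_walk_coords(4, seed=0)
        shifts = rng.normal(size=(50, 1, 3))
        ens = make_ensemble_from_coords(list(base + shifts), fitted=True)
        cc = cross_correlation(ens)
        assert cc.matrix[0, 1] == pytest.approx(1.0)

    def test_opposite_motion_anticorrelated(self):
        rng = np.random.default_rng(0)
        base = synthetic.chain_walk_coords(2, seed=0)
        amp = rng.normal(size=50)
        members = []
        for a in amp:
            c = base.copy()
            c[0] += (a, 0, 0)
            c[1] -= (a, 0, 0)
            members.append(c)
        ens = make_ensemble_from_coords(members, fitted=True)
        cc = cross_correlation(ens)
        assert cc.matrix[0, 1] == pytest.approx(-1.0)

    def test_naive_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        members = list(rng.normal(size=(8, 7, 3)))
        ens = make_ensemble_from_coords(members, fitted=True)
        cc = cross_correlation(ens).matrix
        coords = np.stack(members)
        dev = coords - coords.mean(axis=0)
        for i in range(7):
            for j in range(7):
                num = np.mean([dev[n, i] @ dev[n, j] for n in range(8)])
                den = np.sqrt(np.mean([dev[n, i] @ dev[n, i]
                                       for n in range(8)])
                              * np.mean([dev[n, j] @ dev[n, j]
                                         for n in range(8)]))
                assert cc[i, j] == pytest.approx(num / den, abs=1e-10)

    def test_zero_fluctuation_residue_flagged(self):
        rng = np.random.default_rng(1)
        base = synthetic.chain_walk_coords(5, seed=1)
        members = []
        for _ in range(10):
            c = base + rng.normal(0, 0.5, base.shape)
            c[2] = base[2]  # residue 3 never moves
            members.append(c)
        ens = make_ensemble_from_coords(members, fitted=True)
        cc = cross_correlation(ens)
        assert cc.undefined[2]
        assert np.all(np.isnan(cc.matrix[2]))

    def test_planted_interblock_correlation(self):
        from swiveldyn.validation import dccm_planted_recovery
        res = dccm_planted_recovery(seed=0, n_members=500)
        assert res["inter_block_mean_correlation"] == pytest.approx(
            -0.3, abs=0.05)
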