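import numpy as np
import pytest

from mipam import KSGSettings, mi_matrix, mi_to_dissimilarity, select_g, silhouette_widths
from mipam.synthetic import SyntheticSpectraConfig, generate_block_spectra

from conftest import random_dissimilarity


def two_group_matrix(within=0.01, between=0.99, size=3):
    p = 2 * size
    D = np.full((p, p), between)
    D[:size, :size] = within
    D[size:, size:] = within
    np.fill_diagonal(D, 0.0)
    return D


class TestSilhouette:
    def test_two_tight_groups_hand_value(self):
        D = two_group_matrix(0.01, 0.99, size=2)
        s = silhouette_widths(D, [0, 0, 1, 1])
        assert np.allclose(s, (0.99 - 0.01) / 0.99)

    def test_singleton_convention_zero(self):
        D = two_group_matrix(0.2, 0.8, size=2)
        s = silhouette_widths(D, [0, 0, 0, 1])
        assert s[3] == 0.0

    def test_equidistant_point_zero(self):
        # point 0 has a == b
        D = np.array(
            [
                [0.0, 0.5, 0.5, 0.5],
                [0.5, 0.0, 0.1, 0.9],
                [0.5, 0.1, 0.0, 0.9],
                [0.5, 0.9, 0.9, 0.0],
            ]
        )
        s = silhouette_widths(D, [0, 0, 0, 1])
        assert s[0] == 0.0

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette_widths(two_group_matrix(), [0] * 6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_sklearn_on_random_matrices(self, seed):
        from sklearn.metrics import silhouette_samples

        rng = np.random.default_rng(seed)
        D = random_dissimilarity(rng, 10)
        labels = rng.integers(0, 3, size=10)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 3, size=10)
        mine = silhouette_widths(D, labels)
        ref = silhouette_samples(D, labels, metric="precomputed")
        assert np.allclose(mine, ref, atol=1e-12)

    def test_values_in_range(self):
        rng = np.random.default_rng(9)
        D = random_dissimilarity(rng, 12)
        s = silhouette_widths(D, rng.integers(0, 4, size=12))
        assert np.all(s >= -1.0) and np.all(s <= 1.0)


class TestSelectG:
    def test_recovers_five_planted_blocks(self):
        cfg = SyntheticSpectraConfig(
            n_subjects=85, block_sizes=(6, 5, 4, 4, 3), noise_sd=0.05, seed=17
        )
        ds, blocks = generate_block_spectra(cfg)
        D = mi_to_dissimilarity(mi_matrix(ds, KSGSettings(seed=17)))
        report = select_g(D, 2, 10)
        assert report.chosen_g == 5
        # chosen average silhouette dominates every other candidate
        best = report.avg_silhouette[report.candidate_g.index(report.chosen_g)]
        assert best == max(report.avg_silhouette)
        sizes = sorted(c.size for c in report.cluster_summaries)
        assert sizes == [3, 4, 4, 5, 6]
        for c in report.cluster_summaries:
            assert c.min_norm_mi <= c.mean_norm_mi

    def test_degenerate_sweep_and_determinism(self):
        D = two_group_matrix(0.05, 0.9, size=3)
        r1 = select_g(D, 2, 2)
        r2 = select_g(D, 2, 2)
        assert r1.chosen_g == 2
        assert r1.avg_silhouette == r2.avg_silhouette
        assert r1.partition.medoids == r2.partition.medoids

    def test_singleton_cluster_summary_flagged(self):
        # one far outlier point forms its own cluster at G=2
        D = np.full((5, 5), 0.05)
        D[4, :] = D[:, 4] = 0.99
        np.fill_diagonal(D, 0.0)
        report = select_g(D, 2, 3)
        singletons = [c for c in report.cluster_summaries if c.singleton]
        if singletons:  # present when the sweep keeps the outlier isolated
            assert singletons[0].size == 1
            assert singletons[0].min_norm_mi == 1.0 == singletons[0].mean_norm_mi

    def test_invalid_range_rejected(self):
        D = two_group_matrix()
        with pytest.raises(ValueError):
            select_g(D, 1, 3)
        with pytest.raises(ValueError):
            select_g(D, 2, 6)  # g_max > p-1

    def test_full_scale_preset_recovers_23_blocks(self):
        """Full 631-wavenumber emulation: the sweep lands on the 23 planted
        blocks with perfect agreement (window 18..28 brackets the truth)."""
        from mipam import mi_matrix, mi_to_dissimilarity, KSGSettings
        from mipam.synthetic import fingerprint_preset
        from mipam.synthetic import generate_block_spectra as gen
        from sklearn.metrics import adjusted_rand_score

        cfg = fingerprint_preset(seed=0, noise_sd=0.05)
        ds, blocks = gen(cfg)
        D = mi_to_dissimilarity(mi_matrix(ds, KSGSettings(seed=0)))
        report = select_g(D, 18, 28)
        assert report.chosen_g == 23
        assert adjusted_rand_score(blocks, report.partition.assignment) == 1.0
        for c in report.cluster_summaries:
            assert c.min_norm_mi <= c.mean_norm_mi

    def test_silhouette_tie_prefers_smallest_g(self):
        # fully symmetric all-equal dissimilarities: every G gives avg s = 0
        D = np.full((6, 6), 0.5)
        np.fill_diagonal(D, 0.0)
        report = select_g(D, 2, 4)
        assert report.chosen_g == 2
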