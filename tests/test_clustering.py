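"""Profile clustering: standardization, recovery, determinism, scan_k."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from psdmap import (
    Regulon,
    RegulonDesign,
    build_profiles,
    cluster_profiles,
    scan_k,
    simulate_expression,
    summarize_clusters,
)

from conftest import six_condition_design


def planted_data(archetypes, n_per=40, noise=0.1, seed=0, n_decoys=0):
    """Simulate gene profiles from condition-set archetypes."""
    regulons = [
        Regulon(name=f"arch{i}", conditions=conds, effect=2.0,
                genes=tuple(f"a{i}_g{j}" for j in range(n_per)))
        for i, conds in enumerate(archetypes)
    ]
    design = RegulonDesign(regulons=regulons, noise_sd=noise, seed=seed,
                           n_decoys=n_decoys)
    matrix, dtable, truth = simulate_expression(design)
    return matrix, dtable, truth


class TestBuildProfiles:
    def test_two_condition_standardization(self):
        design = pd.DataFrame({
            "sample": ["x1", "x2", "x3", "y1", "y2", "y3"],
            "condition": ["X"] * 3 + ["Y"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        })
        m = pd.DataFrame([[1.0, 1.0, 1.0, 3.0, 3.0, 3.0]], index=["g"],
                         columns=design["sample"])
        ps = build_profiles(m, design)
        assert ps.means.loc["g"].tolist() == [1.0, 3.0]
        assert np.allclose(ps.standardized.loc["g"],
                           [-0.7071, 0.7071], atol=1e-4)

    def test_constant_gene_flagged_not_dropped(self):
        matrix, dtable, _ = planted_data([("xylan",)], n_per=5, n_decoys=0)
        matrix.loc["flat"] = 3.14
        ps = build_profiles(matrix, dtable)
        assert "flat" in ps.flagged_constant
        assert "flat" in ps.genes
        assert "flat" not in ps.standardized.index

    def test_subset_count_preserved(self):
        matrix, dtable, _ = planted_data(
            [("xylan",), ("starch",)], n_per=90, n_decoys=50
        )
        subset = list(matrix.index[:161])
        ps = build_profiles(matrix, dtable, subset)
        assert len(ps) == 161

    def test_missing_gene_in_subset_errors(self):
        matrix, dtable, _ = planted_data([("xylan",)], n_per=5)
        with pytest.raises(KeyError):
            build_profiles(matrix, dtable, ["nope"])

    def test_pearson_distance_equals_half_squared_euclidean(self):
        matrix, dtable, _ = planted_data(
            [("xylan",), ("starch", "glucose")], n_per=20
        )
        ps = build_profiles(matrix, dtable)
        X = ps.standardized.to_numpy()
        r = np.corrcoef(X[0], X[5])[0, 1]
        d_euclid2 = ((X[0] - X[5]) ** 2).sum()
        assert 1 - r == pytest.approx(d_euclid2 / 2, abs=1e-10)


class TestClusterProfiles:
    def test_two_planted_archetypes_recovered_exactly(self):
        matrix, dtable, truth = planted_data(
            [("arabinan",), ("starch",)], n_per=40, noise=0.1, seed=1
        )
        ps = build_profiles(matrix, dtable)
        clu = cluster_profiles(ps, k=2, seed=5)
        labels_true = [truth.regulon_of[g] for g in clu.assignment.index]
        assert adjusted_rand_score(labels_true, clu.assignment) == 1.0

    def test_seeded_determinism(self):
        matrix, dtable, _ = planted_data(
            [("arabinan",), ("starch",), ("xylan", "xylose")], n_per=25,
            seed=2,
        )
        ps = build_profiles(matrix, dtable)
        a = cluster_profiles(ps, k=3, seed=11)
        b = cluster_profiles(ps, k=3, seed=11)
        pd.testing.assert_series_equal(a.assignment, b.assignment)
        assert a.dispersion == b.dispersion

    def test_gene_order_permutation_invariant(self):
        matrix, dtable, _ = planted_data(
            [("arabinan",), ("starch",)], n_per=30, seed=3
        )
        ps = build_profiles(matrix, dtable)
        clu1 = cluster_profiles(ps, k=2, seed=1)
        perm = matrix.sample(frac=1.0, random_state=7)
        ps2 = build_profiles(perm, dtable)
        clu2 = cluster_profiles(ps2, k=2, seed=1)
        joined = pd.concat([clu1.assignment, clu2.assignment], axis=1,
                           keys=["a", "b"]).dropna()
        assert adjusted_rand_score(joined["a"], joined["b"]) == 1.0

    def test_singleton_clusters_when_k_equals_genes(self):
        matrix, dtable, _ = planted_data(
            [("xylan",), ("starch",), ("glucose",)], n_per=2, noise=0.05
        )
        ps = build_profiles(matrix, dtable)
        n = len(ps.standardized)
        clu = cluster_profiles(ps, k=n, seed=0, n_init=5)
        assert (clu.sizes == 1).all()
        assert clu.dispersion == pytest.approx(0.0, abs=1e-9)

    def test_invalid_k_rejected(self):
        matrix, dtable, _ = planted_data([("xylan",)], n_per=5)
        ps = build_profiles(matrix, dtable)
        with pytest.raises(ValueError):
            cluster_profiles(ps, k=0)
        with pytest.raises(ValueError):
            cluster_profiles(ps, k=10**6)

    def test_recovery_across_20_seeds(self):
        """ARI >= 0.95 for well-separated planted clusters, 20 seeds."""
        ok = 0
        for seed in range(20):
            matrix, dtable, truth = planted_data(
                [("arabinan",), ("starch", "glucose")], n_per=40,
                noise=0.1, seed=seed,
            )
            ps = build_profiles(matrix, dtable)
            clu = cluster_profiles(ps, k=2, seed=seed, n_init=20)
            labels_true = [truth.regulon_of[g] for g in clu.assignment.index]
            if adjusted_rand_score(labels_true, clu.assignment) >= 0.95:
                ok += 1
        assert ok == 20


class TestScanK:
    def test_silhouette_peaks_at_three_planted_archetypes(self):
        matrix, dtable, _ = planted_data(
            [("arabinan",), ("starch",), ("xylan", "arabinose")],
            n_per=30, noise=0.1, seed=4,
        )
        ps = build_profiles(matrix, dtable)
        table = scan_k(ps, range(2, 7), seed=0, n_init=15)
        assert table["silhouette"].idxmax() == 3

    def test_dispersion_nonincreasing_in_k(self):
        matrix, dtable, _ = planted_data(
            [("arabinan",), ("starch",)], n_per=30, noise=0.4, seed=5,
            n_decoys=0,
        )
        ps = build_profiles(matrix, dtable)
        table = scan_k(ps, range(1, 8), seed=0, n_init=10)
        assert (table["dispersion"].diff().dropna() <= 1e-9).all()

    def test_k1_dispersion_is_total_pearson_variance(self):
        matrix, dtable, _ = planted_data([("xylan",)], n_per=10, noise=0.5,
                                         n_decoys=10)
        ps = build_profiles(matrix, dtable)
        clu = cluster_profiles(ps, k=1, seed=0, n_init=1, weighted=False)
        X = ps.standardized.to_numpy()
        c = X.mean(axis=0)
        c = (c - c.mean()) / np.linalg.norm(c - c.mean())
        expected = (1.0 - X @ c).sum()
        assert clu.dispersion == pytest.approx(expected, rel=1e-6)


class TestSummaries:
    def test_singleton_cluster_sd_zero(self):
        matrix, dtable, _ = planted_data(
            [("xylan",), ("starch",)], n_per=2, noise=0.05
        )
        ps = build_profiles(matrix, dtable)
        clu = cluster_profiles(ps, k=len(ps.standardized), seed=0, n_init=3)
        summary, members = summarize_clusters(clu, ps)
        assert (summary["sd"] == 0.0).all()

    def test_k1_mean_equals_global_mean_profile(self):
        matrix, dtable, _ = planted_data([("xylan",)], n_per=15)
        ps = build_profiles(matrix, dtable)
        clu = cluster_profiles(ps, k=1, seed=0, n_init=1)
        summary, members = summarize_clusters(clu, ps)
        clustered = ps.means.loc[clu.assignment.index]
        for cond in ps.conditions:
            row = summary[(summary["cluster"] == 0)
                          & (summary["condition"] == cond)]
            assert row["mean"].iloc[0] == pytest.approx(
                clustered[cond].mean()
            )

    def test_planted_archetype_cluster_mean_near_truth(self):
        matrix, dtable, truth = planted_data(
            [("arabinan",)], n_per=40, noise=0.1, seed=6, n_decoys=0
        )
        ps = build_profiles(matrix, dtable)
        clu = cluster_profiles(ps, k=1, seed=0, n_init=1)
        summary, _ = summarize_clusters(clu, ps)
        ara = summary[summary["condition"] == "arabinan"]["mean"].iloc[0]
        glc = summary[summary["condition"] == "glucose"]["mean"].iloc[0]
        assert ara - glc == pytest.approx(2.0, abs=0.15)


def test_ribbon_plot_writes_a_file(tmp_path):
    matrix, dtable, _ = planted_data([("xylan",), ("starch",)], n_per=10)
    ps = build_profiles(matrix, dtable)
    clu = cluster_profiles(ps, k=2, seed=0, n_init=3)
    from psdmap.clustering import plot_cluster_profiles

    out = plot_cluster_profiles(clu, ps, str(tmp_path / "clusters.png"))
    assert (tmp_path / "clusters.png").stat().st_size > 0
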