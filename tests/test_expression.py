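"""FPKM filtering, UPGMA/Spearman clustering, signal-to-noise ranking."""

import numpy as np
import pandas as pd
import pytest

from bcoritd.expression import (
    cluster_samples,
    filter_genes,
    signal_to_noise_rank,
    spearman_distance,
)
from bcoritd.simulate import simulate_fpkm_matrix


@pytest.fixture(scope="module")
def planted_matrix():
    mat, labels = simulate_fpkm_matrix(3, n_genes=300, group_sizes=(6, 6))
    return mat, labels


class TestFilterGenes:
    def test_constant_gene_removed(self):
        mat = pd.DataFrame({"s1": [5.0, 5.0], "s2": [5.0, 9.0], "s3": [5.0, 2.0]},
                           index=["const", "var"])
        kept = filter_genes(mat)
        assert list(kept.index) == ["var"]

    def test_mean_exactly_at_threshold_removed(self):
        mat = pd.DataFrame(
            {"s1": [0.5, 9.0], "s2": [1.5, 1.0], "s3": [2.5, 2.0]},
            index=["boundary", "pass"],
        )  # boundary gene: mean exactly 1.5, high CV
        kept = filter_genes(mat)
        assert "boundary" not in kept.index

    def test_matches_brute_force_on_planted_matrix(self, planted_matrix):
        mat, _ = planted_matrix
        kept = filter_genes(mat)
        expected = [
            g
            for g in mat.index
            if mat.loc[g].mean() > 1.5
            and mat.loc[g].std(ddof=1) / mat.loc[g].mean() > 0.3
        ]
        assert list(kept.index) == expected

    def test_idempotent(self, planted_matrix):
        mat, _ = planted_matrix
        once = filter_genes(mat)
        pd.testing.assert_frame_equal(filter_genes(once), once)

    def test_ribosomal_prefix_drop(self):
        mat = pd.DataFrame(
            np.array([[10.0, 1.0, 30.0]] * 3).T,
            index=["RPL13", "RPS6", "MYOD1"],
            columns=["s1", "s2", "s3"],
        )
        kept = filter_genes(mat, min_mean=0.0, min_cv=-1.0, drop_ribosomal=True)
        assert list(kept.index) == ["MYOD1"]

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            filter_genes(pd.DataFrame({"s1": [1.0, 2.0]}))


class TestClustering:
    def test_identical_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(0)
        base = rng.random(30) * 10
        mat = pd.DataFrame(
            {"a": base, "b": base, "c": base[::-1]},
            index=[f"g{i}" for i in range(30)],
        )
        result = cluster_samples(mat)
        first = result.merge_order()[0]
        assert first == (frozenset({"a"}), frozenset({"b"}))
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_three_sample_merge_order_matches_hand_computation(self):
        # ranks hand-computed: rho(X,Y)=0.8, rho(X,Z)=-1, rho(Y,Z)=-0.8
        # -> d(X,Y)=0.2 merges first; then d({XY},Z)=avg(2,1.8)=1.9
        mat = pd.DataFrame(
            {"X": [1.0, 2.0, 3.0, 4.0], "Y": [1.0, 2.0, 4.0, 3.0],
             "Z": [4.0, 3.0, 2.0, 1.0]},
            index=["g1", "g2", "g3", "g4"],
        )
        result = cluster_samples(mat)
        dist = result.distance
        assert dist.loc["X", "Y"] == pytest.approx(0.2)
        assert dist.loc["X", "Z"] == pytest.approx(2.0)
        assert dist.loc["Y", "Z"] == pytest.approx(1.8)
        order = result.merge_order()
        assert set(order[0]) == {frozenset({"X"}), frozenset({"Y"})}
        assert set(order[1]) == {frozenset({"X", "Y"}), frozenset({"Z"})}
        assert result.linkage[1, 2] == pytest.approx(1.9)

    def test_distance_matrix_properties(self, planted_matrix):
        mat, _ = planted_matrix
        dist = spearman_distance(mat)
        assert np.allclose(dist.values, dist.values.T)
        assert np.allclose(np.diag(dist.values), 0.0)
        assert (dist.values >= -1e-12).all() and (dist.values <= 2 + 1e-12).all()

    def test_zero_variance_sample_reported_by_name(self):
        mat = pd.DataFrame(
            {"ok": [1.0, 2.0, 3.0], "flat": [2.0, 2.0, 2.0], "ok2": [3.0, 1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="flat"):
            cluster_samples(mat)

    def test_planted_groups_recovered(self):
        hits = 0
        for seed in range(10):
            mat, labels = simulate_fpkm_matrix(100 + seed)
            cut = cluster_samples(mat).cut(2)
            agree = (
                cut.groupby(labels).nunique().eq(1).all()
                and cut.nunique() == 2
            )
            hits += bool(agree)
        assert hits >= 9

    def test_newick_export_is_well_formed(self, planted_matrix):
        import io

        from Bio import Phylo

        mat, _ = planted_matrix
        newick = cluster_samples(mat.iloc[:, :6]).to_newick()
        tree = Phylo.read(io.StringIO(newick), "newick")
        assert tree.count_terminals() == 6


class TestSignalToNoise:
    def test_identical_gene_scores_zero(self):
        mat = pd.DataFrame(
            np.array([[3.0] * 8, [1, 2, 3, 4, 8, 9, 10, 11]]),
            index=["flat", "up"],
            columns=[f"s{i}" for i in range(8)],
        )
        labels = pd.Series(["A"] * 4 + ["B"] * 4, index=mat.columns)
        ranked = signal_to_noise_rank(mat, labels)
        assert ranked.loc["flat", "score"] == 0.0

    def test_planted_up_gene_ranks_first(self, planted_matrix):
        mat, labels = planted_matrix
        ranked = signal_to_noise_rank(mat, labels)
        # genes 0..39 carry the planted B-upregulation: with A as the
        # first phenotype their scores are the most negative, so the most
        # extreme |score| genes are planted ones
        top_abs = ranked["score"].abs().sort_values(ascending=False).index[:10]
        planted = {f"G{i:04d}" for i in range(40)}
        assert len(planted & set(top_abs)) >= 9

    def test_antisymmetry_under_label_swap(self, planted_matrix):
        mat, labels = planted_matrix
        swapped = labels.map({"A": "B", "B": "A"})
        a = signal_to_noise_rank(mat, labels)["score"].sort_index()
        b = signal_to_noise_rank(mat, swapped)["score"].sort_index()
        assert np.allclose(a.values, -b.values)

    def test_invariance_under_positive_gene_scaling(self, planted_matrix):
        mat, labels = planted_matrix
        rng = np.random.default_rng(7)
        scale = pd.Series(rng.uniform(0.5, 3.0, len(mat)), index=mat.index)
        a = signal_to_noise_rank(mat, labels)["score"].sort_index()
        b = signal_to_noise_rank(mat.mul(scale, axis=0), labels)["score"].sort_index()
        assert np.allclose(a.values, b.values)

    def test_small_phenotype_rejected(self, planted_matrix):
        mat, _ = planted_matrix
        labels = pd.Series(["A"] + ["B"] * 11, index=mat.columns)
        with pytest.raises(ValueError):
            signal_to_noise_rank(mat, labels)
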