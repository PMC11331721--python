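"""Marker-gene screening statistics and clustering."""

import numpy as np
import pandas as pd
import pytest

from markerprof.markers import (
    GeneCopyTable,
    compute_marker_stats,
    f05_score,
    mean_relative_distance_matrix,
    select_representatives,
    single_linkage_clusters,
    valid_genes,
)


def copy_table(data, subsets=None):
    df = pd.DataFrame(data).T  # genes as columns after transpose of dict
    return GeneCopyTable(df, subsets or {})


class TestUniversalityDeviance:
    def test_perfect_single_copy(self):
        table = copy_table({"a1": {"g": 1}, "a2": {"g": 1},
                            "a3": {"g": 1}, "a4": {"g": 1}})
        stats = compute_marker_stats(table)["full"]
        assert stats.loc["g", "universality"] == 1.0
        assert stats.loc["g", "deviance"] == 0.0

    def test_missing_copy_balanced_by_double(self):
        # copies (1,1,0,2): universality 0.75 but mean exactly 1
        table = copy_table({f"a{i}": {"g": c}
                            for i, c in enumerate([1, 1, 0, 2])})
        stats = compute_marker_stats(table)["full"]
        assert stats.loc["g", "universality"] == 0.75
        assert stats.loc["g", "deviance"] == 0.0

    def test_duplicated_gene(self):
        table = copy_table({"a1": {"g": 2}, "a2": {"g": 2}})
        stats = compute_marker_stats(table)["full"]
        assert stats.loc["g", "universality"] == 1.0
        assert stats.loc["g", "deviance"] == 1.0

    def test_subset_stats(self):
        table = copy_table(
            {"a1": {"g": 1}, "a2": {"g": 1}, "tiny1": {"g": 0}},
            subsets={"tiny": ["tiny1"]},
        )
        stats = compute_marker_stats(table)
        assert stats["tiny"].loc["g", "universality"] == 0.0
        assert stats["full"].loc["g", "universality"] == pytest.approx(2 / 3)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            copy_table({"a1": {"g": -1}})


class TestF05:
    def test_perfect(self):
        assert f05_score(10, 0, 0) == 1.0

    def test_half_precision(self):
        assert f05_score(50, 50, 0) == pytest.approx(0.625 / 1.125)

    def test_zero_recall(self):
        assert f05_score(0, 5, 5) == 0.0

    def test_undefined(self):
        with pytest.raises(ValueError):
            f05_score(0, 0, 5)


class TestDistances:
    def test_same_position_zero(self):
        d = mean_relative_distance_matrix(
            {"a": {"g1": [100], "g2": [100]}}, {"a": 1000}
        )
        assert d.loc["g1", "g2"] == 0.0

    def test_wraparound(self):
        d = mean_relative_distance_matrix(
            {"a": {"g1": [100], "g2": [900]}}, {"a": 1000}
        )
        assert d.loc["g1", "g2"] == pytest.approx(0.2)

    def test_antipodal_maximum(self):
        d = mean_relative_distance_matrix(
            {"a": {"g1": [0], "g2": [500]}}, {"a": 1000}
        )
        assert d.loc["g1", "g2"] == 0.5

    def test_entries_never_exceed_half(self):
        rng = np.random.default_rng(0)
        positions = {
            f"a{i}": {g: list(rng.integers(0, 10_000, size=2))
                      for g in "wxyz"}
            for i in range(5)
        }
        d = mean_relative_distance_matrix(positions, {f"a{i}": 10_000
                                                      for i in range(5)})
        assert (d.to_numpy() <= 0.5 + 1e-12).all()

    def test_multicopy_uses_minimum(self):
        d = mean_relative_distance_matrix(
            {"a": {"g1": [0], "g2": [400, 50]}}, {"a": 1000}
        )
        assert d.loc["g1", "g2"] == pytest.approx(0.05)

    def test_pair_without_cooccurrence_is_nan(self):
        d = mean_relative_distance_matrix(
            {"a": {"g1": [0]}, "b": {"g2": [0]}}, {"a": 1000, "b": 1000}
        )
        assert np.isnan(d.loc["g1", "g2"])

    def test_position_outside_genome_rejected(self):
        with pytest.raises(ValueError):
            mean_relative_distance_matrix({"a": {"g1": [1000]}}, {"a": 1000})


class TestClustering:
    def dist(self, entries, genes):
        d = pd.DataFrame(np.ones((len(genes), len(genes))),
                         index=genes, columns=genes)
        np.fill_diagonal(d.values, 0.0)
        for g1, g2, v in entries:
            d.loc[g1, g2] = d.loc[g2, g1] = v
        return d

    def test_all_far_apart_singletons(self):
        d = self.dist([], list("abc"))
        assert single_linkage_clusters(d) == [["a"], ["b"], ["c"]]

    def test_chain_merges_transitively(self):
        d = self.dist([("a", "b", 0.03), ("b", "c", 0.04), ("a", "c", 0.2)],
                      list("abc"))
        assert single_linkage_clusters(d) == [["a", "b", "c"]]

    def test_zero_distance_merged(self):
        d = self.dist([("a", "b", 0.0)], list("abc"))
        assert single_linkage_clusters(d) == [["a", "b"], ["c"]]

    def test_cutoff_is_strict(self):
        d = self.dist([("a", "b", 0.05)], list("ab"))
        assert single_linkage_clusters(d) == [["a"], ["b"]]

    def test_order_invariance(self):
        genes = list("abcd")
        d = self.dist([("a", "c", 0.01), ("b", "d", 0.02)], genes)
        shuffled = d.loc[["d", "b", "a", "c"], ["d", "b", "a", "c"]]
        assert single_linkage_clusters(d) == single_linkage_clusters(shuffled)


class TestSelection:
    def stats(self, rows):
        return pd.DataFrame(rows).T.rename(
            columns={0: "universality", 1: "deviance"}
        )

    def test_singleton_cluster(self):
        stats = self.stats({"g1": [1.0, 0.0]})
        assert select_representatives([["g1"]], stats) == ["g1"]

    def test_universality_dominates(self):
        stats = self.stats({"g1": [1.0, 0.001], "g2": [0.995, 0.0]})
        assert select_representatives([["g1", "g2"]], stats) == ["g1"]

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            select_representatives([[]], self.stats({"g": [1, 0]}))

    def test_prefilter_excludes_low_universality(self):
        stats = {
            "full": self.stats({"good": [1.0, 0.0], "weak": [0.98, 0.0]}),
            "tiny": self.stats({"good": [1.0, 0.0], "weak": [1.0, 0.0]}),
        }
        f05 = {"good": 1.0, "weak": 1.0}
        assert valid_genes(stats, f05) == ["good"]

    def test_planted_spatial_clusters_yield_one_rep_each(self):
        """16 genes in two co-located blocks on simulated circular
        genomes: exactly one representative per planted cluster."""
        rng = np.random.default_rng(42)
        genes = [f"g{i:02d}" for i in range(16)]
        blocks = {g: (0 if i < 8 else 1) for i, g in enumerate(genes)}
        positions, lengths = {}, {}
        for a in range(6):
            L = 4_000_000
            anchors = rng.uniform(0, L, size=2)
            positions[f"asm{a}"] = {
                g: [float((anchors[blocks[g]] + rng.uniform(0, 40_000)) % L)]
                for g in genes
            }
            lengths[f"asm{a}"] = L
        d = mean_relative_distance_matrix(positions, lengths)
        clusters = single_linkage_clusters(d)
        assert len(clusters) == 2
        stats = self.stats({g: [1.0, 0.0] for g in genes})
        reps = select_representatives(clusters, stats)
        assert len(reps) == 2
        assert blocks[reps[0]] != blocks[reps[1]]
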