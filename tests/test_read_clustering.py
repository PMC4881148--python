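"""Similarity graph, cluster detection and genome-proportion estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import single_linkage_partition
from repeatchip._alignment import revcomp
from repeatchip.read_clustering import (RepeatCluster, SequenceRead,
                                        assign_proportions, detect_clusters,
                                        genome_proportion,
                                        link_clusters_by_pairs,
                                        pairwise_similarities, quality_filter,
                                        select_annotatable_clusters,
                                        similarity_between)
from repeatchip.synthetic_data import random_dna


def read(rid, bases, quality=None):
    return SequenceRead(id=rid, bases=bases, quality=quality)


class TestQualityFilter:
    def test_error_free_reads_all_retained(self, satellite_reads):
        kept, report = quality_filter(satellite_reads.reads)
        assert report.n_kept == report.n_input
        assert [r.id for r in kept] == [r.id for r in satellite_reads.reads]

    def test_n_rich_read_dropped(self):
        rich = read("n", "N" * 10 + "A" * 40)           # 20 % N
        clean = read("c", "A" * 50)
        kept, report = quality_filter([rich, clean], max_n_fraction=0.05)
        assert [r.id for r in kept] == ["c"]
        assert report.n_high_n == 1

    def test_mean_quality_threshold_counts_exactly(self):
        rng = np.random.default_rng(0)
        q_good = chr(30 + 33) * 50
        q_bad = chr(10 + 33) * 50
        reads = [read(f"g{i}", random_dna(50, rng), q_good) for i in range(900)]
        reads += [read(f"b{i}", random_dna(50, rng), q_bad) for i in range(100)]
        kept, report = quality_filter(reads, min_mean_quality=20)
        assert report.n_kept == 900
        assert report.n_low_quality == 100

    def test_empty_input_and_all_filtered_are_distinct_errors(self):
        with pytest.raises(ValueError, match="no reads"):
            quality_filter([])
        with pytest.raises(ValueError, match="all 1 reads removed"):
            quality_filter([read("b", "A" * 50, chr(5 + 33) * 50)])


class TestPairwiseSimilarities:
    def test_identical_reads_full_identity_edge(self):
        rng = np.random.default_rng(1)
        seq = random_dna(100, rng)
        edges = pairwise_similarities([read("a", seq), read("b", seq)])
        assert len(edges) == 1
        edge = edges[0]
        assert (edge.read_a, edge.read_b) == ("a", "b")
        assert edge.identity == 100.0
        assert edge.alignment_coverage == 1.0

    def test_reverse_complement_detected(self):
        rng = np.random.default_rng(2)
        seq = random_dna(100, rng)
        edges = pairwise_similarities([read("a", seq), read("b", revcomp(seq))])
        assert len(edges) == 1 and edges[0].identity == 100.0

    def test_dissimilar_reads_have_no_edge(self):
        rng = np.random.default_rng(3)
        edges = pairwise_similarities([read("a", random_dna(100, rng)),
                                       read("b", random_dna(100, rng))])
        assert edges == []

    def test_satellite_vs_background_matches_bruteforce(self, satellite_genome):
        """Edges appear only among satellite reads, and the prefiltered edge
        set equals brute-force all-pairs alignment on the 100-read instance."""
        rng = np.random.default_rng(4)
        starts, ends, _ = satellite_genome.truth.merged_intervals()
        lo, hi = int(starts[0]), int(ends[0]) - 100
        reads = []
        for i in range(50):
            pos = int(rng.integers(lo, hi))
            reads.append(read(f"sat{i:02d}",
                              satellite_genome.sequence[pos:pos + 100]))
        for i in range(50):
            reads.append(read(f"bg{i:02d}", random_dna(100, rng)))
        edges = pairwise_similarities(reads)
        assert edges, "satellite reads must link"
        assert all(e.read_a.startswith("sat") and e.read_b.startswith("sat")
                   for e in edges)
        brute = set()
        for i in range(len(reads)):
            for j in range(i + 1, len(reads)):
                if similarity_between(reads[i], reads[j]) is not None:
                    brute.add(tuple(sorted((reads[i].id, reads[j].id))))
        assert {(e.read_a, e.read_b) for e in edges} == brute

    def test_single_read_rejected(self):
        with pytest.raises(ValueError):
            pairwise_similarities([read("a", "ACGT" * 30)])


class TestDetectClusters:
    def test_small_example_partition(self):
        from repeatchip.read_clustering import SimilarityEdge
        edges = [SimilarityEdge("a", "b", 95.0, 0.8),
                 SimilarityEdge("b", "c", 95.0, 0.8)]
        clusters, singles = detect_clusters(edges, ["a", "b", "c", "d", "e"])
        assert len(clusters) == 1
        assert clusters[0].read_ids == frozenset("abc")
        assert clusters[0].cluster_id == 1
        assert singles == {"d", "e"}

    def test_no_edges_all_singletons(self):
        clusters, singles = detect_clusters([], [f"r{i}" for i in range(10)])
        assert clusters == [] and len(singles) == 10

    def test_unknown_read_in_edge_rejected(self):
        from repeatchip.read_clustering import SimilarityEdge
        with pytest.raises(ValueError):
            detect_clusters([SimilarityEdge("a", "zz", 95.0, 0.8)], ["a", "b"])

    @given(st.lists(st.tuples(st.integers(0, 199), st.integers(0, 199)),
                    max_size=400))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_union_find_oracle(self, raw_edges):
        """On arbitrary graphs over 200 reads the partition equals an
        independent union-find transitive closure."""
        from repeatchip.read_clustering import SimilarityEdge
        ids = [f"r{i:03d}" for i in range(200)]
        pairs = sorted({(ids[min(a, b)], ids[max(a, b)])
                        for a, b in raw_edges if a != b})
        edges = [SimilarityEdge(a, b, 95.0, 0.8) for a, b in pairs]
        clusters, singles = detect_clusters(edges, ids)
        o_clusters, o_singles = single_linkage_partition(ids, pairs)
        assert [c.read_ids for c in clusters] == o_clusters
        assert singles == o_singles

    def test_rank_order_and_tie_break(self):
        from repeatchip.read_clustering import SimilarityEdge
        edges = [SimilarityEdge("x1", "x2", 95.0, 0.8),
                 SimilarityEdge("a1", "a2", 95.0, 0.8),
                 SimilarityEdge("m1", "m2", 95.0, 0.8),
                 SimilarityEdge("m2", "m3", 95.0, 0.8)]
        clusters, _ = detect_clusters(edges, "x1 x2 a1 a2 m1 m2 m3".split())
        assert [c.read_ids for c in clusters] == [
            frozenset({"m1", "m2", "m3"}),
            frozenset({"a1", "a2"}),        # size tie -> smallest member id
            frozenset({"x1", "x2"})]


class TestProportions:
    def test_annotation_threshold_unit(self):
        cluster = RepeatCluster(cluster_id=1, read_ids=frozenset(
            f"r{i}" for i in range(140)))
        assert genome_proportion(cluster, 1400000) == pytest.approx(0.01)

    def test_single_cluster_is_everything(self):
        cluster = RepeatCluster(cluster_id=1, read_ids=frozenset(["a", "b"]))
        assert genome_proportion(cluster, 2) == 100.0

    def test_zero_total_rejected(self):
        cluster = RepeatCluster(cluster_id=1, read_ids=frozenset(["a", "b"]))
        with pytest.raises(ValueError):
            genome_proportion(cluster, 0)

    def test_selection_boundary_is_inclusive(self):
        clusters = []
        for i, pct in enumerate([0.02, 0.01, 0.009], start=1):
            c = RepeatCluster(cluster_id=i,
                              read_ids=frozenset([f"a{i}", f"b{i}"]))
            c.genome_proportion = pct
            clusters.append(c)
        kept = select_annotatable_clusters(clusters, threshold=0.01)
        assert [c.cluster_id for c in kept] == [1, 2]
        assert len(select_annotatable_clusters(clusters, threshold=0.0)) == 3

    def test_partition_property_and_proportion_sum(self, satellite_genome,
                                                   satellite_reads):
        reads, _ = quality_filter(satellite_reads.reads)
        edges = pairwise_similarities(reads)
        clusters, singles = detect_clusters(edges, [r.id for r in reads])
        clustered = sum(c.n_reads for c in clusters)
        assert clustered + len(singles) == len(reads)
        assign_proportions(clusters, len(reads))
        total = sum(c.genome_proportion for c in clusters) \
            + 100.0 * len(singles) / len(reads)
        assert total == pytest.approx(100.0, abs=1e-6)

    def test_lower_identity_threshold_coarsens_partition(self):
        """Every cluster found at a strict identity threshold stays inside a
        single cluster at a looser threshold (sizes never shrink)."""
        from repeatchip.synthetic_data import (GenomeSpec, RepeatFamilySpec,
                                               build_synthetic_genome,
                                               simulate_shotgun_pairs)
        spec = GenomeSpec(
            families=[RepeatFamilySpec("sat", "satellite", 327, 20,
                                       divergence=0.04)],
            background_length=8000, seed=31)
        genome = build_synthetic_genome(spec)
        reads = simulate_shotgun_pairs(genome, 1.0, 100, 300, seed=32).reads
        ids = [r.id for r in reads]
        strict, _ = detect_clusters(
            pairwise_similarities(reads, min_identity=95.0), ids)
        loose, _ = detect_clusters(
            pairwise_similarities(reads, min_identity=85.0), ids)
        member_of = {rid: i for i, c in enumerate(loose) for rid in c.read_ids}
        for cluster in strict:
            homes = {member_of.get(rid) for rid in cluster.read_ids}
            assert len(homes) == 1 and None not in homes


class TestClusterLinks:
    def _cluster(self, cid, ids):
        return RepeatCluster(cluster_id=cid, read_ids=frozenset(ids))

    def test_split_element_clusters_are_linked(self):
        c1 = self._cluster(1, ["l1", "l2", "l3", "l4", "l5"])
        c2 = self._cluster(2, ["i1", "i2", "i3", "i4", "i5"])
        pairs = [(f"l{k}", f"i{k}") for k in range(1, 6)]
        table = link_clusters_by_pairs([c1, c2], pairs, min_links=5)
        assert table.values.tolist() == [[1, 2, 5]]

    def test_no_cross_cluster_mates_empty_table(self):
        c1 = self._cluster(1, ["a1", "a2"])
        c2 = self._cluster(2, ["b1", "b2"])
        table = link_clusters_by_pairs([c1, c2], [("a1", "a2"), ("b1", "b2")])
        assert table.empty

    def test_single_spanning_pair_at_min_links_one(self):
        c1 = self._cluster(1, ["a1", "a2"])
        c2 = self._cluster(2, ["b1", "b2"])
        table = link_clusters_by_pairs([c1, c2], [("a1", "b1")], min_links=1)
        assert table.values.tolist() == [[1, 2, 1]]
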