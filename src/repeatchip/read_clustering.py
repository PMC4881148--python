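"""Graph-based identification of repeat clusters from unassembled reads.

Repetitive elements are identified without a genome assembly: every read is
compared with every other read (k-mer prefiltered, strand-aware local
alignment), reads passing an identity/coverage threshold are joined by an
edge, and connected components of the resulting graph with at least two reads
are reported as repeat clusters.  Because shotgun read sampling is uniform,
the fraction of analyzed reads inside a cluster estimates the genome
proportion of the underlying repeat family.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

from ._alignment import LocalAligner, revcomp

VALID_BASES = frozenset("ACGTN")


@dataclass
class SequenceRead:
    """A single sequencing read.

    ``quality`` is a phred+33 ASCII string (as in FASTQ) or ``None`` for
    FASTA input.  ``true_family`` is simulator provenance ("background",
    "junction" or a family name) and is never consulted by the clustering
    itself.
    """

    id: str
    bases: str
    quality: Optional[str] = None
    mate_id: Optional[str] = None
    strand: str = "+"
    true_family: Optional[str] = None
    origin_start: Optional[int] = None   # 0-based genome start (simulated reads)

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"read {self.id!r} has empty sequence")
        if not set(self.bases) <= VALID_BASES:
            bad = sorted(set(self.bases) - VALID_BASES)
            raise ValueError(f"read {self.id!r} has invalid bases {bad}")
        if self.quality is not None and len(self.quality) != len(self.bases):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")

    def mean_quality(self) -> Optional[float]:
        if self.quality is None:
            return None
        return sum(ord(c) - 33 for c in self.quality) / len(self.quality)

    def n_fraction(self) -> float:
        return self.bases.count("N") / len(self.bases)


@dataclass(frozen=True)
class SimilarityEdge:
    """Undirected similarity edge; stored with read_a < read_b."""

    read_a: str
    read_b: str
    identity: float            # percent, over aligned columns
    alignment_coverage: float  # aligned fraction of the shorter read

    def __post_init__(self) -> None:
        if self.read_a >= self.read_b:
            raise ValueError("edges are stored with read_a < read_b")


@dataclass
class RepeatCluster:
    """A connected group of reads representing one repeat family (or part)."""

    cluster_id: int                      # rank, 1 = most reads
    read_ids: frozenset
    genome_proportion: Optional[float] = None   # percent of analyzed reads
    contigs: list = field(default_factory=list)
    annotation: Optional[object] = None

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_kept: int
    n_low_quality: int
    n_high_n: int


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def quality_filter(reads: Sequence[SequenceRead],
                   min_mean_quality: float = 20.0,
                   max_n_fraction: float = 0.05,
                   ) -> tuple[list[SequenceRead], FilterReport]:
    """Drop low-quality and N-rich reads, preserving input order.

    Reads without quality strings (FASTA) pass the quality criterion.
    Raises ``ValueError`` on empty input and, with a distinct message, when
    every read is removed by the filters.
    """
    if not reads:
        raise ValueError("no reads supplied to quality_filter")
    kept: list[SequenceRead] = []
    n_low_q = n_high_n = 0
    for read in reads:
        mq = read.mean_quality()
        if mq is not None and mq < min_mean_quality:
            n_low_q += 1
            continue
        if read.n_fraction() > max_n_fraction:
            n_high_n += 1
            continue
        kept.append(read)
    if not kept:
        raise ValueError(
            f"all {len(reads)} reads removed by filters "
            f"({n_low_q} low quality, {n_high_n} N-rich)")
    return kept, FilterReport(len(reads), len(kept), n_low_q, n_high_n)


# ---------------------------------------------------------------------------
# similarity graph
# ---------------------------------------------------------------------------

def similarity_between(read_a: SequenceRead, read_b: SequenceRead,
                       min_identity: float = 90.0,
                       min_coverage: float = 0.55,
                       aligner: Optional[LocalAligner] = None,
                       ) -> Optional[SimilarityEdge]:
    """Edge between two reads, or None if no qualifying local alignment.

    Both strands are tried; identity is computed over aligned columns of the
    best-scoring alignment, coverage as the aligned fraction of the shorter
    read.  A cheap score bound prunes pairs that cannot qualify: a local
    alignment with >= min_identity over >= min_coverage of the shorter read
    scores at least ``min_cov * len_min * (id*match + (1-id)*mismatch)``
    minus gap costs, and the optimal score is an upper bound for it.
    """
    aligner = aligner or _DEFAULT_READ_ALIGNER
    shorter = min(len(read_a.bases), len(read_b.bases))
    score, strand = aligner.best_strand_score(read_a.bases, read_b.bases)
    # Conservative pruning bound (gap columns charged at the worst rate).
    idf = min_identity / 100.0
    per_col = idf * aligner.match + (1.0 - idf) * min(
        aligner.mismatch, -(aligner.gap_open + aligner.gap_extend))
    bound = min_coverage * shorter * per_col
    if score < bound:
        return None
    hit = aligner.hit(read_a.bases, read_b.bases, strand=strand)
    span = min(hit.query_span, hit.target_span)
    coverage = span / shorter
    if hit.identity >= min_identity and coverage >= min_coverage:
        a, b = sorted((read_a.id, read_b.id))
        return SimilarityEdge(a, b, hit.identity, min(coverage, 1.0))
    return None


def _canonical_kmers(seq: str, k: int) -> set:
    out = set()
    rc = revcomp(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i:i + k]
        rev = rc[n - k - i:n - i]
        out.add(min(fwd, rev))
    return out


@lru_cache(maxsize=None)
def _min_shared_kmers(c_min: int, c_max: int, min_identity: float, k: int) -> int:
    """Lower bound on distinct shared k-mers for any qualifying alignment.

    An alignment with C columns and e non-match columns (e <= (1-id)*C) has
    its matches split into at most e+1 runs, so it exposes at least
    ``(C - e) - (e + 1)(k - 1)`` exact shared k-mers (pigeonhole).  The bound
    is minimized over the admissible column range; it can reach zero for
    short alignments, in which case a single shared k-mer is required.
    Assumes read sequences are not periodic with period < k (tandem monomers
    shorter than the read would need a smaller threshold).
    """
    err = 1.0 - min_identity / 100.0
    best = None
    for c in range(c_min, c_max + 1):
        e = int(err * c)
        m = (c - e) - (e + 1) * (k - 1)
        if best is None or m < best:
            best = m
    return max(1, best if best is not None else 1)


def candidate_pairs(reads: Sequence[SequenceRead], k: int,
                    min_identity: float = 90.0,
                    min_coverage: float = 0.55) -> Iterable[tuple[int, int]]:
    """Index pairs of reads that could satisfy the similarity thresholds.

    Pairs are generated from canonical (strand-collapsed) k-mer buckets and
    kept only when the number of distinct shared k-mers reaches the
    pigeonhole lower bound implied by the identity/coverage thresholds, so
    the prefilter removes no qualifying pair while discarding nearly all
    random collisions without an alignment.
    """
    buckets: dict[str, list[int]] = defaultdict(list)
    for idx, read in enumerate(reads):
        for kmer in _canonical_kmers(read.bases, k):
            buckets[kmer].append(idx)
    shared: dict[tuple[int, int], int] = defaultdict(int)
    for members in buckets.values():
        if len(members) < 2:
            continue
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                shared[(a, b) if a < b else (b, a)] += 1
    for (a, b), count in shared.items():
        shorter = min(len(reads[a].bases), len(reads[b].bases))
        longer = max(len(reads[a].bases), len(reads[b].bases))
        c_min = max(k, int(min_coverage * shorter))
        need = _min_shared_kmers(c_min, 2 * longer, min_identity, k)
        if count >= need:
            yield (a, b)


_DEFAULT_READ_ALIGNER = LocalAligner(match=1, mismatch=-2, gap_open=5, gap_extend=1)


def pairwise_similarities(reads: Sequence[SequenceRead],
                          min_identity: float = 90.0,
                          min_coverage: float = 0.55,
                          kmer_seed_length: int = 8,
                          ) -> list[SimilarityEdge]:
    """All-vs-all similarity edges (k-mer prefiltered, both strands)."""
    if len(reads) < 2:
        raise ValueError("pairwise_similarities needs at least 2 reads")
    ids = [r.id for r in reads]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate read ids")
    edges: list[SimilarityEdge] = []
    for i, j in candidate_pairs(reads, kmer_seed_length,
                                min_identity=min_identity,
                                min_coverage=min_coverage):
        edge = similarity_between(reads[i], reads[j],
                                  min_identity=min_identity,
                                  min_coverage=min_coverage)
        if edge is not None:
            edges.append(edge)
    edges.sort(key=lambda e: (e.read_a, e.read_b))
    return edges


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

def detect_clusters(edges: Iterable[SimilarityEdge],
                    all_read_ids: Iterable[str],
                    ) -> tuple[list[RepeatCluster], set]:
    """Connected components with >= 2 reads, ranked by descending size.

    Ties are broken by the lexicographically smallest member id so ranks are
    reproducible.  Reads touching no edge become singletons; the partition
    over ``all_read_ids`` is exhaustive and disjoint.
    """
    all_ids = set(all_read_ids)
    graph = nx.Graph()
    for edge in edges:
        if edge.read_a not in all_ids or edge.read_b not in all_ids:
            raise ValueError(f"edge references unknown read "
                             f"({edge.read_a}, {edge.read_b})")
        graph.add_edge(edge.read_a, edge.read_b)
    components = [frozenset(c) for c in nx.connected_components(graph)]
    components.sort(key=lambda c: (-len(c), min(c)))
    clusters = [RepeatCluster(cluster_id=rank, read_ids=comp)
                for rank, comp in enumerate(components, start=1)]
    clustered = set().union(*components) if components else set()
    singletons = all_ids - clustered
    return clusters, singletons


def genome_proportion(cluster: RepeatCluster, total_analyzed_reads: int) -> float:
    """Percent of analyzed reads in the cluster (= repeat genome proportion)."""
    if total_analyzed_reads <= 0:
        raise ValueError("total_analyzed_reads must be positive")
    return 100.0 * cluster.n_reads / total_analyzed_reads


def assign_proportions(clusters: Sequence[RepeatCluster],
                       total_analyzed_reads: int) -> None:
    for cluster in clusters:
        cluster.genome_proportion = genome_proportion(cluster, total_analyzed_reads)


def select_annotatable_clusters(clusters: Sequence[RepeatCluster],
                                threshold: float = 0.01) -> list[RepeatCluster]:
    """Clusters at or above the genome-proportion threshold (percent).

    The retained set is the reference against which ChIP/input reads are
    subsequently mapped.
    """
    for cluster in clusters:
        if cluster.genome_proportion is None:
            raise ValueError(f"cluster {cluster.cluster_id} has no proportion")
    return [c for c in clusters if c.genome_proportion >= threshold]


def link_clusters_by_pairs(clusters: Sequence[RepeatCluster],
                           read_pairs: Iterable[tuple[str, str]],
                           min_links: int = 5) -> pd.DataFrame:
    """Inter-cluster mate-pair links (repeats split between clusters).

    Returns a table with columns cluster_a < cluster_b and n_pairs, keeping
    links supported by at least ``min_links`` mate pairs.
    """
    membership: dict[str, int] = {}
    for cluster in clusters:
        for rid in cluster.read_ids:
            membership[rid] = cluster.cluster_id
    counts: dict[tuple[int, int], int] = defaultdict(int)
    for rid_a, rid_b in read_pairs:
        ca, cb = membership.get(rid_a), membership.get(rid_b)
        if ca is None or cb is None or ca == cb:
            continue
        counts[(min(ca, cb), max(ca, cb))] += 1
    rows = [(a, b, n) for (a, b), n in sorted(counts.items()) if n >= min_links]
    return pd.DataFrame(rows, columns=["cluster_a", "cluster_b", "n_pairs"])


def membership_table(clusters: Sequence[RepeatCluster],
                     singletons: Iterable[str]) -> pd.DataFrame:
    rows = [(rid, str(c.cluster_id)) for c in clusters for rid in sorted(c.read_ids)]
    rows += [(rid, "singleton") for rid in sorted(singletons)]
    rows.sort()
    return pd.DataFrame(rows, columns=["read_id", "cluster_id"])
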