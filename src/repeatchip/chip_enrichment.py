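"""ChIP/input read processing, best-hit mapping and enrichment calling.

ChIP and input reads are trimmed to a fixed fragment length and sampled to
the same depth, mapped to the cluster contigs with a BLASTN-like seeded
local alignment (match +2, mismatch -3, gap open 5, gap extend 2, word size
9, e-value cutoff 1e-12), and each read is assigned to at most one cluster
by its best similarity.  Per-cluster enrichment is the plain ratio of ChIP
to input read counts; a cluster is called enriched at ratio >= 1.5
(inclusive).  Clusters with fewer than ``min_input`` input reads get no
ratio and are flagged indeterminate rather than dropped, since a handful of
input reads cannot support a stable ratio.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from ._alignment import LocalAligner, evalue, revcomp
from .read_clustering import SequenceRead


@dataclass(frozen=True)
class BlastnScoring:
    """Scoring and thresholds of the read-to-contig mapping step."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 9
    evalue_cutoff: float = 1e-12


@dataclass(frozen=True)
class MappedRead:
    read_id: str
    cluster_id: Optional[int]          # None = unmapped
    e_value: Optional[float] = None
    alignment_score: Optional[float] = None
    identity: Optional[float] = None
    aligned_length: Optional[int] = None


@dataclass
class EnrichmentRecord:
    cluster_id: int
    chip_count: int
    input_count: int
    ratio: Optional[float]             # None when indeterminate
    enriched: bool = False

    @property
    def indeterminate(self) -> bool:
        return self.ratio is None


@dataclass(frozen=True)
class ClusterContig:
    cluster_id: int
    contig_id: str
    sequence: str


# ---------------------------------------------------------------------------
# read preparation
# ---------------------------------------------------------------------------

def prepare_chip_reads(reads: Sequence[SequenceRead], trim_length: int = 50,
                       n_sample: Optional[int] = None, seed: int = 0,
                       ) -> list:
    """Trim reads to their first ``trim_length`` bases and subsample.

    Reads shorter than the trim length are discarded.  Sampling is uniform
    without replacement and order-preserving, so sampling the full pool is
    the identity.  ChIP and input sets must be prepared to the SAME
    ``n_sample`` for ratios to be unbiased.
    """
    import numpy as np

    trimmed = []
    for read in reads:
        if len(read.bases) < trim_length:
            continue
        trimmed.append(SequenceRead(
            id=read.id, bases=read.bases[:trim_length],
            quality=read.quality[:trim_length] if read.quality else None,
            mate_id=read.mate_id, strand=read.strand,
            true_family=read.true_family))
    if n_sample is None:
        return trimmed
    if n_sample > len(trimmed):
        raise ValueError(
            f"requested {n_sample} reads but only {len(trimmed)} available "
            f"after trimming (shortfall {n_sample - len(trimmed)})")
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(len(trimmed), size=n_sample, replace=False))
    return [trimmed[i] for i in keep]


# ---------------------------------------------------------------------------
# best-hit mapping
# ---------------------------------------------------------------------------

def _contig_kmer_index(contigs: Sequence[ClusterContig], k: int) -> dict:
    index: dict = defaultdict(set)
    for ci, contig in enumerate(contigs):
        seq = contig.sequence
        for i in range(len(seq) - k + 1):
            index[seq[i:i + k]].add(ci)
    return index


def map_reads_to_clusters(reads: Sequence[SequenceRead],
                          contigs: Sequence[ClusterContig],
                          scoring: BlastnScoring = BlastnScoring(),
                          ) -> list:
    """Assign each read to at most one cluster by its best contig hit.

    Word-size seeding: a read/contig pair is aligned only when it shares an
    exact ``word_size``-mer on the tested strand (hits below the e-value
    cutoff at the stated scoring always do).  Best hit = lowest e-value,
    ties by highest alignment score, then lowest cluster_id.
    """
    if not contigs:
        raise ValueError("empty contig set")
    aligner = LocalAligner(match=scoring.match, mismatch=scoring.mismatch,
                           gap_open=scoring.gap_open,
                           gap_extend=scoring.gap_extend)
    k = scoring.word_size
    index = _contig_kmer_index(contigs, k)
    db_len = sum(len(c.sequence) for c in contigs)

    out = []
    for read in reads:
        candidates: dict = {}       # contig idx -> strands to try
        for query, strand in ((read.bases, "+"), (revcomp(read.bases), "-")):
            hit_contigs = set()
            for i in range(len(query) - k + 1):
                hit_contigs |= index.get(query[i:i + k], frozenset())
            for ci in hit_contigs:
                candidates.setdefault(ci, []).append((query, strand))
        best = None     # (evalue, -score, cluster_id, ci, strand_query)
        for ci, strand_queries in candidates.items():
            contig = contigs[ci]
            for query, strand in strand_queries:
                score = aligner.score(contig.sequence, query)
                ev = evalue(score, len(read.bases), db_len,
                            match=scoring.match, mismatch=scoring.mismatch)
                if ev > scoring.evalue_cutoff:
                    continue
                key = (ev, -score, contig.cluster_id)
                if best is None or key < best[0]:
                    best = (key, ci, query, score)
        if best is None:
            out.append(MappedRead(read_id=read.id, cluster_id=None))
            continue
        (ev, neg_score, cluster_id), ci, query, score = best
        hit = aligner.hit(contigs[ci].sequence, query, strand="+")
        out.append(MappedRead(read_id=read.id, cluster_id=cluster_id,
                              e_value=ev, alignment_score=score,
                              identity=hit.identity,
                              aligned_length=hit.aligned_length))
    return out


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def counts_by_cluster(maps: Sequence[MappedRead]) -> dict:
    counts: dict = defaultdict(int)
    for m in maps:
        if m.cluster_id is not None:
            counts[m.cluster_id] += 1
    return dict(counts)


def enrichment_from_counts(chip_counts: Mapping, input_counts: Mapping,
                           cluster_ids: Sequence, min_input: int = 20,
                           ) -> list:
    """EnrichmentRecord per reference cluster from raw mapped counts."""
    records = []
    for cid in cluster_ids:
        chip = int(chip_counts.get(cid, 0))
        inp = int(input_counts.get(cid, 0))
        ratio = chip / inp if inp >= min_input else None
        records.append(EnrichmentRecord(cluster_id=cid, chip_count=chip,
                                        input_count=inp, ratio=ratio))
    return records


def compute_enrichment(chip_maps: Sequence[MappedRead],
                       input_maps: Sequence[MappedRead],
                       cluster_ids: Optional[Sequence] = None,
                       min_input: int = 20) -> list:
    """Per-cluster ChIP/input ratio from two equally sampled map sets.

    Both map sets must come from the same contigs and the same ``n_sample``;
    unequal totals would bias every ratio and raise instead.  Counts are
    reported for all reference clusters, including zeros.
    """
    if len(chip_maps) != len(input_maps):
        raise ValueError(
            f"ChIP and input read totals differ ({len(chip_maps)} vs "
            f"{len(input_maps)}); sample both to the same n_sample")
    chip_counts = counts_by_cluster(chip_maps)
    input_counts = counts_by_cluster(input_maps)
    if cluster_ids is None:
        cluster_ids = sorted(set(chip_counts) | set(input_counts))
    return enrichment_from_counts(chip_counts, input_counts, cluster_ids,
                                  min_input=min_input)


def call_enriched(records: Sequence[EnrichmentRecord],
                  threshold: float = 1.5) -> list:
    """Flag and return records with ratio >= threshold (inclusive).

    Indeterminate records (no ratio) are never called enriched.
    """
    enriched = []
    for rec in records:
        rec.enriched = rec.ratio is not None and rec.ratio >= threshold
        if rec.enriched:
            enriched.append(rec)
    return enriched


# ---------------------------------------------------------------------------
# composition of the enriched fraction
# ---------------------------------------------------------------------------

@dataclass
class CompositionSummary:
    """Per-level composition of ChIP reads in enriched clusters.

    ``pct_of_enriched`` uses ChIP counts over enriched clusters as the
    denominator (sums to 100 within each level); ``pct_of_total`` uses the
    overall read amount introduced into the analysis, when supplied.
    """

    by_group: pd.DataFrame = field(default_factory=pd.DataFrame)
    by_clade: pd.DataFrame = field(default_factory=pd.DataFrame)
    by_family: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def empty(self) -> bool:
        return self.by_group.empty


def composition_summary(enriched_records: Sequence[EnrichmentRecord],
                        annotations: Mapping,
                        total_reads_basis: Optional[int] = None,
                        ) -> CompositionSummary:
    """Summarize enriched-repeat composition at group/clade/family levels.

    Unknown-annotated enriched clusters are pooled as "uncharacterized".
    An empty enriched set yields an explicitly empty summary.
    """
    if not enriched_records:
        return CompositionSummary()
    total_chip = sum(r.chip_count for r in enriched_records)

    def level_table(key_fn) -> pd.DataFrame:
        sums: dict = defaultdict(int)
        for rec in enriched_records:
            ann = annotations.get(rec.cluster_id)
            label = key_fn(ann)
            sums[label] += rec.chip_count
        rows = []
        for label, chip in sorted(sums.items(), key=lambda kv: (-kv[1], kv[0])):
            row = {"label": label, "chip_reads": chip,
                   "pct_of_enriched": 100.0 * chip / total_chip if total_chip else 0.0}
            if total_reads_basis:
                row["pct_of_total"] = 100.0 * chip / total_reads_basis
            rows.append(row)
        return pd.DataFrame(rows)

    def group_of(ann):
        if ann is None or ann.group == "unknown":
            return "uncharacterized"
        return ann.group

    def clade_of(ann):
        g = group_of(ann)
        if g == "uncharacterized" or not ann.superfamily_or_clade:
            return f"{g}|uncharacterized" if g != "uncharacterized" else g
        return f"{g}|{ann.superfamily_or_clade}"

    def family_of(ann):
        c = clade_of(ann)
        if ann is None or not getattr(ann, "family", None):
            return f"{c}|uncharacterized" if not c.endswith("uncharacterized") else c
        return f"{c}|{ann.family}"

    return CompositionSummary(by_group=level_table(group_of),
                              by_clade=level_table(clade_of),
                              by_family=level_table(family_of))


def enrichment_table(records: Sequence[EnrichmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append((r.cluster_id, r.chip_count, r.input_count,
                     "" if r.ratio is None else round(r.ratio, 4),
                     int(r.enriched), int(r.indeterminate)))
    return pd.DataFrame(rows, columns=["cluster_id", "chip_count", "input_count",
                                       "ratio", "enriched", "indeterminate"])
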