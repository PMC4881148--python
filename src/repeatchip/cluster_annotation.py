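"""Per-cluster consensus contigs and hierarchical repeat annotation.

Contigs are built by a deterministic greedy overlap-layout: the pair of
sequences with the longest exact suffix-prefix overlap (strand-aware, at
least ``min_overlap`` bases) is merged repeatedly until no overlap remains.
Contigs only serve as mapping/annotation references, so exactness of the
merge rule is preferred over assembly sophistication.

Annotation assigns each cluster a hierarchical repeat label
(group -> superfamily/clade -> family) by local-alignment similarity of its
contigs to a reference repeat database; each contig's best hit votes with
the number of reads behind the contig, and the label is taken at the
deepest level where a strict majority of voting weight agrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from ._alignment import LocalAligner, revcomp
from .read_clustering import RepeatCluster, SequenceRead

KNOWN_GROUPS = ("satellite", "Ty3-gypsy", "Ty1-copia", "ENV-like", "LINE",
                "SINE", "DNA-transposon", "rDNA", "pararetrovirus", "plastid",
                "telomeric", "unknown")


@dataclass
class Contig:
    """A consensus sequence with the reads that support it."""

    sequence: str
    read_ids: list

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


@dataclass(frozen=True)
class DbRecord:
    id: str
    sequence: str
    group: str
    clade: Optional[str] = None
    family: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.group:
            raise ValueError(f"db record {self.id!r}: empty group label")
        if self.family and not self.clade:
            raise ValueError(f"db record {self.id!r}: family without clade")


@dataclass
class RepeatReferenceDB:
    """Reference repeats with hierarchical labels.

    FASTA header convention: ``>id group|clade|family`` where clade and
    family may be empty.
    """

    records: list

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate db record ids")

    @classmethod
    def from_fasta(cls, path) -> "RepeatReferenceDB":
        from Bio import SeqIO
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            parts = rec.description.split(None, 1)
            if len(parts) < 2:
                raise ValueError(f"db record {rec.id!r}: missing label field")
            labels = (parts[1].split("|") + ["", ""])[:3]
            group, clade, family = (lab.strip() or None for lab in labels)
            records.append(DbRecord(id=rec.id, sequence=str(rec.seq).upper(),
                                    group=group or "", clade=clade, family=family))
        return cls(records=records)


@dataclass(frozen=True)
class RepeatAnnotation:
    group: str
    superfamily_or_clade: Optional[str] = None
    family: Optional[str] = None
    support: float = 1.0
    n_hits: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.support <= 1.0:
            raise ValueError("support must be in (0, 1]")
        if self.family and not self.superfamily_or_clade:
            raise ValueError("family-level annotation requires a clade")


UNKNOWN = RepeatAnnotation(group="unknown", support=1.0, n_hits=0)


# ---------------------------------------------------------------------------
# contig assembly
# ---------------------------------------------------------------------------

def _max_exact_overlap(left: str, right: str, min_overlap: int) -> int:
    """Longest l >= min_overlap with suffix(left, l) == prefix(right, l)."""
    best = 0
    limit = min(len(left), len(right))
    seed = right[:min_overlap]
    if len(seed) < min_overlap:
        return 0
    pos = left.find(seed)
    while pos != -1:
        l = len(left) - pos
        if min_overlap <= l <= limit and left[pos:] == right[:l]:
            best = max(best, l)
        pos = left.find(seed, pos + 1)
    return best


def _best_merge(contigs: Sequence[Contig], min_overlap: int):
    """(overlap, i, j, flip_j) of the longest exact suffix-prefix overlap.

    Orientations tried: i->j, j->i, and each with j reverse-complemented.
    Deterministic tie-break: larger overlap, then smaller (i, j, flip).
    """
    best = None
    for i in range(len(contigs)):
        for j in range(len(contigs)):
            if i == j:
                continue
            a, b = contigs[i].sequence, contigs[j].sequence
            for flip in (False, True):
                bb = revcomp(b) if flip else b
                ov = _max_exact_overlap(a, bb, min_overlap)
                key = (ov, -i, -j, not flip)
                if ov and (best is None or key > best[0]):
                    best = (key, i, j, flip, ov)
    if best is None:
        return None
    _, i, j, flip, ov = best
    return ov, i, j, flip


def build_cluster_contigs(cluster_reads: Sequence[SequenceRead],
                          min_overlap: int = 31) -> list:
    """Greedy exact-overlap assembly of a cluster's reads into contigs.

    Repeatedly merges the pair with the longest exact suffix-prefix overlap
    (strand-aware); merged columns are identical by construction, so the
    consensus is the spliced sequence.  Reads that never merge remain as
    single-read contigs, so the contig set covers every read.
    """
    if len(cluster_reads) < 2:
        raise ValueError("a cluster has at least 2 reads")
    contigs = [Contig(sequence=r.bases, read_ids=[r.id]) for r in cluster_reads]
    while len(contigs) > 1:
        merge = _best_merge(contigs, min_overlap)
        if merge is None:
            break
        ov, i, j, flip = merge
        a, b = contigs[i], contigs[j]
        b_seq = revcomp(b.sequence) if flip else b.sequence
        merged = Contig(sequence=a.sequence + b_seq[ov:],
                        read_ids=a.read_ids + b.read_ids)
        contigs = [c for k, c in enumerate(contigs) if k not in (i, j)]
        contigs.append(merged)
    contigs.sort(key=lambda c: (-len(c.sequence), c.read_ids[0]))
    return contigs


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_ANNOT_ALIGNER = LocalAligner(match=1, mismatch=-2, gap_open=5, gap_extend=1)


def _best_db_hit(contig: Contig, db: RepeatReferenceDB,
                 min_identity: float, min_hit_length: int):
    """Best qualifying database record for one contig, or None.

    Ties are broken by alignment score, then by record id, so permuting the
    database never changes the outcome.
    """
    best = None
    for rec in db.records:
        score, strand = _ANNOT_ALIGNER.best_strand_score(contig.sequence,
                                                         rec.sequence)
        if best is not None and score < best[0]:
            continue
        hit = _ANNOT_ALIGNER.hit(contig.sequence, rec.sequence, strand=strand)
        if hit.identity < min_identity or hit.aligned_length < min_hit_length:
            continue
        if best is None or hit.score > best[0] or \
                (hit.score == best[0] and rec.id < best[1].id):
            best = (hit.score, rec, hit)
    return best


def annotate_cluster(contigs: Sequence[Contig], db: RepeatReferenceDB,
                     min_identity: float = 80.0,
                     min_hit_length: int = 50) -> RepeatAnnotation:
    """Majority-vote hierarchical annotation of a cluster from its contigs.

    Each contig's best database hit votes with weight equal to the number of
    reads in the contig.  The label is assigned at the deepest level (group,
    then clade, then family) where a strict majority (> 50 %) of the voting
    weight agrees; clusters without any qualifying hit are "unknown".
    """
    if not db.records:
        raise ValueError("empty reference database")
    votes = []     # (weight, group, clade, family)
    for contig in contigs:
        hit = _best_db_hit(contig, db, min_identity, min_hit_length)
        if hit is None:
            continue
        _score, rec, _ = hit
        votes.append((contig.n_reads, rec.group, rec.clade, rec.family))
    if not votes:
        return UNKNOWN
    total = sum(w for w, *_ in votes)
    n_hits = len(votes)

    def majority(key_fn):
        tally: dict = {}
        for w, g, c, f in votes:
            key = key_fn(g, c, f)
            if key is not None:
                tally[key] = tally.get(key, 0) + w
        if not tally:
            return None, 0.0
        label, weight = max(tally.items(), key=lambda kv: (kv[1], kv[0]))
        if weight > total / 2:
            return label, weight / total
        return None, 0.0

    group, g_sup = majority(lambda g, c, f: g)
    if group is None:
        return RepeatAnnotation(group="unknown", support=1.0, n_hits=n_hits)
    clade, c_sup = majority(lambda g, c, f: (g, c) if g == group and c else None)
    if clade is None:
        return RepeatAnnotation(group=group, support=g_sup, n_hits=n_hits)
    family, f_sup = majority(
        lambda g, c, f: (g, c, f) if (g, c) == clade and f else None)
    if family is None:
        return RepeatAnnotation(group=group, superfamily_or_clade=clade[1],
                                support=c_sup, n_hits=n_hits)
    return RepeatAnnotation(group=group, superfamily_or_clade=clade[1],
                            family=family[2], support=f_sup, n_hits=n_hits)


def annotate_clusters(clusters: Sequence[RepeatCluster], db: RepeatReferenceDB,
                      min_identity: float = 80.0,
                      min_hit_length: int = 50) -> dict:
    """Annotate every cluster (requires contigs built); returns id -> annotation."""
    out = {}
    for cluster in clusters:
        if not cluster.contigs:
            raise ValueError(f"cluster {cluster.cluster_id} has no contigs")
        ann = annotate_cluster(cluster.contigs, db,
                               min_identity=min_identity,
                               min_hit_length=min_hit_length)
        cluster.annotation = ann
        out[cluster.cluster_id] = ann
    return out


def aggregate_repeat_groups(annotated_clusters: Sequence[RepeatCluster],
                            ) -> pd.DataFrame:
    """Group-level genome proportions summed over annotated clusters."""
    sums: dict = {}
    for cluster in annotated_clusters:
        ann = cluster.annotation
        group = "Unknown" if ann is None or ann.group == "unknown" else ann.group
        sums[group] = sums.get(group, 0.0) + (cluster.genome_proportion or 0.0)
    rows = sorted(sums.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(rows, columns=["group", "genome_proportion_pct"])


def annotation_table(clusters: Sequence[RepeatCluster]) -> pd.DataFrame:
    rows = []
    for c in clusters:
        ann = c.annotation or UNKNOWN
        rows.append((c.cluster_id, ann.group, ann.superfamily_or_clade or "",
                     ann.family or "", round(ann.support, 4), ann.n_hits))
    return pd.DataFrame(rows, columns=["cluster_id", "group", "clade",
                                       "family", "support", "n_hits"])
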