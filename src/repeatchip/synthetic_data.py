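"""Synthetic repeat-rich genomes and read sets with known ground truth.

The generator emulates the repeat landscape of a plant genome at desk scale:
tandem satellite families (contiguous arrays of lightly diverged monomers,
e.g. a 327 bp monomer), dispersed LTR-retrotransposon-like elements sharing
a family consensus, dispersed DNA-transposon-like and plastid-like segments,
and unique single-copy background.  Shotgun paired-end reads, and ChIP/input
single-end read sets whose per-family sampling weights encode known
enrichment factors, are simulated from it so every downstream stage of the
pipeline can be tested against a complete truth table.

The mutation model is substitution-only by default (an indel mode is behind
a flag), reads are error-free by default, and all randomness flows from a
single integer seed per operation, so outputs are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ._alignment import revcomp
from .read_clustering import SequenceRead

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

FAMILY_KINDS = ("satellite", "ltr_retrotransposon", "dna_transposon", "plastid_like")

BACKGROUND = "background"
JUNCTION = "junction"


# ---------------------------------------------------------------------------
# specs and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RepeatFamilySpec:
    """One planted repeat family.

    ``monomer_or_element_length`` is the satellite monomer size for tandem
    families and the full element size for dispersed ones.  ``divergence``
    is the per-base substitution probability applied independently to every
    planted copy relative to the family consensus.
    """

    name: str
    kind: str
    monomer_or_element_length: int
    copies: int
    divergence: float = 0.0
    arrangement: Optional[str] = None   # derived from kind when None

    def __post_init__(self) -> None:
        if self.kind not in FAMILY_KINDS:
            raise ValueError(f"unknown repeat kind {self.kind!r}")
        expected = "tandem" if self.kind == "satellite" else "dispersed"
        if self.arrangement is None:
            object.__setattr__(self, "arrangement", expected)
        elif self.arrangement != expected:
            raise ValueError(
                f"family {self.name!r}: kind {self.kind} requires "
                f"arrangement {expected!r}")
        if self.copies < 1:
            raise ValueError(f"family {self.name!r}: copies must be >= 1")
        if self.monomer_or_element_length < 20:
            raise ValueError(f"family {self.name!r}: unit length must be >= 20 nt")
        if not 0.0 <= self.divergence <= 0.3:
            raise ValueError(f"family {self.name!r}: divergence must be in [0, 0.3]")

    @property
    def total_length(self) -> int:
        return self.monomer_or_element_length * self.copies


@dataclass(frozen=True)
class GenomeSpec:
    families: tuple
    background_length: int
    seed: int

    def __init__(self, families: Sequence[RepeatFamilySpec],
                 background_length: int, seed: int):
        names = [f.name for f in families]
        if len(set(names)) != len(names):
            raise ValueError("duplicate family names")
        if background_length < 0:
            raise ValueError("background_length must be >= 0")
        object.__setattr__(self, "families", tuple(families))
        object.__setattr__(self, "background_length", int(background_length))
        object.__setattr__(self, "seed", int(seed))


@dataclass(frozen=True)
class CopyInterval:
    """One planted copy, 0-based half-open genome coordinates."""

    family: str
    copy_index: int
    start: int
    end: int


@dataclass
class FamilyTruth:
    name: str
    kind: str
    proportion: float            # fraction of genome length
    enrichment_factor: float = 1.0


@dataclass
class GroundTruth:
    """Planted composition of a synthetic genome.

    Per-copy intervals are non-overlapping; adjacent monomer copies of one
    tandem array merge into a single family interval for read labelling.
    """

    genome_length: int
    families: dict                         # name -> FamilyTruth
    intervals: list                        # list[CopyInterval]
    _merged: Optional[tuple] = field(default=None, repr=False)

    def merged_intervals(self) -> tuple:
        """(starts, ends, labels) arrays of merged per-family intervals."""
        if self._merged is None:
            merged: list[tuple[int, int, str]] = []
            for iv in sorted(self.intervals, key=lambda i: i.start):
                if merged and merged[-1][2] == iv.family and merged[-1][1] == iv.start:
                    merged[-1] = (merged[-1][0], iv.end, iv.family)
                else:
                    merged.append((iv.start, iv.end, iv.family))
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            labels = [m[2] for m in merged]
            self._merged = (starts, ends, labels)
        return self._merged

    def family_at(self, position: int) -> str:
        """Family covering a genome position, or "background"."""
        starts, ends, labels = self.merged_intervals()
        idx = int(np.searchsorted(starts, position, side="right")) - 1
        if idx >= 0 and position < ends[idx]:
            return labels[idx]
        return BACKGROUND

    def label_interval(self, start: int, end: int) -> str:
        """Label for a read spanning [start, end).

        Wholly inside one merged family interval -> that family; wholly in
        background -> "background"; anything crossing a boundary ->
        "junction" (excluded from recovery statistics).
        """
        starts, ends, labels = self.merged_intervals()
        idx = int(np.searchsorted(starts, start, side="right")) - 1
        if idx >= 0 and start < ends[idx]:
            return labels[idx] if end <= ends[idx] else JUNCTION
        nxt = idx + 1
        if nxt < len(starts) and end > starts[nxt]:
            return JUNCTION
        return BACKGROUND

    def set_enrichment(self, profile: "ChIPProfile") -> None:
        for name, fam in self.families.items():
            fam.enrichment_factor = profile.factor(name)

    def proportions_sum(self) -> float:
        planted = sum(f.proportion for f in self.families.values())
        repeat_len = sum(iv.end - iv.start for iv in self.intervals)
        background = (self.genome_length - repeat_len) / self.genome_length
        return planted + background


@dataclass
class SyntheticGenome:
    sequence: str
    truth: GroundTruth
    consensi: dict = field(default_factory=dict)   # family -> consensus seq

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ChIPProfile:
    """Per-family enrichment factors; background is fixed at 1.

    With every factor equal to 1 the ChIP read distribution is statistically
    identical to the input control.
    """

    factors: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, f in self.factors.items():
            if f < 0:
                raise ValueError(f"enrichment factor for {name!r} must be >= 0")

    def factor(self, family: str) -> float:
        if family == BACKGROUND:
            return 1.0
        return float(self.factors.get(family, 1.0))


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------

def random_dna(length: int, rng: np.random.Generator) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def mutate(seq: str, divergence: float, rng: np.random.Generator,
           indels: bool = False, indel_rate: float = 0.0) -> str:
    """Substitute bases independently at the given per-base probability.

    The optional indel mode inserts/deletes single bases at ``indel_rate``;
    it is off by default so identity arithmetic stays exact.
    """
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = rng.random(arr.size) < divergence
    n = int(hits.sum())
    if n:
        # Substitute with one of the three other bases, uniformly.
        idx = np.flatnonzero(hits)
        offsets = rng.integers(1, 4, size=n)
        base_idx = np.searchsorted(BASES, arr[idx])
        arr[idx] = BASES[(base_idx + offsets) % 4]
    out = arr.tobytes().decode()
    if indels and indel_rate > 0:
        chars = list(out)
        result = []
        for ch in chars:
            r = rng.random()
            if r < indel_rate / 2:
                continue                        # deletion
            result.append(ch)
            if r >= indel_rate / 2 and r < indel_rate:
                result.append(random_dna(1, rng))   # insertion
        out = "".join(result)
    return out


def build_synthetic_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Assemble a genome by inserting planted repeats into random background.

    Tandem families are emitted as one contiguous array of independently
    mutated monomers; dispersed families as mutated copies inserted at
    random, distinct background positions.  Genome length equals
    background_length plus total planted repeat length by construction, and
    every copy's interval is recorded in the truth table.
    """
    rng = np.random.default_rng(spec.seed)
    background = random_dna(spec.background_length, rng)

    consensi = {f.name: random_dna(f.monomer_or_element_length, rng)
                for f in spec.families}

    # Each segment is (family, copy_indices, sequence) inserted as one block.
    segments: list[tuple[str, list[int], list[str]]] = []
    n_dispersed = 0
    for fam in spec.families:
        if fam.arrangement == "tandem":
            monomers = [mutate(consensi[fam.name], fam.divergence, rng)
                        for _ in range(fam.copies)]
            segments.append((fam.name, list(range(fam.copies)), monomers))
        else:
            n_dispersed += fam.copies
            for c in range(fam.copies):
                copy = mutate(consensi[fam.name], fam.divergence, rng)
                segments.append((fam.name, [c], [copy]))

    slots = spec.background_length + 1
    if n_dispersed + sum(1 for f in spec.families if f.arrangement == "tandem") > slots:
        crowded = max(spec.families, key=lambda f: f.copies)
        raise ValueError(
            f"planted repeats exceed genome capacity: family {crowded.name!r} "
            f"needs more insertion slots than background offers ({slots})")

    points = rng.choice(slots, size=len(segments), replace=False)
    order = np.argsort(points, kind="stable")

    pieces: list[str] = []
    intervals: list[CopyInterval] = []
    cursor = 0      # position in background
    offset = 0      # accumulated inserted length
    for seg_i in order:
        fam_name, copy_idx, parts = segments[seg_i]
        point = int(points[seg_i])
        pieces.append(background[cursor:point])
        offset += point - cursor
        cursor = point
        for ci, part in zip(copy_idx, parts):
            intervals.append(CopyInterval(fam_name, ci, offset, offset + len(part)))
            pieces.append(part)
            offset += len(part)
    pieces.append(background[cursor:])

    sequence = "".join(pieces)
    genome_length = len(sequence)
    assert genome_length == spec.background_length + sum(
        f.total_length for f in spec.families)

    families = {
        f.name: FamilyTruth(f.name, f.kind, f.total_length / genome_length)
        for f in spec.families
    }
    truth = GroundTruth(genome_length=genome_length, families=families,
                        intervals=sorted(intervals, key=lambda i: i.start))
    return SyntheticGenome(sequence=sequence, truth=truth, consensi=consensi)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class PairedReadSet:
    pairs: list     # list[tuple[SequenceRead, SequenceRead]]

    @property
    def reads(self) -> list:
        return [r for pair in self.pairs for r in pair]

    @property
    def mate_tuples(self) -> list:
        return [(a.id, b.id) for a, b in self.pairs]


def _apply_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    return mutate(seq, error_rate, rng)


def simulate_shotgun_pairs(genome: SyntheticGenome, coverage: float,
                           read_length: int, insert_size: int, seed: int,
                           error_rate: float = 0.0) -> PairedReadSet:
    """Uniform paired-end shotgun reads at the requested fold coverage.

    The number of pairs is ``round(coverage * G / (2 * read_length))``;
    fragment starts are uniform, mates sit on opposite strands at the
    fragment ends, and each read records its true family of origin
    (family / background / junction) from the truth intervals.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    G = genome.length
    if not read_length <= insert_size <= G:
        raise ValueError(
            f"need read_length <= insert_size <= genome length "
            f"({read_length} <= {insert_size} <= {G} violated)")
    rng = np.random.default_rng(seed)
    n_pairs = int(round(coverage * G / (2 * read_length)))
    starts = rng.integers(0, G - insert_size + 1, size=n_pairs)
    qual = "I" * read_length
    pairs = []
    for i, s in enumerate(starts):
        s = int(s)
        fwd_seq = genome.sequence[s:s + read_length]
        rev_start = s + insert_size - read_length
        rev_seq = revcomp(genome.sequence[rev_start:rev_start + read_length])
        id1, id2 = f"frag{i:07d}/1", f"frag{i:07d}/2"
        r1 = SequenceRead(id=id1, bases=_apply_errors(fwd_seq, error_rate, rng),
                          quality=qual, mate_id=id2, strand="+",
                          true_family=genome.truth.label_interval(s, s + read_length),
                          origin_start=s)
        r2 = SequenceRead(id=id2, bases=_apply_errors(rev_seq, error_rate, rng),
                          quality=qual, mate_id=id1, strand="-",
                          true_family=genome.truth.label_interval(
                              rev_start, rev_start + read_length),
                          origin_start=rev_start)
        pairs.append((r1, r2))
    return PairedReadSet(pairs=pairs)


def _start_weight_segments(truth: GroundTruth, profile: ChIPProfile,
                           max_start: int) -> tuple:
    """Piecewise-constant weights over valid read start positions.

    A start position is weighted by the enrichment factor of the family
    covering it (background weight 1); segments are clipped to
    [0, max_start].
    """
    starts, ends, labels = truth.merged_intervals()
    seg_bounds: list[tuple[int, int, float, str]] = []
    cursor = 0
    for s, e, lab in zip(starts, ends, labels):
        s, e = int(s), int(e)
        if cursor < s:
            seg_bounds.append((cursor, s, 1.0, BACKGROUND))
        seg_bounds.append((s, e, profile.factor(lab), lab))
        cursor = e
    if cursor < max_start + 1:
        seg_bounds.append((cursor, max_start + 1, 1.0, BACKGROUND))
    clipped = [(s, min(e, max_start + 1), f, lab)
               for s, e, f, lab in seg_bounds if s <= max_start]
    return clipped


def simulate_chip_reads(genome: SyntheticGenome, profile: ChIPProfile,
                        n_reads: int, read_length: int, seed: int,
                        error_rate: float = 0.0,
                        ) -> tuple[list, list]:
    """ChIP and input single-end read sets of exactly ``n_reads`` each.

    Input reads start uniformly over the genome; ChIP read starts are drawn
    with per-position weight equal to the enrichment factor of the family
    covering the position (background weight 1), renormalized.  Under a
    family at genome fraction p with factor f (all else 1) the expected ChIP
    fraction is ``f*p / (f*p + (1-p))``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    G = genome.length
    if read_length > G:
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng(seed)
    max_start = G - read_length
    segments = _start_weight_segments(genome.truth, profile, max_start)
    weights = np.array([(e - s) * f for s, e, f, _ in segments], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all sampling weights are zero")

    def draw(sample_weights: np.ndarray, prefix: str) -> list:
        probs = sample_weights / sample_weights.sum()
        counts = rng.multinomial(n_reads, probs)
        reads = []
        i = 0
        for (s, e, _f, _lab), cnt in zip(segments, counts):
            if cnt == 0:
                continue
            offsets = rng.integers(s, e, size=cnt)
            for off in np.sort(offsets):
                off = int(off)
                seq = genome.sequence[off:off + read_length]
                reads.append(SequenceRead(
                    id=f"{prefix}{i:08d}", bases=_apply_errors(seq, error_rate, rng),
                    quality="I" * read_length, strand="+",
                    true_family=genome.truth.label_interval(off, off + read_length),
                    origin_start=off))
                i += 1
        return reads

    chip = draw(weights, "chip")
    uniform = np.array([e - s for s, e, _f, _lab in segments], dtype=float)
    inp = draw(uniform, "input")
    return chip, inp


def simulate_chip_counts(genome: SyntheticGenome, profile: ChIPProfile,
                         n_reads: int, seed: int, read_length: int = 50,
                         ) -> tuple[dict, dict]:
    """Per-family ChIP and input read counts (fast marginal).

    This is the exact multinomial marginal of ``simulate_chip_reads`` over
    read start positions, with each read attributed to the family covering
    its start; it skips sequence extraction for calibration studies that
    only need counts.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    rng = np.random.default_rng(seed)
    max_start = genome.length - read_length
    segments = _start_weight_segments(genome.truth, profile, max_start)
    labels = sorted({lab for _s, _e, _f, lab in segments})
    lengths = {lab: 0.0 for lab in labels}
    weighted = {lab: 0.0 for lab in labels}
    for s, e, f, lab in segments:
        lengths[lab] += e - s
        weighted[lab] += (e - s) * f
    w = np.array([weighted[lab] for lab in labels])
    u = np.array([lengths[lab] for lab in labels])
    if w.sum() <= 0:
        raise ValueError("all sampling weights are zero")
    chip_counts = rng.multinomial(n_reads, w / w.sum())
    input_counts = rng.multinomial(n_reads, u / u.sum())
    return (dict(zip(labels, chip_counts.tolist())),
            dict(zip(labels, input_counts.tolist())))


def expected_chip_fraction(truth: GroundTruth, profile: ChIPProfile,
                           family: str) -> float:
    """Closed-form expected ChIP read fraction for one family.

    ``f_k p_k / sum_j f_j p_j`` with the background included at factor 1.
    (Edge effects from the last read_length-1 start positions are ignored.)
    """
    total = 0.0
    repeat_fraction = 0.0
    for name, fam in truth.families.items():
        total += profile.factor(name) * fam.proportion
        repeat_fraction += fam.proportion
    total += 1.0 * (1.0 - repeat_fraction)
    return profile.factor(family) * truth.families[family].proportion / total


def expected_enrichment_ratio(truth: GroundTruth, profile: ChIPProfile,
                              family: str) -> float:
    """Expected ChIP/input count ratio for one family: f_k / sum_j f_j p_j."""
    return (expected_chip_fraction(truth, profile, family)
            / truth.families[family].proportion)


# ---------------------------------------------------------------------------
# truth-based recovery evaluation
# ---------------------------------------------------------------------------

def match_clusters_to_truth(clusters: Sequence, reads_by_id: Mapping[str, SequenceRead],
                            ) -> dict:
    """Assign each detected cluster to the planted family of its majority read.

    Junction and background reads are excluded from recovery statistics, so
    the majority is taken over family-labelled reads only.  Returns
    family -> list of clusters whose labelled reads are mostly from it.
    """
    from collections import Counter

    matched: dict[str, list] = {}
    for cluster in clusters:
        votes = Counter()
        for rid in cluster.read_ids:
            fam = reads_by_id[rid].true_family
            if fam not in (None, BACKGROUND, JUNCTION):
                votes[fam] += 1
        if not votes:
            continue
        fam, count = votes.most_common(1)[0]
        if count > sum(votes.values()) / 2:
            matched.setdefault(fam, []).append(cluster)
    return matched


def recovered_proportions(clusters: Sequence, reads: Sequence[SequenceRead],
                          truth: GroundTruth) -> dict:
    """Summed matched-cluster genome proportion (percent) per planted family."""
    reads_by_id = {r.id: r for r in reads}
    matched = match_clusters_to_truth(clusters, reads_by_id)
    out = {}
    for fam in truth.families:
        out[fam] = sum(c.genome_proportion or 0.0 for c in matched.get(fam, []))
    return out
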