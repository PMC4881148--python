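# Methods

This note records the models, parameter choices and numerical conventions
behind `repeatchip`, and what the synthetic studies do and do not
demonstrate.

## Synthetic genomes

A genome is assembled by inserting planted repeats into a uniform-random
single-copy background, so genome length equals background length plus
total planted repeat length by construction, and every copy interval is
known exactly (0-based, half-open). Four repeat archetypes are modelled:

* **satellite** — one contiguous tandem array of `copies` monomers
  (e.g. a 327 bp monomer, the classic centromeric satellite size range);
* **ltr_retrotransposon** — full-length elements dispersed at random
  distinct insertion points, sharing a family consensus;
* **dna_transposon** and **plastid_like** — shorter dispersed segments.

Each planted copy is mutated independently from the family consensus with a
per-base substitution probability (`divergence`, valid range 0–0.3).
Substitution-only mutation keeps identity arithmetic exact, so clustering
thresholds can be tested without confounding; a single-base indel mode
exists behind a flag but is off everywhere. With divergence *d*, the
expected copy-to-consensus identity is exactly `1 − d`, and the expected
copy-to-copy divergence is ≈ `2d(1 − 1/3·…)` ≈ 2*d* for small *d*; at the
default similarity threshold (90 % identity) families up to ~5 % divergence
remain clusterable, matching young plant repeat families.

Shotgun pairs are uniform: `round(coverage·G/(2·read_length))` fragments,
mates at the fragment ends on opposite strands. Reads are error-free by
default (fixed quality `I` = Q40); a uniform error rate is available but
unused, so threshold behavior and noise are tested separately. Every read
records its provenance: the family whose merged interval wholly contains
it, `background`, or `junction` for boundary-spanning reads. Junction reads
are excluded from recovery statistics (they are real reads with ambiguous
truth, not errors).

ChIP/input sampling: input read starts are uniform over valid positions;
ChIP starts are drawn with per-position weight equal to the enrichment
factor of the covering family (background fixed at 1), renormalized. For a
family at genome fraction *p* with factor *f* (all else 1), the expected
ChIP read fraction is `f·p/(f·p + 1 − p)` and the expected ChIP/input count
ratio is `f / Σ_j f_j p_j` (background included at factor 1). With all
factors at 1 the ChIP set is statistically identical to input — the null
used for calibration. `simulate_chip_counts` is the exact multinomial
marginal of this sampling over families (each read attributed to the family
covering its start) and is used for calibration studies where per-read
sequences are irrelevant; its distributional agreement with the full read
simulator is tested.

All randomness flows from a single integer seed per operation
(`numpy.random.default_rng`), making every output byte-reproducible.

## Read clustering

Edges require a strand-aware local alignment at ≥ `min_identity` (90 %)
over ≥ `min_coverage` (0.55) of the shorter read — the documented default
convention of graph-based repeat clustering. Identity is computed over
aligned columns (gaps included) of the best-scoring alignment under a unit
match score (match +1, mismatch −2, gap open 5, extend 1; BLAST gap
convention, length-k gap costs open + k·extend). Two cheap, lossless
filters precede full alignment:

1. **k-mer count prefilter** (default k = 8): a qualifying alignment with C
   columns and e non-matches exposes at least `(C−e) − (e+1)(k−1)` exact
   shared k-mers (pigeonhole over match runs), so pairs sharing fewer
   canonical k-mers than this bound cannot qualify. The bound is minimized
   over the admissible column range per read-length pair. It assumes reads
   are not internally periodic with period < k; all monomers used here are
   ≥ 150 nt.
2. **score bound**: the optimal local score is an upper bound for the score
   of any qualifying alignment, which is at least
   `min_coverage·L_min·(id·match + (1−id)·worst_column_penalty)`.

Clusters are connected components with ≥ 2 reads (networkx), ranked by
descending read count with ties broken by smallest member id. Components
were chosen over community detection deliberately: they are deterministic,
oracle-checkable against single-linkage transitive closure, and the
upstream definition of a cluster is "frequently overlapping reads". A
community-splitting pass would only subdivide components and is out of the
tested surface.

The genome-proportion denominator is the number of post-filter analyzed
reads (clustered + singletons). Both mates enter the graph as independent
reads; mate identity is used only to link clusters afterwards (≥ 5 mate
pairs by default), which flags elements split across clusters (LTRs vs
internal domains, fragmented low-coverage families).

Quality filtering defaults (mean Phred ≥ 20, N-fraction ≤ 5 %) are
package conventions; FASTA reads without qualities pass the quality
criterion and are filtered on N content only.

## Contigs and annotation

Cluster contigs come from a greedy overlap-layout: repeatedly merge the
pair with the longest exact suffix-prefix overlap ≥ `min_overlap` (31 nt),
trying both orientations; exact overlaps make the consensus the spliced
sequence, and unmerged reads stay as single-read contigs so every read is
represented. Contigs are mapping/annotation references, not assemblies of
record; determinism and coverage matter more than contiguity. On diverged
clusters the exact-overlap rule fragments contigs — acceptable because
mapping tolerates redundancy (each read still maps to one cluster).

Annotation: each contig's best database hit (local alignment, both strands,
≥ 80 % identity over ≥ 50 nt) votes with the contig's read count, so
abundance, not contig count, drives the label — mirroring read-count
quantification. The label is assigned at the deepest level (group → clade
→ family) where a strict majority (> 50 %) of total voting weight agrees;
support is that agreeing fraction. Ties are broken by alignment score then
record id, so permuting the database never changes the result. Clusters
with hits but no group-level majority are reported as `unknown` (support
1.0, hits retained) — the same bucket as no-hit clusters; with a curated
database this case is rare and a finer treatment was not warranted.
Translated (protein-domain) searches are intentionally absent.

## ChIP mapping and enrichment

Mapping uses match +2, mismatch −3, gap open 5, gap extend 2, word size 9.
A read/contig pair is aligned only when it shares an exact 9-mer on the
tested strand (the seeding step of word-size-9 search); hits are accepted
at e-value ≤ 1e-12 with
`E = K·m·n·exp(−λS)`, λ solved numerically for the score matrix at uniform
base composition (λ ≈ 0.6337 for +2/−3), K = 0.41 (the tabulated constant
for this scoring), m the read length and n the total contig length, raw
(uncorrected) lengths, both strands searched and the best hit kept. Best
hit = lowest e-value, ties by score, then lowest cluster id; each read maps
to at most one cluster. The e-value parameterization is what makes the
1e-12 cutoff reproducible; the test-suite cross-checks assignments against
an exhaustive Smith–Waterman oracle with an independently solved λ.

Enrichment is the raw count ratio at equal sample depth — no pseudocounts,
no per-sample normalization — because equal `n_sample` makes raw counts
directly comparable and keeps the statistic exactly the published ratio.
`compute_enrichment` refuses unequal totals. Clusters with < 20 mapped
input reads (`min_input`) are flagged indeterminate: below that floor the
ratio's relative error exceeds ~22 % and zero denominators occur; flagged
clusters are reported, never dropped, and never called enriched. The
enrichment call is `ratio ≥ 1.5`, inclusive.

Composition summaries are reported with two denominators, since "normalized
to the overall read amount" is ambiguous between them: `pct_of_enriched`
(ChIP counts over enriched clusters; sums to 100 per hierarchy level; used
in tests) and `pct_of_total` (all reads introduced into the analysis).
Unknown-annotated enriched clusters appear as `uncharacterized`.

## Reporting arithmetic

Megabase conversion is `round_half_up(pct/100 × genome_mb, 2)` in decimal
arithmetic (locale-independent), with deltas computed from the rounded
sides — consistent with how published comparison tables difference their
printed values. Default sizes: 758 Mb estimated genome, 567 Mb assembly.

## Study conditions and problem sizes

The packaged studies are sized so each completes in minutes on one CPU
while keeping estimates statistically meaningful:

* **Clustering oracle**: 20 seeds × 200 reads (one 327 bp satellite, one
  2 kb dispersed element, background), compared against brute-force
  all-pairs single-linkage.
* **Proportion recovery**: 300 kb genome, 1× coverage, 100 nt reads,
  families at ~{10, 5, 2, 0.5} % (327/170/150 bp-monomer satellites and a
  3 kb × 5 LTR element), divergence 0.03, 10 seeds. Repeat units are kept
  large relative to the read length because the read-count estimator
  attributes whole reads to clusters: when an element is only ~2× the read
  length, boundary-spanning reads dominate its clusters and the estimate
  inherits their ambiguity. Kb-scale units are also the biologically
  typical regime (satellite arrays span kilobases; LTR elements are
  multi-kb). Aggregated over seeds, every family is recovered within ±20 %
  relative error with roughly half that to spare.
* **Enrichment calibration**: 50 planted 1 %-families as reference
  clusters, 10⁵ reads per sample, 100 runs, using the count-marginal
  simulator; the alignment mapping path is validated separately against the
  DP oracle (300 reads × 5 contigs).
* **Demo pipeline**: ~50 kb genome, 2× coverage, 2 × 2,000 ChIP/input
  fragments; run twice for byte-identity.

## What the synthetic studies do not show

Simulated reads are error-free, duplication-free, uniformly sampled and
substitution-only diverged; real libraries have quality decay, PCR
duplicates, insert-size spread, indels and biased composition. Passing
recovery and calibration here demonstrates the correctness of the graph
construction, counting, assignment and ratio logic under known truth — not
robustness to real-data noise, which would enter through the quality filter
and alignment tolerances. Cluster counts from real data also depend on
genome size and coverage in ways these desk-scale genomes do not emulate;
no attempt is made to reproduce any published cluster census. Scalability
is bounded by the all-vs-all alignment (quadratic in the repeat read
count); the intended scale is 10³–10⁴ reads per analysis.
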