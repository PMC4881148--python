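"""End-to-end orchestration: simulate -> filter -> cluster -> annotate ->
enrich -> report, driven by a YAML/dict config.

Every stage writes its outputs as TSV/FASTA/FASTQ under the run directory,
and a machine-readable manifest records parameters, seeds and SHA-256
digests of every output file.  No output contains a timestamp, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import sys
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import io as rcio
from . import synthetic_data as sd
from .chip_enrichment import (BlastnScoring, ClusterContig, call_enriched,
                              composition_summary, compute_enrichment,
                              enrichment_table, map_reads_to_clusters,
                              prepare_chip_reads)
from .cluster_annotation import (DbRecord, RepeatReferenceDB, annotate_clusters,
                                 aggregate_repeat_groups, annotation_table,
                                 build_cluster_contigs)
from .read_clustering import (assign_proportions, detect_clusters,
                              link_clusters_by_pairs, membership_table,
                              pairwise_similarities, quality_filter,
                              select_annotatable_clusters)
from .reporting import GenomeSizes, compare_to_assembly, write_manifest

log = logging.getLogger("repeatchip")

KIND_TO_GROUP = {
    "satellite": "satellite",
    "ltr_retrotransposon": "Ty3-gypsy",
    "dna_transposon": "DNA-transposon",
    "plastid_like": "plastid",
}


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return yaml.safe_load(fh)
    return dict(source)


def _family_specs(cfg: Mapping) -> list:
    specs = []
    for fam in cfg["families"]:
        specs.append(sd.RepeatFamilySpec(
            name=fam["name"], kind=fam["kind"],
            monomer_or_element_length=int(fam["length"]),
            copies=int(fam["copies"]),
            divergence=float(fam.get("divergence", 0.0))))
    return specs


def truth_database(genome: sd.SyntheticGenome) -> RepeatReferenceDB:
    """Reference database built from the simulator's family consensi."""
    records = []
    for name, seq in sorted(genome.consensi.items()):
        kind = genome.truth.families[name].kind
        group = KIND_TO_GROUP[kind]
        records.append(DbRecord(id=name, sequence=seq, group=group,
                                clade=f"{name}-like", family=name))
    return RepeatReferenceDB(records=records)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config, outdir: Optional[Path] = None) -> Path:
    """Execute the full pipeline; returns the output directory.

    Any stage failure aborts with the stage name and cause.
    """
    cfg = load_config(config)
    outdir = Path(outdir or cfg.get("outdir", "repeatchip_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    stage = "configure"
    try:
        # --- simulate -----------------------------------------------------
        stage = "simulate"
        sim = cfg["simulate"]
        spec = sd.GenomeSpec(families=_family_specs(sim),
                             background_length=int(sim["background_length"]),
                             seed=seed)
        genome = sd.build_synthetic_genome(spec)
        log.info("simulated genome of %d nt (%d families)",
                 genome.length, len(genome.truth.families))
        profile = sd.ChIPProfile(factors=cfg.get("chip", {}).get("profile", {}))
        genome.truth.set_enrichment(profile)
        rcio.write_fasta(outdir / "genome.fasta", [("genome", genome.sequence)])
        rcio.write_truth_tables(outdir, genome.truth)
        pairs = sd.simulate_shotgun_pairs(
            genome, coverage=float(sim.get("coverage", 1.0)),
            read_length=int(sim.get("read_length", 100)),
            insert_size=int(sim.get("insert_size", 300)),
            seed=seed + 1)
        rcio.write_fastq(outdir / "reads_1.fastq", [p[0] for p in pairs.pairs])
        rcio.write_fastq(outdir / "reads_2.fastq", [p[1] for p in pairs.pairs])

        # --- filter + cluster --------------------------------------------
        stage = "cluster"
        ccfg = cfg.get("cluster", {})
        reads, report = quality_filter(
            pairs.reads,
            min_mean_quality=float(ccfg.get("min_mean_quality", 20.0)),
            max_n_fraction=float(ccfg.get("max_n_fraction", 0.05)))
        log.info("quality filter kept %d/%d reads", report.n_kept, report.n_input)
        edges = pairwise_similarities(
            reads,
            min_identity=float(ccfg.get("min_identity", 90.0)),
            min_coverage=float(ccfg.get("min_coverage", 0.55)),
            kmer_seed_length=int(ccfg.get("kmer_seed_length", 8)))
        clusters, singletons = detect_clusters(edges, [r.id for r in reads])
        assign_proportions(clusters, len(reads))
        selected = select_annotatable_clusters(
            clusters, threshold=float(ccfg.get("proportion_threshold", 0.01)))
        log.info("%d clusters (%d selected), %d singletons",
                 len(clusters), len(selected), len(singletons))
        cluster_df = pd.DataFrame(
            [(c.cluster_id, c.n_reads, round(c.genome_proportion, 6))
             for c in clusters],
            columns=["cluster_id", "n_reads", "proportion_pct"])
        rcio.write_tsv(outdir / "clusters.tsv", cluster_df,
                       params_comment=f"min_identity={ccfg.get('min_identity', 90.0)} "
                                      f"min_coverage={ccfg.get('min_coverage', 0.55)}")
        rcio.write_tsv(outdir / "membership.tsv",
                       membership_table(clusters, singletons))
        links = link_clusters_by_pairs(clusters, pairs.mate_tuples,
                                       min_links=int(ccfg.get("min_links", 5)))
        rcio.write_tsv(outdir / "links.tsv", links)

        # --- contigs + annotation ----------------------------------------
        stage = "annotate"
        acfg = cfg.get("annotate", {})
        reads_by_id = {r.id: r for r in reads}
        contig_records = []
        mapping_contigs = []
        for cluster in selected:
            cluster.contigs = build_cluster_contigs(
                [reads_by_id[rid] for rid in sorted(cluster.read_ids)],
                min_overlap=int(acfg.get("min_overlap", 31)))
            for ci, contig in enumerate(cluster.contigs):
                name = f"CL{cluster.cluster_id}_contig{ci}"
                contig_records.append(
                    (name, f"cluster={cluster.cluster_id} reads={contig.n_reads}",
                     contig.sequence))
                mapping_contigs.append(ClusterContig(
                    cluster_id=cluster.cluster_id, contig_id=name,
                    sequence=contig.sequence))
        rcio.write_fasta(outdir / "contigs.fasta", contig_records)
        db_source = acfg.get("db", "truth")
        db = (truth_database(genome) if db_source == "truth"
              else RepeatReferenceDB.from_fasta(db_source))
        annotations = annotate_clusters(
            selected, db,
            min_identity=float(acfg.get("min_identity", 80.0)),
            min_hit_length=int(acfg.get("min_hit_length", 50)))
        rcio.write_tsv(outdir / "annotations.tsv", annotation_table(selected))
        rcio.write_tsv(outdir / "group_proportions.tsv",
                       aggregate_repeat_groups(selected))

        # --- ChIP enrichment ---------------------------------------------
        stage = "enrich"
        chcfg = cfg.get("chip", {})
        ecfg = cfg.get("enrich", {})
        chip_raw, input_raw = sd.simulate_chip_reads(
            genome, profile, n_reads=int(chcfg.get("n_reads", 2000)),
            read_length=int(chcfg.get("read_length", 138)), seed=seed + 2)
        n_sample = int(chcfg.get("n_sample", min(len(chip_raw), len(input_raw))))
        trim = int(chcfg.get("trim_length", 50))
        chip = prepare_chip_reads(chip_raw, trim_length=trim,
                                  n_sample=n_sample, seed=seed + 3)
        inp = prepare_chip_reads(input_raw, trim_length=trim,
                                 n_sample=n_sample, seed=seed + 4)
        rcio.write_fastq(outdir / "chip.fastq", chip)
        rcio.write_fastq(outdir / "input.fastq", inp)
        scoring = BlastnScoring(
            evalue_cutoff=float(ecfg.get("evalue_cutoff", 1e-12)))
        chip_maps = map_reads_to_clusters(chip, mapping_contigs, scoring=scoring)
        input_maps = map_reads_to_clusters(inp, mapping_contigs, scoring=scoring)
        for name, maps in (("chip_mapping", chip_maps),
                           ("input_mapping", input_maps)):
            df = pd.DataFrame(
                [(m.read_id,
                  "unmapped" if m.cluster_id is None else m.cluster_id,
                  "" if m.e_value is None else f"{m.e_value:.3e}",
                  "" if m.alignment_score is None else m.alignment_score)
                 for m in maps],
                columns=["read_id", "cluster_id", "evalue", "score"])
            rcio.write_tsv(outdir / f"{name}.tsv", df)
        records = compute_enrichment(
            chip_maps, input_maps,
            cluster_ids=[c.cluster_id for c in selected],
            min_input=int(ecfg.get("min_input", 20)))
        call_enriched(records, threshold=float(ecfg.get("threshold", 1.5)))
        rcio.write_tsv(outdir / "enrichment.tsv", enrichment_table(records))
        summary = composition_summary(
            [r for r in records if r.enriched], annotations,
            total_reads_basis=n_sample)
        for level in ("group", "clade", "family"):
            df = getattr(summary, f"by_{level}")
            rcio.write_tsv(outdir / f"composition_{level}.tsv", df)

        # --- report -------------------------------------------------------
        stage = "report"
        sizes_cfg = cfg.get("sizes", {})
        sizes = GenomeSizes(
            estimated_genome_mb=float(sizes_cfg.get("estimated_genome_mb", 758.0)),
            assembly_mb=float(sizes_cfg.get("assembly_mb", 567.0)))
        assembly_table = cfg.get("assembly_table")
        if assembly_table:
            asm = rcio.read_tsv(assembly_table)
            asm_rows = dict(zip(asm.iloc[:, 0], asm.iloc[:, 1]))
            cl_rows = {}
            for cluster in selected:
                ann = cluster.annotation
                label = ann.family or ann.superfamily_or_clade or ann.group
                cl_rows[label] = cl_rows.get(label, 0.0) + cluster.genome_proportion
            comparison = compare_to_assembly(cl_rows, asm_rows, sizes)
            rcio.write_tsv(outdir / "comparison.tsv", comparison)

        # --- manifest ------------------------------------------------------
        digests = {p.name: _sha256(p) for p in sorted(outdir.iterdir())
                   if p.is_file() and p.name != "manifest.json"}
        write_manifest(outdir / "manifest.json", params=cfg, digests=digests)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir


def configure_logging(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")
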