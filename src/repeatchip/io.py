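"""FASTA/FASTQ/TSV readers and writers (Biopython-backed)."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .read_clustering import SequenceRead


def read_reads(path) -> list:
    """Load reads from FASTA or FASTQ (format chosen by extension)."""
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
    reads = []
    for rec in SeqIO.parse(str(path), fmt):
        qual = None
        if fmt == "fastq":
            qual = "".join(chr(q + 33) for q in
                           rec.letter_annotations["phred_quality"])
        reads.append(SequenceRead(id=rec.id, bases=str(rec.seq).upper(),
                                  quality=qual))
    return reads


def write_fasta(path, records: Iterable[tuple]) -> None:
    """Write (id, sequence) or (id, description, sequence) tuples."""
    with open(path, "w") as fh:
        for rec in records:
            if len(rec) == 3:
                name, desc, seq = rec
                fh.write(f">{name} {desc}\n")
            else:
                name, seq = rec
                fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq(path, reads: Sequence[SequenceRead]) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = read.quality or "I" * len(read.bases)
            fh.write(f"@{read.id}\n{read.bases}\n+\n{qual}\n")


def write_tsv(path, df: pd.DataFrame, params_comment: str | None = None) -> None:
    """TSV with a header line and an optional leading parameter comment."""
    with open(path, "w") as fh:
        if params_comment:
            fh.write(f"# {params_comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_truth_tables(outdir, truth, prefix: str = "truth") -> None:
    """Family table (proportions, enrichment factors) and copy-interval BED."""
    outdir = Path(outdir)
    fam_rows = [(f.name, f.kind, f.proportion, f.enrichment_factor)
                for f in truth.families.values()]
    write_tsv(outdir / f"{prefix}_families.tsv",
              pd.DataFrame(fam_rows, columns=["family", "kind", "proportion",
                                              "enrichment_factor"]))
    bed_rows = [("genome", iv.start, iv.end, f"{iv.family}:{iv.copy_index}")
                for iv in truth.intervals]
    write_tsv(outdir / f"{prefix}_intervals.bed.tsv",
              pd.DataFrame(bed_rows, columns=["chrom", "start", "end", "name"]))
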