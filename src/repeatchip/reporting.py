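"""Physical-size conversion and cluster-vs-assembly comparison tables.

Genome proportions estimated from read counts are converted to megabases
against the estimated genome size (758 Mb for the sugar beet genome), while
assembly-based annotations are converted against the assembled size
(567 Mb).  Rounding is decimal half-up to 2 places BEFORE differencing, so
printed deltas equal the difference of the printed sizes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping

import pandas as pd


@dataclass(frozen=True)
class GenomeSizes:
    estimated_genome_mb: float = 758.0
    assembly_mb: float = 567.0

    def __post_init__(self) -> None:
        if self.estimated_genome_mb <= 0 or self.assembly_mb <= 0:
            raise ValueError("genome sizes must be positive")


def proportion_to_megabases(pct: float, genome_mb: float) -> float:
    """pct/100 * genome_mb, rounded half-up to 2 decimals.

    Uses decimal arithmetic so results are exact and locale-independent.
    """
    if pct < 0:
        raise ValueError("genome proportion must be >= 0")
    if genome_mb <= 0:
        raise ValueError("genome size must be > 0")
    mb = Decimal(str(pct)) * Decimal(str(genome_mb)) / Decimal(100)
    return float(mb.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def compare_to_assembly(cluster_rows: Mapping[str, float],
                        assembly_rows: Mapping[str, float],
                        sizes: GenomeSizes = GenomeSizes()) -> pd.DataFrame:
    """Side-by-side repeat contents: clustering estimate vs assembly.

    Inputs map repeat label -> genome proportion (percent) on each side.
    Labels match case-insensitively; a repeat absent from one side carries
    0.00 there.  Duplicate labels within one side raise.
    """
    def fold(rows: Mapping[str, float], side: str) -> dict:
        folded: dict = {}
        for label, pct in rows.items():
            key = label.strip().lower()
            if key in folded:
                raise ValueError(f"duplicate repeat label {label!r} in {side} table")
            folded[key] = (label.strip(), float(pct))
        return folded

    cluster = fold(cluster_rows, "cluster")
    assembly = fold(assembly_rows, "assembly")
    order = list(cluster) + [k for k in assembly if k not in cluster]
    rows = []
    for key in order:
        label = (cluster.get(key) or assembly.get(key))[0]
        c_pct = cluster.get(key, (None, 0.0))[1]
        a_pct = assembly.get(key, (None, 0.0))[1]
        c_mb = proportion_to_megabases(c_pct, sizes.estimated_genome_mb)
        a_mb = proportion_to_megabases(a_pct, sizes.assembly_mb)
        delta = float(Decimal(str(c_mb)) - Decimal(str(a_mb)))
        rows.append((label, a_pct, a_mb, c_pct, c_mb, delta))
    return pd.DataFrame(rows, columns=["repeat", "assembly_pct", "assembly_mb",
                                       "cluster_pct", "cluster_mb", "delta_mb"])


def comparison_round_trip(df: pd.DataFrame) -> bool:
    """Recompute delta_mb from the table's own rounded sizes; True if exact."""
    for _, row in df.iterrows():
        delta = float(Decimal(str(row.cluster_mb)) - Decimal(str(row.assembly_mb)))
        if abs(delta - row.delta_mb) > 1e-9:
            return False
    return True


def write_manifest(path, params: Mapping, digests: Mapping) -> None:
    """Machine-readable run manifest (parameters, seeds, output digests).

    Deliberately contains no timestamps so reruns are byte-identical.
    """
    import repeatchip
    payload = {
        "package": "repeatchip",
        "version": repeatchip.__version__,
        "parameters": dict(params),
        "output_sha256": dict(sorted(digests.items())),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
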