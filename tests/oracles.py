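"""Independent oracles used by the test-suite and the acceptance script.

These deliberately share no algorithmic code with the package:

* ``UnionFind`` — a hand-rolled disjoint-set structure for single-linkage
  transitive closure over brute-force all-pairs alignments;
* ``sw_score`` — an exhaustive affine-gap Smith-Waterman dynamic program
  (numba-compiled) with the BLASTN-like gap convention (a gap of length k
  costs open + extend*k);
* ``oracle_best_hits`` — best-hit read assignment recomputed from the DP
  scores with its own Karlin-Altschul e-value (lambda solved by bisection).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb

    def groups(self):
        out = {}
        for x in self.parent:
            out.setdefault(self.find(x), set()).add(x)
        return list(out.values())


def single_linkage_partition(read_ids, linked_pairs):
    """Partition {read_ids} as frozensets: components of >=2, plus singletons."""
    uf = UnionFind(read_ids)
    for a, b in linked_pairs:
        uf.union(a, b)
    clusters = sorted((frozenset(g) for g in uf.groups() if len(g) >= 2),
                      key=lambda c: (-len(c), min(c)))
    singletons = {x for g in uf.groups() if len(g) == 1 for x in g}
    return clusters, singletons


_ENC = np.full(256, 4, dtype=np.int8)
for i, base in enumerate(b"ACGT"):
    _ENC[base] = i


def encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode(), dtype=np.uint8)]


@njit(cache=True)
def _sw(a, b, match, mismatch, gap_open, gap_extend):
    n, m = a.shape[0], b.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), -10**9, dtype=np.int64)   # gap in a (left)
    F = np.full((n + 1, m + 1), -10**9, dtype=np.int64)   # gap in b (up)
    best = 0
    first_gap = gap_open + gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(E[i, j - 1] - gap_extend, H[i, j - 1] - first_gap)
            F[i, j] = max(F[i - 1, j] - gap_extend, H[i - 1, j] - first_gap)
            s = match if (a[i - 1] == b[j - 1] and a[i - 1] < 4) else mismatch
            h = H[i - 1, j - 1] + s
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


def sw_score(a: str, b: str, match=2, mismatch=-3, gap_open=5, gap_extend=2) -> int:
    """Optimal local alignment score, exhaustive DP."""
    return int(_sw(encode(a), encode(b), match, mismatch, gap_open, gap_extend))


def _revcomp(seq: str) -> str:
    return seq[::-1].translate(str.maketrans("ACGTN", "TGCAN"))


def oracle_lambda(match: int, mismatch: int) -> float:
    """Karlin-Altschul lambda by plain bisection at uniform composition."""
    lo, hi = 1e-9, 10.0
    for _ in range(200):
        mid = (lo + hi) / 2
        val = 0.25 * math.exp(mid * match) + 0.75 * math.exp(mid * mismatch)
        if val < 1.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def oracle_evalue(score: float, query_len: int, db_len: int,
                  match=2, mismatch=-3, K=0.41) -> float:
    return K * query_len * db_len * math.exp(-oracle_lambda(match, mismatch) * score)


def oracle_best_hits(reads, contigs, match=2, mismatch=-3, gap_open=5,
                     gap_extend=2, evalue_cutoff=1e-12):
    """read_id -> cluster_id (or None) by exhaustive SW over every contig
    and strand; best hit = lowest e-value, ties by score then cluster_id."""
    db_len = sum(len(c.sequence) for c in contigs)
    out = {}
    for read in reads:
        best = None      # (evalue, -score, cluster_id)
        for contig in contigs:
            for query in (read.bases, _revcomp(read.bases)):
                score = sw_score(contig.sequence, query, match, mismatch,
                                 gap_open, gap_extend)
                ev = oracle_evalue(score, len(read.bases), db_len,
                                   match, mismatch)
                if ev > evalue_cutoff:
                    continue
                key = (ev, -score, contig.cluster_id)
                if best is None or key < best:
                    best = key
        out[read.id] = None if best is None else best[2]
    return out
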