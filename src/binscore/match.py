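"""Best-hit identification of cluster representatives against the reference DB.

Emulates a megablast "hit table, maximum hits 1" search: a k-mer
seeded candidate search narrows the database, each candidate is aligned with
the exact dynamic program, and the single best hit (BIN, percent identity) is
returned. The heuristic only selects candidates — the identity reported for
the winner is exact — so on any database where seeding finds the true best
reference, the result equals an exhaustive all-references search.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import alignment
from .refdb import ReferenceDB
from .seq import revcomp

HIT_COLUMNS = [
    "query_id",
    "sample",
    "amplicon",
    "coverage",
    "bin_id",
    "process_id",
    "identity_pct",
    "alignment_length",
    "ambiguous",
]


@dataclass(frozen=True)
class HitResult:
    """Single best reference hit for a query sequence."""

    query_id: str
    bin_id: str
    process_id: str
    identity_pct: float
    alignment_length: int
    strand: str = "+"
    ambiguous: bool = False


class KmerIndex:
    """Exact k-mer postings over the reference database (seeding stage)."""

    def __init__(self, db: ReferenceDB, k: int = 11):
        if k < 8:
            raise ValueError("k must be >= 8 for useful seeding")
        self.k = k
        self.db = db
        self.postings: dict[str, list[tuple[int, int]]] = {}
        self.encoded: list[np.ndarray] = []
        for ridx, rec in enumerate(db):
            self.encoded.append(alignment.encode(rec.sequence))
            s = rec.sequence
            for off in range(len(s) - k + 1):
                kmer = s[off : off + k]
                if "N" in kmer:
                    continue
                self.postings.setdefault(kmer, []).append((ridx, off))

    def n_postings(self) -> int:
        return sum(len(v) for v in self.postings.values())

    def candidates(self, seq: str, min_seed_hits: int) -> list[int]:
        """Record indices sharing >= min_seed_hits k-mer postings with seq."""
        counts: Counter[int] = Counter()
        k = self.k
        for off in range(len(seq) - k + 1):
            kmer = seq[off : off + k]
            if "N" in kmer:
                continue
            for ridx, _ in self.postings.get(kmer, ()):
                counts[ridx] += 1
        return [ridx for ridx, c in counts.items() if c >= min_seed_hits]


def build_kmer_index(db: ReferenceDB, k: int = 11) -> KmerIndex:
    return KmerIndex(db, k=k)


def pairwise_identity(a: str, b: str) -> tuple[float, int]:
    """Global-alignment percent identity of two sequences.

    Returns ``(identity_pct, alignment_length)`` where identity is
    100 x identical columns / alignment columns (gap columns included),
    rounded to two decimals. N is always a mismatch.

    The optimal score is unique but the optimal alignment need not be; the
    reported alignment is computed with the lexicographically smaller
    sequence first, which makes the result invariant to argument order.
    """
    if b < a:
        a, b = b, a
    res = alignment.align_global(alignment.encode(a), alignment.encode(b))
    return res.identity_pct, res.columns


def best_hit(
    query_id: str,
    query_seq: str,
    db: ReferenceDB,
    index: KmerIndex,
    min_seed_hits: int = 2,
    min_identity: float = 80.0,
) -> HitResult | None:
    """Single best reference hit for a query, or None.

    Both strands of the query are seeded and aligned; each candidate is
    aligned semi-globally (reference end gaps free) so short amplicon queries
    are scored over their aligned span. Ties are broken by longer alignment,
    then lexicographic process_id; a tie in identity across different BINs
    is flagged ambiguous. Hits below ``min_identity`` (a hard floor bounding
    nonsense hits, far below the scoring bands) are suppressed.
    """
    results: list[tuple[float, int, object, str]] = []
    for strand, seq in (("+", query_seq), ("-", revcomp(query_seq))):
        cand = index.candidates(seq, min_seed_hits)
        if not cand:
            continue
        q = alignment.encode(seq)
        for ridx in cand:
            rec = db.records[ridx]
            res = alignment.align_glocal(q, index.encoded[ridx])
            results.append((res.identity_pct, res.columns, rec, strand))

    if not results:
        return None
    results.sort(key=lambda t: (-t[0], -t[1], t[2].process_id))
    ident, aln_len, rec, strand = results[0]
    if ident < min_identity:
        return None
    ambiguous = any(
        r[0] == ident and r[2].bin_id != rec.bin_id for r in results[1:]
    )
    return HitResult(
        query_id=query_id,
        bin_id=rec.bin_id,
        process_id=rec.process_id,
        identity_pct=ident,
        alignment_length=aln_len,
        strand=strand,
        ambiguous=ambiguous,
    )


def align_sample(
    clusters,
    db: ReferenceDB,
    index: KmerIndex | None = None,
    min_seed_hits: int = 2,
    min_identity: float = 80.0,
) -> pd.DataFrame:
    """Hit table for a collection of clusters (one row per cluster).

    Clusters with no acceptable hit are listed with empty hit fields, so the
    table is a complete census of the queries.
    """
    if index is None:
        index = build_kmer_index(db)
    rows = []
    for cl in clusters:
        hit = best_hit(
            cl.cluster_id,
            cl.representative,
            db,
            index,
            min_seed_hits=min_seed_hits,
            min_identity=min_identity,
        )
        rows.append(
            {
                "query_id": cl.cluster_id,
                "sample": cl.sample,
                "amplicon": cl.amplicon,
                "coverage": cl.coverage,
                "bin_id": hit.bin_id if hit else "",
                "process_id": hit.process_id if hit else "",
                "identity_pct": hit.identity_pct if hit else np.nan,
                "alignment_length": hit.alignment_length if hit else 0,
                "ambiguous": hit.ambiguous if hit else False,
            }
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
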