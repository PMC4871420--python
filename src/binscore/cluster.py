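"""Greedy identity clustering of processed sequences at 98% identity.

The clustering unit is one (sample, amplicon) pool. Sequences are first
dereplicated and ranked by abundance, then scanned greedily: each unique
joins the first existing cluster whose representative it matches at or above
the identity threshold, otherwise it seeds a new cluster. Because the scan is
abundance-ordered, the representative of every cluster is its most abundant
member by construction, and the whole procedure is permutation-stable.
Clusters below the coverage threshold (default 10 reads) are discarded
downstream.

Identity is the same alignment-column identity used for reference matching.
A CD-HIT-style word filter screens candidate pairs before the dynamic
program: an alignment of identity >= t spanning >= L columns must share at
least t*L - (k-1)*((1-t)*L + 1) k-mers (every non-match column destroys at
most k words, and the match columns fall in at most e+1 runs), so a pair
sharing fewer words is provably below threshold and skips the alignment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import alignment

_FILTER_K = 8


@dataclass
class Cluster:
    cluster_id: str
    representative: str
    coverage: int
    sample: str = ""
    amplicon: str = ""
    member_ids: list[str] = field(default_factory=list)


def dereplicate(seqs) -> list[tuple[str, int]]:
    """Unique sequences with abundances, most abundant first.

    Ties are broken by longer sequence, then lexicographically, making the
    ordering (and therefore the greedy clustering) deterministic for any
    permutation of the input.
    """
    counts = Counter(seqs)
    return sorted(counts.items(), key=lambda kv: (-kv[1], -len(kv[0]), kv[0]))


def _kmer_profile(seq: str, k: int = _FILTER_K) -> Counter:
    # N-containing words are kept: clustering scores N by letter equality,
    # so match runs may contain N and the word bound must see their words
    c: Counter[str] = Counter()
    for i in range(len(seq) - k + 1):
        c[seq[i : i + k]] += 1
    return c


def _shared_words(ca: Counter, cb: Counter) -> int:
    if len(cb) < len(ca):
        ca, cb = cb, ca
    return sum(min(n, cb[km]) for km, n in ca.items())


def _word_filter_passes(
    ca: Counter, cb: Counter, la: int, lb: int, threshold_pct: float
) -> bool:
    """False only when the shared-word count proves identity < threshold."""
    t = threshold_pct / 100.0
    lmax = max(la, lb)
    k = _FILTER_K
    bound = t * lmax - (k - 1) * ((1.0 - t) * lmax + 1.0)
    if bound <= 0:
        return True
    return _shared_words(ca, cb) >= bound - 1.0  # one-word safety cushion


def _identity(a: str, b: str, threshold_pct: float, pa=None, pb=None) -> float:
    if a == b:
        return 100.0
    la, lb = len(a), len(b)
    # identity can never exceed min/max length ratio: matches <= min, columns >= max
    if 100.0 * min(la, lb) / max(la, lb) < threshold_pct:
        return 0.0
    if pa is not None and pb is not None and not _word_filter_passes(
        pa, pb, la, lb, threshold_pct
    ):
        return 0.0
    # letter-equality identity (N matches N): N-padded fragments of one
    # template must cluster together, exactly as CD-HIT treats letters;
    # canonical orientation keeps the result order-invariant
    if b < a:
        a, b = b, a
    res = alignment.align_global(
        alignment.encode(a), alignment.encode(b), nn_match=True
    )
    return res.identity_pct


def greedy_cluster(
    uniques: list[tuple[str, int]],
    threshold: float = 0.98,
    sample: str = "",
    amplicon: str = "",
) -> list[Cluster]:
    """CD-HIT-EST-style greedy clustering of abundance-ordered uniques.

    Each unique joins the first cluster whose representative it matches at
    >= ``threshold`` identity (fraction in (0, 1]); otherwise it seeds a new
    cluster with itself as representative. Coverage is the sum of member
    abundances.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"identity threshold must be in (0, 1], got {threshold}")
    thr_pct = 100.0 * threshold
    clusters: list[Cluster] = []
    profiles: list[Counter] = []
    for seq, abundance in uniques:
        pseq = _kmer_profile(seq)
        for cl, prof in zip(clusters, profiles):
            if _identity(seq, cl.representative, thr_pct, pseq, prof) >= thr_pct:
                cl.coverage += abundance
                cl.member_ids.append(seq)
                break
        else:
            clusters.append(
                Cluster(
                    cluster_id=f"cluster_{len(clusters)}",
                    representative=seq,
                    coverage=abundance,
                    sample=sample,
                    amplicon=amplicon,
                    member_ids=[seq],
                )
            )
            profiles.append(pseq)
    return clusters


def cluster_pool(
    processed,
    threshold: float = 0.98,
    sample: str = "",
    amplicon: str = "",
) -> list[Cluster]:
    """Dereplicate and cluster one (sample, amplicon) pool of fragments.

    ``processed`` is an iterable of ProcessedSequence or raw strings; read
    ids, where available, are recorded on the clusters they fall into.
    """
    items = [
        (p, "") if isinstance(p, str) else (p.sequence, p.id) for p in processed
    ]
    uniques = dereplicate(s for s, _ in items)
    clusters = greedy_cluster(uniques, threshold, sample=sample, amplicon=amplicon)
    if any(rid for _, rid in items):
        by_seq = {}
        for cl in clusters:
            for member_seq in cl.member_ids:
                by_seq[member_seq] = cl
        for cl in clusters:
            cl.member_ids = []
        for s, rid in items:
            by_seq[s].member_ids.append(rid)
    return clusters


def filter_coverage(clusters: list[Cluster], min_coverage: int = 10) -> list[Cluster]:
    """Keep clusters with coverage >= min_coverage (inclusive)."""
    return [c for c in clusters if c.coverage >= min_coverage]
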