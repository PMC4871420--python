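"""End-to-end driver: reads -> fragments -> clusters -> hits -> BIN scores."""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import cluster as cluster_mod
from . import match as match_mod
from . import score as score_mod
from .preprocess import PreprocessCounts, SampleManifest, preprocess_pairs
from .refdb import ReferenceDB


@dataclass
class PipelineResult:
    counts: PreprocessCounts
    clusters: dict[tuple[str, str], list]  # (sample, amplicon) -> kept clusters
    n_clusters_dropped: int
    hits: pd.DataFrame
    cards: dict[str, list]  # sample -> list[BinScoreCard]
    cards_frame: pd.DataFrame = field(default_factory=pd.DataFrame)


def run_pipeline(
    pairs_by_amplicon: dict[str, list],
    manifest: SampleManifest,
    db: ReferenceDB,
    identity_threshold: float = 0.98,
    min_coverage: int = 10,
    matrix: score_mod.ScoringMatrix = score_mod.DEFAULT_MATRIX,
    max_primer_mismatches: int = 2,
) -> PipelineResult:
    """Run the full identification pipeline on per-amplicon read pair pools.

    Steps: demultiplex on inline barcodes, validate/orient primers, merge or
    N-join the pairs, cluster each (sample, amplicon) pool at the identity
    threshold, drop clusters under the coverage floor, find each
    representative's best reference hit, reduce hits to the best identity per
    BIN and amplicon, and sum the band scores into per-sample score cards.
    """
    total_counts = PreprocessCounts()
    pools: dict[tuple[str, str], list] = {}
    for amp_name, pairs in pairs_by_amplicon.items():
        out, counts = preprocess_pairs(
            pairs, manifest, max_mismatches=max_primer_mismatches
        )
        total_counts.total += counts.total
        total_counts.unassigned += counts.unassigned
        total_counts.rejected_primer += counts.rejected_primer
        total_counts.rejected_merge += counts.rejected_merge
        total_counts.merged += counts.merged
        total_counts.njoined += counts.njoined
        for amp, sub in counts.per_amplicon.items():
            acc = total_counts.per_amplicon.setdefault(amp, {"merged": 0, "njoined": 0})
            acc["merged"] += sub["merged"]
            acc["njoined"] += sub["njoined"]
        for key, seqs in out.items():
            pools.setdefault(key, []).extend(seqs)

    kept: dict[tuple[str, str], list] = {}
    dropped = 0
    for (sample, amp), seqs in sorted(pools.items()):
        cls = cluster_mod.cluster_pool(
            seqs, threshold=identity_threshold, sample=sample, amplicon=amp
        )
        flt = cluster_mod.filter_coverage(cls, min_coverage)
        dropped += len(cls) - len(flt)
        for i, cl in enumerate(flt):
            cl.cluster_id = f"{sample}:{amp}:cluster_{i}"
        kept[(sample, amp)] = flt

    index = match_mod.build_kmer_index(db)
    all_clusters = [cl for _, cls in sorted(kept.items()) for cl in cls]
    hits = match_mod.align_sample(all_clusters, db, index)

    cards: dict[str, list] = {}
    for sample in sorted(hits["sample"].unique()) if not hits.empty else []:
        sample_hits = hits[hits["sample"] == sample]
        per_amplicon = {
            amp: score_mod.best_identity_per_bin(grp)
            for amp, grp in sample_hits.groupby("amplicon")
        }
        cards[sample] = score_mod.aggregate_bin_scores(
            per_amplicon, matrix, sample=sample
        )

    amp_names = [a.name for a in manifest.amplicons]
    frames = [
        score_mod.cards_to_frame(c, amp_names, db.bin_taxonomy())
        for c in cards.values()
        if c
    ]
    cards_frame = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    return PipelineResult(
        counts=total_counts,
        clusters=kept,
        n_clusters_dropped=dropped,
        hits=hits,
        cards=cards,
        cards_frame=cards_frame,
    )
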