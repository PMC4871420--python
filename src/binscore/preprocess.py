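"""Raw paired amplicon reads -> oriented, primer-trimmed, per-sample sequences.

The steps mirror a standard inline-barcoded amplicon workflow: sort read pairs
on the 8-base sample barcode that precedes the primer, clip remnant sequencing
adapters, require a valid forward/reverse primer combination (sequencing
direction is random, so pairs are re-oriented Fwd->Rev), then either merge the
mates over their overlap or, for amplicons too long for the mates to overlap,
join them with a run of Ns padding the fragment to its expected length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .seq import base_matches, revcomp

#: merged-fragment length at and above which mates cannot overlap on a
#: standard paired run and are N-joined instead of overlap-merged
NJOIN_LENGTH_CUTOFF = 570

BARCODE_LENGTH = 8


@dataclass(frozen=True)
class AmpliconSpec:
    """A named amplicon: degenerate primers and expected merged length."""

    name: str
    fwd_primer: str
    rev_primer: str
    expected_length: int

    def __post_init__(self):
        if not self.fwd_primer or not self.rev_primer:
            raise ValueError(f"amplicon {self.name}: primers must be non-empty")
        if self.expected_length <= len(self.fwd_primer) + len(self.rev_primer):
            raise ValueError(
                f"amplicon {self.name}: expected_length must exceed total primer length"
            )

    @property
    def merge_policy(self) -> str:
        return "njoin" if self.expected_length >= NJOIN_LENGTH_CUTOFF else "overlap"


@dataclass
class SampleManifest:
    """Barcode -> sample mapping plus the amplicon panel of the run."""

    barcodes: dict[str, str]  # 8-base barcode -> sample name
    amplicons: list[AmpliconSpec]

    def __post_init__(self):
        for bc in self.barcodes:
            if len(bc) != BARCODE_LENGTH or set(bc) - set("ACGT"):
                raise ValueError(f"invalid barcode {bc!r}: need 8 bases over ACGT")

    def amplicon(self, name: str) -> AmpliconSpec:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SampleManifest":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        amps = [
            AmpliconSpec(
                name=a["name"],
                fwd_primer=a["fwd_primer"].upper(),
                rev_primer=a["rev_primer"].upper(),
                expected_length=int(a["expected_length"]),
            )
            for a in doc["amplicons"]
        ]
        return cls(barcodes={k.upper(): v for k, v in doc["barcodes"].items()}, amplicons=amps)

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "barcodes": dict(self.barcodes),
            "amplicons": [
                {
                    "name": a.name,
                    "fwd_primer": a.fwd_primer,
                    "rev_primer": a.rev_primer,
                    "expected_length": a.expected_length,
                }
                for a in self.amplicons
            ],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass(frozen=True)
class ReadPair:
    id: str
    fwd_seq: str
    rev_seq: str
    fwd_qual: str
    rev_qual: str

    def __post_init__(self):
        if len(self.fwd_seq) != len(self.fwd_qual) or len(self.rev_seq) != len(
            self.rev_qual
        ):
            raise ValueError(f"read {self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class ProcessedSequence:
    """A merged, primer- and barcode-free fragment in Fwd->Rev orientation."""

    id: str
    sample: str
    amplicon: str
    sequence: str
    quality: str = ""
    joined_with_ns: bool = False


def demultiplex(pair: ReadPair, manifest: SampleManifest):
    """Assign a pair to a sample by exact match of the forward 8-base prefix.

    Returns ``(sample, trimmed_pair)`` or ``None`` for unassigned pairs.
    The barcode is removed from the forward mate, and from the reverse mate
    too when present there (both primers carry the tag in this design).
    """
    bc = pair.fwd_seq[:BARCODE_LENGTH]
    sample = manifest.barcodes.get(bc)
    if sample is None:
        return None
    fwd_seq = pair.fwd_seq[BARCODE_LENGTH:]
    fwd_qual = pair.fwd_qual[BARCODE_LENGTH:]
    rev_seq, rev_qual = pair.rev_seq, pair.rev_qual
    # Sample assignment is exact, but stripping the now-known tag from the
    # other mate tolerates sequencing errors in it (<= 2 mismatches).
    rb = rev_seq[:BARCODE_LENGTH]
    if rb in manifest.barcodes or sum(1 for x, y in zip(rb, bc) if x != y) <= 2:
        rev_seq = rev_seq[BARCODE_LENGTH:]
        rev_qual = rev_qual[BARCODE_LENGTH:]
    return sample, replace(
        pair, fwd_seq=fwd_seq, fwd_qual=fwd_qual, rev_seq=rev_seq, rev_qual=rev_qual
    )


def clip_adapter(
    seq: str, qual: str, adapter: str, min_overlap: int = 5
) -> tuple[str, str]:
    """Remove a remnant adapter prefix found at the 3' end of a read.

    The longest suffix of ``seq`` matching a prefix of ``adapter`` over at
    least ``min_overlap`` bases with at most 10% mismatches is clipped.
    """
    if min_overlap < 5:
        raise ValueError("min_overlap must be >= 5")
    max_l = min(len(seq), len(adapter))
    for length in range(max_l, min_overlap - 1, -1):
        suffix = seq[-length:]
        prefix = adapter[:length]
        mism = sum(1 for x, y in zip(suffix, prefix) if x != y)
        if mism <= 0.1 * length:
            return seq[:-length], qual[:-length]
    return seq, qual


def match_primer(seq: str, primer: str, max_mismatches: int = 2) -> int | None:
    """Leftmost position where the degenerate primer aligns ungapped with at
    most ``max_mismatches`` mismatches; N in the read never matches."""
    lp = len(primer)
    for pos in range(len(seq) - lp + 1):
        mism = 0
        for rb, pc in zip(seq[pos : pos + lp], primer):
            if not base_matches(rb, pc):
                mism += 1
                if mism > max_mismatches:
                    break
        else:
            return pos
    return None


def _primer_at_start(seq: str, primer: str, max_mismatches: int) -> bool:
    if len(seq) < len(primer):
        return False
    mism = sum(
        1 for rb, pc in zip(seq[: len(primer)], primer) if not base_matches(rb, pc)
    )
    return mism <= max_mismatches


def orient_and_trim(
    pair: ReadPair, spec: AmpliconSpec, max_mismatches: int = 2
) -> ReadPair | None:
    """Validate the primer combination and orient the pair Fwd->Rev.

    Accepts the pair iff one mate starts with the forward primer and the
    other with the reverse primer (each within ``max_mismatches``); mates are
    swapped if needed so mate 1 carries the forward primer, then both primers
    are trimmed. Returns None on rejection.
    """
    f, r = spec.fwd_primer, spec.rev_primer
    if _primer_at_start(pair.fwd_seq, f, max_mismatches) and _primer_at_start(
        pair.rev_seq, r, max_mismatches
    ):
        ordered = pair
    elif _primer_at_start(pair.fwd_seq, r, max_mismatches) and _primer_at_start(
        pair.rev_seq, f, max_mismatches
    ):
        ordered = replace(
            pair,
            fwd_seq=pair.rev_seq,
            fwd_qual=pair.rev_qual,
            rev_seq=pair.fwd_seq,
            rev_qual=pair.fwd_qual,
        )
    else:
        return None
    return replace(
        ordered,
        fwd_seq=ordered.fwd_seq[len(f) :],
        fwd_qual=ordered.fwd_qual[len(f) :],
        rev_seq=ordered.rev_seq[len(r) :],
        rev_qual=ordered.rev_qual[len(r) :],
    )


def merge_pair(
    pair: ReadPair,
    spec: AmpliconSpec,
    sample: str = "",
    min_overlap: int = 12,
    max_mismatch_rate: float = 0.1,
) -> ProcessedSequence | None:
    """Combine an oriented pair into one fragment.

    Overlap policy: the reverse mate is reverse-complemented and the overlap
    length maximising the number of matching bases (ties to the longer
    overlap) with mismatch rate <= ``max_mismatch_rate`` and length >=
    ``min_overlap`` is used; at disagreeing overlap columns the base with the
    higher quality wins, and the consensus quality is the max of the two.
    Returns None (a counted rejection) when no acceptable overlap exists.

    N-join policy (long amplicons): the fragment is forward read + run of Ns
    + reverse-complemented reverse read, the N run padding the fragment to
    ``spec.expected_length`` (minimum 1).
    """
    fwd, fq = pair.fwd_seq, pair.fwd_qual
    rc = revcomp(pair.rev_seq)
    rq = pair.rev_qual[::-1]

    if spec.merge_policy == "njoin":
        n_run = max(1, spec.expected_length - len(fwd) - len(rc))
        seq = fwd + "N" * n_run + rc
        qual = fq + "!" * n_run + rq
        return ProcessedSequence(
            pair.id, sample, spec.name, seq, qual, joined_with_ns=True
        )

    best = None  # (matches, overlap_length)
    for ov in range(min_overlap, min(len(fwd), len(rc)) + 1):
        a, b = fwd[-ov:], rc[:ov]
        matches = sum(1 for x, y in zip(a, b) if x == y)
        if (ov - matches) / ov <= max_mismatch_rate:
            if best is None or (matches, ov) > best[:2]:
                best = (matches, ov)
    if best is None:
        return None
    _, ov = best
    cons, consq = [], []
    for i in range(ov):
        fb, fqc = fwd[-ov + i], fq[-ov + i]
        rb, rqc = rc[i], rq[i]
        cons.append(fb if fqc >= rqc else rb)
        consq.append(max(fqc, rqc))
    seq = fwd[:-ov] + "".join(cons) + rc[ov:]
    qual = fq[:-ov] + "".join(consq) + rq[ov:]
    return ProcessedSequence(pair.id, sample, spec.name, seq, qual)


def read_fastq_pairs(r1_path: str | Path, r2_path: str | Path):
    """Iterate ReadPairs from two matched FASTQ files (Phred+33)."""
    with open(r1_path) as f1, open(r2_path) as f2:
        for (t1, s1, q1), (t2, s2, q2) in zip(
            FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        ):
            yield ReadPair(t1.split()[0], s1.upper(), s2.upper(), q1, q2)


@dataclass
class PreprocessCounts:
    total: int = 0
    unassigned: int = 0
    rejected_primer: int = 0
    rejected_merge: int = 0
    merged: int = 0
    njoined: int = 0
    per_amplicon: dict = field(default_factory=dict)


def preprocess_pairs(
    pairs,
    manifest: SampleManifest,
    max_mismatches: int = 2,
    min_overlap: int = 12,
    max_mismatch_rate: float = 0.1,
    adapter: str | None = None,
) -> tuple[dict[tuple[str, str], list[ProcessedSequence]], PreprocessCounts]:
    """Full preprocessing of an iterable of ReadPairs.

    Each pair is demultiplexed, optionally adapter-clipped, assigned to the
    first amplicon in the manifest whose primer combination it carries, and
    merged. Returns fragments keyed by (sample, amplicon) plus counts; every
    input pair is accounted for in exactly one counter.
    """
    out: dict[tuple[str, str], list[ProcessedSequence]] = {}
    counts = PreprocessCounts()
    for pair in pairs:
        counts.total += 1
        assigned = demultiplex(pair, manifest)
        if assigned is None:
            counts.unassigned += 1
            continue
        sample, trimmed = assigned
        if adapter:
            fs, fq = clip_adapter(trimmed.fwd_seq, trimmed.fwd_qual, adapter)
            rs, rq = clip_adapter(trimmed.rev_seq, trimmed.rev_qual, adapter)
            trimmed = replace(trimmed, fwd_seq=fs, fwd_qual=fq, rev_seq=rs, rev_qual=rq)
        merged = None
        for spec in manifest.amplicons:
            oriented = orient_and_trim(trimmed, spec, max_mismatches)
            if oriented is None:
                continue
            merged = merge_pair(
                oriented,
                spec,
                sample=sample,
                min_overlap=min_overlap,
                max_mismatch_rate=max_mismatch_rate,
            )
            break
        else:
            counts.rejected_primer += 1
            continue
        if merged is None:
            counts.rejected_merge += 1
            continue
        amp = counts.per_amplicon.setdefault(spec.name, {"merged": 0, "njoined": 0})
        if merged.joined_with_ns:
            counts.njoined += 1
            amp["njoined"] += 1
        else:
            counts.merged += 1
            amp["merged"] += 1
        out.setdefault((sample, spec.name), []).append(merged)
    return out, counts
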