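"""Synthetic data generator: reference DBs, planted communities, reads.

Emulates the study conditions end to end without any download: a CO1
reference library with known BIN structure, a community of species planted at
controlled identities to their references, and inline-barcoded, primer-
flanked, error-bearing paired reads per amplicon.

The error model is substitution-only (no indels), which keeps the identity
arithmetic of the scoring bands exact: the expected identity of a planted
fragment to its best reference is pure Hamming arithmetic, so the truth table
can predict each BIN's per-amplicon band without running any aligner.

The four default amplicons use the study's primer panel (Table-2-style
degenerate primers) over nested windows of the 658 bp barcode region. Window
coordinates are configuration, not biology: the full-length amplicon (658 bp,
above the 570 bp cutoff) exercises the N-join path, the three shorter ones
the overlap-merge path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import AmpliconSpec, BARCODE_LENGTH, ReadPair, SampleManifest
from .refdb import ReferenceDB, ReferenceRecord
from .score import ScoringMatrix, DEFAULT_MATRIX, score_identity
from .seq import IUPAC, revcomp

# Degenerate CO1 primer panel (forward, reverse) per amplicon.
PRIMERS = {
    "Hco": ("GGTCAACAAATCATAAAGATATTGG", "TAAACTTCAGGGTGACCAAAAATCA"),
    "dgHco": ("GGWACWGGWTGAACWGTWTAYCCYCC", "TAAACTTCAGGGTGACCAAARAAYCA"),
    "miniBC": ("GAAAATCATAATGAAGGCATGAGC", "TCCACTAATCACAARGATATTGGTAC"),
    "LepF": ("ATTCAACCAATCATAAAGATATTGG", "CCTGGTAAAATTAAAATATAAACTTC"),
}

#: default amplicon windows (0-based, half-open) on the 658 bp barcode
DEFAULT_WINDOWS = {
    "Hco": (0, 658),      # full barcode, N-joined (>= 570 bp)
    "dgHco": (345, 658),  # 313 bp 3' fragment
    "miniBC": (181, 311), # 130 bp mini-barcode
    "LepF": (0, 400),     # 400 bp 5' fragment
}

#: deterministic pool of inline sample barcodes
BARCODE_POOL = (
    "ACGTACGT", "TGCATGCA", "GATCGATC", "CTAGCTAG",
    "AACCGGTT", "TTGGCCAA", "AGAGTCTC", "TCTCAGAG",
    "ACACGTGT", "GTGTACAC", "CAGTCAGT", "GTCAGTCA",
    "AATTCCGG", "CCGGAATT", "AGTCAGCT", "TCAGTCGA",
)

_ORDERS = ("Diptera", "Hymenoptera", "Coleoptera", "Lepidoptera")
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class CommunityMember:
    """One planted population: a species at a controlled identity to its
    reference, sequenced at a per-amplicon read depth in one sample."""

    species: int
    sample: str = "S1"
    identity: float = 1.0
    depth: int | dict[str, int] = 20

    def depth_for(self, amplicon: str) -> int:
        if isinstance(self.depth, dict):
            return self.depth.get(amplicon, 0)
        return self.depth


@dataclass
class SimulationConfig:
    seed: int
    n_species: int = 25
    seq_length: int = 658
    error_rate: float = 0.002
    read_length: int = 300
    windows: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_WINDOWS)
    )
    community: list[CommunityMember] | None = None
    max_pairwise_identity: float = 0.85
    max_intra_bin_divergence: float = 0.01

    def __post_init__(self):
        for name, (start, end) in self.windows.items():
            if not (0 <= start < end <= self.seq_length):
                raise ValueError(f"window for {name} does not fit the barcode region")
        if self.community is None:
            self.community = [CommunityMember(i) for i in range(self.n_species)]
        for m in self.community:
            if not 0.8 <= m.identity <= 1.0:
                raise ValueError("identity_to_reference must be in [0.8, 1.0]")

    def amplicons(self) -> list[AmpliconSpec]:
        return [
            AmpliconSpec(
                name=name,
                fwd_primer=PRIMERS[name][0],
                rev_primer=PRIMERS[name][1],
                expected_length=end - start,
            )
            for name, (start, end) in self.windows.items()
        ]

    def manifest(self) -> SampleManifest:
        samples = []
        for m in self.community:
            if m.sample not in samples:
                samples.append(m.sample)
        if len(samples) > len(BARCODE_POOL):
            raise ValueError("more samples than available barcodes")
        barcodes = {BARCODE_POOL[i]: s for i, s in enumerate(samples)}
        return SampleManifest(barcodes=barcodes, amplicons=self.amplicons())


@dataclass
class SyntheticReference:
    """Reference DB plus the per-species ground truth behind it."""

    db: ReferenceDB
    species_seqs: list[str]
    species_bins: list[str]
    record_seqs: list[list[str]]  # per species, canonical first


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def mutate_to_identity(seq: str, target_identity: float, rng: np.random.Generator) -> str:
    """Substitute exactly round((1-target) * len) positions (no indels)."""
    if not 0.8 <= target_identity <= 1.0:
        raise ValueError("target identity must be in [0.8, 1.0]")
    k = round((1.0 - target_identity) * len(seq))
    if k == 0:
        return seq
    positions = rng.choice(len(seq), size=k, replace=False)
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def make_reference_db(cfg: SimulationConfig) -> SyntheticReference:
    """Random species at guaranteed mutual divergence, 1-3 records per BIN.

    Species sequences are rejection-sampled so that every pair is at most
    ``max_pairwise_identity`` identical (global-alignment identity), making
    BIN assignment unambiguous; each species' extra specimen records diverge
    from the canonical sequence by at most ``max_intra_bin_divergence``.
    """
    from . import alignment  # local import to keep module load light

    rng = np.random.default_rng(cfg.seed)
    species_seqs: list[str] = []
    encoded: list[np.ndarray] = []
    attempts = 0
    while len(species_seqs) < cfg.n_species:
        cand = _random_seq(rng, cfg.seq_length)
        cand_enc = alignment.encode(cand)
        if all(
            alignment.align_global(cand_enc, e).identity_pct
            <= 100 * cfg.max_pairwise_identity
            for e in encoded
        ):
            species_seqs.append(cand)
            encoded.append(cand_enc)
            attempts = 0
        else:
            attempts += 1
            if attempts > 50:
                raise RuntimeError(
                    "could not satisfy the divergence constraint; "
                    "use longer sequences or fewer species"
                )

    records: list[ReferenceRecord] = []
    species_bins: list[str] = []
    record_seqs: list[list[str]] = []
    for s, seq in enumerate(species_seqs):
        bin_id = f"BOLD:SIM{s:04d}"
        species_bins.append(bin_id)
        order = _ORDERS[s % len(_ORDERS)]
        n_rec = int(rng.integers(1, 4))
        seqs = [seq]
        for r in range(1, n_rec):
            div = rng.uniform(0, cfg.max_intra_bin_divergence)
            seqs.append(mutate_to_identity(seq, 1.0 - div, rng))
        record_seqs.append(seqs)
        for r, rec_seq in enumerate(seqs):
            records.append(
                ReferenceRecord(
                    process_id=f"SIM{s:04d}-{r}",
                    bin_id=bin_id,
                    order_name=order,
                    family=f"Fam{s % 7}",
                    genus=f"Genus{s}",
                    species=f"Genus{s} sp{s}",
                    sequence=rec_seq,
                )
            )
    return SyntheticReference(
        db=ReferenceDB(records),
        species_seqs=species_seqs,
        species_bins=species_bins,
        record_seqs=record_seqs,
    )


def _concrete_primer(primer: str, rng: np.random.Generator) -> str:
    """Sample concrete bases for degenerate positions, uniformly per read."""
    out = []
    for code in primer:
        options = IUPAC[code]
        out.append(options if len(options) == 1 else options[rng.integers(len(options))])
    return "".join(out)


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    mask = rng.random(len(seq)) < rate
    if not mask.any():
        return seq
    chars = list(seq)
    for pos in np.nonzero(mask)[0]:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[rng.integers(3)]
    return "".join(chars)


def _expected_identity(
    variant_window: str,
    record_windows: list[str],
    x_f: int,
    x_r: int,
) -> tuple[float, bool]:
    """Hamming-arithmetic identity of the merged fragment to its best record.

    ``x_f``/``x_r`` are the insert bases covered by each mate. If the mates
    do not span the window, the gap is N-filled and every N counts as a
    mismatch (the same convention the matcher uses).
    """
    wlen = len(variant_window)
    joined = x_f + x_r < wlen
    best = 0.0
    for rw in record_windows:
        if joined:
            covered = list(range(x_f)) + list(range(wlen - x_r, wlen))
            matches = sum(1 for i in covered if variant_window[i] == rw[i])
        else:
            matches = sum(1 for a, b in zip(variant_window, rw) if a == b)
        best = max(best, round(100.0 * matches / wlen, 2))
    return best, joined


def simulate_reads(
    ref: SyntheticReference, cfg: SimulationConfig
) -> tuple[dict[str, list[ReadPair]], pd.DataFrame]:
    """Generate barcoded paired reads per amplicon plus the truth table.

    The truth table has one row per (community member, amplicon) with the
    planted BIN, the expected best identity of the merged fragment to the
    reference records (exact Hamming arithmetic under the substitution-only
    model) and the scoring band it implies.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    manifest = cfg.manifest()
    barcode_of = {s: bc for bc, s in manifest.barcodes.items()}
    reads: dict[str, list[ReadPair]] = {a.name: [] for a in manifest.amplicons}
    truth_rows = []

    for midx, member in enumerate(cfg.community):
        variant = mutate_to_identity(
            ref.species_seqs[member.species], member.identity, rng
        )
        barcode = barcode_of[member.sample]
        for spec in manifest.amplicons:
            depth = member.depth_for(spec.name)
            start, end = cfg.windows[spec.name]
            window = variant[start:end]
            x_f = min(
                cfg.read_length - BARCODE_LENGTH - len(spec.fwd_primer), len(window)
            )
            x_r = min(
                cfg.read_length - BARCODE_LENGTH - len(spec.rev_primer), len(window)
            )
            rec_windows = [s[start:end] for s in ref.record_seqs[member.species]]
            exp_ident, joined = _expected_identity(window, rec_windows, x_f, x_r)
            band = score_identity(exp_ident)
            truth_rows.append(
                {
                    "member": midx,
                    "species": member.species,
                    "sample": member.sample,
                    "bin_id": ref.species_bins[member.species],
                    "amplicon": spec.name,
                    "depth": depth,
                    "target_identity": member.identity,
                    "expected_identity_pct": exp_ident,
                    "expected_band_score": band if band is not None else 0,
                    "n_joined": joined,
                }
            )
            if depth <= 0:
                continue
            rc_window = revcomp(window)
            for i in range(depth):
                fwd = barcode + _concrete_primer(spec.fwd_primer, rng) + window[:x_f]
                rev = barcode + _concrete_primer(spec.rev_primer, rng) + rc_window[:x_r]
                fwd = _with_errors(fwd, cfg.error_rate, rng)
                rev = _with_errors(rev, cfg.error_rate, rng)
                rid = f"sim:{member.sample}:sp{member.species}:{spec.name}:{i}"
                if rng.random() < 0.5:  # sequencing direction is random
                    fwd, rev = rev, fwd
                reads[spec.name].append(
                    ReadPair(rid, fwd, rev, "I" * len(fwd), "I" * len(rev))
                )
    return reads, pd.DataFrame(truth_rows)


def expected_high_score_bins(
    truth: pd.DataFrame,
    matrix: ScoringMatrix = DEFAULT_MATRIX,
    min_coverage: int = 10,
) -> dict[str, set[str]]:
    """Per-sample set of BINs the truth table predicts as high score.

    An amplicon detection counts when its read depth reaches the coverage
    threshold and its expected identity reaches the scoring floor; per
    (sample, BIN, amplicon) the best expected identity wins, and the band
    scores are summed exactly as the pipeline does.
    """
    out: dict[str, set[str]] = {}
    usable = truth[truth["depth"] >= min_coverage]
    for (sample, bin_id), grp in usable.groupby(["sample", "bin_id"]):
        total = 0
        for _, amp_grp in grp.groupby("amplicon"):
            band = score_identity(amp_grp["expected_identity_pct"].max(), matrix)
            if band:
                total += band
        if total >= matrix.high_score_threshold:
            out.setdefault(sample, set()).add(bin_id)
    return out


def write_fastq(reads: dict[str, list[ReadPair]], outdir: str | Path) -> None:
    """Write per-amplicon paired FASTQ files (Phred+33)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for amp, pairs in reads.items():
        with open(outdir / f"{amp}_R1.fastq", "w") as f1, open(
            outdir / f"{amp}_R2.fastq", "w"
        ) as f2:
            for p in pairs:
                f1.write(f"@{p.id}\n{p.fwd_seq}\n+\n{p.fwd_qual}\n")
                f2.write(f"@{p.id}\n{p.rev_seq}\n+\n{p.rev_qual}\n")
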