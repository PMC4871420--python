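# Methods

## Problem and pipeline

Bulk insect samples (malaise-trap catches) are identified by sequencing four
overlapping amplicons of the CO1-5′ barcode region from each DNA extract and
matching the resulting sequence clusters against a reference library in
which every specimen record carries a Barcode Index Number (BIN), a species
proxy. Because any single amplicon can mis-assign (sequencing error,
primer bias, incomplete reference coverage), the pipeline scores each BIN by
how well, and by how many, of the four amplicons recover it.

Stages, in order:

1. **Demultiplexing.** Paired reads carry an 8-base inline sample barcode 5′
   of the PCR primer. Assignment is by exact match of the forward mate's
   first 8 bases (exact matching is the conservative choice for 8-mers; a
   1-in-65536 tag space makes error-tolerant assignment a cross-talk risk).
   Once a pair is assigned, the now-known tag is stripped from the other
   mate tolerating up to 2 mismatches — the tag's identity is established,
   so tolerance there cannot re-assign the pair.
2. **Adapter clipping.** A suffix of a read matching a prefix of the
   sequencing adapter over ≥ 5 bases with ≤ 10% mismatches is removed
   (longest such suffix wins).
3. **Primer validation and orientation.** A pair is kept iff one mate starts
   with the forward primer and the other with the reverse primer, each
   within `max_mismatches` (default 2; IUPAC degenerate codes match their
   base sets, N in a read matches nothing). Sequencing direction is random,
   so mates are swapped as needed into Fwd→Rev orientation, then primers are
   trimmed.
4. **Merging.** Amplicons with expected fragment length < 570 bp are
   overlap-merged: the overlap maximising matching bases (ties to the longer
   overlap) with mismatch rate ≤ 0.1 and length ≥ 12 is taken; at
   disagreeing columns the higher-quality base wins and the consensus
   quality is the max of the two. Amplicons ≥ 570 bp cannot overlap on a
   2×300 run and are N-joined: forward + N-run + reverse-complemented
   reverse, padded to the expected length (minimum 1 N).
5. **Clustering.** Each (sample, amplicon) pool is dereplicated, ranked by
   abundance (ties: longer, then lexicographic) and clustered greedily at
   98% identity, CD-HIT-EST style: each unique joins the first cluster whose
   representative it matches at ≥ threshold, else founds a new cluster.
   Scanning in abundance order makes the representative the most abundant
   member by construction and the procedure permutation-stable. Clusters
   with coverage (summed read count) < 10 are discarded.
6. **Best-hit identification.** Cluster representatives are searched against
   the reference library with a k-mer-seeded (k = 11, ≥ 2 shared seeds, both
   strands) candidate search followed by exact alignment; the single best
   hit (maximal identity; ties to longer alignment, then lexicographic
   process ID) is reported, mirroring a megablast "maximum hits 1" search.
   Hits under an 80% identity floor are suppressed as noise; an
   equal-identity hit in a different BIN sets an `ambiguous` flag.
7. **Scoring.** Per sample, amplicon and BIN, the maximum identity over all
   clusters hitting that BIN (the most favourable evidence) is banded:
   [97,98) → 70, [98,99) → 150, [99,100) → 240, exactly 100 → 340; < 97
   contributes nothing. Band totals are summed over amplicons; BINs with no
   banded amplicon are omitted; totals ≥ 300 are high-score. The bands are
   half-open so identities quoted at more than two decimals still land in
   exactly one band (99.995 → 240). The threshold is inclusive (≥ 300).

## Alignment and identity

Identity drives everything, so its definition is fixed precisely: global
(Needleman–Wunsch) alignment with match +1, mismatch −1, linear gap −2;
identity = identical columns / alignment columns, gap columns included,
rounded to two decimals — the BLAST-style "identities over alignment
length". The full dynamic-programming matrix is computed (vectorised
row-wise; the linear gap penalty lets the in-row gap recurrence unroll into
a running maximum), so the identity is that of a true optimum rather than a
banded approximation; correctness is pinned to a naive full-matrix oracle in
the tests. The optimal score is unique but the optimal alignment need not
be: the reported alignment uses a fixed traceback preference (diagonal, gap
in second sequence, gap in first) on a canonical orientation
(lexicographically smaller sequence first), which makes the reported
identity deterministic and symmetric in its arguments.

Reference matching treats N as matching nothing — conservative, because the
97/98/99/100 bands must not be reachable through padding. A consequence,
verified by the tests: N-joined long-amplicon fragments fall below the bands
(their N run alone caps identity near 75–80%), so the full-length amplicon
contributes clusters but effectively no score under the default windows.

Queries are usually shorter than the 658 bp references, so the matcher
aligns semi-globally: the query end to end, reference overhangs free and
excluded from the alignment columns (identity over the aligned span, as
BLAST reports it). In the ≥ 97% regime this coincides with the global
identity; at low identity a semi-global optimum can legitimately exceed it.

Clustering compares letters, not base semantics: N equals N there, exactly
as CD-HIT treats characters. Otherwise identical N-joined fragments of one
template could never co-cluster (see above), splintering the long amplicon.
Before any alignment, candidate pairs pass a word filter with a provable
bound: an alignment with identity ≥ t spanning ≥ L columns shares at least
t·L − (k−1)·((1−t)·L + 1) k-mers (k = 8; each non-match column destroys at
most k words and the matches fall in at most e+1 runs), so pairs sharing
fewer words are rejected without alignment. Earlier Hamming-based shortcuts
were removed: equal-length sequences related by compensating indels defeat
them, as the brute-force oracle demonstrated.

## Reference database

A BOLD-style TSV export (process ID, BIN, taxonomy, sequence) is joined into
one record per specimen keyed by process ID. Sequences are uppercased,
alignment gaps stripped, and IUPAC ambiguity codes other than N converted to
N (counted); rows with empty BIN or sequence are dropped and counted, and
the load summary always satisfies records_in = kept + dropped. Records
without species names are retained — the BIN is the reporting unit. The
FASTA serialisation encodes `process_id|bin_id|order|family|genus|species`
in the header ("|" is reserved and rejected inside fields) and round-trips
losslessly. `min_length` defaults to 0 so toy tables survive ingest; 100 is
recommended for real CO1 exports.

## The simulator

The generator emulates the study conditions end to end. A reference library
of `n_species` random 658 bp sequences is rejection-sampled to ≥ 15% mutual
divergence (global-alignment identity ≤ 85%), making BIN assignment
unambiguous; each species owns one BIN and 1–3 specimen records within 1%
of the canonical sequence. A community member plants one species at a
controlled identity (substitutions only, exactly round((1−t)·658)
positions) and a per-amplicon read depth. Reads are built as
barcode + primer (degenerate positions sampled per read) + fragment window,
from both ends, in random mate order, with i.i.d. per-base substitution
errors (default rate 0.002, a MiSeq-like figure) and flat Q40 qualities;
read length defaults to 300 (2×300 chemistry).

The four default amplicons use the study's primer panel over nested windows
of the barcode region — Hco (0, 658), dgHco (345, 658), miniBC (181, 311),
LepF (0, 400) — approximating the 150–400 bp products plus the full-length
fragment; the coordinates are configuration, not biology, and the ≥ 570 bp
window deliberately exercises the N-join path. A configuration with four
short windows is what an all-amplicon 100% community needs to reach the
1360 maximum, since N-joined fragments cannot score.

Because the error model is substitution-only, the truth table can state the
expected best identity of each (member, amplicon) fragment by pure Hamming
arithmetic — including the N-run accounting for unjoinable windows — without
running any aligner, which keeps the end-to-end oracle independent of the
pipeline's alignment code. What the simulator does *not* model: indels,
chimeras, instrument-specific quality profiles, abundance-dependent primer
competition, and contamination. Passing the recovery tests therefore shows
the pipeline's logic is exact under controlled identities and depths, not
that real malaise-trap data will behave as cleanly.

## Parameter defaults

| parameter | default | why |
|---|---|---|
| barcode length / matching | 8 bases, exact | tag design; conservative assignment |
| primer max mismatches | 2 | tolerates ~1 error plus a degenerate-site drift on 24–26-mers |
| merge min overlap / mismatch rate | 12 bp / 0.1 | enough signal to anchor an overlap; consistent with common merger defaults |
| N-join cutoff | 570 bp | fragments at or above this cannot overlap on a 2×300 run |
| clustering identity | 0.98 | species-level CO1 clustering convention |
| cluster coverage floor | 10 reads, inclusive | removes singleton/error clusters |
| seed k / min seeds / identity floor | 11 / 2 / 80% | megablast-like word size; floor far below the scoring bands |
| scoring bands / threshold | 70/150/240/340, ≥ 300 | the confidence matrix and its exclusion rule |

All are configurable at the respective interfaces; the scoring matrix is a
value object so sensitivity analyses can swap band definitions.

## Reporting conventions

Printed percentages are round-half-up integers (268/390 → 69, 31/35 → 89).
Primer efficiency is, per order, each amplicon's share of the order's
BIN-amplicon detections (rows sum to 100 ± rounding); the alternative
denominator — percentage of the order's BINs each amplicon detected — is
available via an option, since either reading is defensible. The
sorted-versus-combined comparison counts shared BINs and shared high-score
BINs between the pre-sorted card sets and the combined (unsorted) sample.

## Test problem sizes

The oracle-equivalence suites run at sizes where exhaustive and naive
computations are exact and fast: best-hit vs exhaustive search on a
200-record library of 160 bp references with 100 queries; greedy clustering
vs a brute-force reimplementation on ≤ 20 sequences of 64 bp over 50 seeds;
end-to-end recovery on 25 species × 4 amplicons at depth 20 with 0.2%
error. These sizes were chosen so each property is checked in full rather
than sampled.

## Known limitations

- Not a BBmerge or BLAST reimplementation: no quality-model merging, no
  E-values, no X-drop heuristics; "maximum hits 1" is enforced at the
  interface.
- Greedy clustering order is abundance-based (so the stated representative
  rule holds by construction), not CD-HIT's length-based order; cluster
  boundaries can differ from CD-HIT-EST on ties.
- The k-mer seeding can miss a true best hit sharing fewer than
  `min_seed_hits` words — below ~75% identity for defaults, safely under
  the 80% floor.
- Coverage is counted per (sample, amplicon) pool, the clustering unit; a
  BIN spread thinly across samples is filtered per pool, not rescued
  globally.
- No query-coverage threshold is applied to hits beyond the identity floor;
  short spurious high-identity alignments are bounded by the semi-global
  query-end-to-end requirement.
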