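# binscore

Multi-amplicon CO1 metabarcoding with a per-BIN confidence score.

`binscore` is a pipeline for identifying the species content of bulk
arthropod samples (e.g. malaise-trap catches) from multiplexed amplicon
sequencing. It takes paired reads from four overlapping CO1 amplicons,
demultiplexes them on 8-base inline sample barcodes, validates and trims the
(degenerate) primers, merges the read pairs, clusters each sample/amplicon
pool at 98% identity, identifies each cluster representative by best hit
against a custom BIN-annotated reference library, and — the core of the
package — aggregates the per-amplicon evidence into a confidence score per
Barcode Index Number (BIN).

## The scoring matrix

For each BIN and each amplicon, the best percent identity of any cluster
hitting that BIN is mapped to a band score; identities below 97% are
discarded as sequencing error / within-species variation:

| identity | score |
|---|---|
| 97.00–97.99% | 70 |
| 98.00–98.99% | 150 |
| 99.00–99.99% | 240 |
| 100% | 340 |

The four per-amplicon scores are summed into an overall confidence index
S = Σₐ score(identityₐ). The maximum is 4 × 340 = 1360; a BIN seen at 97% by
all four amplicons totals only 280; the minimum non-zero total is 70. BINs
with S ≥ 300 are classified **high-score**: a sub-100% detection must be
corroborated by at least a second amplicon to qualify, while a single
perfect (100%, score 340) detection passes on its own.

## Worked example

The built-in simulator plants a community with known identities to a
synthetic reference library and generates barcoded, error-bearing paired
reads for the four amplicons, so the whole pipeline can be exercised and
checked against ground truth:

```python
import binscore as bs

cfg = bs.SimulationConfig(
    seed=7,
    n_species=4,
    community=[
        bs.CommunityMember(0, identity=1.0,   depth=20),
        bs.CommunityMember(1, identity=0.985, depth=20),
        bs.CommunityMember(2, identity=0.975, depth={"miniBC": 20}),
        bs.CommunityMember(3, identity=1.0,   depth=9),
    ],
)
ref = bs.make_reference_db(cfg)
reads, truth = bs.simulate_reads(ref, cfg)
result = bs.run_pipeline(reads, cfg.manifest(), ref.db)
print(result.cards_frame[["bin_id", "identity_dgHco", "identity_miniBC",
                          "identity_LepF", "total_score", "high_score"]]
      .to_string(index=False))
```

prints

```
      bin_id  identity_dgHco  identity_miniBC  identity_LepF  total_score  high_score
BOLD:SIM0000          100.00           100.00          100.0         1020        True
BOLD:SIM0001           97.76            98.46           99.0          460        True
BOLD:SIM0002             NaN            99.23            NaN          240       False
```

Reading the output: species 0 is recovered at 100% by the three
overlap-merged amplicons (3 × 340 = 1020; the full-length Hco amplicon is
N-joined and its N run keeps it below the 97% floor, a documented property
of the N-as-mismatch identity). Species 1 was planted at 98.5% overall and
lands in different bands per amplicon window (70 + 150 + 240 = 460) — a
high-score BIN only because several amplicons corroborate it. Species 2 was
seen by a single amplicon below 100%, so its 240 points stay under the 300
threshold and it is excluded. Species 3 was sequenced at depth 9 and never
appears: clusters under the coverage ≥ 10 filter are dropped.

## Command line

Each stage is also exposed as a thin CLI over the library:

```
binscore simulate   --seed 4 --n-species 6 --depth 15 --outdir demo/
binscore refdb build --table refs.tsv --out refdb.fasta
binscore preprocess --r1 Hco_R1.fastq --r2 Hco_R2.fastq --manifest manifest.yaml --outdir frags/
binscore cluster    --in frags/S1_LepF.fasta --identity 0.98 --min-coverage 10 --out reps.fasta
binscore match      --clusters reps.fasta --refdb refdb.fasta --out hits.csv --sample S1 --amplicon LepF
binscore score      --hits hits_hco.csv hits_dghco.csv hits_minibc.csv hits_lepf.csv --out bins.csv
binscore report     --cards bins.csv --combined combined.csv
```

The hit table columns follow a BLAST outfmt-6-like layout: `query_id,
sample, amplicon, coverage, bin_id, process_id, identity_pct,
alignment_length, ambiguous`.

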