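"""Pairwise identity, k-mer seeding and best-hit search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from binscore.cluster import Cluster
from binscore.match import (
    align_sample,
    best_hit,
    build_kmer_index,
    pairwise_identity,
)
from binscore.refdb import ReferenceDB, ReferenceRecord
from binscore.seq import revcomp
from conftest import naive_global_identity


def _random_seq(r, n):
    return "".join(r.choice(list("ACGT"), size=n))


def _sub(seq, pos):
    return seq[:pos] + {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[pos]] + seq[pos + 1 :]


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        s = _random_seq(rng, 100)
        assert pairwise_identity(s, s) == (100.0, 100)

    def test_single_substitution(self, rng):
        s = _random_seq(rng, 100)
        assert pairwise_identity(s, _sub(s, 42)) == (99.0, 100)

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_n_counts_as_mismatch(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + "N" + a[11:]
        ident, cols = pairwise_identity(a, b)
        assert (ident, cols) == (95.0, 20)

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = _random_seq(r, 60), _random_seq(r, int(r.integers(50, 70)))
        assert pairwise_identity(a, b)[0] == pairwise_identity(b, a)[0]

    @settings(max_examples=120)
    @given(seed=st.integers(min_value=0, max_value=100_000))
    def test_equals_naive_full_matrix_oracle(self, seed):
        """Vectorised DP identity equals a naive full-matrix alignment."""
        r = np.random.default_rng(seed)
        la, lb = int(r.integers(80, 160)), int(r.integers(80, 160))
        if r.random() < 0.5:  # half the pairs related, half random
            a = _random_seq(r, la)
            b = list(a)
            for p in r.choice(la, size=int(r.integers(0, la // 10)), replace=False):
                b[p] = "ACGT"[r.integers(4)]
            b = "".join(b)
        else:
            a, b = _random_seq(r, la), _random_seq(r, lb)
        assert pairwise_identity(a, b) == naive_global_identity(a, b)

    def test_score_matches_independent_library_aligner(self, rng):
        """Optimal alignment scores agree with Biopython's PairwiseAligner."""
        from Bio import Align

        from binscore import alignment as al

        aligner = Align.PairwiseAligner(
            match_score=1, mismatch_score=-1, gap_score=-2, mode="global"
        )
        for _ in range(25):
            a, b = _random_seq(rng, 90), _random_seq(rng, int(rng.integers(80, 100)))
            ours = al.align_global(al.encode(a), al.encode(b)).score
            assert ours == aligner.score(a, b)


def _db(rng, n=6, length=200):
    recs = []
    seqs = []
    for i in range(n):
        s = _random_seq(rng, length)
        seqs.append(s)
        recs.append(ReferenceRecord(f"P{i:02d}", f"BOLD:B{i:03d}", s, order_name="Diptera"))
    return ReferenceDB(recs), seqs


class TestKmerIndex:
    def test_posting_count_is_length_minus_k_plus_one(self):
        db = ReferenceDB([ReferenceRecord("P1", "B1", "ACGTACGTACGT")])
        assert build_kmer_index(db, k=11).n_postings() == 2

    def test_reference_shorter_than_k_yields_no_postings(self):
        db = ReferenceDB([ReferenceRecord("P1", "B1", "ACGTACG")])
        assert build_kmer_index(db, k=11).n_postings() == 0

    def test_duplicate_references_double_the_postings(self):
        one = ReferenceDB([ReferenceRecord("P1", "B1", "ACGTACGTACGTACGT")])
        two = ReferenceDB(
            [
                ReferenceRecord("P1", "B1", "ACGTACGTACGTACGT"),
                ReferenceRecord("P2", "B1", "ACGTACGTACGTACGT"),
            ]
        )
        assert build_kmer_index(two, k=11).n_postings() == 2 * build_kmer_index(
            one, k=11
        ).n_postings()

    def test_kmers_containing_n_are_skipped(self):
        db = ReferenceDB([ReferenceRecord("P1", "B1", "ACGTACGTACGN")])
        assert build_kmer_index(db, k=11).n_postings() == 1

    def test_k_below_8_rejected(self):
        with pytest.raises(ValueError):
            build_kmer_index(ReferenceDB([ReferenceRecord("P1", "B1", "ACGT")]), k=4)


class TestBestHit:
    def test_identical_query_hits_its_reference_at_100(self, rng):
        db, seqs = _db(rng)
        index = build_kmer_index(db)
        hit = best_hit("q", seqs[2], db, index)
        assert (hit.process_id, hit.identity_pct) == ("P02", 100.0)

    def test_reverse_complement_query_gives_same_hit(self, rng):
        db, seqs = _db(rng)
        index = build_kmer_index(db)
        fwd = best_hit("q", seqs[3], db, index)
        rc = best_hit("q", revcomp(seqs[3]), db, index)
        assert (rc.process_id, rc.identity_pct) == (fwd.process_id, fwd.identity_pct)
        assert rc.strand == "-"

    def test_equidistant_hit_breaks_ties_deterministically_and_flags_ambiguity(
        self, rng
    ):
        q = _random_seq(rng, 200)
        db = ReferenceDB(
            [
                ReferenceRecord("P1", "BOLD:X", _sub(q, 10)),
                ReferenceRecord("P0", "BOLD:Y", _sub(q, 20)),
            ]
        )
        hit = best_hit("q", q, db, build_kmer_index(db))
        assert hit.process_id == "P0"  # lexicographic tie-break
        assert hit.identity_pct == 99.5
        assert hit.ambiguous

    def test_identity_floor_suppresses_distant_hits(self, rng):
        db, seqs = _db(rng)
        q = _random_seq(rng, 200)  # unrelated to every reference
        assert best_hit("q", q, db, build_kmer_index(db), min_identity=80.0) is None


class TestAlignSample:
    def test_one_row_per_cluster_with_empty_fields_for_misses(self, rng):
        db, seqs = _db(rng)
        clusters = [
            Cluster("c0", seqs[0], 12, "S1", "Hco"),
            Cluster("c1", seqs[1], 15, "S1", "Hco"),
            Cluster("c2", _random_seq(rng, 200), 30, "S1", "Hco"),
        ]
        table = align_sample(clusters, db)
        assert len(table) == 3
        assert (table["bin_id"] == "").sum() == 1
        assert table.loc[0, "identity_pct"] == 100.0

    def test_empty_cluster_list_gives_header_only_table(self, rng):
        db, _ = _db(rng)
        table = align_sample([], db)
        assert len(table) == 0
        assert "bin_id" in table.columns

    def test_njoined_query_identity_counts_n_columns_as_mismatches(self, rng):
        """An N-joined fragment built from a reference scores exactly the
        non-N matched fraction of its length."""
        db, seqs = _db(rng, n=2, length=200)
        ref = seqs[0]
        query = ref[:80] + "N" * 40 + ref[120:]  # 160 real + 40 N over 200 columns
        hit = best_hit("q", query, db, build_kmer_index(db))
        assert hit.process_id == "P00"
        assert hit.identity_pct == 80.0
        assert hit.alignment_length == 200
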