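"""Demultiplexing, adapter clipping, primer validation, pair merging."""

import pytest
from hypothesis import given, strategies as st

from binscore.preprocess import (
    AmpliconSpec,
    ReadPair,
    SampleManifest,
    clip_adapter,
    demultiplex,
    match_primer,
    merge_pair,
    orient_and_trim,
    preprocess_pairs,
)
from binscore.seq import revcomp

BC1 = "ACGTACGT"
SHORT_SPEC = AmpliconSpec("toy", "AAAA", "TTTT", expected_length=16)
LONG_SPEC = AmpliconSpec("long", "AAAA", "TTTT", expected_length=570)


def _pair(fwd, rev, rid="r1"):
    return ReadPair(rid, fwd, rev, "I" * len(fwd), "I" * len(rev))


def _manifest(**barcodes):
    return SampleManifest(barcodes=barcodes or {BC1: "S1"}, amplicons=[SHORT_SPEC])


class TestDemultiplex:
    def test_matching_prefix_assigns_and_strips_barcode(self):
        pair = _pair(BC1 + "AAAACCCC", BC1 + "TTTTGGGG")
        sample, trimmed = demultiplex(pair, _manifest())
        assert sample == "S1"
        assert trimmed.fwd_seq == "AAAACCCC"
        assert trimmed.rev_seq == "TTTTGGGG"
        assert len(trimmed.fwd_qual) == len(trimmed.fwd_seq)

    def test_unknown_prefix_is_unassigned(self):
        assert demultiplex(_pair("GGGGGGGG" + "AAAA", "TTTT"), _manifest()) is None

    def test_reverse_mate_barcode_stripped_despite_sequencing_error(self):
        bc_err = "ACGTACAT"  # one error in the tag
        pair = _pair(BC1 + "AAAACCCC", bc_err + "TTTTGGGG")
        _, trimmed = demultiplex(pair, _manifest())
        assert trimmed.rev_seq == "TTTTGGGG"

    @given(st.lists(st.sampled_from([BC1, "TGCATGCA", "GGGGGGGG"]), max_size=60))
    def test_binning_is_a_partition(self, prefixes):
        manifest = SampleManifest(
            barcodes={BC1: "S1", "TGCATGCA": "S2"}, amplicons=[SHORT_SPEC]
        )
        bins = {"S1": 0, "S2": 0, None: 0}
        for i, pre in enumerate(prefixes):
            res = demultiplex(_pair(pre + "ACGT", "ACGT", rid=f"r{i}"), manifest)
            bins[res[0] if res else None] += 1
        assert sum(bins.values()) == len(prefixes)
        assert bins["S1"] == sum(p == BC1 for p in prefixes)


class TestClipAdapter:
    ADAPTER = "AGATCGGAAGAGC"

    def test_full_adapter_suffix_removed(self):
        seq = "ACGTACGTAC" + self.ADAPTER
        clipped, q = clip_adapter(seq, "I" * len(seq), self.ADAPTER)
        assert clipped == "ACGTACGTAC"
        assert len(q) == len(clipped)

    def test_sequence_without_adapter_unchanged(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert clip_adapter(seq, "I" * len(seq), self.ADAPTER)[0] == seq

    def test_partial_adapter_prefix_clipped(self):
        seq = "CCCCCCCCCC" + self.ADAPTER[:6]
        clipped, _ = clip_adapter(seq, "I" * len(seq), self.ADAPTER, min_overlap=5)
        assert clipped == "CCCCCCCCCC"


class TestMatchPrimer:
    DGHCO = "TAAACTTCAGGGTGACCAAARAAYCA"

    def test_degenerate_codes_match_their_base_sets(self):
        read = "GG" + "TAAACTTCAGGGTGACCAAAGAATCA" + "CCC"  # R:G, Y:T
        assert match_primer(read, self.DGHCO, max_mismatches=0) == 2

    def test_mismatch_budget_is_enforced(self):
        read = "TAAACTTCAGGGTGACCAAAGAATCA"
        bad = "CCC" + read[3:]
        assert match_primer(bad, self.DGHCO, max_mismatches=2) is None

    def test_exact_prefix_matches_at_zero(self):
        assert match_primer("ACGTACGTACGT", "ACGTACGT", max_mismatches=0) == 0

    def test_n_in_read_never_matches(self):
        assert match_primer("NCGTACGT", "ACGTACGT", max_mismatches=0) is None


class TestOrientAndTrim:
    def test_correct_order_accepted_and_primers_trimmed(self):
        pair = _pair("AAAA" + "CCCCC", "TTTT" + "GGGGG")
        out = orient_and_trim(pair, SHORT_SPEC)
        assert out.fwd_seq == "CCCCC"
        assert out.rev_seq == "GGGGG"

    def test_swapped_mates_are_reordered(self):
        straight = orient_and_trim(_pair("AAAA" + "CCCCC", "TTTT" + "GGGGG"), SHORT_SPEC)
        swapped = orient_and_trim(_pair("TTTT" + "GGGGG", "AAAA" + "CCCCC"), SHORT_SPEC)
        assert (swapped.fwd_seq, swapped.rev_seq) == (straight.fwd_seq, straight.rev_seq)

    def test_pair_without_valid_primer_combination_rejected(self):
        assert orient_and_trim(_pair("CCCCCCCC", "GGGGGGGG"), SHORT_SPEC) is None

    def test_same_primer_on_both_mates_rejected(self):
        assert orient_and_trim(_pair("AAAACCCC", "AAAAGGGG"), SHORT_SPEC) is None


class TestMergePair:
    def test_overlap_merge_length_arithmetic(self):
        fwd = "ACGTACGTAC"
        rc = "GTACGGGGGG"  # overlaps fwd suffix by 4
        pair = _pair(fwd, revcomp(rc))
        merged = merge_pair(pair, SHORT_SPEC, min_overlap=4)
        assert merged.sequence == "ACGTACGTACGGGGGG"
        assert len(merged.sequence) == 10 + 10 - 4
        assert not merged.joined_with_ns

    def test_njoin_pads_to_expected_length(self):
        fwd = "A" * 300
        rev = "C" * 250  # rc = G*250
        merged = merge_pair(_pair(fwd, rev), LONG_SPEC)
        assert merged.joined_with_ns
        assert len(merged.sequence) == 570
        assert merged.sequence.count("N") == 20
        assert merged.sequence == "A" * 300 + "N" * 20 + "G" * 250

    def test_high_mismatch_overlap_rejected(self):
        fwd = "ACGTACGTACGTACGTACGT"
        rc = "AGCTTGCAACTTTGCAACTT"  # ~50% mismatches at any overlap
        assert merge_pair(_pair(fwd, revcomp(rc)), SHORT_SPEC, min_overlap=12) is None

    def test_consensus_takes_higher_quality_base(self):
        fwd = "AAAA" + "T" * 10  # last base disagrees with the reverse mate
        rc = "T" * 9 + "C" + "GGGG"
        pair = ReadPair("r", fwd, revcomp(rc), "I" * 13 + "!", "I" * 14)
        merged = merge_pair(pair, SHORT_SPEC, min_overlap=10)
        # overlap of 10 with one disagreement; the low-quality fwd 'T' loses
        assert merged.sequence == "AAAA" + "T" * 9 + "C" + "GGGG"
        assert merged.quality[13] == "I"

    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_error_free_reads_reconstruct_random_template_exactly(self, seed):
        import numpy as np

        r = np.random.default_rng(seed)
        length = int(r.integers(40, 81))
        read_len = int(r.integers(26, 41))
        template = "".join(r.choice(list("ACGT"), size=length))
        if 2 * read_len - length < 12:
            return  # mates would not overlap
        fwd = template[:read_len]
        rev = revcomp(template[-read_len:])
        spec = AmpliconSpec("t", "AAAA", "TTTT", expected_length=length)
        merged = merge_pair(_pair(fwd, rev), spec)
        assert merged is not None
        assert merged.sequence == template
        assert max(read_len, length) <= len(merged.sequence) <= 2 * read_len - 12


def test_preprocess_accounts_for_every_pair():
    manifest = _manifest()
    insert = "CCCCGGGGCCGGCCGG"[: SHORT_SPEC.expected_length - 8]
    good = _pair(BC1 + "AAAA" + insert[:10], BC1 + "TTTT" + revcomp(insert)[:10])
    bad_bc = _pair("GGGGGGGG" + "AAAA" + insert, BC1 + "TTTT" + insert)
    bad_primer = _pair(BC1 + "CCCC" + insert, BC1 + "GGGG" + insert)
    pools, counts = preprocess_pairs([good, bad_bc, bad_primer], manifest, min_overlap=4)
    assert counts.total == 3
    assert counts.unassigned == 1
    assert counts.rejected_primer == 1
    assert counts.merged + counts.njoined + counts.rejected_merge == 1
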