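"""Demultiplexing, adapter trimming, alignment and stop counting."""

import numpy as np
import pytest

from shapeseq import (
    Alignment,
    ReadPair,
    TargetRNA,
    align_fragment,
    count_stops,
    demultiplex_by_handle,
    trim_adapter,
)
from shapeseq.reads import DEFAULT_ADAPTER


def pair(r1, r2="", rid="r", handle=""):
    return ReadPair(id=rid, r1_seq=r1, r2_seq=r2, handle_seq=handle)


class TestDemultiplex:
    @pytest.mark.parametrize(
        "prefix, expected",
        [
            ("AGAC", "plus"),     # A,G,A are R; C is Y
            ("TCTG", "minus"),    # T,C,T are Y; G is R
            ("ACGT", "unassigned"),  # breaks RRRY at 2 and YYYR at 1
        ],
    )
    def test_channel_assignment(self, prefix, expected):
        channel, _ = demultiplex_by_handle(pair(prefix + "GGAACC"))
        assert channel == expected

    def test_handle_removed_and_recorded(self):
        channel, stripped = demultiplex_by_handle(pair("AGACGGAACC"))
        assert channel == "plus"
        assert stripped.r1_seq == "GGAACC"
        assert stripped.handle_seq == "AGAC"

    def test_swapping_handles_swaps_labels(self):
        for prefix in ("AGAC", "TCTG", "GGGC", "TTCG"):
            fwd, _ = demultiplex_by_handle(pair(prefix + "GG"), "RRRY", "YYYR")
            rev, _ = demultiplex_by_handle(pair(prefix + "GG"), "YYYR", "RRRY")
            flip = {"plus": "minus", "minus": "plus",
                    "unassigned": "unassigned"}
            assert rev == flip[fwd]

    def test_handle_longer_than_read_is_error(self):
        with pytest.raises(ValueError, match="handle length"):
            demultiplex_by_handle(pair("AG"), "RRRY", "YYYR")


class TestTrimAdapter:
    adapter = "AGATCGGAAGAGC"

    def test_exact_readthrough_removed(self):
        assert trim_adapter("GGAACC" + self.adapter[:10], self.adapter,
                            min_overlap=4) == "GGAACC"

    def test_no_adapter_content_unchanged(self):
        assert trim_adapter("GGAACCUUGG", self.adapter, min_overlap=4) == \
            "GGAACCUUGG"

    def test_overlap_below_threshold_unchanged(self):
        seq = "GGAACC" + self.adapter[:3]
        assert trim_adapter(seq, self.adapter, min_overlap=4) == seq

    def test_mismatch_rate_allows_sequencing_error(self):
        readthrough = "AGATCGGAAGAGC"
        corrupted = readthrough[:5] + "T" + readthrough[6:]
        seq = "GGAACC" + corrupted
        assert trim_adapter(seq, self.adapter, 4, max_mismatch_rate=0.1) == \
            "GGAACC"
        assert trim_adapter(seq, self.adapter, 4, max_mismatch_rate=0.0) != \
            "GGAACC"


class TestAlignFragment:
    target = TargetRNA(name="x", sequence="GGAACC", linker="")

    def test_internal_fragment_stop_convention(self):
        # fragment = positions 3..6 -> RT's last base at 3, stop site k = 2
        aln = align_fragment(pair("AACC"), [self.target])
        assert (aln.status, aln.stop_index) == ("aligned", 2)
        assert not aln.full_length

    def test_full_length_readthrough(self):
        aln = align_fragment(pair("GGAACC"), [self.target])
        assert (aln.status, aln.stop_index) == ("aligned", 0)
        assert aln.full_length

    def test_repetitive_match_is_ambiguous(self):
        t = TargetRNA(name="rep", sequence="ACACAC", linker="")
        assert align_fragment(pair("AC"), [t]).status == "ambiguous"

    def test_unaligned(self):
        assert align_fragment(pair("UUUU"), [self.target]).status == "unaligned"

    def test_empty_target_set_is_error(self):
        with pytest.raises(ValueError, match="empty target set"):
            align_fragment(pair("AACC"), [])

    def test_r2_inconsistency_rejects(self):
        # R2 should read the fragment from the 3' side; a wrong R2 kills it
        good = align_fragment(pair("AACC", r2="GGUU"), [self.target])
        bad = align_fragment(pair("AACC", r2="AAAA"), [self.target])
        assert good.status == "aligned"
        assert bad.status == "unaligned"

    def test_linker_extends_alignable_range(self):
        t = TargetRNA(name="lnk", sequence="GGAACC", linker="CACTCGGG")
        # fragment covers positions 4..6 then runs into the linker
        aln = align_fragment(pair("ACCCACU"), [t])
        assert (aln.status, aln.stop_index) == ("aligned", 3)

    def test_untrimmable_adapter_remnant_soft_clipped(self):
        t = TargetRNA(name="lnk", sequence="GGAACC", linker="CACU")
        remnant = DEFAULT_ADAPTER[:2]  # below any sensible min_overlap
        aln = align_fragment(pair("ACCCACU" + remnant), [t], max_overhang=3)
        assert (aln.status, aln.stop_index) == ("aligned", 3)

    def test_hamming_tolerance(self):
        aln = align_fragment(pair("AACG"), [self.target], max_mismatches=1,
                             max_overhang=0)
        assert (aln.status, aln.stop_index) == ("aligned", 2)


class TestCountStops:
    def test_tally(self):
        t = TargetRNA(name="x", sequence="GGA", linker="")
        alns = [Alignment("aligned", "x", None, k) for k in (0, 0, 2)]
        vec = count_stops(alns, t, "plus", exclude_3prime_terminal=True)
        assert vec.counts.tolist() == [2, 0, 1, 0]
        assert vec.total == 3

    def test_empty_stream_all_zero(self):
        t = TargetRNA(name="x", sequence="GGA", linker="")
        vec = count_stops([], t, "minus")
        assert vec.counts.tolist() == [0, 0, 0, 0]

    def test_terminal_exclusion_zeroes_index_L(self):
        t = TargetRNA(name="x", sequence="GGA", linker="")
        alns = [Alignment("aligned", "x", None, 3)]
        on = count_stops(alns, t, "plus", exclude_3prime_terminal=True)
        off = count_stops(alns, t, "plus", exclude_3prime_terminal=False)
        assert on.counts[3] == 0
        assert off.counts[3] == 1
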