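"""Junction location and 3'-anchored fusion extraction."""

import numpy as np
import pytest
from Bio.Seq import Seq

from metasecretome.frames import (AlphabetError, AmbiguousJunctionError,
                                  DEFAULT_CASSETTE, JunctionNotFoundError,
                                  VectorCassette, enumerate_orfs,
                                  extract_fusion_orf, locate_junction,
                                  open_run_bounds, revcomp)

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_run(insert: str, frame_offset: int) -> tuple[int, int]:
    """Independent oracle: translate the whole 3'-anchored frame and anchor
    the run after the last stop symbol."""
    end = len(insert) - frame_offset
    frame = end % 3
    aa = str(Seq(insert[frame:end]).translate(table=11))
    last_stop = aa.rfind("*")
    return frame + 3 * (last_stop + 1), end


class TestLocateJunction:
    def test_read_spanning_both_joints(self):
        insert = "ACGT" * 30
        read = (DEFAULT_CASSETTE.upstream_flank + insert
                + DEFAULT_CASSETTE.downstream_flank)
        j = locate_junction(read, DEFAULT_CASSETTE)
        assert not j.reverse
        assert j.extract(read) == insert

    def test_read_without_flanks_raises(self):
        with pytest.raises(JunctionNotFoundError):
            locate_junction("ACGT" * 20, DEFAULT_CASSETTE)

    def test_three_prime_only_read(self):
        # a sequencing read primed from the pIII side covers only the 3' joint
        insert = "GATTACAGGT" * 30
        read = insert + DEFAULT_CASSETTE.downstream_flank[:20]
        j = locate_junction(read, DEFAULT_CASSETTE)
        assert (j.start, j.end) == (0, 300)

    def test_reverse_orientation_read(self):
        insert = "ACGTTGCAAC" * 30
        read = revcomp(insert + DEFAULT_CASSETTE.downstream_flank[:20])
        j = locate_junction(read, DEFAULT_CASSETTE)
        assert j.reverse
        assert j.extract(read) == insert

    def test_anchors_in_both_orientations_are_ambiguous(self):
        a = DEFAULT_CASSETTE.downstream_flank[:15]
        read = a + "ACGT" * 10 + revcomp(a)
        with pytest.raises(AmbiguousJunctionError):
            locate_junction(read, DEFAULT_CASSETTE)


class TestExtractFusionOrf:
    def test_short_open_run_is_background(self):
        # 12 nt, stop-free: a 4-codon run is far below the 24-aa minimum
        assert extract_fusion_orf("GGGTTTAAACCC") is None

    def test_stop_free_insert_in_piii_frame(self):
        insert = "GGTGCTACT" * 10  # 90 nt, stop-free in every frame
        fo = extract_fusion_orf(insert)
        assert fo is not None
        assert fo.length_aa == 30
        assert fo.in_frame_with_piii
        assert fo.nt_end == 90 and fo.nt_start == 0
        assert "*" not in fo.aa_seq

    def test_stop_near_junction_truncates_run(self):
        insert = "GGTGCTACT" * 9 + "TAA" + "GGTGCT" * 2  # stop 4 codons out
        assert extract_fusion_orf(insert) is None

    def test_strict_mode_requires_initiation_codon(self):
        insert = "GGT" * 30
        assert extract_fusion_orf(insert, min_fusion_len=24) is not None
        assert extract_fusion_orf(insert, min_fusion_len=24,
                                  require_start=True) is None
        with_atg = "GGT" * 4 + "ATG" + "GGT" * 25
        fo = extract_fusion_orf(with_atg, min_fusion_len=24,
                                require_start=True)
        assert fo is not None and fo.aa_seq.startswith("M")

    def test_ambiguity_codes_rejected(self):
        with pytest.raises(AlphabetError):
            extract_fusion_orf("ATGNNN" * 10)

    @pytest.mark.parametrize("frame_offset", [0, 1, 2])
    def test_open_run_agrees_with_translation_oracle(self, frame_offset):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = int(rng.integers(30, 120))
            insert = "".join(rng.choice(list("ACGT"), n))
            cassette = VectorCassette("ATGGCT", "GGTTCTGGT",
                                      frame_offset=frame_offset)
            got = open_run_bounds(insert, frame_offset)
            assert got == brute_force_run(insert, frame_offset)
            fo = extract_fusion_orf(insert, cassette, min_fusion_len=1)
            if fo is not None:
                assert (fo.nt_start, fo.nt_end) == got
                assert "*" not in fo.aa_seq

    def test_fusion_is_suffix_of_an_enumerated_orf(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            insert = "".join(rng.choice(list("ACGT"), 90))
            fo = extract_fusion_orf(insert, min_fusion_len=1)
            if fo is None:
                continue
            spans = [s for s in enumerate_orfs(insert)
                     if s.strand == "+" and s.frame == fo.nt_start % 3]
            assert any(s.start <= fo.nt_start and fo.nt_end <= s.end + 3
                       for s in spans)


class TestEnumerateOrfs:
    def test_stop_free_sequence_has_one_run_per_frame(self):
        # poly-A is stop-free on both strands (K codons forward, F reverse)
        spans = enumerate_orfs("A" * 60, min_len_aa=1)
        assert len(spans) == 6

    def test_all_stop_sequence_has_no_runs(self):
        frame0 = [s for s in enumerate_orfs("TAATAATAA", min_len_aa=1)
                  if s.strand == "+" and s.frame == 0]
        assert frame0 == []

    def test_agrees_with_quadratic_scan_oracle(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        spans = enumerate_orfs(seq, min_len_aa=1)
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            for frame in range(3):
                expected = []
                run_start = frame
                for pos in range(frame, len(oriented) - 2, 3):
                    if oriented[pos:pos + 3] in STOPS:
                        if pos > run_start:
                            expected.append((run_start, pos))
                        run_start = pos + 3
                tail_end = frame + (len(oriented) - frame) // 3 * 3
                if tail_end > run_start:
                    expected.append((run_start, tail_end))
                got = [(s.start, s.end) for s in spans
                       if s.strand == strand and s.frame == frame]
                assert got == expected
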