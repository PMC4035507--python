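"""Synthetic community, shearing/cloning, and mock annotation tables."""

import numpy as np
import pytest
from Bio.Seq import Seq

from metasecretome.cazymes import classify_cellulosome, filter_hits, DomainHit
from metasecretome.frames import revcomp
from metasecretome.signals import SignalCategory
from metasecretome.synth import (CommunitySizingError, HitPlan, RUMEN_LINEAGES,
                                 emit_mock_blast_hits, emit_mock_domain_hits,
                                 generate_community, shear_and_clone)
from metasecretome.taxonomy import assign_taxa, rank_rollup
from metasecretome.io import read_blast_tab, write_blast_tab


class TestGenerateCommunity:
    def test_exact_secretome_count(self):
        com = generate_community(1, 100, 0.20, seed=42)
        assert len(com.secretome_orfs()) == 20

    def test_zero_fraction_has_no_secretome(self):
        com = generate_community(1, 100, 0.0, seed=7)
        assert com.secretome_orfs() == []

    def test_impossible_geometry_raises(self):
        with pytest.raises(CommunitySizingError):
            generate_community(10, 5, 0.2, seed=0)
        with pytest.raises(CommunitySizingError):
            generate_community(1, 100, 0.2, seed=0,
                               replicon_length_budget=1000)

    def test_deterministic_for_fixed_seed(self):
        a = generate_community(2, 60, 0.2, seed=5)
        b = generate_community(2, 60, 0.2, seed=5)
        assert a.replicons == b.replicons
        assert a.orfs == b.orfs

    def test_orf_annotations_match_replicon_sequence(self, community):
        seqs = dict(community.replicons)
        for orf in community.orfs:
            assert (orf.end - orf.start) % 3 == 0
            cds = seqs[orf.replicon_id][orf.start:orf.end]
            translated = str(Seq(cds).translate(table=11))
            assert translated == orf.protein + "*"

    def test_every_orf_has_ground_truth_category(self, community):
        assert all(isinstance(o.signal_category, SignalCategory)
                   for o in community.orfs)


class TestShearAndClone:
    def test_orientation_is_a_fair_coin(self, clone_library):
        n_fwd = sum(c.orientation == "forward" for c in clone_library)
        n = len(clone_library)
        assert abs(n_fwd / n - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_degenerate_length_distribution(self, community):
        clones = shear_and_clone(community, 50, len_min=300, len_max=300,
                                 seed=3)
        assert {len(c.insert) for c in clones} == {300}

    def test_lengths_within_configured_range(self, clone_library):
        lengths = [len(c.insert) for c in clone_library]
        assert min(lengths) >= 700 and max(lengths) <= 5000

    def test_same_seed_gives_identical_clone_set(self, community):
        a = shear_and_clone(community, 100, seed=8)
        b = shear_and_clone(community, 100, seed=8)
        assert a == b

    def test_reverse_clone_is_reverse_complement_of_source(self, community):
        seqs = dict(community.replicons)
        for c in shear_and_clone(community, 200, seed=4):
            g = len(seqs[c.replicon_id])
            frag = (seqs[c.replicon_id][c.src_start:]
                    + seqs[c.replicon_id][:c.src_end - g]) \
                if c.src_end > g else \
                seqs[c.replicon_id][c.src_start:c.src_end]
            expected = frag if c.orientation == "forward" else revcomp(frag)
            assert c.insert == expected

    def test_truth_flags_require_forward_in_frame_junction(self, community):
        orfs = {o.orf_id: o for o in community.orfs}
        for c in shear_and_clone(community, 500, seed=6):
            if c.truth_in_frame:
                assert c.orientation == "forward"
                orf = orfs[c.src_orf_id]
                junction = c.src_end % len(dict(community.replicons)[c.replicon_id])
                assert (junction - orf.start) % 3 == 0
                assert junction - orf.start >= 72
            if c.truth_secretome:
                assert c.truth_in_frame

    def test_community_shorter_than_len_max_raises(self):
        tiny = generate_community(1, 5, 0.2, seed=0)
        with pytest.raises(CommunitySizingError):
            shear_and_clone(tiny, 10, len_min=700, len_max=50_000, seed=0)


class TestMockDomainHits:
    def test_planted_dockerin_pairs_are_recovered(self):
        ids = [f"orf{i}" for i in range(30)]
        df = emit_mock_domain_hits(ids, {"dockerin": HitPlan(10, hits_per_orf=2)},
                                   seed=1)
        hits = [DomainHit(**row) for row in df.to_dict("records")]
        calls = classify_cellulosome(filter_hits(hits))
        assert sum(c.kind == "complete_dockerin" for c in calls) == 10

    def test_sub_threshold_decoys_are_filtered_out(self):
        ids = [f"orf{i}" for i in range(10)]
        df = emit_mock_domain_hits(
            ids, {"GH5": HitPlan(5, evalue=1e-2, aln_len=50)}, seed=2)
        hits = [DomainHit(**row) for row in df.to_dict("records")]
        assert filter_hits(hits) == []

    def test_empty_composition_gives_empty_table(self):
        df = emit_mock_domain_hits(["a"], {}, seed=0)
        assert df.empty and list(df.columns)

    def test_unknown_family_tag_raises(self):
        with pytest.raises(ValueError):
            emit_mock_domain_hits(["a"], {"mystery9": 1}, seed=0)

    def test_requesting_more_orfs_than_proteins_raises(self):
        with pytest.raises(ValueError):
            emit_mock_domain_hits(["a", "b"], {"GH5": 3}, seed=0)


class TestMockBlastHits:
    def test_planted_assignments_are_recovered(self):
        queries = [f"q{i}" for i in range(40)]
        df, truth = emit_mock_blast_hits(queries, seed=3)
        hits = [h for h in read_blast_tab_df(df)]
        assignments = assign_taxa(hits, RUMEN_LINEAGES)
        assert len(assignments) == 40
        for a in assignments:
            assert a.status == "assigned"
            assert ";".join(a.lineage) == RUMEN_LINEAGES[truth[a.query_id]]

    def test_low_identity_hits_roll_up_as_unassigned(self):
        queries = [f"q{i}" for i in range(20)]
        df, _ = emit_mock_blast_hits(queries, seed=4, identity=25.0,
                                     n_decoys=0)
        assignments = assign_taxa(read_blast_tab_df(df), RUMEN_LINEAGES)
        rollup = rank_rollup(assignments, "phylum", identity_min_pct=30.0)
        assert rollup.set_index("taxon")["pct"].to_dict() == {
            "Unassigned": 100.0}

    def test_empty_queries_give_empty_table(self):
        df, truth = emit_mock_blast_hits([], seed=0)
        assert df.empty and truth == {}


def read_blast_tab_df(df, tmp_path=None):
    """Round-trip the mock table through the tabular format reader."""
    import tempfile
    from pathlib import Path
    with tempfile.TemporaryDirectory() as d:
        path = Path(d) / "hits.tsv"
        write_blast_tab(df, path)
        return read_blast_tab(path)
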