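"""Domain-hit filtering, containment dedup, cellulosome calls, class rollup."""

import pytest
from hypothesis import given, strategies as st

from metasecretome.cazymes import (CellulosomeCall, DomainHit, Clusters,
                                   classify_cellulosome, dedup_sequences,
                                   family_class, filter_hits, rollup_classes)
from metasecretome.model import ModelParams


def hit(orf="orf1", family="GH5", aln=100, evalue=1e-10, bits=100.0):
    return DomainHit(orf_id=orf, family=family, aln_len=aln, evalue=evalue,
                     bitscore=bits, env_from=1, env_to=aln)


class TestFamilyClass:
    @pytest.mark.parametrize("family,cls", [
        ("GH5", "GH"), ("GT2", "GT"), ("CBM40", "CBM"), ("AA3", "AA"),
        ("PL11", "PL"), ("CE1", "CE"), ("dockerin", "dockerin"),
        ("Dockerins", "dockerin"), ("cohesin", "cohesin"), ("SLH", "SLH"),
        ("SLH_2", "SLH"), ("dockerin.hmm", "dockerin"),
    ])
    def test_recognised_tags(self, family, cls):
        assert family_class(family) == cls

    def test_unknown_tag_raises(self):
        with pytest.raises(ValueError):
            family_class("XYZ99")


class TestFilterHits:
    @pytest.mark.parametrize("aln,evalue,kept", [
        (100, 1e-6, True),   # long alignment, strict E-value branch
        (50, 1e-4, True),    # short alignment, relaxed branch
        (100, 1e-4, False),  # long alignments get no relaxed branch
        (80, 5e-4, True),    # boundary: 80 aa is not "> 80"
        (81, 5e-4, False),
        (81, 1e-6, True),
        (50, 5e-3, False),
    ])
    def test_two_branch_rule(self, aln, evalue, kept):
        hits = [hit(aln=aln, evalue=evalue)]
        assert (filter_hits(hits) == hits) is kept

    def test_preserves_input_order(self):
        hits = [hit(orf=f"o{i}", evalue=1e-10) for i in range(5)]
        assert filter_hits(hits) == hits

    @given(st.lists(st.tuples(st.integers(10, 200),
                              st.floats(1e-30, 1e-1)), max_size=30),
           st.floats(1e-8, 1e-4), st.floats(1e-6, 1e-2))
    def test_tightening_cutoffs_never_adds_hits(self, rows, strict, relaxed):
        hits = [hit(orf=f"o{i}", aln=a, evalue=e)
                for i, (a, e) in enumerate(rows)]
        loose = ModelParams()
        strict_p = ModelParams(
            evalue_strict=min(strict, loose.evalue_strict),
            evalue_relaxed=min(max(relaxed, 2 * strict),
                               loose.evalue_relaxed))
        assert set(h.orf_id for h in filter_hits(hits, strict_p)) <= \
            set(h.orf_id for h in filter_hits(hits, loose))


class TestDedupSequences:
    def test_identical_sequences_share_a_cluster(self):
        assert len(dedup_sequences({"a": "MKA", "b": "MKA"})) == 1

    def test_substring_containment_joins_cluster_with_longest_rep(self):
        clusters = dedup_sequences({"short": "MKA", "long": "MKAT"})
        assert clusters.representative_of == {"short": "long",
                                              "long": "long"}

    def test_distinct_sequences_stay_apart(self):
        assert len(dedup_sequences({"a": "MKA", "b": "MRA"})) == 2

    @given(st.lists(st.text(alphabet="MKRT", min_size=1, max_size=8),
                    min_size=1, max_size=12))
    def test_idempotent_and_permutation_invariant(self, seqs):
        items = {f"id{i}": s for i, s in enumerate(seqs)}
        clusters = dedup_sequences(items)
        # permutation invariance
        reversed_items = dict(reversed(list(items.items())))
        assert dedup_sequences(reversed_items).representative_of == \
            clusters.representative_of
        # idempotence: reclustering the representatives changes nothing
        reps = {r: items[r] for r in clusters.representatives}
        again = dedup_sequences(reps)
        assert again.representative_of == {r: r for r in reps}
        # containment oracle: every member is a substring of its rep
        for member, rep in clusters.representative_of.items():
            assert items[member] in items[rep]


class TestClassifyCellulosome:
    def test_two_dockerin_repeats_form_complete_domain(self):
        calls = classify_cellulosome([hit(family="dockerin"),
                                      hit(family="dockerin")])
        assert [c.kind for c in calls] == ["complete_dockerin"]

    def test_repeat_with_catalytic_module(self):
        calls = classify_cellulosome([hit(family="dockerin"),
                                      hit(family="GH5")])
        assert [c.kind for c in calls] == ["repeat_plus_other_module"]

    def test_lone_repeat_and_standalone_modules(self):
        calls = classify_cellulosome([
            hit(orf="a", family="dockerin"), hit(orf="b", family="SLH"),
            hit(orf="c", family="cohesin")])
        assert {c.orf_id: c.kind for c in calls} == {
            "a": "single_dockerin_repeat", "b": "slh", "c": "cohesin"}

    def test_counts_invariant_under_row_duplication_plus_dedup(self):
        hits = [hit(orf="a", family="dockerin"),
                DomainHit("a", "dockerin", 22, 1e-9, 40.0, 30, 51),
                hit(orf="b", family="GH5")]
        base = [(c.orf_id, c.kind) for c in classify_cellulosome(hits)]
        doubled = list(dict.fromkeys(hits * 2))
        assert [(c.orf_id, c.kind)
                for c in classify_cellulosome(doubled)] == base


class TestRollupClasses:
    def test_clustered_dockerin_distribution_from_printed_counts(self):
        # 499 dockerin hits of a 7978-hit clustered total -> 6.25%
        hits = [hit(orf=f"d{i}", family="dockerin", aln=22) for i in range(499)]
        hits += [hit(orf=f"g{i}", family="GH5") for i in range(7978 - 499)]
        table = rollup_classes(hits).table.set_index("class")
        assert table.loc["dockerin", "pct_raw"] == 6.25

    def test_single_class_table_is_100_percent(self):
        table = rollup_classes([hit(family="GH9")]).table.set_index("class")
        assert table.loc["GH", "pct_raw"] == 100.0

    def test_planted_composition_is_recovered(self):
        hits = ([hit(orf=f"a{i}", family="GH5") for i in range(60)]
                + [hit(orf=f"b{i}", family="GT2") for i in range(30)]
                + [hit(orf=f"c{i}", family="cohesin") for i in range(10)])
        t = rollup_classes(hits)
        table = t.table.set_index("class")
        assert t.total_raw == 100
        assert table.loc["GH", "count_raw"] == 60
        assert table.loc["cellulosome", "pct_raw"] == 10.0
        class_rows = t.table[t.table["kind"] == "class"]
        assert class_rows["pct_raw"].sum() == pytest.approx(100.0, abs=0.1)

    def test_clustered_counts_use_representatives_only(self):
        hits = [hit(orf="a", family="GH5"), hit(orf="b", family="GH5")]
        clusters = Clusters(representative_of={"a": "a", "b": "a"})
        t = rollup_classes(hits, clusters).table.set_index("class")
        assert t.loc["GH", "count_raw"] == 2
        assert t.loc["GH", "count_clustered"] == 1
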