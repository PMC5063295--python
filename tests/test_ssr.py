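from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from brute import brute_find_ssrs
from triohet.ssr import (SSRCriteria, SSRLocus, canonical_motif,
                         category_percentages, filter_loci, find_ssrs,
                         is_primitive, mark_compound, mine_transcripts,
                         ssr_summary)


def _loc(start, end, motif, reps, tid="t", compound=False):
    return SSRLocus(tid, start, end, motif, canonical_motif(motif),
                    len(motif), reps, compound=compound)


class TestCanonicalMotif:
    @pytest.mark.parametrize("motif,expected", [
        ("CT", "AG"),   # AG/CT pooled under AG
        ("AT", "AT"),   # its own reverse-complement class
        ("GAT", "ATC"),  # rotations of revcomp win
        ("GA", "AG"),
        ("CTT", "AAG"),
    ])
    def test_known_classes(self, motif, expected):
        assert canonical_motif(motif) == expected

    def test_rejects_non_acgt_and_non_primitive(self):
        with pytest.raises(ValueError):
            canonical_motif("AN")
        with pytest.raises(ValueError):
            canonical_motif("ATAT")

    def test_partition_sizes(self):
        """Exhaustive enumeration: 4 dinucleotide and 10 trinucleotide classes."""
        for size, expected in ((2, 4), (3, 10)):
            motifs = ("".join(m) for m in product("ACGT", repeat=size))
            classes = {canonical_motif(m) for m in motifs if is_primitive(m)}
            assert len(classes) == expected

    @settings(derandomize=True, max_examples=200)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=6))
    def test_idempotent(self, motif):
        if not is_primitive(motif):
            return
        c = canonical_motif(motif)
        assert canonical_motif(c) == c


class TestFindSsrs:
    def test_embedded_tri_repeat(self):
        seq = "G" * 5 + "ATC" * 9 + "G" * 5
        loci = find_ssrs("t", seq)
        assert len(loci) == 1
        l = loci[0]
        assert (l.start, l.end, l.unit_size, l.repeat_count) == (6, 32, 3, 9)
        assert l.total_len_bp == 27

    def test_five_dinucleotide_repeats_rejected(self):
        assert find_ssrs("t", "T" + "CA" * 5 + "G") == []

    def test_primitive_unit_wins(self):
        seq = "C" * 3 + "ACGT" * 6 + "C" * 3
        loci = find_ssrs("t", seq)
        assert len(loci) == 1
        assert loci[0].motif == "ACGT"
        assert loci[0].unit_size == 4

    def test_runs_broken_at_n(self):
        seq = "AT" * 4 + "N" + "AT" * 4
        assert find_ssrs("t", seq) == []
        seq = "AT" * 6 + "N" + "AT" * 6
        loci = find_ssrs("t", seq)
        assert [(l.start, l.end) for l in loci] == [(1, 12), (14, 25)]

    def test_partial_trailing_unit_not_counted(self):
        seq = "G" + "CAT" * 7 + "CA" + "GGG"
        loci = find_ssrs("t", seq)
        assert len(loci) == 1
        assert loci[0].repeat_count == 7
        assert loci[0].end == 1 + 21

    def test_total_len_invariant(self):
        seq = "C" * 4 + "TTAG" * 6 + "C" * 4
        for l in find_ssrs("t", seq):
            assert l.total_len_bp == l.unit_size * l.repeat_count


class TestOracleEquivalence:
    def test_random_sequences_match_brute_force(self, rng):
        crit = SSRCriteria()
        for _ in range(150):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 500)])
            got = [(l.start, l.end, l.motif, l.repeat_count)
                   for l in find_ssrs("t", seq, crit)]
            assert got == brute_find_ssrs(seq, crit)

    def test_ssr_dense_sequences_match_brute_force(self, rng):
        """Sequences salted with planted repeats exercise the non-empty paths."""
        bases = np.array(list("ACGT"))
        for _ in range(80):
            parts = []
            for _ in range(6):
                parts.append("".join(bases[rng.integers(0, 4, 30)]))
                unit = int(rng.integers(2, 7))
                motif = "".join(bases[rng.integers(0, 4, unit)])
                parts.append(motif * int(rng.integers(3, 10)))
            seq = "".join(parts)
            got = [(l.start, l.end, l.motif, l.repeat_count)
                   for l in find_ssrs("t", seq)]
            assert got == brute_find_ssrs(seq)

    @settings(derandomize=True, max_examples=150)
    @given(st.text(alphabet="ACGTN", max_size=120))
    def test_arbitrary_text_matches_brute_force(self, seq):
        got = [(l.start, l.end, l.motif, l.repeat_count)
               for l in find_ssrs("t", seq)]
        assert got == brute_find_ssrs(seq)

    def test_no_retained_loci_overlap(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(30):
            seq = "".join(bases[rng.integers(0, 4, 800)])
            loci = find_ssrs("t", seq)
            for a, b in zip(loci, loci[1:]):
                assert a.end < b.start


class TestCompoundAndFilter:
    def test_nearby_loci_both_compound(self):
        a = _loc(1, 14, "AG", 7)
        b = _loc(20, 35, "TC", 8)
        out = mark_compound([a, b], 100)
        assert out[0].compound and out[1].compound

    def test_distant_loci_not_compound(self):
        a = _loc(1, 14, "AG", 7)
        b = _loc(165, 180, "TC", 8)
        out = mark_compound([a, b], 100)
        assert not out[0].compound and not out[1].compound

    def test_compound_flag_transitive_along_chain(self):
        a, b, c = _loc(1, 12, "AG", 6), _loc(50, 61, "CT", 6), _loc(100, 111, "GA", 6)
        out = mark_compound([a, b, c], 100)
        assert all(l.compound for l in out)

    def test_unsorted_input_errors(self):
        with pytest.raises(ValueError):
            mark_compound([_loc(50, 61, "AG", 6), _loc(1, 12, "CT", 6)], 100)

    def test_type_assignment_and_exclusions(self):
        ca10 = _loc(1, 20, "CA", 10)       # 20 bp -> Type I
        gtt6 = _loc(100, 117, "GTT", 6)    # 18 bp -> Type II
        comp = _loc(200, 211, "AG", 6, compound=True)
        out = filter_loci([ca10, gtt6, comp])
        assert [(l.motif, l.ssr_type) for l in out] == [("CA", "I"), ("GTT", "II")]

    def test_short_total_length_dropped(self):
        crit = SSRCriteria(min_reps_by_unit={2: 4, 3: 5, 4: 5, 5: 5, 6: 5},
                           min_total_len_bp=10)
        out = filter_loci([_loc(1, 8, "AG", 4)], crit)
        assert out == []


class TestSummary:
    def test_category_percentages_from_counts(self):
        df = category_percentages({3: 774, 2: 641, 4: 47, 5: 12, 6: 7})
        by_unit = df.set_index("unit_size")["pct"]
        assert round(by_unit[3], 2) == 52.26
        assert round(by_unit[2], 2) == 43.28
        assert df["pct"].sum() == pytest.approx(100.0)

    def test_single_locus_summary(self):
        s = ssr_summary([_loc(1, 12, "AT", 6)], n_unigenes=1)
        assert s.categories.set_index("unit_size")["pct"][2] == 100.0
        assert s.pct_unigenes_with_ssr == 100.0
        assert s.unigenes_single_locus == 1

    def test_empty_loci_all_zero(self):
        s = ssr_summary([], n_unigenes=5)
        assert s.total_loci == 0 and s.unigenes_with_ssr == 0
        assert len(s.categories) == 0 and len(s.motif_table) == 0

    def test_invalid_unigene_count(self):
        with pytest.raises(ValueError):
            ssr_summary([], 0)

    def test_motif_table_pools_canonical_classes(self):
        loci = [_loc(1, 12, "AG", 6), _loc(100, 111, "CT", 6)]
        s = ssr_summary(loci, 2)
        assert list(s.motif_table["canonical_motif"]) == ["AG"]
        assert list(s.motif_table["count"]) == [2]


def test_embedded_truth_ssrs_recovered(small_sim):
    """Every embedded truth SSR is found by the scanner under its canonical
    motif with at least as many reiterations.

    Flanking bases that happen to extend the tract can shift the maximal
    run's phase, so the reported span may start earlier and, because only
    whole units count, may forfeit up to unit_size-1 bases at the right end.
    """
    cfg, reference, truth_ssrs, _ = small_sim
    assert truth_ssrs, "fixture should embed some SSRs"
    for t in truth_ssrs:
        loci = find_ssrs(t.transcript_id, reference[t.transcript_id])
        hits = [l for l in loci
                if l.start <= t.start and l.end >= t.end - (t.unit_size - 1)
                and l.canonical_motif == t.canonical_motif
                and l.repeat_count >= t.repeat_count]
        assert hits, f"embedded SSR not recovered: {t}"


def test_mine_transcripts_returns_filtered_typed_loci(small_sim):
    cfg, reference, _, _ = small_sim
    mined = mine_transcripts(reference)
    assert mined
    for l in mined:
        assert not l.compound
        assert l.ssr_type == ("I" if l.total_len_bp >= 20 else "II")
        assert l.total_len_bp >= 10
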