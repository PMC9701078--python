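"""Tests for read trimming, marker selection, assignment and composition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vagchip.strain_composition import (
    MarkerGeneSet,
    MarkerSelectionParams,
    QualityRead,
    StrainGeneSet,
    assign_reads,
    cross_match,
    estimate_composition,
    per_gene_coverage,
    read_sam_coverage,
    reverse_complement,
    select_marker_genes,
    trim_read_sliding_window,
)
from conftest import random_reads

BASES = np.array(list("ACGT"))


def brute_force_trim(quals, window, min_q):
    """Independent oracle: check every window by direct enumeration."""
    n = len(quals)
    if n == 0:
        return 0
    if n < window:
        return 0 if sum(quals) / n < min_q else n
    for i in range(n - window + 1):
        if sum(quals[i:i + window]) / window < min_q:
            return i
    return n


def rand_seq(rng, n):
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(rng, seq, n_subs):
    arr = list(seq)
    for i in rng.choice(len(arr), size=n_subs, replace=False):
        arr[i] = BASES[(int(np.searchsorted(BASES, arr[i])) + 1) % 4]
    return "".join(arr)


class TestTrimming:
    def test_clean_read_unchanged(self):
        r = QualityRead("r", "ACGTACGTAC", (30,) * 10)
        assert trim_read_sliding_window(r, min_len=1) is r

    def test_worked_example_cuts_at_first_failing_window(self):
        r = QualityRead("r", "ACGTACGT", (30, 30, 30, 30, 10, 10, 10, 10))
        out = trim_read_sliding_window(r, min_len=1)
        assert len(out) == 3
        assert out.sequence == r.sequence[:3]

    def test_short_read_single_window_convention(self):
        good = QualityRead("a", "ACG", (30, 30, 30))
        bad = QualityRead("b", "ACG", (10, 10, 10))
        assert trim_read_sliding_window(good, min_len=1) is good
        assert trim_read_sliding_window(bad, min_len=1) is None

    def test_min_length_drop(self):
        r = QualityRead("r", "ACGTACGT", (30, 30, 30, 30, 10, 10, 10, 10))
        assert trim_read_sliding_window(r, min_len=4) is None

    def test_oracle_agreement_on_random_reads(self):
        rng = np.random.default_rng(42)
        for read in random_reads(rng, 500):
            expect = brute_force_trim(list(read.qualities), 4, 20.0)
            got = trim_read_sliding_window(read, min_len=0)
            got_len = 0 if got is None else len(got)
            # min_len=0 keeps empty results distinguishable from drops
            assert got_len == expect, read.qualities

    @given(st.lists(st.integers(2, 40), min_size=1, max_size=60),
           st.integers(1, 6))
    @settings(max_examples=200, deadline=None)
    def test_output_is_prefix_property(self, quals, window):
        seq = "A" * len(quals)
        r = QualityRead("r", seq, tuple(quals))
        out = trim_read_sliding_window(r, window_bp=window, min_len=0)
        expect = brute_force_trim(quals, window, 20.0)
        assert (0 if out is None else len(out)) == expect
        if out is not None:
            assert r.sequence.startswith(out.sequence)
            assert r.qualities[:len(out)] == out.qualities

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            QualityRead("r", "ACGT", (30, 30))


class TestCrossMatch:
    def test_identical_sequences_match(self):
        rng = np.random.default_rng(0)
        s = rand_seq(rng, 100)
        assert cross_match(s, s)

    def test_low_identity_rejected(self):
        rng = np.random.default_rng(1)
        a = rand_seq(rng, 100)
        b = mutate(rng, a, 40)  # 60% identity, uniform mismatches
        assert not cross_match(a, b)

    def test_high_identity_full_length_matches(self):
        rng = np.random.default_rng(2)
        a = rand_seq(rng, 100)
        b = mutate(rng, a, 15)  # 85% identity
        assert cross_match(a, b)

    def test_short_shared_block_fails_overlap(self):
        # equal lengths: shared 60 bp identical block out of 100 bp covers
        # only 60% of the shorter sequence, below the 70% overlap threshold
        rng = np.random.default_rng(3)
        a = rand_seq(rng, 100)
        b = a[:60] + rand_seq(rng, 40)
        assert not cross_match(a, b)

    def test_substring_overlap_depends_on_denominator(self):
        # a perfect 60 bp substring covers 100% of the shorter sequence but
        # only 60% of the longer one
        rng = np.random.default_rng(4)
        a = rand_seq(rng, 100)
        sub = a[20:80]
        assert cross_match(a, sub)
        assert not cross_match(
            a, sub, MarkerSelectionParams(overlap_denominator="longer"))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cross_match("", "ACGT")


class TestMarkerSelection:
    def test_disjoint_gene_sets_all_markers(self):
        rng = np.random.default_rng(5)
        strains = [
            StrainGeneSet("s1", tuple((f"g{i}", rand_seq(rng, 300))
                                      for i in range(4))),
            StrainGeneSet("s2", tuple((f"g{i}", rand_seq(rng, 300))
                                      for i in range(4))),
        ]
        markers = select_marker_genes(strains)
        assert [len(m.markers) for m in markers] == [4, 4]

    def test_within_strain_duplicate_excluded(self):
        rng = np.random.default_rng(6)
        g = rand_seq(rng, 300)
        dup = mutate(rng, g, 15)  # 95% identity copy
        strains = [StrainGeneSet("s1", (("g1", g), ("g2", dup),
                                        ("g3", rand_seq(rng, 300))))]
        markers = select_marker_genes(strains)
        assert dict(markers[0].markers).keys() == {"g3"}

    def test_cross_strain_shared_gene_excluded_from_both(self):
        rng = np.random.default_rng(7)
        shared = rand_seq(rng, 300)
        strains = [
            StrainGeneSet("s1", (("a1", shared),
                                 ("a2", rand_seq(rng, 300)))),
            StrainGeneSet("s2", (("b1", mutate(rng, shared, 45)),  # 85% id
                                 ("b2", rand_seq(rng, 300)))),
        ]
        markers = select_marker_genes(strains)
        assert dict(markers[0].markers).keys() == {"a2"}
        assert dict(markers[1].markers).keys() == {"b2"}

    def test_uniqueness_is_symmetric(self):
        # copying a gene of strain T into strain S removes it from T's markers
        rng = np.random.default_rng(8)
        t_gene = rand_seq(rng, 300)
        base = [
            StrainGeneSet("S", (("s1", rand_seq(rng, 300)),)),
            StrainGeneSet("T", (("t1", t_gene),)),
        ]
        before = select_marker_genes(base)
        assert dict(before[1].markers).keys() == {"t1"}
        with pytest.warns(UserWarning):
            after = select_marker_genes([
                StrainGeneSet("S", (("s1", base[0].genes[0][1]),
                                    ("s_copy", t_gene))),
                base[1],
            ])
        assert dict(after[1].markers) == {}

    def test_empty_marker_set_warns_and_is_retained(self):
        rng = np.random.default_rng(9)
        g = rand_seq(rng, 300)
        strains = [StrainGeneSet("s1", (("g1", g),)),
                   StrainGeneSet("s2", (("h1", g),))]
        with pytest.warns(UserWarning):
            markers = select_marker_genes(strains)
        assert [m.strain_id for m in markers] == ["s1", "s2"]
        assert all(m.markers == () for m in markers)


def two_strain_markers(rng):
    return [
        MarkerGeneSet("s1", (("g1", rand_seq(rng, 300)),)),
        MarkerGeneSet("s2", (("g2", rand_seq(rng, 300)),)),
    ]


class TestAssignment:
    def test_verbatim_read_assigned(self):
        rng = np.random.default_rng(10)
        markers = two_strain_markers(rng)
        seq = markers[0].markers[0][1][50:200]
        reads = [QualityRead("r1", seq, (35,) * len(seq)),
                 QualityRead("r2", reverse_complement(seq),
                             (35,) * len(seq))]
        res = assign_reads(reads, markers)
        assert res.counts[("s1", "g1")] == 2
        assert res.n_assigned == 2

    def test_random_read_unassigned(self):
        rng = np.random.default_rng(11)
        markers = two_strain_markers(rng)
        seq = rand_seq(rng, 150)
        res = assign_reads([QualityRead("r", seq, (35,) * 150)], markers)
        assert res.n_unassigned == 1
        assert res.unassigned_fraction == 1.0

    def test_multi_strain_collision_discarded(self):
        rng = np.random.default_rng(12)
        shared_kmer = rand_seq(rng, 40)
        markers = [
            MarkerGeneSet("s1", (("g1", rand_seq(rng, 130) + shared_kmer
                                  + rand_seq(rng, 130)),)),
            MarkerGeneSet("s2", (("g2", rand_seq(rng, 130) + shared_kmer
                                  + rand_seq(rng, 130)),)),
        ]
        res = assign_reads(
            [QualityRead("r", shared_kmer + rand_seq(rng, 60), (35,) * 100)],
            markers)
        assert res.n_ambiguous == 1
        assert res.n_assigned == 0

    def test_read_shorter_than_k_unassignable(self):
        rng = np.random.default_rng(13)
        markers = two_strain_markers(rng)
        res = assign_reads([QualityRead("r", "ACGT", (35,) * 4)], markers)
        assert res.n_unassigned == 1


class TestCoverageAndComposition:
    def test_coverage_arithmetic(self):
        table = per_gene_coverage({("s", "g"): 10}, {("s", "g"): 1500},
                                  read_length=150)
        assert table.coverage_x.iloc[0] == pytest.approx(1.0)

    def test_coverage_zero_and_linearity(self):
        lengths = {("s", "g"): 1000}
        assert per_gene_coverage({}, lengths).coverage_x.iloc[0] == 0.0
        c1 = per_gene_coverage({("s", "g"): 5}, lengths).coverage_x.iloc[0]
        c2 = per_gene_coverage({("s", "g"): 10}, lengths).coverage_x.iloc[0]
        assert c2 == pytest.approx(2 * c1)

    def test_single_strain_abundance_one(self):
        table = per_gene_coverage({("s", "g"): 7}, {("s", "g"): 700})
        comp = estimate_composition(table)
        assert comp.relative_abundance.iloc[0] == pytest.approx(1.0)

    def test_hand_computed_medians(self):
        rows = [("A", f"a{i}", 100, 0, c) for i, c in enumerate((10, 12, 14))]
        rows += [("B", f"b{i}", 100, 0, c) for i, c in enumerate((4, 6, 8))]
        table = pd.DataFrame(rows, columns=["strain_id", "gene_id",
                                            "length_bp", "reads",
                                            "coverage_x"])
        comp = estimate_composition(table).set_index("strain_id")
        assert comp.loc["A", "median_coverage"] == 12
        assert comp.loc["A", "relative_abundance"] == pytest.approx(2 / 3)
        assert comp.loc["B", "relative_abundance"] == pytest.approx(1 / 3)

    def test_even_marker_count_uses_central_mean(self):
        rows = [("A", f"a{i}", 100, 0, c) for i, c in enumerate((1, 2, 4, 10))]
        table = pd.DataFrame(rows, columns=["strain_id", "gene_id",
                                            "length_bp", "reads",
                                            "coverage_x"])
        comp = estimate_composition(table)
        assert comp.median_coverage.iloc[0] == pytest.approx(3.0)

    def test_symmetry_four_identical_strains(self):
        rows = [(s, f"{s}g{i}", 100, 0, c)
                for s in "ABCD" for i, c in enumerate((5, 6, 7))]
        table = pd.DataFrame(rows, columns=["strain_id", "gene_id",
                                            "length_bp", "reads",
                                            "coverage_x"])
        comp = estimate_composition(table)
        assert np.allclose(comp.relative_abundance, 0.25)

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, factor):
        rows = [("A", "a", 100, 0, 9.0), ("B", "b", 100, 0, 3.0)]
        table = pd.DataFrame(rows, columns=["strain_id", "gene_id",
                                            "length_bp", "reads",
                                            "coverage_x"])
        base = estimate_composition(table).relative_abundance.to_numpy()
        scaled = table.assign(coverage_x=table.coverage_x * factor)
        got = estimate_composition(scaled).relative_abundance.to_numpy()
        assert np.allclose(base, got)

    def test_permutation_invariance(self):
        rows = [("A", "a", 100, 0, 9.0), ("B", "b", 100, 0, 3.0),
                ("C", "c", 100, 0, 6.0)]
        table = pd.DataFrame(rows, columns=["strain_id", "gene_id",
                                            "length_bp", "reads",
                                            "coverage_x"])
        fwd = estimate_composition(table)
        rev = estimate_composition(table.iloc[::-1])
        pd.testing.assert_frame_equal(fwd, rev)

    def test_no_signal_flagged(self):
        table = per_gene_coverage({}, {("s", "g"): 100, ("t", "h"): 100})
        comp = estimate_composition(table)
        assert comp.attrs["no_signal"]
        assert comp.relative_abundance.isna().all()

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_composition(pd.DataFrame(columns=["strain_id",
                                                       "coverage_x",
                                                       "gene_id"]))


class TestSamCoverage:
    def write_sam(self, path, markers, body_lines):
        header = ["@HD\tVN:1.6\tSO:unknown"]
        for ms in markers:
            for gid, seq in ms.markers:
                header.append(f"@SQ\tSN:{gid}\tLN:{len(seq)}")
        path.write_text("\n".join(header + body_lines) + "\n")

    def test_perfect_alignment_coverage(self, tmp_path):
        rng = np.random.default_rng(14)
        seq = rand_seq(rng, 150)
        markers = [MarkerGeneSet("s1", (("g1", seq),))]
        sam = tmp_path / "aln.sam"
        self.write_sam(sam, markers,
                       [f"r1\t0\tg1\t1\t60\t150M\t*\t0\t0\t{seq}\t*"])
        table = read_sam_coverage(sam, markers)
        assert table.coverage_x.iloc[0] == pytest.approx(1.0)
        assert table.reads.iloc[0] == 1

    def test_empty_body_gives_zero_table(self, tmp_path):
        rng = np.random.default_rng(15)
        markers = [MarkerGeneSet("s1", (("g1", rand_seq(rng, 100)),))]
        sam = tmp_path / "aln.sam"
        self.write_sam(sam, markers, [])
        table = read_sam_coverage(sam, markers)
        assert (table.coverage_x == 0).all()

    def test_secondary_alignments_excluded(self, tmp_path):
        rng = np.random.default_rng(16)
        seq = rand_seq(rng, 150)
        markers = [MarkerGeneSet("s1", (("g1", seq),))]
        sam = tmp_path / "aln.sam"
        self.write_sam(sam, markers, [
            f"r1\t0\tg1\t1\t60\t150M\t*\t0\t0\t{seq}\t*",
            f"r1\t256\tg1\t1\t60\t150M\t*\t0\t0\t{seq}\t*",  # secondary
        ])
        table = read_sam_coverage(sam, markers)
        assert table.reads.iloc[0] == 1

    def test_unknown_reference_rejected(self, tmp_path):
        rng = np.random.default_rng(17)
        seq = rand_seq(rng, 50)
        markers = [MarkerGeneSet("s1", (("g1", seq),))]
        sam = tmp_path / "aln.sam"
        header = ["@HD\tVN:1.6", f"@SQ\tSN:g1\tLN:50",
                  "@SQ\tSN:mystery\tLN:50"]
        body = [f"r1\t0\tmystery\t1\t60\t50M\t*\t0\t0\t{seq}\t*"]
        sam.write_text("\n".join(header + body) + "\n")
        with pytest.raises(ValueError, match="mystery"):
            read_sam_coverage(sam, markers)
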