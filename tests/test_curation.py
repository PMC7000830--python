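"""Alignment curation: reading, site removal, motif collapsing, haplotyping."""

import pytest

import haplogeo as hg
from haplogeo.alignment import AlignmentRecord, HaplotypeAlignment


def write_fasta(path, entries):
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n{seq}\n")


class TestReadAlignment:
    def test_reads_equal_length_fasta_with_labels(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_fasta(f, [("s1", "ACGT"), ("s2", "ACGA"), ("s3", "ACGT")])
        aln = hg.read_alignment(f, {"s1": "X", "s2": "X", "s3": "Y"})
        assert aln.L == 4
        assert aln.n == 3
        assert aln.populations() == ["X", "Y"]

    def test_ragged_alignment_names_offender(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_fasta(f, [("s1", "ACGT"), ("bad", "ACG")])
        with pytest.raises(ValueError, match="bad"):
            hg.read_alignment(f, {"s1": "X", "bad": "X"})

    def test_missing_label_rejected(self, tmp_path):
        f = tmp_path / "a.fasta"
        write_fasta(f, [("s1", "ACGT")])
        with pytest.raises(ValueError, match="s1"):
            hg.read_alignment(f, {})

    def test_round_trip_is_identity(self, tmp_path):
        cfg = hg.SyntheticConfig(
            seed=7, L=345, populations={"P": [4, 3, 2, 1]}, distance_model="tree"
        )
        aln, _ = hg.make_haplotype_dataset(cfg)
        fasta, labels = tmp_path / "x.fasta", tmp_path / "x.tsv"
        hg.write_alignment(aln, fasta, labels)
        back = hg.read_alignment(fasta, hg.read_labels(labels))
        assert back == aln


class TestRemoveSites:
    def test_monomorphic_column_preserves_partition(self, toy_alignment):
        before = hg.collapse_haplotypes(toy_alignment)
        after = hg.collapse_haplotypes(hg.remove_sites(toy_alignment, [1]))
        assert sorted(before.counts.sum(axis=1)) == sorted(after.counts.sum(axis=1))

    def test_removing_single_diagnostic_site_merges(self):
        aln = HaplotypeAlignment(
            [AlignmentRecord("a", "P", "ACG"), AlignmentRecord("b", "P", "ACT")]
        )
        out = hg.remove_sites(aln, [3])
        assert out.records[0].sequence == out.records[1].sequence == "AC"

    def test_length_drops_by_distinct_positions(self):
        recs = [AlignmentRecord("a", "P", "A" * 346), AlignmentRecord("b", "P", "C" * 346)]
        out = hg.remove_sites(HaplotypeAlignment(recs), [156])
        assert out.L == 345

    def test_out_of_range_rejected(self, toy_alignment):
        with pytest.raises(ValueError, match="9"):
            hg.remove_sites(toy_alignment, [9])

    def test_never_increases_haplotype_count(self, toy_alignment):
        h0 = len(hg.collapse_haplotypes(toy_alignment).haplotypes)
        for site in range(1, toy_alignment.L + 1):
            reduced = hg.remove_sites(toy_alignment, [site])
            assert len(hg.collapse_haplotypes(reduced).haplotypes) <= h0


class TestCollapseRepeatMotif:
    def _aln(self, seqs):
        return HaplotypeAlignment(
            [AlignmentRecord(f"s{i}", "P", s) for i, s in enumerate(seqs)]
        )

    def test_one_extra_copy_becomes_one_step(self):
        # 3 vs 4 TA copies, length variation aligned with trailing gaps
        a = "GG" + "TATATA" + "--" + "CC"
        b = "GG" + "TATATATA" + "CC"
        out = hg.collapse_repeat_motif(self._aln([a, b]), "TA", 3)
        s0, s1 = out.records[0].sequence, out.records[1].sequence
        assert len(s0) == len(s1)
        assert sum(x != y for x, y in zip(s0, s1)) == 1

    def test_equal_tracts_leave_differences_unchanged(self):
        a = "GTATATA"
        b = "ATATATA"  # differs at site 1 only
        out = hg.collapse_repeat_motif(self._aln([a, b]), "TA", 2)
        s0, s1 = out.records[0].sequence, out.records[1].sequence
        assert sum(x != y for x, y in zip(s0, s1)) == 1

    def test_three_vs_five_copies_contribute_two_steps(self):
        a = "A" + "TATATA" + "----" + "G"
        b = "A" + "TATATATATA" + "G"
        out = hg.collapse_repeat_motif(self._aln([a, b]), "TA", 2)
        s0, s1 = out.records[0].sequence, out.records[1].sequence
        assert sum(x != y for x, y in zip(s0, s1)) == 2

    def test_idempotent(self):
        a = "A" + "TATATA" + "--" + "G"
        b = "A" + "TATATATA" + "G"
        once = hg.collapse_repeat_motif(self._aln([a, b]), "TA", 2)
        twice = hg.collapse_repeat_motif(once, "TA", 2)
        assert [r.sequence for r in twice.records] == [r.sequence for r in once.records]

    def test_motif_absent_raises(self):
        with pytest.raises(ValueError, match="TA"):
            hg.collapse_repeat_motif(self._aln(["GGGG", "GGGG"]), "TA", 1)


class TestCollapseHaplotypes:
    def test_counts_split_by_population(self, toy_alignment):
        table = hg.collapse_haplotypes(toy_alignment)
        assert len(table.haplotypes) == 3
        assert table.counts["A"].sum() == 3
        assert table.counts["B"].sum() == 3

    def test_ninety_sequences_four_haplotypes(self):
        cfg = hg.SyntheticConfig(
            seed=1, populations={"CL": [31, 45, 12, 2]}, distance_model="star"
        )
        aln, _ = hg.make_haplotype_dataset(cfg)
        table = hg.collapse_haplotypes(aln)
        assert len(table.haplotypes) == 4
        assert int(table.counts["CL"].sum()) == 90

    def test_all_identical_single_haplotype(self):
        aln = HaplotypeAlignment(
            [AlignmentRecord(f"s{i}", "P", "ACGT") for i in range(7)]
        )
        table = hg.collapse_haplotypes(aln)
        assert len(table.haplotypes) == 1
        assert int(table.counts["P"].iloc[0]) == 7

    def test_recovers_generator_partition(self):
        cfg = hg.SyntheticConfig(
            seed=5, populations={"A": [6, 3], "B": [2, 5, 4]}, distance_model="tree"
        )
        aln, truth = hg.make_haplotype_dataset(cfg)
        table = hg.collapse_haplotypes(aln)
        # group samples by recovered haplotype and compare with ground truth
        got = {}
        for hap, seq in table.sequences.items():
            members = frozenset(
                r.sample_id for r in aln.records if r.sequence == seq
            )
            got[members] = hap
        want = {}
        for sid, hap in truth.partition.items():
            want.setdefault(hap, set()).add(sid)
        assert set(got) == {frozenset(v) for v in want.values()}

    def test_ambiguity_merged_into_unique_resolved_partner(self):
        aln = HaplotypeAlignment(
            [
                AlignmentRecord("full", "P", "ACGT"),
                AlignmentRecord("full2", "P", "ACGT"),
                AlignmentRecord("partial", "P", "ACGN"),
                AlignmentRecord("other", "P", "TCGA"),
            ]
        )
        table = hg.collapse_haplotypes(aln)
        assert len(table.haplotypes) == 2
        assert any("N-resolved" in new for _, new in table.merge_log)

    def test_ambiguous_partial_kept_separate(self):
        # partial resolves to two different full sequences: no merge
        aln = HaplotypeAlignment(
            [
                AlignmentRecord("x", "P", "ACGT"),
                AlignmentRecord("y", "P", "ACGA"),
                AlignmentRecord("p", "P", "ACGN"),
            ]
        )
        table = hg.collapse_haplotypes(aln)
        assert len(table.haplotypes) == 3
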