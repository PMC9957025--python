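import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from inteinscan import alnio
from inteinscan.alnio import (Alignment, EmptyPartitionError, FastaFormatError,
                              SiteSet, column_residue_map, define_site_sets,
                              extract_partition, read_fasta, write_fasta)


class TestFastaIO:
    def test_roundtrip_preserves_order_and_sequences(self, toy_alignment, tmp_path):
        p = tmp_path / "a.fasta"
        write_fasta(toy_alignment, p)
        back = read_fasta(p)
        assert back.ids == toy_alignment.ids
        assert back.rows == toy_alignment.rows

    def test_duplicate_header_reported(self, tmp_path):
        p = tmp_path / "dup.fasta"
        p.write_text(">seq1\nMKV\n>seq1\nMKA\n")
        with pytest.raises(FastaFormatError, match="seq1"):
            read_fasta(p)

    def test_illegal_character_names_sequence_and_position(self, tmp_path):
        p = tmp_path / "bad.fasta"
        p.write_text(">ok\nMKV\n>bad\nMJV\n")
        with pytest.raises(FastaFormatError, match="bad"):
            read_fasta(p)

    def test_lowercase_input_is_uppercased(self, tmp_path):
        p = tmp_path / "lc.fasta"
        p.write_text(">s\nmkv\n")
        assert read_fasta(p).rows["s"] == "MKV"

    def test_ragged_rows_rejected_in_aligned_mode(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">a\nMKV\n>b\nMK\n")
        with pytest.raises(FastaFormatError):
            read_fasta(p)
        assert read_fasta(p, aligned=False).rows["b"] == "MK"


class TestSiteSets:
    def test_single_element_partition_sizes(self):
        aln = Alignment(ids=["x"], rows={"x": "A" * 100})
        sets = define_site_sets(aln, [("el", 40, 60)])
        by_name = {s.name: s for s in sets}
        assert len(by_name["extein"]) == 80
        assert len(by_name["el"]) == 20

    def test_sets_partition_all_columns(self):
        aln = Alignment(ids=["x"], rows={"x": "A" * 50})
        sets = define_site_sets(aln, [("e1", 5, 15), ("e2", 30, 40)])
        cols = sorted(c for s in sets for c in s.columns)
        assert cols == list(range(50))

    def test_three_elements_give_four_site_sets(self):
        aln = Alignment(ids=["x"], rows={"x": "A" * 90})
        sets = define_site_sets(aln, [("a", 0, 10), ("b", 20, 30), ("c", 50, 60)])
        assert len(sets) == 4

    def test_overlapping_elements_rejected(self):
        aln = Alignment(ids=["x"], rows={"x": "A" * 50})
        with pytest.raises(ValueError, match="overlap"):
            define_site_sets(aln, [("a", 0, 20), ("b", 10, 30)])

    def test_blocks_roundtrip(self):
        ss = SiteSet.from_blocks("s", [(2, 5), (8, 10)])
        assert ss.columns == (2, 3, 4, 8, 9)
        assert ss.blocks() == [(2, 5), (8, 10)]

    @given(st.lists(st.tuples(st.integers(0, 40), st.integers(1, 10)),
                    min_size=1, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_block_lengths_are_end_minus_start(self, raw):
        # disjointify: lay blocks out left to right
        blocks = []
        cursor = 0
        for gap, width in raw:
            start = cursor + gap + 1   # >= 1 so adjacent runs stay distinct
            blocks.append((start, start + width))
            cursor = start + width
        ss = SiteSet.from_blocks("s", blocks)
        assert len(ss) == sum(e - s for s, e in blocks)
        assert ss.blocks() == [b for b in blocks]


class TestPartitions:
    def test_without_carriers_only_row_count_unchanged(self, toy_alignment):
        ss = SiteSet("s", (0, 1, 2))
        part = extract_partition(toy_alignment, ss)
        assert part.alignment.ids == toy_alignment.ids

    def test_carriers_only_drops_gappy_rows(self):
        rows = {"full": "AAAA", "half": "AA--", "gone": "----"}
        aln = Alignment(ids=list(rows), rows=rows)
        part = extract_partition(aln, SiteSet("s", (0, 1, 2, 3)),
                                 carriers_only=True, min_span=0.6)
        assert part.alignment.ids == ["full"]
        assert set(part.dropped_ids) == {"half", "gone"}

    def test_empty_partition_is_explicit_error(self):
        aln = Alignment(ids=["a"], rows={"a": "----"})
        with pytest.raises(EmptyPartitionError):
            extract_partition(aln, SiteSet("s", (0, 1, 2, 3)), carriers_only=True)

    def test_reassembly_identity(self, two_element_scenario):
        sc = two_element_scenario
        aln = sc.alignment
        elements = [(n, s, e) for n, (s, e) in sc.truth.true_site_sets.items()]
        sets = define_site_sets(aln, elements)
        parts = [extract_partition(aln, s) for s in sets]
        order = np.argsort([c for s in sets for c in s.columns], kind="stable")
        for sid in aln.ids:
            concat = "".join(p.alignment.rows[sid] for p in parts)
            reassembled = "".join(concat[i] for i in order)
            assert reassembled == aln.rows[sid]


class TestColumnResidueMap:
    def test_gapless_row_is_identity(self):
        aln = Alignment(ids=["a"], rows={"a": "MKV"})
        assert column_residue_map(aln, "a") == {0: 0, 1: 1, 2: 2}

    def test_gapped_row(self):
        aln = Alignment(ids=["a", "b"], rows={"a": "A-C", "b": "AAC"})
        assert column_residue_map(aln, "a") == {0: 0, 2: 1}

    def test_bijection_with_ungapped_sequence(self, two_element_scenario):
        aln = two_element_scenario.alignment
        sid = aln.ids[0]
        cmap = column_residue_map(aln, sid)
        ungapped = aln.ungapped(sid)
        assert sorted(cmap.values()) == list(range(len(ungapped)))
        for col, k in cmap.items():
            assert aln.rows[sid][col] == ungapped[k]

    def test_unknown_id_raises(self, toy_alignment):
        with pytest.raises(KeyError):
            column_residue_map(toy_alignment, "nope")


def test_site_set_tsv_roundtrip(tmp_path):
    sets = [SiteSet("extein", tuple(range(0, 10))), SiteSet.from_blocks("el", [(10, 20)])]
    p = tmp_path / "sites.tsv"
    alnio.write_site_sets(sets, p)
    back = alnio.read_site_sets(p)
    assert [(s.name, s.columns) for s in back] == [(s.name, s.columns) for s in sets]
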