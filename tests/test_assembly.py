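from __future__ import annotations

import sys

import numpy as np
import pytest

from clipins.assembly import (
    AssemblyConfig,
    InsertionCall,
    Placement,
    assemble,
    extract_insertion,
    left_normalize_insertion,
    place_contig,
    revcomp,
)
from clipins.genotyper import GenotypeCall
from clipins.io_alignment import LibraryStats, ReferenceAccessor

STATS = LibraryStats(mu=500, sigma=50, cov=30, read_len=150)


def _rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _tile(template, read_len=100, step=10):
    reads = [template[i : i + read_len] for i in range(0, len(template) - read_len + 1, step)]
    return reads + reads  # duplicate so every k-mer clears the count floor


class TestAssemble:
    def test_perfect_tiling_reconstructs_template(self):
        rng = np.random.default_rng(31)
        template = _rand_seq(rng, 600)
        contigs = assemble(_tile(template), AssemblyConfig())
        assert contigs == [template]

    def test_disjoint_templates_give_two_contigs(self):
        rng = np.random.default_rng(32)
        t1, t2 = _rand_seq(rng, 500), _rand_seq(rng, 400)
        contigs = assemble(_tile(t1) + _tile(t2), AssemblyConfig())
        assert sorted(contigs, key=len) == sorted([t2, t1], key=len)

    def test_isolated_error_removed_by_count_floor(self):
        rng = np.random.default_rng(33)
        template = _rand_seq(rng, 500)
        bad = list(template[100:200])
        bad[50] = "ACGT"[("ACGT".index(bad[50]) + 1) % 4]
        contigs = assemble(_tile(template) + ["".join(bad)], AssemblyConfig())
        assert contigs == [template]

    def test_insufficient_input_rejected(self):
        with pytest.raises(ValueError, match="not enough"):
            assemble(["ACGTACGT"], AssemblyConfig(k=31))

    def test_min_contig_len_filters(self):
        rng = np.random.default_rng(34)
        template = _rand_seq(rng, 80)
        assert assemble(_tile(template, read_len=40, step=5), AssemblyConfig(min_contig_len=100)) == []

    def test_k_validation(self):
        with pytest.raises(ValueError):
            AssemblyConfig(k=30)
        with pytest.raises(ValueError):
            AssemblyConfig(k=65)

    def test_external_assembler_contract(self, tmp_path):
        stub = tmp_path / "stub_assembler.py"
        stub.write_text(
            "import sys\n"
            "reads, out = sys.argv[1], sys.argv[2]\n"
            "seqs = [l.strip() for l in open(reads) if not l.startswith('>')]\n"
            "open(out, 'w').write('>c0\\n' + max(seqs, key=len) + '\\n')\n"
        )
        cfg = AssemblyConfig(
            assembler="external",
            external_cmd=f"{sys.executable} {stub} {{reads}} {{out}}",
            min_contig_len=50,
        )
        rng = np.random.default_rng(35)
        long_read = _rand_seq(rng, 200)
        contigs = assemble([long_read, "ACGT" * 20], cfg)
        assert contigs == [long_read]


class TestPlaceContig:
    rng = np.random.default_rng(36)
    ref = ReferenceAccessor({"c": _rand_seq(rng, 4000)})
    p = 2000

    def _contig(self, ins_len=100, flank=200):
        novel = _rand_seq(np.random.default_rng(37), ins_len)
        left = self.ref.fetch("c", self.p - flank, self.p)
        right = self.ref.fetch("c", self.p, self.p + flank)
        return left + novel + right, novel

    def test_flank_insertion_flank_cigar(self):
        contig, novel = self._contig(ins_len=100, flank=200)
        pl = place_contig(contig, self.ref, "c", self.p, STATS)
        assert pl is not None
        assert pl.cigar == [("M", 200), ("I", 100), ("M", 200)]
        assert pl.ref_start == self.p - 200
        got = extract_insertion(pl)
        assert got == (100, novel, self.p)

    def test_pure_reference_contig_all_match(self):
        contig = self.ref.fetch("c", self.p - 300, self.p + 300)
        pl = place_contig(contig, self.ref, "c", self.p, STATS)
        assert pl is not None
        assert pl.cigar == [("M", 600)]
        assert extract_insertion(pl) is None

    def test_novel_only_contig_rejected(self):
        contig = _rand_seq(np.random.default_rng(38), 400)
        assert place_contig(contig, self.ref, "c", self.p, STATS) is None

    def test_reverse_complement_contig_recovered(self):
        contig, novel = self._contig(ins_len=120, flank=150)
        pl = place_contig(revcomp(contig), self.ref, "c", self.p, STATS)
        assert pl is not None
        assert pl.strand == "-"
        got = extract_insertion(pl)
        assert got is not None and got[1] == novel

    def test_mismatched_flanks_tolerated_up_to_identity_floor(self):
        contig, novel = self._contig(ins_len=100, flank=200)
        mutated = list(contig)
        for i in (50, 120, 420):  # 3 mismatches over 400 flank bases
            mutated[i] = "ACGT"[("ACGT".index(mutated[i]) + 2) % 4]
        pl = place_contig("".join(mutated), self.ref, "c", self.p, STATS)
        assert pl is not None
        assert pl.flank_identity >= 0.9
        got = extract_insertion(pl)
        assert got is not None and got[0] == 100


class TestExtractInsertion:
    def _placement(self, cigar, contig, ref_start=1000):
        return Placement(ref_start=ref_start, cigar=cigar, contig=contig, contig_start=0)

    def test_worked_example_length_and_coordinates(self):
        contig = _rand_seq(np.random.default_rng(39), 448)
        pl = self._placement([("M", 132), ("I", 186), ("M", 130)], contig)
        ins_len, ins_seq, refined = extract_insertion(pl)
        assert ins_len == 186
        assert ins_seq == contig[132:318]  # 1-based bases 133-318
        assert refined == 1000 + 132

    def test_same_arithmetic_smaller_case(self):
        contig = _rand_seq(np.random.default_rng(40), 260)
        pl = self._placement([("M", 100), ("I", 60), ("M", 100)], contig)
        ins_len, ins_seq, refined = extract_insertion(pl)
        assert (ins_len, refined) == (60, 1100)
        assert ins_seq == contig[100:160]

    def test_small_insertion_below_floor_rejected(self):
        contig = _rand_seq(np.random.default_rng(41), 330)
        pl = self._placement([("M", 150), ("I", 30), ("M", 150)], contig)
        assert extract_insertion(pl) is None

    def test_length_always_consistent(self):
        contig = _rand_seq(np.random.default_rng(42), 500)
        pl = self._placement([("M", 100), ("I", 300), ("M", 100)], contig)
        ins_len, ins_seq, _ = extract_insertion(pl)
        assert len(ins_seq) == ins_len


class TestNormalization:
    def test_left_shift_over_matching_bases(self):
        ref = ReferenceAccessor({"c": "AAAAATTTTT"})
        # insertion GA at position 5; seq ends with A == ref[4] -> shifts left
        pos, seq = left_normalize_insertion(5, "GA", ref, "c")
        assert (pos, seq) == (4, "AG")

    def test_no_shift_when_boundary_differs(self):
        ref = ReferenceAccessor({"c": "AAAAATTTTT"})
        assert left_normalize_insertion(5, "GC", ref, "c") == (5, "GC")


class TestInsertionCall:
    def test_sequence_length_invariant(self):
        with pytest.raises(ValueError):
            InsertionCall(
                contig="c", position=0,
                genotype=GenotypeCall("homozygous", 1, 0),
                ins_len=5, ins_seq="ACGT",
            )
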