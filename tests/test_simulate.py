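from __future__ import annotations

from collections import Counter

import numpy as np
import pytest

from clipins.simulate import (
    SimConfig,
    implant_insertions,
    make_genome,
    simulate_dataset,
    write_fastq,
)


class TestMakeGenome:
    def test_deterministic_per_seed(self):
        assert make_genome(20_000, 5) == make_genome(20_000, 5)

    def test_base_composition_uniform(self):
        g = make_genome(100_000, 1)
        freqs = Counter(g)
        for b in "ACGT":
            assert abs(freqs[b] / 100_000 - 0.25) < 0.015

    def test_different_seeds_diverge(self):
        a, b = make_genome(100_000, 1), make_genome(100_000, 2)
        ham = sum(x != y for x, y in zip(a, b)) / 100_000
        assert 0.73 < ham < 0.77

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            make_genome(5000, 0)


class TestImplantInsertions:
    def test_no_insertions_identity(self):
        ref = make_genome(50_000, 1)
        cfg = SimConfig(genome_len=50_000, n_insertions=0, seed=1)
        hap_a, hap_b, truth = implant_insertions(ref, cfg)
        assert hap_a.seq == hap_b.seq == ref
        assert truth == []

    def test_homozygous_lengthens_both_haplotypes(self):
        ref = make_genome(50_000, 2)
        cfg = SimConfig(genome_len=50_000, n_insertions=1, size_range=(200, 200),
                        zygosity_mix=0.0, seed=2)
        hap_a, hap_b, truth = implant_insertions(ref, cfg)
        assert len(hap_a.seq) == len(ref) + 200
        assert len(hap_b.seq) == len(ref) + 200
        assert truth[0].genotype == "hom"

    def test_heterozygous_leaves_haplotype_b_reference(self):
        ref = make_genome(50_000, 3)
        cfg = SimConfig(genome_len=50_000, n_insertions=1, size_range=(100, 100),
                        zygosity_mix=1.0, seed=3)
        hap_a, hap_b, truth = implant_insertions(ref, cfg)
        assert hap_b.seq == ref
        assert len(hap_a.seq) == len(ref) + 100

    def test_truth_positions_spaced(self):
        ref = make_genome(200_000, 4)
        cfg = SimConfig(genome_len=200_000, n_insertions=20, seed=4)
        _, _, truth = implant_insertions(ref, cfg)
        pos = [t.position for t in truth]
        # canonical left-alignment can shave a few bases off the nominal gap
        assert min(np.diff(pos)) >= cfg.spacing - 50

    def test_overcrowded_request_fatal(self):
        ref = make_genome(20_000, 5)
        cfg = SimConfig(genome_len=20_000, n_insertions=50, seed=5)
        with pytest.raises(ValueError, match="cannot place"):
            implant_insertions(ref, cfg)

    def test_size_floor_enforced(self):
        with pytest.raises(ValueError):
            SimConfig(size_range=(20, 100))


@pytest.fixture(scope="module")
def clean():
    cfg = SimConfig(genome_len=100_000, n_insertions=0, coverage=30.0, seed=6)
    return simulate_dataset(cfg)


class TestSimulateAlignedPairs:
    def test_fragment_conservation(self, clean):
        cfg = clean.config
        names = Counter(r.query_name for r in clean.reads)
        assert set(names.values()) == {2}
        expected = cfg.coverage * cfg.genome_len / (2 * cfg.read_len)
        assert abs(len(names) - expected) / expected < 0.01

    def test_clean_genome_has_no_abnormal_reads(self, clean):
        assert all(r.is_mapped for r in clean.reads)
        assert not any(r.has_soft_clip() for r in clean.reads)

    def test_depth_matches_requested_coverage(self, clean):
        total = sum(len(r.seq) for r in clean.reads if r.is_mapped)
        depth = total / clean.config.genome_len
        assert abs(depth - 30.0) < 3.0

    def test_insert_size_distribution_recovered(self, clean):
        tlens = [r.template_len for r in clean.reads if r.template_len > 0]
        assert abs(np.mean(tlens) - 500) / 500 < 0.02
        assert abs(np.std(tlens) - 50) / 50 < 0.1

    def test_insertion_produces_clips_on_both_sides(self):
        cfg = SimConfig(genome_len=60_000, n_insertions=1, size_range=(300, 300),
                        zygosity_mix=0.0, coverage=30.0, seed=7)
        data = simulate_dataset(cfg)
        (t,) = data.truth
        heads = [r for r in data.reads
                 if r.is_mapped and r.cigar[0][0] == "S" and r.pos == t.position]
        tails = [r for r in data.reads
                 if r.is_mapped and r.cigar[-1][0] == "S" and r.reference_end == t.position]
        assert heads and tails

    def test_insertion_produces_oea_pairs(self):
        cfg = SimConfig(genome_len=60_000, n_insertions=1, size_range=(300, 300),
                        zygosity_mix=0.0, coverage=30.0, seed=8)
        data = simulate_dataset(cfg)
        oea = [r for r in data.reads if not r.is_mapped and r.mate_is_mapped]
        assert oea
        (t,) = data.truth
        assert all(abs(r.pos - t.position) < 800 for r in oea)

    def test_end_to_end_determinism(self):
        cfg = SimConfig(genome_len=60_000, n_insertions=2, coverage=10.0, seed=9)
        a = simulate_dataset(cfg)
        b = simulate_dataset(cfg)
        assert a.reference == b.reference
        assert [(r.query_name, r.pos, r.seq) for r in a.reads] == [
            (r.query_name, r.pos, r.seq) for r in b.reads
        ]

    def test_fastq_export_pairs(self, clean, tmp_path):
        p1, p2 = write_fastq(clean, tmp_path / "reads")
        n1 = sum(1 for line in open(p1)) // 4
        n2 = sum(1 for line in open(p2)) // 4
        assert n1 == n2 == sum(1 for r in clean.reads) // 2
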