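"""Probe classification, structure mapping and ORF logic vs brute force."""

import numpy as np
import pytest

from structatlas.annotation import (ProbeRecord, StructurePrediction,
                                    annotate_known, classify_probe,
                                    coding_potential, map_structures,
                                    utr_relative_position)
from structatlas.intervals import GeneModel, GenomicInterval

from conftest import random_gene_models, random_interval
from oracles import (annotate_known_oracle, classify_oracle,
                     map_structures_oracle, orf_oracle)

IV = GenomicInterval


def simple_gene(strand="+"):
    return GeneModel("g", [
        (IV("chr1", 100, 200, strand), "five_utr"),
        (IV("chr1", 200, 400, strand), "cds"),
        (IV("chr1", 400, 600, strand), "intron"),
        (IV("chr1", 600, 800, strand), "cds"),
        (IV("chr1", 800, 1000, strand), "three_utr"),
    ])


class TestClassifyProbe:
    def test_probe_inside_three_utr(self):
        assert classify_probe(IV("chr1", 850, 950), [simple_gene()]) == {"three_utr"}

    def test_ten_percent_boundary_is_inclusive(self):
        # 100-nt probe overlapping the 5' UTR by exactly 10 nt
        probe = IV("chr1", 90, 190)
        gene = GeneModel("g", [(IV("chr1", 180, 300), "five_utr")])
        assert classify_probe(probe, [gene], min_frac=0.10) == {"five_utr"}
        assert classify_probe(probe, [gene], min_frac=0.101) == set()

    def test_empty_gene_list_means_intergenic(self):
        assert classify_probe(IV("chr1", 0, 100), []) == {"intergenic"}

    def test_cds_only_probe(self):
        assert classify_probe(IV("chr1", 250, 350), [simple_gene()]) == {"cds"}

    def test_intron_contained_probe(self):
        assert classify_probe(IV("chr1", 450, 550), [simple_gene()]) == {"intronic"}

    def test_probe_spanning_intron_and_gap(self):
        # no exonic base, part intron part intergenic -> both labels
        gene = GeneModel("g", [(IV("chr1", 100, 200), "five_utr"),
                               (IV("chr1", 200, 400), "cds"),
                               (IV("chr1", 400, 600), "intron")])
        assert classify_probe(IV("chr1", 500, 700), [gene]) == \
            {"intronic", "intergenic"}

    def test_matches_perbase_oracle_on_random_instances(self, rng):
        genes = random_gene_models(rng, 30)
        for _ in range(300):
            probe = random_interval(rng)
            assert classify_probe(probe, genes) == classify_oracle(probe, genes)


class TestMapStructures:
    def test_touching_interval_is_not_overlap(self):
        # structure ends exactly where the probe starts: zero shared bases
        probe = ProbeRecord("p", IV("chr1", 100, 200), classes={"intergenic"})
        s = StructurePrediction(IV("chr1", 50, 100), "s")
        assert map_structures(probe, [s], []) == []
        assert not probe.structured

    def test_one_nt_overlap_of_mapped_utr_exon(self):
        gene = simple_gene()
        probe = ProbeRecord("p", IV("chr1", 850, 950), classes={"three_utr"})
        # overlaps the 3' UTR exon [800, 1000) by exactly 1 nt, not the probe
        s = StructurePrediction(IV("chr1", 999, 1050), "s")
        assert map_structures(probe, [s], [gene]) == [s]
        assert probe.structured

    def test_strand_flip_symmetry(self, rng):
        genes = random_gene_models(rng, 10)
        for _ in range(50):
            p_iv = random_interval(rng)
            probe = ProbeRecord("p", p_iv, classes=classify_probe(p_iv, genes))
            s_iv = random_interval(rng)
            for strand in "+-.":
                s = StructurePrediction(IV(s_iv.chrom, s_iv.start, s_iv.end,
                                           strand), "s")
                assert s.interval.strand == "."  # strand discarded on input
            mapped = map_structures(probe, [StructurePrediction(s_iv, "s")],
                                    genes)
            assert isinstance(mapped, list)

    def test_matches_perbase_oracle(self, rng):
        genes = random_gene_models(rng, 20)
        structures = [StructurePrediction(random_interval(rng, max_len=120),
                                          f"s{k}") for k in range(40)]
        for _ in range(100):
            p_iv = random_interval(rng)
            classes = classify_probe(p_iv, genes)
            probe = ProbeRecord("p", p_iv, classes=classes)
            got = {s.source_id for s in map_structures(probe, structures, genes)}
            assert got == map_structures_oracle(p_iv, classes, structures, genes)


def make_transcript(orf_codons: int, total_len: int) -> str:
    """Transcript with one planted ORF; padding cannot form AUG or stops."""
    orf = "AUG" + "GGC" * orf_codons + "UAA"
    pad = total_len - len(orf)
    left = "CU" * (pad // 4)
    right = "CU" * ((pad - len(left)) // 2)
    right += "C" * (total_len - len(orf) - len(left) - len(right))
    return left + orf + right


class TestCodingPotential:
    def test_no_start_codon(self):
        assert coding_potential("CCCUUUCCCUUU") is False

    def test_121_codon_orf_in_900nt_is_coding(self):
        tx = make_transcript(120, 900)  # AUG + 120 codons = 121, 363 nt
        assert len(tx) == 900
        assert coding_potential(tx) is True

    def test_same_orf_in_1200nt_fails_one_third_rule(self):
        tx = make_transcript(120, 1200)  # 363/1200 < 1/3
        assert coding_potential(tx) is False

    def test_exactly_120_codons_is_not_enough(self):
        tx = make_transcript(119, 500)  # 120 codons total: not > 120
        assert coding_potential(tx) is False

    def test_reverse_complement_invariance(self, rng):
        comp = str.maketrans("ACGU", "UGCA")
        for _ in range(25):
            tx = "".join(rng.choice(list("ACGU"), size=600))
            assert coding_potential(tx) == coding_potential(
                tx.translate(comp)[::-1])

    def test_matches_frame_scan_oracle(self, rng):
        for _ in range(50):
            tx = make_transcript(int(rng.integers(100, 140)),
                                 int(rng.integers(500, 1300)))
            assert coding_potential(tx) == orf_oracle(tx)

    def test_rejects_bad_symbols(self):
        with pytest.raises(ValueError):
            coding_potential("AUGNNNUAA")


class TestAnnotateKnown:
    def test_denominator_is_reference_length(self):
        mirna = IV("chr1", 1000, 1100)  # length 100
        # probe covering exactly 10 nt = 10% of the miRNA
        assert annotate_known(IV("chr1", 990, 1010), [(mirna, "mir-1")]) == ["mir-1"]
        # 9 nt = 9%
        assert annotate_known(IV("chr1", 991, 1009), [(mirna, "mir-1")]) == []

    def test_matches_perbase_oracle(self, rng):
        known = [(random_interval(rng, max_len=80), f"rna{k}")
                 for k in range(30)]
        for _ in range(200):
            probe = random_interval(rng)
            assert annotate_known(probe, known) == annotate_known_oracle(probe, known)


class TestUtrRelativePosition:
    def test_centered_structure(self):
        assert utr_relative_position(IV("chr1", 140, 160), IV("chr1", 100, 200),
                                     "+") == pytest.approx(0.5)

    def test_minus_strand(self):
        # overlap midpoint at genomic 190 in a minus-strand UTR [100, 200)
        assert utr_relative_position(IV("chr1", 185, 195), IV("chr1", 100, 200),
                                     "-") == pytest.approx(0.1)

    def test_five_prime_terminus(self):
        # structure hugging the 5' end of a plus-strand UTR
        v = utr_relative_position(IV("chr1", 100, 110), IV("chr1", 100, 200), "+")
        assert v == pytest.approx(0.05)  # half the structure width / UTR length

    def test_disjoint_raises(self):
        with pytest.raises(ValueError):
            utr_relative_position(IV("chr1", 0, 50), IV("chr1", 100, 200), "+")


def test_classification_of_synthetic_genome_matches_planted_truth(tiny_config):
    from structatlas.synthetic import simulate_genome

    genes, probes, structures, sequences, truth = simulate_genome(tiny_config)
    for p in probes:
        classes = classify_probe(p["interval"], genes)
        assert classes == p["classes"], p["probe_id"]
        rec = ProbeRecord(p["probe_id"], p["interval"], classes=classes)
        map_structures(rec, structures, genes)
        assert rec.structured == p["structured"], p["probe_id"]
        assert coding_potential(sequences[p["probe_id"]]) == \
            truth[p["probe_id"]]["coding"], p["probe_id"]
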