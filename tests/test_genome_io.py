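"""Mitogenome parsing, extraction, translation and gene-order tests."""

import pytest

from mitosel import genome_io as gio
from mitosel.comp_stats import base_composition
from mitosel.simulate.genomes import MitogenomeSpec, simulate_mitogenome


def toy_genome():
    # trnF [0,6) H, ND1 [6,18) H, trnV [18,24) L on a 24 nt record
    seq = "AAATTTATGGCTGCTTAACGTGCA"
    feats = [
        gio.GeneFeature("trnF", "tRNA", 0, 6, "H"),
        gio.GeneFeature("ND1", "PCG", 6, 18, "H"),
        gio.GeneFeature("trnV", "tRNA", 18, 24, "L"),
    ]
    return gio.Mitogenome("TOY1", seq, circular=False, features=feats)


class TestGenBankIO:
    def test_toy_roundtrip_preserves_feature_table(self, tmp_path):
        g = toy_genome()
        path = tmp_path / "toy.gb"
        gio.write_genbank(g, path)
        g2 = gio.read_genbank(path)
        assert [(f.name, f.kind, f.start, f.end, f.strand) for f in g.features] == [
            (f.name, f.kind, f.start, f.end, f.strand) for f in g2.features
        ]
        assert g2.sequence == g.sequence

    def test_synthetic_genome_has_37_genes_plus_cr(self, synthetic_genome, tmp_path):
        genome, _ = synthetic_genome
        kinds = [f.kind for f in genome.features]
        assert kinds.count("PCG") == 13
        assert kinds.count("tRNA") == 22
        assert kinds.count("rRNA") == 2
        assert kinds.count("control_region") == 1
        path = tmp_path / "syn.gb"
        gio.write_genbank(genome, path)
        g2 = gio.read_genbank(path)
        assert [(f.name, f.start, f.end) for f in genome.features] == [
            (f.name, f.start, f.end) for f in g2.features
        ]

    def test_feature_beyond_end_rejected_on_linear_record(self):
        with pytest.raises(gio.GenomeValidationError):
            gio.Mitogenome(
                "X", "ACGTACGT", circular=False,
                features=[gio.GeneFeature("trnF", "tRNA", 4, 12, "H")],
            )

    def test_trna_paralog_names_survive(self, synthetic_genome, tmp_path):
        genome, _ = synthetic_genome
        path = tmp_path / "p.gb"
        gio.write_genbank(genome, path)
        names = set(gio.read_genbank(path).gene_names())
        assert {"trnL1", "trnL2", "trnS1", "trnS2"} <= names


class TestExtractGene:
    def test_h_strand_is_plain_substring(self):
        g = toy_genome()
        assert gio.extract_gene(g, "ND1") == g.sequence[6:18]

    def test_l_strand_is_reverse_complemented(self):
        seq = "AACG" + "A" * 8
        g = gio.Mitogenome(
            "X", seq, circular=False,
            features=[gio.GeneFeature("trnQ", "tRNA", 0, 4, "L"),
                      gio.GeneFeature("trnF", "tRNA", 4, 12, "H")],
        )
        assert gio.extract_gene(g, "trnQ") == "CGTT"

    def test_unknown_gene_raises(self):
        with pytest.raises(KeyError):
            gio.extract_gene(toy_genome(), "ND5")

    def test_nd6_sense_strand_cg_rich(self, synthetic_genome):
        genome, _ = synthetic_genome
        nd6 = base_composition(gio.extract_gene(genome, "ND6"), scope="ND6")
        whole = base_composition(genome.sequence)
        assert nd6.gc_fraction > whole.gc_fraction + 0.05


class TestTranslation:
    @pytest.mark.parametrize(
        "cds,expected",
        [("ATATGA", "MW"), ("ATAAGA", "M"), ("ATGGCTAAATAA", "MAK")],
    )
    def test_vertebrate_mito_code(self, cds, expected):
        assert gio.translate_mt(cds) == expected

    def test_polya_completion_reads_truncated_stops_as_taa(self):
        # terminal TA + one A, and terminal T + two A's, both become TAA
        assert gio.translate_mt("ATGGCTTA", completion="polyA") == "MA"
        assert gio.translate_mt("ATGGGTT", completion="polyA") == "MG"

    def test_internal_stop_reports_offset(self):
        with pytest.raises(gio.InternalStopError) as err:
            gio.translate_mt("ATGTAAATGATT")
        assert err.value.offset == 3

    def test_length_arithmetic(self):
        rng_codons = "ATGGCTGGTCAT" * 25  # 100 codons, stop-free
        assert len(gio.translate_mt(rng_codons)) == 100

    def test_every_synthetic_pcg_translates_stop_free(self, synthetic_genome):
        genome, truth = synthetic_genome
        for f in genome.features:
            if f.kind != "PCG":
                continue
            cds = gio.extract_gene(genome, f.name)
            if truth["frameshift"] and truth["frameshift"]["gene"] == f.name:
                skip = truth["frameshift"]["offset"]
                cds = cds[:skip] + cds[skip + 1 :]
            protein = gio.translate_mt(cds, completion="polyA")  # no stop raised
            assert len(protein) >= f.length // 3 - 2


class TestStopCodonStatus:
    def test_complete_and_truncated_statuses(self, synthetic_genome):
        genome, truth = synthetic_genome
        for gene in truth["truncated_genes"]:
            assert gio.detect_incomplete_stop(genome, gene).status == "truncated_TA"
        assert gio.detect_incomplete_stop(genome, "ND1").status == "complete"
        assert gio.detect_incomplete_stop(genome, "COX1").status == "complete"

    def test_truncated_t_classification(self):
        # 3k+1 CDS ending in T, abutting a downstream tRNA
        cds = "ATGGCTGCTT"
        seq = cds + "AAATTT"
        g = gio.Mitogenome(
            "X", seq, circular=False,
            features=[gio.GeneFeature("ND1", "PCG", 0, 10, "H"),
                      gio.GeneFeature("trnF", "tRNA", 10, 16, "H")],
        )
        assert gio.detect_incomplete_stop(g, "ND1").status == "truncated_T"

    def test_non_pcg_rejected(self, synthetic_genome):
        genome, _ = synthetic_genome
        with pytest.raises(ValueError):
            gio.detect_incomplete_stop(genome, "trnF")


class TestFrameshift:
    def test_clean_orf_not_flagged(self):
        assert not gio.detect_frameshift("ATGGCTGGTCATTAA").detected

    def test_planted_insertion_recovered_exactly(self, synthetic_genome):
        genome, truth = synthetic_genome
        report = gio.detect_frameshift(gio.extract_gene(genome, "ND3"))
        assert report.detected
        assert report.skip_position == truth["frameshift"]["offset"]

    def test_planted_recovery_across_seeds(self):
        for seed in range(4):
            genome, truth = simulate_mitogenome(MitogenomeSpec(seed=seed))
            report = gio.detect_frameshift(gio.extract_gene(genome, "ND3"))
            assert report.detected
            assert report.skip_position == truth["frameshift"]["offset"]

    def test_double_insertion_not_rescuable(self, synthetic_genome):
        genome, truth = synthetic_genome
        cds = gio.extract_gene(genome, "ND3")
        broken = cds[:30] + "A" + cds[30:]  # second insertion
        report = gio.detect_frameshift(broken)
        assert not report.detected
        assert "no single-nucleotide skip" in report.note


class TestGeneOrder:
    def test_reference_matches_itself(self):
        ref = gio.ancestral_gene_order()
        assert gio.matches_ancestral(ref)

    def test_synthetic_genome_matches_ancestral(self, synthetic_genome):
        genome, _ = synthetic_genome
        assert gio.matches_ancestral(gio.gene_order_signature(genome))

    def test_rotation_invariance(self, synthetic_genome):
        genome, _ = synthetic_genome
        pivot = genome.feature("COX1").start
        seq = genome.sequence[pivot:] + genome.sequence[:pivot]
        n = len(genome.sequence)
        feats = [
            gio.GeneFeature(f.name, f.kind, (f.start - pivot) % n,
                            (f.start - pivot) % n + f.length, f.strand)
            for f in genome.features
        ]
        rotated = gio.Mitogenome("ROT", seq, circular=True, features=feats)
        assert gio.matches_ancestral(gio.gene_order_signature(rotated))

    def test_pseudo_cr_duplication_breaks_match(self):
        genome, _ = simulate_mitogenome(
            MitogenomeSpec(seed=5, duplicate_pseudo_cr=True)
        )
        assert not gio.matches_ancestral(gio.gene_order_signature(genome))
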