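import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from varscreen import effects
from varscreen import fixtures as fx
from varscreen.normalize import NormalizedVariant
from varscreen.reference_io import GeneModel

from .conftest import make_genome_text


def snv(contig, start, ref, alt):
    return NormalizedVariant(contig, start, ref, alt)


class TestTranslate:
    @pytest.mark.parametrize(
        "codon,aa", [("AAA", "Lys"), ("TAA", "Ter"), ("ANA", "Xaa"), ("ATG", "Met")]
    )
    def test_standard_code(self, codon, aa):
        assert effects.translate(codon) == aa

    def test_wrong_length_rejected(self):
        with pytest.raises(effects.EffectError):
            effects.translate("AAAA")


def single_exon_gene(seq_before, cds, seq_after, strand="+", contig="chrT",
                     symbol="G1", tx="NM_1"):
    """Genome + model where the CDS occupies the middle of one exon."""
    full = seq_before + cds + seq_after
    genome = make_genome_text(full, name=contig)
    model = GeneModel(
        gene_symbol=symbol, refseq_mrna=tx, contig=contig, strand=strand,
        tx_start=0, tx_end=len(full),
        cds_start=len(seq_before), cds_end=len(seq_before) + len(cds),
        exons=[(0, len(full))],
    )
    return genome, model


class TestCodingSequence:
    def test_plus_strand_identity(self):
        genome, model = single_exon_gene("TT", "ATGAAACCC", "GG")
        assert effects.coding_sequence(model, genome) == "ATGAAACCC"

    def test_minus_strand_reverse_complement(self):
        # genomic CDS reads GGGTTTCAT; coding strand is its reverse complement
        genome, model = single_exon_gene("TT", "GGGTTTCAT", "GG", strand="-")
        assert effects.coding_sequence(model, genome) == "ATGAAACCC"

    def test_spliced_cds_skips_intron(self):
        seq = "AA" + "ATGAAA" + "GTTTTAG" + "CCCTAA" + "GG"
        genome = make_genome_text(seq, name="chrT")
        model = GeneModel(
            gene_symbol="G1", refseq_mrna="NM_1", contig="chrT", strand="+",
            tx_start=0, tx_end=len(seq), cds_start=2, cds_end=21,
            exons=[(0, 8), (15, len(seq))],
        )
        assert effects.coding_sequence(model, genome) == "ATGAAACCCTAA"

    def test_noncoding_rejected(self):
        genome, model = single_exon_gene("TT", "ATGAAACCC", "GG")
        model.cds_end = model.cds_start
        with pytest.raises(effects.EffectError):
            effects.coding_sequence(model, genome)


class TestAssignFeatures:
    def spliced(self):
        seq = "A" * 10 + "C" * 20 + "G" * 15 + "T" * 20 + "A" * 10
        genome = make_genome_text(seq, name="chrT")
        model = GeneModel(
            gene_symbol="G1", refseq_mrna="NM_1", contig="chrT", strand="+",
            tx_start=5, tx_end=70, cds_start=15, cds_end=60,
            exons=[(5, 30), (45, 70)],
        )
        return genome, model

    def test_cds_in_second_exon(self):
        _, model = self.spliced()
        (a,) = effects.assign_features(snv("chrT", 50, "T", "A"), [model])
        assert (a.region_class, a.feature_label) == ("CDS", "exon_2;CDS_2")

    def test_intergenic(self):
        _, model = self.spliced()
        (a,) = effects.assign_features(snv("chrT", 2, "A", "G"), [model])
        assert a.region_class == "intergenic"

    def test_utr5_before_cds_start(self):
        _, model = self.spliced()
        (a,) = effects.assign_features(snv("chrT", 10, "C", "T"), [model])
        assert (a.region_class, a.feature_label) == ("UTR5", "exon_1")

    def test_intron(self):
        _, model = self.spliced()
        (a,) = effects.assign_features(snv("chrT", 35, "G", "A"), [model])
        assert a.region_class == "intron"

    def test_minus_strand_ordinals_count_from_five_prime(self):
        _, model = self.spliced()
        model.strand = "-"
        (a,) = effects.assign_features(snv("chrT", 50, "T", "A"), [model])
        assert a.feature_label == "exon_1;CDS_1"

    def test_every_variant_gets_an_assignment(self, genome_and_models):
        genome, models = genome_and_models[0], genome_and_models[1]
        rng = np.random.default_rng(5)
        for _ in range(50):
            pos = int(rng.integers(0, len(genome.contigs["chr1"])))
            ref = genome.fetch("chr1", pos, pos + 1)
            alt = "A" if ref != "A" else "G"
            assert len(effects.assign_features(snv("chr1", pos, ref, alt), models)) >= 1


class TestPredictCodonChange:
    def test_third_position_synonymous(self):
        genome, model = single_exon_gene("TT", "ATG" + "AAA" + "TAA", "GG")
        cc = effects.predict_codon_change(snv("chrT", 7, "A", "G"), model, genome)
        assert (cc.ref_codon, cc.alt_codon) == ("AAA", "AAG")
        assert (cc.ref_aa, cc.alt_aa) == ("Lys", "Lys")
        assert (cc.codon_number, cc.position_in_codon) == (2, 3)

    def test_met_to_ile(self):
        genome, model = single_exon_gene("TT", "ATG" + "AAA" + "TAA", "GG")
        cc = effects.predict_codon_change(snv("chrT", 4, "G", "A"), model, genome)
        assert (cc.ref_aa, cc.alt_aa) == ("Met", "Ile")

    def test_minus_strand_alt_complemented(self):
        # coding ATG AAA TAA; genomic is the reverse complement
        genome, model = single_exon_gene("TT", "TTATTTCAT", "GG", strand="-")
        # coding codon 1 position 1 is genomic position 10 (base T, coding A)
        cc = effects.predict_codon_change(snv("chrT", 10, "T", "C"), model, genome)
        assert cc.position_in_codon == 1
        assert cc.alt_codon[0] == "G"  # genomic T>C is coding A>G

    def test_outside_cds_rejected(self):
        genome, model = single_exon_gene("TT", "ATGAAATAA", "GG")
        with pytest.raises(effects.EffectError):
            effects.predict_codon_change(snv("chrT", 0, "T", "A"), model, genome)


class TestPredictFrameshift:
    def gene(self):
        return single_exon_gene("TT", "ATG" + "AAA" * 8 + "TAA", "GGGG")

    def test_one_bp_deletion_shifts_frame(self):
        genome, model = self.gene()
        nv = NormalizedVariant("chrT", 4, "GA", "G")
        fs = effects.predict_frameshift(nv, model)
        assert fs.is_frameshift and fs.indel_len_in_cds == 1

    def test_three_bp_deletion_in_frame(self):
        genome, model = self.gene()
        nv = NormalizedVariant("chrT", 4, "GAAA", "G")
        fs = effects.predict_frameshift(nv, model)
        assert not fs.is_frameshift and fs.new_frame == fs.original_frame

    def test_deletion_straddling_cds_end_counts_in_cds_bases(self):
        # CDS spans [2, 32); anchored at 28, deleting [29, 33): 3 bases in-CDS
        genome, model = self.gene()
        nv = NormalizedVariant("chrT", 28, genome.fetch("chrT", 28, 33), genome.fetch("chrT", 28, 29))
        fs = effects.predict_frameshift(nv, model)
        assert fs.indel_len_in_cds == 3
        assert not fs.is_frameshift

    def test_indel_outside_cds_rejected(self):
        genome, model = self.gene()
        nv = NormalizedVariant("chrT", 32, genome.fetch("chrT", 32, 35), genome.fetch("chrT", 32, 33))
        with pytest.raises(effects.EffectError):
            effects.predict_frameshift(nv, model)


def mutate_and_translate(cds: str, offset: int, alt_base: str) -> str:
    """Oracle: mutate the spliced CDS directly and translate the whole thing."""
    mutated = cds[:offset] + alt_base + cds[offset + 1 :]
    return str(Seq(mutated).translate())


class TestExhaustiveCodonOracle:
    """Every SNV at every CDS position of a 30-codon gene, both strands."""

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_all_snvs_match_direct_mutation(self, strand):
        rng = np.random.default_rng(99)
        body = "".join(rng.choice(fx._CODONS) for _ in range(28))
        cds = "ATG" + body + "TAA"
        genomic = cds if strand == "+" else effects.reverse_complement(cds)
        genome, model = single_exon_gene("TTTTT", genomic, "GGGGG", strand=strand)
        positions = effects.cds_genomic_positions(model)
        n_checked = 0
        for gpos in positions:
            gref = genome.fetch(model.contig, gpos, gpos + 1)
            for galt in "ACGT":
                if galt == gref:
                    continue
                cc = effects.predict_codon_change(snv("chrT", gpos, gref, galt), model, genome)
                if strand == "+":
                    offset = gpos - positions[0]
                    coding_alt = galt
                else:
                    offset = positions[-1] - gpos
                    coding_alt = effects.reverse_complement(galt)
                expected_prot = mutate_and_translate(cds, offset, coding_alt)
                got_aa = cc.alt_aa
                exp_aa_1 = expected_prot[cc.codon_number - 1]
                exp_aa = "Ter" if exp_aa_1 == "*" else seq3(exp_aa_1)
                assert got_aa == exp_aa, (gpos, galt, cc)
                assert cc.ref_aa == (
                    "Ter" if str(Seq(cds).translate())[cc.codon_number - 1] == "*"
                    else seq3(str(Seq(cds).translate())[cc.codon_number - 1])
                )
                n_checked += 1
        assert n_checked == 270  # 90 positions x 3 alternative bases

    def test_random_indels_match_length_rule(self):
        rng = np.random.default_rng(17)
        genome, model = single_exon_gene("T" * 20, "ATG" + "CAT" * 28 + "TAA", "G" * 20)
        cds_positions = set(effects.cds_genomic_positions(model))
        checked = 0
        while checked < 200:
            start = int(rng.integers(5, 115))
            length = int(rng.integers(1, 9))
            if rng.random() < 0.5:
                nv = NormalizedVariant(
                    "chrT", start, genome.fetch("chrT", start, start + 1 + length),
                    genome.fetch("chrT", start, start + 1),
                )
                in_cds = sum(1 for p in range(start + 1, start + 1 + length)
                             if p in cds_positions)
            else:
                ins = "".join(rng.choice(list("ACGT"), size=length))
                nv = NormalizedVariant(
                    "chrT", start, genome.fetch("chrT", start, start + 1),
                    genome.fetch("chrT", start, start + 1) + ins,
                )
                in_cds = length if (start in cds_positions and (start + 1) in cds_positions) else 0
            if in_cds == 0:
                with pytest.raises(effects.EffectError):
                    effects.predict_frameshift(nv, model)
            else:
                fs = effects.predict_frameshift(nv, model)
                assert fs.is_frameshift == (in_cds % 3 != 0)
                assert fs.indel_len_in_cds == in_cds
            checked += 1
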