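import io

import numpy as np
import pytest

from varscreen import normalize as vn
from varscreen import reference_io as rio

from .conftest import make_genome_text
from .oracles import equivalent_spellings

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def call(contig, pos1, ref, alt, caller="gatk", mapper="bwa", sample="S1"):
    return vn.VariantCall(contig=contig, pos=pos1, ref=ref, alt=alt,
                          sample_id=sample, caller_id=caller, mapper_id=mapper)


class TestReadVcf:
    def test_multiallelic_split(self):
        text = VCF_HEADER + "chr1\t100\t.\tG\tA,T\t50\tPASS\tDP=30\tGT\t0/1\n"
        calls = vn.read_vcf(io.StringIO(text), "gatk", "bwa", "S1")
        assert [(c.ref, c.alt) for c in calls] == [("G", "A"), ("G", "T")]

    def test_depths_from_ad(self):
        text = VCF_HEADER + "chr1\t100\t.\tG\tA\t50\tPASS\tDP=30\tGT:DP:AD\t0/1:30:18,12\n"
        (c,) = vn.read_vcf(io.StringIO(text), "gatk", "bwa", "S1")
        assert (c.depth_total, c.depth_alt) == (30, 12)

    def test_depths_from_dp4(self):
        text = VCF_HEADER + "chr1\t100\t.\tG\tA\t50\tPASS\tDP4=10,8,7,5\tGT\t0/1\n"
        (c,) = vn.read_vcf(io.StringIO(text), "samtools", "bwa", "S1")
        assert (c.depth_total, c.depth_alt) == (30, 12)

    def test_varscan_ad_and_freq(self):
        text = VCF_HEADER + "chr1\t100\t.\tG\tA\t50\tPASS\tDP=40\tGT:DP:AD:FREQ\t0/1:40:12:30.00%\n"
        (c,) = vn.read_vcf(io.StringIO(text), "varscan", "bwa", "S1")
        assert (c.depth_total, c.depth_alt) == (40, 12)

    def test_non_pass_filter_flagged_not_dropped(self):
        text = VCF_HEADER + "chr1\t100\t.\tG\tA\t50\tLowQual\tDP=30\tGT\t0/1\n"
        (c,) = vn.read_vcf(io.StringIO(text), "gatk", "bwa", "S1")
        assert not c.filter_pass

    def test_missing_chrom_header_rejected(self):
        with pytest.raises(vn.VcfFormatError):
            vn.read_vcf(io.StringIO("chr1\t1\t.\tG\tA\t.\t.\t.\n"), "gatk", "bwa", "S1")

    def test_ref_mismatch_reported_and_skipped(self, caplog):
        genome = make_genome_text("ACGTACGT", name="chr1")
        text = VCF_HEADER + "chr1\t1\t.\tG\tA\t50\tPASS\t.\tGT\t0/1\n"
        calls = vn.read_vcf(io.StringIO(text), "gatk", "bwa", "S1", reference=genome)
        assert calls == []
        assert "disagrees" in caplog.text


class TestNormalize:
    def test_homopolymer_deletion_left_aligned(self, homopolymer_genome):
        nv = vn.normalize(call("chrH", 101, "AA", "A"), homopolymer_genome)
        assert (nv.start, nv.ref, nv.alt, nv.vtype) == (99, "CA", "C", "DEL")

    def test_two_caller_spellings_converge(self, homopolymer_genome):
        a = vn.normalize(call("chrH", 101, "AA", "A"), homopolymer_genome)
        b = vn.normalize(call("chrH", 102, "AA", "A"), homopolymer_genome)
        assert a == b

    def test_snv_is_fixed_point(self, homopolymer_genome):
        nv = vn.normalize(call("chrH", 150, "G", "A"), homopolymer_genome)
        assert (nv.start, nv.ref, nv.alt, nv.vtype) == (149, "G", "A", "SNV")

    def test_idempotent(self, homopolymer_genome):
        nv = vn.normalize(call("chrH", 102, "AA", "A"), homopolymer_genome)
        assert vn.normalize(nv, homopolymer_genome) == nv

    def test_identical_alleles_rejected(self, homopolymer_genome):
        with pytest.raises(vn.NotAVariantError):
            vn.normalize(call("chrH", 101, "AA", "AA"), homopolymer_genome)

    def test_padded_snv_trimmed(self, homopolymer_genome):
        # GG>GA at 149/150 is really a 150 G>A SNV
        nv = vn.normalize(call("chrH", 149, "GG", "GA"), homopolymer_genome)
        assert (nv.start, nv.ref, nv.alt) == (149, "G", "A")


class TestVariantKey:
    def test_snv_key_matches_published_format(self):
        nv = vn.NormalizedVariant("chr13", 18258369, "G", "A")
        assert vn.variant_key(nv, "GRCh37") == "chr13.GRCh37:g.18258370G>A"

    def test_single_base_deletion(self):
        # anchor at 1-based 100, deleting the base at 101
        nv = vn.NormalizedVariant("chr1", 99, "CA", "C")
        assert vn.variant_key(nv, "GRCh37").endswith(":g.101del")

    def test_multi_base_deletion_range(self):
        nv = vn.NormalizedVariant("chr1", 99, "CAAT", "C")
        assert vn.variant_key(nv, "GRCh37").endswith(":g.101_103del")

    def test_insertion(self):
        nv = vn.NormalizedVariant("chr1", 199, "G", "GTT")
        assert vn.variant_key(nv, "GRCh37").endswith(":g.200_201insTT")

    def test_snv_key_reparses(self):
        nv = vn.NormalizedVariant("chr13", 18258369, "G", "A")
        key = vn.variant_key(nv, "GRCh37")
        assert vn.parse_variant_key(key) == ("chr13", "GRCh37", 18258370, "G", "A")


class TestConsensus:
    def test_same_snv_two_callers_one_mapper(self, homopolymer_genome):
        calls = [call("chrH", 150, "G", "A", caller="gatk"),
                 call("chrH", 150, "G", "A", caller="samtools")]
        (rec,) = vn.build_consensus(calls, homopolymer_genome)
        assert (rec.n_callers, rec.n_mappers) == (2, 1)

    def test_deletion_spellings_merge(self, homopolymer_genome):
        calls = [call("chrH", 101, "AA", "A", caller="gatk"),
                 call("chrH", 102, "AA", "A", caller="freebayes")]
        (rec,) = vn.build_consensus(calls, homopolymer_genome)
        assert rec.n_callers == 2

    def test_disjoint_variants_stay_separate(self, homopolymer_genome):
        calls = [call("chrH", 150, "G", "A", caller="gatk"),
                 call("chrH", 160, "G", "T", caller="samtools")]
        recs = vn.build_consensus(calls, homopolymer_genome)
        assert [r.n_callers for r in recs] == [1, 1]

    def test_permutation_invariant(self, homopolymer_genome):
        calls = [call("chrH", 150, "G", "A", caller="gatk"),
                 call("chrH", 101, "AA", "A", caller="freebayes"),
                 call("chrH", 102, "AA", "A", caller="samtools")]
        fwd = vn.build_consensus(calls, homopolymer_genome)
        rev = vn.build_consensus(calls[::-1], homopolymer_genome)
        assert [(r.variant, sorted(r.supports)) for r in fwd] == \
               [(r.variant, sorted(r.supports)) for r in rev]

    def test_support_strings_follow_published_spelling(self, homopolymer_genome):
        calls = [call("chrH", 150, "G", "A", caller=c, mapper=m)
                 for c in ("gatk", "freebayes", "samtools", "varscan")
                 for m in ("bwa", "bowtie2", "gsnap")]
        (rec,) = vn.build_consensus(calls, homopolymer_genome)
        assert rec.mapper_string() == "Bwa;Bowtie2;GSNAP"
        assert rec.caller_string() == "gatk;samtools;freebayes;varscan"


class TestOverlapStatistics:
    def mk_records(self, support_sets, genome):
        recs = []
        for i, callers in enumerate(support_sets):
            pos = 10 + i
            c = [call("chrH", pos + 1, genome.fetch("chrH", pos, pos + 1),
                      "A" if genome.fetch("chrH", pos, pos + 1) != "A" else "C",
                      caller=x) for x in callers]
            recs.extend(vn.build_consensus(c, genome))
        return recs

    def test_venn_cells_and_fraction(self, homopolymer_genome):
        recs = self.mk_records([{"a"}, {"a", "b"}, {"a", "b", "c"}], homopolymer_genome)
        stats = vn.overlap_statistics(recs, axis="caller")
        assert stats["SNV"]["cells"] == {"a": 1, "a;b": 1, "a;b;c": 1}
        assert stats["SNV"]["fraction_ge2"] == pytest.approx(2 / 3)

    def test_all_supported_by_all(self, homopolymer_genome):
        recs = self.mk_records([{"a", "b"}, {"a", "b"}], homopolymer_genome)
        stats = vn.overlap_statistics(recs, axis="caller")
        assert stats["SNV"]["fraction_ge2"] == 1.0

    def test_single_caller_axis_rejected(self, homopolymer_genome):
        recs = self.mk_records([{"a"}], homopolymer_genome)
        with pytest.raises(ValueError):
            vn.overlap_statistics(recs, axis="caller")

    def test_cells_sum_to_total(self, homopolymer_genome):
        recs = self.mk_records([{"a"}, {"b"}, {"a", "c"}, {"a", "b", "c"}],
                               homopolymer_genome)
        stats = vn.overlap_statistics(recs, axis="caller")
        assert sum(stats["SNV"]["cells"].values()) == stats["SNV"]["n_variants"] == 4


class TestNormalizationConvergence:
    """Every equivalent spelling of an indel in a repeat tract maps to one key."""

    def random_genome_with_tracts(self, rng, n=4000):
        parts = []
        while sum(len(p) for p in parts) < n:
            if rng.random() < 0.4:  # drop in a repeat tract
                unit = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                parts.append(unit * int(rng.integers(2, 12)))
            else:
                parts.append("".join(rng.choice(list("ACGT"), size=20)))
        return make_genome_text("".join(parts)[:n], name="chrR")

    def test_all_spellings_one_key(self):
        rng = np.random.default_rng(123)
        genome = self.random_genome_with_tracts(rng)
        seq = genome.contigs["chrR"]
        checked = 0
        while checked < 120:
            start = int(rng.integers(30, len(seq) - 40))
            if rng.random() < 0.5:  # deletion
                length = int(rng.integers(1, 7))
                ref = seq[start : start + 1 + length]
                alt = ref[0]
            else:  # insertion of a slice of nearby sequence (often repeat unit)
                length = int(rng.integers(1, 7))
                ref = seq[start : start + 1]
                alt = ref + seq[start + 1 : start + 1 + length]
            if len(ref) == len(alt):
                continue
            spellings = equivalent_spellings(genome, "chrR", start, ref, alt)
            assert (start, ref, alt) in spellings
            keys = set()
            for p, r, a in spellings:
                nv = vn.normalize(
                    vn.VariantCall(contig="chrR", pos=p + 1, ref=r, alt=a,
                                   sample_id="-", caller_id="other", mapper_id="other"),
                    genome,
                )
                assert vn.normalize(nv, genome) == nv  # idempotence
                keys.add(nv)
            assert len(keys) == 1, (start, ref, alt, spellings, keys)
            checked += 1
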