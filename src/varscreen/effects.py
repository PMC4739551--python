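"""Variant effect prediction: feature assignment, codon/amino-acid change, frameshift.

Codons are always assembled from the spliced coding sequence, never from
genomic adjacency, so codons spanning splice junctions are handled correctly.
Amino acids are reported as 3-letter names ("Lys", "Ter" for stop, "Xaa" for
unknown), matching the summary-table style.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .normalize import NormalizedVariant
from .reference_io import GeneModel, ReferenceGenome

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class FeatureAssignment:
    gene_symbol: str
    refseq_mrna: str
    region_class: str  # CDS, UTR5, UTR3, intron, intergenic, noncoding_exon
    feature_label: str  # e.g. "exon_2;CDS_2"
    model: GeneModel | None = None


@dataclass
class CodonChange:
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    codon_number: int  # 1-based within the CDS
    position_in_codon: int  # 1..3


@dataclass
class FrameshiftResult:
    is_frameshift: bool
    indel_len_in_cds: int
    original_frame: int
    new_frame: int


class EffectError(ValueError):
    pass


def translate(codon: str) -> str:
    """Standard nuclear-code translation of one codon to its 3-letter name."""
    if len(codon) != 3:
        raise EffectError(f"codon must be 3 bases, got {codon!r}")
    codon = codon.upper()
    if set(codon) - set("ACGT"):
        aa = str(Seq(codon).translate()) if set(codon) <= set("ACGTN") else "X"
    else:
        aa = str(Seq(codon).translate())
    if aa == "*":
        return "Ter"
    if aa == "X":
        return "Xaa"
    return seq3(aa)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _exon_ordinal(model: GeneModel, exon_index: int) -> int:
    """Exon number in transcript (5'→3') orientation; genomic index in, ordinal out."""
    n = len(model.exons)
    return exon_index + 1 if model.strand == "+" else n - exon_index


def assign_features(nv: NormalizedVariant, models: list[GeneModel]) -> list[FeatureAssignment]:
    """One assignment per overlapping transcript; intergenic if none overlap.

    The affected genomic span of an indel is its reference footprint
    ``[start, start+len(ref))``; a pure insertion's footprint is its anchor
    base.  Labels follow the ``exon_i;CDS_j`` convention with ordinals counted
    from the transcript 5' end.
    """
    span_start, span_end = nv.start, max(nv.end, nv.start + 1)
    hits = []
    for model in models:
        if model.contig != nv.contig:
            continue
        if span_end <= model.tx_start or span_start >= model.tx_end:
            continue
        hits.append(_assign_one(nv, model, span_start, span_end))
    if not hits:
        return [FeatureAssignment("", "", "intergenic", "intergenic")]
    return hits


def _assign_one(nv, model, span_start, span_end) -> FeatureAssignment:
    exon_idx = None
    for i, (s, e) in enumerate(model.exons):
        if span_start < e and span_end > s:
            exon_idx = i
            break
    if exon_idx is None:
        return FeatureAssignment(model.gene_symbol, model.refseq_mrna, "intron", "intron", model)
    exon_ord = _exon_ordinal(model, exon_idx)
    if not model.is_coding:
        return FeatureAssignment(
            model.gene_symbol, model.refseq_mrna, "noncoding_exon", f"exon_{exon_ord}", model
        )
    if span_start < model.cds_end and span_end > model.cds_start:
        coding_exons = [
            i for i, (s, e) in enumerate(model.exons)
            if min(e, model.cds_end) > max(s, model.cds_start)
        ]
        cds_ord_genomic = coding_exons.index(exon_idx) + 1 if exon_idx in coding_exons else 1
        cds_ord = (
            cds_ord_genomic if model.strand == "+" else len(coding_exons) - cds_ord_genomic + 1
        )
        return FeatureAssignment(
            model.gene_symbol, model.refseq_mrna, "CDS", f"exon_{exon_ord};CDS_{cds_ord}", model
        )
    upstream_of_cds = span_end <= model.cds_start
    if model.strand == "+":
        region = "UTR5" if upstream_of_cds else "UTR3"
    else:
        region = "UTR3" if upstream_of_cds else "UTR5"
    return FeatureAssignment(
        model.gene_symbol, model.refseq_mrna, region, f"exon_{exon_ord}", model
    )


def cds_genomic_positions(model: GeneModel) -> list[int]:
    """Genomic 0-based positions of the CDS, in genomic order."""
    out = []
    for s, e in model.cds_exon_intervals():
        out.extend(range(s, e))
    return out


def coding_sequence(model: GeneModel, reference: ReferenceGenome) -> str:
    """Spliced CDS in coding (5'→3' transcript) orientation.

    Exonic CDS segments are concatenated in genomic order and
    reverse-complemented for minus-strand transcripts.
    """
    if not model.is_coding:
        raise EffectError(f"{model.refseq_mrna} is non-coding")
    genomic = "".join(
        reference.fetch(model.contig, s, e) for s, e in model.cds_exon_intervals()
    )
    return reverse_complement(genomic) if model.strand == "-" else genomic


def predict_codon_change(
    nv: NormalizedVariant, model: GeneModel, reference: ReferenceGenome
) -> CodonChange:
    """Codon and amino-acid consequence of an SNV inside a transcript's CDS.

    The CDS offset of the variant base is computed in coding orientation (the
    alt base is complemented for minus-strand genes); the reference allele is
    then replaced inside the extracted codon and both codons translated.
    """
    if nv.vtype != "SNV":
        raise EffectError("codon change is defined for SNVs only")
    if model.warnings:
        raise EffectError(f"{model.refseq_mrna}: malformed CDS ({model.warnings})")
    positions = cds_genomic_positions(model)
    try:
        genomic_idx = positions.index(nv.start)
    except ValueError:
        raise EffectError(f"variant {nv} not in CDS of {model.refseq_mrna}") from None
    cds = coding_sequence(model, reference)
    if model.strand == "+":
        offset = genomic_idx
        alt_base = nv.alt
    else:
        offset = len(positions) - 1 - genomic_idx
        alt_base = reverse_complement(nv.alt)
    codon_number = offset // 3 + 1
    pos_in_codon = offset % 3 + 1
    ref_codon = cds[(codon_number - 1) * 3 : codon_number * 3]
    if ref_codon[pos_in_codon - 1] == alt_base:
        raise EffectError("alt equals the coding-strand reference base")
    alt_codon = (
        ref_codon[: pos_in_codon - 1] + alt_base + ref_codon[pos_in_codon:]
    )
    return CodonChange(
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        ref_aa=translate(ref_codon),
        alt_aa=translate(alt_codon),
        codon_number=codon_number,
        position_in_codon=pos_in_codon,
    )


def predict_frameshift(nv: NormalizedVariant, model: GeneModel) -> FrameshiftResult:
    """Frameshift consequence of an indel overlapping a transcript's CDS.

    Deleted bases count when they are exonic CDS positions; inserted bases
    (which have no genomic coordinate) count in full when the insertion point
    sits between two in-CDS positions.  The new reading frame is the CDS
    length after incorporating the indel, mod 3.
    """
    if nv.vtype == "SNV":
        raise EffectError("frameshift is defined for indels only")
    cds_set = set(cds_genomic_positions(model))
    cds_len = len(cds_set)
    if nv.vtype == "DEL":
        deleted = range(nv.start + 1, nv.start + len(nv.ref))
        in_cds = sum(1 for p in deleted if p in cds_set)
        new_len = cds_len - in_cds
    else:
        anchor_in = nv.start in cds_set
        next_in = (nv.start + 1) in cds_set
        in_cds = (len(nv.alt) - 1) if (anchor_in and next_in) else 0
        new_len = cds_len + in_cds
    if in_cds == 0:
        raise EffectError(f"indel {nv} entirely outside CDS of {model.refseq_mrna}")
    return FrameshiftResult(
        is_frameshift=in_cds % 3 != 0,
        indel_len_in_cds=in_cds,
        original_frame=cds_len % 3,
        new_frame=new_len % 3,
    )
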