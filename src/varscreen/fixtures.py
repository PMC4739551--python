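"""Deterministic synthetic data: genomes, gene models, reads, tracks, caller VCFs.

Everything every module consumes can be generated here from a single integer
seed, at desk scale: kilobase contigs, a handful of genes with well-formed
CDSs (start codon, stop codon, length divisible by 3), reads tiling the
contigs at a chosen depth with planted variants at known allele fractions,
and one VCF per (mapper, caller) whose records spell the same planted
variants with caller-specific jitter (right-shifted indels, suffix-padded
alleles).  Same seed, byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .effects import cds_genomic_positions, coding_sequence, reverse_complement, translate
from .normalize import NormalizedVariant, normalize
from .reference_io import GeneModel, ReferenceGenome

_STOPS = {"TAA", "TAG", "TGA"}
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS]

DEFAULT_MAPPERS = ("bwa", "bowtie2", "gsnap")
DEFAULT_CALLERS = ("gatk", "samtools", "freebayes", "varscan")


@dataclass
class FixtureSpec:
    """Knobs for the synthetic study; defaults are the desk-scale conditions."""

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 10_000
    n_genes: int = 4
    exons_per_gene: int = 2
    read_length: int = 100
    depth: int = 60
    base_error_rate: float = 0.001
    duplicate_fraction: float = 0.1
    allele_fraction: float = 0.5
    utr_length: int = 30
    intron_length: int = 60
    codons_per_gene: int = 40
    caller_jitter: tuple[str, ...] = ("right_shift_indels", "suffix_padding")


@dataclass
class PlantedVariant:
    """Ground-truth variant with its expected consequence label."""

    contig: str
    start: int  # 0-based, already normalized spelling
    ref: str
    alt: str
    af: float = 0.5
    private_to_caller: str | None = None
    label: str = ""  # synonymous / missense / frameshift / inframe / intergenic / known

    @property
    def nv(self) -> NormalizedVariant:
        return NormalizedVariant(self.contig, self.start, self.ref, self.alt)


def make_genome(spec: FixtureSpec):
    """Random contigs with planted genes; returns (genome, models, refflat, ids_tsv).

    Genes alternate strand (+, -, +, ...), each with ``exons_per_gene`` exons
    and a CDS of ``codons_per_gene`` codons beginning ATG and ending TAA, so
    every model satisfies the divisible-by-3 invariant and translates to a
    stop-free peptide ending in Ter.
    """
    rng = np.random.default_rng(spec.seed)
    contigs = {
        f"chr{i + 1}": list(rng.choice(list("ACGT"), size=spec.contig_length))
        for i in range(spec.n_contigs)
    }
    models: list[GeneModel] = []
    refflat_rows, id_rows = [], ["transcript\tentrez\tprotein\tuniprot\tkegg\tomim\thgnc"]
    utr, intron, n_ex = spec.utr_length, spec.intron_length, spec.exons_per_gene
    cds_len = spec.codons_per_gene * 3
    span = 2 * utr + cds_len + intron * (n_ex - 1)
    gap = 900
    cursor, contig_idx = 400, 0
    for g in range(spec.n_genes):
        if cursor + span + 400 > spec.contig_length:
            contig_idx += 1
            cursor = 400
            if contig_idx >= spec.n_contigs:
                raise ValueError(f"gene {g} does not fit any contig")
        contig = f"chr{contig_idx + 1}"
        strand = "+" if g % 2 == 0 else "-"
        # split the CDS across exons; first/last exons carry the UTRs
        chunk = cds_len // n_ex
        chunks = [chunk] * (n_ex - 1) + [cds_len - chunk * (n_ex - 1)]
        exons, pos = [], cursor
        for e in range(n_ex):
            length = chunks[e] + (utr if e == 0 else 0) + (utr if e == n_ex - 1 else 0)
            exons.append((pos, pos + length))
            pos += length + intron
        tx_start, tx_end = exons[0][0], exons[-1][1]
        cds_start, cds_end = tx_start + utr, tx_end - utr
        body = "".join(rng.choice(_CODONS) for _ in range(spec.codons_per_gene - 2))
        cds_seq = "ATG" + body + "TAA"
        genomic_cds = cds_seq if strand == "+" else reverse_complement(cds_seq)
        positions = []
        for s, e in exons:
            s2, e2 = max(s, cds_start), min(e, cds_end)
            positions.extend(range(s2, e2))
        seq = contigs[contig]
        for p, base in zip(positions, genomic_cds):
            seq[p] = base
        tx = f"NM_{100000 + g}"
        model = GeneModel(
            gene_symbol=f"GENE{g + 1}",
            refseq_mrna=tx,
            contig=contig,
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_end,
            cds_start=cds_start,
            cds_end=cds_end,
            exons=exons,
            entrez_id=str(1000 + g),
            refseq_protein=f"NP_{100000 + g}",
            uniprot_id=f"P1{1000 + g}",
            kegg_id=f"hsa0{3440 + g}",
            omim_id=str(600000 + g),
            hgnc_id=str(7000 + g),
        )
        models.append(model)
        refflat_rows.append(
            "\t".join(
                [
                    model.gene_symbol, tx, contig, strand,
                    str(tx_start), str(tx_end), str(cds_start), str(cds_end),
                    str(n_ex),
                    "".join(f"{s}," for s, _ in exons),
                    "".join(f"{e}," for _, e in exons),
                ]
            )
        )
        id_rows.append(
            "\t".join(
                [tx, model.entrez_id, model.refseq_protein, model.uniprot_id,
                 model.kegg_id, model.omim_id, model.hgnc_id]
            )
        )
        cursor = tx_end + gap
    genome = ReferenceGenome(
        contigs={k: "".join(v) for k, v in contigs.items()}, assembly_label="GRCh37"
    )
    return genome, models, "\n".join(refflat_rows) + "\n", "\n".join(id_rows) + "\n"


def plant_coding_snv(
    model: GeneModel, genome: ReferenceGenome, kind: str, codon_number: int
) -> PlantedVariant:
    """Construct an SNV in the given codon with a synonymous or missense effect."""
    cds = coding_sequence(model, genome)
    positions = cds_genomic_positions(model)
    for pos_in_codon in (3, 1, 2):
        offset = (codon_number - 1) * 3 + pos_in_codon - 1
        ref_codon = cds[(codon_number - 1) * 3 : codon_number * 3]
        for alt_base in "ACGT":
            if alt_base == ref_codon[pos_in_codon - 1]:
                continue
            alt_codon = ref_codon[: pos_in_codon - 1] + alt_base + ref_codon[pos_in_codon:]
            if alt_codon in _STOPS:
                continue
            same_aa = translate(alt_codon) == translate(ref_codon)
            if (kind == "synonymous") != same_aa:
                continue
            if model.strand == "+":
                gpos, galt = positions[offset], alt_base
            else:
                gpos = positions[len(positions) - 1 - offset]
                galt = reverse_complement(alt_base)
            gref = genome.fetch(model.contig, gpos, gpos + 1)
            return PlantedVariant(
                contig=model.contig, start=gpos, ref=gref, alt=galt, label=kind
            )
    raise ValueError(f"no {kind} SNV constructible in codon {codon_number}")


def plant_cds_deletion(
    model: GeneModel, genome: ReferenceGenome, length: int, codon_number: int
) -> PlantedVariant:
    """Deletion of ``length`` bases inside the CDS, anchored one base left."""
    positions = cds_genomic_positions(model)
    offset = (codon_number - 1) * 3
    start = positions[offset]  # genomic start of deleted run
    anchor = start - 1
    ref = genome.fetch(model.contig, anchor, start + length)
    alt = ref[0]
    label = "frameshift" if length % 3 else "inframe"
    pv = PlantedVariant(contig=model.contig, start=anchor, ref=ref, alt=alt, label=label)
    nv = normalize(pv.nv, genome)
    return PlantedVariant(
        contig=nv.contig, start=nv.start, ref=nv.ref, alt=nv.alt, label=label
    )


def apply_variants_to_read(
    genome: ReferenceGenome, contig: str, start: int, length: int,
    variants: list[PlantedVariant],
) -> tuple[str, str]:
    """Build (seq, cigar) for a read of ``length`` query bases from ``start``
    on the haplotype carrying ``variants`` (sorted, non-overlapping)."""
    seq_parts: list[str] = []
    ops: list[tuple[str, int]] = []

    def emit(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    qlen = 0
    rpos = start
    contig_len = len(genome.contigs[contig])
    events = sorted(variants, key=lambda v: v.start)
    i = 0
    while qlen < length and rpos < contig_len:
        ev = None
        for v in events[i:]:
            if v.start >= rpos:
                ev = v
                break
        if ev is None or ev.start >= rpos + (length - qlen):
            take = min(length - qlen, contig_len - rpos)
            seq_parts.append(genome.fetch(contig, rpos, rpos + take))
            emit("M", take)
            rpos += take
            qlen += take
            break
        take = min(ev.start - rpos, length - qlen)
        if take > 0:
            seq_parts.append(genome.fetch(contig, rpos, rpos + take))
            emit("M", take)
            rpos += take
            qlen += take
        if qlen >= length:
            break
        if ev.nv.vtype == "SNV":
            seq_parts.append(ev.alt)
            emit("M", 1)
            rpos += 1
            qlen += 1
        elif ev.nv.vtype == "DEL":
            seq_parts.append(ev.alt[:1])
            emit("M", 1)
            qlen += 1
            emit("D", len(ev.ref) - 1)
            rpos = ev.start + len(ev.ref)
        else:  # INS
            piece = ev.alt[: length - qlen]
            seq_parts.append(piece)
            emit("M", 1)
            emit("I", len(piece) - 1)
            rpos += 1
            qlen += len(piece)
        i = events.index(ev) + 1
    seq = "".join(seq_parts)[:length]
    # trim CIGAR to the query length actually kept
    trimmed: list[tuple[str, int]] = []
    q = 0
    for op, n in ops:
        if op in "MI":
            keep = min(n, length - q)
            if keep > 0:
                trimmed.append((op, keep))
                q += keep
            if q >= length:
                break
        else:
            trimmed.append((op, n))
    while trimmed and trimmed[-1][0] not in "MI":
        trimmed.pop()
    cigar = "".join(f"{n}{op}" for op, n in trimmed)
    return seq, cigar


def make_reads(
    genome: ReferenceGenome, planted: list[PlantedVariant], spec: FixtureSpec,
    qname_prefix: str = "r",
) -> str:
    """SAM text tiling every contig at roughly ``spec.depth``x coverage.

    Reads overlapping a planted variant carry its alt allele with probability
    equal to the planted allele fraction; sequencing errors are injected at
    ``base_error_rate`` and a ``duplicate_fraction`` of reads is emitted twice
    (second copy with lower base qualities, so duplicate marking has a
    deterministic survivor).
    """
    rng = np.random.default_rng(spec.seed + 7)
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in genome.contigs.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    by_contig: dict[str, list[PlantedVariant]] = {}
    for v in planted:
        by_contig.setdefault(v.contig, []).append(v)
    rid = 0
    R = spec.read_length
    for contig, seq in genome.contigs.items():
        L = len(seq)
        n_reads = max(1, (spec.depth * L) // R)
        # unique start positions so only injected copies form duplicate groups
        n_reads = min(n_reads, max(1, L - R))
        starts = np.sort(rng.permutation(max(1, L - R))[:n_reads])
        cvars = sorted(by_contig.get(contig, []), key=lambda v: v.start)
        for s in starts:
            s = int(s)
            overlapping = [
                v for v in cvars if s <= v.start < s + R
            ]
            chosen = [v for v in overlapping if rng.random() < v.af]
            read_seq, cigar = apply_variants_to_read(genome, contig, s, R, chosen)
            if len(read_seq) < 30:
                continue
            quals = rng.integers(30, 41, size=len(read_seq))
            bases = list(read_seq)
            for j in range(len(bases)):
                if rng.random() < spec.base_error_rate:
                    bases[j] = "ACGT"[int(rng.integers(0, 4))]
            read_seq = "".join(bases)
            qual_str = "".join(chr(q + 33) for q in quals)
            rid += 1
            lines.append(
                f"{qname_prefix}{rid:06d}\t0\t{contig}\t{s + 1}\t60\t{cigar}\t*\t0\t0\t{read_seq}\t{qual_str}"
            )
            if rng.random() < spec.duplicate_fraction:
                dup_quals = "".join(chr(max(2, q - 5) + 33) for q in quals)
                lines.append(
                    f"{qname_prefix}{rid:06d}d\t0\t{contig}\t{s + 1}\t60\t{cigar}\t*\t0\t0\t{read_seq}\t{dup_quals}"
                )
    return "\n".join(lines) + "\n"


def _right_shift(nv: NormalizedVariant, genome: ReferenceGenome) -> NormalizedVariant:
    """Rightmost equivalent spelling of an indel inside its repeat tract."""
    if nv.vtype == "SNV":
        return nv
    start, ref, alt = nv.start, nv.ref, nv.alt
    contig_len = len(genome.contigs[nv.contig])
    while start + len(ref) < contig_len:
        nxt = genome.fetch(nv.contig, start + len(ref), start + len(ref) + 1)
        # shifting right by one is valid when the base after the ref span
        # equals the base just after the anchor in both alleles
        if len(ref) > len(alt):  # deletion
            if ref[1] != nxt:
                break
            start += 1
            ref = ref[1:] + nxt
            alt = ref[0]
        else:  # insertion
            if alt[1] != nxt:
                break
            start += 1
            alt = alt[1:] + nxt
            ref = alt[0]
    return NormalizedVariant(nv.contig, start, ref, alt)


def _suffix_pad(nv: NormalizedVariant, genome: ReferenceGenome) -> NormalizedVariant:
    nxt_pos = nv.start + len(nv.ref)
    if nxt_pos >= len(genome.contigs[nv.contig]):
        return nv
    nxt = genome.fetch(nv.contig, nxt_pos, nxt_pos + 1)
    return NormalizedVariant(nv.contig, nv.start, nv.ref + nxt, nv.alt + nxt)


def spell_for_caller(
    nv: NormalizedVariant, genome: ReferenceGenome, caller: str, jitter: tuple[str, ...]
) -> NormalizedVariant:
    """Caller-specific representation of the same variant."""
    out = nv
    if "right_shift_indels" in jitter and caller in ("samtools", "varscan"):
        out = _right_shift(out, genome)
    if "suffix_padding" in jitter and caller == "freebayes":
        out = _suffix_pad(out, genome)
    return out


def make_caller_vcfs(
    planted: list[PlantedVariant],
    genome: ReferenceGenome,
    spec: FixtureSpec,
    sample_id: str,
    mappers: tuple[str, ...] = DEFAULT_MAPPERS,
    callers: tuple[str, ...] = DEFAULT_CALLERS,
) -> dict[tuple[str, str], str]:
    """One VCF text per (mapper, caller), with per-caller spelling jitter.

    Shared variants appear in every file; a variant with ``private_to_caller``
    set appears only in that caller's files, creating known Venn structure.
    """
    out = {}
    depth = spec.depth
    for mapper in mappers:
        for caller in callers:
            lines = [
                "##fileformat=VCFv4.2",
                f"##source={caller}",
                '##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">',
                '##INFO=<ID=DP4,Number=4,Type=Integer,Description="Strand depths">',
                '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
                '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">',
                '##FORMAT=<ID=AD,Number=.,Type=Integer,Description="Allele depths">',
                '##FORMAT=<ID=FREQ,Number=1,Type=String,Description="Allele frequency">',
                f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample_id}",
            ]
            records = []
            for v in planted:
                if v.private_to_caller is not None and v.private_to_caller != caller:
                    continue
                spelled = spell_for_caller(v.nv, genome, caller, spec.caller_jitter)
                alt_d = int(round(v.af * depth))
                ref_d = depth - alt_d
                if caller == "samtools":
                    info = f"DP={depth};DP4={ref_d - ref_d // 2},{ref_d // 2},{alt_d - alt_d // 2},{alt_d // 2}"
                    fmt, sample = "GT:DP", f"0/1:{depth}"
                elif caller == "varscan":
                    info = f"DP={depth}"
                    fmt, sample = "GT:DP:AD:FREQ", f"0/1:{depth}:{alt_d}:{100.0 * v.af:.2f}%"
                else:
                    info = f"DP={depth}"
                    fmt, sample = "GT:DP:AD", f"0/1:{depth}:{ref_d},{alt_d}"
                records.append(
                    (spelled.contig, spelled.start,
                     f"{spelled.contig}\t{spelled.start + 1}\t.\t{spelled.ref}\t{spelled.alt}"
                     f"\t100\tPASS\t{info}\t{fmt}\t{sample}")
                )
            records.sort()
            lines.extend(r[2] for r in records)
            out[(mapper, caller)] = "\n".join(lines) + "\n"
    return out


@dataclass
class RunFixture:
    """Everything a full end-to-end run needs, plus the planted ground truth."""

    genome: ReferenceGenome
    models: list[GeneModel]
    planted: dict[str, list[PlantedVariant]]  # patient -> variants
    root: str
    manifest_path: str = ""
    options_path: str = ""
    rsids: dict[tuple, str] = field(default_factory=dict)
    hotspot_variant: PlantedVariant | None = None


def make_run_directory(root: str, spec: FixtureSpec | None = None) -> RunFixture:
    """Write a complete 2-patient run directory under ``root``.

    Patients belong to one family and share two variants.  The planted set
    covers: a known (rsID'd, hotspot-overlapping) coding SNV, synonymous and
    missense SNVs, a frameshift and an in-frame CDS deletion, an intergenic
    SNV with an rsID, one without, and two caller-private SNVs.
    """
    spec = spec or FixtureSpec()
    os.makedirs(root, exist_ok=True)
    for sub in ("tracks", "reads", "calls"):
        os.makedirs(os.path.join(root, sub), exist_ok=True)
    genome, models, refflat, ids_tsv = make_genome(spec)
    g1, g2, g3 = models[0], models[1], models[2 % len(models)]

    v_known = plant_coding_snv(g1, genome, "missense", codon_number=5)
    v_known.label = "known"
    v_syn = plant_coding_snv(g1, genome, "synonymous", codon_number=12)
    v_mis = plant_coding_snv(g2, genome, "missense", codon_number=8)
    v_fs = plant_cds_deletion(g3, genome, length=1, codon_number=10)
    v_inframe = plant_cds_deletion(g1, genome, length=3, codon_number=20)
    inter_pos = 50
    v_inter_rs = PlantedVariant(
        contig=g1.contig, start=inter_pos,
        ref=genome.fetch(g1.contig, inter_pos, inter_pos + 1),
        alt={"A": "G", "C": "T", "G": "A", "T": "C"}[
            genome.fetch(g1.contig, inter_pos, inter_pos + 1)
        ],
        label="intergenic_rsid",
    )
    inter2 = 150
    v_inter = PlantedVariant(
        contig=g1.contig, start=inter2,
        ref=genome.fetch(g1.contig, inter2, inter2 + 1),
        alt={"A": "C", "C": "A", "G": "T", "T": "G"}[
            genome.fetch(g1.contig, inter2, inter2 + 1)
        ],
        label="intergenic",
    )
    v_priv1 = plant_coding_snv(g2, genome, "missense", codon_number=20)
    v_priv1.private_to_caller = "gatk"
    v_priv1.label = "private_gatk"
    v_priv2 = plant_coding_snv(g3, genome, "missense", codon_number=25)
    v_priv2.private_to_caller = "varscan"
    v_priv2.label = "private_varscan"

    p1 = [v_known, v_syn, v_mis, v_fs, v_inframe, v_inter_rs, v_inter, v_priv1, v_priv2]
    p2 = [v_known, v_mis, plant_coding_snv(g1, genome, "missense", codon_number=30)]
    planted = {"P000001": p1, "P000002": p2}

    # membership tracks: rsIDs for the 'known' variants, flags around them
    rsids = {}
    dbsnp_rows = []
    for i, v in enumerate((v_known, v_inter_rs)):
        rs = f"rs17999{i + 10}"
        rsids[(v.contig, v.start, v.ref, v.alt)] = rs
        dbsnp_rows.append(f"{v.contig}\t{v.start}\t{v.start + 1}\t{rs}\t{v.ref}\t{v.alt}")
    tracks = {
        "dbSnp_Id": "\n".join(dbsnp_rows) + "\n",
        "dbSnp_Common": f"{v_known.contig}\t{v_known.start}\t{v_known.start + 1}\trs1799910\n",
        "dbSnp_Coding": f"{v_known.contig}\t{g1.cds_start}\t{g1.cds_end}\n",
        "dbSnp_HapMap": f"{v_known.contig}\t{v_known.start - 5}\t{v_known.start + 5}\n",
        "dbSnp_Flagged": f"{g2.contig}\t{g2.tx_start}\t{g2.tx_start + 1}\n",
        "dbSnp_Mult": f"{g2.contig}\t{g2.tx_start}\t{g2.tx_start + 1}\n",
        "dbSnp_Cpg_Island": f"{v_known.contig}\t{v_known.start - 2}\t{v_known.start + 3}\n",
        "Gwas_Catalogue": f"{v_inter_rs.contig}\t{v_inter_rs.start}\t{v_inter_rs.start + 1}\n",
    }
    for name, text in tracks.items():
        with open(os.path.join(root, "tracks", f"{name}.tsv"), "w") as fh:
            fh.write(text)
    with open(os.path.join(root, "hotspots.bed"), "w") as fh:
        fh.write(f"{v_known.contig}\t{v_known.start}\t{v_known.start + 1}\tHOT_{g1.gene_symbol}\n")

    with open(os.path.join(root, "genome.fa"), "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(os.path.join(root, "genes.refflat"), "w") as fh:
        fh.write(refflat)
    with open(os.path.join(root, "ids.tsv"), "w") as fh:
        fh.write(ids_tsv)

    manifest_rows = [
        "\t".join(
            ("Patient_Id", "Family_Id", "Assay_Id", "Seq_Platform", "Seq_System",
             "Lab_Analysis_Date", "Fastq", "Fastqc_Report", "Sam_Files", "Vcf_Files")
        )
    ]
    for pi, (patient, variants) in enumerate(sorted(planted.items())):
        sub_spec = FixtureSpec(**{**spec.__dict__, "seed": spec.seed + 100 + pi})
        sam_cells, vcf_cells = [], []
        for mapper in DEFAULT_MAPPERS:
            sam_path = f"reads/{patient}_{mapper}.sam"
            with open(os.path.join(root, sam_path), "w") as fh:
                fh.write(make_reads(genome, variants, sub_spec, qname_prefix=f"{patient}_{mapper}_"))
            sam_cells.append(f"{mapper},{sam_path}")
        vcfs = make_caller_vcfs(variants, genome, sub_spec, patient)
        for (mapper, caller), text in sorted(vcfs.items()):
            vcf_path = f"calls/{patient}_{mapper}_{caller}.vcf"
            with open(os.path.join(root, vcf_path), "w") as fh:
                fh.write(text)
            vcf_cells.append(f"{mapper},{caller},{vcf_path}")
        manifest_rows.append(
            "\t".join(
                (patient, "F01", "PANEL1", "Illumina", "HiSeq2000",
                 "2015-06-01_12-00-00", f"{patient}.fq", f"{patient}_qc.html",
                 ";".join(sam_cells), ";".join(vcf_cells))
            )
        )
    manifest_path = os.path.join(root, "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("\n".join(manifest_rows) + "\n")

    options_path = os.path.join(root, "options.txt")
    with open(options_path, "w") as fh:
        fh.write(
            "\n".join(
                [
                    "reference=genome.fa",
                    "genes=genes.refflat",
                    "gene_ids=ids.tsv",
                    "tracks_dir=tracks",
                    "hotspots=hotspots.bed",
                    "assembly=GRCh37",
                    "min_mapq=20",
                    "min_base_qual=20",
                    "require_proper_pair=false",
                    "drop_duplicates=true",
                    "min_total_cov=20",
                    "min_alt_cov=4",
                    "min_af=0.10",
                    "flank_window=10",
                    "outdir=out",
                ]
            )
            + "\n"
        )
    return RunFixture(
        genome=genome,
        models=models,
        planted=planted,
        root=root,
        manifest_path=manifest_path,
        options_path=options_path,
        rsids=rsids,
        hotspot_variant=v_known,
    )
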