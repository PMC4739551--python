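"""Summary-table assembly, per-patient VCF output, and the end-to-end run.

One output row per (patient, normalized variant), in the fixed column order
of the master summary table.  Per-patient processing is independent, so the
run can execute patients concurrently and still produce byte-identical output
(rows are assembled, then sorted by patient, contig, start).
"""

from __future__ import annotations

import logging
import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

from . import annotate, effects, normalize as vn, pileup as vp, reference_io as rio, stats as vs

log = logging.getLogger(__name__)

SUMMARY_COLUMNS: tuple[str, ...] = (
    "Patient_Id", "Family_Id", "Lab_Analysis_Date", "Seq_Platform", "Seq_System",
    "Assay_Id", "Var_Id", "Var_Type", "Var_Cov", "Total_Cov", "A", "C", "G", "T",
    "Var_Chr", "Var_Start", "Var_End", "Var_Strand", "Var_Gene", "Var_RefGene",
    "Var_Feature", "Var_DNA", "Var_Codon", "Var_AA", "Frameshift",
    "FASTQC_Report", "Patient_Fastq", "Patient_Bam", "Patient_Vcf",
) + annotate.ANNOTATION_FIELDS + (
    "Fishers_Exact_Test_pvalue", "Fishers_Exact_Test_pvalue_FDR_corrected",
    "dbSnp_Id",
) + annotate.FLAG_TRACKS + ("Mapper_Name", "Variant_Caller")


@dataclass
class RunOptions:
    """Run configuration, loadable from a key=value options file."""

    reference: str = "genome.fa"
    genes: str = "genes.refflat"
    gene_ids: str = "ids.tsv"
    tracks_dir: str = "tracks"
    hotspots: str = "hotspots.bed"
    assembly: str = "GRCh37"
    min_mapq: int = 20
    min_base_qual: int = 20
    require_proper_pair: bool = False
    drop_duplicates: bool = True
    min_total_cov: int = 20
    min_alt_cov: int = 4
    min_af: float = 0.10
    flank_window: int = 10
    outdir: str = "out"

    @classmethod
    def from_file(cls, path: str) -> "RunOptions":
        opts = cls()
        bools = {"require_proper_pair", "drop_duplicates"}
        ints = {"min_mapq", "min_base_qual", "min_total_cov", "min_alt_cov", "flank_window"}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or "=" not in line:
                    continue
                key, value = line.split("=", 1)
                key, value = key.strip(), value.strip()
                if not hasattr(opts, key):
                    log.warning("unknown option key %r ignored", key)
                    continue
                if key in bools:
                    setattr(opts, key, value.lower() in ("1", "true", "yes"))
                elif key in ints:
                    setattr(opts, key, int(value))
                elif key == "min_af":
                    opts.min_af = float(value)
                else:
                    setattr(opts, key, value)
        return opts

    def read_policy(self) -> vp.ReadFilterPolicy:
        return vp.ReadFilterPolicy(
            min_mapq=self.min_mapq,
            require_proper_pair=self.require_proper_pair,
            drop_duplicates=self.drop_duplicates,
        )

    def filter_policy(self) -> vs.FilterPolicy:
        return vs.FilterPolicy(
            min_total_cov=self.min_total_cov,
            min_alt_cov=self.min_alt_cov,
            min_af=self.min_af,
        )


@dataclass
class ReferenceBundle:
    genome: rio.ReferenceGenome
    models: list[rio.GeneModel]
    tracks: dict[str, rio.MembershipTrack]
    hotspots: rio.HotspotSet


@dataclass
class SummaryRow:
    cells: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in SUMMARY_COLUMNS:
            self.cells.setdefault(col, "")

    def __getitem__(self, col: str) -> str:
        return self.cells[col]

    def to_line(self) -> str:
        return "\t".join(self.cells[c] for c in SUMMARY_COLUMNS)


def load_reference_bundle(options: RunOptions, root: str) -> ReferenceBundle:
    with open(os.path.join(root, options.reference)) as fh:
        genome = rio.load_reference(fh, assembly_label=options.assembly)
    with open(os.path.join(root, options.genes)) as genes_fh:
        ids_path = os.path.join(root, options.gene_ids)
        if os.path.exists(ids_path):
            with open(ids_path) as ids_fh:
                models = rio.load_gene_models(genes_fh, ids_fh)
        else:
            models = rio.load_gene_models(genes_fh)
    tracks: dict[str, rio.MembershipTrack] = {}
    tdir = os.path.join(root, options.tracks_dir)
    if os.path.isdir(tdir):
        for fname in sorted(os.listdir(tdir)):
            name = fname.rsplit(".", 1)[0]
            with open(os.path.join(tdir, fname)) as fh:
                tracks[name] = rio.load_membership_track(name, fh)
    hotspot_path = os.path.join(root, options.hotspots)
    if os.path.exists(hotspot_path):
        with open(hotspot_path) as fh:
            hotspots = rio.load_hotspots(fh)
    else:
        hotspots = rio.HotspotSet(intervals=[])
    return ReferenceBundle(genome=genome, models=models, tracks=tracks, hotspots=hotspots)


def _complement_allele(seq: str) -> str:
    return effects.reverse_complement(seq)


def _var_dna(nv: vn.NormalizedVariant, assignments) -> str:
    """Coding-orientation ref>alt for genic SNVs, genomic orientation otherwise."""
    strand = "+"
    for a in assignments:
        if a.model is not None:
            strand = a.model.strand
            break
    if nv.vtype == "SNV" and strand == "-":
        return f"{_complement_allele(nv.ref)}>{_complement_allele(nv.alt)}"
    return f"{nv.ref}>{nv.alt}"


def _frameshift_cell(results: list[effects.FrameshiftResult]) -> str:
    parts = []
    for r in results:
        word = "yes" if r.is_frameshift else "no"
        parts.append(f"{word}({r.original_frame}>{r.new_frame})")
    return ";".join(parts)


@dataclass
class PatientResult:
    rows: list[SummaryRow]
    counters: dict[str, int]
    vcf_records: list[tuple]


def process_patient(
    patient: rio.ManifestRow,
    bundle: ReferenceBundle,
    options: RunOptions,
    root: str,
) -> PatientResult:
    """Run the full post-alignment analysis for one patient."""
    genome = bundle.genome
    counters = {"reads_parsed": 0, "reads_unmapped": 0, "calls_in": 0,
                "variants_normalized": 0, "variants_pass": 0, "rows_written": 0}

    # reads from the first-listed mapper are the coverage authority
    reads: list[vp.AlignedRead] = []
    if patient.sam_files:
        mapper, sam_path = patient.sam_files[0]
        with open(os.path.join(root, sam_path)) as fh:
            reads, skipped = vp.parse_sam_counted(fh)
        counters["reads_parsed"] = len(reads)
        counters["reads_unmapped"] = skipped
        vp.mark_duplicates(reads)

    calls: list[vn.VariantCall] = []
    for mapper, caller, vcf_path in patient.vcf_files:
        with open(os.path.join(root, vcf_path)) as fh:
            calls.extend(
                vn.read_vcf(fh, caller_id=caller, mapper_id=mapper,
                            sample_id=patient.patient_id, reference=genome)
            )
    counters["calls_in"] = len(calls)
    records = vn.build_consensus([c for c in calls if c.filter_pass], genome)
    counters["variants_normalized"] = len(records)

    policy = options.read_policy()
    fpolicy = options.filter_policy()
    window = options.flank_window

    staged = []
    for rec in records:
        nv = rec.variant
        lo = max(0, nv.start - window)
        hi = min(len(genome.contigs[nv.contig]), nv.end + window)
        columns = vp.build_pileup(
            [r for r in reads if r.contig == nv.contig and r.pos < hi and r.reference_end() > lo],
            nv.contig, lo, hi, policy=policy, min_base_qual=options.min_base_qual,
        ) if reads else []
        col = next((c for c in columns if c.pos == nv.start), None)
        depth = rec.sample_depths.get(patient.patient_id, (None, None))
        if col is not None:
            alt_base = nv.alt if nv.vtype == "SNV" else None
            decomp = vs.coverage_decomposition(col, alt_base, alt_depth_fallback=depth[1])
        else:
            total = depth[0] or 0
            alt_d = depth[1]
            ref_d = max(0, total - (alt_d or 0))
            decomp = vs.CoverageDecomposition(A=ref_d, C=0, G=0, T=alt_d or 0, var_cov=alt_d)
        ok, reasons = vs.apply_filters(decomp, fpolicy)
        if not ok:
            log.info("%s %s filtered: %s", patient.patient_id, nv, reasons)
            continue
        counters["variants_pass"] += 1
        flank = vs.flanking_quality(columns, nv.start, window=window) if columns else None
        staged.append((rec, decomp, flank))

    # per-variant Fisher against the mean counts of the patient's other variants
    counts = []
    for rec, decomp, _ in staged:
        nv = rec.variant
        if nv.vtype == "SNV":
            ref_count = getattr(decomp, nv.ref)
            alt_count = decomp.var_cov or 0
        else:
            alt_count = decomp.var_cov or 0
            ref_count = max(0, decomp.total - alt_count)
        counts.append((ref_count, alt_count))
    fishers = []
    for i in range(len(staged)):
        others = counts[:i] + counts[i + 1 :]
        fishers.append(vs.variant_fisher(counts[i], others))
    pvals = [f.p for f in fishers if f.p is not None]
    adj_iter = iter(vs.adjust_fdr(pvals))
    for f in fishers:
        f.p_adj = next(adj_iter) if f.p is not None else None

    rows: list[SummaryRow] = []
    vcf_records = []
    for (rec, decomp, flank), fisher in zip(staged, fishers):
        nv = rec.variant
        assignments = effects.assign_features(nv, bundle.models)
        vclass, rsid = annotate.classify_variant(nv, assignments, bundle.tracks.get("dbSnp_Id"))
        flags = annotate.membership_flags(nv, bundle.tracks)
        hotspot = annotate.flag_hotspot(nv, bundle.hotspots)
        rec.hotspot = hotspot

        genic = [a for a in assignments if a.model is not None]
        codon_changes, fs_results = [], []
        for a in genic:
            model = a.model
            if a.region_class != "CDS" or not model.is_coding or model.warnings:
                continue
            if nv.vtype == "SNV":
                try:
                    codon_changes.append(effects.predict_codon_change(nv, model, bundle.genome))
                except effects.EffectError:
                    pass
            else:
                try:
                    fs_results.append(effects.predict_frameshift(nv, model))
                except effects.EffectError:
                    pass

        first_model = genic[0].model if genic else None
        identifiers = annotate.XrefIdentifiers(
            rsid=rsid,
            entrez_id=first_model.entrez_id if first_model else "",
            gene_symbol=first_model.gene_symbol if first_model else "",
            refseq_mrna=first_model.refseq_mrna if first_model else "",
            refseq_protein=first_model.refseq_protein if first_model else "",
            uniprot_id=first_model.uniprot_id if first_model else "",
            kegg_id=first_model.kegg_id if first_model else "",
            omim_id=first_model.omim_id if first_model else "",
            hgnc_id=first_model.hgnc_id if first_model else "",
        )
        # links follow the cross-reference matrix column: a variant outside all
        # genes uses the intergenic column even when an rsID matched
        link_class = annotate.INTERGENIC if not genic else vclass
        links = annotate.build_links(identifiers, link_class, nv.contig, nv.start + 1)
        link_map = {l.field_name: l.url for l in links}

        row = SummaryRow()
        c = row.cells
        c["Patient_Id"] = patient.patient_id
        c["Family_Id"] = patient.family_id
        c["Lab_Analysis_Date"] = patient.analysis_date
        c["Seq_Platform"] = patient.seq_platform
        c["Seq_System"] = patient.seq_system
        c["Assay_Id"] = patient.assay_id
        c["Var_Id"] = vn.variant_key(nv, bundle.genome.assembly_label)
        c["Var_Type"] = nv.vtype
        c["Var_Cov"] = "" if decomp.var_cov is None else str(decomp.var_cov)
        c["Total_Cov"] = str(decomp.total)
        for base in "ACGT":
            c[base] = str(getattr(decomp, base))
        c["Var_Chr"] = nv.contig
        c["Var_Start"] = str(nv.start)
        c["Var_End"] = str(nv.end)
        c["Var_Strand"] = first_model.strand if first_model else "+"
        c["Var_Gene"] = ";".join(dict.fromkeys(a.gene_symbol for a in genic))
        c["Var_RefGene"] = ";".join(dict.fromkeys(a.refseq_mrna for a in genic))
        c["Var_Feature"] = ";".join(a.feature_label for a in assignments)
        c["Var_DNA"] = _var_dna(nv, assignments)
        c["Var_Codon"] = ";".join(f"{cc.ref_codon}>{cc.alt_codon}" for cc in codon_changes)
        c["Var_AA"] = ";".join(f"{cc.ref_aa}>{cc.alt_aa}" for cc in codon_changes)
        c["Frameshift"] = _frameshift_cell(fs_results)
        c["FASTQC_Report"] = patient.fastqc_report
        c["Patient_Fastq"] = patient.fastq
        c["Patient_Bam"] = ";".join(p for _, p in patient.sam_files)
        c["Patient_Vcf"] = f"{patient.patient_id}.vcf"
        for name in annotate.ANNOTATION_FIELDS:
            c[name] = link_map.get(name, "")
        c["Fishers_Exact_Test_pvalue"] = "" if fisher.p is None else f"{fisher.p:.6g}"
        c["Fishers_Exact_Test_pvalue_FDR_corrected"] = (
            "" if fisher.p_adj is None else f"{fisher.p_adj:.6g}"
        )
        c["dbSnp_Id"] = rsid
        for name, value in flags.items():
            c[name] = value
        c["Mapper_Name"] = rec.mapper_string()
        c["Variant_Caller"] = rec.caller_string()
        rows.append(row)
        vcf_records.append(
            (nv, rsid, rec, decomp)
        )
    counters["rows_written"] = len(rows)
    return PatientResult(rows=rows, counters=counters, vcf_records=vcf_records)


def assemble_rows(results: dict[str, PatientResult]) -> list[SummaryRow]:
    """All patients' rows, sorted by patient then contig then start."""
    rows = [row for _, res in sorted(results.items()) for row in res.rows]
    rows.sort(key=lambda r: (r["Patient_Id"], r["Var_Chr"], int(r["Var_Start"])))
    return rows


def write_summary(rows: list[SummaryRow], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for row in rows:
            fh.write(row.to_line() + "\n")


def read_summary(path: str) -> list[SummaryRow]:
    """Parse a written summary back (round-trip check support)."""
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != SUMMARY_COLUMNS:
            raise ValueError("summary header does not match the expected column list")
        for line in fh:
            cells = dict(zip(header, line.rstrip("\n").split("\t")))
            rows.append(SummaryRow(cells=cells))
    return rows


def write_patient_vcf(result: PatientResult, path: str, assembly: str) -> None:
    """VCF 4.2 per patient with consensus evidence in INFO."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##reference={assembly}\n")
        fh.write('##INFO=<ID=NCALLERS,Number=1,Type=Integer,Description="Supporting callers">\n')
        fh.write('##INFO=<ID=NMAPPERS,Number=1,Type=Integer,Description="Supporting mappers">\n')
        fh.write('##INFO=<ID=SUPPORTS,Number=.,Type=String,Description="mapper:caller pairs">\n')
        fh.write('##INFO=<ID=TC,Number=1,Type=Integer,Description="Total filtered coverage">\n')
        fh.write('##INFO=<ID=VC,Number=1,Type=Integer,Description="Variant allele coverage">\n')
        fh.write('##INFO=<ID=HOTSPOT,Number=1,Type=String,Description="Overlapping hotspot">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        recs = sorted(result.vcf_records, key=lambda t: t[0].sort_key())
        for nv, rsid, rec, decomp in recs:
            supports = ",".join(f"{m}:{c}" for m, c in sorted(rec.supports))
            info = (
                f"NCALLERS={rec.n_callers};NMAPPERS={rec.n_mappers};SUPPORTS={supports};"
                f"TC={decomp.total}"
            )
            if decomp.var_cov is not None:
                info += f";VC={decomp.var_cov}"
            if rec.hotspot:
                info += f";HOTSPOT={rec.hotspot}"
            fh.write(
                f"{nv.contig}\t{nv.start + 1}\t{rsid or '.'}\t{nv.ref}\t{nv.alt}\t.\tPASS\t{info}\n"
            )


def run_pipeline(
    options: RunOptions, manifest: rio.RunManifest, root: str, workers: int = 1
) -> str:
    """Execute the full post-alignment analysis for every patient in the manifest.

    Aborts before any processing if input files are missing (all missing paths
    reported at once).  Returns the output directory path.
    """
    missing = []
    for p in manifest.rows:
        for _, path in p.sam_files:
            if not os.path.exists(os.path.join(root, path)):
                missing.append(path)
        for _, _, path in p.vcf_files:
            if not os.path.exists(os.path.join(root, path)):
                missing.append(path)
    for path in (options.reference, options.genes):
        if not os.path.exists(os.path.join(root, path)):
            missing.append(path)
    if missing:
        raise FileNotFoundError("missing input files: " + ", ".join(sorted(set(missing))))

    bundle = load_reference_bundle(options, root)
    outdir = os.path.join(root, options.outdir)
    os.makedirs(outdir, exist_ok=True)

    results: dict[str, PatientResult] = {}
    if workers > 1:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            futures = {
                p.patient_id: pool.submit(process_patient, p, bundle, options, root)
                for p in manifest.rows
            }
            results = {pid: fut.result() for pid, fut in futures.items()}
    else:
        for p in manifest.rows:
            results[p.patient_id] = process_patient(p, bundle, options, root)

    rows = assemble_rows(results)
    write_summary(rows, os.path.join(outdir, "summary.tsv"))
    for pid, res in sorted(results.items()):
        write_patient_vcf(res, os.path.join(outdir, f"{pid}.vcf"), bundle.genome.assembly_label)
    with open(os.path.join(outdir, "run.log"), "w") as fh:
        for pid, res in sorted(results.items()):
            for key, value in res.counters.items():
                fh.write(f"{pid}\t{key}\t{value}\n")
    log.info("run complete: %d rows, %d patients", len(rows), len(results))
    return outdir
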