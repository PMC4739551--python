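"""Reference data input: genome FASTA, gene models, membership tracks, hotspots, manifest.

All coordinates are held 0-based half-open internally.  VCF (1-based) and
refFlat/BED (already 0-based) are converted at the I/O boundary, never inside
the analysis modules.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_IUPAC = set("ACGTNRYSWKMBDHV")

MEMBERSHIP_TRACK_NAMES = (
    "dbSnp_Id",
    "dbSnp_Common",
    "dbSnp_Coding",
    "dbSnp_Flagged",
    "dbSnp_Mult",
    "dbSnp_HapMap",
    "dbSnp_Cpg_Island",
    "Gwas_Catalogue",
)


class ReferenceError(ValueError):
    """Malformed or inconsistent reference input."""


@dataclass
class ReferenceGenome:
    """Uppercase nucleotide sequences keyed by contig name.

    ``assembly_label`` (e.g. ``"GRCh37"``) is stamped into every variant
    identifier, so genomes from different builds never produce colliding keys.
    """

    contigs: dict[str, str]
    assembly_label: str = "GRCh37"

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the subsequence ``[start, end)`` (0-based half-open).

        Queries outside the contig fail explicitly rather than clamping.
        """
        if contig not in self.contigs:
            raise ReferenceError(f"unknown contig {contig!r}")
        seq = self.contigs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise ReferenceError(
                f"query {contig}:[{start},{end}) outside contig of length {len(seq)}"
            )
        return seq[start:end]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs


@dataclass
class GeneModel:
    """One stranded transcript with exon and CDS intervals (0-based half-open).

    Exons stay genomic-sorted even on the minus strand; coding order is the
    downstream effect-prediction module's concern.
    """

    gene_symbol: str
    refseq_mrna: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: list[tuple[int, int]]
    entrez_id: str = ""
    refseq_protein: str = ""
    uniprot_id: str = ""
    kegg_id: str = ""
    omim_id: str = ""
    hgnc_id: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    def cds_exon_intervals(self) -> list[tuple[int, int]]:
        """Exon pieces intersected with the CDS interval, genomic order."""
        out = []
        for s, e in self.exons:
            s2, e2 = max(s, self.cds_start), min(e, self.cds_end)
            if s2 < e2:
                out.append((s2, e2))
        return out

    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exon_intervals())


@dataclass
class TrackRecord:
    contig: str
    start: int
    end: int
    rsid: str = ""
    ref: str = ""
    alt: str = ""


@dataclass
class MembershipTrack:
    """Generic genomic interval membership track (dbSNP subtrack, GWAS catalogue...)."""

    name: str
    records: list[TrackRecord]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for rec in self.records:
            tree = self._trees.setdefault(rec.contig, IntervalTree())
            # IntervalTree forbids zero-length intervals; none occur in half-open tracks
            tree.addi(rec.start, rec.end, rec)

    def query(self, contig: str, start: int, end: int) -> list[TrackRecord]:
        return query_overlaps(self._trees, contig, start, end)


@dataclass
class Hotspot:
    contig: str
    start: int
    end: int
    name: str


@dataclass
class HotspotSet:
    """Known recurrent mutation intervals from a BED file; may be empty."""

    intervals: list[Hotspot]
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for h in self.intervals:
            self._trees.setdefault(h.contig, IntervalTree()).addi(h.start, h.end, h)

    def query(self, contig: str, start: int, end: int) -> list[Hotspot]:
        return query_overlaps(self._trees, contig, start, end)


@dataclass
class ManifestRow:
    patient_id: str
    family_id: str
    assay_id: str
    seq_platform: str
    seq_system: str
    analysis_date: str
    fastq: str = ""
    fastqc_report: str = ""
    sam_files: list[tuple[str, str]] = field(default_factory=list)  # (mapper, path)
    vcf_files: list[tuple[str, str, str]] = field(default_factory=list)  # (mapper, caller, path)


@dataclass
class RunManifest:
    rows: list[ManifestRow]

    def __post_init__(self) -> None:
        ids = [r.patient_id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ReferenceError("duplicate patient_id in manifest")

    def families(self) -> dict[str, list[ManifestRow]]:
        fams: dict[str, list[ManifestRow]] = {}
        for r in self.rows:
            fams.setdefault(r.family_id, []).append(r)
        return fams


def _as_stream(source) -> io.TextIOBase:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def load_reference(fasta_stream, assembly_label: str = "GRCh37") -> ReferenceGenome:
    """Read a (possibly wrapped) multi-record FASTA into a :class:`ReferenceGenome`.

    Contig names are the first whitespace-delimited header token; soft-masked
    lowercase bases are uppercased.
    """
    stream = _as_stream(fasta_stream)
    contigs: dict[str, list[str]] = {}
    current: list[str] | None = None
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0] if line[1:].split() else ""
            if not name:
                raise ReferenceError("FASTA record with empty name")
            if name in contigs:
                raise ReferenceError(f"duplicate contig name {name!r}")
            current = contigs[name] = []
        else:
            if current is None:
                raise ReferenceError("sequence data before first FASTA header")
            up = line.upper()
            bad = set(up) - _IUPAC
            if bad:
                raise ReferenceError(f"non-IUPAC characters {sorted(bad)} in FASTA")
            current.append(up)
    if not contigs:
        raise ReferenceError("empty FASTA stream")
    return ReferenceGenome(
        contigs={k: "".join(v) for k, v in contigs.items()},
        assembly_label=assembly_label,
    )


def write_reference(genome: ReferenceGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


REFFLAT_COLUMNS = (
    "geneName",
    "name",
    "chrom",
    "strand",
    "txStart",
    "txEnd",
    "cdsStart",
    "cdsEnd",
    "exonCount",
    "exonStarts",
    "exonEnds",
)


def _parse_comma_list(text: str) -> list[int]:
    # UCSC writes a trailing comma: "10,100,"
    return [int(tok) for tok in text.strip().split(",") if tok != ""]


def load_gene_models(table_stream, id_table_stream=None) -> list[GeneModel]:
    """Parse a refFlat-dialect gene table plus an optional transcript-ID side-table.

    The side-table is a TSV with a header line containing ``transcript`` and any
    of ``entrez, protein, uniprot, kegg, omim, hgnc`` columns.
    A coding transcript whose CDS length is not a multiple of 3 is kept but
    carries a warning flag; downstream codon logic refuses to predict on it.
    """
    ids: dict[str, dict[str, str]] = {}
    if id_table_stream is not None:
        stream = _as_stream(id_table_stream)
        header = stream.readline().rstrip("\n").split("\t")
        for line in stream:
            if not line.strip():
                continue
            row = dict(zip(header, line.rstrip("\n").split("\t")))
            ids[row["transcript"]] = row

    models: list[GeneModel] = []
    for line in _as_stream(table_stream):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 11:
            raise ReferenceError(f"refFlat row with {len(fields)} < 11 columns")
        (gene, tx, chrom, strand, tx_s, tx_e, cds_s, cds_e, n_ex, ex_s, ex_e) = fields[:11]
        starts = _parse_comma_list(ex_s)
        ends = _parse_comma_list(ex_e)
        if len(starts) != int(n_ex) or len(ends) != int(n_ex):
            raise ReferenceError(f"{tx}: exonCount {n_ex} does not match exon lists")
        exons = sorted(zip(starts, ends))
        tx_start, tx_end = int(tx_s), int(tx_e)
        cds_start, cds_end = int(cds_s), int(cds_e)
        if not (tx_start <= cds_start <= cds_end <= tx_end):
            raise ReferenceError(f"{tx}: CDS [{cds_start},{cds_end}) outside tx")
        side = ids.get(tx, {})
        model = GeneModel(
            gene_symbol=gene,
            refseq_mrna=tx,
            contig=chrom,
            strand=strand,
            tx_start=tx_start,
            tx_end=tx_end,
            cds_start=cds_start,
            cds_end=cds_end,
            exons=exons,
            entrez_id=side.get("entrez", ""),
            refseq_protein=side.get("protein", ""),
            uniprot_id=side.get("uniprot", ""),
            kegg_id=side.get("kegg", ""),
            omim_id=side.get("omim", ""),
            hgnc_id=side.get("hgnc", ""),
        )
        if model.is_coding and model.cds_length() % 3 != 0:
            model.warnings.append("cds_length_not_multiple_of_3")
            log.warning("%s: CDS length %d not a multiple of 3", tx, model.cds_length())
        models.append(model)
    return models


def load_membership_track(name: str, stream) -> MembershipTrack:
    """Load one TSV membership track: contig, start, end[, rsid, ref, alt]."""
    records = []
    for line in _as_stream(stream):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        records.append(
            TrackRecord(
                contig=f[0],
                start=int(f[1]),
                end=int(f[2]),
                rsid=f[3] if len(f) > 3 else "",
                ref=f[4] if len(f) > 4 else "",
                alt=f[5] if len(f) > 5 else "",
            )
        )
    records.sort(key=lambda r: (r.contig, r.start, r.end))
    return MembershipTrack(name=name, records=records)


def load_hotspots(bed_stream) -> HotspotSet:
    """Load hotspot intervals from BED3+name text."""
    spots = []
    for line in _as_stream(bed_stream):
        line = line.rstrip("\n")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        f = line.split("\t")
        name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
        spots.append(Hotspot(contig=f[0], start=int(f[1]), end=int(f[2]), name=name))
    return HotspotSet(intervals=spots)


MANIFEST_COLUMNS = (
    "Patient_Id",
    "Family_Id",
    "Assay_Id",
    "Seq_Platform",
    "Seq_System",
    "Lab_Analysis_Date",
    "Fastq",
    "Fastqc_Report",
    "Sam_Files",
    "Vcf_Files",
)


def load_manifest(stream) -> RunManifest:
    """Read the per-patient run manifest TSV.

    ``Sam_Files`` holds ``mapper,path`` pairs joined by ``;``; ``Vcf_Files``
    holds ``mapper,caller,path`` triplets likewise, so every call's provenance
    is explicit.
    """
    stream = _as_stream(stream)
    header = stream.readline().rstrip("\n").split("\t")
    missing = set(MANIFEST_COLUMNS) - set(header)
    if missing:
        raise ReferenceError(f"manifest missing columns: {sorted(missing)}")
    rows = []
    for line in stream:
        if not line.strip():
            continue
        row = dict(zip(header, line.rstrip("\n").split("\t")))
        sam_files = [
            tuple(item.split(",", 1))
            for item in row["Sam_Files"].split(";")
            if item
        ]
        vcf_files = [
            tuple(item.split(",", 2))
            for item in row["Vcf_Files"].split(";")
            if item
        ]
        rows.append(
            ManifestRow(
                patient_id=row["Patient_Id"],
                family_id=row["Family_Id"],
                assay_id=row["Assay_Id"],
                seq_platform=row["Seq_Platform"],
                seq_system=row["Seq_System"],
                analysis_date=row["Lab_Analysis_Date"],
                fastq=row.get("Fastq", ""),
                fastqc_report=row.get("Fastqc_Report", ""),
                sam_files=sam_files,  # type: ignore[arg-type]
                vcf_files=vcf_files,  # type: ignore[arg-type]
            )
        )
    return RunManifest(rows=rows)


def query_overlaps(trees: dict[str, IntervalTree], contig: str, start: int, end: int):
    """All records whose interval intersects ``[start, end)``, genomic order.

    Unknown contigs yield an empty result (logged), not an error: membership
    tracks legitimately cover fewer contigs than the genome.
    """
    if contig not in trees:
        log.debug("interval query on unknown contig %s", contig)
        return []
    if end <= start:  # point query on a zero-length interval
        end = start + 1
    hits = [iv.data for iv in trees[contig].overlap(start, end)]
    hits.sort(key=lambda r: (r.start, r.end))
    return hits
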