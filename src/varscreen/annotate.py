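"""Variant classification, membership flags, hotspot flagging, and database links.

A variant is *known* when it matches a dbSNP rsID, *novel* when it lies in a
gene without one, and *intergenic* otherwise.  Which of the 32 database links
fire depends on that class and on which identifiers the overlapping gene
carries; the applicability matrix and the URL templates are configuration
data, not code, since hosted URL schemes drift while the matrix logic does
not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .effects import FeatureAssignment
from .normalize import NormalizedVariant
from .reference_io import HotspotSet, MembershipTrack

log = logging.getLogger(__name__)

KNOWN, NOVEL, INTERGENIC = "known", "novel", "intergenic"

FLAG_TRACKS = (
    "dbSnp_Common",
    "dbSnp_Coding",
    "Gwas_Catalogue",
    "dbSnp_Flagged",
    "dbSnp_Mult",
    "dbSnp_HapMap",
    "dbSnp_Cpg_Island",
)


@dataclass
class XrefIdentifiers:
    rsid: str = ""
    entrez_id: str = ""
    gene_symbol: str = ""
    refseq_mrna: str = ""
    refseq_protein: str = ""
    uniprot_id: str = ""
    kegg_id: str = ""
    omim_id: str = ""
    hgnc_id: str = ""


@dataclass
class LinkRecord:
    field_name: str
    url: str


# (field name, URL template, driving identifier keys, classes it applies to).
# Field names and their applicability follow the published cross-reference
# matrix exactly, including the historical "GeneTes" spelling.
_ALL = (KNOWN, NOVEL, INTERGENIC)
_K = (KNOWN,)
_KN = (KNOWN, NOVEL)
_KI = (KNOWN, INTERGENIC)

LINK_CONFIG: list[tuple[str, str, tuple[str, ...], tuple[str, ...]]] = [
    ("Entrez_Gene", "https://www.ncbi.nlm.nih.gov/gene/{entrez}", ("entrez",), _KN),
    ("RefSeq_mRNA", "https://www.ncbi.nlm.nih.gov/nuccore/{mrna}", ("mrna",), _K),
    ("RefSeq_Protein", "https://www.ncbi.nlm.nih.gov/protein/{protein}", ("protein",), _K),
    ("HomoloGene", "https://www.ncbi.nlm.nih.gov/homologene/?term={mrna}", ("mrna",), _K),
    ("GEO_Profiles", "https://www.ncbi.nlm.nih.gov/geoprofiles/?term={mrna}", ("mrna",), _K),
    ("UniGene", "https://www.ncbi.nlm.nih.gov/unigene/?term={mrna}", ("mrna",), _K),
    ("Pubmed", "https://pubmed.ncbi.nlm.nih.gov/?term={mrna}", ("mrna",), _K),
    ("dbSNP", "https://www.ncbi.nlm.nih.gov/snp/{rsid}", ("rsid",), _KI),
    ("ClinVar", "https://www.ncbi.nlm.nih.gov/clinvar/?term={entrez}%5Bgeneid%5D", ("entrez",), _K),
    ("dbVar", "https://www.ncbi.nlm.nih.gov/dbvar/?term={entrez}", ("entrez",), _K),
    ("NCBI variation viewer",
     "https://www.ncbi.nlm.nih.gov/variation/view/?q={rsid}", ("rsid",), _KI),
    ("Cosmic", "https://cancer.sanger.ac.uk/cosmic/gene/analysis?ln={symbol}", ("symbol",), _K),
    ("Gen_Test_Reg", "https://www.ncbi.nlm.nih.gov/gtr/all/tests/?term={entrez}", ("entrez",), _K),
    ("Omim", "https://www.omim.org/entry/{omim}", ("omim",), _K),
    ("Hgnc", "https://www.genenames.org/data/gene-symbol-report/#!/hgnc_id/{hgnc}", ("hgnc",), _K),
    ("PolyPhen_2", "http://genetics.bwh.harvard.edu/pph2/dbsearch.shtml?q={rsid}", ("rsid",), _K),
    ("Decipher", "https://www.deciphergenomics.org/browser#q/{chrom}:{pos}-{pos}", ("chrom", "pos"), _ALL),
    ("Kegg", "https://www.genome.jp/dbget-bin/www_bget?pathway:{kegg}", ("kegg",), _K),
    ("Kegg_Locus", "https://www.genome.jp/dbget-bin/www_bget?{kegg}+{entrez}", ("kegg", "entrez"), _K),
    ("Reactome", "https://reactome.org/content/query?q={uniprot}", ("uniprot",), _K),
    ("WikiGenes", "https://www.wikigenes.org/e/gene/e/{entrez}.html", ("entrez",), _KN),
    ("GeneTes", "https://www.ncbi.nlm.nih.gov/gtr/genes/?term={symbol}", ("symbol",), _K),
    ("BioGPS", "http://biogps.org/#goto=genereport&id={entrez}", ("entrez",), _KN),
    ("GENATLAS", "http://genatlas.medecine.univ-paris5.fr/fiche.php?symbol={symbol}", ("symbol",), _K),
    ("GeneCards", "https://www.genecards.org/cgi-bin/carddisp.pl?gene={symbol}", ("symbol",), _K),
    ("GOPubmed", "https://pubmed.ncbi.nlm.nih.gov/?term={symbol}+gene+ontology", ("symbol",), _K),
    ("H_InvDB", "https://h-invitational.jp/hinv/spsoup/locus_view?hix_id={symbol}", ("symbol",), _K),
    ("UniProt", "https://www.uniprot.org/uniprotkb/{uniprot}/entry", ("uniprot",), _K),
    ("QuickGO", "https://www.ebi.ac.uk/QuickGO/annotations?geneProductId={uniprot}", ("uniprot",), _K),
    ("UCSC", "https://genome.ucsc.edu/cgi-bin/hgTracks?position={chrom}:{pos}-{pos}", ("chrom", "pos"), _ALL),
    ("Ensembl", "https://www.ensembl.org/Homo_sapiens/Location/View?r={chrom}:{pos}-{pos}", ("chrom", "pos"), _ALL),
    ("GWAS_Central", "https://www.gwascentral.org/browser?q={chrom}:{pos}..{pos}", ("chrom", "pos"), _ALL),
]

ANNOTATION_FIELDS = tuple(name for name, _, _, _ in LINK_CONFIG)


def classify_variant(
    nv: NormalizedVariant,
    assignments: list[FeatureAssignment],
    dbsnp_track: MembershipTrack | None,
) -> tuple[str, str]:
    """Classify as known / novel / intergenic; return (class, rsid).

    An rsID match requires positional overlap with the dbSNP identifier
    track and, when the track record carries alleles, allele agreement.
    """
    rsid = ""
    if dbsnp_track is not None:
        for rec in dbsnp_track.query(nv.contig, nv.start, max(nv.end, nv.start + 1)):
            if rec.ref and rec.alt and (rec.ref != nv.ref or rec.alt != nv.alt):
                continue
            rsid = rec.rsid
            break
    genic = any(a.region_class != "intergenic" for a in assignments)
    if rsid:
        return KNOWN, rsid
    return (NOVEL, "") if genic else (INTERGENIC, "")


def membership_flags(
    nv: NormalizedVariant, tracks: dict[str, MembershipTrack]
) -> dict[str, str]:
    """One 'X'/'' flag per membership track name, 'X' on positional overlap."""
    flags = {}
    for name in FLAG_TRACKS:
        track = tracks.get(name)
        hit = bool(track and track.query(nv.contig, nv.start, max(nv.end, nv.start + 1)))
        flags[name] = "X" if hit else ""
    return flags


def flag_hotspot(nv: NormalizedVariant, hotspots: HotspotSet | None) -> str | None:
    """Name of the first overlapping hotspot (lexicographic tie-break), else None."""
    if hotspots is None:
        return None
    hits = hotspots.query(nv.contig, nv.start, max(nv.end, nv.start + 1))
    if not hits:
        return None
    return min(h.name for h in hits)


def build_links(
    identifiers: XrefIdentifiers, variant_class: str, contig: str, pos1: int
) -> list[LinkRecord]:
    """Emit the database links applicable to this variant class.

    A known coding variant with every identifier present yields all 32
    fields; a novel genic variant the 7 coordinate/Entrez-keyed ones; an
    intergenic variant with an rsID the 6 coordinate/rsID-keyed ones.  A
    builder whose driving identifier is missing is skipped and logged.
    """
    values = {
        "rsid": identifiers.rsid,
        "entrez": identifiers.entrez_id,
        "symbol": identifiers.gene_symbol,
        "mrna": identifiers.refseq_mrna,
        "protein": identifiers.refseq_protein,
        "uniprot": identifiers.uniprot_id,
        "kegg": identifiers.kegg_id,
        "omim": identifiers.omim_id,
        "hgnc": identifiers.hgnc_id,
        "chrom": contig,
        "pos": str(pos1),
    }
    links = []
    for name, template, keys, classes in LINK_CONFIG:
        if variant_class not in classes:
            continue
        if any(not values[k] for k in keys):
            log.debug("link %s skipped: missing %s", name, keys)
            continue
        links.append(LinkRecord(field_name=name, url=template.format(**values)))
    return links
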