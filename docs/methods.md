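# Methods

`varscreen` implements the post-alignment core of a clinical mutation-screening
workflow: it takes aligned reads (SAM text) and per-caller variant calls (VCF)
for a set of patients, reconciles the calls across mappers and callers, and
produces a single summary table with one line per variant carrying coverage
evidence, predicted coding consequences, per-variant statistics, and clinical
database cross-references.

## Coordinates

All internal coordinates are 0-based half-open. VCF positions (1-based) and
refFlat/BED intervals (0-based) are converted exactly once, at the I/O
boundary. The summary table reports `Var_Start` as the 0-based start and
`Var_End` as the 1-based inclusive end of the reference span (so an SNV at
1-based position *p* prints *p*−1 / *p*), matching the established output
format of this table.

## Read filtering and pileup

Reads failing any of three post-mapping filters are excluded from coverage:

- **minimum mapping quality** (`min_mapq`, default 20 — a standard screening
  threshold; the method itself prescribes the filter but no specific value);
- **proper-pair** (applied only to reads with the paired flag set);
- **PCR duplicates**. Duplicate grouping uses the Picard-style criterion:
  (contig, unclipped 5′ start, strand, mate 5′ start when paired). The group
  member with the highest base-quality sum survives; ties break on the
  lexicographically smallest read name, making marking deterministic and
  idempotent.

The pileup walks each CIGAR: M/=/X deposit base and quality, I consumes query
only, D/N consume reference only, S/H deposit nothing. Each column holds raw
counts (all policy-passing reads) and quality-filtered counts (base quality ≥
`min_base_qual`, default 20, PHRED units). Deletion alleles are not tracked in
the pileup; the coverage decomposition is A/C/G/T only, so indel allele depth
comes from the caller's own fields.

## Variant normalization and consensus

Callers spell the same indel differently. Every call is reduced to a
parsimonious, left-aligned canonical form: right-trim the shared allele
suffix; when one allele would vanish, prepend the previous reference base and
re-trim (this walks the indel leftward through repeat tracts); finally
left-trim the shared prefix. The transform is idempotent and maps every
equivalent spelling inside a repeat tract to one key (verified against an
exhaustive spelling-enumeration oracle). Multiallelic records are split
before normalization.

Consensus groups calls on (contig, start, ref, alt) after normalization and
accumulates distinct (mapper, caller) support pairs. Overlap (Venn)
statistics count, per nonempty support subset, the variants supported by
exactly that subset, separately for SNVs and indels, plus the fraction
supported by ≥2 labels.

Variant identifiers are HGVS-genomic style:
`chr13.GRCh37:g.18258370G>A`, `…:g.101del`, `…:g.101_103del`,
`…:g.200_201insTT`.

Caller depth dialects: per-sample `AD` for GATK/Freebayes, `INFO DP4`
(alt = forward+reverse alt reads) for samtools, per-sample `AD`/`FREQ` for
VarScan. Absent fields leave depth unknown; the pileup recount is the
authoritative coverage for the summary columns.

## Effect prediction

Variants are assigned per overlapping transcript to CDS / 5′UTR / 3′UTR /
intron / noncoding-exon, or intergenic when no transcript overlaps. Exon and
CDS ordinals are counted from the transcript 5′ end (`exon_2;CDS_2`).

For coding SNVs, the spliced CDS is assembled from the exon∩CDS intervals
(reverse-complemented for minus-strand genes), the variant's offset is
computed in coding orientation, the reference base is replaced inside its
codon, and both codons are translated with the standard nuclear code, reported
as 3-letter names with `Ter` for stop and `Xaa` for ambiguous. Codons spanning
splice junctions are therefore handled through the spliced sequence, never by
genomic adjacency.

For indels, the in-CDS indel length is the number of deleted reference bases
that are exonic CDS positions; an insertion counts in full when its insertion
point lies between two in-CDS positions, else zero (the inserted bases have no
genomic coordinates of their own). Frameshift ⟺ that length mod 3 ≠ 0; the
original and new reading frames (CDS length mod 3, before and after the
indel) are reported. Transcripts whose CDS length is not a multiple of 3 are
loaded with a warning flag and excluded from codon/frameshift prediction
rather than crashing the run.

## Per-variant statistics and filters

- **Flanking quality**: mean and median base quality over the ±10-base window
  around the variant (window size configurable; the variant column itself is
  excluded). Median is the lower middle value for even counts, so it is
  always an observed PHRED integer. Zero covered flanking bases → null.
- **Coverage decomposition**: filtered and raw A/C/G/T counts at the variant
  column; `Var_Cov` is the filtered alt-base count for SNVs, the caller-
  reported alt depth for indels.
- **Fisher's exact test**: row 1 is the variant's (ref, alt) counts; row 2 is
  the component-wise arithmetic mean of the (ref, alt) counts over all other
  variants of the same patient, rounded half-up to integers (an exact test
  requires integer cells; the rounding rule is recorded here as the package's
  choice). The two-sided p uses the point-probability rule — the sum of
  hypergeometric probabilities of all same-margin tables no more probable
  than the observed one — computed via `scipy.stats.fisher_exact` and
  verified against exact integer enumeration for every table with margins
  ≤ 30. A patient with a single variant gets a null result.
- **FDR**: Benjamini–Hochberg step-up per patient
  (`statsmodels.stats.multitest`, verified against the literal formula).
- **Pass filter**: total coverage ≥ `min_total_cov` (default 20), variant
  allele coverage ≥ `min_alt_cov` (default 4), allele fraction ≥ `min_af`
  (default 0.10) — the validated screening thresholds of the workflow. Only
  passing variants become summary rows; failures carry machine-readable
  reasons in the log.

## Classification and cross-referencing

A variant matching a dbSNP-identifier track record (position overlap, plus
allele agreement when the track carries alleles) is **known**; otherwise it is
**novel** if it overlaps a gene, **intergenic** if not. Membership flags
(`dbSnp_Common` … `Gwas_Catalogue`) are set per track on positional overlap.
A variant overlapping a hotspot BED interval is flagged with the hotspot name
(lexicographic tie-break) and `hotspot` is appended to its caller provenance
list.

Database links are emitted from a configuration table (field name → URL
template → driving identifiers → applicable classes), not code, because
hosted URL schemes drift while the applicability matrix does not. A known
genic variant with all identifiers present yields all 32 annotation columns;
a novel genic variant the 7 coordinate/Entrez-keyed ones; an intergenic
variant the 4 coordinate-keyed ones plus, when an rsID matched, dbSNP and the
variation viewer (6) — the intergenic column applies to non-genic variants
even when an rsID matched, so PolyPhen-2 (known-genic only) is not emitted
for them. The historical `GeneTes` column spelling is kept for
bit-compatibility with the established output schema.

## Run model

The manifest is a per-patient TSV (`Patient_Id`, `Family_Id`, `Assay_Id`,
`Seq_Platform`, `Seq_System`, `Lab_Analysis_Date`, file columns). Because
every call's provenance must be known, alignment files are listed as
`mapper,path` pairs and VCFs as `mapper,caller,path` triplets, joined with
`;`. The first-listed mapper's alignments are the coverage authority for the
pileup columns (one coverage per row, as the output schema expects, even when
several mappers contributed calls).

Patients are processed independently; the run can execute them concurrently
and still produces byte-identical output because rows are sorted by (patient,
contig, start) before writing. Missing input files abort the run before any
processing, with every missing path named. Outputs: one summary TSV for the
whole run, one VCF per patient (consensus evidence in INFO keys `NCALLERS`,
`NMAPPERS`, `SUPPORTS`, `TC`, `VC`, `HOTSPOT`), and a log of per-stage
counters.

## Synthetic data generator

The fixture module emulates the study conditions at desk scale: two 10 kb
contigs; four genes (alternating strand, two exons each, 40-codon CDSs built
as ATG + stop-free body + TAA, so every model is well-formed); 100 bp
single-end reads at 60× depth with uniform-random unique starts, base errors
at 0.001/bp, 10% exact duplicates (lower-quality copies, so the duplicate
marker has a deterministic survivor); heterozygous planted variants at allele
fraction 0.5; and one VCF per (mapper, caller) across 3 mappers × 4 callers
in which samtools/varscan right-shift indels and freebayes pads allele
suffixes, with a controlled subset of variants private to single callers to
create known Venn structure. A single integer seed governs all randomness.

What it does **not** emulate: realistic quality ramps or context-dependent
error models, paired-end fragment geometry, mapper-specific alignment
artifacts, real caller error profiles, or chromatogram-level Sanger data.
Tests passing on these fixtures demonstrate the correctness of the
post-alignment logic (normalization, consensus, effects, statistics, output
assembly), not the end-to-end accuracy of any upstream aligner or caller on
real sequencing data. Published overlap percentages from large real-data runs
depend on those external tools and are out of scope here; the fixture-based
recovery checks (exact Venn-cell and planted-variant recovery) are the
testable substitute.

## Numerical choices

- Fisher two-sided ties: point-probability rule with ~1e-7 relative slack for
  float ties, the convention of mainstream statistics libraries.
- Mean allele counts for the Fisher cohort row: rounded half-up
  (`floor(x+0.5)`).
- Median: lower middle value for even n.
- Degenerate inputs: empty flanking window → null statistics; zero total
  coverage → filter failure `no_coverage`; single-variant patient → null
  Fisher; unknown contig in an interval query → empty result, logged.
- The `Var_Strand` column reports the gene strand for genic variants and `+`
  for intergenic ones; `Var_DNA` reports coding-orientation alleles for genic
  SNVs and genomic orientation otherwise.

## Known limitations

- Pileups count A/C/G/T only; indel allele depth relies on caller fields.
- BAM/CRAM are not decoded; convert to SAM text upstream (e.g. `samtools
  view`).
- Multi-transcript variants emit one consequence per coding transcript joined
  with `;`; no canonical-transcript selection is attempted.
- HGVS c./p. notation is not produced — only genomic g. keys plus codon and
  amino-acid columns.
- Acceptance-scale problem sizes (10 kb contigs, 60× depth, 12 planted
  variants, Fisher sweep margins ≤ 30) were chosen so the whole suite runs in
  a couple of minutes on one core.
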