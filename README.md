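# varscreen

Post-alignment mutation screening for targeted and gene-panel sequencing:
per-base pileups from SAM text, cross-caller/cross-mapper variant
normalization and consensus, gene-model-based effect prediction (codon,
amino acid, frameshift), per-variant Fisher's exact test with
Benjamini–Hochberg FDR, coverage/allele-frequency filtering, dbSNP/hotspot
flagging, clinical database cross-referencing, and a one-line-per-variant
summary table.

It is aimed at small clinical-genetics analyses where the same sample has
been aligned with several mappers and called with several variant callers
(GATK, samtools, Freebayes, VarScan…), and the question is: *which variants
are supported by more than one tool, what do they do to the protein, and what
is already known about them?*

## The core methods

**Normalization.** Callers spell the same indel differently. Every call is
reduced to a parsimonious, left-aligned representation: right-trim the shared
allele suffix, extending left with the preceding reference base whenever an
allele would vanish (walking the indel leftward through repeat tracts), then
left-trim the shared prefix. All equivalent spellings converge to one key,
e.g. `chr13.GRCh37:g.18258370G>A` or `chrH.GRCh37:g.101del`, so support from
different (mapper, caller) runs can be pooled into consensus records.

**Effect prediction.** The spliced CDS is assembled from exon∩CDS intervals
(reverse-complemented on the minus strand), the reference allele is replaced
at the variant's coding offset, and both codons are translated
(`AAA>AAG` → `Lys>Lys`). For indels, frameshift ⟺ (number of inserted or
deleted bases inside the CDS) mod 3 ≠ 0, with old/new reading frames
reported.

**Statistics.** For each variant, a 2×2 two-tailed Fisher's exact test
compares its (ref, alt) read counts against the mean counts of the patient's
remaining variants (rounded to integers), with BH-FDR across the patient;
plus flanking base quality (±10 bp), the A/C/G/T coverage decomposition
before and after base-quality filtering, and the pass filter
(total ≥ 20, alt ≥ 4, allele fraction ≥ 0.10 by default).

**Cross-referencing.** Variants are classified known / novel / intergenic by
dbSNP membership and gene overlap; 32 database-link columns (UCSC, Ensembl,
dbSNP, ClinVar, OMIM, UniProt, KEGG, …) are emitted according to a fixed
class-applicability matrix.

## Worked example

Generate a fully synthetic 2-patient run (genome, gene models, reads, one VCF
per mapper×caller, dbSNP-style tracks, hotspot BED) and analyze it:

```bash
varscreen fixtures --out demo --seed 1
varscreen run --options demo/options.txt --manifest demo/manifest.tsv --root demo
```

This writes `demo/out/summary.tsv` (one row per variant per patient, 73
columns), one VCF per patient, and a stage-count log. A few columns of one
run's rows:

```
Var_Id                       Var_Type  Var_Cov  Total_Cov  Var_Feature    Var_Codon  Var_AA    Frameshift  Variant_Caller
chr1.GRCh37:g.445C>A         SNV       22       51         exon_1;CDS_1   AAC>AAA    Asn>Lys               gatk;samtools;freebayes;varscan;hotspot
chr1.GRCh37:g.466C>A         SNV       22       50         exon_1;CDS_1   CCC>CCA    Pro>Pro               gatk;samtools;freebayes;varscan
chr1.GRCh37:g.488_490del     DEL       30       41         exon_1;CDS_1                        no(0>0)     gatk;samtools;freebayes;varscan
chr1.GRCh37:g.2738del        DEL       30       52         exon_1;CDS_1                        yes(0>2)    gatk;samtools;freebayes;varscan
```

Reading the first row: the SNV at chr1:445 (0-based 444) was called by all
four callers, overlaps a configured hotspot (hence `;hotspot`), changes codon
`AAC` to `AAA` (Asn→Lys, a missense change), and is covered by 51
quality-filtered reads of which 22 carry the variant allele — passing the
20/4/0.10 screening filter. The single-base deletion at g.2738 shifts the
reading frame (`yes(0>2)`); the 3-base deletion at g.488–490 does not.

The library surface mirrors the pipeline stages (`varscreen.normalize`,
`varscreen.pileup`, `varscreen.effects`, `varscreen.stats`,
`varscreen.annotate`, `varscreen.summary`, `varscreen.fixtures`), and the CLI
exposes `run`, `normalize`, `annotate`, `stats`, and `fixtures` subcommands.

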