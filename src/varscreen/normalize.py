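"""VCF ingestion, left-aligned variant normalization, identifiers, and consensus.

Different variant callers spell the same indel differently (right-shifted,
suffix-padded, bundled into multiallelic records).  Reducing every call to a
parsimonious, left-aligned representation gives one canonical key per variant
so that evidence from several mappers and callers can be pooled.
"""

from __future__ import annotations

import io
import itertools
import logging
from dataclasses import dataclass, field

from .reference_io import ReferenceGenome

log = logging.getLogger(__name__)

CALLER_LABELS = {"gatk": "gatk", "samtools": "samtools", "freebayes": "freebayes", "varscan": "varscan"}
MAPPER_LABELS = {"bwa": "Bwa", "bowtie": "Bowtie", "bowtie2": "Bowtie2", "gsnap": "GSNAP", "tmap": "TMAP"}


class VcfFormatError(ValueError):
    pass


class NotAVariantError(ValueError):
    """REF and ALT describe the same sequence."""


@dataclass
class VariantCall:
    """One (record, alt allele) pair from a caller's VCF, pre-normalization."""

    contig: str
    pos: int  # 1-based, as in the VCF
    ref: str
    alt: str
    sample_id: str
    caller_id: str
    mapper_id: str
    depth_total: int | None = None
    depth_alt: int | None = None
    filter_pass: bool = True


@dataclass(frozen=True)
class NormalizedVariant:
    """Canonical left-aligned, parsimonious variant (0-based start)."""

    contig: str
    start: int
    ref: str
    alt: str

    @property
    def vtype(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "SNV"
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def end(self) -> int:
        """0-based exclusive end of the reference span."""
        return self.start + len(self.ref)

    def sort_key(self) -> tuple:
        return (self.contig, self.start, self.ref, self.alt)


@dataclass
class ConsensusRecord:
    """One normalized variant with its supporting (mapper, caller) evidence."""

    variant: NormalizedVariant
    supports: set[tuple[str, str]] = field(default_factory=set)  # (mapper, caller)
    sample_depths: dict[str, tuple[int | None, int | None]] = field(default_factory=dict)
    hotspot: str | None = None

    @property
    def n_callers(self) -> int:
        return len({c for _, c in self.supports})

    @property
    def n_mappers(self) -> int:
        return len({m for m, _ in self.supports})

    def mapper_string(self) -> str:
        order = list(MAPPER_LABELS) + sorted(
            {m for m, _ in self.supports} - set(MAPPER_LABELS)
        )
        present = {m for m, _ in self.supports}
        return ";".join(MAPPER_LABELS.get(m, m) for m in order if m in present)

    def caller_string(self) -> str:
        order = list(CALLER_LABELS) + sorted(
            {c for _, c in self.supports} - set(CALLER_LABELS)
        )
        present = {c for _, c in self.supports}
        labels = [CALLER_LABELS.get(c, c) for c in order if c in present]
        if self.hotspot is not None:
            labels.append("hotspot")
        return ";".join(labels)


def _alt_depth_from_record(info: dict, fmt_keys: list[str], sample: list[str],
                           alt_index: int, n_alts: int, caller_id: str):
    """Recover (total, alt) depth per caller dialect.

    gatk/freebayes carry per-sample AD (ref followed by alt depths); samtools
    carries INFO DP4 (ref fwd, ref rev, alt fwd, alt rev); varscan carries
    per-sample AD (alt depth only) with RD for the reference.  Anything absent
    is reported as unknown — the pileup recount is authoritative downstream.
    """
    fmt = dict(zip(fmt_keys, sample)) if fmt_keys else {}
    total = None
    if "DP" in fmt:
        total = int(fmt["DP"])
    elif "DP" in info:
        total = int(info["DP"])
    alt_d = None
    if caller_id in ("gatk", "freebayes") and "AD" in fmt:
        ad = [int(x) for x in fmt["AD"].split(",")]
        if len(ad) >= alt_index + 2:
            alt_d = ad[alt_index + 1]
            if total is None:
                total = sum(ad)
    elif caller_id == "samtools" and "DP4" in info:
        dp4 = [int(x) for x in str(info["DP4"]).split(",")]
        if len(dp4) == 4:
            alt_d = dp4[2] + dp4[3]
            if total is None:
                total = sum(dp4)
    elif caller_id == "varscan":
        if "AD" in fmt:
            alt_d = int(fmt["AD"].split(",")[0])
        if alt_d is None and "FREQ" in fmt and total is not None:
            freq = float(fmt["FREQ"].rstrip("%")) / 100.0
            alt_d = round(total * freq)
    elif "AD" in fmt:  # generic fallback for 'other' callers
        ad = [int(x) for x in fmt["AD"].split(",")]
        if len(ad) >= alt_index + 2:
            alt_d = ad[alt_index + 1]
    return total, alt_d


def read_vcf(source, caller_id: str, mapper_id: str, sample_id: str,
             reference: ReferenceGenome | None = None) -> list[VariantCall]:
    """Parse VCF 4.x text into per-alt :class:`VariantCall` records.

    Multiallelic ALTs are split (one call each).  Records whose FILTER is
    neither PASS nor '.' are kept but flagged not-pass.  When a reference
    genome is supplied, records whose REF disagrees with it are reported and
    skipped.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    calls: list[VariantCall] = []
    saw_header = False
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("##"):
            continue
        if line.startswith("#CHROM"):
            saw_header = True
            continue
        if not saw_header:
            raise VcfFormatError("VCF data before #CHROM header line")
        f = line.split("\t")
        if len(f) < 8:
            raise VcfFormatError(f"VCF record with {len(f)} < 8 fields")
        contig, pos, _vid, ref, alts, _qual, filt = f[0], int(f[1]), f[2], f[3].upper(), f[4], f[5], f[6]
        info = {}
        for item in f[7].split(";"):
            if "=" in item:
                k, v = item.split("=", 1)
                info[k] = v
            elif item and item != ".":
                info[item] = True
        fmt_keys = f[8].split(":") if len(f) > 8 else []
        sample = f[9].split(":") if len(f) > 9 else []
        if reference is not None:
            actual = reference.fetch(contig, pos - 1, pos - 1 + len(ref))
            if actual != ref:
                log.warning(
                    "%s:%d REF %s disagrees with reference %s; record skipped",
                    contig, pos, ref, actual,
                )
                continue
        n_alts = len(alts.split(","))
        for i, alt in enumerate(alts.split(",")):
            alt = alt.upper()
            if alt in (".", "*", ref):
                continue
            total, alt_d = _alt_depth_from_record(info, fmt_keys, sample, i, n_alts, caller_id)
            calls.append(
                VariantCall(
                    contig=contig,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    sample_id=sample_id,
                    caller_id=caller_id,
                    mapper_id=mapper_id,
                    depth_total=total,
                    depth_alt=alt_d,
                    filter_pass=filt in ("PASS", "."),
                )
            )
    if not saw_header:
        raise VcfFormatError("missing #CHROM header line")
    return calls


def normalize(call: VariantCall | NormalizedVariant, reference: ReferenceGenome) -> NormalizedVariant:
    """Reduce a call to its parsimonious, left-aligned canonical form.

    Right-trims the shared suffix (left-extending with the preceding reference
    base whenever an allele would vanish — this walks indels leftward through
    repeat tracts), then left-trims the shared prefix.  Idempotent; all
    equivalent spellings of an indel inside a repeat converge to one key.
    """
    if isinstance(call, NormalizedVariant):
        contig, start, ref, alt = call.contig, call.start, call.ref, call.alt
    else:
        contig, start, ref, alt = call.contig, call.pos - 1, call.ref.upper(), call.alt.upper()
    if ref == alt:
        raise NotAVariantError(f"{contig}:{start + 1} {ref}>{alt}")
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if ref and alt and ref[-1] == alt[-1] and (len(ref) == 1 or len(alt) == 1) and start > 0:
            prev = reference.fetch(contig, start - 1, start)
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            start -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    if ref == alt:
        raise NotAVariantError(f"{contig}:{start + 1} alleles identical after trimming")
    return NormalizedVariant(contig=contig, start=start, ref=ref, alt=alt)


def variant_key(nv: NormalizedVariant, assembly_label: str) -> str:
    """HGVS-style genomic identifier, e.g. ``chr13.GRCh37:g.18258370G>A``."""
    prefix = f"{nv.contig}.{assembly_label}:g."
    if nv.vtype == "SNV":
        return f"{prefix}{nv.start + 1}{nv.ref}>{nv.alt}"
    if nv.vtype == "DEL":
        # deleted bases follow the anchor: 1-based [start+2 .. start+len(ref)]
        first = nv.start + 2
        last = nv.start + len(nv.ref)
        if first == last:
            return f"{prefix}{first}del"
        return f"{prefix}{first}_{last}del"
    # INS: inserted sequence sits between anchor (1-based start+1) and the next base
    pos1 = nv.start + 1
    return f"{prefix}{pos1}_{pos1 + 1}ins{nv.alt[1:]}"


def parse_variant_key(key: str) -> tuple[str, str, int, str, str]:
    """Inverse of :func:`variant_key` for SNVs: (contig, assembly, pos1, ref, alt)."""
    locus, desc = key.split(":g.")
    contig, assembly = locus.rsplit(".", 1)
    if ">" in desc:
        i = 0
        while desc[i].isdigit():
            i += 1
        pos1 = int(desc[:i])
        ref, alt = desc[i:].split(">")
        return contig, assembly, pos1, ref, alt
    raise ValueError(f"not an SNV key: {key}")


def build_consensus(calls: list[VariantCall], reference: ReferenceGenome) -> list[ConsensusRecord]:
    """Merge calls across mappers and callers on the normalized variant key.

    Output is sorted by contig then start; input order is irrelevant.  Depth
    evidence per sample keeps the maximum reported total (callers recount the
    same alignments; the pileup recount supersedes this downstream).
    """
    merged: dict[NormalizedVariant, ConsensusRecord] = {}
    for call in calls:
        nv = normalize(call, reference)
        rec = merged.setdefault(nv, ConsensusRecord(variant=nv))
        rec.supports.add((call.mapper_id, call.caller_id))
        prev = rec.sample_depths.get(call.sample_id)
        cand = (call.depth_total, call.depth_alt)
        if prev is None or (cand[0] or -1) > (prev[0] or -1):
            rec.sample_depths[call.sample_id] = cand
    return sorted(merged.values(), key=lambda r: r.variant.sort_key())


def overlap_statistics(records: list[ConsensusRecord], axis: str = "caller") -> dict:
    """Venn-cell counts over mapper or caller support sets, split by variant type.

    For each nonempty subset of the axis labels, counts variants supported by
    exactly that subset, and reports the fraction supported by >= 2 labels.
    Computed separately for SNVs and for indels.
    """
    if axis not in ("caller", "mapper"):
        raise ValueError("axis must be 'caller' or 'mapper'")
    pick = (lambda s: frozenset(c for _, c in s)) if axis == "caller" else (
        lambda s: frozenset(m for m, _ in s))
    labels = sorted(set(itertools.chain.from_iterable(pick(r.supports) for r in records)))
    if len(labels) < 2:
        raise ValueError(f"overlap statistics need >= 2 {axis} labels, found {len(labels)}")
    out: dict = {"axis": axis, "labels": labels}
    for kind, selector in (("SNV", lambda v: v == "SNV"), ("INDEL", lambda v: v != "SNV")):
        cells: dict[frozenset, int] = {}
        n_total = n_multi = 0
        for rec in records:
            if not selector(rec.variant.vtype):
                continue
            subset = pick(rec.supports)
            cells[subset] = cells.get(subset, 0) + 1
            n_total += 1
            if len(subset) >= 2:
                n_multi += 1
        out[kind] = {
            "cells": {";".join(sorted(k)): v for k, v in cells.items()},
            "n_variants": n_total,
            "fraction_ge2": (n_multi / n_total) if n_total else None,
        }
    return out
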