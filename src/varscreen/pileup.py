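"""SAM-text parsing, post-mapping read filters, and per-base pileup construction.

The pileup is the authoritative source for the per-variant coverage
decomposition (A/C/G/T counts before and after base-quality filtering); caller
depth fields are only a fallback when no alignment is available.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

FLAG_PAIRED = 0x1
FLAG_PROPER_PAIR = 0x2
FLAG_UNMAPPED = 0x4
FLAG_REVERSE = 0x10
FLAG_DUP = 0x400

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
QUERY_OPS = set("MIS=X")
REF_OPS = set("MDN=X")


class SamFormatError(ValueError):
    pass


@dataclass
class AlignedRead:
    qname: str
    flag: int
    contig: str
    pos: int  # 0-based leftmost reference position
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    quals: list[int]
    pnext: int = -1  # 0-based mate position, -1 if unset
    duplicate: bool = False

    def __post_init__(self) -> None:
        if self.seq != "*":
            qlen = sum(n for op, n in self.cigar if op in QUERY_OPS)
            if qlen != len(self.seq):
                raise SamFormatError(
                    f"{self.qname}: CIGAR query length {qlen} != seq length {len(self.seq)}"
                )
            if len(self.quals) != len(self.seq):
                raise SamFormatError(f"{self.qname}: qual/seq length mismatch")
        self.duplicate = bool(self.flag & FLAG_DUP)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flag & FLAG_PROPER_PAIR)

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & FLAG_REVERSE)

    def reference_end(self) -> int:
        return self.pos + sum(n for op, n in self.cigar if op in REF_OPS)

    def unclipped_start(self) -> int:
        """5'-most reference coordinate with soft/hard clips restored.

        For reverse-strand reads the sequencing 5' end is the rightmost base,
        so the unclipped end coordinate is used; this lets clipped PCR
        duplicates group with their unclipped siblings.
        """
        if self.is_reverse:
            clip = 0
            for op, n in reversed(self.cigar):
                if op in "SH":
                    clip += n
                else:
                    break
            return self.reference_end() + clip
        clip = 0
        for op, n in self.cigar:
            if op in "SH":
                clip += n
            else:
                break
        return self.pos - clip

    def qual_sum(self) -> int:
        return sum(self.quals)


@dataclass
class ReadFilterPolicy:
    """Post-mapping filters: minimum MAPQ, proper-pair (paired reads only), duplicates."""

    min_mapq: int = 0
    require_proper_pair: bool = False
    drop_duplicates: bool = True

    def passes(self, read: AlignedRead) -> bool:
        if read.mapq < self.min_mapq:
            return False
        if self.require_proper_pair and read.is_paired and not read.is_proper_pair:
            return False
        if self.drop_duplicates and read.duplicate:
            return False
        return True


@dataclass
class PileupColumn:
    contig: str
    pos: int
    raw_counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in "ACGT"})
    filtered_counts: dict[str, int] = field(default_factory=lambda: {b: 0 for b in "ACGT"})
    base_quals: list[int] = field(default_factory=list)

    @property
    def total_raw(self) -> int:
        return sum(self.raw_counts.values())

    @property
    def total_filtered(self) -> int:
        return sum(self.filtered_counts.values())


def _parse_cigar(text: str) -> list[tuple[str, int]]:
    if text == "*":
        return []
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(text)]
    if "".join(f"{n}{op}" for op, n in ops) != text:
        raise SamFormatError(f"malformed CIGAR {text!r}")
    return ops


def parse_sam(source):
    """Yield :class:`AlignedRead` from SAM text, skipping unmapped records.

    Returns a generator; the number of skipped unmapped records is available
    on the generator's ``.skipped`` attribute after exhaustion via
    :func:`parse_sam_counted` (use that form when the counter matters).
    """
    reads, _ = parse_sam_counted(source)
    yield from reads


def parse_sam_counted(source) -> tuple[list[AlignedRead], int]:
    """Parse SAM text fully, returning (mapped reads, skipped-unmapped count)."""
    stream = io.StringIO(source) if isinstance(source, str) else source
    reads: list[AlignedRead] = []
    skipped = 0
    for line in stream:
        line = line.rstrip("\n")
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        if len(f) < 11:
            raise SamFormatError(f"alignment line with {len(f)} < 11 fields")
        flag = int(f[1])
        cigar = _parse_cigar(f[5])
        if flag & FLAG_UNMAPPED or not cigar:
            skipped += 1
            continue
        quals = [] if f[10] == "*" else [ord(c) - 33 for c in f[10]]
        if f[10] == "*" and f[9] != "*":
            quals = [0] * len(f[9])
        reads.append(
            AlignedRead(
                qname=f[0],
                flag=flag,
                contig=f[2],
                pos=int(f[3]) - 1,
                mapq=int(f[4]),
                cigar=cigar,
                seq=f[9].upper(),
                quals=quals,
                pnext=int(f[7]) - 1,
            )
        )
    return reads, skipped


def mark_duplicates(reads: list[AlignedRead]) -> list[AlignedRead]:
    """Flag PCR duplicates in place and return the list.

    Reads sharing (contig, unclipped 5' start, strand, mate 5' start when
    paired) form one group; the member with the highest base-quality sum stays
    unflagged, ties broken by lexicographically smallest qname.  Idempotent.
    """
    groups: dict[tuple, list[AlignedRead]] = {}
    for r in reads:
        mate_key = r.pnext if r.is_paired else None
        key = (r.contig, r.unclipped_start(), r.is_reverse, mate_key)
        groups.setdefault(key, []).append(r)
    for members in groups.values():
        best = min(members, key=lambda r: (-r.qual_sum(), r.qname))
        for r in members:
            r.duplicate = r is not best
    return reads


def build_pileup(
    reads: list[AlignedRead],
    contig: str,
    start: int,
    end: int,
    policy: ReadFilterPolicy | None = None,
    min_base_qual: int = 20,
) -> list[PileupColumn]:
    """Walk CIGARs and tally per-position base counts over ``[start, end)``.

    M/=/X deposit base and quality; I consumes query only (no column); D/N
    consume reference without depositing (deletion alleles are not counted —
    the coverage decomposition is A/C/G/T only); S/H deposit nowhere.
    ``raw_counts`` cover every policy-passing read; ``filtered_counts``
    additionally require base quality >= ``min_base_qual``.
    """
    if end <= start:
        raise ValueError("empty pileup region")
    policy = policy or ReadFilterPolicy()
    columns = [PileupColumn(contig=contig, pos=p) for p in range(start, end)]
    for read in reads:
        if read.contig != contig or not policy.passes(read):
            continue
        rpos, qpos = read.pos, 0
        for op, n in read.cigar:
            if op in "M=X":
                for i in range(n):
                    p = rpos + i
                    if start <= p < end:
                        base = read.seq[qpos + i]
                        qual = read.quals[qpos + i]
                        col = columns[p - start]
                        if base in "ACGT":
                            col.raw_counts[base] += 1
                            col.base_quals.append(qual)
                            if qual >= min_base_qual:
                                col.filtered_counts[base] += 1
                rpos += n
                qpos += n
            elif op == "I":
                qpos += n
            elif op in "DN":
                rpos += n
            elif op == "S":
                qpos += n
            # H, P: consume nothing relevant
    return columns


def pileup_to_tsv(columns: list[PileupColumn]) -> str:
    """Debug export: contig, 1-based pos, raw A/C/G/T, filtered A/C/G/T."""
    lines = ["contig\tpos1\tA\tC\tG\tT\tA_f\tC_f\tG_f\tT_f"]
    for c in columns:
        raw = "\t".join(str(c.raw_counts[b]) for b in "ACGT")
        filt = "\t".join(str(c.filtered_counts[b]) for b in "ACGT")
        lines.append(f"{c.contig}\t{c.pos + 1}\t{raw}\t{filt}")
    return "\n".join(lines) + "\n"
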