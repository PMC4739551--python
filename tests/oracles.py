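"""Independent brute-force oracles used to verify the implementation.

These deliberately avoid the package's own code paths: exact integer
hypergeometric enumeration for Fisher's test, direct read expansion for the
pileup, exhaustive spelling enumeration for indel normalization, and the
literal Benjamini–Hochberg step-up formula.
"""

from __future__ import annotations

from math import comb


def fisher_enum(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration, exact integers."""
    n1, n2, m = a + b, c + d, a + c
    total = comb(n1 + n2, m)
    lo, hi = max(0, m - n2), min(n1, m)
    weights = {k: comb(n1, k) * comb(n2, m - k) for k in range(lo, hi + 1)}
    observed = weights[a]
    # tables whose point probability <= observed's, with a tiny relative slack
    # for float ties (weights are exact integers, so compare integers directly
    # with a multiplicative tolerance)
    numer = sum(w for w in weights.values() if w <= observed + observed * 1e-7)
    return numer / total


def bh_stepup(pvals: list[float]) -> list[float]:
    """Literal BH step-up: sort ascending, adj_i = min_{j>=i} m*p_(j)/j, cap 1."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj_sorted = [0.0] * m
    running = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj_sorted[rank - 1] = min(1.0, running)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out


def expand_read(read) -> list[tuple[int, str, int]]:
    """Explicit (refpos, base, qual) triples for one aligned read."""
    triples = []
    rpos, qpos = read.pos, 0
    for op, n in read.cigar:
        if op in "M=X":
            for i in range(n):
                triples.append((rpos + i, read.seq[qpos + i], read.quals[qpos + i]))
            rpos += n
            qpos += n
        elif op in "IS":
            qpos += n
        elif op in "DN":
            rpos += n
    return triples


def pileup_by_expansion(reads, contig, start, end, policy, min_base_qual):
    """Tally base counts by brute-force expansion; mirrors the pileup contract."""
    raw = {p: {b: 0 for b in "ACGT"} for p in range(start, end)}
    filt = {p: {b: 0 for b in "ACGT"} for p in range(start, end)}
    for read in reads:
        if read.contig != contig or not policy.passes(read):
            continue
        for pos, base, qual in expand_read(read):
            if start <= pos < end and base in "ACGT":
                raw[pos][base] += 1
                if qual >= min_base_qual:
                    filt[pos][base] += 1
    return raw, filt


def equivalent_spellings(genome, contig, start, ref, alt, pad: int = 25):
    """Every (start, ref, alt) whose application to the reference yields the
    same local haplotype as the given variant — exhaustive window scan.

    Only anchored indel spellings (ref and alt sharing a leading base, one of
    them length 1 after the anchor run is ignored) are enumerated, matching
    how VCF callers emit indels.
    """
    seq = genome.contigs[contig]
    lo = max(0, start - pad)
    hi = min(len(seq), start + len(ref) + pad)
    window = seq[lo:hi]
    mutated = seq[:start] + alt + seq[start + len(ref):]
    target = mutated[lo : hi + len(alt) - len(ref)]
    out = []
    indel = abs(len(ref) - len(alt))
    for p in range(lo, hi):
        rel = p - lo
        if len(ref) > len(alt):  # deletions: ref = anchor + run, alt = anchor
            if rel + 1 + indel > len(window):
                continue
            cand_ref = window[rel : rel + 1 + indel]
            cand_alt = cand_ref[0]
            applied = window[:rel] + cand_alt + window[rel + 1 + indel :]
            if applied == target:
                out.append((p, cand_ref, cand_alt))
        else:  # insertions: alt = anchor + inserted run
            cand_ref = window[rel : rel + 1]
            inserted = target[rel + 1 : rel + 1 + indel]
            if len(inserted) < indel:
                continue
            cand_alt = cand_ref + inserted
            applied = window[: rel + 1] + inserted + window[rel + 1 :]
            if applied == target:
                out.append((p, cand_ref, cand_alt))
    return out
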