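"""Per-variant summary statistics and filtering.

Implements the flanking-quality window, the A/C/G/T coverage decomposition,
the per-variant two-tailed Fisher's exact test against the mean allele counts
of the sample's remaining variants, Benjamini–Hochberg FDR across a sample,
and the coverage / allele-frequency pass filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .pileup import PileupColumn


@dataclass
class FlankingQuality:
    mean_qual: float | None
    median_qual: float | None
    n_bases: int


@dataclass
class CoverageDecomposition:
    """Filtered and raw base counts at the variant column, plus the variant's own depth.

    ``var_cov`` is the filtered count of the alt base for SNVs; for indels the
    pileup holds no indel allele, so the caller-reported alt depth is carried
    instead (or None when no caller reported one).
    """

    A: int
    C: int
    G: int
    T: int
    var_cov: int | None
    raw_A: int = 0
    raw_C: int = 0
    raw_G: int = 0
    raw_T: int = 0

    @property
    def total(self) -> int:
        return self.A + self.C + self.G + self.T

    @property
    def total_raw(self) -> int:
        return self.raw_A + self.raw_C + self.raw_G + self.raw_T


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]] | None
    p: float | None
    p_adj: float | None = None


@dataclass
class FilterPolicy:
    """Pass thresholds: total coverage, variant-allele coverage, allele frequency."""

    min_total_cov: int = 20
    min_alt_cov: int = 4
    min_af: float = 0.10

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_af <= 1.0):
            raise ValueError("min_af must be within [0, 1]")


def flanking_quality(
    columns: list[PileupColumn], pos: int, window: int = 10
) -> FlankingQuality:
    """Mean and median base quality in the +/- ``window`` bases around ``pos``.

    The variant column itself is excluded.  Median is the lower middle value
    for even counts, so it is always an observed PHRED integer.  With zero
    covered flanking bases the statistics are null.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    quals: list[int] = []
    for col in columns:
        if col.pos == pos or abs(col.pos - pos) > window:
            continue
        quals.extend(col.base_quals)
    if not quals:
        return FlankingQuality(mean_qual=None, median_qual=None, n_bases=0)
    quals.sort()
    median = quals[(len(quals) - 1) // 2]  # lower middle for even n
    return FlankingQuality(
        mean_qual=sum(quals) / len(quals), median_qual=float(median), n_bases=len(quals)
    )


def coverage_decomposition(
    column: PileupColumn, alt_base: str | None, alt_depth_fallback: int | None = None
) -> CoverageDecomposition:
    """Decompose one pileup column into per-base counts and the variant's depth."""
    if alt_base is not None and alt_base not in "ACGT":
        raise ValueError(f"SNV alt base must be one of A,C,G,T, got {alt_base!r}")
    fc, rc = column.filtered_counts, column.raw_counts
    var_cov = fc[alt_base] if alt_base is not None else alt_depth_fallback
    return CoverageDecomposition(
        A=fc["A"], C=fc["C"], G=fc["G"], T=fc["T"],
        var_cov=var_cov,
        raw_A=rc["A"], raw_C=rc["C"], raw_G=rc["G"], raw_T=rc["T"],
    )


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Point-probability rule: the p-value sums hypergeometric probabilities of
    every table with the same margins whose probability does not exceed that
    of the observed table (with a small relative tolerance for float ties).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table cells must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("all four cells are zero")
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def variant_fisher(
    variant_counts: tuple[int, int], other_counts: list[tuple[int, int]]
) -> FisherResult:
    """Fisher's exact test of one variant's (ref, alt) counts against the sample mean.

    Row 1 is the variant's own (ref_count, alt_count); row 2 is the
    component-wise arithmetic mean over all *other* variants of the same
    sample, rounded half-up to integers (an exact test needs integer cells).
    With no other variants the test is undefined (null result).
    """
    if not other_counts:
        return FisherResult(table=None, p=None)
    mean_ref = _round_half_up(sum(r for r, _ in other_counts) / len(other_counts))
    mean_alt = _round_half_up(sum(a for _, a in other_counts) / len(other_counts))
    a, b = variant_counts
    if a + b + mean_ref + mean_alt == 0:
        return FisherResult(table=None, p=None)
    p = fisher_two_tailed(a, b, mean_ref, mean_alt)
    return FisherResult(table=((a, b), (mean_ref, mean_alt)), p=p)


def adjust_fdr(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in the input order."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


def apply_filters(
    decomposition: CoverageDecomposition, policy: FilterPolicy
) -> tuple[bool, list[str]]:
    """Coverage/frequency pass filter with machine-readable failure reasons."""
    reasons: list[str] = []
    total = decomposition.total
    var_cov = decomposition.var_cov
    if total == 0:
        return False, ["no_coverage"]
    if total < policy.min_total_cov:
        reasons.append("low_total_cov")
    if var_cov is None:
        reasons.append("unknown_alt_cov")
    else:
        if var_cov < policy.min_alt_cov:
            reasons.append("low_alt_cov")
        if var_cov / total < policy.min_af:
            reasons.append("low_af")
    return (not reasons), reasons
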