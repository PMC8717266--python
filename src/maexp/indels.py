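"""Insertion/deletion analysis: size balance, SSR overlap, region bias.

Indels are compared against two genomic strata: protein-coding intervals
(slippage indels shift reading frames, so coding depletion is the
signature of selection or ascertainment) and SSR loci (slippage
hotspots).  Overlap uses the left-normalized affected interval:
``[pos, pos + len(ref))`` for a deletion (anchor base included) and the
insertion point ``pos + 1`` for an insertion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .errors import CoordinateError
from .genome import AnnotatedGenome
from .model import DELETION, INSERTION, MutationCall
from .rates import RateEstimate, poisson_ci
from .spectrum import region_fisher_test
from .ssr import SSRInterval

__all__ = ["IndelSummary", "indel_size_balance", "indel_region_analysis", "MAX_INDEL_SIZE"]

# small-indel class boundary; longer events are structural variants
MAX_INDEL_SIZE = 50


@dataclass(frozen=True)
class IndelSummary:
    """Counts, size balance and genomic context of small indels."""

    n_insertions: int
    n_deletions: int
    bp_inserted: int
    bp_deleted: int
    net_bp: int
    n_in_ssr: int | None = None
    n_coding: int | None = None
    n_noncoding: int | None = None
    expected_coding: float | None = None
    expected_noncoding: float | None = None
    coding_fisher_p: float | None = None
    rate_total: RateEstimate | None = None
    rate_insertions: RateEstimate | None = None
    rate_deletions: RateEstimate | None = None

    @property
    def n_total(self) -> int:
        return self.n_insertions + self.n_deletions

    @property
    def ssr_fraction(self) -> float | None:
        if self.n_in_ssr is None or self.n_total == 0:
            return None
        return self.n_in_ssr / self.n_total


def _check_indels(indels: list[MutationCall]) -> list[MutationCall]:
    bad = [c for c in indels if c.mclass not in (INSERTION, DELETION)]
    if bad:
        raise ValueError(f"{len(bad)} non-indel calls in indel input")
    kept = []
    for c in indels:
        if abs(c.size) > MAX_INDEL_SIZE:
            warnings.warn(
                f"indel of {abs(c.size)} bp at {c.position} exceeds the "
                f"{MAX_INDEL_SIZE} bp small-indel class; excluded",
                stacklevel=3,
            )
            continue
        kept.append(c)
    return kept


def indel_size_balance(indels: list[MutationCall]) -> IndelSummary:
    """Insertion/deletion counts, total bp gained/lost and the signed net."""
    indels = _check_indels(indels)
    ins = [c for c in indels if c.mclass == INSERTION]
    dels = [c for c in indels if c.mclass == DELETION]
    bp_ins = sum(c.size for c in ins)
    bp_del = sum(-c.size for c in dels)
    return IndelSummary(
        n_insertions=len(ins),
        n_deletions=len(dels),
        bp_inserted=bp_ins,
        bp_deleted=bp_del,
        net_bp=bp_ins - bp_del,
    )


def affected_span(call: MutationCall) -> tuple[int, int]:
    """Genomic interval an indel affects, for overlap tests.

    Deletions: ``[pos, pos + len(ref))``; insertions: the zero-width
    insertion point ``[pos + 1, pos + 1)`` (first position after the
    anchor base).
    """
    if call.mclass == DELETION:
        return call.position, call.position + len(call.ref)
    return call.position + 1, call.position + 1


def _overlaps_ssr(call: MutationCall, ssrs: list[SSRInterval]) -> bool:
    a, b = affected_span(call)
    if a == b:  # insertion point
        return any(s.start <= a < s.end for s in ssrs)
    return any(s.start < b and a < s.end for s in ssrs)


def _in_coding(call: MutationCall, genome: AnnotatedGenome) -> bool:
    a, b = affected_span(call)
    if a == b:
        return genome.is_coding(min(a, genome.length - 1))
    return bool(genome.coding_mask[a:b].any())


def indel_region_analysis(
    indels: list[MutationCall],
    genome: AnnotatedGenome,
    ssrs: list[SSRInterval],
    denominator: float | None = None,
    level: float = 0.95,
) -> IndelSummary:
    """Full indel summary: sizes, SSR overlap, coding depletion, rates.

    The expected coding count under uniform placement is
    ``total * coding_fraction`` (reported unrounded); enrichment is
    tested with a two-sided Fisher's exact test on events vs non-event
    site-generations by region when a denominator is given.
    """
    indels = _check_indels(indels)
    for c in indels:
        a, b = affected_span(c)
        if a < 0 or max(a, b) > genome.length:
            raise CoordinateError(f"indel span [{a}, {b}) outside genome")
    base = indel_size_balance(indels)
    n_total = len(indels)
    n_in_ssr = sum(_overlaps_ssr(c, ssrs) for c in indels)
    n_coding = sum(_in_coding(c, genome) for c in indels)
    n_noncoding = n_total - n_coding
    cf = genome.coding_fraction
    expected_coding = n_total * cf
    expected_noncoding = n_total * (1.0 - cf)
    fisher_p = None
    rate_total = rate_ins = rate_del = None
    if denominator is not None and denominator > 0:
        if 0.0 < cf < 1.0:
            _, fisher_p = region_fisher_test(
                n_coding, cf * denominator, n_noncoding, (1.0 - cf) * denominator
            )
        rate_total = _rate(n_total, denominator, level)
        rate_ins = _rate(base.n_insertions, denominator, level)
        rate_del = _rate(base.n_deletions, denominator, level)
    return IndelSummary(
        n_insertions=base.n_insertions,
        n_deletions=base.n_deletions,
        bp_inserted=base.bp_inserted,
        bp_deleted=base.bp_deleted,
        net_bp=base.net_bp,
        n_in_ssr=n_in_ssr,
        n_coding=n_coding,
        n_noncoding=n_noncoding,
        expected_coding=expected_coding,
        expected_noncoding=expected_noncoding,
        coding_fisher_p=fisher_p,
        rate_total=rate_total,
        rate_insertions=rate_ins,
        rate_deletions=rate_del,
    )


def _rate(m: int, denom: float, level: float) -> RateEstimate:
    low, high = poisson_ci(m, denom, level)
    return RateEstimate(m=m, denominator=denom, mu=m / denom, ci_low=low, ci_high=high, level=level)
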