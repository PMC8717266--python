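"""Substitution spectrum: six collapsed classes, ts/tv, coding effects.

Because DNA is double-stranded, the 12 possible single-base changes
collapse into 6 classes (A→G on one strand is T→C on the other).  Two of
the six are transitions (A:T→G:C, G:C→A:T), four are transversions.

The expected nonsynonymous:synonymous (NS:S) ratio under the null of no
selection is computed by enumerating every possible single-base change in
every annotated codon (codon usage enters through the actual coding
sequence) and weighting each specific change by whether it is a
transition or a transversion.  With an observed count ratio ts/tv = R and
each site offering 1 transition and 2 transversions, a per-change weight
ratio w_ti/w_tv = 2R makes the aggregate expected ts:tv count ratio equal
R; the factor 2 is exposed as a parameter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import math

from scipy.stats import chisquare, fisher_exact

from .errors import AnnotationError, CoordinateError
from .genome import CDS, AnnotatedGenome, revcomp, translate_codon
from .model import SUBSTITUTION, MutationCall
from .rates import RateEstimate, poisson_ci

__all__ = [
    "SubstitutionClass",
    "SpectrumSummary",
    "RegionPartition",
    "classify_substitution",
    "count_spectrum",
    "titv_ratio",
    "partition_by_annotation",
    "classify_coding_effect",
    "expected_ns_ratio",
    "ns_ratio_test",
]

TRANSITION = "transition"
TRANSVERSION = "transversion"

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SubstitutionClass(Enum):
    """Strand-collapsed substitution classes."""

    AT_GC = "A:T>G:C"
    GC_AT = "G:C>A:T"
    AT_CG = "A:T>C:G"
    GC_TA = "G:C>T:A"
    AT_TA = "A:T>T:A"
    GC_CG = "G:C>C:G"

    @property
    def kind(self) -> str:
        return TRANSITION if self in (SubstitutionClass.AT_GC, SubstitutionClass.GC_AT) else TRANSVERSION

    @property
    def from_gc(self) -> bool:
        """True if the class mutates a G:C pair (requires a G/C site)."""
        return self in (SubstitutionClass.GC_AT, SubstitutionClass.GC_TA, SubstitutionClass.GC_CG)


# (ref, alt) -> class, for all 12 ordered base pairs
_PAIR_TO_CLASS: dict[tuple[str, str], SubstitutionClass] = {
    ("A", "G"): SubstitutionClass.AT_GC,
    ("T", "C"): SubstitutionClass.AT_GC,
    ("G", "A"): SubstitutionClass.GC_AT,
    ("C", "T"): SubstitutionClass.GC_AT,
    ("A", "C"): SubstitutionClass.AT_CG,
    ("T", "G"): SubstitutionClass.AT_CG,
    ("G", "T"): SubstitutionClass.GC_TA,
    ("C", "A"): SubstitutionClass.GC_TA,
    ("A", "T"): SubstitutionClass.AT_TA,
    ("T", "A"): SubstitutionClass.AT_TA,
    ("G", "C"): SubstitutionClass.GC_CG,
    ("C", "G"): SubstitutionClass.GC_CG,
}

# class -> {ref base on the forward strand: alt base}; used by the simulator
CLASS_TO_CHANGE: dict[SubstitutionClass, dict[str, str]] = {
    SubstitutionClass.AT_GC: {"A": "G", "T": "C"},
    SubstitutionClass.GC_AT: {"G": "A", "C": "T"},
    SubstitutionClass.AT_CG: {"A": "C", "T": "G"},
    SubstitutionClass.GC_TA: {"G": "T", "C": "A"},
    SubstitutionClass.AT_TA: {"A": "T", "T": "A"},
    SubstitutionClass.GC_CG: {"G": "C", "C": "G"},
}


def classify_substitution(ref_base: str, alt_base: str) -> SubstitutionClass:
    """Strand-collapsed class of a single-base substitution."""
    key = (ref_base.upper(), alt_base.upper())
    if key not in _PAIR_TO_CLASS:
        raise ValueError(f"invalid substitution {ref_base!r}->{alt_base!r}")
    return _PAIR_TO_CLASS[key]


def is_transition(ref_base: str, alt_base: str) -> bool:
    r, a = ref_base.upper(), alt_base.upper()
    return (r in _PURINES) == (a in _PURINES) and r != a


@dataclass(frozen=True)
class SpectrumSummary:
    """Class counts, ts/tv and region/effect partition of substitutions."""

    class_counts: dict
    n_transitions: int
    n_transversions: int
    titv: float  # math.inf when there are no transversions
    n_coding: int
    n_noncoding: int
    n_synonymous: int
    n_nonsynonymous: int


def _substitutions_only(calls: list[MutationCall]) -> list[MutationCall]:
    bad = [c for c in calls if c.mclass != SUBSTITUTION]
    if bad:
        raise ValueError(f"{len(bad)} non-substitution calls in spectrum input")
    return calls


def count_spectrum(calls: list[MutationCall]) -> dict[SubstitutionClass, int]:
    """Counts per collapsed class (all six keys always present)."""
    counts = {cls: 0 for cls in SubstitutionClass}
    for c in _substitutions_only(calls):
        counts[classify_substitution(c.ref, c.alt)] += 1
    return counts


def titv_ratio(calls: list[MutationCall]) -> float:
    """Transition/transversion count ratio; ``inf`` if no transversions."""
    counts = count_spectrum(calls)
    n_ti = sum(n for cls, n in counts.items() if cls.kind == TRANSITION)
    n_tv = sum(n for cls, n in counts.items() if cls.kind == TRANSVERSION)
    if n_tv == 0:
        return math.inf
    return n_ti / n_tv


@dataclass(frozen=True)
class RegionPartition:
    """Coding/noncoding partition of calls with region-specific rates."""

    n_coding: int
    n_noncoding: int
    coding_fraction_of_genome: float
    coding_rate: RateEstimate | None
    noncoding_rate: RateEstimate | None
    fisher_odds_ratio: float | None
    fisher_p: float | None
    coding_calls: tuple
    noncoding_calls: tuple


def region_fisher_test(
    n_region_a: int, denom_a: float, n_region_b: int, denom_b: float
) -> tuple[float, float]:
    """Two-sided Fisher's exact test on events vs non-event site-generations."""
    table = [
        [n_region_a, max(round(denom_a) - n_region_a, 0)],
        [n_region_b, max(round(denom_b) - n_region_b, 0)],
    ]
    odds, p = fisher_exact(table, alternative="two-sided")
    return float(odds), float(p)


def partition_by_annotation(
    calls: list[MutationCall],
    genome: AnnotatedGenome,
    denominator: float | None = None,
    level: float = 0.95,
) -> RegionPartition:
    """Label substitutions coding/noncoding and compare region rates.

    Region-specific exposures split the pooled denominator by the genome
    coding fraction.  When ``denominator`` is None only counts are
    reported.
    """
    for c in calls:
        if not 0 <= c.position < genome.length:
            raise CoordinateError(f"call at {c.position} outside genome")
    coding = tuple(c for c in calls if genome.is_coding(c.position))
    noncoding = tuple(c for c in calls if not genome.is_coding(c.position))
    cf = genome.coding_fraction
    coding_rate = noncoding_rate = None
    odds = p = None
    if denominator is not None and denominator > 0 and 0.0 < cf < 1.0:
        d_cod = cf * denominator
        d_non = (1.0 - cf) * denominator
        coding_rate = _region_rate(len(coding), d_cod, level)
        noncoding_rate = _region_rate(len(noncoding), d_non, level)
        odds, p = region_fisher_test(len(coding), d_cod, len(noncoding), d_non)
    return RegionPartition(
        n_coding=len(coding),
        n_noncoding=len(noncoding),
        coding_fraction_of_genome=cf,
        coding_rate=coding_rate,
        noncoding_rate=noncoding_rate,
        fisher_odds_ratio=odds,
        fisher_p=p,
        coding_calls=coding,
        noncoding_calls=noncoding,
    )


def _region_rate(m: int, denom: float, level: float) -> RateEstimate:
    low, high = poisson_ci(m, denom, level)
    return RateEstimate(m=m, denominator=denom, mu=m / denom, ci_low=low, ci_high=high, level=level)


# -- coding effects --------------------------------------------------------


def _effect_in_cds(call: MutationCall, genome: AnnotatedGenome, cds: CDS) -> str:
    if len(cds) % 3 != 0:
        raise AnnotationError(f"CDS [{cds.start}, {cds.end}) length not a multiple of 3")
    pos = call.position
    if cds.strand == "+":
        offset = pos - cds.start
        coding_ref = call.ref
        coding_alt = call.alt
    else:
        offset = cds.end - 1 - pos
        coding_ref = revcomp(call.ref)
        coding_alt = revcomp(call.alt)
    codon_idx = offset // 3
    within = offset % 3
    cseq = genome.coding_sequence(cds)
    codon = cseq[codon_idx * 3 : codon_idx * 3 + 3]
    if codon[within] != coding_ref:
        raise AnnotationError(
            f"reference mismatch at {pos}: genome codon {codon!r} vs call ref {call.ref!r}"
        )
    mutated = codon[:within] + coding_alt + codon[within + 1 :]
    return "synonymous" if translate_codon(codon) == translate_codon(mutated) else "nonsynonymous"


def classify_coding_effect(
    call: MutationCall, genome: AnnotatedGenome, any_frame_nonsynonymous: bool = True
) -> str:
    """Synonymous/nonsynonymous status of a coding substitution.

    The codon containing the site is mutated (strand-aware) and
    translated with the bacterial code.  For positions inside several
    overlapping CDS the call is nonsynonymous if nonsynonymous in any
    frame (default), or classified by the first CDS when
    ``any_frame_nonsynonymous`` is False.
    """
    if call.mclass != SUBSTITUTION:
        raise ValueError("coding effect defined for substitutions only")
    cds_list = genome.cds_at(call.position)
    if not cds_list:
        raise ValueError(f"position {call.position} is not inside any CDS")
    effects = [_effect_in_cds(call, genome, cds) for cds in cds_list]
    if any_frame_nonsynonymous:
        return "nonsynonymous" if "nonsynonymous" in effects else "synonymous"
    return effects[0]


def expected_ns_ratio(
    genome: AnnotatedGenome, titv: float, ti_weight_factor: float = 2.0
) -> float:
    """Expected NS:S ratio from codon usage and the ts/tv ratio.

    All 3L single-base changes over every CDS are enumerated (aggregated
    by codon usage); each transition gets weight ``ti_weight_factor *
    titv`` relative to a transversion weight of 1.  Stop codons of the
    annotation are included; a stop-to-stop change is synonymous and a
    gained stop is nonsynonymous.
    """
    if not genome.cds:
        raise ValueError("genome has no CDS annotation")
    if not titv > 0 or not math.isfinite(titv):
        raise ValueError(f"ts/tv ratio must be finite and positive, got {titv}")
    w_ti = ti_weight_factor * titv
    w_tv = 1.0
    usage: Counter[str] = Counter()
    for cds in genome.cds:
        cseq = genome.coding_sequence(cds)
        if len(cseq) % 3 != 0:
            raise AnnotationError(f"CDS [{cds.start}, {cds.end}) length not a multiple of 3")
        usage.update(cseq[i : i + 3] for i in range(0, len(cseq), 3))
    ns_w = s_w = 0.0
    for codon, n in usage.items():
        aa = translate_codon(codon)
        for i in range(3):
            for alt in "ACGT":
                if alt == codon[i]:
                    continue
                w = n * (w_ti if is_transition(codon[i], alt) else w_tv)
                mutated = codon[:i] + alt + codon[i + 1 :]
                if translate_codon(mutated) == aa:
                    s_w += w
                else:
                    ns_w += w
    if s_w == 0:
        return math.inf
    return ns_w / s_w


def ns_ratio_test(n_nonsyn: int, n_syn: int, expected_ratio: float) -> tuple[float, int, float]:
    """Chi-square goodness of fit of observed NS/S counts to an expected ratio.

    One degree of freedom, no continuity correction.  Returns
    (statistic, df, p-value).
    """
    total = n_nonsyn + n_syn
    if total <= 0:
        raise ValueError("no observations")
    if not expected_ratio > 0:
        raise ValueError("expected ratio must be positive")
    r = expected_ratio
    expected = [total * r / (1.0 + r), total / (1.0 + r)]
    stat, p = chisquare([n_nonsyn, n_syn], f_exp=expected)
    return float(stat), 1, float(p)
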