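"""Mutation-rate estimators for pooled MA-line data.

The pooled point estimate is

    mu = m / sum_i(N_i * T_i)

with m the total number of mutations over all lines, N_i the callable
sites and T_i the generations of line i.  Confidence intervals are exact
(Garwood) Poisson intervals obtained from chi-square quantiles:

    low  = chi2.ppf(alpha/2, 2m) / 2 / D        (0 when m = 0)
    high = chi2.ppf(1 - alpha/2, 2m + 2) / 2 / D

where D is the site-generation denominator.  The SEM is the standard
deviation (n-1 denominator) of the per-line rates m_i/(N_i*T_i) divided
by sqrt(n).

Generation counts per transfer are estimated from colony size as
log2(CFU): a colony founded by one cell that doubled g times contains
2^g cells.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .errors import DegenerateExperimentError
from .model import MALine

__all__ = [
    "RateEstimate",
    "ConditionalRates",
    "generations_from_cfu",
    "site_generations",
    "poisson_ci",
    "pooled_rate",
    "per_genome_rate",
    "conditional_rates",
    "equilibrium_gc",
]


@dataclass(frozen=True)
class RateEstimate:
    """A rate with its exact Poisson CI and (optionally) a between-line SEM."""

    m: int
    denominator: float
    mu: float
    ci_low: float
    ci_high: float
    sem: float | None = None
    level: float = 0.95

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mu <= self.ci_high):
            raise ValueError("CI does not bracket the point estimate")


@dataclass(frozen=True)
class ConditionalRates:
    """Directional rates conditioned on site composition.

    ``mu_gc_to_at`` is the rate of changes away from G:C pairs per G/C
    site-generation (AT direction); ``mu_at_to_gc`` the converse.
    """

    mu_gc_to_at: float
    mu_at_to_gc: float
    gc_fraction: float


def generations_from_cfu(cfu: float) -> float:
    """Generations elapsed in one colony, log2 of its viable cell count."""
    if cfu < 1:
        raise ValueError(f"CFU must be >= 1, got {cfu}")
    return math.log2(cfu)


def site_generations(lines: Iterable[MALine]) -> float:
    """Denominator sum_i N_i * T_i over MA lines."""
    return float(sum(l.site_generations for l in lines))


def poisson_ci(count: int, denominator: float, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) Poisson confidence interval for a rate.

    Parameters
    ----------
    count : int
        Observed number of events.
    denominator : float
        Exposure (site-generations); the returned bounds are rates.
    level : float
        Two-sided confidence level in (0, 1).
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level {level} outside (0, 1)")
    if count < 0:
        raise ValueError("count must be >= 0")
    if denominator <= 0:
        raise DegenerateExperimentError("zero site-generation denominator")
    alpha = 1.0 - level
    low = 0.0 if count == 0 else 0.5 * chi2.ppf(alpha / 2.0, 2 * count) / denominator
    high = 0.5 * chi2.ppf(1.0 - alpha / 2.0, 2 * count + 2) / denominator
    return low, high


def pooled_rate(
    counts: int | Mapping[str, int],
    lines: list[MALine],
    level: float = 0.95,
) -> RateEstimate:
    """Pooled mutation rate over MA lines.

    ``counts`` may be the total event count m, or a mapping
    ``line_id -> m_i`` (lines absent from the mapping contribute 0), in
    which case the between-line SEM is also computed.
    """
    denom = site_generations(lines)
    if denom <= 0:
        raise DegenerateExperimentError("zero site-generation denominator")
    sem = None
    if isinstance(counts, Mapping):
        m = int(sum(counts.values()))
        known = set(l.line_id for l in lines)
        unknown = set(counts) - known
        if unknown:
            raise KeyError(f"counts for unknown lines: {sorted(unknown)}")
        if len(lines) > 1:
            per_line = np.array(
                [counts.get(l.line_id, 0) / l.site_generations for l in lines if l.site_generations > 0]
            )
            if per_line.size > 1:
                sem = float(np.std(per_line, ddof=1) / math.sqrt(per_line.size))
    else:
        m = int(counts)
    if m < 0:
        raise ValueError("negative event count")
    mu = m / denom
    low, high = poisson_ci(m, denom, level)
    return RateEstimate(m=m, denominator=denom, mu=mu, ci_low=low, ci_high=high, sem=sem, level=level)


def per_genome_rate(m: int, n_lines: int, generations: float) -> float:
    """Mutations per genome per generation: m / (n_lines * mean generations)."""
    if n_lines <= 0 or generations <= 0:
        raise ValueError("n_lines and generations must be positive")
    if m < 0:
        raise ValueError("negative event count")
    return m / (n_lines * generations)


def conditional_rates(
    counts_to_at: int,
    counts_to_gc: int,
    gc_fraction: float,
    denominator: float,
) -> ConditionalRates:
    """Directional rates normalized by available site composition.

    ``counts_to_at`` are events at G/C sites (G:C→A:T transitions plus
    G:C→T:A transversions); ``counts_to_gc`` events at A/T sites.  The
    total site-generation denominator is partitioned by the genome GC
    fraction.
    """
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError(f"gc_fraction {gc_fraction} outside (0, 1)")
    if denominator <= 0:
        raise DegenerateExperimentError("zero site-generation denominator")
    if counts_to_at < 0 or counts_to_gc < 0:
        raise ValueError("negative event count")
    return ConditionalRates(
        mu_gc_to_at=counts_to_at / (gc_fraction * denominator),
        mu_at_to_gc=counts_to_gc / ((1.0 - gc_fraction) * denominator),
        gc_fraction=gc_fraction,
    )


def equilibrium_gc(mu_at_to_gc: float, mu_gc_to_at: float) -> float:
    """GC content expected under mutation pressure alone.

    mu_AT->GC / (mu_GC->AT + mu_AT->GC); scale-invariant, so composition-
    normalized counts can be passed directly in place of rates.
    """
    if mu_at_to_gc < 0 or mu_gc_to_at < 0:
        raise ValueError("rates must be >= 0")
    total = mu_at_to_gc + mu_gc_to_at
    if total == 0:
        raise ValueError("equilibrium undefined when both rates are zero")
    return mu_at_to_gc / total
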