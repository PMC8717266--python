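"""Simple-sequence-repeat (SSR) detection.

SSRs — perfect tandem repeats of a 1–6 bp motif — are replication-
slippage hotspots, so indel analysis needs their genomic footprint.  The
scanner reports all maximal perfect tandem arrays whose copy number meets
a per-motif-size threshold, with overlapping candidates of different
periods resolved to the longest span (ties: smallest motif, then
leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import AnnotatedGenome

__all__ = [
    "SSRInterval",
    "DEFAULT_MIN_COPIES",
    "find_ssrs",
    "ssr_genome_fraction",
    "write_bed",
]

# minimum copy number by motif length; chosen so that a random ~60% GC
# genome carries ~1% SSR coverage (see docs/methods.md)
DEFAULT_MIN_COPIES: dict[int, float] = {1: 8, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRInterval:
    """A perfect tandem repeat locus, 0-based half-open."""

    start: int
    end: int
    motif: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty SSR interval")
        if not 1 <= len(self.motif) <= 6:
            raise ValueError(f"motif length {len(self.motif)} outside 1-6")

    @property
    def copies(self) -> float:
        """Repeat copy number; fractional when a partial unit ends the array."""
        return (self.end - self.start) / len(self.motif)

    def __len__(self) -> int:
        return self.end - self.start


def _is_primitive(motif: str) -> bool:
    """True if the motif is not itself a repeat of a shorter unit."""
    k = len(motif)
    for d in range(1, k):
        if k % d == 0 and motif == motif[:d] * (k // d):
            return False
    return True


def _true_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (half-open) indices of runs of True."""
    if mask.size == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return starts, ends


def find_ssrs(
    genome: AnnotatedGenome | str,
    min_copies: dict[int, float] | None = None,
) -> list[SSRInterval]:
    """All maximal perfect tandem repeats meeting the copy thresholds.

    Candidates are found per period k (1-6) as maximal stretches where
    ``seq[x] == seq[x+k]``; a stretch of matches over [a, b) covers the
    tandem span [a, b+k).  Non-primitive motifs are dropped (a
    homopolymer is reported once, at period 1).  Overlaps between
    accepted candidates are resolved longest-first, ties broken by
    smaller motif then leftmost start.
    """
    seq = genome.seq if isinstance(genome, AnnotatedGenome) else str(genome).upper()
    thresholds = dict(DEFAULT_MIN_COPIES)
    if min_copies:
        thresholds.update(min_copies)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[SSRInterval] = []
    for k in range(1, 7):
        if arr.size <= k:
            continue
        eq = arr[:-k] == arr[k:]
        starts, ends = _true_runs(eq)
        min_len = k * thresholds[k]
        for a, b in zip(starts, ends):
            span_len = (b - a) + k
            if span_len < min_len:
                continue
            motif = seq[a : a + k]
            if not _is_primitive(motif):
                continue
            candidates.append(SSRInterval(start=int(a), end=int(a) + span_len, motif=motif))
    # resolve overlaps: longest span wins, then smallest motif, then leftmost
    candidates.sort(key=lambda s: (-(s.end - s.start), len(s.motif), s.start))
    accepted: list[SSRInterval] = []
    occupied_starts: list[int] = []
    occupied_ends: list[int] = []
    import bisect

    for cand in candidates:
        i = bisect.bisect_left(occupied_ends, cand.start + 1)
        if i < len(occupied_starts) and occupied_starts[i] < cand.end:
            continue  # overlaps an accepted (longer or higher-priority) SSR
        j = bisect.bisect_left(occupied_starts, cand.start)
        occupied_starts.insert(j, cand.start)
        occupied_ends.insert(j, cand.end)
        accepted.append(cand)
    accepted.sort(key=lambda s: s.start)
    return accepted


def ssr_genome_fraction(ssrs: list[SSRInterval], genome_length: int) -> float:
    """Fraction of the genome covered by the union of SSR intervals."""
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if not ssrs:
        return 0.0
    ivs = sorted((s.start, s.end) for s in ssrs)
    covered = 0
    cur_start, cur_end = ivs[0]
    for s, e in ivs[1:]:
        if s > cur_end:
            covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    covered += cur_end - cur_start
    return covered / genome_length


def write_bed(ssrs: list[SSRInterval], path: str | Path, name: str = "genome") -> None:
    """Write SSRs as BED (0-based half-open) with motif and copy columns."""
    with open(path, "w") as fh:
        for s in sorted(ssrs, key=lambda x: x.start):
            fh.write(f"{name}\t{s.start}\t{s.end}\t{s.motif}\t{s.copies:.2f}\n")
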