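"""Core record types shared across the pipeline.

A mutation-accumulation (MA) experiment propagates many independent
lineages through repeated single-cell bottlenecks, so that essentially all
non-lethal spontaneous mutations drift to fixation.  The two records here
are the atoms of the downstream analysis: one filtered variant call, and
one lineage's exposure (how many sites were observed for how many
generations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MutationCall", "MALine"]

SUBSTITUTION = "substitution"
INSERTION = "insertion"
DELETION = "deletion"


@dataclass(frozen=True)
class MutationCall:
    """One variant call in one MA line.

    Coordinates are 0-based genome offsets of the first REF base
    (VCF POS - 1).  Indels follow the VCF left-anchored padding-base
    convention: a deletion of ``k`` bp has ``len(ref) == k + 1`` and
    ``len(alt) == 1``.

    Parameters
    ----------
    line_id : str
        Identifier of the MA line the call belongs to.
    position : int
        0-based offset of the first REF base.
    ref, alt : str
        Reference and alternate alleles, upper-case ACGT.
    qual : float, optional
        Phred-scaled site quality (VCF QUAL).
    mq : float, optional
        RMS mapping quality (VCF INFO/MQ).
    allele_fraction : float
        Fraction of reads supporting the alternate allele; the line
        consensus filter acts on this.
    caller : str
        Provenance: ``"A"`` (primary), ``"B"`` (secondary) or ``"both"``.
    """

    line_id: str
    position: int
    ref: str
    alt: str
    qual: float | None = None
    mq: float | None = None
    allele_fraction: float = 1.0
    caller: str = "A"

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if not self.ref or not self.alt:
            raise ValueError("empty allele")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.position}")
        if len(self.ref) == len(self.alt) and len(self.ref) > 1:
            raise ValueError(
                "multi-nucleotide substitutions are not supported "
                f"(ref={self.ref!r}, alt={self.alt!r})"
            )
        if not 0.0 <= self.allele_fraction <= 1.0:
            raise ValueError(f"allele_fraction {self.allele_fraction} not in [0, 1]")

    @property
    def mclass(self) -> str:
        """``"substitution"``, ``"insertion"`` or ``"deletion"``."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return SUBSTITUTION
        return INSERTION if len(self.alt) > len(self.ref) else DELETION

    @property
    def size(self) -> int:
        """Signed length change in bp (0 for substitutions)."""
        return len(self.alt) - len(self.ref)


@dataclass(frozen=True)
class MALine:
    """One lineage's exposure metadata.

    ``generations`` is T_i, the total number of cell divisions the line
    experienced (transfers x generations per transfer); ``callable_sites``
    is N_i, the number of genome positions with enough sequencing evidence
    to have detected a mutation.  The product N_i * T_i is the line's
    contribution to the site-generation denominator of every rate.
    """

    line_id: str
    transfers: int
    generations: float
    callable_sites: int

    def __post_init__(self) -> None:
        if self.transfers < 0:
            raise ValueError("transfers must be >= 0")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")
        if self.callable_sites < 0:
            raise ValueError("callable_sites must be >= 0")

    @property
    def site_generations(self) -> float:
        return float(self.callable_sites) * float(self.generations)
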