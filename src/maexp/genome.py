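"""Annotated reference genome: sequence + CDS intervals + composition.

Internally all coordinates are 0-based half-open; GFF3 emission/ingestion
converts to the on-disk 1-based inclusive convention.  Translation uses
the bacterial/archaeal genetic code (NCBI table 11).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from .errors import AnnotationError, CoordinateError

__all__ = [
    "CDS",
    "AnnotatedGenome",
    "read_genome",
    "write_fasta",
    "write_gff3",
    "revcomp",
    "translate_codon",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
STOP_CODONS = frozenset(_TABLE.stop_codons)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Amino acid for a codon under table 11; ``*`` for stop codons."""
    try:
        return CODON_TO_AA[codon.upper()]
    except KeyError:
        raise AnnotationError(f"cannot translate codon {codon!r}") from None


@dataclass(frozen=True)
class CDS:
    """A protein-coding interval, 0-based half-open, with strand."""

    start: int
    end: int
    strand: str
    cds_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise AnnotationError(f"empty CDS [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise AnnotationError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class AnnotatedGenome:
    """Reference sequence with CDS annotation and derived composition."""

    def __init__(self, seq: str, cds: list[CDS] | tuple = (), name: str = "genome"):
        self.seq = str(seq).upper()
        self.cds = sorted(cds, key=lambda c: (c.start, c.end))
        self.name = name
        self._tree: IntervalTree | None = None
        self._coding_mask: np.ndarray | None = None
        self._ssrs = None  # lazy cache used by the simulator

    # -- basic properties -------------------------------------------------

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def gc_fraction(self) -> float:
        if not self.seq:
            return 0.0
        return (self.seq.count("G") + self.seq.count("C")) / len(self.seq)

    @property
    def coding_mask(self) -> np.ndarray:
        """Boolean array marking positions inside any CDS."""
        if self._coding_mask is None:
            mask = np.zeros(len(self.seq), dtype=bool)
            for c in self.cds:
                mask[c.start : c.end] = True
            self._coding_mask = mask
        return self._coding_mask

    @property
    def coding_fraction(self) -> float:
        if not self.seq:
            return 0.0
        return float(self.coding_mask.sum()) / len(self.seq)

    # -- lookups ----------------------------------------------------------

    def _interval_tree(self) -> IntervalTree:
        if self._tree is None:
            self._tree = IntervalTree()
            for c in self.cds:
                self._tree.addi(c.start, c.end, c)
        return self._tree

    def cds_at(self, position: int) -> list[CDS]:
        """CDS features containing ``position`` (may be several if overlapping)."""
        if not 0 <= position < len(self.seq):
            raise CoordinateError(f"position {position} outside genome of length {len(self.seq)}")
        hits = self._interval_tree()[position]
        return sorted((iv.data for iv in hits), key=lambda c: c.start)

    def is_coding(self, position: int) -> bool:
        if not 0 <= position < len(self.seq):
            raise CoordinateError(f"position {position} outside genome of length {len(self.seq)}")
        return bool(self.coding_mask[position])

    def coding_sequence(self, cds: CDS) -> str:
        """Strand-aware coding-strand sequence of a CDS."""
        s = self.seq[cds.start : cds.end]
        return s if cds.strand == "+" else revcomp(s)


# -- on-disk formats -------------------------------------------------------


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for i, c in enumerate(genome.cds, start=1):
            cid = c.cds_id or f"cds_{i:05d}"
            fh.write(
                f"{genome.name}\tmaexp\tCDS\t{c.start + 1}\t{c.end}\t.\t{c.strand}\t0\tID={cid}\n"
            )


def read_genome(fasta_path: str | Path, gff_path: str | Path | None = None) -> AnnotatedGenome:
    """Load a reference genome (FASTA) and optional CDS annotation (GFF3)."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AnnotationError(f"no sequences in {fasta_path}")
    rec = records[0]
    cds: list[CDS] = []
    if gff_path is not None:
        import gffutils

        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        for feat in db.features_of_type("CDS"):
            if feat.seqid != rec.id:
                continue
            cds.append(
                CDS(
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand if feat.strand in "+-" else "+",
                    cds_id=feat.id or "",
                )
            )
    return AnnotatedGenome(str(rec.seq), cds, name=rec.id)
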