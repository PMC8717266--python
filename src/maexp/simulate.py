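"""Synthetic MA experiments with known ground truth.

Three stages, each deterministic under its seed:

1. ``generate_genome`` builds an annotated bacterial-style genome:
   non-overlapping CDS on both strands (start codon, stop codon, no
   internal stops under genetic-code table 11) separated by noncoding
   spacers, with perfect tandem repeats (SSRs) planted to a target
   genome fraction.  Base composition is solved so the realized GC
   fraction matches the requested one.

2. ``simulate_ma_experiment`` drops mutations onto independent lines
   under the neutral-accumulation model: per-line substitution and indel
   counts are Poisson with mean rate x N_i x T_i; substitution classes
   are drawn from the spectrum weights at sites of the required
   composition; indels are placed with an elevated probability inside
   SSR spans (replication-slippage hotspots) and insertions duplicate
   the adjacent sequence in tandem.

3. ``write_fixtures`` emits the experiment in standard formats (FASTA,
   GFF3, one VCF v4.2 per line, metadata TSV) that round-trip through
   the ingest module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import DegenerateExperimentError, InvalidSpecError
from .genome import CDS, AnnotatedGenome, STOP_CODONS, revcomp, translate_codon, write_fasta, write_gff3
from .model import DELETION, INSERTION, SUBSTITUTION, MALine
from .spectrum import CLASS_TO_CHANGE, SubstitutionClass
from .ssr import DEFAULT_MIN_COPIES, find_ssrs

__all__ = [
    "GenomeSpec",
    "ExperimentConfig",
    "TrueMutation",
    "DEFAULT_SPECTRUM_WEIGHTS",
    "default_indel_size_distribution",
    "generate_genome",
    "simulate_ma_experiment",
    "write_fixtures",
]

_BASES = "ACGT"

# Relative expected counts of the six collapsed classes.  The four
# directional classes follow the observed AT-biased spectrum of the study
# organism (40:17:10:3); the remaining transversion mass is split evenly.
DEFAULT_SPECTRUM_WEIGHTS: dict[SubstitutionClass, float] = {
    SubstitutionClass.GC_AT: 40.0,
    SubstitutionClass.AT_GC: 17.0,
    SubstitutionClass.GC_TA: 10.0,
    SubstitutionClass.AT_CG: 3.0,
    SubstitutionClass.AT_TA: 9.0,
    SubstitutionClass.GC_CG: 9.0,
}


def default_indel_size_distribution(
    p: float = 0.15, max_size: int = 50, insertion_fraction: float = 0.5
) -> dict[int, float]:
    """Truncated-geometric indel size distribution over +-1..max_size bp.

    ``p`` is the geometric parameter (mean size ~1/p, default ~6.7 bp,
    matching the observed mean small-indel sizes); insertions and
    deletions are balanced by default.
    """
    sizes = np.arange(1, max_size + 1)
    pmf = (1 - p) ** (sizes - 1) * p
    pmf = pmf / pmf.sum()
    dist = {}
    for s, q in zip(sizes, pmf):
        dist[int(s)] = insertion_fraction * float(q)
        dist[-int(s)] = (1.0 - insertion_fraction) * float(q)
    return dist


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of a synthetic annotated genome."""

    length: int = 4_130_000
    gc_content: float = 0.605
    coding_fraction: float = 0.883
    ssr_target_fraction: float = 0.0098
    seed: int = 0
    mean_gene_codons: int = 300

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise InvalidSpecError("genome length must be positive")
        for name in ("gc_content", "coding_fraction", "ssr_target_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidSpecError(f"{name}={v} outside [0, 1]")
        if self.ssr_target_fraction > 0.5:
            raise InvalidSpecError("ssr_target_fraction > 0.5 is infeasible")
        if 0 < self.coding_fraction and self.length < 6 and self.coding_fraction * self.length >= 3:
            raise InvalidSpecError("genome too short for any CDS (minimum 6 bp)")
        if self.mean_gene_codons < 10:
            raise InvalidSpecError("mean_gene_codons must be >= 10")


@dataclass(frozen=True)
class TrueMutation:
    """One planted mutation, stored in VCF-style left-anchored form."""

    line_id: str
    position: int  # 0-based offset of the first REF base
    ref: str
    alt: str
    mclass: str
    inside_ssr: bool

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.line_id, self.position, self.ref, self.alt)


@dataclass(frozen=True)
class ExperimentConfig:
    """Parameters of a simulated MA experiment.

    Defaults emulate the study conditions: 69 lines, 159 transfers of
    18.3 generations each (~2,900 generations/line), an AT-biased
    substitution spectrum at 1.22e-10 /site/generation, indels at
    4.35e-11 /site/generation with a ~64-fold rate elevation inside SSRs
    (see docs/methods.md for the derivation).
    """

    n_lines: int = 69
    transfers_per_line: int = 159
    generations_per_transfer: float = 18.3
    sub_rate: float = 1.22e-10
    indel_rate: float = 4.35e-11
    spectrum_weights: dict = field(default_factory=lambda: dict(DEFAULT_SPECTRUM_WEIGHTS))
    indel_size_distribution: dict = field(default_factory=default_indel_size_distribution)
    ssr_hotspot_multiplier: float = 64.0
    callable_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines < 1:
            raise InvalidSpecError("n_lines must be >= 1")
        if self.sub_rate < 0 or self.indel_rate < 0:
            raise InvalidSpecError("rates must be >= 0")
        if self.transfers_per_line < 0 or self.generations_per_transfer < 0:
            raise InvalidSpecError("transfers and generations must be >= 0")
        if self.ssr_hotspot_multiplier < 1:
            raise InvalidSpecError("ssr_hotspot_multiplier must be >= 1")
        if not 0.0 < self.callable_fraction <= 1.0:
            raise InvalidSpecError("callable_fraction must be in (0, 1]")
        w = dict(self.spectrum_weights)
        if any(v < 0 for v in w.values()) or not any(v > 0 for v in w.values()):
            raise InvalidSpecError("spectrum weights must be >= 0 with at least one positive")
        d = dict(self.indel_size_distribution)
        if d and (any(p < 0 for p in d.values()) or not math.isclose(sum(d.values()), 1.0, abs_tol=1e-6)):
            raise InvalidSpecError("indel size distribution must be a probability map")

    @property
    def generations(self) -> float:
        return self.transfers_per_line * self.generations_per_transfer


# -- genome generation -----------------------------------------------------


def _codon_distribution(gc: float) -> tuple[list[str], np.ndarray]:
    """Non-stop codons with sampling probabilities whose expected GC is ``gc``."""
    codons = [a + b + c for a in _BASES for b in _BASES for c in _BASES if a + b + c not in STOP_CODONS]
    gc_counts = np.array([sum(ch in "GC" for ch in c) for c in codons], dtype=float)

    def probs_for(q: float) -> np.ndarray:
        base_p = {"A": (1 - q) / 2, "T": (1 - q) / 2, "G": q / 2, "C": q / 2}
        p = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
        return p / p.sum()

    def expected_gc(q: float) -> float:
        return float(probs_for(q) @ gc_counts) / 3.0

    lo, hi = 1e-4, 1.0 - 1e-4
    target = min(max(gc, expected_gc(lo) + 1e-9), expected_gc(hi) - 1e-9)
    q = brentq(lambda x: expected_gc(x) - target, lo, hi, xtol=1e-10)
    return codons, probs_for(q)


def _sample_stop(rng: np.random.Generator, gc: float) -> str:
    stops = sorted(STOP_CODONS)  # TAA, TAG, TGA
    w = np.array([np.prod([gc / 2 if ch in "GC" else (1 - gc) / 2 for ch in s]) for s in stops])
    return stops[rng.choice(len(stops), p=w / w.sum())]


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=n, p=p)
    return "".join(_BASES[i] for i in idx)


def _plant_ssrs(
    seq: bytearray,
    cds_list: list[CDS],
    spec: GenomeSpec,
    rng: np.random.Generator,
) -> list[tuple[int, int, str]]:
    """Overwrite stretches of the assembled genome with tandem repeats.

    Planting is rolled back whenever it would introduce an internal stop
    codon into an overlapping CDS, so the annotation invariants survive.
    Returns the non-overlapping planted (start, end, motif) spans.
    """
    L = len(seq)
    target_bp = spec.ssr_target_fraction * L
    if target_bp < 1:
        return []
    cds_starts = np.array([c.start for c in cds_list], dtype=int)
    cds_ends = np.array([c.end for c in cds_list], dtype=int)

    def overlapping_cds(a: int, b: int) -> list[CDS]:
        if not cds_list:
            return []
        idx = np.flatnonzero((cds_starts < b) & (cds_ends > a))
        return [cds_list[i] for i in idx]

    def cds_clean(c: CDS) -> bool:
        s = seq[c.start : c.end].decode()
        if c.strand == "-":
            s = revcomp(s)
        if not s.startswith("ATG") or s[-3:] not in STOP_CODONS:
            return False
        aas = [translate_codon(s[i : i + 3]) for i in range(0, len(s) - 3, 3)]
        return "*" not in aas

    motif_sizes = np.arange(1, 7)
    size_probs = np.array([0.35, 0.25, 0.15, 0.10, 0.08, 0.07])
    planted: list[tuple[int, int, str]] = []
    import bisect

    p_starts: list[int] = []
    p_ends: list[int] = []
    planted_bp = 0
    attempts = 0
    max_attempts = max(200, int(40 * target_bp))
    while planted_bp < target_bp and attempts < max_attempts:
        attempts += 1
        k = int(rng.choice(motif_sizes, p=size_probs))
        copies = int(DEFAULT_MIN_COPIES[k]) + int(rng.geometric(0.5)) - 1
        span_len = k * copies
        if span_len + 24 >= L:
            continue
        motif = _random_bases(rng, k, spec.gc_content)
        # primitive motif with at least the variety a tandem array needs
        for d in range(1, k):
            if k % d == 0 and motif == motif[:d] * (k // d):
                motif = ""
                break
        if not motif:
            continue
        pos = int(rng.integers(12, L - span_len - 12))
        # keep planted spans separated so they never merge into one array
        i = bisect.bisect_left(p_ends, pos - 12)
        if i < len(p_starts) and p_starts[i] < pos + span_len + 12:
            continue
        old = bytes(seq[pos : pos + span_len])
        tile = (motif * (copies + 1))[:span_len].encode()
        seq[pos : pos + span_len] = tile
        if any(not cds_clean(c) for c in overlapping_cds(pos, pos + span_len)):
            seq[pos : pos + span_len] = old
            continue
        j = bisect.bisect_left(p_starts, pos)
        p_starts.insert(j, pos)
        p_ends.insert(j, pos + span_len)
        planted.append((pos, pos + span_len, motif))
        planted_bp += span_len
    planted.sort()
    return planted


def generate_genome(spec: GenomeSpec) -> AnnotatedGenome:
    """Build a synthetic annotated genome matching the spec's composition.

    The realized GC and coding fractions land within 0.01 of the
    requested ones; CDS lengths are multiples of 3 with ATG starts, a
    terminal stop and no internal stops; planted SSRs meet the default
    detection thresholds.  Identical seeds give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    coding_target = spec.coding_fraction * L

    # -- gene lengths (codons incl. start and stop) ------------------------
    gene_codons: list[int] = []
    tot_bp = 0
    lo = max(10, spec.mean_gene_codons // 3)
    hi = max(lo + 1, spec.mean_gene_codons * 5 // 3)
    while tot_bp < coding_target - 3:
        n = int(rng.integers(lo, hi + 1))
        if tot_bp + 3 * n > coding_target:
            n = max(2, int(round((coding_target - tot_bp) / 3)))
            if tot_bp + 3 * n > L:
                n = (L - tot_bp) // 3
            if n < 2:
                break
        gene_codons.append(n)
        tot_bp += 3 * n
    if spec.coding_fraction > 0 and not gene_codons:
        if coding_target >= 3:
            raise InvalidSpecError(
                f"coding_fraction {spec.coding_fraction} infeasible for length {L}"
            )
    n_genes = len(gene_codons)

    # -- coding sequences --------------------------------------------------
    codons, codon_p = _codon_distribution(spec.gc_content)
    codon_arr = np.array(codons)
    gene_seqs: list[str] = []
    strands: list[str] = []
    for n in gene_codons:
        body = "".join(codon_arr[rng.choice(len(codons), size=max(n - 2, 0), p=codon_p)])
        g = "ATG" + body + _sample_stop(rng, spec.gc_content)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_seqs.append(g if strand == "+" else revcomp(g))
        strands.append(strand)
    coding_bp = sum(len(g) for g in gene_seqs)
    spacer_bp = L - coding_bp
    if spacer_bp < 0:
        raise InvalidSpecError("coding sequence exceeds genome length")

    # -- spacers: GC solved so the whole genome hits the target ------------
    gc_coding = sum(g.count("G") + g.count("C") for g in gene_seqs)
    if spacer_bp > 0:
        q_nc = (spec.gc_content * L - gc_coding) / spacer_bp
        q_nc = min(max(q_nc, 0.0), 1.0)
        gaps = rng.multinomial(spacer_bp, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    else:
        q_nc = spec.gc_content
        gaps = np.zeros(n_genes + 1, dtype=int)

    parts: list[str] = []
    cds_list: list[CDS] = []
    cursor = 0
    for i, g in enumerate(gene_seqs):
        sp = _random_bases(rng, int(gaps[i]), q_nc)
        parts.append(sp)
        cursor += len(sp)
        cds_list.append(CDS(start=cursor, end=cursor + len(g), strand=strands[i], cds_id=f"cds_{i + 1:05d}"))
        parts.append(g)
        cursor += len(g)
    parts.append(_random_bases(rng, int(gaps[n_genes]), q_nc))
    seq = bytearray("".join(parts).encode())
    assert len(seq) == L

    planted = _plant_ssrs(seq, cds_list, spec, rng)
    genome = AnnotatedGenome(seq.decode(), cds_list, name="synthetic")
    genome.planted_ssrs = planted
    return genome


# -- MA simulation ---------------------------------------------------------


def _genome_ssrs(genome: AnnotatedGenome) -> list:
    if genome._ssrs is None:
        genome._ssrs = find_ssrs(genome)
    return genome._ssrs


def simulate_ma_experiment(
    genome: AnnotatedGenome, config: ExperimentConfig
) -> tuple[dict[str, list[TrueMutation]], list[MALine]]:
    """Simulate neutral mutation accumulation over independent MA lines.

    Returns the ground-truth mutation set (``line_id -> sorted
    mutations``) and the per-line metadata.  Per-line counts are
    Poisson(rate x N_i x T_i); at most one mutation per site per line.
    """
    L = genome.length
    if L == 0:
        raise DegenerateExperimentError("empty genome")
    N = int(round(config.callable_fraction * L))
    if N == 0:
        raise DegenerateExperimentError("zero callable sites")
    T = config.generations
    rng = np.random.default_rng(config.seed)

    arr = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    gc_pos = np.flatnonzero(is_gc)
    at_pos = np.flatnonzero(~is_gc)

    classes = [c for c in SubstitutionClass if config.spectrum_weights.get(c, 0.0) > 0]
    class_w = np.array([config.spectrum_weights[c] for c in classes], dtype=float)
    class_p = class_w / class_w.sum()

    ssrs = _genome_ssrs(genome)
    ssr_starts = np.array([s.start for s in ssrs], dtype=int)
    ssr_ends = np.array([s.end for s in ssrs], dtype=int)
    ssr_lens = ssr_ends - ssr_starts
    S = int(ssr_lens.sum())
    k_hot = config.ssr_hotspot_multiplier
    p_in_ssr = (k_hot * S) / ((L - S) + k_hot * S) if S > 0 else 0.0

    def in_ssr_point(p: int) -> bool:
        if ssr_starts.size == 0:
            return False
        i = np.searchsorted(ssr_ends, p, side="right")
        return i < ssr_starts.size and ssr_starts[i] <= p < ssr_ends[i]

    sizes = sorted(config.indel_size_distribution)
    size_p = np.array([config.indel_size_distribution[s] for s in sizes], dtype=float)
    if size_p.size:
        size_p = size_p / size_p.sum()

    truth: dict[str, list[TrueMutation]] = {}
    lines: list[MALine] = []
    exposure = float(N) * T
    for i in range(config.n_lines):
        lid = f"MA{i + 1:03d}"
        used: set[int] = set()
        muts: list[TrueMutation] = []

        n_sub = rng.poisson(config.sub_rate * exposure) if config.sub_rate > 0 else 0
        for _ in range(n_sub):
            for _try in range(1000):
                cls = classes[rng.choice(len(classes), p=class_p)]
                pool = gc_pos if cls.from_gc else at_pos
                if pool.size == 0:
                    continue
                pos = int(pool[rng.integers(pool.size)])
                if pos in used:
                    continue
                ref = genome.seq[pos]
                alt = CLASS_TO_CHANGE[cls][ref]
                muts.append(TrueMutation(lid, pos, ref, alt, SUBSTITUTION, in_ssr_point(pos)))
                used.add(pos)
                break

        n_indel = rng.poisson(config.indel_rate * exposure) if config.indel_rate > 0 and size_p.size else 0
        for _ in range(n_indel):
            for _try in range(1000):
                size = sizes[rng.choice(len(sizes), p=size_p)]
                d = abs(size)
                if rng.random() < p_in_ssr:
                    j = rng.choice(ssr_lens.size, p=ssr_lens / ssr_lens.sum())
                    pos = int(rng.integers(ssr_starts[j], ssr_ends[j]))
                else:
                    pos = int(rng.integers(1, L - d))
                    if in_ssr_point(pos):
                        continue
                if pos < 1 or pos + d > L:
                    continue
                span = range(pos - 1, pos + d + 1)
                if any(p in used for p in span):
                    continue
                anchor = genome.seq[pos - 1]
                if size > 0:  # tandem duplication of the adjacent d bases
                    ref = anchor
                    alt = anchor + genome.seq[pos : pos + d]
                    mclass = INSERTION
                else:
                    ref = anchor + genome.seq[pos : pos + d]
                    alt = anchor
                    mclass = DELETION
                muts.append(TrueMutation(lid, pos - 1, ref, alt, mclass, in_ssr_point(pos)))
                used.update(span)
                break

        truth[lid] = sorted(muts, key=lambda m: m.position)
        lines.append(
            MALine(line_id=lid, transfers=config.transfers_per_line, generations=T, callable_sites=N)
        )
    return truth, lines


# -- fixture emission ------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=maexp-simulator
##contig=<ID={contig},length={length}>
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_fixtures(
    genome: AnnotatedGenome,
    truth: dict[str, list[TrueMutation]],
    lines: list[MALine],
    out_dir: str | Path,
    qual: float = 1000.0,
    mq: float = 60.0,
    depth: int = 100,
) -> dict[str, Path]:
    """Write FASTA + GFF3 + per-line VCFs + metadata TSV for an experiment.

    CFU in the metadata is ``round(2^g)`` for g generations per transfer,
    so that ``log2(CFU) * transfers`` recovers the line's generations.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "genome.fasta"
    gff = out / "annotation.gff3"
    meta = out / "lines.tsv"
    vcf_dir = out / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    write_fasta(genome, fasta)
    write_gff3(genome, gff)

    with open(meta, "w") as fh:
        fh.write("line_id\ttransfers\tcfu\tcallable_sites\n")
        for line in lines:
            g_per_transfer = line.generations / line.transfers if line.transfers else 0.0
            cfu = int(round(2.0 ** g_per_transfer))
            fh.write(f"{line.line_id}\t{line.transfers}\t{cfu}\t{line.callable_sites}\n")

    paths: dict[str, Path] = {"fasta": fasta, "gff": gff, "metadata": meta}
    for line in lines:
        vp = vcf_dir / f"{line.line_id}.vcf"
        with open(vp, "w") as fh:
            fh.write(
                _VCF_HEADER.format(contig=genome.name, length=genome.length, sample=line.line_id)
            )
            for m in sorted(truth.get(line.line_id, []), key=lambda m: m.position):
                alt_depth = depth
                fh.write(
                    f"{genome.name}\t{m.position + 1}\t.\t{m.ref}\t{m.alt}\t{qual:.0f}\tPASS\t"
                    f"MQ={mq:.2f}\tGT:AD:DP\t1:0,{alt_depth}:{alt_depth}\n"
                )
        paths[line.line_id] = vp
    return paths
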