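"""Call-set ingestion, site/consensus filtering and caller reconciliation.

The filter cascade mirrors standard MA-pipeline practice: hard site
filters on Phred quality and RMS mapping quality (strict inequalities;
boundary values are excluded), a line-consensus filter requiring more
than 99% of reads to carry the alternate allele (a fixed mutation in a
clonal line should be near-homogeneous; the 1% allowance absorbs
aberrant reads), and removal of any variant shared by two or more lines
(shared variants are ancestral polymorphism or systematic artifacts, not
independent spontaneous mutations).
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd

from .errors import CallSetParseError, CoordinateError, MissingMetadataError
from .model import MALine, MutationCall
from .rates import generations_from_cfu

__all__ = [
    "read_callsets",
    "apply_site_filters",
    "apply_consensus_filter",
    "remove_shared_mutations",
    "reconcile_callers",
    "left_normalize",
    "ConcordanceReport",
    "DEFAULT_MIN_QUAL",
    "DEFAULT_MIN_MQ",
    "DEFAULT_MIN_CONSENSUS",
]

DEFAULT_MIN_QUAL = 100.0
DEFAULT_MIN_MQ = 59.0
DEFAULT_MIN_CONSENSUS = 0.99


def _read_metadata(metadata_path: str | Path) -> dict[str, MALine]:
    df = pd.read_csv(metadata_path, sep="\t", dtype={"line_id": str})
    required = {"line_id", "transfers", "callable_sites"}
    missing = required - set(df.columns)
    if missing:
        raise CallSetParseError(f"metadata {metadata_path} lacks columns {sorted(missing)}")
    out: dict[str, MALine] = {}
    for row in df.itertuples(index=False):
        transfers = int(row.transfers)
        if "generations" in df.columns and not pd.isna(getattr(row, "generations")):
            generations = float(getattr(row, "generations"))
        elif "cfu" in df.columns and not pd.isna(getattr(row, "cfu")):
            generations = transfers * generations_from_cfu(float(getattr(row, "cfu")))
        else:
            raise CallSetParseError(
                f"metadata {metadata_path}: line {row.line_id} has neither "
                "a generations nor a cfu column"
            )
        out[str(row.line_id)] = MALine(
            line_id=str(row.line_id),
            transfers=transfers,
            generations=generations,
            callable_sites=int(row.callable_sites),
        )
    return out


def read_callsets(
    vcf_paths: list[str | Path],
    metadata_path: str | Path,
    caller: str = "A",
) -> tuple[list[MutationCall], list[MALine]]:
    """Read per-line VCFs and the line-metadata TSV.

    The line id of each VCF is its file stem and must appear in the
    metadata.  Generations are taken from a ``generations`` column when
    present, otherwise computed as ``transfers * log2(cfu)``.
    Multi-allelic records are split into one call per ALT.
    """
    from cyvcf2 import VCF

    meta = _read_metadata(metadata_path)
    calls: list[MutationCall] = []
    for path in sorted(Path(p) for p in vcf_paths):
        line_id = path.stem
        if line_id not in meta:
            raise MissingMetadataError(
                f"VCF {path} has no metadata row for line {line_id!r}"
            )
        try:
            vcf = VCF(str(path))
        except Exception as exc:  # htslib raises bare OSError subclasses
            raise CallSetParseError(f"cannot open {path}: {exc}") from exc
        for variant in vcf:
            mq = variant.INFO.get("MQ")
            qual = variant.QUAL
            ad = variant.format("AD")
            for alt_idx, alt in enumerate(variant.ALT):
                if ad is not None and ad.size >= 2 + alt_idx:
                    row = ad[0]
                    total = float(sum(x for x in row if x >= 0))
                    af = float(row[1 + alt_idx]) / total if total > 0 else 1.0
                else:
                    af = float(variant.INFO.get("AF", 1.0))
                try:
                    calls.append(
                        MutationCall(
                            line_id=line_id,
                            position=variant.POS - 1,
                            ref=variant.REF.upper(),
                            alt=str(alt).upper(),
                            qual=float(qual) if qual is not None else None,
                            mq=float(mq) if mq is not None else None,
                            allele_fraction=min(max(af, 0.0), 1.0),
                            caller=caller,
                        )
                    )
                except ValueError as exc:
                    raise CallSetParseError(
                        f"{path}: bad record at POS {variant.POS}: {exc}"
                    ) from exc
    return calls, [meta[k] for k in sorted(meta)]


def apply_site_filters(
    calls: list[MutationCall],
    min_qual: float = DEFAULT_MIN_QUAL,
    min_mq: float = DEFAULT_MIN_MQ,
) -> list[MutationCall]:
    """Keep calls with QUAL > min_qual and MQ > min_mq (strict; missing fails)."""
    if min_qual < 0 or min_mq < 0:
        raise ValueError("thresholds must be >= 0")
    return [
        c
        for c in calls
        if c.qual is not None and c.qual > min_qual and c.mq is not None and c.mq > min_mq
    ]


def apply_consensus_filter(
    calls: list[MutationCall], min_fraction: float = DEFAULT_MIN_CONSENSUS
) -> list[MutationCall]:
    """Keep calls whose allele fraction exceeds the line-consensus threshold."""
    if not 0.0 <= min_fraction <= 1.0:
        raise ValueError(f"min_fraction {min_fraction} outside [0, 1]")
    return [c for c in calls if c.allele_fraction > min_fraction]


def remove_shared_mutations(calls: list[MutationCall]) -> list[MutationCall]:
    """Drop any (position, ref, alt) triple observed in two or more lines."""
    lines_by_triple: dict[tuple, set[str]] = defaultdict(set)
    for c in calls:
        lines_by_triple[(c.position, c.ref, c.alt)].add(c.line_id)
    return [c for c in calls if len(lines_by_triple[(c.position, c.ref, c.alt)]) == 1]


def left_normalize(
    position: int, ref: str, alt: str, seq: str | None = None
) -> tuple[int, str, str]:
    """Shift an allele pair to its smallest coordinate representation.

    Standard VCF normalization: shared trailing bases are trimmed
    (extending left through the reference when an allele would become
    empty), then shared leading bases are trimmed.  Without a reference
    sequence only the trimming steps are applied.
    """
    ref, alt = ref.upper(), alt.upper()
    if not ref or not alt:
        raise ValueError("empty allele")
    changed = True
    while changed:
        changed = False
        if ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            trimmed_ref, trimmed_alt = ref[:-1], alt[:-1]
            if not trimmed_ref or not trimmed_alt:
                if seq is None:
                    break  # anchored form cannot shift without a reference
                if position == 0:
                    raise CoordinateError("cannot left-extend past the genome start")
                base = seq[position - 1]
                ref, alt = base + trimmed_ref, base + trimmed_alt
                position -= 1
            else:
                ref, alt = trimmed_ref, trimmed_alt
            changed = True
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        position += 1
    return position, ref, alt


def normalize_call(call: MutationCall, seq: str | None = None) -> MutationCall:
    pos, ref, alt = left_normalize(call.position, call.ref, call.alt, seq)
    if (pos, ref, alt) == (call.position, call.ref, call.alt):
        return call
    return replace(call, position=pos, ref=ref, alt=alt)


@dataclass(frozen=True)
class ConcordanceReport:
    """Agreement between two independent callers on the same lines."""

    n_a: int
    n_b: int
    n_shared: int
    fraction_b_in_a: float


def reconcile_callers(
    calls_a: list[MutationCall],
    calls_b: list[MutationCall],
    seq: str | None = None,
    policy: str = "primary",
) -> tuple[ConcordanceReport, list[MutationCall]]:
    """Compare two call sets and merge them under a configurable policy.

    Matching is on (line, position, ref, alt) after left-normalization.
    Policies: ``primary`` keeps all caller-A calls (marking shared ones
    ``both``), ``intersection`` keeps only shared calls, ``union``
    additionally appends B-only calls.
    """
    if policy not in ("primary", "intersection", "union"):
        raise ValueError(f"unknown merge policy {policy!r}")
    norm_a = [normalize_call(c, seq) for c in calls_a]
    norm_b = [normalize_call(c, seq) for c in calls_b]
    keys_a = {(c.line_id, c.position, c.ref, c.alt) for c in norm_a}
    keys_b = {(c.line_id, c.position, c.ref, c.alt) for c in norm_b}
    shared = keys_a & keys_b
    frac = len(shared) / len(keys_b) if keys_b else 0.0
    report = ConcordanceReport(
        n_a=len(keys_a), n_b=len(keys_b), n_shared=len(shared), fraction_b_in_a=frac
    )

    def tag(c: MutationCall) -> MutationCall:
        in_both = (c.line_id, c.position, c.ref, c.alt) in shared
        return replace(c, caller="both" if in_both else c.caller)

    merged: list[MutationCall]
    if policy == "primary":
        merged = [tag(c) for c in norm_a]
    elif policy == "intersection":
        merged = [tag(c) for c in norm_a if (c.line_id, c.position, c.ref, c.alt) in shared]
    else:  # union
        merged = [tag(c) for c in norm_a]
        merged.extend(
            c for c in norm_b if (c.line_id, c.position, c.ref, c.alt) not in keys_a
        )
    return report, merged
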