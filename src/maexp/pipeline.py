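"""End-to-end orchestration: ingest -> rates -> spectrum -> indels/SSRs.

Every filtering decision is logged to a machine-readable audit table
(stage, calls in, calls out, calls removed) so the cascade is traceable,
and all reports are emitted as TSV plus a plain-text summary.
"""

from __future__ import annotations

import glob as globmod
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import ingest
from .errors import MAExpError
from .genome import AnnotatedGenome, read_genome
from .indels import IndelSummary, indel_region_analysis
from .model import SUBSTITUTION, MALine, MutationCall
from .rates import (
    RateEstimate,
    conditional_rates,
    equilibrium_gc,
    per_genome_rate,
    pooled_rate,
    site_generations,
)
from .spectrum import (
    SubstitutionClass,
    classify_coding_effect,
    count_spectrum,
    expected_ns_ratio,
    ns_ratio_test,
    partition_by_annotation,
    titv_ratio,
)
from .ssr import DEFAULT_MIN_COPIES, find_ssrs, ssr_genome_fraction, write_bed

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "render_summary"]


@dataclass
class PipelineConfig:
    """Paths and thresholds driving one analysis run."""

    genome_fasta: str
    annotation_gff: str
    vcf: str | list[str]
    metadata: str
    out_dir: str
    secondary_vcf: str | list[str] | None = None
    min_qual: float = ingest.DEFAULT_MIN_QUAL
    min_mq: float = ingest.DEFAULT_MIN_MQ
    min_consensus: float = ingest.DEFAULT_MIN_CONSENSUS
    confidence: float = 0.95
    ti_weight_factor: float = 2.0
    ssr_min_copies: dict = field(default_factory=lambda: dict(DEFAULT_MIN_COPIES))
    merge_policy: str = "primary"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genome_fasta", "annotation_gff", "metadata"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise MAExpError(f"{name} does not exist: {p}")
        if not 0.0 < self.confidence < 1.0:
            raise MAExpError(f"confidence {self.confidence} outside (0, 1)")
        if self.merge_policy not in ("primary", "intersection", "union"):
            raise MAExpError(f"unknown merge policy {self.merge_policy!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if "ssr_min_copies" in raw and raw["ssr_min_copies"]:
            raw["ssr_min_copies"] = {int(k): float(v) for k, v in raw["ssr_min_copies"].items()}
        base = Path(path).parent
        for key in ("genome_fasta", "annotation_gff", "metadata", "out_dir"):
            if key in raw and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        for key in ("vcf", "secondary_vcf"):
            if key in raw and isinstance(raw[key], str) and not Path(raw[key]).is_absolute():
                raw[key] = str(base / raw[key])
        return cls(**raw)

    def resolve_vcfs(self, which: str = "primary") -> list[str]:
        src = self.vcf if which == "primary" else self.secondary_vcf
        if src is None:
            return []
        if isinstance(src, str):
            paths = sorted(globmod.glob(src))
            if not paths:
                raise MAExpError(f"no VCFs match {src!r}")
            return paths
        return [str(p) for p in src]


@dataclass
class ReportBundle:
    """All tables produced by one pipeline run."""

    rates: pd.DataFrame
    spectrum: pd.DataFrame
    effects: pd.DataFrame
    indels: pd.DataFrame
    ssr_fraction: float
    n_ssrs: int
    audit: pd.DataFrame
    concordance: pd.DataFrame | None = None
    summary: str = ""


def _audit_row(rows: list, stage: str, n_in: int, n_out: int) -> None:
    rows.append({"stage": stage, "n_in": n_in, "n_out": n_out, "n_removed": n_in - n_out})


def _rate_row(category: str, est: RateEstimate | None) -> dict:
    if est is None:
        return {"category": category, "m": 0, "denominator": float("nan"), "mu": float("nan"),
                "ci_low": float("nan"), "ci_high": float("nan"), "sem": float("nan")}
    return {
        "category": category,
        "m": est.m,
        "denominator": est.denominator,
        "mu": est.mu,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "sem": est.sem if est.sem is not None else float("nan"),
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full analysis and write all reports under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    audit_rows: list[dict] = []
    level = config.confidence

    genome = read_genome(config.genome_fasta, config.annotation_gff)

    calls, lines = ingest.read_callsets(config.resolve_vcfs("primary"), config.metadata, caller="A")
    _audit_row(audit_rows, "ingest", len(calls), len(calls))

    concordance_df = None
    if config.secondary_vcf:
        calls_b, _ = ingest.read_callsets(
            config.resolve_vcfs("secondary"), config.metadata, caller="B"
        )
        report, merged = ingest.reconcile_callers(
            calls, calls_b, seq=genome.seq, policy=config.merge_policy
        )
        concordance_df = pd.DataFrame(
            [
                {"caller": "A", "n_calls": report.n_a, "n_shared": report.n_shared,
                 "fraction_shared": report.n_shared / report.n_a if report.n_a else 0.0},
                {"caller": "B", "n_calls": report.n_b, "n_shared": report.n_shared,
                 "fraction_shared": report.fraction_b_in_a},
            ]
        )
        _audit_row(audit_rows, f"reconcile[{config.merge_policy}]", len(calls), len(merged))
        calls = merged

    filtered = ingest.apply_site_filters(calls, config.min_qual, config.min_mq)
    _audit_row(audit_rows, "site_filters", len(calls), len(filtered))
    consensus = ingest.apply_consensus_filter(filtered, config.min_consensus)
    _audit_row(audit_rows, "consensus_filter", len(filtered), len(consensus))
    unique = ingest.remove_shared_mutations(consensus)
    _audit_row(audit_rows, "unique_filter", len(consensus), len(unique))

    subs = [c for c in unique if c.mclass == SUBSTITUTION]
    indel_calls = [c for c in unique if c.mclass != SUBSTITUTION]
    _audit_row(audit_rows, "class_split[substitution]", len(unique), len(subs))
    _audit_row(audit_rows, "class_split[indel]", len(unique), len(indel_calls))

    denom = site_generations(lines)
    n_lines = len(lines)
    mean_generations = (
        sum(l.generations for l in lines) / n_lines if n_lines else float("nan")
    )

    def per_line_counts(cs: list[MutationCall]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in cs:
            counts[c.line_id] = counts.get(c.line_id, 0) + 1
        return counts

    sub_rate = pooled_rate(per_line_counts(subs), lines, level)
    indel_rate = pooled_rate(per_line_counts(indel_calls), lines, level)

    # -- spectrum ---------------------------------------------------------
    class_counts = count_spectrum(subs)
    titv = titv_ratio(subs) if subs else float("nan")
    region = partition_by_annotation(subs, genome, denominator=denom, level=level)
    to_at = class_counts[SubstitutionClass.GC_AT] + class_counts[SubstitutionClass.GC_TA]
    to_gc = class_counts[SubstitutionClass.AT_GC] + class_counts[SubstitutionClass.AT_CG]
    gc_frac = genome.gc_fraction
    if 0.0 < gc_frac < 1.0 and denom > 0:
        cond = conditional_rates(to_at, to_gc, gc_frac, denom)
        eq_gc = (
            equilibrium_gc(cond.mu_at_to_gc, cond.mu_gc_to_at)
            if (to_at + to_gc) > 0
            else float("nan")
        )
    else:
        cond = None
        eq_gc = float("nan")

    spectrum_rows = []
    for cls, n in class_counts.items():
        est = pooled_rate(n, lines, level) if denom > 0 else None
        row = _rate_row(cls.value, est)
        row["kind"] = cls.kind
        spectrum_rows.append(row)
    spectrum_df = pd.DataFrame(spectrum_rows)

    # -- coding effects ---------------------------------------------------
    n_syn = n_nonsyn = 0
    for c in region.coding_calls:
        if classify_coding_effect(c, genome) == "synonymous":
            n_syn += 1
        else:
            n_nonsyn += 1
    observed_ratio = n_nonsyn / n_syn if n_syn else float("inf")
    if genome.cds and math.isfinite(titv) and titv > 0:
        exp_ratio = expected_ns_ratio(genome, titv, config.ti_weight_factor)
    else:
        exp_ratio = float("nan")
    if (n_syn + n_nonsyn) > 0 and math.isfinite(exp_ratio) and exp_ratio > 0:
        chi2_stat, chi2_df, chi2_p = ns_ratio_test(n_nonsyn, n_syn, exp_ratio)
    else:
        chi2_stat, chi2_df, chi2_p = float("nan"), 1, float("nan")
    effects_df = pd.DataFrame(
        [
            {
                "n_synonymous": n_syn,
                "n_nonsynonymous": n_nonsyn,
                "observed_ratio": observed_ratio,
                "expected_ratio": exp_ratio,
                "chi2": chi2_stat,
                "df": chi2_df,
                "p": chi2_p,
            }
        ]
    )

    # -- SSRs and indels --------------------------------------------------
    ssrs = find_ssrs(genome, config.ssr_min_copies)
    ssr_frac = ssr_genome_fraction(ssrs, genome.length)
    indel_summary = indel_region_analysis(indel_calls, genome, ssrs, denominator=denom, level=level)

    ins_counts = per_line_counts([c for c in indel_calls if c.mclass == "insertion"])
    del_counts = per_line_counts([c for c in indel_calls if c.mclass == "deletion"])
    rates_df = pd.DataFrame(
        [
            _rate_row("substitution", sub_rate),
            _rate_row("indel", indel_rate),
            _rate_row("insertion", pooled_rate(ins_counts, lines, level)),
            _rate_row("deletion", pooled_rate(del_counts, lines, level)),
            _rate_row("substitution_coding", region.coding_rate),
            _rate_row("substitution_noncoding", region.noncoding_rate),
            {
                "category": "mu_GC_to_AT",
                "m": to_at,
                "denominator": gc_frac * denom,
                "mu": cond.mu_gc_to_at if cond else float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "sem": float("nan"),
            },
            {
                "category": "mu_AT_to_GC",
                "m": to_gc,
                "denominator": (1 - gc_frac) * denom,
                "mu": cond.mu_at_to_gc if cond else float("nan"),
                "ci_low": float("nan"),
                "ci_high": float("nan"),
                "sem": float("nan"),
            },
        ]
    )

    indel_rows = []
    for c in indel_calls:
        from .indels import affected_span, _overlaps_ssr, _in_coding

        indel_rows.append(
            {
                "line_id": c.line_id,
                "position": c.position,
                "size": abs(c.size),
                "sign": "+" if c.size > 0 else "-",
                "region": "coding" if _in_coding(c, genome) else "noncoding",
                "in_ssr": _overlaps_ssr(c, ssrs),
            }
        )
    indels_df = pd.DataFrame(
        indel_rows,
        columns=["line_id", "position", "size", "sign", "region", "in_ssr"],
    )

    audit_df = pd.DataFrame(audit_rows)
    bundle = ReportBundle(
        rates=rates_df,
        spectrum=spectrum_df,
        effects=effects_df,
        indels=indels_df,
        ssr_fraction=ssr_frac,
        n_ssrs=len(ssrs),
        audit=audit_df,
        concordance=concordance_df,
    )
    bundle.summary = render_summary(
        bundle,
        extra={
            "lines": n_lines,
            "mean_generations": mean_generations,
            "site_generations": denom,
            "genome_gc": gc_frac,
            "coding_fraction": genome.coding_fraction,
            "titv": titv,
            "equilibrium_gc": eq_gc,
            "per_genome_rate": (
                per_genome_rate(sub_rate.m, n_lines, mean_generations)
                if n_lines and mean_generations > 0
                else float("nan")
            ),
            "indel_summary": indel_summary,
            "n_coding": region.n_coding,
            "n_noncoding": region.n_noncoding,
            "fisher_p": region.fisher_p,
        },
    )

    rates_df.to_csv(out / "rates.tsv", sep="\t", index=False)
    spectrum_df.to_csv(out / "spectrum.tsv", sep="\t", index=False)
    effects_df.to_csv(out / "effects.tsv", sep="\t", index=False)
    indels_df.to_csv(out / "indels.tsv", sep="\t", index=False)
    audit_df.to_csv(out / "audit.tsv", sep="\t", index=False)
    if concordance_df is not None:
        concordance_df.to_csv(out / "concordance.tsv", sep="\t", index=False)
    write_bed(ssrs, out / "ssrs.bed", name=genome.name)
    (out / "summary.txt").write_text(bundle.summary)
    return bundle


def render_summary(bundle: ReportBundle, extra: dict | None = None) -> str:
    """Human-readable roll-up of every analysis table."""
    x = extra or {}
    lines_out: list[str] = []
    a = lines_out.append
    a("MA experiment analysis summary")
    a("=" * 34)
    if x:
        a(f"lines: {x.get('lines', 'NA')}   mean generations/line: {x.get('mean_generations', float('nan')):.1f}")
        a(f"site-generations: {x.get('site_generations', float('nan')):.4g}")
        a(f"genome GC: {x.get('genome_gc', float('nan')):.4f}   coding fraction: {x.get('coding_fraction', float('nan')):.4f}")
    a("")
    a("Rates (per site per generation)")
    a("-" * 34)
    for row in bundle.rates.itertuples(index=False):
        sem = f"  sem={row.sem:.3g}" if row.sem == row.sem else ""
        ci = (
            f"  95%CI [{row.ci_low:.3g}, {row.ci_high:.3g}]"
            if row.ci_low == row.ci_low
            else ""
        )
        a(f"{row.category:<24} m={row.m:<5} mu={row.mu:.4g}{ci}{sem}")
    if "per_genome_rate" in x:
        a(f"{'substitution_per_genome':<24} {x['per_genome_rate']:.4g} per genome per generation")
    a("")
    a("Substitution spectrum")
    a("-" * 34)
    for row in bundle.spectrum.itertuples(index=False):
        a(f"{row.category:<10} ({row.kind:<12}) n={row.m:<5} mu={row.mu:.4g}")
    if "titv" in x:
        a(f"ts/tv ratio: {x['titv']:.3f}")
    if "equilibrium_gc" in x:
        a(f"equilibrium GC content: {100 * x['equilibrium_gc']:.1f}%")
    if "n_coding" in x:
        a(
            f"coding/noncoding substitutions: {x['n_coding']}/{x['n_noncoding']}"
            + (
                f"   Fisher p = {x['fisher_p']:.3g}"
                if x.get("fisher_p") is not None
                else ""
            )
        )
    a("")
    a("Coding effects (NS:S)")
    a("-" * 34)
    for row in bundle.effects.itertuples(index=False):
        a(
            f"synonymous={row.n_synonymous}  nonsynonymous={row.n_nonsynonymous}  "
            f"observed={row.observed_ratio:.3f}  expected={row.expected_ratio:.3f}  "
            f"chi2={row.chi2:.3f} (df={row.df}, p={row.p:.3g})"
        )
    a("")
    a("Indels and SSRs")
    a("-" * 34)
    isum: IndelSummary | None = x.get("indel_summary")
    if isum is not None:
        a(
            f"insertions={isum.n_insertions} ({isum.bp_inserted} bp)  "
            f"deletions={isum.n_deletions} ({isum.bp_deleted} bp)  net={isum.net_bp:+d} bp"
        )
        if isum.n_total:
            a(
                f"in SSRs: {isum.n_in_ssr}/{isum.n_total} "
                f"({100 * (isum.ssr_fraction or 0):.1f}%)"
            )
            a(
                f"coding indels: observed {isum.n_coding}, expected "
                f"{isum.expected_coding:.1f}"
                + (
                    f"   Fisher p = {isum.coding_fisher_p:.3g}"
                    if isum.coding_fisher_p is not None
                    else ""
                )
            )
    a(f"SSR loci: {bundle.n_ssrs}   genome coverage: {100 * bundle.ssr_fraction:.2f}%")
    if bundle.concordance is not None:
        a("")
        a("Caller concordance")
        a("-" * 34)
        for row in bundle.concordance.itertuples(index=False):
            a(
                f"caller {row.caller}: {row.n_calls} calls, {row.n_shared} shared "
                f"({100 * row.fraction_shared:.1f}%)"
            )
    a("")
    a("Filter audit")
    a("-" * 34)
    for row in bundle.audit.itertuples(index=False):
        a(f"{row.stage:<28} in={row.n_in:<6} out={row.n_out:<6} removed={row.n_removed}")
    return "\n".join(lines_out) + "\n"
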