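# Methods

## The measurement model

A mutation-accumulation (MA) experiment propagates independent lineages
through repeated single-colony bottlenecks. Because every transfer passes
the line through an effective population size near one, selection is
essentially powerless and non-lethal spontaneous mutations fix at the
rate they arise. After *T* generations, sequencing each line against the
ancestor and counting fixed mutations *m* over the callable portion *N*
of the genome yields the rate per site per generation.

`maexp` treats each line *i* as contributing an exposure of `Nᵢ·Tᵢ`
site-generations. Generations per transfer are estimated from colony
size at transfer: a colony founded by a single cell that divided *g*
times contains `2^g` cells, so `g = log₂(CFU)`; a line's total is
`transfers × mean g`. Mutation counts are modeled as Poisson over the
summed exposure.

### Estimators

- Pooled rate: `μ = m / Σᵢ Nᵢ·Tᵢ`.
- Exact (Garwood) Poisson CI from χ² quantiles:
  `low = ½·χ²(α/2, 2m)/D`, `high = ½·χ²(1−α/2, 2m+2)/D`, with the
  `m = 0` lower bound defined as 0. This is algebraically identical to
  numerically inverting the Poisson CDF; the test suite checks the two
  routes agree to better than 4 significant figures for counts 1–200.
- SEM: standard deviation (n−1 denominator) of the per-line rates
  `mᵢ/(Nᵢ·Tᵢ)` divided by √n. Lines with zero events contribute zeros.
- Per-genome rate: `m / (n_lines × mean generations)`. Note this is one
  of two near-equivalent conventions (the other being `μ ×` mean
  callable sites); both agree to within the rounding of the inputs, and
  the function implements the count-based form.
- Conditional directional rates divide the pooled denominator by the
  genome-wide GC fraction: `μ_{G/C→A/T} = m_{→AT} / (f_GC · D)` and
  symmetrically for `μ_{A/T→G/C}`. Using the genome-wide composition for
  the callable fraction is an approximation; per-line callable
  composition is not usually reported.
- Equilibrium GC content: `μ_{A/T→G/C} / (μ_{G/C→A/T} + μ_{A/T→G/C})`.
  Scale-invariant, so composition-normalized counts may be passed
  directly.

## Filter cascade

Site filters keep calls with `QUAL > 100` and `MQ > 59` — strict
inequalities, so boundary values are excluded. The consensus filter
keeps calls with allele fraction `> 0.99`: a fixed mutation in a clonal
line should be carried by essentially all reads, and the 1% allowance
absorbs sequencing errors and index contamination. The uniqueness filter
removes any `(position, ref, alt)` triple observed in two or more lines;
identical variants in independent lines are ancestral polymorphism or
systematic calling artifacts, not independent mutations. Distinct ALT
alleles at the same position in different lines are distinct triples and
are kept. All three filters are per-call predicates (idempotent,
order-independent for the first two), and the pipeline logs in/out
counts at each stage.

Two-caller reconciliation matches calls on `(line, position, ref, alt)`
after left-normalization (trailing/leading trimming with leftward
extension through the reference), since callers emit indels in different
anchored representations. The default merge policy keeps the primary
caller's set and marks concordant calls; `intersection` and `union` are
available.

## Coding effects and the expected NS:S ratio

Effects are computed by mutating the codon containing the site
(reverse-complemented for minus-strand CDS) and translating with the
bacterial/archaeal genetic code (NCBI table 11; the organism class this
package targets is bacterial and no experiment we model states
otherwise). Stop-gains count as nonsynonymous; changes within an
annotated stop codon that preserve a stop are synonymous. For positions
inside overlapping CDS annotations the call is counted once,
nonsynonymous if nonsynonymous in any frame (configurable).

The neutral expectation enumerates all `3L` single-base changes over
every CDS — codon usage enters through the actual coding sequence — and
weights each change by its mutational accessibility. With an observed
transition:transversion *count* ratio R, and each site offering one
transition and two transversions, per-change weights satisfying
`w_ti/w_tv = 2R` reproduce R in aggregate; the factor 2 is exposed as
`ti_weight_factor` since other conventions exist. The χ² goodness-of-fit
test compares observed (NS, S) counts to proportions `(r/(1+r), 1/(1+r))`
at 1 df without continuity correction.

## SSR detection and indel context

An SSR is a maximal perfect tandem repeat of a primitive 1–6 bp motif.
Detection scans, for each period *k*, maximal runs of
`seq[x] == seq[x+k]`; a run over `[a, b)` covers the span `[a, b+k)`
with `(b−a+k)/k` copies (fractional final units allowed). Candidates
must meet per-motif-size minimum copies — defaults mono ≥ 8, di ≥ 5,
tri ≥ 4, tetra/penta/hexa ≥ 3 — and overlapping candidates of different
periods are resolved longest-first (ties: smaller motif, then leftmost).
The defaults were chosen so a ~60% GC genome carries about 1% SSR
coverage, the figure reported for the study organism and typical of
prokaryotic genomes; they are fully configurable. Imperfect or compound
repeats are out of scope.

Indel–SSR and indel–coding overlap use the left-normalized affected
interval: `[pos, pos + len(ref))` for deletions (anchor included) and
the insertion point `pos + 1` for insertions. Indels longer than 50 bp
are excluded from the small-indel class with a warning. Expected coding
indel counts under uniform placement are `total × coding fraction`
(reported unrounded); enrichment is tested with two-sided Fisher's exact
tests on events vs non-event site-generations by region, with exposures
rounded to integers (the hypergeometric support is bounded by the event
count, so the exact test is cheap even at ~10¹¹ site-generations).

## The simulator

`generate_genome` emulates a bacterial chromosome, not real genome
architecture: non-overlapping CDS (ATG start, stop codon, no internal
stops) on random strands, separated by noncoding spacers. Codon sampling
probabilities are solved (Brent root-finding on the per-base GC
parameter) so the expected coding GC equals the target despite
stop-codon exclusion; spacer composition then absorbs the residual so
the realized genome GC lands within 0.01 of the request. SSRs are
planted to a target coverage (default 0.98%) with motif sizes weighted
toward mono/dinucleotides and copy numbers at or above the detection
thresholds; any planting that would corrupt an overlapping reading frame
is rolled back. Defaults mirror the study organism: 4.13 Mb, 60.5% GC,
88.3% coding.

`simulate_ma_experiment` implements the neutral-accumulation model
directly: per-line substitution and indel counts are
`Poisson(rate × Nᵢ × Tᵢ)`; substitution classes are drawn from the
spectrum weights and placed uniformly among sites of the required
composition (a G:C→A:T event needs a G/C site); at most one mutation per
site per line (expected per-site hit probability ~3.5×10⁻⁷ at study
scale, so collisions are negligible and redraws are bias-free). Indels
draw sizes from a truncated-geometric distribution over ±1..50 bp
(geometric p = 0.15, mean ≈ 6.7 bp, matching the observed mean insertion
and deletion sizes; insertion:deletion balanced) and are placed inside
SSR spans with probability `k·S / (L − S + k·S)` for hotspot multiplier
*k* and SSR footprint *S*. Insertions duplicate the adjacent sequence in
tandem, the slippage mechanism. Default experiment parameters are the
study conditions: 69 lines, 159 transfers × 18.3 generations,
sub rate 1.22×10⁻¹⁰, indel rate 4.35×10⁻¹¹. The default spectrum weights
are the four published directional class counts (40:17:10:3) with the
residual transversion mass split evenly between the two unreported
classes. The default hotspot multiplier 64 is derived from the reported
12/31 indels inside SSRs covering 0.98% of the genome:
`(12/19) / (0.0098/0.9902) ≈ 64`.

What the simulator does **not** model: reads, sequencing error, mapping
artifacts, coverage heterogeneity (callable sites are a scalar fraction
of the genome, not a spatial mask), within-colony population dynamics
between bottlenecks, multi-allelic sites, and real genome features
(operons, overlapping genes, compositional skew, imperfect repeats).
Passing the round-trip and recovery tests therefore demonstrates
correctness of the estimators and bookkeeping on clean calls — not
robustness to upstream calling noise, which enters this pipeline only
through the QUAL/MQ/consensus fields of real VCFs.

`write_fixtures` emits FASTA, GFF3, one VCF v4.2 per line (QUAL 1000,
MQ 60, AD 0,100 — above all default thresholds) and a metadata TSV whose
CFU column is `round(2^g)` so that `log₂(CFU) × transfers` recovers each
line's generations.

## Numerical and design choices

- Coordinates are 0-based half-open internally; VCF/GFF3 emission and
  ingestion convert to the 1-based on-disk conventions. Indels use the
  VCF left-anchored padding-base representation.
- The `m = 0` Poisson lower bound is 0 by definition; the upper bound
  uses `2m + 2` degrees of freedom.
- χ² in the NS:S test and Fisher in the region tests are used without
  multiple-testing correction, as only two such tests are reported.
- Ties in SSR resolution are deterministic (length, motif size, start),
  making all outputs byte-reproducible for a given seed and config.
- Published MA analyses sometimes print summary statistics that cannot
  be exactly re-derived from their own printed counts (rounded means
  propagate). `maexp` always computes statistics from the counts it is
  given and never hard-codes a published value; the worked-number tests
  accept the few-percent slack that rounding of printed means implies.

## Problem sizes used in the test suite

Unit tests run on 9–150 kb synthetic genomes; study-scale checks
(Poisson mean recovery, estimator bias, CI coverage) use a 3.5 Mb genome
with 69 lines and 100–200 replicates, sized so the whole suite completes
in well under a minute on one core while keeping every statistical check
at the experiment's own event counts (~87 substitutions, ~31 indels per
replicate).

## Known limitations

- Conditional rates use genome-wide composition for the callable
  fraction (see above).
- `callable_sites` is an input; depth-based callability is not computed
  from alignments.
- Fisher tables round site-generation exposures to integers; at ≥10⁶
  site-generations the effect on p-values is far below reporting
  precision.
- The expected NS:S null conditions on the observed ts/tv ratio; it does
  not model context-dependent (e.g. CpG-like) rate variation.
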