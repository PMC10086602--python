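# Methods

## Interval model and merging

Elements are stored 0-based half-open (BED convention); GWAS positions are
1-based (summary-statistics convention), converted once at the mapping
boundary (position p occupies 0-based offset p−1). Two elements merge iff
they share at least one base under half-open semantics; abutting intervals
(end = start) share no base and stay separate. Identical intervals
contributed by different catalogues are retained as distinct elements and
merge into one multi-element region, which is what makes the multi-element
count a meaningful measure of between-catalogue overlap. Merging is a single
sweep over elements sorted by (chromosome, start, end); it is idempotent,
and the region set equals the connected components of the pairwise-overlap
graph (the test suite checks this against a quadratic union-find oracle, and
checks covered-base totals against a base-array union).

A region's mean length is reported both to one decimal and truncated toward
zero, because integer truncation is the convention of the summary tables
this report format follows. Genome coverage is total region length over the
summed chromosome lengths of the supplied chrom.sizes table; the package
never asserts a particular genome total.

## Statistical tests

*Chromosome distribution.* Goodness of fit of per-chromosome region counts
against length-proportional expectations, df = #chromosomes − 1. Counts (not
covered bp) are the observations: regions are the discrete units of the
multinomial. The raw p-value is always retained; display strings floor it at
2.2×10⁻¹⁶, mirroring R's printing convention, since the pipeline's
statistics are otherwise R-compatible.

*Independence contrasts.* Pearson χ² with expected counts from the margins.
Yates continuity correction defaults ON for 2×2 tables (the default of R's
`chisq.test`, the environment this analysis style comes from) and is a flag;
both the corrected and uncorrected forms are available and the report logs
which was used. A zero expected cell raises (the caller must drop the empty
margin); expected cells below 5 only warn. Yates is deliberately
conservative: under null simulation its rejection rate falls below the
nominal α, so the calibration checks in the test suite exercise the
uncorrected statistic.

The three analysis tables are: focal-class vs pooled-rest ×
disease/quantitative mapped-variant counts (the focal class defaults to
hsInsert, the one class where disease variants outnumber quantitative-trait
variants); disease vs quantitative × mapped/unmapped loci; and regulatory vs
non-regulatory × hit/no-hit regions. The regulatory table excludes
multi-type regions (~1% of regions) rather than invent a type priority; the
same choice is exposed for type-level variant counts, where the default is
the opposite — a variant in a multi-type region increments every constituent
type — because there the unit is the mapping event, not the region.

## Significance and locus rules

p < 5×10⁻⁸ and log₁₀BF > 6 are strict, as printed in the conventions this
implements; the boundary cases are tested explicitly. Duplicate rows for one
variant within a trait keep the most significant score with a logged
warning. Cross-trait variant identity is the variant id when present, else
`chrom:pos` — needed only for pleiotropy counting.

Loci are defined by the *reported* lead variants (taken from the input's
lead_id column, not re-derived by clumping) and strict r² > 0.8 membership;
a variant above threshold with several leads joins the highest-r² one, ties
to the smaller lead position. Significant variants with no lead above
threshold are reported as unassigned and excluded from locus counts —
they are not part of any reported independent signal; a singleton mode
(config switch) instead promotes each to a one-variant locus. Loci are
trait-specific: the same genomic lead reported by two traits counts twice,
consistent with summing input loci across studies.

## Synthetic-data generator

The generator is the package's study-condition model, not a test fixture:
it emits exactly the formats the pipeline reads, with ground truth.

* Default study: 5 chromosomes × 2 Mb; nine element classes whose counts
  (83, 2, 30, 45, 1, 360, 4, 16, 58) and log-normal length scales (median
  253–4,197 bp, σ = 0.5, minimum 10 bp) echo the count and length-share
  heterogeneity of the real catalogues at ~1/33 scale; placement weights
  tilt odd chromosomes to make the distribution test non-trivial. Realized
  coverage is ~8% of the toy genome — far above the real ~0.8%, a deliberate
  consequence of keeping element counts small enough for fast repeated
  draws while preserving the length-scale heterogeneity.
* Traits: two quantitative (one p-value-scored, one Bayes-factor-scored) and
  two disease traits, 50 loci each, Poisson(3) block members within ±25 kb
  of the lead, member r² ~ U(0.81, 1.0), plus 10% decoy significant variants
  with r² ~ U(0, 0.8) to the nearest lead (these must never change locus
  counts). Significant p-values are log-uniform in (10⁻³⁰, 5×10⁻⁸);
  Bayes-factor scores are uniform in (6, 30).
* Enrichment is injected at the lead level: a disease lead lands inside a
  region with probability θc/(θc + 1 − c), c the realized coverage, so the
  in-region *odds* are multiplied by θ and the locus-table odds ratio
  identifies θ. Quantitative leads use probability c; θ = 1 is the null.
* Every output is a pure function of the config: one `numpy` Generator
  seeded from `SimConfig.seed` drives the whole draw, and bundles rerun
  byte-identically.

What the generator does *not* emulate: real LD maps (r² values are drawn,
not derived from genotypes), allele frequencies, effect sizes,
winner's-curse p-value shapes, or catalogue-specific biases toward genes or
chromatin states. Passing tests therefore demonstrate the pipeline's
correctness and calibration under the stated model, not conclusions about
real catalogues.

## Experiment designs in tests and the acceptance script

* *θ recovery* uses lead-only loci (members_per_locus = 0, no decoys),
  2,000 loci per category, θ = 3, and a doubled element density (~15%
  coverage). Lead-only blocks are required for identifiability: block
  members within ±25 kb map with a category-independent probability
  (≈ 1 − e^{−m̄c}), which attenuates the observed odds ratio toward 1 — with
  the default m̄ = 3 the attenuation is roughly two-fold. The denser element
  set raises the mapped-locus counts so the odds ratio is stable at this
  study size. The attenuation under proxy-bearing blocks is a known
  limitation of odds-ratio-based enrichment readouts, not of the generator.
* *Power at θ = 4* uses 500 loci per category with the full default block
  structure, 200 draws; the proxy-leakage inflation of both categories'
  mapping rates is included, which is why the per-category locus count is
  sized well above the default study.
* *Null calibration* uses 1,000 pure multinomial/binomial replicates for the
  two χ² routines and 200 θ = 1 end-to-end bundle draws for the locus
  contrast, with rejection rates required inside the 99% binomial band
  around α = 0.05.
* The acceptance script re-derives the published aggregates by running the
  package's own readers and report arithmetic on the published inputs
  (catalogue sizes, region totals, mapped/input tallies), then runs the
  synthetic experiments above at the sizes stated here.

## Numerical and degenerate-input choices

Report percentages are rounded half away from zero to one decimal (raw
ratios are kept alongside); 0/0 rates are reported as 0. Empty element input
merges to an empty region set without error; an empty significant-variant
set produces a zero-count report with the contrasts skipped and the reason
recorded. A pipeline stage failure raises an error naming the stage and
removes partial outputs. Region ids are assigned in (chromosome, start)
order with a karyotype-aware chromosome sort (chr2 before chr10).

## Known limitations

Positional overlap is the only notion of colocalization — no
posterior-probability signal colocalization, no eQTL/sQTL integration, no
liftover, no strand handling. The r² table is consumed, never computed from
genotypes. The odds-ratio attenuation under proxy-bearing blocks (above)
means θ estimated from real locus tables would be conservative.
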