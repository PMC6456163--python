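# Methods

This note documents the models, defaults and numerical choices behind
`plantmut`, and what validation on synthetic data does and does not
establish about real data.

## Calling model

A candidate somatic mutation is a site whose variant-genotype samples form
a coherent group against the rest of the plant, which is presumed to carry
the ancestral allele.

**Topology-based caller.** The variant samples' lowest common ancestor
(LCA) on the declared branch hierarchy is the putative origin node. If the
LCA is the root — the variant spans otherwise unrelated primary branches,
or is present in every sample — the site cannot be distinguished from a
preexisting variant by this method and is left to the frequency-based
caller. Hard filters reject candidates with:

* site variant quality < 50 (applied per site; multi-sample VCFs carry one
  quality per record);
* insufficient mutant-read support: a lone carrier needs ≥ 5 mutant reads;
  shared candidates need ≥ 5 in at least one carrier and ≥ 3 in every
  other;
* missing genotypes in more than 5 samples;
* mutant reads on one strand only (pooled over carriers);
* ≥ 4 base-quality-20 mutant-allele ("mimic") reads in any control sample.

Survivors are graded *confidence* unless evidence is imperfect:
1–5 samples missing, any control with 2–3 mimic reads, or the site seen
only by the alignment-direct upstream call set (flag A), each of which
demotes to *evaluation* with a machine-readable code. Manual review stages
(genome-browser inspection, read realignment) are deliberately replaced by
these codes: anything a human would re-examine stays in the evaluation set
rather than being silently dropped.

Two boundary choices are worth stating because the protocol leaves them
open. Discard applies at > 5 missing samples and masking at ≤ 4, leaving
exactly 5 unaddressed; we treat 5 conservatively as evaluation. A single
mimic read in a control is tolerated in the confidence set (masking starts
at 2); ≥ 4 mimic reads is treated as a hard artifact signature.

**Frequency-based caller.** Any site variant in M of N samples with
M < 0.8 N is tested with the M samples as focal group, under the same hard
filters plus a strictly clean control group (one bq20 mimic read anywhere
rejects). Sites at M ≥ 0.8 N are never called: they are indistinguishable
from preexisting variants with genotyping dropout, or from somatic
recombination. Frequency calls whose focal sets straddle recorded primary
branches feed the topology-error detector: a lone sample repeatedly
(≥ 2 sites) grouping with a foreign branch is flagged for reassignment, and
two complete branches repeatedly sharing mutations are reported as a
suggested sister pair.

Heterozygosity is *not* a filter — somatic recombination, allele-specific
sequencing or mapping can render true mutations apparently homozygous — but
each call records whether its pooled focal allele fraction looks
heterozygous (< 0.8).

**Lane contamination.** Index hopping can deposit a few genuine reads from
one library under another barcode in the same lane. A candidate whose
allele has ≥ 1 bq20 read in an *unrelated* individual sequenced in the same
lane is rejected. Without lane metadata the filter is a warning no-op.

**Microscale profile.** For amplified micropunch samples,
`call_sample_specific` applies the stricter rules such data need: a
single-sample mutation requires zero identical mutant reads in any other
sample and must not be a preexisting polymorphism; a shared microhole
mutation needs ≥ 5 mutant reads in each of ≥ 2 samples.

## Synthetic data: what it emulates

The generator is the test harness for everything above; its defaults are
the study conditions the pipeline is built for.

* **Growth.** `topology_shape = (5, 3, 2)`: five primary branches, each
  bifurcating once per season for three seasons, two leaf samples per
  terminal twig (40 leaves); when a root rate is given, a root system of
  two primaries with root samples is attached. Each branch segment spans
  one year.
* **Mutation process.** Mutations arrive per lineage segment as
  Poisson(rate × year) with tissue-specific rates. Defaults
  (`leaf 3.74/21 ≈ 0.178`, `root 29.8/21 ≈ 1.42` per lineage-year) mimic
  the measured contrast between shoot and root accumulation in a ~21-year
  peach — the core biological signal the pipeline must resolve. A mutation
  on the segment above node v is carried at cell fraction 1 by all
  same-lineage samples under v (fixed in the meristem, heterozygous, so
  ~0.5 allele fraction). Each sample additionally draws one season of
  private, current-season mutations that are mosaic within the sample
  (cell fraction uniform on [0.25, 1]; 0.25 is the detectability floor at
  40× with a 5-read threshold). 1% of mutations appear homozygous
  (haplotype loss), matching the ~99% heterozygous fraction observed in
  real call sets. Mutation classes default to 90% SNV, with small MNV,
  insertion, deletion and replacement fractions.
* **Runner model.** A runner is a chain of segments, each with a runner
  sample and a lateral-bud subtree of leaves. Each runner mutation is
  bud-competent ("transmissible") with probability 1/6 (one of the six
  observed runner mutations behaved that way) and otherwise *restricted*:
  it propagates down the runner but never into lateral-bud descendants.
  This is a hard invariant of the generator.
* **Sequencing.** Depth is negative-binomial (mean 40, dispersion 10; an
  empirical depth profile can be supplied instead). Carrier mutant reads
  are Binomial(depth, 0.5 × cell fraction); non-carriers draw error reads
  at 1% per base × 1/4 same-allele-by-chance = 0.0025 per read, of which
  25% survive the base-quality-20 cut that defines a mimic read (raw error
  reads are mostly low-quality; without this distinction the evaluation
  set would be far larger than real data show). Strand split is
  Binomial(k, 1/2). Genotype status is variant at ≥ 3 mutant reads,
  missing at rate 10⁻³. Site quality is 15 × the maximum per-sample
  mutant-read count, so genuine carriers clear the quality-50 bar while
  error-only sites do not. Call-set provenance is drawn per site at the
  observed SNV concordance (95.5% both / 2.6% B-only / 1.9% A-only).
  Background rows include pure-noise sites and preexisting polymorphic
  sites (variant in every sample) so that the filters are actually
  exercised. Within-lane contamination hits a non-carrier sharing a lane
  with a carrier at 10⁻³ per site-sample (the real intensity is
  unquantified — "a small number of reads" — so this default is explicitly
  arbitrary); a heavier cross-individual injection helper exists for
  validating the lane filter.
* **Progeny.** Heterozygous mutations fixed in the gametogenic branch
  transmit to each seed independently with p = 1/2 (one transmitted
  maternal gamete per seed — the convention behind the absence expectation
  (1/2)^n). Strict selfing of a heterozygote would give presence
  probability 3/4 per seed; that is available as `p_transmit = 0.75`.
  Progeny-specific mutations arrive at Poisson(4.6) per seed, the mean
  specific count observed across selfed peach progeny.

**What passing tests show — and don't.** With these defaults the caller
achieves recall ≥ 0.90 and precision ≥ 0.95 against truth on every seed
tested, and the confidence set holds ≥ 90% of true calls pooled across
seeds (the aggregate form in which the >90% capture claim is made; single
replicates fluctuate a few points either way). That validates the
*logic* of the pipeline — partition, filters, evidence grading — under a
noise model whose parameters are plausible but idealized. The generator
does not emulate alignment artifacts around indels, repeat-induced
mapping errors, amplification bias in MDA material, or somatic
recombination; on real data those failure modes are exactly what the
evaluation set and the (here code-based) review stages exist to absorb, so
real-data precision at the confidence/evaluation boundary cannot be
inferred from these tests.

## Callability and rates

Callable fraction = recovered fraction of 1,000 (default) synthetic
mutations injected one per replicate at random branch nodes carrying the
requested tissue, simulated with the same noise model (tissues are
simulated separately since their depth distributions differ) and called by
the full topology-based caller. Rates divide by
ploidy × genome size × callable fraction × age: the denominator counts
*diploid* base pairs, which reproduces the printed magnitude of normalized
rates (e.g. 3.74 mutations / (2 × 225 Mb × 21 y) ≈ 4.0 × 10⁻¹⁰ before
callability correction; the printed 0.52 × 10⁻⁹ implies a callable
fraction of ≈ 0.76). Because the published per-tree callable fractions are
not available at desk scale, the haploid convention cannot be excluded;
passing `ploidy=1` switches to it. Per-generation rates carry exact
Poisson (Garwood) confidence intervals on the summed mutation count. Rate
operations require branch ages and reject topologies without them.

## Trees

Distances are raw counts of differing mutation columns (not normalized):
mutation counts are small and branch lengths should read as mutation
counts. NJ comes from scikit-bio with first-minimal-pair tie-breaking,
deterministic given input order and seed-independent; the three-taxon case
uses the closed-form three-point solution. Bootstrap resamples mutation
columns with replacement and reports, for each internal split of the
original tree, the percentage of replicates containing it.

## Statistics

* **Dispersion test.** D = sample variance (ddof = 1) / mean of per-branch
  counts. Significance by simulation: the default null redistributes the
  observed *total* count uniformly over the branches (multinomial — a
  permutation-style null conditioning on the total); a plug-in Poisson
  null (independent Poisson draws at the observed mean) is available via
  `method="poisson"`. For 75 branches at mean 0.45 both give
  sd(D) ≈ 0.162 ≈ √(2/74); the conditional null puts an observed D of
  1.031 at p ≈ 0.45. The p-value is the fraction of simulants with
  D ≥ observed.
* **Chi-square with Yates correction** in both the 2×2 form
  N(|ad−bc|−N/2)²/∏margins and the goodness-of-fit form
  Σ(|O−E|−½)²/E, with the correction floored at zero.
* **Brunner–Munzel** is implemented from its definition (midranks, rank
  variances, Satterthwaite degrees of freedom) and cross-checked against
  an independent implementation in tests. Fully tied samples return p = 1;
  completely separated samples, where the variance estimate degenerates,
  fall back to the exchangeability bound 2/C(n₁+n₂, n₁).
* **Poisson rate comparison** is the conditional binomial (exact) test;
  the published analyses do not state their construction, so agreement
  with their printed p-value is not guaranteed.
* **OLS** via statsmodels, reporting the slope test and the
  intercept-versus-zero test. **Spearman** uses exact permutation
  enumeration for n ≤ 9 without ties, the t approximation otherwise.
* All Monte-Carlo procedures are bit-reproducible under a fixed seed.

## Known limitations

* Read-level phenomena (alignment, realignment, homopolymer artifacts) are
  out of scope; the input boundary is the call-level matrix.
* The upstream variant callers are abstracted to provenance flags; a
  single-call-set mode treats all sites as concordant.
* The topology-error detector suggests regroupings; it does not rewrite
  the topology (rerun with a corrected file).
* The runner test implements the mutation-selection null only; a
  cell-selection null would be stricter but is unspecifiable without the
  founder-cell count.
* The nonsynonymous-transmissibility goodness-of-fit statistic printed in
  the source analyses is not reproducible under either chi-square
  construction implemented here; the operation is provided, but that
  number is not treated as a reference value.

## Problem sizes

Defaults used in the test-suite and demo pipeline: 40–56 samples per
plant, ~50–280 true mutations, 1,000-site callability injections,
10,000-replicate dispersion simulations, 100–1,000 bootstrap replicates.
These sizes make every stage's statistical behaviour measurable while the
whole validation battery runs in well under a minute.
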