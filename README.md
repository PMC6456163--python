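# plantmut

Somatic mutation calling and transmissibility analysis over plant branch
topologies.

## The problem

Plants grow by reiterated branching: every branch is a biological replicate
of the same genome, and every somatic mutation is frozen into the subtree of
samples that descend from the cell in which it arose. Sequencing many
tissues (leaves, roots, petals, runners, ...) from one individual therefore
lets you ask questions that are hard to ask in animals: do shoot and root
meristems accumulate mutations at different rates per year? Are mutations in
short-lived petals more numerous than in long-lived leaves? Are some
branches intrinsically more mutagenic than others, or is between-branch
variation pure Poisson noise? And what fraction of the somatic mutations a
plant accumulates are premeiotic — carried into its seeds?

`plantmut` implements the full analysis stack for such studies, for people
who have per-site read-support matrices from multi-sample sequencing of a
single plant and a record of its branch structure:

* **Topology-based calling** — for each candidate site, the set of
  variant-genotype samples is placed on the branch hierarchy; a somatic
  mutation is called when the variant is confined to a single branch
  lineage (its lowest common ancestor node is below the root) and survives
  hard filters: variant quality ≥ 50, ≥ 5 mutant reads in a focal sample
  (≥ 3 in every co-carrier), ≤ 5 missing genotypes, mutant reads on both
  strands. Surviving candidates are graded into a *confidence* set or an
  *evaluation* set (1–5 missing genotypes, 2–3 mutant-allele "mimic" reads
  with base quality ≥ 20 in a control sample, or seen by only the
  alignment-direct upstream caller).
* **Frequency-based calling** — sites variant in M of N samples
  (M < 0.8 N) are tested regardless of branch structure, with a fully clean
  control group required (zero mimic reads). This recovers mutations that
  straddle recorded branches and doubles as a detector of topology
  recording errors.
* **Callability** — synthetic mutations are injected onto the real
  topology, pushed through the sequencing-noise model and the full caller;
  the recovered fraction corrects mutation rates for the accessible genome.
  Rates are normalized as
  `rate = mutations / (ploidy × genome_size × callable_fraction × age_years)`.
* **Ontogenetic trees** — neighbor joining on raw Hamming distances of the
  sample × mutation presence matrix, with column-bootstrap split support.
* **Transmissibility** — N_t/N_o and N_t/N_p accounting for selfed and
  outcrossed progeny, the Mendelian absence expectation (1/2)^n, the
  sequential-selection test for a restricted (germline-like) cell lineage
  in stolons/runners, and per-year accumulation from within-branch carrier
  frequencies.
* **Statistics** — the dispersion (variance/mean) test with simulated null,
  Yates-corrected chi-square (2×2 and goodness-of-fit), the Brunner–Munzel
  rank test, conditional Poisson rate comparison, OLS with intercept test,
  and Spearman correlation with exact small-sample p-values.
* **Synthetic data** — a seeded generator of ground-truth plants
  (tissue-specific Poisson mutation accumulation per lineage-year, a
  restricted-germline runner model, Mendelian transmission to progeny) and
  noisy read matrices (negative-binomial depth, heterozygous support at
  ~0.5 allele fraction, 1%-per-base sequencing error, strand splits,
  missing genotypes, within-lane index hopping, two-caller provenance), so
  the whole pipeline can be validated against a known truth.

## Worked example

```python
import numpy as np
from plantmut import (SimulationParams, SeqParams, simulate_plant, simulate_reads,
                      call_topology_based, call_frequency_based, merge_calls,
                      estimate_callable_fraction, normalize_rate, dispersion_test)

params = SimulationParams(seed=7)          # default: perennial with leaf + root samples
rng = np.random.default_rng(7)
topology, truth = simulate_plant(params, rng=rng)
matrix = simulate_reads(topology, truth, SeqParams(), rng=rng)

calls = merge_calls(call_topology_based(matrix, topology),
                    call_frequency_based(matrix, topology))
true_keys, called_keys = truth.site_keys, {c.key for c in calls}
print(f"recall:    {len(true_keys & called_keys) / len(true_keys):.3f}")
print(f"precision: {len(true_keys & called_keys) / len(called_keys):.3f}")

cr = estimate_callable_fraction(topology, SeqParams(), n=1000, seed=7)
counts = truth.per_sample_counts(topology.sample_ids)
leaf = np.mean([counts[s.sample_id] for s in topology.samples if s.tissue == "leaf"])
rate = normalize_rate(leaf, topology.genome_size, 2, cr.callable_fraction,
                      topology.age_years)
print(f"callable fraction: {cr.callable_fraction:.3f}")
print(f"leaf rate: {rate.rate_per_bp_per_year:.2e} per bp per year")

singletons = [sum(1 for e in truth.entries if e.carriers == frozenset({s}))
              for s in topology.sample_ids]
d = dispersion_test(singletons, reps=10000, seed=7)
print(f"dispersion D = {d.D:.3f}, p = {d.p_value:.3f}")
```

prints

```
recall:    0.946
precision: 1.000
callable fraction: 0.979
leaf rate: 5.67e-10 per bp per year
dispersion D = 1.344, p = 0.055
```

Read: on a simulated 3-season plant at 40× coverage the caller recovers
94.6% of true mutations with no false positives; 97.9% of injected sites
are callable, so observed counts are inflated by ~1/0.979 when converted to
a per-bp-per-year rate; and the per-sample singleton counts show no more
between-sample heterogeneity than a homogeneous-rate (Poisson) null allows
(D near 1, p = 0.055 from 10,000 simulated datasets).

The same functionality is exposed on the command line:

```bash
plantmut simulate --seed 7 --out-prefix demo        # topology YAML, truth TSV, VCF + support TSV
plantmut call --vcf demo.vcf --support demo.support.tsv \
              --topology demo.topology.yaml --mode both --out calls.tsv
plantmut runner-test --bud-sizes 5,5,6,6,6          # -> 0.000925926
plantmut rate --mean-mutations 3.74 --genome-size 225000000 --age-years 21
plantmut reproduce --seed 0                         # end-to-end demo pipeline
```

## Layout

| module | contents |
| --- | --- |
| `plantmut.topology` | branch hierarchy, sample metadata, focal/control partitions, YAML I/O |
| `plantmut.matrix` | per-site × per-sample read support, VCF + TSV I/O |
| `plantmut.calling` | topology- and frequency-based callers, filters, evidence grading, lane-contamination and topology-error detection |
| `plantmut.callability` | injection-based callable fraction, rate normalization, per-generation rates |
| `plantmut.tree` | presence matrices, NJ trees, bootstrap support |
| `plantmut.transmission` | N_t/N_o, N_t/N_p, absence expectation, runner germline test, per-year accumulation |
| `plantmut.stats` | dispersion, chi-square (Yates), Brunner–Munzel, Poisson comparison, OLS, Spearman |
| `plantmut.simulate` | ground-truth generator: plants, mutations, progeny, reads |
| `plantmut.pipeline`, `plantmut.cli` | end-to-end demo pipeline and the `plantmut` command |

See `docs/methods.md` for the model assumptions, parameter defaults and
numerical choices.
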