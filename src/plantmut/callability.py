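"""Callable-genome estimation and mutation-rate normalization.

The raw mutation count per sample undercounts reality because not every
genomic site is callable at the pipeline's thresholds (depth, missing
genotypes, strand representation, ...). The callable fraction is estimated
by injection: place synthetic mutations on the real topology, push them
through the sequencing-noise model and the full caller, and record the
fraction recovered. Rates are then normalized per base pair of accessible
diploid genome per year.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .calling import FilterConfig, call_topology_based
from .simulate import SeqParams, TruthEntry, TruthSet, simulate_reads
from .topology import PlantTopology


@dataclass(frozen=True)
class CallabilityResult:
    """Outcome of a synthetic-injection callability experiment."""

    n_injected: int
    n_called: int
    stratum: str
    seed: int | None

    def __post_init__(self) -> None:
        if not (0 <= self.n_called <= self.n_injected):
            raise ValueError("n_called must be within [0, n_injected]")

    @property
    def callable_fraction(self) -> float:
        return self.n_called / self.n_injected

    @property
    def false_negative_rate(self) -> float:
        return 1.0 - self.callable_fraction


@dataclass(frozen=True)
class RateResult:
    """A normalized mutation accumulation rate."""

    mean_mutations_per_sample: float
    genome_size: int
    ploidy: int
    callable_fraction: float
    age_years: float

    @property
    def rate_per_bp_per_year(self) -> float:
        return self.mean_mutations_per_sample / (
            self.ploidy
            * self.genome_size
            * self.callable_fraction
            * self.age_years
        )


def estimate_callable_fraction(
    topology: PlantTopology,
    seq: SeqParams | None = None,
    cfg: FilterConfig | None = None,
    n: int = 1000,
    seed: int | None = None,
    stratum: str = "leaf",
    depth_profile=None,
    rng: np.random.Generator | None = None,
) -> CallabilityResult:
    """Fraction of injected synthetic mutations recovered by the caller.

    ``n`` synthetic heterozygous mutations are placed one per replicate at a
    random branch node holding samples of the requested tissue ``stratum``
    (tissues are simulated separately because their read-depth distributions
    differ; pass ``depth_profile`` to use empirical depths). Each injected
    site is carried, fully, by the focal samples of its node. The full
    topology-based caller then runs; the callable fraction is the fraction
    of injected sites returned as non-rejected candidates.
    """
    seq = seq or SeqParams()
    cfg = cfg or FilterConfig()
    if rng is None:
        rng = np.random.default_rng(seed)
    if depth_profile is not None:
        profile = np.asarray(depth_profile)
        if profile.size == 0:
            raise ValueError("depth_profile must be nonempty")
        if profile.max() == 0:
            warnings.warn(
                "degenerate depth profile (all zero): callable fraction is 0",
                stacklevel=2,
            )
            return CallabilityResult(n, 0, stratum, seed)
        seq = SeqParams(
            **{
                **seq.__dict__,
                "depth_profile": tuple(int(d) for d in profile),
            }
        )
    tissue_samples = {
        s.sample_id for s in topology.samples if s.tissue == stratum
    }
    if not tissue_samples:
        raise ValueError(f"topology has no samples of tissue {stratum!r}")
    eligible_nodes = [
        nid
        for nid in (n_.node_id for n_ in topology.nodes)
        if nid != topology.root and topology.focal_samples(nid) & tissue_samples
    ]
    # build the n injected sites as one truth set, then batch-simulate reads
    genome = topology.genome_size
    positions = rng.choice(genome, size=n, replace=False) + 1
    entries = []
    from .matrix import Site  # local import to avoid cycle at module load

    bases = "ACGT"
    for i in range(n):
        node = eligible_nodes[int(rng.integers(len(eligible_nodes)))]
        carriers = topology.focal_samples(node) & tissue_samples
        ref = bases[int(rng.integers(4))]
        alt = bases[(bases.index(ref) + 1 + int(rng.integers(3))) % 4]
        entries.append(
            TruthEntry(
                site=Site("chr1", int(positions[i]), ref, alt),
                origin_node=node,
                origin_year=topology.node(node).year_formed,
                lineage_tag="synthetic",
                fractions={c: 1.0 for c in carriers},
            )
        )
    entries.sort(key=lambda e: e.site.pos)
    truth = TruthSet(entries)
    matrix = simulate_reads(topology, truth, seq, rng=rng)
    calls = call_topology_based(matrix, topology, cfg)
    called_keys = {c.key for c in calls if c.status != "rejected"}
    n_called = sum(1 for e in entries if e.site.key in called_keys)
    return CallabilityResult(n, n_called, stratum, seed)


def normalize_rate(
    mean_mutations: float,
    genome_size: int,
    ploidy: int = 2,
    callable_fraction: float = 1.0,
    age_years: float = 1.0,
) -> RateResult:
    """Accumulated mutations per sample -> rate per bp per year.

    rate = mean_mutations / (ploidy x genome_size x callable_fraction x
    age_years). The denominator counts diploid base pairs of the accessible
    genome; pass ``ploidy=1`` for a per-haploid-site rate.
    """
    for name, v in (
        ("mean_mutations", mean_mutations),
        ("genome_size", genome_size),
        ("ploidy", ploidy),
        ("callable_fraction", callable_fraction),
        ("age_years", age_years),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return RateResult(
        mean_mutations_per_sample=float(mean_mutations),
        genome_size=int(genome_size),
        ploidy=int(ploidy),
        callable_fraction=float(callable_fraction),
        age_years=float(age_years),
    )


@dataclass(frozen=True)
class GenerationRate:
    rate: float
    ci_low: float
    ci_high: float
    total_mutations: int
    denominator: float


def per_generation_rate(
    mean_specific_mutations: float,
    genome_size: int,
    ploidy: int = 2,
    callable_fraction: float = 1.0,
    n_progeny: int = 1,
    alpha: float = 0.05,
) -> GenerationRate:
    """Per-generation, per-site mutation rate with an exact Poisson CI.

    The point rate is mean_specific / (ploidy x genome_size x
    callable_fraction); the confidence interval inverts the exact Poisson
    tail probabilities of the summed mutation count over all progeny
    (garwood bounds: chi-square quantiles at 2T and 2T + 2 degrees of
    freedom).
    """
    if genome_size <= 0 or ploidy <= 0 or callable_fraction <= 0:
        raise ValueError("denominator terms must be positive")
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if mean_specific_mutations < 0:
        raise ValueError("mean_specific_mutations must be >= 0")
    total = int(round(mean_specific_mutations * n_progeny))
    denom = ploidy * genome_size * callable_fraction * n_progeny
    low = 0.0 if total == 0 else sps.chi2.ppf(alpha / 2, 2 * total) / 2
    high = sps.chi2.ppf(1 - alpha / 2, 2 * total + 2) / 2
    return GenerationRate(
        rate=total / denom,
        ci_low=low / denom,
        ci_high=high / denom,
        total_mutations=total,
        denominator=denom,
    )


def cell_divisions_from_mass(mass_initial: float, mass_final: float) -> float:
    """Cell-division count from tissue mass growth: log2(final/initial).

    Assumes constant density and cell size, so mass is proportional to cell
    number (e.g. a callus growing from 1.1 mg to 657.3 mg has undergone
    log2(657.3/1.1) ~ 9.2, i.e. about 10, divisions).
    """
    if mass_initial <= 0 or mass_final <= 0:
        raise ValueError("masses must be positive")
    if mass_final < mass_initial:
        raise ValueError("final mass must be >= initial mass")
    return math.log2(mass_final / mass_initial)
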