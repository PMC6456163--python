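"""Somatic mutation identification over a branching topology.

Two complementary callers operate on the same per-site read-support matrix:

* the **topology-based** caller treats each site's variant-genotype samples
  as a putative within-branch mutation: the deepest branch node whose
  sample set contains all variant samples is the putative origin, and a
  candidate is formed only when that node is below the root (i.e. the
  variant is confined to a single branch lineage and the rest of the plant
  witnesses the ancestral allele);
* the **frequency-based** caller considers any site where the variant
  allele is present in M of N samples with M < 0.8 N, regardless of branch
  structure. It applies the same support thresholds but tolerates no mutant
  ("mimic") reads in any control sample, and it recovers mutations that
  straddle recorded branches — which also makes it a detector of errors in
  the recorded topology.

Candidates pass a hard-filter stage (variant quality, read support, missing
genotypes, strand representation) and are then graded into a *confidence*
set (clean evidence) or an *evaluation* set (flagged evidence: some missing
genotypes, 2-3 mimic reads in a control, or seen by the alignment-direct
caller only). Heterozygosity is deliberately not a filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .matrix import MISSING, REF, VAR, Site, SiteCallMatrix
from .topology import PlantTopology

MUT_CLASSES = ("SNV", "MNV", "INS", "DEL", "RPL")

# rejection codes
LOW_QUAL = "LOW_QUAL"
LOW_DEPTH = "LOW_DEPTH"
MANY_MISSING = "MANY_MISSING"
STRAND_BIAS = "STRAND_BIAS"
EXCESS_MIMIC = "EXCESS_MIMIC"
CONTROL_MIMIC = "CONTROL_MIMIC"
LANE_BLEED = "LANE_BLEED"
INDEL_TOO_LONG = "INDEL_TOO_LONG"
NOT_MONOPHYLETIC = "NOT_MONOPHYLETIC"
HIGH_FREQUENCY = "HIGH_FREQUENCY"
# evaluation codes
MISSING_MASK = "MISSING_MASK"
MIMIC_MASK = "MIMIC_MASK"
CALLSET_A_ONLY = "CALLSET_A_ONLY"


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the hard-filter and evidence stages.

    Defaults follow the calling protocol: variant quality >= 50; a lone
    focal sample needs >= 5 mutant reads, shared candidates need one sample
    with >= 5 and every other focal sample with >= 3; sites missing in more
    than 5 samples are discarded while 1-5 missing genotypes demote to the
    evaluation set; 2-3 base-quality-20 mimic reads in any control demote,
    >= 4 reject; both strands must carry mutant reads; the frequency caller
    never considers sites variant in >= 80% of samples; indels above 100 bp
    are out of scope.
    """

    min_variant_quality: float = 50.0
    min_focal_reads: int = 5
    min_shared_reads: int = 3
    max_missing_discard: int = 5
    max_missing_mask: int = 4
    mimic_mask_min: int = 2
    mimic_mask_max: int = 3
    mimic_reject: int = 4
    require_both_strands: bool = True
    freq_cap: float = 0.8
    max_indel_len: int = 100
    single_callset: bool = False
    topo_error_min_sites: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.freq_cap < 1.0):
            raise ValueError("freq_cap must be in (0, 1)")
        for name in (
            "min_focal_reads",
            "min_shared_reads",
            "max_missing_discard",
            "max_missing_mask",
            "mimic_mask_min",
            "mimic_reject",
            "max_indel_len",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class CandidateMutation:
    """A called somatic mutation candidate."""

    site: Site
    mut_class: str
    focal_samples: frozenset[str]
    origin_node: str
    status: str  # "confidence" | "evaluation" | "rejected"
    codes: frozenset[str] = frozenset()
    heterozygous: bool = True

    def __post_init__(self) -> None:
        if self.status == "rejected" and not self.codes:
            raise ValueError("rejected candidate must carry at least one code")

    @property
    def key(self) -> tuple:
        return self.site.key


@dataclass(frozen=True)
class Verdict:
    passed: bool
    codes: frozenset[str] = frozenset()


def classify_mutation_type(ref: str, alt: str, max_indel_len: int = 100) -> str:
    """Mutation class from REF/ALT alleles.

    Equal-length alleles are substitutions (SNV if length 1, MNV otherwise);
    when one allele is a prefix-extension of the other the change is a pure
    insertion or deletion; any other unequal-length pair is a complex
    replacement (RPL).
    """
    if not ref or not alt:
        raise ValueError("empty allele string")
    if max(len(ref), len(alt)) > max_indel_len:
        raise ValueError(
            f"allele length exceeds {max_indel_len} bp; only substitutions and "
            "small indels are considered"
        )
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    if len(alt) > len(ref) and alt.startswith(ref):
        return "INS"
    if len(ref) > len(alt) and ref.startswith(alt):
        return "DEL"
    return "RPL"


# -- filter stages ----------------------------------------------------------


def apply_hard_filters(
    candidate: CandidateMutation, matrix: SiteCallMatrix, cfg: FilterConfig
) -> Verdict:
    """Hard-filter verdict for a candidate: sequencing-error style rejections.

    Rejects on low variant quality, insufficient focal read support, too many
    missing genotypes, single-strand support, an overlong indel, or >= 4
    mimic reads in some control sample (a near-certain artifact signature).
    """
    i = matrix.site_index(candidate.site)
    if i is None:
        raise ValueError(f"candidate site {candidate.site} not in matrix")
    codes: set[str] = set()
    site = candidate.site
    if max(len(site.ref), len(site.alt)) > cfg.max_indel_len:
        codes.add(INDEL_TOO_LONG)
    if matrix.variant_quality[i] < cfg.min_variant_quality:
        codes.add(LOW_QUAL)
    focal_idx = [matrix.sample_index(s) for s in candidate.focal_samples]
    mut = matrix.mut_reads[i]
    focal_reads = mut[focal_idx]
    if len(focal_reads) == 0 or focal_reads.max() < cfg.min_focal_reads:
        codes.add(LOW_DEPTH)
    elif len(focal_reads) > 1 and focal_reads.min() < cfg.min_shared_reads:
        codes.add(LOW_DEPTH)
    if matrix.missing_count(i) > cfg.max_missing_discard:
        codes.add(MANY_MISSING)
    if cfg.require_both_strands:
        fwd = int(matrix.mut_fwd[i, focal_idx].sum())
        rev = int(matrix.mut_rev[i, focal_idx].sum())
        if (fwd + rev) > 0 and (fwd == 0 or rev == 0):
            codes.add(STRAND_BIAS)
    control_idx = [
        j for j in range(len(matrix.samples)) if j not in set(focal_idx)
    ]
    if control_idx:
        control_mimic = matrix.mut_bq20[i, control_idx]
        if control_mimic.max(initial=0) >= cfg.mimic_reject:
            codes.add(EXCESS_MIMIC)
    return Verdict(passed=not codes, codes=frozenset(codes))


def classify_evidence(
    candidate: CandidateMutation, matrix: SiteCallMatrix, cfg: FilterConfig
) -> tuple[str, frozenset[str]]:
    """Grade a hard-filter-passing candidate as confidence or evaluation.

    A candidate is demoted to the evaluation set if genotypes are missing in
    1..max(max_missing_mask, max_missing_discard) samples, if any control
    sample shows 2-3 mimic reads, or if only the alignment-direct call set
    (A) reported the site.
    """
    i = matrix.site_index(candidate.site)
    if i is None:
        raise ValueError(f"candidate site {candidate.site} not in matrix")
    codes: set[str] = set()
    n_missing = matrix.missing_count(i)
    # 1..4 missing genotypes mask per protocol; exactly 5 is treated
    # conservatively as evaluation as well (> 5 was already discarded).
    if 1 <= n_missing <= max(cfg.max_missing_mask, cfg.max_missing_discard):
        codes.add(MISSING_MASK)
    focal = {matrix.sample_index(s) for s in candidate.focal_samples}
    control_idx = [j for j in range(len(matrix.samples)) if j not in focal]
    if control_idx:
        mimic = matrix.mut_bq20[i, control_idx]
        if np.any((mimic >= cfg.mimic_mask_min) & (mimic <= cfg.mimic_mask_max)):
            codes.add(MIMIC_MASK)
    if not cfg.single_callset and matrix.callset_a[i] and not matrix.callset_b[i]:
        codes.add(CALLSET_A_ONLY)
    return ("evaluation" if codes else "confidence", frozenset(codes))


def _heterozygous(matrix: SiteCallMatrix, i: int, focal_idx: list[int]) -> bool:
    depth = matrix.depth[i, focal_idx].sum()
    mut = matrix.mut_reads[i][focal_idx].sum()
    if depth == 0:
        return True
    return (mut / depth) < 0.8


def _build_candidate(
    matrix: SiteCallMatrix,
    i: int,
    focal: frozenset[str],
    origin: str,
    cfg: FilterConfig,
    extra_reject: set[str] | None = None,
) -> CandidateMutation:
    site = matrix.sites[i]
    try:
        mut_class = classify_mutation_type(site.ref, site.alt, cfg.max_indel_len)
    except ValueError:
        mut_class = "RPL"
        extra_reject = (extra_reject or set()) | {INDEL_TOO_LONG}
    cand = CandidateMutation(
        site=site,
        mut_class=mut_class,
        focal_samples=focal,
        origin_node=origin,
        status="confidence",
        heterozygous=_heterozygous(
            matrix, i, [matrix.sample_index(s) for s in focal]
        ),
    )
    verdict = apply_hard_filters(cand, matrix, cfg)
    codes = set(verdict.codes) | (extra_reject or set())
    if codes:
        return replace(cand, status="rejected", codes=frozenset(codes))
    status, ev_codes = classify_evidence(cand, matrix, cfg)
    return replace(cand, status=status, codes=ev_codes)


def call_topology_based(
    matrix: SiteCallMatrix,
    topology: PlantTopology,
    cfg: FilterConfig | None = None,
    keep_rejected: bool = False,
) -> list[CandidateMutation]:
    """Call somatic mutations confined to a single branch lineage.

    For each site the set of variant-genotype samples is located on the
    branch hierarchy; the lowest common ancestor node is the putative origin.
    Sites whose variant samples straddle the root (shared across otherwise
    unrelated primary branches, or present in every sample) are not callable
    by this method and are left to the frequency-based caller.
    """
    cfg = cfg or FilterConfig()
    unknown = set(matrix.samples) - set(topology.sample_ids)
    if unknown:
        raise ValueError(
            f"matrix samples not present in topology: {sorted(unknown)}"
        )
    out: list[CandidateMutation] = []
    for i in range(matrix.n_sites):
        focal = matrix.variant_samples(i)
        if not focal:
            continue
        origin = topology.lca(focal)
        if origin == topology.root:
            # cannot be distinguished from the ancestral state / preexisting
            if keep_rejected:
                out.append(
                    _build_candidate(
                        matrix, i, focal, origin, cfg, {NOT_MONOPHYLETIC}
                    )
                )
            continue
        cand = _build_candidate(matrix, i, focal, origin, cfg)
        if cand.status != "rejected" or keep_rejected:
            out.append(cand)
    return out


def call_frequency_based(
    matrix: SiteCallMatrix,
    topology: PlantTopology,
    cfg: FilterConfig | None = None,
    keep_rejected: bool = False,
) -> list[CandidateMutation]:
    """Call heterogeneous sites by variant-sample frequency (M of N samples).

    The M variant samples form the focal group, the remaining N - M the
    control group. The same hard filters apply, but the control group must be
    entirely clean: a single base-quality-20 mimic read in any control sample
    rejects the site. Sites with M >= freq_cap * N are never called, as they
    are indistinguishable from preexisting variants with genotyping dropout
    (or from somatic recombination).
    """
    cfg = cfg or FilterConfig()
    unknown = set(matrix.samples) - set(topology.sample_ids)
    if unknown:
        raise ValueError(
            f"matrix samples not present in topology: {sorted(unknown)}"
        )
    n_samples = len(matrix.samples)
    out: list[CandidateMutation] = []
    for i in range(matrix.n_sites):
        focal = matrix.variant_samples(i)
        if not focal:
            continue
        if len(focal) >= cfg.freq_cap * n_samples:
            if keep_rejected:
                out.append(
                    _build_candidate(
                        matrix, i, focal, topology.lca(focal), cfg,
                        {HIGH_FREQUENCY},
                    )
                )
            continue
        origin = topology.lca(focal)
        extra: set[str] = set()
        focal_idx = {matrix.sample_index(s) for s in focal}
        control_idx = [j for j in range(n_samples) if j not in focal_idx]
        if control_idx and matrix.mut_bq20[i, control_idx].max(initial=0) >= 1:
            extra.add(CONTROL_MIMIC)
        cand = _build_candidate(matrix, i, focal, origin, cfg, extra or None)
        if cand.status != "rejected" or keep_rejected:
            out.append(cand)
    return out


# -- topology error detection ----------------------------------------------


@dataclass
class TopologyErrorReport:
    """Suspected topology recording errors inferred from cross-branch sharing.

    ``sample_flags`` maps a sample id to ``(suggested_branch, n_sites)``:
    the sample repeatedly shared called mutations with samples of a branch
    other than its recorded one. ``branch_pairs`` maps a frozenset of two
    primary-branch ids to the number of called mutations jointly fixed in
    both, suggesting the pair is ontogenetically sister.
    """

    sample_flags: dict[str, tuple[str, int]] = field(default_factory=dict)
    branch_pairs: dict[frozenset, int] = field(default_factory=dict)

    @property
    def empty(self) -> bool:
        return not self.sample_flags and not self.branch_pairs


def detect_topology_errors(
    freq_calls: list[CandidateMutation],
    topo_calls: list[CandidateMutation],
    topology: PlantTopology,
    min_sites: int | None = None,
    cfg: FilterConfig | None = None,
) -> TopologyErrorReport:
    """Flag samples/branches whose sharing pattern contradicts the topology.

    Only frequency-based calls that straddle more than one recorded primary
    branch are informative. A lone sample grouping with a foreign branch at
    >= ``min_sites`` sites is flagged for reassignment; two complete primary
    branches jointly carrying >= ``min_sites`` mutations are reported as a
    suggested sister pair.
    """
    if min_sites is None:
        min_sites = (cfg or FilterConfig()).topo_error_min_sites
    topo_keys = {c.key for c in topo_calls}
    sample_votes: dict[str, dict[str, int]] = {}
    pair_votes: dict[frozenset, int] = {}
    for cand in freq_calls:
        if cand.status == "rejected" or cand.key in topo_keys:
            continue
        by_branch: dict[str, set[str]] = {}
        for s in cand.focal_samples:
            b = topology.primary_branch(topology.sample(s).node_id)
            by_branch.setdefault(b, set()).add(s)
        if len(by_branch) < 2:
            continue
        if len(by_branch) == 2:
            b1, b2 = sorted(by_branch)
            full1 = by_branch[b1] == set(topology.focal_samples(b1))
            full2 = by_branch[b2] == set(topology.focal_samples(b2))
            if full1 and full2:
                key = frozenset({b1, b2})
                pair_votes[key] = pair_votes.get(key, 0) + 1
                continue
            # a lone stray sample grouping with a (near-)complete other branch
            for lone_b, other_b in ((b1, b2), (b2, b1)):
                if len(by_branch[lone_b]) == 1 and len(by_branch[other_b]) >= 2:
                    (sample,) = by_branch[lone_b]
                    votes = sample_votes.setdefault(sample, {})
                    votes[other_b] = votes.get(other_b, 0) + 1
    report = TopologyErrorReport()
    for sample, votes in sample_votes.items():
        branch, n = max(votes.items(), key=lambda kv: kv[1])
        if n >= min_sites:
            report.sample_flags[sample] = (branch, n)
    for pair, n in pair_votes.items():
        if n >= min_sites:
            report.branch_pairs[pair] = n
    return report


# -- lane contamination ------------------------------------------------------


def remove_lane_contamination(
    candidates: list[CandidateMutation],
    topology: PlantTopology,
    co_laned: list[tuple[PlantTopology, SiteCallMatrix]],
    min_bleed_reads: int = 1,
) -> list[CandidateMutation]:
    """Reject candidates whose allele shows up in co-laned unrelated samples.

    Index hopping ("sample bleeding") lets a small number of reads from one
    library appear under another library's barcode within the same sequencing
    lane. A candidate whose variant allele is supported by >= 1 bq20 read in
    an unrelated individual sequenced in the same lane is rejected.

    ``co_laned`` pairs each unrelated individual's topology with its matrix.
    Candidates are passed through unchanged (with a warning) when lane
    metadata is absent.
    """
    lanes_by_sample = {s.sample_id: s.lane_id for s in topology.samples}
    if all(v is None for v in lanes_by_sample.values()):
        warnings.warn(
            "no lane metadata on focal topology; lane-contamination filter "
            "is a no-op",
            stacklevel=2,
        )
        return list(candidates)
    out: list[CandidateMutation] = []
    for cand in candidates:
        focal_lanes = {
            lanes_by_sample.get(s)
            for s in cand.focal_samples
            if lanes_by_sample.get(s) is not None
        }
        contaminated = False
        for other_topo, other_matrix in co_laned:
            if other_topo.individual_id == topology.individual_id:
                continue
            i = other_matrix.site_index(cand.site)
            if i is None:
                continue
            for j, sample in enumerate(other_matrix.samples):
                lane = next(
                    (
                        s.lane_id
                        for s in other_topo.samples
                        if s.sample_id == sample
                    ),
                    None,
                )
                if lane is None or lane not in focal_lanes:
                    continue
                if other_matrix.mut_bq20[i, j] >= min_bleed_reads:
                    contaminated = True
                    break
            if contaminated:
                break
        if contaminated:
            out.append(
                replace(
                    cand,
                    status="rejected",
                    codes=cand.codes | {LANE_BLEED},
                )
            )
        else:
            out.append(cand)
    return out


# -- microhole / amplified-sample profile ------------------------------------


def call_sample_specific(
    matrix: SiteCallMatrix,
    topology: PlantTopology,
    cfg: FilterConfig | None = None,
) -> list[CandidateMutation]:
    """Strict caller for amplified microscale (micropunch) samples.

    Single-sample candidates are accepted only when no other sample carries
    a single identical mutant read (zero mimic reads anywhere) and the
    allele is not a preexisting polymorphism (variant status confined to the
    focal sample). Shared microhole mutations require the mutant allele in
    at least two samples, each supported by >= min_focal_reads reads.
    """
    cfg = cfg or FilterConfig()
    out: list[CandidateMutation] = []
    n = len(matrix.samples)
    for i in range(matrix.n_sites):
        focal = matrix.variant_samples(i)
        if not focal or len(focal) >= cfg.freq_cap * n:
            continue
        focal_idx = [matrix.sample_index(s) for s in focal]
        control_idx = [j for j in range(n) if j not in set(focal_idx)]
        origin = topology.lca(focal)
        if len(focal) == 1:
            if matrix.mut_reads[i][focal_idx].max() < cfg.min_focal_reads:
                continue
            if control_idx and matrix.mut_reads[i][control_idx].max(initial=0) >= 1:
                continue
        else:
            per_sample = matrix.mut_reads[i][focal_idx]
            if np.sum(per_sample >= cfg.min_focal_reads) < 2:
                continue
            if control_idx and matrix.mut_bq20[i, control_idx].max(initial=0) >= 1:
                continue
        out.append(
            CandidateMutation(
                site=matrix.sites[i],
                mut_class=classify_mutation_type(
                    matrix.sites[i].ref, matrix.sites[i].alt, cfg.max_indel_len
                ),
                focal_samples=focal,
                origin_node=origin,
                status="confidence",
                heterozygous=_heterozygous(matrix, i, focal_idx),
            )
        )
    return out


def merge_calls(
    topo_calls: list[CandidateMutation],
    freq_calls: list[CandidateMutation],
) -> list[CandidateMutation]:
    """Union of the two callers' outputs; the topology-based call wins on ties."""
    seen = {c.key for c in topo_calls}
    return list(topo_calls) + [c for c in freq_calls if c.key not in seen]
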