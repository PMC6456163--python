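"""Seeded generator of ground-truth plants, mutations, progeny and reads.

The generator emulates the data-generating process the calling pipeline
assumes, so every downstream stage can be exercised against a known truth:

* a plant grows as a branching topology over seasons; somatic mutations
  arrive on each one-year lineage segment as a Poisson process with a
  tissue-specific rate (shoot apical meristem lineages mutate slower than
  root apical lineages in perennials — the default rates mimic the leaf/root
  contrast of a ~21-year peach, 3.74 vs 29.8 accumulated mutations per
  sample);
* a mutation arising on the segment above node ``v`` is carried, fully
  (cell fraction 1) by every same-lineage sample descending from ``v``;
  current-season private mutations are mosaic within their single sample
  (cell fraction uniform on [0.25, 1], the detectability floor);
* in strawberry-style runner systems a restricted, germline-like cell
  lineage is modelled: each runner mutation is bud-competent
  ("transmissible") with a small probability and otherwise never appears in
  any sample descending from a lateral bud;
* sequencing produces ~40x negative-binomially dispersed depths,
  heterozygous mutant reads at ~0.5 allele fraction, strand splits,
  1%-per-base errors of which a quarter mimic the mutant allele, missing
  genotypes, low-rate within-lane cross-sample contamination, and
  provenance flags for two concordant-by-default upstream call sets.

Everything is driven by a single :class:`numpy.random.Generator`; with a
fixed seed the generator is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MISSING, REF, VAR, Site, SiteCallMatrix
from .topology import BranchNode, PlantTopology, SampleRecord

BASES = np.array(list("ACGT"))

# lineage tags
TAG_SOMATIC = "somatic"
TAG_TRANSMISSIBLE = "transmissible"
TAG_RESTRICTED = "restricted"


@dataclass(frozen=True)
class RunnerModel:
    """Restricted-germline model for stolon (runner) systems."""

    enabled: bool = False
    germline_fraction: float = 1.0 / 6.0
    n_segments: int = 5
    leaves_per_bud: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.germline_fraction <= 1.0):
            raise ValueError("germline_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth plant and mutation-process parameters.

    ``topology_shape`` is (n_primary_branches, depth, samples_per_tip): each
    primary branch bifurcates once per season down to ``depth`` levels and
    carries ``samples_per_tip`` leaf samples on every terminal twig. When a
    ``root`` rate is given, a root system of ``root_shape`` (default two
    primaries of the same depth) is attached with root samples.

    Rates are expected mutations per sample lineage per year. Defaults mimic
    the leaf/root contrast measured in a ~21-year peach (3.74 and 29.8
    accumulated mutations per sample, i.e. 0.178 and 1.419 per year).
    """

    topology_shape: tuple[int, int, int] = (5, 3, 2)
    genome_size: int = 225_000_000
    ploidy: int = 2
    rate_per_tissue_per_year: dict = field(
        default_factory=lambda: {"leaf": 3.74 / 21.0, "root": 29.8 / 21.0}
    )
    runner_model: RunnerModel = field(default_factory=RunnerModel)
    root_shape: tuple[int, int, int] | None = None
    private_mutation_years: float = 1.0
    mosaic_private: bool = True
    hom_fraction: float = 0.01
    class_probs: dict = field(
        default_factory=lambda: {
            "SNV": 0.90,
            "MNV": 0.02,
            "INS": 0.04,
            "DEL": 0.03,
            "RPL": 0.01,
        }
    )
    individual_id: str = "SIM1"
    lanes: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rate_per_tissue_per_year.values()):
            raise ValueError("mutation rates must be >= 0")
        if self.genome_size <= 0 or self.ploidy <= 0:
            raise ValueError("genome_size and ploidy must be positive")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")


@dataclass(frozen=True)
class SeqParams:
    """Sequencing-noise model.

    ``callset_concordance`` is (p_both, p_B_only, p_A_only) for the two
    upstream call sets (defaults follow the observed SNV concordance:
    95.5% both, 2.6% reassembly-only, 1.9% alignment-direct-only).
    ``base_error_rate`` x ``same_allele_by_chance`` gives the per-read
    probability that a sequencing error mimics the mutant allele; only
    ``error_bq20_fraction`` of such error reads survive the base-quality-20
    cut that defines a "mimic read".
    """

    mean_depth: float = 40.0
    depth_dispersion: float = 10.0
    het_fraction: float = 0.5
    base_error_rate: float = 0.01
    same_allele_by_chance: float = 0.25
    error_bq20_fraction: float = 0.25
    mut_bq20_fraction: float = 0.95
    missing_rate: float = 0.001
    lane_bleed_rate: float = 1e-3
    callset_concordance: tuple[float, float, float] = (0.955, 0.026, 0.019)
    genotype_min_reads: int = 3
    qual_per_read: float = 15.0
    n_noise_sites: int = 50
    n_polymorphic_sites: int = 10
    depth_profile: tuple | None = None

    def __post_init__(self) -> None:
        for name in (
            "het_fraction",
            "base_error_rate",
            "same_allele_by_chance",
            "error_bq20_fraction",
            "mut_bq20_fraction",
            "missing_rate",
            "lane_bleed_rate",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        if abs(sum(self.callset_concordance) - 1.0) > 1e-9:
            raise ValueError("callset_concordance must sum to 1")
        if self.mean_depth < 0 or self.depth_dispersion <= 0:
            raise ValueError("invalid depth model parameters")


@dataclass(frozen=True)
class TruthEntry:
    """One true mutation: site, origin, lineage tag and per-sample fractions."""

    site: Site
    origin_node: str
    origin_year: int
    lineage_tag: str
    fractions: dict  # sample_id -> expected cell fraction in that sample
    het: bool = True
    mut_class: str = "SNV"

    @property
    def carriers(self) -> frozenset[str]:
        return frozenset(self.fractions)


@dataclass
class TruthSet:
    """Ground truth for a simulated plant."""

    entries: list[TruthEntry] = field(default_factory=list)

    def validate(self, topology: PlantTopology) -> None:
        node_ids = {n.node_id for n in topology.nodes}
        for e in self.entries:
            if e.origin_node not in node_ids:
                raise ValueError(
                    f"truth entry {e.site} references unknown node "
                    f"{e.origin_node!r}"
                )
            for frac in e.fractions.values():
                if not (0.0 <= frac <= 1.0):
                    raise ValueError(f"cell fraction out of [0,1] at {e.site}")

    @property
    def sites(self) -> list[Site]:
        return [e.site for e in self.entries]

    @property
    def site_keys(self) -> set:
        return {e.site.key for e in self.entries}

    def per_sample_counts(self, sample_ids) -> dict[str, int]:
        counts = {s: 0 for s in sample_ids}
        for e in self.entries:
            for s in e.carriers:
                if s in counts:
                    counts[s] += 1
        return counts

    def with_tag(self, tag: str) -> list[TruthEntry]:
        return [e for e in self.entries if e.lineage_tag == tag]


# -- topology construction ---------------------------------------------------


def build_topology(params: SimulationParams) -> PlantTopology:
    """Deterministic branch topology implied by the simulation parameters."""
    n_primary, depth, per_tip = params.topology_shape
    if n_primary < 1 or depth < 1 or per_tip < 1:
        raise ValueError("topology_shape entries must be >= 1")
    nodes: list[BranchNode] = [BranchNode("P", None, 0, float(depth))]
    samples: list[SampleRecord] = []

    def lane_of(idx: int) -> str:
        return f"L{idx % params.lanes + 1}"

    counter = {"i": 0}

    def add_subtree(prefix: str, n_prim: int, d: int, per: int, tissue: str):
        tips: list[str] = []
        for b in range(1, n_prim + 1):
            frontier = [f"{prefix}{b}"]
            nodes.append(BranchNode(f"{prefix}{b}", "P", 1, float(d)))
            for level in range(2, d + 1):
                nxt = []
                for nid in frontier:
                    for c in (1, 2):
                        cid = f"{nid}.{c}"
                        nodes.append(
                            BranchNode(cid, nid, level, float(d - level + 1))
                        )
                        nxt.append(cid)
                frontier = nxt
            tips.extend(frontier)
        for tip in tips:
            for j in range(1, per + 1):
                sid = f"{tip}-{tissue[0].upper()}{j}"
                samples.append(
                    SampleRecord(
                        sid,
                        tip,
                        tissue,
                        lane_of(counter["i"]),
                        params.individual_id,
                    )
                )
                counter["i"] += 1

    add_subtree("B", n_primary, depth, per_tip, "leaf")
    if "root" in params.rate_per_tissue_per_year:
        r_prim, r_depth, r_per = params.root_shape or (2, depth, per_tip)
        add_subtree("R", r_prim, r_depth, r_per, "root")
    rm = params.runner_model
    if rm.enabled:
        prev = "P"
        for i in range(1, rm.n_segments + 1):
            seg = f"S{i}"
            nodes.append(BranchNode(seg, prev, i, float(rm.n_segments - i + 1)))
            samples.append(
                SampleRecord(
                    f"{seg}-run",
                    seg,
                    "runner",
                    lane_of(counter["i"]),
                    params.individual_id,
                )
            )
            counter["i"] += 1
            bud = f"{seg}.bud"
            nodes.append(BranchNode(bud, seg, i, float(rm.n_segments - i)))
            for j in range(1, rm.leaves_per_bud + 1):
                samples.append(
                    SampleRecord(
                        f"{bud}-L{j}",
                        bud,
                        "leaf",
                        lane_of(counter["i"]),
                        params.individual_id,
                    )
                )
                counter["i"] += 1
            prev = seg
    return PlantTopology(
        individual_id=params.individual_id,
        genome_size=params.genome_size,
        ploidy=params.ploidy,
        nodes=nodes,
        samples=samples,
        age_years=float(depth),
    )


def _node_lineage_tissue(topology: PlantTopology, node_id: str) -> str:
    """Tissue whose meristem lineage a branch node belongs to."""
    path = topology.path_to_root(node_id)
    if any(p.startswith("R") for p in path[:-1]):
        return "root"
    if node_id.startswith("S") and ".bud" not in node_id:
        return "runner"
    return "leaf"


def _draw_alleles(rng: np.random.Generator, mut_class: str) -> tuple[str, str]:
    def seq(k):
        return "".join(rng.choice(BASES, size=k))

    if mut_class == "SNV":
        ref = seq(1)
        alt = rng.choice([b for b in "ACGT" if b != ref])
        return ref, str(alt)
    if mut_class == "MNV":
        ref = seq(2)
        alt = "".join(
            rng.choice([b for b in "ACGT" if b != r]) for r in ref
        )
        return ref, alt
    if mut_class == "INS":
        ref = seq(1)
        return ref, ref + seq(int(rng.integers(1, 4)))
    if mut_class == "DEL":
        keep = seq(1)
        return keep + seq(int(rng.integers(1, 4))), keep
    ref = seq(2)  # RPL
    return ref, seq(3)


def _unique_positions(
    rng: np.random.Generator, n: int, genome_size: int, taken: set[int]
) -> list[int]:
    out: list[int] = []
    while len(out) < n:
        draw = rng.integers(1, genome_size + 1, size=max(2 * (n - len(out)), 8))
        for p in draw:
            p = int(p)
            if p not in taken:
                taken.add(p)
                out.append(p)
                if len(out) == n:
                    break
    return out


# -- plant + truth -----------------------------------------------------------


def simulate_plant(
    params: SimulationParams,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PlantTopology, TruthSet]:
    """Grow a plant and place true mutations on its lineage segments.

    Mutations arrive on each one-season branch segment as Poisson draws with
    the lineage-appropriate tissue rate and are carried by every
    same-lineage descendant sample. Per-sample private (current-season)
    mutations are additionally drawn for ``private_mutation_years`` seasons
    of terminal growth and are mosaic within their sample. Runner mutations
    are tagged transmissible with probability ``germline_fraction`` and
    otherwise restricted: they never appear in lateral-bud descendants.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed if seed is None else seed)
    topology = build_topology(params)
    rates = params.rate_per_tissue_per_year
    classes = list(params.class_probs)
    class_p = np.array([params.class_probs[c] for c in classes])
    raw: list[tuple[str, int, str, dict]] = []  # origin, year, tag, fractions

    for node in topology.nodes:
        if node.parent_id is None:
            continue
        tissue = _node_lineage_tissue(topology, node.node_id)
        rate = rates.get(tissue, 0.0)
        n_mut = rng.poisson(rate) if rate > 0 else 0
        for _ in range(n_mut):
            if tissue == "runner":
                transmissible = rng.random() < params.runner_model.germline_fraction
                tag = TAG_TRANSMISSIBLE if transmissible else TAG_RESTRICTED
                carriers = []
                for nid in topology.descendants(node.node_id):
                    in_bud = ".bud" in nid
                    if in_bud and tag == TAG_RESTRICTED:
                        continue
                    carriers.extend(
                        s.sample_id for s in topology.samples_at(nid)
                    )
            else:
                tag = TAG_SOMATIC
                carriers = [
                    s.sample_id
                    for nid in topology.descendants(node.node_id)
                    for s in topology.samples_at(nid)
                ]
            if not carriers:
                continue
            raw.append(
                (node.node_id, node.year_formed, tag, {c: 1.0 for c in carriers})
            )
    current_season = max(n.year_formed for n in topology.nodes) + 1
    for sample in topology.samples:
        rate = rates.get(sample.tissue, 0.0) * params.private_mutation_years
        n_mut = rng.poisson(rate) if rate > 0 else 0
        for _ in range(n_mut):
            frac = (
                float(rng.uniform(0.25, 1.0)) if params.mosaic_private else 1.0
            )
            raw.append(
                (sample.node_id, current_season, TAG_SOMATIC, {sample.sample_id: frac})
            )

    taken: set[int] = set()
    positions = _unique_positions(rng, len(raw), params.genome_size, taken)
    entries = []
    for (origin, year, tag, fractions), pos in zip(raw, positions):
        mut_class = str(rng.choice(classes, p=class_p))
        ref, alt = _draw_alleles(rng, mut_class)
        entries.append(
            TruthEntry(
                site=Site("chr1", pos, ref, alt),
                origin_node=origin,
                origin_year=year,
                lineage_tag=tag,
                fractions=fractions,
                het=bool(rng.random() >= params.hom_fraction),
                mut_class=mut_class,
            )
        )
    entries.sort(key=lambda e: e.site.pos)
    truth = TruthSet(entries)
    truth.validate(topology)
    return topology, truth


# -- reads -------------------------------------------------------------------


def _draw_depth(
    rng: np.random.Generator, seq: SeqParams, size: int
) -> np.ndarray:
    if seq.depth_profile is not None:
        profile = np.asarray(seq.depth_profile, dtype=np.int64)
        return rng.choice(profile, size=size)
    k = seq.depth_dispersion
    p = k / (k + seq.mean_depth)
    return rng.negative_binomial(k, p, size=size)


def simulate_reads(
    topology: PlantTopology,
    truth: TruthSet,
    seq: SeqParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SiteCallMatrix:
    """Noisy read-support matrix for the truth sites plus background sites.

    Carrier samples draw mutant reads Binomial(depth, het_fraction x cell
    fraction); non-carriers draw mimic reads Binomial(depth, base_error x
    same_allele_by_chance), of which only a fraction survive the bq20 cut.
    Strand splits are Binomial(k, 1/2). Genotype status is variant when the
    mutant read count reaches ``genotype_min_reads``, missing at
    ``missing_rate``. Background rows comprise pure-noise sites and
    preexisting polymorphic sites (variant in every sample); within-lane
    contamination adds occasional high-quality mutant reads to non-carriers
    that share a lane with a carrier.
    """
    seq = seq or SeqParams()
    if rng is None:
        rng = np.random.default_rng(seed)
    samples = topology.sample_ids
    m = len(samples)
    sample_lane = {
        s.sample_id: s.lane_id for s in topology.samples
    }

    sites: list[Site] = list(truth.sites)
    if len({s.key for s in sites}) != len(sites):
        raise ValueError("truth sites must be unique")
    frac_rows = []
    het_flags = []
    for e in truth.entries:
        frac_rows.append(
            np.array([e.fractions.get(s, 0.0) for s in samples])
        )
        het_flags.append(e.het)
    taken = {s.pos for s in sites}
    genome_size = topology.genome_size
    extra_positions = _unique_positions(
        rng, seq.n_noise_sites + seq.n_polymorphic_sites, genome_size, taken
    )
    n_truth = len(sites)
    for pos in extra_positions[: seq.n_noise_sites]:
        ref, alt = _draw_alleles(rng, "SNV")
        sites.append(Site("chr1", pos, ref, alt))
        frac_rows.append(np.zeros(m))
        het_flags.append(True)
    for pos in extra_positions[seq.n_noise_sites:]:
        ref, alt = _draw_alleles(rng, "SNV")
        sites.append(Site("chr1", pos, ref, alt))
        frac_rows.append(np.ones(m))  # preexisting heterozygous polymorphism
        het_flags.append(True)

    n = len(sites)
    depth = _draw_depth(rng, seq, n * m).reshape(n, m).astype(np.int64)
    frac = np.vstack(frac_rows) if frac_rows else np.zeros((0, m))
    af = np.where(np.array(het_flags)[:, None], seq.het_fraction, 1.0)
    carrier = frac > 0
    p_mut = np.where(
        carrier,
        np.clip(af * frac, 0.0, 1.0),
        seq.base_error_rate * seq.same_allele_by_chance,
    )
    k = rng.binomial(depth, p_mut)
    # lane contamination: non-carriers sharing a lane with a carrier may
    # receive a few genuine (high-quality) reads of the mutant allele
    if seq.lane_bleed_rate > 0 and n_truth > 0:
        lanes = np.array([sample_lane.get(s) or "" for s in samples])
        for i in range(n_truth):
            carrier_lanes = {
                lanes[j] for j in range(m) if carrier[i, j] and lanes[j]
            }
            if not carrier_lanes:
                continue
            eligible = np.array(
                [
                    (not carrier[i, j]) and lanes[j] in carrier_lanes
                    for j in range(m)
                ]
            )
            hits = eligible & (rng.random(m) < seq.lane_bleed_rate)
            if hits.any():
                bleed = 1 + rng.poisson(1.0, size=int(hits.sum()))
                room = depth[i, hits] - k[i, hits]
                k[i, hits] = k[i, hits] + np.minimum(bleed, np.maximum(room, 0))
    fwd = rng.binomial(k, 0.5)
    rev = k - fwd
    bq20_p = np.where(carrier, seq.mut_bq20_fraction, seq.error_bq20_fraction)
    # bleed reads are genuine reads; treat their quality like mutant reads
    bq20 = rng.binomial(k, bq20_p)
    status = np.where(k >= seq.genotype_min_reads, VAR, REF).astype(np.int8)
    miss = rng.random((n, m)) < seq.missing_rate
    status[miss] = MISSING
    qual = seq.qual_per_read * k.max(axis=1)
    cs = rng.choice(3, size=n, p=list(seq.callset_concordance))
    callset_a = cs != 1  # both or A-only
    callset_b = cs != 2  # both or B-only
    return SiteCallMatrix(
        sites=sites,
        samples=samples,
        depth=depth,
        mut_fwd=fwd,
        mut_rev=rev,
        mut_bq20=np.minimum(bq20, k),
        status=status,
        variant_quality=qual,
        callset_a=callset_a,
        callset_b=callset_b,
    )


# -- progeny -----------------------------------------------------------------

TAG_INHERITED = "inherited"
TAG_PROGENY_SPECIFIC = "progeny_specific"


def simulate_progeny(
    topology: PlantTopology,
    truth: TruthSet,
    n_progeny: int,
    mode: str = "selfed",
    p_transmit: float = 0.5,
    meiotic_rate: float = 4.6,
    parent_branch: str | None = None,
    seq: SeqParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[PlantTopology, TruthSet, SiteCallMatrix]:
    """Mendelian transmission of branch-fixed mutations to seeds.

    Heterozygous mutations fixed in the gametogenic branch (origin on the
    path from the plant base to ``parent_branch``, excluding
    runner-restricted lineages) transmit to each seed independently with
    ``p_transmit`` (default 1/2: one transmitted gamete per seed; strict
    selfing of a heterozygote would give 3/4 presence, selectable via
    ``p_transmit=0.75``). Each progeny additionally receives
    Poisson(``meiotic_rate``) private (meiosis- or early-embryo-derived)
    mutations. Returns the progeny topology, truth and read matrix.
    """
    if n_progeny < 1:
        raise ValueError("n_progeny must be >= 1")
    if not (0.0 <= p_transmit <= 1.0):
        raise ValueError("p_transmit must be a probability")
    if mode not in ("selfed", "outcrossed"):
        raise ValueError("mode must be 'selfed' or 'outcrossed'")
    if rng is None:
        rng = np.random.default_rng(seed)
    if parent_branch is None:
        leaf_samples = [s for s in topology.samples if s.tissue == "leaf"]
        parent_branch = (
            leaf_samples[0].node_id if leaf_samples else topology.root
        )
    lineage = set(topology.path_to_root(parent_branch))
    heritable = [
        e
        for e in truth.entries
        if e.origin_node in lineage and e.lineage_tag != TAG_RESTRICTED
    ]
    nodes = [BranchNode("P", None, 0)]
    samples = []
    for j in range(1, n_progeny + 1):
        nid = f"FR{j}"
        nodes.append(BranchNode(nid, "P", 1))
        samples.append(
            SampleRecord(f"FR{j}-S", nid, "seed", None, topology.individual_id)
        )
    prog_topo = PlantTopology(
        individual_id=f"{topology.individual_id}-progeny",
        genome_size=topology.genome_size,
        ploidy=topology.ploidy,
        nodes=nodes,
        samples=samples,
    )
    entries: list[TruthEntry] = []
    for e in heritable:
        carried = {
            f"FR{j}-S": 1.0
            for j in range(1, n_progeny + 1)
            if rng.random() < p_transmit
        }
        if carried:
            entries.append(
                TruthEntry(
                    site=e.site,
                    origin_node="P",
                    origin_year=0,
                    lineage_tag=TAG_INHERITED,
                    fractions=carried,
                    het=e.het,
                    mut_class=e.mut_class,
                )
            )
    taken = {e.site.pos for e in truth.entries}
    for j in range(1, n_progeny + 1):
        n_new = rng.poisson(meiotic_rate)
        for pos in _unique_positions(rng, n_new, topology.genome_size, taken):
            ref, alt = _draw_alleles(rng, "SNV")
            entries.append(
                TruthEntry(
                    site=Site("chr1", pos, ref, alt),
                    origin_node=f"FR{j}",
                    origin_year=1,
                    lineage_tag=TAG_PROGENY_SPECIFIC,
                    fractions={f"FR{j}-S": 1.0},
                )
            )
    entries.sort(key=lambda e: e.site.pos)
    prog_truth = TruthSet(entries)
    prog_truth.validate(prog_topo)
    matrix = simulate_reads(prog_topo, prog_truth, seq, rng=rng)
    return prog_topo, prog_truth, matrix


# -- cross-individual lane contamination -------------------------------------


def inject_lane_bleed(
    target: SiteCallMatrix,
    target_topology: PlantTopology,
    source: SiteCallMatrix,
    source_topology: PlantTopology,
    rate: float = 0.01,
    allele_fraction: float = 0.2,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[SiteCallMatrix, list[Site]]:
    """Contaminate ``target`` with reads from another individual's sites.

    For each variant site of ``source``, every target sample sharing a
    sequencing lane with a source carrier receives, with probability
    ``rate``, a bolus of high-quality mutant reads (Binomial(depth,
    ``allele_fraction``), at least 3) — the heavy end of index hopping.
    Returns a new matrix plus the list of injected sites.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    src_lane = {s.sample_id: s.lane_id for s in source_topology.samples}
    tgt_lane = {s.sample_id: s.lane_id for s in target_topology.samples}
    new_sites = list(target.sites)
    arrays = {
        name: getattr(target, name).copy()
        for name in ("depth", "mut_fwd", "mut_rev", "mut_bq20", "status")
    }
    qual = target.variant_quality.copy()
    csa, csb = target.callset_a.copy(), target.callset_b.copy()
    index = {s.key: i for i, s in enumerate(new_sites)}
    injected: list[Site] = []
    m = len(target.samples)
    for i_src in range(source.n_sites):
        carriers = source.variant_samples(i_src)
        lanes = {src_lane.get(s) for s in carriers} - {None}
        if not lanes:
            continue
        site = source.sites[i_src]
        hit_any = False
        for j, sample in enumerate(target.samples):
            if tgt_lane.get(sample) not in lanes:
                continue
            if rng.random() >= rate:
                continue
            if site.key not in index:
                index[site.key] = len(new_sites)
                new_sites.append(site)
                for name in arrays:
                    pad = np.zeros((1, m), dtype=arrays[name].dtype)
                    arrays[name] = np.vstack([arrays[name], pad])
                arrays["depth"][-1] = np.maximum(
                    rng.poisson(40.0, size=m), 1
                )
                qual = np.append(qual, 0.0)
                csa = np.append(csa, True)
                csb = np.append(csb, True)
            i_tgt = index[site.key]
            d = int(arrays["depth"][i_tgt, j])
            k = max(3, int(rng.binomial(d, allele_fraction)))
            k = min(k, d)
            f = int(rng.binomial(k, 0.5))
            arrays["mut_fwd"][i_tgt, j] = f
            arrays["mut_rev"][i_tgt, j] = k - f
            arrays["mut_bq20"][i_tgt, j] = int(rng.binomial(k, 0.95))
            arrays["status"][i_tgt, j] = VAR if k >= 3 else REF
            qual[i_tgt] = max(qual[i_tgt], 15.0 * k)
            hit_any = True
        if hit_any:
            injected.append(site)
    out = SiteCallMatrix(
        sites=new_sites,
        samples=target.samples,
        depth=arrays["depth"],
        mut_fwd=arrays["mut_fwd"],
        mut_rev=arrays["mut_rev"],
        mut_bq20=np.minimum(
            arrays["mut_bq20"], arrays["mut_fwd"] + arrays["mut_rev"]
        ),
        status=arrays["status"],
        variant_quality=qual,
        callset_a=csa,
        callset_b=csb,
    )
    return out, injected
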