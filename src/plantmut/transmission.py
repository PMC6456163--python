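"""Transmissibility of premeiotic (somatic) mutations to progeny.

Mutations observed in a seedling either match a somatic mutation fixed in
the parental branch that bore the fruit ("inherited", contributing to N_t)
or are specific to the seedling ("not premeiotic": meiotic or
early-embryonic). Two ratios summarise transmissibility: N_t/N_o (inherited
over all mutations observed in progeny) and N_t/N_p (premeiotic mutations
that got transmitted over all premeiotic mutations in the parent). The
module also covers the Mendelian absence expectation (1/2)^n, the
sequential-selection test for a restricted runner germline, and per-year
mutation accumulation from within-branch carrier frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class ProgenyRecord:
    progeny_id: str
    mode: str  # "selfed" | "outcrossed"
    inherited: int
    specific: int | None  # None for outcrossed progeny (undetermined)


@dataclass(frozen=True)
class TransmissionSummary:
    """Pooled inherited/observed accounting over a set of progeny.

    ``n_t`` and ``n_o`` pool the selfed progeny only: for outcrossed seeds
    the progeny-specific mutations cannot be separated from the unrelated
    pollen parent's variants, so their specific counts stay undetermined
    and they contribute to the mean inherited count only.
    """

    per_progeny: tuple[ProgenyRecord, ...]
    n_t: int  # premeiotic mutations transmitted (pooled, selfed)
    n_o: int  # total mutations observed in (selfed) progeny

    def __post_init__(self) -> None:
        if self.n_t < 0 or self.n_o < 0 or self.n_t > self.n_o:
            raise ValueError("need 0 <= N_t <= N_o")

    @property
    def ratio_nt_no(self) -> float:
        return self.n_t / self.n_o if self.n_o else 0.0

    @property
    def mean_inherited(self) -> float:
        recs = self.per_progeny
        return sum(r.inherited for r in recs) / len(recs) if recs else 0.0

    @property
    def mean_specific(self) -> float:
        known = [r.specific for r in self.per_progeny if r.specific is not None]
        return sum(known) / len(known) if known else 0.0


def classify_progeny_mutations(
    progeny_calls: dict,
    parent_mutations,
    modes: dict | str = "selfed",
) -> TransmissionSummary:
    """Label each progeny mutation inherited or progeny-specific.

    Parameters
    ----------
    progeny_calls:
        Mapping progeny id -> set of mutation keys called in that seedling.
    parent_mutations:
        Set of mutation keys of premeiotic (somatic) mutations fixed in the
        gametogenic parental branch.
    modes:
        Either a single mode for all progeny or a mapping progeny id ->
        mode. Outcrossed progeny contribute inherited counts only.
    """
    parent = set(parent_mutations)
    records = []
    n_t = n_o = 0
    for pid in progeny_calls:
        calls = set(progeny_calls[pid])
        mode = modes if isinstance(modes, str) else modes.get(pid, "selfed")
        if mode not in ("selfed", "outcrossed"):
            raise ValueError(f"progeny {pid!r}: unknown mode {mode!r}")
        inherited = len(calls & parent)
        if mode == "selfed":
            specific = len(calls - parent)
            n_t += inherited
            n_o += inherited + specific
        else:
            specific = None
        records.append(ProgenyRecord(pid, mode, inherited, specific))
    return TransmissionSummary(tuple(records), n_t, n_o)


def summary_from_counts(
    inherited,
    specific,
    modes=None,
) -> TransmissionSummary:
    """Build a summary directly from per-progeny count tables.

    ``specific`` entries may be None for outcrossed progeny; ``modes``
    defaults to "outcrossed" exactly where specific is None.
    """
    records = []
    n_t = n_o = 0
    for i, inh in enumerate(inherited):
        spec = specific[i] if i < len(specific) else None
        mode = (
            modes[i]
            if modes is not None
            else ("outcrossed" if spec is None else "selfed")
        )
        if mode == "selfed":
            if spec is None:
                raise ValueError("selfed progeny needs a specific count")
            n_t += inh
            n_o += inh + spec
        else:
            spec = None
        records.append(ProgenyRecord(f"FR{i + 1}", mode, inh, spec))
    return TransmissionSummary(tuple(records), n_t, n_o)


@dataclass(frozen=True)
class NpRatio:
    per_individual: tuple[float, ...]
    pooled: float
    n_t: int
    n_p: int


def transmissibility_np(
    parent_premeiotic_counts,
    transmitted_counts,
) -> NpRatio:
    """Pooled N_t/N_p: transmitted premeiotic over all premeiotic mutations.

    Inputs are per-individual (or per-experiment) counts; the pooled ratio
    is the ratio of the sums.
    """
    premeiotic = [int(x) for x in parent_premeiotic_counts]
    transmitted = [int(x) for x in transmitted_counts]
    if len(premeiotic) != len(transmitted):
        raise ValueError("count vectors must have equal length")
    for p, t in zip(premeiotic, transmitted):
        if t < 0 or p < 0 or t > p:
            raise ValueError(f"need 0 <= transmitted ({t}) <= premeiotic ({p})")
    per = tuple(t / p if p else 0.0 for p, t in zip(premeiotic, transmitted))
    n_t, n_p = sum(transmitted), sum(premeiotic)
    return NpRatio(per, n_t / n_p if n_p else 0.0, n_t, n_p)


def expected_absence_probability(n_seeds: int) -> float:
    """P(no seed inherits a heterozygous branch mutation) = (1/2)^n.

    Treats each seed as receiving one maternal gamete, half of which carry
    the mutant allele. (Under strict selfing of a heterozygote the presence
    probability per seed is 3/4; the single-gamete form is used for the
    absence expectation.)
    """
    if n_seeds < 0:
        raise ValueError("n_seeds must be >= 0")
    return 0.5 ** n_seeds


@dataclass(frozen=True)
class RunnerTestInput:
    """Sequential lateral-bud selection observations along a runner.

    ``bud_mutation_sets`` lists, for each lateral bud in order of
    appearance, the set of runner-mutation ids present in the runner at
    that bud. ``observed_transmitted`` is the single mutation seen in every
    bud's descendants.
    """

    bud_mutation_sets: tuple[frozenset, ...]
    observed_transmitted: object

    def __post_init__(self) -> None:
        for i, s in enumerate(self.bud_mutation_sets):
            if not s:
                raise ValueError(f"bud {i} has an empty mutation set")
            if self.observed_transmitted not in s:
                raise ValueError(
                    "observed mutation must be available at every bud"
                )


@dataclass(frozen=True)
class RunnerTestResult:
    p_value: float
    n_buds: int
    note: str


def runner_germline_test(test_input) -> RunnerTestResult:
    """Probability that the same mutation is picked at every lateral bud.

    Null: each lateral bud independently samples exactly one of the runner
    mutations available at its position, uniformly at random. The first
    bud's pick is conditioned on (no probability attaches to which mutation
    starts the streak); the p-value is the product of 1/|set_i| over the
    remaining buds. With bud sets of sizes (5, 5, 6, 6, 6) this is
    1/5 x (1/6)^3 ~ 9.3e-4.

    Accepts a :class:`RunnerTestInput` or a plain sequence of bud set sizes.
    A stricter cell-selection null (each bud samples founder cells, most of
    which carry no mutation) would give an even smaller probability but
    needs the unknown founder-cell number, so it is not computed.
    """
    if isinstance(test_input, RunnerTestInput):
        sizes = [len(s) for s in test_input.bud_mutation_sets]
    else:
        sizes = [int(x) for x in test_input]
    if any(s < 1 for s in sizes):
        raise ValueError("bud set sizes must be >= 1")
    if len(sizes) < 1:
        raise ValueError("need at least one bud")
    p = 1.0
    for s in sizes[1:]:
        p *= 1.0 / s
    note = (
        "mutation-selection null, first bud conditioned; a cell-selection "
        "null (founder cells mostly unmutated) would be stricter but cannot "
        "be specified without the founder-cell number"
    )
    return RunnerTestResult(p_value=p, n_buds=len(sizes), note=note)


def per_year_accumulation(branch_mutation_frequencies) -> float:
    """Mutations accumulated per leaf from within-branch carrier frequencies.

    Each mutation assigned to a season contributes carriers/n_leaves to the
    per-leaf accumulation for that season; e.g. frequencies 27/29, 14/29 and
    8/29 sum to 1.69 mutations per leaf. A mutation shared by >= 2 leaves of
    a branch predates the current season; singletons belong to the current
    season — apply that rule when splitting mutations into season groups
    before calling this.
    """
    total = 0.0
    for carriers, n_leaves in branch_mutation_frequencies:
        if n_leaves <= 0:
            raise ValueError("n_leaves must be positive")
        if not (0 <= carriers <= n_leaves):
            raise ValueError(
                f"carriers ({carriers}) must be within [0, n_leaves ({n_leaves})]"
            )
        total += carriers / n_leaves
    return total
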