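"""End-to-end demo pipeline: simulate -> call -> callability -> tree ->
transmit -> stats, with a reproducible JSON report.

Every stochastic stage receives its own child seed spawned from the run
seed, so re-running with the same configuration yields a byte-identical
report (timestamps are deliberately not recorded in the JSON body).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .callability import estimate_callable_fraction, normalize_rate
from .calling import (
    FilterConfig,
    call_frequency_based,
    call_topology_based,
    merge_calls,
)
from .simulate import (
    SeqParams,
    SimulationParams,
    simulate_plant,
    simulate_progeny,
    simulate_reads,
)
from .stats import brunner_munzel, dispersion_test, ols_fit
from .transmission import classify_progeny_mutations
from .tree import bootstrap_support, nj_tree, presence_matrix


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    """Configuration of a demo pipeline run."""

    seed: int = 0
    out_dir: str | None = None
    sim: SimulationParams = field(default_factory=SimulationParams)
    seq: SeqParams = field(default_factory=SeqParams)
    filters: FilterConfig = field(default_factory=FilterConfig)
    n_progeny: int = 11
    callability_n: int = 200
    bootstrap_reps: int = 200
    dispersion_reps: int = 10000


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full demo pipeline; returns (and optionally writes) a report."""
    seeds = _child_seeds(config.seed, 6)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": {
            name: s
            for name, s in zip(
                ("plant", "reads", "callability", "progeny", "tree", "stats"),
                seeds,
            )
        },
    }

    def stage(name):
        def deco(fn):
            try:
                report[name] = fn()
            except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
                raise PipelineError(f"[{name}] {exc}") from exc

        return deco

    state: dict = {}

    @stage("simulate")
    def _():
        topo, truth = simulate_plant(config.sim, seed=seeds[0])
        matrix = simulate_reads(topo, truth, config.seq, seed=seeds[1])
        state.update(topo=topo, truth=truth, matrix=matrix)
        return {
            "n_samples": len(topo.sample_ids),
            "n_true_mutations": len(truth.entries),
            "n_sites": matrix.n_sites,
        }

    @stage("call")
    def _():
        topo, truth, matrix = state["topo"], state["truth"], state["matrix"]
        topo_calls = call_topology_based(matrix, topo, config.filters)
        freq_calls = call_frequency_based(matrix, topo, config.filters)
        calls = merge_calls(topo_calls, freq_calls)
        state["calls"] = calls
        true_keys = truth.site_keys
        called_keys = {c.key for c in calls}
        tp = len(true_keys & called_keys)
        return {
            "n_called": len(calls),
            "n_confidence": sum(1 for c in calls if c.status == "confidence"),
            "recall": tp / len(true_keys) if true_keys else None,
            "precision": tp / len(called_keys) if called_keys else None,
            "het_fraction": (
                sum(c.heterozygous for c in calls) / len(calls)
                if calls
                else None
            ),
        }

    @stage("callability")
    def _():
        topo = state["topo"]
        res = estimate_callable_fraction(
            topo,
            config.seq,
            config.filters,
            n=config.callability_n,
            seed=seeds[2],
        )
        rate = normalize_rate(
            mean_mutations=np.mean(
                list(
                    state["truth"]
                    .per_sample_counts(topo.sample_ids)
                    .values()
                )
            ),
            genome_size=topo.genome_size,
            ploidy=topo.ploidy,
            callable_fraction=max(res.callable_fraction, 1e-9),
            age_years=topo.age_years or 1.0,
        )
        return {
            "callable_fraction": res.callable_fraction,
            "false_negative_rate": res.false_negative_rate,
            "rate_per_bp_per_year": rate.rate_per_bp_per_year,
        }

    @stage("tree")
    def _():
        calls = [c for c in state["calls"] if c.status != "rejected"]
        topo = state["topo"]
        leaf_samples = [
            s.sample_id for s in topo.samples if s.tissue in ("leaf", "root")
        ]
        pm = presence_matrix(calls, leaf_samples)
        tree = nj_tree(pm)
        support = bootstrap_support(
            pm, reps=config.bootstrap_reps, seed=seeds[4]
        )
        return {
            "newick": str(tree),
            "n_splits": len(support),
            "mean_support": (
                float(np.mean(list(support.values()))) if support else None
            ),
        }

    @stage("transmit")
    def _():
        topo, truth = state["topo"], state["truth"]
        _, prog_truth, _ = simulate_progeny(
            topo,
            truth,
            n_progeny=config.n_progeny,
            seed=seeds[3],
        )
        calls_by_progeny: dict[str, set] = {
            f"FR{j}": set() for j in range(1, config.n_progeny + 1)
        }
        for e in prog_truth.entries:
            for s in e.carriers:
                calls_by_progeny[s[: -2]].add(e.site.key)
        leaf_node = next(
            s.node_id for s in topo.samples if s.tissue == "leaf"
        )
        lineage = set(topo.path_to_root(leaf_node))
        parent_keys = {
            e.site.key
            for e in truth.entries
            if e.origin_node in lineage and e.lineage_tag != "restricted"
        }
        summary = classify_progeny_mutations(calls_by_progeny, parent_keys)
        return {
            "n_t": summary.n_t,
            "n_o": summary.n_o,
            "ratio_nt_no": summary.ratio_nt_no,
            "mean_inherited": summary.mean_inherited,
        }

    @stage("stats")
    def _():
        topo, truth = state["topo"], state["truth"]
        counts = truth.per_sample_counts(topo.sample_ids)
        leaf = [
            counts[s.sample_id]
            for s in topo.samples
            if s.tissue == "leaf"
        ]
        root = [
            counts[s.sample_id]
            for s in topo.samples
            if s.tissue == "root"
        ]
        out: dict = {}
        singletons = [
            sum(
                1
                for e in truth.entries
                if e.carriers == frozenset({s})
            )
            for s in topo.sample_ids
        ]
        if sum(singletons) > 0:
            disp = dispersion_test(
                singletons, reps=config.dispersion_reps, seed=seeds[5]
            )
            out["dispersion"] = {
                "D": disp.D,
                "p": disp.p_value,
                "sd_sim_D": disp.sd_sim_D,
            }
        if len(leaf) >= 2 and len(root) >= 2:
            bm = brunner_munzel(leaf, root)
            out["bm_leaf_vs_root"] = {
                "statistic": bm.statistic,
                "p": bm.p_value,
                "estimate": bm.estimate,
            }
        return out

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True)
        )
    return report
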