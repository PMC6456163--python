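import numpy as np
import pytest

from plantmut.matrix import MISSING, REF, VAR, Site, SiteCallMatrix
from plantmut.simulate import SimulationParams, build_topology
from plantmut.topology import BranchNode, PlantTopology, SampleRecord


@pytest.fixture
def five_branch_topology() -> PlantTopology:
    """A 40-leaf tree with five primary branches of 8 samples each,
    mirroring the layout used to illustrate the calling flowchart."""
    nodes = [BranchNode("root", None, 0)]
    samples = []
    k = 0
    for b in range(1, 6):
        nodes.append(BranchNode(f"B{b}", "root", 1))
        for _ in range(8):
            k += 1
            samples.append(SampleRecord(str(k), f"B{b}", "leaf", "L1", "T"))
    return PlantTopology("T", 225_000_000, nodes, samples)


def make_matrix(topology, site_specs):
    """Build a small SiteCallMatrix from per-site specs.

    Each spec is a dict with optional keys: pos, ref, alt, qual,
    callsets ("both"|"A"|"B"), and ``per_sample`` mapping sample_id ->
    (depth, fwd, rev, bq20, status_str). Unlisted samples default to clean
    reference support (depth 40, no mutant reads).
    """
    samples = topology.sample_ids
    m = len(samples)
    n = len(site_specs)
    depth = np.full((n, m), 40, dtype=np.int32)
    fwd = np.zeros((n, m), np.int32)
    rev = np.zeros((n, m), np.int32)
    bq20 = np.zeros((n, m), np.int32)
    status = np.zeros((n, m), np.int8)
    quals = np.zeros(n)
    csa = np.ones(n, bool)
    csb = np.ones(n, bool)
    sites = []
    stat_code = {"ref": REF, "variant": VAR, "missing": MISSING}
    for i, spec in enumerate(site_specs):
        sites.append(
            Site(
                "chr1",
                spec.get("pos", 1000 + i),
                spec.get("ref", "A"),
                spec.get("alt", "T"),
            )
        )
        quals[i] = spec.get("qual", 500.0)
        cs = spec.get("callsets", "both")
        csa[i] = cs in ("both", "A")
        csb[i] = cs in ("both", "B")
        for sid, (d, f, r, b, st) in spec.get("per_sample", {}).items():
            j = samples.index(sid)
            depth[i, j] = d
            fwd[i, j] = f
            rev[i, j] = r
            bq20[i, j] = b
            status[i, j] = stat_code[st]
    return SiteCallMatrix(
        sites=sites,
        samples=samples,
        depth=depth,
        mut_fwd=fwd,
        mut_rev=rev,
        mut_bq20=bq20,
        status=status,
        variant_quality=quals,
        callset_a=csa,
        callset_b=csb,
    )


def carrier_spec(n_reads=10, depth=40, status="variant"):
    """Clean heterozygous carrier support tuple."""
    f = n_reads // 2
    return (depth, f, n_reads - f, n_reads, status)


CALIBRATION_RATES = {"leaf": 2.0, "root": 3.0}


def calibration_run(seed, rates=None):
    """Simulate the standard calibration fixture (~200 true mutations)."""
    from plantmut.simulate import SeqParams, simulate_plant, simulate_reads

    params = SimulationParams(
        rate_per_tissue_per_year=rates or CALIBRATION_RATES, seed=seed
    )
    rng = np.random.default_rng(seed)
    topo, truth = simulate_plant(params, rng=rng)
    matrix = simulate_reads(topo, truth, SeqParams(), rng=rng)
    return topo, truth, matrix
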