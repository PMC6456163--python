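import numpy as np
import pytest

from plantmut.calling import (
    CALLSET_A_ONLY,
    CONTROL_MIMIC,
    EXCESS_MIMIC,
    FilterConfig,
    LANE_BLEED,
    LOW_DEPTH,
    LOW_QUAL,
    MANY_MISSING,
    MIMIC_MASK,
    MISSING_MASK,
    STRAND_BIAS,
    CandidateMutation,
    apply_hard_filters,
    call_frequency_based,
    call_sample_specific,
    call_topology_based,
    classify_evidence,
    classify_mutation_type,
    detect_topology_errors,
    merge_calls,
    remove_lane_contamination,
)
from plantmut.simulate import (
    SeqParams,
    SimulationParams,
    inject_lane_bleed,
    simulate_plant,
    simulate_reads,
)

from conftest import calibration_run, carrier_spec, make_matrix

CFG = FilterConfig()


class TestClassifyMutationType:
    @pytest.mark.parametrize(
        "ref, alt, expected",
        [
            ("A", "T", "SNV"),
            ("AT", "GC", "MNV"),
            ("A", "ATT", "INS"),
            ("ATT", "A", "DEL"),
            ("AC", "TGG", "RPL"),
            ("AC", "AGG", "RPL"),
        ],
    )
    def test_classes(self, ref, alt, expected):
        assert classify_mutation_type(ref, alt) == expected

    def test_overlong_indel_rejected(self):
        with pytest.raises(ValueError, match="100"):
            classify_mutation_type("A", "A" + "T" * 150)

    def test_empty_allele(self):
        with pytest.raises(ValueError, match="empty"):
            classify_mutation_type("", "T")


class TestTopologyBasedCaller:
    def test_branch_fixed_mutation_called_confidence(self, five_branch_topology):
        # a mutation fixed in all 8 samples of B1, absent elsewhere
        spec = {"per_sample": {str(i): carrier_spec(20) for i in range(1, 9)}}
        matrix = make_matrix(five_branch_topology, [spec])
        calls = call_topology_based(matrix, five_branch_topology, CFG)
        assert len(calls) == 1
        (c,) = calls
        assert c.status == "confidence"
        assert c.origin_node == "B1"
        assert c.focal_samples == frozenset(str(i) for i in range(1, 9))
        assert c.heterozygous

    def test_empty_matrix(self, five_branch_topology):
        matrix = make_matrix(five_branch_topology, [])
        assert call_topology_based(matrix, five_branch_topology, CFG) == []

    def test_cross_branch_variant_not_called(self, five_branch_topology):
        # variant in B1 and B5 samples straddles the root: left to the
        # frequency-based method
        spec = {
            "per_sample": {
                "2": carrier_spec(18),
                **{str(i): carrier_spec(18) for i in range(33, 41)},
            }
        }
        matrix = make_matrix(five_branch_topology, [spec])
        assert call_topology_based(matrix, five_branch_topology, CFG) == []

    def test_sample_mismatch_raises(self, five_branch_topology):
        matrix = make_matrix(five_branch_topology, [])
        matrix.samples[0] = "stranger"
        matrix._sample_index = {s: j for j, s in enumerate(matrix.samples)}
        with pytest.raises(ValueError, match="stranger"):
            call_topology_based(matrix, five_branch_topology, CFG)

    def test_recall_on_synthetic_truth(self):
        topo, truth, matrix = calibration_run(seed=123)
        calls = call_topology_based(matrix, topo, CFG)
        called = {c.key for c in calls}
        recall = len(truth.site_keys & called) / len(truth.site_keys)
        assert recall >= 0.90


class TestHardFilters:
    def make_candidate(self, topo, matrix, focal, origin="B1"):
        return CandidateMutation(
            site=matrix.sites[0],
            mut_class="SNV",
            focal_samples=frozenset(focal),
            origin_node=origin,
            status="confidence",
        )

    def test_clean_candidate_passes(self, five_branch_topology):
        matrix = make_matrix(
            five_branch_topology,
            [{"per_sample": {"1": (40, 3, 2, 5, "variant")}, "qual": 60.0}],
        )
        cand = self.make_candidate(five_branch_topology, matrix, {"1"})
        verdict = apply_hard_filters(cand, matrix, CFG)
        assert verdict.passed

    def test_low_quality_rejected(self, five_branch_topology):
        matrix = make_matrix(
            five_branch_topology,
            [{"per_sample": {"1": carrier_spec(10)}, "qual": 49.0}],
        )
        cand = self.make_candidate(five_branch_topology, matrix, {"1"})
        verdict = apply_hard_filters(cand, matrix, CFG)
        assert not verdict.passed and LOW_QUAL in verdict.codes

    def test_single_strand_support_rejected(self, five_branch_topology):
        matrix = make_matrix(
            five_branch_topology,
            [{"per_sample": {"1": (40, 7, 0, 7, "variant")}}],
        )
        cand = self.make_candidate(five_branch_topology, matrix, {"1"})
        verdict = apply_hard_filters(cand, matrix, CFG)
        assert not verdict.passed and STRAND_BIAS in verdict.codes

    def test_low_support_rejected(self, five_branch_topology):
        matrix = make_matrix(
            five_branch_topology,
            [{"per_sample": {"1": (40, 2, 2, 4, "variant")}}],
        )
        cand = self.make_candidate(five_branch_topology, matrix, {"1"})
        assert LOW_DEPTH in apply_hard_filters(cand, matrix, CFG).codes

    def test_shared_candidate_needs_three_reads_everywhere(
        self, five_branch_topology
    ):
        per = {str(i): carrier_spec(10) for i in range(1, 8)}
        per["8"] = (40, 1, 1, 2, "variant")  # below the 3-read sharing floor
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        cand = self.make_candidate(
            five_branch_topology, matrix, {str(i) for i in range(1, 9)}
        )
        assert LOW_DEPTH in apply_hard_filters(cand, matrix, CFG).codes

    def test_many_missing_rejected(self, five_branch_topology):
        per = {"1": carrier_spec(10)}
        per.update(
            {str(i): (0, 0, 0, 0, "missing") for i in range(9, 15)}
        )  # 6 missing > 5
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        cand = self.make_candidate(five_branch_topology, matrix, {"1"})
        assert MANY_MISSING in apply_hard_filters(cand, matrix, CFG).codes

    def test_excess_control_mimic_rejected(self, five_branch_topology):
        per = {"1": carrier_spec(10), "20": (40, 2, 2, 4, "ref")}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        cand = self.make_candidate(five_branch_topology, matrix, {"1"})
        assert EXCESS_MIMIC in apply_hard_filters(cand, matrix, CFG).codes


class TestEvidenceClassification:
    def build(self, topo, per_sample, callsets="both"):
        matrix = make_matrix(topo, [{"per_sample": per_sample, "callsets": callsets}])
        cand = CandidateMutation(
            site=matrix.sites[0],
            mut_class="SNV",
            focal_samples=frozenset({"1"}),
            origin_node="B1",
            status="confidence",
        )
        return matrix, cand

    def test_clean_candidate_is_confidence(self, five_branch_topology):
        matrix, cand = self.build(five_branch_topology, {"1": carrier_spec(10)})
        status, codes = classify_evidence(cand, matrix, CFG)
        assert status == "confidence" and not codes

    def test_two_mimic_reads_demote(self, five_branch_topology):
        matrix, cand = self.build(
            five_branch_topology,
            {"1": carrier_spec(10), "30": (40, 1, 1, 2, "ref")},
        )
        status, codes = classify_evidence(cand, matrix, CFG)
        assert status == "evaluation" and MIMIC_MASK in codes

    def test_single_mimic_read_tolerated(self, five_branch_topology):
        matrix, cand = self.build(
            five_branch_topology,
            {"1": carrier_spec(10), "30": (40, 1, 0, 1, "ref")},
        )
        status, _ = classify_evidence(cand, matrix, CFG)
        assert status == "confidence"

    def test_missing_calls_demote(self, five_branch_topology):
        matrix, cand = self.build(
            five_branch_topology,
            {"1": carrier_spec(10), "30": (0, 0, 0, 0, "missing")},
        )
        status, codes = classify_evidence(cand, matrix, CFG)
        assert status == "evaluation" and MISSING_MASK in codes

    def test_callset_a_only_demotes(self, five_branch_topology):
        matrix, cand = self.build(
            five_branch_topology, {"1": carrier_spec(10)}, callsets="A"
        )
        status, codes = classify_evidence(cand, matrix, CFG)
        assert status == "evaluation" and CALLSET_A_ONLY in codes

    def test_single_callset_mode_ignores_provenance(self, five_branch_topology):
        matrix, cand = self.build(
            five_branch_topology, {"1": carrier_spec(10)}, callsets="A"
        )
        cfg = FilterConfig(single_callset=True)
        status, _ = classify_evidence(cand, matrix, cfg)
        assert status == "confidence"


class TestFrequencyBasedCaller:
    def test_medium_frequency_site_called(self, five_branch_topology):
        # clean A->T in 4 of 40 samples, spanning two branches
        per = {s: carrier_spec(16) for s in ("1", "2", "9", "10")}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        calls = call_frequency_based(matrix, five_branch_topology, CFG)
        assert len(calls) == 1
        assert calls[0].focal_samples == frozenset({"1", "2", "9", "10"})

    def test_high_frequency_site_never_called(self, five_branch_topology):
        # variant in 36 of 40 samples (>= 0.8N): indistinguishable from a
        # preexisting variant with dropout
        per = {str(i): carrier_spec(16) for i in range(1, 37)}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        assert call_frequency_based(matrix, five_branch_topology, CFG) == []

    def test_single_control_mimic_read_rejects(self, five_branch_topology):
        per = {s: carrier_spec(16) for s in ("1", "2", "9", "10")}
        per["25"] = (40, 1, 0, 1, "ref")
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        calls = call_frequency_based(
            matrix, five_branch_topology, CFG, keep_rejected=True
        )
        assert len(calls) == 1
        assert calls[0].status == "rejected"
        assert CONTROL_MIMIC in calls[0].codes

    def test_topology_calls_recoverable_by_frequency_caller(self):
        # cross-caller consistency: any within-branch call with clean
        # controls is also found by the frequency-based method
        topo, truth, matrix = calibration_run(seed=77)
        topo_calls = call_topology_based(matrix, topo, CFG)
        freq_keys = {
            c.key for c in call_frequency_based(matrix, topo, CFG)
        }
        for cand in topo_calls:
            i = matrix.site_index(cand.site)
            focal = {matrix.sample_index(s) for s in cand.focal_samples}
            controls = [
                j for j in range(len(matrix.samples)) if j not in focal
            ]
            clean = matrix.mut_bq20[i, controls].max(initial=0) == 0
            if clean and len(cand.focal_samples) < 0.8 * len(matrix.samples):
                assert cand.key in freq_keys


class TestTopologyErrorDetection:
    def test_sister_branches_reported(self, five_branch_topology):
        # B1 and B2 jointly carry two mutations: suggest a sister grouping
        specs = []
        for pos in (100, 200):
            per = {str(i): carrier_spec(14) for i in range(1, 17)}
            specs.append({"pos": pos, "per_sample": per})
        matrix = make_matrix(five_branch_topology, specs)
        freq = call_frequency_based(matrix, five_branch_topology, CFG)
        report = detect_topology_errors(freq, [], five_branch_topology)
        assert report.branch_pairs.get(frozenset({"B1", "B2"})) == 2

    def test_misrecorded_sample_flagged(self, five_branch_topology):
        # sample 2 (recorded in B1) always shares mutations with B5
        specs = []
        for pos in (100, 200, 300):
            per = {"2": carrier_spec(14)}
            per.update({str(i): carrier_spec(14) for i in range(33, 41)})
            specs.append({"pos": pos, "per_sample": per})
        matrix = make_matrix(five_branch_topology, specs)
        freq = call_frequency_based(matrix, five_branch_topology, CFG)
        report = detect_topology_errors(freq, [], five_branch_topology)
        assert "2" in report.sample_flags
        branch, n = report.sample_flags["2"]
        assert branch == "B5" and n == 3

    def test_no_cross_branch_sharing_empty_report(self, five_branch_topology):
        per = {str(i): carrier_spec(14) for i in range(1, 9)}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        freq = call_frequency_based(matrix, five_branch_topology, CFG)
        topo_calls = call_topology_based(matrix, five_branch_topology, CFG)
        report = detect_topology_errors(freq, topo_calls, five_branch_topology)
        assert report.empty


class TestLaneContamination:
    def test_allele_in_co_laned_individual_rejected(self, five_branch_topology):
        from plantmut.topology import BranchNode, PlantTopology, SampleRecord

        per = {"1": carrier_spec(10)}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        calls = call_topology_based(matrix, five_branch_topology, CFG)
        other_topo = PlantTopology(
            "OTHER",
            1_000_000,
            [BranchNode("root", None)],
            [SampleRecord("o1", "root", "leaf", "L1", "OTHER")],
        )
        other_matrix = make_matrix(
            other_topo, [{"per_sample": {"o1": (60, 2, 1, 3, "ref")}}]
        )
        filtered = remove_lane_contamination(
            calls, five_branch_topology, [(other_topo, other_matrix)]
        )
        assert filtered[0].status == "rejected"
        assert LANE_BLEED in filtered[0].codes

    def test_no_co_laned_individuals_unchanged(self, five_branch_topology):
        per = {"1": carrier_spec(10)}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        calls = call_topology_based(matrix, five_branch_topology, CFG)
        assert (
            remove_lane_contamination(calls, five_branch_topology, []) == calls
        )

    def test_missing_lane_metadata_warns(self):
        from plantmut.topology import BranchNode, PlantTopology, SampleRecord

        topo = PlantTopology(
            "X",
            1000,
            [BranchNode("root", None), BranchNode("b", "root")],
            [SampleRecord("s1", "b", "leaf", None)],
        )
        matrix = make_matrix(topo, [{"per_sample": {"s1": carrier_spec(10)}}])
        calls = call_topology_based(matrix, topo, CFG)
        with pytest.warns(UserWarning, match="lane"):
            out = remove_lane_contamination(calls, topo, [])
        assert out == calls

    def test_injected_bleed_sites_all_removed(self):
        # two individuals share a lane; heavy index hopping from B into A
        params_a = SimulationParams(
            individual_id="A",
            rate_per_tissue_per_year={"leaf": 2.0},
            topology_shape=(3, 2, 2),
        )
        params_b = SimulationParams(
            individual_id="B",
            rate_per_tissue_per_year={"leaf": 2.0},
            topology_shape=(3, 2, 2),
        )
        rng = np.random.default_rng(55)
        topo_a, truth_a = simulate_plant(params_a, rng=rng)
        topo_b, truth_b = simulate_plant(params_b, rng=rng)
        seq = SeqParams(n_noise_sites=0, n_polymorphic_sites=0)
        mat_a = simulate_reads(topo_a, truth_a, seq, rng=rng)
        mat_b = simulate_reads(topo_b, truth_b, seq, rng=rng)
        mat_a, injected = inject_lane_bleed(
            mat_a, topo_a, mat_b, topo_b, rate=0.01, rng=rng
        )
        assert injected, "fixture should inject at least one bleed site"
        calls = merge_calls(
            call_topology_based(mat_a, topo_a, CFG),
            call_frequency_based(mat_a, topo_a, CFG),
        )
        filtered = remove_lane_contamination(
            calls, topo_a, [(topo_b, mat_b)]
        )
        injected_keys = {s.key for s in injected}
        survivors = [
            c
            for c in filtered
            if c.key in injected_keys and c.status != "rejected"
        ]
        assert survivors == []
        # genuine mutations of A are untouched
        true_keys = truth_a.site_keys
        assert all(
            c.status != "rejected" or LANE_BLEED not in c.codes
            for c in filtered
            if c.key in true_keys
        )


class TestSampleSpecificProfile:
    def test_lone_sample_with_any_foreign_read_rejected(
        self, five_branch_topology
    ):
        per = {"1": carrier_spec(12), "17": (40, 1, 0, 0, "ref")}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        assert call_sample_specific(matrix, five_branch_topology, CFG) == []

    def test_clean_lone_sample_called(self, five_branch_topology):
        per = {"1": carrier_spec(12)}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        calls = call_sample_specific(matrix, five_branch_topology, CFG)
        assert len(calls) == 1

    def test_shared_microhole_needs_five_reads_in_two_samples(
        self, five_branch_topology
    ):
        per = {"1": carrier_spec(6), "2": (40, 2, 2, 4, "variant")}
        matrix = make_matrix(five_branch_topology, [{"per_sample": per}])
        assert call_sample_specific(matrix, five_branch_topology, CFG) == []
        per2 = {"1": carrier_spec(6), "2": carrier_spec(5)}
        matrix2 = make_matrix(five_branch_topology, [{"per_sample": per2}])
        assert len(call_sample_specific(matrix2, five_branch_topology, CFG)) == 1


class TestHeterozygosityProperty:
    def test_most_calls_heterozygous_on_default_data(self):
        het = total = 0
        for seed in (1, 2, 3):
            topo, truth, matrix = calibration_run(seed=seed)
            calls = merge_calls(
                call_topology_based(matrix, topo, CFG),
                call_frequency_based(matrix, topo, CFG),
            )
            het += sum(c.heterozygous for c in calls)
            total += len(calls)
        assert het / total >= 0.95
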