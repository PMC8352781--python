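import numpy as np
import pytest

from beditscan import io as bio
from beditscan.somatic import (
    PASS,
    RULE_CONTROL_PROXIMITY,
    RULE_DIPLOID,
    RULE_GENOTYPE_QUALITY,
    RULE_VAF,
    CopyRatioSegment,
    FilterThresholds,
    RegionSet,
    SampleEvidence,
    VariantRecord,
    apply_site_quality_flags,
    estimate_detection_sensitivity,
    filter_somatic_indels,
    filter_somatic_snvs,
    normalize_mutation_count,
)
from beditscan.synthetic import (
    DEFAULT_VIOLATION_RULES,
    SimulationPlan,
    simulate_clone_variant_table,
)

from conftest import make_passing_snv
from oracles import (
    record_to_dict,
    snv_cluster_members,
    snv_oracle_passes,
)


def _context(genome_length=60_000):
    callable_regions = RegionSet([("chr1", 0, genome_length), ("chr2", 0, genome_length)])
    known = RegionSet(name="known")
    segments = [CopyRatioSegment("chr1", 0, genome_length, 2.0),
                CopyRatioSegment("chr2", 0, genome_length, 2.0)]
    return callable_regions, known, segments


class TestSiteQualityFlags:
    def test_low_qd_flagged(self):
        clone, _ = make_passing_snv(QD=1.9)
        apply_site_quality_flags([clone])
        assert clone.flags == {"LowQualityDepth"}

    @pytest.mark.parametrize("annot, value, flag", [
        ("MQ", 39.9, "MappingQuality"),
        ("FS", 60.1, "StrandBias"),
        ("HaplotypeScore", 13.5, "HaplotypeScoreHigh"),
        ("MQRankSum", -13.0, "MQRankSumLow"),
        ("ReadPosRankSum", -8.5, "ReadPosRankSumLow"),
    ])
    def test_each_hard_filter(self, annot, value, flag):
        clone, _ = make_passing_snv(**{annot: value})
        apply_site_quality_flags([clone])
        assert flag in clone.flags

    def test_snp_cluster_window(self):
        # three SNVs spanning exactly 35 bp (100..134) are all cluster-flagged
        records = [make_passing_snv(position=p)[0] for p in (100, 120, 134)]
        apply_site_quality_flags(records)
        assert all("SnpCluster" in r.flags for r in records)

    def test_sparse_snvs_not_clustered(self):
        records = [make_passing_snv(position=p)[0] for p in (100, 120, 136)]
        apply_site_quality_flags(records)
        assert all("SnpCluster" not in r.flags for r in records)

    def test_missing_annotations_never_flag(self):
        clone = VariantRecord("chr1", 10, "C", "T", 150.0, {},
                              SampleEvidence(25, 12, 99))
        apply_site_quality_flags([clone])
        assert clone.flags == frozenset()

    def test_unsorted_input_rejected(self):
        records = [make_passing_snv(position=p)[0] for p in (500, 100)]
        with pytest.raises(ValueError):
            apply_site_quality_flags(records)


class TestSnvCascade:
    def test_clean_record_passes(self):
        clone, control = make_passing_snv()
        callable_regions, known, segments = _context()
        passing, tally = filter_somatic_snvs(
            [clone], [control], {"chr1", "chr2"}, known, callable_regions, segments)
        assert passing == [clone]
        assert tally == {PASS: 1}

    @pytest.mark.parametrize("kwargs, rule", [
        (dict(clone_alt=3), RULE_VAF),                      # VAF 0.12 < 0.2
        (dict(clone_gq=50), RULE_GENOTYPE_QUALITY),
        (dict(control_gq=5), RULE_GENOTYPE_QUALITY),
        (dict(control_alt=2), "control-evidence"),
        (dict(qual=95.0), "site-quality"),
        (dict(clone_depth=15, clone_alt=7), "depth"),
        (dict(MQ=55.0), "mapping-quality"),
        (dict(QD=1.5), "site-flag"),
        (dict(contig="chrX"), "autosome"),
    ])
    def test_single_rule_rejections(self, kwargs, rule):
        clone, control = make_passing_snv(**kwargs)
        callable_regions, known, segments = _context()
        passing, tally = filter_somatic_snvs(
            [clone], [control], {"chr1", "chr2"}, known, callable_regions, segments)
        assert passing == []
        assert tally == {rule: 1}

    def test_non_diploid_segment_rejected(self):
        clone, control = make_passing_snv()
        callable_regions, known, _ = _context()
        segments = [CopyRatioSegment("chr1", 0, 60_000, 2.6)]
        _, tally = filter_somatic_snvs(
            [clone], [control], {"chr1"}, known, callable_regions, segments)
        assert tally == {RULE_DIPLOID: 1}

    def test_missing_control_record_tallied_separately(self):
        clone, _ = make_passing_snv()
        callable_regions, known, segments = _context()
        passing, tally = filter_somatic_snvs(
            [clone], [], {"chr1"}, known, callable_regions, segments)
        assert passing == []
        assert tally == {"control-missing": 1}

    def test_known_polymorphism_rejected(self):
        clone, control = make_passing_snv(position=5000)
        callable_regions, _, segments = _context()
        known = RegionSet([("chr1", 4999, 5000)], role="known-polymorphism")
        _, tally = filter_somatic_snvs(
            [clone], [control], {"chr1"}, known, callable_regions, segments)
        assert tally == {"known-polymorphism": 1}


class TestIndelCascade:
    def _run(self, clone, control, extra_control=(), **kw):
        callable_regions, known, segments = _context()
        controls = [control] + list(extra_control)
        return filter_somatic_indels(
            [clone], controls, {"chr1", "chr2"}, known, callable_regions, segments)

    def test_clean_indel_passes_with_distant_control_variant(self):
        clone, control = make_passing_snv(ref="CT", alt="C", qual=260.0, control_gq=99)
        far_control = VariantRecord("chr1", 5150, "A", "G", 200.0, {},
                                    SampleEvidence(30, 15, 99))
        passing, tally = self._run(clone, control, [far_control])
        assert passing == [clone]

    def test_nearby_control_variant_rejected(self):
        clone, control = make_passing_snv(ref="CT", alt="C", qual=260.0, control_gq=99)
        near_control = VariantRecord("chr1", 5080, "A", "G", 200.0, {},
                                     SampleEvidence(30, 15, 99))
        _, tally = self._run(clone, control, [near_control])
        assert tally == {RULE_CONTROL_PROXIMITY: 1}

    def test_control_gq_must_reach_99(self):
        clone, control = make_passing_snv(ref="CT", alt="C", qual=260.0, control_gq=50)
        _, tally = self._run(clone, control)
        assert tally == {RULE_GENOTYPE_QUALITY: 1}

    def test_snv_quality_threshold_insufficient_for_indel(self):
        clone, control = make_passing_snv(ref="CT", alt="C", qual=150.0, control_gq=99)
        _, tally = self._run(clone, control)
        assert tally == {"site-quality": 1}


class TestNormalization:
    def test_direct_ratio(self):
        assert normalize_mutation_count(50, 1_250_000_000, 2_500_000_000) == 100

    def test_identity_when_fully_accounted(self):
        assert normalize_mutation_count(37, 1000, 1000) == 37

    def test_zero_count(self):
        assert normalize_mutation_count(0, 500, 1000) == 0

    def test_zero_accounted_rejected(self):
        with pytest.raises(ValueError):
            normalize_mutation_count(10, 0, 1000)


class TestDetectionSensitivity:
    def test_direct_fraction(self):
        hets = [(i, {"clone1": 0.5 if i < 80 else 0.0}) for i in range(86)]
        result = estimate_detection_sensitivity(hets)
        assert result["clone1"] == pytest.approx(80 / 86)

    def test_all_detected(self):
        hets = [(i, {"c": 0.45}) for i in range(10)]
        assert estimate_detection_sensitivity(hets)["c"] == 1.0

    def test_vaf_exactly_at_threshold_counts_detected(self):
        hets = [(0, {"c": 0.3})]
        assert estimate_detection_sensitivity(hets)["c"] == 1.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            estimate_detection_sensitivity([])


class TestAgainstOracle:
    def _bundle(self, toy_genome, tada_sig, n=1000, seed=77):
        fractions = {rule: 0.03 for rule in DEFAULT_VIOLATION_RULES}
        plan = SimulationPlan(n_snvs=n, violation_fractions=fractions, seed=seed)
        return simulate_clone_variant_table(toy_genome, plan, tada_sig)

    def test_pass_fail_matches_straight_line_oracle(self, toy_genome, tada_sig):
        bundle = self._bundle(toy_genome, tada_sig)
        passing, tally = filter_somatic_snvs(
            bundle.clone_records, bundle.control_records, bundle.autosomes,
            bundle.known_polymorphisms, bundle.callable_regions, bundle.segments)
        passing_keys = {r.key for r in passing}

        control_index = {r.key: record_to_dict(r) for r in bundle.control_records}
        known_iv = bundle.known_polymorphisms.intervals()
        callable_iv = bundle.callable_regions.intervals()
        segments = [(s.contig, s.start, s.end, s.ratio) for s in bundle.segments]
        clusters = snv_cluster_members({
            contig: [r.position for r in bundle.clone_records if r.contig == contig]
            for contig in {r.contig for r in bundle.clone_records}})
        for record in bundle.clone_records:
            expected = snv_oracle_passes(
                record_to_dict(record), control_index.get(record.key),
                set(bundle.autosomes), known_iv, callable_iv, segments, clusters)
            assert (record.key in passing_keys) == expected, record.key

    def test_tally_conserves_input_count(self, toy_genome, tada_sig):
        bundle = self._bundle(toy_genome, tada_sig, n=600, seed=5)
        passing, tally = filter_somatic_snvs(
            bundle.clone_records, bundle.control_records, bundle.autosomes,
            bundle.known_polymorphisms, bundle.callable_regions, bundle.segments)
        assert sum(tally.values()) == len(bundle.clone_records)
        assert tally[PASS] == len(passing)

    def test_generator_truth_labels_reproduced(self, toy_genome, tada_sig):
        bundle = self._bundle(toy_genome, tada_sig, n=500, seed=11)
        passing, _ = filter_somatic_snvs(
            bundle.clone_records, bundle.control_records, bundle.autosomes,
            bundle.known_polymorphisms, bundle.callable_regions, bundle.segments)
        passing_keys = {(r.contig, r.position) for r in passing}
        for row in bundle.truth.itertuples():
            assert ((row.contig, row.position) in passing_keys) == row.expected_pass

    def test_relaxing_thresholds_grows_passing_set(self, toy_genome, tada_sig):
        bundle = self._bundle(toy_genome, tada_sig, n=400, seed=23)
        args = (bundle.clone_records, bundle.control_records, bundle.autosomes,
                bundle.known_polymorphisms, bundle.callable_regions, bundle.segments)
        baseline, _ = filter_somatic_snvs(*args)
        base_keys = {r.key for r in baseline}
        for relaxed in (
            FilterThresholds(vaf_min_somatic=0.05),
            FilterThresholds(depth_min=5),
            FilterThresholds(snv_quality_min=10.0),
            FilterThresholds(clone_gq_min=20),
            FilterThresholds(mapping_quality_min=30.0),
        ):
            bigger, _ = filter_somatic_snvs(*args, relaxed)
            assert base_keys <= {r.key for r in bigger}


def test_vcf_round_trip_preserves_filter_outcome(tmp_path, toy_genome, tada_sig):
    fractions = {rule: 0.05 for rule in ("vaf", "depth", "genotype-quality")}
    plan = SimulationPlan(n_snvs=120, violation_fractions=fractions, seed=9)
    bundle = simulate_clone_variant_table(toy_genome, plan, tada_sig)
    contig_lengths = {name: len(seq) for name, seq in toy_genome.contigs}
    path = tmp_path / "pair.vcf"
    bio.write_clone_bulk_vcf(bundle.clone_records, bundle.control_records,
                             contig_lengths, path)
    clone_back, control_back = bio.read_clone_bulk_vcf(path)
    assert [r.key for r in clone_back] == [r.key for r in bundle.clone_records]

    args_orig = (bundle.clone_records, bundle.control_records, bundle.autosomes,
                 bundle.known_polymorphisms, bundle.callable_regions, bundle.segments)
    args_back = (clone_back, control_back, bundle.autosomes,
                 bundle.known_polymorphisms, bundle.callable_regions, bundle.segments)
    passing_orig, tally_orig = filter_somatic_snvs(*args_orig)
    passing_back, tally_back = filter_somatic_snvs(*args_back)
    assert {r.key for r in passing_orig} == {r.key for r in passing_back}
    assert tally_orig == tally_back
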