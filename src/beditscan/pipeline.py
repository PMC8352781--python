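"""End-to-end pipelines, group reports, and clinical-chemistry helpers.

`run_wgs_pipeline` composes the clone/bulk somatic filter cascade with
callable-length normalization, 96-class profiling, signature spike-in and
cosine-similarity scoring. `run_amplicon_pipeline` composes read simulation
(or FASTQ input), alignment and editing quantification into per-sample and
per-group summaries. Both are deterministic for a fixed seed and write plain
TSV/JSON outputs plus a manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import io as bio
from .amplicon import (
    AmpliconDesign,
    EditingSummary,
    GroupStats,
    align_read_to_amplicon,
    quantify_editing,
    summarize_groups,
)
from .signature import (
    MutationalProfile,
    SignatureVector,
    build_mutational_profile,
    cosine_similarity,
    normalize_profile_to_median,
    spike_in_signature,
    substitution_spectrum,
    write_profile_tsv,
    write_signature_tsv,
)
from .somatic import FilterThresholds, RegionSet, filter_somatic_snvs, normalize_mutation_count
from .synthetic import (
    GenomeSequence,
    SimulatedCloneBundle,
    SimulationPlan,
    generate_reference,
    generate_tada_like_signature,
    simulate_amplicon_reads,
    simulate_clone_variant_table,
)

FRIEDEWALD_TG_LIMIT_MMOL_L = 4.52


@dataclass(frozen=True)
class FriedewaldResult:
    """LDL estimate in mmol/L with a validity flag for high triglycerides."""

    value: float
    triglycerides_exceed_validity: bool

    def __float__(self) -> float:
        return self.value


def friedewald_ldl(
    total_cholesterol: float, hdl: float, triglycerides: float
) -> FriedewaldResult:
    """Friedewald LDL estimate, mmol/L units: LDL = TC - HDL - TG / 2.2.

    The formula loses validity above 4.52 mmol/L triglycerides (400 mg/dL);
    such inputs are flagged on the result rather than rejected.
    """
    if total_cholesterol < 0 or hdl < 0 or triglycerides < 0:
        raise ValueError("lipid concentrations must be non-negative")
    return FriedewaldResult(
        value=total_cholesterol - hdl - triglycerides / 2.2,
        triglycerides_exceed_validity=triglycerides > FRIEDEWALD_TG_LIMIT_MMOL_L,
    )


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class WgsSimulationSettings:
    """Study conditions of the simulated clone/bulk experiment."""

    n_contigs: int = 2
    contig_length: int = 60_000
    gc_fraction: float = 0.42
    n_snvs: int = 428
    background_weight: float = 1.0
    tada_weight: float = 0.0
    depth_mean: float = 30.0
    depth_dispersion: float = 10.0
    clone_vaf: float = 0.5
    tada_concentration: float = 10.0
    violation_fractions: dict = field(default_factory=dict)


@dataclass
class AmpliconSampleSettings:
    n_reads: int = 5000
    target_rate: float = 0.6
    bystander_rate: float = 0.3
    indel_rate: float = 0.003
    error_rate: float = 0.001


@dataclass
class AnalysisConfig:
    """Single configuration object for all stages; defaults are the published
    pipeline constants (428 median SNVs, spike-in 10/25/50/100, q=90, ...)."""

    outdir: str = "beditscan_out"
    seed: int = 0
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    spike_levels: tuple[int, ...] = (10, 25, 50, 100)
    median_snvs: int = 428
    q: float = 90.0
    min_treated_reads: int = 10
    control_ref_fraction_min: float = 0.99
    reference_length: int | None = None
    wgs_simulation: WgsSimulationSettings = field(default_factory=WgsSimulationSettings)
    amplicon_groups: dict[str, list[AmpliconSampleSettings]] = field(default_factory=dict)
    # optional real inputs (paths); when unset the simulators provide them
    clone_bulk_vcf: str | None = None
    callable_bed: str | None = None
    known_polymorphisms_bed: str | None = None
    segments_tsv: str | None = None
    tada_signature_tsv: str | None = None
    reference_fasta: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        data = dict(data)
        if "thresholds" in data and isinstance(data["thresholds"], Mapping):
            t = dict(data["thresholds"])
            if "diploid_ratio_bounds" in t:
                t["diploid_ratio_bounds"] = tuple(t["diploid_ratio_bounds"])
            data["thresholds"] = FilterThresholds(**t)
        if "wgs_simulation" in data and isinstance(data["wgs_simulation"], Mapping):
            data["wgs_simulation"] = WgsSimulationSettings(**data["wgs_simulation"])
        if "amplicon_groups" in data:
            data["amplicon_groups"] = {
                group: [AmpliconSampleSettings(**s) if isinstance(s, Mapping) else s
                        for s in samples]
                for group, samples in data["amplicon_groups"].items()
            }
        if "spike_levels" in data:
            data["spike_levels"] = tuple(data["spike_levels"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Interval arithmetic for the accounted (callable AND diploid) genome length


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def intersect_length(a: RegionSet, b: RegionSet) -> int:
    """Total length of the intersection of two region sets."""
    by_contig_a: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in a.intervals():
        by_contig_a.setdefault(contig, []).append((start, end))
    by_contig_b: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in b.intervals():
        by_contig_b.setdefault(contig, []).append((start, end))
    total = 0
    for contig, ivs_a in by_contig_a.items():
        ivs_b = by_contig_b.get(contig)
        if not ivs_b:
            continue
        merged_a, merged_b = _merge(ivs_a), _merge(ivs_b)
        i = j = 0
        while i < len(merged_a) and j < len(merged_b):
            lo = max(merged_a[i][0], merged_b[j][0])
            hi = min(merged_a[i][1], merged_b[j][1])
            if lo < hi:
                total += hi - lo
            if merged_a[i][1] < merged_b[j][1]:
                i += 1
            else:
                j += 1
    return total


def _diploid_region_set(segments, bounds) -> RegionSet:
    lo, hi = bounds
    return RegionSet(((s.contig, s.start, s.end) for s in segments if lo < s.ratio < hi),
                     name="diploid", role="callable")


# ---------------------------------------------------------------------------
# WGS pipeline


@dataclass
class WgsReport:
    n_input_records: int
    n_passing_snvs: int
    rejection_tally: dict[str, int]
    accounted_length: int
    reference_length: int
    normalized_mutation_count: float
    spectrum: dict[str, float] | None
    spike_similarities: dict[int, float]
    baseline_similarity: float | None
    config_hash: str
    seed: int


def run_wgs_pipeline(config: AnalysisConfig) -> WgsReport:
    """Filter cascade -> length normalization -> profile -> spike-in grid.

    Inputs are read from the configured paths when given, otherwise simulated
    from `config.wgs_simulation` under `config.seed`. All stage outputs are
    written under `config.outdir`.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = config.wgs_simulation
    t = config.thresholds

    if config.clone_bulk_vcf is not None:
        clone_records, control_records = bio.read_clone_bulk_vcf(config.clone_bulk_vcf)
        genome = bio.read_fasta(config.reference_fasta) if config.reference_fasta else None
        callable_regions = bio.read_bed(config.callable_bed, role="callable")
        known_poly = (bio.read_bed(config.known_polymorphisms_bed, role="known-polymorphism")
                      if config.known_polymorphisms_bed else RegionSet(name="known"))
        segments = bio.read_segments_tsv(config.segments_tsv)
        autosomes = genome.autosome_names if genome else frozenset(
            {r.contig for r in clone_records})
        tada = bio_read_signature(config.tada_signature_tsv) if config.tada_signature_tsv else \
            generate_tada_like_signature(sim.tada_concentration, config.seed + 1)
    else:
        genome = generate_reference(sim.n_contigs, sim.contig_length, sim.gc_fraction,
                                    config.seed)
        tada = generate_tada_like_signature(sim.tada_concentration, config.seed + 1)
        plan = SimulationPlan(
            n_snvs=sim.n_snvs,
            background_weight=sim.background_weight,
            tada_weight=sim.tada_weight,
            depth_mean=sim.depth_mean,
            depth_dispersion=sim.depth_dispersion,
            clone_vaf=sim.clone_vaf,
            violation_fractions=sim.violation_fractions,
            seed=config.seed + 2,
        )
        bundle = simulate_clone_variant_table(genome, plan, tada)
        clone_records = bundle.clone_records
        control_records = bundle.control_records
        callable_regions = bundle.callable_regions
        known_poly = bundle.known_polymorphisms
        segments = bundle.segments
        autosomes = bundle.autosomes
        bundle.truth.to_csv(outdir / "truth_labels.tsv", sep="\t", index=False)

    passing, tally = filter_somatic_snvs(
        clone_records, control_records, autosomes, known_poly,
        callable_regions, segments, t)

    diploid_regions = _diploid_region_set(segments, t.diploid_ratio_bounds)
    accounted = intersect_length(callable_regions, diploid_regions)
    reference_length = config.reference_length or (
        genome.total_length if genome else accounted)
    normalized = normalize_mutation_count(len(passing), accounted, reference_length)

    spectrum_labels = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    if passing and genome is not None:
        profile = build_mutational_profile(passing, genome)
        spectrum = dict(zip(spectrum_labels, substitution_spectrum(profile)))
        norm_profile = normalize_profile_to_median(profile, config.median_snvs)
        baseline = cosine_similarity(norm_profile, tada)
        spike = {0: baseline}
        for k in config.spike_levels:
            spike[k] = cosine_similarity(spike_in_signature(norm_profile, tada, k), tada)
        write_profile_tsv(profile, outdir / "mutational_profile.tsv")
        write_profile_tsv(norm_profile, outdir / "mutational_profile_normalized.tsv")
    else:
        # empty passing set (or no reference): report explicit empty markers
        spectrum = None
        baseline = None
        spike = {}
    write_signature_tsv(tada, outdir / "tada_signature.tsv")

    with open(outdir / "rejection_tally.tsv", "w") as fh:
        fh.write("rule\tcount\n")
        for rule, count in sorted(tally.items()):
            fh.write(f"{rule}\t{count}\n")

    report = WgsReport(
        n_input_records=len(clone_records),
        n_passing_snvs=len(passing),
        rejection_tally=dict(tally),
        accounted_length=accounted,
        reference_length=reference_length,
        normalized_mutation_count=normalized,
        spectrum=spectrum,
        spike_similarities=spike,
        baseline_similarity=baseline,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    with open(outdir / "wgs_report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2, default=str)
    return report


def bio_read_signature(path: str) -> SignatureVector:
    from .signature import read_signature_tsv

    return read_signature_tsv(path)


# ---------------------------------------------------------------------------
# Amplicon pipeline


def default_amplicon_design() -> AmpliconDesign:
    """Deterministic toy splice-donor-style design used by the simulators.

    The protospacer (positions 61-80 of a 140-bp amplicon) carries the target
    adenine at protospacer position 5 and a bystander adenine at position 8,
    with an AGG PAM immediately 3'.
    """
    left = ("ACGT" * 15)  # 60 bp
    protospacer = "CGTCAGCATGCTAGCTGTCT"
    pam = "AGG"
    right = ("TGCA" * 15)[:57]
    return AmpliconDesign(
        name="toy_splice_donor",
        amplicon_sequence=left + protospacer + pam + right,
        protospacer_start=61,
        protospacer_end=80,
        strand="+",
        target_adenine_position=5,
        bystander_positions=(8,),
    )


@dataclass
class AmpliconReport:
    samples: dict[str, dict]
    groups: list[GroupStats]
    config_hash: str
    seed: int


def run_amplicon_pipeline(config: AnalysisConfig,
                          design: AmpliconDesign | None = None) -> AmpliconReport:
    """Simulate (or load) amplicon reads per sample, quantify editing, and
    summarize per treatment group with mean +/- sample s.d."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = design or default_amplicon_design()
    groups = config.amplicon_groups or {
        "default": [AmpliconSampleSettings() for _ in range(3)]}

    per_sample: dict[str, dict] = {}
    group_summaries: dict[str, list[EditingSummary]] = {}
    sample_seed = config.seed
    for group, samples in groups.items():
        group_summaries[group] = []
        for i, settings in enumerate(samples):
            sample_seed += 1
            name = f"{group}_{i + 1}"
            rates = {
                design.protospacer_to_amplicon(design.target_adenine_position):
                    settings.target_rate,
            }
            for b in design.bystander_positions:
                rates[design.protospacer_to_amplicon(b)] = settings.bystander_rate
            reads = simulate_amplicon_reads(
                design, rates, settings.indel_rate, settings.error_rate,
                settings.n_reads, seed=sample_seed)
            aligned = [align_read_to_amplicon(r.sequence, design, r.name) for r in reads]
            summary = quantify_editing(aligned, design, sample=name)
            group_summaries[group].append(summary)
            per_sample[name] = {
                "group": group,
                "n_reads": summary.n_reads_total,
                "target_a_to_g_percent": summary.target_a_to_g_percent,
                "indel_percent": summary.indel_percent,
            }

    stats = summarize_groups(group_summaries)
    report = AmpliconReport(
        samples=per_sample,
        groups=stats,
        config_hash=config.config_hash(),
        seed=config.seed,
    )
    with open(outdir / "amplicon_report.json", "w") as fh:
        json.dump({
            "samples": per_sample,
            "groups": [dataclasses.asdict(g) for g in stats],
            "config_hash": report.config_hash,
            "seed": report.seed,
        }, fh, indent=2)
    with open(outdir / "amplicon_groups.tsv", "w") as fh:
        fh.write("group\tn\tmean_target_percent\tsd_target_percent"
                 "\tmean_indel_percent\tsd_indel_percent\n")
        for g in stats:
            sd_t = "" if g.sd_target_percent is None else f"{g.sd_target_percent:.6g}"
            sd_i = "" if g.sd_indel_percent is None else f"{g.sd_indel_percent:.6g}"
            fh.write(f"{g.group}\t{g.n}\t{g.mean_target_percent:.6g}\t{sd_t}"
                     f"\t{g.mean_indel_percent:.6g}\t{sd_i}\n")
    return report
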