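"""Synthetic data generators with known ground truth.

Every pipeline stage in this package can be exercised on simulated inputs that
emulate the statistical structure of the real experiments:

* toy reference genomes (small contigs standing in for chromosomes — the
  filters act per record, not per genome size);
* clone/bulk variant tables in which each somatic SNV's trinucleotide class is
  drawn from a mixture of a flat background and a T>C-concentrated deaminase
  signature, with decoy records that each violate exactly one somatic-filter
  rule;
* amplicon reads with per-position A-to-G conversion rates, small indels and
  uniform substitution error;
* treated/control RNA site tables with spiked A-to-I edits and one-rule
  decoys.

All generators are deterministic for a fixed seed, and truth labels record
which records should survive the corresponding filter stage.
"""

from __future__ import annotations

import math
from bisect import bisect_left, insort
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import somatic
from .amplicon import AmpliconDesign
from .rna import RnaSite, coverage_percentile_threshold
from .signature import (
    BASES,
    N_CLASSES,
    SUBSTITUTIONS,
    TC_INDICES,
    SignatureVector,
    reverse_complement,
)
from .somatic import (
    CopyRatioSegment,
    FilterThresholds,
    RegionSet,
    SampleEvidence,
    VariantRecord,
)

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GenomeSequence:
    """Toy reference genome: named contigs plus a declared autosome subset."""

    contigs: list[tuple[str, str]]
    autosome_names: frozenset = frozenset()

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("contig names must be unique")
        for name, seq in self.contigs:
            if not seq:
                raise ValueError(f"contig {name} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"contig {name} contains non-ACGT characters")
        if not self.autosome_names:
            self.autosome_names = frozenset(names)
        self.autosome_names = frozenset(self.autosome_names)

    def sequence(self, name: str) -> str:
        for n, seq in self.contigs:
            if n == name:
                return seq
        raise KeyError(name)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)


def generate_reference(
    n_contigs: int, contig_length: int, gc_fraction: float, seed: int
) -> GenomeSequence:
    """i.i.d. random genome with the requested GC content."""
    if n_contigs < 1:
        raise ValueError("need at least one contig")
    if contig_length < 1000:
        raise ValueError("contig length must be >= 1000")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1 - gc_fraction) / 2
    gc = gc_fraction / 2
    p = [at, gc, gc, at]  # A, C, G, T
    contigs = []
    for i in range(n_contigs):
        seq = rng.choice(_BASE_BYTES, size=contig_length, p=p).tobytes().decode()
        contigs.append((f"chr{i + 1}", seq))
    return GenomeSequence(contigs)


def generate_tada_like_signature(concentration: float, seed: int) -> SignatureVector:
    """Dirichlet-random T>C-only signature standing in for a deaminase motif.

    All probability mass sits on the 16 T>C trinucleotide classes (other
    substitutions do not contribute); ``concentration`` controls how uniform
    the mass is over those 16 classes.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    probs = np.zeros(N_CLASSES)
    probs[TC_INDICES] = rng.dirichlet([concentration] * len(TC_INDICES))
    return SignatureVector(probs, name="tada-like")


# ---------------------------------------------------------------------------
# Clone/bulk WGS variant tables


@dataclass
class QualityModel:
    """Ranges the site/genotype quality annotations are drawn from.

    The filter cascade consumes annotations, not alignments, so qualities are
    sampled from configurable ranges chosen to pass the default thresholds;
    decoys override single fields.
    """

    site_quality_range: tuple[float, float] = (150.0, 1500.0)
    qd_range: tuple[float, float] = (10.0, 35.0)
    mq_value: float = 60.0
    fs_range: tuple[float, float] = (0.0, 10.0)
    clone_gq: int = 99
    control_gq_range: tuple[int, int] = (30, 99)


DEFAULT_VIOLATION_RULES = (
    somatic.RULE_CONTROL_EVIDENCE,
    somatic.RULE_SITE_FLAG,
    somatic.RULE_SITE_QUALITY,
    somatic.RULE_DEPTH,
    somatic.RULE_MAPPING_QUALITY,
    somatic.RULE_KNOWN_POLYMORPHISM,
    somatic.RULE_GENOTYPE_QUALITY,
    somatic.RULE_VAF,
    somatic.RULE_CALLABLE,
    somatic.RULE_DIPLOID,
)


@dataclass
class SimulationPlan:
    """Parameters of one simulated clone/bulk WGS experiment."""

    n_snvs: int = 428
    background_weight: float = 1.0
    tada_weight: float = 0.0
    depth_mean: float = 30.0
    depth_dispersion: float = 10.0
    clone_vaf: float = 0.5
    quality_model: QualityModel = field(default_factory=QualityModel)
    violation_fractions: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_weight < 0 or self.tada_weight < 0:
            raise ValueError("mixture weights must be non-negative")
        if abs(self.background_weight + self.tada_weight - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if not 0 < self.clone_vaf <= 1:
            raise ValueError("clone_vaf must lie in (0, 1]")
        unknown = set(self.violation_fractions) - set(DEFAULT_VIOLATION_RULES)
        if unknown:
            raise ValueError(f"unknown violation rules: {sorted(unknown)}")
        if sum(self.violation_fractions.values()) > 1:
            raise ValueError("violation fractions sum to more than 1")


@dataclass
class SimulatedCloneBundle:
    """Clone/bulk variant tables plus the region context and truth labels."""

    clone_records: list[VariantRecord]
    control_records: list[VariantRecord]
    truth: pd.DataFrame
    callable_regions: RegionSet
    known_polymorphisms: RegionSet
    segments: list[CopyRatioSegment]
    autosomes: frozenset


def _negative_binomial(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def _build_trinuc_index(genome: GenomeSequence) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in genome.contigs:
        for i in range(1, len(seq) - 1):
            index.setdefault(seq[i - 1:i + 2], []).append((name, i + 1))
    return index


def simulate_clone_variant_table(
    genome: GenomeSequence,
    plan: SimulationPlan,
    tada_signature: SignatureVector,
    min_spacing: int | None = None,
) -> SimulatedCloneBundle:
    """Simulate a clone variant table with paired bulk control and truth labels.

    Each somatic SNV's 96-class is drawn from
    ``background_weight * uniform + tada_weight * tada_signature`` and placed
    at a genome position carrying the required trinucleotide context (on
    either strand). Variants are kept at least ``min_spacing`` bases apart
    (default: the SnpCluster window) so no record accidentally trips the
    cluster flag. A ``violation_fractions`` entry of e.g. ``{"vaf": 0.1}``
    turns 10% of records into decoys that violate exactly the named rule;
    all remaining records are built to pass the full cascade.
    """
    rng = np.random.default_rng(plan.seed)
    thresholds = FilterThresholds()
    if min_spacing is None:
        min_spacing = thresholds.cluster_window
    qm = plan.quality_model

    mixture = plan.background_weight / N_CLASSES + plan.tada_weight * tada_signature.probabilities
    mixture = mixture / mixture.sum()

    trinuc_index = _build_trinuc_index(genome)
    used: dict[str, list[int]] = {name: [] for name, _ in genome.contigs}

    def spacing_ok(contig: str, pos: int) -> bool:
        positions = used[contig]
        i = bisect_left(positions, pos)
        if i < len(positions) and positions[i] - pos < min_spacing:
            return False
        if i > 0 and pos - positions[i - 1] < min_spacing:
            return False
        return True

    # class -> candidate (contig, pos, ref, alt) choices on either strand
    def draw_site(class_idx: int) -> tuple[str, int, str, str]:
        sub = SUBSTITUTIONS[class_idx // 16]
        five = BASES[(class_idx % 16) // 4]
        three = BASES[class_idx % 4]
        ref, alt = sub[0], sub[2]
        pyr_context = five + ref + three
        candidates: list[tuple[str, int, str, str]] = []
        for contig, pos in trinuc_index.get(pyr_context, ()):
            candidates.append((contig, pos, ref, alt))
        rc_ref = reverse_complement(ref)
        rc_alt = reverse_complement(alt)
        for contig, pos in trinuc_index.get(reverse_complement(pyr_context), ()):
            candidates.append((contig, pos, rc_ref, rc_alt))
        if not candidates:
            raise ValueError(f"no genome position offers context {pyr_context}")
        for _ in range(200):
            contig, pos, r, a = candidates[int(rng.integers(len(candidates)))]
            if spacing_ok(contig, pos):
                insort(used[contig], pos)
                return contig, pos, r, a
        raise ValueError("could not place variant; genome too small for n_snvs")

    n = plan.n_snvs
    classes = rng.choice(N_CLASSES, size=n, p=mixture)
    sites = [draw_site(int(c)) for c in classes]

    # assign exactly round(fraction * n) decoys per rule to random records
    rules: list[str | None] = [None] * n
    order = rng.permutation(n)
    cursor = 0
    for rule in DEFAULT_VIOLATION_RULES:
        frac = plan.violation_fractions.get(rule, 0.0)
        count = int(round(frac * n))
        for idx in order[cursor:cursor + count]:
            rules[idx] = rule
        cursor += count

    t = thresholds
    clone_records: list[VariantRecord] = []
    control_records: list[VariantRecord] = []
    known_poly_positions: list[tuple[str, int]] = []
    uncallable_positions: list[tuple[str, int]] = []
    nondiploid_positions: list[tuple[str, int]] = []
    rows = []

    for (contig, pos, ref, alt), rule in zip(sites, rules):
        clone_depth = max(t.depth_min, _negative_binomial(rng, plan.depth_mean, plan.depth_dispersion))
        control_depth = max(t.depth_min, _negative_binomial(rng, plan.depth_mean, plan.depth_dispersion))
        site_quality = float(rng.uniform(*qm.site_quality_range))
        annotations = {
            "QD": float(rng.uniform(*qm.qd_range)),
            "MQ": qm.mq_value,
            "FS": float(rng.uniform(*qm.fs_range)),
            "HaplotypeScore": float(rng.uniform(0.0, 10.0)),
            "MQRankSum": float(rng.uniform(-2.0, 2.0)),
            "ReadPosRankSum": float(rng.uniform(-2.0, 2.0)),
        }
        clone_gq = qm.clone_gq
        control_gq = int(rng.integers(qm.control_gq_range[0], qm.control_gq_range[1] + 1))
        control_alt = 0
        vaf = plan.clone_vaf

        if rule == somatic.RULE_CONTROL_EVIDENCE:
            control_alt = max(1, round(0.3 * control_depth))
        elif rule == somatic.RULE_SITE_FLAG:
            annotations["QD"] = 1.0
        elif rule == somatic.RULE_SITE_QUALITY:
            site_quality = float(rng.uniform(20.0, t.snv_quality_min - 1))
        elif rule == somatic.RULE_DEPTH:
            clone_depth = int(rng.integers(5, t.depth_min))
        elif rule == somatic.RULE_MAPPING_QUALITY:
            annotations["MQ"] = float(rng.uniform(t.mq_flag_min, t.mapping_quality_min - 1))
        elif rule == somatic.RULE_KNOWN_POLYMORPHISM:
            known_poly_positions.append((contig, pos))
        elif rule == somatic.RULE_GENOTYPE_QUALITY:
            clone_gq = int(rng.integers(10, t.clone_gq_min))
        elif rule == somatic.RULE_VAF:
            vaf = 0.1
        elif rule == somatic.RULE_CALLABLE:
            uncallable_positions.append((contig, pos))
        elif rule == somatic.RULE_DIPLOID:
            nondiploid_positions.append((contig, pos))

        clone_alt = min(clone_depth, max(1, math.ceil(clone_depth * vaf))
                        if rule != somatic.RULE_VAF else max(1, math.floor(clone_depth * vaf)))
        clone_records.append(VariantRecord(
            contig, pos, ref, alt, site_quality, annotations,
            SampleEvidence(clone_depth, clone_alt, clone_gq)))
        control_records.append(VariantRecord(
            contig, pos, ref, alt, site_quality, dict(annotations),
            SampleEvidence(control_depth, control_alt, control_gq)))
        rows.append({
            "contig": contig, "position": pos, "ref": ref, "alt": alt,
            "expected_pass": rule is None,
            "violated_rule": rule or "",
            "class_index": None,
        })
    for row, c in zip(rows, classes):
        row["class_index"] = int(c)

    key = lambda r: (r.contig, r.position)
    clone_records.sort(key=key)
    control_records.sort(key=key)
    truth_columns = ["contig", "position", "ref", "alt", "expected_pass",
                     "violated_rule", "class_index"]
    truth = (pd.DataFrame(rows, columns=truth_columns)
             .sort_values(["contig", "position"]).reset_index(drop=True))

    callable_regions = _regions_minus_points(genome, uncallable_positions, "callable")
    known_poly = RegionSet(
        ((c, p - 1, p) for c, p in known_poly_positions), name="known", role="known-polymorphism")
    segments = _segments_around_points(genome, nondiploid_positions)

    return SimulatedCloneBundle(
        clone_records=clone_records,
        control_records=control_records,
        truth=truth,
        callable_regions=callable_regions,
        known_polymorphisms=known_poly,
        segments=segments,
        autosomes=genome.autosome_names,
    )


def _regions_minus_points(
    genome: GenomeSequence, points: Sequence[tuple[str, int]], name: str
) -> RegionSet:
    """Whole-genome region set with a 1-bp hole at each excluded position."""
    holes: dict[str, list[int]] = {}
    for contig, pos in points:
        holes.setdefault(contig, []).append(pos - 1)  # to 0-based
    regions = RegionSet(name=name, role="callable")
    for contig, seq in genome.contigs:
        start = 0
        for hole in sorted(holes.get(contig, [])):
            if hole > start:
                regions.add(contig, start, hole)
            start = hole + 1
        if start < len(seq):
            regions.add(contig, start, len(seq))
    return regions


def _segments_around_points(
    genome: GenomeSequence, points: Sequence[tuple[str, int]], bad_ratio: float = 3.0
) -> list[CopyRatioSegment]:
    """Diploid (ratio 2.0) segments everywhere except 1-bp spikes at points."""
    spikes: dict[str, list[int]] = {}
    for contig, pos in points:
        spikes.setdefault(contig, []).append(pos - 1)
    segments: list[CopyRatioSegment] = []
    for contig, seq in genome.contigs:
        start = 0
        for spike in sorted(spikes.get(contig, [])):
            if spike > start:
                segments.append(CopyRatioSegment(contig, start, spike, 2.0))
            segments.append(CopyRatioSegment(contig, spike, spike + 1, bad_ratio))
            start = spike + 1
        if start < len(seq):
            segments.append(CopyRatioSegment(contig, start, len(seq), 2.0))
    return segments


# ---------------------------------------------------------------------------
# Amplicon reads


@dataclass
class SimulatedRead:
    name: str
    sequence: str


def simulate_amplicon_reads(
    design: AmpliconDesign,
    per_position_edit_rates: Mapping[int, float],
    indel_rate: float,
    error_rate: float,
    n_reads: int,
    seed: int,
) -> list[SimulatedRead]:
    """Full-length amplicon reads with independent per-position conversion.

    ``per_position_edit_rates`` maps 1-based amplicon positions to A-to-G
    conversion probabilities (T-to-C on the plus strand when the protospacer
    is on the minus strand). Indels of 1-10 bp (uniform length, insertion or
    deletion with equal probability, anchored uniformly inside the
    protospacer) occur at ``indel_rate`` per read; uniform substitution error
    at ``error_rate`` per base.
    """
    amplicon = design.amplicon_sequence
    if not amplicon:
        raise ValueError("design has an empty amplicon sequence")
    edited_base = "A" if design.strand == "+" else "T"
    converted = {"A": "G", "T": "C"}[edited_base]
    for pos, rate in per_position_edit_rates.items():
        if not 1 <= pos <= len(amplicon):
            raise ValueError(f"edit position {pos} outside the amplicon")
        if not 0 <= rate <= 1:
            raise ValueError(f"edit rate {rate} outside [0, 1]")
        if amplicon[pos - 1] != edited_base:
            raise ValueError(
                f"position {pos} is {amplicon[pos - 1]}, not an editable {edited_base}")
    if not 0 <= indel_rate <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("rates must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    length = len(amplicon)
    proto_lo, proto_hi = design.protospacer_start, design.protospacer_end
    reads: list[SimulatedRead] = []
    for i in range(n_reads):
        seq = list(amplicon)
        for pos, rate in per_position_edit_rates.items():
            if rng.random() < rate:
                seq[pos - 1] = converted
        n_err = rng.binomial(length, error_rate)
        if n_err:
            for pos in rng.choice(length, size=n_err, replace=False):
                choices = [b for b in "ACGT" if b != seq[pos]]
                seq[pos] = choices[int(rng.integers(3))]
        if rng.random() < indel_rate:
            indel_len = int(rng.integers(1, 11))
            anchor = int(rng.integers(proto_lo, proto_hi + 1)) - 1  # 0-based
            if rng.integers(2) == 0:  # deletion
                del seq[anchor:anchor + indel_len]
            else:  # insertion after anchor
                insert = [BASES[int(b)] for b in rng.integers(0, 4, size=indel_len)]
                seq[anchor + 1:anchor + 1] = insert
        reads.append(SimulatedRead(f"read_{i}", "".join(seq)))
    return reads


# ---------------------------------------------------------------------------
# RNA site tables

RNA_DECOY_RULES = ("control-coverage", "control-ref-fraction", "treated-depth")


@dataclass
class SimulatedRnaTables:
    sites: list[RnaSite]
    labels: pd.DataFrame


def simulate_rna_site_tables(
    n_sites: int,
    n_true_edits: int,
    coverage_model: tuple[float, float] = (50.0, 5.0),
    control_ref_fraction: float = 1.0,
    seed: int = 0,
    min_treated_reads: int = 10,
) -> SimulatedRnaTables:
    """Treated/control RNA site tables with spiked A-to-I edits.

    True edits are A>G or T>C sites that pass all three filters (deep,
    clean control; >= min_treated_reads treated coverage). Every other site
    is a decoy violating exactly one rule, cycling through the three rules.
    The control-coverage threshold is whatever nearest-rank 90th percentile
    the final treated coverages imply, so labels stay sound by construction.
    """
    if n_true_edits > n_sites:
        raise ValueError("n_true_edits cannot exceed n_sites")
    rng = np.random.default_rng(seed)
    mean, dispersion = coverage_model

    kinds: list[str] = ["edit"] * n_true_edits
    for i in range(n_sites - n_true_edits):
        kinds.append(RNA_DECOY_RULES[i % len(RNA_DECOY_RULES)])
    kinds_arr = np.array(kinds, dtype=object)[rng.permutation(n_sites)]

    treated_depths = np.empty(n_sites, dtype=int)
    for i, kind in enumerate(kinds_arr):
        if kind == "treated-depth":
            treated_depths[i] = int(rng.integers(1, min_treated_reads))
        else:
            treated_depths[i] = max(min_treated_reads,
                                    _negative_binomial(rng, mean, dispersion))

    threshold = coverage_percentile_threshold(list(treated_depths), 90)

    sites: list[RnaSite] = []
    rows = []
    for i, kind in enumerate(kinds_arr):
        d = int(treated_depths[i])
        if kind == "edit":
            ref, alt = ("A", "G") if rng.integers(2) == 0 else ("T", "C")
            treated_alt = max(1, int(rng.binomial(d, 0.3)))
        else:
            ref = BASES[int(rng.integers(4))]
            alt = [b for b in BASES if b != ref][int(rng.integers(3))]
            treated_alt = int(rng.binomial(d, 0.2))
        if kind == "control-coverage":
            control_depth = int(rng.integers(1, threshold + 1))
            control_ref = control_depth
        elif kind == "control-ref-fraction":
            control_depth = threshold + int(rng.integers(5, 50))
            control_ref = math.floor(0.95 * control_depth)
        else:
            control_depth = threshold + int(rng.integers(5, 50))
            control_ref = math.ceil(control_ref_fraction * control_depth)
        sites.append(RnaSite(
            contig="chr1", position=(i + 1) * 500, ref=ref, alt=alt,
            treated_depth=d, treated_alt=treated_alt,
            control_depth=control_depth, control_ref=control_ref))
        rows.append({
            "contig": "chr1", "position": (i + 1) * 500, "ref": ref, "alt": alt,
            "kind": "edit" if kind == "edit" else "decoy",
            "violated_rule": "" if kind == "edit" else kind,
            "expected_pass": kind == "edit",
        })
    return SimulatedRnaTables(sites=sites, labels=pd.DataFrame(rows))
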