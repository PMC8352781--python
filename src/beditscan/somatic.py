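"""Clone/bulk somatic variant filter cascade for whole-genome sequencing.

Somatic mutation burden in an expanded hepatocyte clone is estimated by
multisample variant calling against a paired bulk (untreated tissue) control
and then applying a cascade of post-processing filters: autosomal location,
zero alt-supporting reads in the control, GATK-style site-quality flags,
phred quality thresholds (100 for substitutions, 250 for indels), 20x depth
in both samples, mapping quality 60, exclusion of known polymorphisms,
genotype-quality requirements, clone VAF >= 0.2, and restriction to callable
diploid regions (copy-ratio between 1.5 and 2.5). Mutation counts are then
rescaled by the fraction of the genome the accounted regions cover.

Detection sensitivity of the cascade is estimated from germline heterozygous
variants: a germline het is "detected" in a clone when its clone VAF >= 0.3.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

SITE_ANNOTATIONS = ("QD", "MQ", "FS", "HaplotypeScore", "MQRankSum", "ReadPosRankSum")

# rule labels, in cascade order; the tally reports the FIRST failing rule
RULE_AUTOSOME = "autosome"
RULE_CONTROL_MISSING = "control-missing"
RULE_CONTROL_EVIDENCE = "control-evidence"
RULE_SITE_FLAG = "site-flag"
RULE_SITE_QUALITY = "site-quality"
RULE_DEPTH = "depth"
RULE_MAPPING_QUALITY = "mapping-quality"
RULE_KNOWN_POLYMORPHISM = "known-polymorphism"
RULE_GENOTYPE_QUALITY = "genotype-quality"
RULE_CONTROL_PROXIMITY = "control-proximity"
RULE_VAF = "vaf"
RULE_CALLABLE = "callable"
RULE_DIPLOID = "diploid"
PASS = "pass"

SNV_RULE_ORDER = (
    RULE_AUTOSOME,
    RULE_CONTROL_MISSING,
    RULE_CONTROL_EVIDENCE,
    RULE_SITE_FLAG,
    RULE_SITE_QUALITY,
    RULE_DEPTH,
    RULE_MAPPING_QUALITY,
    RULE_KNOWN_POLYMORPHISM,
    RULE_GENOTYPE_QUALITY,
    RULE_VAF,
    RULE_CALLABLE,
    RULE_DIPLOID,
)


@dataclass
class SampleEvidence:
    """Per-sample genotype evidence at one site."""

    depth: int | None = None
    alt_count: int | None = None
    gq: int | None = None

    @property
    def vaf(self) -> float | None:
        if self.depth is None or self.alt_count is None or self.depth == 0:
            return None
        return self.alt_count / self.depth


@dataclass
class VariantRecord:
    """One called variant with site annotations and one sample's evidence."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    site_quality: float | None = None
    annotations: dict = field(default_factory=dict)
    evidence: SampleEvidence = field(default_factory=SampleEvidence)
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("alleles must be non-empty")
        if (self.evidence.depth is not None and self.evidence.alt_count is not None
                and self.evidence.alt_count > self.evidence.depth):
            raise ValueError("alt count exceeds depth")

    @property
    def key(self) -> tuple:
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass
class FilterThresholds:
    """Filter cascade thresholds; defaults are the published pipeline values."""

    snv_quality_min: float = 100.0
    indel_quality_min: float = 250.0
    depth_min: int = 20
    mapping_quality_min: float = 60.0
    clone_gq_min: int = 99
    control_gq_min_snv: int = 10
    vaf_min_somatic: float = 0.2
    vaf_het_min: float = 0.3
    diploid_ratio_bounds: tuple[float, float] = (1.5, 2.5)
    indel_control_proximity_bp: int = 100
    cluster_size: int = 3
    cluster_window: int = 35
    qd_min: float = 2.0
    mq_flag_min: float = 40.0
    fs_max: float = 60.0
    haplotype_score_max: float = 13.0
    mq_rank_sum_min: float = -12.5
    read_pos_rank_sum_min: float = -8.0


@dataclass
class CopyRatioSegment:
    contig: str
    start: int  # 0-based half-open
    end: int
    ratio: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must be < end")
        if self.ratio < 0:
            raise ValueError("copy ratio must be non-negative")


class RegionSet:
    """Named set of genomic intervals (0-based half-open) with point lookup.

    A 1-based variant position p is a member when p-1 falls inside an interval.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = (),
                 name: str = "", role: str = "") -> None:
        self.name = name
        self.role = role
        self._trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            self.add(contig, start, end)

    def add(self, contig: str, start: int, end: int) -> None:
        if start >= end:
            raise ValueError(f"malformed interval {contig}:{start}-{end}")
        self._trees.setdefault(contig, IntervalTree()).addi(start, end)

    def contains(self, contig: str, position: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree is not None and tree.overlaps_point(position - 1))

    def total_length(self) -> int:
        total = 0
        for tree in self._trees.values():
            merged = tree.copy()
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in sorted(self._trees):
            for iv in sorted(self._trees[contig]):
                out.append((contig, iv.begin, iv.end))
        return out


class DiploidIndex:
    """Point lookup: is a position inside a segment with diploid copy ratio?"""

    def __init__(self, segments: Sequence[CopyRatioSegment],
                 bounds: tuple[float, float] = (1.5, 2.5)) -> None:
        lo, hi = bounds
        self._trees: dict[str, IntervalTree] = {}
        self._diploid_length = 0
        for seg in segments:
            if lo < seg.ratio < hi:
                self._trees.setdefault(seg.contig, IntervalTree()).addi(seg.start, seg.end)
                self._diploid_length += seg.end - seg.start

    def contains(self, contig: str, position: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree is not None and tree.overlaps_point(position - 1))

    @property
    def diploid_length(self) -> int:
        return self._diploid_length


def _is_sorted(records: Sequence[VariantRecord]) -> bool:
    seen: list[str] = []
    last: tuple | None = None
    for r in records:
        cur = (r.contig, r.position)
        if last is not None and cur[0] == last[0] and cur[1] < last[1]:
            return False
        if last is None or cur[0] != last[0]:
            if cur[0] in seen:
                return False
            seen.append(cur[0])
        last = cur
    return True


def apply_site_quality_flags(
    records: Sequence[VariantRecord], thresholds: FilterThresholds | None = None
) -> list[VariantRecord]:
    """Attach GATK VariantFiltration-style flags to each record.

    Hard-filter flags (LowQualityDepth, MappingQuality, StrandBias,
    HaplotypeScoreHigh, MQRankSumLow, ReadPosRankSumLow) fire on the site
    annotations; a missing annotation never fires a flag. SnpCluster flags
    every member of any run of >= cluster_size SNVs spanning <= cluster_window
    bases. Records must be sorted by contig then position.
    """
    t = thresholds or FilterThresholds()
    if not _is_sorted(records):
        raise ValueError("records must be sorted by contig and position")

    checks = (
        ("LowQualityDepth", "QD", lambda v: v < t.qd_min),
        ("MappingQuality", "MQ", lambda v: v < t.mq_flag_min),
        ("StrandBias", "FS", lambda v: v > t.fs_max),
        ("HaplotypeScoreHigh", "HaplotypeScore", lambda v: v > t.haplotype_score_max),
        ("MQRankSumLow", "MQRankSum", lambda v: v < t.mq_rank_sum_min),
        ("ReadPosRankSumLow", "ReadPosRankSum", lambda v: v < t.read_pos_rank_sum_min),
    )

    flag_sets: list[set[str]] = []
    for r in records:
        flags = set()
        for flag, key, bad in checks:
            value = r.annotations.get(key)
            if value is not None and bad(value):
                flags.add(flag)
        flag_sets.append(flags)

    # SNP clusters: sliding window of cluster_size SNVs within cluster_window bp
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for i, r in enumerate(records):
        if r.is_snv:
            by_contig.setdefault(r.contig, []).append((r.position, i))
    k = t.cluster_size
    for positions in by_contig.values():
        for j in range(len(positions) - k + 1):
            if positions[j + k - 1][0] - positions[j][0] + 1 <= t.cluster_window:
                for _, idx in positions[j:j + k]:
                    flag_sets[idx].add("SnpCluster")

    for r, flags in zip(records, flag_sets):
        r.flags = frozenset(flags)
    return list(records)


def _shared_rejection(
    clone: VariantRecord,
    control: VariantRecord | None,
    autosomes: frozenset,
) -> str | None:
    """Leading rules shared between the SNV and indel cascades."""
    if clone.contig not in autosomes:
        return RULE_AUTOSOME
    if control is None:
        return RULE_CONTROL_MISSING
    if control.evidence.alt_count is None or control.evidence.alt_count != 0:
        return RULE_CONTROL_EVIDENCE
    return None


def _depth_fails(ev: SampleEvidence, depth_min: int) -> bool:
    return ev.depth is None or ev.depth < depth_min


def filter_somatic_snvs(
    clone_records: Sequence[VariantRecord],
    control_records: Sequence[VariantRecord],
    autosomes: Iterable[str],
    known_polymorphisms: RegionSet,
    callable_regions: RegionSet,
    segments: Sequence[CopyRatioSegment],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], Counter]:
    """Run the somatic SNV cascade; return passing records and a per-rule tally.

    Each rejected record is tallied under the first failing rule in the
    documented order, so passes + tallied rejections equals the input count.
    """
    t = thresholds or FilterThresholds()
    autoset = frozenset(autosomes)
    control_index = {r.key: r for r in control_records}
    diploid = DiploidIndex(segments, t.diploid_ratio_bounds)
    apply_site_quality_flags(clone_records, t)

    passing: list[VariantRecord] = []
    tally: Counter = Counter()
    for clone in clone_records:
        rule = _first_failing_snv_rule(
            clone, control_index.get(clone.key), autoset,
            known_polymorphisms, callable_regions, diploid, t)
        tally[rule or PASS] += 1
        if rule is None:
            passing.append(clone)
    return passing, tally


def _first_failing_snv_rule(clone, control, autoset, known_poly, callable_regions,
                            diploid, t) -> str | None:
    rule = _shared_rejection(clone, control, autoset)
    if rule:
        return rule
    if clone.flags:
        return RULE_SITE_FLAG
    if clone.site_quality is None or clone.site_quality < t.snv_quality_min:
        return RULE_SITE_QUALITY
    if _depth_fails(clone.evidence, t.depth_min) or _depth_fails(control.evidence, t.depth_min):
        return RULE_DEPTH
    mq = clone.annotations.get("MQ")
    if mq is not None and mq < t.mapping_quality_min:
        return RULE_MAPPING_QUALITY
    if known_poly.contains(clone.contig, clone.position):
        return RULE_KNOWN_POLYMORPHISM
    if (clone.evidence.gq is None or clone.evidence.gq < t.clone_gq_min
            or control.evidence.gq is None or control.evidence.gq < t.control_gq_min_snv):
        return RULE_GENOTYPE_QUALITY
    vaf = clone.evidence.vaf
    if vaf is None or vaf < t.vaf_min_somatic:
        return RULE_VAF
    if not callable_regions.contains(clone.contig, clone.position):
        return RULE_CALLABLE
    if not diploid.contains(clone.contig, clone.position):
        return RULE_DIPLOID
    return None


def filter_somatic_indels(
    clone_records: Sequence[VariantRecord],
    control_records: Sequence[VariantRecord],
    autosomes: Iterable[str],
    known_polymorphisms: RegionSet,
    callable_regions: RegionSet,
    segments: Sequence[CopyRatioSegment],
    thresholds: FilterThresholds | None = None,
) -> tuple[list[VariantRecord], Counter]:
    """Somatic indel cascade: quality >= 250, GQ >= 99 in clone AND control,
    and no control-called variant within 100 bp of the indel."""
    t = thresholds or FilterThresholds()
    autoset = frozenset(autosomes)
    control_index = {r.key: r for r in control_records}
    diploid = DiploidIndex(segments, t.diploid_ratio_bounds)

    # control-called variant positions (alt evidence present) for proximity query
    control_variant_pos: dict[str, list[int]] = {}
    for r in control_records:
        if r.evidence.alt_count is not None and r.evidence.alt_count > 0:
            control_variant_pos.setdefault(r.contig, []).append(r.position)
    for positions in control_variant_pos.values():
        positions.sort()

    def near_control_variant(contig: str, pos: int) -> bool:
        positions = control_variant_pos.get(contig)
        if not positions:
            return False
        i = bisect_left(positions, pos - t.indel_control_proximity_bp)
        return i < len(positions) and positions[i] <= pos + t.indel_control_proximity_bp

    passing: list[VariantRecord] = []
    tally: Counter = Counter()
    for clone in clone_records:
        control = control_index.get(clone.key)
        rule = _shared_rejection(clone, control, autoset)
        if rule is None:
            if clone.site_quality is None or clone.site_quality < t.indel_quality_min:
                rule = RULE_SITE_QUALITY
            elif _depth_fails(clone.evidence, t.depth_min) or _depth_fails(control.evidence, t.depth_min):
                rule = RULE_DEPTH
            else:
                mq = clone.annotations.get("MQ")
                if mq is not None and mq < t.mapping_quality_min:
                    rule = RULE_MAPPING_QUALITY
                elif known_polymorphisms.contains(clone.contig, clone.position):
                    rule = RULE_KNOWN_POLYMORPHISM
                elif (clone.evidence.gq is None or clone.evidence.gq < t.clone_gq_min
                        or control.evidence.gq is None or control.evidence.gq < t.clone_gq_min):
                    rule = RULE_GENOTYPE_QUALITY
                elif near_control_variant(clone.contig, clone.position):
                    rule = RULE_CONTROL_PROXIMITY
                elif clone.evidence.vaf is None or clone.evidence.vaf < t.vaf_min_somatic:
                    rule = RULE_VAF
                elif not callable_regions.contains(clone.contig, clone.position):
                    rule = RULE_CALLABLE
                elif not diploid.contains(clone.contig, clone.position):
                    rule = RULE_DIPLOID
        tally[rule or PASS] += 1
        if rule is None:
            passing.append(clone)
    return passing, tally


def normalize_mutation_count(
    raw_count: float, accounted_length: int, reference_length: int
) -> float:
    """Rescale a mutation count from the accounted (callable diploid) genome
    length to the full reference length: raw * reference / accounted."""
    if accounted_length <= 0:
        raise ValueError("accounted length must be positive")
    if accounted_length > reference_length:
        raise ValueError("accounted length cannot exceed reference length")
    return raw_count * reference_length / accounted_length


def estimate_detection_sensitivity(
    germline_het_set: Sequence[tuple[object, Mapping[str, float]]],
    vaf_het_min: float = 0.3,
) -> dict[str, float]:
    """Per-clone detection sensitivity from germline heterozygous variants.

    ``germline_het_set`` is a list of (site, {clone_name: VAF}); a het counts
    as detected in a clone when its VAF there is >= vaf_het_min (inclusive).
    Returns {clone_name: detected fraction}.
    """
    if len(germline_het_set) == 0:
        raise ValueError("germline het set is empty")
    detected: Counter = Counter()
    totals: Counter = Counter()
    for _site, vafs in germline_het_set:
        for clone, vaf in vafs.items():
            totals[clone] += 1
            if vaf >= vaf_het_min:
                detected[clone] += 1
    return {clone: detected[clone] / totals[clone] for clone in totals}
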