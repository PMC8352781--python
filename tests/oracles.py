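"""Independent straight-line re-implementations of the filter rule lists.

Written deliberately without reusing any package code paths: plain loops,
linear interval scans, and literal threshold comparisons, so they can serve
as an oracle for the cascade implementations.
"""

from __future__ import annotations

import math


def snv_cluster_members(snv_positions_by_contig, cluster_size=3, window=35):
    """Positions belonging to any run of >= cluster_size SNVs within a window,
    computed by exhaustive pairwise scanning."""
    flagged = set()
    for contig, positions in snv_positions_by_contig.items():
        positions = sorted(positions)
        n = len(positions)
        for i in range(n):
            for j in range(i + cluster_size - 1, n):
                if positions[j] - positions[i] + 1 <= window:
                    if j - i + 1 >= cluster_size:
                        for p in positions[i:j + 1]:
                            flagged.add((contig, p))
                else:
                    break
    return flagged


def _in_any_interval(intervals, contig, position):
    # variant position is 1-based; intervals are (contig, start, end) 0-based half-open
    p = position - 1
    for c, start, end in intervals:
        if c == contig and start <= p < end:
            return True
    return False


def _has_hard_filter_flag(annotations):
    qd = annotations.get("QD")
    if qd is not None and qd < 2.0:
        return True
    mq = annotations.get("MQ")
    if mq is not None and mq < 40.0:
        return True
    fs = annotations.get("FS")
    if fs is not None and fs > 60.0:
        return True
    hs = annotations.get("HaplotypeScore")
    if hs is not None and hs > 13.0:
        return True
    mqrs = annotations.get("MQRankSum")
    if mqrs is not None and mqrs < -12.5:
        return True
    rprs = annotations.get("ReadPosRankSum")
    if rprs is not None and rprs < -8.0:
        return True
    return False


def snv_oracle_passes(
    clone: dict,
    control: dict | None,
    autosomes: set,
    known_intervals: list,
    callable_intervals: list,
    segments: list,  # (contig, start, end, ratio)
    cluster_flagged: set,
) -> bool:
    """True when a clone SNV record survives every somatic-filter rule.

    ``clone``/``control`` are plain dicts: contig, position, ref, alt, qual,
    annotations, depth, alt_count, gq.
    """
    if clone["contig"] not in autosomes:
        return False
    if control is None:
        return False
    if control["alt_count"] is None or control["alt_count"] != 0:
        return False
    if _has_hard_filter_flag(clone["annotations"]):
        return False
    if (clone["contig"], clone["position"]) in cluster_flagged:
        return False
    if clone["qual"] is None or clone["qual"] < 100.0:
        return False
    if clone["depth"] is None or clone["depth"] < 20:
        return False
    if control["depth"] is None or control["depth"] < 20:
        return False
    mq = clone["annotations"].get("MQ")
    if mq is not None and mq < 60.0:
        return False
    if _in_any_interval(known_intervals, clone["contig"], clone["position"]):
        return False
    if clone["gq"] is None or clone["gq"] < 99:
        return False
    if control["gq"] is None or control["gq"] < 10:
        return False
    if clone["depth"] == 0 or clone["alt_count"] is None:
        return False
    if clone["alt_count"] / clone["depth"] < 0.2:
        return False
    if not _in_any_interval(callable_intervals, clone["contig"], clone["position"]):
        return False
    p = clone["position"] - 1
    diploid = False
    for c, start, end, ratio in segments:
        if c == clone["contig"] and start <= p < end and 1.5 < ratio < 2.5:
            diploid = True
            break
    if not diploid:
        return False
    return True


def indel_oracle_passes(
    clone: dict,
    control: dict | None,
    autosomes: set,
    known_intervals: list,
    callable_intervals: list,
    segments: list,
    control_variant_positions: list,  # (contig, position) with alt evidence
) -> bool:
    if clone["contig"] not in autosomes:
        return False
    if control is None:
        return False
    if control["alt_count"] is None or control["alt_count"] != 0:
        return False
    if clone["qual"] is None or clone["qual"] < 250.0:
        return False
    if clone["depth"] is None or clone["depth"] < 20:
        return False
    if control["depth"] is None or control["depth"] < 20:
        return False
    mq = clone["annotations"].get("MQ")
    if mq is not None and mq < 60.0:
        return False
    if _in_any_interval(known_intervals, clone["contig"], clone["position"]):
        return False
    if clone["gq"] is None or clone["gq"] < 99:
        return False
    if control["gq"] is None or control["gq"] < 99:
        return False
    for c, p in control_variant_positions:
        if c == clone["contig"] and abs(p - clone["position"]) <= 100:
            return False
    if clone["depth"] == 0 or clone["alt_count"] is None:
        return False
    if clone["alt_count"] / clone["depth"] < 0.2:
        return False
    if not _in_any_interval(callable_intervals, clone["contig"], clone["position"]):
        return False
    p = clone["position"] - 1
    for c, start, end, ratio in segments:
        if c == clone["contig"] and start <= p < end and 1.5 < ratio < 2.5:
            return True
    return False


def record_to_dict(record) -> dict:
    return {
        "contig": record.contig,
        "position": record.position,
        "ref": record.ref,
        "alt": record.alt,
        "qual": record.site_quality,
        "annotations": dict(record.annotations),
        "depth": record.evidence.depth,
        "alt_count": record.evidence.alt_count,
        "gq": record.evidence.gq,
    }


def rna_oracle_pass_indices(sites: list[dict], q: float = 90.0) -> set[int]:
    """Indices of sites passing the three RNA filters, re-derived from scratch.

    ``sites`` are dicts: treated_depth, treated_alt, control_depth, control_ref.
    """
    coverages = sorted(s["treated_depth"] for s in sites)
    rank = math.ceil(q / 100.0 * len(coverages))
    threshold = coverages[rank - 1]
    passing = set()
    for i, s in enumerate(sites):
        if s["control_depth"] is None or s["control_ref"] is None:
            continue
        if s["control_depth"] == 0:
            continue
        if s["control_depth"] <= threshold:
            continue
        if s["control_ref"] / s["control_depth"] < 0.99:
            continue
        if s["treated_depth"] < 10:
            continue
        passing.add(i)
    return passing
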