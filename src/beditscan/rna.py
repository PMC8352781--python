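"""Transcriptome A-to-I off-target site filtering.

Candidate RNA variant sites from a deaminase-overexpression experiment are
kept only when (i) the matched control experiment covers the site deeper than
the 90th percentile of read coverage across all candidate sites in the treated
experiment, (ii) at least 99% of control reads carry the reference allele
(a high-confidence reference genotype in the control), and (iii) the treated
sample has at least ten reads. Surviving A>G / T>C sites are counted as
A-to-I editing events (transcript strand unknown, so both genomic orientations
count).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

RULE_CONTROL_MISSING = "control-missing"
RULE_CONTROL_COVERAGE = "control-coverage"
RULE_CONTROL_REF_FRACTION = "control-ref-fraction"
RULE_TREATED_DEPTH = "treated-depth"
PASS = "pass"


@dataclass
class RnaSite:
    """One transcriptome position with treated and control evidence."""

    contig: str
    position: int  # 1-based
    ref: str
    alt: str
    treated_depth: int
    treated_alt: int
    control_depth: int | None = None
    control_ref: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.treated_alt <= self.treated_depth:
            raise ValueError("treated alt count must lie in [0, depth]")
        if (self.control_depth is not None and self.control_ref is not None
                and not 0 <= self.control_ref <= self.control_depth):
            raise ValueError("control ref count must lie in [0, depth]")

    @property
    def is_a_to_i(self) -> bool:
        return (self.ref, self.alt) in (("A", "G"), ("T", "C"))


def coverage_percentile_threshold(treated_site_coverages: Sequence[int], q: float = 90) -> int:
    """Nearest-rank percentile of the treated coverages.

    Returns the value at rank ceil(q/100 * n) of the ascending-sorted list.
    """
    if len(treated_site_coverages) == 0:
        raise ValueError("coverage list is empty")
    if not 0 < q < 100:
        raise ValueError("q must lie strictly between 0 and 100")
    ordered = sorted(treated_site_coverages)
    rank = math.ceil(q / 100 * len(ordered))
    return ordered[rank - 1]


def filter_rna_sites(
    treated: Sequence[RnaSite],
    q: float = 90,
    min_treated_reads: int = 10,
    control_ref_fraction_min: float = 0.99,
) -> tuple[list[RnaSite], Counter]:
    """Apply the three-rule site filter; return passing sites and a tally.

    The coverage threshold is computed once per experiment from all treated
    coverages; "above the percentile" is strict (>). Rejections are tallied
    under the first failing rule: control coverage, control reference
    fraction, then treated depth; a site with no control evidence gets its
    own label.
    """
    if len(treated) == 0:
        return [], Counter()
    threshold = coverage_percentile_threshold([s.treated_depth for s in treated], q)

    passing: list[RnaSite] = []
    tally: Counter = Counter()
    for site in treated:
        if site.control_depth is None or site.control_ref is None or site.control_depth == 0:
            rule = RULE_CONTROL_MISSING
        elif not site.control_depth > threshold:
            rule = RULE_CONTROL_COVERAGE
        elif not site.control_ref / site.control_depth >= control_ref_fraction_min:
            rule = RULE_CONTROL_REF_FRACTION
        elif not site.treated_depth >= min_treated_reads:
            rule = RULE_TREATED_DEPTH
        else:
            rule = PASS
            passing.append(site)
        tally[rule] += 1
    return passing, tally


def count_a_to_i_events(passing_sites: Sequence[RnaSite]) -> tuple[int, list[RnaSite]]:
    """Count A-to-I editing events among filtered sites.

    A>G and T>C substitutions both count (the transcript strand is unknown
    from genome-aligned calls). Returns the count and the contributing sites.
    """
    events = [s for s in passing_sites if s.is_a_to_i]
    return len(events), events
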