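"""Amplicon deep-sequencing quantification of base-editing outcomes.

Reads from a targeted amplicon are globally aligned to the reference amplicon
with free end gaps, then per-position base counts yield A-to-G conversion
percentages; reads with an insertion or deletion overlapping the quantification
window (protospacer +/- 5 bp) are summarized separately as "indels" and
excluded from the substitution denominators.

Protospacer positions are numbered 1-20 from the PAM-distal 5' end; the NGG
PAM sits immediately 3' of position 20 on the protospacer strand. For a
protospacer on the amplicon minus strand, an A-to-G edit appears as T-to-C on
the amplicon plus strand; all bookkeeping here is strand-aware.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from Bio import Align

from .signature import reverse_complement

PROTOSPACER_LENGTH = 20
PAM_LENGTH = 3
_TRANSITION = {"A": "G", "T": "C"}


@dataclass
class AmpliconDesign:
    """Amplicon with protospacer/PAM coordinates and editable adenines.

    Intervals are 1-based inclusive on the amplicon. ``target_adenine_position``
    and ``bystander_positions`` are protospacer positions (1 = PAM-distal 5'
    end).
    """

    name: str
    amplicon_sequence: str
    protospacer_start: int
    protospacer_end: int
    strand: str = "+"
    target_adenine_position: int = 5
    bystander_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.amplicon_sequence = self.amplicon_sequence.upper()
        if not self.amplicon_sequence:
            raise ValueError("amplicon sequence is empty")
        if set(self.amplicon_sequence) - set("ACGT"):
            raise ValueError("amplicon sequence must be A/C/G/T")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.protospacer_end - self.protospacer_start + 1 != PROTOSPACER_LENGTH:
            raise ValueError("protospacer must be 20 bp")
        lo, hi = self.pam_interval
        if lo < 1 or hi > len(self.amplicon_sequence):
            raise ValueError("PAM falls outside the amplicon")
        if not 1 <= self.target_adenine_position <= PROTOSPACER_LENGTH:
            raise ValueError("target position must lie within the protospacer")

    @property
    def pam_interval(self) -> tuple[int, int]:
        """PAM amplicon coordinates: 3' of the protospacer on its strand."""
        if self.strand == "+":
            return (self.protospacer_end + 1, self.protospacer_end + PAM_LENGTH)
        return (self.protospacer_start - PAM_LENGTH, self.protospacer_start - 1)

    def protospacer_to_amplicon(self, i: int) -> int:
        """Map protospacer position i (1-20) to a 1-based amplicon position."""
        if not 1 <= i <= PROTOSPACER_LENGTH:
            raise ValueError(f"protospacer position {i} out of range")
        if self.strand == "+":
            return self.protospacer_start + i - 1
        return self.protospacer_end - i + 1

    def protospacer_base(self, i: int) -> str:
        """Reference base at protospacer position i, on the protospacer strand."""
        base = self.amplicon_sequence[self.protospacer_to_amplicon(i) - 1]
        return base if self.strand == "+" else reverse_complement(base)

    def quantification_window(self, pad: int = 5) -> tuple[int, int]:
        lo = max(1, self.protospacer_start - pad)
        hi = min(len(self.amplicon_sequence), self.protospacer_end + pad)
        return lo, hi


@dataclass
class AlignedRead:
    """A read's alignment to the amplicon, column by column."""

    read_id: str
    score: float
    identity: float
    unalignable: bool
    base_at: dict[int, str] = field(default_factory=dict)  # amplicon pos -> read base
    deletions: frozenset = frozenset()  # deleted amplicon positions
    insertions: tuple[tuple[int, int], ...] = ()  # (amplicon pos before insert, length)
    span: tuple[int, int] = (0, 0)
    contains_indel_in_window: bool = False

    def spans(self, lo: int, hi: int) -> bool:
        return self.span[0] <= lo and self.span[1] >= hi

    @property
    def has_indel(self) -> bool:
        return bool(self.deletions) or bool(self.insertions)


def _make_aligner() -> Align.PairwiseAligner:
    # fixed scoring so results are reproducible: match +2, mismatch -3,
    # gap open -8, extend -1; end gaps free on both sequences
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -8
    aligner.extend_gap_score = -1
    aligner.open_end_gap_score = 0
    aligner.extend_end_gap_score = 0
    return aligner


_ALIGNER = _make_aligner()


def align_read_to_amplicon(
    read: str,
    design: AmpliconDesign,
    read_id: str = "",
    min_identity: float = 0.6,
) -> AlignedRead:
    """Align a read to the amplicon (trying both orientations).

    The better-scoring orientation wins (forward on ties); the alignment
    library's canonical first path is taken, which makes tie-breaking
    deterministic. Reads with identity below ``min_identity`` over their
    aligned columns are flagged unalignable and excluded from summaries.
    """
    if not read:
        raise ValueError("read is empty")
    read = read.upper()
    amplicon = design.amplicon_sequence

    rc = reverse_complement(read)
    fwd_score = _ALIGNER.score(amplicon, read)
    rev_score = _ALIGNER.score(amplicon, rc)
    query = read if fwd_score >= rev_score else rc
    alignment = _ALIGNER.align(amplicon, query)[0]

    base_at: dict[int, str] = {}
    deletions: set[int] = set()
    insertions: list[tuple[int, int]] = []
    matches = 0
    columns = 0

    blocks = alignment.aligned  # pairs of (target block, query block)
    t_blocks, q_blocks = blocks[0], blocks[1]
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        for t, q in zip(range(ts, te), range(qs, qe)):
            base_at[t + 1] = query[q]
            columns += 1
            if query[q] == amplicon[t]:
                matches += 1
    for i in range(len(t_blocks) - 1):
        t_gap_start, t_gap_end = t_blocks[i][1], t_blocks[i + 1][0]
        q_gap = q_blocks[i + 1][0] - q_blocks[i][1]
        for t in range(t_gap_start, t_gap_end):
            deletions.add(t + 1)  # read skips these amplicon positions
        if q_gap > 0:
            insertions.append((t_gap_start, q_gap))  # read bases with no amplicon home

    if not base_at:
        return AlignedRead(read_id, alignment.score, 0.0, True)
    span = (min(base_at), max(base_at))
    identity = matches / columns if columns else 0.0

    lo, hi = design.quantification_window()
    in_window = any(lo <= p <= hi for p in deletions) or any(
        lo <= p + 1 and p <= hi for p, _ in insertions
    )
    return AlignedRead(
        read_id=read_id,
        score=alignment.score,
        identity=identity,
        unalignable=identity < min_identity,
        base_at=base_at,
        deletions=frozenset(deletions),
        insertions=tuple(insertions),
        span=span,
        contains_indel_in_window=in_window,
    )


@dataclass
class EditingSummary:
    """Per-position base counts and headline editing percentages for a sample."""

    sample: str
    n_reads_total: int
    n_spanning: int
    n_reads_with_indel: int
    base_counts: dict[int, dict[str, int]]  # among indel-free spanning reads
    n_indel_free_spanning: dict[int, int]
    a_to_g_percent: dict[int, float]
    indel_percent: float
    target_a_to_g_percent: float
    reference: str = ""

    def conversion_percent(self, position: int, ref_base: str, alt_base: str) -> float:
        n = self.n_indel_free_spanning.get(position, 0)
        if n == 0:
            raise ValueError(f"no indel-free reads span position {position}")
        if self.reference and self.reference[position - 1] != ref_base:
            raise ValueError(
                f"reference base at {position} is {self.reference[position - 1]}, "
                f"not {ref_base}")
        return 100.0 * self.base_counts[position].get(alt_base, 0) / n


def quantify_editing(
    reads: Sequence[AlignedRead], design: AmpliconDesign, sample: str = ""
) -> EditingSummary:
    """Summarize editing outcomes over aligned reads.

    A read "spans" the quantification window when its alignment covers the
    whole window. Indel % is indel-carrying spanning reads over all spanning
    reads; substitution percentages use only indel-free spanning reads, so an
    edited base inside a deletion is never double counted.
    """
    lo, hi = design.quantification_window()
    usable = [r for r in reads if not r.unalignable]
    spanning = [r for r in usable if r.spans(lo, hi)]
    if not spanning:
        raise ValueError("no aligned read spans the quantification window")

    with_indel = [r for r in spanning if r.contains_indel_in_window]
    indel_free = [r for r in spanning if not r.contains_indel_in_window]

    length = len(design.amplicon_sequence)
    base_counts: dict[int, dict[str, int]] = {p: {} for p in range(1, length + 1)}
    n_span: dict[int, int] = {p: 0 for p in range(1, length + 1)}
    for r in indel_free:
        for p in range(r.span[0], r.span[1] + 1):
            base = r.base_at.get(p)
            if base is None:
                continue
            n_span[p] += 1
            counts = base_counts[p]
            counts[base] = counts.get(base, 0) + 1

    a_to_g: dict[int, float] = {}
    for p in range(1, length + 1):
        if design.amplicon_sequence[p - 1] == "A" and n_span[p] > 0:
            a_to_g[p] = 100.0 * base_counts[p].get("G", 0) / n_span[p]

    summary = EditingSummary(
        sample=sample,
        n_reads_total=len(usable),
        n_spanning=len(spanning),
        n_reads_with_indel=len(with_indel),
        base_counts=base_counts,
        n_indel_free_spanning=n_span,
        a_to_g_percent=a_to_g,
        indel_percent=100.0 * len(with_indel) / len(spanning),
        target_a_to_g_percent=math.nan,
        reference=design.amplicon_sequence,
    )
    summary.target_a_to_g_percent = _protospacer_conversion(
        summary, design, design.target_adenine_position)
    return summary


def _protospacer_conversion(summary: EditingSummary, design: AmpliconDesign, i: int) -> float:
    """A->G % at protospacer position i, strand-aware (T->C on minus strand)."""
    pos = design.protospacer_to_amplicon(i)
    if design.strand == "+":
        return summary.conversion_percent(pos, "A", "G")
    return summary.conversion_percent(pos, "T", "C")


def max_protospacer_conversion(summary: EditingSummary, design: AmpliconDesign) -> float:
    """Highest A-to-G conversion % over the protospacer's adenines.

    The headline number for candidate off-target sites: the maximum over
    protospacer positions whose reference base (on the protospacer strand)
    is adenine.
    """
    best: float | None = None
    for i in range(1, PROTOSPACER_LENGTH + 1):
        if design.protospacer_base(i) != "A":
            continue
        pct = _protospacer_conversion(summary, design, i)
        best = pct if best is None else max(best, pct)
    if best is None:
        raise ValueError("protospacer contains no adenine")
    return best


@dataclass
class GroupStats:
    group: str
    n: int
    mean_target_percent: float
    sd_target_percent: float | None
    mean_indel_percent: float
    sd_indel_percent: float | None


def summarize_groups(groups: Mapping[str, Sequence[EditingSummary]]) -> list[GroupStats]:
    """Per-group mean and sample (n-1) standard deviation of the headline
    target A-to-G % and indel %; the s.d. is flagged unavailable for n = 1."""
    out: list[GroupStats] = []
    for name, summaries in groups.items():
        if len(summaries) == 0:
            raise ValueError(f"group {name!r} is empty")
        targets = np.array([s.target_a_to_g_percent for s in summaries])
        indels = np.array([s.indel_percent for s in summaries])
        n = len(summaries)
        out.append(GroupStats(
            group=name,
            n=n,
            mean_target_percent=float(targets.mean()),
            sd_target_percent=float(targets.std(ddof=1)) if n > 1 else None,
            mean_indel_percent=float(indels.mean()),
            sd_indel_percent=float(indels.std(ddof=1)) if n > 1 else None,
        ))
    return out
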