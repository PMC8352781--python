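"""96-trinucleotide mutational profiles, deaminase signatures, and spike-in analysis.

Single-base substitutions are collapsed onto the pyrimidine strand, giving six
substitution types (C>A, C>G, C>T, T>A, T>C, T>G). Together with the 5' and 3'
flanking bases each substitution falls into one of 96 trinucleotide classes.
The canonical ordering used throughout is substitution-major, then 5' flank
(A,C,G,T), then 3' flank (A,C,G,T), so T>C occupies indices 64-79.

The adenine-deaminase (TadA) signature is a probability vector over the 96
classes with all mass on the 16 T>C classes: A>G edits read as T>C after
pyrimidine collapsing, and other substitutions are assumed not to contribute.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"
N_CLASSES = 96

#: indices of the 16 T>C trinucleotide classes (the A-to-G/T-to-C block)
TC_INDICES = np.arange(4 * 16, 5 * 16)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CLASS_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CLASS_INDEX = {label: i for i, label in enumerate(CLASS_LABELS)}


class ContextError(ValueError):
    """Trinucleotide context cannot be determined (edge position or ref mismatch)."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def class_label(five: str, ref: str, alt: str, three: str) -> str:
    """Canonical 96-class label, collapsing purine-reference changes.

    A purine-reference substitution is mapped to the reverse-complement strand:
    ref/alt are complemented and the flanks are swapped and complemented.
    """
    if ref == alt:
        raise ValueError(f"ref equals alt ({ref!r}); not a substitution")
    for b, what in ((five, "5' flank"), (ref, "ref"), (alt, "alt"), (three, "3' flank")):
        if b not in BASES:
            raise ValueError(f"invalid {what} base {b!r}")
    if ref in "AG":
        five, ref, alt, three = (
            three.translate(_COMPLEMENT),
            ref.translate(_COMPLEMENT),
            alt.translate(_COMPLEMENT),
            five.translate(_COMPLEMENT),
        )
    return f"{five}[{ref}>{alt}]{three}"


def class_index(label: str) -> int:
    return _CLASS_INDEX[label]


def trinucleotide_context(sequence: str, position: int, ref: str, alt: str) -> str:
    """Classify a substitution at a 1-based position of ``sequence``.

    Raises :class:`ContextError` if the position lacks a flanking base or the
    stated ref allele does not match the sequence.
    """
    if position < 2 or position > len(sequence) - 1:
        raise ContextError(f"position {position} has no flanking base")
    if sequence[position - 1] != ref:
        raise ContextError(
            f"ref mismatch at position {position}: sequence has "
            f"{sequence[position - 1]!r}, variant says {ref!r}"
        )
    return class_label(sequence[position - 2], ref, alt, sequence[position])


@dataclass
class MutationalProfile:
    """Counts over the 96 trinucleotide mutation classes for one sample."""

    counts: np.ndarray
    sample: str = ""
    skipped_indels: int = 0
    skipped_context_errors: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_CLASSES,):
            raise ValueError(f"profile must have {N_CLASSES} entries")
        if np.any(self.counts < 0):
            raise ValueError("profile counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        subs = np.repeat(SUBSTITUTIONS, 16)
        five = np.tile(np.repeat(list(BASES), 4), 6)
        three = np.tile(list(BASES), 24)
        return pd.DataFrame(
            {"substitution": subs, "fivePrime": five, "threePrime": three, "value": self.counts}
        )


@dataclass
class SignatureVector:
    """Probability vector over the 96 classes; entries sum to 1."""

    probabilities: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (N_CLASSES,):
            raise ValueError(f"signature must have {N_CLASSES} entries")
        if np.any(self.probabilities < 0):
            raise ValueError("signature entries must be non-negative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("signature must sum to 1 within 1e-9")


def build_mutational_profile(variants: Iterable, genome, sample: str = "") -> MutationalProfile:
    """Count SNVs into the 96 trinucleotide classes.

    ``variants`` yields objects with contig/position/ref/alt attributes;
    ``genome`` maps contig name to sequence (a dict or an object with a
    ``sequence(name)`` method). Indels and variants with unresolvable context
    are skipped and counted on the returned profile.
    """
    counts = np.zeros(N_CLASSES)
    skipped_indels = 0
    skipped_errors = 0
    get_seq = genome.sequence if hasattr(genome, "sequence") else genome.__getitem__
    for v in variants:
        if len(v.ref) != 1 or len(v.alt) != 1:
            skipped_indels += 1
            continue
        try:
            label = trinucleotide_context(get_seq(v.contig), v.position, v.ref, v.alt)
        except ContextError:
            skipped_errors += 1
            continue
        counts[_CLASS_INDEX[label]] += 1
    return MutationalProfile(counts, sample, skipped_indels, skipped_errors)


def substitution_spectrum(profile: MutationalProfile) -> np.ndarray:
    """Relative contribution of the six substitution types (sums to 1).

    The T>C class carries all A>G-equivalent events by construction of the
    pyrimidine collapsing.
    """
    if profile.total == 0:
        raise ValueError("spectrum undefined for an empty profile")
    per_class = profile.counts.reshape(6, 16).sum(axis=1)
    return per_class / per_class.sum()


def make_tada_signature(
    components: Sequence[SignatureVector | np.ndarray | Sequence[float]],
    name: str = "TadA",
) -> SignatureVector:
    """Pool component signatures into a single T>C-only deaminase signature.

    Components are summed element-wise, any mass outside the 16 T>C classes is
    zeroed (other substitutions are assumed not to contribute to deaminase
    activity), and the result is renormalized to sum to 1.
    """
    if len(components) == 0:
        raise ValueError("at least one component signature required")
    pooled = np.zeros(N_CLASSES)
    for c in components:
        vec = c.probabilities if isinstance(c, SignatureVector) else np.asarray(c, dtype=float)
        if vec.shape != (N_CLASSES,):
            raise ValueError(f"component must have {N_CLASSES} entries")
        pooled += vec
    masked = np.zeros(N_CLASSES)
    masked[TC_INDICES] = pooled[TC_INDICES]
    total = masked.sum()
    if total <= 0:
        raise ValueError("pooled signature has no T>C mass")
    return SignatureVector(masked / total, name=name)


def normalize_profile_to_median(
    profile: MutationalProfile, median_snvs: float = 428
) -> MutationalProfile:
    """Scale a profile so its counts sum to ``median_snvs`` (default 428).

    Makes samples with different mutation loads comparable; counts stay
    real-valued (no rounding here).
    """
    if profile.total == 0:
        raise ValueError("cannot normalize an empty profile")
    return MutationalProfile(
        profile.counts * (median_snvs / profile.total), sample=profile.sample
    )


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def spike_in_signature(
    profile: MutationalProfile, signature: SignatureVector, k: int
) -> MutationalProfile:
    """Add k signature-distributed SNVs to a profile.

    The k SNVs are distributed over the 96 classes proportionally to the
    signature and rounded half-away-from-zero per class, so the realized total
    added may differ slightly from k.
    """
    if k < 0:
        raise ValueError("spike-in count must be non-negative")
    added = _round_half_away(k * signature.probabilities)
    return MutationalProfile(profile.counts + added, sample=profile.sample)


def cosine_similarity(a, b) -> float:
    """cos(a, b) = a.b / (|a| |b|); 1 means identical direction, 0 orthogonal."""
    va = a.counts if isinstance(a, MutationalProfile) else (
        a.probabilities if isinstance(a, SignatureVector) else np.asarray(a, dtype=float)
    )
    vb = b.counts if isinstance(b, MutationalProfile) else (
        b.probabilities if isinstance(b, SignatureVector) else np.asarray(b, dtype=float)
    )
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


# ---------------------------------------------------------------------------
# TSV interchange: columns substitution, fivePrime, threePrime, value


def write_profile_tsv(profile: MutationalProfile, path: str | Path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False)


def _read_96_values(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    required = {"substitution", "fivePrime", "threePrime", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"expected columns {sorted(required)} in {path}")
    values = np.zeros(N_CLASSES)
    for _, row in df.iterrows():
        label = f"{row['fivePrime']}[{row['substitution']}]{row['threePrime']}"
        values[_CLASS_INDEX[label]] = row["value"]
    return values


def read_profile_tsv(path: str | Path, sample: str = "") -> MutationalProfile:
    return MutationalProfile(_read_96_values(path), sample=sample)


def read_signature_tsv(path: str | Path, name: str = "") -> SignatureVector:
    values = _read_96_values(path)
    return SignatureVector(values / values.sum(), name=name or Path(path).stem)


def write_signature_tsv(signature: SignatureVector, path: str | Path) -> None:
    MutationalProfile(signature.probabilities).to_frame().to_csv(path, sep="\t", index=False)
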