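"""File interchange: FASTA/FASTQ, VCF v4.2, BED, and TSV tables.

VCF carries the clone/bulk pair as a two-sample file with the site
annotations the filter cascade consumes (INFO QD, MQ, FS, HaplotypeScore,
MQRankSum, ReadPosRankSum) and FORMAT DP/AD/GQ. Region files are BED
(0-based half-open); copy-ratio segments are four-column TSV.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rna import RnaSite
from .somatic import (
    SITE_ANNOTATIONS,
    CopyRatioSegment,
    RegionSet,
    SampleEvidence,
    VariantRecord,
)
from .synthetic import GenomeSequence, SimulatedRead

CLONE_SAMPLE = "CLONE"
CONTROL_SAMPLE = "BULK"


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, autosome_names: Iterable[str] = ()) -> GenomeSequence:
    contigs = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return GenomeSequence(contigs, frozenset(autosome_names))


def write_fastq(reads: Sequence[SimulatedRead], path: str | Path, quality: int = 37) -> None:
    with open(path, "w") as fh:
        for read in reads:
            qual = chr(quality + 33) * len(read.sequence)
            fh.write(f"@{read.name}\n{read.sequence}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> list[SimulatedRead]:
    return [SimulatedRead(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fastq")]


# ---------------------------------------------------------------------------
# VCF


def _vcf_header(contig_lengths: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contig_lengths.items():
        header.contigs.add(name, length=length)
    for annot in SITE_ANNOTATIONS:
        header.info.add(annot, 1, "Float", f"Site annotation {annot}")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.add_sample(CLONE_SAMPLE)
    header.add_sample(CONTROL_SAMPLE)
    return header


def write_clone_bulk_vcf(
    clone_records: Sequence[VariantRecord],
    control_records: Sequence[VariantRecord],
    contig_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write paired clone/control records as an uncompressed two-sample VCF."""
    control_index = {r.key: r for r in control_records}
    header = _vcf_header(contig_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for clone in clone_records:
            rec = vcf.new_record(
                contig=clone.contig,
                start=clone.position - 1,
                alleles=(clone.ref, clone.alt),
            )
            if clone.site_quality is not None:
                rec.qual = clone.site_quality
            for annot in SITE_ANNOTATIONS:
                value = clone.annotations.get(annot)
                if value is not None:
                    rec.info[annot] = value
            control = control_index.get(clone.key)
            for sample, record in ((CLONE_SAMPLE, clone), (CONTROL_SAMPLE, control)):
                if record is None:
                    continue
                ev = record.evidence
                fmt = rec.samples[sample]
                if ev.depth is not None and ev.alt_count is not None:
                    fmt["DP"] = ev.depth
                    fmt["AD"] = (ev.depth - ev.alt_count, ev.alt_count)
                    fmt["GT"] = (0, 1) if ev.alt_count > 0 else (0, 0)
                if ev.gq is not None:
                    fmt["GQ"] = ev.gq
            vcf.write(rec)


def read_clone_bulk_vcf(
    path: str | Path,
    clone_sample: str = CLONE_SAMPLE,
    control_sample: str = CONTROL_SAMPLE,
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Read a two-sample VCF into paired clone and control record lists."""
    clone_records: list[VariantRecord] = []
    control_records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            annotations = {}
            for annot in SITE_ANNOTATIONS:
                value = rec.info.get(annot)
                annotations[annot] = float(value) if value is not None else None
            for sample, out in ((clone_sample, clone_records),
                                (control_sample, control_records)):
                fmt = rec.samples[sample]
                depth = fmt.get("DP")
                ad = fmt.get("AD")
                alt_count = ad[1] if ad is not None and len(ad) > 1 and ad[1] is not None else None
                gq = fmt.get("GQ")
                out.append(VariantRecord(
                    contig=rec.contig,
                    position=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    site_quality=rec.qual,
                    annotations=dict(annotations),
                    evidence=SampleEvidence(depth, alt_count, gq),
                ))
    return clone_records, control_records


# ---------------------------------------------------------------------------
# BED regions, copy-ratio segments, tables


def write_bed(regions: RegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in regions.intervals():
            fh.write(f"{contig}\t{start}\t{end}\n")


def read_bed(path: str | Path, name: str = "", role: str = "") -> RegionSet:
    regions = RegionSet(name=name or Path(path).stem, role=role)
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            regions.add(fields[0], int(fields[1]), int(fields[2]))
    return regions


def write_segments_tsv(segments: Sequence[CopyRatioSegment], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["contig", "start", "end", "ratio"])
        for seg in segments:
            writer.writerow([seg.contig, seg.start, seg.end, seg.ratio])


def read_segments_tsv(path: str | Path) -> list[CopyRatioSegment]:
    df = pd.read_csv(path, sep="\t")
    return [CopyRatioSegment(row.contig, int(row.start), int(row.end), float(row.ratio))
            for row in df.itertuples()]


def write_rna_sites_tsv(sites: Sequence[RnaSite], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in sites]).to_csv(path, sep="\t", index=False)


def read_rna_sites_tsv(path: str | Path) -> list[RnaSite]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples():
        control_depth = None if pd.isna(row.control_depth) else int(row.control_depth)
        control_ref = None if pd.isna(row.control_ref) else int(row.control_ref)
        sites.append(RnaSite(
            contig=str(row.contig), position=int(row.position),
            ref=row.ref, alt=row.alt,
            treated_depth=int(row.treated_depth), treated_alt=int(row.treated_alt),
            control_depth=control_depth, control_ref=control_ref))
    return sites
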