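"""Genomic interval primitives and readers for the formats the pipeline touches.

All coordinates follow the BED convention: 0-based, half-open ``[start, end)``.
GTF input (1-based, closed) is converted on read. The only containers defined
here are thin dataclasses; tabular data downstream lives in pandas.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


class BedParseError(ValueError):
    """Raised when a BED/bedGraph line cannot be parsed; message names the line."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GeneModel:
    """A gene with one or more transcription start sites (0-based)."""

    gene_id: str
    chrom: str
    strand: str
    tss_list: list[int]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id}: at least one TSS required")


@dataclass
class PeakSet:
    """One sample's peak intervals for one histone mark, plus library stats."""

    sample_id: str
    mark: str
    intervals: list[GenomicInterval] = field(default_factory=list)
    total_mapped_reads: int | None = None
    spike_reads: int | None = None

    def __post_init__(self) -> None:
        for name in ("total_mapped_reads", "spike_reads"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_peaks(self) -> int:
        return len(self.intervals)


@dataclass
class PromoterWindow:
    """A TSS-centred promoter window, clamped at the chromosome start."""

    gene_id: str
    interval: GenomicInterval
    half_width: int = 2000


@dataclass
class CoverageTrack:
    """Fragment intervals or (interval, depth) pairs for one sample and mark.

    ``mode`` is ``"fragments"`` (records are GenomicInterval) or ``"bedgraph"``
    (records are (GenomicInterval, depth) tuples). Records are sorted by
    (chrom, start) on load.
    """

    sample_id: str
    mark: str
    records: list
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in {"fragments", "bedgraph"}:
            raise ValueError(f"unknown coverage mode {self.mode!r}")


def _data_lines(path: str | Path):
    """Yield (line_number, stripped_line) skipping headers/comments/blank lines."""
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def _parse_interval(fields: Sequence[str], path, lineno: int) -> GenomicInterval:
    if len(fields) < 3:
        raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
    strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
    try:
        return GenomicInterval(chrom, start, end, strand)
    except ValueError as exc:
        raise BedParseError(f"{path}:{lineno}: {exc}") from exc


def read_peak_bed(path: str | Path, sample_id: str, mark: str,
                  total_mapped_reads: int | None = None,
                  spike_reads: int | None = None) -> PeakSet:
    """Read a BED3+ peak file into a PeakSet.

    Header/track/comment lines are skipped; an empty file yields an empty
    PeakSet. Malformed coordinates raise :class:`BedParseError` naming the line.
    """
    intervals = [
        _parse_interval(line.split("\t"), path, lineno)
        for lineno, line in _data_lines(path)
    ]
    return PeakSet(sample_id=sample_id, mark=mark, intervals=intervals,
                   total_mapped_reads=total_mapped_reads, spike_reads=spike_reads)


def write_peak_bed(peaks: PeakSet, path: str | Path) -> None:
    """Write peak intervals as BED6 (name = sample:mark, score 0)."""
    with open(path, "w") as handle:
        for iv in peaks.intervals:
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                f"{peaks.sample_id}:{peaks.mark}\t0\t{iv.strand}\n"
            )


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_gene_models(path: str | Path, fmt: str | None = None) -> list[GeneModel]:
    """Read gene models from BED (>=6 columns) or GTF.

    TSS is the first transcribed base: ``start`` for '+' genes, ``end - 1``
    (0-based) for '-' genes. Multiple transcripts of one gene are pooled into
    a single model with a deduplicated, sorted ``tss_list``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "GTF" if path.suffix.lower() in {".gtf", ".gff"} else "BED"
    fmt = fmt.upper()
    if fmt in {"BED", "BED6", "BED12"}:
        entries = _gene_entries_bed(path)
    elif fmt == "GTF":
        entries = _gene_entries_gtf(path)
    else:
        raise ValueError(f"unrecognized gene-model format {fmt!r}")

    genes: dict[str, GeneModel] = {}
    for gene_id, chrom, strand, tss in entries:
        if gene_id in genes:
            model = genes[gene_id]
            if model.chrom != chrom:
                raise ValueError(
                    f"gene {gene_id}: conflicting chromosomes {model.chrom} vs {chrom}"
                )
            if tss not in model.tss_list:
                model.tss_list.append(tss)
        else:
            genes[gene_id] = GeneModel(gene_id, chrom, strand, [tss])
    for model in genes.values():
        model.tss_list.sort()
    return list(genes.values())


def _gene_entries_bed(path: Path):
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 6:
            raise BedParseError(
                f"{path}:{lineno}: gene-model BED needs >=6 fields (name, strand)"
            )
        iv = _parse_interval(fields, path, lineno)
        strand = fields[5]
        if strand not in {"+", "-"}:
            raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        tss = iv.start if strand == "+" else iv.end - 1
        yield fields[3], iv.chrom, strand, tss


def _gene_entries_gtf(path: Path):
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 9:
            raise BedParseError(f"{path}:{lineno}: GTF needs 9 fields")
        feature = fields[2]
        if feature not in {"transcript", "gene", "mRNA"}:
            continue
        chrom, start1, end1, strand = fields[0], int(fields[3]), int(fields[4]), fields[6]
        if strand not in {"+", "-"}:
            raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        match = _GTF_GENE_ID.search(fields[8])
        if not match:
            raise BedParseError(f"{path}:{lineno}: missing gene_id attribute")
        # GTF is 1-based closed: [start1, end1] -> 0-based half-open [start1-1, end1)
        tss = start1 - 1 if strand == "+" else end1 - 1
        yield match.group(1), chrom, strand, tss


def promoter_windows(genes: Iterable[GeneModel], half_width: int = 2000) -> list[PromoterWindow]:
    """Strand-agnostic TSS +/- half_width windows, one per TSS, clamped at 0."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    windows = []
    for gene in genes:
        for tss in gene.tss_list:
            start = max(0, tss - half_width)
            windows.append(
                PromoterWindow(
                    gene_id=gene.gene_id,
                    interval=GenomicInterval(gene.chrom, start, tss + half_width, gene.strand),
                    half_width=half_width,
                )
            )
    return windows


def read_coverage(path: str | Path, mode: str, sample_id: str = "", mark: str = "") -> CoverageTrack:
    """Read a fragment BED (mode='fragments') or 4-column bedGraph (mode='bedgraph')."""
    records: list = []
    if mode == "fragments":
        for lineno, line in _data_lines(path):
            records.append(_parse_interval(line.split("\t"), path, lineno))
        unsorted = any(
            (a.chrom, a.start) > (b.chrom, b.start) for a, b in zip(records, records[1:])
        )
        records.sort(key=lambda iv: (iv.chrom, iv.start))
    elif mode == "bedgraph":
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 4:
                raise BedParseError(f"{path}:{lineno}: bedGraph needs 4 fields")
            iv = _parse_interval(fields[:3], path, lineno)
            try:
                depth = float(fields[3])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-numeric depth") from exc
            if depth < 0:
                raise BedParseError(f"{path}:{lineno}: negative depth {depth}")
            records.append((iv, depth))
        unsorted = any(
            (a[0].chrom, a[0].start) > (b[0].chrom, b[0].start)
            for a, b in zip(records, records[1:])
        )
        records.sort(key=lambda rec: (rec[0].chrom, rec[0].start))
    else:
        raise ValueError(f"unknown coverage mode {mode!r}")
    if unsorted:
        logger.info("coverage %s was unsorted; sorted on load", path)
    return CoverageTrack(sample_id=sample_id, mark=mark, records=records, mode=mode)
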