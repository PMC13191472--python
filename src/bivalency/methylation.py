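"""Promoter methylation from CpG-level bisulfite calls.

The region summary is the *weighted* methylation level — summed methylated
read counts over summed total read counts across the region's covered CpGs —
so deeply covered CpGs contribute proportionally more than shallow ones.
Regions with fewer than ``min_cpg`` covered CpGs (default 30) are not
classified; a weighted level strictly above 0.5 marks a region
hypermethylated. Also computes CpG density and the observed/expected CpG
ratio from sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import GenomicInterval
from .states import STATE_ORDER, ChromatinState

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CpGCall:
    """Methylation evidence at one CpG dyad (strand-combined)."""

    chrom: str
    pos: int
    meth_reads: int
    total_reads: int

    def __post_init__(self) -> None:
        if self.total_reads < 1:
            raise ValueError("total_reads must be >= 1")
        if not 0 <= self.meth_reads <= self.total_reads:
            raise ValueError("meth_reads must be in [0, total_reads]")


class MethylationClass(str, Enum):
    HYPERMETHYLATED = "HYPERMETHYLATED"
    NOT_HYPERMETHYLATED = "NOT_HYPERMETHYLATED"
    INSUFFICIENT_CPG = "INSUFFICIENT_CPG"


@dataclass
class RegionMethylation:
    region: GenomicInterval
    n_cpg: int
    weighted_level: float | None
    classification: MethylationClass


def weighted_methylation_level(calls: Sequence[CpGCall]) -> float:
    """Coverage-weighted level: sum(meth) / sum(total), not a mean of ratios."""
    if not calls:
        raise ValueError("weighted methylation level of an empty call list")
    meth = sum(c.meth_reads for c in calls)
    total = sum(c.total_reads for c in calls)
    return meth / total


def classify_region_methylation(
    region: GenomicInterval,
    cpg_calls: Iterable[CpGCall],
    min_cpg: int = 30,
    threshold: float = 0.5,
) -> RegionMethylation:
    """Classify one region's methylation from the CpG calls it contains.

    Counts calls with position in ``[start, end)``. Fewer than ``min_cpg``
    covered CpGs -> INSUFFICIENT_CPG (the level is still reported when at
    least one call exists); otherwise HYPERMETHYLATED iff the weighted level
    strictly exceeds ``threshold``.
    """
    inside = [
        c for c in cpg_calls
        if c.chrom == region.chrom and region.start <= c.pos < region.end
    ]
    level = weighted_methylation_level(inside) if inside else None
    if len(inside) < min_cpg:
        cls = MethylationClass.INSUFFICIENT_CPG
    elif level > threshold:
        cls = MethylationClass.HYPERMETHYLATED
    else:
        cls = MethylationClass.NOT_HYPERMETHYLATED
    return RegionMethylation(
        region=region, n_cpg=len(inside), weighted_level=level, classification=cls
    )


def methylation_by_state(
    region_classes: Mapping[str, MethylationClass],
    consensus_states,
) -> pd.DataFrame:
    """Percent hypermethylated promoters per chromatin-state category.

    Genes with INSUFFICIENT_CPG are excluded from denominators (logged);
    categories with no classified gene are absent from the output.
    """
    from .dynamics import _as_state_series  # shared coercion helper

    states = _as_state_series(consensus_states)
    shared = [g for g in region_classes if g in states.index]
    insufficient = sum(
        1 for g in shared
        if region_classes[g] is MethylationClass.INSUFFICIENT_CPG
    )
    if insufficient:
        logger.info("%d genes with insufficient CpG coverage excluded", insufficient)

    rows = []
    for state in STATE_ORDER:
        in_state = [g for g in shared if ChromatinState(states[g]) is state]
        classified = [
            g for g in in_state
            if region_classes[g] is not MethylationClass.INSUFFICIENT_CPG
        ]
        if not classified:
            continue
        n_hyper = sum(
            1 for g in classified
            if region_classes[g] is MethylationClass.HYPERMETHYLATED
        )
        rows.append(
            {
                "state": state.value,
                "n_classified": len(classified),
                "n_hyper": n_hyper,
                "pct_hyper": 100.0 * n_hyper / len(classified),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CpGDensity:
    cg_count: int
    density_per_kb: float
    oe_ratio: float | None  # observed/expected = N_CG * L / (N_C * N_G); None if undefined


def cpg_density(sequence: str, window: GenomicInterval | None = None) -> CpGDensity:
    """CG-dinucleotide count, density per kb and observed/expected ratio.

    ``sequence`` is the chromosome (or any reference) sequence; if ``window``
    is given, the slice ``[start, end)`` is analysed and must lie within the
    sequence. Case-insensitive; N never matches.
    """
    if window is not None:
        if window.end > len(sequence):
            raise ValueError("window extends beyond the supplied sequence")
        sequence = sequence[window.start:window.end]
    seq = sequence.upper()
    length = len(seq)
    cg = sum(1 for i in range(length - 1) if seq[i] == "C" and seq[i + 1] == "G")
    n_c, n_g = seq.count("C"), seq.count("G")
    oe = cg * length / (n_c * n_g) if n_c and n_g else None
    return CpGDensity(cg_count=cg, density_per_kb=cg * 1000.0 / length, oe_ratio=oe)


def read_cpg_calls(path, strand_column: bool | None = None) -> list[CpGCall]:
    """Read CpG calls from a TSV with columns chrom, pos, meth_reads, total_reads.

    If a fifth ``strand`` column is present, minus-strand records (the C of
    the dyad at pos+1) are merged into the plus-strand record at pos with
    summed counts, so one call per CpG dyad results.
    """
    frame = pd.read_csv(path, sep="\t", comment="#")
    cols = list(frame.columns[:4])
    frame = frame.rename(
        columns=dict(zip(cols, ["chrom", "pos", "meth_reads", "total_reads"]))
    )
    has_strand = "strand" in frame.columns or (
        len(frame.columns) > 4 and set(frame.iloc[:, 4].unique()) <= {"+", "-"}
    )
    if strand_column is None:
        strand_column = has_strand
    if strand_column:
        strand = frame["strand"] if "strand" in frame.columns else frame.iloc[:, 4]
        frame = frame.assign(
            pos=frame["pos"].where(strand == "+", frame["pos"] - 1)
        )
        merged = frame.groupby(["chrom", "pos"], as_index=False)[
            ["meth_reads", "total_reads"]
        ].sum()
        logger.info("strand-split CpG input merged to %d dyads", len(merged))
        frame = merged
    return [
        CpGCall(r.chrom, int(r.pos), int(r.meth_reads), int(r.total_reads))
        for r in frame.itertuples(index=False)
    ]
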