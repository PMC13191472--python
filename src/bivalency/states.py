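"""Promoter chromatin-state calling, cohort consensus and sample QC.

A gene's promoter is classified into one of four states per sample from the
presence of H3K4me3 and H3K27me3 peaks within its TSS +/- 2 kb windows:
BIVALENT (both marks), K4_ONLY, K27_ONLY, or UNMARKED. Cohort consensus calls
a gene bivalent when both marks co-occur in more than a threshold fraction of
samples (default strictly > 50%). Samples are QC-filtered to peak counts
within median +/- 30% per mark.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .genome_io import GeneModel, GenomicInterval, PeakSet, PromoterWindow, promoter_windows

logger = logging.getLogger(__name__)

K4 = "H3K4me3"
K27 = "H3K27me3"


class ChromatinState(str, Enum):
    BIVALENT = "BIVALENT"
    K4_ONLY = "K4_ONLY"
    K27_ONLY = "K27_ONLY"
    UNMARKED = "UNMARKED"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STATE_ORDER = [
    ChromatinState.BIVALENT,
    ChromatinState.K4_ONLY,
    ChromatinState.K27_ONLY,
    ChromatinState.UNMARKED,
]


def state_from_presence(k4_present: bool, k27_present: bool) -> ChromatinState:
    if k4_present and k27_present:
        return ChromatinState.BIVALENT
    if k4_present:
        return ChromatinState.K4_ONLY
    if k27_present:
        return ChromatinState.K27_ONLY
    return ChromatinState.UNMARKED


@dataclass
class QCReport:
    """Per-mark peak-count bounds and per-sample retention flags."""

    per_mark: pd.DataFrame  # index mark: median, lower, upper
    per_sample: pd.DataFrame  # rows: sample_id, mark, n_peaks, within_bounds
    retained: dict[str, bool]
    tol: float = 0.3

    @property
    def retained_samples(self) -> list[str]:
        return [s for s, ok in self.retained.items() if ok]


def qc_filter_samples(
    peak_counts: Mapping[str, Mapping[str, int]], tol: float = 0.3
) -> QCReport:
    """Retain samples whose peak counts sit within median +/- tol for every mark.

    Parameters
    ----------
    peak_counts
        mark -> {sample_id -> peak count}. A sample may contribute any subset
        of marks; it is retained only if every mark it supplies is in bounds.
    tol
        Relative half-width of the acceptance band (default 0.3, i.e. +/-30%).

    The per-mark median is computed once over all candidate samples; bounds
    ``[median*(1-tol), median*(1+tol)]`` are inclusive.
    """
    if not peak_counts or all(not v for v in peak_counts.values()):
        raise ValueError("empty cohort: no peak counts supplied")

    mark_rows, sample_rows = [], []
    ok_by_sample: dict[str, bool] = {}
    for mark, counts in peak_counts.items():
        if not counts:
            continue
        median = float(np.median(list(counts.values())))
        lower, upper = median * (1 - tol), median * (1 + tol)
        mark_rows.append({"mark": mark, "median": median, "lower": lower, "upper": upper})
        for sample_id, n in counts.items():
            ok = lower <= n <= upper
            sample_rows.append(
                {"sample_id": sample_id, "mark": mark, "n_peaks": n, "within_bounds": ok}
            )
            ok_by_sample[sample_id] = ok_by_sample.get(sample_id, True) and ok
    return QCReport(
        per_mark=pd.DataFrame(mark_rows).set_index("mark"),
        per_sample=pd.DataFrame(sample_rows),
        retained=ok_by_sample,
        tol=tol,
    )


def _trees_by_chrom(intervals: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    return trees


def _window_hits(trees: dict[str, IntervalTree], window: GenomicInterval) -> list[GenomicInterval]:
    tree = trees.get(window.chrom)
    if tree is None:
        return []
    return [hit.data for hit in tree.overlap(window.start, window.end)]


def _union_overlap_bp(peaks: Sequence[GenomicInterval], windows: Sequence[GenomicInterval]) -> int:
    """Union length of (peak ∩ window) segments across all pairs."""
    segments = []
    for w in windows:
        for p in peaks:
            if p.chrom != w.chrom:
                continue
            lo, hi = max(p.start, w.start), min(p.end, w.end)
            if lo < hi:
                segments.append((w.chrom, lo, hi))
    return _union_length(segments)


def _union_length(segments: list[tuple[str, int, int]]) -> int:
    total = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, lo, hi in segments:
        by_chrom.setdefault(chrom, []).append((lo, hi))
    for spans in by_chrom.values():
        spans.sort()
        cur_lo, cur_hi = spans[0]
        for lo, hi in spans[1:]:
            if lo > cur_hi:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        total += cur_hi - cur_lo
    return total


def classify_gene_state(
    windows: Sequence[PromoterWindow | GenomicInterval],
    k4_peaks: Sequence[GenomicInterval],
    k27_peaks: Sequence[GenomicInterval],
    require_mutual_overlap: bool = False,
) -> ChromatinState:
    """Classify one gene's promoter state from its windows and candidate peaks.

    A mark is *present* iff at least one of its peaks overlaps at least one
    promoter window by >= 1 bp. With ``require_mutual_overlap`` a BIVALENT
    call additionally requires an H3K4me3/H3K27me3 peak pair whose mutual
    intersection is non-empty and itself overlaps a window; failing that, the
    gene takes the state of the mark with the larger total promoter-overlap
    (ties resolve to K4_ONLY, logged).
    """
    wins = [w.interval if isinstance(w, PromoterWindow) else w for w in windows]
    k4_trees = _trees_by_chrom(k4_peaks)
    k27_trees = _trees_by_chrom(k27_peaks)
    k4_hits = {id(p): p for w in wins for p in _window_hits(k4_trees, w)}
    k27_hits = {id(p): p for w in wins for p in _window_hits(k27_trees, w)}
    state = state_from_presence(bool(k4_hits), bool(k27_hits))

    if state is ChromatinState.BIVALENT and require_mutual_overlap:
        for p4 in k4_hits.values():
            for p27 in k27_hits.values():
                if p4.chrom != p27.chrom:
                    continue
                lo, hi = max(p4.start, p27.start), min(p4.end, p27.end)
                if lo >= hi:
                    continue
                shared = GenomicInterval(p4.chrom, lo, hi)
                if any(shared.overlaps(w) for w in wins):
                    return ChromatinState.BIVALENT
        bp4 = _union_overlap_bp(list(k4_hits.values()), wins)
        bp27 = _union_overlap_bp(list(k27_hits.values()), wins)
        if bp4 == bp27:
            logger.info("mutual-overlap tie (%d bp each); resolved to K4_ONLY", bp4)
        return ChromatinState.K4_ONLY if bp4 >= bp27 else ChromatinState.K27_ONLY
    return state


@dataclass
class StateTable:
    """gene x sample chromatin-state matrix for one cohort."""

    states: pd.DataFrame  # index gene_id, columns sample_id, values ChromatinState
    cohort_id: str = ""

    @property
    def genes(self) -> pd.Index:
        return self.states.index

    @property
    def samples(self) -> pd.Index:
        return self.states.columns


def call_states_cohort(
    gene_models: Sequence[GeneModel],
    peak_sets_by_sample: Mapping[str, Mapping[str, PeakSet]],
    half_width: int = 2000,
    require_mutual_overlap: bool = False,
    cohort_id: str = "",
) -> StateTable:
    """Classify every gene in every sample that carries both marks.

    Samples missing either mark are excluded with a log notice. Genes on
    chromosomes absent from a sample's peak universe are UNMARKED there.
    """
    usable = {}
    for sample_id, by_mark in peak_sets_by_sample.items():
        if K4 in by_mark and K27 in by_mark:
            usable[sample_id] = by_mark
        else:
            logger.info("sample %s missing a mark; excluded from state calls", sample_id)
    if not usable:
        raise ValueError("no sample supplies both H3K4me3 and H3K27me3 peaks")

    windows_by_gene: dict[str, list[GenomicInterval]] = {}
    for w in promoter_windows(gene_models, half_width=half_width):
        windows_by_gene.setdefault(w.gene_id, []).append(w.interval)

    columns = {}
    for sample_id, by_mark in usable.items():
        k4_trees = _trees_by_chrom(by_mark[K4].intervals)
        k27_trees = _trees_by_chrom(by_mark[K27].intervals)
        calls = {}
        for gene_id, wins in windows_by_gene.items():
            k4_cand = [p for w in wins for p in _window_hits(k4_trees, w)]
            k27_cand = [p for w in wins for p in _window_hits(k27_trees, w)]
            if require_mutual_overlap:
                calls[gene_id] = classify_gene_state(
                    wins, k4_cand, k27_cand, require_mutual_overlap=True
                )
            else:
                calls[gene_id] = state_from_presence(bool(k4_cand), bool(k27_cand))
        columns[sample_id] = calls

    frame = pd.DataFrame(columns)
    frame.index.name = "gene_id"
    return StateTable(states=frame, cohort_id=cohort_id)


@dataclass
class ConsensusStateTable:
    """Per-gene cohort consensus state with support fractions."""

    table: pd.DataFrame  # columns: consensus_state, bivalent_support, k4_support, k27_support
    threshold: float = 0.5

    @property
    def consensus(self) -> pd.Series:
        return self.table["consensus_state"]


def consensus_states(state_table: StateTable, threshold: float = 0.5) -> ConsensusStateTable:
    """Cohort consensus: BIVALENT iff bivalent in strictly more than ``threshold``
    of samples; otherwise per-mark presence fractions decide the single-mark
    states (K4 takes precedence over K27 if both exceed the threshold, logged)."""
    states = state_table.states
    if states.shape[1] < 1:
        raise ValueError("consensus requires at least one sample")
    n = states.shape[1]
    biv = states.eq(ChromatinState.BIVALENT).sum(axis=1) / n
    k4 = states.isin([ChromatinState.BIVALENT, ChromatinState.K4_ONLY]).sum(axis=1) / n
    k27 = states.isin([ChromatinState.BIVALENT, ChromatinState.K27_ONLY]).sum(axis=1) / n

    consensus = pd.Series(ChromatinState.UNMARKED, index=states.index, dtype=object)
    is_biv = biv > threshold
    k4_wins = ~is_biv & (k4 > threshold)
    k27_wins = ~is_biv & ~k4_wins & (k27 > threshold)
    both_single = (~is_biv & (k4 > threshold) & (k27 > threshold)).sum()
    if both_single:
        logger.info(
            "%d genes exceed the threshold for both single marks without a "
            "bivalent consensus; K4_ONLY precedence applied", both_single
        )
    consensus[is_biv] = ChromatinState.BIVALENT
    consensus[k4_wins] = ChromatinState.K4_ONLY
    consensus[k27_wins] = ChromatinState.K27_ONLY

    table = pd.DataFrame(
        {
            "consensus_state": consensus,
            "bivalent_support": biv,
            "k4_support": k4,
            "k27_support": k27,
        }
    )
    table.index.name = "gene_id"
    return ConsensusStateTable(table=table, threshold=threshold)


def occupancy_matrix(
    state_table: StateTable, marks: Sequence[str] = (K4, K27)
) -> dict[str, pd.DataFrame]:
    """Binary gene x sample presence matrix per mark (PCA-ready)."""
    presence_states = {
        K4: [ChromatinState.BIVALENT, ChromatinState.K4_ONLY],
        K27: [ChromatinState.BIVALENT, ChromatinState.K27_ONLY],
    }
    out = {}
    for mark in marks:
        if mark not in presence_states:
            raise ValueError(f"unknown mark {mark!r}")
        out[mark] = state_table.states.isin(presence_states[mark]).astype(int)
    return out
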