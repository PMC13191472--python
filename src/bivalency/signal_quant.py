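"""Spike-in-calibrated promoter signal quantification and group statistics.

Signals are expressed as reads per million mapped reads (RPM), optionally
rescaled by a per-sample spike-in factor so that coverage is comparable
across samples sequenced at different depths per cell. Also provides merged
H3K27me3 peak widths, per-gene log2 fold changes, the Pearson correlation of
mark-ratio shifts against expression changes, and two-tailed Wilcoxon
rank-sum comparisons with an exact small-sample mode.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import CoverageTrack, GenomicInterval, PromoterWindow

logger = logging.getLogger(__name__)


@dataclass
class SpikeFactors:
    """Per-sample spike-in scaling factors, normalized to cohort mean spike."""

    spike_reads: dict[str, int]
    factors: dict[str, float]


def spike_scaling_factors(spike_reads_by_sample: Mapping[str, int]) -> SpikeFactors:
    """factor_i = mean(spike reads over cohort) / spike_reads_i.

    Any other positive global constant would differ only by a cohort-wide
    multiplier; the mean keeps factors centred near 1.
    """
    for sample, reads in spike_reads_by_sample.items():
        if not reads or reads <= 0:
            raise ValueError(f"sample {sample}: spike reads must be positive")
    mean = float(np.mean(list(spike_reads_by_sample.values())))
    factors = {s: mean / r for s, r in spike_reads_by_sample.items()}
    return SpikeFactors(spike_reads=dict(spike_reads_by_sample), factors=factors)


def _fragment_count(track: CoverageTrack, window: GenomicInterval, count_mode: str) -> float:
    n = 0
    for frag in track.records:
        if frag.chrom != window.chrom:
            continue
        if count_mode == "midpoint":
            mid = (frag.start + frag.end) // 2
            if window.start <= mid < window.end:
                n += 1
        elif frag.overlaps(window):
            n += 1
    return float(n)


def _bedgraph_mean_depth(track: CoverageTrack, window: GenomicInterval) -> float:
    acc = 0.0
    for iv, depth in track.records:
        bp = iv.overlap_bp(window)
        if bp:
            acc += depth * bp
    return acc / window.width


def promoter_signal(
    coverage: CoverageTrack,
    windows: Sequence[PromoterWindow],
    total_mapped_reads: int,
    spike_factor: float = 1.0,
    count_mode: str = "overlap",
) -> pd.DataFrame:
    """Per-window raw counts and spike-scaled RPM for one sample and mark.

    Fragments mode counts fragments overlapping the window by >= 1 bp
    (``count_mode="midpoint"`` counts fragment midpoints instead); bedGraph
    mode uses the interval-weighted mean depth over the window, an
    approximation to a fragment count. ``rpm = raw * 1e6 / total * factor``.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    chroms = {
        (rec.chrom if coverage.mode == "fragments" else rec[0].chrom)
        for rec in coverage.records
    }
    rows = []
    for w in windows:
        if w.interval.chrom not in chroms:
            logger.info("window for %s on %s absent from coverage; rpm 0",
                        w.gene_id, w.interval.chrom)
            raw = 0.0
        elif coverage.mode == "fragments":
            raw = _fragment_count(coverage, w.interval, count_mode)
        else:
            raw = _bedgraph_mean_depth(coverage, w.interval)
        rows.append(
            {
                "gene_id": w.gene_id,
                "chrom": w.interval.chrom,
                "start": w.interval.start,
                "end": w.interval.end,
                "raw_count": raw,
                "rpm": raw * 1e6 / total_mapped_reads * spike_factor,
            }
        )
    return pd.DataFrame(rows)


def gene_level_signal(window_signal: pd.DataFrame, agg: str = "max") -> pd.Series:
    """Collapse per-window RPM to gene level (default: strongest window)."""
    return window_signal.groupby("gene_id")["rpm"].agg(agg)


def merged_peak_width(
    k27_peaks: Sequence[GenomicInterval],
    window: GenomicInterval | PromoterWindow,
    clip: bool = False,
) -> int:
    """Union length (bp) of all peaks intersecting the window.

    Measured on full peak extents by default — the quantity of interest is
    domain breadth, which clipping to the window would censor; ``clip=True``
    restricts to the window.
    """
    win = window.interval if isinstance(window, PromoterWindow) else window
    spans = []
    for p in k27_peaks:
        if not p.overlaps(win):
            continue
        if clip:
            spans.append((max(p.start, win.start), min(p.end, win.end)))
        else:
            spans.append((p.start, p.end))
    if not spans:
        return 0
    spans.sort()
    total, (cur_lo, cur_hi) = 0, spans[0]
    for lo, hi in spans[1:]:
        if lo > cur_hi:
            total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    return total + (cur_hi - cur_lo)


def log2fc_signal(rpm_a, rpm_b, pseudocount: float = 1.0):
    """Per-gene log2((B + c) / (A + c)); antisymmetric in (A, B)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    a, b = np.asanyarray(rpm_a, dtype=float), np.asanyarray(rpm_b, dtype=float)
    result = np.log2((b + pseudocount) / (a + pseudocount))
    if isinstance(rpm_a, pd.Series):
        return pd.Series(result, index=rpm_a.index)
    return result


def build_delta_table(
    rpm_k4_a, rpm_k4_b, rpm_k27_a, rpm_k27_b, expr_a, expr_b, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Assemble per-gene log2 fold changes of both marks and expression.

    ``ratio_shift = d_k4 - d_k27`` measures how much the activating mark
    gains relative to the repressive mark between conditions.
    """
    d_k4 = log2fc_signal(rpm_k4_a, rpm_k4_b, pseudocount)
    d_k27 = log2fc_signal(rpm_k27_a, rpm_k27_b, pseudocount)
    d_expr = log2fc_signal(expr_a, expr_b, pseudocount)
    table = pd.DataFrame({"d_k4": d_k4, "d_k27": d_k27, "d_expr": d_expr})
    table["ratio_shift"] = table["d_k4"] - table["d_k27"]
    return table


def ratio_expression_correlation(delta_table: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r between ratio_shift and d_expr; two-sided p from t (n-2 df)."""
    clean = delta_table[["ratio_shift", "d_expr"]].dropna()
    clean = clean[np.isfinite(clean).all(axis=1)]
    n = len(clean)
    if n < 3:
        raise ValueError("correlation requires >= 3 genes with finite values")
    x, y = clean["ratio_shift"].to_numpy(), clean["d_expr"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in ratio_shift or d_expr; r undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), n


def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def _ranksum_null_moments(ranks: np.ndarray, n1: int) -> tuple[float, float]:
    """Exact 2nd and 4th central moments of the rank-sum under the null.

    The null draws n1 ranks without replacement from the observed (midrank)
    multiset; moments follow from inclusion-indicator expansions, so tied
    ranks are handled exactly (the variance reduces to the classical
    tie-corrected formula).
    """
    N = ranks.size
    y = ranks - ranks.mean()
    f = n1 / N
    p = [1.0]
    for k in range(4):
        p.append(p[-1] * (n1 - k) / (N - k))

    def ej(powers: tuple[int, ...]) -> float:
        # E[prod_k (I_k - f)^{a_k}] over distinct indices; I^a = I for a >= 1,
        # so (I - f)^a = A_a * I + B_a with A_a = (1-f)^a - (-f)^a, B_a = (-f)^a
        A = [(1 - f) ** a - (-f) ** a for a in powers]
        B = [(-f) ** a for a in powers]
        total = 0.0
        r = len(powers)
        for mask in range(1 << r):
            term, cnt = 1.0, 0
            for k in range(r):
                if mask >> k & 1:
                    term *= A[k]
                    cnt += 1
                else:
                    term *= B[k]
            total += term * p[cnt]
        return total

    S = {k: float((y ** k).sum()) for k in range(1, 5)}  # S[1] == 0
    # products of power sums over distinct index patterns
    s31 = S[3] * S[1] - S[4]
    s22 = S[2] ** 2 - S[4]
    s211 = S[2] * S[1] ** 2 - S[2] ** 2 - 2 * S[3] * S[1] + 2 * S[4]
    s1111 = S[1] ** 4 - 6 * S[2] * S[1] ** 2 + 3 * S[2] ** 2 + 8 * S[3] * S[1] - 6 * S[4]
    mu2 = S[2] * ej((2,)) + (S[1] ** 2 - S[2]) * ej((1, 1))
    mu4 = (
        S[4] * ej((4,))
        + 4 * s31 * ej((3, 1))
        + 3 * s22 * ej((2, 2))
        + 6 * s211 * ej((2, 1, 1))
        + s1111 * ej((1, 1, 1, 1))
    )
    return mu2, mu4


def wilcoxon_rank_sum(x, y, exact_max_n: int = 8) -> float:
    """Two-tailed Wilcoxon rank-sum p-value.

    When both groups have at most ``exact_max_n`` observations the p-value is
    computed by full enumeration of rank assignments (midranks for ties):
    p = P(|W - E[W]| >= |w_obs - E[W]|) over all C(n1+n2, n1) splits. Larger
    samples use the normal approximation with exact tie-corrected null
    moments, a continuity correction, and an Edgeworth fourth-moment
    refinement (the skewness terms cancel in the two-sided sum).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = _midranks(np.concatenate([x, y]))
    w_obs = ranks[: x.size].sum()
    mu = x.size * ranks.mean()
    dev = abs(w_obs - mu)
    if x.size <= exact_max_n and y.size <= exact_max_n:
        hits = total = 0
        for combo in combinations(range(x.size + y.size), x.size):
            total += 1
            if abs(ranks[list(combo)].sum() - mu) >= dev - 1e-12:
                hits += 1
        return hits / total
    mu2, mu4 = _ranksum_null_moments(ranks, x.size)
    if mu2 == 0:  # all observations tied
        return 1.0
    z = max(0.0, dev - 0.5) / math.sqrt(mu2)
    excess_kurtosis = mu4 / mu2 ** 2 - 3.0
    tail = stats.norm.sf(z) + excess_kurtosis / 24 * (z ** 3 - 3 * z) * stats.norm.pdf(z)
    return float(min(1.0, max(0.0, 2 * tail)))


def compare_groups(
    values_by_category: Mapping[str, Sequence[float]], exact_max_n: int = 8
) -> pd.DataFrame:
    """All pairwise two-tailed Wilcoxon rank-sum tests between categories."""
    for name, values in values_by_category.items():
        if len(values) == 0:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    names = list(values_by_category)
    for a, b in combinations(names, 2):
        p = wilcoxon_rank_sum(values_by_category[a], values_by_category[b], exact_max_n)
        rows.append({"group_a": a, "group_b": b, "p_value": p})
    return pd.DataFrame(rows)
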