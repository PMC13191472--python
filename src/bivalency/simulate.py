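"""Synthetic cohort generator with planted ground truth.

Emulates the data structure of a bivalent-promoter study at desk scale:
toy chromosomes with non-overlapping promoters, per-sample peak sets with
planted four-state labels, mark dropout and false-positive noise,
state-dependent H3K27me3 peak widths (narrow at newly/cancer-bivalent
promoters, broad at H3K27me3-only loci), spike-in read counts, Poisson
fragment coverage, Beta-Binomial CpG methylation, and expression whose log
fold change is linearly coupled to the planted H3K4me3/H3K27me3 shift.

Every artifact draws from its own random stream seeded as ``seed + offset``
so adding one generator never perturbs the others; identical (config, seed)
yields identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GeneModel, GenomicInterval, PeakSet, PromoterWindow, promoter_windows
from .states import K4, K27, ChromatinState

# stream offsets, one per artifact
_GENOME, _STATES, _PEAKS, _METH, _EXPR, _SPIKE = 1, 2, 3, 4, 5, 6

# H3K27me3 width classes
NARROW, BROAD, STANDARD = "narrow", "broad", "standard"


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n_genes: int = 1000
    n_chroms: int = 4
    n_samples: int = 5
    seed: int = 0
    half_width: int = 2000
    promoter_gap: int = 8000          # bp between adjacent promoter slots
    chrom_length: int | None = None   # None = auto-sized to fit
    state_priors: dict = field(default_factory=lambda: {
        ChromatinState.BIVALENT: 0.15,
        ChromatinState.K4_ONLY: 0.45,
        ChromatinState.K27_ONLY: 0.15,
        ChromatinState.UNMARKED: 0.25,
    })
    dropout: dict = field(default_factory=lambda: {K4: 0.1, K27: 0.1})
    false_positive_rate: float = 0.02
    # ln-scale (mu, sigma) of peak widths per (mark, width class)
    peak_width_params: dict = field(default_factory=lambda: {
        (K4, STANDARD): (math.log(1500), 0.3),
        (K27, STANDARD): (math.log(3000), 0.4),
        (K27, BROAD): (math.log(8000), 0.4),
        (K27, NARROW): (math.log(800), 0.3),
    })
    # Poisson fragment-count means per promoter
    marked_rate: float = 200.0
    background_rate: float = 5.0
    fragment_length: int = 200
    spike_base: int = 50000           # per-sample spike reads ~ U[0.8, 1.2] * base
    # Beta(alpha, beta) of true methylation level per state
    meth_params: dict = field(default_factory=lambda: {
        ChromatinState.BIVALENT: (2.0, 18.0),
        ChromatinState.K4_ONLY: (2.0, 18.0),
        ChromatinState.K27_ONLY: (5.0, 5.0),
        ChromatinState.UNMARKED: (12.0, 4.0),
    })
    meth_depth: int = 20
    n_cpg_per_region: int = 50
    # expression coupling: d_expr = beta * ratio_shift + N(0, sigma);
    # with ratio_shift ~ N(0, 1), beta=1 and sigma=sqrt(3) give true rho = 0.5
    expression_beta: float = 1.0
    expression_sigma: float = math.sqrt(3.0)
    ratio_shift_sigma: float = 1.0
    expression_base_log2: float = 4.0
    expression_base_sd: float = 1.0

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng(self.seed + offset)


def simulate_genome(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, int]]:
    """Place ``n_genes`` with pairwise-disjoint promoters on toy chromosomes.

    Genes are laid out on a slot grid (slot = promoter width + gap) with a
    jittered TSS inside each slot, so promoters can never collide. Returns
    gene models and chromosome lengths.
    """
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = config.rng(_GENOME)
    slot = 2 * config.half_width + config.promoter_gap
    per_chrom = math.ceil(config.n_genes / config.n_chroms)
    needed = per_chrom * slot + config.half_width
    if config.chrom_length is not None and config.chrom_length < needed:
        raise ValueError(
            f"promoters cannot be packed: need {needed} bp per chromosome, "
            f"got {config.chrom_length}; supply larger chromosomes"
        )
    length = config.chrom_length or needed

    genes, chrom_lengths = [], {}
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        chrom_lengths[chrom] = length
        for si in range(per_chrom):
            idx = ci * per_chrom + si
            if idx >= config.n_genes:
                break
            jitter = int(rng.integers(0, config.promoter_gap))
            tss = si * slot + config.half_width + jitter
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"g{idx:05d}", chrom, strand, [tss]))
    return genes, chrom_lengths


def assign_states(genes: list[GeneModel], config: SimulationConfig) -> pd.Series:
    """Draw each gene's true condition-A state from the state priors."""
    rng = config.rng(_STATES)
    states = list(config.state_priors)
    probs = np.array([config.state_priors[s] for s in states], dtype=float)
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("state priors must sum to 1")
    draws = rng.choice(len(states), size=len(genes), p=probs)
    series = pd.Series([states[i] for i in draws],
                       index=[g.gene_id for g in genes], dtype=object)
    series.index.name = "gene_id"
    return series


def simulate_transition(
    truth_a: pd.Series,
    origin_mixture: dict[ChromatinState, float],
    n_new_bivalent: int,
    config: SimulationConfig,
) -> pd.Series:
    """Flip exactly ``n_new_bivalent`` genes to BIVALENT in condition B.

    Origins are drawn from ``origin_mixture`` (a distribution over non-
    bivalent condition-A states); all other genes keep their A state.
    Raises if an origin class lacks enough eligible genes.
    """
    if ChromatinState.BIVALENT in origin_mixture:
        raise ValueError("origin mixture ranges over non-bivalent states only")
    weights = np.array(list(origin_mixture.values()), dtype=float)
    if not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("origin mixture must sum to 1")
    rng = config.rng(_STATES + 100)
    origins = list(origin_mixture)
    counts = rng.multinomial(n_new_bivalent, weights) if n_new_bivalent else np.zeros(len(origins), int)

    truth_b = truth_a.copy()
    for state, k in zip(origins, counts):
        pool = truth_a.index[truth_a == state]
        if len(pool) < k:
            raise ValueError(
                f"not enough {state.value} genes ({len(pool)}) to plant {k} new bivalent"
            )
        chosen = rng.choice(pool, size=k, replace=False)
        truth_b[chosen] = ChromatinState.BIVALENT
    return truth_b


def width_classes(truth: pd.Series, newly_bivalent: pd.Index | None = None) -> pd.Series:
    """H3K27me3 width class per gene: narrow at newly bivalent promoters,
    broad at H3K27me3-only loci, standard elsewhere."""
    classes = pd.Series(STANDARD, index=truth.index, dtype=object)
    classes[truth == ChromatinState.K27_ONLY] = BROAD
    if newly_bivalent is not None:
        classes[truth.index.isin(newly_bivalent)] = NARROW
    return classes


def _territories(windows: dict[str, GenomicInterval]) -> dict[str, tuple[int, int]]:
    """Per gene, the open span between its neighbours' promoters.

    Peaks are clipped to this span so a peak planted at one promoter can
    never create a spurious call at another.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene_id, win in windows.items():
        by_chrom.setdefault(win.chrom, []).append((win.start, win.end, gene_id))
    out: dict[str, tuple[int, int]] = {}
    for spans in by_chrom.values():
        spans.sort()
        for i, (start, end, gene_id) in enumerate(spans):
            lo = spans[i - 1][1] if i > 0 else 0
            hi = spans[i + 1][0] if i + 1 < len(spans) else int(2**40)
            out[gene_id] = (lo, hi)
    return out


def _marks_of(state: ChromatinState) -> set[str]:
    return {
        ChromatinState.BIVALENT: {K4, K27},
        ChromatinState.K4_ONLY: {K4},
        ChromatinState.K27_ONLY: {K27},
        ChromatinState.UNMARKED: set(),
    }[state]


def simulate_cohort(
    truth: pd.Series,
    genes: list[GeneModel],
    config: SimulationConfig,
    condition: str = "A",
    k27_width_class: pd.Series | None = None,
    rng_offset: int = 0,
) -> tuple[dict[str, dict[str, PeakSet]], pd.DataFrame]:
    """Per-sample peak sets for both marks, plus a manifest table.

    For each truly marked promoter a peak overlapping it is emitted with
    probability 1 - dropout; width is log-normal per (mark, width class) and
    the position is jittered while keeping >= 1 bp promoter overlap, so
    dropout is the only false-negative channel. Unmarked promoters receive a
    spurious peak at ``false_positive_rate``. With zero noise, per-sample
    classification reproduces the truth exactly.
    """
    rng = config.rng(_PEAKS + rng_offset)
    spike_rng = config.rng(_SPIKE + rng_offset)
    windows = {w.gene_id: w.interval for w in promoter_windows(genes, config.half_width)}
    territory = _territories(windows)
    if k27_width_class is None:
        k27_width_class = width_classes(truth)

    peak_sets: dict[str, dict[str, PeakSet]] = {}
    manifest_rows = []
    for si in range(config.n_samples):
        sample_id = f"{condition}_s{si + 1}"
        spike = int(round(config.spike_base * spike_rng.uniform(0.8, 1.2)))
        by_mark: dict[str, PeakSet] = {}
        for mark in (K4, K27):
            eps = config.dropout.get(mark, 0.0)
            intervals = []
            for gene in genes:
                win = windows[gene.gene_id]
                state = ChromatinState(truth[gene.gene_id])
                marked = mark in _marks_of(state)
                emit = rng.random() < (1 - eps) if marked else rng.random() < config.false_positive_rate
                if not emit:
                    continue
                wclass = k27_width_class[gene.gene_id] if mark == K27 else STANDARD
                mu, sigma = config.peak_width_params.get(
                    (mark, wclass), config.peak_width_params[(mark, STANDARD)]
                )
                width = max(50, int(round(rng.lognormal(mu, sigma))))
                # any start in [win.start - width + 1, win.end - 1] keeps >= 1 bp overlap
                lo = max(0, win.start - width + 1)
                start = int(rng.integers(lo, win.end))
                # confine the peak to this gene's territory so planted labels
                # stay identifiable; broad widths are censored at the boundary
                t_lo, t_hi = territory[gene.gene_id]
                intervals.append(GenomicInterval(
                    gene.chrom, max(start, t_lo), min(start + width, t_hi)))
            total_mapped = int(1e6 + rng.integers(0, 1e5))
            by_mark[mark] = PeakSet(
                sample_id=sample_id, mark=mark, intervals=intervals,
                total_mapped_reads=total_mapped, spike_reads=spike,
            )
            manifest_rows.append({
                "sample_id": sample_id, "condition": condition, "mark": mark,
                "n_peaks": len(intervals), "total_mapped_reads": total_mapped,
                "spike_reads": spike,
            })
        peak_sets[sample_id] = by_mark
    return peak_sets, pd.DataFrame(manifest_rows)


def simulate_fragments(
    truth: pd.Series,
    genes: list[GeneModel],
    config: SimulationConfig,
    sample_id: str,
    mark: str,
    intensity: pd.Series | None = None,
    rng_offset: int = 0,
) -> tuple[CoverageTrack, int]:
    """Poisson fragment coverage for one sample and mark.

    Fragment counts per promoter are Poisson with mean ``marked_rate``
    (optionally scaled per gene by ``intensity``) at truly marked promoters
    and ``background_rate`` elsewhere; each fragment overlaps its promoter.
    Returns the track and the total mapped-read count (= total fragments).
    """
    rng = config.rng(_PEAKS + 50 + rng_offset)
    windows = {w.gene_id: w.interval for w in promoter_windows(genes, config.half_width)}
    frags = []
    for gene in genes:
        win = windows[gene.gene_id]
        marked = mark in _marks_of(ChromatinState(truth[gene.gene_id]))
        rate = config.marked_rate if marked else config.background_rate
        if intensity is not None and marked:
            rate *= float(intensity[gene.gene_id])
        n = rng.poisson(rate)
        if n == 0:
            continue
        lo = max(0, win.start - config.fragment_length + 1)
        starts = rng.integers(lo, win.end, size=n)
        frags.extend(
            GenomicInterval(gene.chrom, int(s), int(s) + config.fragment_length)
            for s in starts
        )
    frags.sort(key=lambda iv: (iv.chrom, iv.start))
    track = CoverageTrack(sample_id=sample_id, mark=mark, records=frags, mode="fragments")
    return track, len(frags)


def simulate_methylomes(
    windows: list[PromoterWindow],
    truth: pd.Series,
    config: SimulationConfig,
    n_cpg: int | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Beta-Binomial CpG calls per promoter region.

    Per region the true level m ~ Beta(state params); each covered CpG gets
    ``meth_depth`` reads with Binomial(depth, m) methylated. Returns the call
    table (chrom, pos, meth_reads, total_reads) and the true levels.
    """
    rng = config.rng(_METH)
    n_cpg = config.n_cpg_per_region if n_cpg is None else n_cpg
    rows, levels = [], {}
    for w in windows:
        state = ChromatinState(truth[w.gene_id])
        alpha, beta = config.meth_params[state]
        m = float(rng.beta(alpha, beta))
        levels[w.gene_id] = m
        span = w.interval.end - w.interval.start
        k = min(n_cpg, span)
        positions = rng.choice(span, size=k, replace=False) + w.interval.start
        meth = rng.binomial(config.meth_depth, m, size=k)
        for pos, mr in zip(np.sort(positions), meth):
            rows.append({
                "chrom": w.interval.chrom, "pos": int(pos),
                "meth_reads": int(mr), "total_reads": config.meth_depth,
            })
    truth_levels = pd.Series(levels, dtype=float)
    truth_levels.index.name = "gene_id"
    return pd.DataFrame(rows), truth_levels


def simulate_expression(
    ratio_shift: pd.Series, config: SimulationConfig
) -> pd.DataFrame:
    """Two-condition TPM table with planted coupling to the mark-ratio shift.

    ``d_expr = beta * ratio_shift + N(0, sigma)``; TPMs are back-transformed
    from a log2 base abundance, so log2(tpm_b / tpm_a) equals d_expr exactly.
    """
    rng = config.rng(_EXPR)
    rs = ratio_shift.to_numpy(dtype=float)
    noise = rng.normal(0.0, config.expression_sigma, size=rs.size) \
        if config.expression_sigma > 0 else np.zeros(rs.size)
    d_expr = config.expression_beta * rs + noise
    base = rng.normal(config.expression_base_log2, config.expression_base_sd, size=rs.size)
    frame = pd.DataFrame(
        {
            "tpm_a": np.exp2(base),
            "tpm_b": np.exp2(base + d_expr),
            "true_d_expr": d_expr,
            "true_ratio_shift": rs,
        },
        index=ratio_shift.index,
    )
    frame.index.name = "gene_id"
    return frame


def planted_ratio_shift(truth_index: pd.Index, config: SimulationConfig) -> pd.Series:
    """Per-gene true H3K4me3-vs-H3K27me3 log2 shift, N(0, ratio_shift_sigma)."""
    rng = config.rng(_EXPR + 10)
    series = pd.Series(
        rng.normal(0.0, config.ratio_shift_sigma, size=len(truth_index)),
        index=truth_index,
    )
    series.index.name = "gene_id"
    return series


def build_truth_table(
    truth_a: pd.Series,
    truth_b: pd.Series | None = None,
    width_class: pd.Series | None = None,
    meth_levels: pd.Series | None = None,
    ratio_shift: pd.Series | None = None,
    d_expr: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-gene ground-truth table for recovery tests."""
    table = pd.DataFrame({"state_a": [ChromatinState(s).value for s in truth_a]},
                         index=truth_a.index)
    if truth_b is not None:
        table["state_b"] = [ChromatinState(s).value for s in truth_b]
    for name, col in [("k27_width_class", width_class),
                      ("meth_level", meth_levels),
                      ("ratio_shift", ratio_shift),
                      ("d_expr", d_expr)]:
        if col is not None:
            table[name] = col
    table.index.name = "gene_id"
    return table


def simulate_run(config: SimulationConfig, outdir) -> dict:
    """Write a complete synthetic run directory and return its artifacts.

    Emits: gene models BED, per-sample peak BEDs for two conditions plus a
    manifest TSV, the ground-truth table, CpG calls TSV, expression TSV and
    a YAML echo of the configuration.
    """
    import yaml
    from pathlib import Path

    from .genome_io import write_peak_bed

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genes, chrom_lengths = simulate_genome(config)
    truth_a = assign_states(genes, config)
    eligible = int((truth_a != ChromatinState.BIVALENT).sum())
    n_new = min(eligible // 4, 200)
    mixture = {
        ChromatinState.K4_ONLY: 0.7,
        ChromatinState.K27_ONLY: 0.1,
        ChromatinState.UNMARKED: 0.2,
    }
    truth_b = simulate_transition(truth_a, mixture, n_new, config)
    newly = truth_b.index[(truth_b == ChromatinState.BIVALENT)
                          & (truth_a != ChromatinState.BIVALENT)]
    wclass = width_classes(truth_b, newly_bivalent=newly)

    cohorts = {}
    manifests = []
    for condition, truth, offset in (("A", truth_a, 0), ("B", truth_b, 1000)):
        peak_sets, manifest = simulate_cohort(
            truth, genes, config, condition=condition,
            k27_width_class=wclass if condition == "B" else None,
            rng_offset=offset,
        )
        cohorts[condition] = peak_sets
        paths = []
        for sample_id, by_mark in peak_sets.items():
            for mark, ps in by_mark.items():
                path = outdir / f"peaks_{sample_id}_{mark}.bed"
                write_peak_bed(ps, path)
                paths.append(str(path.name))
        manifest = manifest.assign(path=paths)
        manifests.append(manifest)
    manifest = pd.concat(manifests, ignore_index=True)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)

    with open(outdir / "genes.bed", "w") as handle:
        for g in genes:
            for tss in g.tss_list:
                # 1-bp interval: TSS = start on '+' and end-1 on '-', both = tss
                handle.write(f"{g.chrom}\t{tss}\t{tss + 1}\t{g.gene_id}\t0\t{g.strand}\n")

    windows = promoter_windows(genes, config.half_width)
    cpg, meth_levels = simulate_methylomes(windows, truth_b, config)
    cpg.to_csv(outdir / "cpg_calls.tsv", sep="\t", index=False)

    rs = planted_ratio_shift(truth_a.index, config)
    expr = simulate_expression(rs, config)
    expr.to_csv(outdir / "expression.tsv", sep="\t")

    truth = build_truth_table(truth_a, truth_b, wclass, meth_levels, rs,
                              expr["true_d_expr"])
    truth.to_csv(outdir / "truth.tsv", sep="\t")

    cfg = {k: (v if not isinstance(v, dict) else
               {str(kk): list(vv) if isinstance(vv, tuple) else
                (vv.value if isinstance(vv, ChromatinState) else vv)
                for kk, vv in v.items()})
           for k, v in dataclasses.asdict(config).items()}
    with open(outdir / "config.yaml", "w") as handle:
        yaml.safe_dump(cfg, handle, default_flow_style=False)

    return {
        "genes": genes,
        "chrom_lengths": chrom_lengths,
        "truth": truth,
        "cohorts": cohorts,
        "manifest": manifest,
        "cpg_calls": cpg,
        "expression": expr,
        "outdir": outdir,
    }
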