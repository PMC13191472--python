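import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bivalency.dynamics import flow_matrix, origin_fractions
from bivalency.genome_io import promoter_windows
from bivalency.methylation import CpGCall, weighted_methylation_level
from bivalency.signal_quant import ratio_expression_correlation
from bivalency.simulate import (
    SimulationConfig,
    assign_states,
    planted_ratio_shift,
    simulate_cohort,
    simulate_expression,
    simulate_genome,
    simulate_methylomes,
    simulate_transition,
    width_classes,
)
from bivalency.states import (
    K4,
    K27,
    ChromatinState,
    call_states_cohort,
    consensus_states,
)

BIV, K4O, K27O, UNM = (ChromatinState.BIVALENT, ChromatinState.K4_ONLY,
                       ChromatinState.K27_ONLY, ChromatinState.UNMARKED)


class TestGenome:
    def test_deterministic_under_seed(self):
        cfg = SimulationConfig(n_genes=10, seed=7)
        a, _ = simulate_genome(cfg)
        b, _ = simulate_genome(SimulationConfig(n_genes=10, seed=7))
        assert [(g.gene_id, g.chrom, g.strand, g.tss_list) for g in a] == \
               [(g.gene_id, g.chrom, g.strand, g.tss_list) for g in b]

    def test_promoters_pairwise_disjoint(self):
        cfg = SimulationConfig(n_genes=200, n_chroms=3, seed=3)
        genes, _ = simulate_genome(cfg)
        windows = promoter_windows(genes, cfg.half_width)
        by_chrom: dict = {}
        for w in windows:
            by_chrom.setdefault(w.interval.chrom, []).append(w.interval)
        for spans in by_chrom.values():
            spans.sort(key=lambda iv: iv.start)
            for a, b in zip(spans, spans[1:]):
                assert a.end <= b.start

    def test_strand_counts_near_half(self):
        genes, _ = simulate_genome(SimulationConfig(n_genes=1000, seed=11))
        n_plus = sum(g.strand == "+" for g in genes)
        assert abs(n_plus - 500) <= 3 * math.sqrt(1000 / 4)

    def test_too_small_chromosomes_rejected(self):
        with pytest.raises(ValueError, match="packed"):
            simulate_genome(SimulationConfig(n_genes=100, n_chroms=1,
                                             chrom_length=10_000))


def noise_free(**kw):
    defaults = dict(n_genes=150, n_chroms=2, n_samples=3, seed=5,
                    dropout={K4: 0.0, K27: 0.0}, false_positive_rate=0.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestCohort:
    def test_noise_free_calls_equal_truth(self):
        cfg = noise_free()
        genes, _ = simulate_genome(cfg)
        truth = assign_states(genes, cfg)
        peak_sets, _ = simulate_cohort(truth, genes, cfg)
        table = call_states_cohort(genes, peak_sets, half_width=cfg.half_width)
        for sample in table.samples:
            assert (table.states[sample].loc[truth.index] == truth).all()

    def test_total_dropout_gives_all_unmarked(self):
        cfg = noise_free(dropout={K4: 1.0, K27: 1.0})
        genes, _ = simulate_genome(cfg)
        truth = assign_states(genes, cfg)
        peak_sets, _ = simulate_cohort(truth, genes, cfg)
        table = call_states_cohort(genes, peak_sets, half_width=cfg.half_width)
        assert (table.states == UNM).all().all()

    def test_consensus_recovery_matches_binomial_tail(self):
        """With per-mark dropout eps and n samples, P(consensus bivalent) is
        the Binomial(n, (1-eps)^2) tail above floor(n * threshold)."""
        eps, n_samples, n_genes = 0.2, 9, 600
        cfg = SimulationConfig(
            n_genes=n_genes, n_chroms=3, n_samples=n_samples, seed=19,
            state_priors={BIV: 1.0, K4O: 0.0, K27O: 0.0, UNM: 0.0},
            dropout={K4: eps, K27: eps}, false_positive_rate=0.0,
        )
        genes, _ = simulate_genome(cfg)
        truth = assign_states(genes, cfg)
        peak_sets, _ = simulate_cohort(truth, genes, cfg)
        table = call_states_cohort(genes, peak_sets, half_width=cfg.half_width)
        cons = consensus_states(table, threshold=0.5)
        rate = float((cons.consensus == BIV).mean())
        p_sample = (1 - eps) ** 2
        expected = 1 - stats.binom.cdf(math.floor(n_samples * 0.5), n_samples, p_sample)
        se = math.sqrt(expected * (1 - expected) / n_genes)
        assert abs(rate - expected) < 3 * se


class TestTransition:
    def test_degenerate_mixture_gives_pure_origin(self):
        cfg = noise_free(seed=23, state_priors={BIV: 0.1, K4O: 0.6, K27O: 0.1, UNM: 0.2})
        genes, _ = simulate_genome(cfg)
        truth_a = assign_states(genes, cfg)
        truth_b = simulate_transition(truth_a, {K4O: 1.0}, 20, cfg)
        flow = flow_matrix(truth_a, truth_b)
        fractions = origin_fractions(flow)
        assert fractions[K4O] == 1.0

    def test_zero_new_bivalent_changes_nothing(self):
        cfg = noise_free(seed=29)
        genes, _ = simulate_genome(cfg)
        truth_a = assign_states(genes, cfg)
        truth_b = simulate_transition(truth_a, {K4O: 0.5, UNM: 0.5}, 0, cfg)
        assert (truth_a == truth_b).all()

    def test_insufficient_pool_rejected(self):
        cfg = noise_free(seed=31, state_priors={BIV: 0.0, K4O: 0.0, K27O: 0.5, UNM: 0.5})
        genes, _ = simulate_genome(cfg)
        truth_a = assign_states(genes, cfg)
        with pytest.raises(ValueError, match="not enough"):
            simulate_transition(truth_a, {K4O: 1.0}, 10, cfg)

    def test_recovered_mixture_within_multinomial_error(self):
        pi = {K4O: 0.7, K27O: 0.1, UNM: 0.2}
        n_new = 500
        cfg = SimulationConfig(
            n_genes=2000, n_chroms=4, n_samples=1, seed=37,
            state_priors={BIV: 0.05, K4O: 0.55, K27O: 0.15, UNM: 0.25},
            dropout={K4: 0.0, K27: 0.0}, false_positive_rate=0.0,
        )
        genes, _ = simulate_genome(cfg)
        truth_a = assign_states(genes, cfg)
        truth_b = simulate_transition(truth_a, pi, n_new, cfg)
        fractions = origin_fractions(flow_matrix(truth_a, truth_b))
        for state, expected in pi.items():
            se = math.sqrt(expected * (1 - expected) / n_new)
            assert abs(fractions[state] - expected) < 3 * se

    def test_width_classes(self):
        truth = pd.Series({"a": BIV, "b": K27O, "c": K4O})
        classes = width_classes(truth, newly_bivalent=pd.Index(["a"]))
        assert classes["a"] == "narrow"
        assert classes["b"] == "broad"
        assert classes["c"] == "standard"


class TestMethylomes:
    def test_forced_full_methylation(self):
        cfg = noise_free(seed=41, meth_params={
            s: (1e6, 1e-3) for s in ChromatinState})
        genes, _ = simulate_genome(cfg)
        truth = assign_states(genes, cfg)
        windows = promoter_windows(genes, cfg.half_width)[:5]
        calls, levels = simulate_methylomes(windows, truth, cfg)
        assert (calls["meth_reads"] == calls["total_reads"]).mean() > 0.99

    def test_level_recovery_within_binomial_se(self):
        cfg = noise_free(seed=43, meth_depth=20, n_cpg_per_region=50)
        genes, _ = simulate_genome(cfg)
        truth = assign_states(genes, cfg)
        windows = promoter_windows(genes, cfg.half_width)[:30]
        calls, levels = simulate_methylomes(windows, truth, cfg)
        for w in windows:
            inside = calls[(calls.chrom == w.interval.chrom)
                           & (calls.pos >= w.interval.start)
                           & (calls.pos < w.interval.end)]
            est = weighted_methylation_level([
                CpGCall(r.chrom, r.pos, r.meth_reads, r.total_reads)
                for r in inside.itertuples(index=False)])
            m = levels[w.gene_id]
            n_reads = inside["total_reads"].sum()  # depth * n_cpg >= 300
            se = math.sqrt(max(m * (1 - m), 1e-6) / n_reads)
            assert abs(est - m) < max(3 * se, 0.01)

    def test_cpg_count_below_threshold_plumbs_through(self):
        cfg = noise_free(seed=47)
        genes, _ = simulate_genome(cfg)
        truth = assign_states(genes, cfg)
        windows = promoter_windows(genes, cfg.half_width)[:3]
        calls, _ = simulate_methylomes(windows, truth, cfg, n_cpg=29)
        counts = calls.groupby(calls.pos // (10**9)).size()  # all same chrom bucket
        assert len(calls) == 29 * len(windows)


class TestExpression:
    def test_exact_correlation_without_noise(self):
        cfg = noise_free(seed=53, expression_sigma=0.0, expression_beta=1.0)
        rs = planted_ratio_shift(pd.Index([f"g{i}" for i in range(50)]), cfg)
        expr = simulate_expression(rs, cfg)
        table = pd.DataFrame({"ratio_shift": rs, "d_expr": expr["true_d_expr"]})
        r, _, _ = ratio_expression_correlation(table)
        assert r == pytest.approx(1.0)

    def test_tpm_fold_change_encodes_d_expr(self):
        cfg = noise_free(seed=59)
        rs = planted_ratio_shift(pd.Index([f"g{i}" for i in range(20)]), cfg)
        expr = simulate_expression(rs, cfg)
        assert np.allclose(np.log2(expr["tpm_b"] / expr["tpm_a"]),
                           expr["true_d_expr"])

    def test_planted_rho_half_recovered(self):
        """beta=1, sigma=sqrt(3), ratio_shift ~ N(0,1) give true rho = 0.5."""
        cfg = SimulationConfig(seed=61)
        rs = planted_ratio_shift(pd.Index([f"g{i}" for i in range(2000)]), cfg)
        expr = simulate_expression(rs, cfg)
        table = pd.DataFrame({"ratio_shift": rs, "d_expr": expr["true_d_expr"]})
        r, p, n = ratio_expression_correlation(table)
        assert 0.4 < r < 0.6
        assert p < 1e-6 and n == 2000
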