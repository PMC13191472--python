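import numpy as np
import pandas as pd
import pytest

from bivalency.genome_io import GeneModel, GenomicInterval
from bivalency.states import (
    K4,
    K27,
    ChromatinState,
    StateTable,
    call_states_cohort,
    classify_gene_state,
    consensus_states,
    occupancy_matrix,
    qc_filter_samples,
    state_from_presence,
)
from conftest import make_peakset

BIV, K4O, K27O, UNM = (ChromatinState.BIVALENT, ChromatinState.K4_ONLY,
                       ChromatinState.K27_ONLY, ChromatinState.UNMARKED)
WIN = GenomicInterval("chr1", 8000, 12000)


class TestQCFilter:
    @pytest.mark.parametrize(
        "counts, retained, excluded",
        [
            ({"A": 90, "B": 100, "C": 110, "D": 200}, {"A", "B", "C"}, {"D"}),
            ({"A": 500}, {"A"}, set()),
            # median 1150, bounds [805, 1610]
            ({"A": 800, "B": 1000, "C": 1300, "D": 1400}, {"B", "C", "D"}, {"A"}),
        ],
    )
    def test_median_band_retention(self, counts, retained, excluded):
        report = qc_filter_samples({K4: counts})
        assert set(report.retained_samples) == retained
        assert {s for s, ok in report.retained.items() if not ok} == excluded

    def test_bounds_are_median_band(self):
        report = qc_filter_samples({K4: {"A": 90, "B": 100, "C": 110, "D": 200}})
        row = report.per_mark.loc[K4]
        assert row["median"] == 105 and row["lower"] == 73.5 and row["upper"] == 136.5

    def test_sample_must_pass_every_mark_it_supplies(self):
        report = qc_filter_samples({
            K4: {"A": 100, "B": 100, "C": 100},
            K27: {"A": 100, "B": 100, "C": 1000},  # C out of band for K27
        })
        assert set(report.retained_samples) == {"A", "B"}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            qc_filter_samples({})


class TestClassifyGeneState:
    def test_no_peaks_is_unmarked(self):
        assert classify_gene_state([WIN], [], []) is UNM

    def test_single_mark(self):
        k4 = [GenomicInterval("chr1", 9000, 11000)]
        assert classify_gene_state([WIN], k4, []) is K4O
        assert classify_gene_state([WIN], [], k4) is K27O

    def test_bivalent_under_both_modes(self):
        k4 = [GenomicInterval("chr1", 9000, 11000)]
        k27 = [GenomicInterval("chr1", 10500, 13000)]
        assert classify_gene_state([WIN], k4, k27) is BIV
        assert classify_gene_state([WIN], k4, k27, require_mutual_overlap=True) is BIV

    def test_strict_mode_demotes_non_touching_peaks(self):
        # both marks in the window but the peaks never touch each other
        k4 = [GenomicInterval("chr1", 8000, 9000)]
        k27 = [GenomicInterval("chr1", 11000, 11500)]
        assert classify_gene_state([WIN], k4, k27) is BIV
        # K4 has the larger promoter overlap (1000 vs 500 bp)
        assert classify_gene_state([WIN], k4, k27, require_mutual_overlap=True) is K4O

    def test_off_chromosome_peaks_ignored(self):
        k4 = [GenomicInterval("chr2", 9000, 11000)]
        assert classify_gene_state([WIN], k4, []) is UNM

    def test_oracle_equivalence_on_random_instances(self, rng):
        """classify_gene_state matches a naive all-pairs overlap check."""
        def naive(windows, peaks):
            return any(
                p.chrom == w.chrom and p.start < w.end and w.start < p.end
                for w in windows for p in peaks
            )

        for _ in range(1000):
            n_win = rng.integers(1, 4)
            windows = []
            for _ in range(n_win):
                s = int(rng.integers(0, 5000))
                windows.append(GenomicInterval(
                    f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 3000))))
            def rand_peaks():
                out = []
                for _ in range(rng.integers(0, 5)):
                    s = int(rng.integers(0, 8000))
                    out.append(GenomicInterval(
                        f"chr{rng.integers(1, 3)}", s, s + int(rng.integers(1, 2000))))
                return out
            k4, k27 = rand_peaks(), rand_peaks()
            expected = state_from_presence(naive(windows, k4), naive(windows, k27))
            assert classify_gene_state(windows, k4, k27) is expected


class TestCohortCalls:
    def test_constructed_two_by_two_table(self):
        genes = [GeneModel("g1", "chr1", "+", [10000]),
                 GeneModel("g2", "chr1", "+", [50000])]
        cohort = {
            "s1": {K4: make_peakset("s1", K4, [("chr1", 9000, 9500)]),
                   K27: make_peakset("s1", K27, [("chr1", 11000, 11500)])},
            "s2": {K4: make_peakset("s2", K4, [("chr1", 9000, 9500)]),
                   K27: make_peakset("s2", K27, [("chr1", 49000, 49500)])},
        }
        table = call_states_cohort(genes, cohort)
        assert table.states.loc["g1", "s1"] is BIV
        assert table.states.loc["g2", "s1"] is UNM
        assert table.states.loc["g1", "s2"] is K4O
        assert table.states.loc["g2", "s2"] is K27O

    def test_all_empty_peaks_all_unmarked(self, toy_genes):
        cohort = {"s1": {K4: make_peakset("s1", K4, []),
                         K27: make_peakset("s1", K27, [])}}
        table = call_states_cohort(toy_genes, cohort)
        assert (table.states == UNM).all().all()

    def test_duplicate_peaks_idempotent(self, toy_genes):
        peaks = [("chr1", 9000, 11000)]
        one = {"s1": {K4: make_peakset("s1", K4, peaks),
                      K27: make_peakset("s1", K27, [])}}
        dup = {"s1": {K4: make_peakset("s1", K4, peaks * 3),
                      K27: make_peakset("s1", K27, [])}}
        assert call_states_cohort(toy_genes, one).states.equals(
            call_states_cohort(toy_genes, dup).states)

    def test_sample_missing_a_mark_excluded(self, toy_genes):
        cohort = {
            "ok": {K4: make_peakset("ok", K4, []), K27: make_peakset("ok", K27, [])},
            "half": {K4: make_peakset("half", K4, [])},
        }
        table = call_states_cohort(toy_genes, cohort)
        assert list(table.samples) == ["ok"]

    def test_states_partition_gene_universe(self, rng, toy_genes):
        cohort = {"s1": {
            K4: make_peakset("s1", K4, [("chr1", 9000, 9500), ("chr2", 9000, 9500)]),
            K27: make_peakset("s1", K27, [("chr1", 48500, 49000)]),
        }}
        table = call_states_cohort(toy_genes, cohort)
        sizes = table.states["s1"].value_counts()
        assert sizes.sum() == len(toy_genes)

    def test_bivalent_set_monotone_in_half_width(self, rng):
        genes = [GeneModel(f"g{i}", "chr1", "+", [int(t)])
                 for i, t in enumerate(rng.integers(10000, 500000, size=40))]
        def peaks(n):
            out = []
            for _ in range(n):
                s = int(rng.integers(0, 500000))
                out.append(("chr1", s, s + int(rng.integers(200, 4000))))
            return out
        cohort = {"s1": {K4: make_peakset("s1", K4, peaks(60)),
                         K27: make_peakset("s1", K27, peaks(60))}}
        previous = set()
        for hw in (500, 1000, 2000, 5000):
            table = call_states_cohort(genes, cohort, half_width=hw)
            bivalent = set(table.states.index[table.states["s1"] == BIV])
            assert previous <= bivalent
            previous = bivalent


class TestConsensus:
    def test_majority_bivalent(self):
        st = StateTable(pd.DataFrame(
            [[BIV, BIV, BIV, K4O, UNM]], index=["g"], columns=list("abcde")))
        cons = consensus_states(st)
        assert cons.consensus["g"] is BIV
        assert cons.table.loc["g", "bivalent_support"] == 0.6

    def test_exact_half_is_not_bivalent(self):
        st = StateTable(pd.DataFrame(
            [[BIV, BIV, UNM, UNM]], index=["g"], columns=list("abcd")))
        assert consensus_states(st).consensus["g"] is not BIV

    def test_k4_support_decides_when_not_bivalent(self):
        st = StateTable(pd.DataFrame(
            [[K4O, K4O, K4O, BIV, UNM]], index=["g"], columns=list("abcde")))
        cons = consensus_states(st)
        assert cons.consensus["g"] is K4O
        assert cons.table.loc["g", "bivalent_support"] == 0.2
        assert cons.table.loc["g", "k4_support"] == 0.8

    def test_unmarked_when_no_support_passes(self):
        st = StateTable(pd.DataFrame(
            [[K4O, K27O, UNM, UNM]], index=["g"], columns=list("abcd")))
        assert consensus_states(st).consensus["g"] is UNM

    def test_k4_precedence_when_both_single_marks_pass(self):
        # every sample carries both marks but bivalent in only half
        st = StateTable(pd.DataFrame(
            [[BIV, BIV, K4O, K4O, K27O, K27O]], index=["g"], columns=list("abcdef")))
        cons = consensus_states(st)
        # k4_support = k27_support = 4/6 > 0.5, bivalent 2/6: K4 precedence
        assert cons.consensus["g"] is K4O


class TestOccupancyMatrix:
    def test_presence_rows(self):
        st = StateTable(pd.DataFrame(
            [[K4O, UNM]], index=["g"], columns=["s1", "s2"]))
        occ = occupancy_matrix(st)
        assert occ[K4].loc["g"].tolist() == [1, 0]
        assert occ[K27].loc["g"].tolist() == [0, 0]

    def test_all_bivalent_gives_all_ones(self):
        st = StateTable(pd.DataFrame(
            [[BIV] * 3] * 2, index=["g1", "g2"], columns=list("abc")))
        occ = occupancy_matrix(st)
        assert (occ[K4] == 1).all().all() and (occ[K27] == 1).all().all()

    def test_column_sums_recount_mark_positive_genes(self, rng):
        states = np.array([BIV, K4O, K27O, UNM], dtype=object)
        frame = pd.DataFrame(
            states[rng.integers(0, 4, size=(50, 4))],
            index=[f"g{i}" for i in range(50)], columns=list("abcd"))
        occ = occupancy_matrix(StateTable(frame))
        for sample in "abcd":
            expected = sum(s in (BIV, K4O) for s in frame[sample])
            assert occ[K4][sample].sum() == expected
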