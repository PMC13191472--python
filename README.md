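# bivalency

Analysis toolkit for **bivalent promoters** — gene promoters that carry both
the activating H3K4me3 and the Polycomb-repressive H3K27me3 histone mark at
once. Bivalency is a hallmark of developmental genes in embryonic stem
cells, and cancer cells can acquire it *de novo* during state transitions
(e.g. spheroid/stem-like conversion). This package implements the
promoter-centric analyses such a study needs, for computational biologists
working from peak calls, fragment coverage, CpG methylation calls and
expression tables:

- **Four-state promoter classification.** For each gene and sample, the
  promoter (TSS ± 2 kb by default) is *bivalent* if ≥ 1 H3K4me3 peak and
  ≥ 1 H3K27me3 peak overlap a promoter window, *H3K4me3-only* /
  *H3K27me3-only* if one mark is present, *unmarked* otherwise. A stricter
  mode additionally requires the two peaks to physically intersect.
- **Cohort consensus with QC.** Samples are retained when their peak counts
  lie within median ± 30 % per mark; a gene's consensus is bivalent when
  both marks co-occur in strictly more than 50 % of retained samples.
- **State dynamics.** 4 × 4 transition (flow) matrices between conditions,
  origin attribution of newly bivalent genes, conserved vs cancer-specific
  bivalency across ESC/normal/tumor cohorts, and Venn partitions of
  bivalent gene sets.
- **Spike-calibrated signal.** Promoter signal as RPM
  (`raw · 10⁶ / total_mapped · spike_factor`, with
  `spike_factor_i = mean(spike reads)/spike reads_i`), merged H3K27me3 peak
  widths, per-gene log₂ fold changes, and the Pearson correlation between
  the mark-ratio shift `Δlog₂K4 − Δlog₂K27` and expression change.
- **Methylation.** Weighted methylation level `Σ meth / Σ total` over a
  region's covered CpGs (≥ 30 CpGs required; level > 0.5 = hypermethylated),
  crosstabbed against chromatin state; CpG density and observed/expected
  CpG ratio from sequence.
- **Statistics.** Two-tailed Wilcoxon rank-sum comparisons with full
  enumeration for small groups and an Edgeworth-refined normal
  approximation otherwise.
- **Synthetic cohorts.** A seeded generator plants four-state truth,
  mark dropout/false positives, state-dependent H3K27me3 widths, spike-in
  counts, Beta-Binomial CpG methylation, and expression coupled to the
  planted mark-ratio shift — so every stage is testable end to end.

## Worked example

The numbered scripts under `analysis/` form the narrative pipeline over a
simulated two-condition cohort (1000 genes, 5 samples per condition, 10 %
per-mark dropout, 2 % false positives):

```sh
python analysis/01_simulate.py      # write results/simulated_run
python analysis/02_call_states.py   # QC -> states -> consensus -> report
python analysis/03_dynamics.py      # flow matrix, origins, Venn partitions
python analysis/04_signal.py        # spike factors, RPM, K27 widths
python analysis/05_methylation.py   # weighted levels by state
python analysis/06_expression.py    # expression vs state, correlation, DE filter
```

`02_call_states.py` reports per-condition consensus counts and their
agreement with the planted truth:

```
condition A: consensus counts {'K4_ONLY': 464, 'UNMARKED': 242, 'K27_ONLY': 152,
'BIVALENT': 142}; truth agreement 98.5%
condition B: consensus counts {'BIVALENT': 343, 'K4_ONLY': 333, 'UNMARKED': 194,
'K27_ONLY': 130}; truth agreement 98.4%
```

i.e. under realistic noise the median-band QC plus the > 50 % consensus rule
recover ~98 % of planted states. `03_dynamics.py` attributes the origin of
newly bivalent genes (here the generator planted a 70/10/20 mixture):

```
origin of newly bivalent genes (called vs planted):
  K4_ONLY     64.59% (planted  63.50%)
  K27_ONLY    11.96% (planted  11.50%)
  UNMARKED    23.44% (planted  25.00%)
```

and `04_signal.py` shows the planted H3K27me3 domain-width asymmetry that
distinguishes newly bivalent promoters (narrow domains) from
H3K27me3-only loci (broad domains):

```
median merged H3K27me3 width (bp) by planted width class:
broad       7584.5
narrow       776.5
standard    2911.5
```

A `bivalency` console script exposes the same stages
(`simulate`, `call-states`, `dynamics`, `quantify`, `methylation`,
`expression`, `run`, `report`); see `bivalency --help`.

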