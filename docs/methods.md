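# Methods

## Promoter model and state calling

Coordinates are BED-convention throughout: 0-based, half-open `[start, end)`.
GTF input (1-based, closed) is converted on read. The TSS of a '+' gene is
its interval start; for a '−' gene it is `end − 1`, the last covered base.
Promoter windows are `[TSS − h, TSS + h)` with `h = 2000` bp by default
(5000 bp for profile-style analyses), clamped only at position 0 — no
chromosome-length table is required for BED-only input, so right-end
clamping is the caller's responsibility. Genes with several transcripts keep
all TSS windows, and a mark counts as present at the gene if it is present
at *any* of its windows; the analysis is gene-level and no canonical
transcript is chosen.

A mark is **present** when at least one of its peaks overlaps a promoter
window by ≥ 1 bp (interval lookups via an interval tree; a brute-force
all-pairs check is the test oracle). The four states — bivalent,
H3K4me3-only, H3K27me3-only, unmarked — then partition the gene universe in
every sample. Co-occurrence of both marks "at the same locus" is read as
co-presence within the same promoter window by default because only
co-presence yields a total four-way partition; a strict mode additionally
requires an H3K4me3/H3K27me3 peak pair whose mutual intersection is
non-empty and overlaps a window, demoting failures to the state of the mark
with the larger unioned promoter-overlap (ties → H3K4me3-only, logged).

**QC.** Per mark, the cohort median peak count is computed once (no
iteration) and samples outside `[median·0.7, median·1.3]` (bounds inclusive)
for any mark they supply are dropped.

**Consensus.** A gene is consensus-bivalent iff it is called bivalent in
strictly more than `threshold` (default 0.5) of retained samples — the
joint-call reading of the > 50 % rule; the per-mark alternative is exposed
through the per-mark support fractions that the table also reports. When
the bivalent support fails but both single-mark supports exceed the
threshold, H3K4me3-only takes precedence with a logged flag (the case is
rare and any fixed precedence is arbitrary).

## Dynamics

Flow matrices cross-tabulate per-gene states between two conditions over
the shared gene universe (genes missing from one side are dropped and
logged). Origin fractions for newly bivalent genes divide each cell of the
bivalent column (minus the diagonal) by the number of newly bivalent genes;
all four origins are reported and the denominator-empty case is returned as
absent rather than zero. Cancer-specific bivalency requires H3K4me3-only in
*both* ESC and normal tissue plus bivalency in tumor (a relaxed
"non-bivalent in ESC/normal" variant is a flag); conserved bivalency is
bivalent in ESC and tumor. Venn partitions support 2–3 sets exactly.

## Signal quantification

Spike-in factors are `mean(spike reads)/spike readsᵢ`, i.e. normalized to
cohort mean 1; any other positive constant differs only by a cohort-wide
multiplier and cancels in cross-sample comparisons. Promoter signal in
fragments mode counts fragments overlapping the window by ≥ 1 bp (midpoint
counting is a config option); bedGraph mode uses the interval-weighted mean
depth over the window, documented as an approximation to a fragment count.
RPM is `raw · 10⁶ / total_mapped · factor`. Merged H3K27me3 widths are the
union length of all peaks intersecting the window measured on full peak
extents — domain breadth is the quantity of interest and clipping would
censor it; a clipped mode exists. Log₂ fold changes use a pseudocount of
1 RPM (configurable); the mark-ratio shift is `Δlog₂K4 − Δlog₂K27` and its
association with expression change is summarized by Pearson r with the
two-sided t-test p-value (n − 2 df).

**Wilcoxon rank-sum.** Groups of ≤ 8 each are compared by full enumeration
of all `C(n₁+n₂, n₁)` rank splits using midranks, with the symmetric
two-sided definition `p = P(|W − E[W]| ≥ |w − E[W]|)` (identical to the
classical exact two-sided p for tie-free data). Larger groups use a normal
approximation whose null mean, variance and fourth moment are computed
*exactly* from the observed midrank multiset via inclusion-indicator
expansions (the variance reduces to the classical tie-corrected formula),
with a 0.5 continuity correction and an Edgeworth fourth-moment refinement;
the skewness terms cancel in the two-sided sum. At the n = 8 boundary this
approximation agrees with full enumeration to ~5·10⁻⁴, versus ~10⁻² for
the plain corrected normal.

## Methylation

The region summary is the weighted methylation level `Σ meth / Σ total`
over *covered* CpG calls inside `[start, end)` — coverage-weighted, never a
mean of per-CpG ratios, and counted over covered CpGs because covered sites
are the only information bisulfite data provide. Regions with < 30 covered
CpGs are unclassified (the level is still reported when ≥ 1 call exists);
classification is hypermethylated iff level > 0.5, both boundaries read
literally (≥ 30 inclusive, > 0.5 strict). Strand-split caller output (one
record per strand with an explicit strand column) is merged to one record
per CpG dyad with summed counts. CpG density scans the window for the CG
dinucleotide case-insensitively (N never matches); the observed/expected
ratio is `N_CG · L / (N_C · N_G)`, reported absent when `N_C · N_G = 0`.

## Expression

Expression vectors are grouped by consensus state after `log₂(x+1)` and
compared pairwise with the Wilcoxon machinery above. Differential-expression
fitting is upstream; the filter retains genes with FDR strictly < 0.05 and
|log₂FC| strictly > 1 and is monotone in both thresholds. TPM and FPKM are
recorded but never interconverted.

## Synthetic-data generator

The generator emulates the *structure* of a two-condition CUT&Tag/RRBS/
RNA-seq study at desk scale. Genes are laid on a slot grid (slot = promoter
width + 8 kb gap) with jittered TSS and random strand, so promoters are
pairwise disjoint by construction. Per sample and mark, each truly marked
promoter emits a peak with probability `1 − ε` (dropout, default ε = 0.1
per mark); peak widths are log-normal per mark and width class — H3K4me3
`ln N(ln 1500, 0.3)`, H3K27me3 standard `ln N(ln 3000, 0.4)`, broad
(H3K27me3-only loci) `ln N(ln 8000, 0.4)`, narrow (newly bivalent
promoters) `ln N(ln 800, 0.3)` — positions are jittered while keeping ≥ 1 bp
promoter overlap, and every peak is clipped to the open span between its
neighbours' promoters so a planted peak can never create a spurious call at
another gene (broad widths are thereby censored at the territory boundary;
the 8 kb gap keeps censoring rare). Promoters whose truth lacks the mark
receive a spurious peak at rate 2 % by default. Fragment coverage is
Poisson (mean 200 fragments per marked promoter, 5 background); spike reads
are uniform within ±20 % of 50 000 per sample. Methylation draws a true
level per region from a state-specific Beta — Beta(2,18) for bivalent and
H3K4me3-only promoters (CpG-island-like, hypomethylated), Beta(5,5) for
H3K27me3-only, Beta(12,4) for unmarked — then Binomial(depth 20, m) counts
at 50 covered CpGs. Expression plants
`Δexpr = β · ratio_shift + N(0, σ)` with `ratio_shift ~ N(0,1)`, `β = 1`,
`σ = √3`, giving a true Pearson ρ of exactly 0.5; TPMs are back-transformed
from a log₂ base abundance so `log₂(TPM_B/TPM_A)` equals the planted Δexpr.

Each artifact (genome, states, peaks, methylomes, expression, spike counts)
draws from its own stream seeded `seed + fixed offset`, so outputs are
byte-identical under a fixed (config, seed) and adding one generator never
perturbs the others.

**What passing tests do and do not show.** The generator reproduces the
data *shapes* — peak cohorts with planted labels, dropout/false-positive
noise, width asymmetry, Beta-Binomial methylation, coupled expression — but
not real-genome features: no sequence-driven peak placement, no
peak-caller artifacts, no copy-number or mappability structure, no batch
effects beyond the count filter, no correlated dropout between marks.
Recovery rates measured here therefore validate the *logic and calibration*
of the calling rules, not their field performance on any particular
sequencing cohort.

## Problem sizes and checks

The test suite and acceptance script run at desk scale, chosen so each
stochastic check has adequate power: 1000-instance oracle-equivalence
sweeps for interval logic; 600 planted bivalent genes × 9 samples for the
dropout-consensus check against its Binomial(9, 0.64) tail (3-SE band);
5000 genes with 2000 planted transitions for origin-mixture recovery;
2000 genes for the planted-ρ = 0.5 correlation; 1000-gene cohorts for the
narrative analyses. The analysis defaults (5 samples per condition, ε = 0.1,
2 % false positives) are fixed study conditions, not tuning knobs.

## Known limitations

- Promoter windows clamp only at 0; callers supplying FASTA-less input are
  responsible for right-end validity.
- bedGraph-mode promoter signal is a mean-depth approximation, not a
  fragment count.
- The assembly is never checked or lifted over; all inputs must share one.
- The strict mutual-overlap mode's tie-break (H3K4me3-only) is arbitrary
  and logged.
- Exact Wilcoxon enumeration is combinatorial; the ≤ 8-per-group boundary
  keeps it below `C(16,8) = 12870` splits.
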