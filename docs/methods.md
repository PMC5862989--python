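# Methods

## Scope and model

The package evaluates read-depth CNV screening from whole-genome-amplified
single-cell (or few-cell) low-coverage sequencing. Its statistical model
of a WGA sample is:

* the genome is partitioned into windows of equal *mappable* content;
* the expected unique deduplicated read count of window `w` is
  proportional to `(copy_number_w / 2) · f(GC_w)`, where `f` is a smooth,
  kit-specific GC-efficiency curve;
* realised counts are negative-binomial around that expectation,
  `Var = μ + d·μ²`, with the overdispersion `d` depending on the kit and
  on the number of input cells (single cells amplify less evenly than 3–8
  pooled cells, so `d_single ≥ d_multi`).

Everything downstream — NDR normalisation, ΔR_GC, the weighted GC
correction, CV/Pearson QC, segmentation, benchmark scoring — is defined
against this model; the synthetic generator draws from it exactly.

## Window construction

Windows are built by tiling the reference into 50 bp simulated single-end
reads (step configurable, 1 bp by definition; larger steps are a
desk-scale speed knob), re-mapping each read exhaustively against both
strands under a Hamming budget of 2 mismatches (indel-free mapping is the
standard mappability idealisation; a read with two equally-good
placements is unmappable), and grouping uniquely-mapping read starts into
windows of `reads_per_window = 100` with `overlap_reads = 20` shared
between neighbours — preserving the 5:1 window/overlap ratio of a
genome-scale 100 K/20 K window set at desk scale. The exhaustive search
is O(genome² · read length) by design and meant for ≤ tens-of-kb test
genomes; for *generated* (repeat-free, random) references the package
uses an all-positions-mappable track (`full_mappability`), since random
50-mers collide with negligible probability. Per-window GC is the G+C
fraction of the window's reference span, ignoring N; all-N windows are
flagged and excluded downstream.

A read is assigned to a window by its 0-based start position; a start in
the 20-read overlap zone increments both windows (consistent with windows
sharing simulated reads; single-assignment is available by flag).

## Read filtering

Ingestion drops unmapped/secondary/supplementary records. The
variable-length (semiconductor-platform) dialect keeps reads strictly
longer than 30 bp; the fixed-49 bp dialect passes through. Duplicates are
removed on (chrom, position, strand) — strand is included because
same-position opposite-strand reads are distinct molecules; a
position-only key is available. The first-seen read wins, making the
result deterministic for a fixed stream order. Downsampling to a fixed
budget (default 2 × 10⁶ reads) uses single-pass reservoir sampling,
deterministic per seed. Per-base mismatch/deletion/insertion rates are
event bases over aligned (M) bases from CIGARs, with mismatch counts
taken from an explicit edit tally (simulator bookkeeping or an NM-style
tag) — never guessed; ErrorRate is by definition their exact sum.

## ΔR_GC and the weighted correction

The loess behind ΔR_GC is an in-package degree-1 tricube local
regression: the neighbourhood of each point is its `k = int(span·n)`
nearest GC values, weights are tricube in distance scaled by the
neighbourhood radius, with no robustness iterations. Span defaults to
0.3 — smooth at 10⁵ windows yet flexible at 10³ (the statistic is
insensitive to span in the regimes tested; tests pin the fit against a
naive per-point oracle and against statsmodels lowess at `it=0`).
ΔR_GC is computed on raw counts over usable autosomal windows; because
NDR is a scalar multiple of counts, the value is identical either way
(asserted in tests). Degenerate inputs: all-equal counts (TV = 0) return
a flagged undefined result; an LV > TV fit is clamped to 0 and flagged.

The correction uses 100 equal-width GC bins over [0,1]: weight =
autosomal mean / bin mean count, empty bins inheriting the nearest
populated bin's weight, and the corrected autosomal mean re-normalised to
its pre-correction value (preserved to 1e-9 relative; tested).

Two extensions matter at desk scale, where a single CNV can dominate a
sparse GC bin and a naive self-fit would flatten it:

* **copy-ratio-aware fitting** — counts can be divided by a per-window
  expected copy ratio before the bin means, so windows inside known or
  provisionally-called CNVs do not drag their bin's weight;
* **weight smoothing** — an optional running median across bin weights
  (the caller uses width 5), justified because amplification GC bias is
  smooth in GC while a CNV-dominated outlier bin is not.

Both default off in `fit_gc_correction` itself, keeping the plain binned
estimator; the CNV caller turns them on (below).

## QC metrics

Pearson reproducibility matrices are computed over shared usable
autosomal windows; pairs with zero variance are flagged NaN. CV uses the
population standard deviation (at W ~ 10⁵ the sample/population
distinction is negligible, but it must be fixed for determinism). The
uniformity reference is `Poisson(λ=30)/λ` with 124,011 draws, CV
`1/√30 ≈ 0.1826`. Cross-platform consistency is the R² of an OLS fit of
one NDR profile on another (equal to squared Pearson r; asserted).

## CNV calling

Fixed windows are merged greedily per chromosome until the
diploid-expected count (M per fixed window) reaches
`min_expected_reads = 30`, so merged-window NDR noise is at worst on the
Poisson(30) scale of the uniformity reference; flagged fixed windows
(short tails, undefined GC) are excluded before merging. Binary
segmentation then recursively splits each chromosome at the breakpoint
maximising the pooled-sd t-like statistic, accepting a split when its
two-sided normal p-value, Bonferroni-adjusted for the number of candidate
positions scanned, is below `alpha = 0.01` and both sides keep
`min_seg = 3` merged windows. The adjustment matters: the naive per-split
rule fires on ~15% of flat 50-point signals because the candidate
statistics are many and correlated; adjusted, the measured false-split
rate is ~1.5%. Ties break leftmost; the recursion is fully deterministic.

Segment classification uses gain/loss thresholds 1.25/0.75 — midpoints
between integer copy states 2–3 and 1–2 on the NDR scale — and copy
number `round(2·mean NDR)`.

`call_cnvs_corrected` iterates correction and segmentation (≤4 passes,
stopping when the call set stabilises): plain correction → provisional
calls → re-fit with provisional copy ratios → re-call. Post-processing
merges adjacent same-call segments (high-depth segmentation splits one
event over tiny-but-significant mean differences) and bridges neutral
interruptions of ≤8 merged windows flanked by identical calls — roughly
twice the GC-landscape correlation scale (3 kb ≈ 4 windows at benchmark
resolution), which is the footprint of a correction hole left by a GC
range private to the CNV. Calls fully inside excluded regions (sex
chromosomes by default policy) are dropped; partial overlaps are flagged
or dropped per policy. A sample whose raw NDR CV exceeds a configurable
ceiling (default 1.0) is excluded from CNV evaluation and reported,
mirroring the erratic-sample exclusion rule of low-coverage screens.

## Benchmark scoring

One truth CNV segment (a whole-chromosome aneuploidy counts as one) is
one positive signal; one truth-neutral chromosome is one negative
signal. A positive is a TP when a same-direction call reciprocally
overlaps it by ≥0.5; unmatched truths are FN, unmatched calls FP, and
neutral chromosomes untouched by calls TN. TPR = tp/(tp+fn),
FNR = fn/(tp+fn), TNR = tn/(tn+fp), FPR = fp/(tn+fp), and
Sensitivity = TPR/(TPR+FNR), Specificity = TNR/(TNR+FPR) — which, given
the rate identities, equal TPR and TNR (asserted as an algebraic test).
The signal unit and the FPR denominator are this package's explicit
definitions, chosen so every rate lies in [0,1]. Combination aggregation
pools signal counts.

## The synthetic study conditions

The benchmark emulates an 11-cell-line comparison of two WGA kits at two
cell numbers on a desk-scale genome:

* **genome** — six 400 kb autosomes plus a 300 kb chrX; per-base GC
  probability `clip(0.42 + 0.12·z, 0.02, 0.98)` with `z` unit-variance
  Gaussian-smoothed noise of correlation length 3 kb (GC mean near the
  human genome-wide 0.42; the amplitude and correlation length give
  windowed GC spanning roughly 0.15–0.70, wide enough to expose
  GC-efficiency differences);
* **truth panel** — ten focal CNVs (each 1/5 of its chromosome, copy
  numbers alternating 3 and 1) across nine lines (the first line carries
  two), one whole-chromosome trisomy, one copy-neutral negative line.
  The negative line stands for a carrier of a rearrangement balanced at
  read-depth resolution — invisible to depth analysis, hence all-diploid;
* **kits** — GC-efficiency curves `1 + 1.6(g−0.42) + 2(g−0.42)²`
  (GC-rich-preferring, "R") and `1 + 0.9(g−0.42) − 1.0(g−0.42)²` (mild,
  "S"); NB dispersions 0.132 (single cell) and 0.056 (3–8 cells) for
  both kits. These values were calibrated analytically so the simulated
  ΔR_GC (~0.09–0.36 across combinations) and CV (~0.28–0.43) land in the
  ranges reported for real WGA kit comparisons, and they are fixed study
  conditions, not tuning knobs;
* **depth** — 2 × 10⁶ reads per sample over ~3,400 windows.

What the generator does *not* emulate: mappability structure and repeats
(the synthetic genome is uniquely mappable everywhere), chimeric reads
and fragment-length effects, locus-specific amplification artifacts
(allelic dropout, preferential sites), and platform base-error profiles
beyond uniform per-base rates. Passing tests therefore demonstrate that
the pipeline recovers the modelled depth structure — GC bias, NB noise,
copy-number steps — not that it is robust to every artifact of real
single-cell data.

## Problem sizes and determinism

Test and acceptance problem sizes (10⁵-window correction studies,
3,400-window benchmarks, 50-point segmentation fixtures, 100-seed
calibration runs) were chosen so the full suite runs in minutes on one
CPU while keeping Monte-Carlo intervals tight enough for 3–4σ
assertions. Every stochastic component takes an explicit integer seed
and is bit-reproducible given it; derived seeds stay below 2³¹.

## Known limitations

* The exhaustive mappability search does not scale past desk-size
  genomes by design; no FM-index path is provided.
* Single-sample GC correction is fundamentally unidentifiable for a GC
  range occupied *only* by CNV windows; the iterative copy-aware fit,
  weight smoothing and gap bridging mitigate but cannot eliminate this
  (a panel-of-normals correction would, and is out of scope).
* ΔR_GC is a relative measure: at fixed GC bias, noisier amplification
  lowers it. No uniformity adjustment is applied.
* Breakpoint resolution is one merged window; sub-window refinement and
  balanced-rearrangement detection are out of scope.
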