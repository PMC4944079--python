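# Methods

## Overview

`gemusica` turns a probe-set × sample expression matrix into one melody per
sample and compares samples in melody space. The pipeline is:

1. **Normalization.** Input intensities (declared linear or log2; never
   auto-detected) are log2-transformed if needed and quantile-normalized
   across samples: each column's value at rank *r* is replaced by the mean
   of the rank-*r* values over all columns. This is the cross-sample core of
   RMA-style microarray preprocessing; probe-level background correction and
   median-polish summarization are out of scope, since the pipeline starts
   from a summarized probe-set matrix.
2. **Signature selection.** The probe sets with the highest cross-sample
   variance are selected unsupervised. The default fraction is 5%, which on
   an HG-U133A-sized matrix (22,283 probe sets) gives
   ⌊0.05 × 22,283⌋ = 1114 probe sets. The signature is ordered by
   descending variance and reused to project later, jointly re-normalized
   matrices.
3. **Sonification.** Each sample becomes a melody with one note per
   signature probe, in signature order. The log2 intensity *x* is mapped to
   a key index by `round((x − lo)/(hi − lo) × (numkeys − 1))` with half-up
   rounding and clamping, where `(lo, hi)` are the global min/max of the
   analyzed matrix. Key *k* sounds at `minfreq · 2^(k/tonesteps)` Hz.
   Defaults are the 88-key piano: `minfreq = 27.5` (A0), `tonesteps = 12`,
   `numkeys = 88`, so frequencies span 27.5–4186.01 Hz and high pitch means
   high expression.
4. **Comparison.** Melodies are stacked into a feature grid (frequency in
   Hz per position, per sample; key-index space available by flag), compared
   by Manhattan distance and clustered with complete linkage. Pearson
   correlations between query and reference samples yield the relative
   statistic ρ/ρ̄₀ described below.

## Model assumptions and parameter choices

* **Calibration is global.** Pitch bounds come from the whole analyzed
  matrix, never per sample, so a pitch means the same intensity in every
  melody. Per-sample calibration is refused.
* **Note durations are uniform** at `1/mindur` (default: eighth notes).
  The duration-assignment rule of the original scores is not fully
  specified for this pipeline, and uniform durations keep melodies
  bar-aligned and inter-sample comparable; distances and correlations never
  depend on durations. `maxNdots` (default 2) is honored only by the score
  writer when merging tied repeats is explicitly enabled.
* **Rounding is half-up**, fixed explicitly, to avoid platform-dependent
  banker's rounding at key boundaries.
* **Variance uses the unbiased (n−1) estimator** (`ddof` configurable).
  Ties in variance are broken by probe id (ascending), making selection
  deterministic and row-order invariant.
* **Quantile-normalization ties** receive the mean of the rank-means over
  the tied positions, the convention that also preserves the matrix total
  exactly; it matches `limma::normalizeQuantiles(ties=TRUE)` on two-way
  ties, which serves as a frozen cross-check in the tests.
* **Linkage ties** are broken by merging the pair of clusters whose
  (smallest-leaf-name) labels sort first, giving reproducible trees; scipy's
  complete linkage and an exhaustive brute-force oracle cross-check the
  merge heights in the tests.
* **The significance test is Welch's two-sample t-test** (two-sided,
  unequal variances) on the relative correlation values, chosen for the
  small, possibly heteroscedastic groups this statistic is applied to; a
  seeded permutation test is provided as a cross-check.
* **vol → MIDI velocity** is `vol × 16` clamped to [1, 127] — arbitrary but
  fixed; `vol = 4` gives velocity 64.

## The relative correlation statistic

For each query sample *q* and a reference group *R*, ρ(q) is the mean over
r ∈ R of the Pearson correlation between the melody features of *q* and
*r* (references are pooled; per-reference resolution is not reported).
With the query cohort split into unperturbed controls *C* and perturbed
samples *P*, the normalizer ρ̄₀ is the mean ρ over *C*, and every sample is
reported as ρ/ρ̄₀, so the control mean is 1 by construction. Group means ±
SD (per-sample SD, ddof = 1) and the Welch test on control vs. perturbed
relative values summarize the contrast.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes: several
stem-cell-like groups (defaults: ESC, NSC, MSC, EC with 3 samples each) on
an HG-U133A-sized array. Values on the log2 scale are

```
x[p, s] = baseline[p] + marker_effect · 1{p is a marker of group(s)} + ε[p, s]
```

with `baseline[p] ~ N(baseline_mean = 7, baseline_sd = 1.5)` drawn once and
shared by all samples, `marker_effect = 4` log2 units on
`markers_per_group = 100` disjoint marker probes per group, and
`ε ~ N(0, noise_sd = 0.5)` independent per entry. The probe-specific
baseline is the deliberate stand-in for probe affinity effects on real
arrays: it makes all samples strongly positively correlated over the
signature, which is what keeps the ρ̄₀ normalizer positive and stable, as
it is on real data. A 22,283-probe default means the 5% filter reproduces
N = 1114 exactly.

The knockdown perturbation linearly interpolates selected samples' values
at the union of source- and target-group marker probes toward the target
group's mean profile by `shift_fraction ∈ [0, 1]` (0 = identity, 1 = pinned
at the target means). It is deterministic given the matrix.

**What the generator does not model:** probe-level effects, batch effects,
gene–gene correlation beyond the shared baseline, heavy-tailed noise, and
array-specific artifacts. Passing recovery tests therefore show that the
pipeline's transformations preserve and expose the planted group structure
— not that real cohorts of this size are always separable.

## Study designs used by the tests and the acceptance script

* **Partition recovery.** Default cohort (4 groups × 3 samples,
  `marker_effect = 4`, `noise_sd = 0.5`), full pipeline, dendrogram cut at
  4 clusters, scored with the adjusted Rand index; repeated over 20 seeds.
* **Knockdown direction.** An ESC-like cohort of 11 samples: 3 held out as
  the *source* reference, 4 control and 4 perturbed queries; the perturbed
  queries are shifted halfway (`shift_fraction = 0.5`) toward MSC. After the
  full pipeline, the relative correlation of perturbed queries to MSC should
  exceed 1 and to the held-out ESC reference should fall below 1, each with
  Welch p < 0.01. Holding out unperturbed samples of the source cell type
  as its reference avoids correlating queries with themselves while
  preserving the design's logic (queries share the source group's
  expression program). When the study is scaled down (smaller arrays in unit
  tests), the marker count per group scales proportionally so the signature
  retains shared-baseline probes and ρ̄₀ stays positive.

Problem sizes: studies run on full 22,283 × 12 (recovery) and 22,283 × 20
(knockdown) matrices; one end-to-end run takes about two seconds, and the
20-seed loops a minute or two each.

## Numerical and degenerate-input conventions

* A constant matrix cannot be calibrated (degenerate-range error); a
  constant vector has no defined Pearson correlation (error).
* Quantile normalization requires ≥ 2 samples; idempotence holds to 1e-9.
* Identical groups in the Welch test are defined to give statistic 0,
  p = 1 (zero-variance, equal-mean case); zero variance with unequal means
  gives p = 0.
* ρ̄₀ = 0 raises a normalization error rather than returning signed
  infinities.
* Newick branch lengths are parent height minus child height; leaf heights
  are 0, so leaf-to-root path lengths equal the root merge height.

## Known limitations

* No CEL/CDF parsing and no full RMA: inputs must already be summarized
  probe-set matrices.
* No audio rendering or TeX engraving; scores are a LilyPond-compatible
  text subset, and sound output is standard MIDI.
* The intensity→pitch map is linear in log2 intensity between the global
  bounds; a rank-based alternative is not implemented.
* Single-comparison p-values only; no multiple-testing correction across
  reference groups.
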