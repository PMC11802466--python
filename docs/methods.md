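# Methods

## The model

`histoswarm` classifies genes as above- or below-median expressed from the
*shape* of histone-modification ChIP-seq signal around their transcription
start sites (TSSs), not from its amount. The input per gene is a 5 × 200
matrix: five histone marks (H3K4me3, H3K4me1, H3K36me3, H3K9me3, H3K27me3 by
default), each summarized as the mean signal in 200 bins of 50 bp spanning
TSS ± 5000 bp. Bins are indexed −100…−1 upstream and +1…+100 downstream
(no bin 0); minus-strand genes are orientation-flipped so "upstream" always
means 5′ of the TSS in transcription direction.

The elementary feature is a **pattern**: a shape template of L ∈ [2, 8]
values in [0, 1] on one mark, plus a correlation cutoff τ ∈ [0.5, 0.99].
Its value for a gene is the number of window start positions p where the
Pearson correlation r(profile[p…p+L−1], shape) strictly exceeds τ.
Zero-variance (flat) windows never match; overlapping matches each count.
Because Pearson r is invariant under positive affine transforms of the
window, the count is **scale-invariant**: multiplying a profile by any
positive constant (sequencing depth, antibody efficiency) leaves every
feature unchanged. This invariance is the core design commitment and is
enforced by property tests.

## The fitting pipeline

`PatternExpressionModel.fit()` runs four stages and returns a
`PatternExpressionResults`:

1. **Pattern extraction.** Candidate patterns are encoded as 11-vectors in
   the unit box (mark, length, cutoff, 8 shape values; the first L shape
   values are used) and searched with SPSO2007 particle swarm optimization.
   A candidate is scored by the training-subset AUC of an XGBoost classifier
   (50 boosting rounds, shrinkage 0.2, otherwise defaults, `base_score`
   0.5) trained on the already-accepted pattern counts plus the candidate's
   count column. Each round draws a fresh class-stratified subset of up to
   3000 training genes, runs the swarm (optionally several independent
   restarts, keeping the best — the candidate landscape has a broad plateau
   of diffuse low-cutoff patterns beside a narrow basin of crisp ones, and
   restarts guard against the swarm settling on the plateau), and accepts
   the round's best pattern only if it strictly improves the best AUC so
   far. Extraction stops at a training AUC of 0.999 or after a run of
   non-improving rounds. The in-sample objective deliberately overfits;
   the next two stages, both computed on the validation set, are the
   counterweight.
2. **Backward elimination (BE).** Starting from the full accepted set,
   patterns are transiently removed from last-added to first; a removal
   becomes permanent when the validation AUC (booster refit with the fixed
   extraction settings) is equal to or better than the memorized best, after
   which the walk restarts from the new last pattern. BE ends on a clean
   pass. Ties favour removal, so duplicated features cannot jointly survive;
   the memorized validation AUC never decreases and the scan is bounded by
   O(k²) refits.
3. **Hyperparameter tuning.** The same SPSO2007 optimizer searches a box
   over rounds [10, 300], shrinkage [0.01, 0.5], depth [2, 10], minimum
   child weight [1, 10] and row/column subsampling [0.5, 1], maximizing
   validation AUC. One particle starts at the box centre so the tuned
   result can never be worse than that reference point.
4. **Final training and evaluation.** A booster with the tuned parameters is
   trained on the full training set using the surviving patterns and
   evaluated by test-set AUC (the Mann–Whitney concordance statistic; ties
   contribute ½).

SPSO2007 uses the published constants: swarm size 10 + ⌊2√D⌋ unless
overridden, inertia w = 1/(2 ln 2), acceleration c = 0.5 + ln 2 on both the
cognitive and social terms, K = 3 informants re-drawn after any iteration
without global improvement, and boundary clamping with velocity zeroing.
Identical seeds give bit-identical trajectories; every stage of the pipeline
is deterministic under its master seed (a counter-based `SeedSequence`
fan-out derives per-round subset, swarm and booster seeds).

## Explanations

Per-prediction explanations follow the cover-weighted tree-walk
decomposition: within each tree every node is assigned the cover-weighted
mean of the leaf values beneath it; walking a gene's path, each step's change
in expected value is credited to the step's split feature. The intercept is
the base logit plus the sum of root expected values, and intercept +
contributions equals the prediction's log-odds exactly (checked against the
booster's own leaf assignments to < 1e−6 on every gene).

Promoter-position importance spreads each pattern's absolute contribution
for a gene uniformly over the bins covered by that pattern's matches in that
gene's profile, aggregates over genes (and models) and normalizes the
5 × 200 map to sum to one. Signed contributions, correlated with pattern
frequency across genes, give the per-mark activating/repressive summary.
Uniform spreading over matched bins is the least-assumption attribution rule
and the aggregation split (test genes by default, all genes optionally) is a
config choice.

## The synthetic data generator

The generator emulates binned promoter ChIP-seq statistics, not biophysics:

- **Background**: i.i.d. gamma(shape 2, scale 0.5) bin noise — non-negative
  and right-skewed like real coverage.
- **Decoy bumps**: Poisson(3) smooth unimodal peaks per gene per mark
  (Hanning shapes, widths 3–8 bins, amplitudes U(2, 14)), at
  class-independent positions. Real tracks are full of enrichment peaks;
  without decoys, trivially "bump-like" patterns separate the classes and
  nothing forces the search to find the planted shape.
- **Planted motif**: a double-peak (nucleosome-pair-like) template
  (0.05, 0.90, 1.00, 0.10, 0.85, 0.95, 0.15) on the first mark, planted
  additively at amplitude 12 × U(0.6, 1.4) — scale jitter exercises the
  matcher's affine invariance — at non-overlapping positions inside bins
  −85…−15. High-expression genes receive Poisson(5) copies, low-expression
  genes Poisson(1). The bimodal shape is deliberately distinct from the
  unimodal decoys, so only it (or a sub-shape of it) separates classes.
- **Expression**: log-normal with class-separated location parameters,
  clamped to disjoint supports so the median split reproduces the intended
  class of every gene exactly; overall right-skewed like RPKM.
- **Ledger**: every planted occurrence (gene, mark, start, amplitude) is
  recorded. Rescanning with the true motif at τ = 0.95 recovers ≈ 88–97 %
  of entries; the shortfall is plantings masked by an overlapping decoy
  bump, and the test floor (85 %) was locked from those oracle rescans.

What passing on this generator shows: the pipeline can discover a planted,
scale-jittered, position-variable signal shape among realistic distractors
and explain where it acted. What it does not show: performance on real
ChIP-seq, where signal is autocorrelated across bins, marks are dependent,
and expression classes overlap at the median.

With λ_high = 5 vs λ_low = 1 the *ideal* count feature (exact planted copy
numbers) has an AUC of ≈ 0.955; measured match counts at τ = 0.95 reach
≈ 0.94, which is the practical ceiling of the study conditions. Reference
runs land at test AUC ≈ 0.90–0.95.

## Reference study sizes

The bundled studies (`histoswarm.experiments`) use 2000 genes split
1200/400/400 (train fraction chosen so that extraction, the data-hungriest
stage, sees the most genes while validation decisions stay meaningful), a
per-round budget of up to two 40-particle swarms × 60 iterations, at most 14
rounds with a 3-round stagnation stop, and 8 tuning iterations. The
label-permutation null control reports the mean test AUC over three
independent permutations because a single 400-gene test split has a null AUC
standard deviation near 0.04. For the genome-scale gene set the canonical
split (6600 training genes, remainder halved into 5911 validation / 5910
test) is the `split_genes` default.

## Numerical choices and edge cases

- Strict inequality r > τ for matches; windows with zero variance are
  non-matches rather than errors (flat background is ubiquitous).
- Expression values equal to the median are promoted to the high class in
  stable input order until the classes differ by at most one gene; an even
  training-set size is required so training labels can be exactly balanced.
- Discrete particle coordinates (mark, length, boosting rounds, depth)
  decode by interval partition — ⌊u·k⌋ over k levels — keeping both
  endpoints reachable; the decode is total, with a measure-zero constant
  decoded shape nudged to restore a defined correlation.
- A candidate column that is constant with no accepted features scores AUC
  0.5 (uninformative), not an error; a featureless model likewise scores
  0.5 everywhere.
- Boosters run single-threaded with fixed seeds; model JSON round-trips
  reproduce predictions bit-exactly.
- Windows extending past a chromosome start read missing bases as 0 with a
  warning (bedGraph convention: absent intervals are zero signal).

## Known limitations

- The 11-parameter particle encoding and the tuned hyperparameter set are
  reconstructions of under-specified design space; both are config-swappable.
- The extraction objective is in-sample by design and inherits its bias
  toward high-cardinality count features; BE and tuning mitigate but do not
  remove it.
- Bin-level importance assumes a pattern's influence is evenly spread over
  its matched bins; no interaction or conditional-dependence effects are
  modelled, and no causal reading of mark → expression is warranted.
- Cross-sample transfer assumes the target sample carries the same five
  marks binned the same way.
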