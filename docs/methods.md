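# Methods

## Experimental design being modelled

The pipeline assumes a bending time-series on young tree stems: control and
once-bent plants harvested 0.5, 2, 24 and 72 h after a transient bending,
plus a twice-bent arm harvested 0.5 h after a second bending applied 24 h
after the first (so 24.5 h after the first). With `n_replicates = 3` this
gives 27 samples: 4 times × 2 treatments × 3 replicates + 3 twice-bent.
Expression values are normalized log2 intensities; normalization itself
(e.g. GC-RMA from raw arrays) is upstream and out of scope.

Six comparisons are defined, each reported as log2 fold-change
mean(B) − mean(A):

| id        | A                | B                 | meaning |
|-----------|------------------|-------------------|---------|
| C0.5–C72  | control at t     | bent once at t    | single-bending response |
| 2Bvs1B24  | bent once, 24 h  | bent twice, 0.5 h | second response vs. its immediate baseline |
| 2Bvs1B0.5 | bent once, 0.5 h | bent twice, 0.5 h | amplitude change between responses |

## Differential expression

Per comparison and probeset: pooled-variance two-group t-test, two-sided,
df = n_A + n_B − 2. Sidedness is two-sided because the downstream ternary
status (+1/−1/0) needs a direction on top of significance. Degenerate rows
(zero pooled variance) give t = 0, p = 1 when the means agree and p = 0 with
a logged warning when they differ; this makes noise-free data behave as the
limit of vanishing noise. BH adjustment (statsmodels, `fdr_bh`) is applied
within each comparison independently, since DEG lists are reported per
comparison; a pooled mode would share ranks across comparisons and is
deliberately not the default. Status is sign(log2FC) when q < α (default
α = 0.05), else 0.

Two pre-filters run per comparison, before testing:

* **Unexpressed**: a probeset is dropped when *every* intensity in both
  groups is < 4 (log2 scale). Read strictly — one sample at or above the
  threshold retains the probeset.
* **Extreme variance**: probesets whose pooled within-group variance falls
  strictly below the 0.001 or strictly above the 0.999 empirical quantile
  across probesets are dropped, supporting the equal-variance assumption.
  The protocol this reimplements states no cutoffs; the quantiles are
  configurable. Filtering is per comparison (a probeset can be excluded at
  0.5 h and tested at 72 h); a global mode would be a one-line change but
  the per-comparison reading matches where the equal-variance assumption
  lives. **Calibration note**: the low tail removes exactly the probesets
  that produce the smallest null p-values (small pooled s² inflates |t| at
  df = 4), so the full pipeline is *conservative* on null data — the
  acceptance suite verifies nominal calibration of the bare t+BH route and
  an at-or-below-nominal rejection rate for the filtered pipeline.

Probeset→gene collapsing happens after testing (statistics are per
probeset, annotation post-hoc): per gene the probeset with the smallest q
wins; ties break to larger |log2FC|, then lexicographic probeset id.
Unmapped probesets are kept under their own id and flagged.

## Feature encoding and clustering

Profiles are padded with zero fold-change at 0 h and 120 h. Three blocks,
concatenated unweighted (no weighting is stated by the source method;
optional weights would be a sensitivity knob, not a default):

1. **Velocities** (5): per-interval rate of change. The default is the
   difference quotient (a_{t+1} − a_t)/Δt. The formula as historically
   printed uses a "+" in the numerator although it is described as a speed;
   that variant is preserved verbatim behind `velocity_form="sum_printed"`
   so both are available and tested — the package does not silently choose
   for the user beyond the documented default.
2. **Sign grades** (4): the ternary status at each measured time.
3. **Accommodation delta** (1): r_2B − r_1B, grouping genes by their
   behaviour toward the repeated stimulus.

Untested (filtered) comparisons contribute 0, consistent with the padding.
A never-significant, zero-fold-change gene maps to the exact zero vector.

k-means is a hand-rolled Lloyd loop under squared Euclidean distance:
initialization draws k distinct data points uniformly; empty clusters are
re-seeded from the point farthest from its center; the objective (WCSS) is
asserted non-increasing every iteration; the best of `restarts` (default
25) initializations wins. When C(n, k) ≤ restarts the distinct
initializations are enumerated exhaustively instead of sampled, which makes
tiny instances (used by the exhaustive-bipartition oracle tests) reliably
optimal. Rows are canonically ordered by index before initialization so the
result is invariant to input order at fixed seed. k = 35 is the
domain-standard choice for this analysis and is never chosen automatically.
Cluster representatives minimize Euclidean distance to the per-coordinate
median feature vector of their cluster; the secondary annotation criterion
is exposed as an optional candidate filter, not automated.

## Accommodation decision tree

Branching uses test statuses only, with magnitudes entering only to
separate reduced from amplified:

* not DE at 0.5 h after one bending → `newly_regulated` if DE in 2Bvs1B24,
  else `not_applicable`;
* DE at 0.5 h, not DE in 2Bvs1B24 → `accommodated_null`;
* DE in both, amplitude test (2Bvs1B0.5) not significant →
  `non_accommodated`;
* all three significant: sign conflict between r_1B and r_2B →
  `unclassified`; |r_2B| < |r_1B| → `accommodated_reduced`; |r_2B| >
  |r_1B| → `amplified`; numerically equal amplitudes (tolerance 1e-9
  relative) → `non_accommodated`.

The `unclassified` rule is an explicit stand-in — the original analysis
reported a handful of unclassifiable genes without defining the criterion.
Genes still DE 24 h after the first bending pass through the same tree but
are flagged `shifted_baseline`, since their 2Bvs1B0.5 contrast is
confounded by the non-basal 24 h reference level. The summary statistic is
attenuated_percent = 100 · (null + reduced) / (genes DE at 0.5 h), rounded
to the nearest integer; NA when no gene responded.

## Enrichment and qPCR

Term enrichment per cluster is the one-sided hypergeometric upper tail
(scipy), background defaulting to all annotated genes; the default report
filter is raw p < 0.05 (matching the web tool the original analysis used,
whose correction behaviour is unknown) with BH q reported alongside. Flat
annotations only — no ontology-graph propagation.

qPCR: the reference index is the arithmetic mean of the
technical-replicate-averaged Cts of five reference genes (EF-1α, UP1, UP2,
TIP41, UBC); ΔCt = Ct_gene − index per sample, ΔΔCt = mean ΔCt(bent) −
mean ΔCt(control), QRN = 2^(−ΔΔCt) with amplification efficiency fixed at
2. Whether the original index averaged cycles or linearized quantities is
unstated; averaging cycles (geometric mean of quantities) is the
convention adopted. Significance uses a Mann–Whitney test, exact by
enumeration of all C(n+m, n) mid-rank assignments for groups ≤ 8 (p =
probability of |U − nm/2| at least as extreme), normal approximation
beyond.

## Synthetic data: the stated world

The generator emulates the design above with planted truth. Defaults,
chosen once and validated by pre-build Monte-Carlo, not adjusted
afterwards:

* **Archetypes** (trajectory shapes, as multiples of a per-gene magnitude
  E): early transient up (1, 0.5, 0, 0 at the four times), early up
  sustained (1, 1, 0.75, 0), early down (−1, −0.5, 0, 0), late up
  (0, 0, 0, 1), down-then-up (−1, 0, 0, 1), flat. Mix
  0.30/0.05/0.15/0.10/0.05/0.35.
* **Effect magnitude** E ~ Uniform(2, 4) log2 units — comfortably above
  the detection floor at the default noise, with realistic spread.
* **Accommodation classes** for first-bending responders:
  null/reduced/non-accommodated at 0.86/0.10/0.04, mirroring the
  ~986/112/44 proportions of the motivating experiment; reduced genes
  respond to the second bending at 0.4 × their first response. Sustained
  responders are planted only as null or non-accommodated (their published
  branch contains no "reduced" members, and their shifted baseline makes
  that distinction unrecoverable in principle). 5% of non-responders are
  newly regulated.
* **Noise**: i.i.d. Gaussian on the log2 scale, sd 0.2 per measurement
  (Student-t tails available via `noise_df` for robustness checks).
  Replicates are exchangeable; no batch term.
* **Baselines**: N(8, 1.5), with a 10% low-intensity subpopulation near
  Ct-like N(2.5, 0.3) clamped below 4 so the unexpressed filter is
  exercised; these genes are forced flat.
* **Multi-probeset genes**: 10% carry a second probeset with an
  independent noise draw, exercising the collapsing policy.

Twice-bent samples are generated as baseline + effect(24 h) + planted
second-bending effect, so the 2Bvs1B24 contrast recovers the planted
second response exactly at zero noise.

What a green recovery test does and does not establish: the generator
plants clean archetype geometry, homoscedastic Gaussian noise and no batch
or array effects, so recovery accuracy ≥ 0.95 here says the chain of
filters, tests and the tree is correctly wired — not that real microarray
data would classify this accurately. The archetype-recovery clustering
test uses the trajectory blocks (velocities + sign grades) at k = 6: the
accommodation delta deliberately encodes an *orthogonal* partition (a
fully accommodated and a non-accommodated gene with identical trajectories
differ by up to |E| in that coordinate), so including it makes k-means
split responders by accommodation class rather than shape — that partition
is scored separately through the decision tree.

## Numerical choices

* BH via statsmodels; brute-force step-up enumeration is the independent
  test oracle.
* Quantile-based variance cuts use `np.quantile` linear interpolation with
  strict inequalities, so `low_q=0, high_q=1` excludes nothing.
* k-means convergence: stop when WCSS improves by ≤ 1e-12; WCSS
  monotonicity asserted each iteration.
* Exact Mann–Whitney deviations compared with a 1e-12 slack to absorb
  floating-point rank sums.
* All randomness flows from one master seed: per-stage seeds are the first
  four bytes of SHA-256("{seed}:{stage}") mod 2³¹, so any stage can be
  reproduced in isolation.

## Known limitations

* No moderated/empirical-Bayes variance shrinkage — deliberately a plain
  t-test, faithful to the source protocol.
* Flat GO annotations; no true-path propagation or ontology download.
* The clustering k is fixed, not selected; the manual regrouping of
  clusters for presentation is not reproduced.
* qPCR efficiency is fixed at 2; no dilution-series efficiency estimation.
* The generator does not simulate probe-level effects, batch structure, or
  intensity-dependent variance, so it cannot stress normalization or
  array-quality issues.
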