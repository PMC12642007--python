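# Methods

This note states the models implemented in `gazeatlas`, their assumptions,
the parameter defaults and the reasoning behind them, what the synthetic
generator emulates, numerical choices, and limitations. Every quantitative
claim here is either definitional or computed by the test suite /
`scripts/acceptance.py`; nothing is asserted about real-world data.

## 1. From gaze samples to fixations (I-VT)

Gaze is sampled at a fixed rate (default 60 Hz) as `(t, x, y, valid)`
tuples per participant × ad trial. Fixations are identified by velocity
thresholding (I-VT):

1. Valid samples are grouped into maximal chains; an invalid sample always
   breaks a chain (we do not interpolate across signal loss).
2. Angular velocity at each sample is the two-point backward difference of
   position divided by the inter-sample interval, converted to degrees via
   the screen geometry; the first sample of a chain inherits its successor's
   velocity (it has no predecessor).
3. Samples below the velocity threshold form candidate runs; runs whose
   duration (last minus first timestamp) reaches the minimum fixation
   duration become fixations, with centroid = the unweighted mean of member
   coordinates.
4. A merge pass joins adjacent fixations separated by at most the merge gap
   and at most the merge distance (degrees, measured between centroids),
   using duration-weighted centroids, iterating left to right until stable.

Defaults: velocity threshold 30 °/s (the conventional I-VT boundary between
fixational and saccadic motion at these sampling rates), minimum fixation
60 ms (the lower edge of the usual 60–80 ms band; we take the permissive
end so short verification fixations are not discarded), merge distance
0.5°, merge gap 75 ms.

Degrees are converted with
`px_per_degree = 2 · d · tan(0.5°) · (width_px / width_cm)`; at the default
geometry (1920 px, 53 cm wide, 60 cm viewing distance) this is ≈ 37.94
px/°, ≈ 1.05 cm/° on screen.

Trial quality control excludes a trial when (a) it has no valid samples
("disengaged"), (b) its valid-sample fraction falls below the threshold
(default 0.70), or (c) median drift of fixation centroids from their
running mean exceeds a drift bound when one is supplied. Excluded trials
drop out of all denominators.

## 2. AOI geometry and assignment

AOIs are simple (non-self-intersecting) polygons with at least 3 vertices,
attached to one of six semantic categories. Polygons are closed: boundary
points count as inside. When a fixation falls inside several AOIs it is
assigned by category overlap priority —

Website/CTA > Logo > Symbol > Source/Authority > Text > Image/Visual —

with ties broken by smaller area, then lexicographic AOI id. The priority
order encodes that small actionable/branding elements are typically drawn
on top of larger text/image regions, so containment should resolve to the
most specific element. Containment uses polygon covering tests (validated
in the test suite against an independent ray-casting oracle).

## 3. Attention metrics

Per participant × ad × AOI:

* **TTFF**: onset of the earliest fixation in the AOI, right-censored at
  the censor value (default 10,000 ms = the exposure) when the AOI is never
  fixated. Censored rows carry FC = 0, FD = 0.
* **FC**: number of fixations in the AOI; **FD** (dwell): summed duration.
* Censored TTFF values are *included* in latency medians at the censor
  value (median{100, 10000} = 5050) — dropping them would bias latency
  summaries optimistic — but censored AOIs can never be the first hit.

**First hit** of a trial = the AOI with minimum uncensored TTFF; exact ties
(possible with discretized timestamps) break by category priority then
lexicographic id. The first-hit distribution is taken over trials with at
least one uncensored AOI and sums to exactly 100%; percentages are kept
exact internally and rounded to one decimal only at export.

Benchmark tables report medians and IQRs (robust to the heavy right tail
of dwell) per ad × AOI and per ad × category.

## 4. Tie-aware pairwise dominance

For AOIs *i*, *j* within one ad, over the `N_ij` participants with
uncensored dwell on both:

`P_ij = (#{FD_i > FD_j} + 0.5·#{FD_i = FD_j}) / N_ij`.

Restricting to joint observers avoids penalizing an AOI for other AOIs'
censoring; the half-tie convention makes the matrix exactly complementary.
Axioms `P_ii = 0.5` and `P_ij + P_ji = 1` are checked to 1e−12 (they hold
exactly up to one ulp from the complement construction). Pairs with no
joint observer are undefined (NaN) — a different state from display
masking, which greys cells with `N_ij` below the support threshold
(default 5) in figures without touching any computation.

**Dominance score** `S_i = 2·(mean over defined off-diagonal P_ij − 0.5)`,
in [−1, 1]. The diagonal is excluded because its fixed 0.5 would shrink
every score toward zero; undefined pairs are excluded and a key with no
defined pair gets NaN plus a warning. On a complete matrix the scores sum
to zero. Ranks sort by descending S with lexicographic tie-break.

Category-level dominance first sums dwell within category per participant.
The TTFF **precedence matrix** applies the same pairwise construction to
latency with "earlier wins"; a participant contributes to a pair when at
least one member is uncensored (uncensored beats censored; both-censored
contributes nothing).

**Concordance** between dominance scores and median dwell (Pearson and
Spearman over shared keys, minimum 3) is a sanity check that the ordinal
construction agrees with the magnitude summary.

## 5. Audience diagnostics

* **Stratified first-hit**: first-hit distributions within each level of a
  stratification dimension (age band, household type, education).
* **Delta matrix**: subgroup minus overall first-hit percentage per
  category × level, in percentage points. Positive = the subgroup
  over-indexes on that category. Both distributions sum to 100, so each
  column sums to ~0.
* **Early-vs-sticky quadrants**: an AOI is *early* when its first-hit share
  is at or above the within-ad median (inclusive, so the boundary is
  deterministic) and *sticky* when `S > 0` (strict; `S = 0` is a coin flip,
  not stickiness). Quadrants map to actions: protect (early+sticky),
  promote (sticky only), unclutter (early only), reconsider (neither).

## 6. Attention heatmaps

Fixation centroids are splatted onto a downsampled screen grid (default
factor 4 — below the smoothing scale, so no visible aliasing), weighted by
duration (default) or count, smoothed with an isotropic Gaussian of
`sigma_deg` (default 1.0°, converted to pixels via the screen geometry),
and divided by the maximum: the peak is exactly 1 whenever any fixation is
present; empty input yields an all-zero grid.

## 7. Synthetic study generator

The generator emulates a screening-advertisement eye-tracking study:
30 participants, 6 ads with 4/8/10/6/5/8 = 41 AOIs across the six
categories, 10 s exposures sampled at 60 Hz, and a panel stratified by
four age bands, four household types, and four education levels with fixed
marginal proportions. Per trial:

1. An entry AOI is drawn from a multinomial over entry weights (adjusted
   by the participant's stratum modifiers) and is always fixated; the
   smallest drawn log-normal latency is swapped to it.
2. Every other AOI is skipped independently with its `p_skip`.
3. Each fixated AOI draws total dwell from a Gamma model (shape 3 by
   default — right-skewed like empirical dwell; clipped at 120 ms) times
   the participant's stratum dwell multiplier, split over ≥ 1 fixations
   (Dirichlet shares, each ≥ 60 ms). Point-mass (`fixed`) dwell emits a
   single fixation so configured ties are exact.
4. Fixations are scheduled honoring drawn latencies with 100 ms saccade
   gaps. If the trial overflows the exposure, every AOI's *total* dwell is
   rescaled by a common factor — order-preserving across AOIs, so pairwise
   comparisons are unaffected — then re-apportioned with the 60 ms minimum;
   anything still past the exposure is dropped.
5. Optionally, raw gaze samples are synthesized: jittered valid samples
   during fixations, invalid samples in saccade gaps, fast valid sweeps
   outside the fixation span.

The long-form table is derived *from the emitted fixations*, so table,
fixations, and samples are mutually consistent by construction. Randomness
uses counter-derived `SeedSequence` substreams keyed by (participant, ad),
so adding participants never perturbs earlier participants' data.

Analytic ground truth for recovery testing: pairwise `P_ij` by numerical
quadrature of `∫ f_i(x) F_j(x) dx` over the stratum mixture of dwell
multipliers; first-hit shares from the modifier-adjusted entry weights;
category dominance order by seeded Monte Carlo (category dwell is a sum of
a random number of Gamma terms with no convenient closed form).

## 8. Numerical choices

* Axiom tolerance 1e−12: complement construction is exact to one ulp;
  anything larger indicates a logic error, not float noise.
* Percentages and scores are never rounded internally; export rounds to
  one decimal.
* Recovery tests use 3-standard-error bounds computed from the configured
  truth (binomial SE for probabilities), not tuned tolerances.
* Quadrature uses adaptive Gauss–Kronrod on [0, max ppf(1−1e−10)] of the
  two dwell distributions.

## 9. Limitations

* I-VT with a fixed threshold ignores smooth pursuit and microsaccades;
  at 60 Hz the two-point velocity estimate is noisy, so short fixations
  near the 60 ms minimum are uncertain.
* Right-censoring at the exposure conflates "never looked" with "looked
  just after cutoff"; censored values entering latency medians at the
  censor value is a convention, not an estimate.
* Dominance is pairwise-marginal: it does not model intransitivity beyond
  reporting the matrix, and scores average over whichever pairs happen to
  be defined, so sparse designs can make scores incomparable across AOIs.
* The generator's overflow rescale preserves dwell order but flooring each
  AOI's total at one minimum fixation can, in pathological overflow, turn
  a strict win into a tie.
* Synthetic gaze reconstructs plausible samples from scheduled fixations;
  it does not model drift, blinks with partial recovery, or calibration
  error, so preprocessing recovers the emitted table only approximately
  (timestamp quantization of TTFF, edge samples of dwell).
* Quadrant actions are heuristics over two summary axes; they are design
  prompts, not causal claims.
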