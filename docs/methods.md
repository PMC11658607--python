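# Methods notes

This note records the modeling and numerical choices behind `dyadcrqa`, the
defaults and why they hold, what the synthetic generator does and does not
emulate, and the package's known limitations.

## Data model

Coded behavior is interval data: per dyad, each actor (`trained`,
`untrained`) has `gaze` and `point` tracks whose categories come from the
declared item set (default: nine items `A`–`I`), plus a `turn` track whose
categories are actor identities.  Intervals within one (actor, track) must
be mutually exclusive, and the two actors' turn intervals together must tile
`[0, T]` exactly — conversation is always someone's turn.

Rasterization is instantaneous sampling on the half-open convention: sample
k (time k/rate) takes the category of the interval with onset ≤ k/rate <
offset, else `OFF`.  This rule is deterministic, and exactly invertible for
series whose run boundaries lie on the sample grid, which gives the
round-trip identity (series → events → series) that the test suite checks.
Events shorter than one sample period can vanish at 10 Hz; this is accepted
behavior, not an error.  The alternative rule (majority vote within each
sample bin) was considered and rejected because it is not round-trip safe;
the choice only matters for sub-sample events, and 10 Hz dominates the
effective resolution of the analysis either way.

`OFF` ("not on any task item") and `MASK` ("removed by turn conditioning")
never participate in a recurrence match, including with themselves: only
joint attention on task items counts as recurrence.

## Recurrence measures

- **rr denominator.** rr(d) divides the count on diagonal d by the diagonal
  length n − |d|, the standard categorical-CRQA normalization; it keeps
  rr ∈ [0, 1] at every lag, including long ones.
- **Binning.** The 2L+1 = 301 lags are averaged in 43 contiguous groups of
  7; a bin is labeled by its central lag, so bin 22 (index 21) is centered
  on lag 0.  The geometry requires (2L+1) divisible by n_bins and is
  validated at configuration time.
- **CORM normalization.** CORM = Σ(j−i) / (B·N) over in-band points: the
  mean signed lag divided by the band half-width B, dimensionless in
  [−1, 1], zero for any point set symmetric under (i,j) ↔ (j,i).  Any other
  global positive scale factor would leave every t/V/W statistic computed on
  CORM values unchanged (they depend only on signs and ranks/ratios), so no
  downstream inference hinges on this constant.
- **Tie-breaking.** The peak lag of a profile is the maximal-rr lag closest
  to 0, with the negative lag preferred on an exact two-sided tie, reported
  deterministically.
- **Turn conditioning** replaces samples outside the speaker's turns with
  `MASK` in *both* series while preserving the native time axis.
  Concatenating the kept samples instead would fabricate spurious short lags
  across turn boundaries.  A consequence worth remembering when reading
  results: the two turn-conditioned profiles do not sum to the full-record
  profile, because cross-turn recurrence exists only in the latter.
- **Shuffle baseline.** Each of the 100 shuffles (default; there is no
  canonical count) applies an independent uniform permutation to the sample
  order of each series, OFF samples included, and the mean profile over
  shuffles is used.  Under permutation the expected rr at every lag is
  exactly Σ_k p_k q_k for the realized marginal label frequencies p, q; the
  test suite checks the binned baseline against this analytic value within
  three Monte-Carlo standard errors.
- Two equivalent computation routes exist: an explicit recurrence point set
  (used for plots and small inputs) and a per-lag slice counter
  (`rr_by_lag`/`corm_fast`, used for batch runs).  They are verified
  bit-identical against each other and against a naive O(N²) double loop.

## Inference

ANOVAs on binned profiles are balanced two-way fully within-subject designs
(dyad as the experimental unit; condition and lag bin as within factors),
computed from closed-form sums of squares with each effect tested against
its own effect-by-dyad interaction.  Zero-SS conventions: a zero effect SS
reports F = 0, p = 1; a nonzero effect with zero error SS reports F at the
machine ceiling with p = 0 (these arise only in noiseless constructed
fixtures).  The baseline comparison (observed vs shuffled profile) uses the
same dyad-as-unit design, since both profiles come from the same dyads.

CORM tests use a Shapiro–Wilk gate at α = .05 on the tested vector (or the
paired differences): parametric path = one-sample/paired t with a 95% CI,
nonparametric path = Wilcoxon signed-rank with V reported as the
positive-rank sum (R's convention).  Two-sample budget comparisons use the
rank-sum test with W reported in R `wilcox.test` convention (the
Mann–Whitney U of the first sample); the raw rank sum is logged alongside.
Fractions are compared nonparametrically by default.  All tests are
two-sided at α = .05 and no multiple-testing correction is applied; reports
state this.

Dyads with an empty stream (no on-item samples) in a given analysis are
excluded from that analysis only, with a logged count; a test with fewer
than three usable dyads is skipped with an explicit report entry.

## Synthetic dyad generator

Defaults emulate the target study conditions: 9 items, 10 Hz, 314 s
conversations, 18 dyads, trained speaking share ρ = 0.59, pointing-time
shares 0.12 / 0.04, listener follow lag τ = 0.5 s, own-gaze lead δ = 0.2 s.
Mechanism, per dyad (all randomness from `(seed, dyad_seed)` via
SeedSequence):

1. **Turns** alternate, starting randomly; durations are log-normal
   (σ = 0.6, a shape chosen once for right-skewed, occasionally long turns)
   with role-specific means 2ρ·8 s and 2(1−ρ)·8 s, so the expected trained
   share is ρ at a mean turn of 8 s.
2. **Leader walk**: one global semi-Markov walk over items — geometric
   dwell, mean 2.5 s; with probability 0.1 a segment is an `OFF` excursion
   (same dwell distribution, for parsimony); no immediate item repeats.
   The *current speaker* displays this walk.
3. **Listener**: an imperfect delayed copy — the walk shifted by τ, with
   each segment independently replaced by a uniformly random item with
   probability 1 − c (c = 0.8).  Infidelity as independent exploration (not
   lag jitter) produces the uncoupled patches seen in real recurrence
   plots.
4. **Pointing**: only during one's own turns, at the currently gazed item.
   An epoch's onset is uniform within 2 s of settling on an item but at
   least δ after gaze arrival, so own gaze always leads own pointing;
   durations are geometric (mean 1.5 s), clipped to the turn.  Epochs are
   accepted in random order until the configured pointing-time budget is
   met (direct budget calibration), then de-overlapped.  The partner
   re-fixates the pointed item one follow lag after pointing onset (with
   fidelity c), encoding "pointing leads the partner's gaze".

The leader is the *current speaker*, not a fixed individual: this builds the
turn-dependent, training-independent asymmetry into the ground truth, so the
pipeline's headline inference is testable as parameter recovery.  The
recovery tests confirm: the turn-conditioned CORM is positive for the
current speaker's stream, the paired turn-split contrast is detected in
≥ 90% of cohorts, the binned grand profile still peaks in the lag-0 bin, and
the configured follow lag is recovered within one bin width for
τ ∈ {0.5, 1, 2} s.

What the generator does **not** emulate: 2-D gaze coordinates, face gaze,
speech content, coder disagreement, sub-sample event quantization (events
are real-valued seconds), or realistic dwell-time distributions (geometric
dwell is a modeling convenience — real dwell distributions for this task are
unknown).  Passing recovery tests therefore demonstrates correctness of the
analysis machinery under a plausible mechanism, not validity claims about
any particular real data set.

Known limitation: because the untrained member's turns are shorter, the
partner's delayed response to untrained pointing is more often clipped by a
turn switch; the cross-person CORM for that direction is attenuated toward
zero in simulation, while the directional contrast between the two
cross-person profiles (the quantity actually tested) remains positive.  A
"symmetric null" configuration — used for type-I checks — requires equal
speaking shares *and* equal pointing budgets; equalizing speaking share
alone leaves a pointing-driven asymmetry in the full-record gaze CORM.

## Problem sizes

Default test and acceptance runs use the full study-scale conditions
(18 dyads × 3140 samples, 100 shuffles); cohort-level recovery properties
use 50 coupled and 50 symmetric-null cohorts.  The whole suite runs in well
under a minute on one CPU.

## Real-data ingestion

The event-CSV dialect (`dyad_id,actor,track,category,onset_s,offset_s`) is
the package's canonical interchange format.  Deposited data sets from
specific coding tools must be mapped to it by the user; no tool-specific
parser is bundled, because export schemas vary by tool version.  The mapping
is mechanical: one row per coded interval, turn rows attributed to the
speaking actor.
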