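# dyadcrqa

Nominal cross-recurrence analysis of how two people in conversation couple
their visual attention and pointing gestures over time.

## The problem

When a dyad discusses something both members can see — here, a shared display
of nine task items — their gaze and gestures become coupled: they tend to be
on the same item at the same time, and one member's attention shifts may
systematically precede the other's.  `dyadcrqa` quantifies this coupling from
event-coded behavior (gaze-on-item, pointing, and conversational-turn
intervals for a "trained" expert and an "untrained" novice), and asks *who
leads whom*, overall and as a function of who currently holds the
conversational turn.  It is aimed at researchers analyzing dual mobile
eye-tracking / gesture-coding studies of co-present interaction.

## Method

Event intervals are rasterized to categorical series at 10 Hz (label = item
looked/pointed at, `OFF` = not on any task item).  For a series pair
X (rows) and Y (columns) of length *n*:

- **Recurrence set** — all index pairs (i, j) with X<sub>i</sub> =
  Y<sub>j</sub>, both on-item.  The lag of a point is d = j − i; positive
  lags mean X's state precedes Y's matching state (X leads).
- **DCRP** (diagonal cross-recurrence profile) — the recurrence rate per lag,
  rr(d) = #{(i, j) : j − i = d} / (n − |d|), over d ∈ [−L, L] with L = 150
  (±15 s), averaged into 43 equal bins of 7 lags.
- **Shuffle baseline** — the mean DCRP after independently permuting each
  series' sample order (100 shuffles), which preserves label frequencies but
  destroys temporal structure; expected level Σ<sub>k</sub> p<sub>k</sub>q<sub>k</sub>.
- **CORM** (center of recurrence mass) — the signed mean lag of recurrent
  points within a ±B band (B = 40 samples, 4 s), normalized by B:
  CORM = Σ(j − i) / (B · N<sub>band</sub>) ∈ [−1, 1].  Positive values mean
  the row stream leads even when the DCRP peaks at lag 0.
- **Turn conditioning** — samples outside a designated speaker's turns are
  masked in both series, so a recurrence point requires both of its time
  coordinates to fall inside that speaker's turns.

Cohort-level inference uses condition × lag-bin repeated-measures ANOVAs on
binned profiles, paired/one-sample tests on per-dyad CORM values (paired *t*
with a Shapiro–Wilk gate, Wilcoxon signed-rank *V* fallback), and two-sample
rank tests (*W*, R `wilcox.test` convention) on speaking/pointing time
budgets.

A forward simulator (`dyadcrqa.simulate`) generates dyads with a known
ground truth — alternating turns with unequal speaking share, the current
speaker driving a semi-Markov gaze walk over items, the listener following
after a configurable lag with imperfect fidelity, and speaker-only pointing
with own gaze arriving at the target first — so every stage of the pipeline
can be verified by parameter recovery.

## Worked example

```python
import dyadcrqa as d

bundle = d.run_pipeline(d.AnalysisConfig(seed=1))   # default simulated cohort
print("\n".join(bundle.log))
```

prints (abridged):

```
cohort: 18 dyads, 3140 samples at 10 Hz (first dyad)
H1_speaking_time: W = 320, p = 6.258e-07 (n = 36)
H2 grand DCRP peak: rr = 0.6235 at lag 0.5 s (binned argmax at 0 s)
H2_corm_vs_zero: t = 7.049, p = 1.954e-06 (n = 18)
H3_corm_paired: t = 22.12, p = 5.712e-14 (n = 18)
H3_corm_vs_zero_trained_speaking: t = 21.39, p = 9.988e-14 (n = 18)
H3_corm_vs_zero_untrained_speaking: t = -15.53, p = 1.785e-11 (n = 18)
H4_pointing_time: W = 324, p = 3.063e-07 (n = 36)
```

Reading: the trained member speaks more (H1, rank-sum W on per-participant
speaking fractions); the cohort's gaze–gaze profile peaks in the lag-0 bin
(the dyad mostly looks at the same item simultaneously); and the
turn-conditioned CORMs are positive while the trained member speaks and
negative while the untrained member speaks (H3) — whoever currently speaks
leads the joint focus of attention, which is exactly the mechanism the
simulator encodes.  Profile tables, per-dyad CORMs, figures and a run log
are written by `bundle.write(out_dir)` / `d.plot_outputs(bundle, out_dir)`.

The same run is available from the shell:

```bash
dyadcrqa simulate --out sim/ --seed 1
dyadcrqa analyze --from-sim sim/ --out report/ --seed 1
dyadcrqa report report/
```

Real data are supplied as a CSV of coded events
(`dyad_id,actor,track,category,onset_s,offset_s`, one or more dyads) via
`dyadcrqa analyze --events events.csv`.

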