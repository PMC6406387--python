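# Methods

## Questionnaire model

The sensory-profile instrument has 60 Likert items (1 = never … 5 =
always), 15 per quadrant. Because the commercial instrument's item texts
and normative values are copyrighted, the item map (item id → quadrant) and
the normative table (per-quadrant mean and SD) are user-supplied
configuration. The shipped defaults are synthetic: a block layout of
`item_001`–`item_060` over the four quadrants, and a normative table with
mean 45 (the scale midpoint of a 15-item quadrant, range 15–75) and SD 8.
They exist so that simulation and tests run self-contained; real use
requires the published normative table.

Normative categorization uses z = (raw − mean)/sd with five bands. Band
boundaries are inclusive on the inner side (|z| = 1 → *similar*, z = 2 →
*more*), a deterministic tie rule consistent with "within one standard
deviation".

Axis scores: each rating is rescaled to 0–4 (subtracting one point avoids
a gap in the distribution of signed sums), the passive-quadrant and
low-threshold-quadrant sums are negated, and the signed sums are totalled.
Each axis therefore runs over the integers [−120, 120] and is kept exact —
no normalization. The derived quadrant is the sign pattern of (BR, T). A
zero coordinate lies on an axis line, which the model does not assign: such
respondents are *unclassified* and excluded from derived-quadrant
contingency analyses, mirroring the exclusion of raw-score ties from
highest-quadrant analyses. Both exclusions are logged per participant.

The personality questionnaire (24 items, two 12-item scales, exactly two
reverse-scored items) maps each scale from its rescaled 0–48 sum to
[−24, 24] via `sum − 24`, the unique affine map between those ranges.
Which items load on which scale, and which two are reversed, is again
instrument configuration; the default map is an arbitrary fixed assignment
with the same structure.

## SERP pipeline

Processing order is fixed: mastoid-mean reference → average reference →
polynomial detrend → band-pass → epoching → artifact rejection → baseline
correction → averaging → P50 measurement. Notes on each stage:

* **Referencing.** After the average-reference stage the cross-channel
  mean is exactly zero at each sample (the earlier mastoid subtraction is
  absorbed by it); the mastoid stage is retained because rejection
  thresholds act on the intermediate signal in standard practice.
* **Detrend.** Least-squares polynomial per channel on the continuous
  data, default order 1 (linear drift). Computed on a centred/scaled
  abscissa for conditioning.
* **Filter.** 4th-order Butterworth, 10–300 Hz, applied forward–backward
  (`sosfiltfilt`): zero phase, so peak latencies are not shifted. The
  analysis band is used even where an acquisition chain may have been
  narrower; the band edges are parameters.
* **Epochs.** −100..+200 ms, half-open sample windows `[t0 − 0.1·fs,
  t0 + 0.2·fs)`, 0-based indices, time 0 at the marker sample. Markers too
  close to a recording edge are dropped and counted. In the 5 Hz
  single-train paradigm (200 ms onset asynchrony) the 300 ms epochs overlap
  neighbouring stimuli by construction; the measurement window (40–85 ms)
  and baseline window (−100..0 ms) of one epoch do not contain the
  neighbouring stimulus' P50, so the overlap only contributes residual late
  activity, which averages like noise.
* **Artifact rejection.** Template-based artifact-removal routines in
  commercial packages are not reproducible; rejection is peak-to-peak
  amplitude over any channel, default 100 µV, configurable.
* **Baseline.** Mean over the 100 ms pre-stimulus interval, per channel.
  Without it, a "baseline-to-peak" amplitude would depend on filter and
  reference offsets.
* **P50.** Maximum positive sample at Cz in the closed 40–85 ms window —
  no local-maximum requirement, so a flat or negative ERP yields a small
  amplitude that simply fails the 0.5 µV criterion rather than an error.
  The criterion is applied to the single-train P50 for amplitude analyses
  and to the conditioning (first-in-pair) P50 for gating; the test-stimulus
  amplitude is not separately thresholded.
* **Gating.** T/C ratio of the pair-averaged ERP amplitudes; smaller means
  stronger gating. Undefined (flagged invalid, not raised) when the
  conditioning amplitude is below criterion.

The pipeline is linear up to artifact rejection: scaling a recording by k
scales P50 amplitudes by k and leaves the ratio unchanged, which the tests
assert.

## Synthetic data

`simulate_responses` draws archetype cohorts: each respondent has a true
quadrant; on-target items are sampled from a discretized truncated normal
with mean 4.2 (SD 0.8) and all other items with mean 2.2 (SD 0.8), rounded
and clipped to 1–5. The default mixture (0.70 seeking, 0.20 low
registration, 0.05 sensitivity, 0.05 avoiding) reflects the strong skew
toward active/high-threshold patterns seen in healthy-adult convenience
samples. No publication prints response-distribution parameters; these are
package choices, tunable per `CohortSpec`. An optional coupling shifts the
simulated I/E axis mean by behavioral-response group (−3 passive, +2
active), matching the direction of group differences reported for such
samples.

`simulate_eeg` renders 2 kHz, 8-channel recordings: background noise plus
an evoked component at every marker. The component is a Gaussian-windowed
cosine (envelope σ = 6 ms, carrier 55 Hz) peaking 55 ms post-stimulus.
A windowed oscillation rather than an isolated positive bump is used
because the component must live inside the 10–300 Hz analysis band: an
isolated bump of realistic width carries most of its peak in
low-frequency content and loses ~25% of its amplitude to the 10 Hz
high-pass, whereas the windowed oscillation passes with ≈ 4% distortion
(the noiseless end-to-end tests assert ≤ 5%). Its scalp topography is a
fixed zero-mean pattern with weight 1 at Cz, so the average-referenced Cz
amplitude equals the nominal amplitude parameter exactly. Pair-second
responses are scaled by the gating factor g ∈ [0, 1]. Noise is an equal
mix of white and 1/f power (total SD 2.0 µV), independent per channel — a
plausible in-band background level for averaged-ERP work, and again a
package choice, not a published value. Timing follows the study paradigms:
5 Hz single trains and 500 ms within-pair separation with 8 s between
pairs by default.

What the generator does **not** emulate: ocular/muscle artifacts beyond
what the peak-to-peak rejection exercises, alpha rhythm and other
structured background, later ERP components (N100 etc. — only the P50
window is measured), spatially correlated noise, and test–retest
variability. Passing recovery tests therefore shows the pipeline's
correctness on its stated signal model, not robustness to every real-data
pathology.

## Problem sizes

Tests and the acceptance script keep the paradigms' 200 trials but shorten
the interval between pairs from 8 s to 1.5 s, purely to bound recording
length; epochs span 300 ms, so any spacing beyond ~1 s yields identical
measurements. The cohort drivers use n = 139 with one missing EEG session.
Parameter-recovery suites run a 3×3 grid of amplitudes {0.8, 1.5, 3.0} µV
× gating {0.4, 0.6, 0.8} with 20 seeded replicates (10 in the acceptance
script) and require the median recovered amplitude within 15% and the
median ratio within ±0.1. Two opposing small biases are at work there:
the band-pass shaves ~4% off the true peak, while picking the maximum of
a noisy averaged window adds a positive selection bias that grows as
amplitude falls; with 200 averaged trials both stay well inside the bands.

## Statistics

Two-sided p values throughout, α = 0.05. Specific conventions:

* t-tests pool variance (df = n₁ + n₂ − 2), matching the df convention of
  the reported analyses, with effect size r = √(t²/(t²+df)).
* ω is computed from ω² = (SS_b − df_b·MS_w)/(SS_t + MS_w) with negative
  values clipped to 0 before the square root: for F < 1 the standard
  estimator is negative and no published variant reproduces reported ω
  values in that regime, so the clipped magnitude is documented behaviour
  and ω is never used as a frozen expected value in tests.
* r×c Fisher tests use Monte-Carlo sampling of tables with fixed margins
  (Patefield's algorithm via `scipy.stats.random_table`), estimating the
  Freeman–Halton p (total conditional probability of tables no more
  probable than the observed one) with a reported standard error; full
  enumeration is combinatorially expensive beyond toy tables and is kept
  as the independent oracle in the tests.
* Cramér's V is clipped into [0, 1] against floating-point overshoot.

## Orchestration and exclusions

`run_analysis` is a pure function of (cohort, norms, parameters, Fisher
seed). Within each behavioral-response group (passive/active by the
highest-raw quadrant) it compares BR axis scores across the normative
categories of that highest quadrant by ANOVA + Tukey, and analogously for
the threshold axis within low/high groups; categories are whatever levels
are present, and tests whose groups are degenerate (a single category, no
within-group df, zero variance) are skipped with a logged reason rather
than raised. Sub-criterion participants are excluded from single-train
amplitude and gating analyses independently, so the two analyses have
separate inclusion counts, and every report table's group sizes sum to the
number of included participants.

## Known limitations

* The ERP simulator's ground-truth amplitude is defined at Cz after
  average reference; for other topographies the nominal amplitude would
  need re-deriving.
* The Monte-Carlo Fisher p is an estimate; its SE is reported, but
  downstream consumers see a single number.
* Normative categorization with the synthetic default table concentrates
  archetype cohorts in the *more*/*much more* bands; ANOVA tables on
  synthetic cohorts therefore have fewer category levels than a normed
  human sample would.
* BDF/EDF reading requires mne; all shipped fixtures and drivers use the
  plain-text CSV formats.
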