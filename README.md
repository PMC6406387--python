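# sensory-axes

Analysis pipeline for the two axes underlying the four-quadrant model of
sensory processing: **neurological threshold** (low ↔ high) and
**behavioral response** (passive ↔ active). The four quadrants are the
sign patterns of these axes: low registration (passive, high), sensory
seeking (active, high), sensory sensitivity (passive, low) and sensory
avoiding (active, low).

The package is aimed at researchers in clinical neurophysiology and
occupational science who want to test whether these axes behave as ordinal
ranges and whether they track external measures — personality
(introversion/extraversion) and somatosensory evoked potentials (SERP) with
their paired-stimulus gating. It implements, as a tested library with thin
analysis drivers:

* **Questionnaire scoring** (`sensory_axes.profile`): a 60-item instrument
  with 15 Likert items (1–5) per quadrant. Raw quadrant sums are
  z-categorized against a normative table (similar / (much) less / (much)
  more than most people at 1 and 2 SD). Signed axis scores rescale each
  rating to 0–4, negate the passive and low-threshold item sums, and total:
  BR = Σ(active) − Σ(passive), T = Σ(high) − Σ(low), each in [−120, 120].
  The signs of (BR, T) give a *derived quadrant*, compared against the
  quadrant with the highest raw score.
* **Personality scoring** (`sensory_axes.epq`): a 24-item, two-scale brief
  Eysenck questionnaire (introversion/extraversion, neuroticism; two
  reverse-scored items), each scale mapped linearly from 0–48 to [−24, 24].
* **SERP pipeline** (`sensory_axes.serp`): mastoid then average
  re-referencing, polynomial detrend, zero-phase 10–300 Hz Butterworth
  band-pass, −100..+200 ms epochs, 100 µV peak-to-peak artifact rejection,
  baseline correction, averaging, and P50 measurement (maximum positive
  amplitude 40–85 ms post-stimulus at Cz, 0.5 µV inclusion criterion).
  Sensory gating is the T/C ratio: test-P50 / conditioning-P50 over the
  pair-averaged ERPs.
* **Statistics** (`sensory_axes.stats`): χ², Fisher's exact test (exact for
  2×2, Monte-Carlo Freeman–Halton for r×c), one-way ANOVA with ω, Tukey
  HSD, pooled t-test with r = √(t²/(t²+df)), Pearson correlation with r²,
  Cramér's V = √(χ²/(n·(min(r,c)−1))).
* **Synthetic cohorts** (`sensory_axes.simulate`): archetype-structured
  questionnaire responses and 2 kHz EEG (evoked component + white/1-f
  noise) with known amplitude and gating ground truth, so the whole
  pipeline is testable end to end without any external data.
* **Orchestration** (`sensory_axes.runner`): the full analysis sequence on
  a cohort, with per-participant exclusion logging (ties, missing EEG,
  sub-criterion P50).

## Worked example

```python
from sensory_axes.profile import (axis_scores, default_item_map,
                                  derived_quadrant, highest_quadrant,
                                  score_quadrants)
from sensory_axes.profile import ResponseSet

item_map = default_item_map()
# a respondent rating all seeking items 4, avoiding 2, low registration 1,
# sensitivity 2:
per_q = {"seeking": 4, "avoiding": 2, "low_registration": 1, "sensitivity": 2}
resp = ResponseSet("P001", {i: per_q[q] for i, q in item_map.entries.items()})
print(score_quadrants(resp, item_map))
print(axis_scores(resp, item_map))
print(derived_quadrant(axis_scores(resp, item_map)))
```

prints

```
{'low_registration': 15, 'seeking': 60, 'sensitivity': 30, 'avoiding': 30}
AxisScores(br=45, t=15)
seeking
```

— raw sums of the 15 items per quadrant; the signed axis scores
(BR = (45+15) − (0+15) = 45 on the rescaled 0–4 sums, T = (45+0) − (15+15)
= 15); and the derived quadrant from the two positive signs.

The cohort-level narrative lives in `analysis/`:

```
python analysis/01_simulate_cohort.py --seed 1   # cohort + EEG ground truth
python analysis/02_score_questionnaires.py       # scores.csv + cross-table
python analysis/03_erp_pipeline.py               # serp.csv (P50, gating)
python analysis/04_run_statistics.py             # report tables + summary
```

On the default seed-1 cohort (n = 139) this reports, among other things,
138 participants with EEG, 60 with a measurable (≥ 0.5 µV) single-train
P50, a median absolute P50 amplitude recovery error of 5.9% among them,
and perfect agreement between derived and highest-raw-score quadrants
(Cramér's V = 1.0 on this strongly archetyped synthetic cohort).

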