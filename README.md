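# emoseg

Analytics for **emotion segmentation** experiments: studies in which people
watch continuous video and press pause whenever they perceive a change in a
character's emotion, optionally typing a free-text label for what they saw.
The package turns the raw pause timestamps and labels into individual-
difference measures of dynamic emotion perception and active emotion
vocabulary, together with the psychometrics needed to evaluate them. It is a
library first (with a thin `emoseg` command-line front end) aimed at
researchers in affective science and computational behavioral science.

## What it computes

For each participant, from the affective-block trials:

- **MLU** (mean length of unit) — stimulus duration / number of pauses, in
  seconds, averaged across clips; the grain of segmentation.
- **SA** (segmentation agreement) — the point-biserial correlation between a
  participant's 1-s binned pause series and the group's pause-density
  series, scaled by the best correlation attainable with the same number of
  pauses (ideal placement in the densest bins), clamped to [0, 1].
- **CEA** (consensus event agreement) — the proportion of group *consensus
  events* the participant identified, pooled over all clips. Consensus
  events are found by: (1) smoothing each participant's pauses with
  unit-peak Gaussian kernels (SD = 0.8 s, overlaps combined by maximum so
  each person contributes at most height 1); (2) summing curves into the
  group segmentation magnitude; (3) thresholding at the 0.95 quantile of a
  bootstrap null (500 iterations; pause counts preserved, times redrawn
  uniformly); (4) merging supra-threshold local maxima closer than 800 ms;
  (5) bounding each event with the nearest mean–variance changepoints of
  the magnitude series (PELT). A pause inside the closed window counts as
  identifying the event.
- **NUL** (number of unique labels) — unique cleaned, lemmatized emotion
  labels per clip, averaged across clips ("anger" and "angry" count once).
- **AoA / Familiarity** — means of lexical norms over the participant's
  pooled unique labels.
- **SAS** (semantic agreement score) — per consensus event, the Pearson
  correlation between the participant's mean label-embedding profile and the
  group's, averaged over identified events (plus an exploratory
  between-emotion distinctiveness score, SDS).

Reliability and validity statistics: McDonald's omega-total across trials
(one-factor minres fit), two-way absolute-agreement single-measurement
ICC(A,1) for test–retest, Bonferroni-corrected Spearman correlations with
Fisher-z confidence intervals, and rank-based partial correlations.
Participant screening follows the standard protocol: completeness filtering
(every clip segmented) and per-metric median-absolute-deviation outlier
removal (b = 1.4826, threshold 3), blanking cells rather than dropping
participants.

A first-class synthetic-data generator (`emoseg.synthetic`) simulates the
whole paradigm — latent true events, per-observer hit probabilities, timing
jitter, false alarms, and label vocabularies with known norms and
embeddings — so every stage is testable against ground truth.

## Worked example

```bash
python examples/consensus_event_detection.py
```

simulates 30 observers watching a 120-s clip with five latent emotion
changes (hit probability 0.85, jitter 0.3 s, 0.5 false alarms per clip) and
prints:

```
bootstrap threshold: 4.25 (out of 30 observers)
true events at (20.0, 40.0, 60.0, 80.0, 100.0)
detected consensus events:
  t =  20.10 s   window [ 19.30,  21.00]   peak magnitude 22.6
  t =  39.90 s   window [ 39.20,  40.80]   peak magnitude 21.2
  t =  60.10 s   window [ 59.30,  60.90]   peak magnitude 26.3
  t =  80.10 s   window [ 79.20,  81.10]   peak magnitude 23.7
  t = 100.00 s   window [ 99.20, 100.90]   peak magnitude 22.8

recovery: 5 matched, 0 spurious, 0 missed; mean |offset| = 0.080 s
```

The threshold (4.25) is how high the group magnitude gets by chance when the
same number of pauses is placed uniformly; each latent event is recovered
within a tenth of a second, with peak magnitudes near the ~26 observers who
on average detected it. The other scripts in `examples/` walk through the
full pipeline (`simulate_and_run_pipeline.py`), label cleaning and lexical
norms (`vocabulary_metrics.py`), and the reliability statistics
(`reliability_statistics.py`).

The same analyses are available from the shell:

```bash
emoseg simulate --n-participants 50 --seed 11 --out sim/
emoseg consensus --input sim/records.csv --stimuli sim/stimuli.csv --seed 11 --out events.csv
emoseg run --config analysis.yaml
```

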