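# Methods

This note documents the models and procedures emoseg implements, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer should know
about.

## The measurement model

The paradigm treats dynamic emotion perception as an event-segmentation
task: observers watching continuous video press pause at perceived emotion
changes and label them. Two families of scores follow.

**Segmentation performance.** A participant's pause train is compared with
the group's in two ways. Segmentation Agreement (SA) bins pauses into 1-s
bins (half-open `[k, k+1)`, final bin closed at the clip end), correlates
the binary individual series with the group density series (the sum of all
participants' binary series), and scales by the correlation an ideal
observer with the same pause count would reach by occupying the densest
bins. This ideal-placement maximum is exact: Pearson correlation against a
fixed density vector is maximized, over binary vectors with k ones, by
choosing the k largest densities (verified in the tests by exhaustive
enumeration). Ties between equal-density bins are broken toward earlier
bins; the maximum is tie-invariant because the correlation depends only on
the multiset of chosen densities. Negative scaled values are clamped to 0 so
the score lives in [0, 1]; the raw correlation is available via
`compute_sa(..., return_raw=True)`. The group density includes the scored
participant by default (the norming convention in the segmentation
literature); a leave-one-out variant is a flag.

Consensus Event Agreement (CEA) avoids SA's penalty on being slightly early
or late. Each pause is smoothed with a unit-peak Gaussian (SD 0.8 s);
overlapping kernels of one participant combine by maximum, so every
participant contributes at most height 1 anywhere and the group curve reads
as "effective number of participants segmenting near t". The null threshold
preserves each participant's pause count and redraws times uniformly over
the clip, 500 iterations by default; all grid values of all iterations are
pooled and the critical-probability (0.95) quantile is the threshold.
Supra-threshold strict local maxima (plateaus at their midpoint) are event
timestamps; timestamps closer than 800 ms merge transitively to the mean of
the chain. Event windows come from a single pass of changepoint detection
over the magnitude series — PELT with the Gaussian mean+variance cost — the
window running from the nearest changepoint at or before the timestamp to
the nearest one after it, falling back to the clip boundaries. CEA is the
proportion of all events, pooled over the block's clips (not averaged per
clip), with at least one pause inside the closed window.

**Active emotion vocabulary.** Labels are lowercased, stripped of
punctuation and digits, tokenized on whitespace, filtered against an
editable stopword list, and lemmatized. The lemmatizer consults a shipped
derivational merge table first (angry → anger and ~130 similar pairs) and
falls back to simple inflectional suffix rules; canonical forms in the table
are fixed points, making cleaning idempotent. This is deliberately not an
off-the-shelf lemmatizer: those treat adjective/noun pairs as distinct
lemmas, which would double-count a single emotion concept. The merge table
is a plain-text package resource meant to be extended per study. NUL is the
per-clip unique-lemma count averaged over clips; AoA/familiarity are means
of a pluggable norms table over the participant's pooled unique lemmas, with
a coverage floor (default 0.5) below which the means are reported missing.
SAS correlates, per consensus event, the participant's mean label-embedding
vector with the group's mean over all labels at that event (self included by
default; leave-one-out by flag), then averages over the events the
participant identified, pooled across clips rather than averaged per clip —
a single-level aggregation chosen because multi-level averaging is a
suspected source of unreliability in this score. SDS (exploratory, and
flagged as such) assigns each lemma to its maximum-loading emotion
dimension, builds per-emotion mean profiles, and reports their pairwise
correlations and off-diagonal mean.

**Psychometrics.** Omega-total uses a one-factor minimum-residual fit to the
trial correlation matrix (sum-of-squared off-diagonal residuals minimized by
L-BFGS from a principal-component start), then
ω = (Σλ)² / ((Σλ)² + Σψ). Working on the correlation matrix makes the
estimate invariant to affine rescaling of scores; hierarchical omega is out
of scope. ICC(A,1) — two-way random effects, absolute agreement, single
measurement — is assembled directly from the two-way ANOVA mean squares and
cross-checked in tests against an independent implementation. Spearman
confidence intervals use the Fisher transform with variance 1.06/(n−3);
Bonferroni adjustment multiplies raw p by the family size and caps at 1.
Partial rank correlations residualize the control's ranks out of both
variables' ranks by least squares. Missingness: pairwise deletion for
correlations, listwise for omega and ICC — consistent with the per-cell MAD
screening upstream, which blanks flagged cells (|x − median| > 3 × 1.4826 ×
MAD) per metric rather than dropping participants.

## Parameters and defaults

| parameter | default | role |
|---|---|---|
| kernel SD | 0.8 s | pause-timing uncertainty absorbed by the magnitude curve |
| grid step | 0.1 s | ≥ 8 samples per kernel SD; sub-merge-window resolution |
| bootstrap iterations | 500 | null sample size for the threshold |
| critical probability | 0.95 | quantile of the pooled null |
| merge window | 0.8 s | reaction-time differences not treated as distinct events |
| SA bin width | 1 s | binning of the agreement series |
| PELT penalty | 3 ln n | BIC-style: two segment parameters + the changepoint |
| MAD screening | b = 1.4826, threshold 3 | per-metric outlier blanking |
| norms coverage floor | 0.5 | below it AoA/familiarity means are unreliable |

The bootstrap's pooled-quantile convention treats every grid point of every
iteration as one null observation; a stricter family-wise alternative
(quantile of per-iteration curve maxima) is available as
`BootstrapSpec(scheme="max")`. Kernels are truncated at ±4 SD, which
perturbs any magnitude value by less than 4 × 10⁻⁴. The variance in the
PELT cost is floored at 10⁻⁸ so exactly-constant segments remain
well-defined; PELT pruning is exact for this cost (pruning constant zero),
so results equal exhaustive search. Windows of adjacent events may overlap;
overlaps are logged, not truncated. Event-window membership is closed on
both endpoints and compared in continuous time.

## The synthetic generator

`emoseg.synthetic` emulates the generative structure the analysis assumes:
per clip, a set of latent true emotion-change events; per observer, a hit
probability (each event independently detected), Gaussian timing jitter on
hits (clipped to the clip, preserving counts, with provenance retained),
Poisson false alarms at uniform times, and a personal vocabulary — a seeded
subset of a 60-word lexicon (10 words per basic-emotion tag with fixed,
invented norms and 12-dimension embeddings whose argmax recovers the tag).
Hit labels prefer words matching the event's emotion tag, with a
`label_noise` probability of an off-tag word.

The default configuration (`study_conditions()`) mirrors a study-shaped
session: six affective clips of 75/174/127/179/69/141 s and three
non-affective clips of 115/49/45 s, latent events at roughly one per 24 s,
heterogeneous hit probabilities uniform on 0.2–0.9, jitter SD 0.3 s, 0.5
false alarms per clip, vocabulary sizes 6–30, label noise 0.2, and 50
participants — a desk-scale sample chosen so the full pipeline (including
bootstraps) runs in seconds while leaving enough participants for stable
rank correlations.

What the generator does **not** emulate: stimulus-driven temporal structure
(events are conditionally independent given the clip), serial dependence or
fatigue within a session, shared semantic drift between participants'
labels (labels are conditionally independent given the event tag), response
omission correlated with event salience, and any relation between a
participant's vocabulary and their detection ability. Passing tests
therefore demonstrate that the estimators recover the parameters of this
idealized observer model — not that human data satisfy the model.

## Verification strategy

Every scaled or optimized statistic is checked against an independent
route: the SA ideal-placement maximum against exhaustive enumeration of all
pause placements; PELT against brute-force optimal segmentation; the
bootstrap threshold against a naive untruncated re-implementation sharing
the seed protocol; omega against its closed form on a constructed one-factor
correlation matrix (loadings 0.8 → ω = 23.04/25.20 ≈ 0.914) and against
simulation; ICC against hand-assembled ANOVA mean squares and pingouin;
partial rank correlations against pingouin. Calibration and recovery are
property-tested: uniform-keypress data exceed the 0.95 threshold on ≈ 5% of
grid points (±2 points over 50 replicates); with 50 observers, five latent
events, hit 0.9 and jitter 0.3 s, all five events are recovered within 1 s
in ≥ 90% of replicates; CEA rank-tracks true hit probability and NUL
rank-tracks vocabulary size (the latter tested on vocabularies of 2–16
words, because with only a handful of labels per clip larger vocabularies
saturate the unique-label count).

## Known limitations

- The lemmatizer's suffix rules are minimal by design; words outside the
  merge table may lemmatize imperfectly (e.g. "startled" without the table).
  Extend `resources/lemma_overrides.tsv` for new label corpora.
- SA is undefined (missing) for participants whose binary series or whose
  group density has zero variance on a clip.
- The bootstrap null ignores inter-participant timing structure beyond pause
  counts; it answers "how high does magnitude get by chance", not "are these
  events independent".
- SDS is exploratory: its emotion-assignment step is sensitive to the
  embedding's dimension scaling, and the score has not proven robust.
- Omega's one-factor model is a modeling choice; for trial sets with strong
  multidimensional structure the estimate is a lower-bound-style summary
  rather than a faithful decomposition.
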