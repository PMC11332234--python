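"""Synthetic segmentation datasets with known ground truth.

The generator emulates the structure of an emotion-segmentation study: a set
of video stimuli with latent true emotion-change events, observers who detect
each event with some probability and respond with Gaussian timing jitter,
uniform false-alarm pauses, and free-text labels drawn from participant
vocabularies sampled out of a fixed emotion lexicon with known norms and
embeddings. Every stage of the analysis pipeline is thereby testable against
ground truth without any external data.

The shipped lexicon (60 words, 10 per basic-emotion tag) carries invented
but fixed age-of-acquisition / familiarity values and 12-dimension
embeddings; the values are arbitrary constants used only relationally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusEvent
from .io import Dataset, SegmentationRecord, StimulusInfo
from .vocabulary import EmbeddingSpace, NormsTable

EMOTION_TAGS = ("anger", "disgust", "fear", "happiness", "sadness", "surprise")

# word, tag, age of acquisition (years), familiarity (1-7 rating)
_LEXICON_ROWS = [
    ("anger", "anger", 4.5, 6.8), ("rage", "anger", 8.0, 5.6),
    ("fury", "anger", 9.5, 4.9), ("annoyance", "anger", 7.5, 5.8),
    ("frustration", "anger", 8.5, 6.2), ("irritation", "anger", 9.0, 5.7),
    ("resentment", "anger", 11.5, 4.6), ("outrage", "anger", 10.5, 5.0),
    ("hostility", "anger", 12.0, 4.4), ("exasperation", "anger", 13.0, 3.8),
    ("disgust", "disgust", 6.0, 6.0), ("revulsion", "disgust", 13.5, 3.5),
    ("contempt", "disgust", 12.5, 4.2), ("loathing", "disgust", 12.0, 3.9),
    ("distaste", "disgust", 11.0, 4.5), ("repulsion", "disgust", 12.5, 3.9),
    ("aversion", "disgust", 13.0, 4.0), ("scorn", "disgust", 11.5, 4.1),
    ("disdain", "disgust", 12.5, 4.0), ("nausea", "disgust", 9.0, 5.4),
    ("fear", "fear", 4.0, 6.9), ("anxiety", "fear", 9.0, 6.3),
    ("terror", "fear", 8.5, 5.5), ("dread", "fear", 10.0, 4.9),
    ("panic", "fear", 8.0, 6.0), ("worry", "fear", 5.5, 6.7),
    ("apprehension", "fear", 13.5, 3.9), ("unease", "fear", 11.0, 4.6),
    ("fright", "fear", 6.5, 5.6), ("alarm", "fear", 7.0, 6.1),
    ("happiness", "happiness", 3.5, 7.0), ("joy", "happiness", 5.0, 6.6),
    ("delight", "happiness", 7.5, 5.8), ("amusement", "happiness", 8.0, 5.7),
    ("excitement", "happiness", 5.5, 6.7), ("contentment", "happiness", 11.0, 4.8),
    ("pride", "happiness", 7.0, 6.2), ("relief", "happiness", 7.5, 6.3),
    ("affection", "happiness", 9.0, 5.6), ("pleasure", "happiness", 8.0, 6.1),
    ("sadness", "sadness", 4.0, 6.8), ("grief", "sadness", 9.5, 5.3),
    ("sorrow", "sadness", 9.0, 5.0), ("disappointment", "sadness", 7.5, 6.2),
    ("despair", "sadness", 11.0, 4.7), ("misery", "sadness", 9.5, 5.2),
    ("loneliness", "sadness", 7.0, 6.0), ("gloom", "sadness", 10.0, 4.5),
    ("regret", "sadness", 9.5, 5.8), ("hurt", "sadness", 4.5, 6.6),
    ("surprise", "surprise", 4.5, 6.9), ("shock", "surprise", 6.5, 6.3),
    ("astonishment", "surprise", 12.0, 4.3), ("amazement", "surprise", 8.5, 5.5),
    ("confusion", "surprise", 7.0, 6.2), ("disbelief", "surprise", 10.0, 5.1),
    ("wonder", "surprise", 6.0, 6.2), ("bewilderment", "surprise", 13.5, 3.6),
    ("startle", "surprise", 9.0, 4.8), ("awe", "surprise", 10.5, 4.9),
]

_EMBEDDING_SEED = 20211201  # fixture constant; the embedding is part of the lexicon
_N_EXTRA_DIMS = 6


@dataclass(frozen=True)
class LexiconWord:
    word: str
    tag: str
    aoa: float
    familiarity: float


def default_lexicon() -> list[LexiconWord]:
    return [LexiconWord(*row) for row in _LEXICON_ROWS]


def build_norms(lexicon: list[LexiconWord] | None = None) -> NormsTable:
    lex = lexicon if lexicon is not None else default_lexicon()
    return NormsTable(
        aoa={w.word: w.aoa for w in lex},
        familiarity={w.word: w.familiarity for w in lex},
    )


def build_embedding(lexicon: list[LexiconWord] | None = None) -> EmbeddingSpace:
    """12-dimension embedding: loading ~1 on the word's own emotion tag,
    small fixed loadings elsewhere, so argmax over the six tag dimensions
    recovers the tag. Deterministic (fixture constant)."""
    lex = lexicon if lexicon is not None else default_lexicon()
    dims = list(EMOTION_TAGS) + [f"affect_dim{i+1}" for i in range(_N_EXTRA_DIMS)]
    rng = np.random.default_rng(_EMBEDDING_SEED)
    vectors = {}
    for w in lex:
        v = rng.uniform(0.0, 0.4, len(dims))
        v[dims.index(w.tag)] = 1.0 + rng.uniform(0.0, 0.4)
        vectors[w.word] = v
    return EmbeddingSpace(vectors, dims)


@dataclass(frozen=True)
class SyntheticStimulus:
    stimulus_id: str
    duration: float
    event_times: tuple[float, ...]
    event_tags: tuple[str, ...]
    block: str = "affective"

    def __post_init__(self) -> None:
        if any(t < 0 or t > self.duration for t in self.event_times):
            raise ValueError("event times must lie within the stimulus duration")
        if len(self.event_tags) != len(self.event_times):
            raise ValueError("one emotion tag per event required")


def _evenly_spaced_events(duration: float, rate_s: float = 24.0) -> tuple[float, ...]:
    n = max(1, round(duration / rate_s))
    return tuple((i + 1) * duration / (n + 1) for i in range(n))


def study_conditions(n_participants: int = 50) -> "SyntheticConfig":
    """Default study-shaped configuration: six affective clips with the
    canonical durations (75/174/127/179/69/141 s) and three non-affective
    clips (115/49/45 s), true events at roughly one per 24 s."""
    stimuli = []
    for i, dur in enumerate((75.0, 174.0, 127.0, 179.0, 69.0, 141.0)):
        ev = _evenly_spaced_events(dur)
        tags = tuple(EMOTION_TAGS[(i + k) % len(EMOTION_TAGS)] for k in range(len(ev)))
        stimuli.append(SyntheticStimulus(f"aff{i+1}", dur, ev, tags, "affective"))
    for i, dur in enumerate((115.0, 49.0, 45.0)):
        ev = _evenly_spaced_events(dur)
        stimuli.append(SyntheticStimulus(f"ctrl{i+1}", dur, ev, ("",) * len(ev), "non_affective"))
    return SyntheticConfig(n_participants=n_participants, stimuli=tuple(stimuli))


@dataclass(frozen=True)
class SyntheticConfig:
    """Generative parameters of a synthetic segmentation study.

    ``hit_prob`` / ``vocab_size`` may be scalars (every participant alike) or
    (low, high) ranges sampled per participant. ``false_alarm_rate`` is the
    expected number of spurious pauses per participant per clip (Poisson,
    uniform times). ``label_noise`` is the probability that a detected
    event's label is drawn off-tag.
    """

    n_participants: int = 50
    stimuli: tuple[SyntheticStimulus, ...] = ()
    hit_prob: float | tuple[float, float] = (0.2, 0.9)
    jitter_sd: float = 0.3
    false_alarm_rate: float = 0.5
    vocab_size: int | tuple[int, int] = (6, 30)
    label_noise: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter_sd < 0 or self.false_alarm_rate < 0:
            raise ValueError("jitter_sd and false_alarm_rate must be non-negative")
        lo = self.hit_prob[0] if isinstance(self.hit_prob, tuple) else self.hit_prob
        hi = self.hit_prob[1] if isinstance(self.hit_prob, tuple) else self.hit_prob
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("hit_prob must lie in [0, 1]")
        vlo = self.vocab_size[0] if isinstance(self.vocab_size, tuple) else self.vocab_size
        if vlo < 1:
            raise ValueError("vocabulary must contain at least one word")


@dataclass
class GroundTruth:
    """Realized per-participant parameters and per-record provenance."""

    config: SyntheticConfig
    participants: pd.DataFrame  # participant_id, hit_prob, vocab_size
    vocabularies: dict[str, list[str]]
    provenance: list[tuple[str, str, str]] = field(default_factory=list)
    # (participant_id, stimulus_id, "hit:<k>" | "fa")

    def true_events(self, stimulus_id: str) -> np.ndarray:
        for st in self.config.stimuli:
            if st.stimulus_id == stimulus_id:
                return np.asarray(st.event_times, dtype=float)
        raise KeyError(stimulus_id)


def _draw(rng: np.random.Generator, value, integer: bool = False):
    if isinstance(value, tuple):
        if integer:
            return int(rng.integers(value[0], value[1] + 1))
        return float(rng.uniform(value[0], value[1]))
    return value


def generate_dataset(
    cfg: SyntheticConfig, lexicon: list[LexiconWord] | None = None
) -> tuple[Dataset, GroundTruth, NormsTable, EmbeddingSpace]:
    """Simulate a full study; byte-identical output for a given seed.

    Each participant detects each true event with their hit probability;
    detected events produce a pause at the event time plus Normal(0,
    jitter_sd), clipped to the clip (clipping preserves counts). False alarms
    are Poisson per clip at uniform times. Affective-block labels come from
    the participant's vocabulary, preferring words tagged with the event's
    emotion; false alarms and off-tag draws use any vocabulary word.
    """
    lex = lexicon if lexicon is not None else default_lexicon()
    words = [w.word for w in lex]
    by_tag: dict[str, list[str]] = {}
    for w in lex:
        by_tag.setdefault(w.tag, []).append(w.word)
    rng = np.random.default_rng(cfg.seed)

    records: list[SegmentationRecord] = []
    provenance: list[tuple[str, str, str]] = []
    prows = []
    vocabularies: dict[str, list[str]] = {}
    width = max(3, len(str(cfg.n_participants)))
    for i in range(cfg.n_participants):
        pid = f"p{i+1:0{width}d}"
        hit_p = _draw(rng, cfg.hit_prob)
        vsize = min(_draw(rng, cfg.vocab_size, integer=True), len(words))
        vocab = list(rng.choice(words, size=vsize, replace=False))
        vocabularies[pid] = vocab
        prows.append({"participant_id": pid, "hit_prob": hit_p, "vocab_size": vsize})
        vocab_tags = {w: next(lw.tag for lw in lex if lw.word == w) for w in vocab}
        for st in cfg.stimuli:
            affective = st.block == "affective"
            for k, (ev_t, ev_tag) in enumerate(zip(st.event_times, st.event_tags)):
                if rng.random() >= hit_p:
                    continue
                t = ev_t + (rng.normal(0.0, cfg.jitter_sd) if cfg.jitter_sd > 0 else 0.0)
                t = float(np.clip(t, 0.0, st.duration))
                label = ""
                if affective:
                    on_tag = [w for w in vocab if vocab_tags[w] == ev_tag]
                    off_tag = [w for w in vocab if vocab_tags[w] != ev_tag]
                    if on_tag and (not off_tag or rng.random() >= cfg.label_noise):
                        label = str(rng.choice(on_tag))
                    else:
                        label = str(rng.choice(off_tag if off_tag else vocab))
                records.append(SegmentationRecord(pid, st.stimulus_id, t, label))
                provenance.append((pid, st.stimulus_id, f"hit:{k}"))
            n_fa = int(rng.poisson(cfg.false_alarm_rate)) if cfg.false_alarm_rate > 0 else 0
            for t in np.sort(rng.uniform(0.0, st.duration, n_fa)):
                label = str(rng.choice(vocab)) if affective else ""
                records.append(SegmentationRecord(pid, st.stimulus_id, float(t), label))
                provenance.append((pid, st.stimulus_id, "fa"))

    stimuli = [StimulusInfo(st.stimulus_id, st.duration, st.block) for st in cfg.stimuli]
    ds = Dataset(records, stimuli)
    truth = GroundTruth(cfg, pd.DataFrame(prows), vocabularies, provenance)
    return ds, truth, build_norms(lex), build_embedding(lex)


@dataclass(frozen=True)
class RecoveryScore:
    n_matched: int
    n_spurious: int
    n_missed: int
    mean_abs_offset: float


def match_events(detected, true_times, tolerance: float) -> RecoveryScore:
    """Greedy one-to-one matching of detected to true event times.

    Candidate pairs within ``tolerance`` are matched in order of increasing
    absolute offset; unmatched detections are spurious, unmatched true events
    missed.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    det = np.asarray(detected, dtype=float)
    tru = np.asarray(true_times, dtype=float)
    pairs = sorted(
        ((abs(d - t), i, j) for i, d in enumerate(det) for j, t in enumerate(tru) if abs(d - t) <= tolerance)
    )
    used_d, used_t, offsets = set(), set(), []
    for off, i, j in pairs:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        offsets.append(off)
    return RecoveryScore(
        n_matched=len(offsets),
        n_spurious=len(det) - len(offsets),
        n_missed=len(tru) - len(offsets),
        mean_abs_offset=float(np.mean(offsets)) if offsets else float("nan"),
    )


def score_recovery(
    events_by_stimulus: dict[str, list[ConsensusEvent]], truth: GroundTruth, tolerance: float = 1.0
) -> RecoveryScore:
    """Pool event-recovery scores over every stimulus in the ground truth."""
    matched = spurious = missed = 0
    offsets: list[float] = []
    for st in truth.config.stimuli:
        det = [e.timestamp for e in events_by_stimulus.get(st.stimulus_id, [])]
        sc = match_events(det, st.event_times, tolerance)
        matched += sc.n_matched
        spurious += sc.n_spurious
        missed += sc.n_missed
        if sc.n_matched:
            offsets.extend([sc.mean_abs_offset] * sc.n_matched)
    return RecoveryScore(matched, spurious, missed, float(np.mean(offsets)) if offsets else float("nan"))
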