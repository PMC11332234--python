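"""Active emotion vocabulary metrics from free-text labels.

Labels are lowercased, stripped of punctuation/digits, tokenized, filtered
against a stopword list, and lemmatized so inflectional and derivational
variants of one emotion word ("anger"/"angry") count as a single label. On
the cleaned lemmas we compute:

* NUL — mean per-stimulus count of unique lemmas;
* AoA / Familiarity — means of published-style lexical norms over a
  participant's pooled unique lemmas;
* SAS — per consensus event, the Pearson correlation between the
  participant's mean label-embedding profile and the group's, averaged over
  the events the participant identified;
* SDS (exploratory) — within-person between-emotion correlations of
  semantic profiles; lower off-diagonal mean = more distinct emotion
  concepts.

The lemmatizer is deliberately simple: an editable derivational merge table
(shipped as a package resource) consulted first, then a few inflectional
suffix rules. Off-the-shelf lemmatizers keep adjective/noun pairs like
angry/anger distinct, which is exactly what the label-count semantics must
avoid.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .consensus import ConsensusEvent
from .io import Dataset

logger = logging.getLogger(__name__)

_PUNCT_DIGIT = re.compile(r"[^a-z\s]+")


def _load_lines(name: str) -> list[str]:
    text = resources.files("emoseg.resources").joinpath(name).read_text(encoding="utf-8")
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def default_stopwords() -> frozenset[str]:
    return frozenset(_load_lines("stopwords_en.txt"))


def default_lemma_overrides() -> dict[str, str]:
    out = {}
    for ln in _load_lines("lemma_overrides.tsv"):
        surface, lemma = ln.split("\t")
        out[surface] = lemma
    return out


def lemmatize(token: str, overrides: dict[str, str] | None = None) -> str:
    """Canonical lemma of a lowercase token: merge table first, then suffix rules."""
    if overrides is None:
        overrides = default_lemma_overrides()
    if token in overrides:
        return overrides[token]
    if token in set(overrides.values()):
        return token  # canonical forms are fixed points
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("s") and not token.endswith(("ss", "us", "is")) and len(token) > 3:
        return token[:-1]
    if token.endswith("ied") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith("ing") and len(token) > 5:
        return token[:-3]
    if token.endswith("ed") and len(token) > 4:
        return token[:-2]
    return token


@dataclass
class CleanLabelSet:
    """Cleaned lemmas (a multiset) plus the tokens dropped during cleaning."""

    lemmas: list[str] = field(default_factory=list)
    dropped: list[str] = field(default_factory=list)

    @property
    def unique(self) -> set[str]:
        return set(self.lemmas)


def clean_labels(
    raw: list[str],
    stopwords: frozenset[str] | None = None,
    custom_stopwords: frozenset[str] = frozenset(),
    overrides: dict[str, str] | None = None,
) -> CleanLabelSet:
    """Lowercase, strip punctuation/digits, tokenize, de-stopword, lemmatize."""
    if stopwords is None:
        stopwords = default_stopwords()
    if overrides is None:
        overrides = default_lemma_overrides()
    drop = stopwords | custom_stopwords
    out = CleanLabelSet()
    for text in raw:
        cleaned = _PUNCT_DIGIT.sub(" ", str(text).lower())
        for tok in cleaned.split():
            if tok in drop:
                out.dropped.append(tok)
            else:
                out.lemmas.append(lemmatize(tok, overrides))
    return out


@dataclass
class NormsTable:
    """Lexical norms lookup: lemma -> (age of acquisition in years, familiarity rating)."""

    aoa: dict[str, float]
    familiarity: dict[str, float]

    @classmethod
    def read_csv(cls, path) -> "NormsTable":
        df = pd.read_csv(path)
        return cls(
            aoa=dict(zip(df["word"].str.lower(), df["aoa"].astype(float))),
            familiarity=dict(zip(df["word"].str.lower(), df["familiarity"].astype(float))),
        )

    def to_frame(self) -> pd.DataFrame:
        words = sorted(self.aoa)
        return pd.DataFrame(
            {"word": words, "aoa": [self.aoa[w] for w in words], "familiarity": [self.familiarity[w] for w in words]}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class EmbeddingSpace:
    """Word embeddings over named emotion dimensions (AffectVec-style layout)."""

    vectors: dict[str, np.ndarray]
    dimensions: list[str]

    def __post_init__(self) -> None:
        d = len(self.dimensions)
        for w, v in self.vectors.items():
            if len(v) != d:
                raise ValueError(f"embedding for {w!r} has {len(v)} dims, expected {d}")

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def profile(self, lemmas) -> np.ndarray | None:
        """Mean embedding of the embeddable lemmas; None if none are covered."""
        vecs = [self.vectors[w] for w in lemmas if w in self.vectors]
        return np.mean(vecs, axis=0) if vecs else None

    @classmethod
    def read_csv(cls, path) -> "EmbeddingSpace":
        df = pd.read_csv(path)
        dims = [c for c in df.columns if c != "word"]
        vectors = {
            str(w).lower(): np.asarray(row, dtype=float)
            for w, row in zip(df["word"], df[dims].to_numpy())
        }
        return cls(vectors, dims)

    def write_csv(self, path) -> None:
        rows = [{"word": w, **dict(zip(self.dimensions, v))} for w, v in sorted(self.vectors.items())]
        pd.DataFrame(rows).to_csv(path, index=False)


def labels_by_stimulus(
    ds: Dataset,
    block: str = "affective",
    stopwords: frozenset[str] | None = None,
    custom_stopwords: frozenset[str] = frozenset(),
) -> dict[tuple[str, str], CleanLabelSet]:
    """Cleaned label sets keyed by (participant_id, stimulus_id)."""
    if stopwords is None:
        stopwords = default_stopwords()
    overrides = default_lemma_overrides()
    stim_ids = {s.stimulus_id for s in ds.stimuli_in_block(block)}
    raw: dict[tuple[str, str], list[str]] = {}
    for r in ds.records:
        if r.stimulus_id in stim_ids and r.label_text:
            raw.setdefault((r.participant_id, r.stimulus_id), []).append(r.label_text)
    return {
        key: clean_labels(texts, stopwords, custom_stopwords, overrides) for key, texts in raw.items()
    }


def compute_nul(ds: Dataset, block: str = "affective", **clean_kwargs) -> dict[str, float]:
    """Number of Unique Labels: unique-lemma count per stimulus, averaged.

    A participant with no labels on some stimulus of the block contributes a
    zero count there; participants with no labels at all get NaN.
    """
    per_stim = labels_by_stimulus(ds, block, **clean_kwargs)
    stim_ids = [s.stimulus_id for s in ds.stimuli_in_block(block)]
    out = {}
    for p in ds.participants:
        counts = [len(per_stim.get((p, sid), CleanLabelSet()).unique) for sid in stim_ids]
        out[p] = float(np.mean(counts)) if counts and any(counts) else float("nan")
    return out


def lexical_complexity(
    lemmas, norms: NormsTable, coverage_floor: float = 0.5
) -> tuple[float, float, float]:
    """Mean AoA and familiarity over a unique lemma set, plus norms coverage.

    Means are taken over the lemmas found in the norms; below the coverage
    floor the means are reported missing (too few lemmas were normed for the
    average to be trustworthy).
    """
    uniq = sorted(set(lemmas))
    if not uniq:
        return float("nan"), float("nan"), 0.0
    known = [w for w in uniq if w in norms.aoa]
    coverage = len(known) / len(uniq)
    if not known or coverage < coverage_floor:
        logger.info("lexical_complexity: coverage %.2f below floor %.2f", coverage, coverage_floor)
        return float("nan"), float("nan"), coverage
    return (
        float(np.mean([norms.aoa[w] for w in known])),
        float(np.mean([norms.familiarity[w] for w in known])),
        coverage,
    )


def lexical_complexity_table(
    ds: Dataset, norms: NormsTable, block: str = "affective", coverage_floor: float = 0.5, **clean_kwargs
) -> pd.DataFrame:
    """Per-participant AoA/familiarity means over pooled unique lemmas."""
    per_stim = labels_by_stimulus(ds, block, **clean_kwargs)
    rows = []
    for p in ds.participants:
        pooled: list[str] = []
        for (pp, _sid), cls_ in per_stim.items():
            if pp == p:
                pooled.extend(cls_.lemmas)
        aoa, fam, cov = lexical_complexity(pooled, norms, coverage_floor)
        rows.append({"participant_id": p, "aoa": aoa, "familiarity": fam, "coverage": cov})
    return pd.DataFrame(rows)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def event_label_lemmas(
    ds: Dataset,
    events_by_stimulus: dict[str, list[ConsensusEvent]],
    block: str = "affective",
    **clean_kwargs,
) -> dict[tuple[str, int], dict[str, list[str]]]:
    """Lemmas each participant produced inside each event window.

    Keyed by (stimulus_id, event index) -> {participant_id: lemmas}. A pause
    belongs to an event when its time lies in the closed window.
    """
    if "stopwords" not in clean_kwargs or clean_kwargs.get("stopwords") is None:
        clean_kwargs["stopwords"] = default_stopwords()
    overrides = default_lemma_overrides()
    stim_ids = [s.stimulus_id for s in ds.stimuli_in_block(block)]
    out: dict[tuple[str, int], dict[str, list[str]]] = {}
    for sid in stim_ids:
        for k, ev in enumerate(events_by_stimulus.get(sid, [])):
            per_p: dict[str, list[str]] = {}
            for r in ds.records:
                if (
                    r.stimulus_id == sid
                    and r.label_text
                    and ev.window_start <= r.pause_time <= ev.window_end
                ):
                    cl = clean_labels([r.label_text], overrides=overrides, **clean_kwargs)
                    if cl.lemmas:
                        per_p.setdefault(r.participant_id, []).extend(cl.lemmas)
            out[(sid, k)] = per_p
    return out


def compute_sas(
    ds: Dataset,
    events_by_stimulus: dict[str, list[ConsensusEvent]],
    embedding: EmbeddingSpace,
    block: str = "affective",
    leave_one_out: bool = False,
    **clean_kwargs,
) -> dict[str, float]:
    """Semantic Agreement Score per participant.

    For each consensus event the participant identified (>= 1 embeddable
    lemma inside the window), correlate the participant's mean embedding
    profile with the group profile — the mean over all labels produced for
    that event (their own included unless ``leave_one_out``). The score is
    the mean per-event correlation pooled over all events of all stimuli.
    """
    by_event = event_label_lemmas(ds, events_by_stimulus, block, **clean_kwargs)
    scores: dict[str, list[float]] = {p: [] for p in ds.participants}
    for (_sid, _k), per_p in by_event.items():
        group_lemmas = [w for lem in per_p.values() for w in lem]
        for p, lemmas in per_p.items():
            ind = embedding.profile(lemmas)
            if ind is None:
                continue
            pool = (
                [w for q, lem in per_p.items() if q != p for w in lem]
                if leave_one_out
                else group_lemmas
            )
            grp = embedding.profile(pool)
            if grp is None:
                continue
            r = _pearson(ind, grp)
            if np.isfinite(r):
                scores[p].append(r)
            else:
                logger.info("compute_sas: zero-variance profile at an event, skipped")
    return {p: float(np.mean(v)) if v else float("nan") for p, v in scores.items()}


def compute_sds(
    pooled_lemmas: list[str], emotion_set: list[str], embedding: EmbeddingSpace
) -> tuple[pd.DataFrame, float]:
    """Semantic Distinctiveness Score (exploratory).

    Each lemma is assigned to its maximum-loading emotion among
    ``emotion_set`` dimensions; per-emotion profiles (mean embeddings of
    assigned lemmas) are pairwise Pearson-correlated. Returns the correlation
    matrix (NaN rows for unrepresented emotions) and the off-diagonal mean —
    lower means more distinct emotion concepts. Flagged exploratory: this
    construction was not found robust in validation work.
    """
    dim_idx = [embedding.dimensions.index(e) for e in emotion_set]
    assigned: dict[str, list[str]] = {e: [] for e in emotion_set}
    for w in set(pooled_lemmas):
        if w not in embedding:
            continue
        loadings = embedding.vectors[w][dim_idx]
        assigned[emotion_set[int(np.argmax(loadings))]].append(w)
    profiles = {e: embedding.profile(ws) for e, ws in assigned.items()}
    n = len(emotion_set)
    mat = np.full((n, n), np.nan)
    for i, a in enumerate(emotion_set):
        for j, b in enumerate(emotion_set):
            if profiles[a] is not None and profiles[b] is not None:
                mat[i, j] = 1.0 if i == j else _pearson(profiles[a], profiles[b])
    off = mat[~np.eye(n, dtype=bool)]
    off = off[np.isfinite(off)]
    summary = float(np.mean(off)) if len(off) else float("nan")
    return pd.DataFrame(mat, index=emotion_set, columns=emotion_set), summary
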