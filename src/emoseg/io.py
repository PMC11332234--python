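"""Data model and tabular I/O for segmentation experiments.

The interchange format is plain delimited text (comma-separated, UTF-8,
header row). The canonical record table has one row per pause::

    participant_id, stimulus_id, pause_time_s, label_text

and the stimulus table one row per clip::

    stimulus_id, duration_s, block      # block in {"affective", "non_affective"}

A *dialect* mapping lets callers read tables whose columns carry other
names (``{"participant_id": "subj", ...}``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RECORD_COLUMNS = ("participant_id", "stimulus_id", "pause_time_s", "label_text")
STIMULUS_COLUMNS = ("stimulus_id", "duration_s", "block")
BLOCKS = ("affective", "non_affective")


@dataclass(frozen=True)
class SegmentationRecord:
    """One pause event: who paused which stimulus, when, and the free-text label."""

    participant_id: str
    stimulus_id: str
    pause_time: float
    label_text: str = ""

    def __post_init__(self) -> None:
        if not self.participant_id or not self.stimulus_id:
            raise ValueError("participant_id and stimulus_id must be non-empty")
        if not np.isfinite(self.pause_time) or self.pause_time < 0:
            raise ValueError(f"pause_time must be a non-negative real, got {self.pause_time!r}")


@dataclass(frozen=True)
class StimulusInfo:
    """Stimulus metadata: identifier, duration in seconds, and block type."""

    stimulus_id: str
    duration: float
    block: str = "affective"

    def __post_init__(self) -> None:
        if not self.stimulus_id:
            raise ValueError("stimulus_id must be non-empty")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration!r}")
        if self.block not in BLOCKS:
            raise ValueError(f"block must be one of {BLOCKS}, got {self.block!r}")


@dataclass
class Dataset:
    """A validated collection of pause records plus stimulus metadata."""

    records: list[SegmentationRecord]
    stimuli: list[StimulusInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [s.stimulus_id for s in self.stimuli]
        if len(set(ids)) != len(ids):
            raise ValueError("stimulus_ids must be unique")
        by_id = {s.stimulus_id: s for s in self.stimuli}
        for rec in self.records:
            stim = by_id.get(rec.stimulus_id)
            if stim is None:
                raise ValueError(f"record references unknown stimulus {rec.stimulus_id!r}")
            if rec.pause_time > stim.duration:
                raise ValueError(
                    f"pause at {rec.pause_time} s exceeds duration {stim.duration} s "
                    f"of stimulus {rec.stimulus_id!r}"
                )

    @property
    def participants(self) -> list[str]:
        return sorted({r.participant_id for r in self.records})

    def stimuli_in_block(self, block: str) -> list[StimulusInfo]:
        return [s for s in self.stimuli if s.block == block]

    def stimulus(self, stimulus_id: str) -> StimulusInfo:
        for s in self.stimuli:
            if s.stimulus_id == stimulus_id:
                return s
        raise KeyError(stimulus_id)

    def pauses(self, participant_id: str, stimulus_id: str) -> np.ndarray:
        """Sorted pause times (s) of one participant on one stimulus."""
        t = [
            r.pause_time
            for r in self.records
            if r.participant_id == participant_id and r.stimulus_id == stimulus_id
        ]
        return np.sort(np.asarray(t, dtype=float))

    def pauses_by_participant(self, stimulus_id: str) -> dict[str, np.ndarray]:
        out: dict[str, list[float]] = {}
        for r in self.records:
            if r.stimulus_id == stimulus_id:
                out.setdefault(r.participant_id, []).append(r.pause_time)
        return {p: np.sort(np.asarray(t, dtype=float)) for p, t in sorted(out.items())}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.participant_id, r.stimulus_id, r.pause_time, r.label_text) for r in self.records],
            columns=list(RECORD_COLUMNS),
        )

    def stimuli_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.stimulus_id, s.duration, s.block) for s in self.stimuli],
            columns=list(STIMULUS_COLUMNS),
        )


def _apply_dialect(df: pd.DataFrame, dialect: dict[str, str] | None, required: tuple[str, ...]) -> pd.DataFrame:
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing}; available: {list(df.columns)}")
    return df


def read_stimulus_table(path, dialect: dict[str, str] | None = None) -> list[StimulusInfo]:
    """Read stimulus metadata from delimited text."""
    df = _apply_dialect(pd.read_csv(path, float_precision="round_trip"), dialect, STIMULUS_COLUMNS)
    out = [
        StimulusInfo(str(r.stimulus_id), float(r.duration_s), str(r.block))
        for r in df.itertuples(index=False)
    ]
    logger.info("read %d stimuli from %s", len(out), path)
    return out


def read_segmentation_table(
    path,
    stimuli: list[StimulusInfo],
    dialect: dict[str, str] | None = None,
) -> Dataset:
    """Read a pause-record table and validate it against stimulus metadata.

    Rows with non-numeric or negative pause times raise a ``ValueError``
    naming the offending row; duplicated rows are retained with a warning
    (de-duplication is the caller's concern).
    """
    # keep_default_na=False so labels like "nan" or "" survive byte-identically
    df = _apply_dialect(
        pd.read_csv(
            path,
            dtype={"label_text": str},
            keep_default_na=False,
            na_values=[],
            float_precision="round_trip",
        ),
        dialect,
        RECORD_COLUMNS,
    )
    times = pd.to_numeric(df["pause_time_s"], errors="coerce")
    bad = df.index[times.isna() | (times < 0)]
    if len(bad):
        raise ValueError(
            f"unparseable or negative pause_time_s in row(s) {list(bad)} "
            f"(values {df.loc[bad, 'pause_time_s'].tolist()})"
        )
    n_dup = int(df.duplicated().sum())
    if n_dup:
        logger.warning("%d duplicated record row(s) retained in %s", n_dup, path)
    labels = df["label_text"].fillna("")
    records = [
        SegmentationRecord(str(p), str(s), float(t), str(lab))
        for p, s, t, lab in zip(df["participant_id"], df["stimulus_id"], times, labels)
    ]
    ds = Dataset(records, stimuli)
    logger.info("read %d records, %d participants from %s", len(records), len(ds.participants), path)
    return ds


def write_segmentation_table(ds: Dataset, path) -> None:
    ds.to_frame().to_csv(path, index=False)


def write_stimulus_table(ds: Dataset, path) -> None:
    ds.stimuli_frame().to_csv(path, index=False)


def filter_complete_participants(ds: Dataset, block: str = "affective") -> tuple[Dataset, list[str]]:
    """Drop participants lacking a pause on any stimulus of ``block``.

    Mirrors the low-effort screen that removes participants who did not
    segment every clip. Returns the filtered dataset and the removed IDs.
    """
    need = {s.stimulus_id for s in ds.stimuli_in_block(block)}
    seen: dict[str, set[str]] = {}
    for r in ds.records:
        seen.setdefault(r.participant_id, set()).add(r.stimulus_id)
    removed = sorted(p for p, st in seen.items() if not need <= st)
    keep = {p for p in seen if p not in set(removed)}
    out = Dataset([r for r in ds.records if r.participant_id in keep], ds.stimuli)
    if removed:
        logger.info("filter_complete_participants removed %d participant(s): %s", len(removed), removed)
    return out, removed


def detect_outliers_mad(values, b: float = 1.4826, threshold: float = 3.0) -> np.ndarray:
    """Median-absolute-deviation outlier flags over one metric's scores.

    Returns the indices i with ``|x_i - median| > threshold * b * MAD`` where
    ``MAD = median(|x - median|)``. With MAD = 0 every point off the median is
    flagged. NaNs are ignored (never flagged). Requires >= 3 finite values.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("detect_outliers_mad requires at least 3 finite values")
    med = np.median(x[finite])
    mad = np.median(np.abs(x[finite] - med))
    cutoff = threshold * b * mad
    dev = np.abs(x - med)
    flags = finite & (dev > cutoff)
    return np.flatnonzero(flags)


def apply_mad_screening(
    scores: pd.DataFrame, columns: list[str] | None = None, b: float = 1.4826, threshold: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set MAD-flagged cells to missing, per metric across participants.

    Flagged entries are blanked cell-wise (the participant's other metrics are
    kept), so downstream correlations use pairwise-complete observations.
    Returns the screened copy and a boolean mask of removed cells.
    """
    out = scores.copy()
    cols = columns if columns is not None else [c for c in scores.columns if pd.api.types.is_numeric_dtype(scores[c])]
    mask = pd.DataFrame(False, index=scores.index, columns=scores.columns)
    for c in cols:
        col = out[c].to_numpy(dtype=float)
        if np.isfinite(col).sum() < 3:
            continue
        idx = detect_outliers_mad(col, b=b, threshold=threshold)
        if len(idx):
            out.iloc[idx, out.columns.get_loc(c)] = np.nan
            mask.iloc[idx, mask.columns.get_loc(c)] = True
            logger.info("MAD screening removed %d cell(s) from metric %s", len(idx), c)
    return out, mask
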