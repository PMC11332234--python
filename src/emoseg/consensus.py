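"""Group consensus events from kernel-smoothed segmentation magnitude.

Each participant's pauses are smoothed with unit-peak Gaussian kernels
(SD 0.8 s by default); overlapping kernels of one participant combine by
maximum so every participant contributes at most height 1 anywhere, and the
per-participant curves sum to the group segmentation magnitude. Magnitude
therefore reads as "effective number of participants segmenting near t".

Consensus events are local maxima of the group curve that exceed a bootstrap
null threshold (participant pause counts preserved, times redrawn uniformly),
merged when closer than 800 ms. Each event gets a time window bounded by the
nearest mean-variance changepoints of the magnitude series (PELT), and a
participant "identifies" an event when any of their pauses falls inside the
window. Consensus Event Agreement (CEA) is the proportion of all events,
pooled over the analyzed stimuli, that a participant identified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import Dataset

logger = logging.getLogger(__name__)

KERNEL_SD = 0.8         # seconds; Gaussian SD around each keypress
MERGE_WINDOW = 0.8      # seconds; events closer than this are merged
GRID_DT = 0.1           # seconds; magnitude sampling step
KERNEL_TRUNC_SD = 4.0   # kernel support half-width in SDs (error < 4e-4)


@dataclass(frozen=True)
class BootstrapSpec:
    """Null-threshold bootstrap: iterations, critical probability, seed, scheme.

    ``scheme`` selects how the null distribution is summarized: ``"pooled"``
    takes the critical quantile over all grid values of all iterations;
    ``"max"`` takes it over per-iteration curve maxima (a stricter,
    family-wise criterion).
    """

    n_iterations: int = 500
    critical_probability: float = 0.95
    seed: int = 0
    scheme: str = "pooled"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if not 0.0 <= self.critical_probability <= 1.0:
            raise ValueError("critical_probability must lie in [0, 1]")
        if self.scheme not in ("pooled", "max"):
            raise ValueError("scheme must be 'pooled' or 'max'")


@dataclass(frozen=True)
class MagnitudeCurve:
    """Group segmentation magnitude sampled on a regular time grid."""

    stimulus_id: str
    grid: np.ndarray
    values: np.ndarray
    kernel_sd: float = KERNEL_SD

    @property
    def dt(self) -> float:
        return float(self.grid[1] - self.grid[0]) if len(self.grid) > 1 else 0.0


@dataclass(frozen=True)
class ConsensusEvent:
    """A group-agreed emotion-change point with its changepoint-bounded window."""

    stimulus_id: str
    timestamp: float
    window_start: float
    window_end: float
    peak_magnitude: float

    def __post_init__(self) -> None:
        if not self.window_start <= self.timestamp <= self.window_end:
            raise ValueError("event window must contain its timestamp")


def magnitude_grid(duration: float, dt: float = GRID_DT) -> np.ndarray:
    """Regular grid spanning [0, duration] (last point >= duration)."""
    n = int(np.ceil(duration / dt)) + 1
    return np.arange(n) * dt


def participant_magnitude(
    pauses, grid: np.ndarray, kernel_sd: float = KERNEL_SD, out: np.ndarray | None = None
) -> np.ndarray:
    """Unit-peak Gaussian magnitude of one participant; overlaps combine by max.

    Kernels are truncated at ±4 SD; an empty pause list gives the zero vector.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    if out is None:
        out = np.zeros(len(grid), dtype=float)
    else:
        out.fill(0.0)
    half = KERNEL_TRUNC_SD * kernel_sd
    inv = 1.0 / (2.0 * kernel_sd * kernel_sd)
    for p in np.atleast_1d(np.asarray(pauses, dtype=float)):
        lo = np.searchsorted(grid, p - half, side="left")
        hi = np.searchsorted(grid, p + half, side="right")
        if lo >= hi:
            continue
        seg = grid[lo:hi] - p
        np.maximum(out[lo:hi], np.exp(-(seg * seg) * inv), out=out[lo:hi])
    return out


def group_magnitude(
    pauses_by_participant: dict[str, np.ndarray] | list,
    grid: np.ndarray,
    kernel_sd: float = KERNEL_SD,
    stimulus_id: str = "",
) -> MagnitudeCurve:
    """Sum of per-participant magnitude curves on a shared grid."""
    pause_lists = (
        list(pauses_by_participant.values())
        if isinstance(pauses_by_participant, dict)
        else list(pauses_by_participant)
    )
    total = np.zeros(len(grid), dtype=float)
    buf = np.empty(len(grid), dtype=float)
    for pauses in pause_lists:
        total += participant_magnitude(pauses, grid, kernel_sd, out=buf)
    return MagnitudeCurve(stimulus_id, grid, total, kernel_sd)


def bootstrap_threshold(
    pauses_by_participant: dict[str, np.ndarray] | list,
    duration: float,
    spec: BootstrapSpec,
    kernel_sd: float = KERNEL_SD,
    dt: float = GRID_DT,
) -> float:
    """Critical magnitude under a uniform-timing null.

    Each iteration keeps every participant's pause count but redraws the
    times uniformly on [0, duration], recomputes the group curve, and the
    threshold is the ``critical_probability`` quantile of the null values
    (all grid points pooled, or per-iteration maxima under the "max" scheme).
    Deterministic given ``spec.seed``; draw order is iterations outer,
    participants in input order, ``rng.uniform(0, duration, count)`` each.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    pause_lists = (
        list(pauses_by_participant.values())
        if isinstance(pauses_by_participant, dict)
        else list(pauses_by_participant)
    )
    counts = [len(np.atleast_1d(p)) for p in pause_lists]
    if sum(counts) == 0:
        raise ValueError("bootstrap requires at least one pause")
    rng = np.random.default_rng(spec.seed)
    grid = magnitude_grid(duration, dt)
    buf = np.empty(len(grid), dtype=float)
    pooled = []
    for _ in range(spec.n_iterations):
        total = np.zeros(len(grid), dtype=float)
        for c in counts:
            if c == 0:
                continue
            total += participant_magnitude(rng.uniform(0.0, duration, c), grid, kernel_sd, out=buf)
        pooled.append(total.max() if spec.scheme == "max" else total)
    null = np.asarray(pooled) if spec.scheme == "max" else np.concatenate(pooled)
    return float(np.quantile(null, spec.critical_probability))


def find_consensus_timestamps(curve: MagnitudeCurve, threshold: float) -> np.ndarray:
    """Times of local maxima of the magnitude curve exceeding the threshold.

    Plateau maxima are reported at their midpoint; grid endpoints are not
    peaks. Returns a sorted (possibly empty) array of times in seconds.
    """
    if len(curve.values) == 0:
        return np.asarray([], dtype=float)
    peaks, props = find_peaks(curve.values, plateau_size=1)
    mids = []
    for i, left, right in zip(peaks, props["left_edges"], props["right_edges"]):
        if curve.values[i] > threshold:
            mids.append(0.5 * (curve.grid[left] + curve.grid[right]))
    return np.asarray(sorted(mids), dtype=float)


def merge_events(timestamps, merge_window: float = MERGE_WINDOW) -> np.ndarray:
    """Merge event timestamps closer than ``merge_window`` (transitive chains).

    Single-linkage clustering on consecutive gaps < merge_window; each cluster
    is replaced by the mean of its members. Idempotent on its own output in
    the sense that re-merging changes nothing when cluster means stay apart.
    """
    t = np.sort(np.asarray(timestamps, dtype=float))
    if len(t) == 0:
        return t
    merged, cluster = [], [t[0]]
    for x in t[1:]:
        if x - cluster[-1] < merge_window:
            cluster.append(x)
        else:
            merged.append(np.mean(cluster))
            cluster = [x]
    merged.append(np.mean(cluster))
    return np.asarray(merged, dtype=float)


# --- PELT changepoint detection (normal mean+variance cost) ---------------

_VAR_FLOOR = 1e-8  # variance guard for constant segments


def _segment_cost_factory(x: np.ndarray):
    """Twice negative Gaussian log-likelihood of x[i:j] with MLE mean and variance."""
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def cost(i: int, j: int) -> float:
        n = j - i
        mean = (s1[j] - s1[i]) / n
        var = max((s2[j] - s2[i]) / n - mean * mean, _VAR_FLOOR)
        return n * (np.log(2.0 * np.pi) + np.log(var) + 1.0)

    return cost


def default_pelt_penalty(n: int) -> float:
    """BIC-style penalty for a mean+variance change: 3 log n (two segment
    parameters plus the changepoint location)."""
    return 3.0 * np.log(n)


def pelt_meanvar(values, penalty: float | None = None, min_size: int = 2) -> list[int]:
    """Optimal mean–variance changepoints of a series via the PELT recurrence.

    Returns sorted indices k (0 < k < n) at which a new segment starts; the
    segmentation minimizes total Gaussian cost plus ``penalty`` per
    changepoint. Exact (same optimum as exhaustive search) because the
    pruning constant for this cost is zero.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 2 * min_size:
        return []
    if penalty is None:
        penalty = default_pelt_penalty(n)
    cost = _segment_cost_factory(x)
    f = np.full(n + 1, np.inf)
    f[0] = -penalty
    last = np.zeros(n + 1, dtype=int)
    candidates = [0]
    for t in range(min_size, n + 1):
        best, arg = np.inf, 0
        vals = []
        for s in candidates:
            if t - s < min_size:
                vals.append(np.inf)
                continue
            v = f[s] + cost(s, t) + penalty
            vals.append(v)
            if v < best:
                best, arg = v, s
        f[t], last[t] = best, arg
        # PELT pruning: s cannot be optimal for any t' > t if f[s]+C(s,t) > f[t]
        candidates = [s for s, v in zip(candidates, vals) if v - penalty <= f[t] or t - s < min_size]
        candidates.append(t)
    cps = []
    t = n
    while t > 0:
        s = last[t]
        if s > 0:
            cps.append(s)
        t = s
    return sorted(cps)


def compute_event_windows(
    curve: MagnitudeCurve, timestamps, penalty: float | None = None
) -> list[ConsensusEvent]:
    """Bound each consensus timestamp by its nearest changepoints.

    PELT runs once on the full magnitude series; for each timestamp the
    window runs from the nearest changepoint at or before it to the nearest
    changepoint after it, falling back to the stimulus boundaries. Windows of
    nearby events may overlap (overlaps are logged, not truncated).
    """
    ts = np.asarray(timestamps, dtype=float)
    cps = pelt_meanvar(curve.values, penalty=penalty)
    cp_times = curve.grid[cps] if cps else np.asarray([])
    if len(cp_times) == 0 and len(ts):
        logger.info("no changepoints found on %s: whole-stimulus windows", curve.stimulus_id or "curve")
    t0, t1 = float(curve.grid[0]), float(curve.grid[-1])
    events = []
    for t in ts:
        before = cp_times[cp_times <= t]
        after = cp_times[cp_times > t]
        start = float(before[-1]) if len(before) else t0
        end = float(after[0]) if len(after) else t1
        peak = float(np.interp(t, curve.grid, curve.values))
        events.append(ConsensusEvent(curve.stimulus_id, float(t), start, end, peak))
    for a, b in zip(events, events[1:]):
        if b.window_start < a.window_end:
            logger.info("overlapping event windows at %.2f s and %.2f s", a.timestamp, b.timestamp)
    return events


def consensus_events_for_stimulus(
    pauses_by_participant: dict[str, np.ndarray],
    duration: float,
    spec: BootstrapSpec,
    stimulus_id: str = "",
    kernel_sd: float = KERNEL_SD,
    dt: float = GRID_DT,
    merge_window: float = MERGE_WINDOW,
    penalty: float | None = None,
) -> tuple[list[ConsensusEvent], MagnitudeCurve, float]:
    """Full consensus chain for one stimulus: curve, threshold, events."""
    grid = magnitude_grid(duration, dt)
    curve = group_magnitude(pauses_by_participant, grid, kernel_sd, stimulus_id)
    threshold = bootstrap_threshold(pauses_by_participant, duration, spec, kernel_sd, dt)
    stamps = merge_events(find_consensus_timestamps(curve, threshold), merge_window)
    events = compute_event_windows(curve, stamps, penalty)
    logger.info(
        "stimulus %s: threshold %.3f, %d consensus event(s)", stimulus_id or "?", threshold, len(events)
    )
    return events, curve, threshold


def cea_trial_matrix(
    ds: Dataset, events_by_stimulus: dict[str, list[ConsensusEvent]], block: str = "affective"
):
    """Per-stimulus identified-event proportions (participants x stimuli).

    The per-trial analogue of CEA used for internal-reliability estimates;
    stimuli without consensus events yield a missing column.
    """
    stim_ids = [s.stimulus_id for s in ds.stimuli_in_block(block)]
    rows = {}
    for p in ds.participants:
        row = {}
        for sid in stim_ids:
            evs = events_by_stimulus.get(sid, [])
            if not evs:
                row[sid] = float("nan")
                continue
            pauses = ds.pauses(p, sid)
            hit = sum(
                1 for ev in evs if np.any((pauses >= ev.window_start) & (pauses <= ev.window_end))
            )
            row[sid] = hit / len(evs)
        rows[p] = row
    return pd.DataFrame.from_dict(rows, orient="index")[stim_ids]


def compute_cea(
    ds: Dataset, events_by_stimulus: dict[str, list[ConsensusEvent]], block: str = "affective"
) -> dict[str, float]:
    """Consensus Event Agreement per participant.

    An event counts as identified when at least one of the participant's
    pauses on that stimulus lies inside the closed event window; CEA is the
    identified proportion pooled over all events of all analyzed stimuli.
    """
    stim_ids = [s.stimulus_id for s in ds.stimuli_in_block(block)]
    all_events = [(sid, ev) for sid in stim_ids for ev in events_by_stimulus.get(sid, [])]
    if not all_events:
        logger.warning("compute_cea: no consensus events in block %r", block)
        return {p: float("nan") for p in ds.participants}
    out = {}
    for p in ds.participants:
        pauses = {sid: ds.pauses(p, sid) for sid in stim_ids}
        hit = sum(
            1
            for sid, ev in all_events
            if np.any((pauses[sid] >= ev.window_start) & (pauses[sid] <= ev.window_end))
        )
        out[p] = hit / len(all_events)
    return out
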